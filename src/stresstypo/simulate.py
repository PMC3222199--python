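"""Synthetic mixed-type questionnaire cohorts with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that the whole pipeline can run -- and be validated against known
truth -- without any external data:

* two independent standard-normal latent factors (perceived stress and
  perceived control) drive the four ordinal perception scales through a
  fixed loading pattern;
* three independent lifestyle factors (activity, smoking, alcohol) drive the
  nine lifestyle variables (ordinal habit items plus numeric MET volumes,
  with weekly total = walking + moderate + vigorous structurally);
* biochemistry, blood pressure and anthropometrics are drawn per sex from
  configurable mean/SD targets; triglycerides use a moment-matched lognormal
  and MET volumes a zero-censored normal (zero-heavy and right-skewed, the
  shape of self-reported weekly activity);
* reported absenteeism is a zero-inflated negative binomial count linked to
  the stress factor through a Gaussian copula;
* optionally, subject typologies are planted as centroids in the
  6-dimensional classification space (5 latents + absenteeism), and extreme
  outlier rows are injected (by default one 300-lost-days respondent plus a
  tight group of five heavy smokers/drinkers).

Ordinal items are produced by cutting the latent-driven continuous item
score at empirical quantiles (equal-probability by default, or at supplied
marginal frequencies), so declared category counts and orders always hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .schema import CohortTable, VariableSpec, DEFAULT_PLAUSIBLE_RANGES


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# default study conditions

PERCEPTION_LATENTS = ("stress", "control")
LIFESTYLE_LATENTS = ("activity", "smoking", "alcohol")
CLASSIFICATION_VARS = ("stress", "control", "activity", "smoking", "alcohol", "lost_days")

#: loading pattern of the four perception scales on (stress, control)
DEFAULT_PERCEPTION_LOADINGS: dict[str, tuple[float, float]] = {
    "fourq": (0.885, -0.033),
    "stress_scale": (0.870, -0.129),
    "fatigue_scale": (0.885, -0.172),
    "control_scale": (0.310, 0.949),
}

#: loading pattern of lifestyle variables on (activity, smoking, alcohol);
#: met_total is generated structurally as the sum of the three MET columns
DEFAULT_LIFESTYLE_LOADINGS: dict[str, tuple[float, float, float]] = {
    "smoking_habit": (-0.067, 0.961, -0.200),
    "intend_quit": (-0.079, 0.958, -0.205),
    "met_walk": (0.571, 0.102, 0.078),
    "met_moderate": (0.710, -0.029, -0.085),
    "met_vigorous": (0.773, 0.043, -0.040),
    "activity_freq": (0.716, -0.032, -0.112),
    "wine_beer": (0.094, 0.202, 0.816),
    "alcohol": (0.065, 0.265, 0.802),
}

ORDINAL_CATEGORIES: dict[str, tuple[str, ...]] = {
    "smoking_habit": (
        "nonsmoker",
        "quit >1 year",
        "quit <1 year",
        "<=5/day",
        "6-10/day",
        "11-20/day",
        ">20/day",
    ),
    "intend_quit": ("not applicable", "does not intend", "in 6 months", "now"),
    "activity_freq": (
        "none",
        "would like to",
        "sometimes",
        "1 hour/week",
        "3x30 min/week",
        "5x30 min/week",
        "daily",
    ),
    "wine_beer": ("none", "1-2", "3-7", "8-14", "15-21", "22-30", ">30"),
    "alcohol": ("none", "1-2", "3-7", "8-14"),
    "fourq": tuple(str(i) for i in range(21)),
    "stress_scale": tuple(str(i) for i in range(11)),
    "fatigue_scale": tuple(str(i) for i in range(11)),
    "control_scale": tuple(str(i) for i in range(11)),
}

#: per-sex (mean, SD) targets for reported biochemistry and anthropometrics;
#: "lognormal" columns are moment-matched lognormals (right-skewed)
DEFAULT_BIOCHEM_PARAMS: dict[str, dict] = {
    "total_chol": {"male": (203.92, 38.76), "female": (201.43, 36.07), "dist": "normal"},
    "hdl": {"male": (56.68, 23.13), "female": (68.79, 21.70), "dist": "normal"},
    "triglycerides": {"male": (123.16, 74.44), "female": (88.88, 53.91), "dist": "lognormal"},
    "glucose": {"male": (91.89, 17.79), "female": (85.34, 11.90), "dist": "normal"},
    "sbp": {"male": (124.51, 10.17), "female": (118.06, 12.50), "dist": "normal"},
    "dbp": {"male": (79.44, 7.20), "female": (76.15, 9.12), "dist": "normal"},
    "heart_rate": {"male": (69.22, 10.15), "female": (72.37, 9.70), "dist": "normal"},
    "weight": {"male": (79.72, 11.57), "female": (63.55, 11.43), "dist": "normal"},
    "height": {"male": (176.02, 6.00), "female": (164.78, 6.18), "dist": "normal"},
    "waist": {"male": (93.76, 10.30), "female": (81.63, 11.98), "dist": "normal"},
}

#: lognormal (mean, SD) targets for weekly MET-minutes columns
DEFAULT_MET_PARAMS: dict[str, tuple[float, float]] = {
    "met_walk": (436.17, 451.37),
    "met_moderate": (378.38, 445.24),
    "met_vigorous": (551.59, 822.88),
}

#: published marginal frequencies of the lifestyle items, for configs that
#: mimic the survey's skew (rare heavy-consumption categories) instead of
#: the default equal-probability cuts
STUDY_ITEM_MARGINALS: dict[str, tuple[float, ...]] = {
    "smoking_habit": (0.704, 0.114, 0.022, 0.044, 0.051, 0.050, 0.015),
    "intend_quit": (0.828, 0.056, 0.047, 0.069),
    "activity_freq": (0.138, 0.258, 0.105, 0.141, 0.180, 0.111, 0.067),
    "wine_beer": (0.220, 0.328, 0.278, 0.124, 0.034, 0.010, 0.006),
    "alcohol": (0.789, 0.186, 0.022, 0.003),
}

DEFAULT_AGE_PROBS = {"<35": 0.119, "35-44": 0.280, "45-54": 0.470, ">54": 0.131}
DEFAULT_WORK_PROBS = {
    "blue collar": 0.037,
    "junior white collar": 0.546,
    "senior white collar": 0.375,
    "manager": 0.042,
}
DEFAULT_ILLNESS_PROBS = {"none": 0.633, "functional": 0.120, "organic": 0.247}


@dataclass(frozen=True)
class AbsenteeismParams:
    """Zero-inflated negative binomial absenteeism, copula-linked to stress.

    Defaults target a yearly lost-days distribution whose full-cohort mean
    and SD (including the injected 300-day extreme case) are ~5.9 and ~14.8,
    with a Pearson correlation of about 0.2 with the stress factor.
    """

    zero_inflation: float = 0.5
    nb_mean: float = 10.9
    nb_var: float = 125.0
    stress_link: float = 0.30  # copula coefficient on the stress factor

    @property
    def nb_size(self) -> float:
        return self.nb_mean**2 / (self.nb_var - self.nb_mean)


@dataclass(frozen=True)
class TypologySpec:
    """Planted cluster structure in the 6-d classification space."""

    centroids: tuple  # k rows of 6 values: stress, control, activity, smoking, alcohol, absenteeism shift
    weights: tuple
    labels: tuple = ()

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise SimulationError("typology mixing weights must sum to 1")
        if len(self.centroids) != len(self.weights):
            raise SimulationError("centroids and weights must have equal length")


#: seven typologies of the kind the analysis discovers: heavy drinkers,
#: heavy smokers, high stress, physically active, high control, low
#: stress-and-control, and a small absentee group.  Minimum pairwise centroid
#: separation ~3.7 within-cluster SDs.
DEFAULT_TYPOLOGIES = TypologySpec(
    centroids=(
        (0.0, 0.0, 0.0, 0.5, 3.5, 0.0),
        (0.0, 0.0, -0.5, 3.5, 0.0, 0.0),
        (3.0, -1.0, -0.5, 0.0, 0.0, 0.5),
        (-1.0, 0.0, 3.2, 0.0, 0.0, 0.0),
        (-0.5, 3.0, 0.0, 0.0, 0.0, 0.0),
        (-1.5, -1.8, 0.0, 0.0, 0.0, 0.0),
        (0.5, 0.0, 0.0, 0.0, 0.0, 3.8),
    ),
    weights=(0.133, 0.145, 0.130, 0.084, 0.287, 0.191, 0.030),
    labels=(
        "alcohol",
        "smoking",
        "high stress",
        "physical activity",
        "high control",
        "low stress and control",
        "absenteeism",
    ),
)


@dataclass(frozen=True)
class OutlierSpec:
    """Injected extreme rows: a tight small group plus one isolated subject."""

    group_size: int = 5
    group_latents: tuple = (2.5, 0.0, -0.5, 4.5, 9.0)  # stress..alcohol
    group_lost_days: float = 45.0
    group_noise_sd: float = 0.3
    isolated_latents: tuple = (3.27, 0.0, -1.14, 0.0, 0.0)
    isolated_lost_days: float = 300.0


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; defaults are the study conditions."""

    n: int = 683
    male_fraction: float = 495 / 683
    perception_loadings: dict = field(
        default_factory=lambda: dict(DEFAULT_PERCEPTION_LOADINGS)
    )
    lifestyle_loadings: dict = field(
        default_factory=lambda: dict(DEFAULT_LIFESTYLE_LOADINGS)
    )
    item_marginals: dict = field(default_factory=dict)  # name -> category probs
    biochem_params: dict = field(default_factory=lambda: dict(DEFAULT_BIOCHEM_PARAMS))
    met_params: dict = field(default_factory=lambda: dict(DEFAULT_MET_PARAMS))
    absenteeism: AbsenteeismParams = field(default_factory=AbsenteeismParams)
    typology_spec: TypologySpec | None = field(default_factory=lambda: DEFAULT_TYPOLOGIES)
    outlier_spec: OutlierSpec | None = field(default_factory=OutlierSpec)
    #: additive shifts on the female probability per planted typology index
    gender_links: dict = field(default_factory=lambda: {0: -0.12, 2: 0.20, 6: 0.15})
    #: probability mass moved from "none" to illness per planted typology index
    illness_links: dict = field(default_factory=lambda: {2: 0.20, 6: 0.25})
    #: cross-link of lifestyle factors into metabolic components (default off)
    mes_lifestyle_link: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.male_fraction <= 1.0):
            raise SimulationError("male_fraction must lie in [0, 1]")
        for name, row in {**self.perception_loadings, **self.lifestyle_loadings}.items():
            if sum(l * l for l in row) >= 1.0:
                raise SimulationError(
                    f"infeasible loadings for {name!r}: implied noise variance <= 0"
                )


@dataclass
class GeneratedCohort:
    table: CohortTable
    truth: pd.DataFrame  # latents, typology, outlier flag per row
    config: CohortConfig

    def classification_frame(self) -> pd.DataFrame:
        """The six classification columns: true indicator values + lost days."""
        out = self.truth[list(PERCEPTION_LATENTS) + list(LIFESTYLE_LATENTS)].copy()
        out["lost_days"] = self.table.data["lost_days"].to_numpy()
        return out


# ---------------------------------------------------------------------------
# helpers


def _rank_uniform(x: np.ndarray) -> np.ndarray:
    order = stats.rankdata(x, method="ordinal")
    return (order - 0.5) / len(x)


def _lognormal_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * stats.norm.ppf(u))


def _censored_normal_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantiles of a zero-censored normal matched to a target mean and SD.

    ``X = max(0, W)`` with ``W ~ N(m, s)``; the censoring point mass at zero
    reproduces the zero-heavy, right-skewed shape of self-reported weekly
    activity volumes.  ``m/s`` is solved so the censored moments match.
    """

    def moments(alpha: float) -> tuple[float, float]:
        Phi, phi = stats.norm.cdf(alpha), stats.norm.pdf(alpha)
        e1 = alpha * Phi + phi
        e2 = (1.0 + alpha**2) * Phi + alpha * phi
        return e1, np.sqrt(max(e2 - e1 * e1, 1e-12))

    target = sd / mean
    lo, hi = -5.0, 8.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        e1, sdev = moments(mid)
        if sdev / e1 > target:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    e1, _ = moments(alpha)
    s = mean / e1
    m = alpha * s
    return np.maximum(0.0, m + s * stats.norm.ppf(u))


def _cut_ordinal(score: np.ndarray, categories: Sequence[str], probs=None) -> np.ndarray:
    """Assign categories by empirical quantiles of a continuous score."""
    u = _rank_uniform(score)
    if probs is None:
        probs = np.full(len(categories), 1.0 / len(categories))
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(categories) or abs(probs.sum() - 1.0) > 1e-8:
        raise SimulationError("item marginals must match category count and sum to 1")
    cuts = np.cumsum(probs)[:-1]
    codes = np.searchsorted(cuts, u, side="right")
    return np.asarray(categories, dtype=object)[codes]


def _zinb_ppf(u: np.ndarray, params: AbsenteeismParams) -> np.ndarray:
    pi = params.zero_inflation
    r = params.nb_size
    p = r / (r + params.nb_mean)
    out = np.zeros(len(u))
    hot = u > pi
    out[hot] = stats.nbinom.ppf((u[hot] - pi) / (1.0 - pi), r, p)
    return out


def build_schema(config: CohortConfig) -> list[VariableSpec]:
    specs: list[VariableSpec] = [
        VariableSpec("sex", "nominal", ("male", "female")),
        VariableSpec("age_group", "ordinal", tuple(DEFAULT_AGE_PROBS)),
        VariableSpec("work_category", "nominal", tuple(DEFAULT_WORK_PROBS)),
        VariableSpec("illness", "nominal", tuple(DEFAULT_ILLNESS_PROBS)),
    ]
    for name in ("fourq", "stress_scale", "fatigue_scale", "control_scale"):
        specs.append(VariableSpec(name, "ordinal", ORDINAL_CATEGORIES[name], units="AU"))
    for name in ("smoking_habit", "intend_quit", "activity_freq", "wine_beer", "alcohol"):
        specs.append(VariableSpec(name, "ordinal", ORDINAL_CATEGORIES[name]))
    units = {
        "total_chol": "mg/dL",
        "hdl": "mg/dL",
        "triglycerides": "mg/dL",
        "glucose": "mg/dL",
        "sbp": "mmHg",
        "dbp": "mmHg",
        "heart_rate": "bpm",
        "weight": "kg",
        "height": "cm",
        "waist": "cm",
    }
    for name, unit in units.items():
        specs.append(
            VariableSpec(
                name,
                "numeric",
                units=unit,
                plausible_range=DEFAULT_PLAUSIBLE_RANGES.get(name),
            )
        )
    for name in ("met_walk", "met_moderate", "met_vigorous", "met_total"):
        specs.append(VariableSpec(name, "numeric", units="MET-min/week"))
    specs.append(VariableSpec("lost_days", "numeric", units="days/year"))
    return specs


# ---------------------------------------------------------------------------
# main generator


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> GeneratedCohort:
    """Draw a cohort under ``config``; deterministic given ``seed``."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n
    if n < 10:
        raise SimulationError("n must be at least 10")

    # --- typology assignment and latent factors
    if cfg.typology_spec is not None:
        k = len(cfg.typology_spec.centroids)
        typology = rng.choice(k, size=n, p=np.asarray(cfg.typology_spec.weights))
        centroids = np.asarray(cfg.typology_spec.centroids, dtype=float)
        shifts = centroids[typology]  # n x 6
    else:
        typology = np.full(n, -1)
        shifts = np.zeros((n, 6))
    latents = pd.DataFrame(
        rng.standard_normal((n, 5)) + shifts[:, :5],
        columns=list(PERCEPTION_LATENTS) + list(LIFESTYLE_LATENTS),
    )

    # --- outlier latents injected before item generation, so the extreme
    # rows answer the questionnaire accordingly
    outlier = np.zeros(n, dtype=bool)
    grp = iso = None
    if cfg.outlier_spec is not None:
        osp = cfg.outlier_spec
        idx = rng.choice(n, size=osp.group_size + 1, replace=False)
        grp, iso = idx[:-1], idx[-1]
        for j, lat in enumerate(list(PERCEPTION_LATENTS) + list(LIFESTYLE_LATENTS)):
            latents.iloc[grp, j] = osp.group_latents[j] + osp.group_noise_sd * (
                rng.standard_normal(len(grp))
            )
            latents.iloc[iso, j] = osp.isolated_latents[j]
        outlier[idx] = True

    # --- perception scales (ordinal)
    columns: dict[str, np.ndarray] = {}
    f_perc = latents[list(PERCEPTION_LATENTS)].to_numpy()
    for name, row in cfg.perception_loadings.items():
        noise_sd = np.sqrt(1.0 - sum(l * l for l in row))
        score = f_perc @ np.asarray(row) + noise_sd * rng.standard_normal(n)
        columns[name] = _cut_ordinal(
            score, ORDINAL_CATEGORIES[name], cfg.item_marginals.get(name)
        )

    # --- lifestyle variables (ordinal items + lognormal MET volumes)
    f_life = latents[list(LIFESTYLE_LATENTS)].to_numpy()
    met_cols = {}
    for name, row in cfg.lifestyle_loadings.items():
        noise_sd = np.sqrt(1.0 - sum(l * l for l in row))
        score = f_life @ np.asarray(row) + noise_sd * rng.standard_normal(n)
        if name in cfg.met_params:
            mean, sd = cfg.met_params[name]
            met_cols[name] = _censored_normal_ppf(_rank_uniform(score), mean, sd)
        else:
            columns[name] = _cut_ordinal(
                score, ORDINAL_CATEGORIES[name], cfg.item_marginals.get(name)
            )
    columns.update(met_cols)
    columns["met_total"] = (
        columns["met_walk"] + columns["met_moderate"] + columns["met_vigorous"]
    )

    # --- absenteeism: ZINB through a Gaussian copula on the stress factor
    ab = cfg.absenteeism
    rho = ab.stress_link
    z_stress = latents["stress"].to_numpy()
    w = rho * (z_stress - z_stress.mean()) / max(z_stress.std(), 1e-9)
    w = w + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n)
    w = w + shifts[:, 5]  # planted absenteeism shifts push the copula normal up
    columns["lost_days"] = _zinb_ppf(_rank_uniform(w), ab)

    # --- demographics, with optional typology links
    p_female = np.full(n, 1.0 - cfg.male_fraction)
    for t, shift in cfg.gender_links.items():
        if cfg.typology_spec is not None and t < len(cfg.typology_spec.centroids):
            p_female[typology == t] = np.clip(p_female[typology == t] + shift, 0.02, 0.98)
    sex = np.where(rng.random(n) < p_female, "female", "male")
    columns["sex"] = sex
    columns["age_group"] = rng.choice(
        list(DEFAULT_AGE_PROBS), size=n, p=list(DEFAULT_AGE_PROBS.values())
    )
    columns["work_category"] = rng.choice(
        list(DEFAULT_WORK_PROBS), size=n, p=list(DEFAULT_WORK_PROBS.values())
    )
    ill_base = np.asarray(list(DEFAULT_ILLNESS_PROBS.values()))
    illness = np.empty(n, dtype=object)
    labels_ill = list(DEFAULT_ILLNESS_PROBS)
    for i in range(n):
        probs = ill_base.copy()
        shift = cfg.illness_links.get(int(typology[i]), 0.0)
        if shift:
            moved = min(shift, probs[0])
            probs[0] -= moved
            probs[1:] += moved * ill_base[1:] / ill_base[1:].sum()
        illness[i] = rng.choice(labels_ill, p=probs)
    columns["illness"] = illness

    # --- biochemistry / anthropometrics per sex
    male = sex == "male"
    for name, par in cfg.biochem_params.items():
        out = np.zeros(n)
        for label, mask in (("male", male), ("female", ~male)):
            mean, sd = par[label]
            m = int(mask.sum())
            if par.get("dist", "normal") == "lognormal":
                out[mask] = _lognormal_ppf(
                    _rank_uniform(rng.standard_normal(m)), mean, sd
                )
            else:
                out[mask] = mean + sd * rng.standard_normal(m)
        if cfg.mes_lifestyle_link and name in ("triglycerides", "glucose", "waist", "sbp"):
            par_sd = (par["male"][1] + par["female"][1]) / 2.0
            out = out + cfg.mes_lifestyle_link * par_sd * latents["alcohol"].to_numpy()
        columns[name] = out

    # --- outlier absenteeism and questionnaire answers
    if cfg.outlier_spec is not None:
        osp = cfg.outlier_spec
        columns["lost_days"][grp] = osp.group_lost_days + rng.integers(0, 10, len(grp))
        columns["lost_days"][iso] = osp.isolated_lost_days
        # extreme categorical answers for the heavy smoker/drinker group
        for name in ("smoking_habit", "intend_quit", "wine_beer", "alcohol"):
            columns[name][grp] = ORDINAL_CATEGORIES[name][-1]

    schema = build_schema(cfg)
    data = pd.DataFrame({v.name: columns[v.name] for v in schema})
    data.index.name = "row_id"
    table = CohortTable(schema=schema, data=data)
    table.validate()
    truth = latents.copy()
    truth["typology"] = typology
    truth["outlier"] = outlier
    truth.index = data.index
    return GeneratedCohort(table=table, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# recovery metrics


def recovery_harness(
    generated: GeneratedCohort,
    *,
    indicators: pd.DataFrame | None = None,
    latent_names: Sequence[str] | None = None,
    assignments: pd.Series | np.ndarray | None = None,
    detected_outliers: Sequence | None = None,
) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    Returns whichever metrics the supplied outputs allow: absolute
    indicator-latent correlations (dimensions matched to latents by maximum
    |correlation| assignment), the adjusted Rand index of recovered versus
    planted typologies, and outlier recall/precision.
    """
    metrics: dict = {}
    truth = generated.truth
    if indicators is not None:
        names = list(latent_names or (list(PERCEPTION_LATENTS) + list(LIFESTYLE_LATENTS)))
        sub = truth.loc[indicators.index]
        corr = np.zeros((indicators.shape[1], len(names)))
        for i, col in enumerate(indicators.columns):
            for j, lat in enumerate(names):
                corr[i, j] = abs(np.corrcoef(indicators[col], sub[lat])[0, 1])
        if corr.shape[0] != corr.shape[1]:
            raise SimulationError("indicator/latent dimension mismatch")
        ri, ci = linear_sum_assignment(-corr)
        metrics["indicator_latent_corr"] = {
            names[j]: float(corr[i, j]) for i, j in zip(ri, ci)
        }
    if assignments is not None:
        if isinstance(assignments, pd.Series):
            planted = truth.loc[assignments.index, "typology"].to_numpy()
            got = assignments.to_numpy()
        else:
            got = np.asarray(assignments)
            planted = truth["typology"].to_numpy()[: len(got)]
        metrics["ari"] = float(adjusted_rand_score(planted, got))
    if detected_outliers is not None:
        true_set = set(truth.index[truth["outlier"]])
        got_set = set(detected_outliers)
        tp = len(true_set & got_set)
        metrics["outlier_recall"] = tp / len(true_set) if true_set else np.nan
        metrics["outlier_precision"] = tp / len(got_set) if got_set else np.nan
    return metrics
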