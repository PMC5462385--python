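"""Seeded synthetic EHR-style cohorts for longitudinal MMSE trajectory analysis.

The generator emulates the statistical structure of a memory-clinic cohort
derived from mental-health electronic health records: per-subject MMSE series
drawn from a finite mixture of quadratic growth curves on centered time,
irregular visit schedules, recording artifacts (reduced denominators,
same-day duplicate entries), and baseline covariates (drug prescriptions,
HoNOS clinician ratings, demographics) whose distribution depends on the
latent trajectory class through a multinomial-logit link.

Every draw flows from a single :class:`numpy.random.Generator`, so a given
``SimulationConfig`` (including its ``seed``) reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "DEFAULT_CLASS_COEFFICIENTS",
    "DEFAULT_CLASS_SHARES",
    "HONOS_ITEMS",
    "generate_cohort",
    "inject_artifacts",
    "simulate_class_labels",
    "tune_class_intercepts",
    "generate_diagnoses",
    "write_cohort",
]

# ---------------------------------------------------------------------------
# Defaults: the six-trajectory quadratic growth mixture
# ---------------------------------------------------------------------------

#: Per-class (intercept, linear, quadratic) growth coefficients on centered
#: time, MMSE points / points-per-year / points-per-year^2.  Classes are
#: ordered by descending baseline level.
DEFAULT_CLASS_COEFFICIENTS = np.array(
    [
        [27.9, -0.199, -0.0122],
        [24.9, -0.469, -0.127],
        [21.5, -0.841, -0.166],
        [18.7, -2.53, 0.140],
        [17.3, -1.37, -0.175],
        [11.4, -2.81, 0.289],
    ]
)

#: Published class shares 14/22/22/9/18/14 (%) sum to 99 from rounding;
#: renormalized to sum to one.
DEFAULT_CLASS_SHARES = np.array([14, 22, 22, 9, 18, 14], dtype=float) / 99.0

#: The 12 Health of the Nation Outcome Scales items.
HONOS_ITEMS = [
    "behavioural_disturbance",
    "non_accidental_self_injury",
    "drink_drug_abuse",
    "cognitive_problems",
    "physical_illness_disability",
    "hallucinations_delusions",
    "depressive_symptoms",
    "other_mental_behavioural_problems",
    "social_relationships",
    "adl",
    "living_conditions",
    "work_leisure_activities",
]

#: Severity levels as recorded by clinicians (5-level); downstream analysis
#: collapses Moderate and Severe.
RAW_SEVERITIES = ["None", "Minor", "Mild", "Moderate", "Severe"]
ORDINAL_LEVELS = ["Minor", "Mild", "ModerateSevere"]


@dataclass
class CovariateSpec:
    """One class-linked baseline covariate.

    Parameters
    ----------
    name:
        Covariate name. Binary covariates are materialised as drug
        prescription episodes, ordinal ones as HoNOS item ratings, and
        continuous ones as demographic fields (currently ``age``).
    kind:
        ``"binary"``, ``"ordinal4"`` (None/Minor/Mild/ModerateSevere) or
        ``"continuous"``.
    log_rrr:
        Log relative-risk ratios of class membership relative to the
        reference class. Shape ``(K,)`` for binary/continuous covariates
        (entry at the reference class must be 0) or ``(3, K)`` for ordinal
        covariates, one row per non-None level.
    prevalence:
        Marginal distribution: a probability for binary covariates, a
        3-vector ``(P(Minor), P(Mild), P(ModerateSevere))`` for ordinal
        covariates, or ``(mean, sd)`` for continuous covariates.
    """

    name: str
    kind: str
    log_rrr: np.ndarray
    prevalence: object

    def __post_init__(self) -> None:
        self.log_rrr = np.asarray(self.log_rrr, dtype=float)
        if self.kind not in {"binary", "ordinal4", "continuous"}:
            raise ValueError(f"covariate {self.name}: unknown kind {self.kind!r}")
        if self.kind == "ordinal4":
            if self.log_rrr.ndim != 2 or self.log_rrr.shape[0] != 3:
                raise ValueError(
                    f"covariate {self.name}: ordinal4 log_rrr must have shape (3, K)"
                )
            p = np.asarray(self.prevalence, dtype=float)
            if p.shape != (3,) or p.sum() >= 1 or (p < 0).any():
                raise ValueError(
                    f"covariate {self.name}: ordinal4 prevalence must be 3 "
                    "probabilities summing to < 1"
                )
        elif self.log_rrr.ndim != 1:
            raise ValueError(f"covariate {self.name}: log_rrr must be a K-vector")


def _default_covariates() -> list[CovariateSpec]:
    """Class-linked covariates with published effect sizes (reference class 4)."""
    ln = np.log
    return [
        CovariateSpec(
            name="age",
            kind="continuous",
            log_rrr=ln([0.94, 0.99, 1.03, 1.0, 1.04, 1.02]),
            prevalence=(80.0, 8.0),
        ),
        CovariateSpec(
            name="sertraline",
            kind="binary",
            log_rrr=ln([0.70, 0.51, 0.44, 1.0, 0.41, 0.22]),
            prevalence=0.10,
        ),
        CovariateSpec(
            name="behavioural_disturbance",
            kind="ordinal4",
            log_rrr=ln(
                [
                    [0.56, 0.72, 0.79, 1.0, 0.76, 1.04],
                    [0.38, 0.65, 0.73, 1.0, 0.69, 0.98],
                    [0.20, 0.29, 0.26, 1.0, 0.39, 0.66],
                ]
            ),
            prevalence=np.array([0.20, 0.15, 0.15]),
        ),
        CovariateSpec(
            name="cognitive_problems",
            kind="ordinal4",
            log_rrr=ln(
                [
                    [1.35, 1.17, 1.87, 1.0, 2.26, 10.23],
                    [0.78, 1.61, 2.71, 1.0, 4.46, 14.68],
                    [0.65, 0.91, 1.94, 1.0, 6.39, 28.26],
                ]
            ),
            prevalence=np.array([0.25, 0.30, 0.20]),
        ),
    ]


@dataclass
class SimulationConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study conditions of the source cohort: 3441
    subjects, six quadratic trajectory classes, 3-8 visits per subject over
    a log-normal follow-up calibrated to median 1.70 y (IQR 0.79-2.99 y),
    7% of scores with reduced denominators, and class-linked covariates.
    """

    n_subjects: int = 3441
    class_proportions: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_SHARES.copy()
    )
    class_coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_COEFFICIENTS.copy()
    )
    residual_sd: np.ndarray = field(default_factory=lambda: np.full(6, 2.5))
    visits_min: int = 3
    visits_max: int = 8
    followup_median: float = 1.70
    followup_iqr: tuple = (0.79, 2.99)
    #: log-normal tail bounded by the observation window of the study design
    #: (referral and scores within one 8-year period)
    max_followup_years: float = 8.0
    reduced_denominator_rate: float = 0.07
    low_denominator_rate: float = 0.005
    same_day_duplicate_rate: float = 0.02
    covariate_spec: list = field(default_factory=_default_covariates)
    reference_class: int = 4
    study_start: date = date(2007, 1, 1)
    study_end: date = date(2014, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.class_coefficients = np.asarray(self.class_coefficients, dtype=float)
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        self.covariate_spec = [
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in self.covariate_spec
        ]
        if isinstance(self.study_start, str):
            self.study_start = date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = date.fromisoformat(self.study_end)
        self.validate()

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def validate(self) -> None:
        k = self.n_classes
        if abs(self.class_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("class_proportions must sum to 1 (renormalize first)")
        if (self.class_proportions < 0).any():
            raise ValueError("class_proportions must be non-negative")
        if self.class_coefficients.shape != (k, 3):
            raise ValueError(
                f"class_coefficients must have shape ({k}, 3), got "
                f"{self.class_coefficients.shape}"
            )
        if self.residual_sd.shape != (k,):
            raise ValueError(f"residual_sd must have length {k}")
        if (self.residual_sd <= 0).any():
            raise ValueError("residual_sd entries must be > 0")
        if self.visits_min < 3:
            raise ValueError("visits_min must be >= 3")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        for rate_name in (
            "reduced_denominator_rate",
            "low_denominator_rate",
            "same_day_duplicate_rate",
        ):
            r = getattr(self, rate_name)
            if not 0 <= r <= 1:
                raise ValueError(f"{rate_name} must lie in [0, 1]")
        if not 1 <= self.reference_class <= k:
            raise ValueError("reference_class out of range")
        for cov in self.covariate_spec:
            width = cov.log_rrr.shape[-1]
            if width != k:
                raise ValueError(
                    f"covariate {cov.name}: log_rrr has {width} classes, expected {k}"
                )
            ref_col = cov.log_rrr[..., self.reference_class - 1]
            if np.any(np.abs(ref_col) > 1e-12):
                raise ValueError(
                    f"covariate {cov.name}: log_rrr at the reference class must be 0"
                )

    def followup_lognormal_params(self) -> tuple:
        """(mu, sigma) of the log follow-up length implied by median and IQR."""
        q1, q3 = self.followup_iqr
        mu = np.log(self.followup_median)
        # quartiles of a log-normal sit at mu +/- 0.6745 sigma on the log scale
        sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6744898)
        return mu, sigma

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["class_proportions"] = self.class_proportions.tolist()
        d["class_coefficients"] = self.class_coefficients.tolist()
        d["residual_sd"] = self.residual_sd.tolist()
        d["followup_iqr"] = list(self.followup_iqr)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["covariate_spec"] = [
            {
                "name": c.name,
                "kind": c.kind,
                "log_rrr": np.asarray(c.log_rrr).tolist(),
                "prevalence": np.asarray(c.prevalence).tolist()
                if not np.isscalar(c.prevalence)
                else c.prevalence,
            }
            for c in self.covariate_spec
        ]
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class SyntheticCohort:
    """All tables produced by :func:`generate_cohort`."""

    scores: pd.DataFrame
    prescriptions: pd.DataFrame
    honos: pd.DataFrame
    demographics: pd.DataFrame
    true_labels: pd.Series  # subject_id -> generating class (1..K)
    config: SimulationConfig
    covariates: pd.DataFrame | None = None  # latent covariate draws, for testing
    truncation_rate: float = 0.0


# ---------------------------------------------------------------------------
# Class labels given covariates (multinomial-logit inversion)
# ---------------------------------------------------------------------------


def _covariate_design(cov_df: pd.DataFrame, specs: list) -> tuple:
    """Numeric design matrix and per-column (3, K) or (K,) effect stack."""
    cols = []
    effects = []
    for cov in specs:
        if cov.kind == "binary":
            cols.append(cov_df[cov.name].to_numpy(dtype=float))
            effects.append(cov.log_rrr)
        elif cov.kind == "continuous":
            mean = np.asarray(cov.prevalence, dtype=float)[0]
            cols.append(cov_df[cov.name].to_numpy(dtype=float) - mean)
            effects.append(cov.log_rrr)
        else:  # ordinal4: one indicator per non-None level
            level = cov_df[cov.name].to_numpy()
            for j, lev in enumerate(ORDINAL_LEVELS):
                cols.append((level == lev).astype(float))
                effects.append(cov.log_rrr[j])
    if not cols:
        return np.zeros((len(cov_df), 0)), np.zeros((0, 0))
    return np.column_stack(cols), np.vstack(effects)


def tune_class_intercepts(
    design: np.ndarray,
    effects: np.ndarray,
    target_shares: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Intercepts of a multinomial logit matching target marginal class shares.

    Fixed-point iteration: each class intercept is shifted by the log-ratio of
    its target share to the current marginal membership probability. This
    keeps the conditional log-RRR structure intact while pinning the marginal
    class distribution, which makes multinomial parameter recovery on the
    simulated labels well-posed.
    """
    target = np.asarray(target_shares, dtype=float)
    alpha = np.log(target)
    eta_x = design @ effects if design.size else np.zeros((design.shape[0], len(target)))
    for _ in range(max_iter):
        eta = eta_x + alpha
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        marginal = p.mean(axis=0)
        step = np.log(target) - np.log(marginal)
        alpha = alpha + step
        if np.abs(step).max() < tol:
            break
    return alpha - alpha[0]


def simulate_class_labels(
    cov_df: pd.DataFrame,
    specs: list,
    target_shares: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw 1-based class labels from the covariate-conditional logit."""
    design, effects = _covariate_design(cov_df, specs)
    alpha = tune_class_intercepts(design, effects, target_shares)
    eta = (design @ effects if design.size else 0.0) + alpha
    eta = eta - np.max(eta, axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(cov_df))
    return 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _draw_covariates(
    n: int, specs: list, rng: np.random.Generator
) -> pd.DataFrame:
    cov = {}
    for spec in specs:
        if spec.kind == "binary":
            cov[spec.name] = (rng.random(n) < float(spec.prevalence)).astype(int)
        elif spec.kind == "continuous":
            mean, sd = np.asarray(spec.prevalence, dtype=float)
            cov[spec.name] = rng.normal(mean, sd, size=n)
        else:
            p = np.asarray(spec.prevalence, dtype=float)
            probs = np.concatenate([[1 - p.sum()], p])
            idx = rng.choice(4, size=n, p=probs)
            cov[spec.name] = np.array(["None", *ORDINAL_LEVELS], dtype=object)[idx]
    return pd.DataFrame(cov, index=pd.RangeIndex(n))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Returns raw MMSE score records, prescriptions, HoNOS ratings,
    demographics and the ground-truth class labels. Scores follow
    ``beta0_k + beta1_k t* + beta2_k t*^2 + N(0, sigma_k)`` at irregular
    visit times, with ``t*`` centered at the cohort mean visit time, then
    truncated to the instrument range [0, 30].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = config.n_classes

    empty = SyntheticCohort(
        scores=pd.DataFrame(
            columns=["subject_id", "date", "numerator", "denominator", "record_sequence"]
        ),
        prescriptions=pd.DataFrame(
            columns=["subject_id", "drug_name", "start_date", "stop_date"]
        ),
        honos=pd.DataFrame(columns=["subject_id", "item", "severity", "date"]),
        demographics=pd.DataFrame(
            columns=[
                "subject_id",
                "year_of_birth",
                "gender",
                "ethnicity",
                "education_band",
                "cohabiting",
                "retired",
            ]
        ),
        true_labels=pd.Series(dtype=int, name="true_class"),
        config=config,
    )
    if n == 0:
        return empty

    subject_ids = np.array([f"S{i:05d}" for i in range(1, n + 1)])

    # latent covariates, then class given covariates
    cov_df = _draw_covariates(n, config.covariate_spec, rng)
    if config.covariate_spec:
        labels = simulate_class_labels(
            cov_df, config.covariate_spec, config.class_proportions, rng
        )
    else:
        labels = 1 + rng.choice(k, size=n, p=config.class_proportions)

    # visit schedule: per-subject follow-up length from a log-normal matched
    # to the target median/IQR; first and last visit anchor the span, interior
    # visits uniform
    mu, sigma = config.followup_lognormal_params()
    followup = np.minimum(
        np.exp(rng.normal(mu, sigma, size=n)), config.max_followup_years
    )
    n_visits = rng.integers(config.visits_min, config.visits_max + 1, size=n)
    times_per_subject = []
    for i in range(n):
        nv = n_visits[i]
        interior = np.sort(rng.uniform(0.0, followup[i], size=nv - 2))
        times_per_subject.append(np.concatenate([[0.0], interior, [followup[i]]]))
    subj_idx = np.repeat(np.arange(n), n_visits)
    times = np.concatenate(times_per_subject)

    # scores on centered time
    time_center = times.mean()
    tstar = times - time_center
    beta = config.class_coefficients[labels[subj_idx] - 1]
    mean_score = beta[:, 0] + beta[:, 1] * tstar + beta[:, 2] * tstar**2
    noise = rng.normal(0.0, config.residual_sd[labels[subj_idx] - 1])
    raw = mean_score + noise
    truncated = np.clip(raw, 0.0, 30.0)
    truncation_rate = float(np.mean(truncated != raw))

    # baseline dates inside the study window, leaving room for follow-up
    window_days = (config.study_end - config.study_start).days
    base_offset = rng.integers(0, max(window_days - 365, 1), size=n)
    baseline_dates = np.array(
        [config.study_start + timedelta(days=int(d)) for d in base_offset]
    )
    visit_dates = [
        baseline_dates[s] + timedelta(days=int(round(t * 365.25)))
        for s, t in zip(subj_idx, times)
    ]

    scores = pd.DataFrame(
        {
            "subject_id": subject_ids[subj_idx],
            "date": visit_dates,
            "numerator": np.round(truncated).astype(int),
            "denominator": 30,
        }
    )
    # distinct visits can round to the same calendar date: sequence them
    scores["record_sequence"] = (
        scores.groupby(["subject_id", "date"]).cumcount() + 1
    )
    scores = inject_artifacts(
        scores,
        reduced_denominator_rate=config.reduced_denominator_rate,
        low_denominator_rate=config.low_denominator_rate,
        same_day_duplicate_rate=config.same_day_duplicate_rate,
        rng=rng,
        true_scores=truncated,
    )

    prescriptions = _make_prescriptions(
        subject_ids, cov_df, config, baseline_dates, rng
    )
    honos = _make_honos(subject_ids, cov_df, config, baseline_dates, rng)
    demographics = _make_demographics(subject_ids, cov_df, baseline_dates, rng)

    return SyntheticCohort(
        scores=scores,
        prescriptions=prescriptions,
        honos=honos,
        demographics=demographics,
        true_labels=pd.Series(labels, index=subject_ids, name="true_class"),
        config=config,
        covariates=cov_df.set_index(subject_ids),
        truncation_rate=truncation_rate,
    )


def inject_artifacts(
    scores: pd.DataFrame,
    reduced_denominator_rate: float = 0.0,
    low_denominator_rate: float = 0.0,
    same_day_duplicate_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    true_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Degrade clean score records with realistic recording artifacts.

    ``reduced_denominator_rate`` of records get a denominator in 20-29 (items
    skipped during testing), ``low_denominator_rate`` a denominator below 20
    (these are excluded downstream), and ``same_day_duplicate_rate`` of
    records gain a same-date duplicate differing by 1-2 points with a later
    ``record_sequence``. Numerators are rescaled so the weighted score stays
    close to the underlying value.
    """
    for name, r in (
        ("reduced_denominator_rate", reduced_denominator_rate),
        ("low_denominator_rate", low_denominator_rate),
        ("same_day_duplicate_rate", same_day_duplicate_rate),
    ):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if reduced_denominator_rate == low_denominator_rate == same_day_duplicate_rate == 0:
        return scores
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = scores.reset_index(drop=True).copy()
    m = len(out)
    if m == 0:
        return out
    if true_scores is None:
        true_scores = out["numerator"].to_numpy(dtype=float)

    u = rng.random(m)
    reduced = u < reduced_denominator_rate
    low = (u >= reduced_denominator_rate) & (
        u < reduced_denominator_rate + low_denominator_rate
    )
    denom = out["denominator"].to_numpy().copy()
    numer = out["numerator"].to_numpy().copy()
    denom[reduced] = rng.integers(20, 30, size=int(reduced.sum()))
    denom[low] = rng.integers(10, 20, size=int(low.sum()))
    scaled = reduced | low
    numer[scaled] = np.minimum(
        np.round(true_scores[scaled] * denom[scaled] / 30.0).astype(int),
        denom[scaled],
    )
    out["denominator"] = denom
    out["numerator"] = numer

    dup_mask = rng.random(m) < same_day_duplicate_rate
    if dup_mask.any():
        dups = out.loc[dup_mask].copy()
        shift = rng.choice([-2, -1, 1, 2], size=len(dups))
        dups["numerator"] = np.clip(
            dups["numerator"].to_numpy() + shift, 0, dups["denominator"].to_numpy()
        )
        out["_dup"] = 0
        dups["_dup"] = 1
        out = pd.concat([out, dups], ignore_index=True)
        out = out.sort_values(
            ["subject_id", "date", "record_sequence", "_dup"], kind="stable"
        ).reset_index(drop=True)
        # re-sequence so duplicates sort after the record they copy
        out["record_sequence"] = (
            out.groupby(["subject_id", "date"]).cumcount() + 1
        )
        out = out.drop(columns="_dup")
    return out


# ---------------------------------------------------------------------------
# Covariate materialisation as EHR-style tables
# ---------------------------------------------------------------------------

_BACKGROUND_DRUGS = ["donepezil", "memantine", "citalopram", "amlodipine"]


def _episode_rows(rows, subject, drug, start, total_days, rng):
    """Write one medication episode, sometimes split into chained scripts."""
    n_scripts = int(rng.integers(1, 4))
    cursor = start
    for _ in range(n_scripts):
        length = int(rng.integers(20, max(21, total_days // n_scripts + 1)))
        stop = cursor + timedelta(days=length)
        rows.append((subject, drug, cursor, stop))
        cursor = stop + timedelta(days=int(rng.integers(1, 43)))  # gap <= 42: merges


def _make_prescriptions(subject_ids, cov_df, config, baseline_dates, rng):
    rows: list = []
    binary_drugs = [c.name for c in config.covariate_spec if c.kind == "binary"]
    n = len(subject_ids)
    for i in range(n):
        base = baseline_dates[i]
        for drug in binary_drugs:
            if cov_df[drug].iloc[i]:
                start = base + timedelta(days=int(rng.integers(-120, 61)))
                _episode_rows(rows, subject_ids[i], drug, start, 120, rng)
            elif rng.random() < 0.03:
                # old episode well outside the +/-6-month baseline window
                start = base - timedelta(days=int(rng.integers(300, 700)))
                rows.append(
                    (subject_ids[i], drug, start, start + timedelta(days=30))
                )
        for drug in _BACKGROUND_DRUGS:
            if rng.random() < 0.15:
                start = base + timedelta(days=int(rng.integers(-150, 151)))
                rows.append(
                    (
                        subject_ids[i],
                        drug,
                        start,
                        start + timedelta(days=int(rng.integers(28, 120))),
                    )
                )
    return pd.DataFrame(
        rows, columns=["subject_id", "drug_name", "start_date", "stop_date"]
    )


def _make_honos(subject_ids, cov_df, config, baseline_dates, rng):
    """HoNOS ratings near baseline; class-linked items use the drawn level.

    ModerateSevere draws are recorded as raw 'Moderate' or 'Severe' so that
    the preprocessing collapse of those categories is exercised.
    """
    rows: list = []
    ordinal_items = [c.name for c in config.covariate_spec if c.kind == "ordinal4"]
    background = [i for i in HONOS_ITEMS if i not in ordinal_items]
    n = len(subject_ids)
    bg_probs = np.array([0.45, 0.25, 0.18, 0.09, 0.03])
    for i in range(n):
        base = baseline_dates[i]
        when = base + timedelta(days=int(rng.integers(-30, 31)))
        for item in ordinal_items:
            level = cov_df[item].iloc[i]
            if level == "ModerateSevere":
                level = "Moderate" if rng.random() < 0.8 else "Severe"
            rows.append((subject_ids[i], item, level, when))
        for item in background:
            if rng.random() < 0.9:
                sev = RAW_SEVERITIES[rng.choice(5, p=bg_probs)]
                rows.append((subject_ids[i], item, sev, when))
    return pd.DataFrame(rows, columns=["subject_id", "item", "severity", "date"])


def _make_demographics(subject_ids, cov_df, baseline_dates, rng):
    n = len(subject_ids)
    if "age" in cov_df.columns:
        age = np.round(cov_df["age"].to_numpy()).astype(int)
    else:
        age = np.round(rng.normal(80, 8, size=n)).astype(int)
    age = np.clip(age, 40, 105)
    birth_year = np.array([d.year for d in baseline_dates]) - age
    gender = np.where(rng.random(n) < 0.62, "Female", "Male")
    ethnicity = np.array(["White", "Black", "Asian", "Other"], dtype=object)[
        rng.choice(4, size=n, p=[0.78, 0.15, 0.04, 0.03])
    ]
    education = np.array(["7-14", "15-16", "16-22", "Unknown"], dtype=object)[
        rng.choice(4, size=n, p=[0.35, 0.30, 0.15, 0.20])
    ]
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "year_of_birth": birth_year,
            "gender": gender,
            "ethnicity": ethnicity,
            "education_band": education,
            "cohabiting": (rng.random(n) < 0.4).astype(int),
            "retired": (rng.random(n) < 0.9).astype(int),
        }
    )


#: Diagnosis prevalence by trajectory class used by :func:`generate_diagnoses`:
#: dementia and other-mental-health rates fall/rise with disease stage.
_DIAGNOSIS_RATES = {
    "dementia": [0.52, 0.75, 0.80, 0.80, 0.87, 0.87],
    "other_mental_health": [0.54, 0.36, 0.25, 0.33, 0.21, 0.19],
    "alzheimers": [0.30, 0.50, 0.69, 0.59, 0.70, 0.70],
    "vascular_dementia": [0.10, 0.15, 0.21, 0.30, 0.22, 0.22],
    "mci": [0.25, 0.20, 0.14, 0.21, 0.08, 0.05],
    "lewy_body": [0.01, 0.01, 0.01, 0.03, 0.02, 0.02],
    "depression": [0.37, 0.25, 0.20, 0.26, 0.15, 0.12],
    "psychosis": [0.12, 0.08, 0.06, 0.12, 0.06, 0.05],
}


def generate_diagnoses(
    true_labels: pd.Series,
    rng: np.random.Generator | int | None = None,
    rates: dict | None = None,
) -> pd.DataFrame:
    """Long-format diagnosis records with class-dependent prevalence."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rates = rates if rates is not None else _DIAGNOSIS_RATES
    rows = []
    labels = true_labels.to_numpy()
    subjects = true_labels.index.to_numpy()
    for diag, by_class in rates.items():
        p = np.asarray(by_class, dtype=float)[labels - 1]
        hit = rng.random(len(labels)) < p
        offsets = rng.integers(0, 730, size=len(labels))
        for s, o in zip(subjects[hit], offsets[hit]):
            rows.append((s, diag, date(2010, 1, 1) + timedelta(days=int(o))))
    return pd.DataFrame(rows, columns=["subject_id", "diagnosis", "date"])


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write the five tables, true labels and the config YAML; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("scores", cohort.scores),
        ("prescriptions", cohort.prescriptions),
        ("honos", cohort.honos),
        ("demographics", cohort.demographics),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = out / "true_labels.csv"
    cohort.true_labels.rename_axis("subject_id").to_csv(p)
    paths["true_labels"] = p
    p = out / "simulation_config.yaml"
    p.write_text(cohort.config.to_yaml())
    paths["config"] = p
    return paths
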