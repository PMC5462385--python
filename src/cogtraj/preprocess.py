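"""Cohort construction from raw EHR-style tables.

Applies the score-cleaning, subject-retention and baseline-derivation rules:
MMSE scores with denominators below 20 are excluded and those below 30 are
re-weighted to the 0-30 scale; same-day duplicate entries resolve to the
first recorded value; subjects need at least three surviving scores; time is
measured in years from each subject's first retained score; medication
prescriptions merge into episodes (gaps of at most 42 days), with baseline
exposure defined by episode overlap with a +/-6-month window around the
first MMSE; HoNOS items take the rating closest in time to baseline, with
Moderate and Severe collapsed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "PreprocessReport",
    "weight_mmse",
    "weight_scores",
    "dedupe_same_day",
    "build_medication_episodes",
    "flag_baseline_medication",
    "select_baseline_honos",
    "make_analysis_cohort",
    "DAYS_PER_YEAR",
    "EPISODE_GAP_DAYS",
    "BASELINE_WINDOW_DAYS",
    "MIN_SCORES_PER_SUBJECT",
]

DAYS_PER_YEAR = 365.25
#: successive prescriptions for the same drug separated by at most this many
#: days form one episode of use
EPISODE_GAP_DAYS = 42
#: "six months pre or post" baseline, operationalised as days
BASELINE_WINDOW_DAYS = 182
MIN_SCORES_PER_SUBJECT = 3
#: denominators below this exclude the observation outright
MIN_DENOMINATOR = 20
MAX_SCORE = 30

SEVERITY_ORDER = ["None", "Minor", "Mild", "ModerateSevere"]
_COLLAPSE = {"Moderate": "ModerateSevere", "Severe": "ModerateSevere"}


class DataError(ValueError):
    """Raised for records that violate the input contract."""


@dataclass
class PreprocessReport:
    """Row/subject accounting for each cleaning step."""

    n_records_in: int = 0
    n_excluded_denominator: int = 0
    n_removed_duplicate: int = 0
    n_records_retained: int = 0
    n_subjects_in: int = 0
    n_subjects_dropped_few_scores: int = 0
    n_subjects_retained: int = 0
    drugs_dropped_rare: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# Score cleaning
# ---------------------------------------------------------------------------


def weight_mmse(numerator: float, denominator: float) -> float | None:
    """Re-weight a single MMSE observation to the full 0-30 scale.

    Returns ``None`` (exclusion) when the denominator is below 20; otherwise
    ``numerator * 30 / denominator``, kept fractional. A full denominator of
    30 leaves the numerator unchanged.
    """
    if numerator > denominator:
        raise DataError(
            f"numerator {numerator} exceeds denominator {denominator}"
        )
    if denominator < MIN_DENOMINATOR:
        return None
    return numerator * MAX_SCORE / denominator


def weight_scores(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Vectorised :func:`weight_mmse` over a raw score table.

    Returns the retained records with a ``weighted_score`` column and the
    count of excluded low-denominator observations.
    """
    num = records["numerator"].to_numpy(dtype=float)
    den = records["denominator"].to_numpy(dtype=float)
    bad = num > den
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DataError(
            f"numerator exceeds denominator at row {i} "
            f"(subject {records['subject_id'].iloc[i]})"
        )
    keep = den >= MIN_DENOMINATOR
    out = records.loc[keep].copy()
    out["weighted_score"] = num[keep] * MAX_SCORE / den[keep]
    return out, int((~keep).sum())


def dedupe_same_day(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep the first-recorded score on each subject-date.

    "First recorded" is the smallest ``record_sequence``; ties within a
    subject-date are a data error because recording order is then undefined.
    """
    grp = records.groupby(["subject_id", "date"])["record_sequence"]
    dup_min = grp.transform("min")
    is_kept = records["record_sequence"] == dup_min
    n_min = (
        records.loc[is_kept]
        .groupby(["subject_id", "date"])["record_sequence"]
        .size()
    )
    if (n_min > 1).any():
        sid, d = n_min[n_min > 1].index[0]
        raise DataError(
            f"tied record_sequence for subject {sid} on {d}: recording order undefined"
        )
    return records.loc[is_kept].copy(), int((~is_kept).sum())


# ---------------------------------------------------------------------------
# Medications
# ---------------------------------------------------------------------------


def build_medication_episodes(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Merge prescriptions into episodes of continuous use.

    Within a subject-drug, a prescription whose start is at most 42 days
    after the previous stop extends the same episode; the episode spans the
    earliest start to the latest stop. Output episodes for one subject-drug
    are therefore pairwise separated by more than 42 days.
    """
    if prescriptions.empty:
        return pd.DataFrame(
            columns=["subject_id", "drug_name", "episode_start", "episode_end"]
        )
    rx = prescriptions.copy()
    rx["start_date"] = pd.to_datetime(rx["start_date"])
    rx["stop_date"] = pd.to_datetime(rx["stop_date"])
    if (rx["stop_date"] < rx["start_date"]).any():
        bad = rx.loc[rx["stop_date"] < rx["start_date"]].iloc[0]
        raise DataError(
            f"prescription stop before start for subject {bad['subject_id']} "
            f"({bad['drug_name']})"
        )
    rx = rx.sort_values(["subject_id", "drug_name", "start_date"], kind="stable")
    gap = pd.Timedelta(days=EPISODE_GAP_DAYS)

    rows = []
    for (sid, drug), g in rx.groupby(["subject_id", "drug_name"], sort=True):
        start = end = None
        for s, e in zip(g["start_date"], g["stop_date"]):
            if start is None:
                start, end = s, e
            elif s - end <= gap:
                end = max(end, e)
            else:
                rows.append((sid, drug, start, end))
                start, end = s, e
        rows.append((sid, drug, start, end))
    return pd.DataFrame(
        rows, columns=["subject_id", "drug_name", "episode_start", "episode_end"]
    )


def flag_baseline_medication(
    episodes: pd.DataFrame,
    baseline_dates: pd.Series,
    min_prevalence: float = 0.01,
) -> pd.DataFrame:
    """Per-subject boolean drug-exposure flags at baseline.

    A subject is on a drug at baseline when any episode for that drug
    intersects the window [baseline - 182 d, baseline + 182 d]. Drugs flagged
    in fewer than ``min_prevalence`` of the subjects (those with a baseline
    date) are dropped from the output.
    """
    subjects = baseline_dates.index
    if episodes.empty:
        return pd.DataFrame(index=subjects)
    ep = episodes.merge(
        baseline_dates.rename("baseline_date"),
        left_on="subject_id",
        right_index=True,
        how="inner",
    )
    ep["baseline_date"] = pd.to_datetime(ep["baseline_date"])
    window = pd.Timedelta(days=BASELINE_WINDOW_DAYS)
    hit = (ep["episode_start"] <= ep["baseline_date"] + window) & (
        ep["episode_end"] >= ep["baseline_date"] - window
    )
    flags = (
        ep.loc[hit]
        .assign(v=True)
        .pivot_table(index="subject_id", columns="drug_name", values="v", aggfunc="any")
        .reindex(subjects)
    )
    flags = flags.where(flags.notna(), False).astype(bool)
    flags.columns.name = None
    prevalence = flags.mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    dropped = sorted(set(flags.columns) - set(keep))
    if dropped:
        logger.info("dropping rare medications (<%.0f%%): %s", 100 * min_prevalence, dropped)
    return flags[list(keep)]


# ---------------------------------------------------------------------------
# HoNOS
# ---------------------------------------------------------------------------


def select_baseline_honos(
    ratings: pd.DataFrame, baseline_dates: pd.Series
) -> pd.DataFrame:
    """Per subject and item, the rating closest in time to baseline.

    Moderate/Severe collapse to ``ModerateSevere``. No time limit is imposed.
    Equidistant pre/post ratings resolve to the earlier (pre-baseline) one,
    the clinician assessment preceding the cognitive test. Missing items stay
    missing (NaN).
    """
    subjects = baseline_dates.index
    if ratings.empty:
        return pd.DataFrame(index=subjects)
    r = ratings.merge(
        baseline_dates.rename("baseline_date"),
        left_on="subject_id",
        right_index=True,
        how="inner",
    )
    r["date"] = pd.to_datetime(r["date"])
    r["baseline_date"] = pd.to_datetime(r["baseline_date"])
    delta = (r["date"] - r["baseline_date"]).dt.days
    r["abs_days"] = delta.abs()
    # tie-break: smaller |distance| first, then the pre-baseline (earlier) rating
    r = r.sort_values(
        ["subject_id", "item", "abs_days", "date"], kind="stable"
    ).drop_duplicates(["subject_id", "item"], keep="first")
    r["severity"] = r["severity"].replace(_COLLAPSE)
    wide = r.pivot(index="subject_id", columns="item", values="severity")
    wide.columns.name = None
    return wide.reindex(subjects)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def make_analysis_cohort(
    scores: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    prescriptions: pd.DataFrame | None = None,
    honos: pd.DataFrame | None = None,
    min_scores: int = MIN_SCORES_PER_SUBJECT,
) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessReport]:
    """Raw tables -> (clean longitudinal scores, baseline profiles, report).

    Order of operations: re-weight scores (excluding denominators < 20),
    resolve same-day duplicates to the first-recorded value, then retain
    subjects with at least ``min_scores`` surviving observations. Time in
    years runs from each retained subject's first surviving score, which also
    defines the baseline date for covariate derivation.
    """
    report = PreprocessReport(
        n_records_in=len(scores),
        n_subjects_in=scores["subject_id"].nunique() if len(scores) else 0,
    )
    if scores.empty:
        logger.warning("empty score table: returning empty cohort")
        clean = pd.DataFrame(columns=["subject_id", "time_years", "weighted_score"])
        return clean, pd.DataFrame(), report

    recs = scores.copy()
    recs["date"] = pd.to_datetime(recs["date"])
    recs, report.n_excluded_denominator = weight_scores(recs)
    recs, report.n_removed_duplicate = dedupe_same_day(recs)
    report.n_records_retained = len(recs)

    counts = recs.groupby("subject_id").size()
    keep_subjects = counts[counts >= min_scores].index
    report.n_subjects_dropped_few_scores = int((counts < min_scores).sum())
    report.n_subjects_retained = len(keep_subjects)
    recs = recs[recs["subject_id"].isin(keep_subjects)]
    recs = recs.sort_values(["subject_id", "date"], kind="stable")

    first_date = recs.groupby("subject_id")["date"].transform("min")
    clean = pd.DataFrame(
        {
            "subject_id": recs["subject_id"].to_numpy(),
            "time_years": (recs["date"] - first_date).dt.days / DAYS_PER_YEAR,
            "weighted_score": recs["weighted_score"].to_numpy(),
        }
    ).reset_index(drop=True)

    baseline_dates = recs.groupby("subject_id")["date"].min()
    baseline_mmse = (
        recs.loc[recs["date"] == first_date]
        .groupby("subject_id")["weighted_score"]
        .first()
    )
    profiles = pd.DataFrame(
        {"baseline_date": baseline_dates, "baseline_mmse": baseline_mmse}
    )

    if demographics is not None and not demographics.empty:
        demo = demographics.set_index("subject_id").reindex(profiles.index)
        profiles["age_at_baseline"] = (
            profiles["baseline_date"].dt.year - demo["year_of_birth"]
        )
        for col in ("gender", "ethnicity", "education_band", "cohabiting", "retired"):
            if col in demo.columns:
                profiles[col] = demo[col]

    if honos is not None and not honos.empty:
        baseline_honos = select_baseline_honos(honos, baseline_dates)
        baseline_honos.columns = [f"honos_{c}" for c in baseline_honos.columns]
        profiles = profiles.join(baseline_honos)

    if prescriptions is not None and not prescriptions.empty:
        episodes = build_medication_episodes(prescriptions)
        flags = flag_baseline_medication(episodes, baseline_dates)
        report.drugs_dropped_rare = sorted(
            set(prescriptions["drug_name"].unique()) - set(flags.columns)
        )
        flags.columns = [f"med_{c}" for c in flags.columns]
        profiles = profiles.join(flags)
        med_cols = [c for c in profiles.columns if c.startswith("med_")]
        profiles[med_cols] = profiles[med_cols].fillna(False).astype(bool)

    logger.info("preprocess report: %s", report.to_json())
    return clean, profiles, report
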