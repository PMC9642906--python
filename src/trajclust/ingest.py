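"""Reading visit / laboratory tables and deriving analysis-ready records.

Behaviour flags come from three questionnaire items per follow-up visit:

  (a) sex with non-steady partners?           -> nsP
  (b) anal intercourse (with those partners)? -+
  (c) condoms used all the time?              -+-> nsCAI

nsP = 1 iff (a) is yes; nsCAI = 1 iff (a) yes, (b) yes and (c) no. A flag is
missing whenever the first unanswered item makes the rule undecidable.

Incident syphilis is classified from longitudinal serology: a treponemal
seroconversion (negative -> positive), or a VDRL titer above 1:8 that also
exceeds a four-fold rise over the most recent prior titer. Both thresholds
are strict inequalities by default and configurable.

The analysis window is split at a cut-off date into a half-open observation
period [start, cutoff) used for clustering and an outcome period
[cutoff, end] used for prediction.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviourFlags",
    "SyphilisEpisode",
    "CutoffSplit",
    "derive_behaviour_flags",
    "add_behaviour_flags",
    "classify_incident_syphilis",
    "classify_syphilis_episodes",
    "apply_inclusion_criteria",
    "split_periods",
    "derive_outcome_table",
    "read_visits",
    "read_labs",
    "read_sti_reports",
    "read_participants",
]

_ANSWER = {"yes": 1.0, "no": 0.0}

VISIT_COLUMNS = ["participant_id", "visit_date", "ans_nsP", "ans_intercourse",
                 "ans_condom_always"]
LAB_COLUMNS = ["participant_id", "date", "treponemal_result", "vdrl_titer"]
STI_COLUMNS = ["participant_id", "report_date"]
PARTICIPANT_COLUMNS = ["participant_id", "birth_date"]


def _parse_answer(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    if s in ("", "nan", "missing", "na"):
        return np.nan
    if s not in _ANSWER:
        raise ValueError(f"questionnaire answer must be yes/no/missing, got {value!r}")
    return _ANSWER[s]


@dataclass(frozen=True)
class BehaviourFlags:
    """Derived per-visit behaviour indicators; NaN encodes missing."""

    nsP: float
    nsCAI: float


def derive_behaviour_flags(ans_nsP, ans_intercourse, ans_condom_always) -> BehaviourFlags:
    """Map the three questionnaire answers to (nsP, nsCAI) flags.

    Total over the 27 three-state combinations. The gate question (a)
    decides nsP directly. nsCAI is evaluated left to right: a "no" at any
    gate short-circuits to 0 ("yes" for condom use), and the first missing
    answer on the still-open path makes nsCAI missing.
    """
    a = _parse_answer(ans_nsP)
    b = _parse_answer(ans_intercourse)
    c = _parse_answer(ans_condom_always)

    nsP = a
    if np.isnan(a):
        nsCAI = np.nan
    elif a == 0.0:
        nsCAI = 0.0
    elif np.isnan(b):
        nsCAI = np.nan
    elif b == 0.0:
        nsCAI = 0.0
    elif np.isnan(c):
        nsCAI = np.nan
    else:
        nsCAI = 1.0 if c == 0.0 else 0.0
    return BehaviourFlags(nsP=nsP, nsCAI=nsCAI)


def add_behaviour_flags(visits: pd.DataFrame) -> pd.DataFrame:
    """Append derived nsP / nsCAI columns to a visit table."""
    flags = [
        derive_behaviour_flags(r.ans_nsP, r.ans_intercourse, r.ans_condom_always)
        for r in visits.itertuples()
    ]
    out = visits.copy()
    out["nsP"] = [f.nsP for f in flags]
    out["nsCAI"] = [f.nsCAI for f in flags]
    return out


# ---------------------------------------------------------------------------
# Syphilis serology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyphilisEpisode:
    participant_id: object
    episode_date: dt.date
    trigger: str  # "treponemal_seroconversion" | "vdrl_rise"


def classify_incident_syphilis(
    labs: pd.DataFrame,
    titer_threshold: int = 8,
    fold_increase: float = 4.0,
    strict_fold: bool = True,
    rise_from_zero: bool = True,
) -> list[SyphilisEpisode]:
    """Incident syphilis episodes for one participant's serology history.

    ``labs`` must be sorted by date with at most one record per date; columns
    ``participant_id``, ``date``, ``treponemal_result`` (positive/negative/
    missing) and ``vdrl_titer`` (reciprocal titer, 0 = non-reactive, NaN =
    not done). An episode is emitted at a record when either

    * the treponemal result flips negative -> positive relative to the most
      recent non-missing prior result, or
    * the titer exceeds ``titer_threshold`` AND exceeds ``fold_increase``
      times the most recent prior non-missing titer (strict ``>`` by default;
      set ``strict_fold=False`` for ``>=``). A record with no prior titer
      cannot trigger this arm; a prior non-reactive titer of 0 makes any
      titer above the threshold qualify unless ``rise_from_zero=False``.

    A record satisfying both rules yields a single episode (seroconversion
    takes precedence as the trigger).
    """
    dates = pd.to_datetime(labs["date"]).to_list()
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("lab records must be sorted by date, one record per date")

    episodes: list[SyphilisEpisode] = []
    prev_trep: float | None = None  # 1 positive / 0 negative
    prev_titer: float | None = None
    for (_, row), date in zip(labs.iterrows(), dates):
        trep = _parse_trep(row.get("treponemal_result"))
        titer = row.get("vdrl_titer")
        titer = float(titer) if titer is not None and not pd.isna(titer) else None

        trigger = None
        if trep == 1.0 and prev_trep == 0.0:
            trigger = "treponemal_seroconversion"
        elif titer is not None and prev_titer is not None and titer > titer_threshold:
            if prev_titer == 0:
                if rise_from_zero:
                    trigger = "vdrl_rise"
            else:
                ratio_ok = (titer > fold_increase * prev_titer if strict_fold
                            else titer >= fold_increase * prev_titer)
                if ratio_ok:
                    trigger = "vdrl_rise"
        if trigger is not None:
            episodes.append(SyphilisEpisode(row["participant_id"], date.date(), trigger))

        if trep is not None:
            prev_trep = trep
        if titer is not None:
            prev_titer = titer
    return episodes


def _parse_trep(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "nan", "missing", "na"):
        return None
    if s in ("positive", "pos", "1"):
        return 1.0
    if s in ("negative", "neg", "0"):
        return 0.0
    raise ValueError(f"treponemal_result must be positive/negative/missing, got {value!r}")


def classify_syphilis_episodes(labs: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Cohort-level wrapper: sort each participant's records by date and
    classify; returns (participant_id, episode_date, trigger) rows."""
    rows = []
    for _pid, grp in labs.sort_values(["participant_id", "date"]).groupby(
            "participant_id", sort=True):
        rows.extend(classify_incident_syphilis(grp, **kwargs))
    return pd.DataFrame(
        [(e.participant_id, pd.Timestamp(e.episode_date), e.trigger) for e in rows],
        columns=["participant_id", "episode_date", "trigger"],
    )


# ---------------------------------------------------------------------------
# Inclusion criteria and cut-off split
# ---------------------------------------------------------------------------

def apply_inclusion_criteria(
    visits: pd.DataFrame,
    cutoff_date,
    feature: str = "nsCAI",
    min_span_years: float = 2.0,
    min_records: int = 2,
) -> list:
    """Participants eligible for the analysis.

    Requires, per participant: at least ``min_records`` non-missing values of
    the behaviour ``feature`` strictly before the cut-off; a span of at least
    ``min_span_years`` between the first and last such record (calendar-exact
    for whole years); and at least one post-cut-off visit with a non-missing
    value of the feature (so the first-follow-up outcome is defined).
    """
    if feature not in visits.columns:
        raise ValueError(f"visits lack derived flag column {feature!r}; "
                         "call add_behaviour_flags first")
    cutoff = pd.Timestamp(cutoff_date)
    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    obs = v[(v["visit_date"] < cutoff) & v[feature].notna()]
    post = v[(v["visit_date"] >= cutoff) & v[feature].notna()]

    included = []
    post_ids = set(post["participant_id"])
    for pid, grp in obs.groupby("participant_id"):
        if len(grp) < min_records or pid not in post_ids:
            continue
        first, last = grp["visit_date"].min(), grp["visit_date"].max()
        if float(min_span_years).is_integer():
            ok = last >= first + pd.DateOffset(years=int(min_span_years))
        else:
            ok = (last - first).days >= 365.25 * min_span_years
        if ok:
            included.append(pid)
    if not included:
        raise ValueError("no participants satisfy the inclusion criteria")
    logger.info(
        "inclusion: %d of %d participants retained",
        len(included), visits["participant_id"].nunique(),
    )
    return sorted(included)


@dataclass
class CutoffSplit:
    """Records partitioned at the cut-off: [start, cutoff) observation,
    [cutoff, end] outcome."""

    cutoff_date: pd.Timestamp
    observation: pd.DataFrame
    outcome: pd.DataFrame


def split_periods(records: pd.DataFrame, cutoff_date, date_col: str = "visit_date") -> CutoffSplit:
    """Strictly partition dated records at the cut-off (half-open: a record
    dated exactly on the cut-off belongs to the outcome period)."""
    cutoff = pd.Timestamp(cutoff_date)
    dates = pd.to_datetime(records[date_col])
    before = records[dates < cutoff]
    after = records[dates >= cutoff]
    return CutoffSplit(cutoff, before, after)


# ---------------------------------------------------------------------------
# Outcome table
# ---------------------------------------------------------------------------

def derive_outcome_table(
    visits: pd.DataFrame,
    cutoff_date,
    included,
    episodes: pd.DataFrame | None = None,
    sti_reports: pd.DataFrame | None = None,
    participants: pd.DataFrame | None = None,
    feature: str = "nsCAI",
) -> pd.DataFrame:
    """One row per included participant: post-cut-off outcomes + covariates.

    Outcomes: the behaviour flag at the first post-cut-off follow-up with a
    non-missing value (``first_nsCAI`` / ``first_nsP``), any / count of
    nurse- or physician-reported STIs, and any / count of laboratory-
    confirmed syphilis episodes in the outcome period. Covariates: age at
    cut-off (from the participants table's birth dates), the last non-missing
    pre-cut-off flag, and prior syphilis as both indicator and episode count.
    """
    cutoff = pd.Timestamp(cutoff_date)
    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    v = v[v["participant_id"].isin(set(included))]
    split = split_periods(v, cutoff)

    rows = {}
    for pid in included:
        pre = split.observation[split.observation["participant_id"] == pid]
        post = split.outcome[split.outcome["participant_id"] == pid].sort_values("visit_date")
        row = {}
        for feat in ("nsCAI", "nsP"):
            if feat in post.columns:
                valid = post[post[feat].notna()]
                if feat == feature and valid.empty:
                    raise ValueError(
                        f"participant {pid!r} has no post-cut-off {feat} record "
                        "(should have been excluded)"
                    )
                row[f"first_{feat}"] = int(valid[feat].iloc[0]) if not valid.empty else np.nan
        pre_valid = pre[pre[feature].notna()].sort_values("visit_date")
        row["last_flag"] = int(pre_valid[feature].iloc[-1]) if not pre_valid.empty else np.nan
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"

    # STI reports
    out["any_sti"], out["sti_count"] = 0, 0
    if sti_reports is not None and len(sti_reports):
        sti = sti_reports.copy()
        sti["report_date"] = pd.to_datetime(sti["report_date"])
        sti = sti[(sti["report_date"] >= cutoff) & sti["participant_id"].isin(out.index)]
        counts = sti.groupby("participant_id").size()
        out.loc[counts.index, "sti_count"] = counts
        out["any_sti"] = (out["sti_count"] > 0).astype(int)

    # syphilis episodes, before and after cut-off
    out["any_syphilis"], out["syphilis_count"] = 0, 0
    out["prior_syphilis"], out["prior_syphilis_count"] = 0, 0
    if episodes is not None and len(episodes):
        ep = episodes.copy()
        ep["episode_date"] = pd.to_datetime(ep["episode_date"])
        ep = ep[ep["participant_id"].isin(out.index)]
        post_counts = ep[ep["episode_date"] >= cutoff].groupby("participant_id").size()
        prior_counts = ep[ep["episode_date"] < cutoff].groupby("participant_id").size()
        out.loc[post_counts.index, "syphilis_count"] = post_counts
        out.loc[prior_counts.index, "prior_syphilis_count"] = prior_counts
        out["any_syphilis"] = (out["syphilis_count"] > 0).astype(int)
        out["prior_syphilis"] = (out["prior_syphilis_count"] > 0).astype(int)

    # age at cut-off
    if participants is not None:
        birth = participants.set_index("participant_id")["birth_date"]
        birth = pd.to_datetime(birth).reindex(out.index)
        out["age"] = (cutoff - birth).dt.days / 365.25
    else:
        logger.warning("no participants table given; age covariate is missing")
        out["age"] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _read_table(path, required: list[str], date_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - set(required)
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
        df = df[required]
    for col in date_cols:
        df[col] = pd.to_datetime(df[col])
    return df


def read_visits(path) -> pd.DataFrame:
    return _read_table(path, VISIT_COLUMNS, ["visit_date"])


def read_labs(path) -> pd.DataFrame:
    return _read_table(path, LAB_COLUMNS, ["date"])


def read_sti_reports(path) -> pd.DataFrame:
    return _read_table(path, STI_COLUMNS, ["report_date"])


def read_participants(path) -> pd.DataFrame:
    return _read_table(path, PARTICIPANT_COLUMNS, ["birth_date"])
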