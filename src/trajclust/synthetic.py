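"""Synthetic longitudinal cohorts with planted behavioural cluster structure.

Real visit-level behaviour data of the kind this package analyses are
access-restricted, so every downstream stage is exercised on simulated
cohorts with known ground truth. The generator emulates the structure of a
semiannual HIV-cohort follow-up: a fixed calendar grid of half-year bins,
per-participant missing visits, a large "never reports the behaviour"
baseline stratum, and latent subgroups whose probability of reporting the
behaviour follows distinct smooth time curves. Post-cut-off outcomes (next
reported behaviour, STI reports, incident syphilis) are drawn from logistic
or Poisson models whose coefficients are known, so that recovery of both the
cluster structure and the outcome effects can be tested.

Within a participant, bins are conditionally independent given the latent
cluster: the generator plants no serial correlation beyond cluster
membership.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .trajectory import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterProfile",
    "OutcomeEffects",
    "SyntheticTruth",
    "make_default_profiles",
    "simulate_cohort",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_study",
]

# Study-condition defaults: cohort size, stratum weights and noise levels used
# throughout the test-bed simulations.
DEFAULT_N_PARTICIPANTS = 600
DEFAULT_BASELINE_FRACTION = 0.30
DEFAULT_VISIT_MISSINGNESS = 0.20
DEFAULT_K = 3

_MAX_TEMPLATES = 6


@dataclass(frozen=True)
class ClusterProfile:
    """A latent subgroup: per-bin event probabilities and mixture weight.

    ``weight`` is the subgroup's share among non-baseline participants
    (weights across profiles sum to 1; the baseline stratum's share is set
    separately at simulation time).
    """

    label: int
    curve: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "curve", np.asarray(self.curve, dtype=float))
        if self.label < 1:
            raise ValueError("profile labels start at 1 (0 is the baseline stratum)")
        if np.any((self.curve < 0) | (self.curve > 1)):
            raise ValueError("curve probabilities must lie in [0, 1]")
        if not 0 < self.weight < 1 and self.weight != 1.0:
            raise ValueError("weight must lie in (0, 1]")


def make_default_profiles(K: int, n_bins: int) -> list[ClusterProfile]:
    """K well-separated probability curves over ``n_bins`` half-year bins.

    Templates (in order): flat-low, flat-high, rising logistic ramp, falling
    logistic ramp, flat-mid, mid-study hump. Mean pairwise L1 distance
    between any two emitted curves is at least 0.15 by construction.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if K > _MAX_TEMPLATES:
        raise ValueError(
            f"only {_MAX_TEMPLATES} curve templates are implemented; got K={K}"
        )
    t = np.linspace(0.0, 1.0, n_bins)
    ramp_up = 0.05 + 0.80 * expit(10.0 * (t - 0.5))
    templates = [
        np.full(n_bins, 0.12),                       # flat low
        np.full(n_bins, 0.72),                       # flat high
        ramp_up,                                     # rising
        ramp_up[::-1].copy(),                        # falling
        np.full(n_bins, 0.42),                       # flat mid
        0.10 + 0.60 * np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2),  # hump
    ]
    return [
        ClusterProfile(label=i + 1, curve=templates[i], weight=1.0 / K)
        for i in range(K)
    ]


@dataclass
class OutcomeEffects:
    """True coefficients of a generative outcome model (log-odds scale for
    binary outcomes, log-rate scale for counts).

    ``beta_cluster`` has one entry per cluster label 0..K with the baseline
    entry fixed at 0 (reference coding). ``beta_age`` applies per year of
    age centred at 40, so ``intercept`` is the linear predictor of a
    40-year-old baseline-cluster participant with no prior flags.
    """

    intercept: float
    beta_cluster: np.ndarray
    beta_last: float = 0.0
    beta_syphilis: float = 0.0
    beta_age: float = 0.0

    def __post_init__(self) -> None:
        self.beta_cluster = np.asarray(self.beta_cluster, dtype=float)
        if self.beta_cluster[0] != 0.0:
            raise ValueError("baseline cluster effect must be 0 (reference coding)")

    @classmethod
    def default(cls, K: int, family: str = "binary",
                cluster_effect: float = 1.0) -> "OutcomeEffects":
        """Default planted effects: cluster effects alternating +/-
        ``cluster_effect`` (log-odds +/-1 for the binary behaviour outcome),
        modest effects of last flag, prior syphilis and age."""
        beta = np.zeros(K + 1)
        beta[1:] = [cluster_effect * (1 if i % 2 == 1 else -1) for i in range(1, K + 1)]
        if family == "binary":
            return cls(intercept=-1.0, beta_cluster=beta, beta_last=0.5,
                       beta_syphilis=0.7, beta_age=-0.02)
        if family == "count":
            return cls(intercept=float(np.log(0.3)), beta_cluster=0.6 * np.sign(beta),
                       beta_last=0.4, beta_syphilis=0.3, beta_age=-0.02)
        raise ValueError(f"unknown family {family!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort."""

    labels: dict  # participant_id -> planted cluster label (0 = baseline)
    profiles: list[ClusterProfile]
    baseline_fraction: float
    seed: int
    effects: dict = field(default_factory=dict)  # outcome name -> OutcomeEffects

    @property
    def mixture(self) -> dict:
        """Stratum weights including the baseline; sums to 1."""
        bf = self.baseline_fraction
        total_w = sum(p.weight for p in self.profiles)
        mix = {0: bf}
        mix.update({p.label: (1 - bf) * p.weight / total_w for p in self.profiles})
        return mix

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, name="planted_label").rename_axis("participant_id")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "baseline_fraction": self.baseline_fraction,
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "profiles": [
                {"label": p.label, "weight": p.weight, "curve": p.curve.tolist()}
                for p in self.profiles
            ],
            "effects": {
                name: {
                    "intercept": e.intercept,
                    "beta_cluster": e.beta_cluster.tolist(),
                    "beta_last": e.beta_last,
                    "beta_syphilis": e.beta_syphilis,
                    "beta_age": e.beta_age,
                }
                for name, e in self.effects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        profiles = [
            ClusterProfile(p["label"], np.asarray(p["curve"]), p["weight"])
            for p in payload["profiles"]
        ]
        effects = {
            name: OutcomeEffects(
                intercept=e["intercept"], beta_cluster=np.asarray(e["beta_cluster"]),
                beta_last=e["beta_last"], beta_syphilis=e["beta_syphilis"],
                beta_age=e["beta_age"],
            )
            for name, e in payload["effects"].items()
        }
        return cls(labels=dict(payload["labels"]), profiles=profiles,
                   baseline_fraction=payload["baseline_fraction"],
                   seed=payload["seed"], effects=effects)


# ---------------------------------------------------------------------------
# Visit simulation
# ---------------------------------------------------------------------------

def _answers_for_event(event: int, rng: np.random.Generator,
                       condom_user_prob: float = 0.3) -> tuple[str, str, str]:
    # event rows are (yes, yes, no); non-event rows are either non-steady
    # partners with consistent condom use or no non-steady partners at all
    if event:
        return "yes", "yes", "no"
    if rng.random() < condom_user_prob:
        return "yes", "yes", "yes"
    return "no", "", ""


def simulate_cohort(
    profiles: list[ClusterProfile],
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    baseline_fraction: float = DEFAULT_BASELINE_FRACTION,
    visit_missingness: float = DEFAULT_VISIT_MISSINGNESS,
    seed: int = 0,
    grid: TimeGrid | None = None,
    late_entry_max_bins: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a visit table over the semiannual grid.

    Each participant is assigned to the baseline stratum with probability
    ``baseline_fraction`` or to a profile by weight. One visit is scheduled
    per half-year bin, dated uniformly inside the bin, and then thinned by
    independent Bernoulli(``visit_missingness``) dropout per (participant,
    bin); ``late_entry_max_bins`` > 0 additionally truncates a uniformly
    drawn number of leading bins to mimic staggered enrolment. At each
    retained bin a non-baseline participant reports the behaviour with the
    profile's bin probability; baseline participants never do. Identical
    seeds yield byte-identical tables.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if not 0 <= baseline_fraction < 1:
        raise ValueError("baseline_fraction must be in [0, 1)")
    if not 0 <= visit_missingness < 1:
        raise ValueError("visit_missingness must be in [0, 1)")
    grid = grid or TimeGrid.default()
    for p in profiles:
        if len(p.curve) != grid.n_bins:
            raise ValueError(
                f"profile {p.label} curve length {len(p.curve)} != {grid.n_bins} bins"
            )

    rng = np.random.default_rng(seed)
    width = len(str(n_participants))
    ids = [f"P{i:0{width}d}" for i in range(1, n_participants + 1)]

    w = np.array([p.weight for p in profiles], dtype=float)
    w = w / w.sum()
    labels = {}
    rows = []
    curve_by_label = {p.label: p.curve for p in profiles}
    profile_labels = np.array([p.label for p in profiles])

    for pid in ids:
        if rng.random() < baseline_fraction:
            lab = 0
        else:
            lab = int(rng.choice(profile_labels, p=w))
        labels[pid] = lab
        entry = int(rng.integers(0, late_entry_max_bins + 1)) if late_entry_max_bins else 0
        for b in range(grid.n_bins):
            if b < entry or rng.random() < visit_missingness:
                continue
            start, end = grid.bin_start(b), grid.bin_end(b)
            day = int(rng.integers(0, (end - start).days))
            date = start + pd.Timedelta(days=day)
            p_event = 0.0 if lab == 0 else float(curve_by_label[lab][b])
            event = int(rng.random() < p_event)
            a, bq, c = _answers_for_event(event, rng)
            rows.append((pid, pd.Timestamp(date), a, bq, c))

    visits = pd.DataFrame(
        rows, columns=["participant_id", "visit_date", "ans_nsP",
                       "ans_intercourse", "ans_condom_always"],
    )
    truth = SyntheticTruth(labels=labels, profiles=list(profiles),
                           baseline_fraction=baseline_fraction, seed=int(seed))
    logger.info("simulated %d participants, %d visits (%d baseline)",
                n_participants, len(visits), sum(1 for v in labels.values() if v == 0))
    return visits, truth


# ---------------------------------------------------------------------------
# Covariates and outcomes
# ---------------------------------------------------------------------------

def simulate_covariates(
    truth: SyntheticTruth,
    seed: int,
    visits: pd.DataFrame | None = None,
    cutoff_date=None,
    feature: str = "nsCAI",
) -> pd.DataFrame:
    """Per-participant covariates: age, last pre-cut-off flag, prior syphilis.

    Age is Normal(40, 10) truncated to [18, 80]. Prior syphilis is Bernoulli
    with a cluster-dependent probability (0.05 + 0.04 per label step), with a
    small extra Poisson count of further episodes. ``last_flag`` is derived
    from the supplied visit table when given (last non-missing flag before
    ``cutoff_date``), otherwise drawn from the profile's final-bin
    probability.
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(seed)
    ids = sorted(truth.labels)
    lab = np.array([truth.labels[p] for p in ids])
    n = len(ids)

    a, b = (18 - 40) / 10, (80 - 40) / 10
    age = truncnorm.ppf(rng.random(n), a, b, loc=40, scale=10)

    p_prior = np.clip(0.05 + 0.04 * lab, 0, 0.5)
    prior = (rng.random(n) < p_prior).astype(int)
    prior_count = prior * (1 + rng.poisson(0.4, size=n))

    if visits is not None:
        from .ingest import add_behaviour_flags
        v = visits if feature in visits.columns else add_behaviour_flags(visits)
        v = v[v[feature].notna()].sort_values("visit_date")
        if cutoff_date is not None:
            v = v[pd.to_datetime(v["visit_date"]) < pd.Timestamp(cutoff_date)]
        last = v.groupby("participant_id")[feature].last()
        last_flag = last.reindex(ids).fillna(0).astype(int).to_numpy()
    else:
        final_p = {p.label: float(p.curve[-1]) for p in truth.profiles}
        final_p[0] = 0.0
        last_flag = (rng.random(n) < np.array([final_p[l] for l in lab])).astype(int)

    return pd.DataFrame({
        "participant_id": ids,
        "planted_label": lab,
        "age": age,
        "last_flag": last_flag,
        "prior_syphilis": prior,
        "prior_syphilis_count": prior_count,
    }).set_index("participant_id")


def simulate_outcomes(
    truth: SyntheticTruth,
    covariates: pd.DataFrame,
    effects: OutcomeEffects,
    family: str = "binary",
    seed: int = 0,
) -> pd.Series:
    """Draw one outcome per participant from the planted GLM.

    Binary outcomes are Bernoulli(inverse-logit(lp)); counts are
    Poisson(exp(lp)), with lp = intercept + cluster effect + last-flag,
    prior-syphilis and centred-age terms. For count families the
    prior-syphilis term multiplies the episode count rather than the
    indicator.
    """
    if family not in ("binary", "count"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    ids = covariates.index
    lab = np.array([truth.labels[p] for p in ids])
    syph = (covariates["prior_syphilis_count"] if family == "count"
            else covariates["prior_syphilis"]).to_numpy(dtype=float)
    lp = (
        effects.intercept
        + effects.beta_cluster[lab]
        + effects.beta_last * covariates["last_flag"].to_numpy(dtype=float)
        + effects.beta_syphilis * syph
        + effects.beta_age * (covariates["age"].to_numpy(dtype=float) - 40.0)
    )
    if family == "binary":
        y = (rng.random(len(ids)) < expit(lp)).astype(int)
    else:
        y = rng.poisson(np.exp(lp))
    return pd.Series(y, index=ids, name="outcome")


# ---------------------------------------------------------------------------
# Full study simulation (visits + labs + STI reports + outcomes)
# ---------------------------------------------------------------------------

def _default_effects(K: int) -> dict:
    return {
        "first_nsCAI": OutcomeEffects.default(K, "binary"),
        "sti_count": OutcomeEffects.default(K, "count"),
        "syphilis_count": OutcomeEffects(
            intercept=float(np.log(0.15)),
            beta_cluster=0.6 * np.sign(OutcomeEffects.default(K, "binary").beta_cluster),
            beta_last=0.4, beta_syphilis=0.3, beta_age=-0.02,
        ),
    }


def simulate_study(
    K: int = DEFAULT_K,
    n_participants: int = DEFAULT_N_PARTICIPANTS,
    baseline_fraction: float = DEFAULT_BASELINE_FRACTION,
    visit_missingness: float = DEFAULT_VISIT_MISSINGNESS,
    seed: int = 0,
    grid: TimeGrid | None = None,
    cutoff_date="2017-05-01",
    n_post_visits: int = 2,
    effects: dict | None = None,
) -> dict:
    """Simulate a complete study: visit, lab, STI and participant tables.

    Returns a dict with keys ``visits``, ``labs``, ``sti``, ``participants``
    (DataFrames in the CSV dialects the ingest module reads) and ``truth``.
    Post-cut-off behaviour follows a planted logistic model; STI reports and
    syphilis episode counts follow planted Poisson models, and syphilis
    episodes are encoded into a serology history (seroconversion for the
    first episode, titer rises for recurrences) that the classifier recovers
    exactly.
    """
    grid = grid or TimeGrid.default()
    cutoff = pd.Timestamp(cutoff_date)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(6)]

    profiles = make_default_profiles(K, grid.n_bins)
    visits, truth = simulate_cohort(
        profiles, n_participants, baseline_fraction, visit_missingness,
        seed=seeds[0], grid=grid,
    )
    truth.seed = int(seed)
    cov = simulate_covariates(truth, seeds[1], visits=visits, cutoff_date=cutoff)
    eff = effects or _default_effects(K)
    truth.effects = eff

    y_beh = simulate_outcomes(truth, cov, eff["first_nsCAI"], "binary", seeds[2])
    y_sti = simulate_outcomes(truth, cov, eff["sti_count"], "count", seeds[3])
    y_syp = simulate_outcomes(truth, cov, eff["syphilis_count"], "count", seeds[4])

    rng = np.random.default_rng(seeds[5])
    ids = sorted(truth.labels)

    # post-cut-off follow-up visits encoding the behaviour outcome
    post_rows = []
    for pid in ids:
        flag = int(y_beh.loc[pid])
        for j in range(n_post_visits):
            date = cutoff + pd.Timedelta(days=30 + 180 * j + int(rng.integers(0, 21)))
            ev = flag if j == 0 else int(rng.random() < (0.7 if flag else 0.15))
            a, bq, c = _answers_for_event(ev, rng)
            post_rows.append((pid, date, a, bq, c))
    visits = pd.concat(
        [visits, pd.DataFrame(post_rows, columns=visits.columns)],
        ignore_index=True,
    ).sort_values(["participant_id", "visit_date"], kind="stable").reset_index(drop=True)

    # STI reports after cut-off
    sti_rows = []
    for pid in ids:
        for j in range(int(y_sti.loc[pid])):
            date = cutoff + pd.Timedelta(days=20 + 150 * j + int(rng.integers(0, 60)))
            sti_rows.append((pid, date))
    sti = pd.DataFrame(sti_rows, columns=["participant_id", "report_date"])

    # serology history encoding prior and post-cut-off syphilis episodes
    obs_start = pd.Timestamp(grid.span[0])
    lab_rows = []
    for pid in ids:
        lab_rows.append((pid, obs_start + pd.Timedelta(days=14), "negative", 0))
        n_prior = int(cov.loc[pid, "prior_syphilis_count"])
        n_post = int(y_syp.loc[pid])
        window = (cutoff - obs_start).days - 400
        seropositive = False
        for j in range(n_prior):
            d = obs_start + pd.Timedelta(
                days=200 + (j + 1) * window // (n_prior + 1) + int(rng.integers(0, 30)))
            lab_rows.append((pid, d, "positive", 32))
            lab_rows.append((pid, d + pd.Timedelta(days=120), "positive", 2))
            seropositive = True
        for j in range(n_post):
            d = cutoff + pd.Timedelta(days=60 + 300 * j + int(rng.integers(0, 30)))
            if not seropositive:
                lab_rows.append((pid, d, "positive", 32))
                seropositive = True
            else:
                lab_rows.append((pid, d, "positive", 32))
            lab_rows.append((pid, d + pd.Timedelta(days=120), "positive", 2))
    labs = pd.DataFrame(
        lab_rows, columns=["participant_id", "date", "treponemal_result", "vdrl_titer"]
    ).sort_values(["participant_id", "date"], kind="stable").reset_index(drop=True)

    participants = pd.DataFrame({
        "participant_id": ids,
        "birth_date": [cutoff - pd.Timedelta(days=round(cov.loc[p, "age"] * 365.25))
                       for p in ids],
    })

    return {"visits": visits, "labs": labs, "sti": sti,
            "participants": participants, "truth": truth,
            "covariates": cov,
            "outcomes": pd.DataFrame({"first_nsCAI": y_beh, "sti_count": y_sti,
                                      "syphilis_count": y_syp})}
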