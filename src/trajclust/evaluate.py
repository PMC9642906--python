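"""Nested GLM comparison: do behavioural clusters improve prediction?

For each post-cut-off outcome a nested model (age + last pre-cut-off flag +
prior syphilis) is compared against the same model augmented with cluster
membership (reference-coded against baseline cluster 0) or with one of the
simple trajectory summaries (last, last two, ever, mean). Model pairs are
compared by likelihood ratio test, AIC, BIC and in-sample auROC, optionally
re-assessed under seeded stratified k-fold cross-validation, and the number
of clusters is swept by re-cutting the dendrogram.

Binary outcomes use logistic regression and count outcomes Poisson
regression (negative binomial available as an option); prior syphilis enters
as an indicator in binary models and as an episode count in count models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, rankdata

from .cluster import Dendrogram, assign_baseline_cluster, cut_to_k
from .trajectory import TrajectoryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "LRTResult",
    "ComparisonRow",
    "CvReport",
    "NESTED_COVARIATES",
    "fit_glm",
    "likelihood_ratio_test",
    "information_criteria",
    "auroc",
    "kfold_cv",
    "compare_models",
    "sweep_cluster_number",
]

#: covariate set of the conventional ("without clusters") adjustment model
NESTED_COVARIATES = ("age", "last_flag", "prior_syphilis")

_SUMMARY_TOKENS = {"last", "last_two", "ever", "mean"}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, family and covariate tokens of one GLM.

    Covariate tokens: ``age``, ``last_flag``, ``prior_syphilis``, ``cluster``
    (expands to k reference-coded dummies), ``last_two`` (two binary
    columns), ``ever``, ``mean``, ``last`` (alias of ``last_flag``).
    """

    outcome: str
    family: str  # "binary" | "count" | "negbin"
    covariates: tuple = NESTED_COVARIATES

    def __post_init__(self) -> None:
        if self.family not in ("binary", "count", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


def _design(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for token in spec.covariates:
        if token in ("last", "last_flag"):
            cols["last_flag"] = data["last_flag"].to_numpy(dtype=float)
        elif token == "prior_syphilis":
            # indicator for binary outcomes, episode count for count outcomes
            src = ("prior_syphilis_count" if spec.family in ("count", "negbin")
                   else "prior_syphilis")
            cols[src] = data[src].to_numpy(dtype=float)
        elif token == "cluster":
            labels = data["cluster"].to_numpy(dtype=int)
            present = sorted(set(labels))
            # baseline cluster 0 is the reference; if it is empty in the data
            # the lowest present label takes its place
            ref = 0 if 0 in present else present[0]
            for lab in present:
                if lab != ref:
                    cols[f"cluster_{lab}"] = (labels == lab).astype(float)
        elif token == "last_two":
            cols["last_two_older"] = data["last_two_older"].to_numpy(dtype=float)
            # the newer of the two latest values IS the last flag; keep only
            # one copy when both tokens are requested
            if "last_flag" not in cols:
                cols["last_two_newer"] = data["last_two_newer"].to_numpy(dtype=float)
        elif token in ("age", "ever", "mean"):
            cols[token] = data[token].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate token {token!r}")
    X = pd.DataFrame(cols, index=data.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify a set of columns whose removal restores full column rank
    culprits = []
    keep = list(range(arr.shape[1]))
    for j in range(arr.shape[1] - 1, -1, -1):
        trial = [c for c in keep if c != j]
        if np.linalg.matrix_rank(arr[:, trial]) == rank:
            culprits.append(X.columns[j])
            keep = trial
    raise ValueError(f"rank-deficient design; collinear columns: {sorted(culprits)}")


@dataclass
class ModelFit:
    """A fitted GLM: exact log-likelihood, coefficients and fitted means."""

    spec: ModelSpec
    loglik: float
    n_params: int
    n_obs: int
    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    flagged: bool = False
    messages: list = field(default_factory=list)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted mean for new rows (inverse-link of the linear predictor)."""
        X = _design(self.spec, data)[self.params.index]
        lp = X.to_numpy() @ self.params.to_numpy()
        return expit(lp) if self.spec.family == "binary" else np.exp(lp)


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood GLM fit (logistic / Poisson / negative binomial).

    Degenerate situations are surfaced, not silently returned: a constant
    outcome or quasi-separated fit is flagged on the result, and a rank-
    deficient design raises an error naming the collinear columns.
    """
    y = data[spec.outcome]
    if y.isna().any():
        raise ValueError(f"outcome {spec.outcome!r} has missing values")
    y = y.to_numpy(dtype=float)
    if spec.family == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary outcome must be 0/1")
    X = _design(spec, data)
    _check_rank(X)

    if spec.family == "binary":
        family = sm.families.Binomial()
    elif spec.family == "count":
        family = sm.families.Poisson()
    else:
        family = sm.families.NegativeBinomial()

    flagged, messages = False, []
    if len(np.unique(y)) == 1:
        flagged = True
        messages.append(f"degenerate fit: outcome {spec.outcome!r} is constant")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=family).fit()
    for w in caught:
        msg = str(w.message)
        if ("separat" in msg.lower() or "divergence" in msg.lower()) and msg not in messages:
            flagged = True
            messages.append(msg)
    if flagged:
        logger.warning("flagged fit for %s: %s", spec.outcome, "; ".join(messages))
    return ModelFit(
        spec=spec,
        loglik=float(res.llf),
        n_params=int(res.df_model + 1),
        n_obs=int(res.nobs),
        params=res.params,
        bse=res.bse,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        flagged=flagged,
        messages=messages,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(full: ModelFit, nested: ModelFit,
                          tolerance: float = 1e-6) -> LRTResult:
    """Likelihood ratio test of two nested maximum-likelihood fits.

    The statistic 2(ll_full - ll_nested) is referred to a chi-square with
    degrees of freedom equal to the parameter-count difference. Identical
    models (df = 0) give p = 1.
    """
    if full.spec.family != nested.spec.family or full.n_obs != nested.n_obs:
        raise ValueError("models must share family and data")
    if not set(nested.params.index) <= set(full.params.index):
        raise ValueError("models are not nested (covariates are not a subset)")
    if full.loglik < nested.loglik - tolerance:
        raise ValueError(
            f"full model log-likelihood {full.loglik:.6f} below nested "
            f"{nested.loglik:.6f}: not a valid nesting"
        )
    df = full.n_params - nested.n_params
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, pvalue=p)


def information_criteria(fit: ModelFit) -> tuple[float, float]:
    """(AIC, BIC) = (-2 ll + 2k, -2 ll + k ln n)."""
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * np.log(fit.n_obs)
    return float(aic), float(bic)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auROC needs both outcome classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-fold and pooled out-of-sample performance of one model."""

    k_folds: int
    seed: int
    fold_accuracy: list
    fold_auroc: list  # NaN where a held-out fold had a single class
    pooled_accuracy: float
    pooled_auroc: float


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified folds; overall fold sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[counter % k].append(int(i))
            counter += 1
    return [np.sort(np.array(f)) for f in folds]


def kfold_cv(
    spec_with: ModelSpec,
    spec_without: ModelSpec,
    data: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[CvReport, CvReport]:
    """Stratified k-fold cross-validation of two binary-outcome models.

    Folds are drawn by a seeded permutation stratified on the outcome. Any
    pre-computed cluster labels in ``data`` are treated as fixed covariates
    (the clustering is not re-run per training fold; it derives from the
    observation period only). Accuracy classifies at ``threshold`` on the
    fitted probability; a held-out fold with a single outcome class gets an
    undefined (NaN) fold auROC but still contributes accuracy.
    """
    if spec_with.family != "binary" or spec_without.family != "binary":
        raise ValueError("cross-validation is defined for binary outcomes")
    if k < 2 or len(data) < k:
        raise ValueError("need k >= 2 and at least k observations")
    y = data[spec_with.outcome].to_numpy(dtype=float)
    folds = _stratified_folds(y, k, seed)

    reports = []
    for spec in (spec_with, spec_without):
        fold_acc, fold_auc = [], []
        pooled_scores = np.full(len(data), np.nan)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
            fit = fit_glm(spec, data.iloc[train_idx])
            scores = fit.predict(data.iloc[test_idx])
            pooled_scores[test_idx] = scores
            y_test = y[test_idx]
            fold_acc.append(float(np.mean((scores >= threshold) == (y_test == 1))))
            if len(np.unique(y_test)) < 2:
                fold_auc.append(float("nan"))
            else:
                fold_auc.append(auroc(scores, y_test))
        reports.append(CvReport(
            k_folds=k, seed=seed, fold_accuracy=fold_acc, fold_auroc=fold_auc,
            pooled_accuracy=float(np.mean((pooled_scores >= threshold) == (y == 1))),
            pooled_auroc=auroc(pooled_scores, y),
        ))
    return reports[0], reports[1]


# ---------------------------------------------------------------------------
# Model comparison ledger and cluster-number sweep
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    """One line of the model-comparison table for one outcome/comparator."""

    outcome: str
    comparator: str
    family: str
    p_lrt: float            # nested vs nested + comparator
    p_lrt_null: float       # intercept-only vs intercept + comparator
    aic_without: float
    aic_with: float
    bic_without: float
    bic_with: float
    auroc_without: float
    auroc_with: float


def compare_models(
    outcome: str,
    data: pd.DataFrame,
    comparator: str = "cluster",
    family: str = "binary",
) -> ComparisonRow:
    """Fit the conventional adjustment model and the comparator-augmented
    model for one outcome and summarise their comparison.

    ``comparator`` is one of cluster / last / last_two / ever / mean / none.
    Since ``last`` is already part of the adjustment set, that comparator
    (like ``none``) reduces to the nested model and yields p = 1. For count
    outcomes the auROC scores the fitted rate against any-event (count > 0).
    """
    if comparator not in ("cluster", "last", "last_two", "ever", "mean", "none"):
        raise ValueError(f"unknown comparator {comparator!r}")
    nested_spec = ModelSpec(outcome, family, NESTED_COVARIATES)
    if comparator in ("none", "last"):
        full_cov = NESTED_COVARIATES
    else:
        full_cov = NESTED_COVARIATES + (comparator,)
    full_spec = ModelSpec(outcome, family, full_cov)

    nested = fit_glm(nested_spec, data)
    full = fit_glm(full_spec, data) if full_cov != NESTED_COVARIATES else nested
    lrt = likelihood_ratio_test(full, nested)

    null = fit_glm(ModelSpec(outcome, family, ()), data)
    uni_cov = () if comparator in ("none",) else (
        ("last_flag",) if comparator == "last" else (comparator,))
    uni = fit_glm(ModelSpec(outcome, family, uni_cov), data) if uni_cov else null
    lrt_null = likelihood_ratio_test(uni, null)

    aic_wo, bic_wo = information_criteria(nested)
    aic_w, bic_w = information_criteria(full)
    y = data[outcome].to_numpy(dtype=float)
    y_bin = (y > 0).astype(int) if family in ("count", "negbin") else y
    row = ComparisonRow(
        outcome=outcome, comparator=comparator, family=family,
        p_lrt=lrt.pvalue, p_lrt_null=lrt_null.pvalue,
        aic_without=aic_wo, aic_with=aic_w,
        bic_without=bic_wo, bic_with=bic_w,
        auroc_without=auroc(nested.fitted, y_bin),
        auroc_with=auroc(full.fitted, y_bin),
    )
    logger.info(
        "compare_models %s + %s: p_LRT=%.3g BIC %0.1f -> %0.1f",
        outcome, comparator, row.p_lrt, row.bic_without, row.bic_with,
    )
    return row


def sweep_cluster_number(
    tree: Dendrogram,
    matrix: TrajectoryMatrix,
    data: pd.DataFrame,
    outcome: str,
    k_range,
    family: str = "binary",
) -> tuple[pd.DataFrame, int | None]:
    """Re-cut the dendrogram over ``k_range`` and refit the outcome model.

    ``matrix`` is the full trajectory matrix (clustered + baseline
    participants); the tree's leaves are its ever-positive rows. For each k
    the cluster covariate is rebuilt (baseline cluster 0 always included)
    and the nested model refit with it. Returns the per-k table of
    (k, p_LRT, AIC, BIC, loglik) and the BIC-optimal k, or None when no k
    beats the cluster-free model on BIC.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    n_leaves = tree.n_leaves
    if any(k < 1 or k > n_leaves for k in k_range):
        raise ValueError(f"k_range must lie within [1, {n_leaves}]")

    nested = fit_glm(ModelSpec(outcome, family, NESTED_COVARIATES), data)
    _, bic_without = information_criteria(nested)

    clustered_mask = matrix.ever_positive()
    positivity = matrix.subset(clustered_mask).mean_positivity()

    rows = []
    for k in k_range:
        labels = cut_to_k(tree, k, positivity)
        mapping = pd.Series(labels, index=matrix.ids[clustered_mask])
        assignment = assign_baseline_cluster(matrix, mapping)
        d = data.copy()
        d["cluster"] = assignment.labels.reindex(d.index)
        full = fit_glm(ModelSpec(outcome, family, NESTED_COVARIATES + ("cluster",)), d)
        lrt = likelihood_ratio_test(full, nested)
        aic, bic = information_criteria(full)
        rows.append((k, lrt.pvalue, aic, bic, full.loglik))
    table = pd.DataFrame(rows, columns=["k", "p_lrt", "aic", "bic", "loglik"])
    improving = table[table["bic"] < bic_without]
    best_k = None if improving.empty else int(improving.loc[improving["bic"].idxmin(), "k"])
    return table, best_k
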