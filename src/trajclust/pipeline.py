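"""End-to-end analysis pipeline: tables in, comparison ledgers out.

Wires the stages together in the order the method runs: derive behaviour
flags, classify syphilis episodes, apply inclusion criteria, split at the
cut-off, bin trajectories, cluster, build the outcome table, and run the
model comparisons, the cross-validation and the cluster-number sweep.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (assign_baseline_cluster, cluster_trend_curves, cut_to_k,
                      pairwise_distance_matrix, ward_agglomerate)
from .evaluate import (ModelSpec, NESTED_COVARIATES, compare_models, kfold_cv,
                       sweep_cluster_number)
from .ingest import (add_behaviour_flags, apply_inclusion_criteria,
                     classify_syphilis_episodes, derive_outcome_table,
                     split_periods)
from .trajectory import TimeGrid, bin_to_semiannual, summarize_matrix

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Explicit defaults for every analysis choice; loadable from YAML."""

    cutoff_date: str = "2017-05-01"
    feature: str = "nsCAI"          # behaviour feature to cluster on: nsCAI | nsP
    k: int = 4                      # hierarchical clusters (total = k + baseline)
    seed: int = 0
    min_span_years: float = 2.0
    min_records: int = 2
    ward_variant: str = "ward.D2"
    bin_combine: str = "or"         # multiple visits in a bin: "or" | "last"
    grid_start_year: int = 2001
    grid_start_half: int = 2
    grid_n_bins: int = 32
    k_range: list = field(default_factory=lambda: list(range(1, 9)))
    comparators: list = field(default_factory=lambda: ["cluster", "last_two", "ever", "mean"])
    cv_folds: int = 5
    cv_threshold: float = 0.5

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.grid_start_year, self.grid_start_half, self.grid_n_bins)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_analysis(
    visits: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    sti: pd.DataFrame | None = None,
    participants: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> dict:
    """Run the full trajectory-clustering analysis.

    Returns a dict with the trajectory matrix, dendrogram, cluster
    assignment, trend curves, analysis table, comparison table, sweep table
    (+ BIC-optimal k per outcome) and cross-validation reports. When
    ``outdir`` is given, all deliverables are written there as CSV / Newick /
    JSON / PNG.
    """
    cfg = config or AnalysisConfig()
    grid = cfg.grid
    cutoff = pd.Timestamp(cfg.cutoff_date)
    feature = cfg.feature

    n_read = visits["participant_id"].nunique()
    flagged = add_behaviour_flags(visits)
    episodes = (classify_syphilis_episodes(labs)
                if labs is not None and len(labs) else None)

    included = apply_inclusion_criteria(
        flagged, cutoff, feature=feature,
        min_span_years=cfg.min_span_years, min_records=cfg.min_records,
    )
    fl_inc = flagged[flagged["participant_id"].isin(set(included))]
    split = split_periods(fl_inc, cutoff)
    matrix = bin_to_semiannual(split.observation, grid, feature, cfg.bin_combine)
    summaries = summarize_matrix(matrix)

    clustered_mask = matrix.ever_positive()
    sub = matrix.subset(clustered_mask)
    logger.info("pipeline: %d read -> %d included -> %d clustered, %d baseline",
                n_read, len(included), sub.n_participants,
                int((~clustered_mask).sum()))
    dist = pairwise_distance_matrix(sub)
    tree = ward_agglomerate(dist, variant=cfg.ward_variant)
    k = min(cfg.k, sub.n_participants)
    labels = cut_to_k(tree, k, sub.mean_positivity())
    assignment = assign_baseline_cluster(
        matrix, pd.Series(labels, index=sub.ids))
    trends = cluster_trend_curves(matrix, assignment)

    outcome_table = derive_outcome_table(
        flagged, cutoff, included, episodes=episodes, sti_reports=sti,
        participants=participants, feature=feature,
    )
    data = outcome_table.join(summaries.drop(columns=["last"]))
    data["cluster"] = assignment.labels.reindex(data.index)

    binary_outcomes = [f"first_{feature}", "any_sti", "any_syphilis"]
    count_outcomes = ["sti_count", "syphilis_count"]

    rows = []
    for outcome in binary_outcomes + count_outcomes:
        fam = "binary" if outcome in binary_outcomes else "count"
        if data[outcome].nunique() < 2:
            logger.warning("skipping constant outcome %s", outcome)
            continue
        for comparator in cfg.comparators:
            rows.append(dataclasses.asdict(
                compare_models(outcome, data, comparator, fam)))
    comparison = pd.DataFrame(rows)

    sweep_tables, best_ks = [], {}
    for outcome in binary_outcomes + count_outcomes:
        fam = "binary" if outcome in binary_outcomes else "count"
        if data[outcome].nunique() < 2:
            continue
        k_range = [kk for kk in cfg.k_range if kk <= sub.n_participants]
        tab, best = sweep_cluster_number(tree, matrix, data, outcome, k_range, fam)
        tab.insert(0, "outcome", outcome)
        sweep_tables.append(tab)
        best_ks[outcome] = best
    sweep = pd.concat(sweep_tables, ignore_index=True) if sweep_tables else pd.DataFrame()

    cv_reports = {}
    for outcome in binary_outcomes:
        if data[outcome].nunique() < 2:
            continue
        with_spec = ModelSpec(outcome, "binary", NESTED_COVARIATES + ("cluster",))
        without_spec = ModelSpec(outcome, "binary", NESTED_COVARIATES)
        cv_with, cv_without = kfold_cv(
            with_spec, without_spec, data, k=cfg.cv_folds, seed=cfg.seed,
            threshold=cfg.cv_threshold,
        )
        cv_reports[outcome] = {"with_clusters": cv_with, "without_clusters": cv_without}

    results = {
        "config": cfg,
        "included": included,
        "matrix": matrix,
        "summaries": summaries,
        "dendrogram": tree,
        "assignment": assignment,
        "trends": trends,
        "data": data,
        "comparison": comparison,
        "sweep": sweep,
        "best_k": best_ks,
        "cv": cv_reports,
    }
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: AnalysisConfig = results["config"]
    results["comparison"].to_csv(outdir / "comparison_table.csv", index=False,
                                 float_format="%.10g")
    results["sweep"].to_csv(outdir / "sweep.csv", index=False, float_format="%.10g")
    results["trends"].to_csv(outdir / "trends.csv")
    results["assignment"].to_csv(outdir / "assignment.csv")
    results["matrix"].to_csv(outdir / "trajectory_matrix.csv")
    results["dendrogram"].to_csv(outdir / "dendrogram.csv")
    (outdir / "dendrogram.nwk").write_text(results["dendrogram"].to_newick() + "\n")

    cv_payload = {
        outcome: {arm: dataclasses.asdict(rep) for arm, rep in arms.items()}
        for outcome, arms in results["cv"].items()
    }
    (outdir / "cv_report.json").write_text(json.dumps(cv_payload, indent=2, sort_keys=True))

    meta = {
        "software": "trajclust",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "n_included": len(results["included"]),
        "cluster_sizes": {int(kk): int(v) for kk, v in
                          results["assignment"].cluster_sizes.items()},
        "best_k": results["best_k"],
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    _plot_outputs(results, outdir)


def _plot_outputs(results: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trends = results["trends"].proportions
    fig, ax = plt.subplots(figsize=(9, 4.5))
    x = np.arange(trends.shape[1])
    for lab, row in trends.iterrows():
        ax.plot(x, row.to_numpy(), label=f"cluster {lab}")
    step = max(1, len(trends.columns) // 8)
    ax.set_xticks(x[::step], trends.columns[::step], rotation=45)
    ax.set_ylabel("proportion reporting behaviour")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "trends.png", dpi=120)
    plt.close(fig)

    comp = results["comparison"]
    comp = comp[comp["comparator"] == "cluster"]
    if len(comp):
        fig, ax = plt.subplots(figsize=(7, 4))
        idx = np.arange(len(comp))
        ax.bar(idx - 0.2, comp["bic_without"], width=0.4, label="without clusters")
        ax.bar(idx + 0.2, comp["bic_with"], width=0.4, label="with clusters")
        ax.set_xticks(idx, comp["outcome"], rotation=30, ha="right")
        ax.set_ylabel("BIC")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "bic_bars.png", dpi=120)
        plt.close(fig)
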