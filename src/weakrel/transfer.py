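"""Label-function transfer experiment.

The core question: do text-pattern label functions written for one edge
type help a generative model for another?  The design: start from a
database-only baseline for the target edge, then repeatedly sample k
text-pattern functions *with replacement* from a source pool (the target's
own, another edge type's, or the union of all), refit the label model on
the training candidates, and score the hand-labeled tune set.  Sample sizes
are five evenly spaced integers between 1 and the pool size; each point is
repeated (default 50 times) and summarized with bootstrap confidence
intervals.  Optionally a discriminative classifier is trained on each
generative model's annotations (default 3 repeats per point) and scored the
same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .labelers import LabelFunction, LabelMatrix, apply_label_functions
from .label_model import (
    LabelModelParams,
    fit_label_model,
    posterior_probability,
    probabilities,
)
from . import metrics
from .seeding import child_seed
from .synth import CorpusBundle

logger = logging.getLogger(__name__)

ALL_SOURCE = "ALL"


@dataclass
class SamplingDesign:
    """What to sample for one target edge type."""

    target_edge: str
    sources: list[str]  # edge types and/or ALL
    sizes: list[int] | None = None  # None -> five evenly spaced per source
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.sizes is not None:
            if sorted(self.sizes) != list(self.sizes) or any(
                s < 1 for s in self.sizes
            ):
                raise ConfigurationError("sizes must be ascending and >= 1")


@dataclass
class PerformanceRecord:
    """One experiment observation."""

    target_edge: str
    source: str
    size: int
    repeat: int
    model_kind: str  # "generative" | "discriminative"
    auroc: float
    aupr: float
    split: str = "tune"
    failed: bool = False


def evenly_spaced_sizes(pool_size: int) -> list[int]:
    """Five evenly spaced integers from 1 to ``pool_size`` inclusive.

    Interior points are rounded to the nearest integer (ties up);
    duplicates collapse, so tiny pools yield fewer than five sizes.
    """
    if pool_size < 1:
        raise ConfigurationError("pool_size must be >= 1")
    raw = [1.0 + i * (pool_size - 1) / 4.0 for i in range(5)]
    rounded = [int(np.floor(x + 0.5)) for x in raw]
    return sorted(set(rounded))


def sample_lf_set(
    pool: Sequence[LabelFunction], k: int, seed: int = 0
) -> list[LabelFunction]:
    """k independent uniform draws with replacement from the pool."""
    if not pool:
        raise ConfigurationError("cannot sample from an empty pool")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=k)
    return [pool[i] for i in idx]


def _sample_indices(pool_size: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, pool_size, size=k)


@dataclass
class _Precomputed:
    """Vote matrices applied once per (candidate set, pool); sampling then
    reduces to cheap column subsetting."""

    train_db: LabelMatrix
    tune_db: LabelMatrix
    train_tp: dict[str, LabelMatrix]
    tune_tp: dict[str, LabelMatrix]
    tune_gold: np.ndarray


def _precompute(bundle: CorpusBundle, design: SamplingDesign) -> _Precomputed:
    target = design.target_edge
    train = bundle.train_candidates(target)
    tune = bundle.tune_labeled[target]
    db_pool = bundle.lf_pools[target]["DB"]
    train_db = apply_label_functions(train, db_pool)
    tune_db = apply_label_functions(tune, db_pool)
    train_tp, tune_tp = {}, {}
    for source in design.sources:
        pool = source_tp_pool(bundle, source)
        train_tp[source] = apply_label_functions(train, pool)
        tune_tp[source] = apply_label_functions(tune, pool)
    return _Precomputed(
        train_db, tune_db, train_tp, tune_tp, CorpusBundle.gold_vector(tune)
    )


def source_tp_pool(bundle: CorpusBundle, source: str) -> list[LabelFunction]:
    """The text-pattern pool of one source; ALL is the union over edges
    (including the target's own)."""
    if source == ALL_SOURCE:
        return [
            lf
            for edge in bundle.config.edge_types
            for lf in bundle.lf_pools[edge]["TP"]
        ]
    return bundle.lf_pools[source]["TP"]


def _fit_and_score(train_matrix, tune_matrix, gold, hp, seed):
    fitted = fit_label_model(train_matrix, hp, seed=seed)
    scores = probabilities(posterior_probability(fitted, tune_matrix))
    return fitted, metrics.auroc(scores, gold), metrics.aupr(scores, gold)


def run_transfer_experiment(
    bundle: CorpusBundle,
    design: SamplingDesign,
    model_config: LabelModelParams | None = None,
    *,
    discriminative: bool = False,
    discriminative_config=None,
    discriminative_repeats: int = 3,
) -> list[PerformanceRecord]:
    """Baseline + sampled performance curves for one target edge.

    Per-repeat seeds derive from (design seed, source, size, repeat), so any
    sub-grid reproduces in isolation.  A failing grid point is recorded as
    failed and the experiment continues.
    """
    hp = model_config if model_config is not None else LabelModelParams()
    pre = _precompute(bundle, design)
    records: list[PerformanceRecord] = []

    # size-0 baseline: database functions only (identical for every source)
    _, base_auroc, base_aupr = _fit_and_score(
        pre.train_db, pre.tune_db, pre.tune_gold, hp,
        child_seed(design.seed, "baseline"),
    )
    records.append(
        PerformanceRecord(
            design.target_edge, "baseline", 0, 0, "generative",
            base_auroc, base_aupr,
        )
    )

    for source in design.sources:
        pool_m = pre.train_tp[source].m
        sizes = design.sizes or evenly_spaced_sizes(pool_m)
        for size in sizes:
            for repeat in range(design.n_repeats):
                seed = child_seed(design.seed, source, size, repeat)
                try:
                    idx = _sample_indices(pool_m, size, seed)
                    train_m = LabelMatrix.hstack(
                        pre.train_db, pre.train_tp[source].column_subset(idx)
                    )
                    tune_m = LabelMatrix.hstack(
                        pre.tune_db, pre.tune_tp[source].column_subset(idx)
                    )
                    fitted, roc, pr = _fit_and_score(
                        train_m, tune_m, pre.tune_gold, hp, seed
                    )
                    records.append(
                        PerformanceRecord(
                            design.target_edge, source, size, repeat,
                            "generative", roc, pr,
                        )
                    )
                except Exception:  # noqa: BLE001 — experiment must continue
                    logger.exception(
                        "grid point failed (source=%s size=%d repeat=%d)",
                        source, size, repeat,
                    )
                    records.append(
                        PerformanceRecord(
                            design.target_edge, source, size, repeat,
                            "generative", np.nan, np.nan, failed=True,
                        )
                    )
                    continue
                if discriminative and repeat < discriminative_repeats:
                    records.append(
                        _discriminative_record(
                            bundle, design, fitted, train_m, source, size,
                            repeat, discriminative_config, seed,
                        )
                    )

    n_failed = sum(r.failed for r in records)
    if n_failed:
        logger.warning("%d grid points failed", n_failed)
    return records


def _discriminative_record(
    bundle, design, fitted, train_matrix, source, size, repeat, disc_config, seed
):
    from .discriminative import (
        DiscriminativeConfig,
        featurize,
        predict_scores,
        train_discriminative,
    )

    try:
        cfg = disc_config if disc_config is not None else DiscriminativeConfig()
        target = design.target_edge
        train = bundle.train_candidates(target)
        tune = bundle.tune_labeled[target]
        annotations = posterior_probability(fitted, train_matrix)
        clf = train_discriminative(
            featurize(train, dim=cfg.dim), annotations,
            DiscriminativeConfig(
                epochs=cfg.epochs, learning_rate=cfg.learning_rate,
                dim=cfg.dim, seed=child_seed(seed, "disc"),
            ),
        )
        scores = predict_scores(clf, featurize(tune, dim=cfg.dim))
        gold = CorpusBundle.gold_vector(tune)
        return PerformanceRecord(
            target, source, size, repeat, "discriminative",
            metrics.auroc(scores, gold), metrics.aupr(scores, gold),
        )
    except Exception:  # noqa: BLE001
        logger.exception(
            "discriminative point failed (source=%s size=%d repeat=%d)",
            source, size, repeat,
        )
        return PerformanceRecord(
            design.target_edge, source, size, repeat, "discriminative",
            np.nan, np.nan, failed=True,
        )


def records_to_frame(records: Sequence[PerformanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_edge": [r.target_edge for r in records],
            "source": [r.source for r in records],
            "size": [r.size for r in records],
            "repeat": [r.repeat for r in records],
            "model_kind": [r.model_kind for r in records],
            "auroc": [r.auroc for r in records],
            "aupr": [r.aupr for r in records],
            "split": [r.split for r in records],
            "failed": [r.failed for r in records],
        }
    )


def summarize(
    records: Sequence[PerformanceRecord],
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(target, source, size, model kind) means with bootstrap CIs."""
    if not records:
        raise ConfigurationError("no records to summarize")
    frame = records_to_frame(records)
    frame = frame[~frame["failed"]]
    rows = []
    for (target, source, size, kind), grp in frame.groupby(
        ["target_edge", "source", "size", "model_kind"], sort=True
    ):
        row = {
            "target_edge": target, "source": source, "size": size,
            "model_kind": kind, "n_runs": len(grp),
        }
        for metric in ("auroc", "aupr"):
            vals = grp[metric].to_numpy()
            lo, hi = metrics.bootstrap_ci(
                vals, level=level, n_boot=n_boot,
                seed=child_seed(seed, target, source, size, kind, metric),
            )
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_ci_low"] = lo
            row[f"{metric}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def plot_curves(summary: pd.DataFrame, path, metric: str = "auroc") -> None:
    """Minimal performance-vs-sample-size curve plot (one panel per target)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = sorted(summary["target_edge"].unique())
    fig, axes = plt.subplots(
        1, len(targets), figsize=(4 * len(targets), 3.2), squeeze=False
    )
    for ax, target in zip(axes[0], targets):
        sub = summary[summary["target_edge"] == target]
        for source, grp in sub.groupby("source"):
            grp = grp.sort_values("size")
            ax.errorbar(
                grp["size"], grp[f"{metric}_mean"],
                yerr=[
                    grp[f"{metric}_mean"] - grp[f"{metric}_ci_low"],
                    grp[f"{metric}_ci_high"] - grp[f"{metric}_mean"],
                ],
                marker="o", capsize=2, label=str(source),
            )
        ax.set_title(target)
        ax.set_xlabel("sampled label functions")
        ax.set_ylabel(metric.upper())
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
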