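"""Run configuration and the end-to-end pipeline orchestrator.

One YAML file describes a full run: corpus source (synthetic, or paths to a
PubTator file + graph), label-function pools, label-model hyperparameters,
the sampling design, the optional discriminative stage, and promotion
settings.  All randomness funnels through one global seed; every stage
derives its own child seed, and a JSON manifest records the config hash,
seeds and per-stage outputs so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import corpus as corpus_io
from .errors import ConfigurationError
from .discriminative import (
    DiscriminativeConfig,
    featurize,
    predict_scores,
    train_discriminative,
)
from .labelers import apply_label_functions
from .label_model import (
    LabelModelParams,
    fit_label_model,
    posterior_probability,
    probabilities,
    write_annotations,
    write_params,
)
from .metrics import ScoredSet
from .promotion import (
    aggregate_pair_scores,
    equal_error_threshold,
    promote_and_score,
    write_novel_edges_tsv,
)
from .seeding import child_seed
from .synth import CorpusBundle, CorpusConfig, generate_corpus
from .transfer import (
    SamplingDesign,
    records_to_frame,
    run_transfer_experiment,
    summarize,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Schema-validated description of one pipeline run."""

    seed: int = 0
    output_dir: str = "runs/demo"
    corpus: dict = field(default_factory=dict)  # CorpusConfig fields
    target_edge: str = "CbG"
    sources: list[str] = field(default_factory=lambda: ["CbG", "DaG"])
    sizes: list[int] | None = None
    n_repeats: int = 5
    label_model: dict = field(default_factory=dict)  # LabelModelParams fields
    run_experiment: bool = True
    discriminative: bool = False
    discriminative_config: dict = field(default_factory=dict)
    promotion: bool = True
    promotion_top_n: int | None = 25

    def __post_init__(self):
        # validate eagerly: constructing the stage configs raises
        # ConfigurationError before any stage runs
        self.corpus_config()
        self.model_params()
        DiscriminativeConfig(**self.discriminative_config)
        if self.target_edge not in self.corpus_config().edge_types:
            raise ConfigurationError(
                f"target_edge {self.target_edge!r} not among corpus edge types"
            )

    def corpus_config(self) -> CorpusConfig:
        kwargs = dict(self.corpus)
        overlap = kwargs.pop("cross_edge_overlap", None)
        if overlap is not None:
            kwargs["cross_edge_overlap"] = {
                frozenset(k.split("-") if isinstance(k, str) else k): v
                for k, v in overlap.items()
            }
        kwargs.setdefault("seed", child_seed(self.seed, "corpus"))
        if "edge_types" in kwargs:
            kwargs["edge_types"] = tuple(kwargs["edge_types"])
        return CorpusConfig(**kwargs)

    def model_params(self) -> LabelModelParams:
        return LabelModelParams(
            **self.label_model, seed=child_seed(self.seed, "label_model")
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("run config must be a YAML mapping")
    try:
        return RunConfig(**payload)
    except TypeError as exc:
        raise ConfigurationError(f"bad run config: {exc}") from None


def run_pipeline(config: RunConfig) -> dict:
    """Execute corpus -> label functions -> label model -> (experiment,
    discriminative) -> promotion, recording a manifest.

    A stage failure is recorded in the manifest and downstream stages are
    skipped; the manifest is always written.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "failures": [],
    }

    bundle: CorpusBundle | None = None
    fitted = None
    train = tune = test = None
    train_matrix = None
    try:
        bundle = generate_corpus(config.corpus_config())
        target = config.target_edge
        graph_path = os.path.join(out, "graph.tsv")
        with open(graph_path, "w") as fh:
            fh.write(bundle.graph.to_tsv())
        cand_path = os.path.join(out, f"candidates_{target}.tsv")
        corpus_io.write_candidates(bundle.candidates[target], cand_path)
        manifest["stages"]["corpus"] = {
            "graph": graph_path,
            "candidates": cand_path,
            "n_candidates": len(bundle.candidates[target]),
            "n_nodes": bundle.graph.n_nodes,
            "n_edges": bundle.graph.n_edges,
        }
    except Exception as exc:  # noqa: BLE001
        logger.exception("corpus stage failed")
        manifest["failures"].append({"stage": "corpus", "error": repr(exc)})

    if bundle is not None:
        try:
            target = config.target_edge
            pools = bundle.lf_pools[target]
            lfs = pools["DB"] + pools["TP"]
            train = bundle.train_candidates(target)
            tune = bundle.tune_labeled[target]
            test = bundle.test_labeled[target]
            train_matrix = apply_label_functions(train, lfs)
            matrix_path = os.path.join(out, "label_matrix.tsv")
            manifest_path = os.path.join(out, "lf_manifest.tsv")
            train_matrix.write_tsv(matrix_path, manifest_path, lfs)
            manifest["stages"]["labelmatrix"] = {
                "matrix": matrix_path,
                "manifest": manifest_path,
                "shape": [train_matrix.n, train_matrix.m],
            }
        except Exception as exc:  # noqa: BLE001
            logger.exception("labelmatrix stage failed")
            manifest["failures"].append(
                {"stage": "labelmatrix", "error": repr(exc)}
            )
            train_matrix = None

    if train_matrix is not None:
        try:
            fitted = fit_label_model(train_matrix, config.model_params())
            params_path = os.path.join(out, "label_model_params.tsv")
            ann_path = os.path.join(out, "training_annotations.tsv")
            write_params(fitted, params_path)
            annotations = posterior_probability(fitted, train_matrix)
            write_annotations(annotations, ann_path)
            manifest["stages"]["labelmodel"] = {
                "params": params_path,
                "annotations": ann_path,
                "final_loss": fitted.loss_history[-1],
            }
        except Exception as exc:  # noqa: BLE001
            logger.exception("labelmodel stage failed")
            manifest["failures"].append(
                {"stage": "labelmodel", "error": repr(exc)}
            )
            fitted = None

    if bundle is not None and fitted is not None and config.run_experiment:
        try:
            design = SamplingDesign(
                target_edge=config.target_edge,
                sources=list(config.sources),
                sizes=config.sizes,
                n_repeats=config.n_repeats,
                seed=child_seed(config.seed, "experiment"),
            )
            records = run_transfer_experiment(
                bundle, design, config.model_params(),
                discriminative=config.discriminative,
                discriminative_config=DiscriminativeConfig(
                    **config.discriminative_config
                ),
            )
            records_path = os.path.join(out, "records.tsv")
            summary_path = os.path.join(out, "summary.tsv")
            records_to_frame(records).to_csv(
                records_path, sep="\t", index=False
            )
            summarize(
                records, seed=child_seed(config.seed, "summary")
            ).to_csv(summary_path, sep="\t", index=False)
            manifest["stages"]["experiment"] = {
                "records": records_path,
                "summary": summary_path,
                "n_records": len(records),
            }
        except Exception as exc:  # noqa: BLE001
            logger.exception("experiment stage failed")
            manifest["failures"].append(
                {"stage": "experiment", "error": repr(exc)}
            )

    if bundle is not None and fitted is not None and config.promotion:
        try:
            target = config.target_edge
            all_cands = bundle.candidates[target]
            if config.discriminative:
                cfg = DiscriminativeConfig(
                    **config.discriminative_config,
                    seed=child_seed(config.seed, "discriminative"),
                )
                annotations = posterior_probability(fitted, train_matrix)
                clf = train_discriminative(
                    featurize(train, dim=cfg.dim), annotations, cfg
                )
                scores = predict_scores(clf, featurize(all_cands, dim=cfg.dim))
                tune_scores = predict_scores(clf, featurize(tune, dim=cfg.dim))
            else:
                pools = bundle.lf_pools[target]
                lfs = pools["DB"] + pools["TP"]
                scores = probabilities(
                    posterior_probability(
                        fitted, apply_label_functions(all_cands, lfs)
                    )
                )
                tune_scores = probabilities(
                    posterior_probability(
                        fitted, apply_label_functions(tune, lfs)
                    )
                )
            threshold = equal_error_threshold(
                ScoredSet(tune_scores, CorpusBundle.gold_vector(tune))
            )
            pair_scores = aggregate_pair_scores(all_cands, scores)
            report = promote_and_score(
                pair_scores, threshold, bundle.graph, target
            )
            report_path = os.path.join(out, "promotion_report.json")
            novel_path = os.path.join(out, "novel_edges.tsv")
            with open(report_path, "w") as fh:
                fh.write(report.to_json())
            write_novel_edges_tsv(
                pair_scores, threshold, bundle.graph, target, novel_path,
                top_n=config.promotion_top_n,
            )
            manifest["stages"]["promotion"] = {
                "report": report_path,
                "novel_edges": novel_path,
                "threshold": threshold,
                "recall_fraction": report.recall_fraction,
                "n_novel": report.n_novel,
            }
        except Exception as exc:  # noqa: BLE001
            logger.exception("promotion stage failed")
            manifest["failures"].append(
                {"stage": "promotion", "error": repr(exc)}
            )

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    manifest["manifest_path"] = manifest_path
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
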