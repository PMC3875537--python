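"""End-to-end pipeline: preprocess -> multi-model selection -> evaluation.

A :class:`RunConfig` gathers every tunable in one validated document (YAML
on disk).  :func:`run_pipeline` executes the stages, writes TSV/JSON
outputs, and records a manifest with input digests, parameters and the
package version so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .evaluate import count_misclassified, hcluster, pca, to_newick
from .io import read_expression, read_labels, save_model, write_expression
from .multiclass import (ClassScheme, hierarchical_select, ovr_ttest_select,
                         parallel_ovr_select)
from .splot import write_selection

log = logging.getLogger("moplsda")

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """The run configuration is invalid; the message names the key."""


@dataclass
class RunConfig:
    """All pipeline tunables in one document.

    ``hierarchy`` uses the compact string form
    ``"SUPER:SUB1,SUB2;out:OUTGROUP"`` (e.g. ``"ALL:ALL-B,ALL-T;out:AML"``).
    """

    expression: str = ""
    labels: str = ""
    expression_format: str = "gct"
    labels_format: str = "cls"
    out_dir: str = "moplsda_out"
    # preprocessing
    floor: float = 100.0
    ceiling: float = 16000.0
    fold_min: float = 5.0
    range_min: float = 500.0
    # selection
    mode: str = "parallel"                 # "hierarchical" | "parallel"
    hierarchy: str | None = None
    per_model_k: list[int] | None = None
    k_total: int = 50
    n_ortho: str | int = "auto"
    n_folds: int = 7
    cv_scheme: str = "venetian_blind"
    corr_tie_window: float = 0.01
    balanced: bool = False
    baseline_ttest: bool = False
    # evaluation
    distance: str = "euclidean"
    linkage: str = "average"
    n_pca_components: int = 3
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")
        if self.mode not in ("hierarchical", "parallel"):
            raise ConfigError(f"mode must be hierarchical or parallel, got {self.mode!r}")
        if self.mode == "hierarchical" and not self.hierarchy:
            raise ConfigError("hierarchical mode requires the hierarchy key")
        if not self.floor < self.ceiling:
            raise ConfigError("floor must be below ceiling")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_ortho != "auto":
            try:
                self.n_ortho = int(self.n_ortho)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"n_ortho must be 'auto' or an integer, got {self.n_ortho!r}"
                ) from None
            if self.n_ortho < 0:
                raise ConfigError("n_ortho must be >= 0")
        if self.distance not in ("euclidean", "pearson"):
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("ward", "average", "complete"):
            raise ConfigError(f"unknown linkage {self.linkage!r}")
        if not self.expression:
            raise ConfigError("expression file path is required")
        if not self.labels:
            raise ConfigError("labels file path is required")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or not data:
            raise ConfigError(f"{path}: config must be a non-empty mapping")
        return cls.from_dict(data)


def parse_hierarchy(text: str) -> tuple[str, tuple[str, str], str]:
    """Parse ``"SUPER:SUB1,SUB2;out:OUTGROUP"``."""
    try:
        sup_part, out_part = text.split(";")
        sup, subs = sup_part.split(":")
        out_key, out = out_part.split(":")
        sub1, sub2 = subs.split(",")
        if out_key.strip() != "out":
            raise ValueError
        return sup.strip(), (sub1.strip(), sub2.strip()), out.strip()
    except ValueError:
        raise ConfigError(
            f"malformed hierarchy {text!r}; expected 'SUPER:SUB1,SUB2;out:OUTGROUP'"
        ) from None


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and return the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "inputs": {
            "expression": {"path": str(config.expression),
                           "sha256": _sha256(config.expression)},
            "labels": {"path": str(config.labels), "sha256": _sha256(config.labels)},
        },
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        log.info("stage %s: start", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 3)}
        return time.time()

    def done(name, t):
        manifest["stages"][name]["seconds"] = round(time.time() - t, 3)
        log.info("stage %s: %.2fs", name, time.time() - t)

    # -- load
    t = stage("load")
    m = read_expression(config.expression, format=config.expression_format)
    labels = read_labels(config.labels, format=config.labels_format,
                         sample_ids=m.sample_ids)
    m = m.with_labels(labels)
    done("load", t)

    # -- preprocess
    from .preprocess import preprocess  # local import to avoid cycle at module load
    t = stage("preprocess")
    centered, report = preprocess(m, floor=config.floor, ceiling=config.ceiling,
                                  fold_min=config.fold_min,
                                  range_min=config.range_min)
    log10_m = None
    if config.baseline_ttest:
        from .preprocess import log10_transform, threshold_clip, variation_filter
        clipped = threshold_clip(m, config.floor, config.ceiling)
        filt, _ = variation_filter(clipped, config.fold_min, config.range_min)
        log10_m = log10_transform(filt)
    (out / "filter_report.json").write_text(json.dumps({
        "n_retained": report.n_retained,
        "n_dropped": report.n_dropped,
        "dropped": report.dropped,
    }, indent=1))
    manifest["outputs"].append("filter_report.json")
    manifest["stages"]["preprocess"]["n_genes_retained"] = report.n_retained
    done("preprocess", t)

    # -- selection
    t = stage("select")
    classes = centered.classes()
    if config.mode == "hierarchical":
        hierarchy = parse_hierarchy(config.hierarchy)
        scheme = ClassScheme(mode="hierarchical", classes=classes,
                             hierarchy=hierarchy,
                             per_model_k=list(config.per_model_k or []))
        selection, models = hierarchical_select(
            centered, scheme, n_ortho=config.n_ortho, k_total=config.k_total,
            n_folds=config.n_folds, seed=config.seed,
            corr_tie_window=config.corr_tie_window, balanced=config.balanced)
    else:
        scheme = ClassScheme(mode="parallel", classes=classes,
                             per_model_k=list(config.per_model_k or []))
        selection, models = parallel_ovr_select(
            centered, scheme, n_ortho=config.n_ortho,
            n_folds=config.n_folds, seed=config.seed,
            corr_tie_window=config.corr_tie_window, balanced=config.balanced)
    write_selection(selection, out / "panel.tsv")
    manifest["outputs"].append("panel.tsv")
    for name, model in models.items():
        fname = f"model_{name}.oplsda.json"
        save_model(model, out / fname)
        manifest["outputs"].append(fname)
    manifest["stages"]["select"].update({
        "panel_size": len(selection.entries),
        "duplicates_removed": selection.duplicates_removed,
        "models": {name: {"n_ortho": mod.n_ortho, "r2x": mod.r2x,
                          "r2y": mod.r2y, "q2y": mod.q2y}
                   for name, mod in models.items()},
    })
    if config.baseline_ttest and log10_m is not None:
        baseline = ovr_ttest_select(log10_m, scheme)
        write_selection(baseline, out / "panel_ttest.tsv")
        manifest["outputs"].append("panel_ttest.tsv")
    done("select", t)

    # -- evaluation
    t = stage("evaluate")
    panel = centered.subset_genes(selection.gene_ids)
    pca_res = pca(panel, min(config.n_pca_components, panel.n_genes,
                             panel.n_samples))
    with (out / "pca_scores.tsv").open("w") as fh:
        comps = pca_res.scores.shape[1]
        fh.write("sample_id\tclass\t" +
                 "\t".join(f"PC{j + 1}" for j in range(comps)) + "\n")
        for i, s in enumerate(pca_res.sample_ids):
            fh.write(s + "\t" + labels[s] + "\t" +
                     "\t".join(f"{v:.10g}" for v in pca_res.scores[i]) + "\n")
    manifest["outputs"].append("pca_scores.tsv")

    tree = hcluster(panel, distance=config.distance, linkage=config.linkage)
    (out / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
    manifest["outputs"].append("dendrogram.nwk")
    evaluation = count_misclassified(tree, labels, k_clusters=len(classes))
    (out / "evaluation.json").write_text(json.dumps({
        "distance": config.distance,
        "linkage": config.linkage,
        "k_clusters": evaluation.k_clusters,
        "n_misclassified": evaluation.n_misclassified,
        "misclassified": evaluation.misclassified,
        "cluster_to_class": {str(k): v for k, v in evaluation.mapping.items()},
        "pca_explained_fraction": pca_res.explained_fraction.tolist(),
    }, indent=1))
    manifest["outputs"].append("evaluation.json")
    manifest["stages"]["evaluate"]["n_misclassified"] = evaluation.n_misclassified
    done("evaluate", t)

    manifest["seconds_total"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
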