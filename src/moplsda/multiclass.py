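"""Multi-model orchestration for three-class gene selection.

Two arrangements of two-class OPLS-DA models cover a three-class problem:

* **hierarchical** — for classes with subtypes (e.g. AML vs the ALL
  super-class, then ALL-B vs ALL-T within ALL): model 1 separates the
  outgroup from the merged subtypes on all samples, model 2 separates the
  two subtypes using only super-class samples.  Defaults select 40 genes
  from model 1 and 10 from model 2 for a 50-gene panel.
* **parallel** — three one-versus-rest models, one per class, each
  contributing its top genes (default 17 each, deduplicated to ~50).

A one-versus-rest Welch t-test selector over the same contrasts serves as
the conventional baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .opls import OplsModel, fit_opls_da
from .splot import SelectionEntry, SelectionResult, compute_splot, select_top_genes


class SampleSizeError(ValueError):
    """A class has too few samples for the requested contrast."""


@dataclass
class ClassScheme:
    """How three classes are decomposed into two-class contrasts.

    ``hierarchy`` is required in hierarchical mode:
    ``(super_class, (subtype_1, subtype_2), outgroup)``.
    """

    mode: str                                  # "hierarchical" | "parallel"
    classes: list[str]
    hierarchy: tuple[str, tuple[str, str], str] | None = None
    per_model_k: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("hierarchical", "parallel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be distinct")
        if self.mode == "hierarchical":
            if len(self.classes) != 3:
                raise ValueError("hierarchical mode requires exactly three leaf classes")
            if self.hierarchy is None:
                raise ValueError("hierarchical mode requires a hierarchy")
            sup, subs, out = self.hierarchy
            if len(subs) != 2 or len(set(subs)) != 2:
                raise ValueError("the super-class must have exactly two subtypes")
            if set(subs) | {out} != set(self.classes) or out in subs:
                raise ValueError(
                    "hierarchy must cover the three leaf classes: two subtypes "
                    f"plus one outgroup (got {subs} + {out!r} vs {self.classes})"
                )
            if not self.per_model_k:
                self.per_model_k = [40, 10]
            if len(self.per_model_k) != 2:
                raise ValueError("hierarchical mode takes two per-model gene counts")
        else:
            if len(self.classes) < 3:
                raise ValueError("parallel mode requires at least three classes")
            if not self.per_model_k:
                self.per_model_k = [17] * len(self.classes)
            if len(self.per_model_k) != len(self.classes):
                raise ValueError("one gene count per class is required")
        if any(k < 1 for k in self.per_model_k):
            raise ValueError("per-model gene counts must be >= 1")


def hierarchical_scheme(super_class: str, subtypes: tuple[str, str],
                        outgroup: str, per_model_k: list[int] | None = None) -> ClassScheme:
    return ClassScheme(mode="hierarchical",
                       classes=[subtypes[0], subtypes[1], outgroup],
                       hierarchy=(super_class, tuple(subtypes), outgroup),
                       per_model_k=list(per_model_k) if per_model_k else [])


def parallel_scheme(classes: list[str], k_per_model: int = 17) -> ClassScheme:
    return ClassScheme(mode="parallel", classes=list(classes),
                       per_model_k=[k_per_model] * len(classes))


def _check_class_sizes(m: ExpressionMatrix, classes: list[str], minimum: int = 3) -> None:
    labels = m.label_vector()
    for c in classes:
        n = labels.count(c)
        if n < minimum:
            raise SampleSizeError(f"class {c!r} has {n} samples; need >= {minimum}")


def _merge_dedup(selections: list[SelectionResult], k_requested: int) -> SelectionResult:
    """Union of per-model panels keeping the higher-|corr| copy of duplicates."""
    best: dict[str, SelectionEntry] = {}
    duplicates: list[str] = []
    order: list[str] = []
    for sel in selections:
        for e in sel.entries:
            if e.gene_id in best:
                duplicates.append(e.gene_id)
                if abs(e.corr) > abs(best[e.gene_id].corr):
                    best[e.gene_id] = e
            else:
                best[e.gene_id] = e
                order.append(e.gene_id)
    entries = [best[g] for g in order]
    return SelectionResult(entries=entries, k_requested=k_requested,
                           duplicates_removed=sorted(set(duplicates)))


def _fit_contrast(m: ExpressionMatrix, positive_class: str, n_ortho,
                  n_folds: int, seed: int | None) -> tuple[OplsModel, np.ndarray]:
    """Fit one contrast and return the model plus its centered training X."""
    model = fit_opls_da(m, positive_class, n_ortho=n_ortho,
                        n_folds=n_folds, seed=seed)
    X = m.values.T - model.x_means
    return model, X


def _resolve_n_ortho(n_ortho, i: int):
    if isinstance(n_ortho, (list, tuple)):
        return n_ortho[i]
    return n_ortho


def hierarchical_select(m: ExpressionMatrix, scheme: ClassScheme,
                        n_ortho="auto", k_total: int = 50,
                        n_folds: int = 7, seed: int | None = None,
                        corr_tie_window: float = 0.01, balanced: bool = False,
                        ) -> tuple[SelectionResult, dict[str, OplsModel]]:
    """Two-model hierarchical selection for classes with subtypes.

    Model 1: outgroup vs both subtypes merged, fit on all samples; its top
    ``scheme.per_model_k[0]`` genes enter the panel.  Model 2: subtype 1 vs
    subtype 2, fit on super-class samples only (re-centered on that subset);
    contributes ``per_model_k[1]`` genes.  Duplicates keep the higher-|corr|
    occurrence; if deduplication shrinks the union below ``k_total``, the
    panel is topped up with model 1's next-ranked genes.
    """
    if scheme.mode != "hierarchical":
        raise ValueError("scheme.mode must be 'hierarchical'")
    _check_class_sizes(m, scheme.classes)
    sup, (sub1, sub2), outgroup = scheme.hierarchy
    k1, k2 = scheme.per_model_k

    name1 = f"{outgroup}_vs_{sup}"
    model1, X1 = _fit_contrast(m, outgroup, _resolve_n_ortho(n_ortho, 0),
                               n_folds, seed)
    splot1 = compute_splot(model1, X1, gene_ids=m.gene_ids)
    sel1 = select_top_genes(splot1, k1, corr_tie_window, source_model=name1,
                            balanced=balanced)

    labels = m.labels or {}
    sub_ids = [s for s in m.sample_ids if labels.get(s) in (sub1, sub2)]
    m_sub = m.subset_samples(sub_ids)
    name2 = f"{sub1}_vs_{sub2}"
    model2, X2 = _fit_contrast(m_sub, sub1, _resolve_n_ortho(n_ortho, 1),
                               n_folds, seed)
    splot2 = compute_splot(model2, X2, gene_ids=m_sub.gene_ids)
    sel2 = select_top_genes(splot2, k2, corr_tie_window, source_model=name2,
                            balanced=balanced)

    merged = _merge_dedup([sel1, sel2], k_requested=k_total)
    if len(merged.entries) < min(k_total, m.n_genes):
        # top up from model 1's ranking, skipping genes already in the panel
        have = set(merged.gene_ids)
        extra = select_top_genes(splot1, min(m.n_genes, k_total + k2),
                                 corr_tie_window, source_model=name1)
        for e in extra.entries:
            if len(merged.entries) >= min(k_total, m.n_genes):
                break
            if e.gene_id not in have:
                merged.entries.append(e)
                have.add(e.gene_id)
    merged.entries = merged.entries[:k_total]
    return merged, {name1: model1, name2: model2}


def parallel_ovr_select(m: ExpressionMatrix, scheme: ClassScheme,
                        n_ortho="auto", k_per_model: int | None = None,
                        n_folds: int = 7, seed: int | None = None,
                        corr_tie_window: float = 0.01, balanced: bool = False,
                        ) -> tuple[SelectionResult, dict[str, OplsModel]]:
    """One-versus-rest selection: one OPLS-DA model per class.

    Each class is coded 1 against the union of the others; the top
    ``k_per_model`` genes of each model's S-plot are pooled and
    deduplicated (higher-|corr| copy kept, duplicates logged), so the final
    panel holds ``n_classes * k_per_model - duplicates`` genes.
    """
    if scheme.mode != "parallel":
        raise ValueError("scheme.mode must be 'parallel'")
    _check_class_sizes(m, scheme.classes)
    ks = ([k_per_model] * len(scheme.classes) if k_per_model is not None
          else scheme.per_model_k)

    selections: list[SelectionResult] = []
    models: dict[str, OplsModel] = {}
    for i, cls in enumerate(scheme.classes):
        name = f"{cls}_vs_rest"
        model, X = _fit_contrast(m, cls, _resolve_n_ortho(n_ortho, i),
                                 n_folds, seed)
        splot = compute_splot(model, X, gene_ids=m.gene_ids)
        selections.append(select_top_genes(splot, ks[i], corr_tie_window,
                                           source_model=name, balanced=balanced))
        models[name] = model
    merged = _merge_dedup(selections, k_requested=sum(ks))
    return merged, models


# -- OVR t-test baseline ---------------------------------------------------

_EPS_SE = 1e-12


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistic and two-sided p-value.

    ``a`` and ``b`` are gene x sample blocks of the two groups.  The
    standard error carries a 1e-12 guard so zero-variance genes yield a
    finite statistic instead of a division error.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    se = np.sqrt(se2) + _EPS_SE
    t = (m1 - m2) / se
    # Welch–Satterthwaite; guard the denominator for zero-variance genes
    num = se2 ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = np.where(den > 0, num / np.where(den > 0, den, 1.0), n1 + n2 - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def ovr_ttest_select(m: ExpressionMatrix, scheme: ClassScheme,
                     k: list[int] | int | None = None) -> SelectionResult:
    """Welch t-test baseline over the same contrasts as the OPLS-DA scheme.

    Operates on the log10 (uncentered) matrix.  For each contrast, genes
    are ranked by ascending p-value (|t| descending breaks ties) and the
    top k selected; direction comes from the sign of the mean difference
    (positive class minus rest).  Panels are merged with the same
    deduplication rule as the OPLS-DA modes, using |t| in place of |corr|.
    """
    m.require_state("log10", "centered")
    _check_class_sizes(m, scheme.classes, minimum=2)
    labels = np.array(m.label_vector())
    if k is None:
        ks = list(scheme.per_model_k)
    elif isinstance(k, int):
        n_models = 2 if scheme.mode == "hierarchical" else len(scheme.classes)
        ks = [k] * n_models
    else:
        ks = list(k)

    if scheme.mode == "hierarchical":
        sup, (sub1, sub2), outgroup = scheme.hierarchy
        contrasts = [
            (f"{outgroup}_vs_{sup}", labels == outgroup, labels != outgroup),
            (f"{sub1}_vs_{sub2}", labels == sub1, labels == sub2),
        ]
    else:
        contrasts = [
            (f"{cls}_vs_rest", labels == cls, labels != cls)
            for cls in scheme.classes
        ]
    if len(ks) != len(contrasts):
        raise ValueError(f"{len(contrasts)} contrasts but {len(ks)} gene counts")

    selections: list[SelectionResult] = []
    for (name, mask_a, mask_b), kk in zip(contrasts, ks):
        a = m.values[:, mask_a]
        b = m.values[:, mask_b]
        t, p = welch_t(a, b)
        delta = a.mean(axis=1) - b.mean(axis=1)
        order = sorted(range(m.n_genes),
                       key=lambda i: (p[i], -abs(t[i]), m.gene_ids[i]))[:kk]
        entries = [
            SelectionEntry(
                gene_id=m.gene_ids[i], source_model=name,
                corr=float(t[i]),  # ranking score slot: the t statistic
                cov=float(delta[i]),
                direction="up" if delta[i] > 0 else "down",
                rank=r + 1,
            )
            for r, i in enumerate(order)
        ]
        selections.append(SelectionResult(entries=entries, k_requested=kk))
    return _merge_dedup(selections, k_requested=sum(ks))
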