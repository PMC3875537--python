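"""Golub-style microarray preprocessing.

The classic pipeline for Affymetrix intensity data from the late-90s
leukemia studies: clip intensities into a trusted dynamic range
(floor 100, ceiling 16000), discard genes whose variation across samples is
too small to be informative (max/min <= 5 or max - min <= 500), take log10,
and mean-center each gene.  Centering alone (no unit-variance scaling) is
the default downstream because the log transform already brings gene ranges
onto a comparable scale.

Each step consumes an :class:`~moplsda.matrix.ExpressionMatrix` in the
preceding state and returns a new one; the state machine enforces the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import DomainError, ExpressionMatrix


class EmptyFilterError(ValueError):
    """The variation filter removed every gene."""


@dataclass
class FilterReport:
    """Bookkeeping for :func:`variation_filter`.

    ``fold_change`` and ``intensity_range`` hold the per-gene max/min ratio
    and max - min difference (on clipped intensities) for every input gene.
    """

    retained: list[str]
    dropped: list[str]
    fold_min: float
    range_min: float
    fold_change: dict[str, float] = field(repr=False, default_factory=dict)
    intensity_range: dict[str, float] = field(repr=False, default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def threshold_clip(m: ExpressionMatrix, floor: float = 100.0,
                   ceiling: float = 16000.0) -> ExpressionMatrix:
    """Clip raw intensities into ``[floor, ceiling]``.

    Values below the floor are unreliable background; values above the
    ceiling are scanner-saturated.  Idempotent on already-clipped data by
    construction (but the state machine permits it only once).
    """
    m.require_state("raw")
    if not floor < ceiling:
        raise ValueError(f"floor ({floor}) must be below ceiling ({ceiling})")
    if floor <= 0:
        raise ValueError("floor must be positive (log10 follows downstream)")
    return m.advance("clipped", np.clip(m.values, floor, ceiling))


def variation_filter(m: ExpressionMatrix, fold_min: float = 5.0,
                     range_min: float = 500.0) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes with max/min <= fold_min or (max - min) <= range_min.

    A gene is retained only if **both** strict inequalities hold across all
    samples of *m* (the exact complement of the discard rule).  When a
    train/test split exists, run the filter on the training matrix and apply
    ``test.subset_genes(filtered_train.gene_ids)`` to the test matrix so the
    gene list is learned without leakage.

    Returns the filtered matrix and a :class:`FilterReport` naming every
    dropped gene.
    """
    m.require_state("clipped")
    vmax = m.values.max(axis=1)
    vmin = m.values.min(axis=1)
    fold = vmax / vmin
    rng = vmax - vmin
    keep = (fold > fold_min) & (rng > range_min)

    retained = [g for g, k in zip(m.gene_ids, keep) if k]
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    report = FilterReport(
        retained=retained,
        dropped=dropped,
        fold_min=fold_min,
        range_min=range_min,
        fold_change=dict(zip(m.gene_ids, fold.tolist())),
        intensity_range=dict(zip(m.gene_ids, rng.tolist())),
    )
    if not retained:
        n_fold = int(np.count_nonzero(fold <= fold_min))
        n_range = int(np.count_nonzero(rng <= range_min))
        stricter = (
            f"(max - min) <= {range_min} (failed by {n_range}/{m.n_genes})"
            if n_range >= n_fold
            else f"max/min <= {fold_min} (failed by {n_fold}/{m.n_genes})"
        )
        raise EmptyFilterError(
            f"variation filter removed all {m.n_genes} genes; "
            f"strictest criterion: {stricter}"
        )
    filtered = m.advance("filtered", m.values[keep, :], gene_ids=retained)
    return filtered, report


def log10_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace intensities by their base-10 logarithm."""
    m.require_state("filtered")
    if m.values.size and m.values.min() <= 0:
        raise DomainError(f"log10 requires positive values; min is {m.values.min()!r}")
    return m.advance("log10", np.log10(m.values))


def mean_center(m: ExpressionMatrix,
                reference_means: Mapping[str, float] | Sequence[float] | np.ndarray | None = None,
                ) -> ExpressionMatrix:
    """Subtract each gene's mean log expression.

    With ``reference_means`` (a gene_id -> mean mapping, or an array aligned
    to ``m.gene_ids``) the supplied means are subtracted instead — used to
    project a test set onto a training-derived center.  Without it each row
    is centered on its own mean.
    """
    m.require_state("log10")
    if reference_means is None:
        means = m.values.mean(axis=1)
    elif isinstance(reference_means, Mapping):
        missing = [g for g in m.gene_ids if g not in reference_means]
        if missing:
            raise KeyError(f"reference means missing for genes: {missing[:10]}")
        means = np.array([float(reference_means[g]) for g in m.gene_ids])
    else:
        means = np.asarray(reference_means, dtype=float)
        if means.shape != (m.n_genes,):
            raise KeyError(
                f"reference means shape {means.shape} does not match "
                f"{m.n_genes} genes"
            )
    return m.advance("centered", m.values - means[:, None])


def preprocess(m: ExpressionMatrix, floor: float = 100.0, ceiling: float = 16000.0,
               fold_min: float = 5.0, range_min: float = 500.0,
               center: bool = True) -> tuple[ExpressionMatrix, FilterReport]:
    """Run the full pipeline: clip -> filter -> log10 [-> center]."""
    clipped = threshold_clip(m, floor=floor, ceiling=ceiling)
    filtered, report = variation_filter(clipped, fold_min=fold_min, range_min=range_min)
    logged = log10_transform(filtered)
    return (mean_center(logged) if center else logged), report
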