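"""S-plot computation and top-gene selection from a fitted OPLS-DA model.

The S-plot scatters, for every gene, its covariance with the predictive
score (x-axis — the gene's *contribution* to the separation) against its
correlation with that score (y-axis, often written p(corr) — the gene's
*reliability*).  Genes at the tips of the "S" combine both, and those are
the markers worth selecting:

    cov(t, X)_g  = t' X_g / (N - 1)
    corr(t, X)_g = cov(t, X)_g / (s_t * s_Xg)

with s_t and s_Xg the sample standard deviations (N - 1 denominator) of the
score and of gene g's centered column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .opls import OplsModel

_ZERO_SD = 1e-12


@dataclass
class SPlotData:
    """Per-gene S-plot coordinates for one OPLS-DA model."""

    gene_ids: list[str]
    cov: np.ndarray
    corr: np.ndarray
    s_x: np.ndarray
    s_t: float
    positive_class: str
    zero_variance: np.ndarray = field(repr=False, default=None)  # bool mask

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "cov": self.cov,
            "corr": self.corr,
            "s_x": self.s_x,
            "zero_variance": self.zero_variance,
        })


@dataclass
class SelectionEntry:
    gene_id: str
    source_model: str
    corr: float
    cov: float
    direction: str  # "up" / "down" in the source model's positive class
    rank: int       # 1-based within the source model


@dataclass
class SelectionResult:
    """Ordered gene panel, possibly merged from several models."""

    entries: list[SelectionEntry]
    k_requested: int
    duplicates_removed: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"gene_id": e.gene_id, "source_model": e.source_model,
             "corr": e.corr, "cov": e.cov, "direction": e.direction,
             "rank": e.rank}
            for e in self.entries
        ])


def compute_splot(model: OplsModel, X: np.ndarray,
                  gene_ids: list[str] | None = None) -> SPlotData:
    """S-plot vectors of *model* against its centered training matrix *X*.

    *X* must be the sample x gene matrix the model was fitted on (same
    samples, same gene order).  Genes with vanishing standard deviation get
    corr = 0 and are flagged in ``zero_variance``.
    """
    X = np.asarray(X, dtype=float)
    t = model.t
    if X.ndim != 2 or X.shape[0] != t.size:
        raise ValueError(
            f"X has {X.shape[0] if X.ndim == 2 else '?'} samples, "
            f"model score has {t.size}"
        )
    n = t.size
    cov = (t @ X) / (n - 1)
    s_t = float(np.std(t, ddof=1))
    s_x = np.std(X, axis=0, ddof=1)
    zero = s_x < _ZERO_SD
    denom = np.where(zero, 1.0, s_t * s_x)
    corr = np.where(zero, 0.0, cov / denom)
    if gene_ids is None:
        gene_ids = model.gene_ids
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(X.shape[1])]
    if len(gene_ids) != X.shape[1]:
        raise ValueError("gene_ids length does not match gene count")
    return SPlotData(gene_ids=list(gene_ids), cov=cov, corr=corr, s_x=s_x,
                     s_t=s_t, positive_class=model.positive_class,
                     zero_variance=zero)


def _ranked_order(splot: SPlotData, corr_tie_window: float,
                  key: np.ndarray | None = None) -> list[int]:
    """Full deterministic ranking of gene indices.

    Primary key |corr| descending; genes whose |corr| falls within
    ``corr_tie_window`` of the current group's leader are reordered among
    themselves by |cov| descending, then gene_id.  *key* overrides the
    primary vector (used for one-sided/balanced selection).
    """
    a = np.abs(splot.corr) if key is None else key
    acov = np.abs(splot.cov)
    idx = sorted(range(len(a)), key=lambda i: (-a[i], splot.gene_ids[i]))
    groups: list[list[int]] = []
    for i in idx:
        if groups and np.isfinite(a[i]) and a[groups[-1][0]] - a[i] < corr_tie_window:
            groups[-1].append(i)
        else:
            groups.append([i])
    out: list[int] = []
    for g in groups:
        out.extend(sorted(g, key=lambda i: (-acov[i], splot.gene_ids[i])))
    return out


def select_top_genes(splot: SPlotData, k: int, corr_tie_window: float = 0.01,
                     source_model: str = "model", balanced: bool = False) -> SelectionResult:
    """Select the *k* top-ranked genes of an S-plot.

    Ranking follows the correlation-first rule: |corr| descending, with
    |cov| (the contribution) deciding among genes whose correlations are
    practically tied (within ``corr_tie_window``), and the gene identifier
    as the final deterministic tie-break.  ``direction`` is "up" when the
    gene's expression rises in the model's positive class (corr > 0).

    With ``balanced=True`` the panel is forced symmetric: k/2 genes with the
    most positive and k/2 with the most negative correlation (k odd gives
    the extra slot to the positive side).
    """
    n = len(splot.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if balanced:
        k_up = (k + 1) // 2
        k_down = k // 2
        pos_key = np.where(splot.corr > 0, splot.corr, -np.inf)
        neg_key = np.where(splot.corr < 0, -splot.corr, -np.inf)
        order = ([i for i in _ranked_order(splot, corr_tie_window, pos_key)
                  if splot.corr[i] > 0][:k_up]
                 + [i for i in _ranked_order(splot, corr_tie_window, neg_key)
                    if splot.corr[i] < 0][:k_down])
    else:
        order = _ranked_order(splot, corr_tie_window)[:k]
    entries = [
        SelectionEntry(
            gene_id=splot.gene_ids[i],
            source_model=source_model,
            corr=float(splot.corr[i]),
            cov=float(splot.cov[i]),
            direction="up" if splot.corr[i] > 0 else "down",
            rank=r + 1,
        )
        for r, i in enumerate(order)
    ]
    return SelectionResult(entries=entries, k_requested=k)


def write_selection(result: SelectionResult, path) -> None:
    """Write a selection panel as a TSV table."""
    result.frame().to_csv(path, sep="\t", index=False)
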