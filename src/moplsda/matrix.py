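"""Expression-matrix container with an explicit preprocessing state machine.

Microarray preprocessing here is strictly ordered (raw intensities are
clipped, then variation-filtered, then log10-transformed, then mean-centered)
and several downstream operations are only meaningful at a particular stage —
e.g. the variation filter works on clipped raw intensities, while OPLS-DA and
PCA require centered log values.  The :class:`ExpressionMatrix` records which
stage its values are in and refuses out-of-order transitions, so a pipeline
bug surfaces as a loud :class:`StateOrderError` instead of silently filtering
log-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Allowed preprocessing states, in pipeline order.
STATES: tuple[str, ...] = ("raw", "clipped", "filtered", "log10", "centered")

#: States in which every intensity must be strictly positive.
_POSITIVE_STATES = frozenset({"raw", "clipped", "filtered"})


class StateOrderError(RuntimeError):
    """A preprocessing step was applied out of the documented order."""


class DomainError(ValueError):
    """Values violate the numeric domain a step requires (e.g. log of <= 0)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {kind} ids: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table with identifiers and class labels.

    Parameters
    ----------
    values:
        2-D array, one row per gene, one column per sample.  Raw intensity
        units up to state ``filtered``; log10 units afterwards.
    gene_ids, sample_ids:
        Ordered, unique identifiers matching the row/column counts.
    labels:
        Optional ``sample_id -> class name`` mapping.  May cover only a
        subset of samples while a matrix is being assembled, but pipeline
        entry points require full coverage.
    state:
        One of :data:`STATES`.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: dict[str, str] | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[1]} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.state in _POSITIVE_STATES and self.values.size and self.values.min() <= 0:
            raise DomainError(
                f"state {self.state!r} requires strictly positive intensities; "
                f"min is {self.values.min()!r}"
            )

    # -- state machine -----------------------------------------------------

    def require_state(self, *allowed: str) -> None:
        """Raise :class:`StateOrderError` unless the matrix is in one of *allowed*."""
        if self.state not in allowed:
            raise StateOrderError(
                f"operation requires state in {allowed}, matrix is {self.state!r} "
                f"(pipeline order is {' -> '.join(STATES)})"
            )

    def advance(self, new_state: str, values: np.ndarray,
                gene_ids: list[str] | None = None) -> "ExpressionMatrix":
        """Return a copy in *new_state*, enforcing forward-only transitions."""
        if STATES.index(new_state) <= STATES.index(self.state):
            raise StateOrderError(
                f"cannot move from {self.state!r} to {new_state!r}: "
                f"transitions only advance along {' -> '.join(STATES)}"
            )
        return ExpressionMatrix(
            values=values,
            gene_ids=list(gene_ids) if gene_ids is not None else list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            labels=dict(self.labels) if self.labels is not None else None,
            state=new_state,
        )

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def label_vector(self) -> list[str]:
        """Class labels in sample order; requires labels for every sample."""
        if self.labels is None:
            raise ValueError("matrix has no class labels")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without class labels: {missing[:10]}")
        return [self.labels[s] for s in self.sample_ids]

    def classes(self) -> list[str]:
        """Distinct class names in first-appearance (sample) order."""
        out: list[str] = []
        for c in self.label_vector():
            if c not in out:
                out.append(c)
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset (same state); order follows *sample_ids*."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, cols].copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=[str(s) for s in sample_ids],
            labels=dict(self.labels) if self.labels is not None else None,
            state=self.state,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset (same state); order follows *gene_ids*."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[rows, :].copy(),
            gene_ids=[str(g) for g in gene_ids],
            sample_ids=list(self.sample_ids),
            labels=dict(self.labels) if self.labels is not None else None,
            state=self.state,
        )

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionMatrix":
        return replace(self, labels=dict(labels))
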