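"""Synthetic three-class microarray data with planted marker genes.

Emulates the structure of a late-90s Affymetrix leukemia training set:
positive raw intensities spanning roughly 1 to 20000, three classes with
unbalanced sizes (default 19/8/11), a fraction of near-constant probes that
the variation filter should remove, and planted marker genes whose log10
expression shifts by a known amount in specific classes.  Because the
ground-truth marker table is returned alongside the matrix, every pipeline
stage — preprocessing, model fitting, S-plot ranking, panel validation —
can be tested for *recovery* rather than mere execution.

Values are generated additively on the log10 scale (baseline + class
effect + noise) and exponentiated, so planted effects are exactly linear
where the models operate after preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class CapacityError(ValueError):
    """More marker/low-variation genes requested than n_genes provides."""


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults mirror the Golub training composition.

    ``n_markers_per_contrast`` is the (up, down) count planted for each
    contrast.  Contrasts are one-versus-rest per class, or, when
    ``hierarchy`` is set, outgroup-vs-super-class and subtype-vs-subtype.
    ``hierarchy`` is ``(super_class, (subtype_1, subtype_2), outgroup)``.
    """

    n_per_class: tuple[int, ...] = (19, 8, 11)
    class_names: tuple[str, ...] = ("ALL-B", "ALL-T", "AML")
    n_genes: int = 2000
    n_markers_per_contrast: tuple[int, int] = (25, 25)
    baseline_log_mean: float = 2.8
    baseline_log_sd: float = 0.5
    effect: float = 0.6
    noise_sd: float = 0.2
    frac_low_variation: float = 0.1
    hierarchy: tuple[str, tuple[str, str], str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(self.class_names):
            raise ValueError("one sample count per class name required")
        if any(n < 1 for n in self.n_per_class) or self.n_genes < 1:
            raise ValueError("all counts must be positive")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 <= self.frac_low_variation < 1:
            raise ValueError("frac_low_variation must be in [0, 1)")
        if self.hierarchy is not None:
            sup, subs, out = self.hierarchy
            if set(subs) | {out} != set(self.class_names) or len(subs) != 2:
                raise ValueError("hierarchy must name two subtypes and the outgroup")

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """(name, affected class) per contrast, in planting order."""
        if self.hierarchy is not None:
            sup, (sub1, sub2), out = self.hierarchy
            return [(f"{out}_vs_{sup}", out), (f"{sub1}_vs_{sub2}", sub1)]
        return [(f"{c}_vs_rest", c) for c in self.class_names]


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one dataset; returns the raw matrix and the ground-truth table.

    The truth table has columns ``gene_id``, ``contrast``, ``affected_class``
    and ``direction`` ("up"/"down" in the affected class).  Marker sets of
    distinct contrasts are disjoint by construction.  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    contrasts = spec.contrasts
    n_up, n_down = spec.n_markers_per_contrast
    n_markers = (n_up + n_down) * len(contrasts)
    n_low = int(round(spec.frac_low_variation * spec.n_genes))
    if n_markers + n_low > spec.n_genes:
        raise CapacityError(
            f"{n_markers} markers + {n_low} low-variation genes exceed "
            f"n_genes={spec.n_genes}"
        )

    n_samples = int(sum(spec.n_per_class))
    sample_class = np.repeat(np.arange(len(spec.class_names)), spec.n_per_class)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    labels = {s: spec.class_names[c] for s, c in zip(sample_ids, sample_class)}

    width = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]

    # roles are assigned to a random permutation of gene indices
    perm = rng.permutation(spec.n_genes)
    pos = 0
    marker_rows: list[dict] = []
    effect_matrix = np.zeros((spec.n_genes, n_samples))
    for name, affected in contrasts:
        affected_mask = np.array(
            [spec.class_names[c] == affected for c in sample_class]
        )
        for direction, count in (("up", n_up), ("down", n_down)):
            genes = perm[pos:pos + count]
            pos += count
            sign = 1.0 if direction == "up" else -1.0
            effect_matrix[np.ix_(genes, np.nonzero(affected_mask)[0])] = sign * spec.effect
            for g in genes:
                marker_rows.append({
                    "gene_id": gene_ids[g],
                    "contrast": name,
                    "affected_class": affected,
                    "direction": direction,
                })
    low_genes = perm[pos:pos + n_low]
    pos += n_low
    is_low = np.zeros(spec.n_genes, dtype=bool)
    is_low[low_genes] = True

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                          size=spec.n_genes)
    sd = np.where(is_low, spec.noise_sd / 20.0, spec.noise_sd)
    noise = rng.normal(0.0, 1.0, size=(spec.n_genes, n_samples)) * sd[:, None]
    log_values = baseline[:, None] + effect_matrix + noise
    values = 10.0 ** log_values

    matrix = ExpressionMatrix(values=values, gene_ids=gene_ids,
                              sample_ids=sample_ids, labels=labels, state="raw")
    truth = pd.DataFrame(marker_rows,
                         columns=["gene_id", "contrast", "affected_class",
                                  "direction"])
    truth.attrs["low_variation_gene_ids"] = [gene_ids[g] for g in sorted(low_genes)]
    return matrix, truth
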