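"""Pairwise genetic distances between individuals on binary allele data.

Three metrics are provided, all computed from the presence/absence matrix:

* plain Euclidean distance between 0/1 rows (the square root of the Hamming
  distance);
* the modified Rogers' distance D_w, a constant rescaling of the Euclidean
  distance by 1/sqrt(2L) where L is the number of marker loci, so that D_w
  and the Euclidean distance are exactly linearly related with zero
  intercept;
* Nei & Li / Dice similarity, the proportion of shared fragments
  S = 2 n_ab / (n_a + n_b), with the log-transform distance -ln(S).

With dominant 0/1 coding the rescaling to D_w preserves all rank and linear
structure of the Euclidean geometry; the theoretical [0, 1] range of D_w on
frequency data is not guaranteed for binary coding, so the observed range is
reported rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import AlleleMatrix

__all__ = [
    "DistanceMatrix",
    "euclidean_binary",
    "modified_rogers",
    "nei_similarity",
    "nei_distance",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over panel individuals.

    ``n_loci`` records the locus count used for the D_w rescaling so the
    provenance of the constant 1/sqrt(2L) stays attached to the values.
    """

    ids: list[str]
    D: np.ndarray
    metric: str  # euclidean | modified_rogers | nei_distance
    n_loci: int

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.D < 0):
            raise ValueError("distance matrix has negative entries")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.D, checks=False)

    def observed_range(self) -> tuple[float, float]:
        """Min and max off-diagonal distance actually observed."""
        v = self.condensed()
        return float(v.min()), float(v.max())

    def to_dataframe(self) -> pd.DataFrame:
        ix = pd.Index(self.ids, name="individual_id")
        return pd.DataFrame(self.D, index=ix, columns=list(self.ids))

    def to_tsv(self, path) -> None:
        """Square matrix TSV with ids as header row and column."""
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style ``.dist`` export."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.n}\n")
            for i, ind in enumerate(self.ids):
                row = "\t".join(f"{self.D[i, j]:.6f}" for j in range(i))
                fh.write(ind + ("\t" + row if row else "") + "\n")


def euclidean_binary(m: AlleleMatrix) -> DistanceMatrix:
    """Euclidean distance between binary rows: sqrt of the Hamming distance."""
    if m.n < 2:
        raise ValueError("need at least 2 individuals for pairwise distances")
    D = squareform(pdist(m.X.astype(float), metric="euclidean"))
    return DistanceMatrix(list(m.individuals), D, "euclidean", m.n_loci)


def modified_rogers(m: AlleleMatrix) -> DistanceMatrix:
    """Modified Rogers' distance D_w = Euclidean / sqrt(2 L).

    L is the number of marker loci; the rescaling makes D_w exactly linear
    in the Euclidean distance with zero intercept and slope 1/sqrt(2L)
    shared by all pairs.
    """
    if m.n_loci < 1:
        raise ValueError("need at least one marker locus")
    eu = euclidean_binary(m)
    D = eu.D / np.sqrt(2.0 * m.n_loci)
    return DistanceMatrix(eu.ids, D, "modified_rogers", m.n_loci)


def nei_similarity(m: AlleleMatrix) -> pd.DataFrame:
    """Nei & Li / Dice similarity S = 2 n_ab / (n_a + n_b).

    n_ab is the number of fragments shared by the pair, n_a and n_b the
    individuals' fragment totals.  Absence-absence matches do not count as
    sharing.  Undefined when an individual shows no fragment at all.
    """
    if m.n < 2:
        raise ValueError("need at least 2 individuals")
    totals = m.individual_allele_totals().astype(float)
    if np.any(totals == 0):
        empty = [m.individuals[i] for i in np.nonzero(totals == 0)[0]]
        raise ValueError(f"similarity undefined for individual(s) with zero alleles: {empty}")
    X = m.X.astype(float)
    shared = X @ X.T
    S = 2.0 * shared / np.add.outer(totals, totals)
    np.fill_diagonal(S, 1.0)
    ix = pd.Index(m.individuals, name="individual_id")
    return pd.DataFrame(S, index=ix, columns=list(m.individuals))


def nei_distance(S):
    """Log-transform a similarity into a distance: -ln(S).

    Zero at S = 1, strictly decreasing in S, undefined (infinite) at S <= 0.
    Accepts a scalar, array, or the DataFrame from :func:`nei_similarity`.
    """
    if isinstance(S, pd.DataFrame):
        arr = S.to_numpy()
        if np.any(arr <= 0):
            raise ValueError("similarity must be in (0, 1] for -ln conversion")
        return DistanceMatrix(list(S.index), -np.log(arr), "nei_distance", 0)
    arr = np.asarray(S, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError(f"similarity outside (0, 1]: {S!r}")
    out = -np.log(arr)
    return float(out) if np.isscalar(S) or arr.ndim == 0 else out
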