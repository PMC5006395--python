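"""Binary allele presence/absence matrices for dominant-scored SSR panels.

In a dominant scoring of microsatellite (SSR) fragments every distinct
fragment length at a locus is treated as its own binary character: 1 if the
individual shows the fragment, 0 otherwise.  Dosage (how many of the four
homologues of a tetraploid carry the allele) is unobservable, so the matrix
of 0/1 calls is the complete data object for all downstream statistics.

The central container is :class:`AlleleMatrix`: an ``n x A`` table of
individuals by allele columns, with allele columns grouped into marker loci.
Columns are labelled ``MARKERID:SIZE`` where ``SIZE`` is the fragment length
in base pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "MarkerDef",
    "IndividualDef",
    "AlleleColumn",
    "AlleleMatrix",
    "SubsetResult",
    "read_allele_matrix",
    "write_allele_matrix",
    "read_marker_table",
    "write_marker_table",
    "read_individual_table",
    "write_individual_table",
    "subset",
]

#: Status vocabulary for panel individuals (bred variety, advanced cultivated
#: material, traditional landrace, local ecotype, wild collection, or unknown).
STATUS_VALUES = ("cultivar", "cultivated", "landrace", "ecotype", "wild", "NA")

#: Plausible capillary-electrophoresis scoring window for fragment sizes (bp).
MIN_FRAGMENT_BP = 50
MAX_FRAGMENT_BP = 1000

_DNA = set("ACGT")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


@dataclass(frozen=True)
class MarkerDef:
    """One SSR marker: motif, repeat number, expected product size, primers."""

    marker_id: str
    motif: str
    repeats: int
    predicted_size_bp: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValidationError("marker_id must be non-empty")
        if not (2 <= len(self.motif) <= 5) or not set(self.motif) <= _DNA:
            raise ValidationError(
                f"marker {self.marker_id}: motif {self.motif!r} must be a "
                "di- to pentanucleotide over A/C/G/T"
            )
        if self.repeats < 1:
            raise ValidationError(f"marker {self.marker_id}: repeats must be positive")
        if self.predicted_size_bp < 1:
            raise ValidationError(f"marker {self.marker_id}: predicted size must be positive")
        if not self.fwd_primer or not self.rev_primer:
            raise ValidationError(f"marker {self.marker_id}: primers must be non-empty")


@dataclass(frozen=True)
class IndividualDef:
    """One panel individual with its variety/status/origin passport data."""

    individual_id: str
    variety: str = "NA"
    status: str = "NA"
    origin: str = "NA"

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValidationError("individual_id must be non-empty")
        if self.status not in STATUS_VALUES:
            raise ValidationError(
                f"individual {self.individual_id}: status {self.status!r} "
                f"not one of {STATUS_VALUES}"
            )


class AlleleColumn(NamedTuple):
    """One binary allele character: a fragment size at a marker locus."""

    marker_id: str
    fragment_size_bp: int

    @property
    def label(self) -> str:
        return f"{self.marker_id}:{self.fragment_size_bp}"

    @classmethod
    def from_label(cls, label: str) -> "AlleleColumn":
        marker_id, sep, size = label.rpartition(":")
        if not sep or not marker_id:
            raise FormatError(f"allele column {label!r} is not of the form MARKERID:SIZE")
        try:
            size_bp = int(size)
        except ValueError:
            raise FormatError(f"allele column {label!r}: size {size!r} is not an integer") from None
        return cls(marker_id, size_bp)


class SubsetResult(NamedTuple):
    """A subsetted matrix plus the allele columns dropped as unobserved."""

    matrix: "AlleleMatrix"
    dropped_alleles: list[AlleleColumn]


@dataclass
class AlleleMatrix:
    """Individuals x alleles presence/absence table with a locus grouping.

    Parameters
    ----------
    individuals
        Ordered unique individual ids (length ``n``).
    alleles
        Ordered unique :class:`AlleleColumn` labels (length ``A``).  Columns
        of the same marker need not be contiguous, but the locus grouping is
        always derived from the column labels.
    X
        ``n x A`` array of 0/1 (any integer dtype; stored as ``uint8``).

    Invariants (checked by :meth:`validate`): entries binary, every column
    observed at least once (an allele never seen is not an allele of the
    panel), ids and columns unique.
    """

    individuals: list[str]
    alleles: list[AlleleColumn]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.alleles = [
            a if isinstance(a, AlleleColumn) else AlleleColumn(*a) for a in self.alleles
        ]
        self.X = np.asarray(self.X)
        self.validate()
        self.X = self.X.astype(np.uint8)

    # -- structural properties -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def loci(self) -> dict[str, np.ndarray]:
        """Marker id -> column indices, in order of first appearance."""
        out: dict[str, list[int]] = {}
        for j, col in enumerate(self.alleles):
            out.setdefault(col.marker_id, []).append(j)
        return {m: np.asarray(js, dtype=int) for m, js in out.items()}

    @property
    def n_loci(self) -> int:
        return len({a.marker_id for a in self.alleles})

    @property
    def column_labels(self) -> list[str]:
        return [a.label for a in self.alleles]

    def allele_counts(self) -> np.ndarray:
        """Per-allele occurrence counts (column sums) — the single source of
        truth for every downstream frequency."""
        return self.X.sum(axis=0)

    def individual_allele_totals(self) -> np.ndarray:
        """Per-individual number of scored fragments (row sums)."""
        return self.X.sum(axis=1)

    # -- validation ------------------------------------------------------------

    def validate(self) -> None:
        n, A = len(self.individuals), len(self.alleles)
        if n == 0:
            raise ValidationError("matrix has no individuals")
        if A == 0:
            raise ValidationError("matrix has no allele columns")
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.alleles)) != A:
            raise ValidationError("duplicate allele columns")
        for a in self.alleles:
            if not (MIN_FRAGMENT_BP <= a.fragment_size_bp <= MAX_FRAGMENT_BP):
                raise ValidationError(
                    f"allele {a.label}: fragment size outside the plausible "
                    f"scoring range {MIN_FRAGMENT_BP}..{MAX_FRAGMENT_BP} bp"
                )
        if self.X.shape != (n, A):
            raise ValidationError(f"X has shape {self.X.shape}, expected {(n, A)}")
        bad = ~np.isin(self.X, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {self.X[i, j]!r} at individual "
                f"{self.individuals[i]!r}, allele {self.alleles[j].label!r}"
            )
        zero = np.asarray(self.X.sum(axis=0) == 0).nonzero()[0]
        if zero.size:
            labels = ", ".join(self.alleles[j].label for j in zero[:10])
            raise ValidationError(
                f"{zero.size} allele column(s) never observed (an unobserved "
                f"allele is not an allele): {labels}"
            )

    # -- conversions -----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.astype(int),
            index=pd.Index(self.individuals, name="individual_id"),
            columns=self.column_labels,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AlleleMatrix":
        alleles = [AlleleColumn.from_label(str(c)) for c in df.columns]
        return cls(list(df.index), alleles, df.to_numpy())

    # -- reports ---------------------------------------------------------------

    def missingness_report(self) -> pd.DataFrame:
        """Per-locus count of individuals showing no fragment at all.

        A whole-locus zero block is legal (amplification failure) and only
        enters frequencies through the fixed denominator ``n``; this report
        makes such blocks visible.
        """
        rows = []
        for marker, js in self.loci.items():
            absent = int((self.X[:, js].sum(axis=1) == 0).sum())
            rows.append({"marker_id": marker, "n_alleles": len(js), "n_missing_individuals": absent})
        return pd.DataFrame(rows).set_index("marker_id")

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
    ) -> SubsetResult:
        """Restrict to the given individuals and/or marker loci.

        Allele columns that become all-zero in the subpanel are dropped and
        reported (an allele unobserved in the subpanel is not an allele of
        the subpanel).
        """
        ids = self.individuals if individuals is None else [str(i) for i in individuals]
        unknown = [i for i in ids if i not in set(self.individuals)]
        if unknown:
            raise KeyError(f"unknown individual id(s): {unknown}")
        if markers is not None:
            known_markers = set(a.marker_id for a in self.alleles)
            missing = [m for m in markers if m not in known_markers]
            if missing:
                raise KeyError(f"unknown marker id(s): {missing}")
            keep_marker = set(markers)
        else:
            keep_marker = None

        row_ix = [self.individuals.index(i) for i in ids]
        col_ix = [
            j
            for j, a in enumerate(self.alleles)
            if keep_marker is None or a.marker_id in keep_marker
        ]
        sub = self.X[np.ix_(row_ix, col_ix)]
        observed = sub.sum(axis=0) > 0
        dropped = [self.alleles[col_ix[j]] for j in np.nonzero(~observed)[0]]
        kept = [self.alleles[col_ix[j]] for j in np.nonzero(observed)[0]]
        return SubsetResult(AlleleMatrix(ids, kept, sub[:, observed]), dropped)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.alleles == other.alleles
            and np.array_equal(self.X, other.X)
        )


def subset(
    m: AlleleMatrix,
    individuals: Sequence[str] | None = None,
    markers: Sequence[str] | None = None,
) -> SubsetResult:
    """Functional alias for :meth:`AlleleMatrix.subset`."""
    return m.subset(individuals=individuals, markers=markers)


# -- TSV dialect ----------------------------------------------------------------
# UTF-8, tab-separated, '.' decimal, no quoting: chosen for bit-exact diffability.


def read_allele_matrix(path, marker_meta=None) -> AlleleMatrix:
    """Read a presence/absence matrix TSV.

    Expected header: ``individual_id`` then allele columns named
    ``MARKERID:SIZE``; every cell 0 or 1.  When ``marker_meta`` is given, the
    marker table is read and every allele column's marker id is checked
    against it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "individual_id":
            raise FormatError(f"{path}: first header field must be 'individual_id'")
        col_labels = header[1:]
        dupes = {c for c in col_labels if col_labels.count(c) > 1}
        if dupes:
            raise FormatError(f"{path}: duplicate allele column(s): {sorted(dupes)}")
        alleles = [AlleleColumn.from_label(c) for c in col_labels]
        rows: list[list[int]] = []
        ids: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            row = []
            for label, cell in zip(col_labels, fields[1:]):
                if cell not in ("0", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: non-binary cell {cell!r} at individual "
                        f"{fields[0]!r}, column {label!r}"
                    )
                row.append(int(cell))
            rows.append(row)
    m = AlleleMatrix(ids, alleles, np.asarray(rows, dtype=np.uint8))
    if marker_meta is not None:
        markers = read_marker_table(marker_meta)
        known = {d.marker_id for d in markers}
        orphans = sorted({a.marker_id for a in m.alleles} - known)
        if orphans:
            raise ValidationError(f"allele columns reference unknown marker(s): {orphans}")
    return m


def write_allele_matrix(m: AlleleMatrix, path) -> None:
    """Write the matrix in the canonical TSV dialect (re-readable, byte-stable)."""
    m.validate()
    buf = io.StringIO()
    buf.write("individual_id\t" + "\t".join(m.column_labels) + "\n")
    for ind, row in zip(m.individuals, m.X):
        buf.write(ind + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


_MARKER_COLS = ["marker", "motif", "repeats", "predicted_size", "forward_primer", "reverse_primer"]


def read_marker_table(path) -> list[MarkerDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MARKER_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: marker table missing column(s) {missing}")
    defs = [
        MarkerDef(
            marker_id=r["marker"],
            motif=r["motif"],
            repeats=int(r["repeats"]),
            predicted_size_bp=int(r["predicted_size"]),
            fwd_primer=r["forward_primer"],
            rev_primer=r["reverse_primer"],
        )
        for r in df.to_dict("records")
    ]
    ids = [d.marker_id for d in defs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate marker ids")
    return defs


def write_marker_table(markers: Iterable[MarkerDef], path) -> None:
    df = pd.DataFrame(
        [
            {
                "marker": d.marker_id,
                "motif": d.motif,
                "repeats": d.repeats,
                "predicted_size": d.predicted_size_bp,
                "forward_primer": d.fwd_primer,
                "reverse_primer": d.rev_primer,
            }
            for d in markers
        ],
        columns=_MARKER_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


_INDIVIDUAL_COLS = ["individual_id", "variety", "status", "origin"]


def read_individual_table(path) -> list[IndividualDef]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _INDIVIDUAL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: individual table missing column(s) {missing}")
    defs = [IndividualDef(**{k: r[k] for k in _INDIVIDUAL_COLS}) for r in df.to_dict("records")]
    ids = [d.individual_id for d in defs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate individual ids")
    return defs


def write_individual_table(individuals: Iterable[IndividualDef], path) -> None:
    df = pd.DataFrame(
        [
            {
                "individual_id": d.individual_id,
                "variety": d.variety,
                "status": d.status,
                "origin": d.origin,
            }
            for d in individuals
        ],
        columns=_INDIVIDUAL_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
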