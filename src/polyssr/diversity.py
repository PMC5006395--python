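"""Polymorphism statistics for dominant-scored SSR panels.

For dominant (presence/absence) markers in a polyploid, gametic allele
frequencies cannot be recovered from fragment calls because dosage is
unobserved.  Marker informativeness is therefore computed per allele from
its *occurrence frequency* f — the fraction of panel individuals showing the
fragment — via the dominant-marker polymorphism information content

    PIC = 2 f (1 - f),

which peaks at 0.5 for an allele carried by half the panel and vanishes for
alleles that are absent or fixed.  Per-marker summaries average PIC over all
alleles of the locus, monomorphic (f = 1) alleles included, so a locus
carrying a fixed fragment is penalised accordingly.

The occurrence denominator is always the full panel size n, never the number
of individuals that amplified at the locus; the smallest observable
frequency is therefore 1/n, and an allele seen in exactly one individual is
a *private allele* of that individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .matrix import AlleleMatrix

__all__ = [
    "pic_allele",
    "occurrence_frequency",
    "allele_stats",
    "MarkerSummary",
    "marker_summary",
    "marker_summaries",
    "PrivateAlleleStats",
    "private_allele_stats",
    "PanelSummary",
    "panel_summary",
    "status_grouping",
]


def pic_allele(f):
    """Dominant-marker polymorphism information content 2f(1-f).

    Accepts a scalar or array of occurrence frequencies in [0, 1]; the
    maximum 0.5 is attained at f = 0.5, and PIC(f) = PIC(1-f).
    """
    arr = np.asarray(f, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"occurrence frequency outside [0, 1]: {f!r}")
    out = 2.0 * arr * (1.0 - arr)
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out


def occurrence_frequency(m: AlleleMatrix) -> pd.DataFrame:
    """Per-allele occurrence counts and frequencies f = count / n.

    Returns a DataFrame indexed by column label with columns
    ``marker_id, fragment_size_bp, count, f``.
    """
    counts = m.allele_counts().astype(int)
    return pd.DataFrame(
        {
            "marker_id": [a.marker_id for a in m.alleles],
            "fragment_size_bp": [a.fragment_size_bp for a in m.alleles],
            "count": counts,
            "f": counts / m.n,
        },
        index=pd.Index(m.column_labels, name="allele"),
    )


def allele_stats(m: AlleleMatrix) -> pd.DataFrame:
    """Occurrence frequency, PIC and privacy for every allele column.

    ``is_private`` marks alleles observed in exactly one individual;
    ``carrier`` names that individual (NA otherwise).
    """
    df = occurrence_frequency(m)
    df["pic"] = pic_allele(df["f"].to_numpy())
    df["is_private"] = df["count"] == 1
    carriers = []
    for j, priv in enumerate(df["is_private"]):
        if priv:
            i = int(np.nonzero(m.X[:, j])[0][0])
            carriers.append(m.individuals[i])
        else:
            carriers.append(pd.NA)
    df["carrier"] = carriers
    return df


@dataclass(frozen=True)
class MarkerSummary:
    """Per-marker row of the characterisation table."""

    marker_id: str
    pic_av: float
    pic_min: float
    pic_max: float
    noa_tot: int
    noa_priv: int
    min_af: float
    max_af: float
    size_range_bp: tuple[int, int]

    def __post_init__(self) -> None:
        assert self.pic_min <= self.pic_av <= self.pic_max + 1e-12
        assert 0 <= self.noa_priv <= self.noa_tot
        assert self.min_af <= self.max_af


def marker_summary(m: AlleleMatrix, marker_id: str) -> MarkerSummary:
    """Summarise one marker locus: PIC average/extrema over ALL its alleles
    (monomorphic alleles included with PIC 0), allele and private-allele
    counts, occurrence-frequency extrema, fragment size range."""
    loci = m.loci
    if marker_id not in loci:
        raise KeyError(f"unknown marker id {marker_id!r}")
    js = loci[marker_id]
    counts = m.X[:, js].sum(axis=0).astype(int)
    f = counts / m.n
    pic = pic_allele(f)
    sizes = [m.alleles[j].fragment_size_bp for j in js]
    return MarkerSummary(
        marker_id=marker_id,
        pic_av=float(pic.mean()),
        pic_min=float(pic.min()),
        pic_max=float(pic.max()),
        noa_tot=len(js),
        noa_priv=int((counts == 1).sum()),
        min_af=float(f.min()),
        max_af=float(f.max()),
        size_range_bp=(min(sizes), max(sizes)),
    )


def marker_summaries(m: AlleleMatrix) -> pd.DataFrame:
    """All marker summaries as a DataFrame indexed by marker id."""
    rows = [marker_summary(m, mk) for mk in m.loci]
    return pd.DataFrame(
        {
            "pic_av": [r.pic_av for r in rows],
            "pic_min": [r.pic_min for r in rows],
            "pic_max": [r.pic_max for r in rows],
            "noa_tot": [r.noa_tot for r in rows],
            "noa_priv": [r.noa_priv for r in rows],
            "min_af": [r.min_af for r in rows],
            "max_af": [r.max_af for r in rows],
            "size_min_bp": [r.size_range_bp[0] for r in rows],
            "size_max_bp": [r.size_range_bp[1] for r in rows],
        },
        index=pd.Index([r.marker_id for r in rows], name="marker_id"),
    )


class PrivateAlleleStats(NamedTuple):
    flags: pd.Series  # per allele label: observed in exactly one individual
    per_individual: pd.Series  # private alleles carried by each individual
    per_marker: pd.Series  # private alleles at each marker
    total: int


def private_allele_stats(m: AlleleMatrix) -> PrivateAlleleStats:
    """Private-allele accounting: flags, per-carrier and per-marker tallies.

    Consistency: the per-individual and per-marker tallies both sum to the
    total number of columns with occurrence count 1.
    """
    counts = m.allele_counts()
    flags = pd.Series(counts == 1, index=pd.Index(m.column_labels, name="allele"))
    per_ind = pd.Series(0, index=pd.Index(m.individuals, name="individual_id"), dtype=int)
    per_marker = pd.Series(0, index=pd.Index(list(m.loci), name="marker_id"), dtype=int)
    for j in np.nonzero(counts == 1)[0]:
        carrier = m.individuals[int(np.nonzero(m.X[:, j])[0][0])]
        per_ind[carrier] += 1
        per_marker[m.alleles[j].marker_id] += 1
    return PrivateAlleleStats(flags, per_ind, per_marker, int(flags.sum()))


@dataclass(frozen=True)
class PanelSummary:
    """Panel-wide tallies: allele totals, per-individual counts, group tallies."""

    total_alleles: int
    n_loci: int
    mean_alleles_per_marker: float
    mean_alleles_per_individual: float
    mean_alleles_per_individual_per_marker: float
    total_private: int
    per_individual_counts: dict[str, int]
    group_tallies: dict[str, tuple[int, float]]  # group -> (allele_total, mean per individual)


def panel_summary(m: AlleleMatrix, grouping: Mapping[str, str] | None = None) -> PanelSummary:
    """Panel totals plus per-group allele tallies.

    ``grouping`` maps every individual id to a group label (e.g. cultivar /
    non-cultivar from passport status, or downstream cluster labels).  A
    group's allele total counts columns present in at least one member; its
    per-individual mean is the mean row sum within the group.
    """
    row_sums = m.individual_allele_totals().astype(int)
    per_ind = dict(zip(m.individuals, (int(v) for v in row_sums)))
    tallies: dict[str, tuple[int, float]] = {}
    if grouping is not None:
        missing = [i for i in m.individuals if i not in grouping]
        if missing:
            raise KeyError(f"individual(s) missing from grouping: {missing}")
        for g in dict.fromkeys(grouping[i] for i in m.individuals):
            members = [i for i in m.individuals if grouping[i] == g]
            rows = [m.individuals.index(i) for i in members]
            block = m.X[rows]
            allele_total = int((block.sum(axis=0) > 0).sum())
            tallies[g] = (allele_total, float(block.sum() / len(members)))
    priv = private_allele_stats(m)
    return PanelSummary(
        total_alleles=m.n_alleles,
        n_loci=m.n_loci,
        mean_alleles_per_marker=m.n_alleles / m.n_loci,
        mean_alleles_per_individual=float(row_sums.mean()),
        mean_alleles_per_individual_per_marker=float(row_sums.mean() / m.n_loci),
        total_private=priv.total,
        per_individual_counts=per_ind,
        group_tallies=tallies,
    )


def status_grouping(statuses: Mapping[str, str]) -> dict[str, str]:
    """Collapse passport status into the cultivar / non-cultivar split.

    ``cultivar`` and ``cultivated`` count as cultivars; landraces, ecotypes,
    wild material and unknowns are non-cultivars.
    """
    return {
        ind: ("cultivar" if s in ("cultivar", "cultivated") else "non-cultivar")
        for ind, s in statuses.items()
    }
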