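"""Shared data model: genotype matrices, read bundles, population metadata.

The :class:`GenotypeMatrix` is the common currency of every analysis in this
package: a diploid individuals x loci table of integer-coded allele pairs
with population and region labels attached.  Allele codes are dense
non-negative integers per locus; the original labels (fragment lengths,
REF/ALT bases, sequence identities) are retained in ``allele_labels``.

Marker kinds distinguish how the integer codes may be interpreted:

``ssr_length``
    microsatellite alleles coded by repeat length -- allele-size statistics
    (e.g. allele-size variance) are meaningful.
``ssr_id``
    microsatellite alleles coded by arbitrary sequence identity -- integer
    codes carry no length information, so length-based statistics are
    refused for these loci.
``snp``
    biallelic single-nucleotide polymorphisms (codes 0 = REF, 1 = ALT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Sentinel allele code for a missing call.  Both members of the pair are
#: set to MISSING; a half-called genotype is not representable.
MISSING: int = -1

MARKER_KINDS = ("ssr_length", "ssr_id", "snp")

#: Census-size bins used for field estimates of population size.
CENSUS_CATEGORIES = ("1-10", "10-100", "100-1000", "1000-10000")

#: Geometric midpoints of the census bins (lower bound 1 -> sqrt(1*10) etc.).
CENSUS_MIDPOINTS = {
    "1-10": 10.0 ** 0.5,
    "10-100": 10.0 ** 1.5,
    "100-1000": 10.0 ** 2.5,
    "1000-10000": 10.0 ** 3.5,
}


class FragdivError(Exception):
    """Base class for errors raised by this package."""


class ParseError(FragdivError):
    """A file failed to parse; the message names the offending line."""


class UnsupportedFormatError(FragdivError):
    """The requested output format cannot carry the data."""


@dataclass
class GenotypeMatrix:
    """Diploid multi-locus genotypes with population structure.

    Parameters
    ----------
    individuals
        Ordered individual identifiers.
    populations
        Map individual -> population identifier.  Every individual belongs
        to exactly one population.
    regions
        Map population -> region label (free text; the study design uses
        ``"fragmented"`` and ``"continuous"``).  May be empty when the
        source format does not carry regions.
    loci
        Ordered locus identifiers.
    marker_kinds
        One of :data:`MARKER_KINDS` per locus, aligned with ``loci``.
    calls
        ``(n_individuals, n_loci, 2)`` integer array of dense allele codes,
        :data:`MISSING` for no-calls.  Pairs are stored sorted so that
        heterozygotes are order-independent (AB == BA).
    allele_labels
        Optional map locus -> list of original allele labels indexed by the
        dense code (e.g. ``["A", "G"]`` for a SNP, fragment lengths for a
        PCR-SSR).
    """

    individuals: list[str]
    populations: dict[str, str]
    regions: dict[str, str]
    loci: list[str]
    marker_kinds: list[str]
    calls: np.ndarray
    allele_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise FragdivError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.marker_kinds) != len(self.loci):
            raise FragdivError("marker_kinds must align with loci")
        for k in self.marker_kinds:
            if k not in MARKER_KINDS:
                raise FragdivError(f"unknown marker kind {k!r}")
        missing_pop = [i for i in self.individuals if i not in self.populations]
        if missing_pop:
            raise FragdivError(f"individuals without population: {missing_pop[:3]}")
        # canonical order-independent storage; missing pairs forced to (-1,-1)
        self.calls = np.sort(self.calls, axis=2)
        half_missing = (self.calls[:, :, 0] == MISSING) ^ (self.calls[:, :, 1] == MISSING)
        if half_missing.any():
            raise FragdivError("half-missing genotype calls are not supported")

    # -- basic structure -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_ids(self) -> list[str]:
        """Population identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def individuals_of(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        return np.array(
            [i for i, ind in enumerate(self.individuals)
             if self.populations[ind] == population],
            dtype=np.intp,
        )

    def region_of(self, population: str) -> str:
        return self.regions.get(population, "")

    def populations_of_region(self, region: str) -> list[str]:
        return [p for p in self.population_ids() if self.regions.get(p) == region]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individuals/loci."""
        inds = list(individuals) if individuals is not None else list(self.individuals)
        locs = list(loci) if loci is not None else list(self.loci)
        ind_idx = {name: i for i, name in enumerate(self.individuals)}
        loc_idx = {name: i for i, name in enumerate(self.loci)}
        rows = np.array([ind_idx[i] for i in inds], dtype=np.intp)
        cols = np.array([loc_idx[l] for l in locs], dtype=np.intp)
        pops = {i: self.populations[i] for i in inds}
        present = set(pops.values())
        return GenotypeMatrix(
            individuals=inds,
            populations=pops,
            regions={p: r for p, r in self.regions.items() if p in present},
            loci=locs,
            marker_kinds=[self.marker_kinds[c] for c in cols],
            calls=self.calls[np.ix_(rows, cols)],
            allele_labels={l: self.allele_labels[l] for l in locs if l in self.allele_labels},
        )

    # -- allele bookkeeping ----------------------------------------------

    def n_alleles(self, locus_index: int) -> int:
        """Number of distinct allele codes observed at a locus."""
        col = self.calls[:, locus_index, :]
        vals = col[col != MISSING]
        return int(np.unique(vals).size)

    def allele_counts(
        self, locus_index: int, rows: np.ndarray | None = None
    ) -> np.ndarray:
        """Gene-copy counts per dense allele code at one locus.

        Returns a vector indexed by allele code whose length is the maximum
        observed code + 1 (over the selected rows).
        """
        col = self.calls[:, locus_index, :] if rows is None else self.calls[rows, locus_index, :]
        vals = col[col != MISSING]
        if vals.size == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(vals)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Structural equality on the fields every format carries."""
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and self.marker_kinds == other.marker_kinds
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMeta:
    """Field metadata for one sampled population."""

    population: str
    latitude: float
    longitude: float
    census_category: str
    region: str = ""
    census_count: int | None = None

    def __post_init__(self) -> None:
        if self.census_category not in CENSUS_CATEGORIES:
            raise FragdivError(
                f"census_category {self.census_category!r} not one of {CENSUS_CATEGORIES}"
            )
        if not (np.isfinite(self.latitude) and np.isfinite(self.longitude)):
            raise FragdivError("latitude/longitude must be finite")
        if abs(self.latitude) > 90:
            raise FragdivError(f"latitude {self.latitude} out of range")

    @property
    def census_midpoint(self) -> float:
        """Exact census count when recorded, else the bin's geometric midpoint."""
        if self.census_count is not None:
            return float(self.census_count)
        return CENSUS_MIDPOINTS[self.census_category]


class ReadBundleSet:
    """Per-(individual, locus) collections of (sequence, read count).

    The downstream RAD-SSR caller consumes one bundle (a dict mapping
    sequence -> count) per individual per catalog locus.
    """

    def __init__(self) -> None:
        self._bundles: dict[tuple[str, str], dict[str, int]] = {}

    def add(self, individual: str, locus: str, sequence: str, count: int) -> None:
        if count < 1:
            raise FragdivError(
                f"read count must be >= 1 ({individual}/{locus}: {count})"
            )
        key = (individual, locus)
        bundle = self._bundles.setdefault(key, {})
        if sequence in bundle:
            raise FragdivError(
                f"duplicate read row for {individual}/{locus}/{sequence[:20]}"
            )
        bundle[sequence] = count

    def bundle(self, individual: str, locus: str) -> dict[str, int]:
        return dict(self._bundles.get((individual, locus), {}))

    def keys(self) -> list[tuple[str, str]]:
        return list(self._bundles)

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind, _ in self._bundles:
            seen.setdefault(ind, None)
        return list(seen)

    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, locus in self._bundles:
            seen.setdefault(locus, None)
        return list(seen)

    def items(self) -> Iterable[tuple[tuple[str, str], dict[str, int]]]:
        return self._bundles.items()

    def __len__(self) -> int:
        return len(self._bundles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadBundleSet):
            return NotImplemented
        return self._bundles == other._bundles


def sorted_pair(a: int, b: int) -> tuple[int, int]:
    """Canonical (unordered) storage order for a diploid allele pair."""
    return (a, b) if a <= b else (b, a)


def meta_table(metas: Iterable[PopulationMeta]) -> "Mapping[str, PopulationMeta]":
    """Index a collection of population metadata records by population ID."""
    return {m.population: m for m in metas}
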