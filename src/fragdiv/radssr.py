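"""RAD-SSR locus mining and genotype calling.

Microsatellites mined from RAD reads are genotyped from the full read
sequence, so alleles of equal length but different sequence are
distinguished; allele codes are arbitrary dense integers with no length
meaning (marker kind ``ssr_id``).

Calling rules, applied per individual per catalog locus on trimmed reads:

1. sequences supported by fewer than ``min_allele_reads`` identical reads
   are discarded;
2. if the remaining reads total fewer than ``min_total_reads`` the call is
   missing;
3. a single qualifying sequence is called homozygous;
4. a second qualifying sequence is called (making a heterozygote) when its
   count exceeds ``het_fraction`` of the bundle's total reads, counted
   before the support filter.

Loci with more than ``max_unique`` distinct diploid genotypes across
individuals are dropped as likely sequencing-error aggregates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .model import (
    MISSING,
    FragdivError,
    GenotypeMatrix,
    ReadBundleSet,
    sorted_pair,
)


@dataclass
class CatalogLocus:
    """A catalog consensus sequence carrying a di-nucleotide repeat."""

    locus: str
    consensus: str
    motif: str
    repeat_count: int
    n_individuals: int


@dataclass
class SsrGenotypeCall:
    """One individual's integer-coded genotype at one RAD-SSR locus."""

    individual: str
    locus: str
    alleles: tuple[int, int]  # (MISSING, MISSING) for no-call
    support: dict[int, int]  # reads per called allele code
    extra_sequences: int = 0  # qualifying sequences beyond the two called

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] == MISSING


_DINUC_RE = re.compile(r"(?=((AC|AG|AT|CA|CG|CT|GA|GC|GT|TA|TC|TG)\2+))")


def longest_dinucleotide_repeat(sequence: str) -> tuple[str, int]:
    """Longest perfect tandem repeat of a two-distinct-base motif.

    Returns ``(motif, repeat_count)``; ``("", 0)`` when none is present.
    Homopolymer runs (motif bases equal) are never reported.
    """
    best = ("", 0)
    for m in _DINUC_RE.finditer(sequence.upper()):
        run, motif = m.group(1), m.group(2)
        count = len(run) // 2
        if count > best[1]:
            best = (motif, count)
    return best


def find_dinucleotide_loci(catalog: dict[str, str],
                           presence: dict[str, int],
                           min_repeats: int = 5,
                           min_individuals: int = 50) -> list[CatalogLocus]:
    """Scan catalog consensus sequences for usable di-nucleotide SSR loci.

    ``catalog`` maps locus ID -> consensus sequence, ``presence`` maps
    locus ID -> number of individuals with data.  A locus qualifies when
    its consensus contains a perfect repeat of a two-distinct-base motif
    repeated at least ``min_repeats`` times and it has data in strictly
    more than ``min_individuals`` individuals.
    """
    if min_repeats < 2:
        raise FragdivError("min_repeats must be >= 2")
    out: list[CatalogLocus] = []
    for locus, consensus in catalog.items():
        motif, count = longest_dinucleotide_repeat(consensus)
        if count < min_repeats:
            continue
        n_ind = presence.get(locus, 0)
        if n_ind <= min_individuals:  # strict: "> min_individuals"
            continue
        out.append(CatalogLocus(locus=locus, consensus=consensus.upper(),
                                motif=motif, repeat_count=count,
                                n_individuals=n_ind))
    return out


def trim_reads(bundles: ReadBundleSet, n_tail: int = 7) -> ReadBundleSet:
    """Remove the final ``n_tail`` bases of every read sequence.

    Sequences identical after trimming have their counts merged by
    summation.  ``n_tail=0`` is the identity.
    """
    if n_tail < 0:
        raise FragdivError("n_tail must be >= 0")
    out = ReadBundleSet()
    for (ind, locus), bundle in bundles.items():
        merged: dict[str, int] = {}
        for seq, count in bundle.items():
            if len(seq) <= n_tail and n_tail > 0:
                raise FragdivError(
                    f"read of length {len(seq)} at {ind}/{locus} too short "
                    f"to trim {n_tail} bases"
                )
            trimmed = seq[:len(seq) - n_tail] if n_tail else seq
            merged[trimmed] = merged.get(trimmed, 0) + count
        for seq, count in merged.items():
            out.add(ind, locus, seq, count)
    return out


class AlleleRegistry:
    """Per-locus assignment of dense integer codes to allele sequences.

    Codes are assigned in order of first appearance across individuals and
    never reused: distinct sequences always receive distinct codes, even
    when they have equal length.
    """

    def __init__(self) -> None:
        self._codes: dict[str, dict[str, int]] = {}

    def code(self, locus: str, sequence: str) -> int:
        table = self._codes.setdefault(locus, {})
        if sequence not in table:
            table[sequence] = len(table)
        return table[sequence]

    def n_alleles(self, locus: str) -> int:
        return len(self._codes.get(locus, {}))

    def sequences(self, locus: str) -> dict[int, str]:
        return {v: k for k, v in self._codes.get(locus, {}).items()}


def call_genotype(bundle: dict[str, int], individual: str, locus: str,
                  registry: AlleleRegistry,
                  min_total_reads: int = 10,
                  min_allele_reads: int = 3,
                  het_fraction: float = 0.10) -> SsrGenotypeCall:
    """Call one individual x locus genotype from a trimmed read bundle.

    See the module docstring for the rule order.  The heterozygote
    fraction test uses the bundle's total read count (before the
    support filter) as its denominator.
    """
    if min_total_reads <= 0 or min_allele_reads <= 0 or het_fraction <= 0:
        raise FragdivError("calling thresholds must be positive")
    total_reads = sum(bundle.values())
    qualifying = {s: c for s, c in bundle.items() if c >= min_allele_reads}
    if sum(qualifying.values()) < min_total_reads:
        return SsrGenotypeCall(individual, locus, (MISSING, MISSING), {})
    # deterministic ranking: count desc, then sequence lexicographic
    ranked = sorted(qualifying.items(), key=lambda kv: (-kv[1], kv[0]))
    top_seq, top_count = ranked[0]
    second = None
    extra = 0
    if len(ranked) > 1:
        cand_seq, cand_count = ranked[1]
        if cand_count > het_fraction * total_reads:
            second = (cand_seq, cand_count)
        extra = sum(
            1 for s, c in ranked[2:] if c > het_fraction * total_reads
        )
    a = registry.code(locus, top_seq)
    if second is None:
        return SsrGenotypeCall(individual, locus, (a, a),
                               {a: top_count}, extra_sequences=extra)
    b = registry.code(locus, second[0])
    return SsrGenotypeCall(individual, locus, sorted_pair(a, b),
                           {a: top_count, b: second[1]},
                           extra_sequences=extra)


def filter_loci(calls: list[SsrGenotypeCall],
                max_unique: int = 40) -> tuple[bool, str]:
    """Keep/drop decision for one locus given all its genotype calls.

    Returns ``(keep, reason)``: dropped when the number of distinct
    non-missing diploid genotypes exceeds ``max_unique`` (sequencing-error
    risk) or when every call is missing.
    """
    if not calls:
        raise FragdivError("filter_loci needs at least one call")
    genotypes = {c.alleles for c in calls if not c.is_missing}
    if not genotypes:
        return (False, "all_missing")
    if len(genotypes) > max_unique:
        return (False, "too_many_genotypes")
    return (True, "ok")


def call_dataset(bundles: ReadBundleSet,
                 populations: dict[str, str] | None = None,
                 min_total_reads: int = 10,
                 min_allele_reads: int = 3,
                 het_fraction: float = 0.10,
                 max_unique: int = 40,
                 trim_tail: int = 0) -> tuple[GenotypeMatrix, AlleleRegistry]:
    """Call genotypes for every (individual, locus) bundle and assemble a
    genotype matrix of the loci passing :func:`filter_loci`.

    Individuals and loci are ordered by first appearance in the bundle
    set; individuals with no bundle at a kept locus are missing there.
    """
    if trim_tail:
        bundles = trim_reads(bundles, trim_tail)
    registry = AlleleRegistry()
    individuals = bundles.individuals()
    loci = bundles.loci()
    calls_by_locus: dict[str, list[SsrGenotypeCall]] = {l: [] for l in loci}
    call_map: dict[tuple[str, str], SsrGenotypeCall] = {}
    for ind in individuals:  # individual-major order fixes code assignment
        for locus in loci:
            bundle = bundles.bundle(ind, locus)
            if not bundle:
                continue
            call = call_genotype(bundle, ind, locus, registry,
                                 min_total_reads, min_allele_reads,
                                 het_fraction)
            calls_by_locus[locus].append(call)
            call_map[(ind, locus)] = call
    kept = [l for l in loci
            if calls_by_locus[l] and filter_loci(calls_by_locus[l], max_unique)[0]]
    n, m = len(individuals), len(kept)
    mat = np.full((n, m, 2), MISSING, dtype=np.int32)
    for i, ind in enumerate(individuals):
        for j, locus in enumerate(kept):
            call = call_map.get((ind, locus))
            if call is not None and not call.is_missing:
                mat[i, j] = call.alleles
    pops = populations or {ind: "pop1" for ind in individuals}
    return (
        GenotypeMatrix(
            individuals=individuals,
            populations={i: pops.get(i, "pop1") for i in individuals},
            regions={},
            loci=kept,
            marker_kinds=["ssr_id"] * m,
            calls=mat,
        ),
        registry,
    )


# ---------------------------------------------------------------------------
# clone detection

def detect_clones(gm: GenotypeMatrix, min_shared_loci: int = 1) -> list[list[str]]:
    """Group individuals with identical genotypes at every shared locus.

    Two individuals match when their allele pairs are identical at every
    locus where both have data and they share at least ``min_shared_loci``
    such loci.  Groups are the connected components of the match relation;
    within each group the first individual (input order) is the retained
    representative, the rest are flagged clones.
    """
    if gm.n_individuals == 0:
        raise FragdivError("empty genotype matrix")
    if min_shared_loci > gm.n_loci:
        raise FragdivError(
            f"min_shared_loci {min_shared_loci} exceeds locus count {gm.n_loci}"
        )
    n = gm.n_individuals
    present = gm.calls[:, :, 0] != MISSING
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for k in range(i + 1, n):
            both = present[i] & present[k]
            if both.sum() < min_shared_loci:
                continue
            if np.array_equal(gm.calls[i][both], gm.calls[k][both]):
                parent[find(k)] = find(i)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(gm.individuals[i])
    return [g for g in groups.values() if len(g) > 1]


def clone_summary(groups: list[list[str]], n_individuals: int) -> dict:
    """Count flagged clones (group members beyond the representative) and
    their percentage of the assayed individuals."""
    n_clones = sum(len(g) - 1 for g in groups)
    return {
        "n_individuals": n_individuals,
        "n_clones": n_clones,
        "percent_clonal": 100.0 * n_clones / n_individuals if n_individuals else 0.0,
    }
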