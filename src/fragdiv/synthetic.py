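"""Synthetic study generators.

Three generators provide ground-truth data with the statistical structure
the downstream analyses assume:

* :func:`simulate_balding_nichols` -- the forward direction of the
  multinomial-Dirichlet model used by the ML-F_ST estimator: population
  allele frequencies are drawn around regional means with a per-population
  drift parameter F, then diploid genotypes are drawn under Hardy-Weinberg.
* :func:`simulate_wright_fisher_ld` -- a discrete-generation Wright-Fisher
  forward simulation of unlinked biallelic loci, generating the drift
  linkage disequilibrium that the LD-based Ne estimator measures.
* :func:`simulate_rad_reads` -- read bundles (Poisson coverage, binomial
  allele split, per-base substitution errors) for exercising the RAD-SSR
  caller.

:func:`make_study_fixture` assembles a full two-region study design --
29 fragmented-region and 10 continuous-region populations, four marker
sets over shared individuals with the RAD sets on a subset, census-size
categories tied to the drift parameter, and a handful of clonal
duplicates -- mirroring a fragmented/continuous survey of a dwarf tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    MISSING,
    FragdivError,
    GenotypeMatrix,
    PopulationMeta,
    ReadBundleSet,
)

# Per-population post-clone-removal sample sizes and clone counts for the
# study design the fixture emulates: 10 continuous-region populations
# (296 individuals + 8 clones) and 29 fragmented-region populations
# (770 individuals + 41 clones), totalling 1066 + 49 = 1115 assayed
# samples.  RAD subset sizes: 60 continuous + 130 fragmented = 190.
_CONTINUOUS_DESIGN = [
    # (population, n_pcr, n_clones, n_rad, census_category)
    ("NK", 30, 0, 6, "10-100"),
    ("SM", 30, 4, 6, "100-1000"),
    ("TE", 30, 0, 6, "100-1000"),
    ("SK", 32, 0, 6, "100-1000"),
    ("KP", 32, 0, 6, "100-1000"),
    ("KA", 31, 2, 6, "100-1000"),
    ("UG", 23, 2, 6, "1000-10000"),
    ("KR", 31, 0, 6, "1000-10000"),
    ("DJ", 29, 0, 6, "100-1000"),
    ("PT", 28, 0, 6, "1000-10000"),
]

_FRAGMENTED_DESIGN = [
    ("BL", 30, 0, 6, "10-100"),
    ("MO", 25, 11, 6, "10-100"),
    ("BE", 27, 0, 6, "10-100"),
    ("LH", 32, 2, 6, "10-100"),
    ("BW", 29, 0, 6, "100-1000"),
    ("DG", 21, 0, 0, "10-100"),
    ("ME", 26, 0, 6, "10-100"),
    ("GC", 33, 0, 6, "10-100"),
    ("FS", 31, 0, 0, "100-1000"),
    ("DE", 30, 0, 6, "10-100"),
    ("AS", 30, 2, 3, "10-100"),
    ("BB", 33, 0, 6, "10-100"),
    ("PC", 41, 5, 6, "10-100"),
    ("AV", 31, 0, 6, "10-100"),
    ("MD", 28, 5, 6, "10-100"),
    ("SL", 31, 0, 6, "10-100"),
    ("MU1", 31, 0, 6, "1000-10000"),
    ("MU2", 32, 0, 6, "1000-10000"),
    ("LG", 39, 6, 6, "10-100"),
    ("LL", 30, 4, 6, "10-100"),
    ("BG", 5, 0, 1, "1-10"),
    ("LR", 29, 2, 6, "10-100"),
    ("RW", 31, 2, 6, "1000-10000"),
    ("RB", 31, 2, 6, "100-1000"),
    ("RA", 30, 0, 0, "100-1000"),
    ("LX", 29, 0, 6, "10-100"),
    ("EM", 2, 0, 0, "1-10"),
    ("SA", 1, 0, 0, "1-10"),
    ("TD", 2, 0, 0, "1-10"),
]

#: Drift parameter (Balding-Nichols F) per census-size category for
#: fragmented-region populations: smaller census -> stronger drift.
_F_BY_CATEGORY = {
    "1-10": 0.35,
    "10-100": 0.12,
    "100-1000": 0.06,
    "1000-10000": 0.03,
}

#: Continuous-region populations are large and connected: uniform, low F.
_F_CONTINUOUS = 0.02


@dataclass
class SyntheticStudyConfig:
    """Configuration for :func:`make_study_fixture`.

    Defaults reproduce the emulated study design: 29 + 10 populations,
    marker sets of 18 length-coded SSR, 193 identity-coded RAD-SSR,
    4775 transition-SNP and 3306 transversion-SNP loci, with the RAD sets
    assayed on a subset of individuals.
    """

    n_loci_ssr_length: int = 18
    n_loci_ssr_id: int = 193
    n_loci_snp_ti: int = 4775
    n_loci_snp_tv: int = 3306
    alleles_per_ssr_length: int = 23
    alleles_per_ssr_id: int = 9
    fragmented_design: list = field(default_factory=lambda: list(_FRAGMENTED_DESIGN))
    continuous_design: list = field(default_factory=lambda: list(_CONTINUOUS_DESIGN))
    f_by_category: dict = field(default_factory=lambda: dict(_F_BY_CATEGORY))
    f_continuous: float = _F_CONTINUOUS
    rad_coverage_mean: float = 40.0
    rad_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_loci_ssr_length, self.n_loci_ssr_id,
                  self.n_loci_snp_ti, self.n_loci_snp_tv):
            if n < 1:
                raise FragdivError("locus counts must be >= 1")
        for f in list(self.f_by_category.values()) + [self.f_continuous]:
            if not 0 <= f < 1:
                raise FragdivError(f"F={f} outside [0, 1)")


# ---------------------------------------------------------------------------
# Balding-Nichols forward model

def simulate_balding_nichols(regional_freqs: list[np.ndarray],
                             f_per_pop: list[float],
                             n_per_pop: list[int],
                             seed: int | np.random.Generator | None = None,
                             marker_kind: str = "ssr_id",
                             pop_names: list[str] | None = None,
                             region: str = "region") -> GenotypeMatrix:
    """Draw a genotype matrix under the Balding-Nichols model.

    For each population with drift parameter F and each locus with
    regional mean frequencies pi, population frequencies are drawn from
    Dirichlet(pi (1-F)/F) (F = 0 uses pi directly), then 2n gene copies
    are drawn multinomially and paired at random into diploid genotypes
    (Hardy-Weinberg within population).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = [np.asarray(pi, dtype=np.float64) for pi in regional_freqs]
    for pi in freqs:
        if abs(pi.sum() - 1.0) > 1e-9:
            raise FragdivError(f"frequency vector sums to {pi.sum()}, not 1")
    for f in f_per_pop:
        if not 0 <= f < 1:
            raise FragdivError(f"F={f} outside [0, 1)")
    if len(f_per_pop) != len(n_per_pop):
        raise FragdivError("f_per_pop and n_per_pop must align")
    for n in n_per_pop:
        if n < 1:
            raise FragdivError("population sample sizes must be >= 1")

    if pop_names is None:
        pop_names = [f"P{i + 1}" for i in range(len(n_per_pop))]
    individuals: list[str] = []
    populations: dict[str, str] = {}
    n_loci = len(freqs)
    total_n = sum(n_per_pop)
    calls = np.zeros((total_n, n_loci, 2), dtype=np.int32)
    row = 0
    all_biallelic = all(len(pi) == 2 for pi in freqs)
    for pop, f, n in zip(pop_names, f_per_pop, n_per_pop):
        for k in range(n):
            ind = f"{pop}_{k + 1}"
            individuals.append(ind)
            populations[ind] = pop
        if all_biallelic:
            # biallelic loci vectorize: Dirichlet collapses to a Beta
            pi0 = np.array([pi[0] for pi in freqs])
            if f > 0:
                a = pi0 * (1.0 - f) / f
                b = (1.0 - pi0) * (1.0 - f) / f
                p0 = np.where(pi0 <= 0, 0.0,
                              np.where(pi0 >= 1, 1.0,
                                       rng.beta(np.maximum(a, 1e-12),
                                                np.maximum(b, 1e-12))))
            else:
                p0 = pi0
            draws = rng.random((n, n_loci, 2)) < p0[None, :, None]
            calls[row:row + n, :, :] = np.where(draws, 0, 1)
        else:
            for j, pi in enumerate(freqs):
                if f > 0:
                    alpha = pi * (1.0 - f) / f
                    # Dirichlet via gammas; zero-mass components stay zero
                    p = rng.gamma(np.where(alpha > 0, alpha, 1e-12))
                    p[alpha == 0] = 0.0
                    p = p / p.sum()
                else:
                    p = pi
                copies = rng.choice(len(pi), size=2 * n, p=p)
                calls[row:row + n, j, :] = copies.reshape(n, 2)
        row += n
    regions = {p: region for p in pop_names}
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        regions=regions,
        loci=[f"L{j + 1}" for j in range(n_loci)],
        marker_kinds=[marker_kind] * n_loci,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation

def simulate_wright_fisher_ld(ne: int, sample_size: int, n_loci: int,
                              generations: int, mu: float = 0.0,
                              seed: int | np.random.Generator | None = None,
                              init_freq: float = 0.5) -> GenotypeMatrix:
    """Forward Wright-Fisher simulation of unlinked biallelic loci.

    ``ne`` diploid individuals reproduce by random mating for
    ``generations`` discrete generations: each offspring draws two parents
    uniformly and receives one allele per locus from each, with symmetric
    per-locus mutation probability ``mu`` per transmission.  All loci start
    at frequency ``init_freq`` with genotypes in Hardy-Weinberg.  Finally
    ``sample_size`` individuals are sampled without replacement.

    The finite parent pool generates the between-locus drift disequilibrium
    that the LD-based Ne estimator is designed to detect.
    """
    if ne < 2:
        raise FragdivError("Ne must be >= 2")
    if sample_size > ne:
        raise FragdivError(f"sample_size {sample_size} > Ne {ne}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # genotypes: (ne, n_loci, 2) of 0/1
    geno = (rng.random((ne, n_loci, 2)) < init_freq).astype(np.int8)
    for _ in range(generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        m_pick = rng.integers(0, 2, size=(ne, n_loci))
        f_pick = rng.integers(0, 2, size=(ne, n_loci))
        child = np.empty_like(geno)
        child[:, :, 0] = np.take_along_axis(
            geno[mothers], m_pick[:, :, None], axis=2)[:, :, 0]
        child[:, :, 1] = np.take_along_axis(
            geno[fathers], f_pick[:, :, None], axis=2)[:, :, 0]
        if mu > 0:
            flips = rng.random((ne, n_loci, 2)) < mu
            child ^= flips.astype(np.int8)
        geno = child
    keep = rng.choice(ne, size=sample_size, replace=False)
    calls = geno[keep].astype(np.int32)
    individuals = [f"ind{i + 1}" for i in range(sample_size)]
    return GenotypeMatrix(
        individuals=individuals,
        populations={i: "wf" for i in individuals},
        regions={"wf": "simulated"},
        loci=[f"L{j + 1}" for j in range(n_loci)],
        marker_kinds=["snp"] * n_loci,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# RAD read simulation

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_rad_reads(gm: GenotypeMatrix,
                       allele_sequences: dict[str, dict[int, str]],
                       coverage_mean: float,
                       error_rate: float = 0.0,
                       seed: int | np.random.Generator | None = None,
                       het_bias: float = 0.5) -> ReadBundleSet:
    """Simulate read bundles for identity-coded SSR genotypes.

    Per individual per locus the total read count is Poisson with mean
    ``coverage_mean``; for heterozygotes the reads split binomially between
    the two allele sequences (probability ``het_bias`` for the first);
    substitution errors are applied independently per base at
    ``error_rate``.  Missing genotypes yield no reads.
    """
    if coverage_mean < 0:
        raise FragdivError("coverage_mean must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bundles = ReadBundleSet()
    for j, locus in enumerate(gm.loci):
        seq_map = allele_sequences.get(locus)
        if seq_map is None:
            raise FragdivError(f"no allele->sequence map for locus {locus}")
        for i, ind in enumerate(gm.individuals):
            a, b = gm.calls[i, j]
            if a == MISSING:
                continue
            for allele in (int(a), int(b)):
                if allele not in seq_map:
                    raise FragdivError(
                        f"allele {allele} at {locus} has no sequence mapping")
            total = int(rng.poisson(coverage_mean))
            if total == 0:
                continue
            if a == b:
                counts = {int(a): total}
            else:
                k = int(rng.binomial(total, het_bias))
                counts = {int(a): k, int(b): total - k}
            merged: dict[str, int] = {}
            for allele, n_reads in counts.items():
                if n_reads == 0:
                    continue
                seq = seq_map[allele]
                if error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1")
                    for _ in range(n_reads):
                        err = rng.random(len(arr)) < error_rate
                        if err.any():
                            read = arr.copy()
                            shift = rng.integers(1, 4, size=int(err.sum()))
                            idx = np.nonzero(err)[0]
                            base_idx = np.searchsorted(_BASES, read[idx])
                            read[idx] = _BASES[(base_idx + shift) % 4]
                            out = read.tobytes().decode()
                        else:
                            out = seq
                        merged[out] = merged.get(out, 0) + 1
                else:
                    merged[seq] = merged.get(seq, 0) + n_reads
            for seq, n_reads in merged.items():
                bundles.add(ind, locus, seq, n_reads)
    return bundles


def make_ssr_allele_sequences(gm: GenotypeMatrix, read_length: int = 60,
                              seed: int | np.random.Generator | None = None
                              ) -> dict[str, dict[int, str]]:
    """Random allele sequences of uniform length per locus for read simulation.

    Each locus gets a random backbone; each allele differs from the
    backbone at a distinct set of positions, so distinct alleles always
    have distinct sequences of equal length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, dict[int, str]] = {}
    for j, locus in enumerate(gm.loci):
        col = gm.calls[:, j, :]
        alleles = sorted(int(a) for a in np.unique(col[col != MISSING]))
        backbone = rng.integers(0, 4, size=read_length)
        seqs: dict[int, str] = {}
        for k, allele in enumerate(alleles):
            arr = backbone.copy()
            # mutate positions determined by the allele index: unique per allele
            pos = (k * 7) % (read_length - 1)
            arr[pos] = (arr[pos] + 1 + k % 3) % 4
            arr[(pos + 1) % read_length] = (arr[(pos + 1) % read_length] + 1 + k // 3) % 4
            seqs[allele] = "".join("ACGT"[b] for b in arr)
        if len(set(seqs.values())) != len(seqs):
            # extremely unlikely with the deterministic edits above; fall back
            for k, allele in enumerate(alleles):
                seqs[allele] = seqs[allele][:-4] + f"{k:04d}".translate(
                    str.maketrans("0123456789", "AACCGGTTAC"))
        out[locus] = seqs
    return out


# ---------------------------------------------------------------------------
# full study fixture

def _dirichlet_regional_freqs(rng: np.random.Generator, n_loci: int,
                              n_alleles: int, concentration: float = 1.0
                              ) -> list[np.ndarray]:
    return [rng.dirichlet(np.full(n_alleles, concentration)) for _ in range(n_loci)]


def _snp_regional_freqs(rng: np.random.Generator, n_loci: int) -> list[np.ndarray]:
    # ascertained SNPs: minor allele frequency bounded away from 0
    maf = rng.uniform(0.05, 0.5, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    p = np.where(flip, maf, 1.0 - maf)
    return [np.array([pi, 1.0 - pi]) for pi in p]


def make_study_fixture(config: SyntheticStudyConfig | None = None):
    """Generate a complete synthetic study.

    Returns ``(matrices, metas, bundles)`` where ``matrices`` maps marker
    set name (``ssr_length``, ``ssr_id``, ``snp_ti``, ``snp_tv``) to a
    :class:`GenotypeMatrix`, ``metas`` is the population metadata list and
    ``bundles`` a :class:`ReadBundleSet` for the identity-coded SSR loci of
    the RAD subset.

    The fragmented region gets per-population drift parameters tied to the
    census category (small census -> high F) and includes populations with
    only one or two individuals; the continuous region has uniform low F.
    Clonal duplicates are appended to the length-coded SSR matrix
    (duplicated multilocus genotypes) per the design's clone counts.
    """
    cfg = config or SyntheticStudyConfig()
    rng = np.random.default_rng(cfg.seed)

    designs = ([(p, n, c, r, cat, "continuous") for p, n, c, r, cat in cfg.continuous_design]
               + [(p, n, c, r, cat, "fragmented") for p, n, c, r, cat in cfg.fragmented_design])
    pop_names = [d[0] for d in designs]
    n_pcr = [d[1] for d in designs]
    f_per_pop = [
        cfg.f_continuous if d[5] == "continuous" else cfg.f_by_category[d[4]]
        for d in designs
    ]

    marker_plan = {
        "ssr_length": (cfg.n_loci_ssr_length, cfg.alleles_per_ssr_length, "ssr_length"),
        "ssr_id": (cfg.n_loci_ssr_id, cfg.alleles_per_ssr_id, "ssr_id"),
        "snp_ti": (cfg.n_loci_snp_ti, 2, "snp"),
        "snp_tv": (cfg.n_loci_snp_tv, 2, "snp"),
    }
    matrices: dict[str, GenotypeMatrix] = {}
    for name, (n_loci, n_alleles, kind) in marker_plan.items():
        if kind == "snp":
            freqs = _snp_regional_freqs(rng, n_loci)
        else:
            freqs = _dirichlet_regional_freqs(rng, n_loci, n_alleles)
        if name == "ssr_length":
            sizes = n_pcr
            pops = pop_names
            f_list = f_per_pop
        else:
            sizes = [d[3] for d in designs if d[3] > 0]
            pops = [d[0] for d in designs if d[3] > 0]
            f_list = [f for f, d in zip(f_per_pop, designs) if d[3] > 0]
        gm = simulate_balding_nichols(freqs, f_list, sizes, seed=rng,
                                      marker_kind=kind, pop_names=pops)
        gm.regions = {d[0]: d[5] for d in designs if d[0] in gm.regions}
        gm.loci = [f"{name}_{j + 1}" for j in range(n_loci)]
        if kind == "snp":
            ti_pairs = [("A", "G"), ("C", "T")]
            tv_pairs = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
            pairs = ti_pairs if name == "snp_ti" else tv_pairs
            gm.allele_labels = {
                locus: list(pairs[j % len(pairs)])
                for j, locus in enumerate(gm.loci)
            }
        matrices[name] = gm

    # clonal duplicates in the length-coded SSR matrix
    pcr = matrices["ssr_length"]
    clone_rows = []
    clone_names = []
    for d in designs:
        pop, n_clone = d[0], d[2]
        if n_clone == 0:
            continue
        rows = pcr.individuals_of(pop)
        chosen = rng.choice(rows, size=n_clone, replace=True)
        for k, src in enumerate(chosen):
            clone_rows.append(pcr.calls[src])
            clone_names.append((f"{pop}_clone{k + 1}", pop))
    if clone_rows:
        calls = np.concatenate([pcr.calls, np.stack(clone_rows)], axis=0)
        individuals = pcr.individuals + [n for n, _ in clone_names]
        populations = dict(pcr.populations)
        populations.update({n: p for n, p in clone_names})
        matrices["ssr_length"] = GenotypeMatrix(
            individuals=individuals, populations=populations,
            regions=pcr.regions, loci=pcr.loci,
            marker_kinds=pcr.marker_kinds, calls=calls,
            allele_labels=pcr.allele_labels,
        )

    # population metadata: coordinates on two latitude bands
    metas: list[PopulationMeta] = []
    for i, d in enumerate(designs):
        pop, _, _, _, cat, region = d
        if region == "continuous":
            lat = 69.0 + rng.uniform(0, 2.0)
            lon = 25.0 + rng.uniform(0, 3.0)
        else:
            lat = 54.5 + rng.uniform(0, 4.0)
            lon = -5.0 + rng.uniform(0, 3.0)
        count = None
        if cat == "1-10":
            count = int(rng.integers(1, 11))
        metas.append(PopulationMeta(
            population=pop, latitude=float(lat), longitude=float(lon),
            census_category=cat, region=region, census_count=count,
        ))

    # read bundles for the identity-coded SSR set
    radssr = matrices["ssr_id"]
    seq_map = make_ssr_allele_sequences(radssr, seed=rng)
    bundles = simulate_rad_reads(radssr, seq_map,
                                 coverage_mean=cfg.rad_coverage_mean,
                                 error_rate=cfg.rad_error_rate, seed=rng)
    return matrices, metas, bundles
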