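"""Diversity and differentiation statistics.

Implements the within-population diversity measures (rarefied allelic
richness, Nei's unbiased expected heterozygosity, F_IS), Weir–Cockerham
(1984) theta for global and pairwise F_ST with permutation significance,
linearized F_ST M = (1-F_ST)/F_ST, Mantel isolation-by-distance tests and
great-circle geographic distances.

All estimators operate on gene-copy counts derived from a
:class:`~fragdiv.model.GenotypeMatrix`; missing calls simply do not
contribute copies, so sample sizes may differ between loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import MISSING, FragdivError, GenotypeMatrix, PopulationMeta

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# allele counts

def allele_count_matrix(gm: GenotypeMatrix, rows: np.ndarray,
                        locus_index: int) -> np.ndarray:
    """Gene-copy counts per dense allele code for a set of individuals."""
    return gm.allele_counts(locus_index, rows)


# ---------------------------------------------------------------------------
# allelic richness

def rarefied_allelic_richness(counts: np.ndarray | list[int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: for allele i with count N_i out of N total
    copies, the probability that it appears in a random subsample of size g
    is 1 - C(N - N_i, g)/C(N, g); the rarefied richness is the sum over
    alleles.  Computed with log-binomials for stability.
    """
    counts = np.asarray([c for c in np.asarray(counts, dtype=np.int64) if c > 0])
    n_total = int(counts.sum())
    if g < 1:
        raise FragdivError(f"rarefaction size g={g} must be >= 1")
    if g > n_total:
        raise FragdivError(
            f"rarefaction size g={g} exceeds {n_total} gene copies sampled"
        )

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    log_cn = log_comb(n_total, g)
    for n_i in counts:
        if n_total - n_i < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(n_total - n_i, g) - log_cn)
    return float(total)


# ---------------------------------------------------------------------------
# heterozygosity and F_IS

def expected_heterozygosity(counts: np.ndarray | list[int]) -> float:
    """Nei's unbiased gene diversity (n/(n-1)) (1 - sum p_i^2).

    ``n`` is the number of gene copies sampled.  Monomorphic input gives 0.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum()
    if n < 2:
        raise FragdivError("expected_heterozygosity needs >= 2 gene copies")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p ** 2)))


def observed_heterozygosity(gm: GenotypeMatrix, rows: np.ndarray,
                            locus_index: int) -> tuple[float, int]:
    """Fraction of heterozygous individuals and the count genotyped."""
    col = gm.calls[rows, locus_index, :]
    ok = col[:, 0] != MISSING
    n = int(ok.sum())
    if n == 0:
        return (float("nan"), 0)
    het = (col[ok, 0] != col[ok, 1]).mean()
    return (float(het), n)


def fis(gm: GenotypeMatrix, population: str) -> tuple[pd.Series, float]:
    """Per-locus F_IS = 1 - H_obs/H_e for one population and the mean.

    Loci with H_e = 0 (monomorphic in the population) are undefined and
    reported as NaN; the mean over defined loci is weighted by the number
    of individuals genotyped at each locus.
    """
    rows = gm.individuals_of(population)
    values: list[float] = []
    weights: list[int] = []
    for j in range(gm.n_loci):
        counts = gm.allele_counts(j, rows)
        n_copies = counts.sum()
        if n_copies < 4:  # < 2 diploid individuals with data
            values.append(float("nan"))
            weights.append(0)
            continue
        he = expected_heterozygosity(counts)
        if he == 0.0:
            values.append(float("nan"))
            weights.append(0)
            continue
        hobs, n_ind = observed_heterozygosity(gm, rows, j)
        values.append(1.0 - hobs / he)
        weights.append(n_ind)
    series = pd.Series(values, index=gm.loci, name="F_IS")
    w = np.asarray(weights, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(v)
    mean = float(np.average(v[ok], weights=w[ok])) if ok.any() and w[ok].sum() > 0 else float("nan")
    return series, mean


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

@dataclass
class FstResult:
    """Weir–Cockerham theta with the summed variance components."""

    theta: float
    a_sum: float
    abc_sum: float
    n_loci_used: int
    p_value: float | None = None
    per_locus: pd.Series | None = None


def _wc_components(pop_counts: list[np.ndarray],
                   pop_het: list[tuple[np.ndarray, int]]) -> tuple[float, float, float]:
    """Variance components (a, b, c) summed over alleles at one locus.

    ``pop_counts`` holds gene-copy counts per allele code per population;
    ``pop_het`` holds (per-allele observed heterozygote frequency vector,
    n individuals) per population.
    """
    r = len(pop_counts)
    width = max(len(c) for c in pop_counts)
    counts = np.zeros((r, width))
    for i, c in enumerate(pop_counts):
        counts[i, :len(c)] = c
    n_i = np.array([h[1] for h in pop_het], dtype=np.float64)  # individuals
    if (n_i <= 0).any() or r < 2:
        return (0.0, 0.0, 0.0)
    p_i = counts / (2.0 * n_i[:, None])
    n_bar = n_i.mean()
    if n_bar <= 1:
        return (0.0, 0.0, 0.0)
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1.0)
    a_tot = b_tot = c_tot = 0.0
    for allele in range(width):
        if counts[:, allele].sum() == 0:
            continue
        p = p_i[:, allele]
        p_bar = (n_i * p).sum() / (r * n_bar)
        s2 = (n_i * (p - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
        h_i = np.array([h[0][allele] for h in pop_het])
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (
                p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        a_tot += a
        b_tot += b
        c_tot += c
    return (a_tot, b_tot, c_tot)


def _locus_inputs(gm: GenotypeMatrix, pops: list[str], locus_index: int,
                  rows_by_pop: dict[str, np.ndarray]):
    """Per-population counts and per-allele heterozygote frequencies.

    Allele codes are compacted to the alleles observed in scope, so the
    component loop never visits unobserved codes.
    """
    cols = []
    for pop in pops:
        rows = rows_by_pop[pop]
        col = gm.calls[rows, locus_index, :]
        col = col[col[:, 0] != MISSING]
        if col.shape[0] == 0:
            return None
        cols.append(col)
    alleles = np.unique(np.concatenate([c.ravel() for c in cols]))
    out_counts = []
    out_het = []
    for col in cols:
        n_ind = col.shape[0]
        # compact dosage: per observed allele, copies carried per individual
        carries = col[:, :, None] == alleles[None, None, :]  # (n, 2, k)
        counts = carries.sum(axis=(0, 1)).astype(np.float64)
        hz = col[:, 0] != col[:, 1]
        het = (carries.any(axis=1) & hz[:, None]).sum(axis=0) / n_ind
        out_counts.append(counts)
        out_het.append((het, n_ind))
    return out_counts, out_het


def _apply_filters(gm: GenotypeMatrix, pops: list[str],
                   rows_by_pop: dict[str, np.ndarray],
                   max_missing: float, min_maf: float,
                   require_all_pops: bool) -> list[int]:
    """Locus indices surviving the missingness / presence / MAF screens."""
    all_rows = np.concatenate([rows_by_pop[p] for p in pops])
    usable: list[int] = []
    for j in range(gm.n_loci):
        col = gm.calls[all_rows, j, 0]
        miss_frac = (col == MISSING).mean()
        if miss_frac > max_missing:
            continue
        if require_all_pops:
            if any((gm.calls[rows_by_pop[p], j, 0] != MISSING).sum() == 0 for p in pops):
                continue
        counts = gm.allele_counts(j, all_rows)
        total = counts.sum()
        if total == 0:
            continue
        freqs = counts / total
        nonzero = freqs[freqs > 0]
        if len(nonzero) < 2:
            continue  # monomorphic in scope
        # pooled-scope MAF: frequency mass off the most common allele
        if min_maf > 0 and (1.0 - nonzero.max()) <= min_maf:
            continue
        usable.append(j)
    return usable


def wc_fst(gm: GenotypeMatrix, scope: str | tuple[str, str] = "global",
           max_missing: float = 0.25, min_maf: float = 0.05,
           require_all_pops: bool = True, n_permutations: int = 0,
           seed: int | None = None) -> FstResult:
    """Weir–Cockerham (1984) theta over the requested scope.

    Variance components are summed over alleles and loci (ratio of sums).
    ``scope`` is either ``"global"`` (all populations) or a pair of
    population IDs.  When ``n_permutations`` > 0, a one-sided permutation
    p-value is computed by shuffling individuals across populations.
    """
    pops = gm.population_ids() if scope == "global" else list(scope)
    if len(pops) < 2:
        raise FragdivError("F_ST needs at least two populations")
    rows_by_pop = {p: gm.individuals_of(p) for p in pops}
    usable = _apply_filters(gm, pops, rows_by_pop, max_missing, min_maf,
                            require_all_pops)
    if not usable:
        raise FragdivError("no loci pass the F_ST filters")

    def theta_for(rows_by_pop_local: dict[str, np.ndarray]) -> tuple[float, float, float, pd.Series]:
        a_sum = abc_sum = 0.0
        per_locus = {}
        for j in usable:
            inputs = _locus_inputs(gm, pops, j, rows_by_pop_local)
            if inputs is None:
                continue
            a, b, c = _wc_components(*inputs)
            denom = a + b + c
            a_sum += a
            abc_sum += denom
            per_locus[gm.loci[j]] = a / denom if denom != 0 else float("nan")
        theta = a_sum / abc_sum if abc_sum != 0 else float("nan")
        return theta, a_sum, abc_sum, pd.Series(per_locus, name="theta")

    theta, a_sum, abc_sum, per_locus = theta_for(rows_by_pop)
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        all_rows = np.concatenate([rows_by_pop[p] for p in pops])
        sizes = [len(rows_by_pop[p]) for p in pops]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(all_rows)
            shuffled = {}
            start = 0
            for p, s in zip(pops, sizes):
                shuffled[p] = perm[start:start + s]
                start += s
            t_perm = theta_for(shuffled)[0]
            if t_perm >= theta:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_permutations)
    return FstResult(theta=theta, a_sum=a_sum, abc_sum=abc_sum,
                     n_loci_used=len(usable), p_value=p_value,
                     per_locus=per_locus)


def pairwise_fst(gm: GenotypeMatrix, populations: list[str] | None = None,
                 max_missing: float = 0.25, min_maf: float = 0.05,
                 n_permutations: int = 0, seed: int | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir–Cockerham theta estimates."""
    pops = populations if populations is not None else gm.population_ids()
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            try:
                res = wc_fst(gm, (p1, p2), max_missing=max_missing,
                             min_maf=min_maf, n_permutations=n_permutations,
                             seed=seed)
                val = res.theta
            except FragdivError:
                val = float("nan")
            mat.loc[p1, p2] = val
            mat.loc[p2, p1] = val
    return mat


def linearize_fst(fst: float) -> float:
    """Linearized differentiation M = (1 - F_ST)/F_ST.

    Non-positive F_ST estimates (which the Weir–Cockerham estimator can
    produce) are undefined and returned as +inf.
    """
    if fst <= 0:
        return float("inf")
    if fst > 1:
        raise FragdivError(f"F_ST = {fst} > 1")
    return (1.0 - fst) / fst


# ---------------------------------------------------------------------------
# geography and Mantel

def great_circle_distances(metas: list[PopulationMeta]) -> pd.DataFrame:
    """Pairwise haversine great-circle distance (km, sphere R=6371)."""
    for m in metas:
        if abs(m.latitude) > 90:
            raise FragdivError(f"latitude {m.latitude} out of range")
    pops = [m.population for m in metas]
    lat = np.radians([m.latitude for m in metas])
    lon = np.radians([m.longitude for m in metas])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def mantel_test(genetic: pd.DataFrame | np.ndarray,
                geographic: pd.DataFrame | np.ndarray,
                log_distance: bool = True, n_perm: int = 10_000,
                seed: int | None = None,
                exhaustive: bool = False) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Returns the Pearson correlation ``r`` of the upper-triangle entries
    (geographic distances natural-log-transformed when ``log_distance``)
    and a one-sided permutation p-value,
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), from random simultaneous
    row/column permutations of the genetic matrix.  ``exhaustive=True``
    enumerates all n! permutations instead (small n only); the identity
    permutation then counts once, matching the add-one convention.
    """
    g = np.asarray(genetic, dtype=np.float64)
    d = np.asarray(geographic, dtype=np.float64)
    n = g.shape[0]
    if g.shape != (n, n) or d.shape != (n, n):
        raise FragdivError("Mantel matrices must be square and conformable")
    if not (np.allclose(g, g.T) and np.allclose(d, d.T)):
        raise FragdivError("Mantel matrices must be symmetric")
    if n < 4:
        raise FragdivError("Mantel test needs >= 4 populations")
    iu = np.triu_indices(n, k=1)
    if log_distance:
        if (d[iu] <= 0).any():
            raise FragdivError("zero/negative off-diagonal distance under log transform")
        d = np.log(d, where=~np.eye(n, dtype=bool), out=np.zeros_like(d))
    x = d[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(g)
    if exhaustive:
        from itertools import permutations
        exceed = 0
        total = 0
        for perm in permutations(range(n)):
            pg = g[np.ix_(perm, perm)]
            if corr(pg) >= r_obs - 1e-12:
                exceed += 1
            total += 1
        p = (1.0 + exceed) / (1.0 + total)
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if corr(g[np.ix_(perm, perm)]) >= r_obs - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# diversity table

def diversity_table(gm: GenotypeMatrix, g_copies: int = 40,
                    min_individuals: int = 5,
                    min_maf_fst: float = 0.05) -> pd.DataFrame:
    """Per-population and per-region summary table.

    Columns: individuals, loci with data, alleles, rarefied allelic
    richness (mean over loci at ``g_copies`` gene copies; NaN when the
    population is too small for the standard), expected heterozygosity
    (mean over polymorphic-capable loci), F_IS.  Region rows aggregate
    over populations with at least ``min_individuals`` individuals
    (smaller populations are excluded from regional statistics and
    flagged in the ``excluded`` column) and add a global Weir–Cockerham
    F_ST across the included populations.
    """
    records = []
    pops = gm.population_ids()
    for pop in pops:
        rows = gm.individuals_of(pop)
        n_ind = len(rows)
        ar_vals, he_vals = [], []
        n_alleles = 0
        n_loci_data = 0
        for j in range(gm.n_loci):
            counts = gm.allele_counts(j, rows)
            total = counts.sum()
            if total == 0:
                continue
            n_loci_data += 1
            n_alleles += int((counts > 0).sum())
            if total >= 2:
                he_vals.append(expected_heterozygosity(counts))
            if total >= g_copies:
                ar_vals.append(rarefied_allelic_richness(counts, g_copies))
        _, fis_mean = fis(gm, pop)
        records.append({
            "population": pop,
            "region": gm.region_of(pop),
            "n_individuals": n_ind,
            "n_loci": n_loci_data,
            "n_alleles": n_alleles,
            "A_r": float(np.mean(ar_vals)) if ar_vals else float("nan"),
            "H_e": float(np.mean(he_vals)) if he_vals else float("nan"),
            "F_IS": fis_mean,
            "excluded": n_ind < min_individuals,
        })
    table = pd.DataFrame.from_records(records)

    region_rows = []
    for region in sorted({r for r in gm.regions.values()}):
        included = [p for p in pops
                    if gm.region_of(p) == region
                    and len(gm.individuals_of(p)) >= min_individuals]
        if len(included) < 1:
            continue
        keep_inds = [i for i in gm.individuals if gm.populations[i] in included]
        sub = gm.subset(individuals=keep_inds)
        rows = np.arange(sub.n_individuals)
        he_vals, ar_vals = [], []
        n_alleles = 0
        for j in range(sub.n_loci):
            counts = sub.allele_counts(j, rows)
            total = counts.sum()
            if total == 0:
                continue
            n_alleles += int((counts > 0).sum())
            if total >= 2:
                he_vals.append(expected_heterozygosity(counts))
            if total >= g_copies:
                ar_vals.append(rarefied_allelic_richness(counts, g_copies))
        fst = float("nan")
        if len(included) >= 2:
            try:
                fst = wc_fst(sub, "global", min_maf=min_maf_fst).theta
            except FragdivError:
                pass
        region_rows.append({
            "population": f"region:{region}",
            "region": region,
            "n_individuals": sub.n_individuals,
            "n_loci": sub.n_loci,
            "n_alleles": n_alleles,
            "A_r": float(np.mean(ar_vals)) if ar_vals else float("nan"),
            "H_e": float(np.mean(he_vals)) if he_vals else float("nan"),
            "F_IS": float("nan"),
            "F_ST": fst,
            "excluded": False,
        })
    if region_rows:
        table = pd.concat([table, pd.DataFrame.from_records(region_rows)],
                          ignore_index=True)
    return table
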