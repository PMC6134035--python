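"""Linkage-disequilibrium effective-population-size estimation.

Implements the random-mating LD method for unphased diploid data:
Burrows' composite disequilibrium Delta between pairs of unlinked loci,
squared correlation r^2 with the homozygote-excess denominator
correction, the sample-size expectation E(r^2_S), and the quadratic
drift solution for Ne:

    r^2' = mean r^2 - E(r^2_S)
    Ne   = (1/3 + sqrt(1/9 - 2.76 r^2')) / (2 r^2')        (S >= 30)
    Ne   = (0.308 + sqrt(0.308^2 - 2.08 r^2')) / (2 r^2')  (S < 30)

with E(r^2_S) = 1/S + 3.19/S^2 for S >= 30 and
0.0018 + 0.907/S + 4.44/S^2 below.  S is the harmonic-mean number of
individuals genotyped at both loci over the pairs analysed.  Multi-allelic
loci are decomposed into allele-versus-rest pseudo-biallelic comparisons
weighted by allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm

from .model import MISSING, FragdivError, GenotypeMatrix, PopulationMeta


@dataclass
class LdNeEstimate:
    population: str
    r2_mean: float
    expected_r2: float
    r2_prime: float
    harmonic_s: float
    ne_hat: float  # +inf when no drift signal
    n_pairs: int
    maf_cutoff: float
    jackknife_ci: tuple[float, float] | None = None


def burrows_rsq(x: np.ndarray, y: np.ndarray) -> float:
    """Composite-disequilibrium r^2 for two biallelic dosage vectors.

    ``x`` and ``y`` hold copies (0/1/2) of a reference allele at each
    locus for the same individuals (no missing entries).  Burrows'
    composite Delta = mean(x*y)/2 - 2 p q needs no phase information;
    the denominator uses p(1-p) + (P_AA - p^2) per locus, which corrects
    for departures from Hardy-Weinberg (homozygote excess).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise FragdivError("burrows_rsq needs >= 2 individuals")
    p = x.mean() / 2.0
    q = y.mean() / 2.0
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        raise FragdivError("monomorphic locus in burrows_rsq")
    delta = (x * y).mean() / 2.0 - 2.0 * p * q
    hom_x = (x == 2).mean()
    hom_y = (y == 2).mean()
    denom = (p * (1 - p) + (hom_x - p * p)) * (q * (1 - q) + (hom_y - q * q))
    if denom <= 0:
        raise FragdivError("degenerate denominator in burrows_rsq")
    return float(delta * delta / denom)


def expected_sample_rsq(s: float) -> float:
    """Expectation of r^2 from sampling alone at harmonic sample size S.

    Piecewise weights for random mating: S >= 30 uses 1/S + 3.19/S^2,
    smaller samples use 0.0018 + 0.907/S + 4.44/S^2.  The boundary S = 30
    uses the large-sample branch.
    """
    if s <= 1:
        raise FragdivError(f"sample size S={s} must exceed 1")
    if s >= 30:
        return 1.0 / s + 3.19 / (s * s)
    return 0.0018 + 0.907 / s + 4.44 / (s * s)


def ld_ne_estimate(r2_mean: float, s: float) -> float:
    """Solve the drift relation for Ne given mean r^2 and sample size S.

    Returns +inf when the corrected r^2' is non-positive (no detectable
    drift LD) and NaN when the discriminant is negative (LD too extreme
    for the random-mating drift model).
    """
    r2p = r2_mean - expected_sample_rsq(s)
    if r2p <= 0:
        return float("inf")
    if s >= 30:
        third, coef = 1.0 / 3.0, 2.76
    else:
        third, coef = 0.308, 2.08
    disc = third * third - coef * r2p
    if disc < 0:
        return float("nan")
    return (third + np.sqrt(disc)) / (2.0 * r2p)


def _pseudo_biallelic(gm: GenotypeMatrix, rows: np.ndarray, locus_index: int,
                      maf: float) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Allele-vs-rest dosage decompositions of a locus.

    Returns (dosage vector over ``rows`` with -1 for missing, mask of
    genotyped rows, weight) per retained allele.  Biallelic loci
    contribute a single comparison (the minor allele).
    """
    col = gm.calls[rows, locus_index, :]
    ok = col[:, 0] != MISSING
    vals = col[ok]
    if vals.size == 0:
        return []
    counts = np.bincount(vals.ravel())
    total = counts.sum()
    freqs = counts / total
    alleles = np.nonzero(counts)[0]
    if len(alleles) < 2:
        return []
    out = []
    if len(alleles) == 2:
        a = alleles[np.argmin(freqs[alleles])]
        if freqs[a] <= maf or freqs[a] >= 1 - maf:
            return []
        dosage = np.full(len(rows), -1, dtype=np.int8)
        dosage[ok] = (col[ok] == a).sum(axis=1)
        return [(dosage, ok, 1.0)]
    for a in alleles:
        if freqs[a] <= maf or freqs[a] >= 1 - maf:
            continue
        dosage = np.full(len(rows), -1, dtype=np.int8)
        dosage[ok] = (col[ok] == a).sum(axis=1)
        out.append((dosage, ok, float(freqs[a])))
    return out


def ld_ne(gm: GenotypeMatrix, population: str, maf: float = 0.02,
          max_loci: int | None = None,
          seed: int | None = None,
          jackknife: bool = False) -> LdNeEstimate:
    """LD-based Ne estimate for one population.

    All locus pairs (after the MAF screen) contribute allele-vs-rest
    composite r^2 values, averaged with weights given by the product of
    the two allele weights; S is the weighted harmonic mean of per-pair
    sample sizes.  ``max_loci`` optionally subsamples loci (seeded) to
    bound the O(L^2) pair count.
    """
    rows = gm.individuals_of(population)
    if len(rows) < 3:
        raise FragdivError(f"population {population!r} too small for LD-Ne")
    loci = list(range(gm.n_loci))
    if max_loci is not None and len(loci) > max_loci:
        rng = np.random.default_rng(seed)
        loci = sorted(rng.choice(len(loci), size=max_loci, replace=False))
    decomp = {j: _pseudo_biallelic(gm, rows, j, maf) for j in loci}
    r2_vals: list[float] = []
    weights: list[float] = []
    ns: list[int] = []
    pair_loci: list[tuple[int, int]] = []
    for j1, j2 in combinations(loci, 2):
        for d1, ok1, w1 in decomp[j1]:
            for d2, ok2, w2 in decomp[j2]:
                both = ok1 & ok2
                n = int(both.sum())
                if n < 2:
                    continue
                x = d1[both]
                y = d2[both]
                if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                    continue
                try:
                    r2 = burrows_rsq(x, y)
                except FragdivError:
                    continue
                r2_vals.append(r2)
                weights.append(w1 * w2)
                ns.append(n)
                pair_loci.append((j1, j2))
    if not r2_vals:
        raise FragdivError(
            f"no usable locus pairs for population {population!r}")
    w = np.asarray(weights)
    r2_arr = np.asarray(r2_vals)
    n_arr = np.asarray(ns, dtype=np.float64)

    def estimate_from(mask: np.ndarray) -> float:
        wm = w[mask]
        r2_mean = float(np.average(r2_arr[mask], weights=wm))
        s = float(wm.sum() / np.sum(wm / n_arr[mask]))
        return ld_ne_estimate(r2_mean, s)

    r2_mean = float(np.average(r2_arr, weights=w))
    harmonic_s = float(w.sum() / np.sum(w / n_arr))
    ne = ld_ne_estimate(r2_mean, harmonic_s)
    ci = None
    if jackknife:
        touched = np.array(pair_loci)
        pseudo = []
        for l in loci:
            mask = ~((touched[:, 0] == l) | (touched[:, 1] == l))
            if mask.sum() >= 2:
                pseudo.append(estimate_from(mask))
        finite = [v for v in pseudo if np.isfinite(v)]
        if len(finite) == len(pseudo) and len(finite) >= 3 and np.isfinite(ne):
            m = len(finite)
            mean_j = np.mean(finite)
            se = np.sqrt((m - 1) / m * np.sum((np.array(finite) - mean_j) ** 2))
            ci = (max(ne - 1.96 * se, 0.0), ne + 1.96 * se)
        else:  # any delete-one estimate infinite -> unbounded above
            ci = (0.0, float("inf"))
    return LdNeEstimate(
        population=population, r2_mean=r2_mean,
        expected_r2=expected_sample_rsq(harmonic_s),
        r2_prime=r2_mean - expected_sample_rsq(harmonic_s),
        harmonic_s=harmonic_s, ne_hat=ne, n_pairs=len(r2_vals),
        maf_cutoff=maf, jackknife_ci=ci,
    )


def census_ne_regression(estimates: list[LdNeEstimate],
                         metas: list[PopulationMeta]) -> dict:
    """OLS of log Ne on log census size across populations.

    Census size is the exact count when recorded, else the geometric
    midpoint of the census category.  Populations with infinite or
    undefined Ne are excluded (their count is reported).
    """
    meta_by_pop = {m.population: m for m in metas}
    xs, ys = [], []
    n_excluded = 0
    for est in estimates:
        meta = meta_by_pop.get(est.population)
        if meta is None:
            continue
        if not np.isfinite(est.ne_hat) or est.ne_hat <= 0:
            n_excluded += 1
            continue
        xs.append(np.log(meta.census_midpoint))
        ys.append(np.log(est.ne_hat))
    if len(xs) < 4:
        raise FragdivError(
            f"need >= 4 populations with finite Ne (have {len(xs)})")
    X = sm.add_constant(np.asarray(xs))
    fit = sm.OLS(np.asarray(ys), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "f_statistic": float(fit.fvalue),
        "p_value": float(fit.f_pvalue),
        "n_populations": len(xs),
        "n_excluded_infinite": n_excluded,
    }
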