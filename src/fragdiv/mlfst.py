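"""Maximum-likelihood local F_ST under the Balding-Nichols model.

A focal population's allele counts are modelled as multinomial draws from
population frequencies that are themselves Dirichlet-distributed around
the regional mean frequencies pi with concentration (1-F)/F.  Integrating
the population frequencies out gives the Dirichlet-multinomial (compound
multinomial) likelihood

    L(F) = Gamma(A) / Gamma(A + n) * prod_i Gamma(a_i + n_i) / Gamma(a_i)

with a_i = pi_i (1-F)/F and A = sum a_i = (1-F)/F, where n_i are the focal
gene-copy counts.  Summing log L over loci and maximizing in F yields a
per-population drift estimate ("ML-F_ST") relative to the regional mean.
Large F means the focal population has drifted far from the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .model import FragdivError, GenotypeMatrix


@dataclass
class RegionalFrequencies:
    """Mean allele-frequency vectors for a region, per locus.

    ``freqs`` maps locus -> frequency vector indexed by dense allele code;
    loci monomorphic in the region are listed in ``monomorphic`` and must
    be excluded from the likelihood.  ``mode`` records the provenance:
    pooled gene copies or equal-weight population averages.
    """

    region: str
    freqs: dict[str, np.ndarray]
    monomorphic: set[str]
    mode: str
    n_copies: dict[str, int]  # regional gene copies per locus


@dataclass
class MlFstEstimate:
    population: str
    f_hat: float
    log_likelihood: float
    n_loci: int
    at_boundary: bool = False


def regional_mean_frequencies(gm: GenotypeMatrix, region: str,
                              mode: str = "pooled",
                              exclude: str | None = None) -> RegionalFrequencies:
    """Mean allele frequencies over a region's populations.

    ``pooled`` sums gene copies over all the region's individuals;
    ``pop_mean`` averages per-population frequency vectors with equal
    weight.  ``exclude`` optionally drops one (focal) population from the
    mean for sensitivity analyses.
    """
    pops = [p for p in gm.populations_of_region(region) if p != exclude]
    if len(pops) < 2:
        raise FragdivError(f"region {region!r} needs >= 2 populations with data")
    rows_by_pop = {p: gm.individuals_of(p) for p in pops}
    freqs: dict[str, np.ndarray] = {}
    monomorphic: set[str] = set()
    n_copies: dict[str, int] = {}
    for j, locus in enumerate(gm.loci):
        width = 0
        per_pop = []
        for p in pops:
            counts = gm.allele_counts(j, rows_by_pop[p])
            width = max(width, len(counts))
            per_pop.append(counts)
        if width == 0:
            monomorphic.add(locus)  # zero regional data; unusable either way
            n_copies[locus] = 0
            continue
        table = np.zeros((len(pops), width))
        for i, counts in enumerate(per_pop):
            table[i, :len(counts)] = counts
        totals = table.sum(axis=1)
        n_copies[locus] = int(table.sum())
        if mode == "pooled":
            pooled = table.sum(axis=0)
            pi = pooled / pooled.sum()
        elif mode == "pop_mean":
            with_data = totals > 0
            pi = (table[with_data] / totals[with_data, None]).mean(axis=0)
        else:
            raise FragdivError(f"unknown mode {mode!r}")
        if (pi > 0).sum() < 2:
            monomorphic.add(locus)
        freqs[locus] = pi
    return RegionalFrequencies(region=region, freqs=freqs,
                               monomorphic=monomorphic, mode=mode,
                               n_copies=n_copies)


def dirichlet_multinomial_loglik(counts: np.ndarray, pi: np.ndarray,
                                 f: float) -> float:
    """Log-likelihood of focal allele counts at one locus for a given F.

    ``counts`` are gene-copy counts aligned with the frequency vector
    ``pi``; alleles observed in the focal sample must have pi > 0.
    """
    if not 0 < f < 1:
        raise FragdivError(f"F={f} outside (0, 1)")
    counts = np.asarray(counts, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if len(counts) > len(pi):
        counts_extra = counts[len(pi):]
        if counts_extra.sum() > 0:
            raise FragdivError("observed allele beyond frequency vector support")
        counts = counts[:len(pi)]
    if ((counts > 0) & (pi <= 0)).any():
        raise FragdivError("observed allele has zero regional frequency")
    n = counts.sum()
    if n < 1:
        raise FragdivError("no focal gene copies at locus")
    a_total = (1.0 - f) / f
    alpha = pi * a_total
    obs = counts > 0
    return float(
        gammaln(a_total) - gammaln(a_total + n)
        + np.sum(gammaln(alpha[obs] + counts[obs]) - gammaln(alpha[obs]))
    )


def _profile_loglik(gm: GenotypeMatrix, focal: str,
                    freqs: RegionalFrequencies,
                    floor_absent: bool = True):
    """Per-locus (counts, pi) pairs usable in the likelihood."""
    rows = gm.individuals_of(focal)
    if len(rows) == 0:
        raise FragdivError(f"population {focal!r} has no individuals")
    usable = []
    for j, locus in enumerate(gm.loci):
        if locus in freqs.monomorphic or locus not in freqs.freqs:
            continue
        counts = gm.allele_counts(j, rows).astype(np.float64)
        if counts.sum() == 0:
            continue
        pi = freqs.freqs[locus].copy()
        width = max(len(counts), len(pi))
        c = np.zeros(width)
        c[:len(counts)] = counts
        p = np.zeros(width)
        p[:len(pi)] = pi
        novel = (c > 0) & (p <= 0)
        if novel.any():
            if not floor_absent:
                continue
            # allele seen in the focal sample but absent regionally:
            # floor at 1/(2 N_region + k) and renormalize
            k = int(novel.sum())
            floor = 1.0 / (freqs.n_copies.get(locus, 0) + k + 1)
            p[novel] = floor
            p = p / p.sum()
        usable.append((c, p))
    if not usable:
        raise FragdivError(
            f"no usable polymorphic loci for population {focal!r}")
    return usable


def _vectorized_neg_ll(usable: list[tuple[np.ndarray, np.ndarray]]):
    """Summed negative log-likelihood over loci as a fast callable of F.

    Pads the per-locus (counts, pi) pairs into matrices so each likelihood
    evaluation is a handful of vectorized gammaln calls.  Padding cells
    get pi = 1 and count = 0, which contribute exactly zero.
    """
    width = max(len(c) for c, _ in usable)
    n_loci = len(usable)
    counts = np.zeros((n_loci, width))
    pi = np.ones((n_loci, width))
    for i, (c, p) in enumerate(usable):
        counts[i, :len(c)] = c
        pi[i, :len(p)] = np.where((p <= 0) & (c <= 0), 1.0, p)
    totals = counts.sum(axis=1)
    obs = counts > 0

    def neg_ll(f: float) -> float:
        a_total = (1.0 - f) / f
        alpha = pi * a_total
        terms = np.zeros_like(counts)
        terms[obs] = gammaln(alpha[obs] + counts[obs]) - gammaln(alpha[obs])
        ll = (gammaln(a_total) - gammaln(a_total + totals)).sum() + terms.sum()
        return -float(ll)

    return neg_ll


def estimate_mlfst(gm: GenotypeMatrix, focal: str,
                   freqs: RegionalFrequencies,
                   bounds: tuple[float, float] = (1e-4, 0.999),
                   grid_points: int = 200,
                   tol: float = 1e-6) -> MlFstEstimate:
    """Maximize the summed Dirichlet-multinomial log-likelihood over F.

    A coarse log-spaced grid locates the mode's neighbourhood; bounded
    scalar minimization (golden-section style) refines it to ``tol``.
    Estimates at the search bounds are flagged ``at_boundary``.
    """
    lo, hi = bounds
    usable = _profile_loglik(gm, focal, freqs)
    neg_ll = _vectorized_neg_ll(usable)

    grid = np.exp(np.linspace(np.log(lo), np.log(hi), grid_points))
    vals = np.array([neg_ll(f) for f in grid])
    best = int(np.argmin(vals))
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, grid_points - 1)]
    res = minimize_scalar(neg_ll, bounds=(left, right), method="bounded",
                          options={"xatol": tol})
    f_hat = float(res.x)
    ll = -float(res.fun)
    # the bracket interior may still sit at a search bound
    at_boundary = f_hat <= lo * (1 + 1e-3) or f_hat >= hi * (1 - 1e-3)
    if vals[best] < res.fun:  # guard: grid point better than refinement
        f_hat, ll = float(grid[best]), -float(vals[best])
        at_boundary = best in (0, grid_points - 1)
    return MlFstEstimate(population=focal, f_hat=f_hat, log_likelihood=ll,
                         n_loci=len(usable), at_boundary=at_boundary)


def single_individual_mlfst(gm: GenotypeMatrix, freqs: RegionalFrequencies,
                            populations: list[str] | None = None,
                            seed: int | None = None,
                            bounds: tuple[float, float] = (1e-4, 0.999)
                            ) -> dict[str, MlFstEstimate]:
    """ML-F_ST from a single individual per population.

    Discriminates sample-size artifacts: each population is reduced to one
    individual's two gene copies per locus.  The individual is the first
    by input order, or a seeded random draw when ``seed`` is given.
    """
    pops = populations if populations is not None else gm.population_ids()
    rng = np.random.default_rng(seed) if seed is not None else None
    out: dict[str, MlFstEstimate] = {}
    for pop in pops:
        rows = gm.individuals_of(pop)
        if len(rows) == 0:
            continue
        pick = rows[0] if rng is None else rows[int(rng.integers(len(rows)))]
        ind = gm.individuals[pick]
        sub = gm.subset(individuals=[i for i in gm.individuals
                                     if gm.populations[i] != pop or i == ind])
        try:
            out[pop] = estimate_mlfst(sub, pop, freqs, bounds=bounds)
        except FragdivError:
            continue
    return out
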