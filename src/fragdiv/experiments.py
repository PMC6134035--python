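"""Reproducibility experiments: each function runs one end-to-end check
of the package on synthetic data and returns the measured quantities.

These are the verification experiments the package ships with — oracle
equivalences, closed-form checks and parameter-recovery runs — shared by
the test suite and the reproduction script.  All randomness flows through
an explicit seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .abc import (
    AbcDesign,
    PriorSpec,
    abc_model_choice,
    abc_parameter_posterior,
    generate_reference_table,
    posterior_summary,
    simulate_one,
)
from .coalescent import pairwise_tmrca, simulate_single_population
from .ldne import expected_sample_rsq, ld_ne, ld_ne_estimate
from .mlfst import estimate_mlfst, regional_mean_frequencies
from .model import MISSING
from .popgen import expected_heterozygosity, rarefied_allelic_richness
from .radssr import call_dataset, clone_summary, detect_clones
from .synthetic import (
    SyntheticStudyConfig,
    make_ssr_allele_sequences,
    make_study_fixture,
    simulate_balding_nichols,
    simulate_rad_reads,
    simulate_wright_fisher_ld,
)


# ---------------------------------------------------------------------------
# study-fixture bookkeeping

def study_fixture_summary(seed: int = 0) -> dict:
    """Clone percentage and transition:transversion locus ratio of the
    default synthetic study, recomputed from the generated data."""
    matrices, metas, _ = make_study_fixture(SyntheticStudyConfig(seed=seed))
    pcr = matrices["ssr_length"]
    groups = detect_clones(pcr, min_shared_loci=min(10, pcr.n_loci))
    clones = clone_summary(groups, pcr.n_individuals)
    n_ti = matrices["snp_ti"].n_loci
    n_tv = matrices["snp_tv"].n_loci
    return {
        "n_individuals": clones["n_individuals"],
        "n_clones": clones["n_clones"],
        "clone_percent": round(clones["percent_clonal"], 1),
        "titv_per_100": round(100.0 * n_ti / n_tv),
        "n_populations_fragmented": sum(m.region == "fragmented" for m in metas),
        "n_populations_continuous": sum(m.region == "continuous" for m in metas),
    }


# ---------------------------------------------------------------------------
# ML-F_ST

def mlfst_beta_integral_max_dev(f_grid=(0.01, 0.05, 0.1, 0.3, 0.5, 0.7, 0.9),
                                seed: int = 0) -> float:
    """Largest |likelihood - numerical Beta integral| over biallelic cases."""
    from scipy.integrate import quad
    from scipy.special import comb
    from scipy.stats import beta as beta_dist

    from .mlfst import dirichlet_multinomial_loglik

    rng = np.random.default_rng(seed)
    worst = 0.0
    for f in f_grid:
        for _ in range(5):
            n0 = int(rng.integers(0, 12))
            n1 = int(rng.integers(0, 12))
            if n0 + n1 == 0:
                continue
            pi0 = float(rng.uniform(0.1, 0.9))
            a_total = (1 - f) / f
            dist = beta_dist(pi0 * a_total, (1 - pi0) * a_total)
            val, _ = quad(lambda p: comb(n0 + n1, n0) * p ** n0
                          * (1 - p) ** n1 * dist.pdf(p), 0, 1, limit=200)
            got = comb(n0 + n1, n0) * np.exp(
                dirichlet_multinomial_loglik([n0, n1], [pi0, 1 - pi0], f))
            worst = max(worst, abs(got - val))
    return worst


def mlfst_recovery_rate(n_replicates: int = 100, generating_f: float = 0.10,
                        n_loci: int = 500, n_per_pop: int = 30,
                        n_pops: int = 12, band=(0.08, 0.12),
                        seed: int = 0) -> float:
    """Fraction of replicates whose ML-F_ST lands inside ``band``.

    Each replicate draws a ``n_pops``-population region under the
    Balding-Nichols model at the generating F and estimates the focal
    population's F against the pooled regional mean.
    """
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100_003 + rep)
        freqs = [rng.dirichlet([1.0] * 4) for _ in range(n_loci)]
        gm = simulate_balding_nichols(freqs, [generating_f] * n_pops,
                                      [n_per_pop] * n_pops, seed=rng)
        rf = regional_mean_frequencies(gm, "region")
        est = estimate_mlfst(gm, "P1", rf)
        hits += band[0] <= est.f_hat <= band[1]
    return hits / n_replicates


# ---------------------------------------------------------------------------
# rarefaction

def _partitions(n: int, largest: int | None = None):
    """All multisets of positive integers summing to n."""
    if largest is None:
        largest = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, largest), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def rarefaction_exhaustive_max_dev(max_copies: int = 12) -> float:
    """Largest deviation from brute-force enumeration over every allele
    configuration with at most ``max_copies`` gene copies."""
    worst = 0.0
    for n in range(1, max_copies + 1):
        for counts in _partitions(n):
            copies = [a for a, c in enumerate(counts) for _ in range(c)]
            for g in range(1, n + 1):
                brute = np.mean([
                    len({copies[i] for i in sub})
                    for sub in itertools.combinations(range(n), g)
                ])
                got = rarefied_allelic_richness(list(counts), g)
                worst = max(worst, abs(got - brute))
    return worst


# ---------------------------------------------------------------------------
# coalescent calibrations

def tmrca_check(ne: int = 500, n_replicates: int = 10_000,
                seed: int = 0) -> dict:
    """Mean pairwise coalescence time vs the Kingman expectation 2Ne."""
    times = pairwise_tmrca(ne, n_replicates, seed=seed)
    se = float(times.std() / np.sqrt(n_replicates))
    return {
        "mean_tmrca": float(times.mean()),
        "expected": 2.0 * ne,
        "z": float((times.mean() - 2 * ne) / se),
    }


def smm_equilibrium_check(ne: int = 1000, mu: float = 1e-3,
                          n_loci: int = 2000, sample: int = 25,
                          seed: int = 0) -> dict:
    """Stepwise-mutation equilibrium heterozygosity vs 1 - 1/sqrt(1+8 Ne mu)."""
    gm = simulate_single_population(ne, sample, n_loci, marker="ssr_length",
                                    mu=mu, seed=seed)
    hes = [expected_heterozygosity(gm.allele_counts(j))
           for j in range(gm.n_loci)]
    return {
        "mean_he": float(np.mean(hes)),
        "expected": 1.0 - 1.0 / np.sqrt(1.0 + 8 * ne * mu),
    }


# ---------------------------------------------------------------------------
# LD-Ne

def ldne_closed_form(r2_prime: float = 0.01, s: float = 100.0) -> float:
    return ld_ne_estimate(r2_prime + expected_sample_rsq(s), s)


def wright_fisher_ldne_median(true_ne: int = 50, sample: int = 50,
                              n_loci: int = 200, generations: int = 80,
                              n_replicates: int = 20, seed: int = 0) -> float:
    """Median LD-Ne estimate over Wright-Fisher replicates at known Ne."""
    nes = []
    for rep in range(n_replicates):
        gm = simulate_wright_fisher_ld(true_ne, sample, n_loci, generations,
                                       mu=1e-3, seed=seed * 7919 + rep)
        nes.append(ld_ne(gm, "wf", maf=0.05).ne_hat)
    return float(np.median(nes))


# ---------------------------------------------------------------------------
# RAD-SSR round trip

def radssr_concordance(seed: int = 0, coverage: float = 40.0) -> dict:
    """Error-free read simulation -> caller concordance with the truth."""
    rng = np.random.default_rng(seed)
    freqs = [rng.dirichlet([1.0] * 5) for _ in range(25)]
    truth = simulate_balding_nichols(freqs, [0.08] * 5, [10] * 5, seed=rng,
                                     marker_kind="ssr_id")
    seqs = make_ssr_allele_sequences(truth, seed=rng)
    bundles = simulate_rad_reads(truth, seqs, coverage_mean=coverage,
                                 error_rate=0.0, seed=rng)
    called, registry = call_dataset(bundles, populations=truth.populations)
    ind_idx = {i: k for k, i in enumerate(called.individuals)}
    loc_idx = {l: j for j, l in enumerate(called.loci)}
    checked = matched = 0
    for i, ind in enumerate(truth.individuals):
        for j, locus in enumerate(truth.loci):
            if locus not in loc_idx or ind not in ind_idx:
                continue
            got = called.calls[ind_idx[ind], loc_idx[locus]]
            if got[0] == MISSING:
                continue
            got_seqs = {registry.sequences(locus)[int(a)] for a in got}
            want_seqs = {seqs[locus][int(a)] for a in truth.calls[i, j]}
            checked += 1
            matched += got_seqs == want_seqs
    return {"n_calls": checked, "concordance": matched / checked}


# ---------------------------------------------------------------------------
# ABC experiments

def default_abc_design(n_loci: int = 15) -> AbcDesign:
    pops = ["F1", "F2", "F3", "F4"]
    return AbcDesign(focal_pops=pops, outgroup="OG",
                     sample_sizes={p: 6 for p in pops + ["OG"]},
                     marker="ssr_length", n_loci=n_loci)


def draw_bottleneck_truth(rng: np.random.Generator,
                          ne_br: float | None = None) -> dict:
    """Parameters of a strong recent-bottleneck history (scenario 1):
    large historic size, small current size, recent bottleneck time."""
    return {
        "tb1": float(rng.uniform(10, 50)),
        "t1": float(rng.uniform(100, 600)),
        "t2": float(rng.uniform(700, 1500)),
        "ne_br": float(rng.uniform(3000, 8000)) if ne_br is None else ne_br,
        "ne_sc": float(rng.uniform(3000, 9000)),
        "ne_current": float(np.exp(rng.uniform(np.log(50), np.log(200)))),
        "mu": float(np.exp(rng.uniform(np.log(1e-4), np.log(1e-3)))),
    }


def abc_experiment(n_sims_per_scenario: int = 5000, n_pseudo: int = 20,
                   retain_fraction: float = 0.01, seed: int = 0,
                   known_ne_br: float = 5000.0,
                   design: AbcDesign | None = None,
                   priors: PriorSpec | None = None) -> dict:
    """Scenario-choice recovery and NeBr interval coverage.

    Builds one reference table of ``n_sims_per_scenario`` simulations for
    scenarios 1 and 2; then, for each of ``n_pseudo`` pseudo-observed
    datasets simulated under scenario 1 with a strong recent bottleneck,
    records whether scenario 1 receives the higher posterior probability
    and whether the regression-adjusted 0.05-0.95 interval for the
    historic focal size covers the known value ``known_ne_br``.
    """
    design = design or default_abc_design()
    priors = priors or PriorSpec()
    table = generate_reference_table(["1", "2"], design, priors,
                                     n_sims_per_scenario, seed=seed)
    table_s1 = table[table["scenario"] == "1"]
    rng = np.random.default_rng(seed + 1)
    correct = covered = 0
    posteriors = []
    for _ in range(n_pseudo):
        params = draw_bottleneck_truth(rng, ne_br=known_ne_br)
        obs = simulate_one("1", design, params, rng)
        res = abc_model_choice(obs, table, retain_fraction=retain_fraction)
        posteriors.append(res.posteriors["1"])
        correct += res.posteriors["1"] > res.posteriors["2"]
        samples = abc_parameter_posterior(obs, table_s1, ["ne_br"],
                                          retain_fraction=retain_fraction,
                                          priors=priors)
        summary = posterior_summary(samples, "ne_br")
        covered += summary["low"] <= known_ne_br <= summary["high"]
    return {
        "n_pseudo": n_pseudo,
        "scenario1_recovery_rate": correct / n_pseudo,
        "mean_posterior_scenario1": float(np.mean(posteriors)),
        "ne_br_coverage_rate": covered / n_pseudo,
    }
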