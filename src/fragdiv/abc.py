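"""Approximate Bayesian computation: scenario choice and parameter posteriors.

The workflow mirrors rejection-ABC with regression adjustments:

1. draw parameters from priors and simulate reference tables of summary
   statistics per demographic scenario (:func:`generate_reference_table`);
2. estimate scenario posterior probabilities by multinomial logistic
   regression on the retained fraction of simulations closest to the
   observed statistics (:func:`abc_model_choice`);
3. estimate parameter posteriors for the chosen scenario by local-linear
   regression adjustment with Epanechnikov kernel weights
   (:func:`abc_parameter_posterior`);
4. pool evidence across marker sets by multiplying kernel density
   estimates of the per-marker posteriors (:func:`combine_posteriors`);
5. convert event times from generations to calendar years with a
   generation-time range (:func:`calibrate_event_times`).

Summary statistics are computed per marker set; allele-length statistics
are only defined for length-coded microsatellites and are refused for
identity-coded SSR and SNP data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalescent import ScenarioSpec, simulate_scenario
from .model import MISSING, FragdivError, GenotypeMatrix
from .popgen import expected_heterozygosity, wc_fst

log = logging.getLogger("fragdiv.abc")


# ---------------------------------------------------------------------------
# priors

@dataclass
class PriorSpec:
    """Uniform / log-uniform prior ranges per parameter.

    ``ranges`` maps parameter name -> (low, high, dist) with dist in
    {"uniform", "loguniform"}.  Draws enforce the event ordering
    tb1 <= t1 <= t2 by rejection.  Defaults bracket post-glacial
    divergence at a handful of hundreds to thousands of generations with
    current population sizes down to tens of individuals.
    """

    ranges: dict[str, tuple[float, float, str]] = field(default_factory=lambda: {
        "t2": (100.0, 2000.0, "uniform"),
        "t1": (10.0, 1000.0, "uniform"),
        "tb1": (10.0, 1000.0, "uniform"),
        "ne_br": (100.0, 10000.0, "uniform"),
        "ne_sc": (100.0, 10000.0, "uniform"),
        "ne_current": (50.0, 2000.0, "loguniform"),
        "ne_colonization": (50.0, 2000.0, "loguniform"),
        "mu": (1e-4, 1e-3, "loguniform"),
    })

    def __post_init__(self) -> None:
        for name, (low, high, dist) in self.ranges.items():
            if not (0 < low < high and np.isfinite(high)):
                raise FragdivError(f"bad prior range for {name}: ({low}, {high})")
            if dist not in ("uniform", "loguniform"):
                raise FragdivError(f"bad prior dist for {name}: {dist}")

    def support(self, name: str) -> tuple[float, float]:
        low, high, _ = self.ranges[name]
        return (low, high)

    def draw_one(self, name: str, rng: np.random.Generator) -> float:
        low, high, dist = self.ranges[name]
        if dist == "loguniform":
            return float(np.exp(rng.uniform(np.log(low), np.log(high))))
        return float(rng.uniform(low, high))

    def draw(self, rng: np.random.Generator, need_order: bool = True,
             max_tries: int = 10_000) -> dict[str, float]:
        for _ in range(max_tries):
            params = {name: self.draw_one(name, rng) for name in self.ranges}
            if not need_order:
                return params
            if params.get("tb1", 0.0) <= params.get("t1", np.inf) <= params["t2"]:
                return params
        raise FragdivError("could not draw ordered event times from the prior")


# ---------------------------------------------------------------------------
# summary statistics

def allele_size_variance(gm: GenotypeMatrix, locus_index: int,
                         rows: np.ndarray) -> float:
    """Variance of allele size (repeat count) among sampled gene copies."""
    if gm.marker_kinds[locus_index] != "ssr_length":
        raise FragdivError(
            "allele-size statistics are only defined for length-coded SSRs")
    col = gm.calls[rows, locus_index, :]
    vals = col[col != MISSING].astype(np.float64)
    if vals.size < 2:
        return 0.0
    return float(vals.var(ddof=1))


def summary_stats(gm: GenotypeMatrix, marker: str) -> pd.Series:
    """Fixed-order summary-statistic vector for one marker set.

    Statistics: mean alleles per locus; mean within-population expected
    heterozygosity; global Weir-Cockerham F_ST over all populations; mean
    pairwise F_ST between the two regions' populations; and, for
    length-coded SSRs only, the mean within-population allele-size
    variance.  No missing-data or MAF filters are applied (simulated data
    are complete); permutations are never run (deterministic).
    """
    if marker not in ("ssr_length", "ssr_id", "snp"):
        raise FragdivError(f"unknown marker {marker!r}")
    pops = gm.population_ids()
    if len(pops) < 2:
        raise FragdivError("summary statistics need >= 2 populations")
    rows_by_pop = {p: gm.individuals_of(p) for p in pops}
    all_rows = np.arange(gm.n_individuals)

    n_alleles = np.mean([gm.n_alleles(j) for j in range(gm.n_loci)])

    he_by_pop = []
    for p in pops:
        vals = []
        for j in range(gm.n_loci):
            counts = gm.allele_counts(j, rows_by_pop[p])
            if counts.sum() >= 2:
                vals.append(expected_heterozygosity(counts))
        if vals:
            he_by_pop.append(np.mean(vals))
    he_mean = float(np.mean(he_by_pop)) if he_by_pop else 0.0

    def theta_or_zero(scope) -> float:
        try:
            t = wc_fst(gm, scope, max_missing=1.0, min_maf=0.0,
                       require_all_pops=False).theta
            return float(t) if np.isfinite(t) else 0.0
        except FragdivError:
            return 0.0

    fst_global = theta_or_zero("global")

    regions: dict[str, list[str]] = {}
    for p in pops:
        regions.setdefault(gm.region_of(p), []).append(p)
    fst_between = 0.0
    if len(regions) == 2:
        (r1, pops1), (r2, pops2) = regions.items()
        vals = [theta_or_zero((a, b)) for a in pops1 for b in pops2]
        fst_between = float(np.mean(vals)) if vals else 0.0

    stats = {
        "mean_alleles": float(n_alleles),
        "mean_he": he_mean,
        "fst_global": fst_global,
        "fst_between_regions": fst_between,
    }
    if marker == "ssr_length":
        var_by_pop = []
        for p in pops:
            vals = [allele_size_variance(gm, j, rows_by_pop[p])
                    for j in range(gm.n_loci)]
            var_by_pop.append(np.mean(vals))
        stats["mean_allele_size_var"] = float(np.mean(var_by_pop))
    return pd.Series(stats)


# ---------------------------------------------------------------------------
# reference tables

@dataclass
class AbcDesign:
    """Sampling design shared by every simulation in an ABC run."""

    focal_pops: list[str]
    outgroup: str
    sample_sizes: dict[str, int]
    marker: str
    n_loci: int


def make_scenario(scenario: str, design: AbcDesign,
                  params: dict[str, float]) -> ScenarioSpec:
    """Bind drawn parameters into a :class:`ScenarioSpec`."""
    common = dict(
        focal_pops=design.focal_pops,
        outgroup=design.outgroup,
        sample_sizes=design.sample_sizes,
        t1=params["t1"], t2=params["t2"],
        ne_br=params["ne_br"], ne_sc=params["ne_sc"],
    )
    if scenario == "1":
        return ScenarioSpec(scenario="1", tb1=params["tb1"],
                            ne_current=params["ne_current"], **common)
    if scenario == "1b":
        per_pop = {p: params[f"ne_current_{p}"] for p in design.focal_pops}
        return ScenarioSpec(scenario="1b", tb1=params["tb1"],
                            ne_current=per_pop, **common)
    if scenario == "2":
        return ScenarioSpec(scenario="2",
                            ne_current=params["ne_current"],
                            ne_colonization=params["ne_colonization"],
                            **common)
    raise FragdivError(f"unknown scenario {scenario!r}")


def simulate_one(scenario: str, design: AbcDesign, params: dict[str, float],
                 rng: np.random.Generator) -> pd.Series:
    spec = make_scenario(scenario, design, params)
    mu = params.get("mu") if design.marker != "snp" else None
    gm = simulate_scenario(spec, design.marker, design.n_loci, mu=mu, seed=rng)
    return summary_stats(gm, design.marker)


def generate_reference_table(scenarios: list[str], design: AbcDesign,
                             priors: PriorSpec, n_sims: int,
                             seed: int | np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Simulate ``n_sims`` parameter draws per scenario.

    Returns a DataFrame with a ``scenario`` column, one column per drawn
    parameter and ``stat:``-prefixed columns for the summary statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for scenario in scenarios:
        for _ in range(n_sims):
            params = priors.draw(rng)
            if scenario == "1b":
                for p in design.focal_pops:
                    params[f"ne_current_{p}"] = priors.draw_one("ne_current", rng)
            stats = simulate_one(scenario, design, params, rng)
            row = {"scenario": scenario, **params}
            row.update({f"stat:{k}": v for k, v in stats.items()})
            records.append(row)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# rejection + regression machinery

@dataclass
class AbcResult:
    posteriors: dict[str, float]
    retain_fraction: float
    n_retained: int
    method: str  # "logistic" or "rejection"


def _stat_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("stat:")]


def _standardize(table: pd.DataFrame, observed: pd.Series
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """MAD-standardize simulated and observed statistics; drop zero-MAD."""
    cols = _stat_columns(table)
    sims = table[cols].to_numpy(dtype=np.float64)
    obs = np.array([observed[c.removeprefix("stat:")] for c in cols])
    med = np.median(sims, axis=0)
    mad = np.median(np.abs(sims - med), axis=0)
    keep = mad > 0
    if not keep.any():
        raise FragdivError("every summary statistic has zero spread")
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        log.warning("dropping zero-MAD statistics: %s", dropped)
    cols = [c for c, k in zip(cols, keep) if k]
    return sims[:, keep] / mad[keep], obs[keep] / mad[keep], cols


def abc_model_choice(observed: pd.Series, table: pd.DataFrame,
                     retain_fraction: float = 0.01) -> AbcResult:
    """Scenario posterior probabilities by logistic regression.

    Euclidean distances on MAD-standardized statistics select the closest
    ``retain_fraction`` of all simulations; a multinomial logistic
    regression of scenario label on statistics within the retained set is
    evaluated at the observed vector.  Falls back to retained-count
    proportions when the regression is degenerate (e.g. one scenario
    retained).
    """
    scenarios = sorted(table["scenario"].unique())
    if len(scenarios) < 2:
        raise FragdivError("model choice needs >= 2 scenarios")
    sims, obs, _cols = _standardize(table, observed)
    dist = np.sqrt(((sims - obs) ** 2).sum(axis=1))
    n_retain = max(int(np.ceil(retain_fraction * len(table))), 1)
    if n_retain < 100:
        log.warning("only %d simulations retained; posteriors will be noisy",
                    n_retain)
    idx = np.argsort(dist)[:n_retain]
    labels = table["scenario"].to_numpy()[idx]
    x = sims[idx]
    present = sorted(set(labels))
    if len(present) < 2:
        post = {s: float(s == present[0]) for s in scenarios}
        return AbcResult(post, retain_fraction, n_retain, "rejection")
    try:
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(max_iter=1000)
        model.fit(x - obs, labels)
        probs = model.predict_proba((obs - obs)[None, :])[0]
        post = {s: 0.0 for s in scenarios}
        for cls, p in zip(model.classes_, probs):
            post[cls] = float(p)
        method = "logistic"
    except Exception:  # pragma: no cover - degenerate fits
        counts = {s: float((labels == s).sum()) / n_retain for s in scenarios}
        post, method = counts, "rejection"
    return AbcResult(post, retain_fraction, n_retain, method)


def abc_parameter_posterior(observed: pd.Series, table: pd.DataFrame,
                            parameters: list[str],
                            retain_fraction: float = 0.01,
                            priors: PriorSpec | None = None) -> pd.DataFrame:
    """Regression-adjusted posterior samples for the chosen scenario.

    Retains the closest fraction of simulations, weights them with an
    Epanechnikov kernel in distance, adjusts each parameter by a weighted
    local-linear regression on (stats - observed), and clips adjusted
    values to the prior support when priors are given.  Returns a
    DataFrame of adjusted samples with a ``weight`` column.
    """
    sims, obs, _cols = _standardize(table, observed)
    dist = np.sqrt(((sims - obs) ** 2).sum(axis=1))
    n_retain = max(int(np.ceil(retain_fraction * len(table))), 2)
    idx = np.argsort(dist)[:n_retain]
    d = dist[idx]
    d_max = d.max() if d.max() > 0 else 1.0
    weights = np.maximum(1.0 - (d / d_max) ** 2, 1e-12)  # Epanechnikov
    x = sims[idx] - obs  # regression covariates centred on the observation
    out: dict[str, np.ndarray] = {}
    for param in parameters:
        theta = table[param].to_numpy(dtype=np.float64)[idx]
        xw = np.concatenate([np.ones((len(idx), 1)), x], axis=1)
        w_sqrt = np.sqrt(weights)
        try:
            beta, *_ = np.linalg.lstsq(xw * w_sqrt[:, None],
                                       theta * w_sqrt, rcond=None)
            adjusted = theta - x @ beta[1:]
        except np.linalg.LinAlgError:  # rank-deficient: plain rejection
            log.warning("rank-deficient adjustment for %s; returning "
                        "unadjusted rejection samples", param)
            adjusted = theta
        if priors is not None:
            base = param.split(":")[0]
            name = base if base in priors.ranges else (
                "ne_current" if base.startswith("ne_current") else None)
            if name is not None:
                low, high = priors.support(name)
                adjusted = np.clip(adjusted, low, high)
        out[param] = adjusted
    out["weight"] = weights / weights.sum()
    return pd.DataFrame(out)


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float) -> float:
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q, cdf, v))


def posterior_summary(samples: pd.DataFrame, parameter: str,
                      interval: tuple[float, float] = (0.05, 0.95)) -> dict:
    """Mode (weighted KDE peak) and quantile interval for one parameter."""
    v = samples[parameter].to_numpy(dtype=np.float64)
    w = samples["weight"].to_numpy(dtype=np.float64)
    if np.ptp(v) == 0:
        peak = float(v[0])
    else:
        kde = gaussian_kde(v, weights=w)
        grid = np.linspace(v.min(), v.max(), 512)
        peak = float(grid[np.argmax(kde(grid))])
    return {
        "peak": peak,
        "low": weighted_quantile(v, w, interval[0]),
        "high": weighted_quantile(v, w, interval[1]),
    }


# ---------------------------------------------------------------------------
# cross-marker combination

def combine_posteriors(per_marker: list[tuple[np.ndarray, np.ndarray]],
                       support: tuple[float, float],
                       n_grid: int = 512) -> dict:
    """Pool independent per-marker posteriors for a shared parameter.

    ``per_marker`` holds (samples, weights) pairs.  Each marker's
    weighted kernel density is evaluated on a common grid over the prior
    support; the combined density is proportional to the product
    (independent-evidence pooling), renormalized to integrate to one.
    Returns the grid, combined density, its peak and 0.05-0.95 interval.
    """
    if len(per_marker) < 2:
        raise FragdivError("combine_posteriors needs >= 2 marker posteriors")
    grid = np.linspace(support[0], support[1], n_grid)
    log_product = np.zeros(n_grid)
    for samples, weights in per_marker:
        v = np.asarray(samples, dtype=np.float64)
        w = np.asarray(weights, dtype=np.float64)
        if np.ptp(v) == 0:
            dens = np.where(np.abs(grid - v[0]) ==
                            np.min(np.abs(grid - v[0])), 1.0, 1e-300)
        else:
            dens = np.maximum(gaussian_kde(v, weights=w)(grid), 1e-300)
        log_product += np.log(dens)
    peak_log = log_product.max()
    if peak_log < np.log(1e-12):  # no grid point supported by every marker
        raise FragdivError("per-marker posteriors do not overlap")
    log_product -= peak_log
    density = np.exp(log_product)
    area = np.trapezoid(density, grid)
    if area <= 0 or not np.isfinite(area):
        raise FragdivError("per-marker posteriors do not overlap")
    density = density / area
    cdf = np.concatenate([[0.0], np.cumsum(
        (density[1:] + density[:-1]) / 2 * np.diff(grid))])
    cdf = cdf / cdf[-1]
    return {
        "grid": grid,
        "density": density,
        "peak": float(grid[np.argmax(density)]),
        "low": float(np.interp(0.05, cdf, grid)),
        "high": float(np.interp(0.95, cdf, grid)),
    }


def calibrate_event_times(generations: float,
                          gen_time_range: tuple[float, float]
                          ) -> tuple[float, float]:
    """Convert an event time in generations to calendar years.

    With a generation-time range (low, high) in years, an event at ``g``
    generations dates to (g*low, g*high) years before present.
    """
    low, high = gen_time_range
    if generations < 0:
        raise FragdivError("generations must be >= 0")
    if not 0 < low <= high:
        raise FragdivError("generation-time range must satisfy 0 < low <= high")
    return (generations * low, generations * high)
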