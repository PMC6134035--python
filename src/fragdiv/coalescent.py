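"""Backward-in-time coalescent simulator for divergence-tree scenarios.

Simulates unlinked loci under a Kingman coalescent with piecewise-constant
diploid population sizes and no migration, for three demographic
histories of a focal (fragmented) region diverging from an out-group
(continuous) region:

Scenario ``1``
    focal populations split from an ancestral focal population of size
    ``ne_br`` at ``t1`` generations ago, persist at ``ne_br`` and crash to
    a single shared current size at the recent bottleneck time ``tb1``;
    the focal and out-group lineages merge at ``t2`` (ancestral size
    ``ne_sc``).
Scenario ``1b``
    as scenario 1 but each focal population has its own current size.
Scenario ``2``
    the bottleneck happens at colonization instead: the ancestral focal
    population is small (``ne_colonization``) from ``t2`` onward and the
    focal populations stay at their current sizes from ``t1`` to the
    present; there is no recent bottleneck event.

Mutation models: stepwise single-repeat mutations for microsatellites
(each mutation also mints a distinct sequence identity, so loci can be
scored by repeat length or by identity), and a single uniformly-placed
mutation for SNP loci (ascertained to be polymorphic in the sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FragdivError, GenotypeMatrix

#: Root repeat count for length-coded microsatellites; comfortably above
#: the number of net steps a locus accumulates at realistic mutation rates.
ROOT_REPEAT_COUNT = 100


@dataclass
class ScenarioSpec:
    """One demographic history (times in generations, sizes diploid)."""

    scenario: str  # "1", "1b" or "2"
    focal_pops: list[str]
    outgroup: str
    sample_sizes: dict[str, int]  # diploid individuals per population
    t1: float
    t2: float
    ne_br: float
    ne_sc: float
    tb1: float | None = None
    ne_current: float | dict[str, float] | None = None
    ne_colonization: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("1", "1b", "2"):
            raise FragdivError(f"unknown scenario {self.scenario!r}")
        if not self.focal_pops:
            raise FragdivError("at least one focal population required")
        if not 0 < self.t1 <= self.t2:
            raise FragdivError("need 0 < t1 <= t2")
        for pop in self.focal_pops + [self.outgroup]:
            if self.sample_sizes.get(pop, 0) < 1:
                raise FragdivError(f"sample size for {pop!r} must be >= 1")
        if self.scenario in ("1", "1b"):
            if self.tb1 is None or not 0 < self.tb1 <= self.t1:
                raise FragdivError("scenarios 1/1b need 0 < tb1 <= t1")
            if self.ne_current is None:
                raise FragdivError("scenarios 1/1b need current sizes")
        else:
            if self.tb1 is not None:
                raise FragdivError("scenario 2 has no recent bottleneck event")
            if self.ne_colonization is None:
                raise FragdivError("scenario 2 needs ne_colonization")
            if self.ne_current is None:
                raise FragdivError("scenario 2 needs current sizes")
        for size in self._all_sizes():
            if size < 2:
                raise FragdivError(f"population size {size} must be >= 2")

    def _all_sizes(self) -> list[float]:
        sizes = [self.ne_br, self.ne_sc]
        if isinstance(self.ne_current, dict):
            sizes.extend(self.ne_current.values())
        elif self.ne_current is not None:
            sizes.append(self.ne_current)
        if self.ne_colonization is not None:
            sizes.append(self.ne_colonization)
        return sizes

    def current_size(self, pop: str) -> float:
        if isinstance(self.ne_current, dict):
            return float(self.ne_current[pop])
        return float(self.ne_current)


# ---------------------------------------------------------------------------
# tree machinery

@dataclass
class Tree:
    """Binary coalescent tree over 2N sampled gene copies.

    ``parent[i]`` / ``time[i]`` give each node's parent (-1 at the root)
    and age in generations; leaves are nodes ``0..n_leaves-1`` at age 0.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        lengths = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        lengths[has_parent] = (self.time[self.parent[has_parent]]
                               - self.time[has_parent])
        return lengths

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def leaves_under(self, node: int) -> np.ndarray:
        """Leaf indices descending from (and including) ``node``."""
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        stack = [node]
        out = []
        while stack:
            x = stack.pop()
            kids = children.get(x)
            if kids:
                stack.extend(kids)
            elif x < self.n_leaves:
                out.append(x)
        return np.array(sorted(out), dtype=np.intp)

    def preorder(self) -> list[int]:
        children: dict[int, list[int]] = {}
        root = -1
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
            else:
                root = i
        order = []
        stack = [root]
        while stack:
            x = stack.pop()
            order.append(x)
            stack.extend(children.get(x, []))
        return order


def _simulate_tree(pop_of_leaf: list[str], epochs, rng: np.random.Generator) -> Tree:
    """Coalesce leaves through a list of epochs.

    ``epochs`` is a list of (end_time, sizes, merges) where ``sizes`` maps
    population label -> diploid size during the epoch, and ``merges`` maps
    population labels to be absorbed -> destination label at the epoch's
    *start*.  The final epoch has end_time = inf.
    """
    n = len(pop_of_leaf)
    parent = [-1] * (2 * n - 1)
    time = [0.0] * (2 * n - 1)
    lineages: dict[str, list[int]] = {}
    for i, pop in enumerate(pop_of_leaf):
        lineages.setdefault(pop, []).append(i)
    next_node = n
    t = 0.0
    for end_time, sizes, merges in epochs:
        for src, dst in merges.items():
            if src in lineages:
                lineages.setdefault(dst, []).extend(lineages.pop(src))
        while True:
            rates = []
            total = 0.0
            for pop, lin in lineages.items():
                k = len(lin)
                if k >= 2:
                    rate = k * (k - 1) / 2.0 / (2.0 * sizes[pop])
                    rates.append((pop, rate))
                    total += rate
            if total == 0.0:
                t = end_time
                break
            wait = -np.log(rng.random()) / total
            if t + wait >= end_time:
                t = end_time
                break
            t += wait
            u = rng.random() * total
            acc = 0.0
            for pop, rate in rates:
                acc += rate
                if u <= acc:
                    break
            lin = lineages[pop]
            k = len(lin)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i
            a = lin.pop(i)  # i > j so pops stay valid
            b = lin.pop(j)
            node = next_node
            next_node += 1
            parent[a] = node
            parent[b] = node
            time[node] = t
            lin.append(node)
        if sum(len(l) for l in lineages.values()) == 1:
            break
    if sum(len(l) for l in lineages.values()) != 1:
        raise FragdivError("coalescent did not reach a single root")
    return Tree(parent=np.array(parent[:next_node], dtype=np.intp),
                time=np.array(time[:next_node]), n_leaves=n)


def _scenario_epochs(spec: ScenarioSpec):
    sizes_now: dict[str, float] = {spec.outgroup: spec.ne_sc}
    for pop in spec.focal_pops:
        sizes_now[pop] = spec.current_size(pop)
    anc = "__anc_focal__"
    root = "__root__"
    merge_t1 = {pop: anc for pop in spec.focal_pops}
    merge_t2 = {anc: root, spec.outgroup: root}
    if spec.scenario in ("1", "1b"):
        sizes_mid = dict(sizes_now)
        for pop in spec.focal_pops:
            sizes_mid[pop] = spec.ne_br
        return [
            (spec.tb1, sizes_now, {}),
            (spec.t1, sizes_mid, {}),
            (spec.t2, {**sizes_mid, anc: spec.ne_br}, merge_t1),
            (float("inf"), {root: spec.ne_sc}, merge_t2),
        ]
    return [
        (spec.t1, sizes_now, {}),
        (spec.t2, {**sizes_now, anc: spec.ne_colonization}, merge_t1),
        (float("inf"), {root: spec.ne_sc}, merge_t2),
    ]


def simulate_tree(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[Tree, list[tuple[str, str]]]:
    """One coalescent tree for the scenario; returns the tree and the
    (population, individual) label of each pair of leaves."""
    pop_of_leaf: list[str] = []
    leaf_owner: list[tuple[str, str]] = []
    for pop in spec.focal_pops + [spec.outgroup]:
        for i in range(spec.sample_sizes[pop]):
            ind = f"{pop}_{i + 1}"
            pop_of_leaf.extend([pop, pop])
            leaf_owner.append((pop, ind))
    tree = _simulate_tree(pop_of_leaf, _scenario_epochs(spec), rng)
    return tree, leaf_owner


# ---------------------------------------------------------------------------
# mutation models

def mutate_ssr(tree: Tree, mu: float, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise mutations on the tree.

    Returns per-leaf ``(repeat_count, identity)`` arrays: repeat counts
    follow a symmetric single-step walk from the root state; identities
    are fresh integers whenever at least one mutation occurred on the
    branch, so identity-coded alleles separate every mutant lineage.
    """
    lengths = tree.branch_lengths()
    n_nodes = len(tree.parent)
    length_state = np.zeros(n_nodes, dtype=np.int64)
    id_state = np.zeros(n_nodes, dtype=np.int64)
    next_id = 1
    order = tree.preorder()
    root = order[0]
    length_state[root] = ROOT_REPEAT_COUNT
    id_state[root] = 0
    for node in order[1:]:
        p = tree.parent[node]
        k = rng.poisson(mu * lengths[node]) if mu > 0 else 0
        if k == 0:
            length_state[node] = length_state[p]
            id_state[node] = id_state[p]
        else:
            steps = rng.choice((-1, 1), size=k).sum()
            length_state[node] = max(length_state[p] + steps, 1)
            id_state[node] = next_id
            next_id += 1
    leaves = np.arange(tree.n_leaves)
    return length_state[leaves], id_state[leaves]


def mutate_snp(tree: Tree, rng: np.random.Generator) -> np.ndarray:
    """Place one mutation uniformly on the tree; returns 0/1 per leaf.

    Emulates SNP ascertainment: the locus is guaranteed polymorphic in
    the sample because every branch subtends a strict subset of leaves.
    """
    lengths = tree.branch_lengths()
    total = lengths.sum()
    if total <= 0:
        raise FragdivError("degenerate tree with zero length")
    for _ in range(100):
        node = rng.choice(len(lengths), p=lengths / total)
        derived = tree.leaves_under(int(node))
        if 0 < len(derived) < tree.n_leaves:
            out = np.zeros(tree.n_leaves, dtype=np.int64)
            out[derived] = 1
            return out
    raise FragdivError("failed to place a polymorphic mutation")


# ---------------------------------------------------------------------------
# genotype assembly

def simulate_scenario(spec: ScenarioSpec, marker: str, n_loci: int,
                      mu: float | None = None,
                      seed: int | np.random.Generator | None = None,
                      region_labels: tuple[str, str] = ("focal", "outgroup")
                      ) -> GenotypeMatrix:
    """Simulate a genotype matrix under one demographic scenario.

    ``marker`` selects the mutation model: ``ssr_length`` / ``ssr_id``
    (stepwise, rate ``mu`` per generation per locus) or ``snp`` (single
    ascertained mutation).  Leaves are paired into diploid individuals
    within populations.
    """
    if n_loci < 1:
        raise FragdivError("n_loci must be >= 1")
    if marker in ("ssr_length", "ssr_id") and (mu is None or mu < 0):
        raise FragdivError("ssr markers need a mutation rate mu >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pops_order = spec.focal_pops + [spec.outgroup]
    individuals: list[str] = []
    populations: dict[str, str] = {}
    for pop in pops_order:
        for i in range(spec.sample_sizes[pop]):
            ind = f"{pop}_{i + 1}"
            individuals.append(ind)
            populations[ind] = pop
    n_ind = len(individuals)
    calls = np.zeros((n_ind, n_loci, 2), dtype=np.int32)

    for j in range(n_loci):
        tree, _ = simulate_tree(spec, rng)
        if marker == "snp":
            states = mutate_snp(tree, rng)
        else:
            length_states, id_states = mutate_ssr(tree, mu, rng)
            states = length_states if marker == "ssr_length" else id_states
        pairs = states.reshape(n_ind, 2)
        if marker == "ssr_id":
            # dense re-coding per locus, order of first appearance
            codes: dict[int, int] = {}
            flat = pairs.ravel()
            dense = np.empty_like(flat)
            for k, s in enumerate(flat):
                dense[k] = codes.setdefault(int(s), len(codes))
            pairs = dense.reshape(n_ind, 2)
        calls[:, j, :] = pairs

    regions = {pop: region_labels[0] for pop in spec.focal_pops}
    regions[spec.outgroup] = region_labels[1]
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        regions=regions,
        loci=[f"{marker}_{j + 1}" for j in range(n_loci)],
        marker_kinds=[marker] * n_loci,
        calls=calls,
    )


def simulate_single_population(ne: float, n_individuals: int, n_loci: int,
                               marker: str = "ssr_length",
                               mu: float = 0.0,
                               seed: int | np.random.Generator | None = None
                               ) -> GenotypeMatrix:
    """Constant-size single-population coalescent sample.

    Convenience wrapper for calibration checks (pairwise coalescence
    times, stepwise-mutation equilibrium heterozygosity).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop_of_leaf = ["pop"] * (2 * n_individuals)
    calls = np.zeros((n_individuals, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        tree = _simulate_tree(pop_of_leaf,
                              [(float("inf"), {"pop": float(ne)}, {})], rng)
        if marker == "snp":
            states = mutate_snp(tree, rng)
        else:
            lengths, ids = mutate_ssr(tree, mu, rng)
            states = lengths if marker == "ssr_length" else ids
        calls[:, j, :] = states.reshape(n_individuals, 2)
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    return GenotypeMatrix(
        individuals=individuals,
        populations={i: "pop" for i in individuals},
        regions={"pop": "simulated"},
        loci=[f"L{j + 1}" for j in range(n_loci)],
        marker_kinds=[marker] * n_loci,
        calls=calls,
    )


def pairwise_tmrca(ne: float, n_replicates: int,
                   seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Coalescence times of a sample of two gene copies, one per locus."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # for k=2 the waiting time is Exp(1/(2N)) -- simulate through the
    # generic machinery so the check exercises the simulator itself
    times = np.empty(n_replicates)
    for r in range(n_replicates):
        tree = _simulate_tree(["pop", "pop"],
                              [(float("inf"), {"pop": float(ne)}, {})], rng)
        times[r] = tree.tmrca()
    return times
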