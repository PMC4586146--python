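"""Coalescent simulator for haploid mtDNA samples.

Generates alignments under the standard neutral coalescent with either a
constant population size or a sudden (stepwise) expansion, providing null
and alternative datasets for validating diversity statistics, neutrality
tests and mismatch-distribution fits.

Time is measured in *mutational* units: one unit equals the expected number
of mutations per lineage, so a pair of lineages coalesces at rate
``2 / theta`` and the stepwise size change of the expansion model sits at
``tau / 2`` in the past — directly comparable to the ``tau`` fitted from a
mismatch distribution (``tau = 2 u t`` with u the per-locus per-generation
rate and t the age in generations).  Mutation follows the infinite-sites
model by default: each mutation hits a fresh position of an L-bp locus; a
finite-sites option resamples positions with replacement for robustness
checks.

The packaged golden-jackal haplotype tables are re-exported here as
:func:`reference_tables` so simulator and fixtures live behind one surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .hapio import Alignment
from .tables import jackal_cr_table, jackal_cytb_table, reference_tables  # noqa: F401

__all__ = [
    "DemographyModel",
    "SimulationResult",
    "simulate_coalescent",
    "reference_tables",
    "jackal_cr_table",
    "jackal_cytb_table",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DemographyModel:
    """Demographic scenario for the simulator.

    ``constant``: single parameter ``theta`` (= 2Nu per locus).
    ``sudden_expansion``: present-day ``theta1``, ancestral ``theta0`` and
    the expansion age ``tau`` in mutational time; requires theta1 > theta0.
    """

    kind: Literal["constant", "sudden_expansion"] = "constant"
    theta: float = 5.0
    theta0: float = 0.5
    theta1: float = 50.0
    tau: float = 5.0
    n: int = 50
    L: int = 440
    seed: int = 42
    sites_model: Literal["infinite", "finite"] = "infinite"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.kind == "constant":
            if self.theta < 0:
                raise ValueError("theta must be >= 0")
        elif self.kind == "sudden_expansion":
            if not (self.theta1 > self.theta0 >= 0):
                raise ValueError("expansion requires theta1 > theta0 >= 0")
            if self.tau < 0:
                raise ValueError("tau must be >= 0")
        else:
            raise ValueError(f"unknown demography kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationResult:
    alignment: Alignment
    model: DemographyModel
    tree_height: float  # mutational time units
    n_mutations: int
    mutated_positions: tuple[int, ...] = field(default=())


def _simulate_genealogy(model: DemographyModel, rng: np.random.Generator):
    """Kingman coalescent under the demography; returns (parent, branch_len).

    Nodes 0..n-1 are leaves; internal nodes are appended in coalescence
    order.  Branch lengths are in mutational time.
    """
    n = model.n
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n

    def pair_rate(time: float, j: int) -> float:
        if model.kind == "constant":
            theta = model.theta
        else:
            theta = model.theta1 if time < model.tau / 2.0 else model.theta0
        if theta == 0.0:
            return np.inf
        return j * (j - 1) / 2.0 * 2.0 / theta

    while len(active) > 1:
        j = len(active)
        rate = pair_rate(t, j)
        if np.isinf(rate):
            wait = 0.0
        else:
            wait = rng.exponential(1.0 / rate)
        if (
            model.kind == "sudden_expansion"
            and t < model.tau / 2.0
            and t + wait >= model.tau / 2.0
        ):
            # crossed the epoch boundary: restart the exponential clock in
            # the ancestral epoch (memorylessness)
            t = model.tau / 2.0
            continue
        t += wait
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        node_time[node] = t
        active = [x for x in active if x not in (a, b)] + [node]
        t = node_time[node]
    branch = np.zeros(2 * n - 2)
    for v in range(2 * n - 2):
        branch[v] = node_time[parent[v]] - node_time[v]
    return parent, branch, node_time[2 * n - 2]


def simulate_coalescent(
    model: DemographyModel,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Simulate one alignment under the model.

    Mutations are Poisson on branches with rate 1 per unit mutational time;
    under the infinite-sites default each mutation occupies a distinct
    position of the L-bp locus (error if more mutations than positions).
    The returned alignment stores only the mutated columns (1-based
    positions on the simulated locus) plus the declared total length L, so
    downstream statistics scale with the number of variable sites, not L.
    Sample ids are ``s001`` ..., locality ``sim``.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n, L = model.n, model.L
    parent, branch, height = _simulate_genealogy(model, rng)
    total = branch.sum()
    n_mut = int(rng.poisson(total)) if total > 0 else 0
    positions: list[int] = []
    if n_mut > 0:
        if model.sites_model == "infinite":
            if n_mut > L:
                raise ValueError(
                    f"{n_mut} mutations exceed locus length L={L}; increase L"
                )
            pos = rng.choice(L, size=n_mut, replace=False)
        else:
            pos = rng.integers(0, L, size=n_mut)
        positions = sorted(set(int(p) for p in pos))
        col_of = {p: j for j, p in enumerate(positions)}
        ancestral = rng.integers(0, 4, size=len(positions))
        seqs = np.tile(ancestral, (n, 1))
        # assign each mutation to a branch ~ branch length
        branch_of = rng.choice(len(branch), size=n_mut, p=branch / total)
        # leaf sets per node (children appear before parents)
        desc = np.zeros((2 * n - 1, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for v in range(2 * n - 2):
            desc[parent[v]] |= desc[v]
        for p, b in zip(pos, branch_of):
            j = col_of[int(p)]
            carriers = desc[b]
            old = seqs[carriers, j][0] if carriers.any() else ancestral[j]
            seqs[carriers, j] = (old + rng.integers(1, 4)) % 4
        matrix = tuple("".join(_BASES[row]) for row in seqs)
    else:
        matrix = ("",) * n
    width = len(str(n))
    aln = Alignment(
        sample_ids=tuple(f"s{i + 1:0{width}d}" for i in range(n)),
        localities=("sim",) * n,
        sites=tuple(p + 1 for p in positions),
        matrix=matrix,
        length=L,
    )
    return SimulationResult(
        alignment=aln,
        model=model,
        tree_height=float(height),
        n_mutations=n_mut,
        mutated_positions=tuple(positions),
    )
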