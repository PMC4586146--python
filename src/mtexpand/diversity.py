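"""Molecular diversity indices for haploid sequence samples.

Implements the classical summary statistics of intraspecific mtDNA studies:
segregating sites *S*, haplotype (gene) diversity *h* with its sampling
standard deviation, mean pairwise differences *k*, and nucleotide diversity
per site pi = k / L.  Variance formulas follow Nei (1987, chap. 8/10).

Gap handling differs between the programs these statistics are usually
computed with, so every operation takes an explicit ``gap_policy``:

* ``gap_as_state`` — a gap is a fifth character state (a column with both a
  base and '-' is polymorphic);
* ``gap_as_missing`` — '-' and '?' are ignored when testing variability and
  deleted pairwise when counting differences;
* ``complete_deletion`` — columns containing any '-' or '?' are removed
  before anything is counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Literal, Sequence

from .hapio import GAP, MISSING, Alignment, collapse_haplotypes

__all__ = [
    "DiversityStats",
    "segregating_sites",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "diversity_stats",
]

GapPolicy = Literal["gap_as_state", "gap_as_missing", "complete_deletion"]


@dataclass(frozen=True)
class DiversityStats:
    """One row of a molecular-diversity summary table."""

    n: int
    S: int
    n_hap: int
    h: float
    sd_h: float
    pi: float
    sd_pi: float
    k: float
    L: int


def _complete_deletion(aln: Alignment) -> Alignment:
    drop = [
        s
        for j, s in enumerate(aln.sites)
        if any(row[j] in (GAP, MISSING) for row in aln.matrix)
    ]
    return aln.drop_columns(drop)


def segregating_sites(aln: Alignment, gap_policy: GapPolicy = "gap_as_state") -> int:
    """Number of polymorphic columns under the given gap policy."""
    if aln.n < 2:
        raise ValueError("segregating sites require at least 2 sequences")
    if gap_policy == "complete_deletion":
        aln = _complete_deletion(aln)
    count = 0
    for j in range(len(aln.sites)):
        col = [row[j] for row in aln.matrix]
        if gap_policy == "gap_as_state":
            states = {c for c in col if c != MISSING}
        else:
            states = {c for c in col if c not in (GAP, MISSING)}
        if len(states) >= 2:
            count += 1
    return count


def haplotype_diversity(counts: Sequence[int], n: int | None = None) -> tuple[float, float]:
    """Unbiased gene diversity h and its standard deviation.

    ``h = n (1 - sum p_i^2) / (n - 1)`` over haplotype frequencies
    ``p_i = counts_i / n``; the SD is the square root of Nei's sampling
    variance of heterozygosity:

    ``V(h) = 2/(n(n-1)) * [2(n-2)(sum p_i^3 - (sum p_i^2)^2) + sum p_i^2 - (sum p_i^2)^2]``
    """
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"n={n} does not match sum of counts {total}")
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p2 = sum((c / n) ** 2 for c in counts)
    p3 = sum((c / n) ** 3 for c in counts)
    h = n * (1.0 - p2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (p3 - p2 * p2) + p2 - p2 * p2)
    return h, sqrt(max(var, 0.0))


def _pair_diff(a: str, b: str, gap_policy: GapPolicy) -> float:
    if gap_policy == "gap_as_state":
        skip = (MISSING,)
    else:
        skip = (GAP, MISSING)
    return sum(1 for x, y in zip(a, b) if x != y and x not in skip and y not in skip)


def mean_pairwise_differences(aln: Alignment, gap_policy: GapPolicy = "gap_as_missing") -> float:
    """Mean number of pairwise differences k over all C(n,2) sequence pairs.

    Under ``gap_as_missing`` sites with '-' or '?' in either member of a pair
    are deleted pairwise.  Identical rows are grouped first, so cost scales
    with the number of distinct haplotypes rather than n.
    """
    if aln.n < 2:
        raise ValueError("pairwise differences require at least 2 sequences")
    if gap_policy == "complete_deletion":
        aln = _complete_deletion(aln)
        gap_policy = "gap_as_state"  # nothing left to skip
    tbl = collapse_haplotypes(aln, missing_policy="strict")
    reps = tbl.states
    weights = tbl.total_counts
    n = aln.n
    total = 0.0
    for i, j in combinations(range(len(reps)), 2):
        total += weights[i] * weights[j] * _pair_diff(reps[i], reps[j], gap_policy)
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(
    aln: Alignment,
    L: int | None = None,
    gap_policy: GapPolicy = "gap_as_missing",
) -> tuple[float, float]:
    """Nucleotide diversity pi = k / L and its standard deviation.

    ``L`` defaults to ``aln.length``.  The SD uses the no-recombination
    variance approximation of Nei (1987 eq. 10.7, per site):

    ``V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2``
    """
    if L is None:
        L = aln.length
    if not L or L <= 0:
        raise ValueError("nucleotide diversity requires a positive sequence length L")
    k = mean_pairwise_differences(aln, gap_policy)
    pi = k / L
    n = aln.n
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return pi, sqrt(max(var, 0.0))


def diversity_stats(
    aln: Alignment,
    L: int | None = None,
    gap_policy_S: GapPolicy = "gap_as_state",
    gap_policy_k: GapPolicy = "gap_as_missing",
) -> DiversityStats:
    """Full summary row: n, S, haplotype count, h, pi, k.

    Default gap policies differ per statistic, mirroring the conventions of
    the standard population-genetics programs: S counts gaps as a fifth
    state, while k and pi delete gap/missing sites pairwise.
    """
    tbl = collapse_haplotypes(aln, missing_policy="strict")
    h, sd_h = haplotype_diversity(tbl.total_counts)
    k = mean_pairwise_differences(aln, gap_policy_k)
    if L is None:
        L = aln.length or None
    if L:
        pi, sd_pi = nucleotide_diversity(aln, L, gap_policy_k)
    else:
        pi, sd_pi, L = float("nan"), float("nan"), 0
    return DiversityStats(
        n=aln.n,
        S=segregating_sites(aln, gap_policy_S),
        n_hap=tbl.n_haplotypes,
        h=h,
        sd_h=sd_h,
        pi=pi,
        sd_pi=sd_pi,
        k=k,
        L=L,
    )
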