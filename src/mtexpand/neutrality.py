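"""Tajima's D and Fu's Fs neutrality tests with simulation-based p-values.

Both statistics contrast observed sequence variation with the expectation
under the standard neutral coalescent at constant population size; strongly
negative values signal an excess of rare variants / alleles, the classical
footprint of recent demographic expansion.

Tajima's D standardizes the difference between the pairwise estimator of
theta (k, the mean number of pairwise differences) and the Watterson
estimator (S / a1).  Fu's Fs is the log-odds ``ln(S' / (1 - S'))`` of
``S' = P(K >= k_obs | theta = k)``, the Ewens-sampling probability of seeing
at least the observed number of distinct alleles given theta estimated from
k.  P-values are obtained by simulating the constant-size coalescent with
theta set to the observed k (lower tail, matching the expansion-direction
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np

from .hapio import Alignment, collapse_haplotypes
from .diversity import mean_pairwise_differences, segregating_sites

__all__ = [
    "NeutralityResult",
    "tajimas_d",
    "tajima_constants",
    "ewens_log_pmf",
    "fus_fs",
    "neutrality_pvalues",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input (e.g. S=0)."""


@dataclass(frozen=True)
class NeutralityResult:
    D: float
    p_D: float
    Fs: float
    p_Fs: float
    n: int
    S: int
    k: float
    n_alleles: int
    n_sims: int
    seed: int
    #: tail convention used for both p-values
    tail: str = "lower"


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's (1989) variance correction."""
    if n < 2:
        raise ValueError("n >= 2 required")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D from segregating sites S, mean pairwise differences k, and n.

    Negative when rare variants are in excess (demographic expansion or
    purifying selection); undefined for S = 0.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D is undefined when S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k - S / c["a1"]) / sqrt(var)


def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, j)| for j = 0..n, via the triangular recursion in log space."""
    if n > 10_000:
        raise ValueError("n capped at 10,000")
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for i in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        if i == 1:
            new[1:] = row[:-1]  # |s(1,1)| = 1
        else:
            new[1:] = np.logaddexp(row[:-1], row[1:] + log(i - 1))
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = j) for j = 0..n under the Ewens sampling distribution.

    ``P(K = j) = |s(n, j)| theta^j / theta_(n)`` with theta_(n) the rising
    factorial; computed entirely in log space.
    """
    if theta <= 0:
        raise UndefinedStatisticError("Ewens distribution requires theta > 0")
    ls = _log_stirling_first(n)
    j = np.arange(n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return ls + j * log(theta) - log_rising


def fus_fs(k: float, n: int, n_alleles: int) -> float:
    """Fu's Fs statistic.

    theta is estimated by k; ``S' = P(K >= n_alleles)`` under the Ewens
    distribution; ``Fs = ln(S' / (1 - S'))``.  Errors on degenerate inputs
    (k = 0, or S' numerically 0/1).
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if not 1 <= n_alleles <= n:
        raise ValueError("n_alleles must be in [1, n]")
    if k <= 0:
        raise UndefinedStatisticError("Fu's Fs requires k > 0 (theta estimate degenerate)")
    logp = ewens_log_pmf(n, k)
    # log of upper and lower tails via log-sum-exp
    from scipy.special import logsumexp

    log_upper = logsumexp(logp[n_alleles:])
    log_lower = logsumexp(logp[:n_alleles])
    if not np.isfinite(log_lower) or log_upper >= 0.0 and log_lower == -np.inf:
        raise UndefinedStatisticError("S' is numerically 0 or 1; Fs unbounded")
    fs = log_upper - log_lower
    if not np.isfinite(fs):
        raise UndefinedStatisticError("S' is numerically 0 or 1; Fs unbounded")
    return float(fs)


def neutrality_pvalues(
    aln: Alignment,
    n_sims: int = 1000,
    seed: int = 42,
) -> NeutralityResult:
    """Observed D and Fs with coalescent-simulation p-values.

    Simulates ``n_sims`` constant-size samples of the same n with theta set
    to the observed k, and reports the lower-tail fractions
    ``P(D_sim <= D_obs)`` and ``P(Fs_sim <= Fs_obs)`` — the convention under
    which small p supports demographic expansion.
    """
    from .synthetic import DemographyModel, simulate_coalescent

    if n_sims < 100:
        raise ValueError("n_sims >= 100 required for stable p-values")
    n = aln.n
    S = segregating_sites(aln, "gap_as_state")
    k = mean_pairwise_differences(aln, "gap_as_missing")
    n_alleles = collapse_haplotypes(aln).n_haplotypes
    D_obs = tajimas_d(S, k, n)
    Fs_obs = fus_fs(k, n, n_alleles)
    rng = np.random.default_rng(seed)
    d_le = fs_le = 0
    valid_d = valid_fs = 0
    for _ in range(n_sims):
        sim = simulate_coalescent(
            DemographyModel(kind="constant", theta=k, n=n, L=max(aln.length, 1000)),
            rng=rng,
        ).alignment
        S_sim = segregating_sites(sim, "gap_as_state")
        k_sim = mean_pairwise_differences(sim, "gap_as_missing")
        if S_sim >= 1:
            valid_d += 1
            if tajimas_d(S_sim, k_sim, n) <= D_obs:
                d_le += 1
        if k_sim > 0:
            try:
                fs_sim = fus_fs(k_sim, n, collapse_haplotypes(sim).n_haplotypes)
            except UndefinedStatisticError:
                continue
            valid_fs += 1
            if fs_sim <= Fs_obs:
                fs_le += 1
    p_D = d_le / valid_d if valid_d else float("nan")
    p_Fs = fs_le / valid_fs if valid_fs else float("nan")
    return NeutralityResult(
        D=D_obs,
        p_D=p_D,
        Fs=Fs_obs,
        p_Fs=p_Fs,
        n=n,
        S=S,
        k=k,
        n_alleles=n_alleles,
        n_sims=n_sims,
        seed=seed,
    )
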