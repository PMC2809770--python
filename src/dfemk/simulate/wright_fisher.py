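"""Forward Wright-Fisher engine and exact Markov-chain oracles.

The forward simulator and the fundamental-matrix computations here serve as
brute-force references for the transition-matrix expectations used by the
likelihood code (which is implemented separately in :mod:`dfemk.dfe`).

Selection follows the semidominant scheme with genotype fitnesses 1,
1 - s/2 and 1 - s for the wild-type homozygote, heterozygote and mutant
homozygote.  Writing q for the mutant allele frequency, the deterministic
change per generation is

    q' = q (1 - s (1 + q) / 2) / (1 - s q)

followed by binomial sampling of 2N chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "WFState",
    "ForwardResult",
    "deterministic_freq_change",
    "forward_wf_simulate",
    "transition_matrix",
    "exact_absorption_probabilities",
    "exact_sojourn_times",
    "demographic_sojourn_density",
]


@dataclass(frozen=True)
class WFState:
    """A Wright-Fisher population state."""

    pop_size_2N: int
    allele_count: int
    generation: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.allele_count <= self.pop_size_2N:
            raise ValueError(
                f"allele_count {self.allele_count} outside [0, {self.pop_size_2N}]"
            )


@dataclass
class ForwardResult:
    """Outcome of a batch of forward simulations."""

    pop_size_2N: int
    s: float
    final_counts: np.ndarray      # (n_replicates,)
    fixed: np.ndarray             # bool, absorbed at 2N
    lost: np.ndarray              # bool, absorbed at 0
    n_generations: int
    trajectories: Optional[np.ndarray] = None  # (n_replicates, n_generations + 1)

    @property
    def fixation_fraction(self) -> float:
        return float(self.fixed.mean())


def deterministic_freq_change(q: np.ndarray, s: float) -> np.ndarray:
    """Post-selection mutant frequency under the semidominant scheme."""
    q = np.asarray(q, dtype=float)
    return q * (1.0 - s * (1.0 + q) / 2.0) / (1.0 - s * q)


def _check_sim_args(pop_size_2N: int, s: float) -> None:
    if not np.isfinite(s):
        raise ValueError("selection coefficient must be finite")
    if abs(s) >= 1.0:
        raise ValueError(f"|s| must be < 1, got {s}")
    if pop_size_2N < 4:
        raise ValueError(f"pop_size_2N must be >= 4, got {pop_size_2N}")


def forward_wf_simulate(
    pop_size_2N: int,
    s_additive: float,
    n_generations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_replicates: int = 1,
    initial_count: int = 1,
    epochs: Optional[Sequence[Tuple[int, int]]] = None,
    record_trajectories: bool = False,
) -> ForwardResult:
    """Simulate replicate allele-count trajectories forward in time.

    ``epochs`` optionally lists ``(pop_size_2N, n_gens)`` stages describing a
    step-change demography; when given it overrides ``pop_size_2N`` /
    ``n_generations``.  Counts 0 and 2N are absorbing.  Size changes resample
    counts binomially onto the new chromosome number.
    """
    _check_sim_args(pop_size_2N, s_additive)
    if rng is None:
        rng = np.random.default_rng(seed)
    if epochs is None:
        epochs = [(int(pop_size_2N), int(n_generations))]
    total_gens = sum(g for _, g in epochs)

    two_n = int(epochs[0][0])
    if not 0 <= initial_count <= two_n:
        raise ValueError("initial_count outside [0, 2N]")
    counts = np.full(n_replicates, initial_count, dtype=np.int64)

    traj = None
    if record_trajectories:
        traj = np.empty((n_replicates, total_gens + 1), dtype=np.int64)
        traj[:, 0] = counts

    gen = 0
    for epoch_idx, (epoch_two_n, epoch_gens) in enumerate(epochs):
        epoch_two_n = int(epoch_two_n)
        _check_sim_args(epoch_two_n, s_additive)
        if epoch_idx > 0 and epoch_two_n != two_n:
            # resample onto the new chromosome number, preserving frequency
            freq = counts / two_n
            counts = rng.binomial(epoch_two_n, freq)
            two_n = epoch_two_n
        for _ in range(int(epoch_gens)):
            active = (counts > 0) & (counts < two_n)
            if active.any():
                q = counts[active] / two_n
                qp = deterministic_freq_change(q, s_additive)
                counts[active] = rng.binomial(two_n, np.clip(qp, 0.0, 1.0))
            gen += 1
            if traj is not None:
                traj[:, gen] = counts

    return ForwardResult(
        pop_size_2N=two_n,
        s=s_additive,
        final_counts=counts,
        fixed=counts == two_n,
        lost=counts == 0,
        n_generations=total_gens,
        trajectories=traj,
    )


def transition_matrix(two_n: int, s: float) -> np.ndarray:
    """Full (2N+1)x(2N+1) Wright-Fisher transition matrix, rows = current count."""
    _check_sim_args(two_n, s)
    q = np.arange(two_n + 1) / two_n
    qp = np.clip(deterministic_freq_change(q, s), 0.0, 1.0)
    j = np.arange(two_n + 1)
    return sp_stats.binom.pmf(j[None, :], two_n, qp[:, None])


def exact_absorption_probabilities(two_n: int, s: float) -> np.ndarray:
    """Fixation probability from every starting count, by the fundamental matrix.

    Returns a vector of length 2N+1; entries 0 and 2N are 0 and 1.
    """
    a = transition_matrix(two_n, s)
    q = a[1:-1, 1:-1]
    r_fix = a[1:-1, -1]
    fund = np.linalg.inv(np.eye(two_n - 1) - q)
    u = fund @ r_fix
    return np.concatenate([[0.0], u, [1.0]])


def exact_sojourn_times(two_n: int, s: float, start_count: int = 1) -> np.ndarray:
    """Expected generations spent at each transient count 1..2N-1 before absorption."""
    if not 1 <= start_count <= two_n - 1:
        raise ValueError("start_count must be a transient state")
    a = transition_matrix(two_n, s)
    q = a[1:-1, 1:-1]
    fund = np.linalg.inv(np.eye(two_n - 1) - q)
    return fund[start_count - 1, :]


def demographic_sojourn_density(
    two_n1: int,
    two_n2: int,
    t: int,
    s: float,
) -> Tuple[int, np.ndarray]:
    """Stationary-input density of segregating mutations under a step change.

    New mutations enter at count 1 at a rate proportional to population size
    (one per generation at the ancestral size).  The ancestral equilibrium is
    the fundamental-matrix sojourn vector; a size change maps counts onto the
    new grid binomially and the density is then iterated for ``t`` further
    generations at the new size.

    Returns ``(two_n_current, density)`` where ``density`` covers transient
    counts ``1..two_n_current - 1``.  ``t == 0`` ignores ``two_n2`` entirely
    (no change has happened yet).
    """
    v1 = exact_sojourn_times(two_n1, s, start_count=1)
    if t == 0:
        return two_n1, v1
    _check_sim_args(two_n2, s)
    freqs1 = np.arange(1, two_n1) / two_n1
    j = np.arange(1, two_n2)
    mapping = sp_stats.binom.pmf(j[None, :], two_n2, freqs1[:, None])
    v = v1 @ mapping
    a2 = transition_matrix(two_n2, s)
    q2 = a2[1:-1, 1:-1]
    input_rate = two_n2 / two_n1
    e1 = np.zeros(two_n2 - 1)
    e1[0] = input_rate
    for _ in range(int(t)):
        v = v @ q2 + e1
    return two_n2, v
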