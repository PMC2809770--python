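"""Wright-Fisher transition-matrix expectations for folded sample SFSs.

Selection is semidominant (genotype fitnesses 1, 1 - s/2, 1 - s).  The
population allele-frequency density of segregating mutations under a
stationary mutational input is obtained from the linear system
v (I - Q) = e1 at the ancestral size; a step change in size maps the
density binomially onto the new frequency grid and iterates the new
transition matrix for t further generations with input proportional to the
new size.  Expected sample spectra are binomial draws from the density,
folded, with the unobserved classes (0 and n copies in the sample) pooled
into the monomorphic cell.

Population sizes are expressed on a scaled reference grid (exact sizes are
not identifiable; only the size ratio and the scaled time matter).  Scaled
selection S is defined as N1_diploid * s on this grid; s >= ~1 is treated
as lethal (no contribution to polymorphism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import special

from dfemk.sfs import fold_vector

__all__ = [
    "Demography",
    "wf_matrix",
    "population_density",
    "expected_folded_sfs_neutral",
    "expected_folded_sfs_selected",
    "SelectionGrid",
    "integrate_over_dfe",
]

_MAX_TWO_N = 2000
_LETHAL_S = 0.99


@dataclass(frozen=True)
class Demography:
    """Step-change demography on the transition-matrix grid.

    ``two_n1``/``two_n2`` are chromosome counts; ``t`` generations have
    elapsed at size ``two_n2``.  ``t == 0`` means no change has happened.
    """

    two_n1: int
    two_n2: int
    t: int

    def __post_init__(self) -> None:
        if self.two_n1 < 4 or self.two_n2 < 4:
            raise ValueError("population sizes must be >= 4 chromosomes")
        if max(self.two_n1, self.two_n2) > _MAX_TWO_N:
            raise ValueError(
                f"grid size {max(self.two_n1, self.two_n2)} exceeds the "
                f"configured maximum {_MAX_TWO_N}"
            )
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def n1(self) -> float:
        return self.two_n1 / 2.0

    @property
    def n2(self) -> float:
        return self.two_n2 / 2.0


def _selection_shift(q: np.ndarray, s: float) -> np.ndarray:
    # q' = q (1 - s(1+q)/2) / (1 - s q) for fitnesses 1, 1-s/2, 1-s
    return q * (1.0 - 0.5 * s * (1.0 + q)) / (1.0 - s * q)


def _binom_pmf_matrix(n_trials: int, p: np.ndarray) -> np.ndarray:
    """Rows: success probabilities; columns: outcome counts 0..n_trials."""
    k = np.arange(n_trials + 1)
    logpmf = (
        special.gammaln(n_trials + 1)
        - special.gammaln(k + 1)[None, :]
        - special.gammaln(n_trials - k + 1)[None, :]
        + k[None, :] * np.log(np.clip(p, 1e-300, 1.0))[:, None]
        + (n_trials - k)[None, :] * np.log(np.clip(1.0 - p, 1e-300, 1.0))[:, None]
    )
    pmf = np.exp(logpmf)
    pmf[p == 0.0, :] = 0.0
    pmf[p == 0.0, 0] = 1.0
    pmf[p == 1.0, :] = 0.0
    pmf[p == 1.0, n_trials] = 1.0
    return pmf / pmf.sum(axis=1, keepdims=True)


def wf_matrix(two_n: int, s: float) -> np.ndarray:
    """(2N+1)x(2N+1) transition matrix, row = current count."""
    if not math.isfinite(s) or abs(s) >= 1.0:
        raise ValueError(f"require finite |s| < 1, got {s}")
    q = np.arange(two_n + 1) / two_n
    qp = np.clip(_selection_shift(q, s), 0.0, 1.0)
    return _binom_pmf_matrix(two_n, qp)


def _equilibrium_density(two_n: int, s: float) -> np.ndarray:
    """Solve v (I - Q) = e1 over transient counts 1..2N-1."""
    a = wf_matrix(two_n, s)
    q = a[1:-1, 1:-1]
    e1 = np.zeros(two_n - 1)
    e1[0] = 1.0
    return np.linalg.solve((np.eye(two_n - 1) - q).T, e1)


@lru_cache(maxsize=512)
def _population_density_cached(
    two_n1: int, two_n2: int, t: int, s_key: float
) -> Tuple[int, tuple]:
    s = float(s_key)
    v = _equilibrium_density(two_n1, s)
    if t == 0:
        return two_n1, tuple(v)
    if t >= 3 * two_n2:
        # effectively re-equilibrated at the new size (relative error ~e^-3)
        v2 = _equilibrium_density(two_n2, s) * (two_n2 / two_n1)
        return two_n2, tuple(v2)
    freqs = np.arange(1, two_n1) / two_n1
    mapped = v @ _binom_pmf_matrix(two_n2, freqs)
    v2 = mapped[1:-1].copy()
    a2 = wf_matrix(two_n2, s)
    q2 = a2[1:-1, 1:-1]
    inject = np.zeros(two_n2 - 1)
    inject[0] = two_n2 / two_n1  # mutational input scales with population size
    for _ in range(t):
        v2 = v2 @ q2 + inject
    return two_n2, tuple(v2)


def population_density(demog: Demography, s: float = 0.0) -> Tuple[int, np.ndarray]:
    """Density of segregating mutations over counts 1..2N_cur-1 at sampling."""
    two_n, v = _population_density_cached(
        demog.two_n1, demog.two_n2, demog.t, round(float(s), 12)
    )
    return two_n, np.asarray(v)


def _folded_sampled_raw(demog: Demography, s: float, n: int) -> np.ndarray:
    """Unnormalised folded sample vector (sojourn-time units) of length n//2+1.

    Cell 0 holds sojourn mass whose sample lands on 0 or n copies
    (unobserved).  Mutations with s >= ~1 never segregate and contribute a
    zero vector.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if s >= _LETHAL_S:
        return np.zeros(n // 2 + 1)
    two_n, v = population_density(demog, s)
    freqs = np.arange(1, two_n) / two_n
    sample = v @ _binom_pmf_matrix(n, freqs)  # length n+1
    return fold_vector(sample)


def _expected_folded(demog: Demography, s: float, n: int) -> np.ndarray:
    """Normalised folded sample SFS of length n//2+1, cell 0 = unobserved."""
    folded = _folded_sampled_raw(demog, s, n)
    total = folded.sum()
    if total <= 0:
        out = np.zeros(n // 2 + 1)
        out[0] = 1.0
        return out
    return folded / total


@lru_cache(maxsize=4096)
def _expected_folded_cached(two_n1, two_n2, t, s_key, n) -> tuple:
    return tuple(_expected_folded(Demography(two_n1, two_n2, t), float(s_key), n))


def expected_folded_sfs_neutral(demog: Demography, n: int) -> np.ndarray:
    """Expected folded neutral sample SFS (proportions; cell 0 = monomorphic)."""
    return np.asarray(
        _expected_folded_cached(demog.two_n1, demog.two_n2, demog.t, 0.0, n)
    )


def expected_folded_sfs_selected(demog: Demography, S: float, n: int) -> np.ndarray:
    """Expected folded sample SFS under scaled selection S = N1 * s.

    S is deleterious for S > 0 (the magnitude of N s); internally the
    selection coefficient s = S / N1 enters the semidominant transition
    matrix.  S values implying s >= ~1 are treated as lethal.
    """
    if not math.isfinite(S):
        raise ValueError("S must be finite")
    s = S / demog.n1
    if s >= _LETHAL_S:
        out = np.zeros(n // 2 + 1)
        out[0] = 1.0
        return out
    return np.asarray(
        _expected_folded_cached(
            demog.two_n1, demog.two_n2, demog.t, round(float(s), 12), n
        )
    )


class SelectionGrid:
    """Precomputed selected spectra on a log-spaced grid of S values.

    Built once per demography and list of sample sizes, then reused for
    every gamma-DFE integration during optimisation.  S is on the N1 scale
    (S = N1 * s).  The stored vectors are *unnormalised* sojourn-weighted
    sample spectra, so mixing over the DFE correctly down-weights strongly
    selected mutations by their short persistence; gamma mass above the
    lethal end of the grid contributes nothing segregating.
    """

    def __init__(
        self,
        demog: Demography,
        sample_sizes: Sequence[int],
        n_grid: int = 32,
        s_min: float = 1e-3,
    ):
        self.demog = demog
        self.sample_sizes = sorted(set(int(n) for n in sample_sizes))
        s_max = _LETHAL_S * demog.n1 * 0.999
        if s_min >= s_max:
            raise ValueError("selection grid is empty; increase the grid size")
        self.s_values = np.concatenate(
            [[0.0], np.geomspace(s_min, s_max, n_grid)]
        )
        self.spectra: Dict[int, np.ndarray] = {}
        for n in self.sample_sizes:
            rows = [
                _folded_sampled_raw(demog, s / demog.n1, n)
                for s in self.s_values
            ]
            rows.append(np.zeros(n // 2 + 1))  # lethal pseudo-node
            self.spectra[n] = np.vstack(rows)
        # total sojourn mass of a neutral mutation under the same input:
        # the yardstick that ties the selected class to the neutral one
        self.neutral_total = float(population_density(demog, 0.0)[1].sum())

    def gamma_weights(self, shape: float, mean_S: float) -> np.ndarray:
        """Cell masses of gamma(shape, mean_S/shape) over the grid nodes.

        Cells are bounded by log-midpoints between nodes; mass below the
        first positive node goes to that node, mass above the last node to
        the lethal pseudo-node.
        """
        if mean_S <= 0:
            w = np.zeros(len(self.s_values) + 1)
            w[0] = 1.0
            return w
        pos = self.s_values[1:]
        mids = np.sqrt(pos[:-1] * pos[1:])
        # mass beyond the lethal cutoff is invisible to samples (zero vector)
        s_cut = _LETHAL_S * self.demog.n1
        edges = np.concatenate([[0.0], mids, [s_cut]])
        cdf = special.gammainc(shape, edges / (mean_S / shape))
        masses = np.diff(cdf)
        tail = max(1.0 - cdf[-1], 0.0)
        w = np.concatenate([[0.0], masses, [tail]])
        # numerical guard: renormalise
        total = w.sum()
        return w / total if total > 0 else w

    def expected_sfs(self, shape: float, mean_S: float, n: int) -> np.ndarray:
        """Gamma-DFE mixture spectrum at sample size n, on the neutral yardstick.

        Segregating cells are the sojourn-weighted mixture divided by the
        *neutral* total sojourn mass under the same mutational input, so a
        shared f0 links the neutral and selected classes: selection shows up
        both in the spectrum shape and in the deficit of segregating sites.
        Cell 0 absorbs the remainder (monomorphic).
        """
        w = self.gamma_weights(shape, mean_S)
        u = w @ self.spectra[n]
        rho = u / self.neutral_total
        rho[0] = 1.0 - rho[1:].sum()
        return rho


def integrate_over_dfe(
    demog: Demography,
    shape: float,
    mean_S: float,
    n: int,
    n_quadrature: int = 32,
) -> np.ndarray:
    """Expected folded SFS under a gamma DFE, by grid quadrature over S.

    Convenience wrapper building a throw-away :class:`SelectionGrid`; use
    the class directly inside optimisation loops.
    """
    if n_quadrature < 16:
        raise ValueError("n_quadrature must be >= 16")
    grid = SelectionGrid(demog, [n], n_grid=n_quadrature)
    return grid.expected_sfs(shape, mean_S, n)
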