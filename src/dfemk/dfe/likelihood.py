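"""Multinomial log-likelihoods for grouped folded spectra.

Log-likelihoods omit the (parameter-free) multinomial coefficient: they are
sums of observed-count-weighted log cell probabilities.  The monomorphic
cell is a mixture: with probability f0 a site carries no mutation at all,
otherwise the model's own monomorphic/unobserved probability applies.
"""

from __future__ import annotations

import math
from typing import Callable, Dict

import numpy as np

__all__ = ["multinomial_loglik", "f0_adjust", "grouped_sfs_loglik"]


def multinomial_loglik(observed: np.ndarray, probs: np.ndarray) -> float:
    """Sum of obs * log(p) over cells; empty spectra contribute 0.

    A zero model probability with a nonzero observed count yields -inf.
    """
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if observed.shape != probs.shape:
        raise ValueError("observed and probs must have the same shape")
    active = observed > 0
    if not active.any():
        return 0.0
    p = probs[active]
    if (p <= 0).any():
        return -math.inf
    return float(np.sum(observed[active] * np.log(p)))


def f0_adjust(model_probs: np.ndarray, f0: float) -> np.ndarray:
    """Mix a fraction f0 of never-mutated sites into the monomorphic cell."""
    if not 0.0 <= f0 <= 1.0:
        raise ValueError(f"f0 must be in [0, 1], got {f0}")
    q = (1.0 - f0) * np.asarray(model_probs, dtype=float)
    q[0] += f0
    return q


def grouped_sfs_loglik(
    spectra: Dict[int, np.ndarray],
    expected_fn: Callable[[int], np.ndarray],
    f0: float,
) -> float:
    """Sum multinomial log-likelihoods over sample-size groups.

    ``expected_fn(n)`` must return the model's folded proportions (cell 0 =
    monomorphic) for sample size n.
    """
    total = 0.0
    for n, obs in spectra.items():
        probs = f0_adjust(expected_fn(n), f0)
        total += multinomial_loglik(obs, probs)
        if total == -math.inf:
            break
    return total
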