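"""Maximum-likelihood fitting of the gamma DFE and step-change demography.

Fitting is staged: the demographic parameters (size ratio, time since the
change, and the unmutated-site fraction f0) are first estimated from the
neutral spectra alone, a grid of selected spectra over S is then
precomputed at the fitted demography, and the gamma parameters (shape,
mean S) are estimated together with a refined shared f0 by maximising the
joint neutral + selected log-likelihood.  An optional joint polish
re-optimises all five parameters simultaneously.  All optimisation is
derivative-free (the integer time step makes the surface piecewise
constant) with seeded multi-starts.

Selective effects are reported on the weighted recent population size
N_w = N1 (1 - f2) + N2 f2 with f2 = 1 - exp(-t / (2 N2)), a
pair-coalescence-style weighting between the two epochs; internally the
grid works on the N1 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats as sp_stats

from dfemk._rng import substream
from dfemk.sfs import GroupedFoldedSFS
from dfemk.dfe.likelihood import grouped_sfs_loglik
from dfemk.dfe.transition import (
    Demography,
    SelectionGrid,
    expected_folded_sfs_neutral,
)

__all__ = [
    "DemographicModel",
    "GammaDFE",
    "DFEFit",
    "fit_ml",
    "weighted_recent_n",
    "nes_class_proportions",
    "bootstrap_contrast_pvalue",
]

_RATIO_BOUNDS = (0.1, 4.0)
_TAU_MAX = 3.0           # t / (2 N2); beyond this N_w is within 5% of N2
# search-space quantisation: makes every demography evaluation cacheable and
# bounds the number of distinct transition-matrix computations per fit
_N_RATIO_STEPS = 48
_TAU_STEP = _TAU_MAX / 48
_SHAPE_BOUNDS = (0.03, 5.0)
_MEANS_BOUNDS = (1e-4, 1e7)  # mean S on the internal N1 scale
_F0_BOUNDS = (1e-4, 1.0 - 1e-6)


@dataclass(frozen=True)
class DemographicModel:
    """Fitted step-change demography in diploid grid units."""

    n1: float
    n2: float
    t: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("population sizes must be >= 2")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def ratio(self) -> float:
        return self.n2 / self.n1


@dataclass(frozen=True)
class GammaDFE:
    """Gamma distribution of scaled deleterious effects S = N_e s.

    ``mean_S`` is the mean of S over new mutations on the weighted recent
    population size scale; ``shape`` is dimensionless.
    """

    shape: float
    mean_S: float

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.mean_S < 0:
            raise ValueError("mean_S must be >= 0")


@dataclass
class DFEFit:
    dfe: GammaDFE
    demog: DemographicModel
    f0: float
    loglik: float
    weighted_n: float
    nes_class_props: np.ndarray
    mean_S_internal: float
    grid_two_n1: int
    converged: bool
    ci: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def weighted_recent_n(demog: DemographicModel) -> float:
    """Weighted recent population size N_w (pair-coalescence weighting).

    f2 = 1 - exp(-t / (2 N2)) is the weight on the recent epoch, so
    t = 0 gives N1 and t >> N2 gives N2.  This weighting is a documented
    stand-in convention; outputs should carry its label.
    """
    f2 = 1.0 - math.exp(-demog.t / (2.0 * demog.n2)) if demog.t > 0 else 0.0
    return demog.n1 * (1.0 - f2) + demog.n2 * f2


def nes_class_proportions(
    dfe: GammaDFE, boundaries: Sequence[float] = (1.0, 10.0)
) -> np.ndarray:
    """Fractions of mutations with N_e s in [0, b1), [b1, b2), [b2, inf)."""
    if dfe.mean_S == 0:
        out = np.zeros(len(boundaries) + 1)
        out[0] = 1.0
        return out
    cdf = sp_stats.gamma.cdf(
        np.asarray(boundaries, dtype=float), a=dfe.shape,
        scale=dfe.mean_S / dfe.shape,
    )
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _decode_demog(x: np.ndarray, two_n1: int) -> Tuple[Demography, float, float]:
    """Map optimizer coordinates to a quantised demography + bound penalty."""
    log_ratio, log1p_tau, logit_f0 = x
    penalty = 0.0
    ratio = math.exp(log_ratio)
    lo, hi = _RATIO_BOUNDS
    if ratio < lo:
        penalty += (math.log(lo) - log_ratio) ** 2 * 100
        ratio = lo
    elif ratio > hi:
        penalty += (log_ratio - math.log(hi)) ** 2 * 100
        ratio = hi
    # snap the ratio to a log grid and tau to fixed steps so optimisation
    # revisits cached demographies instead of recomputing near-duplicates
    step = math.log(hi / lo) / _N_RATIO_STEPS
    ratio = lo * math.exp(round(math.log(ratio / lo) / step) * step)
    tau = math.expm1(log1p_tau) if log1p_tau > 0 else 0.0
    if log1p_tau < 0:
        penalty += log1p_tau**2 * 100
    if tau > _TAU_MAX:
        penalty += (tau - _TAU_MAX) ** 2 * 100
        tau = _TAU_MAX
    tau = round(tau / _TAU_STEP) * _TAU_STEP
    two_n2 = max(4, int(round(ratio * two_n1 / 2.0)) * 2)
    t = int(round(tau * two_n2))
    f0 = _expit(logit_f0)
    f0 = min(max(f0, _F0_BOUNDS[0]), _F0_BOUNDS[1])
    return Demography(two_n1, two_n2, t), f0, penalty


def _neutral_negll(x: np.ndarray, spectra: Dict[int, np.ndarray], two_n1: int) -> float:
    demog, f0, penalty = _decode_demog(x, two_n1)
    ll = grouped_sfs_loglik(spectra, lambda n: expected_folded_sfs_neutral(demog, n), f0)
    if not math.isfinite(ll):
        return 1e12
    return -ll + penalty


def _profile_f0(
    spectra: Dict[int, np.ndarray], expected: Dict[int, np.ndarray]
) -> Tuple[float, float]:
    """Best shared f0 (and the log-likelihood there) for fixed expectations."""
    res = optimize.minimize_scalar(
        lambda z: -grouped_sfs_loglik(spectra, lambda n: expected[n], _expit(z)),
        bounds=(-9.0, 14.0), method="bounded",
        options={"xatol": 1e-5},
    )
    return _expit(res.x), -res.fun


def _fit_neutral_demography(
    spectra: Dict[int, np.ndarray],
    two_n1: int,
    n_starts: int,
    rng: np.random.Generator,
    maxiter: int,
    warm_start: Optional[Demography] = None,
) -> Tuple[Demography, float, float, bool]:
    """Coarse lattice prescreen over (ratio, tau), then local refinement.

    With ``warm_start`` the lattice is skipped and a single short local
    search runs from the given demography (bootstrap-replicate mode).
    """
    if warm_start is not None:
        tau0 = warm_start.t / warm_start.two_n2
        x0 = np.array([
            math.log(warm_start.two_n2 / two_n1), math.log1p(tau0), 0.0,
        ])
        expected = {n: expected_folded_sfs_neutral(warm_start, n)
                    for n in spectra}
        f0_w, _ = _profile_f0(spectra, expected)
        x0[2] = _logit(f0_w)
        res = optimize.minimize(
            _neutral_negll, x0, args=(spectra, two_n1),
            method="Nelder-Mead",
            options={"maxiter": min(maxiter, 60), "xatol": 1e-3,
                     "fatol": 1e-4},
        )
        demog, f0, _ = _decode_demog(res.x, two_n1)
        return demog, f0, -res.fun, True

    lattice_ratios = [0.125, 0.25, 0.5, 1.0, 2.0, 4.0]
    lattice_taus = [0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0]
    cells = []
    for ratio in lattice_ratios:
        for tau in lattice_taus:
            if ratio == 1.0 and tau > 0:
                continue  # identical to the (1, 0) equilibrium cell
            x = np.array([math.log(ratio), math.log1p(tau), 0.0])
            demog, _, _ = _decode_demog(x, two_n1)
            expected = {n: expected_folded_sfs_neutral(demog, n) for n in spectra}
            f0, ll = _profile_f0(spectra, expected)
            cells.append((ll, ratio, tau, f0))
    cells.sort(key=lambda c: -c[0])

    best = None
    for ll, ratio, tau, f0 in cells[:max(min(n_starts, len(cells)), 1)]:
        x0 = np.array([math.log(ratio), math.log1p(tau), _logit(f0)])
        res = optimize.minimize(
            _neutral_negll, x0, args=(spectra, two_n1),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    demog, f0, _ = _decode_demog(best.x, two_n1)
    return demog, f0, -best.fun, bool(best.success)


def _dfe_negll(
    x: np.ndarray,
    neutral_spectra: Dict[int, np.ndarray],
    selected_spectra: Dict[int, np.ndarray],
    neutral_expected: Dict[int, np.ndarray],
    grid: SelectionGrid,
) -> float:
    log_shape, log_mean, logit_f0 = x
    penalty = 0.0
    shape = math.exp(log_shape)
    if shape < _SHAPE_BOUNDS[0]:
        penalty += (math.log(_SHAPE_BOUNDS[0]) - log_shape) ** 2 * 100
        shape = _SHAPE_BOUNDS[0]
    elif shape > _SHAPE_BOUNDS[1]:
        penalty += (log_shape - math.log(_SHAPE_BOUNDS[1])) ** 2 * 100
        shape = _SHAPE_BOUNDS[1]
    mean_s = math.exp(log_mean)
    if mean_s < _MEANS_BOUNDS[0]:
        mean_s = _MEANS_BOUNDS[0]
    elif mean_s > _MEANS_BOUNDS[1]:
        penalty += (log_mean - math.log(_MEANS_BOUNDS[1])) ** 2 * 100
        mean_s = _MEANS_BOUNDS[1]
    f0 = _expit(logit_f0)
    f0 = min(max(f0, _F0_BOUNDS[0]), _F0_BOUNDS[1])
    ll = grouped_sfs_loglik(neutral_spectra, lambda n: neutral_expected[n], f0)
    ll += grouped_sfs_loglik(
        selected_spectra, lambda n: grid.expected_sfs(shape, mean_s, n), f0
    )
    if not math.isfinite(ll):
        return 1e12
    return -ll + penalty


def fit_ml(
    neutral: GroupedFoldedSFS,
    selected: GroupedFoldedSFS,
    grid_two_n1: int = 100,
    n_starts: int = 5,
    seed: int = 0,
    s_grid_size: int = 32,
    merge_min_sites: int = 50,
    joint_polish: bool = False,
    maxiter: int = 400,
    fixed_demography: Optional[Demography] = None,
    dfe_x0: Optional[Tuple[float, float, float]] = None,
    demog_x0: Optional[Demography] = None,
) -> DFEFit:
    """Fit gamma DFE + step-change demography to a neutral/selected SFS pair.

    ``fixed_demography`` skips the demographic stage and ``dfe_x0``
    (shape, mean_S_internal, f0) warm-starts the DFE stage; both are used
    by fast bootstrap replicates.  Deterministic under ``seed``.
    """
    if neutral.total_sites == 0 or selected.total_sites == 0:
        raise ValueError("both spectra must be non-empty")
    rng = substream(seed, "fit_ml")
    nspec = {n: v.astype(float) for n, v in
             neutral.merged_small_groups(merge_min_sites).spectra.items()}
    sspec = {n: v.astype(float) for n, v in
             selected.merged_small_groups(merge_min_sites).spectra.items()}

    if fixed_demography is None:
        demog, f0, ll_neutral, demog_ok = _fit_neutral_demography(
            nspec, grid_two_n1, min(n_starts, 2), rng, min(maxiter, 100),
            warm_start=demog_x0,
        )
    else:
        demog = fixed_demography
        total = sum(v.sum() for v in nspec.values())
        seg = sum(v[1:].sum() for v in nspec.values())
        f0 = max(1.0 - 3.0 * seg / max(total, 1.0), 0.05)
        demog_ok = True

    neutral_expected = {n: expected_folded_sfs_neutral(demog, n) for n in nspec}
    for n in sspec:
        neutral_expected.setdefault(n, expected_folded_sfs_neutral(demog, n))
    grid = _grid_for(demog, tuple(sorted(sspec)), s_grid_size)

    starts: List[Tuple[float, float, float]] = []
    if dfe_x0 is not None:
        starts.append((math.log(dfe_x0[0]), math.log(dfe_x0[1]),
                       _logit(dfe_x0[2])))
    starts += [
        (math.log(0.3), math.log(demog.n1 * 2.0), _logit(f0)),
        (math.log(0.15), math.log(demog.n1 * 20.0), _logit(f0)),
        (math.log(1.0), math.log(2.0), _logit(f0)),
        (math.log(0.5), math.log(demog.n1 * 0.5), _logit(f0)),
    ]
    while len(starts) < n_starts:
        starts.append(
            (
                rng.uniform(math.log(0.1), math.log(2.0)),
                rng.uniform(math.log(0.5), math.log(demog.n1 * 100.0)),
                _logit(f0) + rng.normal(0, 0.3),
            )
        )
    best = None
    for x0 in starts[:max(n_starts, 1)]:
        res = optimize.minimize(
            _dfe_negll, np.array(x0), args=(nspec, sspec, neutral_expected, grid),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    shape = float(np.clip(math.exp(best.x[0]), *_SHAPE_BOUNDS))
    mean_s_int = float(np.clip(math.exp(best.x[1]), *_MEANS_BOUNDS))
    f0_hat = _expit(best.x[2])
    ll_hat = -best.fun

    if joint_polish and fixed_demography is None:
        x5 = np.array([
            math.log(demog.two_n2 / grid_two_n1),
            math.log(1.0 + demog.t / demog.two_n2),
            math.log(shape), math.log(mean_s_int), _logit(f0_hat),
        ])

        def joint_negll(x):
            d, _, pen = _decode_demog(np.array([x[0], x[1], 0.0]), grid_two_n1)
            ne = {n: expected_folded_sfs_neutral(d, n)
                  for n in set(nspec) | set(sspec)}
            g = _grid_for(d, tuple(sorted(sspec)), s_grid_size)
            return _dfe_negll(x[2:], nspec, sspec, ne, g) + pen

        res = optimize.minimize(
            joint_negll, x5, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
        )
        if res.fun < best.fun:
            d, _, _ = _decode_demog(np.array([res.x[0], res.x[1], 0.0]), grid_two_n1)
            demog = d
            shape = float(np.clip(math.exp(res.x[2]), *_SHAPE_BOUNDS))
            mean_s_int = float(np.clip(math.exp(res.x[3]), *_MEANS_BOUNDS))
            f0_hat = _expit(res.x[4])
            ll_hat = -res.fun
            grid = _grid_for(demog, tuple(sorted(sspec)), s_grid_size)

    demog_model = DemographicModel(n1=demog.n1, n2=demog.n2, t=float(demog.t))
    n_w = weighted_recent_n(demog_model)
    mean_s_w = mean_s_int * n_w / demog_model.n1
    dfe = GammaDFE(shape=shape, mean_S=mean_s_w)
    fit = DFEFit(
        dfe=dfe,
        demog=demog_model,
        f0=float(f0_hat),
        loglik=float(ll_hat),
        weighted_n=n_w,
        nes_class_props=nes_class_proportions(dfe),
        mean_S_internal=mean_s_int,
        grid_two_n1=grid_two_n1,
        converged=bool(best.success) and demog_ok,
        details={
            "selection_grid": grid,
            "demography_grid": demog,
            "weighted_n_convention": "pair-coalescence stand-in: "
            "N_w = N1 (1 - f2) + N2 f2, f2 = 1 - exp(-t / (2 N2))",
        },
    )
    return fit


_grid_cache: Dict[tuple, SelectionGrid] = {}


def _grid_for(demog: Demography, ns: tuple, n_grid: int) -> SelectionGrid:
    key = (demog.two_n1, demog.two_n2, demog.t, ns, n_grid)
    if key not in _grid_cache:
        if len(_grid_cache) > 32:
            _grid_cache.clear()
        _grid_cache[key] = SelectionGrid(demog, list(ns), n_grid=n_grid)
    return _grid_cache[key]


def bootstrap_contrast_pvalue(
    boot_a: np.ndarray, boot_b: np.ndarray
) -> float:
    """Two-sided bootstrap p-value for a difference between two datasets.

    Pairs independent bootstrap replicate streams, computes the replicate
    differences, and returns 2 min(Pr(d <= 0), Pr(d >= 0)) with a +1
    continuity correction.
    """
    import warnings

    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    m = min(len(a), len(b))
    if m < 1:
        raise ValueError("empty bootstrap distributions")
    if m < 100:
        warnings.warn(f"only {m} bootstrap replicates: p-value is coarse")
    d = a[:m] - b[:m]
    p_le = (np.sum(d <= 0) + 1) / (m + 1)
    p_ge = (np.sum(d >= 0) + 1) / (m + 1)
    return float(min(2.0 * min(p_le, p_ge), 1.0))
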