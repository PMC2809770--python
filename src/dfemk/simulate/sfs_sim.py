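"""Draw population-level folded site frequency spectra for a simulated config.

Neutral site classes draw from the (possibly post-size-change) stationary
input density of segregating mutations; 0-fold sites additionally mix over a
gamma distribution of deleterious selection coefficients, discretised into
equal-mass bins.  Finite samples are drawn binomially per site and the
per-site allele number varies through the missing-data rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats as sp_stats

from dfemk._rng import substream
from dfemk.sfs import GroupedFoldedSFS
from dfemk.simulate.config import SimulationConfig
from dfemk.simulate.wright_fisher import demographic_sojourn_density

__all__ = ["simulate_population_sfs", "class_variant_model", "expected_relative_fixation"]

# s at or above this is treated as effectively lethal: no segregating mass.
_LETHAL_S = 0.99

_density_cache: Dict[Tuple[int, int, int, float], Tuple[int, np.ndarray]] = {}


def _cached_density(two_n1: int, two_n2: int, t: int, s: float):
    key = (two_n1, two_n2, t, round(float(s), 12))
    if key not in _density_cache:
        if len(_density_cache) > 256:
            _density_cache.clear()
        _density_cache[key] = demographic_sojourn_density(two_n1, two_n2, t, s)
    return _density_cache[key]


def expected_relative_fixation(shape: float, mean_s_scaled: float, n_points: int = 20000) -> float:
    """E[S / (e^S - 1)] for S ~ gamma(shape, mean): deleterious fixation rate
    relative to neutral, averaged by midpoint quadrature on the quantile scale.

    This is the generator's own calibration constant, computed independently
    of the estimator-side quadrature in :mod:`dfemk.alpha`.
    """
    if mean_s_scaled == 0:
        return 1.0
    u = (np.arange(n_points) + 0.5) / n_points
    x = sp_stats.gamma.ppf(u, a=shape, scale=mean_s_scaled / shape)
    with np.errstate(over="ignore"):
        r = np.where(x < 700, x / np.expm1(np.clip(x, 1e-300, 700)), 0.0)
    r = np.where(x < 1e-8, 1.0, r)
    return float(r.mean())


@dataclass
class VariantModel:
    """Per-site mutation model for one site class under one config.

    ``p_variant`` is the probability that a site carries a (possibly
    unobserved) segregating variant; ``freqs``/``probs`` give the population
    frequency distribution of that variant.
    """

    site_class: str
    p_variant: float
    freqs: np.ndarray
    probs: np.ndarray


_model_cache: Dict[tuple, VariantModel] = {}


def class_variant_model(config: SimulationConfig, site_class: str) -> VariantModel:
    """Build (and cache) the per-site variant model for ``site_class``."""
    selected = site_class == "0fold"
    key = (
        config.two_n1, config.two_n2, config.t_gens, config.theta_neutral,
        config.dfe_shape, config.dfe_mean_S if selected else 0.0,
        config.n_s_bins, selected,
    )
    if key in _model_cache:
        m = _model_cache[key]
        return VariantModel(site_class, m.p_variant, m.freqs, m.probs)

    two_n1, two_n2, t = config.two_n1, config.two_n2, config.t_gens
    two_n_cur, v_neutral = _cached_density(two_n1, two_n2, t, 0.0)
    freqs = np.arange(1, two_n_cur) / two_n_cur

    # calibrate the per-site mutation input so that the expected neutral
    # per-site heterozygosity equals theta_neutral
    het = 2.0 * freqs * (1.0 - freqs)
    denom = float(v_neutral @ het)
    nu = config.theta_neutral / denom if denom > 0 else 0.0

    if not selected or config.dfe_mean_S == 0:
        weights = v_neutral * nu
    else:
        n_w = config.weighted_n()
        k = config.n_s_bins
        u = (np.arange(k) + 0.5) / k
        s_w = sp_stats.gamma.ppf(u, a=config.dfe_shape,
                                 scale=config.dfe_mean_S / config.dfe_shape)
        s_raw = s_w / n_w
        weights = np.zeros_like(v_neutral)
        for s in s_raw:
            if s >= _LETHAL_S:
                continue  # effectively lethal: contributes no polymorphism
            _, v = _cached_density(two_n1, two_n2, t, float(s))
            weights += v * (nu / k)

    p_variant = float(weights.sum())
    if p_variant > 1.0:
        raise ValueError(
            f"theta_neutral={config.theta_neutral} too large for the grid: "
            f"per-site variant probability {p_variant:.3f} > 1"
        )
    probs = weights / p_variant if p_variant > 0 else weights
    model = VariantModel(site_class, p_variant, freqs, probs)
    _model_cache[key] = model
    return model


def _default_site_counts(config: SimulationConfig) -> Dict[str, int]:
    exon_total = config.n_loci * config.exon_len
    usable_intron = max(config.intron_len - 22, 0) * config.n_loci
    return {
        "0fold": int(exon_total * 0.65),
        "2fold": int(exon_total * 0.22),
        "4fold": int(exon_total * 0.13),
        "intron": int(usable_intron),
    }


def simulate_population_sfs(
    config: SimulationConfig,
    n_sites: Optional[Dict[str, int]] = None,
    seed: Optional[int] = None,
    classes: Tuple[str, ...] = ("0fold", "4fold", "intron"),
) -> Dict[str, GroupedFoldedSFS]:
    """Simulate folded sample SFSs per site class.

    Returns a mapping from site class to :class:`GroupedFoldedSFS`.  All
    randomness derives from ``seed`` (default: ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    if n_sites is None:
        n_sites = _default_site_counts(config)
    rng = substream(seed, "simulate_population_sfs")
    out: Dict[str, GroupedFoldedSFS] = {}
    n_alleles = config.n_alleles

    for site_class in classes:
        length = int(n_sites.get(site_class, 0))
        model = class_variant_model(config, site_class)
        sfs = GroupedFoldedSFS(site_class)
        if length == 0:
            out[site_class] = sfs
            continue
        if config.missing_rate > 0:
            cov = rng.binomial(n_alleles, 1.0 - config.missing_rate, size=length)
        else:
            cov = np.full(length, n_alleles)
        usable = cov >= 2
        cov = cov[usable]
        length = len(cov)

        has_variant = rng.random(length) < model.p_variant
        minor = np.zeros(length, dtype=np.int64)
        n_seg = int(has_variant.sum())
        if n_seg and model.probs.sum() > 0:
            idx = rng.choice(len(model.freqs), size=n_seg, p=model.probs)
            x = model.freqs[idx]
            derived = rng.binomial(cov[has_variant], x)
            minor[has_variant] = np.minimum(derived, cov[has_variant] - derived)

        for n in np.unique(cov):
            sel = cov == n
            vec = np.bincount(minor[sel], minlength=int(n) // 2 + 1)
            for k, c in enumerate(vec.tolist()):
                if c:
                    sfs.add_site(int(n), int(k), float(c))
        out[site_class] = sfs
    return out
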