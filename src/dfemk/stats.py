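"""Diversity, skew, divergence, inbreeding and correlation statistics.

All diversity estimators use each site's own number of called alleles;
only Tajima's D requires a fixed sample size, obtained by downsampling
every site to 20 alleles without replacement (sites with fewer are
rejected).  Confidence intervals come from bootstrapping loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sp_stats

from dfemk._rng import substream

logger = logging.getLogger(__name__)
logger.addHandler(logging.NullHandler())

__all__ = [
    "SummaryStats",
    "FisEstimate",
    "harmonic_number",
    "theta_pi_from_counts",
    "theta_w_from_counts",
    "class_base_counts",
    "theta_pi",
    "theta_w",
    "tajima_d",
    "tajima_d_constants",
    "jc_correct",
    "jc_divergence",
    "divergence_counts",
    "bootstrap_by_locus",
    "fis_weir_cockerham",
    "fis_per_snp",
    "ne_from_diversity",
    "diversity_divergence_correlation",
    "summarize_class",
]


@dataclass
class SummaryStats:
    site_class: str
    n_sites: int
    seg_sites: int
    theta_pi: float
    theta_w: float
    tajima_d: Optional[float]
    d_close: Optional[float]
    d_far: Optional[float]
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)


@dataclass
class FisEstimate:
    snp_id: str
    f_is: float
    genotype_counts: Tuple[int, int, int]  # (hom ref-like, het, hom alt)


@dataclass
class NeEstimate:
    theta_pi: float
    mu: float
    ne: float


def harmonic_number(k: int) -> float:
    """a_n = sum_{i=1..k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def class_base_counts(locus, site_class: str, cpg_filter=None) -> np.ndarray:
    """(4, n_sites) A/C/G/T allele counts at sites of one class."""
    mask = locus.class_mask(site_class, cpg_filter=cpg_filter)
    return locus.base_counts()[:, mask]


def theta_pi_from_counts(counts: np.ndarray) -> Tuple[float, int]:
    """Average per-site heterozygosity from a (4, n_sites) count matrix.

    Per site the unbiased estimator (n/(n-1)) (1 - sum p_k^2) with that
    site's own n; sites with coverage < 2 are skipped.  Returns
    (per-site average, number of usable sites).
    """
    n = counts.sum(axis=0)
    usable = n >= 2
    n_used = int(usable.sum())
    if n_used == 0:
        return 0.0, 0
    c = counts[:, usable].astype(float)
    nn = n[usable].astype(float)
    het = (nn / (nn - 1.0)) * (1.0 - ((c / nn) ** 2).sum(axis=0))
    return float(het.sum() / n_used), n_used


def theta_w_from_counts(counts: np.ndarray) -> Tuple[float, int, int]:
    """Watterson's estimator with per-site n: mean of I(segregating)/a_{n-1}.

    Returns (per-site theta_W, number of segregating sites, usable sites).
    """
    n = counts.sum(axis=0)
    usable = n >= 2
    n_used = int(usable.sum())
    if n_used == 0:
        return 0.0, 0, 0
    c = counts[:, usable]
    nn = n[usable]
    seg = (c > 0).sum(axis=0) >= 2
    a = np.array([harmonic_number(int(k) - 1) for k in nn])
    contrib = np.where(seg, 1.0 / a, 0.0)
    return float(contrib.sum() / n_used), int(seg.sum()), n_used


def _pooled_counts(loci, site_class, cpg_filter=None) -> np.ndarray:
    mats = [class_base_counts(l, site_class, cpg_filter) for l in loci]
    if not mats:
        return np.zeros((4, 0), dtype=np.int64)
    return np.concatenate(mats, axis=1)


def theta_pi(loci, site_class: str, cpg_filter=None) -> float:
    return theta_pi_from_counts(_pooled_counts(loci, site_class, cpg_filter))[0]


def theta_w(loci, site_class: str, cpg_filter=None) -> float:
    return theta_w_from_counts(_pooled_counts(loci, site_class, cpg_filter))[0]


def tajima_d_constants(n: int) -> dict:
    """The standard variance constants of Tajima's D for sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_sfs(minor_counts: Sequence[int], n: int) -> Optional[float]:
    """Tajima's D from per-site minor allele counts at fixed sample size n."""
    ks = np.asarray([k for k in minor_counts if 0 < k], dtype=float)
    s = len(ks)
    if s == 0:
        return None
    const = tajima_d_constants(n)
    pi = float(np.sum(ks * (n - ks)) / (n * (n - 1) / 2.0))
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    if var <= 0:
        return None
    return (pi - s / const["a1"]) / math.sqrt(var)


def tajima_d(
    loci,
    site_class: str,
    fixed_n: int = 20,
    seed: int = 0,
    cpg_filter=None,
    rng: Optional[np.random.Generator] = None,
) -> Optional[float]:
    """Tajima's D after downsampling every site to ``fixed_n`` alleles.

    At each site with coverage >= fixed_n, ``fixed_n`` alleles are sampled
    uniformly without replacement; sites with lower coverage are rejected.
    Returns None when no segregating site survives.
    """
    if rng is None:
        rng = substream(seed, "tajima_d")
    minor = []
    for locus in loci:
        counts = class_base_counts(locus, site_class, cpg_filter)
        n = counts.sum(axis=0)
        ok = n >= fixed_n
        for j in np.flatnonzero(ok):
            sub = rng.multivariate_hypergeometric(counts[:, j], fixed_n)
            nb = (sub > 0).sum()
            if nb > 2:
                continue  # triallelic after downsampling: exclude
            minor.append(int(fixed_n - sub.max()))
    if not minor:
        logger.info("tajima_d: no usable sites at fixed_n=%d", fixed_n)
        return None
    return tajima_d_from_sfs(minor, fixed_n)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        raise ValueError(f"JC correction undefined for p = {p} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence_counts(loci, site_class: str, outgroup: str, cpg_filter=None) -> Tuple[int, int]:
    """(differing, valid) site counts between the sample and an outgroup.

    A site counts as divergent when the outgroup base is called and differs
    from every called sample allele; sites lacking a called outgroup base or
    any called sample allele are excluded from both counts.  Polymorphic
    sites whose alleles all differ from the outgroup count once as
    divergent.
    """
    if outgroup not in ("close", "far"):
        raise ValueError("outgroup must be 'close' or 'far'")
    n_diff = n_valid = 0
    for locus in loci:
        mask = locus.class_mask(site_class, cpg_filter=cpg_filter)
        out_seq = (locus.outgroup_close if outgroup == "close" else locus.outgroup_far)
        counts = locus.base_counts()[:, mask]
        cov = counts.sum(axis=0)
        ob = out_seq[mask]
        called_out = np.isin(ob, np.array(list("ACGT")))
        valid = called_out & (cov >= 1)
        if not valid.any():
            continue
        base_index = np.full(ob.shape, -1)
        for i, b in enumerate("ACGT"):
            base_index[ob == b] = i
        cv = np.flatnonzero(valid)
        out_count = counts[base_index[cv], cv]
        n_valid += len(cv)
        n_diff += int((out_count == 0).sum())
    return n_diff, n_valid


def jc_divergence(loci, site_class: str, outgroup: str, cpg_filter=None) -> Optional[float]:
    """JC-corrected per-site divergence to the chosen outgroup."""
    n_diff, n_valid = divergence_counts(loci, site_class, outgroup, cpg_filter)
    if n_valid == 0:
        return None
    return jc_correct(n_diff / n_valid)


def bootstrap_by_locus(
    statistic: Callable[[list], Optional[float]],
    loci: list,
    n_boot: int = 1000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Percentile CI and SD-based SE of a statistic under locus resampling."""
    if len(loci) < 1:
        raise ValueError("need at least one locus")
    if rng is None:
        rng = substream(seed, "bootstrap_by_locus")
    values = []
    n_undef = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(loci), size=len(loci))
        v = statistic([loci[i] for i in idx])
        if v is None or not np.isfinite(v):
            n_undef += 1
        else:
            values.append(v)
    flagged = n_undef > n_boot / 2
    if flagged:
        logger.warning("bootstrap: statistic undefined in %d/%d replicates",
                       n_undef, n_boot)
    arr = np.array(values)
    if len(arr) == 0:
        return {"se": math.nan, "ci": (math.nan, math.nan),
                "values": arr, "flagged": True}
    return {
        "se": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "ci": (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        "values": arr,
        "flagged": flagged,
    }


def fis_weir_cockerham(genotype_counts: Tuple[int, int, int]) -> float:
    """Weir & Cockerham (1984) single-population small-sample f for one SNP.

    ``genotype_counts`` are (homozygote allele 1, heterozygote, homozygote
    allele 2) individual counts.  Undefined (raises) for monomorphic SNPs.
    """
    n11, n12, n22 = genotype_counts
    n = n11 + n12 + n22
    if n < 2:
        raise ValueError("need at least two genotyped individuals")
    p = (2 * n11 + n12) / (2.0 * n)
    if p in (0.0, 1.0):
        raise ValueError("monomorphic SNP: f undefined")
    h_obs = n12 / n
    b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h_obs)
    c = h_obs / 2.0
    if b + c == 0:
        return 0.0
    return float(1.0 - c / (b + c))


def fis_per_snp(loci, site_classes=("4fold", "intron"), min_individuals: int = 2) -> List[FisEstimate]:
    """Weir-Cockerham f for every biallelic SNP in the chosen classes."""
    out: List[FisEstimate] = []
    for locus in loci:
        mask = np.zeros(locus.length, dtype=bool)
        for cls in site_classes:
            mask |= locus.class_mask(cls)
        counts = locus.base_counts()
        nb = (counts > 0).sum(axis=0)
        snp_sites = np.flatnonzero(mask & (nb == 2))
        a = locus.alleles
        n_ind = a.shape[0] // 2
        for j in snp_sites:
            col_a, col_b = a[0::2, j], a[1::2, j]
            called = np.isin(col_a, np.array(list("ACGT"))) & \
                np.isin(col_b, np.array(list("ACGT")))
            if called.sum() < min_individuals:
                continue
            ca, cb = col_a[called], col_b[called]
            bases = sorted(set(ca) | set(cb))
            if len(bases) != 2:
                continue
            b1, b2 = bases
            g11 = int(((ca == b1) & (cb == b1)).sum())
            g22 = int(((ca == b2) & (cb == b2)).sum())
            g12 = int(len(ca) - g11 - g22)
            try:
                f = fis_weir_cockerham((g11, g12, g22))
            except ValueError:
                continue
            out.append(FisEstimate(f"{locus.locus_id}:{j + 1}", f, (g11, g12, g22)))
    return out


def ne_from_diversity(theta_pi_value: float, mu: float, sig_figs: int = 2) -> float:
    """N_e from theta_pi = 4 N_e mu, rounded to ``sig_figs`` significant figures."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if theta_pi_value < 0:
        raise ValueError("theta_pi must be non-negative")
    ne = theta_pi_value / (4.0 * mu)
    if ne == 0 or sig_figs is None:
        return ne
    exponent = math.floor(math.log10(abs(ne)))
    factor = 10.0 ** (exponent - sig_figs + 1)
    return round(ne / factor) * factor


def diversity_divergence_correlation(
    per_locus_divergence: Sequence[float],
    per_locus_diversity: Sequence[float],
) -> Tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with two-sided p."""
    x = np.asarray(per_locus_divergence, dtype=float)
    y = np.asarray(per_locus_diversity, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired loci")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    r, p = sp_stats.spearmanr(x, y)
    return float(r), float(p)


def summarize_class(
    loci,
    site_class: str,
    cpg_filter=None,
    n_boot: int = 0,
    fixed_n: int = 20,
    seed: int = 0,
) -> SummaryStats:
    """Table-1-style summary for one site class, optionally with bootstrap SEs."""
    counts = _pooled_counts(loci, site_class, cpg_filter)
    pi, n_used = theta_pi_from_counts(counts)
    tw, seg, _ = theta_w_from_counts(counts)
    d = tajima_d(loci, site_class, fixed_n=fixed_n, seed=seed, cpg_filter=cpg_filter)
    dc = jc_divergence(loci, site_class, "close", cpg_filter)
    df = jc_divergence(loci, site_class, "far", cpg_filter)
    stats = SummaryStats(site_class, n_used, seg, pi, tw, d, dc, df)
    if n_boot > 0:
        stat_fns = {
            "theta_pi": lambda ls: theta_pi(ls, site_class, cpg_filter),
            "theta_w": lambda ls: theta_w(ls, site_class, cpg_filter),
            "tajima_d": lambda ls: tajima_d(ls, site_class, fixed_n=fixed_n,
                                            seed=seed, cpg_filter=cpg_filter),
            "d_close": lambda ls: jc_divergence(ls, site_class, "close", cpg_filter),
            "d_far": lambda ls: jc_divergence(ls, site_class, "far", cpg_filter),
        }
        import zlib

        for name, fn in stat_fns.items():
            res = bootstrap_by_locus(fn, list(loci), n_boot=n_boot,
                                     seed=seed + zlib.crc32(name.encode()) % 10_000)
            stats.se[name] = res["se"]
            stats.ci[name] = res["ci"]
    return stats
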