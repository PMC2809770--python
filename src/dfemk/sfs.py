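"""Folded site frequency spectra grouped by per-site sampled allele number.

Sites with different numbers of called alleles cannot be pooled into one
spectrum, so spectra are kept per sample size n and the likelihood machinery
sums over groups.  Folding convention: entry k of the size-n spectrum counts
sites whose minor allele is carried by k of n alleles (k = 0 holds
monomorphic sites); the central cell k = n/2 for even n is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import stats as sp_stats

logging.getLogger(__name__).addHandler(logging.NullHandler())
logger = logging.getLogger(__name__)

__all__ = [
    "GroupedFoldedSFS",
    "build_grouped_folded_sfs",
    "downsample_sfs",
    "fold_vector",
    "one_allele_resample",
]

_MISSING = {"N", "-", "n"}


@dataclass
class GroupedFoldedSFS:
    """Folded minor-allele-count spectra grouped by sample size."""

    site_class: str
    spectra: Dict[int, np.ndarray] = field(default_factory=dict)
    n_triallelic_excluded: int = 0

    def add_site(self, n: int, minor_count: int, weight: float = 1.0) -> None:
        if n < 2:
            raise ValueError(f"sample size must be >= 2, got {n}")
        if not 0 <= minor_count <= n // 2:
            raise ValueError(f"minor count {minor_count} invalid for n={n}")
        if n not in self.spectra:
            self.spectra[n] = np.zeros(n // 2 + 1)
        self.spectra[n][minor_count] += weight

    @property
    def total_sites(self) -> float:
        return float(sum(v.sum() for v in self.spectra.values()))

    @property
    def n_segregating(self) -> float:
        return float(sum(v[1:].sum() for v in self.spectra.values()))

    def sample_sizes(self) -> List[int]:
        return sorted(self.spectra)

    def merged_small_groups(self, min_sites: int = 50) -> "GroupedFoldedSFS":
        """Merge sparsely populated n-groups into larger groups.

        Groups with fewer than ``min_sites`` sites are projected
        (hypergeometrically) down to the nearest retained smaller n.  If no
        smaller group is retained, everything left over is projected to the
        smallest retained n; when no group passes the threshold all groups
        are projected to the smallest n present.
        """
        if not self.spectra:
            return GroupedFoldedSFS(self.site_class, {},
                                    self.n_triallelic_excluded)
        retained = [n for n in self.sample_sizes()
                    if self.spectra[n].sum() >= min_sites]
        if not retained:
            retained = [min(self.sample_sizes())]
        out: Dict[int, np.ndarray] = {
            n: self.spectra[n].astype(float).copy() for n in retained
        }
        small = [n for n in self.sample_sizes() if n not in retained]
        # groups below every retained n cannot be projected upward; pool
        # them into their own group at the smallest such n instead
        leftovers = [n for n in small if n < min(retained)]
        if leftovers:
            pool = min(leftovers)
            out[pool] = out.get(pool, np.zeros(pool // 2 + 1))
        for n in small:
            candidates = [m for m in retained if m <= n]
            target = max(candidates) if candidates else min(leftovers)
            out[target] = out[target] + downsample_sfs(self.spectra[n], n, target)
        return GroupedFoldedSFS(self.site_class, out, self.n_triallelic_excluded)

    def pooled(self, m: int) -> np.ndarray:
        """Project every group down to size m and sum (groups with n < m dropped)."""
        total = np.zeros(m // 2 + 1)
        for n, vec in self.spectra.items():
            if n >= m:
                total += downsample_sfs(vec, n, m)
        return total


def fold_vector(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded count/probability vector of length n+1 to length n//2+1."""
    unfolded = np.asarray(unfolded, dtype=float)
    n = len(unfolded) - 1
    half = n // 2
    folded = np.zeros(half + 1)
    for i in range(half + 1):
        j = n - i
        folded[i] = unfolded[i] + (unfolded[j] if j != i else 0.0)
    return folded


def build_grouped_folded_sfs(
    loci: Iterable,
    site_class: str,
    cpg_filter: Optional[bool] = None,
    min_coverage: int = 2,
) -> GroupedFoldedSFS:
    """Tally the folded SFS for one site class across annotated loci.

    ``cpg_filter=False`` keeps only non-CpG-prone sites (``True`` the
    complement; ``None`` keeps everything).  Biallelic polymorphisms only;
    sites with three or more sampled bases are excluded and counted.
    """
    sfs = GroupedFoldedSFS(site_class)
    for locus in loci:
        mask = locus.class_mask(site_class, cpg_filter=cpg_filter)
        counts = locus.base_counts()[:, mask]   # (4, n_sites)
        n = counts.sum(axis=0)
        usable = n >= min_coverage
        counts = counts[:, usable]
        n = n[usable]
        n_bases = (counts > 0).sum(axis=0)
        tri = n_bases > 2
        if tri.any():
            sfs.n_triallelic_excluded += int(tri.sum())
            counts = counts[:, ~tri]
            n = n[~tri]
        minor = n - counts.max(axis=0)
        for nn, mm in zip(n.tolist(), minor.tolist()):
            sfs.add_site(int(nn), int(mm))
    return sfs


def downsample_sfs(folded: np.ndarray, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of a folded size-n spectrum to size m.

    Sites are projected without replacement; the projected minor counts are
    refolded.  ``m == n`` is the identity.
    """
    folded = np.asarray(folded, dtype=float)
    if len(folded) != n // 2 + 1:
        raise ValueError(f"folded spectrum has wrong length for n={n}")
    if m < 2:
        raise ValueError("target sample size must be >= 2")
    if m > n:
        raise ValueError(f"cannot project n={n} up to m={m}")
    if m == n:
        return folded.copy()
    out = np.zeros(m // 2 + 1)
    j = np.arange(m + 1)
    for k in range(n // 2 + 1):
        if folded[k] == 0:
            continue
        # P(j minor alleles in subsample of m | k of n), exchangeable draws
        pj = sp_stats.hypergeom.pmf(j, n, k, m)
        out += folded[k] * fold_vector(pj)
    return out


def one_allele_resample(loci, n_datasets: int = 20, seed: int = 0, rng=None):
    """Build composite one-allele-per-individual datasets.

    For every individual and every site one of the individual's two alleles
    is picked at random (uniformly among called alleles; missing only if
    both are missing), yielding datasets of at most ``n_individuals``
    sequences.  Returns a list of ``n_datasets`` lists of loci.
    """
    import copy

    if rng is None:
        rng = np.random.default_rng(seed)
    datasets = []
    for _ in range(n_datasets):
        new_loci = []
        for locus in loci:
            n_alleles, length = locus.alleles.shape
            if n_alleles % 2 != 0:
                raise ValueError(
                    f"locus {locus.locus_id}: odd number of alleles, cannot pair"
                )
            n_ind = n_alleles // 2
            a = locus.alleles[0::2, :]
            b = locus.alleles[1::2, :]
            pick_b = rng.integers(0, 2, size=(n_ind, length)).astype(bool)
            chosen = np.where(pick_b, b, a)
            other = np.where(pick_b, a, b)
            # if the picked allele is uncalled but the other is called, take it
            miss = np.isin(chosen, list(_MISSING))
            chosen = np.where(miss & ~np.isin(other, list(_MISSING)), other, chosen)
            new = copy.copy(locus)
            new.alleles = chosen
            new.allele_names = [f"ind{i:02d}" for i in range(n_ind)]
            new.invalidate_caches()
            new_loci.append(new)
        datasets.append(new_loci)
    return datasets
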