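"""Generate per-locus multi-individual alignments with known ground truth.

Each locus is laid out as CDS / intron / CDS (the internal intron exercises
splice-window exclusion and frame handling downstream).  Divergence is
placed on the sample lineage (the close outgroup stays identical to the
ancestor), with extra substitutions on the far outgroup branch calibrated so
the pairwise divergences hit their targets.  Polymorphism is injected from
the same population-frequency densities used by
:func:`dfemk.simulate.sfs_sim.simulate_population_sfs`, adaptive 0-fold
substitutions are added so their fraction of 0-fold divergence equals
``alpha_true``, and inbreeding duplicates one allele draw per individual
per locus with probability F.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from dfemk._rng import substream
from dfemk.codons import BASES, STOP_CODONS, GENETIC_CODE, classify_degeneracy
from dfemk.simulate.config import SimulationConfig
from dfemk.simulate.sfs_sim import class_variant_model, expected_relative_fixation

__all__ = ["RawLocus", "LocusSet", "generate_locus_set", "write_locus_set", "read_locus_set"]

_SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


@dataclass
class RawLocus:
    """One locus: aligned sequences plus feature annotation."""

    locus_id: str
    reference: str
    allele_names: List[str]
    alleles: List[str]
    outgroup_close: str
    outgroup_far: str
    # (start, end, feature, frame, strand); BED-style 0-based half-open
    features: List[Tuple[int, int, str, int, str]]

    def __post_init__(self) -> None:
        length = len(self.reference)
        for seq in list(self.alleles) + [self.outgroup_close, self.outgroup_far]:
            if len(seq) != length:
                raise ValueError(f"{self.locus_id}: unequal sequence lengths")


@dataclass
class LocusSet:
    loci: List[RawLocus]
    truth: Dict


def _jc_inverse(d: float) -> float:
    """Raw proportion of differing sites giving JC-corrected divergence d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _far_branch_p(p_total: float, p_sample: float) -> float:
    """Extra substitution probability on the far-outgroup branch.

    Under uniform random replacement bases, two lineages that both
    substituted agree with probability 1/3, so the pairwise differing
    probability is p_s + p_f (1 - 4 p_s / 3).
    """
    denom = 1.0 - 4.0 * p_sample / 3.0
    return max((p_total - p_sample) / denom, 0.0) if denom > 0 else 0.0


def _random_other_base(rng: np.random.Generator, base_idx: np.ndarray) -> np.ndarray:
    """Uniformly pick an index in 0..3 different from base_idx (vectorised)."""
    shift = rng.integers(1, 4, size=base_idx.shape)
    return (base_idx + shift) % 4


def _reference_for_locus(
    rng: np.random.Generator, exon_len: int, intron_len: int
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int, str, int, str]]]:
    """Build a reference sequence, per-site true classes and features."""
    n_codons = exon_len // 3
    codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    transcript = "".join(_SENSE_CODONS[i] for i in codon_idx)

    t_classes = np.empty(exon_len, dtype="<U8")
    for c in range(n_codons):
        codon = transcript[3 * c: 3 * c + 3]
        for p in range(3):
            t_classes[3 * c + p] = classify_degeneracy(codon, p + 1)

    exon_a = exon_len // 2
    exon_b = exon_len - exon_a
    intron_start = exon_a
    intron_end = exon_a + intron_len
    total = exon_len + intron_len

    seq = np.empty(total, dtype="<U1")
    seq[:exon_a] = list(transcript[:exon_a])
    intron_bases = rng.integers(0, 4, size=intron_len)
    seq[intron_start:intron_end] = [BASES[i] for i in intron_bases]
    seq[intron_end:] = list(transcript[exon_a:])

    classes = np.empty(total, dtype="<U8")
    classes[:exon_a] = t_classes[:exon_a]
    classes[intron_end:] = t_classes[exon_a:]
    classes[intron_start:intron_end] = "intron"
    # splice windows: first 6 and last 16 intronic bases are excluded
    if intron_len > 0:
        left = min(6, intron_len)
        classes[intron_start:intron_start + left] = "excluded"
        right = min(16, intron_len)
        classes[max(intron_end - right, intron_start):intron_end] = "excluded"

    frame_b = (3 - exon_a % 3) % 3
    features = [
        (0, exon_a, "CDS", 0, "+"),
        (intron_start, intron_end, "intron", -1, "+"),
        (intron_end, total, "CDS", frame_b, "+"),
    ]
    if intron_len == 0:
        features = [(0, exon_len, "CDS", 0, "+")]
    return seq, classes, features


def generate_locus_set(
    config: SimulationConfig,
    seed: Optional[int] = None,
    out_dir: Optional[str] = None,
) -> LocusSet:
    """Generate ``config.n_loci`` annotated loci plus a ground-truth record.

    When ``out_dir`` is given the FASTA alignments, feature table and truth
    JSON are also written there.
    """
    if seed is None:
        seed = config.seed
    rng = substream(seed, "generate_locus_set")

    # substitution probabilities per class (raw, per site)
    e_r = expected_relative_fixation(config.dfe_shape, config.dfe_mean_S)
    a = config.alpha_true
    d_close_0fold = config.div_neutral_close * e_r / (1.0 - a)
    d_far_0fold = config.div_neutral_far * e_r / (1.0 - a)

    p_s_neutral = _jc_inverse(config.div_neutral_close)
    p_s_0fold = _jc_inverse(d_close_0fold)
    p_far_total_neutral = _jc_inverse(config.div_neutral_far)
    p_far_total_0fold = _jc_inverse(d_far_0fold)
    p_f_neutral = _far_branch_p(p_far_total_neutral, p_s_neutral)
    p_f_0fold = _far_branch_p(p_far_total_0fold, p_s_0fold)

    models = {
        cls: class_variant_model(config, cls)
        for cls in ("0fold", "2fold", "4fold", "intron")
    }
    base_to_idx = {b: i for i, b in enumerate(BASES)}
    base_arr = np.array(BASES)

    loci: List[RawLocus] = []
    class_totals: Dict[str, int] = {}

    for li in range(config.n_loci):
        ref, classes, features = _reference_for_locus(
            rng, config.exon_len, config.intron_len
        )
        total = len(ref)
        for cls in ("0fold", "2fold", "4fold", "intron", "excluded"):
            class_totals[cls] = class_totals.get(cls, 0) + int((classes == cls).sum())

        ref_idx = np.array([base_to_idx[b] for b in ref])
        is_sel = classes == "0fold"

        # sample-lineage substitutions (ancestor -> sampled population)
        p_sub = np.where(is_sel, p_s_0fold, p_s_neutral)
        sub_mask = rng.random(total) < p_sub
        sample_idx = ref_idx.copy()
        sample_idx[sub_mask] = _random_other_base(rng, ref_idx[sub_mask])

        # far outgroup branch
        p_far = np.where(is_sel, p_f_0fold, p_f_neutral)
        far_mask = rng.random(total) < p_far
        far_idx = ref_idx.copy()
        far_idx[far_mask] = _random_other_base(rng, ref_idx[far_mask])

        # polymorphism on the sample background
        n_ind = config.n_individuals
        n_alleles = config.n_alleles
        allele_idx = np.broadcast_to(sample_idx, (n_alleles, total)).copy()

        ibd = rng.random(n_ind) < config.inbreeding_F

        for cls, model in models.items():
            cls_sites = np.flatnonzero(classes == cls)
            if cls_sites.size == 0 or model.p_variant <= 0:
                continue
            seg = cls_sites[rng.random(cls_sites.size) < model.p_variant]
            if seg.size == 0:
                continue
            x = model.freqs[rng.choice(len(model.freqs), size=seg.size, p=model.probs)]
            var_idx = _random_other_base(rng, sample_idx[seg])
            for pos, freq, vb in zip(seg.tolist(), x.tolist(), var_idx.tolist()):
                draws = rng.random((n_ind, 2)) < freq
                draws[ibd, 1] = draws[ibd, 0]  # identical by descent pair
                carriers = draws.reshape(-1)
                allele_idx[carriers, pos] = vb

        alleles = base_arr[allele_idx]
        if config.missing_rate > 0:
            miss = rng.random((n_alleles, total)) < config.missing_rate
            alleles[miss] = "N"

        names = []
        for i in range(n_ind):
            names.extend([f"ind{i:02d}_a", f"ind{i:02d}_b"])
        loci.append(
            RawLocus(
                locus_id=f"locus{li:03d}",
                reference="".join(ref),
                allele_names=names,
                alleles=["".join(row) for row in alleles],
                outgroup_close="".join(base_arr[ref_idx]),
                outgroup_far="".join(base_arr[far_idx]),
                features=features,
            )
        )

    truth = {
        "config": config.to_dict(),
        "seed": int(seed),
        "weighted_n": config.weighted_n(),
        "expected_relative_fixation": e_r,
        "alpha_true": config.alpha_true,
        "class_site_totals": class_totals,
        "p_substitution": {
            "neutral_sample_branch": p_s_neutral,
            "0fold_sample_branch": p_s_0fold,
            "neutral_far_branch": p_f_neutral,
            "0fold_far_branch": p_f_0fold,
        },
        "divergence_targets": {
            "close_neutral": config.div_neutral_close,
            "far_neutral": config.div_neutral_far,
            "close_0fold": d_close_0fold,
            "far_0fold": d_far_0fold,
        },
    }
    locus_set = LocusSet(loci=loci, truth=truth)
    if out_dir is not None:
        write_locus_set(locus_set, out_dir)
    return locus_set


def write_locus_set(locus_set: LocusSet, out_dir: str) -> None:
    """Write FASTA alignments, the feature table and the truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    feat_path = os.path.join(out_dir, "features.tsv")
    with open(feat_path, "w") as fh:
        fh.write("locus\tstart\tend\tfeature\tframe\tstrand\n")
        for locus in locus_set.loci:
            for start, end, feature, frame, strand in locus.features:
                frame_s = "." if frame < 0 else str(frame)
                fh.write(f"{locus.locus_id}\t{start}\t{end}\t{feature}\t{frame_s}\t{strand}\n")
            path = os.path.join(out_dir, f"{locus.locus_id}.fasta")
            with open(path, "w") as fa:
                fa.write(f">reference\n{locus.reference}\n")
                for name, seq in zip(locus.allele_names, locus.alleles):
                    fa.write(f">{name}\n{seq}\n")
                fa.write(f">outgroup_close\n{locus.outgroup_close}\n")
                fa.write(f">outgroup_far\n{locus.outgroup_far}\n")
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(locus_set.truth, fh, indent=1)


def read_locus_set(in_dir: str) -> LocusSet:
    """Read a locus set previously written by :func:`write_locus_set`."""
    from Bio import SeqIO

    feat_by_locus: Dict[str, List[Tuple[int, int, str, int, str]]] = {}
    with open(os.path.join(in_dir, "features.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            locus_id, start, end, feature, frame, strand = line.rstrip("\n").split("\t")
            fr = -1 if frame == "." else int(frame)
            feat_by_locus.setdefault(locus_id, []).append(
                (int(start), int(end), feature, fr, strand)
            )
    loci = []
    for locus_id in sorted(feat_by_locus):
        path = os.path.join(in_dir, f"{locus_id}.fasta")
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
        allele_names = sorted(
            n for n in records
            if n not in ("reference", "outgroup_close", "outgroup_far")
        )
        loci.append(
            RawLocus(
                locus_id=locus_id,
                reference=records["reference"],
                allele_names=allele_names,
                alleles=[records[n] for n in allele_names],
                outgroup_close=records["outgroup_close"],
                outgroup_far=records["outgroup_far"],
                features=feat_by_locus[locus_id],
            )
        )
    truth_path = os.path.join(in_dir, "ground_truth.json")
    truth = {}
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            truth = json.load(fh)
    return LocusSet(loci=loci, truth=truth)
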