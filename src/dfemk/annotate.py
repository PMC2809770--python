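"""Per-site annotation: degeneracy class, splice exclusion, CpG status, coverage.

Degeneracy is assigned from the reference codon (annotation follows the
reference, not the sampled alleles).  Codons containing gaps, ambiguity
codes or encoding stops are excluded, as are partial codons at feature
boundaries.  Splice windows (first 6 bp / last 16 bp of each intron, in
transcript orientation) are excluded from the intron class.  A site is
CpG-prone when any aligned sequence, in any species, has a C immediately
before it or a G immediately after it; sites at alignment edges are
conservatively treated as prone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from dfemk.codons import classify_degeneracy, GENETIC_CODE, STOP_CODONS

logger = logging.getLogger(__name__)
logger.addHandler(logging.NullHandler())

__all__ = [
    "AnnotatedLocus",
    "annotate_locus",
    "annotate_loci",
    "mark_splice_windows",
    "cpg_prone_status",
    "per_site_coverage",
    "classify_degeneracy",
    "annotation_table",
]

SITE_CLASSES = ("0fold", "2fold", "4fold", "intron", "excluded")
_VALID = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}

SPLICE_DONOR_BP = 6     # excluded at the transcript-5' end of each intron
SPLICE_ACCEPTOR_BP = 16  # excluded at the transcript-3' end


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1").astype("<U1")


@dataclass
class AnnotatedLocus:
    """A locus alignment with per-site class, CpG status and coverage."""

    locus_id: str
    allele_names: List[str]
    alleles: np.ndarray          # (n_alleles, L) of single characters
    reference: np.ndarray        # (L,)
    outgroup_close: np.ndarray
    outgroup_far: np.ndarray
    site_class: np.ndarray       # (L,) strings from SITE_CLASSES
    cpg_prone: np.ndarray        # (L,) bool
    features: List[Tuple[int, int, str, int, str]] = field(default_factory=list)
    _coverage: Optional[np.ndarray] = field(default=None, repr=False)
    _base_counts: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        length = self.reference.shape[0]
        for arr in (self.alleles[0] if len(self.alleles) else self.reference,
                    self.outgroup_close, self.outgroup_far,
                    self.site_class, self.cpg_prone):
            if arr.shape[-1] != length:
                raise ValueError(f"{self.locus_id}: inconsistent array lengths")

    @property
    def length(self) -> int:
        return int(self.reference.shape[0])

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    def invalidate_caches(self) -> None:
        self._coverage = None
        self._base_counts = None

    @property
    def coverage(self) -> np.ndarray:
        """Number of non-missing sample alleles per site (outgroups not counted)."""
        if self._coverage is None:
            self._coverage = per_site_coverage(self.alleles)
        return self._coverage

    def base_counts(self) -> np.ndarray:
        """(4, L) counts of A/C/G/T among sample alleles per site."""
        if self._base_counts is None:
            self._base_counts = np.stack(
                [(self.alleles == b).sum(axis=0) for b in "ACGT"]
            )
        return self._base_counts

    def class_mask(
        self, site_class: str, cpg_filter: Optional[bool] = None
    ) -> np.ndarray:
        """Boolean mask of sites in ``site_class``; CpG filter optional.

        ``cpg_filter=False`` restricts to non-CpG-prone sites.
        """
        if site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {site_class!r}")
        mask = self.site_class == site_class
        if cpg_filter is not None:
            mask = mask & (self.cpg_prone == bool(cpg_filter))
        return mask


def per_site_coverage(alleles: np.ndarray) -> np.ndarray:
    """Count called (A/C/G/T) sample alleles at each site."""
    return np.isin(alleles, _VALID).sum(axis=0).astype(np.int64)


def mark_splice_windows(
    length: int,
    intron_spans: Iterable[Tuple[int, int]],
    strand: str = "+",
) -> np.ndarray:
    """Flag splice-window positions of each intron as excluded.

    The first 6 bp and last 16 bp of every intron (transcript orientation)
    are flagged; introns of 22 bp or shorter are excluded entirely.
    """
    excluded = np.zeros(length, dtype=bool)
    for start, end in intron_spans:
        if start < 0 or end > length or end < start:
            raise ValueError(f"intron span ({start}, {end}) outside locus")
        ilen = end - start
        if ilen <= SPLICE_DONOR_BP + SPLICE_ACCEPTOR_BP:
            excluded[start:end] = True
            continue
        head, tail = (SPLICE_DONOR_BP, SPLICE_ACCEPTOR_BP)
        if strand == "-":
            head, tail = tail, head
        excluded[start:start + head] = True
        excluded[end - tail:end] = True
    return excluded


def cpg_prone_status(sequences: np.ndarray) -> np.ndarray:
    """Per-site CpG-prone flags from an (n_seqs, L) alignment stack.

    True wherever any sequence has C at the preceding position or G at the
    following position; alignment-edge sites are treated as prone.
    """
    n_seqs, length = sequences.shape
    prone = np.zeros(length, dtype=bool)
    if length == 0:
        return prone
    prone[1:] |= (sequences[:, :-1] == "C").any(axis=0)
    prone[:-1] |= (sequences[:, 1:] == "G").any(axis=0)
    prone[0] = True
    prone[-1] = True
    return prone


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return np.array([_COMPLEMENT.get(b, "N") for b in arr[::-1]], dtype="<U1")


def _classify_cds(
    locus_id: str,
    reference: np.ndarray,
    cds_features: Sequence[Tuple[int, int, str, int, str]],
) -> np.ndarray:
    """Per-site classes for all CDS positions (others left as '')."""
    length = reference.shape[0]
    classes = np.full(length, "", dtype="<U8")
    if not cds_features:
        return classes
    strand = cds_features[0][4]
    spans = sorted((f[0], f[1]) for f in cds_features)
    order = spans if strand == "+" else spans[::-1]

    genomic_positions: List[int] = []
    for start, end in order:
        pos = range(start, end) if strand == "+" else range(end - 1, start - 1, -1)
        genomic_positions.extend(pos)

    frames = {(f[0], f[1]): f[3] for f in cds_features}
    frame0 = frames[(order[0][0], order[0][1])]
    if frame0 < 0:
        frame0 = 0

    transcript = np.array([
        reference[p] if strand == "+" else _COMPLEMENT.get(reference[p], "N")
        for p in genomic_positions
    ], dtype="<U1")

    t_len = len(transcript)
    t_classes = np.full(t_len, "excluded", dtype="<U8")
    start = frame0
    n_codons = (t_len - start) // 3
    if start:
        logger.info("%s: %d leading bases excluded (frame offset)", locus_id, start)
    leftover = t_len - start - 3 * n_codons
    if leftover:
        logger.info("%s: %d trailing bases form a partial codon, excluded",
                    locus_id, leftover)
    for c in range(n_codons):
        i = start + 3 * c
        codon = "".join(transcript[i:i + 3])
        if codon not in GENETIC_CODE or codon in STOP_CODONS:
            continue  # stays excluded: gap, ambiguity or stop codon
        for p in range(3):
            t_classes[i + p] = classify_degeneracy(codon, p + 1)

    for t_pos, g_pos in enumerate(genomic_positions):
        classes[g_pos] = t_classes[t_pos]
    return classes


def annotate_locus(raw) -> AnnotatedLocus:
    """Annotate a :class:`dfemk.simulate.loci.RawLocus`-like object.

    The input needs ``locus_id``, ``reference``, ``allele_names``,
    ``alleles`` (list of strings), ``outgroup_close``, ``outgroup_far`` and
    ``features`` (start, end, feature, frame, strand).
    """
    reference = _seq_array(raw.reference)
    alleles = np.stack([_seq_array(s) for s in raw.alleles])
    out_close = _seq_array(raw.outgroup_close)
    out_far = _seq_array(raw.outgroup_far)
    length = reference.shape[0]

    cds = [f for f in raw.features if f[2] == "CDS"]
    introns = [f for f in raw.features if f[2] == "intron"]
    strands = {f[4] for f in raw.features}
    if len(strands) > 1:
        raise ValueError(f"{raw.locus_id}: mixed strands among features")
    strand = strands.pop() if strands else "+"

    cds_mask = np.zeros(length, dtype=bool)
    for start, end, *_ in cds:
        cds_mask[start:end] = True
    for start, end, *_ in introns:
        if cds_mask[start:end].any():
            raise ValueError(f"{raw.locus_id}: intron overlaps CDS")

    classes = np.full(length, "excluded", dtype="<U8")
    cds_classes = _classify_cds(raw.locus_id, reference, cds)
    has_cds_class = cds_classes != ""
    classes[has_cds_class] = cds_classes[has_cds_class]
    intron_spans = [(f[0], f[1]) for f in introns]
    splice = mark_splice_windows(length, intron_spans, strand=strand)
    for start, end in intron_spans:
        span = np.zeros(length, dtype=bool)
        span[start:end] = True
        classes[span & ~splice] = "intron"
        classes[span & splice] = "excluded"

    stack = np.vstack([reference[None, :], alleles, out_close[None, :], out_far[None, :]])
    prone = cpg_prone_status(stack)

    return AnnotatedLocus(
        locus_id=raw.locus_id,
        allele_names=list(raw.allele_names),
        alleles=alleles,
        reference=reference,
        outgroup_close=out_close,
        outgroup_far=out_far,
        site_class=classes,
        cpg_prone=prone,
        features=list(raw.features),
    )


def annotate_loci(raw_loci: Iterable) -> List[AnnotatedLocus]:
    return [annotate_locus(r) for r in raw_loci]


def annotation_table(locus: AnnotatedLocus):
    """Per-site annotation as a DataFrame (positions reported 1-based)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "locus": locus.locus_id,
            "pos": np.arange(1, locus.length + 1),
            "class": locus.site_class,
            "cpg_prone": locus.cpg_prone,
            "coverage": locus.coverage,
        }
    )
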