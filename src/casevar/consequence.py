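"""Coding consequences and substitution-spectrum classes.

Maps variants onto gene models (1-based inclusive CDS segments in
translation order), translates reference and alternate codons with the
standard genetic code, and classifies the protein-level effect:
synonymous, missense, stop_gain, frameshift, inframe_indel, or noncoding.
Protein notation is a simplified HGVS dialect: three-letter amino-acid
codes, "*" for stop, a bare "fs" suffix for frameshifts.

Spectrum classes follow the usual definitions: transitions are the
purine<->purine and pyrimidine<->pyrimidine substitutions (A<->G, C<->T),
all other single-base changes are transversions; an anchored indel is an
insertion when the alternate allele is longer than the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "GeneModel",
    "Consequence",
    "codon_of",
    "annotate",
    "substitution_class",
    "indel_class",
    "spectrum_summary",
    "TRANSITION",
    "TRANSVERSION",
    "INSERTION",
    "DELETION",
]

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class GeneModel:
    """A transcript's coding model: CDS segments as 1-based inclusive
    genomic intervals listed in translation order (descending coordinates
    on the minus strand)."""

    gene: str
    transcript: str
    chrom: str
    strand: str  # "+" or "-"
    cds_segments: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError("CDS segment start must not exceed end")

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def span(self) -> Tuple[int, int]:
        starts = [s for s, _ in self.cds_segments]
        ends = [e for _, e in self.cds_segments]
        return (min(starts), max(ends))

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, or None outside CDS."""
        offset = 0
        for start, end in self.cds_segments:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start) + 1
                return offset + (end - pos) + 1
            offset += end - start + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic position of a 1-based CDS coordinate."""
        if cds_pos < 1 or cds_pos > self.cds_length:
            raise ValueError("cds_pos outside CDS")
        remaining = cds_pos - 1
        for start, end in self.cds_segments:
            seg_len = end - start + 1
            if remaining < seg_len:
                return start + remaining if self.strand == "+" else end - remaining
            remaining -= seg_len
        raise AssertionError("unreachable")

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Coding-strand CDS sequence assembled from the genome."""
        contig = genome[self.chrom]
        parts = []
        for start, end in self.cds_segments:
            seg = contig[start - 1 : end]
            if self.strand == "-":
                seg = seg.translate(_COMPLEMENT)[::-1]
            parts.append(seg)
        return "".join(parts).upper()


@dataclass(frozen=True)
class Consequence:
    """Protein-level effect of a variant on one transcript."""

    gene: str
    transcript: str
    kind: str  # synonymous | missense | stop_gain | frameshift | inframe_indel | noncoding
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    hgvs_p: Optional[str] = None
    splice_region: bool = False


def codon_of(cds_pos: int) -> int:
    """1-based codon index of a 1-based CDS nucleotide position: ceil(pos/3).

    CDS position 601 lies in codon 201 (the "c.601" / "p.201" arithmetic of
    transcript-relative notation).
    """
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return math.ceil(cds_pos / 3)


def _aa_of(codon: str) -> str:
    """Single-letter amino acid, '*' for stop."""
    if codon.upper() in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def _protein_notation(ref_aa: str, codon_index: int, alt_aa: str) -> str:
    ref3 = "Ter" if ref_aa == "*" else seq3(ref_aa)
    alt3 = "*" if alt_aa == "*" else seq3(alt_aa)
    return f"p.{ref3}{codon_index}{alt3}"


def annotate(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: Mapping[str, str],
) -> Consequence:
    """Consequence of one anchored variant on one transcript.

    Reverse-strand models have their alleles complemented before
    translation.  A variant whose changed bases are not entirely within the
    CDS is reported as noncoding with the splice-region flag set, for the
    downstream splice-overlap selection criterion.
    """
    if chrom != model.chrom:
        return Consequence(model.gene, model.transcript, "noncoding")

    if len(ref) == 1 and len(alt) == 1:
        cds_pos = model.genomic_to_cds(pos)
        if cds_pos is None:
            return Consequence(model.gene, model.transcript, "noncoding")
        cds = model.cds_sequence(genome)
        idx = codon_of(cds_pos)
        codon_start = (idx - 1) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        if len(ref_codon) < 3:  # incomplete terminal codon
            return Consequence(model.gene, model.transcript, "noncoding")
        ref_base, alt_base = ref.upper(), alt.upper()
        if model.strand == "-":
            ref_base = ref_base.translate(_COMPLEMENT)
            alt_base = alt_base.translate(_COMPLEMENT)
        within = (cds_pos - 1) % 3
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = _aa_of(ref_codon)
        alt_aa = _aa_of(alt_codon)
        if alt_aa == ref_aa:
            kind = "synonymous"
        elif alt_aa == "*":
            kind = "stop_gain"
        else:
            kind = "missense"
        return Consequence(
            gene=model.gene,
            transcript=model.transcript,
            kind=kind,
            cds_pos=cds_pos,
            codon_index=idx,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            hgvs_p=_protein_notation(ref_aa, idx, alt_aa),
        )

    # Anchored indel: the changed bases start after the shared anchor base.
    first_changed = pos + 1
    last_changed = pos + max(len(ref), len(alt)) - 1
    cds_first = model.genomic_to_cds(first_changed)
    cds_last = model.genomic_to_cds(last_changed)
    if cds_first is None or cds_last is None:
        # spans a CDS boundary (or lies outside): splice-region candidate
        near = model.genomic_to_cds(pos) is not None or cds_first is not None
        return Consequence(
            model.gene, model.transcript, "noncoding", splice_region=near
        )
    length_change = abs(len(alt) - len(ref))
    cds_pos = min(cds_first, cds_last)
    idx = codon_of(cds_pos)
    cds = model.cds_sequence(genome)
    codon_start = (idx - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    ref_aa = _aa_of(ref_codon) if len(ref_codon) == 3 else None
    if length_change % 3 != 0:
        kind = "frameshift"
        hgvs = f"p.{seq3(ref_aa)}{idx}fs" if ref_aa and ref_aa != "*" else f"p.{idx}fs"
    else:
        kind = "inframe_indel"
        hgvs = None
    return Consequence(
        gene=model.gene,
        transcript=model.transcript,
        kind=kind,
        cds_pos=cds_pos,
        codon_index=idx,
        ref_aa=ref_aa,
        alt_aa=None,
        hgvs_p=hgvs,
    )


def substitution_class(ref: str, alt: str) -> str:
    """Transition (A<->G, C<->T) or transversion, for single-base changes."""
    r, a = ref.upper(), alt.upper()
    if len(r) != 1 or len(a) != 1 or r == a:
        raise ValueError("substitution_class requires two distinct single bases")
    return TRANSITION if (r, a) in _TRANSITIONS else TRANSVERSION


def indel_class(ref: str, alt: str) -> str:
    """Insertion iff the alternate allele is longer than the reference."""
    if len(ref) == len(alt):
        raise ValueError("indel_class requires alleles of different length")
    return INSERTION if len(alt) > len(ref) else DELETION


def spectrum_summary(
    variants: Iterable[Tuple[str, str]],
) -> Tuple[int, int, int, int]:
    """Counts of (transitions, transversions, insertions, deletions) over
    (ref, alt) allele pairs."""
    ti = tv = ins = dele = 0
    for ref, alt in variants:
        if len(ref) == 1 and len(alt) == 1:
            if substitution_class(ref, alt) == TRANSITION:
                ti += 1
            else:
                tv += 1
        else:
            if indel_class(ref, alt) == INSERTION:
                ins += 1
            else:
                dele += 1
    return (ti, tv, ins, dele)
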