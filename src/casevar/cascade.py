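"""Damaging-variant selection and exclusion filter cascade.

Two stages, both audited per variant:

1. *Selection* keeps variants with a probable functional effect — any of:
   flagged as a clinical SNP, present in a somatic-cancer mutation
   catalogue (Cosmic-style), predicted probably-damaging by a
   PolyPhen-style tool or damaging by a SIFT-style tool, overlapping a
   splice site, creating a stop codon, or being an indel that alters the
   protein.  "Possibly damaging" and "tolerated"/NA predictions do not
   qualify.

2. *Exclusion* removes variants seen in any of the control exomes
   (panel of normals), listed with a population frequency strictly above
   1%, located within segmental duplications, or lying in blacklisted
   gene families (TTN, MUC*, OR<digit>*) that are prone to alignment
   artefacts.

Every filter outcome is recorded for every variant (a FilterTrace), so the
set of survivors is independent of evaluation order and each rejection can
be attributed to the exact filters that fired.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .classify import GERMLINE, SOMATIC, ClassifiedVariant
from .consequence import Consequence
from .pileup import VariantObservation

__all__ = [
    "AnnotationRecord",
    "FilterTrace",
    "ControlPanel",
    "SegDupIndex",
    "select_damaging",
    "exclusion_filters",
    "run_cascade",
    "gene_blacklisted",
    "EXCLUSION_FILTERS",
    "SELECTION_FILTER",
]

logger = logging.getLogger(__name__)

SELECTION_FILTER = "damaging_selection"
EXCLUSION_FILTERS = ("control_panel", "dbsnp_common", "segdup", "gene_blacklist")

DBSNP_COMMON_THRESHOLD = 0.01  # excluded only when strictly above 1%
_OR_FAMILY = re.compile(r"OR\d")

VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant evidence consumed by the cascade."""

    variant_key: VariantKey
    gene: str
    clinical_snp: bool = False
    in_cosmic: bool = False
    polyphen: str = "NA"  # benign | possibly_damaging | probably_damaging | NA
    sift: str = "NA"      # tolerated | damaging | NA
    splice_site_overlap: bool = False
    dbsnp_pop_freq: Optional[float] = None
    in_segdup: bool = False

    def __post_init__(self) -> None:
        if self.dbsnp_pop_freq is not None and not 0.0 <= self.dbsnp_pop_freq <= 1.0:
            raise ValueError("dbsnp_pop_freq must lie in [0, 1]")


@dataclass
class FilterTrace:
    """Ordered record of every filter outcome for one variant."""

    entries: List[Tuple[str, str]] = field(default_factory=list)  # (name, pass|fail)

    def record(self, name: str, passed: bool) -> None:
        self.entries.append((name, "pass" if passed else "fail"))

    @property
    def final(self) -> bool:
        return all(outcome == "pass" for _, outcome in self.entries)

    @property
    def failed_filters(self) -> List[str]:
        return [name for name, outcome in self.entries if outcome == "fail"]


class ControlPanel:
    """Presence matrix of variants across unrelated control exomes.

    Only variants seen in at least one control are stored; absence means a
    zero carrier count.
    """

    def __init__(
        self, carriers: Mapping[VariantKey, int] | None = None, n_samples: int = 97
    ) -> None:
        self.n_samples = n_samples
        self._carriers: Dict[VariantKey, int] = dict(carriers or {})

    def carrier_count(self, key: VariantKey) -> int:
        return self._carriers.get(key, 0)

    def __contains__(self, key: VariantKey) -> bool:
        return self.carrier_count(key) > 0

    def items(self):
        return self._carriers.items()

    def __len__(self) -> int:
        return len(self._carriers)


class SegDupIndex:
    """Segmental-duplication intervals, built from 0-based half-open (BED)
    records and queried with 1-based positions."""

    def __init__(self, bed_records: Iterable[Tuple[str, int, int]] = ()) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        for chrom, start, end in bed_records:
            if end <= start:
                raise ValueError("BED interval must have end > start")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos - 1, pos))  # 1-based point -> 0-based


def gene_blacklisted(gene: str) -> bool:
    """True for TTN (exact), the MUC family (prefix), and olfactory-receptor
    symbols (OR followed by a digit, so ORC1 does not match)."""
    return gene == "TTN" or gene.startswith("MUC") or bool(_OR_FAMILY.match(gene))


def select_damaging(
    variant: VariantObservation,
    consequence: Optional[Consequence],
    annotation: AnnotationRecord,
) -> bool:
    """True iff any selection criterion holds (see module docstring)."""
    kind = consequence.kind if consequence is not None else None
    splice = annotation.splice_site_overlap or (
        consequence is not None and consequence.splice_region
    )
    protein_altering_indel = variant.is_indel and kind in ("frameshift", "inframe_indel")
    return (
        annotation.clinical_snp
        or annotation.in_cosmic
        or annotation.polyphen == "probably_damaging"
        or annotation.sift == "damaging"
        or splice
        or kind == "stop_gain"
        or protein_altering_indel
    )


def exclusion_filters(
    variant: VariantObservation,
    annotation: AnnotationRecord,
    panel: ControlPanel,
    segdups: Optional[SegDupIndex] = None,
) -> FilterTrace:
    """Evaluate every exclusion filter; all outcomes are recorded.

    Segmental-duplication overlap comes from the annotation flag, or is
    recomputed from a SegDupIndex when one is supplied.
    """
    in_segdup = annotation.in_segdup or (
        segdups is not None and segdups.overlaps(variant.chrom, variant.pos)
    )
    freq = annotation.dbsnp_pop_freq
    trace = FilterTrace()
    trace.record("control_panel", variant.key not in panel)
    trace.record("dbsnp_common", freq is None or freq <= DBSNP_COMMON_THRESHOLD)
    trace.record("segdup", not in_segdup)
    trace.record("gene_blacklist", not gene_blacklisted(annotation.gene))
    return trace


def run_cascade(
    classified_variants: Sequence[ClassifiedVariant],
    annotations: Mapping[VariantKey, AnnotationRecord],
    panel: ControlPanel,
    consequences: Mapping[VariantKey, Consequence] | None = None,
    segdups: Optional[SegDupIndex] = None,
) -> Tuple[List[ClassifiedVariant], List[ClassifiedVariant], Dict[VariantKey, FilterTrace]]:
    """Run selection + exclusion over classified variants.

    Returns (somatic survivors, germline survivors, per-variant traces).
    Somatic and germline variants pass through the identical cascade; a
    variant with no annotation record is excluded with a single
    "unannotated" trace entry and a warning.
    """
    consequences = consequences or {}
    somatic_final: List[ClassifiedVariant] = []
    germline_final: List[ClassifiedVariant] = []
    traces: Dict[VariantKey, FilterTrace] = {}

    for cv in classified_variants:
        key = cv.key
        ann = annotations.get(key)
        if ann is None:
            logger.warning("variant %s:%d %s>%s has no annotation; excluded",
                           *key)
            trace = FilterTrace()
            trace.record("unannotated", False)
            traces[key] = trace
            continue
        trace = FilterTrace()
        trace.record(
            SELECTION_FILTER,
            select_damaging(cv.tumour, consequences.get(key), ann),
        )
        exclusion = exclusion_filters(cv.tumour, ann, panel, segdups)
        trace.entries.extend(exclusion.entries)
        traces[key] = trace
        if trace.final:
            if cv.status == SOMATIC:
                somatic_final.append(cv)
            elif cv.status == GERMLINE:
                germline_final.append(cv)
    return somatic_final, germline_final, traces
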