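"""DNA-to-RNA variant-expression integration.

For each DNA variant, the tumour RNA pileup at the site decides whether the
variant allele, only the reference allele, or neither is expressed.  An
allele counts as detected when at least ``min_reads`` RNA observations
support it at base quality >= ``min_quality``.  Raw counts are reported
even below threshold so reports can render "No (0)" vs "Yes (35)" style
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from .pileup import PileupColumn

__all__ = [
    "ExpressionStatus",
    "expression_status",
    "split_summary",
    "VARIANT_EXPRESSED",
    "REF_ONLY",
    "NOT_EXPRESSED",
]

VARIANT_EXPRESSED = "variant_expressed"
REF_ONLY = "ref_only"
NOT_EXPRESSED = "not_expressed"

DEFAULT_MIN_READS = 1
DEFAULT_MIN_QUALITY = 20


@dataclass(frozen=True)
class ExpressionStatus:
    """Expression state of one DNA variant in tumour RNA."""

    variant_key: Tuple[str, int, str, str]
    state: str
    rna_alt_count: int
    rna_ref_count: int
    rna_af: Optional[float]  # percent, None when no allele-informative reads


def expression_status(
    variant_key: Tuple[str, int, str, str],
    rna_column: Optional[PileupColumn],
    min_reads: int = DEFAULT_MIN_READS,
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> ExpressionStatus:
    """Classify a variant's expression from the RNA pileup at its site.

    An empty or missing column yields not_expressed with zero counts.
    Observations supporting alleles other than the variant's ref/alt are
    ignored for the allele fraction.
    """
    chrom, pos, ref, alt = variant_key
    alt_count = ref_count = 0
    if rna_column is not None:
        for obs in rna_column.observations:
            if obs.base_quality < min_quality:
                continue
            if obs.allele == alt:
                alt_count += 1
            elif obs.allele == ref:
                ref_count += 1
    if alt_count >= min_reads:
        state = VARIANT_EXPRESSED
    elif ref_count >= min_reads:
        state = REF_ONLY
    else:
        state = NOT_EXPRESSED
    total = alt_count + ref_count
    af = 100.0 * alt_count / total if total > 0 else None
    return ExpressionStatus(
        variant_key=variant_key,
        state=state,
        rna_alt_count=alt_count,
        rna_ref_count=ref_count,
        rna_af=af,
    )


def split_summary(statuses: Iterable[ExpressionStatus]) -> Tuple[int, int, int]:
    """Counts of (variant_expressed, ref_only, not_expressed); the three
    states partition the input."""
    ve = ro = ne = 0
    for s in statuses:
        if s.state == VARIANT_EXPRESSED:
            ve += 1
        elif s.state == REF_ONLY:
            ro += 1
        else:
            ne += 1
    return (ve, ro, ne)
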