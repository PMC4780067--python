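"""Per-sample variant calling from pileup columns.

A pileup column is the stack of read observations overlapping one genomic
position in one sample.  Each observation carries the allele the read
supports, the base quality at the site, and the number of gaps/mismatches
the read shows inside a fixed window centred on the site (a proxy for local
alignment quality).  Calling is a pure threshold rule: observations failing
the read-level filters leave both numerator and denominator, and a
non-reference allele is emitted when its surviving count and its fraction of
surviving depth both clear the sample's thresholds.

Indel alleles use anchored (VCF-style) representation: a deletion of G after
T is written ref="TG", alt="T"; an insertion of A after T is ref="T",
alt="TA".  Empty alleles are forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

__all__ = [
    "CallerParams",
    "PileupColumn",
    "ReadObservation",
    "VariantObservation",
    "call_variants",
    "tumour_preset",
    "blood_preset",
]

# Guard against float representation artefacts when comparing a count ratio
# with a fractional threshold (e.g. 4/80 vs 0.05); thresholds are inclusive.
_FRACTION_EPS = 1e-9


@dataclass(frozen=True)
class CallerParams:
    """Per-sample calling thresholds.

    Parameters
    ----------
    max_gapmm_in_window:
        Maximum number of gaps/mismatches a read may show within ``window_bp``
        around the site; reads above this leave the pileup.
    window_bp:
        Width of the gap/mismatch window in bp (odd, centred on the site).
    min_base_quality:
        Minimum Phred base quality for an observation to count.
    min_read_count:
        Minimum number of surviving reads supporting the alternate allele.
    min_allele_fraction:
        Minimum alternate fraction of the surviving depth, in [0, 1].
    """

    max_gapmm_in_window: int
    min_base_quality: int
    min_read_count: int
    min_allele_fraction: float
    window_bp: int = 21

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.window_bp % 2 == 0:
            raise ValueError("window_bp must be odd and positive")
        if not 0.0 <= self.min_allele_fraction <= 1.0:
            raise ValueError("min_allele_fraction must lie in [0, 1]")
        if self.min_read_count < 0 or self.max_gapmm_in_window < 0:
            raise ValueError("count thresholds must be non-negative")


def tumour_preset() -> CallerParams:
    """Thresholds for the tumour DNA sample (also applied to tumour RNA):
    at most 2 gaps/mismatches in 21 bp, base quality >= 30, alternate read
    count >= 4, allele fraction >= 5%."""
    return CallerParams(
        max_gapmm_in_window=2,
        min_base_quality=30,
        min_read_count=4,
        min_allele_fraction=0.05,
    )


def blood_preset() -> CallerParams:
    """Thresholds for the constitutional (blood) DNA sample: at most 3
    gaps/mismatches in 21 bp, base quality >= 25, alternate read count >= 1,
    allele fraction >= 2%."""
    return CallerParams(
        max_gapmm_in_window=3,
        min_base_quality=25,
        min_read_count=1,
        min_allele_fraction=0.02,
    )


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at a site: supported allele (anchored string),
    Phred base quality, and gap/mismatch count in the local window."""

    allele: str
    base_quality: int
    gapmm_in_window: int


@dataclass
class PileupColumn:
    """All read observations at one site of one sample.

    ``ref`` is the anchored reference allele string at the site; an
    observation supporting the reference carries ``allele == ref``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    observations: List[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class VariantObservation:
    """A called variant in one sample.

    ``depth_pass`` counts observations surviving the read-level filters;
    ``af`` is the alternate fraction of ``depth_pass``, in percent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth_pass: int
    af: float

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def site(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)


def call_variants(column: PileupColumn, params: CallerParams) -> List[VariantObservation]:
    """Call variants at one pileup column.

    An observation survives iff its base quality is at least
    ``params.min_base_quality`` and its gap/mismatch count is at most
    ``params.max_gapmm_in_window``.  A non-reference allele is emitted iff
    its surviving count reaches ``min_read_count`` and its fraction of the
    surviving depth reaches ``min_allele_fraction``.  Multi-allelic sites
    emit one record per qualifying alternate, ordered by descending count
    then lexicographically by allele.

    Raises
    ------
    ValueError
        If any observation has a negative base quality or an empty allele.
    """
    surviving: List[ReadObservation] = []
    for obs in column.observations:
        if obs.base_quality < 0:
            raise ValueError(
                f"negative base quality at {column.chrom}:{column.pos}"
            )
        if not obs.allele:
            raise ValueError(f"empty allele at {column.chrom}:{column.pos}")
        if (
            obs.base_quality >= params.min_base_quality
            and obs.gapmm_in_window <= params.max_gapmm_in_window
        ):
            surviving.append(obs)

    depth_pass = len(surviving)
    if depth_pass == 0:
        return []

    counts: dict[str, int] = {}
    for obs in surviving:
        if obs.allele != column.ref:
            counts[obs.allele] = counts.get(obs.allele, 0) + 1

    calls: List[VariantObservation] = []
    for allele, count in counts.items():
        if count < params.min_read_count:
            continue
        if count / depth_pass + _FRACTION_EPS < params.min_allele_fraction:
            continue
        calls.append(
            VariantObservation(
                chrom=column.chrom,
                pos=column.pos,
                ref=column.ref,
                alt=allele,
                alt_count=count,
                depth_pass=depth_pass,
                af=100.0 * count / depth_pass,
            )
        )
    calls.sort(key=lambda v: (-v.alt_count, v.alt))
    return calls
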