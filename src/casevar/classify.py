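"""Somatic/germline classification of tumour variants against the blood sample.

A tumour variant is *somatic* when the blood sample shows no qualifying
alternate read under the blood calling thresholds and blood coverage at the
site reaches a minimum (8 reads), so that absence is informative.  It is
*germline* when the variant is also called in blood with an allele fraction
of at least 20% and at least 4 alternate reads.  Everything in between —
insufficient blood coverage, or low-level blood evidence below the germline
thresholds — is *unclassifiable*: neither confidently somatic nor germline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .pileup import VariantObservation

__all__ = ["ClassifiedVariant", "classify", "SOMATIC", "GERMLINE", "UNCLASSIFIABLE"]

SOMATIC = "somatic"
GERMLINE = "germline"
UNCLASSIFIABLE = "unclassifiable"

# Cross-sample thresholds.
MIN_BLOOD_DEPTH_SOMATIC = 8     # blood coverage needed to trust absence
GERMLINE_MIN_BLOOD_AF = 20.0    # percent, in blood
GERMLINE_MIN_BLOOD_COUNT = 4    # alternate reads in blood


@dataclass(frozen=True)
class ClassifiedVariant:
    """A tumour variant with its cross-sample status.

    ``blood_observation`` is the matching blood call (same chrom/pos/ref/alt)
    when one exists; ``blood_depth`` is the raw blood read coverage at the
    site, available whether or not blood called the variant.
    """

    tumour: VariantObservation
    blood_observation: Optional[VariantObservation]
    blood_depth: int
    status: str

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return self.tumour.key


def classify(
    tumour_calls: Iterable[VariantObservation],
    blood_calls: Iterable[VariantObservation],
    blood_depths: Mapping[Tuple[str, int], int],
) -> List[ClassifiedVariant]:
    """Assign somatic/germline/unclassifiable status to each tumour call.

    Parameters
    ----------
    tumour_calls, blood_calls:
        Variant observations from the tumour and blood samples (blood called
        with the more permissive blood thresholds, so that any qualifying
        blood evidence is visible).
    blood_depths:
        Raw blood read coverage keyed by (chrom, pos); required for every
        tumour-call site.

    Raises
    ------
    ValueError
        If blood coverage is missing at a tumour-call site.
    """
    blood_by_key: Dict[Tuple[str, int, str, str], VariantObservation] = {
        b.key: b for b in blood_calls
    }
    out: List[ClassifiedVariant] = []
    for t in tumour_calls:
        if t.site not in blood_depths:
            raise ValueError(
                f"no blood depth available at tumour-call site {t.chrom}:{t.pos}"
            )
        depth = blood_depths[t.site]
        b = blood_by_key.get(t.key)
        if b is None:
            status = SOMATIC if depth >= MIN_BLOOD_DEPTH_SOMATIC else UNCLASSIFIABLE
        elif b.af >= GERMLINE_MIN_BLOOD_AF and b.alt_count >= GERMLINE_MIN_BLOOD_COUNT:
            status = GERMLINE
        else:
            status = UNCLASSIFIABLE
        out.append(
            ClassifiedVariant(
                tumour=t, blood_observation=b, blood_depth=depth, status=status
            )
        )
    return out
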