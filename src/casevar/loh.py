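"""Loss-of-heterozygosity detection and tumour-purity estimation.

A constitutionally heterozygous variant sits near 50% allele fraction in
blood; somatic loss of the wild-type allele shifts the tumour fraction
toward 100%, stopping short of it in proportion to the normal-cell
admixture.  LOH is called when the blood-to-tumour allele-fraction shift
exceeds a minimum (default 20 percentage points) and a two-sided Fisher
exact test on the 2x2 allele-count table is significant (default alpha
0.01).

Purity p (tumour-cell fraction of the sample) is recovered from the tumour
allele fraction under an explicit copy model:

* single_copy_deletion — tumour cells retain one variant copy, normal cells
  are diploid heterozygous: af = 1/(2-p), so p = 2 - 1/af.
* copy_neutral — tumour cells carry two variant copies: af = (1+p)/2, so
  p = 2*af - 1.

The analogous RNA model with tumour transcript fraction f (tumour
transcripts all variant, normal transcripts balanced) predicts an RNA
allele fraction of (1+f)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from scipy.stats import fisher_exact

from .pileup import VariantObservation

__all__ = [
    "LohCall",
    "test_loh",
    "estimate_purity",
    "expected_af",
    "rna_consistency",
    "SINGLE_COPY_DELETION",
    "COPY_NEUTRAL",
    "DEFAULT_MIN_DELTA",
    "DEFAULT_ALPHA",
]

SINGLE_COPY_DELETION = "single_copy_deletion"
COPY_NEUTRAL = "copy_neutral"
_MODELS = (SINGLE_COPY_DELETION, COPY_NEUTRAL)

DEFAULT_MIN_DELTA = 20.0  # percentage points of allele-fraction shift
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class LohCall:
    """LOH decision and purity estimate for one germline variant."""

    variant_key: Tuple[str, int, str, str]
    af_blood: Optional[float]   # percent
    af_tumour: Optional[float]  # percent
    delta_af: Optional[float]   # percentage points
    p_value: Optional[float]
    is_loh: bool
    model: str
    purity_estimate: Optional[float]


def expected_af(purity: float, model: str) -> float:
    """Forward model: tumour allele fraction at an LOH site given purity."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if model == SINGLE_COPY_DELETION:
        return 1.0 / (2.0 - purity)
    if model == COPY_NEUTRAL:
        return (1.0 + purity) / 2.0
    raise ValueError(f"unknown copy model {model!r}")


def estimate_purity(af_tumour: float, model: str) -> Optional[float]:
    """Invert the copy model; af_tumour is a fraction in (0.5, 1].

    Returns None when af_tumour <= 0.5 (no LOH signal to invert).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown copy model {model!r}")
    if af_tumour > 1.0:
        raise ValueError("allele fraction cannot exceed 1")
    if af_tumour <= 0.5:
        return None
    if model == SINGLE_COPY_DELETION:
        return 2.0 - 1.0 / af_tumour
    return 2.0 * af_tumour - 1.0


def test_loh(
    blood_obs: Optional[VariantObservation],
    tumour_obs: Optional[VariantObservation],
    min_delta: float = DEFAULT_MIN_DELTA,
    alpha: float = DEFAULT_ALPHA,
    model: str = SINGLE_COPY_DELETION,
) -> LohCall:
    """Test one germline-classified variant for LOH.

    The 2x2 table contrasts alternate/reference counts (within filtered
    depth) between blood and tumour; the p-value is the two-sided Fisher
    exact probability.  Zero filtered depth in either sample yields an NA
    call (is_loh False, p None).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown copy model {model!r}")
    key = (tumour_obs or blood_obs).key if (tumour_obs or blood_obs) else None
    if (
        blood_obs is None
        or tumour_obs is None
        or blood_obs.depth_pass == 0
        or tumour_obs.depth_pass == 0
    ):
        return LohCall(
            variant_key=key,
            af_blood=blood_obs.af if blood_obs else None,
            af_tumour=tumour_obs.af if tumour_obs else None,
            delta_af=None,
            p_value=None,
            is_loh=False,
            model=model,
            purity_estimate=None,
        )
    b_alt, b_ref = blood_obs.alt_count, blood_obs.depth_pass - blood_obs.alt_count
    t_alt, t_ref = tumour_obs.alt_count, tumour_obs.depth_pass - tumour_obs.alt_count
    _, p = fisher_exact([[b_alt, b_ref], [t_alt, t_ref]], alternative="two-sided")
    delta = tumour_obs.af - blood_obs.af
    is_loh = delta >= min_delta and p <= alpha
    purity = estimate_purity(tumour_obs.af / 100.0, model) if is_loh else None
    return LohCall(
        variant_key=tumour_obs.key,
        af_blood=blood_obs.af,
        af_tumour=tumour_obs.af,
        delta_af=delta,
        p_value=p,
        is_loh=is_loh,
        model=model,
        purity_estimate=purity,
    )


def rna_consistency(
    af_rna: float, tumour_transcript_fraction: float
) -> Tuple[float, float]:
    """Expected RNA allele fraction at an LOH site, and the deviation of the
    observed fraction from it.

    Under equal per-cell expression with tumour transcript fraction f
    (tumour transcripts all variant, normal transcripts heterozygous
    balanced), the expected fraction is (1+f)/2.  Both arguments and both
    returns are fractions in [0, 1]; the second return is observed minus
    expected.  The tumour transcript fraction is a parameter independent of
    DNA purity: expression contamination need not equal cellular
    contamination.
    """
    if not 0.0 <= tumour_transcript_fraction <= 1.0:
        raise ValueError("tumour_transcript_fraction must lie in [0, 1]")
    expected = (1.0 + tumour_transcript_fraction) / 2.0
    return expected, af_rna - expected
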