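"""Pipeline orchestration, case-level summary statistics and standard-format I/O.

Stage order: per-sample calling -> somatic/germline classification ->
damaging-selection + exclusion cascade -> coding consequences ->
RNA-expression integration -> LOH/purity -> summary.  All coordinates in
outputs are 1-based inclusive (VCF/TSV convention); BED input is 0-based
half-open and converted at the boundary.  Allele fractions in reports are
percent to one decimal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .cascade import (
    AnnotationRecord,
    ControlPanel,
    FilterTrace,
    SegDupIndex,
    run_cascade,
)
from .classify import GERMLINE, SOMATIC, ClassifiedVariant, classify
from .consequence import Consequence, GeneModel, annotate, spectrum_summary
from .loh import DEFAULT_ALPHA, DEFAULT_MIN_DELTA, LohCall, test_loh
from .pileup import PileupColumn, VariantObservation, blood_preset, call_variants, tumour_preset
from .rna import ExpressionStatus, expression_status, split_summary
from .simulate import BLOOD_SAMPLE, RNA_SAMPLE, SOMATIC_SAMPLE, CaseBundle

__all__ = [
    "CaseSummary",
    "PipelineResult",
    "mutation_rate",
    "run_pipeline",
    "write_vcf",
    "read_vcf",
]

logger = logging.getLogger(__name__)

VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class CaseSummary:
    """Headline numbers of one analysed case."""

    n_somatic: int
    mutation_rate_per_mb: float
    spectrum: Tuple[int, int, int, int]  # transitions, transversions, ins, del
    n_germline: int
    n_germline_genes: int
    expression_split: Tuple[int, int, int]  # germline: expressed / ref-only / silent
    loh_calls: int

    def to_dict(self) -> dict:
        return {
            "n_somatic": self.n_somatic,
            "mutation_rate_per_mb": self.mutation_rate_per_mb,
            "transitions": self.spectrum[0],
            "transversions": self.spectrum[1],
            "insertions": self.spectrum[2],
            "deletions": self.spectrum[3],
            "n_germline": self.n_germline,
            "n_germline_genes": self.n_germline_genes,
            "germline_variant_expressed": self.expression_split[0],
            "germline_ref_only": self.expression_split[1],
            "germline_not_expressed": self.expression_split[2],
            "loh_calls": self.loh_calls,
        }


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    summary: CaseSummary
    tumour_calls: List[VariantObservation]
    blood_calls: List[VariantObservation]
    classified: List[ClassifiedVariant]
    consequences: Dict[VariantKey, Consequence]
    somatic_final: List[ClassifiedVariant]
    germline_final: List[ClassifiedVariant]
    traces: Dict[VariantKey, FilterTrace]
    expression: Dict[VariantKey, ExpressionStatus]
    loh: List[LohCall]


def mutation_rate(n_somatic: int, callable_bp: int) -> float:
    """Somatic mutations per megabase of callable sequence, to 3 decimals."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    if n_somatic < 0:
        raise ValueError("n_somatic must be non-negative")
    return round(n_somatic / (callable_bp / 1e6), 3)


def _model_lookup(models: Sequence[GeneModel]) -> Dict[str, List[GeneModel]]:
    by_chrom: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    return by_chrom


def _models_at(by_chrom: Mapping[str, List[GeneModel]], chrom: str, pos: int) -> List[GeneModel]:
    out = []
    for m in by_chrom.get(chrom, []):
        lo, hi = m.span
        if lo <= pos <= hi:
            out.append(m)
    return out


def run_pipeline(
    bundle: CaseBundle,
    out_dir: Optional[str | Path] = None,
    loh_min_delta: float = DEFAULT_MIN_DELTA,
    loh_alpha: float = DEFAULT_ALPHA,
) -> PipelineResult:
    """Run the full analysis over a case bundle.

    Deterministic given the bundle; when ``out_dir`` is given, every
    stage's output is serialized there (VCF + TSV + summary JSON).
    """
    cfg = bundle.config
    t_params, b_params = tumour_preset(), blood_preset()

    tumour_calls: List[VariantObservation] = []
    for site in sorted(bundle.pileups[SOMATIC_SAMPLE]):
        tumour_calls.extend(call_variants(bundle.pileups[SOMATIC_SAMPLE][site], t_params))
    blood_calls: List[VariantObservation] = []
    for site in sorted(bundle.pileups[BLOOD_SAMPLE]):
        blood_calls.extend(call_variants(bundle.pileups[BLOOD_SAMPLE][site], b_params))
    blood_depths = {
        site: col.depth for site, col in bundle.pileups[BLOOD_SAMPLE].items()
    }
    logger.info("called %d tumour and %d blood variants", len(tumour_calls), len(blood_calls))

    classified = classify(tumour_calls, blood_calls, blood_depths)

    by_chrom = _model_lookup(bundle.gene_models)
    consequences: Dict[VariantKey, Consequence] = {}
    for cv in classified:
        chrom, pos, ref, alt = cv.key
        hits = _models_at(by_chrom, chrom, pos)
        if hits:
            # one consequence per transcript; the first (most severe not
            # modelled here) is kept for filtering
            consequences[cv.key] = annotate(chrom, pos, ref, alt, hits[0], bundle.genome)

    segdups = SegDupIndex(bundle.segdups)
    somatic_final, germline_final, traces = run_cascade(
        classified, bundle.annotations, bundle.panel, consequences, segdups
    )
    logger.info(
        "cascade: %d somatic and %d germline survivors of %d classified",
        len(somatic_final), len(germline_final), len(classified),
    )

    rna_cols = bundle.pileups[RNA_SAMPLE]
    expression: Dict[VariantKey, ExpressionStatus] = {}
    for cv in somatic_final + germline_final:
        chrom, pos, _, _ = cv.key
        expression[cv.key] = expression_status(cv.key, rna_cols.get((chrom, pos)))

    loh_calls: List[LohCall] = []
    for cv in germline_final:
        call = test_loh(
            cv.blood_observation,
            cv.tumour,
            min_delta=loh_min_delta,
            alpha=loh_alpha,
            model=cfg.loh_model,
        )
        if call.p_value is not None:
            loh_calls.append(call)

    spectrum = spectrum_summary([(cv.key[2], cv.key[3]) for cv in somatic_final])
    germ_split = split_summary([expression[cv.key] for cv in germline_final])
    summary = CaseSummary(
        n_somatic=len(somatic_final),
        mutation_rate_per_mb=mutation_rate(len(somatic_final), cfg.callable_bp),
        spectrum=spectrum,
        n_germline=len(germline_final),
        n_germline_genes=len(
            {bundle.annotations[cv.key].gene for cv in germline_final}
        ),
        expression_split=germ_split,
        loh_calls=sum(1 for c in loh_calls if c.is_loh),
    )

    result = PipelineResult(
        summary=summary,
        tumour_calls=tumour_calls,
        blood_calls=blood_calls,
        classified=classified,
        consequences=consequences,
        somatic_final=somatic_final,
        germline_final=germline_final,
        traces=traces,
        expression=expression,
        loh=loh_calls,
    )
    if out_dir is not None:
        _write_outputs(bundle, result, Path(out_dir))
    return result


# --------------------------------------------------------------------------
# serialization


def write_vcf(
    records: Sequence[VariantObservation],
    path: str | Path,
    sample: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Minimal single-sample VCF v4.2 with AD, DP and AF (percent) FORMAT
    fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (filtered reads)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction, percent">',
    ]
    for chrom, length in sorted((contig_lengths or {}).items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        ad = f"{v.depth_pass - v.alt_count},{v.alt_count}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
            f"AD:DP:AF\t{ad}:{v.depth_pass}:{v.af!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> List[VariantObservation]:
    """Parse a VCF written by :func:`write_vcf` back to observations."""
    out: List[VariantObservation] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        chrom, pos, _, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
        fmt = dict(zip(f[8].split(":"), f[9].split(":")))
        ad = fmt["AD"].split(",")
        out.append(
            VariantObservation(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                alt_count=int(ad[1]),
                depth_pass=int(fmt["DP"]),
                af=float(fmt["AF"]),
            )
        )
    return out


def _yesno(detected: bool, coverage: int) -> str:
    return f"Yes ({coverage})" if detected else f"No ({coverage})"


def _case_report_rows(result: PipelineResult, bundle: CaseBundle, finals) -> List[dict]:
    rows = []
    for cv in finals:
        key = cv.key
        cons = result.consequences.get(key)
        expr = result.expression.get(key)
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "gene": bundle.annotations[key].gene,
                "protein_alteration": cons.hgvs_p if cons else "NA",
                "allele_frequency": round(cv.tumour.af, 1),
                "blood_allele_frequency": (
                    round(cv.blood_observation.af, 1) if cv.blood_observation else "NA"
                ),
                "blood_depth": cv.blood_depth,
                "status": cv.status,
                "mutation_expressed": (
                    "yes" if expr and expr.state == "variant_expressed" else "no"
                ),
                "reference_allele_expressed": (
                    _yesno(expr.rna_ref_count > 0, expr.rna_ref_count) if expr else "NA"
                ),
            }
        )
    return rows


def _write_outputs(bundle: CaseBundle, result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    contig_lengths = {name: len(seq) for name, seq in bundle.genome.items()}
    write_vcf(result.tumour_calls, out / "tumour_calls.vcf", "TUMOUR_DNA", contig_lengths)
    write_vcf(result.blood_calls, out / "blood_calls.vcf", "BLOOD_DNA", contig_lengths)
    write_vcf(
        [cv.tumour for cv in result.somatic_final],
        out / "somatic_final.vcf", "TUMOUR_DNA", contig_lengths,
    )
    write_vcf(
        [cv.tumour for cv in result.germline_final],
        out / "germline_final.vcf", "TUMOUR_DNA", contig_lengths,
    )
    pd.DataFrame(
        _case_report_rows(result, bundle, result.somatic_final)
    ).to_csv(out / "somatic_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        _case_report_rows(result, bundle, result.germline_final)
    ).to_csv(out / "germline_report.tsv", sep="\t", index=False)
    trace_rows = []
    for key, trace in sorted(result.traces.items()):
        for name, outcome in trace.entries:
            trace_rows.append(
                {
                    "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                    "filter": name, "outcome": outcome, "final": trace.final,
                }
            )
    pd.DataFrame(trace_rows).to_csv(out / "filter_traces.tsv", sep="\t", index=False)
    loh_rows = [
        {
            "chrom": c.variant_key[0], "pos": c.variant_key[1],
            "ref": c.variant_key[2], "alt": c.variant_key[3],
            "af_blood": round(c.af_blood, 1),
            "af_tumour": round(c.af_tumour, 1),
            "delta_af": round(c.delta_af, 1),
            "p_value": c.p_value,
            "is_loh": c.is_loh,
            "model": c.model,
            "purity_estimate": (
                "NA" if c.purity_estimate is None else round(c.purity_estimate, 3)
            ),
        }
        for c in result.loh
    ]
    pd.DataFrame(loh_rows).to_csv(out / "loh_report.tsv", sep="\t", index=False)
    # per-filter attrition table
    attrition: Dict[str, int] = {}
    for trace in result.traces.values():
        for name in trace.failed_filters:
            attrition[name] = attrition.get(name, 0) + 1
    pd.DataFrame(
        sorted(attrition.items()), columns=["filter", "n_failed"]
    ).to_csv(out / "filter_attrition.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(result.summary.to_dict(), indent=2) + "\n"
    )
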