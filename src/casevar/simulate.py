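"""Self-contained synthetic tumour/blood/RNA case generator.

Builds a mini-genome (contigs of 10 kb carrying single-CDS gene models), a
three-sample set of pileup columns (tumour DNA, blood DNA, tumour RNA),
annotation tracks, a control-exome panel, segmental-duplication intervals,
gene sets, and a truth table — all seeded and byte-reproducible.

The default configuration plants the structure of the case the package
analyses: seven subclonal somatic mutations at allele fractions
13.8/6.7/7.4/9/14.6/17/5.7% (two transitions, three transversions, one
insertion, one deletion; none expressed in RNA), 205 damaging germline
heterozygous variants across 200 genes with an 81/29/95
expressed / reference-only / silent split, one germline nonsense variant
(CDS position 601, Arg201*) whose wild-type allele is somatically lost in
an impure tumour (purity 6/7 under the single-copy-deletion model gives a
tumour allele fraction of 87.5% and, with half of transcripts
tumour-derived, an RNA fraction of 75%), and decoy variants that pass
every stage of the analysis except exactly one named filter.

Allele counts are binomially sampled at the configured depths.  Columns
backing a planted *pass* record are redrawn until the record is actually
recovered by the caller/classifier/expression rule it must pass
(rejection sampling with a bounded retry count); this makes planted truth
recoverable by construction at any seed while keeping the sampling
binomial conditionally on detection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cascade import AnnotationRecord, ControlPanel
from .classify import GERMLINE_MIN_BLOOD_AF, GERMLINE_MIN_BLOOD_COUNT
from .consequence import GeneModel
from .loh import COPY_NEUTRAL, SINGLE_COPY_DELETION, expected_af
from .pileup import (
    CallerParams,
    PileupColumn,
    ReadObservation,
    call_variants,
    blood_preset,
    tumour_preset,
)
from .rna import (
    NOT_EXPRESSED,
    REF_ONLY,
    VARIANT_EXPRESSED,
    expression_status,
)

__all__ = ["CaseConfig", "TruthRecord", "CaseBundle", "generate_case", "DECOY_FILTERS"]

VariantKey = Tuple[str, int, str, str]

# Fixture geometry: single-CDS genes of 400 codons laid out head-to-tail on
# 10 kb contigs.
CONTIG_LEN = 10_000
CDS_LEN = 1_200
GENE_SPACING = 1_400
GENES_PER_CONTIG = 7
_GENE_OFFSET = 100  # first CDS starts here on each contig

SOMATIC_SAMPLE = "tumour_dna"
BLOOD_SAMPLE = "blood_dna"
RNA_SAMPLE = "tumour_rna"
SAMPLES = (SOMATIC_SAMPLE, BLOOD_SAMPLE, RNA_SAMPLE)

DECOY_FILTERS = (
    "damaging_selection",
    "control_panel",
    "dbsnp_common",
    "segdup",
    "gene_blacklist",
)

# Default somatic plan mirrors the analysed case: gene alias, variant shape,
# target codon, and for SNVs the reference codon planted into the CDS, the
# in-codon position (1-based) and the coding-strand alternate base.
_SOMATIC_TEMPLATES: Tuple[tuple, ...] = (
    ("SEPT03", "del", 343, None, None, None),        # frameshift deletion
    ("H2BFM", "snv", 31, "ACG", 2, "T"),             # Thr31Met, C>T
    ("ZIC4", "ins", 204, None, None, None),          # frameshift insertion
    ("HIST2H2AB", "snv", 52, "CTG", 1, "A"),         # Leu52Met; minus strand -> genomic G>T
    ("ZIK1", "snv", 296, "GAG", 2, "T"),             # Glu296Val, A>T
    ("KRTAP6-3", "snv", 102, "TAC", 2, "C"),         # Tyr102Ser, A>C
    ("IFNA8", "snv", 76, "GCT", 1, "A"),             # Ala76Thr, G>A
)
# Reference-allele RNA base coverages reported for the somatic sites, cycled.
_SOMATIC_RNA_REF_COVERAGE = (35, 0, 55, 0, 11, 0, 0)

# Missense edit templates for germline variants: (planted codon, in-codon
# position, alternate base); all produce an amino-acid change.
_MISSENSE_TEMPLATES = (
    ("GCC", 1, "T"),  # Ala->Ser
    ("CGT", 1, "T"),  # Arg->Cys
    ("GAG", 2, "T"),  # Glu->Val
    ("ACG", 2, "T"),  # Thr->Met
    ("TAC", 2, "G"),  # Tyr->Cys
)
_SYNONYMOUS_TEMPLATE = ("GGA", 3, "G")  # Gly codon wobble change

_BLACKLIST_GENE_POOL = (
    "TTN", "MUC1", "MUC2", "MUC4", "MUC5B", "MUC16",
    "OR1A1", "OR2W1", "OR4F5", "OR5A1", "OR7D2", "OR10H1",
)

_DECOY_AF = 0.25
_MAX_TRIES = 1000
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_DEFAULT_SOMATIC_AFS = (0.138, 0.067, 0.074, 0.09, 0.146, 0.17, 0.057)


@dataclass(frozen=True)
class CaseConfig:
    """Study conditions for the synthetic case.

    Defaults reproduce the analysed case's reported truth: 7 subclonal
    somatic mutations, 205 damaging germline variants over 200 genes with
    an 81/29/95 expression split, tumour purity 6/7 under single-copy
    deletion, half of RNA transcripts tumour-derived, and 10 decoys per
    filter.  Mean sequencing depths (200x DNA, 60x RNA) are fixture
    conventions chosen so planted fractions are recoverable.
    """

    seed: int = 42
    n_somatic: int = 7
    somatic_afs: Optional[Tuple[float, ...]] = None  # default: the reported fractions
    n_germline_pass: int = 205
    n_genes_germline: int = 200
    expression_split: Tuple[int, int, int] = (81, 29, 95)
    depth_dna_tumour: float = 200.0
    depth_dna_blood: float = 200.0
    depth_rna: float = 60.0
    purity: float = 6.0 / 7.0
    loh_model: str = SINGLE_COPY_DELETION
    rna_tumour_fraction: float = 0.5
    n_decoys_per_filter: int = 10
    callable_bp: int = 48_280_000
    n_background_sites: int = 100

    def resolved_somatic_afs(self) -> Tuple[float, ...]:
        if self.somatic_afs is not None:
            return tuple(self.somatic_afs)
        base = _DEFAULT_SOMATIC_AFS
        return tuple(base[i % len(base)] for i in range(self.n_somatic))

    def validate(self) -> None:
        afs = self.resolved_somatic_afs()
        if len(afs) != self.n_somatic:
            raise ValueError("somatic_afs length must equal n_somatic")
        caller_min_af = tumour_preset().min_allele_fraction
        caller_min_count = tumour_preset().min_read_count
        for af in afs:
            if af < caller_min_af:
                raise ValueError(
                    f"somatic allele fraction {af} below the caller minimum "
                    f"{caller_min_af}"
                )
            if af * self.depth_dna_tumour < caller_min_count:
                raise ValueError(
                    f"under-powered fixture: allele fraction {af} cannot yield "
                    f">= {caller_min_count} reads at mean depth "
                    f"{self.depth_dna_tumour}"
                )
        if sum(self.expression_split) != self.n_germline_pass:
            raise ValueError("expression_split must sum to n_germline_pass")
        if any(c < 0 for c in self.expression_split):
            raise ValueError("expression_split counts must be non-negative")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        if not 0.0 <= self.rna_tumour_fraction <= 1.0:
            raise ValueError("rna_tumour_fraction must lie in [0, 1]")
        if self.loh_model not in (SINGLE_COPY_DELETION, COPY_NEUTRAL):
            raise ValueError(f"unknown loh_model {self.loh_model!r}")
        if self.n_germline_pass > 0:
            if self.n_genes_germline < 1 or self.n_genes_germline > self.n_germline_pass:
                raise ValueError("need 1 <= n_genes_germline <= n_germline_pass")
            if 0.5 * self.depth_dna_blood < GERMLINE_MIN_BLOOD_COUNT:
                raise ValueError(
                    "under-powered fixture: blood depth too low for heterozygous "
                    "germline detection"
                )
            if (self.expression_split[0] + self.expression_split[1]) > 0 and (
                self.depth_rna < 20
            ):
                raise ValueError(
                    "under-powered fixture: depth_rna must be >= 20 when "
                    "expressed sites are planted"
                )
        if self.callable_bp <= 0:
            raise ValueError("callable_bp must be positive")
        if self.n_decoys_per_filter < 0 or self.n_background_sites < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "somatic_afs" in data and data["somatic_afs"] is not None:
            data["somatic_afs"] = tuple(data["somatic_afs"])
        if "expression_split" in data:
            data["expression_split"] = tuple(data["expression_split"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "n_somatic": self.n_somatic,
            "somatic_afs": list(self.resolved_somatic_afs()),
            "n_germline_pass": self.n_germline_pass,
            "n_genes_germline": self.n_genes_germline,
            "expression_split": list(self.expression_split),
            "depth_dna_tumour": self.depth_dna_tumour,
            "depth_dna_blood": self.depth_dna_blood,
            "depth_rna": self.depth_rna,
            "purity": self.purity,
            "loh_model": self.loh_model,
            "rna_tumour_fraction": self.rna_tumour_fraction,
            "n_decoys_per_filter": self.n_decoys_per_filter,
            "callable_bp": self.callable_bp,
            "n_background_sites": self.n_background_sites,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one variant."""

    variant_key: VariantKey
    planted_class: str  # somatic_pass | germline_pass | decoy:<filter>
    true_af_tumour: float
    true_af_blood: float
    true_af_rna: float
    expression_state: str
    loh: bool

    def __post_init__(self) -> None:
        if self.planted_class.startswith("decoy:"):
            name = self.planted_class.split(":", 1)[1]
            if name not in DECOY_FILTERS:
                raise ValueError(f"decoy names unknown filter {name!r}")
        elif self.planted_class not in ("somatic_pass", "germline_pass"):
            raise ValueError(f"unknown planted_class {self.planted_class!r}")
        if self.planted_class == "somatic_pass" and self.true_af_blood != 0.0:
            raise ValueError("somatic_pass records must have true_af_blood = 0")


@dataclass
class CaseBundle:
    """Everything the pipeline consumes, plus the truth table."""

    config: CaseConfig
    genome: Dict[str, str]
    gene_models: List[GeneModel]
    pileups: Dict[str, Dict[Tuple[str, int], PileupColumn]]
    annotations: Dict[VariantKey, AnnotationRecord]
    panel_membership: Dict[VariantKey, Tuple[int, ...]]  # control-sample indices
    segdups: List[Tuple[str, int, int]]  # BED: 0-based half-open
    gene_sets: Dict[str, List[str]]
    truth: List[TruthRecord]

    @property
    def panel(self) -> ControlPanel:
        return ControlPanel(
            {k: len(v) for k, v in self.panel_membership.items()}, n_samples=97
        )

    # ------------------------------------------------------------------ I/O
    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gm_rows = [
            {
                "gene": m.gene,
                "transcript": m.transcript,
                "chrom": m.chrom,
                "strand": m.strand,
                "segment_index": i,
                "cds_start": s,
                "cds_end": e,
            }
            for m in self.gene_models
            for i, (s, e) in enumerate(m.cds_segments)
        ]
        pd.DataFrame(gm_rows).to_csv(out / "gene_models.tsv", sep="\t", index=False)
        for sample in SAMPLES:
            rows = []
            for (chrom, pos), col in sorted(self.pileups[sample].items()):
                for obs in col.observations:
                    rows.append(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "ref": col.ref,
                            "allele": obs.allele,
                            "base_quality": obs.base_quality,
                            "gapmm_in_window": obs.gapmm_in_window,
                        }
                    )
            pd.DataFrame(
                rows,
                columns=[
                    "chrom", "pos", "ref", "allele", "base_quality",
                    "gapmm_in_window",
                ],
            ).to_csv(out / f"pileup_{sample}.tsv", sep="\t", index=False)
        ann_rows = [
            {
                "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                "gene": a.gene,
                "clinical_snp": int(a.clinical_snp),
                "in_cosmic": int(a.in_cosmic),
                "polyphen": a.polyphen,
                "sift": a.sift,
                "splice_site_overlap": int(a.splice_site_overlap),
                "dbsnp_pop_freq": "NA" if a.dbsnp_pop_freq is None else a.dbsnp_pop_freq,
                "in_segdup": int(a.in_segdup),
            }
            for k, a in sorted(self.annotations.items())
        ]
        pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
        panel_rows = []
        for k, samples in sorted(self.panel_membership.items()):
            row = {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3]}
            member = set(samples)
            for i in range(97):
                row[f"ctrl{i + 1:02d}"] = int(i in member)
            panel_rows.append(row)
        cols = ["chrom", "pos", "ref", "alt"] + [f"ctrl{i + 1:02d}" for i in range(97)]
        pd.DataFrame(panel_rows, columns=cols).to_csv(
            out / "control_panel.tsv", sep="\t", index=False
        )
        with open(out / "segdups.bed", "w") as fh:
            for chrom, start, end in sorted(self.segdups):
                fh.write(f"{chrom}\t{start}\t{end}\n")
        from .enrichment import write_gmt

        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        truth_rows = [
            {
                "chrom": t.variant_key[0], "pos": t.variant_key[1],
                "ref": t.variant_key[2], "alt": t.variant_key[3],
                "planted_class": t.planted_class,
                "true_af_tumour": t.true_af_tumour,
                "true_af_blood": t.true_af_blood,
                "true_af_rna": t.true_af_rna,
                "expression_state": t.expression_state,
                "loh": int(t.loh),
            }
            for t in self.truth
        ]
        pd.DataFrame(
            truth_rows,
            columns=[
                "chrom", "pos", "ref", "alt", "planted_class", "true_af_tumour",
                "true_af_blood", "true_af_rna", "expression_state", "loh",
            ],
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "config.yaml")

    @classmethod
    def read(cls, in_dir: str | Path) -> "CaseBundle":
        src = Path(in_dir)
        config = CaseConfig.from_yaml(src / "config.yaml")
        genome: Dict[str, str] = {}
        name, chunks = None, []
        for line in (src / "genome.fa").read_text().splitlines():
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].strip(), []
            else:
                chunks.append(line.strip())
        if name is not None:
            genome[name] = "".join(chunks)
        gm = pd.read_csv(src / "gene_models.tsv", sep="\t")
        models: List[GeneModel] = []
        if len(gm):
            for (gene, transcript, chrom, strand), grp in gm.groupby(
                ["gene", "transcript", "chrom", "strand"], sort=False
            ):
                grp = grp.sort_values("segment_index")
                models.append(
                    GeneModel(
                        gene=gene,
                        transcript=transcript,
                        chrom=chrom,
                        strand=strand,
                        cds_segments=tuple(
                            (int(s), int(e))
                            for s, e in zip(grp["cds_start"], grp["cds_end"])
                        ),
                    )
                )
        pileups: Dict[str, Dict[Tuple[str, int], PileupColumn]] = {}
        for sample in SAMPLES:
            df = pd.read_csv(src / f"pileup_{sample}.tsv", sep="\t")
            cols: Dict[Tuple[str, int], PileupColumn] = {}
            for row in df.itertuples(index=False):
                site = (row.chrom, int(row.pos))
                if site not in cols:
                    cols[site] = PileupColumn(row.chrom, int(row.pos), str(row.ref))
                cols[site].observations.append(
                    ReadObservation(
                        str(row.allele), int(row.base_quality),
                        int(row.gapmm_in_window),
                    )
                )
            pileups[sample] = cols
        ann_df = pd.read_csv(src / "annotations.tsv", sep="\t", keep_default_na=False)
        annotations: Dict[VariantKey, AnnotationRecord] = {}
        for row in ann_df.itertuples(index=False):
            key = (row.chrom, int(row.pos), str(row.ref), str(row.alt))
            freq = None if str(row.dbsnp_pop_freq) == "NA" else float(row.dbsnp_pop_freq)
            annotations[key] = AnnotationRecord(
                variant_key=key,
                gene=str(row.gene),
                clinical_snp=bool(row.clinical_snp),
                in_cosmic=bool(row.in_cosmic),
                polyphen=str(row.polyphen),
                sift=str(row.sift),
                splice_site_overlap=bool(row.splice_site_overlap),
                dbsnp_pop_freq=freq,
                in_segdup=bool(row.in_segdup),
            )
        panel_df = pd.read_csv(src / "control_panel.tsv", sep="\t")
        membership: Dict[VariantKey, Tuple[int, ...]] = {}
        for row in panel_df.itertuples(index=False):
            key = (row.chrom, int(row.pos), str(row.ref), str(row.alt))
            membership[key] = tuple(
                i for i in range(97) if getattr(row, f"ctrl{i + 1:02d}") == 1
            )
        segdups = []
        bed = src / "segdups.bed"
        if bed.exists():
            for line in bed.read_text().splitlines():
                if line.strip():
                    chrom, start, end = line.split("\t")
                    segdups.append((chrom, int(start), int(end)))
        from .enrichment import read_gmt

        gene_sets = read_gmt(src / "gene_sets.gmt")
        truth_df = pd.read_csv(src / "truth.tsv", sep="\t")
        truth = [
            TruthRecord(
                variant_key=(row.chrom, int(row.pos), str(row.ref), str(row.alt)),
                planted_class=str(row.planted_class),
                true_af_tumour=float(row.true_af_tumour),
                true_af_blood=float(row.true_af_blood),
                true_af_rna=float(row.true_af_rna),
                expression_state=str(row.expression_state),
                loh=bool(row.loh),
            )
            for row in truth_df.itertuples(index=False)
        ]
        return cls(
            config=config,
            genome=genome,
            gene_models=models,
            pileups=pileups,
            annotations=annotations,
            panel_membership=membership,
            segdups=segdups,
            gene_sets=gene_sets,
            truth=truth,
        )


# --------------------------------------------------------------------------
# sampling helpers


def _draw_depth(rng: np.random.Generator, mean: float, minimum: int) -> int:
    if mean <= 0:
        return 0
    for _ in range(10_000):
        d = int(rng.poisson(mean))
        if d >= minimum:
            return d
    raise ValueError(
        f"under-powered fixture: cannot reach depth >= {minimum} at mean {mean}"
    )


def _make_column(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ref: str,
    alt: Optional[str],
    true_af: float,
    depth: int,
    fixed_quality: Optional[int] = None,
) -> PileupColumn:
    """One pileup column: binomial alternate count, two-point base-quality
    mixture (Q35 90% / Q12 10%), light gap/mismatch contexts."""
    alt_n = int(rng.binomial(depth, true_af)) if alt is not None and true_af > 0 else 0
    alleles = np.array([alt] * alt_n + [ref] * (depth - alt_n), dtype=object)
    alleles = alleles[rng.permutation(depth)] if depth else alleles
    if fixed_quality is not None:
        quals = np.full(depth, fixed_quality, dtype=int)
        gapmm = np.zeros(depth, dtype=int)
    else:
        quals = rng.choice([35, 12], size=depth, p=[0.9, 0.1])
        gapmm = rng.choice([0, 1, 2], size=depth, p=[0.80, 0.15, 0.05])
    obs = [
        ReadObservation(str(a), int(q), int(g))
        for a, q, g in zip(alleles, quals, gapmm)
    ]
    return PileupColumn(chrom=chrom, pos=pos, ref=ref, observations=obs)


def _draw_until(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ref: str,
    alt: Optional[str],
    true_af: float,
    mean_depth: float,
    min_depth: int,
    require: Optional[Callable[[PileupColumn], bool]],
    fixed_depth: Optional[int] = None,
    fixed_quality: Optional[int] = None,
) -> PileupColumn:
    for _ in range(_MAX_TRIES):
        depth = fixed_depth if fixed_depth is not None else _draw_depth(
            rng, mean_depth, min_depth
        )
        col = _make_column(rng, chrom, pos, ref, alt, true_af, depth, fixed_quality)
        if require is None or require(col):
            return col
    raise ValueError(
        f"under-powered fixture: planted outcome at {chrom}:{pos} not reachable "
        f"within {_MAX_TRIES} redraws (af={true_af}, mean depth={mean_depth})"
    )


def _called(key: VariantKey, params: CallerParams) -> Callable[[PileupColumn], bool]:
    def ok(col: PileupColumn) -> bool:
        return any(v.key == key for v in call_variants(col, params))

    return ok


def _blood_germline_ok(key: VariantKey) -> Callable[[PileupColumn], bool]:
    params = blood_preset()

    def ok(col: PileupColumn) -> bool:
        for v in call_variants(col, params):
            if (
                v.key == key
                and v.af >= GERMLINE_MIN_BLOOD_AF
                and v.alt_count >= GERMLINE_MIN_BLOOD_COUNT
            ):
                return True
        return False

    return ok


def _expression_ok(key: VariantKey, state: str) -> Callable[[PileupColumn], bool]:
    def ok(col: PileupColumn) -> bool:
        return expression_status(key, col).state == state

    return ok


# --------------------------------------------------------------------------
# genome / gene scaffolding


def _complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class _PlannedVariant:
    gene_index: int
    kind: str  # snv | ins | del
    codon_index: int
    planted_class: str
    ref_codon: Optional[str] = None     # coding-strand codon planted at the site
    within: Optional[int] = None        # 1-based position inside the codon
    alt_coding: Optional[str] = None    # coding-strand alternate base
    true_af_tumour: float = 0.0
    true_af_blood: float = 0.0
    true_af_rna: float = 0.0
    expression_state: str = NOT_EXPRESSED
    loh: bool = False
    rna_fixed_depth: Optional[int] = None
    # resolved later:
    key: Optional[VariantKey] = None


def generate_case(config: CaseConfig) -> CaseBundle:
    """Generate the full synthetic case bundle for a configuration.

    Identical configurations (including the seed) produce bit-identical
    bundles.  Raises ValueError for configurations whose planted truth is
    not representable at the configured depths.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_decoys = config.n_decoys_per_filter * len(DECOY_FILTERS)
    # -------------------------------------------------- gene naming & layout
    gene_names: List[str] = []
    strands: List[str] = []
    germline_gene_idx: List[int] = []
    somatic_gene_idx: List[int] = []
    decoy_gene_idx: List[int] = []

    for g in range(config.n_genes_germline):
        gene_names.append("SMARCB1" if g == 0 else f"GENE{g:04d}")
        strands.append("+")
        germline_gene_idx.append(len(gene_names) - 1)
    for s in range(config.n_somatic):
        tmpl = _SOMATIC_TEMPLATES[s % len(_SOMATIC_TEMPLATES)]
        name = tmpl[0] if s < len(_SOMATIC_TEMPLATES) else f"SOMG{s + 1:02d}"
        gene_names.append(name)
        # the fourth template gene sits on the minus strand to exercise
        # reverse-strand annotation
        strands.append("-" if tmpl[0] == "HIST2H2AB" and s < len(_SOMATIC_TEMPLATES) else "+")
        somatic_gene_idx.append(len(gene_names) - 1)
    blacklist_cursor = 0
    for f_i, filt in enumerate(DECOY_FILTERS):
        for d in range(config.n_decoys_per_filter):
            if filt == "gene_blacklist":
                if blacklist_cursor < len(_BLACKLIST_GENE_POOL):
                    name = _BLACKLIST_GENE_POOL[blacklist_cursor]
                else:
                    name = f"OR{blacklist_cursor}X1"
                blacklist_cursor += 1
            else:
                name = f"DCY{f_i}{d:03d}"
            gene_names.append(name)
            strands.append("+")
            decoy_gene_idx.append(len(gene_names) - 1)

    n_genes = len(gene_names)
    n_contigs = max(1, -(-n_genes // GENES_PER_CONTIG))
    contigs = [f"ctg{c + 1:02d}" for c in range(n_contigs)]
    _bases = "ACGT"
    contig_chars: Dict[str, List[str]] = {
        name: [_bases[i] for i in rng.integers(0, 4, size=CONTIG_LEN)]
        for name in contigs
    }

    models: List[GeneModel] = []
    for i, (gene, strand) in enumerate(zip(gene_names, strands)):
        contig = contigs[i // GENES_PER_CONTIG]
        slot = i % GENES_PER_CONTIG
        start = _GENE_OFFSET + slot * GENE_SPACING + 1
        models.append(
            GeneModel(
                gene=gene,
                transcript=f"T{i + 1:04d}.1",
                chrom=contig,
                strand=strand,
                cds_segments=((start, start + CDS_LEN - 1),),
            )
        )

    def set_codon(model: GeneModel, codon_index: int, codon: str) -> None:
        chars = contig_chars[model.chrom]
        for j in range(3):
            cds_pos = (codon_index - 1) * 3 + 1 + j
            gpos = model.cds_to_genomic(cds_pos)
            base = codon[j]
            chars[gpos - 1] = _complement(base) if model.strand == "-" else base

    # ------------------------------------------------------ variant planning
    planned: List[_PlannedVariant] = []

    # germline: record 0 is the two-hit nonsense/LOH site when present
    tumour_af_loh = expected_af(config.purity, config.loh_model)
    rna_af_loh = (1.0 + config.rna_tumour_fraction) / 2.0
    states = (
        [VARIANT_EXPRESSED] * config.expression_split[0]
        + [REF_ONLY] * config.expression_split[1]
        + [NOT_EXPRESSED] * config.expression_split[2]
    )
    if config.n_germline_pass > 0:
        # the LOH record takes an expressed slot when one exists
        loh_state = VARIANT_EXPRESSED if VARIANT_EXPRESSED in states else states[0]
        states.remove(loh_state)
        rest_states = [states[i] for i in rng.permutation(len(states))]

        planned.append(
            _PlannedVariant(
                gene_index=germline_gene_idx[0],
                kind="snv",
                codon_index=201,  # CDS position 601
                planted_class="germline_pass",
                ref_codon="CGA",
                within=1,
                alt_coding="T",  # CGA -> TGA, Arg201*
                true_af_tumour=tumour_af_loh,
                true_af_blood=0.5,
                true_af_rna=rna_af_loh if loh_state == VARIANT_EXPRESSED else 0.0,
                expression_state=loh_state,
                loh=True,
            )
        )
        # remaining germline variants: one per remaining gene, extras cycled
        gene_cycle: List[int] = germline_gene_idx[1:] or germline_gene_idx
        assignments: List[int] = []
        for v in range(config.n_germline_pass - 1):
            assignments.append(gene_cycle[v % len(gene_cycle)])
        used_codons: Dict[int, set] = {}
        for v, gene_i in enumerate(assignments):
            state = rest_states[v]
            taken = used_codons.setdefault(gene_i, set())
            while True:
                codon_index = int(rng.integers(2, CDS_LEN // 3 - 1))
                if codon_index not in taken and codon_index != 201:
                    taken.add(codon_index)
                    break
            codon, within, alt = _MISSENSE_TEMPLATES[
                int(rng.integers(0, len(_MISSENSE_TEMPLATES)))
            ]
            planned.append(
                _PlannedVariant(
                    gene_index=gene_i,
                    kind="snv",
                    codon_index=codon_index,
                    planted_class="germline_pass",
                    ref_codon=codon,
                    within=within,
                    alt_coding=alt,
                    true_af_tumour=0.5,
                    true_af_blood=0.5,
                    true_af_rna=0.5 if state == VARIANT_EXPRESSED else 0.0,
                    expression_state=state,
                )
            )

    # somatic
    afs = config.resolved_somatic_afs()
    for s in range(config.n_somatic):
        gene, kind, codon_index, codon, within, alt = _SOMATIC_TEMPLATES[
            s % len(_SOMATIC_TEMPLATES)
        ]
        rna_cov = _SOMATIC_RNA_REF_COVERAGE[s % len(_SOMATIC_RNA_REF_COVERAGE)]
        planned.append(
            _PlannedVariant(
                gene_index=somatic_gene_idx[s],
                kind=kind,
                codon_index=codon_index,
                planted_class="somatic_pass",
                ref_codon=codon,
                within=within,
                alt_coding=alt,
                true_af_tumour=afs[s],
                true_af_blood=0.0,
                true_af_rna=0.0,
                expression_state=REF_ONLY if rna_cov > 0 else NOT_EXPRESSED,
                rna_fixed_depth=rna_cov if rna_cov > 0 else None,
            )
        )

    # decoys: missense (or synonymous for the selection decoy), somatic-like
    d_cursor = 0
    for filt in DECOY_FILTERS:
        for _ in range(config.n_decoys_per_filter):
            gene_i = decoy_gene_idx[d_cursor]
            d_cursor += 1
            if filt == "damaging_selection":
                codon, within, alt = _SYNONYMOUS_TEMPLATE
            else:
                codon, within, alt = _MISSENSE_TEMPLATES[
                    int(rng.integers(0, len(_MISSENSE_TEMPLATES)))
                ]
            planned.append(
                _PlannedVariant(
                    gene_index=gene_i,
                    kind="snv",
                    codon_index=int(rng.integers(2, CDS_LEN // 3 - 1)),
                    planted_class=f"decoy:{filt}",
                    ref_codon=codon,
                    within=within,
                    alt_coding=alt,
                    true_af_tumour=_DECOY_AF,
                )
            )

    # ------------------------------------------- plant codons, resolve keys
    for pv in planned:
        model = models[pv.gene_index]
        if pv.kind == "snv":
            set_codon(model, pv.codon_index, pv.ref_codon)

    genome: Dict[str, str] = {name: "".join(chars) for name, chars in contig_chars.items()}

    for pv in planned:
        model = models[pv.gene_index]
        contig_seq = genome[model.chrom]
        if pv.kind == "snv":
            cds_pos = (pv.codon_index - 1) * 3 + pv.within
            gpos = model.cds_to_genomic(cds_pos)
            g_ref = contig_seq[gpos - 1]
            g_alt = (
                _complement(pv.alt_coding)
                if model.strand == "-"
                else pv.alt_coding
            )
            pv.key = (model.chrom, gpos, g_ref, g_alt)
        elif pv.kind == "del":
            anchor_cds = (pv.codon_index - 1) * 3  # first changed base opens the codon
            gpos = model.cds_to_genomic(anchor_cds)
            ref = contig_seq[gpos - 1 : gpos + 1]
            pv.key = (model.chrom, gpos, ref, ref[0])
        else:  # ins
            anchor_cds = (pv.codon_index - 1) * 3
            gpos = model.cds_to_genomic(anchor_cds)
            ref = contig_seq[gpos - 1]
            pv.key = (model.chrom, gpos, ref, ref + "A")

    # ------------------------------------------------- annotations & tracks
    annotations: Dict[VariantKey, AnnotationRecord] = {}
    panel_membership: Dict[VariantKey, Tuple[int, ...]] = {}
    segdups: List[Tuple[str, int, int]] = []

    def _damaging_flags() -> dict:
        pick = int(rng.integers(0, 4))
        return {
            "clinical_snp": pick == 0,
            "in_cosmic": pick == 1,
            "polyphen": "probably_damaging" if pick == 2 else "NA",
            "sift": "damaging" if pick == 3 else "NA",
        }

    def _rare_freq() -> Optional[float]:
        # uncommon: absent from the population catalogue or at <= 1%
        if rng.random() < 0.7:
            return None
        return float(rng.uniform(0.0, 0.01))

    for pv in planned:
        model = models[pv.gene_index]
        key = pv.key
        base = {
            "variant_key": key,
            "gene": model.gene,
            "clinical_snp": False,
            "in_cosmic": False,
            "polyphen": "NA",
            "sift": "NA",
            "splice_site_overlap": False,
            "dbsnp_pop_freq": _rare_freq(),
            "in_segdup": False,
        }
        cls = pv.planted_class
        if cls == "germline_pass":
            if pv.loh:
                base["in_cosmic"] = True  # catalogued recurrent nonsense
            else:
                base.update(_damaging_flags())
        elif cls == "somatic_pass":
            if pv.kind == "snv":
                base.update(_damaging_flags())
            # indels qualify through the protein-altering-indel criterion
        else:
            filt = cls.split(":", 1)[1]
            if filt != "damaging_selection":
                base["sift"] = "damaging"
            if filt == "control_panel":
                count = int(rng.integers(1, 6))
                members = tuple(
                    int(i) for i in sorted(rng.choice(97, size=count, replace=False))
                )
                panel_membership[key] = members
            elif filt == "dbsnp_common":
                base["dbsnp_pop_freq"] = float(rng.uniform(0.02, 0.30))
            elif filt == "segdup":
                base["in_segdup"] = True
                segdups.append((key[0], max(0, key[1] - 26), key[1] + 25))
            # gene_blacklist decoys carry a blacklisted gene symbol already
        annotations[key] = AnnotationRecord(**base)

    # -------------------------------------------------------------- pileups
    t_params = tumour_preset()
    pileups: Dict[str, Dict[Tuple[str, int], PileupColumn]] = {
        s: {} for s in SAMPLES
    }

    for pv in planned:
        chrom, pos, ref, alt = pv.key
        site = (chrom, pos)
        # tumour DNA: every planted record must be called under the tumour preset
        pileups[SOMATIC_SAMPLE][site] = _draw_until(
            rng, chrom, pos, ref, alt, pv.true_af_tumour,
            config.depth_dna_tumour, min_depth=1,
            require=_called(pv.key, t_params),
        )
        # blood DNA
        if pv.true_af_blood > 0:
            pileups[BLOOD_SAMPLE][site] = _draw_until(
                rng, chrom, pos, ref, alt, pv.true_af_blood,
                config.depth_dna_blood, min_depth=1,
                require=_blood_germline_ok(pv.key),
            )
        else:
            pileups[BLOOD_SAMPLE][site] = _draw_until(
                rng, chrom, pos, ref, None, 0.0,
                config.depth_dna_blood, min_depth=8, require=None,
            )
        # tumour RNA
        if pv.expression_state == VARIANT_EXPRESSED:
            pileups[RNA_SAMPLE][site] = _draw_until(
                rng, chrom, pos, ref, alt, pv.true_af_rna,
                config.depth_rna, min_depth=20,
                require=_expression_ok(pv.key, VARIANT_EXPRESSED),
            )
        elif pv.expression_state == REF_ONLY:
            pileups[RNA_SAMPLE][site] = _draw_until(
                rng, chrom, pos, ref, None, 0.0,
                config.depth_rna, min_depth=20,
                require=_expression_ok(pv.key, REF_ONLY),
                fixed_depth=pv.rna_fixed_depth,
                fixed_quality=35 if pv.rna_fixed_depth is not None else None,
            )
        # NOT_EXPRESSED: no RNA column at the site at all

    # background reference-only sites
    variant_sites = {(pv.key[0], pv.key[1]) for pv in planned}
    placed = 0
    while placed < config.n_background_sites:
        chrom = contigs[int(rng.integers(0, n_contigs))]
        pos = int(rng.integers(1, CONTIG_LEN + 1))
        if (chrom, pos) in variant_sites:
            continue
        variant_sites.add((chrom, pos))
        ref = genome[chrom][pos - 1]
        for sample, mean in (
            (SOMATIC_SAMPLE, config.depth_dna_tumour),
            (BLOOD_SAMPLE, config.depth_dna_blood),
            (RNA_SAMPLE, config.depth_rna),
        ):
            depth = int(rng.poisson(mean)) if mean > 0 else 0
            if depth > 0:
                pileups[sample][(chrom, pos)] = _make_column(
                    rng, chrom, pos, ref, None, 0.0, depth
                )
        placed += 1

    # ------------------------------------------------------------ gene sets
    universe = sorted(set(gene_names))
    gene_sets: Dict[str, List[str]] = {}
    if universe:
        for s in range(5):
            size = min(20, len(universe))
            members = sorted(
                np.array(universe)[rng.choice(len(universe), size, replace=False)]
            )
            gene_sets[f"RANDOM_SET_{s + 1}"] = [str(m) for m in members]
        hit_genes = sorted({models[i].gene for i in germline_gene_idx})[:15]
        if hit_genes:
            gene_sets["GERMLINE_HIT_SET"] = hit_genes

    truth = [
        TruthRecord(
            variant_key=pv.key,
            planted_class=pv.planted_class,
            true_af_tumour=pv.true_af_tumour,
            true_af_blood=pv.true_af_blood,
            true_af_rna=pv.true_af_rna,
            expression_state=pv.expression_state,
            loh=pv.loh,
        )
        for pv in planned
    ]

    return CaseBundle(
        config=config,
        genome=genome,
        gene_models=models,
        pileups=pileups,
        annotations=annotations,
        panel_membership=panel_membership,
        segdups=segdups,
        gene_sets=gene_sets,
        truth=truth,
    )
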