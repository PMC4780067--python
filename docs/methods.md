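# Methods

## Scope and data model

The package analyses one tumour case from three per-site read stacks
(pileup columns): tumour DNA, blood DNA and tumour RNA. A pileup column
records, per read, the supported allele (anchored, VCF-style: deletions
`TG→T`, insertions `T→TA`), the Phred base quality at the site, and the
number of gaps/mismatches the read shows in a 21 bp window around the site
— a read-level alignment-quality proxy that stands in for realignment,
which is out of scope. Alignment itself, duplicate removal and transcript
quantification are upstream of this package: pileup tables are the entry
format.

## Variant calling

Calling is a deterministic threshold rule per sample. Observations failing
the read-level filters (quality, window gap/mismatch count) are removed
from both numerator and denominator; the reported depth (`depth_pass`) is
the surviving read count, and the allele fraction is the alternate share of
that surviving depth. The rationale is that the thresholds describe
properties of countable reads; a read too poor to support the alternate is
also too poor to witness the reference. The "minimum read count" threshold
applies to the alternate allele, not total depth — this is the reading
under which a 5.7% variant at ordinary exome depth is callable. A
consequence worth noting: relaxing the emission thresholds (count,
fraction) can only add calls, but relaxing the read-level filters can
*remove* a call by growing the denominator; the monotonicity property
tested in the suite is therefore stated over the emission thresholds.

Presets: tumour — at most 2 gaps/mismatches per 21 bp, quality ≥ 30,
alternate count ≥ 4, fraction ≥ 5%; blood — 3, ≥ 25, ≥ 1, ≥ 2%. The blood
preset is deliberately permissive so that any qualifying blood evidence is
visible to the classifier. Tumour RNA is called with the tumour preset.
Fraction thresholds are compared with a 1e−9 guard so exact boundary cases
(4 of 80 reads vs 5%) are inclusive rather than at the mercy of binary
representation.

## Somatic/germline classification

Somatic: no blood call for the allele and raw blood coverage ≥ 8, so that
absence is informative. Germline: blood call with VAF ≥ 20% and ≥ 4
alternate reads; these thresholds are applied to the blood sample — the
constitutive tissue — which is a design decision, as the rule's original
phrasing ("present in both samples with a minimum variant frequency of
20%") does not name the sample. Sites with 1–3 alternate blood reads, or
blood evidence below the germline thresholds, are *unclassifiable*: such
low-level blood signal may be contamination, artefact or true low-grade
mosaicism, and the pipeline refuses to decide. Every tumour call gets
exactly one status.

## Selection and exclusion cascade

Selection criteria are OR-combined: clinical-SNP flag, somatic-cancer
catalogue (Cosmic-style) presence, PolyPhen-style `probably_damaging`,
SIFT-style `damaging`, splice-site overlap, stop gain, or protein-altering
indel. `possibly_damaging`, `tolerated` and NA predictions never select.
Database flags are consumed as booleans from the annotation track — live
database semantics are version-bound and out of scope.

Exclusions: presence in any of the 97 control exomes; population frequency
strictly above 1% (exactly 1% passes); segmental-duplication overlap (BED,
0-based half-open, converted to 1-based internally); and a gene blacklist
for families prone to mismapping artefacts — exact `TTN`, prefix `MUC`,
and `OR` followed by a digit (so `ORC1` and `ORAI1` are untouched). The
blacklist matching rule is a design decision; family membership was not
specified as a pattern.

Every filter is evaluated for every variant and recorded in an ordered
trace, so survivors are provably order-independent and each rejection is
attributable. Germline and somatic variants pass through the identical
cascade ("processed in a similar way" is read as: same filters). Variants
with no annotation record are excluded with an `unannotated` trace entry
and a warning rather than an error.

## Coding consequences and spectrum

Gene models are single- or multi-segment CDS intervals in translation
order; reverse-strand models complement alleles before translation
(standard genetic code, via biopython). Codon index is `ceil(cds_pos/3)`;
CDS positions are transcript-relative and 1-based, matching `c.` notation.
Frameshift iff the indel length change is not divisible by 3 within the
CDS; indels whose changed bases leave the CDS are flagged splice-region
and left noncoding for the selection criterion to pick up. Protein strings
are a simplified HGVS dialect (`p.Arg201*`, `p.Glu343fs` — three-letter
codes, `*` for stop, bare `fs`); full HGVS validation is out of scope.
Transitions are A↔G and C↔T; insertions are alternate-longer-than-reference
on anchored alleles.

## RNA integration

An allele is *detected* in RNA with ≥ 1 read at quality ≥ 20 (both
configurable; the detection threshold of one read is a documented choice —
the underlying analysis reports detection without stating one).
States: variant detected → `variant_expressed` (whether or not the
reference is also seen); else reference detected → `ref_only`; else
`not_expressed`. Raw counts are always reported so reports can render
"No (0)" / "Yes (35)" columns, and a hemizygous X-linked male variant
correctly shows a 100% RNA fraction.

## LOH and purity

LOH requires both an effect-size and a significance criterion: allele-
fraction shift ≥ 20 percentage points (blood → tumour) and a two-sided
Fisher exact p ≤ 0.01 on the 2×2 alternate/reference table. The underlying
analysis inferred LOH by inspection; a formal rule is needed for a
pipeline, and these defaults make the decision explicit and tunable. The
shift must be positive (toward loss of the wild-type allele); a significant
shift toward the reference is not LOH.

Purity inverts an explicit copy model: single-copy deletion
(`AF = 1/(2−p)`, `p = 2 − 1/AF`) or copy-neutral LOH (`AF = (1+p)/2`,
`p = 2·AF − 1`). Which model underlies a given case is generally unknowable
from one site, so the model is a parameter and both inversions are exact on
(0.5, 1]; fractions at or below 50% return NA (no signal to invert). The
RNA-side check uses a tumour transcript fraction *f* that is deliberately
independent of DNA purity — expression contamination need not equal
cellular contamination — with expected RNA fraction (1+f)/2.

## Gene-set overlap

Exact hypergeometric upper tail `P(X ≥ k)` with universe N, set size K,
query size n, overlap k (scipy), Benjamini–Hochberg adjustment
(statsmodels). The universe defaults to the genes of the supplied models
and is configurable, since the appropriate background depends on how the
query lists were derived; up- and down-regulated lists are tested
separately. Reproducing any particular signature database's contents is a
non-goal — sets arrive as GMT.

## Synthetic case generator

The generator emulates the analysed case's reported structure on a desk-
scale mini-genome: contigs of 10 kb carrying head-to-tail single-CDS genes
of 400 codons (enough to host the planted codon positions, e.g. codon 343
for the frameshift and codon 201 for the nonsense variant). Planted truth,
all at their reported values by default:

* 7 somatic variants at tumour fractions 13.8/6.7/7.4/9/14.6/17/5.7%,
  blood fraction 0, mirroring the case's allele classes (two transitions,
  three transversions, one frameshift insertion, one frameshift deletion;
  one SNV on a minus-strand gene to exercise strand handling), none
  expressed in RNA, with reference-allele RNA coverages 35/0/55/0/11/0/0.
* 205 germline heterozygous variants (blood fraction 0.5) across 200
  genes, each carrying one qualifying damaging flag, splitting 81/29/95
  into variant-expressed / reference-only / silent RNA states. The first
  is a nonsense variant at CDS position 601 (`CGA→TGA`, Arg201*) with
  somatic LOH: its tumour fraction follows the configured purity model
  (default purity 6/7 under single-copy deletion → 87.5%) and its RNA
  fraction is (1+f)/2 with tumour transcript fraction f (default 0.5 →
  75%).
* 10 decoys per filter (50 total), each engineered to pass every stage
  except exactly one: a synonymous/unflagged variant for the selection
  stage, and otherwise damaging variants that are in the control panel, at
  2–30% population frequency, inside a segmental duplication, or in a
  blacklisted gene (TTN, MUC*, OR*).
* 100 reference-only background sites in all three samples.

Allele counts are binomial at Poisson-distributed depths; base qualities
are a two-point mixture (90% Q35, 10% Q12) so quality filters have bite,
and per-read gap/mismatch contexts are generated directly as counts (no
alignment step). Columns backing a planted *pass* record are redrawn until
the caller/classifier/expression rule they must pass actually recovers
them — rejection sampling with a bounded retry count (1000; exhaustion
raises an "under-powered fixture" error, as do configurations whose
expected alternate count falls below the caller minimum). This makes the
planted counts (7/205/200/81/29) recoverable by construction at any seed,
at the cost of slightly biasing fractions near a threshold upward (the
5.7% variant, conditioned on being callable at 5%, averages a little
high); fractions far from thresholds are unaffected, which the pooled
calibration test over 1,000 heterozygous sites confirms.

Default depths are 200× (both DNA samples) and 60× RNA with a 20× floor at
expressed sites. These are fixture conventions chosen so the planted truth
is representable, not an emulation of any particular sequencing run. The
default callable region of 48.28 Mb is likewise a fixture convention: it
is the effective denominator under which 7 somatic mutations give
0.145/Mb; the full 62.1 Mb enrichment target would give 0.113/Mb, and the
parameter is exposed rather than asserted.

What the generator does *not* emulate: read-level error models beyond base
quality, mapping artefacts (decoys inject filter evidence directly),
transcript isoform structure, library-size effects, or real genome
sequence. Passing recovery tests therefore demonstrates that the pipeline
implements its rules correctly and recovers planted signal at realistic
depths — not that it would be robust to alignment artefacts in real data.

## Numerical and I/O conventions

Coordinates are 1-based inclusive everywhere except BED input (0-based
half-open, converted at the boundary). Allele fractions print as percent
to one decimal; VCF output is v4.2 with `AD`/`DP`/`AF` FORMAT fields and
round-trips exactly (fractions serialized at full precision). Multi-
allelic sites emit one record per qualifying alternate, ordered by
descending count then allele. All randomness flows from a single
`numpy` generator seeded by the configuration; identical configurations
yield byte-identical bundles.

## Problem sizes used in validation

The test suite and the acceptance script run the default case
(262 planted variants + 100 background sites, ~3 s to generate), a
1,000-site calibration case, 10,000 null replicates for the LOH type-I
error check (depth 100), 200 replicates for purity recovery (depth 300),
and fresh single-column simulations at depths 500/400/300 for
allele-fraction recovery. These sizes give the statistical checks
4-standard-error resolution while keeping the whole suite under a minute.

## Known limitations

* The caller has no strand-bias or mapping-quality model (none was
  specified for the analysis it re-implements).
* Somatic classification is a hard rule, not a contamination-aware
  likelihood model; borderline blood evidence is surfaced as
  `unclassifiable` rather than resolved.
* One consequence is computed per variant against the first overlapping
  transcript; severity ranking across transcripts is not modelled (gene
  models in the fixture are single-transcript).
* Purity estimation uses a single LOH site; no genome-wide segmentation
  or B-allele-frequency aggregation.
* The hypergeometric overlap assumes genes are exchangeable within the
  universe; no gene-length or expression-level bias correction.
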