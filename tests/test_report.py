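"""Summary statistics, VCF I/O, pipeline orchestration and the CLI."""

import json

import pytest
from click.testing import CliRunner

from casevar import (
    CaseConfig,
    VariantObservation,
    generate_case,
    mutation_rate,
    read_vcf,
    run_pipeline,
    write_vcf,
)
from casevar.classify import UNCLASSIFIABLE
from casevar.cli import main


class TestMutationRate:
    def test_seven_mutations_over_effective_callable_region(self):
        assert mutation_rate(7, 48_280_000) == pytest.approx(0.145)

    def test_seven_mutations_over_the_enrichment_target(self):
        assert mutation_rate(7, 62_100_000) == pytest.approx(0.113)

    def test_zero_mutations(self):
        assert mutation_rate(0, 48_280_000) == 0.0

    def test_zero_region_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(7, 0)


class TestVcf:
    def test_round_trip(self, tmp_path):
        records = [
            VariantObservation("ctg01", 500, "C", "T", 11, 80, 100 * 11 / 80),
            VariantObservation("ctg01", 900, "TG", "T", 28, 200, 14.0),
            VariantObservation("ctg02", 17, "T", "TA", 9, 121, 100 * 9 / 121),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(records, path, "TUMOUR", {"ctg01": 10_000, "ctg02": 10_000})
        assert read_vcf(path) == sorted(records, key=lambda r: (r.chrom, r.pos))

    def test_header_declares_format_fields(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf([], path, "S")
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        for field in ("AD", "DP", "AF"):
            assert f"##FORMAT=<ID={field}" in text


class TestPipeline:
    def test_headline_numbers_on_default_case(self, default_result):
        s = default_result.summary
        assert s.n_somatic == 7
        assert s.mutation_rate_per_mb == pytest.approx(0.145)
        assert s.spectrum == (2, 3, 1, 1)
        assert s.n_germline == 205
        assert s.n_germline_genes == 200
        assert s.expression_split == (81, 29, 95)
        assert s.loh_calls == 1

    def test_every_variant_lands_in_exactly_one_bucket(self, default_result):
        """Survivors, filter failures and unclassifiable variants partition
        the classified calls."""
        finals = {cv.key for cv in default_result.somatic_final} | {
            cv.key for cv in default_result.germline_final
        }
        failures, unclassifiable = set(), set()
        for cv in default_result.classified:
            trace = default_result.traces[cv.key]
            if not trace.final:
                failures.add(cv.key)
            elif cv.status == UNCLASSIFIABLE:
                unclassifiable.add(cv.key)
        all_keys = {cv.key for cv in default_result.classified}
        assert finals | failures | unclassifiable == all_keys
        assert finals & failures == set()
        assert finals & unclassifiable == set()

    def test_rerun_is_deterministic(self, default_bundle, default_result):
        again = run_pipeline(default_bundle)
        assert again.summary == default_result.summary
        assert [cv.key for cv in again.somatic_final] == [
            cv.key for cv in default_result.somatic_final
        ]

    def test_empty_case_gives_all_zero_summary(self):
        cfg = CaseConfig(
            n_somatic=0, somatic_afs=(), n_germline_pass=0, n_genes_germline=0,
            expression_split=(0, 0, 0), n_decoys_per_filter=0,
            n_background_sites=5,
        )
        s = run_pipeline(generate_case(cfg)).summary
        assert s.n_somatic == 0 and s.n_germline == 0
        assert s.mutation_rate_per_mb == 0.0
        assert s.spectrum == (0, 0, 0, 0)
        assert s.loh_calls == 0

    def test_stage_outputs_are_serialized(self, default_bundle, tmp_path):
        run_pipeline(default_bundle, out_dir=tmp_path / "out")
        produced = {p.name for p in (tmp_path / "out").iterdir()}
        assert {
            "tumour_calls.vcf", "blood_calls.vcf", "somatic_final.vcf",
            "germline_final.vcf", "somatic_report.tsv", "germline_report.tsv",
            "filter_traces.tsv", "loh_report.tsv", "filter_attrition.tsv",
            "summary.json",
        } <= produced
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["n_somatic"] == 7


class TestCli:
    def test_simulate_then_run_all(self, tmp_path):
        runner = CliRunner()
        cfg = CaseConfig(
            seed=3, n_somatic=2, somatic_afs=(0.138, 0.1), n_germline_pass=6,
            n_genes_germline=6, expression_split=(3, 2, 1),
            n_decoys_per_filter=1, n_background_sites=5,
        )
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        bundle_dir = tmp_path / "bundle"
        r = runner.invoke(
            main, ["simulate", "--config", str(cfg_path), "--out-dir", str(bundle_dir)]
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            [
                "run-all", "--bundle-dir", str(bundle_dir),
                "--out-dir", str(tmp_path / "out"),
            ],
        )
        assert r.exit_code == 0, r.output
        summary = json.loads(r.output[r.output.index("{"):])
        assert summary["n_somatic"] == 2
        assert summary["n_germline"] == 6

    def test_enrich_command(self, tmp_path):
        runner = CliRunner()
        universe = [f"U{i}" for i in range(30)]
        (tmp_path / "universe.txt").write_text("\n".join(universe))
        (tmp_path / "query.txt").write_text("\n".join(universe[:6]))
        (tmp_path / "sets.gmt").write_text(
            "HIT\tna\t" + "\t".join(universe[:6]) + "\n"
            "MISS\tna\t" + "\t".join(universe[20:26]) + "\n"
        )
        out = tmp_path / "res.tsv"
        r = runner.invoke(
            main,
            [
                "enrich", "--query", str(tmp_path / "query.txt"),
                "--gmt", str(tmp_path / "sets.gmt"),
                "--universe", str(tmp_path / "universe.txt"),
                "--out", str(out),
            ],
        )
        assert r.exit_code == 0, r.output
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 sets
        assert lines[1].startswith("HIT")
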