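"""Synthetic case generator: determinism, calibration, planted truth."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from casevar import CaseBundle, CaseConfig, generate_case
from casevar.loh import COPY_NEUTRAL, SINGLE_COPY_DELETION
from casevar.simulate import DECOY_FILTERS, SOMATIC_SAMPLE, BLOOD_SAMPLE


def small_config(**kw):
    defaults = dict(
        seed=3,
        n_somatic=2,
        somatic_afs=(0.138, 0.1),
        n_germline_pass=10,
        n_genes_germline=9,
        expression_split=(4, 3, 3),
        n_decoys_per_filter=1,
        n_background_sites=10,
    )
    defaults.update(kw)
    return CaseConfig(**defaults)


class TestConfigValidation:
    def test_af_below_caller_minimum_rejected(self):
        with pytest.raises(ValueError, match="below the caller minimum"):
            small_config(somatic_afs=(0.04, 0.1)).validate()

    def test_af_unrepresentable_at_depth_rejected(self):
        # 5% of 60x is 3 expected reads, under the 4-read calling minimum
        with pytest.raises(ValueError, match="under-powered"):
            small_config(somatic_afs=(0.05, 0.1), depth_dna_tumour=60).validate()

    def test_expression_split_must_sum_to_germline_count(self):
        with pytest.raises(ValueError, match="expression_split"):
            small_config(expression_split=(4, 3, 2)).validate()

    def test_purity_bounds(self):
        with pytest.raises(ValueError, match="purity"):
            small_config(purity=0.0).validate()

    def test_unknown_loh_model_rejected(self):
        with pytest.raises(ValueError, match="loh_model"):
            small_config(loh_model="triploid").validate()

    def test_more_genes_than_variants_rejected(self):
        with pytest.raises(ValueError, match="n_genes_germline"):
            small_config(n_genes_germline=11).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        loaded = CaseConfig.from_yaml(tmp_path / "c.yaml")
        assert loaded.resolved_somatic_afs() == cfg.resolved_somatic_afs()
        assert loaded.expression_split == cfg.expression_split
        assert loaded.seed == cfg.seed


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_case(small_config()).write(a)
        generate_case(small_config()).write(b)
        files = sorted(p.name for p in a.iterdir())
        assert files == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self, tmp_path):
        b1 = generate_case(small_config(seed=3))
        b2 = generate_case(small_config(seed=4))
        assert b1.genome != b2.genome

    def test_bundle_round_trips_through_disk(self, tmp_path):
        bundle = generate_case(small_config())
        bundle.write(tmp_path / "case")
        loaded = CaseBundle.read(tmp_path / "case")
        assert loaded.genome == bundle.genome
        assert loaded.truth == bundle.truth
        assert loaded.annotations == bundle.annotations
        assert loaded.panel_membership == bundle.panel_membership
        assert loaded.segdups == sorted(bundle.segdups)
        assert loaded.gene_sets == bundle.gene_sets
        for sample in bundle.pileups:
            assert set(loaded.pileups[sample]) == set(bundle.pileups[sample])
            site = sorted(bundle.pileups[sample])[0]
            assert (
                loaded.pileups[sample][site].observations
                == bundle.pileups[sample][site].observations
            )


class TestPlantedTruth:
    def test_default_somatic_fractions_are_the_reported_ones(self, default_bundle):
        somatic = [
            t for t in default_bundle.truth if t.planted_class == "somatic_pass"
        ]
        assert len(somatic) == 7
        assert {t.true_af_tumour for t in somatic} == {
            0.138, 0.067, 0.074, 0.09, 0.146, 0.17, 0.057,
        }
        assert all(t.true_af_blood == 0.0 for t in somatic)

    def test_germline_sites_are_heterozygous_in_blood(self, default_bundle):
        germ = [t for t in default_bundle.truth if t.planted_class == "germline_pass"]
        assert len(germ) == 205
        assert all(t.true_af_blood == 0.5 for t in germ)
        assert sum(t.loh for t in germ) == 1

    def test_loh_site_follows_the_purity_model(self, default_bundle):
        (loh,) = [t for t in default_bundle.truth if t.loh]
        # single-copy deletion at purity 6/7: af = 1/(2 - 6/7) = 7/8
        assert loh.true_af_tumour == pytest.approx(7 / 8)
        assert loh.true_af_rna == pytest.approx(0.75)

    def test_decoys_name_each_filter_equally(self, default_bundle):
        decoys = [
            t.planted_class.split(":", 1)[1]
            for t in default_bundle.truth
            if t.planted_class.startswith("decoy:")
        ]
        assert len(decoys) == 50
        for filt in DECOY_FILTERS:
            assert decoys.count(filt) == 10

    def test_empty_case_has_reference_only_pileups(self):
        cfg = CaseConfig(
            n_somatic=0, somatic_afs=(), n_germline_pass=0, n_genes_germline=0,
            expression_split=(0, 0, 0), n_decoys_per_filter=0,
            n_background_sites=20,
        )
        bundle = generate_case(cfg)
        assert bundle.truth == []
        for sample, columns in bundle.pileups.items():
            for col in columns.values():
                assert all(o.allele == col.ref for o in col.observations)


class TestCalibration:
    def test_planting_model_closed_form_matches_simulation(self):
        """Expected LOH allele fraction at purity 0.5 equals 2/3 under the
        deletion model; the mean of 10,000 binomial draws agrees."""
        from casevar import expected_af

        af = expected_af(0.5, SINGLE_COPY_DELETION)
        assert af == pytest.approx(2 / 3)
        rng = np.random.default_rng(5)
        draws = rng.binomial(200, af, size=10_000) / 200
        se = np.sqrt(af * (1 - af) / (200 * 10_000))
        assert abs(draws.mean() - af) < 4 * se
        assert expected_af(0.5, COPY_NEUTRAL) == pytest.approx(0.75)

    def test_empirical_fractions_match_truth_over_thousand_sites(self):
        """Pooled blood allele fraction over 1,000 heterozygous sites stays
        within four binomial standard errors of the planted 0.5."""
        cfg = CaseConfig(
            seed=9, n_somatic=0, somatic_afs=(), n_germline_pass=1000,
            n_genes_germline=1000, expression_split=(0, 0, 1000),
            n_decoys_per_filter=0, n_background_sites=0,
            depth_dna_tumour=100, depth_dna_blood=100, depth_rna=0,
        )
        bundle = generate_case(cfg)
        truth_sites = {
            (t.variant_key[0], t.variant_key[1]): t for t in bundle.truth
        }
        assert len(truth_sites) == 1000
        alt = total = 0
        for site, t in truth_sites.items():
            col = bundle.pileups[BLOOD_SAMPLE][site]
            alt_allele = t.variant_key[3]
            alt += sum(1 for o in col.observations if o.allele == alt_allele)
            total += sum(
                1
                for o in col.observations
                if o.allele in (alt_allele, t.variant_key[2])
            )
        p_hat = alt / total
        se = np.sqrt(0.5 * 0.5 / total)
        assert abs(p_hat - 0.5) < 4 * se
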