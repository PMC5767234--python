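"""Synthetic-data generator: planted truth, determinism, recovery bounds."""

import numpy as np
import pytest

from cocultrace.chem import correction_matrix, parse_formula
from cocultrace.isotopes import C13_NATURAL_ABUNDANCE
from cocultrace.labeling import correct_natural_abundance, total_incorporation
from cocultrace.network import modified_cosine
from cocultrace.simdata import (
    Scenario,
    labeled_ladder_fractions,
    study_scenario,
    simulate_feature_matrix,
    simulate_labeling_spectra,
    simulate_msms_family,
)
from cocultrace.spectra import extract_isotopologues


@pytest.fixture(scope="module")
def scenario():
    return study_scenario(seed=0, n_background=300)


class TestStudyScenario:
    def test_planted_truth_counts(self, scenario):
        counts = scenario.truth_counts()
        assert counts["induced"] == 74
        assert counts["newly_synthesized"] == 58
        assert counts["fold_increased"] == 16
        assert counts["A"] == 20
        assert counts["B"] == 6
        assert counts["both"] == 5
        assert counts["none"] == 43
        assert counts["physical_interaction"] == 12

    def test_reference_trajectories_encoded(self, scenario):
        by_formula = {f.formula: f for f in scenario.induced}
        m490 = by_formula["C24H45NO9"]
        assert m490.enrichment == {"A_d10": 0.19, "A_d20": 0.25}
        assert by_formula["C8H8O4"].enrichment["B_d20"] == 0.14
        c1 = by_formula["C18H14O5"]
        assert c1.producer == "both"
        assert c1.enrichment["B_d20"] == pytest.approx(1.3 * c1.enrichment["A_d20"])

    def test_eleven_labeled_features_increase(self, scenario):
        n_inc = sum(
            1
            for f in scenario.induced
            if f.producer != "none"
            and any(
                f.enrichment.get(f"{o}_d20", 0) > f.enrichment.get(f"{o}_d10", 0)
                for o in "AB"
            )
        )
        assert n_inc == 11

    def test_roster_ids_unique_and_enrichments_valid(self, scenario):
        ids = [f.feature_id for f in scenario.features]
        assert len(ids) == len(set(ids))
        for f in scenario.features:
            assert all(0 <= p <= 1 for p in f.enrichment.values())
            if f.fold_ratio is not None:
                assert f.fold_ratio >= 1

    def test_compound_one_fold_ratio_from_table(self, scenario):
        c1 = next(f for f in scenario.induced if f.formula == "C18H14O5")
        assert c1.fold_ratio == pytest.approx(15.4)

    def test_yaml_round_trip(self, tmp_path, scenario):
        path = tmp_path / "scenario.yaml"
        scenario.to_yaml(path)
        back = Scenario.from_yaml(path)
        assert back.truth_counts() == scenario.truth_counts()
        assert back.seed == scenario.seed
        assert len(back.features) == len(scenario.features)


class TestFeatureMatrix:
    def test_zero_noise_group_means_exact(self, scenario):
        fm = simulate_feature_matrix(scenario, noise_rel_sd=0.0)
        truth = {f.feature_id: f for f in scenario.features}
        for fid in list(fm.intensities.index)[:50]:
            f = truth[fid]
            co = fm.intensities.loc[fid, fm.group_columns("co")]
            assert co.to_numpy() == pytest.approx(np.full(6, f.co_intensity))

    def test_same_seed_identical_matrices(self, scenario):
        m1 = simulate_feature_matrix(scenario)
        m2 = simulate_feature_matrix(scenario)
        assert np.array_equal(m1.intensities.to_numpy(), m2.intensities.to_numpy())

    def test_different_seed_differs(self, scenario):
        other = study_scenario(seed=1, n_background=300)
        m1 = simulate_feature_matrix(scenario)
        m2 = simulate_feature_matrix(other)
        assert not np.array_equal(m1.intensities.to_numpy(), m2.intensities.to_numpy())

    def test_planted_fold_recovered_within_three_sds(self, scenario):
        from cocultrace.induction import fold_change

        fm = simulate_feature_matrix(scenario, noise_rel_sd=0.05)
        feat = next(f for f in scenario.induced if f.fold_ratio == pytest.approx(15.4))
        co = fm.bio_replicate_means(feat.feature_id, "co")
        mono = fm.bio_replicate_means(feat.feature_id, "monoA")
        ratio, _ = fold_change(co, mono)
        # ratio of means over 6 samples each: relative SD ~ 5% * sqrt(2/6)
        sd = 15.4 * 0.05 * np.sqrt(2 / 6)
        assert abs(ratio - 15.4) < 3 * sd


class TestLabelingSpectra:
    def test_unlabeled_matches_natural_abundance(self, scenario):
        feat = next(f for f in scenario.induced if f.producer == "none")
        specs = simulate_labeling_spectra(scenario, "A", 10, "with_sup", 1, 1,
                                          noise_rel_sd=0.0)
        meas = extract_isotopologues(specs, feat.target())
        f = parse_formula(feat.formula)
        expected = labeled_ladder_fractions(f, 0.0) * feat.co_intensity
        assert meas.intensities == pytest.approx(expected, rel=1e-9)

    def test_full_enrichment_dominant_at_m_plus_n(self):
        f = parse_formula("C8H8O4")
        frac = labeled_ladder_fractions(f, 1.0)
        assert np.argmax(frac) == 8

    def test_binomial_ladder_through_pipeline_recovers_p(self, scenario):
        """Noiseless p=0.14 on C8H8O4 -> 14% after extraction + correction."""
        feat = next(f for f in scenario.induced if f.formula == "C8H8O4")
        specs = simulate_labeling_spectra(scenario, "B", 20, "with_sup", 2, 1,
                                          noise_rel_sd=0.0)
        meas = extract_isotopologues(specs, feat.target())
        cm = correction_matrix(parse_formula(feat.formula))
        mid = correct_natural_abundance(meas.intensities, cm)
        assert total_incorporation(mid) == pytest.approx(14.0, abs=1e-6)

    def test_supernatant_dependent_feature_unlabeled_without(self, scenario):
        feat = next(f for f in scenario.induced if f.formula == "C24H45NO9")
        assert feat.supernatant_dependent
        specs = simulate_labeling_spectra(scenario, "A", 20, "without_sup", 1, 1,
                                          noise_rel_sd=0.0)
        meas = extract_isotopologues(specs, feat.target())
        cm = correction_matrix(parse_formula(feat.formula))
        mid = correct_natural_abundance(meas.intensities, cm)
        assert total_incorporation(mid) == pytest.approx(0.0, abs=1e-6)

    def test_natural_13c_on_unlabeled_positions(self):
        # per-carbon heavy probability is p + (1-p) * natural 13C
        f = parse_formula("C2")
        frac = labeled_ladder_fractions(f, 0.5)
        q = 0.5 + 0.5 * C13_NATURAL_ABUNDANCE
        assert frac == pytest.approx([(1 - q) ** 2, 2 * q * (1 - q), q**2], abs=1e-12)

    def test_same_seed_same_spectra(self, scenario):
        s1 = simulate_labeling_spectra(scenario, "A", 10, "with_sup", 1, 1)
        s2 = simulate_labeling_spectra(scenario, "A", 10, "with_sup", 1, 1)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.intensity, b.intensity)

    def test_replicates_differ_under_noise(self, scenario):
        s1 = simulate_labeling_spectra(scenario, "A", 10, "with_sup", 1, 1)
        s2 = simulate_labeling_spectra(scenario, "A", 10, "with_sup", 2, 1)
        assert not np.array_equal(s1[0].intensity, s2[0].intensity)


class TestMsmsFamily:
    BACKBONE = [77.04, 105.03, 117.03, 145.06, 173.02, 207.04, 235.08, 251.07]

    def test_single_member_single_spectrum(self):
        out = simulate_msms_family(self.BACKBONE, [279.0656])
        assert len(out) == 1

    def test_family_members_exceed_network_threshold(self):
        members = simulate_msms_family(
            self.BACKBONE, [279.0656, 306.0775, 334.0733, 581.1208, 629.1419, 251.0712]
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                score, matched = modified_cosine(members[i], members[j])
                assert score > 0.65
                assert matched >= 6

    def test_fragments_below_member_precursor(self):
        members = simulate_msms_family(self.BACKBONE, [251.0712, 629.1419])
        for sp in members:
            assert np.all(sp.mz < sp.precursor_mz + 0.5)
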