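"""Modified-cosine similarity and molecular-network construction."""

import numpy as np
import pytest

from cocultrace.network import (
    build_network,
    export_network,
    load_network,
    modified_cosine,
    read_mgf,
    write_mgf,
)
from cocultrace.simdata import simulate_msms_family

from conftest import exhaustive_modified_cosine, make_msms


def family(n=6, seed=0):
    return simulate_msms_family(
        backbone=[77.04, 105.03, 117.03, 145.06, 173.02, 207.04, 235.08, 251.07],
        precursors=[279.0656 + 14.0157 * k for k in range(n)],
        name="fam",
        seed=seed,
    )


class TestModifiedCosine:
    def test_identical_spectra_score_one(self):
        s = make_msms("s", 279.0656, [(77.04, 100), (117.03, 80), (235.08, 40)])
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        s1 = make_msms("a", 300.0, [(100.0, 50), (150.0, 50)])
        s2 = make_msms("b", 400.0, [(210.0, 50), (260.0, 50)])
        # direct offsets 110/60 Da, shifted offsets 10 Da: nothing matches
        score, matched = modified_cosine(s1, s2, fragment_tol=0.5)
        assert score == 0.0 and matched == 0

    def test_two_peak_hand_computed_example(self):
        # one shared fragment of equal intensity, one unshared each
        s1 = make_msms("a", 300.0, [(100.0, 50), (120.0, 50)])
        s2 = make_msms("b", 350.0, [(100.0, 50), (190.0, 50)])
        score, matched = modified_cosine(s1, s2)
        # sqrt scaling makes both weights 1/sqrt(2); single match -> 0.5
        assert score == pytest.approx(0.5, abs=1e-12)
        assert matched == 1

    def test_shifted_peaks_match_through_precursor_difference(self):
        s1 = make_msms("a", 300.0, [(100.0, 50), (282.0, 50)])
        s2 = make_msms("b", 314.0, [(100.0, 50), (296.0, 50)])
        score, matched = modified_cosine(s1, s2)
        assert matched == 2
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_empty_spectrum_scores_zero(self):
        s1 = make_msms("a", 300.0, [(100.0, 50)])
        s2 = make_msms("b", 300.0, [(100.0, 0.0)])
        assert modified_cosine(s1, s2) == (0.0, 0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s1 = make_msms("a", 300.0, [(m, i) for m, i in
                 zip(np.sort(rng.uniform(50, 290, 6)), rng.uniform(1, 100, 6))])
            s2 = make_msms("b", 321.5, [(m, i) for m, i in
                 zip(np.sort(rng.uniform(50, 310, 6)), rng.uniform(1, 100, 6))])
            assert modified_cosine(s1, s2) == modified_cosine(s2, s1)

    def test_scale_invariance(self):
        s1 = make_msms("a", 300.0, [(100.0, 50), (120.0, 30), (282.0, 20)])
        s2 = make_msms("b", 314.0, [(100.0, 50), (134.0, 30), (296.0, 20)])
        base, _ = modified_cosine(s1, s2)
        s1b = make_msms("a", 300.0, [(100.0, 500), (120.0, 300), (282.0, 200)])
        scaled, _ = modified_cosine(s1b, s2)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_greedy_matches_exhaustive_oracle_on_small_spectra(self):
        """Greedy matching must agree with full matching enumeration."""
        rng = np.random.default_rng(17)
        for trial in range(25):
            n1, n2 = rng.integers(2, 6, 2)
            s1 = make_msms("a", 300.0, sorted(
                (float(m), float(i)) for m, i in
                zip(rng.uniform(50, 290, n1), rng.uniform(1, 100, n1))))
            s2 = make_msms("b", float(300.0 + rng.uniform(-20, 20)), sorted(
                (float(m), float(i)) for m, i in
                zip(rng.uniform(50, 290, n2), rng.uniform(1, 100, n2))))
            got, _ = modified_cosine(s1, s2)
            want, _ = exhaustive_modified_cosine(s1, s2)
            assert got == pytest.approx(want, abs=1e-9)

    def test_against_matchms_reference(self):
        """Cross-check scores against the matchms ModifiedCosine kernel.

        matchms applies no square-root scaling internally, so spectra are
        pre-square-rooted before feeding it.
        """
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(8)
        kernel = ModifiedCosine(tolerance=0.5)
        for trial in range(10):
            n1, n2 = rng.integers(3, 7, 2)
            mz1 = np.sort(rng.uniform(50, 280, n1))
            i1 = rng.uniform(10, 100, n1)
            mz2 = np.sort(rng.uniform(50, 280, n2))
            i2 = rng.uniform(10, 100, n2)
            p1, p2 = 300.0, 300.0 + float(rng.uniform(5, 30))
            s1 = make_msms("a", p1, list(zip(mz1, i1)))
            s2 = make_msms("b", p2, list(zip(mz2, i2)))
            ref = kernel.pair(
                matchms.Spectrum(mz=mz1, intensities=np.sqrt(i1),
                                 metadata={"precursor_mz": p1}),
                matchms.Spectrum(mz=mz2, intensities=np.sqrt(i2),
                                 metadata={"precursor_mz": p2}),
            )
            got, got_matched = modified_cosine(s1, s2)
            assert got == pytest.approx(float(ref["score"]), abs=1e-6)
            assert got_matched == int(ref["matches"])


class TestBuildNetwork:
    def test_planted_family_forms_one_component(self):
        net = build_network(family(6))
        comps = net.components()
        assert len(comps) == 1
        assert len(comps[0]) == 6

    def test_all_dissimilar_spectra_give_empty_network(self):
        rng = np.random.default_rng(4)
        spectra = [
            make_msms(f"s{k}", 200.0 + 50 * k, [
                (float(m), float(i)) for m, i in
                zip(np.sort(rng.uniform(50, 150, 5)) + 40 * k, rng.uniform(1, 100, 5))
            ])
            for k in range(4)
        ]
        net = build_network(spectra)
        assert net.graph.number_of_nodes() == 0

    def test_two_disjoint_families_two_components(self):
        spectra = family(4) + simulate_msms_family(
            backbone=[65.04, 81.03, 95.05, 108.04, 122.06, 136.04, 150.05],
            precursors=[168.0653, 196.0944, 216.1021, 230.1177],
            name="fam2",
        )
        net = build_network(spectra)
        assert len(net.components()) == 2

    def test_max_component_bound_enforced(self):
        net = build_network(family(60), max_component=50)
        assert all(len(c) <= 50 for c in net.components())

    def test_min_cluster_drops_singletons(self):
        net = build_network(family(2) + family(1, seed=99)[:1])
        # the lone third spectrum duplicates a family member id-wise? no:
        assert all(len(c) >= 2 for c in net.components())

    def test_raising_min_cosine_never_adds_edges(self):
        spectra = family(8)
        loose = build_network(spectra, min_cosine=0.65)
        strict = build_network(spectra, min_cosine=0.9)
        loose_edges = {frozenset((e.source, e.target)) for e in loose.edges}
        strict_edges = {frozenset((e.source, e.target)) for e in strict.edges}
        assert strict_edges <= loose_edges


class TestNetworkIO:
    def test_graphml_round_trip(self, tmp_path):
        net = build_network(family(5))
        path = tmp_path / "net.graphml"
        export_network(net, path)
        back = load_network(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            assert back.graph.has_edge(u, v)
            assert back.graph[u][v]["score"] == pytest.approx(d["score"])

    def test_empty_network_round_trip(self, tmp_path):
        from cocultrace.network import MolecularNetwork

        path = tmp_path / "empty.graphml"
        export_network(MolecularNetwork(), path)
        assert load_network(path).graph.number_of_nodes() == 0

    def test_mgf_round_trip(self, tmp_path):
        spectra = family(3)
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 3
        for orig, rt in zip(spectra, back):
            assert rt.spectrum_id == orig.spectrum_id
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz)
            assert rt.mz == pytest.approx(orig.mz)
            assert rt.group == orig.group
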