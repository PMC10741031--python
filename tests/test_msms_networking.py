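"""MGF I/O, modified-cosine similarity and molecular-network construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chebutools.msms_networking import (
    MgfError,
    MolecularNetwork,
    MsmsSpectrum,
    NetworkParams,
    annotate_nodes,
    build_network,
    enhance_component_classes,
    modified_cosine,
    read_mgf,
    to_graphml,
    write_mgf,
)

from conftest import spectrum_from_record


def make_spectrum(sid, precursor, peaks):
    mz, inten = zip(*peaks)
    return MsmsSpectrum(sid, precursor, np.array(mz), np.array(inten))


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every one-to-one pairing of candidate peaks
# ---------------------------------------------------------------------------

def brute_force_modified_cosine(a, b, tol):
    shift = a.precursor_mz - b.precursor_mz
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    pairs = [
        (i, j) for i in range(len(a.mz)) for j in range(len(b.mz))
        if abs(a.mz[i] - b.mz[j]) <= tol or abs(a.mz[i] - (b.mz[j] + shift)) <= tol
    ]
    best = (0.0, 0)
    for r in range(1, len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            used_i = [i for i, _ in combo]
            used_j = [j for _, j in combo]
            if len(set(used_i)) < r or len(set(used_j)) < r:
                continue
            score = sum(wa[i] * wb[j] for i, j in combo)
            if score > best[0]:
                best = (score, r)
    return best


class TestMgfIO:
    def test_round_trip(self, tmp_path, library):
        spectra = [spectrum_from_record(r) for r in library[:3]]
        path = tmp_path / "three.mgf"
        write_mgf(spectra, str(path))
        again = read_mgf(str(path))
        assert len(again) == 3
        for orig, back in zip(spectra, again):
            assert back.spectrum_id == orig.spectrum_id
            assert back.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            np.testing.assert_allclose(back.mz, orig.mz, atol=1e-6)
            np.testing.assert_allclose(back.intensity, orig.intensity, rtol=1e-6)

    def test_missing_pepmass_is_an_error(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=broken\n100.0 10.0\n200.0 20.0\nEND IONS\n")
        with pytest.raises(MgfError, match="PEPMASS"):
            read_mgf(str(path))


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = make_spectrum("s", 500.0, [(100.0, 5.0), (200.0, 50.0), (300.0, 10.0)])
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum("a", 500.0, [(100.0, 1.0), (150.0, 1.0)])
        b = make_spectrum("b", 500.0, [(120.0, 1.0), (170.0, 1.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_precursor_shift_pairs_shifted_peaks(self):
        # b is a +14.0157 homolog of a; the 314 peak pairs with 300 via the shift
        a = make_spectrum("a", 500.0, [(100.0, 10.0), (300.0, 10.0)])
        b = make_spectrum("b", 514.0157, [(100.0, 10.0), (314.0157, 10.0)])
        score, matched = modified_cosine(a, b, fragment_tol=0.01)
        assert matched == 2
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_toy_spectra(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            na, nb = rng.integers(2, 6, size=2)
            a = make_spectrum("a", float(rng.uniform(300, 600)),
                              sorted(zip(rng.uniform(50, 500, na), rng.uniform(1, 100, na))))
            b = make_spectrum("b", float(rng.uniform(300, 600)),
                              sorted(zip(rng.uniform(50, 500, nb), rng.uniform(1, 100, nb))))
            tol = 30.0  # wide tolerance to force overlapping candidate pairs
            score, matched = modified_cosine(a, b, tol)
            oracle_score, _ = brute_force_modified_cosine(a, b, tol)
            assert score == pytest.approx(oracle_score, abs=1e-9)

    def test_at_least_as_good_as_greedy_reference(self, library):
        matchms = pytest.importorskip("matchms")
        from matchms import Spectrum
        from matchms.similarity import ModifiedCosine
        sim = ModifiedCosine(tolerance=0.01)
        specs = [spectrum_from_record(r) for r in library[50:70]]
        for a, b in itertools.combinations(specs, 2):
            ours, _ = modified_cosine(a, b, 0.01)
            # matchms scores raw intensities; feed it the square-rooted
            # peaks so both sides use the same effective weights
            ma = Spectrum(mz=a.mz, intensities=np.sqrt(a.intensity),
                          metadata={"precursor_mz": a.precursor_mz})
            mb = Spectrum(mz=b.mz, intensities=np.sqrt(b.intensity),
                          metadata={"precursor_mz": b.precursor_mz})
            theirs = float(sim.pair(ma, mb)["score"])
            assert ours >= theirs - 1e-9  # exact assignment >= greedy pairing
            assert ours - theirs < 0.1    # and close on real fragment lists

    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 8, size=2)
        a = make_spectrum("a", float(rng.uniform(200, 900)),
                          sorted(zip(rng.uniform(50, 800, na), rng.uniform(1, 100, na))))
        b = make_spectrum("b", float(rng.uniform(200, 900)),
                          sorted(zip(rng.uniform(50, 800, nb), rng.uniform(1, 100, nb))))
        sab, mab = modified_cosine(a, b, 0.5)
        sba, mba = modified_cosine(b, a, 0.5)
        assert sab == pytest.approx(sba, abs=1e-9)
        assert mab == mba
        assert 0.0 <= sab <= 1.0


class TestBuildNetwork:
    def test_copies_of_one_spectrum_form_one_component(self, library_by_id):
        base = spectrum_from_record(library_by_id[95])
        copies = [
            MsmsSpectrum(f"c{i}", base.precursor_mz, base.mz, base.intensity)
            for i in range(5)
        ]
        net = build_network(copies, NetworkParams(min_matched_peaks=3))
        assert len(net.components) == 1
        assert net.graph.number_of_edges() == 10  # complete graph on 5 nodes
        assert net.orphans == []

    def test_two_families_give_two_components(self, library_by_id):
        # spectra within each isomer family share fragment lists; across
        # families they share too few peaks to pass the edge threshold
        fam_a = [spectrum_from_record(library_by_id[i]) for i in (55, 63, 68, 69, 70, 72)]
        fam_b = [spectrum_from_record(library_by_id[i]) for i in (5, 8, 9, 23)]
        net = build_network(fam_a + fam_b, NetworkParams(min_cosine=0.6, min_matched_peaks=3))
        assert len(net.components) == 2
        comps = [set(c) for c in net.components.values()]
        assert {s.spectrum_id for s in fam_a} in comps
        assert {s.spectrum_id for s in fam_b} in comps

    def test_all_below_threshold_means_all_orphans(self):
        a = make_spectrum("a", 400.0, [(100.0, 1.0), (150.0, 1.0)])
        b = make_spectrum("b", 500.0, [(220.0, 1.0), (270.0, 1.0)])
        net = build_network([a, b])
        assert net.components == {}
        assert net.orphans == ["a", "b"]

    def test_invariant_to_input_order(self, library_by_id):
        specs = [spectrum_from_record(library_by_id[i]) for i in (55, 63, 68, 5, 8)]
        p = NetworkParams(min_cosine=0.5, min_matched_peaks=3)
        net1 = build_network(specs, p)
        net2 = build_network(list(reversed(specs)), p)
        assert sorted(net1.graph.edges) == sorted(net2.graph.edges)
        assert net1.components == net2.components

    def test_graphml_export_reads_back(self, tmp_path, library_by_id):
        import networkx as nx
        specs = [spectrum_from_record(library_by_id[i]) for i in (55, 63, 68)]
        net = build_network(specs, NetworkParams(min_cosine=0.5, min_matched_peaks=3))
        path = tmp_path / "net.graphml"
        to_graphml(net, str(path))
        again = nx.read_graphml(str(path))
        assert set(again.nodes) == set(net.graph.nodes)
        assert again.number_of_edges() == net.graph.number_of_edges()


class TestAnnotateNodes:
    def test_chebulagic_node_annotated(self, library, library_by_id):
        spec = spectrum_from_record(library_by_id[95], "query")
        net = build_network([spec])
        annotate_nodes(net, library, [spec])
        assert net.graph.nodes["query"]["annotation"] == 95
        assert net.graph.nodes["query"]["compound_class"] == "chebulic ellagitannin"

    def test_unmatched_precursor_left_unannotated(self, library):
        spec = make_spectrum("query", 4242.0, [(100.0, 1.0), (200.0, 1.0)])
        net = build_network([spec])
        annotate_nodes(net, library, [spec])
        assert "annotation" not in net.graph.nodes["query"]

    def test_isomer_candidates_both_retained(self, library, library_by_id):
        spec = spectrum_from_record(library_by_id[39], "query")
        net = build_network([spec])
        annotate_nodes(net, library, [spec])
        assert set(net.graph.nodes["query"]["candidates"]) == {39, 47}


class TestComponentClasses:
    def test_majority_vote(self, library, library_by_id):
        specs = [spectrum_from_record(library_by_id[i]) for i in (80, 95, 107)]
        net = build_network(specs, NetworkParams(min_cosine=0.3, min_matched_peaks=2))
        annotate_nodes(net, library, specs)
        labels = enhance_component_classes(net)
        assert len(net.components) >= 1
        assert set(labels.values()) == {"chebulic ellagitannin"}

    def test_component_without_annotations_is_unclassified(self):
        a = make_spectrum("a", 400.0, [(100.0, 5.0), (150.0, 5.0), (200.0, 5.0),
                                       (250.0, 5.0), (310.0, 5.0), (350.0, 5.0)])
        b = make_spectrum("b", 400.0, [(100.0, 5.0), (150.0, 5.0), (200.0, 5.0),
                                       (250.0, 5.0), (310.0, 5.0), (350.0, 5.0)])
        net = build_network([a, b])
        labels = enhance_component_classes(net)
        assert labels == {1: "unclassified"}
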