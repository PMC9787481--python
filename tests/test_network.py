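"""Modified-cosine similarity and molecular-network topology rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from crossmet.network import (
    MolecularNetwork,
    NetworkParams,
    build_network,
    candidate_pairs,
    clusters,
    export_graphml,
    read_graphml,
    spectral_similarity,
)
from crossmet.synth import MsmsSpectrum, Peak, simulate_spectra

DEFAULTS = NetworkParams()


def optimal_assignment_score(a, b, params):
    """Exact maximum-weight one-to-one assignment over candidate pairs."""
    wa = np.sqrt(a.intensity_array) if params.sqrt_intensity else a.intensity_array
    wb = np.sqrt(b.intensity_array) if params.sqrt_intensity else b.intensity_array
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    weights = np.zeros((len(wa), len(wb)))
    for i, j in candidate_pairs(a, b, params):
        weights[i, j] = wa[i] * wb[j]
    rows, cols = linear_sum_assignment(-weights)
    return float(weights[rows, cols].sum())


def spec(fid, prec, peaks):
    return MsmsSpectrum(fid, prec, 1.0, [Peak(m, i) for m, i in peaks])


# toy spectra: one exact shared ion, one conjugate-shifted ion, distractors
TOY_A = spec("a", 211.087, [(118.065, 100), (150.0, 20), (183.092, 80), (105.0, 10)])
TOY_B = spec("b", 387.119, [(118.065, 90), (359.124, 30), (160.0, 15), (250.0, 5)])
TOY_C = spec("c", 291.044, [(118.065, 70), (263.048, 25), (130.0, 40)])


class TestSpectralSimilarity:
    def test_self_similarity_is_one(self):
        r = spectral_similarity(TOY_A, TOY_A, DEFAULTS)
        assert r.score == pytest.approx(1.0, abs=1e-9)
        assert r.matched_count == len(TOY_A.peaks)

    def test_disjoint_spectra_score_zero(self):
        a = spec("a", 200.0, [(100.0, 10), (110.0, 10)])
        b = spec("b", 200.0, [(150.0, 10), (160.0, 10)])
        r = spectral_similarity(a, b, DEFAULTS)
        assert r.score == 0.0 and r.matched_count == 0

    def test_shifted_mode_matches_conjugate_fragments(self):
        unshifted = spectral_similarity(TOY_A, TOY_B, NetworkParams(score_mode="unshifted"))
        shifted = spectral_similarity(TOY_A, TOY_B, DEFAULTS)
        # 359.124 = 183.092 + precursor delta: only the modified cosine sees it
        assert shifted.matched_count == unshifted.matched_count + 1
        assert shifted.score > unshifted.score

    @pytest.mark.parametrize("pair", [(TOY_A, TOY_B), (TOY_A, TOY_C), (TOY_B, TOY_C)])
    def test_greedy_equals_optimal_on_toys(self, pair):
        greedy = spectral_similarity(*pair, DEFAULTS).score
        assert greedy == pytest.approx(optimal_assignment_score(*pair, DEFAULTS), abs=1e-12)

    def test_symmetric(self):
        assert spectral_similarity(TOY_A, TOY_B, DEFAULTS) == spectral_similarity(
            TOY_B, TOY_A, DEFAULTS
        )

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ValueError):
            spectral_similarity(TOY_A, MsmsSpectrum("e", 200.0, 1.0, []), DEFAULTS)

    def test_matchms_agreement(self):
        """Independent oracle: matchms ModifiedCosine, raw-intensity mode."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        params = NetworkParams(sqrt_intensity=False)
        for a, b in [(TOY_A, TOY_B), (TOY_A, TOY_C), (TOY_B, TOY_C)]:
            sa = matchms.Spectrum(
                mz=a.mz_array.astype(float),
                intensities=a.intensity_array.astype(float),
                metadata={"precursor_mz": a.precursor_mz},
                metadata_harmonization=False,
            )
            sb = matchms.Spectrum(
                mz=b.mz_array.astype(float),
                intensities=b.intensity_array.astype(float),
                metadata={"precursor_mz": b.precursor_mz},
                metadata_harmonization=False,
            )
            ref = ModifiedCosine(tolerance=params.fragment_tol).pair(sa, sb)
            mine = spectral_similarity(a, b, params)
            assert mine.score == pytest.approx(float(ref["score"]), abs=1e-9)
            assert mine.matched_count == int(ref["matches"])


_peaks = st.lists(
    st.tuples(
        st.floats(min_value=100.0, max_value=300.0, allow_nan=False),
        st.floats(min_value=1.0, max_value=100.0, allow_nan=False),
    ),
    min_size=1,
    max_size=8,
    unique_by=lambda p: round(p[0], 3),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pa=_peaks, pb=_peaks, scale=st.floats(min_value=0.1, max_value=50.0))
def test_similarity_properties(pa, pb, scale):
    a = spec("a", 250.0, pa)
    b = spec("b", 310.0, pb)
    r_ab = spectral_similarity(a, b, DEFAULTS)
    r_ba = spectral_similarity(b, a, DEFAULTS)
    assert 0.0 <= r_ab.score <= 1.0 + 1e-12
    assert r_ab.score == pytest.approx(r_ba.score, abs=1e-12)
    # invariant to uniform intensity scaling
    b_scaled = spec("b", 310.0, [(m, i * scale) for m, i in pb])
    assert spectral_similarity(a, b_scaled, DEFAULTS).score == pytest.approx(
        r_ab.score, abs=1e-9
    )
    # greedy within 5% of the exact optimal assignment
    opt = optimal_assignment_score(a, b, DEFAULTS)
    assert r_ab.score >= 0.95 * opt - 1e-12
    assert r_ab.score <= opt + 1e-12


def reference_network(spectra, params):
    """Naive O(n^2) edge construction, independent of build_network's code."""
    n = len(spectra)
    passing = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = spectral_similarity(spectra[i], spectra[j], params)
            if r.score > params.cosine_threshold and r.matched_count >= params.min_matched_peaks:
                passing[(spectra[i].feature_id, spectra[j].feature_id)] = (
                    r.score,
                    spectra[j].precursor_mz - spectra[i].precursor_mz,
                )
    ranks = {}
    for (u, v), (score, shift) in passing.items():
        ranks.setdefault(u, []).append((-score, abs(shift), v))
        ranks.setdefault(v, []).append((-score, abs(shift), u))
    keep = set()
    for (u, v), (score, shift) in passing.items():
        top_u = [nb for *_, nb in sorted(ranks[u])[: params.top_k]]
        top_v = [nb for *_, nb in sorted(ranks[v])[: params.top_k]]
        if v in top_u and u in top_v:
            keep.add(frozenset((u, v)))
    return keep


class TestBuildNetwork:
    def test_two_identical_spectra_one_edge(self):
        a = spec("a", 211.087, [(100 + i, 10 + i) for i in range(7)])
        b = spec("b", 211.087, [(100 + i, 10 + i) for i in range(7)])
        net = build_network([a, b], DEFAULTS)
        assert net.n_edges == 1
        (u, v, data), = net.graph.edges(data=True)
        assert data["shift"] == pytest.approx(0.0)

    def test_edges_satisfy_all_rules(self, noisy_design):
        sims = simulate_spectra(noisy_design)
        net = build_network(sims["invitro"].spectra, DEFAULTS)
        for u, v, data in net.graph.edges(data=True):
            assert data["score"] > DEFAULTS.cosine_threshold
            assert data["matched"] >= DEFAULTS.min_matched_peaks

    def test_matches_naive_reference(self, zero_noise_design):
        spectra = simulate_spectra(zero_noise_design)["invivo"].spectra[:15]
        net = build_network(spectra, DEFAULTS)
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        assert got == reference_network(spectra, DEFAULTS)

    def test_topk_nminus1_is_noop(self, zero_noise_design):
        spectra = simulate_spectra(zero_noise_design)["invivo"].spectra
        loose = NetworkParams(top_k=len(spectra) - 1)
        strictless = build_network(spectra, loose)
        # without top-k the edge set is exactly threshold+min-matched filtering
        expected = reference_network(spectra, loose)
        assert {frozenset(e) for e in strictless.graph.edges} == expected

    def test_raising_threshold_only_removes_edges(self, zero_noise_design):
        spectra = simulate_spectra(zero_noise_design)["invitro"].spectra
        lo = build_network(spectra, NetworkParams(cosine_threshold=0.5))
        hi = build_network(spectra, NetworkParams(cosine_threshold=0.9))
        lo_edges = {frozenset(e) for e in lo.graph.edges}
        hi_edges = {frozenset(e) for e in hi.graph.edges}
        assert hi_edges <= lo_edges

    def test_no_self_edges(self, zero_noise_design):
        spectra = simulate_spectra(zero_noise_design)["invitro"].spectra
        net = build_network(spectra, DEFAULTS)
        assert all(u != v for u, v in net.graph.edges)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([], DEFAULTS)


class TestClusters:
    def test_edgeless_network_all_singletons(self):
        spectra = [
            spec(f"s{i}", 200.0 + 30 * i, [(100.0 + 17 * i, 10), (110.0 + 17 * i, 5)])
            for i in range(5)
        ]
        net = build_network(spectra, DEFAULTS)
        assert net.n_edges == 0
        assert len(clusters(net)) == 5

    def test_parent_cluster_contains_in_matrix_metabolites(self, zero_noise_result):
        for name, net in zero_noise_result.networks.items():
            sim = zero_noise_result.matrices[name]
            parent_fid = next(k for k, v in sim.truth_map.items() if v == "parent")
            comp = next(c for c in clusters(net) if parent_fid in c)
            members = {sim.truth_map[f] for f in comp}
            expected = {
                e.ref
                for e in zero_noise_result.design.truth
                if (e.in_vitro if name == "invitro" else e.in_vivo)
            }
            assert expected <= members

    def test_graphml_round_trip(self, zero_noise_design, tmp_path):
        spectra = simulate_spectra(zero_noise_design)["invivo"].spectra
        net = build_network(spectra, DEFAULTS)
        path = tmp_path / "net.graphml"
        export_graphml(net, str(path))
        back = read_graphml(str(path))
        assert back.n_edges == net.n_edges
        assert back.n_nodes == net.n_nodes


def test_network_params_validation():
    with pytest.raises(ValueError):
        NetworkParams(cosine_threshold=1.5)
    with pytest.raises(ValueError):
        NetworkParams(fragment_tol=-0.01)
    with pytest.raises(ValueError):
        NetworkParams(score_mode="banana")
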