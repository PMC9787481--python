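"""Synthetic study generator: truth set, spectra, kinetics, I/O round-trips."""

import hashlib

import pytest

from crossmet.formulas import parse_formula
from crossmet.synth import (
    KINETIC_EXCEPTION_REF,
    MsmsSpectrum,
    NoiseModel,
    Peak,
    default_truth_set,
    read_feature_table,
    read_mgf,
    simulate_spectra,
    write_feature_table,
    write_mgf,
)


class TestTruthSet:
    def test_fourteen_metabolites(self, zero_noise_design):
        assert len(zero_noise_design.truth) == 14

    def test_glucuronide_entry(self, zero_noise_design):
        m5a = next(e for e in zero_noise_design.truth if e.ref == "M5a")
        assert m5a.chain == ("glucuronidation",)
        assert m5a.rt_min == 3.7
        assert m5a.in_vivo and m5a.in_vitro
        assert m5a.theoretical_mz(zero_noise_design.parent) == pytest.approx(
            387.1192, abs=5e-5
        )

    def test_dimethyl_sulfate_in_vitro_only(self, zero_noise_design):
        m4 = next(e for e in zero_noise_design.truth if e.ref == "M4")
        assert m4.in_vitro and not m4.in_vivo

    def test_matrix_presence_counts(self, zero_noise_design):
        assert sum(e.in_vivo for e in zero_noise_design.truth) == 8
        assert sum(e.in_vitro for e in zero_noise_design.truth) == 12

    def test_parent_fragments_include_mrm_ions(self, zero_noise_design):
        mzs = [round(p.mz, 1) for p in zero_noise_design.parent_fragments]
        assert 118.1 in mzs or 118.0 in mzs
        assert 183.1 in mzs


class TestSimulateSpectra:
    def test_zero_noise_precursors_exact(self, zero_noise_design):
        sims = simulate_spectra(zero_noise_design)
        parent = zero_noise_design.parent
        for sim in sims.values():
            by_ref = {v: k for k, v in sim.truth_map.items()}
            spectra = {s.feature_id: s for s in sim.spectra}
            assert spectra[by_ref["parent"]].precursor_mz == pytest.approx(
                zero_noise_design.parent_mz, abs=1e-12
            )
            for entry in zero_noise_design.truth:
                if entry.ref not in by_ref:
                    continue
                assert spectra[by_ref[entry.ref]].precursor_mz == pytest.approx(
                    entry.theoretical_mz(parent), abs=1e-12
                )

    def test_conjugates_share_six_fragments_with_parent(self, zero_noise_design):
        # exhaustive pairing oracle: count parent peaks with a metabolite
        # peak within 0.02 Da under a one-to-one constraint
        sims = simulate_spectra(zero_noise_design)
        for sim in sims.values():
            spectra = {s.feature_id: s for s in sim.spectra}
            parent_fid = next(k for k, v in sim.truth_map.items() if v == "parent")
            pmzs = list(spectra[parent_fid].mz_array)
            for fid, ref in sim.truth_map.items():
                if ref in ("parent", "decoy"):
                    continue
                mmzs = list(spectra[fid].mz_array)
                shared = 0
                used = set()
                for a in pmzs:
                    for j, b in enumerate(mmzs):
                        if j not in used and abs(a - b) <= 0.02:
                            used.add(j)
                            shared += 1
                            break
                assert shared >= 6, f"{ref} shares only {shared} ions with parent"

    def test_precursors_within_acquisition_range(self, noisy_design):
        for sim in simulate_spectra(noisy_design).values():
            for s in sim.spectra:
                assert 100.0 <= s.precursor_mz <= 700.0

    def test_in_vivo_kinetic_ordering(self, zero_noise_design):
        sims = simulate_spectra(zero_noise_design)
        sim = sims["invivo"]
        spectra = {s.feature_id: s for s in sim.spectra}
        for fid, ref in sim.truth_map.items():
            if ref in ("parent", "decoy"):
                continue
            levels = spectra[fid].sample_intensities
            if levels.get("H1", 0) and levels.get("H3", 0):
                if ref == KINETIC_EXCEPTION_REF:
                    assert levels["H3"] > levels["H1"]
                else:
                    assert levels["H1"] > levels["H3"]

    def test_in_vitro_appearance_then_decline(self, zero_noise_design):
        sim = simulate_spectra(zero_noise_design)["invitro"]
        spectra = {s.feature_id: s for s in sim.spectra}
        for fid, ref in sim.truth_map.items():
            if ref in ("parent", "decoy"):
                continue
            lv = spectra[fid].sample_intensities
            assert lv["H0"] == 0.0
            assert lv["H24"] > lv["H8"]
            assert lv["H24"] > lv["H48"]

    def test_deterministic_for_fixed_seed(self, tmp_path):
        design = default_truth_set(zero_noise=False, seed=42)
        digests = []
        for run in range(2):
            sims = simulate_spectra(design)
            path = tmp_path / f"run{run}.mgf"
            write_mgf(sims["invivo"].spectra, str(path))
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self):
        a = simulate_spectra(default_truth_set(seed=1))["invivo"].spectra[0]
        b = simulate_spectra(default_truth_set(seed=2))["invivo"].spectra[0]
        assert a.precursor_mz != b.precursor_mz


class TestIo:
    def test_mgf_round_trip(self, zero_noise_design, tmp_path):
        sim = simulate_spectra(zero_noise_design)["invitro"]
        path = tmp_path / "study.mgf"
        write_mgf(sim.spectra, str(path))
        back = read_mgf(str(path))
        assert len(back) == len(sim.spectra)
        for orig, rt in zip(sim.spectra, back):
            assert rt.feature_id == orig.feature_id
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
            assert rt.rt_min == pytest.approx(orig.rt_min, abs=1e-4)
            assert len(rt.peaks) == len(orig.peaks)
            for p, q in zip(orig.peaks, rt.peaks):
                assert q.mz == pytest.approx(p.mz, abs=1e-4)

    def test_mgf_missing_pepmass_rejected(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(ValueError, match="PEPMASS"):
            read_mgf(str(path))

    def test_feature_table_round_trip(self, zero_noise_design, tmp_path):
        sim = simulate_spectra(zero_noise_design)["invivo"]
        path = tmp_path / "features.csv"
        write_feature_table(sim.feature_table, str(path))
        back = read_feature_table(str(path), expected_samples=sim.samples)
        assert back.shape == sim.feature_table.shape
        assert back["H1"].tolist() == pytest.approx(sim.feature_table["H1"].tolist())

    def test_feature_table_sample_mismatch(self, zero_noise_design, tmp_path):
        sim = simulate_spectra(zero_noise_design)["invivo"]
        path = tmp_path / "features.csv"
        write_feature_table(sim.feature_table, str(path))
        with pytest.raises(ValueError, match="sample columns"):
            read_feature_table(str(path), expected_samples=("H1", "H99"))


class TestDomainTypes:
    def test_peak_validation(self):
        with pytest.raises(ValueError):
            Peak(-1.0, 10.0)
        with pytest.raises(ValueError):
            Peak(100.0, -5.0)

    def test_spectrum_sorts_peaks_and_checks_range(self):
        s = MsmsSpectrum("f", 211.087, 5.0, [Peak(200.0, 1.0), Peak(100.0, 2.0)])
        assert [p.mz for p in s.peaks] == [100.0, 200.0]
        with pytest.raises(ValueError):
            MsmsSpectrum("f", 999.0, 5.0, [Peak(100.0, 1.0)])

    def test_noise_model_none(self):
        nm = NoiseModel.none()
        assert nm.mz_jitter_sd == 0.0 and nm.n_noise_peaks == 0
        assert nm.n_decoy_features > 0
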