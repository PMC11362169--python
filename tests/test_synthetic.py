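"""Ground-truth generators: EX2 exchange, peptide maps, assay curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdxconf as hc
from hdxconf.synthetic import homologous_competition_model


class TestExchangeModel:
    def model(self, k=1.0, logpf=0.0, bx=0.0, seq="AG"):
        n = len(seq)
        k_arr = np.array([0.0 if aa == "P" else k for aa in seq])
        return hc.ExchangeModel(seq, k_arr, {"s": np.full(n, float(logpf))},
                                back_exchange=bx)

    def test_zero_exposure_means_zero_uptake(self):
        m = self.model()
        assert m.peptide_uptake("s", 1, 2, 0.0) == 0.0

    def test_saturation_limit_reaches_one(self):
        m = self.model(k=1.0, logpf=0.0, bx=0.0)
        assert m.deuteration("s", 1e9)[1] == pytest.approx(1.0)

    def test_closed_form_matches_ode_integration(self):
        # dD/dt = k_obs (1 - D), k_obs = 0.01 / 10^1, t = 900 s
        from scipy.integrate import solve_ivp

        m = self.model(k=0.01, logpf=1.0)
        analytic = m.deuteration("s", 900.0)[1]
        sol = solve_ivp(lambda t, d: 0.001 * (1 - d), (0, 900), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert analytic == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert analytic == pytest.approx(1 - np.exp(-0.9), abs=1e-12)

    def test_prolines_never_exchange(self):
        m = self.model(seq="APA")
        assert m.deuteration("s", 1e4)[1] == 0.0

    def test_uptake_excludes_first_residue(self):
        m = self.model(seq="AAAA")
        # peptide 1-4 at saturation: residues 2,3,4 -> 3 Da
        assert m.peptide_uptake("s", 1, 4, 1e9) == pytest.approx(3.0)

    def test_back_exchange_scales_plateau(self):
        m = self.model(bx=0.3)
        assert m.deuteration("s", 1e9)[1] == pytest.approx(0.7)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(t1=st.floats(0, 5000), t2=st.floats(0, 5000),
           lp=st.floats(0, 5), dlp=st.floats(0, 2))
    def test_monotone_in_time_and_protection(self, t1, t2, lp, dlp):
        lo, hi = sorted((t1, t2))
        m = hc.ExchangeModel("AA", np.ones(2), {"a": np.full(2, lp),
                                                "b": np.full(2, lp + dlp)})
        assert m.deuteration("a", hi)[1] >= m.deuteration("a", lo)[1]
        assert m.deuteration("b", hi)[1] <= m.deuteration("a", hi)[1]

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="k_int"):
            hc.ExchangeModel("AA", np.array([1.0]), {"s": np.zeros(2)})
        with pytest.raises(ValueError, match="back_exchange"):
            hc.ExchangeModel("AA", np.ones(2), {"s": np.zeros(2)}, back_exchange=1.0)
        with pytest.raises(ValueError, match="logPF"):
            hc.ExchangeModel("AA", np.ones(2), {"s": -np.ones(2)})


class TestUptakeSimulation:
    def test_truth_uptake_bounded_by_max_uptake(self, small_dataset):
        model, pmap, _, _ = small_dataset
        for start, end, seq in pmap.peptides:
            truth = model.peptide_uptake("variant", start, end, 1e9)
            assert truth <= hc.max_uptake(seq) + 1e-9

    def test_exposure_zero_rows_have_zero_truth(self, small_dataset):
        model, pmap, _, _ = small_dataset
        table = hc.simulate_uptake_table(model, pmap, noise_sd=0.0, seed=0)
        t0 = hc.uptake_from_centroids(table)
        z = t0.data[t0.data["exposure"] == 0]
        assert np.allclose(z["uptake"], 0.0, atol=1e-12)

    def test_same_seed_is_bit_identical(self, small_dataset):
        model, pmap, _, _ = small_dataset
        t1 = hc.simulate_uptake_table(model, pmap, seed=42)
        t2 = hc.simulate_uptake_table(model, pmap, seed=42)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_round_trips_through_io_without_loss(self, small_dataset, tmp_path):
        _, _, table, _ = small_dataset
        path = tmp_path / "t.csv"
        hc.write_state_table(table, path)
        back = hc.read_state_table(path)
        assert len(back.rejected) == 0
        assert np.array_equal(back.data["centroid"].to_numpy(),
                              table.data["centroid"].to_numpy())

    def test_bad_inputs_rejected(self, small_dataset):
        model, pmap, _, _ = small_dataset
        with pytest.raises(ValueError, match="0 s reference"):
            hc.simulate_uptake_table(model, pmap, exposures=[30.0])
        with pytest.raises(ValueError, match="noise_sd"):
            hc.simulate_uptake_table(model, pmap, noise_sd=-1.0)
        bad_map = hc.PeptideMap(((1, 5, model.sequence[:5]),), model.length + 50)
        with pytest.raises(ValueError, match="different lengths"):
            hc.simulate_uptake_table(model, bad_map)

    def test_peptide_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hc.PeptideMap(((5, 20, "A" * 16),), 10)


class TestPeptideMap:
    def test_nonoverlapping_tiling_metrics(self):
        seq = "A" * 100
        peptides = tuple((i * 10 + 1, i * 10 + 10, seq[i * 10:i * 10 + 10])
                         for i in range(10))
        cov, red = hc.coverage_metrics(hc.PeptideMap(peptides, 100), 100)
        assert cov == 100.0
        assert red == 1.0

    def test_duplicate_peptides_double_redundancy(self):
        pmap = [(1, 10), (1, 10)]
        cov, red = hc.coverage_metrics(pmap, 10)
        assert cov == 100.0
        assert red == 2.0

    def test_redundancy_matches_brute_force_enumeration(self):
        pmap = hc.generate_peptide_map("A" * 200, seed=9)
        cov, red = hc.coverage_metrics(pmap, 200)
        counts = np.zeros(201)
        for s, e in pmap.intervals:
            for r in range(s, e + 1):
                counts[r] += 1
        covered = counts[1:] > 0
        assert cov == pytest.approx(100.0 * covered.sum() / 200)
        assert red == pytest.approx(counts[1:][covered].mean())

    def test_empty_map_flagged(self):
        cov, red = hc.coverage_metrics([], 100)
        assert cov == 0.0
        assert np.isnan(red)

    def test_mean_length_validation(self):
        with pytest.raises(ValueError, match=">= 3"):
            hc.generate_peptide_map("A" * 50, mean_length=2)
        with pytest.raises(ValueError, match="exceeds"):
            hc.generate_peptide_map("AAAA", mean_length=10)


class TestAssayCurves:
    def test_full_competition_approaches_background(self):
        v = homologous_competition_model(1e12, 34.0, 600.0, 1000.0, 100.0)
        assert v == pytest.approx(100.0, abs=1e-4)

    def test_hand_evaluated_point(self):
        # cold = 0, hot = 34 nM, Kd = 600 nM, Bmax = 1000, bg = 100
        v = homologous_competition_model(0.0, 34.0, 600.0, 1000.0, 100.0)
        assert v == pytest.approx(1000 * 34 / 634 + 100, abs=1e-9)
        assert v == pytest.approx(153.6, abs=0.05)

    def test_binding_validation(self):
        with pytest.raises(ValueError, match="Kd"):
            hc.simulate_binding_curve(kd=0.0)
        with pytest.raises(ValueError, match="non-negative"):
            hc.simulate_binding_curve(cold_concs=[-1.0, 0.0, 1.0, 2.0])

    def test_noiseless_melt_derivative_peaks_at_tm(self):
        data, _ = hc.simulate_melt_curve(tm=60.0, noise_sd=0.0)
        res = hc.melt_temperature(data["temperature_C"], data["fluorescence"])
        assert res.detected
        assert res.tm == pytest.approx(60.0, abs=0.25)

    def test_melt_validation(self):
        with pytest.raises(ValueError, match="within the temperature ramp"):
            hc.simulate_melt_curve(tm=95.0)

    def test_binding_determinism(self):
        d1, _ = hc.simulate_binding_curve(seed=3)
        d2, _ = hc.simulate_binding_curve(seed=3)
        pd.testing.assert_frame_equal(d1, d2)
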