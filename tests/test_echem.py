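"""CA current extraction, CV midpoint estimation, strain statistics."""

import numpy as np
import pytest

from macroscreen import echem, synth
from macroscreen.echem import (
    CATrace,
    StrainCurrentSummary,
    biological_current,
    compare_strains,
    estimate_midpoint,
    steady_state_current,
)


def flat_trace(value=-5e-6, n=300, **kw):
    return CATrace("s", np.arange(n, dtype=float), np.full(n, value), **kw)


class TestSteadyState:
    def test_constant_trace(self):
        assert steady_state_current(flat_trace(-5e-6)) == -5e-6

    def test_alternating_tail_mean(self):
        cur = np.full(300, -5e-6)
        cur[-100:] = np.where(np.arange(100) % 2 == 0, -4e-6, -6e-6)
        tr = CATrace("s", np.arange(300.0), cur)
        assert steady_state_current(tr) == pytest.approx(-5e-6)

    def test_short_trace_is_an_error(self):
        with pytest.raises(ValueError, match="99"):
            steady_state_current(flat_trace(n=99))


class TestBiologicalCurrent:
    def test_abiotic_only_trace_gives_zero(self):
        spec = synth.CATraceSpec(
            baseline_current=-2e-6, abiotic_current=-2e-6, noise_sd=0.0
        )
        tr = synth.simulate_ca_trace(spec, seed=0)
        assert biological_current(tr) == 0.0

    def test_offset_invariance(self):
        spec = synth.CATraceSpec(noise_sd=2e-8)
        tr = synth.simulate_ca_trace(spec, seed=3)
        shifted = CATrace(
            "s", tr.times_s, tr.currents_A + 5e-6,
            inhibitor_time_s=tr.inhibitor_time_s,
        )
        assert biological_current(shifted) == pytest.approx(
            biological_current(tr), abs=1e-18
        )

    def test_missing_inhibitor_time_is_explicit(self):
        with pytest.raises(ValueError, match="inhibitor_time"):
            biological_current(flat_trace())

    def test_insufficient_segment_is_explicit(self):
        tr = flat_trace(n=250, inhibitor_time_s=100.0)  # pre segment too short
        with pytest.raises(ValueError, match="settling"):
            biological_current(tr)

    def test_monte_carlo_within_standard_error(self):
        spec = synth.CATraceSpec(noise_sd=5e-8)
        se = spec.noise_sd * np.sqrt(2.0 / 100.0)
        est = [
            biological_current(synth.simulate_ca_trace(spec, seed=s))
            for s in range(100)
        ]
        err = np.abs(np.array(est) - (-8e-6))
        assert np.mean(err <= 3 * se) >= 0.97


class TestMidpoint:
    def test_symmetric_noiseless_wave(self):
        spec = synth.CVScanSpec(
            formal_potential_mV=-50.0, hysteresis_mV=0.0, noise_sd=0.0
        )
        mp = estimate_midpoint(synth.simulate_cv_scan(spec, seed=0))
        assert mp.midpoint_mV == pytest.approx(-50.0, abs=spec.step_mV / 2)

    def test_hysteresis_averages_out(self):
        spec = synth.CVScanSpec(
            formal_potential_mV=-50.0, hysteresis_mV=20.0, noise_sd=0.0
        )
        mp = estimate_midpoint(synth.simulate_cv_scan(spec, seed=0))
        assert mp.forward_inflection_mV == pytest.approx(-60.0, abs=1.0)
        assert mp.reverse_inflection_mV == pytest.approx(-40.0, abs=1.0)
        assert mp.midpoint_mV == pytest.approx(-50.0, abs=1.0)

    def test_pure_capacitive_scan_flags_edge(self):
        E = np.arange(-322.0, 222.1, 2.0)
        slope = 1e-9  # featureless capacitive ramp
        scan = echem.CVScan(
            "s", E[::-1].copy(), (slope * E)[::-1].copy(), E, slope * E
        )
        with pytest.warns(UserWarning, match="boundary"):
            mp = estimate_midpoint(scan)
        assert "edge_inflection" in mp.flags
        assert mp.midpoint_mV is None

    def test_branch_relabeling_symmetry(self):
        spec = synth.CVScanSpec(formal_potential_mV=-120.0)
        scan = synth.simulate_cv_scan(spec, seed=7)
        swapped = echem.CVScan(
            "s",
            scan.reverse_potential_mV[::-1].copy(),
            scan.reverse_current_A[::-1].copy(),
            scan.forward_potential_mV[::-1].copy(),
            scan.forward_current_A[::-1].copy(),
        )
        a = estimate_midpoint(scan)
        b = estimate_midpoint(swapped)
        assert a.midpoint_mV == pytest.approx(b.midpoint_mV, abs=1e-9)

    def test_estimator_tightens_as_noise_and_grid_shrink(self):
        errs = []
        for noise, step in ((2e-7, 4.0), (5e-8, 2.0), (0.0, 0.5)):
            spec = synth.CVScanSpec(
                formal_potential_mV=-150.0, noise_sd=noise, step_mV=step
            )
            mp = estimate_midpoint(synth.simulate_cv_scan(spec, seed=11))
            errs.append(abs(mp.midpoint_mV - (-150.0)))
        assert errs[2] <= 0.5
        assert errs[2] <= errs[0] + 1e-9

    def test_sparse_branch_rejected(self):
        E = np.linspace(-322.0, 222.0, 10)
        scan_kwargs = dict(
            forward_potential_mV=E[::-1].copy(),
            forward_current_A=np.zeros(10),
            reverse_potential_mV=E,
            reverse_current_A=np.zeros(10),
        )
        with pytest.raises(ValueError, match="at least 20"):
            estimate_midpoint(echem.CVScan("s", **scan_kwargs))

    def test_spar_mapping(self):
        assert echem.edf_from_spar(0.70, 273) == pytest.approx(8.0)
        assert echem.edf_from_spar(1.0, 273) == 2.0
        # monotone: more spar -> fewer degrees of freedom
        edfs = [echem.edf_from_spar(s, 273) for s in (0.1, 0.5, 0.9)]
        assert edfs == sorted(edfs, reverse=True)


class TestStrainComparison:
    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        mk = lambda name, mu: StrainCurrentSummary(
            name, list(rng.normal(mu, 0.5e-6, size=4))
        )
        return [mk("WT", -8e-6), mk("mutX", -1e-6), mk("mutY", -7.8e-6)]

    def test_large_effect_mutant_flagged(self):
        cmp_res = compare_strains(self.planted(), reference="WT")
        assert "mutX" in cmp_res.flagged
        assert "mutY" not in cmp_res.flagged
        assert cmp_res.p_value < 0.05

    def test_identical_groups_give_zero_between_ss(self):
        vals = [-5e-6, -6e-6, -4e-6]
        summaries = [
            StrainCurrentSummary("WT", vals),
            StrainCurrentSummary("mut", vals),
        ]
        cmp_res = compare_strains(summaries, reference="WT")
        assert cmp_res.anova.loc["C(strain)", "sum_sq"] == pytest.approx(0.0, abs=1e-30)
        assert cmp_res.flagged == []

    def test_tukey_agrees_with_independent_implementation(self):
        from scipy.stats import tukey_hsd

        summaries = self.planted(seed=5)
        cmp_res = compare_strains(summaries, reference="WT")
        ref = tukey_hsd(*[np.asarray(s.currents_A) for s in summaries])
        names = [s.strain_id for s in summaries]
        for _, row in cmp_res.tukey.iterrows():
            i, j = names.index(row["group1"]), names.index(row["group2"])
            assert float(row["p_adj"]) == pytest.approx(
                ref.pvalue[i, j], abs=2e-3
            )

    def test_under_replicated_strain_excluded_with_warning(self):
        summaries = self.planted() + [StrainCurrentSummary("thin", [-3e-6, -4e-6])]
        with pytest.warns(UserWarning, match="thin"):
            cmp_res = compare_strains(summaries, reference="WT")
        assert cmp_res.excluded == ["thin"]
        assert "thin" not in set(cmp_res.tukey.group1) | set(cmp_res.tukey.group2)

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            compare_strains(self.planted(), reference="nope")


class TestIO:
    def test_ca_round_trip(self, tmp_path):
        tr = synth.simulate_ca_trace(synth.CATraceSpec(), seed=1)
        path = tmp_path / "ca.csv"
        echem.write_ca_csv(tr, path)
        back = echem.read_ca_csv(path, inhibitor_time_s=600.0)
        assert np.allclose(back.currents_A, tr.currents_A)
        assert biological_current(back) == pytest.approx(biological_current(tr))

    def test_cv_round_trip(self, tmp_path):
        scan = synth.simulate_cv_scan(synth.CVScanSpec(), seed=1)
        path = tmp_path / "cv.csv"
        echem.write_cv_csv(scan, path)
        back = echem.read_cv_csv(path)
        assert np.allclose(back.forward_current_A, scan.forward_current_A)
        assert np.all(np.diff(back.reverse_potential_mV) > 0)

    def test_reference_conversion(self):
        assert echem.to_she(0.0, "Ag/AgCl") == pytest.approx(222.0)
        assert echem.to_she(-600.0, "Ag/AgCl", offset_mV=222.0) == pytest.approx(-378.0)
        assert echem.to_she(100.0) == 100.0
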