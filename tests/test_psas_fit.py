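"""Calibration, ratio normalization, slope fitting, matrix assembly,
classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import grid_search_slope
from psas.assay_sim import (
    AssayRecord,
    StandardCurve,
    default_standard_curves,
    make_scenario,
    observe_absorbance,
    simulate_assay,
)
from psas.psas_fit import (
    BaselineError,
    CalibrationError,
    FitError,
    MatrixError,
    SolubilityCurve,
    build_matrix,
    calibrate,
    classify,
    fit_psas,
    to_ratio,
)
from psas.residues import AROMATIC_RESIDUES, CANONICAL_RESIDUES


def make_curve(conc, ratio, solute="Trp", solvent="Gly", s0=1.0):
    conc = np.asarray(conc, dtype=float)
    return SolubilityCurve(
        solute=solute, solvent=solvent, s0=s0,
        conc=conc, ratio=np.asarray(ratio, dtype=float),
        n_replicates=np.ones(len(conc), dtype=int),
    )


class TestCalibrate:
    def test_linear_inversion(self):
        curve = StandardCurve("Trp", 280, slope=1.0, intercept=0.0)
        assert calibrate(0.5, curve, dilution=10) == pytest.approx(5.0)

    def test_blank_reads_zero(self):
        curve = StandardCurve("Trp", 280, slope=2.0, intercept=0.3)
        assert calibrate(0.3, curve, dilution=7) == 0.0

    def test_below_intercept_is_error(self):
        curve = StandardCurve("Trp", 280, slope=2.0, intercept=0.3)
        with pytest.raises(CalibrationError):
            calibrate(0.1, curve)

    def test_inverse_of_observation_layer(self):
        """calibrate . observe_absorbance recovers solubility to 1e-9."""
        rng = np.random.default_rng(42)
        curves = default_standard_curves()
        records = [
            AssayRecord(
                solute=rng.choice(AROMATIC_RESIDUES),
                solvent="Gly", conc=0.1, replicate=1,
                solubility=float(rng.uniform(0.01, 5.0)),
            )
            for _ in range(100)
        ]
        observed = observe_absorbance(records, curves)
        for rec in observed:
            back = calibrate(rec.absorbance, curves[rec.solute], rec.dilution)
            assert back == pytest.approx(rec.solubility, abs=1e-9)


class TestToRatio:
    def records(self, triples, solute="Trp", solvent="Gly"):
        return [
            AssayRecord(solute, solvent, c, i + 1, s)
            for i, (c, s) in enumerate(triples)
        ]

    def test_ratio_arithmetic(self):
        curve = to_ratio(self.records([(0.0, 2.0), (0.0, 2.0), (1.0, 3.0)]))
        assert curve.s0 == 2.0
        assert dict(zip(curve.conc, curve.ratio)) == {0.0: 1.0, 1.0: 1.5}

    def test_baseline_ratio_is_exactly_one(self):
        curve = to_ratio(self.records([(0.0, 1.9), (0.0, 2.2), (0.5, 2.0)]))
        assert curve.ratio[0] == 1.0

    def test_baseline_only_curve_is_unfittable(self):
        curve = to_ratio(self.records([(0.0, 2.0), (0.0, 2.1)]))
        assert not curve.fittable
        with pytest.raises(FitError):
            fit_psas(curve)

    def test_zero_baseline_rejected(self):
        with pytest.raises(BaselineError):
            to_ratio(self.records([(0.0, 0.0), (1.0, 1.0)]))

    def test_missing_baseline_instructs(self):
        with pytest.raises(BaselineError, match="s0"):
            to_ratio(self.records([(0.5, 2.0), (1.0, 3.0)]))

    def test_explicit_s0_substitutes_for_baseline(self):
        curve = to_ratio(self.records([(1.0, 3.0)]), s0=2.0)
        assert dict(zip(curve.conc, curve.ratio)) == {1.0: 1.5}

    def test_mixed_pairs_rejected(self):
        records = self.records([(0.0, 2.0)]) + self.records([(0.0, 2.0)], solvent="Ala")
        with pytest.raises(ValueError, match="pairs"):
            to_ratio(records)


class TestFitPsas:
    def test_two_point_slope(self):
        entry = fit_psas(make_curve([0.0, 1.0], [1.0, 1.5]))
        assert entry.psas == pytest.approx(0.5)
        assert entry.fit_mode == "fixed"

    def test_closed_form_on_exact_line(self):
        c = np.array([0.0, 0.5, 1.0, 1.5])
        entry = fit_psas(make_curve(c, 1.0 - 0.3 * c))
        assert entry.psas == pytest.approx(-0.3, abs=1e-12)
        assert entry.stderr == pytest.approx(0.0, abs=1e-12)
        assert entry.r2 == pytest.approx(1.0)

    def test_free_intercept_mode(self):
        c = np.array([0.0, 0.5, 1.0, 1.5])
        entry = fit_psas(make_curve(c, 1.1 + 0.4 * c), mode="free")
        assert entry.psas == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        c = np.sort(rng.uniform(0, 2, size=n))
        ratio = 1.0 + rng.uniform(-2, 2) * c + rng.normal(0, 0.1, size=n)
        entry = fit_psas(make_curve(c, ratio))
        oracle = grid_search_slope(c, ratio)
        assert entry.psas == pytest.approx(oracle, abs=1e-6)

    def test_r2_bounded_above(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = np.sort(rng.uniform(0, 1, size=5))
            ratio = 1 + rng.normal(0, 0.5, size=5)
            for mode in ("fixed", "free"):
                assert fit_psas(make_curve(c, ratio), mode=mode).r2 <= 1.0

    def test_no_concentration_variation(self):
        curve = make_curve([1.0, 1.0], [1.4, 1.6])
        with pytest.raises(FitError):
            fit_psas(curve)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            fit_psas(make_curve([0, 1], [1, 1.5]), mode="bayes")

    @settings(max_examples=30, deadline=None)
    @given(
        k_s=st.floats(min_value=0.1, max_value=10),
        k_c=st.floats(min_value=0.1, max_value=10),
        slope=st.floats(min_value=-2, max_value=2),
    )
    def test_scale_equivariance(self, k_s, k_c, slope):
        """Rescaling solubilities leaves the slope unchanged; rescaling
        concentrations by k divides the slope by k."""
        c = np.array([0.0, 0.25, 0.5, 1.0])
        s = 2.0 * (1 + slope * c) + np.array([0.0, 0.01, -0.02, 0.015])
        def fit(cv, sv, s0):
            records = [AssayRecord("Trp", "Gly", ci, 1, si) for ci, si in zip(cv, sv)]
            return fit_psas(to_ratio(records, s0=s0)).psas

        base = fit(c, s, 2.0)
        assert fit(c, k_s * s, k_s * 2.0) == pytest.approx(base, rel=1e-9)
        assert fit(k_c * c, s, 2.0) == pytest.approx(base / k_c, rel=1e-9)


class TestPipeline:
    def test_noiseless_recovery_all_pairs(self, noiseless_scenario, noiseless_matrix):
        for solute in AROMATIC_RESIDUES:
            for solvent in CANONICAL_RESIDUES:
                assert noiseless_matrix.value(solute, solvent) == pytest.approx(
                    noiseless_scenario.truth(solute, solvent), abs=1e-9
                )

    def test_estimator_mean_tracks_truth_under_noise(self):
        sc = make_scenario("paper_like", seed=0, cmax={"Gly": 1.0}, s0={"Trp": 1.0},
                           true_psas={("Trp", "Gly"): 0.5})
        est = []
        for seed in range(300):
            entry = fit_psas(to_ratio(simulate_assay(sc, seed=seed)))
            est.append(entry.psas)
        est = np.asarray(est)
        sem = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < 3 * sem + 0.005


class TestMatrix:
    def test_complete_grid(self, noiseless_matrix):
        assert noiseless_matrix.to_frame().shape == (20, 3)
        assert list(noiseless_matrix.to_frame().index) == list(CANONICAL_RESIDUES)
        assert list(noiseless_matrix.to_frame().columns) == list(AROMATIC_RESIDUES)

    def test_missing_pair_lists_gaps(self, noiseless_matrix):
        entries = [e for k, e in noiseless_matrix.entries.items() if k != ("Trp", "Gly")]
        with pytest.raises(MatrixError, match="Trp/Gly"):
            build_matrix(entries)

    def test_duplicate_pair_rejected(self, noiseless_matrix):
        entries = list(noiseless_matrix.entries.values())
        with pytest.raises(MatrixError, match="duplicate"):
            build_matrix(entries + [entries[0]])

    def test_diagnostics_table(self, noiseless_matrix):
        diag = noiseless_matrix.diagnostics()
        assert len(diag) == 60
        assert set(diag.columns) >= {"psas", "stderr", "r2", "n_points"}


class TestClassify:
    @pytest.mark.parametrize(
        "psas,tau,label",
        [
            (0.5, 0.05, "soluble"),
            (-0.3, 0.05, "insoluble"),
            (0.0, 0.05, "neutral"),
            (0.05, 0.05, "neutral"),   # boundary is neutral
            (-0.05, 0.05, "neutral"),
        ],
    )
    def test_sign_rule(self, psas, tau, label):
        cls = classify(psas, tau=tau)
        assert cls.label == label
        assert cls.tau == tau and cls.psas == psas

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            classify(0.1, tau=-0.01)
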