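"""Agreement metrics: closed forms, mixed-model estimates, empirical oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_paired
from hragree.agreement import (DifferenceModelFit, agreement_by_phase,
                               agreement_report, ccc_vc, cia, classify_ccc,
                               coverage_probability, fit_difference_model,
                               loa_mixed, msd, repeatability_coefficient,
                               total_deviation_index)

Z = 1.959964


def fit_of(bias, subject=0.0, subject_phase=0.0, resid=0.0):
    vc = {"subject": subject, "subject_phase": subject_phase, "resid": resid}
    return DifferenceModelFit(bias=bias, vc_diff=vc,
                              total_var_diff=sum(vc.values()))


class TestDifferenceModel:
    def test_constant_diffs(self):
        paired = make_paired([3.0] * 20, subjects=np.repeat(
            ["A", "B", "C", "D"], 5))
        fit = fit_difference_model(paired)
        assert fit.bias == pytest.approx(3.0)
        assert fit.total_var_diff == pytest.approx(0.0, abs=1e-9)

    def test_sign_flip_negates_bias_only(self, small_paired):
        fit = fit_difference_model(small_paired)
        flipped = small_paired.copy()
        flipped[["hr_ref", "hr_test"]] = \
            flipped[["hr_test", "hr_ref"]].to_numpy()
        flipped["diff"] = -small_paired["diff"]
        fit2 = fit_difference_model(flipped)
        assert fit2.bias == pytest.approx(-fit.bias, rel=1e-4)
        assert fit2.total_var_diff == pytest.approx(fit.total_var_diff,
                                                    rel=1e-3)

    def test_one_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            fit_difference_model(make_paired([1.0, 2.0, 3.0]))


class TestLoa:
    def test_degenerate_zero_interval(self):
        assert loa_mixed(fit_of(0.0)) == (0.0, 0.0, 0.0)

    def test_closed_form_reproduces_printed_shape(self):
        bias, lo, hi = loa_mixed(fit_of(-1.91, resid=8.40 ** 2))
        assert lo == pytest.approx(-1.91 - Z * 8.40, abs=1e-6)
        assert hi == pytest.approx(-1.91 + Z * 8.40, abs=1e-6)
        assert lo == pytest.approx(-18.37, abs=0.01)
        assert hi == pytest.approx(14.55, abs=0.01)

    def test_widening_level_widens_interval(self):
        f = fit_of(1.0, resid=25.0)
        _, lo95, hi95 = loa_mixed(f, 0.95)
        _, lo99, hi99 = loa_mixed(f, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            loa_mixed(fit_of(0.0), level=1.5)


class TestClosedForms:
    def test_msd_identities(self):
        assert msd(fit_of(3.0)) == pytest.approx(9.0)
        assert msd(fit_of(0.0, resid=25.0)) == pytest.approx(25.0)

    def test_msd_matches_empirical_mean_square(self, small_paired):
        fit = fit_difference_model(small_paired)
        empirical = float((small_paired["diff"] ** 2).mean())
        assert msd(fit) == pytest.approx(empirical, rel=0.10)

    def test_cp_normal_quantile_identity(self):
        assert coverage_probability(0.0, 1.0, 1.959964) == pytest.approx(
            0.95, abs=1e-4)

    def test_cp_infinite_boundary(self):
        assert coverage_probability(5.0, 100.0, 1e9) == pytest.approx(1.0)

    def test_cp_zero_variance_indicator(self):
        assert coverage_probability(3.0, 9.0, 10.0) == 1.0
        assert coverage_probability(12.0, 144.0, 10.0) == 0.0

    def test_cp_invalid_msd(self):
        with pytest.raises(ValueError):
            coverage_probability(5.0, 4.0, 10.0)

    def test_cp_increases_with_cad(self):
        cps = [coverage_probability(-1.91, 85.69, c) for c in (5, 10, 20)]
        assert cps[0] < cps[1] < cps[2]

    def test_tdi_closed_form_and_monotonicity(self):
        assert total_deviation_index(25.0, 0.95) == pytest.approx(9.80, abs=0.01)
        assert total_deviation_index(0.0) == 0.0
        assert total_deviation_index(30.0, 0.95) > total_deviation_index(25.0, 0.95)
        assert total_deviation_index(25.0, 0.99) > total_deviation_index(25.0, 0.95)

    def test_tdi_matches_simulated_quantile(self):
        rng = np.random.default_rng(0)
        draws = np.abs(rng.normal(0.0, 5.0, 200_000))
        assert total_deviation_index(25.0, 0.95) == pytest.approx(
            np.quantile(draws, 0.95), rel=0.01)

    def test_tdi_cp_mutual_consistency(self):
        for m in (10.0, 85.69, 300.0):
            t = total_deviation_index(m, 0.95)
            assert coverage_probability(0.0, m, t) == pytest.approx(
                0.95, abs=1e-6)

    def test_repeatability_coefficient(self):
        assert repeatability_coefficient(2.0) == pytest.approx(3.92, abs=0.005)
        assert repeatability_coefficient(0.0) == 0.0

    def test_cia_limits(self):
        assert cia(0.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            cia(5.0, 0.0)

    def test_cia_decreases_with_added_bias(self, small_paired):
        values = []
        for extra in (0.0, -4.0, -8.0, -16.0):  # bias grows in magnitude
            shifted = small_paired.copy()
            shifted["hr_test"] += extra
            shifted["diff"] += extra
            rep = agreement_report(shifted, B=0, per_phase=False)
            values.append(rep.cia)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestCcc:
    @staticmethod
    def two_device_frame(n_sub, s2s, noise_sd, bias, seed=0, m=1):
        rng = np.random.default_rng(seed)
        alpha = np.repeat(rng.normal(0.0, np.sqrt(s2s), n_sub), m)
        subj = np.repeat([f"S{i:04d}" for i in range(n_sub)], m)
        x = 80.0 + alpha + rng.normal(0, noise_sd, n_sub * m)
        y = 80.0 + bias + alpha + rng.normal(0, noise_sd, n_sub * m)
        return pd.DataFrame({
            "subject": subj, "phase": "relaxation",
            "epoch_index": np.tile(np.arange(m), n_sub),
            "hr_ref": x, "hr_test": y, "diff": y - x})

    def test_reduces_to_lin_ccc_no_bias(self):
        # X = a + e1, Y = a + e2 with s2s=3, s2e=1 -> CCC = 3/4
        paired = self.two_device_frame(4000, 3.0, 1.0, 0.0, seed=1)
        res = ccc_vc(paired)
        assert res.ccc == pytest.approx(0.75, abs=0.02)

    def test_reduces_to_lin_ccc_with_bias(self):
        # plus device offset b with b^2/2 = 1 -> CCC = 3/5
        paired = self.two_device_frame(4000, 3.0, 1.0, np.sqrt(2.0), seed=2)
        res = ccc_vc(paired)
        assert res.ccc == pytest.approx(0.6, abs=0.02)

    def test_matches_moment_ccc_on_large_balanced_data(self):
        paired = self.two_device_frame(3000, 50.0, 4.0, -2.0, seed=3)
        x, y = paired["hr_ref"], paired["hr_test"]
        sxy = np.cov(x, y, ddof=1)
        lin = 2 * sxy[0, 1] / (sxy[0, 0] + sxy[1, 1]
                               + (x.mean() - y.mean()) ** 2)
        assert ccc_vc(paired).ccc == pytest.approx(lin, rel=0.02)

    def test_identical_devices_give_one(self, perfect_paired):
        assert ccc_vc(perfect_paired).ccc == 1.0

    def test_interpretation_bands(self):
        assert classify_ccc(0.76) == "poor"
        assert classify_ccc(0.92) == "moderate"
        assert classify_ccc(0.97) == "substantial"
        assert classify_ccc(0.995) == "perfect"


class TestPerPhase:
    def test_identical_devices_perfect_everywhere(self, perfect_paired):
        tab = agreement_by_phase(perfect_paired).set_index("phase")
        assert len(tab) == 4
        for _, row in tab.iterrows():
            assert row["bias"] == pytest.approx(0.0, abs=1e-9)
            assert row["cp"] == 1.0
            assert row["cia"] == 1.0
            assert row["ccc"] == 1.0
            assert row["tdi"] == pytest.approx(0.0, abs=1e-6)

    def test_cp_orders_inversely_to_msd(self, small_paired):
        tab = agreement_by_phase(small_paired)
        order_msd = tab.sort_values("msd")["phase"].tolist()
        order_cp = tab.sort_values("cp", ascending=False)["phase"].tolist()
        assert order_msd == order_cp

    def test_high_hr_error_spares_relaxation(self, small_paired):
        tab = agreement_by_phase(small_paired).set_index("phase")
        assert tab.loc["relaxation", "cia"] > tab.loc["oral", "cia"]
        assert tab.loc["relaxation", "msd"] < tab.loc["oral", "msd"]


class TestReport:
    def test_report_with_bootstrap_cis(self, small_paired):
        rep = agreement_report(small_paired, B=200, seed=4, per_phase=False)
        assert rep.bias_ci[0] <= rep.bias <= rep.bias_ci[1]
        assert rep.msd_ci[0] <= rep.msd <= rep.msd_ci[1]
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        assert rep.msd >= rep.bias ** 2
        assert rep.tdi >= abs(rep.bias)
        assert 0.0 <= rep.cp <= 1.0
        d = rep.to_dict()
        assert isinstance(d["bias_ci"], list)
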