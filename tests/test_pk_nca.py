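"""Profiles, BLQ handling, AUC/lambda_z, NCA and first-pass analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sapsa.pk import (
    NCA,
    FirstPass,
    PKProfile,
    PKSimConfig,
    auc,
    aumc,
    first_pass,
    first_pass_from_aucs,
    fit_lambda_z,
    nca,
    oral_bioavailability,
    preprocess_blq,
    simulate_iv,
)

DENSE = tuple(np.geomspace(0.02, 48.0, 160))


def mono_exp_profile(c0=100.0, k=0.5, times=(0.5, 1, 2, 3, 4, 6, 8, 12), **kw):
    times = np.asarray(times, dtype=float)
    defaults = dict(
        subject_id="s1", site="systemic", route="iv_bolus", dose=1.0, lloq=0.0
    )
    defaults.update(kw)
    return PKProfile(
        times=times, concentrations=c0 * np.exp(-k * times), **defaults
    )


class TestProfileValidation:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            PKProfile("s", "systemic", "iv_bolus", 1.0, [1.0, 1.0], [1.0, 2.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            PKProfile("s", "systemic", "iv_bolus", 1.0, [1.0, 2.0], [1.0, -2.0])

    def test_unknown_site_and_route_rejected(self):
        with pytest.raises(ValueError):
            PKProfile("s", "vena_cava", "iv_bolus", 1.0, [1.0], [1.0])
        with pytest.raises(ValueError):
            PKProfile("s", "systemic", "infusion", 1.0, [1.0], [1.0])


class TestBLQ:
    def base(self, conc):
        return PKProfile(
            "s", "systemic", "oral", 1.0,
            np.arange(1, len(conc) + 1, dtype=float), conc, lloq=0.4,
        )

    def test_leading_blq_set_to_zero(self):
        p = preprocess_blq(self.base([0.1, 5.0, 3.0]))
        assert p.concentrations[0] == 0.0
        assert len(p.times) == 3

    def test_trailing_blq_dropped(self):
        p = preprocess_blq(self.base([5.0, 3.0, 0.2]))
        assert len(p.times) == 2
        assert p.times[-1] == 2.0
        assert any("dropped" in n for n in p.notes)

    def test_embedded_blq_dropped(self):
        p = preprocess_blq(self.base([5.0, 0.1, 3.0]))
        np.testing.assert_array_equal(p.times, [1.0, 3.0])

    def test_no_blq_is_identity(self):
        base = self.base([5.0, 3.0, 1.0])
        assert preprocess_blq(base) is base

    def test_all_blq_is_an_error(self):
        with pytest.raises(ValueError, match="below LLOQ"):
            preprocess_blq(self.base([0.1, 0.2, 0.3]))


class TestAUC:
    def test_triangle(self):
        assert auc([0, 1, 2], [0, 10, 0], "linear") == pytest.approx(10.0)

    def test_log_down_exact_for_mono_exponential(self):
        t = np.array([0, 0.5, 1, 2, 4, 7, 12, 24.0])
        c = 100.0 * np.exp(-0.5 * t)
        segment_exact = (100.0 / 0.5) * (1 - np.exp(-0.5 * 24))
        assert auc(t, c, "linear_up_log_down") == pytest.approx(
            segment_exact, rel=1e-6
        )

    def test_aumc_log_down_exact_for_mono_exponential(self):
        t = np.array([0, 0.5, 1, 2, 4, 7, 12, 24.0])
        k = 0.5
        c = 100.0 * np.exp(-k * t)
        # int_0^T t C dt = C0 [1/k^2 - e^{-kT}(T/k + 1/k^2)]
        exact = 100.0 * (1 / k**2 - np.exp(-k * 24) * (24 / k + 1 / k**2))
        assert aumc(t, c, "linear_up_log_down") == pytest.approx(exact, rel=1e-6)

    def test_single_point_is_an_error(self):
        with pytest.raises(ValueError):
            auc([1.0], [5.0])

    def test_linear_auc_invariant_to_interpolated_point(self):
        t = [0.0, 1.0, 2.0, 4.0]
        c = [0.0, 8.0, 6.0, 2.0]
        base = auc(t, c, "linear")
        # insert the midpoint of the (2, 4) segment
        t2 = [0.0, 1.0, 2.0, 3.0, 4.0]
        c2 = [0.0, 8.0, 6.0, 4.0, 2.0]
        assert auc(t2, c2, "linear") == pytest.approx(base)


class TestLambdaZ:
    def test_exact_mono_exponential(self):
        fit = fit_lambda_z(mono_exp_profile(k=0.5))
        assert fit.lambda_z == pytest.approx(0.5, rel=1e-9)
        assert fit.reliable
        assert np.log(2) / fit.lambda_z == pytest.approx(1.386, abs=1e-3)

    def test_flat_profile_flagged_unreliable(self):
        p = PKProfile(
            "s", "systemic", "iv_bolus", 1.0,
            [1.0, 2, 3, 4, 5], [10.0, 10, 10, 10, 10],
        )
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.0, abs=1e-12)
        assert not fit.reliable

    def test_noisy_recovery_within_ten_percent(self):
        cfg = PKSimConfig(noise_cv=0.10, seed=2024, schedule=DENSE, lloq=1e-9)
        fit = fit_lambda_z(simulate_iv(cfg))
        assert fit.lambda_z == pytest.approx(cfg.k_elim, rel=0.10)

    def test_insufficient_points(self):
        p = PKProfile("s", "systemic", "iv_bolus", 1.0, [1.0, 2.0], [5.0, 2.0])
        with pytest.raises(ValueError):
            fit_lambda_z(p)


class TestNCA:
    def test_iv_recovers_cl_and_vss(self):
        cfg = PKSimConfig(noise_cv=0.0, schedule=DENSE, lloq=1e-12)
        res = NCA(simulate_iv(cfg)).fit()
        assert res.cl == pytest.approx(cfg.CL, rel=0.02)
        assert res.vss == pytest.approx(cfg.V, rel=0.02)
        assert res.t_half == pytest.approx(np.log(2) / cfg.k_elim, rel=0.02)

    def test_cmax_tmax_observed(self):
        p = PKProfile(
            "s", "systemic", "oral", 3.0,
            [0.25, 0.5, 1.0, 2.0], [183.0, 120.0, 60.0, 20.0],
        )
        res = nca(p)
        assert res.cmax == 183.0
        assert res.tmax == 0.25

    def test_auc_inf_not_below_auc_last(self):
        for seed in range(4):
            cfg = PKSimConfig(noise_cv=0.15, seed=seed, lloq=1e-9,
                              schedule=tuple(np.geomspace(0.05, 24, 24)))
            res = NCA(simulate_iv(cfg)).fit()
            assert res.auc_inf >= res.auc_last

    def test_molar_units_require_molecular_weight_for_cl(self):
        p = mono_exp_profile(conc_unit="nM")
        with pytest.raises(ValueError, match="molecular_weight"):
            NCA(p).fit()
        res = NCA(mono_exp_profile(conc_unit="nM", molecular_weight=648.9)).fit()
        assert res.cl is not None

    def test_oral_profile_reports_no_cl_or_vss(self):
        p = PKProfile(
            "s", "systemic", "oral", 3.0,
            [0.25, 0.5, 1, 2, 4, 7.0], [10.0, 20.0, 15.0, 7.0, 2.0, 0.5],
        )
        res = nca(p)
        assert res.cl is None and res.vss is None
        assert res.auc_inf > res.auc_last > 0

    def test_summary_mentions_key_quantities(self):
        res = NCA(mono_exp_profile()).fit()
        text = res.summary()
        for token in ("Cmax", "AUC_inf", "CL", "Vss"):
            assert token in text


class TestBioavailability:
    @pytest.mark.parametrize(
        "auc_oral, auc_iv, printed",
        [(8967, 29618, 30), (896, 13508, 7), (214, 544, 39), (59, 257, 23)],
    )
    def test_published_dose_normalized_auc_pairs(self, auc_oral, auc_iv, printed):
        assert round(oral_bioavailability(auc_oral, auc_iv)) == printed

    def test_identity_is_100_percent(self):
        assert oral_bioavailability(257.0, 257.0) == pytest.approx(100.0)

    def test_zero_iv_auc_rejected(self):
        with pytest.raises(ZeroDivisionError):
            oral_bioavailability(10.0, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_common_unit_rescaling(self, scale):
        assert oral_bioavailability(214.0 * scale, 544.0 * scale) == pytest.approx(
            oral_bioavailability(214.0, 544.0), rel=1e-9
        )


class TestFirstPass:
    def paired(self, portal_conc, jugular_conc, times=(0.25, 0.5, 1, 2, 4, 7)):
        common = dict(route="oral", dose=3.0, lloq=0.0, subject_id="r1")
        t = np.asarray(times, dtype=float)
        return (
            PKProfile(site="portal", times=t, concentrations=portal_conc, **common),
            PKProfile(site="jugular", times=t, concentrations=jugular_conc, **common),
        )

    def test_equal_profiles_give_zero_first_pass(self):
        c = np.array([10.0, 20, 15, 8, 3, 1])
        p, j = self.paired(c, c.copy())
        assert first_pass(p, j).first_pass_pct == pytest.approx(0.0, abs=1e-9)

    def test_published_auc_pair_reproduces_77_percent(self):
        res = first_pass_from_aucs(449.0, 104.0)
        assert round(res.first_pass_pct) == 77
        assert "high extraction" in res.hepatic_extraction_flag

    def test_jugular_exceeding_portal_is_flagged_not_clipped(self):
        res = first_pass_from_aucs(100.0, 120.0)
        assert res.negative_extraction
        assert res.first_pass_pct < 0

    def test_complement_identity(self):
        res = first_pass_from_aucs(1839.0, 1656.0)
        assert res.first_pass_pct + 100.0 * res.auc_jugular / res.auc_portal == (
            pytest.approx(100.0)
        )

    def test_mismatched_subject_or_route_rejected(self):
        p, j = self.paired(np.ones(6) * 5, np.ones(6) * 3)
        j_bad = PKProfile(
            "r2", "jugular", "oral", 3.0, j.times, j.concentrations, lloq=0.0
        )
        with pytest.raises(ValueError, match="subject"):
            FirstPass(p, j_bad)
        iv = PKProfile(
            "r1", "jugular", "iv_bolus", 3.0, j.times, j.concentrations, lloq=0.0
        )
        with pytest.raises(ValueError, match="oral"):
            FirstPass(p, iv)

    def test_common_window_excludes_site_specific_blq_tail(self):
        # jugular 24 h sample below LLOQ (as in a low-exposure control arm):
        # the comparison window must end at the last common quantifiable time
        t = (0.25, 0.5, 1, 2, 4, 7, 24)
        p = PKProfile("r1", "portal", "oral", 3.0, t,
                      [50, 80, 60, 30, 10, 3, 0.5], lloq=0.4)
        j = PKProfile("r1", "jugular", "oral", 3.0, t,
                      [10, 18, 14, 7, 2, 0.6, 0.1], lloq=0.4)
        res = FirstPass(p, j).fit()
        assert res.t_last_common == 7.0
        assert 0 < res.first_pass_pct < 100
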