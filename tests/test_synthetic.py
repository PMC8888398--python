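import math

import numpy as np
import pandas as pd
import pytest

from scdpk.data_model import AssayConfig, StoppingRule
from scdpk.dpk_metrics import elim_rate
from scdpk.sc_profile import site_Q
from scdpk.synthetic import (
    BLANCHING_TIMES,
    ConcentrationProfile,
    SimConfig,
    SubjectParams,
    assay_groups,
    blanching_template,
    clearance_profile,
    emax_link,
    simulate_blanching,
    simulate_study,
    strip_site,
    uptake_profile,
)

from conftest import UNCENSORED_ASSAY


def fd_uptake_solution(d_over_l2: float, t_h: float, nx: int = 201):
    """Independent explicit finite-difference solution of the uptake PDE.

    dC/dt = (D/L^2) d2C/dx2 on x in [0,1], C(0,t)=1, C(1,t)=0, C(x,0)=0.
    Returns (x grid, C profile) with C normalised to the surface value.
    """
    x = np.linspace(0.0, 1.0, nx)
    dx = x[1] - x[0]
    dt = 0.2 * dx * dx / d_over_l2  # stability: r = 0.2 < 0.5
    n_steps = int(math.ceil(t_h / dt))
    dt = t_h / n_steps
    r = d_over_l2 * dt / dx / dx
    c = np.zeros(nx)
    c[0] = 1.0
    for _ in range(n_steps):
        c[1:-1] = c[1:-1] + r * (c[2:] - 2 * c[1:-1] + c[:-2])
        c[0], c[-1] = 1.0, 0.0
    return x, c


class TestUptakeProfile:
    def test_steady_state_is_linear(self, params):
        # t -> infinity: C/kcv -> 1 - x
        c = uptake_profile(0.5, 1e6, params)
        assert c == pytest.approx(0.5 * params.kcv_ng_cm3, rel=1e-12)
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            uptake_profile(x, 1e6, params), params.kcv_ng_cm3 * (1 - x), rtol=1e-10
        )

    def test_initial_condition(self, params):
        x = np.array([0.01, 0.3, 0.9, 1.0])
        np.testing.assert_array_equal(uptake_profile(x, 0.0, params), 0.0)
        assert uptake_profile(0.0, 0.0, params) == params.kcv_ng_cm3

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            uptake_profile(0.5, -1.0, params)

    def test_bounded(self, params):
        x = np.linspace(0, 1, 201)
        for t in (0.01, 0.1, 1.0, 4.0, 100.0):
            c = uptake_profile(x, t, params)
            assert np.all(c >= 0) and np.all(c <= params.kcv_ng_cm3)

    @pytest.mark.parametrize("t_h", [0.5, 4.0])
    def test_monotone_nonincreasing_in_depth(self, params, t_h):
        x = np.linspace(0, 1, 401)
        c = uptake_profile(x, t_h, params)
        assert np.all(np.diff(c) <= 1e-9 * params.kcv_ng_cm3)

    def test_pde_oracle_q_at_4h(self):
        """Areal drug mass vs brute-force finite-difference PDE: <0.5%."""
        params = SubjectParams(kcv_ng_cm3=1.0, d_over_l2_per_h=0.1, sc_thickness_um=1e4)
        prof = ConcentrationProfile(params, 4.0)
        x, c = fd_uptake_solution(0.1, 4.0)
        q_fd = np.trapezoid(c, x)  # kcv=1, L = 1 cm
        q_series = prof.areal_mass(0.0, 1.0)
        assert q_series == pytest.approx(q_fd, rel=5e-3)

    def test_pde_oracle_pointwise(self):
        params = SubjectParams(kcv_ng_cm3=1.0, d_over_l2_per_h=0.03, sc_thickness_um=1e4)
        x, c = fd_uptake_solution(0.03, 4.0)
        c_series = uptake_profile(x, 4.0, params)
        assert np.max(np.abs(c_series - c)) < 5e-3

    def test_slab_integrals_consistent_with_pointwise(self, uptake4h, params):
        # antiderivative route vs numerical quadrature of the pointwise series
        x = np.linspace(0.1, 0.4, 2001)
        c = uptake_profile(x, 4.0, params)
        l_cm = params.sc_thickness_um * 1e-4
        q_quad = np.trapezoid(c, x) * l_cm
        assert uptake4h.areal_mass(0.1, 0.4) == pytest.approx(q_quad, rel=1e-6)


class TestClearanceProfile:
    def test_zero_elapsed_identity(self, uptake4h):
        assert clearance_profile(uptake4h, 0.0, 0.1).scale == uptake4h.scale

    def test_half_life(self, uptake4h):
        cl = clearance_profile(uptake4h, 6.0, math.log(2) / 6.0)
        assert cl.areal_mass(0, 1) == pytest.approx(uptake4h.areal_mass(0, 1) / 2, rel=1e-12)

    def test_pointwise_scaling(self, uptake4h, params):
        cl = clearance_profile(uptake4h, 3.0, params.k_true_per_h)
        x = np.linspace(0, 1, 50)
        np.testing.assert_allclose(
            cl.concentration(x),
            uptake4h.concentration(x) * math.exp(-params.k_true_per_h * 3.0),
            rtol=1e-12,
        )

    def test_self_consistency_recovers_k(self, uptake4h, params):
        """Two-point estimator applied to noise-free Q pair returns k_true."""
        cl = clearance_profile(uptake4h, 6.0, params.k_true_per_h)
        k = elim_rate(uptake4h.areal_mass(0, 1), cl.areal_mass(0, 1), 6.0)
        assert k == pytest.approx(params.k_true_per_h, rel=1e-12)


class TestStripSite:
    def test_infinite_thresholds_give_max_strips(self, uptake4h, params, no_stop_rule, rng):
        site = strip_site(uptake4h, params, no_stop_rule, rng, "s", "x")
        assert len(site.records) == no_stop_rule.max_strips
        assert site.stop_reason == "max_strips"
        assert [r.strip_index for r in site.records] == list(range(1, 21))

    def test_tewl_closed_form_halt(self, params, rng):
        """TEWL follows TEWL0*L/(L-h); at h = 5L/6 it is 60, so the absolute
        (60) and fold (6 x 10) rules fire together at the first crossing."""
        L = params.sc_thickness_um
        n_to_cross = 24  # each noise-free strip removes L/24 -> crossing at 5L/6
        p = SubjectParams(strip_mass_mg_cm2=(L / (2 * n_to_cross)) / 5.0)
        prof = ConcentrationProfile(p, 4.0)
        rule = StoppingRule(tewl_abs_max=60.0, tewl_fold_max=6.0, max_strips=1000)
        site = strip_site(prof, p, rule, rng, "s", "x", strip_cv=0.0, tewl_baseline=10.0)
        # closed-form trace: after strip i+1, h = (i+1) L/24
        for i, tewl in enumerate(site.tewl_trace):
            h = (i + 1) * L / n_to_cross
            assert tewl == pytest.approx(10.0 * L / (L - h), rel=1e-9)
        # halt at the first strip whose TEWL reaches 60 = 6 x baseline (i = 19,
        # up to one strip of float slack at the exact boundary)
        assert len(site.records) in (20, 21)
        assert site.tewl_trace[-1] >= 60.0 * (1 - 1e-9)
        assert site.stop_reason in ("tewl_abs", "tewl_fold")
        assert all(t < 60.0 * (1 + 1e-9) for t in site.tewl_trace[:-1])

    def test_mass_conservation_on_full_removal(self, params, rng):
        """Sum of per-strip drug equals the profile's total Q when all SC removed."""
        p = SubjectParams(strip_mass_mg_cm2=0.5)  # huge strips: SC gone quickly
        prof = ConcentrationProfile(p, 4.0)
        rule = StoppingRule(tewl_abs_max=np.inf, tewl_fold_max=np.inf, max_strips=50)
        site = strip_site(prof, p, rule, rng, "s", "x", strip_cv=0.0)
        assert site.stop_reason == "sc_exhausted"
        total = sum(site.drug_ng)
        q_full = prof.areal_mass(0, 1) * 5.0
        assert total == pytest.approx(q_full, rel=1e-3)

    def test_partial_removal_bounded_by_total(self, uptake4h, params, rule, rng):
        site = strip_site(uptake4h, params, rule, rng, "s", "x")
        assert sum(site.drug_ng) <= uptake4h.areal_mass(0, 1) * 5.0 + 1e-9


class TestAssayGroups:
    def test_noise_free_masses_exact(self, uptake4h, params, no_stop_rule, rng):
        site = strip_site(uptake4h, params, no_stop_rule, rng, "s", "x", strip_cv=0.0)
        groups = assay_groups(site, (2, 6, 6, 6), UNCENSORED_ASSAY, None, 0.0)
        assert len(groups) == 4
        assert [g.strip_indices for g in groups] == [
            tuple(range(1, 3)), tuple(range(3, 9)),
            tuple(range(9, 15)), tuple(range(15, 21)),
        ]
        for g in groups:
            expected = sum(site.drug_ng[i - 1] for i in g.strip_indices)
            assert g.drug_mass_ng == pytest.approx(expected, rel=1e-12)

    def test_blq_threshold(self, uptake4h, params, no_stop_rule, rng):
        # 50 ng in 2 mL = 0.025 ug/mL < 0.032 -> BLQ
        p = SubjectParams(kcv_ng_cm3=1.0)  # vanishingly little drug
        site = strip_site(ConcentrationProfile(p, 4.0), p, no_stop_rule, rng, "s", "x")
        groups = assay_groups(site, (2, 6, 6, 6), AssayConfig(), None, 0.0)
        assert all(g.blq for g in groups)
        loq_mass_ng = 0.032 * 1e3 * 2.0  # 64 ng
        assert 50.0 < loq_mass_ng  # the worked threshold example

    def test_grouping_truncated_when_strips_short(self, uptake4h, params, rng):
        rule = StoppingRule(max_strips=15)
        site = strip_site(uptake4h, params, rule, rng, "s", "x", strip_cv=0.0)
        groups = assay_groups(site, (2, 6, 6, 6), UNCENSORED_ASSAY, None, 0.0)
        assert groups[-1].strip_indices == tuple(range(15, 16))
        assert sum(len(g.strip_indices) for g in groups) == 15

    def test_leftover_strips_form_trailing_group(self, uptake4h, params, no_stop_rule, rng):
        site = strip_site(uptake4h, params, no_stop_rule, rng, "s", "x", strip_cv=0.0)
        groups = assay_groups(site, (2, 6), UNCENSORED_ASSAY, None, 0.0)
        assert groups[-1].strip_indices == tuple(range(9, 21))

    def test_determinism_same_seed(self, uptake4h, params, no_stop_rule):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            site = strip_site(uptake4h, params, no_stop_rule, rng, "s", "x")
            out.append(assay_groups(site, (2, 6, 6, 6), AssayConfig(), rng, 0.1))
        assert out[0] == out[1]


class TestBlanching:
    def test_non_responder_zero_noise_flat(self, rng):
        p = SubjectParams(responder=False)
        readings = simulate_blanching("s", "b", 80.0, p, rng, noise_sd=0.0, drift_sd=0.0)
        base = {r.role: r.a_star for r in readings if r.time_h is None}
        for r in readings:
            if r.time_h is not None:
                assert r.a_star == pytest.approx(base[r.role])

    def test_drift_is_common_to_all_roles(self, rng):
        p = SubjectParams(responder=False)
        readings = simulate_blanching("s", "b", 80.0, p, rng, noise_sd=0.0, drift_sd=2.0)
        deltas = {}
        base = {r.role: r.a_star for r in readings if r.time_h is None}
        for r in readings:
            if r.time_h is not None:
                deltas.setdefault(r.time_h, set()).add(round(r.a_star - base[r.role], 9))
        assert all(len(v) == 1 for v in deltas.values())

    def test_mean_aaec_matches_analytic_integral(self):
        """Empirical AAEC over 500 responders vs -scale*emax*trapz(template)."""
        from scdpk.blanching import BlanchingSeries, aaec, delta_a

        p = SubjectParams(responder=True, blanching_scale=2.0)
        q = 80.0
        rng = np.random.default_rng(2024)
        vals = []
        for _ in range(500):
            readings = simulate_blanching("s", "b", q, p, rng, noise_sd=0.5)
            base = {r.role: r.a_star for r in readings if r.time_h is None}
            times = sorted({r.time_h for r in readings if r.time_h is not None})
            by = {(r.role, r.time_h): r.a_star for r in readings}
            s = BlanchingSeries(
                "s", "b", times,
                base["treated"], [by[("treated", t)] for t in times],
                [base[c] for c in ("control1", "control2", "control3")],
                [[by[(c, t)] for t in times] for c in ("control1", "control2", "control3")],
            )
            vals.append(aaec(delta_a(s), times).aaec_h)
        t = np.array([0.0] + list(BLANCHING_TIMES))
        expected = -p.blanching_scale * emax_link(q) * np.trapezoid(blanching_template(t), t)
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se


class TestSimulateStudy:
    def test_deterministic_given_seed(self):
        a = simulate_study(SimConfig(seed=5, n_subjects=2))
        b = simulate_study(SimConfig(seed=5, n_subjects=2))
        assert a.records == b.records
        assert a.groups == b.groups
        assert a.readings == b.readings
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_seed_changes_output(self):
        a = simulate_study(SimConfig(seed=5, n_subjects=2))
        b = simulate_study(SimConfig(seed=6, n_subjects=2))
        assert a.records != b.records

    def test_design_shape(self, small_study):
        gt = small_study.ground_truth
        assert len(gt) == 3 * 3 * 2  # subjects x doses x phases
        assert set(gt["phase"]) == {"uptake", "clearance"}
        assert set(gt["dose_mg_cm2"]) == {2.0, 5.0, 10.0}
        # one blanching site per subject x dose, 4 roles x (1 baseline + 5 times)
        assert len(small_study.readings) == 3 * 3 * 4 * 6

    def test_calibration_mean_q_in_paper_range(self):
        """Dose-level mean Q_up/Q_cl land in 30-120 ng/cm2 under defaults."""
        gt = simulate_study(SimConfig(seed=11)).ground_truth
        means = gt.groupby(["dose_mg_cm2", "phase"])["q_true_removed_ng_cm2"].mean()
        assert ((means >= 30.0) & (means <= 120.0)).all()
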