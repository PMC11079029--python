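"""ITC forward model, one-site/autoinhibited fits, equilibrium solver."""

import itertools
import math

import numpy as np
import pytest

from tandemww.itc import (
    BindingModel,
    ITCExperiment,
    InjectionSchedule,
    _titration_totals,
    default_schedule,
    fit_isotherm,
    kd_apparent,
    read_itc,
    simulate_isotherm,
    solve_equilibrium,
    tandems_per_peptide,
    wiseman_c,
    write_itc,
)


class TestForwardModel:
    def test_zero_enthalpy_zero_heat(self, itc_schedule):
        exp = simulate_isotherm(BindingModel("one_site", 1.0, 1.4, 0.0), itc_schedule)
        assert np.allclose(exp.heats, 0.0)

    def test_stoichiometric_limit(self):
        """Kd << concentrations: constant heat per injection up to molar
        ratio 1, then ~0; total heat equals dH x moles of limiting species."""
        sched = default_schedule(cell_conc=30.0, syringe_conc=450.0)
        model = BindingModel("one_site", 1.0, 1e-6, -10.0)
        exp = simulate_isotherm(model, sched)
        ratios = exp.molar_ratios()
        pre = exp.heats[(ratios > 0.1) & (ratios < 0.85)]
        post = exp.heats[ratios > 1.3]
        assert np.ptp(pre) / np.abs(pre).max() < 1e-3
        assert np.abs(post).max() < 1e-3 * np.abs(pre).max()
        mts, xts = _titration_totals(sched)
        # in the tight limit every molecule of the limiting species is bound
        bound = np.minimum(mts, xts)
        v0 = sched.cell_volume
        # total heat telescopes to dH x (final complex + complex displaced
        # from the cell by the injections), all in ucal
        displaced = sum(
            dv / v0 * b
            for dv, b in zip(sched.injection_volumes[1:], bound[:-1])
        )
        total_expected = -10.0 * 1e-3 * v0 * (bound[-1] + displaced)
        assert exp.heats.sum() == pytest.approx(total_expected, rel=1e-6)
        # ... which is the enthalpy of the limiting cell species up to the
        # small displacement correction
        assert exp.heats.sum() == pytest.approx(
            -10.0 * mts[-1] * v0 * 1e-3, rel=0.25
        )

    def test_mass_conservation_under_dilution(self, itc_schedule):
        """Cell totals track the displacement-dilution recursion exactly."""
        mts, xts = _titration_totals(itc_schedule)
        v0 = itc_schedule.cell_volume
        mt, xt = itc_schedule.cell_conc, 0.0
        for dv, m_ref, x_ref in zip(itc_schedule.injection_volumes, mts, xts):
            f = 1.0 - dv / v0
            mt = mt * f
            xt = xt * f + itc_schedule.syringe_conc * dv / v0
            assert m_ref == pytest.approx(mt, rel=1e-14)
            assert x_ref == pytest.approx(xt, rel=1e-14)

    def test_autoinhibited_reduces_to_one_site_at_zero_k_closed(self, itc_schedule):
        one = simulate_isotherm(BindingModel("one_site", 1.0, 1.4, -8.0), itc_schedule)
        auto = simulate_isotherm(
            BindingModel("autoinhibited", 1.0, 1.4, -8.0, 0.0), itc_schedule
        )
        assert np.allclose(one.heats, auto.heats, atol=1e-12)


class TestEquilibriumSolver:
    def test_no_ligand_limit(self):
        out = solve_equilibrium(10.0, 0.0, 1.0, k_closed=4.0)
        assert out["bound"] == 0.0
        assert out["closed"] / out["open"] == pytest.approx(4.0)
        assert out["open"] + out["closed"] == pytest.approx(10.0)

    def test_reduces_to_quadratic_without_closed_state(self):
        rt, lt, kd = 20.0, 35.0, 2.5
        out = solve_equilibrium(rt, lt, kd, k_closed=0.0)
        b = rt + lt + kd
        quad = 0.5 * (b - math.sqrt(b * b - 4 * rt * lt))
        assert out["bound"] == pytest.approx(quad, rel=1e-10)

    def test_against_brute_force_scan(self):
        """Agreement with a dense 1-D root bracketing over a parameter grid."""
        for rt, lt, kd, kc in itertools.product(
            (5.0, 30.0), (2.0, 60.0), (0.5, 8.8), (0.0, 1.0, 5.29)
        ):
            out = solve_equilibrium(rt, lt, kd, kc)
            # brute force: scan bound on a fine grid, refine by bisection
            f = lambda b: (rt - b) * (lt - b) / (1 + kc) - kd * b
            grid = np.linspace(0.0, min(rt, lt), 20001)
            vals = f(grid)
            k = int(np.flatnonzero(np.diff(np.sign(vals)) != 0)[0])
            lo, hi = grid[k], grid[k + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert out["bound"] == pytest.approx(0.5 * (lo + hi), rel=1e-8, abs=1e-10)
            # mass balance and both equilibrium constants hold
            assert out["open"] + out["closed"] + out["bound"] == pytest.approx(
                rt, rel=1e-10
            )
            if out["bound"] > 0 and out["open"] > 0:
                assert out["open"] * out["free_ligand"] / out["bound"] == pytest.approx(
                    kd, rel=1e-8
                )


class TestKdApparent:
    def test_closed_form_limits(self):
        assert kd_apparent(1.4, 0.0) == 1.4
        assert kd_apparent(1.4, 8.8 / 1.4 - 1.0) == pytest.approx(8.8)

    def test_matches_numerical_equilibrium_over_grid(self):
        """Kd_app = Kd(1 + k_closed) reproduces the bound fraction of the
        three-species solver to 1e-8 everywhere on a parameter grid."""
        for kd, kc, rt, lt in itertools.product(
            (0.5, 1.4, 8.8, 30.0), (0.0, 0.5, 5.29, 20.0), (10.0, 40.0), (5.0, 80.0)
        ):
            full = solve_equilibrium(rt, lt, kd, kc)["bound"]
            effective = solve_equilibrium(rt, lt, kd_apparent(kd, kc), 0.0)["bound"]
            assert full == pytest.approx(effective, rel=1e-8, abs=1e-12)


class TestFitting:
    @pytest.mark.parametrize(
        "kd,n,dh",
        [
            (0.5, 1.0, -10.0),
            (1.4, 1.0, -8.0),
            (8.8, 1.0, -8.0),
            (10.0, 0.33, -2.0),
            (30.0, 3.0, -10.0),
        ],
    )
    def test_round_trip_recovery_grid(self, kd, n, dh, itc_schedule):
        """fit o simulate is the identity at zero noise over the parameter
        grid (relative error < 1e-6)."""
        model = BindingModel("one_site", n, kd, dh)
        exp = simulate_isotherm(model, itc_schedule)
        fit = fit_isotherm(exp)
        assert fit.model.kd == pytest.approx(kd, rel=1e-6)
        assert fit.model.n_sites == pytest.approx(n, rel=1e-6)
        assert fit.model.dh == pytest.approx(dh, rel=1e-6)

    def test_apparent_kd_from_autoinhibited_data(self, itc_schedule):
        """Autoinhibited synthetic data refit with the plain one-site model
        return Kd(1 + k_closed) — the competition weakens apparent binding."""
        kc = 5.2857
        exp = simulate_isotherm(
            BindingModel("autoinhibited", 1.0, 1.4, -8.0, kc), itc_schedule
        )
        fit = fit_isotherm(exp)
        assert fit.model.kd == pytest.approx(1.4 * (1 + kc), rel=1e-6)

    def test_autoinhibited_fit_with_pinned_kd(self, itc_schedule):
        exp = simulate_isotherm(
            BindingModel("autoinhibited", 1.0, 1.4, -8.0, 3.0), itc_schedule
        )
        fit = fit_isotherm(exp, variant="autoinhibited", fix={"kd": 1.4})
        assert fit.model.k_closed == pytest.approx(3.0, rel=1e-4)

    def test_autoinhibited_fit_requires_pin(self, itc_schedule):
        exp = simulate_isotherm(
            BindingModel("autoinhibited", 1.0, 1.4, -8.0, 3.0), itc_schedule
        )
        with pytest.raises(ValueError, match="pinned"):
            fit_isotherm(exp, variant="autoinhibited")

    def test_multivalent_syringe_construct_stoichiometry(self):
        """Three sites per syringe peptide titrated into the single-site cell
        receptor: the cell-macromolecule fit returns N = 1/3, i.e. 3 tandems
        per peptide after role interpretation."""
        sched = default_schedule(
            cell_conc=30.0,
            syringe_conc=150.0,
            cell_species="tandem",
            syringe_species="peptide",
            macromolecule="syringe",
        )
        exp = simulate_isotherm(BindingModel("one_site", 3.0, 1.4, -8.0), sched)
        fit = fit_isotherm(exp)
        assert fit.model.n_sites == pytest.approx(1.0 / 3.0, rel=1e-6)
        assert tandems_per_peptide(fit.model.n_sites, "syringe") == pytest.approx(
            3.0, rel=1e-6
        )

    def test_flat_isotherm_rejected(self, itc_schedule):
        exp = ITCExperiment(itc_schedule, np.zeros(itc_schedule.n_injections))
        with pytest.raises(ValueError, match="flat"):
            fit_isotherm(exp)

    def test_wiseman_c_reported(self, itc_schedule):
        model = BindingModel("one_site", 1.0, 1.4, -8.0)
        assert wiseman_c(model, itc_schedule) == pytest.approx(30.0 / 1.4)
        fit = fit_isotherm(simulate_isotherm(model, itc_schedule))
        assert fit.c_value == pytest.approx(30.0 / 1.4, rel=1e-4)


class TestIO:
    def test_round_trip(self, itc_schedule, tmp_path):
        exp = simulate_isotherm(BindingModel("one_site", 1.0, 1.4, -8.0), itc_schedule)
        path = tmp_path / "exp.itc"
        write_itc(exp, str(path))
        back = read_itc(str(path))
        assert np.allclose(back.heats, exp.heats)
        assert back.schedule.cell_conc == exp.schedule.cell_conc
        assert back.schedule.injection_volumes == exp.schedule.injection_volumes
        refit = fit_isotherm(back)
        assert refit.model.kd == pytest.approx(1.4, rel=1e-6)
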