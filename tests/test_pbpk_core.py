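"""Elementary rate laws and structural properties of the ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcpbpk import DoseRegimen, load_kp, simulate
from spcpbpk.pbpk_core import (
    IDX,
    N_STATES,
    EHCParams,
    ModelConfig,
    absorption_ka,
    absorption_rate,
    compile_model,
    default_ehc,
    dissolution_rate,
    hepatic_elimination_rate,
    renal_elimination_rate,
)


class TestDissolution:
    def test_nothing_to_dissolve(self):
        assert dissolution_rate(0.0, 0.0, 0.5, 25.0) == 0.0

    def test_saturated_lumen(self):
        assert dissolution_rate(100.0, 500.0, 0.5, 25.0) == 0.0  # 0.5 mg/mL = 500 ug/mL

    def test_halving_with_radius_in_fixed_layer_regime(self):
        # above the 30 um diffusion-layer cap the rate scales as 1/r
        r1 = dissolution_rate(100.0, 0.0, 0.5, 40.0)
        r2 = dissolution_rate(100.0, 0.0, 0.5, 80.0)
        assert r1 == pytest.approx(2.0 * r2, rel=1e-12)

    def test_proportional_to_solid_mass(self):
        assert dissolution_rate(200.0, 0.0, 0.5, 25.0) == pytest.approx(
            2.0 * dissolution_rate(100.0, 0.0, 0.5, 25.0), rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            dissolution_rate(1.0, 0.0, 0.5, 0.0)

    @given(r=st.floats(1.0, 200.0), r_factor=st.floats(1.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_radius(self, r, r_factor):
        assert dissolution_rate(50.0, 0.0, 0.2, r) >= dissolution_rate(
            50.0, 0.0, 0.2, r * r_factor)


class TestAbsorption:
    def test_zero_amount(self):
        assert absorption_rate(0.0, 2.48e-5) == 0.0

    def test_linear_in_papp(self):
        assert absorption_rate(10.0, 2 * 2.48e-5, 0.18) == pytest.approx(
            2 * absorption_rate(10.0, 2.48e-5, 0.18), rel=1e-12)

    def test_ka_value_rat(self):
        # 2 * 2.48e-5 cm/s * 3600 / 0.18 cm
        assert absorption_ka(2.48e-5, 0.18) == pytest.approx(0.992, rel=1e-6)


class TestHepaticElimination:
    def test_zero_concentration(self):
        assert hepatic_elimination_rate(0.0, 0.4, 100.0, 5.0, 2.0) == 0.0

    def test_saturates_at_vmax(self):
        rate = hepatic_elimination_rate(1e9, 0.4, 100.0, 5.0, 2.0)
        assert rate == pytest.approx(100.0, rel=1e-6)

    def test_half_saturation_identity(self):
        fb, km, kl, vmax = 0.4, 5.0, 2.0, 100.0
        c_half = km * kl / fb
        assert hepatic_elimination_rate(c_half, fb, vmax, km, kl) == pytest.approx(
            vmax / 2.0, rel=1e-12)

    def test_linear_limit(self):
        # c << km*kl/fb: rate ~ fb*vmax*c/(km*kl) to first order
        fb, km, kl, vmax = 0.4, 5.0, 2.0, 100.0
        c = 1e-6 * km * kl / fb
        lin = fb * vmax * c / (km * kl)
        assert hepatic_elimination_rate(c, fb, vmax, km, kl) == pytest.approx(
            lin, rel=1e-5)


class TestRenalElimination:
    def test_no_renal_route(self):
        assert renal_elimination_rate(0.5, 0.0, 0.42) == 0.0

    def test_linear_in_concentration(self):
        assert renal_elimination_rate(0.02, 4.669, 0.42) == pytest.approx(
            2 * renal_elimination_rate(0.01, 4.669, 0.42), rel=1e-12)

    def test_value(self):
        # 4.669 L/h * 1000 * 0.01 / 0.42
        assert renal_elimination_rate(0.01, 4.669, 0.42) == pytest.approx(
            111.2, abs=0.05)


class TestEHCParams:
    def test_defaults_per_compound(self, daidzin, methylretusin):
        assert default_ehc(methylretusin).emptying_times == (3.0,)
        assert default_ehc(daidzin).emptying_times == (6.0,)

    def test_validation(self):
        with pytest.raises(ValueError):
            EHCParams(biliary_fraction=1.0)
        with pytest.raises(ValueError):
            EHCParams(emptying_times=(3.0, 2.0))


class TestOdeRhs:
    def test_all_zero_state_is_at_rest(self, daidzin, rat_phys):
        model = compile_model(daidzin, rat_phys)
        dy = model.rhs(0.0, np.zeros(N_STATES))
        assert np.all(dy == 0.0)

    def test_uniform_state_equilibrium_at_unit_kp(self, daidzin, rat_phys):
        """With all k_i = 1 and no elimination/absorption, a uniform
        concentration field is a fixed point of the disposition system."""
        from spcpbpk.data_model import TISSUES, PartitionSet

        kp1 = PartitionSet(kp={t: 1.0 for t in TISSUES})
        cfg = ModelConfig(cl_scale=1e-15, ehc=EHCParams(biliary_fraction=0.0),
                          michaelis_menten=False)
        model = compile_model(daidzin, rat_phys, cfg, kp_set=kp1)
        y = np.zeros(N_STATES)
        y[3:14] = 0.7  # uniform concentration, empty lumen
        dy = model.rhs(0.0, y)
        assert np.allclose(dy[3:14], 0.0, atol=1e-10)

    def test_rhs_conserves_mass_without_elimination(self, daidzin, rat_phys):
        """Summing amount-rates over all pools gives zero at random states
        when elimination is off (structural conservation of the RHS)."""
        cfg = ModelConfig(cl_scale=1e-15, ehc=EHCParams(biliary_fraction=0.0),
                          michaelis_menten=False)
        model = compile_model(daidzin, rat_phys, cfg)
        rng = np.random.default_rng(11)
        vols = {c: model.v_ml[c] for c in
                ("gi", "lung", "liver", "kidney", "heart", "muscle",
                 "spleen", "brain", "rest", "artery", "venous")}
        for _ in range(10):
            y = rng.uniform(0, 1, N_STATES)
            dy = model.rhs(1.0, y)
            total_rate = dy[0] + dy[1] + dy[2] + dy[14] + dy[15]
            total_rate += sum(dy[3 + i] * v for i, v in enumerate(vols.values()))
            scale = max(abs(dy).max(), 1.0)
            assert abs(total_rate) < 1e-9 * scale * max(vols.values())

    def test_rejects_nonfinite_parameters(self, daidzin, rat_phys):
        import dataclasses

        bad = dataclasses.replace(daidzin, mw=np.nan)
        with pytest.raises(ValueError):
            compile_model(bad, rat_phys)


class TestTrajectoryInvariants:
    def test_mass_balance_conserved_over_24h(self, daidzin, rat_phys):
        cfg = ModelConfig(cl_scale=1e-12, ehc=EHCParams(biliary_fraction=0.0))
        res = simulate(daidzin, rat_phys, DoseRegimen(dose=0.71), t_end=24.0,
                       config=cfg)
        assert res.mass_balance_residual <= 1e-6

    def test_mass_balance_accounted_with_elimination(self, daidzin_base_run):
        assert daidzin_base_run.mass_balance_residual <= 1e-4

    def test_no_negative_states(self, daidzin_base_run):
        assert (daidzin_base_run.trajectories.to_numpy() >= 0).all()

    def test_kp_recovery_under_constant_infusion(self, daidzin, rat_phys):
        """Steady-state tissue:arterial ratios equal the input k_i — the
        defining property of perfusion-limited tissues."""
        cfg = ModelConfig(infusion_rate=100.0, michaelis_menten=False,
                          ehc=EHCParams(biliary_fraction=0.0))
        res = simulate(daidzin, rat_phys, DoseRegimen(dose=0.0), t_end=24.0,
                       config=cfg)
        last = res.trajectories.iloc[-1]
        kp = load_kp("daidzin")
        ca = last["artery"]
        for comp, tissue in [("lung", "Lung"), ("heart", "Heart"),
                             ("muscle", "Muscle"), ("spleen", "Spleen"),
                             ("brain", "Brain"), ("rest", "RestOfBody")]:
            assert last[comp] / ca == pytest.approx(kp[tissue], rel=0.01)

    def test_ehc_produces_secondary_peak(self, methylretusin, rat_phys):
        """With biliary recirculation on, the profile shows a local maximum
        after the 3 h gallbladder-emptying event; with it off the profile
        is unimodal after Tmax."""
        res = simulate(methylretusin, rat_phys, DoseRegimen(dose=0.11))
        t, c = res.profile.times, res.profile.conc
        interior = (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
        after_event = t[1:-1] > 3.0
        assert np.any(interior & after_event)

        cfg = ModelConfig(ehc=EHCParams(biliary_fraction=0.0))
        res0 = simulate(methylretusin, rat_phys, DoseRegimen(dose=0.11),
                        config=cfg)
        c0 = res0.profile.conc
        i_max = int(np.argmax(c0))
        assert np.all(np.diff(c0[i_max:]) <= 1e-12 * c0.max())
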