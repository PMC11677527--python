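"""Domain types, loaders, and unit conversions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcpbpk.data_model import (
    COMPOUND_NAMES,
    SAMPLING_TIMES_H,
    TISSUES,
    ConcentrationTimeProfile,
    DoseRegimen,
    ObservedDataset,
    UnknownCompoundError,
    conc_to_molar,
    derive_fb,
    load_compound,
    load_kp,
    load_physiology,
    load_pk_table,
    molar_to_conc,
)
from spcpbpk.pbpk_core import COMPARTMENT_MAP, STATE_LABELS


class TestLoadCompound:
    @pytest.mark.parametrize("name,field,expected", [
        ("daidzin", "mw", 416.38),
        ("daidzin", "log_p", 0.541),
        ("daidzin", "solubility", 0.720),
        ("daidzin", "ref_ph", 6.40),
        ("isolariciresinol", "papp", 0.220e-5),
        ("3'-methoxydadizein", "km", 44.408),
        ("8-O-methylretusin", "vmax", 8.998),
    ])
    def test_tabulated_scalars(self, name, field, expected):
        assert getattr(load_compound(name), field) == pytest.approx(expected)

    def test_both_species_populated(self):
        c = load_compound("isolariciresinol")
        assert c.cl["rat"] == pytest.approx(7.152)
        assert c.cl["human"] > c.cl["rat"]      # allometric upscaling
        assert set(c.rbp) == set(c.fup) == {"rat", "human"}

    def test_daidzin_has_no_enzyme(self):
        c = load_compound("daidzin")
        assert c.enzyme == "none" and c.km is None

    def test_index_aliases(self):
        assert load_compound("3").name == "daidzin"

    def test_unknown_name_lists_valid_options(self):
        with pytest.raises(UnknownCompoundError) as err:
            load_compound("quercetin")
        for valid in COMPOUND_NAMES:
            assert valid in str(err.value)


class TestLoadKp:
    def test_tabulated_values(self):
        kp = load_kp("8-O-methylretusin")
        assert kp["Adipose"] == 6.84
        assert kp["Brain"] == 4.73

    def test_equal_rows(self):
        kp = load_kp("daidzin")
        assert kp["YellowMarrow"] == kp["Adipose"] == 0.15

    @pytest.mark.parametrize("name", COMPOUND_NAMES)
    def test_thirteen_positive_entries(self, name):
        kp = load_kp(name)
        assert set(kp.kp) == set(TISSUES)
        assert all(v > 0 for v in kp.kp.values())

    def test_unknown_name(self):
        with pytest.raises(UnknownCompoundError):
            load_kp("quercetin")


class TestConversions:
    def test_conc_to_molar_daidzin(self):
        assert conc_to_molar(0.0151, 416.38) == pytest.approx(0.03626, abs=5e-5)

    def test_zero_concentration(self):
        assert conc_to_molar(0.0, 500.0) == 0.0

    def test_invalid_mw(self):
        with pytest.raises(ValueError):
            conc_to_molar(1.0, 0.0)

    @given(c=st.floats(1e-6, 1e3), mw=st.floats(50.0, 2000.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, c, mw):
        assert molar_to_conc(conc_to_molar(c, mw), mw) == pytest.approx(c, rel=1e-12)


class TestDeriveFb:
    @pytest.mark.parametrize("fup,rbp,expected", [
        (8.403, 0.915, 0.0918),       # constituent 1, rat
        (39.933, 1.044, 0.3825),      # daidzin, rat
        (100.0, 1.0, 1.0),            # fully unbound, blood = plasma
    ])
    def test_values(self, fup, rbp, expected):
        assert derive_fb(fup, rbp) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("fup,rbp", [(0.0, 1.0), (120.0, 1.0), (50.0, 0.0)])
    def test_domain_errors(self, fup, rbp):
        with pytest.raises(ValueError):
            derive_fb(fup, rbp)

    @given(fup=st.floats(0.01, 100.0), rbp=st.floats(0.05, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_always_a_fraction(self, fup, rbp):
        assert 0 < derive_fb(fup, rbp) <= 1.0


class TestPhysiology:
    @pytest.mark.parametrize("species", ["rat", "human"])
    def test_flow_sum_invariant(self, species):
        phys = load_physiology(species)
        q = sum(phys.flows[k] for k in phys._FLOW_SUM_KEYS)
        assert q == pytest.approx(phys.cardiac_output, rel=1e-6)

    def test_blood_partitions_agree(self, rat_phys):
        v = rat_phys.volumes
        assert v["artery"] + v["venous"] == pytest.approx(
            v["plasma"] + v["erythrocyte"], rel=1e-9)

    def test_portal_flow_within_liver_flow(self, rat_phys, human_phys):
        for phys in (rat_phys, human_phys):
            assert phys.flows["gi"] <= phys.flows["liver"]


class TestSymbolInventory:
    """Every symbol of the published ODE system maps to exactly one field
    across the compound / partition / physiology / state containers."""

    def test_ode_compartment_closure(self, rat_phys):
        for comp, (qk, vk, tissue) in COMPARTMENT_MAP.items():
            assert qk in rat_phys.flows          # Q_i
            assert vk in rat_phys.volumes        # V_i
            assert tissue in TISSUES             # k_i
            assert comp in STATE_LABELS          # C_i

    def test_blood_and_lumen_symbols(self, rat_phys):
        for vk in ("artery", "venous", "plasma", "erythrocyte"):  # V_A, V_V, V_p, V_e
            assert vk in rat_phys.volumes
        assert rat_phys.flows["lung"] == rat_phys.cardiac_output  # Q_Lg = Q
        for state in ("artery", "venous", "gut_solid", "gut_dissolved", "bile"):
            assert state in STATE_LABELS


class TestFixtureRoundTrip:
    @pytest.mark.parametrize("loader,args", [
        (load_pk_table, ("base",)),
        (load_pk_table, ("double",)),
    ])
    def test_csv_roundtrip_bit_identical(self, tmp_path, loader, args):
        df = loader(*args)
        p = tmp_path / "roundtrip.csv"
        df.to_csv(p, index=False)
        df2 = pd.read_csv(p)
        for col in df.columns:
            if df[col].dtype.kind == "f":
                assert np.array_equal(df[col].to_numpy(), df2[col].to_numpy())
            else:
                assert (df[col] == df2[col]).all()

    def test_compound_reload_identical(self):
        a, b = load_compound("daidzin"), load_compound("daidzin")
        assert a == b


class TestProfilesAndRegimens:
    def test_profile_rejects_negative_conc(self):
        with pytest.raises(ValueError):
            ConcentrationTimeProfile(times=[0, 1], conc=[1.0, -0.1])

    def test_profile_requires_increasing_times(self):
        with pytest.raises(ValueError):
            ConcentrationTimeProfile(times=[0, 1, 1], conc=[0, 1, 2])

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DoseRegimen(dose=-1.0)
        with pytest.raises(ValueError):
            DoseRegimen(dose=1.0, n_doses=0)
        assert np.allclose(DoseRegimen(dose=1, n_doses=3, interval=8).dose_times,
                           [0, 8, 16])

    def test_observed_dataset_validation(self):
        with pytest.raises(ValueError):
            ObservedDataset(times=[0, 1], mean_conc=[1, 1], sd_conc=[0.1], n=5)

    def test_study_sampling_design(self):
        assert SAMPLING_TIMES_H.size == 12
        assert SAMPLING_TIMES_H[0] == 0.083 and SAMPLING_TIMES_H[-1] == 12.0
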