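"""Domain types, unit conversions, and loaders for the packaged reference data.

The package ships transcriptions of the published parameter tables for the
four Spatholobi Caulis constituents — 3'-methoxydadizein (1),
8-O-methylretusin (2), daidzin (3), and isolariciresinol (4) — together
with editable rat/human reference physiology files.

Unit conventions
----------------
Public I/O uses the units the tables print: concentrations in ug/mL,
clearances in L/h, doses in mg/kg, solubility in mg/mL, Papp in cm/s and
``f_up`` in **percent** (stored as printed, e.g. ``8.403``; converted to a
fraction internally).  The internal simulation unit system is mass ug,
volume mL, time h.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TISSUES",
    "SPECIES",
    "COMPOUND_NAMES",
    "CompoundParams",
    "PartitionSet",
    "PhysiologySet",
    "DoseRegimen",
    "ConcentrationTimeProfile",
    "ObservedDataset",
    "load_compound",
    "load_kp",
    "load_physiology",
    "load_pk_table",
    "conc_to_molar",
    "molar_to_conc",
    "derive_fb",
    "allometric_scale",
]

#: The 13 tissues of the partition-coefficient table.
TISSUES = (
    "Lung", "Adipose", "Muscle", "Liver", "Spleen", "Heart", "Brain",
    "Kidney", "Skin", "ReproOrg", "RedMarrow", "YellowMarrow", "RestOfBody",
)

SPECIES = ("rat", "human")

#: Canonical constituent names, in the numbering 1-4 used throughout.
COMPOUND_NAMES = (
    "3'-methoxydadizein",
    "8-O-methylretusin",
    "daidzin",
    "isolariciresinol",
)

#: Reference body weights (kg) used for interspecies scaling.
RAT_WEIGHT_KG = 0.25
HUMAN_WEIGHT_KG = 70.0

#: Allometric exponent for single-species clearance scaling.
ALLOMETRIC_EXPONENT = 0.75

#: Default particle radius (um) for the oral dissolution model; the source
#: tables do not print one, so it is a model input, overridable per run.
DEFAULT_PARTICLE_RADIUS_UM = 25.0

#: Base doses (mg/kg) at the 30 g crude drug / kg reference dose.
BASE_DOSES_MG_KG = {
    "3'-methoxydadizein": 0.062,
    "8-O-methylretusin": 0.11,
    "daidzin": 0.71,
    "isolariciresinol": 1.31,
}

#: Crude-drug reference dose (g/kg) corresponding to the base constituent
#: doses; 60 and 120 g/kg scale the mg/kg doses proportionally.
CRUDE_DRUG_BASE_G_KG = 30.0


class UnknownCompoundError(KeyError):
    """Raised for a constituent name not in the packaged tables."""


def _normalize_name(name: str) -> str:
    # tolerate the typographic prime and case differences
    return str(name).strip().replace("′", "'").lower()


_ALIASES = {_normalize_name(n): n for n in COMPOUND_NAMES}
_ALIASES.update({str(i + 1): n for i, n in enumerate(COMPOUND_NAMES)})


def resolve_compound_name(name: str) -> str:
    """Map a user-supplied name (or index '1'-'4') to the canonical name."""
    key = _normalize_name(name)
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnknownCompoundError(
        f"unknown constituent {name!r}; valid names: {', '.join(COMPOUND_NAMES)}"
    )


def _data_path(fname: str):
    return resources.files("spcpbpk.data").joinpath(fname)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical, binding, metabolic and clearance parameters for one
    constituent.

    ``rbp``, ``fup`` and ``cl`` are per-species maps keyed ``rat``/``human``.
    ``fup`` is in percent as printed.  ``cl`` holds the tabulated rat plasma
    clearance and its allometrically scaled human counterpart.  ``vss`` is
    the tabulated steady-state volume, stored verbatim (the model also
    computes its own composition-based value; see ``extrapolation``).
    """

    name: str
    index: int
    mw: float                  # g/mol
    log_p: float
    pka: float
    log_d: float
    solubility: float          # mg/mL at ref_ph
    ref_ph: float
    papp: float                # cm/s
    rbp: dict                  # species -> blood:plasma ratio
    fup: dict                  # species -> percent unbound in plasma
    cl: dict                   # species -> total (plasma) clearance, L/h
    vss: float                 # L, tabulated (rat)
    dose_base: float           # mg/kg at the reference crude-drug dose
    enzyme: str                # 'CYP1A2' | 'CYP2C9' | 'none'
    km: float | None = None    # uM
    vmax: float | None = None  # nM/min/nM enzyme
    particle_radius: float = DEFAULT_PARTICLE_RADIUS_UM  # um

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("mw must be > 0")
        if self.solubility <= 0 or self.papp <= 0:
            raise ValueError("solubility and papp must be > 0")
        for sp, v in self.fup.items():
            if not (0 < v <= 100):
                raise ValueError(f"fup[{sp}] must be in (0, 100]")
        for sp, v in self.rbp.items():
            if v <= 0:
                raise ValueError(f"rbp[{sp}] must be > 0")
        for sp, v in self.cl.items():
            if v < 0:
                raise ValueError(f"cl[{sp}] must be >= 0")
        if self.enzyme != "none" and (self.km is None or self.km <= 0):
            raise ValueError("km must be > 0 when an enzyme is assigned")
        if self.particle_radius <= 0:
            raise ValueError("particle_radius must be > 0")


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:blood-outflow partition coefficients k_i for the 13 tissues."""

    kp: dict

    def __post_init__(self):
        if set(self.kp) != set(TISSUES):
            missing = set(TISSUES) - set(self.kp)
            extra = set(self.kp) - set(TISSUES)
            raise ValueError(f"kp must cover exactly the 13 tissues; missing={missing}, extra={extra}")
        for t, v in self.kp.items():
            if v <= 0:
                raise ValueError(f"kp[{t}] must be > 0")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]


@dataclass(frozen=True)
class PhysiologySet:
    """Per-compartment volumes (L), blood flows (L/h) and whole-body traits.

    Flow bookkeeping follows the circulatory layout of the model: lung flow
    equals cardiac output, the seven systemic tissue flows (liver incl.
    portal, kidney, heart, muscle, spleen, brain, rest) sum exactly to
    cardiac output, and the portal (gi) flow is a sub-flow of the liver.
    """

    species: str
    body_weight: float         # kg
    volumes: dict              # compartment -> L
    flows: dict                # compartment -> L/h
    cardiac_output: float      # L/h
    e_to_p: float              # erythrocyte:plasma concentration ratio
    lumen_volume: float        # L, intestinal fluid for dissolution
    intestinal_radius_cm: float
    vss_volumes: dict          # 13-tissue volumes (L) for the Vss sum

    _FLOW_SUM_KEYS = ("liver", "kidney", "heart", "muscle", "spleen", "brain", "rest")
    _VOLUME_KEYS = ("lung", "liver", "kidney", "heart", "muscle", "spleen",
                    "brain", "gi", "rest", "artery", "venous", "plasma", "erythrocyte")
    _FLOW_KEYS = ("lung", "liver", "gi", "kidney", "heart", "muscle", "spleen", "brain", "rest")

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        for k in self._VOLUME_KEYS:
            if k not in self.volumes:
                raise ValueError(f"missing volume entry {k!r}")
            if self.volumes[k] <= 0:
                raise ValueError(f"volume {k!r} must be > 0")
        for k in self._FLOW_KEYS:
            if k not in self.flows:
                raise ValueError(f"missing flow entry {k!r}")
            if self.flows[k] <= 0:
                raise ValueError(f"flow {k!r} must be > 0")
        if self.body_weight <= 0 or self.cardiac_output <= 0:
            raise ValueError("body_weight and cardiac_output must be > 0")
        q_sum = sum(self.flows[k] for k in self._FLOW_SUM_KEYS)
        if abs(q_sum - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError(
                f"systemic flows sum to {q_sum} L/h but cardiac output is "
                f"{self.cardiac_output} L/h (relative tolerance 1e-6)"
            )
        if self.flows["gi"] > self.flows["liver"]:
            raise ValueError("portal (gi) flow cannot exceed total liver flow")
        if set(self.vss_volumes) != set(TISSUES):
            raise ValueError("vss_volumes must cover exactly the 13 tissues")


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule: ``n_doses`` boluses of ``dose`` mg/kg every
    ``interval`` hours."""

    dose: float                # mg/kg
    n_doses: int = 1
    interval: float = 8.0      # h
    route: str = "oral"

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValueError("interval must be > 0 for multiple dosing")
        if self.route != "oral":
            raise ValueError("only the oral route is modelled")

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval


@dataclass
class ConcentrationTimeProfile:
    """Venous concentration versus time for one simulation or dataset."""

    times: np.ndarray          # h, strictly increasing
    conc: np.ndarray           # ug/mL
    matrix: str = "plasma"     # 'plasma' | 'blood'

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.size != self.conc.size:
            raise ValueError("times and conc must have equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if self.matrix not in ("plasma", "blood"):
            raise ValueError("matrix must be 'plasma' or 'blood'")

    def __len__(self):
        return self.times.size

    def interp(self, t) -> np.ndarray:
        """Linear interpolation of the profile at times ``t``."""
        return np.interp(t, self.times, self.conc)


@dataclass
class ObservedDataset:
    """Mean +/- SD summary of replicate concentration measurements."""

    times: np.ndarray
    mean_conc: np.ndarray
    sd_conc: np.ndarray
    n: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_conc = np.asarray(self.mean_conc, dtype=float)
        self.sd_conc = np.asarray(self.sd_conc, dtype=float)
        if not (self.times.size == self.mean_conc.size == self.sd_conc.size):
            raise ValueError("times, mean_conc, sd_conc must have equal length")
        if np.any(self.sd_conc < 0):
            raise ValueError("sd_conc must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


#: The 12 sampling times (h) of the in-vivo study design.
SAMPLING_TIMES_H = np.array(
    [0.083, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0]
)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def conc_to_molar(c: float, mw: float) -> float:
    """Convert a mass concentration (ug/mL) to uM given molar mass (g/mol)."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return c * 1000.0 / mw


def molar_to_conc(c_um: float, mw: float) -> float:
    """Inverse of :func:`conc_to_molar` (uM -> ug/mL)."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return c_um * mw / 1000.0


def derive_fb(fup: float, rbp: float) -> float:
    """Fraction unbound in whole blood from percent unbound in plasma.

    f_b = (f_up/100) / R_bp, clipped to (0, 1].  This is the standard
    plasma-to-blood conversion of the unbound fraction; the source model
    uses f_b in the hepatic elimination term without defining it.
    """
    if not (0 < fup <= 100):
        raise ValueError("fup (percent) must be in (0, 100]")
    if rbp <= 0:
        raise ValueError("rbp must be > 0")
    return min((fup / 100.0) / rbp, 1.0)


def allometric_scale(cl_rat: float, w_rat: float = RAT_WEIGHT_KG,
                     w_human: float = HUMAN_WEIGHT_KG,
                     exponent: float = ALLOMETRIC_EXPONENT) -> float:
    """Single-species allometric clearance scaling CL*(W_h/W_r)^exponent."""
    if w_rat <= 0 or w_human <= 0:
        raise ValueError("weights must be > 0")
    if cl_rat < 0:
        raise ValueError("cl_rat must be >= 0")
    return cl_rat * (w_human / w_rat) ** exponent


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _table1() -> pd.DataFrame:
    with resources.as_file(_data_path("table1_compounds.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def _table2() -> pd.DataFrame:
    with resources.as_file(_data_path("table2_kp.csv")) as p:
        return pd.read_csv(p, index_col="tissue")


def load_compound(name: str) -> CompoundParams:
    """Load one constituent's parameter record from the packaged table.

    Both species' R_bp/f_up are tabulated; human clearance is populated by
    single-species allometric scaling of the tabulated rat clearance
    (0.25 kg rat -> 70 kg human, exponent 0.75).
    """
    cname = resolve_compound_name(name)
    row = _table1().set_index("name").loc[cname]
    enzyme = str(row["enzyme"])
    km = None if pd.isna(row["km_um"]) else float(row["km_um"])
    vmax = None if pd.isna(row["vmax_nm_min_nm"]) else float(row["vmax_nm_min_nm"])
    cl_rat = float(row["cl_rat"])
    return CompoundParams(
        name=cname,
        index=int(row["index"]),
        mw=float(row["mw"]),
        log_p=float(row["log_p"]),
        pka=float(row["pka"]),
        log_d=float(row["log_d"]),
        solubility=float(row["solubility_mg_ml"]),
        ref_ph=float(row["ref_ph"]),
        papp=float(row["papp_cm_s"]),
        rbp={"rat": float(row["rbp_rat"]), "human": float(row["rbp_human"])},
        fup={"rat": float(row["fup_rat"]), "human": float(row["fup_human"])},
        cl={"rat": cl_rat, "human": allometric_scale(cl_rat)},
        vss=float(row["vss_rat"]),
        dose_base=float(row["dose_base"]),
        enzyme=enzyme,
        km=km,
        vmax=vmax,
    )


def load_kp(name: str) -> PartitionSet:
    """Load the 13-tissue partition-coefficient set for one constituent."""
    cname = resolve_compound_name(name)
    col = _table2()[cname]
    return PartitionSet(kp={t: float(col.loc[t]) for t in TISSUES})


def load_physiology(species_or_path) -> PhysiologySet:
    """Load a physiology file: ``'rat'``/``'human'`` for the packaged
    references, or a path to a user-edited YAML with the same schema."""
    if species_or_path in SPECIES:
        ctx = resources.as_file(_data_path(f"{species_or_path}.yaml"))
        with ctx as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(species_or_path).read_text())
    return PhysiologySet(
        species=raw["species"],
        body_weight=float(raw["body_weight_kg"]),
        volumes={k: float(v) for k, v in raw["volumes_l"].items()},
        flows={k: float(v) for k, v in raw["flows_l_h"].items()},
        cardiac_output=float(raw["cardiac_output_l_h"]),
        e_to_p=float(raw["e_to_p"]),
        lumen_volume=float(raw["lumen_volume_l"]),
        intestinal_radius_cm=float(raw["intestinal_radius_cm"]),
        vss_volumes={k: float(v) for k, v in raw["vss_volumes_l"].items()},
    )


def load_pk_table(dose_level: str = "base") -> pd.DataFrame:
    """Published observed/calculated NCA summary tables.

    ``dose_level='base'`` returns the single-dose comparison (columns
    ``obs``/``calc``); ``'double'`` the doubled-dose comparison (columns
    ``calc``/``val``).  Both carry the printed fold-error column
    ``fe_printed`` for regression testing.
    """
    fname = {"base": "table3_obs_calc.csv", "double": "table4_obs_calc_2x.csv"}
    if dose_level not in fname:
        raise ValueError("dose_level must be 'base' or 'double'")
    with resources.as_file(_data_path(fname[dose_level])) as p:
        return pd.read_csv(p)
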