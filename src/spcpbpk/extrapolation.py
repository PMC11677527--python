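"""Rat-to-human translation: allometric clearance scaling, composition of
the steady-state distribution volume, and assembly of the human model.

CL_human = CL_rat * (W_human / W_rat)^0.75 (single-species scaling from
rat, exponent 0.75).  Vss = V_p + V_e * E/P + sum_t V_t * Kp_t over the 13
partition-coefficient tissues.  The human model reuses the rat partition
coefficients (species-invariant passive partitioning — the dominant
extrapolation uncertainty), takes the tabulated human R_bp / f_up, and
keeps the same mg/kg dose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .data_model import (
    ALLOMETRIC_EXPONENT,
    HUMAN_WEIGHT_KG,
    RAT_WEIGHT_KG,
    TISSUES,
    CompoundParams,
    PartitionSet,
    PhysiologySet,
    load_kp,
    load_physiology,
)

__all__ = ["ScalingInput", "allometric_cl", "vss_from_kp", "build_human_model"]


@dataclass(frozen=True)
class ScalingInput:
    cl_rat: float                        # L/h
    w_rat: float = RAT_WEIGHT_KG         # kg
    w_human: float = HUMAN_WEIGHT_KG     # kg
    exponent: float = ALLOMETRIC_EXPONENT

    def __post_init__(self):
        if self.w_rat <= 0 or self.w_human <= 0:
            raise ValueError("weights must be > 0")
        if self.cl_rat < 0:
            raise ValueError("cl_rat must be >= 0")


def allometric_cl(s: ScalingInput) -> float:
    """Human clearance (L/h) by single-species allometric scaling."""
    return s.cl_rat * (s.w_human / s.w_rat) ** s.exponent


def vss_from_kp(kp: PartitionSet, phys: PhysiologySet,
                e_to_p: float | None = None) -> float:
    """Steady-state distribution volume (L) from tissue composition.

    Vss = V_p + V_e * (E/P) + sum over the 13 tissues of V_t * Kp_t.
    ``e_to_p`` defaults to the physiology file's reference ratio.
    """
    if e_to_p is None:
        e_to_p = phys.e_to_p
    for key in ("plasma", "erythrocyte"):
        if key not in phys.volumes:
            raise ValueError(f"physiology lacks the {key!r} volume")
    missing = [t for t in TISSUES if t not in phys.vss_volumes]
    if missing:
        raise ValueError(f"physiology lacks tissue volumes for: {missing}")
    vss = phys.volumes["plasma"] + phys.volumes["erythrocyte"] * e_to_p
    vss += sum(phys.vss_volumes[t] * kp[t] for t in TISSUES)
    return float(vss)


def build_human_model(compound: CompoundParams,
                      kp_rat: PartitionSet | None = None,
                      human_phys: PhysiologySet | None = None,
                      exponent: float = ALLOMETRIC_EXPONENT):
    """Assemble the human parameter set from a (qualified) rat model.

    Returns ``(compound_h, kp_h, phys_h)``: clearance rescaled
    allometrically to the human body weight, human binding parameters
    selected from the table, rat partition coefficients carried over, and
    the packaged human physiology.
    """
    if human_phys is None:
        human_phys = load_physiology("human")
    if kp_rat is None:
        kp_rat = load_kp(compound.name)
    if "human" not in compound.fup or "human" not in compound.rbp:
        raise ValueError("compound lacks human binding parameters (fup/rbp)")
    cl_h = allometric_cl(ScalingInput(
        cl_rat=compound.cl["rat"],
        w_rat=RAT_WEIGHT_KG,
        w_human=human_phys.body_weight,
        exponent=exponent,
    ))
    compound_h = replace(compound, cl={**compound.cl, "human": cl_h})
    return compound_h, kp_rat, human_phys
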