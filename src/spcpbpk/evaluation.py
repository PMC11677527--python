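"""Model qualification: fold error, observed-vs-calculated regression R^2,
and the FE < 2 / R^2 >= 0.8 acceptance gates.

FE = 10^|log10(simulated/observed)| = max/min of a positive pair, the
symmetric ratio conventionally used to qualify PBPK predictions against
observations; a model passes when every compared PK parameter has FE < 2
and the calculated-vs-observed linear regression has R^2 >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConcentrationTimeProfile, ObservedDataset
from .nca import NCAResult

__all__ = [
    "FE_GATE",
    "R2_GATE",
    "FEReport",
    "QualificationVerdict",
    "fold_error",
    "fe_table",
    "regression_r2",
    "qualify",
]

FE_GATE = 2.0
R2_GATE = 0.8

METRICS = ("cmax", "tmax", "auc_t", "auc_inf")


def fold_error(simulated: float, observed: float) -> float:
    """Symmetric fold error of a positive pair; always >= 1."""
    if simulated <= 0 or observed <= 0:
        raise ValueError("fold error requires positive inputs")
    return float(10.0 ** abs(np.log10(simulated / observed)))


@dataclass
class FEReport:
    """Per-metric fold errors and the FE < 2 verdict for one comparison."""

    fe: dict                    # metric -> FE (missing metrics absent)
    missing: tuple = ()
    r_squared: float | None = None

    @property
    def fe_min(self) -> float:
        return min(self.fe.values())

    @property
    def fe_max(self) -> float:
        return max(self.fe.values())

    @property
    def complete(self) -> bool:
        return not self.missing

    @property
    def passed(self) -> bool:
        return bool(self.fe_max < FE_GATE)


def fe_table(calc: NCAResult, obs: NCAResult) -> FEReport:
    """Fold errors for Cmax, Tmax, AUC0->t and AUC0->inf between a
    calculated and an observed NCA result.

    A metric missing (None / non-positive) on either side is skipped and
    recorded in ``missing``; the report is then flagged partial.
    """
    calc_d, obs_d = calc.as_dict(), obs.as_dict()
    fes, missing = {}, []
    for m in METRICS:
        a, b = calc_d.get(m), obs_d.get(m)
        if a is None or b is None or a <= 0 or b <= 0:
            missing.append(m)
            continue
        fes[m] = fold_error(a, b)
    if not fes:
        raise ValueError("no comparable metrics between the two results")
    return FEReport(fe=fes, missing=tuple(missing))


def regression_r2(calc_curve: ConcentrationTimeProfile,
                  obs: ObservedDataset) -> float:
    """Squared correlation of the calculated curve (interpolated at the
    observation times) against the observed means.

    Computed on untransformed concentrations; being a correlation it is
    invariant to pure scaling of either side.
    """
    if obs.times.size < 3:
        raise ValueError("need at least 3 observation points")
    if obs.times.min() < calc_curve.times[0] - 1e-12 or \
            obs.times.max() > calc_curve.times[-1] + 1e-12:
        raise ValueError("observation times outside the calculated curve range")
    calc_at_obs = calc_curve.interp(obs.times)
    r = np.corrcoef(calc_at_obs, obs.mean_conc)[0, 1]
    return float(r ** 2)


@dataclass
class QualificationVerdict:
    fe_pass: bool
    r2_pass: bool
    fe_max: float
    r_squared: float

    @property
    def passed(self) -> bool:
        return self.fe_pass and self.r2_pass


def qualify(fe_report: FEReport, r2: float) -> QualificationVerdict:
    """Combine the two gates: pass iff fe_max < 2 and R^2 >= 0.8."""
    return QualificationVerdict(
        fe_pass=bool(fe_report.fe_max < FE_GATE),
        r2_pass=bool(r2 >= R2_GATE),
        fe_max=float(fe_report.fe_max),
        r_squared=float(r2),
    )
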