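"""Non-compartmental analysis: Cmax, Tmax, AUC0->t, AUC0->inf, lambda_z.

AUC uses the linear trapezoidal rule (the convention of the DAS-era
tooling whose outputs the package is compared with).  The terminal rate
constant lambda_z comes from log-linear least squares over the tail
window after Tmax that maximizes the adjusted R^2, with a minimum of
three points; AUC0->inf = AUC0->t + C_last / lambda_z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConcentrationTimeProfile

__all__ = ["NCAResult", "cmax_tmax", "auc_trapezoid", "auc_infinity", "run_nca"]


@dataclass
class NCAResult:
    cmax: float                    # ug/mL
    tmax: float | None             # h; None for an all-zero profile
    auc_t: float                   # ug*h/mL
    auc_inf: float | None          # ug*h/mL; None when lambda_z inestimable
    lambda_z: float | None         # 1/h
    n_terminal_points: int

    @property
    def estimable_terminal(self) -> bool:
        return self.lambda_z is not None and self.lambda_z > 0

    def as_dict(self) -> dict:
        return {
            "cmax": self.cmax,
            "tmax": self.tmax,
            "auc_t": self.auc_t,
            "auc_inf": self.auc_inf,
            "lambda_z": self.lambda_z,
        }


def cmax_tmax(profile: ConcentrationTimeProfile):
    """Peak concentration and its time (earliest time on exact ties).

    An all-zero profile returns ``(0.0, None)``.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    cmax = float(profile.conc.max())
    if cmax == 0.0:
        return 0.0, None
    tmax = float(profile.times[int(np.argmax(profile.conc))])  # argmax: first max
    return cmax, tmax


def auc_trapezoid(profile: ConcentrationTimeProfile, t_end: float | None = None,
                  t_start: float = 0.0) -> float:
    """Linear-trapezoidal area between ``t_start`` and ``t_end``.

    End points inside the grid are handled by linear interpolation;
    ``t_end`` beyond the profile raises.
    """
    if len(profile) < 2:
        raise ValueError("profile needs at least two points")
    if t_end is None:
        t_end = float(profile.times[-1])
    if t_end > profile.times[-1] + 1e-12:
        raise ValueError("t_end lies beyond the profile grid")
    if t_start < profile.times[0] - 1e-12 or t_end < t_start:
        raise ValueError("invalid integration bounds")
    ts = profile.times
    cs = profile.conc
    inner = (ts > t_start) & (ts < t_end)
    t = np.concatenate(([t_start], ts[inner], [t_end]))
    c = np.concatenate(([profile.interp(t_start)], cs[inner], [profile.interp(t_end)]))
    return float(np.trapezoid(c, t))


def _loglinear_fit(t: np.ndarray, c: np.ndarray):
    """Least-squares slope/intercept of ln(c) on t with adjusted R^2."""
    n = t.size
    y = np.log(c)
    slope, intercept = np.polyfit(t, y, 1)
    yhat = slope * t + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, adj


def auc_infinity(profile: ConcentrationTimeProfile,
                 max_candidates: int = 200):
    """Extrapolated area and terminal rate constant.

    Candidate tail windows start after Tmax and run to the last positive
    concentration; the window with the best adjusted R^2 of the log-linear
    fit (>= 3 points) defines lambda_z.  A non-decaying tail (lambda_z <=
    0) yields a flagged result with ``auc_inf=None``.  On dense grids the
    candidate start points are thinned to ``max_candidates`` for speed.
    """
    cmax, tmax = cmax_tmax(profile)
    if tmax is None:
        raise ValueError("all-zero profile has no terminal phase")
    ts, cs = profile.times, profile.conc
    tail = (ts > tmax) & (cs > 0)
    t_tail, c_tail = ts[tail], cs[tail]
    if t_tail.size < 3:
        raise ValueError("need at least 3 positive concentrations after Tmax")

    starts = np.arange(t_tail.size - 2)
    if starts.size > max_candidates:
        starts = np.unique(np.linspace(0, starts[-1], max_candidates).astype(int))
    best = None
    for s in starts:
        slope, adj = _loglinear_fit(t_tail[s:], c_tail[s:])
        if best is None or adj > best[1]:
            best = (slope, adj, t_tail.size - s)
    slope, _, n_pts = best
    lambda_z = -slope
    auc_t = auc_trapezoid(profile)
    if lambda_z <= 0:
        return NCAResult(cmax=cmax, tmax=tmax, auc_t=auc_t, auc_inf=None,
                         lambda_z=None, n_terminal_points=n_pts)
    c_last = float(cs[cs > 0][-1]) if np.any(cs > 0) else 0.0
    return NCAResult(cmax=cmax, tmax=tmax, auc_t=auc_t,
                     auc_inf=auc_t + c_last / lambda_z,
                     lambda_z=lambda_z, n_terminal_points=n_pts)


def run_nca(profile: ConcentrationTimeProfile, t_end: float | None = None) -> NCAResult:
    """Full NCA of one profile; AUC0->t uses ``t_end`` (default: last
    time point).  Falls back to the non-extrapolated result when the
    terminal phase is too short or not decaying."""
    cmax, tmax = cmax_tmax(profile)
    auc_t = auc_trapezoid(profile, t_end=t_end)
    if tmax is None:
        return NCAResult(cmax=cmax, tmax=None, auc_t=auc_t, auc_inf=None,
                         lambda_z=None, n_terminal_points=0)
    try:
        res = auc_infinity(profile)
    except ValueError:
        return NCAResult(cmax=cmax, tmax=tmax, auc_t=auc_t, auc_inf=None,
                         lambda_z=None, n_terminal_points=0)
    res.auc_t = auc_t
    if res.auc_inf is not None:
        # auc_inf is defined relative to the full-grid auc; re-anchor on t_end
        c_last = float(profile.conc[profile.conc > 0][-1])
        res.auc_inf = auc_trapezoid(profile) + c_last / res.lambda_z
    return res
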