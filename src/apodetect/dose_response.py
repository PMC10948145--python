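"""Four-parameter log-logistic (4PL) dose-response fitting.

The model is ``y = bottom + (top - bottom) / (1 + (ec50 / x) ** hill)``
with dose 0 anchoring the bottom asymptote (the hill > 0 limit of the
curve).  Fitting is nonlinear least squares with a multi-start over
log-spaced EC50 initial values, so the fit is robust to the usual local
minima of the Hill slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "fit_4pl", "project_response", "counts_by_condition",
           "four_param_logistic"]


def four_param_logistic(dose, bottom, top, ec50, hill):
    """Evaluate the 4PL curve; dose 0 maps to the bottom asymptote (hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, bottom, dtype=float)
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / dose[pos]) ** hill)
    if np.ndim(dose) == 0:
        return float(out)
    return out


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with residuals."""

    bottom: float
    top: float
    ec50: float
    hill: float
    residuals: np.ndarray
    doses: np.ndarray
    responses: np.ndarray
    cov: Optional[np.ndarray] = None

    def predict(self, dose):
        return four_param_logistic(dose, self.bottom, self.top, self.ec50, self.hill)


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    fix_bottom: Optional[float] = None,
    allow_negative_hill: bool = False,
    n_starts: int = 8,
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses (counts) against doses (uM).

    Dose 0 (vehicle) is legal and anchors the bottom asymptote.
    ``fix_bottom`` constrains the bottom parameter (e.g. to the vehicle
    response).  Flat responses raise ``ValueError`` because EC50 and the
    Hill slope are unidentifiable.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1D arrays of equal length")
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")
    min_pts = 3 if fix_bottom is not None else 4
    if len(x) < min_pts:
        raise ValueError(f"need at least {min_pts} (dose, response) points")
    if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("responses are flat: EC50 and Hill slope are unidentifiable")
    pos = x[x > 0]
    if pos.size < 2:
        raise ValueError("need at least two nonzero doses")

    fixed_b = fix_bottom is not None

    def unpack(p):
        if fixed_b:
            top, log_ec50, hill = p
            return fix_bottom, top, np.exp(log_ec50), hill
        bottom, top, log_ec50, hill = p
        return bottom, top, np.exp(log_ec50), hill

    def resid(p):
        b, t, e, h = unpack(p)
        return four_param_logistic(x, b, t, e, h) - y

    y0 = float(y[x == 0].mean()) if np.any(x == 0) else float(y.min())
    top0 = float(y.max())
    hill_lo = -10.0 if allow_negative_hill else 1e-3
    best = None
    for log_e0 in np.linspace(np.log(pos.min()), np.log(pos.max()), n_starts):
        for h0 in (1.0, 3.0):
            p0 = ([top0, log_e0, h0] if fixed_b else [y0, top0, log_e0, h0])
            lo = ([-np.inf, -np.inf, hill_lo] if fixed_b
                  else [-np.inf, -np.inf, -np.inf, hill_lo])
            hi = [np.inf] * len(p0)
            try:
                sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("4PL optimization failed from every start")
    b, t, e, h = unpack(best.x)
    if t < b:
        # keep the canonical orientation: top >= bottom
        b, t, h = t, b, -h
    cov = None
    try:
        J = best.jac
        cov = np.linalg.inv(J.T @ J) * (2 * best.cost / max(1, len(x) - len(best.x)))
    except np.linalg.LinAlgError:
        pass
    return DoseResponseFit(bottom=float(b), top=float(t), ec50=float(e), hill=float(h),
                           residuals=resid(best.x), doses=x, responses=y, cov=cov)


def project_response(fit: DoseResponseFit, dose: float) -> Dict[str, float]:
    """Predicted response at a dose and its fraction of the maximal effect."""
    y = float(fit.predict(dose))
    span = fit.top - fit.bottom
    frac = 0.0 if span == 0 else (y - fit.bottom) / span
    return {"response": y, "fraction_of_max_effect": float(frac)}


def counts_by_condition(
    detections_per_condition: Dict,
    timepoints: Sequence[int],
) -> pd.DataFrame:
    """Cumulative apoptotic count per condition at each timepoint (frame).

    ``detections_per_condition`` maps a condition label (e.g. a dose) to
    its event list (tracks, detections or frame indices).  The result
    (conditions x timepoints) feeds :func:`fit_4pl` per timepoint column.
    """
    from .pipeline import cumulative_counts

    timepoints = list(timepoints)
    T = max(timepoints) + 1
    rows = {}
    for cond, events in detections_per_condition.items():
        series = cumulative_counts(list(events), T)
        rows[cond] = [int(series[t]) for t in timepoints]
    return pd.DataFrame.from_dict(rows, orient="index", columns=timepoints)
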