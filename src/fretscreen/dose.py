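"""Four-parameter log-logistic (Hill) concentration-response fitting.

response(d) = bottom + (top - bottom) / (1 + (ec50 / d) ** hill_slope)

A positive slope gives a rising (agonist) curve, a negative slope a falling
(antagonist/inhibitor) curve; EC50/IC50 is the dose at the half-maximal
response in either case. Fitting is nonlinear least squares on
(log ec50, slope, top, bottom) with multiple starts over the slope sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "hill_curve", "fit_hill", "evaluate_curve"]


@dataclass
class DoseResponseFit:
    ec50: float | None
    hill_slope: float | None
    top: float | None
    bottom: float | None
    residual_norm: float | None
    converged: bool
    direction: str = "agonist"


def hill_curve(dose, ec50: float, hill_slope: float, top: float, bottom: float):
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill_slope)


def _initial_ec50(doses: np.ndarray, responses: np.ndarray) -> float:
    """Geometric mean of the doses bracketing the half-response crossing."""
    order = np.argsort(doses)
    d, r = doses[order], responses[order]
    half = 0.5 * (r.min() + r.max())
    above = r >= half
    for i in range(len(d) - 1):
        if above[i] != above[i + 1]:
            return float(np.sqrt(d[i] * d[i + 1]))
    return float(np.exp(np.mean(np.log(d))))


def fit_hill(
    doses,
    responses,
    direction: str = "agonist",
    fix_top: float | None = None,
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares Hill fit.

    ``direction`` constrains the slope sign ("agonist" rising, "antagonist"
    falling, "auto" tries both). Four free parameters need at least four
    distinct doses; fixing top and/or bottom lowers the requirement
    accordingly. Constant responses are refused (no identifiable curve).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1-D arrays")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if direction not in ("agonist", "antagonist", "auto"):
        raise ValueError(f"unknown direction {direction!r}")
    n_free = 2 + (fix_top is None) + (fix_bottom is None)
    if len(np.unique(doses)) < n_free:
        raise ValueError(
            f"{n_free} free parameters need at least {n_free} distinct doses"
        )
    if np.ptp(responses) == 0:
        raise ValueError("responses are constant; no dose-response to fit")

    rng_top = float(responses.max())
    rng_bottom = float(responses.min())

    def unpack(p):
        i = 2
        top = fix_top
        bottom = fix_bottom
        if fix_top is None:
            top = p[i]
            i += 1
        if fix_bottom is None:
            bottom = p[i]
        return np.exp(p[0]), p[1], top, bottom

    def residuals(p):
        ec50, slope, top, bottom = unpack(p)
        return hill_curve(doses, ec50, slope, top, bottom) - responses

    log_ec50_0 = np.log(_initial_ec50(doses, responses))
    slopes = {"agonist": [1.0, 2.0], "antagonist": [-1.0, -2.0]}.get(
        direction, [1.0, -1.0, 2.0, -2.0]
    )
    best = None
    for s0 in slopes:
        p0 = [log_ec50_0, s0]
        lo = [np.log(doses.min()) - 6.0, 0.0 if s0 > 0 else -np.inf]
        hi = [np.log(doses.max()) + 6.0, np.inf if s0 > 0 else 0.0]
        if fix_top is None:
            p0.append(rng_top)
            lo.append(-np.inf)
            hi.append(np.inf)
        if fix_bottom is None:
            p0.append(rng_bottom)
            lo.append(-np.inf)
            hi.append(np.inf)
        try:
            res = least_squares(
                residuals, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return DoseResponseFit(None, None, None, None, None, False, direction)
    ec50, slope, top, bottom = unpack(best.x)
    return DoseResponseFit(
        ec50=float(ec50),
        hill_slope=float(slope),
        top=float(top),
        bottom=float(bottom),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=True,
        direction=direction,
    )


def evaluate_curve(fit: DoseResponseFit, dose):
    """Predicted response at ``dose``; the fit must have converged.
    At dose = EC50 this is exactly (top + bottom) / 2."""
    if not fit.converged:
        raise ValueError("cannot evaluate a non-converged fit")
    return hill_curve(dose, fit.ec50, fit.hill_slope, fit.top, fit.bottom)
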