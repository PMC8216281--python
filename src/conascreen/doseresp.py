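"""Four-parameter logistic (4PL) concentration-response fitting.

The model is the standard [inhibitor]-vs-response curve

    y(x) = bottom + (top - bottom) / (1 + (x / IC50)^hill)

so y(0) = top, y(IC50) = (top + bottom)/2 and, for hill > 0, y decreases
monotonically with dose.  IC50 is reported as the inflection dose of the
fitted curve (relative IC50).  The fit is ordinary least squares on the
well responses; internally the dose axis enters through log(x/IC50), which
makes the problem exactly equivariant under rescaling all doses.
Standard errors come from the local curvature (Gauss-Newton covariance)
of the objective at the optimum, with the IC50 error mapped back from the
log scale by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import InputError


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with standard errors."""

    top: float
    bottom: float
    ic50: float
    hill: float
    se_top: float
    se_bottom: float
    se_ic50: float
    se_hill: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    @property
    def reliable(self) -> bool:
        """Converged and IC50 better determined than its own magnitude."""
        return self.converged and np.isfinite(self.se_ic50) \
            and self.se_ic50 < self.ic50

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "ic50_uM": self.ic50,
            "hill": self.hill,
            "se_top": self.se_top,
            "se_bottom": self.se_bottom,
            "se_ic50_uM": self.se_ic50,
            "se_hill": self.se_hill,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "reliable": self.reliable,
        }


def four_pl(x, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL; y(0) = top for hill > 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(
            x > 0,
            np.exp(hill * (np.log(np.where(x > 0, x, 1.0)) - np.log(ic50))),
            0.0,
        )
    return bottom + (top - bottom) / (1.0 + ratio)


def predict_4pl(fit: DoseResponseFit, x) -> np.ndarray | float:
    """Fitted response at dose(s) ``x`` (same units as the fitted doses)."""
    y = four_pl(x, fit.top, fit.bottom, fit.ic50, fit.hill)
    return float(y) if np.isscalar(x) else y


def _default_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """top/bottom from the response range; IC50 brackets half-response."""
    top = float(np.max(y))
    bottom = float(np.min(y))
    half = 0.5 * (top + bottom)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    below = np.flatnonzero(ys <= half)
    above = np.flatnonzero(ys > half)
    if below.size and above.size:
        # Geometric mean of the largest dose still above half-response and
        # the smallest dose already below it.
        hi_dose = xs[below[0]]
        lo_dose = xs[above[-1]] if above[-1] < below[0] else hi_dose
        ic50 = float(np.sqrt(max(lo_dose, xs[xs > 0].min()) * hi_dose))
    else:
        ic50 = float(np.exp(np.mean(np.log(xs[xs > 0]))))
    return top, bottom, ic50, 1.0


def fit_4pl(
    concentrations,
    responses,
    init: tuple[float, float, float, float] | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses vs dose.

    Requires at least five distinct concentrations.  Doses of zero are
    accepted (they anchor the top plateau).  Non-convergence or an
    unidentifiable transition yields ``converged = False`` (or an IC50
    standard error exceeding the IC50, see ``DoseResponseFit.reliable``)
    rather than an exception.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("concentrations and responses must be equal-length 1-D")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("doses and responses must be finite")
    if (x < 0).any():
        raise InputError("doses must be >= 0")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise InputError("all doses are equal; dose range required")
    if distinct.size < 5:
        raise InputError(
            f"need >= 5 distinct concentrations, got {distinct.size}"
        )
    p0 = init if init is not None else _default_init(x, y)
    # Fit with log(IC50) as the free parameter: positivity for free and
    # exact dose-scale equivariance.
    q0 = (p0[0], p0[1], float(np.log(p0[2])), p0[3])

    def model(xv, top, bottom, log_ic50, hill):
        return four_pl(xv, top, bottom, float(np.exp(log_ic50)), hill)

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=q0, maxfev=20000, xtol=1e-12, ftol=1e-12,
        )
        converged = True
        message = ""
    except RuntimeError as exc:
        return DoseResponseFit(
            top=float(p0[0]), bottom=float(p0[1]), ic50=float(p0[2]),
            hill=float(p0[3]), se_top=np.inf, se_bottom=np.inf,
            se_ic50=np.inf, se_hill=np.inf, rss=float("nan"),
            n_points=x.size, converged=False, message=str(exc),
        )
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    ic50 = float(np.exp(log_ic50))
    resid = y - model(x, *popt)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    se_ic50 = float(ic50 * se[2])  # delta method from the log scale
    if not np.isfinite(se).all():
        converged = False
        message = "singular covariance: transition not identifiable"
    if bottom > top:
        # Re-orient: the model is symmetric under (top<->bottom, hill->-hill).
        top, bottom = bottom, top
        hill = -hill
        se[0], se[1] = se[1], se[0]
    return DoseResponseFit(
        top=top, bottom=bottom, ic50=ic50, hill=hill,
        se_top=float(se[0]), se_bottom=float(se[1]),
        se_ic50=se_ic50, se_hill=float(se[3]),
        rss=rss, n_points=int(x.size), converged=converged, message=message,
    )
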