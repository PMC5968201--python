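"""Four-parameter logistic (4PL) dose-response fitting and the 1 uM cap.

The model is the standard sigmoidal inhibition curve

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with a *relative* IC50: the concentration at the curve midpoint
``(top + bottom) / 2``. Fitting is bounded nonlinear least squares in
log10(IC50) space with a midpoint-based initial guess and a small
multi-start over Hill slopes, which is robust on 8-point serial-dilution
series without user tuning.

The working concentration for combination assays follows the screening
rule: use the fitted IC50, capped at 1 uM whenever the IC50 exceeds 1 uM
(strictly "higher than": an IC50 of exactly 1 uM is not capped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateFitError, UnconvergedFitError, ValidationError

__all__ = [
    "DoseResponseFit",
    "WorkingConcentration",
    "four_pl",
    "make_dilution_series",
    "fit_four_pl",
    "working_concentration",
]

#: Default working-concentration cap: 1 uM in molar.
DEFAULT_CAP_MOLAR = 1e-6

_HILL_BOUNDS = (0.1, 10.0)
_HILL_STARTS = (1.0, 0.5, 2.0)


@dataclass(frozen=True, slots=True)
class DoseResponseFit:
    """Fitted 4PL parameters for one (cell line, drug) pair.

    ``ic50`` is in molar; ``rss`` is the achieved residual sum of squares;
    ``converged`` reports the optimizer's honest status.
    """

    cell_line: str
    drug: str
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValidationError(f"ic50 must be positive, got {self.ic50}")

    def predict(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float), self.top, self.bottom, self.ic50, self.hill)


@dataclass(frozen=True, slots=True)
class WorkingConcentration:
    """Concentration used in combination assays after applying the cap rule."""

    drug: str
    cell_line: str
    concentration: float
    capped: bool


def four_pl(x, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL inhibition curve at dose(s) ``x`` (molar)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def make_dilution_series(top_dose: float, factor: float, n_points: int) -> list[float]:
    """Descending geometric dilution series ``top_dose / factor**i``.

    An 8-point 5-fold series from 100 uM ends at 100 uM / 5^7 = 1.28 nM,
    the span of a typical drug-sensitivity assay.
    """
    if top_dose <= 0:
        raise ValidationError(f"top_dose must be positive, got {top_dose}")
    if factor <= 1:
        raise ValidationError(f"dilution factor must exceed 1, got {factor}")
    if n_points < 2:
        raise ValidationError(f"need at least 2 points, got {n_points}")
    return [top_dose / factor**i for i in range(n_points)]


def _fit_once(log_x, y, p0, bounds):
    def residuals(p):
        top, bottom, log_ic50, hill = p
        return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_x - log_ic50))) - y

    return least_squares(
        residuals, p0, bounds=bounds, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )


def fit_four_pl(
    doses,
    responses,
    cell_line: str = "",
    drug: str = "",
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses against doses (molar).

    Requires >= 4 distinct positive doses. Initialization: top/bottom from
    the response range, IC50 from the dose whose response is nearest the
    midpoint, Hill slope 1 with a multi-start over {0.5, 1, 2}. Bounds:
    bottom >= 0, hill in [0.1, 10], IC50 within [min dose / 100,
    max dose * 100] to prevent pathological extrapolation.

    Raises
    ------
    DegenerateFitError
        If all responses are identical (no IC50 is definable).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("doses and responses must be 1-D and equally long")
    if np.unique(x).size < 4:
        raise ValidationError("need at least 4 distinct doses")
    if not np.all(x > 0):
        raise ValidationError("doses must be positive for a log-dose fit")
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if np.ptp(y) == 0:
        raise DegenerateFitError("all responses identical; no IC50 definable")

    log_x = np.log10(x)
    lo_ic50, hi_ic50 = math.log10(x.min() / 100.0), math.log10(x.max() * 100.0)
    top0, bottom0 = float(y.max()), float(y.min())
    mid = 0.5 * (top0 + bottom0)
    ic50_0 = float(np.clip(log_x[np.argmin(np.abs(y - mid))], lo_ic50, hi_ic50))
    lower = [-np.inf, 0.0, lo_ic50, _HILL_BOUNDS[0]]
    upper = [np.inf, np.inf, hi_ic50, _HILL_BOUNDS[1]]

    best = None
    for hill0 in _HILL_STARTS:
        res = _fit_once(log_x, y, [top0, max(bottom0, 0.0), ic50_0, hill0], (lower, upper))
        if best is None or res.cost < best.cost:
            best = res
        if best.success and best.cost < 1e-12 * max(1.0, float(y @ y)):
            break

    top, bottom, log_ic50, hill = best.x
    return DoseResponseFit(
        cell_line=cell_line,
        drug=drug,
        top=float(top),
        bottom=float(bottom),
        ic50=float(10**log_ic50),
        hill=float(hill),
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
    )


def working_concentration(
    fit: DoseResponseFit,
    cap: float = DEFAULT_CAP_MOLAR,
    allow_unconverged: bool = False,
) -> WorkingConcentration:
    """Apply the cap rule: use the IC50, but never more than ``cap`` (1 uM).

    ``capped`` is True iff the IC50 is strictly above the cap. Refuses a
    non-converged fit unless ``allow_unconverged`` is set.
    """
    if not fit.converged and not allow_unconverged:
        raise UnconvergedFitError(
            f"fit for ({fit.cell_line!r}, {fit.drug!r}) did not converge; "
            "pass allow_unconverged=True to override"
        )
    if cap <= 0:
        raise ValidationError(f"cap must be positive, got {cap}")
    capped = fit.ic50 > cap
    return WorkingConcentration(
        drug=fit.drug,
        cell_line=fit.cell_line,
        concentration=cap if capped else fit.ic50,
        capped=capped,
    )
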