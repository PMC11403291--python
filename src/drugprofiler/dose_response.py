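"""Dilution series and four-parameter logistic (4PL) dose-response fitting.

Shared machinery for the binding, thermal and synergy engines. All
concentrations are handled internally in μmol/L; potencies (pIC50, pEC50,
pKd) are reported on the molar scale, i.e.

    pec50 = 6 - log10(EC50 [μmol/L]) = -log10(EC50 [mol/L])

so an EC50 of 3.2 nmol/L corresponds to pec50 ≈ 8.5.

The 4PL response model is

    y(c) = bottom + (top - bottom) / (1 + (c / EC50)^hill)

with hill > 0, so ``top`` is always the zero-dose asymptote and ``bottom``
the high-dose plateau. A decreasing curve (competition, viability) has
top > bottom; an increasing curve (thermal stabilization) has top < bottom.
Curve direction is an explicit argument to the fitter, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError, NoDoseDependenceError

__all__ = [
    "DoseSeries",
    "FourPLParams",
    "FourPLFit",
    "make_dilution_series",
    "pec50_from_conc_um",
    "conc_um_from_pec50",
    "fourpl_predict",
    "fit_fourpl",
]

#: Allowed Hill-slope magnitude during fitting.
HILL_BOUNDS = (0.2, 5.0)


def pec50_from_conc_um(conc_um: float) -> float:
    """Molar-scale p-value of a concentration given in μmol/L."""
    return 6.0 - np.log10(conc_um)


def conc_um_from_pec50(pec50: float) -> float:
    """Inverse of :func:`pec50_from_conc_um`."""
    return 10.0 ** (6.0 - pec50)


@dataclass(frozen=True)
class DoseSeries:
    """A descending geometric dilution series in μmol/L."""

    start_conc: float
    dilution_factor: float
    n_points: int

    @property
    def concentrations(self) -> np.ndarray:
        return self.start_conc / self.dilution_factor ** np.arange(self.n_points)

    def __len__(self) -> int:
        return self.n_points


def make_dilution_series(start_conc: float, dilution_factor: float, n_points: int) -> DoseSeries:
    """Build a serial-dilution series, e.g. ``(30, 7, 6)`` for a six-point
    competition experiment starting at 30 μmol/L with a 7-fold dilution step.
    """
    if not start_conc > 0:
        raise InputError(f"start_conc must be positive, got {start_conc}")
    if not dilution_factor > 1:
        raise InputError(f"dilution_factor must exceed 1, got {dilution_factor}")
    if not (isinstance(n_points, (int, np.integer)) and n_points >= 1):
        raise InputError(f"n_points must be a positive integer, got {n_points}")
    return DoseSeries(float(start_conc), float(dilution_factor), int(n_points))


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of a 4PL curve; ``pec50`` is on the molar scale."""

    top: float
    bottom: float
    pec50: float
    hill: float

    def __post_init__(self):
        if not np.isfinite(self.pec50):
            raise InputError("pec50 must be finite")


def fourpl_predict(params: FourPLParams, conc_um) -> np.ndarray | float:
    """Evaluate the 4PL model at concentrations given in μmol/L.

    Zero concentration maps exactly to ``top`` (the zero-dose asymptote).
    """
    scalar = np.isscalar(conc_um)
    conc = np.atleast_1d(np.asarray(conc_um, dtype=float))
    if np.any(conc < 0):
        raise InputError("concentrations must be non-negative")
    ec50 = conc_um_from_pec50(params.pec50)
    ratio = np.zeros_like(conc)
    pos = conc > 0
    ratio[pos] = (conc[pos] / ec50) ** params.hill
    out = params.bottom + (params.top - params.bottom) / (1.0 + ratio)
    return float(out[0]) if scalar else out


@dataclass
class FourPLFit:
    """A fitted 4PL curve with goodness-of-fit diagnostics."""

    params: FourPLParams
    r_squared: float
    rmse: float
    n_points: int
    residuals: np.ndarray = field(repr=False)

    @property
    def pec50(self) -> float:
        return self.params.pec50


def _resolve_constraint(name, constraint, default_init, default_bounds):
    """A constraint is None (free), a float (fixed) or a (lo, hi) bound pair."""
    if constraint is None:
        return default_init, default_bounds
    if np.isscalar(constraint):
        v = float(constraint)
        return v, (v, v)
    lo, hi = (float(constraint[0]), float(constraint[1]))
    if not lo <= hi:
        raise InputError(f"invalid {name} bounds ({lo}, {hi})")
    init = min(max(default_init, lo), hi)
    return init, (lo, hi)


def fit_fourpl(
    concentrations,
    responses,
    *,
    direction: str = "decreasing",
    top=None,
    bottom=None,
    hill_bounds=HILL_BOUNDS,
    flat_epsilon: float = 0.1,
    min_levels: int = 4,
) -> FourPLFit:
    """Bounded nonlinear least-squares 4PL fit.

    Parameters
    ----------
    concentrations, responses
        Paired observations; concentrations in μmol/L (zero allowed, e.g.
        vehicle wells). Replicated concentrations may simply be repeated.
    direction
        ``"decreasing"`` (competition/viability: response falls with dose) or
        ``"increasing"`` (stabilization: response rises with dose).
    top, bottom
        Optional constraints on the zero-dose asymptote (``top``) and the
        high-dose plateau (``bottom``): a float fixes the parameter exactly,
        a ``(lo, hi)`` pair bounds it, ``None`` leaves it free.
    flat_epsilon
        Minimum response range; flatter data raise
        :class:`~drugprofiler.errors.NoDoseDependenceError`.

    The optimiser is restarted from three initial pEC50 guesses (series
    maximum, geometric midpoint, series minimum) and the best solution kept,
    which makes the fit robust without stochastic search.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise InputError("concentrations and responses must be equal-length 1-D arrays")
    if not np.all(np.isfinite(resp)):
        raise InputError("responses must be finite")
    if np.any(conc < 0):
        raise InputError("concentrations must be non-negative")
    pos = conc[conc > 0]
    levels = np.unique(pos)
    if levels.size < min_levels:
        raise InputError(f"need >= {min_levels} positive dose levels, got {levels.size}")
    if levels.max() / levels.min() <= 10:
        raise InputError("dose levels must span more than one order of magnitude")
    if direction not in ("decreasing", "increasing"):
        raise InputError(f"unknown direction {direction!r}")

    span = resp.max() - resp.min()
    if span < flat_epsilon:
        raise NoDoseDependenceError(
            f"response range {span:.4g} below flat_epsilon={flat_epsilon}: no dose dependence"
        )

    # Zero-dose asymptote initial guess comes from the low-dose end.
    if direction == "decreasing":
        top_init, bottom_init = resp.max(), resp.min()
    else:
        top_init, bottom_init = resp.min(), resp.max()
    pad = 0.5 * span
    free_bounds = (resp.min() - pad, resp.max() + pad)
    top_init, top_b = _resolve_constraint("top", top, top_init, free_bounds)
    bottom_init, bottom_b = _resolve_constraint("bottom", bottom, bottom_init, free_bounds)

    pec_lo = pec50_from_conc_um(levels.max()) - 2.0
    pec_hi = pec50_from_conc_um(levels.min()) + 2.0
    gmid = float(np.exp(np.mean(np.log(levels))))
    pec_starts = [
        pec50_from_conc_um(levels.max()),
        pec50_from_conc_um(gmid),
        pec50_from_conc_um(levels.min()),
    ]

    def model(theta):
        t, b, p, h = theta
        return fourpl_predict(FourPLParams(t, b, p, h), conc)

    def residual(theta):
        return model(theta) - resp

    lo = np.array([top_b[0], bottom_b[0], pec_lo, hill_bounds[0]])
    hi = np.array([top_b[1], bottom_b[1], pec_hi, hill_bounds[1]])
    # least_squares requires lo < hi strictly; widen fixed parameters by eps.
    fixed = lo == hi
    hi[fixed] = hi[fixed] + 1e-12

    best = None
    for p0 in pec_starts:
        x0 = np.clip(np.array([top_init, bottom_init, p0, 1.0]), lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - defensive
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("4PL fit failed to converge from all starting points")

    t, b, p, h = best.x
    if fixed[0]:
        t = lo[0]
    if fixed[1]:
        b = lo[1]
    res = model((t, b, p, h)) - resp
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return FourPLFit(
        params=FourPLParams(float(t), float(b), float(p), float(h)),
        r_squared=r2,
        rmse=float(np.sqrt(ss_res / resp.size)),
        n_points=int(resp.size),
        residuals=res,
    )
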