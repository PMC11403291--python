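"""Targeted steroid quantification: calibration fitting, validation, outlier
removal, model selection, sample quantification and treatment statistics.

Each metabolite's LC-MS response is first normalized to its stable-isotope
internal standard (analyte/IS ratio). Calibration series (nominal
concentration -> normalized response) are then fitted with four candidate
models — straight line y = a x + b and quadratic y = a x^2 + b x + c, each
either unweighted or weighted by 1/concentration. A calibration is *valid*
when every retained point back-calculates its own concentration through the
inverse model to within 15% relative error. Invalid calibrations go through
automated outlier removal: the point with the worst back-calculation error
is dropped and the model refitted, up to a budget of 25% of the points.
Among valid candidates the one with most retained points and then highest
R^2 wins per family/weighting; across the four combinations the highest R^2
wins. The chosen model's inverse quantifies the study samples, and
treated-vs-vehicle effects are summarized as a fold change with a Welch
two-sided t-test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NotQuantifiableError

__all__ = [
    "CalibrationModel",
    "normalize_to_internal_standard",
    "fit_calibration",
    "validate_calibration",
    "remove_outliers",
    "select_calibration",
    "quantify_samples",
    "treatment_fold_and_test",
    "FAMILIES",
    "WEIGHTINGS",
]

logger = logging.getLogger(__name__)

FAMILIES = ("straight", "quadratic")
WEIGHTINGS = ("none", "inverse_concentration")
_MIN_POINTS = {"straight": 4, "quadratic": 5}
_DEGREE = {"straight": 1, "quadratic": 2}

#: Deterministic tie-break order across family x weighting combinations.
COMBINATIONS = tuple(itertools.product(FAMILIES, WEIGHTINGS))


def normalize_to_internal_standard(analyte_response: float, is_response: float) -> float:
    """Analyte/internal-standard response ratio."""
    if not is_response > 0:
        raise InputError("internal-standard response must be positive; sample flagged")
    return float(analyte_response) / float(is_response)


@dataclass
class CalibrationModel:
    """A fitted (possibly not yet validated) calibration curve.

    ``coefficients`` are in descending powers (numpy.polyfit convention):
    straight ``(a, b)`` for y = a x + b, quadratic ``(a, b, c)`` for
    y = a x^2 + b x + c.
    """

    family: str
    weighting: str
    coefficients: np.ndarray
    r_squared: float
    nominal_conc: np.ndarray = field(repr=False)
    norm_response: np.ndarray = field(repr=False)
    retained: np.ndarray = field(repr=False)  # boolean mask over all points
    valid: bool = False
    back_calc_errors: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return int(self.retained.size)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def n_removed(self) -> int:
        return self.n_total - self.n_retained

    def predict(self, conc) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(conc, dtype=float))

    def inverse(self, response: float) -> float:
        """Back-calculate a concentration from a response through the
        monotone branch of the calibration curve.

        Returns ``nan`` when no unique admissible root exists (the model is
        then non-invertible for this response).
        """
        cmax = float(self.nominal_conc[self.retained].max())
        if self.family == "straight":
            a, b = self.coefficients
            if abs(a) < 1e-12 * max(1.0, abs(b)):
                return math.nan
            return float((response - a * 0 - b) / a)
        a, b, c = self.coefficients
        if abs(a) < 1e-14:
            if abs(b) < 1e-12:
                return math.nan
            return float((response - c) / b)
        # Monotonicity of the fitted parabola over the calibration range:
        # derivative 2ax + b must not change sign on [cmin, cmax].
        cmin = float(self.nominal_conc[self.retained].min())
        d_lo, d_hi = 2 * a * cmin + b, 2 * a * cmax + b
        if d_lo * d_hi < 0:
            return math.nan
        disc = b * b - 4 * a * (c - response)
        if disc < 0:
            return math.nan
        sq = math.sqrt(disc)
        vertex = -b / (2 * a)
        # The two roots mirror each other across the vertex; the calibration
        # range lies entirely on one side, and the root on that side is the
        # single-valued inverse.
        if (cmin + cmax) / 2 >= vertex:
            root = (-b + sq) / (2 * a) if a > 0 else (-b - sq) / (2 * a)
        else:
            root = (-b - sq) / (2 * a) if a > 0 else (-b + sq) / (2 * a)
        if not -1e-9 <= root <= 2 * cmax:
            return math.nan
        return float(root)


def _weights(conc: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(conc)
    if weighting == "inverse_concentration":
        if np.any(conc <= 0):
            raise InputError("inverse-concentration weighting requires positive concentrations")
        return 1.0 / conc
    raise InputError(f"unknown weighting {weighting!r}")


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        conc = points["nominal_conc"].to_numpy(dtype=float)
        if "norm_response" in points.columns:
            resp = points["norm_response"].to_numpy(dtype=float)
        else:
            resp = (
                points["analyte_response"].to_numpy(dtype=float)
                / points["is_response"].to_numpy(dtype=float)
            )
    else:
        arr = np.asarray(points, dtype=float)
        conc, resp = arr[:, 0], arr[:, 1]
    return conc, resp


def fit_calibration(points, family: str, weighting: str = "none",
                    retained: np.ndarray | None = None) -> CalibrationModel:
    """Weighted least-squares calibration fit (unvalidated).

    ``points`` is a DataFrame with columns ``nominal_conc`` and
    ``norm_response`` (or ``analyte_response``/``is_response``), or an
    (n, 2) array. Weights are 1 or 1/concentration; R^2 is computed on the
    weighted fit so the score matches the objective.
    """
    if family not in FAMILIES:
        raise InputError(f"unknown family {family!r}")
    conc, resp = _as_points(points)
    if retained is None:
        retained = np.ones(conc.size, dtype=bool)
    retained = np.asarray(retained, dtype=bool)
    x, y = conc[retained], resp[retained]
    if np.unique(x).size < _MIN_POINTS[family]:
        raise InputError(
            f"{family} calibration needs >= {_MIN_POINTS[family]} distinct concentrations, "
            f"got {np.unique(x).size}"
        )
    w = _weights(x, weighting)
    # numpy.polyfit applies weights to the residuals, so pass sqrt(w) to
    # minimise sum w * (y - f)^2.
    coef = np.polyfit(x, y, _DEGREE[family], w=np.sqrt(w))
    yhat = np.polyval(coef, x)
    ybar = np.sum(w * y) / np.sum(w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CalibrationModel(
        family=family, weighting=weighting, coefficients=coef, r_squared=r2,
        nominal_conc=conc, norm_response=resp, retained=retained,
    )


def validate_calibration(model: CalibrationModel, tolerance: float = 0.15) -> CalibrationModel:
    """Back-calculation validation: the model is valid iff every retained
    point's concentration, re-predicted from its own response through the
    inverse model, is within ``tolerance`` relative error of nominal.

    Non-invertible responses get an infinite error. Idempotent.
    """
    errs = np.full(model.n_total, np.nan)
    idx = np.flatnonzero(model.retained)
    for i in idx:
        back = model.inverse(float(model.norm_response[i]))
        nominal = float(model.nominal_conc[i])
        if math.isnan(back):
            errs[i] = math.inf
        else:
            errs[i] = abs(back - nominal) / nominal
    model.back_calc_errors = errs
    model.valid = bool(np.all(errs[idx] <= tolerance))
    return model


def remove_outliers(
    points,
    family: str,
    weighting: str = "none",
    max_removed_frac: float = 0.25,
    tolerance: float = 0.15,
) -> CalibrationModel:
    """Greedy automated outlier removal for one family/weighting combination.

    Repeatedly fit on the retained set and validate; while invalid, remove
    one point and refit, up to ``floor(max_removed_frac * n_total)``
    removals. The point to remove is chosen by one-step lookahead: each
    retained point is tentatively dropped and the candidate whose removal
    gives the smallest maximum back-calculation error on the refitted model
    is kept out (a plain worst-residual rule can latch onto low-concentration
    points whose relative error a gross outlier inflates through the
    intercept). Returns the first valid model (which, being found earliest,
    retains the most points); if none is found within the budget the last
    fit is returned with ``valid=False``.
    """
    conc, resp = _as_points(points)
    pts = np.column_stack([conc, resp])
    n_total = conc.size
    budget = math.floor(max_removed_frac * n_total)
    retained = np.ones(n_total, dtype=bool)
    model = None
    for _ in range(budget + 1):
        model = validate_calibration(fit_calibration(pts, family, weighting, retained),
                                     tolerance)
        if model.valid:
            assert model.n_retained >= n_total - budget
            return model
        if retained.sum() - 1 < n_total - budget:
            break
        if np.unique(conc[retained]).size - 1 < _MIN_POINTS[family]:
            break
        best = None
        for cand in np.flatnonzero(retained):
            trial = retained.copy()
            trial[cand] = False
            m = validate_calibration(fit_calibration(pts, family, weighting, trial),
                                     tolerance)
            score = float(np.max(m.back_calc_errors[trial]))
            if best is None or score < best[0]:
                best = (score, cand)
        logger.info("%s/%s: removing point %d (max residual error after removal %.1f%%)",
                    family, weighting, best[1], 100 * best[0])
        retained = retained.copy()
        retained[best[1]] = False
    return model


def select_calibration(
    points,
    max_removed_frac: float = 0.25,
    tolerance: float = 0.15,
) -> CalibrationModel:
    """Choose the calibration model for a metabolite.

    Each of the four family/weighting combinations is taken through
    :func:`remove_outliers`; among the valid results the highest R^2 wins,
    residual ties broken by the fixed order straight-before-quadratic,
    unweighted-before-weighted. Raises
    :class:`~drugprofiler.errors.NotQuantifiableError` when no combination
    yields a valid model.
    """
    conc, resp = _as_points(points)
    candidates: list[CalibrationModel] = []
    for family, weighting in COMBINATIONS:
        if np.unique(conc).size < _MIN_POINTS[family]:
            logger.info("%s/%s: skipped, too few points", family, weighting)
            continue
        try:
            model = remove_outliers(
                np.column_stack([conc, resp]), family, weighting,
                max_removed_frac=max_removed_frac, tolerance=tolerance,
            )
        except InputError as e:
            logger.info("%s/%s: %s", family, weighting, e)
            continue
        logger.info(
            "%s/%s: valid=%s retained=%d R2=%.6f",
            family, weighting, model.valid, model.n_retained, model.r_squared,
        )
        if model is not None and model.valid:
            candidates.append(model)
    if not candidates:
        raise NotQuantifiableError("no valid calibration model; metabolite not quantifiable")
    # max R^2; Python's max keeps the first (fixed-order) candidate on ties.
    return max(candidates, key=lambda m: m.r_squared)


def quantify_samples(model: CalibrationModel, norm_responses, sample_ids=None,
                     groups=None) -> pd.DataFrame:
    """Quantify sample responses through a valid calibration's inverse model.

    Responses outside the calibrated response range are still quantified but
    flagged ``out_of_range``; non-invertible responses get NaN and
    ``not_invertible``.
    """
    if not model.valid:
        raise InputError("cannot quantify with an invalid calibration model")
    resp = np.asarray(norm_responses, dtype=float)
    cal_resp = model.norm_response[model.retained]
    lo, hi = float(cal_resp.min()), float(cal_resp.max())
    rows = []
    for i, y in enumerate(resp):
        conc = model.inverse(float(y))
        if math.isnan(conc):
            flag = "not_invertible"
        elif not lo <= y <= hi:
            flag = "out_of_range"
        else:
            flag = "ok"
        rows.append(
            dict(
                sample_id=(sample_ids[i] if sample_ids is not None else i),
                group=(groups[i] if groups is not None else ""),
                norm_response=float(y),
                concentration=conc,
                flag=flag,
            )
        )
    return pd.DataFrame(rows)


def treatment_fold_and_test(vehicle, treated):
    """Treated/vehicle fold change with a two-sided Welch t-test.

    Returns ``(fold, t, p)``. With zero variance in both groups the test is
    degenerate: identical means give t=0, p=1; different means give p=0.
    """
    v = np.asarray(vehicle, dtype=float)
    t_ = np.asarray(treated, dtype=float)
    if v.size < 2 or t_.size < 2:
        raise InputError("Welch test needs >= 2 values per group")
    mv, mt = float(v.mean()), float(t_.mean())
    if mv == 0:
        raise InputError("zero vehicle mean: fold change undefined")
    fold = mt / mv
    if v.std(ddof=1) == 0 and t_.std(ddof=1) == 0:
        if mv == mt:
            return fold, 0.0, 1.0
        return fold, math.inf if mt > mv else -math.inf, 0.0
    res = stats.ttest_ind(t_, v, equal_var=False)
    return fold, float(res.statistic), float(res.pvalue)
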