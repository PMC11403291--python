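"""Bliss-independence synergy analysis of two-drug dose-combination matrices.

For two agents with monotherapy inhibition fractions f_a and f_b, Bliss
independence predicts a combined inhibition of

    E(f_a, f_b) = f_a + f_b - f_a * f_b .

The per-well Bliss excess (in percentage points) is 100 * (observed -
expected); the whole-matrix Bliss score ``bs_matrix`` is the mean excess
over all combination wells. Significance comes from a per-well bootstrap
over replicate plates, and a combination is classified synergistic when all
four conditions hold: bs_matrix > 3, bootstrap p < 0.05, positive 95% CI,
and a synergy region covering at least two neighboring concentrations of
each compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import fit_fourpl, fourpl_predict
from .errors import FitError, InputError, NoDoseDependenceError

__all__ = [
    "CombinationMatrix",
    "SynergyResult",
    "bliss_expected",
    "score_matrix",
    "bootstrap_significance",
    "detect_region",
    "classify",
    "analyze",
]


@dataclass
class CombinationMatrix:
    """A replicated dose grid of two agents.

    ``viability`` has shape ``(n_replicates, len(doses_a), len(doses_b))``
    in percent of vehicle; both dose axes are ascending and start at 0 (the
    monotherapy row/column of the other agent; well [0, 0] is vehicle).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d[0] != 0:
                raise InputError(f"{name} must include dose 0 (monotherapy axis)")
            if np.any(np.diff(d) <= 0):
                raise InputError(f"{name} must be strictly ascending")
        if self.viability.ndim != 3 or self.viability.shape[1:] != (
            self.doses_a.size,
            self.doses_b.size,
        ):
            raise InputError(
                f"viability must have shape (n_rep, {self.doses_a.size}, {self.doses_b.size})"
            )
        if np.any(self.viability < 0):
            raise InputError("viability must be non-negative")

    @property
    def n_replicates(self) -> int:
        return int(self.viability.shape[0])

    @property
    def inhibition(self) -> np.ndarray:
        """Fractional inhibition, 1 - viability/100, clamped to [0, 1]."""
        return np.clip(1.0 - self.viability / 100.0, 0.0, 1.0)

    def transposed(self) -> "CombinationMatrix":
        """Swap the two agents (axis transpose)."""
        return CombinationMatrix(
            self.doses_b.copy(), self.doses_a.copy(),
            np.swapaxes(self.viability, 1, 2).copy(),
        )


def bliss_expected(f_a, f_b):
    """Expected inhibition under Bliss independence: f_a + f_b - f_a*f_b."""
    fa = np.asarray(f_a, dtype=float)
    fb = np.asarray(f_b, dtype=float)
    if np.any(fa < 0) or np.any(fa > 1) or np.any(fb < 0) or np.any(fb > 1):
        raise InputError("inhibition fractions must lie in [0, 1]")
    out = fa + fb - fa * fb
    return float(out) if np.isscalar(f_a) and np.isscalar(f_b) else out


def _monotherapy(mean_inh: np.ndarray, matrix: CombinationMatrix, smooth: bool):
    mono_a = mean_inh[:, 0].copy()   # agent A alone (b = 0)
    mono_b = mean_inh[0, :].copy()   # agent B alone (a = 0)
    if smooth:
        for doses, mono in ((matrix.doses_a, mono_a), (matrix.doses_b, mono_b)):
            try:
                fit = fit_fourpl(
                    doses, mono, direction="increasing",
                    top=(0.0, 0.2), bottom=(0.0, 1.0),
                )
                mono[:] = np.clip(fourpl_predict(fit.params, doses), 0.0, 1.0)
            except (NoDoseDependenceError, FitError, InputError):
                pass  # inactive or unfittable agent: keep raw means
    return mono_a, mono_b


def score_matrix(matrix: CombinationMatrix, smooth_monotherapy: bool = False):
    """Per-well Bliss excess and whole-matrix Bliss score.

    Observed inhibition is the replicate mean per well; the expectation for
    combination well (i, j) uses the monotherapy inhibitions at dose_a[i] and
    dose_b[j]. With ``smooth_monotherapy`` the monotherapy rows are replaced
    by fitted 4PL values before the expectation (an approximation of
    whole-matrix preprocessing); the default uses raw means.

    Returns ``(well_scores, bs_matrix)`` where ``well_scores`` has shape
    ``(len(doses_a)-1, len(doses_b)-1)`` in percentage points.
    """
    if matrix.doses_a.size < 2 or matrix.doses_b.size < 2:
        raise InputError("need at least one non-zero dose of each agent")
    mean_inh = matrix.inhibition.mean(axis=0)
    mono_a, mono_b = _monotherapy(mean_inh, matrix, smooth_monotherapy)
    expected = bliss_expected(mono_a[1:, None], mono_b[None, 1:])
    well_scores = 100.0 * (mean_inh[1:, 1:] - expected)
    return well_scores, float(well_scores.mean())


def bootstrap_significance(
    matrix: CombinationMatrix,
    n_boot: int = 2000,
    seed: int = 0,
    smooth_monotherapy: bool = False,
):
    """Bootstrap p-value and 95% CI for the whole-matrix Bliss score.

    Replicates are resampled with replacement independently per well,
    ``bs_matrix`` recomputed for each of ``n_boot`` resamples; the CI is the
    2.5/97.5 percentile band, and the two-sided p-value is the (+1-corrected)
    fraction of bootstrap scores on the opposite side of 0 from the observed
    score. An observed score of exactly 0 gives p = 1 (degenerate case).

    With ``smooth_monotherapy`` the 4PL-smoothed monotherapy reference is
    fitted once on the original data and held fixed during resampling (its
    residual uncertainty is small once the fit pools all monotherapy doses),
    so only the combination wells are resampled.
    """
    n_rep = matrix.n_replicates
    if n_rep < 2:
        raise InputError("bootstrap requires replicates")
    _, obs = score_matrix(matrix, smooth_monotherapy)
    na, nb = matrix.doses_a.size, matrix.doses_b.size
    inh = matrix.inhibition  # (n_rep, na, nb)
    # Each well gets its own resampling stream, keyed by the unordered dose
    # pair so that swapping the two agents (matrix transposition) reuses
    # exactly the same draws and the p-value is transpose-invariant.
    boot_mean = np.empty((n_boot, na, nb))
    for i in range(na):
        for j in range(nb):
            key = _well_key(float(matrix.doses_a[i]), float(matrix.doses_b[j]))
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), key]))
            idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
            boot_mean[:, i, j] = inh[idx, i, j].mean(axis=1)
    if smooth_monotherapy:
        ma, mb = _monotherapy(inh.mean(axis=0), matrix, smooth=True)
        expected = bliss_expected(ma[1:, None], mb[None, 1:])
        scores = 100.0 * (boot_mean[:, 1:, 1:] - expected[None, :, :]).mean(axis=(1, 2))
    else:
        ma = boot_mean[:, :, 0]
        mb = boot_mean[:, 0, :]
        expected = ma[:, 1:, None] + mb[:, None, 1:] - ma[:, 1:, None] * mb[:, None, 1:]
        scores = 100.0 * (boot_mean[:, 1:, 1:] - expected).mean(axis=(1, 2))
    ci = (float(np.percentile(scores, 2.5)), float(np.percentile(scores, 97.5)))
    if abs(obs) < 1e-9:  # degenerate (noiseless Bliss-consistent) surface
        p = 1.0
    else:
        opposite = int(np.sum(np.sign(obs) * scores <= 0))
        p = min(1.0, 2.0 * (opposite + 1) / (n_boot + 1))
    return float(p), ci


def _well_key(dose_a: float, dose_b: float) -> int:
    """Deterministic stream key from the unordered (dose_a, dose_b) pair."""
    lo, hi = sorted((round(dose_a, 12), round(dose_b, 12)))
    return abs(hash((lo, hi))) % (2**31)


def detect_region(well_scores: np.ndarray, min_span: int = 2):
    """Find a synergy region: a ``min_span`` x ``min_span`` window of adjacent
    doses in which every well score is positive.

    Returns ``(found, coords)`` where ``coords`` is the ``(row, col)`` origin
    of the best window (maximal mean score), or None.
    """
    ws = np.asarray(well_scores, dtype=float)
    if ws.ndim != 2 or min(ws.shape) < min_span:
        raise InputError(f"well_scores must be at least {min_span}x{min_span}")
    best = None
    for i in range(ws.shape[0] - min_span + 1):
        for j in range(ws.shape[1] - min_span + 1):
            block = ws[i : i + min_span, j : j + min_span]
            if np.all(block > 0):
                m = float(block.mean())
                if best is None or m > best[0]:
                    best = (m, (i, j))
    if best is None:
        return False, None
    return True, best[1]


@dataclass
class SynergyResult:
    """Full synergy analysis of one combination matrix."""

    well_scores: np.ndarray = field(repr=False)
    bs_matrix: float
    p_value: float
    ci95: tuple[float, float]
    region_found: bool
    region_coords: tuple[int, int] | None
    significant: bool = False


def classify(result: SynergyResult, bs_threshold: float = 3.0, alpha: float = 0.05) -> bool:
    """Significance classification: bs_matrix > threshold, p < alpha,
    positive 95% CI, and an adjacent-dose synergy region present."""
    return bool(
        result.bs_matrix > bs_threshold
        and result.p_value < alpha
        and result.ci95[0] > 0
        and result.region_found
    )


def analyze(
    matrix: CombinationMatrix,
    n_boot: int = 2000,
    seed: int = 0,
    smooth_monotherapy: bool = False,
    bs_threshold: float = 3.0,
    alpha: float = 0.05,
    min_span: int = 2,
) -> SynergyResult:
    """Score, bootstrap, region-detect and classify one combination matrix."""
    well_scores, bs = score_matrix(matrix, smooth_monotherapy)
    p, ci = bootstrap_significance(matrix, n_boot=n_boot, seed=seed,
                                   smooth_monotherapy=smooth_monotherapy)
    found, coords = detect_region(well_scores, min_span=min_span)
    result = SynergyResult(
        well_scores=well_scores, bs_matrix=bs, p_value=p, ci95=ci,
        region_found=found, region_coords=coords,
    )
    result.significant = classify(result, bs_threshold=bs_threshold, alpha=alpha)
    return result
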