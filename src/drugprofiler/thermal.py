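"""Thermal-stability analytics: 2D-TPP hit calling, ITDR fitting, DSF melting points.

Three readouts of ligand-induced thermal stabilization:

* **2D-TPP** — per protein, the soluble fraction after heating to each
  temperature of an experimental ladder, at several compound concentrations,
  expressed as fold change vs vehicle at the same temperature. A protein is
  called stabilized when some concentration shows a fold change >= 2.0 at one
  temperature together with >= 1.8 at a ladder-adjacent temperature.
* **ITDR** — isothermal dose-response: stabilization vs concentration at one
  elevated temperature; independent datasets are min-max normalized to [0, 1]
  and pooled into a single increasing 4PL fit with fixed asymptotes, yielding
  one pEC50.
* **DSF** — melting point of a purified protein read as the temperature of
  the maximum of the smoothed first derivative of the 330/350 nm
  fluorescence ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .dose_response import DoseSeries, FourPLFit, fit_fourpl
from .errors import FitError, InputError, NoDoseDependenceError

__all__ = [
    "StabilizationCall",
    "ITDRDataset",
    "DSFTrace",
    "TPP_TEMPERATURE_LADDER",
    "call_stabilized",
    "itdr_fit",
    "dsf_tm",
]

logger = logging.getLogger(__name__)

#: The 12-temperature ladder of the 2D-TPP design (°C).
TPP_TEMPERATURE_LADDER = (
    42.1, 44.1, 46.2, 48.1, 50.4, 51.9, 54.0, 56.1, 58.2, 60.1, 62.4, 63.9,
)

TPP_COLUMNS = ["protein_id", "temperature_c", "concentration_um", "fold_change"]


@dataclass
class StabilizationCall:
    """Outcome of the adjacent-temperature stabilization rule for one protein."""

    protein_id: str
    is_hit: bool
    callable: bool = True
    best_temperature: float | None = None
    best_fold: float | None = None
    best_concentration: float | None = None
    supporting_adjacent_temperature: float | None = None
    supporting_fold: float | None = None
    max_fold: float | None = None


def _validate_tpp_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TPP_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"2D-TPP table missing columns: {missing}")
    if (table["fold_change"] <= 0).any():
        raise InputError("fold_change values must be positive")
    return table


def call_stabilized(
    table: pd.DataFrame,
    primary_threshold: float = 2.0,
    adjacent_threshold: float = 1.8,
    *,
    same_concentration: bool = True,
) -> list[StabilizationCall]:
    """Apply the adjacent-temperature stabilization rule to a 2D-TPP table.

    A protein is a hit iff at some concentration there is a temperature with
    fold change >= ``primary_threshold`` and a ladder-adjacent temperature
    with fold change >= ``adjacent_threshold``. Adjacency is defined on the
    sorted ladder of temperatures present for that protein, not on absolute
    °C spacing. With ``same_concentration=False`` the supporting fold may
    come from any concentration.

    Proteins observed at a single temperature are not callable and are
    flagged (``callable=False``).
    """
    table = _validate_tpp_table(table)
    calls: list[StabilizationCall] = []
    for protein_id, sub in table.groupby("protein_id", sort=False):
        ladder = np.sort(sub["temperature_c"].unique())
        max_fold = float(sub["fold_change"].max())
        if ladder.size < 2:
            logger.info("%s: single temperature, not callable", protein_id)
            calls.append(StabilizationCall(str(protein_id), is_hit=False, callable=False,
                                           max_fold=max_fold))
            continue
        grid = sub.pivot_table(
            index="temperature_c", columns="concentration_um",
            values="fold_change", aggfunc="mean",
        ).reindex(ladder)
        best = None
        for conc in grid.columns:
            col = grid[conc].to_numpy()
            support = grid.max(axis=1).to_numpy() if not same_concentration else col
            for i, f in enumerate(col):
                if not np.isfinite(f) or f < primary_threshold:
                    continue
                for j in (i - 1, i + 1):
                    if 0 <= j < ladder.size and np.isfinite(support[j]) \
                            and support[j] >= adjacent_threshold:
                        cand = (f, ladder[i], conc, ladder[j], support[j])
                        if best is None or cand[0] > best[0]:
                            best = cand
        if best is None:
            calls.append(StabilizationCall(str(protein_id), is_hit=False, max_fold=max_fold))
        else:
            f, t, conc, t_adj, f_adj = best
            calls.append(
                StabilizationCall(
                    str(protein_id), is_hit=True,
                    best_temperature=float(t), best_fold=float(f),
                    best_concentration=float(conc),
                    supporting_adjacent_temperature=float(t_adj),
                    supporting_fold=float(f_adj),
                    max_fold=max_fold,
                )
            )
    return calls


@dataclass
class ITDRDataset:
    """One isothermal dose-response dataset (fixed elevated temperature)."""

    dataset_id: str
    dose_series: DoseSeries
    responses: np.ndarray
    normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.size != self.dose_series.n_points:
            raise InputError(
                f"{self.dataset_id}: expected {self.dose_series.n_points} responses"
            )

    def normalize(self, flat_epsilon: float = 1e-9) -> np.ndarray:
        """Min-max map the raw responses onto [0, 1]."""
        lo, hi = self.responses.min(), self.responses.max()
        if hi - lo < flat_epsilon:
            raise NoDoseDependenceError(f"{self.dataset_id}: flat ITDR dataset")
        self.normalized = (self.responses - lo) / (hi - lo)
        return self.normalized


def itdr_fit(datasets: list[ITDRDataset], *, flat_rel_epsilon: float = 0.1) -> FourPLFit:
    """Combined ITDR fit: normalize each dataset to [0, 1], pool, fit one pEC50.

    Datasets whose raw response range is below ``flat_rel_epsilon`` of their
    mean level are excluded with a warning; if all are flat the fit errors.
    The pooled fit is an increasing 4PL with the zero-dose asymptote fixed at
    0 and the plateau fixed at 1.
    """
    if not datasets:
        raise InputError("no ITDR datasets provided")
    concs, resps = [], []
    for ds in datasets:
        level = max(abs(float(np.mean(ds.responses))), 1e-12)
        if (ds.responses.max() - ds.responses.min()) / level < flat_rel_epsilon:
            logger.warning("%s: flat ITDR dataset excluded", ds.dataset_id)
            continue
        ds.normalize()
        concs.append(ds.dose_series.concentrations)
        resps.append(ds.normalized)
    if not concs:
        raise FitError("all ITDR datasets are flat; no combined fit possible")
    conc = np.concatenate(concs)
    resp = np.concatenate(resps)
    # The asymptotes are anchored near 0 and 1 but left a little slack: a
    # finite dilution series never quite reaches either plateau, so min-max
    # normalized values slightly overshoot the true asymptotes and clamping
    # them exactly would bias the pEC50 at the edges of the series.
    return fit_fourpl(conc, resp, direction="increasing",
                      top=(-0.2, 0.2), bottom=(0.8, 1.2))


@dataclass
class DSFTrace:
    """A nanoDSF thermal ramp: 330/350 nm fluorescence ratio vs temperature."""

    temperatures: np.ndarray
    ratio: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperatures.size != self.ratio.size:
            raise InputError("temperature and ratio arrays differ in length")
        if self.temperatures.size < 10:
            raise InputError("DSF trace needs at least 10 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise InputError("temperatures must be strictly increasing")


def dsf_tm(trace: DSFTrace, *, window: int = 5) -> float:
    """Melting point: temperature of the maximum of d(ratio)/dT.

    The derivative is taken with a local-quadratic (Savitzky-Golay) smoother
    over ``window`` points, which suppresses the noise amplification of raw
    finite differences. The maximum must be interior to the ramp; a boundary
    maximum means no transition was captured.
    """
    if window < 3 or window % 2 == 0:
        raise InputError("window must be an odd integer >= 3")
    dt = np.diff(trace.temperatures)
    deriv = savgol_filter(trace.ratio, window, polyorder=2, deriv=1, delta=float(dt.mean()))
    i = int(np.argmax(deriv))
    # A real transition has an interior peak that stands above the ramp ends;
    # a flat/linear trace only produces floating-point ties.
    tol = 1e-9 * max(1.0, float(np.max(np.abs(deriv))))
    if i == 0 or i == deriv.size - 1 or deriv[i] - max(deriv[0], deriv[-1]) <= tol:
        raise FitError("derivative maximum at grid boundary: no interior transition")
    return float(trace.temperatures[i])
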