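"""Seeded generators for every input class, with known ground truth.

Each generator emulates one experimental design of the study:

* competition-binding dose-response (six-point series, 30 μmol/L start,
  7-fold dilution, triplicates, paired depletion channels),
* 2D-TPP fold-change tables on the 12-temperature ladder with four compound
  concentrations,
* ITDR stabilization curves (seven points, 30 μmol/L start, 8-fold dilution),
* nanoDSF 330/350 nm ratio thermal ramps,
* steroid calibration series with internal standards, proportional noise
  and injectable gross outliers, plus vehicle/treated sample responses,
* two-drug combination viability matrices with a Bliss-excess term.

Noise models: multiplicative lognormal for MS abundances and metabolite
responses (positive signals, CV-scaled), additive Gaussian in percentage
points for viability. Every generator draws from child streams of a single
root seed, so identical specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import CompetitionExperiment
from .dose_response import (
    DoseSeries,
    FourPLParams,
    fourpl_predict,
    make_dilution_series,
)
from .synergy import CombinationMatrix
from .thermal import TPP_COLUMNS, TPP_TEMPERATURE_LADDER, DSFTrace, ITDRDataset

__all__ = [
    "CompetitionSpec",
    "TPPProteinSpec",
    "TPPSpec",
    "ITDRSpec",
    "DSFSpec",
    "CalibrationSpec",
    "CombinationSpec",
    "simulate_competition",
    "simulate_2dtpp",
    "tpp_table_from_folds",
    "simulate_itdr",
    "simulate_dsf",
    "simulate_calibration_and_samples",
    "simulate_combination",
]

#: Default compound concentrations of the 2D-TPP design (μmol/L).
TPP_CONCENTRATIONS = (0.12245, 0.85714, 6.0, 30.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size))


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class CompetitionSpec:
    """Ground truth for a simulated competition-binding experiment."""

    true_pkd_app: float = 8.5
    depletion_ratio: float = 1.0
    start_conc: float = 30.0
    dilution_factor: float = 7.0
    n_points: int = 6
    n_replicates: int = 3
    noise_cv: float = 0.0
    hill: float = 1.0
    bottom: float = 0.0
    protein_id: str = "PARP1"
    seed: int = 0


def simulate_competition(spec: CompetitionSpec) -> list[CompetitionExperiment]:
    """Decreasing 4PL competition curves with paired depletion channels.

    The observable IC50 reflects the bead-depleted equilibrium, so the
    generated pIC50 is ``true_pkd_app + log10(r)``; the depletion-corrected
    pipeline recovers ``true_pkd_app``.
    """
    series = make_dilution_series(spec.start_conc, spec.dilution_factor, spec.n_points)
    pic50 = spec.true_pkd_app + np.log10(spec.depletion_ratio)
    params = FourPLParams(top=1.0, bottom=spec.bottom, pec50=pic50, hill=spec.hill)
    clean = fourpl_predict(params, series.concentrations)
    out = []
    for rep, rng in enumerate(_streams(spec.seed, spec.n_replicates), start=1):
        abund = clean * _lognormal_factor(rng, spec.noise_cv, clean.size)
        first = 100.0 * _lognormal_factor(rng, spec.noise_cv, 1)[0]
        second = first * spec.depletion_ratio
        out.append(
            CompetitionExperiment(
                protein_id=spec.protein_id, dose_series=series,
                rel_abundance=abund, depletion_first=first,
                depletion_second=second, replicate_id=rep,
            )
        )
    return out


@dataclass
class TPPProteinSpec:
    """Melting behaviour of one protein in a 2D-TPP simulation.

    ``dtm_max`` is the maximal thermal shift (°C) at saturating compound;
    ``pec50_um`` the stabilization midpoint in μmol/L. ``dtm_max = 0`` gives
    a non-hit.
    """

    protein_id: str
    tm_c: float = 50.0
    slope_c: float = 1.5
    dtm_max: float = 0.0
    ec50_um: float = 1.0
    hill: float = 1.0


@dataclass
class TPPSpec:
    proteins: list[TPPProteinSpec] = field(default_factory=list)
    temperatures: tuple = TPP_TEMPERATURE_LADDER
    concentrations: tuple = TPP_CONCENTRATIONS
    noise_cv: float = 0.0
    seed: int = 0


def _melt_survival(temp, tm, slope):
    return 1.0 / (1.0 + np.exp((np.asarray(temp) - tm) / slope))


def simulate_2dtpp(spec: TPPSpec) -> pd.DataFrame:
    """Fold-change table from shifted logistic melting curves.

    The treated melting curve is the vehicle curve shifted by
    ``dtm_max * c^h / (c^h + ec50^h)``; the reported fold change at each
    (temperature, concentration) is treated/vehicle soluble fraction.
    """
    rows = []
    rngs = _streams(spec.seed, max(len(spec.proteins), 1))
    for prot, rng in zip(spec.proteins, rngs):
        temps = np.asarray(spec.temperatures, dtype=float)
        vehicle = _melt_survival(temps, prot.tm_c, prot.slope_c)
        for conc in spec.concentrations:
            occ = conc**prot.hill / (conc**prot.hill + prot.ec50_um**prot.hill)
            treated = _melt_survival(temps, prot.tm_c + prot.dtm_max * occ, prot.slope_c)
            fold = treated / vehicle
            fold = fold * _lognormal_factor(rng, spec.noise_cv, fold.size)
            for t, f in zip(temps, fold):
                rows.append((prot.protein_id, float(t), float(conc), float(f)))
    return pd.DataFrame(rows, columns=TPP_COLUMNS)


def tpp_table_from_folds(patterns: dict, concentration_um: float = 30.0) -> pd.DataFrame:
    """Build a 2D-TPP table from explicit per-protein fold patterns.

    ``patterns`` maps protein_id -> {temperature_c: fold_change} (one
    concentration) or -> {(temperature_c, concentration_um): fold_change}.
    Useful for programmed hit/near-miss fixtures.
    """
    rows = []
    for protein_id, folds in patterns.items():
        for key, fold in folds.items():
            if isinstance(key, tuple):
                t, c = key
            else:
                t, c = key, concentration_um
            rows.append((protein_id, float(t), float(c), float(fold)))
    return pd.DataFrame(rows, columns=TPP_COLUMNS)


@dataclass
class ITDRSpec:
    """Ground truth for simulated isothermal dose-response datasets."""

    true_pec50: float = 7.7
    start_conc: float = 30.0
    dilution_factor: float = 8.0
    n_points: int = 7
    n_datasets: int = 2
    noise_cv: float = 0.0
    hill: float = 1.0
    #: per-dataset affine transforms of the raw response (scale, offset)
    scales: tuple = ()
    offsets: tuple = ()
    dataset_prefix: str = "itdr"
    seed: int = 0


def simulate_itdr(spec: ITDRSpec) -> list[ITDRDataset]:
    """Increasing stabilization curves with per-dataset affine raw scales."""
    series = make_dilution_series(spec.start_conc, spec.dilution_factor, spec.n_points)
    params = FourPLParams(top=0.0, bottom=1.0, pec50=spec.true_pec50, hill=spec.hill)
    clean = fourpl_predict(params, series.concentrations)
    datasets = []
    for k, rng in enumerate(_streams(spec.seed, spec.n_datasets)):
        scale = spec.scales[k] if k < len(spec.scales) else 1.0
        offset = spec.offsets[k] if k < len(spec.offsets) else 0.0
        resp = (clean * _lognormal_factor(rng, spec.noise_cv, clean.size)) * scale + offset
        datasets.append(
            ITDRDataset(
                dataset_id=f"{spec.dataset_prefix}_{k + 1}",
                dose_series=DoseSeries(series.start_conc, series.dilution_factor,
                                       series.n_points),
                responses=resp,
            )
        )
    return datasets


@dataclass
class DSFSpec:
    """Ground truth for a simulated nanoDSF ratio trace."""

    true_tm_c: float = 55.0
    slope_c: float = 1.5
    t_min_c: float = 40.0
    t_max_c: float = 70.0
    grid_step_c: float = 0.2
    baseline: float = 0.8
    amplitude: float = 0.2
    noise_sd_frac: float = 0.0
    seed: int = 0


def simulate_dsf(spec: DSFSpec) -> DSFTrace:
    """Rising logistic 330/350 ratio with inflection at ``true_tm_c``."""
    temps = np.arange(spec.t_min_c, spec.t_max_c + spec.grid_step_c / 2, spec.grid_step_c)
    ratio = spec.baseline + spec.amplitude / (
        1.0 + np.exp(-(temps - spec.true_tm_c) / spec.slope_c)
    )
    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        ratio = ratio + rng.normal(0.0, spec.noise_sd_frac * spec.amplitude, ratio.size)
    return DSFTrace(temperatures=temps, ratio=ratio)


@dataclass
class CalibrationSpec:
    """Ground truth for a steroid calibration series plus study samples."""

    metabolite: str = "24,25-epoxycholesterol"
    #: polynomial coefficients, descending powers; (a, b) straight, (a, b, c) quadratic
    true_coefficients: tuple = (1.0, 0.0)
    conc_levels: tuple = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
    is_level: float = 500.0
    noise_cv: float = 0.0
    n_outliers: int = 0
    outlier_factor: float = 3.0
    vehicle_conc: float = 4.0
    true_fold: float = 6.5
    n_vehicle: int = 3
    n_treated: int = 3
    sample_noise_cv: float | None = None  # defaults to noise_cv
    seed: int = 0


def simulate_calibration_and_samples(spec: CalibrationSpec):
    """Calibration and sample tables for the steroid-quantification pipeline.

    Returns ``(calibration_df, samples_df)`` in the long TSV layouts the
    pipeline reads. Gross outliers multiply the analyte response of
    ``n_outliers`` randomly chosen calibration points by ``outlier_factor``.
    """
    rng_cal, rng_out, rng_samp = _streams(spec.seed, 3)
    conc = np.asarray(spec.conc_levels, dtype=float)
    clean = np.polyval(spec.true_coefficients, conc)
    is_resp = spec.is_level * _lognormal_factor(rng_cal, spec.noise_cv, conc.size)
    analyte = clean * is_resp * _lognormal_factor(rng_cal, spec.noise_cv, conc.size)
    if spec.n_outliers > 0:
        idx = rng_out.choice(conc.size, size=spec.n_outliers, replace=False)
        analyte[idx] *= spec.outlier_factor
    cal = pd.DataFrame(
        dict(metabolite=spec.metabolite, nominal_conc=conc,
             analyte_response=analyte, is_response=is_resp)
    )

    cv = spec.noise_cv if spec.sample_noise_cv is None else spec.sample_noise_cv
    rows = []
    for group, n, true_conc in (
        ("vehicle", spec.n_vehicle, spec.vehicle_conc),
        ("treatment", spec.n_treated, spec.vehicle_conc * spec.true_fold),
    ):
        y = np.polyval(spec.true_coefficients, true_conc)
        is_s = spec.is_level * _lognormal_factor(rng_samp, cv, n)
        an_s = y * is_s * _lognormal_factor(rng_samp, cv, n)
        for k in range(n):
            rows.append(
                dict(metabolite=spec.metabolite, sample_id=f"{group}_{k + 1}",
                     group=group, analyte_response=float(an_s[k]),
                     is_response=float(is_s[k]))
            )
    return cal, pd.DataFrame(rows)


@dataclass
class CombinationSpec:
    """Ground truth for a replicated two-drug combination matrix.

    Monotherapy inhibition follows an increasing 4PL (Hill) curve per agent;
    combination wells are the Bliss expectation plus ``excess_pp`` percentage
    points in the block ``excess_rows`` x ``excess_cols`` (indices into the
    positive-dose grid), plus additive Gaussian noise in percentage points.
    """

    start_a: float = 30.0
    start_b: float = 5.0
    dilution_factor: float = 3.0
    n_doses: int = 6
    # EC50s sit near the middle of each dilution series and maximal
    # inhibition is partial (0.7), so the grid spans ~4-65% inhibition and a
    # programmed +15 pp Bliss excess never saturates a well.
    pec50_a: float = 5.7   # molar scale; EC50 2.0 μmol/L
    pec50_b: float = 6.48  # EC50 0.33 μmol/L
    hill_a: float = 1.0
    hill_b: float = 1.0
    emax_a: float = 0.7
    emax_b: float = 0.7
    excess_pp: float = 0.0
    excess_rows: tuple = (2, 3, 4)
    excess_cols: tuple = (2, 3, 4)
    noise_sd_pp: float = 0.0
    n_replicates: int = 3
    seed: int = 0


def _mono_inhibition(doses, pec50, hill, emax):
    params = FourPLParams(top=0.0, bottom=emax, pec50=pec50, hill=hill)
    return fourpl_predict(params, doses)


def simulate_combination(spec: CombinationSpec) -> CombinationMatrix:
    """Replicated viability matrix with a programmed Bliss-excess block."""
    pos_a = np.sort(spec.start_a / spec.dilution_factor ** np.arange(spec.n_doses))
    pos_b = np.sort(spec.start_b / spec.dilution_factor ** np.arange(spec.n_doses))
    doses_a = np.concatenate([[0.0], pos_a])
    doses_b = np.concatenate([[0.0], pos_b])
    fa = _mono_inhibition(doses_a, spec.pec50_a, spec.hill_a, spec.emax_a)
    fb = _mono_inhibition(doses_b, spec.pec50_b, spec.hill_b, spec.emax_b)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    excess = np.zeros_like(expected)
    for i in spec.excess_rows:
        for j in spec.excess_cols:
            excess[i + 1, j + 1] = spec.excess_pp / 100.0
    true_inh = np.clip(expected + excess, 0.0, 1.0)
    (rng,) = _streams(spec.seed, 1)
    inh = true_inh[None, :, :] + rng.normal(
        0.0, spec.noise_sd_pp / 100.0, size=(spec.n_replicates,) + true_inh.shape
    )
    viability = np.clip(100.0 * (1.0 - inh), 0.0, None)
    return CombinationMatrix(doses_a=doses_a, doses_b=doses_b, viability=viability)
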