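"""Competition-binding affinity estimation with bead-depletion correction.

Affinity-enrichment chemoproteomics measures, per protein, the relative
abundance captured on an immobilized-ligand bead matrix while a free
compound competes over a dilution series. The fitted IC50 overstates the
true dissociation constant when the beads themselves deplete the target
from the lysate, so the apparent Kd is corrected by the depletion ratio r —
the fraction of target still available after one bead incubation, estimated
from two consecutive pulldowns:

    r       = capture_second / capture_first        (clamped to [0, 1])
    Kd_app  = IC50 * r    <=>    pKd_app = pIC50 - log10(r)

Replicate pKd_app values are averaged on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseSeries, fit_fourpl, pec50_from_conc_um
from .errors import InputError, NoDoseDependenceError

__all__ = [
    "CompetitionExperiment",
    "depletion_ratio",
    "correct_pic50_to_pkd",
    "selectivity_fold",
    "profile_compound",
]

logger = logging.getLogger(__name__)


@dataclass
class CompetitionExperiment:
    """One replicate of a per-protein competition dose-response.

    ``rel_abundance`` is the captured abundance at each series concentration
    as a fraction of the vehicle channel (vehicle = 1). ``depletion_first``
    and ``depletion_second`` are the paired consecutive-capture channels used
    to estimate the depletion ratio.
    """

    protein_id: str
    dose_series: DoseSeries
    rel_abundance: np.ndarray
    depletion_first: float
    depletion_second: float
    replicate_id: int = 1

    def __post_init__(self):
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if self.rel_abundance.size != self.dose_series.n_points:
            raise InputError(
                f"{self.protein_id}: expected {self.dose_series.n_points} abundances, "
                f"got {self.rel_abundance.size}"
            )
        if np.any(self.rel_abundance < 0):
            raise InputError(f"{self.protein_id}: negative relative abundance")
        if not self.depletion_first > 0:
            raise InputError(f"{self.protein_id}: depletion_first must be positive")


def depletion_ratio(first_capture: float, second_capture: float) -> float:
    """Fraction of target remaining after one bead incubation."""
    if not first_capture > 0:
        raise InputError("first_capture must be positive")
    if second_capture < 0:
        raise InputError("second_capture must be non-negative")
    return float(np.clip(second_capture / first_capture, 0.0, 1.0))


def correct_pic50_to_pkd(pic50: float, r: float) -> float:
    """Depletion-correct a competition pIC50 into an apparent pKd.

    Kd_app = IC50 * r, so on the log scale pkd_app = pic50 - log10(r).
    At r = 1 (no depletion) the pIC50 is returned unchanged; a fully depleted
    target (r = 0) has no defined correction.
    """
    if r == 0:
        raise InputError("target fully depleted; correction undefined")
    if not 0 < r <= 1:
        raise InputError(f"depletion ratio must be in (0, 1], got {r}")
    return float(pic50 - np.log10(r))


def selectivity_fold(pkd_a: float, pkd_b: float) -> float:
    """Fold selectivity between two log-scale affinities: 10**(a - b)."""
    if not (np.isfinite(pkd_a) and np.isfinite(pkd_b)):
        raise InputError("affinities must be finite")
    return float(10.0 ** (pkd_a - pkd_b))


def profile_compound(
    experiments: list[CompetitionExperiment],
    *,
    top=1.0,
    bottom=(0.0, 0.5),
    flat_epsilon: float = 0.1,
) -> pd.DataFrame:
    """Fit every replicate's competition curve and report mean pKd_app per protein.

    Per replicate: decreasing 4PL fit of relative abundance vs concentration
    (vehicle-normalized, so the zero-dose asymptote is constrained to 1 by
    default), pIC50 extracted on the molar scale, corrected by that
    replicate's depletion ratio. Replicate pKd_app values are averaged on the
    log scale.

    Returns one row per protein with columns
    ``protein_id, pic50, r, pkd_app_mean, n, flag``. Proteins whose curves are
    all flat are flagged ``not_competed`` (NaN estimates); a fitted IC50
    outside the measured series is flagged ``censored`` with the boundary
    p-value it exceeds.
    """
    if not experiments:
        raise InputError("no experiments provided")
    rows = []
    by_protein: dict[str, list[CompetitionExperiment]] = {}
    for exp in experiments:
        by_protein.setdefault(exp.protein_id, []).append(exp)

    for protein_id, reps in by_protein.items():
        pkds, pics, rs = [], [], []
        flag = "ok"
        for exp in reps:
            conc = exp.dose_series.concentrations
            try:
                fit = fit_fourpl(
                    conc,
                    exp.rel_abundance,
                    direction="decreasing",
                    top=top,
                    bottom=bottom,
                    flat_epsilon=flat_epsilon,
                )
            except NoDoseDependenceError:
                logger.info("%s replicate %s: flat curve, skipped", protein_id, exp.replicate_id)
                continue
            r = depletion_ratio(exp.depletion_first, exp.depletion_second)
            if r == 0:
                logger.warning("%s: fully depleted, cannot correct", protein_id)
                continue
            pic50 = fit.pec50
            pics.append(pic50)
            rs.append(r)
            pkds.append(correct_pic50_to_pkd(pic50, r))
            # Censoring: an IC50 at or beyond the series boundary is not
            # quantifiable within the measured range.
            if pic50 <= pec50_from_conc_um(conc.max()):
                flag = f"censored: pKd_app > {pec50_from_conc_um(conc.max()):.2f}"
            elif pic50 >= pec50_from_conc_um(conc.min()):
                flag = f"censored: pKd_app < {pec50_from_conc_um(conc.min()):.2f}"
        if not pkds:
            logger.info("%s: not competed (all replicates flat)", protein_id)
            rows.append(
                dict(protein_id=protein_id, pic50=np.nan, r=np.nan,
                     pkd_app_mean=np.nan, n=0, flag="not_competed")
            )
            continue
        rows.append(
            dict(
                protein_id=protein_id,
                pic50=float(np.mean(pics)),
                r=float(np.mean(rs)),
                pkd_app_mean=float(np.mean(pkds)),
                n=len(pkds),
                flag=flag,
            )
        )
    return pd.DataFrame(rows, columns=["protein_id", "pic50", "r", "pkd_app_mean", "n", "flag"])
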