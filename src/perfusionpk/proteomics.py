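"""Isotope-dilution targeted proteomics: calibration, quantification, LOQ.

Absolute transporter-protein quantification by MRM works from exported
light/heavy peptide area ratios: a fixed amount of stable-isotope-labeled
peptide is spiked into every digest, calibration standards with known light
peptide amounts define a response line of area ratio on amount, and each
sample's back-calculated on-column amount divided by the digested protein
mass gives a concentration in fmol per ug protein.

The limit of quantification (LOQ) is defined operationally: the lowest
calibration standard whose back-calculated amount falls within +/-20 % of its
nominal value.  Back-calculated amounts below the LOQ are reported as the
token ``<LOQ`` rather than a number.

Peak integration and transition selection are upstream of this module; the
inputs are exported area ratios.  Some peptides do not distinguish species
orthologs (e.g. a shared human/rat sequence); a per-peptide
``species_specificity`` attribute is carried through into reports so that
caveat survives into the output table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SchemaError, ValidationError

logger = logging.getLogger("perfusionpk")

LOQ_TOKEN = "<LOQ"
#: back-calculation accuracy band defining an acceptable standard
LOQ_ACCURACY = 0.20


class CurveRejectedError(ValidationError):
    """The calibration fit is unusable (e.g. non-positive slope)."""


@dataclass(frozen=True)
class CalibrationStandard:
    known_amount: float  # fmol on column
    area_ratio: float  # light/heavy, unitless

    def __post_init__(self) -> None:
        if self.known_amount < 0 or self.area_ratio < 0:
            raise ValidationError("known_amount and area_ratio must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    loq_fmol: float  # lowest acceptable quantifiable amount
    weighting: str = "1/x"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CurveRejectedError("accepted curve requires slope > 0")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")

    def back_calculate(self, area_ratio: float) -> float:
        """On-column amount (fmol) implied by an area ratio."""
        return (area_ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class ProteinQuantResult:
    """Absolute concentration for one protein in one sample, or below-LOQ."""

    protein: str
    sample_id: str
    concentration: float | None  # fmol ug^-1 protein
    below_loq: bool = False
    species_specificity: str = ""

    def __post_init__(self) -> None:
        if (self.concentration is None) == (not self.below_loq):
            raise ValidationError("concentration present xor below_LOQ status")

    def render(self) -> str:
        if self.below_loq:
            return LOQ_TOKEN
        return "%.12g" % self.concentration


def fit_calibration(
    standards: Sequence[CalibrationStandard], weighting: str = "1/x"
) -> CalibrationCurve:
    """Weighted least-squares line of area ratio on known amount.

    ``weighting`` is ``"none"`` (ordinary least squares) or ``"1/x"`` (the
    usual choice for wide-range isotope-dilution curves; equalizes relative
    error across the range).  Requires at least three distinct non-zero
    standards.  The LOQ is set at the lowest standard back-calculating within
    +/-20 % of nominal; if no standard passes, the LOQ is +inf and every
    sample will report below-LOQ.
    """
    if weighting not in ("none", "1/x"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    pts = [s for s in standards if s.known_amount > 0]
    dropped = len(list(standards)) - len(pts)
    if dropped:
        logger.warning("dropped %d zero-amount standard(s) from the fit", dropped)
    x = np.array([s.known_amount for s in pts], dtype=float)
    y = np.array([s.area_ratio for s in pts], dtype=float)
    if np.unique(x).size < 3:
        raise ValidationError("need >= 3 distinct non-zero standards")

    w = np.ones_like(x) if weighting == "none" else 1.0 / x
    # weighted normal equations for y = a + b x
    sw = w.sum()
    sx, sy = (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy * sxx - sx * sxy) / denom
    if not slope > 0:
        raise CurveRejectedError(
            f"calibration rejected: non-positive slope {slope:.6g} "
            f"(response must increase with amount)"
        )

    resid = y - (intercept + slope * x)
    ss_res = float((w * resid**2).sum())
    ss_tot = float((w * (y - sy / sw) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)

    loq = math.inf
    for amount in np.unique(x):
        ratio = float(y[x == amount].mean())
        back = (ratio - intercept) / slope
        if abs(back - amount) <= LOQ_ACCURACY * amount:
            loq = float(amount)
            break
    if math.isinf(loq):
        logger.warning("no standard back-calculates within +/-20%%; LOQ set to +inf")

    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r_squared, 1.0)),
        loq_fmol=loq,
        weighting=weighting,
    )


def quantify(
    area_ratio: float,
    spiked_standard_fmol: float,
    digested_protein_ug: float,
    curve: CalibrationCurve,
    protein: str = "",
    sample_id: str = "",
    species_specificity: str = "",
) -> ProteinQuantResult:
    """Back-calculate one sample's concentration against an accepted curve.

    ``spiked_standard_fmol`` documents the internal-standard amount common to
    samples and calibration standards (the curve already encodes the
    response); ``digested_protein_ug`` normalizes the on-column amount to a
    concentration.  Amounts below the LOQ (including any negative
    back-calculation) yield a below-LOQ result with no numeric value.
    """
    if not digested_protein_ug > 0:
        raise ValidationError("digested_protein_ug must be > 0")
    if not spiked_standard_fmol > 0:
        raise ValidationError("spiked_standard_fmol must be > 0")
    amount = curve.back_calculate(area_ratio)
    if amount < curve.loq_fmol:
        return ProteinQuantResult(
            protein=protein,
            sample_id=sample_id,
            concentration=None,
            below_loq=True,
            species_specificity=species_specificity,
        )
    return ProteinQuantResult(
        protein=protein,
        sample_id=sample_id,
        concentration=amount / digested_protein_ug,
        below_loq=False,
        species_specificity=species_specificity,
    )


# ---------------------------------------------------------------------------
# Synthetic MRM-area generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MrmDesign:
    """Layout of a synthetic MRM run: standards ladder and sample digests."""

    standard_amounts_fmol: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0)
    digested_protein_ug: float = 50.0
    spiked_standard_fmol: float = 750.0
    response_slope: float = 0.02  # area-ratio per fmol, latent
    response_intercept: float = 0.0
    n_samples: int = 1

    def __post_init__(self) -> None:
        if len(self.standard_amounts_fmol) < 3:
            raise ValidationError("need >= 3 calibration standards")
        if not (self.digested_protein_ug > 0 and self.response_slope > 0):
            raise ValidationError("digested_protein_ug and response_slope must be > 0")


def generate_mrm_areas(
    true_conc_fmol_per_ug: float,
    design: MrmDesign = MrmDesign(),
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> tuple[list[CalibrationStandard], list[float]]:
    """Generate standards and sample area ratios from a latent linear response.

    Area ratios follow ``intercept + slope * amount`` with mean-one
    multiplicative lognormal noise of coefficient of variation ``noise_cv``
    applied to each measured ratio; reproducible given the seed.
    """
    if true_conc_fmol_per_ug < 0:
        raise ValidationError("true concentration must be >= 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    def noisy(ratio: float) -> float:
        if noise_cv == 0.0:
            return ratio
        sigma2 = math.log1p(noise_cv * noise_cv)
        factor = rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2))
        return ratio * float(factor)

    standards = [
        CalibrationStandard(
            known_amount=a,
            area_ratio=noisy(design.response_intercept + design.response_slope * a),
        )
        for a in design.standard_amounts_fmol
    ]
    amount = true_conc_fmol_per_ug * design.digested_protein_ug
    sample_ratios = [
        noisy(design.response_intercept + design.response_slope * amount)
        for _ in range(design.n_samples)
    ]
    return standards, sample_ratios


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

STANDARDS_COLUMNS = ("peptide", "known_fmol", "area_ratio")
MRM_SAMPLE_COLUMNS = ("sample_id", "protein", "peptide", "area_ratio", "digested_protein_ug")


def read_standards(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STANDARDS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"standards file missing column(s): {', '.join(missing)}")
    return df


def read_mrm_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MRM_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"MRM sample file missing column(s): {', '.join(missing)}")
    return df


def quantify_table(
    standards: pd.DataFrame,
    samples: pd.DataFrame,
    weighting: str = "1/x",
    spiked_standard_fmol: float = 750.0,
) -> pd.DataFrame:
    """Fit one curve per peptide and quantify every sample row against it.

    Returns a table with a ``concentration_fmol_per_ug`` column holding either
    a number or the ``<LOQ`` token; the replicate-level values are kept (one
    row per measurement) so replicate means can be formed downstream without
    guessing a rounding convention.
    """
    specificity = {}
    if "species_specificity" in standards.columns:
        specificity = (
            standards.drop_duplicates("peptide")
            .set_index("peptide")["species_specificity"]
            .to_dict()
        )
    curves: dict[str, CalibrationCurve] = {}
    for peptide, sub in standards.groupby("peptide"):
        curves[peptide] = fit_calibration(
            [
                CalibrationStandard(float(r.known_fmol), float(r.area_ratio))
                for r in sub.itertuples()
            ],
            weighting=weighting,
        )
    rows = []
    for rec in samples.to_dict("records"):
        peptide = rec["peptide"]
        if peptide not in curves:
            raise ValidationError(f"no calibration standards for peptide {peptide!r}")
        result = quantify(
            area_ratio=float(rec["area_ratio"]),
            spiked_standard_fmol=spiked_standard_fmol,
            digested_protein_ug=float(rec["digested_protein_ug"]),
            curve=curves[peptide],
            protein=str(rec["protein"]),
            sample_id=str(rec["sample_id"]),
            species_specificity=str(specificity.get(peptide, "")),
        )
        rows.append(
            {
                "sample_id": result.sample_id,
                "protein": result.protein,
                "peptide": peptide,
                "concentration_fmol_per_ug": result.render(),
                "species_specificity": result.species_specificity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "protein",
            "peptide",
            "concentration_fmol_per_ug",
            "species_specificity",
        ],
    )
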