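"""Standard-curve calibration and protein-normalized quantification.

Plate-reader absorbances are converted to concentrations via a fitted
standard curve -- linear (Beer-Lambert regime, the default for colorimetric
metabolite assays) or four-parameter logistic (sandwich ELISAs, which are
sigmoidal).  Metabolite readouts are reported as metabolite:protein ratios to
normalise for specimen size, after undoing any dilution (hemolymph is
routinely diluted 10-fold before assay).

Units are carried as labels and never converted implicitly;
:func:`millimolar_to_ug_per_ml` converts molarity to mass concentration given
a molar mass (e.g. 5 mM glucose at 180 g/mol = 900 ug/mL).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "StandardCurve",
    "SampleQuant",
    "fit_standard",
    "conc_from_abs",
    "normalize_sample",
    "elisa_quantify",
    "millimolar_to_ug_per_ml",
    "sugar_concentration_pct",
]


@dataclass(frozen=True)
class StandardCurve:
    """A fitted absorbance -> concentration calibration.

    model "linear": absorbance = intercept + slope * conc, params (slope,
    intercept).  model "four_parameter_logistic": absorbance =
    d + (a - d) / (1 + (conc / c) ** b), params (a, b, c, d) with a the
    zero-dose and d the infinite-dose asymptote.
    """

    model: str
    params: tuple[float, ...]
    r_squared: float
    conc_range: tuple[float, float]
    abs_range: tuple[float, float]

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        if self.model == "linear":
            slope, intercept = self.params
            return intercept + slope * conc
        a, b, c, d = self.params
        with np.errstate(invalid="ignore", divide="ignore"):
            return d + (a - d) / (1.0 + (conc / c) ** b)


@dataclass(frozen=True)
class SampleQuant:
    """A protein-normalized sample quantification."""

    raw_conc: float
    dilution_factor: float
    protein_conc: float

    @property
    def normalized(self) -> float:
        return self.raw_conc * self.dilution_factor / self.protein_conc


def _four_pl(x, a, b, c, d):
    with np.errstate(invalid="ignore", divide="ignore"):
        return d + (a - d) / (1.0 + (x / c) ** b)


def fit_standard(
    known_conc: Sequence[float],
    absorbance: Sequence[float],
    model: str = "linear",
    blank: Sequence[float] | float | None = None,
) -> StandardCurve:
    """Least-squares fit of a standard curve to calibration wells.

    Requires >= 3 standards with distinct concentrations.  Mean blank
    absorbance, when given, is subtracted before fitting.  A warning is
    raised when r-squared falls below 0.98 (a sloppy calibration).
    """
    x = np.asarray(known_conc, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if x.size != y.size:
        raise ValueError("known_conc and absorbance differ in length")
    if x.size < 3:
        raise ValueError("at least 3 standards required")
    if np.unique(x).size < 2:
        raise ValueError("standards must span distinct concentrations")
    if blank is not None:
        y = y - float(np.mean(blank))
    if model not in ("linear", "four_parameter_logistic", "4pl"):
        raise ValueError(f"unknown model {model!r}")

    if model == "linear":
        res = sps.linregress(x, y)
        params: tuple[float, ...] = (float(res.slope), float(res.intercept))
        yhat = res.intercept + res.slope * x
    else:
        model = "four_parameter_logistic"
        a0 = float(y[np.argmin(x)])
        d0 = float(y[np.argmax(x)])
        c0 = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
        b0 = 1.0 if d0 >= a0 else -1.0
        popt, _ = optimize.curve_fit(
            _four_pl, x, y, p0=(a0, b0, c0, d0), maxfev=20000
        )
        params = tuple(float(v) for v in popt)
        yhat = _four_pl(x, *params)

    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.98:
        warnings.warn(f"standard curve r-squared is low ({r2:.4f})", stacklevel=2)
    ylo, yhi = float(np.min(yhat)), float(np.max(yhat))
    return StandardCurve(
        model=model,
        params=params,
        r_squared=r2,
        conc_range=(float(x.min()), float(x.max())),
        abs_range=(ylo, yhi),
    )


def conc_from_abs(curve: StandardCurve, absorbance) -> np.ndarray | float:
    """Invert a standard curve: absorbance -> concentration.

    Absorbances outside the calibrated range are extrapolated with a warning.
    The four-parameter logistic inverse is closed-form; values at or beyond
    its asymptote ``d`` are non-invertible.
    """
    y = np.asarray(absorbance, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    lo, hi = curve.abs_range
    if ((y < min(lo, hi) - 1e-12) | (y > max(lo, hi) + 1e-12)).any():
        warnings.warn("absorbance outside calibrated range; extrapolating", stacklevel=2)

    if curve.model == "linear":
        slope, intercept = curve.params
        if slope == 0:
            raise ZeroDivisionError("flat calibration cannot be inverted")
        x = (y - intercept) / slope
    else:
        a, b, c, d = curve.params
        if ((y - d) == 0).any():
            raise ValueError("absorbance in non-invertible region of the logistic curve")
        ratio = (a - d) / (y - d)
        if (ratio <= 1e-300).any() or ((ratio - 1.0) < 0).any():
            raise ValueError("absorbance in non-invertible region of the logistic curve")
        x = c * (ratio - 1.0) ** (1.0 / b)
    return float(x[0]) if scalar else x


def normalize_sample(
    raw_conc: float,
    dilution_factor: float,
    protein_conc: float,
) -> SampleQuant:
    """Undo dilution and normalise a metabolite concentration to protein.

    normalized = raw_conc * dilution_factor / protein_conc.
    """
    if protein_conc <= 0:
        raise ValueError("protein concentration must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return SampleQuant(raw_conc=float(raw_conc), dilution_factor=float(dilution_factor), protein_conc=float(protein_conc))


def elisa_quantify(
    standard_conc: Sequence[float],
    standard_abs: Sequence[float],
    sample_abs: Sequence[float] | float,
    model: str = "four_parameter_logistic",
) -> tuple[np.ndarray | float, StandardCurve]:
    """Quantify samples against ELISA peptide standards.

    Fits the standard curve (four-parameter logistic by default, the shape of
    sandwich assays) and inverts it at the sample absorbances.  Samples below
    the lowest or above the highest standard are flagged by the extrapolation
    warning from :func:`conc_from_abs`.
    """
    curve = fit_standard(standard_conc, standard_abs, model=model)
    return conc_from_abs(curve, sample_abs), curve


def millimolar_to_ug_per_ml(conc_mm: float, molar_mass_g_per_mol: float) -> float:
    """Convert a millimolar concentration to ug/mL given the molar mass.

    1 mM x (M g/mol) = M mg/L = M ug/mL; e.g. 5 mM glucose (180 g/mol) is
    900 ug/mL.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return conc_mm * molar_mass_g_per_mol


def sugar_concentration_pct(fold: float, base_pct: float = 6.0) -> float:
    """Dietary sucrose percentage of an N-fold sugar diet.

    The base recipe contains 6% sucrose ("1x"); a 5x diet is 30% sucrose with
    other ingredients unchanged.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    return fold * base_pct
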