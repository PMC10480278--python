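"""Assay reduction, Michaelis-Menten fits and hydrolysis/transglycosylation
specificity.

The transglycosylation readout follows starch consumption through the
starch-triiodide complex (A620): one unit is the enzyme amount that
changes one absorbance unit per minute.  Hydrolysis is read as reducing
sugars by DNS colorimetry (A540) against a glucose standard curve and
expressed as glucose equivalents released per litre, minute and mg of
enzyme.  The specificity readout is the H/T ratio (hydrolytic specific
activity over transglycosylation Vmax, kept in the assays' mixed units),
its fold-change versus a reference variant, and the transition-state
free-energy difference RT ln(Vmax_ref / Vmax_var).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "ASSAY_TEMPERATURE_K",
    "AssayTable",
    "MMFit",
    "SpecificityResult",
    "reduce_transglycosylation",
    "glucose_standard_curve",
    "reduce_dns",
    "correct_full_length",
    "michaelis_menten",
    "fit_mm",
    "ht_ratio",
    "ht_increment",
    "ddg_transition_state",
    "compute_specificity",
]

R_KCAL = 1.987e-3          # gas constant, kcal/(mol K)
ASSAY_TEMPERATURE_K = 343.15   # 70 degC assay temperature


@dataclass(frozen=True)
class AssayTable:
    """Raw absorbance time series for one enzyme sample.

    ``time_min == 0`` rows are the zero-time (or no-enzyme blank)
    readings; each series id must include one.
    """

    time_min: np.ndarray
    absorbance: np.ndarray
    series: np.ndarray
    enzyme_mg: float
    dilution: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        s = np.asarray(self.series)
        if not (t.shape == a.shape == s.shape):
            raise ValueError("time, absorbance and series must align")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbances must be finite")
        if self.enzyme_mg <= 0:
            raise ValueError("enzyme_mg must be positive")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "series", s)

    @classmethod
    def from_csv(cls, path, enzyme_mg: float, dilution: float = 1.0,
                 absorbance_col: str = "a620") -> "AssayTable":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df[absorbance_col].to_numpy(),
                   df["series"].to_numpy(), enzyme_mg, dilution)


def reduce_transglycosylation(assay: AssayTable) -> float:
    """Starch-consumption activity in U/(min mg): mean of
    ``(A620(0) - A620(t)) / (t * enzyme_mg)`` over all nonzero times.

    Negative absorbance drops (starch apparently increasing) are clipped
    to zero with a warning.
    """
    rates = []
    for sid in pd.unique(assay.series):
        mask = assay.series == sid
        t = assay.time_min[mask]
        a = assay.absorbance[mask]
        zero = t == 0
        if not np.any(zero):
            raise ValueError(f"series {sid!r} has no zero-time reading")
        if not np.any(~zero):
            raise ValueError(f"series {sid!r} has only zero-time readings")
        a0 = float(np.mean(a[zero]))
        delta = a0 - a[~zero]
        if np.any(delta < 0):
            warnings.warn(f"series {sid!r}: negative absorbance drop clipped to 0")
            delta = np.clip(delta, 0.0, None)
        rates.extend(delta / t[~zero] / assay.enzyme_mg)
    return float(np.mean(rates))


def glucose_standard_curve(glucose_mm, a540) -> tuple[float, float]:
    """Least-squares line ``A540 = slope * [glc] + intercept``."""
    glucose_mm = np.asarray(glucose_mm, dtype=float)
    a540 = np.asarray(a540, dtype=float)
    if glucose_mm.size < 3:
        raise ValueError("need at least 3 standard points")
    res = stats.linregress(glucose_mm, a540)
    if res.slope <= 0:
        raise ValueError("glucose standard curve slope must be positive")
    return float(res.slope), float(res.intercept)


def reduce_dns(
    sample_a540: float,
    blank_a540: float,
    standards: Sequence[tuple[float, float]],
    time_min: float,
    enzyme_mg: float,
) -> float:
    """Hydrolytic activity in glucose equivalents (mol)/(L min mg).

    The blank (no-enzyme incubation) absorbance is subtracted, the
    standard curve inverted to mM glucose equivalents, and the result
    divided by the incubation time and enzyme mass (mM -> mol/L is the
    1e-3 factor).
    """
    std = np.asarray(standards, dtype=float)
    slope, intercept = glucose_standard_curve(std[:, 0], std[:, 1])
    glucose_mm = (sample_a540 - blank_a540 - intercept) / slope
    glucose_mm = max(glucose_mm, 0.0)
    if time_min <= 0 or enzyme_mg <= 0:
        raise ValueError("time and enzyme mass must be positive")
    return glucose_mm * 1e-3 / time_min / enzyme_mg


def dns_glucose_equivalents(
    sample_a540: float, blank_a540: float,
    standards: Sequence[tuple[float, float]],
) -> float:
    """mM glucose equivalents of one blank-corrected DNS reading."""
    std = np.asarray(standards, dtype=float)
    slope, intercept = glucose_standard_curve(std[:, 0], std[:, 1])
    return (sample_a540 - blank_a540 - intercept) / slope


def correct_full_length(activity: float, fraction: float) -> float:
    """Rescale a specific activity by the full-length protein fraction.

    A sample where only ``fraction`` of the protein mass is intact
    enzyme (e.g. 0.83 for a 17% degradation band) under-reports the
    specific activity by that factor.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"full-length fraction must be in (0, 1], got {fraction}")
    return activity / fraction


def michaelis_menten(s, vmax: float, km: float):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))


@dataclass(frozen=True)
class MMFit:
    vmax: float
    km: float
    se_vmax: float
    se_km: float
    r2: float
    converged: bool = True

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("fitted Vmax and Km must be positive")

    @property
    def vmax_over_km(self) -> float:
        return self.vmax / self.km


def _hanes_start(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
    ok = v > 0
    res = stats.linregress(s[ok], s[ok] / v[ok])
    if res.slope > 0 and res.intercept > 0:
        return 1.0 / res.slope, res.intercept / res.slope
    return float(v.max()), float(np.median(s))


def fit_mm(substrate_mm, velocity) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit, Hanes-initialised."""
    s = np.asarray(substrate_mm, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if np.unique(s).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    p0 = _hanes_start(s, v)
    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=p0, maxfev=10000
        )
    except RuntimeError:
        popt, pcov = p0, np.full((2, 2), np.nan)
        converged = False
        warnings.warn("Michaelis-Menten fit did not converge; Hanes estimate returned")
    fitted = michaelis_menten(s, *popt)
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum((v - fitted) ** 2)) / sst if sst > 0 else np.nan
    se = np.sqrt(np.diag(pcov))
    return MMFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                 r2, converged)


def ht_ratio(hydrolysis: float, t_vmax: float) -> float:
    """H/T specificity ratio in the assays' mixed units."""
    if t_vmax <= 0:
        raise ValueError("transglycosylation Vmax must be positive")
    return hydrolysis / t_vmax


@dataclass(frozen=True)
class SpecificityResult:
    """Specificity summary for one variant (H/T and derived quantities)."""

    label: str
    hydrolysis: float              # Eq glucose/(L min mg)
    t_vmax: float                  # U/(min mg)
    km: Optional[float] = None     # mM
    full_length_fraction: float = 1.0

    @property
    def ht(self) -> float:
        return ht_ratio(self.hydrolysis, self.t_vmax)


def ht_increment(variant: SpecificityResult, reference: SpecificityResult) -> float:
    """Fold-change of H/T relative to the reference, from unrounded means."""
    return variant.ht / reference.ht


def ddg_transition_state(
    vmax_ref: float, vmax_var: float, temperature_k: float = ASSAY_TEMPERATURE_K
) -> float:
    """Transition-state destabilisation RT ln(Vmax_ref / Vmax_var), kcal/mol.

    Positive when the reference enzyme is faster; antisymmetric in its
    two arguments and linear in temperature.
    """
    if vmax_ref <= 0 or vmax_var <= 0:
        raise ValueError("Vmax values must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature_k * float(np.log(vmax_ref / vmax_var))


def compute_specificity(
    label: str,
    kinetics: pd.DataFrame,
    hydrolysis: float,
    full_length_fraction: float = 1.0,
) -> tuple[SpecificityResult, MMFit]:
    """Fit acceptor kinetics and assemble the specificity summary.

    ``kinetics`` columns: ``maltose_mM``, ``velocity`` and optionally
    ``rep``.  With a ``rep`` column each replicate is fitted separately
    and parameters averaged (so Vmax/Km is a mean of per-replicate
    ratios); otherwise a single pooled fit is used.  Both the
    transglycosylation Vmax and the hydrolysis activity are divided by
    the full-length protein fraction.
    """
    if "rep" in kinetics.columns and kinetics["rep"].nunique() > 1:
        fits = [
            fit_mm(g["maltose_mM"], g["velocity"])
            for _, g in kinetics.groupby("rep")
        ]
        vmax = float(np.mean([f.vmax for f in fits]))
        km = float(np.mean([f.km for f in fits]))
        fit = MMFit(vmax, km,
                    float(np.std([f.vmax for f in fits], ddof=1) / np.sqrt(len(fits))),
                    float(np.std([f.km for f in fits], ddof=1) / np.sqrt(len(fits))),
                    float(np.mean([f.r2 for f in fits])))
    else:
        fit = fit_mm(kinetics["maltose_mM"], kinetics["velocity"])
    t_corr = correct_full_length(fit.vmax, full_length_fraction)
    h_corr = correct_full_length(hydrolysis, full_length_fraction)
    result = SpecificityResult(
        label=label, hydrolysis=h_corr, t_vmax=t_corr, km=fit.km,
        full_length_fraction=full_length_fraction,
    )
    return result, fit
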