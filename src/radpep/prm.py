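"""Parallel-reaction-monitoring absolute quantitation.

A light (endogenous) peptide is quantified against a constant heavy
isotope-labeled spike: a dilution series of known light amounts against the
spike yields a linear light/heavy-ratio standard curve; an endogenous
sample's measured ratio is back-calculated through the curve to femtomoles
and converted to copies per cell through Avogadro's number.  Theoretical
b/y fragment masses support discriminating single-residue variant peptides
(e.g. a G>S neoantigen) by their distinguishing ions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as pmass
from scipy import stats

from .types import CalibrationCurve, CopiesPerCellResult

AVOGADRO = 6.02214076e23  # exact (2019 SI)
PROTON = 1.00727646688
WATER = 18.0105646863

# Named modification mass offsets.  Heavy labels are modifications, never
# sequence changes.
MOD_MASSES: dict[str, float] = {
    "K(13C6,15N2)": 6 * 1.0033548378 + 2 * 0.9970348934,  # +8.01420
    "R(13C6,15N4)": 6 * 1.0033548378 + 4 * 0.9970348934,
    "Oxidation": 15.9949146221,
    "Deamidation": 0.9840155848,
    "Phospho": 79.9663304084,
    "Acetyl": 42.0105646863,
    "Cysteinylation": 119.0041340000,
}


# ---------------------------------------------------------------------------
# Standard curve


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    peptide: str = "",
    weighted: bool = False,
) -> CalibrationCurve:
    """Ordinary least-squares fit of light/heavy ratio against light fmol.

    Requires at least three points with non-degenerate fmol spread; a flat
    response (zero ratio variance) is rejected as degenerate.  ``weighted``
    switches to 1/x weighting (zero-amount points get the smallest nonzero
    weight).  The intercept is flagged when it exceeds twice the residual
    standard deviation of the fit.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in fmol amounts")
    if np.ptp(y) == 0:
        raise ValueError("degenerate flat calibration (all ratios equal)")
    if weighted:
        w = np.empty_like(x)
        pos = x > 0
        w[pos] = 1.0 / x[pos]
        w[~pos] = 1.0 / x[pos].min()
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        intercept, slope = float(beta[0]), float(beta[1])
        yhat = intercept + slope * x
        ss_res = float((w * (y - yhat) ** 2).sum())
        ss_tot = float((w * (y - np.average(y, weights=w)) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        slope_se = float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
        slope_se = float(fit.stderr)
    resid = y - (intercept + slope * x)
    resid_sd = float(np.std(resid, ddof=2)) if len(pts) > 2 else 0.0
    return CalibrationCurve(
        peptide=peptide,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        valid_range=(float(x.min()), float(x.max())),
        slope_se=slope_se,
        intercept_warning=abs(intercept) > 2 * resid_sd and resid_sd > 0,
    )


def quantify_endogenous(
    curve: CalibrationCurve,
    ratio: float,
    heavy_spike_fmol: float = 100.0,
) -> tuple[float, bool]:
    """Back-calculate endogenous femtomoles from a measured light/heavy
    ratio: ``(ratio - intercept) / slope``.

    ``heavy_spike_fmol`` documents the spike the curve was built against;
    the curve already encodes it through its slope.  Returns (fmol,
    extrapolated) where the flag marks ratios resolving outside the
    calibrated amount range.
    """
    if curve.slope == 0:
        raise ValueError("degenerate curve: zero slope")
    fmol = (ratio - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    eps = 1e-9 * max(hi - lo, 1.0)
    return float(fmol), not (lo - eps <= fmol <= hi + eps)


def copies_per_cell(endogenous_fmol: float, n_cells: float) -> float:
    """Peptide copies per cell: ``fmol * 1e-15 * N_A / n_cells`` (assumes
    100% recovery)."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return endogenous_fmol * 1e-15 * AVOGADRO / n_cells


def quantify_samples(
    curve: CalibrationCurve,
    ratios: dict[str, float],
    n_cells: float,
    heavy_spike_fmol: float = 100.0,
) -> list[CopiesPerCellResult]:
    """Convert measured per-sample ratios to copies-per-cell results."""
    out = []
    for sample, ratio in ratios.items():
        fmol, extrap = quantify_endogenous(curve, ratio, heavy_spike_fmol)
        out.append(
            CopiesPerCellResult(
                sample=sample,
                light_heavy_ratio=float(ratio),
                endogenous_fmol=fmol,
                n_cells=float(n_cells),
                copies_per_cell=copies_per_cell(fmol, n_cells),
                extrapolated=extrap,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fragment ions


def _residue_masses(peptide: str, mods: Iterable[tuple[str, int]]) -> np.ndarray:
    masses = np.array([pmass.std_aa_mass[a] for a in peptide])
    for name, pos in mods:
        if name not in MOD_MASSES:
            raise KeyError(f"unknown modification {name!r}")
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        masses[pos - 1] += MOD_MASSES[name]
    return masses


def precursor_mh(peptide: str, mods: Iterable[tuple[str, int]] = ()) -> float:
    """Singly-protonated precursor mass MH+."""
    return float(_residue_masses(peptide, mods).sum() + WATER + PROTON)


def theoretical_fragments(
    peptide: str,
    mods: Iterable[tuple[str, int]] = (),
    series: Iterable[str] = ("b", "y"),
    charge: int = 1,
) -> list[tuple[str, float]]:
    """Theoretical b/y fragment m/z values.

    ``b_i`` = sum of the first i residue masses + charge protons;
    ``y_i`` = sum of the last i residue masses + water + charge protons;
    both divided by charge.  Fragments run i = 1..n-1.  Modifications are
    (name, 1-based position) with masses from :data:`MOD_MASSES`, so a heavy
    K label shifts every b ion containing position 1 by its exact offset.
    """
    masses = _residue_masses(peptide, mods)
    n = len(peptide)
    out: list[tuple[str, float]] = []
    series = set(series)
    prefix = np.cumsum(masses)
    if "b" in series:
        for i in range(1, n):
            out.append((f"b{i}", (prefix[i - 1] + charge * PROTON) / charge))
    if "y" in series:
        suffix = np.cumsum(masses[::-1])
        for i in range(1, n):
            out.append(
                (f"y{i}", (suffix[i - 1] + WATER + charge * PROTON) / charge)
            )
    return out


def distinguishing_ions(
    peptide_a: str,
    peptide_b: str,
    mods_a: Iterable[tuple[str, int]] = (),
    mods_b: Iterable[tuple[str, int]] = (),
    tol: float = 1e-6,
) -> list[tuple[str, float, float, float]]:
    """Fragment ions whose theoretical m/z differs between two equal-length
    peptides.

    Returns (ion, mz_a, mz_b, delta) tuples; for a single-residue
    substitution every differing ion carries the same mass delta (the
    residue mass difference), and the b/y indices bracketing the mutated
    position identify it (e.g. b8 discriminates a substitution at position
    7 of a 9-mer alongside b7 and the covering y ions).
    """
    if len(peptide_a) != len(peptide_b):
        raise ValueError("peptides must have equal length")
    fa = dict(theoretical_fragments(peptide_a, mods_a))
    fb = dict(theoretical_fragments(peptide_b, mods_b))
    out = []
    for ion in fa:
        if abs(fa[ion] - fb[ion]) > tol:
            out.append((ion, fa[ion], fb[ion], fb[ion] - fa[ion]))
    return out
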