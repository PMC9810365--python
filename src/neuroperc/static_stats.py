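"""Binned power-law fitting with a KS-based cutoff, scale-free
classification, and the three-level in/out symmetry analysis.

The tail model is a continuous power law: above a cutoff A', densities are
proportional to x^(-alpha).  The data are histogrammed into linearly spaced
bins; the exponent is the maximum-likelihood estimate on the binned tail
counts (the last tail bin is treated as open-ended), and the cutoff is the
bin edge minimizing the Kolmogorov-Smirnov distance between the fitted and
empirical tail CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class PowerLawFitError(ValueError):
    """No candidate cutoff left enough tail samples to fit."""


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float          # alpha > 1
    cutoff: float            # A', lower bound of fitted tail
    ks_statistic: float      # goodness, in [0, 1]
    n_tail: int              # samples above cutoff
    n_bins: int


@dataclass(frozen=True)
class SymmetryResult:
    pearson_r: float
    p_value: float
    avg_change_fraction: float
    level: str               # strictly strong | less strong | relatively weak
    n_pairs_used: int = 0
    n_pairs_excluded: int = 0


def _binned_loglike(alpha: float, edges: np.ndarray, counts: np.ndarray) -> float:
    """Log-likelihood of binned counts under a power-law tail starting at
    edges[0]; the final bin is open-ended [edges[-2], inf)."""
    a = 1.0 - alpha
    lo = edges[:-1] ** a
    hi = edges[1:] ** a
    hi[-1] = 0.0  # open-ended last bin
    probs = (lo - hi) / edges[0] ** a
    probs = np.maximum(probs, 1e-300)
    return float(np.sum(counts * np.log(probs)))


def _fit_tail(edges: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """MLE exponent and KS statistic for one candidate tail."""
    res = optimize.minimize_scalar(
        lambda a: -_binned_loglike(a, edges, counts),
        bounds=(1.000001, 20.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(res.x)
    # KS distance between model and empirical CDFs at interior bin edges
    n = counts.sum()
    emp = np.cumsum(counts) / n
    model = 1.0 - (edges[1:] / edges[0]) ** (1.0 - alpha)
    model[-1] = 1.0
    ks = float(np.max(np.abs(emp - model)))
    return alpha, ks


def fit_binned_power_law(
    values, n_bins: int = 150, min_tail: int = 50
) -> PowerLawFit:
    """Fit a power-law tail to positive samples.

    Candidate cutoffs are the histogram bin edges; for each, the exponent is
    the binned continuous-power-law MLE and the cutoff minimizing the KS
    statistic wins.  Raises :class:`PowerLawFitError` when no candidate
    keeps at least ``min_tail`` samples.
    """
    x = np.asarray(values, float)
    if len(x) < 50:
        raise PowerLawFitError("need at least 50 samples")
    if (x <= 0).any():
        raise ValueError("values must be positive")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise PowerLawFitError("degenerate data range")
    counts, _ = np.histogram(x, bins=edges)
    best: tuple[float, float, float, int] | None = None  # (ks, alpha, cutoff, n_tail)
    cum_from_right = np.cumsum(counts[::-1])[::-1]
    for j in range(n_bins - 1):  # keep >= 2 bins in the tail
        if edges[j] <= 0:
            continue
        n_tail = int(cum_from_right[j])
        if n_tail < min_tail:
            break
        alpha, ks = _fit_tail(edges[j:], counts[j:])
        if best is None or ks < best[0]:
            best = (ks, alpha, float(edges[j]), n_tail)
    if best is None:
        raise PowerLawFitError(
            f"fewer than {min_tail} tail samples above every candidate cutoff"
        )
    ks, alpha, cutoff, n_tail = best
    return PowerLawFit(
        exponent=alpha, cutoff=cutoff, ks_statistic=ks, n_tail=n_tail, n_bins=n_bins
    )


def classify_scale_free(fit: PowerLawFit) -> bool:
    """Scale-free means exponent in the open interval (2, 3) with KS
    goodness strictly below 0.05."""
    return 2.0 < fit.exponent < 3.0 and fit.ks_statistic < 0.05


def fit_report_row(variable: str, fit: PowerLawFit) -> str:
    """One CSV row: variable, exponent, cutoff, ks, n_tail, scale_free_flag."""
    return (
        f"{variable},{fit.exponent:.6g},{fit.cutoff:.6g},"
        f"{fit.ks_statistic:.6g},{fit.n_tail},{int(classify_scale_free(fit))}"
    )


def symmetry_analysis(x, y) -> SymmetryResult:
    """Three-level in/out symmetry between paired variables.

    Reports the Pearson correlation with its two-sided p-value and the
    average change fraction mean(|x_i - y_i| / y_i) over pairs with nonzero
    reference y (zero-denominator pairs are excluded and counted).  The
    level is *strictly strong* when both a strong positive correlation
    (r > 0.9, p < 1e-3) and a small fraction (< 1) hold, *less strong* when
    exactly one holds, *relatively weak* otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    keep = y != 0
    if not keep.any():
        raise ValueError("all reference entries are zero")
    frac = float(np.mean(np.abs(x[keep] - y[keep]) / np.abs(y[keep])))
    strong_corr = (r > 0.9) and (p < 1e-3)
    small_frac = frac < 1.0
    if strong_corr and small_frac:
        level = "strictly strong"
    elif strong_corr or small_frac:
        level = "less strong"
    else:
        level = "relatively weak"
    return SymmetryResult(
        pearson_r=float(r),
        p_value=float(p),
        avg_change_fraction=frac,
        level=level,
        n_pairs_used=int(keep.sum()),
        n_pairs_excluded=int((~keep).sum()),
    )
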