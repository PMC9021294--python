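"""Spike-in normalization and mismatch-vs-stoichiometry calibration.

The calibration fit is a zero-intercept least-squares line of observed
mismatch% against known m1A stoichiometry%, with R^2 computed on the
uncentered total sum of squares (the appropriate convention when the
intercept is suppressed).  Background mismatch is estimated separately
from the 0%-stoichiometry point and is NOT subtracted inside the fit; it
enters only when inverting the curve to estimate stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CalibrationFit:
    slope: float          # mismatch% per stoichiometry%
    r2: float
    background: float     # observed mismatch% at 0% stoichiometry (0 if absent)
    points: tuple[tuple[float, float], ...]

    def predict(self, stoichiometry_pct: float) -> float:
        return self.slope * stoichiometry_pct


def spikein_normalized_frequency(count_table: pd.DataFrame,
                                 library: str = "") -> pd.DataFrame:
    """Cloning frequency of each RNA normalized to total QC-spike-in counts.

    Expects a count table with ``parent``/``trf_class``/``count`` columns
    (spike-in rows have ``trf_class == 'spikeIn'``).  The returned
    frequency (count / total spike-in count) is invariant to library
    depth and therefore comparable across libraries.
    """
    spike_total = count_table.loc[count_table.trf_class == "spikeIn", "count"].sum()
    if spike_total <= 0:
        raise ValueError(f"zero spike-in counts in library {library or '<unnamed>'}")
    out = count_table.copy()
    out["normalized_frequency"] = out["count"] / spike_total
    return out


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Zero-intercept least squares of mismatch% (y) on stoichiometry% (x).

    slope = sum(xy) / sum(x^2); R^2 = 1 - SS_res / sum(y^2).
    """
    if len(points) < 1:
        raise ValueError("calibration needs at least one point")
    x = np.asarray([p[0] for p in points], float)
    y = np.asarray([p[1] for p in points], float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("degenerate calibration: all stoichiometries are zero")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    ss_res = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - ss_res / syy if syy > 0 else 1.0
    background = float(np.mean(y[x == 0])) if np.any(x == 0) else 0.0
    return CalibrationFit(slope, r2, background, tuple((float(a), float(b))
                                                       for a, b in points))


@dataclass(frozen=True)
class StoichiometryEstimate:
    p_hat: float                       # in [0, 1]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    clipped_below_background: bool = False


def estimate_stoichiometry(observed_mismatch_pct: float, fit: CalibrationFit,
                           background_pct: Optional[float] = None,
                           n_reads: Optional[int] = None, n_boot: int = 1000,
                           calibration_n_reads: Optional[int] = None,
                           seed: Union[int, np.random.Generator] = 0
                           ) -> StoichiometryEstimate:
    """Invert the calibration curve: ``p_hat = (observed - background) / slope``.

    The estimate is clamped to [0, 1] (observed below background yields 0,
    flagged).  When the read depth ``n_reads`` underlying the observed
    rate is given, a percentile bootstrap CI is computed by binomial
    resampling of the mismatch count; when ``calibration_n_reads`` (depth
    per calibration level) is also given, each bootstrap replicate refits
    the curve on binomially resampled calibration points, so the CI
    reflects calibration uncertainty as well as counting noise.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive for inversion")
    bg = fit.background if background_pct is None else background_pct

    def invert(obs, slope, background):
        return np.clip((np.asarray(obs, float) - background) / slope / 100.0,
                       0.0, 1.0)

    p_hat = float(invert(observed_mismatch_pct, fit.slope, bg))
    clipped = observed_mismatch_pct < bg
    if n_reads is None:
        return StoichiometryEstimate(p_hat, clipped_below_background=bool(clipped))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = min(max(observed_mismatch_pct / 100.0, 0.0), 1.0)
    boot_obs = 100.0 * rng.binomial(n_reads, rate, size=n_boot) / n_reads
    if calibration_n_reads is None:
        boot_p = invert(boot_obs, fit.slope, bg)
    else:
        x = np.array([p[0] for p in fit.points])
        y = np.clip(np.array([p[1] for p in fit.points]) / 100.0, 0.0, 1.0)
        boot_p = np.empty(n_boot)
        for b in range(n_boot):
            yb = 100.0 * rng.binomial(calibration_n_reads, y) / calibration_n_reads
            fb = fit_calibration(list(zip(x, yb)))
            bgb = fb.background if background_pct is None else background_pct
            boot_p[b] = invert(boot_obs[b], fb.slope, bgb)
    lo, hi = np.percentile(boot_p, [2.5, 97.5])
    return StoichiometryEstimate(p_hat, float(lo), float(hi),
                                 clipped_below_background=bool(clipped))
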