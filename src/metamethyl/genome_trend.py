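"""Replication origin/terminus by GC skew and genome-wide methylation trend.

On the leading strand of most bacterial replichores G outnumbers C, so the
per-window skew (G - C)/(G + C) changes sign at the replication origin and
terminus; the cumulative skew then attains its minimum at *ori* and its
maximum at *ter*.  Methylation fractions of cell-cycle-coupled motifs (the
CcrM-like GANTC) vary smoothly between *ori* and *ter*; that trend is
summarised by a least-squares quartic fit, the conventional degree for a
smile/frown-shaped single-minimum curve over a circular genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GCSkewResult:
    window: int
    step: int
    centers: np.ndarray      # window centre coordinates
    skew: np.ndarray         # (G - C)/(G + C) per window
    cumulative: np.ndarray   # running sum of skew over windows
    ori_pos: int | None      # centre of the cumulative-minimum window
    ter_pos: int | None      # centre of the cumulative-maximum window
    degenerate: bool = False


def gc_skew(seq: str, window: int = 10_000, step: int = 1_000) -> GCSkewResult:
    """Windowed and cumulative GC skew with ori/ter calls.

    Windows of G + C = 0 contribute skew 0.  A sequence with no G/C signal
    anywhere is reported as degenerate (ori/ter None) rather than an error.
    """
    seq = seq.upper()
    if len(seq) < 2 * window:
        raise ValueError("sequence must cover at least two windows")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    starts = np.arange(0, len(seq) - window + 1, step)
    g = is_g[starts + window] - is_g[starts]
    c = is_c[starts + window] - is_c[starts]
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    cumulative = np.cumsum(skew)
    centers = starts + window // 2
    if np.all(skew == 0):
        return GCSkewResult(window, step, centers, skew, cumulative,
                            None, None, degenerate=True)
    ori = int(centers[int(np.argmin(cumulative))])
    ter = int(centers[int(np.argmax(cumulative))])
    return GCSkewResult(window, step, centers, skew, cumulative, ori, ter)


def gc_skew_report(res: GCSkewResult) -> pd.DataFrame:
    return pd.DataFrame({
        "center": res.centers,
        "skew": res.skew,
        "cumulative": res.cumulative,
    })


@dataclass
class TrendFit:
    degree: int
    coef_unit: np.ndarray   # coefficients on positions rescaled to [0, 1]
    coef_raw: np.ndarray    # coefficients on original bp positions
    fitted: np.ndarray      # fitted values at the input positions
    rms_residual: float
    x_min: float
    x_max: float

    def predict(self, positions) -> np.ndarray:
        t = (np.asarray(positions, dtype=float) - self.x_min) \
            / (self.x_max - self.x_min)
        return np.polynomial.polynomial.polyval(t, self.coef_unit)


def fit_trend(positions, fractions, degree: int = 4) -> TrendFit:
    """Least-squares polynomial trend of methylation fraction vs position.

    Positions are rescaled to [0, 1] before fitting (conditioning);
    coefficients are reported in both the unit and the raw-bp scalings.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(x) != len(y):
        raise ValueError("positions and fractions differ in length")
    if len(x) < degree + 1:
        raise ValueError(
            f"need at least degree + 1 = {degree + 1} points, got {len(x)}")
    x_min, x_max = float(x.min()), float(x.max())
    if x_max == x_min:
        raise ValueError("all positions identical")
    t = (x - x_min) / (x_max - x_min)
    coef_unit = np.polynomial.polynomial.polyfit(t, y, degree)
    fitted = np.polynomial.polynomial.polyval(t, coef_unit)
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    poly = np.polynomial.Polynomial(coef_unit, domain=[x_min, x_max],
                                    window=[0.0, 1.0])
    coef_raw = poly.convert(kind=np.polynomial.Polynomial).coef
    return TrendFit(degree, coef_unit, coef_raw, fitted, rms, x_min, x_max)


def trend_minimum(fit: TrendFit, n_grid: int = 10_001) -> float:
    """Position (bp) of the fitted curve's minimum over the data range."""
    xs = np.linspace(fit.x_min, fit.x_max, n_grid)
    ys = fit.predict(xs)
    return float(xs[int(np.argmin(ys))])


def trend_report(positions, fractions, fit: TrendFit) -> pd.DataFrame:
    return pd.DataFrame({
        "position": np.asarray(positions, dtype=float),
        "fraction": np.asarray(fractions, dtype=float),
        "fitted": fit.fitted,
    })
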