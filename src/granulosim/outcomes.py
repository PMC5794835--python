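"""Leukotoxicity endpoints computed from a simulated WBC trajectory.

Three summary measures of leukopenia severity against a normal value of
4.0 ×10^3 leukocytes/µL:

* **WBCAOC** — area between the WBC curve and the threshold wherever the
  curve is below it (10^3 cells/µL × days),
* **DoL** — cumulative duration of leukopenia (days below threshold),
* **MLC** — minimal leukocyte count over the evaluation window.

The trajectory is treated as piecewise linear on its reporting grid;
areas and durations are computed exactly on that geometry (threshold
crossings located by linear interpolation), and the minimum is refined
by local quadratic interpolation around the grid minimum.  The default
evaluation window runs from day 0 to the end of the last chemotherapy
cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["OutcomeMeasures", "wbcaoc", "dol", "mlc", "compute_outcomes"]

DEFAULT_THRESHOLD = 4.0


@dataclass
class OutcomeMeasures:
    wbcaoc: float       # [10^3 cells/µL × d]
    dol: float          # [d]
    mlc: float          # [10^3 cells/µL]
    threshold: float
    window: Tuple[float, float]


def _extract(result, window):
    """Clip (t, wbc) to the window, interpolating the endpoints."""
    if hasattr(result, "wbc"):
        t = np.asarray(result.t, dtype=float)
        w = np.asarray(result.wbc, dtype=float)
    else:
        t, w = (np.asarray(a, dtype=float) for a in result)
    if t.size < 2:
        raise ValueError("trajectory needs at least two grid points")
    if window is None:
        end = getattr(result, "therapy_end", None)
        window = (float(t[0]), float(end) if end else float(t[-1]))
    a, b = float(window[0]), float(window[1])
    if not (t[0] - 1e-9 <= a < b <= t[-1] + 1e-9):
        raise ValueError(f"window {window} outside trajectory span [{t[0]}, {t[-1]}]")
    a, b = max(a, float(t[0])), min(b, float(t[-1]))
    i0, i1 = np.searchsorted(t, a, "right"), np.searchsorted(t, b, "left")
    tt = np.concatenate(([a], t[i0:i1], [b]))
    ww = np.concatenate(([np.interp(a, t, w)], w[i0:i1], [np.interp(b, t, w)]))
    keep = np.concatenate(([True], np.diff(tt) > 1e-12))
    return tt[keep], ww[keep], (a, b)


def wbcaoc(result, threshold: float = DEFAULT_THRESHOLD, window=None) -> float:
    """Area between the WBC curve and the threshold where the curve is below.

    Exact integral of ``max(0, threshold − WBC(t))`` for the piecewise-
    linear trajectory; zero if the curve never dips below the threshold.
    """
    t, w, _ = _extract(result, window)
    d = threshold - w                       # deficit; positive below threshold
    d0, d1 = d[:-1], d[1:]
    h = np.diff(t)
    area = np.zeros_like(h)
    both_below = (d0 >= 0) & (d1 >= 0)
    area[both_below] = 0.5 * (d0[both_below] + d1[both_below]) * h[both_below]
    # crossing segments: triangle on the sub-interval below the threshold
    cross = (d0 > 0) ^ (d1 > 0)
    cross &= ~both_below
    if cross.any():
        dp = np.where(d0[cross] > 0, d0[cross], d1[cross])
        frac = dp / (np.abs(d0[cross] - d1[cross]))
        area[cross] = 0.5 * dp * frac * h[cross]
    return float(area.sum())


def dol(result, threshold: float = DEFAULT_THRESHOLD, window=None) -> float:
    """Cumulative time [d] with WBC strictly below the threshold.

    Sub-grid boundary crossings are located by linear interpolation.
    """
    t, w, _ = _extract(result, window)
    d = threshold - w
    d0, d1 = d[:-1], d[1:]
    h = np.diff(t)
    dur = np.zeros_like(h)
    both_below = (d0 > 0) & (d1 > 0)
    dur[both_below] = h[both_below]
    cross = (d0 > 0) ^ (d1 > 0)
    if cross.any():
        dp = np.where(d0[cross] > 0, d0[cross], d1[cross])
        dur[cross] = dp / np.abs(d0[cross] - d1[cross]) * h[cross]
    return float(dur.sum())


def mlc(result, window=None) -> float:
    """Minimal leukocyte count over the window.

    The grid minimum is refined by fitting a parabola through the
    minimum and its two neighbours when that refinement stays inside the
    bracketing interval.
    """
    t, w, _ = _extract(result, window)
    i = int(np.argmin(w))
    best = float(w[i])
    if 0 < i < t.size - 1:
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        w0, w1, w2 = w[i - 1], w[i], w[i + 1]
        d1, d2 = t1 - t0, t1 - t2
        e1, e2 = w1 - w0, w1 - w2
        denom = d1 * e2 - d2 * e1
        if abs(denom) > 1e-15:
            tv = t1 - 0.5 * (d1 ** 2 * e2 - d2 ** 2 * e1) / denom
            if t0 < tv < t2:
                # Lagrange evaluation at the vertex
                wv = (
                    w0 * (tv - t1) * (tv - t2) / ((t0 - t1) * (t0 - t2))
                    + w1 * (tv - t0) * (tv - t2) / ((t1 - t0) * (t1 - t2))
                    + w2 * (tv - t0) * (tv - t1) / ((t2 - t0) * (t2 - t1))
                )
                best = min(best, float(wv))
    return best


def compute_outcomes(
    result,
    threshold: float = DEFAULT_THRESHOLD,
    window: Optional[Tuple[float, float]] = None,
) -> OutcomeMeasures:
    """All three leukotoxicity measures for one trajectory."""
    t, w, win = _extract(result, window)
    return OutcomeMeasures(
        wbcaoc=wbcaoc((t, w), threshold, win),
        dol=dol((t, w), threshold, win),
        mlc=mlc((t, w), win),
        threshold=threshold,
        window=win,
    )
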