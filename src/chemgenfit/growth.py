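"""Growth-curve utilities: AUC dose metrics, ICx interpolation, doubling
times from the log-phase slope, and within-batch wild-type normalization.

These reproduce the dose-selection computation (area under an OD600 curve
relative to an untreated control, interpolated to the dose giving ~x%
inhibition) and the validation computation (doubling time = ln 2 / slope of
the log-linear window of the growth curve, normalized to the same-batch
wild type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.isotonic import IsotonicRegression


@dataclass
class GrowthCurve:
    time: np.ndarray       # hours, strictly increasing, >= 3 points
    od: np.ndarray         # OD600, >= 0
    strain: str = ""
    condition: str = ""
    batch: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.size < 3:
            raise ValueError("growth curve needs >= 3 time points")
        if self.time.size != self.od.size:
            raise ValueError("time and od lengths differ")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.time[0] < 0:
            raise ValueError("time must start at >= 0")
        if np.any(self.od < 0):
            raise ValueError("negative OD readings")


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the OD600 curve, in OD*h."""
    return float(np.trapezoid(curve.od, curve.time))


def relative_growth(treated: GrowthCurve, control: GrowthCurve) -> float:
    """AUC of the treated curve as a percentage of the control AUC."""
    denom = auc(control)
    if denom <= 0:
        raise ValueError("control AUC must be > 0")
    return 100.0 * auc(treated) / denom


def icx_from_doses(dose_growth: dict[float, float], x: float = 30.0
                   ) -> tuple[float, bool]:
    """Dose producing x% inhibition, by log-dose linear interpolation.

    ``dose_growth`` maps dose -> relative growth (% of control). Growth is
    projected onto a non-increasing curve first (isotonic regression in
    log-dose); the second return value flags whether that projection changed
    anything. The target level 100 - x must be bracketed by the measured
    doses.
    """
    if len(dose_growth) < 2:
        raise ValueError("need >= 2 doses")
    doses = np.array(sorted(dose_growth))
    if np.any(doses <= 0):
        raise ValueError("doses must be positive for log interpolation")
    growth = np.array([dose_growth[d] for d in doses])
    logd = np.log10(doses)
    iso = IsotonicRegression(increasing=False)
    smoothed = iso.fit_transform(logd, growth)
    adjusted = bool(np.max(np.abs(smoothed - growth)) > 1e-12)
    level = 100.0 - x
    if not (smoothed.min() <= level <= smoothed.max()):
        raise ValueError(f"dose range does not span IC{x:g} "
                         f"(growth range {smoothed.min():g}-{smoothed.max():g})")
    exact = np.flatnonzero(np.isclose(smoothed, level))
    if exact.size:
        return float(doses[exact[0]]), adjusted
    # first interval bracketing the level (growth decreasing with dose)
    for i in range(len(doses) - 1):
        g0, g1 = smoothed[i], smoothed[i + 1]
        if g0 >= level >= g1:
            if g0 == g1:
                return float(doses[i]), adjusted
            frac = (g0 - level) / (g0 - g1)
            return float(10 ** (logd[i] + frac * (logd[i + 1] - logd[i]))), adjusted
    raise ValueError(f"dose range does not span IC{x:g}")


def doubling_time(curve: GrowthCurve, window: int = 10,
                  r2_floor: float = 0.98) -> tuple[float | None, str]:
    """Doubling time (h) = ln 2 / slope of the best log-linear window.

    The exponential phase is detected as the sliding window of ``window``
    points on ln(OD) with the highest R^2 among windows with positive slope;
    windows containing zero OD are skipped. Returns (hours, reason) with
    hours None when no window reaches the R^2 floor.
    """
    n = curve.time.size
    w = min(window, n)
    if w < 3:
        return None, "too few points"
    best = None
    for start in range(0, n - w + 1):
        t = curve.time[start:start + w]
        od = curve.od[start:start + w]
        if np.any(od <= 0):
            continue
        res = linregress(t, np.log(od))
        if res.slope <= 0:
            continue
        r2 = res.rvalue ** 2
        if best is None or r2 > best[0]:
            best = (r2, res.slope)
    if best is None:
        return None, "no window with positive growth"
    if best[0] < r2_floor:
        return None, f"best window R^2 {best[0]:.4f} below floor {r2_floor}"
    return float(np.log(2) / best[1]), "ok"


def normalize_to_control(doubling_times: pd.DataFrame,
                         wildtype: str = "WT") -> pd.DataFrame:
    """Divide each mutant doubling time by the mean wild-type doubling time
    of its own batch.

    ``doubling_times`` needs columns strain, batch, doubling_time. Batches
    without a wild-type replicate are an error naming the batch.
    """
    req = {"strain", "batch", "doubling_time"}
    if not req <= set(doubling_times.columns):
        raise ValueError(f"need columns {sorted(req)}")
    wt_mean = (doubling_times[doubling_times["strain"] == wildtype]
               .groupby("batch")["doubling_time"].mean())
    out = doubling_times.copy()
    missing = sorted(set(out["batch"]) - set(wt_mean.index))
    if missing:
        raise ValueError(f"batches without wild-type control: {missing}")
    out["normalized"] = (out["doubling_time"]
                         / out["batch"].map(wt_mean).to_numpy())
    return out
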