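"""Single-component cosinor analysis and actograms.

Circadian rhythmicity of corner-visiting activity is quantified by
ordinary least squares of binned counts on a 24-h sinusoid,

    y(t) = M + beta1 * cos(w t) + beta2 * sin(w t),   w = 2 pi / period,

giving the mesor M (rhythm-adjusted mean), the amplitude
A = sqrt(beta1^2 + beta2^2) (half the peak-to-trough range) and the
acrophase, reported here as the wall-clock hour of the fitted peak in
[0, 24).  Zero rhythmicity is tested with the F test of
(beta1, beta2) = (0, 0).  The period is fixed at 24 h: the experiments
probe entrainment to the light cycle, not free-running period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import ExperimentMetadata

__all__ = ["CosinorFit", "cosinor_fit", "actogram"]


@dataclass
class CosinorFit:
    """Parameters of a fitted 24-h rhythm.

    ``acrophase_h`` is NaN (and ``constant`` True) for a flat series,
    where the phase is undefined.
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    r_squared: float
    zero_amplitude_p: float
    constant: bool = False


def cosinor_fit(
    t_h: np.ndarray, y: np.ndarray, period_h: float = 24.0
) -> CosinorFit:
    """Least-squares cosinor fit of binned activity.

    Parameters
    ----------
    t_h
        Bin-center times in hours (bin centers, not edges, are the
        regression abscissae).
    y
        Activity per bin (e.g. visits/h), same length as ``t_h``.
    period_h
        Fixed rhythm period, hours.

    Notes
    -----
    Requires at least 4 bins spanning at least one period.  A constant
    series returns amplitude 0, undefined acrophase and p = 1 rather
    than raising.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    n = t.size
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 bins")
    if t.max() - t.min() < period_h - (t[1] - t[0] if n > 1 else 0.0):
        raise ValueError("bins must span at least one full period")

    if np.ptp(y) == 0.0:
        return CosinorFit(
            mesor=float(y[0]) if n else 0.0,
            amplitude=0.0,
            acrophase_h=float("nan"),
            period_h=period_h,
            r_squared=0.0,
            zero_amplitude_p=1.0,
            constant=True,
        )

    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = beta
    amplitude = float(np.hypot(b1, b2))
    # peak of M + A*cos(w(t - phi)) with b1 = A cos(w phi), b2 = A sin(w phi)
    acro = float((np.arctan2(b2, b1) / w) % period_h)

    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # F test of the rhythm terms (2 numerator df) against the flat model
    df_res = n - 3
    if df_res > 0 and ss_res > 0:
        f = ((ss_tot - ss_res) / 2.0) / (ss_res / df_res)
        p = float(stats.f.sf(f, 2, df_res))
    elif df_res > 0:
        p = 0.0  # perfect fit of a non-constant series
    else:
        p = float("nan")
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_h=acro,
        period_h=period_h,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        zero_amplitude_p=p,
    )


def actogram(
    visits: pd.DataFrame,
    meta: ExperimentMetadata,
    bin_min: int = 30,
    double_plot: bool = False,
) -> np.ndarray:
    """Day x bin matrix of visit counts for actogram display.

    Each row is one 24-h day (day 0 starts at t = 0), each column one
    ``bin_min``-minute bin of the day, each value a visit count.  With
    ``double_plot`` True, row d is the concatenation of days d and d+1
    (the conventional 48-h double plot; the last row wraps onto zeros).
    """
    if 1440 % bin_min != 0:
        raise ValueError("bin_min must divide 24*60")
    t = visits["start_time_s"].to_numpy() / 3600.0  # hours since start
    n_days = max(1, int(np.ceil((t.max() + 1e-9) / 24.0))) if t.size else 1
    bins_per_day = 1440 // bin_min
    mat = np.zeros((n_days, bins_per_day), dtype=int)
    if t.size:
        day = np.minimum((t // 24).astype(int), n_days - 1)
        b = np.minimum(
            ((t % 24) * 60 / bin_min).astype(int), bins_per_day - 1
        )
        np.add.at(mat, (day, b), 1)
    if double_plot:
        nxt = np.vstack([mat[1:], np.zeros((1, bins_per_day), dtype=int)])
        mat = np.hstack([mat, nxt])
    return mat
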