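"""Field-potential quantification: fEPSP slope, I/O curves, and LTP.

Extracellular field excitatory postsynaptic potentials (fEPSPs) evoked
in stratum radiatum are quantified by the initial (10-90%) slope of
their negative-going deflection, the standard index of synaptic
strength.  Input-output (I/O) curves relate stimulation intensity to
that slope; their trapezoidal AUC indexes network excitability, and the
intensity evoking ~30% of the fitted maximum response is the one used
for long-term potentiation (LTP) induction.  LTP time courses are
expressed as percent of the pre-induction baseline average, with the
AUC taken from induction (t = 0) to the end of the recording.

Sweeps are expected at a uniform sampling rate (10 kHz typical), as a
long-format table ``slice_id, sweep_id, stim_intensity, t_ms, v_mV`` or
as :class:`Sweep` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .metrics import auc_trapezoid

__all__ = [
    "Sweep",
    "IOCurve",
    "LTPSeries",
    "initial_slope",
    "io_curve",
    "gaussian_auc_distribution",
    "ltp_series",
    "excitability_ltp_regression",
    "sweeps_from_table",
]


@dataclass
class Sweep:
    """One evoked field-potential trace.

    ``t_ms``/``v_mV`` must be uniformly sampled and equally long;
    ``stim_time_ms`` marks the stimulus so the artifact can be blanked.
    """

    t_ms: np.ndarray
    v_mV: np.ndarray
    stim_intensity: float = 0.0
    stim_time_ms: float = 0.0
    slice_id: str = ""
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        if self.t_ms.shape != self.v_mV.shape:
            raise ValueError("time and voltage must be equally long")
        dt = np.diff(self.t_ms)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sweep must be uniformly sampled")


@dataclass
class IOCurve:
    """Per-intensity initial slopes with their trapezoidal AUC."""

    intensities: np.ndarray
    slopes: np.ndarray  # mV/ms, positive magnitude
    auc: float
    fitted_max: float
    intensity_at_30pct: float


@dataclass
class LTPSeries:
    """Baseline-normalized slope time course around TBS (t = 0 min)."""

    t_min: np.ndarray
    pct_baseline: np.ndarray
    baseline_window_min: float
    auc: float  # % x min, from t=0 to the end
    baseline_slope: float = field(default=float("nan"))


# peak search window after the stimulus: skip a 1-ms artifact blank and
# look out to 20 ms, typical for CA1 field recordings
ARTIFACT_BLANK_MS = 1.0
SEARCH_END_MS = 20.0


def initial_slope(
    sweep: Sweep, noise_floor_mV: float = 0.01
) -> float | None:
    """Initial (10-90%) slope of the fEPSP, in mV/ms, magnitude positive.

    The negative peak is searched 1-20 ms after the stimulus (1-ms
    artifact blank); baseline is the pre-stimulus mean.  The slope is
    the least-squares fit over the samples on the falling (onset) phase
    whose deflection lies between 10% and 90% of the peak deflection,
    nearest-sample, no interpolation.  Returns None (flagged missing)
    when no deflection exceeds ``noise_floor_mV``.

    The measure is invariant to DC offsets and scales linearly with the
    voltage — both properties of a slope on a baseline-referenced wave.
    """
    t, v = sweep.t_ms, sweep.v_mV
    pre = t < sweep.stim_time_ms
    baseline = float(v[pre].mean()) if pre.any() else float(v[0])

    lo = sweep.stim_time_ms + ARTIFACT_BLANK_MS
    hi = sweep.stim_time_ms + SEARCH_END_MS
    win = (t >= lo) & (t <= hi)
    if not win.any():
        return None
    idx_win = np.flatnonzero(win)
    # sample selection runs on a lightly smoothed copy (0.5-ms boxcar) so
    # noise does not correlate with inclusion at the band edges, which
    # would flatten the fitted slope; the fit itself uses raw samples
    if idx_win.size >= 5:
        kernel = np.ones(5) / 5.0
        v_sel = np.convolve(v, kernel, mode="same")
    else:
        v_sel = v
    depth = baseline - v_sel[idx_win]  # positive = downward deflection
    if (baseline - v[idx_win]).max() <= noise_floor_mV:
        return None
    peak_rel = int(np.argmax(depth))
    peak_depth = depth[peak_rel]
    if peak_depth <= 0:
        return None

    # falling (onset) phase: walk back from the peak through the
    # contiguous limb above 10% depth, keeping samples at <= 90% depth —
    # this excludes pre-onset baseline samples in the depth band
    pts = []
    for i in range(peak_rel, -1, -1):
        if depth[i] < 0.1 * peak_depth:
            break
        if depth[i] <= 0.9 * peak_depth:
            pts.append(idx_win[i])
    pts = np.asarray(pts[::-1], dtype=int)
    if pts.size < 2:
        return None
    slope, _ = np.polyfit(t[pts], v[pts], 1)
    return float(abs(slope))


def io_curve(sweeps: list[Sweep], ltp_fraction: float = 0.30) -> IOCurve:
    """Input-output relationship over a series of increasing intensities.

    Computes the initial slope per sweep, the trapezoidal AUC of slope
    versus intensity, a sigmoid (logistic) fit of the maximum response,
    and the recorded intensity whose response is nearest
    ``ltp_fraction`` (default 30%) of that fitted maximum — the
    intensity conventionally used for LTP induction.
    """
    if len(sweeps) < 5:
        raise ValueError("I/O curve needs sweeps at >= 5 intensities")
    intensities = np.array([s.stim_intensity for s in sweeps], dtype=float)
    if np.any(np.diff(intensities) <= 0):
        raise ValueError("stimulus intensities must be strictly increasing")
    slopes = np.array(
        [s if (s := initial_slope(sw)) is not None else 0.0 for sw in sweeps]
    )
    auc = auc_trapezoid(intensities, slopes)

    def logistic(x, top, x50, k):
        return top / (1.0 + np.exp(-(x - x50) / k))

    span = intensities.max() - intensities.min()
    try:
        popt, _ = optimize.curve_fit(
            logistic,
            intensities,
            slopes,
            p0=[max(slopes.max(), 1e-9), np.median(intensities), max(span / 5, 1e-9)],
            maxfev=5000,
        )
        fitted_max = float(popt[0])
    except RuntimeError:
        fitted_max = float(slopes.max())
    target = ltp_fraction * fitted_max
    at30 = float(intensities[int(np.argmin(np.abs(slopes - target)))])
    return IOCurve(
        intensities=intensities,
        slopes=slopes,
        auc=float(auc),
        fitted_max=fitted_max,
        intensity_at_30pct=at30,
    )


def gaussian_auc_distribution(aucs: np.ndarray) -> tuple[float, float, object]:
    """Maximum-likelihood normal fit of per-slice AUCs.

    Returns ``(mean, sd, frozen_normal)``; the ML sd uses ddof = 0.
    Raises on fewer than 3 values; a zero-variance sample is flagged
    with a ValueError (degenerate fit).
    """
    x = np.asarray(aucs, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 AUC values")
    mu = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate (zero-variance) AUC sample")
    return mu, sd, sps.norm(mu, sd)


def ltp_series(
    sweeps: list[Sweep],
    tbs_time_min: float,
    baseline_window_min: float = 20.0,
) -> LTPSeries:
    """Baseline-normalized LTP time course with its post-induction AUC.

    Initial slopes of all sweeps are expressed as percent of the mean
    slope in the ``baseline_window_min`` minutes before theta-burst
    stimulation (so the baseline mean is 100% by construction), times
    are re-referenced to TBS at t = 0, and the AUC (% x min) is taken
    from t = 0 to the last sweep.
    """
    times = np.array([s.timestamp_min for s in sweeps], dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    slopes = np.array(
        [
            s if (s := initial_slope(sweeps[i])) is not None else np.nan
            for i in order
        ]
    )
    base_mask = (times < tbs_time_min) & (times >= tbs_time_min - baseline_window_min)
    base = slopes[base_mask]
    base = base[~np.isnan(base)]
    if base.size < 10:
        raise ValueError("need >= 10 baseline sweeps before TBS")
    base_mean = float(base.mean())
    if base_mean == 0:
        raise ValueError("zero baseline slope")
    pct = 100.0 * slopes / base_mean
    t_rel = times - tbs_time_min
    post = t_rel >= 0
    if post.sum() < 2:
        raise ValueError("need >= 2 post-TBS sweeps for the AUC")
    auc = auc_trapezoid(t_rel[post], pct[post])
    return LTPSeries(
        t_min=t_rel,
        pct_baseline=pct,
        baseline_window_min=baseline_window_min,
        auc=float(auc),
        baseline_slope=base_mean,
    )


def excitability_ltp_regression(
    io_aucs: np.ndarray, ltp_aucs: np.ndarray, ci: float = 0.90
) -> dict[str, float]:
    """OLS of LTP AUC on the square root of the I/O AUC, per slice.

    The square-root transform linearizes the excitability index before
    regressing the potentiation magnitude on it.  Returns slope,
    intercept, Pearson r, and the two-sided confidence interval for the
    slope at the requested level (default 90%).
    """
    x = np.sqrt(np.asarray(io_aucs, dtype=float))
    y = np.asarray(ltp_aucs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.5 + ci / 2.0, x.size - 2)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "slope_ci_low": float(res.slope - tcrit * res.stderr),
        "slope_ci_high": float(res.slope + tcrit * res.stderr),
    }


def sweeps_from_table(table: pd.DataFrame) -> dict[str, list[Sweep]]:
    """Group a long-format sweep table into Sweep objects per slice.

    Expected columns: ``slice_id, sweep_id, stim_intensity, t_ms, v_mV``
    and optionally ``stim_time_ms`` and ``timestamp_min`` (constant per
    sweep).
    """
    out: dict[str, list[Sweep]] = {}
    for (sid, swid), sub in table.groupby(["slice_id", "sweep_id"], sort=True):
        sub = sub.sort_values("t_ms", kind="stable")
        out.setdefault(str(sid), []).append(
            Sweep(
                t_ms=sub["t_ms"].to_numpy(),
                v_mV=sub["v_mV"].to_numpy(),
                stim_intensity=float(sub["stim_intensity"].iloc[0]),
                stim_time_ms=(
                    float(sub["stim_time_ms"].iloc[0])
                    if "stim_time_ms" in sub.columns
                    else 0.0
                ),
                slice_id=str(sid),
                timestamp_min=(
                    float(sub["timestamp_min"].iloc[0])
                    if "timestamp_min" in sub.columns
                    else 0.0
                ),
            )
        )
    return out
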