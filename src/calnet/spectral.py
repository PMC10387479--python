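"""Welch spectra, dB band power and depth-resolved power maps.

The full waveform of each neuron's dF/Fmin trace is summarized by its
Welch power spectral density and the total band power (in dB re 1 unit^2
of dF/F).  Powers are resolved along the normalized cortical depth as a
2-D proportion map, separately for the baseline period and the
post-stimulus period (optionally subdivided into 150-s windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import CalnetError, StimulusProtocol

__all__ = [
    "PowerSpectrum",
    "DepthPowerMap",
    "welch_power",
    "split_periods",
    "depth_power_map",
    "compare_power",
]

DEFAULT_NPERSEG = 256
SILENT_DB = -np.inf  # sentinel for zero-power ("silent") traces


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    psd: np.ndarray                # one-sided density, unit^2/Hz
    band_power: float              # integral of psd over the band, unit^2
    band_power_db: float           # 10*log10(band_power), -inf if silent
    segment_params: dict

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise CalnetError("psd must be non-negative")


def welch_power(
    trace: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
) -> PowerSpectrum:
    """Welch PSD of one trace plus its total band power.

    Segments default to ``min(256, len(trace))`` samples with 50% overlap
    and a Hann taper; one-sided density convention, so the integral of the
    PSD over the band approximates the trace variance.
    """
    trace = np.asarray(trace, dtype=float)
    if nperseg is None:
        nperseg = min(DEFAULT_NPERSEG, trace.size)
    if trace.size < nperseg:
        raise CalnetError(
            f"trace of {trace.size} samples is shorter than one segment "
            f"({nperseg}); use a smaller nperseg"
        )
    if not (0 <= overlap < 1):
        raise CalnetError("overlap must be in [0, 1)")
    freqs, psd = sps.welch(
        trace,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    band_power = float(np.trapezoid(psd, freqs))
    band_db = SILENT_DB if band_power <= 0 else float(10 * np.log10(band_power))
    return PowerSpectrum(
        frequencies=freqs,
        psd=psd,
        band_power=band_power,
        band_power_db=band_db,
        segment_params={"nperseg": nperseg, "overlap": overlap, "window": window},
    )


def split_periods(
    traces: np.ndarray,
    protocol: StimulusProtocol,
    subwindow_seconds: float | None = None,
) -> dict:
    """Split traces into the baseline and post-stimulus major periods.

    The basal period covers frames ``[0, stim_onset*fs)`` and the
    post-stimulus period the remainder of the recording.  If
    ``subwindow_seconds`` is given, the post period is additionally cut
    into ``floor(post_duration / subwindow_seconds)`` consecutive
    sub-windows (trailing frames dropped).  Returns a dict with ``basal``,
    ``post`` slices of the input and ``subwindows`` (list of arrays).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_frames = traces.shape[1]
    split = int(round(protocol.stim_onset * protocol.fs))
    if split <= 0:
        raise CalnetError("stimulus at t=0 leaves an empty basal period")
    if split >= n_frames:
        raise CalnetError("stimulus onset lies outside the recording")
    out = {
        "basal": traces[:, :split],
        "post": traces[:, split:],
        "basal_frames": (0, split),
        "post_frames": (split, n_frames),
        "subwindows": [],
        "subwindow_frames": [],
    }
    if subwindow_seconds is not None:
        w = int(round(subwindow_seconds * protocol.fs))
        if w < 2:
            raise CalnetError("sub-window too short")
        k = (n_frames - split) // w
        for q in range(k):
            a, b = split + q * w, split + (q + 1) * w
            out["subwindows"].append(traces[:, a:b])
            out["subwindow_frames"].append((a, b))
    return out


@dataclass
class DepthPowerMap:
    depth_edges: np.ndarray
    db_edges: np.ndarray
    proportions: np.ndarray   # (n_depth_bins, n_db_bins), sums to 1
    n_neurons: int            # neurons included in the map
    n_silent: int             # neurons dropped for zero power
    period_label: str

    def __post_init__(self) -> None:
        if self.n_neurons:
            total = float(self.proportions.sum())
            if abs(total - 1.0) > 1e-9:
                raise CalnetError(f"proportions sum to {total}, expected 1")


def depth_power_map(
    band_power_db: np.ndarray,
    depths: np.ndarray,
    depth_step: float = 0.1,
    db_step: float = 1.0,
    period_label: str = "basal",
) -> DepthPowerMap:
    """2-D histogram of (depth, dB power), normalized to the neuron count.

    Silent neurons (dB = -inf) are excluded from the histogram and counted
    in ``n_silent``.  An empty input yields an all-zero map with
    ``n_neurons = 0`` (flagged by that count).
    """
    band_power_db = np.asarray(band_power_db, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if band_power_db.shape != depths.shape:
        raise CalnetError("need exactly one depth per spectrum")
    finite = np.isfinite(band_power_db)
    n_silent = int((~finite).sum())
    db = band_power_db[finite]
    dp = depths[finite]

    depth_edges = np.arange(0, 1 + depth_step / 2, depth_step)
    if db.size:
        lo = np.floor(db.min() / db_step) * db_step
        hi = np.ceil(db.max() / db_step) * db_step
        if hi <= lo:
            hi = lo + db_step
        db_edges = np.arange(lo, hi + db_step / 2, db_step)
        counts, _, _ = np.histogram2d(dp, db, bins=[depth_edges, db_edges])
        props = counts / counts.sum()
    else:
        db_edges = np.array([0.0, db_step])
        props = np.zeros((depth_edges.size - 1, 1))
    return DepthPowerMap(
        depth_edges=depth_edges,
        db_edges=db_edges,
        proportions=props,
        n_neurons=int(db.size),
        n_silent=n_silent,
        period_label=period_label,
    )


@dataclass
class PowerComparison:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    degenerate: bool   # True when both groups have zero variance


def compare_power(group_a: np.ndarray, group_b: np.ndarray) -> PowerComparison:
    """Two-sided two-sample t-test on dB band-power values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CalnetError("need at least 2 values per group")
    if a.var() == 0 and b.var() == 0:
        equal = float(a.mean()) == float(b.mean())
        return PowerComparison(
            statistic=0.0 if equal else np.inf,
            pvalue=1.0 if equal else 0.0,
            n_a=a.size, n_b=b.size, degenerate=True,
        )
    t, p = stats.ttest_ind(a, b)
    return PowerComparison(float(t), float(p), a.size, b.size, False)
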