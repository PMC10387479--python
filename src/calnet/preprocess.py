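"""Trace normalization, filtering, detrending and neuron selection.

The processing order matches the acquisition pipeline the analysis was
built for: raw fluorescence is normalized to dF/Fmin per ROI, low-pass
filtered with a third-order Bessel filter, then corrected for
photobleaching by removing a least-squares linear trend.  Neurons are then
screened for reactivity: a neuron is kept only if its band power during
the 30-s pilocarpine stimulus clearly exceeds its baseline power
distribution (2-SD rule), it likewise responds to the late KCl stimulus,
and it shows activity (non-zero variance) in every stage of the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import CalciumRecording, CalnetError, DegenerateTraceError, StimulusProtocol

__all__ = [
    "ProcessedTraces",
    "normalize_dff",
    "bessel_lowpass",
    "correct_bleaching",
    "process_recording",
    "select_responsive_neurons",
]

DEFAULT_CUTOFF_HZ = 0.5


def normalize_dff(
    trace: np.ndarray,
    fmin_percentile: float | None = None,
    neuron_id: str = "?",
) -> tuple[np.ndarray, float]:
    """dF/Fmin normalization: ``(F - Fmin) / Fmin``.

    ``Fmin`` is the trace minimum by default, or a lower percentile (e.g. 5)
    for noisy data.  Returns the normalized trace and the Fmin used.
    Traces whose Fmin is non-positive cannot be expressed as a relative
    change and raise :class:`DegenerateTraceError`.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise CalnetError("trace must have at least 2 samples")
    if fmin_percentile is None:
        fmin = float(trace.min())
    else:
        if not (0 <= fmin_percentile <= 50):
            raise CalnetError("fmin_percentile must be in [0, 50]")
        fmin = float(np.percentile(trace, fmin_percentile))
    if fmin <= 0:
        raise DegenerateTraceError(
            f"neuron {neuron_id}: Fmin={fmin:g} is not positive; "
            "dF/Fmin is undefined for this trace"
        )
    return (trace - fmin) / fmin, fmin


def bessel_lowpass(
    trace: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fs: float = 3.3,
    order: int = 3,
    zero_phase: bool = True,
) -> np.ndarray:
    """Third-order Bessel low-pass filter with unit DC gain.

    The filter is designed with the -3 dB point at ``cutoff`` and applied
    forward-backward by default (zero phase, so transient onsets are not
    delayed; the effective magnitude response is squared).  Set
    ``zero_phase=False`` for a causal single pass.
    """
    trace = np.asarray(trace, dtype=float)
    nyq = fs / 2.0
    if not (0 < cutoff < nyq):
        raise CalnetError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.bessel(order, cutoff, btype="low", fs=fs, output="sos", norm="mag")
    if zero_phase:
        return sps.sosfiltfilt(sos, trace)
    return sps.sosfilt(sos, trace)


def correct_bleaching(trace: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Remove a linear photobleaching trend fitted to the whole trace.

    An ordinary least-squares line ``intercept + slope*frame`` is fitted and
    the slope term removed, so an exactly linear input becomes constant at
    its intercept.  Returns (corrected trace, slope per frame, intercept).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise CalnetError("trace must have at least 3 samples for a trend fit")
    frames = np.arange(trace.size, dtype=float)
    slope, intercept = np.polyfit(frames, trace, 1)
    return trace - slope * frames, float(slope), float(intercept)


@dataclass
class ProcessedTraces:
    """Normalized, filtered, detrended traces plus the selection report."""

    dff: np.ndarray                       # neuron x frame, dF/Fmin units
    fmin: np.ndarray                      # per-neuron Fmin used
    filter_cutoff: float
    bleach_coefficients: np.ndarray       # (n, 2): slope per frame, intercept
    fs: float
    depths: np.ndarray
    protocol: StimulusProtocol
    neuron_ids: list[str]
    selection_mask: np.ndarray | None = None
    selection_report: pd.DataFrame | None = None
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]


def process_recording(
    rec: CalciumRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fmin_percentile: float | None = None,
    zero_phase: bool = True,
) -> ProcessedTraces:
    """Run normalize -> Bessel filter -> bleach correction on every neuron.

    Neurons with non-positive Fmin are excluded (their rows are zero and
    recorded in ``excluded``) rather than aborting the whole recording.
    """
    n, m = rec.fluorescence.shape
    dff = np.zeros((n, m))
    fmin = np.full(n, np.nan)
    coeffs = np.zeros((n, 2))
    excluded: dict[str, str] = {}
    for i in range(n):
        nid = rec.neuron_ids[i]
        try:
            d, f = normalize_dff(rec.fluorescence[i], fmin_percentile, neuron_id=nid)
        except DegenerateTraceError as err:
            excluded[nid] = str(err)
            continue
        d = bessel_lowpass(d, cutoff=cutoff, fs=rec.fs, zero_phase=zero_phase)
        d, slope, intercept = correct_bleaching(d)
        dff[i] = d
        fmin[i] = f
        coeffs[i] = (slope, intercept)
    return ProcessedTraces(
        dff=dff,
        fmin=fmin,
        filter_cutoff=cutoff,
        bleach_coefficients=coeffs,
        fs=rec.fs,
        depths=rec.depths.copy(),
        protocol=rec.protocol,
        neuron_ids=list(rec.neuron_ids),
        excluded=excluded,
    )


def _band_power(trace: np.ndarray, fs: float) -> float:
    """Total band power of a segment (Welch PSD integrated over the band)."""
    from .spectral import welch_power  # local import: spectral builds on preprocess types

    return welch_power(trace, fs).band_power


def _stage_intervals(protocol: StimulusProtocol) -> dict[str, tuple[int, int]]:
    s0, s1 = protocol.stim_interval
    k0, k1 = protocol.kcl_interval
    T = protocol.total_duration
    return {
        "baseline": protocol.to_frames(0.0, protocol.baseline_span),
        "stimulus": protocol.to_frames(s0, min(s1, T)),
        "washout": protocol.to_frames(min(s1, T), k0),
        "kcl": protocol.to_frames(k0, min(k1, T)),
    }


def select_responsive_neurons(
    proc: ProcessedTraces,
    k_sd: float = 2.0,
    rule: str = "mean",
    segment_seconds: float | None = None,
    overlap: float = 0.5,
) -> ProcessedTraces:
    """Apply the 2-SD reactivity screen and the all-stage activity screen.

    Baseline band power is sampled over sliding sub-segments of the baseline
    interval (length = the stimulus duration by default, 50% overlap) to
    obtain a per-neuron distribution (mean, SD, max).  Under the default
    ``rule='mean'`` a neuron is responsive to a stimulus if its
    stimulus-interval band power exceeds ``baseline_mean + k_sd*SD``;
    ``rule='max'`` uses the literal maximum-anchored variant
    ``baseline_max - k_sd*SD``.  Retained neurons are responsive to both the
    pilocarpine and the KCl stimulus and have non-zero variance in every
    stage.  The applied rule is recorded in the report so downstream results
    state which variant produced them.
    """
    if rule not in ("mean", "max"):
        raise CalnetError("rule must be 'mean' or 'max'")
    if k_sd < 0:
        raise CalnetError("k_sd must be non-negative")
    protocol = proc.protocol
    fs = proc.fs
    n_frames = proc.dff.shape[1]
    stages = _stage_intervals(protocol)
    for name, (a, b) in stages.items():
        if not (0 <= a < b <= n_frames):
            raise CalnetError(
                f"stage {name!r} frames [{a}, {b}) do not fit the recording "
                f"of {n_frames} frames"
            )
    if segment_seconds is None:
        segment_seconds = protocol.stim_duration
    seg_len = int(round(segment_seconds * fs))
    if seg_len < 8:
        raise CalnetError("baseline sub-segments are too short")
    step = max(1, int(round(seg_len * (1 - overlap))))

    b0, b1 = stages["baseline"]
    starts = list(range(b0, b1 - seg_len + 1, step))
    if not starts:
        raise CalnetError("baseline too short for one sub-segment")

    rows = []
    mask = np.zeros(proc.n_neurons, dtype=bool)
    for i in range(proc.n_neurons):
        nid = proc.neuron_ids[i]
        trace = proc.dff[i]
        if nid in proc.excluded:
            rows.append(_report_row(nid, False, proc.excluded[nid]))
            continue
        stage_vars = {k: float(trace[a:b].var()) for k, (a, b) in stages.items()}
        if any(v <= 0 for v in stage_vars.values()):
            silent = [k for k, v in stage_vars.items() if v <= 0]
            rows.append(_report_row(nid, False, f"zero variance in {','.join(silent)}"))
            continue
        base_powers = np.array(
            [_band_power(trace[s : s + seg_len], fs) for s in starts]
        )
        bmean = float(base_powers.mean())
        bsd = float(base_powers.std(ddof=1)) if base_powers.size > 1 else 0.0
        bmax = float(base_powers.max())
        stim_p = _band_power(trace[slice(*stages["stimulus"])], fs)
        kcl_p = _band_power(trace[slice(*stages["kcl"])], fs)
        if rule == "mean":
            pilo = stim_p > bmean + k_sd * bsd
            kcl = kcl_p > bmean + k_sd * bsd
        else:
            pilo = stim_p > bmax - k_sd * bsd
            kcl = kcl_p > bmax - k_sd * bsd
        retained = bool(pilo and kcl)
        reason = "retained" if retained else (
            "not pilocarpine-responsive" if not pilo else "not KCl-responsive"
        )
        mask[i] = retained
        rows.append(
            _report_row(
                nid, retained, reason,
                baseline_mean_power=bmean, baseline_sd_power=bsd,
                baseline_max_power=bmax, stim_power=stim_p, kcl_power=kcl_p,
                pilo_responsive=bool(pilo), kcl_responsive=bool(kcl),
            )
        )

    report = pd.DataFrame(rows)
    report.attrs["rule"] = rule
    report.attrs["k_sd"] = k_sd
    proc.selection_mask = mask
    proc.selection_report = report
    return proc


def _report_row(neuron_id: str, retained: bool, reason: str, **stats) -> dict:
    row = {
        "neuron_id": neuron_id,
        "retained": retained,
        "reason": reason,
        "baseline_mean_power": math.nan,
        "baseline_sd_power": math.nan,
        "baseline_max_power": math.nan,
        "stim_power": math.nan,
        "kcl_power": math.nan,
        "pilo_responsive": False,
        "kcl_responsive": False,
    }
    row.update(stats)
    return row
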