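"""Shared domain types for slice calcium-imaging analysis.

A recording is a neuron-by-frame fluorescence matrix acquired at a fixed
frame rate from one cortical slice, together with one normalized cortical
depth per neuron (0 = white-matter interface, 1 = pial surface) and the
stimulation protocol that structured the session (baseline perfusion, a
brief muscarinic stimulus, and a late KCl stimulus used to census
responsive cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CalnetError(Exception):
    """Base class for input/validation errors raised by this package."""


class DegenerateTraceError(CalnetError):
    """A trace cannot be processed (e.g. non-positive Fmin), names the neuron."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of one slice recording session.

    All times are in seconds from recording onset.  ``baseline_span`` is the
    stretch of stimulus-free baseline used to build the per-neuron baseline
    power distribution; it must end strictly before the stimulus.

    Defaults follow the acquisition scheme the analysis was designed for:
    3.3 Hz frame rate, 3 min of baseline perfusion before a 30-s pilocarpine
    stimulus, a 30-s KCl stimulus near the end, 750 s analysed in total.
    """

    fs: float = 3.3
    baseline_span: float = 150.0
    stim_onset: float = 180.0
    stim_duration: float = 30.0
    kcl_onset: float = 700.0
    kcl_duration: float = 30.0
    total_duration: float = 750.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise CalnetError(f"sampling rate must be positive, got {self.fs}")
        if not (0 <= self.baseline_span < self.stim_onset < self.kcl_onset):
            raise CalnetError(
                "protocol requires 0 <= baseline_span < stim_onset < kcl_onset; got "
                f"baseline_span={self.baseline_span}, stim_onset={self.stim_onset}, "
                f"kcl_onset={self.kcl_onset}"
            )
        for name in ("stim_duration", "kcl_duration", "total_duration"):
            if getattr(self, name) <= 0:
                raise CalnetError(f"{name} must be positive")
        if self.total_duration < self.kcl_onset + self.kcl_duration:
            raise CalnetError(
                "total_duration must cover the KCl stimulus: "
                f"{self.total_duration} < {self.kcl_onset + self.kcl_duration}"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration * self.fs))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def to_frames(self, t0: float, t1: float) -> tuple[int, int]:
        """Half-open frame interval [round(t0*fs), round(t1*fs))."""
        return int(round(t0 * self.fs)), int(round(t1 * self.fs))

    @property
    def stim_interval(self) -> tuple[float, float]:
        return self.stim_onset, self.stim_onset + self.stim_duration

    @property
    def kcl_interval(self) -> tuple[float, float]:
        return self.kcl_onset, self.kcl_onset + self.kcl_duration


@dataclass
class CalciumRecording:
    """Raw fluorescence matrix (neurons x frames) plus per-neuron depth."""

    fluorescence: np.ndarray
    fs: float
    depths: np.ndarray
    protocol: StimulusProtocol
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.fluorescence.ndim != 2:
            raise CalnetError("fluorescence must be a 2-D neuron x frame matrix")
        if not np.all(np.isfinite(self.fluorescence)):
            bad = np.argwhere(~np.isfinite(self.fluorescence))[0]
            raise CalnetError(
                f"non-finite fluorescence at neuron index {bad[0]}, frame {bad[1]}"
            )
        if self.fs <= 0:
            raise CalnetError("fs must be positive")
        n = self.fluorescence.shape[0]
        if self.depths.shape != (n,):
            raise CalnetError("depths length must equal neuron count")
        if np.any((self.depths < 0) | (self.depths > 1)):
            raise CalnetError("depths must lie in [0, 1]")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:04d}" for i in range(n)]
        if len(self.neuron_ids) != n:
            raise CalnetError("neuron_ids length must equal neuron count")

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]
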