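"""Deterministic sensor-data conditioning.

Notch and bandpass filtering, resampling, epoching with baseline
correction, and correct-trial selection. All filters are 4th-order
Butterworth IIR applied forward-backward (zero phase, no latency shift) in
second-order sections; this family is unremarkable on purpose — the study's
contribution lives downstream, and a stable zero-phase filter with a
documented order is all the conditioning stage needs. The 0.1-Hz corner of
the slow band is handled with odd-reflection padding over the full record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .errors import InvalidConfigError, InvalidInputError, NoCorrectTrialsError

logger = logging.getLogger(__name__)

FILTER_ORDER = 4


@dataclass
class EpochSet:
    """Epoched sensor data for one condition.

    Attributes
    ----------
    data : ndarray, shape (trials, sensors, samples)
    fs_hz : float
    t0_ms : float
        Time of the first sample relative to stimulus onset (<= 0; default
        -100 so each epoch carries a 100-ms baseline).
    condition : str
        "memorized" or "novel".
    trial_correct : ndarray of bool or None
        Behavioural correctness per trial.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    condition: str
    trial_correct: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidInputError("epoch data must be (trials, sensors, samples)")
        if self.t0_ms > 0:
            raise InvalidInputError("t0_ms must be <= 0")
        if self.trial_correct is not None and len(self.trial_correct) != len(
            self.data
        ):
            raise InvalidInputError("trial_correct length must match trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.data.shape[2]) * 1000.0 / self.fs_hz


def _sosfiltfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # odd-reflection padding over as much of the record as scipy allows,
    # which stabilises the very low 0.1 Hz corner on finite records
    padlen = min(data.shape[-1] - 1, 3 * 10 * (FILTER_ORDER + 1))
    return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)


def notch_filter(
    data: np.ndarray, fs: float, band: tuple[float, float] = (48.0, 52.0)
) -> np.ndarray:
    """Zero-phase band-stop filter (default 48-52 Hz, power-line band)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise InvalidConfigError(f"notch band {band} must lie within (0, fs/2)")
    sos = signal.butter(FILTER_ORDER, band, btype="bandstop", fs=fs, output="sos")
    return _sosfiltfilt(sos, np.asarray(data, dtype=float))


def bandpass_filter(
    data: np.ndarray, fs: float, band: tuple[float, float] = (0.1, 1.0)
) -> np.ndarray:
    """Zero-phase band-pass filter (default the slow 0.1-1 Hz band used for
    sequence-recognition activity); removes DC."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise InvalidConfigError(f"bandpass band {band} must satisfy 0 < low < high < fs/2")
    sos = signal.butter(FILTER_ORDER, band, btype="bandpass", fs=fs, output="sos")
    return _sosfiltfilt(sos, np.asarray(data, dtype=float))


def resample(data: np.ndarray, fs_in: float, fs_out: float = 150.0) -> np.ndarray:
    """Downsample along the last axis with polyphase anti-alias filtering.

    The output length is ``ceil(n * fs_out / fs_in)`` (scipy's polyphase
    rule); e.g. 1000 samples at 1000 Hz resample to exactly 150 at 150 Hz.
    """
    if fs_out >= fs_in:
        raise InvalidConfigError("fs_out must be < fs_in")
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    # sharp Kaiser window + linear edge extension: DC passes exactly and
    # edge transients stay small
    return signal.resample_poly(
        np.asarray(data, dtype=float),
        frac.numerator,
        frac.denominator,
        axis=-1,
        window=("kaiser", 10.0),
        padtype="line",
    )


def epoch_and_baseline(
    continuous: np.ndarray,
    events: Sequence[int],
    fs: float,
    t0_ms: float = -100.0,
    t1_ms: float = 3400.0,
    condition: str = "memorized",
    trial_correct: Optional[np.ndarray] = None,
) -> EpochSet:
    """Cut trials around stimulus-onset samples and baseline-correct.

    Each epoch spans ``t0_ms..t1_ms`` around its event (default 3500 ms:
    3400 ms of sequence plus 100 ms of baseline) and contains
    ``floor((t1_ms - t0_ms) * fs / 1000)`` samples, the onset sample
    included. The mean of the pre-onset (t < 0) samples is subtracted from
    the whole trial. Events whose epoch would leave the record are rejected
    with a logged warning.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    if t0_ms > 0:
        raise InvalidInputError("t0_ms must be <= 0")
    n_samp = int(np.floor((t1_ms - t0_ms) * fs / 1000.0))
    n_base = int(np.floor(-t0_ms * fs / 1000.0))
    start_off = -n_base
    n_rec = continuous.shape[-1]
    kept, trials = [], []
    for i, ev in enumerate(events):
        start = int(ev) + start_off
        if start < 0 or start + n_samp > n_rec:
            logger.warning(
                "event %d at sample %d too close to the record edge; trial rejected",
                i,
                ev,
            )
            continue
        kept.append(i)
        trials.append(continuous[:, start : start + n_samp])
    data = (
        np.stack(trials) if trials else np.empty((0, continuous.shape[0], n_samp))
    )
    if n_base > 0 and data.size:
        data = data - data[:, :, :n_base].mean(axis=2, keepdims=True)
    correct = None
    if trial_correct is not None:
        correct = np.asarray(trial_correct, dtype=bool)[kept]
    return EpochSet(
        data=data,
        fs_hz=fs,
        t0_ms=-(n_base * 1000.0 / fs),
        condition=condition,
        trial_correct=correct,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's pre-onset mean from the whole trial."""
    n_base = int(np.floor(-epochs.t0_ms * epochs.fs_hz / 1000.0))
    if n_base == 0:
        return epochs
    data = epochs.data - epochs.data[:, :, :n_base].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        fs_hz=epochs.fs_hz,
        t0_ms=epochs.t0_ms,
        condition=epochs.condition,
        trial_correct=epochs.trial_correct,
    )


def select_correct(epochs: EpochSet) -> EpochSet:
    """Keep correctly answered trials only.

    Raises
    ------
    NoCorrectTrialsError
        If no trial is correct; the pipeline excludes such participants
        from group statistics with a logged warning.
    """
    if epochs.trial_correct is None:
        raise InvalidInputError("trial_correct is not defined on this EpochSet")
    keep = np.asarray(epochs.trial_correct, dtype=bool)
    if not keep.any():
        raise NoCorrectTrialsError(
            f"no correct trials in condition {epochs.condition!r}"
        )
    return EpochSet(
        data=epochs.data[keep],
        fs_hz=epochs.fs_hz,
        t0_ms=epochs.t0_ms,
        condition=epochs.condition,
        trial_correct=keep[keep],
    )
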