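"""The five tone windows of the 1250-ms auditory sequence.

Each recognition trial presents a five-tone sequence; analyses subaverage
source activity in five consecutive 250-ms windows aligned to tone onsets:
0-250, 251-500, 501-750, 751-1000 and 1001-1250 ms. A sample at time ``t``
(ms, relative to sequence onset) belongs to window ``w`` (1-based) iff
``250*(w-1) <= t < 250*w`` — half-open bins, so the windows are
non-overlapping and contiguous over 0-1250 ms at any sampling rate.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

#: (start_ms, end_ms) of each tone window, half-open
WINDOWS_MS: tuple[tuple[float, float], ...] = (
    (0.0, 250.0),
    (250.0, 500.0),
    (500.0, 750.0),
    (750.0, 1000.0),
    (1000.0, 1250.0),
)

N_WINDOWS = len(WINDOWS_MS)
SEQUENCE_MS = 1250.0


def window_sample_indices(times_ms: np.ndarray, window: int) -> np.ndarray:
    """Sample indices of 1-based tone ``window`` given per-sample times (ms
    relative to sequence onset)."""
    if not 1 <= window <= N_WINDOWS:
        raise InvalidInputError(f"window must be in 1..{N_WINDOWS}, got {window}")
    lo, hi = WINDOWS_MS[window - 1]
    return np.flatnonzero((times_ms >= lo) & (times_ms < hi))


def check_covers_sequence(times_ms: np.ndarray) -> None:
    """Raise unless the time axis covers the full 0-1250 ms sequence.

    Coverage is in the half-open sense: the final sample may fall short of
    1250 ms by up to one sampling interval.
    """
    if times_ms.size < 2:
        raise InvalidInputError("source time courses must cover 0-1250 ms post-onset")
    dt = float(times_ms[1] - times_ms[0])
    if times_ms[0] > 0.0 or times_ms[-1] < SEQUENCE_MS - dt - 1e-6:
        raise InvalidInputError("source time courses must cover 0-1250 ms post-onset")
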