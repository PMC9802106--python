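"""Tone-window subaveraging and group-level mass-univariate statistics.

The unit of all group statistics is *window activity*: one number per
participant, source voxel, tone window and condition, obtained by averaging
the trial-averaged source time course over each of the five 250-ms tone
windows. Two polarity rules are available: ``signed`` (the default) keeps
raw reconstructed values, which is well defined here because the generator's
forward models make source polarity meaningful; ``rectified`` takes the
absolute value of the evoked time course per sample before window
averaging, the conventional workaround for the arbitrary per-voxel sign of
beamformer output on real anatomy. Rectification makes the window measure
an even function of source amplitude, so it compresses condition effects
and — because any voxel's rectified activity grows with the total leaked
signal power — can couple behaviour-dependent amplitudes to the whole
volume; docs/methods.md discusses this trade-off.

Group statistics:

* condition contrast — one paired t-test per voxel on the
  memorized-minus-novel window activity across participants (df = n - 1);
* brain-behaviour maps — one Pearson correlation per voxel between WM
  scores and the memorized-minus-novel window activity (df = n - 2),
  optionally split by musicianship group;
* behavioural correlation — Pearson r between the number of correct
  recognitions and WM score, two-sided p from the exact t transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .windows import N_WINDOWS, WINDOWS_MS, check_covers_sequence, window_sample_indices

logger = logging.getLogger(__name__)

POLARITY_RULES = ("rectified", "signed")
MIN_GROUP_N = 4


@dataclass
class WindowActivity:
    """Per-participant window-averaged source activity.

    ``data`` has shape (participants, sources, windows, conditions) with
    condition order ("memorized", "novel") and exactly five windows.
    """

    data: np.ndarray
    polarity_rule: str = "signed"
    windows_ms: tuple = WINDOWS_MS

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[2] != N_WINDOWS or self.data.shape[3] != 2:
            raise InvalidInputError(
                "window activity must be (participants, sources, 5 windows, 2 conditions)"
            )
        if self.polarity_rule not in POLARITY_RULES:
            raise InvalidInputError(f"polarity_rule must be one of {POLARITY_RULES}")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    def difference(self, window_index: int) -> np.ndarray:
        """Memorized-minus-novel activity for a 1-based window,
        shape (participants, sources)."""
        _check_window(window_index)
        return self.data[:, :, window_index - 1, 0] - self.data[:, :, window_index - 1, 1]


@dataclass
class StatMap:
    """Per-voxel statistic map (t or Pearson r) with its degrees of freedom.

    ``flags`` marks voxels whose statistic was forced to 0 because the
    per-participant differences had zero variance there.
    """

    values: np.ndarray
    kind: str  # "t_contrast" | "pearson_r"
    df: int
    window_index: int
    n: int
    alpha: Optional[float] = None
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("t_contrast", "pearson_r"):
            raise InvalidInputError(f"unknown StatMap kind {self.kind!r}")
        if self.flags is None:
            self.flags = np.zeros(self.values.shape, dtype=bool)
        if self.kind == "pearson_r" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise InvalidInputError("Pearson r values must lie in [-1, 1]")

    def p_values(self) -> np.ndarray:
        """Two-sided p-values from the exact t transform."""
        if self.df <= 0:
            raise InvalidInputError("degrees of freedom must be positive")
        if self.kind == "t_contrast":
            t = self.values
        else:
            r = np.clip(self.values, -1.0, 1.0)
            with np.errstate(divide="ignore"):
                t = r * np.sqrt(self.df / np.maximum(1.0 - r**2, 1e-300))
        return 2.0 * stats.t.sf(np.abs(t), self.df)


def _check_window(window_index: int) -> None:
    if not 1 <= window_index <= N_WINDOWS:
        raise InvalidInputError(f"window_index must be in 1..{N_WINDOWS}")


def subaverage_windows(
    source_tc_by_condition: dict[str, np.ndarray],
    fs: float,
    t0_ms: float = -100.0,
    polarity_rule: str = "signed",
) -> np.ndarray:
    """Window-average one participant's trial-averaged source time courses.

    Parameters
    ----------
    source_tc_by_condition : {"memorized": (sources, samples), "novel": ...}
    fs : float
    t0_ms : float
        Time of the first sample relative to sequence onset.
    polarity_rule : {"rectified", "signed"}

    Returns
    -------
    ndarray, shape (sources, 5, 2)
    """
    if polarity_rule not in POLARITY_RULES:
        raise InvalidInputError(f"polarity_rule must be one of {POLARITY_RULES}")
    conds = ("memorized", "novel")
    if not all(c in source_tc_by_condition for c in conds):
        raise InvalidInputError("need both 'memorized' and 'novel' time courses")
    n_sources = source_tc_by_condition["memorized"].shape[0]
    out = np.empty((n_sources, N_WINDOWS, 2))
    for ci, cond in enumerate(conds):
        tc = np.asarray(source_tc_by_condition[cond], dtype=float)
        times = t0_ms + np.arange(tc.shape[1]) * 1000.0 / fs
        check_covers_sequence(times)
        if polarity_rule == "rectified":
            tc = np.abs(tc)
        for w in range(1, N_WINDOWS + 1):
            idx = window_sample_indices(times, w)
            out[:, w - 1, ci] = tc[:, idx].mean(axis=1)
    return out


def contrast_map(window_activity: WindowActivity, window_index: int) -> StatMap:
    """Paired t-map of memorized vs novel for one tone window.

    Voxels with zero variance of the paired differences get t = 0 and a
    raised flag rather than NaN.
    """
    n = window_activity.n_participants
    if n < 3:
        raise InvalidInputError("contrast_map needs >= 3 participants")
    diff = window_activity.difference(window_index)
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    flags = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flags, 0.0, mean / (sd / np.sqrt(n)))
    return StatMap(
        values=t,
        kind="t_contrast",
        df=n - 1,
        window_index=window_index,
        n=n,
        flags=flags,
    )


def correlation_map(
    window_activity: WindowActivity,
    covariates: pd.DataFrame,
    window_index: int,
    participants: Optional[np.ndarray] = None,
) -> StatMap:
    """Per-voxel Pearson correlation between WM scores and the
    memorized-minus-novel window activity across participants.

    ``participants`` optionally restricts to a subset (boolean or index
    array), used by the per-group analysis.
    """
    diff = window_activity.difference(window_index)
    wm = covariates["wm_score"].to_numpy(dtype=float)
    if len(wm) != window_activity.n_participants:
        raise InvalidInputError("covariates do not match window activity participants")
    if participants is not None:
        diff = diff[participants]
        wm = wm[participants]
    n = diff.shape[0]
    if n < MIN_GROUP_N:
        raise InvalidInputError("correlation_map needs >= 4 participants")
    if np.std(wm) == 0:
        raise InvalidInputError("WM scores are constant; correlation undefined")
    wm_c = (wm - wm.mean()) / wm.std()
    d_c = diff - diff.mean(axis=0)
    d_sd = diff.std(axis=0)
    flags = d_sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(flags, 0.0, (wm_c @ d_c) / n / np.where(flags, 1.0, d_sd))
    r = np.clip(r, -1.0, 1.0)
    return StatMap(
        values=r,
        kind="pearson_r",
        df=n - 2,
        window_index=window_index,
        n=n,
        flags=flags,
    )


def behavioral_correlation(covariates: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between recognition accuracy (number of correct
    trials) and WM score, with its two-sided p-value."""
    wm = covariates["wm_score"].to_numpy(dtype=float)
    acc = covariates["n_correct"].to_numpy(dtype=float)
    if len(wm) < MIN_GROUP_N:
        raise InvalidInputError("behavioral_correlation needs >= 4 participants")
    if np.std(wm) == 0 or np.std(acc) == 0:
        raise InvalidInputError("zero variance in covariates")
    res = stats.pearsonr(wm, acc)
    return float(res.statistic), float(res.pvalue)


def grouped_correlation_maps(
    window_activity: WindowActivity,
    covariates: pd.DataFrame,
    window_index: int,
) -> dict[str, StatMap]:
    """Correlation maps computed independently per musicianship group.

    Groups with fewer than four participants are skipped with a logged
    warning. Downstream cluster correction uses alpha = .025 for these maps.
    """
    out: dict[str, StatMap] = {}
    groups = covariates["group"].to_numpy()
    for g in pd.unique(groups):
        sel = np.flatnonzero(groups == g)
        if sel.size < MIN_GROUP_N:
            logger.warning(
                "group %r has %d participants (< %d); skipped", g, sel.size, MIN_GROUP_N
            )
            continue
        out[str(g)] = correlation_map(
            window_activity, covariates, window_index, participants=sel
        )
    return out
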