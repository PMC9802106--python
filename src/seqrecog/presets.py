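"""Preset study conditions for validation simulations.

These are the fixed, seeded synthetic-study configurations that the test
suite and the reproduction script run: global-null studies for family-wise
error measurement, and planted-effect studies for cluster recovery. Sizes
are scaled relative to the full study (70 participants, 120 trials per
condition, 150 Hz, 3.5-s epochs) so a complete validation batch runs in
minutes on one CPU while leaving the group-level statistics in the same
regime; docs/methods.md discusses the scaling.

Scaled conditions common to all presets: 12x12x12 full-box 8-mm grid
(1728 sources, 26-connectivity), 96 sensors, 100 Hz sampling, epochs
-100..1250 ms (the five tone windows plus baseline). Trials per condition:
4 for null studies — the trial count only changes the (small) within-
participant noise, which is irrelevant under the group null — and 16 for
recovery studies. Planted effects follow the full design:
d = 0.8 (between-participant Cohen's d) in a 30-voxel contiguous cluster
during tone windows 3-4 for the contrast, and a 20-voxel cluster whose
WM coupling gives population r = 0.6 for the correlation analysis.
"""

from __future__ import annotations

from .grid import SourceGrid, contiguous_region, make_grid
from .simulate import CorrEffectSpec, EffectSpec, SimConfig

GRID_DIMS = (12, 12, 12)
N_SENSORS = 96
FS_HZ = 100.0
BASELINE_MS = 100.0
POST_MS = 1250.0

EFFECT_CENTER = (4, 4, 4)
EFFECT_SIZE = 30
CORR_CENTER = (8, 8, 8)
CORR_SIZE = 20
EFFECT_D = 0.8
CORR_BETA = 0.6
CORR_RESIDUAL_SD = 0.8  # population r = beta / sqrt(beta^2 + sd^2) = 0.6
EFFECT_WINDOWS = [3, 4]


def validation_grid() -> SourceGrid:
    return make_grid(GRID_DIMS, spacing_mm=8.0, mask_rule="full_box", connectivity=26)


def _base(seed: int, n_participants: int, n_trials: int, **kw) -> SimConfig:
    return SimConfig(
        n_participants=n_participants,
        n_trials_per_condition=n_trials,
        fs_hz=FS_HZ,
        baseline_ms=BASELINE_MS,
        post_ms=POST_MS,
        n_sensors=N_SENSORS,
        seed=seed,
        **kw,
    )


def null_config(seed: int, n_participants: int = 30) -> SimConfig:
    """Global-null study (d = 0, beta = 0): no planted effects anywhere."""
    return _base(seed, n_participants, n_trials=4)


def contrast_recovery_config(seed: int, n_participants: int = 70) -> SimConfig:
    """30-voxel contiguous effect, d = 0.8, tone windows 3-4."""
    grid = validation_grid()
    voxels = contiguous_region(grid, EFFECT_CENTER, EFFECT_SIZE).tolist()
    return _base(
        seed,
        n_participants,
        n_trials=16,
        effects=[EffectSpec(voxels=voxels, d=EFFECT_D, windows=EFFECT_WINDOWS)],
    )


def correlation_recovery_config(
    seed: int, n_participants: int = 70, coupled: bool = True
) -> SimConfig:
    """20-voxel cluster whose memorized-minus-novel amplitude is coupled to
    WM (population r = 0.6); ``coupled=False`` gives the matched null
    (same activation, beta = 0)."""
    grid = validation_grid()
    voxels = contiguous_region(grid, CORR_CENTER, CORR_SIZE).tolist()
    spec = CorrEffectSpec(
        voxels=voxels,
        beta=CORR_BETA if coupled else 0.0,
        residual_sd=CORR_RESIDUAL_SD,
        mean_amplitude=0.8,
        windows=EFFECT_WINDOWS,
    )
    return _base(
        seed,
        n_participants,
        n_trials=16 if coupled else 4,
        corr_effects=[spec],
    )
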