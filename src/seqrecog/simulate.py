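"""Seeded synthetic MEG studies with known ground truth.

The generator emulates the statistical structure of a two-condition
(memorized vs novel) auditory sequence recognition study: per-participant
sensor epochs produced by projecting source-space activity through a lead
field, participant covariates (working-memory score, musicianship group,
behavioural accuracy), condition effects confined to contiguous voxel
clusters within designated 250-ms tone windows, and participant effect
amplitudes linearly tied to WM scores in designated correlation clusters.
Ground truth (which voxels/windows carry effects, and each participant's
planted condition-difference amplitude) is retained on the Study object so
recovery tests never re-derive it.

Model
-----
Source activity per trial is white Gaussian noise of SD ``noise_sd``. In the
*memorized* condition, voxel ``v`` in an effect cluster gains a constant
amplitude during its designated tone windows. Amplitudes are expressed in
units of the source noise SD and vary across participants:

* effect clusters:      ``amp[p, v] = d + effect_between_sd * eta[p, v]``
* correlation clusters: ``amp[p, v] = mean_amplitude + beta * z(WM_p)
  + residual_sd * eps[p, v]``

with standard-normal ``eta, eps``. ``effect_between_sd`` defaults to 1 so
``d`` is a between-participant Cohen's d: the group-level paired t at an
effect voxel concentrates near ``d * sqrt(n)``. In correlation clusters the
population correlation between WM and the planted difference amplitude is
``beta / sqrt(beta**2 + residual_sd**2)``.

Sensor epochs are ``leadfield @ source + sensor noise``. The unplanted
(background) part of the source signal only ever reaches the data through
the lead field, so it is drawn at the sensors directly from its exact
implied covariance ``noise_sd^2 * G G^T + sensor_noise_sd^2 * I`` — the
same multivariate-normal law as materializing white noise at every source
and projecting, at a fraction of the cost. Planted effects enter explicitly
through their sources' lead-field columns. Each participant gets an
independently seeded lead field by default (emulating different head
geometries, which is what makes long-range beamformer leakage average out
across participants); ``shared_leadfield=True`` uses a single field.

Behavioural accuracy is drawn through a Gaussian copula with a binomial
margin so that the number of correct trials has a target Pearson correlation
``behavior_wm_r`` with the WM score (default 0, matching the study's
null behavioural finding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .conditioning import EpochSet
from .errors import InvalidConfigError
from .grid import SourceGrid, make_grid
from .leadfield import LeadField, make_lead_field
from .windows import N_WINDOWS, window_sample_indices

logger = logging.getLogger(__name__)

CONDITIONS = ("memorized", "novel")


class EffectSpec(BaseModel):
    """A contiguous condition effect: ``voxels`` (source indices) gain
    amplitude ``d`` (noise-SD units) in the memorized condition during
    1-based tone ``windows``."""

    model_config = ConfigDict(extra="forbid")

    voxels: list[int]
    d: float
    windows: list[int] = Field(default_factory=lambda: [3, 4])

    @model_validator(mode="after")
    def _check(self) -> "EffectSpec":
        if not self.voxels:
            raise InvalidConfigError("effect voxel set is empty")
        if any(w < 1 or w > N_WINDOWS for w in self.windows):
            raise InvalidConfigError(f"windows must be in 1..{N_WINDOWS}")
        return self


class CorrEffectSpec(BaseModel):
    """A WM-coupled effect: per-participant memorized-minus-novel amplitude
    is ``mean_amplitude + beta * z(WM) + residual_sd * eps`` at these voxels
    and windows."""

    model_config = ConfigDict(extra="forbid")

    voxels: list[int]
    beta: float
    residual_sd: float = 0.8
    mean_amplitude: float = 0.8
    windows: list[int] = Field(default_factory=lambda: [3, 4])

    @model_validator(mode="after")
    def _check(self) -> "CorrEffectSpec":
        if not self.voxels:
            raise InvalidConfigError("correlation voxel set is empty")
        if self.residual_sd < 0:
            raise InvalidConfigError("residual_sd must be >= 0")
        if any(w < 1 or w > N_WINDOWS for w in self.windows):
            raise InvalidConfigError(f"windows must be in 1..{N_WINDOWS}")
        return self


class SimConfig(BaseModel):
    """Simulation configuration; the seed fully determines the output."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = 70
    n_trials_per_condition: int = 120
    fs_hz: float = 150.0
    baseline_ms: float = 100.0
    post_ms: float = 3400.0
    n_sensors: int = 102
    smoothness_mm: float = 4.0
    noise_sd: float = 1.0
    sensor_noise_sd: float = 1.0
    effect_between_sd: float = 1.0
    effects: list[EffectSpec] = Field(default_factory=list)
    corr_effects: list[CorrEffectSpec] = Field(default_factory=list)
    wm_mean: float = 100.0
    wm_sd: float = 15.0
    wm_bounds: tuple[float, float] = (40.0, 160.0)
    behavior_wm_r: float = 0.0
    accuracy: float = 0.85
    musician_fraction: float = 48.0 / 71.0
    shared_leadfield: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if self.n_trials_per_condition <= 1:
            raise InvalidConfigError("n_trials_per_condition must be > 1")
        if self.fs_hz <= 0 or self.baseline_ms < 0 or self.post_ms <= 0:
            raise InvalidConfigError("invalid timing parameters")
        if self.n_sensors < 2:
            raise InvalidConfigError("n_sensors must be >= 2")
        if min(self.noise_sd, self.sensor_noise_sd, self.effect_between_sd) < 0:
            raise InvalidConfigError("noise SDs must be >= 0")
        if not -1.0 < self.behavior_wm_r < 1.0:
            raise InvalidConfigError("behavior_wm_r must be in (-1, 1)")
        if not 0.0 < self.accuracy < 1.0:
            raise InvalidConfigError("accuracy must be in (0, 1)")
        if self.wm_sd <= 0 or self.wm_bounds[0] >= self.wm_bounds[1]:
            raise InvalidConfigError("invalid WM score distribution")
        planted = [w for e in self.effects + self.corr_effects for w in e.windows]
        if planted and max(planted) * 250.0 > self.post_ms:
            raise InvalidConfigError(
                "post_ms too short to contain the planted tone windows"
            )
        effect_vox = {v for e in self.effects for v in e.voxels}
        corr_vox = {v for e in self.corr_effects for v in e.voxels}
        if effect_vox & corr_vox:
            raise InvalidConfigError(
                "effect and correlation clusters overlap with conflicting amplitudes"
            )
        for specs in (self.effects, self.corr_effects):
            seen: set[tuple[int, int]] = set()
            for e in specs:
                for v in e.voxels:
                    for w in e.windows:
                        if (v, w) in seen:
                            raise InvalidConfigError(
                                "a voxel/window is claimed by two effect specs"
                            )
                        seen.add((v, w))
        return self

    @property
    def n_samples(self) -> int:
        """Samples per epoch: floor(duration_ms * fs / 1000)."""
        return int(np.floor((self.baseline_ms + self.post_ms) * self.fs_hz / 1000.0))

    @property
    def t0_ms(self) -> float:
        return -self.baseline_ms


@dataclass
class Study:
    """A complete synthetic study with retained ground truth.

    ``epochs[p][condition]`` is an :class:`~seqrecog.conditioning.EpochSet`
    with data of shape (trials, sensors, samples). ``truth`` holds per-window
    boolean effect/correlation masks over sources, the planted parameters,
    and each participant's planted memorized-minus-novel amplitude array
    (participants x sources x windows, source-SD units).
    """

    config: SimConfig
    grid: SourceGrid
    leadfields: list[LeadField]
    epochs: list[dict[str, EpochSet]]
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.epochs)

    @property
    def leadfield(self) -> LeadField:
        """The shared lead field; defined only when all participants share one."""
        if not self.config.shared_leadfield:
            raise InvalidConfigError(
                "study uses per-participant lead fields; index `leadfields` instead"
            )
        return self.leadfields[0]


def draw_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw WM scores, musicianship groups and behavioural accuracy.

    WM scores are truncated-normal; the number of correct trials shares a
    Gaussian copula latent with the WM score at correlation
    ``behavior_wm_r`` and has an exact Binomial(total trials, accuracy)
    margin.
    """
    n = config.n_participants
    lo = (config.wm_bounds[0] - config.wm_mean) / config.wm_sd
    hi = (config.wm_bounds[1] - config.wm_mean) / config.wm_sd
    u_wm = rng.uniform(size=n)
    wm = stats.truncnorm.ppf(u_wm, lo, hi, loc=config.wm_mean, scale=config.wm_sd)
    z_wm = stats.norm.ppf(u_wm)
    r = config.behavior_wm_r
    z_beh = r * z_wm + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    n_total = 2 * config.n_trials_per_condition
    n_correct = stats.binom.ppf(
        stats.norm.cdf(z_beh), n_total, config.accuracy
    ).astype(int)
    n_musicians = int(round(config.musician_fraction * n))
    group = np.array(["nonmusician"] * n, dtype=object)
    group[rng.permutation(n)[:n_musicians]] = "musician"
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "wm_score": wm,
            "group": group,
            "n_correct": n_correct,
        }
    )


def draw_difference_amplitudes(
    config: SimConfig,
    grid: SourceGrid,
    wm_z: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Planted memorized-minus-novel amplitudes, shape
    (participants, sources, windows), in source-noise-SD units."""
    n = config.n_participants
    amp = np.zeros((n, grid.n_sources, N_WINDOWS))
    for spec in config.effects:
        vox = np.asarray(spec.voxels, dtype=int)
        if vox.min(initial=0) < 0 or vox.max(initial=0) >= grid.n_sources:
            raise InvalidConfigError("effect voxel index outside the grid mask")
        eta = rng.standard_normal((n, vox.size))
        per_p = spec.d + config.effect_between_sd * eta
        for w in spec.windows:
            amp[:, vox, w - 1] = per_p
    for spec in config.corr_effects:
        vox = np.asarray(spec.voxels, dtype=int)
        if vox.min(initial=0) < 0 or vox.max(initial=0) >= grid.n_sources:
            raise InvalidConfigError("correlation voxel index outside the grid mask")
        eps = rng.standard_normal((n, vox.size))
        per_p = (
            spec.mean_amplitude
            + spec.beta * wm_z[:, None]
            + spec.residual_sd * eps
        )
        for w in spec.windows:
            amp[:, vox, w - 1] = per_p
    return amp


def _truth_masks(config: SimConfig, grid: SourceGrid) -> dict:
    effect = np.zeros((N_WINDOWS, grid.n_sources), dtype=bool)
    corr = np.zeros((N_WINDOWS, grid.n_sources), dtype=bool)
    for spec in config.effects:
        for w in spec.windows:
            effect[w - 1, spec.voxels] = True
    for spec in config.corr_effects:
        for w in spec.windows:
            corr[w - 1, spec.voxels] = True
    return {"effect_mask": effect, "corr_mask": corr}


def simulate_study(
    config: SimConfig,
    grid: Optional[SourceGrid] = None,
    leadfield: Optional[LeadField] = None,
) -> Study:
    """Simulate a full study from a configuration.

    Parameters
    ----------
    config : SimConfig
    grid : SourceGrid, optional
        Defaults to a 12x12x12 full-box 8-mm grid.
    leadfield : LeadField, optional
        If given (and ``config.shared_leadfield``), used for all
        participants; otherwise per-participant fields are generated from
        the study seed.
    """
    if grid is None:
        grid = make_grid((12, 12, 12))
    root = np.random.SeedSequence(config.seed)
    ss_cov, ss_amp, ss_lf, ss_ep = root.spawn(4)
    cov_df = draw_covariates(config, np.random.default_rng(ss_cov))
    wm = cov_df["wm_score"].to_numpy()
    wm_z = (wm - wm.mean()) / wm.std() if config.n_participants > 1 else np.zeros(1)
    amp = draw_difference_amplitudes(
        config, grid, wm_z, np.random.default_rng(ss_amp)
    )

    n = config.n_participants
    if leadfield is not None:
        if leadfield.n_sources != grid.n_sources:
            raise InvalidConfigError("lead field does not match the grid mask")
        leadfields = [leadfield] * n
    elif config.shared_leadfield:
        leadfields = [
            make_lead_field(grid, config.n_sensors, config.smoothness_mm, ss_lf)
        ] * n
    else:
        leadfields = [
            make_lead_field(grid, config.n_sensors, config.smoothness_mm, child)
            for child in ss_lf.spawn(n)
        ]

    n_samp = config.n_samples
    n_trials = config.n_trials_per_condition
    times = config.t0_ms + np.arange(n_samp) * 1000.0 / config.fs_hz
    win_idx = [window_sample_indices(times, w) for w in range(1, N_WINDOWS + 1)]

    # amplitude units: multiples of the source noise SD (absolute units when
    # noise_sd == 0, so noiseless studies still carry their planted signal)
    amp_scale = config.noise_sd if config.noise_sd > 0 else 1.0

    epochs: list[dict[str, EpochSet]] = []
    for p, child in enumerate(ss_ep.spawn(n)):
        rng_p = np.random.default_rng(child)
        gains = leadfields[p].gains
        # Background at the sensors is leadfield @ (white source noise) plus
        # white sensor noise, i.e. exactly Gaussian with covariance
        # noise_sd^2 * G G^T + sensor_noise_sd^2 * I per time point. Drawing
        # it directly from that covariance is algebraically equivalent to
        # materializing per-source noise and projecting, and much cheaper.
        bg_cov = config.noise_sd**2 * (gains @ gains.T)
        bg_cov[np.diag_indices_from(bg_cov)] += config.sensor_noise_sd**2
        if config.noise_sd > 0 or config.sensor_noise_sd > 0:
            bg_chol = np.linalg.cholesky(
                bg_cov + 1e-12 * np.trace(bg_cov) / len(bg_cov) * np.eye(len(bg_cov))
            ).astype(np.float32)
        else:
            bg_chol = None
        # per-trial correctness: n_correct of the 2*n_trials trials, at random
        correct_flat = np.zeros(2 * n_trials, dtype=bool)
        correct_flat[
            rng_p.permutation(2 * n_trials)[: cov_df["n_correct"].iloc[p]]
        ] = True
        # planted evoked signal at the sensors (memorized condition only)
        planted = np.zeros((config.n_sensors, n_samp), dtype=np.float32)
        for w in range(N_WINDOWS):
            active = np.flatnonzero(amp[p, :, w])
            if active.size:
                pattern = (gains[:, active] @ amp[p, active, w]) * amp_scale
                planted[:, win_idx[w]] += pattern.astype(np.float32)[:, None]
        per_cond: dict[str, EpochSet] = {}
        for ci, cond in enumerate(CONDITIONS):
            white = rng_p.standard_normal(
                (n_trials, config.n_sensors, n_samp), dtype=np.float32
            )
            sensor = (
                np.matmul(bg_chol, white) if bg_chol is not None else np.zeros_like(white)
            )
            if cond == "memorized":
                sensor += planted[None, :, :]
            per_cond[cond] = EpochSet(
                data=sensor,
                fs_hz=config.fs_hz,
                t0_ms=config.t0_ms,
                condition=cond,
                trial_correct=correct_flat[ci * n_trials : (ci + 1) * n_trials].copy(),
            )
        epochs.append(per_cond)

    truth = _truth_masks(config, grid)
    truth.update(
        {
            "amplitudes": amp,
            "d": [e.d for e in config.effects],
            "beta": [e.beta for e in config.corr_effects],
        }
    )
    return Study(
        config=config,
        grid=grid,
        leadfields=leadfields,
        epochs=epochs,
        covariates=cov_df,
        truth=truth,
    )
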