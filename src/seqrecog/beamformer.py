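"""Unit-gain LCMV beamformer (scalar, fixed-orientation dipoles).

For source ``i`` with lead-field column ``l_i`` and sensor covariance
``C``, the linearly constrained minimum-variance spatial filter is

    w_i = C^{-1} l_i / (l_i^T C^{-1} l_i)

which minimises output variance subject to the unit-gain constraint
``w_i^T l_i = 1``. Weights are applied to the sensor data independently at
each time point. Covariance is the second-moment matrix of all pooled
post-stimulus samples of both conditions (common weights, so the filters
cannot be condition-biased), with diagonal loading
``lambda = regularization_fraction * mean(diag)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from .errors import InvalidInputError, RankError
from .leadfield import LeadField


@dataclass(frozen=True)
class SensorCovariance:
    """Regularized sensor covariance.

    ``matrix`` is symmetric and, for ``regularization_fraction > 0`` on
    non-degenerate data, positive definite.
    """

    matrix: np.ndarray
    n_samples_used: int
    regularization_fraction: float

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]


def estimate_covariance(
    epochs: np.ndarray | Sequence[np.ndarray],
    regularization_fraction: float = 0.05,
) -> SensorCovariance:
    """Sample second-moment matrix over all concatenated epoch samples plus
    diagonal loading.

    Parameters
    ----------
    epochs : array (trials, sensors, samples) or sequence of (sensors, samples)
    regularization_fraction : float
        Diagonal loading as a fraction of the mean diagonal (default 0.05).
    """
    if regularization_fraction < 0:
        raise InvalidInputError("regularization_fraction must be >= 0")
    if isinstance(epochs, np.ndarray):
        if epochs.ndim == 2:
            segments: list[np.ndarray] = [epochs]
        elif epochs.ndim == 3:
            segments = [epochs[t] for t in range(epochs.shape[0])]
        else:
            raise InvalidInputError("epochs must be 2-D or 3-D")
    else:
        segments = [np.asarray(s) for s in epochs]
    x = np.concatenate([s.astype(np.float64, copy=False) for s in segments], axis=1)
    n = x.shape[1]
    if n < 2:
        raise InvalidInputError("need >= 2 samples to estimate a covariance")
    c = (x @ x.T) / n
    lam = regularization_fraction * np.mean(np.diag(c))
    c = c + lam * np.eye(c.shape[0])
    c = (c + c.T) / 2.0
    return SensorCovariance(
        matrix=c,
        n_samples_used=n,
        regularization_fraction=regularization_fraction,
    )


def lcmv_weights(leadfield: LeadField | np.ndarray, covariance: SensorCovariance) -> np.ndarray:
    """LCMV weight matrix, shape (n_sources, n_sensors).

    Unit gain ``w_i^T l_i = 1`` holds to machine precision for every source.

    Raises
    ------
    RankError
        If the covariance is singular; increase ``regularization_fraction``.
    """
    gains = leadfield.gains if isinstance(leadfield, LeadField) else np.asarray(leadfield)
    c = covariance.matrix
    if gains.shape[0] != c.shape[0]:
        raise InvalidInputError("lead field and covariance sensor counts differ")
    try:
        cho = sla.cho_factor(c, lower=True)
    except (np.linalg.LinAlgError, sla.LinAlgWarning, ValueError) as exc:
        raise RankError(
            "sensor covariance is singular; regularize (diagonal loading) before inverting"
        ) from exc
    ci_l = sla.cho_solve(cho, gains.astype(np.float64, copy=False))
    denom = np.einsum("ij,ij->j", gains, ci_l)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise RankError("covariance is not positive definite for this lead field")
    return (ci_l / denom).T


def apply_weights(weights: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Project sensor data to source space, independently per time point.

    ``data`` may be (sensors, samples) or (trials, sensors, samples);
    the sensor axis is contracted with the weights.
    """
    weights = np.asarray(weights)
    data = np.asarray(data)
    if data.ndim == 2:
        if data.shape[0] != weights.shape[1]:
            raise InvalidInputError("sensor dimension mismatch")
        return weights @ data
    if data.ndim == 3:
        if data.shape[1] != weights.shape[1]:
            raise InvalidInputError("sensor dimension mismatch")
        return np.einsum("vs,tsn->tvn", weights, data)
    raise InvalidInputError("data must be 2-D or 3-D")


def evoked(epochs: np.ndarray) -> np.ndarray:
    """Trial-averaged sensor data: (trials, sensors, samples) -> (sensors, samples)."""
    epochs = np.asarray(epochs)
    if epochs.ndim != 3 or epochs.shape[0] == 0:
        raise InvalidInputError("need a non-empty (trials, sensors, samples) array")
    return epochs.mean(axis=0)
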