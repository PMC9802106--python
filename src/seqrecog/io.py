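"""Serialization: study containers, statistic maps, cluster tables.

A study directory holds one binary array container (``arrays.npz``:
epochs, lead-field gains, planted amplitudes), a JSON sidecar
(``study.json``: config, grid, truth masks) and a TSV of participant
covariates. Statistic maps and cluster masks export to NIfTI-1 volumes on
the grid's affine; cluster reports export to TSV (per-voxel rows for
significant clusters plus a summary table of all clusters).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cluster import ClusterReport
from .conditioning import EpochSet
from .errors import InvalidInputError
from .grid import SourceGrid
from .leadfield import LeadField
from .simulate import CONDITIONS, SimConfig, Study
from .window_stats import StatMap

ARRAYS_NAME = "arrays.npz"
SIDECAR_NAME = "study.json"
COVARIATES_NAME = "covariates.tsv"


def grid_to_json(grid: SourceGrid) -> dict:
    return {
        "dims": list(grid.dims),
        "spacing_mm": grid.spacing_mm,
        "connectivity": grid.connectivity,
        "affine": grid.affine.tolist(),
        "mask_flat": grid.source_flat.tolist(),
    }


def grid_from_json(g: dict) -> SourceGrid:
    dims = tuple(g["dims"])
    mask = np.zeros(int(np.prod(dims)), dtype=bool)
    mask[np.asarray(g["mask_flat"], dtype=int)] = True
    return SourceGrid(
        dims=dims,
        spacing_mm=float(g["spacing_mm"]),
        mask=mask.reshape(dims),
        affine=np.asarray(g["affine"], dtype=float),
        connectivity=int(g["connectivity"]),
    )


def save_study(study: Study, out_dir: str | Path) -> Path:
    """Write a study directory (arrays.npz + study.json + covariates.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs = np.stack(
        [
            np.stack([study.epochs[p][c].data for c in CONDITIONS])
            for p in range(study.n_participants)
        ]
    ).astype(np.float32)
    correct = np.stack(
        [
            np.stack([study.epochs[p][c].trial_correct for c in CONDITIONS])
            for p in range(study.n_participants)
        ]
    )
    gains = np.stack([lf.gains for lf in study.leadfields]).astype(np.float32)
    np.savez_compressed(
        out / ARRAYS_NAME,
        epochs=epochs,
        trial_correct=correct,
        gains=gains,
        amplitudes=study.truth["amplitudes"].astype(np.float32),
    )
    sidecar = {
        "config": study.config.model_dump(mode="json"),
        "grid": grid_to_json(study.grid),
        "truth": {
            "effect_mask": study.truth["effect_mask"].astype(int).tolist(),
            "corr_mask": study.truth["corr_mask"].astype(int).tolist(),
            "d": study.truth["d"],
            "beta": study.truth["beta"],
        },
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    study.covariates.to_csv(out / COVARIATES_NAME, sep="\t", index=False)
    return out


def load_study(study_dir: str | Path) -> Study:
    """Read a study directory written by :func:`save_study`."""
    d = Path(study_dir)
    sidecar = json.loads((d / SIDECAR_NAME).read_text())
    config = SimConfig.model_validate(sidecar["config"])
    grid = grid_from_json(sidecar["grid"])
    with np.load(d / ARRAYS_NAME) as arrays:
        epochs_arr = arrays["epochs"]
        correct = arrays["trial_correct"]
        gains = arrays["gains"]
        amplitudes = arrays["amplitudes"].astype(float)
    covariates = pd.read_csv(d / COVARIATES_NAME, sep="\t")
    leadfields = [
        LeadField(gains=gains[p], sensor_ids=tuple(f"MEG{i:04d}" for i in range(gains.shape[1])))
        for p in range(gains.shape[0])
    ]
    epochs = []
    for p in range(epochs_arr.shape[0]):
        per_cond = {}
        for ci, cond in enumerate(CONDITIONS):
            per_cond[cond] = EpochSet(
                data=epochs_arr[p, ci],
                fs_hz=config.fs_hz,
                t0_ms=config.t0_ms,
                condition=cond,
                trial_correct=correct[p, ci].astype(bool),
            )
        epochs.append(per_cond)
    truth = {
        "effect_mask": np.asarray(sidecar["truth"]["effect_mask"], dtype=bool),
        "corr_mask": np.asarray(sidecar["truth"]["corr_mask"], dtype=bool),
        "d": sidecar["truth"]["d"],
        "beta": sidecar["truth"]["beta"],
        "amplitudes": amplitudes,
    }
    return Study(
        config=config,
        grid=grid,
        leadfields=leadfields,
        epochs=epochs,
        covariates=covariates,
        truth=truth,
    )


def write_stat_nifti(
    values: StatMap | np.ndarray, grid: SourceGrid, path: str | Path
) -> Path:
    """Write a per-source statistic map (or mask) as a NIfTI-1 volume.

    Background (out-of-mask) voxels are 0; the header voxel size equals the
    grid spacing. Values round-trip to float32 precision.
    """
    vec = values.values if isinstance(values, StatMap) else np.asarray(values)
    if vec.shape != (grid.n_sources,):
        raise InvalidInputError("values must be one per in-mask source")
    vol = grid.embed(vec.astype(np.float32))
    img = nib.Nifti1Image(vol, grid.affine.astype(np.float64))
    img.header.set_zooms((grid.spacing_mm,) * 3)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_stat_nifti(path: str | Path, grid: SourceGrid) -> np.ndarray:
    """Read a per-source vector back from a NIfTI written by
    :func:`write_stat_nifti`."""
    img = nib.load(str(path))
    return grid.extract(np.asarray(img.dataobj))


VOXEL_COLUMNS = [
    "cluster_id", "k", "voxel", "i", "j", "kk", "x_mm", "y_mm", "z_mm", "statistic",
]
SUMMARY_COLUMNS = [
    "cluster_id", "k", "significant", "peak_statistic",
    "peak_x_mm", "peak_y_mm", "peak_z_mm", "threshold_size", "alpha", "sign",
]


def write_cluster_table(
    report: ClusterReport,
    grid: SourceGrid,
    path: str | Path,
    statmap: StatMap | None = None,
) -> tuple[Path, Path]:
    """Write per-voxel rows for each *significant* cluster plus a summary
    table of all clusters. Returns (voxel_table_path, summary_table_path);
    the voxel table is ``<stem>.tsv``, the summary ``<stem>_summary.tsv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.with_suffix("")
    vox_path = stem.with_suffix(".tsv")
    sum_path = Path(str(stem) + "_summary.tsv")
    mm = grid.source_mm
    ijk = grid.source_ijk
    vox_rows, sum_rows = [], []
    for cid, c in enumerate(report.clusters, start=1):
        peak_mm = mm[c.peak_voxel] if c.peak_voxel >= 0 else [np.nan] * 3
        sum_rows.append(
            [cid, c.size, c.significant, c.peak_stat, *np.round(peak_mm, 3),
             report.threshold_size, report.alpha, report.sign]
        )
        if not c.significant:
            continue
        for v in c.voxel_ids:
            stat = statmap.values[v] if statmap is not None else np.nan
            vox_rows.append(
                [cid, c.size, int(v), *ijk[v], *np.round(mm[v], 3), stat]
            )
    pd.DataFrame(vox_rows, columns=VOXEL_COLUMNS).to_csv(vox_path, sep="\t", index=False)
    pd.DataFrame(sum_rows, columns=SUMMARY_COLUMNS).to_csv(sum_path, sep="\t", index=False)
    return vox_path, sum_path
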