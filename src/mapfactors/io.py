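"""File I/O: HDF5 trial datasets, events tables, NIfTI maps, reports.

Formats
-------
* Trial datasets: one HDF5 file with datasets ``betas`` [S,T,V], ``rt`` and
  ``confidence`` [S,T], ``run`` and ``block`` [T], and design/provenance
  attributes.  Round-trips are bit-exact.
* Behavior: BIDS-events-like tab-separated tables with columns
  subject, run, block, trial, rt, confidence (RT in seconds).
* Activation maps: NIfTI-1 volumes through a boolean mask volume; the
  voxel vector order is the row-major (C-order) traversal of the mask grid.
  Contrast/statistic/subset metadata goes to a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import BEHAVIOR_COLUMNS, validate_behavior, zscore_behavior
from .exceptions import DimensionError, FormatError
from .generative import StudyDesign, TrialDataset
from .maps import ActivationMap

_DESIGN_FIELDS = ("n_subjects", "n_runs", "blocks_per_run", "trials_per_block", "n_voxels")


# -- behavior events tables ---------------------------------------------


def write_events(table: pd.DataFrame, path) -> None:
    """Write a behavior table as a tab-separated events file."""
    validate_behavior(table)[BEHAVIOR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read and validate a tab-separated events file."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"events file {path} missing column(s): {', '.join(missing)}")
    return validate_behavior(table)


# -- trial datasets ------------------------------------------------------


def write_dataset(dataset: TrialDataset, path) -> None:
    """Persist a trial dataset to HDF5 (bit-exact round trip)."""
    arrays = dataset.arrays()
    with h5py.File(path, "w") as f:
        f.create_dataset("betas", data=dataset.betas)
        f.create_dataset("rt", data=arrays["rt"])
        f.create_dataset("confidence", data=arrays["confidence"])
        f.create_dataset("run", data=arrays["run"].astype(np.int64))
        f.create_dataset("block", data=arrays["block"].astype(np.int64))
        for name in _DESIGN_FIELDS:
            f.attrs[f"design_{name}"] = getattr(dataset.design, name)
        f.attrs["provenance"] = json.dumps(dataset.provenance)


def read_dataset(path) -> TrialDataset:
    """Load a trial dataset written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        for name in ("betas", "rt", "confidence", "run", "block"):
            if name not in f:
                raise FormatError(f"dataset file {path} missing array {name!r}")
        betas = f["betas"][()]
        rt = f["rt"][()]
        confidence = f["confidence"][()]
        run = f["run"][()]
        block = f["block"][()]
        design = StudyDesign(**{n: int(f.attrs[f"design_{n}"]) for n in _DESIGN_FIELDS})
        provenance = json.loads(f.attrs.get("provenance", "{}"))
    n_subjects, n_trials = rt.shape
    if betas.shape[:2] != (n_subjects, n_trials):
        raise DimensionError(
            f"betas shape {betas.shape} inconsistent with behavior {rt.shape} in {path}"
        )
    behavior = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_trials),
            "run": np.tile(run, n_subjects),
            "block": np.tile(block, n_subjects),
            "trial": np.tile(np.arange(n_trials), n_subjects),
            "rt": rt.ravel(),
            "confidence": confidence.ravel(),
        }
    )
    return TrialDataset(
        betas=betas, behavior=zscore_behavior(behavior), design=design, provenance=provenance
    )


# -- NIfTI maps ----------------------------------------------------------


def load_mask(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    """Load a NIfTI mask; returns the boolean array and the image (for affine)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) != 0
    if not mask.any():
        raise FormatError(f"mask {path} selects no voxels")
    return mask, img


def write_map_nifti(map_or_values, mask: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a voxel vector into the mask's grid as NIfTI-1 (+ JSON sidecar).

    The vector is scattered into the mask positions in row-major (C) order of
    the volume grid, the documented vectorization convention.
    """
    if isinstance(map_or_values, ActivationMap):
        values = map_or_values.values
        meta = {
            "subject_id": int(map_or_values.subject_id),
            "contrast": map_or_values.contrast,
            "statistic": map_or_values.statistic,
            "trial_subset": map_or_values.trial_subset,
        }
    else:
        values, meta = np.asarray(map_or_values), {}
    mask = np.asarray(mask, dtype=bool)
    if values.shape != (int(mask.sum()),):
        raise DimensionError(
            f"map has {values.shape[0]} voxels but mask selects {int(mask.sum())}"
        )
    volume = np.zeros(mask.shape, dtype=np.float64)
    volume[mask] = values  # boolean indexing follows C order
    nib.save(nib.Nifti1Image(volume, affine), str(path))
    if meta:
        Path(str(path)).with_suffix("").with_suffix(".json").write_text(json.dumps(meta))


def read_map_nifti(path, mask: np.ndarray) -> np.ndarray:
    """Read a map written by :func:`write_map_nifti` back to a voxel vector."""
    img = nib.load(str(path))
    volume = np.asarray(img.dataobj)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise DimensionError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    return volume[mask].astype(np.float64)


# -- reports -------------------------------------------------------------


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
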