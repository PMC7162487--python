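"""Study serialization: NIfTI volumes and masks, CSV tables, JSON manifest.

On disk a multi-echo volume is a 4-D NIfTI-1 file with axes
(row, col, slice, echo) and an affine encoding the in-plane spacing
(field of view / matrix) and slice thickness; in memory the package
indexes (slice, row, col, echo), so the first three axes are transposed
on read/write.  Masks are 3-D uint8 NIfTI.  Traces and ground truth are
plain CSV; the manifest is JSON and makes a written study round-trip
losslessly through the readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, MultiEchoVolume
from .relaxometry import ParameterMap
from .synthetic import SyntheticStudy, SyntheticStudyConfig

__all__ = [
    "affine_for",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_parameter_map",
    "write_study",
    "StudyReader",
]


def affine_for(params: AcquisitionParams) -> np.ndarray:
    dr, dc, dz = params.voxel_size
    return np.diag([dr, dc, dz, 1.0])


def _to_disk_order(arr: np.ndarray) -> np.ndarray:
    # (slice, row, col, ...) -> (row, col, slice, ...)
    return np.moveaxis(arr, 0, 2)


def _from_disk_order(arr: np.ndarray) -> np.ndarray:
    return np.moveaxis(arr, 2, 0)


def write_volume(volume: MultiEchoVolume, path: Path) -> None:
    img = nib.Nifti1Image(
        _to_disk_order(volume.intensities).astype(np.float64),
        affine_for(volume.params),
    )
    nib.save(img, str(path))


def read_volume(
    path: Path,
    params: AcquisitionParams,
    subject_id: str = "",
    time_min: float = 0.0,
) -> MultiEchoVolume:
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D multi-echo volume")
    return MultiEchoVolume(
        _from_disk_order(data), params, subject_id=subject_id, time_min=time_min
    )


def write_mask(mask: np.ndarray, params: AcquisitionParams, path: Path) -> None:
    img = nib.Nifti1Image(
        _to_disk_order(mask.astype(np.uint8)), affine_for(params)
    )
    nib.save(img, str(path))


def read_mask(path: Path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return _from_disk_order(data).astype(bool)


def write_parameter_map(pmap: ParameterMap, out_dir: Path, prefix: str = "fit") -> dict:
    """Write amplitude/T2/RSS/converged maps plus a fit-summary CSV row file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = pmap.params or AcquisitionParams(
        matrix_rows=pmap.grid_shape[1],
        matrix_cols=pmap.grid_shape[2],
        n_slices=pmap.grid_shape[0],
    )
    aff = affine_for(params)
    files = {}
    for name, arr, dtype in (
        ("amplitude", pmap.amplitude, np.float64),
        ("t2", pmap.t2, np.float64),
        ("rss", pmap.rss, np.float64),
        ("converged", pmap.converged, np.uint8),
        ("n_iter", pmap.n_iter, np.int32),
    ):
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(_to_disk_order(arr.astype(dtype)), aff), str(p))
        files[name] = p.name
    n_fit = int(np.isfinite(pmap.amplitude).sum())
    summary = pd.DataFrame(
        [
            {
                "subject_id": pmap.subject_id,
                "time_min": pmap.time_min,
                "n_fitted": n_fit,
                "n_converged": int(pmap.converged.sum()),
                "median_t2": float(np.nanmedian(np.where(pmap.converged, pmap.t2, np.nan)))
                if pmap.converged.any()
                else float("nan"),
            }
        ]
    )
    summary.to_csv(out_dir / f"{prefix}_summary.csv", index=False)
    files["summary"] = f"{prefix}_summary.csv"
    return files


def write_study(study: SyntheticStudy, directory: Path) -> dict:
    """Materialize a synthetic study to disk; returns the manifest.

    Layout: one 4-D NIfTI per subject per scan time, per-subject ROI and
    tissue masks, per-subject arterial-pressure trace CSV, a pooled
    ground-truth CSV, and ``manifest.json`` tying everything together.
    Subjects are simulated (and freed) one at a time.
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"no such directory: {directory.parent}")
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": study.config.to_dict(),
        "acquisition": study.params.to_dict(),
        "n_roi_slices": study.n_roi_slices,
        "subjects": [],
    }
    truth_rows = []
    for spec, series, trace, phantom in study.iter_subjects():
        sid = spec.subject_id
        safe = sid.replace("&", "and").replace(" ", "_")
        entry = {
            "subject_id": sid,
            "group": series.group_label,
            "volumes": {},
            "roi_mask": f"{safe}_roi.nii.gz",
            "tissue_mask": f"{safe}_tissue.nii.gz",
            "map_trace": f"{safe}_map.csv",
        }
        for vol in series.volumes:
            fname = f"{safe}_t{vol.time_min:04.0f}.nii.gz"
            write_volume(vol, directory / fname)
            entry["volumes"][str(vol.time_min)] = fname
        write_mask(phantom.roi_mask, study.params, directory / entry["roi_mask"])
        write_mask(phantom.tissue_mask, study.params, directory / entry["tissue_mask"])
        pd.DataFrame(
            {"time_min": trace.times_min, "pressure_mmhg": trace.pressure_mmhg}
        ).to_csv(directory / entry["map_trace"], index=False)
        truth_rows.append(
            {
                "subject_id": sid,
                "group": series.group_label,
                "slope_a": series.slope,
                "intercept_b": series.intercept,
                "map_reduction": trace.reduction,
            }
        )
        manifest["subjects"].append(entry)

    pd.DataFrame(truth_rows).to_csv(directory / "ground_truth.csv", index=False)
    manifest["ground_truth"] = "ground_truth.csv"
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


class StudyReader:
    """Read-side counterpart of :func:`write_study`."""

    def __init__(self, directory: Path):
        self.directory = Path(directory)
        mpath = self.directory / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(f"no study manifest at {mpath}")
        with open(mpath) as fh:
            self.manifest = json.load(fh)
        self.params = AcquisitionParams.from_dict(self.manifest["acquisition"])
        self.config = SyntheticStudyConfig.from_dict(self.manifest["config"])

    @property
    def subjects(self) -> list[dict]:
        return self.manifest["subjects"]

    def roi_mask(self, entry: dict) -> np.ndarray:
        return read_mask(self.directory / entry["roi_mask"])

    def volumes(self, entry: dict) -> list[MultiEchoVolume]:
        out = []
        for t, fname in sorted(
            entry["volumes"].items(), key=lambda kv: float(kv[0])
        ):
            out.append(
                read_volume(
                    self.directory / fname,
                    self.params,
                    subject_id=entry["subject_id"],
                    time_min=float(t),
                )
            )
        return out

    def map_trace(self, entry: dict) -> pd.DataFrame:
        return pd.read_csv(self.directory / entry["map_trace"])

    def ground_truth(self) -> pd.DataFrame:
        return pd.read_csv(self.directory / self.manifest["ground_truth"])
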