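"""File formats: NIfTI images, frame-timing JSON, tab-separated tables.

All tables are position-ordered per the packaged region table; BPSeries
files carry a one-line comment header naming the reference region, and
connectome files use region ids as both row index and column headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Atlas, RegionTable, load_region_table
from .connectivity import Connectome, GroupConnectome
from .kinetics import BPSeries, DynamicImage, FrameSchedule, RegionalTimeSeries

__all__ = [
    "save_dynamic_image", "load_dynamic_image", "save_frame_schedule",
    "load_frame_schedule", "save_timeseries", "load_timeseries",
    "save_bpseries", "load_bpseries", "save_connectome", "load_connectome",
    "save_group_edges", "save_label_volume", "load_atlas",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_dynamic_image(img: DynamicImage, path, timing_path=None) -> None:
    nii = nib.Nifti1Image(img.data.astype(np.float32), _affine(img.voxel_size_mm))
    nib.save(nii, str(path))
    if img.modality == "PET" and timing_path is not None:
        save_frame_schedule(img.timing, timing_path)


def load_dynamic_image(path, timing_path=None, modality: str = "PET",
                       repetition_time_s: float | None = None) -> DynamicImage:
    nii = nib.load(str(path))
    voxel = tuple(float(v) for v in nii.header.get_zooms()[:3])
    data = np.asarray(nii.dataobj, dtype=float)
    if modality == "PET":
        if timing_path is None:
            raise ValueError("PET image requires a frame-timing sidecar")
        return DynamicImage(data=data, voxel_size_mm=voxel, modality="PET",
                            timing=load_frame_schedule(timing_path))
    return DynamicImage(data=data, voxel_size_mm=voxel, modality="BOLD",
                        repetition_time_s=repetition_time_s)


def save_frame_schedule(schedule: FrameSchedule, path) -> None:
    frames = [{"start_min": float(s), "duration_min": float(d)}
              for s, d in zip(schedule.start_min, schedule.duration_min)]
    Path(path).write_text(json.dumps(frames, indent=1))


def load_frame_schedule(path) -> FrameSchedule:
    frames = json.loads(Path(path).read_text())
    return FrameSchedule(np.array([f["start_min"] for f in frames]),
                         np.array([f["duration_min"] for f in frames]))


def save_timeseries(ts: RegionalTimeSeries, path) -> None:
    df = pd.DataFrame(ts.values, index=ts.region_ids,
                      columns=[f"{t:.6g}" for t in ts.frame_mid_min])
    with open(path, "w") as fh:
        fh.write(f"# modality={ts.modality}\n")
        df.to_csv(fh, sep="\t", index_label="region_id")


def load_timeseries(path) -> RegionalTimeSeries:
    with open(path) as fh:
        header = fh.readline().strip()
        modality = header.split("modality=")[1] if "modality=" in header else "PET"
        df = pd.read_csv(fh, sep="\t", index_col="region_id")
    return RegionalTimeSeries(values=df.to_numpy(float),
                              region_ids=[str(i) for i in df.index],
                              frame_mid_min=np.array([float(c) for c in df.columns]),
                              modality=modality)


def save_bpseries(bp: BPSeries, path) -> None:
    df = pd.DataFrame(bp.values, index=bp.region_ids,
                      columns=[f"{t:.6g}" for t in bp.frame_mid_min])
    with open(path, "w") as fh:
        fh.write(f"# reference_region={bp.reference_region}"
                 f" retained_window_min={bp.retained_window_min}\n")
        df.to_csv(fh, sep="\t", index_label="region_id")


def load_bpseries(path) -> BPSeries:
    with open(path) as fh:
        header = fh.readline()
        reference = header.split("reference_region=")[1].split()[0]
        df = pd.read_csv(fh, sep="\t", index_col="region_id")
    return BPSeries(values=df.to_numpy(float),
                    region_ids=[str(i) for i in df.index],
                    frame_mid_min=np.array([float(c) for c in df.columns]),
                    reference_region=reference)


def save_connectome(conn: Connectome, path) -> None:
    pd.DataFrame(conn.z, index=conn.region_ids, columns=conn.region_ids).to_csv(
        path, sep="\t", index_label="region_id")


def load_connectome(path, subject_id: str = "", modality: str = "PET") -> Connectome:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return Connectome(z=df.to_numpy(float), region_ids=[str(i) for i in df.index],
                      subject_id=subject_id, modality=modality)


def save_group_edges(group: GroupConnectome, path) -> None:
    """Edge-list export: one row per unique region pair with group stats."""
    iu = np.triu_indices(group.n_regions, k=1)
    pd.DataFrame({
        "region_i": [group.region_ids[i] for i in iu[0]],
        "region_j": [group.region_ids[j] for j in iu[1]],
        "mean_z": group.mean_z[iu],
        "t": group.edge_t[iu],
        "p": group.edge_p[iu],
        "fwe_pass": group.fwe_mask[iu],
    }).to_csv(path, sep="\t", index=False)


def save_label_volume(atlas: Atlas, path) -> None:
    nii = nib.Nifti1Image(atlas.label_volume.astype(np.int16),
                          _affine(atlas.voxel_size_mm))
    nib.save(nii, str(path))


def load_atlas(label_path, table_path=None) -> Atlas:
    nii = nib.load(str(label_path))
    table = load_region_table(table_path)
    return Atlas(label_volume=np.asarray(nii.dataobj).astype(np.int32),
                 voxel_size_mm=tuple(float(v) for v in nii.header.get_zooms()[:3]),
                 region_table=table)
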