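"""NIfTI / CSV / JSON readers and writers for the pipeline's artifacts.

Multi-echo volumes are stored as 4D NIfTI (x, y, z, echo) with echo times
in a JSON sidecar; label maps as integer 3D NIfTI plus a label-name CSV;
T2 maps as one 3D NIfTI per component.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from myotex.t2_mapping import MultiEchoVolume, T2Map
from myotex.texture_analysis import LabelMap

__all__ = [
    "save_multi_echo",
    "load_multi_echo",
    "save_labelmap",
    "load_labelmap",
    "save_t2map",
    "load_t2map",
]


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_multi_echo(vol: MultiEchoVolume, nii_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    nii_path = Path(nii_path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size)), nii_path)
    sidecar = Path(sidecar_path) if sidecar_path else nii_path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"echo_times_ms": [float(t) for t in vol.echo_times]}, indent=2))


def load_multi_echo(nii_path: str | Path, sidecar_path: str | Path | None = None) -> MultiEchoVolume:
    nii_path = Path(nii_path)
    img = nib.load(nii_path)
    sidecar = Path(sidecar_path) if sidecar_path else nii_path.with_suffix("").with_suffix(".json")
    echo_times = json.loads(sidecar.read_text())["echo_times_ms"]
    zooms = img.header.get_zooms()[:3]
    return MultiEchoVolume(
        data=np.asarray(img.dataobj, dtype=float),
        echo_times=np.asarray(echo_times, dtype=float),
        voxel_size=tuple(float(z) for z in zooms),
    )


def save_labelmap(lmap: LabelMap, nii_path: str | Path, names_csv: str | Path | None = None) -> None:
    nii_path = Path(nii_path)
    nib.save(nib.Nifti1Image(lmap.labels.astype(np.int16), _affine(lmap.voxel_size)), nii_path)
    csv_path = Path(names_csv) if names_csv else nii_path.with_suffix("").with_suffix(".labels.csv")
    pd.DataFrame(
        sorted(lmap.names.items()), columns=["label", "name"]
    ).to_csv(csv_path, index=False)


def load_labelmap(nii_path: str | Path, names_csv: str | Path | None = None) -> LabelMap:
    nii_path = Path(nii_path)
    img = nib.load(nii_path)
    csv_path = Path(names_csv) if names_csv else nii_path.with_suffix("").with_suffix(".labels.csv")
    names_df = pd.read_csv(csv_path)
    names = {int(r.label): str(r.name) for r in names_df.itertuples()}
    zooms = img.header.get_zooms()[:3]
    return LabelMap(
        labels=np.asarray(img.dataobj).astype(np.int32),
        names=names,
        voxel_size=tuple(float(z) for z in zooms),
    )


def save_t2map(t2map: T2Map, out_dir: str | Path, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(t2map.voxel_size)
    nib.save(nib.Nifti1Image(t2map.t2.astype(np.float32), aff), out / f"{prefix}t2.nii.gz")
    nib.save(nib.Nifti1Image(t2map.s0.astype(np.float32), aff), out / f"{prefix}s0.nii.gz")
    nib.save(nib.Nifti1Image(t2map.r2_of_fit.astype(np.float32), aff), out / f"{prefix}r2.nii.gz")
    nib.save(nib.Nifti1Image(t2map.valid_mask.astype(np.uint8), aff), out / f"{prefix}valid.nii.gz")


def load_t2map(out_dir: str | Path, prefix: str = "") -> T2Map:
    out = Path(out_dir)
    t2 = nib.load(out / f"{prefix}t2.nii.gz")
    s0 = nib.load(out / f"{prefix}s0.nii.gz")
    r2 = nib.load(out / f"{prefix}r2.nii.gz")
    valid = nib.load(out / f"{prefix}valid.nii.gz")
    zooms = t2.header.get_zooms()[:3]
    return T2Map(
        t2=np.asarray(t2.dataobj, dtype=float),
        s0=np.asarray(s0.dataobj, dtype=float),
        r2_of_fit=np.asarray(r2.dataobj, dtype=float),
        valid_mask=np.asarray(valid.dataobj).astype(bool),
        voxel_size=tuple(float(z) for z in zooms),
    )
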