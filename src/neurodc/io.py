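"""NIfTI-1 input/output and provenance sidecars.

Images are written with a diagonal affine built from the voxel size.
Loading a 4-D series against a 3-D mask produces the in-mask
voxel x time matrix used by the DC engine.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .dc import DCMap, MaskedBOLD
from .grids import ToyAtlas, ToyGeometry

__all__ = [
    "save_mask",
    "save_atlas",
    "save_bold",
    "save_map",
    "load_geometry",
    "load_atlas",
    "load_bold",
    "write_provenance",
    "sha256_of",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_mask(geometry: ToyGeometry, path: str | Path) -> None:
    img = nib.Nifti1Image(
        geometry.mask.astype(np.uint8), _affine(geometry.voxel_size_mm)
    )
    nib.save(img, str(path))


def save_atlas(atlas: ToyAtlas, path: str | Path) -> None:
    geom = atlas.geometry
    affine = _affine(geom.voxel_size_mm if geom is not None else (1.0, 1.0, 1.0))
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))


def save_bold(bold: MaskedBOLD, path: str | Path) -> None:
    vol = np.zeros(bold.geometry.shape + (bold.n_timepoints,), dtype=np.float32)
    vol[tuple(bold.voxel_index.T)] = bold.data
    nib.save(
        nib.Nifti1Image(vol, _affine(bold.geometry.voxel_size_mm)), str(path)
    )


def save_map(dc_map: DCMap, path: str | Path, sidecar: bool = True) -> None:
    vol = dc_map.to_volume(fill=0.0).astype(np.float32)
    nib.save(
        nib.Nifti1Image(vol, _affine(dc_map.geometry.voxel_size_mm)), str(path)
    )
    if sidecar:
        meta = {
            "stage": dc_map.stage,
            "variant": dc_map.variant,
            "r0": dc_map.r0,
            **{k: v for k, v in dc_map.meta.items() if _jsonable(v)},
            "software": f"neurodc {__version__}",
        }
        Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_geometry(mask_path: str | Path) -> ToyGeometry:
    img = nib.load(str(mask_path))
    mask = np.asarray(img.dataobj) > 0
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ToyGeometry(shape=mask.shape, voxel_size_mm=voxel_size, mask=mask)


def load_atlas(atlas_path: str | Path, geometry: ToyGeometry | None = None) -> ToyAtlas:
    img = nib.load(str(atlas_path))
    labels = np.rint(np.asarray(img.dataobj)).astype(int)
    region_ids = sorted(int(r) for r in np.unique(labels) if r != 0)
    return ToyAtlas(
        labels=labels,
        region_ids=region_ids,
        region_names=[f"region_{r:03d}" for r in region_ids],
        geometry=geometry,
    )


def load_map(
    map_path: str | Path,
    geometry: ToyGeometry,
    stage: str = "smoothed",
    variant: str = "weighted",
    r0: float = 0.25,
) -> DCMap:
    """Load a 3-D map NIfTI back into a masked :class:`DCMap`."""
    vol = np.asarray(nib.load(str(map_path)).dataobj, dtype=float)
    if vol.shape != geometry.shape:
        raise ValueError(f"{map_path}: shape {vol.shape} != geometry {geometry.shape}")
    coords = geometry.mask_coordinates()
    return DCMap(
        values=vol[tuple(coords.T)],
        stage=stage,
        variant=variant,
        r0=r0,
        geometry=geometry,
        voxel_index=coords,
    )


def load_bold(bold_path: str | Path, geometry: ToyGeometry) -> MaskedBOLD:
    img = nib.load(str(bold_path))
    data4d = np.asarray(img.dataobj, dtype=float)
    if data4d.ndim != 4:
        raise ValueError(f"{bold_path}: expected a 4-D series, got {data4d.ndim}-D")
    coords = geometry.mask_coordinates()
    return MaskedBOLD(
        data=data4d[tuple(coords.T)], geometry=geometry, voxel_index=coords
    )


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(
    out_dir: str | Path,
    config_snapshot: dict,
    artifacts: list[str | Path],
    record_timestamps: bool = False,
) -> Path:
    """One provenance record per run: config, version, artifact hashes."""
    out_dir = Path(out_dir)
    record = {
        "software": f"neurodc {__version__}",
        "config": config_snapshot,
        "artifacts": {
            str(Path(p).relative_to(out_dir)): sha256_of(p) for p in artifacts
        },
    }
    if record_timestamps:
        record["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
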