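"""File I/O: tractograms (TCK/TRK), NIfTI masks and maps, tables, configs.

Thin wrappers over nibabel and pandas that move between this package's
in-memory containers (:class:`~ufiber.tractometry.Tractogram`,
:class:`~ufiber.tractometry.Mask`) and the on-disk formats, keeping world-mm
coordinates and header affines consistent in both directions.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines.tractogram import Tractogram as NibTractogram

from .simulate import PhantomSet
from .tractometry import Mask, Tractogram, VolumeGrid


# -- tractograms ------------------------------------------------------------


def write_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    """Write TCK or TRK (by extension); points are stored in world mm."""
    path = Path(path)
    nt = NibTractogram(tractogram.streamlines, affine_to_rasmm=np.eye(4))
    header = {}
    if path.suffix == ".trk":
        header = {
            "voxel_to_rasmm": tractogram.grid.affine.astype(np.float32),
            "voxel_sizes": tractogram.grid.voxel_edges.astype(np.float32),
            "dimensions": np.asarray(tractogram.grid.shape, dtype=np.int16),
        }
        TrkFile(nt, header).save(str(path))
    elif path.suffix == ".tck":
        TckFile(nt, header).save(str(path))
    else:
        raise ValueError(f"unsupported tractogram extension: {path.suffix}")


def read_tractogram(path: str | Path, grid: VolumeGrid) -> Tractogram:
    """Read TCK/TRK into world-mm streamlines on the given reference grid."""
    path = Path(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot parse tractogram {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return Tractogram(streamlines=streamlines, grid=grid)


# -- NIfTI volumes ----------------------------------------------------------


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    grid = VolumeGrid(shape=img.shape[:3], affine=img.affine)
    return Mask(grid=grid, voxels=np.asanyarray(img.dataobj) > 0)


def write_scalar_map(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_scalar_map(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    return (
        np.asanyarray(img.dataobj).astype(float),
        VolumeGrid(shape=img.shape[:3], affine=img.affine),
    )


# -- tables and sidecars ----------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assignment(bundles: dict, path: str | Path) -> None:
    """Per-bundle assignment as JSON {pathway: sorted indices}."""
    payload = {
        name: sorted(int(i) for i in bundle.streamline_indices)
        for name, bundle in bundles.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_assignment(path: str | Path) -> dict[str, list[int]]:
    return json.loads(Path(path).read_text())


def write_phantom(phantom: PhantomSet, out_dir: str | Path) -> None:
    """Phantom as TCK + NIfTI masks + JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tractogram(phantom.tractogram, out / "streamlines.tck")
    for name, mask in phantom.lr_masks.items():
        write_mask(mask, out / f"mask_{name}.nii.gz")
    truth = {
        "grid_shape": list(phantom.grid.shape),
        "grid_affine": phantom.grid.affine.tolist(),
        "pathways": sorted(phantom.lr_masks),
        "truth_labels": [sorted(s) for s in phantom.truth_labels],
        "outlier_flags": phantom.outlier_flags.astype(int).tolist(),
        "in_band": phantom.in_band.astype(int).tolist(),
        "lengths_mm": phantom.lengths.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=1, sort_keys=True))
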