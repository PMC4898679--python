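"""File I/O: GIFTI surfaces and scalar maps, NIfTI tensor volumes and
masks, TrackVis TRK streamlines, TSV tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import gifti
from nibabel.streamlines import Tractogram, TrkFile

from .geometry import ScalarMap, TriSurface
from .tracts import StreamlineSet, TensorVolume, VoxelMask


# -- GIFTI surfaces and per-vertex maps -------------------------------------


def save_surface_gifti(surface: TriSurface, path: str) -> None:
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                surface.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                surface.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, path)


def load_surface_gifti(path: str) -> TriSurface:
    img = nib.load(path)
    pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return TriSurface(np.asarray(pts, float), np.asarray(tris, int))


def save_scalar_gifti(scalar_map: ScalarMap, path: str) -> None:
    da = gifti.GiftiDataArray(
        scalar_map.values.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
    )
    meta = gifti.GiftiMetaData()
    meta["Name"] = scalar_map.name
    meta["Units"] = scalar_map.units
    img = gifti.GiftiImage(darrays=[da], meta=meta)
    nib.save(img, path)


def load_scalar_gifti(path: str) -> ScalarMap:
    img = nib.load(path)
    meta = dict(img.meta) if img.meta else {}
    return ScalarMap(
        np.asarray(img.darrays[0].data, float),
        units=meta.get("Units", ""),
        name=meta.get("Name", ""),
    )


def save_label_gifti(labels: np.ndarray, path: str) -> None:
    """Integer per-vertex label map (cluster ids; 0 = background)."""
    da = gifti.GiftiDataArray(
        np.asarray(labels, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
    )
    nib.save(gifti.GiftiImage(darrays=[da]), path)


# -- NIfTI tensor volumes and masks ------------------------------------------


def save_tensor_nifti(vol: TensorVolume, path: str) -> None:
    """(X, Y, Z, 6) lower-triangular (dxx,dxy,dyy,dxz,dyz,dzz) NIfTI."""
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), path)


def load_tensor_nifti(path: str) -> TensorVolume:
    img = nib.load(path)
    return TensorVolume(np.asarray(img.dataobj, float), img.affine)


def save_mask_nifti(mask: VoxelMask, path: str) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine), path)


def load_mask_nifti(path: str) -> VoxelMask:
    img = nib.load(path)
    return VoxelMask(np.asarray(img.dataobj) > 0, img.affine)


# -- TrackVis TRK -------------------------------------------------------------


def save_streamlines_trk(
    streams: StreamlineSet, path: str, shape: tuple | None = None
) -> None:
    """Write streamlines (world mm, RAS) to a TrackVis file.

    The TRK header voxel size / affine fields are populated from the
    streamline set's reference affine so files round-trip bit-exactly
    through nibabel's RAS+mm space handling.
    """
    affine = streams.affine if streams.affine is not None else np.eye(4)
    header = {}
    header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = affine.astype(np.float32)
    header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.linalg.norm(
        affine[:3, :3], axis=0
    ).astype(np.float32)
    if shape is not None:
        header[nib.streamlines.trk.Field.DIMENSIONS] = np.asarray(shape, np.int16)
    t = Tractogram(streams.lines, affine_to_rasmm=np.eye(4))
    TrkFile(t, header=header).save(path)


def load_streamlines_trk(path: str) -> StreamlineSet:
    trk = TrkFile.load(path)  # nibabel returns points in RAS mm
    affine = np.asarray(trk.header[nib.streamlines.trk.Field.VOXEL_TO_RASMM], float)
    lines = [np.asarray(s, float) for s in trk.tractogram.streamlines]
    return StreamlineSet(lines, affine=affine)


# -- TSV tables ---------------------------------------------------------------


def save_table_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
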