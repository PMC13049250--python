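"""Image containers and NIfTI input/output.

An :class:`ImageStack` bundles the per-measurement magnitude volumes with
the B1+ actual-to-nominal flip-angle ratio map and an ROI label mask, all
on a shared 3D grid.  Volumes are stored measurement-first,
``(n_meas, nx, ny, nz)``; on disk the stack is a single 4D NIfTI with the
measurement axis last, as scanners export it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageStack", "save_stack", "load_stack", "save_maps"]


@dataclass
class ImageStack:
    """Multi-measurement magnitude volumes plus B1+ ratio map and ROI labels.

    ``mask`` holds integer region labels (0 = background); any nonzero voxel
    is fitted.  ``b1_ratio`` must be positive wherever the mask is set.
    """

    volumes: np.ndarray          # (n_meas, nx, ny, nz)
    b1_ratio: np.ndarray         # (nx, ny, nz)
    mask: np.ndarray             # (nx, ny, nz) integer labels
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.b1_ratio = np.asarray(self.b1_ratio, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be a 4D (n_meas, nx, ny, nz) array")
        shape = self.volumes.shape[1:]
        if self.b1_ratio.shape != shape or self.mask.shape != shape:
            raise ValueError("volumes, b1_ratio and mask must share the 3D grid")
        if np.any(self.b1_ratio[self.mask > 0] <= 0):
            raise ValueError("b1_ratio must be positive where the mask is set")

    @property
    def n_measurements(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def voxel_signals(self, index: tuple[int, int, int]) -> np.ndarray:
        """Per-measurement signal vector of one voxel."""
        return self.volumes[(slice(None), *index)]


def save_stack(stack: ImageStack, out_dir) -> None:
    """Write a stack as ``images.nii.gz`` (4D), ``b1.nii.gz``, ``mask.nii.gz``
    plus a JSON sidecar with any metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img4d = np.moveaxis(stack.volumes, 0, -1)
    nib.save(nib.Nifti1Image(img4d, stack.affine), out / "images.nii.gz")
    nib.save(nib.Nifti1Image(stack.b1_ratio, stack.affine), out / "b1.nii.gz")
    nib.save(nib.Nifti1Image(stack.mask.astype(np.int16), stack.affine),
             out / "mask.nii.gz")
    with open(out / "stack.json", "w") as fh:
        json.dump(stack.meta, fh, indent=2, default=str)


def load_stack(images, b1, mask) -> ImageStack:
    """Load a stack from NIfTI files.

    Parameters
    ----------
    images : path or sequence of paths
        A single 4D NIfTI (measurement axis last) or one 3D file per
        measurement.
    b1, mask : path
        B1+ ratio map and integer ROI mask.
    """
    if isinstance(images, (str, Path)):
        img = nib.load(str(images))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("single images file must be 4D")
        volumes = np.moveaxis(data, -1, 0)
        affine = img.affine
    else:
        vols = []
        affine = None
        for p in images:
            img = nib.load(str(p))
            vols.append(np.asarray(img.dataobj, dtype=float))
            affine = img.affine if affine is None else affine
        volumes = np.stack(vols, axis=0)
    b1_arr = np.asarray(nib.load(str(b1)).dataobj, dtype=float)
    mask_arr = np.asarray(nib.load(str(mask)).dataobj).astype(int)
    return ImageStack(volumes=volumes, b1_ratio=b1_arr, mask=mask_arr,
                      affine=affine)


def save_maps(maps: dict, out_dir, affine=None) -> None:
    """Write named 3D maps (e.g. t1/t2/m0/residual/flag) as NIfTI files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    for name, arr in maps.items():
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=float), affine),
                 out / f"{name}.nii.gz")
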