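"""Labelled voxel volumes and their I/O.

The voxel container used throughout the package: a 3-D integer label array
with isotropic-or-not spacing (mm) and a world origin.  World coordinates of
a voxel centre are ``origin + index * spacing``; the slice axis is z (last
axis).  Labels are restricted to the canonical anatomy/tissue classes listed
in :data:`DEFAULT_LABELS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

#: canonical label integers for the segmentation classes
DEFAULT_LABELS = {
    "background": 0,
    "lv_wall": 1,
    "rv_wall": 2,
    "lv_blood": 3,
    "rv_blood": 4,
    "scar": 5,
    "bz": 6,
}

#: labels counted as myocardium (conducting or not)
MYOCARDIUM = ("lv_wall", "rv_wall", "scar", "bz")


@dataclass
class LabelVolume:
    """3-D voxel grid of anatomical/tissue labels with spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integers")
        known = set(self.label_map.values())
        present = set(np.unique(self.data).tolist())
        if not present <= known:
            raise ValueError(f"unknown labels present: {sorted(present - known)}")

    # -- convenience ------------------------------------------------------
    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        m = np.zeros(self.data.shape, dtype=bool)
        for name in names:
            m |= self.data == self.label_map[name]
        return m

    def myocardium_mask(self) -> np.ndarray:
        return self.mask(*MYOCARDIUM)

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.data == self.label_map[name]))

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape (n, 3)."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def copy(self, data: np.ndarray | None = None) -> "LabelVolume":
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            label_map=dict(self.label_map),
            meta=dict(self.meta),
        )


def save_nifti(vol: LabelVolume, path: str) -> None:
    """Write a :class:`LabelVolume` as a NIfTI file (spacing/origin in affine)."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.int16), affine)
    nib.save(img, path)


def load_nifti(path: str, label_map: dict[str, int] | None = None) -> LabelVolume:
    img = nib.load(path)
    affine = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(x) for x in affine[:3, 3])
    data = np.asanyarray(img.dataobj).astype(np.int32)
    return LabelVolume(
        data, spacing=spacing, origin=origin,
        label_map=dict(label_map or DEFAULT_LABELS),
    )


@dataclass(frozen=True)
class ScarSpec:
    """Parameterized anteroseptal scar morphology.

    ``center_uvc`` locates the scar centre as (apicobasal fraction in [0,1],
    rotational angle rad); ``extent`` is the (apicobasal, circumferential)
    half-extent in mm.  ``isthmus_width`` > 0 carves a through-going
    conducting channel (border-zone tissue) of that width through the core;
    ``bz_rim`` is the thickness of the border-zone rim around the core.
    """

    center_uvc: tuple[float, float] = (0.55, 0.5)
    extent: tuple[float, float] = (14.0, 16.0)
    isthmus_width: float = 0.0
    bz_rim: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isthmus_width < 0:
            raise ValueError("isthmus_width must be >= 0")
        if self.bz_rim < 0:
            raise ValueError("bz_rim must be >= 0")
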