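"""Segmented head phantoms on a structured voxel grid.

The simulator works on a uniform voxel grid (default 1 mm) holding an integer
tissue label per voxel (0 = background, 1 = white matter, 2 = grey matter,
3 = cerebrospinal fluid) and a matching per-voxel electric conductivity in
S/m.  The built-in generator produces nested ellipsoidal shells (WM core, GM
shell, CSF shell) standing in for a segmented head template; real label
volumes can be loaded from NIfTI instead.

World coordinates are 0-based: the center of voxel ``(i, j, k)`` sits at
``(i + 0.5) * voxel_size`` mm along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, FormatError, GeometryError, ValidationError

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_GM = 2
LABEL_CSF = 3
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_WM, LABEL_GM, LABEL_CSF})

#: Tissue conductivities in S/m: WM 0.14, GM 0.33, CSF 1.79.
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    LABEL_WM: 0.14,
    LABEL_GM: 0.33,
    LABEL_CSF: 1.79,
}

LABEL_NAMES = {LABEL_BACKGROUND: "background", LABEL_WM: "WM", LABEL_GM: "GM", LABEL_CSF: "CSF"}


@dataclass(frozen=True)
class TissuePhantom:
    """A labeled 3-D voxel volume with per-voxel conductivity.

    Attributes
    ----------
    labels : (nx, ny, nz) int array
        Tissue label per voxel, values in {0, 1, 2, 3}.
    voxel_size : (3,) float array
        Voxel edge lengths in mm.
    conductivity : (nx, ny, nz) float array or None
        Conductivity in S/m; zero on background, positive on tissue.
        ``None`` until :func:`assign_conductivities` is applied.
    """

    labels: np.ndarray
    voxel_size: np.ndarray
    conductivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError(f"labels must be 3-D, got {labels.ndim}-D")
        if any(n < 8 for n in labels.shape):
            raise GeometryError(f"grid needs >= 8 voxels per axis, got {labels.shape}")
        unknown = set(np.unique(labels)) - VALID_LABELS
        if unknown:
            raise ValidationError(f"unknown tissue labels present: {sorted(unknown)}")
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        if np.any(vs <= 0):
            raise GeometryError(f"voxel size must be positive, got {vs}")
        object.__setattr__(self, "labels", labels.astype(np.int16))
        object.__setattr__(self, "voxel_size", vs)
        if self.conductivity is not None:
            cond = np.asarray(self.conductivity, dtype=float)
            if cond.shape != labels.shape:
                raise FormatError("conductivity grid shape must match labels")
            tissue = labels > 0
            if np.any(cond[tissue] <= 0) or np.any(cond[~tissue] != 0):
                raise ValidationError(
                    "conductivity must be > 0 on tissue and 0 on background"
                )
            object.__setattr__(self, "conductivity", cond)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def affine(self) -> np.ndarray:
        """Voxel-index -> world-mm affine (voxel centers at (i + 0.5) * size)."""
        aff = np.diag([*self.voxel_size, 1.0])
        aff[:3, 3] = 0.5 * self.voxel_size
        return aff

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers as an open (sparse) meshgrid."""
        axes = [
            (np.arange(n) + 0.5) * self.voxel_size[i]
            for i, n in enumerate(self.shape)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


def _as_radii(radii_mm) -> np.ndarray:
    """Normalise per-compartment radii to a (3, 3) array of semi-axes (WM, GM, CSF)."""
    arr = [np.broadcast_to(np.asarray(r, dtype=float), (3,)) for r in radii_mm]
    if len(arr) != 3:
        raise GeometryError("exactly three compartment radii (WM, GM, CSF) required")
    return np.stack(arr)


def make_layered_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float | tuple[float, float, float] = 1.0,
    radii_mm=(20.0, 25.0, 28.0),
    center_mm: tuple[float, float, float] | None = None,
) -> TissuePhantom:
    """Build a nested-ellipsoid head stand-in: WM core, GM shell, CSF shell.

    Parameters
    ----------
    radii_mm : sequence of three scalars or three 3-vectors
        Strictly increasing semi-axes of the WM, GM and CSF ellipsoids, mm.
    center_mm : optional
        Ellipsoid center in world mm; defaults to the grid center.
    """
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    radii = _as_radii(radii_mm)
    if not (np.all(radii[0] < radii[1]) and np.all(radii[1] < radii[2])):
        raise GeometryError(f"radii must be strictly increasing per axis, got {radii.tolist()}")
    extent = np.asarray(shape) * vs
    if center_mm is None:
        center = extent / 2.0
    else:
        center = np.asarray(center_mm, dtype=float)
    if np.any(center - radii[2] < 0) or np.any(center + radii[2] > extent):
        raise GeometryError(
            f"outer radius {radii[2].tolist()} mm does not fit inside grid extent {extent.tolist()} mm"
        )

    axes = [(np.arange(n) + 0.5) * vs[i] - center[i] for i, n in enumerate(shape)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    labels = np.zeros(shape, dtype=np.int16)
    # paint outside-in so inner compartments overwrite outer ones
    for label, r in [(LABEL_CSF, radii[2]), (LABEL_GM, radii[1]), (LABEL_WM, radii[0])]:
        inside = (xx / r[0]) ** 2 + (yy / r[1]) ** 2 + (zz / r[2]) ** 2 <= 1.0
        labels[inside] = label
    return TissuePhantom(labels=labels, voxel_size=vs)


def assign_conductivities(
    phantom: TissuePhantom,
    table: Mapping[int, float] | None = None,
) -> TissuePhantom:
    """Fill the per-voxel conductivity from a label -> S/m table.

    The default table is WM 0.14, GM 0.33, CSF 1.79 S/m; background stays 0.
    """
    if table is None:
        table = DEFAULT_CONDUCTIVITIES
    present = set(int(v) for v in np.unique(phantom.labels)) - {LABEL_BACKGROUND}
    missing = present - set(int(k) for k in table)
    if missing:
        names = ", ".join(f"{m} ({LABEL_NAMES.get(m, '?')})" for m in sorted(missing))
        raise ConfigurationError(f"conductivity table missing label(s): {names}")
    cond = np.zeros(phantom.shape, dtype=float)
    for label in present:
        cond[phantom.labels == label] = float(table[label])
    return replace(phantom, conductivity=cond)


def read_labels_nifti(path: str | Path) -> TissuePhantom:
    """Load a 3-D integer label volume (NIfTI) as a TissuePhantom."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D label volume, got {data.ndim}-D")
    labels = np.rint(data).astype(np.int16)
    unknown = set(np.unique(labels)) - VALID_LABELS
    if unknown:
        raise ValidationError(f"unknown tissue labels in {path}: {sorted(unknown)}")
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return TissuePhantom(labels=labels, voxel_size=voxel_size)


def write_volume_nifti(
    volume: np.ndarray | TissuePhantom,
    path: str | Path,
    voxel_size: float | tuple[float, float, float] = 1.0,
) -> None:
    """Write a 3-D volume (or a phantom's labels) to NIfTI-1."""
    if isinstance(volume, TissuePhantom):
        data, vs = volume.labels, volume.voxel_size
        affine = volume.affine
    else:
        data = np.asarray(volume)
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got {data.ndim}-D")
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        affine = np.diag([*vs, 1.0])
        affine[:3, 3] = 0.5 * vs
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def ellipsoid_shell_volumes_mm3(radii_mm) -> dict[int, float]:
    """Analytic compartment volumes of the layered phantom (mm^3 per label)."""
    radii = _as_radii(radii_mm)
    full = 4.0 / 3.0 * np.pi * np.prod(radii, axis=1)
    return {
        LABEL_WM: float(full[0]),
        LABEL_GM: float(full[1] - full[0]),
        LABEL_CSF: float(full[2] - full[1]),
    }
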