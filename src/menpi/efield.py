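"""Quasi-static current-conduction solve for neuronal firing sources.

Neuronal firing is modeled as a balanced volumetric current source (an offset
monopole pair) inside the tissue; the potential solves the steady conduction
equation  div(sigma grad phi) = -J_v  on the voxel grid with insulating
(zero normal current) boundaries at the tissue/background interface, and the
electric field is E = -grad phi.

Discretization: finite-volume on the structured grid with harmonic-mean face
conductivities, which handles the WM/GM/CSF conductivity jumps conservatively.
The linear system is symmetric positive semi-definite (constant nullspace);
it is solved with Jacobi-preconditioned conjugate gradients and the gauge is
fixed by removing the tissue-mean potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, GeometryError, SolverError
from .phantom import TissuePhantom

#: Calibration constant converting the per-capacitance firing current
#: (pA/pF) to a volumetric density: effective membrane capacitance per unit
#: tissue volume, pF/mm^3.  The default is chosen so that the default 2-mm
#: firing spot in the default layered phantom produces a peak |E| of about
#: 100 V/m, the top of the endogenous-field range the particle model targets.
DEFAULT_CAPACITANCE_DENSITY_PF_MM3 = 8.5e5

_PA_PER_PF_TO_A_PER_M3 = 1.0e-12 * 1.0e9  # (pA/pF * pF/mm^3) -> A/m^3


@dataclass(frozen=True)
class FiringSource:
    """A spherical patch of synchronously firing tissue.

    ``current_density_per_capacitance`` is the firing current per membrane
    capacitance (default 70 pA/pF); ``capacitance_density`` converts it to a
    volumetric density.  The return current enters through an identical
    sphere offset by ``sink_offset_voxels`` so the net injected current is
    exactly zero.
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float = 2.0
    current_density_per_capacitance: float = 70.0  # pA/pF
    capacitance_density: float = DEFAULT_CAPACITANCE_DENSITY_PF_MM3  # pF/mm^3
    sink_offset_voxels: tuple[int, int, int] = (1, 0, 0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ConfigurationError("firing-spot diameter must be positive")
        if self.current_density_per_capacitance < 0:
            raise ConfigurationError("pA/pF current density must be non-negative")
        if self.capacitance_density < 0:
            raise ConfigurationError("capacitance density must be non-negative")
        if all(o == 0 for o in self.sink_offset_voxels):
            raise GeometryError("sink offset must be nonzero (source and sink coincide)")

    @property
    def volumetric_density_a_m3(self) -> float:
        """Source density J_v in A/m^3."""
        return (
            self.current_density_per_capacitance
            * self.capacitance_density
            * _PA_PER_PF_TO_A_PER_M3
        )


@dataclass(frozen=True)
class CurrentSourceMap:
    """Per-voxel volumetric current-source density, A/m^3 (balanced)."""

    density: np.ndarray
    voxel_size: np.ndarray

    @property
    def total_current_a(self) -> float:
        voxel_volume_m3 = float(np.prod(self.voxel_size)) * 1.0e-9
        return float(self.density.sum() * voxel_volume_m3)


@dataclass(frozen=True)
class PotentialMap:
    """Electric potential phi (V) on the grid; zero outside tissue."""

    phi: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray
    relative_residual: float = 0.0


@dataclass(frozen=True)
class EFieldMap:
    """Electric field E = -grad phi, V/m, with magnitude; zero off-tissue."""

    components: np.ndarray  # (..., 3)
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        if comps.shape[-1] != 3:
            raise ConfigurationError("field components must be stacked on the last axis")
        mag = np.linalg.norm(comps, axis=-1) if self.magnitude is None else self.magnitude
        mask = mag > 0 if self.mask is None else self.mask
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "mask", mask)


def _sphere_mask(phantom: TissuePhantom, center_mm, diameter_mm: float) -> np.ndarray:
    xx, yy, zz = phantom.voxel_centers_mm()
    r2 = (
        (xx - center_mm[0]) ** 2
        + (yy - center_mm[1]) ** 2
        + (zz - center_mm[2]) ** 2
    )
    return r2 <= (diameter_mm / 2.0) ** 2


def _shift_mask(mask: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Translate a boolean mask by integer voxels, clipping at grid edges."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for o, n in zip(offset, mask.shape):
        if abs(o) >= n:
            return out
        src.append(slice(max(0, -o), min(n, n - o)))
        dst.append(slice(max(0, o), min(n, n + o)))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def firing_to_source(firing: FiringSource, phantom: TissuePhantom) -> CurrentSourceMap:
    """Discretize a firing spot into a balanced volumetric source map.

    The source sphere carries +J_v on its tissue voxels; the sink sphere
    (offset copy) carries a uniform negative density scaled so the two sum
    to exactly zero current.
    """
    tissue = phantom.tissue_mask
    src = _sphere_mask(phantom, firing.center_mm, firing.diameter_mm) & tissue
    if not src.any():
        raise GeometryError(
            f"firing spot at {tuple(firing.center_mm)} mm does not intersect tissue"
        )
    snk = _shift_mask(src, firing.sink_offset_voxels) & tissue
    snk &= ~src  # overlapping voxels stay pure source; sink takes the remainder
    if not snk.any():
        raise GeometryError("sink region is empty: offset pushes it off the tissue")
    density = np.zeros(phantom.shape, dtype=float)
    j_v = firing.volumetric_density_a_m3
    density[src] = j_v
    density[snk] = -j_v * src.sum() / snk.sum()
    return CurrentSourceMap(density=density, voxel_size=phantom.voxel_size)


def _build_system(phantom: TissuePhantom) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble the finite-volume conduction operator over tissue voxels.

    Returns (A, index_map, mask) where ``A phi = I`` with I the per-voxel
    injected current in amperes.  Face conductance between two tissue voxels
    is the harmonic mean of their conductivities times face-area/spacing;
    faces to background are omitted (insulating boundary).
    """
    if phantom.conductivity is None:
        raise ConfigurationError("phantom has no conductivity assigned")
    mask = phantom.tissue_mask
    n = int(mask.sum())
    index = -np.ones(phantom.shape, dtype=np.int64)
    index[mask] = np.arange(n)
    sigma = phantom.conductivity
    h_m = phantom.voxel_size * 1.0e-3

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        pair = mask[sl_lo] & mask[sl_hi]
        s1 = sigma[sl_lo][pair]
        s2 = sigma[sl_hi][pair]
        face_area = float(np.prod(np.delete(h_m, axis)))
        g = (2.0 * s1 * s2 / (s1 + s2)) * face_area / h_m[axis]
        i1 = index[sl_lo][pair]
        i2 = index[sl_hi][pair]
        rows.extend([i1, i2])
        cols.extend([i2, i1])
        vals.extend([-g, -g])
        np.add.at(diag, i1, g)
        np.add.at(diag, i2, g)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return a, index, mask


def solve_potential(
    phantom: TissuePhantom,
    source: CurrentSourceMap,
    tolerance: float = 1.0e-8,
    maxiter: int | None = None,
) -> PotentialMap:
    """Solve div(sigma grad phi) = -J_v with insulating outer boundaries.

    ``tolerance`` bounds the max-norm residual of the discrete current
    balance relative to the largest injected voxel current.  The potential
    is returned with mean-zero gauge over tissue.
    """
    if source.density.shape != phantom.shape:
        raise ConfigurationError("source map shape must match the phantom grid")
    a, index, mask = _build_system(phantom)
    voxel_volume_m3 = float(np.prod(phantom.voxel_size)) * 1.0e-9
    b = source.density[mask] * voxel_volume_m3
    b_inf = np.abs(b).max() if b.size else 0.0
    if b_inf == 0.0:
        return PotentialMap(
            phi=np.zeros(phantom.shape), mask=mask, voxel_size=phantom.voxel_size
        )
    imbalance = abs(b.sum()) / (np.abs(b).sum())
    if imbalance > 1.0e-9:
        raise SolverError(
            f"source is unbalanced (net/gross current = {imbalance:.2e}); "
            "no solution exists with insulating boundaries"
        )
    b = b - b.mean()  # enforce exact compatibility with the singular operator

    n = a.shape[0]
    diag = a.diagonal()
    precond = spla.LinearOperator((n, n), matvec=lambda x: x / diag)
    # cg's stopping rule is 2-norm based; translate the max-norm target.
    rtol = max(tolerance * b_inf / np.linalg.norm(b), 1.0e-14)
    maxiter = maxiter or max(2000, 20 * int(round(n ** (1 / 2))))
    x, info = spla.cg(a, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=precond)
    residual_inf = np.abs(a @ x - b).max() / b_inf
    if info != 0 or residual_inf > tolerance:
        raise SolverError(
            f"conduction solve did not converge: info={info}, "
            f"relative residual {residual_inf:.3e} > {tolerance:.1e}"
        )
    x -= x.mean()
    phi = np.zeros(phantom.shape)
    phi[mask] = x
    return PotentialMap(
        phi=phi,
        mask=mask,
        voxel_size=phantom.voxel_size,
        relative_residual=float(residual_inf),
    )


def conservation_residual(
    phantom: TissuePhantom, potential: PotentialMap, source: CurrentSourceMap
) -> float:
    """Max-norm residual of the discrete current balance, relative to the
    largest injected voxel current.  Small values certify flux conservation
    at every interior voxel."""
    a, _, mask = _build_system(phantom)
    voxel_volume_m3 = float(np.prod(phantom.voxel_size)) * 1.0e-9
    b = source.density[mask] * voxel_volume_m3
    b = b - b.mean()
    r = a @ potential.phi[mask] - b
    scale = np.abs(b).max()
    return float(np.abs(r).max() / scale) if scale > 0 else float(np.abs(r).max())


def efield_from_potential(
    potential: PotentialMap, voxel_size_mm=None
) -> EFieldMap:
    """E = -grad phi in V/m via central differences (one-sided at the tissue
    boundary, zero where no tissue neighbour exists along an axis)."""
    vs = potential.voxel_size if voxel_size_mm is None else np.broadcast_to(
        np.asarray(voxel_size_mm, dtype=float), (3,)
    )
    if np.any(vs <= 0):
        raise ConfigurationError("voxel size must be positive")
    phi = potential.phi
    mask = potential.mask
    phi_pad = np.pad(phi, 1)
    mask_pad = np.pad(mask, 1)
    comps = np.zeros(phi.shape + (3,))
    for axis in range(3):
        h = vs[axis] * 1.0e-3  # m
        up = [slice(1, -1)] * 3
        dn = [slice(1, -1)] * 3
        up[axis] = slice(2, None)
        dn[axis] = slice(0, -2)
        phi_up, phi_dn = phi_pad[tuple(up)], phi_pad[tuple(dn)]
        has_up, has_dn = mask_pad[tuple(up)], mask_pad[tuple(dn)]
        grad = np.zeros(phi.shape)
        both = has_up & has_dn
        only_up = has_up & ~has_dn
        only_dn = has_dn & ~has_up
        grad[both] = (phi_up[both] - phi_dn[both]) / (2.0 * h)
        grad[only_up] = (phi_up[only_up] - phi[only_up]) / h
        grad[only_dn] = (phi[only_dn] - phi_dn[only_dn]) / h
        comps[..., axis] = -grad
    comps[~mask] = 0.0
    magnitude = np.linalg.norm(comps, axis=-1)
    magnitude[~mask] = 0.0
    return EFieldMap(components=comps, magnitude=magnitude, mask=mask)
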