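"""Demodulation of MEN by MN images and electric-field recovery.

The MEN image is the structural image modulated by the local electric field;
dividing it voxelwise by the equivalent MN image (same saturation moment,
no ME coupling) isolates the modulation.  Where the forward model is
unclipped and the particle density uniform, the ratio is

    ratio = 1 + alpha * E[V/cm] / (M_S * M_rel(H_op)),

so the field recovers exactly as

    |E| = (ratio - 1) * M_rel(H_op) * M_S * 100 / alpha   (V/m),

with ``H_op`` the drive amplitude at which in-zone particles are read out.
The division uses the raw (de-normalized) signals so that shared structure
cancels regardless of how each image was normalized for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ModeError, ShapeError
from .magnetics import ParticleSpec, langevin_mrel
from .mpi_imaging import MODE_MEN, MODE_MN, MPIImage


@dataclass(frozen=True)
class DemodulatedEMap:
    """Voxelwise MEN/MN ratio and the electric-field map recovered from it."""

    ratio: np.ndarray
    mask: np.ndarray
    epsilon: float
    e_field_v_per_m: np.ndarray | None = None


def demodulate(
    img_men: MPIImage,
    img_mn: MPIImage,
    epsilon: float | None = None,
) -> DemodulatedEMap:
    """Voxelwise MEN/MN raw-signal ratio where the MN signal is resolvable.

    ``epsilon`` guards the division (default 1e-6 of the MN raw maximum);
    voxels below it are masked out and their ratio set to 1 (no information).
    """
    if img_men.mode != MODE_MEN or img_mn.mode != MODE_MN:
        raise ModeError(
            f"expected (MEN, MN) images, got ({img_men.mode}, {img_mn.mode})"
        )
    if img_men.data.shape != img_mn.data.shape:
        raise ShapeError(
            f"image grids differ: {img_men.data.shape} vs {img_mn.data.shape}"
        )
    mn_raw = img_mn.raw
    men_raw = img_men.raw
    if epsilon is None:
        epsilon = 1.0e-6 * float(mn_raw.max())
    mask = mn_raw > epsilon
    ratio = np.ones(mn_raw.shape)
    ratio[mask] = men_raw[mask] / mn_raw[mask]
    return DemodulatedEMap(ratio=ratio, mask=mask, epsilon=float(epsilon))


def recover_efield(
    demod: DemodulatedEMap,
    spec: ParticleSpec,
    h_operating_oe: float,
) -> DemodulatedEMap:
    """Invert the modulation model to an |E| map (V/m), clipped at zero.

    Requires an ME-active spec (alpha > 0): plain MNs carry no field
    information and cannot be inverted.
    """
    if spec.alpha <= 0:
        raise ConfigurationError(
            "cannot invert: particle has alpha = 0 (no magnetoelectric coupling)"
        )
    m_rel_op = float(langevin_mrel(h_operating_oe, spec))
    e_map = (demod.ratio - 1.0) * m_rel_op * spec.m_s_emu_cc * 100.0 / spec.alpha
    e_map = np.clip(e_map, 0.0, None)
    e_map[~demod.mask] = 0.0
    return DemodulatedEMap(
        ratio=demod.ratio,
        mask=demod.mask,
        epsilon=demod.epsilon,
        e_field_v_per_m=e_map,
    )
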