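"""Typed run configuration (YAML) for the full simulation pipeline.

The schema is strict: unknown keys are rejected, every block has the study
defaults built in, and a single global seed deterministically derives the
per-stage seeds (see :func:`stage_seeds`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .dosimetry import DEFAULT_MOLAR_MASS_G_MOL, DEFAULT_SAFETY_LIMIT_W
from .efield import DEFAULT_CAPACITANCE_DENSITY_PF_MM3, FiringSource
from .errors import ConfigurationError
from .magnetics import ParticleSpec
from .mpi_imaging import ScanConfig
from .phantom import LABEL_CSF, LABEL_GM, LABEL_WM

_LABEL_BY_NAME = {"wm": LABEL_WM, "gm": LABEL_GM, "csf": LABEL_CSF}


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Block):
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    radii_mm: dict[str, float] = Field(
        default_factory=lambda: {"wm": 20.0, "gm": 25.0, "csf": 28.0}
    )
    conductivities: dict[str, float] = Field(
        default_factory=lambda: {"wm": 0.14, "gm": 0.33, "csf": 1.79}
    )

    def radii_tuple(self) -> tuple[float, float, float]:
        try:
            return (self.radii_mm["wm"], self.radii_mm["gm"], self.radii_mm["csf"])
        except KeyError as err:
            raise ConfigurationError(f"phantom.radii_mm missing key {err}") from err

    def conductivity_table(self) -> dict[int, float]:
        try:
            return {_LABEL_BY_NAME[k]: v for k, v in self.conductivities.items()}
        except KeyError as err:
            raise ConfigurationError(
                f"phantom.conductivities has unknown tissue {err}; expected wm/gm/csf"
            ) from err


class SourceBlock(_Block):
    center_mm: tuple[float, float, float] | None = None  # None: mid-GM, left pre-frontal
    diameter_mm: float = 2.0
    current_per_capacitance_pa_pf: float = 70.0
    capacitance_density_pf_mm3: float = DEFAULT_CAPACITANCE_DENSITY_PF_MM3
    sink_offset_voxels: tuple[int, int, int] = (1, 0, 0)

    def resolve_center(self, phantom_block: PhantomBlock) -> tuple[float, float, float]:
        """Default firing spot: mid-GM radius along (-1, +1, +1)/sqrt(3)."""
        if self.center_mm is not None:
            return self.center_mm
        shape = np.asarray(phantom_block.shape, dtype=float)
        center = shape * phantom_block.voxel_size_mm / 2.0
        radii = phantom_block.radii_tuple()
        r_mid = 0.5 * (radii[0] + radii[1])
        direction = np.array([-1.0, 1.0, 1.0]) / np.sqrt(3.0)
        return tuple(center + r_mid * direction)

    def to_firing_source(self, phantom_block: PhantomBlock) -> FiringSource:
        return FiringSource(
            center_mm=self.resolve_center(phantom_block),
            diameter_mm=self.diameter_mm,
            current_density_per_capacitance=self.current_per_capacitance_pa_pf,
            capacitance_density=self.capacitance_density_pf_mm3,
            sink_offset_voxels=self.sink_offset_voxels,
        )


class ParticleBlock(_Block):
    diameter_nm: float = 50.0
    m_s: float = 10.0
    m_s_unit: Literal["emu/cc", "emu/g"] = "emu/cc"
    alpha_g_cm_per_v: float = 0.1
    h_c_oe: float = 100.0
    mass_density_g_cc: float = 5.0
    temperature_k: float = 300.0

    def to_spec(self) -> ParticleSpec:
        return ParticleSpec(
            diameter_nm=self.diameter_nm,
            m_s=self.m_s,
            m_s_unit=self.m_s_unit,
            alpha=self.alpha_g_cm_per_v,
            h_c=self.h_c_oe,
            mass_density=self.mass_density_g_cc,
            temperature=self.temperature_k,
        )


class ParticlesBlock(_Block):
    men: ParticleBlock = Field(default_factory=ParticleBlock)
    mn: ParticleBlock = Field(
        default_factory=lambda: ParticleBlock(m_s=100.0, alpha_g_cm_per_v=0.0)
    )


class DoseBlock(_Block):
    dose_mmol_per_kg: float = 0.1
    bodyweight_kg: float = 50.0
    molar_mass_g_mol: float = DEFAULT_MOLAR_MASS_G_MOL
    safety_limit_w: float = DEFAULT_SAFETY_LIMIT_W
    loop_model: Literal["rectangular", "elliptical"] = "rectangular"


class ScanBlock(_Block):
    background_field_oe: float = 500.0
    selection_field_oe: float = -500.0
    linear_halfwidth_oe: float = 50.0
    gradient_oe_per_mm: float = 25.0
    drive_frequency_hz: float = 1.0e4
    drive_amplitude_oe: float = 2.0
    noise_sd: float = 0.0

    def to_scan_config(self, seed: int) -> ScanConfig:
        return ScanConfig(seed=seed, **self.model_dump())


class StudyBlock(_Block):
    densities_per_cc: list[float] = Field(
        default_factory=lambda: list(np.logspace(12, 17, 11))
    )


class RunConfig(_Block):
    seed: int = 0
    output_dir: str = "menpi_out"
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    source: SourceBlock = Field(default_factory=SourceBlock)
    particles: ParticlesBlock = Field(default_factory=ParticlesBlock)
    dose: DoseBlock = Field(default_factory=DoseBlock)
    scan: ScanBlock = Field(default_factory=ScanBlock)
    study: StudyBlock = Field(default_factory=StudyBlock)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Stage names, in the fixed order used to derive per-stage seeds.
STAGES = ("scan_mn", "scan_men_pre", "scan_men_post")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Per-stage seeds derived deterministically from the global seed.

    ``SeedSequence(global_seed).spawn`` children in the order of
    :data:`STAGES`, reduced mod 2**31 so they serialize as plain ints.
    """
    children = np.random.SeedSequence(int(global_seed)).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except PydanticValidationError as err:
        raise ConfigurationError(str(err)) from err


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
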