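"""Pipeline configuration: schema-validated, YAML-backed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .phantom import OpticalMedia

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline knobs in one validated record.

    media : group refractive indices used for both ray bending and optical
        path conversion.
    zernike_terms : terms per surface expansion (15 = radial orders 0..4).
    eigenlens_k / grid_p / grid_q : basis size and polar-grid resolution.
    icp_* : trimmed-ICP refinement parameters.
    iris_mode : 'corrected' refracts iris points through cornea+aqueous
        before registration, 'raw' uses apparent iris points.
    """

    media: OpticalMedia = field(default_factory=OpticalMedia)
    zernike_terms: int = 15
    eigenlens_k: int = 6
    grid_p: int = 100
    grid_q: int = 100
    n_training: int = 40
    projection_noise_sd: float = 0.005
    icp_max_iter: int = 100
    icp_tol: float = 1e-8
    icp_trim_fraction: float = 0.2
    icp_gate_mm: float = 0.5
    use_icp: bool = True
    iris_mode: str = "corrected"
    axial_scale: float = 9.2
    lateral_range_mm: float = 14.0
    n_ascans: int = 256
    clean_artifacts: bool = False
    artifact_poly_order: int = 4
    artifact_k_sd: float = 3.0
    artifact_max_iter: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.zernike_terms < 3:
            raise ValueError("zernike_terms must be >= 3")
        if self.eigenlens_k < 1:
            raise ValueError("eigenlens_k must be >= 1")
        if self.grid_p < 4 or self.grid_q < 4:
            raise ValueError("polar grid must be at least 4 x 4")
        if self.iris_mode not in ("corrected", "raw"):
            raise ValueError("iris_mode must be 'corrected' or 'raw'")
        if not 0 <= self.icp_trim_fraction < 1:
            raise ValueError("icp_trim_fraction must be in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "media" not in raw:
        raise ValueError("config missing required key 'media'")
    if "media" in raw:
        m = raw["media"]
        if not isinstance(m, dict):
            raise ValueError("config key 'media' must be a mapping of indices")
        mk = {f.name for f in fields(OpticalMedia)}
        bad = set(m) - mk
        if bad:
            raise ValueError(f"unknown media keys: {sorted(bad)}")
        raw = dict(raw, media=OpticalMedia(**m))
    return PipelineConfig(**raw)
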