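"""Top-level modelling interface: LensReconstruction -> fit() -> results.

``LensReconstruction`` bundles the per-incidence segmented acquisitions
with a :class:`~lensrecon.config.PipelineConfig`; ``fit()`` executes the
five reconstruction stages — cleaning, per-incidence 3-D model building,
ray-traced distortion correction, iris/ICP registration, and eigenlens
projection — and returns a :class:`LensReconstructionResults` carrying the
closed full shape, its eigenlens coefficients, the geometric parameters
(DIA, VOL, LSA) and per-stage diagnostics, with ``summary()`` for a
readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .eigenlens import (
    EigenlensBasis,
    LensPolarGrid,
    align_lens,
    build_basis,
    project,
    reconstruct,
    synthetic_training_population,
    to_polar_grid,
)
from .io import Calibration, SegmentedMeridian, pixels_to_mm, read_acquisition
from .metrics import LensMetrics, quantify
from .raytrace import correct_model
from .register import merged_lens_cloud, register_all
from .zernike import EyeModel3D, assemble_model

__all__ = ["LensReconstruction", "LensReconstructionResults"]


@dataclass
class LensReconstructionResults:
    """Fitted full-shape reconstruction and everything computed on the way."""

    metrics: LensMetrics
    coefficients: np.ndarray
    reconstruction: LensPolarGrid
    measured_grid: LensPolarGrid
    basis: EigenlensBasis
    transforms: dict
    registered_clouds: dict
    merged_points: np.ndarray
    merged_surface_code: np.ndarray
    merged_incidence: np.ndarray
    center_shift: np.ndarray
    models: dict[str, EyeModel3D]
    diagnostics: dict = field(default_factory=dict)

    def overlap_rms(self, gate_mm: float = 0.25) -> dict[tuple[str, str], float]:
        """Pairwise RMS disagreement between registered incidences.

        For every incidence pair, the RMS of nearest-neighbour distances
        over the mutually overlapping lens-surface regions (within
        ``gate_mm``).  The redundancy of overlapping views is the natural
        audit of registration quality.
        """
        from scipy.spatial import cKDTree

        out = {}
        keys = list(self.registered_clouds)
        for i, a in enumerate(keys):
            pa = np.vstack([self.registered_clouds[a][s] for s in ("LA", "LP")
                            if s in self.registered_clouds[a]])
            for b in keys[i + 1 :]:
                pb = np.vstack([self.registered_clouds[b][s] for s in ("LA", "LP")
                                if s in self.registered_clouds[b]])
                if not len(pa) or not len(pb):
                    continue
                d, _ = cKDTree(pb).query(pa, k=1)
                d = d[d <= gate_mm]
                if len(d) >= 10:
                    out[(a, b)] = float(np.sqrt(np.mean(d**2)))
        return out

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Full-shape crystalline lens reconstruction",
            "=" * 58,
            f"incidences registered : {len(self.models)}",
            f"merged lens points    : {len(self.merged_points)}",
            f"grid                  : P={self.measured_grid.P} Q={self.measured_grid.Q} "
            f"(observed {100 * self.measured_grid.observed.mean():.1f}%)",
            f"eigenlens K           : {self.basis.K}",
            "coefficients a_k (mm) : "
            + " ".join(f"{a:+.3f}" for a in self.coefficients),
            "-" * 58,
            f"DIA  (equatorial diameter) : {m.DIA:8.3f} mm",
            f"VOL  (lens volume)         : {m.VOL:8.2f} mm^3",
            f"LSA  (lens surface area)   : {m.LSA:8.2f} mm^2",
            "-" * 58,
        ]
        ov = self.diagnostics.get("overlap_rms_mean")
        if ov is not None:
            lines.append(f"mean inter-incidence overlap RMS : {1000 * ov:.1f} um")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        from .io import write_metrics_json, write_point_cloud_ply

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics_json(
            out / "metrics.json",
            {
                "metrics": self.metrics.as_dict(),
                "coefficients": self.coefficients,
                "observed_fraction": float(self.measured_grid.observed.mean()),
            },
        )
        write_point_cloud_ply(out / "merged_lens.ply", self.merged_points)
        write_point_cloud_ply(out / "full_shape.ply", self.reconstruction.to_cartesian())
        (out / "summary.txt").write_text(self.summary() + "\n")


class LensReconstruction:
    """Full-shape reconstruction model over multi-incidence acquisitions.

    Parameters
    ----------
    acquisitions : mapping of incidence label -> list of SegmentedMeridian
        in pixel units (the phantom simulator's output dialect).
    config : pipeline configuration; defaults reproduce the standard
        protocol (15 Zernike terms, indices 1.385/1.345/1.417, 100 x 100
        polar grid, K = 6).
    basis : optional pre-trained eigenlens basis; by default a basis is
        trained on the synthetic parametric lens family at fit time.
    """

    def __init__(
        self,
        acquisitions: dict[str, list[SegmentedMeridian]],
        config: PipelineConfig | None = None,
        basis: EigenlensBasis | None = None,
    ) -> None:
        if not acquisitions:
            raise ValueError("at least one incidence is required")
        self.acquisitions = acquisitions
        self.config = config or PipelineConfig()
        self.basis = basis

    @classmethod
    def from_directory(
        cls, path: str | Path, config: PipelineConfig | None = None, **kw
    ) -> "LensReconstruction":
        """Load every ``<incidence>.csv`` acquisition in a directory."""
        path = Path(path)
        acqs = {}
        for f in sorted(path.glob("*.csv")):
            meridians, _ = read_acquisition(f)
            acqs[f.stem] = meridians
        return cls(acqs, config, **kw)

    @classmethod
    def from_phantom(cls, phantom, protocol, orientations=None, config=None, **kw):
        """Forward-simulate a phantom under the acquisition protocol."""
        from .phantom import forward_simulate

        orientations = orientations or list(protocol.orientations)
        acqs = {o: forward_simulate(phantom, protocol, o) for o in orientations}
        cfg = config or PipelineConfig(
            axial_scale=protocol.axial_scale,
            lateral_range_mm=protocol.lateral_range,
            n_ascans=protocol.n_ascans,
        )
        return cls(acqs, cfg, **kw)

    # -- stages -------------------------------------------------------------
    def _clean(self, meridians: list[SegmentedMeridian]) -> list[SegmentedMeridian]:
        if not self.config.clean_artifacts:
            return meridians
        from .cleaning import BoundaryTrace, reject_artifacts

        cfg = self.config
        out = []
        for m in meridians:
            samples = {}
            for lbl, tr in m.samples.items():
                if lbl in ("CA", "CP") and tr.n_valid >= cfg.artifact_poly_order + 2:
                    bt = BoundaryTrace(tr.lateral, tr.axial, lbl, tr.missing)
                    cleaned, _ = reject_artifacts(
                        bt, cfg.artifact_poly_order, cfg.artifact_k_sd, cfg.artifact_max_iter
                    )
                    keep_lat = set(np.round(cleaned.lateral, 9))
                    miss = tr.missing | ~np.isin(np.round(tr.lateral, 9), list(keep_lat))
                    samples[lbl] = type(tr)(tr.lateral, tr.axial, miss)
                else:
                    samples[lbl] = tr
            out.append(SegmentedMeridian(m.meridian_index, m.meridian_angle, m.direction, samples))
        return out

    def fit(self) -> LensReconstructionResults:
        cfg = self.config
        cal = Calibration(cfg.axial_scale, cfg.lateral_range_mm, cfg.n_ascans)
        models: dict[str, EyeModel3D] = {}
        for inc, meridians in self.acquisitions.items():
            mm = [pixels_to_mm(m, cal) for m in self._clean(meridians)]
            raw = assemble_model(mm, inc, n_terms=cfg.zernike_terms)
            models[inc] = correct_model(
                raw, cfg.media, n_terms=cfg.zernike_terms, iris_mode=cfg.iris_mode
            )
        transforms, clouds = register_all(
            list(models.values()),
            use_icp=cfg.use_icp and len(models) > 1,
            icp_kwargs=dict(
                max_iter=cfg.icp_max_iter,
                tol=cfg.icp_tol,
                trim_fraction=cfg.icp_trim_fraction,
                gate_mm=cfg.icp_gate_mm,
            ),
        )
        pts, scode, prov = merged_lens_cloud(clouds)
        aligned, shift = align_lens(pts, scode, n_terms=min(10, cfg.zernike_terms))
        grid, grid_info = to_polar_grid(aligned, P=cfg.grid_p, Q=cfg.grid_q)
        basis = self.basis
        if basis is None:
            training, meta = synthetic_training_population(
                cfg.n_training, P=cfg.grid_p, Q=cfg.grid_q, rng=cfg.rng_seed
            )
            basis = build_basis(training, K=cfg.eigenlens_k, meta=meta)
        coeffs = project(grid, basis, noise_sd=cfg.projection_noise_sd)
        full = reconstruct(coeffs, basis)
        metrics = quantify(full)
        res = LensReconstructionResults(
            metrics=metrics,
            coefficients=coeffs,
            reconstruction=full,
            measured_grid=grid,
            basis=basis,
            transforms=transforms,
            registered_clouds=clouds,
            merged_points=pts,
            merged_surface_code=scode,
            merged_incidence=prov,
            center_shift=shift,
            models=models,
            diagnostics={"grid": grid_info},
        )
        ov = res.overlap_rms()
        if ov:
            res.diagnostics["overlap_rms"] = {f"{a}|{b}": v for (a, b), v in ov.items()}
            res.diagnostics["overlap_rms_mean"] = float(np.mean(list(ov.values())))
        return res
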