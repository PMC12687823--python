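"""Reading, writing and calibration of segmented OCT meridian data.

The pipeline's canonical on-disk dialect is one CSV per incidence with
columns ``meridian_index, meridian_angle_rad, direction, ascan_index,
surface_label, x_px, z_px, missing_flag`` plus a JSON sidecar carrying the
acquisition protocol metadata.  Surface labels are CA (anterior cornea),
CP (posterior cornea), LA (anterior lens), LP (posterior lens) and IRIS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SURFACE_LABELS = ("CA", "CP", "LA", "LP", "IRIS")

__all__ = [
    "SURFACE_LABELS",
    "SurfaceTrace",
    "SegmentedMeridian",
    "Calibration",
    "pixels_to_mm",
    "mm_to_pixels",
    "map_meridians_to_3d",
    "write_acquisition",
    "read_acquisition",
    "write_point_cloud_ply",
    "write_metrics_json",
    "read_cohort_xlsx",
]


@dataclass
class SurfaceTrace:
    """Samples of one surface along one B-scan (parallel arrays)."""

    lateral: np.ndarray  # px (A-scan index) or mm, matching the parent units
    axial: np.ndarray  # px or mm
    missing: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.axial = np.asarray(self.axial, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.lateral) == len(self.axial) == len(self.missing)):
            raise ValueError("trace arrays must have equal length")

    @property
    def n_valid(self) -> int:
        return int(np.sum(~self.missing))


@dataclass
class SegmentedMeridian:
    """One meridional B-scan: per-surface labeled samples plus scan metadata.

    ``direction`` (+1/-1) encodes where the scan starts: -1 flips the sign of
    the lateral coordinate so that the two half-meridians of an angle pair
    land on opposite sides of the scan axis.
    """

    meridian_index: int
    meridian_angle: float  # rad, in [0, pi)
    direction: int
    samples: dict[str, SurfaceTrace] = field(default_factory=dict)
    units: str = "px"

    def __post_init__(self) -> None:
        if not 0 <= self.meridian_angle < np.pi:
            # normalise angle==pi to 0 with flipped direction
            if abs(self.meridian_angle - np.pi) < 1e-12:
                self.meridian_angle = 0.0
                self.direction = -self.direction
            else:
                raise ValueError("meridian_angle must lie in [0, pi)")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        for label in self.samples:
            if label not in SURFACE_LABELS:
                raise ValueError(f"unknown surface label {label!r}")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre conversion constants.

    axial_scale : µm per pixel along the A-scan (instrument calibration).
    lateral_range_mm / n_ascans : the lateral pixel pitch is
        lateral_range_mm / n_ascans (mm per A-scan step); A-scan index
        (n_ascans - 1) / 2 maps to lateral coordinate 0.
    """

    axial_scale: float = 9.2
    lateral_range_mm: float = 14.0
    n_ascans: int = 256

    def __post_init__(self) -> None:
        if self.axial_scale <= 0 or self.lateral_range_mm <= 0 or self.n_ascans <= 0:
            raise ValueError("calibration constants must be positive")

    @property
    def lateral_scale(self) -> float:
        """mm per A-scan step."""
        return self.lateral_range_mm / self.n_ascans

    @property
    def lateral_center(self) -> float:
        return (self.n_ascans - 1) / 2.0


def pixels_to_mm(meridian: SegmentedMeridian, cal: Calibration) -> SegmentedMeridian:
    """Convert one meridian from pixel units to millimetres.

    Axial mm = axial_px * axial_scale / 1000; lateral mm =
    direction * (ascan_index - center) * lateral_scale.  Missing flags are
    preserved untouched.
    """
    if meridian.units != "px":
        raise ValueError("meridian is not in pixel units")
    out = {}
    for label, tr in meridian.samples.items():
        lat = meridian.direction * (tr.lateral - cal.lateral_center) * cal.lateral_scale
        ax = tr.axial * cal.axial_scale / 1000.0
        out[label] = SurfaceTrace(lat, ax, tr.missing.copy())
    return replace(meridian, samples=out, units="mm")


def mm_to_pixels(meridian: SegmentedMeridian, cal: Calibration) -> SegmentedMeridian:
    """Inverse of :func:`pixels_to_mm` (exact up to rounding)."""
    if meridian.units != "mm":
        raise ValueError("meridian is not in mm units")
    out = {}
    for label, tr in meridian.samples.items():
        idx = tr.lateral / (meridian.direction * cal.lateral_scale) + cal.lateral_center
        ax = tr.axial * 1000.0 / cal.axial_scale
        out[label] = SurfaceTrace(idx, ax, tr.missing.copy())
    return replace(meridian, samples=out, units="px")


def map_meridians_to_3d(
    meridians: list[SegmentedMeridian],
) -> dict[str, pd.DataFrame]:
    """Map per-meridian 2-D samples (mm) into the common 3-D instrument frame.

    x = lateral * cos(angle), y = lateral * sin(angle), z = axial.  Returns
    one DataFrame per surface label with columns
    ``meridian_index, ascan_index, x, y, z`` containing only non-missing
    samples.  Raises on duplicate meridian indices.
    """
    seen: set[int] = set()
    rows: dict[str, list[np.ndarray]] = {}
    for m in meridians:
        if m.units != "mm":
            raise ValueError("meridians must be converted to mm first")
        if m.meridian_index in seen:
            raise ValueError(f"duplicate meridian_index {m.meridian_index}")
        seen.add(m.meridian_index)
        c, s = np.cos(m.meridian_angle), np.sin(m.meridian_angle)
        for label, tr in m.samples.items():
            keep = ~m.samples[label].missing
            if not np.any(keep):
                continue
            lat = tr.lateral[keep]
            block = np.column_stack(
                [
                    np.full(keep.sum(), m.meridian_index, dtype=float),
                    np.flatnonzero(keep).astype(float),
                    lat * c,
                    lat * s,
                    tr.axial[keep],
                ]
            )
            rows.setdefault(label, []).append(block)
    out = {}
    for label, blocks in rows.items():
        df = pd.DataFrame(
            np.vstack(blocks), columns=["meridian_index", "ascan_index", "x", "y", "z"]
        )
        df["meridian_index"] = df["meridian_index"].astype(int)
        df["ascan_index"] = df["ascan_index"].astype(int)
        out[label] = df
    return out


# ---------------------------------------------------------------------------
# on-disk dialect
# ---------------------------------------------------------------------------

def write_acquisition(
    path: str | Path,
    meridians: list[SegmentedMeridian],
    metadata: dict | None = None,
) -> None:
    """Write one incidence's meridians as CSV + JSON sidecar.

    The CSV has one row per (meridian, surface, sample); the sidecar
    ``<path>.json`` stores protocol metadata verbatim.
    """
    path = Path(path)
    recs = []
    for m in meridians:
        for label, tr in m.samples.items():
            for lat, ax, miss in zip(tr.lateral, tr.axial, tr.missing):
                recs.append(
                    (
                        m.meridian_index,
                        m.meridian_angle,
                        m.direction,
                        lat,
                        label,
                        lat,
                        ax if np.isfinite(ax) else np.nan,
                        int(miss),
                    )
                )
    df = pd.DataFrame(
        recs,
        columns=[
            "meridian_index",
            "meridian_angle_rad",
            "direction",
            "ascan_index",
            "surface_label",
            "x_px",
            "z_px",
            "missing_flag",
        ],
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(metadata or {}, indent=1, sort_keys=True))


def read_acquisition(path: str | Path) -> tuple[list[SegmentedMeridian], dict]:
    """Read one incidence written by :func:`write_acquisition`."""
    path = Path(path)
    df = pd.read_csv(path)
    bad = set(df["surface_label"].unique()) - set(SURFACE_LABELS)
    if bad:
        raise ValueError(f"unknown surface labels in {path}: {sorted(bad)}")
    meridians = []
    for (mi, ang, direc), g in df.groupby(
        ["meridian_index", "meridian_angle_rad", "direction"], sort=True
    ):
        samples = {}
        for label, gs in g.groupby("surface_label"):
            samples[str(label)] = SurfaceTrace(
                gs["x_px"].to_numpy(),
                gs["z_px"].to_numpy(),
                gs["missing_flag"].to_numpy().astype(bool),
            )
        meridians.append(
            SegmentedMeridian(int(mi), float(ang), int(direc), samples)
        )
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return meridians, meta


def write_point_cloud_ply(path: str | Path, points: np.ndarray) -> None:
    """Write an (N, 3) point cloud as ASCII PLY (for visual inspection)."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        np.savetxt(fh, pts, fmt="%.6f")


def write_metrics_json(path: str | Path, metrics: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(metrics, indent=1, sort_keys=True, default=_default))


def read_cohort_xlsx(path: str | Path, sheet: str | int = 0) -> pd.DataFrame:
    """Minimal reader for deposited per-subject tables (Excel).

    Expects one row per subject with columns containing DIA (mm), VOL (mm^3)
    and LSA (mm^2), matched case-insensitively; extra columns (age, ...) are
    carried through so the stats module can consume them directly.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("dia", "vol", "lsa"):
        hit = [orig for low, orig in cols.items() if needed in low]
        if not hit:
            raise ValueError(f"cohort table lacks a {needed.upper()} column")
        df = df.rename(columns={hit[0]: needed.upper()})
    return df
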