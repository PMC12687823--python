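"""Multi-incidence rigid registration: iris alignment plus trimmed ICP.

Each incidence views the eye under a different gaze rotation.  The iris is
the anchor structure: it is visible in nearly every meridian, it is planar
to good approximation, and its pupil margin is circular.  Registration
first undoes the gaze tilt by rotating the fitted iris-plane normal onto
+Z and translating the fitted iris-circle centre to the origin, then
refines the residual rigid motion with a trimmed point-to-point iterative
closest point (ICP) match of the lens surfaces against the already
registered views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .zernike import EyeModel3D

__all__ = [
    "RigidTransform",
    "IrisFit",
    "fit_iris",
    "initial_align",
    "icp_refine",
    "register_all",
    "fit_circle_2d",
]


@dataclass(frozen=True)
class RigidTransform:
    """p -> rotation @ p + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-10 or abs(np.linalg.det(R) - 1) > 1e-10:
            raise ValueError("rotation must be orthonormal with det +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1) / 2
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


@dataclass(frozen=True)
class IrisFit:
    plane_normal: np.ndarray  # unit, oriented toward the instrument (-Z side)
    plane_offset: float  # plane: normal . p = offset
    circle_center: np.ndarray
    circle_radius: float
    inlier_count: int


def fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Taubin algebraic circle fit followed by Gauss-Newton polish."""
    p = np.asarray(xy, dtype=float)
    x, y = p[:, 0] - p[:, 0].mean(), p[:, 1] - p[:, 1].mean()
    z = x**2 + y**2
    zm = z.mean()
    # Taubin: minimise ||A u|| with constraint on the gradient norm
    A = np.column_stack([z - zm, x, y])
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    a, b, c = vt[-1]
    if abs(a) < 1e-14:
        raise ValueError("circle fit degenerate (collinear points)")
    cx, cy = -b / (2 * a), -c / (2 * a)
    r = np.sqrt(cx**2 + cy**2 + zm)
    center = np.array([cx, cy])
    for _ in range(20):  # geometric Gauss-Newton
        dx = np.column_stack([x, y]) - center
        d = np.linalg.norm(dx, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        res = d - r
        J = np.column_stack([-dx[:, 0] / d, -dx[:, 1] / d, -np.ones(len(d))])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:
            break
        center = center + step[:2]
        r = r + step[2]
        if np.linalg.norm(step) < 1e-12:
            break
    return center + [p[:, 0].mean(), p[:, 1].mean()], float(r)


def _inner_margin(uv: np.ndarray, n_bins: int = 72, thin_band_mm: float = 0.05) -> np.ndarray:
    """Points defining the pupil-margin circle of a segmented iris.

    Segmented iris points usually cover a band of the iris disc, not just
    the pupil edge; the circle of interest is then the *inner* margin —
    the innermost point per angular bin.  When the input is already a thin
    circle (radial spread below ``thin_band_mm`` about the margin fit),
    all points are returned instead, so measurement noise is averaged
    rather than biased inward by the minimum selection.
    """
    ang = np.arctan2(uv[:, 1], uv[:, 0])
    r = np.hypot(uv[:, 0], uv[:, 1])
    bins = np.floor((ang + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    out = []
    for b in range(n_bins):
        m = bins == b
        if np.any(m):
            idx = np.flatnonzero(m)[np.argmin(r[m])]
            out.append(uv[idx])
    if len(out) < 3:
        return uv
    margin = np.asarray(out)
    try:
        c, rad = fit_circle_2d(margin)
    except ValueError:
        return margin
    resid_all = np.hypot(uv[:, 0] - c[0], uv[:, 1] - c[1]) - rad
    if np.quantile(np.abs(resid_all), 0.8) < thin_band_mm:
        return uv  # thin circle: use every sample
    return margin


def fit_iris(points: np.ndarray) -> IrisFit:
    """Total-least-squares plane + in-plane circle fit of iris points.

    The plane normal is the smallest principal direction of the centred
    covariance, oriented toward the instrument (-Z hemisphere); points are
    projected onto the plane and the pupil-margin circle is fitted there.
    """
    p = np.asarray(points, dtype=float)
    p = p[np.all(np.isfinite(p), axis=1)]
    if len(p) < 3:
        raise ValueError("iris fit needs at least 3 points")
    centroid = p.mean(axis=0)
    q = p - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise ValueError("iris points are collinear: cannot fit a plane")
    normal = vt[2]
    if normal[2] > 0:
        normal = -normal
    # in-plane basis
    e1 = vt[0]
    e2 = np.cross(normal, e1)
    uv = np.column_stack([q @ e1, q @ e2])
    c2, radius = fit_circle_2d(_inner_margin(uv))
    center = centroid + c2[0] * e1 + c2[1] * e2
    return IrisFit(
        plane_normal=normal,
        plane_offset=float(normal @ center),
        circle_center=center,
        circle_radius=radius,
        inlier_count=len(p),
    )


def initial_align(iris: IrisFit) -> RigidTransform:
    """Tilt + centring transform from an iris fit.

    The minimal rotation (axis = normal x Z) maps the iris-plane normal to
    +Z; the translation then brings the rotated circle centre to the
    coordinate origin.  Applying the transform to a model's surfaces puts
    every incidence in the same iris-centred frame.
    """
    from .geometry import rotation_aligning

    R = rotation_aligning(-iris.plane_normal, np.array([0.0, 0.0, 1.0]))
    t = -R @ iris.circle_center
    return RigidTransform(R, t)


def icp_refine(
    source: np.ndarray,
    reference: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    trim_fraction: float = 0.2,
    gate_mm: float = 0.5,
) -> tuple[RigidTransform, dict]:
    """Trimmed point-to-point ICP of ``source`` onto a fixed ``reference``.

    Each iteration: nearest-neighbour correspondences for all source
    points; keep the best (1 - trim_fraction) fraction (fixed count, so
    the trimmed MSE is provably non-increasing); closed-form rigid update
    by SVD of the cross-covariance (Kabsch).  Stops when the trimmed MSE
    improves by less than ``tol`` (mm^2) or after ``max_iter``.

    Raises "no overlap" when no correspondence lies within ``gate_mm`` at
    the start.  Returns the transform and a diagnostics dict with the
    per-iteration trimmed MSE trace and final RMS.
    """
    src = np.asarray(source, dtype=float)
    ref = np.asarray(reference, dtype=float)
    src = src[np.all(np.isfinite(src), axis=1)]
    ref = ref[np.all(np.isfinite(ref), axis=1)]
    if len(src) < 3 or len(ref) < 3:
        raise ValueError("ICP needs at least 3 points in each cloud")
    tree = cKDTree(ref)
    n_keep = max(3, int(np.ceil((1.0 - trim_fraction) * len(src))))
    d0, _ = tree.query(src, k=1)
    if np.min(d0) > gate_mm:
        raise ValueError("no overlap: no correspondence within the gate distance")
    T = RigidTransform.identity()
    cur = src.copy()
    mse_trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        dist, idx = tree.query(cur, k=1)
        order = np.argsort(dist)[:n_keep]
        mse = float(np.mean(dist[order] ** 2))
        mse_trace.append(mse)
        if prev - mse < tol:
            break
        prev = mse
        a = cur[order]
        b = ref[idx[order]]
        am, bm = a.mean(axis=0), b.mean(axis=0)
        H = (a - am).T @ (b - bm)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        t = bm - R @ am
        step = RigidTransform(R, t)
        cur = step.apply(cur)
        T = step.compose(T)
    info = {"mse_trace": np.array(mse_trace), "rms": float(np.sqrt(mse_trace[-1]))}
    return T, info


def register_all(
    models: list[EyeModel3D],
    reference_incidence: str = "on_axis",
    icp_surfaces: tuple[str, ...] = ("LA", "LP"),
    use_icp: bool = True,
    icp_kwargs: dict | None = None,
) -> tuple[dict[str, RigidTransform], dict[str, dict[str, np.ndarray]]]:
    """Register all incidences into the common iris-centred frame.

    Every model is first iris-aligned; the reference incidence defines the
    frame.  The remaining models, in order of increasing initial-alignment
    rotation angle (maximising overlap with the growing reference), are
    ICP-refined against the union of already registered lens-surface
    points.  Returns per-incidence total transforms and the registered
    point clouds per incidence and surface label (lens surfaces + iris),
    from which the merged lens cloud with provenance is assembled.
    """
    icp_kwargs = icp_kwargs or {}
    by_label = {m.incidence: m for m in models}
    if reference_incidence not in by_label:
        reference_incidence = models[0].incidence
    aligned: dict[str, RigidTransform] = {}
    clouds: dict[str, dict[str, np.ndarray]] = {}
    for m in models:
        iris = fit_iris(m.iris_points)
        T = initial_align(iris)
        aligned[m.incidence] = T
        clouds[m.incidence] = {
            lbl: T.apply(m.surface_points(lbl))
            for lbl in ("CA", "CP", "LA", "LP")
            if (m.distortion_state == "corrected" and lbl in m.corrected_points)
            or f"z_{lbl}" in m.rays
        }
        clouds[m.incidence]["IRIS"] = T.apply(m.iris_points)
    order = sorted(
        (inc for inc in clouds if inc != reference_incidence),
        key=lambda inc: aligned[inc].angle_deg,
    )
    merged = [np.vstack([clouds[reference_incidence][s] for s in icp_surfaces])]
    transforms = {reference_incidence: aligned[reference_incidence]}
    for inc in order:
        src = np.vstack([clouds[inc][s] for s in icp_surfaces])
        if use_icp:
            T_icp, _ = icp_refine(src, np.vstack(merged), **icp_kwargs)
        else:
            T_icp = RigidTransform.identity()
        transforms[inc] = T_icp.compose(aligned[inc])
        clouds[inc] = {lbl: T_icp.apply(pts) for lbl, pts in clouds[inc].items()}
        merged.append(np.vstack([clouds[inc][s] for s in icp_surfaces]))
    return transforms, clouds


def merged_lens_cloud(
    clouds: dict[str, dict[str, np.ndarray]],
    surfaces: tuple[str, ...] = ("LA", "LP"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack registered lens points across incidences.

    Returns (points, surface_code, incidence_index); surface_code is 0 for
    the anterior, 1 for the posterior lens surface.
    """
    pts, scode, iprov = [], [], []
    for i, (inc, c) in enumerate(clouds.items()):
        for s_i, s in enumerate(surfaces):
            if s in c and len(c[s]):
                pts.append(c[s])
                scode.append(np.full(len(c[s]), s_i))
                iprov.append(np.full(len(c[s]), i))
    return np.vstack(pts), np.concatenate(scode), np.concatenate(iprov)
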