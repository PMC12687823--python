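"""Eigenlens shape basis: polar-grid resampling, PCA basis, projection.

A full lens shape is represented as the vector of radial elevations
I(theta_p, phi_q) — distances from the lens centre to the surface — on a
fixed polar grid of P equidistant elevation angles (0 at the anterior
pole, pi at the posterior pole) by Q equidistant azimuths, M = P x Q
nodes (10000 at the defaults).  A training population of such vectors
yields, by principal component analysis, the mean lens Ibar and the
eigenlenses e_1..e_K (K = 6): the dominant modes of shape variation.  A
measured lens is projected as a = M_basis^T (I - Ibar) and reconstructed
as Ihat = Ibar + sum_k a_k e_k, which simultaneously compresses, smooths,
and — because the reconstruction is defined on the full grid — closes the
shape over nodes the OCT views never saw.

The training population here is a synthetic parametric family (two
conicoid caps with varied diameter, thickness, thickness split and apex
radii); the basis file format accepts any externally trained basis with
the same grid specification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .phantom import _cap_conicoid

__all__ = [
    "LensPolarGrid",
    "EigenlensBasis",
    "align_lens",
    "to_polar_grid",
    "build_basis",
    "project",
    "reconstruct",
    "cap_pair_profile",
    "synthetic_training_population",
]


@dataclass
class LensPolarGrid:
    """Radial elevations I on the fixed (elevation, azimuth) grid.

    ``I`` is flattened elevation-major: node (p, q) at index p * Q + q.
    ``observed`` marks nodes supported by data (False = to be filled by
    the basis reconstruction).
    """

    P: int = 100
    Q: int = 100
    I: np.ndarray = field(default=None)  # (P*Q,) mm
    observed: np.ndarray = field(default=None)  # (P*Q,) bool

    def __post_init__(self) -> None:
        if self.I is None:
            self.I = np.full(self.P * self.Q, np.nan)
        self.I = np.asarray(self.I, dtype=float).ravel()
        if self.observed is None:
            self.observed = np.isfinite(self.I)
        self.observed = np.asarray(self.observed, dtype=bool).ravel()
        if len(self.I) != self.P * self.Q or len(self.observed) != self.P * self.Q:
            raise ValueError("grid vector length must equal P * Q")

    @property
    def M(self) -> int:
        return self.P * self.Q

    @property
    def theta(self) -> np.ndarray:
        """Elevation angles, 0 (anterior pole) .. pi (posterior pole)."""
        return np.linspace(0.0, np.pi, self.P)

    @property
    def phi(self) -> np.ndarray:
        return np.arange(self.Q) * 2 * np.pi / self.Q

    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (theta, phi) per node, elevation-major."""
        th, ph = np.meshgrid(self.theta, self.phi, indexing="ij")
        return th.ravel(), ph.ravel()

    def to_cartesian(self) -> np.ndarray:
        """(M, 3) surface points; anterior pole toward -Z."""
        th, ph = self.nodes()
        r = self.I
        return np.column_stack(
            [r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph), -r * np.cos(th)]
        )

    @property
    def complete(self) -> bool:
        return bool(np.all(self.observed) and np.all(np.isfinite(self.I)))


@dataclass
class EigenlensBasis:
    """Mean lens + orthonormal eigenlens columns (decreasing eigenvalue)."""

    mean_lens: np.ndarray  # (M,)
    components: np.ndarray  # (M, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,)
    P: int = 100
    Q: int = 100
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_lens = np.asarray(self.mean_lens, dtype=float).ravel()
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        G = self.components.T @ self.components
        if np.abs(G - np.eye(self.K)).max() > 1e-10:
            raise ValueError("eigenlens columns must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in decreasing order")

    @property
    def K(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "P": self.P,
            "Q": self.Q,
            "mean_lens": self.mean_lens.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "training_meta": self.training_meta,
        }
        blob = json.dumps(payload, sort_keys=True)
        payload["checksum"] = hashlib.sha256(blob.encode()).hexdigest()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EigenlensBasis":
        payload = json.loads(Path(path).read_text())
        stored = payload.pop("checksum", None)
        blob = json.dumps(payload, sort_keys=True)
        if stored is not None and hashlib.sha256(blob.encode()).hexdigest() != stored:
            raise ValueError("basis file checksum mismatch")
        return cls(
            mean_lens=np.array(payload["mean_lens"]),
            components=np.array(payload["components"]),
            eigenvalues=np.array(payload["eigenvalues"]),
            P=payload["P"],
            Q=payload["Q"],
            training_meta=payload.get("training_meta", {}),
        )


# ---------------------------------------------------------------------------
# alignment and resampling
# ---------------------------------------------------------------------------

def align_lens(
    points: np.ndarray,
    surface_code: np.ndarray,
    n_terms: int = 10,
    central_radius: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Centre a merged lens cloud for polar-grid resampling.

    Lateral origin: under the anterior surface's maximum-elevation (most
    anterior) point, found on a smooth fit of the central anterior lens;
    axial origin: midpoint between the anterior and posterior apex depths.
    ``surface_code`` is 0 for anterior-lens points, 1 for posterior-lens.
    Returns the shifted cloud and the applied shift (so the inverse is
    available).
    """
    from .zernike import fit_zernike

    pts = np.asarray(points, dtype=float)
    sc = np.asarray(surface_code)
    la = pts[sc == 0]
    lp = pts[sc == 1]
    if len(la) < n_terms or len(lp) < n_terms:
        raise ValueError("need anterior and posterior lens points near the axis")

    def _apex(cloud: np.ndarray, mode: str) -> np.ndarray:
        ctr = cloud[np.hypot(cloud[:, 0] - np.median(cloud[:, 0]),
                             cloud[:, 1] - np.median(cloud[:, 1])) < central_radius]
        if len(ctr) < n_terms:
            ctr = cloud
        fit = fit_zernike(ctr[:, :3], n_terms)
        g = np.linspace(-central_radius, central_radius, 201)
        gx, gy = np.meshgrid(g + fit.center_offset[0], g + fit.center_offset[1])
        z = fit.evaluate(gx.ravel(), gy.ravel(), check_domain=True)
        i = np.nanargmin(z) if mode == "min" else np.nanargmax(z)
        return np.array([gx.ravel()[i], gy.ravel()[i], z[i]])

    apex_a = _apex(la, "min")  # most anterior point (smallest z)
    apex_p = _apex(lp, "max")
    shift = np.array([apex_a[0], apex_a[1], 0.5 * (apex_a[2] + apex_p[2])])
    return pts - shift, shift


def to_polar_grid(
    points: np.ndarray,
    P: int = 100,
    Q: int = 100,
    support_angle_factor: float = 3.0,
    gap_edge_factor: float = 3.0,
) -> tuple[LensPolarGrid, dict]:
    """Resample an aligned, star-convex lens cloud onto the polar grid.

    Each point contributes its radial distance I at its (theta, phi); grid
    node values are barycentric-linear interpolations over a Delaunay
    triangulation of the sample directions in the parameter plane (azimuth
    handled periodically).  A node is flagged *unobserved* — left for the
    basis reconstruction to fill — when (a) it falls outside the sampled
    region, (b) its nearest sample direction is farther than
    ``support_angle_factor`` grid pitches, or (c) its enclosing triangle
    spans a data gap (any edge longer than ``gap_edge_factor`` pitches in
    the metric d^2 = dtheta^2 + (sin(theta) dphi)^2): interpolating across
    such a gap would cut a chord under the true surface rather than
    measure it.

    Returns the grid and an info dict including a star-convexity audit
    (pairs of samples in near-identical directions with grossly different
    radii).
    """
    from scipy.interpolate import LinearNDInterpolator
    from scipy.spatial import Delaunay

    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    r = np.linalg.norm(pts, axis=1)
    ok = r > 1e-9
    pts, r = pts[ok], r[ok]
    u = pts / r[:, None]
    theta = np.arccos(np.clip(-pts[:, 2] / r, -1, 1))
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)

    # star-convexity audit: same direction, conflicting radius
    tree_u = cKDTree(u)
    pitch = np.pi / (P - 1)
    pairs = tree_u.query_pairs(2 * np.sin(pitch / 4), output_type="ndarray")
    violations = 0
    if len(pairs):
        dr = np.abs(r[pairs[:, 0]] - r[pairs[:, 1]])
        violations = int(np.sum(dr > 0.15 * np.maximum(r[pairs[:, 0]], 1.0)))

    grid = LensPolarGrid(P=P, Q=Q, I=np.full(P * Q, np.nan), observed=np.zeros(P * Q, bool))
    gth, gph = grid.nodes()
    # periodic padding in azimuth for the planar triangulation
    margin = 6 * np.pi / Q
    pad_hi = phi > 2 * np.pi - margin
    pad_lo = phi < margin
    th_all = np.concatenate([theta, theta[pad_hi], theta[pad_lo]])
    ph_all = np.concatenate([phi, phi[pad_hi] - 2 * np.pi, phi[pad_lo] + 2 * np.pi])
    r_all = np.concatenate([r, r[pad_hi], r[pad_lo]])
    # pole reflection: a sample at (theta, phi) also constrains the chart at
    # (-theta, phi +/- pi), making grid rows at the poles interior points
    pole_m = 4 * pitch
    sel_n = th_all < pole_m
    sel_s = th_all > np.pi - pole_m
    refl_th = [th_all, -th_all[sel_n], 2 * np.pi - th_all[sel_s]]
    refl_ph = [
        ph_all,
        ph_all[sel_n] + np.where(ph_all[sel_n] < np.pi, np.pi, -np.pi),
        ph_all[sel_s] + np.where(ph_all[sel_s] < np.pi, np.pi, -np.pi),
    ]
    refl_r = [r_all, r_all[sel_n], r_all[sel_s]]
    th_all = np.concatenate(refl_th)
    ph_all = np.concatenate(refl_ph)
    r_all = np.concatenate(refl_r)
    tri = Delaunay(np.column_stack([th_all, ph_all]))
    interp = LinearNDInterpolator(tri, r_all)
    I = interp(gth, gph)

    # gap detection: longest edge of each simplex in the cap metric
    sp = tri.points[tri.simplices]  # (ntri, 3, 2)
    edges = sp - np.roll(sp, 1, axis=1)
    mid_th = 0.5 * (sp[:, :, 0] + np.roll(sp[:, :, 0], 1, axis=1))
    elen2 = edges[:, :, 0] ** 2 + (np.sin(mid_th) * edges[:, :, 1]) ** 2
    max_edge = np.sqrt(elen2.max(axis=1))
    node_simplex = tri.find_simplex(np.column_stack([gth, gph]))
    spans_gap = np.where(
        node_simplex >= 0, max_edge[node_simplex] > gap_edge_factor * pitch, True
    )

    # support by angular distance on the unit sphere
    gu = np.column_stack(
        [np.sin(gth) * np.cos(gph), np.sin(gth) * np.sin(gph), -np.cos(gth)]
    )
    d_near, _ = tree_u.query(gu, k=1)
    max_chord = 2 * np.sin(support_angle_factor * pitch / 2)
    observed = np.isfinite(I) & (d_near <= max_chord) & ~spans_gap
    grid.I = np.where(observed, I, np.nan)
    grid.observed = observed

    # near the poles the (theta, phi) chart degenerates and the planar
    # triangulation (and its gap test) is unreliable; interpolate those
    # nodes directly on the sphere by inverse-distance weighting of the
    # samples in a small angular cone (the pole row itself is one
    # physical point, so its azimuths share one value by construction)
    near_pole = ((gth < 3 * pitch) | (gth > np.pi - 3 * pitch)) & ~observed
    if np.any(near_pole):
        k = min(12, len(r))
        d, idx = tree_u.query(gu[near_pole], k=k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        # adaptive cone: shrink toward the local sampling density so dense
        # data is not over-smoothed
        radius = np.minimum(max_chord, 2 * d_near[near_pole] + 1e-12)[:, None]
        w = np.where(d <= radius, 1.0 / np.maximum(d, 1e-9), 0.0)
        # widen the cone to the full support radius where too sparse
        sparse = (w > 0).sum(axis=1) < 3
        w[sparse] = np.where(d[sparse] <= max_chord, 1.0 / np.maximum(d[sparse], 1e-9), 0.0)
        wsum = w.sum(axis=1)
        vals = np.where(wsum > 0, (w * r[idx]).sum(axis=1) / np.maximum(wsum, 1e-300), np.nan)
        supported = (w > 0).sum(axis=1) >= 3
        tgt = np.flatnonzero(near_pole)[supported]
        grid.I[tgt] = vals[supported]
        grid.observed[tgt] = True
        grid.I[near_pole & ~grid.observed] = np.nan
    info = {
        "n_points": len(pts),
        "star_convexity_violations": violations,
        "observed_fraction": float(observed.mean()),
    }
    return grid, info


# ---------------------------------------------------------------------------
# basis construction and projection
# ---------------------------------------------------------------------------

def build_basis(training: list[LensPolarGrid], K: int = 6, meta: dict | None = None) -> EigenlensBasis:
    """Principal-component basis from complete training grids.

    Ibar is the per-node mean; the centred training matrix is decomposed
    by SVD and the first K right singular vectors (ordered by decreasing
    singular value) become the eigenlens columns.
    """
    if len(training) <= K:
        raise ValueError(f"need more than {K} training lenses for {K} components")
    P, Q = training[0].P, training[0].Q
    X = np.stack([g.I for g in training])
    if np.any(~np.isfinite(X)):
        raise ValueError("training grids must be complete (no missing nodes)")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:K].T
    eigvals = (s[:K] ** 2) / (len(training) - 1)
    return EigenlensBasis(
        mean_lens=mean,
        components=comps,
        eigenvalues=eigvals,
        P=P,
        Q=Q,
        training_meta=meta or {"n_training": len(training)},
    )


def project(
    grid: LensPolarGrid, basis: EigenlensBasis, noise_sd: float = 0.005
) -> np.ndarray:
    """Eigenlens coefficients a of a (possibly incomplete) lens grid.

    Complete grid: a = M_basis^T (I - Ibar) (orthonormal columns, so this
    is the orthogonal projection).  With missing nodes the normal
    equations are restricted to the observed rows; because the trailing
    eigenlenses are concentrated exactly where data are typically missing
    (the equator), the restricted Gram matrix can be near-singular, so the
    solve is stabilised by the training eigenvalue prior (the
    probabilistic-PCA posterior mean):

        a = (A^T A + noise_sd^2 Lambda^{-1})^{-1} A^T r

    with Lambda the eigenvalue diagonal and ``noise_sd`` (mm) the node
    noise scale of the measured elevations.
    """
    if grid.M != len(basis.mean_lens):
        raise ValueError("grid / basis size mismatch")
    obs = grid.observed & np.isfinite(grid.I)
    if obs.sum() < basis.K:
        raise ValueError("not enough observed nodes to project")
    if np.all(obs):
        return basis.components.T @ (grid.I - basis.mean_lens)
    A = basis.components[obs]
    r = grid.I[obs] - basis.mean_lens[obs]
    lam = np.maximum(basis.eigenvalues, 1e-12)
    G = A.T @ A + noise_sd**2 * np.diag(1.0 / lam)
    return np.linalg.solve(G, A.T @ r)


def reconstruct(a: np.ndarray, basis: EigenlensBasis) -> LensPolarGrid:
    """Closed full shape Ihat = Ibar + sum_k a_k e_k on the complete grid."""
    a = np.asarray(a, dtype=float).ravel()
    if len(a) != basis.K:
        raise ValueError(f"coefficient length {len(a)} != basis K {basis.K}")
    I = basis.mean_lens + basis.components @ a
    return LensPolarGrid(P=basis.P, Q=basis.Q, I=I, observed=np.ones(basis.P * basis.Q, bool))


# ---------------------------------------------------------------------------
# synthetic training population
# ---------------------------------------------------------------------------

def cap_pair_profile(
    theta: np.ndarray,
    diameter: float,
    thickness: float,
    anterior_fraction: float,
    radius_ant: float,
    radius_post: float,
) -> np.ndarray:
    """Radial profile I(theta) of a two-conicoid-cap lens about its centre.

    The centre is the midpoint between the two apexes (the same origin the
    alignment step uses); theta = 0 at the anterior pole.  Rotationally
    symmetric, so no azimuth argument.
    """
    req = diameter / 2.0
    h_a = anterior_fraction * thickness
    h_p = thickness - h_a
    ant = _cap_conicoid(radius_ant, h_a, req, -thickness / 2.0, sign=+1)
    post = _cap_conicoid(radius_post, h_p, req, +thickness / 2.0, sign=-1)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    u = np.column_stack([np.sin(theta), np.zeros_like(theta), -np.cos(theta)])
    o = np.zeros_like(u)
    out = np.full(len(u), np.nan)
    for surf in (ant, post):
        t, pts = surf.intersect(o, u)
        rr = np.abs(pts[:, 0])
        ok = np.isfinite(t) & (rr <= req * (1 + 1e-9))
        out = np.where(ok & ~np.isfinite(out), t, out)
    return out


def synthetic_training_population(
    n: int = 40,
    P: int = 100,
    Q: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> tuple[list[LensPolarGrid], dict]:
    """Parametric training family of complete lens grids.

    Draws diameter U(8, 10.5) mm, thickness U(3.2, 4.8) mm and anterior
    thickness fraction U(0.40, 0.44) — a plausible adult range — and apex
    radii as U(0.6, 0.98) of the geometric maximum r_eq^2 / cap_height
    (beyond which a conicoid cap would bulge wider than the equator), then
    evaluates each lens analytically on the polar grid.
    """
    rng = np.random.default_rng(rng)
    theta = np.linspace(0.0, np.pi, P)
    grids = []
    params = []
    for _ in range(n):
        dia = rng.uniform(8.0, 10.5)
        th = rng.uniform(3.2, 4.8)
        f = rng.uniform(0.40, 0.44)
        req = dia / 2.0
        ra = rng.uniform(0.6, 0.98) * req**2 / (f * th)
        rp = rng.uniform(0.6, 0.98) * req**2 / ((1 - f) * th)
        prof = cap_pair_profile(theta, dia, th, f, ra, rp)
        I = np.repeat(prof, Q)
        grids.append(LensPolarGrid(P=P, Q=Q, I=I, observed=np.ones(P * Q, bool)))
        params.append((dia, th, f, ra, rp))
    meta = {
        "family": "two-conicoid-cap",
        "n_training": n,
        "param_names": ["diameter", "thickness", "anterior_fraction", "radius_ant", "radius_post"],
    }
    return grids, meta
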