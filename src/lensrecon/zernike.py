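"""Zernike-polynomial surface fitting and the per-incidence 3-D eye model.

Each segmented surface is approximated by a least-squares expansion over
the first ``n_terms`` Zernike polynomials (default 15, i.e. radial orders
0..4) in OSA/ANSI single-index ordering with the usual unit-variance
normalisation sqrt(2(n+1)/(1+delta_m0)).  Internally every term is expanded
into a bivariate Cartesian polynomial in the normalised coordinates
(u, v) = ((x - x0)/R, (y - y0)/R), which makes evaluation and the analytic
gradient (needed for ray-surface normals) exact and free of polar-axis
singularities.

Evaluation is refused outside the domain mask — the convex hull of the
supporting data in the lateral plane — so a partially observed surface is
never silently extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, factorial

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "osa_index_to_nm",
    "zernike_cartesian_coeffs",
    "ZernikeSurface",
    "fit_zernike",
    "EyeModel3D",
    "assemble_model",
]


def osa_index_to_nm(j: int) -> tuple[int, int]:
    """OSA/ANSI single index j -> (radial order n, azimuthal frequency m)."""
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def _polymul2d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros((a.shape[0] + b.shape[0] - 1, a.shape[1] + b.shape[1] - 1))
    for (i, j), v in np.ndenumerate(a):
        if v != 0:
            out[i : i + b.shape[0], j : j + b.shape[1]] += v * b
    return out


@lru_cache(maxsize=64)
def zernike_cartesian_coeffs(n_terms: int) -> tuple[np.ndarray, ...]:
    """Monomial coefficient matrices C[i, j] (u^i v^j) for OSA terms 0..n_terms-1.

    Built exactly from the radial-polynomial factorial formula; the angular
    factor rho^|m| cos/sin(|m| phi) is expanded via Re/Im((u + i v)^|m|).
    """
    mats = []
    r2 = np.zeros((3, 3))
    r2[2, 0] = r2[0, 2] = 1.0  # u^2 + v^2
    for j in range(n_terms):
        n, m = osa_index_to_nm(j)
        am = abs(m)
        # radial polynomial coefficients of rho^(n-2s)
        radial: dict[int, float] = {}
        for s in range((n - am) // 2 + 1):
            c = (-1) ** s * factorial(n - s) / (
                factorial(s) * factorial((n + am) // 2 - s) * factorial((n - am) // 2 - s)
            )
            radial[n - 2 * s] = radial.get(n - 2 * s, 0.0) + c
        # angular factor: rho^am * cos(am phi) = Re((u+iv)^am), sin -> Im
        ang = np.zeros((am + 1, am + 1))
        for k in range(am + 1):
            coef = comb(am, k)
            if m >= 0:  # cosine: Re(i^k) pattern
                if k % 4 == 0:
                    ang[am - k, k] += coef
                elif k % 4 == 2:
                    ang[am - k, k] -= coef
            else:  # sine: Im
                if k % 4 == 1:
                    ang[am - k, k] += coef
                elif k % 4 == 3:
                    ang[am - k, k] -= coef
        if am == 0:
            ang = np.ones((1, 1))
        mat = np.zeros((n + 1, n + 1))
        for p, c in radial.items():  # rho^p with p >= am, p - am even
            term = ang.copy() * c
            for _ in range((p - am) // 2):
                term = _polymul2d(term, r2)
            mat[: term.shape[0], : term.shape[1]] += term
        norm = np.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))
        mats.append(mat * norm)
    return tuple(mats)


def _eval_terms(mats, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    from numpy.polynomial.polynomial import polyval2d

    return np.stack([polyval2d(u, v, m) for m in mats], axis=-1)


def _grad_mats(mats):
    du, dv = [], []
    for m in mats:
        du.append(np.polynomial.polynomial.polyder(m, axis=0) if m.shape[0] > 1 else np.zeros((1, 1)))
        dv.append(np.polynomial.polynomial.polyder(m, axis=1) if m.shape[1] > 1 else np.zeros((1, 1)))
    return du, dv


@dataclass
class ZernikeSurface:
    """Fitted smooth surface z(x, y) = sum_j c_j Z_j((x-x0)/R, (y-y0)/R).

    The graph lives in a *fit frame*: ``frame_rotation`` maps world
    coordinates into that frame (local = R @ world).  For on-axis data the
    frame is the identity; for steeply tilted off-axis acquisitions the
    frame is chosen so the surface remains a mild-slope graph, which keeps
    a 15-term expansion accurate.  ``evaluate``/``gradient``/``normal``
    work in local lateral coordinates; ``world_normal`` and
    :func:`intersect_ray_surface` handle the frame change.
    """

    coefficients: np.ndarray  # mm
    normalization_radius: float  # mm
    center_offset: tuple[float, float] = (0.0, 0.0)
    surface_label: str = ""
    rms_residual: float = np.nan
    condition_number: float = np.nan
    domain_hull: Delaunay | None = field(default=None, repr=False)
    frame_rotation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.normalization_radius <= 0:
            raise ValueError("normalization_radius must be positive")

    @property
    def n_terms(self) -> int:
        return len(self.coefficients)

    def _uv(self, x, y):
        return (
            (np.asarray(x, float) - self.center_offset[0]) / self.normalization_radius,
            (np.asarray(y, float) - self.center_offset[1]) / self.normalization_radius,
        )

    def in_domain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """True where (x, y) lies inside the lateral support of the fit data."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if self.domain_hull is None:
            u, v = self._uv(x, y)
            return u**2 + v**2 <= 1.0
        return self.domain_hull.find_simplex(np.column_stack([x, y])) >= 0

    def evaluate(
        self, x: np.ndarray, y: np.ndarray, check_domain: bool = True
    ) -> np.ndarray:
        """Surface height z at lateral query points; NaN outside the domain."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        u, v = self._uv(x, y)
        mats = zernike_cartesian_coeffs(self.n_terms)
        z = _eval_terms(mats, u, v) @ self.coefficients
        if check_domain:
            z = np.where(self.in_domain(np.atleast_1d(x), np.atleast_1d(y)).reshape(np.shape(z)), z, np.nan)
        return z

    def gradient(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(dz/dx, dz/dy) from the exact polynomial derivative."""
        u, v = self._uv(x, y)
        mats = zernike_cartesian_coeffs(self.n_terms)
        du, dv = _grad_mats(mats)
        gu = _eval_terms(du, u, v) @ self.coefficients
        gv = _eval_terms(dv, u, v) @ self.coefficients
        R = self.normalization_radius
        return gu / R, gv / R

    def normal(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unit normals (local frame) pointing toward -Z (incoming side)."""
        gx, gy = self.gradient(x, y)
        n = np.column_stack([np.atleast_1d(gx), np.atleast_1d(gy), -np.ones(np.atleast_1d(gx).shape)])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def R_frame(self) -> np.ndarray:
        return np.eye(3) if self.frame_rotation is None else self.frame_rotation

    def world_normal(self, points_world: np.ndarray) -> np.ndarray:
        """Unit world-frame normals at (near-)surface world points."""
        p = np.atleast_2d(np.asarray(points_world, dtype=float))
        loc = p @ self.R_frame.T
        n_loc = self.normal(loc[:, 0], loc[:, 1])
        return n_loc @ self.R_frame

    def in_domain_world(self, points_world: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_world, dtype=float))
        loc = p @ self.R_frame.T
        return self.in_domain(loc[:, 0], loc[:, 1])


def fit_zernike(
    points: np.ndarray,
    n_terms: int = 15,
    normalization_radius: float | None = None,
    surface_label: str = "",
    center_offset: tuple[float, float] | None = None,
    frame_rotation: np.ndarray | None = None,
) -> ZernikeSurface:
    """Least-squares Zernike expansion of a 3-D surface point set.

    ``points`` is (N, 3) with N >= n_terms.  If not given, the
    normalisation radius is the maximal lateral radius of the data about
    the lateral centroid times 1.001 (keeps the basis conditioned on
    partial, off-axis domains).  Solved by SVD-based ``lstsq`` (rank
    revealing); an ill-conditioned design issues a warning through the
    returned ``condition_number``.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < n_terms:
        raise ValueError(
            f"need at least {n_terms} points to fit {n_terms} Zernike terms "
            f"(got {len(pts)}); reduce the term count"
        )
    if frame_rotation is not None:
        pts = pts @ np.asarray(frame_rotation, dtype=float).T
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if center_offset is None:
        center_offset = (float(np.mean(x)), float(np.mean(y)))
    if normalization_radius is None:
        normalization_radius = float(
            np.max(np.hypot(x - center_offset[0], y - center_offset[1])) * 1.001
        )
    u = (x - center_offset[0]) / normalization_radius
    v = (y - center_offset[1]) / normalization_radius
    mats = zernike_cartesian_coeffs(n_terms)
    A = _eval_terms(mats, u, v)
    coef, _, rank, sv = np.linalg.lstsq(A, z, rcond=None)
    resid = z - A @ coef
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    hull = None
    if len(pts) >= 4:
        try:
            hull = Delaunay(np.column_stack([x, y]), qhull_options="QJ")
        except Exception:
            hull = None
    return ZernikeSurface(
        coefficients=coef,
        normalization_radius=normalization_radius,
        center_offset=center_offset,
        surface_label=surface_label,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        condition_number=cond,
        domain_hull=hull,
        frame_rotation=frame_rotation,
    )


@dataclass
class EyeModel3D:
    """One incidence's 3-D model: fitted surfaces + the per-ray sample table.

    ``rays`` has one row per (meridian, A-scan) with the lateral world
    coordinates of the A-scan and the apparent axial depth per surface
    (NaN where missing); ``surfaces`` holds the Zernike fit per label;
    ``iris_points`` are kept as a raw point set for registration.
    ``distortion_state`` transitions raw -> corrected only.
    """

    incidence: str
    rays: "object"  # pandas.DataFrame
    surfaces: dict[str, ZernikeSurface]
    iris_points: np.ndarray
    distortion_state: str = "raw"
    corrected_points: dict[str, np.ndarray] = field(default_factory=dict)
    fit_frame: np.ndarray = field(default_factory=lambda: np.eye(3))
    log: dict = field(default_factory=dict)

    def surface_points(self, label: str) -> np.ndarray:
        """(N, 3) support points of a surface in the current state."""
        if self.distortion_state == "corrected" and label in self.corrected_points:
            return self.corrected_points[label]
        df = self.rays
        keep = np.isfinite(df[f"z_{label}"].to_numpy())
        return np.column_stack(
            [df["x"].to_numpy()[keep], df["y"].to_numpy()[keep], df[f"z_{label}"].to_numpy()[keep]]
        )


def assemble_model(
    meridians_mm: list,
    incidence: str,
    n_terms: int = 15,
    require_cornea: bool = True,
) -> EyeModel3D:
    """Build a raw (uncorrected) EyeModel3D from mm-converted meridians.

    Maps every meridian into the common 3-D frame, assembles the per-ray
    apparent-depth table, and fits a Zernike surface to each refracting
    surface's apparent points.  Raises immediately when the anterior cornea
    is absent but correction is intended (``require_cornea``), rather than
    failing later in the ray tracer.

    For off-axis incidences the whole anterior segment is steeply tilted
    with respect to the instrument axis; fitting tilted surfaces as graphs
    over the instrument lateral plane wastes the low-order expansion on
    tilt.  A per-incidence *fit frame* is therefore estimated from the
    apparent iris plane (total-least-squares normal) and all surfaces are
    fitted as graphs in that frame.
    """
    import pandas as pd

    from .geometry import rotation_aligning
    from .io import map_meridians_to_3d

    clouds = map_meridians_to_3d(meridians_mm)
    if require_cornea and "CA" not in clouds:
        raise ValueError("anterior cornea (CA) missing: distortion correction impossible")
    frame = np.eye(3)
    if "IRIS" in clouds and len(clouds["IRIS"]) >= 10:
        ip = clouds["IRIS"][["x", "y", "z"]].to_numpy()
        q = ip - ip.mean(axis=0)
        _, s, vt = np.linalg.svd(q, full_matrices=False)
        if s[1] > 1e-9 * s[0]:
            nrm = vt[2] if vt[2][2] > 0 else -vt[2]
            if nrm[2] > 0.5:  # sanity: tilt below 60 degrees
                frame = rotation_aligning(nrm, np.array([0.0, 0.0, 1.0]))
    indexed = {
        label: df.set_index(["meridian_index", "ascan_index"]) for label, df in clouds.items()
    }
    xy = pd.concat([d[["x", "y"]] for d in indexed.values()]).groupby(level=[0, 1]).first()
    zcols = [
        d[["z"]].rename(columns={"z": f"z_{label}"}) for label, d in indexed.items()
    ]
    rays = pd.concat([xy] + zcols, axis=1).reset_index()
    surfaces = {}
    for label in ("CA", "CP", "LA", "LP"):
        if label in clouds and len(clouds[label]) >= n_terms:
            surfaces[label] = fit_zernike(
                clouds[label][["x", "y", "z"]].to_numpy(),
                n_terms,
                surface_label=label,
                frame_rotation=frame,
            )
    iris = (
        clouds["IRIS"][["x", "y", "z"]].to_numpy() if "IRIS" in clouds else np.empty((0, 3))
    )
    return EyeModel3D(
        incidence=incidence, rays=rays, surfaces=surfaces, iris_points=iris, fit_frame=frame
    )
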