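"""3-D ray-tracing optical distortion correction.

OCT records each surface crossing at the *optical* depth along the A-scan:
the cumulative optical path length (geometric distance x group index).  A
deep surface therefore appears displaced both axially (index scaling) and
laterally (refraction bends the ray out of the A-scan line — and, for
off-axis incidences, out of the meridian plane entirely, which is why the
correction must be three-dimensional).

The correction walks the interfaces front to back.  For every A-scan ray:
refract at the fitted anterior cornea (air -> cornea), advance along the
refracted direction by OPL(CA->CP) / n_cornea to place the true posterior
cornea point; refit the posterior cornea; refract (cornea -> aqueous) and
advance by OPL(CP->LA) / n_aqueous to place the anterior lens; refit;
refract (aqueous -> lens) and advance by OPL(LA->LP) / n_lens to place the
posterior lens.  Iris points travel through cornea and aqueous only.
A ray whose anterior crossing is missing (e.g. outside the segmented
corneal domain) cannot be corrected, and its deeper samples are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import snell_refract_3d
from .phantom import OpticalMedia
from .zernike import EyeModel3D, ZernikeSurface, fit_zernike

__all__ = [
    "Ray",
    "snell_refract_3d",
    "intersect_ray_surface",
    "correct_surface",
    "correct_model",
    "CORRECTION_ORDER",
]

CORRECTION_ORDER = ("CP", "LA", "LP")


@dataclass(frozen=True)
class Ray:
    """A single ray: origin (mm) and unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("ray direction must be unit length")


def intersect_ray_surface(
    origins: np.ndarray,
    directions: np.ndarray,
    surface: ZernikeSurface,
    t0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest forward intersection of rays with a fitted Zernike surface.

    Works in the surface's fit frame: solves
    ``f(t) = z'(o' + t d') - Z(x'(t), y'(t)) = 0`` per ray by Newton
    iteration with an analytic derivative from the Zernike gradient.
    Returns ``(points, normals, ok)`` in *world* coordinates; rows with no
    forward intersection inside the surface domain are flagged
    ``ok = False`` and filled with NaN.  Normals point toward -Z of the
    fit frame (the incident side).
    """
    Rf = surface.R_frame
    o = np.atleast_2d(np.asarray(origins, dtype=float)) @ Rf.T
    d = np.atleast_2d(np.asarray(directions, dtype=float)) @ Rf.T
    n = len(o)
    if t0 is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(d[:, 2]) > 1e-9, (float(np.nanmean(
                surface.evaluate(o[:1, 0], o[:1, 1], check_domain=False))) - o[:, 2]) / d[:, 2], 1.0)
        t = np.where(np.isfinite(t) & (t > 0), t, 1.0)
    else:
        t = np.asarray(t0, dtype=float).copy()
    ok = np.all(np.isfinite(o), axis=1) & np.all(np.isfinite(d), axis=1)
    t = np.where(ok, t, np.nan)
    for _ in range(max_iter):
        p = o + t[:, None] * d
        z_s = surface.evaluate(p[:, 0], p[:, 1], check_domain=False)
        f = p[:, 2] - z_s
        gx, gy = surface.gradient(p[:, 0], p[:, 1])
        fp = d[:, 2] - gx * d[:, 0] - gy * d[:, 1]
        step = f / np.where(np.abs(fp) > 1e-14, fp, np.nan)
        conv = np.abs(f) < tol
        t = np.where(ok & ~conv, t - step, t)
        if np.all(conv | ~ok):
            break
    p = o + t[:, None] * d
    z_s = surface.evaluate(p[:, 0], p[:, 1], check_domain=False)
    ok = ok & np.isfinite(t) & (np.abs(p[:, 2] - z_s) < 1e-6) & (t > 0)
    ok = ok & surface.in_domain(p[:, 0], p[:, 1])
    pts = np.where(ok[:, None], p, np.nan) @ Rf  # back to world
    normals = surface.normal(p[:, 0], p[:, 1]) @ Rf
    normals = np.where(ok[:, None], normals, np.nan)
    return pts, normals, ok


def _ray_chain(model: EyeModel3D, media: OpticalMedia, upto: str) -> dict[str, np.ndarray]:
    """Trace every A-scan ray through the already-fitted surfaces.

    Returns per-label corrected points for all labels up to ``upto`` in the
    order CA -> CP -> LA -> LP (+ IRIS between CP and LA), using each ray's
    own recorded optical path lengths.  Surfaces anterior to each target
    must already be refit on corrected coordinates.
    """
    df = model.rays
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    n = len(df)
    zcols = {lbl: df[f"z_{lbl}"].to_numpy() if f"z_{lbl}" in df else np.full(n, np.nan)
             for lbl in ("CA", "CP", "LA", "LP", "IRIS")}
    ca = model.surfaces["CA"]
    out: dict[str, np.ndarray] = {}
    # A-scan rays are vertical (telecentric scan); the CA crossing is the
    # ray's intersection with the fitted CA, seeded at the apparent depth
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    origins = np.column_stack([x, y, zcols["CA"] - 1.0])
    p, nrm, okca = intersect_ray_surface(origins, d, ca, t0=np.ones(n))
    valid = np.isfinite(zcols["CA"]) & okca
    p = np.where(valid[:, None], p, np.nan)
    out["CA"] = p.copy()
    d, tir = snell_refract_3d(d, nrm, media.n_air, media.n_cornea_group)
    valid &= ~tir
    if upto == "CA":
        return out
    # posterior cornea
    L = (zcols["CP"] - zcols["CA"]) / media.n_cornea_group
    okcp = valid & np.isfinite(L)
    pcp = p + L[:, None] * d
    out["CP"] = np.where(okcp[:, None], pcp, np.nan)
    if upto == "CP":
        return out
    cp = model.surfaces["CP"]
    ncp = cp.world_normal(pcp)
    d2, tir2 = snell_refract_3d(d, ncp, media.n_cornea_group, media.n_aqueous_group)
    ok2 = okcp & ~tir2
    # iris (through cornea + aqueous)
    Li = (zcols["IRIS"] - zcols["CP"]) / media.n_aqueous_group
    oki = ok2 & np.isfinite(Li)
    out["IRIS"] = np.where(oki[:, None], pcp + Li[:, None] * d2, np.nan)
    # anterior lens
    L2 = (zcols["LA"] - zcols["CP"]) / media.n_aqueous_group
    okla = ok2 & np.isfinite(L2)
    pla = pcp + L2[:, None] * d2
    out["LA"] = np.where(okla[:, None], pla, np.nan)
    if upto == "LA":
        return out
    la = model.surfaces["LA"]
    nla = la.world_normal(pla)
    d3, tir3 = snell_refract_3d(d2, nla, media.n_aqueous_group, media.n_lens_group)
    ok3 = okla & ~tir3
    L3 = (zcols["LP"] - zcols["LA"]) / media.n_lens_group
    oklp = ok3 & np.isfinite(L3)
    out["LP"] = np.where(oklp[:, None], pla + L3[:, None] * d3, np.nan)
    return out


def correct_surface(
    model: EyeModel3D, target: str, media: OpticalMedia | None = None
) -> np.ndarray:
    """Corrected 3-D points of one surface (anterior surfaces must be done).

    Enforces the front-to-back ordering: requesting LP before LA (or LA
    before CP) raises, because the refraction at each preceding boundary
    must already be known on corrected coordinates.
    """
    media = media or OpticalMedia()
    if target not in CORRECTION_ORDER:
        raise ValueError(f"target must be one of {CORRECTION_ORDER}")
    if "CA" not in model.surfaces:
        raise ValueError("anterior cornea fit missing: cannot correct")
    for prior in CORRECTION_ORDER[: CORRECTION_ORDER.index(target)]:
        if prior not in model.corrected_points:
            raise ValueError(
                f"surface {prior} must be corrected (and refit) before {target}"
            )
    chain = _ray_chain(model, media, upto=target)
    pts = chain[target]
    return pts[np.all(np.isfinite(pts), axis=1)]


def correct_model(
    model: EyeModel3D,
    media: OpticalMedia | None = None,
    n_terms: int = 15,
    iris_mode: str = "corrected",
) -> EyeModel3D:
    """Full distortion correction of one incidence (CP, then LA, then LP).

    After each surface is corrected its Zernike expansion is refit on the
    corrected point set, so the next refraction uses true geometry.  The
    returned model has ``distortion_state='corrected'``, corrected point
    sets per surface, refit surfaces, and per-stage counts in ``log``.

    iris_mode : 'corrected' traces iris points through cornea and aqueous;
        'raw' keeps the apparent iris points (both orderings appear in
        practice; the default refracts).
    """
    if model.distortion_state != "raw":
        raise ValueError("model is already corrected")
    media = media or OpticalMedia()
    work = EyeModel3D(
        incidence=model.incidence,
        rays=model.rays,
        surfaces=dict(model.surfaces),
        iris_points=model.iris_points,
        distortion_state="raw",
        corrected_points={},
        log=dict(model.log),
    )
    if "CA" not in work.surfaces:
        raise ValueError("anterior cornea fit missing: cannot correct")
    # CA is imaged in air: apparent == true
    ca_pts = model.surface_points("CA")
    work.corrected_points["CA"] = ca_pts
    counts = {}
    for target in CORRECTION_ORDER:
        if f"z_{target}" not in model.rays:
            continue
        pts = correct_surface(work, target, media)
        work.corrected_points[target] = pts
        counts[target] = len(pts)
        if len(pts) >= n_terms:
            work.surfaces[target] = fit_zernike(
                pts, n_terms, surface_label=target, frame_rotation=model.fit_frame
            )
    if iris_mode == "corrected" and "z_IRIS" in model.rays and "CP" in work.corrected_points:
        chain = _ray_chain(work, media, upto="LA")
        ip = chain.get("IRIS")
        iris = ip[np.all(np.isfinite(ip), axis=1)] if ip is not None else model.iris_points
    else:
        iris = model.iris_points
    work.iris_points = iris
    work.distortion_state = "corrected"
    work.log["corrected_counts"] = counts
    return work
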