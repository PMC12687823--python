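"""Synthetic eye phantoms and the forward OCT acquisition simulator.

A :class:`PhantomEye` is an analytic anterior segment: four conicoid
refracting surfaces (anterior/posterior cornea, anterior/posterior lens),
an iris annulus, and the media between them.  The lens is the closed solid
bounded by the two lens conicoid caps, which meet at the equatorial
contour; its diameter, volume and surface area are available from
high-precision quadrature, independent of the reconstruction pipeline.

:func:`forward_simulate` emulates the multi-incidence acquisition protocol:
the whole phantom is rotated rigidly about the iris-circle centre by the
gaze angle, one telecentric ray is traced per A-scan per meridian, vector
Snell refraction is applied at each interface, and each surface crossing is
recorded as an axial *optical path length* in pixels — exactly the
distortion the reconstruction pipeline must undo.  Lens samples whose ray
hits the iris annulus are flagged missing (occlusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .geometry import Conicoid, rotation_about_axis, snell_refract_3d
from .io import SegmentedMeridian, SurfaceTrace

__all__ = [
    "OpticalMedia",
    "AcquisitionProtocol",
    "PhantomEye",
    "make_phantom",
    "forward_simulate",
    "DEFAULT_ORIENTATIONS",
]


@dataclass(frozen=True)
class OpticalMedia:
    """Group refractive indices of the ocular media."""

    n_air: float = 1.0
    n_cornea_group: float = 1.385
    n_aqueous_group: float = 1.345
    n_lens_group: float = 1.417

    def __post_init__(self) -> None:
        for v in (self.n_air, self.n_cornea_group, self.n_aqueous_group, self.n_lens_group):
            if v < 1:
                raise ValueError("refractive indices must be >= 1")


# gaze label -> (rotation axis, signed angle in degrees)
# nasal/temporal gaze rotates about the vertical (Y) axis, superior/inferior
# about the horizontal (X) axis; signs follow the right-hand rule in the
# instrument frame (+Z into the eye).
DEFAULT_ORIENTATIONS: dict[str, tuple[tuple[float, float, float], float]] = {
    "on_axis": ((0.0, 1.0, 0.0), 0.0),
    "nasal_30": ((0.0, 1.0, 0.0), 30.0),
    "nasal_45": ((0.0, 1.0, 0.0), 45.0),
    "temporal_30": ((0.0, 1.0, 0.0), -30.0),
    "temporal_45": ((0.0, 1.0, 0.0), -45.0),
    "superior_20": ((1.0, 0.0, 0.0), 20.0),
    "superior_30": ((1.0, 0.0, 0.0), 30.0),
    "inferior_45": ((1.0, 0.0, 0.0), -45.0),
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Radial-scan acquisition geometry and noise model.

    Defaults mirror a 65-meridian radial scan at 0.048 rad spacing with
    256 A-scans over a 14 mm lateral range and a 9.2 µm/pixel axial scale.
    """

    orientations: dict[str, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATIONS)
    )
    n_meridians: int = 65
    meridian_step: float = 0.048
    n_ascans: int = 256
    lateral_range: float = 14.0
    axial_scale: float = 9.2
    noise_sd_px: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        span = self.n_meridians * self.meridian_step
        if not 0.9 * np.pi <= span <= 1.1 * np.pi:
            raise ValueError(
                f"n_meridians * meridian_step = {span:.3f} rad does not span ~[0, pi)"
            )

    @property
    def lateral_pitch(self) -> float:
        return self.lateral_range / self.n_ascans


@dataclass(frozen=True)
class PhantomEye:
    """Analytic anterior-segment phantom (see module docstring)."""

    cornea_anterior: Conicoid
    cornea_posterior: Conicoid
    lens_anterior: Conicoid
    lens_posterior: Conicoid
    lens_thickness: float
    lens_equatorial_diameter: float
    iris_plane_z: float
    pupil_radius: float
    iris_outer_radius: float
    media: OpticalMedia = OpticalMedia()

    # -- derived geometry ---------------------------------------------------
    @property
    def equator_radius(self) -> float:
        return self.lens_equatorial_diameter / 2.0

    @property
    def lens_center_z(self) -> float:
        """Axial midpoint between the two lens apexes."""
        return 0.5 * (self.lens_anterior.apex_z + self.lens_posterior.apex_z)

    @property
    def central_corneal_thickness(self) -> float:
        return self.cornea_posterior.apex_z - self.cornea_anterior.apex_z

    def lens_radial_profile(self, theta: np.ndarray, phi: np.ndarray | float = 0.0) -> np.ndarray:
        """Radial distance I(theta, phi) from the lens centre to the surface.

        theta is the elevation from the *anterior* pole (theta=0 points
        toward the instrument, -Z), phi the azimuth about the lens axis.
        NaN where the solid is not star-convex along that direction (the
        validity check of :func:`make_phantom` rejects such phantoms).
        """
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        phi = np.broadcast_to(np.asarray(phi, dtype=float), theta.shape)
        u = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)]
        )
        o = np.tile([0.0, 0.0, self.lens_center_z], (len(u), 1))
        req = self.equator_radius * (1 + 1e-9)
        out = np.full(len(u), np.nan)
        for surf in (self.lens_anterior, self.lens_posterior):
            t, pts = surf.intersect(o, u)
            r = np.hypot(pts[:, 0], pts[:, 1])
            ok = np.isfinite(t) & (r <= req)
            out = np.where(ok & ~np.isfinite(out), t, out)
            # near the equator both caps report the same point; keep first
        return out

    def analytic_metrics(self) -> dict[str, float]:
        """DIA / VOL / LSA of the phantom lens by 1-D adaptive quadrature.

        These serve as the ground truth oracle for pipeline recovery tests;
        they never touch the polar-grid code path used by the pipeline.
        """
        req = self.equator_radius
        za = lambda r: self.lens_anterior.z(r)  # noqa: E731
        zp = lambda r: self.lens_posterior.z(r)  # noqa: E731
        vol, _ = integrate.quad(lambda r: 2 * np.pi * r * (zp(r) - za(r)), 0, req, limit=200)
        area = 0.0
        for surf in (self.lens_anterior, self.lens_posterior):
            sl = surf.sag_slope
            a, _ = integrate.quad(
                lambda r: 2 * np.pi * r * np.sqrt(1 + sl(r) ** 2), 0, req * (1 - 1e-12), limit=200
            )
            area += a
        return {"DIA": 2 * req, "VOL": float(vol), "LSA": float(area)}


def _cap_conicoid(radius: float, height: float, r_eq: float, apex_z: float, sign: int) -> Conicoid:
    """Conicoid cap with given apex radius reaching sag ``height`` at r_eq.

    The conic constant is solved from the sag equation
    r_eq^2 = 2 R h - (1+k) h^2.
    """
    if height <= 0:
        raise ValueError("cap height must be positive")
    if radius * height > r_eq**2 * (1 + 1e-12):
        raise ValueError(
            "cap would bulge wider than the equator: apex radius must not "
            f"exceed r_eq^2 / height = {r_eq**2 / height:.3f} mm"
        )
    k = (2 * radius * height - r_eq**2) / height**2 - 1.0
    return Conicoid(radius=radius, conic=k, apex_z=apex_z, sign=sign)


def make_phantom(
    preset: str = "young_adult",
    *,
    lens_diameter: float | None = None,
    lens_thickness: float | None = None,
    anterior_fraction: float = 0.42,
    lens_radius_ant: float | None = None,
    lens_radius_post: float | None = None,
    cornea_radius_ant: float = 7.8,
    cornea_radius_post: float = 6.5,
    cornea_conic: float = -0.25,
    corneal_thickness: float = 0.55,
    anterior_chamber_depth: float = 3.0,
    pupil_radius: float = 3.5,
    iris_outer_radius: float = 6.0,
    media: OpticalMedia | None = None,
) -> PhantomEye:
    """Construct a validated :class:`PhantomEye`.

    Presets
    -------
    ``young_adult``
        Literature-plausible dilated young adult eye: corneal radii
        7.8 / 6.5 mm (conic -0.25), lens of equatorial diameter 9.2 mm and
        thickness 3.9 mm built from two conicoid caps of apex radii
        10.5 / 6.0 mm, dilated pupil radius 3.5 mm.
    ``spherical``
        Both lens caps spherical with radius ``lens_diameter / 2`` so the
        lens is a full sphere — every metric has a closed form.

    The lens caps are constructed to meet exactly at the equator: the cap
    heights are ``anterior_fraction * thickness`` and the remainder, and
    each cap's conic constant is solved from its apex radius, height and
    the equatorial radius.  Invariants (closed equatorial contour, pupil
    inside the equator, numerical star-convexity about the lens centre) are
    verified and violations rejected with a diagnostic.
    """
    media = media or OpticalMedia()
    if preset == "spherical":
        dia = lens_diameter if lens_diameter is not None else 9.2
        R = dia / 2.0
        thick = dia
        ra = rp = R
        f = 0.5
    elif preset == "young_adult":
        dia = lens_diameter if lens_diameter is not None else 9.2
        thick = lens_thickness if lens_thickness is not None else 3.9
        ra = lens_radius_ant if lens_radius_ant is not None else 10.5
        rp = lens_radius_post if lens_radius_post is not None else 6.0
        f = anterior_fraction
    else:
        raise ValueError(f"unknown preset {preset!r}")

    req = dia / 2.0
    h_ant = f * thick
    h_post = thick - h_ant
    la_apex = corneal_thickness + anterior_chamber_depth
    lp_apex = la_apex + thick
    lens_ant = _cap_conicoid(ra, h_ant, req, la_apex, sign=+1)
    lens_post = _cap_conicoid(rp, h_post, req, lp_apex, sign=-1)

    # cornea apertures kept at physiological semi-diameters; the posterior
    # cornea sits corneal_thickness behind the anterior apex
    ca = Conicoid(cornea_radius_ant, cornea_conic, 0.0, +1, extent_radius=5.5)
    cp = Conicoid(cornea_radius_post, cornea_conic, corneal_thickness, +1, extent_radius=5.2)

    eye = PhantomEye(
        cornea_anterior=ca,
        cornea_posterior=cp,
        lens_anterior=lens_ant,
        lens_posterior=lens_post,
        lens_thickness=thick,
        lens_equatorial_diameter=dia,
        iris_plane_z=la_apex - 0.1,
        pupil_radius=pupil_radius,
        iris_outer_radius=iris_outer_radius,
        media=media,
    )
    _validate_phantom(eye)
    return eye


def _validate_phantom(eye: PhantomEye) -> None:
    req = eye.equator_radius
    za = eye.lens_anterior.z(req)
    zp = eye.lens_posterior.z(req)
    if not (np.isfinite(za) and np.isfinite(zp)):
        raise ValueError("lens surfaces do not reach the equatorial radius: no closed contour")
    if abs(za - zp) > 1e-6:
        raise ValueError(
            f"lens surfaces do not intersect at the equator (gap {abs(za - zp):.3g} mm)"
        )
    if eye.lens_equatorial_diameter <= 2 * eye.pupil_radius:
        raise ValueError("lens equatorial diameter must exceed the pupil diameter")
    theta = np.linspace(1e-4, np.pi - 1e-4, 720)
    prof = eye.lens_radial_profile(theta)
    if not np.all(np.isfinite(prof)):
        raise ValueError("phantom lens is not star-convex about its centre")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def orientation_rotation(
    protocol: AcquisitionProtocol, orientation: str
) -> tuple[np.ndarray, float]:
    """Rotation matrix and angle (deg) for a gaze label."""
    if orientation not in protocol.orientations:
        raise KeyError(f"orientation {orientation!r} not in protocol")
    axis, angle_deg = protocol.orientations[orientation]
    if angle_deg == 0.0:
        return np.eye(3), 0.0
    return rotation_about_axis(np.asarray(axis, float), np.deg2rad(angle_deg)), angle_deg


def forward_simulate(
    phantom: PhantomEye,
    protocol: AcquisitionProtocol,
    orientation: str,
) -> list[SegmentedMeridian]:
    """Simulate one incidence: distorted, iris-occluded segmented meridians.

    The phantom is rotated rigidly by the gaze angle about the iris-circle
    centre; telecentric rays (one per A-scan) are traced through CA, CP,
    iris plane, LA and LP, refracting at each interface; each crossing is
    recorded as cumulative optical path length (geometric segment length x
    group index) converted to axial pixels.  Rays that miss a surface, are
    blocked by the iris annulus, or undergo total internal reflection have
    the affected samples flagged missing.
    """
    R, _ = orientation_rotation(protocol, orientation)
    Rt = R.T
    c = np.array([0.0, 0.0, phantom.iris_plane_z])
    med = phantom.media
    n_mer, n_asc = protocol.n_meridians, protocol.n_ascans
    pitch = protocol.lateral_pitch
    center = (n_asc - 1) / 2.0

    angles = np.arange(n_mer) * protocol.meridian_step
    lat = (np.arange(n_asc) - center) * pitch  # mm, direction=+1
    # rays in world frame: origin well before the cornea, direction +Z
    mer_idx, asc_idx = np.meshgrid(np.arange(n_mer), np.arange(n_asc), indexing="ij")
    a = angles[mer_idx.ravel()]
    l_ = lat[asc_idx.ravel()]
    origins_w = np.column_stack([l_ * np.cos(a), l_ * np.sin(a), np.full(l_.shape, -5.0)])
    d_w = np.tile([0.0, 0.0, 1.0], (len(origins_w), 1))
    # trace in the (rotated) phantom's own frame
    o = (origins_w - c) @ R + c  # R.T applied to rows == rows @ R
    d = d_w @ R
    N = len(o)
    depth = {lbl: np.full(N, np.nan) for lbl in ("CA", "CP", "LA", "LP", "IRIS")}

    # --- anterior cornea (air) --------------------------------------------
    tCA, pCA = phantom.cornea_anterior.intersect(o, d)
    hitCA = np.isfinite(tCA)
    # axial datum: the world plane z = 0; the ray starts at world z = -5 and
    # |d| = 1, so the recorded depth is -5 + n_air * t (world z of the
    # crossing when n_air = 1)
    depth["CA"][hitCA] = -5.0 + med.n_air * tCA[hitCA]
    nCA = phantom.cornea_anterior.normal(pCA, toward=d)
    d1, tir1 = snell_refract_3d(d, nCA, med.n_air, med.n_cornea_group)
    ok = hitCA & ~tir1

    # --- posterior cornea (corneal stroma) --------------------------------
    tCP, pCP = phantom.cornea_posterior.intersect(
        np.where(ok[:, None], pCA, np.nan), np.where(ok[:, None], d1, np.nan)
    )
    okCP = ok & np.isfinite(tCP)
    depth["CP"][okCP] = depth["CA"][okCP] + med.n_cornea_group * tCP[okCP]
    nCP = phantom.cornea_posterior.normal(pCP, toward=d1)
    d2, tir2 = snell_refract_3d(d1, nCP, med.n_cornea_group, med.n_aqueous_group)
    ok2 = okCP & ~tir2

    # --- iris plane (aqueous) ---------------------------------------------
    with np.errstate(invalid="ignore", divide="ignore"):
        t_iris = (phantom.iris_plane_z - pCP[:, 2]) / d2[:, 2]
    p_iris = pCP + t_iris[:, None] * d2
    r_iris = np.hypot(p_iris[:, 0], p_iris[:, 1])
    fwd = ok2 & np.isfinite(t_iris) & (t_iris > 0)
    on_annulus = fwd & (r_iris >= phantom.pupil_radius) & (r_iris <= phantom.iris_outer_radius)
    blocked = fwd & (r_iris >= phantom.pupil_radius)
    depth["IRIS"][on_annulus] = depth["CP"][on_annulus] + med.n_aqueous_group * t_iris[on_annulus]
    through = ok2 & ~blocked

    # --- anterior lens (aqueous) ------------------------------------------
    req = phantom.equator_radius * (1 + 1e-9)
    tLA, pLA = phantom.lens_anterior.intersect(
        np.where(through[:, None], pCP, np.nan), np.where(through[:, None], d2, np.nan)
    )
    rLA = np.hypot(pLA[:, 0], pLA[:, 1])
    okLA = through & np.isfinite(tLA) & (rLA <= req)
    depth["LA"][okLA] = depth["CP"][okLA] + med.n_aqueous_group * tLA[okLA]
    nLA = phantom.lens_anterior.normal(pLA, toward=d2)
    d3, tir3 = snell_refract_3d(d2, nLA, med.n_aqueous_group, med.n_lens_group)
    ok3 = okLA & ~tir3

    # --- posterior lens (lens substance) ----------------------------------
    tLP, pLP = phantom.lens_posterior.intersect(
        np.where(ok3[:, None], pLA, np.nan), np.where(ok3[:, None], d3, np.nan)
    )
    rLP = np.hypot(pLP[:, 0], pLP[:, 1])
    okLP = ok3 & np.isfinite(tLP) & (rLP <= req)
    depth["LP"][okLP] = depth["LA"][okLP] + med.n_lens_group * tLP[okLP]

    # --- pixel conversion + noise -----------------------------------------
    scale_mm_per_px = protocol.axial_scale / 1000.0
    rng = np.random.default_rng(
        np.random.SeedSequence([protocol.rng_seed, _orientation_id(protocol, orientation)])
    )
    meridians: list[SegmentedMeridian] = []
    for i in range(n_mer):
        sl = slice(i * n_asc, (i + 1) * n_asc)
        samples = {}
        for lbl in ("CA", "CP", "LA", "LP", "IRIS"):
            z_mm = depth[lbl][sl]
            miss = ~np.isfinite(z_mm)
            z_px = np.where(miss, np.nan, z_mm / scale_mm_per_px)
            if protocol.noise_sd_px > 0:
                z_px = z_px + rng.normal(0.0, protocol.noise_sd_px, n_asc)
            samples[lbl] = SurfaceTrace(np.arange(n_asc, dtype=float), z_px, miss)
        meridians.append(SegmentedMeridian(i, float(angles[i]), +1, samples))
    return meridians


def _orientation_id(protocol: AcquisitionProtocol, orientation: str) -> int:
    return list(protocol.orientations).index(orientation)
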