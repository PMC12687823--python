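"""Shared geometric primitives: conicoid surfaces, rigid rotations, refraction.

Coordinate convention (used throughout the package): right-handed frame with
+Z pointing from the instrument into the eye, X along the temporal->nasal
axis, Y along the inferior->superior axis.  The origin sits at the on-axis
corneal apex before registration.  All lengths in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Conicoid",
    "rotation_about_axis",
    "rotation_aligning",
    "snell_refract_3d",
    "TIR",
]


class TIR(Exception):
    """Raised by scalar helpers when total internal reflection occurs."""


@dataclass(frozen=True)
class Conicoid:
    """Rotationally symmetric conic-section surface (conicoid).

    The surface is the apex-side branch of

        r^2 = 2 R s - (1 + k) s^2,      s = sign * (z - z_apex),

    i.e. the sag ``s(r) = r^2 / (R + sqrt(R^2 - (1+k) r^2))``.  ``sign=+1``
    gives a surface opening toward +Z (anterior surfaces seen from the
    instrument); ``sign=-1`` mirrors it (posterior lens).  ``extent_radius``
    truncates the surface laterally (physical aperture).

    Parameters
    ----------
    radius : apex radius of curvature, mm (> 0).
    conic : conic constant k (0 sphere, -1 paraboloid, < -1 hyperboloid).
    apex_z : axial apex position, mm.
    sign : +1 or -1, orientation of the sag direction.
    extent_radius : lateral truncation radius, mm.
    """

    radius: float
    conic: float = 0.0
    apex_z: float = 0.0
    sign: int = 1
    extent_radius: float = np.inf

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("conicoid radius must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def max_radius(self) -> float:
        """Largest lateral radius where the sag is defined."""
        p = 1.0 + self.conic
        geom = self.radius / np.sqrt(p) if p > 0 else np.inf
        return float(min(geom, self.extent_radius))

    def sag(self, r: np.ndarray | float) -> np.ndarray:
        """Sag s(r) >= 0 measured from the apex plane; NaN outside support."""
        r = np.asarray(r, dtype=float)
        p = 1.0 + self.conic
        disc = self.radius**2 - p * r**2
        with np.errstate(invalid="ignore"):
            s = r**2 / (self.radius + np.sqrt(np.maximum(disc, 0.0)))
        s = np.where(
            (disc < -1e-9 * self.radius**2) | (r > self.extent_radius * (1 + 1e-12)),
            np.nan,
            s,
        )
        return s

    def z(self, r: np.ndarray | float) -> np.ndarray:
        """Axial position z(r) = apex_z + sign * sag(r)."""
        return self.apex_z + self.sign * self.sag(r)

    def sag_slope(self, r: np.ndarray | float) -> np.ndarray:
        """d sag / d r."""
        r = np.asarray(r, dtype=float)
        p = 1.0 + self.conic
        disc = self.radius**2 - p * r**2
        with np.errstate(invalid="ignore"):
            return np.where(disc > 0, r / np.sqrt(np.maximum(disc, 1e-300)), np.nan)

    def intersect(
        self, origins: np.ndarray, directions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form first intersection of rays with the conicoid branch.

        Parameters
        ----------
        origins, directions : (N, 3) arrays; directions need not be unit
            (the returned parameter t is in units of |direction|).

        Returns
        -------
        t : (N,) ray parameters (NaN where no valid hit).
        points : (N, 3) intersection points (NaN rows where no hit).

        The quadric ``x^2 + y^2 - 2 R s + (1+k) s^2 = 0`` has two roots; the
        apex-side branch is selected by requiring ``R - (1+k) s >= 0`` and
        ``s >= 0``, and the smallest positive t among valid roots is kept.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=float))
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        p = 1.0 + self.conic
        R = self.radius
        # s(t) = sign*(oz + t dz - apex_z)
        oz = self.sign * (o[:, 2] - self.apex_z)
        dz = self.sign * d[:, 2]
        # quadratic A t^2 + B t + C = 0
        A = d[:, 0] ** 2 + d[:, 1] ** 2 + p * dz**2
        B = 2 * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1] + p * oz * dz - R * dz)
        C = o[:, 0] ** 2 + o[:, 1] ** 2 + p * oz**2 - 2 * R * oz
        t = np.full(len(o), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            disc = B**2 - 4 * A * C
            sq = np.sqrt(np.maximum(disc, 0.0))
            quad = np.abs(A) > 1e-14
            roots = np.stack(
                [
                    np.where(quad, (-B - sq) / (2 * A), -C / np.where(np.abs(B) > 1e-300, B, np.nan)),
                    np.where(quad, (-B + sq) / (2 * A), np.nan),
                ],
                axis=1,
            )
            roots = np.where(quad[:, None] & (disc[:, None] < 0), np.nan, roots)
        for col in range(2):
            tc = roots[:, col]
            pt = o + tc[:, None] * d
            s = self.sign * (pt[:, 2] - self.apex_z)
            r2 = pt[:, 0] ** 2 + pt[:, 1] ** 2
            ok = (
                np.isfinite(tc)
                & (tc > 1e-9)
                & (s > -1e-12)
                & (R - p * s >= -1e-9)
                & (r2 <= self.extent_radius**2 + 1e-12)
            )
            take = ok & (~np.isfinite(t) | (tc < t))
            t = np.where(take, tc, t)
        pts = o + t[:, None] * d
        return t, pts

    def normal(self, points: np.ndarray, toward: np.ndarray | None = None) -> np.ndarray:
        """Unit surface normals at on-surface points.

        The gradient of ``F = x^2 + y^2 - 2 R s + (1+k) s^2`` is normalised;
        if ``toward`` (a direction, e.g. the incoming ray) is given, normals
        are flipped so that ``normal . toward < 0`` (facing the ray).
        """
        pt = np.atleast_2d(np.asarray(points, dtype=float))
        s = self.sign * (pt[:, 2] - self.apex_z)
        gz = self.sign * (-2 * self.radius + 2 * (1 + self.conic) * s)
        g = np.column_stack([2 * pt[:, 0], 2 * pt[:, 1], gz])
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        if toward is not None:
            toward = np.atleast_2d(np.asarray(toward, dtype=float))
            flip = np.sum(g * toward, axis=1) > 0
            g[flip] *= -1
        return g


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    a = a / n
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def rotation_aligning(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``v_from`` onto ``v_to``.

    The rotation axis is ``v_from x v_to`` (identity when parallel); for
    anti-parallel inputs an arbitrary perpendicular axis is used.
    """
    a = np.asarray(v_from, float) / np.linalg.norm(v_from)
    b = np.asarray(v_to, float) / np.linalg.norm(v_to)
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-15:
        if c > 0:
            return np.eye(3)
        # 180 deg: any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-12:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, np.pi)
    return rotation_about_axis(axis, float(np.arctan2(n, c)))


def snell_refract_3d(
    direction: np.ndarray, normal: np.ndarray, n1: float, n2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vector form of Snell's law at one interface, vectorised over rays.

    Parameters
    ----------
    direction : (..., 3) unit propagation directions.
    normal : (..., 3) unit surface normals facing the incident medium
        (``normal . direction <= 0``); normals pointing the other way are
        flipped internally.
    n1, n2 : refractive indices of the incident / transmitting media.

    Returns
    -------
    refracted : (..., 3) unit refracted directions (NaN rows on TIR).
    tir : boolean mask, True where total internal reflection occurred.

    The tangential component of the wave vector (n * direction) is conserved
    across the interface; the refracted ray lies in the plane of incidence.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    nv = np.atleast_2d(np.asarray(normal, dtype=float)).copy()
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    flip = np.sum(nv * d, axis=-1) > 0
    nv[flip] *= -1
    eta = n1 / n2
    cos_i = -np.sum(nv * d, axis=-1)
    sin2_t = eta**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.maximum(1.0 - sin2_t, 0.0))
    out = eta * d + (eta * cos_i - cos_t)[:, None] * nv
    out[tir] = np.nan
    # renormalise against rounding drift
    with np.errstate(invalid="ignore"):
        out /= np.linalg.norm(out, axis=-1, keepdims=True)
    if np.asarray(direction).ndim == 1:
        return out[0], bool(tir[0])
    return out, tir
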