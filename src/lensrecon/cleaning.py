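"""Boundary cleaning: eyelash-artifact rejection and manual-point ingestion.

Automatic segmentation of the anterior cornea is prone to eyelash shadows —
isolated samples far off the smooth corneal profile.  These are removed by
iteratively fitting a low-order polynomial and discarding samples beyond
``k_sd`` residual standard deviations, refitting until stable.  Manually
clicked sparse boundaries (used at high incidence angles where automatic
segmentation fails) are densified with a shape-preserving cubic
interpolant, never extrapolated beyond the clicked span: any region not
covered by the click-points stays missing, because uncovered regions cannot
be distortion-corrected downstream and would silently fabricate geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["BoundaryTrace", "reject_artifacts", "densify_manual", "clip_to_pupil"]


@dataclass
class BoundaryTrace:
    """Ordered (lateral, axial) samples of one surface in one B-scan."""

    lateral: np.ndarray
    axial: np.ndarray
    surface_label: str = ""
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.axial = np.asarray(self.axial, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.lateral), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        order = np.argsort(self.lateral, kind="stable")
        self.lateral = self.lateral[order]
        self.axial = self.axial[order]
        self.missing = self.missing[order]


def reject_artifacts(
    trace: BoundaryTrace,
    poly_order: int = 4,
    k_sd: float = 3.0,
    max_iter: int = 10,
) -> tuple[BoundaryTrace, int]:
    """Iterative polynomial outlier rejection.

    Fits a least-squares polynomial of ``poly_order`` to the valid samples,
    removes samples whose absolute residual exceeds ``k_sd`` times the
    residual standard deviation, and refits; stops when a pass removes
    nothing or after ``max_iter`` passes.

    Returns the cleaned trace and the number of samples removed.  Raises if
    fewer than ``poly_order + 2`` samples remain at any point ("degenerate
    trace").
    """
    keep = ~trace.missing
    if keep.sum() < poly_order + 2:
        raise ValueError("degenerate trace: too few samples for the polynomial order")
    x, y = trace.lateral, trace.axial
    removed = 0
    for _ in range(max_iter):
        xs, ys = x[keep], y[keep]
        coef = np.polynomial.polynomial.polyfit(xs, ys, poly_order)
        resid = ys - np.polynomial.polynomial.polyval(xs, coef)
        sd = float(np.std(resid))
        if sd <= 1e-12:  # exact fit: nothing can exceed k_sd * 0 meaningfully
            break
        bad = np.abs(resid) > k_sd * sd
        if not np.any(bad):
            break
        idx = np.flatnonzero(keep)[bad]
        keep[idx] = False
        removed += int(bad.sum())
        if keep.sum() < poly_order + 2:
            raise ValueError("degenerate trace: artifact rejection removed too many samples")
    return (
        BoundaryTrace(x[keep], y[keep], trace.surface_label),
        removed,
    )


def densify_manual(
    points_lateral: np.ndarray,
    points_axial: np.ndarray,
    target_lateral: np.ndarray,
    surface_label: str = "",
) -> BoundaryTrace:
    """Densify >= 5 manual click-points onto the A-scan lateral grid.

    Uses a monotone shape-preserving cubic (PCHIP — no overshoot, so no
    fabricated lens periphery).  Grid positions outside the clicked lateral
    span are flagged missing rather than extrapolated.
    """
    xl = np.asarray(points_lateral, dtype=float)
    ya = np.asarray(points_axial, dtype=float)
    if len(xl) < 5:
        raise ValueError("at least five click-points are required")
    order = np.argsort(xl)
    xl, ya = xl[order], ya[order]
    if np.any(np.diff(xl) <= 0):
        raise ValueError("duplicate lateral positions in click-points")
    if xl[-1] - xl[0] <= 0:
        raise ValueError("zero lateral extent")
    tg = np.asarray(target_lateral, dtype=float)
    interp = PchipInterpolator(xl, ya, extrapolate=False)
    z = interp(tg)
    missing = ~np.isfinite(z)
    return BoundaryTrace(tg, z, surface_label, missing)


def clip_to_pupil(lens_trace: BoundaryTrace, iris_trace: BoundaryTrace) -> BoundaryTrace:
    """Flag lens samples lateral to the innermost iris points as missing.

    The iris trace must have samples on both sides of the scan axis; the
    pupil aperture in this B-scan is the open interval between the
    innermost (closest-to-axis) iris sample on each side.  Lens samples
    outside that interval are occluded and flagged missing.  If the iris
    does not bracket the lens span the trace is returned unchanged.
    """
    ivalid = iris_trace.lateral[~iris_trace.missing]
    left = ivalid[ivalid < 0]
    right = ivalid[ivalid > 0]
    if len(left) == 0 or len(right) == 0:
        return lens_trace
    lo, hi = left.max(), right.min()
    missing = lens_trace.missing | (lens_trace.lateral <= lo) | (lens_trace.lateral >= hi)
    return BoundaryTrace(
        lens_trace.lateral, lens_trace.axial, lens_trace.surface_label, missing
    )
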