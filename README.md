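# lensrecon

Full 3-D reconstruction of the human crystalline lens shape from
multi-incidence anterior-segment OCT.

On-axis OCT only ever sees the central lens through the pupil: the
equatorial region — which carries the lens diameter, volume and surface
area — is hidden behind the iris. When the eye rotates to fixate an
eccentric target, different peripheral sectors of the lens come into view
through the (dilated) pupil. `lensrecon` merges segmented radial-scan
acquisitions taken under several gaze orientations (on-axis; nasal and
temporal 30°/45°; superior 20°/30°; inferior 45°) into one closed lens
surface and quantifies its geometry. It is written for researchers in
ocular biometry and physiological optics working with segmented
anterior-segment OCT data.

## Method

Starting from per-meridian segmented boundaries (anterior/posterior
cornea, anterior/posterior lens, iris) in pixels, the pipeline runs five
stages:

1. **Cleaning** — iterative low-order polynomial fitting with 3·SD outlier
   rejection removes eyelash artifacts; sparse manually clicked boundaries
   are densified with a shape-preserving cubic, never extrapolated.
2. **Per-incidence 3-D model** — pixels → mm (9.2 µm/pixel axial; 14 mm /
   256 A-scans lateral), meridians mapped to 3-D by their scan angle
   (0.048 rad spacing), and each surface approximated by a 15-term Zernike
   expansion (OSA/ANSI ordering) fitted by least squares.
3. **Optical distortion correction** — OCT records optical path length
   along each A-scan, so deep surfaces appear displaced by refraction at
   every interface above them. A native 3-D ray tracer refracts each
   A-scan ray at the fitted anterior cornea (vector Snell's law), advances
   it by OPL/n through each medium (group indices n_cornea = 1.385,
   n_aqueous = 1.345, n_lens = 1.417), and rebuilds CP, LA and LP front to
   back, refitting each surface before the next step.
4. **Registration** — each incidence is aligned by its iris: a
   total-least-squares plane undoes the gaze tilt, the fitted pupil-margin
   circle centre becomes the common origin, and a trimmed
   iterative-closest-point match of the lens surfaces refines the residual
   rigid motion.
5. **Eigenlens projection** — the merged cloud is resampled as radial
   elevations I on a fixed polar grid (P = Q = 100, M = 10 000 nodes) and
   projected onto the first K = 6 principal components ("eigenlenses") of
   a training population: a = Mᵀ(I − Ī), Î = Ī + Σ aₖeₖ. The
   reconstruction smooths noise and closes the shape over sectors no view
   observed. From Î the pipeline reports the equatorial diameter DIA
   (max through-axis caliper), volume VOL (anterior + posterior double
   integral) and surface area LSA (Delaunay triangle sum).

A synthetic eye phantom (`lensrecon.phantom`) with conicoid surfaces and a
closed two-cap lens forward-simulates the whole acquisition — rotation
about the iris centre, per-ray refraction and OPL accumulation, iris
occlusion, pixel noise — so every stage is testable by parameter recovery
against analytic ground truth.

## Worked example

```python
from lensrecon import AcquisitionProtocol, LensReconstruction, make_phantom

eye = make_phantom("young_adult")          # DIA 9.2 mm, 3.9 mm thick lens
protocol = AcquisitionProtocol(noise_sd_px=0.0, rng_seed=1)
result = LensReconstruction.from_phantom(eye, protocol).fit()
print(result.summary())
```

```
Full-shape crystalline lens reconstruction
==========================================================
incidences registered : 8
merged lens points    : 136660
grid                  : P=100 Q=100 (observed 87.8%)
eigenlens K           : 6
coefficients a_k (mm) : -5.293 +6.386 +5.043 -1.224 -0.054 -0.539
----------------------------------------------------------
DIA  (equatorial diameter) :    9.148 mm
VOL  (lens volume)         :   147.50 mm^3
LSA  (lens surface area)   :   159.03 mm^2
----------------------------------------------------------
mean inter-incidence overlap RMS : 46.4 um
```

The phantom's analytic values are DIA 9.200 mm, VOL 148.07 mm³ and LSA
160.94 mm²: the noise-free 8-view round trip recovers the diameter to
0.6 %, the volume to 0.4 % and the surface area to 1.2 %. The 12.2 % of
grid nodes no view observed (an equatorial band, mostly on the superior
side where the protocol reaches only 30°) are filled by the eigenlens
reconstruction. The overlap RMS is the mean disagreement between
different incidences over the lens regions they both observed — the
built-in audit of registration quality.

The same run is available from the shell:

```bash
lensrecon simulate --out-dir sim --seed 1
lensrecon run-all --in-dir sim --out-dir out
lensrecon index-sweep --in-dir sim --out-dir out   # n_lens 1.40/1.417/1.44
```

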