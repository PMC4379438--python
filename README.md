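# azint

Azimuthal integration of 2-D diffraction / SAXS images with ring-based
detector-geometry calibration, implemented as a tested library plus a
non-interactive CLI.

Features:

* **Detector model** — pixel-corner coordinate field `(Ny, Nx, 4, 3)` with
  masking, binning and HDF5 persistence; regular grids and gapped
  multi-module layouts.
* **PONI geometry** — six parameters (sample–PONI distance, two PONI
  coordinates, three rotations) + wavelength; pixel → 2θ/χ/q/r transforms;
  PONI text-file I/O.
* **Calibration** — massif extraction, difference-of-Gaussians scale-space
  blob detection with subpixel (Taylor/Hessian) refinement, ring
  assignment from a calibrant d-spacing file, bounded least-squares
  geometry refinement, two-round recalibration.
* **Integration** — 1-D and 2-D azimuthal integration with three
  pixel-splitting schemes (`nosplit`, `bbox`, `fullsplit`), each available
  as direct histogramming or as a precomputed CSR sparse rebinner
  (numerically identical); dark/flat/solid-angle/polarization corrections,
  static + dynamic (dummy-value) masking; Poisson, azimuthal and
  user-variance error models.
* **Separation** — isotropic/Bragg decomposition by azimuthal percentile
  filtering, phase-correlation image offset, and calibration validation.
* **Fixture engine** — synthetic continuous-ring and spotty-ring
  calibration images with exact ground truth (`calcfrom1d`,
  `fake_calibration_image`, `spotty_rings_image`); LaB6-like, ceria-like
  and silver-behenate-like d-spacing files ship with the package.

## CLI

Four commands are installed: `azint` (integrate), `azcal` (recalibrate),
`azsep` (isotropic/Bragg separation) and `azfake` (synthetic fixtures).
Images may be TIFF, EDF, NPY or HDF5 dataset paths (`file.h5::/path`).

```sh
# generate a synthetic calibration image + ground truth
azfake --poni true.poni --calibrant LaB6.D --noise --seed 1 \
       -o rings.tif --truth-out truth.json

# recalibrate a perturbed geometry from the rings
azcal rings.tif --poni start.poni --calibrant LaB6.D \
      -o refined.poni --report-out report.json

# azimuthal integration, 1000 bins in 2theta degrees
azint rings.tif --poni refined.poni --npt 1000 --unit 2th_deg \
      --scheme fullsplit -o pattern.dat

# isotropic background / Bragg separation
azsep frame.tif --poni refined.poni --prefix out
```

The PONI file format is plain text (`Key: value`, SI units — metres and
radians), with keys `Distance`, `Poni1`, `Poni2`, `Rot1..3`, `Wavelength`
and a detector block. Calibrant files hold one d-spacing (Å) per line
(`#` comments allowed).

## Conventions

* Detector frame: axis 1 = slow/vertical (rows), axis 2 = fast/horizontal
  (columns), origin at the lower-left pixel corner seen from the sample;
  all lengths in metres.
* Rotations are active, right-handed, applied as `R3(rot3)·R2(rot2)·R1(rot1)`
  about the vertical, horizontal and beam axes; with zero rotations the
  beam hits the detector orthogonally at the PONI. Note that `rot3`
  (about the beam axis) does not affect scattering angles and is therefore
  excluded from the default refinement set.
* χ = 0 along the horizontal transverse axis, in `(−π, π]`; q is reported
  in nm⁻¹ (Å⁻¹ available), 2θ in degrees by default on the CLI.
* Caglioti resolution parameters (U, V, W) are expressed so that the FWHM
  comes out in radians of 2θ.
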