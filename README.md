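# dielmap

Pixel-resolved mapping of local dielectric permittivity from
hyperspectral fluorescence stacks of an environment-sensitive dye.

A hyperspectral stack records a full emission spectrum at every pixel
(by default 32 detection windows of 9.75 nm covering 416–728 nm). The
emission of a solvatochromic probe redshifts with the dielectric
permittivity of its molecular surroundings, so each pixel spectrum can
be inverted to a local permittivity once a calibration is available.
`dielmap` implements the complete analysis chain:

- **`dielmap.spectra`** — spectral data types, the discrete spectral
  phasor transform (per-pixel `(G, S)` Fourier coordinates, phase and
  modulus), and skewed-Gaussian spectral fitting to extract the
  emission maximum.
- **`dielmap.calibration`** — the Lippert–Mataga-style calibration
  `1/λmax = a·f(ε) + b` with a pluggable reaction-field function
  `f(ε)` (default `(ε−1)/(2ε+1)`), fitted by exact linear least
  squares to reference solutions; the linear phase↔wavelength window
  mapping; monotone inversion with clamp-and-flag semantics; and the
  Maxwell–Garnett mixture law for constructing reference
  permittivities.
- **`dielmap.mapping`** — intensity thresholding, per-pixel
  permittivity maps, condensate/depleted two-phase segmentation, and
  per-phase statistics including the permittivity contrast
  `ε_condensate − ε_depleted` (the phase is averaged first, then
  converted to permittivity).
- **`dielmap.wetting`** — membrane-wetting mechanics: the intrinsic
  contact angle `arccos((sin θe − sin θc)/sin θi)` from apparent
  contact-angle triples, membrane tension ratios, the affinity
  contrast `W = cos θin · Σce`, and the linear trend of θin versus
  permittivity contrast.
- **`dielmap.synth`** — synthetic-data generation: a spectral forward
  model with known ground truth, two-phase droplet scenes with Poisson
  shot noise, the "sedimenting droplet" artifact (missing
  short-wavelength channels), and synthetic calibration reference
  sets.
- **`dielmap.io` / `dielmap.cli`** — TIFF stack reading/writing, CSV
  and JSON interchange, YAML run configuration, provenance logging,
  and the command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the
transform invariants (linearity, modulus bound, shift covariance,
oracle equivalence), and `tests/test_acceptance.py` with one test per
acceptance criterion (analytic identities, calibration round trips,
end-to-end Monte-Carlo parameter recovery on synthetic stacks, artifact
exclusion, wetting mechanics, and skew-Gaussian recovery).

## Command line

```sh
# generate a synthetic two-phase stack with ground truth
dielmap simulate --seed 1 --out runs/sim

# fit a calibration model from a references CSV
python examples/make_references.py refs.csv
dielmap calibrate --references refs.csv --out model.json

# permittivity map, segmentation and per-phase statistics
dielmap map --stack runs/sim/stack.tif --calibration runs/sim/calibration.json --out runs/map
dielmap segment --stack runs/sim/stack.tif --out runs/seg
dielmap stats --stack runs/sim/stack.tif --calibration runs/sim/calibration.json --out runs/stats.csv

# wetting mechanics from a contact-angle CSV
dielmap wetting --table angles.csv --out wetting.csv --trend-out trend.json
```

Input stacks are multipage/OME TIFF with the spectral channel as the
page axis; channel 0 is the bluest window. Every command writes a
machine-readable run log (configuration echo, seeds, thresholds).

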