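# Methods

## Lattice model

A microtubule wall is modelled as N protofilaments (PFs) on a cylinder of
radius R = N·w/2π, where w is the lateral centre-to-centre PF spacing and R
is the PF centre-line (wall mid-line) radius, consistent with w being
centre-to-centre. Monomers stack along each PF with rise a; laterally
adjacent PFs are offset by the intrinsic lateral rise δx, so the monomers
form an S-start helix (start numbers count monomers: a 3-start is 1.5
dimers, which is what makes a single seam arise in the B lattice).
Accommodation absorbs the closure mismatch S·a − N·δx into the PF tilt,

    tan θ = (S·a − N·δx) / (N·w),

the standard small-angle form; it differs from exact trigonometric closure
only at O(θ³) (≈0.007° at 3.5° skew; the test suite carries an explicit
bond-vector closure oracle for this). The projected moiré repeat is
L = w/tan|θ|, diverging for straight PFs, which is reported as an
"unbounded" result (`math.inf`) analytically and as a ">box" lower bound
when measured from an image.

Sign convention, used everywhere (model, generator, estimators): negative
θ = left-handed supertwist, so 14_3 accommodates to ≈ −0.76° and 12_3 to
≈ +0.89°. Realizing this together with a right-handed coordinate frame
forces the rising S-start monomer helix to be left-handed in the generator
(the rising lateral neighbour sits at decreasing azimuth); with that choice
the measured along-PF interface offset of a generated lattice equals the
intrinsic δx exactly at the accommodation skew.

Parameters and defaults (all configurable):

| symbol | meaning | default | rationale |
|---|---|---|---|
| a | monomer rise (nm) | 4.15 | canonical tubulin monomer spacing; d = 2a |
| w | lateral PF spacing (nm) | 5.15 | canonical MT lateral spacing; never printed in the source data, so it is the dominant uncertainty behind ~700 nm-scale moiré predictions |
| δx | lateral rise (nm) | 3a/13 | makes the canonical mammalian 13_3 lattice exactly unskewed |
| θ | PF skew (deg) | free | *not* forced to the accommodation value: measured skews (e.g. GMPCPP-grown 12-PF tubes) legitimately exceed the accommodation baseline |
| seams | A-lattice interfaces | S mod 2 | single seam for odd starts; parity invariant `#seams ≡ S (mod 2)` enforced |

## Synthetic generator

`build_lattice` places monomer (j, i) at z = (jS/N + i)·a·cosθ and azimuth
φ = −2πj/N + z·tanθ/R; the construction closes the cylinder exactly for any
θ (radial scatter < 10⁻¹⁵ nm), so every measurable quantity follows from
the generating spec. Monomer types alternate along PFs and shift across
A-lattice interfaces; the parity invariant guarantees the ring closes.
`decorate` flags one kinesin site per αβ-dimer (on the β monomer by
default), giving the 8 nm repeat and the A/B register its contrast, with
blobs placed 4 nm outside the wall radius.

Rendering uses isotropic Gaussian blobs (default σ = 1.5 nm) — subunit-scale
contrast only. Projection mode integrates along the view axis so both walls
superpose (the moiré mechanism); noise is additive white Gaussian
parameterized by SNR on the signal variance, with a mandatory seed for any
finite SNR. Defaults: 0.35 nm/px (tomogram emulation) and 0.139 nm/px
(single-particle emulation). Deliberately **not** emulated: missing wedge,
CTF, atomistic detail, bent/curved axes, dynamic ends. Passing the
round-trip tests therefore demonstrates the internal consistency of
geometry, generator and estimators — not robustness to those instrument
effects.

## Measurement operators

**PF number.** Transverse slabs (4 nm) are resampled onto an annulus at the
wall radius (radius from the sub-bin peak of the radial profile of the
averaged section; centre from the positive-intensity centroid). Angular
power spectra are summed over sections and the winning harmonic is searched
in 9..17, which also resolves integer-multiple harmonic ambiguity. The call
carries a confidence (top/second power ratio, threshold 1.5); below
threshold the result is "undetermined", not an exception.

**Moiré repeat.** The discrete subunit lattice does not recur at L (lattice
self-translations and fringe rotation coincide only at near-coincidences),
but the low-passed tube — continuous helical PF centre-lines — is exactly
L-periodic in projection. The image is therefore smoothed axially
(Gaussian, σ = 4.5 nm, which suppresses the 4.15/8.3 nm subunit lines by
≥3×10⁻³ while leaving ≥100 nm fringes intact), the z-invariant column means
are removed, and the normalized axial autocorrelation of the remaining
fringe signal is scanned for its first prominent local maximum (height
≥ 0.4, prominence ≥ 0.2 above the preceding decay; the earliest candidate
within 0.1 of the strongest is taken, since later candidates are period
multiples). Three-point parabolic interpolation gives sub-pixel precision.
If no such peak exists within the field of view the box length is returned
as a `LowerBound` — the ">1000"-style table entry. Long repeats need
proportionally long boxes; the tests size fields of view at ~2.5 expected
periods.

**Axial (layer-line) repeat.** Per-column axial spectra are summed in power
and the peak in the 7.5–9.0 nm band is refined on the continuous windowed
Fourier transform (coarse 4× zero-padded FFT, then bounded scalar
maximization), so precision at high SNR is limited by leakage, not bin
width (≈2×10⁻⁵ relative at 55 repeats, noiseless). A quality criterion —
fraction of windowed signal power at the peak (≈1/3 for a sinusoid, ≈1/n
for noise) — rejects featureless input. Caveat, verified numerically: in a
*fixed-frame projection* of a supertwisted MT the apparent layer line is
displaced by ≈ δx/L with the sign of the handedness, because the fringe
pattern hands over between PFs as it rotates. For skewed tubes the operator
therefore accepts the 3D volume and follows the decoration rows along each
PF (sampling the decoration shell along the drifting azimuth), which is
unbiased at any skew; the 2D spectral path is exact for unskewed tubes.

**Skew.** The phase of the N-fold angular harmonic of the wall annulus is
tracked per 4-nm slab; its fitted slope (weighted by harmonic magnitude,
ends trimmed by 8 nm because partially filled end slabs carry distorted
phases) gives dφ/dz and θ = arctan(R·dφ/dz). Accuracy on the generated
grid is ≤0.05°.

**Lattice type.** Decoration rows are located (a secondary radial ring —
a local maximum after a dip — outside the wall; a plain intensity threshold
would be fooled by the wall blobs' tails), sampled along each PF, and the
inter-row axial phase offsets at the dimer frequency are classified against
the B expectation (δx ≈ S·â/N, 3-start assumed by default and configurable)
versus the A expectation (the same ± one monomer rise) by circular distance.
Call rule over the N interfaces: ≤1 A interface → "B" (the canonical single
seam), ≤1 B interface → "A", otherwise "mixed"; undecorated input →
"undetermined".

**Summaries and statistics.** Percentages are rounded to integer percent
per condition (sum 100 ± 1). Axial-repeat statistics follow the
measurement-group convention: values are assigned round-robin to 3 groups
(configurable) and mean ± s.d. are taken over group means. Group
comparisons use Welch's unequal-variance t-test; degenerate zero-variance
inputs resolve to p = 1 (equal means) or the flagged p → 0 limit.

## Structure comparison

Residues are paired across species by global sequence alignment per chain
(BLOSUM62, affine gaps), never by residue numbering. Superposition is a
least-squares rigid fit on the paired atoms of a caller-supplied core
selection (e.g. a central β-sheet), Cα-only by default with an all-atom
option; RMSD maps report per-residue deviations after the fit, omitting
(and logging) unpairable residues. The inter-dimer rise is the axial
component of the displacement between dimer Cα centroids along the MT axis,
fit as a cylinder axis (radial-scatter minimization) when the model is a
full tube and required explicitly otherwise. Interface footprints replace
buried-surface-area analysis with a distance cutoff (default 4 Å, KD-tree),
optionally restricted to polar/charged residue types
(D,E,K,R,H,N,Q,S,T,Y,W) and side chains. Comparisons against the archived
deposited coordinate entries require those files to be supplied by the
user; the shipped tests validate the metrics on generated pseudo-atom
lattices (rise scenarios at 8.300/8.291/8.144 nm spacings) and hand-built
toy models against brute-force and Kabsch oracles.

## Problem sizes and numerical choices

The round-trip grid (N 11..15 × skew {0, ±0.4°, ±1°} × SNR {∞, 4, 2} × 3
noise seeds) uses 160 nm decorated volumes for PF number, skew, lattice
type and axial repeat, and undecorated projections of ~2.5 moiré periods
for the repeat measurement; the whole grid runs in ~4 minutes on one CPU.
Deterministic seeding throughout (`numpy` Generator; pipeline seeds spawned
from the run seed), so identical configs give byte-identical outputs. MRC
files are mode-2 MRC2014 with the voxel size in the Ångström cell header;
the exact pixel size and 2D axis convention are additionally carried in a
header label so round trips through the package reproduce `pixel_nm`
bit-exactly. Internal units are nm for lattices and images, Å for atomic
models, converted only in `mtarch.units` and `mtarch.mrcio`.

## Known limitations

* No missing wedge/CTF/bent axes in the generator (above); estimator
  robustness to those effects is untested by design.
* The 2D layer-line path carries the ≈δx/L supertwist displacement
  inherent to fixed-frame projections; use the 3D path for skewed tubes.
* Lattice-type calling assumes a 3-start register by default and requires
  decoration; it reports "mixed" for any seam count between 2 and N−2.
* The accommodation formula is the small-angle model; beyond ~5° skew the
  O(θ³) departure from exact closure becomes visible in the oracle.
* w and δx cannot both be pinned by a single observed moiré repeat; the
  defaults are the canonical values and are exposed in every config.
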