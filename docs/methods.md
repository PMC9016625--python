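# Methods

`gcmorph` quantifies the cytoskeletal architecture of neuronal growth cones
as it appears in cryo-electron tomograms: hexagonally bundled F-actin with
periodic crosslinks, two half-helical-repeat classes of filament, Arp2/3
branches, and microtubules (MTs) with their protofilament number, polarity,
lumenal particles, lattice defects and end morphologies.  Because cellular
tomograms of this kind are not publicly deposited, every operator is
validated against a ground-truthed synthetic scene generator that emulates
the imaging physics of single-axis cryo-ET.  This note records the models,
the parameters that matter, the numerical choices, and what passing tests do
and do not demonstrate.

## The synthetic scene model

**Density.**  All protein is rendered as isotropic Gaussian blobs of s.d.
`radius/1.5` and unit peak amplitude, deposited by trilinear interpolation
and convolved analytically (one FFT-free separable convolution per blob
class).  This is deliberate: every quantity measured here lives at the
nanometre scale (lattice spacings, repeat lengths, particle diameters), so
subunit-resolution blobs carry exactly the information the measurements
need and nothing more.  Consequences of this choice are flagged below where
they matter.

**Actin.**  A filament is a two-start long-pitch helix: subunits every
5.5 nm per strand at helix radius 2 nm, strands staggered 2.75 nm and
offset 180°, twisting `t` degrees per subunit so the apparent crossover
(half helical repeat) is `L = 5.5·180/t` nm.  Two generator classes are
built in: bare actin (`t = 26.68°`, `L = 37.1` nm, blob radius 2.5 nm) and
a cofilin-decorated class with a shorter repeat and wider appearance
(`t = 36.26°`, `L = 27.3` nm, blob radius 3.0 nm).  Axial phase offsets are
integer multiples of 5.5 nm, realized as a rotation by the twist angle
(helix equivalence), which is what makes the inter-filament subunit-offset
measurement meaningful.

**Bundles.**  Filaments sit on a 2D hexagonal lattice (constant 12.1 nm,
row pitch √3/2·a) in the plane perpendicular to the bundle axis, with
optional Gaussian positional jitter.  Crosslinkers are single fascin-scale
blobs (radius 2.5 nm, the size of a ~55 kDa protein) placed at the
inter-axis midpoint of adjacent filament pairs every 37.1 nm.  Modelling
the crosslinker as one compact globule rather than a rod matches fascin's
shape and makes its detectability independent of the exact pair gap.

**Microtubules.**  The wall is a continuous B-style helical lattice (the
seam is invisible at blob resolution): `n` protofilaments at equal
azimuths, monomers every 4.1 nm along each protofilament, neighbouring
protofilaments offset axially by 0.92 nm (the 3-start monomer helix).  The
outer diameter scales with protofilament number at fixed 4.92 nm lateral
spacing (25 nm at n = 13).  Lumenal particles are blobs (σ = diameter/3) or
8-blob rings; lattice defects remove monomers over an axial interval and a
protofilament span; ends are blunt, flared (terminal 16 nm displaced up to
+3 nm radially) or tapered (protofilament terminations staggered over the
taper length).

**Polarity in the density model.**  A subtle point discovered during
implementation: for radially symmetric subunit blobs the lab-frame lattice
is *identical* for the two polarities (the end-for-end flip maps the
lattice onto itself), and the depth-rotation of the 3-start helix is a
flip-invariant pseudoscalar — so no measurement of such a shaft could ever
read polarity.  Real microtubule walls are not radially symmetric: the
tubulin surface decorates outward with a fixed handedness relative to the
dimer orientation.  The generator therefore gives each subunit a weaker
outer-surface lobe (amplitude 0.4, 1.8 nm outside the wall centre)
azimuthally offset by `wall_skew` (default 12°), anticlockwise when viewed
from the plus end.  This is the feature the rotational-average "slew"
reads out.  The 12° magnitude is a free generator parameter chosen to give
a clear but sub-protofilament-spacing skew; the sign convention is fixed by
recovery tests, not asserted as absolute truth.

**Imaging physics.**  The missing wedge is applied as a binary Fourier
sector mask: a tilt series about x over `[tilt_min, tilt_max]` samples the
spatial frequencies with `atan(kz/ky)` inside the tilt range
(central-slice theorem); everything else is zeroed.  The zero-frequency
term always survives, so total density is conserved.  No CTF or discrete
projection model is included — the wedge is the dominant cryo-ET artefact
for the morphometric quantities targeted here.  Noise is additive white
Gaussian; the default s.d. of 0.33 gives blob-peak SNR ≈ 3, comparable to
the visual quality of 4×-binned cellular tomograms.  A fixed seed makes a
scene byte-reproducible.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: CTF oscillations and defocus gradients,
reconstruction artefacts from discrete tilts, crowding by membranes,
ribosomes and unrelated filaments, curved and locally distorted lattices,
centerline localization error (measurement operators receive centerlines as
input), and the true atomic-scale contrast of tubulin and actin.  Recovery
rates measured here are therefore upper bounds on real-data performance;
the value of the tests is that they verify the *operators* implement their
definitions correctly under the dominant cryo-ET degradation.

## Measurement operators and numerical choices

**Half helical repeat.**  Density is sampled on 16 lines parallel to the
centerline (radii 2 and 3 nm, azimuths every 45°); as the two strands
revolve, each line's intensity peaks once per crossover.  The period is the
dominant peak of the mean windowed periodogram (Hann window, 4× zero
padding, parabolic refinement) within 20–50 nm.  A peak below
`2 + 3/√n_lines` times the median band power counts as no periodicity: the
null maximum of a periodogram is ~5–7× the median for one trace but
concentrates as independent line spectra are averaged.  Classification
windows are 33–42 nm (bare) and 23–31 nm (cofilin-like) with a dead zone;
nothing is force-assigned, mirroring the observed bimodal population with
no intermediates.  Sampling lines avoid the beam direction, where the wedge
degrades contrast.

**Crosslink spacing.**  Detection runs on a matched-filtered volume
(smoothed with the 1.7 nm crosslinker kernel, which shrinks white noise
~14×).  The midline profile between two roughly parallel filaments is
baseline-corrected with a 15 nm median filter — the missing wedge prints
*negative* sidelobes around filaments, and the baseline absorbs them —
and peaks must exceed both 3.2× the profile's robust noise s.d. and 18% of
the on-axis filament density.  Pairs whose centre gap falls below 9.5 nm
(surfaces within a crosslinker length) raise an error rather than returning
garbage: discrete bridges are physically unresolvable there.  A residual
limitation: for pairs separated along the beam axis the wedge smears the
filaments into the midline and weakens bump contrast, so occasional missed
crosslinks appear as doubled spacings in dense 3D bundles; spacings along a
single crosslinked sheet (the geometry of the published measurement) are
recovered to ±1 nm.

**Hexagonal lattice statistics.**  Inter-filament distances use distance
shells on the cross-section point set: nearest-neighbour pairs within
1.3·â (short axis) and the second shell within [1.50, 1.95]·â (long axis,
≈√3·a, excluding the 2a third shell), with â the median nearest-neighbour
distance.  The ψ₆ bond-orientational score averages over interior points
(six nearest neighbours all within 1.6·â); 0.75 is the hexagonal flag
threshold.  Bundle width/height are filament counts after rotating into
the lattice frame (row direction from the ψ₆ phase, disambiguated by the
principal axis) and clustering row coordinates at pitch √3/2·â with a
circular offset estimate.

**Branch angles** are measured purely from centerline geometry: total
least-squares tangents over 20 nm windows on each side of the junction
(snap radius 5 nm), angle between the parent's through-going direction and
the child's outgoing direction.

**Protofilament number.**  A 30 nm transverse slab is resampled onto a
cylindrical grid (the wall radius is estimated per MT from the radial
density peak, so binned or rescaled volumes work).  The wedge imprints a
2-fold amplitude envelope on the wall's angular ripple, which throws
deterministic sidebands at n±2 around the true order — about half the peak
height, enough to defeat a naive dominance rule.  The statistic is the
product of the raw angular spectrum and an envelope-flattened spectrum
(ripple high-passed, analytic-signal envelope smoothed to orders ≤4 and
divided out); the protofilament count is the dominant order in 9–16, and
the call is indeterminate unless that peak exceeds the next order and
towers 120× over the high-order floor.  Measured margins: genuine 12/13/14
lattices sit ≥400× above the floor, featureless rings and noise ≤50×.

**Polarity.**  The slew of the rotationally averaged cross-section is
quantified as the slope of the n-fold ridge azimuth against radius between
lumen and outer wall (amplitude-weighted fit).  Anticlockwise-outward slew
toward the viewer means the plus end faces the viewer.  Two gates guard the
call: the fitted slope must exceed 3× its standard error *and* 0.015
rad/nm — the anisotropic wedge PSF alone imprints drifts up to ~0.008
rad/nm on a perfectly achiral wall, so smaller slews are not interpretable.

**Moiré filtering.**  The longitudinal projection is band-pass filtered
with the origin masked; the fringe period is the dominant transverse
periodicity in 3–8 nm.  At blob resolution the projected protofilament-line
contrast is heavily attenuated (~25×), so the fringe period serves as a
lattice fingerprint — present for real walls, absent for noise,
reproducibly distinct between protofilament numbers — while the
protofilament estimate attached to the output comes from the measured wall
circumference at the canonical 4.92 nm lateral spacing.

**Ends.**  Wall occupancy (fraction of 26 angular sectors above 40% of the
intact median) is tracked toward each terminus; the taper length runs from
the last fully occupied position to the end of any lattice density, with
>50 nm classed tapered, ≤8 nm blunt, and intermediate values curved.
Flaring is a ≥0.8 nm outward shift of the terminal wall radial peak
relative to the shaft (fine radial grid, parabolically refined); the
generator's flared and blunt ends separate at 1.4–1.7 vs ±0.25 nm on this
statistic.

**Lumenal particles.**  Local maxima of the smoothed lumen (centres within
6 nm of the axis, so the inner wall tail cannot masquerade as particles;
wall-touching particles still count) above a threshold set from the
background outside the MT plus a floor of 25% of the wall peak, merged
within 4 nm; ring particles contribute several annulus maxima that are
clustered by axial position.  Diameters of globular particles are measured
from the *axial* profile — the wedge mask is independent of the axial
frequency, so the axial blob shape is undistorted, whereas in-plane
profiles acquire narrowed shoulders — by a bounded Gaussian fit over a
5×5-voxel transverse patch average (separability preserves the axial shape
exactly while suppressing noise), inverted with the generator's blob
convention d = 3σ.  Ring diameters are twice the outer half-max radius of
the in-plane annulus.  Noiseless recovery is exact; under default noise and
wedge the population mean is recovered to better than 0.1 nm.

**Defects.**  The per-slice minimum over 26 wall sectors (each integrating
two angular subsamples and the full radial band, smoothed 6 nm axially) is
thresholded with hysteresis: intervals seed where the minimum drops below
30% of its own intact baseline (its 75th percentile, stable even when a
600 nm defect occupies half the MT) and extend below 55%.  The deep seed is
essential at scale: a single moderate threshold false-alarms ~0.45/µm over
long MTs because of the extreme-value tail of the sector minimum, whereas
the hysteresis detector makes zero false calls on ~80 µm of intact control
and still catches single-dimer (8.2 nm) gaps spanning three protofilaments.
Lengths are measured at half depth between the local intact baseline and
the dip minimum (unbiased for any gap depth) and quantized to whole dimers;
16 nm splits small from large.  Flanking protofilament counts and polarity
reuse the rotational-average machinery 30 nm outside each defect.

## Statistics

Super-plot summaries report every item value, per-tomogram means, the
overall mean ± s.d. across items (the convention matching the printed
sample sizes) and, separately, the s.d. across tomogram means, so either
aggregation convention is recoverable.  The Mann–Whitney U test is exact by
complete enumeration of rank arrangements with mid-ranks for ties up to
combined n = 25 (tomogram-level comparisons are far smaller); larger
samples fall back to the flagged normal approximation.  The outlier rule
for frequency comparisons is a Tukey fence at Q3 + 3·IQR within each arm,
with 'nearest' quartiles so that tiny samples are not fenced by
interpolation toward their own extreme; reports always carry the p-value
with and without flagged outliers.  Mass conversion uses the minimal
anhydrous protein sphere R = 0.066·M^(1/3) nm; lumen occupancy treats each
8.2 nm of a 15 nm-bore lumen as a cylinder holding the measured frequency
of mean-diameter spheres.

## Problem sizes and reproducibility

All simulations run at 1 nm voxels (binned-tomogram scale; the generator
supports the native 0.538 nm sampling) with the ±60°/3° wedge and default
noise unless a test needs the noiseless control.  The defect-rate
experiment uses 2000 µm of synthetic MT in the reproduction script and
984 µm in the test suite — at the 1-per-20 µm rate the reported mean
length per defect is a Poisson draw whose relative s.d. is ~10% and ~14%
respectively, which dominates the error budget since detection is exact on
these populations.  Particle-diameter recovery uses ~390 drawn particles.
Every stochastic step takes an explicit seed, and a fixed seed reproduces
scenes byte-for-byte.

## Known limitations

Centerlines are inputs, not outputs: no de novo filament tracing.  The
polarity sign convention and the wall-skew magnitude are generator
conventions validated by recovery, not measurements of nature.  Crosslink
detection degrades for filament pairs separated along the beam axis (wedge
smear) and refuses pairs in near-contact.  The moiré fringe period is a
fingerprint, not a quantitative protofilament readout, at blob resolution.
The mass conversion reproduces the ~200 and ~1400 kDa anchor points of the
sphere law but gives ~26 kDa (not 15 kDa) for the smallest 3.9 nm
particles; the exact conversion used for that lower bound is not
recoverable from the sphere relation alone.
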