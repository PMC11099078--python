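# Methods

This note records the models, conventions, defaults and numerical choices
behind `mig`, and what the synthetic validation does and does not show.

## Coordinate models and annotation

Atomic models are ordered atom records (element, atom/residue naming,
chain, position in Å, mass in Da) read from PDB/mmCIF via gemmi; hydrogens,
alternate locations beyond `A` and zero-occupancy atoms are dropped, since
cryo-EM depositions rarely define them consistently.  Biological roles are
attached through a YAML sidecar (`SpokeMap`): chain → spoke index 1–14 and
component (γ-tubulin or GCP2–6), and chain → protofilament index.  Because
deposited models name chains arbitrarily, the sidecar is the single source
of role information; the synthetic generators emit matching sidecars.
Protofilament species (α/β) and layer may be given per chain or carried by
residues (names `ATB`/`BTB`, residue number = layer counting from the minus
end); one chain per protofilament with residue-level species is the
generator's convention, since one chain per monomer cannot be written to
single-character PDB chain IDs.

Centres of mass default to mass weighting (a `geometric` mode exists for
sensitivity checks; for the equal-mass marker atoms of the synthetic
assemblies the two coincide).  Superposition is closed-form least squares
(Kabsch) with a reflection guard: the sign of the smallest singular vector
is flipped when the determinant of the candidate rotation is negative, so
the result is always a proper rotation.  Internal units are Å throughout;
nm values appear only in reports.

## Synthetic assemblies — what they emulate

The generators define the study conditions for every validation in this
package.

**Lattice.** An N-protofilament wall (default N = 13) with monomer repeat
41 Å and start number 3.  The lateral rise is derived, not free:
`3·41/N` Å (9.4615 Å at N = 13, i.e. the canonical value at two-decimal
rounding), so the lattice closes exactly.  Default radius keeps the
inter-protofilament chord at 52 Å (≈ 108.6 Å at N = 13).  Each monomer is a
centre marker plus two lateral contact markers placed so facing markers of
adjacent protofilaments sit exactly `contact_gap` = 5 Å apart at matching
height in the unperturbed wall; the tangential marker offset
`(chord − gap) / (2 cos(π/N))` makes this exact, including across the
cyclic closure interface.  The seam is built by shifting the α/β register
of the walls beyond `seam_index` by one monomer; with an odd start number
this yields exactly one heterotypic interface at any chosen position
(the closure interface carries the register swap when `seam_index = N`).
Positional noise is a seeded rigid Gaussian offset per monomer.

Non-13 walls carry a supertwist of `0.3°·(13−N)` per 41 Å layer (a ~5–7 µm
pitch at N = 12/14, the magnitude reported for such walls), so projections
show Moiré transitions; 13-protofilament walls are straight.  The value is
a documented convention, not a fitted constant.

**Ring.** 14 spokes, each an exact rigid copy of a canonical spoke (γ
marker with the Thr145/Tyr152 anchor residues, GCP body with per-GCP anchor
residues at a fixed spoke-local offset).  The closed template is the
MT-compatible helix (Δφ = 360/13°, Δz = 9.4615 Å, spoke 14 in-plane on
spoke 1); the open template spreads the same spokes so the spoke-1/14
in-plane separation is `open_separation` (default 47 Å, the open-state
value).  Intermediate closure interpolates spoke positions *linearly in
Cartesian coordinates*; because the closed template puts spoke 14 exactly
over spoke 1, the separation is then `(1−closure)·open_separation`
identically, which the closure analyses exploit as an exact oracle.
GCP identities follow the vertebrate spoke order (GCP2/3 alternating on
spokes 1–8, then GCP4, 5, 4, 6, 2, 3).

**Density maps and projections.** Maps are sums of isotropic Gaussians with
peak amplitude equal to the atomic mass (molmap convention; map integral
`Σmᵢ(2π)^{3/2}σ³`), truncated at 6σ.  Projections are analytic 2D splats
with the same total.  `depth_blur` widens footprints linearly with depth
along the view axis (integral preserved), emulating the defocus gradient
that makes the far wall of a filament blurrier than the near one — without
it an even-N wall projects exactly mirror-symmetrically (antipodal
protofilament pairing) and no left/right Moiré asymmetry can exist.

**Profiles.** Per filament: unit lattice baseline scaled by `enrichment`
within `end_window_um` (0.6 µm) of the anchor, Gaussian noise, a Gaussian
γ-TuRC peak at the anchor, 0.13 µm sampling, 8 µm length, 69 filaments in
3 replicates by default.  Ground truth rides along with every object.

What passing on these conditions does *not* show: robustness to CTF and
ice artefacts in real micrographs, to atomistically realistic tubulin
density (markers are 3 atoms per monomer), to non-Gaussian fluorescence
background, or to mis-annotated chains.

## Ring geometry

The axis is the total-least-squares line (SVD of the centred points)
through the four anchor centroids over spokes 1–13, oriented from the mean
of the GCP centroids toward the mean of the γ centroids.  With four
non-collinear centroids a best-fit line is required; TLS is symmetric in
the anchors and deterministic.  Fewer than two distinct centroids or a
spread under 1 Å raises a degenerate-axis error.  The azimuth reference is
the spoke-1 γ-tubulin direction, so cylindrical outputs are equivariant
under joint rigid transforms.

By convention the axis used for closure and per-spoke reports is fitted on
the hypothetical fully closed reference built from the model (each spoke
rigid-body superposed onto the closed template), since the closed
conformation defines the reference frame for all states; this also removes
the spurious axis tilt an open spiral induces.  Closure separation projects
the spoke-1/14 γ centres onto the plane normal to that axis.  Distances to
the closed reference are 3D Euclidean distances between matched γ centres
after aligning on spokes 3–9 (where conformational changes are minimal) in
coordinate space — a map-space route (`model_map_correlation` +
`dock_rigid_body`) exists for cross-checking; the marker superposition
substitutes for docking into a simulated 10 Å map and is exact on rigid
subunits.

Model-vs-map correlation is Pearson over voxels within 3σ of any atom,
between the map and a same-grid simulation.

## Lattice building

`dock_rigid_body` searches a translation grid (default ±3 Å, 1 Å step per
axis) times a rotation grid about a chosen axis, then refines each
translation axis by quadratic interpolation through the three surrounding
samples (rejected if the vertex is not a maximum or the refined pose scores
worse).  Poses that leave the map score −1; a best correlation below 0.2 is
a no-fit error.  Docking assumes per-protofilament segmented density; in an
unsegmented multi-protofilament map, neighbouring density can bias the peak
by more than half a grid step.

`optimize_contact_rotation` sweeps protofilaments in ascending order; on
the first sweep each minimizes the mean facing contact-pair distance to its
already placed lower-index neighbour, thereafter to both cyclic neighbours
(at the exact register the two single-sided biases cancel by the mirror
symmetry of the contact markers, making the register the fixed point).
Facing pairs farther than half a monomer repeat (as above the 3-monomer
offset of the closure interface) are excluded from the mean.  Each 1D
minimization is a 1° coarse grid (ties toward the smallest |angle|)
followed by bounded scalar refinement at `tol/20`; the sweep loop stops
when no protofilament moves more than `0.1·tol` (so accumulated angles
settle well inside the reported 0.01° tolerance), and 100 sweeps without
convergence is an error.

`axial_register` scans ±60 Å (covering > one 41 Å monomer repeat) at 1 Å
steps; local correlation maxima above half the global maximum seed a
simultaneous least-squares fit of K Gaussians plus a constant baseline.
The chosen shift is the mean of the highest-amplitude Gaussian — amplitude
is the natural maximum-correlation criterion — with a `nearest` mode
selecting the Gaussian closest to the docked position for use inside
pseudo-periodic maps where the registers tie; both choices are recorded in
the returned profile.

The MT axis for the lattice metrics is the TLS line through per-layer
anchor centroids (α-tubulin Gln15 in atomistic models; the centre markers
otherwise).  Per-protofilament radius is the mean in-plane distance of its
subunit centres; γ–α offsets are in-plane distances between a spoke's γ
centre and the first α-tubulin of its protofilament (protofilament i
corresponds to spoke i+1).  Recovery oracles pass the generator's true
axis, since a displaced protofilament also moves a freshly fitted axis.

## Seam register arithmetic

Heights are reduced to per-protofilament residuals: base height = median of
(height − (layer−1)·repeat), minus the helical ramp of one lateral rise per
protofilament, with the offset fixed by the median over the non-focus
protofilaments (the regular distal lattice defines the register).  Relative
to a neighbour, homotypic registers repeat every dimer (82 Å) and the
heterotypic (seam) register sits one monomer away — except across the
cyclic closure interface of an odd-start lattice, where the built-in
3-monomer offset swaps the two register classes.  This parity bookkeeping
is why the two seam options of one protofilament need movements differing
by about one monomer repeat rather than a common value modulo 41 Å.
A neighbour whose own residual is off-register by more than 2 Å is assumed
to first make its own movement (reported separately as a prerequisite,
snapped to the nearest regular register).  Movements are reported as
magnitudes with signed values alongside.

Contact classification takes the minimal facing contact-pair distance per
cyclic interface; above the threshold (default 12 Å between contact
markers, configurable, with the exceedance reported so sensitivity is
auditable) the interface is a gap, otherwise the species of the closest
pair decide homotypic vs heterotypic.  The minus-end pitch is the median
axial offset over non-gap interfaces (robust to single outliers).  Seam
prediction: one heterotypic interface → the seam; one protofilament
isolated by gaps on both sides → both flanking interfaces ranked by
required movement; anything else → an explicit ambiguous status.

## Protofilament counting

References are projections of the generator's walls for each candidate N
(default 11–16) at 4–5 rotations covering one azimuthal asymmetric unit,
low-pass filtered with a Gaussian of FWHM 15 Å, rendered at 5.08 Å/px.
Segment scores are the maximal normalized cross-correlation over all
in-plane shifts (skimage `match_template`) and the rotation grid; NCC makes
labels invariant to intensity scale and offset, and exact ties are reported
as ambiguous rather than broken arbitrarily.  This 2D matched-projection
scoring is a desk-scale analogue of supervised 3D classification against
pf-number references: the decision rule (maximum similarity to a rendered
reference) is the same; alignment subtleties of 3D refinement are not
modelled.  Consensus per filament is the plurality label; dataset fractions
carry the binomial standard deviation `sqrt(p(1−p)/n)` — the natural
reading of an error bar centred on a fraction of n filaments.

The Moiré filter keeps a centred rectangle of the 2D spectrum (default
half-widths 6 px along the axis — passing only beat periods longer than the
monomer repeat — and 24 px across; the exact mask is a config parameter)
and returns the real inverse transform.  A Tukey taper (`apodize`)
suppresses the ringing the hard mask produces at abrupt filament ends.
Transitions are counted as sign flips of the median-detrended left/right
intensity asymmetry along the axis, thresholded at 0.3% of the mean row
intensity with 20% of the rows trimmed at each end: straight 13-pf walls
give a machine-flat residual (zero flips), supertwisted walls oscillate two
orders of magnitude above the threshold.

## Profile statistics

The minus-end anchor is the argmax of the γ-TuRC channel after a 3-sample
moving average.  Extraction samples a spline through the polyline vertices
(cubic where ≥ 4 vertices, lower order otherwise) at equal arc-length steps,
averaging 3 perpendicular bilinear samples; the per-filament background is
the mean along a parallel polyline offset by 8 px (the opposite side is
used if that exits the image), subtracted per channel.  Normalization
divides the probe channel by its mean lattice intensity (outside the end
window), per filament or pooled per replicate.  Aligned averages put the
anchor at 0 and use t-based 95% CIs with the per-position n.  The end test
partitions *samples* by distance to the anchor (matching sample-level
counts; a per-filament aggregation mode exists) and applies Welch's
unequal-variance t with Satterthwaite degrees of freedom, one-tailed with
the alternative fixed as end > lattice.  The enrichment ratio CI is a
delta-method interval on the ratio of the two group means.

## Validation problem sizes

The test-suite and acceptance-script simulations use: 100 seeds for axis
recovery and for each seam-recovery condition (noiseless and σ = 2 Å);
13 protofilaments per docking/rotation recovery; 5 shifts for axial
registration; 200 segments per classification condition (50 per candidate
N at random rotations; signal-to-noise 0.5 defined as noise variance twice
the signal variance); 100 seeds × 3 enrichment levels for unbiasedness,
500 null seeds for the type-I rate, and 20–69 filaments per profile set.
These sizes give stable Monte-Carlo estimates while keeping a full run in
the minutes range on one CPU.

## Known limitations

* Marker subunits are rotationally sparse: docking rotation grids finer
  than the marker geometry supports add no information.
* The supertwist convention and `depth_blur` are generator conventions;
  absolute Moiré periodicities of real micrographs are not calibrated.
* Global mirroring flips the sign of twist and of signed axial offsets;
  all other reported metrics are mirror-invariant.
* `mig reproduce paper-targets` requires user-supplied deposited models;
  the package never downloads data, so those measurements run only when
  the files are present (the measurement code paths themselves are
  validated on synthetic stand-ins with injected ground truth).
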