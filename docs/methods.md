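# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying procedure was
originally manual.

## Imaging model and containers

All images are `(T, Z, C, Y, X)` stacks with a physical calibration. The
default calibration is 0.1 µm/pixel laterally (a typical 100× objective
with an sCMOS-class camera; the acquisition descriptions specify the
objective but not the pixel pitch), 0.2 µm z-steps and 5 s frame intervals.
Stacks round-trip through OME-TIFF with calibration and channel roles
(`mito`, `er`, `drp1`, `mfn1`, `ddfp`, `native`, `converted`) in the OME
metadata. Pixel coordinates are 0-based `(row, col)`; ROIs are specified by
a pixel origin and a physical size and are half-open after conversion.
Unknown on-disk axis orders are rejected rather than guessed.

## Synthetic-microscopy generator

The generator emulates the three acquisition types the analyses consume:

* **Constriction z-stacks** (`SceneParams.constriction_stack`): one
  timepoint, 12 slices at 0.2 µm; mitochondria + ER channels; 60% of ER
  crossings carry a constriction.
* **Puncta movies** (`SceneParams.puncta_movie`, `node_movie`): 2 min at
  5 s intervals; machinery-puncta channels. Control values: Mfn1 density
  0.30/µm, Drp1 crossing occupancy 0.47, node density 0.34/µm. Mfn1-density
  and node scenes are separate acquisitions, mirroring separate
  transfection experiments.
* **Photoconversion movies** (`SceneParams.photoconversion_movie`): 5 min
  at 5 s intervals; native + converted OMM-label channels; control event
  rates 0.19 (tip-to-middle fusion), 0.06 (tip-to-tip fusion) and 0.17
  (fission) per mitochondrion per minute.

**Geometry.** Mitochondria are smooth random polylines (4–8 µm; tube radius
0.15 µm) placed with pairwise clearance and a self-clearance check that
forbids hairpins (legs closer than 0.8 µm would render as one blob). ER
tubules span the field edge-to-edge; crossings are exact polyline
intersections (computed with shapely). The photoconversion scene is sparser
(26 µm field, 2.8 µm clearance) because partners must be able to approach
the followed mitochondrion through resolvable space.

**Constrictions** are multiplicative Gaussian dips in tube radius
(minimum factor 0.3–0.5, width 0.25 µm) centred at ER crossings. The
matrix marker fills the tube volume, so emitters per unit length scale with
the radius factor squared and a radius factor *f* renders as a centreline
intensity dip of at least 1 − *f*² — deeper than the 40% calling threshold
for every programmed site.

**Puncta** are diffraction-limited Gaussian spots anchored to filament arc
positions. Same-role puncta keep a 0.45 µm hard-core minimum separation:
the scored quantity is a count of resolvable, discrete structures, and two
emitters closer than the diffraction limit would not be countable by any
method (or by eye). Transient puncta (2-frame lifetime) are added at a low
density to exercise the persistence filter.

**Events.** Event times are homogeneous Poisson with intensity
rate × n_mito (per minute). Fusion partners enter the field three frames
before their event, resting with their tip 1.1 µm from the chosen contact
point, and dock by instantaneous tip extension — the donor never
translates, so every pre-dock pixel stays inside the docked footprint and
overlap tracking follows it through the merge. The merged object
equilibrates the converted label within one frame, matching scoring by
fluorescence mixing. Tip-to-tip events dock at a free tip of the converted
lineage; tip-to-middle events dock on its mid-body, with exclusion margins
around existing tips (1.8 µm), junctions (1.0 µm) and previous dock sites
(1.2 µm) so the event class is unambiguous at the classifier's 0.5 µm
scale. Fission splits a naive filament at mid-length with 0.65 µm
retraction per daughter so the masks separate. Contacts are only placed on
material that joined the lineage at least two frames earlier, because the
classifier reads the pre-event geometry. Events that cannot be realised
after bounded retries are dropped from the realised schedule with a warning
(≲10% at control rates); ground-truth rates are recomputed from the
realised list. Optional kiss-and-run contacts dock for two frames without
label transfer.

**Optics and noise.** Channels render by splatting Gaussian line/point
sources (PSF σ 0.15 µm added in quadrature with the tube cross-section),
scaled by 2000 counts per unit density over a 100-count background, with
Poisson shot noise and 3-count Gaussian read noise; z-stacks attenuate
axially with a 0.35 µm Gaussian focus profile. These SNR values are
declared choices — the source acquisitions publish no intensity statistics.
Everything derives from one integer seed.

## Morphology

Thresholding is Otsu's criterion (strictly-above threshold); particle
analysis uses 8-connected components with a 5-pixel minimum size. Mean area
per mitochondrion = total foreground area in the ROI / number of qualifying
objects intersecting the ROI, and errors explicitly when the count is zero.
Skeletons come from topological thinning with junction-pixel clustering
(adjacent junction pixels are one node), spur pruning (default 0.3 µm) and
4-/8-step path lengths. `skeleton_length_with_tips` adds the
distance-transform value at each endpoint, recovering the length a line
drawn end-to-end would measure (the medial axis stops about one half-width
short of each tip).

## Contacts and constrictions

A **crossing** is a maximal run of mitochondrial-skeleton pixels inside the
ER mask, with two robustness rules beyond the plain definition: runs
separated by less than 0.3 µm of skeleton merge (mask noise splits
crossings), and the ER mask must appear on both sides of the mitochondrial
axis near the run midpoint (an annulus test, 0.25–0.8 µm) — a tubule
grazing one flank is a touch, not a crossing. Runs longer than 1.0 µm
(ER travelling along the organelle) are unresolvable and leave all
denominators.

**Line profiles** sample one value per path pixel with bilinear
interpolation, per z-slice for stacks. The **dip caller** smooths with a
3-sample moving average, finds strict local minima, takes the larger of the
two flanking local maxima as the reference peak (profile boundary samples
count as peaks when they exceed their neighbour — a drawn line scan starts
and ends on bright regions), and calls a constriction when
1 − I(min)/I(peak) ≥ 0.40. Multi-slice input requires the dip in at least
2 adjacent slices within 0.3 µm ("several z-planes" operationalised).
Calls are scale-invariant by construction.

`analyze_constriction_stack` works on a configurable z-projection (max by
default). The skeleton mask uses hysteresis thresholding (Otsu seeds, a
background + 3×MAD low floor) plus light closing so the centreline stays
continuous through dim constrictions — exactly what a scientist tracing the
organelle does. Crossings within 0.7 µm of a line-scan end are flagged
unresolvable: a dip can only be scored between two flanking peaks, so such
crossings are unscorable and leave numerator and denominator together. The
readout is the fraction of resolvable crossings with a call within 0.5 µm;
adjacent calls at one crossing count once.

**Overlap** is the Mander's-style fraction |A ∩ B| / |B| with B fixed to
the mitochondrial mask ("percentage … over total mitochondrial area");
masks default to per-channel Otsu when no manual threshold is supplied.

## Puncta

Spots are scale-space (Laplacian-of-Gaussian) blob maxima with a robust-SNR
floor (peak ≥ 5 × MAD noise) and weighted-centroid sub-pixel refinement.
Frame-to-frame linking is greedy nearest-neighbour within 0.4 µm; "present
throughout the movie" is relaxed to ≥ 80% of frames because strict 100% is
unattainable under shot noise. Puncta assign to the mitochondrial network
within 0.5 µm of the skeleton; densities divide by the tip-corrected
skeleton length. The crossing-occupancy readout matches puncta to
resolvable crossings within 0.3 µm (≈ the diffraction limit; no numeric
radius is stated in the original procedure). A **node** is a one-to-one,
nearest-first matched Drp1–Mfn1 pair within 0.3 µm — one Mfn1 punctum can
never validate two Drp1 puncta — making node density symmetric in the two
channels.

## Dynamics

Per-frame Otsu segmentation of the native (total OMM label) channel feeds
overlap-based tracking: objects link when their pixel overlap is at least
30% of the smaller object; one-to-many topology records a split,
many-to-one a merge. Note the generator renders the native label on
converted mitochondria too (green-channel depletion after photoconversion
is not modelled), so segmentation sees every object.

**Fusion**: the photoconverted source is the highest converted-channel
object at frame 0. At each merge of a converted with an unconverted track,
fusion is confirmed when the mean converted intensity over the unconverted
partner's pre-merge footprint reaches 10% of the donor's mean within three
frames — transient (kiss-and-run) contacts never transfer label and are
rejected. The mixing threshold is a declared stand-in for a visual
criterion and is calibrated against the simulator. **Fission** is a split
whose daughters persist ≥ 3 frames (15 s) without re-merging with each
other; a daughter that itself splits or merges again still counts as
persisting, and splits of objects born from a merge fewer than 3 frames
earlier are treated as transient contacts. Events within one frame of the
movie boundaries are excluded.

**Classification** reads the last frame at which both partners were
separate. The contact is localised from the newly grown material bridging
the partners at the merge frame (falling back to the closest mask
approach), and each partner's distance-to-tip is measured *geodesically*:
the contact snaps to the nearest centreline pixel and the shortest
along-skeleton path to an endpoint is computed. Euclidean distance to
endpoint pixels fails systematically because masks overshoot blunt tips by
about the tube half-width while the medial axis stops short of them.
Tip-to-tip requires both partners within 0.5 µm of an end; a donor tip on
the acceptor's mid-body is tip-to-middle; anything else is tip-to-middle
with an `atypical` flag. Classification skeletons are pruned at 0.8 µm
because junction blobs in merged objects grow thinning artifacts whose
endpoints would mimic tips.

**Rates** divide event counts by (first-frame mitochondrion count ×
minutes); the denominator choice is logged and configurable in principle —
objects appearing later (incoming fusion partners) do not change it. Class
rates sum exactly to the total fusion rate.

## Statistics

More-than-two-group comparisons use one-way ANOVA with Tukey's HSD
(studentized-range distribution, via scipy); two groups use the two-tailed
Student's t (equal-variance by default, Welch behind a flag). Zero total
variance returns F = 0, p = 1 by convention. Violin summaries report n,
median and linear-interpolation quartiles. Stars follow ns, \*\*p<0.01,
\*\*\*p<0.001, \*\*\*\*p<0.0001; p-values between 0.01 and 0.05 print as
"ns" because no single-star level is defined in that convention. LFQ
enrichment averages replicate intensities per condition, ranks by WT/mutant
ratio, floor-imputes missing values at half the smallest positive intensity
in the table and flags proteins detected in only one condition; the ranking
is invariant to uniform rescaling.

## What passing tests do and do not show

The simulator provides tubular organelles with stationary geometry between
events, instantaneous docking, uniform labelling, and spatially uniform
noise. It does not model organelle motility, photobleaching, axial PSF
asymmetry, out-of-focus haze from a dense 3-D network, or green-channel
loss after photoconversion. Recovery of programmed parameters therefore
demonstrates that the quantification rules are implemented correctly and
are robust to realistic shot noise — not that they are robust to every
artefact of live-cell data. Problem sizes in the test-suite and acceptance
runs (30 synthetic cells per readout, 5-min movies with ~6 scored
mitochondria each) were chosen to give a few hundred scored objects per
readout, comparable to the per-condition cell counts in typical live-cell
studies. A dense ER field (8 tubules per 15 µm) reflects the ~1–2 µm mesh
of the peripheral tubular ER and yields a realistic number of scoreable
crossings per cell.

## Repository shape

The package is a library: the importable API plus `examples/` narrative
scripts are its interface, and the per-stage workflows
(`analyze_constriction_stack`, `analyze_puncta_movie`, `score_movie`) are
the entry points a shell wrapper would call. No console script is shipped.

## Known limitations

* Fusion scoring requires the photoconverted lineage to participate;
  events between two unlabelled mitochondria are invisible, as in the
  underlying assay.
* The realised event schedule can fall short of the scheduled one when the
  field is too crowded to place a partner (dropped with a warning); rate
  recovery is validated against the programmed values including this loss.
* Constrictions at organelle tips cannot be called (no flanking peak) and
  are excluded as unresolvable rather than counted as negative.
* 2-D geometry with a Gaussian axial focus profile; no volumetric
  skeletonisation or 3-D tracking.
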