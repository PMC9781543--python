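# Methods

## Scope and model

The package estimates three kinds of quantity from systematically sampled
serial sections: region volumes (Cavalieri point counting), particle
numbers (optical fractionator), and fiber lengths (Spaceballs). All three
are *design-based*: their unbiasedness comes from the randomized sampling
design (a uniform random grid offset, a uniform random starting section),
not from any model of the tissue. The companion simulator supplies tissue
whose ground truth is known by construction, so every estimator is
validated by parameter recovery rather than against opaque reference
software.

Coordinates are µm throughout, right-handed, with z the cutting
(rostro-caudal) axis; sections are indexed 0-based from the rostral end
over half-open intervals `[z0 + i·t, z0 + (i+1)·t)`, so no point can be
assigned to two sections. Millimetre and metre units appear only at the
reporting boundary (conversions are centralized in `units.py`:
10⁻⁹ mm³/µm³, and 10³ (m/mm³) per µm⁻² of length density).

## Synthetic tissue

**Cell fields.** Neurons and glia are homogeneous Poisson point processes
at a prescribed intensity (cells/mm³); immunoreactivity compartments
(nuclear / cytoplasmic / both / none) are i.i.d. categorical labels.
Glial cells carry cytoplasmic-only labels, matching how microglial and
astrocytic immunoreactivity is scored. A hard-core (minimum-distance)
option exists but is off by default: the estimators' unbiasedness
derivations assume no point interaction, and realism of the pair
correlation is irrelevant to first-moment recovery. Each simulated cell is
a single representative point; whether real counting used somata or
nucleoli as the counting item is immaterial for point-like items, and the
simulator does not model item extent.

**Fiber fields.** Axons are modelled as straight segments of fixed length
(default 500 µm — long enough that each segment crosses several sections,
as real axon stretches do, short enough that an ellipsoidal nucleus is
locally straight at segment scale) with isotropic orientations and Poisson
midpoints. Midpoints are generated in the region dilated by one segment
length and each segment is clipped to the region, keeping only the
in-region chord; by stationarity the expected retained length is exactly
`Lv × V`, with no boundary deficit. Fiber fields require a convex
(ellipsoid) region, where the in-region part of any chord is a single
interval; voxel-mask regions support point fields and sectioning only.

**Sectioning and shrinkage.** Content is cut into `⌈extent/t⌉` sections of
cut thickness t (50 µm). The shrinkage model has three parameters: an
in-plane linear factor (areas scale by its square), a z-collapse factor
mapping cut to mounted thickness, and a truncation fraction removing
`⌈f·n⌉` sections from the caudal end (emulating a damaged caudal third).
The mounted thickness is an explicit parameter with default 20 µm
(z-collapse 0.4 from 50 µm): an 18 µm disector plus two 1 µm guard zones
requires at least 20 µm of mounted tissue, which pins the default.
Within each mounted section, local z is rescaled by the collapse factor —
a uniform z distribution stays uniform, which is what the thickness
sampling fraction assumes. Fibers are cut at section faces; each section
keeps its sub-chords (assignment is lazy per section, since probes touch
only every k-th section).

## Probes

**SRS sites.** A systematic random sampling grid has a single uniform
offset in `[0, gx) × [0, gy)`; sites are the grid translates whose
counting frame intersects the section contour. The offset is drawn
independently per section within a probe run. A frame that partly leaves
the contour still counts the items inside it — items only exist inside
tissue, so this introduces no bias and needs no border correction beyond
the frame rule.

**Counting rule.** Point-like items are counted with half-open intervals
on all three axes (`[x0, x0+fw) × [y0, y0+fh) × [guard, guard+h)`), which
is the inclusion/exclusion-line rule specialized to points: a tiling of
frames counts every item exactly once (the census identity is tested
exactly). Extended-object forbidden-line logic is out of scope.

**Fractionator.** `N = ΣQ⁻ (1/ssf)(1/asf)(1/tsf)` with `tsf` computed
against *mounted* thickness (18/20), not cut thickness — using cut
thickness would inflate estimates by 2.5×, because the disector samples
the collapsed section, not the original slab. The runner refuses a design
whose mounted thickness disagrees with the stack's. Counting is
implemented as a vectorized lattice-membership test, which is exactly
equivalent to looping the frame rule over sites (each tissue point lies in
exactly one grid translate, and that translate is always a valid site);
this also means a missing pole-cap contour (a section whose mid-plane
lies outside the region) cannot silently drop counts.

**Cavalieri.** `V = d · a_p · ΣP` with d the sampled-section spacing
(period × cut thickness). The point spacing is configurable; the default
2000 µm gives ΣP ≈ 150–250 on an IC-sized structure, the conventional
operating range for a CE well under 0.09. Section areas are evaluated on
the mid-plane contour of each section.

**Gundersen–Jensen CE.** Computed from the covariogram terms of the
ordered per-section counts; smoothness m = 1 (divisor 240; m = 0 with
divisor 12 is available). The nugget variance ν = Σc subtracts local
counting noise from the covariogram and adds it back as Poisson noise —
it is on by default for disector and Spaceballs counts and off for
Cavalieri point counts on smooth contours, both exposed. An all-zero
count sequence raises; estimators then report value 0 with CE flagged
undefined (NaN).

**Spaceballs.** Each site carries a sphere of radius 18 µm whose surface
is restricted to the disector slab, giving probe area `S = 2πr·min(h, 2r)`
per site (Archimedes: the lateral area of a spherical zone depends only on
slab height). A full 36 µm sphere cannot fit a 20 µm mounted section,
hence the truncation; a full-sphere mode (4πr²) exists for thick synthetic
blocks. Crossings are transversal intersections of fiber chords with the
zone surface, found by a quadratic solve (tangencies count zero, a
measure-zero event). `Lv = 2ΣI/(n_sites·S)` is unbiased for any fiber
orientation distribution when the probe surface is a full sphere; for the
slab-truncated zone, anisotropy biases the estimate — fully z-aligned
fibers are underestimated by ≈ 50%, a property the test suite asserts
rather than hides. Sites are kept when their centre lies inside the
contour; spheres overhanging the lateral boundary lose part of their
sampling fraction, a negative edge effect of order r/extent (≲ 1% on the
structures simulated here).

**Spaceballs and z-collapse.** The published length densities refer to the
processed tissue state (they are quoted against Cavalieri volumes), and
collapsing a fiber field in z would both shorten the fibers and
anisotropize their orientations, changing the very quantity being
estimated. The fiber pipeline therefore sections with identity z-collapse
(full 50 µm sections); the 18 µm probe slab sits inside the section in
either convention and the zone area is identical. The neuron pipeline, by
contrast, uses the full z-collapse (0.4) plus the 18/20 thickness
fraction, since particle number is invariant under collapse.

## Reported quantities

Densities are totals over reference volumes; the density × volume = total
identity is exact by construction in reports. Printed-style percentages
round half-up to integers (so 35.5 → 36), the convention needed to
reproduce published tables deterministically. Volume ratios are always
reported as processed/reference × 100 (Cavalieri over MRI), never
inverted. Pooling across subnuclei uses either neuron-weighted fractions
(`Σfᵢwᵢ/Σwᵢ`) or unweighted means, matching the two pooling conventions
in the source tables. Cross-specimen tables flag pairs with different
processing (DPX vs celloidin): differential shrinkage of ~50% can inflate
apparent densities several-fold, so such ratios are incommensurable.

The reference-value table notes one internal inconsistency of the source
study (a VCN total printed once as 3.16 million and once as 316.38
thousand); the table records the density-consistent 316.38 thousand and
keeps the discrepancy as metadata rather than resolving it silently.

## Heatmaps

Counted coordinates are pooled across sections (an explicit choice; no
per-section weighting) and projected onto the coronal x–y plane, binned at
50 µm pixels, smoothed with an isotropic Gaussian (default bandwidth
250 µm, configurable — the bandwidth of the original visualization script
is not published), and max-normalized. The kernel is normalized with a
reflecting boundary, so pre-normalization mass equals the point count
exactly. Averaged region contours are vertex-wise means of per-section
polygons resampled to a fixed vertex count by arc length and aligned on
centroids (congruent translated contours average to the shape at the mean
position; circles of radii 1 and 3 average to radius 2).

## Problem sizes and statistical tolerances

Study-scale validations use an ellipsoidal synthetic central nucleus of
exactly 1362 mm³ (semi-axes 7.04 × 4.30 × 10.74 mm, longest axis
rostro-caudal), holding ≈ 4.85 million neurons or ≈ 2300 m of fiber —
the full published scale. The acceptance script averages 20 independent
pipeline replicates per quantity (the sampling SEM of a single replicate
is ≈ 4–6%, so the mean is determined to ≈ 1%); unit-level unbiasedness
tests use smaller nuclei with proportionally scaled designs and 50–200
replicates. Stochastic assertions use 3–3.5 standard-error bounds with a
1–2% systematic allowance; exact identities (census, partition,
components product, CE hand arithmetic) are asserted to floating-point
tolerance.

## Known limitations

* The simulator does not model staining intensity, item extent, cell
  morphology, vascular geometry, or spatial inhomogeneity of real nuclei;
  passing recovery tests demonstrates estimator correctness under the
  stated sampling designs, not robustness to tissue artifacts
  (lost caps, non-uniform collapse, overprojection).
* Fiber simulation is restricted to convex regions, and segments are
  straight with a fixed length; curvature within a segment is not
  represented (irrelevant to length recovery, relevant to per-section
  tortuosity).
* The multi-probe spread of repeated counts on the same real tissue
  cannot be reproduced without the underlying per-probe totals, which the
  source tables do not list individually; `combine_probe_totals` is
  validated on synthetic replicates instead.
* MRI reference volumes enter as scalars; no image registration or
  segmentation is performed.
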