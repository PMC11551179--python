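# Methods

This note documents the models, conventions and numerical choices behind
vascuflow, what the synthetic data generator does and does not emulate,
and where the design was genuinely open.

## Conventions

All volumes are indexed `(z, x, y)` with axis 0 pointing into the tissue
(increasing depth). Physical coordinates are micrometres, velocities
mm/s, pressures Pa, volumetric flows um^3/s. Axial velocity `v_z > 0`
means flow toward increasing depth and maps to a positive Doppler shift;
this one convention is used consistently by the simulator and the
velocimetry (which sign the hardware produces is a calibration matter).
Each graph segment has an arbitrary but persistent start node; flow
direction and the sign of the segment-level axial velocity are expressed
relative to it.

## Synthetic vasculature and flow

The generator builds what cortical imaging resolves: pial arteries and
veins confined to a thin surface band (default 30 um), trees that dive or
ascend through a configurable number of bifurcation generations with
Murray-law radii (`r_child = r_parent * 2^(-1/gamma)`, gamma = 3 by
default), and a capillary mesh of multi-segment paths joining arterial to
venous terminals so that every capillary lies on an artery-to-vein path.
Tree segments taper linearly between generation radii; capillary radii
are constant per segment. An optional minimum-clearance mode keeps
non-adjacent vessels separated (with a minimum branching angle at shared
nodes) and fails loudly when a spec is too dense — used by the topology
round-trip studies, where rasterized vessels must not merge.

Flows solve the steady Hagen–Poiseuille network problem: segment
conductance `pi r_bar^4 / (8 eta L)` with the blood viscosity eta =
3.5 mPa s, fixed pressures at pial artery inlets (9 kPa default) and vein
outlets (1 kPa), and a sparse linear solve for the interior pressures.
Zero net flow at every interior node then holds by construction (residual
at machine precision). The default desk-scale network (a few hundred
segments) lands capillaries in the 0.5–5 mm/s band where the cortical
velocity distribution peaks. Because each arteriole feeds a handful of
capillary paths rather than the hundreds a real penetrating arteriole
supplies, arterial velocities stay within a few mm/s of capillary ones at
this scale; the tens-of-mm/s arterial regime is exercised separately by
the velocimetry grid and the flow phantom.

Rasterization tests every voxel against per-edge capsules (local radius
interpolated along the polyline) and keeps, for overlapping capsules, the
value of the closest centerline. Velocity at a foreground voxel is the
segment tangent times the local speed — plug profile by default, or the
laminar parabolic profile `2 v_bar (1 - (rho/r)^2)`. Vessels thinner than
a voxel are rasterized at least one voxel wide, with a warning.

## OCT signal model

At a perfused voxel the dynamic signal is a complex Gaussian process
whose power spectrum is Gaussian with mean `f_D = 2 n v_z / lambda0` and
standard deviation `sigma = v_t / kappa`. Synthesis shapes complex white
noise with this envelope in the frequency domain (including +/- f_s
replicas, so wrapped spectra carry the correct circular statistics) and
inverse transforms; a transverse-only voxel is statistically correct, an
axial-only voxel degenerates to a pure tone at the (folded) Doppler
shift. Static tissue contributes a constant-phase component, and complex
white noise sets the SNR (default amplitude ratio 10:1, i.e. 20 dB).
Shifts beyond the Nyquist band fold back and are flagged, never hidden.
The transverse calibration kappa = 3.196 um is a single scalar fixed by
the worked calibration point (sigma = 3817 Hz corresponds to
12.2 mm/s); the underlying beam-optics derivation is out of scope here,
as is multiple-scattering tail broadening below large vessels (a known
limitation of the physical measurement, not a modelled effect).

Repeated B-scans for angiography use a complex AR(1) process across
repeats with correlation `exp(-speed / v_dec)` (v_dec = 1 mm/s default):
moving blood decorrelates, static tissue repeats up to noise. This is a
generic decorrelation model — sufficient for contrast and segmentation
studies, not a quantitative speckle simulation.

## Doppler velocimetry

The high-pass filter is realised as a zero-phase projection: the discrete
Fourier modes of the 250-sample record below 270 Hz are zeroed. On such
short records an IIR forward–backward filter leaves an edge-transient
ridge just above the cutoff that systematically captures the spectral
fits; the projection is exact, removes the constant (static) component
completely, and preserves the spectral mean of the flow signal. The
notched band (plus one resolution bin of margin) is excluded from the
fitting, since those samples carry no information.

The "modified Gaussian" is a Gaussian plus constant offset, evaluated
circularly (wrap replicas at +/- f_s) and convolved with the record's
spectral window |Dirichlet_250|^2. The window convolution matters: without
it, fitted widths are biased upward by up to ~10% at sigma ~100 Hz.
Fits run per voxel by trust-region least squares with an analytic
Jacobian on a 4x-decimated frequency grid (the 4096-point padded spectrum
is ~16x oversampled), initialised from circular spectral moments with
multi-start rescue for degenerate landings. Failures return
`valid=False` with a reason code, never an exception.

Two statistical facts shape the defaults:

- The periodogram of a Gaussian process has ~100%/sqrt(M) multiplicative
  noise after averaging M spectra, so the R^2 of a *correct* fit is
  bounded near M/(M+1) — about 0.75 for the three-volume protocol. The
  validation threshold therefore defaults to 0.6 (configurable), and is
  relaxed further when fitting only inside a segmentation mask, where the
  attainable R^2 also drops for broad spectra (their shape variance
  shrinks relative to speckle noise) and static-tissue rejection is
  already done. Static voxels are additionally rejected by an adaptive
  per-depth-slice Otsu threshold on the spectral maximum D_max.
- Once sigma approaches f_s/4, the wrapped Gaussian is degenerate with
  its offset up to the first circular harmonic; sigma then remains
  identifiable only if the noise floor is pinned. `fit_dps` accepts a
  noise-floor value for exactly this purpose, and the studies measure it
  from noise-only voxels processed identically (a dark calibration, as
  real spectrometers perform).

Spectral moments are circular (the frequency axis is treated as a
circle), with an optional exact window deconvolution: circular resultants
multiply under convolution, so dividing by the window's resultant removes
the finite-record broadening.

Averaging across the protocol's three volumes happens on power spectra,
before fitting. Aliasing is not unwrapped; fits operate on the wrapped
axis and voxels with |mu| > 0.45 f_s are flagged.

### The velocity-grid round trip

The validation grid holds 25 (v_z, v_t) pairs — five speed magnitudes
{0.5, 2, 8, 16, 30} mm/s at five inclinations each — all inside the
method's measurable domain, which the protocol itself implies: |f_D| at
most 0.4 f_s (axial components up to ~4.5 mm/s), mu clear of the 270 Hz
cutoff, sigma above the 92 Hz record resolution. Per pair, 320 replicate
voxels (each with three-volume averaging) are pooled into one spectrum
before the single fit; the averaging depth was set so the first-harmonic
contrast of the broadest spectra clears estimator noise. Recovery is
checked to 10% for sigma and v_tot, and for mu to one intrinsic
resolution bin (f_s/N_t = 92 Hz; the 5.6 Hz padded bins are
interpolation) plus 5% of the pair's total Doppler scale 2 n v_tot /
lambda0 — mu and sigma jointly encode the velocity vector, and at
near-transverse pairs mu carries only a few percent of it.

For the capillary high-pass study (80% static amplitude, v_tot =
1 mm/s), the filtered fit recovers sigma within a few percent while the
unfiltered fit locks onto the near-delta DC peak and collapses sigma —
a deviation of ~99%. The DC peak dominating the unfiltered fit is the
mechanism either way; the direction of the failure (collapse rather than
broadening) follows from the static component being constant-phase.

## Segmentation, skeleton, graph

The angiogram is complex inter-repeat decorrelation (mean magnitude of
consecutive differences after global bulk-phase correction). The
segmentation baseline is threshold (Otsu by default, explicitly settable
— on sparse vasculature a global Otsu can split the background mode, so
quantitative studies pass an explicit threshold or consume external
masks), small-component removal, and morphological closing; external
deep-learning masks pass through closing only. This baseline is
deliberately modest: the contract is that downstream stages work given a
mask of reasonable quality.

Skeletonization uses 3D medial-axis thinning with two guards developed
against synthetic data:

- a coverage check that detects the thinning degeneracy on perfectly
  symmetric prisms (a 6x6xN box thins to nothing) and retries on
  asymmetrically shaved variants, shaving only thick structures;
- spur pruning (a terminal chain shorter than `prune_strength` = 3 times
  the local radius is a thinning artifact) and contraction of short
  junction–junction stubs and loops (one thick bifurcation thinned into
  two nearby junctions), the role the bulge-size parameter plays in
  dedicated vascular skeletonizers.

Nodes sit at junction-cluster centroids and endpoints; chains become
segments with polylines in um, arc length, tortuosity (arc over chord;
guarded for loops) and provisional distance-transform radii. On
self-avoiding synthetic trees with branch spacing above four voxels the
reconstruction recovers node and segment counts exactly (about 19 of 20
random seeds; residual failures are rasterization tangencies).

Diameters are refined at every skeleton point from line profiles
orthogonal to the local tangent (four azimuths, half-length four
provisional radii). A Gaussian+offset fit supplies the baseline,
amplitude, centre and an R^2 quality gate (> 0.8); the diameter is the
full width of the measured profile at the fitted half-maximum level.
This reading is exact for PSF-blurred flat-topped vessels and identical
to the fit's own FWHM for truly Gaussian profiles, whereas the
LSQ-Gaussian FWHM converges to ~0.88x the width of wide flat-topped
profiles. A five-point moving average fills rejected points; segments
with no accepted fit fall back to distance-transform radii and are
flagged.

## Velocity mapping, directions, recovery

Registration between the Doppler-derived D_max volume and the angiogram
is a 3D affine (SimpleITK, correlation metric); co-simulated volumes use
the identity. A deformable refinement is intentionally out of scope.

Per skeleton point, valid voxel velocities within a sphere of the local
fitted diameter contribute; the point value is the mean of the top 30%
(the bright-voxel average also compensates partial-volume dropout in real
data; on clean plug-profile simulations it overestimates by a few
percent, visible in the phantom slope of ~1.02). Profiles are smoothed
(five-point moving average); the segment velocity is the median along the
segment.

Direction voting compares sign(v_z) with sign(tangent_z) along the
segment, weighted by |v_z|·|tangent_z|, with a floor |tangent_z| >= 0.1
to reject noise-dominated votes. Points near the segment ends are
excluded (15% each side): their spheres overlap junctions where a
neighbouring vessel's opposite axial flow contaminates the vote. With
this guard, direction accuracy on fully simulated networks is 100% of
eligible segments in the validation runs (criterion: at least 98%).

Missing velocities are recovered by the local conservation rule, applied
iteratively: for an unset segment, each node whose other incident
segments all have velocity and direction yields a flow estimate
`Q = -sum(signed v_i * pi r_i^2)`; two determinable nodes average their
speed estimates; conflicting implied directions keep the larger-|Q| node
and flag the segment; nodes are processed most-determined-first and the
sweep repeats to a fixpoint. Measured segments are never modified and a
completed graph is a fixpoint. Cross-sectional areas use the segment
mean radius. On networks where every unknown is uniquely determined the
fixpoint equals the direct conservation solution exactly (the Poiseuille
ground truth serves as that oracle in the tests). A global least-squares
re-optimisation over all nodes is intentionally not implemented — the
local iterative rule is the method under study.

## Network analysis

Artery/vein labels propagate breadth-first from pial seed segments and
halt at pre-capillaries (median diameter below 12 um); conflicts stay
capillary and are flagged. The synthetic generator assigns its own
ground-truth classes with the same 12 um convention, so narrower tree
branches count as capillary-class in both. Branching orders are minimum
segment-hop counts to the nearest artery-/vein-labelled segment (the
"shortest path" metric is hops, consistent with order semantics).

Arteriovenous path profiles: for each capillary segment, the shortest
paths to the closest artery and vein are joined through it; duplicate
paths are counted once; paths with fewer than three capillary segments
are discarded (falsely allocated direct shunts). Each path's per-segment
velocities sit at normalized cumulative hop midpoints and are linearly
interpolated onto a common 21-point grid; medians and MADs are taken per
grid point across paths. Path-length histograms use the segment counts
before normalization; with several networks, histogram heights average
across networks with the standard error of the mean.

The node-degree-versus-axial-window curve anchors windows at the cortical
surface (minimum z by default, configurable) and grows them downward;
segment pieces crossing the boundary are cut there, cut points become
degree-1 endpoints, and the mean degree is taken over retained nodes.
The reader for published ex vivo graphs consumes node/edge CSV tables and
preserves whatever node structure the dataset defines (including
high-curvature points); no curvature nodes are inserted by this package's
own pipeline.

## Problem sizes

Validation runs are sized for a single CPU: recovery studies use five
networks of ~500–650 segments; the velocity grid uses 320 replicate
voxels per pair; the phantom tube is 16 um in diameter on a 2 um grid
with five pump steps (the full-scale 180 um tube would add nothing but
voxels); direction studies use a ~100-segment network with ~3000
foreground voxels, with pressures scaled so capillaries stay in the
physiological 0.5–5 mm/s band and axial flows stay below the Nyquist
velocity, as in the imaging protocol.

## Known limitations

- No pulsatility, hematocrit-dependent viscosity or discrete-RBC flow;
  steady Poiseuille only.
- No beam-optics simulation (PSF, k-linearization, spectrometer); the
  OCT model is the spectral-statistics level the velocimetry assumes, so
  passing round trips validate the estimator chain, not the optics.
- Aliasing is flagged, not unwrapped: axial velocities beyond the Nyquist
  velocity (~5.7 mm/s at 23 kHz) fold and can flip direction votes.
- The thresholding segmentation is a baseline; realistic OCTA artifact
  regimes (tails, depth-dependent SNR loss) are not emulated, which is
  precisely why external masks are first-class inputs.
- The synthetic capillary bed is a set of random paths, not a
  space-filling mesh; topology statistics beyond branching order (e.g.
  loop structure) are not representative of real cortex.
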