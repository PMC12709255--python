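# Methods

## Model

A presynaptic bouton is represented as a rotationally symmetric prolate
ellipsoid whose major axis lies on the axis of a cylindrical axon
(200 nm diameter, 5 µm long, chosen so the axon and its periodic ends have
little influence on bouton recovery times).  The accessible space is the
union of the ellipsoid interior and the axon lumen, so the bouton opens
into the axon at both poles.  Space is discretized into 25-nm cubic voxels
(matching the resolution of the electron-microscopy data such geometries
are derived from).  Mitochondria and vacuoles are excluded volume, modeled
as random ellipsoid-shaped voxel blobs grown to a target volume fraction
and re-sampled if they would disconnect the accessible space.  Each
synaptic vesicle occupies a single voxel (a ~40-nm vesicle vs. a 25-nm
voxel; one voxel per vesicle is the simplest consistent choice) that
remains accessible to diffusing protein but additionally supports binding.

Protein dynamics follow the reaction–diffusion master equation: hopping
between face-adjacent accessible voxels at rate D/a² per open face,
binding at rate k_b per free protein in a vesicle voxel, unbinding at rate
1/T per bound protein.  Bound proteins do not hop.  Binding capacity is
unlimited (nothing is known about per-vesicle site numbers; at the copy
numbers simulated this is immaterial).  Events are generated by the next
subvolume method: an indexed priority queue keyed by per-voxel next-event
times selects the voxel, the direct method selects the channel within it.
After an event the affected voxels' waiting times are resampled from fresh
exponentials, which is statistically exact by memorylessness.  The queue
is a 4-ary indexed min-heap storing (time, voxel) pairs contiguously;
per-event work is O(log n_voxels).  Random numbers come from a seedable
xorshift128+ generator inside the compiled kernel; every public entry
point takes an integer seed and is fully reproducible.

Crossing a periodic axon end re-inserts the protein at the opposite end
and, if it was photobleached, converts it back to unbleached: the far axon
acts as an unbounded reservoir of fresh fluorescent protein.

## Initial condition and equilibration

Proteins are placed by sampling the exact stationary measure: voxel
weights 1 for cytosol and 1 + k_b·T for vesicle voxels, with the bound
state drawn per vesicle voxel with probability k_b·T/(1 + k_b·T).  Because
the initial state is already at equilibrium, the default burn-in is only a
decorrelation horizon max(1 s, 5 T) rather than a full diffusive
relaxation; a stationarity check (bouton occupancy compared between the
two horizon halves against binomial counting noise) warns if the state
drifts.  Uniform and axon-only initializations are available for
relaxation studies, where a longer horizon should be supplied explicitly.

## Measurement chain

Three bleaching protocols are implemented: instantaneous whole-bouton,
instantaneous 400-nm spot, and the experimental protocol — the same spot
held for 80 ms, during which every protein entering the beam is flagged
(implemented exactly, as an event-coupled species conversion on hops into
the spot).  The spot cylinder runs along the optical axis, perpendicular
to the axon, through the bouton centroid; axon FRAP uses the same
continuous protocol centered on the axon midway between the bouton pole
and the periodic boundary.

Frames store per-voxel unbleached counts.  Imaging projects them along
the optical axis onto a 128×128 pixel grid whose field of view spans the
5-µm axon (≈39 nm/pixel) and convolves with a unit-sum Gaussian PSF of
250 nm FWHM (a standard diffraction-limited stand-in for a measured GFP
PSF; downstream results depend only weakly on its exact shape).  No
detector noise is added by default; a Poisson option exists.

The recovery ROI follows the experimental analysis: the difference
between the pre-bleach image and the first image 0.5 s after the start of
the laser pulse is thresholded at mean + 0.5·std (mean + 1·std for axon
FRAP), statistics over the entire image including dark background.  One
refinement is required at simulated protein numbers: the global threshold
also passes isolated shot-noise pixels far from the bleach, so only the
connected component containing the spot-center pixel is kept — the
bleached area is a single enclosed region.  For the two instantaneous
protocols the ROI is the pixel footprint of the bleached region itself.
Traces are ROI sums normalized to the pre-bleach value.

## Curve fitting

The headline analysis fits I(t) = I₀(1 − e^(−t/τ)) with zero floor, the
form used on the real experiments; the immobile fraction is
1 − I₀ (clipped to [0, 1], with a flag when clipping occurs).  When the
trace opens with a rapid jump (partially bleached bouton) this form pins τ
to the fast redistribution timescale, which is precisely what makes the
protocol comparison and the master curve come out as observed; a variant
with the post-bleach floor as a free offset (`floor_mode="fit"`) recovers
(τ, I₀, floor) of offset-form traces to machine precision and is the
right tool for clean two-regime separation.  A double-exponential fit
(τ_fast < τ_slow enforced by sorting, degenerate components flagged)
captures the redistribution + influx two-timescale shape.  Fits are
nonlinear least squares with half-recovery initialization for τ and
bounds τ ∈ [0.01, 10⁴] s.  Replicates are combined by averaging the
fitted τ and IF values, never by fitting the averaged trace.

## Effective-diffusion theory and mechanism classification

Fast binding equilibrium gives D_eff = D/(1 + ρ·T·k_b), with ρ the
vesicle voxel density of the bouton.  The bleach length scale is
L_b = d_b + 2√(2·D·t_b) (D replaced by D_eff for binders; the spot
diameter d_b can be dropped via a switch, as the binder-case rescaling
can also be read without it).  L̃ = L/L_b sorts recovery into axonal
influx (L̃ small), intra-bouton redistribution (L̃ large) and mixed
regimes.  Fits are labeled by thresholds on the ensemble-mean L̃:
axon for L̃ ≤ 0.7, redistribution for L̃ ≥ 1.4, both between.  The
thresholds are a documented stand-in for an unpublished rule; they are
calibrated so that the five reference protein fits (intersectin,
α-tubulin, synapsin, PIP5KIγ, dynamin) receive their known labels under
the default ensemble, and they are configurable.

## Default ensemble

The generator draws, per bouton: major axis length (log-normal, median
510 nm at EM scale, σ_log 0.17, clipped to [375, 750] nm, then rescaled
×2 to fluorescence scale, giving built lengths of 0.75–1.5 µm), aspect
ratio (log-normal, median 1.4, clipped [1, 2.2]), organelle counts
(Poisson, means 1 and 2) and volume fraction (log-normal, median 0.10,
clipped below 0.30), and a vesicle *density* (log-normal, median 0.041,
σ_log 0.30) that is converted to a vesicle count via the sampled bouton
volume — so vesicle number scales with volume, and bouton volumes and
vesicle counts each span more than an order of magnitude across 30 draws.

Three published anchors fix the free constants: (i) the ensemble-average
vesicle density is 0.0456, the value implied consistently (to four
digits) by the (D, k_b, T, D_eff) rows of the reference fit table;
(ii) the mean built length is ~1 µm, required for the mechanism-dissection
experiment in which a free D = 0.5 µm²/s protein sits near the τ(L̃)
maximum while an equally mobile strong vesicle binder falls on the fast
redistribution branch; (iii) the order-of-magnitude volume spread.  What
the generator does not emulate: correlated EM covariates (e.g. larger
boutons having disproportionately many mitochondria), non-ellipsoidal
bouton shapes, vesicle clustering, and vesicle mobility — so passing
tests demonstrate the measurement-chain physics on idealized geometry,
not fidelity to any particular synapse.

A note on the recovery-time/length relation: at D = 0.1 µm²/s this
ensemble lies on the redistribution branch (L̃ ≈ 1.1–2), so recovery
times fall with bouton length — the elongated bouton is only centrally
bleached and refills locally, while the compact one is bleached outright
and must await axonal influx.  This is the same physics as the
protocol-comparison and master-curve results; ensembles of smaller
boutons sit on the rising (influx-limited) branch where the association
reverses sign.

## Axon observables at reduced scale

Two practical points about axon FRAP worth knowing.  First, the thin shaft
holds only ~10–20% of the protein in a full bouton+axon geometry, so at
reduced copy numbers the axon ROI is photon-starved and the fitted
recovery time flips between the fast (jump) and slow (tail) branches of
the least-squares problem.  The library therefore measures axon
observables on a bouton-free axon tube (`build_axon_tube`) at higher
labeling density, once per diffusion coefficient — the shaft is identical
in every ensemble geometry, contains no vesicles, and sits ~1.2 µm from
the bouton, so binding parameters do not measurably touch τ_axon or
IF_axon.  The generic per-cell, full-geometry path remains available
(`ensemble_observables`).  Second, because the threshold ROI scales with
the bleach spread (~√(D·t)), the refill time of the ROI is nearly
D-independent in this regime; the D information of the axon measurement is
carried mostly by IF_axon (the plateau shortfall within the recording),
which is cleanly monotone in D.

## Library round-trip at reduced scale

The shipped round-trip check uses a 3×3×3 grid (D ∈ {0.02, 0.06, 0.2}
µm²/s, k_b ∈ {0, 50, 500} /s, T ∈ {0.05, 0.5, 5} s), two geometries, three
replicates, 450 proteins (3500 on the axon tube), 50-s bouton and 24-s
axon recordings.  The synthetic "experimental" table holds five proteins
(a strong binder, two pure diffusers, and two fillers that give the
z-normalization a realistically spread protein set).  Pure diffusers
recover D and D_eff exactly; the strong binder recovers to the true cell
or an immediate neighbor with D_eff preserved — confusions run along the
k_b·T-degenerate diagonal, which leaves D_eff unchanged, exactly the
near-degeneracy expected of this estimator.  A *weak* binder
(k_b·T ≈ 25, D_eff ≈ D/2) is close to indistinguishable from its twin
cells at this scale and is deliberately not part of the assertion; at the
reference scale (30 geometries × 5 replicates) the extra averaging removes
the fit-branch noise that causes it.

## Problem sizes

Reference conditions are 5000 proteins, 30 geometries and 5 replicates
per condition.  The shipped tests and the acceptance script run reduced
versions chosen to keep full runs in the tens of minutes on one CPU:
typically 5–8 geometries, 150–1500 proteins (fewer for fast diffusers,
whose event rate scales as N·6D/a²), one replicate, and recordings
truncated to 4–80 s depending on the expected recovery time.  At these
sizes the qualitative properties (orderings, spreads, peak positions,
round-trip recovery to a neighboring grid cell) are stable under seed
changes; absolute values carry Monte-Carlo scatter of order 10%.

## Numerical details and edge cases

Zero total propensity (D = 0 and no binding) raises a quiescent-state
error rather than stalling.  Equal event times are resolved by heap order,
which is deterministic for a fixed seed.  Voxels emptied by an event keep
an infinite key until repopulated.  The compiled kernel deliberately
avoids `fastmath`: its no-infinity assumption breaks the infinite-key
sentinel.  Counts are 64-bit integers; times are 64-bit floats in seconds;
lengths are nanometers internally (D converted once, 1 µm²/s = 10⁶ nm²/s).
Degenerate ROI selection (identical pre/post images) is flagged and
rejected before tracing.  Immobile fractions outside [0, 1] are clipped
and flagged.  Library cells with k_b = 0 or T = 0 are physically identical
pure-diffusion conditions; they are simulated once per D and replicated
across the degenerate grid cells, keeping the search grid complete.

## Known limitations

No protein–protein crowding; vesicles are static and unlimited-capacity;
the PSF is an isotropic 2D Gaussian (no defocus); the mechanism labels
depend on calibrated thresholds; the fitting library is a nearest-neighbor
lookup without interpolation, so parameter resolution is the grid spacing;
and the zero-floor/offset-floor fit duality means a reported τ must always
be read together with the fit form that produced it.
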