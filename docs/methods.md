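# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `smbleach`.

## Physical model

A field of fluorescently labeled receptor particles sits immobile on a
membrane (paraformaldehyde-fixed cells; no diffusion). Each particle is an
oligomer of order i ∈ {1..N_max}; each of its subunits independently carries
a functional fluorophore with probability P_f (the labeling efficiency,
measured independently in the underlying experiments; default 0.8). Each
fluorophore emits at a constant rate until it photobleaches, once and
irreversibly, at an exponentially distributed time. A particle's intensity
trace is therefore a staircase whose downward step count equals its labeled
subunit number.

The observation model conditions on visibility: a particle with zero labeled
subunits never appears in any image, so the probability that a *visible*
order-i particle shows m steps is

    A[m,i] = C(i,m) P_f^m (1−P_f)^(i−m) / (1 − (1−P_f)^i),   1 ≤ m ≤ i.

A is column-stochastic and upper-triangular; with observed step fractions R,
the linear system A·w = R holds for the visible-particle order weights
w_i ∝ (1−(1−P_f)^i)·x_i. This conditioning is the only convention under
which the system is well-posed for observed histograms (the m = 0 class is
never counted). The unconditional variant — columns summing to the
visibility instead of 1 — is retained behind
`LabelingModel(visibility_conditioned=False)` for sensitivity analysis,
because published two-step ratios for obligate dimers are sometimes quoted
against the unconditional P_f² rather than the conditioned value.

Truncation: N_max = 5 (monomer through pentamer) by default; higher orders
contribute negligibly at the densities considered and make the inversion
increasingly ill-conditioned.

## Inversion

`solve_corrected_fractions` solves A·w = R by non-negative least squares
(scipy's NNLS), undoes the visibility weighting, and renormalizes. NNLS
guarantees a valid (non-negative) distribution on noisy histograms; when the
solution is interior it coincides with the direct linear solve. Reported
diagnostics: the NNLS residual norm and cond(A). As P_f → 1, A → I, the
condition number → 1, and corrected → observed. For P_f below ~0.2 the
condition number exceeds 10³ and a warning is attached — corrected fractions
are then unstable and should not be trusted.

Uncertainty: percentile bootstrap (default B = 1000, 2.5/97.5 percentiles)
by multinomial resampling of the observed histogram, re-solving per
replicate. The paper-style point arithmetic is deliberately simple:
receptors per cell = density × cell area (default 1200 μm², a typical
COS-7 surface area), rounded to the nearest ten; expression levels over
physiological references are plain B_max ratios.

Statistical resolution: propagating multinomial histogram noise through the
inversion (delta method) for a truth of (0.13, 0.56, 0.14, 0.17, 0) at
P_f = 0.8 and 10,000 particles gives per-order standard errors of 0.6–1.0
percentage points and a joint probability of ~92.5% that all five orders
land within 2 pp — the inversion roughly doubles the raw multinomial noise.
The acceptance tests assert this oracle-derived behavior (unbiasedness of
the replicate mean, and a binomial lower bound on the 2 pp coverage).

## Synthetic data generator

`SimulationConfig` defaults describe the low-density imaging condition of
the study system:

| parameter | default | meaning |
|---|---|---|
| true_fractions | (0.435, 0.467, 0.049, 0.049, 0) | particle fractions over orders 1..5; the 9.8% high-order remainder is split evenly between trimers and tetramers because no finer split is published |
| labeling_efficiency | 0.8 | per-subunit fluorophore probability |
| particle_density | 0.22 /μm² | Poisson placement; `n_particles` overrides with an exact count |
| image_shape, pixel_size | 256×256 px, 0.107 μm/px | 16 μm EMCCD pixel ÷ 150× objective |
| psf_sigma | 1.3 px | Gaussian PSF width (~140 nm at 488 nm, NA 1.45) |
| unit_intensity | 300 counts | peak amplitude per active fluorophore; integrated flux is 2πσ²·unit |
| background_level, read_noise_sd | 200, 10 counts | camera floor |
| em_gain_excess_factor | 2.0 | multiplies shot variance (EM-register excess noise); `shot_noise=False` disables the signal-dependent term for exactness tests |
| mean_bleach_time | 100 frames | exponential bleaching (5 s at 50 ms/frame) |
| n_frames, frame_interval | 1000, 50 ms | acquisition length |
| preacq_frames, preacq_scale | 0, 0.02 | optional low-excitation search segment; raising the laser produces the characteristic upstroke |
| min_separation | 0 px | optional hard-core placement radius for controlled-overlap studies |
| blink_prob, blink_duration_mean | 0, 5 frames | optional two-state blinking for QC robustness tests |

Bleach times are drawn as continuous exponentials t and recorded as the
frame index ceil(t); a fluorophore contributes to frames f < ceil(t). This
frame-aligned convention keeps noiseless traces exactly piecewise constant
(no fractional-frame levels), at the cost of a +0.5-frame discretization
offset in mean bleach frames, which the tests account for explicitly.

What the generator does **not** emulate: diffusing particles, triplet/dark
states beyond the optional telegraph blinking, FRET between fluorophores,
drift, chromatic effects, non-uniform illumination, and the exact gamma
statistics of EM gain (a Gaussian with inflated shot variance stands in).
Passing tests therefore demonstrate correctness of the analysis chain under
idealized fixed-cell imaging, not robustness to every artifact of real data.

## Spot detection

Each frame is decomposed with the undecimated à trous B3-spline wavelet
(kernel [1,4,6,4,1]/16, holes doubling per level, mirror boundaries; 3
levels). Significance is judged on the level-2 detail plane — the scale that
matches a σ ≈ 1.3 px PSF — thresholded at k_sigma (default 3) times a
MAD-based noise estimate of that plane. Candidate maxima, however, are taken
on the *band-pass sum* of planes 1..2: the level-2 plane alone merges the
maxima of pairs closer than ~3.4 px, while the sharper band-pass resolves
pairs down to ~3.0 px, which is what keeps detection recall above 0.95 at
0.8 particles/μm². Sub-pixel refinement is a 3×3 intensity-weighted centroid
of the band-pass plane (chosen over larger windows because it is unbiased by
bright neighbors at 4–5 px) or, where precision matters (frame 0, density
estimation), a bounded least-squares 2D Gaussian fit with analytic Jacobian
(σ constrained to [0.5, 3] px, window half-width 4 px; out-of-bounds windows
and non-converged fits are flagged, never dropped silently). Converged fits
from distinct candidates that slide onto the same center are deduplicated
(brightest wins). A single-Gaussian fit is *not* used to measure pair
distances: for two spots inside one fit window it collapses toward the
midpoint.

Particle density = converged frame-0 fits / field area. Fit windows cannot
cross the image edge, so a border band of ~half-window width is effectively
excluded; at 512×512 this biases density low by ~6%, within the accepted
tolerance, and could be corrected by using the fittable area if needed.

## Linking, traces, and quality control

Particles are fixed, so linking is greedy nearest-neighbor with a 2 px gate
and no gap closing, rather than a motion-model tracker; KD-trees keep it
linear. Because a single missed frame then splits a track, fragments whose
anchors coincide within 1.5 px are merged afterwards — for stationary
particles coincident anchors are the same molecule. This merge step, plus a
minimum track length (3 detections), is what makes the pipeline robust to
the thousands of single-frame false detections a 3σ threshold produces on
noisy movies.

Traces are extracted at the fixed track anchor over *all* frames (so the
post-bleach baseline is observed): disc aperture of radius 3 px minus the
median of a 5–7 px annulus times the disc area. Trace-level QC replaces the
original manual curation with explicit rules, each logged with a reason:
`border` (annulus would leave the image), `short track`, `crowded` (another
valid track's anchor within 3·psf_sigma — the isolation requirement;
crowding is judged among valid tracks only, so noise clusters cannot
disqualify real particles), `not fully bleached` (final plateau above half a
unit step), `blinking` (re-brightening by more than half a unit after
reaching background), and `too short` (bleached within 3 frames).

## Step counting

Greedy binary segmentation fits a piecewise-constant model per trace:
change points are inserted while the residual-sum-of-squares gain exceeds
penalty × σ̂², with penalty = 2·log(n) (BIC-style) and σ̂ estimated robustly
from first differences (MAD/√2). The noise floor is clamped to a tiny
positive value so exactly-constant noiseless plateaus terminate cleanly.
Adjacent plateaus closer than min_step are merged (smallest gap first);
steps are the strictly downward transitions, and any upward transition
disqualifies the trace.

min_step defaults to half the estimated unit step. The unit (single
fluorophore) intensity is estimated as the **median of per-trace maximum
downward steps** over a first no-floor pass, then the fit is repeated once
with the floor. The per-trace maximum is used rather than the last step
because, with a 3 px aperture, a neighbor at 4–6 px leaks a small fraction
of its flux into the disc and its bleach produces a small *trailing* step —
the last step is therefore biased toward cross-talk, while every fully
bleached trace's largest step is a genuine single- (rarely double-) unit
drop. Residual cross-talk steps fall below min_step and are merged away.

Accuracy at a per-frame SNR of 8 exceeds 97% per class for 1–4 fluorophores;
the dominant irreducible error is two fluorophores bleaching within the same
frame, which merges two unit steps into one double step (~1–2% of dimers at
the default 100-frame mean bleach time).

## Pipeline and reproducibility

`run_pipeline` chains simulate → detect → link → trace → steps → correct,
writing every intermediate as CSV (movies as 16-bit TIFF) so stages can be
re-run independently; configs are JSON with strict schema validation
(unknown keys are errors). All randomness flows from a single integer seed
through numpy Generators; identical config + seed reproduces reports
byte-for-byte. Movies are float32 and noise is generated frame-wise in
place, keeping peak memory near one movie copy (~0.5 GB for 512×512×500).

Problem sizes used by the shipped tests were chosen to give tight
statistical resolution while remaining desk-scale: the end-to-end movie
check uses 2000 particles on a 512×512×500 noiseless movie with a 4 px
hard-core placement (the controlled-overlap switch), where the corrected
fractions carry ~1.8 pp of irreducible multinomial noise; step-accuracy
checks use 1000 traces per class; detection performance uses ~2400 spots in
one frame at 0.8 /μm². End-to-end comparisons are made against the realized
ground-truth composition of the simulated sample (and, at small n, against
the inversion of the realized label counts), since at finite n the
generator's own sampling noise is comparable to the tolerances being tested.

## Known limitations

- P_f is an input, not estimated from the data; errors in P_f propagate
  directly into the corrected fractions.
- Particles closer than ~2.6 px merge optically; at the default densities
  this is rare and the crowding rejection removes flagged cases, but merged
  pairs that survive inflate apparent order slightly.
- The correction assumes independent labeling across subunits and identical
  bleach kinetics for all fluorophores.
- Step counting assumes downward-only dynamics after QC; genuine reversible
  photophysics is rejected rather than modeled.
- The maximum-likelihood multinomial alternative to NNLS is out of scope, as
  is estimating oligomer order from intensity rather than step counts.
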