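# smbleach

Single-molecule photobleaching subunit counting for membrane receptors.

When a fluorescently labeled, surface-immobilised receptor oligomer is imaged
by TIRF microscopy under continuous excitation, each fluorophore bleaches in
one irreversible step, so the number of downward intensity steps in a spot's
time course counts its labeled subunits. Because labeling is incomplete
(typically ~80% per subunit with Halo-tag chemistry), the observed step
histogram systematically understates oligomer order: a dimer shows two steps
only with probability P_f², one step with 2·P_f(1−P_f), and is invisible
with (1−P_f)². `smbleach` implements the full measurement chain and the
binomial correction that inverts it:

1. **simulate** — synthetic TIRF movies of fixed particles with known
   stoichiometry, exponential bleaching, EMCCD-like noise (`smbleach.simulate`)
2. **detect** — à trous B3-spline wavelet filtering and 2D Gaussian PSF
   fitting for sub-pixel spot localization (`smbleach.detect`)
3. **link + trace** — nearest-neighbor linking of stationary spots and
   fixed-aperture trace extraction with annulus background (`smbleach.tracking`)
4. **count** — automated change-point step counting by penalized binary
   segmentation (`smbleach.steps`)
5. **correct** — inversion of the observed step histogram
   (`smbleach.stoichiometry`)

## The correction model

Let x_i be the true fraction of order-i particles (i = 1..N, truncated at
pentamers, N = 5) and P_f the per-subunit labeling probability. An order-i
particle shows m steps with probability

    P_im = C(i, m) · P_f^m · (1 − P_f)^(i−m).

Unlabeled particles (m = 0) are undetectable, so the observation matrix is
conditioned on visibility, A[m,i] = P_im / (1 − (1−P_f)^i), and the observed
step fractions satisfy A·w = R with w_i ∝ (1 − (1−P_f)^i)·x_i. The solver
inverts R by non-negative least squares and renormalizes w back to particle
fractions; entity (subunit-level) fractions follow as E_i = i·x_i / Σ_j j·x_j.
Bootstrap resampling of the histogram provides confidence intervals.

## Worked example

```sh
python examples/labeling_correction.py
```

prints, for a low-density composition of 43.5% monomers, 46.7% dimers and a
9.8% higher-order remainder at P_f = 0.8:

```
low density:
  true particle fractions : [0.435 0.467 0.049 0.049 0.   ]
  expected step fractions : [0.563 0.364 0.051 0.022 0.   ]  (one-step 56.3%)
  re-inverted fractions   : [0.435 0.467 0.049 0.049 0.   ]  (residual 0.0e+00)
  entity shares           : monomer 25%, dimer 55%, oligomer 20%
```

That is: under 80% labeling this mixture would *appear* ~56% monomeric in a
photobleaching experiment, the inversion recovers the true composition
exactly from noise-free fractions, and in subunit terms only 25% of
receptors are monomeric. The other examples simulate traces and count steps
(`simulate_and_count_steps.py`), run the whole movie pipeline end to end
(`full_pipeline.py`), and do receptor-density bookkeeping
(`density_arithmetic.py`).

A command-line interface wraps the pipeline:

```sh
smbleach pipeline --seed 7 --out scratch/run          # simulate + analyze
smbleach analyze --movie my_stack.tif --out scratch/a # analyze an existing TIFF
```

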