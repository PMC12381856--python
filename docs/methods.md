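# Methods

This note records the models, numerical choices and limitations behind
`crypticfold`, in the spirit of a methods appendix.

## Three-state irreversible unfolding kinetics

**Model.** Sequential irreversible unfolding N → I → D with first-order
rate constants parametrized as k_i(T) = exp[(Eₐᵢ/R)(1/T*ᵢ − 1/T)] in
min⁻¹, R = 8.314 J mol⁻¹ K⁻¹.  T*ᵢ (K) is the temperature where step
*i* runs at 1 min⁻¹; this (Eₐ, T*) pair is the standard identifiable
parametrization for scan-rate-dependent irreversible denaturation —
equivalent to an Eyring/Arrhenius form but without the astronomically
correlated pre-exponential factor.  Activation free energies for
reporting are obtained by Eyring inversion, ΔG‡ = −RT ln[k h/(k_B T)]
with k in s⁻¹, at 40/60/80 °C by default.

**Assumptions.** Unfolding is kinetically controlled (no folding-back
term), justified for scan-rate-dependent, poorly reversible melts.  ΔCp
of activation and of unfolding are set to zero: the data contract is
baseline-subtracted DSC and per-state *linear* spectroscopic baselines,
which absorb gentle heat-capacity drifts but deliberately disable
extrapolation of barriers far outside the measured range.

**Signals.**
- DSC: C_p^exc(T) = [ΔH₁·k₁(T)·x_N(T) + ΔH₂·k₂(T)·x_I(T)]/v
  (kJ mol⁻¹ K⁻¹); its integral over a complete transition equals
  ΔH₁ + ΔH₂ (verified to <1 %).
- Spectroscopy (BCM, CD) and isothermal traces:
  y = Σ_s (a_s + b_s(T − T_ref))·x_s, with b_s = 0 for isothermal.
- The SLS aggregation signal is *not* fitted; it is min–max normalised
  and correlated against x_I, x_D and x_I + x_D to name the species
  whose accumulation it tracks.

**Integration.** The scan ODE becomes very stiff past the transition
(k₂/v grows exponentially), so the default propagator is a fixed-substep
(0.005 K) exponential–trapezoidal stepper: x_N is advanced by the exact
exponential of the trapezoidal rate integral, and x_I by the exact decay
factor e^(−a) with the φ(a) = (1 − e^(−a))/a weight on the trapezoidal
source.  The scheme is unconditionally stable, positivity-preserving,
O(h²)-accurate (~1e-6 against adaptive LSODA at rtol 1e-8, which is
available as `method="ivp"` and used as the cross-check in the tests),
and fast enough (numba-compiled, ~10⁻⁴ s per scan; a pure-numpy fallback
with identical semantics exists) to sit inside a multistart fit.
Conservation x_N + x_I + x_D = 1 holds to 1e-9 by construction;
round-off is clipped only below 1e-12.  Isothermal propagation is the
closed-form solution, with the k₁ ≈ k₂ degenerate branch switched at
|k₁ − k₂| < 1e-8 min⁻¹.

**Global fit.** All datasets share (Eₐ₁, T*₁, Eₐ₂, T*₂); enthalpies are
shared across DSC datasets and baselines are per dataset.  Because the
model is linear in ΔH and the baselines, those are solved exactly by
(bounded, ΔH ≥ 0) linear least squares inside the residual — variable
projection — leaving a 4-parameter nonlinear problem solved by bounded
trust-region least squares from a data-informed start (T* placed at the
steepest observed transition) plus 20 Latin-hypercube starts (seeded;
deterministic early stop after 8 consecutive non-improving starts, best
rss wins, ties to the first index), followed by a tight-tolerance
polish, so refitting from the solution moves parameters by <1e-6
relative.  Default bounds: Eₐ ∈ [50, 800] kJ/mol, T* ∈ [300, 390] K.

**Weighting.** Per-dataset inverse variance, with the noise sd
estimated from the median absolute second difference of the curve
(σ ≈ MAD(Δ²y)/(√6·0.6745)).  Second differences cancel smooth signal,
so the estimate is unbiased even for traces that decay from the first
point — important because a biased (inflated) σ for fast isothermal
traces down-weights exactly the data that identify the second step.
Uniform weighting is available.

**Enthalpy dissection.** With scan-rate-limited data the split of the
total enthalpy between the two steps is poorly determined; following
standard practice the fit pins ΔH₁ or ΔH₂ to zero ("fix_dHcal1" /
"fix_dHcal2"), or fits both constraints and keeps the lower rss
("auto", the default; the choice is recorded in the result).

**Identifiability.** Fewer than two scan rates triggers a warning flag.
Standard errors come from the full finite-difference Jacobian at the
solution; when it is rank deficient (e.g. DSC-only data with ΔH₂ = 0
carry no information about step 2, or high-temperature isothermal
traces whose native/intermediate design columns vanish) the errors are
withheld and `jacobian_rank_deficient` is flagged rather than reporting
meaningless numbers.

**Curve descriptors.** tm_peak = argmax; tm_midpoint = midpoint of a
4-parameter logistic (fit-failure raised when the residual exceeds 25 %
of the amplitude or the midpoint leaves the data range); agg_max = max
within 20–80 °C by default; t_onset = first crossing of the
pre-transition mean + 5σ (k configurable; the onset definition is a
package choice since no standard exists); reversibility = 100 ×
∫reheat/∫first by trapezoid, flagged if >100 %.

## Macrostate assignment

**Features.** 1-D Cα RMSD to a native reference after Kabsch (SVD)
superposition, by default over residues 12–285 (flexible termini
excluded); trajectories shorter than a configurable minimum length can
be dropped.

**Discretisation.** k-means in 1-D: exact Lloyd iterations (10 inits)
up to 2·10⁴ frames, mini-batch k-means (batch 4096) beyond — small
inputs need the tight WCSS optimum (verified within 1 % of the exact
dynamic-programming 1-D optimum in the tests), large ones the speed.
Centres are re-ordered ascending so microstate ids are monotone in
RMSD.  Desk-scale default is 50–100 microstates (a production
trajectory set would use ~1000).

**MSM.** Sliding-window transition counts at the lag, restricted to the
largest strongly connected microstate set, row-normalised
(non-reversible maximum likelihood); a detailed-balance estimator
(symmetrised counts) is available behind a flag.  The stationary
distribution is the leading left eigenvector (π·T = π to 1e-10).  The
lag is fixed by configuration; an implied-timescales helper exists but
no automatic selection is performed.

**Coarse-graining.** PCCA-style spectral grouping: k-means (seeded) on
the microstates' coordinates in the top n_macro right eigenvectors.
Macrostates are ordered by stationary-weighted mean RMSD and labelled
folded / intermediate / unfolded; with n_macro = 4 the two middle
groups merge into a single intermediate so the output always has three
labels.  A degenerate spectral gap (eigenvalue tie within 1e-10) is
flagged and broken deterministically.  Macro-level transition matrices
are stationary-flux aggregates of the micro matrix.

**Validation.** Chapman–Kolmogorov: ‖T_est(fτ) − T(τ)^f‖_max per
factor, reported with a 3σ binomial sampling bound from the
directly-estimated counts.  The test is run on the *microstate* chain —
the object the Markov assumption is made on.  A known limitation:
the projected 3-label macro sequence carries a small (~0.01 absolute)
systematic CK excess that does not shrink with lag; this is the
textbook non-Markovianity of coarse-grained observables (emission
overlap produces label noise with memory), not an estimator defect.

**Per-state statistics.** Backbone B-factors B = (8π²/3)·⟨|r − ⟨r⟩|²⟩
per atom (residue value = mean over C, Cα, N, O) after iterative
superposition onto the state-mean structure; representative frames are
sampled uniformly without replacement with a seeded generator.

## Exposure analysis

**SASA.** Shrake–Rupley with a golden-spiral point lattice (default 960
points, probe 1.4 Å, Bondi vdW radii, hydrogens excluded by default).
Accuracy against closed forms: isolated sphere and the two-sphere lens
within 1 % at 960 points; doubling the point count changes a 50-atom
cluster's total by <0.05 %.  An independent implementation (mdtraj)
agrees within ~2 % on random clusters.

**rASA.** SASA divided by the Tien et al. theoretical maxima (bundled);
exposed means rASA ≥ 0.25, *inclusive*.  Values slightly above 1 are
tolerated (extended conformations), above 1.25 flagged.  Custom maxima
tables are supported — required for coarse-grained bead models, where
the natural normaliser is the isolated-bead area.

**Aggregation per state.** Default: mean rASA over frames, then
threshold; an "exposed in ≥50 % of frames" mode is available since the
choice between per-frame and per-state-average thresholding is a
genuine convention choice.  Exposure change between states:
newly_exposed = {i : native < 0.25 ≤ other}, newly_buried the reverse.

## Cryptic-APR analysis

APR segments are maximal runs of residues with aggregation score
*strictly* above 0.25 (scores are external predictor outputs; the
asymmetry — score > 0.25 vs rASA ≥ 0.25 — follows the respective
conventions of the two thresholds).  min_length defaults to 1
(faithful to a bare threshold definition) and is configurable since
single-residue APRs are rarely meaningful.  The overlap statistic is
100·|exposed ∩ ∪segments|/|exposed|; an empty exposed set yields an
explicit *undefined* flag, never 0.  A segment is cryptic iff it
contains ≥ min_hits (default 2) newly exposed residues and the majority
of its residues are natively buried.

Mutation strings ("E20S + F80R + …") are parsed tolerantly of stray
internal whitespace; when a sequence is supplied, wild-type letters are
validated against it and mismatches fail loudly (no renumbering
heuristics).  Surface hydrophobicity is the sum of min–max-normalised
scale values over natively exposed residues; the mutant sum substitutes
residue identities while keeping wild-type exposure status (no mutant
structure is predicted — a stated limitation), and the change is
reported in percent, independently per scale (Kyte–Doolittle and
Eisenberg consensus bundled; the choice of scales is a package default,
so absolute percentages are comparable only within a scale).

## Synthetic data

Generators draw from a single seeded `numpy.random.default_rng` stream
and are bit-reproducible.  Defaults define the study conditions used
throughout the tests:

- Kinetic truth Eₐ₁ = 300, T*₁ = 333 K, Eₐ₂ = 250, T*₂ = 341 K,
  ΔH₁ = 450, ΔH₂ = 0 kJ/mol — DSC peaks near 325–345 K with a ~3 K
  shift across 0.5→2 K/min, the regime of kinetically controlled
  unfolding; scan rates {0.5, 1, 2} K/min; noise i.i.d. Gaussian with
  sd given as a fraction (default 2 %) of each curve's amplitude;
  isothermal holds spanning 50–80 °C.
- Hidden-Markov RMSD series: metastable 3-state chain (self-transition
  0.98, stationary (¼, ½, ¼)), Gaussian emissions at 2/8/14 Å (sd 1 Å),
  initial states drawn from the stationary law.
- Toy ensembles: one bead per residue; a patch is sequestered inside a
  closed shell (radius 4 Å, spacing ~2 Å, which keeps shell and patch
  rASA far from the 0.25 threshold on either side) in the "native"
  state and translated outward in the "intermediate"; per-frame
  Gaussian jitter 0.1 Å.
- Score profiles: background ~0.1 (clipped ≤ 0.22), planted APRs ~0.6
  (clipped ≥ 0.30), so segmentation at 0.25 recovers the planted ranges
  exactly; overlapping planted ranges merge with a warning.

What the generators do *not* emulate: heteroscedastic or correlated
instrument noise, reversible refolding contributions, force-field-level
structural realism, sequence-dependent aggregation scores, or exposure
patterns coupled to real secondary structure.  Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not instrument-grade robustness on real data.

## Problem sizes

The test and reproduction runs use desk-scale sizes chosen to exercise
every code path: 20 replicate global fits (150-point scans × 6, 80-point
traces × 3), 10⁵-frame Markov series with 50 microstates, 56-bead
ensembles at 240–960 sphere points, and 1000 random overlap fixtures.

## Known limitations

- The enthalpy split between steps is structurally unidentifiable
  without the pinning constraint; "auto" reports which constraint won,
  not evidence that the losing one is wrong.
- Step-2 parameters are only as good as the data that see the
  intermediate; with ΔH₂ = 0 they rest entirely on spectroscopic
  baselines and isothermal traces.
- Macro-label sequences are not exactly Markov (above); CK validation
  is at the microstate level.
- LCPO-style SASA (used by some trajectory tools) differs slightly from
  Shrake–Rupley; downstream results depend only on 0.25-threshold
  crossings, which are robust to that difference.
- Mutant exposure status is frozen at the wild-type structure.
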