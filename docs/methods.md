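# Methods

## Delayed stochastic simulation algorithm

The engine (`silentsnp.ssa`) implements the Gillespie direct method for
uni- and bimolecular mass-action networks, extended with per-product release
delays. State is the vector of integer copy numbers plus a *waitlist* — a
time-ordered queue of scheduled releases. Each step draws a candidate
reaction time `t + Exp(a0)` from the total propensity `a0`; if the earliest
waitlist release precedes (or ties) the candidate, the clock jumps to the
release, the species count is incremented, and the exponential draw is
discarded and redrawn at the next step. Discard-and-redraw is exact because
the exponential distribution is memoryless; ties resolve release-first
because releases are deterministic scheduled events, and equal release
times drain in FIFO order so trajectories are reproducible.

Numerical/implementation choices:

- Counts are plain integers; propensities are recomputed from scratch every
  step (the translation network has only five reactions, so dependency
  tracking would buy nothing). The hot loop in `simulate()` consumes the
  random stream in exactly the same order as the public `step()` API, and a
  test asserts the two paths produce identical trajectories.
- Sampling is piecewise-constant and right-continuous on a uniform grid
  (default interval 10 s): each sample records the state immediately after
  the last event at or before the sample time. The recording grid is a
  convention of this package, as is the default horizon (see below).
- Each trajectory also records, per species, the number of molecules
  pending on the waitlist at every sample. This makes conservation checks
  exact: free + complexed + waitlisted totals can be asserted with zero
  tolerance instead of being inferred.
- RNG streams derive from `numpy.random.SeedSequence((master_seed, stream,
  replicate))`, so replicates and parameter sets are independent and any
  single run is reproducible in isolation.
- A constant source is modelled with an immutable source species held at
  count 1 (`Source → Source + X`); the translation model itself needs no
  such device.
- A dead system (zero propensity, empty waitlist) terminates the run and
  holds the final state to the end of the sample grid; it is not an error.

## Translation model

Five reactions coarse-grain translation of one mRNA around a focal codon
(see README for the scheme). Parameters and their defaults: `k_p1 = 0.01
/(molecule·s)` (ribosome–mRNA association, reused for the downstream
elongation step), `k_release = 1 /s` (unimolecular completion), `k_P_decay
= 3e-4 /s` (protein turnover, i.e. a ~55 min protein lifetime), delays
`τ_p1 = 10 s`, `τ_p2 = 25 s`, `τ_mRNA = 5 s`, `τ_Rib = 50 s`, `τ_prot =
300 s`, and initial counts `Rib = 100`, `mRNA₁ = mRNA₂ = 50`, `tRNA = 50`,
`Prot = 0`. A variant is a `(k_codon, τ_codon)` pair; the wild-type
reference is `(0.4e-3, 0.1)` and the SNP grid is `k_snp ∈
1e-3·{0.4, 0.8, 1.6, 4}` × `τ_snp ∈ {0.1, 1, 5}`.

Both mRNA halves start at 50 copies: they are two labels for one physical
mRNA pool, and both must be stocked for the first and third stages to
proceed; symmetric stocking is the only reading under which the two labels
mirror a single pool of 50.

Protocol: each parameter set runs 50 independent realisations; the
statistic per run is the time-weighted mean protein count over
`t > 10⁴ s` (the transient cutoff). The default horizon is `t_end = 3×10⁴
s`, chosen so the post-transient window spans 2×10⁴ s — more than two
protein-decay time constants beyond the cutoff — which puts the relative
standard error of a 50-replicate grand mean well under 1%. The ratio
surface divides each cell's grand mean by the shared WT reference grand
mean; its standard error combines both Monte-Carlo errors in quadrature.

### Mean-field cross-check

An independent flux-balance oracle (in the test suite, deliberately outside
the package) treats the stationary model as a cyclic queue: one flux `J`
runs through all four stages, Little's law converts each fixed delay into a
standing occupancy `J·τ`, and the pool-conservation plus mass-action-flux
equations close on a single scalar root for `J`; the plateau protein level
is `J / k_P_decay`. The deterministic solution ignores count–count
correlations, so only agreement within 15% is asserted; in practice the
stochastic means sit within ~1% of it at both the WT and SNP reference
points, because pool sizes of 50–100 molecules keep relative fluctuations
small.

## Drug-response classification

AUC values are standardised to Z-scores with the sample (n−1) standard
deviation, strictly within each (drug × dataset) stratum — AUC scales are
not comparable across source databases, so strata are never pooled. A line
is called sensitive when `z < −1.5`; equality at the cutoff is
non-sensitive (the strict inequality is a convention of this package).
Cohorts pool heterozygous with homozygous SNP lines (a dominant-effect
reading of the biomarker) and are compared with an unpaired two-tailed
t-test; Welch's unequal-variance form is the default, with a flag for the
classic pooled-variance test. A constant AUC column yields `t = 0`,
`p = 1` and no sensitive calls rather than an error.

## Synthetic panel generator

`generate_panel` emulates the structure of a mined cell-line panel: per
drug, AUC is Gaussian around a baseline (default mean 0.85, sd 0.08, the
scale of area-under-curve values normalised to 1); for designated effect
drugs every SNP-cohort line is shifted by `snp_effect` baseline-sd (default
−1), and a `sensitive_fraction` of SNP-cohort lines is shifted a further
`planted_shift` sd (the ground-truth positives). Default cohort sizes are
40 WT/WT, 20 WT/SNP, 10 SNP/SNP lines. A Student-t (df = 3) noise variant
sits behind a flag for robustness testing.

The planted depth was designed, not tuned: a planted line must fall below
`Z = −1.5` after standardisation against a panel whose sd the planted tail
itself inflates. With fraction `f` of a panel of `n` lines planted `D` sd
deep, the panel sd grows like `sqrt(1 + f·n·D²/(n−1))` and the planted
line's Z-margin below −1.5 must exceed ~2 of its own noise-sd for reliable
recovery. The defaults `f = 0.1` (of the SNP cohort) and `D = −5` satisfy
this with a wide margin; a shallow, common plant (e.g. a quarter of the
cohort at −3 sd) demonstrably does not — its recovery rate per line is only
~80% — which is why the defaults model a rare, strongly sensitive
subpopulation.

What the generator does **not** emulate: real GDSC/CTD2 marginal AUC
distributions, dose–response curve fitting, inter-drug correlations within
a line, BRCA-status covariates, or cell-line identities. Passing the
recovery and calibration tests therefore shows the pipeline is correct and
well-calibrated under Gaussian panel structure, not that the effect exists
in any real database.

## Known limitations

- The translation model is a single-codon coarse-graining: no codon-by-codon
  elongation, no tRNA recharging kinetics, no transcription. Absolute
  protein counts are not meant to match any measured abundance; only the
  SNP/WT ratio is interpreted.
- The delayed SSA supports at most bimolecular reactions and distinct
  reactant species — exactly what the model needs — and makes no attempt at
  tau-leaping or next-reaction efficiency.
- Z-scores are sensitive to panel composition; with small panels the
  planted-tail sd inflation discussed above applies to any real outlier
  screen as well.
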