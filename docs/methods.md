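# Methods

## The model

`perisilence` models transcriptional silencing of fission-yeast
pericentromeric repeats by the RNAi/H3K9-methylation feedback loop.  Three
variables are tracked: the concentration of repeat-derived long non-coding
RNA (`x1`), of siRNA (`x2`), and the fraction of methylated H3K9 sites
(`x3`, normalised to 1).  The repeat copy number `C` enters only through
the maximal transcription rate `C*alpha`: each repeat is transcribed
independently, so transcription is linear in `C` at fixed methylation.

Methylation feeds back three ways, each as a Hill function of `x3`:

* it represses transcription (coefficient `rho1 = 1`, half-max `k1`);
* it routes lncRNA into siRNA biogenesis instead of plain degradation
  (`rho2 = 2`, half-max `k2`) — the RITS/RDRC/Dcr1 feedforward loop;
* it cooperates with siRNA-guided methylation of free sites
  (`rho3 = 1`, half-max `k3`) — the Chp1/Clr4 read-write coupling.

Methylation is removed at rate `delta3`, spreads in *cis* at rate `phi`,
and occurs at a basal RNAi-independent rate `zeta`.  The `rho2 = 2`
cooperativity plus the methylation-gated siRNA route are what make the
system bistable: with few repeats the siRNA supply cannot sustain
methylation (desilenced state), with many repeats it can (silenced state),
and in between both states coexist.

The five-variable variant resolves three histone states — methylated
(`x3`), acetylated (`x4`) and unmodified (`x5`), with `x3+x4+x5 = 1`
conserved.  Only unmodified histones can be methylated or acetylated;
histone turnover `xi` replaces histones of any state with acetylated ones;
`delta4` (deacetylation) stands for HDAC (Sir2/Clr3) activity.  Summing the
three histone equations gives `xi*(1 - x3 - x4 - x5)`, so the simplex is
exactly invariant.

## Parameter values and calibration

Two values are fixed a priori: the lncRNA lifetime of 50 min
(`delta1 = 0.02 /min`) and the Hill coefficients `rho = (1, 2, 1)`.  The
remaining rates are not independently measured; the package ships one
reference ("wild-type") set, calibrated once against the qualitative and
threshold phenotypes the model is meant to exhibit, and then frozen:

* bistable for copy numbers 1–11, monostably silenced from 12 (wild type
  `C = 15` is silenced, with the silenced branch near `x3 ≈ 0.87`);
* deletion phenotypes: `epsilon = 0` or `gamma = 0` desilenced at every
  copy number; `delta3 = 0` silenced; `delta1 = 0` monostable and silenced
  above copy number 1; `delta2 = 0` bistable only at copy number 1;
  `phi = 0` bistable from copy number 2 out to ~38;
* ±25% sensitivity thresholds: the demethylation-rate band is uniformly
  silenced first at copy number 28 and the spreading-rate band at 17.

The calibration exploited the structure of the reduced model (below):
fixed points satisfy `C = R(x3)`, so the saddle-node folds are local
extrema of `R`, and their elasticities with respect to each rate can be
matched to the target thresholds.  Two scale freedoms (the units of `x1`
and of `x2`) are fixed by convention: `alpha = 0.004` puts the unrepressed
RNA level at `0.2*C`, and `delta2 = 0.00125 /min` (siRNA turnover much
slower than RNA turnover, as expected for Argonaute-bound species) sets
the siRNA scale; both rescalings leave every methylation trajectory
invariant.

Two further threshold targets considered during calibration (a `delta1`
band threshold of 12 and an `epsilon` band threshold of 14) are *provably
unreachable* in this model family and are reported as the model gives
them (15 and 16):

* `C` and `epsilon` enter the fixed-point equations only through the
  product `C*epsilon`, so the epsilon-band threshold is forced to
  `ceil(B/0.75)` where `B ∈ (11, 12)` is the bistable boundary — i.e. 15
  or 16, never 14.
* at the desilenced fold the elasticity ratio
  `el_phi/el_delta3 = phi*(1-x3)/delta3` together with the slope budget
  needed to sustain the fold couples the `delta1` and `delta3` thresholds;
  any set with the `delta3` threshold at 28 has a `delta1` fold ratio near
  the full 1.25 scaling, putting the `delta1` threshold at 14–15, not 12.

The five-variable shared rates equal the three-variable ones;
`epsilon, phi1, zeta1` are divided by the acetylation partition
`delta4/(delta4+zeta2) = 0.8` so that with slow turnover
(`xi = 5e-4 /min`) the effective methylation fluxes — and hence the
copy-number phenotypes — carry over.  Lowering `delta4` (weaker HDAC)
raises the acetylated fraction, starves methylation of substrate and
desilences the wild type; `delta4 = 0` abolishes methylation entirely.

## Quasi-steady-state reduction and fixed points

RNA relaxes on the `1/delta1 = 50 min` timescale, much faster than siRNA
(`1/delta2 = 800 min`), so `x1` is taken at its equilibrium for the
current `(x2, x3)`.  The two nullclines of the reduced system are closed
forms in `x3`; the siRNA nullcline is linear in `C`, the H3K9me nullcline
is `C`-independent and singular at `x3 = 0, 1`.

Fixed points are found by evaluating `dx3/dt` along the siRNA nullcline on
a uniform 4001-point grid over `(1e-6, 1-1e-6)` and bisecting every sign
change to `|dx3| < 1e-12`.  This formulation is equivalent to intersecting
the nullclines when `epsilon > 0` (the negative-siRNA branch of the
H3K9me nullcline is excluded automatically) and remains well defined at
`epsilon = 0` or `gamma = 0`, where the unique root is the basal
methylation balance.  The grid density resolves root pairs separated by
more than ~5e-4; more than three roots is treated as an error, not
truncated.  Stability comes from the eigenvalues of the reduced 2×2
Jacobian (central differences, step 1e-7); tests confirm the sign pattern
always agrees with the full 3×3 Jacobian.

Regime labels: desilenced below `x3 = 0.2`, silenced above `x3 = 0.5`,
intermediate between.  The 0.5 cutoff is this package's choice (the
silenced branch sits at 0.7–0.9 over the relevant copy numbers, the
desilenced branch below 0.01, so any cutoff in (0.2, 0.7) gives identical
classifications at the defaults).  Saddle nodes are reported as the grid
interval over which the stable-point count changes — matching the integer
copy-number resolution of the scans — rather than continued to the fold.

## Full-model bifurcation protocol

For each copy number the three-variable model is integrated for
25,000 min (LSODA, `rtol 1e-8`, `atol 1e-10`) from a deterministic lattice
of 24 initial states: RNA in {0, unrepressed equilibrium}, siRNA in
{0, nullcline value at full methylation}, methylation in
{0, 0.25, 0.5, 0.75, 0.9, 1}.  The lattice is always built from the
*reference* parameter scales so deletion and sensitivity scans probe the
same initial states as the wild-type scan.  Endpoint methylation values
are split by deterministic 1-D k-means (k = 2, centroids seeded at the
extremes, so the scalar clustering has no run-to-run stochasticity);
cluster means differing by more than 0.085 means bistable.  Endpoints are
verified to land within 1e-3 of a stable reduced-model branch, and the
bistable/monostable call agrees with the reduced-model stable-point count
at every copy number scanned.

`find_attractor` declares convergence when the RHS max-norm at 25,000 min
is below 1e-7; non-convergence is flagged, never silently returned.  The
solver is trusted to keep `x3` in [0, 1] (the flow is forward-invariant);
recorded fractions are clipped, with a warning if the excursion exceeds
1e-6.

The random-initial-condition fractions use `x3 ~ U(0,1)` and
`x1, x2 ~ U(0, 2× silenced scale)`.  Limitation: with the calibrated set
the desilenced branch sits at `x3 ≈ 0.005` and its basin occupies a thin
slab of this box, so both basins are reliably sampled only at copy
numbers 1–2; the desilenced fraction still decreases monotonically with
copy number, but quantitative basin-fraction curves should not be read
off this distribution.

## Sensitivity and deletion scans

Sensitivity maps classify every (parameter value, copy number) cell on a
21-point grid spanning ±25% of the reference value × copy numbers 1–40,
using the reduced-model fixed-point structure (two stable points →
bistable; otherwise the single branch's regime label).  A monostable
intermediate state would be reported as its own label, never coerced.
Deletion experiments instead use the full-model endpoint protocol, because
the reduction is unavailable at `delta2 = 0` (siRNA no longer decays;
whether a copy number *appears* bistable there is a question of transit
time through the 25,000-min window, which is exactly what the endpoint
scan measures).  Branch RNA levels are read off the RNA quasi-equilibrium
at the branch methylation level.

## Stochastic simulation

The exact SSA maps concentrations to counts: RNA and siRNA are rescaled
by `omega` (default 100; `N2 ≈ 2100` at the silenced wild type), and
methylation becomes `M` out of `n_sites_per_copy * C` sites
(default 20/copy → 300 sites at `C = 15`; the per-copy site count is a
resolution choice, set so site noise is comparable to the rescaled
molecule noise).  Channel propensities follow mass-action volume scaling:
transcription scales with `omega*V`, first-order channels are volume-free,
and the bimolecular siRNA-guided methylation uses the siRNA concentration
`N2/(omega*V)`.  A test verifies the propensities reproduce the ODE terms
exactly in the deterministic limit.

Cell volume grows linearly from `v_min = 2/3` to `v_max = 4/3` (mean 1)
over one division time and is evaluated exactly at every propensity
computation (no event-order artifact); without division `V = 1`.  At each
division RNA, siRNA and methylated sites are halved (`floor(n/2)`;
binomial partitioning is available as a config option) and the volume
resets.  Extrinsic noise adds three channels with rates `beta * count`
firing ±1 steps with equal probability, clamped to the count bounds.
Runs start on the silenced deterministic branch (the wild-type state) and
the first 4,000 of 10,000 min are discarded as burn-in.  The silencing
fraction is the fraction of post-burn-in samples with methylation above
0.5 (midpoint between the branches; the quantity of interest is
distributional, so the threshold choice is uncritical), averaged over
replicates (replicate r uses seed `seed + r`).

The kernel is numba-compiled and uses NumPy's legacy MT19937 generator
seeded inside the kernel, so a given `(parameters, config, seed)` triple
is bit-reproducible.  A runaway total propensity (> 1e9/min) aborts with
diagnostics.

Problem sizes used in the shipped analyses: the deterministic scans run
the full protocol (24 ICs × copy numbers 1–20 or 1–40 grids); the
SSA-vs-ODE check uses `omega = 1000` with 200 sites/copy and 8
replicates; trend grids use 3 division times × 3 noise rates with 12–20
replicates, and single-condition fractions use the full 50 replicates.

## Known limitations

* Parameter values are calibrated to phenotypes, not fitted to
  measurements; only ratios and thresholds, not absolute concentrations,
  should be interpreted.
* No spatial structure: repeats are pooled, with no nearest-neighbour
  coupling, boundary elements or 3D compaction.
* Single-cell line with synchronous divisions; no population or lineage
  bookkeeping.
* The ±25% sensitivity thresholds for `delta1` and `epsilon` printed by
  this package (15 and 16) follow from the structural constraints
  described above and cannot be moved to 12/14 without changing the model
  family (e.g. decoupling the transcription and biogenesis Hill
  functions or adding a second siRNA sink).
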