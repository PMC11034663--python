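# perisilence

Deterministic and stochastic models of RNAi-dependent H3K9 methylation at
the pericentromeric repeats of fission yeast, with the repeat **copy
number** as an explicit control parameter.

Pericentromeric heterochromatin in *S. pombe* is nucleated by an
RNAi feedback loop: repeat-derived lncRNAs are processed into siRNAs in a
methylation-dependent way, siRNAs guide further H3K9 methylation, and
methylation represses transcription.  Because every repeat copy is
transcribed independently, the strength of this loop scales with the
number of copies.  This package asks — and lets you recompute — when that
loop locks into stable silencing: for whom is it useful?  Modellers of
chromatin-based epigenetic memory, and experimentalists who want a
quantitative null model for copy-number, deletion and growth-rate
perturbations of pericentromeric silencing.

## The model

Three coupled ODEs for lncRNA `x1`, siRNA `x2` and the methylated fraction
of H3K9 sites `x3` (Hill functions `H_i(x) = (x/k_i)^ρi / (1+(x/k_i)^ρi)`):

    dx1/dt = C·α/(1+(x3/k1)^ρ1) − δ1·x1 − γ·x1·H2(x3)
    dx2/dt = γ·x1·H2(x3) − δ2·x2
    dx3/dt = ε·x2·(1−x3)·H3(x3) − δ3·x3 + φ·(1−x3)·x3 + ζ·(1−x3)

with ρ = (1, 2, 1).  A quasi-steady-state reduction (RNA equilibrated)
turns steady states into intersections of two nullclines in the
`(x3, x2)` plane; the siRNA nullcline is linear in the copy number `C`,
so raising `C` sweeps the system through a saddle-node bifurcation from
bistability (silenced *and* desilenced states coexist) to a single
silenced state.  A five-variable variant adds acetylated/unmodified
histone states and HDAC activity, and an exact Gillespie simulation adds
molecule-level noise, linear cell growth, division (a two-fold dilution
of RNA, siRNA and methylation marks) and an extrinsic random-walk noise
channel.

## Worked example

```python
import perisilence as ps

wt = ps.default_parameters("three")          # reference set, C = 15

# wild type: a single, silenced steady state
for fp in ps.find_fixed_points(wt):
    print(f"C=15  x3={fp.x3:.3f}  {fp.stability}  {fp.regime}")

# five repeat copies: two stable states separated by an unstable one
for fp in ps.find_fixed_points(wt.replace(copy_number=5)):
    print(f"C=5   x3={fp.x3:.4f}  {fp.stability}  {fp.regime}")

# where does bistability end?  (full model, 24 ICs x 25,000 min, k-means)
result = ps.full_bifurcation_diagram(wt, cn_range=range(1, 21))
print("largest bistable copy number:", result.largest_bistable_cn)
```

prints

```
C=15  x3=0.872  stable  silenced
C=5   x3=0.0052  stable  desilenced
C=5   x3=0.0202  unstable  desilenced
C=5   x3=0.7141  stable  silenced
largest bistable copy number: 11.0
```

The wild-type repeat count (~15) sits safely in the monostable silenced
regime with ~87% of H3K9 sites methylated; at 5 copies the same cell
could inherit either fate (methylation 0.5% or 71%), and the switch
between the two behaviours happens between 11 and 12 copies — silencing
is a sharp, copy-number-thresholded property.

The same analyses are available from the shell:

```
perisilence --out results bifurcation --cn-min 1 --cn-max 20
perisilence --out results deletion --param epsilon      # clr4Δ-like
perisilence --out results sensitivity --param delta3
perisilence --out results --seed 7 ssa --division-time 240 --noise-rate 1
```

Every command writes RFC-4180 CSV plus a `*.provenance.json` sidecar
recording the exact parameters, seed and package version.

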