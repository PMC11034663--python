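# Reference ("wild-type") parameter sets for the pericentromeric silencing
# models.  Units: rates in min^-1 (alpha in concentration min^-1 per repeat
# copy; epsilon per siRNA concentration per min); Hill half-max constants are
# methylation fractions in (0, 1]; copy_number 15 corresponds to the dg/dh
# repeat count of wild-type S. pombe.
#
# delta1 = 1/50 min^-1 (lncRNA lifetime 50 min) and the Hill coefficients
# rho = (1, 2, 1) are fixed model choices.  The remaining rates were
# calibrated once so that the reference phenotypes of the wild-type model
# hold: the deterministic system is bistable for copy numbers 1-11 and
# monostably silenced for 12 and above, the demethylation-rate (+/-25%) sweep
# becomes uniformly silenced first at copy number 28 and the spreading-rate
# sweep at 17, deletions reproduce the qualitative phenotype table
# (epsilon=0 / gamma=0 desilenced, delta3=0 silenced, delta1=0 monostable
# silenced above copy number 1, delta2=0 bistable only at copy number 1,
# phi=0 bistable out to large copy number), and the silenced branch sits
# near x3 ~ 0.87 at copy number 15.  See docs/methods.md for the
# calibration rationale and for the trade-offs this entails.

three_state:
  alpha: 0.004        # transcription rate per repeat copy
  delta1: 0.02        # lncRNA degradation rate (lifetime 50 min)
  delta2: 0.00125     # siRNA degradation rate (Argonaute-stabilised)
  delta3: 0.094       # H3K9 demethylation rate
  gamma: 0.2          # siRNA biogenesis (RDRC/Dcr1) rate
  epsilon: 0.03       # siRNA-guided methylation rate
  phi: 0.034          # methylation spreading rate
  zeta: 0.00029       # basal (RNAi-independent) methylation rate
  rho1: 1.0           # Hill coefficient, transcriptional repression
  rho2: 2.0           # Hill coefficient, siRNA biogenesis
  rho3: 1.0           # Hill coefficient, siRNA-guided methylation
  k1: 1.0             # half-max methylation, transcriptional repression
  k2: 1.0             # half-max methylation, siRNA biogenesis
  k3: 0.02            # half-max methylation, siRNA-guided methylation
  copy_number: 15

# Five-variable model: histone H3K9 exists in methylated (x3), acetylated
# (x4) and unmodified (x5) states; only unmodified histones can be
# methylated or acetylated, and histone turnover (xi) replaces histones with
# acetylated ones.  Shared rates equal the three-state values; epsilon, phi
# (here phi1) and zeta (here zeta1) are divided by the steady acetylation
# partition delta4/(delta4+zeta2) = 0.8 so that the effective methylation
# fluxes, and hence the copy-number phenotypes, match the three-state model.
five_state:
  alpha: 0.004
  delta1: 0.02
  delta2: 0.00125
  delta3: 0.094
  gamma: 0.2
  epsilon: 0.0375
  phi1: 0.0425
  zeta1: 0.00036
  rho1: 1.0
  rho2: 2.0
  rho3: 1.0
  k1: 1.0
  k2: 1.0
  k3: 0.02
  copy_number: 15
  xi: 0.0005          # histone turnover rate
  zeta2: 0.02         # acetylation rate
  delta4: 0.08        # deacetylation (HDAC) rate
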