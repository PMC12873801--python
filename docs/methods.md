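# Methods

## The reduced model and what it is for

The package's kinetic core is deliberately a *reduced* model.  Published
whole-pathway glycolysis models carry ten or more enzyme rate equations
fitted to in vitro kinetics; here the pathway is lumped into three stages
around the one enzyme whose regulation is under study — PFK — plus a
single reversible ATP synthase standing in for respiration, a fixed-Vmax
ATPase standing in for cellular ATP demand, and adenylate kinase so that
AMP (a PFK effector) is defined.  The reduction preserves the regulatory
architecture that the scientific question needs: an MWC-regulated control
point whose activity F26BP can tune, fermentation yielding 2 ATP per
glucose, respiration yielding ATP from ADP and Pi, and a demand that pins
total production.  It does not attempt to reproduce absolute metabolite
concentrations of any real cell type.

Units are SI (molar, seconds) throughout the model; experimental units
(nmol/h/µg, pmol O2/min) exist only at the I/O boundary of the accounting
module, which converts exactly or raises.

### Rate laws and parameters

* **ATP synthase.** Reversible Michaelis–Menten with competitive product
  inhibition; K_M,ADP = K_M,Pi = 1e-5 M, K_eq = 1e6 M⁻¹, and K_M,ATP =
  1000 M.  The last value is kept exactly as the model convention even
  though it is not a physiological affinity: its role is to remove ATP
  competitive inhibition from the denominator, and "fixing" it would
  change the model's behaviour.
* **MWC PFK.**  Exclusive R-state substrate binding (c = 0), n = 4
  (tetramer), effectors scaling the allosteric constant L by (1+x/K)^n:
  activators F26BP (K 5e-7 M), ADP (3e-5 M), AMP (1e-4 M), Pi (2e-3 M);
  inhibitors ATP (1e-3 M) and citrate (1e-3 M); L0 = 4000, K_R = 1e-4 M,
  catalytic ATP site K = 1e-4 M.  These constants are stand-ins chosen to
  give strong F26BP responsiveness over the 1e-8–1e-4 M clamp window; all
  are overridable.  The ADP activator constant is deliberately strong
  enough that at high glycolytic shares — where the steady-state ADP pool
  is larger because the synthase must run nearer its capacity — PFK is
  already partially activated, so the *fold* effect of F26BP shrinks as
  the glycolytic share of demand grows (from ~7.5x at a respiratory
  capacity fraction of 0.9 down to ~5x at 0.2).  That is the package's
  reading of "the effect of F26BP is larger at low glycolytic rates": the
  absolute flux difference instead scales with glycolytic capacity and
  therefore *decreases* with the respiratory fraction, a structural
  property of any model in which the activated flux is supply-capped
  proportionally to capacity.  `scan_respiration_fraction` reports both
  measures.
* **Lumped stages.**  The upper stage (HK/PGI) is Michaelis–Menten in
  glucose and ATP with an F6P product-inhibition factor 1/(1+[F6P]/1e-5 M).
  This factor is essential, not cosmetic: it stands in for hexokinase
  inhibition by hexose phosphates.  Without it the upper stage feeds F6P at
  a fixed rate regardless of downstream congestion, and the model exhibits
  the classic "turbo design" failure — FBP accumulates without bound,
  sequesters the phosphate pool, and the adenylate pool collapses to AMP.
  The same robustness argument sets the lower stage's ADP and Pi constants
  (1e-5 and 1e-4 M): the steady-state ADP pool sits near the synthase's
  K_M,ADP = 1e-5 M, and the lower stage must remain responsive there or an
  F26BP clamp jump transiently outruns it and triggers the same collapse.
  Upper and lower Vmax are set to 5x the PFK flux capacity by the capacity
  split, so they never limit in normal operation.
* **ATPase demand.**  K_M = 1e-9 M, so the demanded flux is constant to
  ~1e-5 relative even in corner states where ATP settles below 0.1 mM
  (pure glycolysis at saturating F26BP).  This constancy is what makes
  "total production equals demand" an exact model property rather than an
  approximation.
* **Adenylate kinase.**  Mass action, k = 1e5 M⁻¹s⁻¹, K_eq = 1, i.e.
  rapid near-equilibrium; AMP ≈ [ADP]²/[ATP].
* **Conserved pools.**  Adenine 5 mM, phosphorus 19.05 mM, both fixed by
  the default initial state (ATP 4 mM, ADP 0.9 mM, AMP 0.1 mM, Pi 5 mM,
  F6P = FBP = 50 µM); glucose clamped at 5 mM, matching the assay medium.
  Clamped species are parameters with zero derivative, so both
  conservation laws are exact properties of the stoichiometry.

### Numerics

Steady states are found by stiff integration (Radau, LSODA fallback;
rtol 1e-8, atol 1e-15) over doubling horizons from 1e3 s up to a 1e7 s
cap, stopping when max|dx/dt| / max(|x|/τ, 1e-15) < 1e-10 with τ = 1 s.
The tight residual keeps integrated steady states within 1e-8 of the
algebraic root of the derivative system (the test suite checks this
against an independent log-space root solve with ATP and Pi eliminated
through the conservation laws).  Scans warm-start each clamp level from
the previous converged state.  Demand infeasibility — ATP collapsed *and*
the ATPase delivering materially less than its Vmax — raises a distinct
error rather than returning a "converged" collapsed state, which is
itself a genuine fixed point of the equations.

At very high F26BP clamps with a low respiratory capacity share the
reversible synthase can run net-backward (glycolytic supply pushes
[ATP]/([ADP][Pi]) above K_eq).  This is a direct consequence of the
printed reversible rate law and is left visible in scan outputs rather
than clamped.

## Assay analyses

* **Longest linear slope.**  All contiguous windows spanning at least the
  minimum duration (1 min for the PPi-PFK assay, 10 min for the
  reconstituted assay) are scored by OLS; the longest window with
  R² ≥ 0.99 wins, ties broken by earliest start.  The R² criterion is the
  package's operationalisation of "linear region" (only the minimum window
  length is prescribed by the protocol); it is exposed as a parameter.  If
  no window qualifies (flat noisy controls), the best minimal window is
  returned flagged.
* **EC50-dilution quantification.**  Relative rates (each slope over the
  no-F26BP control slope) are fitted in log-dilution space with a
  four-parameter logistic whose top and bottom are fixed to the positive
  and negative control rates; the Hill slope is free by default.  The
  fitted half-maximal dilution is assigned 5 nM F26BP in the assay well;
  the extract concentration follows by multiplying back through the
  dilution chain, which the caller supplies explicitly (the well-to-extract
  factor is protocol-dependent and not hard-coded).  EC50s outside the
  sampled dilution range are flagged extrapolated and propagate a
  low-confidence flag to the concentration.
* **ATP accounting.**  Glycolytic ATP = lactate secretion rate (OLS slope
  of the 2/4/8 h time course per µg protein); respiratory ATP =
  24 × leak-corrected OCR per µg protein, the yield being a configurable
  constant.  Negative leak-corrected OCR clamps to zero with a warning —
  it occurs in noisy wells and an error would be wrong there.  ECAR is
  carried as an auxiliary observable only.
* **Screen and titrations.**  Screen fold-change is background-subtracted:
  (measured − no-F6P)/(control − no-F6P).  Titrations are fitted with a
  one-parameter Hill-1 inhibition curve (top 1, bottom 0); the standard
  error comes from the log-scale parameter by the delta method.  The
  default PFKFB3 effector constants (PEP 1e-4 M most potent, then
  cis-aconitate/2PG, then citrate/3PG; Pi activating up to 2-fold) are
  synthetic-data settings reproducing the screen's qualitative potency
  ordering, not measured constants — quantitative K_i fitting to the
  original titrations is out of scope because those points are not
  tabulated.
* **Coupled assay simulation.**  Two phases: 20 min of PFKFB3 alone
  (F6P → F26BP), then 60 min with PFKP added.  The aldolase/TPI/G3PDH
  coupling system is treated as instantaneous (enzymes in excess), so each
  FBP consumes exactly 2 NADH and the readout conversion is exact; NADH
  depletion terminates the readout by event detection and floors the
  trace, flagged.  ATP, ADP and Pi are non-depleting at assay scale.
  PFKFB3 is kinase-only by default (kinase-dominant isoform); a
  phosphatase term exists and defaults to zero.  PFKP uses the MWC law
  with the weaker (3e-4 M) ADP activator constant so that the assay's
  10:1 ATP/ADP composition leaves it strongly ATP-inhibited unless F26BP
  relieves it — this is what makes PEP inhibition strictly conditional on
  PFKFB3's presence.

## Synthetic data

Each generator inverts exactly one analysis stage: linear-then-saturating
NADH traces (slope-continuous exponential knee once the signal nears the
depletion floor, one read per 6 s), dilution series following the
calibrated hyperbolic response (EC50 dilution = well concentration /
5 nM), and paired lactate/OCR well sets consistent with the accounting
formulas at a specified glycolytic fraction, total ATP rate (default
30 pmol/min/µg, a typical cultured-cell scale) and leak fraction (0.2).
Noise is additive Gaussian on the observed signals, never on parameters,
and all generators are bit-reproducible per seed with ground truth
embedded in the returned objects.

What they do not emulate: instrument drift, plate-edge effects, well
covariates, heteroscedastic detector noise, or biological replicate
variance.  Passing round-trip tests therefore demonstrates correctness of
the estimators under the stated noise model, not robustness to every
failure mode of real plates.

## Problem sizes and determinism

Default scans use 25 logarithmic clamp levels; the test suite and the
acceptance script use 25-point scans, 4 random capacity splits, 24-well
accounting sets and 10-seed fit-recovery ensembles — sizes chosen so a
full run completes in well under a minute on one CPU while keeping
Monte-Carlo assertions stable.  All randomness flows from explicit seeds;
the acceptance script derives every internal seed from its `--seed`
argument.

## Known limitations

* The MWC constants and lumped-stage parameters are stand-ins; absolute
  fluxes and metabolite levels are not calibrated to any cell line.
* Exclusive R-state binding (c = 0) cannot represent partial T-state
  catalysis; with the (1+x/K)^n effector scaling, PFK loses essentially
  all energy-state feedback at saturating F26BP, which is why the
  supply-side cap (upper-stage F6P inhibition) then sets the glycolytic
  rate.
* No NAD⁺/NADH redox state, pH, FBPase/TIGAR back-flux, or time-varying
  F26BP driven by PFKFB expression dynamics.
* The accounting assumes fixed stoichiometric yields (2 ATP/lactate,
  24 ATP/O2); deviations from full coupling are not modelled.
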