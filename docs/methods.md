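# Methods

## Model

`pif4net` simulates a minimal gene-regulatory network for the
threshold-dependent negative autoregulation of PIF4 in *Arabidopsis*
seedlings. Six state variables evolve over time t (hours): photoactive
phytochrome B `B`, ELF3 `E`, COP1 `C`, PIF4 `P`, a PIF4-promoter-driven GUS
reporter `F` (all in arbitrary concentration units) and hypocotyl length `G`
(mm). The equations are reproduced in the README. Key structural
assumptions:

- **Hard threshold switch.** Autoinhibition of PIF4 synthesis (`pself`) and
  the PIF4-linked reporter production term `pF/(1 + pFP·P)` are active
  exactly on the set `P ≥ P*`. The boundary `P = P*` is assigned to the
  active branch; this measure-zero convention only matters for determinism
  of the event logic. There is no hysteresis — the branch is a pure function
  of the current P.
- **Light forcing.** `L(t)` is binary. Within a protocol segment, lights-on
  defines Zeitgeber time 0 and the diurnal clock is segment-local, so a
  shift protocol (e.g. five days of constant light followed by a dark day)
  restarts its phase at the shift. ELF3 synthesis follows the oscillatory
  form with logistic transitions of sharpness α and collapses to the exact
  constant limits pE1 + pE2 (day length 0) and pE1 − pE2 (day length 24).
- **Temperature.** Temperature enters as a discrete label (22 / 27 °C)
  selecting a parameter variant for the temperature-dependent subset
  (pB, kr, pE1, pE2, pPE, pCL, k0, P*, pself); switches are instantaneous at
  protocol boundaries. No continuous temperature dependence is modeled.
- **Growth equation grouping.** `dG/dt = pG + kG·pGP·P/(1 + pGE·E + pGB·B)`:
  the basal elongation rate pG is unconditional, and only the PIF4-driven
  term is damped by ELF3 and phyB. The alternative grouping with a shared
  denominator is available behind the
  `growth_grouping_shared_denominator` flag; the default was chosen because
  PIF4-null seedlings still elongate, implying an ELF3/phyB-independent
  basal term.
- **`mutB` semantics.** The phyB factor scales the photoconversion capacity,
  `pB·L·(mutB − B)`, i.e. the pool size rather than the synthesis rate, as
  the equation is written.
- **Genotypes.** A genotype is a set of multiplicative production factors
  (mutB, mutE, mutC, mutP) plus optional overrides of exactly {P*, pself,
  pFP} — the same three quantities the per-genotype calibration is allowed
  to vary. Red-light and tissue-specific conditions are not separate input
  channels; they are represented by different autoinhibition strengths
  (presets use the strength variants 25 / 75 / 15 for low / red-light-like /
  cotyledon-like inhibition).

## Discontinuity handling

Light transitions and temperature shifts occur at known times; the
integrator (scipy's RK45 with events) restarts there. Threshold crossings
are localized by root-finding on `P − P*`. At a crossing both one-sided
derivatives of P are evaluated:

- if the receiving branch pushes P onward, the crossing is transversal and
  integration continues on that branch (the state is continuous; only the
  vector field jumps);
- if both one-sided fields point **toward** the surface, the exact solution
  slides along `P = P*` (Filippov). The integrator then pins P at the
  threshold (dP/dt = 0, reporter on the active branch, all other equations
  evaluated at P = P*) and leaves the sliding segment when one of the
  one-sided derivatives changes sign, located again by root-finding.

Sliding is not an edge case here: the printed strong-feedback variants
(pself = 25, 75) and several overexpressor genotypes drive the night-time
PIF4 level onto the threshold. Handling it as a sliding mode gives clean
event sequences (threshold events strictly alternate in direction; sign of
P − P* is constant, possibly zero, between events) instead of solver
chattering. A guard still aborts with a diagnostic if an inter-breakpoint
interval needs more than `max_restarts_per_interval` (default 500) restarts.

The independent fixed-step reference (`reference_rk4`, classical 4th-order,
default h = 10⁻³ h) uses the same branch semantics: it steps on the smooth
branch of the current side, bisects crossings inside a step, and pins P
while the sliding condition holds, bisecting the exit time. Adaptive and
reference solutions agree to ~3·10⁻⁶ max-abs over a diurnal cycle on the
shipped wild type.

Interpolation between stored samples is linear; endpoint observables
(day-6 hypocotyl, harvest-time reporter) sit on exact sample nodes because
segment boundaries and day boundaries are breakpoints. Default tolerances
rtol 10⁻⁶ / atol 10⁻⁹ leave day-6 G stable to < 0.1% under 10× refinement;
fitting and synthetic-data generation use a coarser sampling cap
(max_step = 2 h) that changes endpoint observables by < 10⁻⁷ relative while
roughly halving runtime.

## Default calibration (repository-derived)

No machine-readable parameter values or raw measurements accompany the
study this model describes, so the shipped `ParameterSet` and
`GenotypeRegistry` are **calibrated within this repository** and are not
published values. The calibration proceeded in the order a practitioner
would:

1. **Scales.** Base rates were set on physiological scales: phyB
   photoconversion fast relative to its dark reversion (pB = 2 h⁻¹,
   kr = 0.19 h⁻¹, i.e. a ~3.6 h half-life so phyB persists into the night);
   COP1 higher in darkness (pCD/pCL = 4); ELF3 oscillating 0.2–1.8 conc/h;
   PIF4 turnover on the hour scale with strong COP1 stabilization (kPC = 3)
   and strong light-dependent degradation (dPB = 7).
2. **Threshold region.** P* = 0.6 and pself = 8 place the wild type below
   threshold in constant light and during the photoperiod day, with a
   night-time up-crossing a few hours after dusk — this single choice
   reproduces, qualitatively, dark-induction of the reporter after a shift
   to darkness, the end-of-night (ZT23) reporter activity in short days,
   and a diurnal PIF4 oscillation riding on the threshold.
3. **Growth parameters.** Day-6 wild-type hypocotyl anchors at day lengths
   4/8/12/16 h were fixed at 6.5 / 5.0 / 3.5 / 2.3 mm — realistic magnitudes
   for these photoperiods — and (pG, kG) were fitted to them by the
   package's own least-squares machinery with pself held fixed
   (R² ≈ 0.98). The anchors are packaged in
   `pif4net.defaults.WT_HYPOCOTYL_ANCHORS_MM`.
4. **Genotype factors.** mutK magnitudes were chosen so the simulated
   panels reproduce the observed orderings: overexpressor dose series
   (mutP = 2.5 / 5 / 8), near-null pif4-101 (mutP = 0.05), strong/weak COP1
   alleles (mutC = 0.1–0.15), phyB null and overexpressor
   (mutB = 0.05 / 2). The phyB overexpression factor is deliberately
   moderate: a larger pool delays the night-time threshold crossing so much
   that the reporter readout at ZT23 drops below the wild type, contrary to
   observation.
5. **pif4-101 threshold override.** With the printed reporter equations,
   the below-threshold branch produces only basal reporter (k0), so a
   genotype whose PIF4 never reaches the threshold would show the *lowest*
   promoter activity — while the PIF4 null is observed to show the highest.
   Since the threshold is a per-genotype calibration quantity, the shipped
   registry assigns `pif4-101` a near-zero P* (0.01): its residual PIF4
   keeps the promoter on the active branch at negligible self-repression,
   yielding maximal reporter output. This is a calibration device, recorded
   here because it is load-bearing for the panel orderings.
6. **27 °C variants** implement the assumed directions of change without
   fitting: weaker phyB input (lower pB, faster kr), weaker ELF3 repression,
   higher threshold and slightly weaker feedback (P* = 0.75, pself = 6).

Known consequences of the printed reporter branch structure, visible in
simulations and accepted as model behavior: under constant light the
overexpressor baseline reporter exceeds the wild-type baseline (the wild
type sits below threshold, at basal production, until darkness pushes it
over), and at the long-day ZT4 harvest the overexpressors exceed the wild
type for the same reason. The short-day ZT23 panel — the primary comparison
point — shows the observed ordering.

## Fitting

`fit_wildtype` is trust-region-reflective least squares
(`scipy.optimize.least_squares`) on replicate-level residuals: one residual
per observed seedling, observed minus simulated day-6 hypocotyl at that
row's day length (replicates weigh, they are not averaged). Rows are
canonically sorted before fitting, so estimates are bit-identical under
permutation of the input. Standard deviations come from the Gauss–Newton
covariance s²(JᵀJ)⁻¹ at the optimum (the `uncertainty_method` field names
this; replicate resampling can be layered on top by refitting seeded
resamples). R² is reported over the replicate observations, and the
Jacobian condition number is returned as an identifiability diagnostic with
a log warning above 10⁵.

Two shipped free-parameter sets:

- `default_calibration_spec` — seven parameters (pG, kG, pself, pP, pPE,
  dP, dPB), mirroring a seven-parameter wild-type calibration. With only
  four distinct day-length means this set is deliberately over-parameterized
  and is *not* jointly identifiable; the condition-number diagnostic flags
  this. It exists to reproduce the calibration workflow, not for recovery
  claims.
- `default_recovery_spec` — (kG, pself), the subset that a four-day-length,
  20-replicate, 0.5 mm-noise design actually identifies (expected relative
  standard errors ≈ 3% and 16% from the sensitivity analysis at the shipped
  truth). pG is held at its calibrated value: it is pinned by the PIF4-null
  phenotype rather than by the wild-type day-length curve, and freeing it
  drives the design singular.

`fit_genotype` refits only {P*, pself, one mut factor} against a genotype's
data, holding everything else — explicitly including dEC, k0, pF, dF and
pFP — bit-identical to the wild type; requesting any held-fixed parameter is
a configuration error.

## Synthetic data

`synthetic_data` emulates the measurement design of the experiments the
model addresses: day-6 hypocotyl lengths at day lengths 4/8/12/16 h with 20
replicates per condition, and reporter activities at stated harvest times
(ZT23 short-day, ZT4 long-day, or arbitrary time courses). Hypocotyl noise
is additive Gaussian (0.5 mm default — error bars for such measurements are
reported as absolute standard deviations of a few tenths of a millimetre);
reporter noise is multiplicative Gaussian (20% default) because activities
span orders of magnitude across genotypes. Neither noise magnitude is an
empirical estimate; both are order-of-magnitude choices recorded in the
generated table's provenance (`SyntheticSpec`). Draws below zero are
truncated to zero rather than resampled so the output is a pure function of
the seed. The generator reproduces the mean structure of the model exactly
(noiseless mode) but none of the systematic features of real assays —
between-batch effects, tissue heterogeneity, staining saturation — so
passing recovery tests demonstrate statistical, not biological, fidelity.

## Problem sizes used by the tests and acceptance script

Six-day protocols (144 h) for all observables; 12-day burn-in for the
periodic-orbit check; one diurnal cycle at h = 10⁻³ h for the fixed-step
reference comparison; 20 seeds × (4 day lengths × 20 replicates) for the
recovery property in the test suite and 10 seeds in the acceptance script.

## Limitations

- All concentrations are in arbitrary units; only within-panel ratios (and
  the hypocotyl millimetres) are comparable to measurements.
- Two discrete temperatures; no continuous thermal response.
- No molecular noise, no tissue resolution (tissue specificity is modeled
  only through different autoinhibition strengths), no downstream
  target-gene, biomass or yield modeling.
- The reporter branch structure implies the constant-light and long-day
  ZT4 caveats described under "Default calibration".
- The seven-parameter calibration spec is not identifiable from the
  four-day-length design; uncertainty statements are only meaningful for
  the identifiable recovery subset.
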