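# Methods

## Models and assumptions

All models are mass-action reaction networks in µM and seconds.  Four
are shipped:

**Wild-type core.**  Two reactions over the conserved glutaredoxin
moiety Grx(SH)₂ + GrxSS = Grx_tot, with PSSG and GSH clamped:
deglutathionylation v1 = k1·[PSSG]·[Grx(SH)₂] and GrxSS reduction
v2 = k2·[GrxSS]·[GSH]².  The second order in GSH encodes that two GSH
are consumed per GrxSS reduced.  The dithiol representation is used
throughout: the transient glutaredoxin–GSH mixed disulphide
(GrxSSGSH) is not an explicit species, because including the
intermediate steps makes the mono- and dithiol schemes the same network,
and the intermediate is too short-lived to shape steady-state kinetics.
It exists only in this documentation.

**Mutant core.**  The single-cysteine analogue: GrxSH + PSSG → GrxSSG +
PSH and GrxSSG + GSH → GrxSH + GSSG, first order in GSH.  Its reduction
constant k2′ (µM⁻¹s⁻¹) is dimensionally different from the wild type's
k2 (µM⁻²s⁻¹); the two are never interchangeable and carry distinct
fields with unit tags.

**GR-coupled system.**  Three reactions: glutathione reductase
(NADPH + GSSG → 2 GSH + NADP), GrxSS reduction (order 2 in GSH), and
deglutathionylation releasing PSH and GSH.  GR uses the separable
generic irreversible two-substrate law
v = kcat·E·(a·b)/((1+a)(1+b)), a = NADPH/K_NADPH, b = GSSG/K_GSSG,
which saturates at kcat·E and reduces to Michaelis–Menten in each
substrate; the published GR parameters used here are kcat 900 s⁻¹,
K_NADPH 15 µM, K_GSSG 74.6 µM.  The deglutathionylation step has an
optional net-reversible form k1·([Grx(SH)₂][PSSG] − [GrxSS][PSH][GSH]/Keq)
with the convention Keq = [GrxSS][PSH][GSH]/([Grx(SH)₂][PSSG]) at
equilibrium, units µM, default 1 µM.  In the reversible variant PSH must
be clamped (default 1 µM): with PSSG clamped and PSH free to accumulate,
the reverse term grows without bound and no steady state exists.

**HED-assay model.**  GR plus GrxSS reduction plus a lumped HED
reduction Grx(SH)₂ + HED → GrxSS with rate k_hed·[Grx(SH)₂][HED].  The
lump nets out the spontaneous GSH + HED → ESSG + β-ME pre-reaction with
the Grx-catalysed reduction of ESSG, so the lumped step carries **no**
net glutathione stoichiometry: GSH is catalytic across the pair.  This
is not just bookkeeping hygiene — if the lumped step released free GSH
from clamped HED, the closed glutathione pool would gain a source, the
GSSG and GSH balances would become inconsistent, and the model would
have no steady state.  With the lump, GSH + 2·GSSG is conserved
(998 + 2·1 = 1000 µM under the reference background) while glutathione
cycles through GR, and the measured observable — the GR (NADPH
consumption) flux — equals the HED-reduction flux at steady state.  The
treatment is irreversible because the HED equilibrium constant is not
known; real HED assays show mild deviations at the extremes of the HED
range for exactly this reason, and synthetic data generated by this
model inherit the irreversible idealisation.

### Clamping policy

NADPH and NADP are always clamped.  In reciprocal-plot protocols PSSG
and GSH (and PSH when reversible) are clamped per curve, because those
protocols treat them as independently set axes; whether the original
bench protocols clamped GSH or fixed total glutathione is not knowable
from published figures, and clamping is the assumption made here.  In
the closed assay model GSH/GSSG are dynamic with the glutathione moiety
conserved.  Stoichiometric actions on clamped species are retained in
the reaction definitions (they are no-ops during simulation) so that
un-clamping a species never changes the chemistry.

### Default parameters

| field | unit | Grx1 default | origin |
|---|---|---|---|
| k1 | µM⁻¹s⁻¹ | 0.073 | fitted deglutathionylation/HED constant (yeast Grx1) |
| k2_wt | µM⁻²s⁻¹ | 4.23e-6 | fitted GrxSS-reduction constant (yeast Grx1) |
| k2p_mut | µM⁻¹s⁻¹ | 4.2e-3 | ≈ k2_wt·GSH at GSH ≈ 1 mM, so wild-type and mutant rates are comparable at the reference assay background; no published mutant constant exists |
| k_hed | µM⁻¹s⁻¹ | 0.073 | as k1 |
| keq_deglut | µM | 1.0 | reported order of magnitude for the reversible step |
| gr_kcat / gr_K_NADPH / gr_K_GSSG | s⁻¹ / µM / µM | 900 / 15 / 74.6 | published yeast GR kinetics |
| gr_conc | µM | 0.02 | assay GR concentration |
| grx_tot | µM | 0.24 | 0.12 + 0.12 µM assay split of Grx(SH)₂/GrxSS |

The Grx2 profile differs in k2_wt = 6.74e-5, k_hed = 0.252 and
grx_tot = 0.04.  The GR-coupled reciprocal-plot system uses k1 = 0.1
µM⁻¹s⁻¹, k2 = 1e-5 µM⁻²s⁻¹, grx_tot = 1 µM: the constants of the
original bacterial model are not published, so these are round
placeholder magnitudes in the realistic regime, and every test against
this model checks pattern shape (linearity, parallelism, convergence),
never absolute values.

## Numerics

Steady states are defined operationally as max|d[x]/dt| < 1e-10 µM s⁻¹.
Moiety-closed mass-action networks have rank-deficient stoichiometry, so
before root finding one species per registered conserved moiety is
eliminated through its conserved total; Powell hybrid root finding then
runs on the reduced system from the model's initial state, and if that
fails the system is relaxed by stiff LSODA integration over
geometrically growing horizons (1 s × 100ᵏ up to 1e9 s) with the root
re-polished after each.  The assay models mix a 900 s⁻¹ enzyme with
~1e-6 µM⁻²s⁻¹ constants, which is what makes the stiff integrator and
the relaxation fallback necessary.  Concentrations are clipped at zero
only inside integrator trial steps; a final state with a negative
concentration or an above-tolerance residual is reported as
non-converged, and a model with no steady state raises an explicit
error rather than returning a bad root.  Rate functions return the
continuous limit 0 at zero substrate so saturation grids may include
zero; the reciprocal transform separately drops (and counts)
zero/near-zero points.

## Analyses

Reciprocal-line fits are unweighted OLS on the transformed points — the
classical reading of such plots — with an optional 1/var weighting that
is deliberately not the default.  The parallel/converging call, made by
eye in the experimental literature, is quantified as: "parallel" when
the maximum pairwise relative slope spread is < 5%, "converging" when
the spread is ≥ 5% and slopes are strictly monotone in GSH, otherwise
"neither".  The 5% threshold sits an order of magnitude above the
solver/OLS noise floor (measured spreads on noiseless data are ~1e-16)
and is robust under the default 5%-CV noise model with 3 replicates.
Curvature of the 1/GSH plot is tested by the t-statistic of the
quadratic coefficient in an OLS fit of 1/v on (1/GSH, 1/GSH²).

Hill fits minimise least squares on **untransformed** rates (no Hill
linearisation, which would bias the noise structure), initialised at
V = max rate, K_half = x at half-max (interpolated), n = 1, with n ∈
[0.05, 10] and optionally fixed.  The claim being tested is about the
functional form, so noiseless simulated curves must return n = 2
(wild type) and n = 1 (mutant) to within 0.01.

## Rate-constant fitting

Constants are fitted by Levenberg–Marquardt on log10-transformed
parameters (positivity by construction), with the full model re-solved
to steady state at every trial point so the identical procedure covers
the GR-coupled assay model.  A trial parameter set whose steady-state
solve fails contributes a large penalty residual instead of aborting
the optimisation.  Default initialisation is a 5-per-parameter
log-spaced grid search spanning one decade either side of the
template's current constants.  Standard errors come from the Jacobian
at the optimum, mapped to natural units by the delta method; 95%
confidence intervals are formed on the log scale using the Student-t
quantile with n − p degrees of freedom, since the noise scale is
estimated from the residuals.  Residuals are unweighted by default;
when a dataset carries per-point standard deviations, 1/sd weighting is
available and is what the recovery harness uses, because the synthetic
noise is multiplicative (heteroscedastic) and the generated sds are
exact.

## Synthetic data

The generator emulates steady-state initial-rate assays: true rates are
model steady-state fluxes on a concentration grid; observed rates are
true·(1 + ε) with ε ~ N(0, cv²) truncated at −0.99 (truncations are
counted in the dataset metadata), optionally replicated; every point
carries its exact sd = cv·true when cv > 0.  Defaults: cv = 0.05
(enzyme-assay error typically scales with signal), HED grid 10–500 µM
(15 log-spaced points, bracketing the 70 µM reference), GSH grid
0.1–4000 µM (25 points, so the fitted half-saturation is interior).
Everything is a pure function of settings and a mandatory integer seed;
families of curves derive independent child seeds from one parent.

What the generator does **not** emulate: progress-curve (time-series
absorbance) data, instrument drift or systematic error, outliers,
pipetting correlation between replicates, and the reversibility of the
real HED chemistry.  Passing recovery tests therefore demonstrate that
the estimation machinery is correct and calibrated under the stated
noise model — not that the published constants would be recovered from
the original bench data, which are not publicly deposited.  Fitting
those constants exactly requires the external dataset.

## Problem sizes

The shipped analyses use 15-point PSSG grids at 3 GSH levels for
line-family work, 25-point GSH grids for Hill fits, 100 random draws
for the closed-form/solver equivalence sweep, and a 100-seed × 20-point
Monte Carlo for parameter recovery — sizes at which every quantity is
stable to well inside its test tolerance while a full run of the
acceptance script completes in seconds to tens of seconds.

## Known limitations

* Only the deglutathionylation step has a reversible form; the package
  does not attempt thermodynamically consistent reversibility of the
  whole network.
* No SBML import/export; models live as Python objects and flat YAML
  parameter profiles.
* Classification is the geometric parallel/converging criterion only;
  no formal model-discrimination statistics (e.g. AIC between ping-pong
  and sequential fits).
* No stochastic simulation, events, or bifurcation analysis.
* The high-substrate rate-ratio limit k2·GSH/k2′ is implemented and
  tested under the condition that makes GSH oxidation rate limiting
  (k1·PSSG ≫ k2·GSH² and ≫ k2′·GSH); outside that regime the full
  ratio expression should be used.
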