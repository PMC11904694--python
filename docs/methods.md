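# Methods

## Problem and model class

`kinwfi` models batch chemical reactions as networks of *elementary
steps*: each step has integer stoichiometry, molecularity 1 or 2, and a
mass-action rate `k(T) · ∏ [reactant]^ν`. Rate constants follow the
Arrhenius law `k(T) = A·exp(−Ea/RT)` (R = 8.314 J mol⁻¹ K⁻¹). The
restriction to integer orders is deliberate: fractional-order rate laws
can interpolate a data set well yet extrapolate poorly, because they are
not the rate law of any physical set of elementary events.

The built-in chemistry is the benzylation of unprotected aniline (**1**)
by benzyl bromide (BnBr) to the mono- (**2**) and dibenzylated
(**di-2**) products, in acetonitrile with excess hindered amine base.
Three candidate mechanisms are provided:

| model | steps | rate-determining structure |
|---|---|---|
| `sn2` | 2 | direct bimolecular substitution, `1+BnBr→2`, `2+BnBr→di-2` (k in L mol⁻¹ s⁻¹) |
| `sn1` | 3 | unimolecular ionization `BnBr→BnCation` (k in s⁻¹), then fast cation capture by **1** or **2** |
| `borderline` | 5 | the union: both pathways compete on the same substrate |

Modeling assumptions: the base and the bromide leaving group do not
appear in any rate law (the base is in constant excess and no
base-order dependence is modeled); ionization is irreversible (no
common-ion return); the benzyl cation is integrated explicitly rather
than eliminated by a steady-state approximation, which keeps the five
elementary steps literal at the cost of stiffness.

Two linear invariants are carried with every model and checked against
trajectories as an integrator oracle: the aniline-moiety balance
`[1]+[2]+[di-2]` and the benzyl balance `[BnBr]+[BnCation]+[2]+2·[di-2]`
(the di-product carries two benzyl groups).

## Numerical integration

The ODE system is integrated with a stiff solver (LSODA) with an
analytic Jacobian, rtol 1e-8 and atol 1e-10 mol/L. Fast cation capture
(fixed at 1e3 L mol⁻¹ s⁻¹) against slow ionization (~1e-4–1e-2 s⁻¹)
makes the borderline system stiff; a non-stiff solver is not safe here.
Time is seconds and concentration mol/L internally; the user-facing
scale is minutes and conversion yield (percent of initial aniline).
Negative excursions of integrator-noise size (≲ atol) are clipped to
zero on reporting; anything beyond 1e-6 mol/L below zero raises an
error rather than silently propagating.

Isothermal batches are the default; a piecewise-linear internal
temperature profile `(time, °C)` is accepted because rate constants
respond to the *actual* internal temperature, which in practice should
be logged with every sample.

## The weighted error band and the WFI

Experimental conversion yields have a relative error that is large at
low conversion and settles to a plateau at high conversion. That decay
is described by a Stirling-type exponential-decay curve

    f(x) = a + (b/k)·(exp(k·x) − 1),   b < 0, k < 0,

with `f(0) = a` and plateau `a − b/k`. The reference parameterization
`a = 1, b = −9, k = −10` (fraction scale) starts at 100% relative error
at zero conversion and plateaus at 10%; it reproduces a stage table of
assumed errors (50% at 10% yield, 15% at 30%, 10% at and above 50%).
`calibrate` fits `(a, b, k)` to any such assumed-error table by bounded
least squares from five deterministic starts (bounds `a ∈ (0, 1.5]`,
`b, k ∈ [−100, 0)`), so the band can be re-derived when better precision
information is available.

Applying `f` to each **simulated** yield defines a continuous error
band centered on the simulation curve, with absolute half-width

    w(Ys) = max(f(Ys)·Ys, floor).

The floor (default 0.005 yield fraction, i.e. 0.5 percentage points)
represents the analytical limit of quantitation and removes the
singularity at `Ys = 0`. Centering on the simulation rather than the
data makes the comparison a test of the model's curve shape: model
uncertainty, not data scatter, is the quantity being minimized during
model selection.

The weighted fitting index of a matched series is

    WFI = (1/n) · Σᵢ |Y_s,i − Y_e,i| / w(Y_s,i).

WFI = 0 means perfect overlay, WFI = 1 means the average deviation sits
exactly at the band edge, and WFI < 1 is the acceptance contract: the
average distance is within the weighted range. The `t = 0` point is
excluded by default — both curves pass through the initial condition
exactly, so it carries no shape information and would only dilute the
index. Reports are tabulated per experiment and species with row
averages, and pooled by averaging the row averages.

A subtlety worth stating: the band is wider at low yield only in
*relative* terms. Its absolute half-width grows with yield (from the
floor at 0 to ~0.1 at full conversion with the reference curve), so for
equal *relative* deviation low-yield points are penalized less, while
for equal absolute deviation they are penalized more. The property
tests assert the relative-deviation form, which is the one the decaying
curve actually implies.

## Fitting

Parameters are estimated by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) on band-weighted residuals
`(Y_s − Y_e)/w` stacked over species and experiments; each point is
weighted only by its own band half-width, with no extra inter-experiment
weighting. Each step is parameterized as `(log10 k at 298.15 K, Ea in
kJ/mol)` instead of `(A, Ea)` to decorrelate the search coordinates;
`A` is recovered algebraically. Bounds: `log10 k ∈ [−8, 2]`,
`Ea ∈ [0, 200]` kJ/mol.

In the ionization branch only the ionization constant and the di/mono
capture *ratio* are identifiable when capture is fast, so the
mono-capture constant is fixed at 1e3 L mol⁻¹ s⁻¹ (barrierless,
Ea = 0) and the ratio (log10, bounds ±2) is the free parameter.
Activation energies are declared unidentifiable — and fitting refuses
to start — unless the training set spans at least two temperatures.

Multi-start is deterministic: a data-driven start (early-time substrate
consumption gives a flux scale; an Arrhenius line through per-experiment
fluxes gives an effective Ea; the flux is split 50/50 between branches),
the bound-box center, two branch-heavy variants of the data-driven start
(90/10 and 10/90 splits — the branch split is the dominant ambiguity in
a two-pathway model), then unscrambled Sobol points. The default is 8
starts; the heavy test fixtures use 4 (borderline) and 2
(single-mechanism), which reach the same optima on this problem family.

One numerical detail matters: the finite-difference step for the
Jacobian is set to 1e-4 (relative). With the default `sqrt(eps)` step
the residual change per step falls below the ODE-integration error and
the corrupted gradients stall the optimizer far from the optimum.
During fitting the integrator runs at rtol 1e-7/atol 1e-9 (final
reports re-simulate at 1e-8/1e-10); the FD step is chosen so residual
changes dominate that integration noise by two orders of magnitude.

Two objectives are exposed. `wls` reports the sum of squared weighted
residuals. `wfi` runs the same residual engine and reports the pooled
WFI (mean absolute band ratio) at the optimum; on noise-free data both
coincide at the truth, and on real data they rank models almost
identically because the residuals are already band-scaled.

Model evaluation is two-staged, and the second stage is the one that
matters: `self_reproducibility` tabulates WFI on the training
experiments; `extrapolability_check` predicts held-out conditions
*without refitting* (asserted by a parameter hash) and tabulates WFI
there. A model that merely interpolates shows up as a gap between the
two tables. `compare_models` ranks candidates by pooled training WFI
and carries the extrapolation column alongside; non-converged
candidates are flagged and excluded from the ranking.

Confidence intervals are deliberately de-emphasized: statistical
indicators computed within one candidate model cannot tell whether the
model itself is the right one, which is precisely the question the
extrapolation stage answers. Local curvature estimates can be derived
from the returned residuals and Jacobian if needed, but nothing in the
reports presents them as model-selection evidence.

## The synthetic study

`make_study` generates the six-experiment reference design from a known
("truth") parameterization of the borderline model, initial aniline
0.344 mol/L throughout:

| id | T (°C) | BnBr (equiv) | role | sampling (min) |
|---|---|---|---|---|
| 1 | 40 | 1.2 | training | 1, 2, 4, …, 512 |
| 2 | 30 | 1.3 | training | 1, 2, 4, …, 512 |
| 3 | 50 | 1.1 | training | 1, 2, 4, …, 512 |
| 4 | 20 | 1.4 | training | 1, 2, 4, …, 512 |
| cold_0C | 0 | 2.1 | extrapolation | 1, 2, 4, …, 512 |
| hot_79C | 79 | 1.05 | extrapolation | 0.25, 0.5, …, 128 |

Sampling is exponential (1, 2, 4, 8, … min): early points pin down the
curve shape where the rate is largest; sparse late points avoid
overweighting the flat tail and the bias accumulation that dense
late-stage sampling invites. The hot run keeps the same doubling rule
with an earlier first sample because the reaction there is roughly
twenty times faster. `demo_curves` constructs the classic
schedule-sensitivity example — an exponential and a sigmoid
indistinguishable at uniform knots but separated by >5 yield points at
an added early sample.

The default truth parameters (stored in `truth.json` next to every
generated study, and labelled synthetic) are

| step | k(298 K) | Ea (kJ/mol) |
|---|---|---|
| sn2_mono | 1.0e-3 L mol⁻¹ s⁻¹ | 85 |
| sn2_di | 5.0e-4 L mol⁻¹ s⁻¹ | 88 |
| ionization | 8.0e-4 s⁻¹ | 38 |
| capture_mono | 1e3 L mol⁻¹ s⁻¹ (fixed) | 0 |
| capture_di | 1.2e3 L mol⁻¹ s⁻¹ | 0 |

They were chosen so that (i) the two branches contribute comparably in
the 30–40 °C window (ionization carries ~76% of the flux at 20 °C,
~52% at 40 °C), (ii) the bimolecular branch is the more
temperature-sensitive, so the mechanism balance tilts to ionization in
the cold extrapolation (~93%) and to direct substitution in the hot one
(~89%), and (iii) the branches differ in mono/di selectivity (SN2
di/mono 0.5 vs capture di/mono 1.2), which gives the species-resolved
WFI a shape signature to discriminate on at the extrapolation
temperatures. Overall mono/di selectivity remains modest, as expected
for an unselective cation and a mild-base direct pathway.

Noise emulates heteroscedastic HPLC scatter tied to the band:
truncated-normal deviations with sd = w/2 truncated at ±2 sd, so every
generated point lies inside the band and roughly 95% of an untruncated
normal's mass would. A uniform-within-band alternative, a systematic
bias offset (percentage points) and Gaussian sampling-time jitter
(sampled at the jittered time, recorded at the nominal one) are
available to emulate the main bias families. Generation is
byte-reproducible for a fixed seed.

What the generator does *not* emulate: chromatographic drift,
internal-standard quantification mechanics, correlated within-run
biases, temperature excursions during sampling, or model error (the
truth lives inside the fitted model class). Passing tests therefore
demonstrate the machinery — band calibration, fitting, discrimination
by self-reproducibility and extrapolability — under the stated error
structure, not performance on real chromatographic data.

## Identifiability under band-level noise

The band-level noise is large in estimation terms. A linearized
(Cramér–Rao) analysis at the truth parameters gives 1σ uncertainties of
roughly 30–160% on the rate constants and 15–25 kJ/mol-relative on the
activation energies for a single six-experiment realization: the two
branches are nearly collinear in data space, and only the temperature
span and the selectivity signature separate them. Point recovery of
individual rate constants from one noisy study is therefore poor even
at the exact likelihood optimum — while the *functional* predictions
(training and extrapolation WFI, mechanism ranking) remain stable.
This is the expected behavior of a sloppy multi-parameter model and is
the reason model evaluation here leans on prediction quality rather
than on parameter confidence intervals. Noise-free recovery, by
contrast, is essentially exact (≲0.02% on rate constants), confirming
that the limitation is information, not optimization.

## Degenerate inputs and tie-breaks

Zero rate constants are legal (a switched-off step) and reduce the
borderline model exactly to either single-mechanism model. A pathway
ratio with both branch rates zero is flagged as undefined rather than
returned as NaN. Empty series, mismatched sample times, unknown species
and single-temperature Ea fits raise errors with actionable messages.
Simulation failures surface solver diagnostics; parameter regions where
the integrator fails during fitting are penalized with large residuals
instead of aborting the run. Calibration non-convergence returns the
best candidate with a warning rather than an exception.

## Problem sizes

The shipped study uses 10 samples per experiment, 3 observed species,
4 training + 2 extrapolation experiments (120 training points). Fits
use 2–4 multi-starts in the test suite and 8 by default on the CLI.
These sizes keep a full three-model comparison in the low minutes on a
single core while leaving the discrimination margins comfortably
resolved.
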