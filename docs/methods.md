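# Methods

## Dose–response model

Each single agent (and each fixed-ratio mixture treated as one agent in
total dose) is modeled by the median-effect equation
`Fa/Fu = (D/Dm)^m`. The model assumes a monotone, saturating inhibition
curve described by two parameters; multi-phasic or non-monotone responses
are out of scope. Fitting is unweighted ordinary least squares on the
log-linearized plot (log10 throughout): `m` is the slope and
`Dm = 10^(−intercept/m)`, which makes the predicted inhibition at the
fitted Dm exactly 50% by construction. The Pearson r of the transformed
plot is reported as the fit diagnostic; fits with r < 0.90 are flagged
but not rejected, since no principled rejection threshold exists for
3–6-point plate designs.

Observations with fa ≤ ε or fa ≥ 1 − ε (default ε = 0.01, configurable)
are excluded before the regression: the log-odds diverges at fa ∈ {0, 1}
and amplifies noise violently near them. Exclusions are returned and
logged, never silent, and at least 3 points must survive for a fit.
Normalized fa values that land outside [0, 1] because of noise are
clamped to the interval first, with each clamp logged. A fitted slope
m ≤ 0 is a hard failure (the dose inversion `Dx = Dm·(fa/fu)^(1/m)` is
undefined), as are fits where all retained doses coincide.

Choosing OLS on the transformed plot (rather than, say, weighted or
iteratively refined regression) is the classical median-effect procedure
and keeps the estimator exactly invertible: noise-free data generated by
the model refit to the generating parameters to machine precision, which
the test suite verifies at 1e-9 relative error.

## Combination index and Fa–CI simulation

The combination index uses the two-term (mutually exclusive) form
`CI = Da/Dxa + Db/Dxb` with no third interaction term. Iso-effective
doses come from each agent's own median-effect fit; CI is undefined at
fa ∈ {0, 1} and such points raise rather than propagate infinities.

Constant-ratio designs anchor the dose ratio at the two agents' IC50s
estimated in the same study, so the dose fraction of drug A is
`ρa = IC50a/(IC50a + IC50b)` at every level. CI at a design level is
computed per experiment — that experiment's own single-agent fits, the
combination's replicate-averaged observed fa, and the administered doses
recovered from the well records — then aggregated as mean ± sample SD
(n − 1) across experiments. Design levels are identified from the total
dose series by anchoring on its middle element (the 1× point of the
canonical 6-level series); this keeps the report labels correct for the
default design and merely relabels levels for custom ones.

The Fa–CI profile evaluates, for each fa on a grid (default 0.01–0.99,
step 0.01), the total dose the mixture model assigns to fa, splits it on
the constant ratio, and applies the CI equation. The mixture model is the
per-experiment mixture fits pooled on the parameter scale (mean of
log10 Dm, mean of m), producing one mean curve per pair. A test verifies
the closed-form evaluation against a brute-force oracle that inverts the
mixture model numerically by bisection (agreement ≤ 1e-8 relative on a
99-point grid).

## Verbal classification

The 11 bands run: very strong synergism (0, 0.1), strong synergism
[0.1, 0.3), synergism [0.3, 0.7), moderate synergism [0.7, 0.85), slight
synergism [0.85, 0.9), nearly additive [0.9, 1.1], slight antagonism
(1.1, 1.2], moderate antagonism (1.2, 1.45], antagonism (1.45, 3.3],
strong antagonism (3.3, 10], very strong antagonism (10, ∞). The
conventional printed bands overlap at 0.9 and 1.45 and abut at 1.1/1.2;
this package resolves every boundary toward the band containing 1
(closed on the side nearer 1, open away from it), so the scale partitions
(0, ∞) with no gaps or overlaps — a property test sweeps a dense grid
including every boundary and its floating-point neighbors. The convention
is a design choice of this package, encoded in the exported `CI_SCALE`
object.

## Synthetic plate generator

The generator emulates a 72-h proliferation assay on 96-well plates:
untreated control wells anchor the normalization, single-agent series run
at fractions/multiples of the true IC50 (default 1/8, 1/4, 1/2, 1, 2, 4),
and combination arms follow the constant-ratio design anchored at the
true IC50s. Defaults: 4 independent experiments, 3 wells per dose, 8
control wells per experiment, 5% multiplicative Gaussian signal noise
(`signal = baseline × fu × (1 + ε)`, truncated at 0) — plate-reader
absorbance noise is approximately proportional to signal. Example agent
IC50s span the micromolar-to-nanomolar range typical of iron-chelator
panels; slopes default to m ∈ [1.5, 2], documented as assumptions since
slopes are rarely reported.

The interaction ground truth is a constant target combination index CI*:
at each total dose D the generated fa solves
`ρa·D/Dxa(fa) + ρb·D/Dxb(fa) = CI*` by Brent's method. The left side is
strictly decreasing in fa (both iso-effective doses increase with fa), so
the root is unique; doses outside the achievable effect range are emitted
with fa clamped to the bracket edge and flagged. This mechanism makes CI
exactly recoverable by the analysis pipeline (noise-free recovery to
1e-6 is tested for CI* from 0.1 to 3) and covers the full verbal scale. A
callable `ci_star(fa)` hook generates dose-varying interactions (e.g.
U-shaped profiles) by the same root-finding with a level-dependent
target. Seeding uses one `SeedSequence`-spawned stream per experiment, so
output is byte-identical under a fixed seed and arms are statistically
independent across experiments.

What the generator does not emulate: mechanistic cell growth, plate-edge
or spatial effects, inter-experiment biological drift (optional log-normal
IC50 jitter exists but is off by default), and non-median-effect response
shapes. Passing recovery tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to real-world
model misspecification.

## Normalization and reporting

Viability is signal divided by the mean control signal of the same
experiment (per-experiment scope; each assay run carries its own
controls); fa = 1 − viability, clamped to [0, 1] with logging. Replicate
wells are averaged to one fa per dose per experiment before fitting — the
standard plate workflow — though the underlying fitters accept any
observation layout. Concentrations are µM throughout. Every arm of the
input appears in the study report exactly once, either as a result or as
a flagged failure; exclusions, clamps and failed fits are written to a
machine-readable `flags.json` next to the CSV tables.

## Numerical choices and problem sizes

Root-finding tolerance 1e-12 on fa; fit window ε = 0.01; fa grid step
0.01. Test-suite simulations use 2–4 experiments, 3 replicates and
6 dose levels — sizes at which every stochastic check (noisy CI recovery
within 15% of CI* at σ = 0.05, n = 4, fixed seeds; the tolerance was
confirmed by a seeded Monte-Carlo run whose worst-case relative error was
12%) is stable and the full suite runs in seconds.

## Known limitations

- The two-term CI assumes mutually exclusive drug effects; the
  mutually-nonexclusive three-term variant is not offered.
- The mixture's median-effect fit is a straight-line approximation: for
  Loewe-additive pairs with unequal slopes the true mixture curve is not
  median-effect, so the simulated Fa–CI profile of an additive pair bows
  below 1 mid-range and above 1 at the extremes — a property of the
  method itself, reproduced (not corrected) here.
- CI standard deviations across experiments conflate biological and
  fit variance; no decomposition is attempted.
- Bliss independence, response-surface models, dose-reduction indices,
  checkerboard designs and ≥3-drug combinations are out of scope.
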