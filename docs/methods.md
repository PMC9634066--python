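# Methods

`navsim` simulates the retrieval side of cognitive-map navigation: how a
remembered route is recalled landmark by landmark under control of a
prefrontal rule system, and how that recall degrades under attention deficit
or Alzheimer-like oscillatory slowing.  Learning is assumed complete; the
package models recall only.  This note documents the models, their
parameters, the numerical choices, and what the synthetic test conditions do
and do not establish.

## The cognitive map (`cogmap`)

Spatial long-term memory is a matrix with one row per learned route step,

    [x_next, y_next, w_next, x_motor, y_motor],

holding the coordinates and identification frequency `w` of the next
expected landmark, and the agent's own coordinates at that step.  The default
environment is an orthogonal staircase of six route landmarks LM1..LM6
(frequency codes 4..9) whose turning points each carry a straight-through
wrong-path branch landmark LM7..LM11:

| LM | (x, y) | code | | LM | (x, y) | code |
|----|--------|------|-|----|--------|------|
| 1  | (0, 0) | 4    | | 7  | (0, 2) | 10   |
| 2  | (4, 0) | 5    | | 8  | (6, 0) | 11   |
| 3  | (4, 3) | 6    | | 9  | (4, 5) | 12   |
| 4  | (7, 3) | 7    | | 10 | (9, 3) | 13   |
| 5  | (7, 6) | 8    | | 11 | (7, 8) | 14   |
| 6  | (10, 6)| 9    | |    |        |      |

The specific coordinates are a repo convention (any orthogonal geometry can
be supplied through the YAML map schema); the model content lies in the
topology, the code<->id relation (code = id + 3, extended to the branch
landmarks, whose codes are otherwise arbitrary symbols), and the branch
attachment 1->7 ... 5->11.  Amnesia is modelled by `lesion`, which zeroes the
matrix rows targeting the given landmarks; the landmark remains in the
environment and still emits its stimulus, but the corresponding retrieval
fails.

## Where stream (`where_stream`)

Egocentric landmark position (r, theta) is population-coded by 360 polar
radial-basis neurons (36 azimuth x 10 radial divisions over r_max = 10 map
units) with activation

    R_i = exp(-d(theta_i, theta)^2 / sigma_theta^2) * exp(-(r_i - r)^2 / sigma_r^2),

sigma_r^2 = 0.06, sigma_theta^2 = 0.002 rad^2 (radians are the only reading
under which the printed variance gives sensible tuning widths).  The variance
appears directly in the denominator — no factor 2 — so the worked numbers in
the tests are self-consistent.  Angular differences are wrapped to
[-pi, pi].  Radial centres are cell-centred, at (i + 0.5) r_max / 10: with
edge-anchored centres a target near r = 0 would decode almost a full bin
away, while cell-centred placement guarantees the half-bin decode bound for
every in-range radius.  Decoding is the activation-weighted mean of neuron
centres, with the circular (vector) mean for the angle; the round-trip error
is at most half a bin per coordinate (r_max/20 radially, 5 degrees in
azimuth).

## What stream (`what_stream`)

Each stored landmark has a neuronal-ensemble unit modelled as a driven
Van-der-Pol oscillator

    dX/dt = (lambda - Y^2) X - P^2 Y + B As sin(omega_s t),   dY/dt = X,

with natural frequency P equal to the landmark's code (4..9), coupling
B = 1.5, stimulus amplitude As = 1, and bifurcation parameter lambda = 0.2
in the healthy regime.  Averaging the equivalent scalar form
`Y'' - (lambda - Y^2) Y' + P^2 Y = 0` (substituting Y = sqrt(lambda) u gives
the classical oscillator with mu = lambda) yields an unforced limit-cycle
amplitude of 2 sqrt(lambda); the package adopts this value (numerically
confirmed to <1%) over the alternative 2*lambda reading, which fails the same
check.  2 sqrt(0.2) ~ 0.894 sits just below the unity recognition threshold:
a unit crosses 1 only when the stimulus pumps it resonantly.

Recognition is adaptive resonance.  A unit recognises the stimulus when

1. its steady-state envelope crosses the unity threshold, and
2. its dominant response frequency matches the drive frequency and its own
   tuning P (5% relative tolerance each).

The frequency conditions are not decorative.  At lambda = 15.2 every unit
sustains a relaxation oscillation of amplitude 2 sqrt(15.2) ~ 7.8, so the
threshold alone would "recognise" everything; and a slowed unit whose
intrinsic frequency happens to land near the drive (P = 9 slowed to ~7.8,
driven at 8) can even frequency-lock to the stimulus, so matching the drive
alone is insufficient.  Requiring resonance at the *stored* tuning P captures
the intended mechanism — recognition happens when the input frequency is the
unit's code — and makes the AD bank reject every route landmark.

Numerical choices:

- Integration: `scipy.integrate.solve_ivp` RK45 (rtol 1e-8, atol 1e-10)
  sampled on a uniform grid; a fixed-step RK4 fallback is available and
  agrees to ~0.1%.  Guard: dt * max(P, omega_s) <= 0.1.
- Initial state: (0.1, 0) unforced (the limit cycle needs a seed), (0, 0)
  driven.
- Window: t_end = 80, dt = 0.005 by default; the first 30% is discarded as
  transient, leaving ~36 cycles at P = 4 (and >= 20 cycles even for the
  slowed AD fundamental), which is also the precondition enforced by
  `spectral_summary`.  The unforced amplitude-law checks integrate to
  t_end = 250 because the limit cycle grows at rate ~lambda and lambda = 0.1
  has not settled by t = 80.
- Envelope: magnitude of the analytic signal (Hilbert).  The scalar
  "steady-state envelope" is the median over the late half of the
  post-transient window.  A high quantile is the wrong statistic here: a
  mismatched unit carries its own limit cycle (~0.89) plus a forced
  off-resonance component (~B As/|P^2-omega_s^2|), and the beat maximum of
  that two-tone signal transiently exceeds 1 for the adjacent unit, while its
  steady amplitude stays well below.  The median reads through both beats and
  edge artifacts; measured values under the code-4 drive: matched unit 1.375,
  mismatched 0.879-0.898.
- Spectra: Welch PSD on the post-transient window, reported on the angular
  frequency axis ("code units"), on which a unit with parameter P peaks at
  the value P.  The dominant frequency uses a Hann-windowed, zero-padded FFT
  with parabolic peak interpolation, giving sub-bin accuracy (a raw Welch bin,
  ~0.15 code units, is too coarse to separate 4.00 from 3.94).
- Band powers integrate the PSD below/above a split of 3 code units.

Raising lambda through {0.2, 2, 8, 15.2} slows the dominant frequency of an
unforced P = 4 unit monotonically (measured ~4.00, 3.94, 3.29, 2.53) and
shifts power into the low band, the oscillatory analogue of EEG slowing in
Alzheimer's disease.  The low-band share is floor-limited by leakage while
the fundamental is still above the split, so the share comparison in tests is
non-strict in the middle of the range and strict between the endpoints.

## mPFC controller (`mpfc_fuzzy`)

The retrieval controller is a fuzzy lookup-table over (here, goal,
attention).  Here/goal/next-step use Gaussian membership functions with
sigma = 0.15 centred on the landmark-id axis (1..11); at unit spacing this
leaves effectively no overlap, matching the assumption that exactly one
next-step landmark is visible at a time.  Attention uses the standard
quadratic-spline smf ("with") and zmf ("without") with foot 1 and shoulder 2;
their crossover, 1.5, serves as the attention-deficit threshold.  The
controller receives frequency codes and maps them to the id axis through the
map's affine code<->id fit, so a perceived code of 4.2 lands at id 1.2 and
still fires LM1's rules at membership exp(-0.04/0.045) ~ 0.411.

The complete base holds one rule per ordered (here, goal) pair of the six
route landmarks and per attention state: 36 antecedent pairs, 72 rules
(here = goal pairs are included, with "stay" consequents, as the 6 x 6
arithmetic implies).  With attention the consequent is the next landmark
toward the goal; without attention it is the branch attached at the current
landmark (stay, where none is attached, i.e. at LM6).  The two learned routes
activate 16 rules (10 for LM1->LM6, 6 for LM4->LM1), reproducing the printed
tables row for row.  One printed low-attention consequent for the return
route (here LM4, goal LM1) is ambiguous between LM10 and LM5; the default
follows the branch-attachment pattern (LM10) and can be overridden per rule.

Inference is product firing strength with centre-average defuzzification
(exactly the formula above, no normalisation tricks), so the raw output is a
convex combination of firing consequents and interpolates continuously; for
the discrete routing decision it is snapped to the nearest firing consequent
centre (distance ties take the lower centre, logged).  Rule-base
construction from exemplars with duplicated antecedents keeps the
highest-degree rule (`prune_by_degree`), degree = antecedent x consequent
membership of the generating exemplar, ties again to the lower consequent.

## Closed loop (`navigator`)

One decision cycle: perceive the landmark at the agent's position with the
oscillator bank -> check the recognised code against the next-subgoal STM
buffer (mismatch raises a wrong-path message) -> run the fuzzy controller on
(here code, goal code, attention) -> load the retrieved memory row into the
next-subgoal buffer, shifting its old content to the previous-subgoal buffer
-> move along the grid to the retrieved landmark.  Movement is
landmark-to-landmark (one trace record per decision); per-cell animation is
out of scope.

Attention below 1.5 at a decision landmark makes the low-attention rules
dominate, so the controller itself emits the branch landmark; the agent
enters it knowingly, dwells while attention stays low, and on recovery
backtracks to the decision landmark and reapplies the high-attention rule
(the recovery mechanics are a design choice; only the existence of recovery
is constrained).  When retrieval fails — a lesioned row, or no landmark
recognised in the AD regime — the next step falls to weighted path
competition: neighbouring landmarks weighted by 1/(1 + |code - lost code|),
equal weights falling back to the smallest turning angle from the previous
heading, then the lowest id (an optional seeded-RNG mode samples by weight
instead).  A failed retrieval loads a zeroed row into the STM buffer, and a
competition-driven wander onto a branch schedules no correction: the agent
does not know it is lost.  The AD preset therefore wanders deterministically
(LM2, LM8, LM2, LM1, LM7, ...) until the step budget, 4x the route length,
declares it lost.

Scenario presets: `fig12` (healthy: start LM1 perceived as code 4.2, goal
code 9, attention 2.3), `fig13` (same with attention 1.0 at the LM4 decision
for two steps, then restored — the dwell length on the branch simply follows
the attention profile, which is not otherwise constrained), `ad`
(lambda = 15.2).  All runs are deterministic; identical configs produce
byte-identical traces.

## What the synthetic conditions do and do not show

All inputs are generated in-repo: the map, the rule tables, and the
scenario parameters are the model's own printed operating point, not data.
Passing tests show the mechanisms are implemented as specified and behave as
claimed *at that operating point* — they say nothing about real EEG,
behavioural navigation data, pharmacology, or maps beyond a linear route
with single-branch decision points.  Rule learning, emotional modulation and
striatal competition are explicitly out of scope.

## Known limitations

- Routes are linear chains; the controller's "toward the goal" convention
  exploits the monotone id ordering and would need regeneration for general
  graphs.
- The recognition frequency tolerance (5%) is a modelling constant; stimuli
  whose codes differ from a stored tuning by less than ~5% would be
  confounded.
- The where stream is exercised as a standalone codec; the closed loop keys
  perception on exact grid positions rather than decoded polar coordinates.
- `spectral_summary`'s 20-cycle precondition bounds how short a simulation
  can be while still reporting band powers; very slow units need windows
  sized accordingly.
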