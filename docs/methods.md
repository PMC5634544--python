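# Methods

This note documents the model, the numerical machinery, and the design
choices behind `sleepenergy`, in the spirit of a methods appendix: enough
detail to reproduce or deliberately deviate from every number the package
prints.

## Model and assumptions

One day is the unit of time. The day consists of exactly two consolidated,
monophasic states — wake on `[0, 1 − TST/24)`, then sleep — with the four
energy rates `r_Ww, r_Bw, r_Ws, r_Bs` constant within a state. The state
variables are biological requirements BR (maintenance obligations generated
by all metabolic activity, weighted by prices) and biological investment BI
(completed maintenance); their difference BD = BR − BI is the homeostatic
variable and must stay positive. Within a day,

    dBR/dt = p_W·r_W(t) + p_B1·BD·r_B(t)
    dBI/dt = C(t)·BD/(1 + BD²) · r_B(t)

and at each day boundary BI resets to 0, BR to BD (a pure bookkeeping reset:
BD is continuous). Both right-hand sides depend on (BR, BI) only through
BD, so the debt obeys a scalar equation — the reduction is exact, and the
package exposes both forms (`rhs` and `rhs_bd`), with their agreement
enforced by property tests.

The conversion efficiency has two multiplicative parts. The circadian
multiplier `C(t) = m_C − A·sin(2π(t − 1/4 + TST/48))` has period one day
and peaks in the middle of the sleep phase; `A < m_C` keeps it positive.
The reactive part `BD/(1 + BD²)` is small at low debt, maximal at BD = 1,
and decays to zero at high debt — efficiency is best at moderate debt.
Consequences worth knowing: at large debt, investment cannot keep up and
trajectories diverge (this bounds every stable cycle's basin of attraction
from above by an unstable fixed point); at `p_W·r_W = 0` debt can decay
toward zero without ever crossing it.

What the model deliberately leaves out: REM/NREM structure, somnogen or
adenosine mechanisms, stochasticity of any kind, the infrastructure cost of
running all programs simultaneously, and any fitting to empirical sleep or
metabolic data. Every computed number is a property of the deterministic
ODE system under the stated parameters, nothing more.

## Parameters

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| `p_W` | price of waking effort | 1.3 | – (must be > 0) |
| `p_B1` | price slope of investment, `p_B = p_B1·BD` | 0.7 | – (≥ 0) |
| `m_C` | circadian mean level | 5 | – (> 0) |
| `A` | circadian amplitude (half peak-to-trough) | 2.5 | – (0 ≤ A < m_C) |
| `TST_h` | total sleep time | 8 | hours in [0, 24) |
| `r_Ww, r_Bw` | wake-phase rates (effort, investment) | 0.5, 0.5 | energy/day |
| `r_Ws, r_Bs` | sleep-phase rates | 0.5, 0.5 | energy/day |

The defaults are the standard values used for all headline results; the
Wake baseline uses equal wake rates of 0.5 so that its mean metabolic rate
is exactly 1 and savings read directly in percent. All parameters are
plain dimensionless model units — debt is reported in arbitrary units, and
nothing is calibrated to kilojoules.

## Limit cycles and the Poincaré map

Daily periodic solutions are fixed points of the start-of-day-debt return
map `P`. Because the scalar debt flow is one-dimensional, `P` is strictly
increasing, and in the explored parameter space crosses the diagonal 0, 1,
or 2 times; with two crossings the smaller-debt fixed point is stable.
Stability is classified by the centered finite-difference slope of `P`
(step 1e−5): slope < 1 stable, > 1 unstable, within 1e−3 of 1 half-stable.
Half-stable (tangent) cycles are admitted wherever averages are taken.

Two integration routes coexist, by design:

* **Trajectories** (`integrate_day`): scipy `solve_ivp` (adaptive RK45,
  rtol 1e−10, atol 1e−12) on the (BR, BI) pair, with a mandatory
  breakpoint at the wake→sleep switch (the right-hand side is
  discontinuous there) and a terminal event at the debt floor (1e−12);
  hitting the floor raises an invalid-trajectory error rather than
  clamping, since the model requires BD > 0. Output is sampled on ≥ 401
  points; cycle averages `m_BD` use the trapezoid rule on that grid.
* **Map evaluations** (`poincare_map` and everything built on it): an
  in-package numba-compiled fixed-step RK4 kernel, 1920 steps/day split
  across the two phases. The integrand is smooth within each phase, so
  the global error (~h⁴) is far below every tolerance used; the
  equivalence of the two routes at 1e−8 is property-tested. The kernel
  exists because fixed-point searches, matching bisections, and the
  sensitivity grid together need on the order of 10⁴–10⁵ one-day
  integrations, where `solve_ivp`'s per-call overhead dominates.

Fixed points are located on a 60-point geometric grid over the search
interval (1e−6, 50] — the divergence of debt at large BD makes a larger
upper bound pointless for standard-scale parameters — followed by brentq
on `P(BD) − BD` to 1e−8. A near-tangent pair that slips between grid
points is recovered by bounded minimization of the residual at interior
positive local minima. The saddle-node onset along a one-parameter family
(`find_bifurcation`) is found by bisection on cycle existence to 1e−5 in
the parameter; no arclength continuation is needed for a monotone
one-parameter family.

## The energy-savings protocol

The comparison is anchored by *Strategy Wake* (TST = 0, equal wake rates):
its stable cycle's time-averaged debt `m_BD` (0.35136 at standard
parameters; start-of-day fixed point 0.33624) is the level every sleep
strategy must reproduce, and its mean metabolic rate `m_MR1 = r_Ww + r_Bw`
is the denominator of all savings.

For a sleep strategy, `r_Ww` is held at the Wake value, and the sleep rates
follow from the requested `ρ` and target MAI:

    r_Ws = max{0, (1−ρ)((1−MAI)·r_Ww − MAI·r_Bw)}
    r_Bs = (1−ρ)(r_Ww + r_Bw) − r_Ws

so `ρ` holds exactly by construction while the clamp can leave the achieved
MAI (recomputed from the resolved rates) short of the target — this is what
caps the feasible MAI near 0.71 at an 8 h quota with ρ = 0.3. The matching
scan raises `r_Bw` in steps of 0.02 until a stable cycle exists and its
mean debt crosses the baseline (mean debt decreases monotonically in `r_Bw`
past the onset — verified on grids before trusting bisection), then brentq
refines the crossing; matches are accepted at 1e−4 relative. When the
cycle is born with mean debt already below baseline, savings are computed
at the bifurcation point and flagged `matched=False` — such points are
reported, never dropped. If no periodic solution exists for any scanned
`r_Bw` (bounded at 10), the scenario is recorded as having no cycle.

Savings are pure arithmetic on mean metabolic rates,
`m_MR = (1 − TST/24)(r_Ww + r_Bw) + (TST/24)(r_Ws + r_Bs)`, expressed in
percent of `m_MR1`.

## Sweeps, restriction runs, and shape diagnostics

Sweep functions return tidy tables (one row per grid point) carrying the
resolved rates and all three mean metabolic rates, so every savings number
in a table is re-derivable from its own row by exact arithmetic — a
consistency property the tests enforce. Default grid steps: MAI 0.05,
TST 1 h, ρ 0.05, A 0.25, prices 0.1 (all configurable). The sensitivity
grid ties `A = m_C/2` and, since the parameter domain requires `p_W > 0`,
evaluates `p_W = 0` grid labels at 1e−9 (the dynamics are continuous in
`p_W`). The shipped acceptance run coarsens the price step to 0.25 with
`m_C ∈ {2, 3.5, 5, 6.5}` (324 points, ~2 minutes); the spread of savings
is reported over points that admit a stable cycle.

Multi-day restriction runs chain one-day integrations through the daily
reset with *fixed* rates — by default those matched at TST = 8, MAI target
0.4, ρ = 0.3, a convention chosen because re-matching per quota would
change the question from "what happens to this organism when sleep is cut"
to "what would an optimally re-tuned organism look like" (both modes are
available). Steady state is declared when the relative change of the daily
mean debt falls below 1e−4; *escalation* ("escape from homeostasis", which
has no closed-form definition in this model) is operationalized as the
daily mean debt growing by strictly increasing increments across the final
three days. Under the default rates, 12-day runs reach a flat steady state
at 8 h, an elevated steady state at 6 h, fail to settle below 4 h, and
escalate at ≤ 1 h.

Shape diagnostics (`bd_shape_metrics`) reduce a daily debt curve to
per-phase monotonicity fractions, interior extremum counts, and per-phase
convexity signs. They distinguish the three regimes the model predicts:
flat debt when `A = 0` and MAI = 0; a single-peaked sinusoid-like wave when
`A > 0` without partitioning; and, once MAI > 0, a concave rise through
wake and convex fall through sleep — the temporal signature of the
homeostatic Process S in the two-process model of sleep regulation.

## Known limitations and numerical caveats

* The mean-debt match anchors on exact quadrature of the Wake cycle.
  Published figures derived from display-rounded rate values can differ
  from exact matching by a few tenths of a percentage point in savings;
  this package always reports the exactly-matched values.
* The matching scan assumes mean debt decreases in `r_Bw` past the cycle
  onset; this holds throughout the explored parameter space but is not
  proven globally. The monotonicity premise is covered by tests.
* Stability classification near a tangency is conventional: within 1e−3
  of unit slope the cycle is called half-stable, and bisection on
  existence (not slope) locates the onset.
* `ρ = 1` with TST > 0 zeroes the sleep metabolic rate; the MAI of such a
  scenario is undefined (zero denominator) and reported as NaN.
* Very long quotas (TST → 24) leave a sliver of wake; step counts per
  phase are floored at 4 so the kernel stays well-defined, and scenarios
  are validated for TST in [0, 24) only.
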