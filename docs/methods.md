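# Methods

## Model

`reciprosim` studies indirect reciprocity in the pairwise donation game: a
donor either cooperates — paying a cost *c* so the recipient gains a
benefit *b* > *c* — or defects at no cost. Behavior is conditioned on
binary moral reputations through three strategies: ALLC (always
cooperate), ALLD (always defect), and DISC (cooperate only with recipients
viewed as good). Reputations are updated by second-order social norms, 2×2
tables over (donor action, recipient reputation). The four canonical norms
are implemented as data (`core.NORMS`), so user-defined tables are
accepted as experimental extensions:

| norm | defect vs bad | coop vs bad | defect vs good | coop vs good |
|---|---|---|---|---|
| Stern Judging | G | B | B | G |
| Simple Standing | G | G | B | G |
| Scoring | B | G | B | G |
| Shunning | B | B | B | G |

Two error processes: an intended cooperation is executed as defection with
probability *e1*, and any single reputation assignment is flipped with
probability *e2*. The composite ε = (1−e2)(1−e1) + e2·e1 is the chance
that an intended cooperation with a good-view recipient leaves the donor
assessed as good. All assessment probabilities are generated from the norm
table plus these two errors rather than hard-coded, which keeps custom
norms consistent with the canonical four.

Reputations may be **private** (each observer holds her own image of
everyone, formed from independently observed interactions) or
**institutional**: *Q* designated observers each assess every member once
per round, and the member is broadcast as good iff at least
k_min = ⌈qQ⌉ votes are good. *q* is the strictness threshold; q < 1/Q
("tolerant") means one good vote suffices, q > (Q−1)/Q ("strict") requires
unanimity. The prose convention "more than qQ votes" differs from the
ceiling rule when qQ is an integer; the ceiling rule is used everywhere
(analytics and simulator) because it reduces exactly to the tolerant and
strict limits. q = 0 yields k_min = 0 (everyone broadcast good) and is
permitted with a warning.

## Reputation equilibria

Strategy change is assumed slow relative to reputation updating, so every
payoff evaluation uses reputation frequencies at their fixed point
(timescale separation).

Under **full adherence**, the per-observer good-fractions g_i of the three
strategies satisfy a norm-specific system linear in the mean broadcast
G = Σ f_i G_i, closed by the binomial vote aggregation
G_i = Σ_{k≥k_min} C(Q,k) g_i^k (1−g_i)^{Q−k}.

Under **mixed adherence** the population contains institutional adherents
(Za), private discriminators (Zn), and optionally ALLC (X) and ALLD (Y).
The unknowns are cross-class good-fractions g_{i,j} (donor class *i* in
the eyes of observer class *j* ∈ {Za, Zn}), coupled through agreement
aggregates: G (broadcast mean), g• (mean private view), γ2 (probability an
adherent and a non-adherent agree someone is good), and g2 (probability
two non-adherents agree). Each g_{i,j} is assembled by enumerating the
joint distribution of (observer view, donor view) of a random recipient
and weighting the norm's assessment probability by the donor's intent
under her own operative view.

Modelling assumptions worth making explicit:

- **Independence closure.** Distinct observers' views of the same
  individual are conditionally independent given that individual's class.
  This is what the product forms γ2, g2 and the binomial vote counts
  assume. Correlated-observation models are out of scope.
- **Independent observations.** Each institutional observer evaluates a
  donor from her own independently sampled interaction, not a shared one —
  the binomial closure requires this.
- **Board kinds.** An *external* board consists of dedicated observers who
  assess recipients by the public broadcast. An *internal* board is
  staffed by population members who use their own mode (broadcast if
  adherent, private image otherwise); its composition is drawn from the
  discriminator classes with weights f_Za/(f_Za+f_Zn) and
  f_Zn/(f_Za+f_Zn). That renormalization is this package's extension
  choice for four-class populations, where the two-class mixture rule does
  not directly apply; it matches the simulation protocol in which
  discriminators staff the board.
- For a defector observed privately under Stern Judging, the generic
  table construction gives g_{Y,Zn} = g•·e2 + (1−g•)(1−e2); a variant
  with ε in the first term is reproducible via the `literal_eq16` switch
  of the mixed solver for comparison, but the generic construction is the
  default since it is the one consistent with the assessment table (the DISC entry under Scoring is handled the same
  way: Scoring and Shunning share g_Z = εG + e2(1−G) because DISC never
  cooperates with a bad-view recipient).

### Numerics

Both systems are solved by damped fixed-point iteration
(new = (1−λ)·old + λ·map(old)) with absolute tolerance 1e−12 on the
undamped residual and a 10^5 iteration cap; non-convergence raises an
error carrying the last residual. For e1, e2 > 0 every right-hand side is
a convex combination of values in (0,1) and the solution is unique, but
the *undamped* map is not a contraction everywhere: for Q ≥ 2 the
aggregation G_i(g_i) is steep enough (slope up to Q near the ends) that
the iteration can lock into a stable 2-cycle (observed under tolerant
Stern Judging at some strategy mixes, residual stalled near 2×10⁻³). The
default λ = 0.5 averages the cycle away; all uniqueness tests (50 random
interior starts, every norm, both boards) converge to the same point
within 1e−8. Solvers warn when e1 = 0 or e2 = 0, where the uniqueness
argument fails; those settings are reserved for analytic edge cases.

The mixed model at f_Zn = 1 under Stern Judging has the exact solution
g_{Zn,Zn} = 1/2 for any errors in (0, 0.5): the fixed-point equation is
invariant under exchanging good and bad. The solver reproduces this to
machine precision and the property is asserted in the tests.

## Replicator dynamics

Frequencies follow ḟ_i = f_i(Π_i − Π̄) with donation-game payoffs
evaluated at reputation equilibrium; every derivative evaluation re-solves
the fixed point, warm-started from the previous solution. "Private
assessment" for three-strategy dynamics is the mixed model at f_Za = 0
(non-empathetic); empathy in the replicator layer is not modelled — it
enters only the agent-based simulator.

Trajectories are integrated with adaptive RK45 (rtol 1e−8) in chunks of
500 time units, stopping when the derivative norm falls below 1e−9, with
renormalization onto the simplex between chunks (drift stays below 1e−9).
`find_equilibria_and_basins` integrates from a barycentric lattice
(default 50 starts per edge, shifted 1e−4 inward because boundary faces
are invariant and stall integration), clusters endpoints with radius
1e−3, and labels stability by the eigenvalues of a central-difference
Jacobian (h = 1e−6) of the reduced two-coordinate system. Trajectories
still moving at t_max (default 20 000; dynamics under strict Scoring are
exceptionally slow) are reported as unclassified, never dropped.
`classify_equilibrium` exposes the same fixed-point/stability check for a
single state, which is what the fast structural tests use in place of a
full basin scan.

Selection on institutional adherence at frequency f_Za (rest DISC-PRIVATE)
is summarized two ways that agree by construction at the sign change:
the instantaneous growth rate ḟ_Za = f_Za f_Zn (Π_Za − Π_Zn) (the
payoff difference is exposed as an auxiliary output), and the critical
benefit-to-cost ratio

ρ = (G − g•) / ( f_Zn [g_{Za,Zn} − g_{Zn,Zn}] + f_Za [G_Za − G_Zn] ),

evaluated at the reputation equilibrium (which does not involve b or c,
so ρ is a single number at fixed frequencies). Because the inequality
direction flips with the sign of the denominator, ρ is returned with an
orientation flag: `favored_above` (adherence favored for b/c > ρ),
`favored_below`, or `neutral` (denominator zero, ρ = +∞). With the
default errors e1 = e2 = 0.02 and f_Za = 1/50, tolerant (q = 0.1) Q = 2
Stern Judging gives ρ ≈ 49.3 favored above, and strict (q = 0.9) Q = 2
Shunning gives ρ ≈ 53.3 favored below.

The tax/bribe arithmetic (`institution_economics`) applies the one-shot
argument: individuals gaining b − c per round from institutionalized
cooperation will pay a per-round tax up to T = b − cρ, each of the Q
members collects NT/Q, and a member resists a bribe B when
(1 − p)B < NT/Q given discovery probability p.

## Agent-based simulator

The finite-population Monte Carlo (numba-compiled kernels, bit-exact under
a fixed seed) runs discrete generations:

1. every ordered donor–recipient pair, including self, plays one game;
   self-pairs are observable but contribute no net payoff;
2. every individual privately re-assesses every donor from one uniformly
   sampled interaction of that donor (sampling is independent across
   observers, with replacement); with probability *E* (empathy) the
   observer adopts the donor's own operative view of the recipient;
   institutional voters sample their own interactions and use the
   broadcast view (external board or adherent internal members) or their
   private image (non-adherent internal members), with no empathy;
3. broadcasts are recomputed from exactly Q fresh votes per member per
   round and take effect the following generation;
4. one random ordered pair (i, j) of distinct individuals: i adopts j's
   heritable trait with probability 1/(1+exp(−w[Π_j − Π_i])), payoffs
   averaged as total/N; the trait is the strategy, the adherence flag, or
   the joint type, depending on the protocol;
5. (strategy protocols only) with probability μ one random individual
   switches to a uniformly random strategy, possibly its current one.

Initial states draw strategies uniformly and all images and broadcasts as
fair coins. Adherents' private images are maintained but never consulted,
keeping the state uniform at no behavioral cost. External-board votes
depend only on broadcasts, so no persistent board state is kept.

Fixation experiments equilibrate reputations for 100 generations without
trait evolution, introduce the invader(s), run with mutation off until the
adherence trait hits 0 or N (a generous generation cap guards against
non-termination and raises rather than truncating), and report the
invader's fixation proportion with a Wilson 95% CI. The mean good
frequency at introduction averages the private image matrix over all
(observer, member) perspectives; a switch can weight in the broadcast as
an extra perspective.

### What the simulator does and does not emulate

The generator's defaults are the study conditions: N = 50, w = 1,
μ = 0.025, e1 = e2 = 0.02, b = 5, c = 1, complete factorial play each
generation. It captures demographic stochasticity, reputation
disagreement, and drift; it does not model spatial or network structure,
asynchronous payoff accounting, or evolution of the empathy parameter
itself. Agreement between the simulator and the analytic fixed points is
itself a test (an N = 500 all-adherent DISC population under strict Stern
Judging must realize the analytic cooperation rate within two standard
errors), with the analytic side serving as the independent oracle.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script
within minutes on one core, as the package's own choice of scale:
stationary-cooperation checks use 30 replicates × 4000 generations
(averaging the last 2000); strict-versus-tolerant ordering checks use 200
replicates × 1500 generations; neutral-fixation calibration uses 3000
replicates. Full-scale settings (2500 replicates, 10^4 generations) are
plain parameter choices away and produce tighter error bars, not
different conclusions. One quantity is genuinely borderline: stationary
cooperation under Q = 1 Scoring sits just below 50% with a heavily
bimodal replicate distribution (individual runs near 0 or near 0.95), so
30-replicate estimates scatter by several percentage points around ~47%.

## Known limitations

- The replicator layer treats empathy E only at 0 (private) or,
  implicitly, 1 (public); intermediate E exists solely in the simulator.
- Basin fractions from a finite lattice are estimates; resolutions below
  10 starts per edge are rejected.
- The internal-board composition rule for four-class populations is an
  extension choice (see above), not uniquely determined by the two-class
  mixture formula.
- Third- and higher-order norms (conditioning on donor reputation) and
  continuous reputations are out of scope.
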