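# reciprosim

Evolutionary dynamics of indirect reciprocity when moral reputations are
provided by a public institution.

In the donation game, a donor pays a cost *c* to give a recipient a
benefit *b*, or defects for free. Cooperation by indirect reciprocity
works when discriminators (DISC) help only partners of good moral
standing, with reputations updated by a second-order social norm — Stern
Judging, Simple Standing, Scoring, or Shunning. When everyone judges
privately, disagreements between observers erode cooperation; a public
institution of *Q* observers that broadcasts a thresholded consensus
("good" iff at least ⌈qQ⌉ of Q votes are good, with strictness *q*)
can restore it. `reciprosim` provides, for all four norms:

- **Reputation equilibria** — fixed-point solvers for the good-fraction of
  each strategy under full institutional adherence, and for the
  cross-class image matrix when institutional adherents (DISC-ADHERE)
  coexist with private assessors (DISC-PRIVATE), ALLC, and ALLD, with
  external or internal review boards.
- **Replicator dynamics** — payoffs at reputation equilibrium, trajectory
  integration on the strategy simplex, equilibrium detection with
  stability labels and basins of attraction, the growth rate of rare
  institutional adherents, the critical benefit-to-cost ratio ρ at which
  selection on adherence changes sign, and the tax/bribe bounds
  T = b − cρ and (1 − p)B < NT/Q for a self-sustaining institution.
- **Monte Carlo simulation** — a finite-population simulator (pairwise
  comparison imitation, execution and assessment errors, empathy,
  external/internal boards) for stationary cooperation rates and fixation
  probabilities of the adherence trait, bit-reproducible under a seed.

Intended users: researchers in evolutionary game theory and social
evolution who want a tested, scriptable implementation of
institutionalized moral assessment models.

## Worked example

```python
from reciprosim import (
    GameParams, Institution, get_norm,
    solve_mixed_equilibrium, critical_ratio, institution_economics,
)

params = GameParams(b=5, c=1, e1=0.02, e2=0.02)
norm = get_norm("stern_judging")

# An all-DISC population judging privately under Stern Judging settles at
# exactly 50% good reputations:
reps = solve_mixed_equilibrium(norm, params, Institution.tolerant(2),
                               (0, 0, 0, 1))
print(f"{100 * reps.g('Zn', 'Zn'):.1f}%")          # 50.0%

# Critical benefit-to-cost ratio for a rare adherent (frequency 1/50) of a
# tolerant Q=2 external institution:
cr = critical_ratio(norm, params, Institution(Q=2, q=0.1),
                    (0, 0, 1/50, 49/50))
print(f"rho = {cr.rho:.2f} ({cr.orientation})")     # rho = 49.33 (favored_above)

# Economics of a tax-funded institution at b/c above the threshold:
econ = institution_economics(b=60, c=1, rho=cr.rho, N=50, Q=2)
print(f"tax T = {econ.tax:.2f}, bribe bound = {econ.bribe_bound:.1f}")
# tax T = 10.67, bribe bound = 266.8
```

The first number says private Stern Judging leaves half the population
looking bad to any given observer — the disagreement burden institutions
remove. The second says adherence to this tolerant institution spreads
only when cooperation is worth more than ~49× its cost; above that, each
citizen would pay up to T per round in tax to keep the institution
running, and a board member loses more than any bribe below ~267 payoff
units by being caught.

From the shell, the same analyses run as subcommands that write CSV
tables, e.g.

```sh
reciprosim economics  --norm stern_judging,shunning --q 0.1,0.9 --out results/
reciprosim growth-map --norm shunning --q 0.9 --bc-grid 5:100:20 --out results/
reciprosim coop-sweep --norm scoring --q 0.05:0.95:19 --replicates 200 --out results/
```

See `reciprosim --help`; `docs/methods.md` documents the model, its
assumptions, and all numerical choices.

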