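# Methods

## The model

Twenty-five point agents (14 females, ids 0–13; 11 males) live on an
unbounded continuous plane. Time is event-driven: every agent carries a
waiting timer; the smallest timer fires next, all timers shrink by the
elapsed wait, and the actor redraws its timer uniformly from (0, 1]. One
*period* is 20 × group size = 500 activations; a run is 350 periods, and
all statistics use the collection window, periods 201–350, so that the
transient from the arbitrary initial configuration is excluded.

On activation an agent first looks for company within its personal
interaction range `per_space`. If anyone is there, an interaction partner
is drawn uniformly among those in range (a deliberate departure from a
strict nearest-neighbour rule: with persistent spatial positions the
nearest neighbour is almost always the previous partner, which locks
agents into exclusive pair bonds and starves the bystander statistics that
this package exists to measure). The interaction proceeds as:

1. **Mental battle.** Attack with probability *w*ᵏ where
   *w* = *D*ᵢ/(*D*ᵢ + *D*ⱼ). The exponent *k* (default 4) encodes risk
   aversion: an agent attacks freely only when clearly superior. *k*
   controls the fight rate per encounter and thereby — at the fixed 4:1
   groom:fight calibration — the per-encounter grooming probability; *k* = 1
   recovers the textbook "attack as often as you expect to win" rule, but
   makes a 4:1 groom:fight ratio unreachable (fights would be half of all
   encounters).
2. **Fight.** The winner is drawn with probability *w*; dominance updates
   by `step · (outcome − w)` with equal and opposite signs (winner–loser
   effect; upsets move values most), clamped at 0.01. Step sizes are
   sex-specific (females 0.08, males 0.10 — the "low intensity" regime
   that keeps the hierarchy shallow). The winner advances `chase_distance`
   toward the loser; the loser turns away and flees `flee_distance`. Both
   opponents' anxiety rises by `fight_increment`.
3. **Grooming.** If the agent declines to fight it grooms the partner with
   probability `g₀ · (anxiety + motivation)`, clamped to [0, 1]. Receiving
   grooming multiplies the receiver's anxiety by (1 − 0.5), giving it by
   (1 − 0.1); both participants' motivation resets to 0. Motivation grows
   by 0.05 per own activation while not being groomed; anxiety relaxes
   toward its baseline 0.25 by 5% of the gap per own activation.

Without a partner in range the agent follows the grouping rule: it keeps
its heading while at least `min_near_neighbors` (8) others are within
`near_view` (5 units); otherwise it turns toward the centroid of everyone
within `max_view` (50); if truly alone it rotates by the 90° search angle.
Requiring several near neighbours — rather than one — is what keeps the
group together on an unbounded plane: a fleeing loser and its pursuer
would otherwise satisfy each other's "someone is near" test and march away
from the group indefinitely (we observed exactly this failure mode:
25 agents decayed into travelling dyads spread over >1000 units).

**Social facilitation.** Immediately after every fight, each non-opponent
within `social_facilitation_radius` (4 units) of the fight has its current
timer multiplied by `facilitation_factor` (0.02) and keeps multiplying its
next `facilitation_boost_draws` (4) redraws by the same factor. The fight's
neighbourhood therefore acts next and keeps acting for a short burst. A
single one-off timer shrink is *not* enough: it merely reorders a fixed
set of activations, and the PC-vs-MC first-contact race then nets to zero;
the short sustained burst is what adds bystander activity to the
post-conflict window beyond what the matched control sees.

## Initial dominance

Initial values interpolate a uniform grid between 8 and 24.
`init_dominance_from_adi` maps any empirical dominance-index vector
affinely onto that range; absent one, the default sex-by-rank pattern is
constructed so that the initial female dominance index — the proportion of
male–female dyads in which the female outranks the male — equals the
0.48 calibration anchor as nearly as the 154 dyads allow, and the
measured index over the collection window lands at 0.49 ± 0.02.

## Variants

Each knock-out alters exactly one mechanism; only the grooming constant is
then re-calibrated (bisection on short pilot runs; frozen values in
`experiments.CALIBRATED_GROOM`) so that the groom:fight event ratio stays
near 4:1 and comparisons are not confounded by interaction volume.

| variant | change | grooming constant |
|---|---|---|
| complete | — | g₀ = 1.68 |
| no_social_facilitation | facilitation factor 1 (timers never shrunk) | g₀ = 1.66 |
| random_partners | partner drawn uniformly from the other 24; an interaction gate of 0.77 keeps the per-individual interaction volume at the complete model's level (random opponents are more mismatched, hence more fights) | g₀ = 2.53 |
| no_anxiety_increase | opponents' anxiety not raised by fights | g₀ = 2.64 |
| anxiety_independent_grooming | grooming probability a constant | p = 0.325 |

## PC-MC analysis

Every collection-window fight whose aggressor and/or victim is female
yields one conflict per female opponent. The post-conflict window spans
the focal's next three activations and restarts when the same two
opponents fight again before the focal's first activation; the matched
control anchors at the same within-period activation ordinal of the next
period (one period = one observation day) and never restarts. Windows
cut short by the log end, and conflicts in the final period (no control
day), are dropped.

A contact is a groom between the focal and a female bystander (both
opponents excluded): *received* if the bystander grooms the focal,
*solicited* if the focal grooms the bystander. Attracted / dispersed /
neutral classification compares the first-contact positions of the two
windows at the finest model resolution — elapsed activations since the
window anchor, the model-time analogue of the empirical 10-s block. (The
coarse alternative, three blocks delimited by the focal's activations, is
retained per pair for audit but is too blunt for classification: a
facilitation-driven contact burst and an ordinary control contact usually
share "block 1" and would tie as neutral, hiding precisely the effect
under study.) The per-female tendency is 100 (attracted − dispersed) /
total; group values average the females with at least one pair; study
values average 10 replicas.

For observational data the adapter maps timestamped records onto the same
pipeline with the field parameters: 5-minute windows, 10-s blocks,
restart on renewed aggression within 30 s, and PC–MC session pairing
supplied by the observer.

## Sociometric statistics

- **ADI / ranks** — mean over fought dyads of the fraction of dyadic
  fights won; ranks descend, ties and never-fighters to the bottom by id.
- **TauKr** — mean over rows of Kendall's τ-b between corresponding rows
  of two actor × receiver matrices (diagonal excluded, constant rows
  skipped); significance from jointly permuting the row and column
  identities of one matrix (p = (1 + #{≥ observed}) / (n + 1)).
  "Grooming in another context" excludes grooms inside any window whose
  focal is either member of the dyad, so post-conflict affiliation is
  never correlated with its own events.
- **Rank tests** — Mann-Whitney U (U = #{x > y} + ½ ties) and Wilcoxon
  signed ranks (statistic = sum of positive-difference ranks, zeros
  dropped, exact null for n ≤ 25), via scipy.
- **Cross-run combination** — Hochberg's step-up over the 10 per-run
  p-values; the combined probability is the smallest monotonized adjusted
  p.

## Numerical and design notes

- All randomness flows from one seeded generator per run; replica seeds
  derive from (study seed, run index) and runs are bit-reproducible.
- Ties in the scheduler and in nearest-neighbour queries break to the
  lowest id; tendencies from empty strata propagate as missing (NaN),
  never as zero.
- Fight location is the opponents' midpoint; facilitation is applied on
  the same clock tick as the fight.
- Overlapping windows from different conflicts are processed
  independently; both focals of a female–female fight are followed.
- Event logs are plain CSV; a manifest carries the fully-resolved
  configuration so any output is reproducible from its manifest alone.

## What the synthetic fixtures do and do not show

`fixtures.generate_planted_log` emulates only the statistical skeleton the
analysis assumes — round-robin activations with jitter, Bernoulli fights,
a planted probability that a bystander grooms the focal (or the focal a
bystander) in the first post-fight block, identical background grooming
inside and outside windows. It has no space, no dominance and no anxiety,
so fixture-based tests validate the PC-MC bookkeeping and its closed-form
expectations (E[tendency] = 100 p at zero background; a first-contact
race formula otherwise, accurate for small rates), not the simulator.
Conversely, passing fixture tests say nothing about whether the spatial
model produces realistic contact structure — that is what the study-level
checks are for.

## Parameters that matter most

| parameter | default | role |
|---|---|---|
| `risk_exponent` k | 4 | fight rate per encounter; with the 4:1 calibration also sets grooming propensity |
| `per_space` | 3 | interaction range; sets encounter rate and bystander reach |
| `near_view` / `min_near_neighbors` | 5 / 8 | group density (mean nearest-neighbour distance ≈ 1.5–2) |
| `social_facilitation_radius` | 4 | who counts as "close to a fight"; beyond ~the group radius facilitation degenerates into a global no-op |
| `facilitation_factor` / `boost_draws` | 0.02 / 4 | strength and persistence of the post-fight activation burst |
| `anxiety.fight_increment` | 0.15 | size of the solicited-affiliation signal |
| `groom_rate_scale` g₀ | 1.68 | calibrated, not free: pinned by the 4:1 groom:fight target |

## Known limitations

- The received-by-aggressor tendency runs ~5–8 points below the
  received-by-victim tendency for the same female (windows following her
  as aggressor are systematically less attractive than windows following
  her as victim), where field-calibrated expectations put the aggressor
  side slightly *above* the victim side. None of the explored levers
  (burst strength and persistence, facilitation radius, group density,
  fight displacement, partner rules, movement noise, risk exponent)
  removed this asymmetry; it appears rooted in the continuous-space
  geometry of who initiates fights where.
- Grooming propensity heterogeneity (via persistent anxiety differences)
  leaves a residual positive TauKr between received affiliation and
  grooming even under random partners; the correlations collapse to well
  under half their complete-model size rather than to exactly zero.
- No coalitions, no counter-attacks, no third dimension, no visual
  occlusion; affiliation in model logs is grooming only.
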