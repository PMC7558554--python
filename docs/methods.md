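# Methods

## Model overview and assumptions

The simulator couples three processes on a fixed undirected social network:
(1) a willingness-gated mapping from private emotion to public attitude,
(2) synchronous rounds of attitude exchange combining conformity-driven
type switching with a bounded-confidence value update, and (3) an
internalization step that writes interacted attitudes back into emotion and
re-opens the externalization gate under public-opinion feedback.

Standing assumptions:

- Four basic emotions (joy, anger, sadness, fear) with fixed arousal levels
  0.8 / 0.8 / 0.6 / 1.0. Arousal is a pure function of emotion type; no
  other arousal values ever occur.
- Attitude types mirror emotion types; type 0 means "not expressed" and
  always carries value 0. Silent agents neither send nor update, but they
  do count in the neighborhood-share denominators (an agent's audience
  includes its quiet contacts).
- The network is static: no entry, exit or rewiring. Participation changes
  only through the willingness gate at the two externalization events.
- Exactly two externalization cycles are simulated. Emotions of silent
  agents are frozen during interaction; internalization applies once, at
  the end of stage 1, to expressing agents only.
- All updates within a round are synchronous (computed from the time-t
  snapshot), so results are independent of agent iteration order.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| N | agents | 1000 | baseline network: BA, m=10 |
| α, γ, λ | extroversion, conformity, receptivity | N(0.5, 0.15) on [0,1] | clipped normal |
| δ | expression ability | N(1, 0.2) on [0,2] | δ>1 exaggerates |
| ζ | internalization ability | N(0.9, 0.05) on [0,1] | scales attitude→emotion |
| x² | initial pleasure | ±N(0.5, 0.15) | joy positive, others negative |
| β₁, β₂ | life relevance, political sensitivity | 0.9, 0.5 | event properties |
| k₁ | subjective-willingness constant | 0.7 | |
| k₂ | feedback coefficient | 1.0 | no published value; exposed in config |
| W_part, W_full | expression thresholds | 0.2, 0.4 | closed on the left |
| a | perception adjustment | 1.0 | ε = a·arousal; no published value |
| d₁, θ₁ | assimilation threshold / rate | 0.5, 0.5 | no published values |
| P₁, P₂ | formation thresholds | 0.5, 0.3 | participation / dominant share |
| t₁ | stage-1 rounds | 30 | schedule knob |
| S_ij | tie strengths | N(0.5, 0.15) on (0,1] | no published distribution |

k₂, a, d₁ and θ₁ have no published values; the defaults above were fixed
once as round mid-range choices and are exposed as top-level config keys.
Tie strengths reuse the clipped-normal family of the traits for
consistency, truncated to (0, 1] so every edge transmits.

## Numerical and design choices

- **Switch rule.** The model states only that an agent keeps its type when
  Pn_i > T_iu. We switch deterministically to the mainstream type whenever
  that gate fails (and T_iu > 0). This choice is what produces the
  characteristic one-round collapse to the dominant attitude under a
  heavily skewed emotion mix, and the 20–30-round stabilization bands; a
  probabilistic variant (switch with probability T_iu) is available via
  `interact_round(..., bernoulli_switch=True)` but converges far more
  slowly, with geometric tails of late switches. Note that agents whose
  conformity clips to exactly 0 can never switch; in a 1000-agent
  population a handful of such holdouts occasionally survive an otherwise
  one-sided collapse.
- **Boundaries.** The externalization bands are closed on the left
  (W = W_part expresses partially, W = W_full fully), making the three
  branches a partition. Willingness is clamped to [0, 1]; attitude values
  are clamped to [−1, 1] (exaggeration δ > 1 and perceived averages can
  otherwise leave the representation range; removing the clamp changes the
  steady-round measurements by less than one round).
- **Assimilation condition.** The bounded-confidence gate is read with an
  absolute value, |y − ȳ| < d₁, as symmetry of a threshold demands.
- **Degenerate neighborhoods.** An expressing agent with no neighbors or no
  expressing neighbors is inert for the round. An agent that keeps its type
  but has no same-type neighbors leaves its value unchanged (the weighted
  average is undefined). Mainstream ties break toward the lowest type
  index, deterministically.
- **Initialization edge cases.** Emotion-type allocation uses
  largest-remainder rounding so scenario proportions like 70/10/10/10 are
  exact (a multinomial mode exists behind a flag). A pleasure draw clipped
  onto 0 is redrawn once and then nudged to ±1e-6: an exactly neutral agent
  would be permanently silent.
- **Steadiness.** A round is quiet when no agent changed type and the
  largest per-agent value change is < 1e-3. The steady round is the round
  of the last change, confirmed by a trailing window of 3 quiet rounds.
  Because the assimilation update either moves a value by θ₁·|ȳ − y| or
  stops exactly (once the gap reaches d₁), quieting is sharp rather than
  asymptotic under the deterministic switch rule.
- **Stage 2.** Opinion-field shares and N_A for the feedback term are taken
  among expressers at the end of stage 1. If the formation test fails
  (participation, steadiness or dominance), the feedback term is 0 and
  stage 2 still runs — agents may drop out through subjective willingness
  alone. Agents already expressing keep their interacted value when they
  re-qualify; newly joining agents externalize from their (internalized or
  frozen) emotion. Stage 2 stops at steadiness or after 200 rounds.
- **RNG discipline.** Every stochastic step takes a numpy Generator; one
  round consumes exactly one uniform per node, in node order, so a
  straight-line reference implementation can replay the same draws. Sweep
  replicates derive child seeds from a single base seed via SeedSequence.

## Network generation and metrics

Topologies come from networkx: Barabási–Albert (m = 10 → mean degree
≈ 19.3 at N = 1000), connected Watts–Strogatz (K = 30, p = 0.1; rewiring
conserves edges, so the mean degree is exactly K), Erdős–Rényi (p = 0.0202
→ mean degree ≈ 20.2) and complete. Disconnected draws are rejected (up to
100 retries) because the mean path length must be finite. Metrics use
scipy: BFS all-pairs distances and a dense triangle count
(diag(A³)/deg(deg−1)), which keeps the 1000-node complete graph at a few
seconds; nodes of degree < 2 contribute clustering 0. Path-length and
clustering values of the random families are seed-dependent; only the
complete graph's (1, 1, 999) and the WS mean degree are exact.

## What the synthetic populations do and do not capture

The generator produces the study conditions themselves — clipped-normal
traits, fixed emotion-type proportions with sign-constrained pleasure, and
parametric random graphs. It does not emulate real social-media data:
no degree-correlated traits, no content, no heterogeneous activity rhythms
or forgetting, and tie strengths are i.i.d. rather than structurally
embedded. Passing tests therefore demonstrate internal consistency of the
mechanism and reproducibility of the simulated regularities, not empirical
validity on platform data.

## Problem sizes used in tests

Unit tests run on populations of ≤ 200 agents and hand-built graphs of
≤ 6 nodes (where the vectorized round is checked against a brute-force
transcription). The end-to-end checks use the full 1000-agent baseline
with 20 replicate seeds per condition, and stage-1 horizons of 100–150
rounds, which the steady-state early stop keeps to seconds per condition.

## Known limitations

- Sadness-dominant populations stabilize in ≈ 27 rounds here, slower than
  joy/fear (≈ 24), not faster; the stabilization time is governed by the
  unpublished assimilation parameters (d₁, θ₁) and by the sparser
  expressing subgraph of the low-arousal scenario.
- Under an even initial emotion mix, the deterministic conformity gate
  locks in near-equal attitude shares on every topology, so the
  public-opinion feedback term stays small and stage-2 participation falls
  below stage 1 on all four network families (ordering
  WS > ER > BA > complete). The model does not reproduce a qualitative
  amplification contrast between scale-free/random and
  small-world/complete topologies.
- Exactly two cycles; no churn, forgetting, or online-time heterogeneity.
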