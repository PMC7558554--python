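# emopinion

A Monte-Carlo multi-agent simulator of how individual emotions turn into
publicly expressed attitudes and, through interaction on a social network,
into online public opinion — and how that formed opinion feeds back on who
keeps talking. It is aimed at researchers in opinion dynamics and
computational social science who want a reproducible, config-driven
implementation of an emotion-aware public-opinion propagation model.

## The model

Each of N agents carries an internal emotion `x_i = (x¹, x², x³)`: a basic
emotion type x¹ ∈ {joy, anger, sadness, fear}, a signed pleasure (valence)
degree x² ∈ (−1, 1), and an arousal level x³ fixed by the type (sadness
0.6 < joy = anger 0.8 < fear 1.0). Public state is an attitude
`y_i = (y¹, y²)` with type y¹ (0 = silent) and value y² ∈ [−1, 1].

**Externalization.** An agent speaks when its expression willingness
`W_i = clamp(WS_i + WO_i)` crosses thresholds `W_part < W_full`:

- subjective willingness `WS_i = |x²| · x³ · α_i · (β₁/β₂) · k₁`, with
  extroversion α_i, event life-relevance β₁ and political sensitivity β₂;
- objective willingness `WO_i = k₂ · (P_i − 0.25) · N_A/N`, active only
  after public opinion has formed: holding a view shared by more than a
  quarter of the expressers encourages speaking, a minority view suppresses
  it.

Between the thresholds the attitude is partially expressed; above `W_full`
fully: `y² = δ_i · x²` with expression ability δ_i ∈ [0, 2] (δ > 1
exaggerates).

**Interaction.** Each round, every expressing agent perceives each
expressing neighbor j as `O_ij = y²_j · ε_j · λ_i · S_ij` (inciting force
ε_j = a·x³_j, receptivity λ_i, tie strength S_ij). With Pn_iu the all-
neighbor share holding the local mainstream attitude u and Pn_i the share
holding the agent's own, the conformity pressure is
`T_iu = |Pn_iu − Pn_i| · γ_i`. If `Pn_i > T_iu` the agent keeps its type and
applies a bounded-confidence update against the perceived same-type average
ȳ: when `|y² − ȳ| < d₁`, the attitude strengthens by `θ₁·|ȳ − y²|` in its
own direction; otherwise it switches to u and adopts the perceived
mainstream average.

**Formation and feedback.** Public opinion forms when participation
N_A/N ≥ P₁ (50%), attitudes are steady, and at least one type holds ≥ P₂
(30%) of the expressers. After t₁ rounds, expressing agents internalize
their attitude back into emotion (`x¹ ← y¹`, `x² ← ζ_i · y²`), willingness
is recomputed with the feedback term, silent agents may join and weakly
motivated ones drop out, and interaction continues until steady.

## Worked example

```python
from emopinion import SimulationConfig, run_from_config

traj = run_from_config(SimulationConfig(), seed=7)
print(traj.summary())
```

prints

```
{'opinion_formed': True, 'dominant_types': [2, 4], 'stage1_steady_round': 27,
 'stage2_steady_round': 31, 'n_expressing_stage1': 645, 'n_expressing_stage2': 538}
```

With the baseline configuration (1000 agents on a scale-free network, equal
25% emotion shares), 645 agents externalized an attitude; attitudes were
steady by round 27, public opinion formed with anger (2) and fear (4) as
dominant attitudes, and 538 agents carried the discussion into the second
externalization stage. `traj.to_frame()` gives the per-round trajectory
(participation, per-type expresser shares and mean attitude values):

```
   stage  t  n_expressing  prop_type1  prop_type4
0      1  0           645    0.258915    0.322481
1      1  1           645    0.275969    0.353488
2      1  2           645    0.274419    0.367442
```

The same runs are available from the shell:

```bash
emopinion run -c config.yaml --seed 7 --out run_out/
emopinion netstats --kind complete -n 200
# {"network":"complete","n_nodes":200,"avg_path_length":1.0,...}
emopinion sweep -c config.yaml -s sweep.yaml --replicates 20 --out sweep_out/
```

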