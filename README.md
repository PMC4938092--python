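# glmpp — point-process GLM inference of call-timing networks

When animals call in a group, several influences converge on each
individual at once: its own recent calls, its partner's, everyone
else's.  Pairwise cross-correlation cannot disentangle these (a chain
A → B → C produces a spurious A → C correlation), and Markov sequence
models discard timing.  `glmpp` fits a *generative* model of the group's
call timing — a set of coupled linear–nonlinear Poisson processes — and
reads the directed influence structure straight off the fitted
parameters.  It was built for timestamped call data from small groups of
zebra finches (4–8 birds, ~12 calls/bird/min, sessions of 15–240 min,
optionally split by call type), but applies to any multi-channel event
train.

## Model

Channel j emits events with conditional intensity

    λ_j(t) = σ( b_j + Σ_i (K_ij ∗ y_i)(t) )

where y_i is channel i's event train, K_ij the influence kernel from i
to j (reflexive i = j included — self-suppression while calling is real
structure), b_j a constant base drive, and σ a monotonic non-negative
nonlinearity.  Influences can combine **additively** on the rate scale
(σ = softplus) or **multiplicatively** on the log-rate scale (σ = exp);
both are fitted by penalised maximum likelihood (ridge MAP) and compared
by likelihood ratio.  Kernels live on a raised-cosine basis over lags
0–2 s.  Fitted kernels are summarised by relation category
(self–self / self–partner / self–other) as median ± 5–95 percentile
bands, and projected by *uncentered* PCA into 2-D, where distance from
the origin is a scalar influence magnitude.  Permutation (MRPP),
correlation and predictability tests quantify network structure and its
day-to-day stability.

## Worked example

```python
from glmpp import GroupScenarioConfig, PointProcessGLM, group_scenario

# a synthetic 30 min session of 4 birds with known ground-truth kernels
model, session = group_scenario(GroupScenarioConfig(seed=42, duration=1800.0))
res = PointProcessGLM(session).fit("additive")
print(res.summary())
```

```
Point-process GLM network fit
================================================================
channels: 4   link: additive   nonlinearity: softplus
bins: 180000 x 10 ms   basis: 8 bumps over 2.00 s
neg. log-likelihood: 9764.77 (penalized 9785.32, ridge 1.0)
converged: True   iterations (max/receiver): 49
----------------------------------------------------------------
channel       events    rate/s  base drive rest rate/s
bird1            384     0.213       0.071       0.111
bird2            383     0.213       0.040       0.091
bird3            359     0.199       0.037       0.090
bird4            364     0.202       0.074       0.113
----------------------------------------------------------------
strongest cross-channel kernels (by L2 norm):
  bird1 -> bird3: peak +0.736 at 280 ms
  bird3 -> bird2: peak +0.897 at 240 ms
  bird1 -> bird4: peak +0.685 at 180 ms
  bird1 -> bird2: peak +0.723 at 280 ms
  bird2 -> bird1: peak +0.669 at 230 ms
```

Each bird called at ~0.2 events/s (12 calls/min).  The recovered
cross-bird kernels peak at +0.7–0.9 events/s of excess calling rate
around 180–280 ms after a stimulus call — the ground truth used to
generate this session peaks at +0.6 at 250 ms, so shapes and timescales
are recovered from half an hour of data.  `res.kernel(i, j)` returns any
single influence curve; `res.simulate(duration, seed)` generates new
synthetic sessions from the fitted network; `res.kernel_table()` feeds
the PCA/summary layer.

The same workflow is available from the shell:

```sh
glmpp simulate --scenario group --seed 42 --duration 1800 --out-dir data/
glmpp pipeline --events data/events.csv --out-dir analysis/
glmpp demo-chain --out-dir chain/ --seed 1     # the A->B->C comparison
glmpp stats mrpp --projection analysis/projection.csv --out mrpp.json
```

Event CSVs have columns `time,individual[,calltype][,session]`, times in
seconds; `#` lines are comments.

`fit` and `pipeline` accept a YAML config (`--config fit.yaml`) whose keys
mirror `FitConfig`:

```yaml
bin_width: 0.01        # s, likelihood discretisation
n_basis: 8             # raised-cosine bumps per kernel
support: 2.0           # s, kernel memory
stretch: 0.1           # log-warp of the bump spacing
penalty: 1.0           # ridge strength on kernel weights
link_mode: additive    # additive | multiplicative | both
nonlinearity_scale: 0.1
tol: 1.0e-6            # optimiser gradient tolerance
max_iter: 500
```

`simulate --config` takes the corresponding scenario dataclass fields
(e.g. `n_individuals`, `target_rate`, `self_suppression`,
`other_excitation`, `pair_structure` for the group scenario).  Exit
codes: 0 ok, 2 validation error, 3 fit did not converge.

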