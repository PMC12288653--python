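# softmode

Tools for studying how **simple (low-dimensional) integral-feedback
controllers** shape the eigenmode structure of high-dimensional regulatory
networks. Selection for homeostasis under a controller that senses only
`k ≪ N` linear projections of the state drives the emergence of a *soft
mode* — a slow eigendirection with a large mode gap — which channels
high-dimensional perturbations into one direction that the simple controller
can sense and correct.

The package provides:

- **`softmode.grn_dynamics`** — nonlinear Michaelis–Menten gene-network ODEs
  with static environmental forcing and controller coupling; fixed points,
  analytic Jacobians, eigenmode ordering, mode gap, stiff integration.
- **`softmode.controller`** — k-channel proportional–integral controllers
  with orthonormal sensing rows and per-channel action vectors; knockouts.
- **`softmode.linear_theory`** — the analytic linear model: uncontrolled and
  integral-controlled steady-state responses, exact second-moment expected
  deviation over Gaussian forcing ensembles (with a Monte-Carlo oracle),
  entropy-based effective rank, optimal sensing/action geometry versus mode
  gap, and the gap-benefit curve.
- **`softmode.evolution`** — simulated-annealing in-silico evolution of
  network parameters under selection for homeostasis (stiffness-normalized
  relative deviation cost, common-random-number Metropolis acceptance,
  elitist trace).
- **`softmode.experiments`** — the two prediction experiments: *dual
  buffering* (a controller selected against environmental perturbations also
  buffers mutational ones, but only on gap networks) and *knockout
  dimensionality reduction* (knocking the controller out exposes the soft
  mode and lowers the PCA dimensionality of the environmental response).
- **`softmode.config` / `softmode.io` / `softmode.cli`** — strict YAML
  configs, JSON/CSV artifact round-trips, seed-substream management, and the
  command-line interface.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion; the
in-silico evolution criteria share a session fixture that runs twenty
annealing chains (a few minutes on one CPU). Everything else is fast.

## CLI

```sh
softmode fixtures make-network --seed 3 --out net.json
softmode simulate --net net.json --seed 1 --out traj.csv
softmode evolve --config cfg.yaml --seed 0 --out trace.csv --net-out net.json
softmode theory-sweep --n-dims 20 --gaps 1,3,10,30,100 --out sweep.csv
softmode experiment dual-buffering --net-gap gap.json --net-nogap flat.json \
    --ctrl ctrl.json --out result.csv
softmode experiment knockout-dim --net gap.json --ctrl ctrl.json --out dim.csv
```

Configs are YAML with sections `network`, `controller`, `fitness`, `anneal`,
`mutation`, `ensemble` and a global `seed`; unknown keys are rejected. Every
stochastic component draws from a substream derived from the global seed and
a named salt, so any result CSV regenerates bit-identically from its config
and seed.

## Model sketch

Gene expression follows
`dn_a/dt = Σ_b k_ab n_b/(n_b+K_ab) − γ_a n_a + δe_a n_a − Σ_i g_a^(i) I_i`,
with `I_i = c_p s_i·δn + c_i ∫ s_i·δn dt` the PI error of channel `i`. In
the linear regime the integral feedback zeroes the sensed projection, leaving
`δx = δẽ − [(δẽ·s)/(ã·s)] ã` in rescaled eigencoordinates. With one slow
mode and a mode gap `g`, the optimally aligned controller cancels the slow
component entirely and the residual deviation falls as the gap grows — the
fitness benefit that drives soft-mode evolution when the controller is
simple, and disappears when it has full observability.
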