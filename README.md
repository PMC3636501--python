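# ca3metric

How much of the Euclidean metric of physical space survives inside a
self-organised neural map?  `ca3metric` simulates a rate model of the
hippocampal CA3 network driven by sparse, effectively random dentate-gyrus
(DG) input while a virtual rat explores a 1 m² periodic environment, decodes
the resulting population activity, and quantifies the *metric resolution* of
the representation — the headline result being that a CA3-like map preserves
the global torus topology of the environment almost perfectly while retaining
only about 10 % of the optimal local spatial resolution (χ ≈ 0.1).

It is a library for computational neuroscientists studying population codes
for space, with a thin command line for running the full protocol.

## Model

CA3 pyramidal units are threshold-linear:

```
η_i(x) = g [ Σ_j c^MF_ij J^MF β_j(x) + Σ_k c^RC_ik J^RC_ik η_k(x) + δ_i − T ]₊
```

* **DG input** — granule cell *j* is active with probability `p_DG = 0.033`
  and carries `Q_j ~ Poisson(q)` Gaussian place fields of width `σ_f`:
  `β_j(x) = Σ_k β₀ exp(−(x − x_jk)² / 2σ_f²)`.
* **Sparsity control** — at every update the threshold `T` is set so the
  population sparsity `a = ⟨η⟩²/⟨η²⟩` equals 0.1 and the gain `g` so the mean
  rate equals 0.1 (inhibition is summarized by this control, not modelled).
* **Learning** — during exploration the recurrent weights follow a
  trace-based Hebbian rule `ΔJ_ij = γ η_i (η_j − Λ_j)` with `Λ_j` the mean of
  the presynaptic rate over the last τ = 14 theta steps; weights are clipped
  at zero and the incoming weights of each unit are normalised to sum to 1 at
  the end of the session.
* **Decoding** — position templates (mean population vector per bin of an
  8×8 grid) are built from a training run; test activity is decoded to the
  nearest template in Euclidean distance, giving a 64×64 confusion matrix
  `P(decoded | actual)` per unit sample, and its translation average, the
  reduced matrix `Q(x − x₀)`.
* **Metric resolution** — the reduced matrix is fitted with a Gaussian bump
  (peak `pc`, width `w`, volume `a`).  Reference confusion matrices made of
  `1/a` bumps of adjustable width σ interpolate between a spatially exact
  code (σ = 0) and one whose bump is pure spatial blur (σ = w).  Solving σ so
  the reference information matches the measured full-matrix information
  defines `χ = 1 − σ/w`.  When the DG input is removed (attractor retrieval
  with deterministic drift), each reference bump is split into two adjacent
  half-height bumps.

## Worked example

```python
import numpy as np
import ca3metric as cm

cfg = cm.ExperimentConfig.from_preset("desk", seed=1)   # 4,500 DG / 300 CA3
result = cm.run_experiment(cfg)

chi = result.chi["on"]
print(np.round(chi.chi, 3))        # chi per sample size 1..256
print(round(chi.chi_mean, 3), round(chi.chi_sd, 3))
print(round(result.embedding.stress, 4))
```

prints (a few minutes on one CPU):

```
[0.    0.156 0.071 0.049 0.097 0.051 0.035 0.043 0.049]
0.061 0.042
0.0435
```

meaning: across decoding samples of 1–256 units the metric resolution of the
DG-driven map hovers around χ ≈ 0.06–0.1 — the error bump in the reduced
matrix is almost entirely (σ ≈ 0.94 w) genuine spatial imprecision, close to
the loosest metric compatible with the observed errors — while the Sammon
stress of 0.04 shows the 64 templates still arrange themselves on an almost
perfect torus: global topology is preserved, local metric is loose.

The `examples/` directory walks through each capability (trajectory and DG
input, learning, decoding, metric resolution, global topology); each script
prints and explains its numbers.  The CLI mirrors the library:

```
ca3metric run-all --preset desk --seed 1 --out runs/desk1
ca3metric simulate-learn --preset tiny runs/t && ca3metric build-templates runs/t
```

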