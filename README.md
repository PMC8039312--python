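# stlrnet

Simulator comparing two biologically grounded synaptic plasticity rules —
the Hebbian learning rule (HEBLR) and the spatiotemporal learning rule
(STLR) — on a single-layer feed-forward network of binary threshold
neurons trained on similar spatiotemporal context sequences. It is aimed at
computational neuroscientists studying how hippocampal-style learning rules
self-organize synaptic weight distributions, and in particular at the
contrast between **pattern completion** (similar input sequences collapse
onto one output representation) and **pattern discrimination** (similar
sequences are mapped to distinct representations).

## Model

The network is a McCulloch–Pitts layer of *N* output neurons fully connected
to *N* binary inputs. For an input frame *X(t)* = (*x*₁, …, *x_N*) ∈ {0,1}ᴺ:

- internal state: *sᵢ = Σⱼ wᵢⱼ xⱼ*
- output: *yᵢ = F(sᵢ − η)* with the Heaviside step *F* (equality fires).

Training presents a sequence of 5 frames, one weight update per frame.
Frames are constant-weight binary patterns (length 120, exactly 60 ones)
with **exact** pairwise Hamming distance 10, built by a shared-core design;
a *same-context* sequence repeats one pattern, a *different-context*
sequence presents five distinct patterns.

**HEBLR** — output-gated potentiation. Whenever *sᵢ ≥ η*, every active
synapse of neuron *i* gains a fixed increment: *wᵢⱼ ← wᵢⱼ + δw* for
*xⱼ = 1*. Non-firing neurons never change.

**STLR** — coincidence-gated LTP/LTD, independent of output firing. Each
active synapse carries a coincidence coefficient *Iᵢⱼ* measuring the
cooperative activity of the other coactive inputs
(*Iᵢⱼ = wᵢⱼxⱼ / sᵢ* in the large-network approximation; by default the
classification uses the unit-sphere projection *Ĩᵢⱼ = w̃ᵢⱼ · s̃ᵢ*).
Two BCM-style thresholds split the active synapses into three branches:

- *Iᵢⱼ ≥ θ₁* → enhancement (+δw),
- *θ₁ > Iᵢⱼ > θ₂* → invariance (no change),
- *Iᵢⱼ ≤ θ₂* → attenuation (−δw, weights may go negative).

The per-neuron branch fractions *qᵢ + rᵢ + pᵢ = 1* and the R1/R2/R3
classification of neurons by normalized state *s̃ᵢ* are exposed as
diagnostics. After training, the pooled weight histogram is summarized by a
fixed mode-detection procedure (moving-average smoothing + prominence-based
peak finding), which turns "bimodal" / "multimodal" into machine-checkable
statements.

The estimators follow scikit-learn conventions (`fit` on a frame stack,
`predict`/`decision_function`, `get_params`/`set_params`, fitted attributes
with trailing underscores) and compose with sklearn pipelines.

## Worked example

```python
import stlrnet as sn

ps = sn.generate_pattern_set(n=120, k=5, hd=10, seed=0)
seq = sn.make_different_context_sequence(ps)          # frames A1..A5
net = sn.STLRNetwork(random_state=2).fit(seq.frames)  # 5 plasticity steps
hist = sn.weight_histogram(net.coef_, columns=net.active_mask_)
print(sn.count_modes(hist).n_modes)                   # -> 4
```

or, from the shell, the full 2×2 rule × context protocol:

```bash
stlrnet grid --seed 0 --out results/demo
stlrnet report --results results/demo
```

which prints

```
seed: 0
  heblr_different    modes 1 -> 2  at [0.607, 1.912]
  heblr_same         modes 1 -> 2  at [0.113, 2.092]
  stlr_different     modes 1 -> 4  at [-1.075, -0.095, 1.095, 2.005]
  stlr_same          modes 1 -> 3  at [-1.075, 1.305, 2.005]
  heblr              mean pairwise output Hamming distance 13.20
  stlr               mean pairwise output Hamming distance 16.60
```

Reading: every condition starts from a flat (uniform) weight distribution
(1 mode). Hebbian training ends bimodal in **both** contexts — an enhanced
block (winners' potentiated synapses, right mode) and an untouched block —
because the winner set is frozen by the firing threshold and insensitive to
the small differences between frames. The STLR ends with a dominant
**negative** (attenuation) and **positive** (enhancement) mode for a
repeated frame, plus additional modes — one neighbourhood per distinct
input — in the different-context condition (4 modes here). The last two
lines compare five replicate networks (shared initial weights) trained on
the five similar same-context sequences: STLR outputs end further apart
than HEBLR outputs, the output-level signature of discrimination vs.
completion.

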