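# torsiondiff

Generative modeling of protein backbone structures by denoising diffusion
over internal angles.

Designing new proteins starts with designing plausible backbones. Instead
of generating Cartesian coordinates — which forces equivariant
architectures and tends to break chirality — this package describes a
backbone of `N` residues (N, Cα, C atoms) as a matrix of six wrapped
angles per residue pair,

    x ∈ [−π, π)^{(N−1)×6},   rows = (ψ, ω, φ, θ₁, θ₂, θ₃),

three dihedrals and three bond angles that fully determine each next
residue's placement given the current one. Because every residue is its
own reference frame, the representation is invariant to rotation and
translation, and a *plain* bidirectional transformer suffices as the
denoiser. A denoising diffusion probabilistic model corrupts angles with
wrapped Gaussian noise under a cosine variance schedule,

    q(x_t | x_{t−1}) = N_wrapped(x_t; √(1−β_t) x_{t−1}, β_t I),  t = 1..T,

trains the network to predict the noise ε with a wrapped smooth-L1 loss
(transition β_L = 0.1π), and generates backbones by iterative denoising
from wrapped white noise, re-wrapping at every step, then un-shifting by
the training set's circular mean. Cartesian structures are rebuilt by
natural extension of reference frame with average bond lengths, and
carbonyl oxygens placed in the trans peptide-plane position.

It is aimed at researchers in protein design and generative structural
biology who want a transparent, fully inspectable reference
implementation: every component — geometry, schedule, loss, transformer,
backprop, sampler — is plain numpy/scipy, testable end to end on synthetic
data with no downloads.

## What's in the box

| module | contents |
| --- | --- |
| `torsiondiff.geometry` | dihedral/bond-angle math, featurization, NeRF reconstruction, oxygen placement, PDB I/O |
| `torsiondiff.diffusion` | wrap function, cosine schedule, wrapped forward/reverse processes, wrapped smooth-L1 |
| `torsiondiff.model` | the transformer denoiser, training loop (AdamW, warmup/decay), self-describing checkpoints |
| `torsiondiff.data` | domain-set loading/filtering, 80/10/10 splits, random crops, circular-mean normalization, synthetic fixtures |
| `torsiondiff.baselines` | angle-shuffle generator, autoregressive next-angle transformer |
| `torsiondiff.evaluation` | circular angle histograms, Ramachandran densities, P-SEA-style SSE annotation, diversity clustering, designability shell |
| `torsiondiff.cli` | `torsiondiff train / sample / evaluate / fixtures` |

## Worked example

Train a small denoiser on a synthetic two-mode wrapped-Gaussian mixture
(one helix-like mode, one strand-like, weights 0.65/0.35) and check that
sampling recovers the mixture:

```python
import numpy as np
from torsiondiff.experiments import mixture_recovery_study

result = mixture_recovery_study(seed=0)
print("max mode-location error (rad):",
      round(result["mode_location_error_rad"], 4))
print("max mode-weight error:", round(result["mode_weight_error"], 4))
print("empirical weights:", result["empirical_weights"].round(3))
```

On one CPU this takes a few minutes and prints

```
max mode-location error (rad): 0.018
max mode-weight error: 0.0831
empirical weights: [0.733 0.267]
```

meaning the 1008 generated angle rows place both mode centers within
0.02 rad of the ground truth and the helix/strand mixing proportions
within 0.09 of the true 0.65/0.35 — the denoiser has learned the wrapped
mixture, not merely its mean.

Backbones come out as real structures, too:

```python
from torsiondiff.geometry import reconstruct_backbone, place_oxygens, write_pdb
from torsiondiff.experiments import train_toy_denoiser
from torsiondiff.diffusion import sample

ck = train_toy_denoiser(seed=0)
angles = sample(ck.denoiser(), length=17, schedule=ck.schedule,
                mu=ck.mu, rng=np.random.default_rng(1))
write_pdb(place_oxygens(reconstruct_backbone(angles)), "generated.pdb")
```

At full scale the CLI drives the same pipeline over a local copy of a
domain set (e.g. CATH v4.3.0 non-redundant): `torsiondiff train` filters
chains under 40 residues, crops longer chains to 128-residue windows each
epoch, splits 80/10/10, and trains the d=384 transformer;
`torsiondiff sample` then generates 10 backbones per integer length in
[50, 128) — 780 structures — and `torsiondiff evaluate` compares angle
distributions, Ramachandran densities, and secondary-structure
co-occurrence against a reference set. See `scripts/train_cath_full.py`
for the full-scale protocol (requires the dataset locally and substantial
compute).

## Documentation

The model, its assumptions, all numerical conventions (dihedral sign, seed
frame, the edge-row bond angle, degenerate torsions), and the synthetic
study conditions are documented in [`docs/methods.md`](docs/methods.md).
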