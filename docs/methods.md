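# Methods

## Representation: six wrapped internal angles per residue pair

A backbone of `N` residues (atoms N, Cα, C) is encoded as a matrix
`x ∈ [−π, π)^{(N−1)×6}`. Row `i` holds, in fixed order, the dihedrals
ψᵢ (Nᵢ–Cαᵢ–Cᵢ–Nᵢ₊₁), ωᵢ (Cαᵢ–Cᵢ–Nᵢ₊₁–Cαᵢ₊₁), φᵢ (Cᵢ–Nᵢ₊₁–Cαᵢ₊₁–Cᵢ₊₁)
and the bond angles θ₁ (Nᵢ–Cαᵢ–Cᵢ), θ₂ (Cαᵢ–Cᵢ–Nᵢ₊₁), θ₃ (Cᵢ–Nᵢ₊₁–Cαᵢ₊₁).
Row `i` depends only on atoms of residues `i` and `i+1`, so the
representation is invariant under rigid motion of the whole chain and the
generative model needs no equivariance machinery.

Cartesian coordinates are recovered by natural extension of reference frame
(NeRF): each atom is placed at a fixed average bond length, at the stored
bond angle to the two preceding atoms, and at the stored torsion to the
three preceding atoms. Bond lengths are configurable constants with
Engh–Huber-style defaults (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; C=O
1.231 Å and an O–C–N angle of 122.7° for oxygen placement).

Numerical conventions worth stating explicitly:

- **Dihedral sign.** Torsions follow the standard structural-biology
  convention (the `atan2` form used by biotite and MDAnalysis): looking
  along the central bond, clockwise rotation of the far bond relative to
  the near bond is positive. Under this convention right-handed α-helices
  have φ ≈ −57°, which is what the Ramachandran region boxes and the
  chirality analyses assume.
- **Seed frame.** Reconstruction is made deterministic by convention:
  residue 0's N at the origin, its Cα on +x, its C in the xy-plane with
  positive y. Internal angles are invariant to this choice.
- **Edge row.** The matrix has `N−1` rows but placement consumes one bond
  angle more than the θ₁ column provides (θ₁ of the final residue has no
  slot; row 0's θ₁ is absorbed by the seed frame). The last residue's C is
  therefore placed reusing the final row's θ₁. The angle-space round trip
  featurize(reconstruct(A)) = A remains exact; the Cartesian round trip is
  exact whenever θ₁ varies smoothly (exactly, for idealized fixtures).
- **Degenerate torsions.** If three consecutive atoms are collinear during
  reconstruction, the undefined azimuth is resolved as 0 about an arbitrary
  perpendicular axis. Wrapped bond angles of −π (i.e. π) produce collinear
  placement, as expected.

## Wrapped denoising diffusion

The forward process corrupts wrapped angles over `T` discrete steps,

    q(x_t | x_{t−1}) = N_wrapped(x_t ; sqrt(1−β_t) x_{t−1}, β_t I),

with a cosine variance schedule: ᾱ_t = f(t)/f(0),
f(t) = cos²(((t/T + s)/(1 + s))·π/2), s = 8×10⁻³, and
β_t = clip(1 − ᾱ_t/ᾱ_{t−1}, ≤ 0.999). The squared-cosine form is the
default (it is the form that makes ᾱ a smooth squared-cosine ramp, and the
one in the schedule's original formulation); a `form="literal-cosine"`
switch drops the square for comparison. After clipping, ᾱ is recomputed as
the cumulative product of (1−β_t) so the clip propagates consistently.
The reverse-process standard deviation is
σ_t = sqrt(((1−ᾱ_{t−1})/(1−ᾱ_t))·β_t) with ᾱ₀ ≡ 1, hence σ₁ = 0 — moot
because the final reverse step forces z = 0.

Wrapped-normal sampling is implemented exactly as "draw a normal, then wrap
with w(x) = ((x+π) mod 2π) − π"; no truncation of the wrapped density's
infinite sum is ever needed. The network regresses the *raw* (unwrapped)
noise draw ε; the training residual d = w(ε − nn(x_t, t)) is wrapped before
entering a smooth-L1 loss that is quadratic for |d| < β_L and linear
beyond, with β_L = 0.1π. The loss is periodic, symmetric, and continuous at
the transition. Training timesteps are sampled uniformly over 1..T.
Training data are normalized to zero *circular* mean per angle column
(arithmetic means are wrong near the ±π boundary); validation and test sets
are shifted by the training-set offset, and sampling ends by un-shifting:
return w(x₀ + μ).

Sampling starts from x_T ~ w(N(0, I)) and applies the standard DDPM update
wrapped at every step; every tensor crossing a module boundary during
sampling lies in [−π, π). Timesteps are 1..T in all public signatures and
0-based internally.

## The denoiser

A plain bidirectional transformer: the 6-vector input is linearly upscaled
to the embedding dimension (default d = 384), a random-Fourier-feature
embedding of the timestep (fixed Gaussian frequencies, scale 16, with a
trainable projection) is added at every position, then 12 pre-LN blocks
(6 heads, feed-forward 2d) with learned relative-position attention biases
(per-head bias on the clipped offset j−i), a final layer norm, and a
regression head dense(d,d) → GELU → layer norm → dense(d,6). The default
configuration has ≈14.5 M trainable parameters; depth/heads/feed-forward
are configurable since only the embedding dimension is pinned by design.
Variable lengths are batched with key masking; masked slots carry the
post-shift pad value 0 and provably never influence unmasked outputs.

Because no suitable tensor framework is assumed, the layers, backward
passes, and the AdamW optimizer (decoupled weight decay 0.01) are
implemented directly in numpy and verified against finite differences.
The learning rate ramps linearly to its peak over the first 10% of steps
and decays linearly to zero; the best-validation-loss state is checkpointed
(validation noise uses a fixed seed so the metric is comparable across
epochs). Checkpoints are self-describing: weights plus a JSON manifest
with config, schedule, normalization offset, seeds, and history.

## Baselines

- **Shuffle.** All test-set rows are pooled into x̂ ∈ [−π, π)^{N̂×6}; a
  "structure" of length l draws l−1 row indices uniformly *with
  replacement* (the literal reading of uniform index sampling). Rows stay
  intact, so per-row joints (Ramachandran) are preserved while ordering —
  and hence lag-1 circular autocorrelation — collapses.
- **Autoregressive.** Same transformer body and head, but causal attention,
  absolute (learned) positional embeddings, and a Fourier embedding of the
  *total* sequence length added at every position. Output position i
  regresses row i+1 under the same wrapped smooth-L1. Decoding is greedy
  and deterministic, seeded with the first 4 angle rows of a natural
  structure; which structure seeds a generation is an explicit seeded
  choice.

## Evaluations

- **Angle histograms** use fixed equal-width binning over [−π, π); the
  domain is the full circle, so mass at ±π lands in the two seam-adjacent
  bins. The per-angle divergence score is the Jensen–Shannon divergence of
  the binned distributions (0 iff identical).
- **Ramachandran regions** are conventional configurable boxes:
  RH-helix φ∈(−180°, 0°), ψ∈(−100°, 50°); LH-helix the mirror
  φ∈(0°, 180°), ψ∈(−50°, 100°); sheet φ∈(−180°, 0°) with ψ wrapping
  through 180° (ψ ≥ 50° or ψ < −100°). They are conventions for mass
  accounting, not fitted decision boundaries.
- **Secondary structure** is annotated from Cα geometry alone in the style
  of P-SEA: Cα(i)–Cα(i+2|3|4) distances plus the pseudo bond angle over
  three and pseudo torsion over four consecutive Cα atoms, matched against
  helix/strand windows (defaults from the P-SEA publication, all
  configurable), requiring minimum runs of 5 (helix) / 4 (strand) and
  extending one relaxed-criterion residue at each edge. Helices and sheets
  are counted as maximal H/E runs — strictly speaking strand runs, which
  may overcount "sheets" relative to annotators that merge paired strands.
  The annotator is validated on idealized fixtures against biotite's
  P-SEA implementation; parity with the original binary on experimental
  structures is not claimed.
- **Diversity clustering** builds d = 1 − similarity from an injectable
  backend (an external TM-score binary wrapper is provided; tests inject an
  RMSD-based metric) and applies scipy average-linkage clustering. The
  TM-score algorithm itself is deliberately not reimplemented.
- **Designability** is exposed as an orchestration shell around
  user-supplied external tools (inverse folding, structure prediction,
  similarity scoring): per structure, 8 candidate sequences, scTM = max
  similarity, designable iff scTM ≥ 0.5. Without those tools the feature
  is unavailable with a clear message; no bundled model stands in for them.

## Synthetic study conditions

The package is exercised end to end without any downloaded data:

- **Idealized secondary-structure fixtures** are reconstructed from
  constant rows — helix (φ, ψ) = (−57°, −47°), strand (−119°, 113°),
  trans ω, idealized bond angles (111.0°, 116.2°, 121.7°). These are
  literature idealizations, not values fitted to any dataset. The helix
  fixture shows the canonical ~1.5 Å rise per residue.
- **Wrapped-Gaussian mixtures** over angle rows with known parameters are
  the stand-in for the training distribution. The default study mixture has
  a helix-like and a strand-like mode (weights 0.65/0.35, σ = 0.2 rad);
  the chirality study uses a single mode concentrated in the RH-helix
  region (σ = 0.15 rad).
- **Desk-scale training protocol** (`torsiondiff.experiments`): 512 items
  of 16 rows, schedule T = 100, a 3-layer 64-dim denoiser, 400 epochs at
  peak LR 2×10⁻³ (the distribution-recovery study; the easier chirality
  study uses 200 epochs). These sizes keep a full train-and-sample cycle
  within a few CPU-minutes while leaving the learning problem non-trivial.

What passing these studies shows — and does not show: rows of the mixtures
are i.i.d., so they exercise the wrapped forward/reverse processes, the
loss, normalization, and mode coverage, but not long-range sequential
structure; the idealized fixtures exercise geometry and annotation, but
carry none of the conformational heterogeneity, chain breaks, or
measurement noise of experimental structures. Full-scale training on the
real domain set (30,395 domains, ≥40 residues, 128-residue random crops,
80/10/10 split by the floor convention) is provided as
`scripts/train_cath_full.py` and needs substantial compute plus a local
copy of the dataset.

## Known limitations

- The lever-arm effect of internal coordinates: a single angle error early
  in a long chain moves everything downstream. Round-trip error stays at
  numerical precision, but generative errors can translate into large
  Cartesian displacements.
- No clash detection or relaxation; no side chains, hydrogens, B-factors,
  or multi-chain complexes.
- Chain breaks in experimental files are treated as hard errors (the chain
  is excluded) rather than imputed.
- The AR baseline's known qualitative failure mode (collapsing to single
  helices at full scale) is noted but not asserted by tests, as it is a
  property of full-scale training.
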