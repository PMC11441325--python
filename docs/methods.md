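# Methods

## Problem and data model

The package predicts unobserved drug–microbe associations from three
matrices: a binary association matrix R (Nd×Nm), a drug–drug structural
similarity D_struct and a microbe–microbe sequence similarity M_sim, both
symmetric with unit diagonal and entries in [0,1]. Similarity computation
from raw chemical structures or genomes is upstream of this package; the
matrices are consumed as given.

## Graph construction

* Gaussian interaction-profile kernel between drugs:
  D_gauss[i,j] = exp(−μ‖R_i − R_j‖²), μ = μ′ / ((1/Nd) Σ_i ‖R_i‖²), with the
  original bandwidth μ′ = 1. An all-zero R leaves the bandwidth undefined
  and is rejected.
* Fused drug similarity D_sim = (D_struct + D_gauss)/2.
* Node attributes Z = [[D_sim, R], [Rᵀ, M_sim]]; row i is node i's profile.
* Normalization uses D^(−1/2) M D^(−1/2) where D counts the **non-zero
  entries** of a row (not the row sum). This printed degree definition is
  applied uniformly to both similarity graphs and the bipartite graph; for
  dense similarity blocks it divides by ≈n, acting as a uniform scale. The
  bipartite matrix is normalized through its square embedding
  [[0,R],[Rᵀ,0]], which equals D_row^(−1/2) R D_col^(−1/2).
* Zero-degree rows map to zero rows (D^(−1/2) entry defined as 0), so
  isolated nodes neither emit nor receive messages and no non-finite
  values arise. "Non-zero" means strictly > 0; no epsilon thresholding.

## Encoders

**NHCN.** The incidence matrix of the dynamic hypergraph is
H = max(Z·E, 0) for a trainable E ∈ R^(n×Ne) (Ne = 32 hyperedges by
default). The clamp is needed because E is signed during training while
degrees must be non-negative; the clamped region passes no gradient, which
is also why E is initialized *positive* (uniform on (0, 0.2)): Z is
entrywise positive, so the entries of a column of Z·E share the sign of
that column's mean embedding, and a column clamped at birth would receive
zero gradient forever (a permanently dead hyperedge). Starting in the open
region keeps every hyperedge trainable; the clamp still governs sign once
training moves E. Convolution runs Lhnn = 2 layers of
LeakyReLU(D_B^(−1/2) H D_E^(−1) Hᵀ D_B^(−1/2) X) with slope 0.01, degree
pseudo-inverses as above, on X = [Z ‖ Y] where Y holds per-type category
vectors (width 64 by default, one shared trainable row per node type).
H is rebuilt from (Z, current E) once per forward pass and shared by all
layers within the pass; E evolves only through optimizer steps, which is
the only update mechanism stated for it.

**GCNFP.** Homogeneous stack B⁰ = Z, B^l = A_homo B^(l−1) W^l; heterogeneous
stack B⁰ = Z, B^l = A_hete [B^(l−1) ‖ diag(α_g)·B_homo^l] W^l, Lgcn = 2
layers, hidden width 256. No activation sits between propagation layers —
the printed update rules are linear, and the nonlinearity enters at the
Tanh projection — an activation can be inserted via configuration for
experimentation. α_g initializes at 1 (neutral pass-through) and is
trained; the NFPS ablation freezes it at 0. Orders 0..Lgcn are
concatenated per node and Tanh-projected to d_proj = 128, with separate
weights for drugs vs microbes and for the homogeneous vs heterogeneous
stream (four projection heads).

**SCA.** Attribute rows are zero-padded to a multiple of the patch size
P = 50 and reshaped row-major to N×P (pad zeros participate in attention
like real entries, preserving the stated order of operations). Eight heads
by default, each with W_Q, W_K, W_V ∈ R^(P×N_dim), N_dim = 50, *shared
between the drug and microbe streams of a pair* but distinct across heads.
Scores are scaled by 1/√N_dim; cross-attention aggregates the values of
the attended (other) stream, matching the architecture diagram where the
printed value subscript is ambiguous. Self and cross outputs are summed
elementwise, heads concatenated, streams flattened and stacked. No
positional encoding and no dropout.

## Fusion head

The three pair blocks have incompatible native widths, so each passes
through a learned bias-free linear map to a common width d_fuse before
stacking into the 8×d_fuse map (2 rows NHCN, 4 rows GCNFP, 2 rows SCA); an
ablated block contributes a zero block of the same shape. Defaults
d_fuse = 300 and conv channels (8, 16) were chosen so a full desk-scale
cross-validation runs at interactive speed on one CPU (wider settings gave
no measurable benefit at Nd = 60, Nm = 30 and are ~4× slower per step);
both are configurable. Kernels are 2×10 then 1×10, stride 1, ReLU
(σ(0) = 0 preserves the zero-input invariant), max-pooling over
non-overlapping 1×10 windows with the trailing remainder dropped. The
flattened output feeds a two-logit softmax classifier; p[1] is the
association probability, trained with binary cross-entropy (mean reduction
by default, so the learning rate is batch-size independent).

## Training and evaluation protocol

Adam, 80 epochs, batch 32, learning rate 5·10⁻⁴ are the reference training
settings; desk-scale experiments in this package use 30 epochs. An L2
weight decay (default 2·10⁻²) is applied inside Adam: with ~230 training
pairs against ~7·10⁵ parameters the unregularized model memorizes the
training set within a few epochs and held-out ranking quality decays
monotonically; decay holds it near its early-epoch generalization level.
Set `weight_decay=0` to recover the literal reference setup.

Five-fold cross-validation: positives are shuffled once and distributed
round-robin (this also handles remainders); each fold trains on the other
four parts plus an equal number of training negatives sampled uniformly
without replacement from the unknown pairs, and is evaluated on its
held-out positives against **all** unknown pairs not used as training
negatives — so test prevalence is realistically low (~2%) and AUPR
baselines are small. Per fold the entire graph bundle (kernel similarity,
Z, adjacencies) is rebuilt from the training-masked R (held-out positives
zeroed); otherwise test labels would leak into the model input through
node attributes. Ranking ties are broken by stable pair index; AUC counts
ties as one half. Per-drug recall@k and per-drug AUC/AUPR are computed only
for drugs whose test candidates contain the needed classes. All
randomness (fold shuffle, negative sampling, parameter initialization,
batch order) derives from one master seed through named sub-streams.

## Synthetic data

The generator plants the structure the model assumes: non-negative latent
factors U (Nd×r), V (Nm×r) with gamma(2,1) entries; R thresholds U·Vᵀ at
the (1−density) quantile and then flips each entry independently with the
noise probability; similarities are cosine similarities of the latent
factors, so similar drugs genuinely share microbes. Defaults — Nd = 60,
Nm = 30, r = 4, density = 0.08, noise = 0.05 — are the desk-scale study
conditions. The generator does **not** emulate chemical-structure or
sequence statistics, hub-degree skew of curated databases, or correlated
annotation errors; passing tests on it show that the pipeline recovers a
planted low-rank signal, not that it matches performance on curated data.

A consequence of the default noise worth stating explicitly: with 8%
density and 5% independent flips, a fraction 0.92·0.05/(0.08·0.95+0.92·0.05)
≈ 38% of the positive labels are flip noise carrying no signal. The
Bayes-optimal ranking (the generator's own latent scores, reported by
`scripts/acceptance.py` as `planted_oracle_auc`) therefore tops out around
0.8 on the held-out evaluation, and any model is bounded by it; the full
model lands within ~0.05–0.08 of that ceiling, and roughly 0.25 above the
shuffled-label null of ≈0.5.

## Numerical choices

* All model math runs on the package's reverse-mode autodiff core over
  numpy arrays; training uses float32 (the memory-bound conv/pool path is
  ~2× faster), while the functional reference implementations and all
  oracle comparisons use float64. Gradients of every op and of the full
  model are verified against central finite differences.
* Degree inverses use the pseudo-inverse convention (0 at 0) everywhere.
* Max-pool backward routes gradient to the first argmax on ties.
* Softmax/log-softmax subtract the detached row maximum for stability;
  the binary cross-entropy endpoint 0·log 0 is evaluated as 0.
* Determinism: given a seed, runs are bit-reproducible on a fixed
  BLAS build; across BLAS builds results may differ in reduction order.

## Known limitations

* Desk-scale defaults; the real-data regime (Nd ≈ 1400) would need
  minibatched graph encoders or a GPU framework backend.
* The dynamic topology is recomputed per forward pass from the fixed Z;
  variants that re-multiply transformed features with E between layers are
  not implemented (the architecture description admits both readings; the
  fixed-Z reading was chosen because training is the only stated update
  mechanism for E).
* Output probabilities are not calibrated; scores are for ranking.
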