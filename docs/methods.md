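# Methods

## Problem and model

`fallgcn` classifies a skeleton sequence — a `C × T × V` array of joint
coordinates over time — into one of six action classes (*drop, pick up,
sit down, wear a shoe, take off a shoe, fall*), with *fall* as the positive
class for screening metrics.  The premise is kinematic: during a fall the
body's centre of gravity moves from a high to a low position, and the
magnitude of displacement differs strongly between body parts (the head
travels much farther than the legs), whereas confusable daily activities
share only part of that signature.

The network separates spatial and temporal modelling:

1. **Feature encoding.**  Four per-joint streams — absolute position,
   position relative to the per-frame centre joint, one-frame and
   two-frame forward differences (trailing frames zero-filled) — are
   embedded pairwise by 1×1 convolution + ReLU into `C1 = 16` channels and
   summed.  A two-layer ReLU MLP embeds each joint's one-hot identity into
   another `C1` channels ("type semantics"), concatenated along channels:
   the trunk sees `2·C1 = 32` channels.  Positions and motions use separate
   weights because they carry different physical units.
2. **Subgraph-partitioned adaptive graph convolution.**  The skeleton tree
   is divided into five body-part subgraphs (torso + four limbs) that share
   their root joints (shoulders, hips; mid-hip for the OpenPose layout), so
   every natural bone lies inside at least one part.  Neighbour aggregation
   uses the spatial-configuration partition (`l = 3` subsets: self,
   centripetal, centrifugal, by hop distance to the centre joint); each
   part's per-subset adjacency is superimposed and clipped to binary, then
   row-normalised (`D⁻¹A`).  The resulting `3 × V × V` tensor initialises a
   *learnable* adjacency that is frozen for the first 10 epochs and updated
   as an ordinary parameter afterwards.  Three blocks with output channels
   64/128/256 each apply: spatial graph convolution (one 1×1 map per
   subset, aggregated and summed, ReLU), temporal convolution (`Kt = 3`,
   same-length padding), and **sub-graph attention (SGA)**: gather each
   part's joints (zero-padded to the largest part size `M`), average-pool
   over frames, squeeze channels 4× through a shared affine map,
   batch-norm + sigmoid, map to one gate per joint slot, softmax over the
   part's valid slots, multiply the part's features by its weights, and
   scatter back (averaging on shared joints).
3. **Temporal head.**  Spatial max-pooling over joints, a multi-scale
   temporal convolution (MTCN) with parallel kernels 3/5/7 of width 128
   whose outputs are concatenated and projected back to 256 channels by a
   1×1 map, temporal max-pooling over frames, and an affine softmax head.

The default 25-joint, 6-class model has **1,008,172** learnable scalars
(adjacency included), within the 1.2 M lightweight budget that motivates
the architecture.

## Numerical core

No GPU framework is used: the model runs on a small reverse-mode autodiff
engine over numpy (`fallgcn.autodiff`) providing exactly the operations
the network needs.  Heavy maps are expressed as per-sample GEMMs;
parameters default to float32 (float64 is available and is used by the
oracle-equivalence tests, which compare every stage against literal
loop-based implementations at 1e-6 relative error).  All gradients are
validated against central finite differences, in both training and
evaluation batch-norm modes.  The optimiser is SGD with Nesterov momentum
(velocity `v ← μv + g + λθ`, step `θ ← θ − η(g + λθ + μv)`).

Design points where the architecture description left choices open:

- **MTCN fusion**: per-branch width 128 with concatenation + 1×1
  projection.  A plain three-branch 256→256 stack would cost ~983 K
  parameters in this stage alone and break the lightweight budget;
  concat-project keeps multi-scale fusion within it.
- **Temporal kernel** `Kt = 3`, stride 1, same-length padding: preserves
  sequence length ahead of the pooling stages and keeps the budget.
- **Batch normalisation** follows each spatial and temporal convolution
  and each MTCN branch (per channel, statistics over batch × frames ×
  joints; running estimates at evaluation).  Convolution stacks of this
  depth are not stable under the lr = 0.1 recipe without it.
- **SGA softmax axis**: over each part's joint slots (padded slots masked
  to exactly zero), so the attention map is a per-part distribution over
  joints.  Shared joints receive the average of their parts' reweighted
  values.
- **Adjacency freeze boundary**: epochs 0–9 frozen, trainable from epoch
  10.  The adjacency is always included in the parameter count.
- **Argmax ties** in evaluation resolve to the lowest class index;
  metric ratios with zero denominators are reported as NaN with a warning,
  never silently as 0.
- **OpenPose input** is 2-D + detection score; the three channels
  (x, y, score) are treated uniformly with Kinect (x, y, z), but only
  coordinate channels are shifted by normalisation or mixed by rotation.
  Multi-person frames keep the highest-scoring person (OpenPose) or the
  first body (NTU files).  An undetected centre joint in frame 0 falls
  back to the first detected joint, with a warning.
- **Long sequences**: inputs above the target length are subsampled with a
  uniform stride before replay padding (`fit_length`).

## Training recipe

Defaults in `TrainConfig` follow the standard recipe for this model
family: 60 epochs of Nesterov SGD (momentum 0.9, weight decay 5e-4),
cross-entropy loss, batch size 16, initial learning rate 0.1 decayed 10×
at epochs 20 and 40, sequences replay-padded to 300 frames, random
rotation augmentation (default ±17°, z-only for 2-D data), and per-sequence
centre-joint normalisation (frame-0 centre subtracted from all coordinate
channels).

## Synthetic data: what it does and does not show

The generator (`fallgcn.synthetic_data`) produces labelled stick-figure
sequences from per-class kinematic templates: a hip-height trajectory
(start height 1 m; final fraction 0.12 for falls — below the 0.3 threshold
that encodes "high to low" — vs ≥ 0.5 for non-fall classes), a trunk pitch,
per-part displacement scales (head 0.85 vs legs 0.12 for falls), class-
specific limb-oscillation frequencies, and i.i.d. Gaussian coordinate
noise (σ = 0.01 m).  Durations are drawn per class from 40–70 frames.
Everything is deterministic in `(class, layout, T, seed)`.

The templates are documented constants chosen for structure, not fitted to
recordings.  The data reproduce the *statistical premise* of the task
(centre-of-gravity descent, part-wise asymmetry, confusable intermediate
classes) but not biomechanics, camera projection artefacts, occlusion, or
pose-extractor noise beyond additive Gaussian perturbation.  Passing the
recovery test therefore shows that the model and training loop can learn
the intended class structure — it says nothing about accuracy on real
fall recordings.

## Desk-scale protocol

The synthetic-recovery check runs a reduced-width preset
(`ModelConfig.desk()`: C1 = 8, channels 16/32/64, MTCN width 32 — same
topology and depth) on 50 sequences per class, padded to 64 frames (the
generator's sequences are 40–64 frames long), trained ≤ 20 epochs at
lr 0.01 with the recipe otherwise unchanged.  The full-width learning rate
of 0.1 is calibrated to large-batch, large-dataset GPU training; at 15
mini-batches per epoch it diverges, so the desk protocol scales it down
once and documents it here.  Under this protocol the model reaches ≥ 0.95
held-out accuracy (stratified 80/20 split).

## Known limitations

- Single person per sequence; no tracking.
- No temporal striding: memory grows linearly with `target_T`.
- The pure-numpy engine is single-threaded; full-width training at
  300-frame padding is slow compared with GPU frameworks — the package is
  written for method verification and small-scale use, not production
  training speed.
- Batch-norm statistics make evaluation depend on training history via the
  running buffers (standard behaviour, but worth remembering when
  comparing checkpoints).
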