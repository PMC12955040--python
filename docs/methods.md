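# Methods

This note documents the models, numerical choices and study conditions
implemented in `lffusion`, and what the desk-scale benchmark does and does
not demonstrate.

## Optical forward model

Both microscope arms share a scalar-diffraction core.

**Debye focal field.** The field near focus of a point source at axial
position z is the aperture integral

    Ub(r) = ∫₀^θmax Uo(θ) · J₀(2π r sinθ / λ) · sinθ dθ,

with θmax = asin(NA/n) and the defocus folded into the pupil function,
Uo(θ) = A(θ)·exp(i·(2π/λ)·n·z·cosθ). The apodization A(θ) defaults to 1
(the literature varies between 1 and √cosθ; it is a configurable hook).
The integral is evaluated by Gauss–Legendre quadrature with 256 nodes;
doubling the node count changes the result by < 1e-6 relative (enforced by
a test). Fields are evaluated on unique radii only, so radial symmetry is
exact on the grid, and a 1D radial table plus linear interpolation is used
inside PSF loops for speed.

**Angular-spectrum propagation.** Free-space propagation multiplies the
field spectrum by exp(i·(2π/λ)·d·√(1−(λfx)²−(λfy)²)), zeroing evanescent
components. The primitive is implemented without padding, which makes it
exactly unitary on the propagating band (energy conservation and ±d round
trips hold to rounding); the PSF pipelines zero-pad to twice the extent
before calling it and crop afterwards to suppress periodic wrap-around.
This split — exact primitive, padding at the call site — is deliberate:
padding inside the primitive would silently break its unitarity contract.

**Microlens array.** A periodic pure-phase mask; each pitch-d tile carries
the thin-lens phase exp(−iπ(x′²+y′²)/(λ f_ml)) about its lenslet centre,
with one lenslet centred on the grid origin.

**LFM PSF.** For every depth and every cell-centred sub-lenslet source
offset (one pitch subdivided n_offsets × n_offsets times), the chain is
Debye field (relay magnification folded into the image-plane grid) → MLA
phase → propagation over f_ml → squared magnitude → binning into sensor
pixels (pitch/N_num each). The N_num × N_num pixel window of the central
lenslet is recorded, giving the 5D tensor (z, s_y, s_x, u, v) — with the
published 40×/0.8 preset (61 depths, 16×16 offsets, N_num = 11) this is
(61, 16, 16, 11, 11). Point symmetry PSF(x,y,z) = PSF(−x,−y,z) is
exploited: only half the offsets are simulated, the rest are mirrored with
the pixel window flipped. Limitations: light spreading beyond the central
lenslet window is truncated, so strongly defocused responses lose energy
off-window; this is the standard single-window (view-kernel) approximation
that keeps the projector a per-view 2D convolution.

**FLFM PSF.** Per depth: Debye field → pupil clipping with a super-Gaussian
transmission P(ρ) = exp(−(ρ/λc)^(2α)) on the normalized pupil radius →
sinc band-limit → intensity PSF, normalized to unit sum → OTF. The
band-limit multiplies the spectrum by the ideal frequency response of the
continuous sinc(2ρ/λc) kernel (unity inside the radial frequency 1/λc,
zero outside, DC gain 1); building the response from a sampled, truncated
spatial kernel was rejected because its transform carries a band-edge boost
and ringing that contradict the filter's anti-aliasing role. The stored
decomposition is R(fx,fy,z) = OTF_z / w(z) with w(z) the unit-modulus phase
of the on-axis field amplitude: w(z) is genuinely complex away from focus
(it carries the defocus phase), while the product w·R is exactly the
Hermitian OTF, so projected images are real to rounding. The 2-3-2 view
layout (seven lenslets: rows of 2, 3, 2) is recorded as offsets in pitch
units together with sensor-pixel view centres and a parallax gain
(px of image shift per µm of depth per unit pitch offset), derived from
the pupil-offset angle pitch/f_obj.

**Aperture refinement.** The pupil transmission can be refined by projected
gradient descent on J(P) = ‖PSF_target − PSF_sim‖₂² + λ₁‖∇P‖₁, with
PSF_sim = |IDFT(U·P)|² for a fixed base wavefront U (orthonormal DFT).
The data-term gradient is analytic (4·Re[conj(U)·DFT(resid·amp)]); the
total-variation term uses forward differences with subgradient 0 at ties.
Steps are accepted only if J does not increase, halving the step up to 20
times, so the J history is non-increasing by construction; exhaustion
raises a convergence error carrying the history. The update direction is
descent (J is minimized).

## Projectors

**LFM.** L(u,v)[·] = Σ_z vol_z ∗ K_{z,u,v}, an FFT convolution per view with
'same' cropping; the per-depth unit-sum normalization of the PSF makes the
projector flux-preserving for interior sources. The volume's lateral grid
is identified with the PSF's source-offset grid (each arm projects at its
own sampling; the network adapters resample, since the two arms share no
common pixel grid in the published setups either).

**FLFM.** In the frequency domain: F{I} = Σ_z w(z)·F{vol_z}·R_z, with a
per-view Hermitian phase ramp applying the depth-proportional parallax
shift of that view; the inverse transform's imaginary residue is checked
(≤ 1e-8 relative) and discarded, negatives are clipped with the clipped
mass logged. The seven views are returned as a stack plus an optional
mosaic sensor canvas with each view pasted at its centre. The adjoint
(matched transpose) of both projectors is implemented for deconvolution.

## EPI extraction

EPI stacks are pure axis permutations (bit-exact invertible): LFM
(u,v,w,h) → (v·w, u, h) and (u·h, v, w); FLFM uses the central row of the
2-3-2 layout for the c-w stack (h, c, w) and the central column for the
c-h stack (w, c, h) — those are the only complete collinear view triples
in the layout, so c = 3. The slope utility estimates the dominant EPI line
orientation with an accumulated structure tensor (ties broken toward slope
0, constant slices flagged NaN) and refines it by shearing the slice with
the current estimate and re-estimating the residual twice; the refinement
removes the finite-difference alias bias for slopes steeper than ~1 px per
view. On desk-preset point sources the FLFM |slope| tracks |z| with
Spearman ρ ≈ 0.99; the LFM signed slope decreases strictly monotonically
with z but carries a constant offset from the single-window truncation, so
magnitude-based checks use the FLFM arm.

## Phantoms

`tubulin` phantoms are sparse smooth 3D curves (cubic splines through
random control points, rasterized and blurred with a Gaussian of the
configured radius); `vessel` phantoms are recursive bifurcating trees with
radius tapering (default 0.7 per generation), rasterized as tubes by
maximum-stamping Gaussian balls along the centre line. Morphology
parameters are package choices (the source data the phantoms emulate are
confocal stacks): defaults aim for sparse filament density and visible
branching. Real-data features *not* emulated: sensor noise (projections
are noiseless by default), background autofluorescence, aberrations and
sample-induced scattering, anisotropic labelling. Passing benchmarks here
therefore demonstrates correctness and the relative value of the
modalities under the stated forward model, not robustness to real-world
noise.

`make_dataset` derives per-sample seeds from one master seed (SeedSequence
spawning), projects both modalities and all four EPI stacks per sample,
and splits 8:2 by a seeded shuffle; everything regenerates bit-exactly.

## Reconstruction network

Four branches — LFM view stack (u·v channels), FLFM view stack (7
channels), LFM EPIs (two sub-stacks) and FLFM EPIs (two sub-stacks) — each
pass through an adapter (bilinear resize to the ground-truth lateral size,
then convolutions to a unified channel width; EPI sub-stacks have separate
adapters whose features are concatenated and merged) and a 2D U-Net
(depth 2, leaky-ReLU, average-pool down / nearest-neighbour up, skip
concatenations) that emits the volume with depth as output channels.
Fusion is a hierarchical result-level cascade: A = fuse(LFM, LFM_EPI),
B = fuse(FLFM, FLFM_EPI), final = fuse(A, B). A fusion block computes
g_a·a + g_b·b + C(a,b): learnable per-depth-plane gates initialized to
0.5 plus a two-layer convolutional correction whose output layer is
zero-initialized. A freshly built block therefore returns the branch
average — a warm start chosen over the plain zero-init output (which
would start the cascade at the zero volume and stall the fused head
early in training); the gates let the cascade re-weight unequal branches
instead of averaging them.

The loss is the unweighted sum of five mean-squared-error terms — one per
branch volume and one for the fused volume — so every branch is supervised
against the 3D ground truth directly. Training uses Adam (lr 2e-3 at desk
scale), seeded end to end; a NaN loss aborts and restores the last finite
state. Ablation variants instantiate only the selected branches; the
cascade degenerates gracefully (a missing partner passes the present
volume through, a single branch is its own "fused" output).

The network stack (reverse-mode autodiff, im2col convolutions, Adam) is a
compact NumPy implementation inside `lffusion.nn`; it is deterministic
given the seeds, gradient-checked against finite differences, and sized
for CPU-scale experiments.

## Baselines and metrics

Richardson–Lucy uses the classic multiplicative update with the matched
adjoint of the corresponding linear projector (never a surrogate kernel);
iterates are non-negative and the I-divergence between measurement and
reprojection is non-increasing (both tested). PSNR uses the per-sample
ground-truth maximum as the data range; SSIM is computed per z-slice with
a 7×7 Gaussian window (K1 = 0.01, K2 = 0.03) and averaged over depth; both
conventions are recorded in every metric report because the literature
rarely states them.

## Desk-scale benchmark conditions

The published experiments use 176×176×61 volumes and thousands of training
pairs on a GPU; this package's quantitative claims are made at a desk
scale chosen for single-CPU runs: volumes (21, 32, 32) at the desk optics
presets, 22 training and 6 test volumes, one uniform training recipe
(Adam 2e-3, batch 2, trained to plateau: at most 60 epochs, stopping when
the loss improves < 2% between consecutive 5-epoch windows), and the
median over three model seeds per modality combination.

The desk arms are sized so the benchmark sits in the same regime as the
published geometry, where each modality alone is information-incomplete:

- LFM (10×/0.4, 50 µm MLA, 5×5 views): the light field is sampled at
  lenslet pitch (one lenslet per 4 volume voxels), so a single modality
  measures 25 views × 8×8 lenslets = 1 600 values against 21 504 unknowns
  — heavily underdetermined, like real LFM where views live at lenslet
  resolution. The published 40×/0.8 preset is not used for the benchmark
  because its ±30 µm defocus range spreads light far beyond one lenslet
  window at desk grid sizes; the full-geometry PSFs (61 depths, 16×16
  offsets, 11×11 views; (61,1,1) FLFM weights) are still computed and
  checked structurally.
- FLFM (6×/0.45, seven 2-3-2 views, ≈0.48 px/µm parallax): spatially
  sharp at volume resolution but with only 7 angular samples — 7 168
  values, also underdetermined.

Multi-branch models use cascaded pretraining — the standard multimodal
transfer protocol, which also makes the single/dual/full comparison a
controlled one: single-modality runs are trained first and seed the
branches of every multi-branch model; the full four-branch model
additionally inherits the view branches and the cross-arm fusion stage
from the same-seed trained LFM+FLFM dual, so (with its pass-through
within-arm stages) it starts at exactly the dual's function and fine-tunes
from there. Every run restores the state with the best training loss
(initial state included as a candidate). Within-arm fusion stages
initialize their gates to pass the view branch through (gate 1/0),
reflecting the EPI branches' role as providers of parallax
side-information; the cross-arm final stage starts at the plain average
(gate 0.5/0.5). Because the EPI stacks are bijective rearrangements of the
view data, the EPI branches add representation rather than information;
at desk scale the fused-vs-best-dual margin is accordingly small (tenths
of a dB) and can tie within evaluation noise on some dataset seeds.

On this benchmark the expected ordering is: full four-branch fusion ≥ best
dual-modality variant ≥ best single-modality variant, and fusion above the
Richardson–Lucy baselines. The desk acceptance fixes "the RL baseline" as
RL on the LFM light field (the modality whose reconstruction the method is
designed to improve); the FLFM-RL number is reported alongside. Because
the desk data are noiseless and RL uses the exact matched forward model,
the RL baselines here are stronger relative to the networks than the
published full-scale comparison, where RL trails every learned method.

## Numerical conventions

- Volumes are (z, y, x), z index 0 at the most negative depth; grids have
  the origin on the sample at index N//2; 0-based indices everywhere.
- Light fields are (u, v, w, h): u is the angular coordinate conjugate to
  the second spatial axis h, v conjugate to w; channel stacking is
  row-major (u outer, v inner). The 2-3-2 views are ordered top-left to
  bottom-right.
- Degenerate inputs: all-zero PSFs, empty datasets, mismatched shapes and
  out-of-bounds crops raise typed errors; constant EPI slices return a NaN
  slope flag rather than raising.
- The only randomness is in phantom geometry, dataset shuffling and weight
  initialization; all of it flows from explicit seeds (spawned via
  SeedSequence, kept below 2³¹).
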