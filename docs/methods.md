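# Methods

This note records the models implemented in `allt1`, the numerical choices
behind them, and what the synthetic experiments do and do not demonstrate.

## Signal model

The alternating Look-Locker (aLL) acquisition alternates two
saturation-recovery segments.  In the inverted segment the magnetization is
saturated, allowed to recover for a delay `Td`, inverted, and then sampled
continuously; the non-inverted segment repeats this without the inversion.
After binning the readout into images at times `t_i` the voxel signal is

    S-(t_i) = Mss - (Mss + I*M0) exp(-t_i / Teff)
    S+(t_i) = Mss - (Mss - M0)  exp(-t_i / Teff)

with `Mss` the steady-state magnetization under continuous excitation, `M0`
the magnetization recovered after saturation and delay, `I` the
inversion-efficiency parameter and `Teff` the effective relaxation time.
The decaying-exponential convention is used throughout: both curves must
approach `Mss` as `t -> infinity`, which pins the sign of the exponent.

T1 follows from the fitted parameters through

    T1 (1 - exp(-Td/T1)) = M0 TR / (Mss (1 - exp(-TR/Teff)))

The left-hand side is strictly increasing in T1 with supremum `Td`, so the
root is unique whenever the right-hand side lies in `(0, Td)`; it is found
by bisection (default bracket 1 ms - 20 s, tolerance 0.01 ms).  Voxels whose
ratio falls outside the admissible interval are set to NaN and masked.

Default timing: TR = 2.9624 ms, Td = 3 s, 1476 spokes per segment binned
into 6 images; the bin centers `(i - 1/2) * 246 * TR` round (to 10 ms) to
360, 1090, 1820, 2550, 3280 and 4010 ms.  Rounding is display-only; internal
times are exact centers.

## Temporal subspace

A dictionary of `[S-(t_1..t_6), S+(t_1..t_6)]` rows is simulated on dense
Cartesian grids — by default 401 `Teff` in [0.5, 0.9] s, 17 `Mss/M0` in
[0.74, 0.9] and 78 `I` in [0.23, 1.0], with `M0 = 1` (the ranges describe
fixed ex vivo brain tissue at high field; the `I` grid size is
configurable).  The top K = 4 right singular vectors of the dictionary form
the orthonormal temporal basis; at K = 4 the worst-case signal-wise
projection nRMSE over the dictionary is about 0.5 %, comfortably below 1 %.
The SVD sign ambiguity is fixed by making the largest-magnitude entry of
each basis column positive.  The dictionary is real; image phase is handled
by the reconstruction, not the basis.

## Trajectory

Spoke directions come from irrational golden-means increments, so that any
contiguous subsequence is quasi-uniform — the property that makes
retrospective undersampling by truncating each bin's spoke list valid.  In
3-D the m-th spoke has `cos(theta) = 2 frac(m phi1) - 1` and azimuth
`2 pi frac(m phi2)`.  With `t` the real root of `x^3 = x^2 + 1`, the order-N
pair is

    phi2 = 1 / (t + N - 1),     phi1 = (t^2 - t) / (t + N - 1)

which reproduces the classical 2-D golden means (0.4656, 0.6823) at N = 1
and shrinks the angular step between consecutively acquired spokes as N
grows (default order 55).  Since 1, phi1 and phi2 are rationally independent
(t is a degree-3 algebraic irrational), Weyl equidistribution guarantees
asymptotic uniformity for every order; the ratio pair is also accepted
explicitly for users who want a published tabulated pair.  In 2-D the analog
is the tiny golden angle `pi / (tau + N - 1)` with `tau` the golden ratio.

The direction stream is partitioned into `T = 12` contiguous, near-equal
sections, one per image; repetition `j` of the two-segment cycle acquires
spokes `j*spb .. (j+1)*spb - 1` of every section in bin order (`spb` = spokes
per bin per repetition).  Every spoke records its own time inside the
relaxation segment.  Where the resulting acquisition order jumps by more
than a threshold angle (default: twice the median jump; the threshold is a
free parameter), spokes are inserted along the great-circle arc, flagged,
and assigned to the bin and time of the spoke that follows them.

Full radial sampling of an isotropic matrix `N` needs `pi N^2` center-out
spokes in 3-D and `pi N / 2` in 2-D (counts round up).  The acceleration
factor AF is that number divided by the spokes actually used per image;
undersampling keeps, per bin, the leading `floor(full/AF)` spokes in
acquisition order.

## Forward model and NUFFT

The encoding operator is block diagonal over bins: the samples of bin `t`
are non-uniform Fourier samples of image `t` along that bin's spokes, with
readouts modeled as ideal center-out lines, twice-oversampled (`S = N`
samples at radii `j (N/2)/S` cycles/FOV).  Coil sensitivities, when
provided, multiply in image domain before encoding; the default is a single
uniform channel.

No NUFFT library being a dependency, the transform is a standard
Kaiser-Bessel gridding NUFFT: deapodization, zero-padding to a 2x
oversampled grid, FFT, and sparse-matrix interpolation with a width-7
Kaiser-Bessel kernel (Beatty shape parameter).  Materializing the
interpolation as a sparse matrix makes the adjoint the exact conjugate
transpose of the forward map (dot tests pass at machine precision), and
forward accuracy against a direct DFT is ~1e-6 relative on small grids.
Coordinates are in cycles/FOV with the image-center phase convention
(a centered impulse transforms to a zero-phase constant).

The subspace-composed operator maps K coefficient images to samples by
expanding `x_t = sum_k basis[t,k] lambda_k` bin by bin; the T-image series
is never materialized.

## Reconstruction

Eight models are supported (see the table in `allt1.recon`).  Unregularized
models (LS, S-LS) are solved by LSMR with a fixed budget of 5 iterations.
The data fidelity of all models is density-weighted: each sample is weighted
by the square root of a ramp `max(kr, dr/4)^(d-1)` normalized to unit mean —
the radial density-compensation profile — which acts as the diagonal
preconditioner that makes a handful of LSMR iterations meaningful on
center-heavy radial data.  The weighting is applied consistently to the
fidelity term of every model, so the ADMM-with-zero-weights limit coincides
with the plain LSMR solution.

Regularized models use scaled-form ADMM with one splitting per regularizer:

* **STV** — isotropic spatial total variation per image (or coefficient
  image), one-sided forward differences with replicate boundary so constant
  images have exactly zero TV.  The splitting variable is the gradient
  field; its proximal map is the voxelwise group soft-threshold over the
  gradient components, applied jointly to real and imaginary parts.
* **LLR** — locally low-rank: non-overlapping blocks (default 8^d; 13^d for
  the reference model; edge blocks truncated) are reshaped to Casorati
  matrices (voxels x images) and their singular values soft-thresholded.

The x-update is a regularized least-squares solved by 2 LSMR iterations
warm-started from the previous iterate; 30 outer iterations by default.
The ADMM penalty defaults to the scale-aware choice `rho_r = alpha_r /
delta_r`, where `delta_r` is the median magnitude of the corresponding
splitting variable (image gradients for STV; block singular values for
LLR) at a quick unregularized solve of the same data.  This places the
proximal threshold `alpha/rho = delta` at the data's own scale, making the
30-iteration budget effective regardless of intensity normalization — the
simpler `rho = alpha` heuristic couples the splitting far too weakly (or
strongly) whenever image intensities are far from order one, and at this
package's k-space normalization it silently disabled the regularizers.
Explicit `rho` values remain available in the model config.
Initialization is zero; warm starting carries the primal iterate, and the
duals persist across outer iterations.  Subspace models optimize the coefficient images, with
the regularizers applied to the coefficients, and recover the series as
`x = basis @ coeffs` exactly.

Convergence at the default 30-iteration budget is approximate by design
(matching the acquisition-scale protocol); on a 1-D TV-denoising instance a
300-iteration run agrees with a 10^4-iteration projected-gradient dual
reference to better than 0.1 % in objective.

## Parameter fitting

Reconstructed series are optionally smoothed by a complex Gaussian
prefilter (sigma 0.6 voxels, kernel radius 4 sigma, unit-sum kernel) and
fitted voxelwise by complex nonlinear least squares over
(Mss, M0, I, Teff, phase), with a single phase shared by both segments
(appropriate for acquisitions with near-constant minimal phase; a per-part
phase would be a small extension).  The optimizer is a batched
Levenberg-Marquardt with analytic Jacobian: all voxels advance through
damped Gauss-Newton steps with per-voxel damping and box projection
(Teff in [0.05, 5] s, I in [0, 1.2], magnitudes nonnegative), which makes
whole-map fitting deterministic and fast (a 128^2 map fits in seconds).
Initialization is closed-form: phase from the first non-inverted sample,
M0 from that sample's rotated real part, Mss from the late samples, Teff
from a log-linear fit of `S+ - S- = (I+1) M0 exp(-t/Teff)`, I = 0.9.
T1 then follows per voxel by the bisection above.

## Phantom and noise model

The phantom is a support ellipse containing nested elliptical tissue
regions; per-tissue parameters are drawn uniformly inside the dictionary
ranges (so the K = 4 subspace represents every phantom signal), M0 varies
mildly around 1, and a smooth low-order polynomial phase map (a few tenths
of a radian across the field of view) exercises the complex fit and the
TV-on-complex-images path.  K-space simulation is exact at tissue
granularity: each tissue's static profile is encoded once per bin and every
spoke's samples are scaled by the tissue signal at that spoke's own time,
so the data contain the true within-bin signal evolution while fitting uses
bin-center times — reproducing the binning approximation of a real
acquisition.

Measurement noise is circular complex Gaussian per sample.  The experiment
parameterizes its level by the image-domain SNR of the full-data
least-squares reconstruction (mean tissue magnitude over propagated noise
std, measured by pushing a unit-variance probe through the same solver);
the default target is SNR 50, the same level used by the fitting noise
benchmark.  Raw k-space SNR is a poor proxy because radial sampling
concentrates energy at the k-space center.

What the phantom does **not** emulate: anatomically realistic geometry,
B0/B1 inhomogeneity, the zero-echo-time readout's gaps and sidebands,
multi-channel phase, or partial-volume textures.  Passing tests therefore
demonstrate correctness of the operators, solvers and fits under the stated
model, and the qualitative regularization behaviour — not performance on
any particular specimen.

## The acceleration experiment

The default desk-scale study uses a 2-D 128^2 phantom with 6 tissues,
image SNR 50, AFs {1, 6, 12} and models {LS, STV, LLR, S-STV+LLR}.  Its
sequence timing keeps the full-scale relaxation window and bin times but
spreads them over 96 excitations per sweep (TR lengthened by the same
1476/96 factor) and acquires 16 sweeps (256 spokes per bin against the 202
needed for full 2-D sampling, i.e. reference AF ~ 0.79).  Many short
sweeps matter because retrospective acceleration keeps each bin's leading
spokes in acquisition order: only when that prefix spans complete sweeps
does the retained data cover each bin's full time window, keeping the
effective sample time at the bin center.  The full-scale acquisition has
this property through its hundreds of repetitions; a single-sweep desk
acquisition does not (its prefix covers only the start of each bin's
window, which visibly biases T1 at high acceleration).  The reference is the
LLR-regularized full-data reconstruction with the larger 13^2 blocks (the
block-size asymmetry mirrors the bias-avoidance of the full-scale
protocol).  For each model and AF the pipeline undersamples, reconstructs,
prefilters, fits and scores T1 against the reference inside the phantom
support with nRMSE, SSIM (Gaussian window sigma 1.5, k1 = 0.01, k2 = 0.03,
data range = ROI maximum of the reference) and MNAD (median of
|T1 - T1_ref| / T1_ref; the median variant is the primary definition, a
mean variant is a one-line change).  These sizes keep a full sweep within a
few minutes on one CPU; the operators are dimension-agnostic, so the same
code runs 3-D volumes where compute allows.

Regularization weights are specified in relative units: the effective ADMM
weight is `alpha_rel * n_samples`, which transfers a single value across
acceleration factors on unit-RMS-normalized data.  The fixed-policy
defaults were chosen by the documented calibration: per model and
acceleration factor, a grid search minimizing T1 nRMSE against the
reference map (the reference's own weight was chosen by minimizing T1
nRMSE against the phantom's ground truth, which a synthetic study uniquely
allows).  A per-run grid-search policy (`weight_policy="grid"`) reproduces
the selection online instead.

Model ranking is data-dependent and is not asserted anywhere; the runner
only enables the comparison.  The properties that are asserted on the
default study are the two robust qualitative trends: T1 error does not
decrease with acceleration, and at strong acceleration every regularized
model outperforms plain least squares.

## Known limitations

* The ADMM penalty `rho = alpha` is a heuristic; poorly scaled weights can
  make 30 outer iterations visibly under-converged.
* The LSMR density weighting changes the least-squares geometry (weighted
  LS); it is the standard practical choice for radial data but is not an
  unweighted-optimum-preserving preconditioner.
* Gap-spoke interpolation assigns inserted spokes to the following bin;
  a real sequence would schedule extra TRs.
* Single-coil reception is the default; coil maps are accepted but no
  sensitivity estimation is provided.
* The fit's box projection can stick at bounds for pathological voxels;
  such voxels surface through the residual map and validity mask.
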