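# Methods

## The structure function

For a series of N frames I₀ … I_{N−1} at uniform interval Δt, the image
structure function at lag m is

    d(m) = 1/(N−m) · Σ_{n=m}^{N−1} |F_xy(I_{n−m} − I_n)|² ,

the power spectrum of frame differences averaged over every pair with
the same delay. It is the imaging analogue of the structure function of
classical dynamic light scattering: any signal component that is static
or drifts slowly compared with the delay cancels in the difference, so
no background subtraction or flat-fielding is performed anywhere in the
pipeline — intensities are used exactly as read from disk.

`structure_naive` evaluates the definition literally (difference first,
transform second) and is retained purely as the validation oracle: it
costs Σ_m (N−m) spatial FFTs. `structure_direct` uses the linearity of
the Fourier transform to difference cached spectra Ĩ_n = F_xy I_n
instead, reducing the spatial FFTs to N while keeping O(Σ_m (N−m))
elementwise work; its cost grows with the number of requested lags, so
it pairs naturally with a log-spaced lag sublist.

## The Wiener–Khinchin engine

Expanding the squared modulus,

    d(m) = 1/(N−m) · [ Σ_{k=0}^{N−1−m} |Ĩ_k|²  +  Σ_{n=m}^{N−1} |Ĩ_n|²
                       − 2 Re Σ_{n=m}^{N−1} Ĩ*_{n−m} Ĩ_n ] .

The first two terms are forward and backward running sums of the
per-frame power spectra (O(N) per wave vector, computed as cumulative
sums). The third is the linear lagged autocorrelation C(m) of each wave
vector's complex time series s(n) = Ĩ_n(q). For a series of length N,
C is obtained through the Wiener–Khinchin theorem: zero-pad s to length
P, the smallest power of two ≥ 2N, take the temporal FFT, form the
squared modulus, inverse-transform, and read lags 0 … N−1. The padding
is not optional: it is what makes the circular correlation of the FFT
route equal the finite linear sum of the definition exactly (to
rounding), so the engine reproduces the pair-difference definition to
better than 1e−9 relative in double precision. Per wave vector the
engine performs exactly one forward and one inverse temporal transform
— O(N log N) work — regardless of how many lags are requested, which is
why it always returns all N lags and `lags` merely selects a subset.
The per-lag normalization 1/(N−m) is applied once, after the three
terms are assembled. d(0) is set to its exact value 0 (the expansion
collapses identically at m = 0; the FFT route would leave ~1e−12
relative rounding residue).

Instrumented counters (`WorkCounters`) expose these operation counts so
the complexity claims are asserted structurally in the test suite
rather than through hardware-dependent timings, which are logged by the
CLI but never tested.

## Conventions

* **FFT normalization**: unnormalized forward transform (no 1/(HW)
  factor). DC equals the pixel sum and Parseval reads
  Σ_fullplane |Ĩ(q)|² = H·W·Σ_xy I(x,y)². All engines, expectations and
  tests share this convention.
* **Half-plane storage**: frames are real, so only the Hermitian-reduced
  H×(W/2+1) half plane is stored; a multiplicity array (2 for columns
  0 < k_x < W/2, 1 for the self-conjugate k_x = 0 and Nyquist columns)
  makes every weighted half-plane average equal the full-plane average.
  Only even frame dimensions are accepted, which keeps the Nyquist
  bookkeeping trivial.
* **Wave vectors**: q_i = 2π k_i/(n_i · pixel size) in rad/m with
  integer frequency index k_i ∈ [−n_i/2, n_i/2).
* **Precision**: spectra are complex128 by default; an explicit
  single-precision mode stores complex64 but still accumulates sums in
  double, since N can reach 10⁴ summands. No window or apodization is
  applied before the spatial transform.

## Memory-budgeted chunking

Holding every wave vector's time series at working precision costs
(N + P) complex values per wave vector (series plus temporal-FFT
workspace). When H·(W/2+1) wave vectors exceed the byte budget, the
half plane is split into G = ⌈n_q / ⌊budget/cost⌋⌉ contiguous,
count-balanced groups — the fewest groups whose members each fit the
budget — and the spatial FFTs are recomputed once per group rather than
spilled to disk. The split is a pure execution strategy: results are
identical (≤ 1e−12 relative, in practice bit-for-bit) for any G, which
the suite asserts for G ∈ {1, 2, 4, 7}.

## Azimuthal averaging

Ring r collects half-plane wave vectors with round(|q|/Δq) = r, where
Δq = 2π/(max(H,W) · pixel size); rounding is round-half-even so ties
break deterministically. Members contribute with their Hermitian
multiplicity; q = 0 is always excluded and empty rings are dropped.
Ring centers are reported as r·Δq. For rectangular frames the larger
dimension sets Δq (finer rings); anisotropic pixels and
sector-restricted averages are out of scope.

## ISF fitting

Each ring is fitted with d(q,t) = A(q)·(1 − e^{−t/τ(q)}) + B(q) over
t = mΔt, m ≥ 1 (the zero lag is identically zero and carries no
information), by bounded least squares (A ≥ 0, τ > 0). Initial guesses:
B₀ = min d, A₀ = max − min, τ₀ = earliest t where d crosses
B₀ + (1 − e⁻¹)A₀, falling back to the mid-range t. Rings that fail to
converge, or whose curve is flat so τ is unidentifiable, are flagged
(`converged=False`, τ = NaN) and excluded from pooled fits — never
silently dropped. Weighting is uniform across lags.

`measure_diffusion` fits each ring on a log-spaced sublist of ~40 lags
rather than the full linear lag set: with ~10³ linear lags almost all
points sit on the long-time plateau, whose finite-sample fluctuations
are strongly correlated, and they dominate the least squares at the
expense of the decay; log spacing balances the leverage of both
regions.

The diffusion coefficient pools converged rings inside a user-chosen
band [q_min, q_max] through the origin-constrained linear regression
1/τ = Dq², i.e. D = Σ q²/τ / Σ q⁴ — closed-form, no iterative solver.
The band edges are physics, not statistics: below q_min the decay time
approaches the observation window NΔt (and, in gravity-affected
experiments, buoyancy modifies the dynamics — no gravitational model is
implemented); above q_max the optical signal falls into the noise
floor. The companion diagnostic `tau_scaling_exponent` is the plain
unweighted slope of log τ versus log q over the same band, −2 for
simple diffusion. Because the slow rings near q_min carry only a few
independent decorrelation intervals, this slope scatters by roughly
±0.1–0.2 between random seeds at the default fixture size; the pooled D
is much stiffer (q⁴ weighting) and lands within a few percent.

The amplitude A(q) and baseline B(q) absorb instrument factors (optical
transfer function, camera noise); no transfer-function model is fitted
because τ(q) is unaffected by them.

## Synthetic fixtures

`generate_brownian_series` renders n_particles independent 2D random
walkers (per-axis step variance 2·D·Δt, periodic wrapping) as Gaussian
blobs of width σ_blob on a uniform background, plus i.i.d. Gaussian
camera noise. Two properties make it an exact oracle: the wave vectors
of the periodic domain are commensurate with the box, so wrapping is
invisible to e^{iq·x} and the ISF is exactly exp(−D q² t); and the blob
envelope attenuates signal power as exp(−σ_blob² q_pix²), making the
recoverable q-band predictable. The latent trajectories are returned
alongside the frames so displacement-level checks (MSD = 4DΔt·m) need
not re-infer positions from images. Blob stamps are truncated at 4σ;
blob widths below 1 px are rejected to keep the signal band-limited.

Defaults mirror a desk-scale acquisition: N = 1024 frames of 128×128 px
at 25 Hz (Δt = 0.04 s), 1 µm pixels, 200 particles, D = 0.5 µm²/s,
σ_blob = 2 px, 1000 integrated counts per particle on a 100-count
background with 2 counts of read noise — a realistic SNR for a 16-bit
camera. With these values the diffusive band spans ring indices ≈ 8–24
(τ from ~13 s down to ~1.4 s inside a 41 s record), which is where
`measure_diffusion`'s recommended q-band sits. What the fixture does
*not* emulate: optical transfer-function oscillations, gravity effects
on low-q dynamics, hydrodynamic interactions, polydispersity, finite
exposure blur. Passing the end-to-end test therefore validates the
computation and the statistics, not the optics of any particular
instrument.

`generate_noise_series` draws i.i.d. zero-mean Gaussian frames; for
σ the structure function expectation is flat, E d(m,q) = 2HWσ² for all
m ≥ 1 and q ≠ 0 under the unnormalized-FFT convention — the "noise
plateau" used as an analytic end-to-end check.

All randomness uses numpy's `default_rng` (PCG64) with a mandatory
seed; identical seeds give bit-identical fixtures.

## Validation problem sizes

The suite validates engine equivalence on seeded 16-bit-range random
series (N = 64, 32×32, five seeds), chunk invariance on the same data,
the autocorrelation identity on 100 random complex series of length
≤ 64, the noise plateau at N = 512 frames of 64×64, and the full
Brownian pipeline at the fixture defaults above. These sizes keep the
whole suite in the tens of seconds on one CPU while leaving every
statistical check well-powered; the engines themselves are size-generic.

## Known limitations

* Uniform frame interval only; no gap or drop-out handling.
* Even frame dimensions only.
* Single-exponential ISF model only (no stretched/double exponentials,
  no ballistic or advective models).
* The memory planner balances by wave-vector count with uniform cost;
  it does not model allocator overhead or FFT plan storage.
* GPU execution and disk-backed spectrum caches are out of scope.
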