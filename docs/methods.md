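# Methods

This note records the model, the numerical choices, and the places
where the design was genuinely open — with the reasoning behind each
choice.  Nothing here reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The package treats Fisher's infinitesimal model (infinitely many
additive loci, infinite population) with all loci on **one continuous
circular chromosome**.  Selection acts on haploid gametes and keeps
those with trait value exactly `μ + βσ` — the infinite-population
idealisation of truncation selection, which turns selection into a
linear constraint and keeps every within-lineage distribution Gaussian.
Recombination uses exactly two diametrically opposed crossovers, i.e. a
flat recombination landscape and equal-size transmitted segments.
Consequences of these choices: no dominance (selection never sees the
diploid phase), no mutation, no drift, a fixed genetic map length.

In Fourier coordinates the trait is the mode-0 coefficient, and the
rotation-invariant complex-normal projection reduces the population
state to one variance per mode.  The projection is exact for the first
generation and an approximation afterwards (the true population is a
mixture of Gaussians over crossover histories); the Monte-Carlo
simulator exists to measure what that approximation costs.

## The variance recursion (`spectral_core`)

State: variance deficits `c_k = 1 − σ²_k`, stored for `0 ≤ k ≤ N`
(mirror symmetry resolves negative modes).  One generation is the reset
`c_0 ← 1` (injecting `σ²_0` of deficit) followed by convolution with
the kernel {retention ½; weight `2/(π²j²)` to each signed odd offset
`j`}.  All computation is in 64-bit floats; deficits spanning many
orders of magnitude are exactly why the recursion is iterated in `c`
rather than `σ²`.

Numerical choices, and why:

* **Kernel residual.**  The kernel is truncated at a half-width `J`
  (default `N` + tail extent); the weight beyond `J` is evaluated in
  closed form through the trigamma function and carried explicitly as
  `residual_mass` instead of renormalising the kernel.  Renormalising
  would silently repair matter conservation that the truncation in fact
  violates; keeping the residual visible lets `matter_balance` verify
  conservation honestly (injected = stored change + boundary leak +
  residual loss, to 1e−10 per step).
* **Tail closure.**  The recursion couples every mode to every other,
  so a hard cutoff at `N` would starve boundary modes.  Deficits beyond
  `N` are extended by a power law `c_k = a·k^(−p)` fitted by log-log
  least squares on the top 20 % of retained modes, with `p` clamped to
  `[1, 4]`.  A power law is the right family because the Cauchy Green
  function of the kernel implies an asymptotic `k^(−2)` deficit tail;
  fitting `p` rather than pinning it at 2 absorbs pre-asymptotic
  curvature.  Adequacy is tested by cutoff doubling (N vs 2N
  trajectories agree on `σ²_{0,g}` to < 1 % for `g ≤ N/8`; measured
  agreement is ~1e−7) — not by comparison with any particular closed
  form.
* **FFT convolution.**  The mirrored, tail-closed spectrum is embedded
  in a zero-padded buffer of length ≥ `2(N+E) + 2J + 1` so the circular
  transform realises an exact linear convolution; an O(N·J) literal
  sum (`convolve_direct`) is kept as the oracle and the two agree to
  1e−12.
* **Validity guard.**  Finite-`N` truncation error becomes visible when
  `g` is comparable to `N`; `iterate` warns beyond `g = N/4`, and the
  default scaling-fit window is `[64, N/4]` for the same reason.
* **Exactness check.**  Because the deficit recursion is linear, the
  mode-0 trajectory has a closed-form infinite-lattice solution:
  `c_{0,g} = Σ_{g₁≤g} inj(g₁)·R(g−g₁+1)` with return mass
  `R_t = (1/π)∫₀^π (1−q/π)^t dq = 1/(t+1)` (the kernel's
  characteristic function is the tent `1 − |q|/π`).  The implementation
  reproduces this oracle to ~1e−8 at `N = 2048`, so the cutoff and tail
  machinery introduce no measurable error inside the validity window.

## The no-linkage control (`no_linkage`)

Free recombination is implemented at **finite M with exact linear
algebra**: conditioning an M-variate Gaussian on its sum, half-subset
variances, and block covariance assembly for offspring of two
independent parents.  The classical results come out exactly:
post-selection per-locus variance `(1/M)(1−1/M)`, pairwise covariance
`−1/M²`, Var(G) = 0, half-sum variance exactly ¼ for *every* even M
(the `∓1/(2M)` corrections cancel identically), released offspring
variance exactly ½.

One caution discovered in the algebra: the "steady state in one
generation" is an `M → ∞` statement.  After the first cycle the
population covariance is no longer exchangeable (it carries the block
structure of the recombination split), and iterating the cycle at
finite M lets Var(G) wander away from ½ by O(1/M) per generation.  The
tests therefore assert the first cycle exactly and the 1/M shrinkage of
the multi-cycle deviation, rather than a spurious exact fixed point.

## The Monte-Carlo simulator (`gametes`)

A finite population (`P` gametes, modes `0..K`, seeded NumPy
generators) that applies the *exact* recombination operator in
coefficient space.  Design choices:

* **Hard conditioning** (`ε = 0`): selection overwrites every `X_0`
  with `μ + βσ`.  Under the projection, mode 0 is independent of the
  rest, so this is the exact-value selection; an `ε`-window mode exists
  to probe whether hard conditioning distorts the true (mixture)
  population.
* **Effective recombination truncation.**  Step-function harmonics
  beyond `|j| = 2K−1` cannot couple two stored modes, so the operator
  caps the requested truncation there; the generous default (1023)
  therefore costs nothing at `K = 128`.
* **Batched update.**  The per-child phase factors out of the harmonic
  convolution, and the remaining fixed convolution is evaluated as
  multiplication by the truncated square wave on a θ-grid with
  `N_grid > 2K + J` (alias-free by bandwidth counting) — two real FFTs
  per child.  The batch is asserted identical (1e−12) to the literal
  per-pair operator.
* **Parent pairing**: uniform with replacement, the two parents of one
  child forced distinct (infinite-population panmixia never selfs);
  one crossover angle per child (the two crossovers are `ψ` and
  `ψ + π` — a single degree of freedom).

**What the simulator emulates, and what it does not.**  It validates
the complex-normal projection and the recombination algebra.  It is a
*finite-P, finite-K* instrument: finite P adds sampling noise (s.e. of
a variance ≈ `σ²√(2/P)`) and a little drift; finite K removes the
variance reservoir in modes beyond K, a *deterministic* shortfall of
≈ 0.2/K per generation at mode 0.  Cross-validation therefore compares
the simulator to the recursion iterated on the *same truncated mode
set* (`truncated_reference`), and checks separately that the gap
between truncated and infinite references equals the predicted
truncation effect.  With `P = 1e5`, `K = 128`, 8–16 replicates, the
Monte-Carlo means sit within ~1 standard error of the matched reference
for `g ≤ 4`; by `g = 5` a small negative deviation of order 1e−3
(≈ 2 ensemble standard errors, ~0.3 % of the variance) becomes
resolvable — the expected signature of the projection approximation,
which grows with the number of mixture components, i.e. with `g`.
These deviations are reported by the cross-validation tests rather
than absorbed into tolerances.  Passing says nothing about finite real
populations (drift) or about `g` beyond the tested range.

## Scaling analysis (`scaling`)

`log2(g)·σ²_{0,g}` is regressed on `{1, log2(log2 g)/log2 g}` by
unweighted OLS (no error model exists for a deterministic trajectory;
the fit is linear in both constants and exactly recovers
self-generated data).  The default window `[64, N/4]` comes from the
finite-N validity rule; both endpoints are overridable and recorded in
the output.

Measured behaviour of the constants: at `N = 8192`, window
`[64, 2048]`, the fit gives `A ≈ 1.66`, `B ≈ −1.12`; windows at larger
`g` (run on the exact infinite-lattice oracle) drift towards
`A ≈ 1.50`, `B ≈ −0.6`.  The leading constant is consistent with
`1/ln 2 ≈ 1.44` plus slowly-decaying corrections — the value implied by
a self-consistency argument: the iterated kernel's central return mass
is `1/(g+1)`, so the injected deficit `σ²_{0,g}` must satisfy
`1 ≈ Σ σ²_{0,g₁}/(g−g₁)`, giving `σ²_{0,g} ≈ 1/ln g`.  The log-log
correction term is genuinely large in every accessible window (the
correction is ~50 % of the leading term at `g = 64`), which is why the
fitted constants move with the window; reported fits always carry their
window.

**Green-function diagnostics.**  The `g`-fold iterated kernel is
computed spectrally on a circular lattice (renormalising the truncated
kernel's ~1e−5 missing mass so lattice mass is exactly conserved).  Its
characteristic function is the tent `1 − |q|/π` — verified in the tests
against an independent polylogarithm evaluation — whose corner at
`q = 0` is the spectral signature of the `1/j²` tail: the iterate
converges to a **Cauchy** profile, the α = 1 stable law.  Because the
retention factor makes the printed scale convention ambiguous (`2g/π`
vs the half-participation value `g/π`), the default comparator *fits*
the scale to the central value and reports its linearity in `g`
(R² > 0.999 over `g ∈ [32, 512]`, doubling ratio → 2); the fitted scale
sides with `g/π`, consistently with the tent characteristic function
(`(1−|q|/π)^g → e^{−g|q|/π}`, a Cauchy of scale `g/π`).

## Interfaces

Trajectories and spectra are CSV (17 significant digits, so reruns are
byte-identical); fits and summaries are JSON; configs are flat YAML
mirroring the CLI flags (explicit flags win).  Every CLI run writes a
`manifest.json` (full parameters, seed, timestamps, outputs, package
version) sufficient to reconstruct it, and writes it even on failure
with the error recorded.

## Problem sizes

Defaults were chosen as the smallest sizes at which the quantities of
interest are converged: recursion cutoff `N = 8192` with 2048
generations (cutoff-doubling agreement ~1e−7 over the fit window);
Monte-Carlo `P = 1e5`, `K = 128`, 8 replicates (variance s.e. ≈ 5e−4 on
the ensemble mean); Green-function comparisons on supports of 64·g
lattice sites.

## Known limitations

* The aging-law constants depend visibly on the fit window at every
  accessible `g`; only window-tagged values are meaningful.
* The ε-window selection mode is exercised but not deeply
  characterised; differences from hard conditioning are a diagnostic,
  not a calibrated correction.
* No diploid phase, dominance, mutation, drift, multiple or linear
  chromosomes, or position-dependent recombination — deliberate
  non-goals of this model family.
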