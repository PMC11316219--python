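# linkinf — Fisher's infinitesimal model with genetic linkage

`linkinf` implements the infinitesimal model of quantitative genetics in
the strong-linkage limit: infinitely many additive loci on **one
continuous circular chromosome**, an infinite population, and recurrent
cycles of directional selection (at an exact trait value) followed by
panmictic mating with exactly two diametrically opposed crossovers.

It is written for quantitative and population geneticists who want to
study how linkage disequilibrium built up by selection (the Bulmer
effect) reshapes the long-term response to selection — and for anyone
interested in the underlying mathematics: a heavy-tailed lattice
diffusion with resetting that sits exactly at the Cauchy (alpha = 1)
stable boundary and exhibits aging dynamics.

## The model

A gamete's allelic profile `x(θ)` on the circular chromosome (`θ ∈
[0, 2π)`) is represented by its Fourier coefficients
`X_k = (1/2π) ∫ e^{-ikθ} x(θ) dθ`; the genetic value is `G = X_0`.
Linkage equilibrium is complex white noise: all modes independent with
unit complex variance.  One generation is:

1. **selection** — keep gametes with `G = μ + βσ` exactly; this
   collapses the mode-0 variance to zero and touches nothing else;
2. **recombination** — each child combines two random parents through
   crossovers at angles `ψ` and `ψ + π`.  In coefficients,
   `Y_k = (X_k + X'_k)/2 + Σ_{odd j} h_j e^{-ijψ}(X_{k-j} - X'_{k-j})`
   with `h_j = -i/(πj)` the harmonics of the half-circle step function.

Under the rotation-invariant complex-normal projection, the population
state reduces to the per-mode variances `σ²_{k,g}`, which obey

    σ²_{k,g+1} = σ̂²_{k,g}/2 + (2/π²) Σ_{odd k'} σ̂²_{k+k',g} / k'²,
    μ_{g+1} = μ_g + β σ_{0,g},

where `σ̂²` is the post-selection spectrum (`σ̂²_0 = 0`).  Without
linkage the model has a steady state (variance released back to 1/2
every generation, constant gain `β·√½` per generation).  With linkage
it does not: the genetic variance decays to zero like an inverse
logarithm,

    log2(g)·σ²_{0,g} = A + B·log2(log2 g)/log2 g,

slowly enough that the cumulative gain still diverges.

## What is in the box

| module | contents |
|---|---|
| `linkinf.spectral_core` | deterministic variance recursion: diffusion kernel (retention ½, odd-offset weights `2/(π²j²)` per sign, closed-form residual), FFT/direct convolution, analytic power-law tail closure beyond the cutoff, trajectory recording |
| `linkinf.no_linkage`   | exact finite-M Gaussian algebra for the free-recombination control: conditioning on `G` (Bulmer covariances `-1/M²`), half-sum variance ¼, released variance ½, steady-state summary |
| `linkinf.gametes`      | seeded Monte-Carlo forward simulator of gamete Fourier spectra (exact-value selection, two-crossover recombination), cross-validating the projection |
| `linkinf.scaling`      | aging-law fits, finite-cutoff validity windows, iterated-kernel vs Cauchy Green-function comparator |
| `linkinf.cli`          | `linkinf run / fit / simulate / baseline / greenfn` with YAML configs and reproducible run manifests |

## Worked example

Iterate the recursion at cutoff N = 2048 for 512 generations and fit
the aging law on the trustworthy window:

```bash
$ linkinf run --cutoff 2048 --generations 512 --out-dir demo
g=     1 sigma2_0=0.500000 mu=1.0000
g=     2 sigma2_0=0.416667 mu=1.7071
g=     4 sigma2_0=0.348611 mu=2.9650
g=     8 sigma2_0=0.294868 mu=5.2431
...
g=   256 sigma2_0=0.155044 mu=110.5153
g=   512 sigma2_0=0.140727 mu=208.6172

$ linkinf fit --trajectory demo/trajectory.csv --cutoff 2048 --out-dir demo
A = 1.7238  B = -1.2926  window = [64, 512]  residual rms = 1.45e-03
```

Reading the numbers: one cycle from linkage equilibrium releases
exactly half the variance (`σ²_{0,1} = 1/2`, the same value the exact
no-linkage control gives — no disequilibrium exists yet); two cycles
leave `5/12`; from then on the variance keeps sliding without a plateau
(`0.1407` by g = 512) while the mean `μ` keeps growing — without bound,
but by ever smaller increments `β·σ_{0,g}`.  The fitted `A` estimates the asymptotic level
of `log2(g)·σ²_{0,g}`; it drifts down toward ≈ 1.5 as larger cutoffs
open longer trustworthy fit windows.

The Monte-Carlo simulator reproduces the same release stochastically:

```bash
$ linkinf simulate --pop 100000 --modes 128 --generations 1 --seed 7
g=0 empirical Var(G) = 1.00001
g=1 empirical Var(G) = 0.49826
```

(`0.49826` vs the truncation-matched deterministic value `0.49842`:
a K = 128 simulator misses the variance reservoir beyond its stored
modes, worth ≈ 0.0016 in the first generation.)

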