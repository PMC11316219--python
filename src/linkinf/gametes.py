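"""Seeded Monte-Carlo forward simulator of gametes in Fourier space.

Each gamete of a finite population carries one continuous circular
chromosome whose allelic profile ``x(theta)`` is stored through its
truncated Fourier coefficients ``X_k`` (``0 <= k <= K``; negative modes
are complex conjugates and ``X_0``, the genetic value, is real).  The
initial population is linkage equilibrium: ``X_0 ~ N(0, 1)`` and, for
``k >= 1``, independent real/imaginary parts of variance 1/2 each, i.e.
unit complex variance per mode.

A generation is (i) selection at the exact trait value ``mu + beta*sigma``
and (ii) panmictic mating in which each child combines two random
parents through two diametrically opposed crossovers at angle ``psi``:
the child profile is ``x(theta)H(theta-psi) + x'(theta)H(theta-psi-pi)``
with ``H`` the periodic half-circle step function.  In coefficients,

    Y_k = (X_k + X'_k)/2
          + sum_{odd j, |j| <= J_r} h_j e^{-i j psi} (X_{k-j} - X'_{k-j}),

with ``h_j = -i/(pi j)`` the step-function harmonics (``h_0 = 1/2``,
even ``j != 0`` vanish).  The simulator is the stochastic cross-check of
the deterministic variance recursion: its empirical per-mode variances
should track ``sigma^2_{k,g}`` up to finite-population noise and the
error made by the complex-normal projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import fft as _fft

__all__ = [
    "GameteSpectrum",
    "PopulationState",
    "SimConfig",
    "init_population",
    "genetic_value",
    "select",
    "recombine",
    "step_harmonics",
    "advance_generation",
    "rotate",
    "estimate_spectrum",
    "run_cycles",
    "simulate_replicates",
]

_CHUNK = 8192  # children recombined per batch (bounds working memory)


@dataclass
class GameteSpectrum:
    """Truncated Fourier coefficients ``X_0 .. X_K`` of one gamete."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.ndim != 1 or len(self.coeffs) < 1:
            raise ValueError("coeffs must be a non-empty 1-D complex array")
        if abs(self.coeffs[0].imag) > 1e-9:
            raise ValueError("X_0 must be real")
        if not np.all(np.isfinite(self.coeffs.view(float))):
            raise ValueError("non-finite coefficients")
        self.coeffs[0] = self.coeffs[0].real

    @property
    def mode_cutoff(self) -> int:
        return len(self.coeffs) - 1


@dataclass
class PopulationState:
    """Finite population of gametes; rows of ``coeffs`` are gametes."""

    coeffs: np.ndarray  # complex, shape (P, K+1)
    generation: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] < 2:
            raise ValueError("population needs at least 2 gametes")

    @property
    def size(self) -> int:
        return self.coeffs.shape[0]

    @property
    def mode_cutoff(self) -> int:
        return self.coeffs.shape[1] - 1

    @property
    def genetic_values(self) -> np.ndarray:
        return self.coeffs[:, 0].real

    @property
    def mean_G(self) -> float:
        return float(self.genetic_values.mean())

    @property
    def var_G(self) -> float:
        return float(self.genetic_values.var())

    def gamete(self, i: int) -> GameteSpectrum:
        return GameteSpectrum(self.coeffs[i].copy())


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one Monte-Carlo run.

    ``recomb_truncation`` is the largest odd step-function harmonic
    retained in the recombination operator; only offsets ``|j| < 2K``
    can couple stored modes, so the default is generous.  A zero
    ``selection_window`` means hard conditioning (every gamete's ``X_0``
    is overwritten with the threshold value); a positive window retains
    gametes within ``epsilon*sigma`` of the threshold instead.
    """

    population_size: int = 100_000
    mode_cutoff: int = 128
    recomb_truncation: int = 1023
    beta: float = 1.0
    selection_window: float = 0.0
    generations: int = 5
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.mode_cutoff < 1:
            raise ValueError("mode_cutoff must be >= 1")
        if self.recomb_truncation % 2 == 0:
            raise ValueError("recomb_truncation must be odd")
        if self.selection_window < 0:
            raise ValueError("selection_window must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def init_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PopulationState:
    """Draw a linkage-equilibrium population (unit complex variances)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P, K = config.population_size, config.mode_cutoff
    coeffs = np.empty((P, K + 1), dtype=complex)
    flat = coeffs.view(float)  # interleaved (re, im) columns
    flat[:, 0] = rng.standard_normal(P)
    flat[:, 1] = 0.0
    flat[:, 2:] = rng.standard_normal((P, 2 * K)) * math.sqrt(0.5)
    return PopulationState(coeffs=coeffs, generation=0)


def genetic_value(gamete: GameteSpectrum) -> float:
    """Trait value ``G`` of a gamete: its mode-0 coefficient."""
    return float(gamete.coeffs[0].real)


def select(
    pop: PopulationState, beta: float, epsilon: float = 0.0
) -> PopulationState:
    """Select at the trait threshold ``mu + beta*sigma``.

    ``epsilon = 0``: hard conditioning -- every gamete's ``X_0`` is
    overwritten with the threshold (valid under the complex-normal
    projection, where mode 0 is independent of the others).
    ``epsilon > 0``: retain gametes with ``|G - threshold| <=
    epsilon*sigma``; signals an empty (or single-gamete) window.
    """
    if pop.var_G <= 0:
        raise ValueError("population has no trait variance to select on")
    mu, sigma = pop.mean_G, math.sqrt(pop.var_G)
    threshold = mu + beta * sigma
    if epsilon == 0.0:
        coeffs = pop.coeffs.copy()
        coeffs[:, 0] = threshold
        return replace(pop, coeffs=coeffs)
    keep = np.abs(pop.genetic_values - threshold) <= epsilon * sigma
    if keep.sum() < 2:
        raise ValueError(
            f"selection window epsilon={epsilon} around G={threshold:.3f} "
            f"retains {int(keep.sum())} gametes (need >= 2)"
        )
    return replace(pop, coeffs=pop.coeffs[keep].copy())


def step_harmonics(j_max: int) -> np.ndarray:
    """Dense harmonics of the half-circle step over offsets ``-J..J``.

    ``h_j = -i/(pi j)`` for odd ``j``, zero for even ``j != 0``; the
    ``j = 0`` term (1/2) is handled separately as the parental mean.
    """
    j = np.arange(-j_max, j_max + 1)
    h = np.zeros(2 * j_max + 1, dtype=complex)
    odd = (j % 2) != 0
    h[odd] = -1j / (np.pi * j[odd])
    return h


def _full_modes(coeffs: np.ndarray) -> np.ndarray:
    """Extend ``X_0..X_K`` rows to ``X_{-K}..X_K`` via conjugate mirror."""
    return np.concatenate([np.conj(coeffs[..., :0:-1]), coeffs], axis=-1)


def _effective_truncation(j_r: int, mode_cutoff: int) -> int:
    # offsets beyond 2K-1 cannot couple two stored modes
    return min(j_r, 2 * mode_cutoff - 1)


def recombine(
    parent1: GameteSpectrum,
    parent2: GameteSpectrum,
    psi: float,
    j_r: int,
) -> GameteSpectrum:
    """Two-crossover recombination of a single parent pair at angle ``psi``.

    Literal evaluation of the coefficient formula (module docstring);
    the batched generation update is algebraically identical but
    phase-factored for speed.
    """
    if j_r % 2 == 0:
        raise ValueError("recombination truncation must be odd")
    if not 0.0 <= psi < 2.0 * math.pi:
        raise ValueError("psi must lie in [0, 2*pi)")
    if parent1.mode_cutoff != parent2.mode_cutoff:
        raise ValueError("parents must share the mode cutoff")
    K = parent1.mode_cutoff
    f1 = _full_modes(parent1.coeffs)
    f2 = _full_modes(parent2.coeffs)
    diff = f1 - f2
    child_full = 0.5 * (f1 + f2)
    j_eff = _effective_truncation(j_r, K)
    for j in range(-j_eff, j_eff + 1, 2):
        h = -1j / (math.pi * j) * np.exp(-1j * j * psi)
        # child_full index m <-> mode m - K; source mode (m - K) - j
        lo = max(0, j)
        hi = 2 * K + 1 + min(0, j)
        child_full[lo:hi] += h * diff[lo - j : hi - j]
    child = child_full[K:]
    child[0] = child[0].real
    return GameteSpectrum(child)


def advance_generation(
    pop: PopulationState,
    config: SimConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Produce ``population_size`` children by panmictic mating.

    Each child draws two distinct parents uniformly with replacement and
    a uniform crossover angle ``psi``; all children of the batch apply
    the same coefficient-space recombination operator as ``recombine``.
    Two algebraic identities make the batch fast.  First, the per-child
    phase factors out of the step-harmonic convolution:
    ``h_j e^{-i j psi} D_{k-j} = e^{-i k psi} h_j [e^{i m psi} D_m]_{k-j}``,
    leaving one *fixed* kernel for every child.  Second, that fixed
    convolution is evaluated as multiplication by the truncated square
    wave ``sum_{odd j <= J} (2/(pi j)) sin(j theta)`` on a real theta
    grid fine enough (``Ng > 2K + J``) that no aliased harmonic can
    reach a stored mode, so each child costs two real FFTs.
    """
    P_out = config.population_size
    P_in = pop.size
    K = pop.mode_cutoff
    p1 = rng.integers(0, P_in, P_out)
    p2 = rng.integers(0, P_in, P_out)
    clash = p2 == p1
    while np.any(clash):  # parents of one child must be distinct
        p2[clash] = rng.integers(0, P_in, int(clash.sum()))
        clash = p2 == p1
    psi = rng.uniform(0.0, 2.0 * math.pi, P_out)

    j_eff = _effective_truncation(config.recomb_truncation, K)
    n_grid = _fft.next_fast_len(2 * K + j_eff + 2)
    theta = 2.0 * np.pi * np.arange(n_grid) / n_grid
    odd = np.arange(1, j_eff + 1, 2)
    square_wave = ((2.0 / (np.pi * odd))[None, :] * np.sin(np.outer(theta, odd))).sum(
        axis=1
    )
    m = np.arange(K + 1)
    child = np.empty((P_out, K + 1), dtype=complex)
    for lo in range(0, P_out, _CHUNK):
        hi = min(lo + _CHUNK, P_out)
        f1 = pop.coeffs[p1[lo:hi]]
        f2 = pop.coeffs[p2[lo:hi]]
        ramp = np.exp(1j * np.outer(psi[lo:hi], m))
        twisted = (f1 - f2) * ramp  # still conjugate-symmetric in +-m
        spec = np.zeros((hi - lo, n_grid // 2 + 1), dtype=complex)
        spec[:, : K + 1] = twisted
        profile = _fft.irfft(spec, n_grid, axis=1) * n_grid
        masked = _fft.rfft(profile * square_wave[None, :], axis=1)[:, : K + 1]
        child[lo:hi] = 0.5 * (f1 + f2) + np.conj(ramp) * (masked / n_grid)
    child[:, 0] = child[:, 0].real
    return PopulationState(coeffs=child, generation=pop.generation + 1)


def rotate(pop: PopulationState, delta: float) -> PopulationState:
    """Rotate every chromosome by ``delta``: ``X_k -> e^{-i k delta} X_k``."""
    k = np.arange(pop.mode_cutoff + 1)
    return replace(pop, coeffs=pop.coeffs * np.exp(-1j * k * delta)[None, :])


def estimate_spectrum(pop: PopulationState, num_offdiag: int = 8) -> dict:
    """Empirical per-mode complex variances and diagonality diagnostics.

    Returns ``modes`` (DataFrame ``k, emp_variance, std_err`` with the
    within-population standard error of each variance estimate) and
    ``offdiag`` (magnitudes of a few covariances ``Cov(X_k, X_k')``,
    ``k != k'``, which the rotation-invariance argument predicts to
    vanish).
    """
    if pop.size < 100:
        raise ValueError("spectrum estimation needs at least 100 gametes")
    X = pop.coeffs
    P = pop.size
    centered = X - X.mean(axis=0, keepdims=True)
    sq = np.abs(centered) ** 2
    var = sq.mean(axis=0)
    se = sq.std(axis=0) / math.sqrt(P)
    modes = pd.DataFrame(
        {"k": np.arange(pop.mode_cutoff + 1), "emp_variance": var, "std_err": se}
    )
    pairs = []
    K = pop.mode_cutoff
    for i in range(min(num_offdiag, K)):
        k, kp = i, i + 1
        cov = np.mean(np.conj(centered[:, k]) * centered[:, kp])
        pairs.append((k, kp, abs(cov)))
    offdiag = pd.DataFrame(pairs, columns=["k", "k_prime", "cov_abs"])
    return {"modes": modes, "offdiag": offdiag}


def truncated_reference(
    mode_cutoff: int,
    generations: int,
    j_r: int | None = None,
    full_spectrum: bool = False,
) -> np.ndarray:
    """Deterministic projection of the *truncated* simulator model.

    The simulator stores modes ``|k| <= K`` only, so modes beyond ``K``
    carry no variance (rather than the unit variance of the infinite
    model).  Iterating the selection-reset + odd-offset diffusion
    recursion on exactly that finite mode set gives the reference the
    Monte-Carlo mode-0 variance should be compared against when testing
    the complex-normal projection itself; the gap to the infinite-model
    recursion is a separate, deterministic truncation effect of order
    ``0.2/K`` per generation.

    Returns ``sigma^2_{0,g}`` for ``g = 0 .. generations``, or the full
    per-mode arrays ``sigma^2_{k,g}`` (``k = 0..K``, one row per
    generation) when ``full_spectrum`` is set.
    """
    K = int(mode_cutoff)
    j_eff = _effective_truncation(
        2 * K - 1 if j_r is None else j_r, K
    )
    sigma2 = np.ones(2 * K + 1)  # modes -K..K, center index K
    odd = np.arange(1, j_eff + 1, 2)
    w = 2.0 / (np.pi**2 * odd.astype(float) ** 2)
    rows = [sigma2[K:].copy()]
    for _ in range(generations):
        hat = sigma2.copy()
        hat[K] = 0.0
        new = 0.5 * hat
        for j, wj in zip(odd, w):
            shifted = np.zeros_like(hat)
            shifted[j:] += hat[:-j] if j > 0 else hat
            shifted[:-j] += hat[j:]
            new += wj * shifted
        sigma2 = new
        rows.append(sigma2[K:].copy())
    stacked = np.asarray(rows)
    return stacked if full_spectrum else stacked[:, 0]


def run_cycles(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    record_spectra: bool = True,
) -> dict:
    """Run one seeded replicate of the full selection-mating cycle.

    Returns per-generation trait summaries (``generation, mean_G,
    var_G``; generation 0 is the initial population) and, optionally,
    the empirical mode spectrum of each generation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pop = init_population(config, rng)
    rows = [(0, pop.mean_G, pop.var_G)]
    spectra = []

    def snap(p: PopulationState) -> None:
        if record_spectra:
            frame = estimate_spectrum(p)["modes"].copy()
            frame.insert(0, "generation", p.generation)
            spectra.append(frame)

    snap(pop)
    for _ in range(config.generations):
        selected = select(pop, config.beta, config.selection_window)
        pop = advance_generation(selected, config, rng)
        rows.append((pop.generation, pop.mean_G, pop.var_G))
        snap(pop)
    trajectory = pd.DataFrame(rows, columns=["generation", "mean_G", "var_G"])
    spectrum = (
        pd.concat(spectra, ignore_index=True)
        if spectra
        else pd.DataFrame(columns=["generation", "k", "emp_variance", "std_err"])
    )
    return {"trajectory": trajectory, "spectrum": spectrum, "final": pop}


def simulate_replicates(config: SimConfig) -> dict:
    """Run ``config.replicates`` independent replicates and aggregate.

    Replicate seeds are spawned from ``config.seed`` so replicates are
    independent but the whole ensemble is reproducible.  The aggregated
    spectrum reports the across-replicate mean variance per mode and its
    standard error (within-population standard error when there is a
    single replicate).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    trajs, specs = [], []
    for r, ss in enumerate(seeds):
        out = run_cycles(config, rng=np.random.default_rng(ss))
        t = out["trajectory"].copy()
        t.insert(0, "replicate", r)
        trajs.append(t)
        s = out["spectrum"].copy()
        s.insert(0, "replicate", r)
        specs.append(s)
    trajectory = pd.concat(trajs, ignore_index=True)
    spectrum_all = pd.concat(specs, ignore_index=True)
    grouped = spectrum_all.groupby(["generation", "k"])["emp_variance"]
    if config.replicates >= 2:
        agg = grouped.agg(["mean", "sem"]).reset_index()
        agg.columns = ["generation", "k", "emp_variance", "std_err"]
    else:
        agg = spectrum_all[["generation", "k", "emp_variance", "std_err"]].copy()
    return {
        "trajectory": trajectory,
        "spectrum": agg,
        "per_replicate_spectrum": spectrum_all,
    }
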