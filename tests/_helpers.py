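"""Shared test utilities: random gametes and the grid-masking oracle."""

import math

import numpy as np

from linkinf import gametes as gm


def random_gamete(rng, K):
    c = np.empty(K + 1, dtype=complex)
    c[0] = rng.normal()
    c[1:] = (rng.normal(size=K) + 1j * rng.normal(size=K)) * math.sqrt(0.5)
    return gm.GameteSpectrum(c)


def grid_masking_oracle(p1, p2, psi, n_grid=1 << 16):
    """Independent construction of the recombined gamete: evaluate both
    parental profiles on a fine theta grid, mask with the two sharp
    half-circle indicator functions at psi (snapped to the grid; the jump
    nodes take the half-value, which restores the trapezoidal rule's
    second-order accuracy for piecewise-smooth integrands), and transform
    back.  Returns the child's coefficients and the snapped psi."""
    K = p1.mode_cutoff
    i0 = int(round(psi / (2 * np.pi) * n_grid)) % n_grid
    psi_snapped = 2 * np.pi * i0 / n_grid
    theta = 2 * np.pi * np.arange(n_grid) / n_grid
    ks = np.arange(-K, K + 1)

    def profile(p):
        full = gm._full_modes(p.coeffs)
        return (full[None, :] * np.exp(1j * np.outer(theta, ks))).sum(axis=1)

    mask = np.zeros(n_grid)
    idx = (np.arange(n_grid) - i0) % n_grid
    mask[idx < n_grid // 2] = 1.0
    mask[idx == 0] = 0.5
    mask[idx == n_grid // 2] = 0.5
    y = profile(p1) * mask + profile(p2) * (1.0 - mask)
    coeffs = np.fft.fft(y)[: K + 1] / n_grid
    return coeffs, psi_snapped
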