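"""Unit and property tests for the deterministic variance recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkinf import spectral_core as sc


# --- kernel -----------------------------------------------------------------


class TestKernel:
    def test_rejects_nonpositive_half_width(self):
        with pytest.raises(ValueError):
            sc.build_kernel(0)

    @pytest.mark.parametrize("half_width", [1, 2, 3, 17, 256, 10_001])
    def test_mass_normalisation(self, half_width):
        """Retention + both-sign transfer + residual must total exactly 1."""
        k = sc.build_kernel(half_width)
        assert k.retention == 0.5
        assert abs(k.total_mass() - 1.0) < 1e-12

    def test_transfer_weights_closed_form(self):
        k = sc.build_kernel(9)
        for j, w in k.transfer_weights.items():
            assert j % 2 == 1
            assert w == pytest.approx(2.0 / (math.pi**2 * j**2), abs=1e-16)
        assert k.transfer_weights[1] == pytest.approx(2.0 / math.pi**2, rel=1e-15)

    def test_residual_against_brute_force_sum(self):
        """Closed-form residual == direct summation of 4/(pi^2 j^2) tails."""
        j = np.arange(3, 20_000_001, 2, dtype=float)
        brute = float(np.sum(4.0 / (math.pi**2 * j**2)))
        # j > 2e7 contributes < 1e-7 -> integral bound closes the sum
        brute += 4.0 / (math.pi**2) * 0.5 / j[-1]
        k = sc.build_kernel(1)
        assert k.residual_mass == pytest.approx(0.5 - 4.0 / math.pi**2, abs=1e-12)
        assert k.residual_mass == pytest.approx(brute, abs=1e-9)

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mass_normalisation_property(self, half_width):
        assert abs(sc.build_kernel(half_width).total_mass() - 1.0) < 1e-12


# --- selection reset --------------------------------------------------------


class TestSelectionReset:
    def test_initial_state_reset(self):
        state = sc.VarianceSpectrum.initial(32)
        reset, injected = sc.selection_reset(state)
        assert injected == 1.0  # full unit of matter enters at g=0
        assert reset.deficit[0] == 1.0
        assert np.all(reset.deficit[1:] == 0.0)

    def test_idempotent(self):
        state = sc.VarianceSpectrum(deficit=np.linspace(0.9, 0.0, 20))
        once, _ = sc.selection_reset(state)
        twice, injected2 = sc.selection_reset(once)
        np.testing.assert_array_equal(once.deficit, twice.deficit)
        assert injected2 == 0.0  # nothing left to inject


# --- convolution oracle equivalence ----------------------------------------


class TestConvolutions:
    def test_delta_deficit_single_offset_kernel(self):
        """A J=1 kernel moves a lone spike: half stays, 2/pi^2 to each side."""
        deficit = np.zeros(11)
        deficit[5] = 1.0
        out = sc.convolve_direct(deficit, sc.build_kernel(1))
        w = 2.0 / math.pi**2
        assert out[5] == pytest.approx(0.5)
        assert out[4] == pytest.approx(w)
        assert out[6] == pytest.approx(w)
        assert np.all(out[[0, 1, 2, 3, 7, 8, 9, 10]] == 0.0)

    def test_zero_in_zero_out(self):
        out = sc.convolve_fft(np.zeros(33), sc.build_kernel(64))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x = rng.random(65)
        k = sc.build_kernel(33)
        np.testing.assert_allclose(
            sc.convolve_fft(3.5 * x, k), 3.5 * sc.convolve_fft(x, k), atol=1e-12
        )

    @pytest.mark.parametrize("n,j", [(16, 5), (64, 63), (256, 255), (512, 301)])
    def test_fft_matches_direct_on_random_states(self, n, j):
        rng = np.random.default_rng(n + j)
        deficit = rng.random(n + 1)
        tail = rng.random(n // 4) * 1e-3
        kernel = sc.build_kernel(j)
        direct = sc.convolve_direct(deficit, kernel, tail)
        fft = sc.convolve_fft(deficit, kernel, tail)
        np.testing.assert_allclose(fft, direct, atol=1e-12)

    def test_insufficient_padding_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            sc.convolve_fft(np.zeros(65), sc.build_kernel(64), pad=32)

    def test_mirroring_reaches_negative_modes(self):
        """A stored spike at k=1 is physically a pair at +-1; mode 0 then
        collects weight from both signs, mode 2 from k=1 and the k=-1 mirror."""
        deficit = np.zeros(9)
        deficit[1] = 1.0
        out = sc.convolve_direct(deficit, sc.build_kernel(3))
        w1 = 2.0 / math.pi**2
        w3 = 2.0 / (math.pi**2 * 9)
        assert out[0] == pytest.approx(2 * w1)
        assert out[1] == pytest.approx(0.5)  # retention only
        assert out[2] == pytest.approx(w1 + w3)
        assert out[4] == pytest.approx(w3)


# --- diffusion closed forms -------------------------------------------------


class TestDiffusionClosedForms:
    def test_first_generation(self):
        """From linkage equilibrium one cycle releases exactly half:
        sigma2_0 = 1/2, odd modes 1 - 2/(pi^2 k^2), even modes untouched."""
        state = sc.VarianceSpectrum.initial(4096)
        reset, _ = sc.selection_reset(state)
        new = sc.diffuse(reset, sc.build_kernel(4096), method="fft", extent=0)
        sigma2 = new.sigma2
        assert sigma2[0] == pytest.approx(0.5, abs=1e-12)
        odd = np.arange(1, 4096, 2)
        np.testing.assert_allclose(
            sigma2[odd], 1.0 - 2.0 / (math.pi**2 * odd**2), atol=1e-9
        )
        even = np.arange(2, 4096, 2)
        np.testing.assert_allclose(sigma2[even], 1.0, atol=1e-12)

    def test_second_generation_hand_composed(self):
        """Two cycles: sigma2_{0,2} = 1 - (1/2 + 8/pi^4 * sum 1/j^4) = 5/12."""
        params = sc.ModelParams(cutoff=2048, generations=2, tail_extent=2048)
        traj = sc.iterate(params)
        assert traj.frame.sigma2_0.iloc[0] == pytest.approx(0.5, abs=1e-9)
        assert traj.frame.sigma2_0.iloc[1] == pytest.approx(5.0 / 12.0, abs=1e-9)

    def test_diffuse_requires_reset_state(self):
        state = sc.VarianceSpectrum.initial(32)
        with pytest.raises(ValueError, match="reset"):
            sc.diffuse(state, sc.build_kernel(8))

    def test_beta_does_not_affect_spectrum(self):
        t0 = sc.iterate(sc.ModelParams(cutoff=64, generations=8, beta=0.0))
        t2 = sc.iterate(sc.ModelParams(cutoff=64, generations=8, beta=2.0))
        np.testing.assert_array_equal(t0.frame.sigma2_0, t2.frame.sigma2_0)
        assert np.all(t0.frame.mu == 0.0)

    def test_mean_recursion_rules(self):
        """mu_1 = beta under std_dev (sigma_0 = 1 at g=0) for either rule."""
        ts = sc.iterate(sc.ModelParams(cutoff=64, generations=2, beta=1.0))
        assert ts.frame.mu.iloc[0] == pytest.approx(1.0)
        # second step adds beta*sigma = sqrt(1/2) under std_dev
        assert ts.frame.mu.iloc[1] == pytest.approx(1.0 + math.sqrt(0.5), abs=1e-9)
        tv = sc.iterate(
            sc.ModelParams(cutoff=64, generations=2, beta=1.0, gain_rule="variance")
        )
        assert tv.frame.mu.iloc[1] == pytest.approx(1.5, abs=1e-9)


# --- tail closure -----------------------------------------------------------


class TestTailClosure:
    def test_exact_power_law_recovered(self):
        k = np.arange(1, 129, dtype=float)
        state = sc.VarianceSpectrum(deficit=np.concatenate([[1.0], k**-2.0])[:129])
        ext = sc.tail_closure(state, 32)
        expect = np.arange(129, 161, dtype=float) ** -2.0
        np.testing.assert_allclose(ext, expect, rtol=1e-10)

    def test_empty_spectrum_zero_extension(self):
        state = sc.VarianceSpectrum.initial(64)
        assert np.all(sc.tail_closure(state, 16) == 0.0)

    def test_exponent_clamped(self):
        k = np.arange(1, 65, dtype=float)
        state = sc.VarianceSpectrum(deficit=np.concatenate([[1.0], k**-8.0])[:65])
        _, p = sc.fit_tail(state)
        assert p == 4.0

    def test_late_state_consistent_with_larger_cutoff(self):
        """Tail extension of an evolved spectrum tracks the spectrum a run
        with doubled cutoff actually develops there (within 10%)."""
        small = sc.iterate(sc.ModelParams(cutoff=256, generations=32))
        big = sc.iterate(sc.ModelParams(cutoff=512, generations=32))
        state = sc.VarianceSpectrum(
            deficit=small.snapshots[32], generation=32
        )
        ext = sc.tail_closure(state, 64)
        truth = big.snapshots[32][257 : 257 + 64]
        np.testing.assert_allclose(ext, truth, rtol=0.10)


# --- iteration-level properties ---------------------------------------------


@pytest.fixture(scope="module")
def medium_run():
    return sc.iterate(sc.ModelParams(cutoff=2048, generations=512))


class TestIterate:
    def test_single_generation_trajectory(self):
        traj = sc.iterate(sc.ModelParams(cutoff=1024, generations=1))
        row = traj.frame.iloc[0]
        assert row.generation == 1
        assert row.sigma2_0 == pytest.approx(0.5, abs=1e-12)
        assert row.injected_mass == 1.0

    def test_bounds_and_monotone_decay(self, medium_run):
        s2 = medium_run.frame.sigma2_0.to_numpy()
        assert np.all((s2 >= 0.0) & (s2 <= 1.0))
        assert np.all(np.diff(s2[1:]) < 0.0)  # strictly decreasing for g >= 2

    def test_no_plateau_halving(self, medium_run):
        """sigma2_{0,2g} < sigma2_{0,g}: the decay never stalls."""
        f = medium_run.frame.set_index("generation").sigma2_0
        g = np.arange(8, 257)
        assert np.all(f.loc[2 * g].to_numpy() < f.loc[g].to_numpy())

    def test_sigma_column_consistent(self, medium_run):
        np.testing.assert_allclose(
            medium_run.frame.sigma_0**2, medium_run.frame.sigma2_0, atol=1e-15
        )

    def test_snapshots_at_powers_of_two(self, medium_run):
        assert set(medium_run.snapshots) == {1, 2, 4, 8, 16, 32, 64, 128, 256, 512}

    def test_deterministic_csv_bytes(self, tmp_path):
        params = sc.ModelParams(cutoff=128, generations=16)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        sc.iterate(params).to_csv(p1)
        sc.iterate(params).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_warns_beyond_validity(self):
        with pytest.warns(UserWarning, match="truncation"):
            sc.iterate(sc.ModelParams(cutoff=8, generations=16))

    def test_cutoff_doubling_consistency(self, medium_run):
        """N and 2N runs agree on sigma2_{0,g} within 1% for g <= N/8."""
        small = sc.iterate(sc.ModelParams(cutoff=1024, generations=128))
        f_small = small.frame.set_index("generation").sigma2_0
        f_big = medium_run.frame.set_index("generation").sigma2_0
        g = np.arange(1, 129)
        rel = np.abs(f_big.loc[g].to_numpy() / f_small.loc[g].to_numpy() - 1.0)
        assert rel.max() < 0.01

    def test_matches_exact_return_mass_oracle(self):
        """Independent oracle: by linearity of the deficit recursion,
        c_{0,g} = sum_{g1<=g} inj(g1) R(g-g1+1) with the exact return
        mass R_t = (1/pi) int_0^pi (1-q/pi)^t dq = 1/(t+1) of the
        infinite lattice (the kernel charfn is the tent 1-|q|/pi)."""
        G = 64
        R = 1.0 / (np.arange(G + 2) + 1.0)
        inj = np.zeros(G + 1)
        c0 = np.zeros(G + 1)
        for g in range(1, G + 1):
            inj[g] = 1.0 - c0[g - 1]
            c0[g] = float(np.dot(inj[1 : g + 1], R[g:0:-1]))
        traj = sc.iterate(sc.ModelParams(cutoff=2048, generations=G))
        np.testing.assert_allclose(
            traj.frame.sigma2_0.to_numpy(), (1.0 - c0)[1:], atol=1e-7
        )


class TestMatterBalance:
    def test_diffusion_conserves_matter(self):
        """Injected matter = stored change + boundary leak + kernel residual."""
        params = sc.ModelParams(cutoff=4096, generations=8, kernel_half_width=4096,
                                tail_extent=0)
        kernel = sc.build_kernel(4096)
        state = sc.VarianceSpectrum.initial(4096)
        for _ in range(8):
            reset, injected = sc.selection_reset(state)
            bal = sc.matter_balance(reset, kernel, extent=0)
            new = sc.diffuse(reset, kernel, extent=0)
            delta_stored = new.total_deficit() - state.total_deficit()
            assert injected == pytest.approx(
                delta_stored + bal["leaked"] + bal["residual_loss"], abs=1e-10
            )
            state = new

    def test_full_convolution_mass_exact(self):
        rng = np.random.default_rng(3)
        state = sc.VarianceSpectrum(deficit=rng.random(257) * 0.5)
        state.deficit[0] = 1.0
        kernel = sc.build_kernel(256)
        bal = sc.matter_balance(state, kernel, extent=0)
        # leak + stored output reproduces (1-residual) * input mass
        assert bal["stored_out"] + bal["leaked"] == pytest.approx(
            (1.0 - kernel.residual_mass) * bal["stored_in"], abs=1e-12
        )
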