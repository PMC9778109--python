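import numpy as np
import pytest

from etpath import (
    UmbrellaWindow,
    binding_depth,
    gen_umbrella_windows,
    solve_wham,
)
from etpath.constants import KB_KCAL

from conftest import double_well

KT = KB_KCAL * 298.15


def exact_biased_samples(u, center, spring_k, n, rng, lo, hi):
    """Independent exact sampler: inverse-CDF draws from
    exp(-(U + bias)/kT) on a fine grid (no Metropolis chain)."""
    xs = np.linspace(lo, hi, 20_001)
    logp = -(u(xs) + 0.5 * spring_k * (xs - center) ** 2) / KT
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, xs)


class TestSolveWham:
    def test_single_nearly_unbiased_window_inverts_histogram(self):
        """With a negligible spring the PMF is just -kT ln(histogram)."""
        rng = np.random.default_rng(1)

        def u(x):
            return 2.0 * (np.asarray(x) - 5.0) ** 2

        samples = exact_biased_samples(u, 5.0, 1e-9, 200_000, rng, 3.0, 7.0)
        w = UmbrellaWindow(center=5.0, spring_k=1e-9, samples=samples)
        pmf = solve_wham([w], bin_size=0.1)
        keep = pmf.free_energy < 3.0  # well-populated bins only
        ref = u(pmf.bin_centers[keep])
        ref -= ref.min()
        assert np.abs(pmf.free_energy[keep] - ref).max() < 0.15

    def test_flat_landscape_gives_flat_pmf(self):
        rng = np.random.default_rng(2)
        flat = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        windows = [
            UmbrellaWindow(
                center=c,
                spring_k=14.0,
                samples=exact_biased_samples(flat, c, 14.0, 30_000, rng, 0.0, 6.0),
            )
            for c in (2.0, 2.7, 3.4, 4.1)
        ]
        pmf = solve_wham(windows, bin_size=0.2)
        core = (pmf.bin_centers > 1.6) & (pmf.bin_centers < 4.5)
        assert pmf.converged
        core_f = pmf.free_energy[core]
        assert core_f.max() - core_f.min() < 0.25

    def test_double_well_depth_recovery(self):
        """Harmonic-bias protocol (15 windows, 0.7 A spacing, k = 14)
        recovers a known 10 kcal/mol well depth within 0.5."""
        centers = 2.3 + 0.7 * np.arange(15)
        windows = gen_umbrella_windows(
            double_well, centers, spring_k=14.0, n_per_window=10_000, seed=3
        )
        pmf = solve_wham(windows, bin_size=0.2)
        assert pmf.converged
        depth = binding_depth(pmf, (2.0, 4.5), (10.5, 12.0))
        assert depth == pytest.approx(10.0, abs=0.5)

    def test_pmf_shape_invariant_to_bin_halving(self):
        centers = 2.3 + 0.7 * np.arange(15)
        windows = gen_umbrella_windows(
            double_well, centers, spring_k=14.0, n_per_window=10_000, seed=3
        )
        d1 = binding_depth(solve_wham(windows, bin_size=0.2), (2.0, 4.5), (10.5, 12.0))
        d2 = binding_depth(solve_wham(windows, bin_size=0.1), (2.0, 4.5), (10.5, 12.0))
        assert d1 == pytest.approx(d2, abs=0.4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        flat = lambda x: 0.5 * np.asarray(x, dtype=float)
        windows = [
            UmbrellaWindow(
                center=c,
                spring_k=14.0,
                samples=exact_biased_samples(flat, c, 14.0, 20_000, rng, 0.0, 6.0),
            )
            for c in (2.0, 2.7, 3.4)
        ]
        pmf_a = solve_wham(windows, bin_size=0.2)
        shifted = [
            UmbrellaWindow(center=w.center + 10.0, spring_k=w.spring_k,
                           samples=w.samples + 10.0)
            for w in windows
        ]
        pmf_b = solve_wham(shifted, bin_size=0.2)
        assert np.allclose(pmf_b.bin_centers - 10.0, pmf_a.bin_centers)
        assert np.allclose(pmf_b.free_energy, pmf_a.free_energy, atol=1e-6)

    def test_rms_recovery_over_sampled_range(self):
        """Recovered PMF deviates < 0.5 kcal/mol RMS from the true
        profile over the well-sampled range."""
        centers = 2.3 + 0.7 * np.arange(15)
        windows = gen_umbrella_windows(
            double_well, centers, spring_k=14.0, n_per_window=10_000, seed=5
        )
        pmf = solve_wham(windows, bin_size=0.2)
        core = (pmf.bin_centers > 2.3) & (pmf.bin_centers < 11.5)
        truth = double_well(pmf.bin_centers[core])
        est = pmf.free_energy[core]
        # both min-anchored over the compared range
        resid = (est - est.min()) - (truth - truth.min())
        resid -= resid.mean()
        assert np.sqrt((resid**2).mean()) < 0.5

    def test_wham_matches_independent_mbar(self):
        """Binless MBAR fixed point, written here from scratch, agrees
        with the histogram WHAM solution on the shared bins."""
        centers = np.array([2.0, 2.7, 3.4, 4.1, 4.8])

        def u(x):
            x = np.asarray(x, dtype=float)
            return -3.0 * np.exp(-((x - 3.2) ** 2) / 0.6)

        windows = gen_umbrella_windows(
            u, centers, spring_k=14.0, n_per_window=4_000, seed=11
        )
        pmf = solve_wham(windows, bin_size=0.2)

        # --- independent MBAR ---
        xs = np.concatenate([w.production_samples() for w in windows])
        n_k = np.array([w.production_samples().size for w in windows])
        bias = np.stack([0.5 * 14.0 * (xs - c) ** 2 for c in centers])  # (K, N)
        f = np.zeros(len(centers))
        for _ in range(3_000):
            log_denom = np.logaddexp.reduce(
                np.log(n_k)[:, None] + f[:, None] - bias / KT, axis=0
            )
            f_new = -np.array(
                [np.logaddexp.reduce(-bias[k] / KT - log_denom) for k in range(len(centers))]
            )
            f_new -= f_new[0]
            if np.abs(f_new - f).max() < 1e-8:
                f = f_new
                break
            f = f_new
        log_w = -np.logaddexp.reduce(
            np.log(n_k)[:, None] + f[:, None] - bias / KT, axis=0
        )
        w_n = np.exp(log_w - log_w.max())
        # same global bin grid that the histogram solver uses
        lo = np.floor(xs.min() / 0.2) * 0.2
        hi = np.ceil(xs.max() / 0.2) * 0.2
        edges = np.arange(lo, hi + 0.1, 0.2)
        hist, _ = np.histogram(xs, bins=edges, weights=w_n)
        cbin = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        g_mbar = -KT * np.log(hist[keep])
        g_mbar -= g_mbar.min()

        common = np.intersect1d(
            np.round(pmf.bin_centers, 3), np.round(cbin[keep], 3)
        )
        assert common.size >= 10
        wham_map = dict(zip(np.round(pmf.bin_centers, 3), pmf.free_energy))
        mbar_map = dict(zip(np.round(cbin[keep], 3), g_mbar))
        # well-sampled interior only: boundary bins are noise-dominated
        pop = [
            c for c in common
            if wham_map[c] < 4.0 and centers.min() <= c <= centers.max()
        ]
        assert len(pop) >= 8
        diffs = np.array([wham_map[c] - mbar_map[c] for c in pop])
        assert np.abs(diffs - diffs.mean()).max() < 0.3

    def test_non_overlapping_windows_error_names_gap(self):
        rng = np.random.default_rng(4)
        flat = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        w1 = UmbrellaWindow(2.0, 14.0, exact_biased_samples(flat, 2.0, 14.0, 5_000, rng, 0.0, 10.0))
        w2 = UmbrellaWindow(8.0, 14.0, exact_biased_samples(flat, 8.0, 14.0, 5_000, rng, 0.0, 10.0))
        with pytest.raises(ValueError, match="overlap"):
            solve_wham([w1, w2], bin_size=0.2)

    def test_non_convergence_reported_honestly(self):
        centers = np.array([2.0, 2.7, 3.4])
        windows = gen_umbrella_windows(
            double_well, centers, spring_k=14.0, n_per_window=2_000, seed=9
        )
        pmf = solve_wham(windows, bin_size=0.2, tol=1e-12, max_iter=3)
        assert not pmf.converged and pmf.n_iterations == 3


class TestBindingDepth:
    def make_pmf(self, values, centers=None):
        from etpath.wham import PMFResult

        values = np.asarray(values, dtype=float)
        if centers is None:
            centers = np.arange(len(values), dtype=float)
        return PMFResult(
            bin_centers=np.asarray(centers, dtype=float),
            free_energy=values - values.min(),
            window_offsets=np.zeros(1),
            converged=True,
            n_iterations=1,
            gaps=[],
        )

    def test_flat_pmf_zero_depth(self):
        pmf = self.make_pmf(np.zeros(10))
        assert binding_depth(pmf, (0.0, 4.0), (6.0, 9.0)) == 0.0

    def test_constructed_plateau(self):
        vals = np.concatenate([np.zeros(5), np.full(5, 5.0)])
        pmf = self.make_pmf(vals)
        assert binding_depth(pmf, (0.0, 4.0), (5.0, 9.0)) == pytest.approx(5.0)

    def test_region_outside_support_raises(self):
        pmf = self.make_pmf(np.zeros(10))
        with pytest.raises(ValueError, match="outside"):
            binding_depth(pmf, (0.0, 4.0), (20.0, 25.0))


class TestWindowValidation:
    def test_spring_must_be_positive(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, spring_k=0.0, samples=np.ones(10))

    def test_discard_prefix_applies(self):
        w = UmbrellaWindow(center=1.0, spring_k=1.0, samples=np.arange(10.0),
                           discarded_prefix=4)
        assert w.production_samples().tolist() == [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, spring_k=1.0, samples=np.arange(3.0),
                           discarded_prefix=3)
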