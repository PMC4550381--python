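"""Brownian dynamics, pulling, umbrella windows and WHAM."""

import numpy as np
import pytest

from photogate.sampling import (DEFAULT_K_BIAS, Potential1D, UmbrellaWindow,
                                brownian_1d, convergence_report,
                                histogram_overlap, pmf_extrema, pull,
                                pull_duration_ps, run_windows, wham)
from photogate.synthetic_data import make_surface
from photogate.units import KB_KJ_PER_MOL_K as KB, kcal_to_kj

KT = KB * 300.0


def harmonic(k=200.0, a=1.0):
    return Potential1D(lambda x: 0.5 * k * (np.asarray(x) - a) ** 2,
                       lambda x: k * (np.asarray(x) - a), "harmonic",
                       {"k": k, "a": a})


def test_unit_round_trip_of_bias_constant():
    assert kcal_to_kj(500.0) == pytest.approx(2092.0, rel=1e-4)
    assert DEFAULT_K_BIAS == pytest.approx(2092.0, rel=1e-4)


# ---------------------------------------------------------------------------
# Brownian integrator
# ---------------------------------------------------------------------------

def test_brownian_harmonic_equilibrium_variance():
    k = 200.0
    xs = brownian_1d(harmonic(k), 1.0, 2e-4, 150_000, seed=1)
    assert np.var(xs[10_000:]) == pytest.approx(KT / k, rel=0.05)


def test_brownian_zero_temperature_stays_at_minimum():
    xs = brownian_1d(harmonic(), 1.0, 5e-4, 1000, temperature=0.0, seed=0)
    np.testing.assert_allclose(xs, 1.0, atol=1e-12)


def test_brownian_is_seed_reproducible():
    a = brownian_1d(harmonic(), 1.0, 5e-4, 500, seed=3)
    b = brownian_1d(harmonic(), 1.0, 5e-4, 500, seed=3)
    c = brownian_1d(harmonic(), 1.0, 5e-4, 500, seed=4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_brownian_divergence_raises():
    steep = Potential1D(lambda x: -1e6 * np.asarray(x) ** 2,
                        lambda x: -2e6 * np.asarray(x), "inverted")
    with pytest.raises(RuntimeError, match="diverged"):
        brownian_1d(steep, 0.1, 5e-4, 2000, seed=0)


def test_double_well_basin_occupancy_matches_boltzmann():
    """Occupancy ratio of an asymmetric double well's basins must match the
    Boltzmann weights from numeric quadrature."""
    pot = make_surface("custom", m1=0.8, m2=1.2, barrier_kcal=1.0)
    tilted = Potential1D(lambda x: pot(x) + 8.0 * (np.asarray(x) - 0.8),
                         lambda x: -pot.force(x) + 8.0, "tilted")
    xs = brownian_1d(tilted, 0.8, 5e-4, 300_000, seed=6)
    xs = xs[30_000:]
    split = 1.0
    got = np.mean(xs < split) / np.mean(xs >= split)
    grid_l = np.linspace(0.4, split, 2001)
    grid_r = np.linspace(split, 1.6, 2001)
    wl = np.trapezoid(np.exp(-tilted(grid_l) / KT), grid_l)
    wr = np.trapezoid(np.exp(-tilted(grid_r) / KT), grid_r)
    assert got == pytest.approx(wl / wr, rel=0.25)


# ---------------------------------------------------------------------------
# pulling
# ---------------------------------------------------------------------------

def test_pull_duration_at_production_rate():
    # 0.5 -> 1.4 nm at 1e-5 nm/ps takes 9e4 ps
    assert pull_duration_ps(0.5, 1.4, 1e-5) == pytest.approx(9.0e4)


def test_pull_snapshots_track_restraint_centers():
    pot = make_surface("trans_like")
    centers = np.linspace(0.5, 1.4, 19)
    snaps = pull(pot, 0.5, 1.4, centers, rate_nm_per_ps=5e-3, seed=2)
    assert snaps.shape == (19,)
    assert np.all(np.isfinite(snaps))
    # monotone in the window centers up to the restraint width
    width = 3.0 * np.sqrt(KT / DEFAULT_K_BIAS)
    assert np.all(np.diff(snaps) > -4 * width)
    assert np.max(np.abs(snaps - centers)) < 10 * width


def test_pull_high_stiffness_keeps_walker_at_center():
    flat = Potential1D(lambda x: np.zeros_like(np.asarray(x, float)),
                       lambda x: np.zeros_like(np.asarray(x, float)), "flat")
    k_pull = 20_000.0
    centers = np.linspace(0.6, 1.2, 7)
    snaps = pull(flat, 0.5, 1.3, centers, rate_nm_per_ps=5e-3,
                 k_pull=k_pull, dt_ps=5e-5, seed=4)
    width = np.sqrt(KT / k_pull)
    assert np.max(np.abs(snaps - centers)) < 5 * width


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def test_run_windows_default_ladder_spacing_and_overlap():
    pot = make_surface("trans_like")
    centers = np.linspace(0.5, 1.4, 19)
    np.testing.assert_allclose(np.diff(centers), 0.05)
    windows = run_windows(pot, centers, n_steps=4000, seed=1)
    assert len(windows) == 19
    ov = histogram_overlap(windows)
    assert np.all(np.diag(ov, k=1) > 0)


def test_window_means_shift_down_the_potential_gradient():
    pot = make_surface("trans_like")
    centers = np.linspace(0.5, 1.4, 19)
    windows = run_windows(pot, centers, n_steps=20_000, seed=2)
    for w in windows:
        # the biased mean sits near the minimizer of U(x) + bias, displaced
        # from the center in the direction of the unbiased force
        grid = np.linspace(w.center - 0.3, w.center + 0.3, 6001)
        biased = pot(grid) + 0.5 * w.k_bias * (grid - w.center) ** 2
        x_min = grid[np.argmin(biased)]
        got = float(np.mean(w.samples))
        assert got == pytest.approx(x_min, abs=0.012)
        force = float(pot.force(w.center))
        if abs(force) > 20.0:  # kJ/mol/nm, beyond noise
            assert np.sign(got - w.center) == np.sign(force)


def test_histogram_overlap_identity_far_and_hand_formula(rng):
    a = UmbrellaWindow(0.0, 1.0, rng.normal(0.0, 0.05, 4000))
    b = UmbrellaWindow(2.0, 1.0, rng.normal(2.0, 0.05, 4000))
    ov = histogram_overlap([a, a, b], n_bins=60)
    assert ov[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert ov[0, 2] == pytest.approx(0.0, abs=1e-9)
    # hand computation of the Bhattacharyya sum on the same common bins
    lo = min(a.samples.min(), b.samples.min())
    hi = max(a.samples.max(), b.samples.max())
    pad = 1e-9 * max(1.0, abs(hi))
    edges = np.linspace(lo - pad, hi + pad, 61)
    pa = np.histogram(a.samples, bins=edges)[0] / a.samples.size
    pb = np.histogram(b.samples, bins=edges)[0] / b.samples.size
    assert ov[0, 2] == pytest.approx(np.sum(np.sqrt(pa * pb)), abs=1e-12)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def test_wham_flat_potential_single_window_is_flat(rng):
    flat_samples = rng.uniform(0.0, 1.0, 200_000)
    w = UmbrellaWindow(0.5, 1e-9, flat_samples)
    prof = wham([w], n_bins=20, x_range=(0.0, 1.0))
    spread = np.nanmax(prof.free_energy) - np.nanmin(prof.free_energy)
    assert spread < 0.05  # kcal/mol, binomial noise only


def test_wham_harmonic_matches_analytic_profile():
    pot = harmonic(200.0, 1.0)
    centers = np.linspace(0.7, 1.3, 13)
    windows = run_windows(pot, centers, n_steps=60_000, seed=7)
    prof = wham(windows, n_bins=60, x_range=(0.7, 1.3))
    xs = prof.bin_centers[prof.valid]
    got = prof.free_energy[prof.valid]
    ana = (0.5 * 200.0 * (xs - 1.0) ** 2) / 4.184
    ana -= ana.min()
    assert np.max(np.abs(got - ana)) < 0.1  # kcal/mol


def test_wham_matches_boltzmann_inversion_oracle():
    """Windowed WHAM on the trans-like well must agree with direct
    Boltzmann inversion of one long unbiased run."""
    pot = make_surface("trans_like")
    long_run = brownian_1d(pot, 0.76, 2e-4, 2_000_000, seed=42)
    edges = np.linspace(0.55, 1.35, 81)
    counts, _ = np.histogram(long_run, bins=edges)
    dens, _ = np.histogram(long_run, bins=edges, density=True)
    f_inv = np.where(dens > 0, -KT * np.log(np.where(dens > 0, dens, 1.0)), np.nan)
    f_inv -= np.nanmin(f_inv)
    windows = run_windows(pot, np.linspace(0.5, 1.4, 19), n_steps=120_000,
                          dt_ps=2e-4, seed=4)
    prof = wham(windows, n_bins=80, x_range=(0.55, 1.35))
    # compare only where the unbiased oracle itself is statistically solid
    well_sampled = (counts >= 1000) & prof.valid
    dev = np.abs(prof.free_energy[well_sampled] * 4.184 - f_inv[well_sampled])
    assert np.max(dev) / 4.184 < 0.2  # kcal/mol


def test_wham_invariant_to_constant_energy_shift():
    pot = make_surface("trans_like")
    shifted = Potential1D(lambda x: pot(x) + 123.0, lambda x: -pot.force(x),
                          "shifted")
    centers = np.linspace(0.5, 1.4, 19)
    w1 = run_windows(pot, centers, n_steps=8000, seed=3)
    w2 = run_windows(shifted, centers, n_steps=8000, seed=3)
    p1 = wham(w1, x_range=(0.5, 1.4))
    p2 = wham(w2, x_range=(0.5, 1.4))
    both = p1.valid & p2.valid
    np.testing.assert_allclose(p1.free_energy[both], p2.free_energy[both],
                               atol=1e-6)


def test_wham_min_is_zero_and_empty_bins_masked():
    pot = make_surface("cis_like")
    windows = run_windows(pot, np.linspace(0.5, 1.4, 21), n_steps=6000, seed=9)
    prof = wham(windows, x_range=(0.3, 1.6))  # deliberately wider than sampled
    assert np.nanmin(prof.free_energy) == pytest.approx(0.0, abs=1e-12)
    assert np.any(~prof.valid)  # unsampled bins are masked, not infinite


def test_wham_non_overlapping_windows_error_names_gap(rng):
    a = UmbrellaWindow(0.5, 2092.0, rng.normal(0.5, 0.02, 2000))
    b = UmbrellaWindow(1.4, 2092.0, rng.normal(1.4, 0.02, 2000))
    with pytest.raises(ValueError, match="0.5.*1.4"):
        wham([a, b])


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def test_convergence_identical_data_gives_zero_deviation():
    pot = make_surface("trans_like")
    windows = run_windows(pot, np.linspace(0.5, 1.4, 19), n_steps=4000, seed=5)
    n = windows[0].samples.size
    rep = convergence_report(windows, fractions=((n - 0.5) / n, 1.0))
    assert rep.deviations[0] == pytest.approx(0.0, abs=1e-12)


def test_convergence_deviation_small_on_well_sampled_data():
    pot = make_surface("trans_like")
    windows = run_windows(pot, np.linspace(0.5, 1.4, 19), n_steps=40_000, seed=4)
    rep = convergence_report(windows, fractions=(0.5, 1.0))
    assert rep.max_deviation < 0.2  # kcal/mol over the basin region


def test_pmf_extrema_on_analytic_double_well():
    spec_pot = make_surface("trans_like")
    x = np.linspace(0.55, 1.35, 161)
    from photogate.sampling import PMFProfile
    prof = PMFProfile(x, spec_pot(x) / 4.184, 300.0)
    m1, m2, barrier = pmf_extrema(prof)
    assert m1 == pytest.approx(0.76, abs=0.005)
    assert m2 == pytest.approx(1.20, abs=0.005)
    assert barrier == pytest.approx(1.5, abs=0.02)
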