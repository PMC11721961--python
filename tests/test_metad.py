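"""Unit tests for the model potentials, sampler, and metadynamics."""

import math

import numpy as np
import pytest

from allokin import metad
from allokin._errors import InvalidParameterError, ParseError
from allokin.constants import R_KJ


# ---------------------------------------------------------------------------
# Model potential construction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sep,bar,asym",
    [(4, 20, 0), (4, 20, 5), (4, 5, 0), (4, 5, 2), (3, 10, 3), (6, 30, 10)],
)
def test_double_well_critical_energies_exact(sep, bar, asym):
    pot = metad.make_double_well(sep, bar, asym)
    energies = sorted(e for _, e in pot.minima)
    assert energies[0] == pytest.approx(0.0, abs=1e-8)
    assert energies[1] == pytest.approx(asym, abs=1e-8)
    assert pot.saddles[0][1] == pytest.approx(bar, abs=1e-8)
    # minima sit on the CV1 axis, separated as requested (approximately:
    # well overlap pulls them slightly together)
    (x1, _), (x2, _) = pot.minima[0][0], pot.minima[1][0]
    assert abs(abs(x2 - x1) - sep) < 0.2 * sep


def test_double_well_gradient_vanishes_at_critical_points():
    pot = metad.make_double_well(4, 20, 5)
    for (x, y), _ in pot.minima + pot.saddles:
        gx, gy = pot.gradient(x, y)
        assert abs(gx) < 1e-6 and abs(gy) < 1e-6


def test_double_well_validation():
    with pytest.raises(InvalidParameterError):
        metad.make_double_well(separation=-1.0)
    with pytest.raises(InvalidParameterError):
        metad.make_double_well(barrier=0.0)
    with pytest.raises(InvalidParameterError):
        metad.make_double_well(barrier=10.0, asymmetry=10.0)


def test_gradient_matches_finite_differences():
    pot = metad.make_double_well(4, 20, 5)
    rng = np.random.default_rng(0)
    h = 1e-6
    for x, y in rng.uniform(2.0, 8.0, (10, 2)):
        gx, gy = pot.gradient(x, y)
        fx = (pot.energy(x + h, y) - pot.energy(x - h, y)) / (2 * h)
        fy = (pot.energy(x, y + h) - pot.energy(x, y - h)) / (2 * h)
        assert gx == pytest.approx(fx, abs=1e-5)
        assert gy == pytest.approx(fy, abs=1e-5)


def test_energy_grid_matches_scalar_energy():
    pot = metad.make_double_well(4, 20, 0)
    X, Y = np.meshgrid(np.linspace(1, 9, 5), np.linspace(3, 7, 4))
    E = pot.energy_grid(X, Y)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            assert E[i, j] == pytest.approx(pot.energy(X[i, j], Y[i, j]))


# ---------------------------------------------------------------------------
# Langevin sampler
# ---------------------------------------------------------------------------


def test_sampler_deterministic_and_seed_sensitive():
    pot = metad.make_double_well()
    cfg = metad.SamplerConfig(n_steps=2000, seed=3)
    t1 = metad.sample_langevin(pot, cfg)
    t2 = metad.sample_langevin(pot, cfg)
    np.testing.assert_array_equal(t1.frames, t2.frames)
    t3 = metad.sample_langevin(pot, metad.SamplerConfig(n_steps=2000, seed=4))
    assert not np.array_equal(t1.frames, t3.frames)


def test_sampler_respects_bounds():
    pot = metad.make_double_well(bounds=((0.0, 10.0), (4.0, 6.0)))
    traj = metad.sample_langevin(
        pot, metad.SamplerConfig(n_steps=5000, seed=1, step_size=0.3)
    )
    assert traj.frames[:, 0].min() >= 0.0 and traj.frames[:, 0].max() <= 10.0
    assert traj.frames[:, 1].min() >= 4.0 and traj.frames[:, 1].max() <= 6.0


def test_sampler_frozen_at_zero_temperature():
    pot = metad.make_double_well()
    cfg = metad.SamplerConfig(
        temperature=0.0, n_steps=100, seed=0, start=(3.3, 5.2)
    )
    traj = metad.sample_langevin(pot, cfg)
    np.testing.assert_allclose(traj.frames, [[3.3, 5.2]] * len(traj.frames))


def test_sampler_unstable_step_detected():
    pot = metad.make_double_well()
    with pytest.raises(metad.UnstableStepError):
        metad.sample_langevin(
            pot, metad.SamplerConfig(n_steps=100, seed=0, step_size=50.0)
        )


def test_sampler_stride_and_step_indices():
    pot = metad.make_double_well()
    traj = metad.sample_langevin(
        pot, metad.SamplerConfig(n_steps=1000, seed=0, sample_stride=100)
    )
    assert len(traj.frames) == 10
    np.testing.assert_array_equal(traj.step_indices, np.arange(100, 1001, 100))


def test_harmonic_equipartition():
    # pure harmonic confinement: lab-frame variance should equal kB*T/k
    pot = metad.ModelPotential(
        terms=[],
        bounds=((0.0, 10.0), (0.0, 10.0)),
        harmonic_k=(10.0, 10.0),
        harmonic_center=(5.0, 5.0),
        offset=0.0,
    )
    cfg = metad.SamplerConfig(
        temperature=310.0, step_size=0.05, n_steps=200_000, seed=7,
        start=(5.0, 5.0), sample_stride=5,
    )
    traj = metad.sample_langevin(pot, cfg)
    var = traj.frames[5000:].var(axis=0)
    expected = R_KJ * 310.0 / 10.0
    assert var[0] == pytest.approx(expected, rel=0.15)
    assert var[1] == pytest.approx(expected, rel=0.15)


def test_boltzmann_occupancy_matches_partition_function():
    # high-temperature double well: basin occupancies against the
    # numerically integrated Boltzmann weights (3-seed average)
    pot = metad.make_double_well(4, 5, 2)
    T = 900.0
    kBT = R_KJ * T
    xs = np.linspace(0, 10, 2001)
    ys = np.linspace(0, 10, 401)
    X, Y = np.meshgrid(xs, ys)
    B = np.exp(-pot.energy_grid(X, Y) / kBT)
    exact = B[:, xs > 5].sum() / B[:, xs < 5].sum()
    ratios = []
    for seed in (1, 2, 3):
        cfg = metad.SamplerConfig(
            temperature=T, step_size=0.1, n_steps=1_000_000, seed=seed,
            start=(3.0, 5.0), sample_stride=10,
        )
        x = metad.sample_langevin(pot, cfg).frames[:, 0]
        ratios.append(np.sum(x > 5.0) / np.sum(x < 5.0))
    assert np.mean(ratios) == pytest.approx(exact, rel=0.15)


# ---------------------------------------------------------------------------
# Metadynamics and bias bookkeeping
# ---------------------------------------------------------------------------


def test_metadynamics_deposits_expected_hill_count():
    pot = metad.make_double_well()
    cfg = metad.SamplerConfig(n_steps=10_000, seed=0)
    _, bias = metad.run_metadynamics(
        pot, cfg, metad.HillParams(deposition_interval=500)
    )
    assert len(bias.hills) == 20
    assert all(h.height <= 1.20 + 1e-12 for h in bias.hills)


def test_well_tempered_heights_decay_under_confinement():
    # strong confinement pins the walker, so successive hills land on
    # top of each other and their heights must decrease monotonically
    pot = metad.ModelPotential(
        terms=[],
        bounds=((0.0, 10.0), (0.0, 10.0)),
        harmonic_k=(400.0, 400.0),
        harmonic_center=(5.0, 5.0),
        offset=0.0,
    )
    cfg = metad.SamplerConfig(
        n_steps=4000, seed=2, step_size=0.02, start=(5.0, 5.0)
    )
    _, bias = metad.run_metadynamics(
        pot, cfg, metad.HillParams(deposition_interval=200, sigma=(0.5, 0.5))
    )
    heights = [h.height for h in bias.hills]
    centers = [h.center for h in bias.hills]
    assert len(heights) == 20
    # strong decay overall
    assert heights[-1] < 0.6 * heights[0]
    # at revisited points (nearly coincident centers) the later hill
    # must be the smaller one
    revisits = 0
    for i in range(len(heights)):
        for j in range(i + 1, len(heights)):
            d = np.hypot(
                centers[i][0] - centers[j][0], centers[i][1] - centers[j][1]
            )
            if d < 0.1:
                revisits += 1
                assert heights[j] < heights[i] * 1.02
    assert revisits > 0


def test_well_tempered_height_formula():
    # the first hill has no prior bias; the height of any later hill
    # equals w0 * exp(-V_prior(center) / ((gamma-1) kB T))
    pot = metad.make_double_well()
    cfg = metad.SamplerConfig(n_steps=3000, seed=5)
    hp = metad.HillParams(deposition_interval=500)
    _, bias = metad.run_metadynamics(pot, cfg, hp)
    assert bias.hills[0].height == pytest.approx(hp.initial_height, rel=1e-6)
    kT = R_KJ * cfg.temperature
    for k in (2, 5):
        prior = metad.BiasState(
            hills=bias.hills[:k], bias_factor=hp.bias_factor
        )
        x, y = bias.hills[k].center
        expected = hp.initial_height * math.exp(
            -prior.bias_potential(x, y) / ((hp.bias_factor - 1.0) * kT)
        )
        # the sampler reads the bias off its interpolation grid, so
        # allow a small interpolation tolerance
        assert bias.hills[k].height == pytest.approx(expected, rel=0.02)


def test_reconstruct_fes_from_single_hill():
    bias = metad.BiasState(
        hills=[
            metad.GaussianHill(
                time_index=1,
                center=(5.0, 5.0),
                sigma=(0.3, 0.3),
                height=1.0,
                bias_factor=10.0,
            )
        ],
        bias_factor=10.0,
    )
    grid = metad.reconstruct_fes(
        bias, metad.GridSpec(bounds=((4.0, 6.0), (4.0, 6.0)), shape=(41, 41))
    )
    # F = -(gamma/(gamma-1)) V, anchored at 0: the hill center is the
    # minimum and far away F approaches (gamma/(gamma-1)) * height
    assert grid.values[20, 20] == 0.0
    corner = grid.values[0, 0]
    v_corner = bias.bias_potential(4.0, 4.0)
    assert corner == pytest.approx((10.0 / 9.0) * (1.0 - v_corner), rel=1e-9)


def test_reconstruct_fes_empty_bias_raises():
    with pytest.raises(metad.EmptyBiasError):
        metad.reconstruct_fes(
            metad.BiasState(),
            metad.GridSpec(bounds=((0, 1), (0, 1)), shape=(5, 5)),
        )


def test_hill_params_validation():
    with pytest.raises(InvalidParameterError):
        metad.HillParams(bias_factor=1.0)
    with pytest.raises(InvalidParameterError):
        metad.HillParams(initial_height=0.0)
    with pytest.raises(InvalidParameterError):
        metad.HillParams(deposition_interval=0)


# ---------------------------------------------------------------------------
# Hills I/O
# ---------------------------------------------------------------------------


def test_hills_roundtrip(tmp_path):
    pot = metad.make_double_well()
    _, bias = metad.run_metadynamics(
        pot,
        metad.SamplerConfig(n_steps=3000, seed=9),
        metad.HillParams(deposition_interval=300),
    )
    p = tmp_path / "out.hills"
    metad.write_hills(bias, p)
    back = metad.read_hills(p)
    assert len(back.hills) == len(bias.hills)
    for a, b in zip(bias.hills, back.hills):
        assert a.time_index == b.time_index
        assert a.center == pytest.approx(b.center)
        assert a.height == pytest.approx(b.height)
    assert back.bias_factor == bias.bias_factor


def test_read_hills_malformed_line_names_lineno(tmp_path):
    p = tmp_path / "bad.hills"
    p.write_text("# header\n1 2 3 4 5 6 7\n8 9 10\n")
    with pytest.raises(ParseError, match=":3"):
        metad.read_hills(p)
    p2 = tmp_path / "bad2.hills"
    p2.write_text("1 2 3 4 5 not-a-number 7\n")
    with pytest.raises(ParseError, match=":1"):
        metad.read_hills(p2)


def test_read_hills_comment_only_warns(tmp_path):
    p = tmp_path / "empty.hills"
    p.write_text("# just a header\n\n")
    with pytest.warns(RuntimeWarning):
        bias = metad.read_hills(p)
    assert bias.hills == []
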