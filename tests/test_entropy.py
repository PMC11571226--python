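"""Molar fractions, entropy density, integration, and the cell estimator."""

import numpy as np
import pytest

from mixent import (
    BroadeningSpec,
    CellPartition,
    DensityField,
    IntegrationNotConverged,
    MolarFractionField,
    ParticleFrame,
    cell_entropy_estimate,
    entropy_density,
    entropy_of_mixing,
    equilibrium_entropy,
    integrate_entropy,
    make_chain_1d,
    make_random,
    make_slabs,
    molar_fraction,
)

LN2 = np.log(2.0)


class TestEquilibriumEntropy:
    def test_equimolar_binary_is_ln2(self):
        assert equilibrium_entropy([0.5, 0.5]) == pytest.approx(LN2, rel=1e-14)
        assert round(equilibrium_entropy({"A": 0.5, "B": 0.5}), 2) == 0.69

    def test_pure_phase_is_zero(self):
        assert equilibrium_entropy([1.0, 0.0]) == 0.0

    def test_quarter_mixture(self):
        # -(0.25 ln 0.25 + 0.75 ln 0.75)
        assert equilibrium_entropy([0.25, 0.75]) == pytest.approx(0.5623, abs=5e-5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            equilibrium_entropy([0.5, 0.4])

    def test_fractions_must_be_non_negative(self):
        with pytest.raises(ValueError):
            equilibrium_entropy([1.2, -0.2])


@pytest.fixture
def ab_field(two_species_frame):
    return MolarFractionField.from_frame(two_species_frame,
                                         BroadeningSpec(sigma=1.0))


class TestMolarFraction:
    def test_midpoint_symmetry(self, ab_field):
        mid = [[5.0, 5.0, 5.0]]
        assert molar_fraction(ab_field, "A", mid)[0] == pytest.approx(0.5, rel=1e-12)
        assert molar_fraction(ab_field, "B", mid)[0] == pytest.approx(0.5, rel=1e-12)

    def test_quarter_point_two_gaussian_ratio(self, ab_field):
        # closed form: x_A = g(d_A) / (g(d_A) + g(d_B)) for the two kernels
        pt = np.array([[4.5, 5.0, 5.0]])
        g = lambda r: np.exp(-0.5 * r**2)
        want = g(0.5) / (g(0.5) + g(1.5))
        assert molar_fraction(ab_field, "A", pt)[0] == pytest.approx(want, rel=1e-10)

    def test_pure_region_is_one(self):
        frame = ParticleFrame(
            np.array([[2.0, 5.0, 5.0], [12.0, 5.0, 5.0]]), ["A", "B"],
            [20.0, 10.0, 10.0],
        )
        # the B kernel is truncated well before x = 2, so the point is pure A
        field = MolarFractionField.from_frame(frame, BroadeningSpec(sigma=1.0))
        assert molar_fraction(field, "A", [[2.0, 5.0, 5.0]])[0] == 1.0

    def test_vacuum_is_nan_sentinel(self):
        frame = ParticleFrame(
            np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]]), ["A", "B"],
            [30.0, 30.0, 30.0],
        )
        field = MolarFractionField.from_frame(frame, BroadeningSpec(sigma=0.5))
        assert np.isnan(molar_fraction(field, "A", [[20.0, 20.0, 20.0]])[0])

    def test_unknown_species_is_error(self, ab_field):
        with pytest.raises(KeyError, match="unknown species"):
            molar_fraction(ab_field, "C", [[5.0, 5.0, 5.0]])

    def test_fractions_sum_to_one_where_occupied(self, ab_field):
        rng = np.random.default_rng(0)
        pts = rng.random((50, 3)) * 10.0
        frac, vacuum = ab_field.fractions(pts)
        occupied = ~vacuum
        np.testing.assert_allclose(frac[occupied].sum(axis=1), 1.0, rtol=1e-12)
        assert np.all((frac[occupied] >= 0) & (frac[occupied] <= 1))


class TestEntropyDensity:
    def test_equal_fractions_give_ln2_over_V(self, ab_field):
        v = ab_field.frame.volume
        s = entropy_density(ab_field, [[5.0, 5.0, 5.0]])[0]
        assert s == pytest.approx(LN2 / v, rel=1e-12)

    def test_pure_region_vanishes(self):
        # two adjacent same-species sites suppress the other species locally
        chain = make_chain_1d("AAAAABBBBB", 1.0)
        field = MolarFractionField.from_frame(chain, BroadeningSpec(sigma=0.5))
        # x = 1.25 is more than 4 sigma away from every B site
        deep_a = entropy_density(field, np.array([[1.25]]))[0]
        assert deep_a == 0.0

    def test_interface_profile_peaks_at_midpoint(self):
        chain = make_chain_1d("AAAAABBBBB", 1.0)
        field = MolarFractionField.from_frame(chain, BroadeningSpec(sigma=0.5))
        x = np.linspace(0.0, 10.0, 2000, endpoint=False)[:, None]
        s = entropy_density(field, x)
        peak = x[np.argmax(s), 0]
        assert min(abs(peak - 4.5), abs(peak - 9.5)) < 0.01
        # decays to ~0 within 3 sigma of the interfaces
        away = (np.minimum(np.abs(x[:, 0] - 4.5), 10 - np.abs(x[:, 0] - 4.5)) > 1.5) & (
            np.minimum(np.abs(x[:, 0] - 9.5), 10 - np.abs(x[:, 0] - 9.5)) > 1.5
        )
        assert s[away].max() < 0.01 * s.max()


class TestIntegration:
    def test_separated_slabs_give_small_entropy(self):
        frame = make_slabs((120, 120), (20.0, 20.0, 20.0), seed=3)
        result = entropy_of_mixing(frame, sigma=0.5)
        assert 0.0 <= result.delta_S < 0.05

    def test_alternating_chain_approaches_ln2_from_below(self):
        chain = make_chain_1d("AB" * 10, 1.0)
        values = [
            entropy_of_mixing(chain, sigma=s, resolution=0.05).delta_S
            for s in (0.5, 1.0, 2.0)
        ]
        assert values[0] < values[1] <= values[2] + 1e-12
        assert values[2] == pytest.approx(LN2, abs=1e-3)
        assert all(v <= LN2 + 1e-9 for v in values)

    def test_grid_refinement_oracle(self):
        # grid at sigma/4 against an independent Riemann sum at sigma/8
        frame = make_random((30, 30), (14.4, 14.4, 14.4), seed=5)
        sigma = 1.5
        coarse = entropy_of_mixing(frame, sigma=sigma).delta_S
        field = MolarFractionField.from_frame(frame, BroadeningSpec(sigma=sigma))
        n = int(round(14.4 / (sigma / 8)))
        ax = (np.arange(n) + 0.5) * (14.4 / n)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        shannon = field.shannon(pts.reshape(-1, 3))
        fine = shannon.sum() * (14.4 / n) ** 3 / frame.volume
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_adaptive_agrees_with_grid(self):
        frame = make_random((20, 20), (10.0, 10.0, 10.0), seed=2)
        grid = entropy_of_mixing(frame, sigma=1.5, method="grid")
        adaptive = entropy_of_mixing(frame, sigma=1.5, method="adaptive",
                                     rtol=1e-4)
        assert adaptive.delta_S == pytest.approx(
            grid.delta_S, rel=0.01, abs=grid.integration_error + 1e-4
        )
        assert adaptive.integration_error < 1e-3

    def test_result_respects_theoretical_bound(self):
        for seed in range(5):
            frame = make_random((40, 40), (15.0, 15.0, 15.0), seed=seed)
            r = entropy_of_mixing(frame, sigma=1.5)
            assert 0.0 <= r.delta_S <= r.theoretical_max + r.integration_error + 1e-9

    def test_species_swap_symmetry(self):
        frame = make_random((30, 30), (14.0, 14.0, 14.0), seed=9)
        swapped = ParticleFrame(
            frame.coordinates.copy(),
            np.where(frame.species == "A", "B", "A").astype(object),
            frame.box.copy(),
        )
        a = entropy_of_mixing(frame, sigma=1.5).delta_S
        b = entropy_of_mixing(swapped, sigma=1.5).delta_S
        assert a == pytest.approx(b, rel=1e-10)

    def test_intensivity_under_tiling(self):
        frame = make_random((25, 25), (12.0, 12.0, 12.0), seed=6)
        base = entropy_of_mixing(frame, sigma=1.5).delta_S
        tiled = entropy_of_mixing(frame.tiled(2), sigma=1.5).delta_S
        assert tiled == pytest.approx(base, rel=0.01)

    def test_three_species_bounded_by_ln3(self):
        frame = make_random((40, 40, 40), (16.0, 16.0, 16.0), seed=8,
                            species=("A", "B", "C"))
        r = entropy_of_mixing(frame, sigma=2.0)
        assert 0.0 < r.delta_S <= np.log(3.0) + 1e-9
        assert r.theoretical_max == pytest.approx(np.log(3.0), rel=1e-12)

    def test_density_weighting_close_to_volume_weighting_when_filled(self):
        frame = make_random((60, 60), (12.0, 12.0, 12.0), seed=4)
        vol = entropy_of_mixing(frame, sigma=2.0, weighting="volume").delta_S
        dens = entropy_of_mixing(frame, sigma=2.0, weighting="density").delta_S
        assert dens == pytest.approx(vol, rel=0.15)

    def test_non_converged_adaptive_raises_with_best_estimate(self):
        frame = make_random((20, 20), (10.0, 10.0, 10.0), seed=2)
        field = MolarFractionField.from_frame(frame, BroadeningSpec(sigma=1.5))
        with pytest.raises(IntegrationNotConverged) as err:
            integrate_entropy(field, method="adaptive", rtol=1e-14,
                              atol=1e-16, max_subdivisions=8)
        assert err.value.result.delta_S > 0

    def test_bad_method_and_weighting_rejected(self, ab_field):
        with pytest.raises(ValueError):
            integrate_entropy(ab_field, method="magic")
        with pytest.raises(ValueError):
            integrate_entropy(ab_field, weighting="massive")


class TestCellEstimator:
    def test_all_pure_cells_give_exact_zero(self):
        frame = make_slabs((100, 100), (20.0, 20.0, 20.0), seed=1)
        # 2 cells along the slab axis: each cell holds one pure species
        result = cell_entropy_estimate(frame, (1, 1, 2))
        assert result.delta_S == 0.0

    def test_uniform_cells_reduce_to_equilibrium_formula(self):
        # checkerboard occupation: every 2x2x2 cell holds 4 A and 4 B
        idx = np.stack(np.meshgrid(*[np.arange(4)] * 3, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        coords = (idx + 0.5) * 1.0
        labels = np.where(idx.sum(axis=1) % 2 == 0, "A", "B").astype(object)
        frame = ParticleFrame(coords, labels, [4.0, 4.0, 4.0])
        result = cell_entropy_estimate(frame, 2)
        assert result.delta_S == pytest.approx(LN2, rel=1e-14)
        assert result.delta_S == pytest.approx(result.theoretical_max, rel=1e-14)

    def test_four_cell_toy_hand_value(self):
        # cells (4A/0B, 3A/1B, 1A/3B, 0A/4B) with equal mole weights:
        # 0.25 * (0 + h(3/4) + h(1/4) + 0) with h = -sum x ln x = 0.5623
        xs = np.concatenate([
            np.repeat([0.5], 4), np.repeat([1.5], 3), np.repeat([2.5], 1),
            np.repeat([1.5], 1), np.repeat([2.5], 3), np.repeat([3.5], 4),
        ])
        labels = np.array(["A"] * 8 + ["B"] * 8, dtype=object)
        coords = np.stack([xs, np.full(16, 0.5)], axis=1)
        frame = ParticleFrame(coords, labels, [4.0, 1.0])
        result = cell_entropy_estimate(frame, (4, 1))
        hand = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75)) / 2.0
        assert result.delta_S == pytest.approx(hand, rel=1e-12)
        assert round(result.delta_S, 4) == 0.2812

    def test_partition_mismatch_is_error(self):
        frame = make_random((10, 10), (8.0, 8.0, 8.0), seed=0)
        other = make_random((12, 12), (8.0, 8.0, 8.0), seed=0)
        partition = CellPartition.from_frame(other, 2)
        with pytest.raises(ValueError, match="inconsistent"):
            cell_entropy_estimate(frame, partition)

    def test_partition_counts_conserve_sites(self):
        frame = make_random((33, 44), (9.0, 9.0, 9.0), seed=3)
        p = CellPartition.from_frame(frame, 3)
        assert int(p.counts["A"].sum()) == 33
        assert int(p.counts["B"].sum()) == 44
        assert p.weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_agrees_with_field_integration_when_well_mixed(self):
        frame = make_random((250, 250), (30.0, 30.0, 30.0), seed=1)
        spacing = (frame.volume / frame.n_sites) ** (1 / 3)
        field_value = entropy_of_mixing(frame, sigma=1.5 * spacing).delta_S
        cell_value = cell_entropy_estimate(frame, 3).delta_S
        assert field_value == pytest.approx(cell_value, rel=0.10)
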