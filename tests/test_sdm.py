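import numpy as np
import pytest
from scipy.stats import chisquare

from redlisting import (
    DataError,
    OccurrenceSet,
    auc,
    consensus_map,
    fit_maxent_like,
    map_points,
    run_ensemble,
    sample_background,
)
from redlisting.sdm import SdmRun

from .conftest import make_layer, make_stack
from .oracles import auc_pair_enumeration


class TestBackgroundSampling:
    def test_exhaustive_when_n_equals_data_cells(self):
        stack = make_stack([np.zeros((10, 10))])
        bg = sample_background(stack, n=100, seed=0)
        assert len(bg) == 100
        assert len(np.unique(bg.coords, axis=0)) == 100

    def test_deterministic_under_seed(self):
        stack = make_stack([np.zeros((20, 20))])
        a = sample_background(stack, n=50, seed=7)
        b = sample_background(stack, n=50, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_uniformity_chi_square(self):
        stack = make_stack([np.zeros((2, 5))], cell_size=1.0)
        counts = np.zeros(10)
        for s in range(10_000):
            bg = sample_background(stack, n=1, seed=s)
            r, c = stack.grid.cell_of(bg.coords[:, 0], bg.coords[:, 1])
            counts[r[0] * 5 + c[0]] += 1
        assert chisquare(counts).pvalue > 0.01


class TestMaxentLike:
    def test_no_signal_gives_chance_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for s in range(5):
            pres = rng.normal(size=(50, 2))
            bg = rng.normal(size=(200, 2))
            model = fit_maxent_like(pres, bg)
            aucs.append(auc(model.predict(pres), model.predict(bg)))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_separable_covariate_gives_high_auc(self):
        rng = np.random.default_rng(1)
        pres = rng.normal(10.0, 1.0, size=(60, 1))
        bg = rng.normal(0.0, 1.0, size=(300, 1))
        model = fit_maxent_like(pres, bg)
        sp, sb = model.predict(pres), model.predict(bg)
        assert auc(sp, sb) > 0.95
        assert auc_pair_enumeration(sp, sb) > 0.95

    def test_predictions_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(2)
        pres = rng.normal(2.0, 1.0, size=(30, 2))
        bg = rng.normal(0.0, 1.0, size=(100, 2))
        grid = rng.normal(size=(40, 2))
        p1 = fit_maxent_like(pres, bg).predict(grid)
        scale = np.array([1000.0, 0.01])
        shift = np.array([-5.0, 40.0])
        p2 = fit_maxent_like(pres * scale + shift, bg * scale + shift).predict(
            grid * scale + shift
        )
        np.testing.assert_allclose(p1, p2, atol=1e-4)

    def test_too_few_presences_rejected(self):
        with pytest.raises(DataError, match="at least 5"):
            fit_maxent_like(np.zeros((3, 2)), np.zeros((10, 2)))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_sets_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_hand_enumerated_example(self):
        # 4 pairs: (0.9,0.5) (0.9,0.1) (0.4,0.1) win; (0.4,0.5) loses -> 3/4
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        sp = rng.integers(0, 5, 20) / 4
        sb = rng.integers(0, 5, 30) / 4
        assert auc(sp, sb) == pytest.approx(auc_pair_enumeration(sp, sb))


@pytest.fixture(scope="module")
def recovery():
    from redlisting import fixtures

    land, species, records = fixtures.recovery_setup(seed=0)
    return land, species, records


class TestEnsemble:
    def test_single_run_binary_consistent_with_threshold(self, recovery):
        land, _, records = recovery
        (run,) = run_ensemble(records, land.quantitative(), runs=1, background_n=300, seed=1)
        mask = run.probability.mask
        expected = run.probability.values[mask] >= run.threshold
        np.testing.assert_array_equal(run.binary.values[mask].astype(bool), expected)

    def test_same_seed_reproduces_runs(self, recovery):
        land, _, records = recovery
        quant = land.quantitative()
        a = run_ensemble(records, quant, runs=3, background_n=200, seed=11)
        b = run_ensemble(records, quant, runs=3, background_n=200, seed=11)
        for ra, rb in zip(a, b):
            assert ra.test_auc == rb.test_auc
            np.testing.assert_array_equal(
                np.nan_to_num(ra.binary.values), np.nan_to_num(rb.binary.values)
            )

    def test_strong_virtual_species_recovers_high_auc(self, recovery):
        land, _, records = recovery
        runs = run_ensemble(records, land.quantitative(), runs=10, background_n=1000, seed=5)
        assert np.mean([r.test_auc for r in runs]) > 0.8


def _run_from_binary(binary01: np.ndarray, test_auc: float) -> SdmRun:
    layer = make_layer(binary01.astype(float), cell_size=1.0)
    return SdmRun(model=None, probability=layer, threshold=0.5, test_auc=test_auc, binary=layer)


class TestConsensus:
    def test_unanimous_runs_reproduce_the_map(self):
        binary = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        runs = [_run_from_binary(binary, 1.0) for _ in range(5)]
        ens = consensus_map(runs)
        for layer in (ens.consensus, ens.lower, ens.upper):
            np.testing.assert_array_equal(layer.values, binary)

    def test_three_run_hand_example(self):
        # AUCs 1.0/0.9/0.6 -> weights 0.25/0.16/0.01; a cell present in
        # runs 1-2 scores 0.41/0.42 > 0.5 -> consensus presence, and at
        # 2/3 = 67% of runs it is in the upper CL but not the lower
        cell = np.zeros((1, 2))
        maps = [cell.copy(), cell.copy(), cell.copy()]
        maps[0][0, 0] = maps[1][0, 0] = 1.0  # cell (0,0) present in runs 1-2
        for m in maps:
            m[0, 1] = 1.0  # keep a unanimous cell so no map is empty
        runs = [_run_from_binary(m, a) for m, a in zip(maps, [1.0, 0.9, 0.6])]
        ens = consensus_map(runs)
        assert ens.consensus.values[0, 0] == 1.0
        assert ens.upper.values[0, 0] == 1.0
        assert ens.lower.values[0, 0] == 0.0

    def test_cl_frequency_boundaries_at_100_runs(self):
        base = np.zeros((1, 3))
        base[0, 2] = 1.0  # unanimous cell
        maps = [base.copy() for _ in range(100)]
        for i in range(98):
            maps[i][0, 0] = 1.0  # cell present in 98/100 runs
        for i in range(2):
            maps[i][0, 1] = 1.0  # cell present in 2/100 runs
        runs = [_run_from_binary(m, 0.9) for m in maps]
        ens = consensus_map(runs)
        assert ens.lower.values[0, 0] == 1.0  # 98% >= 97.5%
        assert ens.lower.values[0, 1] == 0.0
        assert ens.upper.values[0, 1] == 0.0  # 2% < 2.5%

    def test_all_chance_aucs_rejected(self):
        runs = [_run_from_binary(np.ones((2, 2)), 0.5) for _ in range(3)]
        with pytest.raises(DataError, match="uninformative"):
            consensus_map(runs)

    def test_consensus_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(4)
        maps = [(rng.random((5, 5)) > 0.5).astype(float) for _ in range(7)]
        aucs = 0.6 + 0.3 * rng.random(7)
        runs_a = [_run_from_binary(m, a) for m, a in zip(maps, aucs)]
        # same vote shape: AUCs transformed so each weight scales by 4
        runs_b = [_run_from_binary(m, 0.5 + 2 * (a - 0.5)) for m, a in zip(maps, aucs)]
        ca = consensus_map(runs_a).consensus.values
        cb = consensus_map(runs_b).consensus.values
        np.testing.assert_array_equal(ca, cb)

    def test_lower_nested_in_upper_over_seeds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            maps = [(rng.random((6, 6)) > rng.random()).astype(float) for _ in range(9)]
            runs = [_run_from_binary(m, 0.55 + 0.4 * rng.random()) for m in maps]
            try:
                ens = consensus_map(runs)
            except DataError:
                continue  # empty consensus map: nothing to check
            low = np.nan_to_num(ens.lower.values) > 0
            upp = np.nan_to_num(ens.upper.values) > 0
            assert not np.any(low & ~upp)


class TestMapPoints:
    def test_single_record_single_cell(self):
        stack = make_stack([np.zeros((5, 5))])
        recs = OccurrenceSet(np.array([[2500.0, 2500.0]]), crs="metric")
        layer, rv = map_points(recs, stack)
        assert np.nansum(layer.values) == 1.0
        assert rv.aoo_km2 == 4.0

    def test_duplicates_collapse_to_one_cell(self):
        stack = make_stack([np.zeros((5, 5))])
        recs = OccurrenceSet(np.array([[2500.0, 2500.0]] * 3), crs="metric")
        layer, _ = map_points(recs, stack)
        assert np.nansum(layer.values) == 1.0

    def test_cells_match_direct_binning(self, island):
        land, rec, _ = island
        layer, _ = map_points(rec, land)
        r, c = land.grid.cell_of(rec.coords[:, 0], rec.coords[:, 1])
        # the presence map is masked to data cells, so the sea record drops out
        expected = {rc for rc in zip(r.tolist(), c.tolist()) if land.grid.mask[rc]}
        got = set(zip(*np.nonzero(np.nan_to_num(layer.values) > 0)))
        assert got == expected

    def test_off_extent_record_reports_indices(self):
        stack = make_stack([np.zeros((5, 5))])
        recs = OccurrenceSet(np.array([[2500.0, 2500.0], [99_000.0, 0.0]]), crs="metric")
        with pytest.raises(DataError, match=r"\[1\]"):
            map_points(recs, stack)
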