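"""Decision-grid enumeration and specification-curve summaries."""

import numpy as np
import pandas as pd
import pytest

from relimaps import (
    DecisionGrid,
    build_smoothing_grid,
    collect_estimates,
    enumerate_permutations,
    grid_from_config,
    percentile_select,
    permutation_medians,
)

from conftest import make_mask, make_volume

MOTION4 = ("opt1", "opt2", "opt3", "opt4")
MOTION6 = MOTION4 + ("opt5", "opt6")
MODELS = ("cue", "fixation", "anticipation")
CONTRASTS = ("LGainNeut", "LGainBase", "SGainNeut", "SGainBase")


def realized_grid():
    return DecisionGrid(
        fwhm_options=(3.6, 4.8, 6.0, 7.2, 8.4),
        motion_options=MOTION4,
        model_options=MODELS,
        contrast_options=CONTRASTS,
    )


class TestEnumeration:
    def test_realized_grid_has_240_cells(self):
        assert len(enumerate_permutations(realized_grid())) == 240

    def test_proposed_grid_has_360_cells(self):
        grid = DecisionGrid(
            fwhm_options=(3.6, 4.8, 6.0, 7.2, 8.4),
            motion_options=MOTION6,
            model_options=MODELS,
            contrast_options=CONTRASTS,
        )
        assert len(enumerate_permutations(grid)) == 360

    def test_single_cell_grid(self):
        grid = DecisionGrid((6.0,), ("m",), ("cue",), ("c",))
        perms = enumerate_permutations(grid)
        assert len(perms) == 1 and perms[0].id == 1

    def test_ordering_fwhm_outermost_contrast_innermost(self):
        perms = enumerate_permutations(realized_grid())
        assert [p.contrast for p in perms[:4]] == list(CONTRASTS)
        assert perms[0].fwhm == 3.6
        assert perms[-1].fwhm == 8.4
        assert [p.id for p in perms] == list(range(1, 241))

    def test_size_always_product_of_option_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(1, 5, size=4)
            grid = DecisionGrid(
                tuple(np.arange(counts[0], dtype=float)),
                tuple(f"m{i}" for i in range(counts[1])),
                tuple(f"p{i}" for i in range(counts[2])),
                tuple(f"c{i}" for i in range(counts[3])),
            )
            assert len(enumerate_permutations(grid)) == int(np.prod(counts))

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            DecisionGrid((), ("m",), ("p",), ("c",))


class TestSmoothingGrid:
    def test_isotropic_24mm_voxels(self):
        assert build_smoothing_grid(2.4) == [3.6, 4.8, 6.0, 7.2, 8.4]

    def test_4mm_voxels_with_half_weight(self):
        assert build_smoothing_grid(4.0, weight=0.5) == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_unit_voxel_returns_multipliers(self):
        assert build_smoothing_grid(1.0) == [1.5, 2.0, 2.5, 3.0, 3.5]

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_smoothing_grid(0.0)
        with pytest.raises(ValueError):
            build_smoothing_grid(2.4, weight=-1.0)


class TestCollectEstimates:
    def test_ranks_follow_estimates(self):
        grid = DecisionGrid((1.0, 2.0), ("m1", "m2"), ("p",), ("c",))
        perms = enumerate_permutations(grid)
        values = {1: 0.1, 2: 0.4, 3: 0.2, 4: 0.3}
        estimates = {(pid, "s1"): v for pid, v in values.items()}
        table = collect_estimates(estimates, perms)
        by_perm = table.set_index("permutation_id")["rank"]
        assert by_perm.to_dict() == {1: 1, 2: 4, 3: 2, 4: 3}
        assert table["percentile"].iloc[-1] == 1.0

    def test_ties_break_by_permutation_id(self):
        grid = DecisionGrid((1.0,), ("m1", "m2", "m3"), ("p",), ("c",))
        perms = enumerate_permutations(grid)
        table = collect_estimates({(i, "s"): 0.5 for i in (1, 2, 3)}, perms)
        assert list(table["permutation_id"]) == [1, 2, 3]
        assert list(table["rank"]) == [1, 2, 3]

    def test_point_estimate_and_ci_across_samples(self):
        grid = DecisionGrid((1.0,), ("m1",), ("p",), ("c",))
        perms = enumerate_permutations(grid)
        table = collect_estimates(
            {(1, "abcd"): 0.1, (1, "ahrb"): 0.3, (1, "mls"): 0.2}, perms
        )
        assert table.loc[0, "estimate"] == pytest.approx(0.2)
        se = 0.1 / np.sqrt(3)
        assert table.loc[0, "ci_lower"] == pytest.approx(0.2 - 1.96 * se)
        assert table.loc[0, "ci_upper"] == pytest.approx(0.2 + 1.96 * se)

    def test_missing_permutation_is_an_error(self):
        grid = DecisionGrid((1.0,), ("m1", "m2"), ("p",), ("c",))
        perms = enumerate_permutations(grid)
        with pytest.raises(ValueError, match="no estimates for permutation"):
            collect_estimates({(1, "s"): 0.5}, perms)

    def test_rank_invariant_to_input_row_order_and_rerun_identical(self):
        rng = np.random.default_rng(1)
        perms = enumerate_permutations(realized_grid())
        df = pd.DataFrame(
            {
                "permutation_id": [p.id for p in perms],
                "sample": "s1",
                "estimate": rng.normal(size=240),
            }
        )
        shuffled = df.sample(frac=1.0, random_state=2).reset_index(drop=True)
        t1 = collect_estimates(df, perms)
        t2 = collect_estimates(shuffled, perms)
        pd.testing.assert_frame_equal(t1, t2)

    def test_percentile_select_nearest_rank(self):
        rng = np.random.default_rng(3)
        perms = enumerate_permutations(realized_grid())
        df = pd.DataFrame(
            {
                "permutation_id": [p.id for p in perms],
                "sample": "s1",
                "estimate": rng.normal(size=240),
            }
        )
        table = collect_estimates(df, perms)
        assert percentile_select(table, 0.25)["rank"] == 60
        assert percentile_select(table, 0.75)["rank"] == 180


class TestPermutationMedians:
    def test_constant_maps_give_their_constants(self):
        supra = make_mask([[[1]], [[1]], [[0]], [[0]]])
        sub = make_mask([[[0]], [[0]], [[1]], [[1]]])
        maps = {
            1: make_volume(np.full((4, 1, 1), 0.2)),
            2: make_volume(np.full((4, 1, 1), 0.7)),
        }
        table = permutation_medians(maps, supra, sub)
        assert list(table["median_supra"]) == [pytest.approx(0.2),
                                               pytest.approx(0.7)]
        assert list(table["median_sub"]) == [pytest.approx(0.2),
                                             pytest.approx(0.7)]

    def test_disjoint_masks_are_independent(self):
        supra = make_mask([[[1]], [[1]], [[0]], [[0]]])
        sub = make_mask([[[0]], [[0]], [[1]], [[1]]])
        vol = make_volume([0.1, 0.3, 0.8, 0.6], shape=(4, 1, 1))
        table = permutation_medians({1: vol}, supra, sub)
        assert table.loc[0, "median_supra"] == pytest.approx(0.2)
        assert table.loc[0, "median_sub"] == pytest.approx(0.7)

    def test_monotone_construction_orders_spec_curve_by_fwhm(self):
        """Assign uniformly higher maps to higher smoothing: ranks must
        follow the smoothing order."""
        grid = DecisionGrid((3.6, 6.0, 8.4), ("m",), ("p",), ("c",))
        perms = enumerate_permutations(grid)
        supra = make_mask([[[1]], [[1]], [[1]], [[0]]])
        sub = make_mask([[[0]], [[0]], [[0]], [[1]]])
        maps = {
            p.id: make_volume(np.full((4, 1, 1), 0.1 * p.fwhm)) for p in perms
        }
        medians = permutation_medians(maps, supra, sub)
        estimates = {
            (int(r.permutation_id), "s1"): r.median_supra
            for r in medians.itertuples()
        }
        table = collect_estimates(estimates, perms)
        ranked_fwhm = list(table.sort_values("rank")["fwhm"])
        assert ranked_fwhm == [3.6, 6.0, 8.4]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "grid.yaml"
        cfg.write_text(
            "voxel_mm: 2.4\n"
            "motion_options: [opt1, opt2, opt3, opt4]\n"
            "model_options: [cue, fixation, anticipation]\n"
            "contrast_options: [LGainNeut, LGainBase, SGainNeut, SGainBase]\n"
        )
        grid = grid_from_config(cfg)
        assert grid.size == 240
        assert grid.fwhm_options == (3.6, 4.8, 6.0, 7.2, 8.4)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            grid_from_config(
                {
                    "voxel_mm": 2.4,
                    "motion_options": ["a"],
                    "model_options": ["b"],
                    "contrast_options": ["c"],
                    "typo_key": 1,
                }
            )

    def test_missing_keys_rejected(self):
        with pytest.raises(ValueError, match="missing config keys"):
            grid_from_config({"voxel_mm": 2.4})
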