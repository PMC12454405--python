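"""Vegetation-index library, importance ranking, and sequence assembly."""

import numpy as np
import pandas as pd
import pytest

import ricelai
from ricelai.features import (
    ImportanceRanking,
    VI_NAMES,
    build_feature_table,
    build_sequences,
    compute_vi,
    rank_importance,
    select_top_k,
)


def _oracle_vi(name, b, g, r, re, n):
    """Independent hand-coded evaluator of the canonical index formulas."""
    if name == "NDVI":
        return (n - r) / (n + r)
    if name == "NDRE":
        return (n - re) / (n + re)
    if name == "NIRv":
        return (n - r) / (n + r) * n
    if name == "EVI2":
        return 2.5 * (n - r) / (n + 2.4 * r + 1)
    if name == "WDRVI":
        return (0.2 * n - r) / (0.2 * n + r)
    if name == "VARI":
        return (g - r) / (g + r - b)
    if name == "DVI":
        return n - r
    if name == "RVI":
        return n / r
    if name == "EVI":
        return 2.5 * (n - r) / (n + 6 * r - 7.5 * b + 1)
    if name == "OSAVI":
        return 1.16 * (n - r) / (n + r + 0.16)
    if name == "MTCI":
        return (n - re) / (re - r)
    if name == "TVI":
        return 0.5 * (120 * (n - g) - 200 * (r - g))
    if name == "GNDVI":
        return (n - g) / (n + g)
    if name == "LCI":
        return (n - re) / (n + r)
    if name == "SAVI":
        return 1.5 * (n - r) / (n + r + 0.5)
    raise KeyError(name)


class TestComputeVI:
    def test_all_indices_match_oracle_on_grid(self, rng):
        """Every canonical formula agrees with an independent evaluator."""
        grid = rng.uniform(0.01, 1.0, size=(100, 5))
        for name in VI_NAMES:
            ours = compute_vi(name, grid)
            oracle = np.array([_oracle_vi(name, *row) for row in grid])
            np.testing.assert_allclose(ours, oracle, atol=1e-12, rtol=0)

    def test_symmetry_zero(self):
        assert compute_vi("NDVI", [0.1, 0.2, 0.4, 0.3, 0.4]) == 0.0

    @pytest.mark.parametrize("name,refl,expected", [
        ("NDVI", [0.05, 0.08, 0.1, 0.2, 0.6], 0.714286),   # (0.6-0.1)/0.7
        ("SAVI", [0.05, 0.08, 0.1, 0.2, 0.6], 0.625),      # 1.5*0.5/1.2
        ("RVI", [0.05, 0.08, 0.1, 0.2, 0.6], 6.0),
    ])
    def test_hand_evaluated_examples(self, name, refl, expected):
        assert compute_vi(name, refl) == pytest.approx(expected, abs=1e-6)

    def test_normalized_indices_bounded(self, rng):
        refl = rng.uniform(0.01, 1.0, size=(200, 5))
        for name in ("NDVI", "NDRE", "GNDVI", "WDRVI"):
            vals = compute_vi(name, refl)
            assert np.all((vals >= -1) & (vals <= 1))

    def test_zero_denominator_yields_nan_not_exception(self):
        val = compute_vi("RVI", [0.1, 0.1, 0.0, 0.1, 0.5])
        assert np.isnan(val)

    def test_printed_variant_is_degenerate(self):
        # the sign-degenerate transcription of NDVI is identically one
        assert compute_vi("NDVI", [0.1, 0.2, 0.3, 0.4, 0.5], variant="printed") == 1.0

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            compute_vi("NOPE", [0.1] * 5)


class TestFeatureTable:
    def test_full_campaign_shape(self, feature_table):
        assert len(feature_table) == 270
        assert all(name in feature_table.columns for name in VI_NAMES)

    def test_single_observation(self, default_obs):
        t = build_feature_table(default_obs.iloc[[0]])
        assert len(t) == 1
        assert t[list(VI_NAMES)].notna().all().all()

    def test_degenerate_row_flagged_others_computed(self, default_obs):
        obs = default_obs.head(3).copy()
        obs.loc[obs.index[1], ["b475", "b560", "b668", "b717", "b842"]] = 0.0
        t = build_feature_table(obs)
        assert t.loc[1, list(VI_NAMES)].isna().any()
        assert t.loc[[0, 2], list(VI_NAMES)].notna().all().all()

    def test_empty_input_rejected(self, default_obs):
        with pytest.raises(ValueError):
            build_feature_table(default_obs.iloc[0:0])


class TestRanking:
    def _table(self, rng, n=120):
        lai = rng.uniform(1, 9, n)
        cols = {"plot_id": ["P"] * n, "stage_index": range(n)}
        cols.update({name: rng.normal(size=n) for name in VI_NAMES})
        cols["lai"] = lai
        return pd.DataFrame(cols), lai

    def test_exact_copy_of_target_dominates(self, rng):
        wins = 0
        for _ in range(10):
            table, lai = self._table(rng)
            table["NDVI"] = lai  # one feature equals the target exactly
            ranking = rank_importance(table, n_trees=200, seed=int(rng.integers(1e6)))
            wins += ranking.names[0] == "NDVI" and ranking.scores[0] > 0.5
        assert wins > 5

    def test_identical_copies_near_uniform(self, rng):
        table, lai = self._table(rng)
        base = lai + rng.normal(0, 1, len(lai))
        for name in VI_NAMES:
            table[name] = base
        scores = []
        for seed in range(5):
            r = rank_importance(table, n_trees=200, seed=seed)
            scores.append(r.scores)
        mean_scores = np.mean(scores, axis=0)
        assert mean_scores.max() - mean_scores.min() < 0.2

    def test_scores_normalized_and_descending(self, ranking):
        assert sum(ranking.scores) == pytest.approx(1.0, abs=1e-9)
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))

    def test_nir_indices_outrank_visible_only(self):
        """NIRv/EVI2 outrank VARI; the selected top-6 all use the NIR band."""
        visible_only = {"VARI"}
        wins_nirv = wins_evi2 = wins_top6 = 0
        for seed in range(10):
            obs = ricelai.generate_dataset(ricelai.SimulationConfig(seed=seed))
            names = rank_importance(ricelai.build_feature_table(obs), seed=seed).names
            pos = {n: i for i, n in enumerate(names)}
            wins_nirv += pos["NIRv"] < pos["VARI"]
            wins_evi2 += pos["EVI2"] < pos["VARI"]
            wins_top6 += not (set(names[:6]) & visible_only)
        assert wins_nirv > 5 and wins_evi2 > 5 and wins_top6 > 5

    def test_constant_target_rejected(self, rng):
        table, _ = self._table(rng)
        table["lai"] = 3.0
        with pytest.raises(ValueError):
            rank_importance(table, seed=0)


class TestSelection:
    def test_top_k_sizes(self, ranking):
        assert len(select_top_k(ranking, 6)) == 6
        assert select_top_k(ranking, 15) == ranking.names
        assert select_top_k(ranking, 1) == ranking.names[:1]

    @pytest.mark.parametrize("k", [0, 16])
    def test_out_of_range_k(self, ranking, k):
        with pytest.raises(ValueError):
            select_top_k(ranking, k)


class TestSequences:
    def test_sequence_count_conservation(self, sequence_data):
        assert len(sequence_data) == 270
        assert sequence_data.X.shape == (270, 9, 6)

    def test_first_stage_has_single_unmasked_step(self, feature_table, ranking):
        data = build_sequences(feature_table, select_top_k(ranking, 6))
        first = [i for i, s in enumerate(data.stage_indices) if s == 0]
        assert all(data.mask[i].sum() == 1 for i in first)
        # target corresponds to the last (always unmasked) step
        assert data.mask[:, -1].all()

    def test_window_one_degenerates_to_current_stage(self, feature_table, ranking):
        sel = select_top_k(ranking, 6)
        data = build_sequences(feature_table, sel, window=1)
        assert data.X.shape == (270, 1, 6)
        row = feature_table.set_index(["plot_id", "stage_index"])
        i = 17
        expected = row.loc[(data.plot_ids[i], data.stage_indices[i]), sel].to_numpy(float)
        np.testing.assert_allclose(data.X[i, 0], expected)

    def test_standardization_uses_supplied_stats(self, sequence_data):
        stats = sequence_data.feature_stats()
        std = sequence_data.standardized(stats)
        vals = std.X[std.mask]
        np.testing.assert_allclose(vals.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=0), 1, atol=1e-9)
        assert np.all(std.X[~std.mask] == 0)

    def test_unknown_feature_rejected(self, feature_table):
        with pytest.raises(KeyError):
            build_sequences(feature_table, ["NOPE"])
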