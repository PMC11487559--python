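import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcellstates as tcs
from tcellstates import ValidationError

from conftest import brute_force_u_fraction


def _matrix(values, genes=None, samples=None, stage="corrected"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return tcs.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), stage=stage
    )


class TestSelectBackground:
    def test_default_draw_is_5000_genes_100_per_bin(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.lognormal(1, 1, size=(10_000, 3)))
        bg = tcs.select_background(m, seed=5)
        assert len(bg.genes) == 5000
        assert len(set(bg.genes)) == 5000
        assert bg.n_bins == 50 and bg.per_bin == 100

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.lognormal(1, 1, size=(10_000, 2)))
        assert (
            tcs.select_background(m, seed=9).genes
            == tcs.select_background(m, seed=9).genes
        )
        assert (
            tcs.select_background(m, seed=9).genes
            != tcs.select_background(m, seed=10).genes
        )

    def test_draws_from_known_expression_deciles(self):
        # 100 genes with strictly decreasing pooled expression: gene g0 is
        # the highest, so bin k holds exactly genes g(10k)..g(10k+9)
        values = np.arange(100, 0, -1, dtype=float)[:, None] * [[1.0, 1.0]]
        m = _matrix(values)
        bg = tcs.select_background(m, n_bins=10, per_bin=5, seed=2)
        assert len(bg.genes) == 50
        for k in range(10):
            bin_members = {f"g{i}" for i in range(10 * k, 10 * k + 10)}
            drawn = set(bg.genes[5 * k : 5 * k + 5])
            assert drawn <= bin_members and len(drawn) == 5

    def test_shrinks_per_bin_when_matrix_is_small(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.lognormal(1, 1, size=(600, 2)))
        with pytest.warns(UserWarning, match="per_bin shrunk"):
            bg = tcs.select_background(m, n_bins=50, per_bin=100, seed=1, reserve=30)
        assert bg.per_bin == (600 - 30) // 50
        assert len(bg.genes) == 50 * bg.per_bin

    def test_too_few_genes_errors(self):
        m = _matrix(np.ones((20, 2)))
        with pytest.raises(ValidationError, match="bins"):
            tcs.select_background(m, n_bins=50, per_bin=100)
        m2 = _matrix(np.ones((120, 2)))
        with pytest.raises(ValidationError, match="cannot draw"):
            tcs.select_background(m2, n_bins=50, per_bin=100)


class TestRankSample:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((5, 1, 4, 3, 2), (5, 1, 4, 3, 2)),
            ((2, 2), (1.5, 1.5)),
            ((1, 1, 1, 9), (2, 2, 2, 4)),
        ],
    )
    def test_known_rankings(self, values, expected):
        assert tcs.rank_sample(np.array(values)).tolist() == list(expected)


class TestTcssPrime:
    def test_worked_example_both_modes(self):
        # markers {5, 1}, background {4, 3, 2}: pooled ranks are
        # markers (5, 1), background (4, 3, 2); U = 6 - 3 = 3
        pooled = np.array([4.0, 3.0, 2.0, 5.0, 1.0])  # background first
        ranks = tcs.rank_sample(pooled)
        marker_ranks = ranks[3:]
        assert tcs.tcss_prime(marker_ranks, 2, 3, mode="unit") == 0.5
        assert tcs.tcss_prime(marker_ranks, 2, 3, mode="printed") == pytest.approx(0.6)

    def test_extremes(self):
        top = np.array([9.0, 10.0])  # ranks 4,5 among N=5
        bottom = np.array([1.0, 2.0])
        bg_ranks_top = tcs.rank_sample(np.array([1.0, 2.0, 3.0, 9.0, 10.0]))[3:]
        bg_ranks_bottom = tcs.rank_sample(np.array([3.0, 4.0, 5.0, 1.0, 2.0]))[3:]
        assert tcs.tcss_prime(bg_ranks_top, 2, 3, mode="unit") == 1.0
        assert tcs.tcss_prime(bg_ranks_bottom, 2, 3, mode="unit") == 0.0

    def test_fewer_than_two_markers_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 markers"):
            tcs.tcss_prime(np.array([3.0]), 1, 4)

    def test_matches_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_mk = int(rng.integers(3, 11))
            n_bg = int(rng.integers(20, 201))
            # integer-valued draws produce plenty of ties
            vals = rng.integers(0, 30, size=n_mk + n_bg).astype(float)
            bg, mk = vals[:n_bg], vals[n_bg:]
            ranks = tcs.rank_sample(np.concatenate([bg, mk]))
            got = tcs.tcss_prime(ranks[n_bg:], n_mk, n_bg, mode="unit")
            assert got == pytest.approx(brute_force_u_fraction(mk, bg), abs=1e-12)

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=10),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=60),
    )
    def test_unit_mode_always_in_unit_interval(self, mk, bg):
        ranks = tcs.rank_sample(np.array(bg + mk))
        score = tcs.tcss_prime(ranks[len(bg):], len(mk), len(bg), mode="unit")
        assert 0.0 <= score <= 1.0


class TestReferencePercentage:
    def test_equal_expression_gives_all_ones(self):
        sp = np.array([1.0, 2.0, 0.0])
        assert tcs.reference_percentage(sp, sp).tolist() == [1.0, 1.0, 1.0]

    def test_half_reference_gives_half_weight(self):
        ref = np.array([2.0, 4.0])
        assert tcs.reference_percentage(ref / 2, ref).tolist() == [0.5, 0.5]

    def test_zero_reference_cannot_penalize(self):
        w = tcs.reference_percentage(np.array([0.0, 5.0]), np.array([0.0, 0.0]))
        assert w.tolist() == [1.0, 1.0]

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            tcs.reference_percentage(np.array([-1.0]), np.array([1.0]))

    @given(
        st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=20),
    )
    def test_weights_always_in_unit_interval(self, sp, ref):
        n = min(len(sp), len(ref))
        w = tcs.reference_percentage(np.array(sp[:n]), np.array(ref[:n]))
        assert ((w >= 0) & (w <= 1)).all()


class TestTcssFinal:
    def test_identity_and_scaling(self):
        assert tcs.tcss_final(0.8, np.ones(4)) == 0.8
        assert tcs.tcss_final(0.8, np.array([0.25, 0.75])) == pytest.approx(0.4)
        assert tcs.tcss_final(0.0, np.array([0.1, 0.9])) == 0.0

    def test_never_exceeds_prime(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            prime = rng.uniform(0, 1)
            w = rng.uniform(0, 1, size=rng.integers(1, 20))
            assert tcs.tcss_final(prime, w) <= prime + 1e-15


class TestScoreSamples:
    def test_planted_effect_separates_groups(self):
        cfg = tcs.default_states_config(effect=0.0)
        cfg["Cytotoxicity"] = tcs.StateConfig(16, 3.0)  # 8-fold up in group A
        bundle = tcs.generate_cohort(
            n_genes=6000, n_samples=16, states_config=cfg, seed=21
        )
        result = tcs.score_samples(
            bundle.expression,
            bundle.marker_sets,
            bundle.reference,
            bundle.housekeeping,
            seed=3,
        )
        scores = result.scores.loc["Cytotoxicity"]
        group_a = bundle.truth == "Cytotoxicity"
        assert scores[group_a.values].mean() > scores[~group_a.values].mean()

    def test_bitwise_deterministic(self, small_bundle):
        args = (
            small_bundle.expression,
            small_bundle.marker_sets,
            small_bundle.reference,
            small_bundle.housekeeping,
        )
        a = tcs.score_samples(*args, seed=4)
        b = tcs.score_samples(*args, seed=4)
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
        assert a.effective_markers == b.effective_markers

    def test_unit_scores_in_unit_interval(self, small_result):
        values = small_result.scores.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_gene_order_does_not_change_scores(self, small_bundle):
        shuffled = tcs.ExpressionMatrix(
            small_bundle.expression.data.sample(frac=1.0, random_state=0),
            stage="tpm",
        )
        a = tcs.score_samples(
            small_bundle.expression,
            small_bundle.marker_sets,
            small_bundle.reference,
            small_bundle.housekeeping,
            seed=4,
        )
        b = tcs.score_samples(
            shuffled,
            small_bundle.marker_sets,
            small_bundle.reference,
            small_bundle.housekeeping,
            seed=4,
        )
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), rtol=1e-12)

    def test_state_with_missing_markers_skipped_or_strict_error(self, small_bundle):
        expr = small_bundle.expression
        helper_markers = small_bundle.marker_sets["Helper"]
        pruned = tcs.ExpressionMatrix(
            expr.data.drop(index=helper_markers[1:]), stage="tpm"
        )
        with pytest.warns(UserWarning, match="Helper"):
            result = tcs.score_samples(
                pruned,
                small_bundle.marker_sets,
                small_bundle.reference,
                small_bundle.housekeeping,
            )
        assert "Helper" not in result.scores.index
        assert any("Helper" in w for w in result.warnings)
        with pytest.raises(ValidationError, match="Helper"):
            tcs.score_samples(
                pruned,
                small_bundle.marker_sets,
                small_bundle.reference,
                small_bundle.housekeeping,
                strict=True,
            )

    def test_monotone_transform_of_one_sample_preserves_rank_score(self):
        # with the background held fixed, the rank score depends on one
        # sample's values only through their ordering, so any strictly
        # monotone transform of that column leaves it unchanged
        rng = np.random.default_rng(17)
        n_bg, n_mk = 60, 6
        column = rng.lognormal(1, 1, size=n_bg + n_mk)
        transforms = [
            lambda v: 2.0 * v,
            lambda v: v + 5.0,
            lambda v: np.log2(v + 1.0),
            lambda v: v**3,
        ]
        base_ranks = tcs.rank_sample(column)
        base = tcs.tcss_prime(base_ranks[n_bg:], n_mk, n_bg, mode="unit")
        for f in transforms:
            ranks = tcs.rank_sample(f(column))
            got = tcs.tcss_prime(ranks[n_bg:], n_mk, n_bg, mode="unit")
            assert got == pytest.approx(base, abs=1e-12)

    def test_raising_marker_expression_never_lowers_rank_score(self, small_bundle):
        flat_ref = tcs.ReferenceSpectrum(
            pd.DataFrame(
                0.0,
                index=small_bundle.reference.genes,
                columns=small_bundle.reference.states,
            )
        )
        base = tcs.score_samples(
            small_bundle.expression,
            small_bundle.marker_sets,
            flat_ref,
            small_bundle.housekeeping,
            seed=6,
        )
        boosted_data = small_bundle.expression.data.copy()
        markers = small_bundle.marker_sets["Senescence"]
        boosted_data.loc[markers, boosted_data.columns[0]] *= 4.0
        # keep the housekeeping mean untouched: markers are not hk genes
        boosted = tcs.score_samples(
            tcs.ExpressionMatrix(boosted_data, stage="tpm"),
            small_bundle.marker_sets,
            flat_ref,
            small_bundle.housekeeping,
            seed=6,
        )
        s0 = boosted.scores.columns[0]
        assert (
            boosted.scores.at["Senescence", s0]
            >= base.scores.at["Senescence", s0] - 1e-12
        )

    def test_background_seed_stability_of_sample_ordering(self):
        # scoring is robust to the background draw: across seeds, the
        # per-state ordering of samples barely moves
        from scipy.stats import spearmanr

        bundle = tcs.generate_cohort(
            n_genes=12_000, n_samples=24, seed=31,
            states_config=tcs.default_states_config(effect=2.0),
        )
        results = [
            tcs.score_samples(
                bundle.expression,
                bundle.marker_sets,
                bundle.reference,
                bundle.housekeeping,
                seed=s,
            ).scores
            for s in range(20)
        ]
        for state in results[0].index:
            for other in results[1:]:
                rho = spearmanr(
                    results[0].loc[state].to_numpy(), other.loc[state].to_numpy()
                ).statistic
                assert rho >= 0.95
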