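import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topicphewas import (
    AssociationResult,
    bonferroni_threshold,
    fixed_effects_meta,
    select_significant_topics,
)
from topicphewas.meta_analysis import MetaResult


def wave_result(beta, se, wave="w", trait="topic0", status="ok"):
    if status != "ok":
        return AssociationResult(
            trait_id=trait, wave=wave, beta=float("nan"), se=float("nan"),
            stat=float("nan"), p=float("nan"), n=100, model="linear",
            status=status,
        )
    z = beta / se
    from scipy.stats import norm

    return AssociationResult(
        trait_id=trait, wave=wave, beta=beta, se=se, stat=z,
        p=max(2 * norm.sf(abs(z)), np.finfo(float).tiny), n=100,
        model="linear",
    )


def scalar_meta_oracle(betas, ses):
    """Independent scalar fixed-effects pooling, written longhand."""
    w = [1.0 / s**2 for s in ses]
    bp = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    sp = 1.0 / math.sqrt(sum(w))
    q = sum(wi * (bi - bp) ** 2 for wi, bi in zip(w, betas))
    return bp, sp, q


class TestFixedEffectsMeta:
    def test_equal_weight_symmetric_case(self):
        res = fixed_effects_meta(
            [wave_result(1.0, 1.0, "w1"), wave_result(3.0, 1.0, "w2")]
        )
        assert res.beta_pooled == pytest.approx(2.0, abs=1e-10)
        assert res.se_pooled == pytest.approx(math.sqrt(0.5), abs=1e-10)
        assert res.q_het == pytest.approx(2.0, abs=1e-10)
        assert res.df_het == 1

    def test_unequal_weight_closed_form(self):
        res = fixed_effects_meta(
            [wave_result(0.0, 1.0, "w1"), wave_result(2.0, 2.0, "w2")]
        )
        assert res.beta_pooled == pytest.approx(0.4, abs=1e-10)
        assert res.se_pooled == pytest.approx(1.0 / math.sqrt(1.25), abs=1e-10)

    def test_single_wave_is_identity(self):
        r = wave_result(0.7, 0.2)
        res = fixed_effects_meta([r])
        assert res.beta_pooled == pytest.approx(r.beta, abs=1e-12)
        assert res.se_pooled == pytest.approx(r.se, abs=1e-12)
        assert res.q_het == 0.0 and res.df_het == 0

    def test_skipped_waves_excluded_and_counted(self):
        res = fixed_effects_meta(
            [
                wave_result(1.0, 1.0, "w1"),
                wave_result(0, 0, "w2", status="skipped_low_frequency"),
            ]
        )
        assert res.n_waves_used == 1
        assert res.n_waves_skipped == 1
        assert res.beta_pooled == pytest.approx(1.0)

    def test_zero_usable_waves_is_an_error(self):
        with pytest.raises(ValueError, match="no usable wave"):
            fixed_effects_meta(
                [wave_result(0, 0, status="failed_separation")]
            )

    def test_mixed_traits_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            fixed_effects_meta(
                [wave_result(1, 1, trait="topic0"),
                 wave_result(1, 1, trait="topic1")]
            )

    def test_identical_waves_shrink_se_by_sqrt_w(self):
        results = [wave_result(0.5, 0.3, f"w{i}") for i in range(4)]
        res = fixed_effects_meta(results)
        assert res.beta_pooled == pytest.approx(0.5, abs=1e-12)
        assert res.se_pooled == pytest.approx(0.3 / 2.0, abs=1e-12)
        assert res.q_het == pytest.approx(0.0, abs=1e-20)

    def test_matches_statsmodels_reference(self):
        # independent cross-check against statsmodels' fixed-effects pooling
        from statsmodels.stats.meta_analysis import combine_effects

        betas = [0.12, -0.05, 0.31, 0.02]
        ses = [0.1, 0.25, 0.18, 0.07]
        res = fixed_effects_meta(
            [wave_result(b, s, f"w{i}") for i, (b, s) in
             enumerate(zip(betas, ses))]
        )
        ref = combine_effects(np.array(betas), np.array(ses) ** 2)
        assert res.beta_pooled == pytest.approx(ref.mean_effect_fe, abs=1e-10)
        assert res.se_pooled == pytest.approx(ref.sd_eff_w_fe, abs=1e-10)

    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5),
                st.floats(0.01, 3.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_pooled_se_never_exceeds_best_wave(self, pairs):
        results = [
            wave_result(b, s, f"w{i}") for i, (b, s) in enumerate(pairs)
        ]
        res = fixed_effects_meta(results)
        assert res.se_pooled <= min(s for _, s in pairs) + 1e-12
        assert res.q_het >= -1e-12
        bp, sp, q = scalar_meta_oracle(*zip(*pairs))
        assert res.beta_pooled == pytest.approx(bp, rel=1e-10, abs=1e-12)
        assert res.se_pooled == pytest.approx(sp, rel=1e-10)
        assert res.q_het == pytest.approx(q, rel=1e-8, abs=1e-10)

    def test_permutation_invariant_over_wave_order(self):
        results = [
            wave_result(0.1, 0.2, "w1"),
            wave_result(-0.3, 0.5, "w2"),
            wave_result(0.25, 0.15, "w3"),
        ]
        fwd = fixed_effects_meta(results)
        rev = fixed_effects_meta(results[::-1])
        assert fwd.beta_pooled == pytest.approx(rev.beta_pooled, abs=1e-14)
        assert fwd.se_pooled == pytest.approx(rev.se_pooled, abs=1e-14)
        assert fwd.q_het == pytest.approx(rev.q_het, abs=1e-12)


class TestBonferroni:
    def test_fifty_topics_gives_one_in_a_thousand(self):
        assert bonferroni_threshold(50, 0.05) == 0.001

    def test_single_test_leaves_alpha(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    def test_thousand_tests(self):
        assert bonferroni_threshold(1000, 0.05) == pytest.approx(5e-5)

    @pytest.mark.parametrize("n,alpha", [(0, 0.05), (10, 0.0), (10, 1.0)])
    def test_invalid_arguments(self, n, alpha):
        with pytest.raises(ValueError):
            bonferroni_threshold(n, alpha)


class TestSelectSignificant:
    def make_meta(self, trait, p):
        return MetaResult(
            trait_id=trait, beta_pooled=0.1, se_pooled=0.05, z=2.0, p=p,
            q_het=0.0, df_het=1, n_waves_used=2,
        )

    def test_all_at_or_above_threshold_empty(self):
        metas = [self.make_meta("a", 0.01), self.make_meta("b", 0.5)]
        assert select_significant_topics(metas, 0.01) == []

    def test_boundary_is_strict(self):
        metas = [self.make_meta("a", 0.001)]
        assert select_significant_topics(metas, 0.001) == []
        assert select_significant_topics(metas, 0.0011) == ["a"]

    def test_sorted_by_p_ascending(self):
        metas = [
            self.make_meta("a", 1e-3),
            self.make_meta("b", 1e-6),
            self.make_meta("c", 0.5),
        ]
        assert select_significant_topics(metas, 0.01) == ["b", "a"]
        assert metas[1].significant and not metas[2].significant
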