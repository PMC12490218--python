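import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisprog.signature import (
    EffectSignature,
    cis_sen_score,
    cis_sen_scores,
    classify_sensitivity,
    cohens_d,
    extract_signature,
    signature_agreement,
    signature_gene_sets,
    universal_signature,
)
from cisprog.simulate import SimConfig, generate_experiment


class TestCohensD:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [3, 4, 5], -2.0),  # pooled SD = 1
            ([5, 5, 6, 6], [5, 5, 6, 6], 0.0),
            ([3, 4, 5], [1, 2, 3], 2.0),
        ],
    )
    def test_hand_values(self, a, b, expected):
        assert cohens_d(a, b) == pytest.approx(expected)

    def test_zero_pooled_sd_flagged_missing(self):
        assert np.isnan(cohens_d([1, 1], [1, 1]))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1], [1, 2])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        shift=st.floats(-10, 10),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_affine_invariance(self, a, b, shift, scale):
        d = cohens_d(a, b)
        if np.isnan(d):
            return
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-9)
        a2 = [scale * x + shift for x in a]
        b2 = [scale * x + shift for x in b]
        d2 = cohens_d(a2, b2)
        if np.isnan(d2):
            # affine transform cancelled the group variances at float precision
            return
        assert d2 == pytest.approx(d, rel=1e-6, abs=1e-9)


class TestExtractSignature:
    def test_no_treatment_effect_gives_null_signature(self, small_bundle):
        bundle = small_bundle
        ctrl = bundle.mask(dose_fraction=0.0)
        # overwrite treated counts with control counts -> identical groups
        counts = bundle.counts.copy()
        treated_idx = np.flatnonzero(~ctrl)
        ctrl_idx = np.flatnonzero(ctrl)
        counts[treated_idx] = counts[ctrl_idx[np.arange(treated_idx.size) % ctrl_idx.size]]
        clone = type(bundle)(
            counts=counts, cell_meta=bundle.cell_meta, gene_ids=bundle.gene_ids
        )
        sig = extract_signature(clone)
        vals = sig.d_values[~np.isnan(sig.d_values)]
        assert np.all(np.abs(vals) < 0.35)  # no systematic shift at this n

    def test_constant_gene_flagged_missing(self, small_bundle):
        # a gene constant on the normalized scale (all-zero counts) must be
        # flagged NaN rather than infinite
        counts = small_bundle.counts.copy()
        counts[:, 1] = 0
        sig = extract_signature(
            type(small_bundle)(
                counts=counts, cell_meta=small_bundle.cell_meta, gene_ids=small_bundle.gene_ids
            )
        )
        assert np.isnan(sig.d_values[1])

    def test_recovers_planted_response(self, default_bundle):
        sig = extract_signature(default_bundle)
        r = np.corrcoef(sig.d_values, default_bundle.ground_truth.response_vector)[0, 1]
        assert r > 0.8


class TestAgreementAndUniversal:
    def _sig(self, d, exp="e1"):
        return EffectSignature(exp, [f"g{i}" for i in range(len(d))], np.array(d, float), 5, 5)

    def test_identical_and_negated(self):
        s = self._sig([1.0, -0.5, 0.2, 0.8])
        m = signature_agreement([s, self._sig([1.0, -0.5, 0.2, 0.8], "e2")])
        assert m.iloc[0, 1] == pytest.approx(1.0)
        m = signature_agreement([s, self._sig([-1.0, 0.5, -0.2, -0.8], "e2")])
        assert m.iloc[0, 1] == pytest.approx(-1.0)

    def test_nan_genes_dropped_pairwise(self):
        a = self._sig([1.0, np.nan, 0.0, 2.0], "a")
        b = self._sig([2.0, 5.0, 0.0, 4.0], "b")
        m = signature_agreement([a, b])
        # correlation over the 3 shared genes [1,0,2] vs [2,0,4] -> exactly 1
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_universal_is_identity_for_one(self):
        s = self._sig([0.3, -0.1, 2.0])
        u = universal_signature([s])
        assert np.allclose(u.d_values, s.d_values)
        assert u.experiment_id == "universal"

    def test_universal_averages_and_skips_missing(self):
        a = self._sig([1.0, 0.0, np.nan], "a")
        b = self._sig([0.0, 1.0, 4.0], "b")
        u = universal_signature([a, b])
        assert np.allclose(u.d_values, [0.5, 0.5, 4.0])

    def test_replicate_signatures_agree(self, small_config):
        sigs = [
            extract_signature(generate_experiment(small_config, 0, r)) for r in range(2)
        ]
        m = signature_agreement(sigs)
        assert m.iloc[0, 1] > 0.5


class TestCisSenScore:
    def _signature(self, n, top, bottom):
        """Signature whose top set is genes [0:top], bottom set [n-bottom:]."""
        d = np.linspace(1.0, -1.0, n)
        return EffectSignature("e", [f"g{i:03d}" for i in range(n)], d, 5, 5)

    def test_hand_value(self):
        sig = self._signature(4, 1, 1)
        counts = np.zeros(4, int)
        counts[0] = 7  # top set (1 gene at 5% of 4 -> capped to 1)
        counts[2:] = [1, 2]  # bottom set = 50% of 4 = 2 genes, sum 3
        top_idx, bottom_idx, info = signature_gene_sets(sig, 1000, 10000)
        assert info["scaled_to_panel"]
        score = cis_sen_score(counts, sig)
        assert score == pytest.approx(np.log2(8 / 4))

    def test_all_zero_cell_scores_zero(self):
        sig = self._signature(100, 5, 50)
        assert cis_sen_score(np.zeros(100, int), sig) == 0.0

    def test_equal_sums_score_zero(self):
        sig = self._signature(40, 2, 20)
        top_idx, bottom_idx, _ = signature_gene_sets(sig, 2, 20)
        counts = np.zeros(40, int)
        counts[top_idx] = 5
        counts[bottom_idx[:2]] = 5
        assert cis_sen_score(counts, sig, 2, 20) == 0.0

    def test_permutation_within_sets_invariant_and_monotone(self):
        rng = np.random.default_rng(0)
        sig = self._signature(200, 10, 100)
        counts = rng.integers(0, 20, size=200)
        top_idx, _, _ = signature_gene_sets(sig, 10, 100)
        base = cis_sen_score(counts, sig, 10, 100)
        shuffled = counts.copy()
        shuffled[top_idx] = rng.permutation(counts[top_idx])
        assert cis_sen_score(shuffled, sig, 10, 100) == pytest.approx(base)
        bumped = counts.copy()
        bumped[top_idx[3]] += 1
        assert cis_sen_score(bumped, sig, 10, 100) > base

    def test_alternative_thresholds_consistent(self, default_bundle):
        """Score variants (top 1/5/10% vs rest) rank cells consistently."""
        from scipy.stats import spearmanr

        sig = extract_signature(default_bundle)
        stratum = default_bundle.mask(dose_fraction=2.0, duration_h=24.0)
        counts = default_bundle.counts[stratum]
        n = len(sig.gene_ids)
        default = cis_sen_scores(counts, sig)  # 5% / 50% panel scaling
        for frac in (0.01, 0.05, 0.10):
            top = max(1, int(frac * n))
            alt = cis_sen_scores(counts, sig, top_n=top, bottom_n=n - top)
            assert spearmanr(default, alt).statistic > 0.8

    def test_discriminates_planted_responsiveness(self, default_bundle):
        from scipy.stats import mannwhitneyu

        sig = extract_signature(default_bundle)
        stratum = default_bundle.mask(dose_fraction=2.0, duration_h=24.0)
        scores = cis_sen_scores(default_bundle.counts[stratum], sig)
        resp = default_bundle.ground_truth.cell_responsiveness[stratum]
        top = resp >= np.quantile(resp, 0.9)
        bottom = resp <= np.quantile(resp, 0.1)
        u = mannwhitneyu(scores[top], scores[bottom]).statistic
        auc = u / (top.sum() * bottom.sum())
        assert auc >= 0.9


class TestClassification:
    def test_quartile_split(self):
        calls = classify_sensitivity(np.arange(1.0, 9.0), fraction=0.25)
        cls = calls.set_index("cis_sen_score")["sens_class"]
        assert set(cls[cls == "more_sensitive"].index) == {7.0, 8.0}
        assert set(cls[cls == "less_sensitive"].index) == {1.0, 2.0}
        assert (cls == "unlabeled").sum() == 4

    def test_median_split_labels_everyone(self):
        calls = classify_sensitivity(np.arange(1.0, 9.0), fraction=0.5)
        assert (calls["sens_class"] == "unlabeled").sum() == 0

    def test_degenerate_scores_warn_and_fill_quota(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            calls = classify_sensitivity(np.full(8, 3.0), fraction=0.25)
        assert (calls["sens_class"] == "more_sensitive").sum() == 2
        assert (calls["sens_class"] == "less_sensitive").sum() == 2

    def test_class_counts_match_fraction(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=103)
        calls = classify_sensitivity(scores, fraction=0.25)
        quota = 0.25 * len(scores)
        for cls in ("more_sensitive", "less_sensitive"):
            assert abs((calls["sens_class"] == cls).sum() - quota) <= 1

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            classify_sensitivity(np.array([1.0, 2.0, 3.0]))
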