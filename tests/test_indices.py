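import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from empoweranc import indices as idx


def all_at(schema, pos):
    """Responses with every item at its min (pos=0) or max (pos=-1) level."""
    return np.array([[it.levels[pos] for it in schema.items]])


class TestWeaiScore:
    def test_extremes_span_0_to_100(self):
        schema = idx.default_schema()
        assert idx.score_weai(all_at(schema, -1), schema).aggregate[0] == 100.0
        assert idx.score_weai(all_at(schema, 0), schema).aggregate[0] == 0.0

    def test_equal_domain_weights(self):
        # one domain maximal, the others minimal -> exactly a third of 100
        schema = idx.default_schema()
        resp = all_at(schema, 0)
        resp[0, schema.domain_indices("decision")] = 2
        agg = idx.score_weai(resp, schema).aggregate[0]
        assert agg == pytest.approx(100.0 / 3.0, abs=1e-12)

    def test_subscales_are_raw_sums(self):
        schema = idx.default_schema()
        s = idx.score_weai(all_at(schema, -1), schema)
        assert s.decision[0] == 14 and s.movement[0] == 9 and s.assets[0] == 10

    def test_invalid_response_reports_item(self):
        schema = idx.default_schema()
        resp = all_at(schema, 0)
        resp[0, 4] = 7
        with pytest.raises(ValueError, match="item 4"):
            idx.score_weai(resp, schema)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_in_every_item(self, data):
        schema = idx.default_schema()
        resp = np.array(
            [
                [data.draw(st.sampled_from(it.levels)) for it in schema.items]
            ]
        )
        base = idx.score_weai(resp, schema).aggregate[0]
        j = data.draw(st.integers(0, 14))
        levels = schema.items[j].levels
        pos = levels.index(resp[0, j])
        if pos == len(levels) - 1:
            return
        bumped = resp.copy()
        bumped[0, j] = levels[pos + 1]
        assert idx.score_weai(bumped, schema).aggregate[0] >= base


class TestCategorizeQuantile:
    def test_distinct_scores_split_25_50_25(self):
        cats, cuts = idx.categorize_quantile(np.arange(1.0, 101.0))
        assert (cats == "low").sum() == 25
        assert (cats == "medium").sum() == 50
        assert (cats == "high").sum() == 25
        assert cuts[0] < cuts[1]

    def test_heavy_ties_follow_threshold_rule(self):
        # hand enumeration on sorted [1,1,1,1,1,2,3,3,3,3,4,5]: interpolated
        # cutpoints are q25 = 1.0 and q75 = 3.0; the < / >= rule puts every 1
        # in medium (nothing is strictly below 1) and every 3 in high, so the
        # realized split is 0 / 6 / 6 instead of 3 / 6 / 3
        scores = np.array([1, 1, 1, 1, 1, 2, 3, 3, 3, 3, 4, 5], dtype=float)
        cats, cuts = idx.categorize_quantile(scores)
        assert cuts == (1.0, 3.0)
        assert (cats == "low").sum() == 0
        assert (cats == "medium").sum() == 6
        assert (cats == "high").sum() == 6

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            idx.categorize_quantile(np.ones(20))
        with pytest.raises(ValueError, match="4 distinct"):
            idx.categorize_quantile(np.array([1.0, 2.0, 1.0, 2.0, 1.0]))


class TestSwperPca:
    @staticmethod
    def block_items(n=600, noise=0.5, seed=5):
        """Items driven by three independent block latents."""
        rng = np.random.default_rng(seed)
        schema = idx.default_schema()
        latents = {d: rng.normal(0, 1, n) for d in idx.DOMAINS}
        X = np.zeros((n, 15), dtype=int)
        for j, item in enumerate(schema.items):
            t = latents[item.domain] + rng.normal(0, noise, n)
            L = len(item.levels)
            cuts = (-1.0 + 2.0 * np.arange(1, L) / L) * 1.1
            X[:, j] = np.asarray(item.levels)[np.searchsorted(cuts, t)]
        return X, schema

    def test_components_recover_blocks(self):
        X, schema = self.block_items()
        pca = idx.score_swper_pca(X, schema)
        # each retained component loads predominantly on one domain block,
        # and the three components cover the three blocks
        assigned = set()
        for k in range(3):
            load = np.abs(pca.loadings[:, k])
            per_domain = {
                d: load[schema.domain_indices(d)].mean() for d in idx.DOMAINS
            }
            top = max(per_domain, key=per_domain.get)
            assert np.argmax(load) in set(schema.domain_indices(top))
            assigned.add(top)
        assert assigned == set(idx.DOMAINS)
        assert set(pca.matched_subscale) == set(idx.DOMAINS)

    def test_variance_explained_non_increasing(self):
        X, schema = self.block_items(seed=8)
        ve = idx.score_swper_pca(X, schema).variance_explained
        assert ve[0] >= ve[1] >= ve[2] > 0

    def test_duplicating_rows_leaves_loadings_unchanged(self):
        X, schema = self.block_items(n=200, seed=9)
        a = idx.score_swper_pca(X, schema)
        b = idx.score_swper_pca(np.vstack([X, X]), schema)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-10)

    def test_scores_pairwise_uncorrelated(self):
        X, schema = self.block_items(seed=11)
        s = idx.score_swper_pca(X, schema).scores
        c = np.corrcoef(s.T)
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_sign_aligned_with_subscales(self):
        X, schema = self.block_items(seed=13)
        pca = idx.score_swper_pca(X, schema)
        from empoweranc.indices import score_weai

        weai = score_weai(X, schema)
        for k, d in enumerate(pca.matched_subscale):
            r = np.corrcoef(pca.scores[:, k], weai.subscale(d))[0, 1]
            assert r > 0


class TestWami:
    def test_published_scale_extremes(self):
        top = idx.score_wami(1, 1, np.ones((1, 8)), 16, 500)
        assert top.score[0] == 32.0
        bottom = idx.score_wami(0, 0, np.zeros((1, 8)), 0, 0)
        assert bottom.score[0] == 0.0

    def test_printed_tercile_cutoffs(self):
        cats = idx.categorize_wami([16.9, 17.0, 20.9, 21.0])
        assert list(cats) == ["low", "medium", "medium", "high"]

    def test_out_of_range_components_rejected(self):
        with pytest.raises(ValueError):
            idx.score_wami(2, 0, np.zeros((1, 8)), 5, 100)
        with pytest.raises(ValueError):
            idx.score_wami(1, 0, np.zeros((1, 8)), -1, 100)


class TestWealthPca:
    def test_recovers_latent_wealth_gradient(self, rng):
        n = 800
        latent = rng.normal(0, 1, n)
        cuts = np.linspace(-2, 2, 43)
        p = 1 / (1 + np.exp(-(2.0 * latent[:, None] + cuts[None, :])))
        assets = (rng.random((n, 43)) < p).astype(float)
        pc = idx.wealth_pca(assets)
        assert np.corrcoef(pc, latent)[0, 1] > 0.9
        assert abs(pc.mean()) < 1e-10
        assert np.corrcoef(pc, assets.sum(1))[0, 1] > 0

    def test_constant_assets_rejected(self):
        with pytest.raises(ValueError):
            idx.wealth_pca(np.ones((50, 4)))
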