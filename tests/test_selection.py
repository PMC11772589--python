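"""Multi-trait selection: marginal likelihood oracles, search, FDR, filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

import trimodalqtl as tq
from trimodalqtl.selection import _model_size_log_prior
from conftest import make_window


def enumerate_mppi(x, y, g=None):
    """Exhaustive-enumeration posterior inclusion probabilities (oracle)."""
    n, k = x.shape
    g = float(n) if g is None else g
    scores = {}
    for r in range(k + 1):
        for comb in itertools.combinations(range(k), r):
            scores[comb] = tq.log_marginal_likelihood(x, y, comb, g) + _model_size_log_prior(r, k)
    mx = max(scores.values())
    weights = {m: np.exp(s - mx) for m, s in scores.items()}
    total = sum(weights.values())
    mppi = np.zeros(k)
    for m, w in weights.items():
        for j in m:
            mppi[j] += w
    return mppi / total


class TestDefineWindows:
    baits = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 10_400,
                           "bait_id": "b1", "egene": "G1"}])
    variants = pd.DataFrame([{"chrom": "chr1", "pos": 10_100, "variant_id": "rs1"}])
    promoters = pd.DataFrame([{"egene": "G1", "chrom": "chr1", "pos": 500_000}])

    def test_intersection_of_expansions(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 12_000, "end": 12_500,
                               "peak_id": "p1"}])
        win = tq.define_windows(self.baits, peaks, self.variants, self.promoters)
        assert len(win) == 1
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (7_000, 15_400)

    def test_disjoint_expansions_give_no_window(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 40_000, "end": 40_500,
                               "peak_id": "p1"}])
        win = tq.define_windows(self.baits, peaks, self.variants, self.promoters)
        assert len(win) == 0

    def test_dpnii_flagged_variant_drops_window(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 12_000, "end": 12_500,
                               "peak_id": "p1"}])
        win = tq.define_windows(self.baits, peaks, self.variants, self.promoters,
                                dpnii_flagged_variants={"rs1"})
        assert len(win) == 0

    def test_variant_near_promoter_drops_window(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 12_000, "end": 12_500,
                               "peak_id": "p1"}])
        close_prom = pd.DataFrame([{"egene": "G1", "chrom": "chr1", "pos": 19_100}])
        # variant at 10,100 is 9 kb from the promoter -> dropped
        win = tq.define_windows(self.baits, peaks, self.variants, close_prom)
        assert len(win) == 0

    def test_malformed_interval_reports_line(self):
        bad = pd.DataFrame([{"chrom": "chr1", "start": 500, "end": 100, "bait_id": "b"}])
        with pytest.raises(ValueError, match="line"):
            tq.define_windows(bad, bad, self.variants, self.promoters)


class TestLogMarginalLikelihood:
    def test_null_model_closed_form(self, rng):
        x, y = make_window(rng, n=60, k=4)
        got = tq.log_marginal_likelihood(x, y, (), 60.0)
        expect = -(59 / 2) * np.log((y**2).sum(axis=0)).sum()
        assert got == pytest.approx(expect, rel=1e-12)

    def test_index_order_invariance(self, rng):
        x, y = make_window(rng, n=60, k=5)
        assert tq.log_marginal_likelihood(x, y, (3, 1), 60.0) == pytest.approx(
            tq.log_marginal_likelihood(x, y, (1, 3), 60.0), rel=1e-12)

    def test_duplicated_column_is_rank_neutral(self, rng):
        x, y = make_window(rng, n=60, k=4)
        x_dup = np.column_stack([x, x[:, 2]])  # column 4 duplicates column 2
        a = tq.log_marginal_likelihood(x, y, (2,), 60.0)
        b = tq.log_marginal_likelihood(x_dup, y, (2, 4), 60.0)
        assert a == pytest.approx(b, rel=1e-10)

    def test_two_variant_brute_force_oracle(self, rng):
        """Direct dense-projection evaluation of the g-prior marginal."""
        n, g = 40, 40.0
        x, y = make_window(rng, n=n, k=2)
        gamma = (0, 1)
        h = x @ np.linalg.inv(x.T @ x) @ x.T
        expect = 0.0
        for t in range(3):
            yt = y[:, t]
            expect += -(2 / 2) * np.log(1 + g) - ((n - 1) / 2) * np.log(
                yt @ yt - g / (1 + g) * yt @ h @ yt)
        got = tq.log_marginal_likelihood(x, y, gamma, g)
        assert got == pytest.approx(expect, rel=1e-10)


class TestSearch:
    def test_mppi_matches_enumeration_small_window(self, rng):
        x, y = make_window(rng, n=80, k=5, effects=np.array(
            [[0, 0, 0], [0.4, 0.3, 0.5], [0, 0, 0], [0, 0, 0], [0, 0, 0]]))
        oracle = enumerate_mppi(x, y)
        res = tq.search_models(x, y, n_iter=8000, burn_in=2000, seed=4)
        assert np.abs(res.mppi - oracle).max() < 0.05

    def test_planted_variant_recovered(self, rng):
        hits = 0
        for rep in range(10):
            b = np.zeros((8, 3))
            b[5] = [0.65, 0.65, 0.65]  # per-trait R^2 ~ 0.3
            x, y = make_window(np.random.default_rng(rep), n=100, k=8, effects=b)
            res = tq.search_models(x, y, n_iter=4000, burn_in=1000, seed=rep)
            hits += int(np.argmax(res.mppi) == 5)
        assert hits >= 9

    def test_pure_noise_prefers_null_model(self):
        nulls = 0
        for rep in range(10):
            x, y = make_window(np.random.default_rng(100 + rep), n=100, k=8)
            res = tq.search_models(x, y, n_iter=4000, burn_in=1000, seed=rep)
            nulls += int(res.best_model == ())
        assert nulls > 5

    def test_bad_iteration_counts(self, rng):
        x, y = make_window(rng, n=30, k=3)
        with pytest.raises(ValueError):
            tq.search_models(x, y, n_iter=100, burn_in=100)

    def test_seeded_determinism(self, rng):
        x, y = make_window(rng, n=50, k=4)
        a = tq.search_models(x, y, n_iter=2000, burn_in=500, seed=9)
        b = tq.search_models(x, y, n_iter=2000, burn_in=500, seed=9)
        assert np.array_equal(a.mppi, b.mppi)
        assert a.best_model == b.best_model


class TestFdrSelect:
    def test_worked_examples(self):
        assert tq.fdr_select(np.array([0.99, 0.98, 0.50]), 0.05) == [0, 1]
        assert tq.fdr_select(np.array([0.99, 0.98, 0.50]), 0.05, rule="cumulative_sum") == [0, 1]
        assert tq.fdr_select(np.array([0.2, 0.2, 0.2]), 0.05) == []
        assert tq.fdr_select(np.array([1.0]), 0.05) == [0]

    def test_brute_force_prefix_property(self, rng):
        """Selection equals the best prefix over the descending-mPPI order."""
        for _ in range(200):
            k = int(rng.integers(1, 12))
            mppi = rng.random(k)
            got = tq.fdr_select(mppi, 0.05)
            order = np.lexsort((np.arange(k), -mppi))
            best = []
            for j in range(1, k + 1):
                if np.mean(1 - mppi[order[:j]]) <= 0.05:
                    best = sorted(order[:j].tolist())
            assert got == best

    def test_monotone_in_q(self, rng):
        for _ in range(50):
            mppi = rng.random(8)
            small = set(tq.fdr_select(mppi, 0.02))
            large = set(tq.fdr_select(mppi, 0.10))
            assert small <= large


class TestBMA:
    def test_single_model_equals_conditional_mean(self, rng):
        n = 60
        x, y = make_window(rng, n=n, k=3)
        model = frozenset({1})
        beta, se, z = tq.bma_effects({model: 10}, x, y, g=float(n))
        xs = x[:, [1]]
        shrink = n / (n + 1)
        expect = shrink * (np.linalg.pinv(xs.T @ xs) @ xs.T @ y)
        assert np.allclose(beta[1], expect[0])
        assert np.all(beta[[0, 2]] == 0)

    def test_two_equal_weight_models_average(self, rng):
        n = 60
        x, y = make_window(rng, n=n, k=3)
        b1, _, _ = tq.bma_effects({frozenset({0}): 1}, x, y, g=float(n))
        b2, _, _ = tq.bma_effects({frozenset({1}): 1}, x, y, g=float(n))
        both, _, _ = tq.bma_effects({frozenset({0}): 1, frozenset({1}): 1}, x, y, g=float(n))
        assert np.allclose(both, (b1 + b2) / 2)

    def test_null_only_visits_give_zero_z(self, rng):
        x, y = make_window(rng, n=40, k=2)
        beta, se, z = tq.bma_effects({frozenset(): 5}, x, y, g=40.0)
        assert np.all(beta == 0) and np.all(z == 0)


class TestFinalize:
    def _selection(self, rows):
        df = pd.DataFrame(rows)
        df["fdr_selected"] = True
        return df

    def test_kept_and_concordant(self):
        sel = self._selection([{"variant_id": "v1", "mppi": 0.99, "beta_chic": 0.007,
                                "beta_atac": 0.002, "beta_rna": 0.005}])
        bias = pd.DataFrame([{"variant_id": "v1", "ai0": 0.5}])
        out = tq.finalize_trimodal(sel, bias_table=bias)
        assert len(out["final"]) == 1
        assert bool(out["final"].loc[0, "concordant"])

    def test_small_chic_effect_filtered(self):
        sel = self._selection([{"variant_id": "v1", "mppi": 0.99, "beta_chic": 0.004,
                                "beta_atac": 0.002, "beta_rna": 0.005}])
        out = tq.finalize_trimodal(sel)
        assert len(out["final"]) == 0
        assert out["dropped"].loc[0, "reason"] == "small_effect"

    def test_bias_and_missing_bias_drop(self):
        sel = self._selection([
            {"variant_id": "v1", "mppi": 0.9, "beta_chic": 0.01, "beta_atac": 0.01,
             "beta_rna": 0.01},
            {"variant_id": "v2", "mppi": 0.9, "beta_chic": 0.01, "beta_atac": 0.01,
             "beta_rna": 0.01},
        ])
        bias = pd.DataFrame([{"variant_id": "v1", "ai0": 0.35}])
        out = tq.finalize_trimodal(sel, bias_table=bias)
        reasons = dict(zip(out["dropped"]["variant_id"], out["dropped"]["reason"]))
        assert reasons == {"v1": "discarded_bias", "v2": "missing_bias"}

    def test_random_sign_null_concordance_is_quarter(self):
        """Exact enumeration: 2 of the 8 sign patterns are all-concordant."""
        patterns = list(itertools.product([-1, 1], repeat=3))
        concordant = [p for p in patterns if len(set(p)) == 1]
        assert len(concordant) / len(patterns) == 0.25
        rows = []
        for i, p in enumerate(patterns):
            rows.append({"variant_id": f"v{i}", "mppi": 0.99,
                         "beta_chic": 0.01 * p[0], "beta_atac": 0.01 * p[1],
                         "beta_rna": 0.01 * p[2]})
        out = tq.finalize_trimodal(self._selection(rows))
        assert out["concordant_fraction"] == pytest.approx(0.25)


class TestSelectorFacade:
    def test_fit_exposes_sklearn_style_attributes(self, rng):
        b = np.zeros((6, 3))
        b[2] = [0.8, 0.7, 0.9]
        x, y = make_window(rng, n=80, k=6, effects=b)
        sel = tq.TrimodalSelector(n_iter=4000, burn_in=1000, seed=2).fit(x, y)
        assert sel.mppi_.shape == (6,)
        assert 2 in sel.best_model_
        assert 2 in sel.fdr_set_
        assert sel.bma_beta_.shape == (6, 3)
        df = sel.summary()
        assert {"variant_id", "mppi", "fdr_selected", "beta_chic", "z_rna"} <= set(df.columns)
        assert sel.get_params()["n_iter"] == 4000
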