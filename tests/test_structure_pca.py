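"""Correlation structure, timepoint-specific PCA and the unified index."""

import numpy as np
import pandas as pd
import pytest

from hrvpipe.hrv_battery import METRIC_REGISTRY
from hrvpipe.structure_pca import (
    PCAResultSet,
    compare_structures,
    correlation_summary,
    domain_contributions,
    fit_pca,
    select_k,
    unified_index,
)


def _zmat(n, m, seed=0, factors=None):
    rng = np.random.default_rng(seed)
    if factors:
        f = rng.normal(size=(n, factors))
        load = rng.normal(size=(m, factors))
        x = f @ load.T + 0.01 * rng.normal(size=(n, m))
    else:
        x = rng.normal(size=(n, m))
    if n > 1:
        x = (x - x.mean(0)) / x.std(0)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(n)],
                        columns=[f"m{i}" for i in range(m)])


class TestCorrelationSummary:
    def test_pair_count_formula(self):
        s = correlation_summary(_zmat(30, 94, seed=1))
        assert s.n_pairs == 94 * 93 // 2 == 4371

    def test_independent_columns_low_mean_abs_r(self):
        s = correlation_summary(_zmat(500, 40, seed=2))
        assert s.mean_abs_r < 0.1

    def test_duplicate_pair_counted(self):
        m = _zmat(30, 10, seed=3)
        m["m9"] = m["m0"]
        s = correlation_summary(m)
        assert s.high_pair_count >= 1

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError):
            correlation_summary(_zmat(3, 5))


class TestCompareStructures:
    def test_self_comparison_p_is_one(self):
        m = _zmat(20, 12, seed=4)
        res = compare_structures(m, m, n_perm=200, seed=0)
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_low_n_perm_refused(self):
        m = _zmat(20, 12, seed=5)
        with pytest.raises(ValueError):
            compare_structures(m, m, n_perm=50)

    def test_detects_halved_loadings(self):
        # structure B built with halved factor loadings: weaker correlations
        rng = np.random.default_rng(6)
        f = rng.normal(size=(28, 2))
        load = rng.normal(size=(20, 2))
        a = f @ load.T + 0.5 * rng.normal(size=(28, 20))
        f2 = rng.normal(size=(28, 2))
        b = f2 @ (0.3 * load).T + 0.5 * rng.normal(size=(28, 20))
        cols = [f"m{i}" for i in range(20)]
        res = compare_structures(pd.DataFrame(a, columns=cols),
                                 pd.DataFrame(b, columns=cols),
                                 n_perm=300, seed=1)
        assert res["p_value"] < 0.05

    def test_null_p_values_roughly_uniform(self):
        # modest replicate count: check no gross anti-conservatism
        rng = np.random.default_rng(7)
        ps = []
        for i in range(30):
            a = pd.DataFrame(rng.normal(size=(14, 10)),
                             columns=[f"m{j}" for j in range(10)])
            b = pd.DataFrame(rng.normal(size=(14, 10)),
                             columns=[f"m{j}" for j in range(10)])
            ps.append(compare_structures(a, b, n_perm=100, seed=i)["p_value"])
        assert (np.array(ps) < 0.05).mean() < 0.2


class TestFitPCA:
    def test_select_k_rule_arithmetic(self):
        ratios = np.array([0.50, 0.25, 0.10, 0.08, 0.07])
        assert select_k(ratios) == 3  # 0.85 >= 0.80 first at 3

    def test_k_minimal(self):
        m = _zmat(28, 40, seed=8, factors=4)
        pca = fit_pca(m)
        cum = np.cumsum(pca.explained_ratio)
        assert cum[pca.k_selected - 1] >= 0.80 - 1e-12
        if pca.k_selected > 1:
            assert cum[pca.k_selected - 2] < 0.80

    def test_three_orthogonal_factors_low_noise(self):
        # three equal-variance orthogonal latent dimensions, noise -> 0
        rng = np.random.default_rng(9)
        f, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        load = rng.normal(size=(25, 3))
        load /= np.linalg.norm(load, axis=0)  # equal variance per dimension
        x = f @ load.T + 1e-6 * rng.normal(size=(30, 25))
        x = (x - x.mean(0)) / x.std(0)
        m = pd.DataFrame(x, columns=[f"m{i}" for i in range(25)])
        assert fit_pca(m).k_selected == 3

    def test_sign_convention_deterministic(self):
        m = _zmat(25, 15, seed=10, factors=3)
        pca = fit_pca(m)
        for c in pca.loadings.columns:
            lead = pca.loadings[c].abs().idxmax()
            assert pca.loadings.loc[lead, c] > 0

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError):
            fit_pca(_zmat(1, 5))


class TestUnifiedIndex:
    def test_k1_equals_pc1_score(self):
        m = _zmat(20, 10, seed=11, factors=1)
        pca = fit_pca(m)
        assert pca.k_selected == 1
        idx = unified_index(pca)
        assert np.allclose(idx.to_numpy(), pca.scores["PC1"].to_numpy())

    def test_matrix_product_oracle(self):
        m = _zmat(24, 18, seed=12, factors=3)
        pca = fit_pca(m)
        centered = m.to_numpy() - m.to_numpy().mean(0)
        scores = centered @ pca.loadings.to_numpy()
        oracle = scores[:, : pca.k_selected].sum(axis=1)
        assert np.allclose(unified_index(pca).to_numpy(), oracle, atol=1e-8)

    def test_centered_over_subjects(self):
        m = _zmat(24, 18, seed=13, factors=2)
        idx = unified_index(fit_pca(m))
        assert idx.mean() == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_metric_ordering(self):
        m = _zmat(24, 18, seed=14, factors=3)
        a = unified_index(fit_pca(m))
        shuffled = m[list(np.random.default_rng(1).permutation(m.columns))]
        b = unified_index(fit_pca(shuffled))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)


class TestDomainContributions:
    def _pca_with_loadings(self, loadings, metrics):
        n_comp = loadings.shape[1]
        return PCAResultSet(
            timepoint="t", explained_ratio=np.full(n_comp, 1.0 / n_comp),
            k_selected=n_comp,
            loadings=pd.DataFrame(loadings, index=metrics,
                                  columns=[f"PC{i+1}" for i in range(n_comp)]),
            scores=pd.DataFrame(np.zeros((2, n_comp)),
                                columns=[f"PC{i+1}" for i in range(n_comp)]),
        )

    def test_equal_loadings_equal_contributions(self):
        metrics = list(METRIC_REGISTRY)[:20]
        pca = self._pca_with_loadings(np.full((20, 2), 0.3), metrics)
        table = domain_contributions(pca, METRIC_REGISTRY)
        assert table["mean_abs_loading_pc1"].nunique() == 1

    def test_scale_equivariance(self):
        metrics = list(METRIC_REGISTRY)[:30]
        rng = np.random.default_rng(15)
        load = rng.normal(size=(30, 2))
        a = domain_contributions(self._pca_with_loadings(load, metrics),
                                 METRIC_REGISTRY)
        b = domain_contributions(self._pca_with_loadings(2 * load, metrics),
                                 METRIC_REGISTRY)
        assert np.allclose(b["mean_abs_loading_pc1"],
                           2 * a["mean_abs_loading_pc1"])

    def test_two_regime_fixture_sign_pattern(self):
        # early factor loads only on frequency metrics, late only on
        # complexity: frequency contribution falls, complexity rises
        freq = [m for m, s in METRIC_REGISTRY.items() if s.domain == "frequency"]
        cx = [m for m, s in METRIC_REGISTRY.items() if s.domain == "complexity"][:6]
        metrics = freq + cx
        early = np.zeros((len(metrics), 1))
        early[: len(freq), 0] = 0.8
        early[len(freq):, 0] = 0.05
        late = np.zeros((len(metrics), 1))
        late[: len(freq), 0] = 0.05
        late[len(freq):, 0] = 0.8
        early_pca = self._pca_with_loadings(early, metrics)
        late_pca = self._pca_with_loadings(late, metrics)
        table = domain_contributions(late_pca, METRIC_REGISTRY, other=early_pca)
        by_dom = table.set_index("domain")["pct_change_pc1"]
        assert by_dom["frequency"] < 0
        assert by_dom["complexity"] > 0
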