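"""Co-expression network construction, module detection, hub genes."""

import numpy as np
import pandas as pd
import pytest

from imsubtype import SurvivalTable, simulate_block_expression
from imsubtype.coexpr import (
    CoexpressionModules,
    _tom_from_adjacency,
    build_network,
    detect_modules,
    hub_genes,
    mad_filter,
    module_trait_correlation,
)

from conftest import tom_tripleloop_oracle


class TestMADFilter:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=[f"s{j}" for j in range(len(rows[0]))])

    def test_top_half_by_mad_kept(self):
        rows = [[5.0] * 5,                                # MAD 0
                [0.0, 1.0, 2.0, 3.0, 4.0],               # MAD 1... scaled
                [0.0, 2.0, 4.0, 6.0, 8.0],
                [0.0, 3.0, 6.0, 9.0, 12.0]]
        out = mad_filter(self._frame(rows), top_prop=0.5)
        assert list(out.index) == ["g2", "g3"]

    def test_top_prop_one_is_identity(self):
        frame = self._frame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        out = mad_filter(frame, top_prop=1.0)
        pd.testing.assert_frame_equal(out, frame)

    def test_constant_gene_always_removed_below_one(self):
        frame = self._frame([[7.0] * 4, [1.0, 2.0, 3.0, 4.0]])
        out = mad_filter(frame, top_prop=0.9)
        assert "g0" not in out.index

    def test_all_constant_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            mad_filter(self._frame([[1.0] * 4, [2.0] * 4]))


class TestNetwork:
    def test_tom_hand_example(self):
        a = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.4], [0.2, 0.4, 1.0]])
        tom = _tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx((0.2 * 0.4 + 0.8)
                                          / (min(1.0, 1.2) + 1 - 0.8))
        assert tom[0, 1] == pytest.approx(0.73333333333)

    def test_tom_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.uniform(0, 1, size=(10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(_tom_from_adjacency(a),
                                       tom_tripleloop_oracle(a), atol=1e-12)

    def test_tom_bounded_on_random_adjacency(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = _tom_from_adjacency(a)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        x = np.linspace(0, 1, 8)
        frame = pd.DataFrame([x, 2 * x + 1, -x + 0.5],
                             index=["a", "b", "c"])
        net = build_network(frame, beta=10)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.adjacency[0, 2] == pytest.approx(1.0)

    def test_independent_genes_have_tiny_adjacency(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(5, 2000)),
                             index=[f"g{i}" for i in range(5)])
        net = build_network(frame, beta=10)
        off = net.adjacency[~np.eye(5, dtype=bool)]
        assert off.max() < 0.05

    def test_zero_variance_gene_is_named_in_error(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [5.0] * 4,
                              [2.0, 1.0, 2.0, 1.0]],
                             index=["a", "flat", "c"])
        with pytest.raises(ValueError, match="flat"):
            build_network(frame)


class TestModules:
    def test_planted_blocks_recovered(self):
        frame, truth = simulate_block_expression(
            n_blocks=2, block_size=80, n_noise=40, n_samples=100, seed=0)
        est = CoexpressionModules(beta=6, min_size=60).fit(frame)
        modules = est.modules_
        assert len(modules.module_names) == 2
        block_genes = truth[truth >= 0]
        assigned = modules.assignments.loc[block_genes.index]
        # map each module to its majority planted block, then score
        correct = 0
        for mod in modules.module_names:
            members = block_genes[assigned == mod]
            if len(members):
                correct += (members == members.mode()[0]).sum()
        assert correct / len(block_genes) >= 0.95

    def test_pure_noise_yields_no_modules(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(300, 100)),
                             index=[f"g{i}" for i in range(300)])
        net = build_network(frame, beta=10)
        with pytest.warns(UserWarning, match="unassigned"):
            modules = detect_modules(net, frame, min_size=60)
        assert modules.module_names == []
        assert (modules.assignments == "grey").all()

    def test_highly_correlated_blocks_are_merged(self):
        rng = np.random.default_rng(11)
        n_samples = 120
        f = rng.normal(size=n_samples)
        g = 0.95 * f + np.sqrt(1 - 0.95**2) * rng.normal(size=n_samples)
        rows, ids = [], []
        for b, latent in enumerate((f, g)):
            for i in range(70):
                rows.append(np.sqrt(0.85) * latent
                            + np.sqrt(0.15) * rng.normal(size=n_samples))
                ids.append(f"B{b}_{i}")
        frame = pd.DataFrame(rows, index=ids)
        est = CoexpressionModules(beta=6, min_size=60,
                                  merge_height=0.25).fit(frame)
        assert len(est.modules_.module_names) == 1

    def test_gene_order_permutation_preserves_partition(self):
        frame, _ = simulate_block_expression(
            n_blocks=2, block_size=70, n_noise=30, n_samples=80, seed=2)
        est1 = CoexpressionModules(beta=6, min_size=60).fit(frame)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(frame))
        est2 = CoexpressionModules(beta=6, min_size=60).fit(frame.iloc[perm])
        a = est1.modules_.assignments
        b = est2.modules_.assignments.loc[a.index]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_eigengene_sign_makes_mean_kme_positive(self):
        frame, _ = simulate_block_expression(
            n_blocks=2, block_size=70, n_noise=20, n_samples=80, seed=3)
        est = CoexpressionModules(beta=6, min_size=60).fit(frame)
        modules = est.modules_
        from imsubtype.coexpr import _kme

        for mod in modules.module_names:
            members = modules.members(mod)
            kmes = _kme(frame.loc[members], members,
                        modules.eigengenes.loc[mod].to_numpy())
            assert kmes.mean() > 0


class TestTraitsAndHubs:
    def _modules(self, seed=4):
        frame, truth = simulate_block_expression(
            n_blocks=2, block_size=70, n_noise=20, n_samples=90, seed=seed)
        est = CoexpressionModules(beta=6, min_size=60).fit(frame)
        return frame, truth, est.modules_

    def test_eigengene_equal_to_indicator_has_unit_correlation(self):
        frame, _, modules = self._modules()
        mod = modules.module_names[0]
        trait = pd.Series(modules.eigengenes.loc[mod].to_numpy(),
                          index=modules.eigengenes.columns, name="t")
        table = module_trait_correlation(modules, trait)
        row = table[(table["module"] == mod) & (table["trait"] == "t")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_trait_is_an_error(self):
        _, _, modules = self._modules()
        trait = pd.Series(1.0, index=modules.eigengenes.columns, name="t")
        with pytest.raises(ValueError, match="constant trait"):
            module_trait_correlation(modules, trait)

    def test_hub_gene_construction_selected_null_rarely(self):
        frame, truth, modules = self._modules(seed=5)
        mod = modules.module_names[0]
        eig = modules.eigengenes.loc[mod]
        rng = np.random.default_rng(6)
        # survival driven by the module eigengene -> high-kME genes selected
        risk = eig.to_numpy()
        risk = (risk - risk.mean()) / risk.std()
        t = rng.exponential(1.0 / (0.003 * np.exp(1.5 * risk)))
        surv = SurvivalTable(pd.DataFrame(
            {"time_days": t, "event": 1},
            index=pd.Index(eig.index, name="sample_id")))
        rep = hub_genes(frame, modules, mod, surv, kme_thresh=0.85)
        high = rep[rep["kME"] > 0.85]
        if len(high):
            assert high["selected"].mean() > 0.5
        # null survival -> selection near the nominal error rate
        t0 = rng.exponential(300.0, size=len(eig))
        surv0 = SurvivalTable(pd.DataFrame(
            {"time_days": t0, "event": 1},
            index=pd.Index(eig.index, name="sample_id")))
        rep0 = hub_genes(frame, modules, mod, surv0, kme_thresh=0.85)
        high0 = rep0[rep0["kME"] > 0.85]
        if len(high0) >= 10:
            assert high0["selected"].mean() <= 0.2

    def test_empty_module_is_an_error(self):
        frame, _, modules = self._modules()
        surv = SurvivalTable(pd.DataFrame(
            {"time_days": [100.0], "event": [1]},
            index=pd.Index([frame.columns[0]], name="sample_id")))
        with pytest.raises(ValueError, match="empty or unknown"):
            hub_genes(frame, modules, "grey99", surv)
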