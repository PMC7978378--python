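"""Autodiff correctness, both classifiers, grid search and filtering."""

import numpy as np
import pytest
from rdkit import Chem

import adascreen as ada
from adascreen.neuralmodels import (DNNConfig, ModelParams, NFPConfig,
                                    _init_dnn, _init_nfp, dnn_loss,
                                    dnn_loss_and_grads, evaluate_predictions,
                                    grid_search_batch, nfp_forward, nfp_loss,
                                    nfp_loss_and_grads, predict_dnn,
                                    predict_nfp, train_dnn, train_nfp)


def _finite_difference_check(loss_fn, params, grads, rng, n_per_array=4,
                             eps=1e-6):
    """Worst relative error between analytic and central-difference grads."""
    worst = 0.0
    for name, arr in params.arrays.items():
        flat = arr.ravel()
        for idx in rng.choice(flat.size, size=min(n_per_array, flat.size),
                              replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss_fn()
            flat[idx] = orig - eps
            lm = loss_fn()
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[name].ravel()[idx]
            denom = max(abs(fd), abs(an), 1e-8)
            worst = max(worst, abs(an - fd) / denom)
    return worst


class TestAutodiffGradients:
    def test_dnn_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        config = DNNConfig(hidden_widths=(6, 4), dropout=0.0, l2=1e-4, seed=2)
        params = ModelParams("dnn", config, _init_dnn(8, config))
        X = rng.random((9, 8))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1])
        _, grads = dnn_loss_and_grads(X, y, params)
        worst = _finite_difference_check(
            lambda: dnn_loss(X, y, params), params, grads, rng)
        assert worst < 1e-4

    def test_nfp_gradients_match_finite_differences_three_atom_graph(self):
        rng = np.random.default_rng(1)
        config = NFPConfig(conv_layers=2, fp_length=5, hidden_width=4,
                           l2=1e-4, seed=9)
        params = ModelParams("nfp", config, _init_nfp(config))
        graphs = [ada.mol_graph("CCO")]
        y = np.array([1])
        _, grads = nfp_loss_and_grads(graphs, y, params)
        worst = _finite_difference_check(
            lambda: nfp_loss(graphs, y, params), params, grads, rng)
        assert worst < 1e-4


class TestNfpForward:
    def _params(self, conv_layers=2, fp_length=8, seed=5):
        config = NFPConfig(conv_layers=conv_layers, fp_length=fp_length,
                           hidden_width=6, seed=seed)
        return ModelParams("nfp", config, _init_nfp(config))

    def test_output_length(self):
        params = self._params(fp_length=12)
        fp = nfp_forward(ada.mol_graph("c1ccccc1O"), params)
        assert fp.shape == (12,)

    def test_atom_permutation_invariance(self):
        rng = np.random.default_rng(7)
        params = self._params()
        for smi in ("CC(=O)Nc1ccccc1", "c1ccc2nc(NCC)ncc2c1", "CCOC(=O)CN"):
            mol = Chem.MolFromSmiles(smi)
            ref = nfp_forward(ada.mol_graph(mol), params)
            for _ in range(5):
                perm = [int(p) for p in rng.permutation(mol.GetNumAtoms())]
                shuffled = Chem.RenumberAtoms(mol, perm)
                out = nfp_forward(ada.mol_graph(shuffled), params)
                assert np.allclose(out, ref, atol=1e-12)

    def test_zero_conv_layers_base_case(self):
        # fingerprint must equal the softmax-projected raw atom features
        params = self._params(conv_layers=0)
        graph = ada.mol_graph("CCO")
        fp = nfp_forward(graph, params)
        z = graph.atom_features @ params.arrays["Wo0"] + params.arrays["bo0"]
        e = np.exp(z - z.max(axis=1, keepdims=True))
        softmax = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(fp, softmax.sum(axis=0), atol=1e-12)

    def test_two_atom_graph_hand_computed(self):
        # 2 "atoms" with 2-dim features, one conv layer, 2-dim fingerprint:
        # every matrix small enough to follow by hand
        config = NFPConfig(conv_layers=1, fp_length=2, hidden_width=2, seed=0)
        feat = np.array([[1.0, 0.0], [0.0, 1.0]])
        graph = ada.MolGraph(atom_features=feat, neighbors=[[1], [0]])
        arrays = {
            "Wo0": np.array([[1.0, 0.0], [0.0, 1.0]]), "bo0": np.zeros(2),
            "Wh0": np.array([[1.0, -1.0], [0.5, 0.5]]), "bh0": np.zeros(2),
            "Wo1": np.array([[2.0, 0.0], [0.0, 2.0]]), "bo1": np.zeros(2),
            "Wd0": np.eye(2), "bd0": np.zeros(2),
            "Wd1": np.eye(2), "bd1": np.zeros(2),
        }
        params = ModelParams("nfp", config, arrays)
        # radius 0: softmax rows of feat @ I = feat -> softmax([1,0]) and
        # softmax([0,1]); summed: [e/(1+e)+1/(1+e)] symmetric
        e = np.e
        r0 = np.array([e / (1 + e) + 1 / (1 + e),
                       1 / (1 + e) + e / (1 + e)])  # = [1, 1]
        # conv: msg = feat + adj@feat = [[1,1],[1,1]];
        # h = relu(msg @ Wh0) = relu([[1.5,-0.5],[1.5,-0.5]]) = [[1.5,0],[1.5,0]]
        # radius 1: softmax([3,0]) per atom, summed over 2 atoms
        s = np.exp([3.0, 0.0])
        s = s / s.sum()
        expected = r0 + 2 * s
        assert np.allclose(nfp_forward(graph, params), expected, atol=1e-10)


class TestTraining:
    def test_separable_data_recovered(self, library_arrays, trained_dnn):
        la = library_arrays
        params, _ = trained_dnn
        p = predict_dnn(params, la["X"][la["idx_test"]])
        ms = evaluate_predictions(p, la["y"][la["idx_test"]])
        assert ms.se >= 0.95 and ms.sp >= 0.95

    def test_nfp_separable_data_recovered(self, library_arrays, trained_nfp):
        la = library_arrays
        params, log = trained_nfp
        p = predict_nfp(params, [la["graphs"][i] for i in la["idx_test"]])
        ms = evaluate_predictions(p, la["y"][la["idx_test"]])
        assert ms.auc >= 0.9
        assert len(log) == params.config.num_epochs  # per-epoch loss recorded

    def test_same_seed_identical_loss(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.random((20, 12)) + 0.4, rng.random((20, 12)) - 0.4])
        y = np.array([1] * 20 + [0] * 20)
        config = DNNConfig(batch_size=10, num_epochs=8, hidden_widths=(8,),
                           seed=17)
        _, log1 = train_dnn(X, y, config)
        _, log2 = train_dnn(X, y, config)
        assert log1[-1]["loss"] == log2[-1]["loss"]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_dnn(X, np.ones(10, dtype=int),
                      DNNConfig(num_epochs=1, hidden_widths=(4,)))

    def test_default_configs_carry_selected_optimum(self):
        dnn = DNNConfig()
        assert (dnn.batch_size, dnn.learning_rate, dnn.num_epochs,
                dnn.dropout, dnn.l2) == (250, 0.001, 500, 0.2, 0.0001)
        assert dnn.hidden_widths == (3000, 2000, 1000)
        assert NFPConfig().conv_layers == 5
        assert NFPConfig().batch_size == 200


class TestGridSearch:
    def test_one_row_per_batch_size(self, library_arrays):
        la = library_arrays
        # take both ends so the subset keeps both classes
        tr = la["idx_train"][:30] + la["idx_train"][-30:]
        te = la["idx_test"][:15] + la["idx_test"][-15:]
        base = DNNConfig(num_epochs=6, hidden_widths=(16,), seed=2)
        grid = [50, 100, 150, 200, 250, 300]  # the study's batch grid
        table, best = grid_search_batch(
            la["X"][tr], la["y"][tr], la["X"][te], la["y"][te],
            "dnn", grid, base_config=base)
        assert len(table) == 6
        assert set(table.columns) == {"batch_size", "se", "sp", "q_plus",
                                      "q_minus", "mcc", "auc"}
        assert best.config.batch_size in set(grid)

    def test_single_batch_size_trivial_selection(self, library_arrays):
        la = library_arrays
        tr = la["idx_train"][:30] + la["idx_train"][-30:]
        te = la["idx_test"][:15] + la["idx_test"][-15:]
        base = DNNConfig(num_epochs=4, hidden_widths=(8,), seed=1)
        table, best = grid_search_batch(
            la["X"][tr], la["y"][tr], la["X"][te], la["y"][te],
            "dnn", [20], base_config=base)
        assert len(table) == 1 and best.config.batch_size == 20

    def test_table_consistent_with_metric_recomputation(self, library_arrays):
        la = library_arrays
        # take both ends so the subset keeps both classes
        tr = la["idx_train"][:30] + la["idx_train"][-30:]
        te = la["idx_test"][:15] + la["idx_test"][-15:]
        base = DNNConfig(num_epochs=6, hidden_widths=(16,), seed=2)
        table, _ = grid_search_batch(
            la["X"][tr], la["y"][tr], la["X"][te], la["y"][te],
            "dnn", [20], base_config=base)
        config = DNNConfig(num_epochs=6, hidden_widths=(16,), seed=2,
                           batch_size=20)
        params, _ = train_dnn(la["X"][tr], la["y"][tr], config)
        ms = evaluate_predictions(predict_dnn(params, la["X"][te]),
                                  la["y"][te])
        row = table.iloc[0]
        assert row["mcc"] == pytest.approx(ms.mcc)
        assert row["auc"] == pytest.approx(ms.auc)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_batch(None, None, None, None, "dnn", [])


class TestFilter:
    def test_threshold_extremes(self, library_arrays, trained_dnn):
        la = library_arrays
        params, _ = trained_dnn
        ids = [r.id for r in la["records"]]
        all_pass, _ = ada.predict_filter(params, ids, la["X"], threshold=0.0)
        none_pass, _ = ada.predict_filter(params, ids, la["X"], threshold=1.0)
        assert all_pass == set(ids)
        assert none_pass == set()

    def test_raising_threshold_never_enlarges(self, library_arrays,
                                              trained_dnn):
        la = library_arrays
        params, _ = trained_dnn
        ids = [r.id for r in la["records"]]
        previous = None
        for threshold in (0.0, 0.25, 0.5, 0.75, 0.99):
            passing, _ = ada.predict_filter(params, ids, la["X"], threshold)
            if previous is not None:
                assert passing <= previous
            previous = passing

    def test_intersection_is_subset(self, library_arrays, trained_dnn,
                                    trained_nfp):
        la = library_arrays
        ids = [r.id for r in la["records"]]
        a, _ = ada.predict_filter(trained_dnn[0], ids, la["X"], 0.5)
        b, _ = ada.predict_filter(trained_nfp[0], ids, la["graphs"], 0.5)
        both = ada.intersect_filters(a, b)
        assert both <= a and both <= b

    def test_fingerprint_length_mismatch_rejected(self, trained_dnn):
        params, _ = trained_dnn
        with pytest.raises(ValueError, match="length"):
            predict_dnn(params, np.zeros((2, 16)))


class TestCheckpoints:
    def test_roundtrip(self, trained_dnn, tmp_path):
        params, _ = trained_dnn
        path = tmp_path / "model.npz"
        ada.save_params(params, path)
        back = ada.load_params(path)
        assert back.kind == "dnn"
        assert back.config == params.config
        X = np.random.default_rng(0).random((4, params.arrays["W0"].shape[0]))
        assert np.allclose(predict_dnn(back, X), predict_dnn(params, X))
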