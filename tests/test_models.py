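"""GNN backbone, probability heads, loss, and the training loop."""

import numpy as np
import pytest

import fragspec as fs
from fragspec import autodiff as ad
from fragspec import models as M

SMALL = fs.GNNConfig(layers=2, hidden_dim=16, maxelem=12, seed=0, mlp_hidden=32)


def head_probs(mol, kind, cfg=SMALL, frag_config=None):
    fc = frag_config or fs.FragmentationConfig()
    batch = M.build_candidates(mol, kind, cfg, frag_config=fc)
    params = M._init_params(kind, cfg)
    return batch, params, M._forward_probs(batch, cfg, params).value.ravel()


class TestGNN:
    def test_isolated_atom_depends_only_on_itself(self):
        x0 = np.eye(3, 17)
        a = np.zeros((3, 3))
        params = M._init_params("formula", SMALL)
        out1 = M.gnn_forward(x0, a, SMALL, params).value
        x0b = x0.copy()
        x0b[2] = np.random.default_rng(1).random(17)
        out2 = M.gnn_forward(x0b, a, SMALL, params).value
        assert np.allclose(out1[0], out2[0]) and np.allclose(out1[1], out2[1])

    def test_methane_hydrogen_rows_identical(self, methane):
        params = M._init_params("formula", SMALL)
        out = M.gnn_forward(
            fs.atom_features(methane), fs.build_adjacency(methane), SMALL, params
        ).value
        h_rows = [out[i] for i, s in enumerate(methane.atoms) if s == "H"]
        assert all(np.allclose(r, h_rows[0]) for r in h_rows)

    def test_permutation_equivariance(self, ethanol):
        params = M._init_params("formula", SMALL)
        x0, a = fs.atom_features(ethanol), fs.build_adjacency(ethanol)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ethanol.n_atoms)
        out = M.gnn_forward(x0, a, SMALL, params).value
        out_p = M.gnn_forward(x0[perm], a[np.ix_(perm, perm)], SMALL, params).value
        assert np.allclose(out[perm], out_p, atol=1e-10)

    def test_shape_mismatch_raises(self):
        params = M._init_params("formula", SMALL)
        with pytest.raises(ValueError, match="shape"):
            M.gnn_forward(np.zeros((3, 17)), np.zeros((4, 4)), SMALL, params)


class TestFormulaHead:
    def test_probabilities_normalized(self, ethanol):
        _, _, p = head_probs(ethanol, "formula")
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_candidate_gets_probability_one(self, methane):
        cfg = SMALL
        batch = M.build_candidates(methane, "formula", cfg)
        batch.enc = batch.enc[:1]
        params = M._init_params("formula", cfg)
        x_d = M.gnn_forward(batch.x0, batch.adjacency, cfg, params)
        p = M.formulanet_forward(x_d, batch.enc, cfg, params).value
        assert p.ravel() == pytest.approx([1.0])

    def test_duplicate_rows_equal_probability(self, methane):
        cfg = SMALL
        batch = M.build_candidates(methane, "formula", cfg)
        enc = np.vstack([batch.enc, batch.enc[3]])
        params = M._init_params("formula", cfg)
        # randomize all heads so equality is not just the zero-init artefact
        rng = np.random.default_rng(5)
        for k, t in params.items():
            t.value = rng.normal(0, 0.2, size=t.value.shape)
        x_d = M.gnn_forward(batch.x0, batch.adjacency, cfg, params)
        p = M.formulanet_forward(x_d, enc, cfg, params).value.ravel()
        assert p[3] == pytest.approx(p[-1], rel=1e-9)

    def test_row_permutation_equivariance(self, ethanol):
        cfg = SMALL
        batch = M.build_candidates(ethanol, "formula", cfg)
        params = M._init_params("formula", cfg)
        rng = np.random.default_rng(6)
        for k, t in params.items():
            t.value = rng.normal(0, 0.2, size=t.value.shape)
        x_d = M.gnn_forward(batch.x0, batch.adjacency, cfg, params)
        p = M.formulanet_forward(x_d, batch.enc, cfg, params).value.ravel()
        perm = rng.permutation(len(p))
        p2 = M.formulanet_forward(x_d, batch.enc[perm], cfg, params).value.ravel()
        assert np.allclose(p[perm], p2, atol=1e-12)

    def test_empty_batch_raises(self, methane):
        cfg = SMALL
        params = M._init_params("formula", cfg)
        x_d = M.gnn_forward(
            fs.atom_features(methane), fs.build_adjacency(methane), cfg, params
        )
        with pytest.raises(M.DegenerateInputError):
            M.formulanet_forward(x_d, np.zeros((0, 8 * cfg.maxelem)), cfg, params)


class TestSubsetHead:
    def test_singleton_subset_embedding_is_atom_row(self, ethanol):
        cfg = SMALL
        params = M._init_params("subset", cfg)
        x_d = M.gnn_forward(
            fs.atom_features(ethanol), fs.build_adjacency(ethanol), cfg, params
        )
        indicator = np.zeros((1, ethanol.n_atoms))
        indicator[0, 2] = 1.0
        emb = (ad.Tensor(indicator) @ x_d).value / 1.0
        assert np.allclose(emb[0], x_d.value[2])

    def test_identical_masks_identical_probabilities(self, ethane):
        cfg = SMALL
        params = M._init_params("subset", cfg)
        rng = np.random.default_rng(7)
        for k, t in params.items():
            t.value = rng.normal(0, 0.2, size=t.value.shape)
        batch = M.build_candidates(ethane, "subset", cfg)
        ind = np.vstack([batch.indicator, batch.indicator[0]])
        enc = np.vstack([batch.enc, batch.enc[0]])
        x_d = M.gnn_forward(batch.x0, batch.adjacency, cfg, params)
        p = M.subsetnet_forward(x_d, ind, enc, params).value.ravel()
        assert p[0] == pytest.approx(p[-1], rel=1e-9)

    def test_probabilities_sum_to_one(self, ethanol):
        _, _, p = head_probs(ethanol, "subset")
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_atom_subset_raises(self, methane):
        cfg = SMALL
        params = M._init_params("subset", cfg)
        x_d = M.gnn_forward(
            fs.atom_features(methane), fs.build_adjacency(methane), cfg, params
        )
        with pytest.raises(M.DegenerateInputError):
            M.subsetnet_forward(x_d, np.zeros((2, 5)), np.zeros((2, 96)), params)


class TestScaledL2Loss:
    def test_identical_spectra_zero(self):
        s = fs.Spectrum(np.array([42, 50]), np.array([0.6, 0.8]))
        for power in (0.5, 1.0, 2.0):
            assert fs.scaled_l2_loss(s, s, power) == 0.0

    def test_power_one_is_plain_l2(self):
        s1 = fs.Spectrum(np.array([42]), np.array([1.0]))
        s2 = fs.Spectrum(np.array([42]), np.array([0.5]))
        assert fs.scaled_l2_loss(s1, s2, 1.0) == pytest.approx(0.25)

    def test_disjoint_unit_peaks_power_half(self):
        s1 = fs.Spectrum(np.array([42]), np.array([1.0]))
        s2 = fs.Spectrum(np.array([43]), np.array([1.0]))
        assert fs.scaled_l2_loss(s1, s2, 0.5) == pytest.approx(2.0)

    def test_grid_mismatch_raises(self):
        s1 = fs.Spectrum(np.array([42]), np.array([1.0]), resolution=1.0)
        s2 = fs.Spectrum(np.array([42]), np.array([1.0]), resolution=0.1)
        with pytest.raises(ValueError):
            fs.scaled_l2_loss(s1, s2)


class TestTrainingAndPrediction:
    def test_untrained_model_predicts_uniform_assembly(self, methane):
        model = M.TrainedModel(
            "formula", SMALL, fs.TrainingConfig(), fs.FragmentationConfig(),
            M._init_params("formula", SMALL),
        )
        pred = fs.predict_spectrum(methane, model)
        candidates = list(fs.enumerate_subformulae(methane.formula()))
        uniform = fs.FragmentProbabilities(
            [(f, 1.0 / len(candidates)) for f in candidates]
        )
        direct = fs.assemble_spectrum(uniform, resolution=1.0)
        assert pred.as_dict() == pytest.approx(direct.as_dict(), abs=1e-9)

    def test_train_is_deterministic(self, toy_molecules):
        mol = toy_molecules[0]
        spec, _ = fs.planted_spectrum(mol, fs.PlantedModel(seed=2))
        tcfg = fs.TrainingConfig(epochs=3, seed=0, batch_size=1)
        log1 = fs.train([(mol, spec)], "formula", SMALL, tcfg).loss_log
        log2 = fs.train([(mol, spec)], "formula", SMALL, tcfg).loss_log
        assert log1 == log2

    def test_loss_decreases_when_overfitting_one(self, toy_molecules):
        mol = toy_molecules[1]
        spec, _ = fs.planted_spectrum(mol, fs.PlantedModel(seed=3))
        tcfg = fs.TrainingConfig(epochs=40, learning_rate=1e-2, seed=0, batch_size=1)
        model = fs.train([(mol, spec)], "subset", SMALL, tcfg)
        assert model.loss_log[-1] < model.loss_log[0] * 0.2

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            fs.train([], "formula", SMALL, fs.TrainingConfig())

    def test_resolution_consistency(self, toy_molecules):
        model = M.TrainedModel(
            "formula", SMALL, fs.TrainingConfig(), fs.FragmentationConfig(),
            M._init_params("formula", SMALL),
        )
        mol = toy_molecules[2]
        fine = fs.predict_spectrum(mol, model, resolution=0.1)
        coarse = fs.predict_spectrum(mol, model, resolution=1.0)
        re = fs.normalize(fs.rebin(fine, 1.0), "L2")
        assert re.as_dict() == pytest.approx(coarse.as_dict(), abs=1e-9)

    def test_prediction_is_valid_spectrum(self, toy_molecules):
        model = M.TrainedModel(
            "subset", SMALL, fs.TrainingConfig(), fs.FragmentationConfig(max_subsets=256),
            M._init_params("subset", SMALL),
        )
        pred = fs.predict_spectrum(toy_molecules[3], model)
        assert (pred.intensity >= 0).all()
        assert pred.l2_norm() == pytest.approx(1.0, abs=1e-9)

    def test_checkpoint_round_trip(self, toy_molecules, tmp_path):
        mol = toy_molecules[0]
        spec, _ = fs.planted_spectrum(mol, fs.PlantedModel(seed=2))
        tcfg = fs.TrainingConfig(epochs=2, seed=0, batch_size=1)
        model = fs.train([(mol, spec)], "formula", SMALL, tcfg)
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        loaded = M.TrainedModel.load(path)
        p1 = fs.predict_spectrum(mol, model)
        p2 = fs.predict_spectrum(mol, loaded)
        assert p1.as_dict() == pytest.approx(p2.as_dict(), abs=1e-12)
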