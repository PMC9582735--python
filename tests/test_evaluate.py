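"""Metrics, SRD, saliency maps, and substitution-effect summaries."""

import itertools
import json

import numpy as np
import pytest

from deltadock._graph_batch import collate, prepare_graph
from deltadock.chem import parse_smiles
from deltadock.data import build_labeled_graph, make_oracle_dataset
from deltadock.enumeration import DiDerivativeRecord, SubstituentLibrary, substitutable_positions
from deltadock.evaluate import (
    export_viewer_payload,
    mono_vs_di_summary,
    mse_ranking,
    saliency,
    saliency_from_gradient,
    sign_accuracy,
    srd,
    substituent_effect_summary,
)
from deltadock.models import GNNNodeRegressor, masked_mse
from deltadock.scoring import DeltaRecord, OracleParams, oracle_delta


class TestSignAccuracy:
    TRUE = np.array([[-0.5, 0.3, -2.0]])
    PRED = np.array([[-1.0, 0.4, 0.2]])
    MASK = np.ones((1, 3))

    def test_plain_accuracy(self):
        report = sign_accuracy(self.PRED, self.TRUE, self.MASK)
        assert report.sign_accuracy == pytest.approx(2 / 3)
        assert report.n_evaluated == 3

    def test_margin_filters_small_true_changes(self):
        report = sign_accuracy(self.PRED, self.TRUE, self.MASK, margin=0.4)
        assert report.n_evaluated == 2
        assert report.sign_accuracy == pytest.approx(0.5)

    def test_perfect_predictions_at_any_margin(self):
        for margin in (0.0, 0.1, 1.0):
            report = sign_accuracy(self.TRUE, self.TRUE, self.MASK, margin=margin)
            if report.n_evaluated:
                assert report.sign_accuracy == 1.0

    def test_mask_is_respected(self):
        report = sign_accuracy(self.PRED, self.TRUE, np.array([[0, 1, 0]]))
        assert report.n_evaluated == 1

    def test_empty_survivors_flagged_not_crash(self):
        report = sign_accuracy(self.PRED, self.TRUE, self.MASK, margin=99.0)
        assert report.n_evaluated == 0
        assert not report.defined
        assert np.isnan(report.sign_accuracy)

    def test_zero_delta_counts_as_increase(self):
        report = sign_accuracy(np.array([[0.0]]), np.array([[0.4]]), np.array([[1]]))
        assert report.sign_accuracy == 1.0


class TestMseRanking:
    def test_perfect_prediction_zero(self):
        x = np.array([[1.0, -0.5]])
        assert mse_ranking(x, x, np.ones_like(x)) == 0.0

    def test_constant_mean_predictor_gives_variance(self):
        rng = np.random.default_rng(0)
        true = rng.standard_normal((4, 5))
        pred = np.full_like(true, true.mean())
        assert mse_ranking(pred, true, np.ones_like(true)) == pytest.approx(true.var())

    def test_agrees_with_masked_mse(self):
        rng = np.random.default_rng(1)
        pred, true = rng.standard_normal((2, 3, 4))
        mask = rng.integers(0, 2, size=(3, 4)).astype(float)
        mask[0, 0] = 1
        assert mse_ranking(pred, true, mask) == masked_mse(pred, true, mask)


class TestSRD:
    def test_identical_ordering_is_zero(self):
        value, norm = srd([1, 2, 3, 4], [10, 20, 30, 40])
        assert value == 0 and norm == 0

    def test_reversed_ordering_of_four_items(self):
        value, norm = srd([4, 3, 2, 1], [1, 2, 3, 4])
        assert value == 8  # |1-4|+|2-3|+|3-2|+|4-1|
        assert norm == 1.0

    def test_normalisation_bounded_over_all_permutations(self):
        """Exhaustive check: normalised SRD lies in [0, 1] for every permutation."""
        for n in (2, 3, 4, 5, 6):
            ref = list(range(n))
            for perm in itertools.permutations(ref):
                _, norm = srd(list(perm), ref)
                assert 0.0 <= norm <= 1.0

    def test_symmetric_in_arguments(self):
        a, b = [3.0, 1.0, 2.0, 5.0], [1.0, 2.0, 3.0, 4.0]
        assert srd(a, b)[0] == srd(b, a)[0]

    def test_zero_iff_identical_ranking(self):
        value, _ = srd([1.0, 3.0, 2.0], [1.0, 2.0, 3.0])
        assert value > 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            srd([1, 2], [1, 2, 3])


class TestSaliencyFromGradient:
    def test_linear_model_closed_form(self):
        """For y = 3*x1 - 4*x2 on one node, the maps are known exactly."""
        gradient = np.array([[3.0, -4.0]])
        assert saliency_from_gradient(gradient, "classical")[0] == pytest.approx(3.0)
        assert saliency_from_gradient(gradient, "negative")[0] == pytest.approx(4.0)
        assert saliency_from_gradient(gradient, "pos_neg")[0] == pytest.approx(-1.0)

    def test_pos_neg_is_classical_minus_negative(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal((7, 42))
        expected = saliency_from_gradient(g, "classical") - saliency_from_gradient(g, "negative")
        assert np.allclose(saliency_from_gradient(g, "pos_neg"), expected)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            saliency_from_gradient(np.ones((1, 2)), "absolute")


class TestSaliency:
    def test_maps_are_nonnegative_and_consistent(self, small_model):
        model = small_model["model"]
        graph = small_model["graphs"][0]
        atom = substitutable_positions(graph.molecule)[0]
        classical = saliency(model, graph, atom, 0, "classical")
        negative = saliency(model, graph, atom, 0, "negative")
        pos_neg = saliency(model, graph, atom, 0, "pos_neg")
        assert (classical.values >= 0).all() and (negative.values >= 0).all()
        assert np.allclose(pos_neg.values, classical.values - negative.values)
        assert classical.values.shape == (graph.molecule.n_atoms,)

    def test_infeasible_target_raises(self, small_model):
        model = small_model["model"]
        pyridine = build_labeled_graph(parse_smiles("c1ccncc1", "pyridine"), [])
        n_idx = next(a.index for a in pyridine.molecule.atoms if a.element == "N")
        with pytest.raises(ValueError, match="feasible"):
            saliency(model, pyridine, n_idx, 0)

    @pytest.mark.parametrize("layer_type", ["gcn", "gat"])
    def test_locality_zero_outside_receptive_field(self, layer_type):
        """Atoms farther than n_conv bonds from the target get exactly zero."""
        graphs, _ = make_oracle_dataset(12, seed=4, sigma=0.0)
        model = GNNNodeRegressor(
            n_conv=3, layer_type=layer_type, hidden=8, epochs=2, batch_size=8
        ).fit(graphs)
        # a long chain separating two rings: ring atoms on the far side are
        # more than 3 hops from any atom of the first ring
        mol = parse_smiles("c1ccc(CCCCCCc2ccccc2)cc1", "spaced-biphenyl")
        graph = build_labeled_graph(mol, [])
        atom = substitutable_positions(graph.molecule)[0]
        result = saliency(model, graph, atom, 0, "classical")
        import networkx as nx

        g = nx.Graph([(i, j) for i, j, _ in mol.bonds])
        dist = nx.single_source_shortest_path_length(g, atom)
        far = [i for i, d in dist.items() if d > 3]
        assert far, "test molecule must have atoms outside the receptive field"
        assert np.all(result.values[far] == 0.0)

    def test_gradient_matches_finite_differences(self, small_model):
        """Backprop input gradients agree with central differences (<=1e-4 rel)."""
        model = small_model["model"]
        graph = small_model["graphs"][1]
        atom = substitutable_positions(graph.molecule)[0]
        prepared = prepare_graph(graph, model.use_dummy_node)
        batch = collate([prepared])
        from deltadock._autodiff import Tensor

        x = Tensor(batch.x.copy(), requires_grad=True)
        out = model._forward(batch, training=False, x_input=x)
        seed = np.zeros_like(out.data)
        seed[atom, 0] = 1.0
        out.backward(seed)
        grad = x.grad
        rng = np.random.default_rng(0)
        eps = 1e-5
        checked = 0
        for _ in range(30):
            i = int(rng.integers(batch.x.shape[0]))
            j = int(rng.integers(batch.x.shape[1]))
            xp, xm = batch.x.copy(), batch.x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            bp, bm = batch, batch
            bp = collate([prepared]); bp.x = xp
            bm = collate([prepared]); bm.x = xm
            yp = model._forward(bp, training=False).data[atom, 0]
            ym = model._forward(bm, training=False).data[atom, 0]
            numeric = (yp - ym) / (2 * eps)
            scale = max(abs(grad[i, j]), abs(numeric), 1e-6)
            assert abs(grad[i, j] - numeric) / scale <= 1e-4
            checked += 1
        assert checked == 30


class TestSubstituentEffectSummary:
    def test_single_substituent_mean(self):
        records = [DeltaRecord("m", 0, 0, -0.4), DeltaRecord("m", 1, 0, -0.6)]
        stats, hist = substituent_effect_summary(records)
        assert stats.loc["F", "mean"] == pytest.approx(-0.5)
        assert stats.loc["F", "count"] == 2

    def test_histogram_partitions_all_records(self):
        rng = np.random.default_rng(3)
        records = [
            DeltaRecord("m", i, int(rng.integers(15)), float(rng.normal(0, 2)))
            for i in range(200)
        ]
        _, hist = substituent_effect_summary(records)
        assert hist.sum() == 200
        assert list(hist.index) == ["[0,1)", "[1,2)", "[2,4)", "[4,inf)"]

    def test_noiseless_oracle_matches_closed_form(self):
        """Per-substituent means equal the oracle's analytic expectation."""
        graphs, params = make_oracle_dataset(30, seed=6, sigma=0.0)
        records, arom, degree = [], {}, {}
        for g in graphs:
            atom_idx, sub_idx = np.nonzero(g.labels.mask)
            for i, s in zip(atom_idx, sub_idx):
                records.append(DeltaRecord(g.id, int(i), int(s), g.labels.values[i, s]))
                atom = g.molecule.rdkit_mol.GetAtomWithIdx(int(i))
                arom.setdefault(int(s), []).append(float(atom.GetIsAromatic()))
                degree.setdefault(int(s), []).append(atom.GetDegree())
        stats, _ = substituent_effect_summary(records, params.library)
        for s, frag in enumerate(params.library):
            expected = (
                params.alpha[s]
                + params.beta[s] * np.mean(arom[s])
                + params.gamma[s] * (np.mean(degree[s]) - 2)
            )
            assert stats.loc[frag, "mean"] == pytest.approx(expected, abs=1e-12)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            substituent_effect_summary([])


class TestMonoVsDi:
    def _di(self, positions, delta):
        return (DiDerivativeRecord("m", positions, "CC", True), delta)

    def test_uniformly_worse_di_flags_mono_preferred(self):
        mono = [DeltaRecord("m", 0, 0, -0.4), DeltaRecord("m", 1, 1, -0.3)]
        di = [self._di(((0, 0), (1, 1)), 0.5), self._di(((0, 1), (2, 0)), 0.6)]
        table = mono_vs_di_summary(mono, di)
        assert table["mono_preferred"].all()

    def test_identical_distributions_zero_difference(self):
        mono = [DeltaRecord("m", 0, 0, 0.2)]
        di = [self._di(((0, 0), (1, 0)), 0.2)]
        table = mono_vs_di_summary(mono, di)
        assert table.loc["overall", "difference"] == pytest.approx(0.0)

    def test_additive_oracle_doubles_the_mean(self, benzene):
        """If di deltas are sums of two mono deltas drawn from the same pool,
        the di mean is twice the mono mean."""
        params = OracleParams(sigma=0.0, seed=0)
        positions = substitutable_positions(benzene)
        mono = [
            DeltaRecord("benzene", a, s, oracle_delta(benzene, a, s, params))
            for a in positions
            for s in range(15)
        ]
        di = []
        for (a1, s1), (a2, s2) in itertools.product(
            [(p, s) for p in positions[:3] for s in range(15)], repeat=2
        ):
            if a1 >= a2:
                continue
            delta = oracle_delta(benzene, a1, s1, params) + oracle_delta(benzene, a2, s2, params)
            di.append(self._di(((a1, s1), (a2, s2)), delta))
        table = mono_vs_di_summary(mono, di)
        assert table.loc["overall", "di_mean"] == pytest.approx(
            2 * table.loc["overall", "mono_mean"], rel=1e-9
        )


class TestViewerPayload:
    def test_manifest_round_trips(self, tmp_path, benzene):
        derivative = parse_smiles("Fc1ccccc1", "benzene|F")
        path = export_viewer_payload(benzene, derivative, -7.2, -7.7, tmp_path)
        manifest = json.loads(path.read_text())
        assert manifest["delta"] == pytest.approx(-0.5)
        assert manifest["parent"]["smiles"] == benzene.smiles
        assert manifest["poses"] == {}

    def test_pose_files_are_copied(self, tmp_path, benzene):
        pose = tmp_path / "pose.sdf"
        pose.write_text("fake pose\n")
        out = tmp_path / "payload"
        path = export_viewer_payload(
            benzene, parse_smiles("Clc1ccccc1", "d"), -7.0, -7.3, out,
            poses={"derivative": pose},
        )
        manifest = json.loads(path.read_text())
        assert (out / manifest["poses"]["derivative"]).exists()

    def test_missing_score_raises(self, tmp_path, benzene):
        with pytest.raises(ValueError, match="scores"):
            export_viewer_payload(benzene, benzene, None, -7.0, tmp_path)
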