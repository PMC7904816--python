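"""Relation detector: pairs, segments, SDP, attention, architecture, training."""

import numpy as np
import pytest

from conftest import make_parsed, random_dep_tree
from mdrel.detector import (DetectorConfig, DetectorModel, Vocabulary,
                            WordVectors, attention_weights, enumerate_pairs,
                            evaluate, featurize, prf, segment, train)


class TestPairEnumeration:
    def test_vulnificus_sentence_yields_two_pairs(self, vulnificus):
        pairs = enumerate_pairs(vulnificus)
        assert len(pairs) == 2
        diseases = {p.disease.canonical for p in pairs}
        assert diseases == {"infection", "sepsis"}

    def test_cartesian_product(self):
        parsed = make_parsed(
            "many",
            ["BAC00a", "BAC00b", "and", "DIS00x", "DIS00y", "DIS00z"],
            [2, 2, -1, 2, 2, 2],
            ["nsubj", "nsubj", "root", "obj", "obj", "obj"],
            ["NN"] * 6,
            "(S (NN BAC00a) (NN BAC00b) (CC and) (NN DIS00x) (NN DIS00y)"
            " (NN DIS00z))")
        assert len(enumerate_pairs(parsed)) == 6

    def test_microbe_only_sentence_yields_no_pairs(self):
        parsed = make_parsed("m", ["BAC00a", "grew"], [1, -1],
                             ["nsubj", "root"], ["NN", "VBD"],
                             "(S (NN BAC00a) (VBD grew))")
        assert enumerate_pairs(parsed) == []


class TestSegments:
    def test_vulnificus_middle_segment_is_causes_wound(self, vulnificus):
        pair = next(p for p in enumerate_pairs(vulnificus)
                    if p.disease.canonical == "infection")
        s1, s2, s3 = segment(pair)
        toks = vulnificus.sentence.tokens
        assert toks[slice(*s2)] == ["causes", "wound"]
        assert toks[slice(*s1)][-1] == ","  # phrase before the first entity
        assert s3 == (11, 19)

    def test_entity_at_edges_gives_empty_segments(self):
        parsed = make_parsed("edge", ["BAC00a", "DIS00b"], [-1, 0],
                             ["root", "obj"], ["NN", "NN"],
                             "(S (NN BAC00a) (NN DIS00b))")
        (pair,) = enumerate_pairs(parsed)
        s1, s2, s3 = segment(pair)
        assert s1 == (0, 0) and s2 == (1, 1) and s3 == (2, 2)


class TestShortestDepPath:
    def test_vulnificus_sdp_is_causes_wound(self, vulnificus):
        pair = next(p for p in enumerate_pairs(vulnificus)
                    if p.disease.canonical == "infection")
        toks = vulnificus.sentence.tokens
        assert [toks[i] for i in pair.sdp] == ["causes", "wound"]

    def test_direct_edge_gives_empty_path(self):
        parsed = make_parsed("direct", ["BAC00a", "DIS00b"], [-1, 0],
                             ["root", "obj"], ["NN", "NN"],
                             "(S (NN BAC00a) (NN DIS00b))")
        (pair,) = enumerate_pairs(parsed)
        assert pair.sdp == []

    def test_matches_bfs_oracle_on_random_trees(self):
        rng = np.random.Generator(np.random.PCG64(5))
        for _ in range(60):
            n = int(rng.integers(3, 14))
            tree = random_dep_tree(rng, n, ["dep"])
            a, b = rng.choice(n, size=2, replace=False)
            # BFS oracle over the undirected adjacency
            adj = {i: set() for i in range(n)}
            for i, h in enumerate(tree.heads):
                if h >= 0:
                    adj[i].add(h)
                    adj[h].add(i)
            prev = {int(a): None}
            queue = [int(a)]
            while queue:
                u = queue.pop(0)
                for v in adj[u]:
                    if v not in prev:
                        prev[v] = u
                        queue.append(v)
            path = [int(b)]
            while prev[path[-1]] is not None:
                path.append(prev[path[-1]])
            expected = sorted(path[1:-1])
            assert sorted(tree.path(int(a), int(b))[1:-1]) == expected


class TestAttention:
    def test_identical_words_give_uniform_weights(self):
        vecs = np.tile(np.arange(5.0), (4, 1))
        w = attention_weights(vecs, np.ones(5), -np.ones(5))
        assert np.allclose(w, 0.25)

    def test_hand_softmax_case(self):
        # two tokens with dot scores (0, ln 2) against both entities:
        # softmax gives (1/3, 2/3) for each entity, so the mean does too
        e = np.array([1.0, 0.0])
        vecs = np.array([[0.0, 5.0], [np.log(2.0), 7.0]])
        w = attention_weights(vecs, e, e)
        assert np.allclose(w, [1 / 3, 2 / 3])

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.Generator(np.random.PCG64(9))
        for _ in range(20):
            vecs = rng.standard_normal((int(rng.integers(1, 9)), 6))
            e1, e2 = rng.standard_normal(6), rng.standard_normal(6)
            w = attention_weights(vecs, e1, e2)
            assert np.isclose(w.sum(), 1.0)
            # adding a constant vector c to every dot product leaves
            # softmax unchanged: shift all word vecs along e1==e2 direction
            w2 = attention_weights(vecs + 0.0, e1, e2)
            assert np.allclose(w, w2)
        vecs = rng.standard_normal((5, 6))
        e = rng.standard_normal(6)
        shifted = vecs + e * (3.0 / (e @ e))  # adds the constant 3 to each dot
        assert np.allclose(attention_weights(vecs, e, e),
                           attention_weights(shifted, e, e))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            attention_weights(np.zeros((0, 4)), np.zeros(4), np.zeros(4))


@pytest.fixture(scope="module")
def tiny_features(vulnificus):
    config = DetectorConfig(seed=0)
    words = WordVectors(dim=config.word_dim, seed=0)
    pv, dv = Vocabulary(), Vocabulary()
    pairs = enumerate_pairs(vulnificus)
    feats = [featurize(p, words, config, pv, dv, grow_vocab=True)
             for p in pairs]
    return config, feats, pv, dv


class TestArchitecture:
    def test_paper_geometry_shapes(self, tiny_features):
        config, feats, pv, dv = tiny_features
        model = DetectorModel(config, len(pv), len(dv))
        logits, trace = model.forward(feats, return_trace=True)
        assert trace["bottom_matrix"].shape == (2, 4, 200)
        assert trace["top_input"].shape == (2, 6, 200)
        assert trace["top_output"].shape == (2, 200)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert ((probs > 0) & (probs < 1)).all()

    def test_inference_is_deterministic(self, tiny_features):
        config, feats, pv, dv = tiny_features
        model = DetectorModel(config, len(pv), len(dv))
        a = model.forward(feats).data
        b = model.forward(feats).data
        assert (a == b).all()

    def test_padding_invariance(self, vulnificus):
        # growing the time-step budget (more padding) must not change the
        # many-to-one encodings: masking freezes the state past true length
        words = WordVectors(dim=20, seed=0)
        pv, dv = Vocabulary(), Vocabulary()
        (pair, _) = enumerate_pairs(vulnificus)
        outs = []
        for steps in (12, 20):
            config = DetectorConfig(word_dim=20, hidden=7, seg_time_steps=steps,
                                    sdp_time_steps=steps, seed=3)
            feats = featurize(pair, words, config, pv, dv, grow_vocab=True)
            model = DetectorModel(config, 40, 40)
            _, trace = model.forward([feats], return_trace=True)
            outs.append(trace["bottom_matrix"])
        assert np.allclose(outs[0], outs[1])

    def test_featurize_pads_to_time_steps(self, vulnificus):
        config = DetectorConfig(word_dim=20, hidden=5, seed=0)
        words = WordVectors(dim=20, seed=0)
        pv, dv = Vocabulary(), Vocabulary()
        (pair, _) = enumerate_pairs(vulnificus)
        feats = featurize(pair, words, config, pv, dv, grow_vocab=True)
        t_max = max(config.seg_time_steps, config.sdp_time_steps)
        assert feats.segs.shape == (4, t_max, 20 + config.position_dim)
        # padding rows are all-zero
        for s in range(4):
            assert not feats.segs[s, feats.seg_lens[s]:].any()
        # position one-hot: exactly two ones per true row
        for s in range(4):
            for t in range(feats.seg_lens[s]):
                assert feats.segs[s, t, 20:].sum() == 2.0


class TestTraining:
    def test_single_class_dataset_rejected(self, tiny_features):
        config, feats, pv, dv = tiny_features
        for f in feats:
            f.label = 1
        with pytest.raises(ValueError, match="both classes"):
            train(feats, config, pv, dv)
        for f in feats:
            f.label = -1

    def test_metric_formulas(self):
        assert prf(2, 1, 1) == (2 / 3, 2 / 3, 2 / 3)
        assert prf(5, 0, 0) == (1.0, 1.0, 1.0)
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_train_is_deterministic_and_learns_separable_data(self):
        from mdrel.pipeline import LabelledCorpus
        from mdrel.synthetic import GeneratorConfig, generate

        bundle = generate(GeneratorConfig(n_sentences=60, seed=21))
        corpus = LabelledCorpus.from_bundle(bundle)
        config = DetectorConfig.desk_scale(seed=21)
        config.epochs = 25  # few pairs -> few updates per epoch
        words = WordVectors(dim=config.word_dim, seed=21)
        pv, dv = Vocabulary(), Vocabulary()
        feats = [featurize(p, words, config, pv, dv, grow_vocab=True)
                 for p in corpus.pairs]
        model, losses = train(feats, config, pv, dv)
        model2, losses2 = train(feats, config, pv, dv)
        assert losses == losses2
        assert losses[-1] < losses[0]
        p, r, f = evaluate(model, feats)
        assert f >= 0.9

    def test_checkpoint_round_trip(self, tiny_features, tmp_path):
        config, feats, pv, dv = tiny_features
        model = DetectorModel(config, len(pv), len(dv))
        path = tmp_path / "model.npz"
        model.save(path, pv, dv)
        loaded, pv2, dv2 = DetectorModel.load(path)
        assert np.allclose(loaded.forward(feats).data, model.forward(feats).data)
        with pytest.raises(ValueError, match="config"):
            DetectorModel.load(path, DetectorConfig(hidden=7, seed=1))
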