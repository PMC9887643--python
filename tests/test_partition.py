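"""Partitioning: dedup, threshold clustering, splits, negatives, corruption."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from attnmpi import partition as pt


def make_interactions(pairs, label=1):
    frame = pd.DataFrame(pairs, columns=["metabolite_id", "protein_id"])
    frame["label"] = label
    return pt.InteractionTable(frame)


def transitive_closure_oracle(X, T):
    """O(n^2) reference: repeatedly merge any two groups with a linked pair."""
    n = len(X)
    link = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            link[i, j] = np.linalg.norm(X[i] - X[j]) < T[i, j] or i == j
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(link[i, j] for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    labels = np.empty(n, dtype=int)
    for g, members in enumerate(groups):
        for i in members:
            labels[i] = g
    return labels


class TestCollapseDuplicates:
    def test_identical_sequences_merge(self):
        seqs = {"a": "ACDE", "b": "ACDE", "c": "GHIK"}
        mets = pd.DataFrame({"f": [1.0, 2.0]}, index=["m1", "m2"])
        inter = make_interactions([("m1", "a"), ("m1", "b")])
        _, seq_out, out, _, prot_remap = pt.collapse_duplicates(mets, seqs, inter)
        assert set(seq_out) == {"a", "c"}
        assert prot_remap["b"] == "a"
        # the two rows collapse onto one representative pair
        assert len(out) == 1

    def test_all_distinct_is_identity(self):
        seqs = {"a": "ACDE", "b": "GHIK"}
        mets = pd.DataFrame({"f": [1.0, 2.0]}, index=["m1", "m2"])
        inter = make_interactions([("m1", "a"), ("m2", "b")])
        m, s, out, met_remap, prot_remap = pt.collapse_duplicates(mets, seqs, inter)
        assert met_remap == {"m1": "m1", "m2": "m2"}
        assert prot_remap == {"a": "a", "b": "b"}
        assert len(out) == 2

    def test_shared_fingerprint_pools_interactions(self):
        # 3 metabolites with one fingerprint, each with a distinct positive
        mets = pd.DataFrame({"f1": [1.0, 1.0, 1.0], "f2": [0.0, 0.0, 0.0]},
                            index=["m1", "m2", "m3"])
        seqs = {"p1": "ACDE", "p2": "GHIK", "p3": "LMNP"}
        inter = make_interactions([("m1", "p1"), ("m2", "p2"), ("m3", "p3")])
        m, _, out, met_remap, _ = pt.collapse_duplicates(mets, seqs, inter)
        assert len(m) == 1
        rep = met_remap["m1"]
        assert (out.frame["metabolite_id"] == rep).all()
        assert len(out) == 3


class TestThresholdSchedule:
    def test_protein_defaults_at_extremes(self):
        sizes = pd.Series({"short": 50, "mid": 525, "long": 1000})
        thr = pt.threshold_schedule(sizes, *pt.PROTEIN_THRESHOLDS)
        assert thr["short"] == pytest.approx(7.0)
        assert thr["long"] == pytest.approx(29.0)
        assert thr["mid"] == pytest.approx(18.0)  # linear midpoint

    def test_metabolite_defaults_at_extremes(self):
        thr = pt.threshold_schedule(pd.Series({"l": 100.0, "h": 900.0}),
                                    *pt.METABOLITE_THRESHOLDS)
        assert thr["l"] == pytest.approx(1.2)
        assert thr["h"] == pytest.approx(5.0)

    def test_degenerate_sizes_give_min(self):
        thr = pt.threshold_schedule(pd.Series({"a": 5.0, "b": 5.0}), 7, 29)
        assert (thr == 7).all()

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            pt.threshold_schedule(pd.Series({"a": 1.0}), 5, 2)


class TestClusterEntities:
    def test_identical_vectors_cocluster(self):
        feats = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        thr = pd.Series({"a": 0.5, "b": 0.5})
        cl = pt.cluster_entities(feats, thr)
        assert cl.cluster_of("a") == cl.cluster_of("b")

    def test_chain_transitivity(self):
        # a-b linked, b-c linked, a-c not -> all one cluster
        feats = pd.DataFrame([[0.0], [1.0], [2.0]], index=["a", "b", "c"])
        thr = pd.Series({"a": 1.5, "b": 1.5, "c": 1.5})
        cl = pt.cluster_entities(feats, thr)
        assert len({cl.cluster_of(x) for x in "abc"}) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        X = rng.normal(size=(n, 3)) * 2
        t = rng.uniform(0.5, 3.0, n)
        ids = [f"e{i}" for i in range(n)]
        cl = pt.cluster_entities(pd.DataFrame(X, index=ids),
                                 pd.Series(t, index=ids))
        T = (t[:, None] + t[None, :]) / 2
        expect = transitive_closure_oracle(X, T)
        got = np.array([cl.cluster_of(i) for i in ids])
        # same partition up to relabelling
        for i in range(n):
            for j in range(n):
                assert (got[i] == got[j]) == (expect[i] == expect[j])

    def test_dimension_mismatch_errors(self):
        feats = pd.DataFrame([[0.0]], index=["a"])
        with pytest.raises(ValueError):
            pt.cluster_entities(feats, pd.Series({"b": 1.0}))


def toy_bipartite(n_met=10, n_prot=10, n_pairs=40, seed=0):
    rng = np.random.default_rng(seed)
    mets = [f"m{i}" for i in range(n_met)]
    prots = [f"p{i}" for i in range(n_prot)]
    chosen = rng.choice(n_met * n_prot, size=n_pairs, replace=False)
    pairs = [(mets[i // n_prot], prots[i % n_prot]) for i in chosen]
    met_cl = pt.ClusterAssignment({m: i // 2 for i, m in enumerate(mets)})
    prot_cl = pt.ClusterAssignment({p: i // 2 for i, p in enumerate(prots)})
    return make_interactions(pairs), met_cl, prot_cl


class TestDoubleBlindSplit:
    def test_routing_matches_bruteforce(self):
        inter, met_cl, prot_cl = toy_bipartite()
        folds = pt.double_blind_split(inter, met_cl, prot_cl, 0.3, 0.3, seed=5)
        hm, hp = folds.heldout_met_clusters, folds.heldout_prot_clusters
        for _, row in inter.frame.iterrows():
            m_out = met_cl.cluster_of(row["metabolite_id"]) in hm
            p_out = prot_cl.cluster_of(row["protein_id"]) in hp
            expected = {(False, False): "train", (False, True): "protein_blind",
                        (True, False): "metabolite_blind",
                        (True, True): "double_blind"}[(m_out, p_out)]
            table = dict(folds.items())[expected]
            assert ((table.frame["metabolite_id"] == row["metabolite_id"])
                    & (table.frame["protein_id"] == row["protein_id"])).any()

    def test_fold_invariants(self):
        inter, met_cl, prot_cl = toy_bipartite(seed=3)
        folds = pt.double_blind_split(inter, met_cl, prot_cl, 0.3, 0.3, seed=1)
        train_mc = {met_cl.cluster_of(m) for m in folds.train.frame["metabolite_id"]}
        train_pc = {prot_cl.cluster_of(p) for p in folds.train.frame["protein_id"]}
        for name in ("protein_blind", "double_blind"):
            t = dict(folds.items())[name]
            assert all(prot_cl.cluster_of(p) not in train_pc
                       for p in t.frame["protein_id"])
        for name in ("metabolite_blind", "double_blind"):
            t = dict(folds.items())[name]
            assert all(met_cl.cluster_of(m) not in train_mc
                       for m in t.frame["metabolite_id"])
        # pair disjointness across folds
        all_pairs = [tuple(r) for _, t in folds.items()
                     for r in t.frame[["metabolite_id", "protein_id"]].itertuples(index=False)]
        assert len(all_pairs) == len(set(all_pairs)) == len(inter)

    def test_deterministic_given_seed(self):
        inter, met_cl, prot_cl = toy_bipartite(seed=2)
        f1 = pt.double_blind_split(inter, met_cl, prot_cl, 0.3, 0.3, seed=9)
        f2 = pt.double_blind_split(inter, met_cl, prot_cl, 0.3, 0.3, seed=9)
        for (_, a), (_, b) in zip(f1.items(), f2.items()):
            pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_bad_fraction_errors(self):
        inter, met_cl, prot_cl = toy_bipartite()
        with pytest.raises(ValueError):
            pt.double_blind_split(inter, met_cl, prot_cl, 0.0, 0.3, seed=0)


class TestLenientSplit:
    def test_sizes_and_disjointness(self):
        inter, _, _ = toy_bipartite(n_pairs=100, n_met=20, n_prot=20)
        train, val = pt.lenient_split(inter, val_frac=0.2, seed=0)
        assert len(val) == 20 and len(train) == 80
        assert not (train.pair_set(1) & val.pair_set(1))

    def test_determinism_and_seed_sensitivity(self):
        inter, _, _ = toy_bipartite(n_pairs=60, n_met=20, n_prot=20)
        v1 = pt.lenient_split(inter, 0.3, seed=4)[1].pair_set(1)
        v2 = pt.lenient_split(inter, 0.3, seed=4)[1].pair_set(1)
        v3 = pt.lenient_split(inter, 0.3, seed=5)[1].pair_set(1)
        assert v1 == v2
        assert v1 != v3

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            pt.lenient_split(make_interactions([("m", "p")]), 0.5, seed=0)


class TestSampleNegatives:
    def test_no_overlap_with_positives(self):
        inter, _, _ = toy_bipartite(n_pairs=40)
        negs = pt.sample_negatives(inter, seed=0)
        assert len(negs) == 40
        assert not (negs.pair_set(0) & inter.pair_set(1))
        assert (negs.frame["label"] == 0).all()

    def test_complete_graph_errors(self):
        pairs = [(m, p) for m in ("m1", "m2") for p in ("p1", "p2")]
        with pytest.raises(ValueError):
            pt.sample_negatives(make_interactions(pairs), seed=0)

    def test_single_pair_no_candidates_errors(self):
        with pytest.raises(ValueError):
            pt.sample_negatives(make_interactions([("m1", "p1")]), seed=0)

    def test_marginals_match_positive_frequencies(self):
        # sparse bipartite graph (~1% density) and many balanced resamples:
        # in a dense graph, rejection against the positive set measurably
        # distorts the marginals, and a single huge unique draw saturates the
        # pair space (the sampler's assumptions hold in the sparse regime)
        inter, _, _ = toy_bipartite(n_met=120, n_prot=120, n_pairs=200, seed=1)
        negs = pd.concat([pt.sample_negatives(inter, seed=s).frame
                          for s in range(25)], ignore_index=True)
        pos = inter.positives
        for col in ("metabolite_id", "protein_id"):
            pos_freq = pos[col].value_counts(normalize=True)
            observed = (negs[col].value_counts()
                        .reindex(pos_freq.index).fillna(0).to_numpy())
            expected = pos_freq.to_numpy() * observed.sum()
            _, p = chisquare(observed, expected)
            assert p > 0.01, col


class TestCorruptPairs:
    def test_single_pair_unchanged(self):
        out = pt.corrupt_pairs(make_interactions([("m1", "p1")]), seed=0)
        assert out.pair_set(1) == {("m1", "p1")}

    def test_frequency_spectrum_preserved(self):
        inter, _, _ = toy_bipartite(n_pairs=60, seed=4)
        out = pt.corrupt_pairs(inter, seed=1)
        assert len(out) == len(inter)
        for col in ("metabolite_id", "protein_id"):
            pd.testing.assert_series_equal(
                inter.frame[col].value_counts().sort_index(),
                out.frame[col].value_counts().sort_index())

    def test_collision_rate_near_expectation(self):
        # fraction of preserved pairs under a uniform permutation of the
        # protein column ~ Monte-Carlo expectation
        inter, _, _ = toy_bipartite(n_met=10, n_prot=10, n_pairs=100, seed=6)
        pos = inter.pair_set(1)
        rng = np.random.default_rng(0)
        prots = inter.frame["protein_id"].to_numpy()
        mets = inter.frame["metabolite_id"].to_numpy()
        mc = np.mean([
            np.mean([(m, p) in pos for m, p in
                     zip(mets, prots[rng.permutation(len(prots))])])
            for _ in range(300)])
        observed = np.mean([
            np.mean([(m, p) in pos for m, p in
                     zip(pt.corrupt_pairs(inter, seed=s).frame["metabolite_id"],
                         pt.corrupt_pairs(inter, seed=s).frame["protein_id"])])
            for s in range(30)])
        assert abs(observed - mc) < 0.1


class TestCorruptFeatures:
    def test_single_entity_identity(self):
        frame = pd.DataFrame({"f": [1.0]}, index=["m1"])
        out = pt.corrupt_features(frame, seed=0, kind="metabolite")
        pd.testing.assert_frame_equal(out, frame)

    def test_multiset_preserved(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(20, 4)),
                             index=[f"m{i}" for i in range(20)])
        out = pt.corrupt_features(frame, seed=3, kind="metabolite")
        assert sorted(map(tuple, out.to_numpy())) == \
            sorted(map(tuple, frame.to_numpy()))
        assert list(out.index) == list(frame.index)

    def test_seed_sensitivity(self):
        seqs = {f"p{i}": "ACDE" * (i + 1) for i in range(10)}
        a = pt.corrupt_features(seqs, seed=1, kind="protein")
        b = pt.corrupt_features(seqs, seed=2, kind="protein")
        assert a != b

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError):
            pt.corrupt_features({}, seed=0, kind="gene")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_cluster_oracle_property(seed):
    """cluster_entities equals the transitive-closure oracle on random instances."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    X = rng.normal(size=(n, 2))
    t = rng.uniform(0.1, 2.0, n)
    ids = [f"e{i}" for i in range(n)]
    cl = pt.cluster_entities(pd.DataFrame(X, index=ids), pd.Series(t, index=ids))
    expect = transitive_closure_oracle(X, (t[:, None] + t[None, :]) / 2)
    got = np.array([cl.cluster_of(i) for i in ids])
    same_got = got[:, None] == got[None, :]
    same_exp = expect[:, None] == expect[None, :]
    assert (same_got == same_exp).all()
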