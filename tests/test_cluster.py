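import math

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from ngsdesk import cluster
from ngsdesk.profile import SNVProfile
from ngsdesk.tree import TreeNode


def random_profile(rng, n_positions=200, ref_id="ref"):
    profile = SNVProfile(ref_id=ref_id)
    for pos in range(n_positions):
        profile.depths[pos] = int(rng.integers(1, 100))
        if rng.random() < 0.3:
            profile.freqs[pos] = float(rng.uniform(0.01, 1.0))
    return profile


def random_distance_matrix(rng, n=8):
    """Random symmetric matrix with distinct positive entries."""
    vals = rng.uniform(1.0, 10.0, size=(n, n))
    mat = np.triu(vals, 1)
    mat = mat + mat.T
    labels = [f"s{i}" for i in range(n)]
    return cluster.DistanceMatrix(labels=labels, values=mat)


# ---------------------------------------------------------------------------
# filter_profile
# ---------------------------------------------------------------------------

def test_filter_empty_filters_is_identity():
    rng = np.random.default_rng(90)
    profile = random_profile(rng)
    params = cluster.ClusterParams(min_depth=1, min_freq=0.0)
    out = cluster.filter_profile(profile, params)
    assert out.freqs == profile.freqs
    assert out.depths == profile.depths


def test_filter_min_freq_boundary():
    profile = SNVProfile(ref_id="ref", freqs={1: 0.5, 2: 1.0}, depths={1: 30, 2: 30})
    params = cluster.ClusterParams(min_freq=1.0)
    out = cluster.filter_profile(profile, params)
    assert out.freqs == {2: 1.0}


def test_filter_brute_force_predicate_oracle():
    rng = np.random.default_rng(91)
    profile = random_profile(rng)
    whitelist = [(10, 60), (100, 150)]
    blacklist = [(70, 80)]
    params = cluster.ClusterParams(
        min_depth=20, min_freq=0.1,
        position_whitelist=whitelist, position_blacklist=blacklist,
    )
    out = cluster.filter_profile(profile, params)
    for pos, freq in profile.freqs.items():
        keep = (
            profile.depths[pos] >= 20
            and any(s <= pos < e for s, e in whitelist)
            and not any(s <= pos < e for s, e in blacklist)
            and freq >= 0.1
        )
        assert (pos in out.freqs) == keep


def test_filter_contradictory_lists_error():
    with pytest.raises(ValueError):
        cluster.ClusterParams(
            position_whitelist=[(0, 100)], position_blacklist=[(50, 60)]
        )


# ---------------------------------------------------------------------------
# profile_distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("metric", cluster.METRICS)
def test_distance_to_self_is_zero(metric):
    rng = np.random.default_rng(92)
    profile = random_profile(rng)
    d = cluster.profile_distance(profile, profile, metric)
    if metric == "pearson":
        # self-correlation is exact: r = 1 -> distance 0 (non-constant vector)
        assert d == pytest.approx(0.0, abs=1e-12)
    else:
        assert d == 0.0


def test_distance_single_coordinate():
    a = SNVProfile(ref_id="ref", freqs={5: 1.0}, depths={5: 50})
    b = SNVProfile(ref_id="ref", freqs={}, depths={5: 50})
    assert cluster.profile_distance(a, b, "manhattan") == pytest.approx(1.0)
    assert cluster.profile_distance(a, b, "euclidean") == pytest.approx(1.0)
    assert cluster.profile_distance(a, b, "canberra") == pytest.approx(1.0)


def test_distance_brute_force_oracle():
    rng = np.random.default_rng(93)
    a, b = random_profile(rng), random_profile(rng)
    union = sorted(set(a.freqs) | set(b.freqs))
    kept = [p for p in union if p in a.depths and p in b.depths]
    va = [a.freqs.get(p, 0.0) for p in kept]
    vb = [b.freqs.get(p, 0.0) for p in kept]

    euclid = math.sqrt(sum((x - y) ** 2 for x, y in zip(va, vb)))
    manhattan = sum(abs(x - y) for x, y in zip(va, vb))
    canberra = sum(
        abs(x - y) / (x + y) for x, y in zip(va, vb) if x + y > 0
    )
    mean_a = sum(va) / len(va)
    mean_b = sum(vb) / len(vb)
    cov = sum((x - mean_a) * (y - mean_b) for x, y in zip(va, vb))
    var_a = sum((x - mean_a) ** 2 for x in va)
    var_b = sum((y - mean_b) ** 2 for y in vb)
    pearson = 1.0 - cov / math.sqrt(var_a * var_b)

    assert cluster.profile_distance(a, b, "euclidean") == pytest.approx(euclid, abs=1e-12)
    assert cluster.profile_distance(a, b, "manhattan") == pytest.approx(manhattan, abs=1e-12)
    assert cluster.profile_distance(a, b, "canberra") == pytest.approx(canberra, abs=1e-12)
    assert cluster.profile_distance(a, b, "pearson") == pytest.approx(pearson, abs=1e-12)


def test_distance_uncovered_positions_dropped_for_both():
    a = SNVProfile(ref_id="ref", freqs={5: 0.8}, depths={5: 40})
    b = SNVProfile(ref_id="ref", freqs={}, depths={})  # position 5 uncovered in b
    assert cluster.profile_distance(a, b, "manhattan") == 0.0


def test_distance_different_ref_errors():
    a = SNVProfile(ref_id="x", freqs={}, depths={})
    b = SNVProfile(ref_id="y", freqs={}, depths={})
    with pytest.raises(ValueError):
        cluster.profile_distance(a, b, "euclidean")


# ---------------------------------------------------------------------------
# distance_matrix
# ---------------------------------------------------------------------------

def test_matrix_identical_profiles_all_zero():
    rng = np.random.default_rng(94)
    profile = random_profile(rng)
    params = cluster.ClusterParams(metric="manhattan")
    mat = cluster.distance_matrix(
        [("a", profile), ("b", profile), ("c", profile)], params
    )
    assert np.allclose(mat.values, 0.0)


def test_matrix_two_profiles():
    rng = np.random.default_rng(95)
    a, b = random_profile(rng), random_profile(rng)
    params = cluster.ClusterParams(metric="euclidean")
    mat = cluster.distance_matrix([("a", a), ("b", b)], params)
    assert mat.values.shape == (2, 2)
    assert mat.values[0, 1] == mat.values[1, 0] > 0


def test_matrix_consistency_with_pairwise_op():
    rng = np.random.default_rng(96)
    profiles = [(f"s{i}", random_profile(rng)) for i in range(5)]
    params = cluster.ClusterParams(metric="canberra", min_depth=10)
    mat = cluster.distance_matrix(profiles, params)
    assert np.allclose(mat.values, mat.values.T)
    filtered = [cluster.filter_profile(p, params) for _, p in profiles]
    for i in range(5):
        for j in range(5):
            expected = (
                0.0 if i == j
                else cluster.profile_distance(filtered[i], filtered[j], "canberra")
            )
            assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_matrix_fewer_than_two_errors():
    rng = np.random.default_rng(97)
    with pytest.raises(ValueError):
        cluster.distance_matrix([("a", random_profile(rng))], cluster.ClusterParams())


# ---------------------------------------------------------------------------
# hierarchical_cluster
# ---------------------------------------------------------------------------

def test_two_samples_forced_upgma():
    mat = cluster.DistanceMatrix(
        labels=["A", "B"], values=np.array([[0.0, 2.0], [2.0, 0.0]])
    )
    from ngsdesk.core_io import write_newick

    tree = cluster.hierarchical_cluster(mat, "average")
    assert write_newick(tree) == "(A:1.0,B:1.0);"


@pytest.mark.parametrize("linkage", ["single", "complete", "average"])
def test_dominant_pair_merges_first(linkage):
    values = np.array(
        [[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]]
    )
    mat = cluster.DistanceMatrix(labels=["A", "B", "C"], values=values)
    tree = cluster.hierarchical_cluster(mat, linkage)
    # first merge is (A, B): one child of root holds exactly {A, B}
    child_leafsets = [frozenset(c.leaf_labels()) for c in tree.children]
    assert frozenset({"A", "B"}) in child_leafsets


@pytest.mark.parametrize("linkage", ["single", "complete", "average"])
def test_agglomerative_matches_scipy_cophenetic(linkage):
    rng = np.random.default_rng(98)
    for _ in range(5):
        mat = random_distance_matrix(rng, n=8)
        tree = cluster.hierarchical_cluster(mat, linkage)
        ours = tree.cophenetic()
        scipy_linkage = sch.linkage(squareform(mat.values), method=linkage)
        coph = squareform(sch.cophenet(scipy_linkage))
        for i in range(8):
            for j in range(i + 1, 8):
                key = frozenset((mat.labels[i], mat.labels[j]))
                assert ours[key] == pytest.approx(coph[i, j], abs=1e-9)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns root."""
    nodes = [TreeNode(label=f"t{i}", length=float(rng.uniform(0.5, 3.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.5, 3.0))
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


def test_nj_recovers_additive_topology():
    rng = np.random.default_rng(99)
    for _ in range(5):
        truth = random_additive_tree(rng, 8)
        labels = sorted(truth.leaf_labels())
        coph = truth.cophenetic()
        values = np.zeros((8, 8))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    values[i, j] = coph[frozenset((a, b))]
        mat = cluster.DistanceMatrix(labels=labels, values=values)
        nj = cluster.hierarchical_cluster(mat, "neighbor_joining")
        assert nj.splits() == truth.splits()
        # NJ on additive data also reproduces the leaf-pair distances
        nj_coph = nj.cophenetic()
        for key, value in coph.items():
            assert nj_coph[key] == pytest.approx(value, abs=1e-9)


def test_upgma_is_ultrametric():
    rng = np.random.default_rng(100)
    mat = random_distance_matrix(rng, n=10)
    tree = cluster.hierarchical_cluster(mat, "average")
    depths = tree.leaf_depths()
    values = list(depths.values())
    assert max(values) - min(values) < 1e-9


def test_leaf_set_equals_input_labels():
    rng = np.random.default_rng(101)
    mat = random_distance_matrix(rng, n=7)
    for linkage in cluster.LINKAGES:
        tree = cluster.hierarchical_cluster(mat, linkage)
        assert sorted(tree.leaf_labels()) == sorted(mat.labels)


@pytest.mark.parametrize("linkage", cluster.LINKAGES)
def test_permutation_invariance(linkage):
    rng = np.random.default_rng(102)
    mat = random_distance_matrix(rng, n=6)
    perm = rng.permutation(6)
    permuted = cluster.DistanceMatrix(
        labels=[mat.labels[i] for i in perm],
        values=mat.values[np.ix_(perm, perm)],
    )
    t1 = cluster.hierarchical_cluster(mat, linkage)
    t2 = cluster.hierarchical_cluster(permuted, linkage)
    c1, c2 = t1.cophenetic(), t2.cophenetic()
    assert set(c1) == set(c2)
    for key in c1:
        assert c1[key] == pytest.approx(c2[key], abs=1e-9)


def test_invalid_matrix_rejected():
    bad = cluster.DistanceMatrix(
        labels=["A", "B"], values=np.array([[0.0, 1.0], [1.0, 0.0]])
    )
    bad.values[0, 1] = bad.values[1, 0] = float("nan")
    with pytest.raises(ValueError):
        cluster.hierarchical_cluster(bad, "average")


def test_distance_matrix_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(103)
    mat = random_distance_matrix(rng, n=4)
    path = tmp_path / "dist.tsv"
    cluster.write_distance_matrix(mat, path)
    back = cluster.read_distance_matrix(path)
    assert back.labels == mat.labels
    assert np.allclose(back.values, mat.values, atol=1e-9)
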