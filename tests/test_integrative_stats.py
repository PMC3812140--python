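"""Statistics layer: Spearman with exact permutation p, Fisher exact vs full
enumeration, concordance, intersection, classical MDS and bi-clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from conftest import make_expression
from lnccompartment import (
    ContingencyTable2x2,
    StatsError,
    bicluster_grid,
    classical_mds,
    correlation_distance_matrix,
    fisher_exact,
    fold_change_concordance,
    intersect_de,
    length_expression_grid,
    odds_ratio,
    pair_concordance,
    spearman_rho,
)
from lnccompartment.integrative_stats import last_joining_singleton, linkage_to_newick
from lnccompartment.synthetic_data import simulate_concordant_pairs


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_identity():
    assert spearman_rho([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)


def test_spearman_hand_value():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 6
    assert spearman_rho([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)


def test_spearman_symmetry_and_monotone_invariance():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=30), rng.normal(size=30)
    a = spearman_rho(x, y)
    assert spearman_rho(y, x).rho == pytest.approx(a.rho)
    assert spearman_rho(np.exp(x), y**3).rho == pytest.approx(a.rho)


def test_spearman_constant_vector_absent():
    res = spearman_rho([1, 1, 1], [1, 2, 3])
    assert res.is_absent()
    assert res.reason == "constant input"


@pytest.mark.parametrize("n", [5, 6, 7])
def test_spearman_exact_p_matches_bruteforce_enumeration(n):
    rng = np.random.default_rng(n)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    res = spearman_rho(x, y)
    # independent oracle: scipy rho over every permutation of y
    obs = abs(sps.spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(sps.spearmanr(x, perm).statistic) >= obs - 1e-12:
            count += 1
    assert res.p == pytest.approx(count / total)


def test_spearman_t_approximation_at_large_n():
    rng = np.random.default_rng(11)
    x, y = rng.normal(size=50), rng.normal(size=50)
    res = spearman_rho(x, y)
    t = res.rho * math.sqrt(48 / (1 - res.rho**2))
    assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 48))


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _enumeration_p(t: ContingencyTable2x2) -> float:
    """Full hypergeometric enumeration over tables with fixed margins."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2

    def prob(a):
        return comb(r1, a, exact=True) * comb(r2, c1 - a, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(t.a)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_symmetric_table():
    res = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_two_sided == pytest.approx(1.0)


@pytest.mark.parametrize("cells", [(1, 9, 11, 3), (0, 10, 10, 0), (3, 0, 0, 7), (2, 5, 9, 1)])
def test_fisher_p_matches_enumeration_hand_cases(cells):
    t = ContingencyTable2x2(*cells)
    assert fisher_exact(t).p_two_sided == pytest.approx(_enumeration_p(t))


def test_fisher_p_matches_enumeration_sweep_margins_up_to_30():
    rng = np.random.default_rng(8)
    # exhaustive small corner plus random tables with margins <= 30
    for a, b, c, d in itertools.product(range(4), repeat=4):
        t = ContingencyTable2x2(a, b, c, d)
        if t.total == 0:
            continue
        assert fisher_exact(t).p_two_sided == pytest.approx(_enumeration_p(t))
    for _ in range(150):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        t = ContingencyTable2x2(a, b, c, d)
        if t.total == 0:
            continue
        assert fisher_exact(t).p_two_sided == pytest.approx(_enumeration_p(t))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
def test_fisher_p_matches_enumeration_property(cells):
    t = ContingencyTable2x2(*cells)
    assert fisher_exact(t).p_two_sided == pytest.approx(_enumeration_p(t))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True),
    st.randoms(use_true_random=False),
)
def test_spearman_invariant_under_strictly_monotone_transforms(x, rnd):
    y = list(x)
    rnd.shuffle(y)
    base = spearman_rho(x, y).rho
    # transforms chosen to be exactly injective on doubles (smooth maps like
    # exp() collapse distinct subnormals, which would create spurious ties)
    from scipy.stats import rankdata

    assert spearman_rho(rankdata(x) ** 3, y).rho == pytest.approx(base)
    assert spearman_rho(x, 8.0 * np.asarray(y)).rho == pytest.approx(base)


def test_odds_ratio_conventions():
    assert odds_ratio(ContingencyTable2x2(0, 10, 10, 0)) == 0.0
    assert odds_ratio(ContingencyTable2x2(10, 0, 0, 10)) == math.inf
    assert odds_ratio(ContingencyTable2x2(0, 0, 5, 5)) == 0.0
    assert odds_ratio(ContingencyTable2x2(8, 2, 2, 8)) == pytest.approx(16.0)
    # Haldane smoothing keeps zero-cell tables finite
    assert odds_ratio(ContingencyTable2x2(10, 0, 0, 10), haldane=True) == pytest.approx(441.0)


def test_fisher_all_zero_errors():
    with pytest.raises(StatsError):
        fisher_exact(ContingencyTable2x2(0, 0, 0, 0))


# ---------------------------------------------------------------------------
# fold-change concordance
# ---------------------------------------------------------------------------

def _de_frame(log2fc, direction, passed=None, ids=None):
    n = len(log2fc)
    ids = ids or [f"p{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "fc": 2.0 ** np.asarray(log2fc, dtype=float),
            "log2fc": log2fc,
            "direction": direction,
            "passed_flag_filter": passed if passed is not None else [True] * n,
        },
        index=pd.Index(ids, name="probe_id"),
    )


def test_concordance_of_identical_tables():
    de = _de_frame([2.0, -2.0, 0.1, 1.5], ["up", "down", "unchanged", "up"])
    corr, table, fisher = fold_change_concordance(de, de)
    assert corr.rho == pytest.approx(1.0)
    assert (table.b, table.c) == (0, 0)
    assert fisher.odds_ratio == math.inf


def test_concordance_hand_ranked_three_probes():
    a = _de_frame([0.1, 0.2, 0.3], ["unchanged"] * 3)
    b = _de_frame([0.5, 0.1, 0.3], ["unchanged"] * 3)
    corr, table, _ = fold_change_concordance(a, b)
    assert corr.rho == pytest.approx(-0.5)  # ranks (1,2,3) vs (3,1,2)
    assert table.total == 0


def test_concordance_requires_shared_flagged_probes():
    a = _de_frame([1.0, 2.0, 3.0], ["up"] * 3, passed=[False, False, True])
    b = _de_frame([1.0, 2.0, 3.0], ["up"] * 3)
    with pytest.raises(StatsError, match="fewer than 3"):
        fold_change_concordance(a, b)


# ---------------------------------------------------------------------------
# triple intersection
# ---------------------------------------------------------------------------

def _classes_frame(ids, class4="intergenic", partner=None):
    return pd.DataFrame(
        {
            "lnc_id": ids,
            "class6": class4,
            "class4": class4,
            "partner_gene_id": partner,
            "tss_distance_bp": None,
        }
    )


def test_intersect_disjoint_de_sets_empty():
    ids = [f"p{i}" for i in range(3)]
    classes = _classes_frame(ids)
    a = _de_frame([2, 0, 0], ["up", "unchanged", "unchanged"], ids=ids)
    b = _de_frame([0, 2, 0], ["unchanged", "up", "unchanged"], ids=ids)
    c = _de_frame([0, 0, 2], ["unchanged", "unchanged", "up"], ids=ids)
    assert len(intersect_de(a, b, c, classes)) == 0


def test_intersect_matches_planted_overlap_and_is_order_invariant(small_study, small_de):
    de = small_de["lnc"]
    out = intersect_de(
        de["heart"], de["plasma"], de["whole_blood"], small_study.truth,
        probe_transcript=small_study.lnc_expr.probe_transcript,
    )
    d = small_study.planted.table
    expected = (
        pd.concat(
            [d[f"direction_{c}"] != "unchanged" for c in ("heart", "plasma", "whole_blood")],
            axis=1,
        )
        .all(axis=1)
        .sum()
    )
    assert len(out) == int(expected)
    # permuting input row order changes nothing
    perm = np.random.default_rng(0).permutation(len(de["heart"]))
    out2 = intersect_de(
        de["heart"].iloc[perm], de["plasma"], de["whole_blood"], small_study.truth,
        probe_transcript=small_study.lnc_expr.probe_transcript,
    )
    assert sorted(out2["lnc_id"]) == sorted(out["lnc_id"])


def test_intersect_directions_use_plus_minus():
    ids = ["p0"]
    classes = _classes_frame(ids)
    up = _de_frame([2.0], ["up"], ids=ids)
    down = _de_frame([-2.0], ["down"], ids=ids)
    out = intersect_de(up, down, down, classes)
    assert out.iloc[0][["dir_heart", "dir_plasma", "dir_whole_blood"]].tolist() == ["+", "-", "-"]


# ---------------------------------------------------------------------------
# pair concordance
# ---------------------------------------------------------------------------

def test_pair_concordance_all_codirectional_infinite_or():
    n = 10
    lnc_ids = [f"l{i}" for i in range(n)]
    gene_ids = [f"g{i}" for i in range(n)]
    dirs = ["up"] * 5 + ["down"] * 5
    lnc_de = _de_frame([1] * n, dirs, ids=lnc_ids)
    mrna_de = _de_frame([1] * n, dirs, ids=gene_ids)
    classes = _classes_frame(lnc_ids, class4="sense_overlap", partner=gene_ids)
    res = pair_concordance(lnc_de, mrna_de, classes)
    assert res["sense_overlap"].fisher.odds_ratio == math.inf
    assert res["antisense_overlap"] is None


def test_pair_concordance_hand_table():
    # 8 concordant-up, 2 up/down, 2 down/up, 8 concordant-down -> OR 16
    lnc_dirs = ["up"] * 10 + ["down"] * 10
    mrna_dirs = ["up"] * 8 + ["down"] * 2 + ["up"] * 2 + ["down"] * 8
    lnc_ids = [f"l{i}" for i in range(20)]
    gene_ids = [f"g{i}" for i in range(20)]
    lnc_de = _de_frame([1] * 20, lnc_dirs, ids=lnc_ids)
    mrna_de = _de_frame([1] * 20, mrna_dirs, ids=gene_ids)
    classes = _classes_frame(lnc_ids, class4="antisense_overlap", partner=gene_ids)
    res = pair_concordance(lnc_de, mrna_de, classes)["antisense_overlap"]
    assert res.table.as_array().tolist() == [[8, 2], [2, 8]]
    assert res.fisher.odds_ratio == pytest.approx(16.0)
    assert res.fisher.p_two_sided == pytest.approx(
        _enumeration_p(ContingencyTable2x2(8, 2, 2, 8))
    )


def test_pair_concordance_null_or_recovery():
    lnc_de, mrna_de, classes = simulate_concordant_pairs(1.0, 1000, seed=2)
    res = pair_concordance(lnc_de, mrna_de, classes)["sense_overlap"]
    assert 0.7 <= res.fisher.odds_ratio <= 1.4


# ---------------------------------------------------------------------------
# correlation distance + classical MDS
# ---------------------------------------------------------------------------

def test_correlation_distance_limits():
    x = np.arange(10.0)
    df = pd.DataFrame({"a": x, "b": x, "c": x[::-1]})
    D = correlation_distance_matrix(df)
    assert D.loc["a", "b"] == pytest.approx(0.0)
    assert D.loc["a", "c"] == pytest.approx(2.0)
    np.testing.assert_allclose(D.values, D.values.T)
    np.testing.assert_allclose(np.diag(D.values), 0.0)


def test_correlation_distance_rejects_constant_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(StatsError, match="'b'"):
        correlation_distance_matrix(df)


def test_mds_reproduces_345_triangle_to_machine_tolerance():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    emb = classical_mds(pd.DataFrame(D, index=list("abc"), columns=list("abc")))
    X = emb.coords.values
    got = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.testing.assert_allclose(got, D, atol=1e-9)
    np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)


def test_mds_reproduces_random_planar_metrics():
    rng = np.random.default_rng(4)
    P = rng.normal(size=(4, 2))
    D = np.sqrt(((P[:, None] - P[None]) ** 2).sum(-1))
    emb = classical_mds(D)
    X = emb.coords.values
    got = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    np.testing.assert_allclose(got, D, atol=1e-9)


def test_mds_zero_distances_collapse_to_origin():
    with pytest.warns(UserWarning, match="padding"):
        emb = classical_mds(np.zeros((3, 3)))
    np.testing.assert_allclose(emb.coords.values, 0.0)


def test_mds_validates_input():
    with pytest.raises(StatsError):
        classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(StatsError):
        classical_mds(np.array([[1.0, 1.0], [1.0, 1.0]]))  # nonzero diagonal


# ---------------------------------------------------------------------------
# bi-clustering
# ---------------------------------------------------------------------------

def _profile_grid():
    """Class x sample rho grid at the planted study-profile values, with the
    pooled Total row as the mixture-weighted class average."""
    from lnccompartment import SimulationConfig

    cfg = SimulationConfig.paper_profile()
    weights = {"sense_overlap": 0.20, "antisense_overlap": 0.20, "bidirectional": 0.10, "intergenic": 0.50}
    cols = {}
    for sample, per_class in cfg.length_expr_rho.items():
        total = sum(per_class[c] * w for c, w in weights.items())
        cols[sample] = [total, per_class["antisense_overlap"], per_class["bidirectional"],
                        per_class["sense_overlap"], per_class["intergenic"]]
    return pd.DataFrame(cols, index=["Total", "Antisense", "Bidirectional", "Sense", "Intergenic"])


def test_bicluster_identical_rows_merge_first():
    grid = pd.DataFrame(
        [[0.1, 0.2], [0.1, 0.2], [0.9, -0.5]], index=["r1", "r2", "r3"], columns=["c1", "c2"]
    )
    res = bicluster_grid(grid)
    assert res.row_linkage[0, 2] == pytest.approx(0.0)
    assert set(res.row_linkage[0, :2].astype(int)) == {0, 1}  # r1, r2 merge first
    assert abs(res.row_order.index("r1") - res.row_order.index("r2")) == 1


def test_bicluster_deterministic():
    grid = _profile_grid()
    a = bicluster_grid(grid)
    b = bicluster_grid(grid.copy())
    assert a.row_order == b.row_order
    assert a.col_order == b.col_order
    assert a.col_newick == b.col_newick


def test_bicluster_hf_plasma_is_last_joining_singleton():
    """The decoupled HF-plasma column is the outgroup of the sample tree."""
    res = bicluster_grid(_profile_grid())
    assert last_joining_singleton(res.col_linkage, list(_profile_grid().columns)) == "plasma_HF"


def test_bicluster_rejects_absent_cells():
    grid = pd.DataFrame([[0.1, np.nan]], index=["r"], columns=["c1", "c2"])
    with pytest.raises(StatsError, match=r"\(r,c2\)"):
        bicluster_grid(grid)


def test_newick_output_parses_with_dendropy():
    import dendropy

    res = bicluster_grid(_profile_grid())
    tree = dendropy.Tree.get(data=res.col_newick, schema="newick", preserve_underscores=True)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    assert leaves == set(_profile_grid().columns)


# ---------------------------------------------------------------------------
# length-expression grid
# ---------------------------------------------------------------------------

def _tiny_grid_inputs(n=30, antitone=False, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"L{i}" for i in range(n)]
    lengths = pd.Series(rng.integers(200, 50_000, size=n).astype(float), index=ids)
    classes = _classes_frame(ids)
    idx = pd.Index([f"probe_{i}" for i in range(n)], name="probe_id")
    if antitone:
        inten = 1e6 / lengths.values
    else:
        inten = rng.lognormal(8, 1, size=n)
    intensity = pd.DataFrame({"heart_HF": inten, "heart_control": inten[::-1].copy()}, index=idx)
    flags = pd.DataFrame("P", index=idx, columns=intensity.columns)
    samples = pd.DataFrame(
        {"compartment": "heart", "condition": ["HF", "control"]}, index=intensity.columns
    )
    from lnccompartment.expression_core import ExpressionMatrix

    m = ExpressionMatrix(intensity, flags, pd.Series(ids, index=idx), samples)
    return m, lengths, classes


def test_grid_perfect_antitone_gives_minus_one():
    m, lengths, classes = _tiny_grid_inputs(antitone=True)
    grid = length_expression_grid(m, lengths, classes)
    assert grid.rho.loc["Total", "heart_HF"] == pytest.approx(-1.0)
    assert grid.rho.loc["Intergenic", "heart_HF"] == pytest.approx(-1.0)


def test_grid_small_classes_reported_absent():
    m, lengths, classes = _tiny_grid_inputs()
    grid = length_expression_grid(m, lengths, classes)
    assert np.isnan(grid.rho.loc["Sense", "heart_HF"])  # class empty -> absent
    assert grid.n.loc["Sense", "heart_HF"] == 0


def test_grid_requires_lengths_and_classes():
    m, lengths, classes = _tiny_grid_inputs()
    with pytest.raises(StatsError, match="length"):
        length_expression_grid(m, lengths.iloc[:-5], classes)
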