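import numpy as np
import pytest
from scipy import stats

from deltacf.concordance import (
    GeneTreeClass,
    annotate_species_tree,
    classify_gene_tree,
    gene_concordance,
    polytomy_chi2,
    records_to_dataframe,
    site_concordance,
    with_site_concordance,
)
from deltacf.trees import BranchContext, branch_contexts, parse_newick

CTX4 = BranchContext(
    "b1", frozenset("a"), frozenset("b"), frozenset("c"), frozenset("d")
)


# ----------------------------------------------------------- classification


@pytest.mark.parametrize(
    "newick,expected",
    [
        ("((a,b),(c,d));", GeneTreeClass.CONCORDANT),
        ("((a,c),(b,d));", GeneTreeClass.ALT1),
        ("((a,d),(b,c));", GeneTreeClass.ALT2),
        ("((a,b),c);", GeneTreeClass.NOT_DECISIVE),  # <4 leaves
    ],
)
def test_classify_four_taxon(newick, expected):
    assert classify_gene_tree(parse_newick(newick), CTX4) == expected


def test_classify_missing_group_not_decisive():
    ctx = BranchContext(
        "b", frozenset({"a1", "a2"}), frozenset("b"), frozenset("c"), frozenset("d")
    )
    # no member of C present
    gt = parse_newick("((a1,a2),(b,d));")
    assert classify_gene_tree(gt, ctx) == GeneTreeClass.NOT_DECISIVE


def test_classify_multi_taxon_groups():
    ctx = BranchContext(
        "b", frozenset({"a1", "a2"}), frozenset("b"), frozenset("c"), frozenset("d")
    )
    # the (b,d) cherry induces the split {b,d} | {a1,a2,c} = (A∪C)|(B∪D)
    gt = parse_newick("((a1,c),(a2,(b,d)));")
    assert classify_gene_tree(gt, ctx) == GeneTreeClass.ALT1


def test_classify_paraphyletic():
    ctx = BranchContext(
        "b", frozenset({"a1", "a2"}), frozenset("b"), frozenset("c"), frozenset("d")
    )
    # splits {a1,c}|{a2,b,d} and {a2,d}|{a1,b,c}: none of the three
    # arrangements is displayed
    gt = parse_newick("((a1,c),(b,(a2,d)));")
    assert classify_gene_tree(gt, ctx) == GeneTreeClass.PARAPHYLETIC


def test_classify_subset_of_group_is_enough():
    ctx = BranchContext(
        "b", frozenset({"a1", "a2"}), frozenset("b"), frozenset("c"), frozenset("d")
    )
    # a2 missing: decisiveness needs one representative per group
    gt = parse_newick("((a1,b),(c,d));")
    assert classify_gene_tree(gt, ctx) == GeneTreeClass.CONCORDANT


def test_classify_rejects_alien_taxa():
    with pytest.raises(Exception):
        classify_gene_tree(parse_newick("((a,b),(c,zz));"), CTX4)


# ------------------------------------------------------- gene concordance


def test_identical_gene_trees_give_gcf_100():
    sp = parse_newick("((((a,b),c),d),e);")
    genes = [parse_newick("((((a,b),c),d),e);") for _ in range(3)]
    for rec in gene_concordance(sp, genes):
        assert rec.gcf == 100.0
        assert rec.n_decisive == 3


def test_fig2_counts_give_gcf_34_21():
    sp = parse_newick("((a,b),(c,d));")
    genes = (
        [parse_newick("((a,b),(c,d));")] * 442
        + [parse_newick("((a,c),(b,d));")] * 437
        + [parse_newick("((a,d),(b,c));")] * 413
    )
    (rec,) = gene_concordance(sp, genes)
    assert rec.n_decisive == 1292
    assert rec.gcf == pytest.approx(100 * 442 / 1292)
    assert rec.gcf == pytest.approx(34.21, abs=0.005)
    assert {rec.n_alt1, rec.n_alt2} == {437, 413}


def test_percentage_conservation_and_order_invariance(rng):
    sp = parse_newick("((((a,b),c),d),e);")
    pool = [
        "((((a,b),c),d),e);",
        "((((a,c),b),d),e);",
        "((((a,d),b),c),e);",
        "(((a,b),(c,d)),e);",
        "((a,b),(c,e));",
        "((a,e),(b,c));",
    ]
    genes = [parse_newick(pool[i]) for i in rng.integers(0, len(pool), size=60)]
    recs = gene_concordance(sp, genes)
    for rec in recs:
        total = rec.n_concordant + rec.n_alt1 + rec.n_alt2 + rec.n_paraphyletic
        assert total == rec.n_decisive
        if rec.n_decisive > 0:
            assert rec.gcf + rec.gdf1 + rec.gdf2 + rec.gdfp == pytest.approx(100.0)
    shuffled = [genes[i] for i in rng.permutation(len(genes))]
    recs2 = gene_concordance(sp, shuffled)
    assert recs == recs2


def test_cd_swap_exchanges_alternatives():
    swapped = BranchContext("b1", CTX4.a, CTX4.b, CTX4.d, CTX4.c)
    gt = parse_newick("((a,c),(b,d));")
    assert classify_gene_tree(gt, CTX4) == GeneTreeClass.ALT1
    assert classify_gene_tree(gt, swapped) == GeneTreeClass.ALT2


def test_no_decisive_trees_gives_undefined_percentages():
    sp = parse_newick("((a,b),(c,d));")
    genes = [parse_newick("((a,b),c);")]  # 3 leaves: never decisive
    (rec,) = gene_concordance(sp, genes)
    assert rec.n_decisive == 0
    assert rec.gcf is None


# ------------------------------------------------------------ polytomy test


def test_polytomy_equal_counts():
    chi2, p = polytomy_chi2(10, 10, 10)
    assert chi2 == 0.0 and p == 1.0


def test_polytomy_fig2_counts():
    chi2, p = polytomy_chi2(442, 437, 413)
    assert chi2 == pytest.approx(1.116, abs=0.001)
    assert p == pytest.approx(0.572, abs=0.001)


def test_polytomy_extreme():
    chi2, p = polytomy_chi2(300, 0, 0)
    assert chi2 == pytest.approx(600.0)
    assert p < 1e-100


def test_polytomy_all_zero_raises():
    with pytest.raises(ValueError):
        polytomy_chi2(0, 0, 0)


def test_polytomy_matches_scipy_oracle():
    obs = (37, 52, 19)
    chi2, p = polytomy_chi2(*obs)
    ref = stats.chisquare(obs)
    assert chi2 == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


# --------------------------------------------------------- site concordance


def _aln(columns: dict[str, str], n: int) -> dict[str, str]:
    return {k: v * n for k, v in columns.items()}


def test_scf_pure_concordant_columns():
    sp = parse_newick("((a,b),(c,d));")
    aln = _aln({"a": "A", "b": "A", "c": "C", "d": "C"}, 50)
    res = site_concordance(sp, [aln], n_quartets=10, seed=1)
    (sc,) = res.values()
    assert sc.scf == pytest.approx(100.0)
    assert sc.n_quartets_used == 10


def test_scf_equal_thirds():
    sp = parse_newick("((a,b),(c,d));")
    aln = {
        "a": "A" * 30 + "A" * 30 + "A" * 30,
        "b": "A" * 30 + "C" * 30 + "C" * 30,
        "c": "C" * 30 + "A" * 30 + "C" * 30,
        "d": "C" * 30 + "C" * 30 + "A" * 30,
    }
    res = site_concordance(sp, [aln], n_quartets=20, seed=2)
    (sc,) = res.values()
    assert sc.scf == pytest.approx(100 / 3, abs=1e-9)


def test_scf_gaps_and_ambiguity_disqualify():
    sp = parse_newick("((a,b),(c,d));")
    # one decisive concordant column; one column gapped; one ambiguous
    aln = {"a": "A-N", "b": "A-A", "c": "C-A", "d": "CCA"}
    res = site_concordance(sp, [aln], n_quartets=5, seed=3)
    (sc,) = res.values()
    assert sc.scf == pytest.approx(100.0)
    assert sc.mean_decisive_sites == pytest.approx(1.0)


def test_scf_no_decisive_sites_undefined():
    sp = parse_newick("((a,b),(c,d));")
    aln = _aln({"a": "A", "b": "A", "c": "A", "d": "A"}, 10)
    res = site_concordance(sp, [aln], n_quartets=5, seed=4)
    (sc,) = res.values()
    assert sc.scf is None
    assert sc.n_quartets_used == 0


def test_scf_reproducible_from_seed():
    rng = np.random.default_rng(8)
    sp = parse_newick("((((a,b),c),d),e);")
    bases = "ACGT"
    aln = {lab: "".join(rng.choice(list(bases), size=200)) for lab in "abcde"}
    r1 = site_concordance(sp, [aln], n_quartets=50, seed=77)
    r2 = site_concordance(sp, [aln], n_quartets=50, seed=77)
    assert {k: v.scf for k, v in r1.items()} == {k: v.scf for k, v in r2.items()}


# ----------------------------------------------------- merging / reporting


def test_with_site_concordance_and_dataframe():
    sp = parse_newick("((a,b),(c,d));")
    genes = [parse_newick("((a,b),(c,d));")] * 4
    recs = gene_concordance(sp, genes)
    scf = site_concordance(sp, [_aln({"a": "A", "b": "A", "c": "C", "d": "C"}, 20)],
                           n_quartets=5, seed=1)
    merged = with_site_concordance(recs, scf)
    df = records_to_dataframe(merged)
    assert list(df.columns) == [
        "branch_id", "n_decisive", "n_concordant", "n_alt1", "n_alt2",
        "n_paraphyletic", "gCF", "gDF1", "gDF2", "gDFP", "sCF",
        "n_quartets_used", "clade",
    ]
    assert df.loc[0, "gCF"] == 100.0
    assert df.loc[0, "sCF"] == pytest.approx(100.0)


def test_annotate_species_tree_labels():
    sp = parse_newick("((((a,b),c),d),e);")
    genes = [parse_newick("((((a,b),c),d),e);")] * 2
    recs = gene_concordance(sp, genes)
    out = annotate_species_tree(sp, recs).to_newick()
    assert "100" in out
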