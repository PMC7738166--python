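import math

import numpy as np
import pytest
from scipy import stats

from deltacf.concordance import GeneTreeClass, classify_gene_tree, gene_concordance
from deltacf.msc import (
    IntrogressionPulse,
    SimConfig,
    SimConfigError,
    expected_concordance,
    sim_config_from_yaml,
    simulate_alignment,
    simulate_gene_trees,
)
from deltacf.trees import branch_contexts, parse_newick

# 4-taxon species tree whose AB branch has length T; upper branches are long
# enough (8 units) that the closed form 1-(2/3)exp(-T) applies to the AB
# branch with error ~exp(-8).
def _species_tree(T: float):
    return parse_newick(
        f"(((A:1,B:1)AB:{T},C:{1+T})ABC:8,D:{9+T});"
    )


# ------------------------------------------------------------- closed form


def test_expected_concordance_values():
    assert expected_concordance(0.0) == pytest.approx(1 / 3)
    # exact value 1-(2/3)exp(-0.005) = 0.3366583...; quoted to ~1e-5
    assert expected_concordance(0.005) == pytest.approx(
        1 - (2 / 3) * math.exp(-0.005)
    )
    assert expected_concordance(0.005) == pytest.approx(0.336663, abs=1e-5)
    assert expected_concordance(50.0) == pytest.approx(1.0)


def test_expected_concordance_monotone():
    ts = np.linspace(0, 5, 50)
    vals = [expected_concordance(t) for t in ts]
    assert all(b > a for a, b in zip(vals, vals[1:]))


# ------------------------------------------------------------- simulation


def test_simulated_trees_are_binary_with_positive_lengths():
    cfg = SimConfig(species_tree=_species_tree(0.5), n_loci=50, seed=3)
    trees, truth = simulate_gene_trees(cfg)
    assert len(trees) == 50
    assert len(truth.records) == 50
    for t in trees:
        assert t.leaves == {"A", "B", "C", "D"}
        assert t.is_binary_rooted()
        for edge in t.dendropy_tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


def test_same_seed_bit_identical():
    cfg = SimConfig(species_tree=_species_tree(0.3), n_loci=30, seed=11)
    t1, _ = simulate_gene_trees(cfg)
    t2, _ = simulate_gene_trees(cfg)
    assert [t.to_newick() for t in t1] == [t.to_newick() for t in t2]


def test_locus_streams_independent_of_n_loci():
    base = dict(species_tree=_species_tree(0.3), seed=21)
    t10, _ = simulate_gene_trees(SimConfig(n_loci=10, **base))
    t4, _ = simulate_gene_trees(SimConfig(n_loci=4, **base))
    assert [t.to_newick() for t in t4] == [t.to_newick() for t in t10[:4]]


def test_gamma_zero_pulse_identical_to_no_pulse():
    sp = _species_tree(0.5)
    pulse = IntrogressionPulse(donor="C", recipient="A", time=0.5, gamma=0.0)
    t_no, _ = simulate_gene_trees(SimConfig(species_tree=sp, n_loci=40, seed=9))
    t_p, _ = simulate_gene_trees(
        SimConfig(species_tree=sp, pulses=(pulse,), n_loci=40, seed=9)
    )
    assert [t.to_newick() for t in t_no] == [t.to_newick() for t in t_p]


def test_gamma_one_pulse_forces_reroute():
    # gamma=1 pulse from C into A at the base of A's tip branch: every A
    # lineage moves to C's population and coalesces with C before the AB
    # ancestor with probability 1-exp(-available time).
    sp = _species_tree(1.0)
    pulse = IntrogressionPulse(donor="C", recipient="A", time=0.01, gamma=1.0)
    cfg = SimConfig(species_tree=sp, pulses=(pulse,), n_loci=300, seed=13)
    trees, truth = simulate_gene_trees(cfg)
    (ctx,) = branch_contexts(sp)
    classes = [classify_gene_tree(t, ctx) for t in trees]
    n_alt1 = sum(c == GeneTreeClass.ALT1 for c in classes)
    n_alt2 = sum(c == GeneTreeClass.ALT2 for c in classes)
    assert all(r.pulse_rerouted[0] == 1 for r in truth.records)
    # AC pairing strongly inflated relative to AD|BC
    assert n_alt1 > 10 * max(n_alt2, 1)


def test_truth_log_matches_classifier():
    sp = _species_tree(0.2)
    cfg = SimConfig(species_tree=sp, n_loci=40, seed=5)
    trees, truth = simulate_gene_trees(cfg)
    (ctx,) = branch_contexts(sp)
    for tree, rec in zip(trees, truth.records):
        expected = classify_gene_tree(tree, ctx)
        assert rec.branch_classes[ctx.branch_id] == expected.name


def test_missing_taxa_dropped_per_locus():
    cfg = SimConfig(
        species_tree=_species_tree(0.2), n_loci=200, missing_prob=0.3, seed=17
    )
    trees, _ = simulate_gene_trees(cfg)
    sizes = {t.n_leaves for t in trees}
    assert min(sizes) >= 3
    assert any(t.n_leaves < 4 for t in trees)
    assert any(t.n_leaves == 4 for t in trees)


def test_alt_classes_statistically_equal_under_null(rng):
    sp = _species_tree(0.2)
    (ctx,) = branch_contexts(sp)
    ok = 0
    n_sets = 20
    for i in range(n_sets):
        cfg = SimConfig(species_tree=sp, n_loci=300, seed=1000 + i)
        trees, _ = simulate_gene_trees(cfg)
        recs = gene_concordance(sp, trees)
        rec = next(r for r in recs if r.branch_id == ctx.branch_id)
        n_disc = rec.n_alt1 + rec.n_alt2
        p = stats.binomtest(rec.n_alt1, n_disc, 0.5).pvalue if n_disc else 1.0
        ok += p > 0.001
    assert ok >= n_sets - 1


def test_config_validation():
    with pytest.raises(SimConfigError):
        SimConfig(species_tree=_species_tree(0.5), n_loci=0)
    with pytest.raises(SimConfigError):
        SimConfig(species_tree=_species_tree(0.5), missing_prob=1.5)
    with pytest.raises(SimConfigError):
        IntrogressionPulse(donor="A", recipient="A", time=0.1, gamma=0.5)
    with pytest.raises(SimConfigError):
        IntrogressionPulse(donor="A", recipient="B", time=0.1, gamma=1.5)


# --------------------------------------------------------- msprime oracle


def test_concordance_matches_msprime_oracle():
    msprime = pytest.importorskip("msprime")
    T = 0.5
    n = 3000
    # this package's simulator
    sp = _species_tree(T)
    cfg = SimConfig(species_tree=sp, n_loci=n, seed=99)
    trees, _ = simulate_gene_trees(cfg)
    (ctx,) = branch_contexts(sp)
    ours = np.mean(
        [classify_gene_tree(t, ctx) == GeneTreeClass.CONCORDANT for t in trees]
    )
    # independent oracle: same demography in msprime (ploidy 1 with
    # population size 1 makes one generation = one coalescent unit)
    dem = msprime.Demography()
    for name in ["A", "B", "C", "D", "AB", "ABC", "R"]:
        dem.add_population(name=name, initial_size=1.0)
    dem.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=1.0 + T, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(time=9.0 + T, derived=["ABC", "D"], ancestral="R")
    reps = msprime.sim_ancestry(
        samples={"A": 1, "B": 1, "C": 1, "D": 1},
        demography=dem,
        ploidy=1,
        num_replicates=n,
        random_seed=1234,
    )
    conc = 0
    for ts in reps:
        t = ts.first()
        mrca_ab = t.mrca(0, 1)
        mrca_cd = t.mrca(2, 3)
        if set(t.leaves(mrca_ab)) == {0, 1} or set(t.leaves(mrca_cd)) == {2, 3}:
            conc += 1
    theirs = conc / n
    p_hat = (ours * n + conc) / (2 * n)
    se = math.sqrt(p_hat * (1 - p_hat) * (2 / n))
    assert abs(ours - theirs) <= 4 * se
    # and both near the closed form
    assert abs(ours - expected_concordance(T)) <= 4 * math.sqrt(
        expected_concordance(T) * (1 - expected_concordance(T)) / n
    )


# ------------------------------------------------------------------ JC69


def test_jc69_two_leaf_closed_form():
    t = parse_newick("(x:1,y:1);")
    length = 10_000
    scale = 0.1  # total path 0.2 substitutions/site
    aln = simulate_alignment(t, length, scale, seed=6)
    diff = sum(a != b for a, b in zip(aln["x"], aln["y"])) / length
    p_exp = 0.75 * (1 - math.exp(-4 * 0.2 / 3))
    se = math.sqrt(p_exp * (1 - p_exp) / length)
    assert abs(diff - p_exp) <= 3 * se


def test_jc69_scale_zero_identical():
    t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    aln = simulate_alignment(t, 200, 0.0, seed=1)
    assert len(set(aln.values())) == 1


def test_jc69_same_seed_identical():
    t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    assert simulate_alignment(t, 300, 0.05, seed=4) == simulate_alignment(
        t, 300, 0.05, seed=4
    )


def test_jc69_requires_branch_lengths():
    t = parse_newick("((a,b),(c,d));")
    with pytest.raises(ValueError):
        simulate_alignment(t, 100, 0.05, seed=1)


# ------------------------------------------------------------------ config


def test_sim_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        'species_tree: "(((A:1,B:1):0.5,C:1.5):8,D:9.5);"\n'
        "pulses:\n"
        "  - {donor: C, recipient: A, time: 0.5, gamma: 0.2}\n"
        "n_loci: 12\n"
        "seed: 3\n"
    )
    cfg = sim_config_from_yaml(p)
    assert cfg.n_loci == 12
    assert cfg.pulses[0].gamma == 0.2
    trees, _ = simulate_gene_trees(cfg)
    assert len(trees) == 12
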