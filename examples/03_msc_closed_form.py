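"""Verify the MSC simulator against the coalescent closed form.

For an internal branch of length T (coalescent units), the probability that
a gene tree is concordant is 1 - (2/3) exp(-T).  We sweep T, simulate
5,000 loci per point, and compare observed concordant fractions with the
formula.

Run:  python examples/03_msc_closed_form.py
"""

from deltacf import (
    GeneTreeClass,
    SimConfig,
    branch_contexts,
    classify_gene_tree,
    expected_concordance,
    parse_newick,
    simulate_gene_trees,
)


def main() -> None:
    n = 5000
    print(f"{'T':>6}  {'observed':>9}  {'expected':>9}")
    for i, T in enumerate([0.05, 0.2, 0.5, 1.0, 2.0]):
        species = parse_newick(f"(((A:1,B:1):{T},C:{1 + T}):8,D:{9 + T});")
        trees, _ = simulate_gene_trees(
            SimConfig(species_tree=species, n_loci=n, seed=100 + i)
        )
        ctx = next(c for c in branch_contexts(species)
                   if (c.a | c.b) == {"A", "B"})
        obs = sum(
            classify_gene_tree(t, ctx) == GeneTreeClass.CONCORDANT
            for t in trees
        ) / n
        print(f"{T:>6}  {obs:>9.4f}  {expected_concordance(T):>9.4f}")


if __name__ == "__main__":
    main()
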