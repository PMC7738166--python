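"""Gene and site concordance factors, gene-tree classification, polytomy test.

For every internal branch of a species tree, each gene tree is classified
against the branch's four-group context (A, B = child clades; C = sister;
D = the rest):

* ``CONCORDANT`` -- some gene-tree split places all sampled members of A∪B on
  one side and all sampled members of C∪D on the other;
* ``ALT1`` / ``ALT2`` -- the split instead matches the (A∪C)|(B∪D) or
  (A∪D)|(B∪C) nearest-neighbour rearrangement;
* ``PARAPHYLETIC`` -- the gene tree is decisive but displays none of the three
  arrangements;
* ``NOT_DECISIVE`` -- at least one of the four groups has no sampled member.

The gene concordance factor gCF is the percentage of decisive gene trees that
are concordant; gDF1/gDF2/gDFP are the analogous percentages for the two
alternative arrangements and for paraphyly.  The site concordance factor sCF
is the mean, over randomly sampled quartets (one taxon per group), of the
fraction of decisive alignment sites supporting the concordant pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import BranchContext, Tree, TreeValidationError, branch_contexts

__all__ = [
    "GeneTreeClass",
    "ConcordanceRecord",
    "SiteConcordance",
    "classify_gene_tree",
    "gene_concordance",
    "site_concordance",
    "with_site_concordance",
    "polytomy_chi2",
    "records_to_dataframe",
    "annotate_species_tree",
]

logger = logging.getLogger(__name__)


class GeneTreeClass(IntEnum):
    CONCORDANT = 0
    ALT1 = 1
    ALT2 = 2
    PARAPHYLETIC = 3
    NOT_DECISIVE = 4


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-branch gene-tree (and optionally site) concordance summary.

    Percentages are ``None`` (undefined) when no gene tree is decisive for the
    branch; otherwise ``gcf + gdf1 + gdf2 + gdfp == 100``.
    """

    branch_id: str
    clade: tuple[str, ...]
    n_concordant: int
    n_alt1: int
    n_alt2: int
    n_paraphyletic: int
    n_decisive: int
    gcf: float | None
    gdf1: float | None
    gdf2: float | None
    gdfp: float | None
    scf: float | None = None
    n_quartets_used: int | None = None
    mean_decisive_sites: float | None = None

    @property
    def n_discordant(self) -> int:
        return self.n_decisive - self.n_concordant


@dataclass(frozen=True)
class SiteConcordance:
    """Per-branch site concordance factor from sampled quartets."""

    branch_id: str
    scf: float | None
    n_quartets_used: int
    mean_decisive_sites: float | None


def _separates(side: frozenset, comp: frozenset, p: frozenset, q: frozenset) -> bool:
    return (p <= side and q <= comp) or (q <= side and p <= comp)


def _classify_clades(
    clades: Sequence[frozenset],
    leaves: frozenset,
    context: BranchContext,
) -> GeneTreeClass:
    a = context.a & leaves
    b = context.b & leaves
    c = context.c & leaves
    d = context.d & leaves
    if not (a and b and c and d):
        return GeneTreeClass.NOT_DECISIVE
    ab, cd = a | b, c | d
    ac, bd = a | c, b | d
    ad, bc = a | d, b | c
    # Splits of a single tree are pairwise compatible, so at most one of the
    # three arrangements can be displayed; check order is immaterial.
    for side in clades:
        comp = leaves - side
        if _separates(side, comp, ab, cd):
            return GeneTreeClass.CONCORDANT
        if _separates(side, comp, ac, bd):
            return GeneTreeClass.ALT1
        if _separates(side, comp, ad, bc):
            return GeneTreeClass.ALT2
    return GeneTreeClass.PARAPHYLETIC


def classify_gene_tree(gene_tree: Tree, context: BranchContext) -> GeneTreeClass:
    """Classify one gene tree against one species-tree branch context.

    Gene trees with missing taxa are allowed; a tree lacking all members of
    any one group (including any tree with fewer than 4 leaves) is
    ``NOT_DECISIVE``.
    """
    leaves = gene_tree.leaves
    extra = leaves - context.universe
    if extra:
        raise TreeValidationError(
            "gene tree labels outside the species taxon universe: "
            + ", ".join(sorted(extra))
        )
    return _classify_clades(gene_tree.clade_sets(), leaves, context)


def classify_many(
    gene_trees: Sequence[Tree], context: BranchContext
) -> np.ndarray:
    """Vector of :class:`GeneTreeClass` codes, one per gene tree."""
    return np.array(
        [int(classify_gene_tree(gt, context)) for gt in gene_trees], dtype=np.int8
    )


def _percentages(counts: tuple[int, int, int, int], n_decisive: int):
    if n_decisive == 0:
        return (None, None, None, None)
    return tuple(100.0 * k / n_decisive for k in counts)


def gene_concordance(
    species_tree: Tree,
    gene_trees: Sequence[Tree],
    contexts: Sequence[BranchContext] | None = None,
) -> list[ConcordanceRecord]:
    """Gene concordance factors for every internal branch of the species tree.

    Deterministic and invariant to the input order of ``gene_trees``.
    Branches with no decisive gene tree are reported with undefined
    percentages rather than raising.
    """
    if not gene_trees:
        raise ValueError("at least one gene tree is required")
    if contexts is None:
        contexts = branch_contexts(species_tree)
    universe = species_tree.leaves
    for i, gt in enumerate(gene_trees):
        extra = gt.leaves - universe
        if extra:
            raise TreeValidationError(
                f"gene tree {i}: labels outside the species taxon universe: "
                + ", ".join(sorted(extra))
            )
    prepared = [(gt.clade_sets(), gt.leaves) for gt in gene_trees]
    records = []
    for ctx in contexts:
        tallies = [0, 0, 0, 0, 0]
        for clades, leaves in prepared:
            tallies[int(_classify_clades(clades, leaves, ctx))] += 1
        n_conc, n_alt1, n_alt2, n_para = tallies[:4]
        n_dec = n_conc + n_alt1 + n_alt2 + n_para
        gcf, gdf1, gdf2, gdfp = _percentages(
            (n_conc, n_alt1, n_alt2, n_para), n_dec
        )
        records.append(
            ConcordanceRecord(
                branch_id=ctx.branch_id,
                clade=ctx.clade,
                n_concordant=n_conc,
                n_alt1=n_alt1,
                n_alt2=n_alt2,
                n_paraphyletic=n_para,
                n_decisive=n_dec,
                gcf=gcf,
                gdf1=gdf1,
                gdf2=gdf2,
                gdfp=gdfp,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Site concordance
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_concordance(
    species_tree: Tree,
    alignments: Sequence[Mapping[str, str]],
    n_quartets: int = 300,
    seed: int | None = None,
    contexts: Sequence[BranchContext] | None = None,
) -> dict[str, SiteConcordance]:
    """Site concordance factors from randomly sampled quartets.

    For each branch, ``n_quartets`` quartets are drawn (one taxon uniformly
    from each of the four groups, with replacement).  A site is decisive for a
    quartet when all four taxa carry unambiguous A/C/G/T bases and the column
    supports exactly one of the three quartet pairings (patterns xxyy, xyxy,
    xyyx).  The per-quartet support fraction is the share of decisive sites
    supporting the concordant pairing; sCF is the unweighted mean over
    quartets with at least one decisive site, as a percentage.  Gaps and
    ambiguity codes disqualify a site for that quartet only.
    """
    if n_quartets < 1:
        raise ValueError("n_quartets must be >= 1")
    if contexts is None:
        contexts = branch_contexts(species_tree)
    encoded: list[dict[str, np.ndarray]] = []
    for aln in alignments:
        lens = {len(s) for s in aln.values()}
        if len(lens) > 1:
            raise ValueError("sequences within one alignment must share a length")
        encoded.append({lab: _encode(s) for lab, s in aln.items()})

    master = np.random.SeedSequence(seed)
    results: dict[str, SiteConcordance] = {}
    for ctx, child in zip(contexts, master.spawn(len(contexts))):
        rng = np.random.default_rng(child)
        groups = [sorted(ctx.a), sorted(ctx.b), sorted(ctx.c), sorted(ctx.d)]
        fracs = []
        decisive_counts = []
        for _ in range(n_quartets):
            qa, qb, qc, qd = (g[rng.integers(len(g))] for g in groups)
            n_conc = n_alt1 = n_alt2 = 0
            for aln in encoded:
                if not all(t in aln for t in (qa, qb, qc, qd)):
                    continue
                sa, sb, sc, sd = aln[qa], aln[qb], aln[qc], aln[qd]
                ok = (sa != 255) & (sb != 255) & (sc != 255) & (sd != 255)
                n_conc += int(np.count_nonzero((sa == sb) & (sc == sd) & (sa != sc) & ok))
                n_alt1 += int(np.count_nonzero((sa == sc) & (sb == sd) & (sa != sb) & ok))
                n_alt2 += int(np.count_nonzero((sa == sd) & (sb == sc) & (sa != sb) & ok))
            total = n_conc + n_alt1 + n_alt2
            if total > 0:
                fracs.append(n_conc / total)
                decisive_counts.append(total)
        if fracs:
            results[ctx.branch_id] = SiteConcordance(
                branch_id=ctx.branch_id,
                scf=100.0 * float(np.mean(fracs)),
                n_quartets_used=len(fracs),
                mean_decisive_sites=float(np.mean(decisive_counts)),
            )
        else:
            results[ctx.branch_id] = SiteConcordance(
                branch_id=ctx.branch_id, scf=None, n_quartets_used=0,
                mean_decisive_sites=None,
            )
    return results


def with_site_concordance(
    records: Iterable[ConcordanceRecord],
    scf_results: Mapping[str, SiteConcordance],
) -> list[ConcordanceRecord]:
    """Merge sCF results into gene-concordance records (by branch id)."""
    out = []
    for rec in records:
        sc = scf_results.get(rec.branch_id)
        if sc is None:
            out.append(rec)
        else:
            out.append(
                replace(
                    rec,
                    scf=sc.scf,
                    n_quartets_used=sc.n_quartets_used,
                    mean_decisive_sites=sc.mean_decisive_sites,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Polytomy test and output helpers
# ---------------------------------------------------------------------------

def polytomy_chi2(n1: int, n2: int, n3: int) -> tuple[float, float]:
    """Chi-square goodness-of-fit of three topology counts against equal thirds.

    2 degrees of freedom; failing to reject is consistent with a hard
    polytomy at the branch.  Operates on whole-tree topology counts, which
    approximates (but is not identical to) quartet-frequency formulations of
    the same test.
    """
    counts = [n1, n2, n3]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("at least one count must be positive")
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


def records_to_dataframe(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "branch_id": r.branch_id,
                "n_decisive": r.n_decisive,
                "n_concordant": r.n_concordant,
                "n_alt1": r.n_alt1,
                "n_alt2": r.n_alt2,
                "n_paraphyletic": r.n_paraphyletic,
                "gCF": r.gcf,
                "gDF1": r.gdf1,
                "gDF2": r.gdf2,
                "gDFP": r.gdfp,
                "sCF": r.scf,
                "n_quartets_used": r.n_quartets_used,
                "clade": ",".join(r.clade),
            }
        )
    return pd.DataFrame(rows)


def annotate_species_tree(
    species_tree: Tree, records: Sequence[ConcordanceRecord]
) -> Tree:
    """Copy of the species tree with internal labels set to ``gCF/sCF``."""
    by_id = {r.branch_id: r for r in records}
    annotated = species_tree.copy()
    ctxs = {c.branch_id for c in branch_contexts(annotated)}
    universe = annotated.leaves
    below = annotated.leaf_sets_below()
    from .trees import _branch_id_for  # shared id derivation

    for node in annotated.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = below[node]
        rest = universe - side
        if len(side) < 2 or len(rest) < 2:
            continue
        canon = min(side, rest, key=lambda s: (len(s), sorted(s)))
        bid = _branch_id_for(sorted(canon))
        rec = by_id.get(bid)
        if rec is None or bid not in ctxs:
            continue
        gcf = "NA" if rec.gcf is None else f"{rec.gcf:.1f}"
        if rec.scf is None:
            node.label = gcf
        else:
            node.label = f"{gcf}/{rec.scf:.1f}"
    return annotated
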