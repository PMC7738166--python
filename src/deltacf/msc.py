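"""Multispecies-coalescent gene-tree simulator with introgression pulses.

Gene trees are generated under the structured coalescent on a rooted binary
species tree whose branch lengths are in coalescent units (1 unit = 2N
generations under the diploid convention).  Within each species-tree branch,
k active lineages coalesce at rate k(k−1)/2 per unit; lineages that fail to
coalesce pass to the parent branch.  An introgression pulse (donor D,
recipient R, time t, admixture proportion γ) instantaneously reroutes each
lineage present in R at time t into D with probability γ, independently —
the discrete-event idealisation of a hybridisation episode.

Every locus draws its randomness from an independent substream of the master
seed, so per-locus results do not depend on the order loci are generated.
A per-locus truth log records the genealogy, which pulses actually rerouted
lineages, and the topology class of the gene tree at each species-tree
branch, enabling exact power/attribution checks downstream.

Also provided: the closed-form probability that a gene tree is concordant at
an internal branch of duration T (``1 − (2/3)e^{−T}``), and a Jukes–Cantor
sequence simulator for generating alignments along gene trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .concordance import GeneTreeClass, _classify_clades
from .trees import BranchContext, Tree, TreeValidationError, branch_contexts

__all__ = [
    "IntrogressionPulse",
    "SimConfig",
    "LocusTruth",
    "TruthLog",
    "simulate_gene_trees",
    "expected_concordance",
    "simulate_alignment",
    "sim_config_from_yaml",
]


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class IntrogressionPulse:
    """Instantaneous admixture: recipient lineages reroute to the donor.

    ``donor`` and ``recipient`` name populations: a leaf label, an internal
    node label, or a comma-joined list of leaf labels (resolved to their
    MRCA's branch).  ``time`` is in coalescent units before the present;
    ``gamma`` is the per-lineage rerouting probability.
    """

    donor: str
    recipient: str
    time: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise SimConfigError("gamma must be in [0, 1]")
        if self.time < 0:
            raise SimConfigError("pulse time must be >= 0")
        if self.donor == self.recipient:
            raise SimConfigError("pulse donor and recipient must differ")


@dataclass(frozen=True)
class SimConfig:
    """Parameters for one simulated gene-tree dataset."""

    species_tree: Tree
    pulses: tuple[IntrogressionPulse, ...] = ()
    n_loci: int = 100
    samples_per_species: int = 1
    missing_prob: float = 0.0
    seed: int | None = None
    locus_length: int | None = None
    subst_scale: float | None = None  # substitutions/site per coalescent unit

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise SimConfigError("n_loci must be >= 1")
        if self.samples_per_species < 1:
            raise SimConfigError("samples_per_species must be >= 1")
        if not (0.0 <= self.missing_prob < 1.0):
            raise SimConfigError("missing_prob must be in [0, 1)")
        if self.locus_length is not None and self.locus_length < 1:
            raise SimConfigError("locus_length must be >= 1")


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth for one simulated locus."""

    locus: int
    newick: str
    taxa: tuple[str, ...]
    branch_classes: Mapping[str, str]
    pulse_rerouted: tuple[int, ...]  # lineages rerouted, per configured pulse


@dataclass
class TruthLog:
    records: list[LocusTruth] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "locus": r.locus,
                "n_taxa": len(r.taxa),
                "newick": r.newick,
            }
            for i, k in enumerate(r.pulse_rerouted):
                row[f"pulse{i}_rerouted"] = k
            for bid, cls in r.branch_classes.items():
                row[f"class_{bid}"] = cls
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def expected_concordance(T: float) -> float:
    """Probability a gene tree is concordant at an internal branch of length T.

    Standard coalescent result: with two lineages entering a branch of T
    coalescent units, the concordant topology has probability 1 − (2/3)e^{−T};
    the two discordant resolutions share the remainder equally.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    return 1.0 - (2.0 / 3.0) * float(np.exp(-T))


# ---------------------------------------------------------------------------
# Species-tree preparation
# ---------------------------------------------------------------------------

class _Prepared:
    """Species tree indexed for simulation: node ages and population lookup."""

    def __init__(self, species_tree: Tree):
        self.tree = species_tree
        dt = species_tree.dendropy_tree
        if not species_tree.is_binary_rooted():
            raise SimConfigError("species tree must be rooted and binary")
        depth: dict = {}
        for node in dt.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                if node.edge.length is None:
                    raise SimConfigError(
                        "species tree must have branch lengths on all non-root edges"
                    )
                depth[node] = depth[node.parent_node] + node.edge.length
        maxdepth = max(depth[lf] for lf in dt.leaf_node_iter())
        self.age = {n: maxdepth - d for n, d in depth.items()}
        self.root = dt.seed_node
        self.label_to_node: dict[str, object] = {}
        below = species_tree.leaf_sets_below()
        self.below = below
        for node in dt.preorder_node_iter():
            if node.is_leaf():
                self.label_to_node[node.taxon.label] = node
            elif node.label:
                self.label_to_node[node.label] = node

    def resolve_population(self, label: str):
        if label in self.label_to_node:
            return self.label_to_node[label]
        if "," in label:
            taxa = frozenset(t.strip() for t in label.split(","))
            for node, leaves in self.below.items():
                if leaves == taxa:
                    return node
            mrca = self.tree.dendropy_tree.mrca(taxon_labels=sorted(taxa))
            if mrca is not None:
                return mrca
        raise SimConfigError(f"unknown population label: {label!r}")

    def parent_age(self, node) -> float:
        return float("inf") if node.parent_node is None else self.age[node.parent_node]

    def validate_pulse(self, pulse: IntrogressionPulse):
        donor = self.resolve_population(pulse.donor)
        recip = self.resolve_population(pulse.recipient)
        if donor is recip:
            raise SimConfigError("pulse donor and recipient must differ")
        for node, role in ((donor, "donor"), (recip, "recipient")):
            lo, hi = self.age[node], self.parent_age(node)
            if not (lo <= pulse.time < hi):
                raise SimConfigError(
                    f"pulse time {pulse.time} outside the {role} population's "
                    f"existence interval [{lo}, {hi})"
                )
        return donor, recip


# ---------------------------------------------------------------------------
# Per-locus structured coalescent
# ---------------------------------------------------------------------------

class _GNode:
    __slots__ = ("label", "children", "height")

    def __init__(self, label=None, children=(), height=0.0):
        self.label = label
        self.children = list(children)
        self.height = height

    def newick(self) -> str:
        def fmt(node, parent_height):
            blen = parent_height - node.height
            if node.children:
                inner = ",".join(fmt(ch, node.height) for ch in node.children)
                core = f"({inner})"
            else:
                core = node.label
            return f"{core}:{blen:.10g}" if parent_height is not None else core

        if not self.children:
            return f"{self.label};"
        inner = ",".join(fmt(ch, self.height) for ch in self.children)
        return f"({inner});"


def _simulate_locus(
    prep: _Prepared,
    pulses: Sequence[tuple[IntrogressionPulse, object, object]],
    taxa: Sequence[str],
    samples_per_species: int,
    rng: np.random.Generator,
) -> tuple[_GNode, list[int]]:
    # events: (time, priority, kind, payload); merges/activations before pulses
    events: list[tuple[float, int, str, object]] = []
    dt = prep.tree.dendropy_tree
    taxa_set = set(taxa)
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            if node.taxon.label in taxa_set:
                events.append((prep.age[node], 0, "activate", node))
        else:
            events.append((prep.age[node], 0, "merge", node))
    for i, (pulse, donor, recip) in enumerate(pulses):
        if pulse.gamma > 0.0:  # γ=0 pulses are no-ops; omitting them keeps the
            # random stream identical to a pulse-free run
            events.append((pulse.time, 1, "pulse", (i, pulse, donor, recip)))
    events.sort(key=lambda e: (e[0], e[1]))

    active: dict = {}
    rerouted = [0] * len(pulses)
    t = 0.0
    n_total = 0
    ev_i = 0

    def total_rate():
        return sum(
            k * (k - 1) / 2.0 for k in (len(v) for v in active.values()) if k >= 2
        )

    while True:
        rate = total_rate()
        next_ev_t = events[ev_i][0] if ev_i < len(events) else float("inf")
        wait = rng.exponential(1.0 / rate) if rate > 0 else float("inf")
        if t + wait < next_ev_t:
            t = t + wait
            # pick population proportional to its pair count
            pops = [(n, lin) for n, lin in active.items() if len(lin) >= 2]
            weights = np.array([len(l) * (len(l) - 1) / 2.0 for _, l in pops])
            pop_i = rng.choice(len(pops), p=weights / weights.sum())
            lineages = pops[pop_i][1]
            i, j = rng.choice(len(lineages), size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            right = lineages.pop(j)
            left = lineages.pop(i)
            lineages.append(_GNode(children=(left, right), height=t))
            n_total -= 1
            if n_total == 1 and ev_i >= len(events):
                (last,) = [l for lin in active.values() for l in lin]
                return last, rerouted
        else:
            if ev_i >= len(events):
                # single lineage left and no events: finished above
                (last,) = [l for lin in active.values() for l in lin]
                return last, rerouted
            t = next_ev_t
            _, _, kind, payload = events[ev_i]
            ev_i += 1
            if kind == "activate":
                node = payload
                lab = node.taxon.label
                labels = (
                    [lab]
                    if samples_per_species == 1
                    else [f"{lab}_{k + 1}" for k in range(samples_per_species)]
                )
                active.setdefault(node, []).extend(
                    _GNode(label=l, height=t) for l in labels
                )
                n_total += len(labels)
            elif kind == "merge":
                node = payload
                pool = []
                for ch in node.child_nodes():
                    pool.extend(active.pop(ch, []))
                if pool:
                    active.setdefault(node, []).extend(pool)
            elif kind == "pulse":
                idx, pulse, donor, recip = payload
                if pulse.gamma <= 0.0:
                    continue
                src = active.get(recip, [])
                movers = [l for l in src if rng.random() < pulse.gamma]
                if movers:
                    active[recip] = [l for l in src if l not in movers]
                    active.setdefault(donor, []).extend(movers)
                    rerouted[idx] = len(movers)
        if n_total == 1 and ev_i >= len(events):
            (last,) = [l for lin in active.values() for l in lin]
            return last, rerouted


def simulate_gene_trees(config: SimConfig) -> tuple[list[Tree], TruthLog]:
    """Simulate ``config.n_loci`` gene trees under the MSC with optional pulses.

    Returns the gene trees (binary, with coalescent-time branch lengths) and a
    :class:`TruthLog` with one entry per locus.  Reproducible from
    ``config.seed``; per-locus substreams make results independent of
    generation order.
    """
    prep = _Prepared(config.species_tree)
    resolved = [
        (p, *prep.validate_pulse(p)) for p in config.pulses
    ]
    all_taxa = sorted(config.species_tree.leaves)
    try:
        contexts = branch_contexts(config.species_tree)
    except TreeValidationError:
        contexts = []

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_loci)
    trees: list[Tree] = []
    log = TruthLog()
    for locus, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        taxa = all_taxa
        if config.missing_prob > 0.0:
            while True:
                mask = rng.random(len(all_taxa)) >= config.missing_prob
                if mask.sum() >= min(3, len(all_taxa)):
                    break
            taxa = [t for t, keep in zip(all_taxa, mask) if keep]
        root, rerouted = _simulate_locus(
            prep, resolved, taxa, config.samples_per_species, rng
        )
        tree = Tree.from_newick(root.newick())
        classes = {
            ctx.branch_id: GeneTreeClass(
                _classify_clades(tree.clade_sets(), tree.leaves, ctx)
            ).name
            for ctx in contexts
        }
        log.records.append(
            LocusTruth(
                locus=locus,
                newick=tree.to_newick(),
                taxa=tuple(taxa),
                branch_classes=classes,
                pulse_rerouted=tuple(rerouted),
            )
        )
        trees.append(tree)
    return trees, log


# ---------------------------------------------------------------------------
# Jukes-Cantor sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_alignment(
    gene_tree: Tree,
    length: int,
    scale: float,
    seed: int | None = None,
) -> dict[str, str]:
    """Evolve a Jukes–Cantor alignment along a gene tree.

    ``scale`` converts the tree's branch-length units into substitutions per
    site (expected substitutions on an edge = edge length × scale).  The root
    state is uniform over A/C/G/T and sites are independent.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = np.random.default_rng(seed)
    dt = gene_tree.dendropy_tree
    states: dict = {dt.seed_node: rng.integers(0, 4, size=length, dtype=np.uint8)}
    out: dict[str, str] = {}
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            pass
        else:
            if node.edge.length is None:
                raise ValueError("gene tree must have branch lengths everywhere")
            tsub = node.edge.length * scale
            p_change = 0.75 * (1.0 - np.exp(-4.0 * tsub / 3.0))
            parent_state = states[node.parent_node]
            state = parent_state.copy()
            hit = rng.random(length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # a changed site moves to one of the three other bases uniformly
                state[hit] = (state[hit] + rng.integers(1, 4, size=n_hit,
                                                        dtype=np.uint8)) % 4
            states[node] = state
        if node.is_leaf():
            out[node.taxon.label] = _BASES[states[node]].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Config file loading
# ---------------------------------------------------------------------------

def sim_config_from_yaml(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file.

    Schema::

        species_tree: "((A:1,B:1)ab:1,C:2)root;"   # or {file: path/to.nwk}
        pulses:
          - {donor: C, recipient: A, time: 0.5, gamma: 0.2}
        n_loci: 1000
        samples_per_species: 1
        missing_prob: 0.0
        seed: 42
        sequences: {length: 1000, scale: 0.05}      # optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    st = doc["species_tree"]
    if isinstance(st, dict):
        with open(st["file"]) as fh:
            st = fh.read()
    tree = Tree.from_newick(st)
    pulses = tuple(
        IntrogressionPulse(
            donor=str(p["donor"]),
            recipient=str(p["recipient"]),
            time=float(p["time"]),
            gamma=float(p["gamma"]),
        )
        for p in doc.get("pulses", []) or []
    )
    seq = doc.get("sequences") or {}
    return SimConfig(
        species_tree=tree,
        pulses=pulses,
        n_loci=int(doc.get("n_loci", 100)),
        samples_per_species=int(doc.get("samples_per_species", 1)),
        missing_prob=float(doc.get("missing_prob", 0.0)),
        seed=doc.get("seed"),
        locus_length=int(seq["length"]) if "length" in seq else None,
        subst_scale=float(seq["scale"]) if "scale" in seq else None,
    )
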