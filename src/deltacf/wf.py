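"""Forward Wright–Fisher check that purifying selection does not bias topologies.

A haploid WF model with multiplicative fitness ``(1+s)^k`` (k = deleterious
mutations carried at a non-recombining locus) is run forward on the
three-population history ((p2,p3),p1): an ancestral population evolves to
mutation–selection balance, splits into p1 and the (p2,p3) ancestor, which
splits again after a short internal interval; the three tip populations then
evolve independently.  One chromosome is sampled per population per locus
and its recorded ancestry is traced backward; the first pair of sample
lineages to share an ancestor fixes the rooted triplet topology.

Because the claim under test is about genealogy *distributions*, loci are
independent (free recombination) and each locus is its own single-locus WF
process with selection acting on that locus alone.  The ancestral tracing is
exact: founder labels carry each lineage through the tip phases, and stored
parent arrays (pedigrees) cover the internal branch and a finite traced
window of the root population.  Loci whose three lineages fail to coalesce
inside the traced root window are counted as unresolved and excluded from
topology counts (the window default of 3N generations leaves ~e^{-9} of loci
unresolved).

Under neutrality the triplet topology frequencies converge to the
multispecies-coalescent closed form with internal-branch length T = (internal
generations)/N in haploid coalescent units (set ``diploid_units=True`` when
mirroring diploid simulators, which halves T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WFConfig",
    "TopologyCounts",
    "simulate_wf_genealogies",
    "topology_bias_test",
    "pool_counts",
]


class ExtinctionError(RuntimeError):
    """Mean fitness underflowed; the population is effectively extinct."""


@dataclass(frozen=True)
class WFConfig:
    """Wright–Fisher simulation parameters.

    Defaults mirror the replication target: selection coefficient scaled as
    Ns = −7.5, per-locus deleterious mutation rate 3e−7 per generation, an
    internal branch of 0.01·N generations, tip branches of 8·N generations,
    and a p3 population 0.04 times the size of p1/p2, with 50 loci per
    replicate and 100 replicates.
    """

    n_pop: int = 500
    p3_size_ratio: float = 0.04
    internal_gens: int | None = None  # default 0.01 * N
    tip_gens: int | None = None  # default 8 * N
    mutation_rate: float = 3e-7  # U, per locus per generation
    ns: float = -7.5  # population-scaled selection coefficient N·s
    n_loci: int = 50
    n_replicates: int = 100
    root_trace_gens: int | None = None  # default 3 * N
    burnin_gens: int | None = None  # default max(200, 4/|s|) when s,U > 0
    diploid_units: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pop < 10:
            raise ValueError("n_pop must be >= 10")
        if self.n_pop > 32000:
            raise ValueError("n_pop must be <= 32000 (pedigrees are int16)")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if not np.isfinite(self.ns):
            raise ValueError("Ns must be finite")
        if self.n_loci < 1 or self.n_replicates < 1:
            raise ValueError("n_loci and n_replicates must be >= 1")
        for name in ("internal_gens", "tip_gens", "root_trace_gens"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1 generation")

    @property
    def s(self) -> float:
        return self.ns / self.n_pop

    @property
    def internal(self) -> int:
        v = self.internal_gens
        return int(v) if v is not None else max(1, round(0.01 * self.n_pop))

    @property
    def tips(self) -> int:
        v = self.tip_gens
        return int(v) if v is not None else 8 * self.n_pop

    @property
    def root_window(self) -> int:
        v = self.root_trace_gens
        return int(v) if v is not None else 3 * self.n_pop

    @property
    def burnin(self) -> int:
        if self.burnin_gens is not None:
            return int(self.burnin_gens)
        if self.s == 0.0 or self.mutation_rate == 0.0:
            return 0
        return max(200, int(4.0 / abs(self.s)))

    @property
    def p3_size(self) -> int:
        return max(2, round(self.p3_size_ratio * self.n_pop))

    @property
    def internal_T(self) -> float:
        """Internal branch length in coalescent units for the closed form."""
        ploidy = 2.0 if self.diploid_units else 1.0
        return self.internal / (ploidy * self.n_pop)


@dataclass(frozen=True)
class TopologyCounts:
    """Rooted-triplet topology counts for one replicate."""

    n_concordant: int  # (p2,p3) coalesce first -- the species-tree triplet
    n_p1p2: int
    n_p1p3: int
    n_unresolved: int = 0

    @property
    def n_resolved(self) -> int:
        return self.n_concordant + self.n_p1p2 + self.n_p1p3

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_concordant, self.n_p1p2, self.n_p1p3)


def pool_counts(counts: Iterable[TopologyCounts]) -> TopologyCounts:
    arr = np.array([(c.n_concordant, c.n_p1p2, c.n_p1p3, c.n_unresolved)
                    for c in counts], dtype=np.int64).sum(axis=0)
    return TopologyCounts(int(arr[0]), int(arr[1]), int(arr[2]), int(arr[3]))


# ---------------------------------------------------------------------------
# Core WF machinery (vectorised across loci; loci are rows)
# ---------------------------------------------------------------------------

def _weighted_rows(k_rows: np.ndarray, n_off: int, s: float,
                   rng: np.random.Generator, gen_label: str) -> np.ndarray:
    """Fitness-weighted parent choice for loci that carry mutations.

    Exact vectorised rejection sampling: propose uniform parents and accept
    with probability w/w_max per row.  With deleterious mutations nearly all
    weights equal the row maximum, so acceptance is essentially 1 and each
    round is a single gather-and-compare.
    """
    n_rows, n_par = k_rows.shape
    table = (1.0 + s) ** np.arange(int(k_rows.max()) + 1, dtype=np.float64)
    w = table[k_rows]
    totals = w.sum(axis=1)
    if not np.isfinite(totals).all() or (totals <= 0.0).any():
        raise ExtinctionError(f"mean fitness underflow at {gen_label}")
    w_norm = w / w.max(axis=1)[:, np.newaxis]
    row_offsets = np.arange(n_rows, dtype=np.int64) * n_par
    wn_flat = w_norm.reshape(-1)

    parents = rng.integers(0, n_par, size=(n_rows, n_off), dtype=np.int32)
    flat = parents.astype(np.int64) + row_offsets[:, np.newaxis]
    accept = rng.random((n_rows, n_off)) <= wn_flat[flat]
    parents_flat = parents.reshape(-1)
    pending = np.flatnonzero(~accept.reshape(-1))
    while pending.size:
        prop = rng.integers(0, n_par, size=pending.size, dtype=np.int32)
        src = (pending // n_off) * n_par + prop
        ok = rng.random(pending.size) <= wn_flat[src]
        parents_flat[pending[ok]] = prop[ok]
        pending = pending[~ok]
    return parents


def _wf_generation(
    k: np.ndarray,
    n_off: int,
    s: float,
    U: float,
    rng: np.random.Generator,
    gen_label: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """One WF generation: returns (parent indices, offspring mutation counts).

    Offspring pick parents with probability proportional to (1+s)^k and gain
    ``Poisson(U)`` new mutations each (drawn as a pooled scatter, which is an
    identical superposition).
    """
    L, n_par = k.shape
    row_any = k.any(axis=1)
    has_mut = bool(row_any.any())
    if has_mut:
        if s != 0.0:
            loaded = np.flatnonzero(row_any)
            parents = np.empty((L, n_off), dtype=np.int32)
            unloaded = np.flatnonzero(~row_any)
            if unloaded.size:
                parents[unloaded] = rng.integers(
                    0, n_par, size=(unloaded.size, n_off), dtype=np.int32
                )
            parents[loaded] = _weighted_rows(k[loaded], n_off, s, rng, gen_label)
        else:
            parents = rng.integers(0, n_par, size=(L, n_off), dtype=np.int32)
        flat = parents.astype(np.int64)
        flat += (np.arange(L, dtype=np.int64) * n_par)[:, np.newaxis]
        k_new = k.reshape(-1)[flat]
    else:
        parents = rng.integers(0, n_par, size=(L, n_off), dtype=np.int32)
        if n_off == n_par:
            k_new = k  # still all zeros; copied below only if mutations land
        else:
            k_new = np.zeros((L, n_off), dtype=k.dtype)
    if U > 0.0:
        m = rng.poisson(U * L * n_off)
        if m:
            if k_new is k:
                k_new = k.copy()
            li = rng.integers(0, L, size=m)
            ni = rng.integers(0, n_off, size=m)
            np.add.at(k_new, (li, ni), 1)
    return parents, k_new


def _gather_rows(arr: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Row-wise gather ``arr[i, parents[i, j]]`` via flat fancy indexing."""
    flat = parents.astype(np.int64)
    flat += (np.arange(arr.shape[0], dtype=np.int64) * arr.shape[1])[:, np.newaxis]
    return arr.reshape(-1)[flat]


def _counts_only_generation(k, s, U, rng, gen_label=""):
    """Burn-in fast path: parent identities are not recorded."""
    if k.any():
        _, k = _wf_generation(k, k.shape[1], s, U, rng, gen_label)
        return k
    if U > 0.0:
        m = rng.poisson(U * k.size)
        if m:
            li = rng.integers(0, k.shape[0], size=m)
            ni = rng.integers(0, k.shape[1], size=m)
            np.add.at(k, (li, ni), 1)
    return k


def _simulate_replicate(config: WFConfig, rng: np.random.Generator) -> TopologyCounts:
    L, N, M = config.n_loci, config.n_pop, config.p3_size
    s, U = config.s, config.mutation_rate
    rows = np.arange(L)

    # Ancestral population: burn-in to mutation-selection balance, then a
    # traced window whose pedigree supports backward coalescent tracing.
    k = np.zeros((L, N), dtype=np.int16)
    for g in range(config.burnin):
        k = _counts_only_generation(k, s, U, rng, f"burn-in gen {g}")
    R = config.root_window
    P_root = np.empty((R, L, N), dtype=np.int16)
    for g in range(R):
        parents, k = _wf_generation(k, N, s, U, rng, f"root gen {g}")
        P_root[g] = parents

    # Split 1: p1 and the (p2,p3) ancestor are founded from the root pool.
    F_p1, k_p1 = _wf_generation(k, N, s, U, rng, "p1 founding")
    F_anc, k_anc = _wf_generation(k, N, s, U, rng, "anc23 founding")

    # Internal branch: p1 evolves with founder labels; anc23 keeps a pedigree.
    lab_p1 = F_p1.astype(np.int32)  # ancestor index in the root final gen
    G_int = config.internal
    P_anc = np.empty((G_int, L, N), dtype=np.int16)
    for g in range(G_int):
        parents, k_p1 = _wf_generation(k_p1, N, s, U, rng, f"p1 internal gen {g}")
        lab_p1 = _gather_rows(lab_p1, parents)
        parents, k_anc = _wf_generation(k_anc, N, s, U, rng, f"anc23 gen {g}")
        P_anc[g] = parents

    # Split 2: p2 (size N) and p3 (size M) founded from anc23's final gen.
    F_p2, k_p2 = _wf_generation(k_anc, N, s, U, rng, "p2 founding")
    F_p3, k_p3 = _wf_generation(k_anc, M, s, U, rng, "p3 founding")

    # Tip phase: label propagation only.  p1 and p2 share a stacked buffer.
    k12 = np.concatenate([k_p1, k_p2], axis=0)
    lab12 = np.concatenate([lab_p1, F_p2.astype(np.int32)], axis=0)
    lab_p3 = F_p3.astype(np.int32)
    for g in range(config.tips):
        parents, k12 = _wf_generation(k12, N, s, U, rng, f"tips(p1,p2) gen {g}")
        lab12 = _gather_rows(lab12, parents)
        parents, k_p3 = _wf_generation(k_p3, M, s, U, rng, f"tips(p3) gen {g}")
        lab_p3 = _gather_rows(lab_p3, parents)

    # Sample one chromosome per population per locus.
    x1 = rng.integers(0, N, size=L)
    x2 = rng.integers(0, N, size=L)
    x3 = rng.integers(0, M, size=L)
    r1 = lab12[rows, x1]  # index into root final generation
    a2 = lab12[L + rows, x2]  # index into anc23 final generation
    a3 = lab_p3[rows, x3]

    # Trace p2/p3 lineages back through the internal branch.  Once two
    # lineages share an ancestor they remain merged, so per-level checks
    # identify the first coalescence.
    conc = a2 == a3
    pos2, pos3 = a2.copy(), a3.copy()
    for g in range(G_int - 1, -1, -1):
        pos2 = P_anc[g][rows, pos2].astype(np.int64)
        pos3 = P_anc[g][rows, pos3].astype(np.int64)
        conc |= pos2 == pos3
    r2 = F_anc[rows, pos2]
    r3 = F_anc[rows, pos3]
    conc |= r2 == r3

    # Trace all three lineages through the root window; the first pair to
    # merge fixes the triplet topology.
    CONC, P12, P13, UNRES = 1, 2, 3, 0
    result = np.zeros(L, dtype=np.int8)
    result[conc] = CONC
    pos = np.stack([r1, r2, r3]).astype(np.int64)  # (3, L)

    def _check(undecided: np.ndarray) -> None:
        e23 = pos[1] == pos[2]
        e12 = pos[0] == pos[1]
        e13 = pos[0] == pos[2]
        triple = undecided & e12 & e13
        if triple.any():
            result[triple] = rng.integers(1, 4, size=int(triple.sum()))
            undecided &= ~triple
        for mask, code in ((e23, CONC), (e12, P12), (e13, P13)):
            hit = undecided & mask
            if hit.any():
                result[hit] = code
                undecided &= ~hit

    undecided = result == UNRES
    _check(undecided)
    for g in range(R - 1, -1, -1):
        if not undecided.any():
            break
        pos = P_root[g][rows, pos].astype(np.int64)
        _check(undecided)

    return TopologyCounts(
        n_concordant=int(np.count_nonzero(result == CONC)),
        n_p1p2=int(np.count_nonzero(result == P12)),
        n_p1p3=int(np.count_nonzero(result == P13)),
        n_unresolved=int(np.count_nonzero(result == UNRES)),
    )


def simulate_wf_genealogies(config: WFConfig) -> list[TopologyCounts]:
    """Run ``config.n_replicates`` replicates of ``config.n_loci`` loci each."""
    master = np.random.SeedSequence(config.seed)
    out = []
    for ss in master.spawn(config.n_replicates):
        out.append(_simulate_replicate(config, np.random.default_rng(ss)))
    return out


def wf_config_from_yaml(path) -> WFConfig:
    """Load a :class:`WFConfig` from a YAML file.

    Schema (all keys optional; defaults as in :class:`WFConfig`)::

        n_pop: 500
        p3_size_ratio: 0.04
        internal_gens: 5        # default 0.01 * n_pop
        tip_gens: 4000          # default 8 * n_pop
        mutation_rate: 3.0e-7   # U, per locus per generation
        ns: -7.5                # population-scaled selection coefficient
        n_loci: 50
        n_replicates: 100
        diploid_units: false
        seed: 42
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    allowed = {f for f in WFConfig.__dataclass_fields__}
    unknown = sorted(set(doc) - allowed)
    if unknown:
        raise ValueError(f"unknown WF config keys: {', '.join(unknown)}")
    return WFConfig(**doc)


__all__.append("wf_config_from_yaml")


# ---------------------------------------------------------------------------
# Topology-distribution comparison
# ---------------------------------------------------------------------------

def topology_bias_test(
    neutral: TopologyCounts | Sequence[TopologyCounts],
    selected: TopologyCounts | Sequence[TopologyCounts],
    mc_samples: int = 10_000,
    mc_seed: int = 0,
) -> tuple[float, float]:
    """Compare two pooled topology-count distributions (3×2 contingency test).

    Uses the chi-square test of homogeneity; when any expected cell count is
    below 5 the p-value is instead computed by Monte-Carlo sampling of random
    tables with the observed margins (logged via the return value only --
    the statistic reported is the same chi-square).
    """
    if not isinstance(neutral, TopologyCounts):
        neutral = pool_counts(neutral)
    if not isinstance(selected, TopologyCounts):
        selected = pool_counts(selected)
    if neutral.n_resolved == 0 or selected.n_resolved == 0:
        raise ValueError("both pools must contain resolved loci")
    table = np.array([neutral.as_tuple(), selected.as_tuple()], dtype=np.int64)
    keep = table.sum(axis=0) > 0  # drop empty topology columns
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if (expected < 5).any():
        rng = np.random.default_rng(mc_seed)
        dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
        samples = dist.rvs(mc_samples, random_state=rng)
        exp = expected[np.newaxis]
        samp_stat = ((samples - exp) ** 2 / exp).sum(axis=(1, 2))
        p = (1 + int((samp_stat >= res.statistic - 1e-12).sum())) / (mc_samples + 1)
        return float(res.statistic), float(p)
    return float(res.statistic), float(res.pvalue)
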