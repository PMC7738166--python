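"""The gene-tree Δ test for introgression, at genome scale.

For a species-tree branch with discordant gene-tree counts, the two
alternative nearest-neighbour arrangements are ranked by frequency (DF1 = the
more frequent, DF2 = the less frequent) and

    Δ = (DF1 − DF2) / (DF1 + DF2),

so Δ ∈ [0, 1] with expectation 0 under incomplete lineage sorting alone and
Δ > 0 when introgression (or another asymmetry-generating process) inflates
one alternative.  Significance comes from a gene-tree bootstrap: the full
gene-tree list is resampled with replacement, Δ is recomputed per replicate
with the DF1/DF2 group identities frozen from the observed data (re-ranking
per replicate would bias the null upward), and z = Δ_obs / sd(Δ_boot).

Because Δ_obs is the absolute value of an asymptotically normal difference,
its null distribution is half-normal; the one-sided p-value of the test of
Δ > 0 is therefore ``min(1, 2·Φ̄(z))``.  (``tail="normal"`` selects the plain
upper-tail ``Φ̄(z)`` instead, which is anti-conservative by a factor of two
at the usual thresholds.)  Family-wise error over m tested branches is
controlled with the Dunn–Šidák cutoff ``1 − (1−α)^(1/m)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ConcordanceRecord, GeneTreeClass, classify_many
from .trees import BranchContext, Tree, TreeValidationError

__all__ = [
    "DeltaResult",
    "ScreenConfig",
    "delta_statistic",
    "sidak_cutoff",
    "screen_branches",
    "bootstrap_delta",
    "quartet_followup",
    "delta_results_to_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Branch screening and bootstrap-test configuration.

    ``min_discordant_fraction`` mirrors the >5 %-discordant screen; ``n_boot``
    the 2,000 pseudo-replicate datasets; ``m`` the number of comparisons used
    for the Dunn–Šidák correction.
    """

    min_discordant_fraction: float = 0.05
    alpha: float = 0.05
    m: int = 17
    n_boot: int = 2000
    seed: int | None = None
    tail: str = "half-normal"  # or "normal"

    def __post_init__(self) -> None:
        if not (0 <= self.min_discordant_fraction < 1):
            raise ValueError("min_discordant_fraction must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.tail not in ("half-normal", "normal"):
            raise ValueError("tail must be 'half-normal' or 'normal'")


@dataclass(frozen=True)
class DeltaResult:
    """Δ with its gene-tree bootstrap null summary for one branch."""

    branch_id: str
    n_df1: int
    n_df2: int
    delta: float | None
    boot_sd: float | None
    z_score: float | None
    p_value: float | None
    n_boot: int
    seed: int | None
    significant_raw: bool
    significant_corrected: bool
    df1_arrangement: str = "ALT1"
    degenerate: bool = False
    n_loci_used: int | None = None

    @property
    def defined(self) -> bool:
        return self.delta is not None


def delta_statistic(n_df1: int, n_df2: int) -> float:
    """Δ = (max − min)/(max + min) of the two alternative-topology counts.

    The caller may pass the counts in either order; ranking happens here, so
    Δ >= 0 wherever defined.  Returns ``nan`` when both counts are zero
    (no discordance to test).
    """
    if n_df1 < 0 or n_df2 < 0:
        raise ValueError("counts must be non-negative")
    hi, lo = max(n_df1, n_df2), min(n_df1, n_df2)
    if hi + lo == 0:
        return float("nan")
    return (hi - lo) / (hi + lo)


def sidak_cutoff(alpha: float, m: int) -> float:
    """Dunn–Šidák per-comparison cutoff 1 − (1−α)^(1/m) for m comparisons."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def screen_branches(
    records: Sequence[ConcordanceRecord],
    config: ScreenConfig | None = None,
) -> list[str]:
    """Branch ids whose discordant fraction of decisive trees exceeds the screen.

    The denominator is the number of decisive trees: non-decisive trees carry
    no information about the branch.  Branches with no decisive tree are
    never selected.
    """
    config = config or ScreenConfig()
    out = []
    for rec in records:
        if rec.n_decisive == 0:
            continue
        frac = rec.n_discordant / rec.n_decisive
        if frac > config.min_discordant_fraction:
            out.append(rec.branch_id)
    return out


def _delta_from_classes(
    classes: np.ndarray,
    branch_id: str,
    config: ScreenConfig,
    n_loci_used: int | None = None,
) -> DeltaResult:
    classes = np.asarray(classes, dtype=np.int8)
    c1 = int(np.count_nonzero(classes == GeneTreeClass.ALT1))
    c2 = int(np.count_nonzero(classes == GeneTreeClass.ALT2))
    cutoff = sidak_cutoff(config.alpha, config.m)
    if c1 + c2 == 0:
        return DeltaResult(
            branch_id=branch_id, n_df1=0, n_df2=0, delta=None, boot_sd=None,
            z_score=None, p_value=None, n_boot=config.n_boot, seed=config.seed,
            significant_raw=False, significant_corrected=False,
            n_loci_used=n_loci_used,
        )
    # DF1/DF2 identities frozen from the observed counts; ties go to ALT1.
    df1_is_alt1 = c1 >= c2
    n_df1, n_df2 = (c1, c2) if df1_is_alt1 else (c2, c1)
    delta_obs = (n_df1 - n_df2) / (n_df1 + n_df2)

    seed_seq = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(int(branch_id, 16),)
    )
    rng = np.random.default_rng(seed_seq)
    n = classes.size
    rep_delta = np.empty(config.n_boot)
    df1_code = GeneTreeClass.ALT1 if df1_is_alt1 else GeneTreeClass.ALT2
    df2_code = GeneTreeClass.ALT2 if df1_is_alt1 else GeneTreeClass.ALT1
    chunk = max(1, min(config.n_boot, 8_000_000 // max(n, 1)))
    done = 0
    while done < config.n_boot:
        k = min(chunk, config.n_boot - done)
        idx = rng.integers(0, n, size=(k, n))
        sampled = classes[idx]
        d1 = np.count_nonzero(sampled == df1_code, axis=1)
        d2 = np.count_nonzero(sampled == df2_code, axis=1)
        tot = d1 + d2
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, (d1 - d2) / np.maximum(tot, 1), 0.0)
        rep_delta[done : done + k] = vals
        done += k
    if np.unique(rep_delta).size < 4:
        logger.warning(
            "branch %s: fewer than 4 distinct bootstrap Delta values", branch_id
        )
    boot_sd = float(np.std(rep_delta, ddof=1))
    degenerate = False
    if boot_sd == 0.0:
        if delta_obs == 0.0:
            z, p = 0.0, 1.0
        else:
            z, p, degenerate = float("inf"), 0.0, True
            logger.warning(
                "branch %s: zero bootstrap SD with nonzero Delta", branch_id
            )
    else:
        z = delta_obs / boot_sd
        if config.tail == "half-normal":
            p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        else:
            p = float(stats.norm.sf(z))
    return DeltaResult(
        branch_id=branch_id,
        n_df1=n_df1,
        n_df2=n_df2,
        delta=delta_obs,
        boot_sd=boot_sd,
        z_score=z,
        p_value=p,
        n_boot=config.n_boot,
        seed=config.seed,
        significant_raw=p < config.alpha,
        significant_corrected=p < cutoff,
        df1_arrangement="ALT1" if df1_is_alt1 else "ALT2",
        degenerate=degenerate,
        n_loci_used=n_loci_used,
    )


def bootstrap_delta(
    gene_trees: Sequence[Tree],
    species_tree: Tree,
    branch: BranchContext,
    config: ScreenConfig | None = None,
) -> DeltaResult:
    """Observed Δ and its gene-tree bootstrap test for one branch.

    The resampling unit is the whole gene tree (the full input list is
    resampled with replacement at its original size), and results are
    bit-reproducible from ``config.seed``.
    """
    config = config or ScreenConfig()
    classes = classify_many(gene_trees, branch)
    return _delta_from_classes(classes, branch.branch_id, config)


def quartet_followup(
    gene_trees: Sequence[Tree],
    species_tree: Tree,
    branch: BranchContext,
    chosen: Sequence[str],
    config: ScreenConfig | None = None,
) -> DeltaResult:
    """Four-taxon follow-up Δ test: one chosen taxon per context group.

    Gene trees missing any chosen taxon are dropped; the remainder are
    restricted to the four taxa and the bootstrap runs on that restricted
    set, with the number of usable loci recorded.
    """
    config = config or ScreenConfig()
    chosen = list(chosen)
    if len(chosen) != 4 or len(set(chosen)) != 4:
        raise TreeValidationError("exactly 4 distinct taxa must be chosen")
    groups = {"A": branch.a, "B": branch.b, "C": branch.c, "D": branch.d}
    assignment: dict[str, str] = {}
    for taxon in chosen:
        hits = [g for g, members in groups.items() if taxon in members]
        if not hits:
            raise TreeValidationError(f"taxon {taxon!r} is not in any context group")
        assignment[taxon] = hits[0]
    if sorted(assignment.values()) != ["A", "B", "C", "D"]:
        raise TreeValidationError(
            "chosen taxa must include exactly one member of each of A, B, C, D"
        )
    by_group = {g: t for t, g in assignment.items()}
    quartet_ctx = BranchContext(
        branch_id=branch.branch_id,
        a=frozenset([by_group["A"]]),
        b=frozenset([by_group["B"]]),
        c=frozenset([by_group["C"]]),
        d=frozenset([by_group["D"]]),
    )
    chosen_set = set(chosen)
    usable = [gt for gt in gene_trees if chosen_set <= gt.leaves]
    if not usable:
        raise TreeValidationError("no gene tree contains all four chosen taxa")
    restricted = [gt.restrict(chosen_set) for gt in usable]
    classes = classify_many(restricted, quartet_ctx)
    return _delta_from_classes(
        classes, branch.branch_id, config, n_loci_used=len(usable)
    )


def delta_results_to_dataframe(
    results: Sequence[DeltaResult],
    records: Sequence[ConcordanceRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate Δ results; concordance counts merged in when provided."""
    by_id = {r.branch_id: r for r in (records or [])}
    rows = []
    for res in results:
        rec = by_id.get(res.branch_id)
        rows.append(
            {
                "branch_id": res.branch_id,
                "n_decisive": None if rec is None else rec.n_decisive,
                "n_concordant": None if rec is None else rec.n_concordant,
                "n_df1": res.n_df1,
                "n_df2": res.n_df2,
                "delta": res.delta,
                "boot_sd": res.boot_sd,
                "z": res.z_score,
                "p": res.p_value,
                "sig_raw": res.significant_raw,
                "sig_sidak": res.significant_corrected,
                "n_loci_used": res.n_loci_used,
            }
        )
    return pd.DataFrame(rows)
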