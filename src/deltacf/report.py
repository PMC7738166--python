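"""Reports and run manifests.

``report_cf_vs_age`` reproduces the concordance-versus-node-age summary:
ordinary least squares of gCF (and sCF when present) against user-supplied
node ages, reporting r².  Dating is out of scope, so ages always come from
the caller.

``RunManifest`` records everything needed to reproduce a stochastic run
bit-identically: the command, its configuration, the master seed, SHA-256
digests of every input file, the package version, and a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .concordance import ConcordanceRecord
from .io import sha256_of

__all__ = ["CfAgeResult", "report_cf_vs_age", "RunManifest"]


@dataclass(frozen=True)
class CfAgeResult:
    """OLS summary of concordance factors against node age."""

    table: pd.DataFrame  # branch_id, age, gCF, sCF
    r2_gcf: float | None
    r2_scf: float | None
    slope_gcf: float | None
    slope_scf: float | None
    n_branches: int
    degenerate: bool  # zero variance in age (or in every response)

    def summary(self) -> str:
        def fmt(r2, slope):
            if r2 is None:
                return "n/a"
            return f"r^2 = {r2:.4f} (slope {slope:.4g})"

        lines = [
            f"branches with ages: {self.n_branches}",
            f"gCF vs age: {fmt(self.r2_gcf, self.slope_gcf)}",
            f"sCF vs age: {fmt(self.r2_scf, self.slope_scf)}",
        ]
        if self.degenerate:
            lines.append("degenerate fit: ages (or responses) have zero variance")
        return "\n".join(lines)


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(r², slope, degenerate) for an OLS fit; zero-variance inputs give r²=0."""
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0, 0.0, True
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), False


def report_cf_vs_age(
    records: Sequence[ConcordanceRecord],
    node_ages: Mapping[str, float],
) -> CfAgeResult:
    """Regress per-branch gCF (and sCF when present) on node age.

    ``node_ages`` maps branch ids to ages in the caller's time units.
    Branches without an age or without a defined gCF are dropped; at least 3
    branches must remain.
    """
    rows = []
    for rec in records:
        age = node_ages.get(rec.branch_id)
        if age is None or rec.gcf is None:
            continue
        rows.append(
            {"branch_id": rec.branch_id, "age": float(age),
             "gCF": rec.gcf, "sCF": rec.scf}
        )
    if len(rows) < 3:
        raise ValueError(
            f"need >= 3 branches with both an age and a defined gCF, got {len(rows)}"
        )
    table = pd.DataFrame(rows)
    ages = table["age"].to_numpy()
    r2_g, slope_g, deg_g = _ols_r2(ages, table["gCF"].to_numpy())
    r2_s = slope_s = None
    deg_s = False
    scf = table["sCF"].dropna()
    if len(scf) >= 3:
        sub = table.loc[scf.index]
        r2_s, slope_s, deg_s = _ols_r2(
            sub["age"].to_numpy(), sub["sCF"].to_numpy()
        )
    return CfAgeResult(
        table=table,
        r2_gcf=r2_g,
        r2_scf=r2_s,
        slope_gcf=slope_g,
        slope_scf=slope_s,
        n_branches=len(table),
        degenerate=deg_g or deg_s,
    )


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record for one command invocation."""

    command: str
    config: Mapping
    seed: int | None
    inputs: Mapping[str, str]  # path -> sha256
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def collect(
        cls,
        command: str,
        config: Mapping,
        seed: int | None,
        input_paths: Sequence[str],
    ) -> "RunManifest":
        return cls(
            command=command,
            config=dict(config),
            seed=seed,
            inputs={str(p): sha256_of(p) for p in input_paths},
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")
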