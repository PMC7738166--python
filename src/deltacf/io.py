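"""Alignment and table I/O.

Alignments are plain mappings ``{taxon label: sequence string}``.  FASTA and
relaxed PHYLIP are read through Biopython; format detection uses the file
extension first and falls back to sniffing the first non-blank character.
Taxon labels are matched exactly (no normalisation).

TSV outputs use one fixed dialect everywhere: tab-separated, ``.`` decimal,
header row, no quoting, ``\\n`` newlines, ``NA`` for missing values.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "AlignmentError",
    "read_alignment",
    "read_alignment_dir",
    "write_fasta",
    "write_tsv",
    "read_tsv",
    "sha256_of",
]

_FASTA_EXT = {".fa", ".fasta", ".fna", ".fas"}
_PHYLIP_EXT = {".phy", ".phylip"}
_ALN_EXT = _FASTA_EXT | _PHYLIP_EXT


class AlignmentError(ValueError):
    """Raised when an alignment file cannot be read or is inconsistent."""


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _PHYLIP_EXT:
        return "phylip-relaxed"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "phylip-relaxed"
    raise AlignmentError(f"{path}: empty alignment file")


def read_alignment(path) -> dict[str, str]:
    """Read one FASTA or relaxed-PHYLIP alignment into ``{label: sequence}``."""
    path = Path(path)
    fmt = _detect_format(path)
    try:
        if fmt == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), fmt))
    except (ValueError, IndexError) as exc:
        raise AlignmentError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    out: dict[str, str] = {}
    lengths = set()
    for rec in records:
        if not rec.id:
            raise AlignmentError(f"{path}: sequence with empty label")
        if rec.id in out:
            raise AlignmentError(f"{path}: duplicate label {rec.id!r}")
        seq = str(rec.seq)
        out[rec.id] = seq
        lengths.add(len(seq))
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: sequences have unequal lengths {sorted(lengths)}"
        )
    return out


def read_alignment_dir(path) -> list[dict[str, str]]:
    """Read every alignment file in a directory, sorted by file name.

    Files with recognised extensions ({fa,fasta,fna,fas,phy,phylip}) are
    loaded; anything else is ignored.
    """
    path = Path(path)
    if not path.is_dir():
        raise AlignmentError(f"{path}: not a directory")
    files = sorted(p for p in path.iterdir()
                   if p.is_file() and p.suffix.lower() in _ALN_EXT)
    if not files:
        raise AlignmentError(f"{path}: no alignment files found")
    return [read_alignment(p) for p in files]


def write_fasta(alignment: Mapping[str, str], path, width: int = 70) -> None:
    """Write an alignment mapping as FASTA (labels in insertion order)."""
    with open(path, "w") as fh:
        for label, seq in alignment.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a data frame in the package's fixed TSV dialect."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def sha256_of(path) -> str:
    """Hex SHA-256 digest of a file's bytes (for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
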