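"""Readers for the plain-text input formats (TSV throughout).

Expression matrices are stored genes x samples on disk (the usual array
convention) and handed around samples x variables in memory (the usual
statistics convention).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError
from .graph import PathwayGraph
from .refine import EvidenceSet

__all__ = [
    "read_expression",
    "read_groups",
    "read_deg_list",
    "read_superfamily",
    "read_evidence",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV; returns a samples x genes frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{Path(path).name}: empty expression matrix")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{Path(path).name}: duplicate gene IDs {dups[:5]}")
    return df.T.astype(float)


def read_groups(path) -> pd.Series:
    """Read a sample TAB label TSV into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ParseError(f"{Path(path).name}: expected exactly one label column")
    return df.iloc[:, 0].astype(str)


def read_deg_list(path) -> list:
    """One gene ID per line; '#' comments and blanks skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    if not out:
        raise ParseError(f"{Path(path).name}: empty DEG list")
    return out


def read_superfamily(path) -> dict:
    """Two-column TSV gene TAB family -> {gene: family}."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{Path(path).name}:{lineno}: expected 2 fields")
        out[fields[0].strip()] = fields[1].strip()
    return out


def read_evidence(path, pathway: PathwayGraph | None = None) -> EvidenceSet:
    """Two-column TSV of unordered interaction pairs."""
    pairs = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{Path(path).name}:{lineno}: expected 2 fields")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            raise ParseError(f"{Path(path).name}:{lineno}: self-pair {a!r}")
        pairs.add(frozenset((a, b)))
    return EvidenceSet(string_edges=pairs, pathway=pathway)
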