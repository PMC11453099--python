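"""Readers/writers for the plain-text tabular formats used across the package.

All files are TSV.  Residues are identified by (chain, seqnum, icode); the
insertion-code column is written as an empty string when absent, so readers
must not interpret empty fields as NaN.

Formats
-------
score file        chain  seqnum  icode  score          (one file per classifier)
annotation file   antigen_id  chain  seqnum  icode     (one residue per line)
prediction file   chain  seqnum  icode  consensus_score  in_top_n  cluster_id
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .structure import ResidueId

_READ_KW = dict(sep="\t", dtype={"chain": str, "icode": str}, keep_default_na=False)


def _rid(row, resname: str = "") -> ResidueId:
    return ResidueId(str(row.chain), int(row.seqnum), str(row.icode), resname)


def read_score_file(path: str | Path) -> dict[tuple[str, int, str], float]:
    """Map residue key -> score from a per-classifier score TSV."""
    df = pd.read_csv(path, **_READ_KW)
    return {_rid(r).key: float(r.score) for r in df.itertuples()}


def write_score_file(path: str | Path, scores: dict[ResidueId, float]) -> None:
    rows = [(r.chain, r.seqnum, r.icode, s) for r, s in scores.items()]
    pd.DataFrame(rows, columns=["chain", "seqnum", "icode", "score"]).to_csv(
        path, sep="\t", index=False)


def read_annotation_file(path: str | Path) -> dict[str, set[ResidueId]]:
    """Annotation TSV -> {antigen_id: residue set}."""
    df = pd.read_csv(path, **_READ_KW)
    out: dict[str, set[ResidueId]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.antigen_id), set()).add(_rid(r))
    return out


def write_annotation_file(path: str | Path, annotations: dict[str, set[ResidueId]]) -> None:
    rows = [
        (aid, r.chain, r.seqnum, r.icode)
        for aid, residues in annotations.items()
        for r in sorted(residues, key=lambda x: x.key)
    ]
    pd.DataFrame(rows, columns=["antigen_id", "chain", "seqnum", "icode"]).to_csv(
        path, sep="\t", index=False)


def write_prediction_file(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_prediction_file(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, **_READ_KW)
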