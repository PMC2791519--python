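"""Delimited-text I/O for log-evidence matrices and volume manifests."""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .core import LogEvidenceMatrix

__all__ = ["read_logev_table", "write_logev_table", "read_volume_manifest"]


def read_logev_table(path: str | os.PathLike, sep: str = "\t") -> LogEvidenceMatrix:
    """Read a subjects x models log-evidence table.

    First row: model names; first column: subject identifiers.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 model columns, got {df.shape[1]}")
    return LogEvidenceMatrix(
        df.to_numpy(dtype=float),
        subject_ids=tuple(str(s) for s in df.index),
        model_names=tuple(str(m) for m in df.columns),
    )


def write_logev_table(
    logev: LogEvidenceMatrix, path: str | os.PathLike, sep: str = "\t"
) -> None:
    df = pd.DataFrame(
        logev.values, index=list(logev.subject_ids), columns=list(logev.model_names)
    )
    df.to_csv(path, sep=sep)


def read_volume_manifest(
    path: str | os.PathLike,
) -> tuple[list[list[str]], list[str], list[str]]:
    """Read an explicit subject/model/path manifest (CSV).

    Columns ``subject``, ``model``, ``path``; every subject must list every
    model exactly once. Returns (paths[n][k], subject_ids, model_names) with
    subjects and models in first-appearance order — explicit pairing, no
    directory globbing, so the N x K layout is unambiguous.
    """
    df = pd.read_csv(path)
    required = {"subject", "model", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {sorted(missing)}")
    subjects = list(dict.fromkeys(df["subject"].astype(str)))
    models = list(dict.fromkeys(df["model"].astype(str)))
    table = df.set_index([df["subject"].astype(str), df["model"].astype(str)])["path"]
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate manifest entry for {dup}")
    paths: list[list[str]] = []
    for s in subjects:
        row = []
        for m in models:
            if (s, m) not in table.index:
                raise ValueError(f"{path}: missing volume for subject {s}, model {m}")
            row.append(str(table.loc[(s, m)]))
        paths.append(row)
    return paths, subjects, models
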