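"""File formats: FASTA sequence stores, labeled pair lists, headered
feature matrices, prediction tables, and persisted models."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PairRecord",
    "read_fasta",
    "read_pairs",
    "write_pairs",
    "write_fasta",
    "write_matrix",
    "read_matrix",
    "save_model",
    "load_model",
]

#: sentinel label for 2-column (prediction-mode) pair files
UNKNOWN = 0

_GAP_CHARS = set("-*")


@dataclass(frozen=True)
class PairRecord:
    idA: str
    idB: str
    label: int  # +1, -1, or UNKNOWN


def read_fasta(path: str | Path, gap_policy: str = "strict") -> dict[str, str]:
    """Load a FASTA file into an id -> upper-cased sequence mapping.

    The id is the first whitespace-delimited header token.  Duplicate
    ids and empty records are errors.  Gap/stop characters ('-', '*')
    are rejected under ``gap_policy="strict"`` and removed under
    ``"lenient"``.
    """
    if gap_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    store: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        if rec.id in store:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        bad = set(seq) & _GAP_CHARS
        if bad:
            if gap_policy == "strict":
                raise ValueError(
                    f"record {rec.id!r} contains gap/stop characters {sorted(bad)}"
                )
            seq = "".join(c for c in seq if c not in _GAP_CHARS)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        store[rec.id] = seq
    if not store:
        raise ValueError(f"no FASTA records found in {path}")
    return store


def write_fasta(store: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in store.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_POS_TOKENS = {"1", "+1"}
_NEG_TOKENS = {"-1", "−1"}  # ASCII and unicode minus


def read_pairs(path: str | Path, zero_is_negative: bool = False) -> list[PairRecord]:
    """Parse a tab-separated pair list of 2 (unlabeled) or 3 columns.

    Labels: "1"/"+1" -> +1; "-1" -> -1; "0" -> -1 only when
    ``zero_is_negative``.  Anything else is an error with its line
    number.  CRLF and LF both accepted.
    """
    rows: list[PairRecord] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) == 2:
                rows.append(PairRecord(cols[0].strip(), cols[1].strip(), UNKNOWN))
                continue
            if len(cols) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(cols)}"
                )
            tok = cols[2].strip()
            if tok in _POS_TOKENS:
                label = 1
            elif tok in _NEG_TOKENS or (zero_is_negative and tok == "0"):
                label = -1
            else:
                raise ValueError(f"{path}:{lineno}: unparseable label {tok!r}")
            rows.append(PairRecord(cols[0].strip(), cols[1].strip(), label))
    if not rows:
        raise ValueError(f"no pairs found in {path}")
    return rows


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            if p.label == UNKNOWN:
                fh.write(f"{p.idA}\t{p.idB}\n")
            else:
                fh.write(f"{p.idA}\t{p.idB}\t{'1' if p.label == 1 else '-1'}\n")


def write_matrix(
    X: np.ndarray,
    columns: Sequence[str],
    path: str | Path,
    index: Sequence[str] | None = None,
) -> None:
    """Write a feature matrix as headered TSV at full float precision."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("matrix must be 2-D and non-empty")
    if X.shape[1] != len(columns):
        raise ValueError(f"{X.shape[1]} columns but {len(columns)} names")
    df = pd.DataFrame(X, columns=list(columns))
    if index is not None:
        df.insert(0, "pair", list(index))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(
    path: str | Path, expect_columns: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Read a headered TSV matrix; returns (values, columns, row ids).

    ``expect_columns`` enforces exact name-and-order agreement with the
    columns a fitted model was trained on.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise ValueError(f"empty matrix in {path}")
    ids = None
    if df.columns[0] == "pair":
        ids = df["pair"].astype(str).tolist()
        df = df.drop(columns=["pair"])
    cols = df.columns.tolist()
    if expect_columns is not None and cols != list(expect_columns):
        raise ValueError(
            "matrix columns do not match the model's training columns "
            f"(got {len(cols)} columns starting {cols[:3]}, "
            f"expected {len(expect_columns)} starting {list(expect_columns)[:3]})"
        )
    return df.to_numpy(dtype=float), cols, ids


def save_model(model, metadata: dict, path: str | Path) -> None:
    """Persist a fitted model with its feature-mode/column metadata."""
    joblib.dump({"model": model, "metadata": dict(metadata)}, path)


def load_model(path: str | Path):
    """Load a persisted model; returns (model, metadata)."""
    blob = joblib.load(path)
    if not isinstance(blob, dict) or "model" not in blob or "metadata" not in blob:
        raise ValueError(f"{path} is not a seqppi model file")
    return blob["model"], blob["metadata"]
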