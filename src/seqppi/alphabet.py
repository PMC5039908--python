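"""Amino-acid alphabet constants: the seven functional groups and the
six-property physicochemical table.

The 20 standard residues are partitioned into seven functional groups
(C0..C6) defined by the dipole and side-chain volume of the residue, the
same clustering used by the Conjoint Triad descriptor.  Six per-residue
physicochemical scales — hydrophobicity (H), side-chain volume (VSC),
polarity (P1), polarizability (P2), solvent-accessible surface area (SASA)
and net charge index of the side chain (NCISC) — are shipped as a
plain-text table and z-scored column-wise before use in autocorrelation
descriptors.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: The 20 standard residues, alphabetical by one-letter code.
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Seven functional groups over the 20 standard residues.  The index in
#: this tuple is the group code (0..6).
GROUPS: tuple[str, ...] = ("AGV", "C", "DE", "FILP", "HNQW", "KR", "MSTY")

N_GROUPS: int = len(GROUPS)

#: residue -> group code 0..6
RESIDUE_TO_GROUP: dict[str, int] = {
    res: code for code, members in enumerate(GROUPS) for res in members
}

#: Physicochemical descriptor names, in fixed column order.
PROPERTY_NAMES: tuple[str, ...] = ("H", "VSC", "P1", "P2", "SASA", "NCISC")


class NonStandardResidueError(ValueError):
    """Raised for a residue outside the 20-letter standard alphabet."""

    def __init__(self, residue: str, position: int | None = None):
        self.residue = residue
        self.position = position
        loc = "" if position is None else f" at position {position}"
        super().__init__(f"non-standard residue {residue!r}{loc}")


def classify_residue(residue: str) -> int:
    """Map a one-letter residue code to its functional-group code 0..6.

    Raises :class:`NonStandardResidueError` for anything outside the 20
    standard codes (B, J, O, U, X, Z, gaps, ...).
    """
    try:
        return RESIDUE_TO_GROUP[residue.upper()]
    except KeyError:
        raise NonStandardResidueError(residue) from None


def encode_sequence(sequence: str, on_nonstandard: str = "error") -> np.ndarray:
    """Re-code a protein sequence as an int8 array of group codes 0..6.

    Parameters
    ----------
    sequence
        Residue string; upper-cased before classification.
    on_nonstandard
        ``"error"`` (default) raises :class:`NonStandardResidueError`
        naming the first offending position; ``"drop"`` removes
        non-standard residues before encoding.  Silent coercion is never
        performed: it would corrupt the group frequencies downstream.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if on_nonstandard not in ("error", "drop"):
        raise ValueError(f"unknown non-standard-residue policy {on_nonstandard!r}")
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for res, grp in RESIDUE_TO_GROUP.items():
        lut[ord(res)] = grp
    out = lut[codes]
    bad = out < 0
    if bad.any():
        if on_nonstandard == "error":
            pos = int(np.flatnonzero(bad)[0])
            raise NonStandardResidueError(seq[pos], pos)
        out = out[~bad]
        if out.size == 0:
            raise ValueError("sequence empty after dropping non-standard residues")
    return out


def _load_raw_table() -> pd.DataFrame:
    with resources.files("seqppi.data").joinpath("physchem_properties.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    df = df.loc[list(RESIDUES), list(PROPERTY_NAMES)]
    return df.astype(float)


def normalize_properties(raw: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score each descriptor column to zero mean and unit SD.

    ``ddof=0`` (population SD over the 20 residues) is the default: it
    makes "unit standard deviation" of the 20 listed values exact.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D residue-by-property grid")
    if not np.isfinite(raw).all():
        raise ValueError("property grid contains non-finite values")
    sd = raw.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero-SD property column cannot be normalized")
    return (raw - raw.mean(axis=0)) / sd


#: 20x6 raw property grid, rows in RESIDUES order, columns in PROPERTY_NAMES order.
RAW_PROPERTY_TABLE: pd.DataFrame = _load_raw_table()

#: Column-z-scored grid (population SD), same layout.
NORMALIZED_PROPERTY_TABLE: pd.DataFrame = pd.DataFrame(
    normalize_properties(RAW_PROPERTY_TABLE.to_numpy()),
    index=RAW_PROPERTY_TABLE.index,
    columns=RAW_PROPERTY_TABLE.columns,
)

#: residue -> row index into the property tables
RESIDUE_INDEX: dict[str, int] = {res: i for i, res in enumerate(RESIDUES)}


def encode_residue_indices(sequence: str, on_nonstandard: str = "error") -> np.ndarray:
    """Re-code a sequence as row indices 0..19 into the property tables."""
    if not sequence:
        raise ValueError("empty sequence")
    if on_nonstandard not in ("error", "drop"):
        raise ValueError(f"unknown non-standard-residue policy {on_nonstandard!r}")
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for res, i in RESIDUE_INDEX.items():
        lut[ord(res)] = i
    out = lut[codes]
    bad = out < 0
    if bad.any():
        if on_nonstandard == "error":
            pos = int(np.flatnonzero(bad)[0])
            raise NonStandardResidueError(seq[pos], pos)
        out = out[~bad]
        if out.size == 0:
            raise ValueError("sequence empty after dropping non-standard residues")
    return out


def group_table_text() -> str:
    """Printable dump of the seven-group classification, for documentation."""
    lines = ["group\tmembers"]
    for code, members in enumerate(GROUPS):
        lines.append(f"C{code}\t{','.join(members)}")
    return "\n".join(lines)
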