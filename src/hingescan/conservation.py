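"""Per-column identity and conservative-substitution statistics from
multiple sequence alignments, partitioned by taxon group.

"Conservative substitution" is operationalized as a non-identical letter
with a positive BLOSUM62 score against the reference letter (the closest
reconstructable version of BLAST "positives"). Gaps and X count in the
denominator as non-conservative mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class LabeledAlignment:
    """Rows of equal length; row 1 is the reference; groups by sequence id."""

    ids: list[str]
    sequences: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 rows")
        L = len(self.sequences[0])
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: row {i + 1} has length {len(s)}, expected {L}"
                )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def reference(self) -> str:
        return self.sequences[0]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def group_rows(self, group: str) -> list[int]:
        rows = [i for i, sid in enumerate(self.ids) if self.groups.get(sid) == group]
        if not rows:
            raise ValueError(f"group {group!r} is empty")
        return rows

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def to_fasta(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")
        if groups_path is not None:
            with open(groups_path, "w") as fh:
                for sid, g in self.groups.items():
                    fh.write(f"{sid}\t{g}\n")


def read_alignment(
    path: str | Path, groups: Mapping[str, str] | str | Path | None = None
) -> LabeledAlignment:
    """Read an aligned FASTA; attach group labels from a map or sidecar TSV.

    When no group source is given, headers of the form ``group|id`` are used.
    Row 1 is the reference sequence.
    """
    msa = AlignIO.read(str(path), "fasta")
    ids = [rec.id for rec in msa]
    seqs = [str(rec.seq).upper() for rec in msa]
    if isinstance(groups, (str, Path)):
        table = {}
        with open(groups) as fh:
            for line in fh:
                if line.strip():
                    sid, g = line.rstrip("\n").split("\t")
                    table[sid] = g
        groups = table
    elif groups is None:
        groups = {
            sid: sid.split("|", 1)[0] for sid in ids if "|" in sid
        }
    unknown = set(groups) - set(ids)
    if unknown:
        raise ValueError(f"group labels for unknown sequence ids: {sorted(unknown)[:5]}")
    return LabeledAlignment(ids=ids, sequences=seqs, groups=dict(groups))


def map_columns(aln: LabeledAlignment) -> dict[int, int]:
    """1-based column -> reference residue number (non-gap positions only)."""
    out = {}
    n = 0
    for col, letter in enumerate(aln.reference, start=1):
        if letter != "-":
            n += 1
            out[col] = n
    if not out:
        warnings.warn("reference row is all gaps; no columns mapped")
    return out


def is_conservative(ref: str, letter: str) -> bool:
    if letter == ref or letter not in _AA or ref not in _AA:
        return False
    return _BLOSUM62[ref, letter] > 0


def column_stats(aln: LabeledAlignment, column: int, group: str) -> tuple[float, float]:
    """(identity %, conservative %) of one 1-based column within a group."""
    ref = aln.reference[column - 1]
    if ref == "-":
        raise ValueError(f"reference has a gap at column {column}")
    rows = aln.group_rows(group)
    n = len(rows)
    ident = sum(1 for i in rows if aln.sequences[i][column - 1] == ref)
    cons = sum(1 for i in rows if is_conservative(ref, aln.sequences[i][column - 1]))
    return 100.0 * ident / n, 100.0 * cons / n


def conservation_profile(
    aln: LabeledAlignment, groups: Iterable[str] | None = None
) -> pd.DataFrame:
    """Tidy per-residue, per-group profile mapped to reference numbering.

    Columns: residue, group, n, identity_pct, conservative_pct, combined_pct.
    """
    groups = list(groups) if groups is not None else aln.group_names
    colmap = map_columns(aln)
    rows = []
    for col, res in colmap.items():
        for g in groups:
            ident, cons = column_stats(aln, col, g)
            rows.append(
                {
                    "residue": res,
                    "group": g,
                    "n": len(aln.group_rows(g)),
                    "identity_pct": ident,
                    "conservative_pct": cons,
                    "combined_pct": ident + cons,
                }
            )
    return pd.DataFrame(rows)


def profile_from_table(
    table: Mapping[int, Mapping[str, tuple[float, float]]]
) -> pd.DataFrame:
    """Build a profile DataFrame from printed (identity, conservative) values."""
    rows = []
    for res, by_group in table.items():
        for g, (ident, cons) in by_group.items():
            rows.append(
                {
                    "residue": int(res),
                    "group": g,
                    "n": np.nan,
                    "identity_pct": float(ident),
                    "conservative_pct": float(cons),
                    "combined_pct": float(ident) + float(cons),
                }
            )
    return pd.DataFrame(rows)


def flag_conserved(
    profile: pd.DataFrame,
    identity_min: float = 90.0,
    groups_required: tuple[str, ...] = ("bacteria", "animals"),
    mode: str = "identity",
) -> set[int]:
    """Residues meeting the conservation threshold in every required group.

    ``mode="identity"`` compares identity_pct; ``mode="combined"`` compares
    identity + conservative. The comparison is inclusive (>= identity_min),
    which is what reproduces the published highlighted set (a 90% row counts
    at a 90% threshold).
    """
    if mode not in ("identity", "combined"):
        raise ValueError("mode must be 'identity' or 'combined'")
    col = "identity_pct" if mode == "identity" else "combined_pct"
    have = set(profile["group"])
    missing = [g for g in groups_required if g not in have]
    if missing:
        raise ValueError(f"profile lacks required groups: {missing}")
    out: set[int] = set()
    for res, sub in profile.groupby("residue"):
        ok = True
        for g in groups_required:
            vals = sub.loc[sub["group"] == g, col]
            if len(vals) == 0 or not (vals.iloc[0] >= identity_min):
                ok = False
                break
        if ok:
            out.add(int(res))
    return out
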