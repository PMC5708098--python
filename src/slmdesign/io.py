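"""Readers and writers for the text formats the toolkit touches.

Sequences travel as FASTA (record IDs are construct names), PWMs as
JASPAR-style labelled 4-row matrices (see :mod:`slmdesign.motifs`), and all
tabular data as TSV: TF atlases (columns factor, ap_bin, concentration),
expression profiles (construct, ap_bin, value) and per-nucleus tables
(embryo, nucleus, ap_percent, fluorescence, line).  TSV writers prepend a
commented provenance header with the tool version and the seed/parameters
of the run.
"""

from __future__ import annotations

from collections import OrderedDict
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import ExpressionProfile, TfProfile
from .variability import NUCLEUS_COLUMNS

__all__ = [
    "read_fasta", "write_fasta",
    "read_expression_table", "write_expression_table",
    "read_atlas", "write_atlas",
    "read_nucleus_table", "write_nucleus_table",
]

_VALID = set("ACGT")


def _provenance(seed: int | None, **params) -> str:
    from . import __version__

    bits = [f"slmdesign v{__version__}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(bits) + "\n"


def read_fasta(path: str | Path) -> "OrderedDict[str, str]":
    """Read a multi-record FASTA into an ordered name -> sequence mapping.

    Sequences are uppercased; non-ACGT letters and duplicate IDs are
    rejected with the record name (and offset) in the message.
    """
    records: OrderedDict[str, str] = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for off, ch in enumerate(seq):
            if ch not in _VALID:
                raise ValueError(
                    f"record {rec.id!r}: non-ACGT character {ch!r} at offset {off}"
                )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: "OrderedDict[str, str] | dict[str, str]", path: str | Path,
                width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None, **params) -> None:
    buf = StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(_provenance(seed, **params) + buf.getvalue())


def read_expression_table(path: str | Path) -> dict[str, ExpressionProfile]:
    """One expression profile per construct; all constructs must share the
    same AP grid."""
    df = _read_tsv(path, ("construct", "ap_bin", "value"))
    profiles: dict[str, ExpressionProfile] = {}
    grids: dict[str, np.ndarray] = {}
    for construct, grp in df.groupby("construct", sort=False):
        grp = grp.sort_values("ap_bin")
        grids[construct] = grp["ap_bin"].to_numpy(dtype=float)
        profiles[str(construct)] = ExpressionProfile(
            str(construct), grids[construct], grp["value"].to_numpy(dtype=float)
        )
    names = list(profiles)
    ragged = [
        n for n in names[1:]
        if grids[n].shape != grids[names[0]].shape
        or not np.allclose(grids[n], grids[names[0]])
    ]
    if ragged:
        raise ValueError(f"constructs on ragged AP grids: {ragged}")
    return profiles


def write_expression_table(
    profiles: dict[str, ExpressionProfile], path: str | Path, seed: int | None = None
) -> None:
    rows = [
        {"construct": name, "ap_bin": float(b), "value": float(v)}
        for name, prof in profiles.items()
        for b, v in zip(prof.grid, prof.values)
    ]
    _write_tsv(pd.DataFrame(rows), path, seed)


def read_atlas(path: str | Path) -> list[TfProfile]:
    df = _read_tsv(path, ("factor", "ap_bin", "concentration"))
    out = []
    for factor, grp in df.groupby("factor", sort=False):
        grp = grp.sort_values("ap_bin")
        out.append(
            TfProfile(str(factor), grp["ap_bin"].to_numpy(dtype=float),
                      grp["concentration"].to_numpy(dtype=float))
        )
    return out


def write_atlas(atlas: list[TfProfile], path: str | Path, seed: int | None = None) -> None:
    rows = [
        {"factor": p.factor_name, "ap_bin": float(b), "concentration": float(c)}
        for p in atlas
        for b, c in zip(p.grid, p.concentrations)
    ]
    _write_tsv(pd.DataFrame(rows), path, seed)


def read_nucleus_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, NUCLEUS_COLUMNS)


def write_nucleus_table(table: pd.DataFrame, path: str | Path,
                        seed: int | None = None) -> None:
    _write_tsv(table[list(NUCLEUS_COLUMNS)], path, seed)
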