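"""File input/output: FASTA via Biopython, provenance-stamped CSV tables.

Every table written by the pipeline carries a small comment header
(``# key: value`` lines) recording the package version, the master seed and a
hash of the configuration, so any artifact can be traced back to the exact run
that produced it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write ``{name: sequence}`` to a FASTA file (order preserved)."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}`` (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None, index: bool = False) -> None:
    """Write a CSV with an optional ``# key: value`` provenance header."""
    buf = _io.StringIO()
    if meta:
        for key, value in meta.items():
            buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=index)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping comment lines."""
    return pd.read_csv(path, comment="#", **kwargs)


def read_provenance(path: str | Path) -> dict[str, str]:
    """Parse the ``# key: value`` comment header of a table."""
    meta: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta
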