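"""File readers and report writers.

Sequence input is FASTA (via Biopython) or two-column CSV; energy-difference
samples come as plain one-value-per-line text or GROMACS xvg dialect
(``#``/``@`` lines skipped). Reports are CSV/TSV/JSON with a deterministic
column order, two-decimal energies, one-decimal errors, and a provenance
header carrying the package version and parameter checksum -- identical
inputs always produce byte-identical output.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import FormatError
from .parameters import ParameterSet


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs, upper-cased, in file order.

    Ids are the header token up to the first whitespace. Empty files and
    header-only records raise :class:`FormatError` with the offending line.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError("empty FASTA file", path=path, line=1)
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    if not records:
        raise FormatError("no FASTA records found", path=path, line=1)
    header_lines = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            token = line[1:].split()[0] if line[1:].split() else ""
            header_lines.setdefault((token, ln), ln)
    headers = [(tok, ln) for (tok, ln) in header_lines]
    out = []
    for k, rec in enumerate(records):
        seq = str(rec.seq).upper()
        if not seq:
            line = headers[k][1] if k < len(headers) else None
            raise FormatError(f"record {rec.id!r} has an empty sequence", path=path, line=line)
        out.append((rec.id, seq))
    return out


def read_sequence_csv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (id, sequence) CSV; '#' comment lines allowed."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "id" not in cols or "sequence" not in cols:
        raise FormatError("sequence CSV needs 'id' and 'sequence' columns", path=path)
    out = []
    for k, row in df.iterrows():
        seq = row["sequence"]
        if not isinstance(seq, str) or not seq.strip():
            raise FormatError(f"row {row['id']!r} has an empty sequence", path=path)
        out.append((str(row["id"]), seq.strip().upper()))
    if not out:
        raise FormatError("no sequence rows found", path=path)
    return out


def read_samples(path: str | Path, column: int = 0) -> np.ndarray:
    """Energy differences (kJ/mol) from plain text or GROMACS xvg dialect.

    Lines starting with ``#`` or ``@`` are skipped; ``column`` selects the
    numeric column (0-based) for multi-column files.
    """
    path = Path(path)
    values = []
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "@")):
            continue
        fields = stripped.split()
        if column >= len(fields):
            raise FormatError(f"line has {len(fields)} column(s), need column {column}", path=path, line=ln)
        try:
            values.append(float(fields[column]))
        except ValueError:
            raise FormatError(f"non-numeric value {fields[column]!r}", path=path, line=ln) from None
    if not values:
        raise FormatError("no numeric samples found", path=path, line=1)
    return np.asarray(values, dtype=float)


def reference_table() -> pd.DataFrame:
    """The packaged reference peptide set (sequences, simulated and reported
    model energies, published relative errors) as a DataFrame."""
    from importlib import resources

    with resources.as_file(resources.files("pepgcm") / "data" / "reference_peptides.csv") as p:
        df = pd.read_csv(p, comment="#")
    return df


_ENERGY_HINTS = ("kjmol", "energy", "dg", "sum", "correction", "deviation", "ideal")
_ERROR_HINTS = ("error", "pct")


def _format_cell(column: str, value) -> str:
    if isinstance(value, bool) or value is None or isinstance(value, str):
        return "" if value is None else str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    name = column.lower()
    if any(h in name for h in _ERROR_HINTS):
        return f"{value:.1f}"
    if any(h in name for h in _ENERGY_HINTS):
        return f"{value:.2f}"
    return f"{value:.6g}"


def write_report(
    records: Sequence[Mapping[str, object]],
    fmt: str,
    path: str | Path,
    params: ParameterSet | None = None,
    seed: int | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as CSV, TSV or JSON with a provenance header.

    Column order is ``columns`` if given, else the key order of the first
    record; energies print with two decimals and percent errors with one.
    An empty record set yields a header-only file (``columns`` required).
    """
    fmt = fmt.lower()
    if fmt not in ("csv", "tsv", "json"):
        raise FormatError(f"unsupported report format {fmt!r}")
    if columns is None:
        if not records:
            raise FormatError("empty record set needs an explicit column list")
        columns = list(records[0].keys())
    meta = {"generator": f"pepgcm {__version__}"}
    if params is not None:
        meta["parameter_checksum"] = params.checksum()
        meta["parameter_source"] = params.provenance
    if seed is not None:
        meta["seed"] = seed

    path = Path(path)
    if fmt == "json":
        payload = {
            "meta": meta,
            "records": [
                {c: rec.get(c) for c in columns} for rec in records
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=False, default=float) + "\n", encoding="utf-8")
        return

    sep = "," if fmt == "csv" else "\t"
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    lines.append(sep.join(columns))
    for rec in records:
        lines.append(sep.join(_format_cell(c, rec.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a CSV/TSV report written by :func:`write_report`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, comment="#", sep=sep)
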