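"""Readers and writers for the delimited-text formats used by the pipeline.

Supported formats
-----------------
Genotype table
    Header ``sample,LOCUS.1,LOCUS.2,...`` (two allele columns per locus) or
    ``sample,LOCUS,...`` with ``a/b`` cells.  Missing calls are encoded by
    ``0`` or an empty field.
Allele-frequency table
    First column = allele label, one column per locus, blank cells where an
    allele is absent (the layout population studies publish).
Distance matrix
    Square labelled delimited table.
Trees
    Newick, via scikit-bio's tree machinery.
"""
from __future__ import annotations

import io as _io
import os
import re
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import (
    MISSING_SENTINELS,
    AlleleFrequencySpectrum,
    AlleleLabel,
    DistanceMatrix,
    Genotype,
    GenotypeTable,
    sort_alleles,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_allele_frequency_table",
    "write_allele_frequency_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_newick",
    "read_newick",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared layout."""


def _as_handle(stream) -> TextIO:
    if hasattr(stream, "read"):
        return stream
    return open(stream, "r", encoding="utf-8")


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_genotype_table(stream, population_id: str | None = None) -> GenotypeTable:
    """Parse a delimited genotype table.

    The dialect (two columns per locus vs one ``a/b`` column) is inferred
    from the header: paired columns are named ``LOCUS.1``/``LOCUS.2``.
    """
    fh = _as_handle(stream)
    close = fh is not stream
    try:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    finally:
        if close:
            fh.close()
    if not lines:
        raise FormatError("empty genotype table")
    sep = _sniff_sep(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]
    if len(header) < 2:
        raise FormatError("genotype table needs a sample column plus loci")
    cols = header[1:]
    paired = all(re.search(r"\.[12]$", c) for c in cols)
    if paired:
        if len(cols) % 2:
            raise FormatError("odd number of allele columns")
        loci = []
        for i in range(0, len(cols), 2):
            base1 = cols[i][:-2]
            base2 = cols[i + 1][:-2]
            if base1 != base2 or not cols[i].endswith(".1") \
                    or not cols[i + 1].endswith(".2"):
                raise FormatError(
                    f"allele columns not paired: {cols[i]!r}, {cols[i+1]!r}")
            loci.append(base1)
    else:
        loci = cols

    individual_ids: list[str] = []
    calls: dict[str, list[Genotype | None]] = {l: [] for l in loci}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != len(header):
            raise FormatError(
                f"line {lineno}: {len(fields)} fields, expected {len(header)}")
        individual_ids.append(fields[0])
        body = fields[1:]
        for j, locus in enumerate(loci):
            if paired:
                a, b = body[2 * j], body[2 * j + 1]
            else:
                cell = body[j]
                if cell in MISSING_SENTINELS:
                    a = b = ""
                else:
                    if "/" not in cell:
                        raise FormatError(
                            f"line {lineno}, locus {locus}: expected 'a/b' "
                            f"cell, got {cell!r}")
                    a, _, b = cell.partition("/")
                    a, b = a.strip(), b.strip()
            if a in MISSING_SENTINELS or b in MISSING_SENTINELS:
                calls[locus].append(None)
                continue
            try:
                calls[locus].append(Genotype.of(a, b))
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}, locus {locus}: {exc}") from exc
    return GenotypeTable(population_id or "population",
                         individual_ids, loci, calls)


def write_genotype_table(table: GenotypeTable, stream=None, sep: str = ",",
                         dialect: str = "two-column") -> str:
    """Serialize a genotype table; returns the text (and writes if given)."""
    buf = _io.StringIO()
    if dialect == "two-column":
        header = ["sample"]
        for locus in table.loci:
            header += [f"{locus}.1", f"{locus}.2"]
        buf.write(sep.join(header) + "\n")
        for i, ind in enumerate(table.individual_ids):
            row = [ind]
            for locus in table.loci:
                g = table.calls[locus][i]
                row += ["0", "0"] if g is None else [str(g.a1), str(g.a2)]
            buf.write(sep.join(row) + "\n")
    elif dialect == "slash":
        buf.write(sep.join(["sample"] + table.loci) + "\n")
        for i, ind in enumerate(table.individual_ids):
            row = [ind]
            for locus in table.loci:
                g = table.calls[locus][i]
                row.append("0" if g is None else str(g))
            buf.write(sep.join(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = buf.getvalue()
    if stream is not None:
        if isinstance(stream, (str, bytes, os.PathLike)):
            with open(stream, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_allele_frequency_table(stream, n: int,
                                sum_tol: float = 5e-3,
                                ) -> list[AlleleFrequencySpectrum]:
    """Parse a published-style frequency table (rows = alleles, cols = loci).

    ``n`` is the number of typed individuals per locus (published tables
    state it in the caption).  Columns must each sum to ~1; a column outside
    ``1 +/- sum_tol`` raises naming the locus.
    """
    df = pd.read_csv(_as_handle(stream), sep=None, engine="python",
                     index_col=0)
    specs: list[AlleleFrequencySpectrum] = []
    for locus in df.columns:
        col = df[locus].dropna()
        col = col[col > 0]
        if col.empty:
            raise FormatError(f"locus {locus}: no alleles")
        s = float(col.sum())
        if abs(s - 1.0) > sum_tol:
            raise FormatError(
                f"locus {locus}: column sums to {s:.4f}, outside "
                f"[{1-sum_tol:.3f}, {1+sum_tol:.3f}]")
        freqs = {AlleleLabel.parse(str(a)): float(v)
                 for a, v in col.items()}
        specs.append(AlleleFrequencySpectrum(locus=str(locus), n=n,
                                             freqs=freqs))
    return specs


def write_allele_frequency_table(specs: Sequence[AlleleFrequencySpectrum],
                                 stream=None, sep: str = ",",
                                 precision: int | None = None) -> str:
    """Write spectra as a rows-by-alleles table mirroring published layout.

    With ``precision=None`` frequencies are written at full precision so a
    round-trip regenerates counts exactly.
    """
    all_alleles = sort_alleles({a for s in specs for a in s.freqs})
    loci = [s.locus for s in specs]
    buf = _io.StringIO()
    buf.write(sep.join(["alleles"] + loci) + "\n")
    for a in all_alleles:
        row = [str(a)]
        for s in specs:
            f = s.freqs.get(a)
            if f is None:
                row.append("")
            elif precision is None:
                row.append(repr(float(f)))
            else:
                row.append(f"{f:.{precision}f}")
        buf.write(sep.join(row) + "\n")
    text = buf.getvalue()
    if stream is not None:
        if isinstance(stream, (str, bytes, os.PathLike)):
            with open(stream, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_distance_matrix(stream) -> DistanceMatrix:
    df = pd.read_csv(_as_handle(stream), sep=None, engine="python",
                     index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise FormatError("distance matrix rows and columns disagree")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, stream=None,
                          sep: str = ",") -> str:
    buf = _io.StringIO()
    buf.write(sep.join([""] + dm.labels) + "\n")
    for i, lab in enumerate(dm.labels):
        buf.write(sep.join([lab] + [repr(float(x)) for x in dm.d[i]])
                  + "\n")
    text = buf.getvalue()
    if stream is not None:
        if isinstance(stream, (str, bytes, os.PathLike)):
            with open(stream, "w", encoding="utf-8") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def write_newick(tree: TreeNode, stream=None) -> str:
    """Serialize a tree to Newick text terminated by ';'."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    if stream is not None:
        if isinstance(stream, (str, bytes, os.PathLike)):
            with open(stream, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        else:
            stream.write(text + "\n")
    return text


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = _io.StringIO(source)
    elif isinstance(source, str) and source.rstrip().endswith(";") \
            and "\n" not in source.strip():
        # single-leaf newick like "A;"
        source = _io.StringIO(source)
    return TreeNode.read(_as_handle(source), format="newick")
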