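"""Readers and writers for the plain-text formats the package consumes.

Formats
-------
Genotype TSV
    Header row of marker ids, first column ``individual_id``, cells are
    diploid calls ``"X/Y"`` or ``"."`` for missing.  Individuals are
    rows, markers are columns.
Marker metadata TSV
    Columns ``marker_id``, ``chrom``, ``pos``, ``alleles``
    (comma-separated), ``class`` (functional|linkage).
Phenotype TSV
    Long format: columns ``individual_id``, ``trait``, ``value``,
    ``unit``.
Interacting-sets file
    One set per line, comma-separated marker ids; ``#`` comments and
    blank lines ignored.
VCF
    Standard VCF 4.x; only the GT field is used, mapped onto allele
    indices (requires cyvcf2).
"""

from __future__ import annotations

import re
from collections.abc import Sequence
from pathlib import Path

import pandas as pd

from .core import (
    MISSING,
    GenotypeMatrix,
    Marker,
    MarkerClass,
    ParseError,
    PhenotypeTable,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_metadata",
    "write_marker_metadata",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_interacting_sets",
    "write_interacting_sets",
]

_CHROM_POS = re.compile(r"^(?P<chrom>[A-Za-z0-9.]+)_(?P<pos>\d+)$")


def _infer_markers(calls: pd.DataFrame) -> list[Marker]:
    """Build marker definitions from observed calls when no metadata is given.

    Chromosome and position are parsed from ids of the form
    ``Chr03_28907974`` where possible; alleles are the sorted set seen in
    the calls.
    """
    markers = []
    for mid in calls.columns:
        alleles: set[str] = set()
        for c in calls[mid]:
            c = str(c).strip()
            if c in (MISSING, "./.", "", "nan"):
                continue
            alleles.update(c.split("/"))
        if len(alleles) < 2:
            # monomorphic or fully missing column: pad with a dummy alt
            alleles.update({"?alt"} if alleles else {"?ref", "?alt"})
        m = _CHROM_POS.match(mid)
        chrom = m.group("chrom") if m else "?"
        pos = int(m.group("pos")) if m else 1
        markers.append(Marker(mid, chrom, pos, tuple(sorted(alleles))))
    return markers


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    markers: Sequence[Marker] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    Parameters
    ----------
    path : path
    dialect : {"tsv", "vcf"}
    markers : sequence of Marker, optional
        Panel definitions used to validate calls.  For TSV, inferred
        from the file when omitted; for VCF, always taken from the file.

    Raises
    ------
    ParseError
        Malformed row (names the line number).
    GenotypeError
        A call uses an allele not defined for its marker (names marker
        and individual).
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_genotype_tsv(path, markers)
    if dialect == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genotype_tsv(path: Path, markers: Sequence[Marker] | None) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    marker_ids = header[1:]
    rows, index = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        index.append(fields[0])
        rows.append(fields[1:])
    calls = pd.DataFrame(rows, index=index, columns=marker_ids)
    if markers is None:
        panel = _infer_markers(calls)
    else:
        by_id = {m.marker_id: m for m in markers}
        try:
            panel = [by_id[mid] for mid in marker_ids]
        except KeyError as exc:
            raise ParseError(f"{path}: marker {exc.args[0]!r} has no metadata") from None
    return GenotypeMatrix.from_raw(panel, calls)


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an extra
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    markers: list[Marker] = []
    columns: dict[str, list[str]] = {}
    for rec in vcf:
        alleles = tuple([rec.REF] + list(rec.ALT))
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        marker = Marker(mid, rec.CHROM, rec.POS, alleles)
        markers.append(marker)
        col = []
        for gt in rec.genotypes:  # [a, b, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col.append(MISSING)
            else:
                i, j = sorted((a, b))
                col.append(f"{alleles[i]}/{alleles[j]}")
        columns[mid] = col
    calls = pd.DataFrame(columns, index=individuals)
    return GenotypeMatrix(markers, calls)


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect; round-trips exactly with :func:`read_genotype_table`."""
    df = gm.calls.copy()
    df.insert(0, "individual_id", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_marker_metadata(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "chrom", "pos", "alleles", "class"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: marker metadata needs columns {sorted(required)}")
    return [
        Marker(
            row["marker_id"],
            row["chrom"],
            int(row["pos"]),
            tuple(a.strip() for a in row["alleles"].split(",")),
            MarkerClass(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def write_marker_metadata(markers: Sequence[Marker], path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "chrom": [m.chrom for m in markers],
            "pos": [m.pos for m in markers],
            "alleles": [",".join(m.alleles) for m in markers],
            "class": [m.marker_class.value for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path, trait: str) -> PhenotypeTable:
    """Read one trait from a long-format phenotype TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "trait": str})
    required = {"individual_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: phenotype table needs columns {sorted(required)}")
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ParseError(f"{path}: no rows for trait {trait!r}")
    units = sub["unit"].dropna().unique() if "unit" in sub.columns else []
    if len(units) > 1:
        raise ParseError(f"{path}: trait {trait!r} has inconsistent units {list(units)}")
    values = pd.Series(sub["value"].astype(float).values, index=sub["individual_id"])
    return PhenotypeTable(trait=trait, values=values, unit=units[0] if len(units) else "")


def write_phenotype_table(
    tables: Sequence[PhenotypeTable], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {
                "individual_id": t.values.index,
                "trait": t.trait,
                "value": t.values.values,
                "unit": t.unit,
            }
        )
        for t in tables
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_interacting_sets(path: str | Path) -> list[list[str]]:
    sets = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            members = [m.strip() for m in ln.split(",") if m.strip()]
            if len(members) < 1:
                continue
            sets.append(members)
    return sets


def write_interacting_sets(sets: Sequence[Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(",".join(s) + "\n")
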