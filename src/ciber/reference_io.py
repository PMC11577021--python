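"""Readers and writers for barcode references, manifests, count tables and FASTQ.

The barcode library is described by a table with one id per row, where each
id encodes its own annotation as ``{gene}_{spacer}_{additional info...}``
(e.g. ``AADACL2_GAAAGTCAGAAACCCGA_2832.7_DTKP``).  Count tables are dense
TSV matrices (every reference barcode present, zeros explicit) because the
downstream abundance filters need explicit zeros.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ciber.errors import ValidationError

logger = logging.getLogger(__name__)

SPACER_ALPHABET = frozenset("ACGT")

FRACTIONS = ("cells", "sEVs")
CAS9_STATES = ("plus", "minus")

_FRACTION_ALIASES = {"cells": "cells", "cell": "cells", "sevs": "sEVs", "sev": "sEVs"}
_CAS9_ALIASES = {"plus": "plus", "+": "plus", "minus": "minus", "-": "minus"}


@dataclass(frozen=True)
class BarcodeReference:
    """One library member: a gRNA spacer used as an sEV barcode."""

    barcode_id: str
    gene: str
    spacer: str
    sublibrary: str = "default"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample of a screen.

    ``fraction`` is the compartment the RNA came from (``cells`` or
    ``sEVs``); ``cas9`` says whether the producing cells carried active
    Cas9 (``plus``) or only the catalytically dead fusion (``minus``).
    """

    sample_id: str
    fraction: str
    cas9: str
    screen: str
    sublibrary: str
    source: str = ""


def _parse_barcode_id(barcode_id: str, spacer_length: int) -> tuple[str, str, str | None]:
    """Split an id into (gene, spacer, sublibrary-or-None).

    The first underscore-separated token is the gene, the second the
    spacer.  A trailing non-numeric token (beyond the spacer) is read as
    the sublibrary label; gene symbols containing underscores are
    unsupported by this format.
    """
    tokens = barcode_id.split("_")
    if len(tokens) < 2:
        raise ValidationError(f"barcode id {barcode_id!r} has no spacer token")
    gene, spacer = tokens[0], tokens[1]
    if len(spacer) != spacer_length:
        raise ValidationError(
            f"barcode id {barcode_id!r}: spacer {spacer!r} has length "
            f"{len(spacer)}, expected {spacer_length}"
        )
    if not set(spacer) <= SPACER_ALPHABET:
        raise ValidationError(f"barcode id {barcode_id!r}: spacer {spacer!r} is not ACGT-only")
    sublibrary = None
    if len(tokens) >= 3:
        last = tokens[-1]
        try:
            float(last)
        except ValueError:
            if last:
                sublibrary = last
    return gene, spacer, sublibrary


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    return pd.read_csv(path, sep=sep, dtype=str, engine="python")


def read_barcode_reference(
    path: str | Path,
    id_column: str = "id",
    spacer_length: int = 17,
    sublibrary_column: str | None = "sublibrary",
) -> list[BarcodeReference]:
    """Load the barcode library from an xlsx or delimited table.

    Sublibrary assignment falls back in order: trailing id token, the
    optional ``sublibrary_column``, the literal ``"default"``.

    Raises
    ------
    ValidationError
        Listing every malformed id (with its row number) and every
        duplicate id or spacer (naming both offending ids).
    """
    table = _read_table(path)
    if id_column not in table.columns:
        raise ValidationError(f"reference table {path} has no column named {id_column!r}")

    problems: list[str] = []
    records: list[BarcodeReference] = []
    seen_ids: dict[str, int] = {}
    seen_spacers: dict[str, str] = {}
    has_sublib_col = sublibrary_column is not None and sublibrary_column in table.columns

    sublib_cells = table[sublibrary_column] if has_sublib_col else None
    for row_number, raw_id in enumerate(table[id_column], start=1):
        barcode_id = str(raw_id).strip()
        try:
            gene, spacer, sublib = _parse_barcode_id(barcode_id, spacer_length)
        except ValidationError as exc:
            problems.append(f"row {row_number}: {exc}")
            continue
        if barcode_id in seen_ids:
            problems.append(
                f"row {row_number}: duplicate barcode id {barcode_id!r} "
                f"(first seen at row {seen_ids[barcode_id]})"
            )
            continue
        if spacer in seen_spacers:
            problems.append(
                f"row {row_number}: spacer {spacer!r} of {barcode_id!r} duplicates "
                f"that of {seen_spacers[spacer]!r}"
            )
            continue
        seen_ids[barcode_id] = row_number
        seen_spacers[spacer] = barcode_id
        if sublib is None and sublib_cells is not None:
            cell = sublib_cells.iloc[row_number - 1]
            if pd.notna(cell) and str(cell).strip():
                sublib = str(cell).strip()
        records.append(
            BarcodeReference(barcode_id=barcode_id, gene=gene, spacer=spacer, sublibrary=sublib or "default")
        )

    if problems:
        raise ValidationError(problems)
    if not records:
        raise ValidationError(f"reference table {path} contains no barcodes")
    return records


def write_barcode_reference(records: Sequence[BarcodeReference], path: str | Path) -> None:
    """Write the reference as TSV with columns id, gene, spacer, sublibrary."""
    pd.DataFrame(
        {
            "id": [r.barcode_id for r in records],
            "gene": [r.gene for r in records],
            "spacer": [r.spacer for r in records],
            "sublibrary": [r.sublibrary for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(read_id, sequence)`` pairs from a plain or gzipped FASTQ.

    Quality lines are parsed (they delimit the records) but discarded.
    A truncated trailing record raises ValidationError with the record index.
    """
    with _open_maybe_gzip(path) as handle:
        record_index = 0
        try:
            for title, sequence, _quality in FastqGeneralIterator(handle):
                record_index += 1
                yield title.split()[0] if title else "", sequence
        except ValueError as exc:
            raise ValidationError(f"truncated or malformed FASTQ record {record_index + 1} in {path}: {exc}") from exc


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Load a sample manifest (TSV with sample_id, fraction, cas9, screen, sublibrary[, source])."""
    table = _read_table(path)
    required = {"sample_id", "fraction", "cas9", "screen", "sublibrary"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"manifest {path} lacks columns: {sorted(missing)}")

    problems: list[str] = []
    records: list[SampleRecord] = []
    for row_number, row in table.iterrows():
        fraction = _FRACTION_ALIASES.get(str(row["fraction"]).strip().lower())
        cas9 = _CAS9_ALIASES.get(str(row["cas9"]).strip().lower())
        if fraction is None:
            problems.append(f"row {row_number + 1}: fraction {row['fraction']!r} not one of {FRACTIONS}")
        if cas9 is None:
            problems.append(f"row {row_number + 1}: cas9 {row['cas9']!r} not one of {CAS9_STATES} (or +/-)")
        if fraction is None or cas9 is None:
            continue
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                fraction=fraction,
                cas9=cas9,
                screen=str(row["screen"]).strip(),
                sublibrary=str(row["sublibrary"]).strip(),
                source=str(row["source"]).strip() if "source" in table.columns and pd.notna(row.get("source")) else "",
            )
        )
    if problems:
        raise ValidationError(problems)

    ids = [r.sample_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"manifest {path} has duplicate sample ids: {sorted(dupes)}")
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def check_screen_complete(records: Iterable[SampleRecord], screen: str) -> dict[tuple[str, str, str], SampleRecord]:
    """Verify a screen has all four (fraction x cas9) samples per sublibrary.

    Returns a lookup keyed by ``(sublibrary, fraction, cas9)``.
    """
    samples = [r for r in records if r.screen == screen]
    if not samples:
        raise ValidationError(f"no samples found for screen {screen!r}")
    lookup: dict[tuple[str, str, str], SampleRecord] = {}
    for record in samples:
        key = (record.sublibrary, record.fraction, record.cas9)
        if key in lookup:
            raise ValidationError(
                f"screen {screen!r} has two samples for sublibrary={key[0]}, "
                f"fraction={key[1]}, cas9={key[2]}: {lookup[key].sample_id!r} and {record.sample_id!r}"
            )
        lookup[key] = record
    problems = []
    for sublibrary in sorted({r.sublibrary for r in samples}):
        for fraction in FRACTIONS:
            for cas9 in CAS9_STATES:
                if (sublibrary, fraction, cas9) not in lookup:
                    problems.append(
                        f"screen {screen!r} sublibrary {sublibrary!r} is missing the "
                        f"({fraction}, Cas9 {cas9}) sample"
                    )
    if problems:
        raise ValidationError(problems)
    return lookup


def read_count_table(
    path: str | Path,
    reference: Sequence[BarcodeReference] | None = None,
    required_samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read a TSV count table into a barcode x sample integer DataFrame.

    When a reference is given, the rows are conformed to it: barcodes
    absent from the file are inserted as zero rows (with a warning), and
    barcodes unknown to the reference raise an error.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"count table {path} has duplicate barcode rows: {dupes[:5]}")
    try:
        counts = table.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"count table {path} has non-integer counts: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)].tolist()
        raise ValidationError(f"count table {path} has negative counts for barcodes: {bad[:5]}")

    if required_samples is not None:
        missing = [s for s in required_samples if s not in counts.columns]
        if missing:
            raise ValidationError(f"count table {path} is missing samples: {missing}")

    if reference is not None:
        ref_ids = [r.barcode_id for r in reference]
        unknown = counts.index.difference(ref_ids)
        if len(unknown):
            raise ValidationError(
                f"count table {path} has barcodes absent from the reference: {unknown.tolist()[:5]}"
            )
        absent = [b for b in ref_ids if b not in counts.index]
        if absent:
            logger.warning(
                "count table %s lacks %d reference barcodes; inserting zero rows", path, len(absent)
            )
        counts = counts.reindex(ref_ids, fill_value=0)
    counts.index.name = "barcode_id"
    return counts


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a barcode x sample count matrix as TSV (write-read round-trips)."""
    out = counts.copy()
    out.index.name = "barcode_id"
    out.to_csv(path, sep="\t")
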