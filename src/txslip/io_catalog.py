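"""Read and write the file formats the pipeline touches.

Indel catalogs follow the six-column layout of the deposited data sets
(accession, replicate, 1-based genomic location, >=9 bases of upstream
context, the inserted/deleted sequence, downstream context), optionally with a
seventh ``kind`` column. TSV is the primary dialect; XLSX is supported
read-only for fidelity to the deposited spreadsheets. Genomes are FASTA (read
through Biopython), annotations 6-column BED or a GFF3 subset (CDS lines),
coverage tables two-column TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .records import CatalogError, CoverageTable, Gene, GenomeAnnotation, IndelRecord

CATALOG_COLUMNS = [
    "source_id",
    "replicate",
    "location",
    "upstream",
    "event_seq",
    "downstream",
]

_ALPHA = set("ACGTU")


def _clean_seq(raw: str, row_num: int, col: str) -> str:
    seq = raw.strip().upper()
    if not _ALPHA.issuperset(seq):
        bad = sorted(set(seq) - _ALPHA)
        raise CatalogError(f"row {row_num}: {col} contains non-ACGTU characters {bad}")
    return seq.replace("U", "T")


def _rows_to_records(rows, kind: str | None, has_kind_col: bool) -> list[IndelRecord]:
    records: list[IndelRecord] = []
    for row_num, row in rows:
        row = [str(c) if c is not None else "" for c in row]
        # tolerate trailing empty cells (common in exported spreadsheets)
        while row and row[-1] == "":
            row.pop()
        expected = 7 if has_kind_col else 6
        if len(row) != expected:
            raise CatalogError(
                f"row {row_num}: expected {expected} columns, got {len(row)}"
            )
        row_kind = row[6].strip().lower() if has_kind_col else kind
        if row_kind is None:
            raise CatalogError(
                f"row {row_num}: no 'kind' column and no kind= argument given"
            )
        try:
            location = int(float(row[2]))
        except ValueError as exc:
            raise CatalogError(f"row {row_num}: bad location {row[2]!r}") from exc
        records.append(
            IndelRecord(
                source_id=row[0].strip(),
                replicate=row[1].strip(),
                location=location,
                kind=row_kind,
                upstream=_clean_seq(row[3], row_num, "upstream"),
                event_seq=_clean_seq(row[4], row_num, "event_seq"),
                downstream=_clean_seq(row[5], row_num, "downstream"),
            )
        )
    return records


def read_indel_catalog(
    path: str | Path, format: str = "tsv", kind: str | None = None
) -> list[IndelRecord]:
    """Load a six/seven-column indel catalog.

    ``kind`` supplies the event type for six-column files; files carrying an
    explicit ``kind`` header column override it. A header-only file yields an
    empty list. Malformed rows raise :class:`CatalogError` naming the row.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise CatalogError(f"{path}: empty file, expected a header row")
            rows = [(i, row) for i, row in enumerate(reader, start=2) if row]
    elif format == "xlsx":
        from openpyxl import load_workbook

        ws = load_workbook(path, read_only=True, data_only=True).active
        it = ws.iter_rows(values_only=True)
        header = [str(c) if c is not None else "" for c in next(it)]
        rows = [
            (i, list(row))
            for i, row in enumerate(it, start=2)
            if any(c not in (None, "") for c in row)
        ]
    else:
        raise ValueError(f"unknown catalog format {format!r}")

    header = [str(h).strip().lower() for h in header]
    has_kind_col = len(header) >= 7 and header[6] == "kind"
    if header[:6] != CATALOG_COLUMNS:
        raise CatalogError(
            f"{path}: header {header[:6]} does not match the six-column layout "
            f"{CATALOG_COLUMNS}"
        )
    return _rows_to_records(rows, kind, has_kind_col)


def write_indel_catalog(
    records: list[IndelRecord], path: str | Path, format: str = "tsv"
) -> None:
    """Write records as a seven-column TSV (six data-set columns + kind)."""
    if format != "tsv":
        raise ValueError("catalogs are written as TSV only")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(CATALOG_COLUMNS + ["kind"])
        for r in records:
            writer.writerow(
                [r.source_id, r.replicate, r.location, r.upstream, r.event_seq,
                 r.downstream, r.kind]
            )


def read_genome(path: str | Path) -> GenomeAnnotation:
    """Load FASTA reference sequences (uppercased) into a GenomeAnnotation."""
    ann = GenomeAnnotation()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ann.sequences:
            raise CatalogError(f"duplicate sequence name {rec.id!r} in {path}")
        ann.sequences[rec.id] = str(rec.seq).upper()
    return ann


def write_genome(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in annotation.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_annotation(path: str | Path, annotation: GenomeAnnotation | None = None) -> GenomeAnnotation:
    """Load gene intervals from 6-column BED or GFF3 CDS lines.

    BED is 0-based half-open on disk and stored verbatim; GFF3 coordinates are
    1-based inclusive and converted. Reverse-strand genes are stored with
    strand '-' and genomic coordinates unmodified — orientation is applied by
    callers via :meth:`GenomeAnnotation.transcript_sequence`.
    """
    path = Path(path)
    ann = annotation if annotation is not None else GenomeAnnotation()
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_gff:
                if f[2] not in ("CDS", "gene"):
                    continue
                seq_name, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
                gene_id = _gff_attr(f[8], "ID") or f"{seq_name}:{start}-{end}"
            else:
                seq_name, start, end = f[0], int(f[1]), int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{seq_name}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "+"
            ann.genes.append(Gene(gene_id, seq_name, start, end, strand))
    if ann.sequences:
        ann.validate()
    return ann


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        k, _, v = part.strip().partition("=")
        if k == key:
            return v
    return None


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as 6-column BED."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            fh.write(f"{g.seq_name}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def read_coverage(path: str | Path) -> CoverageTable:
    """Load a two-column (gene_id, mean_depth) TSV coverage table."""
    depths: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0].strip().lower() != "gene_id":
            raise CatalogError(f"{path}: expected a 'gene_id\\tmean_depth' header")
        for row in reader:
            if not row:
                continue
            depths[row[0]] = float(row[1])
    return CoverageTable(depths)


def write_coverage(coverage: CoverageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_depth\n")
        for gid, d in coverage.depths.items():
            fh.write(f"{gid}\t{d:.6g}\n")
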