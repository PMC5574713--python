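"""Extraction of transcript-oriented indel records from a reference genome.

Both the synthetic generator and the coverage-weighted null model place events
at transcript-space positions inside genes and need the flanking sequence in
transcript orientation, extending beyond the gene boundary into the genome
when an event sits near a gene end. Reverse-strand genes are handled by
working on the reverse-complemented genomic context, so upstream always means
5' on the mRNA.
"""

from __future__ import annotations

from .records import Gene, GenomeAnnotation, IndelRecord, revcomp


def transcript_window(
    annotation: GenomeAnnotation, gene: Gene, t_start: int, t_end: int
) -> str:
    """Transcript-sense sequence for transcript coordinates [t_start, t_end).

    Coordinates may run past the gene boundary in either direction; the
    window is then filled from the surrounding genome (clamped at the
    chromosome ends).
    """
    chrom = annotation.sequences[gene.seq_name]
    if gene.strand == "+":
        g0, g1 = gene.start + t_start, gene.start + t_end
        return chrom[max(0, g0) : max(0, g1)]
    g0, g1 = gene.end - t_end, gene.end - t_start
    return revcomp(chrom[max(0, g0) : max(0, g1)])


def genome_location(gene: Gene, t: int) -> int:
    """1-based genomic position of transcript offset ``t`` (first affected base)."""
    if gene.strand == "+":
        return gene.start + t + 1
    return gene.end - t


def extract_deletion_record(
    annotation: GenomeAnnotation,
    gene: Gene,
    t: int,
    length: int,
    source_id: str = "sim",
    replicate: str = "1",
    up_n: int = 15,
    down_n: int = 15,
) -> IndelRecord:
    """Deletion of ``length`` transcript bases starting at transcript offset ``t``."""
    return IndelRecord(
        source_id=source_id,
        replicate=replicate,
        location=genome_location(gene, t),
        kind="deletion",
        upstream=transcript_window(annotation, gene, t - up_n, t),
        event_seq=transcript_window(annotation, gene, t, t + length),
        downstream=transcript_window(annotation, gene, t + length, t + length + down_n),
    )


def extract_insertion_record(
    annotation: GenomeAnnotation,
    gene: Gene,
    t: int,
    inserted: str,
    source_id: str = "sim",
    replicate: str = "1",
    up_n: int = 15,
    down_n: int = 15,
) -> IndelRecord:
    """Insertion of ``inserted`` immediately before transcript offset ``t``."""
    return IndelRecord(
        source_id=source_id,
        replicate=replicate,
        location=genome_location(gene, t),
        kind="insertion",
        upstream=transcript_window(annotation, gene, t - up_n, t),
        event_seq=inserted,
        downstream=transcript_window(annotation, gene, t, t + down_n),
    )
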