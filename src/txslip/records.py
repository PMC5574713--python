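"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; file formats that use
1-based inclusive coordinates (the six-column indel catalogs, GFF) are
converted at the I/O boundary. Catalog sequences are mRNA-sense DNA: upstream
and downstream flanks are given in transcript orientation, and events on
reverse-strand genes are reverse-complemented when they are extracted from the
genome, never at catalog load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class CatalogError(ValueError):
    """A malformed catalog row or file."""


class ContextUnavailableError(ValueError):
    """A record lacks the flanking sequence an operation needs."""


@dataclass(frozen=True)
class IndelRecord:
    """One transcription insertion or deletion.

    ``location`` is the 1-based reference position of the first affected base,
    as printed in the catalog files. ``upstream`` holds at least the nine
    bases immediately 5' of the event in transcript orientation (more when
    available), ``event_seq`` the inserted or deleted bases, ``downstream``
    the bases immediately 3' of the event.
    """

    source_id: str
    replicate: str
    location: int
    kind: str  # "insertion" | "deletion"
    upstream: str
    event_seq: str
    downstream: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise CatalogError(f"unknown indel kind {self.kind!r}")
        if len(self.event_seq) < 1:
            raise CatalogError("event_seq must be non-empty")
        if self.location < 1:
            raise CatalogError(f"location must be >= 1, got {self.location}")
        for name in ("upstream", "event_seq", "downstream"):
            seq = getattr(self, name)
            if not _DNA.issuperset(seq):
                bad = sorted(set(seq) - _DNA)
                raise CatalogError(f"{name} contains non-ACGT characters {bad}")

    def with_(self, **kw) -> "IndelRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class Gene:
    """A coding interval on a named sequence (0-based half-open)."""

    gene_id: str
    seq_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Reference sequences plus coding-gene intervals."""

    sequences: dict[str, str] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            if g.seq_name not in self.sequences:
                raise ValueError(f"gene {g.gene_id} references unknown sequence {g.seq_name!r}")
            if g.end > len(self.sequences[g.seq_name]):
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start}, {g.end}) exceeds "
                    f"sequence {g.seq_name!r} of length {len(self.sequences[g.seq_name])}"
                )

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript_sequence(self, gene: Gene) -> str:
        """mRNA-sense DNA sequence of a gene (reverse-complemented for '-')."""
        seq = self.sequences[gene.seq_name][gene.start : gene.end]
        return revcomp(seq) if gene.strand == "-" else seq


@dataclass
class CoverageTable:
    """Per-gene mean read depth over coding nucleotides.

    The total number of transcribed nucleotides — the denominator of every
    per-nucleotide rate — is the depth-weighted sum of coding lengths.
    """

    depths: dict[str, float]

    def __post_init__(self) -> None:
        for gid, d in self.depths.items():
            if d < 0:
                raise ValueError(f"negative depth {d} for gene {gid}")

    def total_transcribed_nt(self, annotation: GenomeAnnotation) -> float:
        total = 0.0
        for g in annotation.genes:
            total += self.depths.get(g.gene_id, 0.0) * g.length
        return total
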