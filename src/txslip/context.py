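"""Sequence-context placement and classification of transcription indels.

Deletions in repetitive sequence have several equivalent placements; they are
resolved to the unique right-most (3'-most) placement, so that when a repeat
unit is deleted it is always the last copy of the repeat that is recorded as
deleted. Insertions are classified as backward-slippage-consistent when the
inserted bases duplicate the immediately preceding bases. Homopolymer runs of
length >= 4 on the mRNA-sense strand of each gene define the run context for
the run-length rate curves.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ContextUnavailableError, GenomeAnnotation, IndelRecord

MIN_RUN = 4  # minimum homopolymer run length considered a run


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal single-nucleotide tract (0-based start, transcript sense)."""

    seq_name: str
    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class RepeatContext:
    """Repeat classification of one (normalized) deletion site."""

    in_tandem_repeat: bool
    unit_length: int
    unit_count: int
    normalized: bool = True


def normalize_deletion_3prime(record: IndelRecord) -> IndelRecord:
    """Shift an ambiguous deletion to its right-most equivalent placement.

    While the first downstream base equals the first deleted base the deleted
    window can slide one base 3' without changing either the reference or the
    resulting mRNA: the first deleted base moves onto the upstream flank and
    the first downstream base joins the (rotated) deleted sequence. The result
    is the unique placement in which the ambiguity sits at the 3' end of the
    deletion; the operation is idempotent and preserves upstream+event+downstream.
    """
    if record.kind != "deletion":
        raise ValueError("3' normalization applies to deletions only")
    up, ev, down, loc = record.upstream, record.event_seq, record.downstream, record.location
    while down and down[0] == ev[0]:
        up = up + ev[0]
        ev = ev[1:] + down[0]
        down = down[1:]
        loc += 1
    if (up, ev, down) == (record.upstream, record.event_seq, record.downstream):
        return record
    return record.with_(upstream=up, event_seq=ev, downstream=down, location=loc)


def find_homopolymer_runs(
    sequence: str, min_run: int = MIN_RUN, seq_name: str = ""
) -> list[HomopolymerRun]:
    """All maximal homopolymeric runs of length >= min_run, sorted by start."""
    runs: list[HomopolymerRun] = []
    i, n = 0, len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_run:
            runs.append(HomopolymerRun(seq_name, i, j - i, sequence[i]))
        i = j
    return runs


def classify_insertion(
    record: IndelRecord,
    annotation: GenomeAnnotation | None = None,
    gene_id: str | None = None,
) -> bool:
    """True iff the inserted sequence duplicates the immediately preceding bases.

    An insertion produced by backward slippage followed by retranscription
    carries a copy of the bases just transcribed, so the inserted sequence
    equals the upstream suffix of the same length. When the catalog's 9-base
    upstream column is shorter than the insert, context is extended from the
    genome if one is supplied; otherwise the record is rejected as lacking
    context.
    """
    if record.kind != "insertion":
        raise ValueError("classify_insertion applies to insertions only")
    k = len(record.event_seq)
    upstream = record.upstream
    if len(upstream) < k:
        if annotation is None or gene_id is None:
            raise ContextUnavailableError(
                f"insertion of {k} nt but only {len(upstream)} upstream bases "
                "and no genome to extend from"
            )
        upstream = _extend_upstream(record, annotation, gene_id, k)
    return upstream[-k:] == record.event_seq


def _extend_upstream(
    record: IndelRecord, annotation: GenomeAnnotation, gene_id: str, need: int
) -> str:
    gene = annotation.gene_by_id(gene_id)
    chrom = annotation.sequences[gene.seq_name]
    pos0 = record.location - 1
    if gene.strand == "+":
        start = max(0, pos0 - need)
        return chrom[start:pos0]
    from .records import revcomp

    # transcript-upstream of a '-' gene lies 3' in genome coordinates
    end = min(len(chrom), pos0 + 1 + need)
    return revcomp(chrom[pos0 + 1 : end])


def deletion_repeat_context(record: IndelRecord) -> RepeatContext:
    """Classify a 3'-normalized deletion by short-tandem-repeat membership.

    The deletion (length k) sits in a tandem repeat when the deleted k-mer is
    immediately preceded by at least one more copy of itself; the unit count
    includes the deleted copy, so a deletion of the second of two "TTC" units
    has unit_length 3 and unit_count 2.
    """
    if record.kind != "deletion":
        raise ValueError("deletion_repeat_context applies to deletions only")
    k = len(record.event_seq)
    copies = 1
    up = record.upstream
    while len(up) >= k and up[-k:] == record.event_seq:
        copies += 1
        up = up[:-k]
    return RepeatContext(in_tandem_repeat=copies >= 2, unit_length=k, unit_count=copies)


def locate_in_homopolymer(
    record: IndelRecord, runs: list[HomopolymerRun], position: int | None = None
) -> bool:
    """Whether an indel was initiated within a homopolymeric run.

    ``runs`` must be in the same coordinate frame / orientation as the record
    (``position`` overrides ``record.location - 1`` for transcript-space
    coordinates). An insertion belongs to a run when the inserted base matches
    the run base and the insertion point lies inside or immediately 3' of the
    run; a deletion when its first deleted base (after 3' normalization) lies
    within a run.
    """
    pos = record.location - 1 if position is None else position
    for run in runs:
        if record.kind == "insertion":
            if record.event_seq[0] == run.base and run.start <= pos <= run.end:
                return True
        else:
            if run.start <= pos < run.end:
                return True
    return False


def local_run_length(record: IndelRecord) -> tuple[str, int]:
    """Run base and length of the homopolymer tract at the event site,
    computed from the record's own flanks (no genome needed).

    For insertions the tract is the maximal run of the inserted base spanning
    the upstream suffix and downstream prefix; for deletions it is the run
    containing the first deleted base.
    """
    if record.kind == "insertion":
        base = record.event_seq[0]
        n = _suffix_run(record.upstream, base) + _prefix_run(record.downstream, base)
    else:
        base = record.event_seq[0]
        n = _suffix_run(record.upstream, base) + _prefix_run(record.event_seq, base)
        if set(record.event_seq) == {base}:
            n += _prefix_run(record.downstream, base)
    return base, n


def in_homopolymer_by_context(record: IndelRecord, min_run: int = MIN_RUN) -> bool:
    """Run membership judged from the record's flanks alone.

    Insertions must additionally be uniform copies of the run base (a
    multi-base insertion of mixed composition is never a homopolymer event).
    """
    base, n = local_run_length(record)
    if record.kind == "insertion" and set(record.event_seq) != {base}:
        return False
    return n >= min_run


def _suffix_run(seq: str, base: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def _prefix_run(seq: str, base: str) -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n
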