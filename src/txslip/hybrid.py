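"""Reconstruction of the RNA:DNA hybrid left after a forward-slippage deletion.

Inside the elongation complex the last ~9 transcribed nucleotides pair with
the template as an RNA:DNA hybrid. After a forward slip the transcript 3' end
(the nine bases preceding the deletion start) finds itself over a new template
region (the nine bases preceding the deletion end). Both windows are compared
in mRNA-sense space: identity of sense-strand bases at a position is
equivalent to complementary RNA:template pairing at that position, so the
number of matching positions is the number of complementary base pairs in the
reconstructed hybrid. Deletions shorter than the hybrid length make the two
windows overlap; this is a property of the reconstruction itself, not an
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ContextUnavailableError, IndelRecord

HYBRID_LEN = 9  # length of the RNA:DNA hybrid in the elongation complex


@dataclass(frozen=True)
class HybridReconstruction:
    """Pre- and post-slip hybrid windows with complementarity metrics."""

    pre_slip: str
    post_slip: str
    match_mask: tuple[bool, ...]
    n_match: int
    terminal_run: int


def reconstruct_hybrid(record: IndelRecord, hybrid_len: int = HYBRID_LEN) -> HybridReconstruction:
    """Hybrid windows for a (normalized) deletion.

    pre_slip is the upstream suffix of length ``hybrid_len`` (the transcript
    3' end at the moment of slippage); post_slip is the suffix of
    upstream+event_seq (the template region where slippage stopped).
    """
    if record.kind != "deletion":
        raise ValueError("hybrids are reconstructed for deletions only")
    if len(record.upstream) < hybrid_len:
        raise ContextUnavailableError(
            f"need {hybrid_len} upstream bases, have {len(record.upstream)}"
        )
    pre = record.upstream[-hybrid_len:]
    post = (record.upstream + record.event_seq)[-hybrid_len:]
    mask = tuple(a == b for a, b in zip(pre, post))
    n_match = sum(mask)
    terminal = 0
    for m in reversed(mask):
        if not m:
            break
        terminal += 1
    return HybridReconstruction(pre, post, mask, n_match, terminal)


def complementarity_histogram(
    records: list[IndelRecord], hybrid_len: int = HYBRID_LEN
) -> np.ndarray:
    """Counts of records at each complementarity level 0..hybrid_len."""
    counts = np.zeros(hybrid_len + 1, dtype=int)
    for rec in records:
        counts[reconstruct_hybrid(rec, hybrid_len).n_match] += 1
    return counts


def terminal_complementarity_fractions(
    records: list[IndelRecord], depths: tuple[int, ...] = (1, 2, 3, 4),
    hybrid_len: int = HYBRID_LEN,
) -> dict[int, float]:
    """Fraction of deletions whose hybrid ends in >= d consecutive matches.

    Monotonically non-increasing in d: a hybrid complementary in its last
    three positions is also complementary in its last two.
    """
    if not records:
        return {d: float("nan") for d in depths}
    runs = [reconstruct_hybrid(r, hybrid_len).terminal_run for r in records]
    return {d: sum(t >= d for t in runs) / len(runs) for d in depths}


def terminal_complementarity_counts(
    records: list[IndelRecord], depths: tuple[int, ...] = (1, 2, 3, 4),
    hybrid_len: int = HYBRID_LEN,
) -> dict[int, int]:
    """Number of deletions with terminal complementarity >= d."""
    runs = [reconstruct_hybrid(r, hybrid_len).terminal_run for r in records]
    return {d: sum(t >= d for t in runs) for d in depths}
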