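"""Indel calling from tandem-repeat (circularized-fragment) reads.

A circularized mRNA fragment is reverse-transcribed into a cDNA carrying
several linked copies of the fragment, so a 300-nt read holds at least three
repeats of an 80-100 nt fragment. True transcript indels appear identically
in every repeat copy, whereas sequencing errors hit single copies; the caller
therefore aligns each repeat copy to the reference window independently and
accepts an indel only when it is present at the identical position with the
identical size in every fully aligned repeat, inserted bases carry quality
>= 20 in every repeat, and deleted sites are flanked on both sides by bases
of quality >= 20 in every repeat. Because random priming of the circle makes
reads start anywhere in the fragment, the true register is recovered by a
rotation search before calling.

Per-repeat alignment uses Biopython's pairwise aligner with affine gap
penalties in infix mode; everything downstream of the alignment — rotation
search, repeat splitting, concordance and quality filtering — is implemented
here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

MIN_REPEATS = 3
DEFAULT_Q_THRESHOLD = 20
DEFAULT_MIN_FLANK = 5  # exact matches required on each side of an indel
DEFAULT_MIN_IDENTITY = 0.7

class UnmappableReadError(ValueError):
    """No rotation of the read aligns to the reference window."""


class InsufficientRepeatsError(ValueError):
    """The read holds fewer than three full repeat copies."""


@dataclass
class RepeatRead:
    """One sequencing read with per-base Phred qualities."""

    bases: str
    qualities: np.ndarray
    true_fragment_len: int | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities differ in length")
        if self.qualities.size and not (0 <= self.qualities.min() <= self.qualities.max() <= 60):
            raise ValueError("qualities must lie in [0, 60]")


@dataclass
class RepeatSupport:
    """Evidence for a candidate indel in one repeat copy."""

    present: bool
    position: int | None = None  # reference-window coordinate
    size: int | None = None
    inserted_quals: tuple[int, ...] = ()
    flank_quals: tuple[int, ...] = ()
    left_match: int = 0
    right_match: int = 0


@dataclass
class CandidateIndel:
    """An indel candidate with its per-repeat support."""

    position: int  # reference-window coordinate of the first affected base
    kind: str
    size: int
    event_seq: str
    support: list[RepeatSupport] = field(default_factory=list)
    accepted: bool = False
    reason: str | None = None


def estimate_fragment_length(read: RepeatRead, lo: int = 60, hi: int = 120) -> int:
    """Fragment length as the period minimizing the mean Hamming distance
    between adjacent read slices."""
    arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    best_len, best_d = lo, np.inf
    for L in range(lo, min(hi, len(arr) // 2) + 1):
        n = (len(arr) // L - 1) * L
        if n < L:
            continue
        d = np.mean(arr[:n] != arr[L : n + L])
        if d < best_d - 1e-12:
            best_d, best_len = d, L
    return best_len


def split_into_repeats(
    read: RepeatRead, fragment_len: int
) -> list[tuple[str, np.ndarray]]:
    """Cut a read into its full repeat copies; the trailing partial copy is
    discarded. Fewer than three full copies → InsufficientRepeatsError."""
    if fragment_len < 20:
        raise ValueError("fragment_len must be >= 20")
    n = len(read.bases) // fragment_len
    if n < MIN_REPEATS:
        raise InsufficientRepeatsError(
            f"{n} full repeats of {fragment_len} nt in a {len(read.bases)} nt read"
        )
    return [
        (read.bases[i * fragment_len : (i + 1) * fragment_len],
         read.qualities[i * fragment_len : (i + 1) * fragment_len])
        for i in range(n)
    ]


def _consensus(seqs: list[str]) -> str:
    return "".join(Counter(col).most_common(1)[0][0] for col in zip(*seqs))


def rotation_score(read: RepeatRead, reference_window: str, offset: int,
                   fragment_len: int) -> float:
    """Alignment score of one candidate rotation: the repeat copies are
    un-rotated by ``offset``, collapsed by majority vote, and the collapsed
    fragment is scored against the window with the same affine-gap scheme the
    caller uses (so rotations rank consistently with how indels are called)."""
    L = fragment_len
    copies = [read.bases[i * L : (i + 1) * L] for i in range(len(read.bases) // L)]
    if not copies:
        raise InsufficientRepeatsError("read shorter than one fragment")
    cut = (L - offset) % L
    frag = _consensus([c[cut:] + c[:cut] for c in copies])
    return float(_ALIGNER.score(reference_window, frag))


def find_best_rotation(
    read: RepeatRead,
    reference_window: str,
    fragment_len: int | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[int, int]:
    """Rotation offset restoring the fragment register, by brute force.

    Random priming of the circularized fragment makes every repeat copy a
    cyclic permutation of the fragment: copy = frag[o:] + frag[:o] for the
    same unknown offset o. Every candidate o is scored with
    :func:`rotation_score`; ties break toward the smallest offset. Returns
    (offset, score).
    """
    L = fragment_len or read.true_fragment_len or estimate_fragment_length(read)
    best: tuple[int, int] | None = None
    for o in range(L):
        score = rotation_score(read, reference_window, o, L)
        if best is None or score > best[1]:
            best = (o, score)
    assert best is not None
    if best[1] < min_identity * L:
        raise UnmappableReadError(
            f"best rotation scores {best[1]}/{L}, below identity {min_identity}"
        )
    return best


@dataclass
class _RepeatAlignment:
    identity: float
    indels: list[tuple]  # (kind, ref_pos, size, seq, lmatch, rmatch, ins_q, flank_q)


def _make_aligner() -> Align.PairwiseAligner:
    # affine gaps keep a multi-base indel contiguous instead of splitting it
    # across equal-cost unit gaps; free target end gaps give infix alignment
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -0.5
    # unaligned reference flanks are free (infix alignment of a repeat copy
    # against a wider reference window)
    a.end_deletion_score = 0.0
    return a


_ALIGNER = _make_aligner()


def _exact_suffix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def _exact_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _align_repeat(seq: str, quals: np.ndarray, window: str) -> _RepeatAlignment:
    aln = _ALIGNER.align(window, seq)[0]
    t_blocks, q_blocks = aln.aligned
    matches = sum(
        1
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
        for a, b in zip(window[ts:te], seq[qs:qe])
        if a == b
    )
    indels = []
    for i in range(len(t_blocks) - 1):
        t_end, q_end = t_blocks[i][1], q_blocks[i][1]
        t_next, q_next = t_blocks[i + 1][0], q_blocks[i + 1][0]
        t_gap, q_gap = int(t_next - t_end), int(q_next - q_end)
        lmatch = _exact_suffix(window[t_blocks[i][0] : t_end],
                               seq[q_blocks[i][0] : q_end])
        rmatch = _exact_prefix(window[t_next : t_blocks[i + 1][1]],
                               seq[q_next : q_blocks[i + 1][1]])
        if q_gap > 0:  # bases present in the read, absent from the reference
            ins_q = tuple(int(q) for q in quals[q_end:q_next])
            indels.append(("insertion", int(t_end), q_gap, seq[q_end:q_next],
                           lmatch, rmatch, ins_q, ()))
        if t_gap > 0:  # reference bases missing from the read
            flank_q = tuple(int(quals[j]) for j in (q_end - 1, q_next)
                            if 0 <= j < len(quals))
            indels.append(("deletion", int(t_end), t_gap, window[t_end:t_next],
                           lmatch, rmatch, (), flank_q))
    return _RepeatAlignment(identity=matches / len(seq), indels=indels)


def call_indels(
    repeats: list[tuple[str, np.ndarray]],
    reference_window: str,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_flank: int = DEFAULT_MIN_FLANK,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[CandidateIndel]:
    """Call indels supported concordantly by every repeat copy.

    Acceptance requires (i) an indel of identical kind, position, and size in
    every repeat, flanked on both sides by >= min_flank exactly matching
    bases; (ii) for insertions, every inserted base at quality >= q_threshold
    in every repeat; for deletions, both flanking bases at quality >=
    q_threshold in every repeat. Rejected candidates carry a reason:
    discordant_size, discordant_position, absent_in_repeat, low_quality, or
    not_flanked. Results are independent of repeat order.
    """
    if len(repeats) < MIN_REPEATS:
        raise InsufficientRepeatsError(f"{len(repeats)} repeats, need >= {MIN_REPEATS}")
    alns = [_align_repeat(seq, q, reference_window) for seq, q in repeats]
    for a in alns:
        if a.identity < min_identity:
            raise UnmappableReadError(
                f"repeat identity {a.identity:.2f} below {min_identity}"
            )
    keys = sorted({(ind[0], ind[1], ind[2], ind[3]) for a in alns for ind in a.indels})
    out: list[CandidateIndel] = []
    for kind, pos, size, seq in keys:
        cand = CandidateIndel(position=pos, kind=kind, size=size, event_seq=seq)
        statuses = []
        for a in alns:
            exact = [d for d in a.indels
                     if d[0] == kind and d[1] == pos and d[2] == size and d[3] == seq]
            if exact:
                d = exact[0]
                cand.support.append(RepeatSupport(True, d[1], d[2], d[6], d[7],
                                                  d[4], d[5]))
                statuses.append("ok")
            elif any(d[0] == kind and d[1] == pos and d[2] == size
                     for d in a.indels):
                cand.support.append(RepeatSupport(False))
                statuses.append("discordant_sequence")
            elif any(d[0] == kind and d[1] == pos for d in a.indels):
                cand.support.append(RepeatSupport(False))
                statuses.append("discordant_size")
            elif any(d[0] == kind for d in a.indels):
                cand.support.append(RepeatSupport(False))
                statuses.append("discordant_position")
            else:
                cand.support.append(RepeatSupport(False))
                statuses.append("absent_in_repeat")
        if any(s != "ok" for s in statuses):
            for reason in ("discordant_sequence", "discordant_size",
                           "discordant_position", "absent_in_repeat"):
                if reason in statuses:
                    cand.reason = reason
                    break
        elif any(s.left_match < min_flank or s.right_match < min_flank
                 for s in cand.support):
            cand.reason = "not_flanked"
        elif kind == "insertion" and any(
            q < q_threshold for s in cand.support for q in s.inserted_quals
        ):
            cand.reason = "low_quality"
        elif kind == "deletion" and any(
            len(s.flank_quals) < 2 or min(s.flank_quals) < q_threshold
            for s in cand.support
        ):
            cand.reason = "low_quality"
        else:
            cand.accepted = True
        out.append(cand)
    return out


def _call_at_rotation(read, reference_window, L, rotation, **kw):
    cut = (L - rotation) % L
    repeats = [
        (seq[cut:] + seq[:cut], np.concatenate([q[cut:], q[:cut]]))
        for seq, q in split_into_repeats(read, L)
    ]
    return call_indels(repeats, reference_window, **kw)


def call_read(
    read: RepeatRead,
    reference_window: str,
    fragment_len: int | None = None,
    rotation: int | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_indel_slack: float = 36.0,
    **kw,
) -> list[CandidateIndel]:
    """Rotation search + repeat split + concordance calling for one read.

    The rotation restoring the true fragment register is searched by
    alignment score, but an indel-bearing read is kept at the highest-scoring
    rotation that still contains an accepted indel (``max_indel_slack`` bounds
    how far below the best score that rotation may sit — one maximal indel).
    """
    L = fragment_len or read.true_fragment_len or estimate_fragment_length(read)
    if rotation is not None:
        return _call_at_rotation(read, reference_window, L, rotation, **kw)
    scores = [rotation_score(read, reference_window, o, L) for o in range(L)]
    best = max(scores)
    if best < min_identity * L:
        raise UnmappableReadError(
            f"best rotation scores {best}/{L}, below identity {min_identity}"
        )
    # A rotation cutting through an indel can score higher than the true
    # register (the junction hides the gap), so candidate rotations within a
    # slack of one maximal indel below the best score are examined from the
    # top down and the highest-scoring rotation that yields an accepted indel
    # wins — a read whose candidate rotations all come up empty is reported
    # at its best-scoring register.
    floor = max(best - max_indel_slack, min_identity * L)
    order = sorted((o for o, s in enumerate(scores) if s >= floor),
                   key=lambda o: (-scores[o], o))
    first_result = None
    clean_score = None  # score of the best indel-free register seen
    for o in order:
        if clean_score is not None and scores[o] < clean_score:
            # an indel-free register strictly outscores every remaining
            # rotation: the read carries no authentic indel
            break
        try:
            result = _call_at_rotation(read, reference_window, L, o, **kw)
        except UnmappableReadError:
            continue
        if first_result is None:
            first_result = result
        if any(c.accepted for c in result):
            return result
        if not result and clean_score is None:
            clean_score = scores[o]
            first_result = result
    if first_result is None:
        raise UnmappableReadError("no candidate rotation is alignable")
    return first_result
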