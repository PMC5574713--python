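"""Catalog annotation: one tidy table combining placement normalization,
sequence-context classification, and hybrid complementarity metrics."""

from __future__ import annotations

import pandas as pd

from .context import (
    deletion_repeat_context,
    in_homopolymer_by_context,
    local_run_length,
    normalize_deletion_3prime,
)
from .hybrid import HYBRID_LEN, reconstruct_hybrid
from .records import ContextUnavailableError, IndelRecord


def annotate_catalog(
    records: list[IndelRecord],
    min_run: int = 4,
    hybrid_len: int = HYBRID_LEN,
    normalize: bool = True,
) -> pd.DataFrame:
    """Annotate every record with its repeat/homopolymer context and, for
    deletions, the reconstructed hybrid complementarity.

    Deletions are 3'-normalized first (the observed-data convention), so the
    repeat and hybrid columns describe the right-most equivalent placement.
    """
    rows = []
    for rec in records:
        if rec.kind == "deletion" and normalize:
            rec = normalize_deletion_3prime(rec)
        run_base, run_len = local_run_length(rec)
        row = {
            "source_id": rec.source_id,
            "replicate": rec.replicate,
            "location": rec.location,
            "kind": rec.kind,
            "upstream": rec.upstream,
            "event_seq": rec.event_seq,
            "downstream": rec.downstream,
            "in_homopolymer": in_homopolymer_by_context(rec, min_run),
            "run_base": run_base,
            "run_length": run_len,
            "in_repeat": False,
            "unit_count": 0,
            "slippage_consistent": None,
            "n_match": None,
            "terminal_run": None,
        }
        if rec.kind == "insertion":
            k = len(rec.event_seq)
            row["slippage_consistent"] = (
                len(rec.upstream) >= k and rec.upstream[-k:] == rec.event_seq
            )
        else:
            ctx = deletion_repeat_context(rec)
            row["in_repeat"] = ctx.in_tandem_repeat
            row["unit_count"] = ctx.unit_count
            try:
                h = reconstruct_hybrid(rec, hybrid_len)
                row["n_match"] = h.n_match
                row["terminal_run"] = h.terminal_run
            except ContextUnavailableError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
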