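"""Rates, compositional/positional biases, periodicity, run-length curves,
and complementarity tests for transcription indel catalogs.

Expected counts come from the coverage-weighted simulation null
(:mod:`txslip.nullmodel`) so that placement adjustments (3' normalization)
affect observed and expected identically; a closed-form transcriptome-
composition mode is available for cross-checking. Families of tests are
corrected with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import bisect
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .context import in_homopolymer_by_context, local_run_length
from .hybrid import HYBRID_LEN
from .records import CoverageTable, GenomeAnnotation, IndelRecord

BASES = list("ACGT")
DINUCS = [a + b for a in BASES for b in BASES]


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# rates


@dataclass
class RateTable:
    """Per-replicate indel rates and their cross-replicate means."""

    per_replicate: pd.DataFrame  # columns: replicate, kind, count, denominator, rate

    def mean_rate(self, kind: str) -> float:
        sub = self.per_replicate[self.per_replicate["kind"] == kind]
        return float(sub["rate"].mean()) if len(sub) else float("nan")


def indel_rate(
    records: list[IndelRecord],
    coverage: CoverageTable,
    annotation: GenomeAnnotation,
) -> RateTable:
    """Events per transcribed nucleotide, per replicate and kind.

    The denominator is the depth-weighted sum of coding lengths (the total
    number of transcribed nucleotides sequenced).
    """
    denom = coverage.total_transcribed_nt(annotation)
    if denom <= 0:
        raise ValueError("zero transcribed-nucleotide denominator")
    counts = Counter((r.replicate, r.kind) for r in records)
    reps = sorted({r.replicate for r in records})
    rows = [
        {"replicate": rep, "kind": kind, "count": counts.get((rep, kind), 0),
         "denominator": denom, "rate": counts.get((rep, kind), 0) / denom}
        for rep in reps for kind in ("insertion", "deletion")
    ]
    return RateTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# homopolymer run-length curve


def homopolymer_rate_curve(
    records: list[IndelRecord],
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    min_run: int = 4,
    kind: str = "insertion",
    run_bases: str = "AT",
) -> tuple[pd.DataFrame, dict | None]:
    """Per-run-length indel frequencies and their exponential fit.

    Events are assigned a run length from their own flanking context; the
    frequency for length L is the event count divided by the sequenced
    nucleotides in runs of length L (sum over runs of depth x L). The fit is
    linear least squares of log frequency on run length over the strictly
    positive classes, reported as a.e^{b.L} with r^2 and the regression
    p-value; with fewer than three positive classes the fit is omitted.
    """
    from .context import find_homopolymer_runs

    cov_by_len: Counter = Counter()
    for g in annotation.genes:
        depth = coverage.depths.get(g.gene_id, 0.0)
        for run in find_homopolymer_runs(annotation.transcript_sequence(g), min_run):
            if run.base in run_bases:
                cov_by_len[run.length] += depth * run.length
    count_by_len: Counter = Counter()
    for r in records:
        if r.kind != kind:
            continue
        if not in_homopolymer_by_context(r, min_run):
            continue
        base, length = local_run_length(r)
        if base in run_bases:
            count_by_len[length] += 1
    lengths = sorted(set(cov_by_len) | set(count_by_len))
    table = pd.DataFrame(
        {
            "run_length": lengths,
            "count": [count_by_len.get(L, 0) for L in lengths],
            "coverage": [cov_by_len.get(L, 0.0) for L in lengths],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["frequency"] = np.where(
            table["coverage"] > 0, table["count"] / table["coverage"], np.nan
        )
    pos = table[(table["frequency"] > 0) & np.isfinite(table["frequency"])]
    if len(pos) < 3:
        warnings.warn("fewer than 3 positive run-length classes; fit omitted")
        return table, None
    reg = sps.linregress(pos["run_length"], np.log(pos["frequency"]))
    r2 = float(reg.rvalue**2)
    pval = float(reg.pvalue)
    if math.isnan(r2):  # zero variance in log frequency: perfectly flat curve
        r2, pval = 0.0, 1.0
    fit = {
        "a": float(math.exp(reg.intercept)),
        "b": float(reg.slope),
        "r2": r2,
        "p": pval,
        "n_classes": int(len(pos)),
    }
    return table, fit


# ---------------------------------------------------------------------------
# compositional biases


def transcriptome_composition(
    annotation: GenomeAnnotation, coverage: CoverageTable
) -> dict[str, float]:
    """Coverage-weighted base frequencies of the coding transcriptome."""
    weighted: dict[str, float] = {b: 0.0 for b in BASES}
    total = 0.0
    for g in annotation.genes:
        depth = coverage.depths.get(g.gene_id, 0.0)
        if depth == 0:
            continue
        t = annotation.transcript_sequence(g)
        for b in BASES:
            weighted[b] += depth * t.count(b)
        total += depth * len(t)
    return {b: weighted[b] / total for b in BASES}


def composition_bias_test(
    records: list[IndelRecord],
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
) -> tuple[pd.DataFrame, dict]:
    """Deleted-base composition vs the transcriptome, per base.

    Per replicate, the fraction of deleted nucleotides that are A/C/G/T is
    compared with the coverage-weighted transcriptome composition by a paired
    Wilcoxon signed-rank test across replicates; q-values are BH-corrected
    over the four bases. With a single replicate a per-base binomial test is
    used instead (warned). Also returns a G+C summary.
    """
    dels = [r for r in records if r.kind == "deletion"]
    expected = transcriptome_composition(annotation, coverage)
    reps = sorted({r.replicate for r in dels})
    frac = {b: [] for b in BASES}
    for rep in reps:
        deleted = "".join(r.event_seq for r in dels if r.replicate == rep)
        n = max(1, len(deleted))
        for b in BASES:
            frac[b].append(deleted.count(b) / n)
    rows = []
    for b in BASES:
        obs = np.array(frac[b])
        if len(reps) >= 2:
            diffs = obs - expected[b]
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(diffs).pvalue)
        else:
            warnings.warn("single replicate: falling back to a binomial test")
            deleted = "".join(r.event_seq for r in dels)
            p = float(sps.binomtest(deleted.count(b), len(deleted), expected[b]).pvalue)
        rows.append(
            {"label": b, "observed": float(obs.mean()), "expected": expected[b],
             "p": p,
             "direction": "enriched" if obs.mean() > expected[b] else "depleted"}
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_correct(df["p"])
    deleted_all = "".join(r.event_seq for r in dels)
    gc_by_rep = [frac["G"][i] + frac["C"][i] for i in range(len(reps))]
    summary = {
        "deleted_gc_mean": float(np.mean(gc_by_rep)) if gc_by_rep else float("nan"),
        "deleted_gc_pooled": (
            (deleted_all.count("G") + deleted_all.count("C")) / len(deleted_all)
            if deleted_all else float("nan")
        ),
        "transcriptome_gc": expected["G"] + expected["C"],
        "n_replicates": len(reps),
    }
    return df, summary


def _base_at(record: IndelRecord, pos: int) -> str | None:
    """Base at signed flank position (-1 = last upstream, +1 = first
    downstream); None when the flank is too short."""
    if pos < 0:
        return record.upstream[pos] if len(record.upstream) >= -pos else None
    return record.downstream[pos - 1] if len(record.downstream) >= pos else None


def positional_bias(
    observed: list[IndelRecord],
    expected: list[IndelRecord],
    window: int = 15,
) -> pd.DataFrame:
    """Fisher tests of base composition at each flank position +-1..window.

    For every (position, base) cell, a 2x2 Fisher exact test compares
    observed records carrying that base at that position against the null-
    simulated records; q-values are BH-corrected across all cells. Records
    whose flank does not reach a position are dropped from that position (the
    per-position totals record how many were usable).
    """
    positions = [-(i + 1) for i in range(window)][::-1] + [i + 1 for i in range(window)]
    rows = []
    for pos in positions:
        obs_b = [b for b in (_base_at(r, pos) for r in observed) if b is not None]
        exp_b = [b for b in (_base_at(r, pos) for r in expected) if b is not None]
        n_obs, n_exp = len(obs_b), len(exp_b)
        if n_obs == 0 or n_exp == 0:
            continue
        co, ce = Counter(obs_b), Counter(exp_b)
        for base in BASES:
            table = [[co.get(base, 0), n_obs - co.get(base, 0)],
                     [ce.get(base, 0), n_exp - ce.get(base, 0)]]
            p = float(sps.fisher_exact(table).pvalue)
            rows.append(
                {"position": pos, "label": base,
                 "observed": co.get(base, 0) / n_obs,
                 "expected": ce.get(base, 0) / n_exp,
                 "n_observed": n_obs, "n_expected": n_exp, "p": p,
                 "direction": "enriched"
                 if co.get(base, 0) / n_obs > ce.get(base, 0) / n_exp else "depleted"}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_correct(df["p"])
    return df


def dinucleotide_bias(
    observed: list[IndelRecord],
    expected: list[IndelRecord],
) -> pd.DataFrame:
    """Fisher tests for the 16 dinucleotides immediately preceding events."""
    obs = Counter(r.upstream[-2:] for r in observed if len(r.upstream) >= 2)
    exp = Counter(r.upstream[-2:] for r in expected if len(r.upstream) >= 2)
    n_obs, n_exp = sum(obs.values()), sum(exp.values())
    rows = []
    for d in DINUCS:
        table = [[obs.get(d, 0), n_obs - obs.get(d, 0)],
                 [exp.get(d, 0), n_exp - exp.get(d, 0)]]
        p = float(sps.fisher_exact(table).pvalue)
        rows.append(
            {"label": d, "observed": obs.get(d, 0) / n_obs if n_obs else np.nan,
             "expected": exp.get(d, 0) / n_exp if n_exp else np.nan, "p": p,
             "direction": "enriched"
             if n_obs and n_exp and obs.get(d, 0) / n_obs > exp.get(d, 0) / n_exp
             else "depleted"}
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_correct(df["p"])
    return df


def periodicity_test(
    observed: list[IndelRecord],
    expected: list[IndelRecord],
    max_len: int = 6,
) -> dict:
    """Enrichment of in-frame (length 3 or 6) short deletions.

    2x2 Fisher exact on deletions of length <= max_len: counts at lengths
    {3, 6} vs the other short lengths, observed vs null-simulated. Reported
    one-sided (enrichment of multiples of three) and two-sided.
    """
    def split(recs):
        short = [len(r.event_seq) for r in recs
                 if r.kind == "deletion" and len(r.event_seq) <= max_len]
        return sum(1 for L in short if L % 3 == 0), sum(1 for L in short if L % 3 != 0)

    o3, orest = split(observed)
    e3, erest = split(expected)
    if o3 + orest == 0:
        return {"p_one_sided": float("nan"), "p_two_sided": float("nan"),
                "table": [[0, 0], [e3, erest]], "note": "no short deletions"}
    table = [[o3, orest], [e3, erest]]
    return {
        "p_one_sided": float(sps.fisher_exact(table, alternative="greater").pvalue),
        "p_two_sided": float(sps.fisher_exact(table).pvalue),
        "table": table,
    }


# ---------------------------------------------------------------------------
# complementarity


def _pool_tail(observed: np.ndarray, expected: np.ndarray, min_expected: float = 1.0):
    """Merge histogram cells inward from both ends until every expected count
    reaches min_expected. Returns (obs, exp, labels)."""
    obs = [int(x) for x in observed]
    exp = [float(x) for x in expected]
    labels = [[i] for i in range(len(obs))]
    # high tail inward
    while len(exp) > 1 and exp[-1] < min_expected:
        e, o, l = exp.pop(), obs.pop(), labels.pop()
        exp[-1] += e
        obs[-1] += o
        labels[-1].extend(l)
    while len(exp) > 1 and exp[0] < min_expected:
        e, o, l = exp.pop(0), obs.pop(0), labels.pop(0)
        exp[0] += e
        obs[0] += o
        labels[0] = l + labels[0]
    return np.array(obs), np.array(exp), labels


def complementarity_chisq(
    observed_hist,
    expected_hist,
    hybrid_len: int = HYBRID_LEN,
) -> dict:
    """Chi-square comparison of observed vs expected hybrid complementarity.

    The expected histogram (null-model mean) is rescaled to the observed
    total; low-expectation cells are pooled inward from the tails until every
    expected count is >= 1 (the pooling is reported). Per-cell Fisher exact
    follow-ups with BH correction localize which complementarity levels
    deviate.
    """
    obs = np.asarray(observed_hist, dtype=float)
    exp = np.asarray(expected_hist, dtype=float)
    if obs.shape != (hybrid_len + 1,) or exp.shape != (hybrid_len + 1,):
        raise ValueError(f"histograms must cover 0..{hybrid_len}")
    if exp.sum() <= 0:
        raise ValueError("expected histogram is all zero")
    exp_scaled = exp * obs.sum() / exp.sum()
    obs_p, exp_p, pooled = _pool_tail(obs.astype(int), exp_scaled)
    chi, p = sps.chisquare(obs_p, exp_p)
    n_obs, n_exp = int(obs.sum()), exp.sum()
    cells = []
    exp_int = np.maximum(np.rint(exp_scaled).astype(int), 0)
    for i in range(hybrid_len + 1):
        table = [[int(obs[i]), n_obs - int(obs[i])],
                 [int(exp_int[i]), int(exp_int.sum()) - int(exp_int[i])]]
        cells.append({"label": i, "observed": int(obs[i]),
                      "expected": float(exp_scaled[i]),
                      "p": float(sps.fisher_exact(table).pvalue)})
    per_cell = pd.DataFrame(cells)
    per_cell["q"] = bh_correct(per_cell["p"])
    return {
        "statistic": float(chi), "df": int(len(obs_p) - 1), "p": float(p),
        "pooled_cells": pooled, "per_cell": per_cell,
    }


# ---------------------------------------------------------------------------
# coverage binning


def coverage_bin_edges() -> list[float]:
    """Bin edges: 1x steps to 10, 10x steps to 100, 100x steps to 500, then
    500-1000, 1000-2000, >2000 (26 bins)."""
    edges = [float(x) for x in range(0, 11)]
    edges += [float(x) for x in range(20, 101, 10)]
    edges += [float(x) for x in range(200, 501, 100)]
    edges += [1000.0, 2000.0, float("inf")]
    return edges


def assign_gene(annotation: GenomeAnnotation, record: IndelRecord):
    """Gene whose interval contains the record's genomic location."""
    pos0 = record.location - 1
    for g in annotation.genes:
        if g.start <= pos0 < g.end:
            return g
    return None


def bin_by_coverage(
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    records: list[IndelRecord],
) -> pd.DataFrame:
    """Per-coverage-bin event counts, total sequenced nucleotides, and rate."""
    edges = coverage_bin_edges()
    n_bins = len(edges) - 1
    cov_tot = np.zeros(n_bins)
    events = np.zeros(n_bins, dtype=int)
    gene_bin: dict[str, int] = {}
    for g in annotation.genes:
        depth = coverage.depths.get(g.gene_id, 0.0)
        if depth < 0:
            raise ValueError(f"negative depth for {g.gene_id}")
        b = bisect.bisect_right(edges, depth) - 1
        b = min(b, n_bins - 1)
        gene_bin[g.gene_id] = b
        cov_tot[b] += depth * g.length
    for r in records:
        g = assign_gene(annotation, r)
        if g is not None:
            events[gene_bin[g.gene_id]] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(cov_tot > 0, events / cov_tot, np.nan)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "events": events,
         "coverage": cov_tot, "rate": rate}
    )
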