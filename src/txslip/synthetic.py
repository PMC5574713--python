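"""Synthetic genomes, slippage events, and circularized-fragment reads.

The generator implements the slippage model the analysis is designed to
detect, so the whole pipeline can be exercised end to end with known ground
truth:

* genomes are i.i.d. base draws at a tunable G+C (an equitable ~0.53 genome
  and an A+T-rich ~0.26 endosymbiont-like genome are the two study
  conditions), tiled with protein-coding genes carrying long-tailed
  expression depths;
* insertions arise by backward slippage: sites concentrate on A/T
  homopolymeric runs with weight proportional to e^{b.L} in the run length L
  (run base re-transcribed), plus a minority of duplications of the 1-3
  preceding bases outside runs;
* deletions arise by forward slippage: a start site is drawn
  coverage-weighted, a slip distance is drawn from a truncated geometric
  distribution, and the candidate stop site is accepted with probability
  proportional to e^{gamma.n_match}, where n_match is the complementarity of
  the reconstructed 9-nt RNA:DNA hybrid at the new template location;
  candidates failing the gate correspond to aborted transcripts and emit no
  event;
* reads are tandem repeats of an 80-100 nt mRNA fragment (circularized,
  randomly primed, hence rotated), >=3 full copies per 300-nt read, with
  per-base qualities and independent per-copy sequencing errors.

Everything is driven by one numpy Generator, so a fixed seed reproduces the
whole chain bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import RepeatRead
from .context import find_homopolymer_runs
from .extract import extract_deletion_record, extract_insertion_record, transcript_window
from .records import CoverageTable, Gene, GenomeAnnotation, IndelRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SlippageSimParams:
    """Generative-model parameters; defaults emulate the equitable-G+C study
    condition."""

    gc_content: float = 0.53
    n_genes: int = 40
    mean_gene_length: int = 900
    sd_gene_length: int = 200
    min_gene_length: int = 300
    spacer_length: int = 120
    depth_lognorm_mean: float = 3.0
    depth_lognorm_sigma: float = 1.0
    # insertions: site weight on an A/T run of length L is depth * e^{b.L}
    insertion_run_exponent: float = 0.8
    min_insertion_run: int = 4
    insertion_nonrun_fraction: float = 0.0
    # deletions: forward-slip distance ~ 1 + Geometric, truncated
    deletion_distance_p: float = 0.25
    max_deletion_length: int = 20
    gamma: float = 2.0
    t_min: int = 0
    hybrid_len: int = 9
    # reads
    fragment_len_range: tuple[int, int] = (80, 100)
    read_length: int = 300
    seq_error_rate: float = 0.0  # per-base substitution rate
    seq_indel_error_rate: float = 0.0  # per-base 1-nt insertion/deletion rate
    base_quality: int = 40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        lo, hi = self.fragment_len_range
        if not (60 <= lo <= hi <= 120):
            raise ValueError("fragment_len_range must lie within [60,120]")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One planted slippage event with its mechanism label."""

    gene_id: str
    kind: str
    position: int  # transcript offset of the first affected base
    event_seq: str
    mechanism: str  # backward_homopolymer | backward_repeat | forward_slip
    n_match: int | None
    record: IndelRecord


@dataclass
class ReadTruth:
    """Provenance of one synthetic read: which event (if any) it carries and
    the reference window it should be called against."""

    read_index: int
    gene_id: str
    event_index: int  # index into the event list, -1 for background
    fragment_len: int
    rotation: int
    window: str  # transcript-sense reference window around the fragment
    frag_in_window: int  # offset of the fragment start within the window
    frag_t0: int = 0  # transcript offset of the fragment start


def generate_genome(
    params: SlippageSimParams, rng: np.random.Generator | None = None
) -> tuple[GenomeAnnotation, CoverageTable]:
    """Random genome with tiled genes and long-tailed per-gene depths."""
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    p = np.array(
        [(1 - params.gc_content) / 2, params.gc_content / 2,
         params.gc_content / 2, (1 - params.gc_content) / 2]
    )
    lengths = np.maximum(
        params.min_gene_length,
        (rng.normal(params.mean_gene_length, params.sd_gene_length, params.n_genes)
         // 3).astype(int) * 3,
    )
    genes: list[Gene] = []
    pos = params.spacer_length
    for i, ln in enumerate(lengths):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{i:04d}", "chr1", pos, pos + int(ln), strand))
        pos += int(ln) + params.spacer_length
    seq = "".join(rng.choice(_BASES, size=pos, p=p))
    ann = GenomeAnnotation(sequences={"chr1": seq}, genes=genes)
    ann.validate()
    depths = rng.lognormal(params.depth_lognorm_mean, params.depth_lognorm_sigma,
                           params.n_genes)
    cov = CoverageTable({g.gene_id: float(d) for g, d in zip(genes, depths)})
    return ann, cov


# ---------------------------------------------------------------------------
# event simulation


def _encoded_transcripts(
    annotation: GenomeAnnotation, margin: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All gene transcripts (with genomic margin on both sides) packed into one
    byte array; returns (array, per-gene offset of transcript position 0,
    per-gene transcript length)."""
    chunks, offsets, lens = [], [], []
    pos = 0
    for g in annotation.genes:
        ext = transcript_window(annotation, g, -margin, g.length + margin)
        chunks.append(np.frombuffer(ext.encode(), dtype=np.uint8))
        offsets.append(pos + margin)
        lens.append(g.length)
        pos += len(ext)
    return np.concatenate(chunks), np.array(offsets), np.array(lens)


def simulate_insertions(
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    params: SlippageSimParams,
    n_events: int,
    rng: np.random.Generator,
    replicate: str = "1",
) -> list[GroundTruthEvent]:
    """Backward-slippage insertions, mostly on A/T homopolymeric runs."""
    runs = []  # (gene, run) with A/T base only
    weights = []
    b = params.insertion_run_exponent
    for g in annotation.genes:
        tseq = annotation.transcript_sequence(g)
        for run in find_homopolymer_runs(tseq, params.min_insertion_run, g.gene_id):
            if run.base in "AT":
                runs.append((g, run))
                # per covered nucleotide of a run the slip rate grows as
                # e^{b.L}, so a whole run of length L carries weight L.e^{b.L}
                weights.append(
                    coverage.depths.get(g.gene_id, 0.0) * run.length
                    * np.exp(b * run.length)
                )
    n_nonrun = int(round(n_events * params.insertion_nonrun_fraction))
    n_run = n_events - n_nonrun
    events: list[GroundTruthEvent] = []
    if n_run:
        if not runs:
            raise ValueError("no A/T homopolymeric runs available for insertions")
        w = np.asarray(weights)
        idx = rng.choice(len(runs), size=n_run, p=w / w.sum())
        for i in idx:
            g, run = runs[i]
            t = run.end  # insertion point immediately 3' of the run
            rec = extract_insertion_record(annotation, g, t, run.base,
                                           replicate=replicate)
            events.append(GroundTruthEvent(g.gene_id, "insertion", t, run.base,
                                           "backward_homopolymer", None, rec))
    # non-run insertions: duplication of the 1-3 preceding bases
    depths = np.array([coverage.depths.get(g.gene_id, 0.0) for g in annotation.genes])
    for _ in range(n_nonrun):
        gi = rng.choice(len(annotation.genes), p=depths / depths.sum())
        g = annotation.genes[gi]
        k = rng.choice([1, 2, 3], p=[0.6, 0.2, 0.2])
        t = int(rng.integers(k + 1, g.length - 1))
        ins = transcript_window(annotation, g, t - k, t)
        rec = extract_insertion_record(annotation, g, t, ins, replicate=replicate)
        events.append(GroundTruthEvent(g.gene_id, "insertion", t, ins,
                                       "backward_repeat", None, rec))
    return events


def simulate_deletions(
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    params: SlippageSimParams,
    n_events: int,
    rng: np.random.Generator,
    replicate: str = "1",
    pool_size: int | None = None,
) -> tuple[list[GroundTruthEvent], int]:
    """Forward-slippage deletions gated by hybrid complementarity.

    Candidate (start, distance) pairs are drawn coverage-weighted/uniform/
    geometric, their stop-site complementarity n_match is computed, and events
    are emitted in proportion to e^{gamma.n_match} (t_min filters stop sites
    with too little terminal pairing). Returns (events, n_aborted) where
    n_aborted counts candidates that failed the gate.
    """
    h = params.hybrid_len
    pool = pool_size if pool_size is not None else max(200 * n_events, 20_000)
    big, offsets, lens = _encoded_transcripts(annotation, margin=h + 21)
    depths = np.array([coverage.depths.get(g.gene_id, 0.0) for g in annotation.genes])
    usable = lens >= params.max_deletion_length + 2
    w = depths * usable
    gi = rng.choice(len(lens), size=pool, p=w / w.sum())
    d = 1 + rng.geometric(params.deletion_distance_p, size=pool)
    d = np.minimum(d, params.max_deletion_length)
    t = (rng.random(pool) * (lens[gi] - d)).astype(int)
    start = offsets[gi] + t
    idx_pre = start[:, None] + np.arange(-h, 0)
    idx_post = (start + d)[:, None] + np.arange(-h, 0)
    match = big[idx_pre] == big[idx_post]
    n_match = match.sum(axis=1)
    terminal = match[:, ::-1].cumprod(axis=1).sum(axis=1)
    weight = np.exp(params.gamma * (n_match.astype(float) - h))
    weight[terminal < params.t_min] = 0.0
    positive = weight > 0
    if positive.sum() == 0:
        raise ValueError("no candidate stop site satisfies the gating rule")
    p_sel = weight / weight.sum()
    replace = positive.sum() < n_events
    chosen = rng.choice(pool, size=n_events, replace=replace, p=p_sel)
    n_aborted = pool - n_events
    events = []
    for c in chosen:
        g = annotation.genes[gi[c]]
        rec = extract_deletion_record(annotation, g, int(t[c]), int(d[c]),
                                      replicate=replicate)
        events.append(GroundTruthEvent(g.gene_id, "deletion", int(t[c]),
                                       rec.event_seq, "forward_slip",
                                       int(n_match[c]), rec))
    return events, n_aborted


def simulate_slippage_events(
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    params: SlippageSimParams,
    n_insertions: int,
    n_deletions: int,
    rng: np.random.Generator | None = None,
    replicate: str = "1",
) -> list[GroundTruthEvent]:
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    events = simulate_insertions(annotation, coverage, params, n_insertions, rng,
                                 replicate) if n_insertions else []
    if n_deletions:
        dels, _ = simulate_deletions(annotation, coverage, params, n_deletions, rng,
                                     replicate)
        events.extend(dels)
    return events


# ---------------------------------------------------------------------------
# circularized-fragment reads


def _mutant_fragment(
    annotation: GenomeAnnotation, gene: Gene, event: GroundTruthEvent | None,
    f0: int, frag_len: int,
) -> str:
    """Transcript fragment [f0, f0+frag_len) of the (possibly mutant) mRNA."""
    if event is None:
        return transcript_window(annotation, gene, f0, f0 + frag_len)
    t = event.position
    if event.kind == "deletion":
        d = len(event.event_seq)
        left = transcript_window(annotation, gene, f0, t)
        right = transcript_window(annotation, gene, t + d, t + d + frag_len)
        return (left + right)[:frag_len]
    left = transcript_window(annotation, gene, f0, t)
    right = transcript_window(annotation, gene, t, t + frag_len)
    return (left + event.event_seq + right)[:frag_len]


def _ambiguity_span(
    annotation: GenomeAnnotation, gene: Gene, event: GroundTruthEvent
) -> tuple[int, int]:
    """How far the event's placement can slide left/right through equivalent
    representations (repeat/run ambiguity), in transcript bases."""
    t = event.position
    s = event.event_seq
    ctx = transcript_window(annotation, gene, t - 40, t + 40)
    anchor = 40
    if event.kind == "deletion":
        left = 0
        while anchor - left > 0 and ctx[anchor - left - 1] == ctx[anchor - left - 1 + len(s)]:
            left += 1
        right = 0
        while anchor + right + len(s) < len(ctx) and ctx[anchor + right] == ctx[anchor + right + len(s)]:
            right += 1
        return left, right
    cur, p, left = s, anchor, 0
    while p > 0 and ctx[p - 1] == cur[-1]:
        cur = cur[-1] + cur[:-1]
        p -= 1
        left += 1
    cur, p, right = s, anchor, 0
    while p < len(ctx) and ctx[p] == cur[0]:
        cur = cur[1:] + cur[0]
        p += 1
        right += 1
    return left, right


def emit_circular_reads(
    annotation: GenomeAnnotation,
    coverage: CoverageTable,
    events: list[GroundTruthEvent],
    params: SlippageSimParams,
    n_background: int = 0,
    reads_per_event: int = 1,
    rng: np.random.Generator | None = None,
    window_margin: int = 40,
    flank_margin: int = 8,
) -> tuple[list[RepeatRead], list[ReadTruth]]:
    """Tandem-repeat reads from mutant and wild-type mRNA fragments.

    Event-bearing fragments place the event at least ``flank_margin`` bases
    from both fragment ends, and the circularization rotation is drawn so the
    event stays intact within each repeat copy (a rotation through the event
    splits it across the repeat junction; such reads are unusable for calling
    and are not emitted). Sequencing errors are substitutions applied
    independently to every base of the read.
    """
    rng = np.random.default_rng(params.rng_seed + 1) if rng is None else rng
    lo, hi = params.fragment_len_range
    reads: list[RepeatRead] = []
    truths: list[ReadTruth] = []
    genes = {g.gene_id: g for g in annotation.genes}
    depths = np.array([coverage.depths.get(g.gene_id, 0.0) for g in annotation.genes])

    def _emit(gene: Gene, event: GroundTruthEvent | None, event_index: int) -> None:
        frag_len = int(rng.integers(lo, hi + 1))
        if event is None:
            f0 = int(rng.integers(0, max(1, gene.length - frag_len)))
            rotation = int(rng.integers(0, frag_len))
        else:
            ev_width = len(event.event_seq) if event.kind == "insertion" else 0
            amb_l, amb_r = _ambiguity_span(annotation, gene, event)
            # The whole equivalence interval of the event needs flank margin,
            # and a deletion additionally needs enough non-repetitive sequence
            # on both sides that the gapped alignment outscores a gap-free
            # mismatch-only representation (a quasi-repeat deletion with a
            # short tail is invisible to any aligner).
            guard = 16 if event.kind == "deletion" else 0
            a_min = flank_margin + amb_l + guard
            a_max = frag_len - ev_width - flank_margin - amb_r - guard
            if a_min > a_max:
                raise ValueError("fragment too short for event plus flanks")
            a = int(rng.integers(a_min, a_max + 1))
            f0 = event.position - a
            allowed = [
                r for r in range(frag_len)
                if not (a - amb_l - flank_margin < r
                        < a + ev_width + amb_r + flank_margin)
            ]
            rotation = int(rng.choice(allowed))
        frag = _mutant_fragment(annotation, gene, event, f0, frag_len)
        n_copies = params.read_length // frag_len + 2
        tandem = (frag[rotation:] + frag[:rotation]) * n_copies
        bases = list(tandem)
        if params.seq_error_rate > 0:
            err = rng.random(len(bases)) < params.seq_error_rate
            for i in np.flatnonzero(err):
                bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
        if params.seq_indel_error_rate > 0:
            # sequencer indels shift everything downstream of the error, so a
            # single-copy indel appears at discordant positions across copies
            err = rng.random(len(bases)) < params.seq_indel_error_rate
            for i in sorted(np.flatnonzero(err), reverse=True):
                if rng.random() < 0.5:
                    bases.insert(i, str(rng.choice(list("ACGT"))))
                else:
                    del bases[i]
        bases = bases[: params.read_length]
        quals = np.full(len(bases), params.base_quality, dtype=int)
        d = len(event.event_seq) if event is not None and event.kind == "deletion" else 0
        window = transcript_window(annotation, gene, f0 - window_margin,
                                   f0 + frag_len + d + window_margin)
        reads.append(RepeatRead("".join(bases), quals, true_fragment_len=frag_len))
        truths.append(ReadTruth(len(reads) - 1, gene.gene_id, event_index,
                                frag_len, rotation, window, window_margin, f0))

    for ei, ev in enumerate(events):
        for _ in range(reads_per_event):
            _emit(genes[ev.gene_id], ev, ei)
    for _ in range(n_background):
        gi = rng.choice(len(annotation.genes), p=depths / depths.sum())
        _emit(annotation.genes[gi], None, -1)
    return reads, truths


def write_fastq(reads: list[RepeatRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@read{i}\n{r.bases}\n+\n{qual}\n")


def events_to_catalog(events: list[GroundTruthEvent]) -> list[IndelRecord]:
    return [e.record for e in events]


def parameter_recovery_suite(
    params: SlippageSimParams,
    n_insertions: int = 8000,
    n_deletions: int = 500,
    planted_rate: float = 2e-5,
    b_tolerance: float = 0.25,
    alpha: float = 0.01,
) -> dict:
    """End-to-end consistency check of the generator against the estimators.

    Runs generate -> simulate -> annotate -> stats and verifies that (i) the
    run-length exponent b is recovered by the homopolymer rate curve within
    ``b_tolerance``, (ii) complementarity enrichment is detected (chi-square
    p < alpha) exactly when the gating strength gamma > 0, and (iii) an indel
    count planted at ``planted_rate`` per transcribed nucleotide is estimated
    within three binomial standard deviations. Returns a report dict with an
    overall ``passed`` flag.
    """
    from . import nullmodel, stats  # local import: stats sits above synthetic

    rng = np.random.default_rng(params.rng_seed)
    ann, cov = generate_genome(params, rng)
    report: dict = {"checks": {}}

    # (i) run-length exponent recovery
    ins = simulate_insertions(ann, cov, params, n_insertions, rng)
    _, fit = stats.homopolymer_rate_curve(
        events_to_catalog(ins), ann, cov, min_run=params.min_insertion_run
    )
    b_true = params.insertion_run_exponent
    b_ok = fit is not None and abs(fit["b"] - b_true) <= b_tolerance * abs(b_true)
    report["checks"]["run_length_exponent"] = {
        "true": b_true, "estimated": fit["b"] if fit else None, "passed": bool(b_ok),
    }

    # (ii) complementarity enrichment iff gamma > 0
    from .context import normalize_deletion_3prime
    from .hybrid import complementarity_histogram

    dels, _ = simulate_deletions(ann, cov, params, n_deletions, rng)
    obs_cat = [normalize_deletion_3prime(r) for r in events_to_catalog(dels)]
    cfg = nullmodel.SimulationConfig(
        annotation=ann, coverage=cov,
        lengths_by_replicate=nullmodel.lengths_from_catalog(obs_cat),
        n_replicates=20, rng_seed=int(rng.integers(2**31)),
    )
    null_cats = nullmodel.simulate_expected_deletions(cfg)
    exp_hist = np.mean([complementarity_histogram(c) for c in null_cats], axis=0)
    chisq = stats.complementarity_chisq(complementarity_histogram(obs_cat), exp_hist)
    significant = chisq["p"] < alpha
    comp_ok = significant == (params.gamma > 0)
    report["checks"]["complementarity_gating"] = {
        "gamma": params.gamma, "p": chisq["p"], "significant": bool(significant),
        "passed": bool(comp_ok),
    }

    # (iii) planted indel rate recovered within 3 binomial sigma
    total_nt = cov.total_transcribed_nt(ann)
    n_plant = int(rng.poisson(planted_rate * total_nt))
    n_plant = max(n_plant, 1)
    plant_params = SlippageSimParams(**{**params.__dict__, "gamma": 0.0})
    planted, _ = simulate_deletions(ann, cov, plant_params, n_plant, rng)
    rate_tab = stats.indel_rate(events_to_catalog(planted), cov, ann)
    est = rate_tab.mean_rate("deletion")
    sigma = np.sqrt(planted_rate / total_nt)
    rate_ok = abs(est - planted_rate) <= 3 * sigma
    report["checks"]["planted_rate"] = {
        "true": planted_rate, "estimated": float(est), "sigma": float(sigma),
        "passed": bool(rate_ok),
    }
    report["passed"] = all(c["passed"] for c in report["checks"].values())
    return report
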