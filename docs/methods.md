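# Methods

## The slippage model

During elongation, the last ~9 nucleotides of the nascent transcript pair
with the template strand as an RNA:DNA hybrid inside the polymerase. When
transcript and template lose register, the complex can slip backward
(retranscribing template, producing an insertion) or forward (skipping
template, producing a deletion). The analysis rests on a single
reconstruction: after a forward slip of *d* bases, the transcript 3′ end is
the nine mRNA-sense bases preceding the deletion start, and the new template
region is the nine bases preceding the deletion end. Because both windows
are taken on the sense strand, positional identity between them is
equivalent to complementary transcript:template pairing, so the number of
matching positions (`n_match`, 0–9) counts complementary base pairs in the
reconstructed hybrid, and the length of the suffix of consecutive matches
(`terminal_run`) measures pairing at the catalytically critical 3′ end. For
deletions shorter than nine bases the two windows overlap; that is a
property of the reconstruction, not an artifact, and is kept.

## Conventions

Coordinates are 0-based half-open in memory and 1-based inclusive in files.
Catalog sequences are mRNA-sense DNA (U mapped to T on load); reverse-strand
genes are reverse-complemented when events are extracted from the genome,
never at catalog load. Deletions in repetitive sequence admit several
equivalent placements; all are resolved to the unique right-most (3′-most)
placement before any context or hybrid computation, and the same
normalization is applied to simulated deletions so placement artifacts
cancel in every observed-vs-expected comparison. The normalization may
inflate apparent 3′ terminal complementarity; treating observed and
simulated catalogs identically is the control for this, and
`annotate_catalog(..., normalize=False)` exposes the un-normalized variant.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `q_threshold` | 20 | minimum Phred quality for inserted bases / deletion flanks, per repeat copy |
| `min_flank` | 5 | exactly matching bases required on each side of an indel in every repeat copy ("fully aligned" flank; configurable, not externally prescribed) |
| `min_run` | 4 | minimum homopolymer run length counted as a run |
| hybrid length | 9 | RNA:DNA hybrid length in the elongation complex (config knob) |
| `n_replicates` | 100 | simulation replicates in the null model |
| repeat units | ≥ 2 | minimum copies for a sequence to count as a tandem repeat |

## Consensus calling from tandem-repeat reads

Each read holds ≥3 copies of a circularized 80–100 nt fragment, rotated by
random priming. Per-copy alignment to the reference window uses Biopython's
`PairwiseAligner` (match +1, mismatch −1, gap open −3, extend −0.5, free
end gaps on the reference side): affine gap costs keep a multi-base indel
contiguous, where a unit-cost edit distance splits it into equal-cost
fragments. The rotation is found by brute force: every cyclic offset is
scored by majority-collapsing the copies and aligning the collapsed fragment
with the same scoring scheme. Two subtleties required explicit design:

- a rotation that cuts through an indel can outscore the true register
  (the junction hides the gap), so rotations within one maximal-indel score
  slack (36) of the best are examined from the top down and the
  highest-scoring rotation yielding an accepted indel wins;
- on an indel-free read every copy is identical, so any alignment artifact
  would be concordant across copies; an indel-free register that strictly
  outscores all remaining rotations therefore preempts acceptance.

Acceptance then requires identical kind, position, size, and sequence in
every copy, ≥ `min_flank` exact matches on both sides, and the quality
rules above; rejections carry `discordant_sequence`, `discordant_size`,
`discordant_position`, `absent_in_repeat`, `low_quality`, or `not_flanked`.
A deletion of a near-perfect repeat unit that sits too close to a fragment
end is genuinely invisible to any aligner (a mismatch-only alignment
outscores the gapped one); the read generator therefore leaves a 16-base
non-repetitive guard on both sides of planted deletions, and this bound on
detectability is a known limitation for real data as well.

## Null model

Expected deletions are sampled by exact cumulative-weight inversion over
per-gene mean depths (genes with zero depth excluded), uniform position
within the coding region, and a random permutation of each replicate's
observed length multiset — each observed length used exactly once per
simulated replicate, so the simulated length spectrum is conserved exactly.
Events whose 9–15-base upstream window would leave the gene are extended
from the surrounding genome rather than discarded (discarding would bias
against short genes). Replicate *r* of a run seeds its own
`numpy.random.Generator` with the sequence `(seed, r)`, so catalogs are
bit-reproducible and replicates are independent streams.

## Statistics

- Rates divide event counts by the depth-weighted sum of coding lengths
  (total transcribed nucleotides) per replicate and average across
  replicates.
- Run-length curves normalize per-length event counts by the sequenced
  nucleotides in runs of that length and fit log-frequency on length by
  least squares over strictly positive classes (reported as a·e^{b·L} with
  r² and regression p; omitted below three classes; a perfectly flat curve
  reports r² = 0).
- Composition uses a paired Wilcoxon signed-rank across replicates against
  the coverage-weighted transcriptome composition (binomial fallback with a
  warning for a single replicate), BH-corrected over the four bases.
- Positional (±15) and dinucleotide (16-cell) biases use two-sided Fisher
  exact tests of observed vs null-simulated counts, BH-corrected across the
  family. The expected side defaults to the simulation null rather than
  closed-form transcriptome frequencies — the simulation inherits the 3′
  normalization — but the closed-form route is available for cross-checks
  (the null's dinucleotide expectations agree with coverage-weighted
  transcriptome content within Monte-Carlo error).
- Periodicity: one-sided (and two-sided) Fisher exact on in-frame {3,6}
  versus other lengths among deletions ≤ 6 nt, observed vs null.
- Complementarity: chi-square of the observed `n_match` histogram against
  the null mean scaled to the observed total, pooling cells inward from both
  tails until every expected count is ≥ 1 (pooling reported), with
  per-cell Fisher follow-ups under BH. The expected histogram must come
  from enough simulation replicates that its Monte-Carlo noise is
  negligible — with few replicates the chi-square anticonservatively treats
  a noisy expectation as exact (the calibration tests use ≥ 20).
- Coverage bins follow the fixed 26-bin scheme: 1× steps to 10, 10× steps
  to 100, 100× steps to 500, then 500–1000, 1000–2000, > 2000.

## Synthetic data generator

The generator emulates the two study conditions: an equitable genome
(G+C 0.53) and an A+T-rich one (G+C 0.26), with i.i.d. bases, genes tiled on
both strands (lengths ~N(900, 200²) rounded to codons, minimum 300), and
log-normal per-gene depths (μ=3, σ=1 on the log scale) giving a long-tailed
expression distribution. Insertions arise on A/T homopolymeric runs with
per-run weight depth·L·e^{b·L} (so the rate *per covered run nucleotide*
grows as e^{b·L}, the quantity the rate curve measures; b defaults to 0.8),
inserting the run base 3′ of the run; an optional fraction instead
duplicates the 1–3 preceding bases outside runs. Deletions draw a
coverage-weighted start, a truncated-geometric slip distance (p=0.25,
max 20), and are emitted with probability proportional to
e^{γ·(n_match−9)} over a large candidate pool (γ defaults to 2; γ=0 turns
the gate off and reproduces the unconditional candidate distribution);
candidates failing the gate are counted as aborted transcripts and emit
nothing, matching the observational reality that only completed transcripts
are sequenced. The exponential form of the gate is this package's choice of
a one-parameter monotone link; upstream elongation-complex pushing is not
modeled mechanistically — the slip-distance distribution stands in for it.

Reads copy an 80–100 nt fragment of the (possibly mutant) transcript ≥3
times into a 300-nt read with per-base qualities, a random circular
rotation, and independent per-base substitution and 1-nt indel errors.
Event-bearing fragments keep the event's whole equivalence interval at
least 8 bases from both fragment ends (plus the 16-base guard for
deletions) and draw rotations that do not split the event across the repeat
junction — rotations that would are exactly the reads a real pipeline loses
as unflankable.

What the generator does not emulate: realistic Illumina error profiles and
quality distributions, RNA secondary structure, transcription of
non-coding regions, operon structure, and any true biological abort/pause
kinetics. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated generative model, not the
biological accuracy of that model on real libraries.

## Problem sizes used in the test suite

Property suites run 10⁴ random cases against brute-force oracles; the
null-model goodness-of-fit uses 10⁵ events over a 40-gene genome;
statistical calibration runs 1000 seeds of small (64-deletion,
8-replicate) catalogs against a 30-replicate pooled null; power checks use
50 seeds at 500 deletions with a 20-replicate null; the consensus-caller
guarantees use ~10³ error-free reads with full rotation search and 10⁴
noisy reads at known register. These sizes were chosen as the smallest at
which the binomial/Monte-Carlo error bands in the assertions are
meaningful.

## Known limitations

- The rotation + affine-alignment caller stands in for the original
  aligner-based pipeline; score functions differ, so per-read agreement
  with that pipeline is not expected, only the filtering semantics.
- Quasi-repeat deletions near fragment ends are undetectable (see above).
- Fisher tests build their 2×2 tables against integer null counts pooled
  over simulation replicates; with very small nulls the tests are
  conservative.
- The catalogs' genomic locations for reverse-strand genes are preserved
  verbatim from file; anchoring conventions across strands are the
  caller's responsibility when mapping events back to a genome.
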