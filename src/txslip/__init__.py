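"""txslip — genome-wide spectra of transcription insertions and deletions.

Tools for calling indels from circularized-fragment (tandem-repeat) RNA-seq
reads, normalizing and classifying them by sequence context, reconstructing
the post-slippage RNA:DNA hybrid, building a coverage-weighted simulation
null, and testing the compositional and complementarity biases that
characterize RNA polymerase slippage — together with a synthetic slippage
generator so every stage runs on data with known ground truth.
"""

from importlib import resources

from .consensus import (
    CandidateIndel,
    RepeatRead,
    call_indels,
    call_read,
    estimate_fragment_length,
    find_best_rotation,
    split_into_repeats,
)
from .context import (
    HomopolymerRun,
    RepeatContext,
    classify_insertion,
    deletion_repeat_context,
    find_homopolymer_runs,
    in_homopolymer_by_context,
    locate_in_homopolymer,
    normalize_deletion_3prime,
)
from .hybrid import (
    HybridReconstruction,
    complementarity_histogram,
    reconstruct_hybrid,
    terminal_complementarity_counts,
    terminal_complementarity_fractions,
)
from .io_catalog import (
    read_annotation,
    read_coverage,
    read_genome,
    read_indel_catalog,
    write_annotation,
    write_coverage,
    write_genome,
    write_indel_catalog,
)
from .nullmodel import (
    SimulationConfig,
    expected_context_distributions,
    lengths_from_catalog,
    simulate_expected_deletions,
)
from .records import (
    CatalogError,
    ContextUnavailableError,
    CoverageTable,
    Gene,
    GenomeAnnotation,
    IndelRecord,
    revcomp,
)
from .stats import (
    RateTable,
    bh_correct,
    bin_by_coverage,
    complementarity_chisq,
    composition_bias_test,
    dinucleotide_bias,
    homopolymer_rate_curve,
    indel_rate,
    periodicity_test,
    positional_bias,
)
from .synthetic import (
    GroundTruthEvent,
    SlippageSimParams,
    emit_circular_reads,
    events_to_catalog,
    generate_genome,
    simulate_slippage_events,
)

__version__ = "0.1.0"


def load_table1_fixture():
    """The bundled 19-row catalog of non-homopolymeric insertions used as the
    package's worked example (the first row carries its extended 11-base
    upstream context)."""
    path = resources.files("txslip").joinpath("data/table1_insertions.tsv")
    with resources.as_file(path) as p:
        return read_indel_catalog(p, format="tsv")
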