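"""equimsy: sequence-class, gametolog-evolution and block-diagnostic analyses
for male-specific Y (MSY) assemblies, with a synthetic data generator.

The package mirrors the analytical core of an equid MSY study: self-identity
dot-plot scanning and sequence-class delineation, Li/Pamilo-Bianchi Ka/Ks
with evolutionary-strata segmentation, a Sawyer-style gene-conversion scan,
k-mer mappability with block coverage/mismatch diagnostics, a
high-mappability-block supermatrix with neighbor-joining phylogeny, and
gene-catalog/expression summaries.  All stages run on synthetic MSY-like
inputs from :mod:`equimsy.synth`, which records exact ground truth.
"""

from ._seq import GenomeSequence
from .gametolog import (
    GametologPair,
    LiCounts,
    StratumAssignment,
    assign_strata,
    classify_codon_sites,
    classify_y_topology,
    clock_date,
    geneconv_scan,
    kaks_from_counts,
    li93_kaks,
)
from .seqclass import (
    AmpliconBlock,
    IdentityHit,
    TransposedSegment,
    class_partition,
    detect_ampliconic_blocks,
    find_transposed_segment,
    self_identity_hits,
)
from .popblocks import (
    MappabilityTrack,
    SampleCalls,
    block_coverage,
    block_mean_mappability,
    flag_cnv,
    mappability_track,
    mismatch_rates,
    normalize_coverage,
)
from .blocktree import (
    PhyloTree,
    Supermatrix,
    build_supermatrix,
    nj_tree,
    pairwise_distances,
    select_blocks,
)
from .catalog import (
    AnnotationHit,
    ComparativeMatrix,
    CountMatrix,
    GeneRecord,
    comparative_matrix,
    expression_compare,
    filter_annotation_hits,
    load_catalog,
    load_packaged_catalog,
    summarize_catalog,
)
from .synth import (
    AmpliconSpec,
    CnvSpec,
    CountsSpec,
    SampleSpec,
    StratumSpec,
    SynthConfig,
    TranspositionSpec,
    TruthSet,
    simulate_calls,
    simulate_counts,
    simulate_gametologs,
    simulate_reference,
)

__version__ = "0.1.0"


def printed_interval_length(start: int, end: int) -> int:
    """Length of a printed coordinate pair under the study's convention.

    Printed assembly coordinates such as Y:429,056-554,227 are treated as a
    half-open interval, so the length is simply end - start (the published
    125,171 bp segment length follows from exactly this convention).
    """
    if end <= start:
        raise ValueError("end must exceed start")
    return end - start
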