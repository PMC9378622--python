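"""In-silico design of CNO-responsive DREADD-based GPCR chimeras.

The package annotates GPCR domain architecture by projecting a reference
(bovine rhodopsin) through a protein alignment, cross-validates the
annotation against predicted transmembrane helices, assembles chimeric
receptors at protein and DNA level (signaling-domain swaps, N-terminal
signal peptide / VSV-G / linker modifications, restriction-site flanks),
and provides the companion cell-type specificity statistic and
functional-assay normalisation formulas.
"""

from importlib import resources

__version__ = "0.1.0"

from .records import (  # noqa: F401
    CANONICAL_ORDER,
    CdsRecord,
    DomainAnnotation,
    ProteinRecord,
    Segment,
    SIGNALING_LABELS,
)
from .alignment import (  # noqa: F401
    AlignedPair,
    Msa,
    ReferenceAnnotation,
    align_pairwise,
    export_signaling_library,
    ingest_msa,
    load_reference_annotation,
    project_domains,
)
from .topology import (  # noqa: F401
    FlankingReport,
    TmPrediction,
    check_flanking,
    ingest_tm_table,
    predict_tm,
)
from .chimera import (  # noqa: F401
    ChimeraDesign,
    ChimeraProtein,
    ConstructRecord,
    NTerminalMods,
    add_restriction_flanks,
    assemble_cds,
    assemble_protein,
    map_protein_segments_to_cds,
)
from .specificity import (  # noqa: F401
    compute_mean_data,
    heatmap_normalize,
    rank_sum_p,
    specificity_ratio,
    specificity_table,
)
from .assay import (  # noqa: F401
    CqTable,
    PlateTrace,
    baseline_fold_change,
    ddcq_fold_change,
    dual_reporter_fold,
    lentiviral_titer,
    vehicle_normalize,
)


def default_reference_path() -> str:
    """Filesystem path of the shipped bovine-rhodopsin reference annotation."""
    return str(resources.files("gpcrchimera.data") / "rhodopsin_domains.yaml")
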