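"""End-to-end orchestration: reads -> FLNC -> isoforms -> matrices -> TE/chimera.

This is the programmatic equivalent of running the individual tools in
sequence on one library; each step is also available on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import flnc as flnc_mod
from .alignments import SplicedAlignment, group_by_read
from .isoforms import (
    IsoformModel,
    classify_orf_type,
    classify_structural,
    collapse_isoforms,
    filter_artifacts,
    flag_cage_support,
    isoform_sequence,
    predict_orf,
)
from .matrices import CellFeatureMatrix, build_matrix, normalize_cpm10
from .reference import ToyReference
from .te import (
    GeneExonIndex,
    TEQuantResult,
    build_te_index,
    build_te_matrix,
    detect_chimeric,
    assign_read_to_te,
)


@dataclass
class PipelineResult:
    flnc_records: list
    library_stats: object
    read_meta: dict[str, tuple[str, str]]  # read_id -> (corrected CB, UMI)
    isoforms: list[IsoformModel]  # kept (FSM/ISM/NIC/NNC, junction-supported)
    read_isoform: dict[str, str]
    isoform_gene: dict[str, str]
    gene_matrix: CellFeatureMatrix
    isoform_matrix: CellFeatureMatrix
    spikein_matrix: CellFeatureMatrix | None
    te_result: TEQuantResult
    chimera_links: list
    chimera_table: pd.DataFrame
    molecule_orf_types: dict[str, str] = field(default_factory=dict)


def match_reference_transcript(
    iso: IsoformModel, reference: ToyReference
) -> str | None:
    """Reference transcript with an identical intron chain (FSM match)."""
    chain = iso.intron_chain
    for g in reference.genes:
        if g.chromosome != iso.chromosome or g.strand != iso.strand:
            continue
        for t in g.transcripts:
            if t.introns == chain:
                if chain:
                    return t.transcript_id
                s, e = iso.span
                if t.span[0] < e and s < t.span[1]:
                    return t.transcript_id
    return None


def classify_molecule_orfs(
    flnc_records: list, min_length_aa: int = 100
) -> dict[str, str]:
    """Per-molecule ORF-integrity type from the FLNC insert sequence."""
    out = {}
    for r in flnc_records:
        if r.fl_status == "FL" and r.insert_sequence:
            out[r.read_id] = classify_orf_type(
                predict_orf(r.insert_sequence, min_length_aa=min_length_aa)
            )
    return out


def spikein_assignments(
    result: PipelineResult, reference: ToyReference, truth: list
) -> list[tuple[str, str]]:
    """(truth transcript, assigned transcript) per spike-in molecule.

    The assigned transcript is the reference transcript whose intron chain
    matches the collapsed isoform the molecule's read supports; molecules
    whose isoform matches no reference chain are labelled ``unassigned``.
    """
    iso_by_id = {iso.isoform_id: iso for iso in result.isoforms}
    match_cache: dict[str, str | None] = {}
    out = []
    for t in truth:
        if t.feature_kind != "spikein":
            continue
        iso_id = result.read_isoform.get(t.read_id)
        if iso_id is None:
            continue
        if iso_id not in match_cache:
            match_cache[iso_id] = match_reference_transcript(
                iso_by_id[iso_id], reference
            )
        out.append((t.source_feature, match_cache[iso_id] or "unassigned"))
    return out


def run_pipeline(
    reference: ToyReference,
    reads: list,
    alignments: list[SplicedAlignment],
    whitelist: set[str],
    cell_stage: dict[str, str],
    min_cells_per_isoform: int = 5,
    classify_orfs_per_molecule: bool = False,
) -> PipelineResult:
    """Run the whole single-library analysis in memory.

    ``reads`` are simulator reads (or any objects with ``read_id`` and
    ``sequence()``); ``alignments`` the corresponding spliced alignments
    (truth SAM or a real aligner's output, already parsed).
    """
    records = flnc_mod.process_reads(
        [(r.read_id, r.sequence()) for r in reads], whitelist
    )
    stats = flnc_mod.summarize_library(records)
    read_meta = {
        r.read_id: (r.corrected_barcode, r.umi)
        for r in records
        if r.fl_status == "FL" and r.corrected_barcode
    }

    groups = group_by_read(alignments)
    single_primary = [
        segs[0]
        for rid, segs in groups.items()
        if len(segs) == 1 and segs[0].is_primary and rid in read_meta
    ]
    multi = [
        seg for rid, segs in groups.items() if len(segs) > 1 for seg in segs
        if rid in read_meta
    ]

    # --- isoform construction (genes and spike-ins) ---
    isoforms = collapse_isoforms(single_primary)
    for iso in isoforms:
        cls, gene = classify_structural(iso, reference.genes)
        iso.structural_class = cls
        iso.assigned_gene = gene
        iso.cage_supported = flag_cage_support(iso, reference.cage_peaks)
        orf = predict_orf(isoform_sequence(iso, reference.chromosomes))
        iso.orf_type = classify_orf_type(orf)
        iso.predicted_protein_length = orf.length_aa
    kept = filter_artifacts(isoforms, single_primary)

    read_isoform = {
        rid: iso.isoform_id for iso in kept for rid in iso.support_read_ids
    }
    isoform_gene = {iso.isoform_id: iso.assigned_gene for iso in kept}

    cells = sorted(set(cell_stage))
    spike_iso = {
        iso.isoform_id
        for iso in kept
        if iso.assigned_gene and iso.assigned_gene.startswith("SPIKE")
    }
    gene_records, iso_records, spike_records = [], [], []
    for rid, iso_id in read_isoform.items():
        bc, umi = read_meta[rid]
        gene = isoform_gene[iso_id]
        if iso_id in spike_iso:
            spike_records.append((bc, umi, gene))
        else:
            iso_records.append((bc, umi, iso_id))
            if gene:
                gene_records.append((bc, umi, gene))

    gene_matrix = build_matrix(
        flnc_mod.deduplicate_molecules(gene_records),
        kind="gene",
        cells=cells,
        stages=cell_stage,
    )
    isoform_matrix = build_matrix(
        flnc_mod.deduplicate_molecules(iso_records),
        kind="isoform",
        cells=cells,
        stages=cell_stage,
        min_cells=min_cells_per_isoform,
    )
    spikein_matrix = (
        build_matrix(
            flnc_mod.deduplicate_molecules(spike_records),
            kind="spikein",
            cells=cells,
            stages=cell_stage,
        )
        if spike_records
        else None
    )
    normalize_cpm10(gene_matrix)
    if isoform_matrix.features:
        normalize_cpm10(isoform_matrix)

    # --- TE quantification (single-segment unique reads only) ---
    te_index = build_te_index(reference.te_loci)
    assignments = [assign_read_to_te(a, te_index) for a in single_primary]
    te_result = build_te_matrix(
        assignments,
        read_meta,
        reference.te_loci,
        cells=cells,
        stages=cell_stage,
    )

    # --- chimeric transcripts (split reads only) ---
    gene_index = GeneExonIndex(
        [g for g in reference.genes if not g.gene_id.startswith("SPIKE")]
    )
    links, table = detect_chimeric(multi, te_index, gene_index, read_meta=read_meta)

    result = PipelineResult(
        flnc_records=records,
        library_stats=stats,
        read_meta=read_meta,
        isoforms=kept,
        read_isoform=read_isoform,
        isoform_gene=isoform_gene,
        gene_matrix=gene_matrix,
        isoform_matrix=isoform_matrix,
        spikein_matrix=spikein_matrix,
        te_result=te_result,
        chimera_links=links,
        chimera_table=table,
    )
    if classify_orfs_per_molecule:
        result.molecule_orf_types = classify_molecule_orfs(records)
    return result
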