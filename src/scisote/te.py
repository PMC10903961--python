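"""Locus-resolved transposable-element quantification and chimera linkage.

A uniquely aligned full-length read is assigned to at most one TE locus by
three rules applied in order:

1. the read must be uniquely aligned (primary, not secondary, mapq above a
   threshold);
2. the genomic start OR end position of the alignment must fall inside an
   overlapping TE locus (candidate restriction);
3. among candidate loci, the one with the longest total exon-block overlap
   wins, with deterministic tie-breaking (overlap length, then leftmost
   locus start, then locus id).

Overlap is computed on exon blocks, not the genomic span, so spliced reads
do not claim intronic TE bases.  Strand is ignored (antisense TE
transcription is real, and the rmsk strand refers to the repeat consensus).

Chimeric (split-aligned) reads are routed to a separate detector that links
a TE-locus segment to a protein-coding-gene segment of the same read and
aggregates UMI-deduplicated links into a TE-locus x gene table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignments import SplicedAlignment, group_by_read
from .matrices import CellFeatureMatrix, build_matrix
from .reference import GeneModel, TELocus

DEFAULT_MIN_MAPQ = 30


@dataclass
class TEAssignment:
    read_id: str
    locus_id: str | None
    overlap_length: int
    rejection_reason: str  # not_unique | no_overlap | endpoints_outside | none

    def __post_init__(self):
        if self.locus_id is not None:
            assert self.overlap_length > 0 and self.rejection_reason == "none"


@dataclass
class ChimericLink:
    read_id: str
    te_locus_id: str
    gene_id: str
    cell_barcode: str | None = None
    umi: str | None = None


class TEIndex:
    """Interval index over TE loci supporting overlap queries per chromosome."""

    def __init__(self, loci: list[TELocus]):
        seen = set()
        for lo in loci:
            if lo.locus_id in seen:
                raise ValueError(f"duplicate TE locus id {lo.locus_id}")
            seen.add(lo.locus_id)
        self.loci = list(loci)
        self.by_id = {lo.locus_id: lo for lo in loci}
        self._trees: dict[str, IntervalTree] = {}
        for lo in loci:
            self._trees.setdefault(lo.chromosome, IntervalTree()).addi(
                lo.start, lo.end, lo
            )

    def query(self, chromosome: str, start: int, end: int) -> list[TELocus]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda lo: (lo.start, lo.end, lo.locus_id))
        return hits

    def containing(self, chromosome: str, position: int) -> list[TELocus]:
        return self.query(chromosome, position, position + 1)


def build_te_index(loci: list[TELocus]) -> TEIndex:
    return TEIndex(loci)


def _block_overlap(blocks: list[tuple[int, int]], locus: TELocus) -> int:
    total = 0
    for s, e in blocks:
        total += max(0, min(e, locus.end) - max(s, locus.start))
    return total


def assign_read_to_te(
    alignment: SplicedAlignment,
    index: TEIndex,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    require_no_supplementary: bool = True,
    apply_endpoint_rule: bool = True,
) -> TEAssignment:
    """Assign one alignment to a TE locus under the unique/endpoint/longest-
    overlap rules (see module docstring)."""
    rid = alignment.read_id
    unique = (
        not alignment.is_secondary
        and alignment.mapq >= min_mapq
        and (
            (alignment.is_primary and not alignment.has_supplementary)
            if require_no_supplementary
            else True
        )
    )
    if not unique:
        return TEAssignment(rid, None, 0, "not_unique")
    span_s, span_e = alignment.span
    overlapping = [
        lo
        for lo in index.query(alignment.chromosome, span_s, span_e)
        if _block_overlap(alignment.blocks, lo) > 0
    ]
    if not overlapping:
        return TEAssignment(rid, None, 0, "no_overlap")
    if apply_endpoint_rule:
        candidates = [
            lo
            for lo in overlapping
            if lo.start <= span_s < lo.end or lo.start <= span_e - 1 < lo.end
        ]
        if not candidates:
            return TEAssignment(rid, None, 0, "endpoints_outside")
    else:
        candidates = overlapping
    best = min(
        candidates,
        key=lambda lo: (-_block_overlap(alignment.blocks, lo), lo.start, lo.locus_id),
    )
    return TEAssignment(rid, best.locus_id, _block_overlap(alignment.blocks, best), "none")


@dataclass
class TEQuantResult:
    matrix: CellFeatureMatrix  # cells x TE loci
    rollups: dict[str, pd.DataFrame]  # by rep_name / rep_family / rep_class
    per_cell_expressed_loci: pd.Series  # nonzero loci per cell
    per_locus_active_mean: pd.Series  # mean count among cells where active
    assignments: list[TEAssignment] = field(default_factory=list)


def build_te_matrix(
    assignments: list[TEAssignment],
    read_meta: dict[str, tuple[str, str]],
    loci: list[TELocus],
    cells: list[str] | None = None,
    stages: dict[str, str] | None = None,
) -> TEQuantResult:
    """Cell x TE-locus UMI matrix plus subfamily/family/class rollups.

    ``read_meta`` maps read_id -> (cell barcode, UMI); assignments are
    UMI-deduplicated by (barcode, umi, locus) before counting.
    """
    by_id = {lo.locus_id: lo for lo in loci}
    molecules = set()
    for a in assignments:
        if a.locus_id is None or a.read_id not in read_meta:
            continue
        bc, umi = read_meta[a.read_id]
        molecules.add((bc, umi, a.locus_id))
    counts: dict[tuple[str, str], int] = {}
    for bc, _, locus in molecules:
        counts[(bc, locus)] = counts.get((bc, locus), 0) + 1
    matrix = build_matrix(
        counts,
        kind="te_locus",
        cells=cells,
        features=sorted({lo for _, lo in counts}) or None,
        stages=stages,
    )
    dense = matrix.to_dense_frame()
    rollups = {}
    for level, attr in [
        ("rep_name", "rep_name"),
        ("rep_family", "rep_family"),
        ("rep_class", "rep_class"),
    ]:
        groups = pd.Series(
            {f: getattr(by_id[f], attr) for f in matrix.features}, name=level
        )
        rollups[level] = dense.T.groupby(groups).sum().T
    active = dense.where(dense > 0)
    per_locus_active_mean = active.mean(axis=0, skipna=True).fillna(0.0)
    per_cell_expressed = (dense > 0).sum(axis=1)
    return TEQuantResult(
        matrix=matrix,
        rollups=rollups,
        per_cell_expressed_loci=per_cell_expressed,
        per_locus_active_mean=per_locus_active_mean,
        assignments=list(assignments),
    )


class GeneExonIndex:
    """Interval index over protein-coding exons for chimera gene overlap."""

    def __init__(self, genes: list[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    self._trees.setdefault(t.chromosome, IntervalTree()).addi(
                        s, e, g.gene_id
                    )

    def overlap(self, chromosome: str, blocks: list[tuple[int, int]]) -> dict[str, int]:
        """gene_id -> total exon-block overlap (merged per gene)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return {}
        per_gene: dict[str, list[tuple[int, int]]] = {}
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                a, b = max(s, iv.begin), min(e, iv.end)
                if a < b:
                    per_gene.setdefault(iv.data, []).append((a, b))
        out = {}
        for gid, ivs in per_gene.items():
            ivs.sort()
            total = 0
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
            out[gid] = total
        return out


def detect_chimeric(
    alignments: list[SplicedAlignment],
    te_index: TEIndex,
    gene_index: GeneExonIndex,
    read_meta: dict[str, tuple[str, str]] | None = None,
    min_gene_overlap: int = 50,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[list[ChimericLink], pd.DataFrame]:
    """TE-gene chimeric transcript links from split-aligned reads.

    A read yields a link iff it has >=2 alignment segments, one segment
    passes the TE assignment rules and a different segment overlaps a
    protein-coding gene's exons by >= ``min_gene_overlap`` nt.  Links are
    deduplicated by (barcode, umi, te_locus, gene) and aggregated to a
    TE-locus x gene UMI table.
    """
    links: list[ChimericLink] = []
    for rid, segs in sorted(group_by_read(alignments).items()):
        if len(segs) < 2:
            continue
        te_hits: list[tuple[int, str, int]] = []
        gene_hits: list[tuple[int, str, int]] = []
        for i, seg in enumerate(segs):
            if seg.is_secondary or seg.mapq < min_mapq:
                continue
            a = assign_read_to_te(
                seg, te_index, min_mapq=min_mapq, require_no_supplementary=False
            )
            if a.locus_id is not None:
                te_hits.append((i, a.locus_id, a.overlap_length))
            for gid, ov in gene_index.overlap(seg.chromosome, seg.blocks).items():
                if ov >= min_gene_overlap:
                    gene_hits.append((i, gid, ov))
        best_link = None
        for ti, te_id, tov in sorted(te_hits, key=lambda x: (-x[2], x[1])):
            for gi, gid, gov in sorted(gene_hits, key=lambda x: (-x[2], x[1])):
                if gi != ti:
                    best_link = (te_id, gid)
                    break
            if best_link:
                break
        if best_link:
            bc, umi = (read_meta or {}).get(rid, (None, None))
            links.append(ChimericLink(rid, best_link[0], best_link[1], bc, umi))

    seen = set()
    dedup: list[ChimericLink] = []
    for ln in links:
        key = (ln.cell_barcode, ln.umi, ln.te_locus_id, ln.gene_id)
        if ln.cell_barcode is not None and key in seen:
            continue
        seen.add(key)
        dedup.append(ln)
    if dedup:
        table = (
            pd.DataFrame(
                [(l.te_locus_id, l.gene_id) for l in dedup],
                columns=["te_locus_id", "gene_id"],
            )
            .value_counts()
            .rename("umi_count")
            .reset_index()
            .sort_values(["te_locus_id", "gene_id"])
            .reset_index(drop=True)
        )
    else:
        table = pd.DataFrame(columns=["te_locus_id", "gene_id", "umi_count"])
    return dedup, table


def write_assignment_audit(assignments: list[TEAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "locus_id": a.locus_id or "",
                "overlap_length": a.overlap_length,
                "rejection_reason": a.rejection_reason,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)
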