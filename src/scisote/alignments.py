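"""Spliced-alignment records and SAM input/output (via pysam)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam


@dataclass
class SplicedAlignment:
    """One alignment segment of a read, as exon blocks on the genome.

    ``blocks`` are 0-based half-open genomic intervals, ascending and
    non-overlapping; gaps between consecutive blocks are introns (``N`` in
    the CIGAR).  ``read_id`` is the molecule identifier; the barcode/UMI
    decoration of SAM query names (``read|CB|UMI``) is stripped on input.
    """

    read_id: str
    chromosome: str
    strand: str
    blocks: list[tuple[int, int]]
    is_primary: bool = True
    is_supplementary: bool = False
    has_supplementary: bool = False
    is_secondary: bool = False
    mapq: int = 60

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("alignment needs at least one block")
        for i in range(1, len(self.blocks)):
            if self.blocks[i][0] < self.blocks[i - 1][1]:
                raise ValueError("blocks must be ascending and non-overlapping")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


def _blocks_from_cigar(ref_start: int, cigartuples) -> list[tuple[int, int]]:
    """Exon blocks from a CIGAR: D extends the current block, N splits it."""
    blocks: list[tuple[int, int]] = []
    pos = ref_start
    cur_start = None
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = pos
            pos += ln
        elif op == 2:  # D: consumes reference, same exon
            if cur_start is None:
                cur_start = pos
            pos += ln
        elif op == 3:  # N: intron
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += ln
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def read_sam(path: str | Path) -> list[SplicedAlignment]:
    """Read spliced alignments from SAM/BAM, flagging split reads."""
    out: list[SplicedAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            read_id = a.query_name.split("|")[0]
            out.append(
                SplicedAlignment(
                    read_id=read_id,
                    chromosome=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=_blocks_from_cigar(a.reference_start, a.cigartuples),
                    is_primary=not (a.is_secondary or a.is_supplementary),
                    is_supplementary=a.is_supplementary,
                    is_secondary=a.is_secondary,
                    mapq=a.mapping_quality,
                )
            )
    mark_supplementary_pairs(out)
    return out


def mark_supplementary_pairs(alignments: list[SplicedAlignment]) -> None:
    """Set ``has_supplementary`` on every segment of split reads."""
    split = {a.read_id for a in alignments if a.is_supplementary}
    for a in alignments:
        a.has_supplementary = a.read_id in split


def group_by_read(
    alignments: list[SplicedAlignment],
) -> dict[str, list[SplicedAlignment]]:
    groups: dict[str, list[SplicedAlignment]] = {}
    for a in alignments:
        groups.setdefault(a.read_id, []).append(a)
    return groups


@dataclass
class SamSegment:
    """A fully specified SAM record to be written (used for truth output)."""

    qname: str
    chromosome: str
    strand: str
    blocks: list[tuple[int, int]]
    seq: str  # genome-orientation sequence incl. soft-clipped bases
    clip_left: int = 0
    clip_right: int = 0
    is_supplementary: bool = False
    mapq: int = 60
    tags: dict = field(default_factory=dict)


def write_sam(
    segments: list[SamSegment], chromosome_lengths: dict[str, int], path: str | Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in chromosome_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        hdr = fh.header
        for seg in segments:
            a = pysam.AlignedSegment(hdr)
            a.query_name = seg.qname
            a.flag = (16 if seg.strand == "-" else 0) | (
                2048 if seg.is_supplementary else 0
            )
            a.reference_id = hdr.get_tid(seg.chromosome)
            a.reference_start = seg.blocks[0][0]
            a.mapping_quality = seg.mapq
            cig = []
            if seg.clip_left:
                cig.append((4, seg.clip_left))
            for i, (s, e) in enumerate(seg.blocks):
                if i:
                    cig.append((3, s - seg.blocks[i - 1][1]))
                cig.append((0, e - s))
            if seg.clip_right:
                cig.append((4, seg.clip_right))
            a.cigartuples = cig
            a.query_sequence = seg.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seg.seq))
            for k, v in seg.tags.items():
                a.set_tag(k, v)
            fh.write(a)
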