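"""Isoform collapse, structural classification, CAGE support, ORF typing.

Collapse merges spliced reads with identical intron chains into one
nonredundant isoform, tolerating terminal-exon jitter, and deliberately does
NOT merge a read whose chain is a 3'-anchored suffix of a longer chain
(5'-degraded molecules stay separate isoforms).  Structural classes follow
the usual long-read taxonomy against reference gene models:

FSM   intron chain equals a reference transcript's chain
ISM   chain is a consecutive sub-chain of a reference chain
NIC   chain is novel but uses only known splice sites
NNC   chain uses at least one novel splice site
other antisense / intergenic / unmatched mono-exon

ORF integrity is typed from a deterministic longest-ORF scan of the three
forward frames: complete, 5'-partial (no start codon), 3'-partial (no stop
codon), internal (neither), or `others` when no ORF reaches the minimum
length.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .alignments import SplicedAlignment
from .reference import CagePeak, GeneModel, STOP_CODONS


@dataclass
class IsoformModel:
    isoform_id: str
    chromosome: str
    strand: str
    exon_blocks: list[tuple[int, int]]
    support_read_ids: list[str]
    assigned_gene: str | None = None
    structural_class: str | None = None  # FSM | ISM | NIC | NNC | other
    cage_supported: bool | None = None
    orf_type: str | None = None
    predicted_protein_length: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_blocks[0][0], self.exon_blocks[-1][1]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exon_blocks[i][1], self.exon_blocks[i + 1][0])
            for i in range(len(self.exon_blocks) - 1)
        )

    @property
    def five_prime_position(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1] - 1


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def collapse_isoforms(
    alignments: list[SplicedAlignment],
    end_tolerance: int = 50,
    mono_exon_min_overlap: float = 0.5,
) -> list[IsoformModel]:
    """Collapse primary spliced alignments into nonredundant isoforms.

    Multi-exon reads merge iff their intron chains are identical and both
    terminal ends lie within ``end_tolerance`` of the cluster seed; a chain
    that is a strict suffix of another chain is its own isoform.  Mono-exon
    reads merge by reciprocal overlap >= ``mono_exon_min_overlap`` with the
    cluster seed.  Isoforms are grouped into gene clusters by overlapping
    span on the same strand and numbered PB-style (``PB.<cluster>.<n>``).
    """
    primaries = [a for a in alignments if a.is_primary and not a.is_secondary]
    clusters: list[dict] = []  # {chrom, strand, chain, start, end, reads}
    by_group: dict[tuple[str, str], list[SplicedAlignment]] = {}
    for a in primaries:
        by_group.setdefault((a.chromosome, a.strand), []).append(a)

    for (chrom, strand), group in sorted(by_group.items()):
        # multi-exon: bucket by exact intron chain, then cluster terminal ends
        chains: dict[tuple, list[SplicedAlignment]] = {}
        monos: list[SplicedAlignment] = []
        for a in group:
            if len(a.blocks) == 1:
                monos.append(a)
            else:
                chains.setdefault(a.junctions, []).append(a)
        for chain in sorted(chains):
            reads = sorted(chains[chain], key=lambda a: (a.span, a.read_id))
            open_clusters: list[dict] = []
            for a in reads:
                s, e = a.span
                home = None
                for c in open_clusters:
                    if abs(s - c["seed"][0]) <= end_tolerance and abs(
                        e - c["seed"][1]
                    ) <= end_tolerance:
                        home = c
                        break
                if home is None:
                    # the seed's termini represent the isoform: this keeps
                    # collapse idempotent (seeds are pairwise > tolerance)
                    home = {
                        "chrom": chrom, "strand": strand, "chain": chain,
                        "seed": (s, e), "start": s, "end": e, "reads": [],
                    }
                    open_clusters.append(home)
                home["reads"].append(a)
            clusters.extend(open_clusters)
        # mono-exon
        open_clusters = []
        for a in sorted(monos, key=lambda a: (a.span, a.read_id)):
            s, e = a.span
            home = None
            for c in open_clusters:
                if _reciprocal_overlap((s, e), c["seed"]) >= mono_exon_min_overlap:
                    home = c
                    break
            if home is None:
                home = {
                    "chrom": chrom, "strand": strand, "chain": (),
                    "seed": (s, e), "start": s, "end": e, "reads": [],
                }
                open_clusters.append(home)
            home["reads"].append(a)
        clusters.extend(open_clusters)

    # gene clusters: connected overlapping spans per (chrom, strand)
    isoforms: list[IsoformModel] = []
    gene_groups: list[list[dict]] = []
    for (chrom, strand) in sorted({(c["chrom"], c["strand"]) for c in clusters}):
        members = sorted(
            (c for c in clusters if c["chrom"] == chrom and c["strand"] == strand),
            key=lambda c: (c["start"], c["end"]),
        )
        current: list[dict] = []
        reach = -1
        for c in members:
            if current and c["start"] >= reach:
                gene_groups.append(current)
                current = []
            current.append(c)
            reach = max(reach, c["end"])
        if current:
            gene_groups.append(current)
    gene_groups.sort(key=lambda g: (g[0]["chrom"], g[0]["start"], g[0]["strand"]))

    for gi, members in enumerate(gene_groups, start=1):
        members = sorted(members, key=lambda c: (c["start"], c["end"], c["chain"]))
        for ni, c in enumerate(members, start=1):
            # exon blocks: internal junctions fixed, terminal ends extended
            chain = c["chain"]
            if chain:
                blocks = [(c["start"], chain[0][0])]
                blocks += [
                    (chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)
                ]
                blocks.append((chain[-1][1], c["end"]))
            else:
                blocks = [(c["start"], c["end"])]
            isoforms.append(
                IsoformModel(
                    isoform_id=f"PB.{gi}.{ni}",
                    chromosome=c["chrom"],
                    strand=c["strand"],
                    exon_blocks=blocks,
                    support_read_ids=sorted(a.read_id for a in c["reads"]),
                )
            )
    return isoforms


# ---------------------------------------------------------------------------
# structural classification
# ---------------------------------------------------------------------------

def _is_consecutive_subchain(sub: tuple, chain: tuple) -> bool:
    if not sub or len(sub) > len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if chain[i : i + len(sub)] == sub:
            return True
    return False


def classify_structural(
    isoform: IsoformModel, genes: list[GeneModel]
) -> tuple[str, str | None]:
    """Return (structural_class, assigned_gene).

    ``assigned_gene`` is the same-strand reference gene with maximal span
    overlap, or None for antisense/intergenic isoforms.
    """
    s, e = isoform.span
    same, anti = [], []
    for g in genes:
        if g.chromosome != isoform.chromosome:
            continue
        gs, ge = g.span
        if gs < e and s < ge:
            (same if g.strand == isoform.strand else anti).append(g)
    if not same:
        return "other", None
    gene = max(
        same,
        key=lambda g: (min(e, g.span[1]) - max(s, g.span[0]), g.gene_id),
    )
    ref_chains = []
    donors: set[int] = set()
    acceptors: set[int] = set()
    for g in same:
        for t in g.transcripts:
            ch = t.introns
            ref_chains.append(ch)
            for d, a in ch:
                donors.add(d)
                acceptors.add(a)

    chain = isoform.intron_chain
    if not chain:  # mono-exon: FSM if it matches a mono-exon transcript
        best = None
        for g in same:
            for t in g.transcripts:
                for es, ee in t.exons:
                    if es < e and s < ee:  # overlaps a reference exon
                        if len(t.exons) == 1:
                            return "FSM", gene.gene_id
                        best = "ISM"
        return (best or "other"), gene.gene_id
    if chain in ref_chains:
        return "FSM", gene.gene_id
    if any(_is_consecutive_subchain(chain, rc) for rc in ref_chains):
        return "ISM", gene.gene_id
    known = all(d in donors and a in acceptors for d, a in chain)
    return ("NIC" if known else "NNC"), gene.gene_id


# ---------------------------------------------------------------------------
# CAGE support
# ---------------------------------------------------------------------------

def flag_cage_support(
    isoform: IsoformModel, peaks: list[CagePeak], window: int = 200
) -> bool:
    """True iff the isoform's 5' end is within ``window`` bp of a
    same-strand CAGE peak (distance 0 inside a peak)."""
    pos = isoform.five_prime_position
    starts: list[tuple[int, int]] = sorted(
        (p.start, p.end)
        for p in peaks
        if p.chromosome == isoform.chromosome and p.strand == isoform.strand
    )
    if not starts:
        return False
    i = bisect_left(starts, (pos, pos))
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(starts):
            ps, pe = starts[j]
            dist = 0 if ps <= pos < pe else min(abs(pos - ps), abs(pos - (pe - 1)))
            if dist <= window:
                return True
    return False


# ---------------------------------------------------------------------------
# ORF prediction and typing
# ---------------------------------------------------------------------------

@dataclass
class ORFResult:
    orf_start: int  # transcript coords, 0-based, includes stop codon if any
    orf_end: int
    has_start_codon: bool
    has_stop_codon: bool
    length_aa: int
    below_threshold: bool = False
    relative_length: float | None = None


def predict_orf(sequence: str, min_length_aa: int = 100) -> ORFResult:
    """Longest-ORF scan of the 3 forward frames of a 5'->3' transcript.

    Candidates per frame: ATG..stop (complete); frame-start..stop with no
    upstream ATG (5'-open); ATG..sequence-end with no stop (3'-open); and
    frame-start..sequence-end with neither (open both ends).  The longest
    candidate wins (ties: leftmost start, then lowest frame); if none reaches
    ``min_length_aa`` a below-threshold marker is returned.
    """
    seq = sequence.upper()
    if any(c not in "ACGTN" for c in seq):
        raise ValueError("sequence must be DNA")
    candidates: list[tuple[int, int, int, bool, bool]] = []
    n = len(seq)
    for frame in range(3):
        seg_start = frame  # start of current stop-free stretch
        first_atg = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon == "ATG" and first_atg is None:
                first_atg = i
            if codon in STOP_CODONS:
                _add_candidate(
                    candidates, seg_start, first_atg, i + 3, True, frame
                )
                seg_start = i + 3
                first_atg = None
            i += 3
        # trailing open segment
        if seg_start + 3 <= n or first_atg is not None:
            end = frame + 3 * ((n - frame) // 3)
            _add_candidate(candidates, seg_start, first_atg, end, False, frame)

    viable = []
    for start, end, frame, has_start, has_stop in candidates:
        aa = (end - start) // 3 - (1 if has_stop else 0)
        if aa <= 0:
            continue
        viable.append((-aa, start, frame, end, has_start, has_stop, aa))
    if not viable:
        return ORFResult(0, 0, False, False, 0, below_threshold=True)
    viable.sort()
    neg_aa, start, frame, end, has_start, has_stop, aa = viable[0]
    return ORFResult(
        orf_start=start,
        orf_end=end,
        has_start_codon=has_start,
        has_stop_codon=has_stop,
        length_aa=aa,
        below_threshold=aa < min_length_aa,
    )


def _add_candidate(candidates, seg_start, first_atg, end, has_stop, frame):
    """Append the candidate for one stop-free stretch of one frame."""
    if first_atg is not None:
        candidates.append((first_atg, end, frame, True, has_stop))
    elif seg_start == frame:
        # no ATG: only valid if the stretch is anchored at the sequence start
        candidates.append((seg_start, end, frame, False, has_stop))


def classify_orf_type(orf: ORFResult) -> str:
    """Map ORF flags to the five transcript-integrity types."""
    if orf.below_threshold:
        return "others"
    if orf.has_start_codon and orf.has_stop_codon:
        return "complete"
    if orf.has_start_codon:
        return "three_prime_partial"
    if orf.has_stop_codon:
        return "five_prime_partial"
    return "internal"


def filter_artifacts(
    isoforms: list[IsoformModel],
    alignments: list[SplicedAlignment],
    min_flank: int = 10,
    keep_classes: tuple[str, ...] = ("FSM", "ISM", "NIC", "NNC"),
) -> list[IsoformModel]:
    """Drop `other`-class isoforms and those with an unsupported junction.

    A junction is supported when at least one assigned read spans it with at
    least ``min_flank`` aligned bases on both sides.
    """
    by_id = {a.read_id: a for a in alignments if a.is_primary}
    kept = []
    for iso in isoforms:
        if iso.structural_class is not None and iso.structural_class not in keep_classes:
            continue
        ok = True
        for j in iso.intron_chain:
            supported = False
            for rid in iso.support_read_ids:
                a = by_id.get(rid)
                if a is None:
                    continue
                for i, (d, acc) in enumerate(a.junctions):
                    if (d, acc) == j:
                        left = a.blocks[i][1] - a.blocks[i][0]
                        right = a.blocks[i + 1][1] - a.blocks[i + 1][0]
                        if left >= min_flank and right >= min_flank:
                            supported = True
                        break
                if supported:
                    break
            if not supported:
                ok = False
                break
        if ok:
            kept.append(iso)
    return kept


def isoform_sequence(isoform: IsoformModel, chromosomes: dict[str, str]) -> str:
    from .reference import revcomp

    seq = "".join(chromosomes[isoform.chromosome][s:e] for s, e in isoform.exon_blocks)
    return revcomp(seq) if isoform.strand == "-" else seq


def write_isoform_gtf(isoforms: list[IsoformModel], path) -> None:
    """Collapsed isoforms as GTF (1-based inclusive, PB-style ids)."""
    with open(path, "w") as fh:
        for iso in isoforms:
            s, e = iso.span
            attr = (
                f'gene_id "{iso.assigned_gene or iso.isoform_id.rsplit(".", 1)[0]}"; '
                f'transcript_id "{iso.isoform_id}";'
            )
            fh.write(
                f"{iso.chromosome}\tscisote\ttranscript\t{s + 1}\t{e}\t.\t"
                f"{iso.strand}\t.\t{attr}\n"
            )
            for bs, be in iso.exon_blocks:
                fh.write(
                    f"{iso.chromosome}\tscisote\texon\t{bs + 1}\t{be}\t.\t"
                    f"{iso.strand}\t.\t{attr}\n"
                )


def write_classification_tsv(isoforms: list[IsoformModel], path) -> None:
    cols = [
        "isoform_id", "assigned_gene", "chromosome", "strand", "n_exons",
        "structural_class", "orf_type", "cage_supported",
        "predicted_protein_length", "n_support_reads",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for iso in isoforms:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        iso.isoform_id, iso.assigned_gene or "", iso.chromosome,
                        iso.strand, len(iso.exon_blocks),
                        iso.structural_class or "", iso.orf_type or "",
                        iso.cage_supported if iso.cage_supported is not None else "",
                        iso.predicted_protein_length
                        if iso.predicted_protein_length is not None else "",
                        len(iso.support_read_ids),
                    ]
                )
                + "\n"
            )
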