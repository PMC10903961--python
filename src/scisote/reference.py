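"""Toy reference construction: genome, gene models, TE annotation, CAGE peaks.

The generator builds a miniature genome in which every downstream step of the
pipeline is exercisable with known ground truth: multi-isoform protein-coding
genes with intact ORFs, RepeatMasker-style TE loci drawn from a small
class/family/subfamily hierarchy, CAGE peaks at annotated TSSs, and spike-in
transcripts of known molar abundance on a dedicated contig.

Transcript sequences are designed so that ORF integrity is unambiguous:

* the 5' UTR contains no ``A`` and therefore no spurious upstream ATG;
* the CDS is ``ATG`` + codons drawn from the 60 non-stop, non-ATG codons +
  one stop codon, so the annotated start is the only in-frame ATG and the
  annotated stop the only in-frame stop.

A molecule truncated before the stop codon is then, by construction, typed as
3'-partial by any correct longest-ORF finder, which is what makes planted
truncation truth usable as a classification oracle.

Coordinates are 0-based half-open internally.  GTF output is 1-based
inclusive; rmsk/BED outputs are 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STOP_CODONS = ("TAA", "TAG", "TGA")
#: the 60 sense codons that are neither a stop nor ATG
_SAFE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS and "".join(c) != "ATG"
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SizingError(ValueError):
    """Requested features do not fit in the requested genome."""


@dataclass(frozen=True)
class TELocus:
    """One rmsk-style repeat annotation record."""

    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_family: str
    rep_class: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty TE interval for {self.locus_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CagePeak:
    chromosome: str
    start: int
    end: int
    strand: str


@dataclass
class TranscriptModel:
    """One annotated isoform: genomic exons plus transcript-coordinate CDS."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, ascending, non-overlapping
    cds_start: int | None = None  # transcript coords, 0-based half-open
    cds_end: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def sequence(self, chromosomes: dict[str, str]) -> str:
        chrom = chromosomes[self.chromosome]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def transcript_interval_to_genomic(
        self, t_start: int, t_end: int
    ) -> list[tuple[int, int]]:
        """Map a transcript-coordinate interval to ascending genomic blocks."""
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError("transcript interval out of bounds")
        blocks = []
        offset = 0
        for s, e in self.exons_in_transcript_order():
            exon_len = e - s
            lo = max(t_start - offset, 0)
            hi = min(t_end - offset, exon_len)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + lo, s + hi))
                else:
                    blocks.append((e - hi, e - lo))
            offset += exon_len
        blocks.sort()
        return blocks

    @property
    def five_prime_position(self) -> int:
        """Genomic position of the transcript's first base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


@dataclass
class ToyReference:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    te_loci: list[TELocus]
    cage_peaks: list[CagePeak]
    spikein_designs: list[tuple[str, float]] = field(default_factory=list)

    def transcripts(self):
        for g in self.genes:
            yield from g.transcripts

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._tx_index()[transcript_id]

    def _tx_index(self) -> dict[str, TranscriptModel]:
        if not hasattr(self, "_tx_cache"):
            self._tx_cache = {t.transcript_id: t for t in self.transcripts()}
        return self._tx_cache

    def te_locus(self, locus_id: str) -> TELocus:
        if not hasattr(self, "_te_cache"):
            self._te_cache = {t.locus_id: t for t in self.te_loci}
        return self._te_cache[locus_id]

    def validate(self) -> None:
        seen = set()
        for te in self.te_loci:
            if te.locus_id in seen:
                raise ValueError(f"duplicate TE locus id {te.locus_id}")
            seen.add(te.locus_id)
            clen = len(self.chromosomes[te.chromosome])
            if not (0 <= te.start < te.end <= clen):
                raise ValueError(f"TE {te.locus_id} outside chromosome")
        for t in self.transcripts():
            clen = len(self.chromosomes[t.chromosome])
            prev_end = -1
            for s, e in t.exons:
                if not (0 <= s < e <= clen):
                    raise ValueError(f"{t.transcript_id} exon outside chromosome")
                if s < prev_end:
                    raise ValueError(f"{t.transcript_id} exons overlap")
                prev_end = e
            if t.cds_start is not None:
                seq = t.sequence(self.chromosomes)
                if seq[t.cds_start : t.cds_start + 3] != "ATG":
                    raise ValueError(f"{t.transcript_id} missing start codon")
                if seq[t.cds_end - 3 : t.cds_end] not in STOP_CODONS:
                    raise ValueError(f"{t.transcript_id} missing stop codon")
        for p in self.cage_peaks:
            clen = len(self.chromosomes[p.chromosome])
            if not (0 <= p.start < p.end <= clen):
                raise ValueError("CAGE peak outside chromosome")


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

#: miniature repeat hierarchy: (repClass, repFamily, repName choices)
TE_HIERARCHY = [
    ("LINE", "L1", ("Lx7", "L1Md_T", "L1_Mus3")),
    ("LTR", "ERVL", ("MT2_mm", "MERVL-int", "MT2B1")),
    ("SINE", "B1", ("B1_Mus1", "B1_Mm")),
    ("DNA", "hAT-Charlie", ("Charlie4", "MER5A")),
    ("Satellite", "Satellite", ("GSAT_MM",)),
]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


@dataclass
class _MasterGene:
    """A gene laid out in transcript coordinates before genomic placement."""

    transcript_seq: str
    cds_start: int
    cds_end: int
    # exon slices of the master transcript, transcript order
    exon_slices: list[tuple[int, int]]
    # per-isoform: indices into exon_slices (ascending)
    isoform_exon_sets: list[tuple[int, ...]]


def _build_master_gene(rng: np.random.Generator, n_isoforms: int) -> _MasterGene:
    utr5_len = int(rng.integers(40, 90))
    n_codons = int(rng.integers(160, 320))
    utr3_len = int(rng.integers(120, 250))
    utr5 = _random_seq(rng, utr5_len, alphabet="CGT")  # A-free: no upstream ATG
    codons = rng.integers(0, len(_SAFE_CODONS), n_codons)
    cds = "ATG" + "".join(_SAFE_CODONS[i] for i in codons) + STOP_CODONS[
        int(rng.integers(0, 3))
    ]
    utr3 = _random_seq(rng, utr3_len)
    seq = utr5 + cds + utr3
    cds_start, cds_end = utr5_len, utr5_len + len(cds)

    # exonize: 1-2 UTR5 exons, 2-4 codon-aligned CDS exons, 1-2 UTR3 exons
    bounds = [0]
    if utr5_len >= 70 and rng.random() < 0.7:
        bounds.append(int(rng.integers(30, utr5_len - 29)))
    bounds.append(cds_start)
    n_cds_exons = int(rng.integers(2, 5))
    # candidate cut points 20 codons apart so every CDS exon is >=60 nt
    grid = np.arange(25, n_codons - 24, 20)
    n_cuts = min(n_cds_exons - 1, len(grid))
    cuts = sorted(rng.choice(grid, size=n_cuts, replace=False)) if n_cuts else []
    for c in cuts:
        bounds.append(cds_start + 3 + 3 * int(c))  # codon-aligned within CDS
    bounds.append(cds_end)
    if utr3_len >= 110 and rng.random() < 0.6:
        bounds.append(cds_end + int(rng.integers(50, utr3_len - 49)))
    bounds.append(len(seq))
    bounds = sorted(set(bounds))
    exon_slices = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    n_exons = len(exon_slices)

    # exon roles for variant construction
    cds_exon_idx = [
        i for i, (a, b) in enumerate(exon_slices) if a >= cds_start and b <= cds_end
    ]
    full = tuple(range(n_exons))
    variants: list[tuple[int, ...]] = [full]

    def add(v: tuple[int, ...]):
        if v not in variants and len(v) >= 1:
            variants.append(v)

    # skip one codon-aligned internal CDS exon (keeps the ORF in frame and
    # long enough to stay above the ORF-caller's minimum length)
    internal_cds = [i for i in cds_exon_idx[1:-1]] if len(cds_exon_idx) >= 3 else []
    for i in internal_cds:
        a, b = exon_slices[i]
        remaining_codons = (cds_end - cds_start - (b - a)) // 3 - 2
        if remaining_codons >= 130:
            add(tuple(j for j in full if j != i))
    # skip a pure-UTR internal exon
    for i in range(1, n_exons - 1):
        a, b = exon_slices[i]
        if b <= cds_start or a >= cds_end:
            add(tuple(j for j in full if j != i))
    # 5'-shorter suffix: drop leading pure-UTR5 exons (intron chain suffix)
    if exon_slices[0][1] <= cds_start and n_exons >= 3:
        add(tuple(range(1, n_exons)))
        for v in list(variants[1:]):
            if v[0] == 0 and exon_slices[0][1] <= cds_start:
                add(v[1:])
    return _MasterGene(seq, cds_start, cds_end, exon_slices, variants[:n_isoforms])


def _place_gene(
    rng: np.random.Generator,
    master: _MasterGene,
    gene_id: str,
    chromosome: str,
    offset: int,
    strand: str,
) -> tuple[str, GeneModel]:
    """Render a master gene into genomic sequence starting at ``offset``."""
    n_exons = len(master.exon_slices)
    introns = [int(rng.integers(80, 600)) for _ in range(n_exons - 1)]
    # plus-strand layout of the master transcript
    plus_exons = []
    pieces = []
    pos = 0
    for i, (a, b) in enumerate(master.exon_slices):
        plus_exons.append((pos, pos + (b - a)))
        pieces.append(master.transcript_seq[a:b])
        pos += b - a
        if i < n_exons - 1:
            pieces.append(_random_seq(rng, introns[i]))
            pos += introns[i]
    block = "".join(pieces)
    if strand == "-":
        L = len(block)
        block = revcomp(block)
        plus_exons = [(L - e, L - s) for s, e in plus_exons]

    # exon index (transcript order) -> genomic interval; the flip above
    # rewrites coordinates in place, so list order stays transcript order
    geno = {i: (offset + s, offset + e) for i, (s, e) in enumerate(plus_exons)}

    transcripts = []
    for k, exon_set in enumerate(master.isoform_exon_sets, start=1):
        slices = [master.exon_slices[i] for i in exon_set]
        # CDS in isoform transcript coordinates
        cds_s = cds_e = None
        acc = 0
        for a, b in slices:
            if a <= master.cds_start < b:
                cds_s = acc + (master.cds_start - a)
            if a < master.cds_end <= b:
                cds_e = acc + (master.cds_end - a)
            acc += b - a
        exons = sorted(geno[i] for i in exon_set)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{k}",
                gene_id=gene_id,
                chromosome=chromosome,
                strand=strand,
                exons=exons,
                cds_start=cds_s,
                cds_end=cds_e,
            )
        )
    return block, GeneModel(gene_id, chromosome, strand, transcripts)


# ---------------------------------------------------------------------------
# top-level builder
# ---------------------------------------------------------------------------

def build_toy_reference(
    seed: int,
    n_chromosomes: int = 2,
    n_genes: int = 20,
    n_te_loci: int = 40,
    *,
    te_adjacent_fraction: float = 0.35,
    te_far_fraction: float = 0.25,
    n_spikein_genes: int = 8,
    spikein_copies: tuple[float, ...] = (1, 2, 4, 8, 16, 32, 64, 128),
    n_background_cage_peaks: int = 10,
    max_chromosome_length: int = 500_000,
) -> ToyReference:
    """Build a deterministic toy reference.

    Genes are laid head-to-tail with intergenic gaps on ``n_chromosomes``
    contigs; TE loci are placed in intergenic space, a fraction of them
    within 10 kb of a gene and a fraction on a dedicated gene-free contig
    (``chrU``) that stands in for loci >1 Mb from any gene.  Spike-in
    transcripts live on ``chrS``.
    """
    if n_genes < 1 or n_te_loci < 1 or n_chromosomes < 1:
        raise ValueError("need at least one chromosome, gene and TE locus")
    rng = np.random.default_rng(seed)

    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    genes_per_chrom = {c: 0 for c in chrom_names}
    for i in range(n_genes):
        genes_per_chrom[chrom_names[i % n_chromosomes]] += 1

    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_counter = 0
    intergenic: dict[str, list[tuple[int, int]]] = {}
    for chrom in chrom_names:
        pieces = []
        pos = 0
        gaps = []
        for _ in range(genes_per_chrom[chrom]):
            gap = int(rng.integers(3000, 12000))
            pieces.append(_random_seq(rng, gap))
            gaps.append((pos, pos + gap))
            pos += gap
            gene_counter += 1
            gene_id = f"G{gene_counter:04d}"
            master = _build_master_gene(rng, n_isoforms=int(rng.integers(1, 7)))
            strand = "+" if rng.random() < 0.5 else "-"
            block, gene = _place_gene(rng, master, gene_id, chrom, pos, strand)
            pieces.append(block)
            pos += len(block)
            genes.append(gene)
        tail = int(rng.integers(3000, 12000))
        pieces.append(_random_seq(rng, tail))
        gaps.append((pos, pos + tail))
        pos += tail
        if pos > max_chromosome_length:
            raise SizingError(
                f"{chrom} would be {pos} bp > {max_chromosome_length}; "
                "reduce n_genes or raise max_chromosome_length"
            )
        chromosomes[chrom] = "".join(pieces)
        intergenic[chrom] = gaps

    # gene-free contig for "far" TE loci
    n_far = int(round(n_te_loci * te_far_fraction))
    n_adj = int(round(n_te_loci * te_adjacent_fraction))
    n_other = n_te_loci - n_far - n_adj
    if n_other < 0:
        raise ValueError("te_adjacent_fraction + te_far_fraction > 1")
    chromosomes["chrU"] = _random_seq(rng, max(50_000, 4000 * max(n_far, 1)))

    te_loci: list[TELocus] = []

    def add_te(chrom: str, start: int, end: int):
        ci = int(rng.integers(0, len(TE_HIERARCHY)))
        rep_class, rep_family, names = TE_HIERARCHY[ci]
        rep_name = names[int(rng.integers(0, len(names)))]
        strand = "+" if rng.random() < 0.5 else "-"
        te_loci.append(
            TELocus(
                locus_id=f"{chrom}:{start}-{end}:{rep_name}",
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                rep_name=rep_name,
                rep_family=rep_family,
                rep_class=rep_class,
            )
        )

    # adjacent loci: inside an intergenic gap, within 10 kb of a gene edge
    gene_cycle = itertools.cycle(genes)
    placed = 0
    attempts = 0
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    for g in genes:
        occupied[g.chromosome].append(g.span)

    def free(chrom: str, s: int, e: int) -> bool:
        return all(e <= a or s >= b for a, b in occupied[chrom])

    while placed < n_adj:
        attempts += 1
        if attempts > 200 * n_adj:
            raise SizingError("cannot place adjacent TE loci; genome too dense")
        g = next(gene_cycle)
        span = g.span
        length = int(rng.integers(300, 2500))
        side = rng.random() < 0.5
        gap = int(rng.integers(200, 8000))
        start = span[1] + gap if side else span[0] - gap - length
        end = start + length
        clen = len(chromosomes[g.chromosome])
        if start < 0 or end > clen or not free(g.chromosome, start, end):
            continue
        # stay <10 kb from the flanking gene but clear of all genes
        add_te(g.chromosome, start, end)
        occupied[g.chromosome].append((start, end))
        placed += 1

    # far loci on the gene-free contig
    for _ in range(n_far):
        for _try in range(400):
            length = int(rng.integers(300, 2500))
            start = int(rng.integers(0, len(chromosomes["chrU"]) - length))
            if free("chrU", start, start + length):
                add_te("chrU", start, start + length)
                occupied["chrU"].append((start, start + length))
                break
        else:
            raise SizingError("cannot place far TE loci on chrU")

    # remaining loci anywhere intergenic on gene chromosomes
    for _ in range(n_other):
        for _try in range(400):
            chrom = chrom_names[int(rng.integers(0, n_chromosomes))]
            gaps = intergenic[chrom]
            s0, e0 = gaps[int(rng.integers(0, len(gaps)))]
            length = int(rng.integers(300, 2500))
            if e0 - s0 <= length + 2:
                continue
            start = s0 + int(rng.integers(1, e0 - s0 - length))
            if free(chrom, start, start + length):
                add_te(chrom, start, start + length)
                occupied[chrom].append((start, start + length))
                break
        else:
            raise SizingError("cannot place intergenic TE loci")

    # CAGE peaks: one per gene TSS plus random background peaks
    cage_peaks = []
    for g in genes:
        t = g.transcripts[0]
        p5 = t.five_prime_position
        cage_peaks.append(
            CagePeak(g.chromosome, max(0, p5 - 25), p5 + 25, g.strand)
        )
    for _ in range(n_background_cage_peaks):
        chrom = chrom_names[int(rng.integers(0, n_chromosomes))]
        start = int(rng.integers(0, len(chromosomes[chrom]) - 60))
        cage_peaks.append(
            CagePeak(chrom, start, start + 50, "+" if rng.random() < 0.5 else "-")
        )

    # spike-ins: mono/multi-isoform genes on chrS with known copies per cell
    spike_pieces = []
    spike_genes: list[GeneModel] = []
    pos = 0
    spikein_designs = []
    for i in range(n_spikein_genes):
        gap = 2000
        spike_pieces.append(_random_seq(rng, gap))
        pos += gap
        master = _build_master_gene(rng, n_isoforms=2)
        block, gene = _place_gene(rng, master, f"SPIKE{i + 1:02d}", "chrS", pos, "+")
        spike_pieces.append(block)
        pos += len(block)
        spike_genes.append(gene)
        copies = spikein_copies[i % len(spikein_copies)]
        for t in gene.transcripts:
            spikein_designs.append((t.transcript_id, float(copies)))
    spike_pieces.append(_random_seq(rng, 2000))
    chromosomes["chrS"] = "".join(spike_pieces)
    genes.extend(spike_genes)

    ref = ToyReference(chromosomes, genes, te_loci, cage_peaks, spikein_designs)
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# writers (FASTA / GTF / rmsk TSV / BED6)
# ---------------------------------------------------------------------------

def write_fasta(reference: ToyReference, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(reference: ToyReference, path: str | Path) -> None:
    """GTF, 1-based inclusive, gene/transcript/exon features."""
    with open(path, "w") as fh:
        for gene in reference.genes:
            gs, ge = gene.span
            attr = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chromosome}\ttoy\tgene\t{gs + 1}\t{ge}\t.\t"
                f"{gene.strand}\t.\t{attr}\n"
            )
            for t in gene.transcripts:
                ts, te = t.span
                attr = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chromosome}\ttoy\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{t.strand}\t.\t{attr}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chromosome}\ttoy\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{attr}\n"
                    )


def write_rmsk(reference: ToyReference, path: str | Path) -> None:
    """UCSC rmsk-style TSV (bin-less subset), 0-based half-open."""
    cols = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for te in reference.te_loci:
            fh.write(
                f"{te.chromosome}\t{te.start}\t{te.end}\t{te.strand}\t"
                f"{te.rep_name}\t{te.rep_class}\t{te.rep_family}\n"
            )


def read_rmsk(path: str | Path) -> list[TELocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom = f[idx["genoName"]]
            start, end = int(f[idx["genoStart"]]), int(f[idx["genoEnd"]])
            name = f[idx["repName"]]
            loci.append(
                TELocus(
                    locus_id=f"{chrom}:{start}-{end}:{name}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=f[idx["strand"]],
                    rep_name=name,
                    rep_family=f[idx["repFamily"]],
                    rep_class=f[idx["repClass"]],
                )
            )
    return loci


def write_te_bed(reference: ToyReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in reference.te_loci:
            fh.write(
                f"{te.chromosome}\t{te.start}\t{te.end}\t"
                f"{te.rep_name}\t0\t{te.strand}\n"
            )


def write_cage_bed(reference: ToyReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(reference.cage_peaks):
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\tpeak{i + 1}\t0\t{p.strand}\n"
            )
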