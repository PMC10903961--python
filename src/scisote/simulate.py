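"""Barcoded full-length cDNA molecule simulation with exact ground truth.

Emulates a plate-scale single-cell full-length cDNA library: each molecule is
``5' primer + cell barcode + UMI + cDNA + polyA + 3' primer``, optionally
reverse-complemented, with stage-structured gene programs, planted
stage-specific features, isoform switches, 5'/3' truncations, TE-locus
transcription, TE-gene chimeric molecules and spike-ins at known copy
numbers.  Truth alignments are emitted directly (SAM), so no aligner is
needed downstream; the pipeline equally accepts a real aligner's SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import SamSegment, SplicedAlignment, mark_supplementary_pairs
from .reference import ToyReference, TranscriptModel, revcomp

PRIMER_5 = "AAGCAGTGGTATCAACGCAGAGTAC"
PRIMER_3 = "CCCATGTACTCTGCGTTGATACCAC"

DEFAULT_STAGES = ("oocyte", "zygote", "E2C", "L2C", "4C", "8C", "16_32C", "blastocyst")

_BASES = np.array(list("ACGT"))


def generate_whitelist(
    n: int, length: int = 16, min_distance: int = 5, seed: int = 0
) -> list[str]:
    """Random barcode whitelist with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("cannot build whitelist at this distance")
        cand = rng.integers(0, 4, length)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
    return ["".join(_BASES[c]) for c in chosen]


@dataclass
class MoleculeTruth:
    """Ground truth for one distinct molecule (pre-PCR-duplication)."""

    read_id: str
    cell_barcode: str  # true barcode
    umi: str
    source_feature: str  # isoform / TE locus / spike-in transcript id
    feature_kind: str  # isoform | te_locus | spikein | chimera
    gene_id: str | None
    stage: str
    truncation: str  # none | three_prime | five_prime | internal
    chimera_partner: str | None = None  # TE locus id for chimeric molecules
    observed_barcode: str | None = None  # set by corrupt_barcodes


@dataclass
class SimulatedRead:
    read_id: str
    barcode: str  # observed (may be corrupted)
    umi: str
    cdna: str
    is_reverse: bool
    is_duplicate: bool
    truth: MoleculeTruth
    polya_len: int = 20

    def sequence(self, primer_5: str = PRIMER_5, primer_3: str = PRIMER_3) -> str:
        fwd = (
            primer_5 + self.barcode + self.umi + self.cdna
            + "A" * self.polya_len + primer_3
        )
        return revcomp(fwd) if self.is_reverse else fwd


@dataclass
class ExperimentDesign:
    """Everything the simulator needs beyond the reference itself."""

    stages: list[str]
    cells_per_stage: int
    whitelist: list[str]
    cell_stage: dict[str, str]  # barcode -> stage
    expression_program: dict[tuple[str, str], float]  # (stage, feature) -> mean
    isoform_usage: dict[str, dict[str, dict[str, float]]]  # gene -> stage -> iso -> w
    truncation_rates: dict[str, tuple[float, float]]  # stage -> (p3, p5)
    planted_stage_specific: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_switches: list[tuple[str, str, str, int]] = field(default_factory=list)
    chimera_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    barcode_length: int = 16
    umi_length: int = 10
    duplicate_rate: float = 0.2
    substitution_rate: float = 0.0
    polya_len: int = 20
    spikeins: bool = True
    min_kept_codons: int = 120  # truncations keep at least this much ORF

    def validate(self, reference: ToyReference) -> None:
        tx = {t.transcript_id for t in reference.transcripts()}
        gene_ids = {g.gene_id for g in reference.genes}
        te_ids = {t.locus_id for t in reference.te_loci}
        for (stage, feat), mean in self.expression_program.items():
            if mean < 0:
                raise ValueError("expected counts must be >= 0")
            if stage not in self.stages:
                raise ValueError(f"unknown stage {stage}")
            if feat not in gene_ids and feat not in te_ids and feat not in tx:
                raise ValueError(f"program references unknown feature {feat}")
        for stage, (p3, p5) in self.truncation_rates.items():
            if not (0 <= p3 <= 1 and 0 <= p5 <= 1 and p3 + p5 <= 1):
                raise ValueError("truncation probabilities must be in [0,1]")
        for te_id, gene_id, mean in self.chimera_pairs:
            if te_id not in te_ids or gene_id not in gene_ids or mean < 0:
                raise ValueError("bad chimera pair")
        for feat in self.planted_stage_specific:
            if feat not in gene_ids and feat not in te_ids:
                raise ValueError(f"planted feature {feat} not in reference")


def default_design(
    reference: ToyReference,
    *,
    seed: int = 0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    cells_per_stage: int = 6,
    base_gene_mean: tuple[float, float] = (2.0, 8.0),
    n_stage_specific_genes: int = 0,
    gene_fold_change: float = 8.0,
    te_expressed_fraction: float = 0.8,
    base_te_mean: tuple[float, float] = (1.0, 4.0),
    n_stage_specific_te: int = 0,
    te_fold_change: float = 8.0,
    couple_adjacent_te: bool = False,
    n_switch_genes: int = 0,
    switch_fractions: tuple[float, float] = (0.9, 0.1),
    n_chimera_pairs: int = 0,
    chimera_mean: float = 0.5,
    truncation_p3: dict[str, float] | float = 0.0,
    truncation_p5: dict[str, float] | float = 0.0,
    duplicate_rate: float = 0.2,
    spikeins: bool = True,
    whitelist_size: int | None = None,
    whitelist_min_distance: int = 5,
) -> ExperimentDesign:
    """Build a study design with planted structure over a toy reference.

    Defaults describe the study conditions the analyses assume: stage-
    structured expression means, a dominant-major isoform usage profile per
    gene, and optional planted stage-specific features, switches, chimeras
    and truncations controlled by the keyword arguments.
    """
    rng = np.random.default_rng(seed)
    stages = list(stages)
    n_cells = cells_per_stage * len(stages)
    wl_n = whitelist_size or n_cells
    if wl_n < n_cells:
        raise ValueError("whitelist smaller than number of cells")
    whitelist = generate_whitelist(wl_n, min_distance=whitelist_min_distance, seed=seed)
    cell_stage = {
        whitelist[i]: stages[i // cells_per_stage] for i in range(n_cells)
    }

    real_genes = [g for g in reference.genes if not g.gene_id.startswith("SPIKE")]
    program: dict[tuple[str, str], float] = {}
    # gene programs: flat across stages unless planted
    planted: dict[str, tuple[str, float]] = {}
    spec_genes = list(
        rng.choice(
            [g.gene_id for g in real_genes],
            size=min(n_stage_specific_genes, len(real_genes)),
            replace=False,
        )
    )
    for g in real_genes:
        base = float(rng.uniform(*base_gene_mean))
        if g.gene_id in spec_genes:
            peak = stages[int(rng.integers(0, len(stages)))]
            planted[g.gene_id] = (peak, gene_fold_change)
            for s in stages:
                program[(s, g.gene_id)] = base * (
                    gene_fold_change if s == peak else 1.0
                )
        else:
            for s in stages:
                program[(s, g.gene_id)] = base

    # TE programs
    te_gene_neighbors = _adjacent_gene_map(reference) if couple_adjacent_te else {}
    te_ids = [t.locus_id for t in reference.te_loci]
    expressed = list(
        rng.choice(
            te_ids, size=int(round(te_expressed_fraction * len(te_ids))), replace=False
        )
    )
    spec_te = list(
        rng.choice(
            expressed, size=min(n_stage_specific_te, len(expressed)), replace=False
        )
    )
    for te_id in expressed:
        base = float(rng.uniform(*base_te_mean))
        neighbor = te_gene_neighbors.get(te_id)
        if neighbor is not None and neighbor in program_genes(program, stages):
            # shared program with the adjacent gene (scaled), independent noise
            for s in stages:
                program[(s, te_id)] = base * program[(s, neighbor)] / max(
                    1e-9, np.mean([program[(x, neighbor)] for x in stages])
                )
        elif te_id in spec_te:
            peak = stages[int(rng.integers(0, len(stages)))]
            planted[te_id] = (peak, te_fold_change)
            for s in stages:
                program[(s, te_id)] = base * (te_fold_change if s == peak else 1.0)
        else:
            for s in stages:
                program[(s, te_id)] = base

    # isoform usage: dirichlet with a dominant major isoform
    usage: dict[str, dict[str, dict[str, float]]] = {}
    switches: list[tuple[str, str, str, int]] = []
    multi_iso = [g for g in real_genes if len(g.transcripts) >= 2]
    switch_genes = list(
        rng.choice(
            [g.gene_id for g in multi_iso],
            size=min(n_switch_genes, len(multi_iso)),
            replace=False,
        )
    )
    for g in real_genes:
        iso_ids = [t.transcript_id for t in g.transcripts]
        w = rng.dirichlet(np.full(len(iso_ids), 0.8)) if len(iso_ids) > 1 else [1.0]
        base_w = {i: float(x) for i, x in zip(iso_ids, w)}
        per_stage = {s: dict(base_w) for s in stages}
        if g.gene_id in switch_genes:
            a, b = iso_ids[0], iso_ids[1]
            boundary = int(rng.integers(1, len(stages)))
            hi, lo = switch_fractions
            rest = max(0.0, 1.0 - hi - lo) / max(1, len(iso_ids) - 2)
            for si, s in enumerate(stages):
                w1 = {i: rest for i in iso_ids}
                if si < boundary:
                    w1[a], w1[b] = hi, lo
                else:
                    w1[a], w1[b] = lo, hi
                per_stage[s] = w1
            switches.append((g.gene_id, a, b, boundary))
        usage[g.gene_id] = per_stage

    # spike-ins: constant copies in every cell
    if spikeins:
        for s in stages:
            for tx_id, copies in reference.spikein_designs:
                program[(s, tx_id)] = float(copies)

    # chimera pairs: TE loci near genes when available, else arbitrary
    pairs: list[tuple[str, str, float]] = []
    if n_chimera_pairs:
        neigh = _adjacent_gene_map(reference)
        cand = [(t, g) for t, g in neigh.items()]
        other = [
            (t.locus_id, g.gene_id)
            for t in reference.te_loci
            for g in real_genes[:1]
            if t.locus_id not in neigh
        ]
        pool = cand + other
        idx = rng.choice(len(pool), size=min(n_chimera_pairs, len(pool)), replace=False)
        pairs = [(pool[i][0], pool[i][1], chimera_mean) for i in idx]

    if not isinstance(truncation_p3, dict):
        truncation_p3 = {s: float(truncation_p3) for s in stages}
    if not isinstance(truncation_p5, dict):
        truncation_p5 = {s: float(truncation_p5) for s in stages}
    trunc = {s: (truncation_p3[s], truncation_p5[s]) for s in stages}

    design = ExperimentDesign(
        stages=stages,
        cells_per_stage=cells_per_stage,
        whitelist=whitelist,
        cell_stage=cell_stage,
        expression_program=program,
        isoform_usage=usage,
        truncation_rates=trunc,
        planted_stage_specific=planted,
        planted_switches=switches,
        chimera_pairs=pairs,
        seed=seed,
        duplicate_rate=duplicate_rate,
        spikeins=spikeins,
    )
    design.validate(reference)
    return design


def program_genes(program: dict[tuple[str, str], float], stages: list[str]):
    return {f for (_, f) in program}


def _adjacent_gene_map(reference: ToyReference, max_gap: int = 10_000):
    """TE locus -> nearest gene within max_gap on the same chromosome."""
    out: dict[str, str] = {}
    for te in reference.te_loci:
        best, best_d = None, None
        for g in reference.genes:
            if g.chromosome != te.chromosome or g.gene_id.startswith("SPIKE"):
                continue
            gs, ge = g.span
            d = 0 if (te.start < ge and gs < te.end) else max(gs - te.end, te.start - ge)
            if d < max_gap and (best_d is None or d < best_d):
                best, best_d = g.gene_id, d
        if best is not None:
            out[te.locus_id] = best
    return out


# ---------------------------------------------------------------------------
# molecule emission
# ---------------------------------------------------------------------------

def _sample_truncation(
    rng: np.random.Generator, p3: float, p5: float
) -> str:
    u = rng.random()
    if u < p3:
        return "three_prime"
    if u < p3 + p5:
        return "five_prime"
    return "none"


def _truncate_interval(
    rng: np.random.Generator, t: TranscriptModel, truncation: str, min_codons: int
) -> tuple[int, int, str]:
    """Kept transcript interval for a truncation type (may fall back to none)."""
    L = t.length
    if truncation == "none" or t.cds_start is None:
        return 0, L, "none"
    stop_start = t.cds_end - 3
    if truncation == "three_prime":
        lo = t.cds_start + 3 + 3 * min_codons
        if lo >= stop_start:
            return 0, L, "none"
        end = int(rng.integers(lo, stop_start))  # strictly before the stop codon
        return 0, end, "three_prime"
    if truncation == "five_prime":
        hi = stop_start - 3 * min_codons
        if hi <= t.cds_start + 1:
            return 0, L, "none"
        start = int(rng.integers(t.cds_start + 1, hi))  # strictly after the start
        return start, L, "five_prime"
    # internal
    lo = t.cds_start + 1
    hi = stop_start - 3 * min_codons
    if hi <= lo:
        return 0, L, "none"
    start = int(rng.integers(lo, hi))
    end = int(rng.integers(start + 3 * min_codons, stop_start))
    return start, end, "internal"


def simulate_molecules(
    reference: ToyReference, design: ExperimentDesign
) -> tuple[list[SimulatedRead], list[MoleculeTruth], list[SamSegment]]:
    """Emit reads, molecule truth, and truth alignment segments.

    Molecule counts per (cell, feature) are Poisson around the design
    expectation.  PCR duplicates are extra reads sharing (barcode, UMI,
    feature); truth has one record per distinct molecule.
    """
    design.validate(reference)
    rng = np.random.default_rng(design.seed)
    reads: list[SimulatedRead] = []
    truth: list[MoleculeTruth] = []
    segments: list[SamSegment] = []
    counter = 0
    used_umis: set[tuple[str, str, str]] = set()
    tx_by_gene = {
        g.gene_id: [t.transcript_id for t in g.transcripts] for g in reference.genes
    }
    spike_tx = {tx for tx, _ in reference.spikein_designs}

    def new_umi(cell: str, feature: str) -> str:
        while True:
            umi = "".join(_BASES[rng.integers(0, 4, design.umi_length)])
            if (cell, umi, feature) not in used_umis:
                used_umis.add((cell, umi, feature))
                return umi

    def emit(read_id, cell, umi, cdna, segs, tr: MoleculeTruth):
        truth.append(tr)
        n_copies = 1 + (1 if rng.random() < design.duplicate_rate else 0)
        for c in range(n_copies):
            rid = read_id if c == 0 else f"{read_id}d{c}"
            cdna_c = cdna
            if design.substitution_rate > 0:
                arr = np.array(list(cdna))
                hit = rng.random(len(arr)) < design.substitution_rate
                if hit.any():
                    arr[hit] = _BASES[rng.integers(0, 4, int(hit.sum()))]
                    cdna_c = "".join(arr)
            reads.append(
                SimulatedRead(
                    read_id=rid,
                    barcode=cell,
                    umi=umi,
                    cdna=cdna_c,
                    is_reverse=bool(rng.random() < 0.5),
                    is_duplicate=c > 0,
                    truth=tr,
                    polya_len=design.polya_len,
                )
            )
            qname = f"{rid}|{cell}|{umi}"
            for seg in segs:
                segments.append(
                    SamSegment(
                        qname=qname,
                        chromosome=seg.chromosome,
                        strand=seg.strand,
                        blocks=seg.blocks,
                        seq=seg.seq,
                        clip_left=seg.clip_left,
                        clip_right=seg.clip_right,
                        is_supplementary=seg.is_supplementary,
                    )
                )

    cells = [bc for bc in design.whitelist if bc in design.cell_stage]
    for cell in cells:
        stage = design.cell_stage[cell]
        p3, p5 = design.truncation_rates.get(stage, (0.0, 0.0))
        for (s, feature), mean in design.expression_program.items():
            if s != stage or mean <= 0:
                continue
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            if feature in tx_by_gene:  # gene: pick isoforms by usage weights
                iso_ids = tx_by_gene[feature]
                w = design.isoform_usage.get(feature, {}).get(stage)
                probs = (
                    np.array([w.get(i, 0.0) for i in iso_ids])
                    if w
                    else np.full(len(iso_ids), 1.0)
                )
                probs = probs / probs.sum()
                choices = rng.choice(len(iso_ids), size=n, p=probs)
                for ci in choices:
                    counter += 1
                    t = reference.transcript(iso_ids[ci])
                    trunc = _sample_truncation(rng, p3, p5)
                    t0, t1, trunc = _truncate_interval(
                        rng, t, trunc, design.min_kept_codons
                    )
                    seq = t.sequence(reference.chromosomes)[t0:t1]
                    blocks = t.transcript_interval_to_genomic(t0, t1)
                    geno_seq = "".join(
                        reference.chromosomes[t.chromosome][a:b] for a, b in blocks
                    )
                    umi = new_umi(cell, t.transcript_id)
                    rid = f"m{counter:07d}"
                    tr = MoleculeTruth(
                        read_id=rid,
                        cell_barcode=cell,
                        umi=umi,
                        source_feature=t.transcript_id,
                        feature_kind="spikein" if t.transcript_id in spike_tx else "isoform",
                        gene_id=t.gene_id,
                        stage=stage,
                        truncation=trunc,
                    )
                    seg = SamSegment(
                        qname="", chromosome=t.chromosome, strand=t.strand,
                        blocks=blocks, seq=geno_seq,
                    )
                    emit(rid, cell, umi, seq, [seg], tr)
            elif feature.startswith("SPIKE") or feature in spike_tx:
                t = reference.transcript(feature)
                for _ in range(n):
                    counter += 1
                    seq = t.sequence(reference.chromosomes)
                    blocks = list(t.exons)
                    geno_seq = "".join(
                        reference.chromosomes[t.chromosome][a:b] for a, b in blocks
                    )
                    umi = new_umi(cell, feature)
                    rid = f"m{counter:07d}"
                    tr = MoleculeTruth(
                        read_id=rid, cell_barcode=cell, umi=umi,
                        source_feature=feature, feature_kind="spikein",
                        gene_id=t.gene_id, stage=stage, truncation="none",
                    )
                    seg = SamSegment(
                        qname="", chromosome=t.chromosome, strand=t.strand,
                        blocks=blocks, seq=geno_seq,
                    )
                    emit(rid, cell, umi, seq, [seg], tr)
            else:  # TE locus
                te = reference.te_locus(feature)
                for _ in range(n):
                    counter += 1
                    length = int(
                        rng.integers(min(200, te.length), min(1200, te.length) + 1)
                    )
                    start = te.start + int(rng.integers(0, te.length - length + 1))
                    seq = reference.chromosomes[te.chromosome][start : start + length]
                    umi = new_umi(cell, feature)
                    rid = f"m{counter:07d}"
                    tr = MoleculeTruth(
                        read_id=rid, cell_barcode=cell, umi=umi,
                        source_feature=feature, feature_kind="te_locus",
                        gene_id=None, stage=stage, truncation="none",
                    )
                    seg = SamSegment(
                        qname="", chromosome=te.chromosome, strand="+",
                        blocks=[(start, start + length)], seq=seq,
                    )
                    emit(rid, cell, umi, seq, [seg], tr)

        # chimeric molecules: TE segment (5') + full gene transcript (3')
        for te_id, gene_id, mean in design.chimera_pairs:
            n = int(rng.poisson(mean))
            for _ in range(n):
                counter += 1
                te = reference.te_locus(te_id)
                t = reference.transcript(tx_by_gene[gene_id][0])
                te_len = int(rng.integers(min(250, te.length), min(700, te.length) + 1))
                te_start = te.start + int(rng.integers(0, te.length - te_len + 1))
                te_seq = reference.chromosomes[te.chromosome][te_start : te_start + te_len]
                gene_seq = t.sequence(reference.chromosomes)
                cdna = te_seq + gene_seq
                umi = new_umi(cell, f"{te_id}~{gene_id}")
                rid = f"m{counter:07d}"
                tr = MoleculeTruth(
                    read_id=rid, cell_barcode=cell, umi=umi,
                    source_feature=t.transcript_id, feature_kind="chimera",
                    gene_id=gene_id, stage=stage, truncation="none",
                    chimera_partner=te_id,
                )
                gene_geno = "".join(
                    reference.chromosomes[t.chromosome][a:b] for a, b in t.exons
                )
                # SAM SEQ is the whole read in genome orientation
                if t.strand == "+":
                    primary = SamSegment(
                        qname="", chromosome=t.chromosome, strand="+",
                        blocks=list(t.exons), seq=te_seq + gene_geno,
                        clip_left=te_len,
                    )
                else:
                    primary = SamSegment(
                        qname="", chromosome=t.chromosome, strand="-",
                        blocks=list(t.exons), seq=gene_geno + revcomp(te_seq),
                        clip_right=te_len,
                    )
                supp = SamSegment(
                    qname="", chromosome=te.chromosome, strand="+",
                    blocks=[(te_start, te_start + te_len)], seq=cdna,
                    clip_right=len(gene_seq), is_supplementary=True,
                )
                emit(rid, cell, umi, cdna, [primary, supp], tr)

    return reads, truth, segments


def corrupt_barcodes(
    reads: list[SimulatedRead], rate: float, seed: int
) -> list[SimulatedRead]:
    """Substitute one barcode position in a Bernoulli(rate) subset of reads.

    The truth record keeps the original barcode; the read carries the
    corrupted one.  Reads are modified in place and returned.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    for read in reads:
        read.truth.observed_barcode = read.truth.cell_barcode
        if rng.random() < rate:
            bc = list(read.barcode)
            pos = int(rng.integers(0, len(bc)))
            alt = [b for b in "ACGT" if b != bc[pos]]
            bc[pos] = alt[int(rng.integers(0, 3))]
            read.barcode = "".join(bc)
            read.truth.observed_barcode = read.barcode
    return reads


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            seq = r.sequence()
            fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def truth_alignments_in_memory(segments: list[SamSegment]) -> list[SplicedAlignment]:
    """Convert truth segments to SplicedAlignment records without SAM I/O."""
    out = []
    for seg in segments:
        out.append(
            SplicedAlignment(
                read_id=seg.qname.split("|")[0],
                chromosome=seg.chromosome,
                strand=seg.strand,
                blocks=list(seg.blocks),
                is_primary=not seg.is_supplementary,
                is_supplementary=seg.is_supplementary,
                mapq=seg.mapq,
            )
        )
    mark_supplementary_pairs(out)
    return out


def write_truth_tables(
    truth: list[MoleculeTruth], design: ExperimentDesign, directory: str | Path
) -> dict[str, Path]:
    """TSV outputs for molecule truth, planted features, switches, chimeras."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    mol = pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "cell_barcode": t.cell_barcode,
                "observed_barcode": t.observed_barcode or t.cell_barcode,
                "umi": t.umi,
                "source_feature": t.source_feature,
                "feature_kind": t.feature_kind,
                "gene_id": t.gene_id or "",
                "stage": t.stage,
                "truncation": t.truncation,
                "chimera_partner": t.chimera_partner or "",
            }
            for t in truth
        ],
        columns=[
            "read_id", "cell_barcode", "observed_barcode", "umi", "source_feature",
            "feature_kind", "gene_id", "stage", "truncation", "chimera_partner",
        ],
    )
    paths["molecules"] = directory / "truth_molecules.tsv"
    mol.to_csv(paths["molecules"], sep="\t", index=False)

    spec = pd.DataFrame(
        [
            {"feature_id": f, "peak_stage": s, "fold_change": fc}
            for f, (s, fc) in design.planted_stage_specific.items()
        ],
        columns=["feature_id", "peak_stage", "fold_change"],
    )
    paths["stage_specific"] = directory / "truth_stage_specific.tsv"
    spec.to_csv(paths["stage_specific"], sep="\t", index=False)

    sw = pd.DataFrame(
        design.planted_switches,
        columns=["gene_id", "isoform_a", "isoform_b", "stage_boundary"],
    )
    paths["switches"] = directory / "truth_switches.tsv"
    sw.to_csv(paths["switches"], sep="\t", index=False)

    ch = pd.DataFrame(
        design.chimera_pairs, columns=["te_locus_id", "gene_id", "expected_per_cell"]
    )
    paths["chimeras"] = directory / "truth_chimeras.tsv"
    ch.to_csv(paths["chimeras"], sep="\t", index=False)
    return paths


def load_truth_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    names = {
        "molecules": "truth_molecules.tsv",
        "stage_specific": "truth_stage_specific.tsv",
        "switches": "truth_switches.tsv",
        "chimeras": "truth_chimeras.tsv",
    }
    return {
        k: pd.read_csv(directory / v, sep="\t", keep_default_na=False)
        for k, v in names.items()
    }
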