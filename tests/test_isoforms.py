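"""Collapse, structural classing, CAGE support, ORF prediction — vs oracles."""

import numpy as np
import pytest

import scisote as sc
from scisote.alignments import SplicedAlignment
from scisote.isoforms import isoform_sequence, predict_orf
from scisote.reference import STOP_CODONS, CagePeak


def aln(read_id, blocks, strand="+", chrom="chr1", **kw):
    return SplicedAlignment(
        read_id=read_id, chromosome=chrom, strand=strand, blocks=blocks, **kw
    )


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_identical_chains_merge_despite_end_jitter(self):
        a = aln("r1", [(100, 200), (300, 400), (500, 600), (700, 820)])
        b = aln("r2", [(110, 200), (300, 400), (500, 600), (700, 800)])
        isos = sc.collapse_isoforms([a, b])
        assert len(isos) == 1
        assert isos[0].support_read_ids == ["r1", "r2"]
        # terminal ends follow the cluster seed (leftmost read)
        assert isos[0].span == (100, 820)

    def test_five_prime_shorter_suffix_not_merged(self):
        # B's chain is the last 2 introns of A's 3-intron chain, same 3' end
        a = aln("rA", [(0, 100), (200, 300), (400, 500), (600, 700)])
        b = aln("rB", [(210, 300), (400, 500), (600, 700)])
        isos = sc.collapse_isoforms([a, b])
        assert len(isos) == 2

    def test_end_jitter_beyond_tolerance_not_merged(self):
        a = aln("r1", [(100, 200), (300, 400)])
        b = aln("r2", [(100, 200), (300, 480)])  # 3' ends differ by 80 > 50
        assert len(sc.collapse_isoforms([a, b])) == 2

    def test_mono_exon_reciprocal_overlap(self):
        a = aln("r1", [(100, 300)])
        b = aln("r2", [(150, 320)])  # reciprocal overlap > 0.5
        c = aln("r3", [(290, 700)])  # overlap with a is tiny
        isos = sc.collapse_isoforms([a, b, c])
        assert len(isos) == 2

    def test_empty_input(self):
        assert sc.collapse_isoforms([]) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_quadratic_all_pairs_oracle(self, seed):
        """Random instances built so cluster membership is unambiguous:
        terminal jitter < tol/2 within a cluster, >2*tol between clusters."""
        rng = np.random.default_rng(seed)
        junction_pool = [
            (int(s), int(s) + int(g))
            for s, g in zip(
                rng.choice(np.arange(1000, 50000, 500), 12, replace=False),
                rng.integers(100, 400, 12),
            )
        ]
        reads = []
        used_chains = set()
        for ci in range(rng.integers(3, 8)):
            for _ in range(50):
                njunc = int(rng.integers(1, 4))
                start_j = int(rng.integers(0, len(junction_pool) - njunc))
                chain = tuple(sorted(junction_pool[start_j : start_j + njunc]))
                if chain not in used_chains:
                    used_chains.add(chain)
                    break
            else:
                continue
            base_start = chain[0][0] - int(rng.integers(200, 400))
            base_end = chain[-1][1] + int(rng.integers(200, 400))
            for ri in range(int(rng.integers(1, 6))):
                s = base_start + int(rng.integers(-20, 21))
                e = base_end + int(rng.integers(-20, 21))
                reads.append(aln(f"c{ci}_r{ri}", _blocks(chain, s, e)))
        isos = sc.collapse_isoforms(reads)
        got = {frozenset(i.support_read_ids) for i in isos}
        # oracle: union-find over the pairwise merge predicate
        expected = _oracle_partition(reads, tol=50)
        assert got == expected

    def test_idempotent(self, pipeline_result):
        isos = pipeline_result.isoforms
        realn = [
            aln(i.isoform_id, i.exon_blocks, strand=i.strand, chrom=i.chromosome)
            for i in isos
        ]
        again = sc.collapse_isoforms(realn)
        assert len(again) == len(isos)
        assert {tuple(i.exon_blocks) for i in again} == {
            tuple(i.exon_blocks) for i in isos
        }

    def test_read_conservation(self, pipeline_result):
        # every supporting read maps to exactly one isoform
        seen = []
        for i in pipeline_result.isoforms:
            seen.extend(i.support_read_ids)
        assert len(seen) == len(set(seen))


def _blocks(chain, start, end):
    blocks = [(start, chain[0][0])]
    blocks += [(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)]
    blocks.append((chain[-1][1], end))
    return blocks


def _oracle_partition(reads, tol):
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if a.junctions != b.junctions:
                continue
            if a.junctions:
                close = (
                    abs(a.span[0] - b.span[0]) <= tol
                    and abs(a.span[1] - b.span[1]) <= tol
                )
            else:
                inter = min(a.span[1], b.span[1]) - max(a.span[0], b.span[0])
                close = inter > 0 and (
                    inter / (a.span[1] - a.span[0]) >= 0.5
                    and inter / (b.span[1] - b.span[0]) >= 0.5
                )
            if close:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(reads[i].read_id)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# structural classification
# ---------------------------------------------------------------------------

class TestStructuralClass:
    def test_against_brute_force_on_pipeline_isoforms(
        self, toy_reference, pipeline_result
    ):
        for iso in pipeline_result.isoforms:
            got = iso.structural_class
            assert got == _brute_force_class(iso, toy_reference)

    def test_exact_chain_is_fsm(self, toy_reference):
        t = next(toy_reference.transcripts())
        iso = sc.IsoformModel(
            "PB.1.1", t.chromosome, t.strand, list(t.exons), ["r"]
        )
        cls, gene = sc.classify_structural(iso, toy_reference.genes)
        assert cls == "FSM" and gene == t.gene_id

    def test_consecutive_subchain_is_ism(self, toy_reference):
        t = next(
            x for x in toy_reference.transcripts() if len(x.exons) >= 4
        )
        introns = t.introns[1:3]
        blocks = [
            (introns[0][0] - 50, introns[0][0]),
            (introns[0][1], introns[1][0]),
            (introns[1][1], introns[1][1] + 50),
        ]
        iso = sc.IsoformModel("PB.1.1", t.chromosome, t.strand, blocks, ["r"])
        cls, _ = sc.classify_structural(iso, toy_reference.genes)
        assert cls == "ISM"

    def test_novel_combination_is_nic(self, toy_reference):
        t = next(
            x for x in toy_reference.transcripts() if len(x.exons) >= 4
        )
        # skip one junction of the reference chain: all sites known,
        # chain novel unless it matches an annotated variant
        chain = (t.introns[0], t.introns[2])
        blocks = _blocks(chain, t.span[0], t.span[1])
        iso = sc.IsoformModel("PB.1.1", t.chromosome, t.strand, blocks, ["r"])
        cls, _ = sc.classify_structural(iso, toy_reference.genes)
        assert cls == _brute_force_class(iso, toy_reference)
        assert cls in ("NIC", "FSM", "ISM")

    def test_novel_splice_site_is_nnc(self, toy_reference):
        t = next(toy_reference.transcripts())
        d, a = t.introns[0]
        chain = ((d + 7, a),)  # shifted donor: novel site
        blocks = _blocks(chain, t.span[0], t.span[1])
        iso = sc.IsoformModel("PB.1.1", t.chromosome, t.strand, blocks, ["r"])
        cls, _ = sc.classify_structural(iso, toy_reference.genes)
        assert cls == "NNC"

    def test_antisense_and_intergenic_are_other(self, toy_reference):
        t = next(toy_reference.transcripts())
        anti = sc.IsoformModel(
            "PB.1.1", t.chromosome, "-" if t.strand == "+" else "+",
            list(t.exons), ["r"],
        )
        assert sc.classify_structural(anti, toy_reference.genes)[0] == "other"
        clen = len(toy_reference.chromosomes["chrU"])
        inter = sc.IsoformModel(
            "PB.1.1", "chrU", "+", [(clen - 500, clen - 100)], ["r"]
        )
        assert sc.classify_structural(inter, toy_reference.genes)[0] == "other"

    def test_classes_partition_isoform_set(self, pipeline_result):
        for iso in pipeline_result.isoforms:
            assert iso.structural_class in ("FSM", "ISM", "NIC", "NNC")


def _brute_force_class(iso, reference):
    same = [
        g
        for g in reference.genes
        if g.chromosome == iso.chromosome
        and g.strand == iso.strand
        and g.span[0] < iso.span[1]
        and iso.span[0] < g.span[1]
    ]
    if not same:
        return "other"
    chains, donors, acceptors, exons = [], set(), set(), []
    for g in same:
        for t in g.transcripts:
            chains.append((t.introns, len(t.exons)))
            for d, a in t.introns:
                donors.add(d)
                acceptors.add(a)
            exons.append((t.exons, len(t.exons)))
    chain = iso.intron_chain
    if not chain:
        hit = None
        for exon_list, n in exons:
            for es, ee in exon_list:
                if es < iso.span[1] and iso.span[0] < ee:
                    if hit != "FSM":
                        hit = "FSM" if n == 1 else "ISM"
        return hit or "other"
    if any(chain == c for c, _ in chains):
        return "FSM"
    for c, _ in chains:
        for k in range(len(c) - len(chain) + 1):
            if c[k : k + len(chain)] == chain:
                return "ISM"
    if all(d in donors and a in acceptors for d, a in chain):
        return "NIC"
    return "NNC"


# ---------------------------------------------------------------------------
# CAGE support
# ---------------------------------------------------------------------------

class TestCageSupport:
    PEAKS = [CagePeak("chr1", 1000, 1050, "+"), CagePeak("chr1", 5000, 5050, "-")]

    def iso(self, start, end, strand="+"):
        return sc.IsoformModel("PB.1.1", "chr1", strand, [(start, end)], ["r"])

    def test_five_prime_end_at_peak_edge(self):
        assert sc.flag_cage_support(self.iso(1000, 2000), self.PEAKS)

    def test_distance_200_supported_201_not(self):
        assert sc.flag_cage_support(self.iso(1250 - 1, 2000), self.PEAKS)
        # peak ends at 1049 (last base); 5' end at 1049+201 is out of range
        assert not sc.flag_cage_support(self.iso(1049 + 201, 2000), self.PEAKS)

    def test_strand_aware(self):
        assert not sc.flag_cage_support(self.iso(1000, 2000, "-"), self.PEAKS)
        assert sc.flag_cage_support(self.iso(4000, 5020, "-"), self.PEAKS)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = [
            CagePeak(
                "chr1",
                int(s),
                int(s) + int(rng.integers(20, 80)),
                "+" if rng.random() < 0.5 else "-",
            )
            for s in rng.integers(0, 100_000, 30)
        ]
        for _ in range(200):
            start = int(rng.integers(0, 100_000))
            strand = "+" if rng.random() < 0.5 else "-"
            iso = self.iso(start, start + 500, strand)
            pos = iso.five_prime_position
            oracle = any(
                p.strand == strand
                and (
                    p.start <= pos < p.end
                    or min(abs(pos - p.start), abs(pos - (p.end - 1))) <= 200
                )
                for p in peaks
            )
            assert sc.flag_cage_support(iso, peaks) == oracle


# ---------------------------------------------------------------------------
# ORF prediction and typing
# ---------------------------------------------------------------------------

class TestPredictORF:
    def test_embedded_complete_orf(self):
        seq = "CCCCCC" + "ATG" + "AAA" * 5 + "TGA" + "CCCCCC"
        orf = predict_orf(seq, min_length_aa=2)
        assert orf.has_start_codon and orf.has_stop_codon
        assert orf.length_aa == 6  # ATG + 5 codons
        assert sc.classify_orf_type(orf) == "complete"

    def test_orf_running_off_three_prime_end(self):
        # early stops in the other frames keep their candidates short;
        # the ATG-initiated ORF runs off the 3' end with no stop
        seq = "CTAAGTGAC" + "ATG" + "CAA" * 12
        orf = predict_orf(seq, min_length_aa=2)
        assert orf.has_start_codon and not orf.has_stop_codon
        assert orf.orf_start == 9
        assert sc.classify_orf_type(orf) == "three_prime_partial"

    def test_open_five_prime(self):
        # frame 0: no ATG, one stop near the end -> 5'-open candidate wins;
        # frames 1/2 carry early stops and no ATG at all
        seq = "CTAAGTGAC" + "CAA" * 15 + "TAA"
        orf = predict_orf(seq, min_length_aa=2)
        assert not orf.has_start_codon and orf.has_stop_codon
        assert orf.orf_start == 0 and orf.length_aa == len(seq) // 3 - 1
        assert sc.classify_orf_type(orf) == "five_prime_partial"

    def test_below_threshold_is_others(self):
        orf = predict_orf("ATGAAATGA", min_length_aa=100)
        assert orf.below_threshold
        assert sc.classify_orf_type(orf) == "others"

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            predict_orf("ATGXXX")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 400))))
            got = predict_orf(seq, min_length_aa=1)
            exp = _enumerate_best_orf(seq)
            assert (
                got.orf_start, got.orf_end, got.has_start_codon,
                got.has_stop_codon, got.length_aa,
            ) == exp


def _enumerate_best_orf(seq):
    """Exhaustive candidate enumeration, independent of the scanner."""
    cands = []
    n = len(seq)
    for frame in range(3):
        codons = [(i, seq[i : i + 3]) for i in range(frame, n - 2, 3)]
        stops = [i for i, c in codons if c in STOP_CODONS]
        bounds = [frame] + [i + 3 for i in stops]
        for bi, seg_start in enumerate(bounds):
            seg_stop = stops[bi] if bi < len(stops) else None
            seg_end = (seg_stop + 3) if seg_stop is not None else frame + 3 * (
                (n - frame) // 3
            )
            atgs = [
                i for i, c in codons if c == "ATG" and seg_start <= i < seg_end
            ]
            if atgs:
                start = atgs[0]
                has_start = True
            elif seg_start == frame:
                start = seg_start
                has_start = False
            else:
                continue
            has_stop = seg_stop is not None
            aa = (seg_end - start) // 3 - (1 if has_stop else 0)
            if aa > 0:
                cands.append((-aa, start, frame, seg_end, has_start, has_stop, aa))
    if not cands:
        return (0, 0, False, False, 0)
    cands.sort()
    neg, start, frame, end, has_start, has_stop, aa = cands[0]
    return (start, end, has_start, has_stop, aa)


class TestORFTypeRecovery:
    def test_truncation_truth_recovered(self, small_simulation, pipeline_result):
        _, truth, _ = small_simulation
        tmap = {
            "none": "complete",
            "three_prime": "three_prime_partial",
            "five_prime": "five_prime_partial",
            "internal": "internal",
        }
        tr = {t.read_id: t for t in truth}
        agree = total = 0
        for rid, got in pipeline_result.molecule_orf_types.items():
            t = tr.get(rid.split("d")[0])
            if t is None or t.feature_kind not in ("isoform", "spikein"):
                continue
            total += 1
            agree += got == tmap[t.truncation]
        assert total > 500
        assert agree / total >= 0.99
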