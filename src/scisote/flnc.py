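"""Full-length read identification, barcode/UMI handling, deduplication.

A full-length non-concatemer (FLNC) read carries both the 5' and the 3'
amplification primer in the expected orientation; the cell barcode and UMI
sit immediately after the 5' primer and the polyA tail is trimmed from the
insert.  Barcode correction is Hamming-distance-1 against a whitelist with a
unique-neighbour requirement; UMI collapse is exact-match (HiFi-grade reads
make 1-mismatch UMI clustering unnecessary).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .reference import revcomp
from .simulate import PRIMER_3, PRIMER_5


@dataclass
class FLNCRecord:
    read_id: str
    fl_status: str  # FL | non-FL | unknown
    raw_barcode: str | None = None
    umi: str | None = None
    insert_sequence: str | None = None  # 5'->3', primers/BC/UMI/polyA trimmed
    corrected_barcode: str | None = None
    barcode_status: str = "none"  # exact | corrected | dropped | none
    was_reverse: bool = False


@dataclass
class LibraryStats:
    n_reads: int
    n_fl: int
    n_non_fl: int
    n_unknown: int
    n_cb_in_whitelist: int
    n_cb_corrected: int

    @property
    def pct_fl(self) -> float:
        return 100.0 * self.n_fl / self.n_reads if self.n_reads else 0.0

    @property
    def pct_non_fl(self) -> float:
        return 100.0 * self.n_non_fl / self.n_reads if self.n_reads else 0.0

    @property
    def pct_unknown(self) -> float:
        return 100.0 * self.n_unknown / self.n_reads if self.n_reads else 0.0

    @property
    def n_total_assigned(self) -> int:
        return self.n_cb_in_whitelist + self.n_cb_corrected

    @property
    def pct_cb_in_whitelist(self) -> float:
        return 100.0 * self.n_cb_in_whitelist / self.n_fl if self.n_fl else 0.0

    @property
    def pct_cb_corrected(self) -> float:
        return 100.0 * self.n_cb_corrected / self.n_fl if self.n_fl else 0.0

    @property
    def pct_total_assigned(self) -> float:
        return 100.0 * self.n_total_assigned / self.n_fl if self.n_fl else 0.0

    def to_rows(self) -> list[tuple[str, float]]:
        return [
            ("n_reads", self.n_reads),
            ("FL", self.n_fl),
            ("FL (%)", round(self.pct_fl, 2)),
            ("Non-FL", self.n_non_fl),
            ("Non-FL (%)", round(self.pct_non_fl, 2)),
            ("Unknown", self.n_unknown),
            ("Unknown (%)", round(self.pct_unknown, 2)),
            ("CB in Whitelist", self.n_cb_in_whitelist),
            ("CB in Whitelist (%)", round(self.pct_cb_in_whitelist, 2)),
            ("CB Correction", self.n_cb_corrected),
            ("CB Correction (%)", round(self.pct_cb_corrected, 2)),
            ("Total Corrected CB", self.n_total_assigned),
            ("Total Corrected CB (%)", round(self.pct_total_assigned, 2)),
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.to_rows():
                fh.write(f"{k}\t{v}\n")


def _find_primer(seq: str, primer: str, start: int, stop: int, max_mm: int) -> int:
    """Leftmost offset in [start, stop) where primer matches with <=max_mm
    substitutions, or -1."""
    plen = len(primer)
    for off in range(max(0, start), min(stop, len(seq) - plen + 1)):
        mm = 0
        for a, b in zip(seq[off : off + plen], primer):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return off
    return -1


def _trim_polya(insert: str, min_run: int = 10) -> str:
    """Trim a terminal polyA run of at least ``min_run`` A's."""
    i = len(insert)
    while i > 0 and insert[i - 1] == "A":
        i -= 1
    if len(insert) - i >= min_run:
        return insert[:i]
    return insert


def identify_flnc(
    read_id: str,
    sequence: str,
    primer_5: str = PRIMER_5,
    primer_3: str = PRIMER_3,
    max_mismatch: int = 2,
    barcode_length: int = 16,
    umi_length: int = 10,
    polya_min_run: int = 10,
    search_slop: int = 10,
) -> FLNCRecord:
    """Classify a read as FL / non-FL / unknown and extract BC/UMI/insert.

    Orientation is inferred by looking for the 5' primer near the read start
    and the 3' primer near the read end, in both the given and the
    reverse-complement orientation.  Both primers present -> FL; exactly one
    -> non-FL; neither -> unknown.
    """
    if not sequence:
        raise ValueError("empty read")

    def scan(seq: str) -> tuple[int, int]:
        p5 = _find_primer(seq, primer_5, 0, search_slop + 1, max_mismatch)
        p3 = _find_primer(
            seq,
            primer_3,
            len(seq) - len(primer_3) - search_slop,
            len(seq) - len(primer_3) + 1,
            max_mismatch,
        )
        return p5, p3

    fwd5, fwd3 = scan(sequence)
    rev_seq = revcomp(sequence)
    rev5, rev3 = scan(rev_seq)
    fwd_hits = (fwd5 >= 0) + (fwd3 >= 0)
    rev_hits = (rev5 >= 0) + (rev3 >= 0)
    if max(fwd_hits, rev_hits) == 0:
        return FLNCRecord(read_id=read_id, fl_status="unknown")
    if rev_hits > fwd_hits:
        seq, p5, p3, was_rev = rev_seq, rev5, rev3, True
    else:
        seq, p5, p3, was_rev = sequence, fwd5, fwd3, False
    if p5 < 0 or p3 < 0:
        return FLNCRecord(read_id=read_id, fl_status="non-FL", was_reverse=was_rev)

    bc_start = p5 + len(primer_5)
    raw_bc = seq[bc_start : bc_start + barcode_length]
    umi = seq[bc_start + barcode_length : bc_start + barcode_length + umi_length]
    insert = seq[bc_start + barcode_length + umi_length : p3]
    insert = _trim_polya(insert, min_run=polya_min_run)
    return FLNCRecord(
        read_id=read_id,
        fl_status="FL",
        raw_barcode=raw_bc,
        umi=umi,
        insert_sequence=insert,
        was_reverse=was_rev,
    )


def correct_barcode(
    raw: str, whitelist: set[str] | frozenset[str]
) -> tuple[str | None, str]:
    """Whitelist barcode correction at Hamming distance <= 1.

    Exact member -> ``exact``; otherwise a unique whitelist member at
    distance 1 -> ``corrected``; ambiguous or distant -> ``dropped``.
    """
    wl_lens = {len(b) for b in whitelist}
    if wl_lens and len(raw) not in wl_lens:
        raise ValueError("barcode length does not match whitelist")
    if raw in whitelist:
        return raw, "exact"
    hit = None
    for pos in range(len(raw)):
        for base in "ACGT":
            if base == raw[pos]:
                continue
            cand = raw[:pos] + base + raw[pos + 1 :]
            if cand in whitelist:
                if hit is not None and hit != cand:
                    return None, "dropped"
                hit = cand
    if hit is not None:
        return hit, "corrected"
    return None, "dropped"


def process_reads(
    reads: list[tuple[str, str]],
    whitelist: set[str],
    **flnc_kwargs,
) -> list[FLNCRecord]:
    """identify_flnc + correct_barcode over (read_id, sequence) pairs."""
    whitelist = frozenset(whitelist)
    records = []
    for read_id, seq in reads:
        rec = identify_flnc(read_id, seq, **flnc_kwargs)
        if rec.fl_status == "FL":
            corrected, status = correct_barcode(rec.raw_barcode, whitelist)
            rec.corrected_barcode = corrected
            rec.barcode_status = status
        records.append(rec)
    return records


def deduplicate_molecules(
    records: list[tuple[str, str, str]],
) -> dict[tuple[str, str], int]:
    """UMI-collapse (barcode, umi, feature) triples to molecule counts.

    Returns counts per (barcode, feature): the number of distinct UMIs.
    """
    molecules = {(bc, umi, feat) for bc, umi, feat in records}
    counts: Counter[tuple[str, str]] = Counter()
    for bc, _, feat in molecules:
        counts[(bc, feat)] += 1
    return dict(counts)


def summarize_library(records: list[FLNCRecord]) -> LibraryStats:
    n = len(records)
    n_fl = sum(r.fl_status == "FL" for r in records)
    n_non = sum(r.fl_status == "non-FL" for r in records)
    n_unk = sum(r.fl_status == "unknown" for r in records)
    n_exact = sum(r.barcode_status == "exact" for r in records)
    n_corr = sum(r.barcode_status == "corrected" for r in records)
    return LibraryStats(
        n_reads=n,
        n_fl=n_fl,
        n_non_fl=n_non,
        n_unknown=n_unk,
        n_cb_in_whitelist=n_exact,
        n_cb_corrected=n_corr,
    )


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_whitelist(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_flnc_fasta(records: list[FLNCRecord], path: str | Path) -> None:
    """FLNC inserts with ``read_id|CB|UMI`` naming (assigned FL reads only)."""
    with open(path, "w") as fh:
        for r in records:
            if r.fl_status == "FL" and r.corrected_barcode:
                fh.write(
                    f">{r.read_id}|{r.corrected_barcode}|{r.umi}\n"
                    f"{r.insert_sequence}\n"
                )
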