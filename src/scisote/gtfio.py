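"""Minimal GTF reading into gene models (exon features, 1-based inclusive)."""

from __future__ import annotations

import re
from pathlib import Path

from .reference import GeneModel, TranscriptModel

_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Build gene models from a GTF's exon lines (CDS annotation ignored)."""
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                continue
            rec = tx.setdefault(
                tid,
                {"gene": gid, "chrom": f[0], "strand": f[6], "exons": []},
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    genes: dict[str, list[TranscriptModel]] = {}
    for tid, rec in tx.items():
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene"],
            chromosome=rec["chrom"],
            strand=rec["strand"],
            exons=sorted(rec["exons"]),
        )
        genes.setdefault(rec["gene"], []).append(model)
    return [
        GeneModel(
            gene_id=gid,
            chromosome=models[0].chromosome,
            strand=models[0].strand,
            transcripts=sorted(models, key=lambda t: t.transcript_id),
        )
        for gid, models in sorted(genes.items())
    ]
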