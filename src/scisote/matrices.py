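"""Single-cell UMI matrices: construction, CPM/10 normalization, QC, spike-ins.

Counts are UMI-collapsed molecules per (cell, feature).  Normalization is
copy number per 100,000 mapped molecules per cell (CPM/10).  Isoform
matrices drop features detected in fewer than 5 cells, matching the
pipeline's detection-confidence filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import pearsonr


@dataclass
class CellFeatureMatrix:
    """Sparse cells x features UMI-count matrix with optional stage labels."""

    cells: list[str]
    features: list[str]
    counts: sp.csr_matrix  # integer, cells x features
    kind: str  # gene | isoform | te_locus | spikein
    stages: dict[str, str] = field(default_factory=dict)  # cell -> stage
    normalized: sp.csr_matrix | None = None  # CPM/10

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cell_index(self, cell: str) -> int:
        return self.cells.index(cell)

    def feature_index(self, feature: str) -> int:
        return self.features.index(feature)

    def total_molecules(self) -> int:
        return int(self.counts.sum())

    def to_dense_frame(self, normalized: bool = False) -> pd.DataFrame:
        m = self.normalized if normalized else self.counts
        if m is None:
            raise ValueError("matrix not normalized yet")
        return pd.DataFrame(
            np.asarray(m.todense()), index=self.cells, columns=self.features
        )


MIN_CELLS_PER_ISOFORM = 5


def build_matrix(
    molecule_counts: dict[tuple[str, str], int],
    kind: str,
    cells: list[str] | None = None,
    features: list[str] | None = None,
    stages: dict[str, str] | None = None,
    min_cells: int | None = None,
) -> CellFeatureMatrix:
    """Build a sparse matrix from deduplicated (barcode, feature) counts.

    Total matrix sum equals total deduplicated molecules.  For
    ``kind='isoform'`` features detected in fewer than 5 cells are removed
    (configurable via ``min_cells``).
    """
    if features is not None and len(set(features)) != len(features):
        raise ValueError("duplicate feature ids")
    if cells is None:
        cells = sorted({bc for bc, _ in molecule_counts})
    if features is None:
        features = sorted({f for _, f in molecule_counts})
    ci = {c: i for i, c in enumerate(cells)}
    fi = {f: i for i, f in enumerate(features)}
    rows, cols, data = [], [], []
    for (bc, feat), n in molecule_counts.items():
        if bc in ci and feat in fi and n:
            rows.append(ci[bc])
            cols.append(fi[feat])
            data.append(int(n))
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cells), len(features)), dtype=np.int64
    )
    if min_cells is None:
        min_cells = MIN_CELLS_PER_ISOFORM if kind == "isoform" else 0
    if min_cells > 1:
        detected = np.asarray((counts > 0).sum(axis=0)).ravel()
        keep = detected >= min_cells
        counts = counts[:, keep]
        features = [f for f, k in zip(features, keep) if k]
    return CellFeatureMatrix(
        cells=list(cells),
        features=list(features),
        counts=counts,
        kind=kind,
        stages=dict(stages or {}),
    )


def normalize_cpm10(matrix: CellFeatureMatrix) -> CellFeatureMatrix:
    """Per cell: value = count / total molecules in the cell * 100,000."""
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cell(s) have zero counts; left at zero")
    scale = np.divide(1e5, totals, out=np.zeros_like(totals), where=totals > 0)
    matrix.normalized = sp.diags(scale) @ matrix.counts.astype(float)
    matrix.normalized = sp.csr_matrix(matrix.normalized)
    return matrix


def per_cell_stats(matrix: CellFeatureMatrix) -> pd.DataFrame:
    """(cell, stage, n_features_detected, n_umis) table."""
    n_feat = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    n_umis = np.asarray(matrix.counts.sum(axis=1)).ravel()
    return pd.DataFrame(
        {
            "cell": matrix.cells,
            "stage": [matrix.stages.get(c, "") for c in matrix.cells],
            "n_features_detected": n_feat.astype(int),
            "n_umis": n_umis.astype(int),
        }
    )


def saturation_curve(
    records: list[tuple[str, str]],
    depths: list[float],
    seed: int = 0,
) -> list[tuple[float, int]]:
    """Genes detected vs sequencing depth for one cell.

    ``records`` are read-level (umi, gene) pairs of a single cell.  Reads
    are subsampled without replacement at each depth fraction with nested
    subsamples (a shallower depth is a subset of a deeper one), then
    UMI-deduplicated and distinct genes counted.
    """
    if any(not (0 < d <= 1) for d in depths):
        raise ValueError("depths must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    out = []
    for d in sorted(depths):
        k = int(round(d * len(records)))
        taken = [records[i] for i in order[:k]]
        genes = {g for _, g in {(u, g) for u, g in taken}}
        out.append((d, len(genes)))
    return out


@dataclass
class SpikeinEvaluation:
    abundance: pd.DataFrame  # spikein gene, true copies, observed UMIs
    correlation: float | None  # Pearson on log10(x+1), None if undefined
    confusion: pd.DataFrame  # truth isoform x assigned isoform molecule counts

    @property
    def off_diagonal_total(self) -> int:
        c = self.confusion.to_numpy()
        return int(c.sum() - np.trace(c))


def evaluate_spikeins(
    matrix: CellFeatureMatrix,
    designs: list[tuple[str, float]],
    isoform_assignments: list[tuple[str, str]],
    spikein_gene: callable = lambda tx: tx.rsplit(".", 1)[0],
) -> SpikeinEvaluation:
    """Spike-in abundance correlation and isoform confusion matrix.

    ``designs`` lists (spikein transcript, true copies per cell);
    ``isoform_assignments`` lists (truth transcript, assigned transcript)
    per molecule.  Correlation is Pearson on log10(x+1) between true copies
    and observed UMIs per spike-in gene, summed over cells.
    """
    true_by_gene: dict[str, float] = {}
    for tx, copies in designs:
        g = spikein_gene(tx)
        true_by_gene[g] = true_by_gene.get(g, 0.0) + copies
    obs_by_gene: dict[str, float] = {g: 0.0 for g in true_by_gene}
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    for f, tot in zip(matrix.features, totals):
        g = spikein_gene(f)
        if g in obs_by_gene:
            obs_by_gene[g] += float(tot)
    genes = sorted(true_by_gene)
    ab = pd.DataFrame(
        {
            "spikein_gene": genes,
            "true_copies_per_cell": [true_by_gene[g] for g in genes],
            "observed_umis": [obs_by_gene[g] for g in genes],
        }
    )
    levels = ab["true_copies_per_cell"].nunique()
    if levels < 3:
        warnings.warn("fewer than 3 spike-in abundance levels; correlation undefined")
        corr = None
    else:
        corr = float(
            pearsonr(
                np.log10(ab["true_copies_per_cell"] + 1),
                np.log10(ab["observed_umis"] + 1),
            )[0]
        )
    txs = sorted({tx for tx, _ in designs})
    confusion = pd.DataFrame(0, index=txs, columns=txs, dtype=int)
    for truth_tx, assigned_tx in isoform_assignments:
        if truth_tx in confusion.index and assigned_tx in confusion.columns:
            confusion.loc[truth_tx, assigned_tx] += 1
    return SpikeinEvaluation(abundance=ab, correlation=corr, confusion=confusion)


# ---------------------------------------------------------------------------
# serialization: MatrixMarket + TSV sidecars, dense TSV option
# ---------------------------------------------------------------------------

def write_matrix(matrix: CellFeatureMatrix, directory: str | Path, dense: bool = False):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), matrix.counts.tocoo())
    pd.DataFrame(
        {"cell": matrix.cells, "stage": [matrix.stages.get(c, "") for c in matrix.cells]}
    ).to_csv(directory / "barcodes.tsv", sep="\t", index=False)
    pd.DataFrame({"feature": matrix.features, "kind": matrix.kind}).to_csv(
        directory / "features.tsv", sep="\t", index=False
    )
    if dense:
        matrix.to_dense_frame().to_csv(directory / "matrix_dense.tsv", sep="\t")


def read_matrix(directory: str | Path) -> CellFeatureMatrix:
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    bc = pd.read_csv(directory / "barcodes.tsv", sep="\t", keep_default_na=False)
    ft = pd.read_csv(directory / "features.tsv", sep="\t", keep_default_na=False)
    return CellFeatureMatrix(
        cells=list(bc["cell"]),
        features=list(ft["feature"]),
        counts=counts.astype(np.int64),
        kind=str(ft["kind"].iloc[0]) if len(ft) else "gene",
        stages=dict(zip(bc["cell"], bc["stage"])),
    )
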