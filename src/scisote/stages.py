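"""Stage-specific features, isoform diversity/dominance, switches, adjacency.

Stage-specific selection tests each feature between every pair of adjacent
developmental stages: log2 fold change on pseudocounted stage means of
CPM/10 values, plus a two-sided Wilcoxon rank-sum test on per-cell values;
a feature is selected when any adjacent pair passes |logFC| > 1 and
p < 0.01, and selected features are grouped by the stage of peak mean
expression.

Isoform switching between two stages is scored per isoform by the change in
isoform fraction (dIF) of pooled stage counts and a 2x2 Fisher exact test of
(isoform, other-isoform) UMIs across the pair; gene-level p is the
Bonferroni-adjusted minimum isoform p.  Both sets are BH-adjusted, and a
switch calls requires |dIF| >= 0.1, isoform q < 0.05 and gene q < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, pearsonr, ranksums
from statsmodels.stats.multitest import multipletests

from .matrices import CellFeatureMatrix, normalize_cpm10
from .reference import GeneModel, TELocus


@dataclass
class StageDesign:
    stages: list[str]  # ordered
    cell_stage: dict[str, str]

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        unknown = set(self.cell_stage.values()) - set(self.stages)
        if unknown:
            raise ValueError(f"cells labeled with unknown stages: {unknown}")

    @property
    def adjacent_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def cells_of(self, stage: str, cells: list[str]) -> list[str]:
        return [c for c in cells if self.cell_stage.get(c) == stage]


@dataclass
class StageSpecificResult:
    feature_id: str
    kind: str
    pair_logfc: dict[tuple[str, str], float]
    pair_p: dict[tuple[str, str], float]
    selected: bool
    peak_stage: str | None
    cluster: int | None  # index of the peak stage among stages with hits


def _norm_values(matrix: CellFeatureMatrix) -> np.ndarray:
    if matrix.normalized is None:
        normalize_cpm10(matrix)
    return np.asarray(matrix.normalized.todense())


def stage_specific_features(
    matrix: CellFeatureMatrix,
    design: StageDesign,
    logfc_min: float = 1.0,
    p_max: float = 0.01,
) -> list[StageSpecificResult]:
    """Differential selection between adjacent stages + peak-stage clustering.

    logFC is computed on stage-mean CPM/10 with pseudocount 1; p from a
    two-sided rank-sum test on per-cell CPM/10 values.  Stages with fewer
    than 2 cells are skipped (with a warning) for the pairs they belong to.
    """
    values = _norm_values(matrix)
    stage_cells = {
        s: [i for i, c in enumerate(matrix.cells) if design.cell_stage.get(c) == s]
        for s in design.stages
    }
    for s, idx in stage_cells.items():
        if len(idx) < 2:
            warnings.warn(f"stage {s} has <2 cells; its pairs are skipped")
    stage_means = {
        s: values[idx].mean(axis=0) if idx else np.zeros(values.shape[1])
        for s, idx in stage_cells.items()
    }

    pair_logfc: dict[tuple[str, str], np.ndarray] = {}
    pair_p: dict[tuple[str, str], np.ndarray] = {}
    for s1, s2 in design.adjacent_pairs:
        i1, i2 = stage_cells[s1], stage_cells[s2]
        if len(i1) < 2 or len(i2) < 2:
            continue
        m1, m2 = stage_means[s1], stage_means[s2]
        pair_logfc[(s1, s2)] = np.log2((m2 + 1.0) / (m1 + 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = mannwhitneyu(
                values[i1], values[i2], alternative="two-sided", axis=0
            ).pvalue
        pair_p[(s1, s2)] = np.asarray(p)

    results = []
    mean_mat = np.vstack([stage_means[s] for s in design.stages])
    for j, feat in enumerate(matrix.features):
        lf = {pair: float(v[j]) for pair, v in pair_logfc.items()}
        pv = {pair: float(v[j]) for pair, v in pair_p.items()}
        selected = any(
            abs(lf[pair]) > logfc_min and pv[pair] < p_max for pair in lf
        )
        peak = design.stages[int(np.argmax(mean_mat[:, j]))] if selected else None
        results.append(
            StageSpecificResult(
                feature_id=feat,
                kind=matrix.kind,
                pair_logfc=lf,
                pair_p=pv,
                selected=selected,
                peak_stage=peak,
                cluster=None,
            )
        )
    # cluster index: ordered stages that have at least one peaking feature
    peaked = [s for s in design.stages if any(r.peak_stage == s for r in results)]
    cluster_of = {s: i + 1 for i, s in enumerate(peaked)}
    for r in results:
        if r.peak_stage is not None:
            r.cluster = cluster_of[r.peak_stage]
    return results


def isoform_diversity(
    isoform_matrix: CellFeatureMatrix,
    isoform_gene: dict[str, str],
    design: StageDesign,
) -> pd.DataFrame:
    """Per stage, expressed genes bucketed by number of detected isoforms.

    Categories are 1..5 and '>5'; fractions are over genes expressed in the
    stage (any isoform UMI in any of the stage's cells).
    """
    rows = []
    counts = isoform_matrix.counts
    for stage in design.stages:
        idx = [
            i
            for i, c in enumerate(isoform_matrix.cells)
            if design.cell_stage.get(c) == stage
        ]
        if not idx:
            continue
        stage_sum = np.asarray(counts[idx].sum(axis=0)).ravel()
        per_gene: dict[str, int] = {}
        for f, tot in zip(isoform_matrix.features, stage_sum):
            if tot > 0:
                g = isoform_gene.get(f)
                if g is not None:
                    per_gene[g] = per_gene.get(g, 0) + 1
        n_genes = len(per_gene)
        cat_counts = {c: 0 for c in ["1", "2", "3", "4", "5", ">5"]}
        for g, k in per_gene.items():
            cat_counts[str(k) if k <= 5 else ">5"] += 1
        for cat, n in cat_counts.items():
            rows.append(
                {
                    "stage": stage,
                    "category": cat,
                    "n_genes": n,
                    "fraction": n / n_genes if n_genes else 0.0,
                }
            )
    return pd.DataFrame(rows)


def major_isoform_ratio(
    isoform_umis: dict[str, int], min_gene_umis: int = 5
) -> float | None:
    """Major-isoform UMI fraction of a gene, or None when the gene's total
    UMI count is not above ``min_gene_umis``."""
    total = sum(isoform_umis.values())
    if total <= min_gene_umis:
        return None
    return max(isoform_umis.values()) / total


def major_isoform_ratios_per_stage(
    isoform_matrix: CellFeatureMatrix,
    isoform_gene: dict[str, str],
    design: StageDesign,
    min_gene_umis: int = 5,
) -> pd.DataFrame:
    rows = []
    for stage in design.stages:
        idx = [
            i
            for i, c in enumerate(isoform_matrix.cells)
            if design.cell_stage.get(c) == stage
        ]
        if not idx:
            continue
        stage_sum = np.asarray(isoform_matrix.counts[idx].sum(axis=0)).ravel()
        per_gene: dict[str, dict[str, int]] = {}
        for f, tot in zip(isoform_matrix.features, stage_sum):
            g = isoform_gene.get(f)
            if g is not None and tot > 0:
                per_gene.setdefault(g, {})[f] = int(tot)
        for g, umis in per_gene.items():
            r = major_isoform_ratio(umis, min_gene_umis=min_gene_umis)
            if r is not None:
                rows.append({"stage": stage, "gene_id": g, "major_isoform_ratio": r})
    return pd.DataFrame(rows)


@dataclass
class SwitchResult:
    gene_id: str
    isoform_id: str
    stage_pair: tuple[str, str]
    dif: float
    isoform_p: float
    gene_p: float
    isoform_q: float = np.nan
    gene_q: float = np.nan
    switched: bool = False


def detect_isoform_switch(
    isoform_matrix: CellFeatureMatrix,
    isoform_gene: dict[str, str],
    design: StageDesign,
    stage_pair: tuple[str, str],
    min_gene_umis: int = 10,
    min_dif: float = 0.1,
    isoform_q_max: float = 0.05,
    gene_q_max: float = 0.01,
) -> list[SwitchResult]:
    """Isoform-switch candidates between two stages (see module docstring).

    Genes with fewer than ``min_gene_umis`` pooled UMIs in either stage are
    skipped.
    """
    s1, s2 = stage_pair
    idx1 = [
        i for i, c in enumerate(isoform_matrix.cells) if design.cell_stage.get(c) == s1
    ]
    idx2 = [
        i for i, c in enumerate(isoform_matrix.cells) if design.cell_stage.get(c) == s2
    ]
    pooled1 = np.asarray(isoform_matrix.counts[idx1].sum(axis=0)).ravel()
    pooled2 = np.asarray(isoform_matrix.counts[idx2].sum(axis=0)).ravel()
    genes: dict[str, list[int]] = {}
    for j, f in enumerate(isoform_matrix.features):
        g = isoform_gene.get(f)
        if g is not None:
            genes.setdefault(g, []).append(j)

    results: list[SwitchResult] = []
    for g, cols in sorted(genes.items()):
        tot1 = int(pooled1[cols].sum())
        tot2 = int(pooled2[cols].sum())
        if tot1 < min_gene_umis or tot2 < min_gene_umis or len(cols) < 2:
            continue
        iso_ps = []
        for j in cols:
            a, b = int(pooled1[j]), tot1 - int(pooled1[j])
            c, d = int(pooled2[j]), tot2 - int(pooled2[j])
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            dif = c / tot2 - a / tot1
            iso_ps.append((j, p, dif))
        gene_p = min(1.0, min(p for _, p, _ in iso_ps) * len(cols))
        for j, p, dif in iso_ps:
            results.append(
                SwitchResult(
                    gene_id=g,
                    isoform_id=isoform_matrix.features[j],
                    stage_pair=stage_pair,
                    dif=float(dif),
                    isoform_p=p,
                    gene_p=gene_p,
                )
            )
    if results:
        iso_q = multipletests([r.isoform_p for r in results], method="fdr_bh")[1]
        gene_ps = {}
        for r in results:
            gene_ps.setdefault(r.gene_id, r.gene_p)
        gq_values = multipletests(list(gene_ps.values()), method="fdr_bh")[1]
        gene_q = dict(zip(gene_ps.keys(), gq_values))
        for r, q in zip(results, iso_q):
            r.isoform_q = float(q)
            r.gene_q = float(gene_q[r.gene_id])
            r.switched = (
                abs(r.dif) >= min_dif
                and r.isoform_q < isoform_q_max
                and r.gene_q < gene_q_max
            )
    return results


@dataclass
class AdjacencyCorrelation:
    te_locus_id: str
    gene_id: str
    distance: float  # nt; inf for different chromosomes
    relation: str  # adjacent | non_adjacent
    correlation: float | None  # None when a vector is degenerate


def te_gene_correlation(
    te_matrix: CellFeatureMatrix,
    gene_matrix: CellFeatureMatrix,
    te_loci: list[TELocus],
    genes: list[GeneModel],
    min_mean_umi: float = 5.0,
    adjacent_max: int = 10_000,
    non_adjacent_min: int = 1_000_000,
) -> list[AdjacencyCorrelation]:
    """Correlate TE-locus and gene expression across cells by adjacency.

    TE loci are restricted to those with mean UMI count > ``min_mean_umi``
    across cells.  Distance is the gap between closest interval edges (0 when
    overlapping, inf across chromosomes); pairs < 10 kb are `adjacent`,
    > 1 Mb `non_adjacent`, and anything between is excluded.  Correlation is
    Pearson on CPM/10 values over the shared cell set.
    """
    cells = [c for c in te_matrix.cells if c in set(gene_matrix.cells)]
    te_vals = _norm_values(te_matrix)
    gene_vals = _norm_values(gene_matrix)
    te_rows = [te_matrix.cells.index(c) for c in cells]
    gene_rows = [gene_matrix.cells.index(c) for c in cells]
    te_by_id = {t.locus_id: t for t in te_loci}
    mean_umi = np.asarray(te_matrix.counts.mean(axis=0)).ravel()
    out: list[AdjacencyCorrelation] = []
    for fj, locus_id in enumerate(te_matrix.features):
        if mean_umi[fj] <= min_mean_umi or locus_id not in te_by_id:
            continue
        te = te_by_id[locus_id]
        x = te_vals[te_rows, fj]
        for g in genes:
            if g.gene_id not in gene_matrix.features:
                continue
            if g.chromosome != te.chromosome:
                dist = float("inf")
            else:
                gs, ge = g.span
                dist = (
                    0.0
                    if (te.start < ge and gs < te.end)
                    else float(max(gs - te.end, te.start - ge))
                )
            if dist < adjacent_max:
                relation = "adjacent"
            elif dist > non_adjacent_min:
                relation = "non_adjacent"
            else:
                continue
            gj = gene_matrix.features.index(g.gene_id)
            y = gene_vals[gene_rows, gj]
            if np.std(x) == 0 or np.std(y) == 0:
                corr = None
            else:
                corr = float(pearsonr(x, y)[0])
            out.append(
                AdjacencyCorrelation(
                    te_locus_id=locus_id,
                    gene_id=g.gene_id,
                    distance=dist,
                    relation=relation,
                    correlation=corr,
                )
            )
    return out


def compare_adjacency(
    correlations: list[AdjacencyCorrelation],
) -> tuple[float, float, float]:
    """(mean adjacent r, mean non-adjacent r, rank-sum p) over defined pairs."""
    adj = [c.correlation for c in correlations if c.relation == "adjacent" and c.correlation is not None]
    non = [c.correlation for c in correlations if c.relation == "non_adjacent" and c.correlation is not None]
    if not adj or not non:
        raise ValueError("need both adjacent and non-adjacent correlations")
    stat, p = ranksums(adj, non)
    return float(np.mean(adj)), float(np.mean(non)), float(p)
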