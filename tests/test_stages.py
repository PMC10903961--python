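"""Stage-specific selection, diversity, dominance, switches, adjacency."""

import numpy as np
import pytest
import scipy.sparse as sp

import scisote as sc
from scisote.matrices import CellFeatureMatrix
from scisote.stages import (
    StageDesign,
    compare_adjacency,
    isoform_diversity,
    major_isoform_ratios_per_stage,
)


def count_matrix(counts, stages_per_cell, kind="gene", features=None):
    cells = sorted(stages_per_cell)
    features = features or sorted({f for _, f in counts})
    mat = np.zeros((len(cells), len(features)), dtype=np.int64)
    for (c, f), n in counts.items():
        mat[cells.index(c), features.index(f)] = n
    return CellFeatureMatrix(
        cells=cells,
        features=features,
        counts=sp.csr_matrix(mat),
        kind=kind,
        stages=dict(stages_per_cell),
    )


def simulate_count_matrix(
    rng, stages, cells_per_stage, n_features, n_planted, fold=8.0,
    base=(3.0, 10.0), kind="gene",
):
    """Poisson count matrix with the first ``n_planted`` features planted
    stage-specific (one peak stage each, ``fold``-times the base mean)."""
    cells, cell_stage = [], {}
    for si, s in enumerate(stages):
        for k in range(cells_per_stage):
            c = f"{s}_c{k}"
            cells.append(c)
            cell_stage[c] = s
    lam = rng.uniform(*base, n_features)
    peaks = rng.integers(0, len(stages), n_features)
    mat = np.zeros((len(cells), n_features))
    truth_peak = {}
    for j in range(n_features):
        for i, c in enumerate(cells):
            si = stages.index(cell_stage[c])
            mean = lam[j] * (
                fold if (j < n_planted and si == peaks[j]) else 1.0
            )
            mat[i, j] = rng.poisson(mean)
        if j < n_planted:
            truth_peak[f"F{j:04d}"] = stages[peaks[j]]
    features = [f"F{j:04d}" for j in range(n_features)]
    m = CellFeatureMatrix(
        cells=cells, features=features,
        counts=sp.csr_matrix(mat.astype(np.int64)), kind=kind, stages=cell_stage,
    )
    return m, truth_peak


STAGES8 = ["oocyte", "zygote", "E2C", "L2C", "4C", "8C", "16_32C", "blastocyst"]


class TestStageSpecific:
    def test_flat_feature_not_selected(self):
        rng = np.random.default_rng(0)
        stages = ["A", "B", "C"]
        m, _ = simulate_count_matrix(rng, stages, 10, 50, n_planted=0)
        design = StageDesign(stages, m.stages)
        res = sc.stage_specific_features(m, design)
        frac = np.mean([r.selected for r in res])
        assert frac <= 0.05

    def test_planted_jump_selected_with_correct_peak(self):
        rng = np.random.default_rng(1)
        m, truth_peak = simulate_count_matrix(
            rng, STAGES8, 20, 200, n_planted=30, fold=8.0
        )
        design = StageDesign(STAGES8, m.stages)
        res = {r.feature_id: r for r in sc.stage_specific_features(m, design)}
        planted = list(truth_peak)
        recall = np.mean([res[f].selected for f in planted])
        assert recall >= 0.9
        correct_peak = np.mean(
            [res[f].peak_stage == truth_peak[f] for f in planted if res[f].selected]
        )
        assert correct_peak >= 0.95

    def test_cluster_is_argmax_of_stage_means(self):
        rng = np.random.default_rng(2)
        m, _ = simulate_count_matrix(rng, STAGES8, 8, 100, n_planted=20)
        design = StageDesign(STAGES8, m.stages)
        res = sc.stage_specific_features(m, design)
        sc.normalize_cpm10(m)
        vals = np.asarray(m.normalized.todense())
        for r in res:
            if not r.selected:
                continue
            j = m.features.index(r.feature_id)
            means = [
                vals[[i for i, c in enumerate(m.cells) if m.stages[c] == s], j].mean()
                for s in STAGES8
            ]
            assert r.peak_stage == STAGES8[int(np.argmax(means))]

    def test_small_stage_skipped_with_warning(self):
        counts = {("a1", "F1"): 5, ("b1", "F1"): 50, ("b2", "F1"): 60}
        m = count_matrix(counts, {"a1": "A", "b1": "B", "b2": "B"})
        design = StageDesign(["A", "B"], m.stages)
        with pytest.warns(UserWarning):
            res = sc.stage_specific_features(m, design)
        assert not res[0].pair_p  # the only pair was skipped


class TestDiversityAndDominance:
    def test_categories(self):
        cell_stage = {f"c{i}": "A" for i in range(6)}
        counts = {}
        for i in range(6):  # gene G1: one isoform; G2: six isoforms
            counts[(f"c{i}", "G1.t1")] = 1
            for k in range(6):
                counts[(f"c{i}", f"G2.t{k}")] = 1
        m = count_matrix(counts, cell_stage, kind="isoform")
        iso_gene = {f: f.split(".")[0] for f in m.features}
        df = isoform_diversity(m, iso_gene, StageDesign(["A", "A2"], cell_stage))
        a = df[df.stage == "A"].set_index("category")
        assert a.loc["1", "n_genes"] == 1
        assert a.loc[">5", "n_genes"] == 1

    def test_major_isoform_ratio_values(self):
        assert sc.major_isoform_ratio({"t1": 8, "t2": 2}) == pytest.approx(0.8)
        assert sc.major_isoform_ratio({"t1": 7}) == 1.0
        # gene with total 5 UMIs is excluded (needs > 5)
        assert sc.major_isoform_ratio({"t1": 3, "t2": 2}) is None

    def test_ratios_per_stage_bounds(self, pipeline_result):
        df = major_isoform_ratios_per_stage(
            pipeline_result.isoform_matrix,
            pipeline_result.isoform_gene,
            StageDesign(["A", "B"], pipeline_result.isoform_matrix.stages),
        )
        assert ((df.major_isoform_ratio > 0) & (df.major_isoform_ratio <= 1)).all()


def switch_matrix(rng, n_genes, umis_per_stage, frac_a, frac_b, n_cells=5):
    """Two-stage isoform matrix; every gene has 2 isoforms with stage-wise
    major-isoform fractions frac_a (stage A) and frac_b (stage B)."""
    counts = {}
    cell_stage = {}
    for s, frac in (("A", frac_a), ("B", frac_b)):
        for k in range(n_cells):
            cell_stage[f"{s}{k}"] = s
    for g in range(n_genes):
        for s, frac in (("A", frac_a), ("B", frac_b)):
            per_cell = umis_per_stage // n_cells
            for k in range(n_cells):
                n1 = rng.binomial(per_cell, frac)
                counts[(f"{s}{k}", f"G{g}.t1")] = n1
                counts[(f"{s}{k}", f"G{g}.t2")] = per_cell - n1
    features = [f"G{g}.t{i}" for g in range(n_genes) for i in (1, 2)]
    return count_matrix(counts, cell_stage, kind="isoform", features=features)


class TestSwitch:
    def test_null_fractions_not_switched(self):
        rng = np.random.default_rng(0)
        m = switch_matrix(rng, 20, 200, 0.5, 0.5)
        iso_gene = {f: f.split(".")[0] for f in m.features}
        res = sc.detect_isoform_switch(
            m, iso_gene, StageDesign(["A", "B"], m.stages), ("A", "B")
        )
        assert not any(r.switched for r in res)

    def test_planted_switch_detected(self):
        rng = np.random.default_rng(1)
        m = switch_matrix(rng, 10, 200, 0.9, 0.1)
        iso_gene = {f: f.split(".")[0] for f in m.features}
        res = sc.detect_isoform_switch(
            m, iso_gene, StageDesign(["A", "B"], m.stages), ("A", "B")
        )
        switched_genes = {r.gene_id for r in res if r.switched}
        assert switched_genes == {f"G{g}" for g in range(10)}
        # dIF matches the pooled fraction change
        for r in res:
            assert abs(abs(r.dif) - 0.8) < 0.15

    def test_symmetry_under_stage_swap(self):
        rng = np.random.default_rng(2)
        m = switch_matrix(rng, 8, 120, 0.8, 0.3)
        iso_gene = {f: f.split(".")[0] for f in m.features}
        design = StageDesign(["A", "B"], m.stages)
        fwd = sc.detect_isoform_switch(m, iso_gene, design, ("A", "B"))
        rev = sc.detect_isoform_switch(m, iso_gene, design, ("B", "A"))
        f = {(r.gene_id, r.isoform_id): r for r in fwd}
        for r in rev:
            other = f[(r.gene_id, r.isoform_id)]
            assert r.dif == pytest.approx(-other.dif)
            assert r.isoform_q == pytest.approx(other.isoform_q)
            assert r.switched == other.switched

    def test_low_coverage_genes_skipped(self):
        rng = np.random.default_rng(3)
        m = switch_matrix(rng, 5, 8, 0.9, 0.1)  # 8 UMIs/stage < 10
        iso_gene = {f: f.split(".")[0] for f in m.features}
        res = sc.detect_isoform_switch(
            m, iso_gene, StageDesign(["A", "B"], m.stages), ("A", "B")
        )
        assert res == []


class TestAdjacency:
    def test_relations_by_distance(self, toy_reference):
        design = sc.default_design(
            toy_reference, seed=31, cells_per_stage=6, stages=("A", "B"),
            base_te_mean=(8.0, 12.0),
        )
        _, truth, _ = sc.simulate_molecules(toy_reference, design)
        te_counts, gene_counts = {}, {}
        for t in truth:
            if t.feature_kind == "te_locus":
                k = (t.cell_barcode, t.source_feature)
                te_counts[k] = te_counts.get(k, 0) + 1
            elif t.feature_kind == "isoform":
                k = (t.cell_barcode, t.gene_id)
                gene_counts[k] = gene_counts.get(k, 0) + 1
        cells = sorted(design.cell_stage)
        tm = sc.build_matrix(te_counts, "te_locus", cells=cells)
        gm = sc.build_matrix(gene_counts, "gene", cells=cells)
        genes = [g for g in toy_reference.genes if not g.gene_id.startswith("SPIKE")]
        cors = sc.te_gene_correlation(tm, gm, toy_reference.te_loci, genes)
        assert cors
        for c in cors:
            if c.relation == "adjacent":
                assert c.distance < 10_000
            else:
                assert c.distance > 1_000_000

    def test_proportional_counts_correlate_perfectly(self):
        from scisote.reference import TELocus, GeneModel, TranscriptModel
        from scisote.stages import te_gene_correlation

        cells = {f"c{i}": "A" for i in range(6)}
        te_counts = {(f"c{i}", "te1"): 10 * (i + 1) for i in range(6)}
        gene_counts = {(f"c{i}", "G1"): 30 * (i + 1) for i in range(6)}
        tm = count_matrix(te_counts, cells, kind="te_locus")
        gm = count_matrix(gene_counts, cells, kind="gene")
        te = TELocus("te1", "chr1", 1000, 2000, "+", "Lx7", "L1", "LINE")
        gene = GeneModel(
            "G1", "chr1", "+",
            [TranscriptModel("G1.t1", "G1", "chr1", "+", [(5000, 6000)])],
        )
        cors = te_gene_correlation(tm, gm, [te], [gene])
        assert len(cors) == 1
        assert cors[0].relation == "adjacent"
        # CPM/10 within each cell makes both vectors constant unless the
        # matrices have other features; proportional raw counts give r=1
        # on the normalized scale too when totals scale together
        assert cors[0].correlation is None or abs(cors[0].correlation - 1) < 1e-9


def test_compare_adjacency_requires_both_groups():
    from scisote.stages import AdjacencyCorrelation

    with pytest.raises(ValueError):
        compare_adjacency(
            [AdjacencyCorrelation("t", "g", 0.0, "adjacent", 0.5)]
        )
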