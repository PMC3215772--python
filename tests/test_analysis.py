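"""Correlations, family binning, significance tests and distributions."""

import numpy as np
import pandas as pd
import pytest

from isomap import (
    SimulationConfig,
    cochran_q_test,
    correlate_density,
    correlate_gc_expression,
    distribution_across_families,
    family_mean_genic_expression,
    family_significance_test,
    fraction_isochores_without_cds,
    generate_gene_models,
    generate_isochore_map,
    pearson_correlation,
    simulate_gene_counts,
    Isochore,
)
from isomap.analysis import (
    expressed_mask,
    never_expressed_mask,
    non_detected_in_one_tissue_mask,
)
from isomap.expression import classify_expression_status


def hand_cochran_q(matrix):
    """Direct evaluation of Q = k(k-1) * sum((Cj - Cbar)^2) / (k*sum(Ri) - sum(Ri^2))."""
    arr = np.asarray(matrix)
    k = arr.shape[1]
    C = arr.sum(axis=0)
    R = arr.sum(axis=1)
    denom = k * R.sum() - (R**2).sum()
    return k * (k - 1) * ((C - C.mean()) ** 2).sum() / denom


def gene_frame(families, statuses_by_tissue, e_by_tissue=None):
    df = pd.DataFrame({"family": families})
    for t, statuses in statuses_by_tissue.items():
        df[f"status_{t}"] = statuses
    for t, e in (e_by_tissue or {}).items():
        df[f"E_CDS_{t}"] = e
    return df


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_two_points_anticorrelated(self):
        assert pearson_correlation([1, 2], [2, 1]) == pytest.approx(-1.0)

    def test_three_point_hand_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_undefined(self):
        assert np.isnan(pearson_correlation([1, 1, 1], [1, 2, 3]))

    def test_nan_pairs_dropped(self):
        x = [1, 2, 3, np.nan]
        y = [1, 3, 2, 100.0]
        assert pearson_correlation(x, y) == pytest.approx(0.5)


@pytest.fixture(scope="module")
def simulated_expression():
    """Moderate-scale simulated isochore expression table, one per module."""
    from isomap import build_count_table, isochore_expression_table, \
        gene_expression_table, assign_genes_to_isochores
    from isomap.simulate import simulate_dataset

    cfg = SimulationConfig(
        n_chromosomes=3,
        chromosome_length=40_000_000,
        total_reads_per_tissue=200_000,
        seed=77,
    )
    isochores, genes, reads = simulate_dataset(cfg)
    table = build_count_table(reads, isochores, genes)
    expr = isochore_expression_table(table, isochores)
    gene_expr = gene_expression_table(table, genes, isochores)
    return cfg, isochores, genes, table, expr, gene_expr


class TestCorrelations:
    def test_positive_beta_recovered_and_sign_checked(self, simulated_expression):
        cfg, isochores, genes, table, expr, _ = simulated_expression
        r = correlate_gc_expression(expr, "brain", "E_L")
        assert r > 0
        # recompute from raw counts, bypassing the table
        gc = expr["GC"].to_numpy()
        counts = expr["count_brain"].to_numpy().astype(float)
        lengths = expr["Length"].to_numpy()
        el = np.where(counts > 0,
                      np.log2(np.maximum(counts, 1) / (table.total_reads["brain"] * lengths)),
                      np.nan)
        assert np.sign(r) == np.sign(pearson_correlation(gc, el))
        assert r == pytest.approx(pearson_correlation(gc, el))

    def test_ed_uses_only_cds_containing_isochores(self, simulated_expression):
        *_, expr, _ = simulated_expression
        has_cds = expr["CDS_count"] > 0
        r_manual = pearson_correlation(
            expr.loc[has_cds, "GC"], expr.loc[has_cds, "E_D_brain"]
        )
        assert correlate_gc_expression(expr, "brain", "E_D") == pytest.approx(r_manual)
        assert expr.loc[~has_cds, "E_D_brain"].isna().all()

    def test_null_beta_gives_no_correlation(self):
        cfg = SimulationConfig(
            tissue_effects={"brain": 0.0},
            gene_density_slope=0.0,
            seed=13,
        )
        isochores = generate_isochore_map(cfg)
        assert len(isochores) >= 2000
        genes = generate_gene_models(isochores, cfg)
        counts, _ = simulate_gene_counts(isochores, genes, cfg, "brain")
        idx = {iso.name: k for k, iso in enumerate(isochores)}
        iso_counts = np.bincount(
            np.array([idx[g.host_isochore] for g in genes]),
            weights=counts, minlength=len(isochores),
        )
        L = np.array([i.length_mb for i in isochores])
        el = np.where(iso_counts > 0,
                      np.log2(np.maximum(iso_counts, 1) / (cfg.total_reads_per_tissue * L)),
                      np.nan)
        r = pearson_correlation(np.array([i.gc for i in isochores]), el)
        assert abs(r) < 0.1

    def test_permuted_gc_labels_center_at_zero(self, simulated_expression):
        *_, expr, _ = simulated_expression
        rng = np.random.default_rng(0)
        gc = expr["GC"].to_numpy()
        el = expr["E_L_brain"].to_numpy()
        rs = [
            pearson_correlation(rng.permutation(gc), el) for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.03
        assert np.quantile(rs, 0.05) < 0 < np.quantile(rs, 0.95)

    def test_density_correlations(self, simulated_expression):
        *_, expr, _ = simulated_expression
        assert correlate_density(expr, "GC") > 0
        assert correlate_density(expr, "E_L", "brain") > 0
        # reorder invariance
        shuffled = expr.sample(frac=1.0, random_state=1)
        assert correlate_density(shuffled, "GC") == pytest.approx(
            correlate_density(expr, "GC")
        )

    def test_constant_density_undefined(self):
        df = pd.DataFrame({"GeneDensity": [2.0, 2.0, 2.0], "GC": [30.0, 40.0, 50.0]})
        assert np.isnan(correlate_density(df, "GC"))


class TestFamilyMeans:
    def test_two_genes_arithmetic(self):
        df = gene_frame(
            ["H1", "H1", "L2"],
            {"brain": ["expressed"] * 3},
            {"brain": [-8.0, -6.0, np.nan]},
        )
        means = family_mean_genic_expression(df, "brain")
        assert means["H1"] == pytest.approx(-7.0)
        assert np.isnan(means["L2"])  # only an undefined value there
        assert np.isnan(means["H3"])  # no genes at all

    def test_family_means_increase_with_gc(self, simulated_expression):
        *_, gene_expr = simulated_expression
        means = family_mean_genic_expression(gene_expr, "brain").dropna()
        # allow sampling noise in sparse families: compare well-populated ones
        populated = gene_expr["family"].value_counts()
        solid = [f for f in means.index if populated.get(f, 0) >= 100]
        vals = means[solid].to_numpy()
        assert len(solid) >= 3
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSignificance:
    def test_identical_columns_q_zero(self):
        m = np.tile(np.array([[1], [0], [1]]), (1, 3))
        q, p = cochran_q_test(m)
        assert q == 0.0 and p == 1.0

    def test_toy_matrix_matches_hand_formula(self):
        m = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1], [1, 0, 1]])
        q, p = cochran_q_test(m)
        assert q == pytest.approx(hand_cochran_q(m))
        assert 0 <= p <= 1

    def test_between_family_grouping(self, simulated_expression):
        *_, gene_expr = simulated_expression
        q, p = family_significance_test(
            gene_expr, ["L2", "H2"], grouping="families", tissue="brain"
        )
        assert np.isfinite(q) and 0 <= p <= 1

    def test_between_tissue_grouping(self, simulated_expression):
        *_, gene_expr = simulated_expression
        q, p = family_significance_test(
            gene_expr, ["brain", "liver"], grouping="tissues", family="H1"
        )
        assert np.isfinite(q) and 0 <= p <= 1

    def test_mannwhitney_identical_samples(self):
        df = gene_frame(
            ["H1"] * 10 + ["H2"] * 10,
            {"brain": ["expressed"] * 20},
            {"brain": list(range(10)) + list(range(10))},
        )
        stat, p = family_significance_test(
            df, ["H1", "H2"], grouping="families", tissue="brain",
            method="mannwhitney",
        )
        assert p > 0.99

    def test_single_group_degenerate(self):
        df = gene_frame(["H1"], {"brain": ["expressed"]})
        q, p = family_significance_test(df, ["H1"], tissue="brain")
        assert np.isnan(q) and np.isnan(p)


class TestDistributions:
    def test_single_family_subset(self):
        df = gene_frame(["L2"] * 7, {"brain": ["expressed"] * 7})
        dist = distribution_across_families(df)
        assert dist["L2"] == pytest.approx(100.0)
        assert dist.sum() == pytest.approx(100.0)

    def test_sixty_percent_in_l2(self):
        df = gene_frame(["L2"] * 6 + ["H1"] * 4, {})
        dist = distribution_across_families(df)
        assert dist["L2"] == pytest.approx(60.0)
        assert dist["H1"] == pytest.approx(40.0)

    def test_empty_subset_all_zero(self):
        dist = distribution_across_families(pd.Series([], dtype=object))
        assert (dist == 0).all()

    def test_subsets_partition_and_match_enumeration(self, simulated_expression):
        *_, gene_expr = simulated_expression
        tissues = ["brain", "liver", "muscle"]
        never = never_expressed_mask(gene_expr, tissues)
        # set oracle: per-gene enumeration of the zero-count intersection
        manual = gene_expr.apply(
            lambda row: all(row[f"count_{t}"] == 0 for t in tissues), axis=1
        )
        assert (never == manual).all()
        only_brain = non_detected_in_one_tissue_mask(gene_expr, "brain", tissues)
        manual_ob = gene_expr.apply(
            lambda row: row["count_brain"] == 0
            and all(row[f"count_{t}"] > 0 for t in ("liver", "muscle")),
            axis=1,
        )
        assert (only_brain == manual_ob).all()
        dist = distribution_across_families(gene_expr[expressed_mask(gene_expr, "brain")])
        assert dist.sum() == pytest.approx(100.0)

    def test_status_partition_disjoint_exhaustive(self, simulated_expression):
        *_, gene_expr = simulated_expression
        statuses = gene_expr["status_brain"]
        assert set(statuses.unique()) <= {"expressed", "non_expressed", "indeterminate"}
        counts = gene_expr["count_brain"]
        assert ((counts == 0) == (statuses == "non_expressed")).all()
        assert ((counts >= 10) == (statuses == "expressed")).all()

    def test_raising_threshold_never_increases_expressed(self, simulated_expression):
        *_, gene_expr = simulated_expression
        for fam in gene_expr["family"].dropna().unique():
            counts = gene_expr.loc[gene_expr["family"] == fam, "count_brain"]
            n10 = sum(classify_expression_status(int(c), 10) == "expressed" for c in counts)
            n100 = sum(classify_expression_status(int(c), 100) == "expressed" for c in counts)
            assert n100 <= n10


class TestFractionWithoutCds:
    def test_all_hosting(self):
        isochores = [Isochore(f"i{k}", "chr1", k * 10**6, (k + 1) * 10**6, 44.0)
                     for k in range(4)]
        for iso in isochores:
            iso.gene_count = 1
        pct = fraction_isochores_without_cds(isochores)
        assert pct["H1"] == pytest.approx(0.0)
        assert np.isnan(pct["L1"])  # no L1 isochores at all

    def test_two_of_nine_empty(self):
        isochores = [Isochore(f"i{k}", "chr1", k * 10**6, (k + 1) * 10**6, 55.0)
                     for k in range(9)]
        for iso in isochores[:7]:
            iso.gene_count = 3
        pct = fraction_isochores_without_cds(isochores)
        assert pct["H3"] == pytest.approx(100 * 2 / 9, abs=0.05)

    def test_bounded(self, simulated_expression):
        _, isochores, *_ = simulated_expression
        pct = fraction_isochores_without_cds(isochores).dropna()
        assert ((0 <= pct) & (pct <= 100)).all()
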