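"""Connectivity, distance, PCA1-gene correlation, and cross-region
concordance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from txstate import (
    FoldChangeTable,
    ValidationError,
    compute_pca1,
    connectivity_state_curve,
    euclidean_profile,
    gene_connectivity,
    pca1_gene_correlations,
    regional_concordance,
    zscore_rows,
)
from txstate.structure import ConnectivityTable, correlation_pvalues

from helpers import make_matrix, zscore_array
from oracles import connectivity_bruteforce, pearson_p, pearson_r


def fold_table(log2_fc, p_value, probe_ids=None):
    log2_fc = np.asarray(log2_fc, float)
    probe_ids = probe_ids or [f"p{i}" for i in range(len(log2_fc))]
    return FoldChangeTable(
        table=pd.DataFrame(
            {"log2_fc": log2_fc, "p_value": p_value, "direction": np.sign(log2_fc)},
            index=probe_ids,
        )
    )


class TestGeneConnectivity:
    def test_duplicated_genes_are_connected(self, rng):
        base = rng.normal(size=8)
        values = np.vstack([base, base] + [rng.normal(size=8) for _ in range(4)])
        z = make_matrix(zscore_array(values))
        scores = compute_pca1(z)
        table = gene_connectivity(z, scores, alpha=0.001, max_genes=None)
        assert table.table["n_connections"].iloc[0] >= 1
        assert table.table["n_connections"].iloc[1] >= 1

    def test_identical_genes_fully_connected(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        z = make_matrix(zscore_array(np.tile(base, (5, 1))))
        scores = compute_pca1(z)
        table = gene_connectivity(z, scores, max_genes=None)
        assert (table.table["n_connections"] == 4).all()
        np.testing.assert_allclose(table.table["connectivity"], 4 / 5)

    def test_matches_pairwise_bruteforce_oracle(self, rng):
        values = zscore_array(rng.normal(size=(12, 9)))
        z = make_matrix(values)
        scores = compute_pca1(z)
        table = gene_connectivity(z, scores, alpha=0.05, max_genes=None)
        oracle = connectivity_bruteforce(values, alpha=0.05)
        np.testing.assert_array_equal(table.table["n_connections"].to_numpy(), oracle)

    def test_null_connection_rate_close_to_alpha(self, rng):
        # Independent genes: the fraction of connected pairs estimates
        # the test's size.
        alpha = 0.01
        n_pairs = 0
        n_conn = 0
        for _ in range(8):
            values = zscore_array(rng.normal(size=(30, 50)))
            z = make_matrix(values)
            scores = compute_pca1(z)
            table = gene_connectivity(z, scores, alpha=alpha, max_genes=None)
            n_conn += table.table["n_connections"].sum() / 2
            n_pairs += 30 * 29 / 2
        rate = n_conn / n_pairs
        assert rate == pytest.approx(alpha, abs=0.01)

    def test_seeded_subsampling_reproducible(self, small_study):
        z = zscore_rows(small_study.expression["dorsal"])
        scores = compute_pca1(z)
        a = gene_connectivity(z, scores, max_genes=100, seed=5)
        b = gene_connectivity(z, scores, max_genes=100, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_few_samples_rejected(self):
        z = make_matrix(zscore_array(np.random.default_rng(0).normal(size=(5, 3))))
        with pytest.raises(ValidationError, match="4 samples"):
            gene_connectivity(z, compute_pca1(z))

    def test_correlation_pvalues_match_textbook(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        r = pearson_r(x, y)
        assert correlation_pvalues(np.array([r]), 10)[0] == pytest.approx(
            pearson_p(r, 10), abs=1e-12
        )


class TestConnectivityStateCurve:
    @staticmethod
    def _table(conn, abs_r):
        g = len(conn)
        counts = (np.asarray(conn) * g).round().astype(int)
        frame = pd.DataFrame(
            {
                "n_connections": counts,
                "connectivity": counts / g,
                "r_with_pca1": abs_r,
                "p_with_pca1": np.full(g, 0.5),
            },
            index=[f"g{i}" for i in range(g)],
        )
        return ConnectivityTable(table=frame, alpha=0.001, n_genes=g)

    def test_monotone_identity_gives_spearman_one(self):
        conn = np.arange(20) / 20
        table = self._table(conn, conn)
        # |r with PCA1| equal to connectivity exactly: monotone identity
        _, rho = connectivity_state_curve(table, n_bins=5)
        assert rho == pytest.approx(1.0)

    def test_independent_columns_give_near_zero_rho(self, rng):
        rhos = []
        for _ in range(40):
            conn = rng.integers(0, 50, size=50) / 50
            abs_r = rng.uniform(0, 1, size=50)
            _, rho = connectivity_state_curve(self._table(conn, abs_r), n_bins=5)
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.0, abs=0.1)

    def test_sign_flip_of_scores_is_invisible(self, small_study):
        z = zscore_rows(small_study.expression["dorsal"])
        scores = compute_pca1(z)
        table = gene_connectivity(z, scores, max_genes=150, seed=1)
        flipped = gene_connectivity(z, scores.flipped("test"), max_genes=150, seed=1)
        _, rho_a = connectivity_state_curve(table)
        _, rho_b = connectivity_state_curve(flipped)
        assert rho_a == pytest.approx(rho_b, abs=1e-12)

    def test_hierarchy_emerges_in_synthetic_study(self, small_study):
        z = zscore_rows(small_study.expression["dorsal"])
        scores = compute_pca1(z)
        table = gene_connectivity(z, scores, max_genes=400, seed=2)
        binned, rho = connectivity_state_curve(table)
        assert rho > 0
        assert binned["mean_connectivity"].is_monotonic_increasing

    def test_identical_connectivities_single_bin(self):
        table = self._table([0.2] * 10, np.linspace(0, 1, 10))
        binned, rho = connectivity_state_curve(table)
        assert len(binned) == 1
        assert np.isnan(rho)


class TestEuclideanProfile:
    def test_reference_distance_zero_and_tie_break(self, rng):
        values = zscore_array(rng.normal(size=(20, 6)))
        z = make_matrix(values)
        scores = compute_pca1(z)
        profile = euclidean_profile(z, scores)
        assert profile.as_series()[profile.reference_sample] == 0
        assert profile.reference_sample == z.sample_ids[int(np.argmin(scores.pca1))]

    def test_rank_one_data_is_exactly_linear(self):
        v = np.array([0.0, 1.0, 3.0, 7.0, 2.0])
        rows = np.outer(np.array([1.0, 2.0, -1.5, 0.5]), v)
        z = make_matrix(zscore_array(rows))
        scores = compute_pca1(z)
        profile = euclidean_profile(z, scores)
        assert profile.linearity_r == pytest.approx(1.0, abs=1e-9)
        # distance proportional to score offset from the minimum
        offset = scores.pca1 - scores.pca1.min()
        nz = offset > 0
        ratio = profile.distance[nz] / offset[nz]
        np.testing.assert_allclose(ratio, ratio[0])

    def test_distances_match_hand_arithmetic(self):
        values = np.array(
            [
                [-1.0, 0.0, 1.0, 0.0],
                [0.0, -1.0, 1.0, 0.0],
            ]
        )
        z = make_matrix(zscore_array(values), sample_ids=list("ABCD"))
        scores = compute_pca1(z)
        profile = euclidean_profile(z, scores)
        ref = z.sample_ids.index(profile.reference_sample)
        for j in range(4):
            expected = np.sqrt(((z.values[:, j] - z.values[:, ref]) ** 2).sum())
            assert profile.distance[j] == pytest.approx(expected, abs=1e-12)

    def test_linearity_increases_as_noise_vanishes(self):
        from txstate import GeneratorParams, generate_study, score_matrix
        from txstate.preprocess import drop_constant_rows, zscore_rows as zs

        rs = []
        for noise in (1.5, 0.5, 0.05):
            study = generate_study(
                GeneratorParams(seed=11, n_probes=500, noise_sd=noise)
            )
            z = zs(drop_constant_rows(study.expression["dorsal"]))
            scores = compute_pca1(z)
            rs.append(abs(euclidean_profile(z, scores).linearity_r))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.99


class TestPca1GeneCorrelations:
    def test_probe_equal_to_score_is_perfectly_correlated(self, rng):
        values = zscore_array(rng.normal(size=(10, 8)))
        z = make_matrix(values)
        scores = compute_pca1(z)
        augmented = make_matrix(
            np.vstack([values, zscore_array(scores.pca1[None, :]), -zscore_array(scores.pca1[None, :])]),
            probe_ids=[f"p{i}" for i in range(10)] + ["probe_pos", "probe_neg"],
        )
        table = pca1_gene_correlations(augmented, scores)
        assert table.loc["probe_pos", "r"] == pytest.approx(1.0, abs=1e-9)
        assert table.loc["probe_pos", "significant"]
        assert table.loc["probe_pos", "direction"] == 1
        assert table.loc["probe_neg", "r"] == pytest.approx(-1.0, abs=1e-9)
        assert table.loc["probe_neg", "direction"] == -1

    def test_linked_fraction_dominates_unlinked(self, small_study):
        from txstate.preprocess import drop_constant_rows, zscore_rows as zs

        z = zs(drop_constant_rows(small_study.expression["dorsal"]))
        scores = compute_pca1(z)
        table = pca1_gene_correlations(z, scores)
        beta = small_study.truth["beta"].reindex(table.index)
        sig_linked = table.loc[beta != 0, "significant"].mean()
        sig_unlinked = table.loc[beta == 0, "significant"].mean()
        assert sig_linked > 0.3
        assert sig_unlinked < 0.15


class TestRegionalConcordance:
    def test_identical_tables_agree_perfectly(self, rng):
        fc = rng.normal(size=20)
        p = rng.uniform(0.001, 0.2, size=20)
        table = fold_table(fc, p)
        report = regional_concordance(table, fold_table(fc, p))
        assert report.pearson_r_fc == pytest.approx(1.0)
        assert report.pct_same_dir_any == 100.0
        assert report.pct_same_dir_both == 100.0

    def test_antisymmetric_tables_fully_discordant(self, rng):
        fc = rng.normal(size=15)
        p = np.full(15, 0.001)
        report = regional_concordance(fold_table(fc, p), fold_table(-fc, p))
        assert report.pearson_r_fc == pytest.approx(-1.0)
        assert report.pct_same_dir_any == 0.0
        assert report.pct_same_dir_both == 0.0

    def test_ten_probe_hand_enumeration(self):
        # dorsal: probes 0-5 significant; ventral: probes 4-7 significant.
        # significant in >=1 region: 8 probes (0-7); in both: 2 (4, 5).
        # directions agree for all probes except 3 and 5.
        d_fc = np.array([1, 1, -1, 1, 1, -1, 1, -1, 1, 1], float)
        v_fc = np.array([1, 1, -1, -1, 1, 1, 1, -1, 1, -1], float)
        d_p = np.array([0.01] * 6 + [0.5] * 4)
        v_p = np.array([0.5] * 4 + [0.01] * 4 + [0.5] * 2)
        report = regional_concordance(fold_table(d_fc, d_p), fold_table(v_fc, v_p))
        assert report.pct_sig_any == pytest.approx(80.0)
        assert report.pct_sig_both == pytest.approx(20.0)
        assert report.pct_same_dir_any == pytest.approx(100 * 6 / 8)
        assert report.pct_same_dir_both == pytest.approx(100 * 1 / 2)
        assert report.pearson_r_fc == pytest.approx(pearson_r(d_fc, v_fc))

    def test_zero_fold_changes_excluded_from_direction(self):
        d_fc = np.array([0.0, 1.0, -1.0, 2.0])
        v_fc = np.array([1.0, 1.0, -1.0, 2.0])
        p = np.full(4, 0.01)
        report = regional_concordance(fold_table(d_fc, p), fold_table(v_fc, p))
        # probe 0 has no direction in dorsal; remaining 3 all agree
        assert report.pct_same_dir_any == 100.0

    def test_mismatched_probe_sets_rejected(self):
        a = fold_table([1.0, -1.0], [0.01, 0.01], probe_ids=["p0", "p1"])
        b = fold_table([1.0, -1.0], [0.01, 0.01], probe_ids=["p0", "p2"])
        with pytest.raises(ValidationError, match="p1"):
            regional_concordance(a, b)

    def test_both_bounded_by_any(self, small_study):
        from txstate import log_fold_change

        tables = {}
        for region in ("dorsal", "ventral"):
            matrix = small_study.expression[region]
            treated = [s.sample_id for s in small_study.samples_for_region(region) if s.treatment == "CORT_FLX"]
            control = [s.sample_id for s in small_study.samples_for_region(region) if s.treatment == "CORT"]
            tables[region] = log_fold_change(matrix, treated, control)
        report = regional_concordance(tables["dorsal"], tables["ventral"])
        assert report.pct_sig_both <= report.pct_sig_any
        per_region = [tables[r].significant().mean() * 100 for r in tables]
        assert report.pct_sig_both <= min(per_region) + 1e-9
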