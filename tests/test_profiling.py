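"""Profiling: MYH calls, marker tables, filter/impute/cluster/annotate, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from fibertype import (
    ClusterResult,
    SimConfig,
    annotate_percentages,
    cluster_profiles,
    filter_valid,
    generate,
    group_medians,
    impute_downshift,
    marker_table,
    myh_fiber_call,
    pca_loadings,
    quantify,
    zscore_rows,
)

from conftest import make_matrix

TYPES = ["I", "IIa", "IIb", "IIx"]

# Per-fiber-type summed proteotypic peptide intensities of the four MYH
# isoforms (units 10^7), used as a worked example for fiber calling.
MYH_SUMS = {
    "MYH7": {
        "DTQIQLDDAVR": (226.57, 45.22, 0.00, 0.00),
        "IEDEQALGSQLQK": (162.65, 34.33, 0.05, 0.19),
        "ANDDLKENIAIVER": (137.41, 27.70, 0.01, 0.01),
        "GQNVQQVSYAIGALAK": (80.46, 15.95, 0.04, 0.03),
        "SLQSLLK": (74.67, 15.45, 0.02, 0.03),
    },
    "MYH2": {
        "LINDLTTQR": (95.23, 216.18, 8.32, 14.98),
        "AAYLQGLNSADLLK": (77.60, 179.82, 8.17, 11.76),
        "VLNASAIPEGQYIDSK": (74.62, 173.66, 6.23, 11.20),
        "GQTVEQVTNAVGALAK": (39.80, 106.67, 3.76, 7.45),
        "IEDEQAIGIQLQK": (25.58, 71.06, 2.53, 5.65),
    },
    "MYH4": {
        "VAEQELLDASER": (3.78, 3.82, 221.71, 49.27),
        "LINELSTQK": (4.17, 4.55, 175.11, 37.76),
        "AAYLTSLNSADLLK": (1.87, 2.98, 129.68, 24.67),
        "LQDAEEHVEAVNSK": (1.42, 1.34, 75.10, 17.27),
        "RVAEQELLDASER": (1.52, 2.48, 74.18, 19.12),
    },
    "MYH1": {
        "AAYLQNLNSADLLK": (14.02, 20.54, 25.48, 122.96),
        "SALAHALQSSR": (14.19, 20.28, 17.76, 97.12),
        "DSLVSQLSR": (8.37, 11.42, 13.79, 49.63),
        "NAYEESLDHLETLKR": (4.60, 6.71, 8.68, 41.85),
        "QLDEKDSLVSQLSR": (4.59, 6.82, 8.77, 41.53),
    },
}
EXPECTED_CALL = {"MYH7": "I", "MYH2": "IIa", "MYH4": "IIb", "MYH1": "IIx"}


def myh_worked_example_matrix():
    """Reference per-type peptide sums as a 4-'sample' toy matrix."""
    values = {
        pep: dict(zip(TYPES, sums))
        for iso, peps in MYH_SUMS.items()
        for pep, sums in peps.items()
    }
    protein_of = {pep: iso for iso, peps in MYH_SUMS.items() for pep in peps}
    m = make_matrix(values, protein_of, labels={t: t for t in TYPES})
    # zero sums mean "not detected": encode as missing
    m.intensities = m.intensities.replace(0.0, np.nan)
    return m


class TestMyhFiberCall:
    def test_worked_example_assigns_characteristic_types(self):
        m = myh_worked_example_matrix()
        call = myh_fiber_call(m, {iso: iso for iso in MYH_SUMS})
        for iso, fiber in EXPECTED_CALL.items():
            assert call.called_type[iso] == (fiber,)
            assert call.call(iso) == fiber

    def test_isoform_nonzero_in_single_type(self):
        m = make_matrix(
            {"PEPLONGA": {"a": 5.0, "b": np.nan}},
            {"PEPLONGA": "ISO1"},
            labels={"a": "IIb", "b": "I"},
        )
        call = myh_fiber_call(m, {"ISO1": "MYHX"})
        assert call.called_type["MYHX"] == ("IIb",)

    def test_tie_reports_all_maximizers(self):
        m = make_matrix(
            {"PEPLONGA": {"a": 5.0, "b": 5.0}},
            {"PEPLONGA": "ISO1"},
            labels={"a": "I", "b": "IIa"},
        )
        call = myh_fiber_call(m, {"ISO1": "MYHX"})
        assert set(call.called_type["MYHX"]) == {"I", "IIa"}
        with pytest.raises(ValueError, match="ambiguous"):
            call.call("MYHX")

    def test_non_proteotypic_peptides_do_not_contribute(self):
        m = make_matrix(
            {"PEPLONGA": {"a": 5.0, "b": 1.0}, "PEPLONGB": {"a": 1.0, "b": 50.0}},
            {"PEPLONGA": "ISO1", "PEPLONGB": "ISO1"},
            proteotypic={"PEPLONGA": True, "PEPLONGB": False},
            labels={"a": "I", "b": "IIa"},
        )
        call = myh_fiber_call(m, {"ISO1": "MYHX"})
        assert call.called_type["MYHX"] == ("I",)

    def test_isoform_without_proteotypic_peptides_excluded_with_warning(self):
        m = make_matrix(
            {"PEPLONGA": {"a": 5.0, "b": 1.0}},
            {"PEPLONGA": "ISO1"},
            labels={"a": "I", "b": "IIa"},
        )
        with pytest.warns(UserWarning, match="MYH9"):
            call = myh_fiber_call(m, {"ISO1": "MYH1", "ISO2": "MYH9"})
        assert "MYH9" not in call.called_type

    def test_synthetic_default_output_calls_all_four(self, small_sim):
        _, matrix, _ = small_sim
        iso = {f"{n}_SYN": n for n in ("MYH7", "MYH2", "MYH4", "MYH1")}
        call = myh_fiber_call(matrix, iso)
        for iso_name, fiber in EXPECTED_CALL.items():
            assert call.called_type[iso_name] == (fiber,)


class TestMarkerTable:
    def test_slow_gradient_marker_monotone(self, small_sim):
        _, matrix, _ = small_sim
        quant = quantify(matrix, normalize=False)
        table = marker_table(quant, {"SLOW1_SYN": "slow", "FAST1_SYN": "fast"})
        slow = table.loc["SLOW1_SYN", ["I", "IIa", "IIx", "IIb"]].astype(float)
        assert slow.is_monotonic_decreasing
        fast = table.loc["FAST1_SYN", ["I", "IIa", "IIx", "IIb"]].astype(float)
        assert fast.is_monotonic_increasing

    def test_marker_only_in_type_I(self):
        m = make_matrix(
            {
                "PEPLONGA": {"i1": 8.0, "i2": 8.0, "f1": np.nan, "f2": np.nan},
                "PEPLONGB": {"i1": 2.0, "i2": 2.0, "f1": 4.0, "f2": 4.0},
            },
            {"PEPLONGA": "MARK", "PEPLONGB": "OTHER"},
            labels={"i1": "I", "i2": "I", "f1": "IIb", "f2": "IIb"},
        )
        quant = quantify(m, normalize=False)
        table = marker_table(quant, {"MARK": "slow"})
        assert table.loc["MARK", "I"] > 0
        assert np.isnan(table.loc["MARK", "IIb"])

    def test_absent_marker_gets_missing_row(self, small_sim):
        _, matrix, _ = small_sim
        quant = quantify(matrix, normalize=False)
        table = marker_table(quant, {"NOT_THERE": "slow"})
        assert table.loc["NOT_THERE", "indicative_for"] == "slow"
        assert table.loc["NOT_THERE", ["I", "IIa", "IIb", "IIx"]].isna().all()


class TestFilterValid:
    @pytest.mark.parametrize("n_obs,kept", [(28, True), (27, False), (56, True)])
    def test_half_valid_threshold_on_56_samples(self, n_obs, kept):
        row = [1.0] * n_obs + [np.nan] * (56 - n_obs)
        df = pd.DataFrame([row], index=["P1"])
        out = filter_valid(df, 0.5)
        assert ("P1" in out.index) is kept

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        f1=st.floats(min_value=0.05, max_value=1.0),
        f2=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_monotone_in_threshold(self, f1, f2):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, (30, 10))
        vals[rng.random((30, 10)) < 0.4] = np.nan
        df = pd.DataFrame(vals)
        lo, hi = sorted([f1, f2])
        assert set(filter_valid(df, hi).index) <= set(filter_valid(df, lo).index)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_valid(pd.DataFrame([[1.0]]), 0.0)


class TestImputation:
    def test_no_missing_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(20, 2, (30, 4)))
        pd.testing.assert_frame_equal(impute_downshift(df, seed=1), df)

    def test_fixed_seed_reproducible_and_observed_untouched(self, rng):
        vals = rng.normal(20, 2, (50, 4))
        vals[rng.random((50, 4)) < 0.3] = np.nan
        df = pd.DataFrame(vals)
        a = impute_downshift(df, seed=9)
        b = impute_downshift(df, seed=9)
        pd.testing.assert_frame_equal(a, b)
        obs = ~np.isnan(vals)
        assert (a.to_numpy()[obs] == vals[obs]).all()

    def test_moments_match_downshifted_normal(self, rng):
        """Imputed cells follow Normal(mu - 1.8 sigma, (0.3 sigma)^2)."""
        n_obs, n_miss = 20_000, 100_000
        col = np.concatenate([rng.normal(25, 2, n_obs), np.full(n_miss, np.nan)])
        df = pd.DataFrame({"s": col})
        mu = np.nanmean(col)
        sigma = np.nanstd(col, ddof=1)
        out = impute_downshift(df, width=0.3, downshift=1.8, seed=3)
        imputed = out["s"].to_numpy()[n_obs:]
        se_mean = 0.3 * sigma / np.sqrt(n_miss)
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * se_mean
        se_sd = 0.3 * sigma / np.sqrt(2 * n_miss)
        assert abs(imputed.std(ddof=1) - 0.3 * sigma) < 3 * se_sd

    def test_too_few_observed_values_rejected(self):
        df = pd.DataFrame({"s": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="'s'"):
            impute_downshift(df, seed=0)


class TestClustering:
    @staticmethod
    def _archetype_data(rng, n_per=50, reps=3, noise=0.1):
        arch = {1: [2, 1, -1, -2], 2: [-2, -1, 1, 2], 3: [1, -2, 2, -1],
                4: [-1, 2, -2, 1]}
        samples = [f"{t}_{i}" for t in TYPES for i in range(reps)]
        labels = pd.Series([s.split("_")[0] for s in samples], index=samples)
        rows, truth = [], []
        for k, profile in arch.items():
            for _ in range(n_per):
                level = rng.normal(20, 2)
                row = np.repeat(profile, reps) + rng.normal(0, noise, 4 * reps)
                rows.append(row + level)
                truth.append(k)
        df = pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))],
                          columns=samples)
        return df, labels, truth

    def test_recovers_archetype_partition(self, rng):
        df, labels, truth = self._archetype_data(rng)
        result = cluster_profiles(df, labels, seed=0)
        assert adjusted_rand_score(truth, result.assignment.to_numpy()) == 1.0
        assert result.sizes.sum() == len(df)

    def test_partition_property(self, rng):
        df, labels, _ = self._archetype_data(rng, n_per=10)
        result = cluster_profiles(df, labels, seed=0)
        assert result.assignment.index.equals(
            zscore_rows(group_medians(df, labels)).index
        )
        assert not result.assignment.index.has_duplicates

    def test_kmeans_stage_degenerates_below_k_pre(self, rng):
        """With fewer rows than k_pre the result equals plain linkage on rows."""
        df, labels, _ = self._archetype_data(rng, n_per=10)
        z = zscore_rows(group_medians(df, labels))
        direct = fcluster(linkage(z.to_numpy(), "average", "euclidean"),
                          4, "maxclust")
        result = cluster_profiles(df, labels, k_pre=300, seed=0)
        assert adjusted_rand_score(direct, result.assignment.to_numpy()) == 1.0

    def test_average_linkage_matches_brute_force_oracle(self, rng):
        """Merge heights and compositions vs an O(n^3) oracle on <= 8 rows."""
        x = rng.normal(0, 1, (8, 4))
        z = linkage(x, method="average", metric="euclidean")

        # oracle: explicit average-linkage agglomeration
        clusters = {i: [i] for i in range(8)}
        merges = []
        next_id = 8
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    d = np.mean([
                        np.linalg.norm(x[i] - x[j])
                        for i in clusters[a] for j in clusters[b]
                    ])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            merges.append((frozenset(clusters[a] + clusters[b]), d))
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1

        members = {i: frozenset([i]) for i in range(8)}
        for row_idx, (ia, ib, height, _) in enumerate(z):
            merged = members[int(ia)] | members[int(ib)]
            members[8 + row_idx] = merged
            assert merged == merges[row_idx][0]
            assert height == pytest.approx(merges[row_idx][1])

    def test_n_final_larger_than_rows_rejected(self, rng):
        df, labels, _ = self._archetype_data(rng, n_per=1)
        with pytest.raises(ValueError, match="n_final"):
            cluster_profiles(df, labels, n_final=50, seed=0)

    def test_zscored_rows_have_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame(rng.normal(20, 3, (40, 6)))
        z = zscore_rows(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, rtol=1e-9)


class TestAnnotation:
    def test_reference_percentage_arithmetic(self):
        """4 of 77 -> 5.19%; 14 of 271 -> 5.17% after 2-decimal rounding."""
        proteins = [f"A{i}" for i in range(77)] + [f"B{i}" for i in range(271)]
        assignment = pd.Series([3] * 77 + [4] * 271, index=proteins)
        result = ClusterResult(
            assignment=assignment,
            profiles=pd.DataFrame(),
            sizes=assignment.value_counts().sort_index(),
        )
        categories = {f"A{i}": "Respiratory chain" for i in range(4)}
        categories.update(
            {f"B{i}": "Fatty acid beta oxidation" for i in range(14)}
        )
        table = annotate_percentages(result, categories)
        assert table.percent.loc[3, "Respiratory chain"] == 5.19
        assert table.percent.loc[4, "Fatty acid beta oxidation"] == 5.17
        assert table.counts.loc[3, "Respiratory chain"] == 4
        assert table.counts.loc[4, "Fatty acid beta oxidation"] == 14

    def test_single_category_is_100_percent(self):
        assignment = pd.Series([1, 1, 1], index=["P1", "P2", "P3"])
        result = ClusterResult(assignment, pd.DataFrame(),
                               assignment.value_counts())
        table = annotate_percentages(result, {p: "Sarcomere" for p in assignment.index})
        assert table.percent.loc[1, "Sarcomere"] == 100.0

    def test_unmapped_proteins_become_other(self):
        assignment = pd.Series([1, 1], index=["P1", "P2"])
        result = ClusterResult(assignment, pd.DataFrame(),
                               assignment.value_counts())
        table = annotate_percentages(result, {"P1": "Glycolysis"})
        assert table.counts.loc[1, "Other"] == 1


class TestPCA:
    def test_separating_protein_has_top_loading(self, rng):
        n = 20
        df = pd.DataFrame(
            rng.normal(0, 0.05, (5, 2 * n)),
            index=[f"P{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(2 * n)],
        )
        df.iloc[2, :n] += 10.0  # P2 splits the samples into two clusters
        scores, loadings, _ = pca_loadings(df)
        assert loadings.index[0] == "P2"
        assert loadings["PC1"].abs().idxmax() == "P2"

    def test_duplicated_samples_get_identical_scores(self, rng):
        df = pd.DataFrame(rng.normal(20, 2, (10, 4)),
                          columns=["a", "b", "c", "a2"])
        df["a2"] = df["a"]
        scores, _, _ = pca_loadings(df)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["a2"], atol=1e-9)

    def test_component_variances_match_eigendecomposition(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (15, 12)))
        _, _, explained = pca_loadings(df)
        x = df.T.to_numpy()
        cov = np.cov(x - x.mean(axis=0), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert explained[0] >= explained[1]
        np.testing.assert_allclose(explained, eig[:2], rtol=1e-8)

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.full((5, 4), 3.0))
        with pytest.raises(ValueError, match="constant"):
            pca_loadings(df)
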