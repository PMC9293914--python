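"""Signature scoring, Wilcoxon DE with BH, conserved markers, ortholog
mapping, bulk preparation and group comparison — each checked against an
independent oracle where one exists."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dciscope import (
    bulk_prepare,
    compare_groups,
    conserved_markers,
    lognormalize,
    map_signature_orthologs,
    rank_top_markers,
    score_signature,
    synthetic,
    wilcoxon_de,
)
from dciscope.containers import CountMatrix, GeneSignature, NormalizedMatrix
from dciscope.pipeline import concat_samples
from dciscope.sigstats import _ranksum_p, benjamini_hochberg

from conftest import toy_norm_matrix


# ---------------------------------------------------------------------------
# independent oracles


def bh_brute_force(pvals):
    """BH by the sorted cumulative-minimum definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def ranksum_exact_enumeration(x, y):
    """Two-sided rank-sum p by full enumeration of all rank splits."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    observed = ranks[:n1].sum()
    expected = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = ranks[list(combo)].sum()
        if abs(stat - expected) >= abs(observed - expected) - 1e-12:
            count += 1
        total += 1
    return count / total


def welch_by_hand(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / math.sqrt(va + vb)


# ---------------------------------------------------------------------------


class TestScoreSignature:
    def test_single_gene_identity(self):
        scaled = toy_norm_matrix([[1.5, -0.5], [0.0, 2.0]], kind="scaled")
        out = score_signature(scaled, GeneSignature("s", "", ("g0",)))
        np.testing.assert_allclose(out["score"].to_numpy(), [1.5, -0.5])

    def test_all_genes_equals_column_mean(self):
        scaled = toy_norm_matrix([[1.0, 2.0], [3.0, 4.0]], kind="scaled")
        out = score_signature(scaled, GeneSignature("s", "", ("g0", "g1")))
        np.testing.assert_allclose(out["score"].to_numpy(), [2.0, 3.0])

    def test_hand_mean(self):
        scaled = toy_norm_matrix([[1.0], [-0.5]], kind="scaled")
        out = score_signature(scaled, GeneSignature("s", "", ("g0", "g1")))
        assert out["score"].iloc[0] == pytest.approx(0.25)

    def test_zero_overlap_raises(self):
        scaled = toy_norm_matrix([[1.0]], kind="scaled")
        with pytest.raises(ValueError, match="sig"):
            score_signature(scaled, GeneSignature("sig", "", ("absent",)))

    def test_linearity_in_matrix(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        sig = GeneSignature("s", "", ("g0", "g2", "g5"))
        sa = score_signature(toy_norm_matrix(a, kind="scaled"), sig)["score"]
        sb = score_signature(toy_norm_matrix(b, kind="scaled"), sig)["score"]
        sab = score_signature(toy_norm_matrix(a + b, kind="scaled"), sig)["score"]
        np.testing.assert_allclose(sab.to_numpy(), (sa + sb).to_numpy())

    def test_planted_program_scores_higher_in_target(self, default_run):
        """Malignant-targeted program genes score higher in malignant
        cells than elsewhere (rank-sum p < 1e-6)."""
        import scipy.stats

        config = default_run["config"]
        program = config.signature_programs[0]
        sig = GeneSignature(program.name, "", program.genes)
        scores = score_signature(default_run["scaled"], sig).set_index("unit_id")
        is_target = default_run["truth"].loc[scores.index, "is_malignant"]
        p = scipy.stats.mannwhitneyu(
            scores.loc[is_target.to_numpy(), "score"],
            scores.loc[~is_target.to_numpy(), "score"],
            alternative="greater",
        ).pvalue
        assert p < 1e-6


class TestWilcoxonDE:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 1, size=(30, 6))
        both = np.hstack([vals, vals])  # group2 duplicates group1
        norm = toy_norm_matrix(both)
        res = wilcoxon_de(
            norm,
            [f"c{i}" for i in range(6)],
            [f"c{i}" for i in range(6, 12)],
            logfc_threshold=0.0,
            min_pct=0.0,
        )
        assert (res["p_adjusted"] >= 0.99).all()

    def test_exact_p_for_separated_ranks(self):
        """{1,2,3,4} vs {5,6,7,8}: two-sided exact p = 2/70 ≈ 0.028571."""
        g1 = np.array([[1.0, 2, 3, 4]])
        g2 = np.array([[5.0, 6, 7, 8]])
        norm = toy_norm_matrix(np.hstack([g1, g2]))
        res = wilcoxon_de(
            norm,
            ["c0", "c1", "c2", "c3"],
            ["c4", "c5", "c6", "c7"],
            logfc_threshold=0.0,
            min_pct=0.0,
        )
        assert res["p_value"].iloc[0] == pytest.approx(0.0285714, abs=1e-6)

    def test_ranksum_matches_enumeration_oracle(self, rng):
        """Exact path agrees with full rank-split enumeration (n ≤ 8)."""
        for n1, n2 in [(3, 5), (4, 4), (6, 8), (8, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(loc=0.8, size=n2)
            assert _ranksum_p(x, y) == pytest.approx(
                ranksum_exact_enumeration(x, y), abs=1e-9
            )

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04],
        )

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=1000,
        )
    )
    def test_bh_matches_brute_force(self, pvals):
        np.testing.assert_allclose(
            benjamini_hochberg(pvals), bh_brute_force(pvals), atol=1e-12
        )

    def test_logfc_prefilter_applies(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.1, size=(5, 10))
        norm = toy_norm_matrix(np.hstack([base, base * 1.01]))
        res = wilcoxon_de(
            norm,
            [f"c{i}" for i in range(10)],
            [f"c{i}" for i in range(10, 20)],
            logfc_threshold=0.25,
        )
        assert res.empty  # no gene clears the fold-change bar

    def test_overlapping_groups_rejected(self):
        norm = toy_norm_matrix(np.ones((2, 6)))
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(norm, ["c0", "c1", "c2"], ["c2", "c3", "c4"])


class TestRankTopMarkers:
    def make_results(self):
        return pd.DataFrame(
            {
                "gene": ["b", "a", "c", "d"],
                "log_fc": [1.0, 1.0, 2.0, -1.0],
                "p_value": [0.01, 0.01, 0.001, 0.0001],
                "p_adjusted": [0.02, 0.02, 0.004, 0.0004],
            }
        )

    def test_downregulated_excluded_and_sorted(self):
        top = rank_top_markers(self.make_results(), 10)
        assert top == ["c", "a", "b"]  # d is downregulated; a/b tie -> lexicographic

    def test_n_larger_than_results(self):
        assert len(rank_top_markers(self.make_results(), 100)) == 3

    def test_planted_markers_recovered_in_top50(self):
        """50 strongly expressed malignant-program genes dominate the
        malignant-vs-normal-epithelium marker ranking."""
        base = synthetic.classifier_config(seed=2, with_segments=False)
        samples, _, _ = synthetic.simulate_experiment(base)
        counts, _ = concat_samples(samples)
        means = np.asarray(counts.values.mean(axis=1)).ravel()
        expressed = counts.gene_ids[np.argsort(means)[::-1][100:150]]
        cfg = dataclasses.replace(
            base,
            signature_programs=(
                synthetic.SignatureProgram(
                    "markers", tuple(expressed), "malignant", fold=4.0
                ),
            ),
        )
        samples, _, truth = synthetic.simulate_experiment(cfg)
        counts, _ = concat_samples(samples)
        norm = lognormalize(counts)
        truth = truth.set_index("cell_id")
        is_mal = truth.loc[norm.cell_ids, "is_malignant"].to_numpy()
        is_epi = (truth.loc[norm.cell_ids, "cell_type"] == "epithelial").to_numpy()
        mal = norm.cell_ids[is_mal][:300]
        nrm = norm.cell_ids[is_epi & ~is_mal][:300]
        res = wilcoxon_de(norm, mal, nrm)
        top = rank_top_markers(res, 50)
        assert len(set(top) & set(expressed)) >= 45


class TestConservedMarkers:
    def build_norm(self, effects):
        """3 conditions × (4 target + 4 rest) cells, one gene; ``effects``
        gives the per-condition shift of the target group."""
        rng = np.random.default_rng(0)
        cols, vals, groups, conds = [], [], {}, {}
        for ci, eff in enumerate(effects):
            for j in range(8):
                cid = f"cond{ci}_c{j}"
                cols.append(cid)
                shift = eff if j < 4 else 0.0
                vals.append(rng.normal(loc=2.0 + shift, scale=0.05))
                groups[cid] = "target" if j < 4 else "rest"
                conds[cid] = f"cond{ci}"
        norm = NormalizedMatrix(
            pd.DataFrame([vals], index=["g0"], columns=cols), kind="lognorm"
        )
        return norm, pd.Series(groups), pd.Series(conds)

    def test_gene_up_in_two_of_three_conditions_excluded(self):
        norm, groups, conds = self.build_norm([2.0, 2.0, 0.0])
        out = conserved_markers(
            norm, groups, conds, "target", logfc_threshold=0.0, min_pct=0.0
        )
        assert out.empty

    def test_gene_up_everywhere_qualifies_with_max_p(self):
        norm, groups, conds = self.build_norm([2.0, 2.0, 2.0])
        out = conserved_markers(
            norm, groups, conds, "target", logfc_threshold=0.0, min_pct=0.0
        )
        assert list(out["gene"]) == ["g0"]
        per_cond = out.filter(like="p_adjusted_cond").iloc[0]
        assert out["max_p_adjusted"].iloc[0] == pytest.approx(per_cond.max())

    def test_alpha_one_keeps_consistent_direction(self):
        norm, groups, conds = self.build_norm([0.5, 0.6, 0.4])
        out = conserved_markers(
            norm, groups, conds, "target",
            logfc_threshold=0.0, min_pct=0.0, alpha=1.0,
        )
        assert list(out["gene"]) == ["g0"]

    def test_planted_program_recovered_across_states(self):
        """A malignant program active in every disease state is found by
        the conserved-marker conjunction (recall ≥ 0.9)."""
        base = synthetic.default_config(seed=9, cells_per_replicate=300)
        states = tuple(
            dataclasses.replace(s, malignant_fraction=0.3) for s in base.states
        )
        base = dataclasses.replace(
            base, states=states, cna_segments=(), signature_programs=()
        )
        samples, _, _ = synthetic.simulate_experiment(base)
        counts, _ = concat_samples(samples)
        means = np.asarray(counts.values.mean(axis=1)).ravel()
        expressed = counts.gene_ids[np.argsort(means)[::-1][100:130]]
        cfg = dataclasses.replace(
            base,
            signature_programs=(
                synthetic.SignatureProgram(
                    "prog", tuple(expressed), "malignant", fold=4.0
                ),
            ),
        )
        samples, _, truth = synthetic.simulate_experiment(cfg)
        counts, _ = concat_samples(samples)
        norm = lognormalize(counts)
        truth = truth.set_index("cell_id")
        epi = norm.cell_ids[
            (truth.loc[norm.cell_ids, "cell_type"] == "epithelial").to_numpy()
        ]
        norm_epi = NormalizedMatrix(norm.values[epi], kind="lognorm")
        groups = truth.loc[epi, "is_malignant"].map(
            {True: "malignant", False: "rest"}
        )
        out = conserved_markers(
            norm_epi, groups, truth.loc[epi, "state"], "malignant"
        )
        recall = len(set(expressed) & set(out["gene"])) / len(expressed)
        assert recall >= 0.9

    def test_condition_missing_group_raises(self):
        norm, groups, conds = self.build_norm([2.0, 2.0])
        groups[conds == "cond1"] = "rest"
        with pytest.raises(ValueError, match="cond1"):
            conserved_markers(
                norm, groups, conds, "target", logfc_threshold=0.0
            )


class TestMapSignatureOrthologs:
    def table(self):
        return pd.DataFrame(
            {
                "source_symbol": ["Krt8", "Krt18", "Gapdh", "Gapdh"],
                "target_symbol": ["KRT8", "KRT18", "GAPDH", "GAPDHP1"],
                "mapping_class": [
                    "one-to-one", "one-to-one", "one-to-many", "one-to-many",
                ],
            }
        )

    def test_one_to_one_lookup(self):
        sig = GeneSignature("epi", "", ("Krt8", "Krt18"))
        mapped, unmapped = map_signature_orthologs(sig, self.table())
        assert mapped.genes == ("KRT8", "KRT18")
        assert unmapped == []

    def test_absent_gene_reported_unmapped(self):
        sig = GeneSignature("s", "", ("Krt8", "Novel1"))
        mapped, unmapped = map_signature_orthologs(sig, self.table())
        assert mapped.genes == ("KRT8",)
        assert unmapped == ["Novel1"]

    def test_one_to_many_dropped_under_one_to_one_policy(self):
        sig = GeneSignature("s", "", ("Krt8", "Gapdh"))
        mapped, unmapped = map_signature_orthologs(sig, self.table())
        assert mapped.genes == ("KRT8",)
        assert unmapped == ["Gapdh"]

    def test_all_policy_keeps_multi_targets(self):
        sig = GeneSignature("s", "", ("Gapdh",))
        mapped, _ = map_signature_orthologs(sig, self.table(), policy="all")
        assert set(mapped.genes) == {"GAPDH", "GAPDHP1"}

    def test_empty_mapping_raises(self):
        sig = GeneSignature("s", "", ("Novel1",))
        with pytest.raises(ValueError, match="no genes map"):
            map_signature_orthologs(sig, self.table())


class TestBulkPrepare:
    def counts(self, arrays, samples):
        import scipy.sparse as sp

        arr = np.column_stack(arrays).astype(np.int64)
        return CountMatrix(
            sp.csr_matrix(arr),
            pd.Index([f"g{i}" for i in range(arr.shape[0])]),
            pd.Index(samples),
        )

    def test_identical_samples_identical_columns(self):
        col = np.arange(1, 21)
        cm = self.counts([col, col], ["s1", "s2"])
        out = bulk_prepare(cm)
        pd.testing.assert_series_equal(
            out.values["s1"], out.values["s2"], check_names=False
        )

    def test_every_gene_median_zero(self):
        rng = np.random.default_rng(0)
        cm = self.counts(
            [rng.poisson(50, 30) for _ in range(5)], [f"s{i}" for i in range(5)]
        )
        out = bulk_prepare(cm)
        assert np.abs(out.values.median(axis=1).to_numpy()).max() < 1e-12

    def test_upper_quartile_scaling_arithmetic(self):
        """Samples with nonzero-count upper quartiles 40 and 10 are scaled
        by 0.5 and 2 toward the geometric-mean target of 20."""
        a = np.array([10, 20, 30, 40])  # UQ of nonzero = 32.5 -> craft exact
        # use constant columns for exact quartiles
        a = np.full(20, 40)
        b = np.full(20, 10)
        cm = self.counts([a, b], ["A", "B"])
        out = bulk_prepare(cm)
        # after scaling, both columns are constant 20 -> log2(21) pre-centering
        recovered = out.values + np.log2(21)  # undo zero medians per gene
        assert np.allclose(recovered.to_numpy(), np.log2(21))

    def test_degenerate_sample_raises(self):
        cm = self.counts([np.zeros(5, dtype=int), np.ones(5, dtype=int)],
                         ["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            bulk_prepare(cm)


class TestCompareGroups:
    def scores(self, groups):
        rows = []
        for g, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"{g}_{i}", "sig", v, 1))
        return pd.DataFrame(
            rows, columns=["unit_id", "signature", "score", "n_genes_used"]
        )

    def labels(self, groups):
        return pd.Series(
            {
                f"{g}_{i}": g
                for g, vals in groups.items()
                for i in range(len(vals))
            }
        )

    def test_identical_groups_t_zero_p_one(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        out = compare_groups(self.scores(groups), self.labels(groups))
        assert out["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_hand_welch(self):
        """{1,2,3} vs {4,5,6}: Welch t = −3.674, p = 0.0214."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        out = compare_groups(self.scores(groups), self.labels(groups))
        assert out["t_statistic"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert out["p_value"].iloc[0] == pytest.approx(0.0214, abs=1e-3)
        assert out["t_statistic"].iloc[0] == pytest.approx(
            welch_by_hand([1, 2, 3], [4, 5, 6]), abs=1e-12
        )

    def test_single_pair_adjusted_equals_raw(self):
        groups = {"a": [1.0, 2.0], "b": [2.0, 4.0]}
        out = compare_groups(self.scores(groups), self.labels(groups))
        assert out["p_adjusted"].iloc[0] == out["p_value"].iloc[0]

    def test_three_groups_all_pairs_with_bh(self):
        groups = {
            "a": [1.0, 2.0, 3.0],
            "b": [4.0, 5.0, 6.0],
            "c": [1.5, 2.5, 3.5],
        }
        out = compare_groups(self.scores(groups), self.labels(groups))
        assert len(out) == 3
        np.testing.assert_allclose(
            out["p_adjusted"].to_numpy(),
            bh_brute_force(out["p_value"].to_numpy()),
        )

    def test_small_group_rejected(self):
        groups = {"a": [1.0], "b": [2.0, 3.0]}
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(self.scores(groups), self.labels(groups))
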