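"""Signature scoring, differential expression and cross-species mapping.

Per-cell signature scores are the mean scaled expression of the
signature's genes (computed over all genes, not just the variable
subset). Differential expression uses the two-sided Wilcoxon rank-sum
test with a natural-log fold-change prefilter (default threshold 0.25)
and Benjamini–Hochberg adjustment. Bulk samples are prepared by
upper-quartile normalization, log2(x+1) and per-gene median centering;
bulk group comparisons use Welch t-tests with BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneSignature, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "score_signature",
    "score_signature_bulk",
    "wilcoxon_de",
    "rank_top_markers",
    "conserved_markers",
    "map_signature_orthologs",
    "bulk_prepare",
    "compare_groups",
    "benjamini_hochberg",
]

_LOGFC_EPS = 1e-9
_EXACT_MAX_N = 25  # exact rank-sum up to this group size (no ties)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH false-discovery-rate adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def score_signature(
    scaled: NormalizedMatrix, sig: GeneSignature
) -> pd.DataFrame:
    """Mean scaled expression of the signature genes, per cell."""
    present = scaled.gene_ids.intersection(pd.Index(sig.genes))
    if len(present) == 0:
        raise ValueError(
            f"signature {sig.name!r} has no genes in the expression matrix"
        )
    missing = len(sig.genes) - len(present)
    if missing:
        logger.info(
            "signature %r: %d gene(s) absent from the matrix", sig.name, missing
        )
    scores = scaled.values.loc[present].mean(axis=0)
    return pd.DataFrame(
        {
            "unit_id": scores.index,
            "signature": sig.name,
            "score": scores.to_numpy(),
            "n_genes_used": len(present),
        }
    )


# bulk samples are scored identically; the alias documents intent
score_signature_bulk = score_signature


def _log_fc(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    return np.log((m1 + _LOGFC_EPS) / (m2 + _LOGFC_EPS))


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small tie-free groups, else normal
    approximation with tie correction and continuity correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method
        ).pvalue
    )


def wilcoxon_de(
    norm: NormalizedMatrix,
    group1,
    group2,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Genes are prefiltered: |log fold change| ≥ ``logfc_threshold`` and
    expressed fraction ≥ ``min_pct`` in at least one group. The log fold
    change is ln of the ratio of group means of expm1(lognorm values).
    BH adjustment runs over the tested genes only; rows are sorted by
    p-value.
    """
    g1 = pd.Index(group1)
    g2 = pd.Index(group2)
    if len(g1.intersection(g2)):
        raise ValueError("groups overlap")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("both groups need at least 3 cells")
    v1 = norm.values[g1].to_numpy()
    v2 = norm.values[g2].to_numpy()

    e1 = np.expm1(v1) if norm.kind == "lognorm" else v1
    e2 = np.expm1(v2) if norm.kind == "lognorm" else v2
    log_fc = _log_fc(e1.mean(axis=1), e2.mean(axis=1))
    pct1 = (v1 > 0).mean(axis=1)
    pct2 = (v2 > 0).mean(axis=1)
    tested = (np.abs(log_fc) >= logfc_threshold) & (
        np.maximum(pct1, pct2) >= min_pct
    )

    genes = norm.gene_ids[tested]
    pvals = np.array(
        [
            _ranksum_p(v1[i], v2[i])
            for i in np.flatnonzero(tested)
        ]
    )
    out = pd.DataFrame(
        {
            "gene": genes,
            "log_fc": log_fc[tested],
            "p_value": pvals,
            "p_adjusted": benjamini_hochberg(pvals),
            "pct_group1": pct1[tested],
            "pct_group2": pct2[tested],
        }
    )
    out["direction"] = np.sign(out["log_fc"]).astype(int)
    return out.sort_values(
        ["p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)


def rank_top_markers(results: pd.DataFrame, n: int = 100) -> list:
    """Top ``n`` upregulated genes by adjusted p, then |log fc|, then id."""
    up = results[results["log_fc"] > 0]
    ranked = up.assign(abs_fc=up["log_fc"].abs()).sort_values(
        ["p_adjusted", "abs_fc", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ranked["gene"].head(n).tolist()


def conserved_markers(
    norm: NormalizedMatrix,
    group_labels: pd.Series,
    condition_labels: pd.Series,
    target_group,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes upregulated in ``target_group`` within *every* condition.

    For each condition, target-group cells are tested against the rest
    of that condition; a gene qualifies iff it is significantly
    upregulated (adjusted p < alpha, positive log fc) in all conditions.
    The reported p-value is the worst (maximum) across conditions.
    """
    cells = norm.cell_ids
    group_labels = group_labels.loc[cells]
    condition_labels = condition_labels.loc[cells]
    per_condition = {}
    for cond in condition_labels.unique():
        in_cond = condition_labels == cond
        g1 = cells[(in_cond & (group_labels == target_group)).to_numpy()]
        g2 = cells[(in_cond & (group_labels != target_group)).to_numpy()]
        if len(g1) < 3 or len(g2) < 3:
            raise ValueError(
                f"condition {cond!r} lacks cells of one group"
            )
        res = wilcoxon_de(norm, g1, g2, logfc_threshold, min_pct)
        per_condition[cond] = res.set_index("gene")

    common = None
    for cond, res in per_condition.items():
        ok = res.index[(res["log_fc"] > 0) & (res["p_adjusted"] < alpha)]
        common = ok if common is None else common.intersection(ok)
    rows = []
    for gene in sorted(common):
        stats = {
            f"p_adjusted_{cond}": res.loc[gene, "p_adjusted"]
            for cond, res in per_condition.items()
        }
        stats["gene"] = gene
        stats["max_p_adjusted"] = max(
            res.loc[gene, "p_adjusted"] for res in per_condition.values()
        )
        stats["min_log_fc"] = min(
            res.loc[gene, "log_fc"] for res in per_condition.values()
        )
        rows.append(stats)
    cols = ["gene", "max_p_adjusted", "min_log_fc"] + [
        f"p_adjusted_{c}" for c in per_condition
    ]
    return pd.DataFrame(rows, columns=cols)


def map_signature_orthologs(
    sig: GeneSignature,
    table: pd.DataFrame,
    policy: str = "one_to_one",
) -> tuple:
    """Translate a signature across species via an ortholog symbol table.

    ``policy="one_to_one"`` keeps only unambiguous pairs;
    ``policy="all"`` keeps every mapped target. Returns
    ``(mapped_signature, unmapped_genes)``.
    """
    if policy not in ("one_to_one", "all"):
        raise ValueError(f"unknown policy {policy!r}")
    sub = table[table["source_symbol"].isin(sig.genes)]
    if policy == "one_to_one":
        sub = sub[sub["mapping_class"] == "one-to-one"]
    mapped, seen = [], set()
    by_source = sub.groupby("source_symbol", sort=False)["target_symbol"]
    targets = {src: list(vals) for src, vals in by_source}
    unmapped = [g for g in sig.genes if g not in targets]
    for g in sig.genes:
        for t in targets.get(g, ()):
            if t not in seen:
                seen.add(t)
                mapped.append(t)
    if not mapped:
        raise ValueError(
            f"signature {sig.name!r}: no genes map under policy {policy!r}"
        )
    out = GeneSignature(
        sig.name, f"{sig.description} (ortholog-mapped)", tuple(mapped)
    )
    return out, unmapped


def bulk_prepare(counts: CountMatrix) -> NormalizedMatrix:
    """Upper-quartile normalize, log2(x+1), per-gene median center.

    Each sample is scaled so its 75th percentile of nonzero counts
    equals the geometric mean of all samples' upper quartiles.
    """
    dense = counts.to_frame().astype(float)
    uqs = {}
    for s in dense.columns:
        nz = dense[s][dense[s] > 0]
        if nz.empty:
            raise ValueError(f"sample {s!r} has no nonzero counts")
        uq = np.percentile(nz, 75)
        if uq <= 0:
            raise ValueError(f"sample {s!r} has a degenerate upper quartile")
        uqs[s] = uq
    target = scipy.stats.gmean(list(uqs.values()))
    scaled = dense * (target / pd.Series(uqs))
    logged = np.log2(scaled + 1.0)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return NormalizedMatrix(centered, kind="scaled", scale_factor=target)


def compare_groups(
    scores: pd.DataFrame, group_labels: pd.Series
) -> pd.DataFrame:
    """Welch t-tests between every pair of groups, BH across pairs.

    ``scores`` is a signature score table (``unit_id``, ``score``);
    ``group_labels`` maps unit id → group.
    """
    labels = group_labels.loc[scores["unit_id"]]
    values = {
        g: scores["score"].to_numpy()[(labels == g).to_numpy()]
        for g in labels.unique()
    }
    for g, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 units")
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in combinations(values, 2):
        t, p = scipy.stats.ttest_ind(values[a], values[b], equal_var=False)
        rows.append((a, b, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "t_statistic", "p_value"])
    out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    return out
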