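"""Cell-composition shifts across disease states via per-cluster
binomial regression.

For each cluster *k* the model is a one-vs-rest logistic regression

    logit P(cell ∈ k) = β₀ + Σ β_state·I(state) [+ Σ β_batch·I(batch)]

fit by maximum likelihood; ``exp(β_state)`` is the odds ratio of finding
a cluster-*k* cell in that state relative to the reference state, with
Wald 95% confidence intervals and p-values, BH-adjusted across clusters.
Technical replicates enter as fixed batch effects nested within state
(one batch per state absorbed into the state term). A cluster entirely
absent from a state (perfect separation) falls back to the
Haldane–Anscombe-corrected 2×2 contingency estimate and is flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .sigstats import benjamini_hochberg

__all__ = ["composition_table", "fit_composition", "contingency_odds_ratio"]

_REQUIRED = ("cell_id", "cluster_label", "state_label", "batch_label")
_Z95 = scipy.stats.norm.ppf(0.975)


def _check_input(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in cells.columns]
    if missing:
        raise ValueError(f"composition input missing columns {missing}")
    if cells[list(_REQUIRED)].isna().any().any():
        raise ValueError("composition input contains missing labels")
    if cells["state_label"].nunique() < 2:
        raise ValueError("composition analysis needs at least 2 states")
    return cells


def composition_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-(state, cluster) counts and within-state proportions.

    Empty (state, cluster) combinations are reported with count 0.
    """
    missing = [c for c in ("cluster_label", "state_label") if c not in cells.columns]
    if missing:
        raise ValueError(f"composition input missing columns {missing}")
    counts = (
        cells.groupby(["state_label", "cluster_label"], sort=True)
        .size()
        .unstack(fill_value=0)
        .stack()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("state_label")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def contingency_odds_ratio(
    n1_in: int, n1_out: int, n2_in: int, n2_out: int, correct: bool = False
):
    """Closed-form 2×2 log odds ratio (group 2 vs group 1) with Wald SE.

    With ``correct`` (or any zero cell) the Haldane–Anscombe 0.5 is
    added to every cell of the table.
    """
    cells = np.array([n1_in, n1_out, n2_in, n2_out], dtype=float)
    if correct or np.any(cells == 0):
        cells = cells + 0.5
    a_in, a_out, b_in, b_out = cells
    log_or = np.log(b_in * a_out) - np.log(b_out * a_in)
    se = np.sqrt((1.0 / cells).sum())
    return float(log_or), float(se)


def _design(cells: pd.DataFrame, reference_state, other_states, include_batch):
    cols = {"const": np.ones(len(cells))}
    for s in other_states:
        cols[f"state_{s}"] = (cells["state_label"] == s).to_numpy(float)
    if include_batch:
        # within-state effect (sum-to-zero) coding: the state coefficient
        # is then the state contrast at the average of its batch effects,
        # i.e. a marginal-means-style contrast rather than a comparison
        # of two arbitrary baseline batches
        for s in [reference_state] + other_states:
            batches = sorted(
                cells.loc[cells["state_label"] == s, "batch_label"].unique()
            )
            for b in batches[1:]:
                col = np.zeros(len(cells))
                col[(cells["batch_label"] == b).to_numpy()] = 1.0
                col[(cells["batch_label"] == batches[0]).to_numpy()] = -1.0
                cols[f"batch_{b}"] = col
    return pd.DataFrame(cols, index=cells.index)


def fit_composition(
    cells: pd.DataFrame,
    reference_state: str,
    include_batch: bool = True,
) -> pd.DataFrame:
    """Odds ratios of cluster membership for each state vs the reference.

    Returns one row per (cluster, contrast) with the odds ratio, Wald
    95% CI, p-value and BH-adjusted p (adjusted across clusters within
    each contrast). ``flagged`` marks clusters where perfect separation
    forced the contingency fallback.
    """
    cells = _check_input(cells)
    states = sorted(cells["state_label"].unique())
    if reference_state not in states:
        raise ValueError(f"reference state {reference_state!r} not present")
    other_states = [s for s in states if s != reference_state]
    clusters = sorted(cells["cluster_label"].unique())

    X = _design(cells, reference_state, other_states, include_batch)
    ct = pd.crosstab(cells["state_label"], cells["cluster_label"])
    n_state = ct.sum(axis=1)

    rows = []
    for cluster in clusters:
        y = (cells["cluster_label"] == cluster).to_numpy(float)
        in_state = ct[cluster]
        separated = bool(
            ((in_state == 0) | (in_state == n_state)).any()
        )
        fit = None
        if not separated:
            try:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=200
                )
                if not np.isfinite(
                    fit.bse[[f"state_{s}" for s in other_states]]
                ).all():
                    fit = None
            except Exception:
                fit = None
        for s in other_states:
            if fit is not None:
                log_or = float(fit.params[f"state_{s}"])
                se = float(fit.bse[f"state_{s}"])
                flagged = False
            else:
                log_or, se = contingency_odds_ratio(
                    int(in_state[reference_state]),
                    int(n_state[reference_state] - in_state[reference_state]),
                    int(in_state[s]),
                    int(n_state[s] - in_state[s]),
                    correct=True,
                )
                flagged = True
            z = log_or / se
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            rows.append(
                {
                    "cluster": cluster,
                    "contrast": f"{s}_vs_{reference_state}",
                    "odds_ratio": float(np.exp(log_or)),
                    "ci_low": float(np.exp(log_or - _Z95 * se)),
                    "ci_high": float(np.exp(log_or + _Z95 * se)),
                    "p_value": float(p),
                    "flagged": flagged,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "p_adjusted"] = benjamini_hochberg(
            out.loc[idx, "p_value"].to_numpy()
        )
    return out
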