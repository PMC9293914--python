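"""Dual-correlation designation of copy-number-high (malignant) cells.

Given per-cell CNA profiles, the classifier (i) ranks candidate cells by
a CNA burden statistic (mean squared profile value), (ii) averages the
top fraction (default 5%) into an "aberrant" reference profile and the
known-normal cells into a "normal" reference profile, (iii) correlates
every cell with both references, and (iv) calls a cell malignant when it
correlates above the median with the aberrant reference AND below the
median with the normal reference. An alternative rule places the two
cutoffs at mean ± k·SD of each correlation distribution instead of the
medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .cna import CNAProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierParams",
    "cna_burden",
    "build_reference_profiles",
    "dual_correlation",
    "classify_cells",
    "call_malignant_cells",
]


@dataclass(frozen=True)
class ClassifierParams:
    top_fraction: float = 0.05
    rule: str = "median"          # or "mean_sd"
    sd_multiplier: float = 2.0
    correlation: str = "pearson"  # or "spearman"
    flag_ambiguous: bool = False

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.rule not in ("median", "mean_sd"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")


def cna_burden(profiles: CNAProfileMatrix) -> pd.Series:
    """Per-cell burden: mean over genes of the squared profile value."""
    vals = profiles.values.to_numpy()
    burden = pd.Series(
        (vals ** 2).mean(axis=0), index=profiles.cell_ids, name="burden"
    )
    return burden


def build_reference_profiles(
    profiles: CNAProfileMatrix,
    candidate_cells,
    normal_cells,
    params: ClassifierParams = ClassifierParams(),
):
    """Mean profile of the top-burden candidates and of the normal cells.

    The aberrant reference averages the ``ceil(top_fraction × n)``
    highest-burden candidate cells; burden ties break by cell id so the
    reference is deterministic.
    """
    candidates = pd.Index(candidate_cells)
    normals = pd.Index(normal_cells)
    if len(candidates) == 0 or len(normals) == 0:
        raise ValueError("candidate and normal cell sets must be non-empty")
    missing = candidates.union(normals).difference(profiles.cell_ids)
    if len(missing):
        raise KeyError(f"cells absent from profiles: {list(missing[:5])}")

    burden = cna_burden(profiles).loc[candidates]
    n_top = math.ceil(params.top_fraction * len(candidates))
    ranked = burden.to_frame().assign(cell=burden.index).sort_values(
        ["burden", "cell"], ascending=[False, True], kind="mergesort"
    )
    top = ranked.index[:n_top]
    if len(top) == 0:
        raise ValueError("top-burden candidate set is empty")
    malignant_ref = profiles.values[top].mean(axis=1)
    normal_ref = profiles.values[normals].mean(axis=1)
    return malignant_ref, normal_ref


def _correlate(vals: np.ndarray, ref: np.ndarray, method: str) -> np.ndarray:
    """Column-wise correlation of ``vals`` (genes × cells) with ``ref``."""
    if np.ptp(ref) == 0:
        raise ValueError("reference profile is constant; correlation undefined")
    if method == "spearman":
        vals = scipy.stats.rankdata(vals, axis=0)
        ref = scipy.stats.rankdata(ref)
    ref_c = ref - ref.mean()
    vals_c = vals - vals.mean(axis=0, keepdims=True)
    denom = np.sqrt((vals_c ** 2).sum(axis=0)) * np.sqrt((ref_c ** 2).sum())
    constant = denom == 0
    if constant.any():
        logger.warning(
            "%d constant cell profile(s); their correlations are set to 0",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vals_c * ref_c[:, None]).sum(axis=0) / denom
    return np.where(constant, 0.0, r)


def dual_correlation(
    profiles: CNAProfileMatrix,
    malignant_ref: pd.Series,
    normal_ref: pd.Series,
    params: ClassifierParams = ClassifierParams(),
    cells=None,
) -> pd.DataFrame:
    """Correlation of each cell's profile with both reference profiles."""
    cols = pd.Index(cells) if cells is not None else profiles.cell_ids
    vals = profiles.values[cols].to_numpy()
    r_mal = _correlate(vals, malignant_ref.to_numpy(), params.correlation)
    r_norm = _correlate(vals, normal_ref.to_numpy(), params.correlation)
    return pd.DataFrame(
        {"r_malignant": r_mal, "r_normal": r_norm}, index=cols
    )


def classify_cells(
    correlations: pd.DataFrame,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Apply the dual-correlation decision rule to the classified set.

    ``median`` rule: malignant iff r_malignant strictly exceeds the
    median r_malignant of the classified set AND r_normal lies strictly
    below the median r_normal. ``mean_sd`` rule: the same directionality
    with limits mean(r_malignant) + k·SD and mean(r_normal) − k·SD. A
    cell passing exactly one condition is "ambiguous" when
    ``flag_ambiguous`` is set, "normal" otherwise.
    """
    if len(correlations) < 2:
        raise ValueError("classification needs at least 2 cells")
    r_mal = correlations["r_malignant"]
    r_norm = correlations["r_normal"]
    if params.rule == "median":
        lim_mal = r_mal.median()
        lim_norm = r_norm.median()
    else:
        k = params.sd_multiplier
        lim_mal = r_mal.mean() + k * r_mal.std(ddof=1)
        lim_norm = r_norm.mean() - k * r_norm.std(ddof=1)
    pass_mal = r_mal > lim_mal
    pass_norm = r_norm < lim_norm
    call = np.where(
        pass_mal & pass_norm,
        "malignant",
        np.where(
            (pass_mal ^ pass_norm) & params.flag_ambiguous,
            "ambiguous",
            "normal",
        ),
    )
    out = correlations.copy()
    out["call"] = call
    return out


def call_malignant_cells(
    profiles: CNAProfileMatrix,
    candidate_cells,
    normal_cells=None,
    params: ClassifierParams = ClassifierParams(),
    sample_labels: pd.Series | None = None,
    normal_fraction: float = 0.5,
) -> pd.DataFrame:
    """End-to-end classification of the candidate cells.

    When ``sample_labels`` (cell id → sample id) is given, candidates
    are classified per sample, each sample building its own aberrant
    reference from its own top-burden candidates. The normal reference
    averages ``normal_cells`` when given; otherwise it averages the
    sample's own presumed-normal cells — the bottom ``normal_fraction``
    of candidates by burden — so that the normal pole shares the
    sample's systematic (batch) profile component the way the aberrant
    pole does. Returns a table with cell_id, sample, burden, both
    correlations and the call.
    """
    if not 0 < normal_fraction <= 1:
        raise ValueError("normal_fraction must lie in (0, 1]")
    candidates = pd.Index(candidate_cells)
    if sample_labels is None:
        groups = {"all": candidates}
    else:
        lab = sample_labels.loc[candidates]
        groups = {s: candidates[(lab == s).to_numpy()] for s in lab.unique()}
    burden = cna_burden(profiles)
    tables = []
    for sample, cells in groups.items():
        if len(cells) == 0:
            continue
        if normal_cells is None:
            ranked = burden.loc[cells].to_frame().assign(cell=cells)
            ranked = ranked.sort_values(
                ["burden", "cell"], ascending=[True, True], kind="mergesort"
            )
            normals = ranked.index[: math.ceil(normal_fraction * len(cells))]
        else:
            normals = pd.Index(normal_cells)
        mal_ref, norm_ref = build_reference_profiles(
            profiles, cells, normals, params
        )
        corr = dual_correlation(profiles, mal_ref, norm_ref, params, cells)
        calls = classify_cells(corr, params)
        calls.insert(0, "sample", sample)
        calls.insert(1, "burden", burden.loc[cells])
        tables.append(calls)
    out = pd.concat(tables)
    out.index.name = "cell_id"
    return out.reset_index()
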