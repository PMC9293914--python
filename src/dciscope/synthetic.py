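"""Synthetic scRNA-seq and bulk RNA-seq generator with planted ground truth.

The generator emulates the statistical structure of a multi-state mouse
mammary-gland single-cell experiment: several disease states (normal duct
→ in-situ lesion → invasive tumor) each profiled in replicate, every
sample a mixture of normal epithelial, malignant epithelial and
stromal/immune cells. Malignant cells carry arm-level copy-number dosage
effects (contiguous gene blocks whose expression is multiplied by a
segment factor), subpopulations carry gene-signature programs, and a
"dying cell" subset carries an elevated mitochondrial fraction so QC
filtering has something to remove.

Counts are negative binomial: for cell *c* and gene *g*,

    count ~ NB(mean = L_c · λ_g(type) · dosage_{g,c} · program_{g,c},
               dispersion θ)

with library size ``L_c`` lognormal, per-type relative expression λ
drawn once from a gamma distribution and normalized to sum to one, and a
single shared dispersion θ (var = μ + μ²/θ). Ground truth (cell type,
malignancy, active programs, batch) is returned alongside the counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "CellTypeProfile",
    "StateConfig",
    "CNASegment",
    "SignatureProgram",
    "SimConfig",
    "simulate_experiment",
    "BulkSubtype",
    "BulkConfig",
    "simulate_bulk",
    "derive_centroids",
    "simulate_composition",
    "generating_log_odds_ratio",
    "default_config",
    "classifier_config",
]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class CellTypeProfile:
    """Baseline expression descriptor for one cell type.

    Relative per-gene means are drawn once from Gamma(shape, scale) and
    normalized; ``markers`` are boosted ``marker_fold``-fold before
    normalization so marker-based typing is possible downstream.
    """

    name: str
    gamma_shape: float = 0.6
    gamma_scale: float = 1.0
    epithelial: bool = False
    markers: tuple = ()
    marker_fold: float = 8.0


@dataclass(frozen=True)
class StateConfig:
    """One disease state: replicate count, size and composition."""

    name: str
    proportions: dict  # cell-type name -> fraction, sums to 1
    n_replicates: int = 2
    cells_per_replicate: int = 500
    malignant_fraction: float = 0.0  # of epithelial cells in this state


@dataclass(frozen=True)
class CNASegment:
    """Contiguous dosage event: genes [start, end) of one chromosome ×m."""

    chromosome: str
    start: int
    end: int
    multiplier: float


@dataclass(frozen=True)
class SignatureProgram:
    """Fold-change program active in a target subpopulation.

    ``target`` is a cell-type name or the special label ``"malignant"``;
    ``states`` optionally restricts the program to given disease states.
    """

    name: str
    genes: tuple
    target: str
    fold: float = 2.0
    states: tuple | None = None


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_chromosomes: int = 10
    genes_per_chromosome: tuple | None = None  # None -> even split
    cell_type_profiles: tuple = ()
    states: tuple = ()
    cna_segments: tuple = ()
    signature_programs: tuple = ()
    library_size_mu: float = math.log(5000.0)
    library_size_sigma: float = 0.3
    nb_dispersion: float = 2.0
    mito_gene_fraction: float = 0.02
    dying_cell_fraction: float = 0.02
    dying_mito_target: float = 0.5
    batch_sigma: float = 0.0  # per-sample lognormal gene factor; 0 = off
    seed: int = 0

    # ---- derived geometry -------------------------------------------------
    def chromosome_sizes(self) -> tuple:
        if self.genes_per_chromosome is not None:
            sizes = tuple(int(s) for s in self.genes_per_chromosome)
            if sum(sizes) != self.n_genes:
                raise ConfigurationError(
                    "genes_per_chromosome must sum to n_genes"
                )
            return sizes
        base, extra = divmod(self.n_genes, self.n_chromosomes)
        return tuple(
            base + (1 if i < extra else 0) for i in range(self.n_chromosomes)
        )

    def n_mito_genes(self) -> int:
        return int(round(self.mito_gene_fraction * self.n_genes))

    def gene_names(self) -> list:
        """Gene universe; mitochondrial genes are the trailing ``mt-`` block."""
        n_mito = self.n_mito_genes()
        cut = self.n_genes - n_mito
        return [f"g{i:04d}" for i in range(cut)] + [
            f"mt-{i}" for i in range(cut, self.n_genes)
        ]

    def annotation(self) -> pd.DataFrame:
        sizes = self.chromosome_sizes()
        chroms, starts = [], []
        for ci, size in enumerate(sizes):
            chroms.extend([f"chr{ci + 1}"] * size)
            starts.extend(range(0, size * 1000, 1000))
        return pd.DataFrame(
            {"gene_id": self.gene_names(), "chromosome": chroms, "start": starts}
        )

    def validate(self) -> None:
        names = {p.name for p in self.cell_type_profiles}
        if len(names) != len(self.cell_type_profiles):
            raise ConfigurationError("duplicate cell-type profile names")
        epithelial = {p.name for p in self.cell_type_profiles if p.epithelial}
        universe = set(self.gene_names())
        for prof in self.cell_type_profiles:
            stray = set(prof.markers) - universe
            if stray:
                raise ConfigurationError(
                    f"profile {prof.name!r} markers outside gene universe: "
                    f"{sorted(stray)[:5]}"
                )
        for state in self.states:
            total = sum(state.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"state {state.name!r} proportions sum to {total}, not 1"
                )
            stray = set(state.proportions) - names
            if stray:
                raise ConfigurationError(
                    f"state {state.name!r} references unknown cell types {stray}"
                )
            if not 0.0 <= state.malignant_fraction <= 1.0:
                raise ConfigurationError("malignant_fraction outside [0, 1]")
            if state.malignant_fraction > 0 and not epithelial:
                raise ConfigurationError(
                    "malignant cells requested but no epithelial cell type"
                )
        sizes = dict(
            zip([f"chr{i + 1}" for i in range(len(self.chromosome_sizes()))],
                self.chromosome_sizes())
        )
        for seg in self.cna_segments:
            if seg.chromosome not in sizes:
                raise ConfigurationError(f"unknown chromosome {seg.chromosome!r}")
            if not (0 <= seg.start < seg.end <= sizes[seg.chromosome]):
                raise ConfigurationError(
                    f"segment {seg} outside chromosome {seg.chromosome!r}"
                )
            if seg.multiplier <= 0:
                raise ConfigurationError("dosage multipliers must be positive")
        for prog in self.signature_programs:
            stray = set(prog.genes) - universe
            if stray:
                raise ConfigurationError(
                    f"program {prog.name!r} genes outside universe: "
                    f"{sorted(stray)[:5]}"
                )
            if prog.fold <= 0:
                raise ConfigurationError("program fold must be positive")


# ---------------------------------------------------------------------------


def _segment_mask(config: SimConfig) -> np.ndarray:
    """Per-gene dosage multiplier vector for malignant cells."""
    ann = config.annotation()
    dosage = np.ones(config.n_genes)
    offsets = {}
    pos = 0
    for ci, size in enumerate(config.chromosome_sizes()):
        offsets[f"chr{ci + 1}"] = pos
        pos += size
    for seg in config.cna_segments:
        lo = offsets[seg.chromosome] + seg.start
        hi = offsets[seg.chromosome] + seg.end
        dosage[lo:hi] *= seg.multiplier
    assert len(ann) == config.n_genes
    return dosage


def _type_lambdas(config: SimConfig, rng: np.random.Generator) -> dict:
    """Draw one normalized relative-expression vector per cell type."""
    genes = pd.Index(config.gene_names())
    lambdas = {}
    for prof in config.cell_type_profiles:
        lam = rng.gamma(prof.gamma_shape, prof.gamma_scale, size=config.n_genes)
        lam = np.maximum(lam, 1e-8)
        if prof.markers:
            idx = genes.get_indexer(pd.Index(prof.markers))
            lam[idx] *= prof.marker_fold
        lambdas[prof.name] = lam / lam.sum()
    return lambdas


def simulate_experiment(config: SimConfig):
    """Simulate every sample of the configured experiment.

    Returns ``(samples, annotation, truth)`` where ``samples`` maps
    sample id (``state_repN``) to a :class:`CountMatrix`, ``annotation``
    is the gene table (gene_id, chromosome, start) and ``truth`` is the
    per-cell ground-truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = pd.Index(config.gene_names())
    lambdas = _type_lambdas(config, rng)
    dosage = _segment_mask(config)
    mito_mask = genes.str.startswith("mt-")
    profiles = {p.name: p for p in config.cell_type_profiles}
    theta = config.nb_dispersion

    prog_rows = {
        prog.name: genes.get_indexer(pd.Index(prog.genes))
        for prog in config.signature_programs
    }

    samples: dict = {}
    truth_rows = []
    for state in config.states:
        type_names = sorted(state.proportions)
        probs = np.array([state.proportions[t] for t in type_names])
        for rep in range(1, state.n_replicates + 1):
            sample_id = f"{state.name}_rep{rep}"
            n = state.cells_per_replicate
            cell_ids = [f"{sample_id}:c{i:05d}" for i in range(n)]
            types = rng.choice(type_names, size=n, p=probs)
            is_epi = np.array([profiles[t].epithelial for t in types])
            malignant = np.zeros(n, dtype=bool)
            if state.malignant_fraction > 0:
                malignant[is_epi] = (
                    rng.random(is_epi.sum()) < state.malignant_fraction
                )
            dying = rng.random(n) < config.dying_cell_fraction
            libsize = rng.lognormal(
                config.library_size_mu, config.library_size_sigma, size=n
            )

            mean = np.empty((config.n_genes, n))
            for t in type_names:
                cols = np.flatnonzero(types == t)
                if cols.size:
                    mean[:, cols] = lambdas[t][:, None]
            # planted copy-number dosage on malignant cells
            if malignant.any():
                mean[:, malignant] *= dosage[:, None]
            # signature programs
            active = [[] for _ in range(n)]
            for prog in config.signature_programs:
                if prog.states is not None and state.name not in prog.states:
                    continue
                if prog.target == "malignant":
                    cols = np.flatnonzero(malignant)
                else:
                    cols = np.flatnonzero(types == prog.target)
                if cols.size:
                    mean[np.ix_(prog_rows[prog.name], cols)] *= prog.fold
                    for c in cols:
                        active[c].append(prog.name)
            # dying cells: shift mass onto the mitochondrial block
            if dying.any() and mito_mask.any():
                for c in np.flatnonzero(dying):
                    s = mean[mito_mask, c].sum() / mean[:, c].sum()
                    tgt = config.dying_mito_target
                    if 0 < s < tgt:
                        boost = tgt * (1 - s) / (s * (1 - tgt))
                        mean[mito_mask, c] *= boost
            # per-cell library size (means are relative, so scale columns)
            mean *= libsize[None, :]
            # optional per-sample batch factor
            if config.batch_sigma > 0:
                batch = rng.lognormal(0.0, config.batch_sigma, config.n_genes)
                mean *= batch[:, None]

            shape = rng.gamma(theta, mean / theta)
            counts = rng.poisson(shape).astype(np.int64)
            samples[sample_id] = CountMatrix(
                sp.csr_matrix(counts), genes.copy(), pd.Index(cell_ids)
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "sample_id": sample_id,
                        "state": state.name,
                        "batch": sample_id,
                        "cell_type": types,
                        "is_epithelial": is_epi,
                        "is_malignant": malignant,
                        "is_dying": dying,
                        "active_programs": [";".join(a) for a in active],
                    }
                )
            )
    truth = pd.concat(truth_rows, ignore_index=True)
    return samples, config.annotation(), truth


# ---------------------------------------------------------------------------
# bulk simulation


@dataclass(frozen=True)
class BulkSubtype:
    name: str
    marker_genes: tuple
    fold: float = 4.0


@dataclass(frozen=True)
class BulkConfig:
    n_genes: int = 500
    subtypes: tuple = ()
    n_samples_per_subtype: int = 10
    library_size_mu: float = math.log(1e6)
    library_size_sigma: float = 0.2
    nb_dispersion: float = 20.0
    gamma_shape: float = 0.8
    gamma_scale: float = 1.0
    seed: int = 0

    def gene_names(self) -> list:
        return [f"g{i:04d}" for i in range(self.n_genes)]


def _bulk_lambdas(config: BulkConfig) -> dict:
    """Shared baseline with subtype-specific marker folds, normalized."""
    if len(config.subtypes) < 1:
        raise ConfigurationError("bulk simulation needs at least one subtype")
    rng = np.random.default_rng(config.seed + 104729)
    genes = pd.Index(config.gene_names())
    base = np.maximum(
        rng.gamma(config.gamma_shape, config.gamma_scale, config.n_genes), 1e-8
    )
    lambdas = {}
    for st in config.subtypes:
        stray = set(st.marker_genes) - set(genes)
        if stray:
            raise ConfigurationError(
                f"subtype {st.name!r} markers outside universe: {sorted(stray)[:5]}"
            )
        lam = base.copy()
        lam[genes.get_indexer(pd.Index(st.marker_genes))] *= st.fold
        lambdas[st.name] = lam / lam.sum()
    return lambdas


def simulate_bulk(config: BulkConfig):
    """Bulk genes × samples NB counts plus truth subtype labels."""
    lambdas = _bulk_lambdas(config)
    rng = np.random.default_rng(config.seed)
    genes = pd.Index(config.gene_names())
    cols, labels = [], []
    counts = []
    for st in config.subtypes:
        for i in range(config.n_samples_per_subtype):
            sid = f"{st.name}_s{i:02d}"
            lib = rng.lognormal(config.library_size_mu, config.library_size_sigma)
            mean = lambdas[st.name] * lib
            theta = config.nb_dispersion
            counts.append(rng.poisson(rng.gamma(theta, mean / theta)))
            cols.append(sid)
            labels.append(st.name)
    mat = sp.csr_matrix(np.column_stack(counts).astype(np.int64))
    cm = CountMatrix(mat, genes, pd.Index(cols))
    truth = pd.Series(labels, index=pd.Index(cols, name="sample_id"), name="subtype")
    return cm, truth


def derive_centroids(config: BulkConfig):
    """Centroid model from the generating means (log2 CPM, median-centered).

    This plays the role of an externally supplied subtype predictor: it
    is computed from the generator's expected profiles, not from any
    simulated sample.
    """
    from .containers import CentroidModel

    lambdas = _bulk_lambdas(config)
    prof = pd.DataFrame(
        {name: np.log2(lam * 1e6 + 1) for name, lam in lambdas.items()},
        index=pd.Index(config.gene_names()),
    )
    centered = prof.sub(prof.median(axis=1), axis=0)
    return CentroidModel(centered)


# ---------------------------------------------------------------------------
# composition simulation (for the cell-proportion GLM)


def simulate_composition(
    prevalence: dict,
    n_cells_per_batch: int = 1000,
    n_batches: int = 2,
    batch_sigma: float = 0.1,
    seed: int = 0,
):
    """Per-cell (cluster, state, batch) labels with planted prevalences.

    ``prevalence`` maps state → {cluster → probability}; the remaining
    mass goes to a background cluster ``"other"``. Batch effects jitter
    each cluster's log-odds by Normal(0, ``batch_sigma``) per batch.

    Returns ``(cells, truth)``: the per-cell label table and a truth
    table holding the post-jitter probability actually planted in each
    (batch, cluster) — the generative parameters a recovery analysis
    should be compared against (see
    :func:`generating_log_odds_ratio`).
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for state, clusters in prevalence.items():
        if sum(clusters.values()) > 1.0 + 1e-9:
            raise ConfigurationError(
                f"state {state!r} cluster prevalences exceed 1"
            )
        for b in range(1, n_batches + 1):
            batch = f"{state}_b{b}"
            names = list(clusters) + ["other"]
            logits = np.array(
                [math.log(p / (1 - p)) for p in clusters.values()]
            )
            logits = logits + rng.normal(0.0, batch_sigma, size=len(logits))
            probs = 1.0 / (1.0 + np.exp(-logits))
            for name, p in zip(clusters, probs):
                truth_rows.append((state, batch, name, float(p)))
            probs = np.append(probs, max(1.0 - probs.sum(), 1e-12))
            probs = probs / probs.sum()
            draws = rng.choice(names, size=n_cells_per_batch, p=probs)
            for i, cl in enumerate(draws):
                rows.append((f"{batch}:c{i:05d}", cl, state, batch))
    cells = pd.DataFrame(
        rows, columns=["cell_id", "cluster_label", "state_label", "batch_label"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["state_label", "batch_label", "cluster_label", "planted_p"],
    )
    return cells, truth


def generating_log_odds_ratio(
    truth: pd.DataFrame, cluster: str, state_a: str, state_b: str
) -> float:
    """Generative log odds ratio (state_b vs state_a) for one cluster:
    the difference of batch-averaged planted log-odds."""
    sub = truth[truth["cluster_label"] == cluster]

    def mean_logit(state):
        p = sub.loc[sub["state_label"] == state, "planted_p"]
        if p.empty:
            raise ConfigurationError(f"state {state!r} absent from truth")
        return float(np.mean(np.log(p / (1 - p))))

    return mean_logit(state_b) - mean_logit(state_a)


# ---------------------------------------------------------------------------
# standard study-like configurations


def default_config(seed: int = 0, cells_per_replicate: int = 500) -> SimConfig:
    """Three disease states × 2 replicates, mixed cell types, planted
    copy-number events and two signature programs.

    Mirrors the design of a staged mammary tumor-progression study:
    an early normal-duct state, an in-situ (DCIS-like) state and an
    invasive tumor state, each sampled in duplicate, with malignant
    epithelial burden rising along the progression.
    """
    profiles = (
        CellTypeProfile(
            "epithelial",
            epithelial=True,
            markers=tuple(f"g{i:04d}" for i in range(950, 960)),
        ),
        CellTypeProfile(
            "fibroblast", markers=tuple(f"g{i:04d}" for i in range(1150, 1160))
        ),
        CellTypeProfile(
            "immune", markers=tuple(f"g{i:04d}" for i in range(1350, 1360))
        ),
    )
    states = (
        StateConfig(
            "prepuberty",
            {"epithelial": 0.55, "fibroblast": 0.30, "immune": 0.15},
            cells_per_replicate=cells_per_replicate,
            malignant_fraction=0.05,
        ),
        StateConfig(
            "dcis",
            {"epithelial": 0.50, "fibroblast": 0.30, "immune": 0.20},
            cells_per_replicate=cells_per_replicate,
            malignant_fraction=0.30,
        ),
        StateConfig(
            "tumor",
            {"epithelial": 0.60, "fibroblast": 0.25, "immune": 0.15},
            cells_per_replicate=cells_per_replicate,
            malignant_fraction=0.60,
        ),
    )
    segments = (
        CNASegment("chr1", 0, 200, 1.5),
        CNASegment("chr3", 0, 200, 0.5),
    )
    programs = (
        SignatureProgram(
            "proliferation",
            tuple(f"g{i:04d}" for i in range(1550, 1580)),
            target="malignant",
            fold=3.0,
        ),
        SignatureProgram(
            "caf",
            tuple(f"g{i:04d}" for i in range(1650, 1680)),
            target="fibroblast",
            fold=3.0,
            states=("tumor",),
        ),
    )
    return SimConfig(
        n_genes=2000,
        n_chromosomes=10,
        cell_type_profiles=profiles,
        states=states,
        cna_segments=segments,
        signature_programs=programs,
        batch_sigma=0.2,
        seed=seed,
    )


def classifier_config(
    seed: int = 0,
    n_cells: int = 3000,
    with_segments: bool = True,
    n_reference_cells: int = 500,
) -> SimConfig:
    """Single tumor-like state plus a pure normal reference sample.

    The tumor state holds ``n_cells`` cells of which 20% are malignant
    (50% epithelial × 40% malignant among epithelial); malignant cells
    carry one 200-gene gain at 1.5× and one 200-gene loss at 0.5×. The
    ``normalref`` sample emulates normal mammary epithelium from a
    healthy animal of the same strain and supplies the diploid baseline.
    """
    profiles = (
        CellTypeProfile(
            "epithelial",
            epithelial=True,
            markers=tuple(f"g{i:04d}" for i in range(950, 960)),
        ),
        CellTypeProfile(
            "fibroblast", markers=tuple(f"g{i:04d}" for i in range(1150, 1160))
        ),
        CellTypeProfile(
            "immune", markers=tuple(f"g{i:04d}" for i in range(1350, 1360))
        ),
    )
    states = (
        StateConfig(
            "normalref",
            {"epithelial": 1.0},
            n_replicates=1,
            cells_per_replicate=n_reference_cells,
            malignant_fraction=0.0,
        ),
        StateConfig(
            "tumor",
            {"epithelial": 0.5, "fibroblast": 0.3, "immune": 0.2},
            n_replicates=2,
            cells_per_replicate=n_cells // 2,
            malignant_fraction=0.4,
        ),
    )
    segments = (
        (CNASegment("chr1", 0, 200, 1.5), CNASegment("chr3", 0, 200, 0.5))
        if with_segments
        else ()
    )
    return SimConfig(
        n_genes=2000,
        n_chromosomes=10,
        cell_type_profiles=profiles,
        states=states,
        cna_segments=segments,
        batch_sigma=0.2,
        seed=seed,
    )
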