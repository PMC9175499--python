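"""Digital spatial profiling (DSP) analysis of ROI-level gene counts.

Emulates the GeoMX-style workflow on a genes × ROIs count matrix in which each
region of interest (ROI) is labelled as fibroblastic focus, dense fibrosis, or
normal lung: quality control, housekeeping and upper-quartile (Q3)
normalization, per-gene differential expression with Benjamini–Hochberg
q-values and a fold-change filter, hierarchical clustering under uncentered
Pearson distance, principal component analysis, and gene set enrichment
analysis (GSEA) with gene-set permutation.

Counts are expected at gene level.  A probe-level table (multiple probes per
gene) can be collapsed with :func:`collapse_probes` (geometric mean per gene)
before constructing the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import DataError

log = logging.getLogger(__name__)

ROI_CLASSES = ["focus", "fibrosis", "normal"]

#: DE selection thresholds: BH q-value below 0.05 and linear fold change of at
#: least 1.5 in either direction (inclusive).
Q_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


@dataclass
class DSPExperiment:
    """ROI-class-labelled gene count matrix with its housekeeping gene list."""

    counts: pd.DataFrame  # genes (rows) × ROIs (columns), non-negative
    roi_meta: pd.DataFrame  # columns: roi_id, class, case_id
    housekeeping: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        meta = self.roi_meta.set_index("roi_id") if "roi_id" in self.roi_meta.columns else self.roi_meta
        missing_meta = [c for c in self.counts.columns if c not in meta.index]
        if missing_meta:
            raise DataError(f"ROIs without metadata: {missing_meta[:5]}")
        self.roi_meta = meta.loc[list(self.counts.columns)].reset_index().rename(
            columns={"index": "roi_id"}
        )
        bad_hk = [g for g in self.housekeeping if g not in self.counts.index]
        if bad_hk:
            raise DataError(f"housekeeping genes absent from counts: {bad_hk[:5]}")
        bad_cls = set(self.roi_meta["class"]) - set(ROI_CLASSES)
        if bad_cls:
            raise DataError(f"unknown ROI class labels: {sorted(bad_cls)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def rois(self) -> list[str]:
        return list(self.counts.columns)

    def rois_of_class(self, cls: str) -> list[str]:
        meta = self.roi_meta
        return list(meta.loc[meta["class"] == cls, "roi_id"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_experiment(counts_path, meta_path, housekeeping_path=None) -> DSPExperiment:
    """Read counts TSV (first column gene id), ROI metadata TSV, and an
    optional housekeeping list (one gene id per line)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("roi_id", "class"):
        if col not in meta.columns:
            raise DataError(f"ROI metadata lacks column {col!r}")
    hk: list[str] = []
    if housekeeping_path is not None:
        with open(housekeeping_path) as fh:
            hk = [line.strip() for line in fh if line.strip()]
    return DSPExperiment(counts=counts, roi_meta=meta, housekeeping=hk)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise DataError(f"{path}: no gene sets parsed")
    return sets


def collapse_probes(probe_counts: pd.DataFrame, gene_col: str = "gene") -> pd.DataFrame:
    """Collapse a probe-level table to gene level by per-gene geometric mean."""
    if gene_col not in probe_counts.columns:
        raise DataError(f"probe table lacks column {gene_col!r}")
    grouped = np.log1p(probe_counts.set_index(gene_col)).groupby(level=0).mean()
    return np.expm1(grouped)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    exp: DSPExperiment, min_roi_total: float, min_gene_mean: float = 0.0
) -> DSPExperiment:
    """Drop under-sequenced ROIs and near-silent genes.

    ROIs whose total count is below ``min_roi_total`` and genes whose mean
    count (over retained ROIs) is below ``min_gene_mean`` are removed;
    housekeeping genes are never dropped.  Every removal is logged.  Removing
    every ROI of a class is a QC failure.
    """
    totals = exp.counts.sum(axis=0)
    keep_rois = totals[totals >= min_roi_total].index.tolist()
    for roi in exp.counts.columns:
        if roi not in keep_rois:
            log.info("qc_filter: dropping ROI %s (total %s < %s)", roi, totals[roi], min_roi_total)
    counts = exp.counts[keep_rois]
    gene_means = counts.mean(axis=1)
    keep_genes = [
        g
        for g in counts.index
        if gene_means[g] >= min_gene_mean or g in set(exp.housekeeping)
    ]
    for g in counts.index:
        if g not in set(keep_genes):
            log.info("qc_filter: dropping gene %s (mean %.3g < %s)", g, gene_means[g], min_gene_mean)
    meta = exp.roi_meta[exp.roi_meta["roi_id"].isin(keep_rois)]
    for cls in sorted(set(exp.roi_meta["class"])):
        if cls not in set(meta["class"]):
            raise DataError(f"QC removed every ROI of class {cls!r}")
    return DSPExperiment(
        counts=counts.loc[keep_genes],
        roi_meta=meta.reset_index(drop=True),
        housekeeping=list(exp.housekeeping),
    )


def _geomean(a: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(a), axis=0))


def hk_normalize(exp: DSPExperiment) -> pd.DataFrame:
    """Housekeeping normalization.

    Each ROI's scale factor is the geometric mean of its housekeeping-gene
    counts divided by the geometric mean of those per-ROI geomeans across the
    study; counts are divided by the factor.  A zero housekeeping count is a
    hard error naming the ROI and gene (no silent pseudo-count imputation).
    """
    if not exp.housekeeping:
        raise DataError("experiment has no housekeeping genes")
    hk = exp.counts.loc[exp.housekeeping]
    zero = np.argwhere(hk.to_numpy() == 0)
    if zero.size:
        g, r = zero[0]
        raise DataError(
            f"zero housekeeping count: gene {hk.index[g]!r} in ROI {hk.columns[r]!r}"
        )
    roi_geomeans = _geomean(hk.to_numpy())
    factors = roi_geomeans / stats.gmean(roi_geomeans)
    return exp.counts / pd.Series(factors, index=exp.counts.columns)


def q3_normalize(exp: DSPExperiment) -> pd.DataFrame:
    """Upper-quartile normalization.

    Each ROI's factor is its 75th-percentile count (linear interpolation)
    divided by the geometric mean of all ROIs' 75th percentiles.
    """
    q3 = exp.counts.quantile(0.75, axis=0, interpolation="linear")
    if (q3 <= 0).any():
        bad = q3.index[q3 <= 0].tolist()
        raise DataError(f"non-positive 75th percentile in ROI(s) {bad[:5]}")
    factors = q3 / stats.gmean(q3.to_numpy())
    return exp.counts / factors


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def de_test(
    norm: pd.DataFrame,
    class_a_rois: list[str],
    class_b_rois: list[str],
    method: str = "welch",
    q_threshold: float = Q_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene differential expression between two ROI groups.

    Tests log2(count + 1) per gene with Welch's two-sample t-test by default
    (``method="mannwhitney"`` switches to the rank test).  log2FC is the
    difference of group means on the log2 scale (A over B); fold_change is
    2^|log2FC| with the direction kept in the sign of log2FC.  q-values are
    Benjamini–Hochberg over all tested genes; a gene is selected iff
    q < ``q_threshold`` and fold_change >= ``fc_threshold``.
    """
    if len(class_a_rois) < 2 or len(class_b_rois) < 2:
        raise DataError("each compared class needs at least 2 ROIs")
    a = np.log2(norm[class_a_rois].to_numpy(dtype=float) + 1.0)
    b = np.log2(norm[class_b_rois].to_numpy(dtype=float) + 1.0)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    if method == "welch":
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "mannwhitney":
        p = np.array(
            [stats.mannwhitneyu(a[i], b[i]).pvalue for i in range(a.shape[0])]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    # degenerate genes: zero variance in both groups
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(var0 & (log2fc == 0), 1.0, p)
    p = np.where(var0 & (log2fc != 0), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    fc = 2.0 ** np.abs(log2fc)
    table = pd.DataFrame(
        {
            "gene": norm.index,
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_fold_change": log2fc,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
        }
    ).set_index("gene")
    table["selected"] = (table["q_value"] < q_threshold) & (table["fold_change"] >= fc_threshold)
    return table


def de_focus_vs_rest(exp: DSPExperiment, norm: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """The headline contrast: fibroblastic foci vs pooled fibrosis + normal."""
    focus = exp.rois_of_class("focus")
    rest = [r for r in exp.rois if r not in set(focus)]
    return de_test(norm, focus, rest, **kwargs)


# ---------------------------------------------------------------------------
# Clustering, PCA
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list
    labels: list

    def to_newick(self) -> str:
        """Serialise the dendrogram as a Newick string."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hier_cluster(matrix: pd.DataFrame, axis: str = "columns") -> ClusterResult:
    """Average-linkage hierarchical clustering under 1 − uncentered Pearson.

    The uncentered Pearson correlation of two profiles is their cosine
    similarity, so the dissimilarity is the cosine distance.  ``axis`` chooses
    whether columns (ROIs) or rows (genes) are clustered.
    """
    X = matrix.to_numpy(dtype=float).T if axis == "columns" else matrix.to_numpy(dtype=float)
    labels = list(matrix.columns) if axis == "columns" else list(matrix.index)
    if X.shape[0] < 2:
        raise DataError("clustering needs at least 2 items")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [labels[i] for i in np.flatnonzero(norms == 0)]
        raise DataError(f"zero-vector item(s) under uncentered correlation: {bad[:5]}")
    dist = np.clip(pdist(X, metric="cosine"), 0.0, None)
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(linkage=Z, leaf_order=[labels[i] for i in order], labels=labels)


def heatmap_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene (row) into [−1, +1] by its maximum absolute value,
    after row-centering the log2 values — the display transform for heat maps."""
    X = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    X = X - X.mean(axis=1, keepdims=True)
    denom = np.abs(X).max(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    return pd.DataFrame(X / denom, index=matrix.index, columns=matrix.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # ROIs × components
    loadings: pd.DataFrame  # genes × components
    explained_variance_ratio: np.ndarray


def pca(norm: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of ROIs over the row-centered log2 expression matrix.

    Components are eigenvectors of the gene-space covariance across ROIs,
    ordered by decreasing variance.  Sign convention: within each component
    the largest-magnitude gene loading is made positive.
    """
    X = np.log2(norm.to_numpy(dtype=float) + 1.0)
    if X.shape[1] < 2:
        raise DataError("PCA needs at least 2 ROIs")
    Xc = X - X.mean(axis=1, keepdims=True)  # center each gene
    D = Xc.T  # ROIs as samples
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    k = n_components or min(D.shape)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for j in range(min(k, loadings.shape[1])):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=norm.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=norm.index, columns=comp_names),
        explained_variance_ratio=np.asarray(ratio[:k]),
    )


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


@dataclass
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    size: int


def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Weighted running-sum enrichment score over a ranked list.

    Member genes advance the running sum by their |score| weight (normalised
    to sum 1 over the set); every position retires the uniform expectation
    1/N, so the sum is a bridge ending at 0.  The ES is the extremum of
    largest magnitude, sign retained.
    """
    n = in_set.size
    w = weights * in_set
    total = w.sum()
    if total > 0:
        hit = np.cumsum(w) / total
    else:  # all-zero scores: fall back to unweighted hit fraction
        hit = np.cumsum(in_set) / max(in_set.sum(), 1)
    running = hit - np.arange(1, n + 1) / n
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext])


def gsea(
    scores: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene set enrichment analysis over a score-ranked gene list.

    Genes are ranked by decreasing score (ties broken by gene id for
    determinism); the running-sum statistic weights member genes by |score|
    (weight exponent 1).  Because ROI-level designs are far too small for
    phenotype permutation, the null is generated by gene-set permutation:
    ``n_perm`` same-size sets are resampled from the ranked universe with a
    seeded RNG.  NES = ES / mean(|permuted ES| of matching sign); the nominal
    p-value counts matching-sign permutations at least as extreme, and the
    FDR q compares each NES against the pooled permutation NES distribution
    across all tested sets (GSEA-style ratio, clipped to [0, 1]).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    ranked = np.asarray([scores[g] for g in order], dtype=float)
    if not np.all(np.isfinite(ranked)):
        raise DataError("gene scores must be finite")
    universe = list(order)
    gene_pos = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    weights = np.abs(ranked)
    rng = np.random.default_rng(seed)

    rows = []
    perm_nes_pos: list[float] = []
    perm_nes_neg: list[float] = []
    obs_nes = {}
    for name, members in gene_sets.items():
        hit_idx = sorted({gene_pos[g] for g in members if g in gene_pos})
        if not hit_idx:
            raise DataError(f"gene set {name!r} has empty intersection with the ranked list")
        if len(hit_idx) >= n:
            raise DataError(f"gene set {name!r} covers the whole ranked universe")
        in_set = np.zeros(n)
        in_set[hit_idx] = 1.0
        es = _enrichment_score(in_set, weights)
        size = len(hit_idx)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n)
            mask[idx] = 1.0
            perm_es[b] = _enrichment_score(mask, weights)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            same_sign = np.abs(perm_es)
        denom = np.mean(np.abs(same_sign))
        nes = es / denom if denom > 0 else 0.0
        nominal_p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        # pooled permutation NES for the FDR step
        pos = perm_es[perm_es > 0]
        neg = perm_es[perm_es < 0]
        if pos.size:
            perm_nes_pos.extend((pos / np.mean(pos)).tolist())
        if neg.size:
            perm_nes_neg.extend((neg / np.mean(np.abs(neg))).tolist())
        obs_nes[name] = nes
        rows.append({"gene_set": name, "es": es, "nes": nes, "nominal_p": nominal_p, "size": size})

    nes_values = np.array([r["nes"] for r in rows])
    for r in rows:
        nes = r["nes"]
        if nes >= 0:
            pool = np.asarray(perm_nes_pos)
            frac_null = np.mean(pool >= nes) if pool.size else 0.0
            frac_obs = np.mean(nes_values >= nes)
        else:
            pool = np.asarray(perm_nes_neg)
            frac_null = np.mean(pool <= nes) if pool.size else 0.0
            frac_obs = np.mean(nes_values <= nes)
        r["fdr_q"] = float(np.clip(frac_null / max(frac_obs, 1e-12), 0.0, 1.0))
    table = pd.DataFrame(rows).set_index("gene_set")
    return table[["es", "nes", "nominal_p", "fdr_q", "size"]]


def rank_genes_for_gsea(de_table: pd.DataFrame) -> pd.Series:
    """Signed ranking score from a DE table: signed −log10(p)."""
    p = de_table["p_value"].clip(lower=1e-300)
    return np.sign(de_table["log2_fold_change"]) * (-np.log10(p))
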