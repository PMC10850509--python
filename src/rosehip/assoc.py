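"""Target-gene association statistics.

Peak-count expression bins with a Welch test, observed-vs-random overlap
chi-square, fold-change correlations between perturbations, the
fold/adjusted-p responsive-gene selection, and top-percent / PC1
contributor gene selection.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GenomeModel, Peak


@dataclass
class SelectionConfig:
    min_fold: float = 8.0  # linear scale, inclusive
    max_padj: float = 0.01  # strict <
    top_percent: float = 1.0
    pc1_coefficient_min: float = 0.05

    def __post_init__(self) -> None:
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if not (0.0 < self.max_padj <= 1.0):
            raise ValueError("max_padj must be in (0, 1]")
        if not (0.0 < self.top_percent <= 100.0):
            raise ValueError("top_percent must be in (0, 100]")


# ---- peak-count expression bins ----------------------------------------


@dataclass
class PeakCountBinsResult:
    bins: pd.DataFrame  # per peak count: n, mean, q25, q75
    t_statistic: float  # Welch t, (>=3 group) minus (1-2 group)
    p_value: float
    n_low: int
    n_high: int


def peak_count_expression_contrast(
    gene_peak_counts: dict[str, int] | pd.Series,
    expression: pd.DataFrame,
    high_threshold: int = 3,
) -> PeakCountBinsResult:
    """Bin genes by associated peak count; Welch-test {1..2} vs {>= 3}.

    ``expression`` needs gene_id and log2fc columns.  Genes without a
    positive peak count are excluded.  The test is the two-sided
    heteroscedastic (Welch) t comparing mean log2FC of genes with 1-2
    peaks against genes with >= ``high_threshold`` peaks.
    """
    counts = pd.Series(gene_peak_counts, name="n_peaks")
    df = expression.merge(
        counts.rename_axis("gene_id").reset_index(), on="gene_id", how="inner"
    )
    df = df[df["n_peaks"] >= 1]
    bins = (
        df.groupby("n_peaks")["log2fc"]
        .agg(
            n="size",
            mean="mean",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    low = df.loc[df["n_peaks"] < high_threshold, "log2fc"].to_numpy()
    high = df.loc[df["n_peaks"] >= high_threshold, "log2fc"].to_numpy()
    if len(low) < 2 or len(high) < 2:
        warnings.warn("fewer than 2 genes in a bin group; Welch test skipped")
        return PeakCountBinsResult(bins, float("nan"), float("nan"), len(low), len(high))
    if np.var(low) == 0 and np.var(high) == 0 and low.mean() == high.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(high, low, equal_var=False)
    return PeakCountBinsResult(bins, float(t), float(p), len(low), len(high))


# ---- observed vs random overlap chi-square ------------------------------


@dataclass
class OverlapTestResult:
    table: np.ndarray  # 2x2: rows observed/random, cols overlap yes/no
    chi2: float
    df: int
    p_value: float
    n_draws: int
    observed_overlap: int
    random_overlap: int


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table without continuity correction."""
    t = np.asarray(table, dtype=float)
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _count_overlapping(peaks: list[Peak], trees: dict[str, IntervalTree]) -> int:
    return sum(
        1
        for p in peaks
        if p.chrom in trees and trees[p.chrom].overlap(p.start, p.end)
    )


def overlap_chi2_vs_random(
    peaks_a: list[Peak],
    feature_peaks: list[Peak],
    genome: GenomeModel,
    n_draws: int = 1,
    seed: int = 0,
) -> OverlapTestResult:
    """Chi-square of observed feature overlap against random placement.

    Observed: peaks in ``peaks_a`` overlapping >= 1 feature peak by >= 1 bp.
    Random: the same count after width-preserving uniform re-placement of
    each peak within its own chromosome, averaged over ``n_draws`` draws
    and rounded.  The 2x2 table [observed, random] x [overlap, no-overlap]
    is tested without continuity correction at df = 1.  With ``n_draws``
    = 1 the random arm is a genuine single realization and the test is
    calibrated; averaging many draws shrinks the random arm's variance and
    makes the test conservative.
    """
    lengths = genome.chrom_lengths
    for p in peaks_a:
        if p.chrom not in lengths:
            raise ValueError(f"peak {p.name}: unknown chromosome {p.chrom}")
        if p.width > lengths[p.chrom]:
            raise ValueError(f"peak {p.name} wider than chromosome {p.chrom}")
    trees: dict[str, IntervalTree] = {}
    for f in feature_peaks:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end)

    n = len(peaks_a)
    observed = _count_overlapping(peaks_a, trees)

    rng = np.random.default_rng(seed)
    draw_counts = []
    for _ in range(n_draws):
        count = 0
        for p in peaks_a:
            start = int(rng.integers(0, lengths[p.chrom] - p.width + 1))
            tree = trees.get(p.chrom)
            if tree and tree.overlap(start, start + p.width):
                count += 1
        draw_counts.append(count)
    random_overlap = int(round(float(np.mean(draw_counts))))

    table = np.array(
        [[observed, n - observed], [random_overlap, n - random_overlap]], dtype=float
    )
    chi2, p = chi2_2x2(table)
    return OverlapTestResult(table, chi2, 1, p, n_draws, observed, random_overlap)


# ---- fold-change correlation -------------------------------------------


@dataclass
class CorrelationResult:
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n_genes: int


def foldchange_correlation(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    gene_set: set[str] | None = None,
) -> CorrelationResult:
    """Spearman and Pearson correlation of log2FC between two contrasts,
    over the intersection of ``gene_set`` with both tables (midrank ties)."""
    a = expr_a.set_index("gene_id")["log2fc"]
    b = expr_b.set_index("gene_id")["log2fc"]
    genes = a.index.intersection(b.index)
    if gene_set is not None:
        genes = genes.intersection(pd.Index(sorted(gene_set)))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    x = a.loc[genes].to_numpy()
    y = b.loc[genes].to_numpy()
    rho, rho_p = stats.spearmanr(x, y)
    r, r_p = stats.pearsonr(x, y)
    return CorrelationResult(float(rho), float(rho_p), float(r), float(r_p), len(genes))


# ---- responsive-gene selection -----------------------------------------


def select_responsive_genes(
    contrasts: dict[str, pd.DataFrame], config: SelectionConfig | None = None
) -> set[str]:
    """Genes upregulated >= min_fold with padj < max_padj in EVERY contrast.

    A gene missing from any contrast fails that contrast.  Fold is linear
    (log2fc >= log2(min_fold), inclusive); adjusted p strictly below.
    """
    config = config or SelectionConfig()
    if not contrasts:
        raise ValueError("no contrasts supplied")
    log2_min = math.log2(config.min_fold)
    selected: set[str] | None = None
    for name, df in contrasts.items():
        ok = df[(df["log2fc"] >= log2_min) & (df["padj"] < config.max_padj)]
        genes = set(ok["gene_id"])
        selected = genes if selected is None else selected & genes
    return selected or set()


# ---- top-percent and PC1-contributor selection --------------------------


@dataclass
class TopPc1Result:
    top_genes: list[str]
    pc1_contributors: list[str]
    pc1_loadings: pd.Series
    explained_variance_ratio: float


def top_and_pc1_selection(
    scores: pd.Series,
    expression_matrix: pd.DataFrame,
    control_samples: list[str],
    knockdown_samples: list[str],
    config: SelectionConfig | None = None,
) -> TopPc1Result:
    """Top-percent genes by aggregate score, then PC1 contributors.

    The top set is the highest ceil(n * pct / 100) genes by score (ties by
    gene_id).  PCA is an eigen-decomposition of the gene-wise covariance
    of the row-centered expression matrix (genes x samples) restricted to
    the top set.  PC1's sign is oriented so its gene loadings correlate
    positively with the mean control-minus-knockdown difference;
    contributors are genes with loading > ``pc1_coefficient_min``.
    """
    config = config or SelectionConfig()
    n = len(scores)
    if n == 0:
        raise ValueError("empty score table")
    k = math.ceil(n * config.top_percent / 100.0)
    ranked = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    top_genes = list(ranked.index[:k])

    missing = [g for g in top_genes if g not in expression_matrix.index]
    if missing:
        raise ValueError(f"{len(missing)} top genes absent from expression matrix")
    X = expression_matrix.loc[top_genes].to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples for the component analysis")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("expression matrix is constant; components undefined")
    cov = np.cov(Xc)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]
    evr = float(eigvals[-1] / eigvals.sum()) if eigvals.sum() > 0 else float("nan")

    cols = list(expression_matrix.columns)
    ctrl_idx = [cols.index(s) for s in control_samples]
    kd_idx = [cols.index(s) for s in knockdown_samples]
    diff = X[:, ctrl_idx].mean(axis=1) - X[:, kd_idx].mean(axis=1)
    orient = np.dot(pc1, diff - diff.mean())
    if orient < 0:
        pc1 = -pc1
    loadings = pd.Series(pc1, index=top_genes, name="pc1_loading")
    contributors = sorted(loadings.index[loadings > config.pc1_coefficient_min])
    return TopPc1Result(top_genes, contributors, loadings, evr)
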