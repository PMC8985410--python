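"""Weighted coexpression network construction and module detection.

The workflow mirrors standard unsigned WGCNA: Pearson correlation across
samples, soft-thresholding ``a_ij = |r_ij| ** beta`` with the power chosen
so that the connectivity distribution is approximately scale-free
(log-log fit R^2 above a target, 0.80 by default), transformation to the
topological overlap matrix (TOM), average-linkage hierarchical clustering
on the 1 - TOM distance with a fixed-height cut, module eigengenes as
first principal components, and eigengene-phenotype correlation to pick
the disease-associated module.

The network is unsigned (absolute correlation) and clustering uses a
deterministic fixed-height cut with a minimum module size rather than the
full dynamic tree cut; both choices are documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthdata import ExpressionStudy


def correlation_matrix(study: ExpressionStudy) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes across samples (unit diagonal).

    Zero-variance genes get correlation 0 with every other gene (with a
    warning), keeping the matrix well defined.
    """
    values = study.values.to_numpy()
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance genes: correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=study.values.index, columns=study.values.index)


def adjacency(correlation: np.ndarray | pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``a_ij = |r_ij| ** beta``."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    r = np.asarray(correlation, dtype=float)
    return np.abs(r) ** beta


@dataclass
class SoftThresholdScan:
    """Scale-free fit record per candidate power."""

    powers: list[int]
    fit_r2: list[float]  # signed R^2 (negative when slope is positive)
    mean_connectivity: list[float]
    chosen_power: int
    target_reached: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; log10
    frequency is regressed on log10 mean connectivity per bin.  The R^2 is
    given the sign opposite to the slope, so only a decreasing (scale-free
    like) distribution scores positively.
    """
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_freq = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_freq.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    res = stats.linregress(log_k, log_freq)
    return float(np.sign(-res.slope) * res.rvalue**2)


def pick_soft_threshold(
    correlation: np.ndarray | pd.DataFrame,
    powers: range | list[int] = range(1, 21),
    r2_target: float = 0.80,
) -> SoftThresholdScan:
    """Scan powers 1..20 and pick the smallest achieving scale-free fit.

    For each power the adjacency is formed, per-gene connectivity
    ``k_i = sum_{j != i} a_ij`` computed, and the signed log-log fit R^2
    evaluated.  The chosen power is the smallest with fit above
    ``r2_target``; if none qualifies the argmax is returned with
    ``target_reached=False`` and a warning.
    """
    r = np.asarray(correlation, dtype=float)
    powers = list(powers)
    fits, mean_k = [], []
    for beta in powers:
        a = adjacency(r, beta)
        k = a.sum(axis=0) - np.diag(a)
        fits.append(_scale_free_fit(k))
        mean_k.append(float(k.mean()))
    qualifying = [b for b, f in zip(powers, fits) if f > r2_target]
    if qualifying:
        chosen, reached = qualifying[0], True
    else:
        chosen, reached = powers[int(np.argmax(fits))], False
        warnings.warn(
            f"no power reached scale-free fit {r2_target}; "
            f"using argmax power {chosen}",
            stacklevel=2,
        )
    return SoftThresholdScan(
        powers=powers,
        fit_r2=fits,
        mean_connectivity=mean_k,
        chosen_power=chosen,
        target_reached=reached,
    )


def tom(adjacency_matrix: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity ``k`` excluding the diagonal; ``TOM_ii = 1``.
    """
    a = np.asarray(adjacency_matrix, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=0) - np.diag(a)
    # (A @ A)_ij counts u = i and u = j once each as a_ij (unit diagonal)
    shared = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    numerator = shared + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numerator / denominator
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


@dataclass
class ModulePartition:
    """Gene-to-module assignment with module eigengenes.

    Label 0 means unassigned; labels 1, 2, ... are ordered by decreasing
    module size.
    """

    assignment: pd.Series
    min_module_size: int
    cut_height: float
    eigengenes: pd.DataFrame | None = None  # samples x modules
    module_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})


def cluster_modules(
    tom_matrix: np.ndarray | pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a fixed-height cut.

    ``cut_height`` is relative to the dendrogram: the tree is cut at
    ``q5 + cut_height * (max - q5)`` where ``q5`` and ``max`` are the 5th
    percentile and maximum of the merge heights.  (An absolute cut fails
    whenever soft-thresholding concentrates all TOM distances just below
    1; the relative form is the convention of tree-cut implementations.)
    Clusters smaller than ``min_module_size`` are relabeled 0
    (unassigned); surviving modules are renumbered by decreasing size
    (ties by first occurrence).
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must lie in (0, 1]")
    t = np.asarray(tom_matrix, dtype=float)
    gene_index = (
        tom_matrix.index
        if isinstance(tom_matrix, pd.DataFrame)
        else pd.RangeIndex(t.shape[0])
    )
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    lo, hi = np.percentile(heights, 5), heights.max()
    threshold = lo + cut_height * (hi - lo)
    raw = hierarchy.fcluster(link, t=threshold, criterion="distance")

    counts = pd.Series(raw).value_counts()
    keep = counts[counts >= min_module_size]
    order = sorted(
        keep.index,
        key=lambda lab: (-keep[lab], int(np.argmax(raw == lab))),
    )
    relabel = {old: new for new, old in enumerate(order, start=1)}
    assignment = pd.Series(
        [relabel.get(lab, 0) for lab in raw], index=gene_index, name="module"
    )
    sizes = {new: int(keep[old]) for old, new in relabel.items()}
    return ModulePartition(
        assignment=assignment,
        min_module_size=min_module_size,
        cut_height=cut_height,
        module_sizes=sizes,
    )


def module_eigengene(
    study: ExpressionStudy, assignment: pd.Series, module: int
) -> pd.Series:
    """First principal component of a module's z-scored expression submatrix.

    Oriented so that its mean correlation with member genes is positive,
    and scaled to unit (sample) variance.
    """
    members = assignment.index[assignment == module]
    if len(members) == 0:
        raise ValueError(f"module {module} is empty")
    sub = study.values.loc[members].to_numpy()
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    # right singular vector of the gene x sample matrix = PC1 across samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    member_cor = np.array([np.corrcoef(eig, row)[0, 1] for row in z if row.std() > 0])
    if member_cor.size and member_cor.mean() < 0:
        eig = -eig
    eig = (eig - eig.mean()) / eig.std(ddof=1)
    return pd.Series(eig, index=study.values.columns, name=f"ME{module}")


def module_eigengenes(study: ExpressionStudy, partition: ModulePartition) -> pd.DataFrame:
    """Eigengenes of all assigned modules, samples in rows."""
    cols = {
        f"ME{m}": module_eigengene(study, partition.assignment, m)
        for m in partition.labels
    }
    return pd.DataFrame(cols)


def module_trait_correlation(
    eigengenes: pd.DataFrame, phenotype: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with the 0/1 phenotype.

    Two-sided p-value from the Student-t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` at n - 2 degrees of freedom.
    """
    y = phenotype.to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant")
    n = len(y)
    rows = []
    for name in eigengenes.columns:
        r = float(np.corrcoef(eigengenes[name].to_numpy(), y)[0, 1])
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t_stat = r * np.sqrt((n - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(t_stat), df=n - 2))
        rows.append({"module": name, "correlation": r, "p_value": p})
    return pd.DataFrame(rows, columns=["module", "correlation", "p_value"]).set_index(
        "module"
    )


def select_ad_module(trait_table: pd.DataFrame, alpha: float = 0.05) -> str | None:
    """Module with the largest positive phenotype correlation at p < alpha.

    Ties are broken by the smaller module label; returns ``None`` when no
    module has a significant positive correlation.
    """
    if trait_table.empty:
        raise ValueError("trait table is empty")
    sig = trait_table[
        (trait_table["correlation"] > 0) & (trait_table["p_value"] < alpha)
    ]
    if sig.empty:
        return None
    best = sig["correlation"].max()
    winners = sorted(sig.index[np.isclose(sig["correlation"], best)])
    return winners[0]
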