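"""Tissue expression analytics and stress qRT-PCR analysis.

FPKM matrices (genes x tissues) get expressed/not-expressed calls at a
threshold (default FPKM > 1 in at least one tissue), a log2(x+1) transform
(the offset handles zeros and is configurable), and agglomerative
hierarchical clustering with a deterministic lowest-index tie-break,
serialized as a Newick dendrogram.

qRT-PCR tables are analysed with the Livak 2^-ddCt method against a
reference (housekeeping) gene, followed by one-way ANOVA with Fisher's
protected LSD post-hoc test (default alpha 0.01): a pair of groups is
significant only when the omnibus ANOVA passes and the mean difference
exceeds LSD = t(1-alpha/2, df_error) * sqrt(MSE * (1/n_i + 1/n_j)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FPKM matrix analytics
# ---------------------------------------------------------------------------

def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """FPKM semantics: numeric, nonnegative, no missing cells."""
    if matrix.isna().any().any():
        raise ExpressionError("expression matrix contains missing cells")
    if (matrix.values < 0).any():
        raise ExpressionError("expression matrix contains negative values")
    return matrix


def expressed_calls(matrix: pd.DataFrame, threshold: float = 1.0
                    ) -> tuple[pd.Series, pd.Series]:
    """Per-gene expressed call (any tissue above threshold) and per-tissue
    expressed-gene counts."""
    validate_matrix(matrix)
    per_gene = (matrix > threshold).any(axis=1)
    per_tissue = (matrix > threshold).sum(axis=0)
    return per_gene, per_tissue


def log_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """x -> log2(x + offset); monotone, zero-preserving at offset 1."""
    validate_matrix(matrix)
    return np.log2(matrix + offset)


# ---------------------------------------------------------------------------
# Hierarchical clustering (deterministic tie-break)
# ---------------------------------------------------------------------------

def _row_distances(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = values[:, None, :] - values[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    if metric == "correlation":
        c = np.corrcoef(values)
        c = np.nan_to_num(c, nan=0.0)
        d = 1.0 - c
        np.fill_diagonal(d, 0.0)
        return d
    raise ExpressionError(f"unknown metric {metric!r}")


@dataclass
class Dendrogram:
    newick: str
    leaf_order: list[str]
    merges: list[tuple[int, int, float]]  # (cluster_i, cluster_j, height)


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "average",
                         metric: str = "euclidean") -> Dendrogram:
    """Agglomerative clustering of matrix rows.

    Ties in the minimum inter-cluster distance are broken by merging the
    lowest-index pair, making the dendrogram reproducible for fixed input.
    Average linkage is size-weighted (UPGMA); complete linkage takes the max.
    """
    if linkage not in ("average", "complete"):
        raise ExpressionError(f"unknown linkage {linkage!r}")
    labels = list(matrix.index.astype(str))
    n = len(labels)
    if n < 2:
        raise ExpressionError("need at least 2 rows to cluster")
    d = _row_distances(matrix.to_numpy(dtype=float), metric)

    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    newicks = {i: labels[i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    nxt = n
    while len(active) > 1:
        best = min(((dist[i, j], i, j)
                    for k, i in enumerate(active) for j in active[k + 1:]),
                   key=lambda t: t)
        h, i, j = best
        bl_i = max(h / 2 - heights[i], 0.0)
        bl_j = max(h / 2 - heights[j], 0.0)
        newicks[nxt] = f"({newicks[i]}:{bl_i:.6g},{newicks[j]}:{bl_j:.6g})"
        heights[nxt] = h / 2
        merges.append((i, j, h))
        for k in active:
            if k in (i, j):
                continue
            a, b = dist[min(i, k), max(i, k)], dist[min(j, k), max(j, k)]
            if linkage == "average":
                nk = (sizes[i] * a + sizes[j] * b) / (sizes[i] + sizes[j])
            else:
                nk = max(a, b)
            dist[k, nxt] = dist[min(k, nxt), max(k, nxt)] = nk
        sizes[nxt] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    root = active[0]
    newick = newicks[root] + ";"
    order = [tok.split(":")[0].lstrip("(")
             for tok in newick.replace(")", "").split(",")]
    return Dendrogram(newick=newick, leaf_order=order, merges=merges)


# ---------------------------------------------------------------------------
# qRT-PCR: 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    condition: str  # "control" | "treated"
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (0 < v < 45):
                raise ExpressionError(
                    f"{self.gene}: Ct value {v} outside (0, 45)")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    ddct: float
    fold_change: float
    log2_ratio: float  # exactly -ddct
    significant: bool | None = None


def ddct_fold_change(measurements: list[QpcrMeasurement],
                     paired: bool = False) -> list[FoldChangeResult]:
    """Livak relative expression per gene.

    dCt = mean(Ct_target - Ct_reference) per condition;
    ddCt = dCt_treated - dCt_control; fold = 2^-ddCt. With ``paired`` the
    dCt differences are taken per replicate index before averaging.
    """
    by_gene: dict[str, dict[str, list[QpcrMeasurement]]] = {}
    for m in measurements:
        by_gene.setdefault(m.gene, {}).setdefault(m.condition, []).append(m)
    results = []
    for gene in sorted(by_gene):
        conds = by_gene[gene]
        for needed in ("control", "treated"):
            if needed not in conds or not conds[needed]:
                raise ExpressionError(f"{gene}: missing {needed} replicates")
        if paired:
            ctl = {m.replicate: m.ct_target - m.ct_reference
                   for m in conds["control"]}
            trt = {m.replicate: m.ct_target - m.ct_reference
                   for m in conds["treated"]}
            common = sorted(set(ctl) & set(trt))
            if not common:
                raise ExpressionError(f"{gene}: no paired replicates")
            ddct = float(np.mean([trt[r] - ctl[r] for r in common]))
        else:
            dct = {c: float(np.mean([m.ct_target - m.ct_reference
                                     for m in ms]))
                   for c, ms in conds.items()}
            ddct = dct["treated"] - dct["control"]
        results.append(FoldChangeResult(
            gene=gene, ddct=ddct, fold_change=2.0 ** (-ddct),
            log2_ratio=-ddct))
    return results


# ---------------------------------------------------------------------------
# ANOVA + LSD
# ---------------------------------------------------------------------------

@dataclass
class LsdResult:
    anova_F: float
    anova_p: float
    degenerate: bool
    significant_pairs: list[tuple[str, str]]
    lsd: dict[tuple[str, str], float]


def anova_lsd(groups: dict[str, "np.ndarray | list[float]"],
              alpha: float = 0.01) -> LsdResult:
    """One-way ANOVA with Fisher's protected LSD pairwise test.

    A pair is significant iff the ANOVA p-value is <= alpha and the absolute
    mean difference exceeds LSD for that pair. Zero pooled within-group
    variance is flagged degenerate (no calls made).
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ExpressionError("need at least 2 groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ExpressionError(f"group {k!r} has fewer than 2 replicates")
    n_total = sum(len(a) for a in arrays.values())
    df_error = n_total - len(names)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_error
    if mse == 0:
        return LsdResult(np.inf, 0.0, True, [], {})
    F, p = stats.f_oneway(*arrays.values())
    tcrit = stats.t.ppf(1 - alpha / 2, df_error)
    lsd_vals: dict[tuple[str, str], float] = {}
    sig: list[tuple[str, str]] = []
    for a, b in combinations(names, 2):
        lsd = tcrit * np.sqrt(mse * (1 / len(arrays[a]) + 1 / len(arrays[b])))
        lsd_vals[a, b] = float(lsd)
        if p <= alpha and abs(arrays[a].mean() - arrays[b].mean()) > lsd:
            sig.append((a, b))
    return LsdResult(float(F), float(p), False, sig, lsd_vals)
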