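"""Phenotype removal and residual co-expression clustering.

Genes in the fingerprint set are correlated with each other in part simply
because they all track egg quality. To find the co-expression structure
that remains *after* the quality effect, the modeling direction is
reversed: a small network maps the single phenotype value to all gene
expression levels at once, the fit is subtracted, and the residuals are
clustered with modulated modularity clustering (MMC) — a scan over a
correlation-sharpening exponent that maximizes weighted Newman modularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from eggprint._nn import TinyNet
from eggprint.annmodel import AnnConfig
from eggprint.dataio import ExpressionMatrix, PhenotypeTable

__all__ = [
    "ResidualMatrix",
    "ModulePartition",
    "reverse_residualize",
    "mmc_cluster",
    "clustergram",
    "weighted_modularity",
]


class FingerprintError(ValueError):
    pass


@dataclass
class ResidualMatrix:
    """Observed = fitted + residual, per gene and sample, on the glog scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    residuals: np.ndarray  # genes x samples
    fitted: np.ndarray

    def __post_init__(self) -> None:
        if self.residuals.shape != self.fitted.shape:
            raise FingerprintError("residual/fitted shape mismatch")
        if self.residuals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FingerprintError("residual shape does not match identifiers")

    @property
    def observed(self) -> np.ndarray:
        return self.residuals + self.fitted


@dataclass
class ModulePartition:
    """Gene -> module assignment at the modularity-maximizing sharpness."""

    module_of: dict[str, int]  # 1..K
    sharpness: float
    modularity: float
    low_confidence: bool = False

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.module_of.values():
            out[m] = out.get(m, 0) + 1
        return out

    def labels(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.module_of[g] for g in gene_ids])


def reverse_residualize(
    expr: ExpressionMatrix,
    target: np.ndarray | pd.Series | PhenotypeTable,
    config: AnnConfig | None = None,
    target_name: str = "pct_4h_viable",
    per_gene: bool = False,
) -> ResidualMatrix:
    """Regress every gene on the phenotype with a reversed network and
    return residuals.

    A single multi-output network (phenotype -> all genes) is the default;
    ``per_gene=True`` fits one network per gene instead. Fitted values are
    computed on all samples, so residual + fitted = observed holds exactly
    by construction. A constant phenotype carries no information: the fit
    degenerates to per-gene means and the residuals are simply centered
    data (flagged via ``low_confidence`` downstream, not an error).
    """
    # the reverse map has a single input; unlike the forward p >> n ensembles
    # it needs only mild shrinkage, and heavy L2 would leave phenotype signal
    # in the residuals
    config = config or AnnConfig(l2_penalty=1e-3)
    if isinstance(target, PhenotypeTable):
        y = target.target(target_name).reindex(expr.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(target, dtype=float)
    if not np.isfinite(y).all():
        raise FingerprintError("phenotype target has non-finite values")
    G = expr.values  # genes x samples
    n = len(y)

    if y.std() == 0:
        fitted = np.tile(G.mean(axis=1, keepdims=True), (1, n))
        return ResidualMatrix(
            list(expr.probe_ids), list(expr.sample_ids), G - fitted, fitted
        )

    z = ((y - y.mean()) / y.std(ddof=0)).reshape(-1, 1)
    # standardize outputs for a well-scaled fit, then undo
    mu = G.mean(axis=1)
    sd = np.maximum(G.std(axis=1, ddof=0), 1e-12)
    Y = ((G - mu[:, None]) / sd[:, None]).T  # samples x genes

    def _fit(yy: np.ndarray, seed_offset: int) -> np.ndarray:
        est = TinyNet(
            n_hidden=config.hidden_units,
            alpha=config.l2_penalty,
            seed=(int(config.seed) + seed_offset) & 0x7FFFFFFF,
            max_iter=config.max_iterations,
        )
        est.fit(z, yy)
        return est.predict(z)

    if per_gene:
        fit_std = np.column_stack([_fit(Y[:, j], j + 1) for j in range(Y.shape[1])])
    else:
        fit_std = _fit(Y, 0)
        if fit_std.ndim == 1:
            fit_std = fit_std[:, None]
    fitted = fit_std.T * sd[:, None] + mu[:, None]
    return ResidualMatrix(
        list(expr.probe_ids), list(expr.sample_ids), G - fitted, fitted
    )


# ---------------------------------------------------------------------------
# modulated modularity clustering


def weighted_modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q of a partition of a weighted undirected graph:
    Q = sum_modules [ S_in/(2m) - (S_deg/(2m))^2 ], diagonal excluded."""
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for mod in np.unique(labels):
        mask = labels == mod
        s_in = W[np.ix_(mask, mask)].sum()  # counts both triangles = 2*w_in
        s_deg = deg[mask].sum()
        q += s_in / two_m - (s_deg / two_m) ** 2
    return float(q)


def _best_partition_for_weights(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize Q over partitions of one weight matrix: average-linkage
    agglomeration on 1 - w scanning every merge level, then greedy
    single-node reassignment until no move improves Q."""
    n = W.shape[0]
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    link = hierarchy.linkage(squareform(D, checks=False), method="average")
    best_q = -np.inf
    best_labels = np.ones(n, dtype=int)
    # merge levels: k = n..1 clusters
    for k in range(n, 0, -1):
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        q = weighted_modularity(W, labels)
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12 and len(np.unique(labels)) < len(np.unique(best_labels))
        ):
            best_q, best_labels = q, labels.copy()
    best_labels, best_q = _greedy_refine(W, best_labels, best_q)
    return _canonical_labels(best_labels), best_q


def _greedy_refine(W: np.ndarray, labels: np.ndarray, q: float,
                   max_sweeps: int = 20) -> tuple[np.ndarray, float]:
    n = len(labels)
    Wz = W.copy()
    np.fill_diagonal(Wz, 0.0)
    deg = Wz.sum(axis=1)
    two_m = deg.sum()
    if two_m == 0:
        return labels, q
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            current = labels[i]
            # gain of moving i from its module / into another
            options = np.unique(labels)
            best_gain, best_mod = 0.0, current
            for mod in options:
                if mod == current:
                    continue
                gain = _move_gain(Wz, deg, two_m, labels, i, current, mod)
                if gain > best_gain + 1e-12:
                    best_gain, best_mod = gain, mod
            if best_mod != current:
                labels = labels.copy()
                labels[i] = best_mod
                q += best_gain
                improved = True
        if not improved:
            break
    return labels, weighted_modularity(W, labels)


def _move_gain(W, deg, two_m, labels, i, src, dst) -> float:
    in_src = W[i, labels == src].sum() - 0.0  # W diagonal is zero
    in_dst = W[i, labels == dst].sum()
    deg_src = deg[labels == src].sum() - deg[i]
    deg_dst = deg[labels == dst].sum()
    dq = 2.0 * (in_dst - in_src) / two_m + 2.0 * deg[i] * (deg_src - deg_dst) / (two_m**2)
    return float(dq)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K in order of first appearance (stable across
    gene-order permutations of equivalent partitions up to renaming)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def mmc_cluster(
    residuals: ResidualMatrix | ExpressionMatrix,
    sharpness_grid: list[float] | None = None,
    correlation: str = "pearson",
    weights: np.ndarray | None = None,
) -> ModulePartition:
    """Modulated modularity clustering of residual co-expression.

    The gene-gene correlation matrix is sharpened through the monotone
    family ``w = |r|**s`` for each s on the grid (default 1..30); for each
    weight matrix, weighted Newman modularity is maximized by average-
    linkage agglomeration over all merge levels plus greedy refinement, and
    the partition/sharpness pair with the global maximum Q wins. Ties favor
    fewer modules. Because sharpening inflates Q even on unstructured data,
    the result is flagged low-confidence when Q* does not clearly beat the
    same scan on a per-gene permutation null.

    ``weights`` bypasses the correlation step with a caller-supplied
    symmetric weight matrix in [0, 1] (sharpening still applies).
    """
    if sharpness_grid is None:
        sharpness_grid = list(range(1, 31))
    if isinstance(residuals, ResidualMatrix):
        gene_ids = residuals.gene_ids
        data = residuals.residuals
    else:
        gene_ids = residuals.probe_ids
        data = residuals.values

    if weights is None:
        if len(gene_ids) < 3:
            raise FingerprintError("need at least 3 genes")
        if data.shape[1] < 4:
            raise FingerprintError("need at least 4 samples")
        sds = data.std(axis=1)
        dead = [g for g, s in zip(gene_ids, sds) if s == 0]
        if dead:
            raise FingerprintError(f"zero-variance gene(s): {dead[:5]}")
        if correlation == "pearson":
            r = np.corrcoef(data)
        elif correlation == "spearman":
            from scipy.stats import rankdata

            r = np.corrcoef(rankdata(data, axis=1))
        else:
            raise FingerprintError(f"unknown correlation {correlation!r}")
        base_w = np.abs(r)
    else:
        base_w = np.asarray(weights, dtype=float)
        if base_w.shape != (len(gene_ids), len(gene_ids)):
            raise FingerprintError("weight matrix shape mismatch")

    q_star, neg_s, labels = _scan_sharpness(base_w, sharpness_grid)

    # confidence: sharpened random correlations also reach sizable Q, so
    # the absolute value of Q* is not evidence of structure by itself. The
    # flag instead counts correlation pairs beyond the 3-sigma Fisher-z
    # null bound tanh(3/sqrt(n-3)); with no real co-expression that count
    # stays at its null expectation (0.27% of pairs).
    if weights is None:
        n_samp = data.shape[1]
        thr = np.tanh(3.0 / np.sqrt(max(n_samp - 3, 1)))
        iu = np.triu_indices(len(gene_ids), k=1)
        n_pairs = len(iu[0])
        exceed = int((base_w[iu] >= thr).sum())
        expected_null = 2.0 * 0.00135 * n_pairs  # two-sided 3-sigma tail
        low_confidence = exceed <= max(3.0 * expected_null, 1.0)
    else:
        low_confidence = q_star < 0.05
    return ModulePartition(
        module_of={g: int(m) for g, m in zip(gene_ids, labels)},
        sharpness=float(-neg_s),
        modularity=float(q_star),
        low_confidence=bool(low_confidence),
    )


def _scan_sharpness(base_w: np.ndarray, sharpness_grid) -> tuple[float, float, np.ndarray]:
    """Best (Q, -sharpness, labels) over the grid; ties favor fewer modules,
    then lower sharpness."""
    best = None
    for s in sharpness_grid:
        W = base_w**s
        labels, q = _best_partition_for_weights(W)
        cand = (q, -len(np.unique(labels)), -s, labels)
        if best is None or (cand[0] > best[0] + 1e-12) or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1:3] > best[1:3]
        ):
            best = cand
    return best[0], best[2], best[3]


# ---------------------------------------------------------------------------
# clustergram


@dataclass
class Clustergram:
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    matrix: pd.DataFrame  # ordered fold-difference matrix (genes x samples)


def clustergram(
    expr: ExpressionMatrix,
    image_path: str | None = None,
) -> Clustergram:
    """Two-way hierarchical clustering of grand-mean-centered expression.

    The displayed value for gene g in sample i is the glog expression minus
    gene g's mean over all samples (approximately the log2 fold difference
    from the grand mean). Both axes are clustered with average linkage on
    correlation distance 1 - r; zero-variance genes get zero fold
    differences and sort to the end of the gene ordering.
    """
    if expr.scale_flag != "normalized":
        raise FingerprintError("clustergram expects normalized expression")
    X = expr.values - expr.values.mean(axis=1, keepdims=True)
    sds = X.std(axis=1)
    live = sds > 0
    if live.sum() < 2 or X.shape[1] < 2:
        raise FingerprintError("need >= 2 varying genes and >= 2 samples")

    def _corr_linkage(M: np.ndarray) -> np.ndarray:
        r = np.corrcoef(M)
        d = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        return hierarchy.linkage(squareform(d, checks=False), method="average")

    gl = _corr_linkage(X[live])
    sl = _corr_linkage(X.T)
    gene_order_live = hierarchy.leaves_list(gl)
    live_ids = [g for g, ok in zip(expr.probe_ids, live) if ok]
    dead_ids = [g for g, ok in zip(expr.probe_ids, live) if not ok]
    ordered_genes = [live_ids[i] for i in gene_order_live] + dead_ids
    ordered_samples = [expr.sample_ids[i] for i in hierarchy.leaves_list(sl)]
    df = pd.DataFrame(X, index=expr.probe_ids, columns=expr.sample_ids)
    df = df.loc[ordered_genes, ordered_samples]

    if image_path is not None:
        _render_heatmap(df, image_path)
    return Clustergram(gene_linkage=gl, sample_linkage=sl, matrix=df)


def _render_heatmap(df: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(4, len(df) * 0.02)))
    vmax = np.abs(df.to_numpy()).max() or 1.0
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(df.columns)), labels=df.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{len(df)} genes (clustered)")
    fig.colorbar(im, ax=ax, label="fold difference from grand mean (glog2)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
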