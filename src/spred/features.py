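"""Normalization and pairwise-relationship features.

The model never sees raw expression.  Each gene (row) is Box-Cox transformed
(per-gene maximum-likelihood lambda) and z-scored; if the matrix contains any
non-positive value, all entries are first shifted by a single constant making
the minimum strictly positive.  From the normalized matrix, five symmetric
pairwise-relationship matrices are computed over a context of the nTF
candidate TFs plus one target gene (N = nTF + 1 rows):

    covariance, Pearson correlation, Spearman correlation, discrete mutual
    information (equal-frequency bins, plug-in estimator, nats), and the
    precision matrix (covariance + eps * I)^-1 with eps = 1e-3.

These are assembled into per-sample feature tensors: the single-pair (SP)
layout has one (nTF+1) x 5 matrix per candidate TF (its pairs with every TF,
self pair included, plus its pair with the target gene), while the
multi-label (ML) layout has one (nTF^2 + nTF) x 5 matrix per target gene
(all ordered TF-TF pairs followed by all TF-gene pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .grn import GrnSpec
from .simulate import ExpressionMatrix

__all__ = [
    "FEATURE_ORDER",
    "PairFeatureSet",
    "SpInput",
    "MlInput",
    "normalize",
    "pairwise_matrices",
    "assemble_sp_inputs",
    "assemble_ml_input",
    "SpDataset",
    "MlDataset",
    "featurize_grn_sp",
    "featurize_grn_ml",
]

FEATURE_ORDER = ("cov", "pearson", "spearman", "mi", "precision")
DEFAULT_EPSILON = 1e-3
BOXCOX_LAMBDA_BOUNDS = (-5.0, 5.0)


def _n_bins(m: int) -> int:
    """Equal-frequency bin count for the mutual-information estimate."""
    return max(2, int(np.floor(np.sqrt(m))))


@dataclass
class PairFeatureSet:
    """The five symmetric N x N relation matrices for one gene's context."""

    cov: np.ndarray
    pearson: np.ndarray
    spearman: np.ndarray
    mi: np.ndarray
    precision: np.ndarray
    epsilon: float
    row_index: list[int]  # matrix row -> expression-matrix row (TFs..., gene)

    def stack(self, features: tuple[str, ...] = FEATURE_ORDER) -> np.ndarray:
        """(N, N, n_features) tensor in the requested feature-column order."""
        unknown = set(features) - set(FEATURE_ORDER)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        return np.stack([getattr(self, f) for f in features], axis=-1)


@dataclass
class SpInput:
    """One single-pair sample: candidate TF i against gene g.

    ``features`` has nTF rows of (TF_i, TF_j) pair features (j ordered by TF
    index, self pair included) followed by one (TF_i, gene) row.
    """

    features: np.ndarray
    label: int
    tf_index: int
    gene_index: int


@dataclass
class MlInput:
    """One multi-label sample: all candidate TFs against gene g.

    ``features`` has nTF^2 ordered TF-TF rows (row-major by TF index) followed
    by nTF TF-gene rows; ``labels`` marks each TF as regulator or not.
    """

    features: np.ndarray
    labels: np.ndarray
    gene_index: int


def _boxcox_mle_lambda(x: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        lambda lm: -stats.boxcox_llf(lm, x),
        bounds=BOXCOX_LAMBDA_BOUNDS,
        method="bounded",
    )
    return float(res.x)


def normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Box-Cox (per-gene MLE lambda) then z-transform each row.

    If any entry is <= 0, the whole matrix is first shifted by
    ``1 - min(values)``.  Constant rows cannot be scaled to unit variance;
    they are set to all zeros and flagged in ``constant_row_flags``.
    """
    if expr.n_conditions < 3:
        raise ValueError("normalization requires at least 3 conditions")
    values = expr.values.astype(float).copy()
    vmin = values.min()
    if vmin <= 0:
        values += 1.0 - vmin
    out = np.zeros_like(values)
    flags = np.zeros(values.shape[0], dtype=bool)
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            flags[i] = True
            continue
        lam = _boxcox_mle_lambda(row)
        t = special.boxcox(row, lam)
        sd = t.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            flags[i] = True
            continue
        out[i] = (t - t.mean()) / sd
    return ExpressionMatrix(
        values=out,
        row_roles=expr.row_roles.copy(),
        condition_ids=list(expr.condition_ids),
        constant_row_flags=flags,
    )


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _bin_rows(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin assignment per row (ties broken by sort order)."""
    m = values.shape[1]
    edges = (np.arange(m) * n_bins) // m
    bins = np.empty(values.shape, dtype=np.int64)
    order = np.argsort(values, axis=1, kind="stable")
    for i in range(values.shape[0]):
        bins[i, order[i]] = edges
    return bins


def _mi_matrix(bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Plug-in mutual information (nats) between all pairs of binned rows."""
    r, m = bins.shape
    onehot = np.zeros((r, m, n_bins))
    rows = np.repeat(np.arange(r), m)
    cols = np.tile(np.arange(m), r)
    onehot[rows, cols, bins.ravel()] = 1.0
    joint = np.einsum("imb,jmc->ijbc", onehot, onehot) / m
    marg = onehot.sum(axis=1) / m  # (r, n_bins)
    outer = marg[:, None, :, None] * marg[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(joint > 0, np.log(joint / outer), 0.0)
    mi = (joint * logterm).sum(axis=(2, 3))
    return np.maximum(0.5 * (mi + mi.T), 0.0)


def _corr_with_guard(values: np.ndarray) -> np.ndarray:
    """Correlation matrix with rows of zero variance mapped to zero entries."""
    sd = values.std(axis=1)
    ok = sd > 0
    corr = np.zeros((values.shape[0], values.shape[0]))
    if ok.any():
        sub = np.corrcoef(values[ok])
        sub = np.clip(0.5 * (sub + sub.T), -1.0, 1.0)
        corr[np.ix_(ok, ok)] = sub
    return corr


def pairwise_matrices(
    normed: ExpressionMatrix,
    rows: list[int] | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> PairFeatureSet:
    """Compute the five relation matrices for the given rows (TFs + gene)."""
    rows = list(int(r) for r in rows)
    x = normed.values[rows]
    n, m = x.shape
    if m < 3:
        raise ValueError("need at least 3 conditions")
    cov = np.cov(x, ddof=1)
    cov = 0.5 * (cov + cov.T)
    pearson = _corr_with_guard(x)
    spearman = _corr_with_guard(_rank_rows(x))
    mi = _mi_matrix(_bin_rows(x, _n_bins(m)), _n_bins(m))
    precision = np.linalg.inv(cov + epsilon * np.eye(n))
    precision = 0.5 * (precision + precision.T)
    return PairFeatureSet(
        cov=cov,
        pearson=pearson,
        spearman=spearman,
        mi=mi,
        precision=precision,
        epsilon=epsilon,
        row_index=rows,
    )


def _context_rows(normed: ExpressionMatrix, gene_row: int) -> list[int]:
    return [int(r) for r in normed.tf_rows] + [int(gene_row)]


def assemble_sp_inputs(
    pfs: PairFeatureSet,
    grn: GrnSpec,
    gene: int,
    features: tuple[str, ...] = FEATURE_ORDER,
) -> list[SpInput]:
    """One SpInput per candidate TF for the given target gene.

    ``gene`` is the GRN node index of the target; ``pfs`` must have been
    computed on the context (all TFs in index order, then the gene).
    """
    n_tf = grn.n_tf
    if len(pfs.row_index) != n_tf + 1:
        raise ValueError("feature set context does not match the GRN's TF count")
    if gene not in grn.gene_ids:
        raise ValueError(f"node {gene} is not a target gene of the GRN")
    tensor = pfs.stack(features)  # (N, N, F)
    true_edges = grn.tf_gene_edge_set()
    out = []
    g = n_tf  # gene is the last context row
    for i in range(n_tf):
        feat = np.concatenate([tensor[i, :n_tf, :], tensor[i, g : g + 1, :]], axis=0)
        label = int((grn.n_mr + i, gene) in true_edges)
        out.append(SpInput(features=feat, label=label, tf_index=i, gene_index=gene))
    return out


def assemble_ml_input(
    pfs: PairFeatureSet,
    grn: GrnSpec,
    gene: int,
    features: tuple[str, ...] = FEATURE_ORDER,
) -> MlInput:
    """The multi-label sample for one target gene (all TFs scored at once)."""
    n_tf = grn.n_tf
    if len(pfs.row_index) != n_tf + 1:
        raise ValueError("feature set context does not match the GRN's TF count")
    if gene not in grn.gene_ids:
        raise ValueError(f"node {gene} is not a target gene of the GRN")
    tensor = pfs.stack(features)
    tf_tf = tensor[:n_tf, :n_tf, :].reshape(n_tf * n_tf, -1)
    tf_gene = tensor[:n_tf, n_tf, :]
    feat = np.concatenate([tf_tf, tf_gene], axis=0)
    true_edges = grn.tf_gene_edge_set()
    labels = np.array(
        [int((grn.n_mr + i, gene) in true_edges) for i in range(n_tf)], dtype=float
    )
    return MlInput(features=feat, labels=labels, gene_index=gene)


# ---------------------------------------------------------------------------
# Dataset assembly (stacked arrays for training)


@dataclass
class SpDataset:
    """Stacked single-pair samples: TF-TF block and TF-gene row kept separate
    (the model convolves them with separate kernels)."""

    x_tf: np.ndarray  # (n, n_tf, F)
    x_tg: np.ndarray  # (n, 1, F)
    y: np.ndarray  # (n,)
    group_ids: np.ndarray  # (n,) GRN of origin, for grouped validation splits
    feature_names: tuple[str, ...] = FEATURE_ORDER

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_tf(self) -> int:
        return self.x_tf.shape[1]


@dataclass
class MlDataset:
    """Stacked multi-label samples."""

    x_tt: np.ndarray  # (n, n_tf^2, F)
    x_tg: np.ndarray  # (n, n_tf, F)
    y: np.ndarray  # (n, n_tf)
    group_ids: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_ORDER

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_tf(self) -> int:
        return self.x_tg.shape[1]


def _gene_feature_tensors(
    normed: ExpressionMatrix,
    epsilon: float,
    features: tuple[str, ...],
):
    """Yield (gene_row_position, tensor) per gene, sharing cross-gene blocks.

    The covariance / correlation / MI entries between two TFs do not depend
    on which target gene completes the context, so they are computed once
    over all TF and gene rows and sliced; only the precision matrix needs a
    per-gene inverse of the (nTF+1) x (nTF+1) context covariance.
    """
    unknown = set(features) - set(FEATURE_ORDER)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    tf_rows = [int(r) for r in normed.tf_rows]
    gene_rows = [int(r) for r in normed.gene_rows]
    all_rows = tf_rows + gene_rows
    x = normed.values[all_rows]
    n_tf = len(tf_rows)
    m = x.shape[1]
    cov = np.cov(x, ddof=1)
    cov = 0.5 * (cov + cov.T)
    pearson = _corr_with_guard(x)
    spearman = _corr_with_guard(_rank_rows(x))
    mi = _mi_matrix(_bin_rows(x, _n_bins(m)), _n_bins(m))
    base = {"cov": cov, "pearson": pearson, "spearman": spearman, "mi": mi}
    eye = np.eye(n_tf + 1)
    for gi in range(len(gene_rows)):
        idx = list(range(n_tf)) + [n_tf + gi]
        ctx_cov = cov[np.ix_(idx, idx)]
        precision = np.linalg.inv(ctx_cov + epsilon * eye)
        precision = 0.5 * (precision + precision.T)
        mats = {f: base[f][np.ix_(idx, idx)] for f in base}
        mats["precision"] = precision
        tensor = np.stack([mats[f] for f in features], axis=-1)
        yield gi, tensor


def featurize_grn_sp(
    expr: ExpressionMatrix,
    grn: GrnSpec,
    features: tuple[str, ...] = FEATURE_ORDER,
    epsilon: float = DEFAULT_EPSILON,
    group_id: int = 0,
) -> SpDataset:
    """All nTF * nG single-pair samples of one GRN + expression matrix."""
    normed = normalize(expr)
    n_tf, n_gene = grn.n_tf, grn.n_gene
    nf = len(features)
    true_edges = grn.tf_gene_edge_set()
    x_tf = np.empty((n_tf * n_gene, n_tf, nf))
    x_tg = np.empty((n_tf * n_gene, 1, nf))
    y = np.empty(n_tf * n_gene)
    k = 0
    for gi, tensor in _gene_feature_tensors(normed, epsilon, features):
        gene = grn.n_mr + n_tf + gi
        for i in range(n_tf):
            x_tf[k] = tensor[i, :n_tf, :]
            x_tg[k, 0] = tensor[i, n_tf, :]
            y[k] = float((grn.n_mr + i, gene) in true_edges)
            k += 1
    return SpDataset(
        x_tf=x_tf,
        x_tg=x_tg,
        y=y,
        group_ids=np.full(n_tf * n_gene, group_id),
        feature_names=tuple(features),
    )


def featurize_grn_ml(
    expr: ExpressionMatrix,
    grn: GrnSpec,
    features: tuple[str, ...] = FEATURE_ORDER,
    epsilon: float = DEFAULT_EPSILON,
    group_id: int = 0,
) -> MlDataset:
    """All nG multi-label samples of one GRN + expression matrix."""
    normed = normalize(expr)
    n_tf, n_gene = grn.n_tf, grn.n_gene
    nf = len(features)
    true_edges = grn.tf_gene_edge_set()
    x_tt = np.empty((n_gene, n_tf * n_tf, nf))
    x_tg = np.empty((n_gene, n_tf, nf))
    y = np.empty((n_gene, n_tf))
    for gi, tensor in _gene_feature_tensors(normed, epsilon, features):
        gene = grn.n_mr + n_tf + gi
        x_tt[gi] = tensor[:n_tf, :n_tf, :].reshape(n_tf * n_tf, nf)
        x_tg[gi] = tensor[:n_tf, n_tf, :]
        y[gi] = [float((grn.n_mr + i, gene) in true_edges) for i in range(n_tf)]
    return MlDataset(
        x_tt=x_tt,
        x_tg=x_tg,
        y=y,
        group_ids=np.full(n_gene, group_id),
        feature_names=tuple(features),
    )


def concat_sp(datasets: list[SpDataset]) -> SpDataset:
    if not datasets:
        raise ValueError("no datasets to concatenate")
    return SpDataset(
        x_tf=np.concatenate([d.x_tf for d in datasets]),
        x_tg=np.concatenate([d.x_tg for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        group_ids=np.concatenate([d.group_ids for d in datasets]),
        feature_names=datasets[0].feature_names,
    )


def concat_ml(datasets: list[MlDataset]) -> MlDataset:
    if not datasets:
        raise ValueError("no datasets to concatenate")
    return MlDataset(
        x_tt=np.concatenate([d.x_tt for d in datasets]),
        x_tg=np.concatenate([d.x_tg for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        group_ids=np.concatenate([d.group_ids for d in datasets]),
        feature_names=datasets[0].feature_names,
    )
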