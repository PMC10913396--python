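"""Per-gene evaluation of edge predictions and benchmark sweeps.

Every metric is computed per target gene — ranking the nTF candidate TFs by
their predicted score against the gene's true regulators — and averaged over
genes.  Average precision AP = sum_n (R_n - R_{n-1}) * P_n over distinct
score thresholds (tied scores share a threshold); AUROC is the Mann–Whitney
probability that a random positive outranks a random negative, ties counting
one half.  Genes with zero positives (possible only in external gold
standards) are excluded from averages and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_ORDER, featurize_grn_sp
from .grn import GrnConfig, GrnSpec, sample_grn, sample_interaction_params
from .models import SPREdML, SPREdSP, score_edges
from .simulate import (
    DEFAULT_N_CELLTYPE,
    ExpressionMatrix,
    SimParams,
    inject_dropout,
    sample_mr_rates,
    simulate_steady_state,
    subsample_conditions,
)

__all__ = [
    "EdgeScoreMatrix",
    "EvalResult",
    "average_precision",
    "auroc",
    "evaluate_predictions",
    "random_baseline_ap",
    "BenchSetting",
    "generate_test_case",
    "score_test_case_sp",
    "run_benchmark",
    "read_scores_tsv",
    "write_scores_tsv",
]


@dataclass
class EdgeScoreMatrix:
    """TF x gene real-valued prediction scores."""

    scores: np.ndarray
    tf_ids: list
    gene_ids: list
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("scores shape must be (n_tf, n_gene)")


@dataclass
class EvalResult:
    per_gene_ap: np.ndarray
    per_gene_auroc: np.ndarray
    mean_ap: float
    mean_auroc: float
    n_positive_per_gene: np.ndarray
    n_excluded: int = 0
    config_fingerprint: dict = field(default_factory=dict)


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP over distinct descending score thresholds; requires >= 1 positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    n_pred = np.arange(1, len(y) + 1)
    # last index of each distinct-threshold group
    is_last = np.r_[s[1:] != s[:-1], True]
    tp_t, n_t = tp[is_last], n_pred[is_last]
    precision = tp_t / n_t
    recall = tp_t / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUROC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _truth_matrix(truth, tf_ids: list, gene_ids: list) -> np.ndarray:
    if isinstance(truth, GrnSpec):
        edge_set = truth.tf_gene_edge_set()
    else:
        edge_set = {(t, g) for t, g in truth}
    out = np.zeros((len(tf_ids), len(gene_ids)))
    for j, g in enumerate(gene_ids):
        for i, t in enumerate(tf_ids):
            if (t, g) in edge_set:
                out[i, j] = 1.0
    return out


def evaluate_predictions(pred: EdgeScoreMatrix, truth) -> EvalResult:
    """Per-gene AP and AUROC against a GrnSpec or an iterable of (tf, gene)."""
    labels = _truth_matrix(truth, pred.tf_ids, pred.gene_ids)
    aps, aurocs, n_pos = [], [], []
    n_excluded = 0
    for j in range(labels.shape[1]):
        pos = int(labels[:, j].sum())
        if pos == 0 or pos == labels.shape[0]:
            n_excluded += 1
            continue
        aps.append(average_precision(pred.scores[:, j], labels[:, j]))
        aurocs.append(auroc(pred.scores[:, j], labels[:, j]))
        n_pos.append(pos)
    aps_arr = np.array(aps)
    aurocs_arr = np.array(aurocs)
    return EvalResult(
        per_gene_ap=aps_arr,
        per_gene_auroc=aurocs_arr,
        mean_ap=float(aps_arr.mean()) if len(aps_arr) else float("nan"),
        mean_auroc=float(aurocs_arr.mean()) if len(aurocs_arr) else float("nan"),
        n_positive_per_gene=np.array(n_pos, dtype=int),
        n_excluded=n_excluded,
        config_fingerprint={"method": pred.method_tag},
    )


def random_baseline_ap(n_tf: int, d: int, n_draws: int = 2000, seed: int = 0) -> float:
    """Expected AP of a uniformly random ranking with d positives of n_tf.

    Estimated by permutation Monte Carlo (exact as n_draws grows; for d = 1
    the closed form is H(n_tf) / n_tf).
    """
    if not 1 <= d <= n_tf:
        raise ValueError("need 1 <= d <= n_tf")
    if d == n_tf:
        return 1.0
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_tf)
    labels[:d] = 1.0
    total = 0.0
    for _ in range(n_draws):
        total += average_precision(rng.random(n_tf), labels)
    return total / n_draws


# ---------------------------------------------------------------------------
# Benchmark harness


@dataclass(frozen=True)
class BenchSetting:
    """Generation parameters of one benchmark configuration.

    ``n_mr`` and ``d_tf_gene`` may be tuples of alternatives, in which case
    test GRNs cycle through them in equal numbers (heterogeneous benchmark).
    """

    n_grn: int = 50
    n_gene: int = 100
    n_tf: int = 100
    n_mr: int | tuple[int, ...] = 5
    d_mr_tf: int = 3
    d_tf_gene: tuple[int, int] | tuple[tuple[int, int], ...] = (3, 7)
    m: int = 50
    dropout: float = 0.0
    sim: SimParams = field(default_factory=SimParams)

    def grn_config(self, index: int) -> GrnConfig:
        n_mr = self.n_mr if isinstance(self.n_mr, int) else self.n_mr[index % len(self.n_mr)]
        d = self.d_tf_gene
        d_range = d if isinstance(d[0], int) else d[index % len(d)]
        return GrnConfig(
            n_mr=n_mr,
            n_tf=self.n_tf,
            n_gene=self.n_gene,
            d_mr_tf=min(self.d_mr_tf, n_mr),
            d_tf_gene_range=tuple(d_range),
        )


def generate_test_case(
    setting: BenchSetting, index: int, seed: int
) -> tuple[GrnSpec, ExpressionMatrix]:
    """One benchmark GRN and its m-condition (optionally dropped-out) matrix."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    seeds = ss.generate_state(5)
    cfg = setting.grn_config(index)
    grn = sample_interaction_params(sample_grn(cfg, int(seeds[0])), int(seeds[1]))
    panel = sample_mr_rates(cfg.n_mr, DEFAULT_N_CELLTYPE, seed=int(seeds[2]))
    expr = simulate_steady_state(grn, panel, setting.sim, seed=int(seeds[3]))
    if setting.m < expr.n_conditions:
        expr = subsample_conditions(expr, setting.m, seed=int(seeds[4]))
    if setting.dropout > 0:
        expr = inject_dropout(expr, setting.dropout, seed=int(seeds[4]) + 1)
    return grn, expr


def score_test_case_sp(
    model: SPREdSP,
    grn: GrnSpec,
    expr: ExpressionMatrix,
    features: tuple[str, ...] = FEATURE_ORDER,
) -> EdgeScoreMatrix:
    """Score every candidate TF→gene edge of one test case with SPREd-SP."""
    ds = featurize_grn_sp(expr, grn, features=features)
    scores = score_edges(model, ds).reshape(grn.n_gene, grn.n_tf).T
    return EdgeScoreMatrix(
        scores=scores,
        tf_ids=list(grn.tf_ids),
        gene_ids=list(grn.gene_ids),
        method_tag="SPREd-SP",
    )


def run_benchmark(
    setting: BenchSetting,
    model: SPREdSP,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_ORDER,
) -> tuple[pd.DataFrame, EvalResult]:
    """Evaluate a trained SPREd-SP model on freshly generated test GRNs.

    Returns a tidy per-gene table (one row per evaluated gene) and the
    pooled EvalResult over all genes of all test GRNs.
    """
    rows = []
    all_ap, all_auroc, all_npos = [], [], []
    n_excluded = 0
    for index in range(setting.n_grn):
        grn, expr = generate_test_case(setting, index, seed)
        pred = score_test_case_sp(model, grn, expr, features=features)
        res = evaluate_predictions(pred, grn)
        n_excluded += res.n_excluded
        for g, ap, auc, npos in zip(
            range(len(res.per_gene_ap)),
            res.per_gene_ap,
            res.per_gene_auroc,
            res.n_positive_per_gene,
        ):
            rows.append(
                {
                    "grn": index,
                    "gene": g,
                    "ap": ap,
                    "auroc": auc,
                    "n_positive": npos,
                    "m": setting.m,
                    "dropout": setting.dropout,
                    "method": pred.method_tag,
                }
            )
        all_ap.append(res.per_gene_ap)
        all_auroc.append(res.per_gene_auroc)
        all_npos.append(res.n_positive_per_gene)
    ap = np.concatenate(all_ap)
    auc = np.concatenate(all_auroc)
    npos = np.concatenate(all_npos)
    pooled = EvalResult(
        per_gene_ap=ap,
        per_gene_auroc=auc,
        mean_ap=float(ap.mean()),
        mean_auroc=float(auc.mean()),
        n_positive_per_gene=npos,
        n_excluded=n_excluded,
        config_fingerprint={
            "n_grn": setting.n_grn,
            "n_gene": setting.n_gene,
            "n_tf": setting.n_tf,
            "m": setting.m,
            "dropout": setting.dropout,
            "seed": seed,
        },
    )
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# External score files (comparator tools)


def write_scores_tsv(pred: EdgeScoreMatrix, path: str | Path) -> None:
    rows = [
        {"tf_id": t, "gene_id": g, "score": pred.scores[i, j]}
        for i, t in enumerate(pred.tf_ids)
        for j, g in enumerate(pred.gene_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores_tsv(
    path: str | Path, tf_ids: list, gene_ids: list, method_tag: str = ""
) -> EdgeScoreMatrix:
    """Align an external (tf_id, gene_id, score) TSV onto a candidate grid.

    Pairs missing from the file are scored -inf so they rank last.
    """
    df = pd.read_csv(path, sep="\t")
    scores = np.full((len(tf_ids), len(gene_ids)), -np.inf)
    ti = {t: i for i, t in enumerate(tf_ids)}
    gi = {g: j for j, g in enumerate(gene_ids)}
    for t, g, s in zip(df["tf_id"], df["gene_id"], df["score"]):
        if t in ti and g in gi:
            scores[ti[t], gi[g]] = s
    return EdgeScoreMatrix(scores=scores, tf_ids=tf_ids, gene_ids=gene_ids, method_tag=method_tag)
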