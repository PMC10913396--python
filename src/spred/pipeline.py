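"""End-to-end orchestration: generate → featurize → train → benchmark.

A run is fully described by a :class:`RunManifest` (YAML on disk): the GRN
connectivity, simulation, training and benchmark parameters plus a single
master seed from which every stage derives a named substream.  Identical
manifests give identical artifacts up to floating-point backend
reproducibility.  Stages are resumable: an existing checkpoint or summary is
reused unless ``overwrite`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import BenchSetting, run_benchmark
from .features import FEATURE_ORDER, SpDataset, concat_sp, featurize_grn_sp
from .grn import GrnConfig, sample_grn, sample_interaction_params, write_targets_file
from .models import SpModelConfig, SPREdSP, load_checkpoint, save_checkpoint
from .simulate import (
    DEFAULT_N_CELLTYPE,
    SimParams,
    sample_mr_rates,
    simulate_steady_state,
    subsample_conditions,
    write_expression_tsv,
)
from .train import TrainConfig, train_model

__all__ = ["RunManifest", "run_pipeline", "build_training_set", "make_fixtures"]

_STAGES = ("grn", "sim", "train", "bench")


@dataclass
class RunManifest:
    """Machine-readable description of one full experiment."""

    seed: int = 0
    n_train_grn: int = 250
    grn: GrnConfig = field(
        default_factory=lambda: GrnConfig(
            n_mr=5, n_tf=100, n_gene=100, d_mr_tf=3, d_tf_gene_range=(3, 7)
        )
    )
    m: int = 50
    sim: SimParams = field(default_factory=SimParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    bench: BenchSetting = field(default_factory=BenchSetting)
    features: tuple[str, ...] = FEATURE_ORDER

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunManifest":
        kwargs: dict = {}
        for key in ("seed", "n_train_grn", "m"):
            if key in raw:
                kwargs[key] = raw[key]
        if "features" in raw:
            kwargs["features"] = tuple(raw["features"])
        if "grn" in raw:
            g = dict(raw["grn"])
            g["d_tf_gene_range"] = tuple(g["d_tf_gene_range"])
            kwargs["grn"] = GrnConfig(**g)
        if "sim" in raw:
            kwargs["sim"] = SimParams(**raw["sim"])
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        if "bench" in raw:
            b = dict(raw["bench"])
            if "d_tf_gene" in b:
                d = b["d_tf_gene"]
                b["d_tf_gene"] = (
                    tuple(tuple(x) for x in d)
                    if d and isinstance(d[0], (list, tuple))
                    else tuple(d)
                )
            if "n_mr" in b and isinstance(b["n_mr"], list):
                b["n_mr"] = tuple(b["n_mr"])
            if "sim" in b:
                b["sim"] = SimParams(**b["sim"])
            kwargs["bench"] = BenchSetting(**b)
        unknown = set(raw) - {"seed", "n_train_grn", "m", "features", "grn", "sim", "train", "bench"}
        if unknown:
            raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Named substream seed derived from the master seed (below 2^31)."""
        key = f"{stage}:{index}".encode()
        digest = hashlib.sha256(str(self.seed).encode() + b"|" + key).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def build_training_set(manifest: RunManifest, n_grn: int | None = None) -> SpDataset:
    """Simulate n_train_grn GRN + expression pairs and featurize them (SP)."""
    n_grn = manifest.n_train_grn if n_grn is None else n_grn
    datasets = []
    for i in range(n_grn):
        grn = sample_interaction_params(
            sample_grn(manifest.grn, manifest.stage_seed("grn", i)),
            manifest.stage_seed("grn-params", i),
        )
        panel = sample_mr_rates(
            manifest.grn.n_mr, DEFAULT_N_CELLTYPE, seed=manifest.stage_seed("rates", i)
        )
        expr = simulate_steady_state(
            grn, panel, manifest.sim, seed=manifest.stage_seed("sim", i)
        )
        if manifest.m < expr.n_conditions:
            expr = subsample_conditions(expr, manifest.m, seed=manifest.stage_seed("sub", i))
        datasets.append(
            featurize_grn_sp(expr, grn, features=manifest.features, group_id=i)
        )
    return concat_sp(datasets)


def run_pipeline(manifest: RunManifest, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    (out / "manifest.json").write_text(
        json.dumps({"version": __version__, **manifest.to_dict()}, indent=2)
    )

    ckpt = out / "model_sp"
    if ckpt.with_suffix(".npz").exists() and not overwrite:
        model = load_checkpoint(ckpt)
        history = None
    else:
        dataset = build_training_set(manifest)
        model = SPREdSP(
            SpModelConfig(n_tf=manifest.grn.n_tf, n_features=len(manifest.features)),
            seed=manifest.stage_seed("init"),
        )
        result = train_model(dataset, model, manifest.train)
        save_checkpoint(model, ckpt)
        history = result.history
        with open(out / "training_log.jsonl", "w") as fh:
            for rec in result.history:
                fh.write(json.dumps(rec) + "\n")

    table, pooled = run_benchmark(
        manifest.bench, model, seed=manifest.stage_seed("bench"), features=manifest.features
    )
    table.to_csv(out / "per_gene.tsv", sep="\t", index=False)
    summary = {
        "mean_ap": pooled.mean_ap,
        "mean_auroc": pooled.mean_auroc,
        "n_genes": int(len(pooled.per_gene_ap)),
        "n_excluded": pooled.n_excluded,
        "elapsed_s": round(time.time() - t0, 2),
        "trained": history is not None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Tiny deterministic fixture set for tests and examples.

    Returns (and optionally writes) a small parameterized GRN, its panel and
    expression matrix, and a perfect-prediction score matrix whose AP and
    AUROC against the GRN are exactly 1.
    """
    from .evaluate import EdgeScoreMatrix

    cfg = GrnConfig(n_mr=2, n_tf=5, n_gene=6, d_mr_tf=1, d_tf_gene_range=(1, 3))
    grn = sample_interaction_params(sample_grn(cfg, seed), seed + 1)
    panel = sample_mr_rates(cfg.n_mr, 20, seed=seed + 2)
    expr = simulate_steady_state(
        grn, panel, SimParams(burn_in=400, n_steps=100), seed=seed + 3
    )
    truth = grn.tf_gene_edge_set()
    scores = np.zeros((cfg.n_tf, cfg.n_gene))
    for i, t in enumerate(grn.tf_ids):
        for j, g in enumerate(grn.gene_ids):
            scores[i, j] = 1.0 if (t, g) in truth else 0.0
    perfect = EdgeScoreMatrix(
        scores=scores,
        tf_ids=list(grn.tf_ids),
        gene_ids=list(grn.gene_ids),
        method_tag="perfect",
    )
    fixtures = {"grn": grn, "panel": panel, "expr": expr, "perfect_scores": perfect}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_targets_file(grn, out / "targets.csv")
        write_expression_tsv(expr, out / "expression.tsv")
        from .evaluate import write_scores_tsv

        write_scores_tsv(perfect, out / "perfect_scores.tsv")
    return fixtures
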