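"""Random three-layer gene regulatory networks.

A network has three layers of nodes — master regulators (MRs), transcription
factors (TFs) and target genes — with signed, Hill-parameterized regulatory
edges running strictly MR→TF and TF→gene.  Node identifiers are 0-based
contiguous integers ordered MR-block, TF-block, gene-block.  The MR layer
exists to induce co-expression among TFs, mimicking the correlated candidate
regulators seen in real expression compendia.

Interaction strengths K are drawn uniformly from [1.0, 5.0] and negated
(repression) with probability 0.2; Hill coefficients are 2 with probability
0.9 and 1 otherwise.  Networks round-trip through a SERGIO-compatible
"targets" CSV dialect: one record per regulated node listing the child
identifier, its regulator count, the regulator identifiers, the K values and
the Hill coefficients, comma-separated in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RegEdge",
    "GrnConfig",
    "GrnSpec",
    "sample_grn",
    "sample_interaction_params",
    "write_targets_file",
    "read_targets_file",
]

# Role tags for the three node layers.
ROLE_MR = "MR"
ROLE_TF = "TF"
ROLE_GENE = "GENE"

K_ABS_MIN = 1.0
K_ABS_MAX = 5.0
P_REPRESS = 0.2  # probability K is negated
P_HILL_2 = 0.9  # probability the Hill coefficient is 2 (else 1)


@dataclass(frozen=True)
class RegEdge:
    """One regulatory edge parent→child.

    ``k`` is the signed interaction strength (negative = repression) and
    ``hill_n`` the Hill coefficient; both are None until parameters are
    sampled.
    """

    parent: int
    child: int
    k: float | None = None
    hill_n: int | None = None


@dataclass(frozen=True)
class GrnConfig:
    """Connectivity parameters of a three-layer GRN."""

    n_mr: int
    n_tf: int
    n_gene: int
    d_mr_tf: int
    d_tf_gene_range: tuple[int, int]

    def validate(self) -> None:
        if min(self.n_mr, self.n_tf, self.n_gene) < 0:
            raise ValueError("layer sizes must be non-negative")
        lo, hi = self.d_tf_gene_range
        if self.n_tf > 0 and not (1 <= self.d_mr_tf <= self.n_mr):
            raise ValueError(
                f"d_mr_tf={self.d_mr_tf} must lie in [1, n_mr={self.n_mr}]"
            )
        if self.n_gene > 0 and not (1 <= lo <= hi <= self.n_tf):
            raise ValueError(
                f"d_tf_gene_range={self.d_tf_gene_range} must satisfy "
                f"1 <= lo <= hi <= n_tf={self.n_tf}"
            )


@dataclass
class GrnSpec:
    """A sampled three-layer GRN with edges grouped by child node."""

    n_mr: int
    n_tf: int
    n_gene: int
    edges: list[RegEdge] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.n_mr + self.n_tf + self.n_gene

    @property
    def mr_ids(self) -> range:
        return range(self.n_mr)

    @property
    def tf_ids(self) -> range:
        return range(self.n_mr, self.n_mr + self.n_tf)

    @property
    def gene_ids(self) -> range:
        return range(self.n_mr + self.n_tf, self.n_nodes)

    def role_of(self, node: int) -> str:
        if node < self.n_mr:
            return ROLE_MR
        if node < self.n_mr + self.n_tf:
            return ROLE_TF
        return ROLE_GENE

    def roles(self) -> np.ndarray:
        return np.array(
            [ROLE_MR] * self.n_mr + [ROLE_TF] * self.n_tf + [ROLE_GENE] * self.n_gene
        )

    def parents_of(self, child: int) -> list[RegEdge]:
        return [e for e in self.edges if e.child == child]

    def tf_gene_edge_set(self) -> set[tuple[int, int]]:
        """Set of (tf, gene) pairs that are true regulatory edges."""
        first_gene = self.n_mr + self.n_tf
        return {(e.parent, e.child) for e in self.edges if e.child >= first_gene}

    def validate(self) -> None:
        """Check the strict three-layer structure invariants."""
        by_child: dict[int, list[int]] = {}
        for e in self.edges:
            by_child.setdefault(e.child, []).append(e.parent)
        first_tf, first_gene = self.n_mr, self.n_mr + self.n_tf
        for child, parents in by_child.items():
            if child < first_tf:
                raise ValueError(f"MR node {child} must not have parents")
            if len(set(parents)) != len(parents):
                raise ValueError(f"duplicate parents for node {child}")
            if child < first_gene:  # TF
                if any(not (0 <= p < first_tf) for p in parents):
                    raise ValueError(f"TF {child} has a non-MR parent")
            else:  # gene
                if any(not (first_tf <= p < first_gene) for p in parents):
                    raise ValueError(f"gene {child} has a non-TF parent")


def sample_grn(config: GrnConfig, seed: int) -> GrnSpec:
    """Sample a random GRN with the configured connectivity.

    Each TF receives exactly ``d_mr_tf`` MR parents, each gene an in-degree
    drawn uniformly from ``d_tf_gene_range``; parent sets are uniform without
    replacement.  Edge parameters (k, hill_n) are left unset.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    grn = GrnSpec(config.n_mr, config.n_tf, config.n_gene)
    lo, hi = config.d_tf_gene_range
    for tf in grn.tf_ids:
        parents = rng.choice(config.n_mr, size=config.d_mr_tf, replace=False)
        for p in sorted(int(x) for x in parents):
            grn.edges.append(RegEdge(parent=p, child=tf))
    for gene in grn.gene_ids:
        d = int(rng.integers(lo, hi + 1))
        parents = rng.choice(config.n_tf, size=d, replace=False) + config.n_mr
        for p in sorted(int(x) for x in parents):
            grn.edges.append(RegEdge(parent=p, child=gene))
    return grn


def sample_interaction_params(grn: GrnSpec, seed: int) -> GrnSpec:
    """Draw interaction strengths and Hill coefficients for every edge.

    |k| ~ Uniform[1, 5], negated with probability 0.2; hill_n = 2 with
    probability 0.9 and 1 otherwise, independently per edge.  The same
    distribution is applied to MR→TF and TF→gene edges.
    """
    rng = np.random.default_rng(seed)
    n = len(grn.edges)
    mag = rng.uniform(K_ABS_MIN, K_ABS_MAX, size=n)
    sign = np.where(rng.random(n) < P_REPRESS, -1.0, 1.0)
    hill = np.where(rng.random(n) < P_HILL_2, 2, 1)
    edges = [
        replace(e, k=float(s * m), hill_n=int(h))
        for e, m, s, h in zip(grn.edges, mag, sign, hill)
    ]
    return GrnSpec(grn.n_mr, grn.n_tf, grn.n_gene, edges)


def _format_float(x: float) -> str:
    return repr(float(x))


def write_targets_file(grn: GrnSpec, path: str | Path) -> None:
    """Write the SERGIO-style targets file.

    One comma-separated record per regulated (non-MR) node:
    child_id, n_regulators, parent ids..., k values..., hill coefficients...
    """
    by_child: dict[int, list[RegEdge]] = {}
    for e in grn.edges:
        if e.k is None or e.hill_n is None:
            raise ValueError("GRN edges must be fully parameterized before writing")
        by_child.setdefault(e.child, []).append(e)
    lines = []
    for child in sorted(by_child):
        edges = by_child[child]
        fields = (
            [str(child), str(len(edges))]
            + [str(e.parent) for e in edges]
            + [_format_float(e.k) for e in edges]
            + [str(e.hill_n) for e in edges]
        )
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_targets_file(path: str | Path, n_mr: int | None = None) -> GrnSpec:
    """Read a targets file back into a :class:`GrnSpec` (inverse of write).

    Layer sizes are inferred from the strict three-layer structure: every
    non-MR node appears as a child, so the smallest child identifier is the
    number of MRs (pass ``n_mr`` explicitly for edgeless networks).
    """
    text = Path(path).read_text()
    records: list[tuple[int, list[RegEdge]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        fields = line.split(",")
        child, n_reg = int(fields[0]), int(fields[1])
        if len(fields) != 2 + 3 * n_reg:
            raise ValueError(f"malformed targets record for node {child}")
        parents = [int(x) for x in fields[2 : 2 + n_reg]]
        ks = [float(x) for x in fields[2 + n_reg : 2 + 2 * n_reg]]
        hills = [int(x) for x in fields[2 + 2 * n_reg :]]
        records.append(
            (
                child,
                [
                    RegEdge(parent=p, child=child, k=k, hill_n=h)
                    for p, k, h in zip(parents, ks, hills)
                ],
            )
        )
    if not records:
        return GrnSpec(n_mr or 0, 0, 0)
    children = [c for c, _ in records]
    inferred_mr = min(children)
    if n_mr is None:
        n_mr = inferred_mr
    # TFs are children whose parents are all MRs; genes follow them.
    tf_children = {c for c, es in records if all(e.parent < n_mr for e in es)}
    n_tf = len(tf_children)
    n_gene = len(records) - n_tf
    grn = GrnSpec(n_mr, n_tf, n_gene)
    for _, es in sorted(records):
        grn.edges.extend(es)
    grn.validate()
    return grn
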