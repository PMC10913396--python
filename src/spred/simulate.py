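"""Steady-state expression simulation from a three-layer GRN.

Emulates the "clean" mode of steady-state GRN simulators: each biological
condition ("cell type") is defined by a vector of master-regulator production
rates; transcription dynamics follow Hill-regulation ODEs with a
chemical-Langevin noise term, integrated by Euler–Maruyama; one cell is read
out per cell type after a fixed burn-in.

For node i with production term P_i and shared first-order degradation rate
``decay``, the state evolves as

    dx_i = (P_i(x) - decay * x_i) * dt
           + noise_scale * sqrt(max(P_i, 0) + decay * x_i) * sqrt(dt) * xi,

with xi standard normal and x clipped at zero.  For an MR, P_i is its
condition-specific production rate.  For a TF or gene, P_i sums |k| * H(x_p)
over parents p, where H is the activating Hill function x^n / (h^n + x^n)
for k > 0 and the repressing form h^n / (h^n + x^n) for k < 0.  The
half-response h of each parent is estimated once per GRN as that parent's
mean deterministic steady-state expression across cell types (a pre-pass
that is analytic layer by layer on the three-layer DAG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grn import ROLE_GENE, ROLE_MR, ROLE_TF, GrnSpec

__all__ = [
    "ConditionPanel",
    "SimParams",
    "ExpressionMatrix",
    "DEFAULT_RANGE_POOL",
    "sample_mr_rates",
    "deterministic_steady_state",
    "simulate_steady_state",
    "subsample_conditions",
    "inject_dropout",
    "write_master_rates_file",
    "read_master_rates_file",
    "write_expression_tsv",
    "read_expression_tsv",
]

# Candidate (low, high) production-rate range pairs; one pair is chosen per
# GRN and each MR rate is drawn from the low or the high interval with equal
# probability, per (MR, cell type).
DEFAULT_RANGE_POOL: list[tuple[tuple[float, float], tuple[float, float]]] = [
    ((0.2, 0.5), (0.7, 1.0)),
    ((0.5, 1.0), (1.5, 2.5)),
    ((1.0, 1.5), (2.0, 3.0)),
]

DEFAULT_N_CELLTYPE = 100


class NonConvergenceWarning(UserWarning):
    """Deterministic component had a large residual at read-out."""


@dataclass
class ConditionPanel:
    """Per-condition master-regulator production rates.

    ``rates`` has one row per MR and one column per cell type; every entry is
    strictly positive.
    """

    rates: np.ndarray
    low_range: tuple[float, float]
    high_range: tuple[float, float]

    @property
    def n_mr(self) -> int:
        return self.rates.shape[0]

    @property
    def n_celltype(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class SimParams:
    """Integration parameters of the Langevin simulator.

    decay: shared first-order degradation rate (1/time).
    noise_scale: amplitude of the chemical-Langevin noise term; 0 gives the
        deterministic ODE limit.
    dt: Euler–Maruyama step; dt * decay must stay below 1 for stability.
    n_steps: integration steps after burn-in before the cell is read.
    burn_in: steps discarded to approach the steady-state distribution.
    """

    decay: float = 0.8
    noise_scale: float = 1.0
    dt: float = 0.01
    n_steps: int = 500
    burn_in: int = 2000

    def __post_init__(self) -> None:
        if self.dt * self.decay >= 1.0:
            raise ValueError("unstable integration: require dt * decay < 1")
        if min(self.dt, self.decay) <= 0 or self.noise_scale < 0:
            raise ValueError("decay and dt must be positive, noise_scale >= 0")
        if self.n_steps <= 0 or self.burn_in <= 0:
            raise ValueError("n_steps and burn_in must be positive")


@dataclass
class ExpressionMatrix:
    """A genes × conditions matrix with role-tagged rows (MR, TF, GENE blocks)."""

    values: np.ndarray
    row_roles: np.ndarray
    condition_ids: list[str]
    constant_row_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_roles = np.asarray(self.row_roles)
        if self.values.shape != (len(self.row_roles), len(self.condition_ids)):
            raise ValueError("values shape must match row_roles × condition_ids")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.row_roles == role)

    @property
    def mr_rows(self) -> np.ndarray:
        return self.role_indices(ROLE_MR)

    @property
    def tf_rows(self) -> np.ndarray:
        return self.role_indices(ROLE_TF)

    @property
    def gene_rows(self) -> np.ndarray:
        return self.role_indices(ROLE_GENE)

    def row_names(self) -> list[str]:
        counts = {ROLE_MR: 0, ROLE_TF: 0, ROLE_GENE: 0}
        prefix = {ROLE_MR: "MR", ROLE_TF: "TF", ROLE_GENE: "G"}
        names = []
        for role in self.row_roles:
            names.append(f"{prefix[str(role)]}{counts[str(role)]}")
            counts[str(role)] += 1
        return names

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.row_roles.copy(),
            list(self.condition_ids),
            None if self.constant_row_flags is None else self.constant_row_flags.copy(),
        )


def sample_mr_rates(
    n_mr: int,
    n_celltype: int = DEFAULT_N_CELLTYPE,
    range_pool: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    seed: int = 0,
) -> ConditionPanel:
    """Draw per-condition MR production rates.

    One (low, high) interval pair is chosen uniformly from ``range_pool`` for
    the whole panel (i.e. per GRN); each rate is then drawn uniformly from the
    low or the high interval, decided by a fair coin flip per (MR, cell type).
    """
    pool = DEFAULT_RANGE_POOL if range_pool is None else range_pool
    for low, high in pool:
        if not (0 < low[0] <= low[1] < high[0] <= high[1]):
            # low interval strictly positive and strictly below the high one
            raise ValueError(f"invalid rate interval pair {(low, high)}")
    rng = np.random.default_rng(seed)
    low, high = pool[int(rng.integers(len(pool)))]
    use_high = rng.random((n_mr, n_celltype)) < 0.5
    u = rng.random((n_mr, n_celltype))
    rates = np.where(
        use_high,
        high[0] + u * (high[1] - high[0]),
        low[0] + u * (low[1] - low[0]),
    )
    return ConditionPanel(rates=rates, low_range=low, high_range=high)


def _edge_arrays(grn: GrnSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized edge representation: parent, child, k, hill arrays."""
    if not grn.edges:
        z = np.zeros(0)
        return z.astype(int), z.astype(int), z, z.astype(int)
    parents = np.array([e.parent for e in grn.edges])
    children = np.array([e.child for e in grn.edges])
    ks = np.array([e.k for e in grn.edges], dtype=float)
    hills = np.array([e.hill_n for e in grn.edges])
    if np.any(np.isnan(ks)):
        raise ValueError("GRN edges must be fully parameterized")
    return parents, children, ks, hills


def _hill(x: np.ndarray, h: np.ndarray, n: np.ndarray, activating: np.ndarray) -> np.ndarray:
    """Hill response per edge; x, h, n broadcast over (n_edges, n_celltype)."""
    xn = np.where(n[:, None] == 2, x * x, x)
    hn = np.where(n == 2, h * h, h)[:, None]
    denom = hn + xn
    act = np.divide(xn, denom, out=np.zeros_like(xn), where=denom > 0)
    rep = np.divide(hn, denom, out=np.ones_like(xn), where=denom > 0)
    return np.where(activating[:, None], act, rep)


def deterministic_steady_state(
    grn: GrnSpec, panel: ConditionPanel, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free fixed point of the Hill ODE system, analytic layer by layer.

    Returns ``(values, half_response)``: values is (n_nodes, n_celltype);
    half_response is the per-node h (mean deterministic steady state across
    cell types) used for all edges out of that node.
    """
    n_nodes, n_ct = grn.n_nodes, panel.n_celltype
    parents, children, ks, hills = _edge_arrays(grn)
    activating = ks > 0
    x = np.zeros((n_nodes, n_ct))
    h = np.zeros(n_nodes)
    mr = np.arange(grn.n_mr)
    x[mr] = panel.rates / params.decay
    h[mr] = x[mr].mean(axis=1)
    for lo, hi in ((grn.n_mr, grn.n_mr + grn.n_tf), (grn.n_mr + grn.n_tf, n_nodes)):
        mask = (children >= lo) & (children < hi)
        if mask.any():
            contrib = np.abs(ks[mask])[:, None] * _hill(
                x[parents[mask]], h[parents[mask]], hills[mask], activating[mask]
            )
            prod = np.zeros((n_nodes, n_ct))
            np.add.at(prod, children[mask], contrib)
            x[lo:hi] = prod[lo:hi] / params.decay
        h[lo:hi] = x[lo:hi].mean(axis=1)
    return x, h


def simulate_steady_state(
    grn: GrnSpec,
    panel: ConditionPanel,
    params: SimParams | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate one steady-state cell per cell type.

    All cell types are integrated in parallel from a zero initial state for
    ``burn_in + n_steps`` Euler–Maruyama steps; the state at the final step is
    the read-out.  With ``noise_scale=0`` the output converges to the
    deterministic Hill-ODE fixed point.
    """
    if params is None:
        params = SimParams()
    if panel.n_mr != grn.n_mr:
        raise ValueError("panel MR count does not match GRN")
    if np.any(panel.rates <= 0):
        raise ValueError("MR production rates must be strictly positive")
    rng = np.random.default_rng(seed)
    n_nodes, n_ct = grn.n_nodes, panel.n_celltype
    parents, children, ks, hills = _edge_arrays(grn)
    activating = ks > 0
    det, h = deterministic_steady_state(grn, panel, params)
    # A parent pinned at zero in every condition would make its Hill response
    # degenerate (0/0); guard with a tiny floor.
    h_edge = np.maximum(h[parents], 1e-12)
    abs_k = np.abs(ks)[:, None]

    # Aggregate per-edge contributions into per-child production via a sparse
    # incidence matrix (fast segment sum).
    from scipy import sparse

    n_edges = len(ks)
    incidence = sparse.csr_matrix(
        (np.ones(n_edges), (children, np.arange(n_edges))), shape=(n_nodes, n_edges)
    )

    mr = np.arange(grn.n_mr)
    prod = np.zeros((n_nodes, n_ct))
    prod[mr] = panel.rates
    x = np.zeros((n_nodes, n_ct))
    decay, dt = params.decay, params.dt
    sqrt_dt = np.sqrt(dt)
    total_steps = params.burn_in + params.n_steps
    for _ in range(total_steps):
        if n_edges:
            contrib = abs_k * _hill(x[parents], h_edge, hills, activating)
            prod[grn.n_mr :] = (incidence @ contrib)[grn.n_mr :]
        drift = (prod - decay * x) * dt
        if params.noise_scale > 0:
            amp = params.noise_scale * np.sqrt(np.maximum(prod, 0.0) + decay * x)
            x = x + drift + amp * sqrt_dt * rng.standard_normal((n_nodes, n_ct))
        else:
            x = x + drift
        np.maximum(x, 0.0, out=x)

    # Convergence check on the deterministic component: the zero-initialized
    # ODE trajectory approaches the fixed point as exp(-decay * t).
    residual = np.exp(-decay * dt * total_steps)
    if residual > 1e-3:
        warnings.warn(
            f"deterministic component may not have converged "
            f"(relative residual ~ {residual:.2e})",
            NonConvergenceWarning,
        )

    roles = grn.roles()
    condition_ids = [f"c{j}" for j in range(n_ct)]
    return ExpressionMatrix(values=x, row_roles=roles, condition_ids=condition_ids)


def subsample_conditions(expr: ExpressionMatrix, m: int, seed: int = 0) -> ExpressionMatrix:
    """Keep m conditions chosen uniformly without replacement, order preserved."""
    if m > expr.n_conditions:
        raise ValueError(f"cannot subsample {m} of {expr.n_conditions} conditions")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(expr.n_conditions, size=m, replace=False))
    return ExpressionMatrix(
        values=expr.values[:, keep],
        row_roles=expr.row_roles.copy(),
        condition_ids=[expr.condition_ids[j] for j in keep],
    )


def inject_dropout(expr: ExpressionMatrix, fraction: float, seed: int = 0) -> ExpressionMatrix:
    """Zero out exactly round(fraction * size) entries, uniformly at random."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("dropout fraction must lie in [0, 1]")
    out = expr.copy()
    n_zero = int(round(fraction * out.values.size))
    if n_zero:
        rng = np.random.default_rng(seed)
        flat = rng.choice(out.values.size, size=n_zero, replace=False)
        out.values.ravel()[flat] = 0.0
    return out


# ---------------------------------------------------------------------------
# File formats


def write_master_rates_file(panel: ConditionPanel, path: str | Path) -> None:
    """SERGIO-style master regulators file: one record per MR, identifier
    followed by one production rate per cell type, comma-separated."""
    lines = [
        ",".join([str(i)] + [repr(float(r)) for r in panel.rates[i]])
        for i in range(panel.n_mr)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_master_rates_file(path: str | Path) -> ConditionPanel:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        fields = line.split(",")
        rows.append((int(fields[0]), [float(x) for x in fields[1:]]))
    rows.sort()
    rates = np.array([r for _, r in rows])
    lo, hi = float(rates.min()), float(rates.max())
    return ConditionPanel(rates=rates, low_range=(lo, lo), high_range=(hi, hi))


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Expression TSV: role-prefixed row identifiers, condition columns."""
    df = pd.DataFrame(expr.values, index=expr.row_names(), columns=expr.condition_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    roles = []
    for name in df.index:
        if name.startswith("MR"):
            roles.append(ROLE_MR)
        elif name.startswith("TF"):
            roles.append(ROLE_TF)
        else:
            roles.append(ROLE_GENE)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        row_roles=np.array(roles),
        condition_ids=[str(c) for c in df.columns],
    )
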