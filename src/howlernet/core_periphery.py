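"""Categorical core-periphery structure in bipartite matrices.

Both node sets are partitioned into a core (generalists, densely
interacting) and a periphery.  Fit quality is the Pearson correlation
between the observed cells and the ideal block pattern — ones in the
core-row x core-column block, zeros in the periphery x periphery block,
mixed blocks ignored.  Memberships are found by simulated annealing, and
the classification is repeated over independent runs to report, per node,
the percentage of runs in which it fell in the core (the occurrence table).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import InteractionMatrix
from .network_metrics import _as_binary_array

__all__ = [
    "CorePeripheryResult",
    "cp_fitness",
    "fit_core_periphery",
    "core_periphery_occurrence",
]


def cp_fitness(
    matrix: InteractionMatrix | np.ndarray,
    row_core: np.ndarray,
    col_core: np.ndarray,
) -> float:
    """Correlation between the matrix and the ideal core-periphery pattern.

    Cells in the core x core block are compared against 1, cells in the
    periphery x periphery block against 0; core x periphery blocks are
    excluded.  Returns NaN when either compared vector has zero variance
    (e.g. an empty block, or identical cell values throughout).
    """
    a = _as_binary_array(matrix)
    rc = np.asarray(row_core, dtype=bool)
    cc = np.asarray(col_core, dtype=bool)
    if rc.shape != (a.shape[0],) or cc.shape != (a.shape[1],):
        raise ValueError("membership lengths do not match matrix shape")
    n1 = int(rc.sum()) * int(cc.sum())
    n0 = int((~rc).sum()) * int((~cc).sum())
    n = n1 + n0
    if n1 == 0 or n0 == 0:
        return float("nan")
    s1 = float(a[np.ix_(rc, cc)].sum())
    s0 = float(a[np.ix_(~rc, ~cc)].sum())
    s = s1 + s0
    # Pearson r between x (cell values) and y (block indicator) from sums:
    # x binary is not assumed, but x*x = x for 0/1 matrices.
    sum_x = s
    sum_xx = s  # binary cells
    sum_y = n1
    sum_xy = s1
    cov = sum_xy - sum_x * sum_y / n
    var_x = sum_xx - sum_x**2 / n
    var_y = sum_y - sum_y**2 / n
    if var_x <= 1e-12 or var_y <= 1e-12:
        return float("nan")
    return cov / np.sqrt(var_x * var_y)


def _orient(a: np.ndarray, rc: np.ndarray, cc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the core/periphery label-swap degeneracy: the core is the
    side with the higher mean degree (generalists)."""
    deg = np.concatenate([a.sum(axis=1), a.sum(axis=0)])
    core = np.concatenate([rc, cc])
    if core.all() or (~core).all():
        return rc, cc
    if deg[core].mean() < deg[~core].mean():
        return ~rc, ~cc
    return rc, cc


def fit_core_periphery(
    matrix: InteractionMatrix | np.ndarray,
    seed: int | np.random.SeedSequence | None = None,
    proposals_per_node: int = 200,
    n_restarts: int = 4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One annealing run: (row_core, col_core, fitness).

    Simulated annealing over the joint row/column membership vector with
    single-label flip proposals, geometric cooling, and roughly
    ``proposals_per_node x (R + C)`` proposals split over ``n_restarts``
    random restarts; the best labelling across restarts is returned after
    orienting so that core nodes have the higher mean degree.

    The ignore-mixed-blocks fitness is degenerate on perfect block
    matrices (dropping a core node moves its cells into an ignored block
    without changing the correlation), so equal-fitness labellings are
    tie-broken toward the larger core block, making the planted labelling
    of an exact block matrix the unique winner.
    """
    a = _as_binary_array(matrix)
    r, c = a.shape
    if r < 2 or c < 2:
        raise ValueError("core-periphery fit requires at least 2 rows and 2 columns")
    if a.all() or not a.any():
        raise ValueError("matrix is uniform (all ones or all zeros): no structure")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n_nodes = r + c
    steps = max(1, (proposals_per_node * n_nodes) // n_restarts)
    t0, t1 = 0.25, 0.002
    cooling = (t1 / t0) ** (1.0 / steps)

    best_fit = -np.inf
    best_core = -1
    best_rc = best_cc = None

    def consider(fit: float, rc: np.ndarray, cc: np.ndarray) -> None:
        nonlocal best_fit, best_core, best_rc, best_cc
        core_size = int(rc.sum()) * int(cc.sum())
        if fit > best_fit + 1e-12 or (
            abs(fit - best_fit) <= 1e-12 and core_size > best_core
        ):
            best_fit = fit
            best_core = core_size
            best_rc, best_cc = rc.copy(), cc.copy()

    for _ in range(n_restarts):
        rc = rng.random(r) < 0.5
        cc = rng.random(c) < 0.5
        fit = cp_fitness(a, rc, cc)
        if not np.isfinite(fit):
            fit = -1.0
        consider(fit, rc, cc)
        temp = t0
        for _ in range(steps):
            node = int(rng.integers(n_nodes))
            if node < r:
                rc[node] = ~rc[node]
            else:
                cc[node - r] = ~cc[node - r]
            new = cp_fitness(a, rc, cc)
            new_eff = new if np.isfinite(new) else -1.0
            if new_eff >= fit or rng.random() < np.exp((new_eff - fit) / temp):
                fit = new_eff
                consider(fit, rc, cc)
            else:  # revert
                if node < r:
                    rc[node] = ~rc[node]
                else:
                    cc[node - r] = ~cc[node - r]
            temp *= cooling
    best_rc, best_cc = _orient(a, best_rc, best_cc)
    achieved = cp_fitness(a, best_rc, best_cc)
    return best_rc, best_cc, float(achieved)


@dataclass(frozen=True)
class CorePeripheryResult:
    """Occurrence of each node in the core across independent runs.

    ``table`` has one row per node (side, label, percent_core,
    percent_periphery); runs whose fit is degenerate (NaN fitness) abstain,
    so the two percentages may sum to less than 100.
    """

    table: pd.DataFrame
    n_runs: int
    fitness: list = field(default_factory=list)

    def for_side(self, side: str) -> pd.DataFrame:
        return self.table[self.table["side"] == side].reset_index(drop=True)


def core_periphery_occurrence(
    matrix: InteractionMatrix,
    n_runs: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    **fit_kwargs,
) -> CorePeripheryResult:
    """Repeat the annealing fit ``n_runs`` times and tabulate, per node,
    the percentage of runs in which it was classified core vs periphery."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    a = _as_binary_array(matrix)
    r, c = a.shape
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    core_counts = np.zeros(r + c)
    valid_counts = np.zeros(r + c)
    fitnesses = []
    for child in ss.spawn(n_runs):
        rc, cc, fit = fit_core_periphery(a, seed=child, **fit_kwargs)
        fitnesses.append(fit)
        if not np.isfinite(fit):
            continue  # abstention
        lab = np.concatenate([rc, cc])
        core_counts += lab
        valid_counts += 1
    if isinstance(matrix, InteractionMatrix):
        labels = matrix.row_labels + matrix.col_labels
    else:
        labels = [f"row_{i}" for i in range(r)] + [f"col_{j}" for j in range(c)]
    sides = ["row"] * r + ["col"] * c
    pct_core = 100.0 * core_counts / n_runs
    pct_peri = 100.0 * (valid_counts - core_counts) / n_runs
    table = pd.DataFrame(
        {
            "node": labels,
            "side": sides,
            "percent_core": pct_core,
            "percent_periphery": pct_peri,
        }
    )
    return CorePeripheryResult(table=table, n_runs=n_runs, fitness=fitnesses)
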