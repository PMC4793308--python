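"""Bipartite network attributes for individual-based diet matrices.

Implements the qualitative nestedness metric NODF (percentage overlap among
row pairs and column pairs with strictly decreasing marginal fill),
connectance, mean links per species, Shannon interaction diversity, and the
network-level specialization index H2' standardized by the entropy extremes
compatible with the marginal totals.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import InteractionMatrix, Individual, AgeClass, Sex, class_label

__all__ = [
    "NetworkAttributes",
    "nodf",
    "connectance",
    "links_per_species",
    "interaction_diversity",
    "h2_bounds",
    "h2_selectivity",
    "network_attributes",
    "class_diet_summary",
    "round2",
]


def round2(x: float) -> float:
    """Round half-even to 2 decimals, the convention of the reporting layer."""
    return float(np.round(x, 2))


def _as_binary_array(matrix: InteractionMatrix | np.ndarray) -> np.ndarray:
    a = matrix.weights if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(
            "matrix is not binary; call .binary() (or binarize) before "
            "computing this metric"
        )
    return a.astype(float)


def _as_array(matrix: InteractionMatrix | np.ndarray) -> np.ndarray:
    a = matrix.weights if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    return np.asarray(a, dtype=float)


# ---------------------------------------------------------------------------
# NODF


def _nodf_axis_sum(a: np.ndarray) -> float:
    """Sum of paired overlap percentages over row pairs of ``a``.

    For rows u, v with fill(u) > fill(v) > 0, the pair contributes
    100 * |ones(v) ∩ ones(u)| / fill(v); pairs with equal fill or an empty
    lighter row contribute 0.
    """
    fills = a.sum(axis=1)
    overlap = a @ a.T
    fi = fills[:, None]
    fj = fills[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where((fi > fj) & (fj > 0), 100.0 * overlap / fj, 0.0)
    return float(contrib.sum())


def nodf(matrix: InteractionMatrix | np.ndarray) -> float:
    """Nestedness metric based on overlap and decreasing fill, in [0, 100].

    Averages the paired overlap percentage over all row pairs and all
    column pairs; only pairs whose marginal fills strictly decrease can
    contribute (equal fills score 0), so a perfectly nested matrix with
    distinct fills scores 100 and an identity matrix scores 0.
    """
    a = _as_binary_array(matrix)
    r, c = a.shape
    if r < 2 or c < 2:
        raise ValueError("NODF requires at least 2 rows and 2 columns")
    total = _nodf_axis_sum(a) + _nodf_axis_sum(a.T)
    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return total / n_pairs


# ---------------------------------------------------------------------------
# Simple attributes


def connectance(matrix: InteractionMatrix | np.ndarray) -> float:
    """Realized links divided by the number of cells in the matrix."""
    a = _as_array(matrix)
    if a.size == 0:
        raise ValueError("empty matrix")
    return float(np.count_nonzero(a)) / a.size


def links_per_species(matrix: InteractionMatrix | np.ndarray) -> float:
    """Mean linkage level: links divided by total node count (rows + cols)."""
    a = _as_array(matrix)
    r, c = a.shape
    if r + c == 0:
        raise ValueError("empty matrix")
    return float(np.count_nonzero(a)) / (r + c)


def interaction_diversity(
    matrix: InteractionMatrix | np.ndarray, weighted: bool = False
) -> float:
    """Shannon diversity (nats) of the interaction frequency distribution.

    With ``weighted=False`` the binary link matrix is used, so the result
    is exactly ln(L) for L links; with ``weighted=True`` cell weights are
    normalized to proportions first.
    """
    a = _as_array(matrix)
    if not weighted:
        a = (a > 0).astype(float)
    total = a.sum()
    if total <= 0:
        raise ValueError("matrix has no interactions")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# H2' specialization


def _entropy(weights: np.ndarray, total: float) -> float:
    w = np.asarray(weights, dtype=float).ravel()
    w = w[w > 0]
    p = w / total
    return float(-(p * np.log(p)).sum())


def _enumerate_extremes(
    rows: np.ndarray, cols: np.ndarray, total: float
) -> tuple[float, float]:
    """Exact entropy extremes over all nonnegative-integer matrices with the
    given marginals, by depth-first enumeration of the transportation
    polytope.  Only used for small problems (see :func:`h2_bounds`)."""
    r, c = len(rows), len(cols)
    best = {"min": np.inf, "max": -np.inf}

    cols0 = np.asarray(cols, dtype=int)

    def rec(i: int, remaining_cols: np.ndarray, cells: list[int]) -> None:
        if i == r:
            if remaining_cols.any():
                return
            h = _entropy(np.array(cells, dtype=float), total)
            best["min"] = min(best["min"], h)
            best["max"] = max(best["max"], h)
            return
        target = int(rows[i])
        # tail feasibility: remaining rows must absorb what's left
        tail = int(rows[i + 1 :].sum())
        if int(remaining_cols.sum()) - target != tail:
            return

        def comp(j: int, left: int, row_cells: list[int]) -> None:
            if j == c - 1:
                if left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row_cells + [left]),
                        cells + row_cells + [left])
                return
            for v in range(min(left, int(remaining_cols[j])) + 1):
                comp(j + 1, left - v, row_cells + [v])

        comp(0, target, [])

    rec(0, cols0.copy(), [])
    return best["min"], best["max"]


def _greedy_pack_entropy(rows: np.ndarray, cols: np.ndarray, total: float) -> float:
    """Entropy of the maximally packed matrix: repeatedly place
    min(remaining row, remaining col) in the cell of the two largest
    remaining marginals (heuristic lower entropy bound)."""
    r = np.asarray(rows, dtype=float).copy()
    c = np.asarray(cols, dtype=float).copy()
    cells: list[float] = []
    while r.sum() > 1e-12 and c.sum() > 1e-12:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        v = min(r[i], c[j])
        if v <= 0:
            break
        cells.append(v)
        r[i] -= v
        c[j] -= v
    return _entropy(np.array(cells), total)


def _even_fill_entropy(
    rows: np.ndarray, cols: np.ndarray, total: float, integer: bool
) -> float:
    """Entropy of the maximally even matrix compatible with the marginals.

    Starts from the independence expectation e_ij = r_i c_j / m; with
    ``integer=True`` the expectation is adjusted to an integer-compatible
    allocation by flooring and distributing the remaining units to feasible
    cells with the largest remainders (largest-remainder heuristic)."""
    r = np.asarray(rows, dtype=float)
    c = np.asarray(cols, dtype=float)
    e = np.outer(r, c) / total
    if not integer:
        return _entropy(e, total)
    a = np.floor(e)
    row_def = (r - a.sum(axis=1)).astype(int)
    col_def = (c - a.sum(axis=0)).astype(int)
    rem = e - a
    while row_def.sum() > 0:
        mask = (row_def[:, None] > 0) & (col_def[None, :] > 0)
        if not mask.any():  # numerically impossible for integer marginals
            break
        masked = np.where(mask, rem, -np.inf)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        a[i, j] += 1
        rem[i, j] -= 1
        row_def[i] -= 1
        col_def[j] -= 1
    return _entropy(a, total)


#: exact enumeration is used when the matrix is at most this many cells ...
EXACT_MAX_CELLS = 16
#: ... and the total weight at most this many units.
EXACT_MAX_TOTAL = 12


def h2_bounds(
    row_totals: Sequence[float],
    col_totals: Sequence[float],
    integer: bool = True,
) -> tuple[float, float]:
    """Entropy extremes (H2min, H2max) compatible with the marginal totals.

    For small integer problems (at most ``EXACT_MAX_CELLS`` cells and
    ``EXACT_MAX_TOTAL`` total weight) the extremes are exact, by
    enumerating every nonnegative-integer matrix with the given marginals;
    otherwise heuristics are used: greedy packing for H2min and the
    (integer-adjusted) independence expectation for H2max.
    """
    rows = np.asarray(row_totals, dtype=float)
    cols = np.asarray(col_totals, dtype=float)
    if rows.min(initial=0) < 0 or cols.min(initial=0) < 0:
        raise ValueError("marginal totals must be nonnegative")
    total = rows.sum()
    if not np.isclose(total, cols.sum()):
        raise ValueError(
            f"row totals sum to {total}, column totals to {cols.sum()}: "
            "marginals are incompatible"
        )
    if total <= 0:
        raise ValueError("total weight must be positive")

    is_int = integer and np.allclose(rows, np.round(rows)) and np.allclose(
        cols, np.round(cols)
    )
    if (
        is_int
        and rows.size * cols.size <= EXACT_MAX_CELLS
        and total <= EXACT_MAX_TOTAL
    ):
        h2min, h2max = _enumerate_extremes(
            np.round(rows).astype(int), np.round(cols).astype(int), total
        )
    else:
        h2min = _greedy_pack_entropy(rows, cols, total)
        h2max = _even_fill_entropy(rows, cols, total, integer=is_int)
        h2max = max(h2max, h2min)
    return h2min, h2max


def h2_selectivity(
    matrix: InteractionMatrix | np.ndarray, integer: bool = True
) -> float:
    """Network-level specialization H2' in [0, 1].

    H2' = (H2max - H2) / (H2max - H2min) where H2 is the Shannon entropy
    of the weighted matrix and H2min/H2max are the entropy extremes
    compatible with its marginal totals; 0 marks extreme generalization
    (interactions follow the independence expectation), 1 extreme
    specialization.  Returns 0 when the bounds coincide (degenerate
    marginals leave no room for specialization).
    """
    a = _as_array(matrix)
    total = a.sum()
    if total <= 0:
        raise ValueError("matrix has no interactions")
    h2 = _entropy(a, total)
    h2min, h2max = h2_bounds(a.sum(axis=1), a.sum(axis=0), integer=integer)
    if h2max - h2min < 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Attribute bundle


@dataclass(frozen=True)
class NetworkAttributes:
    """The per-habitat network attribute bundle."""

    n_rows: int
    n_cols: int
    n_links: int
    nodf: float
    connectance: float
    links_per_species: float
    interaction_diversity: float
    h2_selectivity: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_series(self, rounded: bool = True) -> pd.Series:
        """Attribute table with the canonical metric row names."""
        fmt = round2 if rounded else (lambda x: x)
        return pd.Series(
            {
                "No. of monkeys": self.n_rows,
                "No. of plant species": self.n_cols,
                "Nestedness (NODF-metric)": fmt(self.nodf),
                "Links per species": fmt(self.links_per_species),
                "Connectance (C)": fmt(self.connectance),
                "Interaction diversity": fmt(self.interaction_diversity),
                "Resource selectivity (H2')": fmt(self.h2_selectivity),
            },
            dtype=object,
        )


def network_attributes(
    matrix: InteractionMatrix,
    diversity_weighted: bool = False,
    h2_weighted: bool = True,
) -> NetworkAttributes:
    """Compute the full attribute bundle for one habitat's matrix.

    Nestedness, connectance, and links per species always use the binary
    link structure (the qualitative approach).  Interaction diversity is
    binary by default, so it equals ln(L); H2' defaults to the weighted
    cells, because with binary input the marginal-compatible entropy
    maximum is (near) the observed entropy and the index degenerates to 0.
    Passing an already-binary matrix with ``h2_weighted=True`` simply
    computes the binary H2'.
    """
    binary = matrix.binary()
    r, c = matrix.shape
    return NetworkAttributes(
        n_rows=r,
        n_cols=c,
        n_links=binary.n_links,
        nodf=nodf(binary),
        connectance=connectance(binary),
        links_per_species=links_per_species(binary),
        interaction_diversity=interaction_diversity(
            matrix if diversity_weighted else binary, weighted=diversity_weighted
        ),
        h2_selectivity=h2_selectivity(matrix if h2_weighted else binary),
    )


# ---------------------------------------------------------------------------
# Age/sex class diet summary


def class_diet_summary(
    matrix: InteractionMatrix, individuals: Sequence[Individual]
) -> pd.DataFrame:
    """Diet breadth per age/sex class.

    Returns one row per class present among the matrix rows with the
    number of individuals, the union diet size (distinct partner species),
    and mean per-individual degree.  Every matrix row label must have a
    matching individual.
    """
    by_id = {ind.individual_id: ind for ind in individuals}
    missing = [r for r in matrix.row_labels if r not in by_id]
    if missing:
        raise KeyError(f"matrix rows without an individual record: {missing}")
    b = matrix.binary().weights
    rows = []
    for sex, age in (
        (Sex.F, AgeClass.adult), (Sex.M, AgeClass.adult),
        (Sex.F, AgeClass.juvenile), (Sex.M, AgeClass.juvenile),
        (Sex.F, AgeClass.infant), (Sex.M, AgeClass.infant),
    ):
        idx = [
            i
            for i, rid in enumerate(matrix.row_labels)
            if by_id[rid].sex is sex and by_id[rid].age_class is age
        ]
        if not idx:
            continue
        sub = b[idx]
        union = sub.max(axis=0)
        rows.append(
            {
                "class": class_label(sex, age),
                "sex": sex.value,
                "age_class": age.value,
                "n_individuals": len(idx),
                "species_count": int(union.sum()),
                "mean_degree": float(sub.sum(axis=1).mean()),
            }
        )
    return pd.DataFrame(rows)


def diet_is_subset(
    matrix: InteractionMatrix,
    individuals: Sequence[Individual],
    inner: AgeClass = AgeClass.infant,
    outer: AgeClass = AgeClass.adult,
) -> bool:
    """True iff the union diet of ``inner``-class individuals is a subset of
    the union diet of ``outer``-class individuals."""
    by_id = {ind.individual_id: ind for ind in individuals}
    b = matrix.binary().weights
    def union(age: AgeClass) -> np.ndarray:
        idx = [
            i
            for i, rid in enumerate(matrix.row_labels)
            if by_id[rid].age_class is age
        ]
        if not idx:
            return np.zeros(matrix.shape[1])
        return b[idx].max(axis=0)
    return bool(np.all(union(inner) <= union(outer)))
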