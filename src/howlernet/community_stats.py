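"""Vegetation-community and dietary-composition statistics.

Covers the non-network side of the analysis: importance value index (IVI)
from 50 x 2 m vegetation transects, Jaccard similarity between species
lists, permutation Mantel tests between distance matrices, two-sample
t-tests after variance-stabilizing transforms, feeding-time fractions per
plant item, and a nested ANOVA of angular-transformed item-time fractions
(plant item nested within habitat).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .io_model import (
    Habitat,
    Item,
    ObservationRecord,
    StatTestResult,
    TransectRecord,
)

__all__ = [
    "IVIRecord",
    "compute_ivi",
    "jaccard",
    "mantel_test",
    "transformed_t_test",
    "item_time_fractions",
    "nested_anova",
    "arcsine_sqrt",
]


# ---------------------------------------------------------------------------
# Importance value index


@dataclass(frozen=True)
class IVIRecord:
    """Per-species community importance: the mean of relative density,
    relative frequency, and relative dominance (basal-area share), each on
    a 0-1 scale, so IVI sums to 1 over species within a habitat."""

    species: str
    relative_density: float
    relative_frequency: float
    relative_dominance: float
    ivi: float


def _basal_area(dbh_cm: float) -> float:
    return math.pi * (dbh_cm / 2.0) ** 2


def compute_ivi(
    transects: Sequence[TransectRecord], habitat: Habitat | str
) -> list[IVIRecord]:
    """Importance value index of every species recorded in one habitat.

    relative density = share of stems; relative frequency = share of
    (transect, species) occurrences; relative dominance = share of total
    basal area, with basal area pi (dbh/2)^2 per stem.  IVI is the mean of
    the three components.
    """
    habitat = Habitat(habitat)
    sub = [t for t in transects if t.habitat is habitat]
    if not sub:
        raise ValueError(f"no transect trees for habitat {habitat.value!r}")
    species = sorted({t.species for t in sub})
    stems = {s: 0 for s in species}
    basal = {s: 0.0 for s in species}
    occur = {s: set() for s in species}
    for t in sub:
        stems[t.species] += 1
        basal[t.species] += _basal_area(t.dbh)
        occur[t.species].add((t.site_id, t.transect_id))
    n_stems = sum(stems.values())
    n_occ = sum(len(v) for v in occur.values())
    total_basal = sum(basal.values())
    out = []
    for s in species:
        rd = stems[s] / n_stems
        rf = len(occur[s]) / n_occ
        rdom = basal[s] / total_basal
        out.append(IVIRecord(s, rd, rf, rdom, (rd + rf + rdom) / 3.0))
    return sorted(out, key=lambda r: r.ivi, reverse=True)


def ivi_table(records: Iterable[IVIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "relative_density": r.relative_density,
                "relative_frequency": r.relative_frequency,
                "relative_dominance": r.relative_dominance,
                "ivi": r.ivi,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Similarity and Mantel


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard coefficient |A n B| / |A u B| between two species sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> StatTestResult:
    """Permutation Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the upper off-diagonal
    triangles.  Significance is two-tailed: the fraction of joint
    row/column permutations of the second matrix (the identity included in
    the count) whose |r| reaches |r_observed|.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share labels and order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m1 = np.asarray(d1.data, dtype=float)
    m2 = np.asarray(d2.data, dtype=float)
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = m1[iu]
    if x.std() == 0 or m2[iu].std() == 0:
        raise ValueError("zero variance in a distance triangle")
    xc = x - x.mean()
    xs = np.sqrt((xc**2).sum())

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        return float((xc * yc).sum() / (xs * np.sqrt((yc**2).sum())))

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(m2[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            count += 1
    return StatTestResult(
        statistic=r_obs,
        df=float(len(x) - 2),
        p_value=count / (n_perm + 1),
        transform_applied="none",
        name="mantel",
    )


# ---------------------------------------------------------------------------
# Transforms and t-tests


def arcsine_sqrt(p) -> np.ndarray:
    """Angular transform arcsin(sqrt(p)), radians; maps [0, 1] onto [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    return np.arcsin(np.sqrt(p))


_TRANSFORMS = {
    "none": lambda x: np.asarray(x, dtype=float),
    "log1p": lambda x: np.log1p(np.asarray(x, dtype=float)),
    "arcsine_sqrt": arcsine_sqrt,
}


def transformed_t_test(
    x_values: Sequence[float],
    y_values: Sequence[float],
    transform: str = "log1p",
) -> StatTestResult:
    """Two-sample Student t-test after a variance-stabilizing transform.

    ``log1p`` for counts/richness, ``arcsine_sqrt`` for proportions.
    Pooled-variance t with df = n1 + n2 - 2.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    x = _TRANSFORMS[transform](x_values)
    y = _TRANSFORMS[transform](y_values)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return StatTestResult(
        statistic=float(t),
        df=float(len(x) + len(y) - 2),
        p_value=float(p),
        transform_applied=transform,
        name="two-sample t",
    )


# ---------------------------------------------------------------------------
# Item-time fractions and nested ANOVA


def item_time_fractions(
    records: Sequence[ObservationRecord],
) -> pd.DataFrame:
    """Fraction of feeding time per plant item within each habitat.

    Returns a habitat x item table of time fractions; rows sum to 1.
    """
    rows = [
        {"habitat": r.habitat.value, "item": r.item.value, "duration": r.duration}
        for r in records
        if r.duration > 0
    ]
    if not rows:
        raise ValueError("no records with positive duration")
    frame = pd.DataFrame(rows)
    totals = frame.groupby("habitat")["duration"].sum()
    table = (
        frame.groupby(["habitat", "item"])["duration"].sum().unstack(fill_value=0.0)
    )
    return table.div(totals, axis=0)


def nested_anova(
    values: Sequence[float],
    habitat_factor: Sequence,
    item_factor: Sequence,
    transform: str = "arcsine_sqrt",
) -> tuple[StatTestResult, StatTestResult]:
    """Nested ANOVA of item-time fractions: plant item nested in habitat.

    Values (fractions in [0, 1]) are angular-transformed before fitting.
    The sums of squares decompose into habitat, item-within-habitat, and
    residual; both F ratios use the residual mean square as denominator
    (fixed-effects convention).  Returns (habitat test, item test), each
    with its (numerator, denominator) df pair.
    """
    y = _TRANSFORMS[transform](values)
    hab = np.asarray(habitat_factor)
    item = np.asarray(item_factor)
    if not (len(y) == len(hab) == len(item)):
        raise ValueError("values and factors must have equal length")
    n = len(y)
    grand = y.mean()

    hab_levels = pd.unique(hab)
    ss_hab = 0.0
    ss_item = 0.0
    ss_err = 0.0
    df_item = 0
    n_cells = 0
    for h in hab_levels:
        mh = hab == h
        yh = y[mh]
        ss_hab += len(yh) * (yh.mean() - grand) ** 2
        cells = pd.unique(item[mh])
        df_item += len(cells) - 1
        n_cells += len(cells)
        for it in cells:
            mc = mh & (item == it)
            yc = y[mc]
            if len(yc) < 1:
                raise ValueError("empty habitat x item cell")
            ss_item += len(yc) * (yc.mean() - yh.mean()) ** 2
            ss_err += ((yc - yc.mean()) ** 2).sum()

    df_hab = len(hab_levels) - 1
    df_err = n - n_cells
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom (one value per cell)")
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_hab = 0.0 if ss_hab == 0 else float("inf")
        f_item = 0.0 if ss_item == 0 else float("inf")
    else:
        f_hab = (ss_hab / df_hab) / ms_err if df_hab > 0 else float("nan")
        f_item = (ss_item / df_item) / ms_err if df_item > 0 else float("nan")
    p_hab = float(stats.f.sf(f_hab, df_hab, df_err)) if df_hab > 0 else float("nan")
    p_item = float(stats.f.sf(f_item, df_item, df_err)) if df_item > 0 else float("nan")
    return (
        StatTestResult(
            statistic=float(f_hab),
            df=(float(df_hab), float(df_err)),
            p_value=p_hab,
            transform_applied=transform,
            name="nested ANOVA: habitat",
        ),
        StatTestResult(
            statistic=float(f_item),
            df=(float(df_item), float(df_err)),
            p_value=p_item,
            transform_applied=transform,
            name="nested ANOVA: item within habitat",
        ),
    )
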