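"""Probabilistic null model and Monte-Carlo significance of nestedness.

The randomization scheme ("Null Model II") assigns each cell an occurrence
probability equal to the mean of its row's and its column's fill
proportions, so the probability of an interaction is proportional to the
generalism of both partners.  Expected marginal degrees are preserved;
exact degrees are not.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io_model import InteractionMatrix
from .network_metrics import nodf, _as_binary_array

__all__ = [
    "NullModelResult",
    "null2_probabilities",
    "sample_null2",
    "nestedness_test",
]


@dataclass(frozen=True)
class NullModelResult:
    """Observed nestedness against its Monte-Carlo null distribution.

    ``z_score`` is NaN when the null distribution is degenerate
    (zero standard deviation); ``p_value`` is the one-tailed fraction of
    null draws at least as nested as the observation.
    """

    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    n_randomizations: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def null2_probabilities(matrix: InteractionMatrix | np.ndarray) -> np.ndarray:
    """Cell probabilities p_ij = (k_i / C + k_j / R) / 2.

    k_i and k_j are the row and column degrees of the binary matrix; the
    probabilities lie in [0, 1] and sum exactly to the observed link count.
    """
    a = _as_binary_array(matrix)
    r, c = a.shape
    row_fill = a.sum(axis=1) / c
    col_fill = a.sum(axis=0) / r
    return (row_fill[:, None] + col_fill[None, :]) / 2.0


def sample_null2(
    probabilities: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One random binary matrix: independent Bernoulli draw per cell."""
    p = np.asarray(probabilities, dtype=float)
    if p.min(initial=0) < 0 or p.max(initial=0) > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(p.shape) < p).astype(int)


def nestedness_test(
    matrix: InteractionMatrix | np.ndarray,
    n: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    plus_one: bool = False,
    probabilities: np.ndarray | None = None,
) -> NullModelResult:
    """Monte-Carlo significance of NODF under the degree-proportional null.

    Draws ``n`` random matrices from the cell-probability model and reports
    the observed NODF, the null mean and SD, the z-score, and a one-tailed
    p-value ``count(null >= observed) / n`` (with ``plus_one=True`` the
    conservative ``(count + 1) / (n + 1)`` variant is used instead).

    By default the cell probabilities are estimated from the observed
    matrix's own degrees, as in routine analyses.  ``probabilities``
    overrides them with a known probability matrix; this makes the p-value
    exactly uniform when the observation really was drawn from that
    matrix, which is the basis of calibration experiments (re-estimating
    probabilities from data is only approximately calibrated, and runs
    anti-conservative for strongly heterogeneous degree sequences).

    Each sample uses its own spawned random substream, so enlarging ``n``
    extends the null sample without reshuffling earlier draws, and a fixed
    seed makes the whole result bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = _as_binary_array(matrix)
    observed = nodf(a)
    p = null2_probabilities(a) if probabilities is None else np.asarray(probabilities)
    if p.shape != a.shape:
        raise ValueError("probability matrix shape does not match the data")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    null = np.empty(n)
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        null[i] = nodf(sample_null2(p, rng))
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else float("nan")
    count = int((null >= observed).sum())
    p_value = (count + 1) / (n + 1) if plus_one else count / n
    seed_out = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    if not isinstance(seed_out, (int, type(None))):
        seed_out = None
    return NullModelResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z_score=z,
        p_value=float(p_value),
        n_randomizations=n,
        seed=seed_out,
    )
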