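"""k-nearest-neighbour imputation of missing log-IC50 entries.

Missing entries of the drug x sample response matrix are filled by a weighted
mean over the k drugs nearest to the target drug (default k=5). Distance
between two drug rows is the root mean squared difference over their
pairwise-complete samples — i.e. Euclidean distance corrected for the number
of shared observations — so drugs with different missingness patterns remain
comparable. Weights are inverse distances (1 / (d + epsilon)) renormalised to
sum to one; a ``uniform`` scheme is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for :func:`knn_impute_responses`.

    k: number of neighbour drugs (>= 1).
    weight_scheme: ``inverse_distance`` or ``uniform``.
    epsilon: additive guard against zero distances (> 0).
    """

    k: int = 5
    weight_scheme: str = "inverse_distance"
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.weight_scheme not in ("inverse_distance", "uniform"):
            raise ValidationError(
                "weight_scheme must be 'inverse_distance' or 'uniform'"
            )


def pairwise_drug_distances(values: np.ndarray) -> np.ndarray:
    """Scale-corrected Euclidean distances between drug rows.

    ``values`` is drugs x samples with NaN marking missing entries. Entry
    (i, j) is sqrt(mean((x_i - x_j)^2)) over samples observed in both rows;
    +inf where no sample is shared. The diagonal is set to +inf so a drug is
    never its own neighbour.
    """
    observed = np.isfinite(values)
    X = np.where(observed, values, 0.0)
    Xsq = X * X
    O = observed.astype(float)
    shared = O @ O.T
    # sum over shared s of (x_i - x_j)^2, expanded so masked terms vanish
    sumsq = Xsq @ O.T + O @ Xsq.T - 2.0 * (X @ X.T)
    sumsq = np.maximum(sumsq, 0.0)  # clip tiny negative round-off
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(sumsq / shared)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)
    return dist


def knn_impute_responses(
    ic: pd.DataFrame, cfg: ImputationConfig | None = None
) -> pd.DataFrame:
    """Fill NaN entries of a drug x sample response matrix by drug-wise kNN.

    Observed entries are returned unchanged. For each missing cell (d, s) the
    k drugs nearest to d that are observed at sample s contribute a weighted
    mean. Raises if a drug row is entirely missing, or if a missing cell has
    no observed candidate neighbour at its sample.
    """
    cfg = cfg or ImputationConfig()
    values = ic.to_numpy(dtype=float)
    observed = np.isfinite(values)

    empty_rows = ~observed.any(axis=1)
    if empty_rows.any():
        raise ValidationError(
            f"drug rows with no observed entries: {ic.index[empty_rows].tolist()}"
        )
    if observed.all():
        return ic.copy()

    dist = pairwise_drug_distances(values)
    out = values.copy()
    n_drugs = values.shape[0]
    short = 0
    for d, s in zip(*np.where(~observed)):
        candidates = np.flatnonzero(observed[:, s] & np.isfinite(dist[d]))
        if candidates.size == 0:
            raise ValidationError(
                f"missing cell (drug {ic.index[d]!r}, sample {ic.columns[s]!r}) "
                "has no observed neighbour drug at that sample"
            )
        order = np.lexsort((candidates, dist[d, candidates]))  # distance, then row order
        nearest = candidates[order[: cfg.k]]
        if nearest.size < cfg.k:
            short += 1
        if cfg.weight_scheme == "uniform":
            weights = np.ones(nearest.size)
        else:
            weights = 1.0 / (dist[d, nearest] + cfg.epsilon)
        weights = weights / weights.sum()
        out[d, s] = float(weights @ values[nearest, s])
    if short:
        logger.warning(
            "%d cells had fewer than k=%d valid neighbours; used all available",
            short,
            cfg.k,
        )
    if n_drugs - 1 < cfg.k:
        logger.warning("k=%d exceeds the %d available neighbour drugs", cfg.k, n_drugs - 1)
    return pd.DataFrame(out, index=ic.index, columns=ic.columns)
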