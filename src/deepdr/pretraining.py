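"""Autoencoder pre-training on a large omics corpus.

A symmetric autoencoder (encoder widths w1 > w2 > bottleneck, decoder the
exact mirror, ReLU throughout with a linear reconstruction output) is trained
per omics type on the corpus. Architecture and batch size are chosen by an
exhaustive grid: every candidate is trained for a short screening run
(20 epochs), the best reconstruction error wins, and the winner is re-trained
from a fresh init for the long run (100 epochs). The encoder half (input ->
bottleneck) is what downstream models transplant.

The default grid is the full production grid — first layer {4096, 2048, 1024},
second {512, 256, 128}, bottleneck {64, 32, 16}, batch size {128, 64}: 54
candidates. Desk-scale runs pass a smaller grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .neural_core import MLPParams, TrainConfig, forward, he_uniform_init, mse, train_mse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchGrid:
    """Candidate widths and batch sizes for the architecture screen."""

    layer1_widths: tuple[int, ...] = (4096, 2048, 1024)
    layer2_widths: tuple[int, ...] = (512, 256, 128)
    bottleneck_widths: tuple[int, ...] = (64, 32, 16)
    batch_sizes: tuple[int, ...] = (128, 64)
    screen_epochs: int = 20
    refit_epochs: int = 100

    def __post_init__(self) -> None:
        for name in ("layer1_widths", "layer2_widths", "bottleneck_widths", "batch_sizes"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")

    def combinations(self):
        """Yield (widths, batch_size) over the full cartesian product."""
        for w1, w2, bn, bs in itertools.product(
            self.layer1_widths, self.layer2_widths, self.bottleneck_widths, self.batch_sizes
        ):
            yield (w1, w2, bn), bs

    @property
    def size(self) -> int:
        return (
            len(self.layer1_widths)
            * len(self.layer2_widths)
            * len(self.bottleneck_widths)
            * len(self.batch_sizes)
        )


#: Desk-scale counterpart of the production grid: one architecture sized for
#: a few-hundred-gene corpus, screened and refit with the same 20-epoch /
#: long-refit protocol. The first layer stays at roughly twice the supervised
#: training-sample count, preserving the over-parameterized regime of the
#: production setup. Used by the bundled experiments and the CLI examples.
DESK_GRID = SearchGrid(
    layer1_widths=(512,),
    layer2_widths=(64,),
    bottleneck_widths=(16,),
    batch_sizes=(64,),
    screen_epochs=20,
    refit_epochs=200,
)

#: Optimizer settings for desk-scale pre-training. The slightly raised
#: learning rate compensates for the small corpus (uncentered non-negative
#: inputs make the reconstruction objective slow to traverse at 1e-3).
DESK_PRETRAIN_CFG = TrainConfig(learning_rate=3e-3, batch_size=64)


def pretrain_encoders(
    corpus_mutation,
    corpus_expression,
    seed: int,
    grid: SearchGrid | None = None,
    train_cfg: TrainConfig | None = None,
    refit_restarts: tuple[int, int] = (2, 4),
) -> tuple[MLPParams, MLPParams]:
    """Pre-train both omics encoders on a corpus (gene x sample DataFrames).

    Convenience wrapper running :func:`grid_search_autoencoder` per omics with
    seed-derived sub-seeds; returns ``(mutation_encoder, expression_encoder)``.
    ``refit_restarts`` is (mutation, expression); the sparse binary mutation
    matrix has a flat reconstruction landscape and needs fewer restarts.
    """
    grid = grid or DESK_GRID
    train_cfg = train_cfg or DESK_PRETRAIN_CFG
    rng = np.random.default_rng(seed)
    res_m = grid_search_autoencoder(
        np.asarray(corpus_mutation, dtype=float).T, grid,
        seed=int(rng.integers(2**31)), train_cfg=train_cfg,
        refit_restarts=refit_restarts[0],
    )
    res_e = grid_search_autoencoder(
        np.asarray(corpus_expression, dtype=float).T, grid,
        seed=int(rng.integers(2**31)), train_cfg=train_cfg,
        refit_restarts=refit_restarts[1],
    )
    return res_m.encoder, res_e.encoder


def autoencoder_dims(input_dim: int, widths: tuple[int, int, int]) -> list[int]:
    """Full symmetric chain [input, w1, w2, bottleneck, w2, w1, input]."""
    w1, w2, bn = widths
    return [input_dim, w1, w2, bn, w2, w1, input_dim]


def build_autoencoder(
    input_dim: int, widths: tuple[int, int, int], seed: int = 0
) -> MLPParams:
    """He-uniform-initialised symmetric autoencoder.

    ReLU on all layers except the linear reconstruction output. Warns when the
    bottleneck is at least as wide as the input (no compression).
    """
    if any(w < 1 for w in widths) or input_dim < 1:
        raise ValidationError("widths and input_dim must be positive")
    if widths[2] >= input_dim:
        logger.warning(
            "bottleneck width %d >= input dim %d: degenerate compression",
            widths[2],
            input_dim,
        )
    dims = autoencoder_dims(input_dim, widths)
    activations = ["relu"] * (len(dims) - 2) + ["linear"]
    return he_uniform_init(dims, seed, activations)


def split_encoder(autoencoder: MLPParams) -> MLPParams:
    """Extract the encoder half (first three layers: input -> bottleneck)."""
    n_half = len(autoencoder.layers) // 2
    return MLPParams([l for l in autoencoder.copy().layers[:n_half]])


def encode(encoder: MLPParams, X: np.ndarray) -> np.ndarray:
    """Bottleneck representation of a samples x features batch."""
    return forward(encoder, X)


@dataclass
class GridSearchResult:
    best_widths: tuple[int, int, int]
    best_batch_size: int
    encoder: MLPParams
    autoencoder: MLPParams
    log: pd.DataFrame = field(repr=False)
    refit_loss: float = float("nan")


def _param_count(input_dim: int, widths: tuple[int, int, int]) -> int:
    dims = autoencoder_dims(input_dim, widths)
    return sum(fi * fo + fo for fi, fo in zip(dims, dims[1:]))


def grid_search_autoencoder(
    corpus: np.ndarray,
    grid: SearchGrid,
    seed: int,
    holdout_fraction: float = 0.1,
    select_on: str = "holdout",
    train_cfg: TrainConfig | None = None,
    refit_restarts: int = 1,
) -> GridSearchResult:
    """Exhaustive architecture screen followed by a long refit of the winner.

    ``corpus`` is samples x features. Each grid combination is trained for
    ``grid.screen_epochs``; the selection criterion is reconstruction MSE on a
    held-out ``holdout_fraction`` slice (``select_on="train"`` evaluates on the
    training slice instead). Ties break toward the smaller parameter count,
    then lexicographically smaller widths. The winner is re-trained for
    ``grid.refit_epochs`` from a fresh seed-derived init and its encoder half
    returned.

    Deep reconstruction nets occasionally settle into poor basins from an
    unlucky init; ``refit_restarts`` > 1 re-runs the refit from that many
    fresh inits and keeps the lowest evaluated reconstruction loss.
    """
    if refit_restarts < 1:
        raise ValidationError("refit_restarts must be >= 1")
    corpus = np.atleast_2d(np.asarray(corpus, dtype=float))
    if corpus.shape[0] < 2:
        raise ValidationError("corpus needs at least 2 samples")
    if select_on not in ("holdout", "train"):
        raise ValidationError("select_on must be 'holdout' or 'train'")
    if grid.size == 0:
        raise ValidationError("empty search grid")

    base_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    n = corpus.shape[0]
    n_holdout = max(1, int(round(holdout_fraction * n))) if select_on == "holdout" else 0
    order = rng.permutation(n)
    holdout_idx, train_idx = order[:n_holdout], order[n_holdout:]
    X_train = corpus[train_idx]
    X_eval = corpus[holdout_idx] if select_on == "holdout" else X_train

    input_dim = corpus.shape[1]
    rows = []
    for i, (widths, batch_size) in enumerate(grid.combinations()):
        init_seed = int(rng.integers(2**31))
        ae = build_autoencoder(input_dim, widths, seed=init_seed)
        cfg = replace(
            base_cfg,
            batch_size=batch_size,
            max_epochs=grid.screen_epochs,
            patience=None,
            seed=int(rng.integers(2**31)),
        )
        trained, _ = train_mse(ae, X_train, X_train, cfg)
        loss = mse(forward(trained, X_eval), X_eval)
        rows.append(
            {
                "layer1": widths[0],
                "layer2": widths[1],
                "bottleneck": widths[2],
                "batch_size": batch_size,
                "screen_loss": loss,
                "n_params": _param_count(input_dim, widths),
            }
        )
    log = pd.DataFrame(rows)
    ranked = log.sort_values(
        ["screen_loss", "n_params", "layer1", "layer2", "bottleneck", "batch_size"],
        kind="stable",
    )
    best = ranked.iloc[0]
    best_widths = (int(best["layer1"]), int(best["layer2"]), int(best["bottleneck"]))
    best_batch = int(best["batch_size"])

    refit, refit_loss = None, np.inf
    for _ in range(refit_restarts):
        ae = build_autoencoder(input_dim, best_widths, seed=int(rng.integers(2**31)))
        cfg = replace(
            base_cfg,
            batch_size=best_batch,
            max_epochs=grid.refit_epochs,
            patience=None,
            seed=int(rng.integers(2**31)),
        )
        candidate, _ = train_mse(ae, X_train, X_train, cfg)
        loss = mse(forward(candidate, X_eval), X_eval)
        if loss < refit_loss:
            refit, refit_loss = candidate, loss
    return GridSearchResult(
        best_widths=best_widths,
        best_batch_size=best_batch,
        encoder=split_encoder(refit),
        autoencoder=refit,
        log=log,
        refit_loss=refit_loss,
    )
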