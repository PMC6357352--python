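"""The complete drug-response prediction model and its comparison benchmark.

Two pre-trained omics encoders (mutation, expression) feed a prediction head
P with dims [64+64, 128, 128, 128, D] (ReLU hidden, linear output producing
log10 IC50 for D drugs). The encoders arrive with corpus-pre-trained
parameters and stay trainable; P is freshly He-uniform initialized. Training
is joint and end-to-end on an 80/10/10 sample split, with patience-based
early stopping on the validation slice and metrics reported on the test
slice.

``run_benchmark`` repeats the published comparison protocol: the pre-trained model
against a randomly initialized twin, PCA-projection encoders, single-omics
variants, multivariate linear regression and per-drug support-vector
regression on merged principal components, across fresh random splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

from .exceptions import ValidationError
from .neural_core import (
    Adam,
    EarlyStopping,
    MLPParams,
    TrainConfig,
    TrainHistory,
    backward,
    forward,
    forward_cached,
    he_uniform_init,
    mse,
)

logger = logging.getLogger(__name__)

#: Desk-scale prediction-head widths and joint-training settings, matched to
#: the 16+16 bottlenecks of :data:`deepdr.pretraining.DESK_GRID`.
DESK_HEAD_HIDDEN = (64, 64, 64)
DESK_TRAIN_CFG = TrainConfig(max_epochs=100, patience=3, batch_size=64)

BENCHMARK_MODELS = (
    "deepdr",
    "random_init",
    "pca_encoders",
    "eenc_only",
    "menc_only",
    "linear_regression",
    "svm_per_drug",
)


@dataclass
class DeepDRModel:
    """Mutation encoder + expression encoder + prediction head.

    Either encoder may be None (single-omics variants); the head's input width
    must equal the sum of the present bottleneck widths. Optional gene id
    lists let prediction validate feature alignment by name.
    """

    menc: MLPParams | None
    eenc: MLPParams | None
    head: MLPParams
    mut_genes: list[str] | None = None
    expr_genes: list[str] | None = None
    drug_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.menc is None and self.eenc is None:
            raise ValidationError("at least one encoder is required")
        width = sum(e.output_dim for e in (self.menc, self.eenc) if e is not None)
        if self.head.input_dim != width:
            raise ValidationError(
                f"head input {self.head.input_dim} != concatenated bottleneck {width}"
            )

    @property
    def n_drugs(self) -> int:
        return self.head.output_dim

    def n_params(self) -> int:
        return sum(
            p.n_params() for p in (self.menc, self.eenc, self.head) if p is not None
        )

    def _branches(self) -> list[MLPParams]:
        return [e for e in (self.menc, self.eenc) if e is not None]


def assemble_model(
    menc: MLPParams | None,
    eenc: MLPParams | None,
    n_drugs: int,
    seed: int,
    head_hidden: tuple[int, ...] = (128, 128, 128),
    mut_genes: list[str] | None = None,
    expr_genes: list[str] | None = None,
    drug_ids: list[str] | None = None,
) -> DeepDRModel:
    """Transplant the encoders (copied) and attach a freshly initialized head."""
    if n_drugs <= 0:
        raise ValidationError("n_drugs must be positive")
    encoders = [e for e in (menc, eenc) if e is not None]
    if not encoders:
        raise ValidationError("at least one encoder is required")
    fan_in = sum(e.output_dim for e in encoders)
    head_dims = [fan_in, *head_hidden, n_drugs]
    head = he_uniform_init(head_dims, seed, ["relu"] * len(head_hidden) + ["linear"])
    return DeepDRModel(
        menc=menc.copy() if menc is not None else None,
        eenc=eenc.copy() if eenc is not None else None,
        head=head,
        mut_genes=list(mut_genes) if mut_genes is not None else None,
        expr_genes=list(expr_genes) if expr_genes is not None else None,
        drug_ids=list(drug_ids) if drug_ids is not None else None,
    )


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test sample-id partitions."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if not all(sets):
            raise ValidationError("every split set must be non-empty")
        total = len(self.train) + len(self.val) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValidationError("split sets overlap or contain duplicates")


def split_samples(
    sample_ids,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Random train/validation/test partition.

    Validation and test sizes are round(fraction * n); the remainder goes to
    training. Deterministic given ``seed``.
    """
    ids = [str(s) for s in sample_ids]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    n = len(ids)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError(
            f"split sizes ({n_train}, {n_val}, {n_test}) must all be >= 1"
        )
    perm = np.random.default_rng(seed).permutation(n)
    test = tuple(ids[i] for i in perm[:n_test])
    val = tuple(ids[i] for i in perm[n_test : n_test + n_val])
    train = tuple(ids[i] for i in perm[n_test + n_val :])
    return SplitAssignment(train=train, val=val, test=test, seed=seed)


@dataclass
class MetricsReport:
    """Overall MSE plus per-sample Pearson/Spearman correlations across drugs."""

    mse: float
    pearson: pd.Series
    spearman: pd.Series
    epochs: int = 0


def _sample_arrays(
    M: pd.DataFrame | None, E: pd.DataFrame | None, ids
) -> list[np.ndarray]:
    ids = list(ids)
    out = []
    if M is not None:
        out.append(M.loc[:, ids].to_numpy(dtype=float).T)
    if E is not None:
        out.append(E.loc[:, ids].to_numpy(dtype=float).T)
    return out


def _predict_arrays(model: DeepDRModel, Xs: list[np.ndarray]) -> np.ndarray:
    hs = [forward(enc, X) for enc, X in zip(model._branches(), Xs)]
    return forward(model.head, np.concatenate(hs, axis=1))


def _joint_train(
    model: DeepDRModel,
    Xs: list[np.ndarray],
    Y: np.ndarray,
    cfg: TrainConfig,
    validation: tuple[list[np.ndarray], np.ndarray] | None = None,
) -> TrainHistory:
    """End-to-end mini-batch Adam over the encoder branches and the head.

    Modifies ``model`` in place and returns the loss history. Mirrors
    :func:`deepdr.neural_core.train_mse` but backpropagates through the
    concatenation of encoder outputs.
    """
    nets = model._branches() + [model.head]
    widths = [enc.output_dim for enc in model._branches()]
    arrays = [a for net in nets for layer in net.layers for a in (layer.W, layer.b)]
    adam = Adam(cfg)
    rng = np.random.default_rng(cfg.seed)
    stopper = (
        EarlyStopping(cfg.patience) if (cfg.patience and validation is not None) else None
    )
    history = TrainHistory()
    n = Y.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            hs, caches = [], []
            for enc, X in zip(model._branches(), Xs):
                h, c = forward_cached(enc, X[idx])
                hs.append(h)
                caches.append(c)
            H = np.concatenate(hs, axis=1)
            pred, head_cache = forward_cached(model.head, H)
            grad = (2.0 / pred.size) * (pred - Y[idx])
            head_grads, gH = backward(model.head, head_cache, grad)
            flat = []
            offset = 0
            for enc, c, w in zip(model._branches(), caches, widths):
                enc_grads, _ = backward(enc, c, gH[:, offset : offset + w])
                offset += w
                flat.extend(g for pair in enc_grads for g in pair)
            flat.extend(g for pair in head_grads for g in pair)
            adam.step(arrays, flat)
        history.train_loss.append(mse(_predict_arrays(model, Xs), Y))
        history.stopped_epoch = epoch
        if validation is not None:
            val_loss = mse(_predict_arrays(model, validation[0]), validation[1])
            history.val_loss.append(val_loss)
            if stopper is not None and stopper.update(val_loss, epoch):
                break
    return history


def train_deepdr(
    model: DeepDRModel,
    M: pd.DataFrame | None,
    E: pd.DataFrame | None,
    IC: pd.DataFrame,
    split: SplitAssignment,
    cfg: TrainConfig,
) -> tuple[DeepDRModel, MetricsReport]:
    """Train end-to-end on the train split; early-stop on validation; score on test.

    ``M``/``E`` are gene x sample, ``IC`` drug x sample with no missing
    entries (impute first). Test rows never touch the parameters.
    """
    if IC.isna().any().any():
        raise ValidationError("IC contains missing entries; run imputation first")
    for name, df in (("M", M), ("E", E)):
        if df is not None and list(df.columns) != list(IC.columns):
            if set(df.columns) != set(IC.columns):
                raise ValidationError(f"{name} and IC sample ids differ")
    Y = IC.T
    Xs_train = _sample_arrays(M, E, split.train)
    Xs_val = _sample_arrays(M, E, split.val)
    Xs_test = _sample_arrays(M, E, split.test)
    Y_train = Y.loc[list(split.train)].to_numpy(dtype=float)
    Y_val = Y.loc[list(split.val)].to_numpy(dtype=float)

    history = _joint_train(model, Xs_train, Y_train, cfg, validation=(Xs_val, Y_val))
    pred_test = _predict_arrays(model, Xs_test)
    pred_df = pd.DataFrame(pred_test.T, index=IC.index, columns=list(split.test))
    report = compute_metrics(pred_df, IC.loc[:, list(split.test)])
    report.epochs = history.stopped_epoch
    return model, report


def predict_ic50(
    model: DeepDRModel, M: pd.DataFrame | None, E: pd.DataFrame | None
) -> pd.DataFrame:
    """Predict the full drug x sample response matrix for new profiles."""
    pairs = []
    if model.menc is not None:
        if M is None:
            raise ValidationError("model has a mutation encoder but M is None")
        pairs.append(("mutation", M, model.menc, model.mut_genes))
    if model.eenc is not None:
        if E is None:
            raise ValidationError("model has an expression encoder but E is None")
        pairs.append(("expression", E, model.eenc, model.expr_genes))
    samples = pairs[0][1].columns
    for name, df, enc, genes in pairs:
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise ValidationError(
                    f"{name} matrix lacks {len(missing)} model genes "
                    f"(e.g. {missing[:5]})"
                )
        if df.shape[0] != enc.input_dim:
            raise ValidationError(
                f"{name} matrix has {df.shape[0]} genes; encoder expects {enc.input_dim}"
            )
        if list(df.columns) != list(samples):
            raise ValidationError("mutation and expression sample ids differ")
    Xs = []
    for name, df, enc, genes in pairs:
        aligned = df.loc[genes] if genes is not None else df
        Xs.append(aligned.to_numpy(dtype=float).T)
    pred = _predict_arrays(model, Xs)
    drug_ids = model.drug_ids or [f"drug_{i}" for i in range(model.n_drugs)]
    if len(drug_ids) != model.n_drugs:
        raise ValidationError("model drug_ids length does not match head output")
    return pd.DataFrame(pred.T, index=pd.Index(drug_ids, name="drug"), columns=samples)


def compute_metrics(pred: pd.DataFrame, truth: pd.DataFrame) -> MetricsReport:
    """Overall MSE plus per-sample Pearson/Spearman across the drug axis.

    Samples whose prediction or truth vector has zero variance get NaN
    correlations (with a warning).
    """
    if pred.shape != truth.shape or list(pred.columns) != list(truth.columns):
        raise ValidationError("pred and truth must be aligned drug x sample matrices")
    P = pred.to_numpy(dtype=float)
    T = truth.to_numpy(dtype=float)
    overall = mse(P, T)
    pearson, spearman = [], []
    degenerate = 0
    for j in range(P.shape[1]):
        p, t = P[:, j], T[:, j]
        if np.std(p) == 0 or np.std(t) == 0:
            degenerate += 1
            pearson.append(np.nan)
            spearman.append(np.nan)
            continue
        pearson.append(stats.pearsonr(p, t)[0])
        spearman.append(stats.spearmanr(p, t)[0])
    if degenerate:
        logger.warning("%d samples had zero-variance vectors; correlations set to NaN", degenerate)
    cols = pred.columns
    return MetricsReport(
        mse=overall,
        pearson=pd.Series(pearson, index=cols, name="pearson"),
        spearman=pd.Series(spearman, index=cols, name="spearman"),
    )


@dataclass
class PCAProjector:
    """Centering vector + top-k loading matrix fitted on training samples."""

    mean_: np.ndarray
    components_: np.ndarray  # k x features

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) @ self.components_ + self.mean_


def pca_encoder(X_train: np.ndarray, n_components: int = 64) -> PCAProjector:
    """Fit a PCA projection (training samples only) as a fixed linear encoder."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if n_components > min(X_train.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds data dims {X_train.shape}"
        )
    centered = X_train - X_train.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if n_components > rank:
        raise ValidationError(f"n_components={n_components} exceeds data rank {rank}")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full").fit(X_train)
    return PCAProjector(mean_=pca.mean_, components_=pca.components_)


@dataclass
class BenchmarkTable:
    """Per-iteration test MSEs/epochs for each model, plus median summaries."""

    per_iteration: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return (
            self.per_iteration.groupby("model")[["test_mse", "epochs"]]
            .median()
            .rename(columns={"test_mse": "median_test_mse", "epochs": "median_epochs"})
        )

    def median_mse(self, model: str) -> float:
        rows = self.per_iteration[self.per_iteration["model"] == model]
        return float(rows["test_mse"].median())


def save_model(model: DeepDRModel, out_dir) -> None:
    """Persist a model as per-subnetwork npz archives plus a JSON manifest."""
    import json
    from pathlib import Path

    from .neural_core import save_params

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parts = {}
    for name, params in (("menc", model.menc), ("eenc", model.eenc), ("head", model.head)):
        if params is not None:
            save_params(params, out / f"{name}.npz")
            parts[name] = f"{name}.npz"
    manifest = {
        "parts": parts,
        "mut_genes": model.mut_genes,
        "expr_genes": model.expr_genes,
        "drug_ids": model.drug_ids,
    }
    (out / "model.json").write_text(json.dumps(manifest))


def load_model(model_dir) -> DeepDRModel:
    import json
    from pathlib import Path

    from .neural_core import load_params

    path = Path(model_dir)
    manifest = json.loads((path / "model.json").read_text())
    parts = {name: load_params(path / fn) for name, fn in manifest["parts"].items()}
    return DeepDRModel(
        menc=parts.get("menc"),
        eenc=parts.get("eenc"),
        head=parts["head"],
        mut_genes=manifest.get("mut_genes"),
        expr_genes=manifest.get("expr_genes"),
        drug_ids=manifest.get("drug_ids"),
    )


def _head_only_model(n_features: int, n_drugs: int, head_hidden, seed: int) -> MLPParams:
    dims = [n_features, *head_hidden, n_drugs]
    return he_uniform_init(dims, seed, ["relu"] * len(head_hidden) + ["linear"])


def run_benchmark(
    M: pd.DataFrame,
    E: pd.DataFrame,
    IC: pd.DataFrame,
    menc: MLPParams,
    eenc: MLPParams,
    n_iter: int = 100,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    head_hidden: tuple[int, ...] = (128, 128, 128),
    pca_components: int = 64,
    svr_params: dict | None = None,
    models: tuple[str, ...] = BENCHMARK_MODELS,
) -> BenchmarkTable:
    """Compare the pre-trained model with its baselines over random splits.

    Each iteration draws a fresh 80/10/10 split and trains/evaluates every
    requested model on it: the pre-trained network, a randomly initialized
    twin, PCA-projection encoders feeding the same head, single-omics
    variants, multivariate linear regression and one RBF support-vector
    regressor per drug on the merged principal components.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    unknown = set(models) - set(BENCHMARK_MODELS)
    if unknown:
        raise ValidationError(f"unknown benchmark models: {sorted(unknown)}")
    base_cfg = train_cfg or TrainConfig(patience=3)
    svr_params = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1, **(svr_params or {})}
    rng = np.random.default_rng(seed)
    D = IC.shape[0]
    rows = []

    for it in range(n_iter):
        split = split_samples(IC.columns, seed=int(rng.integers(2**31)))
        cfg = replace(base_cfg, seed=int(rng.integers(2**31)))
        init_seed = int(rng.integers(2**31))

        def nn_eval(model_name: str, model: DeepDRModel, use_m=True, use_e=True):
            _, report = train_deepdr(
                model, M if use_m else None, E if use_e else None, IC, split, cfg
            )
            rows.append(
                {"model": model_name, "iteration": it, "test_mse": report.mse,
                 "epochs": report.epochs}
            )

        if "deepdr" in models:
            nn_eval("deepdr", assemble_model(menc, eenc, D, init_seed, head_hidden))
        if "random_init" in models:
            rand_m = he_uniform_init(menc.dims, int(rng.integers(2**31)))
            rand_e = he_uniform_init(eenc.dims, int(rng.integers(2**31)))
            nn_eval("random_init", assemble_model(rand_m, rand_e, D, init_seed, head_hidden))
        if "eenc_only" in models:
            nn_eval(
                "eenc_only",
                assemble_model(None, eenc, D, init_seed, head_hidden),
                use_m=False,
            )
        if "menc_only" in models:
            nn_eval(
                "menc_only",
                assemble_model(menc, None, D, init_seed, head_hidden),
                use_e=False,
            )

        needs_pca = {"pca_encoders", "linear_regression", "svm_per_drug"} & set(models)
        if needs_pca:
            Xm_tr = _sample_arrays(M, None, split.train)[0]
            Xe_tr = _sample_arrays(None, E, split.train)[0]
            k = min(pca_components, min(Xm_tr.shape) - 1, min(Xe_tr.shape) - 1)
            if k < pca_components:
                logger.warning("pca_components capped at %d by data dims", k)
            proj_m = pca_encoder(Xm_tr, k)
            proj_e = pca_encoder(Xe_tr, k)

            def merged(ids):
                Xm, Xe = _sample_arrays(M, E, ids)
                return np.concatenate([proj_m.transform(Xm), proj_e.transform(Xe)], axis=1)

            Z_train, Z_val, Z_test = merged(split.train), merged(split.val), merged(split.test)
            Y = IC.T
            Y_train = Y.loc[list(split.train)].to_numpy(dtype=float)
            Y_val = Y.loc[list(split.val)].to_numpy(dtype=float)
            Y_test = Y.loc[list(split.test)].to_numpy(dtype=float)

            if "pca_encoders" in models:
                from .neural_core import train_mse as _train_mse

                head = _head_only_model(2 * k, D, head_hidden, init_seed)
                head, hist = _train_mse(head, Z_train, Y_train, cfg, validation=(Z_val, Y_val))
                rows.append(
                    {"model": "pca_encoders", "iteration": it,
                     "test_mse": mse(forward(head, Z_test), Y_test),
                     "epochs": hist.stopped_epoch}
                )
            if "linear_regression" in models:
                reg = LinearRegression().fit(Z_train, Y_train)
                rows.append(
                    {"model": "linear_regression", "iteration": it,
                     "test_mse": mse(reg.predict(Z_test), Y_test), "epochs": np.nan}
                )
            if "svm_per_drug" in models:
                preds = np.empty_like(Y_test)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for d in range(D):
                        svr = SVR(**svr_params).fit(Z_train, Y_train[:, d])
                        preds[:, d] = svr.predict(Z_test)
                rows.append(
                    {"model": "svm_per_drug", "iteration": it,
                     "test_mse": mse(preds, Y_test), "epochs": np.nan}
                )
    return BenchmarkTable(per_iteration=pd.DataFrame(rows))
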