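"""Feed-forward age prediction from expression profiles.

A small fully-connected network (hidden widths 4 and 2, one linear output)
is trained with a mean-absolute-error loss and an L2 weight penalty
(lambda = 7.3e-5) to map a gene-expression profile to developmental age in
minutes.  Inputs are log2(x+1)-transformed and standardized with
training-set statistics only.  Includes the evaluation protocol: repeated
~90/10 splits, shuffled-prediction controls, random feature-count sweeps,
representative-marker evaluation and small-subset search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix

__all__ = [
    "AgeModelConfig",
    "MLPAgeRegressor",
    "AgeModelReport",
    "fit_age_model",
    "evaluate_trial",
    "shuffled_control",
    "run_trials",
    "feature_sweep",
    "marker_eval",
    "subset_search",
    "log_standardize",
]


@dataclass
class AgeModelConfig:
    hidden: tuple[int, ...] = (4, 2)
    l2: float = 7.3e-5
    train_fraction: float = 0.9
    trials: int = 100
    learning_rate: float = 0.02
    max_iter: int = 2500
    tol: float = 1e-6
    activation: str = "leaky_relu"
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def log_standardize(
    train: np.ndarray, *others: np.ndarray
) -> tuple[np.ndarray, ...]:
    """log2(x+1) then per-feature standardization by training statistics.

    Features constant in the training set are scaled by 1 (left centered),
    preventing division by zero and test-set leakage alike.
    """
    lt = np.log2(np.asarray(train, float) + 1.0)
    mu = lt.mean(axis=0)
    sd = lt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out = [(lt - mu) / sd]
    for o in others:
        out.append((np.log2(np.asarray(o, float) + 1.0) - mu) / sd)
    return tuple(out)


class MLPAgeRegressor:
    """Small MLP regressor: MAE loss + L2 weight penalty, full-batch Adam.

    Deterministic given (architecture, seed, data).  Weights are stored as
    plain arrays so the model serializes to JSON.
    """

    def __init__(
        self,
        hidden: tuple[int, ...] = (4, 2),
        l2: float = 7.3e-5,
        learning_rate: float = 0.02,
        max_iter: int = 2500,
        tol: float = 1e-6,
        seed: int = 0,
    ) -> None:
        self.hidden = tuple(hidden)
        self.l2 = l2
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.hidden, 1]
        W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        return W, b

    #: leaky-rectifier slope; keeps narrow hidden layers from dying entirely
    _LEAK = 0.01

    def _forward(self, X, W, b):
        acts = [X]
        h = X
        for i in range(len(W) - 1):
            z = h @ W[i] + b[i]
            h = np.where(z > 0, z, self._LEAK * z)
            acts.append(h)
        acts.append(h @ W[-1] + b[-1])
        return acts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPAgeRegressor":
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        if np.ptp(y) == 0:
            raise ValueError("degenerate training target: all ages equal")
        n = len(y)
        self._y_mu = float(y.mean())
        self._y_sd = float(y.std())
        yz = (y - self._y_mu) / self._y_sd

        rng = np.random.default_rng(self.seed)
        W, b = self._init_params(X.shape[1], rng)
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        prev_loss = np.inf
        for it in range(1, self.max_iter + 1):
            acts = self._forward(X, W, b)
            pred = acts[-1].ravel()
            err = pred - yz
            loss = np.abs(err).mean() + self.l2 * sum((w**2).sum() for w in W)
            if abs(prev_loss - loss) < self.tol:
                break
            prev_loss = loss
            delta = (np.sign(err) / n)[:, None]
            gW, gb = [], []
            for i in range(len(W) - 1, -1, -1):
                gW.insert(0, acts[i].T @ delta + 2 * self.l2 * W[i])
                gb.insert(0, delta.sum(axis=0))
                if i > 0:
                    delta = (delta @ W[i].T) * np.where(acts[i] > 0, 1.0, self._LEAK)
            for i in range(len(W)):
                for g, p, m, v in ((gW[i], W[i], mW[i], vW[i]), (gb[i], b[i], mb[i], vb[i])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    mhat = m / (1 - beta1**it)
                    vhat = v / (1 - beta2**it)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        self.weights_, self.biases_ = W, b
        self.train_loss_ = float(prev_loss)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        out = self._forward(np.asarray(X, float), self.weights_, self.biases_)[-1].ravel()
        return out * self._y_sd + self._y_mu

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        blob = {
            "hidden": list(self.hidden),
            "l2": self.l2,
            "y_mu": self._y_mu,
            "y_sd": self._y_sd,
            "weights": [w.tolist() for w in self.weights_],
            "biases": [x.tolist() for x in self.biases_],
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPAgeRegressor":
        blob = json.loads(Path(path).read_text())
        model = cls(hidden=tuple(blob["hidden"]), l2=blob["l2"])
        model.weights_ = [np.asarray(w) for w in blob["weights"]]
        model.biases_ = [np.asarray(x) for x in blob["biases"]]
        model._y_mu = blob["y_mu"]
        model._y_sd = blob["y_sd"]
        return model


# ---------------------------------------------------------------------------
# trial protocol


#: normalized training loss above which a fit is considered collapsed
#: (a constant predictor scores ~0.8 on standardized targets)
_COLLAPSE_LOSS = 0.55


def fit_age_model(
    train_X: np.ndarray, train_ages: np.ndarray, config: AgeModelConfig, seed: int = 0
) -> MLPAgeRegressor:
    """Fit the network on pre-transformed training features.

    The narrow architecture occasionally lands in a dead-unit optimum; up
    to ``config.n_restarts`` deterministic re-initializations are tried and
    the lowest-training-loss model kept.
    """
    if len(train_ages) < 10:
        raise ValueError("need at least 10 training samples")
    best = None
    for attempt in range(max(1, config.n_restarts)):
        model = MLPAgeRegressor(
            hidden=config.hidden,
            l2=config.l2,
            learning_rate=config.learning_rate,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=seed + 1_000_003 * attempt,
        ).fit(train_X, train_ages)
        if best is None or model.train_loss_ < best.train_loss_:
            best = model
        if best.train_loss_ < _COLLAPSE_LOSS:
            break
    return best


def evaluate_trial(
    model: MLPAgeRegressor, test_X: np.ndarray, test_ages: np.ndarray
) -> tuple[float, np.ndarray]:
    """MAE (minutes) and per-sample predictions over the test set."""
    if len(test_ages) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test_X)
    return float(np.abs(pred - np.asarray(test_ages, float)).mean()), pred


def shuffled_control(
    predictions: np.ndarray, true_ages: np.ndarray, seed: int = 0
) -> float:
    """MAE after permuting the predictions against the true ages."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(predictions))
    return float(np.abs(np.asarray(predictions)[perm] - np.asarray(true_ages)).mean())


@dataclass
class AgeModelReport:
    """Per-trial evaluation records plus any sweep summary."""

    trials: pd.DataFrame  # columns: label, trial, n_features, mae, shuffled_mae
    sweep: pd.DataFrame | None = None  # columns: n_features, mean_mae, mean_shuffled_mae

    def mean_mae(self, label: str | None = None) -> float:
        t = self.trials if label is None else self.trials[self.trials["label"] == label]
        return float(t["mae"].mean())


def _split_indices(n: int, train_fraction: float, rng: np.random.Generator):
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def run_trials(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series,
    gene_subset: list[str] | None,
    config: AgeModelConfig,
    n_trials: int,
    seed: int,
    label: str = "all",
    split_seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Repeated ~90/10 split -> fit -> test MAE -> shuffled-control MAE.

    ``split_seeds`` fixes the per-trial train/test partition so different
    gene selections can share identical splits (paired trials).
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if gene_subset is not None:
        vals = vals.loc[list(gene_subset)]
    X_all = vals.to_numpy(float).T  # samples x genes
    y_all = ages.loc[vals.columns].to_numpy(float)
    n = len(y_all)
    root = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    if split_seeds is None:
        split_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_trials)]
    rows = []
    for t in range(n_trials):
        rng = np.random.default_rng(split_seeds[t])
        tr, te = _split_indices(n, config.train_fraction, rng)
        Xtr, Xte = log_standardize(X_all[tr], X_all[te])
        model = fit_age_model(Xtr, y_all[tr], config, seed=split_seeds[t])
        mae, pred = evaluate_trial(model, Xte, y_all[te])
        shuf = shuffled_control(pred, y_all[te], seed=split_seeds[t] + 1)
        rows.append(
            {
                "label": label,
                "trial": t,
                "n_features": X_all.shape[1],
                "mae": mae,
                "shuffled_mae": shuf,
            }
        )
    return pd.DataFrame(rows)


def feature_sweep(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series,
    sizes: list[int],
    config: AgeModelConfig | None = None,
    n_trials: int = 100,
    seed: int = 0,
) -> AgeModelReport:
    """Random gene subsets of each size, fresh per trial, shared splits.

    The train/test split sequence is identical across sizes (one shared
    split-seed stream); gene draws use an independent stream per size.
    """
    config = config or AgeModelConfig()
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    genes = list(vals.index)
    for s in sizes:
        if s > len(genes):
            raise ValueError(f"size {s} exceeds {len(genes)} available genes")
    root = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    split_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_trials)]
    all_rows = []
    for si, size in enumerate(sizes):
        draw = np.random.default_rng(np.random.SeedSequence((seed, 202, si)))
        frames = []
        for t in range(n_trials):
            idx = np.sort(draw.choice(len(genes), size=size, replace=False))
            subset = [genes[i] for i in idx]
            frames.append(
                run_trials(
                    vals,
                    ages,
                    subset,
                    config,
                    n_trials=1,
                    seed=seed,
                    label=f"n{size}",
                    split_seeds=[split_seeds[t]],
                ).assign(trial=t, n_features=size)
            )
        all_rows.append(pd.concat(frames, ignore_index=True))
    trials = pd.concat(all_rows, ignore_index=True)
    sweep = (
        trials.groupby("n_features")[["mae", "shuffled_mae"]]
        .mean()
        .rename(columns={"mae": "mean_mae", "shuffled_mae": "mean_shuffled_mae"})
        .reset_index()
    )
    return AgeModelReport(trials=trials, sweep=sweep)


def marker_eval(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series,
    representative_genes: list[str],
    config: AgeModelConfig | None = None,
    n_trials: int = 100,
    seed: int = 0,
    include_all_genes: bool = True,
) -> tuple[AgeModelReport, float]:
    """Representative-k vs random-k (vs all genes), paired splits.

    Returns the report and the one-sided Mann-Whitney p-value that the
    representative-set MAEs are smaller than the random-set MAEs.
    """
    config = config or AgeModelConfig()
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    k = len(representative_genes)
    genes = list(vals.index)
    root = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    split_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_trials)]
    draw = np.random.default_rng(np.random.SeedSequence((seed, 303)))

    rep = run_trials(
        vals, ages, representative_genes, config, n_trials, seed,
        label="representative", split_seeds=split_seeds,
    )
    rand_frames = []
    for t in range(n_trials):
        subset = [genes[i] for i in draw.choice(len(genes), size=k, replace=False)]
        rand_frames.append(
            run_trials(
                vals, ages, subset, config, 1, seed,
                label="random", split_seeds=[split_seeds[t]],
            ).assign(trial=t)
        )
    frames = [rep, pd.concat(rand_frames, ignore_index=True)]
    if include_all_genes:
        frames.append(
            run_trials(vals, ages, None, config, n_trials, seed, label="all", split_seeds=split_seeds)
        )
    trials = pd.concat(frames, ignore_index=True)
    p = float(
        stats.mannwhitneyu(
            trials.loc[trials["label"] == "representative", "mae"],
            trials.loc[trials["label"] == "random", "mae"],
            alternative="less",
        ).pvalue
    )
    return AgeModelReport(trials=trials), p


def subset_search(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series,
    representative_genes: list[str],
    draw_size: int = 5,
    n_draws: int = 1000,
    trials_per_draw: int = 3,
    config: AgeModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random ``draw_size``-gene subsets of the representatives, ranked by MAE.

    Returns a frame (rank, genes, mean_mae, mean_shuffled_mae) sorted
    ascending by mean MAE over ``trials_per_draw`` paired trials.
    """
    if draw_size > len(representative_genes):
        raise ValueError("draw_size exceeds number of representatives")
    config = config or AgeModelConfig()
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    root = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    split_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=trials_per_draw)]
    draw = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    seen: set[tuple[str, ...]] = set()
    rows = []
    for d in range(n_draws):
        subset = tuple(
            sorted(
                representative_genes[i]
                for i in draw.choice(len(representative_genes), size=draw_size, replace=False)
            )
        )
        if subset in seen:
            continue
        seen.add(subset)
        res = run_trials(
            vals, ages, list(subset), config, trials_per_draw, seed,
            label="subset", split_seeds=split_seeds,
        )
        rows.append(
            {
                "genes": ",".join(subset),
                "mean_mae": res["mae"].mean(),
                "mean_shuffled_mae": res["shuffled_mae"].mean(),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_mae", ignore_index=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
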