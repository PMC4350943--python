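"""ε-insensitive support vector regression with a Tanimoto kernel.

The regression function has the kernel form

    f(x) = Σ_i (α_i − α_i*) · K(x_i, x) + b

where the sum runs over support vectors, the dual coefficients are bounded
by the regularization term C (``|α_i − α_i*| ≤ C``), and K is the Tanimoto
kernel, which on binary fingerprints equals the Tanimoto coefficient. The
primal objective minimizes ``½‖w‖² + C Σ(ξ_i + ξ_i*)`` subject to the
ε-tube constraints: training targets mispredicted by less than ε incur no
penalty; points outside the tube become support vectors.

The quadratic program is delegated to scikit-learn's libsvm-backed solver
with a precomputed kernel matrix (no on-the-fly kernel callbacks, for
determinism and testability); kernel construction and the prediction sum
above are implemented here and predictions are always reproducible from the
stored model fields alone.

Errors follow the ε-insensitive absolute-error convention

    err = Σ_i max(0, |y_i − f(x_i)| − ε)

i.e. the realized slack sum of the objective, not the plain L1 error; the
mean error divides by the number of compounds.

The experimental protocol is a regularization sweep: for each C in an
ordered grid (default {1, …, 50, 100, 250, 500, 1000} with ε = 0.1), models
are fitted on a fixed collection of random 50/50 train/test splits (default
10 trials) and the per-C mean/sd train and test errors are recorded; the
preferred C is the one with the lowest mean test error. The same split
partitions are reused across all C values so that C is the only varying
factor per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _SkSVR

from .data_io import DataSet
from .errors import ConfigError, ConvergenceError, ValidationError
from .similarity import kernel_blocks, pairwise_matrix

#: The default regularization grid: 1–50 by 1, then 100, 250, 500, 1000.
DEFAULT_C_GRID: tuple[float, ...] = tuple(float(c) for c in range(1, 51)) + (
    100.0,
    250.0,
    500.0,
    1000.0,
)


@dataclass(frozen=True)
class SvrConfig:
    """Sweep protocol parameters (C grid, ε, trials, split, seed)."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    epsilon: float = 0.1
    n_trials: int = 10
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.c_grid) == 0:
            raise ConfigError("c_grid must be non-empty")
        if any(c <= 0 for c in self.c_grid):
            raise ConfigError("all C values must be > 0")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must lie in (0, 1)")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")


@dataclass
class SvrModel:
    """A fitted ε-SVR: dual coefficients, intercept, support-vector refs."""

    dual_coeffs: np.ndarray  # (n_sv,), values are alpha_i - alpha_i*
    intercept: float
    support_indices: np.ndarray  # indices into the training set
    train_fingerprints: np.ndarray  # (n_train, universe) boolean, referenced
    C: float
    epsilon: float


def tanimoto_kernel_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tanimoto kernel between the rows of two boolean fingerprint matrices."""
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"fingerprint universe mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    inner = Af @ Bf.T
    na = Af.sum(axis=1)[:, None]
    nb = Bf.sum(axis=1)[None, :]
    return inner / (na + nb - inner)


def fit_svr(
    train_fingerprints: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float = 0.1,
    kernel: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> SvrModel:
    """Fit an ε-SVR with the Tanimoto kernel on binary fingerprints.

    Parameters
    ----------
    train_fingerprints
        Boolean (n, universe) on-bit matrix.
    y
        pKi target values, length n.
    C, epsilon
        Regularization term and ε-tube half width.
    kernel
        Optional precomputed train/train Tanimoto kernel (reused across a
        sweep); computed from the fingerprints when omitted.

    Raises
    ------
    ConvergenceError
        If the solver hits its iteration cap; never silent.
    """
    y = np.asarray(y, dtype=float)
    if train_fingerprints.shape[0] != y.size:
        raise ValidationError("fingerprint/target length mismatch")
    if train_fingerprints.shape[0] < 2:
        raise ValidationError("fit_svr needs >= 2 training records")
    if C <= 0:
        raise ConfigError(f"C must be > 0, got {C}")
    if kernel is None:
        kernel = tanimoto_kernel_matrix(train_fingerprints, train_fingerprints)
    est = _SkSVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            est.fit(kernel, y)
        except ConvergenceWarning as exc:
            raise ConvergenceError(f"SVR solver did not converge: {exc}", C=C) from exc
    return SvrModel(
        dual_coeffs=est.dual_coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        support_indices=est.support_.copy(),
        train_fingerprints=train_fingerprints,
        C=float(C),
        epsilon=float(epsilon),
    )


def predict(model: SvrModel, fingerprints: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = Σ (α_i − α_i*)·K(x_i, x) + b from stored fields alone."""
    sv = model.train_fingerprints[model.support_indices]
    K = tanimoto_kernel_matrix(np.asarray(fingerprints), sv)
    return K @ model.dual_coeffs + model.intercept


def predict_precomputed(model: SvrModel, kernel_rows: np.ndarray) -> np.ndarray:
    """Predict from precomputed kernel rows vs the *full* training set."""
    return kernel_rows[:, model.support_indices] @ model.dual_coeffs + model.intercept


def eps_insensitive_abs_error(y_true, y_pred, epsilon: float) -> float:
    """Σ max(0, |y − f(x)| − ε): the realized slack sum of the objective."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return float(np.sum(np.maximum(0.0, np.abs(y_true - y_pred) - epsilon)))


def mean_abs_error(y_true, y_pred, epsilon: float, n: int | None = None) -> float:
    """ε-insensitive absolute error divided by the number of compounds."""
    if n is None:
        n = np.asarray(y_true).size
    if n == 0:
        raise ValidationError("mean_abs_error requires n > 0")
    return eps_insensitive_abs_error(y_true, y_pred, epsilon) / n


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (≤ 1, may be < 0)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValidationError("r_squared needs >= 2 values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("r_squared undefined for zero-variance targets")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class TrialResult:
    """One random-split fit: indices, Eq-7 predictions, and slack errors."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_predictions: np.ndarray
    test_predictions: np.ndarray
    train_eps_error: float
    test_eps_error: float
    model: SvrModel


@dataclass
class SweepResult:
    """Per-C mean/sd of train and test errors over the trial collection."""

    c_values: tuple[float, ...]
    mean_train_errors: np.ndarray
    sd_train_errors: np.ndarray
    mean_test_errors: np.ndarray
    sd_test_errors: np.ndarray
    n_trials: int
    trials: dict[float, list[TrialResult]] = field(default_factory=dict)

    @property
    def best_c(self) -> float:
        return select_best_c(self)


def make_splits(
    n: int, n_trials: int, split_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random train/test partitions (train = ⌊n·fraction⌋)."""
    rng = np.random.default_rng(seed)
    splits = []
    n_train = int(np.floor(n * split_fraction))
    if n_train < 2 or n - n_train < 1:
        raise ConfigError(f"split of n={n} leaves too few compounds")
    for _ in range(n_trials):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def run_trials(
    dataset: DataSet,
    C: float,
    config: SvrConfig,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    sim_matrix: np.ndarray | None = None,
) -> list[TrialResult]:
    """Fit one model per random split at a fixed C; reproducible under seed."""
    n = len(dataset)
    if n < 4:
        raise ValidationError("run_trials needs >= 4 compounds")
    if splits is None:
        splits = make_splits(n, config.n_trials, config.split_fraction, config.seed)
    if sim_matrix is None:
        sim_matrix = pairwise_matrix(dataset)
    X = dataset.fingerprint_matrix()
    y = dataset.potencies()
    results = []
    for train_idx, test_idx in splits:
        K_train = kernel_blocks(sim_matrix, train_idx, train_idx)
        model = fit_svr(X[train_idx], y[train_idx], C, config.epsilon, kernel=K_train)
        train_pred = predict_precomputed(model, K_train)
        K_test = kernel_blocks(sim_matrix, test_idx, train_idx)
        test_pred = predict_precomputed(model, K_test)
        results.append(
            TrialResult(
                train_indices=train_idx,
                test_indices=test_idx,
                train_predictions=train_pred,
                test_predictions=test_pred,
                train_eps_error=eps_insensitive_abs_error(
                    y[train_idx], train_pred, config.epsilon
                ),
                test_eps_error=eps_insensitive_abs_error(
                    y[test_idx], test_pred, config.epsilon
                ),
                model=model,
            )
        )
    return results


def sweep(
    dataset: DataSet,
    config: SvrConfig,
    sim_matrix: np.ndarray | None = None,
    keep_trials: bool = False,
) -> SweepResult:
    """Regularization sweep over the C grid with shared trial splits."""
    if sim_matrix is None:
        sim_matrix = pairwise_matrix(dataset)
    splits = make_splits(
        len(dataset), config.n_trials, config.split_fraction, config.seed
    )
    mean_tr, sd_tr, mean_te, sd_te = [], [], [], []
    kept: dict[float, list[TrialResult]] = {}
    for C in config.c_grid:
        trials = run_trials(dataset, C, config, splits=splits, sim_matrix=sim_matrix)
        tr = np.array([t.train_eps_error for t in trials])
        te = np.array([t.test_eps_error for t in trials])
        ddof = 1 if len(trials) > 1 else 0
        mean_tr.append(tr.mean())
        sd_tr.append(tr.std(ddof=ddof))
        mean_te.append(te.mean())
        sd_te.append(te.std(ddof=ddof))
        if keep_trials:
            kept[C] = trials
    return SweepResult(
        c_values=tuple(config.c_grid),
        mean_train_errors=np.array(mean_tr),
        sd_train_errors=np.array(sd_tr),
        mean_test_errors=np.array(mean_te),
        sd_test_errors=np.array(sd_te),
        n_trials=config.n_trials,
        trials=kept,
    )


def select_best_c(sweep_result: SweepResult) -> float:
    """arg-min of mean test error; ties break toward the smallest C."""
    if len(sweep_result.c_values) == 0:
        raise ValidationError("select_best_c on an empty sweep")
    order = np.argsort(sweep_result.c_values, kind="stable")
    errs = sweep_result.mean_test_errors[order]
    return float(np.asarray(sweep_result.c_values)[order][int(np.argmin(errs))])
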