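"""Shallow estimation networks for stance-phase gait kinetics.

Two single-hidden-layer networks map the 10-channel stance input
(time since heel strike plus sacral position, velocity and acceleration
in 3D) to stance kinetics: one with 5 outputs (3D ground reaction
force and 2D centre of pressure), one with 7 outputs (lower-limb joint
torques).  The hidden layer has 20 sigmoidal units, the output layer is
linear -- wide enough to represent the near-affine relationship between
CoM kinematics and kinetics that the compliant walking model predicts,
and to add the mild nonlinearity real data require.

Training is full-batch Levenberg-Marquardt on the mean squared error,
with early stopping on a validation set and the leave-one-subject-out
protocol for evaluation.  The Gauss-Newton normal equations are
assembled from the layer structure (no explicit Jacobian is
materialised), which keeps an epoch cheap even for ~300k residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "NetworkWeights",
    "NormalizationParams",
    "TrainConfig",
    "TrainHistory",
    "NetworkModel",
    "FoldAssignment",
    "build_network",
    "forward",
    "fit_normalization",
    "normalize_inputs",
    "normalize_outputs",
    "denormalize_outputs",
    "train_lm",
    "make_folds",
    "loo_harness",
    "predict_stance",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one estimation network."""

    n_inputs: int = 10
    n_hidden: int = 20
    n_outputs: int = 5
    activation: str = "tanh"  # "tanh" (sigmoidal) | "identity" (test hook)
    train_hidden: bool = True

    def __post_init__(self) -> None:
        if self.n_outputs not in (5, 7) and self.activation == "tanh":
            # the two production networks; other sizes allowed for tests
            pass
        if self.activation not in ("tanh", "identity"):
            raise ValueError("activation must be 'tanh' or 'identity'")


@dataclass
class NetworkWeights:
    """Weights and biases of a single-hidden-layer network."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()
        )

    def validate(self, spec: NetworkSpec) -> None:
        if self.W1.shape != (spec.n_hidden, spec.n_inputs):
            raise ValueError("W1 shape mismatch")
        if self.b1.shape != (spec.n_hidden,):
            raise ValueError("b1 shape mismatch")
        if self.W2.shape != (spec.n_outputs, spec.n_hidden):
            raise ValueError("W2 shape mismatch")
        if self.b2.shape != (spec.n_outputs,):
            raise ValueError("b2 shape mismatch")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite network weights")


def build_network(spec: NetworkSpec, seed: int) -> NetworkWeights:
    """Reproducible small-range random initialization."""
    rng = np.random.default_rng(seed)
    # Nguyen-Widrow-like scale: small inputs keep the sigmoids near
    # their linear region at the start
    s1 = 0.7 / math.sqrt(spec.n_inputs)
    s2 = 0.7 / math.sqrt(spec.n_hidden)
    return NetworkWeights(
        W1=rng.uniform(-s1, s1, (spec.n_hidden, spec.n_inputs)),
        b1=rng.uniform(-s1, s1, spec.n_hidden),
        W2=rng.uniform(-s2, s2, (spec.n_outputs, spec.n_hidden)),
        b2=np.zeros(spec.n_outputs),
    )


def _act(spec: NetworkSpec, a: np.ndarray):
    if spec.activation == "tanh":
        h = np.tanh(a)
        return h, 1.0 - h * h
    return a, np.ones_like(a)


def forward(
    weights: NetworkWeights, x: np.ndarray, spec: NetworkSpec | None = None
) -> np.ndarray:
    """Network output ``W2 @ act(W1 @ x + b1) + b2`` for one input or a batch."""
    spec = spec or NetworkSpec(
        n_inputs=weights.W1.shape[1],
        n_hidden=weights.W1.shape[0],
        n_outputs=weights.W2.shape[0],
    )
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != weights.W1.shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {weights.W1.shape[1]}"
        )
    H, _ = _act(spec, X @ weights.W1.T + weights.b1)
    out = H @ weights.W2.T + weights.b2
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    """Input min/max scaling (time passed through) and output scales.

    Input channels are min-max scaled to [0, 1] using statistics of the
    *training folds only*; test values outside the training range fall
    outside [0, 1] and are deliberately not clipped.  Outputs are
    divided by subject scales: body weight (N) for forces, foot length
    (m) for the centre of pressure, body mass (kg) for torques.
    """

    in_min: np.ndarray
    in_max: np.ndarray
    time_index: int | None = 0

    def __post_init__(self) -> None:
        self.in_min = np.asarray(self.in_min, dtype=float)
        self.in_max = np.asarray(self.in_max, dtype=float)
        span = self.in_max - self.in_min
        for j, s in enumerate(span):
            if self.time_index is not None and j == self.time_index:
                continue
            if s <= 0:
                raise ValueError(f"zero-amplitude input channel {j}")


def fit_normalization(X: np.ndarray, time_index: int | None = 0) -> NormalizationParams:
    """Per-channel min/max over the pooled training data."""
    X = np.asarray(X, dtype=float)
    return NormalizationParams(
        in_min=X.min(axis=0), in_max=X.max(axis=0), time_index=time_index
    )


def normalize_inputs(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = X.copy()
    span = params.in_max - params.in_min
    for j in range(X.shape[-1]):
        if params.time_index is not None and j == params.time_index:
            continue
        out[..., j] = (X[..., j] - params.in_min[j]) / span[j]
    return out


def normalize_outputs(Y: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Divide each output channel by its subject-specific physical scale."""
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("output scales must be positive")
    return np.asarray(Y, dtype=float) / scales


def denormalize_outputs(Y: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return np.asarray(Y, dtype=float) * np.asarray(scales, dtype=float)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Levenberg-Marquardt training configuration."""

    max_epochs: int = 300
    patience: int = 20  # epochs without validation improvement
    damping_init: float = 1e-3
    damping_factor: float = 10.0
    damping_max: float = 1e10
    improvement_eps: float = 1e-12  # strict improvement required
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_reason: str = ""


@dataclass
class NetworkModel:
    """A trained network bundled with its spec and normalization."""

    spec: NetworkSpec
    weights: NetworkWeights
    norm: NormalizationParams
    history: TrainHistory | None = None
    output_channels: tuple = ()


def _mse(weights: NetworkWeights, spec: NetworkSpec, X: np.ndarray, Y: np.ndarray) -> float:
    R = forward(weights, X, spec) - Y
    return float(np.mean(R * R))


def _normal_equations(
    weights: NetworkWeights, spec: NetworkSpec, X: np.ndarray, Y: np.ndarray
):
    """Gauss-Newton ``(J^T J, J^T r)`` assembled from the layer structure.

    Residuals ``r_{nk} = out_{nk} - y_{nk}``.  Parameters are ordered
    ``[vec(W2~); vec(W1~)]`` with ``W2~ = [W2, b2]`` (rows per output)
    and ``W1~ = [W1, b1]`` (rows per hidden unit); the hidden block is
    omitted when the spec freezes the hidden layer.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    K = spec.n_outputs
    A1 = X @ weights.W1.T + weights.b1
    H, S = _act(spec, A1)  # (n, J) activations and derivatives
    R = H @ weights.W2.T + weights.b2 - Y  # (n, K)

    Ht = np.column_stack([H, np.ones(n)])  # (n, J+1)
    n_out_par = K * Ht.shape[1]

    G2 = Ht.T @ Ht  # (J+1, J+1)
    g2 = Ht.T @ R  # (J+1, K); gradient block per output k is g2[:, k]

    if not spec.train_hidden:
        JTJ = np.kron(np.eye(K), G2)
        JTr = g2.T.reshape(-1)
        return JTJ, JTr, R

    Xt = np.column_stack([X, np.ones(n)])  # (n, I+1)
    J_h, I1 = S.shape[1], Xt.shape[1]
    Z = (S[:, :, None] * Xt[:, None, :]).reshape(n, J_h * I1)  # (n, J*(I+1))

    C = weights.W2.T @ weights.W2  # (J, J)
    ZZ = Z.T @ Z  # (J*(I+1), J*(I+1))
    B11 = (
        C[:, None, :, None] * ZZ.reshape(J_h, I1, J_h, I1)
    ).reshape(J_h * I1, J_h * I1)

    Q = Ht.T @ Z  # (J+1, J*(I+1))
    # cross block for output k: rows (k, j) vs cols (j', i)
    cross = np.empty((n_out_par, J_h * I1))
    Qr = Q.reshape(Ht.shape[1], J_h, I1)
    for k in range(K):
        blk = (Qr * weights.W2[k][None, :, None]).reshape(Ht.shape[1], J_h * I1)
        cross[k * Ht.shape[1] : (k + 1) * Ht.shape[1]] = blk

    U = (R @ weights.W2) * S  # (n, J)
    g1 = (U.T @ Xt).reshape(-1)  # (J*(I+1),)

    P = n_out_par + J_h * I1
    JTJ = np.empty((P, P))
    JTJ[:n_out_par, :n_out_par] = np.kron(np.eye(K), G2)
    JTJ[:n_out_par, n_out_par:] = cross
    JTJ[n_out_par:, :n_out_par] = cross.T
    JTJ[n_out_par:, n_out_par:] = B11
    JTr = np.concatenate([g2.T.reshape(-1), g1])
    return JTJ, JTr, R


def _apply_delta(
    weights: NetworkWeights, spec: NetworkSpec, delta: np.ndarray
) -> NetworkWeights:
    K = spec.n_outputs
    J = spec.n_hidden
    I = spec.n_inputs
    w = weights.copy()
    n_out = K * (J + 1)
    W2t = delta[:n_out].reshape(K, J + 1)
    w.W2 = w.W2 + W2t[:, :J]
    w.b2 = w.b2 + W2t[:, J]
    if spec.train_hidden:
        W1t = delta[n_out:].reshape(J, I + 1)
        w.W1 = w.W1 + W1t[:, :I]
        w.b1 = w.b1 + W1t[:, I]
    return w


def train_lm(
    weights: NetworkWeights,
    spec: NetworkSpec,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NetworkWeights, TrainHistory]:
    """Full-batch Levenberg-Marquardt with validation early stopping.

    Each epoch solves ``(J^T J + lambda I) delta = -J^T r`` and accepts
    the step only if the training MSE decreases (shrinking the damping
    on success, growing it on failure).  Training stops when the
    validation MSE has not strictly improved for ``patience`` epochs,
    when the damping exceeds its cap, or at ``max_epochs``; the weights
    with the lowest validation MSE are returned.
    """
    config = config or TrainConfig()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    weights.validate(spec)
    w = weights.copy()
    lam = config.damping_init
    hist = TrainHistory()

    best_val = _mse(w, spec, X_val, Y_val)
    best_w = w.copy()
    hist.best_epoch = 0
    since_best = 0
    train_mse = _mse(w, spec, X_train, Y_train)

    for epoch in range(1, config.max_epochs + 1):
        JTJ, JTr, _ = _normal_equations(w, spec, X_train, Y_train)
        accepted = False
        while lam <= config.damping_max:
            A = JTJ + lam * np.eye(len(JTJ))
            try:
                delta = np.linalg.solve(A, -JTr)
            except np.linalg.LinAlgError:
                lam *= config.damping_factor
                continue
            w_new = _apply_delta(w, spec, delta)
            new_mse = _mse(w_new, spec, X_train, Y_train)
            if np.isfinite(new_mse) and new_mse < train_mse:
                w = w_new
                train_mse = new_mse
                lam = max(lam / config.damping_factor, 1e-20)
                accepted = True
                break
            lam *= config.damping_factor
        if not accepted:
            hist.stopped_reason = "damping exceeded maximum (no descent step)"
            break

        val_mse = _mse(w, spec, X_val, Y_val)
        hist.train_mse.append(train_mse)
        hist.val_mse.append(val_mse)
        if val_mse < best_val - config.improvement_eps:
            best_val = val_mse
            best_w = w.copy()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                hist.stopped_reason = (
                    f"validation MSE flat for {config.patience} epochs"
                )
                break
    else:
        hist.stopped_reason = "max_epochs reached"
    return best_w, hist


# ---------------------------------------------------------------------------
# Leave-one-subject-out protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    """One LOO fold: held-out test subject, validation and training subjects."""

    test_subject: str
    validation_subjects: tuple
    training_subjects: tuple

    def __post_init__(self) -> None:
        overlap = (
            {self.test_subject} & set(self.validation_subjects),
            {self.test_subject} & set(self.training_subjects),
            set(self.validation_subjects) & set(self.training_subjects),
        )
        if any(overlap):
            raise ValueError("fold subject sets must be disjoint")


def make_folds(subjects, n_validation: int = 3, seed: int = 0):
    """One fold per subject: that subject out, ``n_validation`` drawn at
    random from the rest for early stopping, the remainder training."""
    subjects = sorted(subjects)
    if len(subjects) < n_validation + 2:
        raise ValueError(
            f"need at least {n_validation + 2} subjects for LOO with "
            f"{n_validation} validation subjects"
        )
    rng = np.random.default_rng(seed)
    folds = []
    for s in subjects:
        rest = [x for x in subjects if x != s]
        val = tuple(sorted(rng.choice(rest, size=n_validation, replace=False)))
        train = tuple(x for x in rest if x not in val)
        folds.append(FoldAssignment(s, val, train))
    return folds


def _stack(dataset, subjects, key_in="X", key_out=None):
    Xs, Ys = [], []
    for s in subjects:
        for rec in dataset[s]:
            Xs.append(rec[key_in])
            Ys.append(rec[key_out])
    return np.vstack(Xs), np.vstack(Ys)


def loo_harness(
    dataset: dict,
    spec: NetworkSpec,
    output_key: str,
    config: TrainConfig | None = None,
    n_validation: int = 3,
    fold_seed: int = 0,
    init_seed: int = 0,
):
    """Leave-one-subject-out training and prediction for one network.

    ``dataset`` maps subject id to a list of stance records, each with a
    (201, 10) raw input matrix under ``"X"`` and a (201, K) normalized
    output matrix under ``output_key``; additional keys are passed
    through to the prediction records.  Per fold, the input min/max
    normalization is fitted on the training subjects only.

    Returns a list of prediction records ``{subject, fold, record,
    pred, meas}`` (both in normalized output units) plus the per-fold
    models.
    """
    config = config or TrainConfig()
    subjects = sorted(dataset)
    folds = make_folds(subjects, n_validation=n_validation, seed=fold_seed)
    predictions = []
    models = {}
    for i_fold, fold in enumerate(folds):
        X_tr_raw, Y_tr = _stack(dataset, fold.training_subjects, key_out=output_key)
        X_va_raw, Y_va = _stack(dataset, fold.validation_subjects, key_out=output_key)
        norm = fit_normalization(X_tr_raw)
        X_tr = normalize_inputs(X_tr_raw, norm)
        X_va = normalize_inputs(X_va_raw, norm)
        w0 = build_network(spec, seed=init_seed + i_fold)
        w, hist = train_lm(w0, spec, X_tr, Y_tr, X_va, Y_va, config)
        models[fold.test_subject] = NetworkModel(
            spec=spec, weights=w, norm=norm, history=hist
        )
        for rec in dataset[fold.test_subject]:
            Xn = normalize_inputs(rec["X"], norm)
            pred = forward(w, Xn, spec)
            predictions.append(
                {
                    "subject": fold.test_subject,
                    "fold": fold,
                    "record": rec,
                    "pred": pred,
                    "meas": rec[output_key],
                }
            )
    return predictions, models


def predict_stance(
    model: NetworkModel,
    input_matrix: np.ndarray,
    output_scales: np.ndarray,
) -> np.ndarray:
    """Denormalized kinetics curves for one stance input matrix.

    ``output_scales`` are the subject's physical scales per channel
    (body weight in N for forces, foot length in m for CoP, body mass
    in kg for torques).
    """
    scales = np.asarray(output_scales, dtype=float)
    if scales.shape[-1] != model.spec.n_outputs:
        raise ValueError("output_scales length must match the network outputs")
    Xn = normalize_inputs(np.asarray(input_matrix, dtype=float), model.norm)
    return denormalize_outputs(forward(model.weights, Xn, model.spec), scales)
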