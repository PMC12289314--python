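"""Three-layer autoencoder family for tabular patient snapshots.

A single encoder-decoder architecture,

    Z  = phi1(X W^T + b)        (encoder, latent dimension l)
    X' = phi2(Z W'^T + b')      (decoder)

underlies five variants that differ only in input corruption and loss:

=======  ==============================================================
variant  loss
=======  ==============================================================
AE       MSE(X, X')
DAE      MSE(X, g(f(X_noise)))  with swap noise on the input
CAE      MSE + lambda * ||J_f(X)||_F^2   (contractive Jacobian penalty)
SAE      MSE + beta * KL(rho || rho_hat) (Bernoulli sparsity penalty)
RAE      -MCC(X, X') + beta * KL(rho || rho_hat) + lambda * ||W||^2 / 2
=======  ==============================================================

Everything (forward pass, all loss terms, their gradients, the Adam /
Adamax / RMSprop optimizers, early stopping) is implemented in numpy with
analytic gradients; tests check them against finite differences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

VARIANTS = ("AE", "DAE", "CAE", "SAE", "RAE")
ACTIVATIONS = ("sigmoid", "relu")
OPTIMIZERS = ("adam", "adamax", "rmsprop")

# Grid axes for the hyperparameter search (4 x 3 x 7 x 2 = 168 configurations
# per variant).
GRID_LEARNING_RATES = (1e-5, 1e-4, 1e-3, 1e-2)
GRID_OPTIMIZERS = OPTIMIZERS
GRID_LATENT_RATIOS = (0.02, 0.05, 0.10, 0.15, 0.30, 0.50, 0.75)
GRID_ACTIVATIONS = ACTIVATIONS

_EPS = 1e-7


@dataclass(frozen=True)
class AEConfig:
    """One trainable configuration: a variant plus its hyperparameters.

    The four shared axes (learning_rate, optimizer, latent_ratio,
    activation) are the grid of the hyperparameter study; the remaining
    fields are variant-specific penalties fixed ahead of the grid search.
    """

    variant: str = "AE"
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    latent_ratio: float = 0.15
    activation: str = "sigmoid"
    # variant-specific
    swap_p: float = 0.15          # DAE corruption probability
    lambda_cae: float = 1e-4      # CAE Jacobian penalty strength
    rho_sparsity: float = 0.05    # SAE/RAE target mean activation
    beta_sparsity: float = 1e-3   # SAE/RAE KL penalty strength
    sigma_mcc: float = 1.0        # RAE correntropy kernel width
    lambda_decay: float = 1e-4    # RAE weight decay strength
    # training protocol
    max_epochs: int = 2000
    patience: int = 5
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0.0 <= self.swap_p <= 1.0:
            raise ValueError("swap_p must lie in [0, 1]")
        if not 0.0 < self.rho_sparsity < 1.0:
            raise ValueError("rho_sparsity must lie in (0, 1)")
        if self.sigma_mcc <= 0:
            raise ValueError("sigma_mcc must be positive")
        for name in ("lambda_cae", "beta_sparsity", "lambda_decay", "learning_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def latent_dim(self, m: int) -> int:
        """Round-half-away-from-zero of latent_ratio * m, floored at 1."""
        return max(1, int(np.floor(self.latent_ratio * m + 0.5)))


@dataclass
class EncoderDecoder:
    """Parameters of the 3-layer network; W is (l, m), W' is (m, l)."""

    W: np.ndarray
    b: np.ndarray
    Wp: np.ndarray
    bp: np.ndarray
    act1: str = "sigmoid"
    act2: str = "sigmoid"

    def __post_init__(self) -> None:
        l, m = self.W.shape
        if self.b.shape != (l,) or self.Wp.shape != (m, l) or self.bp.shape != (m,):
            raise ValueError("inconsistent parameter shapes")

    @property
    def m(self) -> int:
        return self.W.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.W.shape[0]


@dataclass
class TrainingTrace:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _activate(name: str, A: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return expit(A)
    if name == "relu":
        return np.maximum(A, 0.0)
    raise ValueError(f"unknown activation {name!r}")


def _activate_deriv(name: str, A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return Z * (1.0 - Z)
    if name == "relu":
        return (A > 0).astype(float)
    raise ValueError(f"unknown activation {name!r}")


def init_model(m: int, latent_dim: int, act1: str, act2: str,
               seed: int = 0) -> EncoderDecoder:
    """Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(seed)
    lim_enc = np.sqrt(6.0 / (m + latent_dim))
    lim_dec = np.sqrt(6.0 / (m + latent_dim))
    return EncoderDecoder(
        W=rng.uniform(-lim_enc, lim_enc, (latent_dim, m)),
        b=np.zeros(latent_dim),
        Wp=rng.uniform(-lim_dec, lim_dec, (m, latent_dim)),
        bp=np.zeros(m),
        act1=act1,
        act2=act2,
    )


def encode(model: EncoderDecoder, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.m:
        raise ValueError(f"expected {model.m} features, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in input")
    return _activate(model.act1, X @ model.W.T + model.b)


def decode(model: EncoderDecoder, Z: np.ndarray) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.latent_dim:
        raise ValueError(f"expected {model.latent_dim} latent units, got {Z.shape[1]}")
    return _activate(model.act2, Z @ model.Wp.T + model.bp)


def reconstruct(model: EncoderDecoder, X: np.ndarray) -> np.ndarray:
    return decode(model, encode(model, X))


# ---------------------------------------------------------------------------
# Loss components


def mse_loss(X: np.ndarray, Xp: np.ndarray) -> float:
    X, Xp = np.asarray(X, dtype=float), np.asarray(Xp, dtype=float)
    if X.shape != Xp.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((X - Xp) ** 2))


def swap_noise(X: np.ndarray, p: float,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Corrupt each entry with probability p by a value drawn uniformly (with
    replacement) from the same column."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p == 0.0:
        return X.copy()
    n = X.shape[0]
    mask = rng.random(X.shape) < p
    donor_rows = rng.integers(0, n, size=X.shape)
    cols = np.broadcast_to(np.arange(X.shape[1]), X.shape)
    return np.where(mask, X[donor_rows, cols], X)


def contractive_penalty(model: EncoderDecoder, X: np.ndarray) -> float:
    """Mean (over samples) squared Frobenius norm of the encoder Jacobian.

    The Jacobian of z = phi1(Wx + b) is diag(phi1'(a)) W, so the squared
    Frobenius norm is sum_k phi1'(a_k)^2 * sum_j W_kj^2 per sample — a
    closed form for both sigmoid and (a.e.) relu.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = X @ model.W.T + model.b
    Z = _activate(model.act1, A)
    s = _activate_deriv(model.act1, A, Z)
    row_sq = (model.W ** 2).sum(axis=1)  # per latent unit
    return float((s ** 2 @ row_sq).mean())


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """KL(Bernoulli(rho) || Bernoulli(rho_hat_j)), summed over latent units;
    rho_hat is clipped to [eps, 1-eps]."""
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    r = np.clip(np.asarray(rho_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(np.sum(rho * np.log(rho / r) + (1 - rho) * np.log((1 - rho) / (1 - r))))


def mcc(X: np.ndarray, Xp: np.ndarray, sigma: float) -> float:
    """Correntropy: elementwise Gaussian kernel on residuals, summed over
    features and averaged over samples."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X, Xp = np.atleast_2d(np.asarray(X, float)), np.atleast_2d(np.asarray(Xp, float))
    if X.shape != Xp.shape:
        raise ValueError("shape mismatch")
    c = 1.0 / (np.sqrt(2.0 * np.pi) * sigma)
    k = c * np.exp(-((X - Xp) ** 2) / (2.0 * sigma ** 2))
    return float(k.sum(axis=1).mean())


def weight_decay(model: EncoderDecoder) -> float:
    """Half the summed squared entries of both weight matrices (no biases)."""
    return float(0.5 * ((model.W ** 2).sum() + (model.Wp ** 2).sum()))


def loss(variant: str, model: EncoderDecoder, X_clean: np.ndarray,
         X_input: np.ndarray, config: AEConfig) -> float:
    """The variant's full training loss for a given (clean, possibly
    corrupted) input pair."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    X_clean = np.atleast_2d(np.asarray(X_clean, dtype=float))
    X_input = np.atleast_2d(np.asarray(X_input, dtype=float))
    Z = encode(model, X_input)
    Xp = decode(model, Z)
    if variant in ("AE", "DAE"):
        return mse_loss(X_clean, Xp)
    if variant == "CAE":
        return mse_loss(X_clean, Xp) + config.lambda_cae * contractive_penalty(model, X_input)
    if variant == "SAE":
        return mse_loss(X_clean, Xp) + config.beta_sparsity * kl_sparsity(
            config.rho_sparsity, Z.mean(axis=0))
    # RAE
    return (-mcc(X_clean, Xp, config.sigma_mcc)
            + config.beta_sparsity * kl_sparsity(config.rho_sparsity, Z.mean(axis=0))
            + config.lambda_decay * weight_decay(model))


# ---------------------------------------------------------------------------
# Gradients


def _loss_and_grads(variant: str, model: EncoderDecoder, X_clean: np.ndarray,
                    X_input: np.ndarray, config: AEConfig):
    """Full loss and analytic gradients for all four parameter arrays."""
    n, m = X_clean.shape
    A1 = X_input @ model.W.T + model.b
    Z = _activate(model.act1, A1)
    A2 = Z @ model.Wp.T + model.bp
    Xp = _activate(model.act2, A2)
    R = X_clean - Xp

    total = 0.0
    if variant == "RAE":
        c = 1.0 / (np.sqrt(2.0 * np.pi) * config.sigma_mcc)
        K = c * np.exp(-(R ** 2) / (2.0 * config.sigma_mcc ** 2))
        total += -float(K.sum(axis=1).mean())
        # d(-MCC)/dXp: dK/dXp = K * R / sigma^2 (R = X - Xp)
        dXp = -(K * R / config.sigma_mcc ** 2) / n
    else:
        total += float((R ** 2).mean())
        dXp = -2.0 * R / (n * m)

    dA2 = dXp * _activate_deriv(model.act2, A2, Xp)
    dWp = dA2.T @ Z
    dbp = dA2.sum(axis=0)
    dZ = dA2 @ model.Wp

    if variant in ("SAE", "RAE"):
        rho = config.rho_sparsity
        rho_hat = Z.mean(axis=0)
        r = np.clip(rho_hat, _EPS, 1.0 - _EPS)
        total += config.beta_sparsity * float(
            np.sum(rho * np.log(rho / r) + (1 - rho) * np.log((1 - rho) / (1 - r))))
        inside = (rho_hat > _EPS) & (rho_hat < 1.0 - _EPS)
        dKL = np.where(inside, -rho / r + (1 - rho) / (1 - r), 0.0)
        dZ = dZ + config.beta_sparsity * dKL / n

    s = _activate_deriv(model.act1, A1, Z)
    dA1 = dZ * s
    dW = dA1.T @ X_input
    db = dA1.sum(axis=0)

    if variant == "CAE":
        row_sq = (model.W ** 2).sum(axis=1)
        total += config.lambda_cae * float((s ** 2 @ row_sq).mean())
        # Penalty P = (1/n) sum_i sum_k s_ik^2 r_k with r_k = sum_j W_kj^2.
        # Two gradient paths: directly through r_k, and through a_ik in s.
        lam = config.lambda_cae
        dW = dW + lam * (2.0 / n) * ((s ** 2).sum(axis=0))[:, None] * model.W
        if model.act1 == "sigmoid":
            sp = s * (1.0 - 2.0 * Z)  # d s / d a for sigmoid
            coef = (2.0 / n) * s * sp * row_sq  # (n, l)
            dW = dW + lam * coef.T @ X_input
            db = db + lam * coef.sum(axis=0)
        # relu: s' = 0 a.e., only the direct W path contributes

    if variant == "RAE":
        total += config.lambda_decay * weight_decay(model)
        dW = dW + config.lambda_decay * model.W
        dWp = dWp + config.lambda_decay * model.Wp

    return total, {"W": dW, "b": db, "Wp": dWp, "bp": dbp}


# ---------------------------------------------------------------------------
# Optimizers (numpy ports of the standard update rules)


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        self.kind, self.lr, self.t = kind, lr, 0
        self.state: dict[str, dict[str, np.ndarray]] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, g in grads.items():
            st = self.state.setdefault(name, {
                "m": np.zeros_like(g), "v": np.zeros_like(g), "u": np.zeros_like(g)})
            if self.kind == "adam":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1 ** self.t)
                vhat = st["v"] / (1 - b2 ** self.t)
                params[name] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            elif self.kind == "adamax":
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["u"] = np.maximum(b2 * st["u"], np.abs(g))
                params[name] -= (self.lr / (1 - b1 ** self.t)) * st["m"] / (st["u"] + eps)
            elif self.kind == "rmsprop":
                alpha = 0.99
                st["v"] = alpha * st["v"] + (1 - alpha) * g * g
                params[name] -= self.lr * g / (np.sqrt(st["v"]) + eps)
            else:
                raise ValueError(f"unknown optimizer {self.kind!r}")


# ---------------------------------------------------------------------------
# Training


def train(X_train: np.ndarray, X_val: np.ndarray, config: AEConfig
          ) -> tuple[EncoderDecoder, TrainingTrace]:
    """Minibatch training with early stopping on the validation loss.

    Stops once the validation loss has failed to improve for more than
    ``config.patience`` consecutive epochs and returns the parameters from
    the best validation epoch. Fully deterministic given ``config.seed``
    (corruption noise for the DAE uses an independent stream, so a DAE with
    swap_p=0 reproduces the vanilla AE epoch for epoch).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    n, m = X_train.shape
    latent = config.latent_dim(m)

    ss = np.random.SeedSequence(config.seed)
    seed_init, seed_shuffle, seed_noise = [int(s.generate_state(1)[0]) % (2 ** 31)
                                           for s in ss.spawn(3)]
    model = init_model(m, latent, config.activation, config.activation, seed_init)
    rng_shuffle = np.random.default_rng(seed_shuffle)
    rng_noise = np.random.default_rng(seed_noise)
    opt = _Optimizer(config.optimizer, config.learning_rate)
    params = {"W": model.W, "b": model.b, "Wp": model.Wp, "bp": model.bp}

    trace = TrainingTrace()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0
    corrupt = config.variant == "DAE" and config.swap_p > 0

    for epoch in range(config.max_epochs):
        order = rng_shuffle.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb = X_train[idx]
            Xin = swap_noise(Xb, config.swap_p, rng_noise) if corrupt else Xb
            value, grads = _loss_and_grads(config.variant, model, Xb, Xin, config)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} "
                    f"(variant={config.variant}, lr={config.learning_rate}, "
                    f"optimizer={config.optimizer})")
            opt.step(params, grads)
            epoch_loss += value
            n_batches += 1
        trace.train_losses.append(epoch_loss / max(n_batches, 1))

        val = loss(config.variant, model, X_val, X_val, config)
        trace.val_losses.append(val)
        if val < best_val:
            best_val = val
            best_params = {k: v.copy() for k, v in params.items()}
            trace.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    trace.stopped_epoch = len(trace.val_losses) - 1

    best = EncoderDecoder(W=best_params["W"], b=best_params["b"],
                          Wp=best_params["Wp"], bp=best_params["bp"],
                          act1=config.activation, act2=config.activation)
    return best, trace


def validation_split(X: np.ndarray, y: np.ndarray | None = None,
                     frac: float = 0.10, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hold out a validation slice for early stopping, stratified by ``y``
    when given. Returns (train_idx, val_idx)."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if y is None:
        order = rng.permutation(n)
        n_val = max(1, int(round(frac * n)))
        return np.sort(order[n_val:]), np.sort(order[:n_val])
    val_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(members.size)]
        n_val = max(1, int(round(frac * members.size)))
        val_idx.append(members[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    return train_idx, val_idx


def transform(model: EncoderDecoder, fitted_preprocessor, table) -> np.ndarray:
    """Preprocess a feature table with frozen statistics, then encode it."""
    processed = fitted_preprocessor.apply(table)
    return encode(model, processed.values)


def save_model(model: EncoderDecoder, path, config: AEConfig | None = None) -> None:
    """Checkpoint as portable JSON (shapes, activations, parameters, config)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    payload = {
        "act1": model.act1, "act2": model.act2,
        "shape": [model.latent_dim, model.m],
        "W": model.W.tolist(), "b": model.b.tolist(),
        "Wp": model.Wp.tolist(), "bp": model.bp.tolist(),
        "config": asdict(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> tuple[EncoderDecoder, AEConfig | None]:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    model = EncoderDecoder(
        W=np.array(d["W"]), b=np.array(d["b"]),
        Wp=np.array(d["Wp"]), bp=np.array(d["bp"]),
        act1=d["act1"], act2=d["act2"])
    config = AEConfig(**d["config"]) if d.get("config") else None
    return model, config
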