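"""Variational autoencoder for small item-response tables.

Architecture: a probabilistic encoder (items -> hidden ReLU layer ->
latent means and log-variances), a single reparameterized Monte-Carlo
draw z = mu + sigma * eps, and a mirror-image decoder (latent -> hidden
ReLU -> items, linear output).  The loss is the reconstruction error
(squared error summed over items, averaged over the batch) plus the
closed-form KL divergence between the diagonal-Gaussian posterior and a
standard-normal prior:

    KL = -1/2 * sum(1 + log s^2 - mu^2 - s^2).

Training uses Adam and k-fold cross-validation; the fold model with the
lowest held-out reconstruction error is retained and then encodes and
reconstructs the full sample.  Latent means serve as factor-score
estimates.  Everything is plain numpy with hand-written gradients, seeded
for bit-reproducible runs on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from .alignment import procrustes_align

__all__ = [
    "VAEConfig",
    "VAESolution",
    "train",
    "encode_scores",
    "reconstruct",
    "kl_divergence",
    "VAETrainingError",
]

_PARAM_NAMES = (
    "enc_w1", "enc_b1", "enc_wm", "enc_bm", "enc_wv", "enc_bv",
    "dec_w1", "dec_b1", "dec_w2", "dec_b2",
)


class VAETrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters; the defaults are the study's architecture."""

    n_items: int = 8
    latent_dim: int = 1
    hidden_units: int = 4
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 100
    k_folds: int = 10
    batch_size: int = 32
    kl_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.activation != "relu":
            raise ValueError("only relu hidden activations are supported")
        for name in ("n_items", "latent_dim", "hidden_units", "epochs",
                     "k_folds", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.latent_dim >= self.n_items:
            raise ValueError("latent_dim must be smaller than n_items")


@dataclass
class VAESolution:
    """Trained parameters plus per-subject latent statistics."""

    params: dict[str, np.ndarray]
    config: VAEConfig
    latent_mean: np.ndarray  # (subjects, q)
    latent_logvar: np.ndarray  # (subjects, q)
    sampled_z: np.ndarray  # (subjects, q), draw under sample_seed
    reconstructed: np.ndarray  # (subjects, items), from sampled_z
    reconstructed_mean: np.ndarray  # (subjects, items), from latent_mean
    fold_losses: np.ndarray  # (k,) held-out reconstruction MSE per fold
    selected_fold: int
    train_curve: np.ndarray  # per-epoch training loss of the selected fold
    sample_seed: int
    alignment: tuple | None = None


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Closed-form KL(N(mu, diag e^logvar) || N(0, I)) per row."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    return -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)


def _init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p, h, q = config.n_items, config.hidden_units, config.latent_dim

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return {
        "enc_w1": glorot(p, h), "enc_b1": np.zeros(h),
        "enc_wm": glorot(h, q), "enc_bm": np.zeros(q),
        "enc_wv": glorot(h, q), "enc_bv": np.zeros(q),
        "dec_w1": glorot(q, h), "dec_b1": np.zeros(h),
        "dec_w2": glorot(h, p), "dec_b2": np.zeros(p),
    }


def _encode(params, x):
    h1 = np.maximum(x @ params["enc_w1"] + params["enc_b1"], 0.0)
    mu = h1 @ params["enc_wm"] + params["enc_bm"]
    logvar = h1 @ params["enc_wv"] + params["enc_bv"]
    return h1, mu, logvar


def _decode(params, z):
    h2 = np.maximum(z @ params["dec_w1"] + params["dec_b1"], 0.0)
    return h2, h2 @ params["dec_w2"] + params["dec_b2"]


def _loss_and_grads(params, x, eps, kl_weight):
    """Batch loss and gradients through the reparameterized draw."""
    n_b = x.shape[0]
    h1, mu, logvar = _encode(params, x)
    s = np.exp(0.5 * logvar)
    z = mu + s * eps
    h2, xh = _decode(params, z)

    recon = float(np.sum((xh - x) ** 2) / n_b)
    kl = float(np.sum(kl_divergence(mu, logvar)) / n_b)
    loss = recon + kl_weight * kl

    g = {}
    dxh = 2.0 * (xh - x) / n_b
    g["dec_w2"] = h2.T @ dxh
    g["dec_b2"] = dxh.sum(axis=0)
    dh2 = (dxh @ params["dec_w2"].T) * (h2 > 0)
    g["dec_w1"] = z.T @ dh2
    g["dec_b1"] = dh2.sum(axis=0)
    dz = dh2 @ params["dec_w1"].T

    dmu = dz + kl_weight * mu / n_b
    dlogvar = dz * eps * 0.5 * s + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n_b
    g["enc_wm"] = h1.T @ dmu
    g["enc_bm"] = dmu.sum(axis=0)
    g["enc_wv"] = h1.T @ dlogvar
    g["enc_bv"] = dlogvar.sum(axis=0)
    dh1 = (dmu @ params["enc_wm"].T + dlogvar @ params["enc_wv"].T) * (h1 > 0)
    g["enc_w1"] = x.T @ dh1
    g["enc_b1"] = dh1.sum(axis=0)
    return loss, g


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _train_one(x_train, config: VAEConfig, init_seed: int, shuffle_seed: int):
    rng_init = np.random.default_rng(init_seed)
    rng = np.random.default_rng(shuffle_seed)
    params = _init_params(config, rng_init)
    opt = _Adam(params, config.learning_rate)
    n = x_train.shape[0]
    curve = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            loss, grads = _loss_and_grads(params, xb, eps, config.kl_weight)
            if not np.isfinite(loss):
                raise VAETrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.step(params, grads)
            losses.append(loss)
        curve[epoch] = np.mean(losses)
    return params, curve


def train(responses: np.ndarray, config: VAEConfig) -> VAESolution:
    """K-fold training; the fold with the best held-out reconstruction wins.

    Held-out performance is the mean squared reconstruction error of the
    deterministic (latent-mean) decode on the validation fold.  The selected
    model then encodes the full sample; the stored sampled draw regenerates
    exactly under the stored seed.
    """
    x = np.asarray(responses, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("responses must be finite")
    config.validate()
    if x.shape[1] != config.n_items:
        config = _replace_items(config, x.shape[1])

    ss = np.random.SeedSequence([config.seed, 0x7AE])
    children = ss.spawn(config.k_folds * 2 + 2)
    shuffle_master = int(children[-1].generate_state(1)[0] % 2**31)
    sample_seed = int(children[-2].generate_state(1)[0] % 2**31)

    kf = KFold(n_splits=config.k_folds, shuffle=True, random_state=shuffle_master)
    fold_params, fold_curves, fold_losses = [], [], []
    for fold, (tr_idx, va_idx) in enumerate(kf.split(x)):
        init_seed = int(children[2 * fold].generate_state(1)[0] % 2**31)
        shuf_seed = int(children[2 * fold + 1].generate_state(1)[0] % 2**31)
        try:
            params, curve = _train_one(x[tr_idx], config, init_seed, shuf_seed)
        except VAETrainingError as err:
            raise VAETrainingError(f"fold {fold}: {err}") from err
        _, mu, _ = _encode(params, x[va_idx])
        _, xh = _decode(params, mu)
        val_mse = float(np.mean((xh - x[va_idx]) ** 2))
        fold_params.append(params)
        fold_curves.append(curve)
        fold_losses.append(val_mse)

    best = int(np.argmin(fold_losses))
    params = fold_params[best]
    _, mu, logvar = _encode(params, x)
    eps = np.random.default_rng(sample_seed).standard_normal(mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps
    _, recon_sampled = _decode(params, z)
    _, recon_mean = _decode(params, mu)
    return VAESolution(
        params=params,
        config=config,
        latent_mean=mu,
        latent_logvar=logvar,
        sampled_z=z,
        reconstructed=recon_sampled,
        reconstructed_mean=recon_mean,
        fold_losses=np.asarray(fold_losses),
        selected_fold=best,
        train_curve=fold_curves[best],
        sample_seed=sample_seed,
    )


def _replace_items(config: VAEConfig, n_items: int) -> VAEConfig:
    d = asdict(config)
    d["n_items"] = n_items
    return VAEConfig(**d)


def encode_scores(
    solution: VAESolution,
    responses: np.ndarray,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Latent means as factor-score estimates, aligned to a reference.

    The latent space is identified only up to orthogonal rotation (sign in
    the one-factor case); the closest rotation onto ``reference`` (true
    scores in simulations) is applied.  Without a reference the first
    principal axes of the responses serve as the alignment target.
    """
    x = np.asarray(responses, dtype=float)
    if x.shape[1] != solution.config.n_items:
        raise ValueError(
            f"expected {solution.config.n_items} items, got {x.shape[1]}"
        )
    _, mu, _ = _encode(solution.params, x)
    if reference is None:
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        reference = xc @ vt[: solution.config.latent_dim].T
    reference = np.atleast_2d(np.asarray(reference, dtype=float).T).T
    aligned, rot = procrustes_align(mu, reference)
    solution.alignment = rot
    return aligned


def reconstruct(solution: VAESolution, mode: str = "sampled") -> np.ndarray:
    """Decode the latent draw (``sampled``) or the latent means (``mean``)."""
    if mode == "sampled":
        return solution.reconstructed
    if mode == "mean":
        return solution.reconstructed_mean
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# portable serialization (JSON keeps the deliverables text-only)


def save_solution(solution: VAESolution, path: str | Path) -> None:
    blob = {
        "config": asdict(solution.config),
        "params": {k: v.tolist() for k, v in solution.params.items()},
        "fold_losses": solution.fold_losses.tolist(),
        "selected_fold": solution.selected_fold,
        "sample_seed": solution.sample_seed,
    }
    Path(path).write_text(json.dumps(blob))


def load_solution(path: str | Path, responses: np.ndarray) -> VAESolution:
    """Rebuild a solution from disk; latent statistics are recomputed."""
    blob = json.loads(Path(path).read_text())
    config = VAEConfig(**blob["config"])
    params = {k: np.asarray(v) for k, v in blob["params"].items()}
    x = np.asarray(responses, dtype=float)
    _, mu, logvar = _encode(params, x)
    eps = np.random.default_rng(blob["sample_seed"]).standard_normal(mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps
    _, recon_sampled = _decode(params, z)
    _, recon_mean = _decode(params, mu)
    return VAESolution(
        params=params,
        config=config,
        latent_mean=mu,
        latent_logvar=logvar,
        sampled_z=z,
        reconstructed=recon_sampled,
        reconstructed_mean=recon_mean,
        fold_losses=np.asarray(blob["fold_losses"]),
        selected_fold=blob["selected_fold"],
        train_curve=np.array([]),
        sample_seed=blob["sample_seed"],
    )
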