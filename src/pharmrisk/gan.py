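"""Vanilla GAN for tabular PRR feature blocks, in pure NumPy.

A generator G maps latent Gaussian noise to k-dimensional feature vectors in
[0, 1]; a discriminator D scores vectors as real vs generated.  They play
the minimax game

    min_G max_D  E_x[log D(x)] + E_z[log(1 - D(G(z)))]

trained by alternating gradient steps: each minibatch the discriminator
ascends its objective, and after every ``d_steps_per_g_step`` discriminator
updates the generator takes one descent step.  Both networks are small
fully-connected MLPs (ReLU hidden layers, sigmoid output) optimised with
Adam; the training data are min-max normalised per feature to [0, 1] to
match the generator's sigmoid range, and samples are inverse-transformed
back to the PRR scale.

The generator's literal objective (descend log(1 - D(G(z)))) saturates when
the discriminator wins early, which on sparse PRR blocks leaves the
generator stuck emitting mid-range values; the default is therefore the
standard non-saturating surrogate (ascend log D(G(z))), with the literal
saturating loss available via ``GanConfig.generator_loss``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PreconditionError, TrainingDivergenceError

__all__ = ["GanConfig", "FeatureGan", "train_gan"]


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the feature GAN.

    Defaults are minimal stable settings for a ~1000 x 200 sparse PRR block:
    64-d noise, two 128-unit hidden layers in both networks, Adam at 2e-4,
    batch 64, one discriminator step per generator step, 2000 epochs.
    ``zero_threshold`` is the PRR-scale epsilon below which a generated
    entry counts as zero when measuring sparsity.
    """

    noise_dim: int = 64
    hidden: tuple[int, ...] = (128, 128)
    epochs: int = 2000
    batch_size: int = 64
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    d_steps_per_g_step: int = 1
    seed: int = 0
    zero_threshold: float = 0.01
    generator_loss: str = "non_saturating"  # or "saturating"
    log_scale: bool = True  # train on log1p(PRR) before min-max scaling

    def validate(self) -> None:
        counts = (self.noise_dim, self.epochs, self.batch_size, self.d_steps_per_g_step)
        if any(c <= 0 for c in counts) or any(h <= 0 for h in self.hidden):
            raise ConfigurationError("all GAN size/step counts must be positive")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.zero_threshold <= 0:
            raise ConfigurationError("zero_threshold must be positive")
        if self.generator_loss not in ("saturating", "non_saturating"):
            raise ConfigurationError(f"unknown generator_loss {self.generator_loss!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Mlp:
    """Fully-connected net, ReLU hidden + sigmoid output, with Adam state."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_t = 0
        self._m = [np.zeros_like(p) for p in self.W + self.b]
        self._v = [np.zeros_like(p) for p in self.W + self.b]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for layer, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = _sigmoid(z) if layer == len(self.W) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return h, acts

    def backward(
        self, acts: list[np.ndarray], dz_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Gradients of all parameters plus the input, from dL/dz of the
        output layer (sigmoid already folded in by the caller)."""
        dW = [np.empty(0)] * len(self.W)
        db = [np.empty(0)] * len(self.b)
        dz = dz_out
        for layer in range(len(self.W) - 1, -1, -1):
            dW[layer] = acts[layer].T @ dz
            db[layer] = dz.sum(axis=0)
            dh = dz @ self.W[layer].T
            if layer > 0:  # through the ReLU of the previous hidden layer
                dz = dh * (acts[layer] > 0)
            else:
                dz = dh
        return dW, db, dz

    def adam_step(self, dW: list[np.ndarray], db: list[np.ndarray], lr: float,
                  beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = dW + db
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g * g
            mhat = self._m[i] / (1 - beta1 ** t)
            vhat = self._v[i] / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class FeatureGan:
    """Trained generator/discriminator pair with its feature scaler."""

    def __init__(self, config: GanConfig, n_features: int):
        config.validate()
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng([2, config.seed])
        self._rng = rng
        self.G = _Mlp([config.noise_dim, *config.hidden, n_features], rng)
        self.D = _Mlp([n_features, *config.hidden, 1], rng)
        self.feature_min: np.ndarray | None = None
        self.feature_max: np.ndarray | None = None
        self.log: pd.DataFrame | None = None

    # -- scaling ---------------------------------------------------------
    # PRR values are heavy-tailed, so min-max on the raw scale crushes all
    # structure near zero; training on log1p(PRR) keeps the near-zero
    # region resolvable by the sigmoid output.
    def _pre(self, X: np.ndarray) -> np.ndarray:
        return np.log1p(X) if self.config.log_scale else X

    def _post(self, X: np.ndarray) -> np.ndarray:
        return np.expm1(X) if self.config.log_scale else X

    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        Xp = self._pre(X)
        self.feature_min = Xp.min(axis=0)
        self.feature_max = Xp.max(axis=0)
        return self._transform(X)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return (self._pre(X) - self.feature_min) / span

    def _inverse_transform(self, U: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        return self._post(self.feature_min + U * span)

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray) -> "FeatureGan":
        """Adversarial training on a raw-scale m x k feature block."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise PreconditionError("training block shape does not match the GAN")
        if X.shape[0] < cfg.batch_size:
            raise PreconditionError("need at least one full batch of training rows")
        if not np.isfinite(X).all():
            raise PreconditionError("training block contains non-finite values")
        Xn = self._fit_scaler(X)
        rng = self._rng
        m_total = Xn.shape[0]
        records = []
        step = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(m_total)
            dx_sum = dgz_sum = 0.0
            n_batches = 0
            for start in range(0, m_total - cfg.batch_size + 1, cfg.batch_size):
                real = Xn[order[start:start + cfg.batch_size]]
                m = real.shape[0]
                # --- discriminator ascent on log D(x) + log(1 - D(G(z)))
                z = rng.standard_normal((m, cfg.noise_dim))
                fake, _ = self.G.forward(z)
                y_real, acts_r = self.D.forward(real)
                y_fake, acts_f = self.D.forward(fake)
                dW_r, db_r, _ = self.D.backward(acts_r, (y_real - 1.0) / m)
                dW_f, db_f, _ = self.D.backward(acts_f, y_fake / m)
                self.D.adam_step(
                    [a + b for a, b in zip(dW_r, dW_f)],
                    [a + b for a, b in zip(db_r, db_f)],
                    cfg.lr_d,
                )
                step += 1
                # --- generator step every d_steps_per_g_step batches
                if step % cfg.d_steps_per_g_step == 0:
                    z = rng.standard_normal((m, cfg.noise_dim))
                    fake, acts_g = self.G.forward(z)
                    y_fake, acts_f = self.D.forward(fake)
                    if cfg.generator_loss == "saturating":
                        dz_d = -y_fake / m          # descend log(1 - D(G(z)))
                    else:
                        dz_d = (y_fake - 1.0) / m   # ascend log D(G(z))
                    _, _, d_input = self.D.backward(acts_f, dz_d)
                    # through the generator's sigmoid output
                    dz_g = d_input * acts_g[-1] * (1.0 - acts_g[-1])
                    dW_g, db_g, _ = self.G.backward(acts_g, dz_g)
                    self.G.adam_step(dW_g, db_g, cfg.lr_g)
                dx_sum += float(y_real.mean())
                dgz_sum += float(y_fake.mean())
                n_batches += 1
            eps = 1e-12
            d_x = dx_sum / n_batches
            d_gz = dgz_sum / n_batches
            d_loss = -(np.log(d_x + eps) + np.log(1 - d_gz + eps))
            if not np.isfinite(d_loss):
                raise TrainingDivergenceError(epoch)
            records.append({"epoch": epoch, "d_x": d_x, "d_gz": d_gz, "d_loss": d_loss})
        self.log = pd.DataFrame.from_records(records)
        return self

    # -- sampling --------------------------------------------------------
    def sample(self, n_rows: int, seed: int | None = None) -> np.ndarray:
        """Generate n_rows feature vectors on the original PRR scale."""
        if self.feature_min is None:
            raise PreconditionError("generator has not been trained")
        rng = np.random.default_rng([3, self.config.seed if seed is None else seed])
        z = rng.standard_normal((n_rows, self.config.noise_dim))
        u, _ = self.G.forward(z)
        return self._inverse_transform(u)

    def discriminate(self, X_raw: np.ndarray) -> np.ndarray:
        """Discriminator scores in (0, 1) for raw-scale rows."""
        y, _ = self.D.forward(self._transform(np.asarray(X_raw, dtype=float)))
        return y.ravel()


def train_gan(submatrix: np.ndarray, config: GanConfig) -> tuple[FeatureGan, pd.DataFrame]:
    """Train a GAN on a selected m x k PRR submatrix; returns (model, log)."""
    model = FeatureGan(config, n_features=np.asarray(submatrix).shape[1])
    model.fit(np.asarray(submatrix, dtype=float))
    return model, model.log
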