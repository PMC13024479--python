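"""Knowledge-distilled cross-sectional student models.

The student is a compact multi-head feed-forward network that consumes only
the pruned follow-up predictors and jointly predicts the three domain risks:

    input -> 128 (ReLU, dropout) -> 128 (ReLU, dropout)
          -> 32-dim linear embedding -> sigmoid head per domain

It trains under the composite distillation loss

    L = sum_d [ lambda * BCE(y_d, p_hat_d) + (1 - lambda) * (p_hat_d - p_tilde_d)^2 ]

mixing hard-label supervision with imitation of the teacher's out-of-fold
probabilities p_tilde.  ``lambda_mix = 1`` recovers the direct (non-
distilled) student with identical architecture.  The network and its AdamW
optimizer are implemented directly in numpy with explicit backpropagation,
which keeps training bit-reproducible under a fixed seed.

Inference consumes follow-up predictors alone — never baseline columns or
teacher outputs — which is asserted at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alscreen.teacher import FoldPlan

_CLIP = 1e-7


class StudentError(ValueError):
    pass


@dataclass(frozen=True)
class StudentConfig:
    """Student architecture and optimization hyperparameters."""

    hidden_layers: int = 2
    hidden_width: int = 128
    embedding_dim: int = 32
    dropout: float = 0.25
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    lambda_mix: float = 0.7
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise StudentError("lambda_mix must lie in [0, 1]")
        if self.hidden_layers != 2:
            raise StudentError("the student architecture has two hidden layers")
        if not 0.0 <= self.dropout < 1.0:
            raise StudentError("dropout must lie in [0, 1)")


def distill_loss(y, p_hat, p_tilde, lambda_mix: float) -> float:
    """Composite distillation loss for one individual (summed over domains).

    ``p_hat`` is clipped away from {0, 1} before the cross-entropy term.
    With ``lambda_mix = 1`` the teacher term vanishes and ``p_tilde`` may be
    ``None``.
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise StudentError("lambda_mix must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p_hat, dtype=float), _CLIP, 1 - _CLIP)
    bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    loss = lambda_mix * bce.sum()
    if lambda_mix < 1.0:
        if p_tilde is None:
            raise StudentError("distillation (lambda_mix < 1) requires teacher probabilities")
        pt = np.asarray(p_tilde, dtype=float)
        loss += (1 - lambda_mix) * ((p - pt) ** 2).sum()
    return float(loss)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Net:
    """The feed-forward network with explicit backprop and AdamW."""

    def __init__(self, n_in: int, n_heads: int, cfg: StudentConfig, rng: np.random.Generator):
        w = cfg.hidden_width
        e = cfg.embedding_dim
        def he(shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / shape[0])
        self.params = {
            "W1": he((n_in, w)), "b1": np.zeros(w),
            "W2": he((w, w)), "b2": np.zeros(w),
            "W3": he((w, e)), "b3": np.zeros(e),
            "W4": he((e, n_heads)), "b4": np.zeros(n_heads),
        }
        self.cfg = cfg
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)] for k, v in self.params.items()}
        self._t = 0

    def forward(self, X, rng: np.random.Generator | None = None):
        """Returns (probs, embedding, cache).  Dropout only when rng given."""
        P = self.params
        cfg = self.cfg
        z1 = X @ P["W1"] + P["b1"]
        h1 = np.maximum(z1, 0.0)
        if rng is not None and cfg.dropout > 0:
            m1 = (rng.random(h1.shape) >= cfg.dropout) / (1 - cfg.dropout)
            h1d = h1 * m1
        else:
            m1 = None
            h1d = h1
        z2 = h1d @ P["W2"] + P["b2"]
        h2 = np.maximum(z2, 0.0)
        if rng is not None and cfg.dropout > 0:
            m2 = (rng.random(h2.shape) >= cfg.dropout) / (1 - cfg.dropout)
            h2d = h2 * m2
        else:
            m2 = None
            h2d = h2
        emb = h2d @ P["W3"] + P["b3"]
        logits = emb @ P["W4"] + P["b4"]
        probs = _sigmoid(logits)
        cache = (X, z1, m1, h1d, z2, m2, h2d, emb)
        return probs, emb, cache

    def batch_loss(self, probs, y, p_tilde):
        lam = self.cfg.lambda_mix
        p = np.clip(probs, _CLIP, 1 - _CLIP)
        loss = lam * -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)
        if lam < 1.0:
            loss = loss + (1 - lam) * ((p - p_tilde) ** 2).sum(axis=1)
        return float(loss.mean())

    def backward(self, probs, y, p_tilde, cache):
        X, z1, m1, h1d, z2, m2, h2d, emb = cache
        P = self.params
        lam = self.cfg.lambda_mix
        B = len(X)
        # d loss / d logits
        dz = lam * (probs - y)
        if lam < 1.0:
            dz = dz + (1 - lam) * 2.0 * (probs - p_tilde) * probs * (1 - probs)
        dz /= B
        grads = {}
        grads["W4"] = emb.T @ dz
        grads["b4"] = dz.sum(axis=0)
        demb = dz @ P["W4"].T
        grads["W3"] = h2d.T @ demb
        grads["b3"] = demb.sum(axis=0)
        dh2d = demb @ P["W3"].T
        if m2 is not None:
            dh2d = dh2d * m2
        dz2 = dh2d * (z2 > 0)
        grads["W2"] = h1d.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dh1d = dz2 @ P["W2"].T
        if m1 is not None:
            dh1d = dh1d * m1
        dz1 = dh1d * (z1 > 0)
        grads["W1"] = X.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def adamw_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        cfg = self.cfg
        self._t += 1
        for k, p in self.params.items():
            m, v = self._adam[k]
            g = grads[k]
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= cfg.lr * (mhat / (np.sqrt(vhat) + eps))
            if cfg.weight_decay > 0 and k.startswith("W"):
                p -= cfg.lr * cfg.weight_decay * p

    def snapshot(self):
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap):
        for k in self.params:
            self.params[k][:] = snap[k]


@dataclass
class StudentResult:
    oof_probs: np.ndarray       # n x heads, strictly out-of-fold
    embeddings: np.ndarray      # n x embedding_dim, strictly out-of-fold
    diagnostics: list[dict] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    fold_models: list[StudentFoldModel] = field(default_factory=list)


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = np.nanmean(train, axis=0)
    sd = np.nanstd(train, axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    def f(a):
        a = (a - mu) / sd
        return np.where(np.isnan(a), 0.0, a)
    return f(train), f(other), mu, sd


@dataclass
class StudentFoldModel:
    """A fitted per-fold student: network plus its training-fold scaler."""

    net: "_Net"
    mu: np.ndarray
    sd: np.ndarray
    feature_names: list[str]


def _fit_one(
    X_tr, y_tr, pt_tr, X_val, y_val, pt_val, cfg: StudentConfig, rng: np.random.Generator
):
    net = _Net(X_tr.shape[1], y_tr.shape[1], cfg, rng)
    n = len(X_tr)
    best_val = np.inf
    best_snap = net.snapshot()
    best_epoch = 0
    bad = 0
    first_epoch_loss = None
    last_epoch_loss = None
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs, _, cache = net.forward(X_tr[idx], rng=rng)
            pt_b = None if pt_tr is None else pt_tr[idx]
            loss = net.batch_loss(probs, y_tr[idx], pt_b)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}"
                )
            losses.append(loss)
            grads = net.backward(probs, y_tr[idx], pt_b, cache)
            net.adamw_step(grads)
        epoch_loss = float(np.mean(losses))
        if first_epoch_loss is None:
            first_epoch_loss = epoch_loss
        last_epoch_loss = epoch_loss
        val_probs, _, _ = net.forward(X_val)
        val_loss = net.batch_loss(val_probs, y_val, pt_val)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_snap = net.snapshot()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    net.restore(best_snap)
    diag = {
        "first_epoch_loss": first_epoch_loss,
        "last_epoch_loss": last_epoch_loss,
        "best_epoch": best_epoch,
        "best_val_loss": float(best_val),
        "epochs_run": epoch + 1,
    }
    return net, diag


def train_student(
    X_M3: pd.DataFrame,
    y_M3: np.ndarray,
    teacher_probs: np.ndarray | None,
    plan: FoldPlan,
    config: StudentConfig | None = None,
) -> StudentResult:
    """Train the student per outer fold and emit out-of-fold probabilities.

    ``y_M3`` is n x heads (one column per domain); ``teacher_probs`` is the
    matching matrix of out-of-fold teacher probabilities, or ``None`` for
    the direct student (``lambda_mix`` must then be 1).  Each outer training
    split reserves an inner validation fraction for early stopping on the
    composite loss; features are standardized with training-fold statistics.
    """
    config = config or StudentConfig()
    config.validate()
    y = np.atleast_2d(np.asarray(y_M3, dtype=float))
    if y.shape[0] != plan.n:
        y = y.T
    if config.lambda_mix < 1.0 and teacher_probs is None:
        raise StudentError("distillation requires teacher probabilities")
    pt = None if teacher_probs is None else np.asarray(teacher_probs, dtype=float).reshape(y.shape)
    A = X_M3.to_numpy(dtype=float)
    n, heads = y.shape
    oof = np.full((n, heads), np.nan)
    embeddings = np.full((n, config.embedding_dim), np.nan)
    diagnostics = []
    fold_models: list[StudentFoldModel] = []
    for f, train, test in plan.split():
        rng = np.random.default_rng((config.seed, f))
        # inner validation split for early stopping
        perm = rng.permutation(len(train))
        n_val = max(1, int(round(config.val_fraction * len(train))))
        val_idx = train[perm[:n_val]]
        tr_idx = train[perm[n_val:]]
        X_tr, X_rest, mu, sd = _standardize(A[tr_idx], A[np.concatenate([val_idx, test])])
        X_val = X_rest[: len(val_idx)]
        X_te = X_rest[len(val_idx):]
        pt_tr = None if pt is None else pt[tr_idx]
        pt_val = None if pt is None else pt[val_idx]
        net, diag = _fit_one(
            X_tr, y[tr_idx], pt_tr, X_val, y[val_idx], pt_val, config, rng
        )
        probs, emb, _ = net.forward(X_te)
        oof[test] = probs
        embeddings[test] = emb
        diag["fold"] = f
        diagnostics.append(diag)
        fold_models.append(
            StudentFoldModel(net=net, mu=mu, sd=sd, feature_names=list(X_M3.columns))
        )
    return StudentResult(
        oof_probs=oof,
        embeddings=embeddings,
        diagnostics=diagnostics,
        feature_names=list(X_M3.columns),
        fold_models=fold_models,
    )


def predict_student(model: StudentFoldModel, X: pd.DataFrame) -> np.ndarray:
    """Cross-sectional inference guard: only the pruned follow-up features.

    Refuses inputs carrying baseline-wave columns or teacher-probability
    columns — the deployed student never sees them.
    """
    forbidden = [
        c for c in X.columns
        if c not in model.feature_names
        or "M2" in str(c)
        or str(c).startswith(("teacher", "p_tilde"))
    ]
    if forbidden:
        raise StudentError(
            f"student inference accepts only the pruned follow-up features; "
            f"got {forbidden}"
        )
    A = X[model.feature_names].to_numpy(dtype=float)
    A = (A - model.mu) / model.sd
    A = np.where(np.isnan(A), 0.0, A)
    probs, _, _ = model.net.forward(A)
    return probs
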