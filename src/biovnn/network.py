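"""Sparse feedforward engine shared by the pathway-structured network and its
matched dense baseline.

A network is a list of blocks evaluated in topological order.  Each block
reads either a slice of the input vector (leaf blocks) or the concatenation
of other blocks' states, and computes

    state = Dropout(BatchNorm(Mish(W q + b)))

Every non-root block carries a scalar auxiliary head (sigmoid-linear) trained
against the same label, so each block is an auxiliary classifier; the root
block carries the output head.

Batch normalization uses batch statistics while training.  Inference
statistics are recomputed after every epoch by a full pass over the training
samples ("precise" statistics) rather than a running average, which keeps the
forward pass purely functional for autodiff.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .errors import ConfigurationError, FingerprintError

BN_EPS = 1e-5


def mish(x):
    """x * tanh(softplus(x)) — smooth, nonmonotonic activation."""
    softplus = anp.maximum(x, 0.0) + anp.log1p(anp.exp(-anp.abs(x)))
    return x * anp.tanh(softplus)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def weighted_bce_with_logits(logits, y, neg_weight: float):
    """Binary cross-entropy from logits; the negative class is weighted by the
    training-set positive:negative ratio to counter class imbalance."""
    softplus_pos = anp.maximum(logits, 0.0) + anp.log1p(anp.exp(-anp.abs(logits)))
    # softplus(-z) = softplus(z) - z
    return y * (softplus_pos - logits) + neg_weight * (1.0 - y) * softplus_pos


@dataclass
class BlockSpec:
    """Wiring of one block: where its input comes from and its state size."""

    name: str
    out_size: int
    level: int
    x_indices: np.ndarray | None = None   # read these input columns ...
    children: list[str] = field(default_factory=list)  # ... or these blocks

    @property
    def reads_input(self) -> bool:
        return self.x_indices is not None


class SparseNet:
    """Topologically ordered blocks + auxiliary heads + root output head."""

    def __init__(self, specs: list[BlockSpec], root: str, n_inputs: int,
                 alpha: float = 0.3, lam: float = 1.0,
                 dropout_p: float = 0.5, seed: int = 0,
                 fingerprint_extra: str = ""):
        if not specs:
            raise ConfigurationError("cannot build a network with no blocks")
        names = [s.name for s in specs]
        if root not in names:
            raise ConfigurationError(f"root block {root!r} missing")
        self.specs = specs
        self.by_name = {s.name: s for s in specs}
        self.root = root
        self.n_inputs = n_inputs
        self.alpha = alpha
        self.lam = lam
        self.dropout_p = dropout_p
        self.neg_weight = 1.0
        self._in_sizes: dict[str, int] = {}
        for s in specs:
            if s.reads_input:
                if len(s.x_indices) == 0:
                    raise ConfigurationError(f"block {s.name!r} reads zero inputs")
                self._in_sizes[s.name] = len(s.x_indices)
            else:
                if not s.children:
                    raise ConfigurationError(f"block {s.name!r} has no inputs")
                self._in_sizes[s.name] = sum(self.by_name[c].out_size
                                             for c in s.children)
        self.fingerprint = self._fingerprint(fingerprint_extra)
        self.params = self._init_params(seed)
        self.bn_stats: dict[str, tuple[np.ndarray, np.ndarray]] = {
            s.name: (np.zeros(s.out_size), np.ones(s.out_size)) for s in specs
        }

    # -- construction -------------------------------------------------------

    def _fingerprint(self, extra: str) -> str:
        h = hashlib.sha256()
        h.update(extra.encode())
        h.update(str(self.n_inputs).encode())
        for s in self.specs:
            h.update(s.name.encode())
            h.update(str(s.out_size).encode())
            if s.reads_input:
                h.update(np.asarray(s.x_indices, dtype=np.int64).tobytes())
            else:
                h.update(",".join(s.children).encode())
        return h.hexdigest()

    def _init_params(self, seed: int) -> dict[str, np.ndarray]:
        """Kaiming (He) initialization: W ~ N(0, 2/fan_in), zero biases."""
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        for s in self.specs:
            fan_in = self._in_sizes[s.name]
            params[f"W:{s.name}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(s.out_size, fan_in))
            params[f"b:{s.name}"] = np.zeros(s.out_size)
            params[f"gamma:{s.name}"] = np.ones(s.out_size)
            params[f"beta:{s.name}"] = np.zeros(s.out_size)
            if s.name != self.root:
                params[f"auxW:{s.name}"] = rng.normal(
                    0.0, np.sqrt(2.0 / s.out_size), size=s.out_size)
                params[f"auxb:{s.name}"] = np.zeros(1)
        root_size = self.by_name[self.root].out_size
        params["headW"] = rng.normal(0.0, np.sqrt(2.0 / root_size), size=root_size)
        params["headb"] = np.zeros(1)
        return params

    # -- forward ------------------------------------------------------------

    def _forward(self, params, X, training: bool,
                 dropout_masks: dict[str, np.ndarray] | None):
        """Returns (root logit vector, aux logit dict, state dict)."""
        states: dict[str, anp.ndarray] = {}
        aux: dict[str, anp.ndarray] = {}
        for s in self.specs:
            if s.reads_input:
                q = X[:, s.x_indices]
            else:
                q = anp.concatenate([states[c] for c in s.children], axis=1)
            a = mish(q @ params[f"W:{s.name}"].T + params[f"b:{s.name}"])
            if training:
                mu = anp.mean(a, axis=0)
                var = anp.var(a, axis=0)
            else:
                mu, var = self.bn_stats[s.name]
            h = (a - mu) / anp.sqrt(var + BN_EPS)
            h = h * params[f"gamma:{s.name}"] + params[f"beta:{s.name}"]
            if dropout_masks is not None and s.name in dropout_masks:
                h = h * dropout_masks[s.name]
            states[s.name] = h
            if s.name != self.root:
                aux[s.name] = h @ params[f"auxW:{s.name}"] + params[f"auxb:{s.name}"]
        root_logit = states[self.root] @ params["headW"] + params["headb"]
        return root_logit, aux, states

    def make_dropout_masks(self, batch_size: int,
                           rng: np.random.Generator) -> dict[str, np.ndarray]:
        keep = 1.0 - self.dropout_p
        return {
            s.name: rng.binomial(1, keep, size=(batch_size, s.out_size)) / keep
            for s in self.specs
        }

    def forward(self, X: np.ndarray, collect_states: bool = False):
        """Inference pass: root probabilities, optional per-block states, and
        per-block auxiliary probabilities.  Deterministic (dropout off,
        normalization uses stored statistics)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected input of width {self.n_inputs}, got shape {X.shape}")
        root_logit, aux, states = self._forward(self.params, X, False, None)
        probs = sigmoid(root_logit)
        aux_probs = {k: sigmoid(v) for k, v in aux.items()}
        return (probs, states if collect_states else None, aux_probs)

    def predict(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        out = []
        for start in range(0, len(X), batch_size):
            out.append(self.forward(X[start:start + batch_size])[0])
        return np.concatenate(out) if out else np.zeros(0)

    # -- objective ----------------------------------------------------------

    def loss_value(self, params, X, y, dropout_masks, include_reg: bool = True,
                   training: bool = True):
        """Training objective: weighted BCE at the root, alpha-scaled sum of
        per-block auxiliary BCEs, plus lam * sum of squared weights."""
        root_logit, aux, _ = self._forward(params, X, training, dropout_masks)
        per_sample = weighted_bce_with_logits(root_logit, y, self.neg_weight)
        for name, logits in aux.items():
            per_sample = per_sample + self.alpha * weighted_bce_with_logits(
                logits, y, self.neg_weight)
        total = anp.mean(per_sample)
        if include_reg and self.lam > 0:
            reg = 0.0
            for key, value in params.items():
                if key.startswith(("W:", "auxW:")) or key == "headW":
                    reg = reg + anp.sum(value ** 2)
            total = total + self.lam * reg
        return total

    def loss(self, X, y, include_reg: bool = True) -> float:
        """Evaluation-mode objective on plain arrays (no dropout)."""
        y = np.asarray(y, dtype=np.float64)
        if np.any((y != 0) & (y != 1)):
            raise ValueError("labels must be binary (0/1)")
        return float(self.loss_value(self.params, np.asarray(X, float), y,
                                     None, include_reg, training=False))

    def loss_and_grad(self, X, y, dropout_masks):
        y = np.asarray(y, dtype=np.float64)
        if np.any((y != 0) & (y != 1)):
            raise ValueError("labels must be binary (0/1)")
        fn = value_and_grad(
            lambda p: self.loss_value(p, X, y, dropout_masks))
        return fn(self.params)

    def loss_and_grad_manual(self, X, y, dropout_masks):
        """Hand-derived backward pass for the training objective.

        Functionally identical to :meth:`loss_and_grad` (which differentiates
        the forward pass with autograd) but avoids tracing overhead; the two
        are cross-checked in the test suite."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if np.any((y != 0) & (y != 1)):
            raise ValueError("labels must be binary (0/1)")
        B = len(X)
        w = self.neg_weight
        p = self.params

        # ---- forward, caching intermediates per block
        cache: dict[str, dict] = {}
        states: dict[str, np.ndarray] = {}
        loss_bce = np.zeros(B)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit: dict[str, np.ndarray] = {}
        for s in self.specs:
            if s.reads_input:
                q = X[:, s.x_indices]
            else:
                q = np.concatenate([states[c] for c in s.children], axis=1)
            z1 = q @ p[f"W:{s.name}"].T + p[f"b:{s.name}"]
            sp = np.maximum(z1, 0.0) + np.log1p(np.exp(-np.abs(z1)))
            tsp = np.tanh(sp)
            a = z1 * tsp
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            xhat = (a - mu) * inv_std
            h = xhat * p[f"gamma:{s.name}"] + p[f"beta:{s.name}"]
            mask = dropout_masks.get(s.name) if dropout_masks else None
            hd = h * mask if mask is not None else h
            states[s.name] = hd
            cache[s.name] = dict(q=q, z1=z1, sp=sp, tsp=tsp, xhat=xhat,
                                 inv_std=inv_std, mask=mask)
            if s.name != self.root:
                logit = hd @ p[f"auxW:{s.name}"] + p[f"auxb:{s.name}"]
                sig = 0.5 * (np.tanh(0.5 * logit) + 1.0)
                spl = np.maximum(logit, 0.0) + np.log1p(np.exp(-np.abs(logit)))
                loss_bce += self.alpha * (y * (spl - logit) + w * (1 - y) * spl)
                dlogit[s.name] = (self.alpha / B) * (
                    y * (sig - 1.0) + w * (1 - y) * sig)
        root_logit = states[self.root] @ p["headW"] + p["headb"]
        sig = 0.5 * (np.tanh(0.5 * root_logit) + 1.0)
        spl = np.maximum(root_logit, 0.0) + np.log1p(np.exp(-np.abs(root_logit)))
        loss_bce += y * (spl - root_logit) + w * (1 - y) * spl
        droot = (1.0 / B) * (y * (sig - 1.0) + w * (1 - y) * sig)

        loss = float(loss_bce.mean())
        if self.lam > 0:
            loss += self.lam * self.weight_norm()

        # ---- backward, reverse topological order
        dstate = {s.name: np.zeros((B, s.out_size)) for s in self.specs}
        dstate[self.root] += np.outer(droot, p["headW"])
        grads["headW"] += droot @ states[self.root]
        grads["headb"] += np.array([droot.sum()])
        for s in reversed(self.specs):
            c = cache[s.name]
            if s.name != self.root:
                dl = dlogit[s.name]
                grads[f"auxW:{s.name}"] += dl @ states[s.name]
                grads[f"auxb:{s.name}"] += np.array([dl.sum()])
                dstate[s.name] += np.outer(dl, p[f"auxW:{s.name}"])
            dh = dstate[s.name]
            if c["mask"] is not None:
                dh = dh * c["mask"]
            # batch-norm backward (batch statistics)
            gamma = p[f"gamma:{s.name}"]
            grads[f"gamma:{s.name}"] += (dh * c["xhat"]).sum(axis=0)
            grads[f"beta:{s.name}"] += dh.sum(axis=0)
            dxhat = dh * gamma
            da = (c["inv_std"] / B) * (
                B * dxhat - dxhat.sum(axis=0)
                - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0))
            # Mish backward: d/dz [z tanh(softplus(z))]
            z1, tsp = c["z1"], c["tsp"]
            sig_z = 0.5 * (np.tanh(0.5 * z1) + 1.0)
            dz1 = da * (tsp + z1 * (1.0 - tsp ** 2) * sig_z)
            grads[f"W:{s.name}"] += dz1.T @ c["q"]
            grads[f"b:{s.name}"] += dz1.sum(axis=0)
            dq = dz1 @ p[f"W:{s.name}"]
            if not s.reads_input:
                off = 0
                for child in s.children:
                    size = self.by_name[child].out_size
                    dstate[child] += dq[:, off:off + size]
                    off += size
        if self.lam > 0:
            for key, value in p.items():
                if key.startswith(("W:", "auxW:")) or key == "headW":
                    grads[key] += 2.0 * self.lam * value
        return loss, grads

    def weight_norm(self) -> float:
        """Sum of squared entries of every weight matrix/vector (no biases)."""
        return float(sum(np.sum(v ** 2) for k, v in self.params.items()
                         if k.startswith(("W:", "auxW:")) or k == "headW"))

    # -- batch-norm statistics ----------------------------------------------

    def update_bn_stats(self, X: np.ndarray) -> None:
        """Set inference normalization statistics from a pass over ``X``.

        Blocks are processed in order so deeper blocks see children already
        normalized with their new statistics, matching the inference path."""
        X = np.asarray(X, dtype=np.float64)
        states: dict[str, np.ndarray] = {}
        for s in self.specs:
            if s.reads_input:
                q = X[:, s.x_indices]
            else:
                q = np.concatenate([states[c] for c in s.children], axis=1)
            a = mish(q @ self.params[f"W:{s.name}"].T + self.params[f"b:{s.name}"])
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            self.bn_stats[s.name] = (mu, var)
            h = (a - mu) / np.sqrt(var + BN_EPS)
            states[s.name] = h * self.params[f"gamma:{s.name}"] \
                + self.params[f"beta:{s.name}"]

    # -- accounting & persistence -------------------------------------------

    def count_parameters(self) -> int:
        """All trainable scalars: weights, biases, normalization affine
        parameters and both kinds of heads."""
        return int(sum(v.size for v in self.params.values()))

    def state_copy(self):
        return ({k: v.copy() for k, v in self.params.items()},
                {k: (m.copy(), v.copy()) for k, (m, v) in self.bn_stats.items()})

    def load_state(self, state) -> None:
        params, bn = state
        self.params = {k: v.copy() for k, v in params.items()}
        self.bn_stats = {k: (m.copy(), v.copy()) for k, (m, v) in bn.items()}

    def save(self, path: str | Path) -> None:
        arrays = {f"param.{k}": v for k, v in self.params.items()}
        for k, (m, v) in self.bn_stats.items():
            arrays[f"bn_mean.{k}"] = m
            arrays[f"bn_var.{k}"] = v
        np.savez(path, fingerprint=np.array(self.fingerprint),
                 neg_weight=np.array(self.neg_weight), **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path, allow_pickle=False) as data:
            stored = str(data["fingerprint"])
            if stored != self.fingerprint:
                raise FingerprintError(
                    "checkpoint was built for a different ontology/architecture "
                    f"(fingerprint {stored[:12]}... != {self.fingerprint[:12]}...)")
            self.neg_weight = float(data["neg_weight"])
            for key in data.files:
                if key.startswith("param."):
                    self.params[key[len("param."):]] = data[key]
                elif key.startswith("bn_mean."):
                    name = key[len("bn_mean."):]
                    self.bn_stats[name] = (data[key],
                                           data[f"bn_var.{name}"])
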