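"""Fingerprint-conditioned stochastic policy over transformation actions.

Architecture: a shared two-layer ReLU backbone (2048-bit Morgan fingerprint
input, hidden width 512) feeding three parallel heads — an action head
(three layers, width 512, 33 logits), a core-fragment head (three layers,
width 256, one logit per library fragment) and a decoration head (three
layers, width 256, 7 logits).  Heads see only the backbone features of the
current molecule; they are not conditioned on the sampled action.

Sampling applies temperature scaling to the logits first and nucleus
(top-p) truncation second: the smallest prefix of descending-sorted
probabilities whose cumulative mass reaches ``top_p`` is kept and
renormalized.  Log-probabilities used by the policy-gradient step are taken
under this truncated distribution — the law actually sampled from.

The network and its gradients are implemented in plain numpy (float64):
the model is small enough that explicit backpropagation through the dense
layers is both fast and exactly checkable against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .properties import FINGERPRINT_BITS, fingerprint_array
from .records import MoleculeRecord
from .transforms import N_ACTIONS, STOP_ACTION

N_DECORATIONS = 7


@dataclass
class PolicyConfig:
    fingerprint_bits: int = FINGERPRINT_BITS
    fingerprint_radius: int = 2
    backbone_width: int = 512
    action_head_width: int = 512
    fragment_head_width: int = 256
    n_actions: int = N_ACTIONS
    n_core_fragments: int = 16
    n_decorations: int = N_DECORATIONS
    temperature: float = 1.0
    top_p: float = 0.95

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.top_p <= 1:
            raise ValueError("top_p must lie in (0, 1]")


@dataclass(frozen=True)
class ActionDistribution:
    action_probs: np.ndarray
    core_probs: np.ndarray
    decoration_probs: np.ndarray


class _MLP:
    """Dense ReLU stack; the final layer is linear (logits)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.weights = []
        self.biases = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            # He (fan-in) initialization, appropriate for ReLU stacks
            scale = np.sqrt(2.0 / n_in)
            self.weights.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.biases.append(np.zeros(n_out))

    def forward(self, x: np.ndarray, *, relu_output: bool = False):
        """Forward pass; ``x`` may be one vector or a (batch, in) matrix."""
        acts = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last or relu_output:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def backward(self, acts, dout: np.ndarray, *, relu_output: bool = False):
        """Gradient of a scalar loss w.r.t. params and input.

        ``dout`` is dL/d(output), one row per batch element (or a single
        vector); batch rows are summed into the parameter gradients.
        Returns (dx, [(dW, db), ...]).
        """
        single = dout.ndim == 1
        d = np.atleast_2d(dout)
        grads = [None] * len(self.weights)
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            if i < last or relu_output:
                d = d * (np.atleast_2d(acts[i + 1]) > 0)
            a = np.atleast_2d(acts[i])
            grads[i] = (a.T @ d, d.sum(axis=0))
            d = d @ self.weights[i].T
        dx = d[0] if single else d
        return dx, grads

    def params(self):
        for w, b in zip(self.weights, self.biases):
            yield w
            yield b


class PolicyNetwork:
    """Backbone + three heads with explicit forward/backward passes."""

    def __init__(self, config: PolicyConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        c = config
        self.backbone = _MLP(
            [c.fingerprint_bits, c.backbone_width, c.backbone_width], rng)
        self.action_head = _MLP(
            [c.backbone_width, c.action_head_width, c.action_head_width,
             c.n_actions], rng)
        self.core_head = _MLP(
            [c.backbone_width, c.fragment_head_width, c.fragment_head_width,
             c.n_core_fragments], rng)
        self.decoration_head = _MLP(
            [c.backbone_width, c.fragment_head_width, c.fragment_head_width,
             c.n_decorations], rng)
        # near-zero final layers start each head at a near-uniform policy,
        # so learning shapes preferences instead of unlearning init noise
        for head in (self.action_head, self.core_head, self.decoration_head):
            head.weights[-1] *= 0.01

    # -- forward ------------------------------------------------------------

    def _features(self, mol) -> np.ndarray:
        if isinstance(mol, np.ndarray):
            return mol
        if isinstance(mol, MoleculeRecord):
            return fingerprint_array(mol)
        raise TypeError("expected MoleculeRecord or fingerprint array")

    def logits(self, mol):
        x = self._features(mol)
        feats, bb_acts = self.backbone.forward(x, relu_output=True)
        za, a_acts = self.action_head.forward(feats)
        zc, c_acts = self.core_head.forward(feats)
        zd, d_acts = self.decoration_head.forward(feats)
        caches = {"x": x, "backbone": bb_acts, "action": a_acts,
                  "core": c_acts, "decoration": d_acts}
        return (za, zc, zd), caches

    def forward(self, mol) -> ActionDistribution:
        (za, zc, zd), _ = self.logits(mol)
        t = self.config.temperature
        return ActionDistribution(
            action_probs=softmax(za / t),
            core_probs=softmax(zc / t),
            decoration_probs=softmax(zd / t),
        )

    # -- backward -----------------------------------------------------------

    def backward(self, caches, d_action, d_core, d_decoration):
        """Accumulate parameter gradients from per-head dL/dlogits."""
        dfa, ga = self.action_head.backward(caches["action"], d_action)
        dfc, gc = self.core_head.backward(caches["core"], d_core)
        dfd, gd = self.decoration_head.backward(caches["decoration"],
                                                d_decoration)
        _, gb = self.backbone.backward(caches["backbone"], dfa + dfc + dfd,
                                       relu_output=True)
        return {"backbone": gb, "action": ga, "core": gc, "decoration": gd}

    # -- parameter plumbing --------------------------------------------------

    def named_mlps(self):
        return {"backbone": self.backbone, "action": self.action_head,
                "core": self.core_head, "decoration": self.decoration_head}

    def flat_params(self) -> list[np.ndarray]:
        out = []
        for name in ("backbone", "action", "core", "decoration"):
            out.extend(self.named_mlps()[name].params())
        return out

    def zero_grads(self):
        return {
            name: [(np.zeros_like(w), np.zeros_like(b))
                   for w, b in zip(mlp.weights, mlp.biases)]
            for name, mlp in self.named_mlps().items()
        }

    # -- persistence ---------------------------------------------------------

    def save_checkpoint(self, path: str) -> None:
        arrays = {}
        for name, mlp in self.named_mlps().items():
            for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
                arrays[f"{name}_w{i}"] = w
                arrays[f"{name}_b{i}"] = b
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.__dict__).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path: str) -> "PolicyNetwork":
        try:
            data = np.load(path, allow_pickle=False)
            cfg = PolicyConfig(**json.loads(bytes(data["config_json"]).decode()))
        except Exception as exc:
            raise IOError(f"cannot load checkpoint {path!r}: {exc}") from exc
        net = cls(cfg, rng_seed=0)
        for name, mlp in net.named_mlps().items():
            for i in range(len(mlp.weights)):
                mlp.weights[i] = data[f"{name}_w{i}"]
                mlp.biases[i] = data[f"{name}_b{i}"]
        return net


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def nucleus_truncate(probs: np.ndarray, top_p: float):
    """Smallest descending-probability prefix with cumulative mass >= top_p.

    Returns (support indices, renormalized probabilities over the support).
    """
    if probs.sum() <= 0:
        raise ValueError("degenerate all-zero probability vector")
    order = np.argsort(-probs, kind="stable")
    csum = np.cumsum(probs[order])
    k = int(np.searchsorted(csum, top_p - 1e-12)) + 1
    k = min(k, len(order))
    support = order[:k]
    renorm = probs[support] / probs[support].sum()
    return support, renorm


def nucleus_sample(probs: np.ndarray, top_p: float,
                   rng: np.random.Generator | int):
    """Draw an index by nucleus sampling.

    Returns (index, log-probability of the draw under the truncated,
    renormalized distribution).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    support, renorm = nucleus_truncate(np.asarray(probs, dtype=float), top_p)
    j = int(rng.choice(len(support), p=renorm))
    return int(support[j]), float(np.log(renorm[j]))


def masked_action_probs(action_logits: np.ndarray, temperature: float,
                        mask_stop: bool) -> np.ndarray:
    """Action probabilities with the STOP action optionally masked out."""
    z = action_logits / temperature
    if mask_stop:
        z = z.copy()
        z[STOP_ACTION] = -np.inf
    return softmax(z)
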