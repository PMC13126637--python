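"""Episodic REINFORCE training of the transformation policy.

Each episode starts from a source molecule and applies sampled actions until
STOP is selected (forbidden at the first step) or the step limit M is
reached.  The terminal reward balances synthetic accessibility and
drug-likeness,

    R = 0.5 * SA_norm(m_gen) + 0.5 * QED(m_gen),    SA_norm = 1 - (SA-1)/9,

with a -0.05 penalty when the generated molecule is identical to its
source.  The gradient estimator is episodic REINFORCE with a per-source
baseline (exponential moving average, decay 0.9, updated only after the
15-episode batch for a source) and entropy regularization over the three
heads' truncated sampling distributions.  Gradients are averaged over the
batch, clipped at global norm 1.0 and applied with Adam (lr 1e-4).

Training follows a curriculum: epoch 0 is seeded from methane alone; each
later epoch draws its sources uniformly without replacement from the unique
molecules generated in the previous epoch.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fragments import DECORATIONS, FragmentLibrary
from .properties import fingerprint_array, qed_score, sa_score, tanimoto_mols
from .records import MoleculeRecord
from .transforms import (
    ACTION_CATALOG,
    DEFAULT_CORE_FRAGMENTS,
    STOP_ACTION,
    apply_action,
)
from .policy import (
    PolicyConfig,
    PolicyNetwork,
    masked_action_probs,
    nucleus_sample,
    nucleus_truncate,
    softmax,
)

METHANE = "C"


@dataclass
class TrainerConfig:
    max_steps: int = 1                 # M, transformation steps per episode
    episodes_per_source: int = 15
    baseline_decay: float = 0.9        # alpha
    entropy_coeff: float = 0.01        # beta
    learning_rate: float = 1e-4
    grad_clip_norm: float = 1.0
    epochs: int = 100
    epoch_sample_size: int = 5000
    identity_penalty: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("max_steps", "episodes_per_source", "baseline_decay",
                     "learning_rate", "grad_clip_norm", "epochs",
                     "epoch_sample_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.entropy_coeff < 0 or self.identity_penalty < 0:
            raise ValueError("coefficients must be non-negative")


@dataclass(frozen=True)
class RewardBreakdown:
    sa_raw: float
    sa_norm: float
    qed: float
    penalty_applied: bool
    reward: float


@dataclass(frozen=True)
class EpisodeStep:
    fingerprint: np.ndarray
    action: int
    fragment_index: Optional[int]
    decoration_index: Optional[int]
    stop_masked: bool
    log_prob: float


@dataclass(frozen=True)
class Episode:
    source: MoleculeRecord
    steps: tuple
    final: MoleculeRecord
    reward: float
    breakdown: Optional["RewardBreakdown"] = None

    @property
    def n_transform_steps(self) -> int:
        return sum(1 for s in self.steps if s.action != STOP_ACTION)


def compute_reward(source: MoleculeRecord, generated: MoleculeRecord,
                   identity_penalty: float = 0.05) -> RewardBreakdown:
    sa_raw = sa_score(generated)
    sa_norm = 1.0 - (sa_raw - 1.0) / 9.0
    qed = qed_score(generated)
    identical = generated.smiles == source.smiles
    reward = 0.5 * sa_norm + 0.5 * qed - (identity_penalty if identical else 0.0)
    return RewardBreakdown(sa_raw=sa_raw, sa_norm=sa_norm, qed=qed,
                           penalty_applied=identical, reward=reward)


def _fragment_smiles(index: int, library: Optional[FragmentLibrary]) -> str:
    if library is not None and len(library) > 0:
        return library.sample_fragment(index % len(library))
    return DEFAULT_CORE_FRAGMENTS[index % len(DEFAULT_CORE_FRAGMENTS)]


def policy_rollout(policy: PolicyNetwork, source: MoleculeRecord,
                   max_steps: int, rng: np.random.Generator,
                   library: Optional[FragmentLibrary] = None,
                   record_steps: bool = True):
    """Run one policy episode; returns (final molecule, steps tuple)."""
    cfg = policy.config
    state = source
    steps = []
    for t in range(max_steps):
        fp = fingerprint_array(state)
        (za, zc, zd), _ = policy.logits(fp)
        mask = t == 0
        p_a = masked_action_probs(za, cfg.temperature, mask_stop=mask)
        action, logp = nucleus_sample(p_a, cfg.top_p, rng)
        if action == STOP_ACTION:
            if record_steps:
                steps.append(EpisodeStep(fp, action, None, None, mask, logp))
            break
        spec = ACTION_CATALOG[action]
        frag_idx = deco_idx = None
        core = deco = None
        if spec.needs_core_fragment:
            frag_idx, lp_c = nucleus_sample(softmax(zc / cfg.temperature),
                                            cfg.top_p, rng)
            core = _fragment_smiles(frag_idx, library)
            logp += lp_c
        if spec.needs_decoration:
            deco_idx, lp_d = nucleus_sample(softmax(zd / cfg.temperature),
                                            cfg.top_p, rng)
            deco = DECORATIONS[deco_idx]
            logp += lp_d
        result = apply_action(state, action, int(rng.integers(2 ** 31)),
                              core_fragment=core, decoration=deco,
                              library=library)
        if result.status == "success":
            state = result.molecule
        if record_steps:
            steps.append(EpisodeStep(fp, action, frag_idx, deco_idx, mask, logp))
    return state, tuple(steps)


def run_episode(policy: PolicyNetwork, source: MoleculeRecord, max_steps: int,
                rng: np.random.Generator | int,
                library: Optional[FragmentLibrary] = None,
                identity_penalty: float = 0.05) -> Episode:
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    final, steps = policy_rollout(policy, source, max_steps, rng, library)
    breakdown = compute_reward(source, final, identity_penalty)
    return Episode(source=source, steps=steps, final=final,
                   reward=breakdown.reward, breakdown=breakdown)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def _dlogp(n: int, probs_masked: np.ndarray, sampled: int, top_p: float,
           temperature: float) -> np.ndarray:
    """d log p_trunc(sampled) / d logits for a temperature softmax head."""
    support, renorm = nucleus_truncate(probs_masked, top_p)
    grad = np.zeros(n)
    pos = {int(i): k for k, i in enumerate(support)}
    for i, k in pos.items():
        grad[i] = ((1.0 if i == sampled else 0.0) - renorm[k]) / temperature
    return grad


def _dentropy(n: int, probs_masked: np.ndarray, top_p: float,
              temperature: float) -> tuple[float, np.ndarray]:
    """Entropy of the truncated distribution and its logits gradient."""
    support, renorm = nucleus_truncate(probs_masked, top_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(renorm > 0, np.log(np.maximum(renorm, 1e-300)), 0.0)
    ent = float(-(renorm * logs).sum())
    grad = np.zeros(n)
    for k, i in enumerate(support):
        if renorm[k] > 0:
            grad[int(i)] = -renorm[k] * (logs[k] + ent) / temperature
    return ent, grad


def episode_gradients(policy: PolicyNetwork, episodes, baseline: float,
                      config: TrainerConfig):
    """Averaged REINFORCE + entropy gradient of the surrogate loss.

    Loss = -mean_ep[(R - b) * sum_steps log-probs]
           - beta * mean_ep[mean_steps (H_action + H_core + H_decoration)].
    Returns (grads, mean_entropy).  Assumes policy weights are unchanged
    since the episodes were sampled, so forward passes are recomputed here.
    """
    cfg = policy.config
    n_ep = len(episodes)
    rows = [(ep, step) for ep in episodes for step in ep.steps]
    if not rows:
        return policy.zero_grads(), 0.0
    X = np.stack([step.fingerprint for _, step in rows])
    (ZA, ZC, ZD), caches = policy.logits(X)
    DZA = np.zeros_like(ZA)
    DZC = np.zeros_like(ZC)
    DZD = np.zeros_like(ZD)
    total_entropy = 0.0
    for r, (ep, step) in enumerate(rows):
        # fold the 1/n_ep batch average into the per-row coefficients
        adv = (ep.reward - baseline) / n_ep
        n_steps = max(1, len(ep.steps))
        p_a = masked_action_probs(ZA[r], cfg.temperature,
                                  mask_stop=step.stop_masked)
        p_c = softmax(ZC[r] / cfg.temperature)
        p_d = softmax(ZD[r] / cfg.temperature)

        DZA[r] = -adv * _dlogp(ZA.shape[1], p_a, step.action, cfg.top_p,
                               cfg.temperature)
        if step.fragment_index is not None:
            DZC[r] = -adv * _dlogp(ZC.shape[1], p_c, step.fragment_index,
                                   cfg.top_p, cfg.temperature)
        if step.decoration_index is not None:
            DZD[r] = -adv * _dlogp(ZD.shape[1], p_d, step.decoration_index,
                                   cfg.top_p, cfg.temperature)

        # entropy is regularized on the full softmax policy (top_p = 1), not
        # the truncated sampling law: truncated entropy vanishes along with
        # its gradient once one action exceeds top_p, so it cannot stop the
        # positive-feedback collapse onto a single action
        ha, dha = _dentropy(ZA.shape[1], p_a, 1.0, cfg.temperature)
        hc, dhc = _dentropy(ZC.shape[1], p_c, 1.0, cfg.temperature)
        hd, dhd = _dentropy(ZD.shape[1], p_d, 1.0, cfg.temperature)
        total_entropy += (ha + hc + hd) / (n_steps * n_ep)
        scale = config.entropy_coeff / (n_steps * n_ep)
        DZA[r] -= scale * dha
        DZC[r] -= scale * dhc
        DZD[r] -= scale * dhd
    grads = policy.backward(caches, DZA, DZC, DZD)
    return grads, total_entropy


def clip_gradients(grads, max_norm: float) -> float:
    """Scale gradients in place to a global L2 norm cap; returns the norm."""
    sq = 0.0
    for layers in grads.values():
        for gw, gb in layers:
            sq += float((gw ** 2).sum() + (gb ** 2).sum())
    norm = math.sqrt(sq)
    if norm > max_norm:
        factor = max_norm / norm
        for layers in grads.values():
            for gw, gb in layers:
                gw *= factor
                gb *= factor
    return norm


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float = 1e-4):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = None
        self.v = None

    def _init_state(self, grads):
        zero = lambda: {name: [(np.zeros_like(w), np.zeros_like(b))
                               for w, b in layers]
                        for name, layers in grads.items()}
        self.m = zero()
        self.v = zero()

    def step(self, policy: PolicyNetwork, grads) -> None:
        if self.m is None:
            self._init_state(grads)
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for name, mlp in policy.named_mlps().items():
            for layer in range(len(mlp.weights)):
                for kind, param in ((0, mlp.weights[layer]),
                                    (1, mlp.biases[layer])):
                    g = grads[name][layer][kind]
                    m = self.m[name][layer][kind]
                    v = self.v[name][layer][kind]
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    param -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def policy_gradient_update(policy: PolicyNetwork, episodes, baseline: float,
                           config: TrainerConfig, optimizer: Adam) -> float:
    """One REINFORCE update from a batch of same-source episodes.

    Returns the post-batch baseline
    ``alpha * baseline + (1 - alpha) * mean(R)``.
    """
    sources = {ep.source.smiles for ep in episodes}
    if len(sources) != 1:
        raise ValueError("all episodes in a batch must share one source")
    grads, _ = episode_gradients(policy, episodes, baseline, config)
    for layers in grads.values():
        for gw, gb in layers:
            if not (np.isfinite(gw).all() and np.isfinite(gb).all()):
                raise FloatingPointError("non-finite gradient in policy update")
    clip_gradients(grads, config.grad_clip_norm)
    optimizer.step(policy, grads)
    mean_r = float(np.mean([ep.reward for ep in episodes]))
    return config.baseline_decay * baseline + (1 - config.baseline_decay) * mean_r


# ---------------------------------------------------------------------------
# Curriculum training
# ---------------------------------------------------------------------------

LOG_COLUMNS = ("epoch", "avg_reward", "avg_sim", "avg_sa", "avg_qed",
               "avg_traj_len")


def curriculum_train(config: TrainerConfig,
                     library: Optional[FragmentLibrary] = None,
                     out_dir: Optional[str] = None,
                     policy: Optional[PolicyNetwork] = None):
    """Train a policy by the methane-seeded curriculum.

    Epoch 0 uses methane as the only source; epoch e samples its sources
    uniformly without replacement from the unique molecules generated at
    epoch e-1.  Returns (policy, log rows); the per-epoch CSV log and
    checkpoints are written when ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_core = len(library) if library is not None and len(library) > 0 \
        else len(DEFAULT_CORE_FRAGMENTS)
    if policy is None:
        policy = PolicyNetwork(PolicyConfig(n_core_fragments=n_core),
                               rng_seed=int(rng.integers(2 ** 31)))
    optimizer = Adam(lr=config.learning_rate)
    # one running EMA baseline, held fixed across a source's episode batch
    # and updated only after that batch
    baseline = 0.0
    sources = [MoleculeRecord.from_smiles(METHANE)]
    log_rows = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    for epoch in range(config.epochs):
        pool: dict[str, MoleculeRecord] = {}
        rewards, sims, sas, qeds, lengths = [], [], [], [], []
        for src in sources:
            episodes = [
                run_episode(policy, src, config.max_steps, rng, library,
                            config.identity_penalty)
                for _ in range(config.episodes_per_source)
            ]
            baseline = policy_gradient_update(
                policy, episodes, baseline, config, optimizer)
            for ep in episodes:
                pool[ep.final.smiles] = ep.final
                rewards.append(ep.reward)
                sims.append(tanimoto_mols(ep.final, src))
                sas.append(ep.breakdown.sa_raw)
                qeds.append(ep.breakdown.qed)
                lengths.append(ep.n_transform_steps)
        if not pool:
            raise RuntimeError(f"epoch {epoch} produced no unique molecules")
        log_rows.append({
            "epoch": epoch,
            "avg_reward": float(np.mean(rewards)),
            "avg_sim": float(np.mean(sims)),
            "avg_sa": float(np.mean(sas)),
            "avg_qed": float(np.mean(qeds)),
            "avg_traj_len": float(np.mean(lengths)),
        })
        if out_dir:
            policy.save_checkpoint(os.path.join(out_dir, f"epoch{epoch:04d}.npz"))
        uniques = sorted(pool)
        n_draw = min(config.epoch_sample_size, len(uniques))
        chosen = rng.choice(len(uniques), size=n_draw, replace=False)
        sources = [pool[uniques[i]] for i in chosen]
    if out_dir:
        with open(os.path.join(out_dir, "training_log.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=LOG_COLUMNS)
            writer.writeheader()
            writer.writerows(log_rows)
    return policy, log_rows
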