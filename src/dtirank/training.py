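"""Negative sampling, mini-batching, and the Adam training loop.

Interaction data is one-class: only positives are observed.  Each epoch a
fresh set of negatives is drawn per drug — proportional in count to that
drug's positives and uniform over its unobserved targets — so no fixed
pseudo-negative set biases the fit.  The three variants consume,
respectively, labelled (drug, target) pairs, (drug, positive, negative)
triples, and lists of one positive plus K negatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import yaml

from .data import Dataset, InteractionMatrix
from .models import (
    ModelSpec,
    ModelState,
    init_state,
    interaction_loss_and_grads,
    similarity_grads,
    similarity_penalty,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters for one training run.

    ``lam`` is the L2 weight on all learnable parameters (one knob shared
    by the three variants); ``lam_d``/``lam_t`` weight the drug / target
    similarity penalties.  ``neg_ratio`` is negatives per positive for the
    point-wise sampler, ``per_positive`` the triples per positive for the
    pair-wise sampler, and ``K`` the negatives per list for the list-wise
    sampler.  All randomness flows from ``seed``.
    """

    k: int = 16
    tau: float = 0.01  # Adam learning rate
    depth: int = 1
    batch: int = 128
    lam: float = 1e-4
    lam_d: float = 0.0
    lam_t: float = 0.0
    neg_ratio: float = 1.0
    per_positive: int = 1
    K: int = 4
    epochs: int = 100
    seed: int = 0
    hidden_widths: Optional[list[int]] = None  # default: constant width k
    sim_mode: str = "auto"  # exact | stochastic | auto (exact when n <= 1000)
    cold_start: str = "sim_embed"  # sim_embed | sim_avg
    pairwise_squash: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.depth < 1 or self.batch < 1:
            raise ValueError("k, depth, and batch must be positive")
        if self.epochs < 0 or self.neg_ratio <= 0 or self.per_positive < 1 or self.K < 1:
            raise ValueError("invalid sampling/epoch configuration")
        if self.sim_mode not in ("auto", "exact", "stochastic"):
            raise ValueError(f"unknown sim_mode {self.sim_mode!r}")
        if self.cold_start not in ("sim_embed", "sim_avg"):
            raise ValueError(f"unknown cold_start {self.cold_start!r}")

    def model_spec(self, variant: str) -> ModelSpec:
        widths = self.hidden_widths or [self.k] * self.depth
        return ModelSpec(variant=variant, k=self.k, hidden_widths=widths)

    @classmethod
    def from_file(cls, path) -> "TrainingConfig":
        """Load from a YAML mapping or flat ``key=value`` lines."""
        with open(path) as fh:
            text = fh.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError:
            doc = None
        if not isinstance(doc, dict):
            doc = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                doc[key.strip()] = yaml.safe_load(value.strip())
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# samplers


def _usable(train: InteractionMatrix, exclude: Optional[np.ndarray]) -> np.ndarray:
    """Boolean mask of cells whose labels may be used for training."""
    mask = np.ones(train.values.shape, dtype=bool)
    if exclude is not None:
        if exclude.shape != train.values.shape:
            raise ValueError("exclude mask shape mismatch")
        mask &= ~exclude
    return mask


def sample_pointwise(
    train: InteractionMatrix,
    neg_ratio: float,
    seed,
    exclude: Optional[np.ndarray] = None,
    drugs: Optional[Sequence[int]] = None,
):
    """Labelled sample: every usable positive once plus, per drug,
    ceil(neg_ratio * #positives) negatives drawn uniformly without
    replacement from that drug's unobserved targets (capped at the number
    available, with a warning when the cap bites).

    Returns index arrays ``(d_idx, t_idx, labels)``.
    """
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    rng = np.random.default_rng(seed)
    usable = _usable(train, exclude)
    rows = range(train.n_drugs) if drugs is None else drugs
    d_out, t_out, y_out = [], [], []
    capped = 0
    for d in rows:
        pos = np.flatnonzero((train.values[d] == 1) & usable[d])
        if len(pos) == 0:
            continue
        neg_pool = np.flatnonzero((train.values[d] == 0) & usable[d])
        want = math.ceil(neg_ratio * len(pos))
        take = min(want, len(neg_pool))
        if take < want:
            capped += 1
        neg = rng.choice(neg_pool, size=take, replace=False) if take else np.empty(0, np.intp)
        d_out.append(np.full(len(pos) + take, d, dtype=np.intp))
        t_out.append(np.concatenate([pos, neg]).astype(np.intp))
        y_out.append(np.concatenate([np.ones(len(pos)), np.zeros(take)]))
    if capped:
        logger.warning("negative sampling capped for %d drugs (too few unobserved targets)", capped)
    if not d_out:
        return np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0)
    return np.concatenate(d_out), np.concatenate(t_out), np.concatenate(y_out)


def sample_triplets(
    train: InteractionMatrix,
    per_positive: int,
    seed,
    exclude: Optional[np.ndarray] = None,
    drugs: Optional[Sequence[int]] = None,
):
    """(drug, positive target, negative target) triples: for every usable
    positive, ``per_positive`` negatives uniform without replacement from
    the drug's unobserved targets.  Returns ``(d_idx, t_idx, i_idx)``.
    """
    if per_positive < 1:
        raise ValueError("per_positive must be >= 1")
    rng = np.random.default_rng(seed)
    usable = _usable(train, exclude)
    rows = range(train.n_drugs) if drugs is None else drugs
    d_out, t_out, i_out = [], [], []
    for d in rows:
        pos = np.flatnonzero((train.values[d] == 1) & usable[d])
        neg_pool = np.flatnonzero((train.values[d] == 0) & usable[d])
        if len(pos) == 0 or len(neg_pool) == 0:
            if len(pos) and not len(neg_pool):
                logger.warning("drug %d has no unobserved targets; yields no triples", d)
            continue
        take = min(per_positive, len(neg_pool))
        for t in pos:
            negs = rng.choice(neg_pool, size=take, replace=False)
            d_out.append(np.full(take, d, dtype=np.intp))
            t_out.append(np.full(take, t, dtype=np.intp))
            i_out.append(negs.astype(np.intp))
    if not d_out:
        return np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0, np.intp)
    return np.concatenate(d_out), np.concatenate(t_out), np.concatenate(i_out)


def sample_lists(
    train: InteractionMatrix,
    K: int,
    seed,
    exclude: Optional[np.ndarray] = None,
    drugs: Optional[Sequence[int]] = None,
):
    """One (positive, K negatives) list per usable positive; lists whose
    drug has fewer than K unobserved targets are dropped with a warning.

    Returns ``(d_idx, T)`` where ``T`` has shape (B, K+1) with the positive
    in column 0.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    usable = _usable(train, exclude)
    rows = range(train.n_drugs) if drugs is None else drugs
    d_out, lists = [], []
    dropped = 0
    for d in rows:
        pos = np.flatnonzero((train.values[d] == 1) & usable[d])
        neg_pool = np.flatnonzero((train.values[d] == 0) & usable[d])
        if len(pos) == 0:
            continue
        if len(neg_pool) < K:
            dropped += len(pos)
            continue
        for t in pos:
            negs = rng.choice(neg_pool, size=K, replace=False)
            d_out.append(d)
            lists.append(np.concatenate([[t], negs]))
    if dropped:
        logger.warning("dropped %d lists (drugs with fewer than K unobserved targets)", dropped)
    if not d_out:
        return np.empty(0, np.intp), np.empty((0, K + 1), np.intp)
    return np.asarray(d_out, dtype=np.intp), np.asarray(lists, dtype=np.intp)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard moment estimates (beta1=0.9, beta2=0.999)."""

    def __init__(self, state: ModelState, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr, dtype=float) for name, arr in state.param_items()}
        self.v = {name: np.zeros_like(arr, dtype=float) for name, arr in state.param_items()}

    def step(self, state: ModelState, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for name, arr in state.param_items():
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            update = self.lr * (self.m[name] / b1c) / (np.sqrt(self.v[name] / b2c) + self.eps)
            state.set_param(name, np.asarray(arr, dtype=float) - update)


# ---------------------------------------------------------------------------
# training loop


def _epoch_sample(variant, train, cfg: TrainingConfig, rng, exclude, drugs):
    seed = rng.integers(0, 2**31)
    if variant == "pointwise":
        d, t, y = sample_pointwise(train, cfg.neg_ratio, seed, exclude, drugs)
        return d, (d, t, y)
    if variant == "pairwise":
        d, t, i = sample_triplets(train, cfg.per_positive, seed, exclude, drugs)
        return d, (d, t, i)
    if variant == "listwise":
        d, T = sample_lists(train, cfg.K, seed, exclude, drugs)
        return d, (d, T)
    raise ValueError(f"unknown variant {variant!r}")


def _slice_batch(variant, sample, idx):
    if variant == "pointwise":
        d, t, y = sample
        return d[idx], t[idx], y[idx]
    if variant == "pairwise":
        d, t, i = sample
        return d[idx], t[idx], i[idx]
    d, T = sample
    return d[idx], T[idx]


def train(
    spec: ModelSpec,
    data: Dataset,
    cfg: TrainingConfig,
    heldout_drugs: Optional[Sequence[int]] = None,
    exclude: Optional[np.ndarray] = None,
) -> tuple[ModelState, list[float]]:
    """Fit a model with Adam, resampling negatives every epoch.

    ``heldout_drugs`` (cold-start evaluation) are excluded from all
    interaction sampling; their embedding rows receive gradients only from
    the drug-similarity penalty, so with ``lam_d == 0`` they keep their
    initial values.  ``exclude`` marks additional cells (e.g. a test fold)
    whose labels must not be used.  Returns the final state and the
    per-epoch mean loss trace.
    """
    train_mat = data.interactions
    n, m = train_mat.n_drugs, train_mat.n_targets
    heldout = np.asarray(sorted(heldout_drugs), dtype=np.intp) if heldout_drugs is not None else None
    train_drugs = (
        np.setdiff1d(np.arange(n), heldout) if heldout is not None else None
    )

    root = np.random.SeedSequence(cfg.seed)
    init_seed, sample_seed = (int(s) for s in root.generate_state(2))
    state = init_state(spec, n, m, init_seed)
    if cfg.epochs == 0:
        return state, []

    rng = np.random.default_rng(sample_seed)
    opt = Adam(state, cfg.tau)

    S_d = data.drug_sim.values if data.drug_sim is not None else None
    S_t = data.target_sim.values if data.target_sim is not None else None
    lam_d = cfg.lam_d if S_d is not None else 0.0
    lam_t = cfg.lam_t if S_t is not None else 0.0
    sim_mode = cfg.sim_mode
    if sim_mode == "auto":
        sim_mode = "exact" if max(n, m) <= 1000 else "stochastic"

    trace: list[float] = []
    for epoch in range(cfg.epochs):
        batch_d, sample = _epoch_sample(spec.variant, train_mat, cfg, rng, exclude, train_drugs)
        n_items = len(batch_d)
        if n_items == 0:
            raise ValueError("no trainable interactions after masking")
        order = rng.permutation(n_items)
        losses = []
        for start in range(0, n_items, cfg.batch):
            idx = order[start : start + cfg.batch]
            batch = _slice_batch(spec.variant, sample, idx)
            loss, grads = interaction_loss_and_grads(
                state, batch, cfg.lam, spec.variant, cfg.pairwise_squash
            )
            if heldout is not None:
                # cold-start rows learn from the drug-similarity term only
                grads["P"][heldout] = 0.0
            if lam_d or lam_t:
                if sim_mode == "exact":
                    similarity_grads(state, S_d, S_t, lam_d, lam_t, grads)
                    loss += similarity_penalty(state, S_d, S_t, lam_d, lam_t)
                else:
                    similarity_grads(
                        state, S_d, S_t, lam_d, lam_t, grads,
                        rows_d=batch[0], rows_t=_touched_targets(spec.variant, batch),
                    )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch}"
                )
            opt.step(state, grads)
            losses.append(loss)
        if (lam_d or lam_t) and sim_mode == "stochastic":
            # one exact full-matrix pass per epoch keeps the approximation honest
            grads = state.zero_grads()
            similarity_grads(state, S_d, S_t, lam_d, lam_t, grads)
            opt.step(state, grads)
        epoch_loss = float(np.mean(losses))
        if sim_mode == "stochastic" and (lam_d or lam_t):
            epoch_loss += similarity_penalty(state, S_d, S_t, lam_d, lam_t)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite epoch loss at epoch {epoch}")
        trace.append(epoch_loss)
    return state, trace


def _touched_targets(variant, batch) -> np.ndarray:
    if variant == "pointwise":
        return batch[1]
    if variant == "pairwise":
        return np.concatenate([batch[1], batch[2]])
    return batch[1].ravel()


def cold_start_embeddings(
    state: ModelState, S_d: np.ndarray, heldout: Sequence[int], train_drugs: Sequence[int]
) -> ModelState:
    """Similarity-weighted average fallback for new drugs:
    p_d = sum_j S[d, j] p_j / sum_j S[d, j] over training drugs j."""
    out = state.copy()
    train_drugs = np.asarray(train_drugs, dtype=np.intp)
    for d in heldout:
        w = S_d[d, train_drugs]
        denom = w.sum()
        if denom > 0:
            out.P[d] = (w @ state.P[train_drugs]) / denom
    return out
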