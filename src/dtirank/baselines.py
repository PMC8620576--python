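"""Matrix-factorization reference methods: PMF, CMF, and BPR-MF.

All three score a pair by the inner product p_d . q_t of k-dimensional
latent factors — the linear counterparts of the neural variants:

* PMF minimizes squared error on observed interactions (adapted to
  one-class data by sampling negatives, since on positives alone the
  constant predictor 1 would be optimal);
* CMF adds the Frobenius similarity penalties
  lam_d ||S_d - P P^T||^2 + lam_t ||S_t - Q Q^T||^2;
* BPR-MF minimizes the pair-wise loss -ln sigmoid(p_d.q_t - p_d.q_i)
  over (positive, negative) target pairs.

One optimizer (Adam) is used across the repository, so CMF with zero
similarity weights reduces to PMF step-for-step under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .data import Dataset, InteractionMatrix
from .models import _sigmoid, _softplus, similarity_grads, similarity_penalty
from .training import Adam, TrainingConfig, sample_pointwise, sample_triplets

__all__ = ["MFState", "pmf_fit", "cmf_fit", "bpr_fit", "mf_scores", "fit_baseline"]


@dataclass
class MFState:
    """Latent factors only — a depth-0 model scored by the inner product."""

    P: np.ndarray  # (n, k)
    Q: np.ndarray  # (m, k)

    def __post_init__(self) -> None:
        if self.P.shape[1] != self.Q.shape[1]:
            raise ValueError("P and Q must share the latent dimension k")
        if not (np.all(np.isfinite(self.P)) and np.all(np.isfinite(self.Q))):
            raise ValueError("non-finite factors")

    def param_items(self) -> Iterator[tuple[str, np.ndarray]]:
        yield "P", self.P
        yield "Q", self.Q

    def set_param(self, name: str, value: np.ndarray) -> None:
        setattr(self, name, value)

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {"P": np.zeros_like(self.P), "Q": np.zeros_like(self.Q)}

    def sq_norm(self) -> float:
        return float(np.sum(self.P**2) + np.sum(self.Q**2))

    def copy(self) -> "MFState":
        return MFState(self.P.copy(), self.Q.copy())


def mf_scores(state: MFState) -> np.ndarray:
    """Score every cell: the inner-product matrix P Q^T."""
    return state.P @ state.Q.T


def _init_mf(n: int, m: int, k: int, seed: int) -> MFState:
    rng = np.random.default_rng(seed)
    return MFState(rng.normal(0.0, 0.1, (n, k)), rng.normal(0.0, 0.1, (m, k)))


def _eig_factors(S: np.ndarray, k: int) -> np.ndarray:
    """Best rank-k factorization of a symmetric psd-ish similarity matrix."""
    w, V = np.linalg.eigh(S)
    idx = np.argsort(w)[::-1][: min(k, len(w))]
    F = V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    if F.shape[1] < k:  # pad degenerate case
        F = np.hstack([F, np.zeros((len(S), k - F.shape[1]))])
    return F


def spectral_init(
    Y: InteractionMatrix,
    S_d: np.ndarray,
    S_t: np.ndarray,
    k: int,
    exclude: Optional[np.ndarray] = None,
    train_drugs: Optional[np.ndarray] = None,
) -> MFState:
    """Similarity-spectral warm start for CMF.

    Each similarity penalty is minimized in closed form by the rank-k
    eigenfactorization of its matrix, but those factor bases are only
    defined up to rotation.  The remaining k x k linear map between them
    is fit by least squares on the usable training cells, then split
    symmetrically (via its SVD) between the two factor sets, so the
    initial state already reconstructs both similarity matrices and the
    observed interactions.
    """
    Pe = _eig_factors(S_d, k)
    Qe = _eig_factors(S_t, k)
    usable = np.ones(Y.values.shape, dtype=bool)
    if exclude is not None:
        usable &= ~exclude
    if train_drugs is not None:
        mask_rows = np.zeros(Y.n_drugs, dtype=bool)
        mask_rows[train_drugs] = True
        usable &= mask_rows[:, None]
    d_idx, t_idx = np.nonzero(usable)
    X = np.einsum("ca,cb->cab", Pe[d_idx], Qe[t_idx]).reshape(len(d_idx), k * k)
    y = Y.values[usable].astype(float)
    M, *_ = np.linalg.lstsq(X, y, rcond=None)
    U, s, Vt = np.linalg.svd(M.reshape(k, k))
    return MFState(Pe @ U * np.sqrt(s), Qe @ Vt.T * np.sqrt(s))


def bpr_triple_loss(state: MFState, d_idx, t_idx, i_idx, lam: float) -> float:
    """Pair-wise ranking loss on inner-product scores (shared formula with
    the neural pair-wise head: -sum ln sigmoid(score gap) + lam * Omega)."""
    x_pos = np.sum(state.P[d_idx] * state.Q[t_idx], axis=1)
    x_neg = np.sum(state.P[d_idx] * state.Q[i_idx], axis=1)
    return float(np.sum(_softplus(-(x_pos - x_neg)))) + lam * state.sq_norm()


def cmf_objective(
    state: MFState, d_idx, t_idx, y, lam: float, lam_d: float, lam_t: float, S_d, S_t
) -> float:
    """Squared reconstruction error + L2 + similarity penalties at a state."""
    yhat = np.sum(state.P[d_idx] * state.Q[t_idx], axis=1)
    obj = float(np.sum((np.asarray(y, dtype=float) - yhat) ** 2)) + lam * state.sq_norm()
    return obj + similarity_penalty(state, S_d, S_t, lam_d, lam_t)


def cmf_fit(
    data: Dataset,
    k: int,
    lam: float,
    lam_d: float,
    lam_t: float,
    tau: float,
    epochs: int,
    seed: int,
    batch: int = 128,
    neg_ratio: float = 1.0,
    exclude: Optional[np.ndarray] = None,
    heldout_drugs: Optional[Sequence[int]] = None,
    return_trace: bool = False,
    init: str = "auto",
):
    """Fit CMF by mini-batch Adam on sampled cells plus similarity penalties.

    ``init`` selects the starting point: ``random`` (small normals),
    ``spectral`` (:func:`spectral_init` from the similarity matrices), or
    ``auto`` — spectral whenever both similarity matrices are present and
    at least one similarity weight is nonzero, random otherwise.  With
    ``lam_d == lam_t == 0`` the similarity code path contributes nothing
    and the run is identical to :func:`pmf_fit` under the same seed.
    Held-out (cold-start) drugs are excluded from interaction sampling
    and their factors learn from the drug-similarity term only.
    """
    Y = data.interactions
    n, m = Y.n_drugs, Y.n_targets
    heldout = (
        np.asarray(sorted(heldout_drugs), dtype=np.intp) if heldout_drugs is not None else None
    )
    train_drugs = np.setdiff1d(np.arange(n), heldout) if heldout is not None else None

    if init not in ("auto", "random", "spectral"):
        raise ValueError(f"unknown init {init!r}")
    have_sims = data.drug_sim is not None and data.target_sim is not None
    use_spectral = init == "spectral" or (
        init == "auto" and have_sims and (lam_d > 0 or lam_t > 0)
    )
    if use_spectral and not have_sims:
        raise ValueError("spectral init requires both similarity matrices")

    root = np.random.SeedSequence(seed)
    init_seed, sample_seed = (int(s) for s in root.generate_state(2))
    if use_spectral:
        state = spectral_init(
            Y, data.drug_sim.values, data.target_sim.values, k, exclude, train_drugs
        )
    else:
        state = _init_mf(n, m, k, init_seed)
    if epochs == 0:
        return (state, []) if return_trace else state
    rng = np.random.default_rng(sample_seed)
    opt = Adam(state, tau)

    S_d = data.drug_sim.values if (data.drug_sim is not None and lam_d) else None
    S_t = data.target_sim.values if (data.target_sim is not None and lam_t) else None

    trace = []
    for epoch in range(epochs):
        d_all, t_all, y_all = sample_pointwise(
            Y, neg_ratio, rng.integers(0, 2**31), exclude, train_drugs
        )
        if len(d_all) == 0:
            raise ValueError("no trainable interactions after masking")
        order = rng.permutation(len(d_all))
        losses = []
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            d_idx, t_idx, y = d_all[idx], t_all[idx], y_all[idx]
            p, q = state.P[d_idx], state.Q[t_idx]
            yhat = np.sum(p * q, axis=1)
            resid = yhat - y
            loss = float(np.sum(resid**2)) + lam * state.sq_norm()
            grads = state.zero_grads()
            np.add.at(grads["P"], d_idx, 2.0 * resid[:, None] * q)
            np.add.at(grads["Q"], t_idx, 2.0 * resid[:, None] * p)
            grads["P"] += 2.0 * lam * state.P
            grads["Q"] += 2.0 * lam * state.Q
            if heldout is not None:
                grads["P"][heldout] = 0.0
            if S_d is not None or S_t is not None:
                similarity_grads(state, S_d, S_t, lam_d, lam_t, grads)
                loss += similarity_penalty(state, S_d, S_t, lam_d, lam_t)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(state, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return (state, trace) if return_trace else state


def pmf_fit(
    train: InteractionMatrix | Dataset,
    k: int,
    lam: float,
    tau: float,
    epochs: int,
    seed: int,
    **kwargs,
):
    """Probabilistic-MF baseline: CMF with both similarity weights at zero."""
    data = train if isinstance(train, Dataset) else Dataset(interactions=train)
    return cmf_fit(data, k, lam, 0.0, 0.0, tau, epochs, seed, **kwargs)


def bpr_fit(
    train: InteractionMatrix | Dataset,
    k: int,
    lam: float,
    tau: float,
    epochs: int,
    seed: int,
    batch: int = 128,
    per_positive: int = 1,
    exclude: Optional[np.ndarray] = None,
    heldout_drugs: Optional[Sequence[int]] = None,
    return_trace: bool = False,
):
    """Fit BPR-MF by mini-batch Adam on freshly sampled triples each epoch."""
    Y = train.interactions if isinstance(train, Dataset) else train
    n, m = Y.n_drugs, Y.n_targets
    heldout = (
        np.asarray(sorted(heldout_drugs), dtype=np.intp) if heldout_drugs is not None else None
    )
    train_drugs = np.setdiff1d(np.arange(n), heldout) if heldout is not None else None

    root = np.random.SeedSequence(seed)
    init_seed, sample_seed = (int(s) for s in root.generate_state(2))
    state = _init_mf(n, m, k, init_seed)
    if epochs == 0:
        return (state, []) if return_trace else state
    rng = np.random.default_rng(sample_seed)
    opt = Adam(state, tau)

    trace = []
    for epoch in range(epochs):
        d_all, t_all, i_all = sample_triplets(
            Y, per_positive, rng.integers(0, 2**31), exclude, train_drugs
        )
        if len(d_all) == 0:
            raise ValueError("no trainable triples after masking")
        order = rng.permutation(len(d_all))
        losses = []
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            d_idx, t_idx, i_idx = d_all[idx], t_all[idx], i_all[idx]
            p = state.P[d_idx]
            gap = np.sum(p * (state.Q[t_idx] - state.Q[i_idx]), axis=1)
            loss = float(np.sum(_softplus(-gap))) + lam * state.sq_norm()
            dgap = -_sigmoid(-gap)
            grads = state.zero_grads()
            np.add.at(grads["P"], d_idx, dgap[:, None] * (state.Q[t_idx] - state.Q[i_idx]))
            np.add.at(grads["Q"], t_idx, dgap[:, None] * p)
            np.add.at(grads["Q"], i_idx, -dgap[:, None] * p)
            grads["P"] += 2.0 * lam * state.P
            grads["Q"] += 2.0 * lam * state.Q
            if heldout is not None:
                grads["P"][heldout] = 0.0
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(state, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return (state, trace) if return_trace else state


def fit_baseline(
    name: str,
    data: Dataset,
    cfg: TrainingConfig,
    exclude: Optional[np.ndarray] = None,
    heldout_drugs: Optional[Sequence[int]] = None,
) -> MFState:
    """Dispatch a baseline fit from a :class:`TrainingConfig`."""
    common = dict(batch=cfg.batch, exclude=exclude, heldout_drugs=heldout_drugs)
    if name == "pmf":
        return pmf_fit(data, cfg.k, cfg.lam, cfg.tau, cfg.epochs, cfg.seed,
                       neg_ratio=cfg.neg_ratio, **common)
    if name == "cmf":
        return cmf_fit(data, cfg.k, cfg.lam, cfg.lam_d, cfg.lam_t, cfg.tau,
                       cfg.epochs, cfg.seed, neg_ratio=cfg.neg_ratio, **common)
    if name == "bpr":
        return bpr_fit(data, cfg.k, cfg.lam, cfg.tau, cfg.epochs, cfg.seed,
                       per_positive=cfg.per_positive, **common)
    raise ValueError(f"unknown baseline {name!r}")
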