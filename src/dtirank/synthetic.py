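"""Synthetic DTI datasets with planted low-rank structure.

The generator emulates the regime of the public gold-standard sets: a
sparse binary interaction matrix driven by latent drug/target factors,
plus drug-drug and target-target similarity matrices that are noisy
transforms of the same factors (as SIMCOMP / normalized Smith-Waterman
scores are of the underlying chemistry and sequences).  Because the
planted factors generate both the interactions and the similarities, the
data are solvable by the models the package implements, which makes every
training and evaluation path testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import math

import numpy as np

from .data import Dataset, InteractionMatrix, SimilarityMatrix


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``density`` is the fraction of cells set to 1 (exactly, by top-score
    thresholding); ``sim_noise`` is the standard deviation of the additive
    perturbation applied to the similarity matrices; ``link`` selects a
    linear (inner-product) or nonlinear latent score.
    """

    n: int = 100
    m: int = 80
    k_true: int = 8
    density: float = 0.08
    sim_noise: float = 0.05
    link: Literal["linear", "nonlinear"] = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density < 0.5):
            raise ValueError("density must lie in (0, 0.5)")
        if self.k_true > min(self.n, self.m) or self.k_true < 1:
            raise ValueError("k_true must lie in [1, min(n, m)]")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be >= 0")
        if self.link not in ("linear", "nonlinear"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class GroundTruth:
    """Planted factors and the latent score matrix behind a synthetic dataset."""

    P: np.ndarray  # (n, k_true)
    Q: np.ndarray  # (m, k_true)
    scores: np.ndarray  # (n, m) latent scores before thresholding


def _similarity_from_factors(F: np.ndarray, noise_sd: float, rng, prefix: str) -> SimilarityMatrix:
    """Min-max map the off-diagonal Gram entries of F to [0, 1], set the
    diagonal to 1, then add symmetric noise and re-clip."""
    G = F @ F.T
    off = ~np.eye(len(G), dtype=bool)
    lo, hi = G[off].min(), G[off].max()
    S = (G - lo) / (hi - lo) if hi > lo else np.zeros_like(G)
    np.fill_diagonal(S, 1.0)
    if noise_sd > 0:
        E = rng.normal(0.0, noise_sd, size=G.shape)
        S = S + (E + E.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    ids = [f"{prefix}{i:04d}" for i in range(len(G))]
    return SimilarityMatrix(ids, S)


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw a dataset from planted factors; deterministic under ``spec.seed``.

    Factors P*, Q* are standard normal; the latent score is the inner
    product (linear link) or a tanh of a fixed random projection of the
    element-wise product (nonlinear link).  Exactly
    ``ceil(density * n * m)`` cells — those with the highest latent scores
    — become 1, so the positive count is exact and deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    P = rng.normal(0.0, 1.0, (spec.n, spec.k_true))
    Q = rng.normal(0.0, 1.0, (spec.m, spec.k_true))
    if spec.link == "linear":
        Z = P @ Q.T
    else:
        w = rng.normal(0.0, 1.0, spec.k_true)
        # element-wise product through a fixed random projection + tanh
        Z = np.tanh(np.einsum("nk,mk,k->nm", P, Q, w) / math.sqrt(spec.k_true))

    n_ones = math.ceil(spec.density * spec.n * spec.m)
    flat = Z.ravel()
    top = np.argpartition(flat, -n_ones)[-n_ones:]
    Y = np.zeros(spec.n * spec.m, dtype=np.int8)
    Y[top] = 1
    Y = Y.reshape(spec.n, spec.m)

    drugs = [f"D{i:04d}" for i in range(spec.n)]
    targets = [f"hsa{j:04d}" for j in range(spec.m)]
    interactions = InteractionMatrix(drugs, targets, Y)
    drug_sim = _similarity_from_factors(P, spec.sim_noise, rng, "D")
    target_sim = _similarity_from_factors(Q, spec.sim_noise, rng, "hsa")
    data = Dataset(
        interactions=interactions,
        drug_sim=drug_sim,
        target_sim=target_sim,
        name=f"synthetic(n={spec.n},m={spec.m},k={spec.k_true},seed={spec.seed})",
    )
    return data, GroundTruth(P=P, Q=Q, scores=Z)
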