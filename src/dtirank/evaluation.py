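"""Ranking metrics and cross-validation protocols.

Two 10-fold settings are supported:

* ``cv_dt`` — folds partition the drug-target *cells* of Y; a fold's cells
  (both their 1s and 0s) are masked from training and scored at test time.
* ``cv_nd`` — folds partition the *drugs*; held-out drugs are cold-start
  cases whose entire rows are masked and scored.

AUC is the tie-aware Mann-Whitney probability that a positive outranks a
negative; AUPR is the non-interpolated step sum over descending-score
thresholds (average precision).  Per-fold metrics are micro-averaged over
the fold's pooled test cells; single-class folds are skipped with a
warning and excluded from the means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import Dataset, InteractionMatrix
from .models import ModelSpec, score_matrix
from .training import TrainingConfig, cold_start_embeddings, train

logger = logging.getLogger(__name__)

Setting = Literal["cv_dt", "cv_nd"]

BASELINE_NAMES = ("pmf", "cmf", "bpr")


class UndefinedMetricError(ValueError):
    """Raised when a ranking metric is requested for single-class labels."""


def auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC needs both a positive and a negative label")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, non-interpolated step summation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive label")
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldPlan:
    """Ten near-equal test partitions of cells (cv_dt) or drugs (cv_nd)."""

    setting: Setting
    folds: list[np.ndarray]  # cv_dt: flat cell indices; cv_nd: drug indices
    seed: int
    shape: tuple[int, int]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def test_mask(self, fold: int) -> np.ndarray:
        """Boolean (n, m) mask of cells tested in ``fold``."""
        n, m = self.shape
        mask = np.zeros(n * m, dtype=bool)
        if self.setting == "cv_dt":
            mask[self.folds[fold]] = True
            return mask.reshape(n, m)
        mask = np.zeros((n, m), dtype=bool)
        mask[self.folds[fold], :] = True
        return mask

    def to_file(self, path, mat: InteractionMatrix) -> None:
        with open(path, "w") as fh:
            fh.write(f"# setting={self.setting} seed={self.seed} "
                     f"shape={self.shape[0]}x{self.shape[1]}\n")
            for f, idx in enumerate(self.folds):
                for i in idx:
                    if self.setting == "cv_dt":
                        d, t = divmod(int(i), self.shape[1])
                        fh.write(f"{f}\t{mat.drugs[d]}\t{mat.targets[t]}\n")
                    else:
                        fh.write(f"{f}\t{mat.drugs[int(i)]}\n")

    @classmethod
    def from_file(cls, path, mat: InteractionMatrix) -> "FoldPlan":
        drug_pos = {d: i for i, d in enumerate(mat.drugs)}
        target_pos = {t: i for i, t in enumerate(mat.targets)}
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            folds: dict[int, list[int]] = {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                f = int(parts[0])
                if meta["setting"] == "cv_dt":
                    idx = drug_pos[parts[1]] * mat.n_targets + target_pos[parts[2]]
                else:
                    idx = drug_pos[parts[1]]
                folds.setdefault(f, []).append(idx)
        return cls(
            setting=meta["setting"],
            folds=[np.asarray(folds[f], dtype=np.intp) for f in sorted(folds)],
            seed=int(meta["seed"]),
            shape=tuple(int(x) for x in meta["shape"].split("x")),
        )


def make_folds(
    Y: InteractionMatrix, setting: Setting, seed: int, n_folds: int = 10
) -> FoldPlan:
    """Random partition into ``n_folds`` test sets with sizes differing by <= 1."""
    rng = np.random.default_rng(seed)
    n, m = Y.values.shape
    if setting == "cv_dt":
        order = rng.permutation(n * m)
    elif setting == "cv_nd":
        if n < n_folds:
            raise ValueError(f"need at least {n_folds} drugs for {setting}")
        order = rng.permutation(n)
    else:
        raise ValueError(f"unknown CV setting {setting!r}")
    folds = [np.sort(chunk).astype(np.intp) for chunk in np.array_split(order, n_folds)]
    return FoldPlan(setting=setting, folds=folds, seed=seed, shape=(n, m))


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass
class EvalResult:
    """Per-fold AUC/AUPR with their means and standard deviations."""

    fold_auc: list[float]
    fold_aupr: list[float]
    skipped_folds: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def std_aupr(self) -> float:
        return float(np.std(self.fold_aupr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold": range(len(self.fold_auc)),
                             "auc": self.fold_auc, "aupr": self.fold_aupr})

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        summary = pd.DataFrame(
            {"fold": ["mean", "std"],
             "auc": [self.mean_auc, self.std_auc],
             "aupr": [self.mean_aupr, self.std_aupr]}
        )
        pd.concat([df, summary]).to_csv(path, sep="\t", index=False)


Model = Union[ModelSpec, str, Callable]


def _fit_and_score(
    model: Model,
    data: Dataset,
    cfg: TrainingConfig,
    exclude: Optional[np.ndarray],
    heldout: Optional[np.ndarray],
) -> np.ndarray:
    """Train ``model`` on the unmasked portion and return an (n, m) score matrix."""
    if callable(model) and not isinstance(model, ModelSpec):
        return np.asarray(model(data, exclude, heldout), dtype=float)
    if isinstance(model, str):
        from . import baselines  # local import to avoid a cycle

        if model not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {model!r}")
        state = baselines.fit_baseline(model, data, cfg, exclude=exclude, heldout_drugs=heldout)
        if heldout is not None and cfg.cold_start == "sim_avg" and data.drug_sim is not None:
            train_drugs = np.setdiff1d(np.arange(data.interactions.n_drugs), heldout)
            state = cold_start_embeddings(state, data.drug_sim.values, heldout, train_drugs)
        return baselines.mf_scores(state)
    spec = model
    state, _ = train(spec, data, cfg, heldout_drugs=heldout, exclude=exclude)
    if heldout is not None and cfg.cold_start == "sim_avg" and data.drug_sim is not None:
        train_drugs = np.setdiff1d(np.arange(data.interactions.n_drugs), heldout)
        state = cold_start_embeddings(state, data.drug_sim.values, heldout, train_drugs)
    return score_matrix(state)


def cross_validate(
    model: Model,
    data: Dataset,
    cfg: TrainingConfig,
    setting: Setting,
    n_folds: int = 10,
    max_folds: Optional[int] = None,
    plan: Optional[FoldPlan] = None,
) -> EvalResult:
    """Run the 10-fold protocol and collect per-fold AUC / AUPR.

    ``model`` is a :class:`~dtirank.models.ModelSpec` (neural variants), a
    baseline name (``pmf`` / ``cmf`` / ``bpr``), or a callable
    ``(data, exclude_mask, heldout_drugs) -> score matrix`` for custom
    scorers.  Per-fold training seeds are derived from ``cfg.seed`` and the
    fold index so folds are decorrelated but the whole run is reproducible.
    """
    Y = data.interactions
    if plan is None:
        plan = make_folds(Y, setting, cfg.seed, n_folds)
    fold_auc, fold_aupr, skipped = [], [], 0
    folds = range(plan.n_folds if max_folds is None else min(max_folds, plan.n_folds))
    for f in folds:
        test_mask = plan.test_mask(f)
        if setting == "cv_dt":
            exclude, heldout = test_mask, None
        else:
            exclude, heldout = None, plan.folds[f]
        labels = Y.values[test_mask]
        if labels.min() == labels.max():
            logger.warning("fold %d has single-class test labels; skipped", f)
            skipped += 1
            continue
        fold_seed = int(np.random.SeedSequence((cfg.seed, f)).generate_state(1)[0])
        scores = _fit_and_score(model, data, replace(cfg, seed=fold_seed), exclude, heldout)
        s = scores[test_mask]
        fold_auc.append(auc(s, labels))
        fold_aupr.append(aupr(s, labels))
    if not fold_auc:
        raise UndefinedMetricError("every fold had single-class test labels")
    return EvalResult(fold_auc=fold_auc, fold_aupr=fold_aupr, skipped_folds=skipped)


def grid_search(
    model: Model,
    data: Dataset,
    grid: dict[str, Sequence],
    setting: Setting,
    seed: int,
    base_cfg: Optional[TrainingConfig] = None,
    fast: bool = False,
) -> tuple[TrainingConfig, pd.DataFrame]:
    """Exhaustive search over ``grid`` (TrainingConfig field -> candidates).

    Each point is scored by :func:`cross_validate` (all folds, or a single
    validation fold when ``fast``); the config maximizing mean AUC wins,
    ties broken by smaller ``k`` then smaller ``depth``.  Returns the best
    config and the full results table.
    """
    if not grid:
        raise ValueError("empty grid")
    base = base_cfg or TrainingConfig()
    keys = sorted(grid)
    rows = []
    best: tuple = ()
    best_cfg: Optional[TrainingConfig] = None
    for values in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, values))
        cfg = replace(base, seed=seed, **overrides)
        spec_model = model
        if isinstance(model, ModelSpec):
            spec_model = cfg.model_spec(model.variant)
        res = cross_validate(
            spec_model, data, cfg, setting, max_folds=1 if fast else None
        )
        rows.append({**overrides, "mean_auc": res.mean_auc, "mean_aupr": res.mean_aupr})
        key = (-res.mean_auc, cfg.k, cfg.depth)
        if best_cfg is None or key < best:
            best, best_cfg = key, cfg
    return best_cfg, pd.DataFrame(rows)
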