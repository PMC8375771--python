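"""Sparse forward encoding models from classifier stages to vertex responses.

A vertex's response to the training (regular) images is modelled as a sparse
linear combination of one classifier stage's unit activations plus an
intercept, ``y = X w`` with ``X`` an m x (n+1) matrix whose last column is
constant 1.  Because the number of training images (m, default 40) is far
below the number of stage units (n), the weights are found with regularized
orthogonal matching pursuit (ROMP): per iteration the residual is correlated
with all columns, the s strongest correlations are regularized to a
comparable-magnitude subset (max |u| <= 2 min |u|) of maximal energy, that
subset joins the support, and the support is refit by least squares.

Generalization is tested by predicting each vertex's responses to the
adversarial images and correlating prediction with measurement across
images (Pearson), with unit-subsample bootstrap CIs and label-permutation
p-values per (ROI, stage) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    STAGE_NAMES,
    ActivationStack,
    ConfigurationError,
    DataError,
    SurrogateModel,
    forward_with_activations,
)
from .synth import ResponseDataset


def stack_activations(model: SurrogateModel, stimulus_set) -> dict[str, np.ndarray]:
    """Per-stage (n_images x n_features) activation matrices for a stimulus set."""
    stacks = [forward_with_activations(model, im.pixels) for im in stimulus_set.images]
    return {
        stage: np.stack([s.per_stage[stage] for s in stacks]) for stage in STAGE_NAMES
    }


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class EncodingDesign:
    """Standardized feature matrix for one stage, with reusable scaling.

    ``X`` is m x (n+1): per-column z-scored stage activations (training
    statistics) with the intercept column of ones appended last.
    """

    X: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    stage: str
    image_order: np.ndarray

    @property
    def intercept_col(self) -> int:
        return self.X.shape[1] - 1

    def transform(self, acts: np.ndarray) -> np.ndarray:
        """Apply the stored training scaling to new (images x units) activations."""
        if acts.shape[1] != self.mean.size:
            raise DataError(
                f"stage {self.stage}: expected {self.mean.size} units, got {acts.shape[1]}"
            )
        z = (acts - self.mean) / self.sd
        return np.hstack([z, np.ones((acts.shape[0], 1))])


def build_feature_matrix(
    activation_stacks: list[ActivationStack],
    stage: str,
    image_order: np.ndarray | None = None,
) -> EncodingDesign:
    """Assemble the m x (n+1) design for one stage.

    Rows follow ``image_order`` (default: the stack order); columns are
    standardized on these rows (constant columns are left centred with unit
    divisor) and the intercept column is exempt.
    """
    lengths = {s.per_stage[stage].size for s in activation_stacks}
    if len(lengths) != 1:
        raise DataError(f"ragged activation lengths for stage {stage}: {sorted(lengths)}")
    acts = np.stack([s.per_stage[stage] for s in activation_stacks])
    order = np.arange(acts.shape[0]) if image_order is None else np.asarray(image_order)
    acts = acts[order]
    mean = acts.mean(axis=0)
    sd = acts.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X = np.hstack([(acts - mean) / sd, np.ones((acts.shape[0], 1))])
    return EncodingDesign(X=X, mean=mean, sd=sd, stage=stage, image_order=order)


# ---------------------------------------------------------------------------
# ROMP
# ---------------------------------------------------------------------------


@dataclass
class SparseSolution:
    w: np.ndarray  # full length n+1; exactly zero off-support
    support: np.ndarray  # sorted indices of fitted columns (incl. intercept)
    residual_norm: float
    iterations: int
    rank_deficient: bool = False
    residual_history: list = field(default_factory=list)  # norm after each refit


def _regularized_subset(u_abs: np.ndarray, candidates: np.ndarray, s: int) -> np.ndarray:
    """ROMP selection: among the s largest |u|, the maximal-energy contiguous
    (in sorted order) subset whose values are within a factor of 2."""
    order = candidates[np.argsort(u_abs[candidates])[::-1][:s]]
    vals = u_abs[order]
    best, best_energy = order[:1], float(vals[0] ** 2)
    n = vals.size
    j_end = 0
    for i in range(n):
        if vals[i] == 0:
            break
        j_end = max(j_end, i)
        while j_end + 1 < n and vals[i] <= 2.0 * vals[j_end + 1]:
            j_end += 1
        energy = float(np.sum(vals[i : j_end + 1] ** 2))
        if energy > best_energy:
            best, best_energy = order[i : j_end + 1], energy
    return best


def romp_solve(
    X: np.ndarray,
    y: np.ndarray,
    sparsity_s: int,
    residual_tol: float | None = None,
    intercept_col: int | None = None,
) -> SparseSolution:
    """Regularized orthogonal matching pursuit.

    Halts when the support (intercept excluded) reaches ``2 * sparsity_s``
    or the residual norm drops to ``residual_tol`` (default ``1e-6 * ||y||``).
    The intercept column (default: last) is always in the support.  A
    rank-deficient least-squares refit falls back to the minimum-norm
    solution with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[1] < 1:
        raise ConfigurationError("X must be a 2-D matrix with at least one column")
    if sparsity_s < 1:
        raise ConfigurationError("sparsity_s must be >= 1")
    m, ncol = X.shape
    if y.size != m:
        raise DataError(f"y has {y.size} entries for {m} rows of X")
    if intercept_col is None:
        intercept_col = ncol - 1
    if residual_tol is None:
        residual_tol = 1e-6 * np.linalg.norm(y)

    support = [intercept_col]
    rank_deficient = False

    def refit(sup: list[int]) -> tuple[np.ndarray, np.ndarray]:
        nonlocal rank_deficient
        cols = sorted(sup)
        coef, _, rank, _ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        if rank < len(cols):
            rank_deficient = True
            warnings.warn(
                f"rank-deficient least squares on support of size {len(cols)}; "
                "using the minimum-norm solution",
                RuntimeWarning,
                stacklevel=3,
            )
        return np.array(cols), coef

    cols, coef = refit(support)
    residual = y - X[:, cols] @ coef
    history = [float(np.linalg.norm(residual))]
    iterations = 0
    max_support = 2 * sparsity_s  # non-intercept columns
    while (
        len(support) - 1 < max_support
        and np.linalg.norm(residual) > residual_tol
    ):
        u_abs = np.abs(X.T @ residual)
        u_abs[list(support)] = 0.0
        candidates = np.flatnonzero(u_abs > 0)
        if candidates.size == 0:
            break
        chosen = _regularized_subset(u_abs, candidates, sparsity_s)
        room = max_support - (len(support) - 1)
        if chosen.size > room:  # keep the strongest, respect the budget
            chosen = chosen[np.argsort(u_abs[chosen])[::-1][:room]]
        support.extend(int(c) for c in chosen)
        cols, coef = refit(support)
        residual = y - X[:, cols] @ coef
        history.append(float(np.linalg.norm(residual)))
        iterations += 1

    w = np.zeros(ncol)
    w[cols] = coef
    return SparseSolution(
        w=w, support=cols, residual_norm=float(np.linalg.norm(residual)),
        iterations=iterations, rank_deficient=rank_deficient,
        residual_history=history,
    )


# ---------------------------------------------------------------------------
# model bank: training and generalization
# ---------------------------------------------------------------------------


@dataclass
class ModelBank:
    """One sparse solution per (vertex, stage), grouped as ROI x stage."""

    designs: dict[str, EncodingDesign]
    models: dict[tuple[str, str], dict[int, SparseSolution]]
    sparsity_s: int

    @property
    def cells(self) -> list[tuple[str, str]]:
        return list(self.models.keys())


def train_models(
    responses: ResponseDataset,
    activation_stacks: list[ActivationStack],
    selection: pd.DataFrame,
    sparsity_s: int | None = None,
    residual_tol: float | None = None,
    stages: tuple[str, ...] = STAGE_NAMES,
) -> ModelBank:
    """Fit one ROMP model per selected vertex per stage on the RE responses.

    Repetitions are averaged before fitting.  The default sparsity budget is
    ``m // 4`` for m training images (10 at the default 40).
    """
    y_all = responses.mean_over_reps("RE")  # vertices x images
    m = y_all.shape[1]
    if len(activation_stacks) != m:
        raise DataError(
            f"{len(activation_stacks)} activation stacks for {m} response images"
        )
    if sparsity_s is None:
        sparsity_s = max(1, m // 4)
    designs = {stage: build_feature_matrix(activation_stacks, stage) for stage in stages}
    id_to_row = {
        int(v): i for i, v in enumerate(responses.sheet.table["vertex_id"].to_numpy())
    }
    models: dict[tuple[str, str], dict[int, SparseSolution]] = {}
    for roi, block in selection.groupby("roi", sort=False):
        vids = block["vertex_id"].to_numpy()
        for stage in stages:
            X = designs[stage].X
            cell = {}
            for vid in vids:
                y = y_all[id_to_row[int(vid)]]
                cell[int(vid)] = romp_solve(X, y, sparsity_s, residual_tol)
            models[(roi, stage)] = cell
    return ModelBank(designs=designs, models=models, sparsity_s=sparsity_s)


def _columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (images x vertices) arrays;
    zero-variance columns yield r = 0 (no predictive signal)."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = np.sqrt((az**2).sum(axis=0))
    sb = np.sqrt((bz**2).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az * bz).sum(axis=0) / denom
    return np.where(denom == 0, 0.0, r)


def _per_vertex_accuracy(
    bank: ModelBank,
    activation_stacks: list[ActivationStack],
    responses: ResponseDataset,
    image_type: str,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-cell vector of per-vertex prediction accuracies (Pearson r)."""
    measured_all = responses.mean_over_reps(image_type)
    id_to_row = {
        int(v): i for i, v in enumerate(responses.sheet.table["vertex_id"].to_numpy())
    }
    out = {}
    for (roi, stage), cell in bank.models.items():
        design = bank.designs[stage]
        acts = np.stack([s.per_stage[stage] for s in activation_stacks])
        X_adv = design.transform(acts)
        vids = sorted(cell.keys())
        W = np.stack([cell[v].w for v in vids], axis=1)
        predicted = X_adv @ W
        measured = measured_all[[id_to_row[v] for v in vids]].T
        out[(roi, stage)] = _columnwise_pearson(predicted, measured)
    return out


def generalization_difference(
    bank: ModelBank,
    stacks_ai: list[ActivationStack],
    stacks_an: list[ActivationStack],
    responses: ResponseDataset,
    frac: float = 0.8,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap comparison of AI vs AN prediction accuracy per cell.

    Vertices are resampled (``frac`` without replacement, ``n_boot`` times);
    per replicate the difference of mean accuracies (AI minus AN) is
    recorded; one-sided p = (1 + #{diff <= 0}) / (n_boot + 1).
    """
    acc_ai = _per_vertex_accuracy(bank, stacks_ai, responses, "AI")
    acc_an = _per_vertex_accuracy(bank, stacks_an, responses, "AN")
    rng = np.random.default_rng(seed)
    rows = []
    for cell in bank.models:
        r_ai, r_an = acc_ai[cell], acc_an[cell]
        k = max(1, int(np.floor(frac * r_ai.size)))
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(r_ai.size, size=k, replace=False)
            diffs[b] = r_ai[idx].mean() - r_an[idx].mean()
        p = (1.0 + np.sum(diffs <= 0.0)) / (n_boot + 1.0)
        rows.append((*cell, float(r_ai.mean() - r_an.mean()), float(p)))
    return pd.DataFrame(rows, columns=["roi", "stage", "diff", "p"])


def test_generalization(
    bank: ModelBank,
    activation_stacks_adv: list[ActivationStack],
    responses: ResponseDataset,
    image_type: str,
    frac: float = 0.8,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    orientation: str = "per_vertex",
) -> pd.DataFrame:
    """Prediction accuracy of the RE-trained models on adversarial images.

    Per vertex, Pearson r between predicted and measured responses across
    the adversarial images (``orientation='per_vertex'``, default) or per
    image across vertices (``'per_image'``).  Per (ROI, stage) cell:
    mean accuracy, bootstrap CI from resampling ``frac`` of the vertices
    ``n_boot`` times without replacement, and a permutation p from shuffling
    the image labels of the measured responses.
    """
    if orientation not in ("per_vertex", "per_image"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    measured_all = responses.mean_over_reps(image_type)  # vertices x images
    id_to_row = {
        int(v): i for i, v in enumerate(responses.sheet.table["vertex_id"].to_numpy())
    }
    rng = np.random.default_rng(seed)
    rows = []
    for (roi, stage), cell in bank.models.items():
        design = bank.designs[stage]
        acts = np.stack([s.per_stage[stage] for s in activation_stacks_adv])
        X_adv = design.transform(acts)
        vids = sorted(cell.keys())
        W = np.stack([cell[v].w for v in vids], axis=1)  # (n+1) x vertices
        predicted = X_adv @ W  # images x vertices
        measured = measured_all[[id_to_row[v] for v in vids]].T  # images x vertices
        if orientation == "per_vertex":
            r_obs = _columnwise_pearson(predicted, measured)
        else:
            r_obs = _columnwise_pearson(predicted.T, measured.T)
        mean_r = float(r_obs.mean())

        k = max(1, int(np.floor(frac * r_obs.size)))
        boot = np.array([
            r_obs[rng.choice(r_obs.size, size=k, replace=False)].mean()
            for _ in range(n_boot)
        ])
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

        m = measured.shape[0]
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(m)
            if orientation == "per_vertex":
                null[b] = _columnwise_pearson(predicted, measured[perm]).mean()
            else:
                null[b] = _columnwise_pearson(predicted.T, measured[perm].T).mean()
        p = (1.0 + np.sum(null >= mean_r)) / (n_perm + 1.0)
        rows.append((roi, stage, image_type, mean_r, ci[0], ci[1], float(p), len(vids)))
    return pd.DataFrame(
        rows,
        columns=["roi", "stage", "image_type", "mean_r", "ci_lo", "ci_hi", "p", "n_vertices"],
    )


# the name follows the operation it implements; it is not a pytest test
test_generalization.__test__ = False
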