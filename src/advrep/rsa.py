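"""Representational similarity analysis with resampling inference.

The central objects are representational dissimilarity matrices (RDMs):
for a set of items (images), the pairwise dissimilarity between the response
patterns they evoke in some unit population (one classifier stage's
artificial neurons, or a set of cortical vertices).  Two representational
geometries are compared by Spearman rank correlation of the strictly upper
triangles of their RDMs.

Inference follows the resampling scheme used throughout the analysis:

* the RE-AI vs RE-AN *difference* is assessed by subsampling 80% of the
  units without replacement 1000 times and recomputing both similarities
  (one-sided bootstrap p for a positive difference);
* *absolute* similarities are tested against a label-permutation null in
  which the RE item labels are shuffled within each unit subsample;
* monotonic trends across the 8 classifier stages use the Mann-Kendall test
  (tie-corrected variance, continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .model import ConfigurationError, DataError
from .synth import CorticalSheet, ResponseDataset

# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------


@dataclass
class RDM:
    matrix: np.ndarray
    item_ids: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise DataError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise DataError("RDM diagonal must be zero")

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        """Strictly-upper-triangle entries, row-major."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.item_ids, columns=self.item_ids)


def compute_rdm(
    activations: np.ndarray,
    item_ids: np.ndarray | None = None,
    metric: str = "correlation",
) -> RDM:
    """RDM over an (items x features) matrix.

    ``metric='correlation'`` (default): 1 - Pearson correlation between item
    feature vectors.  ``metric='euclidean'`` is available as an alternative.
    An item whose feature vector has zero variance makes correlation distance
    undefined and raises a :class:`DataError` naming the item.
    """
    acts = np.asarray(activations, dtype=np.float64)
    if acts.ndim != 2 or acts.shape[0] < 2:
        raise DataError("need an (items x features) matrix with >= 2 items")
    n = acts.shape[0]
    ids = np.arange(n) if item_ids is None else np.asarray(item_ids)
    if ids.shape[0] != n:
        raise DataError("item_ids length must match the number of items")
    if metric == "correlation":
        sd = acts.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DataError(
                f"zero-variance feature vector for item(s) {ids[bad].tolist()}: "
                "correlation distance undefined"
            )
        mat = 1.0 - np.corrcoef(acts)
    elif metric == "euclidean":
        mat = squareform(pdist(acts, metric="euclidean"))
    else:
        raise ConfigurationError(f"unknown RDM metric {metric!r}")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return RDM(matrix=mat, item_ids=ids)


def rdm_similarity(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rank correlation of the two strictly-upper triangles
    (average ranks for ties)."""
    if rdm_a.n_items != rdm_b.n_items or not np.array_equal(rdm_a.item_ids, rdm_b.item_ids):
        raise DataError("RDMs must share item sets and ordering")
    return float(stats.spearmanr(rdm_a.upper(), rdm_b.upper()).statistic)


def _triplet_similarities(
    acts_re: np.ndarray, acts_an: np.ndarray, acts_ai: np.ndarray, metric: str
) -> tuple[float, float]:
    rdm_re = compute_rdm(acts_re, metric=metric)
    rdm_an = compute_rdm(acts_an, metric=metric)
    rdm_ai = compute_rdm(acts_ai, metric=metric)
    return rdm_similarity(rdm_re, rdm_an), rdm_similarity(rdm_re, rdm_ai)


def similarity_pair(
    acts_re: np.ndarray,
    acts_an: np.ndarray,
    acts_ai: np.ndarray,
    metric: str = "correlation",
) -> tuple[float, float]:
    """(RE-AN, RE-AI) RDM similarities for one unit population.

    Rows must be ordered identically (by class) across the three matrices.
    """
    shapes = {a.shape for a in (acts_re, acts_an, acts_ai)}
    if len(shapes) != 1:
        raise DataError(f"activation matrices must share shape, got {shapes}")
    return _triplet_similarities(acts_re, acts_an, acts_ai, metric)


# ---------------------------------------------------------------------------
# resampling inference
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """80%-unit-subsample distribution of the RE-AI minus RE-AN difference."""

    diffs: np.ndarray
    point_diff: float
    ci: tuple[float, float]
    p: float  # one-sided: evidence that RE-AI exceeds RE-AN
    n_boot: int
    frac: float


def bootstrap_difference(
    acts_re: np.ndarray,
    acts_an: np.ndarray,
    acts_ai: np.ndarray,
    frac: float = 0.8,
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "correlation",
) -> BootstrapResult:
    """Subsample ``floor(frac * n_units)`` units without replacement
    ``n_boot`` times; per replicate recompute both similarities and the
    difference.  CI is the empirical 2.5/97.5 percentile interval; the
    one-sided p uses the add-one estimator ``(1 + #{diff <= 0}) / (n_boot + 1)``.
    """
    if not 0.0 < frac <= 1.0:
        raise ConfigurationError(f"frac must lie in (0, 1], got {frac}")
    n_units = acts_re.shape[1]
    if n_units < 10:
        raise DataError("need at least 10 units to subsample")
    k = int(np.floor(frac * n_units))
    rng = np.random.default_rng(seed)
    r_an, r_ai = similarity_pair(acts_re, acts_an, acts_ai, metric=metric)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.choice(n_units, size=k, replace=False)
        s_an, s_ai = _triplet_similarities(
            acts_re[:, cols], acts_an[:, cols], acts_ai[:, cols], metric
        )
        diffs[b] = s_ai - s_an
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    p = (1.0 + np.sum(diffs <= 0.0)) / (n_boot + 1.0)
    return BootstrapResult(diffs=diffs, point_diff=r_ai - r_an, ci=ci,
                           p=float(p), n_boot=n_boot, frac=frac)


@dataclass
class PermutationResult:
    """Label-permutation null for one absolute RE-adversarial similarity."""

    null: np.ndarray
    observed: float
    p: float  # one-sided: observed >= null
    n_perm: int


def permutation_null(
    acts_re: np.ndarray,
    acts_adv: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    frac: float = 0.8,
    metric: str = "correlation",
) -> PermutationResult:
    """Null distribution by shuffling the RE item labels.

    Per replicate a random unit subsample (``frac`` without replacement) is
    drawn and the RE rows are permuted within it before recomputing the
    similarity — the permutation is nested inside the unit resampling.
    ``frac=1.0`` gives a plain label permutation on the full unit set.
    """
    if acts_re.shape[0] < 5:
        raise DataError("need at least 5 items for a meaningful permutation null")
    if not 0.0 < frac <= 1.0:
        raise ConfigurationError(f"frac must lie in (0, 1], got {frac}")
    n_items, n_units = acts_re.shape
    k = int(np.floor(frac * n_units))
    rng = np.random.default_rng(seed)
    observed = rdm_similarity(compute_rdm(acts_re, metric=metric),
                              compute_rdm(acts_adv, metric=metric))
    null = np.empty(n_perm)
    for b in range(n_perm):
        cols = rng.choice(n_units, size=k, replace=False) if frac < 1.0 else slice(None)
        perm = rng.permutation(n_items)
        null[b] = rdm_similarity(
            compute_rdm(acts_re[perm][:, cols], metric=metric),
            compute_rdm(acts_adv[:, cols], metric=metric),
        )
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(null=null, observed=float(observed), p=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------


@dataclass
class MannKendallResult:
    S: int
    variance: float
    z: float
    p: float  # two-sided


def mann_kendall(sequence) -> MannKendallResult:
    """Mann-Kendall monotonic-trend test.

    ``S`` is the sum of ``sign(x_j - x_i)`` over all pairs ``i < j``; its
    variance uses the tie correction; ``z`` applies the +-1 continuity
    correction and the p-value is two-sided normal.
    """
    x = np.asarray(sequence, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ConfigurationError("Mann-Kendall needs a sequence of length >= 3")
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return MannKendallResult(S=s, variance=float(var), z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# per-population summary, layer profile, searchlight
# ---------------------------------------------------------------------------


@dataclass
class SimilaritySummary:
    r_re_an: float
    r_re_ai: float
    diff: float
    boot_ci: tuple[float, float]
    boot_p: float
    perm_p_an: float
    perm_p_ai: float
    n_boot: int
    n_perm: int
    n_units: int


def summarize_similarity(
    acts_re: np.ndarray,
    acts_an: np.ndarray,
    acts_ai: np.ndarray,
    frac: float = 0.8,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "correlation",
) -> SimilaritySummary:
    """Full inferential summary for one unit population (ROI or stage)."""
    r_an, r_ai = similarity_pair(acts_re, acts_an, acts_ai, metric=metric)
    boot = bootstrap_difference(acts_re, acts_an, acts_ai, frac=frac,
                                n_boot=n_boot, seed=seed, metric=metric)
    perm_an = permutation_null(acts_re, acts_an, n_perm=n_perm, seed=seed + 1,
                               frac=frac, metric=metric)
    perm_ai = permutation_null(acts_re, acts_ai, n_perm=n_perm, seed=seed + 2,
                               frac=frac, metric=metric)
    return SimilaritySummary(
        r_re_an=float(r_an), r_re_ai=float(r_ai), diff=float(r_ai - r_an),
        boot_ci=boot.ci, boot_p=boot.p, perm_p_an=perm_an.p, perm_p_ai=perm_ai.p,
        n_boot=n_boot, n_perm=n_perm, n_units=acts_re.shape[1],
    )


@dataclass
class LayerProfile:
    summaries: dict[str, SimilaritySummary]  # per stage, in L1..L8 order
    trend_re_an: MannKendallResult
    trend_re_ai: MannKendallResult


def layer_profile(
    model,
    re_set,
    an_set,
    ai_set,
    frac: float = 0.8,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "correlation",
) -> LayerProfile:
    """Per-stage similarity summaries plus Mann-Kendall trends over stages.

    Activation matrices are built per stage from the three stimulus sets
    (rows ordered by the shared class ordering of the sets).
    """
    from .encoding import stack_activations  # shared activation plumbing

    acts = {kind: stack_activations(model, s)
            for kind, s in (("RE", re_set), ("AN", an_set), ("AI", ai_set))}
    stages = list(acts["RE"].keys())
    summaries = {}
    for i, stage in enumerate(stages):
        summaries[stage] = summarize_similarity(
            acts["RE"][stage], acts["AN"][stage], acts["AI"][stage],
            frac=frac, n_boot=n_boot, n_perm=n_perm, seed=seed + 10 * i, metric=metric,
        )
    an_vals = [summaries[s].r_re_an for s in stages]
    ai_vals = [summaries[s].r_re_ai for s in stages]
    return LayerProfile(
        summaries=summaries,
        trend_re_an=mann_kendall(an_vals),
        trend_re_ai=mann_kendall(ai_vals),
    )


def searchlight_disks(sheet: CorticalSheet, radius: float = 3.0) -> list[np.ndarray]:
    """Vertex ids within ``radius`` (flat-map Euclidean distance) of each
    vertex, hemisphere-restricted.  The flat-map distance stands in for the
    geodesic distance on the flattened surface."""
    table = sheet.table
    ids = table["vertex_id"].to_numpy()
    disks: dict[int, np.ndarray] = {}
    for hemi in table["hemisphere"].unique():
        mask = (table["hemisphere"] == hemi).to_numpy()
        coords = table.loc[mask, ["x", "y"]].to_numpy()
        hemi_ids = ids[mask]
        tree = cKDTree(coords)
        neighbours = tree.query_ball_point(coords, r=radius)
        for vid, nb in zip(hemi_ids, neighbours):
            disks[int(vid)] = hemi_ids[np.sort(nb)]
    return [disks[int(v)] for v in ids]


def searchlight_map(
    responses: ResponseDataset,
    radius: float = 3.0,
    metric: str = "correlation",
    min_disk: int = 3,
) -> pd.DataFrame:
    """Per-vertex (RE-AN, RE-AI) similarity over the vertex's searchlight disk.

    Repetitions are averaged; disks with fewer than ``min_disk`` vertices
    yield missing values.  Returns a frame with columns vertex_id, roi,
    hemisphere, n_disk, r_re_an, r_re_ai.
    """
    sheet = responses.sheet
    mean = {k: responses.mean_over_reps(k) for k in ("RE", "AN", "AI")}
    id_to_row = {int(v): i for i, v in enumerate(sheet.table["vertex_id"].to_numpy())}
    rows = []
    for (vid, roi, hemi), disk in zip(
        sheet.table[["vertex_id", "roi", "hemisphere"]].itertuples(index=False),
        searchlight_disks(sheet, radius),
    ):
        if disk.size < min_disk:
            rows.append((vid, roi, hemi, disk.size, np.nan, np.nan))
            continue
        sel = [id_to_row[int(v)] for v in disk]
        r_an, r_ai = similarity_pair(
            mean["RE"][sel].T, mean["AN"][sel].T, mean["AI"][sel].T, metric=metric
        )
        rows.append((vid, roi, hemi, disk.size, r_an, r_ai))
    return pd.DataFrame(
        rows, columns=["vertex_id", "roi", "hemisphere", "n_disk", "r_re_an", "r_re_ai"]
    )
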