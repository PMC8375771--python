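"""Synthetic inputs for the adversarial-representation pipeline.

Everything the analysis chain consumes can be generated here from seeds:

* class-labelled parametric images (stand-ins for natural object categories),
* the event-related experiment design (runs of image/blank trials),
* a flattened two-hemisphere cortical sheet with five visual ROIs,
* vertex "beta" responses built as sparse linear combinations of classifier
  layer features, with controllable representational coupling between the
  regular-image responses and the simulated adversarial-image responses.

The response simulator operates at the response-pattern level: the responses
to adversarial-interference (AI) and adversarial-noise (AN) images are
variance-matched mixtures of the vertex's regular-image (RE) pattern and
independent noise, with mixing weights ``rho_AI`` / ``rho_AN``.  This makes
the ground truth of every recovery test explicit and tunable, which feeding
adversarial images through a simulated brain would not.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ConfigurationError, DataError

BLANK = None  # sentinel for blank trials inside a run
ROIS = ("V1", "V2", "V3", "V4", "LO")
HEMISPHERES = ("LH", "RH")
#: default mapping from ROI to the classifier stage that drives its vertices,
#: following the ventral-stream hierarchy (early ROIs <- early stages)
DEFAULT_LAYER_ASSIGNMENT = {"V1": "L1", "V2": "L2", "V3": "L3", "V4": "L4", "LO": "L5"}


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImage:
    pixels: np.ndarray  # H x W x C, float in [0, 255]
    class_id: int
    nuisance: dict

    def __post_init__(self):
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise DataError("pixel intensities must lie in [0, 255]")


@dataclass
class StimulusSet:
    images: list[SyntheticImage]
    image_type: str  # RE | AN | AI
    image_size: int
    n_classes: int
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.images)

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([im.class_id for im in self.images])

    def pixel_array(self) -> np.ndarray:
        """All images stacked to (N, H, W, C)."""
        return np.stack([im.pixels for im in self.images])


def _class_parameters(k: int, n_classes: int) -> dict:
    """Deterministic per-class pattern parameters (orientation, frequency,
    blob placement, RGB tint) spread so neighbouring classes differ in at
    least one strong cue."""
    theta = np.pi * k / n_classes
    freq = 2.0 + (k % 5)
    blob_angle = 2.0 * np.pi * ((k * 7) % n_classes) / max(n_classes, 1)
    tint = np.array([
        1.0,
        0.55 + 0.45 * np.cos(2 * np.pi * k / n_classes),
        0.55 + 0.45 * np.sin(2 * np.pi * k / n_classes),
    ])
    return {"theta": theta, "freq": freq, "blob_angle": blob_angle, "tint": tint}


def _render_image(size: int, params: dict, nuisance: dict) -> np.ndarray:
    u, v = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size), indexing="ij")
    theta = params["theta"] + nuisance["dtheta"]
    grating = np.sin(
        2 * np.pi * params["freq"] * (u * np.cos(theta) + v * np.sin(theta))
        + nuisance["phase"]
    )
    cx = 0.5 + 0.3 * np.cos(params["blob_angle"]) + nuisance["blob_dx"]
    cy = 0.5 + 0.3 * np.sin(params["blob_angle"]) + nuisance["blob_dy"]
    blob = np.exp(-(((u - cx) ** 2 + (v - cy) ** 2) / (2 * 0.12**2)))
    pattern = nuisance["amplitude"] * (0.6 * grating + 1.0 * blob - 0.35)
    img = 127.5 + 95.0 * pattern[:, :, None] * params["tint"][None, None, :]
    img = img + nuisance["pixel_noise"]
    return np.clip(img, 0.0, 255.0)


def generate_image_classes(
    n_classes: int = 40,
    n_per_class: int = 1,
    image_size: int = 32,
    seed: int = 0,
) -> StimulusSet:
    """Generate the regular (RE) stimulus set: parametric class exemplars.

    Each class is defined by an oriented grating (class-specific orientation
    and spatial frequency), a Gaussian blob at a class-specific position and
    an RGB tint; nuisance jitter (phase, small orientation perturbation,
    amplitude, blob displacement, pixel noise) varies across exemplars.
    """
    if n_classes < 2:
        raise ConfigurationError("need at least 2 image classes")
    if image_size < 16:
        raise ConfigurationError("image_size must be >= 16")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images = []
    for k in range(n_classes):
        params = _class_parameters(k, n_classes)
        for _ in range(n_per_class):
            nuis = {
                "phase": float(rng.uniform(0, 2 * np.pi)),
                "dtheta": float(rng.uniform(-np.deg2rad(2.0), np.deg2rad(2.0))),
                "amplitude": float(rng.uniform(0.85, 1.15)),
                "blob_dx": float(rng.uniform(-0.03, 0.03)),
                "blob_dy": float(rng.uniform(-0.03, 0.03)),
            }
            noise = rng.normal(0.0, 6.0, (image_size, image_size, 3))
            nuis["pixel_noise"] = noise
            pixels = _render_image(image_size, params, nuis)
            nuis_record = {k2: v for k2, v in nuis.items() if k2 != "pixel_noise"}
            images.append(SyntheticImage(pixels=pixels, class_id=k, nuisance=nuis_record))
    return StimulusSet(
        images=images, image_type="RE", image_size=image_size,
        n_classes=n_classes, seed=seed,
        metadata={"n_per_class": n_per_class},
    )


def save_stimulus_set(stim: StimulusSet, directory: str | Path) -> None:
    """Write images as PNG plus a JSON manifest of labels and parameters."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "image_type": stim.image_type, "image_size": stim.image_size,
        "n_classes": stim.n_classes, "seed": stim.seed,
        "metadata": stim.metadata, "images": [],
    }
    for i, im in enumerate(stim.images):
        name = f"{stim.image_type.lower()}_{i:04d}_class{im.class_id:03d}.png"
        Image.fromarray(np.round(im.pixels).astype(np.uint8)).save(directory / name)
        manifest["images"].append({"file": name, "class_id": im.class_id,
                                   "nuisance": im.nuisance})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Trial orders of an event-related design: sessions of runs of trials.

    A trial is ``(image_id, onset_index)`` with ``image_id=None`` for blanks.
    Every non-blank image of a session appears exactly ``reps_per_image``
    times in every run of that session.
    """

    sessions: list[list[list[tuple[int | None, int]]]]
    reps_per_image: int
    blanks_per_run: int
    n_images_per_session: int
    seed: int

    @property
    def n_images_total(self) -> int:
        return self.n_images_per_session * len(self.sessions)

    @property
    def trials_per_run(self) -> int:
        return self.n_images_per_session * self.reps_per_image + self.blanks_per_run


def build_design(
    n_images_per_session: int = 60,
    reps_per_image: int = 2,
    blanks_per_run: int = 9,
    runs_per_session: int = 5,
    sessions: int = 2,
    seed: int = 0,
) -> ExperimentDesign:
    """Build the trial orders: per run, every session image ``reps_per_image``
    times plus ``blanks_per_run`` blank trials, in seeded-random order.

    At the defaults each run holds 60 x 2 + 9 = 129 trials, and the image
    set is split evenly over the sessions (session s shows images
    ``[s*60, (s+1)*60)``).
    """
    counts = dict(n_images_per_session=n_images_per_session, reps_per_image=reps_per_image,
                  runs_per_session=runs_per_session, sessions=sessions)
    for name, val in counts.items():
        if not isinstance(val, (int, np.integer)) or val < 1:
            raise ConfigurationError(f"{name} must be a positive integer, got {val!r}")
    if not isinstance(blanks_per_run, (int, np.integer)) or blanks_per_run < 0:
        raise ConfigurationError(f"blanks_per_run must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    session_list = []
    for s in range(sessions):
        image_ids = np.arange(s * n_images_per_session, (s + 1) * n_images_per_session)
        runs = []
        for _r in range(runs_per_session):
            pool = np.concatenate([np.repeat(image_ids, reps_per_image),
                                   np.full(blanks_per_run, -1)])
            order = rng.permutation(pool)
            runs.append([(None if x < 0 else int(x), t) for t, x in enumerate(order)])
        session_list.append(runs)
    return ExperimentDesign(
        sessions=session_list, reps_per_image=reps_per_image,
        blanks_per_run=blanks_per_run, n_images_per_session=n_images_per_session,
        seed=seed,
    )


@dataclass
class ConditionTable:
    """GLM predictors: one per (image, repetition) pair plus a single blank."""

    predictors: list[tuple[int, int] | str]

    def __len__(self):
        return len(self.predictors)


def enumerate_conditions(design: ExperimentDesign) -> ConditionTable:
    """One distinct predictor per (image, within-run repetition index) over
    the whole experiment, plus exactly one predictor for all blank trials.

    At the defaults: 120 images x 2 repetitions + 1 blank = 241 predictors.
    """
    predictors: list[tuple[int, int] | str] = [
        (img, rep)
        for img in range(design.n_images_total)
        for rep in range(design.reps_per_image)
    ]
    predictors.append("BLANK")
    return ConditionTable(predictors=predictors)


# ---------------------------------------------------------------------------
# cortical sheet
# ---------------------------------------------------------------------------

@dataclass
class CorticalSheet:
    """Flattened-surface vertex table: id, hemisphere, ROI, 2D coordinate.

    Coordinates are in sheet units with typical nearest-neighbour spacing of
    about 1; (ROI, hemisphere) blocks are laid out spatially disjoint so that
    searchlight disks never span blocks.
    """

    table: pd.DataFrame  # columns: vertex_id, hemisphere, roi, x, y

    def __len__(self):
        return len(self.table)

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["roi"]))

    def block(self, roi: str, hemisphere: str) -> np.ndarray:
        t = self.table
        return t.loc[(t.roi == roi) & (t.hemisphere == hemisphere), "vertex_id"].to_numpy()

    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def make_sheet(
    n_vertices_per_roi_per_hemi: int = 150,
    rois: tuple[str, ...] = ROIS,
    seed: int = 0,
    jitter: float = 0.15,
    block_gap: float = 12.0,
) -> CorticalSheet:
    """Lay each (ROI, hemisphere) block out as a jittered square grid.

    Unit grid spacing; ``block_gap`` sheet units separate blocks so local
    neighbourhoods stay within one block.
    """
    if n_vertices_per_roi_per_hemi < 1:
        raise ConfigurationError("need at least 1 vertex per block")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_vertices_per_roi_per_hemi)))
    rows = []
    vid = 0
    for hi, hemi in enumerate(HEMISPHERES):
        for ri, roi in enumerate(rois):
            x0 = ri * (side + block_gap)
            y0 = hi * (side + block_gap)
            gi, gj = np.unravel_index(
                np.arange(n_vertices_per_roi_per_hemi), (side, side)
            )
            xs = x0 + gi + rng.uniform(-jitter, jitter, gi.size)
            ys = y0 + gj + rng.uniform(-jitter, jitter, gj.size)
            for x, y in zip(xs, ys):
                rows.append((vid, hemi, roi, float(x), float(y)))
                vid += 1
    table = pd.DataFrame(rows, columns=["vertex_id", "hemisphere", "roi", "x", "y"])
    return CorticalSheet(table=table)


# ---------------------------------------------------------------------------
# vertex responses
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to regenerate a ResponseDataset bit-exactly."""

    source_layer: np.ndarray  # per-vertex stage name
    feature_indices: np.ndarray  # n_vertices x sparsity_k
    weights: np.ndarray  # n_vertices x sparsity_k
    rho_AI: float
    rho_AN: float
    rep_noise_sd: float
    sparsity_k: int
    n_reps: int
    seed: int


@dataclass
class ResponseDataset:
    """Beta responses (vertex x image x repetition) per image type, plus the
    sheet and the generating ground truth."""

    betas: dict[str, np.ndarray]  # keys RE, AN, AI
    sheet: CorticalSheet
    ground_truth: GroundTruth

    @property
    def n_vertices(self) -> int:
        return self.betas["RE"].shape[0]

    @property
    def n_images(self) -> int:
        return self.betas["RE"].shape[1]

    @property
    def n_reps(self) -> int:
        return self.betas["RE"].shape[2]

    def mean_over_reps(self, image_type: str) -> np.ndarray:
        return self.betas[image_type].mean(axis=2)


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def simulate_vertex_responses(
    activations_by_layer: dict[str, np.ndarray],
    sheet: CorticalSheet,
    sparsity_k: int = 3,
    rho_AI: float = 0.8,
    rho_AN: float = 0.0,
    rep_noise_sd: float = 0.5,
    seed: int = 0,
    n_reps: int = 2,
    layer_assignment: dict[str, str] | None = None,
) -> ResponseDataset:
    """Simulate vertex betas for RE, AN and AI images.

    Each vertex's noiseless RE response pattern is a ``sparsity_k``-sparse
    linear combination of its assigned classifier stage's features over the
    RE images, z-scored across images.  AI and AN patterns are mixtures
    ``rho * RE + sqrt(1 - rho**2) * independent noise`` rescaled to unit
    variance; ``rho=1`` reproduces RE exactly and ``rho=0`` is independent.
    Gaussian repetition noise (sd ``rep_noise_sd``) is added per presentation.

    ``activations_by_layer`` maps stage names to (n_images x n_features)
    matrices of RE-image activations; the ROI->stage assignment defaults to
    the ventral-hierarchy mapping V1..LO -> L1..L5.
    """
    if not 0.0 <= rho_AI <= 1.0 or not 0.0 <= rho_AN <= 1.0:
        raise ConfigurationError("rho_AI and rho_AN must lie in [0, 1]")
    if sparsity_k < 1:
        raise ConfigurationError("sparsity_k must be >= 1")
    assignment = dict(layer_assignment or DEFAULT_LAYER_ASSIGNMENT)
    for roi in sheet.rois:
        stage = assignment.get(roi)
        if stage is None:
            raise DataError(f"no layer assignment for ROI {roi}")
        if stage not in activations_by_layer:
            raise DataError(f"missing activations for stage {stage} (ROI {roi})")

    n_images = next(iter(activations_by_layer.values())).shape[0]
    n_vertices = len(sheet)
    rng = np.random.default_rng(seed)

    rois_per_vertex = sheet.table["roi"].to_numpy()
    source_layer = np.array([assignment[r] for r in rois_per_vertex])
    feat_idx = np.empty((n_vertices, sparsity_k), dtype=np.int64)
    weights = np.empty((n_vertices, sparsity_k))
    re_pattern = np.empty((n_vertices, n_images))
    for v in range(n_vertices):
        acts = activations_by_layer[source_layer[v]]
        feat_idx[v] = rng.choice(acts.shape[1], size=sparsity_k, replace=False)
        weights[v] = rng.normal(0.0, 1.0, sparsity_k)
        re_pattern[v] = acts[:, feat_idx[v]] @ weights[v]
    re_pattern = _zscore_rows(re_pattern)

    def mixture(rho: float) -> np.ndarray:
        noise = _zscore_rows(rng.normal(0.0, 1.0, (n_vertices, n_images)))
        mixed = rho * re_pattern + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        return re_pattern.copy() if rho == 1.0 else _zscore_rows(mixed)

    patterns = {"RE": re_pattern, "AI": mixture(rho_AI), "AN": mixture(rho_AN)}
    betas = {}
    for kind in ("RE", "AN", "AI"):
        noise = rng.normal(0.0, rep_noise_sd, (n_vertices, n_images, n_reps))
        betas[kind] = patterns[kind][:, :, None] + noise

    gt = GroundTruth(
        source_layer=source_layer, feature_indices=feat_idx, weights=weights,
        rho_AI=float(rho_AI), rho_AN=float(rho_AN), rep_noise_sd=float(rep_noise_sd),
        sparsity_k=int(sparsity_k), n_reps=int(n_reps), seed=int(seed),
    )
    return ResponseDataset(betas=betas, sheet=sheet, ground_truth=gt)


def regenerate_responses(
    dataset: ResponseDataset, activations_by_layer: dict[str, np.ndarray]
) -> ResponseDataset:
    """Re-run the simulator from the stored ground-truth parameters.

    With the same activation matrices this reproduces the betas bit-exactly
    (the simulator is a pure function of its arguments).
    """
    gt = dataset.ground_truth
    assignment = {
        roi: gt.source_layer[dataset.sheet.table["roi"].to_numpy() == roi][0]
        for roi in dataset.sheet.rois
    }
    return simulate_vertex_responses(
        activations_by_layer, dataset.sheet, sparsity_k=gt.sparsity_k,
        rho_AI=gt.rho_AI, rho_AN=gt.rho_AN, rep_noise_sd=gt.rep_noise_sd,
        seed=gt.seed, n_reps=gt.n_reps, layer_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 container + CSV sheet export)
# ---------------------------------------------------------------------------

def save_responses(dataset: ResponseDataset, path: str | Path) -> None:
    """HDF5 layout: /betas/<type>, /sheet/<column>, /ground_truth/<field>."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("betas")
        for kind, arr in dataset.betas.items():
            g.create_dataset(kind, data=arr)
        s = f.create_group("sheet")
        for col in dataset.sheet.table.columns:
            data = dataset.sheet.table[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            s.create_dataset(col, data=data)
        gt = dataset.ground_truth
        t = f.create_group("ground_truth")
        t.create_dataset("source_layer", data=gt.source_layer.astype("S"))
        t.create_dataset("feature_indices", data=gt.feature_indices)
        t.create_dataset("weights", data=gt.weights)
        for name in ("rho_AI", "rho_AN", "rep_noise_sd", "sparsity_k", "n_reps", "seed"):
            t.attrs[name] = getattr(gt, name)


def load_responses(path: str | Path) -> ResponseDataset:
    import h5py

    with h5py.File(path, "r") as f:
        betas = {k: f["betas"][k][()] for k in f["betas"]}
        cols = {}
        for col in f["sheet"]:
            data = f["sheet"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        table = pd.DataFrame(cols)[["vertex_id", "hemisphere", "roi", "x", "y"]]
        t = f["ground_truth"]
        gt = GroundTruth(
            source_layer=t["source_layer"][()].astype(str),
            feature_indices=t["feature_indices"][()],
            weights=t["weights"][()],
            rho_AI=float(t.attrs["rho_AI"]), rho_AN=float(t.attrs["rho_AN"]),
            rep_noise_sd=float(t.attrs["rep_noise_sd"]),
            sparsity_k=int(t.attrs["sparsity_k"]), n_reps=int(t.attrs["n_reps"]),
            seed=int(t.attrs["seed"]),
        )
    return ResponseDataset(betas=betas, sheet=CorticalSheet(table=table), ground_truth=gt)
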