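"""Adversarial image generation against any model exposing input gradients.

Two families of adversarial stimuli:

* **AN (adversarial noise)** — images that look noise-like but are classified
  into a target class with high confidence.  Generated by regularized
  gradient ascent on ``P_c(I) - lambda * ||I - I_mean||^2`` starting from the
  mean image, with pixel clipping, until the target-class probability reaches
  the stopping threshold (default 0.99).

* **AI (adversarial interference)** — regular images plus small noise that
  flips the classifier's label.  The default generator is an accept/reject
  hill-climb: fresh uniform noise in [-5, 5] is added to every pixel and the
  step is kept only if the wrong-class probability strictly increases,
  until it exceeds 0.5.  A gradient variant (same ascent as AN but anchored
  to the regular image, threshold 0.99) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ConfigurationError, SurrogateModel, input_gradient
from .synth import StimulusSet, SyntheticImage


@dataclass
class AdversarialConfig:
    """Knobs of both generators; see the module docstring for semantics.

    ``pixel_change_tol`` implements convergence detection for the gradient
    ascenders: stop (unconverged) when the max-abs pixel change over the
    last 10 iterations falls below it.
    """

    lambda_reg: float = 1e-8
    step_size: float = 500.0
    max_iter: int = 3000
    target_prob: float = 0.99
    noise_bound: float = 5.0
    pixel_range: tuple[float, float] = (0.0, 255.0)
    pixel_change_tol: float = 1e-3
    gradient_of: str = "logprob"  # ascend log P_c (same direction as P_c,
    # rescaled by 1/P_c; avoids the softmax plateau at P_c ~ 0); "prob" optional

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ConfigurationError("lambda_reg must be >= 0")
        if not 0.0 < self.target_prob < 1.0:
            raise ConfigurationError("target_prob must lie in (0, 1)")
        if self.noise_bound <= 0:
            raise ConfigurationError("noise_bound must be positive")


#: hill-climb default stops at wrong-class probability 0.5; proposals are
#: cheap (one forward pass), so the iteration budget is generous
AI_HILLCLIMB_CONFIG = AdversarialConfig(target_prob=0.5, max_iter=20000)


@dataclass
class GenerationResult:
    image: SyntheticImage
    trajectory: np.ndarray  # per-iteration target-class probability (incl. start)
    iterations: int
    converged: bool
    stop_reason: str
    metadata: dict = field(default_factory=dict)

    @property
    def final_prob(self) -> float:
        return float(self.trajectory[-1])


def _target_prob(model: SurrogateModel, image: np.ndarray, class_id: int) -> float:
    return float(model.predict_proba(image[None])[0, class_id])


def _gradient_ascent(
    model: SurrogateModel,
    init: np.ndarray,
    target_class: int,
    anchor: np.ndarray,
    config: AdversarialConfig,
    metadata: dict,
) -> GenerationResult:
    lo, hi = config.pixel_range
    img = np.clip(np.asarray(init, dtype=np.float64).copy(), lo, hi)
    traj = [_target_prob(model, img, target_class)]
    recent_changes: list[float] = []
    stop_reason = "max_iter"
    iters = 0
    if traj[0] >= config.target_prob:
        stop_reason = "target_prob"
    else:
        for iters in range(1, config.max_iter + 1):
            g = input_gradient(model, img, target_class, of=config.gradient_of)
            g = g - 2.0 * config.lambda_reg * (img - anchor)
            new = np.clip(img + config.step_size * g, lo, hi)
            recent_changes.append(float(np.abs(new - img).max()))
            img = new
            traj.append(_target_prob(model, img, target_class))
            if traj[-1] >= config.target_prob:
                stop_reason = "target_prob"
                break
            if len(recent_changes) >= 10 and max(recent_changes[-10:]) < config.pixel_change_tol:
                stop_reason = "pixel_convergence"
                break
    converged = traj[-1] >= config.target_prob
    result_img = SyntheticImage(pixels=img, class_id=target_class,
                                nuisance=dict(metadata))
    return GenerationResult(
        image=result_img, trajectory=np.array(traj), iterations=iters,
        converged=converged, stop_reason=stop_reason, metadata=metadata,
    )


def generate_an(
    model: SurrogateModel,
    target_class: int,
    mean_image: np.ndarray,
    config: AdversarialConfig | None = None,
    seed: int | None = None,
) -> GenerationResult:
    """Adversarial-noise image: regularized ascent from the mean image.

    ``seed`` is accepted for interface symmetry; the ascent itself is
    deterministic.  A converged result satisfies
    ``P_target >= config.target_prob`` (default 0.99); non-convergence is
    flagged, never silent.
    """
    config = config or AdversarialConfig()
    meta = {"mode": "AN", "target_class": int(target_class),
            "init": "mean_image", "lambda_reg": config.lambda_reg,
            "step_size": config.step_size, "seed": seed}
    return _gradient_ascent(model, mean_image, target_class, mean_image, config, meta)


def generate_ai_gradient(
    model: SurrogateModel,
    re_image: np.ndarray,
    wrong_class: int,
    config: AdversarialConfig | None = None,
) -> GenerationResult:
    """Gradient-variant AI image: same ascent as AN but anchored to the
    regular image (threshold 0.99 by default)."""
    config = config or AdversarialConfig()
    meta = {"mode": "AI-grad", "wrong_class": int(wrong_class),
            "init": "re_image", "lambda_reg": config.lambda_reg,
            "step_size": config.step_size}
    return _gradient_ascent(model, re_image, wrong_class, re_image, config, meta)


def generate_ai_hillclimb(
    model: SurrogateModel,
    re_image: np.ndarray,
    wrong_class: int,
    config: AdversarialConfig | None = None,
    seed: int = 0,
) -> GenerationResult:
    """Accept/reject noise hill-climb toward the wrong class.

    Per iteration fresh uniform noise in ``[-noise_bound, +noise_bound]`` is
    added to every pixel (then clipped); the proposal is kept iff the
    wrong-class probability strictly increases.  Stops when that probability
    exceeds ``config.target_prob`` (default 0.5) or at ``max_iter``.
    """
    config = config or AI_HILLCLIMB_CONFIG
    rng = np.random.default_rng(seed)
    lo, hi = config.pixel_range
    img = np.clip(np.asarray(re_image, dtype=np.float64).copy(), lo, hi)
    prob = _target_prob(model, img, wrong_class)
    traj = [prob]
    stop_reason = "max_iter"
    iters = 0
    if prob > config.target_prob:
        stop_reason = "target_prob"
    else:
        for iters in range(1, config.max_iter + 1):
            noise = rng.uniform(-config.noise_bound, config.noise_bound, img.shape)
            proposal = np.clip(img + noise, lo, hi)
            p_new = _target_prob(model, proposal, wrong_class)
            if p_new > prob:
                img, prob = proposal, p_new
            traj.append(prob)
            if prob > config.target_prob:
                stop_reason = "target_prob"
                break
    meta = {"mode": "AI", "wrong_class": int(wrong_class), "seed": int(seed),
            "noise_bound": config.noise_bound}
    result_img = SyntheticImage(pixels=img, class_id=wrong_class, nuisance=dict(meta))
    return GenerationResult(
        image=result_img, trajectory=np.array(traj), iterations=iters,
        converged=prob > config.target_prob, stop_reason=stop_reason, metadata=meta,
    )


def assign_wrong_classes(class_ids: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded random derangement: every image gets a wrong class != its own."""
    class_ids = np.asarray(class_ids)
    classes = np.unique(class_ids)
    if classes.size < 2:
        raise ConfigurationError("need at least 2 classes for a derangement")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(classes)
        if not np.any(perm == classes):
            break
    mapping = dict(zip(classes.tolist(), perm.tolist()))
    return np.array([mapping[c] for c in class_ids.tolist()])


def select_wrong_classes(
    model: SurrogateModel,
    stimuli: StimulusSet,
    seed: int = 0,
    n_probes: int = 30,
    noise_bound: float = 5.0,
) -> np.ndarray:
    """Pre-select each image's wrong class by confusability probing.

    For each regular image, ``n_probes`` noisy copies (uniform noise within
    ``noise_bound``) are classified and the non-true class with the highest
    mean probability is chosen — the class the hill-climb can actually
    reach, mirroring the practice of pre-selecting a confusable wrong label
    (e.g. dog -> bird) rather than an arbitrary one.
    """
    rng = np.random.default_rng(seed)
    wrong = np.empty(len(stimuli), dtype=np.int64)
    for i, im in enumerate(stimuli.images):
        noisy = np.clip(
            im.pixels[None] + rng.uniform(-noise_bound, noise_bound,
                                          (n_probes,) + im.pixels.shape),
            0.0, 255.0,
        )
        mean_prob = model.predict_proba(noisy).mean(axis=0)
        mean_prob[im.class_id] = -1.0
        wrong[i] = int(np.argmax(mean_prob))
    return wrong


def mean_image(stimuli: StimulusSet) -> np.ndarray:
    """Grand average over the regular image set (the ascent's start/anchor)."""
    return stimuli.pixel_array().mean(axis=0)


def generate_adversarial_sets(
    model: SurrogateModel,
    re_set: StimulusSet,
    an_config: AdversarialConfig | None = None,
    ai_config: AdversarialConfig | None = None,
    seed: int = 0,
    wrong_class_policy: str = "confusability",
) -> tuple[StimulusSet, StimulusSet, dict]:
    """One AN and one AI counterpart per regular image.

    AN targets the regular image's own class (from the mean image); AI flips
    it to a pre-selected wrong class via the hill-climb.  Wrong classes are
    chosen by confusability probing by default (``'derangement'`` assigns a
    seeded random derangement instead).  Returns the two stimulus sets plus
    per-image diagnostics.
    """
    i_mean = mean_image(re_set)
    if wrong_class_policy == "confusability":
        wrong = select_wrong_classes(model, re_set, seed=seed)
    elif wrong_class_policy == "derangement":
        wrong = assign_wrong_classes(re_set.class_ids, seed=seed)
    else:
        raise ConfigurationError(f"unknown wrong_class_policy {wrong_class_policy!r}")
    an_images, ai_images, diags = [], [], {"AN": [], "AI": [], "wrong_classes": wrong.tolist()}
    for i, im in enumerate(re_set.images):
        an = generate_an(model, im.class_id, i_mean, config=an_config)
        an_images.append(replace(an.image, class_id=im.class_id))
        diags["AN"].append({"converged": an.converged, "iterations": an.iterations,
                            "final_prob": an.final_prob, "stop_reason": an.stop_reason})
        ai = generate_ai_hillclimb(model, im.pixels, int(wrong[i]),
                                   config=ai_config, seed=seed + 1000 + i)
        ai_images.append(replace(ai.image, class_id=im.class_id))
        diags["AI"].append({"converged": ai.converged, "iterations": ai.iterations,
                            "final_prob": ai.final_prob, "stop_reason": ai.stop_reason})
    mk = lambda imgs, kind: StimulusSet(  # noqa: E731
        images=imgs, image_type=kind, image_size=re_set.image_size,
        n_classes=re_set.n_classes, seed=seed,
    )
    return mk(an_images, "AN"), mk(ai_images, "AI"), diags
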