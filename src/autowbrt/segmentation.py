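"""Trainable DRR -> field-aperture segmentation.

The model is a compact per-pixel classifier: a fixed multi-scale context
feature bank (Gaussian pyramid, gradient and band-pass channels of the
per-image-normalized DRR, BEV coordinates, and the projected-body mask
with its signed distance) feeding a small multilayer perceptron trained
with weighted cross-entropy plus a soft-Dice overlap loss.  It is sized
to train in minutes on a CPU with a few dozen synthetic cases; inference
post-selection (threshold, largest component, hole fill, body clip)
turns the probability map into a single clean aperture mask.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .aperture import ApertureMask, clip_to_body, polygon_to_mask
from .projection import DRRImage

__all__ = [
    "SplitResult",
    "TrainingExample",
    "ModelState",
    "split_dataset",
    "train_model",
    "predict_aperture",
    "examples_from_cases",
]

FEATURE_NAMES = (
    "drr",
    "gauss1",
    "gauss2",
    "gauss4",
    "gauss8",
    "gauss16",
    "gradmag",
    "bandpass",
    "u_norm",
    "v_norm",
    "body",
    "body_sdist",
)

DEFAULT_CONFIG = {
    "hidden": (48, 24),
    "epochs": 30,
    "learning_rate": 0.01,
    "pos_weight": 2.0,
    "dice_weight": 1.0,
    "threshold": 0.5,
}


@dataclass(frozen=True)
class SplitResult:
    """A disjoint train / cross-validation / test partition of case ids."""

    train_ids: list
    cv_ids: list
    test_ids: list
    seed: int
    ratios: tuple[float, float, float]


def split_dataset(ids: list, ratios, seed: int) -> SplitResult:
    """Seeded shuffle then contiguous partition.

    Sizes follow ``train = round(r1*n)``, ``cv = round(r2*n)``,
    ``test = remainder`` — so 520 ids at (0.6, 0.2, 0.2) give 312/104/104.
    """
    r1, r2, r3 = (float(r) for r in ratios)
    if min(r1, r2, r3) < 0 or abs(r1 + r2 + r3 - 1.0) > 1e-9:
        raise ValueError("ratios must be nonnegative and sum to 1")
    ids = list(ids)
    n = len(ids)
    if n == 0:
        return SplitResult([], [], [], seed, (r1, r2, r3))
    if n < 3 and min(r1, r2, r3) > 0:
        raise ValueError("need at least 3 ids when all three ratios are positive")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    n_train = int(round(r1 * n))
    n_cv = int(round(r2 * n))
    return SplitResult(
        train_ids=shuffled[:n_train],
        cv_ids=shuffled[n_train : n_train + n_cv],
        test_ids=shuffled[n_train + n_cv :],
        seed=seed,
        ratios=(r1, r2, r3),
    )


@dataclass
class TrainingExample:
    """One (DRR, pre-flash body-clipped label) pair for one beam."""

    drr: DRRImage
    label: ApertureMask
    case_id: str
    beam_side: str
    body_projection: Polygon

    def __post_init__(self) -> None:
        if self.drr.pixels.shape != self.label.pixels.shape:
            raise ValueError("DRR and label must share a grid shape")


def featurize(drr: DRRImage, body_projection: Polygon) -> np.ndarray:
    """Per-pixel feature matrix (H*W, n_features)."""
    p = drr.pixels.astype(float)
    rng_ = p.max() - p.min()
    p = (p - p.min()) / (rng_ if rng_ > 0 else 1.0)
    g1 = ndimage.gaussian_filter(p, 1.0)
    g2 = ndimage.gaussian_filter(p, 2.0)
    g4 = ndimage.gaussian_filter(p, 4.0)
    g8 = ndimage.gaussian_filter(p, 8.0)
    g16 = ndimage.gaussian_filter(p, 16.0)
    gy, gx = np.gradient(g1)
    grad = np.hypot(gx, gy)
    band = p - g8
    uu, vv = drr.grid.meshgrid()
    body = polygon_to_mask(body_projection, drr.grid).pixels
    s = drr.grid.pixel_spacing_mm
    d_in = ndimage.distance_transform_edt(body, sampling=(s, s))
    d_out = ndimage.distance_transform_edt(~body, sampling=(s, s))
    sdist = (d_in - d_out) / 50.0
    chans = [p, g1, g2, g4, g8, g16, grad, band, uu / 100.0, vv / 100.0,
             body.astype(float), sdist]
    return np.stack([c.ravel() for c in chans], axis=1)


def _init_params(n_in: int, hidden, rng) -> list[np.ndarray]:
    sizes = [n_in, *hidden, 1]
    params = []
    for a, b in zip(sizes, sizes[1:]):
        params.append(rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b)) * 0.5)
        params.append(np.zeros(b))
    return params


def _forward(params, X):
    acts = [X]
    h = X
    n_layers = len(params) // 2
    for i in range(n_layers):
        W, b = params[2 * i], params[2 * i + 1]
        z = h @ W + b
        h = z if i == n_layers - 1 else np.tanh(z)
        acts.append(h)
    q = 1.0 / (1.0 + np.exp(-np.clip(h[:, 0], -30, 30)))
    return q, acts


def _backward(params, acts, dlogit):
    grads = [None] * len(params)
    n_layers = len(params) // 2
    delta = dlogit[:, None]
    for i in range(n_layers - 1, -1, -1):
        h_prev = acts[i]
        grads[2 * i] = h_prev.T @ delta
        grads[2 * i + 1] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params[2 * i].T) * (1.0 - acts[i] ** 2)
    return grads


def _loss_and_dlogit(q, y, pos_weight, dice_weight):
    eps = 1e-7
    w = np.where(y > 0.5, pos_weight, 1.0)
    wsum = w.sum()
    bce = -(w * (y * np.log(q + eps) + (1 - y) * np.log(1 - q + eps))).sum() / wsum
    dlogit = w * (q - y) / wsum
    S = 2.0 * (q * y).sum() + 1.0
    D = q.sum() + y.sum() + 1.0
    dice_loss = 1.0 - S / D
    ddice_dq = -(2.0 * y * D - S) / D**2
    dlogit = dlogit + dice_weight * ddice_dq * q * (1.0 - q)
    return bce + dice_weight * dice_loss, dlogit


def hard_dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    denom = pred.sum() + ref.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (pred & ref).sum() / denom


@dataclass
class ModelState:
    """Serialized model: architecture tag, weights, config and log."""

    architecture: str
    params: list[np.ndarray]
    config: dict
    seed: int
    log: list[dict] = field(default_factory=list)
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict_proba(self, drr: DRRImage, body_projection: Polygon) -> np.ndarray:
        X = featurize(drr, body_projection)
        q, _ = _forward(self.params, X)
        return q.reshape(drr.pixels.shape)

    def save(self, path) -> None:
        meta = {
            "architecture": self.architecture,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.items()},
            "seed": self.seed,
            "log": self.log,
            "feature_names": list(self.feature_names),
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            params = [f[f"p{i}"] for i in range(len(f.files) - 1)]
        cfg = meta["config"]
        if "hidden" in cfg:
            cfg["hidden"] = tuple(cfg["hidden"])
        return cls(
            architecture=meta["architecture"],
            params=params,
            config=cfg,
            seed=meta["seed"],
            log=meta["log"],
            feature_names=tuple(meta["feature_names"]),
        )


def train_model(
    train: list[TrainingExample],
    cv: list[TrainingExample],
    config: dict | None = None,
    seed: int = 0,
) -> ModelState:
    """Train the pixel classifier; returns the best-by-cv-Dice checkpoint.

    Full-image batches with Adam; the per-epoch log records mean training
    loss and cross-validation Dice.  With an empty cv set the final-epoch
    weights are returned.  Deterministic for a fixed (seed, data, config).
    """
    if not train:
        raise ValueError("training set must be non-empty")
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    rng = np.random.default_rng(seed)
    Xs = [featurize(ex.drr, ex.body_projection) for ex in train]
    ys = [ex.label.pixels.ravel().astype(float) for ex in train]
    Xcv = [featurize(ex.drr, ex.body_projection) for ex in cv]
    ycv = [ex.label.pixels for ex in cv]

    params = _init_params(Xs[0].shape[1], cfg["hidden"], rng)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    lr, b1, b2, eps = cfg["learning_rate"], 0.9, 0.999, 1e-8
    t = 0
    log: list[dict] = []
    best = (copy.deepcopy(params), -np.inf)

    def cv_dice(p) -> float:
        if not Xcv:
            return np.nan
        scores = []
        for X, y in zip(Xcv, ycv):
            q, _ = _forward(p, X)
            scores.append(hard_dice(q.reshape(y.shape) >= cfg["threshold"], y))
        return float(np.mean(scores))

    for epoch in range(int(cfg["epochs"])):
        order = rng.permutation(len(Xs))
        losses = []
        for i in order:
            q, acts = _forward(params, Xs[i])
            loss, dlogit = _loss_and_dlogit(
                q, ys[i], cfg["pos_weight"], cfg["dice_weight"]
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            grads = _backward(params, acts, dlogit)
            t += 1
            for j, g in enumerate(grads):
                m[j] = b1 * m[j] + (1 - b1) * g
                v[j] = b2 * v[j] + (1 - b2) * g**2
                mh = m[j] / (1 - b1**t)
                vh = v[j] / (1 - b2**t)
                params[j] = params[j] - lr * mh / (np.sqrt(vh) + eps)
        d = cv_dice(params)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "cv_dice": d}
        )
        if Xcv and d > best[1]:
            best = (copy.deepcopy(params), d)
    final_params = best[0] if (Xcv and np.isfinite(best[1])) else params
    return ModelState(
        architecture="multiscale-context-mlp",
        params=final_params,
        config=cfg,
        seed=seed,
        log=log,
    )


def predict_aperture(
    model: ModelState, drr: DRRImage, body_projection: Polygon
) -> ApertureMask:
    """Probability map -> threshold -> largest component -> fill -> clip."""
    prob = model.predict_proba(drr, body_projection)
    binary = prob >= model.config.get("threshold", 0.5)
    if not binary.any():
        raise ValueError("no aperture predicted")
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    binary = ndimage.binary_fill_holes(binary)
    out = clip_to_body(ApertureMask(binary, drr.grid), body_projection)
    if out.is_empty():
        raise ValueError("no aperture predicted")
    return out


def examples_from_cases(cases, sides=("left-lateral", "right-lateral")):
    """Build training examples (lateral DRRs + clipped reference labels).

    Labels are the case's clinical-extent reference apertures clipped to
    the projected body (pre-flash), one example per beam side; the label
    hygiene invariant (label == clip_to_body(label)) is asserted here.
    """
    from .projection import compute_drr, project_contour_bev

    out = []
    for case in cases:
        for side in sides:
            beam = case.beam(side)
            body_poly = project_contour_bev(case.structures["body"], beam)
            drr = compute_drr(case.ct, beam, case.bev_grid)
            ref = case.reference_apertures[(side, case.clinical_extent)]
            label = clip_to_body(ref.mask, body_poly)
            out.append(
                TrainingExample(
                    drr=drr,
                    label=label,
                    case_id=case.case_id,
                    beam_side=side,
                    body_projection=body_poly,
                )
            )
    return out
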