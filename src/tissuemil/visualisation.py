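"""Attention overlays confined to tissue outlines and occlusion saliency.

Instance-level attention is rendered strictly inside the anatomical
boundaries of the tissues (outline pixels coloured on a diverging blue-to-
red scale, monotone in attention), in contrast to rectangular tile-grid
heatmaps whose cells carry no anatomical meaning.  For within-instance
saliency, a small per-instance "student" network is distilled from a trained
bag model: it predicts the slide label from a single crop, trained with an
attention-scaled squared-error loss (instances with low attention contribute
little).  Sliding a grey occlusion window over a crop and recording the drop
in the student's score yields a per-pixel saliency map confined to the
instance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from matplotlib import colormaps
from scipy import ndimage as ndi
from skimage import transform

from .containers import TissueInstance


@dataclass
class OverlayFigure:
    """A rendered overlay plus the colour-scale metadata to reproduce it."""

    image: np.ndarray  # (H, W, 3) uint8
    values: np.ndarray  # the per-instance (or per-tile) scores that were mapped
    cmap_name: str
    vmin: float
    vmax: float
    coloured_mask: np.ndarray | None = None  # pixels the overlay touched
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.image)


def _colour_for(values: np.ndarray, cmap_name: str) -> tuple[np.ndarray, float, float]:
    vmin, vmax = float(np.min(values)), float(np.max(values))
    cmap = colormaps[cmap_name]
    if vmax == vmin:  # uniform attention: mid-scale colour
        unit = np.full(len(values), 0.5)
    else:
        unit = (values - vmin) / (vmax - vmin)
    rgba = cmap(unit)
    return (rgba[:, :3] * 255).astype(np.uint8), vmin, vmax


def attention_overlay(
    image: np.ndarray,
    instances: Sequence[TissueInstance],
    attention: Sequence[float],
    cmap: str = "coolwarm",
    outline_px: int = 2,
    fill: bool = False,
    fill_alpha: float = 0.35,
) -> OverlayFigure:
    """Colour instance outlines (optionally interiors) by attention.

    Colouring is strictly confined to the instance masks: outlines are the
    mask minus its erosion, so no painted pixel leaves the instance
    geometry.  The colour scale is monotone in attention (diverging blue =
    low to red = high).
    """
    attention = np.asarray(attention, dtype=float)
    if len(instances) != attention.size:
        raise ValueError("attention must align with instances")
    if attention.size and not np.isclose(attention.sum(), 1.0, atol=1e-6):
        raise ValueError("attention weights must sum to 1")
    h, w = image.shape[:2]
    for inst in instances:
        if inst.mask.shape != (h, w):
            raise ValueError(f"instance {inst.instance_id} mask is not in image frame")
    colours, vmin, vmax = _colour_for(attention, cmap)
    out = image.copy()
    touched = np.zeros((h, w), dtype=bool)
    for inst, col in zip(instances, colours):
        outline = inst.mask & ~ndi.binary_erosion(inst.mask, iterations=outline_px)
        if fill:
            interior = inst.mask & ~outline
            out[interior] = (
                (1 - fill_alpha) * out[interior] + fill_alpha * col
            ).astype(np.uint8)
            touched |= inst.mask
        out[outline] = col
        touched |= outline
    return OverlayFigure(
        image=out,
        values=attention,
        cmap_name=cmap,
        vmin=vmin,
        vmax=vmax,
        coloured_mask=touched,
    )


def tile_overlay(
    image: np.ndarray,
    tile_size: int,
    tile_scores: np.ndarray,
    cmap: str = "coolwarm",
    alpha: float = 0.4,
) -> OverlayFigure:
    """Rectangular tile-grid heatmap (the comparison baseline).

    The grid has ``ceil(H / t) x ceil(W / t)`` cells (the last row/column is
    clipped at the image border); no interpolation between tiles.
    """
    h, w = image.shape[:2]
    nrow = -(-h // tile_size)
    ncol = -(-w // tile_size)
    tile_scores = np.asarray(tile_scores, dtype=float)
    if tile_scores.shape != (nrow, ncol):
        raise ValueError(f"tile_scores must be {nrow}x{ncol} for this image")
    colours, vmin, vmax = _colour_for(tile_scores.ravel(), cmap)
    colours = colours.reshape(nrow, ncol, 3)
    out = image.astype(float).copy()
    for r in range(nrow):
        for c in range(ncol):
            sl = (slice(r * tile_size, min((r + 1) * tile_size, h)),
                  slice(c * tile_size, min((c + 1) * tile_size, w)))
            out[sl] = (1 - alpha) * out[sl] + alpha * colours[r, c]
    return OverlayFigure(
        image=np.clip(out, 0, 255).astype(np.uint8),
        values=tile_scores,
        cmap_name=cmap,
        vmin=vmin,
        vmax=vmax,
        meta={"tile_size": tile_size, "grid": (nrow, ncol)},
    )


class StudentModel:
    """Small per-instance image regressor distilled from an attention model.

    Crops are resized to a fixed input resolution, flattened, and passed
    through one hidden tanh layer to a scalar slide-label score.  Trained
    with the attention-scaled L2 loss ``sum_k a_k (f(x_k) - y_k)^2``; the
    architecture is deliberately minimal — correctness is defined by the
    loss contract, not the network depth.
    """

    def __init__(self, input_px: int = 16, hidden: int = 32, seed: int = 0):
        self.input_px = input_px
        self.hidden = hidden
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None
        self.history: list[float] = []

    def _vec(self, crop: np.ndarray) -> np.ndarray:
        img = np.asarray(crop, dtype=float)
        if img.max() > 1.5:
            img = img / 255.0
        small = transform.resize(
            img, (self.input_px, self.input_px), anti_aliasing=True, mode="reflect"
        )
        return small.ravel()

    def fit(
        self,
        crops: Sequence[np.ndarray],
        attentions: Sequence[float],
        labels: Sequence[float],
        epochs: int = 400,
        lr: float = 0.01,
        val_fraction: float = 0.25,
        patience: int = 60,
    ) -> "StudentModel":
        a = np.asarray(attentions, dtype=float)
        y = np.asarray(labels, dtype=float)
        if np.all(a == 0):
            raise ValueError("all-zero attentions: nothing to learn from")
        X = np.vstack([self._vec(c) for c in crops])
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 3 else 0
        va, tr = perm[:n_val], perm[n_val:]
        if tr.size == 0:
            tr, va = perm, np.array([], dtype=int)
        params = {
            "W1": rng.normal(0, 1.0 / np.sqrt(d), (d, self.hidden)),
            "b1": np.zeros(self.hidden),
            "w2": rng.normal(0, 1.0 / np.sqrt(self.hidden), self.hidden),
            "b2": np.zeros(1),
        }
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        best = None
        best_val = np.inf
        stale = 0
        aw = a / a.sum()
        for epoch in range(epochs):
            H = np.tanh(X[tr] @ params["W1"] + params["b1"])
            f = H @ params["w2"] + params["b2"][0]
            err = f - y[tr]
            wts = aw[tr]
            grads = {
                "w2": H.T @ (2 * wts * err),
                "b2": np.array([float(np.sum(2 * wts * err))]),
            }
            dH = np.outer(2 * wts * err, params["w2"]) * (1 - H * H)
            grads["W1"] = X[tr].T @ dH
            grads["b1"] = dH.sum(axis=0)
            # Adam update
            t = epoch + 1
            for k in params:
                m[k] = 0.9 * m[k] + 0.1 * grads[k]
                v[k] = 0.999 * v[k] + 0.001 * grads[k] ** 2
                mhat = m[k] / (1 - 0.9**t)
                vhat = v[k] / (1 - 0.999**t)
                params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + 1e-8)
            if va.size:
                Hv = np.tanh(X[va] @ params["W1"] + params["b1"])
                val = float(np.sum(aw[va] * (Hv @ params["w2"] + params["b2"][0] - y[va]) ** 2))
            else:
                val = float(np.sum(wts * err**2))
            self.history.append(val)
            if val < best_val - 1e-9:
                best_val = val
                best = {k: p.copy() for k, p in params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        self.params = best if best is not None else params
        return self

    def score(self, crop: np.ndarray) -> float:
        if self.params is None:
            raise RuntimeError("student is not trained")
        x = self._vec(crop)
        h = np.tanh(x @ self.params["W1"] + self.params["b1"])
        return float(h @ self.params["w2"] + self.params["b2"][0])

    __call__ = score


def train_student(
    crops: Sequence[np.ndarray],
    attentions: Sequence[float],
    labels: Sequence[float],
    seed: int = 0,
    **kwargs,
) -> StudentModel:
    """Distil a per-instance student from bag-level attention and labels."""
    return StudentModel(seed=seed).fit(crops, attentions, labels, **kwargs)


def occlusion_saliency(
    scorer: Callable[[np.ndarray], float],
    crop: np.ndarray,
    window: int = 16,
    stride: int = 8,
    mask: np.ndarray | None = None,
    fill: np.ndarray | float | None = None,
) -> np.ndarray:
    """Occlusion saliency: mean score drop over windows covering each pixel.

    A ``window x window`` patch filled with ``fill`` (default: the crop's
    mean colour) slides with ``stride``; saliency at a pixel is the average
    drop of ``scorer`` over all windows covering it.  If ``mask`` is given
    the map is zeroed outside it.
    """
    h, w = crop.shape[:2]
    if window > min(h, w):
        raise ValueError("window must fit inside the crop")
    if fill is None:
        fill = crop.reshape(-1, crop.shape[2]).mean(axis=0) if crop.ndim == 3 else float(
            crop.mean()
        )
    base = scorer(crop)
    drops = np.zeros((h, w), dtype=float)
    counts = np.zeros((h, w), dtype=float)
    tops = list(range(0, h - window + 1, stride))
    lefts = list(range(0, w - window + 1, stride))
    if tops[-1] != h - window:
        tops.append(h - window)
    if lefts[-1] != w - window:
        lefts.append(w - window)
    for top in tops:
        for left in lefts:
            occ = crop.copy()
            occ[top : top + window, left : left + window] = fill
            drop = base - scorer(occ)
            drops[top : top + window, left : left + window] += drop
            counts[top : top + window, left : left + window] += 1.0
    sal = np.divide(drops, counts, out=np.zeros_like(drops), where=counts > 0)
    if mask is not None:
        sal = np.where(mask, sal, 0.0)
    return sal
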