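"""Ensemble fusion, min-cut instance extraction, quality weights and crops.

The segmentation ensemble (any source: this package never trains one) hands
over a stack of per-model, per-class probability maps.  Fusion computes the
across-model mean ``p_mean`` and standard deviation ``p_sigma`` and corrects
overconfident pixels with

    p_tilde = max(p_mean - A * p_sigma, 0)

so pixels on which the models disagree are suppressed — this removes
false-positive segments that only a subset of models produce.  Instances are
then obtained by a two-label min-cut (unary costs are negative log-odds of
``p_tilde``, pairwise a Potts smoothness term on the 4-neighbour grid),
followed by 8-connected components.  Per-instance quality weights are the
slide-wise min-max normalisation of the squared mean ensemble SD over each
mask:

    g_k = (max_j s_j^2 - s_k^2) / (max_j s_j^2 - min_j s_j^2)

with g = 1 everywhere when all s_j^2 coincide (equal evidence quality should
not down-weight anyone).  Finally each instance is cropped with a physical
padding and the area outside its mask blurred, so extra-tissue context cannot
contribute sharp structure to downstream features.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow
from skimage import measure

from .containers import FusedMap, ProbabilityStack, TissueInstance

_EPS = 1e-6


def fuse_ensemble(stack: ProbabilityStack, A: float, ddof: int = 0) -> FusedMap:
    """Fuse a probability stack into ``(p_mean, p_sigma, p_tilde)``.

    ``ddof=0`` (population SD across models) is the default: the ensemble is
    the full model set, not a sample of a larger population.

    Parameters
    ----------
    stack
        Co-registered per-model, per-class probability maps (>= 2 models).
    A
        Nonnegative uncertainty penalty; ``A=0`` leaves ``p_tilde == p_mean``.
    """
    if A < 0:
        raise ValueError("A must be >= 0")
    if stack.n_models < 2:
        raise ValueError("ensemble SD is undefined for a single model")
    p_mean = stack.maps.mean(axis=0)
    p_sigma = stack.maps.std(axis=0, ddof=ddof)
    p_tilde = np.maximum(p_mean - A * p_sigma, 0.0)
    return FusedMap(
        p_mean=p_mean,
        p_sigma=p_sigma,
        p_tilde=p_tilde,
        A=float(A),
        class_names=stack.class_names,
        mpp=stack.mpp,
    )


def _mincut_binarise(p: np.ndarray, smoothness: float, scale: int = 4096) -> np.ndarray:
    """Two-label min-cut segmentation of a probability map.

    Unary costs are ``-log p`` (foreground) vs ``-log(1 - p)`` (background)
    with probabilities clamped to ``[eps, 1-eps]``; the pairwise term is a
    Potts penalty of weight ``smoothness`` on the 4-neighbour grid.  Costs
    are scaled to integers for the max-flow solver.  At ``smoothness == 0``
    the result equals thresholding ``p`` at 0.5.
    """
    h, w = p.shape
    n = h * w
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    cost_bg = -np.log1p(-pc)  # paid when the pixel is background
    cost_fg = -np.log(pc)  # paid when the pixel is foreground

    # nodes: 0 = source (foreground side), 1..n pixels, n+1 = sink
    src, snk = 0, n + 1
    cap_s = np.rint(cost_bg.ravel() * scale).astype(np.int64) * 2
    cap_t = np.rint(cost_fg.ravel() * scale).astype(np.int64) * 2
    # rounding may misorder near-tie unaries; repair with a sub-quantum nudge
    # so that p > 0.5 always implies cap_s > cap_t and vice versa
    fg_true = pc.ravel() > 0.5
    need_gt = fg_true & (cap_s <= cap_t)
    cap_s[need_gt] = cap_t[need_gt] + 1
    need_le = ~fg_true & (cap_s > cap_t)
    cap_s[need_le] = cap_t[need_le]
    rows = [np.full(n, src), np.arange(1, n + 1)]
    cols = [np.arange(1, n + 1), np.full(n, snk)]
    caps = [cap_s, cap_t]
    if smoothness > 0:
        wpair = int(round(smoothness * scale)) * 2
        idx = np.arange(n).reshape(h, w)
        for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
            a = a.ravel() + 1
            b = b.ravel() + 1
            rows += [a, b]
            cols += [b, a]
            caps += [np.full(a.size, wpair, dtype=np.int64)] * 2
    graph = csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
        dtype=np.int64,
    )
    res = maximum_flow(graph, src, snk)
    residual = graph - res.flow
    # pixels reachable from the source in the residual graph are foreground
    reach = _reachable_from(residual, src, n + 2)
    return reach[1 : n + 1].reshape(h, w)


def _reachable_from(residual: csr_matrix, src: int, n_nodes: int) -> np.ndarray:
    from scipy.sparse.csgraph import breadth_first_order

    pos = residual.tocsr().copy()
    pos.data = (pos.data > 0).astype(np.int8)
    pos.eliminate_zeros()
    order = breadth_first_order(pos, src, directed=True, return_predecessors=False)
    seen = np.zeros(n_nodes, dtype=bool)
    seen[order] = True
    return seen


def extract_instances(
    fused: FusedMap,
    class_label: str,
    min_area_px: int = 32,
    smoothness: float = 0.0,
) -> list[TissueInstance]:
    """Extract tissue instances of one class from the corrected map.

    Foreground is the min-cut binarisation of ``p_tilde`` for the class;
    8-connected components below ``min_area_px`` are discarded.  An empty
    foreground yields an empty list.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    ci = fused.class_index(class_label)
    p = fused.p_tilde[ci]
    if not (p > 0.5 - _EPS).any():
        return []
    fg = _mincut_binarise(p, smoothness)
    labelled = measure.label(fg, connectivity=2)
    out: list[TissueInstance] = []
    for region in measure.regionprops(labelled):
        if region.area < min_area_px:
            continue
        mask = labelled == region.label
        out.append(
            TissueInstance(instance_id=len(out), class_label=class_label, mask=mask)
        )
    return out


def compute_quality_weights(
    instances: list[TissueInstance], p_sigma: np.ndarray
) -> list[TissueInstance]:
    """Fill ``s2`` and ``g`` for all instances of one slide (in place).

    ``s_k`` is the mean of ``p_sigma`` over mask ``k``; ``g`` is the slide-wise
    min-max normalisation of ``s_k**2`` (1 at the minimum, 0 at the maximum,
    all 1 when every ``s_j**2`` coincides).
    """
    if not instances:
        raise ValueError("need >= 1 instance")
    s2 = np.empty(len(instances))
    for j, inst in enumerate(instances):
        if not inst.mask.any():
            raise ValueError(f"instance {inst.instance_id} has an empty mask")
        sj = float(p_sigma[inst.mask].mean())
        s2[j] = sj * sj
    g = quality_weights_from_s2(s2)
    for inst, s2_j, g_j in zip(instances, s2, g):
        inst.s2 = float(s2_j)
        inst.g = float(g_j)
    return instances


def quality_weights_from_s2(s2) -> np.ndarray:
    """Min-max quality weights from squared mean-SD values (one slide)."""
    s2 = np.asarray(s2, dtype=float)
    if s2.size == 0:
        raise ValueError("need >= 1 value")
    if np.any(s2 < 0):
        raise ValueError("s2 must be nonnegative")
    hi, lo = s2.max(), s2.min()
    if hi == lo:
        return np.ones_like(s2)
    return (hi - s2) / (hi - lo)


def crop_instance(
    image: np.ndarray,
    instance: TissueInstance,
    pad_um: float = 1.32,
    mpp: float = 0.44,
    blur_sigma_px: float = 8.0,
) -> np.ndarray:
    """Cut a padded crop of the instance with the exterior blurred.

    The crop bounds are the mask bounding box expanded by
    ``round(pad_um / mpp)`` pixels per side, clipped to the image (clipping
    sets ``instance.truncated``).  Pixels outside the mask are replaced by a
    Gaussian-blurred copy of the image — the blur is computed before masking
    so tissue colour does not bleed back as sharp structure — while pixels
    inside the mask are untouched.  Sets ``instance.crop`` and
    ``instance.bbox`` and returns the crop.
    """
    if pad_um < 0:
        raise ValueError("pad_um must be >= 0")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    h, w = image.shape[:2]
    r0, c0, r1, c1 = instance.mask_bbox()
    pad = int(round(pad_um / mpp))
    R0, C0 = r0 - pad, c0 - pad
    R1, C1 = r1 + pad, c1 + pad
    truncated = R0 < 0 or C0 < 0 or R1 > h or C1 > w
    R0, C0 = max(R0, 0), max(C0, 0)
    R1, C1 = min(R1, h), min(C1, w)

    margin = int(np.ceil(3 * blur_sigma_px))
    E0, F0 = max(R0 - margin, 0), max(C0 - margin, 0)
    E1, F1 = min(R1 + margin, h), min(C1 + margin, w)
    region = image[E0:E1, F0:F1].astype(float)
    blurred = np.empty_like(region)
    for ch in range(region.shape[2]):
        blurred[..., ch] = ndi.gaussian_filter(region[..., ch], blur_sigma_px, mode="nearest")
    sub = slice(R0 - E0, R1 - E0), slice(C0 - F0, C1 - F0)
    crop = blurred[sub].copy()
    mask_crop = instance.mask[R0:R1, C0:C1]
    crop[mask_crop] = image[R0:R1, C0:C1].astype(float)[mask_crop]
    crop = np.clip(np.rint(crop), 0, 255).astype(image.dtype)

    instance.crop = crop
    instance.bbox = (R0, C0, R1, C1)
    instance.truncated = bool(truncated)
    return crop


def sweep_penalty(
    stack: ProbabilityStack,
    gt_masks: dict[str, list[np.ndarray]],
    candidates,
    min_area_px: int = 32,
    smoothness: float = 0.0,
) -> tuple[float, dict[float, float]]:
    """Select the penalty A maximising mean instance-level Jaccard.

    Stands in for determining A empirically from training data: for each
    candidate, instances are extracted per class and greedily matched to the
    ground-truth masks; the A with the highest mean Jaccard wins.
    """
    scores: dict[float, float] = {}
    for A in candidates:
        fused = fuse_ensemble(stack, A)
        jac = []
        for cname, masks in gt_masks.items():
            found = extract_instances(fused, cname, min_area_px, smoothness)
            for gt in masks:
                best = 0.0
                for inst in found:
                    inter = float(np.logical_and(gt, inst.mask).sum())
                    union = float(np.logical_or(gt, inst.mask).sum())
                    if union > 0:
                        best = max(best, inter / union)
                jac.append(best)
            # unmatched extra instances count as zeros
            for inst in found:
                if all(not np.logical_and(gt, inst.mask).any() for gt in masks):
                    jac.append(0.0)
        scores[float(A)] = float(np.mean(jac)) if jac else 0.0
    best_A = max(scores, key=lambda a: (scores[a], -a))
    return best_A, scores


def instances_to_records(instances: list[TissueInstance]) -> list[dict]:
    """GeoJSON-style per-instance records (outline coordinates, class, g, s2)."""
    records = []
    for inst in instances:
        contours = measure.find_contours(inst.mask.astype(float), 0.5)
        records.append(
            {
                "instance_id": inst.instance_id,
                "class_label": inst.class_label,
                "g": inst.g,
                "s2": inst.s2,
                "bbox": list(inst.bbox) if inst.bbox is not None else None,
                "truncated": inst.truncated,
                "polygons": [c[:: max(1, len(c) // 128)].tolist() for c in contours],
            }
        )
    return records
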