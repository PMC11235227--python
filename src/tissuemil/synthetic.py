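"""Synthetic biopsy-like slides, ensemble probability stacks and MIL bag sets.

Real renal biopsy slides live in an access-restricted biobank, so the whole
workflow is exercised on synthetic material with analytic ground truth:

* :func:`make_slide` draws biopsy-like compartments on an RGB canvas —
  tubule-like annular ellipses with a lumen, glomerulus-like capsule rings
  enclosing a tuft of packed blobs with an empty "urinary space" gap,
  vessel-like thick rings with a configurable lumen fraction, and small dark
  nucleus disks scattered inside compartments.  Every instance records the
  generative shape parameters, so areas and eccentricities can be recomputed
  analytically and used as oracles for the feature extractor.
* :func:`make_probability_stack` simulates a segmentation ensemble: each
  model sees the Gaussian-smoothed ground-truth indicator perturbed by
  model-specific noise whose per-instance amplitude follows a requested
  disagreement level, optionally with false-positive blobs present in only a
  subset of models (the failure mode the uncertainty-penalised fusion is
  designed to suppress).
* :func:`make_bags` builds multi-instance bag datasets with known
  positive-instance structure, controllable corrupted-instance contamination
  (corrupted instances mimic the signal signature — misleading the bag label
  wherever that conflicts with it — and carry a high ensemble-disagreement
  proxy ``sigma2``), and an ordinal three-class mode keyed to the
  signal-instance count (<7, 7-9, >=10) that mirrors the glomerular-adequacy
  counting task used for hyperparameter tuning.

Every generator is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .containers import Bag, BagSet, ProbabilityStack

CLASS_NAMES = ("tubule", "glomerulus", "vessel", "nucleus")

# Palette loosely evoking a PAS stain: pink tissue on a pale background.
_BACKGROUND = np.array([234, 228, 232], dtype=float)
_COLOURS = {
    "tubule_ring": np.array([205, 145, 165], dtype=float),
    "tubule_lumen": np.array([242, 236, 240], dtype=float),
    "glom_tuft": np.array([175, 110, 140], dtype=float),
    "glom_capsule": np.array([205, 155, 170], dtype=float),
    "vessel_wall": np.array([185, 120, 150], dtype=float),
    "vessel_lumen": np.array([246, 242, 245], dtype=float),
    "nucleus": np.array([72, 52, 110], dtype=float),
}


@dataclass(frozen=True)
class SlideConfig:
    """Generation parameters for one synthetic slide.

    Radii are pixel ranges ``(lo, hi)`` sampled uniformly.  ``vessel_lumen_frac``
    is the lumen-to-total *area* fraction, i.e. ``(r_lumen / r_outer)**2``.
    """

    height: int = 512
    width: int = 512
    mpp: float = 0.44
    n_tubules: int = 3
    n_glomeruli: int = 2
    n_vessels: int = 2
    nuclei_per_compartment: tuple[int, int] = (3, 7)
    tubule_radius: tuple[float, float] = (22.0, 32.0)
    tubule_lumen_frac: float = 0.45  # linear fraction of the semi-axes
    tubule_aspect: tuple[float, float] = (0.6, 0.95)
    glom_radius: tuple[float, float] = (30.0, 42.0)
    glom_gap_px: float = 4.0  # urinary-space width
    glom_capsule_px: float = 3.0
    vessel_radius: tuple[float, float] = (24.0, 40.0)
    vessel_lumen_frac: float = 0.25
    nucleus_radius: tuple[float, float] = (2.0, 3.5)
    background_noise: float = 2.0
    margin: int = 6
    max_place_tries: int = 300

    def validate(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.height < 256 or self.width < 256:
            raise ValueError("image dimensions must be >= 256x256")
        for name in ("n_tubules", "n_glomeruli", "n_vessels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        max_r = max(self.tubule_radius[1], self.glom_radius[1], self.vessel_radius[1])
        if 2 * (max_r + self.margin) > min(self.height, self.width):
            raise ValueError("configured shapes cannot fit the canvas")
        if not 0 < self.vessel_lumen_frac < 1:
            raise ValueError("vessel_lumen_frac must be in (0, 1)")


@dataclass
class SlideInstance:
    """A single ground-truth compartment with its generative parameters."""

    mask: np.ndarray
    class_label: str
    shape_params: dict[str, Any]


@dataclass
class SyntheticSlide:
    image: np.ndarray  # (H, W, 3) uint8
    mpp: float
    instances: list[SlideInstance]
    seed: int
    config: SlideConfig

    def masks_for(self, class_label: str) -> list[np.ndarray]:
        return [i.mask for i in self.instances if i.class_label == class_label]

    def class_map(self, class_label: str) -> np.ndarray:
        out = np.zeros(self.image.shape[:2], dtype=bool)
        for m in self.masks_for(class_label):
            out |= m
        return out


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.disk((cy, cx), r, shape=shape)
    m[rr, cc] = True
    return m


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, rot: float
) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(cy, cx, a, b, shape=shape, rotation=rot)
    m[rr, cc] = True
    return m


def _place(rng, occupied, shape, radius, margin, tries):
    """Rejection-sample a centre whose footprint disk is free and on-canvas."""
    h, w = shape
    for _ in range(tries):
        cy = rng.uniform(radius + margin, h - radius - margin)
        cx = rng.uniform(radius + margin, w - radius - margin)
        foot = _disk_mask(shape, cy, cx, radius + 2)
        if not (occupied & foot).any():
            return cy, cx, foot
    raise RuntimeError("could not place a shape: configuration does not fit the canvas")


def make_slide(config: SlideConfig | None = None, seed: int = 0) -> SyntheticSlide:
    """Generate a biopsy-like RGB slide with ground-truth instance masks.

    Tubule masks are the annular ring (lumen excluded, recoverable as the
    enclosed hole); glomerulus masks are capsule ring plus tuft blobs with
    the urinary-space gap left empty; vessel masks are the wall ring.  Nuclei
    are separate instances of class ``"nucleus"``.
    """
    config = config or SlideConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.height, config.width)
    img = np.ones((*shape, 3), dtype=float) * _BACKGROUND
    if config.background_noise > 0:
        img += rng.normal(0.0, config.background_noise, img.shape)
    occupied = np.zeros(shape, dtype=bool)
    instances: list[SlideInstance] = []
    interiors: list[np.ndarray] = []  # where nuclei may be scattered

    for _ in range(config.n_vessels):
        r_o = rng.uniform(*config.vessel_radius)
        r_i = float(np.sqrt(config.vessel_lumen_frac) * r_o)
        cy, cx, foot = _place(rng, occupied, shape, r_o, config.margin, config.max_place_tries)
        outer = _disk_mask(shape, cy, cx, r_o)
        lumen = _disk_mask(shape, cy, cx, r_i)
        ring = outer & ~lumen
        img[ring] = _COLOURS["vessel_wall"]
        img[lumen] = _COLOURS["vessel_lumen"]
        occupied |= foot
        instances.append(
            SlideInstance(
                mask=ring,
                class_label="vessel",
                shape_params={
                    "kind": "vessel",
                    "center": (cy, cx),
                    "r_outer": r_o,
                    "r_lumen": r_i,
                    "analytic_total_area_px": float(np.pi * r_o**2),
                    "analytic_lumen_area_px": float(np.pi * r_i**2),
                    "analytic_lumen_ratio": float((r_i / r_o) ** 2),
                    "analytic_eccentricity": 0.0,
                },
            )
        )
        interiors.append(ring)

    for _ in range(config.n_glomeruli):
        r = rng.uniform(*config.glom_radius)
        cy, cx, foot = _place(rng, occupied, shape, r, config.margin, config.max_place_tries)
        capsule = _disk_mask(shape, cy, cx, r) & ~_disk_mask(shape, cy, cx, r - config.glom_capsule_px)
        tuft_r = r - config.glom_capsule_px - config.glom_gap_px
        tuft = np.zeros(shape, dtype=bool)
        n_blobs = int(rng.integers(6, 12))
        for _b in range(n_blobs):
            br = rng.uniform(0.18 * tuft_r, 0.38 * tuft_r)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, tuft_r - br)
            tuft |= _disk_mask(shape, cy + rad * np.sin(ang), cx + rad * np.cos(ang), br)
        tuft &= _disk_mask(shape, cy, cx, tuft_r)
        mask = capsule | tuft
        img[capsule] = _COLOURS["glom_capsule"]
        img[tuft] = _COLOURS["glom_tuft"]
        occupied |= foot
        instances.append(
            SlideInstance(
                mask=mask,
                class_label="glomerulus",
                shape_params={
                    "kind": "glomerulus",
                    "center": (cy, cx),
                    "r_capsule": r,
                    "capsule_px": config.glom_capsule_px,
                    "gap_px": config.glom_gap_px,
                    "analytic_capsule_area_px": float(
                        np.pi * (r**2 - (r - config.glom_capsule_px) ** 2)
                    ),
                    "analytic_hull_area_px": float(np.pi * r**2),
                },
            )
        )
        interiors.append(tuft)

    for _ in range(config.n_tubules):
        a = rng.uniform(*config.tubule_radius)
        b = a * rng.uniform(*config.tubule_aspect)
        rot = rng.uniform(0, np.pi)
        cy, cx, foot = _place(rng, occupied, shape, a, config.margin, config.max_place_tries)
        outer = _ellipse_mask(shape, cy, cx, a, b, rot)
        f = config.tubule_lumen_frac
        lumen = _ellipse_mask(shape, cy, cx, a * f, b * f, rot)
        ring = outer & ~lumen
        img[ring] = _COLOURS["tubule_ring"]
        img[lumen] = _COLOURS["tubule_lumen"]
        occupied |= foot
        big, small = max(a, b), min(a, b)
        instances.append(
            SlideInstance(
                mask=ring,
                class_label="tubule",
                shape_params={
                    "kind": "tubule",
                    "center": (cy, cx),
                    "semi_axes": (a, b),
                    "rotation": rot,
                    "lumen_frac": f,
                    "analytic_total_area_px": float(np.pi * a * b),
                    "analytic_lumen_area_px": float(np.pi * a * b * f**2),
                    "analytic_lumen_ratio": float(f**2),
                    "analytic_eccentricity": float(np.sqrt(1 - (small / big) ** 2)),
                },
            )
        )
        interiors.append(ring)

    # nuclei scattered inside compartment tissue (not in lumina / background)
    lo, hi = config.nuclei_per_compartment
    if hi > 0:
        for host in interiors:
            n_nuc = int(rng.integers(lo, hi + 1))
            ys, xs = np.nonzero(ndi.binary_erosion(host, iterations=2))
            if ys.size == 0:
                continue
            for _n in range(n_nuc):
                j = int(rng.integers(ys.size))
                r_n = rng.uniform(*config.nucleus_radius)
                nuc = _disk_mask(shape, float(ys[j]), float(xs[j]), r_n) & host
                if not nuc.any():
                    continue
                shade = rng.uniform(0.85, 1.15)
                img[nuc] = np.clip(_COLOURS["nucleus"] * shade, 0, 255)
                instances.append(
                    SlideInstance(
                        mask=nuc,
                        class_label="nucleus",
                        shape_params={
                            "kind": "nucleus",
                            "center": (float(ys[j]), float(xs[j])),
                            "radius": r_n,
                            "analytic_area_px": float(np.pi * r_n**2),
                        },
                    )
                )

    return SyntheticSlide(
        image=np.clip(img, 0, 255).astype(np.uint8),
        mpp=config.mpp,
        instances=instances,
        seed=seed,
        config=config,
    )


def make_probability_stack(
    slide: SyntheticSlide,
    n_models: int = 4,
    disagreement: float | Sequence[float] = 0.0,
    seed: int = 0,
    n_false_positives: int = 0,
    fp_prob: float = 0.9,
    fp_models: int = 1,
    fp_radius: tuple[float, float] = (8.0, 16.0),
    smooth_sigma: float = 1.0,
) -> ProbabilityStack:
    """Simulate an ensemble of per-class probability maps for a slide.

    Each model's map is the ground-truth class indicator smoothed with a
    Gaussian (``smooth_sigma`` px, so maps are soft like network outputs) plus
    a model-specific per-instance perturbation ``a ~ N(0, disagreement_i)``
    applied along the smoothed indicator, clipped to [0, 1].  ``disagreement``
    may be a scalar or one value per (non-nucleus first, then nucleus)
    instance.  ``n_false_positives`` blobs of probability ``fp_prob`` are
    injected into ``fp_models`` of the models at background locations.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    dis = np.asarray(disagreement, dtype=float)
    if np.any(dis < 0):
        raise ValueError("disagreement must be >= 0")
    if dis.ndim == 0:
        dis = np.full(len(slide.instances), float(dis))
    elif dis.shape != (len(slide.instances),):
        raise ValueError("disagreement must be scalar or one value per instance")

    rng = np.random.default_rng(seed)
    shape = slide.image.shape[:2]
    maps = np.zeros((n_models, len(CLASS_NAMES), *shape), dtype=float)
    smoothed = []
    for inst in slide.instances:
        smoothed.append(ndi.gaussian_filter(inst.mask.astype(float), smooth_sigma))
    for ci, cname in enumerate(CLASS_NAMES):
        idx = [k for k, inst in enumerate(slide.instances) if inst.class_label == cname]
        base = np.zeros(shape)
        for k in idx:
            base += smoothed[k]
        for m in range(n_models):
            layer = base.copy()
            for k in idx:
                if dis[k] > 0:
                    layer += rng.normal(0.0, dis[k]) * smoothed[k]
            maps[m, ci] = layer

    fp_info = []
    occupied = np.zeros(shape, dtype=bool)
    for inst in slide.instances:
        occupied |= inst.mask
    for _ in range(n_false_positives):
        r = rng.uniform(*fp_radius)
        for _try in range(200):
            cy = rng.uniform(r + 2, shape[0] - r - 2)
            cx = rng.uniform(r + 2, shape[1] - r - 2)
            blob = _disk_mask(shape, cy, cx, r)
            if not (blob & occupied).any():
                break
        else:  # pragma: no cover - generous canvas in practice
            raise RuntimeError("could not place a false-positive blob")
        occupied |= blob
        ci = int(rng.integers(0, 3))  # tubule/glomerulus/vessel
        which = rng.choice(n_models, size=fp_models, replace=False)
        soft = ndi.gaussian_filter(blob.astype(float), smooth_sigma) * fp_prob
        for m in which:
            maps[m, ci] += soft
        fp_info.append(
            {
                "center": (float(cy), float(cx)),
                "radius": float(r),
                "class": CLASS_NAMES[ci],
                "models": [int(m) for m in which],
                "prob": float(fp_prob),
                "mask": blob,
            }
        )

    maps = np.clip(maps, 0.0, 1.0)
    return ProbabilityStack(
        maps=maps,
        class_names=CLASS_NAMES,
        mpp=slide.mpp,
        meta={"seed": seed, "disagreement": dis, "false_positives": fp_info},
    )


@dataclass(frozen=True)
class BagSetConfig:
    """Generative configuration for synthetic MIL bag sets.

    Background instances are standard multivariate normal; signal instances
    are shifted by ``effect_size`` along a fixed unit direction; corrupted
    instances carry the same shift — a signature that conflicts with the bag
    label wherever corruption can sway it — and are flagged with ``sigma2``
    drawn from a strictly higher-mean distribution.  Binary bags follow the
    standard MIL rule
    (positive iff >= 1 signal instance); the ordinal mode labels bags by the
    signal-instance count against ``ordinal_thresholds`` and appends a
    slide-level bag-size column to every instance (attention-averaged bag
    representations cannot encode counts on their own, so count information
    must enter through instance features — the same reason slide-level
    values such as the total biopsy area are appended per tissue in the real
    workflow).
    """

    n_bags: int = 200
    instances_per_bag: tuple[int, int] = (5, 15)
    n_features: int = 10
    effect_size: float = 3.0
    contamination: float = 0.0
    n_classes: int = 2
    n_donors: int = 40
    signal_per_positive: tuple[int, int] = (1, 3)
    ordinal_thresholds: tuple[int, int] = (7, 10)
    sigma2_clean_mean: float = 0.05
    sigma2_corrupt_mean: float = 0.5
    seed: int = 0
    ensure_separable: bool = False

    def validate(self) -> None:
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_donors < 2:
            raise ValueError("need >= 2 donors")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 (binary MIL) or 3 (ordinal count task)")
        if self.ensure_separable and self.effect_size == 0:
            raise ValueError("effect_size 0 cannot produce separable bags")


def signal_direction(n_features: int) -> np.ndarray:
    """The fixed unit direction along which signal instances are shifted."""
    v = np.ones(n_features)
    return v / np.linalg.norm(v)


def ordinal_label(n_signal: int, thresholds: tuple[int, int] = (7, 10)) -> int:
    """Class by signal-instance count: 0 (<lo), 1 ([lo, hi)), 2 (>=hi)."""
    lo, hi = thresholds
    if n_signal >= hi:
        return 2
    if n_signal >= lo:
        return 1
    return 0


def make_bags(config: BagSetConfig | None = None) -> BagSet:
    """Generate a synthetic MIL bag set with known instance roles."""
    config = config or BagSetConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    u = signal_direction(config.n_features)
    donors = [f"D{j:03d}" for j in range(config.n_donors)]
    lo_k, hi_k = config.instances_per_bag

    bags: list[Bag] = []
    for i in range(config.n_bags):
        if config.n_classes == 2:
            K = int(rng.integers(lo_k, hi_k + 1))
            label = int(rng.integers(0, 2))
            if label == 1:
                s_lo, s_hi = config.signal_per_positive
                n_signal = int(rng.integers(s_lo, min(s_hi, K) + 1))
            else:
                n_signal = 0
        else:
            # balanced ordinal count task: draw the class, then a signal
            # count within its band, then pad with background instances
            lo_t, hi_t = config.ordinal_thresholds
            label = int(rng.integers(0, 3))
            if label == 0:
                n_signal = int(rng.integers(0, lo_t))
            elif label == 1:
                n_signal = int(rng.integers(lo_t, hi_t))
            else:
                n_signal = int(rng.integers(hi_t, hi_t + 5))
            K = n_signal + int(rng.integers(3, 9))

        roles = ["signal"] * n_signal + ["background"] * (K - n_signal)
        for k in range(n_signal, K):
            if rng.random() < config.contamination:
                roles[k] = "corrupted"
        rng.shuffle(roles)

        X = rng.standard_normal((K, config.n_features))
        if config.n_classes == 3:
            # slide-level column: standardised bag size, same for every
            # instance of the bag (scaled to roughly unit variance)
            X = np.concatenate([X, np.full((K, 1), (K - 12.0) / 5.0)], axis=1)
        sigma2 = np.empty(K)
        for k, role in enumerate(roles):
            if role == "signal":
                X[k, : config.n_features] += config.effect_size * u
                sigma2[k] = rng.gamma(4.0, config.sigma2_clean_mean / 4.0)
            elif role == "corrupted":
                # corrupted instances mimic the signal signature, so their
                # features conflict with the bag's label wherever corruption
                # can sway it: negative bags in the binary task, the apparent
                # signal count in the ordinal task (cf. duplicated tissue
                # sections inflating glomerulus counts)
                X[k, : config.n_features] += config.effect_size * u
                sigma2[k] = rng.gamma(4.0, config.sigma2_corrupt_mean / 4.0)
            else:
                sigma2[k] = rng.gamma(4.0, config.sigma2_clean_mean / 4.0)

        bags.append(
            Bag(
                bag_id=f"B{i:04d}",
                donor_id=donors[i % config.n_donors],
                label=label,
                features=X,
                sigma2=sigma2,
                roles=tuple(roles),
            )
        )
    return BagSet(bags=bags, config=config)


def slide_manifest(slide: SyntheticSlide) -> dict[str, Any]:
    """JSON-serialisable sidecar: mpp, seed, per-instance outline polygons."""
    from skimage import measure

    records = []
    for k, inst in enumerate(slide.instances):
        contours = measure.find_contours(inst.mask.astype(float), 0.5)
        polys = [c[:: max(1, len(c) // 64)].tolist() for c in contours]
        params = {
            key: (list(v) if isinstance(v, tuple) else v)
            for key, v in inst.shape_params.items()
        }
        records.append(
            {
                "instance_id": k,
                "class_label": inst.class_label,
                "polygons": polys,
                "shape_params": params,
            }
        )
    return {
        "mpp": slide.mpp,
        "seed": slide.seed,
        "config": dataclasses.asdict(slide.config),
        "instances": records,
    }
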