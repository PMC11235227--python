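"""Shared in-memory containers for the analysis workflow.

These are deliberately thin dataclasses: the heavy lifting lives in the
functional modules (:mod:`tissuemil.fusion`, :mod:`tissuemil.features`,
:mod:`tissuemil.mil`).  Masks are stored in the slide pixel frame as boolean
arrays; bounding boxes are 0-based, half-open ``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd


@dataclass
class ProbabilityStack:
    """Per-model, per-class probability maps for one slide region.

    Parameters
    ----------
    maps
        Array indexed ``(model, class, y, x)`` with values in [0, 1].
    class_names
        Ordered class names matching the class axis.
    mpp
        Microns per pixel of the maps.
    meta
        Optional provenance (e.g. injected false-positive blobs of the
        synthetic generator).
    """

    maps: np.ndarray
    class_names: tuple[str, ...]
    mpp: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.class_names = tuple(self.class_names)
        if self.maps.ndim != 4:
            raise ValueError("maps must be indexed (model, class, y, x)")
        if self.maps.shape[0] < 2:
            raise ValueError("a probability stack needs >= 2 models")
        if self.maps.shape[1] != len(self.class_names):
            raise ValueError("class_names length must match the class axis")
        if self.maps.min() < 0 or self.maps.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def n_models(self) -> int:
        return self.maps.shape[0]

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; have {self.class_names}") from None


@dataclass
class FusedMap:
    """Ensemble mean/SD and the uncertainty-corrected map ``p~``.

    ``p_tilde = max(p_mean - A * p_sigma, 0)`` per pixel and class.
    """

    p_mean: np.ndarray
    p_sigma: np.ndarray
    p_tilde: np.ndarray
    A: float
    class_names: tuple[str, ...]
    mpp: float

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; have {self.class_names}") from None


@dataclass
class TissueInstance:
    """One segmented tissue compartment.

    ``s2`` is the squared mean ensemble SD over the mask and ``g`` the
    per-slide min-max quality weight derived from it (1 = most consistent
    instance of the slide).  ``crop`` is the padded, outside-blurred RGB crop.
    """

    instance_id: int
    class_label: str
    mask: np.ndarray
    s2: float | None = None
    g: float | None = None
    crop: np.ndarray | None = None
    bbox: tuple[int, int, int, int] | None = None
    truncated: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def mask_bbox(self) -> tuple[int, int, int, int]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        if rows.size == 0:
            raise ValueError(f"instance {self.instance_id} has an empty mask")
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


@dataclass
class Bag:
    """One slide for multi-instance learning.

    ``features`` is the (n_instances, n_features) matrix; ``g`` the optional
    per-instance quality weights; ``n_tissues`` is the tissue count used as
    the slide's weight in evaluation.
    """

    bag_id: str
    donor_id: str
    label: int
    features: np.ndarray
    g: np.ndarray | None = None
    sigma2: np.ndarray | None = None
    roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("a bag needs >= 1 instance feature row")
        if not self.donor_id:
            raise ValueError("donor_id must be nonempty")
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float)
            if self.g.shape != (self.n_instances,):
                raise ValueError("g must have one entry per instance")
            if self.g.min() < 0 or self.g.max() > 1:
                raise ValueError("g must lie in [0, 1]")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.n_instances


@dataclass
class BagSet:
    """A labelled collection of bags plus the generative configuration."""

    bags: list[Bag]
    config: Any = None

    def __len__(self) -> int:
        return len(self.bags)

    def __iter__(self):
        return iter(self.bags)

    def __getitem__(self, i):
        return self.bags[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags])

    @property
    def donors(self) -> list[str]:
        return sorted({b.donor_id for b in self.bags})

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Export as (instances, bags) tables mirroring the CSV interchange
        format: instances carry ``bag_id, instance_id, role, sigma2, f_*``."""
        inst_rows = []
        bag_rows = []
        for b in self.bags:
            bag_rows.append({"bag_id": b.bag_id, "donor_id": b.donor_id, "label": b.label})
            for k in range(b.n_instances):
                row: dict[str, Any] = {
                    "bag_id": b.bag_id,
                    "instance_id": k,
                    "role": b.roles[k] if b.roles is not None else "",
                    "sigma2": b.sigma2[k] if b.sigma2 is not None else np.nan,
                }
                if b.g is not None:
                    row["g"] = b.g[k]
                for d in range(b.features.shape[1]):
                    row[f"f_{d}"] = b.features[k, d]
                inst_rows.append(row)
        return pd.DataFrame(inst_rows), pd.DataFrame(bag_rows)

    @classmethod
    def from_frames(cls, instances: pd.DataFrame, bags: pd.DataFrame) -> "BagSet":
        feat_cols = sorted(
            (c for c in instances.columns if c.startswith("f_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        out: list[Bag] = []
        for _, brow in bags.iterrows():
            sub = instances[instances["bag_id"] == brow["bag_id"]].sort_values("instance_id")
            if sub.empty:
                raise ValueError(f"bag {brow['bag_id']!r} has no instances")
            out.append(
                Bag(
                    bag_id=str(brow["bag_id"]),
                    donor_id=str(brow["donor_id"]),
                    label=int(brow["label"]),
                    features=sub[feat_cols].to_numpy(float),
                    g=sub["g"].to_numpy(float) if "g" in sub.columns else None,
                    sigma2=sub["sigma2"].to_numpy(float) if "sigma2" in sub.columns else None,
                    roles=tuple(sub["role"]) if "role" in sub.columns else None,
                )
            )
        return cls(bags=out)


def validate_weights(w: Sequence[float] | np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w
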