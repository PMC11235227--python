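"""Array-archive and multichannel-TIFF persistence for stacks and maps.

Probability stacks and fused maps travel either as ``.npz`` archives or as
multichannel float32 TIFFs with a JSON sidecar carrying the class names and
pixel scale (TIFF pages cannot).  The sidecar sits next to the raster with
suffix ``.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import FusedMap, ProbabilityStack


def save_stack(stack: ProbabilityStack, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack.maps.astype(np.float32), photometric="minisblack")
        path.with_suffix(".json").write_text(
            json.dumps({"class_names": list(stack.class_names), "mpp": stack.mpp})
        )
    else:
        np.savez_compressed(
            path,
            maps=stack.maps.astype(np.float32),
            class_names=np.array(stack.class_names),
            mpp=stack.mpp,
        )
    return path


def load_stack(path) -> ProbabilityStack:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        maps = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return ProbabilityStack(
            maps=maps, class_names=tuple(meta["class_names"]), mpp=float(meta["mpp"])
        )
    with np.load(path) as z:
        return ProbabilityStack(
            maps=z["maps"].astype(float),
            class_names=tuple(str(c) for c in z["class_names"]),
            mpp=float(z["mpp"]),
        )


def save_fused(fused: FusedMap, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stacked = np.stack([fused.p_mean, fused.p_sigma, fused.p_tilde]).astype(np.float32)
        tifffile.imwrite(path, stacked, photometric="minisblack")
        path.with_suffix(".json").write_text(
            json.dumps(
                {"class_names": list(fused.class_names), "mpp": fused.mpp, "A": fused.A}
            )
        )
    else:
        np.savez_compressed(
            path,
            p_mean=fused.p_mean.astype(np.float32),
            p_sigma=fused.p_sigma.astype(np.float32),
            p_tilde=fused.p_tilde.astype(np.float32),
            A=fused.A,
            class_names=np.array(fused.class_names),
            mpp=fused.mpp,
        )
    return path


def load_fused(path) -> FusedMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stacked = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return FusedMap(
            p_mean=stacked[0],
            p_sigma=stacked[1],
            p_tilde=stacked[2],
            A=float(meta["A"]),
            class_names=tuple(meta["class_names"]),
            mpp=float(meta["mpp"]),
        )
    with np.load(path) as z:
        return FusedMap(
            p_mean=z["p_mean"].astype(float),
            p_sigma=z["p_sigma"].astype(float),
            p_tilde=z["p_tilde"].astype(float),
            A=float(z["A"]),
            class_names=tuple(str(c) for c in z["class_names"]),
            mpp=float(z["mpp"]),
        )
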