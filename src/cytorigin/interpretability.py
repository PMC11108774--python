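"""Attention-score extraction and heatmap overlay rendering.

Each patch of the source frame is outlined with a colored square frame: the
patch's attention score, min-max normalized across the image, is mapped
through the diverging blue-to-red ``coolwarm`` colormap.  Reddish frames mark
regions highly informative for the classification decision; bluish frames
mark regions of low diagnostic value.  Pixels outside the frame borders are
left untouched unless an interior overlay opacity is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from matplotlib import colormaps

from .bagio import CytologyImage, PatchBag
from .errors import CytoriginError
from .mil_models import FeatureBag, MILModel


class RenderError(CytoriginError):
    """Overlay cannot be rendered (no source raster); carries the AttentionMap."""

    def __init__(self, message, attention_map=None):
        super().__init__(message)
        self.attention_map = attention_map


@dataclass
class AttentionMap:
    """Per-patch attention scores with their grid anchors."""

    scores: np.ndarray
    coords: Sequence[Tuple[int, int]]
    norm_range: Tuple[float, float] = (0.0, 1.0)

    def normalized(self) -> np.ndarray:
        lo, hi = self.norm_range
        if hi <= lo:
            return np.full_like(self.scores, 0.5, dtype=float)
        return np.clip((self.scores - lo) / (hi - lo), 0.0, 1.0)


def render_heatmap(scores: np.ndarray, coords, image: CytologyImage,
                   patch_size: int = 224, frame_width: int = 6,
                   interior_alpha: float = 0.0, cmap: str = "coolwarm",
                   norm_range: Optional[Tuple[float, float]] = None
                   ) -> Tuple[np.ndarray, AttentionMap]:
    """Overlay colored patch frames onto the source image.

    Scores are min-max normalized per image by default; pass ``norm_range``
    for fixed global coloring.  Returns the overlay raster (same dimensions
    as the source) and the AttentionMap.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = (float(scores.min()), float(scores.max())) if norm_range is None else norm_range
    amap = AttentionMap(scores=scores, coords=list(coords), norm_range=(lo, hi))
    if image is None:
        raise RenderError("no source raster to render onto", attention_map=amap)
    overlay = np.asarray(image.pixels)
    if overlay.ndim == 2:
        overlay = np.stack([overlay] * 3, axis=-1)
    overlay = overlay.astype(np.uint8).copy()
    colors = (np.asarray(colormaps[cmap](amap.normalized()))[:, :3] * 255).astype(np.uint8)
    fw = frame_width
    for (r, c), color in zip(amap.coords, colors):
        y0, x0 = r * patch_size, c * patch_size
        y1, x1 = y0 + patch_size, x0 + patch_size
        if interior_alpha > 0:
            block = overlay[y0:y1, x0:x1].astype(float)
            overlay[y0:y1, x0:x1] = ((1 - interior_alpha) * block
                                     + interior_alpha * color).astype(np.uint8)
        overlay[y0:y0 + fw, x0:x1] = color
        overlay[y1 - fw:y1, x0:x1] = color
        overlay[y0:y1, x0:x0 + fw] = color
        overlay[y0:y1, x1 - fw:x1] = color
    return overlay, amap


def attention_heatmap(model: MILModel, bag: PatchBag, image: Optional[CytologyImage],
                      features: Optional[np.ndarray] = None, cov=None,
                      patch_size: int = 224, **render_kwargs
                      ) -> Tuple[np.ndarray, AttentionMap]:
    """Attention overlay for a case.

    ``features`` (n x d) must be supplied when the model consumes feature
    bags (the usual case); scores come from the model's per-patch attention
    (gated attention for the AbMIL variants — the predicted class's branch for
    the multi-branch head — and last-layer class-token attention averaged
    over heads for the transformer variants, as recorded in the map metadata).
    """
    X = features if features is not None else bag.features
    if X is None:
        raise RenderError("bag carries neither features nor a feature matrix")
    scores = model.attention_scores(FeatureBag(X, case_id=bag.case_id), cov)
    if image is None and not bag.has_rasters:
        # still return the scores through the error object
        amap = AttentionMap(scores=scores, coords=list(bag.coords),
                            norm_range=(float(scores.min()), float(scores.max())))
        raise RenderError("feature-only bag without a source raster", attention_map=amap)
    return render_heatmap(scores, bag.coords, image, patch_size=patch_size, **render_kwargs)
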