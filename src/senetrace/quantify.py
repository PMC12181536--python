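"""Per-cell feature quantification from multi-round immunofluorescence images.

Given a labeled nuclear mask and registered channel images, each cell yields
its nuclear area (pixel count), per-marker nuclear mean, nuclear total
(area x mean — the total-protein proxy), and the mean over a fixed-width
cytoplasmic ring around the nucleus.  Rounds are aligned by integer-pixel
phase correlation with a normalized cross-correlation quality score replacing
a manual alignment check.

The ring is the set of pixels within Chebyshev distance ``width`` of a
nucleus, excluding all nuclear pixels of any label; pixels reachable from
several nuclei go to the nearest one (ties to the smaller label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "RegistrationResult",
    "register_rounds",
    "apply_shift",
    "segment_nuclei",
    "nuclear_features",
    "cytoplasm_ring",
    "screen_artifacts",
    "quantify_scene",
]


@dataclass
class RegistrationResult:
    """Estimated integer translation of a moving round."""

    offset: Tuple[int, int]      # (dy, dx): displacement of moving vs reference
    score: float                 # normalized cross-correlation in [-1, 1]
    ok: bool                     # False when no correlation peak exists


def register_rounds(reference: np.ndarray, moving: np.ndarray) -> RegistrationResult:
    """Estimate the integer-pixel displacement of ``moving`` relative to
    ``reference`` by phase correlation.

    ``offset`` is the displacement that was applied to the moving round: a
    scene translated by (5, -3) reports (5, -3).  Aligning the moving image
    back onto the reference is ``apply_shift(moving, (-dy, -dx))``.  The
    score is the normalized cross-correlation of the overlapping region at
    the estimated displacement.  An all-constant image has no correlation
    peak and is flagged ``ok=False``.
    """
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share dimensions")
    if not (np.isfinite(reference).all() and np.isfinite(moving).all()):
        raise ValueError("images must contain finite values")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        warnings.warn("constant image: no correlation peak", stacklevel=2)
        return RegistrationResult((0, 0), 0.0, False)

    from skimage.registration import phase_cross_correlation

    # skimage returns the shift that registers moving onto the reference,
    # i.e. the negative of the displacement
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=1)
    dy, dx = -int(round(shift[0])), -int(round(shift[1]))
    score = _ncc_at_shift(reference, moving, -dy, -dx)
    return RegistrationResult((dy, dx), score, True)


def apply_shift(img: np.ndarray, offset: Tuple[int, int]) -> np.ndarray:
    """Apply an integer (dy, dx) translation with zero fill."""
    dy, dx = offset
    out = np.zeros_like(img)
    h, w = img.shape
    out[max(dy, 0):min(h, h + dy), max(dx, 0):min(w, w + dx)] = \
        img[max(-dy, 0):min(h, h - dy), max(-dx, 0):min(w, w - dx)]
    return out


def _ncc_at_shift(ref: np.ndarray, mov: np.ndarray, dy: int, dx: int) -> float:
    h, w = ref.shape
    a = ref[max(dy, 0):min(h, h + dy), max(dx, 0):min(w, w + dx)]
    b = mov[max(-dy, 0):min(h, h - dy), max(-dx, 0):min(w, w - dx)]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    return float(np.clip((a * b).mean(), -1.0, 1.0))


def segment_nuclei(dna: np.ndarray, min_distance: int = 7,
                   smooth_sigma: float = 1.0) -> np.ndarray:
    """Segment nuclei from a DNA channel by Otsu thresholding followed by a
    distance-transform watershed that splits touching nuclei.

    Adequate for phantom scenes; externally produced masks (e.g. from a
    learned segmenter) can be passed anywhere a mask is accepted.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import gaussian, threshold_otsu
    from skimage.measure import label as cc_label
    from skimage.segmentation import watershed

    if dna.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(dna) == 0:
        warnings.warn("empty image: returning empty mask", stacklevel=2)
        return np.zeros(dna.shape, dtype=np.uint16)

    smoothed = gaussian(dna.astype(float), sigma=smooth_sigma, preserve_range=True)
    fg = smoothed > threshold_otsu(smoothed)
    if not fg.any():
        warnings.warn("no foreground after thresholding", stacklevel=2)
        return np.zeros(dna.shape, dtype=np.uint16)

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(dna.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return cc_label(fg).astype(np.uint16)
    labels = watershed(-dist, markers, mask=fg)
    return labels.astype(np.uint16)


def nuclear_features(mask: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Per-label (area, mean, total) over the nuclear mask.

    total is area x mean, the total-protein proxy; it equals the per-pixel
    sum over the label exactly.
    """
    if mask.shape != channel.shape:
        raise ValueError("mask and channel must share dimensions")
    from skimage.measure import regionprops_table

    if mask.max() == 0:
        return pd.DataFrame(columns=["label", "area", "mean", "total"])
    props = regionprops_table(mask.astype(np.int32), intensity_image=channel,
                              properties=("label", "area", "intensity_mean"))
    df = pd.DataFrame(props).rename(columns={"intensity_mean": "mean"})
    df["area"] = df["area"].astype(float)
    df["total"] = df["area"] * df["mean"]
    return df


def cytoplasm_ring(mask: np.ndarray, width_px: int = 5) -> np.ndarray:
    """Per-label cytoplasmic ring mask.

    A pixel belongs to label L's ring iff it is background, within Chebyshev
    distance <= ``width_px`` of L's pixels, and L is the nearest nucleus by
    that metric (ties to the smaller label id).  Returns an integer image of
    ring labels (0 elsewhere).  A label fully enclosed by other nuclei gets an
    empty ring.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros(mask.shape, dtype=np.int32)
    if labels.size == 0:
        return out

    background = mask == 0
    best_dist = np.full(mask.shape, np.iinfo(np.int32).max, dtype=np.int64)
    # iterate labels in increasing order so ties keep the smaller id
    for lab in labels:
        # chessboard distance from every pixel to this label's nearest pixel
        d = ndi.distance_transform_cdt(mask != lab, metric="chessboard")
        cand = background & (d <= width_px) & (d > 0)
        better = cand & (d < best_dist)
        out[better] = lab
        best_dist[better] = d[better]
    return out


def _touches_border(mask: np.ndarray) -> Dict[int, bool]:
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    on_border = set(np.unique(border)) - {0}
    return {int(lab): int(lab) in on_border for lab in np.unique(mask) if lab != 0}


def screen_artifacts(
    records: pd.DataFrame,
    area_bounds: Tuple[float, float] = (50.0, 10_000.0),
    border_policy: str = "exclude",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Artifact screen on quantified records.

    Removes labels outside ``area_bounds`` and (under the default policy)
    labels flagged as touching the image border via a boolean
    ``touches_border`` column.  Returns ``(kept, exclusion_log)`` where the
    log lists one row per excluded cell with a reason code.  Idempotent.
    """
    lo, hi = area_bounds
    if lo >= hi:
        raise ValueError(f"area bounds min ({lo}) must be < max ({hi})")
    if border_policy not in ("exclude", "keep"):
        raise ValueError("border_policy must be 'exclude' or 'keep'")

    reasons = []
    keep = np.ones(len(records), dtype=bool)
    area = records["nuclear_area_px"].to_numpy()
    for i, idx in enumerate(records.index):
        if border_policy == "exclude" and bool(records.get(
                "touches_border", pd.Series(False, index=records.index))[idx]):
            reasons.append((records.loc[idx, "cell_id"], "border"))
            keep[i] = False
        elif area[i] < lo:
            reasons.append((records.loc[idx, "cell_id"], "area_min"))
            keep[i] = False
        elif area[i] > hi:
            reasons.append((records.loc[idx, "cell_id"], "area_max"))
            keep[i] = False
    log = pd.DataFrame(reasons, columns=["cell_id", "reason"])
    return records.loc[keep].copy(), log


def quantify_scene(
    mask: np.ndarray,
    rounds: Sequence[Dict[str, np.ndarray]],
    day: int,
    ring_width: int = 5,
    reference_channel: str = "DNA",
    register: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a full multi-round scene into the per-cell feature table.

    Each round is registered to the first via its reference channel, all
    channels are shifted into the common frame, and per-label features are
    extracted.  Returns ``(records, registration_table)``; records carry a
    ``touches_border`` column for downstream screening.  Cytoplasmic means of
    labels with empty rings are NaN (flagged missing).
    """
    ref = rounds[0][reference_channel]
    reg_rows = [{"round": 0, "dy": 0, "dx": 0, "score": 1.0}]
    aligned: List[Dict[str, np.ndarray]] = [dict(rounds[0])]
    for i, rnd in enumerate(rounds[1:], start=1):
        if register:
            reg = register_rounds(ref, rnd[reference_channel])
            dy, dx = reg.offset
            reg_rows.append({"round": i, "dy": dy, "dx": dx, "score": reg.score})
            aligned.append({k: apply_shift(v, (-dy, -dx)) for k, v in rnd.items()})
        else:
            reg_rows.append({"round": i, "dy": 0, "dx": 0, "score": np.nan})
            aligned.append(dict(rnd))

    ring = cytoplasm_ring(mask, width_px=ring_width)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    base = pd.DataFrame({"cell_id": labels.astype(int)})
    base["day"] = day
    areas = ndi.sum_labels(np.ones_like(mask, dtype=float), mask, labels)
    base["nuclear_area_px"] = areas
    border = _touches_border(mask)

    for rnd in aligned:
        for marker, img in rnd.items():
            if marker == reference_channel:
                continue
            feats = nuclear_features(mask, img).set_index("label")
            base[f"{marker}_nuc_mean"] = feats.reindex(labels)["mean"].to_numpy()
            base[f"{marker}_nuc_total"] = feats.reindex(labels)["total"].to_numpy()
            ring_sum = ndi.sum_labels(img, ring, labels)
            ring_n = ndi.sum_labels(np.ones_like(img), ring, labels)
            with np.errstate(invalid="ignore", divide="ignore"):
                cyto = np.where(ring_n > 0, ring_sum / np.maximum(ring_n, 1), np.nan)
            base[f"{marker}_cyto_mean"] = cyto

    base["touches_border"] = [border.get(int(lab), False) for lab in labels]
    return base, pd.DataFrame(reg_rows)
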