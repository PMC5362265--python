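"""Nuclear vs non-nuclear classification from inter-anchor intensity profiles.

In cells with two spindle-pole-body anchoring platforms the nucleus lies
between them, so a recruited prey that accumulates between the two anchors is
scored as nuclear. The classifier extracts the intensity profile along the
line joining the brightest pixel of each anchor (both channels, background
subtracted), locates the two red peaks and the green maximum, and calls the
prey nuclear when the green peak falls strictly between the red peaks with a
configurable margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabeledSpots

__all__ = [
    "AnchorPair",
    "ProfileClassification",
    "pair_anchors",
    "line_profile",
    "subtract_field_median",
    "classify_localization",
    "classify_pair",
    "nuclear_fraction",
]


@dataclass
class AnchorPair:
    label_a: int
    label_b: int
    pos_a: tuple[int, int]  # brightest pixel (row, col)
    pos_b: tuple[int, int]
    separation_um: float


@dataclass
class ProfileClassification:
    red_profile: np.ndarray
    green_profile: np.ndarray
    red_peaks: tuple[int, int]  # profile indices
    green_peak: int
    green_peak_fraction: float  # position as fraction of inter-red-peak span
    prominence: float
    label: str  # nuclear | non_nuclear | ambiguous
    reason: str = ""


def pair_anchors(anchors: LabeledSpots, pixel_size: float,
                 d_min: float = 1.0, d_max: float = 4.0) -> list[AnchorPair]:
    """Greedily pair mutually nearest anchors with separation in [d_min, d_max] µm.

    Admissible pairs are taken closest-first; each anchor joins at most one
    pair and leftovers are dropped.
    """
    tab = anchors.table
    if len(tab) < 2:
        return []
    pos = tab[["max_row", "max_col"]].to_numpy(dtype=float)
    labels = tab["label"].to_numpy(dtype=int)
    cands = []
    for i in range(len(tab)):
        for j in range(i + 1, len(tab)):
            d = math.hypot(*(pos[i] - pos[j])) * pixel_size
            if d_min <= d <= d_max:
                cands.append((d, i, j))
    cands.sort()
    used: set[int] = set()
    pairs = []
    for d, i, j in cands:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(AnchorPair(int(labels[i]), int(labels[j]),
                                tuple(int(x) for x in pos[i]),
                                tuple(int(x) for x in pos[j]), d))
    return pairs


def subtract_field_median(image: np.ndarray) -> np.ndarray:
    """Per-channel background subtraction: remove the field-wide median."""
    image = np.asarray(image, dtype=np.float64)
    return image - np.median(image)


def line_profile(image: np.ndarray, p0, p1) -> np.ndarray:
    """Bilinear-interpolated intensity sampled at ~1 px spacing along p0→p1
    inclusive."""
    image = np.asarray(image, dtype=np.float64)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("profile endpoints must differ")
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError(f"profile endpoint {tuple(p)} outside image")
    dist = float(np.hypot(*(p1 - p0)))
    n = max(2, int(round(dist)) + 1)
    t = np.linspace(0.0, 1.0, n)
    coords = np.vstack([p0[0] + t * (p1[0] - p0[0]),
                        p0[1] + t * (p1[1] - p0[1])])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def classify_localization(red_profile: np.ndarray, green_profile: np.ndarray,
                          margin: float = 0.15,
                          prominence_factor: float = 3.0,
                          end_window: float = 0.2) -> ProfileClassification:
    """Classify a prey profile as nuclear / non_nuclear / ambiguous.

    Red peaks are the argmax within ``end_window`` of each profile end. The
    green global maximum is nuclear iff it lies in the open interval between
    the red peaks shrunk by ``margin`` x the inter-peak distance on each side,
    and its prominence above the profile median exceeds ``prominence_factor``
    x the profile's MAD-based noise sigma.
    """
    red = np.asarray(red_profile, dtype=float)
    green = np.asarray(green_profile, dtype=float)
    if red.shape != green.shape:
        raise ValueError("profiles must share a length")
    n = red.size
    if n < 5:
        raise ValueError("profiles must have length >= 5")
    w = max(2, int(math.ceil(end_window * n)))
    left_peak = int(np.argmax(red[:w]))
    right_peak = int(n - w + np.argmax(red[n - w:]))
    g = int(np.argmax(green))
    med = float(np.median(green))
    mad_sigma = 1.4826 * float(np.median(np.abs(green - med)))
    prominence = float(green[g] - med)

    span = right_peak - left_peak
    frac = (g - left_peak) / span if span > 0 else float("nan")

    def result(label: str, reason: str = "") -> ProfileClassification:
        return ProfileClassification(red, green, (left_peak, right_peak), g,
                                     frac, prominence, label, reason)

    red_med = float(np.median(red))
    red_sigma = 1.4826 * float(np.median(np.abs(red - red_med)))
    red_floor = red_med + prominence_factor * red_sigma
    if span < 2 or red[left_peak] <= red_floor or red[right_peak] <= red_floor:
        return result("ambiguous", "red_peaks_unresolved")
    if prominence <= prominence_factor * mad_sigma:
        return result("ambiguous", "low_prominence")
    lo = left_peak + margin * span
    hi = right_peak - margin * span
    if lo < g < hi:
        return result("nuclear")
    return result("non_nuclear")


def classify_pair(fld_red: np.ndarray, fld_green: np.ndarray, pair: AnchorPair,
                  margin: float = 0.15, prominence_factor: float = 3.0,
                  subtract_background: bool = True) -> ProfileClassification:
    """Convenience wrapper: background-subtract, profile both channels along
    the anchor pair, and classify."""
    red, green = fld_red, fld_green
    if subtract_background:
        red = subtract_field_median(red)
        green = subtract_field_median(green)
    rp = line_profile(red, pair.pos_a, pair.pos_b)
    gp = line_profile(green, pair.pos_a, pair.pos_b)
    return classify_localization(rp, gp, margin=margin,
                                 prominence_factor=prominence_factor)


def nuclear_fraction(records: list[ProfileClassification] | pd.DataFrame) -> float:
    """Fraction of unambiguous calls scored nuclear."""
    if isinstance(records, pd.DataFrame):
        labels = records["class"].tolist()
    else:
        labels = [r.label for r in records]
    calls = [l for l in labels if l in ("nuclear", "non_nuclear")]
    if not calls:
        return float("nan")
    return sum(l == "nuclear" for l in calls) / len(calls)
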