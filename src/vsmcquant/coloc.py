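"""Thresholded two-channel colocalization statistics.

Implements the quantities reported by the standard ImageJ colocalization
plugins: Pearson's r excluding zero-zero pixels, thresholded Manders split
coefficients tM1/tM2 (the fraction of each channel's above-threshold signal
that co-occurs with the other channel), percent volume colocalised, and the
Costes automatic threshold (thresholds lowered along the channel-channel
regression until the below-threshold pixels are uncorrelated).  A
round-structure prefilter restricts the analysis to compact, circular
objects (e.g. actin-tail cross-sections) before computing overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "ColocResult",
    "costes_thresholds",
    "manders_split",
    "pearson_above_threshold",
    "percent_volume",
    "round_structure_filter",
    "coloc_report",
]


@dataclass(frozen=True)
class ColocResult:
    pearson_above_threshold: float
    tM1: float
    tM2: float
    percent_volume_ch1: float
    percent_volume_ch2: float
    t1: float
    t2: float


def _flatten(ch1, ch2, roi=None):
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != ch1.shape:
            raise ValueError("ROI shape differs from channels")
        return ch1[roi], ch2[roi]
    return ch1.ravel(), ch2.ravel()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return float("nan")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def costes_thresholds(
    ch1,
    ch2,
    roi=None,
    max_candidates: int = 512,
) -> tuple[float, float]:
    """Costes automatic thresholds for a channel pair.

    Fits the orthogonal (total least squares) regression ch2 = a·ch1 + b,
    then walks candidate thresholds (t1, a·t1 + b) down from the brightest
    ch1 value; the first pair for which the Pearson correlation of pixels
    below *both* thresholds drops to <= 0 is returned.  Perfectly correlated
    pairs never decorrelate, so the minimum-intensity pair is returned.
    Constant channels make the regression undefined and raise.
    """
    x, y = _flatten(ch1, ch2, roi)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant channel: Costes regression undefined")
    cov = np.cov(np.stack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("vertical regression line: Costes scan undefined")
    a = v[1] / v[0]
    b = y.mean() - a * x.mean()

    cands = np.unique(x)[::-1]
    if len(cands) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        cands = np.unique(np.quantile(x, qs))[::-1]
    t_pair = (float(x.min()), float(a * x.min() + b))
    for t1 in cands:
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        if below.sum() < 2:
            continue
        r = _pearson(x[below], y[below])
        if np.isnan(r):
            continue
        if r <= 0:
            return (float(t1), float(t2))
    return t_pair


def manders_split(
    ch1,
    ch2,
    t1: float,
    t2: float,
    roi=None,
    denominator: str = "above_threshold",
) -> tuple[float, float]:
    """Thresholded Manders split coefficients (tM1, tM2).

    tM1 = Σ ch1 over pixels (ch1 > t1 ∧ ch2 > t2) / Σ ch1 over (ch1 > t1);
    tM2 symmetric.  ``denominator="total"`` divides by the whole-image
    channel sum instead (the classic unthresholded M1/M2 denominator).
    NaN is returned for a channel whose denominator set is empty.
    """
    if denominator not in ("above_threshold", "total"):
        raise ValueError("denominator must be 'above_threshold' or 'total'")
    x, y = _flatten(ch1, ch2, roi)
    both = (x > t1) & (y > t2)

    def one(sig, own_above):
        denom = sig[own_above].sum() if denominator == "above_threshold" else sig.sum()
        if denom <= 0:
            return float("nan")
        return float(sig[both].sum() / denom)

    return one(x, x > t1), one(y, y > t2)


def pearson_above_threshold(
    ch1,
    ch2,
    t1: float = 0.0,
    t2: float = 0.0,
    roi=None,
    mode: str = "zero_zero",
) -> float:
    """Pearson correlation excluding uninformative pixels.

    ``mode="zero_zero"`` (default) drops only pixels that are zero in both
    channels; ``mode="above_union"`` restricts to pixels above threshold in
    at least one channel.  NaN when fewer than 3 qualifying pixels remain
    or a selected channel is constant.
    """
    if mode not in ("zero_zero", "above_union"):
        raise ValueError("mode must be 'zero_zero' or 'above_union'")
    x, y = _flatten(ch1, ch2, roi)
    if mode == "zero_zero":
        sel = ~((x == 0) & (y == 0))
    else:
        sel = (x > t1) | (y > t2)
    if sel.sum() < 3:
        return float("nan")
    return _pearson(x[sel], y[sel])


def percent_volume(ch1, ch2, t1: float, t2: float, roi=None) -> tuple[float, float]:
    """Percent of each channel's above-threshold pixels that colocalize.

    %ch1 = 100 · |{ch1 > t1 ∧ ch2 > t2}| / |{ch1 > t1}|; symmetric for ch2.
    NaN when a channel has no above-threshold pixels.
    """
    x, y = _flatten(ch1, ch2, roi)
    a1, a2 = x > t1, y > t2
    both = a1 & a2

    def pct(above):
        n = above.sum()
        return float(100.0 * both.sum() / n) if n else float("nan")

    return pct(a1), pct(a2)


def round_structure_filter(
    binary,
    circularity_min: float = 0.8,
    min_area_px: int | None = None,
    max_area_px: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Keep compact round connected components (circularity 4πA/P² ≥ cutoff).

    Perimeter is skimage's weighted contour-length estimate, which is ≈ πd
    for a digitized disk so that disks score ≈ 1 while lines and elongated
    bars score far below the 0.8 default.  Optional pixel-area bounds reject
    specks and large patches.  Returns the filtered mask and the kept
    component labels (of the internal labelling).
    """
    binary = np.asarray(binary) > 0
    labels = measure.label(binary, connectivity=2)
    keep_mask = np.zeros_like(binary)
    kept = []
    for prop in measure.regionprops(labels):
        if min_area_px is not None and prop.area < min_area_px:
            continue
        if max_area_px is not None and prop.area > max_area_px:
            continue
        perim = prop.perimeter
        circ = 1.0 if perim == 0 else 4.0 * np.pi * prop.area / perim**2
        if circ >= circularity_min:
            keep_mask |= labels == prop.label
            kept.append(prop.label)
    return keep_mask, kept


def coloc_report(
    ch1,
    ch2,
    thresholds: tuple[float, float] | str = "auto",
    roi=None,
    pearson_mode: str = "zero_zero",
) -> ColocResult:
    """Full colocalization report for one channel pair.

    ``thresholds="auto"`` uses the Costes procedure; otherwise pass
    ``(t1, t2)`` explicitly.
    """
    if thresholds == "auto":
        t1, t2 = costes_thresholds(ch1, ch2, roi=roi)
    else:
        t1, t2 = thresholds
    tm1, tm2 = manders_split(ch1, ch2, t1, t2, roi=roi)
    pv1, pv2 = percent_volume(ch1, ch2, t1, t2, roi=roi)
    r = pearson_above_threshold(ch1, ch2, t1, t2, roi=roi, mode=pearson_mode)
    return ColocResult(
        pearson_above_threshold=r,
        tM1=tm1,
        tM2=tm2,
        percent_volume_ch1=pv1,
        percent_volume_ch2=pv2,
        t1=float(t1),
        t2=float(t2),
    )
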