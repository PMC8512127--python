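"""Bi-level and multilevel Otsu threshold selection.

Given a gray-level histogram, segmenting into M classes requires M-1
thresholds Th_1 < ... < Th_(M-1).  Gray level i belongs to class k iff
Th_(k-1) < i <= Th_k (with Th_0 = -1 and Th_M = L-1).  Each class k has
cumulative probability

    omega_k = sum_{i in C_k} p_i
    mu_k    = sum_{i in C_k} i p_i / omega_k

and the optimal thresholds maximise the interclass variance

    sigma_B^2 = sum_k omega_k (mu_k - mu_T)^2

over all admissible threshold combinations.  The search here is
exhaustive but uses zeroth/first cumulative moments so that the
three-threshold (M = 4) search over 256 levels stays well under a
second.  Ties are broken by the lexicographically smallest threshold
vector, which makes results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import probabilities

__all__ = [
    "DegenerateHistogramError",
    "ClassStats",
    "class_stats",
    "otsu_thresholds",
    "foreground_mask",
]

_OMEGA_MIN = 1e-12  # classes with less cumulative probability are empty


def _ratio(s: "np.ndarray | float", w: "np.ndarray | float") -> "np.ndarray | float":
    """s^2 / w with empty classes contributing exactly 0.

    Cumulative-sum cancellation can leave s ~ 1e-14 while w is exactly 0;
    dividing would explode, so anything below _OMEGA_MIN counts as empty.
    """
    w = np.asarray(w, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    return np.where(w > _OMEGA_MIN, s * s / np.maximum(w, _OMEGA_MIN), 0.0)


class DegenerateHistogramError(ValueError):
    """Histogram has fewer occupied gray levels than requested classes."""


@dataclass(frozen=True)
class ClassStats:
    """Per-class statistics for a threshold set applied to a histogram."""

    omega: tuple[float, ...]  # cumulative probability per class
    mu: tuple[float, ...]  # mean gray level per class (0 for empty classes)
    mu_t: float  # global mean
    sigma_b2: float  # interclass variance

    @property
    def n_classes(self) -> int:
        return len(self.omega)


def class_stats(hist: np.ndarray, thresholds: tuple[int, ...] | list[int]) -> ClassStats:
    """Compute omega_k, mu_k, mu_T and sigma_B^2 for the given thresholds.

    Empty classes are legal: they carry omega_k = 0 and contribute
    nothing to the interclass variance.
    """
    p = probabilities(np.asarray(hist))
    levels = np.arange(p.size, dtype=np.float64)
    bounds = [-1, *thresholds, p.size - 1]
    if any(b >= c for b, c in zip(bounds[:-1], bounds[1:])):
        raise ValueError(f"thresholds must be strictly increasing in range: {thresholds}")
    omega, mu = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sl = slice(lo + 1, hi + 1)
        w = float(p[sl].sum())
        omega.append(w)
        mu.append(float((levels[sl] * p[sl]).sum() / w) if w > 0 else 0.0)
    mu_t = float((levels * p).sum())
    sigma = sum(w * (m - mu_t) ** 2 for w, m in zip(omega, mu) if w > 0)
    return ClassStats(tuple(omega), tuple(mu), mu_t, float(sigma))


def _best_m2(p0: np.ndarray, p1: np.ndarray, mu_t: float) -> tuple[float, tuple[int, ...]]:
    l = p0.size
    w1 = np.cumsum(p0)[:-1]  # class 1 = [0..t], t = 0..L-2
    s1 = np.cumsum(p1)[:-1]
    w2 = 1.0 - w1
    s2 = mu_t - s1
    sigma = _ratio(s1, w1) + _ratio(s2, w2) - mu_t**2
    t = int(np.argmax(sigma))  # first occurrence = lexicographic smallest
    return float(sigma[t]), (t,)


def _best_m3(p0: np.ndarray, p1: np.ndarray, mu_t: float) -> tuple[float, tuple[int, ...]]:
    l = p0.size
    c0 = np.concatenate(([0.0], np.cumsum(p0)))  # c0[i] = sum p[0..i-1]
    c1 = np.concatenate(([0.0], np.cumsum(p1)))
    t1 = np.arange(l - 2)[:, None]  # t1 < t2 <= L-2
    t2 = np.arange(l - 1)[None, :]
    valid = t2 > t1
    w1, s1 = c0[t1 + 1], c1[t1 + 1]
    w2, s2 = c0[t2 + 1] - c0[t1 + 1], c1[t2 + 1] - c1[t1 + 1]
    w3, s3 = 1.0 - c0[t2 + 1], mu_t - c1[t2 + 1]
    sigma = _ratio(s1, w1) + _ratio(s2, w2) + _ratio(s3, w3) - mu_t**2
    sigma = np.where(valid, sigma, -np.inf)
    flat = int(np.argmax(sigma))  # C order scans t1-major: lexicographic
    i, j = divmod(flat, sigma.shape[1])
    return float(sigma[i, j]), (i, j)


def _best_m4(p0: np.ndarray, p1: np.ndarray, mu_t: float) -> tuple[float, tuple[int, ...]]:
    l = p0.size
    c0 = np.concatenate(([0.0], np.cumsum(p0)))
    c1 = np.concatenate(([0.0], np.cumsum(p1)))
    best_sigma, best = -np.inf, None
    t2g = np.arange(l - 2)[:, None]
    t3g = np.arange(l - 1)[None, :]
    for t1 in range(l - 3):
        valid = (t2g > t1) & (t3g > t2g)
        w1, s1 = c0[t1 + 1], c1[t1 + 1]
        w2, s2 = c0[t2g + 1] - w1, c1[t2g + 1] - s1
        w3, s3 = c0[t3g + 1] - c0[t2g + 1], c1[t3g + 1] - c1[t2g + 1]
        w4, s4 = 1.0 - c0[t3g + 1], mu_t - c1[t3g + 1]
        sigma = (
            _ratio(s1, w1) + _ratio(s2, w2) + _ratio(s3, w3) + _ratio(s4, w4)
            - mu_t**2
        )
        sigma = np.where(valid, sigma, -np.inf)
        flat = int(np.argmax(sigma))
        i, j = divmod(flat, sigma.shape[1])
        if sigma[i, j] > best_sigma:  # strict: keeps smallest t1 on ties
            best_sigma, best = float(sigma[i, j]), (t1, i, j)
    assert best is not None
    return best_sigma, best


def otsu_thresholds(hist: np.ndarray, n_classes: int) -> tuple[int, ...]:
    """Exhaustively select the n_classes-1 thresholds maximising sigma_B^2.

    Parameters
    ----------
    hist : array of gray-level counts (length L).
    n_classes : 2, 3 or 4 — bi-, three- or four-level thresholding.

    Returns
    -------
    Strictly increasing integer thresholds, length ``n_classes - 1``.

    Raises
    ------
    DegenerateHistogramError
        If the histogram occupies fewer distinct levels than classes.
    """
    hist = np.asarray(hist)
    if n_classes not in (2, 3, 4):
        raise ValueError(f"n_classes must be 2, 3 or 4, got {n_classes}")
    if int(np.count_nonzero(hist)) < n_classes:
        raise DegenerateHistogramError(
            f"{int(np.count_nonzero(hist))} occupied levels < {n_classes} classes"
        )
    p = probabilities(hist)
    levels = np.arange(p.size, dtype=np.float64)
    p1 = levels * p
    mu_t = float(p1.sum())
    fn = {2: _best_m2, 3: _best_m3, 4: _best_m4}[n_classes]
    _, ts = fn(p, p1, mu_t)
    return tuple(int(t) for t in ts)


def foreground_mask(
    gray: np.ndarray,
    thresholds: tuple[int, ...],
    fg_rule: str = "top_class",
    area_min: int | None = None,
    area_max: int | None = None,
) -> np.ndarray:
    """Turn a thresholded gray image into a boolean foreground mask.

    ``top_class`` marks pixels brighter than the last threshold — in
    near-infrared night frames and sharpened day frames the leaves are
    the brightest structure.  ``brightest_valid_class`` builds candidate
    masks per class from the brightest downward and returns the first
    whose connected components include at least one with area inside
    ``[area_min, area_max]``; it falls back to the top class if none
    qualifies.
    """
    from scipy import ndimage as ndi

    gray = np.asarray(gray)
    ts = sorted(thresholds)
    if fg_rule == "top_class":
        return gray > ts[-1]
    if fg_rule != "brightest_valid_class":
        raise ValueError(f"unknown fg_rule {fg_rule!r}")
    if area_min is None or area_max is None:
        raise ValueError("brightest_valid_class needs area_min and area_max")
    bounds = [-1, *ts, 255]
    for k in range(len(bounds) - 2, -1, -1):  # brightest class first
        mask = (gray > bounds[k]) & (gray <= bounds[k + 1])
        if not mask.any():
            continue
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        areas = np.bincount(labels.ravel())[1:]
        if np.any((areas >= area_min) & (areas <= area_max)):
            return mask
    return gray > ts[-1]
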