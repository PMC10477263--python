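"""Geometric Cobb-angle extraction from vertebral corner landmarks.

The measurement follows the end-vertebra convention used clinically: each
vertebra gets a signed inclination (degrees from the image horizontal,
positive clockwise with y pointing down); the most tilted vertebrae bound
the curves, and a curve's Cobb angle is the difference between the
inclinations of its end vertebrae.

Algorithm, given the 17 inclinations ordered T1..L5:

1. find the interior local maxima and minima of the inclination profile;
2. iteratively delete adjacent extremum pairs whose tilt difference is
   below ``min_diff`` (default 5 degrees), smallest difference first,
   until stable;
3. add T1 and L5 to the end-vertebra list if absent;
4. consecutive end-vertebra pairs become curves; curves whose angle is
   still below ``min_diff`` are dropped;
5. curves are classified thoracic/lumbar by apex level (T11 or above is
   thoracic), the two largest thoracic and the single largest lumbar curve
   are retained and labelled major / minor1 / minor2 in descending angle.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Curve, CurveSet, LandmarkSet, N_VERTEBRAE, T11_INDEX

MIN_CURVE_DIFF_DEG = 5.0


def _wrap_half(angle_deg: float) -> float:
    """Map an angle to the (-90, 90] range (a line's tilt, not a ray's)."""
    a = math.fmod(angle_deg, 180.0)
    if a <= -90.0:
        a += 180.0
    elif a > 90.0:
        a -= 180.0
    return a


def _wrap_half_vec(angles_deg) -> np.ndarray:
    """Vectorised (-90, 90] wrap."""
    return np.array([_wrap_half(a) for a in np.asarray(angles_deg, dtype=float)])


def vertebra_inclination(corners: np.ndarray, mode: str = "midline") -> float:
    """Signed inclination in degrees of a single vertebra from its 4 corners.

    corners is a (4, 2) array in (UL, UR, LL, LR) order, coordinates (x, y).

    mode="midline" (default): the angle of the vector joining the midpoint
    of the left edge (UL, LL) to the midpoint of the right edge (UR, LR).
    mode="edge-mean": the mean of the top-edge and bottom-edge angles.
    The two definitions coincide on parallelograms.
    """
    c = np.asarray(corners, dtype=float)
    if c.shape != (4, 2):
        raise ValueError(f"corners must be (4, 2), got {c.shape}")
    ul, ur, ll, lr = c
    # degenerate quadrilateral check via the shoelace area of UL,UR,LR,LL
    ring = np.array([ul, ur, lr, ll])
    area = 0.5 * abs(
        np.sum(ring[:, 0] * np.roll(ring[:, 1], -1) - np.roll(ring[:, 0], -1) * ring[:, 1])
    )
    if area <= 0.0:
        raise ValueError("degenerate vertebra: corner quadrilateral has zero area")
    if mode == "midline":
        left = (ul + ll) / 2.0
        right = (ur + lr) / 2.0
        d = right - left
        return _wrap_half(math.degrees(math.atan2(d[1], d[0])))
    elif mode == "edge-mean":
        top = ur - ul
        bottom = lr - ll
        a_top = _wrap_half(math.degrees(math.atan2(top[1], top[0])))
        a_bot = _wrap_half(math.degrees(math.atan2(bottom[1], bottom[0])))
        # average on the half-circle; safe because endplate angles of one
        # vertebra are nearly parallel
        diff = _wrap_half(a_bot - a_top)
        return _wrap_half(a_top + diff / 2.0)
    raise ValueError(f"unknown inclination mode {mode!r}")


def inclination_profile(landmarks: LandmarkSet, mode: str = "midline") -> np.ndarray:
    """17 signed inclinations, T1..L5, from a complete landmark set."""
    if not landmarks.all_present:
        missing = np.argwhere(~landmarks.present)
        raise ValueError(f"incomplete landmarks; missing (vertebra, corner) pairs: {missing.tolist()}")
    return np.array(
        [vertebra_inclination(landmarks.points[i], mode=mode) for i in range(N_VERTEBRAE)]
    )


def _interior_extrema(values: np.ndarray) -> list[tuple[int, int]]:
    """Strict interior local extrema as (index, type) with type +1 max / -1 min."""
    out = []
    for i in range(1, len(values) - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            out.append((i, +1))
        elif values[i] < values[i - 1] and values[i] < values[i + 1]:
            out.append((i, -1))
    return out


def find_extrema(
    values: np.ndarray,
    min_diff: float = MIN_CURVE_DIFF_DEG,
    pair_removal: bool = True,
) -> list[int]:
    """End-vertebra candidate indices from a 17-value inclination profile.

    Interior strict extrema are filtered: while some adjacent extremum pair
    differs by less than ``min_diff``, the pair with the smallest difference
    is deleted (both members when ``pair_removal``, else only the member
    closer in value to its other neighbour).  T1 (0) and L5 (16) are then
    appended if absent.  Returns sorted indices.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or not np.all(np.isfinite(v)):
        raise ValueError("inclination profile must be a finite 1-D sequence")
    ext = _interior_extrema(v)

    while len(ext) >= 2:
        diffs = [abs(v[ext[j][0]] - v[ext[j + 1][0]]) for j in range(len(ext) - 1)]
        jmin = int(np.argmin(diffs))
        if diffs[jmin] >= min_diff:
            break
        if pair_removal:
            del ext[jmin : jmin + 2]
        else:
            # drop the less extreme member of the pair (smaller |value|)
            a, b = ext[jmin], ext[jmin + 1]
            drop = jmin if abs(v[a[0]]) <= abs(v[b[0]]) else jmin + 1
            del ext[drop]

    # enforce max/min alternation among survivors (safety net for ties):
    # of any adjacent same-type pair keep the more extreme member
    changed = True
    while changed:
        changed = False
        for j in range(len(ext) - 1):
            (i1, t1), (i2, t2) = ext[j], ext[j + 1]
            if t1 == t2:
                if t1 * v[i1] >= t1 * v[i2]:
                    del ext[j + 1]
                else:
                    del ext[j]
                changed = True
                break

    idx = [i for i, _ in ext]
    if 0 not in idx:
        idx.append(0)
    if len(v) - 1 not in idx:
        idx.append(len(v) - 1)
    return sorted(idx)


def _apex(values: np.ndarray, upper: int, lower: int) -> int:
    """Apex = interior vertebra deviating most from the chord of the curve.

    The chord interpolates inclination linearly between the end vertebrae.
    Ties go to the vertebra nearest the midpoint (then the more cranial);
    a two-vertebra curve has no interior, its apex is the midpoint floor.
    """
    if lower - upper < 2:
        return (upper + lower) // 2
    j = np.arange(upper + 1, lower)
    chord = values[upper] + (values[lower] - values[upper]) * (j - upper) / (lower - upper)
    dev = np.abs(values[j] - chord)
    best = dev.max()
    tied = j[np.isclose(dev, best)]
    mid = (upper + lower) / 2.0
    return int(tied[np.lexsort((tied, np.abs(tied - mid)))[0]])


def label_curves(curves: list[Curve]) -> list[Curve]:
    """Keep at most 2 thoracic + 1 lumbar curve; label major/minor1/minor2.

    Within a region curves are ranked by Cobb angle (descending); across
    the survivors the rank labels follow descending angle, ties broken by
    the more cranial upper end vertebra.
    """
    def sort_key(c: Curve):
        return (-c.cobb_angle, c.upper_end)

    thoracic = sorted((c for c in curves if c.region == "thoracic"), key=sort_key)[:2]
    lumbar = sorted((c for c in curves if c.region == "lumbar"), key=sort_key)[:1]
    kept = sorted(thoracic + lumbar, key=sort_key)
    labels = ["major", "minor1", "minor2"]
    out = []
    for c, lab in zip(kept, labels):
        c.rank = lab
        out.append(c)
    return out


def extract_curves(
    values: np.ndarray,
    min_diff: float = MIN_CURVE_DIFF_DEG,
    pair_removal: bool = True,
) -> CurveSet:
    """Build the labelled CurveSet from a 17-value inclination profile."""
    v = np.asarray(values, dtype=float)
    ends = find_extrema(v, min_diff=min_diff, pair_removal=pair_removal)
    curves: list[Curve] = []
    for u, l in zip(ends[:-1], ends[1:]):
        angle = abs(v[u] - v[l])
        if angle < min_diff:
            continue
        apex = _apex(v, u, l)
        curves.append(
            Curve(
                upper_end=u,
                lower_end=l,
                cobb_angle=float(angle),
                apex=apex,
                region="thoracic" if apex <= T11_INDEX else "lumbar",
                direction=int(np.sign(v[u] - v[l])),
            )
        )
    labelled = label_curves(curves)
    return CurveSet(curves=labelled, inclinations=v.copy())


def measure(
    landmarks: LandmarkSet,
    min_diff: float = MIN_CURVE_DIFF_DEG,
    inclination_mode: str = "midline",
    pair_removal: bool = True,
) -> CurveSet:
    """Full measurement: corner landmarks -> inclinations -> labelled curves."""
    profile = inclination_profile(landmarks, mode=inclination_mode)
    return extract_curves(profile, min_diff=min_diff, pair_removal=pair_removal)


def curves_to_table(curve_set: CurveSet):
    """Curve table as a pandas DataFrame, angles rounded to 0.1 degree."""
    import pandas as pd

    from .core import LEVELS

    rows = []
    for c in curve_set.curves:
        rows.append(
            {
                "upper_end": LEVELS[c.upper_end],
                "lower_end": LEVELS[c.lower_end],
                "cobb_angle": round(c.cobb_angle, 1),
                "region": c.region,
                "rank": c.rank,
            }
        )
    return pd.DataFrame(rows, columns=["upper_end", "lower_end", "cobb_angle", "region", "rank"])
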