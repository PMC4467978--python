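"""Normalized image contrast of stained neo-tissue.

The contrast read-out works on a greyscale line profile drawn through one
transaxial slice so that it crosses background, neo-tissue and scaffold.
Writing ``A`` for the mean greyscale difference between scaffold and
neo-tissue and ``B`` for the difference between neo-tissue and background,
the normalized contrast is ``B / (A + B)`` — the fraction of the total
background-to-scaffold dynamic range claimed by the stained tissue. Phase
means are computed over plateau samples only: values near a phase's median,
excluding the transition ramps between phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "LineProfile",
    "PlateauStats",
    "extract_line_profile",
    "detect_plateaus",
    "normalized_contrast",
    "auto_profile_lines",
]


@dataclass
class LineProfile:
    """Ordered greyscale samples along a segment in one transaxial slice."""

    samples: np.ndarray
    slice_index: int
    start: tuple[float, float]  # (y, x)
    end: tuple[float, float]
    step: float  # sampling step in voxels, <= 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 3:
            raise ValueError("a line profile needs at least 3 samples")


@dataclass
class PlateauStats:
    """Plateau means of the three phases and the contrast differences.

    ``A = mean_scaffold - mean_neo`` and ``B = mean_neo - mean_background``,
    so ``A + B`` equals the scaffold-to-background difference exactly, by
    construction.
    """

    mean_background: float
    mean_neo: float
    mean_scaffold: float
    plateau_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def A(self) -> float:
        return self.mean_scaffold - self.mean_neo

    @property
    def B(self) -> float:
        return self.mean_neo - self.mean_background


def extract_line_profile(volume: ImageVolume, slice_index: int,
                         p_start: tuple[float, float],
                         p_end: tuple[float, float]) -> LineProfile:
    """Sample the greyscale along a segment by bilinear interpolation.

    Samples are taken at steps of at most one voxel (exactly one voxel for
    integer-length segments, so axis-aligned profiles reduce to lookups).
    """
    nz, ny, nx = volume.shape
    if not (0 <= slice_index < nz):
        raise IndexError(f"slice {slice_index} out of range [0, {nz})")
    for (y, x) in (p_start, p_end):
        if not (0 <= y <= ny - 1 and 0 <= x <= nx - 1):
            raise ValueError(f"endpoint {(y, x)} outside slice of shape {(ny, nx)}")
    y0, x0 = p_start
    y1, x1 = p_end
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = max(int(np.ceil(length)) + 1, 3)
    t = np.linspace(0.0, 1.0, n)
    coords = np.vstack([y0 + t * (y1 - y0), x0 + t * (x1 - x0)])
    samples = ndimage.map_coordinates(volume.slice(slice_index).astype(float),
                                      coords, order=1, mode="nearest")
    step = length / (n - 1) if n > 1 else 0.0
    return LineProfile(samples=samples, slice_index=slice_index,
                       start=tuple(p_start), end=tuple(p_end), step=step)


def _phase_boundaries(samples: np.ndarray, min_phase_len: int) -> tuple[int, int]:
    """Locate the two phase transitions as maximal-gradient crossings.

    The profile is 3-sample median filtered (removing single-sample spikes)
    and candidate crossings are taken where the absolute gradient reaches
    20% of its maximum (falling back to 10% when fewer than two qualify).
    Among the candidate pairs, the one maximizing the between-segment
    variance of the resulting three segments is chosen — a weak
    background-to-tissue step then cannot be outranked by a strong artifact
    edge inside a phase.
    """
    smooth = ndimage.median_filter(samples, size=3, mode="nearest")
    grad = np.abs(np.diff(smooth))
    gmax = grad.max()
    if gmax == 0:
        raise ValueError("flat profile: no phase transitions found")
    n = smooth.size
    csum = np.concatenate(([0.0], np.cumsum(smooth)))

    def seg_mean(a: int, b: int) -> float:  # samples[a:b]
        return (csum[b] - csum[a]) / (b - a)

    def best_pair(cand: np.ndarray):
        best, best_v = None, -np.inf
        for ii, b1 in enumerate(cand):
            for b2 in cand[ii + 1:]:
                lens = (b1 + 1, b2 - b1, n - b2 - 1)
                if min(lens) < min_phase_len:
                    continue
                means = (seg_mean(0, b1 + 1), seg_mean(b1 + 1, b2 + 1),
                         seg_mean(b2 + 1, n))
                v = sum(l * m * m for l, m in zip(lens, means))
                if v > best_v:
                    best_v, best = v, (int(b1), int(b2))
        return best

    for frac in (0.2, 0.1):
        cand = np.flatnonzero(grad >= frac * gmax)
        pair = best_pair(cand) if cand.size >= 2 else None
        if pair is not None:
            return pair
    if cand.size < 2:
        raise ValueError("fewer than two phase transitions along the profile")
    raise ValueError("phase transitions too close: a phase would be too short")


def detect_plateaus(profile: LineProfile, tolerance_fraction: float = 0.1,
                    min_phase_len: int = 3) -> PlateauStats:
    """Split a profile into three phases and average their plateaus.

    Phase boundaries sit at the two dominant absolute-gradient crossings of
    the median-smoothed profile (a deterministic stand-in for marking the
    transitions by eye). Within each phase the plateau is the set of samples
    within ``tolerance_fraction`` of the phase-median span (the difference
    between the highest and lowest phase median — robust to isolated
    spikes) around the phase median; transition values are thereby excluded
    from the means.

    The three phase means must be monotone along the profile (background ->
    neo-tissue -> scaffold in either direction); anything else raises.
    """
    s = profile.samples
    b1, b2 = _phase_boundaries(s, min_phase_len)
    segments = [(0, b1 + 1), (b1 + 1, b2 + 1), (b2 + 1, s.size)]

    medians = []
    for (a, b) in segments:
        if b - a < min_phase_len:
            raise ValueError("plateau too short")
        medians.append(float(np.median(s[a:b])))
    tol = tolerance_fraction * (max(medians) - min(medians))

    means, ranges = [], []
    for (a, b), med in zip(segments, medians):
        seg = s[a:b]
        plateau = seg[np.abs(seg - med) <= tol]
        if plateau.size < min_phase_len:
            raise ValueError("plateau too short")
        means.append(float(plateau.mean()))
        ranges.append((a, b))

    m0, m1, m2 = means
    if not (m0 < m1 < m2 or m0 > m1 > m2):
        raise ValueError("non-monotone phase ordering along the profile")
    if m0 > m2:  # profile ran scaffold -> background; reorder
        means = means[::-1]
        ranges = ranges[::-1]
    return PlateauStats(mean_background=means[0], mean_neo=means[1],
                        mean_scaffold=means[2],
                        plateau_ranges=tuple(ranges))  # type: ignore[arg-type]


def normalized_contrast(stats: PlateauStats) -> float:
    """``B / (A + B)``: neo-tissue contrast normalized to the full range.

    0 when the tissue greyscale equals background, 1 when it equals the
    scaffold. Raises when the phases are not separable (``A + B <= 0``).
    """
    denom = stats.A + stats.B
    if denom <= 0:
        raise ValueError("phases not separable: scaffold mean <= background mean")
    return stats.B / denom


def auto_profile_lines(volume: ImageVolume, slice_index: int,
                       scaffold_mask: np.ndarray, n_lines: int = 3
                       ) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Choose reproducible profile lines through a slice.

    A manually drawn "arbitrary line" through background, neo-tissue and
    scaffold is not reproducible, so axis-aligned rays are cast from the
    four slice borders along the central row/column towards the center. Each
    ray targets the scaffold strut nearest the slice center and the profile
    runs from the middle of the background gap preceding that strut to the
    strut's far edge — guaranteeing a background -> neo-tissue -> scaffold
    traversal with a usable background plateau on construct geometries. Up
    to ``n_lines`` of the four candidates that cross the scaffold are
    returned.
    """
    nz, ny, nx = volume.shape
    scaf = np.asarray(scaffold_mask, bool)
    if scaf.shape != volume.shape:
        raise ValueError("scaffold mask shape must match the volume")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    sl = scaf[slice_index]
    # axis-aligned rays through the center, crossing the whole slice
    starts = [((1.0, cx), (0, 1.0, 0.0)), ((ny - 2.0, cx), (0, -1.0, 0.0)),
              ((cy, 1.0), (1, 0.0, 1.0)), ((cy, nx - 2.0), (1, 0.0, -1.0))]
    lines: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for (y0, x0), (axis, dy, dx) in starts:
        if len(lines) == n_lines:
            break
        steps = (ny if axis == 0 else nx) - 3
        tt = np.arange(steps + 1, dtype=float)
        ys = y0 + dy * tt
        xs = x0 + dx * tt
        on_scaf = sl[np.rint(ys).astype(int), np.rint(xs).astype(int)]
        hits = np.flatnonzero(on_scaf)
        if hits.size == 0:
            continue
        # scaffold runs along the ray; target the one holding the center so
        # the profile crosses the full strut diameter
        run_starts = hits[np.concatenate(([True], np.diff(hits) > 1))]
        run_ends = hits[np.concatenate((np.diff(hits) > 1, [True]))]
        t_center = abs((cy - y0) if axis == 0 else (cx - x0))
        mid = (run_starts + run_ends) / 2.0
        k = int(np.argmin(np.abs(mid - t_center)))
        a, b = int(run_starts[k]), int(run_ends[k])
        prev_end = int(run_ends[k - 1]) + 1 if k > 0 else 0
        start_idx = (prev_end + a) // 2  # middle of the preceding background gap
        lines.append(((float(ys[start_idx]), float(xs[start_idx])),
                      (float(ys[b]), float(xs[b]))))
    if not lines:
        raise ValueError("no profile line crossing the scaffold found in this slice")
    return lines
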