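"""Per-slice multi-level Otsu segmentation of stained neo-tissue.

Multi-level Otsu partitions the greyscale histogram into ``k`` classes at
``k - 1`` thresholds chosen to maximize the between-class variance
``sum_k w_k (mu_k - mu)^2``. Segmentation is applied to every transaxial
slice independently (per-slice histograms adapt to axial bias), the classes
whose mean greyscale lies between background and scaffold are binarized as
neo-tissue, and the number of Otsu levels is selected per contrast-agent
profile from the mismatched-slice fraction against a reference mask.

Threshold semantics are half-open: class ``k`` holds grey bins ``g`` with
``t_{k-1} < g <= t_k``. Ties in the variance objective are broken by the
lexicographically smallest threshold tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume

__all__ = [
    "GreyHistogram",
    "SegmentationResult",
    "otsu_thresholds",
    "between_class_variance",
    "segment_slice",
    "segment_volume",
    "binarize_neo_tissue",
    "suppress_scaffold",
    "optimize_otsu_levels",
]

logger = logging.getLogger(__name__)

N_BINS = 256  # 8-bit native; deeper data is rebinned to 256 bins


@dataclass
class GreyHistogram:
    """Greyscale histogram on a fixed 256-bin grid."""

    counts: np.ndarray
    bin_edges: np.ndarray  # length N_BINS + 1, in greyscale units

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1D")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be >= 0")
        if self.counts.sum() <= 0:
            raise ValueError("histogram is empty")

    @property
    def n_nonempty(self) -> int:
        return int((self.counts > 0).sum())

    @classmethod
    def from_data(cls, data: np.ndarray,
                  value_range: tuple[float, float] | None = None) -> "GreyHistogram":
        data = np.asarray(data, dtype=float)
        if value_range is None:
            lo, hi = float(data.min()), float(data.max())
            if lo == hi:
                hi = lo + 1.0
        else:
            lo, hi = value_range
        counts, edges = np.histogram(data.ravel(), bins=N_BINS, range=(lo, hi))
        return cls(counts=counts, bin_edges=edges)

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index of each greyscale value (clipped to the grid)."""
        lo, hi = self.bin_edges[0], self.bin_edges[-1]
        width = (hi - lo) / N_BINS
        idx = np.floor((np.asarray(values, float) - lo) / width).astype(np.int64)
        return np.clip(idx, 0, N_BINS - 1)


def _class_sums(counts: np.ndarray):
    """Prefix weights/moments so that w(a, b) = S(a,b)^2 / W(a,b)."""
    vals = np.arange(counts.size, dtype=np.float64)
    cw = np.concatenate(([0.0], np.cumsum(counts.astype(np.float64))))
    cs = np.concatenate(([0.0], np.cumsum(counts * vals)))

    def term(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        w = cw[b] - cw[a]
        s = cs[b] - cs[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
        return out

    return term


def otsu_thresholds(hist: GreyHistogram, n_classes: int) -> tuple[int, ...]:
    """Optimal multi-level Otsu thresholds (bin indices).

    Maximizes the between-class variance over all threshold tuples; class
    ``k`` holds bins ``t_{k-1} < g <= t_k``. k = 2 and 3 use exhaustive
    (vectorized) search over all bin boundaries; k = 4 and 5 use dynamic
    programming over cumulative moments, which returns the same
    lexicographically smallest optimum.
    """
    if not (2 <= n_classes <= 5):
        raise ValueError("n_classes must be between 2 and 5")
    counts = hist.counts
    n = counts.size
    if hist.n_nonempty < n_classes:
        raise ValueError("degenerate histogram: fewer non-empty bins than classes")
    term = _class_sums(counts)

    if n_classes == 2:
        t = np.arange(n - 1)
        v = term(np.zeros_like(t), t + 1) + term(t + 1, np.full_like(t, n))
        return (int(np.argmax(v)),)

    if n_classes == 3:
        t1 = np.arange(n - 2)
        t2 = np.arange(1, n - 1)
        first = term(np.zeros_like(t1), t1 + 1)                     # (n-2,)
        last = term(t2 + 1, np.full_like(t2, n))                    # (n-2,)
        a = np.broadcast_to((t1 + 1)[:, None], (t1.size, t2.size))
        b = np.broadcast_to((t2 + 1)[None, :], (t1.size, t2.size))
        mid = term(a.ravel(), b.ravel()).reshape(t1.size, t2.size)
        v = (first[:, None] + mid) + last[None, :]
        v = np.where(a < b, v, -np.inf)  # require t1 < t2
        i, j = np.unravel_index(np.argmax(v), v.shape)  # row-major: lexicographic
        return (int(t1[i]), int(t2[j]))

    # k = 4, 5: suffix DP. g[c][i] = best score for bins[i:] in c classes.
    k = n_classes
    g = np.empty((k + 1, n + 1))
    choice = np.zeros((k + 1, n + 1), dtype=np.int64)
    idx = np.arange(n + 1)
    g[1] = term(idx, np.full(n + 1, n))
    for c in range(2, k + 1):
        for i in range(n + 1):
            j = np.arange(i + 1, n - (c - 1) + 1)  # split points (start of rest)
            if j.size == 0:
                g[c, i] = -np.inf
                continue
            vals = term(np.full_like(j, i), j) + g[c - 1][j]
            best = int(np.argmax(vals))  # first occurrence -> smallest split
            g[c, i] = vals[best]
            choice[c, i] = j[best]
    ths = []
    i = 0
    for c in range(k, 1, -1):
        j = int(choice[c, i])
        ths.append(j - 1)  # threshold = last bin of the class
        i = j
    return tuple(ths)


def between_class_variance(hist: GreyHistogram, thresholds: tuple[int, ...]) -> float:
    """Between-class variance of a given threshold tuple (bin indices)."""
    counts = hist.counts.astype(np.float64)
    vals = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    mu = (counts * vals).sum() / total
    bounds = [0] + [t + 1 for t in thresholds] + [counts.size]
    var = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        w = counts[a:b].sum()
        if w == 0:
            continue
        mk = (counts[a:b] * vals[a:b]).sum() / w
        var += (w / total) * (mk - mu) ** 2
    return float(var)


@dataclass
class SegmentationResult:
    """Per-slice multi-level Otsu segmentation of a volume."""

    labels: np.ndarray                       # uint8 label volume, values in [0, k)
    thresholds: list[tuple[float, ...] | None]  # per slice, greyscale units
    n_classes: int
    voxel_size_um: float = 3.75


def segment_slice(slice_data: np.ndarray, n_classes: int) -> np.ndarray:
    """Label one slice by its own multi-level Otsu thresholds.

    A constant (or too-degenerate) slice is labeled all-0 with a logged
    warning rather than raising — real stacks contain empty end slices.
    """
    sl = np.asarray(slice_data, dtype=float)
    if sl.min() == sl.max():
        logger.warning("constant slice: labeled all background")
        return np.zeros(sl.shape, dtype=np.uint8)
    hist = GreyHistogram.from_data(sl)
    try:
        ths = otsu_thresholds(hist, n_classes)
    except ValueError as exc:
        logger.warning("slice segmentation degenerate (%s): labeled all background", exc)
        return np.zeros(sl.shape, dtype=np.uint8)
    bins = hist.bin_of(sl)
    return np.searchsorted(np.asarray(ths), bins, side="left").astype(np.uint8)


def _slice_thresholds_grey(sl: np.ndarray, n_classes: int) -> tuple[float, ...] | None:
    sl = np.asarray(sl, dtype=float)
    if sl.min() == sl.max():
        return None
    hist = GreyHistogram.from_data(sl)
    try:
        ths = otsu_thresholds(hist, n_classes)
    except ValueError:
        return None
    return tuple(float(hist.bin_edges[t + 1]) for t in ths)


def segment_volume(volume: ImageVolume, n_classes: int) -> SegmentationResult:
    """Apply :func:`segment_slice` to every transaxial slice independently."""
    labels = np.empty(volume.shape, dtype=np.uint8)
    thresholds: list[tuple[float, ...] | None] = []
    for z in range(volume.n_slices):
        sl = volume.slice(z)
        labels[z] = segment_slice(sl, n_classes)
        thresholds.append(_slice_thresholds_grey(sl, n_classes))
    return SegmentationResult(labels=labels, thresholds=thresholds,
                              n_classes=n_classes,
                              voxel_size_um=volume.voxel_size_um)


def binarize_neo_tissue(result: SegmentationResult,
                        selector: set[int] | None = None) -> np.ndarray:
    """Binarize the segmentation classes corresponding to the neo-tissue.

    Since labels are ordered by greyscale, the default rule selects the
    classes whose mean greyscale lies strictly between the background class
    (label 0) and the scaffold class (label k-1), i.e. labels 1..k-2; for
    k = 2 (scaffold-suppressed volumes) the upper class is the tissue. An
    explicit ``selector`` of label indices overrides the rule; multiple
    qualifying classes are unioned.
    """
    k = result.n_classes
    if selector is None:
        selector = {1} if k == 2 else set(range(1, k - 1))
    else:
        selector = set(int(i) for i in selector)
        if any(i < 0 or i >= k for i in selector):
            raise ValueError(f"selector indices out of range [0, {k})")
    return np.isin(result.labels, sorted(selector))


def suppress_scaffold(volume: ImageVolume, scaffold_mask: np.ndarray,
                      dilation_radius: float = 0.0) -> ImageVolume:
    """Replace (dilated) scaffold voxels by a background-level estimate.

    Used by the two-class contrast-agent profile, where the bright scaffold
    must not claim an Otsu class of its own: after suppression the histogram
    is effectively two-phase (background vs tissue).
    """
    from scipy import ndimage

    mask = np.asarray(scaffold_mask, bool)
    if mask.shape != volume.shape:
        raise ValueError("scaffold mask shape must match the volume")
    if dilation_radius > 0:
        mask = ndimage.distance_transform_edt(~mask) <= dilation_radius
    rest = volume.data[~mask]
    fill = float(np.percentile(rest, 25)) if rest.size else 0.0
    data = volume.data.astype(float).copy()
    data[mask] = fill
    return ImageVolume(data, voxel_size_um=volume.voxel_size_um,
                       bit_depth=volume.bit_depth)


def optimize_otsu_levels(volumes: list[ImageVolume],
                         references: list[np.ndarray],
                         candidate_levels: tuple[int, ...] = (2, 3, 4, 5),
                         mismatch_threshold: float = 0.01,
                         selector: set[int] | None = None):
    """Pick the number of Otsu levels from the mismatched-slice fraction.

    For every candidate level the mismatched-slice fraction (see the dataset
    quality module) against the reference masks is averaged over the given
    volumes. The chosen level is the *smallest* one whose mean fraction lies
    within one standard error of the minimum: extra levels cost processing
    time, so they must buy a real quality improvement.

    Returns ``(chosen_level, mean_fraction_per_level, se_per_level)``.
    """
    from .quality import mismatched_slice_report

    if len(volumes) == 0 or len(volumes) != len(references):
        raise ValueError("need >= 1 volume, each with a reference mask")
    means: dict[int, float] = {}
    ses: dict[int, float] = {}
    for k in candidate_levels:
        fracs = []
        for vol, ref in zip(volumes, references):
            seg = segment_volume(vol, k)
            if all(t is None for t in seg.thresholds):
                continue  # degenerate at this level
            neo = binarize_neo_tissue(seg, selector)
            rep = mismatched_slice_report(ref, neo, threshold=mismatch_threshold)
            fracs.append(rep.mismatched_slice_fraction)
        if not fracs:
            continue
        arr = np.asarray(fracs)
        means[k] = float(arr.mean())
        ses[k] = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    if not means:
        raise ValueError("all candidate levels are degenerate on these volumes")
    best_level = min(means, key=lambda k: (means[k], k))
    cutoff = means[best_level] + ses[best_level]
    chosen = min(k for k in means if means[k] <= cutoff)
    return chosen, means, ses
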