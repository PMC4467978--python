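"""Dataset quality: reference-vs-binarized mismatch scoring per slice.

A segmentation is only usable for quantitative analysis where the binarized
neo-tissue agrees with the stained (reference) neo-tissue. The read-out is
built from a voxelwise differential overlay of the two masks: per slice, the
mismatched area fraction is the share of disagreeing voxels in the full
slice; slices at or above the mismatch threshold (default 1% of the slice
surface — mismatches below 1% are attributed to background noise and
excluded) are flagged, and the headline "dataset quality" statistic is the
fraction of flagged slices in the stack.

The reference mask is an explicit input: ground truth for phantoms, a
user-supplied stained-tissue mask for real scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DifferentialOverlay",
    "MismatchReport",
    "differential_overlay",
    "slice_mismatch_fraction",
    "mismatched_slice_report",
    "flagged_zones",
]


@dataclass
class DifferentialOverlay:
    """Voxelwise ternary agreement map between two binary masks.

    ``+1`` where the reference mask is set but the binarized one is not,
    ``-1`` for the converse, ``0`` where the masks agree (including
    both-empty).
    """

    codes: np.ndarray  # int8 volume in {-1, 0, +1}

    @property
    def shape(self) -> tuple[int, ...]:
        return self.codes.shape

    @property
    def n_reference_only(self) -> int:
        return int((self.codes == 1).sum())

    @property
    def n_binarized_only(self) -> int:
        return int((self.codes == -1).sum())


@dataclass
class MismatchReport:
    """Per-slice mismatch fractions and the flagged-slice summary."""

    slice_fractions: np.ndarray          # mismatched voxels / slice voxels
    flagged_slices: list[int]            # fraction >= threshold
    mismatched_slice_fraction: float     # flagged / total
    threshold: float


def differential_overlay(reference_mask: np.ndarray,
                         binarized_mask: np.ndarray) -> DifferentialOverlay:
    """Ternary overlay of reference vs binarized neo-tissue masks."""
    ref = np.asarray(reference_mask, bool)
    bin_ = np.asarray(binarized_mask, bool)
    if ref.shape != bin_.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {bin_.shape}")
    codes = ref.astype(np.int8) - bin_.astype(np.int8)
    return DifferentialOverlay(codes=codes)


def slice_mismatch_fraction(overlay: DifferentialOverlay, slice_index: int) -> float:
    """Share of disagreeing voxels in one transaxial slice."""
    sl = overlay.codes[slice_index]
    return float(np.count_nonzero(sl) / sl.size)


def mismatched_slice_report(reference_mask: np.ndarray,
                            binarized_mask: np.ndarray,
                            threshold: float = 0.01) -> MismatchReport:
    """Flag slices whose mismatch reaches ``threshold`` of the slice surface.

    The comparison is inclusive: a slice with exactly 1% mismatch is
    flagged (only mismatches strictly below the threshold are excluded as
    background noise).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    overlay = differential_overlay(reference_mask, binarized_mask)
    nz = overlay.codes.shape[0]
    if overlay.codes.size == 0 or nz == 0:
        raise ValueError("empty volume")
    per_slice = np.count_nonzero(overlay.codes.reshape(nz, -1), axis=1) \
        / (overlay.codes[0].size)
    flagged = [int(z) for z in np.flatnonzero(per_slice >= threshold)]
    return MismatchReport(slice_fractions=per_slice.astype(float),
                          flagged_slices=flagged,
                          mismatched_slice_fraction=len(flagged) / nz,
                          threshold=threshold)


def flagged_zones(report: MismatchReport) -> list[tuple[int, int]]:
    """Contiguous runs of flagged slices, as inclusive (start, stop) pairs.

    Purely presentational: mirrors how mismatch zones are reported along the
    construct height.
    """
    zones: list[tuple[int, int]] = []
    for z in report.flagged_slices:
        if zones and z == zones[-1][1] + 1:
            zones[-1] = (zones[-1][0], z)
        else:
            zones.append((z, z))
    return zones
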