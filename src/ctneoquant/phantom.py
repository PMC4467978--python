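"""Synthetic CT-like phantoms of a scaffold + stained neo-tissue construct.

Real contrast-enhanced CT scans of tissue-engineering constructs show three
greyscale phases — dark background, intermediate stained neo-tissue, bright
scaffold — degraded by partial-volume blur, detector noise and metal
artifacts (streaks, beam-hardening bias). No public scan data exists for
such constructs, so this module builds voxel phantoms with the same
statistical structure: a cylindrical domain containing a rectilinear strut
lattice, wrapped in a neo-tissue shell of controllable (possibly sub-voxel)
thickness, plus the degradations above. Ground-truth masks make every
downstream read-out testable.

All randomness flows from the single ``seed`` field of :class:`PhantomSpec`;
two calls with equal specs are bit-identical.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "apply_shrinkage",
    "add_artifacts",
    "render_from_masks",
    "radial_bias_field",
]

#: Supersampling factor per axis used to render sub-voxel shell occupancy
#: when partial-volume blur is requested.
SUPERSAMPLE = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic construct.

    Greyscale means are in arbitrary reconstruction units and must satisfy
    ``mu_background < mu_neo < mu_scaffold``. ``neo_shell_thickness_vox``
    controls the neo-tissue volume level and may be fractional: thicknesses
    near 2-3 voxels emulate tissue near the spatial resolution limit of the
    scans (2-3x the voxel size), where the partial-volume effect degrades
    segmentation.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 3.75
    scaffold_pitch_vox: int = 24
    strut_radius_vox: int = 3
    neo_shell_thickness_vox: float = 3.0
    mu_background: float = 20.0
    mu_neo: float = 120.0
    mu_scaffold: float = 220.0
    psf_sigma_vox: float = 0.0
    noise_sigma: float = 0.0
    streak_amplitude: float = 0.0
    bias_amplitude: float = 0.0
    shrinkage_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive extents")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if not (self.mu_background < self.mu_neo < self.mu_scaffold):
            raise ValueError("greyscale means must satisfy background < neo < scaffold")
        if self.scaffold_pitch_vox <= 0 or self.strut_radius_vox <= 0:
            raise ValueError("lattice pitch and strut radius must be positive")
        if self.neo_shell_thickness_vox <= 0:
            raise ValueError("neo shell thickness must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        for name in ("psf_sigma_vox", "noise_sigma", "streak_amplitude", "bias_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.shrinkage_fraction < 1.0):
            raise ValueError("shrinkage_fraction must lie in [0, 1)")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["shape"] = list(d["shape"])
        return yaml.safe_dump({"phantom": d}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(io.StringIO(text))
        if isinstance(d, dict) and "phantom" in d:
            d = d["phantom"]
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class PhantomOutput:
    """A rendered phantom: greyscale volume plus ground-truth masks.

    ``scaffold_mask`` and ``neo_mask`` are disjoint and derived from the
    pre-blur phase occupancy (a voxel belongs to a phase when its occupancy
    is >= 0.5), so they are the reference against which segmentation quality
    is scored.
    """

    volume: ImageVolume
    scaffold_mask: np.ndarray
    neo_mask: np.ndarray
    metadata: PhantomSpec


def _folded_distance(coords: np.ndarray, pitch: float) -> np.ndarray:
    """Distance from each coordinate to the nearest multiple of ``pitch``."""
    u = np.mod(coords, pitch)
    return np.minimum(u, pitch - u)


def _phase_labels(spec: PhantomSpec, factor: int) -> np.ndarray:
    """Phase id per (super)voxel: 0 background, 1 neo shell, 2 scaffold.

    The scaffold is a rectilinear lattice of cylindrical struts along all
    three axes, clipped to a cylindrical construct envelope; the neo shell
    is the set of points within ``neo_shell_thickness_vox`` of a strut
    surface.
    """
    nz, ny, nx = spec.shape
    p = float(spec.scaffold_pitch_vox)
    # supersampled coordinates in voxel units, centered on voxel centers
    zc = (np.arange(nz * factor, dtype=np.float32) + 0.5) / factor - 0.5
    yc = (np.arange(ny * factor, dtype=np.float32) + 0.5) / factor - 0.5
    xc = (np.arange(nx * factor, dtype=np.float32) + 0.5) / factor - 0.5
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0

    # in-plane strut layers sit half a pitch off the stack center, keeping
    # the central and quartile slice heights at pore level
    fz = _folded_distance(zc - cz - p / 2.0, p)[:, None, None]
    fy = _folded_distance(yc - cy, p)[None, :, None]
    fx = _folded_distance(xc - cx, p)[None, None, :]

    # distance to nearest strut axis, per strut orientation, then overall
    d = np.hypot(fy, fx)  # struts parallel to z -> (1, ny, nx)
    d = np.broadcast_to(d, (nz * factor, ny * factor, nx * factor)).copy()
    np.minimum(d, np.hypot(fz, fx), out=d)  # struts parallel to y
    np.minimum(d, np.hypot(fz, fy), out=d)  # struts parallel to x

    r_cyl = min(ny, nx) / 2.0 - 1.0
    in_cyl = (yc[None, :, None] - cy) ** 2 + (xc[None, None, :] - cx) ** 2 <= r_cyl**2
    in_cyl = np.broadcast_to(in_cyl, d.shape)

    labels = np.zeros(d.shape, dtype=np.uint8)
    labels[in_cyl & (d <= spec.strut_radius_vox)] = 2
    labels[in_cyl & (d > spec.strut_radius_vox)
           & (d <= spec.strut_radius_vox + spec.neo_shell_thickness_vox)] = 1
    return labels


def _occupancies(labels: np.ndarray, factor: int, shape: tuple[int, int, int]):
    """Per-voxel occupancy of the neo and scaffold phases (box average)."""
    nz, ny, nx = shape
    if factor == 1:
        return (labels == 1).astype(np.float32), (labels == 2).astype(np.float32)
    view = labels.reshape(nz, factor, ny, factor, nx, factor)
    occ_neo = (view == 1).mean(axis=(1, 3, 5), dtype=np.float32)
    occ_scaf = (view == 2).mean(axis=(1, 3, 5), dtype=np.float32)
    return occ_neo, occ_scaf


def generate_phantom(spec: PhantomSpec, neo_concentration: float = 1.0) -> PhantomOutput:
    """Render a phantom volume with ground-truth masks.

    ``neo_concentration`` scales the neo-tissue greyscale elevation above
    background (emulating contrast-agent concentration): the effective
    neo-tissue mean is ``mu_background + c * (mu_neo - mu_background)``.

    Raises
    ------
    ValueError
        If the neo shell floods the whole construct interior ("phantom
        saturated") or the effective neo mean leaves the
        background < neo < scaffold ordering.
    """
    if neo_concentration <= 0:
        raise ValueError("neo_concentration must be positive")
    mu_neo_eff = spec.mu_background + neo_concentration * (spec.mu_neo - spec.mu_background)
    if not (spec.mu_background < mu_neo_eff < spec.mu_scaffold):
        raise ValueError("effective neo-tissue mean must stay between background and scaffold")

    factor = SUPERSAMPLE if spec.psf_sigma_vox > 0 else 1
    labels = _phase_labels(spec, factor)
    occ_neo, occ_scaf = _occupancies(labels, factor, spec.shape)
    del labels

    # saturation: no background voxel remains strictly inside the cylinder
    nz, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_cyl = min(ny, nx) / 2.0 - 1.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    interior = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_cyl - 1.0) ** 2
    bg_occ = 1.0 - occ_neo - occ_scaf
    if interior.any() and not (bg_occ[:, interior] >= 0.5).any():
        raise ValueError("phantom saturated: neo-tissue shell fills the construct")

    grey = (spec.mu_background * bg_occ
            + mu_neo_eff * occ_neo
            + spec.mu_scaffold * occ_scaf).astype(np.float64)

    scaffold_mask = occ_scaf >= 0.5
    neo_mask = (occ_neo >= 0.5) & ~scaffold_mask

    if spec.psf_sigma_vox > 0:
        grey = ndimage.gaussian_filter(grey, spec.psf_sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
        grey = grey + rng.normal(0.0, spec.noise_sigma, size=grey.shape)

    vol = ImageVolume(grey, voxel_size_um=spec.voxel_size_um, bit_depth=16)
    if spec.streak_amplitude > 0 or spec.bias_amplitude > 0:
        vol = add_artifacts(vol, spec)
    return PhantomOutput(volume=vol, scaffold_mask=scaffold_mask,
                         neo_mask=neo_mask, metadata=spec)


def radial_bias_field(shape_yx: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth beam-hardening-like bias: a radially increasing quadratic.

    ``b(y, x) = amplitude * (r / r_max)**2`` with ``r`` the distance from
    the slice center and ``r_max`` the corner distance, so the bias spans
    [0, amplitude] over the slice.
    """
    ny, nx = shape_yx
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2_max = cy**2 + cx**2
    if r2_max == 0:
        return np.zeros(shape_yx)
    return amplitude * r2 / r2_max


def _lattice_nodes(spec: PhantomSpec) -> np.ndarray:
    """(y, x) positions of strut-lattice nodes inside the cylinder."""
    _, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_cyl = min(ny, nx) / 2.0 - 1.0
    p = spec.scaffold_pitch_vox
    ks = np.arange(-(max(ny, nx) // p + 1), max(ny, nx) // p + 2)
    nodes = []
    for i in ks:
        for j in ks:
            y, x = cy + i * p, cx + j * p
            if 0 <= y < ny and 0 <= x < nx and (y - cy) ** 2 + (x - cx) ** 2 <= r_cyl**2:
                nodes.append((y, x))
    return np.array(nodes) if nodes else np.array([[cy, cx]])


def add_artifacts(volume: ImageVolume, spec: PhantomSpec,
                  bias_field: np.ndarray | None = None) -> ImageVolume:
    """Add metal-artifact-like degradations: streak rays and a radial bias.

    Streaks are straight in-plane rays seeded at scaffold-lattice corners
    with alternating sign (the first ray is bright, carrying the full
    amplitude at its seed) and linear radial decay; ray directions are drawn
    per slice, so the mismatch they induce varies along the construct
    height. The bias field is the radially increasing quadratic of
    :func:`radial_bias_field`, identical in every slice. Zero amplitudes
    return the input unchanged.
    """
    nz, ny, nx = volume.shape
    if bias_field is not None and bias_field.shape != (ny, nx):
        raise ValueError(
            f"bias field shape {bias_field.shape} does not match slice shape {(ny, nx)}")
    if spec.streak_amplitude == 0 and spec.bias_amplitude == 0:
        return volume

    data = volume.data.astype(np.float64).copy()

    if spec.streak_amplitude > 0:
        nodes = _lattice_nodes(spec)
        length = min(ny, nx) / 2.0
        t = np.arange(0.0, length, 0.5)
        for z in range(nz):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, z]))
            plane = np.zeros((ny, nx), dtype=np.float64)
            sign = 1.0
            for (y0, x0) in nodes:
                for _ in range(2):
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    ys = np.rint(y0 + t * np.sin(theta)).astype(int)
                    xs = np.rint(x0 + t * np.cos(theta)).astype(int)
                    inside = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
                    yv, xv, tv = ys[inside], xs[inside], t[inside]
                    # keep the first (closest-to-seed) sample per voxel
                    _, first = np.unique(yv * nx + xv, return_index=True)
                    value = sign * spec.streak_amplitude * (1.0 - tv[first] / length)
                    ray = np.zeros_like(plane)
                    ray[yv[first], xv[first]] = value
                    # a voxel crossed by several rays keeps the strongest one
                    plane = np.where(np.abs(ray) > np.abs(plane), ray, plane)
                    sign = -sign
            data[z] += plane

    if spec.bias_amplitude > 0:
        data += (bias_field if bias_field is not None
                 else radial_bias_field((ny, nx), spec.bias_amplitude))[None, :, :]

    return ImageVolume(data, voxel_size_um=volume.voxel_size_um,
                       bit_depth=volume.bit_depth)


def render_from_masks(scaffold_mask: np.ndarray, neo_mask: np.ndarray,
                      spec: PhantomSpec, neo_concentration: float = 1.0,
                      noise_stream: int = 2) -> ImageVolume:
    """Render a greyscale volume from explicit phase masks.

    Used to image the *same* construct under a second stain condition (e.g.
    after applying :func:`apply_shrinkage` to the neo-tissue mask): the
    geometry comes from the masks, while blur, noise and artifacts follow
    ``spec``. ``noise_stream`` decorrelates the noise from the first
    rendering of the same seed.
    """
    scaf = np.asarray(scaffold_mask, bool)
    neo = np.asarray(neo_mask, bool) & ~scaf
    if scaf.shape != tuple(spec.shape):
        raise ValueError("mask shape does not match spec shape")
    mu_neo_eff = spec.mu_background + neo_concentration * (spec.mu_neo - spec.mu_background)
    grey = np.full(scaf.shape, spec.mu_background, dtype=np.float64)
    grey[neo] = mu_neo_eff
    grey[scaf] = spec.mu_scaffold
    if spec.psf_sigma_vox > 0:
        grey = ndimage.gaussian_filter(grey, spec.psf_sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, noise_stream]))
        grey = grey + rng.normal(0.0, spec.noise_sigma, size=grey.shape)
    vol = ImageVolume(grey, voxel_size_um=spec.voxel_size_um, bit_depth=16)
    if spec.streak_amplitude > 0 or spec.bias_amplitude > 0:
        vol = add_artifacts(vol, spec)
    return vol


def apply_shrinkage(mask: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Shrink a binary mask to ``(1 - fraction)`` of its voxel count.

    Emulates stain-induced tissue shrinkage for parameter-recovery tests:
    the mask is iteratively eroded (6-connected) and, on the final step,
    randomly chosen boundary voxels are removed so the target count is hit
    exactly (well within the +/-0.5% contract). The random trim is drawn
    from a spatially smoothed random field, so it carves coherent shallow
    patches (as physical shrinkage does) rather than salt-and-pepper pits
    that a later morphological closing would simply refill. The result is
    always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    n0 = int(mask.sum())
    if n0 == 0:
        raise ValueError("mask is empty")
    target = int(round((1.0 - fraction) * n0))
    out = mask.copy()
    if target == n0:
        return out

    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    rng = np.random.default_rng(seed)
    while int(out.sum()) > target:
        eroded = ndimage.binary_erosion(out, structure=structure, border_value=0)
        if int(eroded.sum()) >= target:
            out = eroded
            continue
        # final step: trim boundary voxels down to the target, preferring
        # spatially coherent patches (smoothed random priority field)
        boundary = out & ~eroded
        need = int(out.sum()) - target
        idx = np.flatnonzero(boundary.ravel())
        if len(idx) == 0:  # single-layer remnant: erosion empties it
            idx = np.flatnonzero(out.ravel())
        field = ndimage.gaussian_filter(
            rng.standard_normal(out.shape), sigma=2.0).ravel()[idx]
        drop = idx[np.argsort(field)[::-1][:min(need, len(idx))]]
        out_flat = out.ravel()
        out_flat[drop] = False
        out = out_flat.reshape(mask.shape)
    return out
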