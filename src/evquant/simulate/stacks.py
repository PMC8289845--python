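"""Synthetic multi-channel image stacks with planted compartment overlap.

Compartments are rendered as solid spheres of known voxel support placed
uniformly inside the stack.  A configurable fraction of channel-2 (and
channel-3) compartments is centered on channel-1 compartments, sharing radius
and amplitude, so that with ``overlap_fraction = 1`` and zero noise the
channels are voxel-identical; with ``overlap_fraction = 0`` the supports are
disjoint by construction (rejection-sampled placement).

The exact boolean sphere masks are returned alongside the intensity stack,
and the ground truth records the voxel-count overlap fractions computed
directly from those masks — the oracle for Mander's-coefficient recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ImageSimConfig:
    shape: tuple[int, int, int] = (8, 128, 128)  # (z, y, x)
    pixel_size: float = 0.1  # length units per pixel
    n_timepoints: int = 1
    n_channels: int = 2
    n_compartments: int = 40
    radius_range: tuple[float, float] = (2.0, 4.0)
    overlap_fraction: float = 0.5
    background: float = 5.0
    noise_sd: float = 1.0
    amplitude_range: tuple[float, float] = (80.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.n_channels not in (2, 3):
            raise ValueError("n_channels must be 2 or 3")
        rmin, rmax = self.radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("invalid radius_range")
        if 2 * rmax >= min(self.shape[1], self.shape[2]):
            raise ValueError("compartment radius larger than image extent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_compartments < 1:
            raise ValueError("n_compartments must be >= 1")


def _sphere_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2


def _place_disjoint(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    radius: float,
    avoid: list[tuple[np.ndarray, float]],
    max_tries: int = 500,
) -> np.ndarray:
    """Uniform center at least (r_i + r_j + 1) away from every sphere in avoid."""
    lo = np.array([0.0, radius, radius])
    hi = np.array([shape[0] - 1.0, shape[1] - 1 - radius, shape[2] - 1 - radius])
    for _ in range(max_tries):
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - c0) > radius + r0 + 1.0 for c0, r0 in avoid):
            return c
    raise RuntimeError(
        "could not place a non-overlapping compartment; reduce n_compartments "
        "or radius_range"
    )


def gen_coloc_stack(
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate intensity stack, boolean masks and overlap ground truth.

    Returns
    -------
    stack : float ndarray, shape (t, channel, z, y, x)
        Sphere amplitudes + background + Gaussian noise, clipped at 0.
    masks : bool ndarray, shape (t, channel, z, y, x)
        Exact voxel support of the planted spheres per channel.
    truth : DataFrame
        One row per (timepoint, ordered channel pair): voxel-overlap fraction
        |m_i & m_j| / |m_i| plus per-channel compartment and voxel counts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t_, nc, (nz, ny, nx) = cfg.n_timepoints, cfg.n_channels, cfg.shape
    stack = np.zeros((t_, nc, nz, ny, nx), dtype=float)
    masks = np.zeros((t_, nc, nz, ny, nx), dtype=bool)
    truth_rows = []

    n_overlap = int(round(cfg.overlap_fraction * cfg.n_compartments))
    for t in range(t_):
        # channel 1 spheres
        ch1: list[tuple[np.ndarray, float, float]] = []  # (center, radius, amp)
        placed: list[tuple[np.ndarray, float]] = []
        for _ in range(cfg.n_compartments):
            r = rng.uniform(*cfg.radius_range)
            c = _place_disjoint(rng, cfg.shape, r, placed)
            a = rng.uniform(*cfg.amplitude_range)
            ch1.append((c, r, a))
            placed.append((c, r))
        per_channel = {0: ch1}
        for ch in range(1, nc):
            spheres: list[tuple[np.ndarray, float, float]] = []
            # shared compartments reuse center, radius and amplitude
            for c, r, a in ch1[:n_overlap]:
                spheres.append((c, r, a))
            for _ in range(cfg.n_compartments - n_overlap):
                r = rng.uniform(*cfg.radius_range)
                c = _place_disjoint(rng, cfg.shape, r, placed)
                a = rng.uniform(*cfg.amplitude_range)
                spheres.append((c, r, a))
                placed.append((c, r))
            per_channel[ch] = spheres

        for ch, spheres in per_channel.items():
            img = np.zeros((nz, ny, nx), dtype=float)
            m = np.zeros((nz, ny, nx), dtype=bool)
            for c, r, a in spheres:
                sm = _sphere_mask(cfg.shape, c, r)
                img[sm] = np.maximum(img[sm], a)
                m |= sm
            img += cfg.background
            if cfg.noise_sd > 0:
                img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
            stack[t, ch] = np.clip(img, 0.0, None)
            masks[t, ch] = m

        for i in range(nc):
            for j in range(nc):
                if i == j:
                    continue
                mi, mj = masks[t, i], masks[t, j]
                ni = int(mi.sum())
                frac = float((mi & mj).sum() / ni) if ni else np.nan
                truth_rows.append(
                    {
                        "timepoint": t,
                        "channel_i": i,
                        "channel_j": j,
                        "overlap_fraction": frac,
                        "voxels_i": ni,
                        "n_compartments_i": cfg.n_compartments,
                    }
                )

    truth = pd.DataFrame(truth_rows)
    return stack, masks, truth
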