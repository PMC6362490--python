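"""Synthetic resting-state cohorts with planted local-correlation hubs.

Each subject is a 4D volume of unit-variance AR(1) noise in which spherical
"hub" regions carry a shared band-limited (0.01–0.08 Hz) latent signal, and
every voxel additionally carries a weak brain-wide "global" fluctuation — the
physiological signal that global-signal regression removes in real data. A
hub voxel with effective coupling ``c`` and global amplitude ``g`` receives

    g * G(t) + c * L_h(t) + sqrt(1 - g^2 - c^2) * eps_v(t),

while non-hub voxels get ``g * G(t) + sqrt(1 - g^2) * eps_v(t)``. With the
global component at zero, two hub voxels with couplings c_i, c_j have
expected raw correlation c_i * c_j (c^2 for a homogeneous hub). Without a
global component, the mask-mean series of a small grid is dominated by the
hub latent itself and global-signal regression would cancel the very
coupling being planted — the opposite of its effect on real brains, where
the global signal is carried by the whole mask.

The voxel noise ``eps_v`` is unit-variance AR(1) in time and, by default,
weakly correlated in space (a small Gaussian point-spread, as produced by
EPI acquisition and physiological structure). The spatial correlation gives
the lFCD map a positive noise floor everywhere, like real data; with
spatially independent noise, most background voxels would have lFCD exactly
zero in every subject and downstream group statistics would degenerate.
The coupling is

    c = clamp(base + group_effect * [group == "top"] + slope * z, 0, 1)

where ``z`` is the subject's rank level standardized within its group's rank
range — the covariate effect therefore expresses within-group expertise
variation and leaves the group contrast driven by ``group_effect`` alone.
Everything is deterministic given ``(design.seed, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groupstats import Cohort
from .preprocess import bandpass_series
from .volumeio import BrainMask, FunctionalImage

#: rank-level sampling ranges (uniform) per group, on a fixed 0–100 scale.
RANK_RANGES = {"top": (70.0, 95.0), "lower": (35.0, 60.0)}


@dataclass
class Hub:
    """A spherical hub: voxels within ``radius`` (Euclidean, voxels) of ``center``."""

    center: tuple[int, int, int]
    radius: float
    base_coupling: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_coupling <= 1.0:
            raise ValueError("base_coupling must lie in [0, 1]")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


def _default_hubs() -> list[Hub]:
    return [Hub(center=(8, 8, 8), radius=3.0, base_coupling=0.45)]


@dataclass
class SynthDesign:
    """Cohort-level simulation parameters.

    Defaults mirror a typical single-site resting-state acquisition
    (TR 2 s, 255 volumes) on a reduced 16^3 grid of 3 mm voxels, with one
    central hub of radius 3 and a moderate group effect on coupling.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    t_volumes: int = 255
    tr_sec: float = 2.0
    voxel_size_mm: float = 3.0
    hubs: list[Hub] = field(default_factory=_default_hubs)
    group_effect: float = 0.3
    covariate_slope: float = 0.0
    noise_ar1: float = 0.3
    global_amp: float = 0.3
    noise_spatial_fwhm_vox: float = 1.4
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_volumes < 30:
            raise ValueError("t_volumes must be >= 30")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if not 0.0 <= self.global_amp < 1.0:
            raise ValueError("global_amp must lie in [0, 1)")
        if self.noise_spatial_fwhm_vox < 0:
            raise ValueError("noise_spatial_fwhm_vox must be >= 0")
        shape = np.asarray(self.grid_shape)
        masks = [self._hub_voxels(h) for h in self.hubs]
        for h, hm in zip(self.hubs, masks):
            c = np.asarray(h.center)
            if (c < 0).any() or (c >= shape).any():
                raise ValueError(f"hub center {h.center} lies outside the grid")
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    raise ValueError("overlapping hubs are not supported")

    def _hub_voxels(self, hub: Hub) -> np.ndarray:
        grid = np.indices(self.grid_shape)
        d2 = sum((grid[a] - hub.center[a]) ** 2 for a in range(3))
        return d2 <= hub.radius**2

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def hub_mask(self) -> np.ndarray:
        """Ground-truth binary mask: union of all hub spheres."""
        out = np.zeros(self.grid_shape, dtype=bool)
        for h in self.hubs:
            out |= self._hub_voxels(h)
        return out

    def brain_mask(self) -> BrainMask:
        """Whole-grid analysis mask on the design's affine."""
        return BrainMask(data=np.ones(self.grid_shape, dtype=bool), affine=self.affine)


def standardized_rank(group: str, rank_level: float) -> float:
    """Rank level standardized within its group's uniform sampling range."""
    lo, hi = RANK_RANGES[group]
    sd = (hi - lo) / np.sqrt(12.0)
    return (rank_level - (lo + hi) / 2.0) / sd


def _ar1_noise(
    rng: np.random.Generator, shape: tuple, t: int, phi: float, spatial_fwhm_vox: float = 0.0
) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis.

    ``spatial_fwhm_vox > 0`` convolves each frame with a periodic Gaussian of
    that width (variance-renormalized), yielding stationary spatially
    correlated noise.
    """
    w = rng.standard_normal(shape + (t,))
    if spatial_fwhm_vox > 0:
        from scipy import ndimage

        sigma = spatial_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        impulse = np.zeros(shape)
        impulse[tuple(s // 2 for s in shape)] = 1.0
        kernel = ndimage.gaussian_filter(impulse, sigma=sigma, mode="wrap")
        scale = np.sqrt((kernel**2).sum())
        w = ndimage.gaussian_filter(w, sigma=(sigma,) * len(shape) + (0.0,), mode="wrap") / scale
    if phi == 0.0:
        return w
    x = np.empty_like(w)
    x[..., 0] = w[..., 0]
    gain = np.sqrt(1.0 - phi * phi)
    for k in range(1, t):
        x[..., k] = phi * x[..., k - 1] + gain * w[..., k]
    return x


def _band_limited_latent(rng: np.random.Generator, t: int, tr: float, low: float, high: float) -> np.ndarray:
    """Unit-variance latent series with power confined to [low, high] Hz."""
    x = bandpass_series(rng.standard_normal(t), tr, low, high)
    sd = x.std()
    if sd <= 0:  # pragma: no cover - requires a degenerate band
        raise ValueError("latent series is degenerate; widen the passband")
    return (x - x.mean()) / sd


def effective_coupling(design: SynthDesign, hub: Hub, group: str, rank_level: float) -> float:
    """Per-subject hub coupling, clamped so total signal variance stays 1.

    The clamp is ``[0, sqrt(1 - global_amp^2)]`` (plain ``[0, 1]`` when no
    global component is simulated).
    """
    z = standardized_rank(group, rank_level)
    c = hub.base_coupling + design.group_effect * (group == "top") + design.covariate_slope * z
    c_max = float(np.sqrt(1.0 - design.global_amp**2))
    return float(np.clip(c, 0.0, c_max))


def simulate_subject(
    design: SynthDesign, group: str, rank_level: float, subject_seed: int
) -> FunctionalImage:
    """One subject's 4D volume; deterministic given (design.seed, subject_seed)."""
    if group not in RANK_RANGES:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([design.seed, subject_seed])
    latents = [
        _band_limited_latent(rng, design.t_volumes, design.tr_sec, design.band_low_hz, design.band_high_hz)
        for _ in design.hubs
    ]
    g_amp = design.global_amp
    g_series = (
        g_amp
        * _band_limited_latent(rng, design.t_volumes, design.tr_sec, design.band_low_hz, design.band_high_hz)
        if g_amp > 0
        else 0.0
    )
    data = _ar1_noise(
        rng,
        tuple(design.grid_shape),
        design.t_volumes,
        design.noise_ar1,
        design.noise_spatial_fwhm_vox,
    )
    data *= np.sqrt(1.0 - g_amp**2)
    for hub, latent in zip(design.hubs, latents):
        c = effective_coupling(design, hub, group, rank_level)
        hv = design._hub_voxels(hub)
        # hub voxels: rescale the voxel-specific noise so variance stays unit
        noise_scale = np.sqrt(max(1.0 - g_amp**2 - c * c, 0.0) / (1.0 - g_amp**2))
        data[hv] = c * latent + noise_scale * data[hv]
    data += g_series
    return FunctionalImage(data=data, affine=design.affine, tr_sec=design.tr_sec)


@dataclass
class SynthCohort:
    """A simulated cohort: table + raw images + analysis mask + ground truth."""

    table: pd.DataFrame
    images: list[FunctionalImage]
    mask: BrainMask
    truth_hub_mask: np.ndarray

    def cohort(self, maps: np.ndarray) -> Cohort:
        """Bundle per-subject derived maps with the table for inference."""
        return Cohort(table=self.table, maps=maps)


def simulate_cohort(design: SynthDesign, n_top: int, n_lower: int) -> SynthCohort:
    """Simulate ``n_top`` expert and ``n_lower`` comparison subjects.

    Rank levels are drawn uniformly from each group's fixed range; subject
    seeds are consecutive integers so the cohort is reproducible from
    ``design.seed`` alone.
    """
    if n_top < 1 or n_lower < 1:
        raise ValueError("each group needs at least one subject")
    rng = np.random.default_rng([design.seed, 999_983])  # rank-level stream
    rows = []
    images = []
    subject_seed = 0
    for group, n in (("top", n_top), ("lower", n_lower)):
        lo, hi = RANK_RANGES[group]
        ranks = rng.uniform(lo, hi, size=n)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            rows.append({"subject_id": sid, "group": group, "rank_level": float(ranks[i])})
            images.append(simulate_subject(design, group, float(ranks[i]), subject_seed))
            subject_seed += 1
    return SynthCohort(
        table=pd.DataFrame(rows),
        images=images,
        mask=design.brain_mask(),
        truth_hub_mask=design.hub_mask(),
    )
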