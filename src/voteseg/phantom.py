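"""Synthetic dental CBCT phantoms and controllably degraded predictions.

The phantom emulates the gross intensity structure of a maxillofacial
CBCT at isotropic 0.19 mm voxels: an air background, a soft-tissue block,
a parabolic bone arch in the axial plane, and a row of tooth units along
the arch, each an enamel crown (ellipsoid) over a dentin root (cylinder).
Gaussian read-out noise is additive; the ground-truth mask marks exactly
the tooth voxels and is noise-free.  Optional metal voxels adjacent to
crowns emulate restorations for the metallic-burden screen.

Degraded predictions model the error modes a single segmentation network
shows on such data: small round false-positive speckles scattered over
tooth-free regions, partial false-negative erosion of tooth components,
and a ragged boundary.  A prediction *set* draws one degraded mask per
voter; an inter-voter correlation knob mixes a shared error field with
voter-private fields so that rho = 0 gives independent errors and
rho = 1 identical ones.

The phantom is a geometric test-bed, not an anatomical model: it has no
beam hardening, streaks, cone-beam artifacts or realistic tooth shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .io_preprocess import DEFAULT_SPACING, BinaryMask, Volume
from .morphology import StructuringElement, dilate

#: nominal HU of each tissue class
DEFAULT_INTENSITIES = {
    "air": -1000.0,
    "soft": 50.0,
    "bone": 1200.0,
    "dentin": 2000.0,
    "enamel": 2800.0,
    "metal": 3100.0,
}


@dataclass
class PhantomConfig:
    """Geometry, intensities and noise of the synthetic head volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_teeth: int = 6
    crown_semiaxes: tuple[float, float, float] = (3.0, 3.0, 4.0)  # voxels
    root_radius: float = 2.0
    root_length: int = 6
    intensities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sd: float = 30.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        order = ("air", "soft", "bone", "dentin", "enamel", "metal")
        vals = [self.intensities[k] for k in order]
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ConfigError(
                "intensities must be ordered air < soft < bone < dentin "
                "< enamel < metal"
            )
        if self.n_teeth < 0 or self.noise_sd < 0:
            raise ConfigError("n_teeth and noise_sd must be non-negative")


@dataclass
class DegradationConfig:
    """Error structure of a simulated single-model prediction."""

    fp_speckle_rate: float = 0.5  # expected speckles per axial slice
    speckle_radius: int = 1  # ball radius in voxels (7 voxels at r=1)
    fn_component_drop: float = 0.1  # P(partially erode a tooth component)
    boundary_jitter: int = 1  # half-width of the ragged-boundary band
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_component_drop <= 1.0:
            raise ConfigError("fn_component_drop must be a probability")
        if self.fp_speckle_rate < 0 or self.speckle_radius < 1:
            raise ConfigError("speckle rate must be >= 0 and radius >= 1")
        if self.boundary_jitter < 0:
            raise ConfigError("boundary_jitter must be >= 0")


def make_phantom(cfg: PhantomConfig) -> tuple[Volume, BinaryMask]:
    """Build the dental-arch phantom and its noise-free tooth mask."""
    nx, ny, nz = cfg.shape
    hu = cfg.intensities
    rng = np.random.default_rng(cfg.seed)

    data = np.full(cfg.shape, hu["air"], dtype=float)
    # soft-tissue block occupying the lower two thirds of y
    data[:, : int(ny * 2 / 3), :] = hu["soft"]

    xs = np.arange(nx)[:, None, None]
    ys = np.arange(ny)[None, :, None]
    zs = np.arange(nz)[None, None, :]

    # parabolic bone arch in the axial plane, extruded over a z slab
    apex_y = 0.15 * ny
    curv = 0.35 * ny / max((nx / 2.0) ** 2, 1.0)
    arch_y = apex_y + curv * (xs - nx / 2.0) ** 2
    band = np.abs(ys - arch_y) <= max(2.0, 0.06 * ny)
    z_lo, z_hi = int(0.25 * nz), int(0.75 * nz)
    bone = band & (zs >= z_lo) & (zs < z_hi)
    data[bone] = hu["bone"]

    # tooth units spaced along the arch
    mask = np.zeros(cfg.shape, dtype=bool)
    ax, ay, az = cfg.crown_semiaxes
    for t in range(cfg.n_teeth):
        fx = (t + 1) / (cfg.n_teeth + 1)
        cx = fx * (nx - 1)
        cy = float(apex_y + curv * (cx - nx / 2.0) ** 2)
        crown_z = z_lo + cfg.root_length + int(az)
        _check_fits(cfg, cx, cy, crown_z)

        crown = (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - crown_z) / az) ** 2
        ) <= 1.0
        root = (
            ((xs - cx) ** 2 + (ys - cy) ** 2 <= cfg.root_radius**2)
            & (zs >= crown_z - int(az) - cfg.root_length)
            & (zs < crown_z - int(az) + 1)
        )
        data[root] = hu["dentin"]
        data[crown] = hu["enamel"]
        mask |= crown | root

    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    return Volume(data=data, spacing=cfg.spacing), BinaryMask(
        data=mask, spacing=cfg.spacing
    )


def _check_fits(cfg: PhantomConfig, cx: float, cy: float, crown_z: int) -> None:
    ax, ay, az = cfg.crown_semiaxes
    nx, ny, nz = cfg.shape
    root_top = crown_z - int(az) + 1
    if (
        cx - ax < 0 or cx + ax >= nx
        or cy - ay < 0 or cy + ay >= ny
        or crown_z + az >= nz
        or root_top - cfg.root_length - 1 < 0
    ):
        raise ConfigError(
            f"tooth geometry at ({cx:.1f}, {cy:.1f}, {crown_z}) overflows "
            f"shape {cfg.shape}"
        )


def add_metal(vol: Volume, n_voxels: int, seed: int = 0) -> Volume:
    """Plant metal-density voxels adjacent to crowns (enamel-dense regions).

    Candidates are sub-enamel voxels within two voxels of any voxel at or
    above enamel density, so restorations sit on or beside crowns.
    """
    if n_voxels < 0:
        raise ConfigError("n_voxels must be >= 0")
    if n_voxels == 0:
        return Volume(data=vol.data.copy(), spacing=vol.spacing)
    enamel_hu = DEFAULT_INTENSITIES["enamel"]
    metal_hu = DEFAULT_INTENSITIES["metal"]
    crowns = vol.data >= enamel_hu
    shell = ndimage.binary_dilation(
        crowns, structure=StructuringElement(2).footprint
    ) & ~crowns
    idx = np.flatnonzero(shell)
    if idx.size < n_voxels:
        raise ConfigError(
            f"only {idx.size} crown-adjacent voxels available, need {n_voxels}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_voxels, replace=False)
    out = vol.data.copy()
    out.flat[chosen] = metal_hu
    return Volume(data=out, spacing=vol.spacing)


# ---------------------------------------------------------------------------
# Prediction degradation
# ---------------------------------------------------------------------------


def degrade_prediction(
    gt: BinaryMask,
    cfg: DegradationConfig,
    *,
    return_details: bool = False,
) -> BinaryMask | tuple[BinaryMask, dict]:
    """Corrupt a ground-truth mask into a plausible model prediction.

    Order of operations: boundary jitter (random label flips in a band of
    half-width ``boundary_jitter`` around the GT surface), false-negative
    dropout (each connected tooth component is partially eroded with
    probability ``fn_component_drop``), then false-positive speckles
    (per-axial-slice Poisson counts of radius-``speckle_radius`` balls
    planted clear of the ground truth).  Fully seeded and reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    pred = gt.data.copy()

    if cfg.boundary_jitter > 0 and pred.any():
        elem = StructuringElement(cfg.boundary_jitter).footprint
        band = ndimage.binary_dilation(pred, elem) & ~ndimage.binary_erosion(
            pred, elem, border_value=0
        )
        flips = band & (rng.random(pred.shape) < 0.25)
        pred ^= flips

    if cfg.fn_component_drop > 0 and pred.any():
        labels, n_comp = ndimage.label(gt.data)
        eroded = ndimage.binary_erosion(
            gt.data, StructuringElement(1).footprint, border_value=0
        )
        for comp in range(1, n_comp + 1):
            if rng.random() < cfg.fn_component_drop:
                sel = labels == comp
                pred[sel] &= eroded[sel]

    speckle_mask = np.zeros(gt.shape, dtype=bool)
    n_planted = 0
    if cfg.fp_speckle_rate > 0:
        r = cfg.speckle_radius
        # keep speckle centres one ball-radius plus one voxel clear of GT
        forbidden = ndimage.binary_dilation(
            gt.data, StructuringElement(r + 1).footprint
        )
        nx, ny, nz = gt.shape
        off = StructuringElement(r).footprint
        if nx < 2 * r + 1 or ny < 2 * r + 1:
            raise ConfigError(
                f"in-plane extent {nx}x{ny} too small for speckle radius {r}"
            )
        for z in range(nz):
            for _ in range(rng.poisson(cfg.fp_speckle_rate)):
                cx = rng.integers(r, max(nx - r, r + 1))
                cy = rng.integers(r, max(ny - r, r + 1))
                if forbidden[cx, cy, z]:
                    continue
                sl = (
                    slice(cx - r, cx + r + 1),
                    slice(cy - r, cy + r + 1),
                    slice(max(z - r, 0), min(z + r + 1, nz)),
                )
                zlo = max(z - r, 0) - (z - r)
                speckle_mask[sl] |= off[:, :, zlo : zlo + sl[2].stop - sl[2].start]
                n_planted += 1
    pred |= speckle_mask

    result = BinaryMask(data=pred, spacing=gt.spacing)
    if return_details:
        return result, {"n_speckles": n_planted, "speckle_mask": speckle_mask}
    return result


def simulate_prediction_set(
    gt: BinaryMask,
    cfgs: Mapping[str, DegradationConfig] | Sequence[DegradationConfig],
    rho: float = 0.0,
    master_seed: int = 0,
) -> "PredictionSet":
    """Generate one degraded mask per voter with tunable error correlation.

    Each voter's error field (prediction XOR ground truth) is assembled
    per voxel from a *shared* realisation with probability ``rho`` and a
    voter-private realisation otherwise, so rho = 0 yields independent
    errors and rho = 1 (with identical configs) identical voters.  The
    mixing is a simulation convention, not a claim about real models.
    """
    from .voting import PredictionSet  # local import to avoid a cycle

    if not 0.0 <= rho <= 1.0:
        raise ConfigError("rho must be in [0, 1]")
    if not isinstance(cfgs, Mapping):
        cfgs = {f"voter{i + 1}": c for i, c in enumerate(cfgs)}
    if not cfgs:
        raise ConfigError("need at least one voter config")

    ss = np.random.SeedSequence(master_seed)
    shared_seed, mix_seed, *voter_seeds = ss.spawn(len(cfgs) + 2)
    mix_rng = np.random.default_rng(mix_seed)

    masks: dict[str, BinaryMask] = {}
    for (name, cfg), vseed in zip(cfgs.items(), voter_seeds):
        private = degrade_prediction(
            gt, replace(cfg, seed=int(vseed.generate_state(1)[0] % 2**31))
        )
        if rho == 0.0 or len(cfgs) == 1:
            # a lone voter has no one to correlate with
            masks[name] = private
            continue
        shared = degrade_prediction(
            gt, replace(cfg, seed=int(shared_seed.generate_state(1)[0] % 2**31))
        )
        take_shared = mix_rng.random(gt.shape) < rho
        err = np.where(
            take_shared, shared.data ^ gt.data, private.data ^ gt.data
        )
        masks[name] = BinaryMask(data=gt.data ^ err, spacing=gt.spacing)
    return PredictionSet(masks=masks)
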