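"""Synthetic multiplexed-imaging data with known ground truth.

No raw imaging data from exchangeable-probe neuronal experiments is
publicly deposited, so every downstream stage is validated against
simulations that emulate the relevant structure of such data:

* confocal image sets — synapse punctae scattered along piecewise-linear
  dendrite backbones, per-channel integrated intensities drawn from a
  correlated multivariate lognormal, synapse sub-types with suppressed
  channels, a multiplicative illumination field, per-round rigid drift,
  Poisson + Gaussian noise, elliptical nuclei in a DAPI-like channel and
  intranuclear decoy punctae in the synapsin channel;
* PAINT localization streams — Poisson-thinned binding events at docking
  sites (discs, filaments or explicit points) with Gaussian localization
  noise, persistent fiducial markers, and a smooth cumulative drift.

All generator distributions are modeling choices of this package, not
measured properties of any particular dataset; they are documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ChannelImage, ImageSet

__all__ = [
    "SubtypeDef",
    "SimConfig",
    "GroundTruth",
    "PaintConfig",
    "PaintGroundTruth",
    "simulate_confocal_dataset",
    "simulate_localization_dataset",
]


@dataclass(frozen=True)
class SubtypeDef:
    """A synapse sub-type: channels suppressed to background, and its mixing fraction."""

    name: str
    suppressed_channels: tuple[str, ...]
    fraction: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the confocal simulator.

    The defaults describe a single 224 px field (42 um at 187 nm/px)
    containing 200 synapses on a dense dendrite mesh (about 0.2 synapses
    per um^2, roughly 2 um center-to-center spacing along dendrites, as in
    mature dissociated cultures), five synaptic channels plus reference
    (MAP2) and nuclear (DAPI) channels, correlated lognormal intensities,
    a smooth vignette, +-3 px inter-round drift and Poisson + Gaussian
    noise giving punctum SNR well above 5.
    """

    image_size: int = 224
    pixel_size_nm: float = 187.0
    synaptic_channels: tuple[str, ...] = ("synapsin", "PSD95", "bassoon", "Homer", "SHANK3")
    reference_channel: str = "MAP2"
    nuclear_channel: str = "DAPI"
    n_synapses: int = 200
    correlation: np.ndarray | None = None  # over synaptic channels; None = 0.5 off-diagonal
    lognormal_sigma: float = 0.25
    mean_intensity: float = 5000.0
    punctum_sigma_px: float = 1.6
    min_separation_px: float = 12.0
    subtypes: tuple[SubtypeDef, ...] = (SubtypeDef("core", (), 1.0),)
    background: float = 20.0
    poisson_noise: bool = True
    poisson_gain: float = 1.0
    read_noise_sigma: float = 2.0
    illumination_strength: float = 0.3
    drift_max_px: int = 3
    subpixel_drift: bool = False
    n_nuclei: int = 3
    n_decoy_puncta: int = 6
    n_dendrites: int = 26
    seed: int = 0

    def resolved_correlation(self) -> np.ndarray:
        k = len(self.synaptic_channels)
        if self.correlation is None:
            corr = np.full((k, k), 0.5)
            np.fill_diagonal(corr, 1.0)
            return corr
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        ev = np.linalg.eigvalsh(corr)
        if ev.min() < -1e-10:
            raise ValueError(f"correlation matrix is not PSD (min eigenvalue {ev.min():.3g})")
        return corr

    def validate(self) -> None:
        self.resolved_correlation()
        total = sum(s.fraction for s in self.subtypes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"subtype fractions must sum to 1 (got {total})")
        for s in self.subtypes:
            unknown = set(s.suppressed_channels) - set(self.synaptic_channels)
            if unknown:
                raise ValueError(f"subtype {s.name!r} suppresses unknown channels {unknown}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the confocal simulator planted.

    ``synapses``: id, x, y (px, pre-drift reference frame), radius_px,
    subtype.  ``intensities``: one column per synaptic channel of true
    integrated intensities (a.u.).  ``decoys``: intranuclear decoy punctae
    in the synapsin channel.  ``drift``: per-round (dx, dy) in px.
    """

    synapses: pd.DataFrame
    intensities: pd.DataFrame
    decoys: pd.DataFrame
    illumination: np.ndarray
    drift: pd.DataFrame
    nuclei_mask: np.ndarray


def _dendrite_backbones(rng: np.random.Generator, size: int, n: int) -> list[np.ndarray]:
    """Piecewise-linear dendrite paths spanning the field."""
    paths = []
    for _ in range(n):
        n_knots = rng.integers(3, 6)
        xs = np.sort(rng.uniform(0, size, n_knots))
        ys = rng.uniform(0.1 * size, 0.9 * size, n_knots)
        if rng.random() < 0.5:
            xs, ys = ys, xs
        paths.append(np.column_stack([xs, ys]))
    return paths


def _sample_on_paths(
    rng: np.random.Generator,
    paths: list[np.ndarray],
    n: int,
    jitter: float,
    margin: float,
    size: int,
    min_separation: float = 12.0,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample synapse centers along dendrites with physical exclusion.

    Synapses are discrete ~0.5-1 um structures and cannot overlap, so
    centers are rejection-sampled to keep at least ``min_separation`` px
    apart (about 2 um center-to-center at 187 nm pixels, a typical mature-
    culture spacing); positions inside ``exclude_mask`` (nuclei) are
    rejected, since somatic/nuclear synapsin signal is not synaptic.  The
    separation constraint is relaxed if the requested density is
    geometrically infeasible.
    """
    pts: list[np.ndarray] = []
    segs = []
    for p in paths:
        for a, b in zip(p[:-1], p[1:]):
            segs.append((a, b))
    lengths = np.array([np.hypot(*(b - a)) for a, b in segs])
    prob = lengths / lengths.sum()
    sep = min_separation
    attempts = 0
    while len(pts) < n:
        i = rng.choice(len(segs), p=prob)
        a, b = segs[i]
        t = rng.random()
        xy = a + t * (b - a) + rng.normal(0, jitter, 2)
        attempts += 1
        if attempts > 200 * n:  # density infeasible at this separation
            sep *= 0.8
            attempts = 0
        if not (margin <= xy[0] <= size - 1 - margin and margin <= xy[1] <= size - 1 - margin):
            continue
        if exclude_mask is not None and exclude_mask[int(round(xy[1])), int(round(xy[0]))]:
            continue
        if pts and sep > 0:
            d = np.min(np.hypot(*(np.array(pts) - xy).T))
            if d < sep:
                continue
        pts.append(xy)
    return np.array(pts)


def _render_gaussians(
    size: int, xy: np.ndarray, amplitudes: np.ndarray, sigma: float
) -> np.ndarray:
    """Add isotropic 2D Gaussians (unit integral times amplitude) to a field."""
    img = np.zeros((size, size), dtype=float)
    if len(xy) == 0:
        return img
    half = int(np.ceil(4 * sigma))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    for (x, y), a in zip(xy, amplitudes):
        cx, cy = int(round(x)), int(round(y))
        kern = np.exp(-(((xx + cx - x) ** 2) + ((yy + cy - y) ** 2)) / (2 * sigma**2))
        kern /= 2 * np.pi * sigma**2
        y0, y1 = max(0, cy - half), min(size, cy + half + 1)
        x0, x1 = max(0, cx - half), min(size, cx + half + 1)
        img[y0:y1, x0:x1] += a * kern[
            y0 - (cy - half) : y1 - (cy - half), x0 - (cx - half) : x1 - (cx - half)
        ]
    return img


def _illumination_field(rng: np.random.Generator, size: int, strength: float) -> np.ndarray:
    """A smooth strictly positive multiplicative vignette with spatial mean 1."""
    if strength == 0:
        return np.ones((size, size))
    cy, cx = rng.uniform(0.3 * size, 0.7 * size, 2)
    sig = rng.uniform(0.6, 1.0) * size
    yy, xx = np.mgrid[0:size, 0:size]
    g = np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2)) / (2 * sig**2))
    f = 1.0 + strength * (g - g.mean())
    f = np.clip(f, 0.05, None)
    return f / f.mean()


def _shift_int(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    y0, y1 = max(0, dy), min(h, h + dy)
    x0, x1 = max(0, dx), min(w, w + dx)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = img[y0 - dy : y1 - dy, x0 - dx : x1 - dx]
    return out


def _nuclei(rng: np.random.Generator, size: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical nuclei mask and their centers."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    centers = []
    for _ in range(n):
        cx, cy = rng.uniform(0.2 * size, 0.8 * size, 2)
        # semi-axes ~3-4 um at 187 nm pixels: realistic neuronal nuclei
        lo = max(14.0, 0.07 * size)
        hi = max(20.0, 0.10 * size)
        a, b = rng.uniform(lo, hi, 2)
        th = rng.uniform(0, np.pi)
        xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        centers.append((cx, cy))
    return mask, np.array(centers)


def simulate_confocal_dataset(config: SimConfig) -> tuple[ImageSet, GroundTruth]:
    """Generate a multi-round confocal image set with known ground truth.

    Each synaptic channel is acquired in its own imaging round together
    with the reference channel; the nuclear channel is acquired in round 0.
    Rendering order: punctae (2D Gaussians whose integral equals the
    planted intensity) -> multiply by illumination field -> shift by the
    round's drift -> Poisson + Gaussian noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    chans = config.synaptic_channels
    k = len(chans)
    n = config.n_synapses
    sigma = config.punctum_sigma_px
    margin = 4 * sigma + config.drift_max_px + 1

    paths = _dendrite_backbones(rng, size, config.n_dendrites)
    nuclei, _ = _nuclei(rng, size, config.n_nuclei)

    if n > 0:
        xy = _sample_on_paths(
            rng,
            paths,
            n,
            jitter=2.0,
            margin=margin,
            size=size,
            min_separation=config.min_separation_px,
            exclude_mask=nuclei,
        )
        z = rng.multivariate_normal(
            np.zeros(k), config.resolved_correlation(), size=n, method="cholesky"
        )
        intens = config.mean_intensity * np.exp(config.lognormal_sigma * z)
        labels = rng.choice(
            [s.name for s in config.subtypes],
            size=n,
            p=[s.fraction for s in config.subtypes],
        )
        suppress = {s.name: set(s.suppressed_channels) for s in config.subtypes}
        for i, lab in enumerate(labels):
            for j, ch in enumerate(chans):
                if ch in suppress[lab]:
                    intens[i, j] *= 0.01  # near background
    else:
        xy = np.zeros((0, 2))
        intens = np.zeros((0, k))
        labels = np.array([], dtype=str)

    synapses = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": xy[:, 0] if n else np.array([]),
            "y": xy[:, 1] if n else np.array([]),
            "radius_px": np.full(n, 2 * sigma),
            "subtype": labels,
        }
    )
    intens_df = pd.DataFrame(intens, columns=list(chans))
    intens_df.insert(0, "id", np.arange(n))

    # intranuclear decoy punctae in the synapsin channel
    syn_ch = chans[0]
    decoy_rows = []
    if config.n_decoy_puncta > 0 and nuclei.any():
        coords = np.argwhere(nuclei)
        inner = coords[
            (coords[:, 0] > margin)
            & (coords[:, 0] < size - margin)
            & (coords[:, 1] > margin)
            & (coords[:, 1] < size - margin)
        ]
        if len(inner):
            pick = inner[rng.choice(len(inner), size=config.n_decoy_puncta)]
            for r, c in pick:
                decoy_rows.append(
                    {"x": float(c), "y": float(r), "intensity": config.mean_intensity}
                )
    decoys = pd.DataFrame(decoy_rows, columns=["x", "y", "intensity"])

    illum = _illumination_field(rng, size, config.illumination_strength)

    # per-round integer drift; round 0 is the reference
    rounds = [str(r) for r in range(k)]
    if config.drift_max_px > 0:
        d = rng.integers(-config.drift_max_px, config.drift_max_px + 1, size=(k, 2))
        d[0] = 0
    else:
        d = np.zeros((k, 2), dtype=int)
    drift = pd.DataFrame({"round": rounds, "dx": d[:, 0], "dy": d[:, 1]})

    # reference-channel content: dendrite backbones as thick lines
    ref_img = np.zeros((size, size))
    for p in paths:
        for a, b in zip(p[:-1], p[1:]):
            length = max(int(np.hypot(*(b - a)) * 2), 2)
            ts = np.linspace(0, 1, length)
            pts = a[None, :] + ts[:, None] * (b - a)[None, :]
            ref_img += _render_gaussians(
                size, pts, np.full(len(pts), config.mean_intensity / 20), 2.0
            )

    def _corrupt(clean: np.ndarray, dx: int, dy: int) -> np.ndarray:
        img = clean * illum
        img = _shift_int(img, dx, dy)
        img = img + config.background
        if config.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None) / config.poisson_gain) * config.poisson_gain
        if config.read_noise_sigma > 0:
            img = img + rng.normal(0, config.read_noise_sigma, img.shape)
        return img.astype(float)

    images: list[ChannelImage] = []
    for j, ch in enumerate(chans):
        clean = _render_gaussians(size, xy, intens[:, j], sigma)
        if ch == syn_ch and len(decoys):
            clean += _render_gaussians(
                size,
                decoys[["x", "y"]].to_numpy(),
                decoys["intensity"].to_numpy(),
                sigma,
            )
        dx, dy = int(d[j, 0]), int(d[j, 1])
        images.append(ChannelImage(_corrupt(clean, dx, dy), ch, round_id=rounds[j]))
        images.append(
            ChannelImage(_corrupt(ref_img, dx, dy), config.reference_channel, round_id=rounds[j])
        )
    dapi_img = np.where(nuclei, config.mean_intensity / 10.0, 0.0)
    images.append(ChannelImage(_corrupt(dapi_img, 0, 0), config.nuclear_channel, round_id=rounds[0]))

    gt = GroundTruth(
        synapses=synapses,
        intensities=intens_df,
        decoys=decoys,
        illumination=illum,
        drift=drift,
        nuclei_mask=nuclei,
    )
    return ImageSet(images=images, pixel_size_nm=config.pixel_size_nm), gt


def simulate_cluster_pair_images(
    scale_nm: float,
    n_clusters: int = 12,
    locs_per_cluster: int = 600,
    bin_nm: float = 5.4,
    smooth_sigma_bins: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render two channels of co-localized synapse-scale clusters.

    Both channels draw localizations independently from the same Gaussian
    clusters of sd ``scale_nm / 2`` (so their radial cross-correlation,
    C(r) - 1, decays as exp(-r^2/scale^2) with 1/e length ``scale_nm``).
    The field grows with the structure (>= 25x the scale) so clusters stay
    isolated; returns (image_a, image_b, bin_nm).
    """
    from .paint import render_histogram

    rng = np.random.default_rng(seed)
    field = max(5000.0, 25.0 * scale_nm)
    centers = rng.uniform(0.15 * field, 0.85 * field, (n_clusters, 2))
    imgs = []
    for _ in range(2):
        pts = np.vstack(
            [rng.normal(c, scale_nm / 2.0, (locs_per_cluster, 2)) for c in centers]
        )
        locs = pd.DataFrame({"frame": 0, "x_nm": pts[:, 0], "y_nm": pts[:, 1]})
        img, _ = render_histogram(
            locs, bin_nm, smooth_sigma_bins, extent_nm=(0, field, 0, field)
        )
        imgs.append(img)
    return imgs[0], imgs[1], bin_nm


def simulate_feature_tables(
    channels: tuple[str, ...] = ("synapsin", "PSD95", "bassoon", "Homer", "SHANK3"),
    correlation: np.ndarray | None = None,
    lognormal_sigma: float = 0.3,
    mean_intensity: float = 5000.0,
    wells: list[tuple[str, str, str]] | None = None,
    synapses_per_image: int = 50,
    images_per_well: int = 3,
    effects: dict[str, dict[str, float]] | None = None,
    well_effect_sigma: float = 0.05,
    subtypes: tuple[SubtypeDef, ...] = (SubtypeDef("core", (), 1.0),),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate synapse-level feature tables directly from the intensity model.

    Emulates the measurement output of the confocal pipeline (one row per
    synapse with per-channel integrated intensities and areas) without
    rendering images, so the downstream statistics can be exercised at
    large n.  ``wells`` is a list of (well id, treatment label, batch id);
    ``effects`` maps a treatment label to per-channel multiplicative
    intensity effects; ``well_effect_sigma`` is the lognormal sd of the
    per-well random effect shared by all synapses in a well (biological
    well-to-well variability).
    """
    rng = np.random.default_rng(seed)
    if wells is None:
        wells = [("W1", "untreated", "B1")]
    k = len(channels)
    if correlation is None:
        corr = np.full((k, k), 0.5)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.asarray(correlation, float)
    total = sum(s.fraction for s in subtypes)
    if not np.isclose(total, 1.0):
        raise ValueError(f"subtype fractions must sum to 1 (got {total})")
    rows = []
    sid = 0
    for well, treatment, batch in wells:
        well_factor = np.exp(rng.normal(0.0, well_effect_sigma, k))
        eff = np.ones(k)
        if effects and treatment in effects:
            for j, ch in enumerate(channels):
                eff[j] = effects[treatment].get(ch, 1.0)
        for img in range(images_per_well):
            n = synapses_per_image
            z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
            intens = mean_intensity * np.exp(lognormal_sigma * z) * eff * well_factor
            labels = rng.choice(
                [s.name for s in subtypes], size=n, p=[s.fraction for s in subtypes]
            )
            suppress = {s.name: set(s.suppressed_channels) for s in subtypes}
            for i in range(n):
                for j, ch in enumerate(channels):
                    if channels[j] in suppress[labels[i]]:
                        intens[i, j] *= 0.01
            # area scales weakly with intensity (bigger synapses are brighter)
            area = 0.6 * (intens / mean_intensity) ** 0.5 + rng.normal(0, 0.02, (n, k))
            area = np.clip(area, 0.05, None)
            for i in range(n):
                rec = {
                    "synapse_id": sid,
                    "well": well,
                    "image_id": f"{well}_{img}",
                    "treatment": treatment,
                    "batch": batch,
                    "subtype": labels[i],
                }
                for j, ch in enumerate(channels):
                    rec[f"{ch}_intensity"] = intens[i, j]
                    rec[f"{ch}_area_um2"] = area[i, j]
                rows.append(rec)
                sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PAINT localization simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaintConfig:
    """Parameters of the localization-stream simulator.

    Docking-site geometry is supplied as explicit point coordinates (nm);
    helpers below build filament and disc geometries.  Each site emits a
    localization in a frame with probability ``binding_rate``; fiducials
    emit with probability ``fiducial_detection`` (>= 0.95 by contract).
    Drift is a smoothed Gaussian random walk (or linear ramp) anchored at
    (0, 0) in frame 0.
    """

    n_frames: int = 5000
    sites_nm: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    fiducials_nm: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    binding_rate: float = 0.002
    fiducial_detection: float = 0.98
    localization_sigma_nm: float = 10.0
    drift_mode: str = "random_walk"  # or "linear" or "none"
    drift_step_nm: float = 0.5  # per-frame step (random walk) or rate (linear)
    drift_smooth_frames: int = 200
    seed: int = 0


@dataclass(frozen=True)
class PaintGroundTruth:
    """Planted drift trajectory, site and fiducial coordinates."""

    drift: pd.DataFrame  # frame, dx_nm, dy_nm
    sites_nm: np.ndarray
    fiducials_nm: np.ndarray


def filament_sites(
    start_nm: tuple[float, float],
    end_nm: tuple[float, float],
    n_sites: int,
    cross_sigma_nm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Docking sites along a filament with Gaussian cross-section."""
    a = np.asarray(start_nm, float)
    b = np.asarray(end_nm, float)
    t = rng.random(n_sites)
    axis = (b - a) / np.linalg.norm(b - a)
    perp = np.array([-axis[1], axis[0]])
    offsets = rng.normal(0, cross_sigma_nm, n_sites)
    return a[None, :] + t[:, None] * (b - a)[None, :] + offsets[:, None] * perp[None, :]


def disc_sites(
    center_nm: tuple[float, float], radius_nm: float, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Docking sites uniform in a disc (a synapse-scale protein cluster)."""
    r = radius_nm * np.sqrt(rng.random(n_sites))
    th = rng.uniform(0, 2 * np.pi, n_sites)
    return np.asarray(center_nm, float)[None, :] + np.column_stack(
        [r * np.cos(th), r * np.sin(th)]
    )


def _drift_trajectory(config: PaintConfig, rng: np.random.Generator) -> np.ndarray:
    f = config.n_frames
    if config.drift_mode == "none" or config.drift_step_nm == 0:
        return np.zeros((f, 2))
    if config.drift_mode == "linear":
        t = np.arange(f)[:, None]
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        return config.drift_step_nm * t * direction[None, :]
    if config.drift_mode == "random_walk":
        steps = rng.normal(0, config.drift_step_nm, (f, 2))
        walk = np.cumsum(steps, axis=0)
        w = max(int(config.drift_smooth_frames), 1)
        kernel = np.ones(w) / w
        sm = np.column_stack(
            [np.convolve(walk[:, i], kernel, mode="same") for i in range(2)]
        )
        return sm - sm[0]
    raise ValueError(f"unknown drift mode {config.drift_mode!r}")


def simulate_localization_dataset(
    config: PaintConfig,
) -> tuple[pd.DataFrame, PaintGroundTruth]:
    """Generate a PAINT localization table (frame, x_nm, y_nm) with ground truth.

    Per frame: docking sites are Poisson-thinned by the binding rate, each
    emitted event gets Gaussian localization noise and the cumulative drift
    of that frame; fiducials emit in nearly every frame with the same noise
    and drift.
    """
    if config.n_frames <= 0:
        raise ValueError("number of frames must be positive")
    if config.fiducial_detection < 0.95 and len(config.fiducials_nm):
        raise ValueError("fiducial detection probability must be >= 0.95")
    rng = np.random.default_rng(config.seed)
    drift = _drift_trajectory(config, rng)
    sites = np.asarray(config.sites_nm, float).reshape(-1, 2)
    fids = np.asarray(config.fiducials_nm, float).reshape(-1, 2)
    sig = config.localization_sigma_nm

    frames_out: list[np.ndarray] = []
    coords_out: list[np.ndarray] = []
    for f in range(config.n_frames):
        if len(sites):
            on = rng.random(len(sites)) < config.binding_rate
            pts = sites[on]
        else:
            pts = np.zeros((0, 2))
        if len(fids):
            on_f = rng.random(len(fids)) < config.fiducial_detection
            pts = np.vstack([pts, fids[on_f]])
        if len(pts) == 0:
            continue
        noisy = pts + rng.normal(0, sig, pts.shape) + drift[f][None, :]
        frames_out.append(np.full(len(noisy), f))
        coords_out.append(noisy)
    if frames_out:
        frame_col = np.concatenate(frames_out).astype(int)
        xy = np.vstack(coords_out)
    else:
        frame_col = np.array([], dtype=int)
        xy = np.zeros((0, 2))
    locs = pd.DataFrame({"frame": frame_col, "x_nm": xy[:, 0], "y_nm": xy[:, 1]})
    gt = PaintGroundTruth(
        drift=pd.DataFrame(
            {"frame": np.arange(config.n_frames), "dx_nm": drift[:, 0], "dy_nm": drift[:, 1]}
        ),
        sites_nm=sites,
        fiducials_nm=fids,
    )
    return locs, gt
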