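"""Synthetic blood-well simulator.

Generates ground-truth particle populations for wells of diluted whole
blood (or EpCAM-enriched cartridges) and renders them into multi-channel
fluorescence frame stacks.  Per-well particle numbers are Poisson with
mean ``concentration * sampled_volume * retention``; particles fall
uniformly over frames and positions; each marker-positive particle is
rendered as a disc of its physical diameter convolved with a Gaussian
defocus kernel, on top of a flat background with Gaussian pixel noise.
The ``extra`` channel receives background and noise only.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .config import OpticsConfig, SampleConfig, optics_config_to_dict

__all__ = [
    "GroundTruthParticle", "undiluted_volume", "sampled_volume",
    "sample_well", "render_frame", "render_well", "truth_table",
    "touching_clusters", "write_well", "read_well",
]


@dataclass(slots=True)
class GroundTruthParticle:
    """Latent state of one simulated object."""

    particle_id: int
    class_name: str
    well_id: str
    frame_id: int
    center: tuple[float, float]          # (row, col), sub-pixel
    diameter_um: float
    defocus_sigma: float                 # pixels
    marker_intensities: dict = field(default_factory=dict)  # channel -> peak a.u.


def undiluted_volume(config: SampleConfig) -> float:
    """Microlitres of undiluted blood represented by one loaded well."""
    return config.loaded_volume_ul / config.dilution_factor


def sampled_volume(config: SampleConfig) -> float:
    """Blood volume (uL) a well/cartridge draws its particles from."""
    if config.mode == "epcam_enriched":
        return config.processed_volume_ul
    return undiluted_volume(config)


def _well_rng(config: SampleConfig, well_index: int, stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed),
                                spawn_key=(int(well_index), int(stream)))
    return np.random.default_rng(ss)


def sample_well(config: SampleConfig, well_index: int,
                optics: OpticsConfig | None = None,
                well_id: str | None = None) -> list[GroundTruthParticle]:
    """Draw the ground-truth particle population of one well.

    Deterministic in ``(config.seed, well_index)``.  Raises ``ValueError``
    when the expected count of any population exceeds
    ``config.max_expected_per_well`` (implausible configuration guard).
    """
    if optics is None:
        optics = OpticsConfig.for_mode(config.mode)
    panel = set(optics.channel_roles)
    for pop in config.populations:
        if set(pop.marker_expression) != panel:
            raise ValueError(
                f"population {pop.class_name!r} expression keys "
                f"{sorted(pop.marker_expression)} do not match panel {sorted(panel)}")

    rng = _well_rng(config, well_index)
    vol = sampled_volume(config)
    rows_max, cols_max = optics.frame_shape
    if well_id is None:
        well_id = f"well{well_index}"

    particles: list[GroundTruthParticle] = []
    pid = 0
    for pop in config.populations:
        mean = pop.concentration * vol * config.retention_for(pop.class_name)
        if mean > config.max_expected_per_well:
            raise ValueError(
                f"expected {mean:.3g} {pop.class_name} objects per well exceeds "
                f"cap {config.max_expected_per_well:.3g}")
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        lo, hi = pop.diameter_range
        diam = rng.uniform(lo, hi, n)
        frames = rng.integers(0, config.frames_per_well, n)
        rr = rng.uniform(0.0, rows_max, n)
        cc = rng.uniform(0.0, cols_max, n)
        slo, shi = optics.defocus_sigma_range
        sigma = rng.uniform(slo, shi, n) if pop.suspended else np.zeros(n)
        # per-channel peak amplitudes; negative expression is exactly zero
        amp = {}
        for role, level in pop.marker_expression.items():
            base = optics.intensity_per_expression[level]
            ch = optics.channel_roles[role]
            if base > 0:
                amp[ch] = base * np.exp(rng.normal(0.0, optics.intensity_cv, n))
            else:
                amp[ch] = np.zeros(n)
        for i in range(n):
            particles.append(GroundTruthParticle(
                particle_id=pid, class_name=pop.class_name, well_id=well_id,
                frame_id=int(frames[i]), center=(float(rr[i]), float(cc[i])),
                diameter_um=float(diam[i]), defocus_sigma=float(sigma[i]),
                marker_intensities={ch: float(a[i]) for ch, a in amp.items()},
            ))
            pid += 1

    if config.mode == "epcam_enriched" and config.cluster_fraction > 0:
        _cluster_leukocytes(particles, config, optics, rng)
    return particles


def _cluster_leukocytes(particles, config, optics, rng) -> None:
    """Move a fraction of leukocytes to touching distance of another one.

    Models cells aggregating along the cartridge's magnetic field lines,
    which downstream segmentation merges into single objects.
    """
    leuk = [p for p in particles if p.class_name == "leukocyte"]
    if len(leuk) < 2:
        return
    k = min(int(round(config.cluster_fraction * len(leuk))), len(leuk) - 1)
    chosen = set(int(i) for i in rng.choice(len(leuk), size=k, replace=False))
    placed = [i for i in range(len(leuk)) if i not in chosen]
    if not placed:  # unreachable given k <= n-1, kept as a guard
        placed = [chosen.pop()]
    # attach each mover to an already-settled particle so every mover ends
    # within touching distance of its host's final position
    for i in sorted(chosen):
        host = leuk[placed[int(rng.integers(0, len(placed)))]]
        mover = leuk[i]
        r_sum_px = (host.diameter_um + mover.diameter_um) / 2.0 / optics.pixel_pitch
        dist = r_sum_px * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        mover.frame_id = host.frame_id
        mover.center = (host.center[0] + dist * math.sin(theta),
                        host.center[1] + dist * math.cos(theta))
        placed.append(i)


# ---------------------------------------------------------------------------
# Rendering

def _add_blurred_disc(img: np.ndarray, row: float, col: float,
                      radius_px: float, sigma: float, amplitude: float) -> None:
    """Add one disc (soft 1-pixel edge) blurred by a Gaussian, in place."""
    half = int(math.ceil(radius_px + 3.0 * sigma + 2.0))
    r0 = int(round(row)) - half
    c0 = int(round(col)) - half
    size = 2 * half + 1
    rows_img, cols_img = img.shape
    # patch/frame overlap
    pr0, pr1 = max(0, -r0), min(size, rows_img - r0)
    pc0, pc1 = max(0, -c0), min(size, cols_img - c0)
    if pr0 >= pr1 or pc0 >= pc1:
        return
    yy = np.arange(size, dtype=np.float32)[:, None] + (r0 - row)
    xx = np.arange(size, dtype=np.float32)[None, :] + (c0 - col)
    dist = np.sqrt(yy * yy + xx * xx)
    patch = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    if sigma > 0.05:
        patch = gaussian_filter(patch, sigma, truncate=3.0)
    img[r0 + pr0:r0 + pr1, c0 + pc0:c0 + pc1] += amplitude * patch[pr0:pr1, pc0:pc1]


def render_frame(particles, optics: OpticsConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one frame: (n_channels, rows, cols) float32 stack."""
    shape = optics.frame_shape
    stack = np.empty((len(optics.channel_names),) + shape, dtype=np.float32)
    for ci in range(stack.shape[0]):
        stack[ci] = optics.background_level
        if optics.noise_sd > 0:
            stack[ci] += optics.noise_sd * rng.standard_normal(shape, dtype=np.float32)
    ch_index = {name: i for i, name in enumerate(optics.channel_names)}
    for p in particles:
        radius_px = p.diameter_um / 2.0 / optics.pixel_pitch
        for ch, amp in p.marker_intensities.items():
            if amp > 0:
                _add_blurred_disc(stack[ch_index[ch]], p.center[0], p.center[1],
                                  radius_px, p.defocus_sigma, amp)
    return stack


def render_well(particles, optics: OpticsConfig, n_frames: int,
                rng: np.random.Generator | None = None,
                seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render all frames of a well.

    Returns a ``(channels, frames, rows, cols)`` float32 stack and the
    ground-truth table of every particle.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_frame: dict[int, list] = {}
    for p in particles:
        if not 0 <= p.frame_id < n_frames:
            raise ValueError(f"particle {p.particle_id} frame_id {p.frame_id} "
                             f"outside 0..{n_frames - 1}")
        by_frame.setdefault(p.frame_id, []).append(p)
    shape = optics.frame_shape
    stack = np.empty((len(optics.channel_names), n_frames) + shape, dtype=np.float32)
    for f in range(n_frames):
        stack[:, f] = render_frame(by_frame.get(f, []), optics, rng)
    return stack, truth_table(particles, optics)


def truth_table(particles, optics: OpticsConfig) -> pd.DataFrame:
    """Tabulate ground truth; off-frame centers are flagged ``clipped``."""
    rows_max, cols_max = optics.frame_shape
    recs = []
    for p in particles:
        rec = {
            "particle_id": p.particle_id, "well_id": p.well_id,
            "frame_id": p.frame_id, "class": p.class_name,
            "row": p.center[0], "col": p.center[1],
            "diameter_um": p.diameter_um, "defocus_sigma": p.defocus_sigma,
            "clipped": not (0 <= p.center[0] < rows_max and 0 <= p.center[1] < cols_max),
        }
        for ch in optics.channel_names:
            rec[f"intensity_{ch}"] = p.marker_intensities.get(ch, 0.0)
        recs.append(rec)
    cols = (["particle_id", "well_id", "frame_id", "class", "row", "col",
             "diameter_um", "defocus_sigma", "clipped"]
            + [f"intensity_{ch}" for ch in optics.channel_names])
    return pd.DataFrame(recs, columns=cols)


def touching_clusters(particles, optics: OpticsConfig,
                      margin_px: float = 1.5) -> list[list[int]]:
    """Group same-frame particles whose discs touch (union-find).

    Two particles touch when their center distance is below the sum of
    their pixel radii plus ``margin_px`` (segmentation merges them into
    one connected component).  Returns clusters as lists of indices into
    ``particles``.
    """
    n = len(particles)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    by_frame: dict[int, list[int]] = {}
    for i, p in enumerate(particles):
        by_frame.setdefault(p.frame_id, []).append(i)
    for idxs in by_frame.values():
        for ai in range(len(idxs)):
            i = idxs[ai]
            pi = particles[i]
            ri = pi.diameter_um / 2.0 / optics.pixel_pitch
            for aj in range(ai + 1, len(idxs)):
                j = idxs[aj]
                pj = particles[j]
                rj = pj.diameter_um / 2.0 / optics.pixel_pitch
                d = math.hypot(pi.center[0] - pj.center[0], pi.center[1] - pj.center[1])
                if d <= ri + rj + margin_px:
                    ra, rb = find(i), find(j)
                    if ra != rb:
                        parent[rb] = ra
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


# ---------------------------------------------------------------------------
# On-disk format: 16-bit multi-page TIFF per channel + JSON sidecar + CSV truth

def write_well(out_dir: str, well_id: str, stack: np.ndarray,
               truth: pd.DataFrame, optics: OpticsConfig) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for ci, ch in enumerate(optics.channel_names):
        arr = np.clip(stack[ci], 0, 65535).astype(np.uint16)
        tifffile.imwrite(os.path.join(out_dir, f"{well_id}_{ch}.tif"), arr,
                         photometric="minisblack")
    truth.to_csv(os.path.join(out_dir, f"{well_id}_truth.csv"), index=False)
    meta = {"well_id": well_id, "n_frames": int(stack.shape[1]),
            "optics": optics_config_to_dict(optics)}
    with open(os.path.join(out_dir, f"{well_id}_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_well(out_dir: str, well_id: str) -> tuple[np.ndarray, dict]:
    """Read back a written well: float32 stack + metadata dict."""
    with open(os.path.join(out_dir, f"{well_id}_meta.json")) as fh:
        meta = json.load(fh)
    channels = meta["optics"]["channel_names"]
    frames = []
    for ch in channels:
        arr = tifffile.imread(os.path.join(out_dir, f"{well_id}_{ch}.tif"))
        if arr.ndim == 2:
            arr = arr[None]
        frames.append(arr.astype(np.float32))
    return np.stack(frames, axis=0), meta
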