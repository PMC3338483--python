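"""Seeded synthetic microscopy with ground truth.

Generates still planes (cells as filled ellipses) and time-lapse stacks
(cells as bright disks over a drifting speckled gel background) whose
population statistics reproduce the configured condition parameters, so the
morphometry and tracking stages can be validated against known truth.

Distributional choices
----------------------
Cell area and aspect ratio are drawn from shifted-gamma distributions
(support > 0 for area, ≥ 1 for AR) whose mean and SD equal the configured
values *exactly*; a truncated normal cannot represent the measured AR
moments (e.g. 1.6 ± 0.8 with support ≥ 1) and truncation would bias the
realized means. Migration speed uses a normal truncated at zero, where the
truncation bias is negligible for the measured conditions. The two-population
structure near the interface is a two-component mixture (spindle vs rounded)
whose component means are moment-matched so the pooled mean/SD still equal
the configured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.ndimage import shift as nd_shift
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from geledge.conditions import ConditionParams, condition_at_depth  # noqa: F401

BACKGROUND = 100.0
CELL_INTENSITY = 1000.0
SPECKLE_INTENSITY = 180.0


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and timing of the emulated experiment."""

    pixel_size: float = 1.0           # µm / px
    frame_interval: float = 20.0      # minutes
    duration: float = 12.0            # hours
    image_shape: tuple[int, int] = (512, 512)
    z_planes: tuple[float, ...] = ()  # µm
    noise_sd: float = 20.0            # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("pixel_size, frame_interval and duration must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 60.0 / self.frame_interval)) + 1

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)


@dataclass
class TrackTruth:
    """Ground-truth trajectory of one synthetic cell."""

    cell_id: int
    positions: np.ndarray            # (n_frames, 2) µm, columns (x, y)
    true_speed: float                # path length / time, µm/hr
    drift: np.ndarray | None = None  # (n_frames, 2) µm global offset, if applied


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def shifted_gamma(rng: np.random.Generator, mean: float, sd: float,
                  lower: float, n: int) -> np.ndarray:
    """Draw n samples > lower with the requested mean and SD (gamma shape)."""
    if mean <= lower:
        raise ValueError(f"mean {mean} must exceed lower bound {lower}")
    if sd == 0:
        return np.full(n, mean)
    shape = ((mean - lower) / sd) ** 2
    scale = sd**2 / (mean - lower)
    return lower + rng.gamma(shape, scale, size=n)


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     lower: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _mixture_components(mean: float, sd: float, p: float, separation: float,
                        lower: float) -> tuple[float, float, float]:
    """(spindle mean, rounded mean, common component sd) matching pooled moments.

    Component means are offset by ``separation``·sd around the pooled mean
    (spindle above, rounded below) and a common component SD absorbs the
    rest of the pooled variance. Raises if the pooled SD is too small to
    support the requested separation, or a component mean falls outside the
    support.
    """
    delta = separation * sd
    m_spindle = mean + (1.0 - p) * delta
    m_round = mean - p * delta
    var = sd**2 - p * (1.0 - p) * delta**2
    if var < 0:
        raise ValueError(
            "infeasible mixture: pooled sd too small for the component separation"
        )
    if m_round <= lower or m_spindle <= lower:
        raise ValueError("infeasible mixture: component mean outside support")
    return m_spindle, m_round, float(np.sqrt(var))


def sample_cell_shapes(params: ConditionParams, n: int, seed=0,
                       separation: float = 1.0) -> pd.DataFrame:
    """Sample per-cell (area, aspect ratio) from the condition's mixture.

    Returns a DataFrame with columns ``area_um2, aspect_ratio, spindle``;
    pooled mean/SD of both metrics match the condition parameters by
    construction. Spindle membership is shared between area and AR, so
    spindle cells are jointly larger and more elongated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    p = params.spindle_fraction
    spindle = rng.random(n) < p

    def draw(mean: float, sd: float, lower: float) -> np.ndarray:
        if p in (0.0, 1.0):
            return shifted_gamma(rng, mean, sd, lower, n)
        m_s, m_r, s = _mixture_components(mean, sd, p, separation, lower)
        out = np.empty(n)
        out[spindle] = shifted_gamma(rng, m_s, s, lower, int(spindle.sum()))
        out[~spindle] = shifted_gamma(rng, m_r, s, lower, int((~spindle).sum()))
        return out

    return pd.DataFrame({
        "area_um2": draw(params.area_mean, params.area_sd, 0.0),
        "aspect_ratio": draw(params.ar_mean, params.ar_sd, 1.0),
        "spindle": spindle,
    })


def render_plane(shapes: pd.DataFrame, config: ImagingConfig, seed=0,
                 max_tries: int = 300) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize cells as filled ellipses into a noisy fluorescence image.

    Each cell becomes an ellipse with the truth area and axis ratio
    (A = πab, AR = a/b), random orientation, placed uniformly without
    overlap (3 px clearance) and clear of the image border. Returns the
    uint16 image and a truth table (cell_id, x_um, y_um, area_um2,
    aspect_ratio).

    Raises if a cell cannot be placed; fewer or smaller cells (or a larger
    field) fix that.
    """
    rng = _rng(seed)
    ps = config.pixel_size
    h, w = config.image_shape
    image = np.full((h, w), BACKGROUND)
    occupied = np.zeros((h, w), dtype=bool)
    border = 3
    clearance = 3.0

    rows = []
    order = np.argsort(-shapes["area_um2"].to_numpy())  # big cells first
    for cell_id, idx in enumerate(order):
        area = float(shapes["area_um2"].iloc[idx])
        ar = float(shapes["aspect_ratio"].iloc[idx])
        a_px = np.sqrt(area * ar / np.pi) / ps   # semi-major, px
        b_px = np.sqrt(area / (np.pi * ar)) / ps  # semi-minor, px
        margin = a_px + border
        if 2 * margin >= min(h, w):
            raise RuntimeError(
                f"could not place cell of area {area:.0f} µm²: its extent "
                f"exceeds the {h}×{w} px field; use a larger field"
            )
        for _ in range(max_tries):
            theta = rng.uniform(0.0, np.pi)
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            grown = draw_ellipse(r0, c0, b_px + clearance, a_px + clearance,
                                 shape=(h, w), rotation=theta)
            if occupied[grown].any():
                continue
            rr, cc = draw_ellipse(r0, c0, b_px, a_px, shape=(h, w),
                                  rotation=theta)
            occupied[grown] = True
            image[rr, cc] = CELL_INTENSITY
            rows.append({
                "cell_id": cell_id,
                "x_um": float(cc.mean()) * ps,
                "y_um": float(rr.mean()) * ps,
                "area_um2": area,
                "aspect_ratio": ar,
                "orientation": theta,
            })
            break
        else:
            raise RuntimeError(
                f"could not place cell of area {area:.0f} µm² without overlap "
                f"after {max_tries} tries; use fewer/smaller cells or a larger field"
            )
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0, 65535).astype(np.uint16)
    return image, pd.DataFrame(rows)


def simulate_tracks(params: ConditionParams, n_cells: int,
                    config: ImagingConfig, persistence: float = 0.7,
                    seed=0, margin_um: float = 60.0) -> list[TrackTruth]:
    """Persistent-random-walk trajectories with exact path-length speeds.

    Per cell the target speed is drawn from a normal truncated at zero; every
    frame the cell takes a step of constant length speed·Δt whose direction
    follows a wrapped-normal persistent walk (directional correlation =
    ``persistence``). The realized path-length speed equals the target
    exactly. Cells start on a jittered grid inside the field margins.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must lie in [0, 1)")
    rng = _rng(seed)
    n_frames = config.n_frames
    dt_hr = config.frame_interval / 60.0
    fy, fx = config.field_um

    speeds = truncated_normal(rng, params.speed_mean, params.speed_sd, 0.0, n_cells)
    # jittered grid start positions
    n_side = int(np.ceil(np.sqrt(n_cells)))
    gx = np.linspace(margin_um, fx - margin_um, n_side)
    gy = np.linspace(margin_um, fy - margin_um, n_side)
    grid = np.array([(x, y) for y in gy for x in gx])[:n_cells]
    grid = grid + rng.uniform(-0.25, 0.25, grid.shape) * min(
        gx[1] - gx[0] if n_side > 1 else margin_um, 40.0
    )

    sigma_theta = np.sqrt(-2.0 * np.log(persistence)) if persistence > 0 else None
    tracks = []
    for cid in range(n_cells):
        step = speeds[cid] * dt_hr
        if sigma_theta is None:
            theta = rng.uniform(0.0, 2.0 * np.pi, n_frames - 1)
        else:
            theta = np.cumsum(
                np.concatenate([[rng.uniform(0.0, 2.0 * np.pi)],
                                rng.normal(0.0, sigma_theta, n_frames - 2)])
            )
        moves = step * np.column_stack([np.cos(theta), np.sin(theta)])
        pos = np.vstack([grid[cid], grid[cid] + np.cumsum(moves, axis=0)])
        tracks.append(TrackTruth(cell_id=cid, positions=pos,
                                 true_speed=float(speeds[cid])))
    return tracks


def make_drift(config: ImagingConfig, drift_scale: float, seed=0,
               smooth_frames: float = 2.0) -> np.ndarray:
    """Smooth global gel-drift offsets (n_frames, 2) µm; frame 0 is zero.

    Gel swelling is largely directional: the per-frame increment combines a
    persistent component (random direction, magnitude ~drift_scale) with
    smoothed stochastic wander, so the offset grows steadily rather than
    diffusing around zero.
    """
    rng = _rng(seed)
    if drift_scale == 0:
        return np.zeros((config.n_frames, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])
    wander = rng.normal(0.0, drift_scale, (config.n_frames - 1, 2))
    wander = gaussian_filter1d(wander, smooth_frames, axis=0, mode="nearest")
    inc = 0.7 * drift_scale * direction + wander
    return np.vstack([np.zeros(2), np.cumsum(inc, axis=0)])


def apply_drift(tracks: list[TrackTruth], config: ImagingConfig,
                drift_scale: float = 1.0, seed=0,
                drift: np.ndarray | None = None
                ) -> tuple[list[TrackTruth], np.ndarray]:
    """Add one global offset sequence to all tracks; returns (tracks, truth).

    The same smooth drift (gel swelling) applies to every cell in the field.
    Pass an explicit ``drift`` array to override the generated one.
    """
    if drift is None:
        if drift_scale < 0:
            raise ValueError("drift_scale must be >= 0")
        drift = make_drift(config, drift_scale, seed)
    drift = np.asarray(drift, dtype=float)
    drifted = [
        TrackTruth(t.cell_id, t.positions + drift, t.true_speed, drift=drift)
        for t in tracks
    ]
    return drifted, drift


def render_time_lapse(tracks: list[TrackTruth], config: ImagingConfig,
                      drift: np.ndarray | None = None, seed=0,
                      cell_radius_um: float = 8.0, n_speckles: int = 1000,
                      speckle_radius_um: float = 1.5) -> np.ndarray:
    """Rasterize tracks into a (n_frames, H, W) uint16 time-lapse stack.

    Cells are bright disks at their (drifted) positions. The gel itself is
    textured with dim speckles fixed in gel coordinates, which carry the
    drift — the stationary features a translation registration keys on.
    """
    rng = _rng(seed)
    ps = config.pixel_size
    h, w = config.image_shape
    if drift is None:
        drift = np.zeros((config.n_frames, 2))
    # gel texture rendered once in gel coordinates, then translated per frame
    texture = np.full((h, w), BACKGROUND)
    speckles = rng.uniform(0.0, [w * ps, h * ps], size=(n_speckles, 2))
    for sx, sy in speckles:
        rr, cc = draw_disk((sy / ps, sx / ps), speckle_radius_um / ps,
                           shape=(h, w))
        texture[rr, cc] += SPECKLE_INTENSITY
    stack = np.empty((config.n_frames, h, w), dtype=np.uint16)
    for t in range(config.n_frames):
        if np.any(drift[t]):
            frame = nd_shift(texture, (drift[t, 1] / ps, drift[t, 0] / ps),
                             order=1, mode="nearest")
        else:
            frame = texture.copy()
        for track in tracks:
            x, y = track.positions[t]
            rr, cc = draw_disk((y / ps, x / ps), cell_radius_um / ps,
                               shape=(h, w))
            frame[rr, cc] = CELL_INTENSITY
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, frame.shape)
        stack[t] = np.clip(frame, 0, 65535).astype(np.uint16)
    return stack


def tracks_to_table(tracks: list[TrackTruth], config: ImagingConfig) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for frame, (x, y) in enumerate(t.positions):
            rows.append({"cell_id": t.cell_id, "frame": frame,
                         "t_min": frame * config.frame_interval,
                         "x_um": x, "y_um": y, "true_speed_um_hr": t.true_speed})
    return pd.DataFrame(rows)


def write_dataset(out_dir: str | Path,
                  stacks: dict[str, np.ndarray] | None = None,
                  tables: dict[str, pd.DataFrame] | None = None,
                  config: ImagingConfig | None = None) -> dict[str, Path]:
    """Write image stacks as multi-page TIFF and truth tables as CSV.

    TIFF pages are z-planes or time frames; acquisition metadata (pixel
    size, frame interval, z positions) travels in the TIFF description.
    Re-reading reproduces pixel data bit-exactly (uint16, lossless).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    meta = {}
    if config is not None:
        meta = {"pixel_size_um": config.pixel_size,
                "frame_interval_min": config.frame_interval,
                "z_planes_um": list(config.z_planes)}
    for name, stack in (stacks or {}).items():
        path = out / f"{name}.tif"
        tifffile.imwrite(path, np.asarray(stack), metadata=meta)
        written[name] = path
    for name, table in (tables or {}).items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        written[name] = path
    return written
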