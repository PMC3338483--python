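"""Drift registration, detection linking, and path-length migration speeds.

The gel swells during a time-lapse, translating the whole field; frames are
registered (translation only) to the first frame by the cross-correlation
peak with subpixel refinement, and detections are corrected by the recovered
offsets before linking. Linking is greedy nearest-neighbour between
consecutive frames with a maximum step; migration speed is total path length
over observation time, in µm/hr.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import shift as nd_shift
from scipy.spatial.distance import cdist
from skimage.registration import phase_cross_correlation

from geledge.morphometry import measure_plane


def register_frames(frames: np.ndarray, upsample_factor: int = 20,
                    return_corrected: bool = True
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Translation-register every frame to the first.

    Returns ``offsets`` with shape (n_frames, 2) in pixels, ordered
    (row, col): the shift to apply to frame t to align it with frame 0 (a
    frame whose content moved by +d gets offset −d). ``corrected`` holds the
    realigned frames (linear interpolation) unless disabled.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("expected a stack of >= 2 frames")
    reference = frames[0]
    offsets = np.zeros((frames.shape[0], 2))
    for t in range(1, frames.shape[0]):
        frame = frames[t]
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            warnings.warn(f"featureless frame {t}: assuming zero offset")
            continue
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=upsample_factor,
            normalization="phase",
        )
        offsets[t] = shift
    corrected = None
    if return_corrected:
        corrected = np.stack(
            [frames[0].astype(float)]
            + [nd_shift(frames[t].astype(float), offsets[t], order=1)
               for t in range(1, frames.shape[0])]
        )
    return offsets, corrected


def correct_detections(detections: list[pd.DataFrame], offsets: np.ndarray,
                       pixel_size: float = 1.0) -> list[pd.DataFrame]:
    """Apply registration offsets (px, row/col order) to detection tables."""
    out = []
    for t, det in enumerate(detections):
        det = det.copy()
        det["x_um"] = det["x_um"] + offsets[t, 1] * pixel_size
        det["y_um"] = det["y_um"] + offsets[t, 0] * pixel_size
        out.append(det)
    return out


def link_detections(detections: list[pd.DataFrame], max_step_um: float,
                    min_track_fraction: float = 0.8) -> pd.DataFrame:
    """Greedy nearest-neighbour frame-to-frame linking.

    Each detection is used at most once; links longer than ``max_step_um``
    are forbidden; unmatched detections start new tracks. Tracks observed in
    fewer than ``min_track_fraction`` of the frames are dropped (no gap
    closing — a missed detection splits the track).

    Returns a track table with columns cell_id, frame, x_um, y_um.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be > 0")
    n_frames = len(detections)
    tracks: list[dict] = []  # {"frames": [...], "points": [...]}
    active: list[int] = []  # indices into tracks with a point in frame t-1

    for t, det in enumerate(detections):
        points = det[["x_um", "y_um"]].to_numpy(dtype=float)
        matched_track = set()
        matched_det = set()
        if active and len(points):
            prev = np.array([tracks[i]["points"][-1] for i in active])
            dist = cdist(prev, points)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            for i, j in order:
                if dist[i, j] > max_step_um:
                    break
                if i in matched_track or j in matched_det:
                    continue
                matched_track.add(int(i))
                matched_det.add(int(j))
                tracks[active[i]]["frames"].append(t)
                tracks[active[i]]["points"].append(points[j])
        new_active = [active[i] for i in sorted(matched_track)]
        for j in range(len(points)):
            if j not in matched_det:
                tracks.append({"frames": [t], "points": [points[j]]})
                new_active.append(len(tracks) - 1)
        active = new_active

    min_len = min_track_fraction * n_frames
    rows = []
    cell_id = 0
    for track in tracks:
        if len(track["frames"]) < min_len:
            continue
        for frame, (x, y) in zip(track["frames"], track["points"]):
            rows.append({"cell_id": cell_id, "frame": frame, "x_um": x, "y_um": y})
        cell_id += 1
    return pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um"])


def track_speed(positions: np.ndarray, frame_interval_min: float) -> float:
    """Path length / observation time for one track, in µm/hr."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 positions to compute a speed")
    path = float(np.linalg.norm(np.diff(positions, axis=0), axis=1).sum())
    hours = (positions.shape[0] - 1) * frame_interval_min / 60.0
    return path / hours


def speeds_per_track(tracks: pd.DataFrame, frame_interval_min: float) -> pd.DataFrame:
    """Per-cell path-length speeds from a track table (cell_id, speed_um_hr)."""
    rows = []
    for cell_id, group in tracks.sort_values("frame").groupby("cell_id"):
        rows.append({
            "cell_id": cell_id,
            "n_frames": len(group),
            "speed_um_hr": track_speed(group[["x_um", "y_um"]].to_numpy(),
                                       frame_interval_min),
        })
    return pd.DataFrame(rows, columns=["cell_id", "n_frames", "speed_um_hr"])


def summarize_speeds(tracks: pd.DataFrame, frame_interval_min: float,
                     group_label: str = "", min_n: int = 15
                     ) -> tuple[int, float, float]:
    """(n, mean, sample sd) of per-cell speeds; warns below ``min_n`` cells."""
    speeds = speeds_per_track(tracks, frame_interval_min)["speed_um_hr"]
    n = len(speeds)
    if n == 0:
        raise ValueError("no tracks to summarize")
    if n < min_n:
        warnings.warn(
            f"group '{group_label}': only {n} tracks (< {min_n}); "
            "speed summary may be unreliable"
        )
    sd = float(speeds.std(ddof=1)) if n > 1 else 0.0
    return n, float(speeds.mean()), sd


def analyze_time_lapse(stack: np.ndarray, frame_interval_min: float,
                       pixel_size: float = 1.0, min_area_um2: float = 50.0,
                       max_step_um: float | None = None,
                       expected_speed_um_hr: float = 30.0,
                       min_track_fraction: float = 0.8
                       ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Register, detect, link and measure speeds for a time-lapse stack.

    ``max_step_um`` defaults to 3 × the expected per-frame travel. Returns
    (track table, per-cell speeds, registration offsets).
    """
    if max_step_um is None:
        max_step_um = 3.0 * expected_speed_um_hr * frame_interval_min / 60.0
    offsets, _ = register_frames(stack, return_corrected=False)
    detections = [
        measure_plane(frame, plane_z=0.0, pixel_size=pixel_size,
                      min_area_um2=min_area_um2)
        for frame in stack
    ]
    detections = correct_detections(detections, offsets, pixel_size)
    tracks = link_detections(detections, max_step_um, min_track_fraction)
    speeds = speeds_per_track(tracks, frame_interval_min)
    return tracks, speeds, offsets
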