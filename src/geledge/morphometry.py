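"""Per-plane cell morphometry: segmentation, area, ellipse aspect ratio.

Cells labeled with a cytoplasmic dye are segmented by a global threshold
(Otsu by default) and connected components; each region's spreading area is
its pixel count scaled by the pixel size, and its aspect ratio is the
major/minor axis ratio of the ellipse with the same second central moments.
Heights are normalized so that zero is the first (lowest) plane containing
cells, and metrics are profiled in height bins; interface-driven spreading
decays exponentially with height and can be fit as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border


def segment_plane(image: np.ndarray, pixel_size: float = 1.0,
                  min_area_um2: float = 50.0,
                  threshold: float | str = "otsu") -> list:
    """Segment one fluorescence plane into labeled cell regions.

    Global threshold → 8-connected components → discard regions smaller than
    ``min_area_um2`` or touching the image border. Returns scikit-image
    region objects (possibly empty; a blank plane is not an error).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if threshold == "otsu":
        thr = threshold_otsu(image)
    else:
        thr = float(threshold)
    mask = clear_border(image > thr)
    labels = label(mask, connectivity=2)
    min_px = min_area_um2 / pixel_size**2
    return [r for r in regionprops(labels) if r.area >= min_px]


def measure_area(region, pixel_size: float = 1.0) -> float:
    """Region area in µm² (pixel count × pixel_size²)."""
    return float(region.area) * pixel_size**2


def ellipse_aspect_ratio(region, max_ratio: float = 100.0) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (≥ 1).

    Degenerate regions (collinear pixels, zero minor axis) report the
    configurable cap instead of infinity.
    """
    if region.area < 5:
        raise ValueError("region too small for a moment ellipse (< 5 px)")
    minor = region.axis_minor_length
    if minor <= 0:
        return float(max_ratio)
    return float(min(region.axis_major_length / minor, max_ratio))


def measure_plane(image: np.ndarray, plane_z: float, pixel_size: float = 1.0,
                  min_area_um2: float = 50.0,
                  threshold: float | str = "otsu") -> pd.DataFrame:
    """Segment and measure one plane into cell records.

    Columns: cell_id, plane_z, area_um2, aspect_ratio, x_um, y_um.
    """
    regions = segment_plane(image, pixel_size, min_area_um2, threshold)
    rows = []
    for i, region in enumerate(regions):
        cy, cx = region.centroid
        rows.append({
            "cell_id": i,
            "plane_z": plane_z,
            "area_um2": measure_area(region, pixel_size),
            "aspect_ratio": ellipse_aspect_ratio(region),
            "x_um": cx * pixel_size,
            "y_um": cy * pixel_size,
        })
    return pd.DataFrame(
        rows, columns=["cell_id", "plane_z", "area_um2", "aspect_ratio",
                       "x_um", "y_um"],
    )


def normalize_height_origin(records: pd.DataFrame) -> pd.DataFrame:
    """Shift plane heights so the lowest plane containing cells maps to 0.

    Mirrors the measurement convention for rough substrates: height is
    counted from the first plane where cells are observed, not from the
    (unknown) substrate surface. Idempotent.
    """
    if records.empty:
        raise ValueError("no cells in any plane; cannot set a height origin")
    out = records.copy()
    out["plane_z"] = out["plane_z"] - out["plane_z"].min()
    return out


#: Reporting landmarks: interface bin, interfacial region, bulk (> 500 µm).
DEFAULT_BIN_EDGES = (0.0, 50.0, 100.0, 200.0, 500.0, np.inf)


def profile_by_height(records: pd.DataFrame, metric: str = "area_um2",
                      bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Mean ± sample SD of a metric per height bin; empty bins omitted.

    Columns: z_lo, z_hi, z_mid, n, mean, sd. ``sd`` is the n−1 sample SD,
    reported 0 for single-cell bins (flagged by n = 1).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.digitize(records["plane_z"], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        values = records.loc[idx == b, metric]
        if len(values) == 0:
            continue
        z_hi = edges[b + 1]
        rows.append({
            "z_lo": edges[b],
            "z_hi": z_hi,
            "z_mid": 0.5 * (edges[b] + z_hi) if np.isfinite(z_hi) else edges[b],
            "n": len(values),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["z_lo", "z_hi", "z_mid", "n", "mean", "sd"])


@dataclass(frozen=True)
class ExponentialFit:
    """m(z) = m_bulk + (m0 − m_bulk)·exp(−z/λ) fit of a height profile."""

    m0: float
    m_bulk: float
    decay_length: float
    residual_norm: float
    flat: bool = False  # λ unidentifiable (no height dependence)


def fit_exponential_profile(profile: pd.DataFrame,
                            rel_flat_tol: float = 1e-3) -> ExponentialFit:
    """Least-squares exponential decay fit to a height profile.

    Requires ≥ 4 bins. Flat profiles (no resolvable height dependence) are
    flagged: λ is unidentifiable there and the fit degenerates to the mean.
    """
    if len(profile) < 4:
        raise ValueError("need at least 4 height bins to fit a decay")
    z = profile["z_mid"].to_numpy(dtype=float)
    m = profile["mean"].to_numpy(dtype=float)
    span = m.max() - m.min()
    if span <= rel_flat_tol * max(abs(m.mean()), 1e-12):
        return ExponentialFit(m0=float(m.mean()), m_bulk=float(m.mean()),
                              decay_length=np.nan, residual_norm=0.0, flat=True)

    def model(zz, m0, m_bulk, lam):
        return m_bulk + (m0 - m_bulk) * np.exp(-zz / lam)

    z_scale = max(z.max() - z.min(), 1.0)
    p0 = (m[0], m[-1], z_scale / 3.0)
    try:
        popt, _ = curve_fit(
            model, z, m, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"exponential profile fit did not converge: {err}") from err
    resid = float(np.linalg.norm(m - model(z, *popt)))
    return ExponentialFit(m0=float(popt[0]), m_bulk=float(popt[1]),
                          decay_length=float(popt[2]), residual_norm=resid)
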