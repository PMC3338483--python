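"""Scalar measures derived from an indentation solve."""

from __future__ import annotations

import numpy as np

from geledge.fem.types import AxisymMesh, IndentationResult


def von_mises_field(result: IndentationResult) -> np.ndarray:
    """Per-element von Mises stress (Pa) from the axisymmetric tensor.

    Principal stresses are the eigenvalues of the in-plane (r, z) block plus
    the hoop stress σ_θθ, which is itself principal (no θ shear in an
    axisymmetric state).
    """
    srr, szz, stt, srz = result.stresses.T
    center = 0.5 * (srr + szz)
    radius = np.sqrt((0.5 * (srr - szz)) ** 2 + srz**2)
    s1, s2, s3 = center + radius, center - radius, stt
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))


def interface_stress(result: IndentationResult, mesh: AxisymMesh) -> float:
    """Maximum von Mises stress (Pa) over elements touching the bonded bottom."""
    vm = von_mises_field(result)
    on_bottom = np.isin(mesh.elements, mesh.boundary["bottom"]).any(axis=1)
    if not on_bottom.any():
        raise ValueError("mesh has no bottom-adjacent elements tagged")
    return float(vm[on_bottom].max())


def effective_stiffness(result: IndentationResult) -> float:
    """Straight-line fit slope of the force–deflection record, in N/m.

    Plain least squares over all recorded (δ, F) points including (0, 0),
    with a free intercept — the slope of the whole curve, not a secant.
    """
    steps = np.asarray(result.steps, dtype=float)
    if steps.shape[0] < 2:
        raise ValueError("need at least 2 load steps to fit a stiffness")
    depth_m = steps[:, 0] * 1e-6
    slope = np.polyfit(depth_m, steps[:, 1], 1)[0]
    return float(slope)
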