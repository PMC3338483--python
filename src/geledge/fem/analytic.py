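"""Closed-form contact oracles used to validate the finite-element solver."""

from __future__ import annotations

import numpy as np

from geledge.fem.types import UM, ElasticMaterial


def hertz_half_space_force(material: ElasticMaterial, radius_um: float,
                           depth_um: float) -> float:
    """Hertz force (N) for a rigid sphere on an elastic half space.

    F = (4/3) · E/(1-ν²) · √R · δ^{3/2}. Valid in the small-indentation
    limit (δ ≪ R) on a thick substrate.
    """
    if depth_um < 0:
        raise ValueError("depth must be >= 0")
    e_star = material.youngs_modulus / (1.0 - material.poisson_ratio**2)
    r = radius_um * UM
    d = depth_um * UM
    return (4.0 / 3.0) * e_star * np.sqrt(r) * d**1.5


def bonded_layer_correction(radius_um: float, depth_um: float,
                            height_um: float) -> float:
    """Finite-thickness stiffening factor for a bonded incompressible layer.

    Multiplies the Hertz half-space force; χ = √(R·δ)/h. Tends to 1 as the
    layer thickens and grows monotonically as it thins.
    """
    if height_um <= 0:
        raise ValueError("height must be > 0")
    chi = np.sqrt(radius_um * depth_um) / height_um
    return float(
        1.0 + 1.133 * chi + 1.283 * chi**2 + 0.769 * chi**3 + 0.0975 * chi**4
    )
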