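"""Domain types for the indentation model.

All geometric interfaces are in micrometres and stresses in pascal; the
assembly and solver convert to SI (m, Pa, N) internally so that stiffness
comes out in N/m without unit juggling at 1e-6 scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UM = 1e-6  # metres per micrometre


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic gel.

    Parameters
    ----------
    youngs_modulus:
        Young's modulus E in Pa (default 450 Pa, soft basement-membrane gel).
    poisson_ratio:
        Poisson ratio ν, in [0, 0.5). Hydrogels are water-dominated and close
        to incompressible; the default 0.45 keeps the displacement
        formulation well conditioned while staying near-incompressible.
    """

    youngs_modulus: float = 450.0
    poisson_ratio: float = 0.45

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        e, nu = self.youngs_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class IndenterSpec:
    """Rigid frictionless spherical indenter, displacement controlled."""

    radius: float = 5.0  # µm
    max_depth: float = 5.0  # µm
    n_steps: int = 10

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def contact_radius_estimate(self) -> float:
        """Hertzian contact-radius scale sqrt(R·δ_max) in µm."""
        return float(np.sqrt(self.radius * self.max_depth))


@dataclass(frozen=True)
class GelGeometry:
    """Cylindrical gel disc: height (thickness) and model radius, µm.

    The physical dish is millimetres wide; the model radius is truncated
    (default 500 µm) because the indentation field decays over the contact
    radius (~5 µm). The side boundary is left free, as in the experiment.
    """

    height: float
    radius: float = 500.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class MeshParams:
    """Grading parameters for the structured axisymmetric mesh (µm)."""

    refine_radius: float = 15.0
    fine_size: float = 0.5
    coarse_size: float = 25.0
    growth: float = 1.25

    def __post_init__(self) -> None:
        if self.fine_size >= self.coarse_size:
            raise ValueError("fine_size must be < coarse_size")
        if self.growth <= 1.0:
            raise ValueError("growth ratio must be > 1")


@dataclass
class AxisymMesh:
    """Structured quad mesh of the (r, z) gel cross-section, coordinates in µm.

    ``boundary`` maps {"bottom", "axis", "side", "top"} to node-index arrays.
    """

    nodes: np.ndarray  # (n_nodes, 2) float, columns (r, z)
    elements: np.ndarray  # (n_elements, 4) int, counter-clockwise
    boundary: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]


@dataclass
class IndentationResult:
    """Output of a displacement-controlled contact solve.

    ``steps`` holds (depth µm, reaction force N) including the trivial (0, 0)
    point; ``displacements`` (µm) and ``stresses`` (Pa, per-element centroid
    components σ_rr, σ_zz, σ_θθ, σ_rz) refer to the final step.
    """

    steps: np.ndarray  # (n_steps + 1, 2)
    displacements: np.ndarray  # (n_nodes, 2) µm
    stresses: np.ndarray  # (n_elements, 4) Pa
    contact_nodes: np.ndarray  # node indices in contact at final step

    @property
    def final_force(self) -> float:
        return float(self.steps[-1, 1])

    @property
    def final_depth(self) -> float:
        return float(self.steps[-1, 0])
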