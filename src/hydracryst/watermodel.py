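"""Rigid three-site water model constants and orientation helpers.

The geometry and nonbonded parameters are those of the standard three-point
transferable water model: O-H 0.9572 A, H-O-H 104.52 deg, charges
(O -0.834 e, H +0.417 e), Lennard-Jones on oxygen only
(sigma 3.1507 A, epsilon 0.1521 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Physical constants
KB_KCAL = 0.0019872041       # Boltzmann constant, kcal/mol/K
COULOMB_K = 332.0637128      # e^2/A -> kcal/mol
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class WaterModelParams:
    """Rigid-water geometry and nonbonded parameters."""

    oh_length: float = 0.9572        # A
    hoh_angle: float = 104.52        # degrees
    q_o: float = -0.834              # e
    q_h: float = 0.417               # e
    sigma_oo: float = 3.1507         # A
    epsilon_oo: float = 0.1521       # kcal/mol
    cutoff: float = 10.0             # A, molecule-based spherical cutoff

    def __post_init__(self) -> None:
        if abs(self.q_o + 2 * self.q_h) > 1e-9:
            raise ValueError("water charges must sum to zero")

    @property
    def site_charges(self) -> np.ndarray:
        return np.array([self.q_o, self.q_h, self.q_h])


def water_template(params: WaterModelParams | None = None) -> np.ndarray:
    """Site coordinates (O, H1, H2) of one water, oxygen at the origin."""
    p = params or WaterModelParams()
    half = np.deg2rad(p.hoh_angle) / 2
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [p.oh_length * np.sin(half), p.oh_length * np.cos(half), 0.0],
            [-p.oh_length * np.sin(half), p.oh_length * np.cos(half), 0.0],
        ]
    )


WATER_GEOMETRY = water_template()


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake's uniform quaternion method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation about a (unit) axis by an angle, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_water_sites(oxygen: np.ndarray, rng: np.random.Generator,
                       params: WaterModelParams | None = None) -> np.ndarray:
    """Sites of one randomly oriented rigid water with its oxygen at ``oxygen``."""
    template = water_template(params) if params else WATER_GEOMETRY
    rot = random_rotation_matrix(rng)
    return template @ rot.T + np.asarray(oxygen, dtype=float)
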