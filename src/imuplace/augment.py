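"""Rotation-based walk-pattern augmentation.

Sensor re-donning never reproduces an IMU's orientation exactly, so the
training set is expanded with randomly rotated copies of each walk pattern:
for every IMU in a pattern, one 3x3 rotation matrix is drawn and applied at
every time step to the accelerometer 3-vector and, with the same matrix, to
the gyroscope 3-vector (both triads are rigid in one housing).  Rotations
are isometries, so per-sample triplet norms are preserved exactly.

Rotation magnitudes default to Euler angles uniform in +/-15 degrees per
axis, a realistic re-donning misalignment; unbounded rotations would
scramble the gravity axis and change the learning problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import WalkPattern

__all__ = [
    "RotationAugmentConfig",
    "random_rotation",
    "rotation_angle_deg",
    "apply_rotations",
    "augment_pattern",
]


@dataclass(frozen=True)
class RotationAugmentConfig:
    factor: int = 10
    max_angle_deg: float = 15.0
    mode: Literal["per_imu_independent", "shared_across_imus"] = "per_imu_independent"
    angle_distribution: Literal["uniform_euler", "uniform_axis_angle"] = "uniform_euler"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if not 0.0 <= self.max_angle_deg <= 180.0:
            raise ValueError("max_angle_deg must lie in [0, 180]")


def random_rotation(
    max_angle_deg: float,
    angle_distribution: str = "uniform_euler",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one proper rotation matrix (orthonormal, det +1).

    ``uniform_euler``: intrinsic x-y-z Euler angles each uniform in
    +/-max_angle_deg (the total rotation angle may exceed the per-axis
    bound, up to three times it).  ``uniform_axis_angle``: axis uniform on
    the sphere, angle uniform in [0, max_angle_deg], so the recovered
    axis-angle magnitude never exceeds the bound.
    """
    rng = np.random.default_rng() if rng is None else rng
    if max_angle_deg == 0.0:
        return np.eye(3)
    if angle_distribution == "uniform_euler":
        angles = rng.uniform(-max_angle_deg, max_angle_deg, size=3)
        return Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    if angle_distribution == "uniform_axis_angle":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
        return Rotation.from_rotvec(angle * axis).as_matrix()
    raise ValueError(f"unknown angle_distribution: {angle_distribution!r}")


def rotation_angle_deg(R: np.ndarray) -> float:
    """Axis-angle magnitude recovered from the trace, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def apply_rotations(pattern: WalkPattern, rotations: Sequence[np.ndarray]) -> np.ndarray:
    """Rotate each IMU's accel and gyro triplets by its matrix.

    ``rotations`` holds one 3x3 matrix per included location, in the
    pattern's block order.  Returns the rotated (6n x 400) matrix.
    """
    m = pattern.matrix
    if m.shape[0] % 6 != 0:
        raise ValueError(
            f"pattern rows ({m.shape[0]}) are not grouped in 6-row IMU blocks"
        )
    n_imus = m.shape[0] // 6
    if len(rotations) != n_imus:
        raise ValueError(f"need {n_imus} rotation matrices, got {len(rotations)}")
    out = np.empty_like(m)
    for b, R in enumerate(rotations):
        out[6 * b : 6 * b + 3] = R @ m[6 * b : 6 * b + 3]
        out[6 * b + 3 : 6 * b + 6] = R @ m[6 * b + 3 : 6 * b + 6]
    return out


def augment_pattern(
    pattern: WalkPattern,
    config: RotationAugmentConfig,
    rng: np.random.Generator | None = None,
) -> list[WalkPattern]:
    """Produce ``config.factor`` rotated copies of one walk pattern.

    Surface label and (participant, trial) provenance are preserved;
    ``augmentation_index`` runs 1..factor.  In ``per_imu_independent`` mode
    each IMU gets its own rotation; in ``shared_across_imus`` one matrix is
    applied to every IMU of a copy.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_imus = pattern.combination.n_locations
    copies: list[WalkPattern] = []
    for i in range(1, config.factor + 1):
        if config.mode == "shared_across_imus":
            R = random_rotation(config.max_angle_deg, config.angle_distribution, rng)
            rotations = [R] * n_imus
        elif config.mode == "per_imu_independent":
            rotations = [
                random_rotation(config.max_angle_deg, config.angle_distribution, rng)
                for _ in range(n_imus)
            ]
        else:
            raise ValueError(f"unknown augmentation mode: {config.mode!r}")
        copies.append(
            replace(
                pattern,
                matrix=apply_rotations(pattern, rotations),
                augmented=True,
                augmentation_index=i,
            )
        )
    return copies
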