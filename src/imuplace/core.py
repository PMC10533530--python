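"""Domain types and combination algebra for multi-IMU walk patterns.

A walking trial carries 36 synchronized channels (6 body locations x
[3-axis accelerometer + 3-axis gyroscope]) sampled at 100 Hz.  A *walk
pattern* is the fixed-size (6n x 400) matrix obtained by restricting the
first 4 s of a trial to a subset ("combination") of the six candidate
attachment locations.  The 63 non-empty location subsets are catalogued
with a fixed numbering so that results are comparable across runs.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "BodyLocation",
    "SurfaceClass",
    "ChannelId",
    "IMUTrial",
    "CombinationSpec",
    "WalkPattern",
    "WalkPatternDataset",
    "SAMPLE_RATE_HZ",
    "WINDOW_SAMPLES",
    "all_channels",
    "channel_index",
    "enumerate_combinations",
    "get_combination",
    "find_combination",
    "build_walk_pattern",
    "assemble_dataset",
    "comparison_schedule",
    "ComparisonDescriptor",
]

SAMPLE_RATE_HZ = 100
#: analysis window: first 4 s of each trial
WINDOW_SAMPLES = 400


class BodyLocation(enum.Enum):
    """The six candidate IMU attachment sites, in canonical order."""

    TRUNK = "trunk"
    WRIST = "wrist"
    LEFT_THIGH = "left_thigh"
    RIGHT_THIGH = "right_thigh"
    LEFT_SHANK = "left_shank"
    RIGHT_SHANK = "right_shank"

    @property
    def index(self) -> int:
        return _LOCATION_ORDER.index(self)


_LOCATION_ORDER = list(BodyLocation)


class SurfaceClass(enum.Enum):
    """The seven walking surfaces (the classification labels)."""

    FLAT_UNEVEN = "flat_uneven"
    BANKED_LEFT = "banked_left"
    BANKED_RIGHT = "banked_right"
    STAIR_UP = "stair_up"
    STAIR_DOWN = "stair_down"
    SLOPE_UP = "slope_up"
    SLOPE_DOWN = "slope_down"

    @property
    def index(self) -> int:
        return _SURFACE_ORDER.index(self)


_SURFACE_ORDER = list(SurfaceClass)

Sensor = Literal["accel", "gyro"]
Axis = Literal["vertical", "mediolateral", "anterior_posterior"]

SENSORS: tuple[Sensor, ...] = ("accel", "gyro")
AXES: tuple[Axis, ...] = ("vertical", "mediolateral", "anterior_posterior")


@dataclass(frozen=True)
class ChannelId:
    """One of the 36 recorded channels.

    Units: accelerometer channels are m/s^2, gyroscope channels rad/s.
    """

    location: BodyLocation
    sensor: Sensor
    axis: Axis

    @property
    def index(self) -> int:
        """Row index in a full 36-channel trial matrix."""
        return channel_index(self.location, self.sensor, self.axis)

    @property
    def short_name(self) -> str:
        sens = "acc" if self.sensor == "accel" else "gyr"
        ax = {"vertical": "v", "mediolateral": "ml", "anterior_posterior": "ap"}[self.axis]
        return f"{self.location.value}_{sens}_{ax}"


def channel_index(location: BodyLocation, sensor: Sensor, axis: Axis) -> int:
    """Canonical row index: locations in canonical order; within a location
    accel(vertical, mediolateral, anterior_posterior) then gyro(same)."""
    return location.index * 6 + (0 if sensor == "accel" else 3) + AXES.index(axis)


def all_channels() -> list[ChannelId]:
    """The 36 channels in canonical row order."""
    return [
        ChannelId(loc, sensor, axis)
        for loc in BodyLocation
        for sensor in SENSORS
        for axis in AXES
    ]


@dataclass
class IMUTrial:
    """One walking trial: 36 channels x T samples at 100 Hz."""

    participant_id: int
    surface: SurfaceClass
    trial_index: int
    samples: np.ndarray
    sample_rate: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != 36:
            raise ValueError(
                f"trial samples must be (36, T); got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trial samples contain non-finite values")
        if self.participant_id < 1:
            raise ValueError("participant_id must be >= 1")
        if not 1 <= self.trial_index:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


# The fixed catalogue of the 63 location combinations.  The numbering and the
# within-combination location order are part of the package contract (results
# are reported per combination number), so they are hard-coded rather than
# derived from an enumeration order.
_L = BodyLocation
_CATALOGUE: dict[int, tuple[BodyLocation, ...]] = {
    1: (_L.TRUNK,),
    2: (_L.WRIST,),
    3: (_L.LEFT_THIGH,),
    4: (_L.RIGHT_THIGH,),
    5: (_L.LEFT_SHANK,),
    6: (_L.RIGHT_SHANK,),
    7: (_L.TRUNK, _L.LEFT_THIGH),
    8: (_L.TRUNK, _L.RIGHT_THIGH),
    9: (_L.TRUNK, _L.LEFT_SHANK),
    10: (_L.TRUNK, _L.RIGHT_SHANK),
    11: (_L.TRUNK, _L.WRIST),
    12: (_L.WRIST, _L.LEFT_THIGH),
    13: (_L.WRIST, _L.RIGHT_THIGH),
    14: (_L.WRIST, _L.LEFT_SHANK),
    15: (_L.WRIST, _L.RIGHT_SHANK),
    16: (_L.LEFT_THIGH, _L.RIGHT_THIGH),
    17: (_L.LEFT_THIGH, _L.LEFT_SHANK),
    18: (_L.LEFT_THIGH, _L.RIGHT_SHANK),
    19: (_L.RIGHT_THIGH, _L.LEFT_SHANK),
    20: (_L.RIGHT_THIGH, _L.RIGHT_SHANK),
    21: (_L.LEFT_SHANK, _L.RIGHT_SHANK),
    22: (_L.TRUNK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    23: (_L.TRUNK, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    24: (_L.TRUNK, _L.LEFT_SHANK, _L.RIGHT_THIGH),
    25: (_L.TRUNK, _L.LEFT_SHANK, _L.LEFT_THIGH),
    26: (_L.TRUNK, _L.RIGHT_SHANK, _L.RIGHT_THIGH),
    27: (_L.TRUNK, _L.RIGHT_SHANK, _L.LEFT_THIGH),
    28: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH),
    29: (_L.TRUNK, _L.WRIST, _L.RIGHT_THIGH),
    30: (_L.TRUNK, _L.WRIST, _L.LEFT_SHANK),
    31: (_L.TRUNK, _L.WRIST, _L.RIGHT_SHANK),
    32: (_L.WRIST, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    33: (_L.WRIST, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    34: (_L.WRIST, _L.LEFT_SHANK, _L.RIGHT_THIGH),
    35: (_L.WRIST, _L.LEFT_SHANK, _L.LEFT_THIGH),
    36: (_L.WRIST, _L.RIGHT_SHANK, _L.RIGHT_THIGH),
    37: (_L.WRIST, _L.RIGHT_SHANK, _L.LEFT_THIGH),
    38: (_L.LEFT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    39: (_L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    40: (_L.LEFT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    41: (_L.RIGHT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    42: (_L.TRUNK, _L.LEFT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    43: (_L.TRUNK, _L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    44: (_L.TRUNK, _L.LEFT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    45: (_L.TRUNK, _L.RIGHT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    46: (_L.TRUNK, _L.WRIST, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    47: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    48: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.LEFT_SHANK),
    49: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.RIGHT_SHANK),
    50: (_L.TRUNK, _L.WRIST, _L.RIGHT_THIGH, _L.LEFT_SHANK),
    51: (_L.TRUNK, _L.WRIST, _L.RIGHT_THIGH, _L.RIGHT_SHANK),
    52: (_L.WRIST, _L.LEFT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    53: (_L.WRIST, _L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    54: (_L.WRIST, _L.LEFT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    55: (_L.WRIST, _L.RIGHT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    56: (_L.LEFT_SHANK, _L.RIGHT_SHANK, _L.LEFT_THIGH, _L.RIGHT_THIGH),
    57: (_L.TRUNK, _L.LEFT_THIGH, _L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    58: (_L.WRIST, _L.LEFT_THIGH, _L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    59: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.RIGHT_THIGH, _L.LEFT_SHANK),
    60: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.RIGHT_THIGH, _L.RIGHT_SHANK),
    61: (_L.TRUNK, _L.WRIST, _L.LEFT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    62: (_L.TRUNK, _L.WRIST, _L.RIGHT_THIGH, _L.LEFT_SHANK, _L.RIGHT_SHANK),
    63: (
        _L.TRUNK,
        _L.WRIST,
        _L.LEFT_THIGH,
        _L.RIGHT_THIGH,
        _L.LEFT_SHANK,
        _L.RIGHT_SHANK,
    ),
}


@dataclass(frozen=True)
class CombinationSpec:
    """One of the 63 numbered body-location subsets."""

    comb_num: int
    locations: tuple[BodyLocation, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.comb_num <= 63:
            raise ValueError(f"comb_num must be in 1..63, got {self.comb_num}")
        if not 1 <= len(self.locations) <= 6:
            raise ValueError("a combination holds between 1 and 6 locations")
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("duplicate locations in combination")

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def n_channels(self) -> int:
        return 6 * self.n_locations

    def channel_rows(self) -> np.ndarray:
        """Row indices into a 36-channel trial matrix, block per location."""
        return np.concatenate(
            [np.arange(loc.index * 6, loc.index * 6 + 6) for loc in self.locations]
        )

    @property
    def label(self) -> str:
        return "+".join(loc.value for loc in self.locations)


def get_combination(comb_num: int) -> CombinationSpec:
    """Look up one catalogued combination by its number."""
    try:
        locations = _CATALOGUE[comb_num]
    except KeyError:
        raise ValueError(f"comb_num must be in 1..63, got {comb_num}") from None
    return CombinationSpec(comb_num=comb_num, locations=locations)


def find_combination(locations: Iterable[BodyLocation]) -> CombinationSpec:
    """Find the catalogued combination matching a location set (order-free)."""
    wanted = frozenset(locations)
    for num, locs in _CATALOGUE.items():
        if frozenset(locs) == wanted:
            return get_combination(num)
    raise ValueError(f"no catalogued combination for {sorted(l.value for l in wanted)}")


def enumerate_combinations() -> list[CombinationSpec]:
    """All 63 combinations in catalogue order.

    The count with n locations equals C(6, n) = 6!/(n!(6-n)!), i.e.
    6, 15, 20, 15, 6, 1 for n = 1..6, summing to 63.
    """
    return [get_combination(i) for i in range(1, 64)]


@dataclass
class WalkPattern:
    """A (6n x 400) classifier input extracted from one trial."""

    combination: CombinationSpec
    surface: SurfaceClass
    matrix: np.ndarray
    participant_id: int
    trial_index: int
    augmented: bool = False
    augmentation_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        expected = (self.combination.n_channels, WINDOW_SAMPLES)
        if self.matrix.shape != expected:
            raise ValueError(
                f"walk-pattern matrix must be {expected}, got {self.matrix.shape}"
            )

    @property
    def source(self) -> tuple[int, int]:
        return (self.participant_id, self.trial_index)


def build_walk_pattern(
    trial: IMUTrial, combination: CombinationSpec, window_start: int = 0
) -> WalkPattern:
    """Restrict a trial to a combination over a 400-sample window.

    The default window is the first 4 s of the recording.  Row blocks follow
    the combination's location order; within a block the canonical channel
    order (accel v/ml/ap then gyro v/ml/ap) is preserved.
    """
    end = window_start + WINDOW_SAMPLES
    if trial.n_samples < end:
        raise ValueError(
            f"trial has {trial.n_samples} samples but the window "
            f"[{window_start}, {end}) requires {end}"
        )
    matrix = trial.samples[combination.channel_rows(), window_start:end]
    return WalkPattern(
        combination=combination,
        surface=trial.surface,
        matrix=matrix.copy(),
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
    )


@dataclass
class WalkPatternDataset:
    """All walk patterns of one combination, in canonical order."""

    combination: CombinationSpec
    patterns: list[WalkPattern] = field(default_factory=list)

    @property
    def labels(self) -> list[SurfaceClass]:
        return [p.surface for p in self.patterns]

    def __len__(self) -> int:
        return len(self.patterns)

    def stack(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y): X (N, 6n, 400), y integer surface codes."""
        X = np.stack([p.matrix for p in self.patterns]).astype(dtype)
        y = np.array([p.surface.index for p in self.patterns], dtype=np.int64)
        return X, y

    def group_ids(self) -> np.ndarray:
        """One id per source trial; augmented siblings share an id."""
        keys = sorted({(p.participant_id, p.surface.index, p.trial_index) for p in self.patterns})
        lookup = {k: i for i, k in enumerate(keys)}
        return np.array(
            [lookup[(p.participant_id, p.surface.index, p.trial_index)] for p in self.patterns],
            dtype=np.int64,
        )

    def class_counts(self) -> dict[SurfaceClass, int]:
        counts = {s: 0 for s in SurfaceClass}
        for p in self.patterns:
            counts[p.surface] += 1
        return counts


def _canonical_sort(patterns: list[WalkPattern]) -> list[WalkPattern]:
    # interleaves the surface classes so fixed-order (shuffle=never) batches
    # stay class-balanced; deterministic for a given pattern set
    return sorted(
        patterns,
        key=lambda p: (p.participant_id, p.trial_index, p.augmentation_index, p.surface.index),
    )


def assemble_dataset(
    trials: Sequence[IMUTrial],
    combination: CombinationSpec,
    augment_factor: int = 0,
    rng_seed: int = 0,
    window_start: int = 0,
    keep_original: bool = False,
    augment_config=None,
) -> WalkPatternDataset:
    """Build the walk-pattern dataset of one combination from trials.

    With ``augment_factor = a > 0`` each pattern is replaced by ``a``
    rotation-augmented copies (so 60 originals per surface become ``60*a``;
    the study design uses a = 10 giving 600).  With ``keep_original`` the
    original is retained and ``a - 1`` copies are added instead, which
    yields the same counts.

    Raises ``ValueError`` naming any surface class absent from ``trials``.
    """
    present = {t.surface for t in trials}
    missing = [s.value for s in SurfaceClass if s not in present]
    if missing:
        raise ValueError(f"trials missing surface classes: {missing}")

    patterns = [build_walk_pattern(t, combination, window_start) for t in trials]

    if augment_factor > 0:
        from .augment import RotationAugmentConfig, augment_pattern

        config = augment_config or RotationAugmentConfig(
            factor=augment_factor, seed=rng_seed
        )
        rng = np.random.default_rng(rng_seed)
        out: list[WalkPattern] = []
        n_copies = augment_factor - 1 if keep_original else augment_factor
        for p in patterns:
            if keep_original:
                out.append(p)
            if n_copies > 0:
                out.extend(augment_pattern(p, replace(config, factor=n_copies), rng))
        patterns = out

    return WalkPatternDataset(combination=combination, patterns=_canonical_sort(patterns))


@dataclass(frozen=True)
class ComparisonDescriptor:
    """One cell of the significance-screening schedule."""

    mode: Literal["across_surfaces", "across_locations"]
    pair: tuple  # (SurfaceClass, SurfaceClass) or (BodyLocation, BodyLocation)
    sensor: Sensor
    axis: Axis
    context: object  # the fixed BodyLocation (across_surfaces) or SurfaceClass

    @property
    def output(self) -> tuple[Sensor, Axis]:
        return (self.sensor, self.axis)


def comparison_schedule(mode: str) -> list[ComparisonDescriptor]:
    """The full pairwise-comparison schedule for one screening mode.

    ``across_surfaces``: C(7,2)=21 surface pairs x 6 sensor outputs x 6
    locations = 756 descriptors.  ``across_locations``: C(6,2)=15 location
    pairs x 6 outputs x 7 surfaces = 630 descriptors.
    """
    outputs = [(s, a) for s in SENSORS for a in AXES]
    if mode == "across_surfaces":
        return [
            ComparisonDescriptor(mode, pair, sensor, axis, loc)
            for loc in BodyLocation
            for sensor, axis in outputs
            for pair in itertools.combinations(SurfaceClass, 2)
        ]
    if mode == "across_locations":
        return [
            ComparisonDescriptor(mode, pair, sensor, axis, surf)
            for surf in SurfaceClass
            for sensor, axis in outputs
            for pair in itertools.combinations(BodyLocation, 2)
        ]
    raise ValueError(f"unknown schedule mode: {mode!r}")
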