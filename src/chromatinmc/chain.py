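"""Segment-chain model of a chromatin fiber.

Chromatin is represented as a chain of segments: cylindrical linker-DNA
segments connecting nucleosome "stem" segments.  Every segment carries a
position and a right-handed orthonormal local frame (u, v, f); u points
along the segment, i.e. toward the next segment's position, and (v, f)
track torsion.  Nucleosome core particles are spherocylindrical units
placed rigidly relative to their stem segment by a distance ``d`` and six
angles; systems with and without linker histone H1 differ by the angle
set, and additionally by the rest entry/exit kink imposed at the joints
flanking each stem (the H1 "stem" motif narrows the angle between
entering and exiting linker arms, folding the fiber back on itself).

Linker DNA lengths are converted from base pairs at 0.34 nm/bp and
discretized into at least 2 segments; linkers longer than 20 nm get
ceil(length / 10 nm) equal segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .regions import GenomicInterval, NucleosomeSet

NM_PER_BP = 0.34

__all__ = [
    "NM_PER_BP",
    "bp_to_nm",
    "discretize_linker",
    "assign_h1",
    "NucleosomeGeometry",
    "ChainTopology",
    "Configuration",
    "build_chain",
    "nucleosome_center",
    "initial_configuration",
]


def bp_to_nm(length_bp):
    """Convert a DNA length in base pairs to nanometers (0.34 nm/bp)."""
    arr = np.asarray(length_bp, dtype=float)
    if np.any(arr < 0):
        raise ValueError("DNA length must be >= 0 bp")
    out = arr * NM_PER_BP
    return float(out) if np.isscalar(length_bp) or arr.ndim == 0 else out


def discretize_linker(length_nm: float) -> tuple[int, float]:
    """Number of segments and per-segment length for one linker.

    At least 2 segments; above 20 nm the count is ceil(length / 10 nm).
    Returns ``(n_segments, segment_length_nm)``.
    """
    if length_nm <= 0:
        raise ValueError("linker length must be > 0 nm")
    n = 2 if length_nm <= 20.0 else math.ceil(length_nm / 10.0)
    return n, length_nm / n


def assign_h1(
    n_nucleosomes: int, fraction: float, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Independent Bernoulli H1 occupancy per nucleosome.

    ``fraction=1.0`` binds every nucleosome, ``0.0`` none; intermediate
    values emulate a random partial H1 distribution.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if fraction == 1.0:
        return np.ones(n_nucleosomes, dtype=bool)
    if fraction == 0.0:
        return np.zeros(n_nucleosomes, dtype=bool)
    return rng.random(n_nucleosomes) < fraction


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    return _rot_axis(ez, alpha) @ _rot_axis(ey, beta) @ _rot_axis(ez, gamma)


@dataclass
class NucleosomeGeometry:
    """Nucleosome placement and shape parameters (all lengths nm, angles deg).

    The six placement angles are, in order: polar and azimuthal angle of
    the center-offset direction in the (pre-twisted) stem frame; ZYZ Euler
    angles of the nucleosome body frame in that same basis; and a
    pre-twist applied about the stem axis before everything else.  Default
    values realise a generic crossed-linker geometry and are meant to be
    overridden from a config file; the H1 state selects between the two
    angle sets and between the two entry/exit rest kink angles.
    """

    d: float = 8.0
    angles_no_h1: tuple = (90.0, 0.0, 90.0, 90.0, 0.0, 0.0)
    angles_h1: tuple = (85.0, 0.0, 90.0, 85.0, 0.0, 0.0)
    diameter: float = 11.0
    height: float = 5.5
    stem_length: float = 2.5
    entry_exit_deg_no_h1: float = 40.0
    entry_exit_deg_h1: float = 145.0

    def angles(self, h1: bool) -> tuple:
        return self.angles_h1 if h1 else self.angles_no_h1

    def entry_exit_rad(self, h1: bool) -> float:
        return math.radians(self.entry_exit_deg_h1 if h1 else self.entry_exit_deg_no_h1)

    def placement(self, h1: bool) -> tuple[np.ndarray, np.ndarray]:
        """Offset vector (incl. d) and body-frame rotation, in stem-frame coords.

        Lab-frame center = stem midpoint + offset_local @ frame;
        lab-frame body rows = rotation_local @ frame, with ``frame`` the
        (3, 3) matrix whose rows are the stem's (u, v, f).
        """
        th, ph, al, be, ga, tw = (math.radians(a) for a in self.angles(h1))
        ex = np.array([1.0, 0.0, 0.0])
        pre = _rot_axis(ex, tw)  # pre-twist about the stem axis (local x = u)
        direction = np.array(
            [math.cos(th), math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph)]
        ) @ pre.T
        # map the local-z-referenced Euler rotation into the (u, v, f) = (x, y, z) basis
        body = _euler_zyz(al, be, ga)
        rot = body @ pre.T
        return self.d * direction, rot

    @classmethod
    def from_yaml(cls, path) -> "NucleosomeGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        for key in ("angles_no_h1", "angles_h1"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Topology and configuration
# ---------------------------------------------------------------------------

@dataclass
class ChainTopology:
    """Immutable description of the segment chain built from a NucleosomeSet."""

    interval: GenomicInterval
    seg_len0: np.ndarray        # (n,) rest lengths, nm
    is_stem: np.ndarray         # (n,) bool
    joint_bp: np.ndarray        # (n+1,) genomic anchor at each segment boundary
    stem_seg: np.ndarray        # (n_nuc,) stem segment index per nucleosome
    h1_flags: np.ndarray        # (n_nuc,) bool
    geometry: NucleosomeGeometry
    nuc_offset: np.ndarray = field(default=None, repr=False)  # (n_nuc, 3)
    nuc_rot: np.ndarray = field(default=None, repr=False)     # (n_nuc, 3, 3)
    joint_theta0: np.ndarray = field(default=None, repr=False)  # (n-1,) rest bend

    def __post_init__(self) -> None:
        self.seg_len0 = np.asarray(self.seg_len0, float)
        self.is_stem = np.asarray(self.is_stem, bool)
        self.joint_bp = np.asarray(self.joint_bp, float)
        self.stem_seg = np.asarray(self.stem_seg, np.int64)
        self.h1_flags = np.asarray(self.h1_flags, bool)
        n = self.seg_len0.size
        if self.joint_bp.size != n + 1:
            raise ValueError("joint_bp must have n_segments + 1 entries")
        if np.any(self.seg_len0 <= 0):
            raise ValueError("segment rest lengths must be > 0")
        if self.nuc_offset is None:
            self._build_placement()

    def _build_placement(self) -> None:
        n_nuc = self.stem_seg.size
        self.nuc_offset = np.zeros((n_nuc, 3))
        self.nuc_rot = np.zeros((n_nuc, 3, 3))
        for i in range(n_nuc):
            off, rot = self.geometry.placement(bool(self.h1_flags[i]))
            self.nuc_offset[i] = off
            self.nuc_rot[i] = rot
        theta0 = np.zeros(max(self.n_segments - 1, 0))
        for i, s in enumerate(self.stem_seg):
            half = 0.5 * self.geometry.entry_exit_rad(bool(self.h1_flags[i]))
            for j in (s, s + 1):           # joints flanking the stem
                if 1 <= j <= self.n_segments - 1:
                    theta0[j - 1] = half
        self.joint_theta0 = theta0

    @property
    def n_segments(self) -> int:
        return int(self.seg_len0.size)

    @property
    def n_nucleosomes(self) -> int:
        return int(self.stem_seg.size)

    @property
    def contour_length(self) -> float:
        return float(self.seg_len0.sum())

    def joint_index_for_bp(self, bp: float) -> int:
        """Chain joint (segment boundary) nearest to a genomic coordinate."""
        if not self.interval.start <= bp <= self.interval.end:
            raise ValueError(f"bp {bp} outside interval {self.interval}")
        return int(np.argmin(np.abs(self.joint_bp - bp)))

    def with_h1(self, h1_flags: np.ndarray) -> "ChainTopology":
        """Same chain with a different H1 assignment."""
        h1 = np.asarray(h1_flags, bool)
        if h1.size != self.n_nucleosomes:
            raise ValueError("h1_flags length mismatch")
        return ChainTopology(
            self.interval, self.seg_len0, self.is_stem, self.joint_bp,
            self.stem_seg, h1, self.geometry,
        )


@dataclass
class Configuration:
    """Chain coordinates: joint positions and per-segment orthonormal frames."""

    pos: np.ndarray     # (n+1, 3), nm
    frames: np.ndarray  # (n, 3, 3), rows u, v, f

    def copy(self) -> "Configuration":
        return Configuration(self.pos.copy(), self.frames.copy())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.pos[-1] - self.pos[0]))

    def validate(self, tol: float = 1e-9) -> None:
        f = self.frames
        gram = np.einsum("nij,nkj->nik", f, f)
        if np.max(np.abs(gram - np.eye(3))) > tol:
            raise ValueError("frames not orthonormal within tolerance")
        seg = self.pos[1:] - self.pos[:-1]
        u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        if np.max(np.abs(np.cross(u, f[:, 0]))) > 1e-6:
            raise ValueError("u vectors not parallel to segment directions")

    def orthonormalize(self) -> None:
        """Re-align u with segment directions and re-orthogonalize (v, f)."""
        seg = self.pos[1:] - self.pos[:-1]
        u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        v = self.frames[:, 1]
        v = v - np.sum(v * u, axis=1, keepdims=True) * u
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        self.frames[:, 0] = u
        self.frames[:, 1] = v
        self.frames[:, 2] = np.cross(u, v)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_chain(
    ns: NucleosomeSet,
    geometry: NucleosomeGeometry | None = None,
    h1_flags: np.ndarray | None = None,
    min_linker_bp: int = 1,
) -> ChainTopology:
    """Convert a nucleosome set into a simulatable segment chain.

    Linker DNA (including naked DNA at the interval edges) is converted at
    0.34 nm/bp and discretized; each nucleosome contributes one stem
    segment spanning its footprint.  Touching footprints get a
    *min_linker_bp* (default 1 bp = 0.34 nm) stub so the chain stays
    well-defined.  Genomic anchors are preserved at every segment boundary.
    """
    if geometry is None:
        geometry = NucleosomeGeometry()
    n_nuc = len(ns)
    if h1_flags is None:
        h1_flags = np.zeros(n_nuc, dtype=bool)
    h1_flags = np.asarray(h1_flags, bool)
    if h1_flags.size != n_nuc:
        raise ValueError("h1_flags length must match nucleosome count")

    seg_len0: list[float] = []
    is_stem: list[bool] = []
    joint_bp: list[float] = [float(ns.interval.start)]
    stem_seg: list[int] = []

    def add_linker(bp_from: float, bp_to: float) -> None:
        bp_len = bp_to - bp_from
        if bp_len <= 0:
            return
        eff_bp = max(bp_len, min_linker_bp)
        nseg, seg_nm = discretize_linker(bp_to_nm(eff_bp))
        for i in range(nseg):
            seg_len0.append(seg_nm)
            is_stem.append(False)
            joint_bp.append(bp_from + bp_len * (i + 1) / nseg)

    if n_nuc == 0:
        if ns.interval.length <= 0:
            raise ValueError("empty interval")
        add_linker(ns.interval.start, ns.interval.end)
    else:
        cursor = float(ns.interval.start)
        for i in range(n_nuc):
            start, end = float(ns.starts[i]), float(ns.ends[i])
            if start > cursor:
                add_linker(cursor, start)
            elif start < cursor:
                raise ValueError("overlapping or out-of-order footprints")
            else:  # touching: insert minimal stub
                if seg_len0:
                    nseg, seg_nm = discretize_linker(bp_to_nm(min_linker_bp))
                    for _ in range(nseg):
                        seg_len0.append(seg_nm)
                        is_stem.append(False)
                        joint_bp.append(cursor)
            stem_seg.append(len(seg_len0))
            seg_len0.append(geometry.stem_length)
            is_stem.append(True)
            joint_bp.append(end)
            cursor = end
        if cursor < ns.interval.end:
            add_linker(cursor, ns.interval.end)

    return ChainTopology(
        ns.interval,
        np.array(seg_len0),
        np.array(is_stem),
        np.array(joint_bp),
        np.array(stem_seg, np.int64),
        h1_flags,
        geometry,
    )


def nucleosome_center(
    config: Configuration, topology: ChainTopology, index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame center position and body frame of nucleosome *index*.

    A rigid transform of the stem segment's frame by the geometry's
    (d, six angles) for the nucleosome's H1 state.
    """
    s = int(topology.stem_seg[index])
    mid = 0.5 * (config.pos[s] + config.pos[s + 1])
    frame = config.frames[s]
    center = mid + topology.nuc_offset[index] @ frame
    orient = topology.nuc_rot[index] @ frame
    return center, orient


def initial_configuration(
    topology: ChainTopology,
    mode: str = "straight",
    seed=None,
    rng: np.random.Generator | None = None,
    min_separation: float = 1.0,
    max_retries: int = 200,
) -> Configuration:
    """Build a starting configuration.

    ``straight``: collinear segments along x with identity frames.
    ``random_walk``: freely-jointed directions; each placed joint must stay
    at least *min_separation* nm from all earlier joints (set 0 to disable
    self-avoidance), retrying up to *max_retries* whole-chain restarts.
    """
    n = topology.n_segments
    lens = topology.seg_len0
    if mode == "straight":
        pos = np.zeros((n + 1, 3))
        pos[1:, 0] = np.cumsum(lens)
        frames = np.tile(np.eye(3), (n, 1, 1))
        return Configuration(pos, frames)
    if mode != "random_walk":
        raise ValueError(f"unknown mode {mode!r}")

    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        pos = np.zeros((n + 1, 3))
        frames = np.zeros((n, 3, 3))
        ok = True
        for i in range(n):
            placed = False
            for _ in range(50):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pos[i] + lens[i] * u
                if min_separation <= 0 or i == 0 or np.min(
                    np.linalg.norm(pos[: max(i - 1, 1)] - cand, axis=1)
                ) >= min_separation:
                    placed = True
                    break
            if not placed:
                ok = False
                break
            pos[i + 1] = cand
            ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            v = np.cross(ref, u)
            v /= np.linalg.norm(v)
            frames[i] = np.stack([u, v, np.cross(u, v)])
        if ok:
            return Configuration(pos, frames)
    raise RuntimeError(
        f"random_walk placement failed after {max_retries} restarts; "
        "lower min_separation or use straight mode"
    )
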