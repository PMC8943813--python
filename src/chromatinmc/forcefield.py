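"""Force field: elastic, electrostatic, internucleosomal and excluded volume.

The total configuration energy (in kT at the 293 K reference temperature)
is the sum of

* harmonic stretch, bend and twist at every segment/joint, with the bend
  constant per joint calibrated so the discrete chain reproduces the
  requested bending persistence length exactly (see ``docs/methods.md``);
* Debye-Hückel screened repulsion between charge points placed at linker
  segment midpoints (Manning-reduced linear charge density);
* an anisotropic internucleosomal attraction of the Gay-Berne/Zewdie
  family with orientation-dependent range and depth, truncated and
  shifted at the cutoff and depth-normalized so its global minimum
  (coaxial face-to-face stacking) is exactly -E_max;
* capped quartic excluded-volume repulsion between linker cylinders,
  linkers and nucleosomes, and nucleosome pairs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy.optimize import brentq, minimize_scalar

from . import _kernels as K
from .chain import ChainTopology, Configuration, NucleosomeGeometry

__all__ = [
    "ForceField",
    "EnergyBreakdown",
    "EnergyModel",
    "elastic_energy",
    "electrostatic_energy",
    "nucleosome_pair_energy",
    "excluded_volume_energy",
    "total_energy",
    "calibrate_bend_constant",
]

# relative weights of the isotropic, axis-alignment and stacking depth terms;
# stacking-dominated so the attraction drives face-to-face aggregation rather
# than orientation-independent droplet collapse
_EPS_WEIGHTS = (0.1, 0.3, 0.6)


@dataclass
class ForceField:
    """All tunable energy parameters (lengths nm, energies kT, charges e)."""

    stretch_modulus: float = 500.0      # kT/nm^2 harmonic stretch per segment
    bend_persistence: float = 50.0      # nm (DNA bending persistence length)
    torsion_persistence: float = 75.0   # nm
    debye_length: float = 0.96          # nm; 100 mM monovalent salt
    bjerrum_length: float = 0.7         # nm, water at room temperature
    linear_charge: float = 1.4          # e/nm after Manning counterion reduction
    emax: float = 4.0                   # max internucleosomal attraction, kT
    cutoff: float = 20.0                # internucleosomal interaction cutoff, nm
    es_cutoff_factor: float = 6.0       # electrostatic cutoff in Debye lengths
    ev_radius_dna: float = 1.2          # linker DNA radius, nm
    nuc_ev_radius: float = 4.5          # effective nucleosome radius vs. DNA, nm
    ev_cap: float = 1000.0              # excluded-volume cap, kT
    enable_ev: bool = True
    charge_points_per_segment: int = 1

    def __post_init__(self) -> None:
        for name in (
            "stretch_modulus", "bend_persistence", "torsion_persistence",
            "debye_length", "bjerrum_length", "cutoff", "es_cutoff_factor",
            "ev_radius_dna", "nuc_ev_radius", "ev_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.emax < 0:
            raise ValueError("emax must be >= 0")
        if self.charge_points_per_segment < 1:
            raise ValueError("charge_points_per_segment must be >= 1")

    def describe(self) -> dict:
        """All parameters as a plain dict (for provenance output)."""
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.describe(), fh, sort_keys=False)


@dataclass
class EnergyBreakdown:
    stretch: float
    bend: float
    twist: float
    electrostatic: float
    nucleosome: float
    excluded_volume: float

    @property
    def elastic(self) -> float:
        return self.stretch + self.bend + self.twist

    @property
    def total(self) -> float:
        return self.elastic + self.electrostatic + self.nucleosome + self.excluded_volume

    @classmethod
    def from_array(cls, arr) -> "EnergyBreakdown":
        return cls(*(float(x) for x in arr))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.stretch, self.bend, self.twist,
             self.electrostatic, self.nucleosome, self.excluded_volume]
        )


# ---------------------------------------------------------------------------
# Bend-constant calibration
# ---------------------------------------------------------------------------

_THETA_GRID = np.linspace(0.0, math.pi, 2001)
_SIN_GRID = np.sin(_THETA_GRID)
_COS_GRID = np.cos(_THETA_GRID)


def _mean_cos_theta(k: float) -> float:
    w = np.exp(-0.5 * k * _THETA_GRID**2) * _SIN_GRID
    return float(np.trapezoid(w * _COS_GRID) / np.trapezoid(w))


def calibrate_bend_constant(segment_length: float, persistence: float) -> float:
    """Harmonic bend constant (kT/rad^2) giving the requested persistence length.

    Solves <cos θ> = exp(-l/Lp) for the joint constant k under the
    p(θ) ∝ exp(-k θ²/2) sin θ equilibrium density, so that the discrete
    chain's tangent correlation decays exactly as the continuous worm-like
    chain's.  The naive k = Lp/l underestimates Lp by ~l/(2Lp).
    """
    if segment_length <= 0 or persistence <= 0:
        raise ValueError("lengths must be > 0")
    target = math.exp(-segment_length / persistence)
    lo, hi = 1e-3, 1e6
    if _mean_cos_theta(lo) > target:
        return lo
    return float(brentq(lambda k: _mean_cos_theta(k) - target, lo, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# Energy model: kernel-ready arrays
# ---------------------------------------------------------------------------

class EnergyModel:
    """Flattened (topology, force field) pair ready for the numba kernels."""

    def __init__(self, topology: ChainTopology, ff: ForceField):
        self.topology = topology
        self.ff = ff
        n = topology.n_segments
        self.l0 = topology.seg_len0.astype(np.float64)
        self.is_stem = topology.is_stem.astype(np.bool_)
        self.kstretch = np.full(n, ff.stretch_modulus)

        # joint elastic constants; joint j sits between segments j-1 and j
        ljoint = 0.5 * (self.l0[:-1] + self.l0[1:])
        cache: dict[float, float] = {}
        kbend = np.empty(max(n - 1, 0))
        for j, l in enumerate(ljoint):
            key = round(float(l), 9)
            if key not in cache:
                cache[key] = calibrate_bend_constant(float(l), ff.bend_persistence)
            kbend[j] = cache[key]
        self.kbend = kbend
        self.theta0 = topology.joint_theta0.astype(np.float64)
        self.ktwist = ff.torsion_persistence / np.maximum(ljoint, 1e-9)

        self.q = np.where(self.is_stem, 0.0, ff.linear_charge * self.l0)
        self.seg_nuc = np.full(n, -1, np.int64)
        for k, s in enumerate(topology.stem_seg):
            self.seg_nuc[s] = k
        self.stem_seg = topology.stem_seg.astype(np.int64)
        self.nuc_off = topology.nuc_offset.astype(np.float64)
        self.nuc_axis = topology.nuc_rot[:, 2, :].astype(np.float64).copy() \
            if topology.n_nucleosomes else np.zeros((0, 3))

        self.params = self._build_params()

    def _build_params(self) -> np.ndarray:
        ff = self.ff
        geo = self.topology.geometry
        p = np.zeros(K.N_PARAMS)
        p[K.P_LB] = ff.bjerrum_length
        p[K.P_LAM] = ff.debye_length
        es_rc = ff.es_cutoff_factor * ff.debye_length
        p[K.P_ESRC2] = es_rc**2
        p[K.P_EMAX] = ff.emax
        p[K.P_SIGS] = geo.diameter
        p[K.P_SIGE] = geo.height + 0.5
        p[K.P_SIG0] = p[K.P_SIGE]
        p[K.P_RC] = ff.cutoff
        w0, w1, w2 = _EPS_WEIGHTS
        p[K.P_W0], p[K.P_W1], p[K.P_W2] = w0, w1, w2
        p[K.P_CAP] = ff.ev_cap
        p[K.P_RDNA] = ff.ev_radius_dna
        p[K.P_RNUC] = ff.nuc_ev_radius
        p[K.P_NNFRAC] = 0.8
        p[K.P_EVON] = 1.0 if ff.enable_ev else 0.0
        p[K.P_ZMIN] = 0.55
        p[K.P_SCALE] = 1.0
        p[K.P_SCALE] = self._depth_normalization(p)
        # per-class early-exit radii: the midpoint separation over-estimates
        # the closest approach by at most half of each segment length plus,
        # for nucleosomes, the center offset d
        lmax = float(np.max(self.l0))
        p[K.P_SKIP_LL2] = (max(es_rc, 2 * ff.ev_radius_dna) + lmax) ** 2
        p[K.P_SKIP_SS2] = (ff.cutoff + 2 * geo.d + geo.stem_length) ** 2
        p[K.P_SKIP_SL2] = (
            ff.nuc_ev_radius + ff.ev_radius_dna + geo.d
            + 0.5 * (lmax + geo.stem_length)
        ) ** 2
        return p

    def _depth_normalization(self, p: np.ndarray) -> float:
        """Scale so the shifted potential's global minimum is exactly -E_max."""
        if self.ff.emax == 0:
            return 1.0
        e = np.array([0.0, 0.0, 1.0])

        def u_at(r: float) -> float:
            val, _ = K.nuc_pair_terms(0.0, 0.0, r, e[0], e[1], e[2],
                                      e[0], e[1], e[2], p)
            return val

        res = minimize_scalar(
            u_at, bounds=(0.5 * p[K.P_SIGE], p[K.P_RC]), method="bounded",
            options={"xatol": 1e-10},
        )
        depth = -float(res.fun)
        if depth <= 0:
            return 1.0
        return self.ff.emax / depth

    # -- evaluation ---------------------------------------------------------
    def energy_array(self, config: Configuration) -> np.ndarray:
        return K.full_energy(
            config.pos, config.frames, self.l0, self.kstretch, self.is_stem,
            self.seg_nuc, self.q, self.kbend, self.theta0, self.ktwist,
            self.stem_seg, self.nuc_off, self.nuc_axis, self.params,
        )

    def energy(self, config: Configuration) -> EnergyBreakdown:
        return EnergyBreakdown.from_array(self.energy_array(config))


# ---------------------------------------------------------------------------
# Public per-term operations
# ---------------------------------------------------------------------------

def elastic_energy(
    config: Configuration, topology: ChainTopology, ff: ForceField
) -> EnergyBreakdown:
    """Stretch + bend + twist terms only (other terms reported as zero)."""
    m = EnergyModel(topology, ff)
    e_s, e_b, e_t = K.elastic_full(
        config.pos, config.frames, m.l0, m.kstretch, m.kbend, m.theta0, m.ktwist
    )
    return EnergyBreakdown(e_s, e_b, e_t, 0.0, 0.0, 0.0)


def electrostatic_energy(
    config: Configuration,
    topology: ChainTopology,
    ff: ForceField,
    points_per_segment: int | None = None,
) -> float:
    """Screened Debye-Hückel repulsion between non-adjacent linker segments.

    With ``points_per_segment > 1`` each linker segment's charge is spread
    over equally spaced points along its axis (refinement of the default
    midpoint-charge approximation); the kernel path is the 1-point case.
    """
    m = EnergyModel(topology, ff)
    npts = ff.charge_points_per_segment if points_per_segment is None else points_per_segment
    if npts == 1:
        es, _, _ = K.nonbonded_full(
            config.pos, config.frames, m.is_stem, m.seg_nuc, m.q,
            m.stem_seg, m.nuc_off, m.nuc_axis, m.params,
        )
        return float(es)
    # refined: sub-charges along each linker axis, same exclusions
    linkers = np.nonzero(~m.is_stem)[0]
    frac = (np.arange(npts) + 0.5) / npts
    pts, qs, seg_of = [], [], []
    for i in linkers:
        a, b = config.pos[i], config.pos[i + 1]
        pts.append(a[None, :] + frac[:, None] * (b - a)[None, :])
        qs.append(np.full(npts, m.q[i] / npts))
        seg_of.append(np.full(npts, i))
    if not pts:
        return 0.0
    pts = np.concatenate(pts)
    qs = np.concatenate(qs)
    seg_of = np.concatenate(seg_of)
    rc = ff.es_cutoff_factor * ff.debye_length
    total = 0.0
    for i in range(pts.shape[0]):
        d = pts[i + 1:] - pts[i]
        r = np.linalg.norm(d, axis=1)
        mask = (np.abs(seg_of[i + 1:] - seg_of[i]) >= 2) & (r < rc) & (r > 0)
        if np.any(mask):
            total += ff.bjerrum_length * qs[i] * np.sum(
                qs[i + 1:][mask] * np.exp(-r[mask] / ff.debye_length) / r[mask]
            )
    return float(total)


def nucleosome_pair_energy(
    center_i,
    orient_i,
    center_j,
    orient_j,
    ff: ForceField,
    geometry: NucleosomeGeometry | None = None,
) -> float:
    """Anisotropic internucleosomal interaction for one pair (kT).

    *orient* may be a full (3, 3) body frame (symmetry axis = row 2 / f)
    or a bare 3-vector axis.  Zero beyond the cutoff; global minimum
    -E_max at coaxial face-to-face stacking.
    """
    if geometry is None:
        geometry = NucleosomeGeometry()
    model = _pair_model(ff, geometry)
    ei = np.asarray(orient_i, float)
    ej = np.asarray(orient_j, float)
    if ei.ndim == 2:
        ei = ei[2]
    if ej.ndim == 2:
        ej = ej[2]
    r = np.asarray(center_j, float) - np.asarray(center_i, float)
    e_nuc, _ = K.nuc_pair_terms(
        r[0], r[1], r[2], ei[0], ei[1], ei[2], ej[0], ej[1], ej[2], model.params
    )
    return float(e_nuc)


_pair_model_cache: dict[tuple, EnergyModel] = {}


def _pair_model(ff: ForceField, geometry: NucleosomeGeometry) -> EnergyModel:
    """Minimal two-nucleosome model used for standalone pair evaluation."""
    key = (tuple(sorted(ff.describe().items())), geometry.d, geometry.diameter,
           geometry.height, geometry.stem_length)
    if key not in _pair_model_cache:
        from .regions import GenomicInterval, NucleosomeSet
        from .chain import build_chain

        ns = NucleosomeSet(
            GenomicInterval("toy", 0, 1000),
            np.array([100, 500]), np.array([147, 147]), np.array([1.0, 1.0]),
        )
        topo = build_chain(ns, geometry)
        _pair_model_cache[key] = EnergyModel(topo, ff)
    return _pair_model_cache[key]


def excluded_volume_energy(
    config: Configuration, topology: ChainTopology, ff: ForceField
) -> float:
    """Capped quartic overlap penalty over all non-bonded pair classes."""
    m = EnergyModel(topology, ff)
    _, _, ev = K.nonbonded_full(
        config.pos, config.frames, m.is_stem, m.seg_nuc, m.q,
        m.stem_seg, m.nuc_off, m.nuc_axis, m.params,
    )
    return float(ev)


def total_energy(
    config: Configuration, topology: ChainTopology, ff: ForceField
) -> EnergyBreakdown:
    """Per-term and total configuration energy in kT."""
    return EnergyModel(topology, ff).energy(config)
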