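"""Energy terms: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

from chromatinmc.chain import (
    ChainTopology,
    Configuration,
    NucleosomeGeometry,
    build_chain,
    initial_configuration,
)
from chromatinmc.forcefield import (
    ForceField,
    calibrate_bend_constant,
    elastic_energy,
    electrostatic_energy,
    excluded_volume_energy,
    nucleosome_pair_energy,
    total_energy,
)
from chromatinmc.regions import GenomicInterval, NucleosomeSet
from chromatinmc.sampler import MCState


def _bare_topology(seg_lengths):
    """Naked-DNA topology with explicit segment lengths (test scaffold)."""
    seg_lengths = np.asarray(seg_lengths, float)
    n = seg_lengths.size
    bp = np.concatenate([[0.0], np.cumsum(seg_lengths)]) / 0.34
    iv = GenomicInterval("chrT", 0, int(math.ceil(bp[-1])) + 1)
    return ChainTopology(
        iv, seg_lengths, np.zeros(n, bool), bp, np.zeros(0, np.int64),
        np.zeros(0, bool), NucleosomeGeometry(),
    )


def _config_from_positions(pos):
    pos = np.asarray(pos, float)
    n = pos.shape[0] - 1
    cfg = Configuration(pos, np.zeros((n, 3, 3)))
    cfg.frames[:, 1] = [0.0, 0.0, 1.0]
    seg = pos[1:] - pos[:-1]
    u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    cfg.frames[:, 0] = u
    v = cfg.frames[:, 1] - np.sum(cfg.frames[:, 1] * u, axis=1, keepdims=True) * u
    if np.any(np.linalg.norm(v, axis=1) < 1e-9):
        cfg.frames[:, 1] = [1.0, 0.0, 0.0]
        v = cfg.frames[:, 1] - np.sum(cfg.frames[:, 1] * u, axis=1, keepdims=True) * u
    cfg.frames[:, 1] = v / np.linalg.norm(v, axis=1, keepdims=True)
    cfg.frames[:, 2] = np.cross(cfg.frames[:, 0], cfg.frames[:, 1])
    return cfg


class TestElastic:
    def test_straight_relaxed_chain_zero(self, naked_topology, straight_config, elastic_ff):
        e = elastic_energy(straight_config, naked_topology, elastic_ff)
        assert e.total == pytest.approx(0.0, abs=1e-20)

    def test_single_joint_harmonic_closed_form(self, elastic_ff):
        l = 10.0
        topo = _bare_topology([l, l])
        k = calibrate_bend_constant(l, elastic_ff.bend_persistence)
        for theta in (0.2, 0.4):
            pos = np.array(
                [[0, 0, 0], [l, 0, 0],
                 [l + l * math.cos(theta), l * math.sin(theta), 0]]
            )
            cfg = _config_from_positions(pos)
            e = elastic_energy(cfg, topo, elastic_ff)
            assert e.bend == pytest.approx(0.5 * k * theta**2, rel=1e-6)
        # doubling the angle quadruples the energy
        e1 = 0.5 * k * 0.2**2
        e2 = 0.5 * k * 0.4**2
        assert e2 / e1 == pytest.approx(4.0)

    def test_stretch_quadratic(self, elastic_ff):
        topo = _bare_topology([10.0])
        cfg = _config_from_positions([[0, 0, 0], [11.0, 0, 0]])
        e = elastic_energy(cfg, topo, elastic_ff)
        assert e.stretch == pytest.approx(0.5 * elastic_ff.stretch_modulus * 1.0**2)


class TestElectrostatics:
    def _hairpin(self, sep):
        """Two antiparallel 10-nm rods a distance sep apart, joined by a spacer."""
        topo = _bare_topology([10.0, sep, 10.0])
        pos = [[0, 0, 0], [10, 0, 0], [10, sep, 0], [0, sep, 0]]
        return topo, _config_from_positions(pos)

    def test_screening_limit(self):
        ff = ForceField()
        sep = 20 * ff.debye_length
        topo, cfg = self._hairpin(sep)
        assert electrostatic_energy(cfg, topo, ff) < 1e-6

    def test_monotone_in_separation(self):
        ff = ForceField()
        topo1, cfg1 = self._hairpin(4.0)
        topo2, cfg2 = self._hairpin(2.0)
        e_far = electrostatic_energy(cfg1, topo1, ff)
        e_near = electrostatic_energy(cfg2, topo2, ff)
        assert 0 < e_far < e_near

    def test_parallel_rods_vs_quadrature(self):
        """Refined charge discretization matches the screened double line integral.

        The cutoff is pushed far out so that truncation does not enter the
        comparison; only the discretization of the line charge is tested.
        """
        ff = ForceField(es_cutoff_factor=40.0)
        sep = 5.0
        topo, cfg = self._hairpin(sep)
        e_model = electrostatic_energy(cfg, topo, ff, points_per_segment=60)
        lam, lB, nu = ff.debye_length, ff.bjerrum_length, ff.linear_charge

        def integrand(t, s):
            r = math.sqrt((s - t) ** 2 + sep**2)
            return math.exp(-r / lam) / r

        integral, _ = dblquad(integrand, 0, 10, 0, 10, epsabs=1e-12)
        e_exact = lB * nu**2 * integral
        assert e_model == pytest.approx(e_exact, rel=0.02)


class TestNucleosomePair:
    @pytest.mark.parametrize("emax", [4.0, 6.0])
    def test_optimal_stacking_reaches_minus_emax(self, emax):
        ff = ForceField(emax=emax)
        ez = np.array([0.0, 0.0, 1.0])
        rs = np.linspace(4.0, 19.9, 400)
        vals = [
            nucleosome_pair_energy([0, 0, 0], ez, [0, 0, r], ez, ff) for r in rs
        ]
        assert min(vals) == pytest.approx(-emax, rel=1e-3)

    def test_zero_beyond_cutoff(self):
        ff = ForceField()
        ez = np.array([0.0, 0.0, 1.0])
        assert nucleosome_pair_energy([0, 0, 0], ez, [0, 0, ff.cutoff + 0.1], ez, ff) == 0.0

    def test_emax_zero_pure_repulsion_off(self):
        ff = ForceField(emax=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            e1 = rng.normal(size=3)
            e1 /= np.linalg.norm(e1)
            e2 = rng.normal(size=3)
            e2 /= np.linalg.norm(e2)
            r = rng.uniform(3, 25, size=3)
            assert nucleosome_pair_energy([0, 0, 0], e1, r, e2, ff) == 0.0

    def test_deeper_attraction_with_larger_emax(self):
        ez = np.array([0.0, 0.0, 1.0])
        e4 = nucleosome_pair_energy([0, 0, 0], ez, [0, 0, 6.0], ez, ForceField(emax=4.0))
        e6 = nucleosome_pair_energy([0, 0, 0], ez, [0, 0, 6.0], ez, ForceField(emax=6.0))
        assert e6 < e4 < 0


class TestExcludedVolume:
    def test_straight_chain_zero(self, naked_topology, straight_config):
        assert excluded_volume_energy(straight_config, naked_topology, ForceField()) == 0.0

    def test_coincident_nucleosomes_forbidden(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        # collapse the chain so two stems coincide
        s0, s1 = topo.stem_seg[0], topo.stem_seg[1]
        shift = cfg.pos[s0] - cfg.pos[s1]
        cfg.pos[s1:] += shift
        e = excluded_volume_energy(cfg, topo, ForceField())
        assert e > 100.0

    def test_continuity_across_contact(self):
        # two antiparallel linker rods scanned through contact distance
        ff = ForceField()
        vals = []
        seps = np.linspace(1.5 * ff.ev_radius_dna, 3.0 * ff.ev_radius_dna, 60)
        for sep in seps:
            topo = _bare_topology([10.0, float(sep), 10.0])
            cfg = _config_from_positions(
                [[0, 0, 0], [10, 0, 0], [10, sep, 0], [0, sep, 0]]
            )
            vals.append(excluded_volume_energy(cfg, topo, ff))
        vals = np.array(vals)
        assert vals[0] > 0 and vals[-1] == 0.0
        # monotone decay to zero with no jump at the contact distance
        assert np.all(np.diff(vals) <= 1e-12)
        last_pos = vals[vals > 0][-1]
        assert last_pos < 0.05


class TestTotalEnergy:
    def test_straight_dilute_chain_electrostatics_only(self, naked_topology, straight_config):
        e = total_energy(straight_config, naked_topology, ForceField())
        assert e.elastic == pytest.approx(0.0, abs=1e-12)
        assert e.excluded_volume == 0.0
        assert e.nucleosome == 0.0
        assert e.total == pytest.approx(e.electrostatic)

    def test_incremental_equals_full(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        st = MCState(topo, ForceField(), cfg, seed=3)
        st.run(2000, 1.5, refresh=True)
        assert st.last_drift < 1e-6

    def test_isometry_invariance(self, small_set):
        topo = build_chain(small_set)
        ff = ForceField()
        cfg = initial_configuration(topo, "random_walk", seed=4, min_separation=3.0)
        e0 = total_energy(cfg, topo, ff)
        theta = 1.1
        R = np.array(
            [[math.cos(theta), 0, math.sin(theta)],
             [0, 1, 0],
             [-math.sin(theta), 0, math.cos(theta)]]
        )
        cfg.pos[:] = cfg.pos @ R.T + np.array([5.0, -3.0, 2.0])
        cfg.frames[:] = np.einsum("ij,nkj->nki", R, cfg.frames)
        e1 = total_energy(cfg, topo, ff)
        np.testing.assert_allclose(e1.as_array(), e0.as_array(), atol=1e-8)
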