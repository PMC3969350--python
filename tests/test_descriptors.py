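"""The five descriptors: lipophilic intensity, moments, HBD surface terms."""

import numpy as np
import pytest

from conftest import random_rotation
from cyclodesc.descriptors import (
    ResidueLipo,
    compute_descriptors,
    exclusive_lipophilicity,
    hbd_amphipathic_moment,
    hbd_surface_area,
    lipophilic_moment,
    lipophilic_resultant,
    loop_lipophilicity_profile,
    residue_lipophilicity,
    total_lipophilicity,
)
from cyclodesc.fixtures import SyntheticSpec, make_cck_toy, make_toy_peptide
from cyclodesc.lipo_scale import ScaleEntry, max_sidechain_sasa
from cyclodesc.structpep import Atom, Peptide, UnsupportedResidueError, assign_loops, \
    build_extended_tripeptide, make_residue
from cyclodesc.surface import classify_hbd, electrostatic_potential, shrake_rupley


def rl(intensity, direction, scale_value=None):
    direction = np.asarray(direction, float)
    n = np.linalg.norm(direction)
    return ResidueLipo(
        residue_index=0, intensity=intensity,
        direction=direction / n if n else direction,
        normalized_scale=scale_value if scale_value is not None else intensity,
    )


class TestResidueLipophilicity:
    def test_fully_exposed_tripeptide_reaches_scale_value(self, scale):
        # with sasa_max computed by the same pipeline the exposure fraction
        # of the central residue in Gly-X-Gly is exactly 1
        code = "ILE"
        own_max = max_sidechain_sasa(code)
        scale.add_entry(ScaleEntry(code=code, name="Ile", sasa_max=own_max,
                                   normalized=0.38))
        pep = build_extended_tripeptide(code)
        sasa, _ = shrake_rupley(pep)
        out = residue_lipophilicity(pep, scale, sasa)
        assert out[1].intensity == pytest.approx(0.38, abs=1e-9)

    def test_buried_residue_has_zero_intensity(self, scale):
        pep = make_toy_peptide(SyntheticSpec(n_residues=8, seed=0))
        sasa = np.zeros(len(pep.atoms))
        out = residue_lipophilicity(pep, scale, sasa)
        assert all(r.intensity == 0.0 for r in out)

    def test_burial_reduces_intensity_of_same_residue(self, scale):
        # the same Trp side chain, exposed vs crowded by neighbours
        def scaffold(crowded):
            residues = [make_residue("TRP", 1, [
                Atom("CA", "C", np.array([0.0, 0.0, 0.0]), 1.70),
                Atom("CB", "C", np.array([0.0, 0.0, 2.0]), 1.70),
            ])]
            if crowded:
                for i, (x, y) in enumerate([(2.2, 0), (-2.2, 0), (0, 2.2), (0, -2.2)],
                                           start=2):
                    residues.append(make_residue("GLY", i, [
                        Atom("CA", "C", np.array([x, y, 2.0]), 1.70)]))
            return Peptide(label="w", residues=residues)

        def trp_intensity(pep):
            sasa, _ = shrake_rupley(pep)
            return residue_lipophilicity(pep, scale, sasa)[0].intensity

        assert trp_intensity(scaffold(True)) < trp_intensity(scaffold(False))

    def test_unknown_residue_lists_codes(self, scale):
        pep = Peptide(label="u", residues=[make_residue("XXX", 1, [
            Atom("CA", "C", np.zeros(3), 1.7),
            Atom("CB", "C", np.array([1.5, 0, 0]), 1.7)])])
        with pytest.raises(UnsupportedResidueError, match="XXX"):
            residue_lipophilicity(pep, scale, np.zeros(2))


class TestLipophilicMoment:
    def test_symmetric_cancellation(self):
        residues = [rl(0.3, d) for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]]
        assert lipophilic_moment(residues) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self, rng):
        residues = [rl(v, rng.normal(size=3)) for v in rng.uniform(-0.5, 0.5, 12)]
        m0 = lipophilic_moment(residues)
        R = random_rotation(rng)
        rotated = [rl(r.intensity, R @ r.direction, r.normalized_scale)
                   for r in residues]
        assert lipophilic_moment(rotated) == pytest.approx(m0, abs=1e-9)

    def test_segregated_exceeds_scrambled(self, scale, rng):
        pep = make_toy_peptide(SyntheticSpec(n_residues=30, seed=11,
                                             spatial_segregation=1.0))
        sasa, _ = shrake_rupley(pep)
        ordered = residue_lipophilicity(pep, scale, sasa)
        m_ordered = lipophilic_moment(ordered)
        scrambled_max = 0.0
        for _ in range(20):
            perm = rng.permutation(len(ordered))
            scrambled = [
                ResidueLipo(residue_index=i,
                            intensity=ordered[p].intensity,
                            direction=ordered[i].direction,
                            normalized_scale=ordered[p].normalized_scale)
                for i, p in enumerate(perm)
            ]
            scrambled_max = max(scrambled_max, lipophilic_moment(scrambled))
        assert m_ordered > scrambled_max

    def test_empty_is_zero(self):
        assert lipophilic_moment([]) == 0.0


class TestScalarLipophilicity:
    def test_all_lipophobic(self):
        residues = [rl(-0.2, (1, 0, 0), -0.4), rl(-0.1, (0, 1, 0), -0.2)]
        assert total_lipophilicity(residues) < 0
        assert exclusive_lipophilicity(residues) == 0.0

    def test_single_lipophilic_residue(self):
        residues = [rl(0.25, (0, 0, 1), 0.38)]
        assert total_lipophilicity(residues) == pytest.approx(0.25)
        assert exclusive_lipophilicity(residues) == pytest.approx(0.25)

    def test_opposite_lipophobe_lowers_ls_not_lsstar(self):
        cluster = [rl(0.3, (0, 0, 1), 0.38), rl(0.2, (0.1, 0, 1), 0.19)]
        with_phobe = cluster + [rl(-0.4, (0, 0, -1), -0.62)]
        assert total_lipophilicity(with_phobe) < total_lipophilicity(cluster)
        assert exclusive_lipophilicity(with_phobe) == pytest.approx(
            exclusive_lipophilicity(cluster))

    def test_zero_resultant_falls_back_with_warning(self):
        residues = [rl(0.3, (1, 0, 0), 0.3), rl(0.3, (-1, 0, 0), 0.3)]
        with pytest.warns(UserWarning, match="zero lipophilic resultant"):
            val = exclusive_lipophilicity(residues)
        assert val == pytest.approx(0.6)


def polar_fixture(radius=10.0, equal_radii=True, n_pos=1, n_hyd=1):
    """Charged tips on the +z pole, hydrophobic tips on the -z pole."""
    residues = []
    idx = 1
    r_h = 1.55 if equal_radii else 1.70
    for i in range(n_pos):
        x = 3.0 * i
        residues.append(make_residue("LYS", idx, [
            Atom("NZ", "N", np.array([x, 0.0, radius]), 1.55)]))
        idx += 1
    for i in range(n_hyd):
        x = 3.0 * i
        a = Atom("CG1", "C", np.array([x, 0.0, -radius]), r_h)
        residues.append(make_residue("ILE", idx, [a]))
        idx += 1
    return Peptide(label="poles", residues=residues)


def run_surface(pep):
    sasa, s = shrake_rupley(pep)
    electrostatic_potential(pep, s)
    classify_hbd(pep, s)
    return s


class TestHbdDescriptors:
    def test_no_charges_zero_es(self, scale):
        pep = Peptide(label="n", residues=[make_residue("ALA", 1, [
            Atom("CB", "C", np.zeros(3), 1.7)])])
        s = run_surface(pep)
        assert hbd_surface_area(s) == 0.0

    def test_two_lys_exceed_one(self, scale):
        one = run_surface(polar_fixture(n_pos=1))
        two = run_surface(polar_fixture(n_pos=2))
        assert hbd_surface_area(two) > hbd_surface_area(one)

    def test_es_area_scaling(self):
        """Doubling every length (coordinates, radii, probe) quadruples E_S."""
        pep1 = polar_fixture()
        sasa, s1 = shrake_rupley(pep1, probe=1.4)
        electrostatic_potential(pep1, s1)
        classify_hbd(pep1, s1)
        pep2 = polar_fixture()
        for a in pep2.atoms:
            a.coords = a.coords * 2.0
            a.vdw_radius = a.vdw_radius * 2.0
        _, s2 = shrake_rupley(pep2, probe=2.8)
        electrostatic_potential(pep2, s2)
        classify_hbd(pep2, s2)
        assert hbd_surface_area(s2) == pytest.approx(4 * hbd_surface_area(s1),
                                                     rel=1e-6)

    def test_em_pole_separation(self, scale):
        pep = polar_fixture(radius=10.0, equal_radii=True)
        s = run_surface(pep)
        # single spheres at z = ±10 with equal radii: centroid separation 20 Å
        assert hbd_amphipathic_moment(pep, s, scale) == pytest.approx(20.0, rel=0.05)

    def test_em_cocentered_symmetric_fixture_is_zero(self, scale):
        # charged and hydrophobic tips arranged with a common centroid and
        # equal sphere radii: the quadrature offsets cancel exactly
        residues = [
            make_residue("LYS", 1, [Atom("NZ", "N", np.array([10.0, 0, 0]), 1.55)]),
            make_residue("LYS", 2, [Atom("NZ", "N", np.array([-10.0, 0, 0]), 1.55)]),
            make_residue("ILE", 3, [Atom("CG1", "C", np.array([0, 10.0, 0]), 1.55)]),
            make_residue("ILE", 4, [Atom("CG1", "C", np.array([0, -10.0, 0]), 1.55)]),
        ]
        pep = Peptide(label="sym", residues=residues)
        s = run_surface(pep)
        assert hbd_amphipathic_moment(pep, s, scale) == pytest.approx(0.0, abs=1e-6)

    def test_em_translation_invariance(self, scale):
        pep = polar_fixture()
        e0 = hbd_amphipathic_moment(pep, run_surface(pep), scale)
        pep.translate([7.0, -3.0, 2.0])
        e1 = hbd_amphipathic_moment(pep, run_surface(pep), scale)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestLoopProfile:
    def test_all_gly_loop_is_zero(self, scale):
        pep = make_cck_toy([["GLY", "GLY"], ["ILE"], ["TRP"], ["SER"], ["PHE"], []])
        assign_loops(pep)
        sasa, _ = shrake_rupley(pep)
        profile = loop_lipophilicity_profile(
            pep, residue_lipophilicity(pep, scale, sasa))
        assert profile[1] == 0.0

    def test_partition_identity(self, scale):
        pep = make_cck_toy([["ALA", "ILE"], ["ASN"], ["TRP"], ["GLU"], ["PHE"],
                            ["SER", "THR"]])
        assign_loops(pep)
        sasa, _ = shrake_rupley(pep)
        residues = residue_lipophilicity(pep, scale, sasa)
        profile = loop_lipophilicity_profile(pep, residues)
        cys_sum = sum(r.intensity for r, res in zip(residues, pep.residues)
                      if res.code == "CYS")
        assert sum(profile.values()) == pytest.approx(
            total_lipophilicity(residues) - cys_sum, abs=1e-9)

    def test_lipophilic_loop5_is_maximal(self, scale):
        pep = make_cck_toy([["SER"], ["ASN"], ["THR"], ["SER"],
                            ["TRP", "ILE", "PHE"], ["ASN"]])
        assign_loops(pep, anchor=0)  # file convention: residue 1 is the loop-1 Cys
        sasa, _ = shrake_rupley(pep)
        profile = loop_lipophilicity_profile(
            pep, residue_lipophilicity(pep, scale, sasa))
        assert max(profile, key=profile.get) == 5

    def test_unassigned_loops_raise(self, scale):
        pep = make_toy_peptide(SyntheticSpec(n_residues=8, seed=1))
        sasa, _ = shrake_rupley(pep)
        residues = residue_lipophilicity(pep, scale, sasa)
        with pytest.raises(ValueError, match="assign_loops"):
            loop_lipophilicity_profile(pep, residues)


class TestDescriptorSetProperties:
    def test_deterministic_recomputation(self, scale):
        pep = make_toy_peptide(SyntheticSpec(n_residues=16, seed=9))
        d1 = compute_descriptors(pep, scale)
        d2 = compute_descriptors(pep, scale)
        assert d1 == d2

    def test_moment_plot_populations_linearly_separable(self, scale):
        high, low = [], []
        for seed in range(8):
            dh = compute_descriptors(make_toy_peptide(SyntheticSpec(
                seed=seed, spatial_segregation=1.0)), scale)
            dl = compute_descriptors(make_toy_peptide(SyntheticSpec(
                seed=seed, spatial_segregation=0.0)), scale)
            high.append((dh.L_M, dh.E_M))
            low.append((dl.L_M, dl.E_M))
        # a threshold on L_M alone already separates the populations,
        # hence the two clusters are linearly separable in the plane
        assert min(p[0] for p in high) > max(p[0] for p in low)
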