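from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cosolvmap.pmap import PreferableSurface
from cosolvmap.probes import get_probe
from cosolvmap.profile import (
    EXCLUDED,
    ResidueTypeScheme,
    UnknownResidueError,
    build_profile,
    classify_residue,
    extract_environments,
    probe_on_surface,
    profile_geometry_for,
    residues_within,
    superpose_probe,
)
from cosolvmap.superpose import RigidTransform
from cosolvmap.trajectory import AtomRecord, ProbeInstance, ResidueRecord
from oracles import brute_on_surface, brute_residues_within, horn_superpose


def make_probe_instance(coords_by_name, alignment, mappings):
    return ProbeInstance(
        copy_id="P1",
        atoms=[AtomRecord(n, n[0], c) for n, c in coords_by_name.items()],
        alignment_atom_names=list(alignment),
        symmetry_mappings=[list(m) for m in mappings],
    )


def make_residue(resname, cb, resseq=1):
    res = ResidueRecord(resname, "A", resseq)
    res.atoms.append(AtomRecord("CA", "C", np.asarray(cb) + [0, 0, 1.53]))
    if resname != "GLY":
        res.atoms.append(AtomRecord("CB", "C", cb))
    return res


def make_surface(member, origin=(0, 0, 0), spacing=1.0, theta=0.2):
    return PreferableSurface(
        member=np.asarray(member, dtype=bool),
        theta=theta,
        origin=np.asarray(origin, dtype=float),
        spacing=spacing,
    )


class TestResidueTypeScheme:
    SCHEME = ResidueTypeScheme.default()

    @pytest.mark.parametrize(
        "resname,expected",
        [
            ("ASP", "acidic"), ("GLU", "acidic"),
            ("ARG", "basic"), ("HIS", "basic"), ("LYS", "basic"),
            ("ASN", "hydrophilic"), ("CYS", "hydrophilic"), ("GLN", "hydrophilic"),
            ("SER", "hydrophilic"), ("THR", "hydrophilic"),
            ("ALA", "hydrophobic"), ("ILE", "hydrophobic"), ("LEU", "hydrophobic"),
            ("MET", "hydrophobic"), ("PRO", "hydrophobic"), ("VAL", "hydrophobic"),
            ("PHE", "aromatic"), ("TRP", "aromatic"), ("TYR", "aromatic"),
        ],
    )
    def test_table_assignments(self, resname, expected):
        assert classify_residue(resname, self.SCHEME) == expected

    def test_glycine_excluded(self):
        assert classify_residue("GLY", self.SCHEME) == EXCLUDED

    def test_covers_exactly_19_residues(self):
        assert len(self.SCHEME.mapping) == 19
        assert len(self.SCHEME.types) == 5

    def test_unknown_raises_by_default(self):
        with pytest.raises(UnknownResidueError):
            classify_residue("XYZ", self.SCHEME)

    def test_unknown_warns_when_lenient(self):
        assert classify_residue("XYZ", self.SCHEME, strict=False) == EXCLUDED


class TestProbeOnSurface:
    def test_all_atoms_outside(self):
        member = np.zeros((4, 4, 4), dtype=bool)
        member[0, 0, 0] = True
        probe = make_probe_instance({"C1": [3.5, 3.5, 3.5]}, ["C1"], [["C1"]])
        assert not probe_on_surface(probe, make_surface(member))

    def test_atom_at_member_center(self):
        member = np.zeros((4, 4, 4), dtype=bool)
        member[2, 1, 3] = True
        probe = make_probe_instance({"C1": [2.5, 1.5, 3.5]}, ["C1"], [["C1"]])
        assert probe_on_surface(probe, make_surface(member))

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            member = rng.random((5, 5, 5)) < 0.2
            coords = {f"C{i}": rng.uniform(-1, 6, 3) for i in range(1, 4)}
            probe = make_probe_instance(coords, ["C1", "C2", "C3"], [["C1", "C2", "C3"]])
            expected = brute_on_surface(
                probe.heavy_coords(), member, (0, 0, 0), 1.0
            )
            assert probe_on_surface(probe, make_surface(member)) == expected


class TestResiduesWithin:
    def test_boundary_cases(self):
        probe = make_probe_instance({"C1": [0.0, 0.0, 0.0]}, ["C1"], [["C1"]])
        near = make_residue("ASP", [3.9, 0, 0], resseq=1)
        far = make_residue("ASP", [4.1, 0, 0], resseq=2)
        out = residues_within(probe, [near, far], cutoff=4.0)
        assert [r.resseq for r in out] == [1]

    def test_exactly_at_cutoff_included(self):
        probe = make_probe_instance({"C1": [0.0, 0.0, 0.0]}, ["C1"], [["C1"]])
        res = make_residue("SER", [4.0, 0, 0])
        assert residues_within(probe, [res], cutoff=4.0) == [res]

    def test_distant_probe_empty(self):
        probe = make_probe_instance({"C1": [50.0, 50.0, 50.0]}, ["C1"], [["C1"]])
        assert residues_within(probe, [make_residue("ASP", [0, 0, 0])]) == []

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            coords = {f"C{i}": rng.uniform(0, 10, 3) for i in range(1, 4)}
            probe = make_probe_instance(coords, ["C1", "C2", "C3"], [["C1", "C2", "C3"]])
            residues = [
                make_residue("ASP", rng.uniform(0, 14, 3), resseq=i) for i in range(50)
            ]
            result = residues_within(probe, residues, cutoff=4.0)
            expected_idx = brute_residues_within(
                probe.heavy_coords(),
                [r.heavy_coords() for r in residues],
                4.0,
            )
            assert [r.resseq for r in result] == expected_idx


class TestSuperposeProbe:
    def test_identity(self, vprobe):
        probe = make_probe_instance(
            {n: vprobe.atoms[n] for n in vprobe.atom_names},
            vprobe.alignment_atom_names,
            vprobe.symmetry_mappings,
        )
        transform, rmsd = superpose_probe(probe, vprobe)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0, atol=1e-9)

    def test_recovers_random_rotation(self, vprobe, rng):
        rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True).as_matrix()
        t = rng.uniform(-20, 20, 3)
        probe = make_probe_instance(
            {n: rot @ vprobe.atoms[n] + t for n in vprobe.atom_names},
            vprobe.alignment_atom_names,
            vprobe.symmetry_mappings,
        )
        transform, rmsd = superpose_probe(probe, vprobe)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # for a symmetric probe the winning mapping may be the swapped one,
        # so compare the recovered *site set*, not per-name positions
        back = transform.apply(probe.coords_of(vprobe.alignment_atom_names))
        ref = vprobe.alignment_coords()
        for site in back:
            assert np.min(np.linalg.norm(ref - site, axis=1)) < 1e-6

    def test_matches_quaternion_oracle(self, rng):
        # non-planar point set: the optimal rotation is unique, so the
        # matrices themselves must agree (planar sets admit two optima)
        from cosolvmap.probes import ProbeDefinition

        reference = ProbeDefinition(
            name="bent", resname="BNT",
            atoms={
                "A": np.array([1.2, 0.1, 0.4]),
                "B": np.array([-1.0, 0.3, -0.2]),
                "C": np.array([0.2, 1.1, 0.6]),
                "D": np.array([-0.1, -0.9, -0.8]),
            },
            alignment_atom_names=["A", "B", "C", "D"],
        )
        coords = {n: reference.atoms[n] + rng.normal(0, 0.2, 3) for n in reference.atom_names}
        probe = make_probe_instance(coords, reference.alignment_atom_names, [reference.alignment_atom_names])
        transform, rmsd = superpose_probe(probe, reference)
        o_rot, o_t, o_rmsd = horn_superpose(
            probe.coords_of(reference.alignment_atom_names), reference.alignment_coords()
        )
        assert rmsd == pytest.approx(o_rmsd, abs=1e-9)
        assert np.allclose(transform.rotation, o_rot, atol=1e-8)
        assert np.allclose(transform.translation, o_t, atol=1e-8)

    def test_benzene_symmetry_rotation_reaches_zero(self):
        benzene = get_probe("benzene")
        rot60 = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        coords = {n: rot60 @ benzene.atoms[n] for n in benzene.atom_names}
        probe = make_probe_instance(coords, benzene.alignment_atom_names, benzene.symmetry_mappings)
        _, rmsd = superpose_probe(probe, benzene)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_mapping_rescues_mirror_relabel(self):
        """A non-planar probe whose A/B swap is a mirror symmetry: with the
        swap in the mapping list the relabeled pose fits exactly; restricted
        to the identity mapping, a proper rotation cannot reach it."""
        from cosolvmap.probes import ProbeDefinition

        atoms = {
            "A": np.array([1.0, 0.0, 0.0]),
            "B": np.array([-1.0, 0.0, 0.0]),
            "C": np.array([0.0, 0.5, 0.5]),
            "D": np.array([0.0, -0.5, 0.5]),
        }
        reference = ProbeDefinition(
            name="wedge", resname="WDG", atoms=atoms,
            alignment_atom_names=["A", "B", "C", "D"],
            symmetry_mappings=[["A", "B", "C", "D"], ["B", "A", "C", "D"]],
        )
        relabeled = dict(atoms)
        relabeled["A"], relabeled["B"] = atoms["B"], atoms["A"]
        probe = make_probe_instance(relabeled, reference.alignment_atom_names, reference.symmetry_mappings)
        _, rmsd = superpose_probe(probe, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

        reference_id_only = ProbeDefinition(
            name="wedge", resname="WDG", atoms=atoms,
            alignment_atom_names=["A", "B", "C", "D"],
            symmetry_mappings=[["A", "B", "C", "D"]],
        )
        _, rmsd_plain = superpose_probe(probe, reference_id_only)
        assert rmsd_plain > 0.3

    def test_proper_rotation_enforced(self, vprobe):
        # a mirrored pose cannot be matched by a proper rotation: RMSD > 0
        coords = {n: vprobe.atoms[n] * np.array([1, 1, -1]) for n in vprobe.atom_names}
        coords["C1"] = coords["C1"] + np.array([0.3, 0.9, 0.0])  # break symmetry
        probe = make_probe_instance(coords, vprobe.alignment_atom_names, [vprobe.alignment_atom_names])
        transform, _ = superpose_probe(probe, vprobe)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestExtractEnvironments:
    def test_probes_never_on_surface_gives_empty(self, small_reference):
        runs, _, probe = small_reference
        member = np.zeros((4, 4, 4), dtype=bool)
        surface = make_surface(member, origin=(-500, -500, -500))
        assert extract_environments(runs[0], surface, probe) == []

    def test_counting_small_case(self, small_reference, small_surface):
        runs, _, probe = small_reference
        _, _, _, surface = small_surface
        envs = extract_environments(runs[0], surface, probe)
        # independent scripted recount of (frame, probe) gating events
        expected = 0
        for snap in runs[0].snapshots:
            for p in snap.probes:
                if brute_on_surface(
                    p.heavy_coords(), surface.member, surface.origin, surface.spacing
                ):
                    expected += 1
        assert len(envs) == expected
        assert all(e.alignment_rmsd < 1e-6 for e in envs)

    def test_every_environment_satisfies_4A_rule(self, small_reference, small_surface):
        runs, _, probe = small_reference
        _, _, _, surface = small_surface
        envs = extract_environments(runs[0], surface, probe)
        assert envs
        for env in envs:
            probe_coords = np.array([a.coords for a in env.probe_atoms if a.is_heavy])
            for res in env.residues:
                d = np.linalg.norm(
                    res.heavy_coords()[:, None] - probe_coords[None], axis=-1
                )
                assert d.min() <= 4.0 + 1e-9


class TestBuildProfile:
    def test_single_environment_single_count(self, vprobe):
        member = np.ones((40, 40, 40), dtype=bool)
        surface = make_surface(member, origin=(-20, -20, -20))
        probe = make_probe_instance(
            {n: vprobe.atoms[n] for n in vprobe.atom_names},
            vprobe.alignment_atom_names,
            vprobe.symmetry_mappings,
        )
        from cosolvmap.profile import ResidueEnvironment

        cb = np.array([0.0, 0.0, 4.0])
        env = ResidueEnvironment(
            run_id="r", time=10.0, probe_id="P1",
            probe_atoms=probe.atoms,
            residues=[make_residue("ASP", cb)],
            alignment_rmsd=0.0,
        )
        geometry = profile_geometry_for(vprobe, margin=8.5)
        profile = build_profile([env], geometry, vprobe)
        acidic = profile.grids["acidic"]
        idx = tuple(geometry.point_to_index(cb)[0])
        assert acidic.values[idx] == 1.0
        assert acidic.values.sum() == 1.0
        for rtype in ("basic", "hydrophilic", "hydrophobic", "aromatic"):
            assert profile.grids[rtype].values.sum() == 0.0

    def test_mass_conservation_per_type(self, small_reference, small_surface, vprobe):
        runs, _, probe = small_reference
        _, _, _, surface = small_surface
        envs = []
        for traj in runs:
            envs.extend(extract_environments(traj, surface, probe))
        geometry = profile_geometry_for(probe, margin=8.5)
        profile = build_profile(envs, geometry, probe)
        scheme = ResidueTypeScheme.default()
        # direct recount of (environment, residue) pairs with in-bounds CB
        expected = {t: 0 for t in scheme.types}
        missing = 0
        for env in envs:
            for res in env.residues:
                rtype = classify_residue(res.resname, scheme, strict=False)
                if rtype == EXCLUDED:
                    continue
                cb = res.atom("CB")
                if cb is None:
                    missing += 1
                    continue
                idx = geometry.point_to_index(cb.coords)[0]
                if np.all(idx >= 0) and np.all(idx < np.array(geometry.shape)):
                    expected[rtype] += 1
        for rtype, total in profile.total_counts().items():
            assert total == expected[rtype]
        assert profile.n_missing_atom == missing

    def test_empty_environments_raise(self, vprobe):
        geometry = profile_geometry_for(vprobe)
        with pytest.raises(ValueError):
            build_profile([], geometry, vprobe)

    def test_glycine_cb_skipped_not_binned(self, vprobe):
        from cosolvmap.profile import ResidueEnvironment

        gly = make_residue("GLY", [0.0, 0.0, 4.0])
        ala = make_residue("ALA", [0.0, 0.0, 4.0])
        env = ResidueEnvironment(
            run_id="r", time=10.0, probe_id="P1", probe_atoms=[],
            residues=[gly, ala], alignment_rmsd=0.0,
        )
        profile = build_profile([env], profile_geometry_for(vprobe, margin=8.5), vprobe)
        assert profile.total_counts()["hydrophobic"] == 1.0
        assert sum(profile.total_counts().values()) == 1.0

    def test_unknown_selector_counts_missing(self, vprobe):
        from cosolvmap.profile import ResidueEnvironment

        env = ResidueEnvironment(
            run_id="r", time=10.0, probe_id="P1", probe_atoms=[],
            residues=[make_residue("ASP", [0.0, 0.0, 4.0])], alignment_rmsd=0.0,
        )
        profile = build_profile(
            [env], profile_geometry_for(vprobe, margin=8.5), vprobe, atom_selector="OD1"
        )
        assert profile.n_missing_atom == 1
        assert sum(profile.total_counts().values()) == 0.0
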