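import itertools
import json
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rsk import fixtures as fx
from rsk import motiflib as ml
from rsk import structio as sio
from rsk.chem import CHI_BEARING, CHI_DEFINITIONS, canonical_backbone_frame, dihedral

#: ≥3-atom rigid sets used for the inversion round trip of every
#: chi-bearing identity (internal geometry independent of the chis).
ROUND_TRIP_SETS = {
    "SER": ("CA", "CB", "OG"),
    "CYS": ("CA", "CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "PRO": ("CB", "CG", "CD"),
    "LEU": ("CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CD1", "CG2"),
    "MET": ("CG", "SD", "CE"),
    "PHE": ("CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CE1", "CE2", "CZ", "OH"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLU": ("CG", "CD", "OE1", "OE2"),
    "GLN": ("CG", "CD", "OE1", "NE2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("CD", "CE", "NZ"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
}


def _random_chi(identity, rng):
    return tuple(rng.uniform(-170, 170, len(CHI_DEFINITIONS[identity])))


class TestForwardBuild:
    def test_glycine_has_no_sidechain(self):
        res = ml.build_sidechain_forward("GLY", canonical_backbone_frame(), ())
        assert {a.atom_name for a in res.atoms} == {"N", "CA", "C"}

    def test_alanine_cb_geometry(self):
        res = ml.build_sidechain_forward("ALA", canonical_backbone_frame(), ())
        d = np.linalg.norm(res.atom("CB").coords - res.atom("CA").coords)
        assert d == pytest.approx(1.52, abs=0.02)

    def test_serine_chi_round_trip(self):
        frame = canonical_backbone_frame()
        res = ml.build_sidechain_forward("SER", frame, (60.0,))
        measured = dihedral(res.atom("N").coords, res.atom("CA").coords,
                            res.atom("CB").coords, res.atom("OG").coords)
        assert measured == pytest.approx(60.0, abs=1e-6)

    def test_l_chirality(self):
        # improper dihedral C-N-CA-CB is ~ +120° for L-amino acids
        res = ml.build_sidechain_forward("ALA", canonical_backbone_frame(), ())
        improper = dihedral(res.atom("C").coords, res.atom("N").coords,
                            res.atom("CA").coords, res.atom("CB").coords)
        assert improper == pytest.approx(120.0, abs=5.0)

    def test_chi_length_mismatch(self):
        with pytest.raises(ValueError, match="chi"):
            ml.build_sidechain_forward("LYS", canonical_backbone_frame(),
                                       (60.0,))


class TestInvertRotamer:
    @pytest.mark.parametrize("identity", CHI_BEARING)
    def test_round_trip_all_chi_bearing_identities(self, identity, rng):
        chi = _random_chi(identity, rng)
        rot = Rotation.random(random_state=11).as_matrix()
        frame0 = canonical_backbone_frame() @ rot.T + np.array([4.0, -2.0, 7.0])
        built = ml.build_sidechain_forward(identity, frame0, chi)
        cat = ml.CatalyticResidue(identity, {
            n: built.atom(n).coords for n in ROUND_TRIP_SETS[identity]})
        frame = ml.invert_rotamer(cat, chi)
        assert np.abs(frame - frame0).max() <= 1e-6

    def test_forward_oracle_two_chi_sets(self):
        # same fixed functional atoms, two chi sets → two distinct frames,
        # both reproducing the functional atoms under forward build
        identity = "TYR"
        fset = ROUND_TRIP_SETS[identity]
        built = ml.build_sidechain_forward(
            identity, canonical_backbone_frame(), (-65.0, 95.0))
        cat = ml.CatalyticResidue(identity,
                                  {n: built.atom(n).coords for n in fset})
        frames = [ml.invert_rotamer(cat, chi)
                  for chi in ((-65.0, 95.0), (170.0, 40.0))]
        assert np.abs(frames[0] - frames[1]).max() > 0.5
        for chi, frame in zip(((-65.0, 95.0), (170.0, 40.0)), frames):
            rebuilt = ml.build_sidechain_forward(identity, frame, chi)
            for name in fset:
                np.testing.assert_allclose(
                    rebuilt.atom(name).coords, cat.functional_atoms[name],
                    atol=1e-6)

    def test_functional_atoms_never_move(self):
        # fixed lysine NZ: chi4 change moves CA but leaves NZ exactly fixed
        built = ml.build_sidechain_forward(
            "LYS", canonical_backbone_frame(), (-60.0, 180.0, 180.0, 180.0))
        shift = -built.atom("NZ").coords
        cat = ml.CatalyticResidue("LYS", {
            n: built.atom(n).coords + shift for n in ("CD", "CE", "NZ")})
        f1 = ml.invert_rotamer(cat, (-60.0, 180.0, 180.0, 180.0))
        f2 = ml.invert_rotamer(cat, (-60.0, 180.0, 180.0, 60.0))
        assert np.linalg.norm(f1[1] - f2[1]) > 0.1  # CA moved
        for chi in ((-60.0, 180.0, 180.0, 180.0), (-60.0, 180.0, 180.0, 60.0)):
            frame = ml.invert_rotamer(cat, chi)
            rebuilt = ml.build_sidechain_forward("LYS", frame, chi)
            assert np.linalg.norm(rebuilt.atom("NZ").coords) <= 1e-9

    def test_degenerate_functional_frame(self):
        cat = ml.CatalyticResidue("LYS", {
            "CD": [0.0, 0.0, 0.0], "CE": [1.0, 0.0, 0.0],
            "NZ": [2.0, 0.0, 0.0]})
        with pytest.raises(sio.DegeneracyError):
            ml.invert_rotamer(cat, (-60.0, 180.0, 180.0, 180.0))


class TestCompatibleRotamers:
    def _library(self):
        lib = ml.RotamerLibrary(bin_width=10.0)
        for p, chi in [(0.5, (60.0,)), (0.3, (-60.0,)), (0.1, (180.0,))]:
            lib.add("SER", -60.0, -45.0, ml.Rotamer(chi=chi, probability=p))
        return lib

    def test_empty_bin(self):
        lib = self._library()
        assert ml.compatible_rotamers("SER", 100.0, 100.0, lib) == []

    def test_filter_and_sort(self):
        lib = self._library()
        out = ml.compatible_rotamers("SER", -60.0, -45.0, lib, min_prob=0.2)
        assert [r.probability for r in out] == [0.5, 0.3]

    def test_helical_bin_lookup(self, rotamer_library):
        stored = rotamer_library.lookup("LYS", -57.0, -47.0)
        out = ml.compatible_rotamers("LYS", -60.0, -45.0, rotamer_library)
        assert sorted(r.chi for r in out) == sorted(r.chi for r in stored)

    def test_missing_identity(self):
        with pytest.raises(KeyError):
            ml.compatible_rotamers("TRP", 0.0, 0.0, self._library())


class TestPlaceFragment:
    def test_identity_transform(self, helix7):
        rot = ml.Rotamer(chi=(-60.0, 180.0, 180.0, 180.0), probability=0.5)
        placement = ml.place_fragment(helix7, helix7.anchor_frame(), rot,
                                      "LYS")
        np.testing.assert_allclose(placement.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(placement.translation, 0.0, atol=1e-9)

    def test_anchor_matches_frame(self, helix7, rng):
        target = (canonical_backbone_frame()
                  @ Rotation.random(random_state=2).as_matrix().T
                  + np.array([10.0, 5.0, -3.0]))
        rot = ml.Rotamer(chi=(60.0,), probability=0.9)
        placement = ml.place_fragment(helix7, target, rot, "SER")
        assert np.abs(placement.anchor_frame() - target).max() <= 1e-3

    def test_rigidity(self, helix7):
        target = canonical_backbone_frame() + np.array([3.0, 3.0, 3.0])
        rot = ml.Rotamer(chi=(60.0,), probability=0.9)
        placement = ml.place_fragment(helix7, target, rot, "SER")
        before = helix7.all_coords()
        after = np.array([c for bb in placement.transformed_backbone()
                          for c in bb.values()])
        d_before = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d_after = np.linalg.norm(after[:, None] - after[None], axis=-1)
        assert np.abs(d_before - d_after).max() <= 1e-6


class TestClashCheck:
    def test_far_apart(self):
        a = [("CA", np.zeros(3))]
        b = [("CA", np.array([100.0, 0.0, 0.0]))]
        assert ml.clash_check(a, b).count == 0

    def test_hand_threshold(self):
        # two carbons at 2.0 Å, γ = 0.75 → threshold 2.55 Å → clash
        a = [("CA", np.zeros(3))]
        b = [("CA", np.array([2.0, 0.0, 0.0]))]
        report = ml.clash_check(a, b, ml.ClashParams(tolerance_factor=0.75))
        assert report.count == 1
        # just outside the threshold → no clash
        b = [("CA", np.array([2.56, 0.0, 0.0]))]
        assert ml.clash_check(a, b).count == 0

    def test_brute_force_oracle(self, rng):
        params = ml.ClashParams()
        a = [("CA", c) for c in rng.uniform(-4, 4, size=(25, 3))]
        b = [("O", c) for c in rng.uniform(-4, 4, size=(25, 3))]
        expected = sum(
            1 for (_, ca), (_, cb) in itertools.product(a, b)
            if np.linalg.norm(ca - cb) < 0.75 * (1.7 + 1.52))
        assert ml.clash_check(a, b, params).count == expected

    def test_unknown_element(self):
        with pytest.raises(ValueError, match="radius"):
            ml.clash_check([("XX", np.zeros(3))],
                           [("CA", np.ones(3))],
                           ml.ClashParams(vdw_radii={"C": 1.7}))

    def test_exempt_pairs(self):
        a = [("CA", np.zeros(3))]
        b = [("CB", np.array([1.5, 0.0, 0.0]))]
        params = ml.ClashParams(exempt_pairs=frozenset({frozenset(("CA", "CB"))}))
        assert ml.clash_check(a, b, params).count == 0


def _fake_placement(coords, prob=0.5, abundance=1.0):
    atoms = [("CA", np.asarray(c, dtype=float)) for c in coords]
    return SimpleNamespace(
        heavy_atoms=lambda: atoms,
        rotamer=SimpleNamespace(probability=prob),
        fragment=SimpleNamespace(abundance=abundance, fragment_id="fake"),
    )


class TestEnumerate:
    def test_single_residue(self):
        col = [_fake_placement([[i * 10.0, 0, 0]]) for i in range(4)]
        assemblies, _ = ml.enumerate_assemblies([col], max_out=100)
        assert len(assemblies) == 4

    def test_brute_force_oracle_constructed(self, rng):
        # 3 residues × 4 placements, random positions → compare with the
        # brute-force Cartesian-product filter over all 64 combinations
        cols = [[_fake_placement([rng.uniform(-6, 6, 3)],
                                 prob=float(rng.uniform(0.1, 1.0)))
                 for _ in range(4)] for _ in range(3)]
        params = ml.ClashParams()
        assemblies, _ = ml.enumerate_assemblies(cols, params=params,
                                                max_out=1000)
        expected = 0
        for combo in itertools.product(*cols):
            ok = all(
                ml.clash_check(a.heavy_atoms(), b.heavy_atoms(), params).count == 0
                for a, b in itertools.combinations(combo, 2))
            expected += ok
        assert len(assemblies) == expected

    def test_brute_force_oracle_pipeline(self, tetrad_array, rotamer_library,
                                         helix7):
        # full-pipeline candidates, exhaustive comparison (≤ 1000 combos)
        params = ml.ClashParams()
        candidates = []
        for idx, cat in enumerate(tetrad_array.residues):
            col = []
            phi, psi = helix7.anchor_phi_psi()
            for rot in ml.compatible_rotamers(cat.identity, phi, psi,
                                              rotamer_library):
                frame = ml.invert_rotamer(cat, rot.chi)
                col.append(ml.place_fragment(helix7, frame, rot,
                                             cat.identity, idx))
            candidates.append(col)
        assert np.prod([len(c) for c in candidates]) <= 1000
        assemblies, _ = ml.enumerate_assemblies(
            candidates, ligand=tetrad_array.ligand, params=params,
            max_out=10 ** 6)
        expected = 0
        lig = [(a.atom_name, a.coords) for a in tetrad_array.ligand.atoms]
        for combo in itertools.product(*candidates):
            ok = all(
                ml.clash_check(a, b, params).count == 0
                for a, b in itertools.combinations(combo, 2))
            ok = ok and all(ml.clash_check(p, lig, params).count == 0
                            for p in combo)
            expected += ok
        assert len(assemblies) == expected
        # no returned assembly contains a clash (post-hoc re-check)
        for assembly in assemblies:
            for a, b in itertools.combinations(assembly.placements, 2):
                assert ml.clash_check(a, b, params).count == 0

    def test_truncation_deterministic(self, rng):
        cols = [[_fake_placement([[i * 10.0, j * 10.0, 0]],
                                 prob=0.1 + 0.2 * i)
                 for i in range(4)] for j in range(2)]
        full, _ = ml.enumerate_assemblies(cols, max_out=1000)
        top5, _ = ml.enumerate_assemblies(cols, max_out=5)
        assert len(top5) == 5
        assert [a.score for a in top5] == [a.score for a in full[:5]]
        scores = [a.score for a in full]
        assert scores == sorted(scores, reverse=True)

    def test_empty_candidate_list(self):
        assemblies, diag = ml.enumerate_assemblies(
            [[_fake_placement([[0, 0, 0]])], []])
        assert assemblies == []
        assert "reason" in diag

    def test_combination_cap(self):
        col = [_fake_placement([[i * 10.0, 0, 0]]) for i in range(10)]
        with pytest.raises(ml.CombinationCapError):
            ml.enumerate_assemblies([col] * 3, combination_cap=100)


class TestScore:
    def test_zero_score(self):
        a = ml.MotifAssembly(placements=[
            _fake_placement([[0, 0, 0]], prob=1.0, abundance=0.0)])
        assert ml.score_assembly(a, (2.0, 3.0)) == 0.0

    def test_hand_values(self):
        a1 = ml.MotifAssembly(placements=[
            _fake_placement([[0, 0, 0]], prob=0.5, abundance=0.0),
            _fake_placement([[9, 0, 0]], prob=0.5, abundance=0.0)])
        a2 = ml.MotifAssembly(placements=[
            _fake_placement([[0, 0, 0]], prob=0.9, abundance=0.0),
            _fake_placement([[9, 0, 0]], prob=0.1, abundance=0.0)])
        s1 = ml.score_assembly(a1)
        s2 = ml.score_assembly(a2)
        assert s1 == pytest.approx(np.log(0.5))  # −0.693
        assert s2 == pytest.approx((np.log(0.9) + np.log(0.1)) / 2)  # −1.204
        assert s1 > s2

    def test_monotone_in_abundance(self):
        def score(ab):
            return ml.score_assembly(ml.MotifAssembly(placements=[
                _fake_placement([[0, 0, 0]], prob=0.5, abundance=ab),
                _fake_placement([[9, 0, 0]], prob=0.5, abundance=1.0)]))

        values = [score(ab) for ab in (0.0, 1.0, 5.0, 100.0)]
        assert values == sorted(values)
        assert len(set(values)) == len(values)


class TestBuildLibrary:
    def test_end_to_end_functional_fixed_point(self, tetrad_library,
                                               tetrad_array):
        assert len(tetrad_library.assemblies) >= 1
        for assembly in tetrad_library.assemblies:
            assert assembly.functional_atom_coords(tetrad_array) <= 1e-3
            assert assembly.clash_free

    def test_mbh_triad_end_to_end(self, triad_array, rotamer_library, helix7):
        lib = ml.build_motif_library(triad_array, rotamer_library, [helix7],
                                     ml.MotifLibraryConfig(max_out=5))
        assert len(lib.assemblies) >= 1
        for assembly in lib.assemblies:
            assert assembly.functional_atom_coords(triad_array) <= 1e-3

    def test_forced_failure_gives_diagnostic(self, rotamer_library, helix7):
        # two lysines with overlapping functional groups + maximal strictness
        built = ml.build_sidechain_forward(
            "LYS", canonical_backbone_frame(), (-60.0, 180.0, 180.0, 180.0))
        atoms = {n: built.atom(n).coords for n in ("CD", "CE", "NZ")}
        array = ml.CatalyticArray(residues=[
            ml.CatalyticResidue("LYS", atoms),
            ml.CatalyticResidue("LYS", {k: v + 0.5 for k, v in atoms.items()}),
        ])
        lib = ml.build_motif_library(
            array, rotamer_library, [helix7],
            ml.MotifLibraryConfig(clash_tolerance=1.0))
        assert lib.assemblies == []
        assert lib.diagnostic is not None
        assert "tightest_clash_distance" in lib.diagnostic

    def test_ranking_total_order(self, tetrad_library):
        scores = [a.score for a in tetrad_library.assemblies]
        assert scores == sorted(scores, reverse=True)

    def test_deterministic_byte_identical(self, tetrad_array, rotamer_library,
                                          helix7):
        outs = []
        for _ in range(2):
            lib = ml.build_motif_library(
                tetrad_array, rotamer_library, [helix7],
                ml.MotifLibraryConfig(max_out=10, seed=42))
            outs.append(ml.serialize_library(lib))
        assert outs[0] == outs[1]

    def test_serialization_round_trip(self, tetrad_library):
        pdb_text, sidecar = ml.serialize_library(tetrad_library)
        parsed = sio.parse_structure(pdb_text)
        original = ml.library_to_structure(tetrad_library)
        assert len(parsed.models) == len(original.models)
        for m1, m2 in zip(original.models, parsed.models):
            for r1, r2 in zip(m1.residues, m2.residues):
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    np.testing.assert_allclose(a1.coords, a2.coords,
                                               atol=1e-3)
        payload = json.loads(sidecar)
        assert len(payload["assemblies"]) == len(tetrad_library.assemblies)


class TestTsvFormats:
    def test_rotamer_library_round_trip(self, rotamer_library):
        text = rotamer_library.to_tsv()
        lib2 = ml.RotamerLibrary.from_tsv(text)
        assert lib2.to_tsv() == text

    def test_fragment_round_trip(self, helix7):
        frags = [helix7, fx.make_ideal_helix(9)]
        text = ml.fragments_to_tsv(frags)
        back = ml.fragments_from_tsv(text)
        assert [f.length for f in back] == [7, 9]
        assert [f.anchor_index for f in back] == [3, 4]
        for f1, f2 in zip(frags, back):
            np.testing.assert_allclose(f1.all_coords(), f2.all_coords(),
                                       atol=1e-5)
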