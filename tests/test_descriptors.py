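import numpy as np
import pytest
from helpers import dihedral_oracle

from deamipred.descriptors import (
    FEATURE_COLUMNS,
    FeatureVector,
    MissingAtomsError,
    SiteStatus,
    accessibility,
    attack_distance,
    bfactor_descriptors,
    featurize,
    featurize_chain,
    features_to_frame,
    normalize_bfactors,
    site_dihedrals,
)
from deamipred.fixtures import PeptideSpec, build_structure
from deamipred.secondary import assign_secondary_structure
from deamipred.structure import (
    AtomRecord,
    ResidueRecord,
    Structure,
    enumerate_asn_sites,
    select_chain,
)


def _residue(chain, num, name, atom_specs):
    atoms = {
        n: AtomRecord(n, n[0], np.array(xyz, dtype=float), b, 1.0)
        for n, xyz, b in atom_specs
    }
    return ResidueRecord(chain, num, name, atoms)


class TestAttackDistance:
    def test_axis_aligned(self):
        asn = _residue("A", 1, "ASN", [("CG", (0, 0, 0), 20)])
        nxt = _residue("A", 2, "GLY", [("N", (3, 0, 0), 20)])
        assert attack_distance(asn, nxt) == pytest.approx(3.0)

    def test_pythagorean(self):
        asn = _residue("A", 1, "ASN", [("CG", (1, 2, 2), 20)])
        nxt = _residue("A", 2, "GLY", [("N", (0, 0, 0), 20)])
        assert attack_distance(asn, nxt) == pytest.approx(3.0)  # sqrt(1+4+4)

    def test_coincident_warns(self):
        asn = _residue("A", 1, "ASN", [("CG", (1, 1, 1), 20)])
        nxt = _residue("A", 2, "GLY", [("N", (1, 1, 1), 20)])
        with pytest.warns(UserWarning, match="zero"):
            assert attack_distance(asn, nxt) == 0.0

    def test_missing_atoms_listed(self):
        asn = _residue("A", 1, "ASN", [("CB", (0, 0, 0), 20)])
        nxt = _residue("A", 2, "GLY", [("CA", (3, 0, 0), 20)])
        with pytest.raises(MissingAtomsError) as err:
            attack_distance(asn, nxt)
        assert set(err.value.atoms) == {"CG", "N(i+1)"}


class TestBfactorNormalization:
    def test_two_atom_example(self):
        res = _residue("A", 1, "GLY", [("N", (0, 0, 0), 10), ("CA", (1, 0, 0), 20)])
        z = normalize_bfactors(Structure(chains={"A": [res]}))
        assert z[("A", "1", "N")] == pytest.approx(-1.0)  # mu=15, sigma=5
        assert z[("A", "1", "CA")] == pytest.approx(1.0)

    def test_uniform_b_gives_zero_with_warning(self):
        structure = build_structure(PeptideSpec("GANGA", bfactor_default=15.0))
        with pytest.warns(UserWarning, match="uniform"):
            z = normalize_bfactors(structure)
        assert all(v == 0.0 for v in z.values())

    def test_zscore_identity(self):
        rng = np.random.default_rng(7)
        bfacs = {}
        structure = build_structure(PeptideSpec("GANGANGA"))
        for res in structure.iter_residues():
            for atom in res.atoms.values():
                atom.bfactor = float(rng.uniform(5, 60))
        z = np.array(list(normalize_bfactors(structure).values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_recomputation(self):
        rng = np.random.default_rng(11)
        structure = build_structure(PeptideSpec("GANGA"))
        raw = {}
        for res in structure.iter_residues():
            for atom in res.atoms.values():
                atom.bfactor = float(rng.uniform(5, 60))
                raw[(res.chain_id, res.seq_id, atom.name)] = atom.bfactor
        values = np.array(list(raw.values()))
        mu, sigma = values.mean(), values.std()
        z = normalize_bfactors(structure)
        for key, b in raw.items():
            assert z[key] == pytest.approx((b - mu) / sigma)

    def test_planted_two_sigma_cb(self):
        # 8 atoms: six at 20, one at 10, CB at 30 -> mu=20, sigma=5, z_CB=2
        specs = [("N", (0, 0, 0), 20), ("CA", (1.5, 0, 0), 20),
                 ("C", (3, 0, 0), 20), ("O", (3, 1, 0), 20),
                 ("CB", (1.5, 1.5, 0), 30), ("CG", (1.5, 3, 0), 20),
                 ("OD1", (2.5, 3.5, 0), 20), ("ND2", (0.5, 3.5, 0), 10)]
        res = _residue("A", 1, "ASN", specs)
        z = normalize_bfactors(Structure(chains={"A": [res]}))
        assert z[("A", "1", "CB")] == pytest.approx(2.0)
        zb = bfactor_descriptors(res, z)
        assert zb == pytest.approx((0.0, 0.0, 2.0, 0.0))

    def test_missing_carbon_raises(self):
        res = _residue("A", 1, "ASN", [("N", (0, 0, 0), 20), ("CA", (1, 0, 0), 10)])
        z = normalize_bfactors(Structure(chains={"A": [res]}))
        with pytest.raises(MissingAtomsError) as err:
            bfactor_descriptors(res, z)
        assert "CB" in err.value.atoms


class TestSiteDihedrals:
    def test_round_trip_helixlike(self, ganga_site):
        chain, site = ganga_site
        phi, psi, chi1, chi2 = site_dihedrals(chain, site)
        assert phi == pytest.approx(-60.0, abs=1e-6)
        assert psi == pytest.approx(-45.0, abs=1e-6)
        assert chi1 == pytest.approx(-65.0, abs=1e-6)
        assert chi2 == pytest.approx(-20.0, abs=1e-6)

    def test_extended_round_trip(self):
        structure = build_structure(PeptideSpec("GANGA", phi=180.0, psi=180.0))
        chain = select_chain(structure)
        site = enumerate_asn_sites(chain)[0]
        phi, psi, _, _ = site_dihedrals(chain, site)
        assert phi == pytest.approx(180.0, abs=1e-6)
        assert psi == pytest.approx(180.0, abs=1e-6)

    def test_matches_oracle_on_arbitrary_fixture(self):
        spec = PeptideSpec("GANGA", phi=-97.0, psi=143.0, chi1=58.0, chi2=-171.0)
        structure = build_structure(spec)
        chain = select_chain(structure)
        site = enumerate_asn_sites(chain)[0]
        asn = chain[site.list_index]
        prev, nxt = chain[site.list_index - 1], chain[site.list_index + 1]
        expected = (
            dihedral_oracle(prev.atom_coords("C"), asn.atom_coords("N"),
                            asn.atom_coords("CA"), asn.atom_coords("C")),
            dihedral_oracle(asn.atom_coords("N"), asn.atom_coords("CA"),
                            asn.atom_coords("C"), nxt.atom_coords("N")),
            dihedral_oracle(asn.atom_coords("N"), asn.atom_coords("CA"),
                            asn.atom_coords("CB"), asn.atom_coords("CG")),
            dihedral_oracle(asn.atom_coords("CA"), asn.atom_coords("CB"),
                            asn.atom_coords("CG"), asn.atom_coords("OD1")),
        )
        assert site_dihedrals(chain, site) == pytest.approx(expected, abs=1e-9)

    def test_n_terminal_phi_is_none(self):
        structure = build_structure(PeptideSpec("NGA"))
        chain = select_chain(structure)
        site = enumerate_asn_sites(chain)[0]
        phi, psi, chi1, chi2 = site_dihedrals(chain, site)
        assert phi is None
        assert psi is not None

    def test_missing_atoms_listed(self, ganga_site):
        chain, site = ganga_site
        del chain[site.list_index].atoms["OD1"]
        with pytest.raises(MissingAtomsError) as err:
            site_dihedrals(chain, site)
        assert "OD1" in err.value.atoms


class TestAccessibility:
    def test_isolated_asn_near_full_exposure(self):
        structure = build_structure(PeptideSpec("GNG", phi=180.0, psi=180.0))
        asn = structure.chains["A"][1]
        isolated = Structure(chains={"A": [asn]})
        psa, pssa = accessibility(isolated, asn)
        assert psa == pytest.approx(100.0, abs=15.0)
        assert pssa == pytest.approx(100.0, abs=15.0)

    def test_caged_asn_buried(self):
        structure = build_structure(PeptideSpec("GNG", phi=180.0, psi=180.0, cage=True))
        psa, pssa = accessibility(structure, structure.chains["A"][1])
        assert psa < 5.0
        assert pssa < 5.0

    def test_sampling_convergence(self):
        structure = build_structure(PeptideSpec("GANGA"))
        asn = structure.chains["A"][2]
        psa1, _ = accessibility(structure, asn, n_points=960)
        psa2, _ = accessibility(structure, asn, n_points=1920)
        assert abs(psa1 - psa2) < 1.0


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        structure = build_structure(PeptideSpec("A" * 10, phi=-57.0, psi=-47.0))
        codes = assign_secondary_structure(select_chain(structure))
        assert set(codes[2:8]) == {1}

    def test_extended_has_no_helix(self):
        structure = build_structure(PeptideSpec("A" * 10, phi=180.0, psi=180.0))
        codes = assign_secondary_structure(select_chain(structure))
        assert 1 not in codes

    def test_two_residue_chain_is_coil(self):
        structure = build_structure(PeptideSpec("AN"))
        codes = assign_secondary_structure(select_chain(structure))
        assert list(codes) == [3, 3]


class TestFeaturize:
    def test_full_vector(self, ganga_structure, half_life_table):
        chain = select_chain(ganga_structure)
        site = enumerate_asn_sites(chain)[0]
        fv = featurize(ganga_structure, chain, site, half_life_table)
        assert isinstance(fv, FeatureVector)
        arr = fv.as_array()
        assert arr.shape == (13,)
        assert np.all(np.isfinite(arr))
        assert fv.secondary_structure in (1, 2, 3, 4)
        assert list(fv.as_dict()) == FEATURE_COLUMNS

    def test_yyy_gln_not_predictable(self, half_life_table):
        structure = build_structure(PeptideSpec("GANQA"))
        chain = select_chain(structure)
        site = enumerate_asn_sites(chain)[0]
        status = featurize(structure, chain, site, half_life_table)
        assert isinstance(status, SiteStatus)
        assert not status.predictable
        assert "Q" in status.reason

    def test_missing_od1_propagates(self, ganga_structure, half_life_table):
        chain = select_chain(ganga_structure)
        site = enumerate_asn_sites(chain)[0]
        del chain[site.list_index].atoms["OD1"]
        status = featurize(ganga_structure, chain, site, half_life_table)
        assert isinstance(status, SiteStatus)
        assert "OD1" in status.reason

    def test_bit_reproducible(self, ganga_structure, half_life_table):
        chain = select_chain(ganga_structure)
        site = enumerate_asn_sites(chain)[0]
        a = featurize(ganga_structure, chain, site, half_life_table)
        b = featurize(ganga_structure, chain, site, half_life_table)
        assert a.as_array().tobytes() == b.as_array().tobytes()

    def test_frame_layout(self, ganga_structure, half_life_table):
        chain = select_chain(ganga_structure)
        sites = enumerate_asn_sites(chain)
        frame = features_to_frame(
            featurize_chain(ganga_structure, chain, sites, half_life_table)
        )
        assert list(frame.columns) == (
            ["chain", "residue", "xxx", "yyy", "yyy2"] + FEATURE_COLUMNS + ["status"]
        )
        assert len(frame) == 1
        assert frame.loc[0, "status"] == "ok"
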