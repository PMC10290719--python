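import math
import os

import numpy as np
import pytest

from kinoprof.pharm3d import (
    DEFAULT_BINS,
    DEFAULT_FAMILIES,
    ConformerEmbeddingError,
    build_signature_space,
    compute_3ced,
    conformer_signature,
    generate_conformers,
    perceive_sites,
    signature_from_sites,
)

from _oracles import brute_force_signature


def expected_dimension(n_families, n_bins, point_counts=(2, 3)):
    return sum(
        math.comb(n_families + n - 1, n) * n_bins ** math.comb(n, 2)
        for n in point_counts
    )


class TestSignatureSpace:
    def test_default_dimension_is_3348(self, space):
        assert space.dimension == 3348
        assert space.bins == ((0.0, 3.0), (3.0, 6.0), (6.0, 9.0))
        assert len(space.families) == 8

    @pytest.mark.parametrize(
        "n_fam,bins,points,expected",
        [
            (2, 3, (2,), 9),  # 3 family pairs x 3 bins
            (2, 1, (2,), 3),
            (2, 3, (2, 3), 117),
            (8, 3, (2, 3), 3348),
        ],
    )
    def test_dimension_formula(self, n_fam, bins, points, expected):
        fams = DEFAULT_FAMILIES[:n_fam]
        bin_edges = [(3.0 * i, 3.0 * (i + 1)) for i in range(bins)]
        sp = build_signature_space(fams, bin_edges, points)
        assert sp.dimension == expected
        assert sp.dimension == expected_dimension(n_fam, bins, points)

    @pytest.mark.parametrize("n_fam", [2, 6, 7, 8])
    def test_dimension_matches_independent_factory(self, n_fam):
        # cross-check against the pharmacophore signature factory of the
        # chemistry toolkit, an independent implementation of the same space
        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures
        from rdkit.Chem.Pharm2D.SigFactory import SigFactory

        ff = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
        skip = [f for f in ff.GetFeatureFamilies() if f not in DEFAULT_FAMILIES[:n_fam]]
        sf = SigFactory(ff, minPointCount=2, maxPointCount=3, skipFeats=skip)
        sf.SetBins([(0, 3), (3, 6), (6, 9)])
        sf.Init()
        sp = build_signature_space(DEFAULT_FAMILIES[:n_fam], DEFAULT_BINS, (2, 3))
        assert sp.dimension == sf.GetSigSize()

    def test_bin_lookup_half_open(self, space):
        assert space.bin_of(0.0) == 0
        assert space.bin_of(3.0) == 1
        assert space.bin_of(8.999) == 2
        assert space.bin_of(9.0) is None

    def test_describe_round_trip(self, space):
        label = space.describe(0)
        assert label.startswith("2pt(")
        assert "[0,3)" in label

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            build_signature_space([], DEFAULT_BINS)
        with pytest.raises(ValueError):
            build_signature_space(DEFAULT_FAMILIES, [(0, 3), (2, 6)])


class TestConformers:
    def test_cap_respected_for_flexible_molecule(self):
        ens = generate_conformers("CC(C)Cc1ccc(cc1)C(C)C(=O)O", max_n=16, seed=7)
        assert 1 <= len(ens) <= 16

    def test_rigid_molecule_collapses_to_one(self):
        ens = generate_conformers("C", max_n=16, seed=7)
        assert len(ens) == 1

    def test_deterministic_under_seed(self):
        a = generate_conformers("CCOc1ccccc1", max_n=8, seed=3)
        b = generate_conformers("CCOc1ccccc1", max_n=8, seed=3)
        assert len(a) == len(b)
        for ca, cb in zip(a.conformer_ids, b.conformer_ids):
            np.testing.assert_allclose(a.coordinates(ca), b.coordinates(cb))

    def test_empty_molecule_rejected(self):
        with pytest.raises(Exception):
            generate_conformers("[H][H]", max_n=4, seed=1)


class TestConformerSignature:
    def test_hand_built_donor_acceptor_pair(self, space):
        donor = space.family_index("Donor")
        acceptor = space.family_index("Acceptor")
        sites = [(donor, np.zeros(3)), (acceptor, np.array([4.2, 0.0, 0.0]))]
        sig = signature_from_sites(sites, space)
        assert sig.sum() == 1
        expected = space.signature_index(tuple(sorted((donor, acceptor))), (1,))
        assert sig[expected] == 1

    def test_no_features_gives_zero_vector(self, space):
        assert signature_from_sites([], space).sum() == 0

    def test_pairs_beyond_last_bin_ignored(self, space):
        sites = [(0, np.zeros(3)), (1, np.array([9.0, 0.0, 0.0]))]
        assert signature_from_sites(sites, space).sum() == 0

    @pytest.mark.parametrize("smiles", ["CC(=O)Oc1ccccc1C(=O)O", "Nc1ccc(O)cc1", "OCCN"])
    def test_matches_brute_force_enumeration(self, smiles, space):
        ens = generate_conformers(smiles, max_n=4, seed=7)
        for cid in ens.conformer_ids:
            sites = perceive_sites(ens.mol_h, cid, space)
            assert len(sites) <= 15
            got = conformer_signature(ens, cid, space)
            expected = brute_force_signature(
                [(f, tuple(p)) for f, p in sites], space
            )
            np.testing.assert_array_equal(got, expected)

    def test_rigid_motion_invariance(self, space):
        ens = generate_conformers("Nc1ccc(O)cc1", max_n=2, seed=7)
        sites = perceive_sites(ens.mol_h, ens.conformer_ids[0], space)
        base = signature_from_sites(sites, space)
        rng = np.random.default_rng(0)
        # random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 10
        moved = [(f, q @ p + t) for f, p in sites]
        np.testing.assert_array_equal(signature_from_sites(moved, space), base)


class TestCompute3CED:
    def test_single_conformer_identity(self, space):
        ens = generate_conformers("OCCN", max_n=1, seed=7)
        sig = compute_3ced(ens, space)
        np.testing.assert_array_equal(
            sig.values, conformer_signature(ens, ens.conformer_ids[0], space)
        )

    def test_mean_of_unit_vectors(self, space):
        # two conformers whose signatures are unit vectors on different slots
        e1 = np.zeros(space.dimension)
        e2 = np.zeros(space.dimension)
        e1[3], e2[7] = 1, 1
        mean = np.stack([e1, e2]).mean(axis=0)
        assert mean[3] == mean[7] == 0.5

    def test_conformer_permutation_invariance(self, space):
        ens = generate_conformers("CC(=O)Oc1ccccc1C(=O)O", max_n=6, seed=7)
        sig = compute_3ced(ens, space).values
        ens.conformer_ids = ens.conformer_ids[::-1]
        np.testing.assert_allclose(compute_3ced(ens, space).values, sig)

    def test_mean_bounded_by_conformer_extremes(self, space):
        ens = generate_conformers("CC(C)Cc1ccc(cc1)C(C)C(=O)O", max_n=8, seed=7)
        per_conf = np.stack(
            [conformer_signature(ens, cid, space) for cid in ens.conformer_ids]
        )
        mean = compute_3ced(ens, space).values
        assert np.all(mean >= per_conf.min(axis=0) - 1e-12)
        assert np.all(mean <= per_conf.max(axis=0) + 1e-12)

    def test_empty_ensemble_rejected(self, space):
        ens = generate_conformers("OCCN", max_n=1, seed=7)
        ens.conformer_ids = []
        with pytest.raises(ValueError):
            compute_3ced(ens, space)
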