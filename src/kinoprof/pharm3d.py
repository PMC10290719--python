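"""3D conformer-ensemble pharmacophore descriptors (3CED).

A molecule is embedded into up to 16 distance-geometry conformers.  For each
conformer, pharmacophore feature sites (donor, acceptor, ionizable, aromatic,
hydrophobe families) are perceived and every 2- and 3-point combination of
sites is counted into a signature indexed by the family combination and the
distance-bin assignment of its pairwise distances (default bins [0,3), [3,6),
[6,9) Angstrom; pairs at >= 9 A contribute nothing).  The 3CED vector is the
element-wise mean of the per-conformer count vectors.

The signature space enumerates, for each point count n, all family
combinations-with-repetition and all ordered bin assignments to the C(n,2)
pairwise distances:

    dimension = sum_n C(F + n - 1, n) * B ** C(n, 2)

With the default 8 feature families, bins (0-3, 3-6, 6-9 A) and point counts
{2, 3} this gives 36*3 + 120*27 = 3348 signatures.

When a combination's families repeat, the site ordering is ambiguous; the
canonical index uses the lexicographically smallest bin tuple over all site
orderings consistent with the sorted family tuple, so each site combination
increments exactly one signature.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures

from .descriptors2d import Molecule, as_molecule

#: Pharmacophore feature families of the default perception model, in the
#: perception model's own order.
DEFAULT_FAMILIES: tuple[str, ...] = (
    "Donor",
    "Acceptor",
    "NegIonizable",
    "PosIonizable",
    "ZnBinder",
    "Aromatic",
    "Hydrophobe",
    "LumpedHydrophobe",
)

#: Half-open distance bins in Angstrom.
DEFAULT_BINS: tuple[tuple[float, float], ...] = ((0.0, 3.0), (3.0, 6.0), (6.0, 9.0))

DEFAULT_MAX_CONFORMERS = 16
DEFAULT_PRUNE_RMS = 0.5


class ConformerEmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a molecule."""


@lru_cache(maxsize=1)
def _feature_factory():
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    return ChemicalFeatures.BuildFeatureFactory(fdef)


@dataclass(frozen=True)
class SignatureSpace:
    """Canonical index space for binned 2-/3-point pharmacophore signatures."""

    families: tuple[str, ...] = DEFAULT_FAMILIES
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS
    point_counts: tuple[int, ...] = (2, 3)
    _combos: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.families) < 1:
            raise ValueError("at least one feature family is required")
        if len(set(self.families)) != len(self.families):
            raise ValueError("feature families must be unique")
        for (lo, hi), (lo2, _) in zip(self.bins, self.bins[1:]):
            if hi > lo2:
                raise ValueError("bins must be ordered and non-overlapping")
        if any(hi <= lo for lo, hi in self.bins):
            raise ValueError("each bin must satisfy lo < hi")
        if any(n not in (2, 3) for n in self.point_counts):
            raise ValueError("only 2- and 3-point signatures are supported")
        # canonical index layout: point counts in ascending order; within a
        # point count, family combinations-with-repetition in family-index
        # lexicographic order, each spanning B**C(n,2) consecutive slots for
        # the ordered bin assignment to pair slots ((0,1),(0,2),(1,2)).
        offsets = {}
        combos = {}
        dim = 0
        for n in sorted(self.point_counts):
            combo_list = list(
                itertools.combinations_with_replacement(range(len(self.families)), n)
            )
            combos[n] = {c: i for i, c in enumerate(combo_list)}
            offsets[n] = dim
            dim += len(combo_list) * len(self.bins) ** math.comb(n, 2)
        self._combos["offsets"] = offsets
        self._combos["index"] = combos
        self._combos["dimension"] = dim

    @property
    def dimension(self) -> int:
        return self._combos["dimension"]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_of(self, distance: float) -> int | None:
        """Bin index of a distance, or None when outside every bin."""
        for i, (lo, hi) in enumerate(self.bins):
            if lo <= distance < hi:
                return i
        return None

    def family_index(self, family: str) -> int:
        try:
            return self.families.index(family)
        except ValueError:
            raise KeyError(f"family {family!r} not in signature space") from None

    def signature_index(self, family_indices: Sequence[int], bin_indices: Sequence[int]) -> int:
        """Flat index of a (sorted family tuple, ordered bin tuple) signature.

        ``family_indices`` must be sorted ascending; ``bin_indices`` holds one
        bin per pair slot in the order (0,1), (0,2), (1,2) for 3 points or the
        single pair for 2 points.
        """
        n = len(family_indices)
        fam = tuple(family_indices)
        combo_rank = self._combos["index"][n][fam]
        b = 0
        for bi in bin_indices:
            b = b * self.n_bins + bi
        block = self.n_bins ** math.comb(n, 2)
        return self._combos["offsets"][n] + combo_rank * block + b

    def describe(self, index: int) -> str:
        """Human-readable name of a signature slot."""
        for n in sorted(self.point_counts, reverse=True):
            off = self._combos["offsets"][n]
            block = self.n_bins ** math.comb(n, 2)
            if index >= off:
                rel = index - off
                combo_rank, rem = divmod(rel, block)
                combo = list(self._combos["index"][n])[combo_rank]
                # decode base-B bin digits, most-significant (pair 0,1) first
                digits = []
                for k in range(math.comb(n, 2) - 1, -1, -1):
                    digits.append(rem // self.n_bins**k)
                    rem %= self.n_bins**k
                fams = "|".join(self.families[f] for f in combo)
                bins_s = ",".join(f"[{self.bins[d][0]:g},{self.bins[d][1]:g})" for d in digits)
                return f"{n}pt({fams};{bins_s})"
        raise IndexError(index)

    def config_dict(self) -> dict:
        return {
            "families": list(self.families),
            "bins": [list(b) for b in self.bins],
            "point_counts": list(self.point_counts),
            "dimension": self.dimension,
        }

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.config_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def build_signature_space(
    families: Sequence[str] = DEFAULT_FAMILIES,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    point_counts: Sequence[int] = (2, 3),
) -> SignatureSpace:
    """Enumerate the canonical signature space for the given configuration."""
    return SignatureSpace(
        families=tuple(families),
        bins=tuple(tuple(b) for b in bins),
        point_counts=tuple(sorted(point_counts)),
    )


@dataclass
class ConformerEnsemble:
    """A molecule with explicit hydrogens and one or more 3D conformers."""

    molecule: Molecule
    mol_h: Chem.Mol
    conformer_ids: list[int]
    seed: int

    def __len__(self) -> int:
        return len(self.conformer_ids)

    def coordinates(self, conf_id: int) -> np.ndarray:
        conf = self.mol_h.GetConformer(conf_id)
        return np.array(conf.GetPositions(), dtype=np.float64)


def generate_conformers(
    mol_or_smiles,
    max_n: int = DEFAULT_MAX_CONFORMERS,
    seed: int = 7,
    prune_rms: float = DEFAULT_PRUNE_RMS,
    optimize: bool = False,
) -> ConformerEnsemble:
    """Embed up to ``max_n`` distance-geometry conformers (deterministic per seed).

    Heavy-atom RMSD pruning at ``prune_rms`` Angstrom removes near-duplicate
    conformers, so rigid molecules yield fewer than ``max_n``.  Embedding
    failure after a random-coordinate retry raises
    :class:`ConformerEmbeddingError`.
    """
    molecule = as_molecule(mol_or_smiles)
    if molecule.mol.GetNumHeavyAtoms() < 1:
        raise ValueError("molecule has no heavy atoms")
    mol_h = Chem.AddHs(molecule.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = float(prune_rms)
    ids = list(AllChem.EmbedMultipleConfs(mol_h, numConfs=int(max_n), params=params))
    if not ids:
        params.useRandomCoords = True
        ids = list(AllChem.EmbedMultipleConfs(mol_h, numConfs=int(max_n), params=params))
    if not ids:
        raise ConformerEmbeddingError(
            f"3D embedding failed for {molecule.canonical_smiles!r}"
        )
    if optimize:
        AllChem.MMFFOptimizeMoleculeConfs(mol_h)
    return ConformerEnsemble(
        molecule=molecule, mol_h=mol_h, conformer_ids=ids, seed=int(seed)
    )


def perceive_sites(
    mol: Chem.Mol, conf_id: int, space: SignatureSpace
) -> list[tuple[int, np.ndarray]]:
    """Pharmacophore feature sites of one conformer.

    Returns (family index, centroid coordinates) pairs for every perceived
    feature whose family belongs to the space; other families are ignored.
    """
    factory = _feature_factory()
    sites = []
    for feat in factory.GetFeaturesForMol(mol, confId=int(conf_id)):
        fam = feat.GetFamily()
        if fam not in space.families:
            continue
        pos = feat.GetPos(int(conf_id))
        sites.append((space.family_index(fam), np.array([pos.x, pos.y, pos.z])))
    return sites


def signature_from_sites(
    sites: Sequence[tuple[int, np.ndarray]], space: SignatureSpace
) -> np.ndarray:
    """Count vector over the signature space for a set of 3D feature sites.

    Every unordered pair/triple of distinct sites whose pairwise distances all
    fall inside the bins increments exactly one canonical slot.
    """
    counts = np.zeros(space.dimension, dtype=np.int64)
    n_sites = len(sites)
    fams = [f for f, _ in sites]
    xyz = [p for _, p in sites]

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(xyz[i] - xyz[j]))

    if 2 in space.point_counts:
        for i, j in itertools.combinations(range(n_sites), 2):
            b = space.bin_of(dist(i, j))
            if b is None:
                continue
            fi, fj = sorted((fams[i], fams[j]))
            counts[space.signature_index((fi, fj), (b,))] += 1
    if 3 in space.point_counts:
        for i, j, k in itertools.combinations(range(n_sites), 3):
            d = {
                frozenset((i, j)): space.bin_of(dist(i, j)),
                frozenset((i, k)): space.bin_of(dist(i, k)),
                frozenset((j, k)): space.bin_of(dist(j, k)),
            }
            if any(b is None for b in d.values()):
                continue
            idx = _canonical_triple_index((i, j, k), fams, d, space)
            counts[idx] += 1
    return counts


def _canonical_triple_index(triple, fams, bins_by_pair, space: SignatureSpace) -> int:
    """Canonical slot of a 3-site combination.

    Sites are ordered so their families are ascending; among orderings tied on
    families the lexicographically smallest bin tuple (d01, d02, d12) wins.
    """
    best = None
    fam_sorted = tuple(sorted(fams[s] for s in triple))
    for perm in itertools.permutations(triple):
        if tuple(fams[s] for s in perm) != fam_sorted:
            continue
        bt = (
            bins_by_pair[frozenset((perm[0], perm[1]))],
            bins_by_pair[frozenset((perm[0], perm[2]))],
            bins_by_pair[frozenset((perm[1], perm[2]))],
        )
        if best is None or bt < best:
            best = bt
    return space.signature_index(fam_sorted, best)


def conformer_signature(
    ensemble: ConformerEnsemble, conf_id: int, space: SignatureSpace
) -> np.ndarray:
    """Per-conformer signature counts (nonnegative integer vector)."""
    sites = perceive_sites(ensemble.mol_h, conf_id, space)
    return signature_from_sites(sites, space)


@dataclass(frozen=True)
class Signature3CED:
    """Ensemble-averaged pharmacophore signature vector."""

    values: np.ndarray
    n_conformers: int
    space_hash: str


def compute_3ced(ensemble: ConformerEnsemble, space: SignatureSpace) -> Signature3CED:
    """Element-wise mean of per-conformer signatures over the ensemble."""
    if len(ensemble) == 0:
        raise ValueError("conformer ensemble is empty")
    sigs = np.stack(
        [conformer_signature(ensemble, cid, space) for cid in ensemble.conformer_ids]
    )
    return Signature3CED(
        values=sigs.mean(axis=0),
        n_conformers=len(ensemble),
        space_hash=space.config_hash(),
    )


def featurize_3ced(
    smiles_list: Iterable[str],
    space: SignatureSpace | None = None,
    max_n: int = DEFAULT_MAX_CONFORMERS,
    seed: int = 7,
) -> np.ndarray:
    """3CED matrix (n molecules x space.dimension)."""
    space = space or build_signature_space()
    rows = []
    for smi in smiles_list:
        ens = generate_conformers(smi, max_n=max_n, seed=seed)
        rows.append(compute_3ced(ens, space).values)
    return np.asarray(rows)
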