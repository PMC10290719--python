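"""2D molecular descriptor blocks computed with RDKit.

Three fixed-length blocks describe a ligand's 2D structure:

* **PCPP** — 208 physicochemical properties (topological/topochemical indices,
  Crippen LogP and molar refractivity, Lipinski counts, fragment counts) from
  a pinned, explicitly named registry evaluated in registry order.
* **MCFP** — the 167 MACCS structural keys.
* **MGFP** — hashed circular (Morgan) fingerprints at radii 2, 3 and 4 folded
  to 256, 512 and 1024 bits and concatenated (1792 bits).

Descriptor vectors are deterministic functions of the canonical isomeric
SMILES.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Molecule:
    """A parsed structure with its canonical isomeric SMILES."""

    canonical_smiles: str
    mol: Chem.Mol

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.canonical_smiles == other.canonical_smiles


def canonicalize(smiles: str) -> Molecule:
    """Parse a SMILES and return the molecule with canonical isomeric SMILES.

    Stereochemistry is preserved; canonicalization is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # re-parse so the atom ordering (and with it every computed descriptor)
    # depends only on the canonical form, not the input notation
    mol = Chem.MolFromSmiles(canonical)
    return Molecule(canonical_smiles=canonical, mol=mol)


def as_molecule(mol_or_smiles) -> Molecule:
    if isinstance(mol_or_smiles, Molecule):
        return mol_or_smiles
    return canonicalize(mol_or_smiles)


# Pinned registry of 208 physicochemical property names.  Descriptor sets
# drift across toolkit releases; pinning the membership keeps the block
# length and ordering reproducible.
PCPP_NAMES: tuple[str, ...] = (
    "MaxAbsEStateIndex", "MaxEStateIndex", "MinAbsEStateIndex", "MinEStateIndex", "qed", "MolWt",
    "HeavyAtomMolWt", "ExactMolWt", "NumValenceElectrons", "NumRadicalElectrons",
    "MaxPartialCharge", "MinPartialCharge", "MaxAbsPartialCharge", "MinAbsPartialCharge",
    "FpDensityMorgan1", "FpDensityMorgan2", "FpDensityMorgan3", "BCUT2D_MWHI", "BCUT2D_MWLOW",
    "BCUT2D_CHGHI", "BCUT2D_CHGLO", "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW", "BCUT2D_MRHI",
    "BCUT2D_MRLOW", "BalabanJ", "BertzCT", "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v",
    "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v", "HallKierAlpha", "Ipc", "Kappa1",
    "Kappa2", "Kappa3", "LabuteASA", "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12",
    "PEOE_VSA13", "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5", "PEOE_VSA6",
    "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9", "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3",
    "SMR_VSA4", "SMR_VSA5", "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SlogP_VSA1",
    "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4",
    "SlogP_VSA5", "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9", "TPSA", "EState_VSA1",
    "EState_VSA10", "EState_VSA11", "EState_VSA2", "EState_VSA3", "EState_VSA4", "EState_VSA5",
    "EState_VSA6", "EState_VSA7", "EState_VSA8", "EState_VSA9", "VSA_EState1", "VSA_EState10",
    "VSA_EState2", "VSA_EState3", "VSA_EState4", "VSA_EState5", "VSA_EState6", "VSA_EState7",
    "VSA_EState8", "VSA_EState9", "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles", "NumAliphaticRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles", "NumAromaticRings", "NumHAcceptors",
    "NumHDonors", "NumHeteroatoms", "NumRotatableBonds", "NumSaturatedCarbocycles",
    "NumSaturatedHeterocycles", "NumSaturatedRings", "RingCount", "MolLogP", "MolMR", "fr_Al_COO",
    "fr_Al_OH", "fr_Al_OH_noTert", "fr_ArN", "fr_Ar_COO", "fr_Ar_N", "fr_Ar_NH", "fr_Ar_OH",
    "fr_COO", "fr_COO2", "fr_C_O", "fr_C_O_noCOO", "fr_C_S", "fr_HOCCN", "fr_Imine", "fr_NH0",
    "fr_NH1", "fr_NH2", "fr_N_O", "fr_Ndealkylation1", "fr_Ndealkylation2", "fr_Nhpyrrole", "fr_SH",
    "fr_aldehyde", "fr_alkyl_carbamate", "fr_alkyl_halide", "fr_allylic_oxid", "fr_amide",
    "fr_amidine", "fr_aniline", "fr_aryl_methyl", "fr_azide", "fr_azo", "fr_barbitur", "fr_benzene",
    "fr_benzodiazepine", "fr_bicyclic", "fr_diazo", "fr_dihydropyridine", "fr_epoxide", "fr_ester",
    "fr_ether", "fr_furan", "fr_guanido", "fr_halogen", "fr_hdrzine", "fr_hdrzone", "fr_imidazole",
    "fr_imide", "fr_isocyan", "fr_isothiocyan", "fr_ketone", "fr_ketone_Topliss", "fr_lactam",
    "fr_lactone", "fr_methoxy", "fr_morpholine", "fr_nitrile", "fr_nitro", "fr_nitro_arom",
    "fr_nitro_arom_nonortho", "fr_nitroso", "fr_oxazole", "fr_oxime", "fr_para_hydroxylation",
    "fr_phenol", "fr_phenol_noOrthoHbond", "fr_phos_acid", "fr_phos_ester", "fr_piperdine",
    "fr_piperzine", "fr_priamide", "fr_prisulfonamd", "fr_pyridine", "fr_quatN", "fr_sulfide",
    "fr_sulfonamd", "fr_sulfone", "fr_term_acetylene", "fr_tetrazole", "fr_thiazole", "fr_thiocyan",
    "fr_thiophene", "fr_unbrch_alkane", "fr_urea",
)

PCPP_LENGTH = 208
MCFP_LENGTH = 167
MGFP_RADII = ((2, 256), (3, 512), (4, 1024))
MGFP_LENGTH = sum(n for _, n in MGFP_RADII)  # 1792

assert len(PCPP_NAMES) == PCPP_LENGTH, "physicochemical registry must hold 208 names"
assert len(set(PCPP_NAMES)) == PCPP_LENGTH, "physicochemical registry names must be unique"

_PCPP_FUNCS = {name: fn for name, fn in Descriptors.descList}
_missing = [n for n in PCPP_NAMES if n not in _PCPP_FUNCS]
assert not _missing, f"descriptor registry entries missing from toolkit: {_missing}"


def compute_pcpp(mol_or_smiles) -> np.ndarray:
    """208 physicochemical properties in registry order (float vector).

    Descriptors that raise or return a non-finite value are replaced by 0.0
    and logged; downstream models cannot consume NaN.
    """
    mol = as_molecule(mol_or_smiles).mol
    out = np.zeros(PCPP_LENGTH, dtype=np.float64)
    for i, name in enumerate(PCPP_NAMES):
        try:
            v = float(_PCPP_FUNCS[name](mol))
        except Exception:  # descriptor failure policy
            logger.warning("descriptor %s failed; substituting 0.0", name)
            v = 0.0
        if not math.isfinite(v):
            logger.warning("descriptor %s non-finite; substituting 0.0", name)
            v = 0.0
        out[i] = v
    return out


def compute_mcfp(mol_or_smiles) -> np.ndarray:
    """167 MACCS structural keys as a {0,1} vector."""
    mol = as_molecule(mol_or_smiles).mol
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(MCFP_LENGTH, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def compute_mgfp(mol_or_smiles) -> np.ndarray:
    """1792-bit multi-radius Morgan fingerprint (radius 2 | 3 | 4 blocks)."""
    mol = as_molecule(mol_or_smiles).mol
    parts = []
    for radius, n_bits in MGFP_RADII:
        gen = _morgan_generator(radius, n_bits)
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        parts.append(arr)
    return np.concatenate(parts)


_GEN_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GEN_CACHE:
        _GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return _GEN_CACHE[key]


@dataclass(frozen=True)
class DescriptorVector:
    """Named, concatenable descriptor blocks."""

    blocks: tuple[tuple[str, np.ndarray], ...]

    @property
    def block_names(self) -> list[str]:
        return [name for name, _ in self.blocks]

    @property
    def total_length(self) -> int:
        return sum(len(v) for _, v in self.blocks)

    def block(self, name: str) -> np.ndarray:
        for n, v in self.blocks:
            if n == name:
                return v
        raise KeyError(f"no descriptor block named {name!r}")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([np.asarray(v, dtype=np.float64) for _, v in self.blocks])


def feature_block_2d(mol_or_smiles) -> DescriptorVector:
    """The three 2D blocks [PCPP, MCFP, MGFP]; total length 2167."""
    mol = as_molecule(mol_or_smiles)
    return DescriptorVector(
        blocks=(
            ("PCPP", compute_pcpp(mol)),
            ("MCFP", compute_mcfp(mol)),
            ("MGFP", compute_mgfp(mol)),
        )
    )


def read_molecules(path) -> list[Molecule]:
    """Read structures from a SMILES list (one per line) or an SDF file."""
    path = str(path)
    if path.lower().endswith(".sdf"):
        mols = []
        for mol in Chem.SDMolSupplier(path):
            if mol is None:
                raise MoleculeParseError(f"unreadable record in {path}")
            mols.append(canonicalize(Chem.MolToSmiles(mol)))
        return mols
    with open(path) as fh:
        return [
            canonicalize(ln.strip())
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]


def featurize_2d(smiles_list: Iterable[str]) -> tuple[np.ndarray, list[str]]:
    """Descriptor matrix (n, 2167) for a list of SMILES, plus canonical forms."""
    rows, canon = [], []
    for smi in smiles_list:
        mol = as_molecule(smi)
        rows.append(feature_block_2d(mol).values)
        canon.append(mol.canonical_smiles)
    return np.asarray(rows), canon
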