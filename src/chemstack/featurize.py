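"""Structure standardization and SMILES-based feature descriptors.

Five descriptor families are exposed through a fixed registry, each with
a declared width that is part of the package contract:

========  =====  ======  ==============================================
family    width  values  content
========  =====  ======  ==============================================
AP2DC       780  binary  atom pairs at various topological distances
CDKExt     1024  binary  path-based fingerprint incl. ring features
FP4C        307  count   SMARTS functional-group match counts
MACCS       166  binary  MACCS structural keys
Pubchem     881  binary  substructure-pattern keys
========  =====  ======  ==============================================

All families are computed with RDKit.  Where RDKit's native width for a
family differs from the registered width the fingerprint is hashed or
folded to the registered width; the contract is dimension, determinism
and value kind, not bit-level parity with any particular fingerprint
program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Fragments, MACCSkeys, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConfigurationError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

#: sentinel scaffold key for ring-free molecules
ACYCLIC_SENTINEL = "<acyclic>"

_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
_FRAGMENT_PARENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def standardize_structure(smiles: str) -> str:
    """Canonical, salt-stripped, tautomer-standardized SMILES.

    Keeps the largest organic fragment, canonicalizes the tautomer and
    returns RDKit canonical SMILES.  Idempotent: re-applying to its own
    output returns the same string.
    """
    mol = _mol_from_smiles(smiles)
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_PARENT.choose(mol)
    mol = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# descriptor families


def _maccs_bits(mol) -> np.ndarray:
    # RDKit MACCS vectors carry 167 bits with bit 0 permanently unset;
    # dropping it yields the canonical 166-key block.
    fp = MACCSkeys.GenMACCSKeys(mol)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8)[1:] - ord("0")


def _bitvect_to_array(fp) -> np.ndarray:
    arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def _atom_pair_bits(mol, n_bits=780) -> np.ndarray:
    fp = rdMolDescriptors.GetHashedAtomPairFingerprintAsBitVect(mol, nBits=n_bits)
    return _bitvect_to_array(fp)


def _path_bits(mol, n_bits=1024) -> np.ndarray:
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return _bitvect_to_array(fp)


def _pattern_bits(mol, n_bits=881) -> np.ndarray:
    fp = Chem.PatternFingerprint(mol, fpSize=n_bits)
    return _bitvect_to_array(fp)


# functional-group count block: RDKit's fragment SMARTS counters, placed
# at fixed columns of a 307-wide registry (trailing columns stay zero)
_FR_FUNCS = sorted(
    (name, getattr(Fragments, name))
    for name in dir(Fragments)
    if name.startswith("fr_")
)


def _fragment_counts(mol, width=307) -> np.ndarray:
    out = np.zeros(width, dtype=np.int64)
    for i, (_, func) in enumerate(_FR_FUNCS):
        out[i] = func(mol)
    return out


#: family -> (dimension, value_kind, per-molecule row function)
FAMILY_REGISTRY = {
    "AP2DC": (780, "binary", _atom_pair_bits),
    "CDKExt": (1024, "binary", _path_bits),
    "FP4C": (307, "count", _fragment_counts),
    "MACCS": (166, "binary", _maccs_bits),
    "Pubchem": (881, "binary", _pattern_bits),
}

DEFAULT_FAMILIES = tuple(sorted(FAMILY_REGISTRY))


@dataclass
class DescriptorBlock:
    """n_compounds × d feature matrix for one descriptor family."""

    family: str
    matrix: np.ndarray
    value_kind: str
    feature_names: list[str] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self):
        if not self.feature_names:
            self.feature_names = [f"{self.family}_{i}" for i in range(self.d)]


def compute_descriptor_block(smiles_list, family: str) -> DescriptorBlock:
    """Compute one descriptor family for a list of standardized SMILES.

    The returned matrix has exactly the registry width for the family,
    row order matching input order, and is deterministic for a fixed
    RDKit version.
    """
    if family not in FAMILY_REGISTRY:
        raise ConfigurationError(
            f"unknown descriptor family {family!r}; "
            f"valid families: {sorted(FAMILY_REGISTRY)}"
        )
    dim, kind, row_func = FAMILY_REGISTRY[family]
    rows = []
    for smi in smiles_list:
        mol = _mol_from_smiles(smi)
        row = row_func(mol)
        assert row.shape == (dim,)
        rows.append(row)
    matrix = (
        np.vstack(rows) if rows else np.zeros((0, dim), dtype=np.uint8)
    )
    return DescriptorBlock(family=family, matrix=matrix, value_kind=kind)


def compute_descriptor_blocks(smiles_list, families=DEFAULT_FAMILIES):
    """All requested families as ``{family: DescriptorBlock}``."""
    return {fam: compute_descriptor_block(smiles_list, fam) for fam in families}


# ---------------------------------------------------------------------------
# physicochemical properties, circular fingerprints, scaffolds


@dataclass
class PhyschemProfile:
    """Six oral-bioavailability-relevant properties of one molecule."""

    mw: float      # molecular weight, Da
    alogp: float   # Wildman–Crippen logP
    hba: int       # H-bond acceptors
    hbd: int       # H-bond donors
    tpsa: float    # topological polar surface area, Å²
    nrotb: int     # rotatable bonds


def compute_physchem(smiles_list) -> list:
    """Physicochemical profile per compound.

    Parse failures yield a :class:`SmilesParseError` entry in the output
    list instead of aborting the batch.
    """
    profiles = []
    for smi in smiles_list:
        try:
            mol = _mol_from_smiles(smi)
        except SmilesParseError as exc:
            profiles.append(exc)
            continue
        profiles.append(
            PhyschemProfile(
                mw=Descriptors.MolWt(mol),
                alogp=Descriptors.MolLogP(mol),
                hba=rdMolDescriptors.CalcNumHBA(mol),
                hbd=rdMolDescriptors.CalcNumHBD(mol),
                tpsa=Descriptors.TPSA(mol),
                nrotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
            )
        )
    return profiles


def ecfp4(smiles: str, n_bits: int = 2048) -> np.ndarray:
    """Radius-2 Morgan (ECFP4-style) fingerprint folded to ``n_bits``."""
    mol = _mol_from_smiles(smiles)
    fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(mol, radius=2, nBits=n_bits)
    return _bitvect_to_array(fp)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| between two bit vectors.

    Two all-zero vectors have undefined overlap; 0.0 is returned with a
    warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("tanimoto of two empty bit vectors defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class ScaffoldKey:
    """Bemis–Murcko framework of a molecule as a canonical SMILES key."""

    scaffold_smiles: str
    is_acyclic_sentinel: bool = False


def murcko_scaffold(smiles: str) -> ScaffoldKey:
    """Bemis–Murcko scaffold: ring systems plus linkers, side chains pruned.

    Ring-free molecules share a single sentinel key.
    """
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(scaffold)
    if not smi:
        return ScaffoldKey(ACYCLIC_SENTINEL, is_acyclic_sentinel=True)
    return ScaffoldKey(smi)
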