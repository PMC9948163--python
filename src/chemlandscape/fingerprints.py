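"""Binary molecular fingerprints: ECFP4, MACCS, and PubChem-layout keys.

Three representations, all returned as fixed-length boolean vectors:

* ``ecfp4`` — Morgan circular fingerprint, radius 2, hashed to 2048 bits;
* ``maccs`` — the 166 MACCS structural keys;
* ``pubchem`` — an 881-position substructure-key fingerprint laid out like
  the PubChem/CACTVS fingerprint (hierarchic element counts, ring counts
  by size and composition, bonded atom pairs and neighbourhoods, and a
  functional-group panel). The catalogue is generated deterministically at
  import time and is **not** bit-compatible with CACTVS; the landscape
  statistics built on top of it are fingerprint-pluggable, and an external
  key generator can be substituted via :func:`register_fingerprint`.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import ChemLandscapeError, CurationError

FP_SIZES = {"ecfp4": 2048, "maccs": 166, "pubchem": 881}

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_ATOMIC_NUM = {"C": 6, "N": 7, "O": 8, "S": 16, "F": 9, "Cl": 17, "Br": 35,
               "I": 53, "P": 15}


def _mol(smiles: str | Chem.Mol) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else smiles
    if mol is None:
        raise CurationError(f"unparsable SMILES: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# ECFP4 / MACCS


@lru_cache(maxsize=1)
def _morgan_generator():
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def ecfp4_fingerprint(mol: Chem.Mol) -> np.ndarray:
    return _morgan_generator().GetFingerprintAsNumPy(mol).astype(bool)


def maccs_fingerprint(mol: Chem.Mol) -> np.ndarray:
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(167, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr[1:]  # bit 0 is a placeholder in RDKit's MACCS implementation


# ---------------------------------------------------------------------------
# PubChem-layout key catalogue


def _element_count_keys() -> list[tuple[str, str, int]]:
    """(kind='count', feature, threshold) element and global count keys."""
    spec = [
        ("C", (1, 2, 4, 8, 12, 16, 20, 24, 28, 32)),
        ("N", (1, 2, 3, 4, 5, 6, 7, 8)),
        ("O", (1, 2, 3, 4, 5, 6, 8, 10, 12, 16)),
        ("S", (1, 2, 3, 4)),
        ("F", (1, 2, 3, 4, 6, 8)),
        ("Cl", (1, 2, 3, 4, 6)),
        ("Br", (1, 2, 3)),
        ("I", (1, 2)),
        ("P", (1, 2)),
    ]
    keys = [("count", f"elem_{el}", t) for el, ts in spec for t in ts]
    for el in ("B", "Si", "Se", "Li", "Na", "K", "Mg", "Ca", "Zn", "Fe"):
        keys.append(("count", f"elem_{el}", 1))
    for feature, ts in [
        ("heavy_atoms", (4, 8, 12, 16, 20, 24, 28, 32, 40, 48)),
        ("aromatic_atoms", (1, 4, 6, 8, 10, 12, 16, 20)),
        ("heteroatoms", (1, 2, 3, 4, 6, 8, 10, 12)),
        ("halogens", (1, 2, 3, 4, 5, 6)),
        ("ring_atoms", (3, 5, 6, 8, 10, 12, 16, 20)),
        ("pos_charges", (1,)),
        ("neg_charges", (1,)),
    ]:
        keys.extend(("count", feature, t) for t in ts)
    return keys


def _ring_count_keys() -> list[tuple[str, str, int]]:
    keys = []
    for size in range(3, 11):
        for variant in ("any", "carbo", "nitro", "hetero"):
            keys.extend(
                ("count", f"ring{size}_{variant}", t) for t in (1, 2, 3, 4, 5)
            )
    for feature, ts in [
        ("aromatic_rings", (1, 2, 3, 4, 5)),
        ("heteroaromatic_rings", (1, 2, 3, 4)),
        ("saturated_rings", (1, 2, 3, 4)),
        ("total_rings", (1, 2, 3, 4, 5, 6)),
        ("fused_ring_bonds", (1, 2, 4, 6)),
    ]:
        keys.extend(("count", feature, t) for t in ts)
    return keys


def _pair_smarts_keys() -> list[tuple[str, str]]:
    keys = []
    for i, a in enumerate(_ELEMENTS):
        for b in _ELEMENTS[i:]:
            keys.append(("smarts", f"[#{_ATOMIC_NUM[a]}]~[#{_ATOMIC_NUM[b]}]"))
    single = ("C", "N", "O", "S", "P")
    for i, a in enumerate(single):
        for b in single[i:]:
            keys.append(("smarts", f"[#{_ATOMIC_NUM[a]}]-[#{_ATOMIC_NUM[b]}]"))
    double = ("C", "N", "O", "S")
    for i, a in enumerate(double):
        for b in double[i:]:
            keys.append(("smarts", f"[#{_ATOMIC_NUM[a]}]=[#{_ATOMIC_NUM[b]}]"))
    keys.append(("smarts", "C#C"))
    keys.append(("smarts", "C#N"))
    for pat in ("c:c", "c:n", "n:n", "c:o", "c:s"):
        keys.append(("smarts", pat))
    return keys


def _triple_smarts_keys() -> list[tuple[str, str]]:
    keys = []
    for centre in ("C", "N", "O", "S"):
        for i, a in enumerate(_ELEMENTS):
            for b in _ELEMENTS[i:]:
                keys.append(
                    (
                        "smarts",
                        f"[#{_ATOMIC_NUM[a]}]~[#{_ATOMIC_NUM[centre]}]"
                        f"~[#{_ATOMIC_NUM[b]}]",
                    )
                )
    return keys


def _ring_context_keys() -> list[tuple[str, str]]:
    keys = []
    for i, a in enumerate(_ELEMENTS):
        for b in _ELEMENTS[i:]:
            keys.append(
                ("smarts", f"[#{_ATOMIC_NUM[a]};R]~[#{_ATOMIC_NUM[b]};R]")
            )
    for a in _ELEMENTS:
        for b in _ELEMENTS:
            keys.append(
                ("smarts", f"[#{_ATOMIC_NUM[a]};!R]~[#{_ATOMIC_NUM[b]};R]")
            )
    return keys


def _chain_smarts_keys() -> list[tuple[str, str]]:
    keys = []
    for i, a in enumerate(_ELEMENTS):
        for b in _ELEMENTS[i:]:
            keys.append(
                ("smarts", f"[#{_ATOMIC_NUM[a]}]~[#6]~[#6]~[#{_ATOMIC_NUM[b]}]")
            )
    for a in _ELEMENTS:
        for b in _ELEMENTS:
            keys.append(
                ("smarts", f"[#{_ATOMIC_NUM[a]}]~[#6]~[#7]~[#{_ATOMIC_NUM[b]}]")
            )
    return keys


FUNCTIONAL_SMARTS = (
    "C(=O)[OX2H1]", "C(=O)O[#6]", "C(=O)[NX3]", "C(=O)[NX3H2]",
    "C(=O)[NX3H1][#6]", "C(=O)[NX3]([#6])[#6]", "[#6]C(=O)[#6]", "[CX3H1]=O",
    "[NX3]C(=O)O", "[NX3]C(=O)[NX3]", "[NX3]C(=S)[NX3]", "[NX3]C(=N)[NX3]",
    "C(=N)[NX3]", "N=C=O", "[N+](=O)[O-]", "[NX2]=O", "N=N", "N=[N+]=[N-]",
    "[NX3][NX3]", "[NX3][OX2H]", "C=N[OX2H]", "C=N", "C=C[NX3]", "c[NX3]",
    "[NX3H2][#6]", "[NX3H1]([#6])[#6]", "[NX3]([#6])([#6])[#6]", "[NX4+]",
    "[#6][OX2H]", "c[OX2H]", "[#6][OX2][#6]", "c[OX2][#6]", "[OX2][CH3]",
    "[OX2][OX2]", "C1OC1", "[CX4]([OX2])[OX2]", "[#6][SX2H]",
    "[#6][SX2][#6]", "[SX2][SX2]", "[SX3]=O", "S(=O)(=O)",
    "S(=O)(=O)[NX3]", "S(=O)(=O)[OX2H]", "S(=O)(=O)O[#6]", "C=S",
    "P(=O)(O)(O)O", "[PX4](=O)", "C(F)(F)F", "C(Cl)(Cl)Cl", "[CX4](F)F",
    "cF", "cCl", "cBr", "cI", "[CX4][F,Cl,Br,I]", "C=C", "C=CC",
    "C=CC=C", "C=CC=O", "c[CH2]", "cC=C", "c1ccccc1-c1ccccc1",
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1cc[nH]c1", "c1ccoc1",
    "c1ccsc1", "c1c[nH]cn1", "c1cc[nH]n1", "c1ocnc1", "c1scnc1",
    "c1ccc2ccccc2c1", "c1ccc2c(c1)cc[nH]2", "c1ccc2ncccc2c1",
    "C1COCCN1", "C1CNCCN1", "C1CCNCC1", "C1CCNC1", "C1CCOC1",
    "c1ccc(cc1)[F,Cl,Br,I]", "cC(=O)[NX3]", "cS(=O)(=O)", "OC(F)(F)F",
    "cC#N", "cC(F)(F)F", "[OX2H][CX4][CX4][OX2H]", "[NX3][CX4][CX4][OX2H]",
    "cncn", "cnc[nH]", "c-n", "[#6]=[#6]-[#6]=[#6]-[#6]=[#6]",
)


@lru_cache(maxsize=1)
def _pubchem_catalogue():
    """The deterministic 881-key catalogue (kind, payload[, threshold])."""
    keys: list[tuple] = []
    keys.extend(_element_count_keys())
    keys.extend(_ring_count_keys())
    keys.extend(_pair_smarts_keys())
    keys.extend(_triple_smarts_keys())
    keys.extend(_ring_context_keys())
    keys.extend(_chain_smarts_keys())
    keys.extend(("smarts", s) for s in FUNCTIONAL_SMARTS)
    if len(keys) < 881:
        raise ChemLandscapeError(
            f"pubchem key catalogue too small: {len(keys)} < 881"
        )
    keys = keys[:881]
    compiled = []
    for key in keys:
        if key[0] == "smarts":
            query = Chem.MolFromSmarts(key[1])
            if query is None:
                raise ChemLandscapeError(f"bad SMARTS in catalogue: {key[1]}")
            compiled.append(("smarts", query))
        else:
            compiled.append(key)
    return compiled


def _count_features(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    halogens = {9, 17, 35, 53}
    n_hetero = n_arom = n_halo = n_ring = n_pos = n_neg = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[f"elem_{sym}"] = counts.get(f"elem_{sym}", 0) + 1
        z = atom.GetAtomicNum()
        if z not in (1, 6):
            n_hetero += 1
        if atom.GetIsAromatic():
            n_arom += 1
        if z in halogens:
            n_halo += 1
        if atom.IsInRing():
            n_ring += 1
        if atom.GetFormalCharge() > 0:
            n_pos += 1
        elif atom.GetFormalCharge() < 0:
            n_neg += 1
    counts["heavy_atoms"] = mol.GetNumHeavyAtoms()
    counts["aromatic_atoms"] = n_arom
    counts["heteroatoms"] = n_hetero
    counts["halogens"] = n_halo
    counts["ring_atoms"] = n_ring
    counts["pos_charges"] = n_pos
    counts["neg_charges"] = n_neg

    ring_info = mol.GetRingInfo()
    n_aromatic_rings = n_heteroaromatic = n_saturated = 0
    for ring in ring_info.AtomRings():
        size = len(ring)
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        has_hetero = any(a.GetAtomicNum() not in (1, 6) for a in atoms)
        has_n = any(a.GetAtomicNum() == 7 for a in atoms)
        if 3 <= size <= 10:
            for variant, hit in (
                ("any", True),
                ("carbo", not has_hetero),
                ("nitro", has_n),
                ("hetero", has_hetero),
            ):
                if hit:
                    name = f"ring{size}_{variant}"
                    counts[name] = counts.get(name, 0) + 1
        if aromatic:
            n_aromatic_rings += 1
            if has_hetero:
                n_heteroaromatic += 1
        elif all(
            not a.GetIsAromatic() for a in atoms
        ) and not any(
            mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % size]).GetBondType()
            != Chem.BondType.SINGLE
            for i in range(size)
        ):
            n_saturated += 1
    counts["aromatic_rings"] = n_aromatic_rings
    counts["heteroaromatic_rings"] = n_heteroaromatic
    counts["saturated_rings"] = n_saturated
    counts["total_rings"] = ring_info.NumRings()
    counts["fused_ring_bonds"] = sum(
        1 for b in mol.GetBonds() if ring_info.NumBondRings(b.GetIdx()) >= 2
    )
    return counts


def pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    catalogue = _pubchem_catalogue()
    counts = _count_features(mol)
    bits = np.zeros(881, dtype=bool)
    for i, key in enumerate(catalogue):
        if key[0] == "count":
            bits[i] = counts.get(key[1], 0) >= key[2]
        else:
            bits[i] = mol.HasSubstructMatch(key[1])
    return bits


# ---------------------------------------------------------------------------
# dispatch

_BACKENDS: dict[str, Callable[[Chem.Mol], np.ndarray]] = {
    "ecfp4": ecfp4_fingerprint,
    "maccs": maccs_fingerprint,
    "pubchem": pubchem_fingerprint,
}


def register_fingerprint(
    kind: str, size: int, fn: Callable[[Chem.Mol], np.ndarray]
) -> None:
    """Plug in an alternative fingerprint backend (e.g. an external
    PubChem key generator for bit-exact parity)."""
    _BACKENDS[kind] = fn
    FP_SIZES[kind] = size


def fingerprint(smiles: str | Chem.Mol, kind: str = "ecfp4") -> np.ndarray:
    """Boolean bit vector of the requested kind for one molecule."""
    if kind not in _BACKENDS:
        raise ChemLandscapeError(
            f"unknown fingerprint kind {kind!r}; choose from {sorted(_BACKENDS)}"
        )
    mol = _mol(smiles)
    bits = _BACKENDS[kind](mol)
    if mol.GetNumHeavyAtoms() >= 1 and not bits.any():
        import logging

        logging.getLogger(__name__).info(
            "all-zero %s fingerprint for a molecule with heavy atoms", kind
        )
    return bits


def fingerprint_matrix(
    smiles_list: Sequence[str], kind: str = "ecfp4"
) -> np.ndarray:
    """Stack fingerprints into an (n, n_bits) boolean matrix."""
    return np.vstack([fingerprint(s, kind) for s in smiles_list])
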