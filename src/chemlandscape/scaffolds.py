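"""Murcko scaffolds, cyclic skeletons, diversity metrics, EF, R-groups.

A Bemis-Murcko scaffold is a molecule's framework: all ring systems plus
the linker atoms connecting them, with terminal side chains removed. The
cyclic skeleton (CSK) abstracts the scaffold one step further — every atom
becomes carbon and every bond a single bond — so it captures ring/linker
topology only (benzene and pyridine share one CSK).

Scaffold diversity is summarised by N (molecules), Ns (scaffolds), Nss
(singleton scaffolds) and Ncsk (cyclic skeletons) with the ratios Ns/N,
Nss/N, Ncsk/N and Ncsk/Ns. The enrichment factor (EF) of a scaffold is
the proportion of group-1 (potent+active) molecules among its members
divided by the group-1 proportion of the whole dataset; EF > 1 marks a
favourable scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ChemLandscapeError, CurationError, DecompositionError
from .io_curation import ActivityClass, CuratedMolecule, GROUP1_CLASSES

logger = logging.getLogger(__name__)

#: Sentinel scaffold SMILES for acyclic molecules.
ACYCLIC = ""


@dataclass
class ScaffoldRecord:
    """One distinct Murcko scaffold with its members and enrichment factor."""

    scaffold_smiles: str
    csk_smiles: str
    member_ids: tuple[str, ...]
    frequency: int
    ef: Optional[float] = None
    acyclic: bool = False


@dataclass
class DiversityReport:
    """Raw diversity counts; ratios are derived, reported to 3 decimals."""

    n: int
    ns: int
    nss: int
    ncsk: int

    @property
    def ns_n(self) -> float:
        return self.ns / self.n

    @property
    def nss_n(self) -> float:
        return self.nss / self.n

    @property
    def ncsk_n(self) -> float:
        return self.ncsk / self.n

    @property
    def ncsk_ns(self) -> float:
        return self.ncsk / self.ns

    def as_row(self) -> dict:
        return {
            "N": self.n,
            "Ns": self.ns,
            "Nss": self.nss,
            "Ncsk": self.ncsk,
            "Ns/N": round(self.ns_n, 3),
            "Nss/N": round(self.nss_n, 3),
            "Ncsk/N": round(self.ncsk_n, 3),
            "Ncsk/Ns": round(self.ncsk_ns, 3),
        }


def murcko_scaffold(smiles: str | Chem.Mol) -> str:
    """Canonical SMILES of the Bemis-Murcko framework ('' if acyclic)."""
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else smiles
    if mol is None:
        raise CurationError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC
    return Chem.MolToSmiles(scaffold)


def cyclic_skeleton(scaffold_smiles: str) -> str:
    """CSK of a scaffold: every atom to carbon, every bond to single."""
    if not scaffold_smiles:
        raise ChemLandscapeError("cyclic skeleton of an empty scaffold is undefined")
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise CurationError(f"unparsable scaffold SMILES: {scaffold_smiles!r}")
    generic = MurckoScaffold.MakeScaffoldGeneric(mol)
    return Chem.MolToSmiles(generic)


def build_scaffold_table(
    curated: Sequence[CuratedMolecule],
) -> list[ScaffoldRecord]:
    """Group molecules by scaffold; sort by frequency desc, then SMILES.

    Acyclic molecules are pooled under one record flagged ``acyclic``.
    Enrichment factors are filled in when the dataset has at least one
    group-1 molecule, otherwise left ``None`` with a warning.
    """
    if not curated:
        raise ChemLandscapeError("curated set is empty")
    groups: dict[str, list[CuratedMolecule]] = {}
    for m in curated:
        groups.setdefault(murcko_scaffold(m.smiles), []).append(m)

    n_group1 = sum(1 for m in curated if m.activity_class in GROUP1_CLASSES)
    if n_group1 == 0:
        logger.warning("dataset has no potent/active molecules: EF undefined")

    records = []
    for scaffold, members in groups.items():
        acyclic = scaffold == ACYCLIC
        if acyclic:
            logger.warning("%d acyclic molecule(s) pooled under empty scaffold",
                           len(members))
        rec = ScaffoldRecord(
            scaffold_smiles=scaffold,
            csk_smiles=cyclic_skeleton(scaffold) if not acyclic else "",
            member_ids=tuple(m.molecule_id for m in members),
            frequency=len(members),
            acyclic=acyclic,
        )
        if n_group1 > 0:
            rec.ef = enrichment_factor(rec, curated)
        records.append(rec)
    records.sort(key=lambda r: (-r.frequency, r.scaffold_smiles))
    return records


def enrichment_factor(
    record: ScaffoldRecord, curated: Sequence[CuratedMolecule]
) -> float:
    """EF = (group-1 fraction among members) / (group-1 fraction overall)."""
    by_id = {m.molecule_id: m for m in curated}
    n_group1 = sum(1 for m in curated if m.activity_class in GROUP1_CLASSES)
    if n_group1 == 0:
        raise ChemLandscapeError("EF undefined: dataset has no group-1 molecules")
    member_group1 = sum(
        1
        for mid in record.member_ids
        if by_id[mid].activity_class in GROUP1_CLASSES
    )
    return (member_group1 / record.frequency) / (n_group1 / len(curated))


def _diversity_of(curated: Sequence[CuratedMolecule]) -> DiversityReport:
    scaffolds = [murcko_scaffold(m.smiles) for m in curated]
    distinct = set(scaffolds)
    counts = pd.Series(scaffolds).value_counts()
    csks = {cyclic_skeleton(s) for s in distinct if s != ACYCLIC}
    return DiversityReport(
        n=len(curated),
        ns=len(distinct),
        nss=int((counts == 1).sum()),
        ncsk=len(csks),
    )


def diversity_metrics(
    curated: Sequence[CuratedMolecule], by_class: bool = True
) -> dict[str, DiversityReport]:
    """Diversity report for the complete set and (optionally) per class.

    Per-class sets are computed independently, so class-level counts may
    add up to more than the complete set where scaffolds are shared
    between classes.
    """
    if not curated:
        raise ChemLandscapeError("curated set is empty")
    reports = {"complete": _diversity_of(curated)}
    if by_class:
        for cls in ActivityClass:
            members = [m for m in curated if m.activity_class == cls]
            if not members:
                logger.warning("class %s is empty: report omitted", cls.value)
                continue
            reports[cls.value] = _diversity_of(members)
    return reports


def diversity_frame(reports: dict[str, DiversityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {name: rep.as_row() for name, rep in reports.items()}
    ).T.rename_axis("subset")


# ---------------------------------------------------------------------------
# R-group decomposition


def _scaffold_positions(scaffold: Chem.Mol) -> dict[int, str]:
    """Map substitutable scaffold atom index -> R-label.

    Positions are scaffold atoms with at least one hydrogen; labels R1..Rk
    follow the canonical atom ranking of the scaffold so they are stable
    across members and runs.
    """
    ranks = list(Chem.CanonicalRankAtoms(scaffold))
    subs = [
        a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() > 0
    ]
    subs.sort(key=lambda i: ranks[i])
    return {idx: f"R{pos + 1}" for pos, idx in enumerate(subs)}


def rgroup_decompose(
    member: CuratedMolecule | str, scaffold_smiles: str
) -> dict[str, str]:
    """Substituent SMILES per scaffold position; hydrogen where unsubstituted."""
    smiles = member.smiles if isinstance(member, CuratedMolecule) else member
    member_id = member.molecule_id if isinstance(member, CuratedMolecule) else smiles
    mol = Chem.MolFromSmiles(smiles)
    scaffold = Chem.MolFromSmiles(scaffold_smiles) if scaffold_smiles else None
    if mol is None or scaffold is None:
        raise CurationError(f"unparsable SMILES in decomposition for {member_id}")
    if not mol.HasSubstructMatch(scaffold):
        raise DecompositionError(
            f"member {member_id} does not contain scaffold {scaffold_smiles}"
        )
    labels = _scaffold_positions(scaffold)
    result = {label: "[H]" for label in labels.values()}

    stripped = Chem.ReplaceCore(mol, scaffold, labelByIndex=True)
    if stripped is None:
        raise DecompositionError(f"decomposition failed for member {member_id}")
    for frag in Chem.GetMolFrags(stripped, asMols=True, sanitizeFrags=False):
        attach_idx = None
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                # ReplaceCore encodes the core attachment atom index as the
                # dummy's isotope
                attach_idx = atom.GetIsotope()
                break
        if attach_idx is None:
            continue
        label = labels.get(attach_idx)
        if label is None:
            raise DecompositionError(
                f"substituent at non-substitutable scaffold atom {attach_idx} "
                f"for member {member_id}"
            )
        frag_smiles = Chem.MolToSmiles(frag)
        result[label] = frag_smiles
    return result


def rgroup_table(
    curated: Sequence[CuratedMolecule], scaffold_smiles: str
) -> pd.DataFrame:
    """Long-format SAR table: one row per member of the given scaffold."""
    rows = []
    for m in curated:
        mol = Chem.MolFromSmiles(m.smiles)
        scaffold = Chem.MolFromSmiles(scaffold_smiles)
        if mol is None or not mol.HasSubstructMatch(scaffold):
            continue
        row = {
            "molecule_id": m.molecule_id,
            "pic50": m.pic50,
            "activity_class": m.activity_class.value,
        }
        row.update(rgroup_decompose(m, scaffold_smiles))
        rows.append(row)
    if not rows:
        raise DecompositionError(
            f"no curated molecule contains scaffold {scaffold_smiles}"
        )
    return pd.DataFrame(rows).set_index("molecule_id")
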