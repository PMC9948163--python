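"""ChEMBL-shaped synthetic bioactivity tables with known ground truth.

The generator emits an IC50 assay table whose structure mirrors a real
ChEMBL export: scaffold families with R-group variants, lognormal IC50
values spanning all four activity classes, exact duplicate rows by
molecule ID, records with missing values or qualified (non-"=") relations,
and planted activity-cliff pairs.

Each of the eight scaffold family templates carries three substitution
slots. Two of them (``x1``, ``x2``) sit at the para positions of a pair of
symmetry-equivalent aryl arms; the third (``y``) sits on the core. A
planted cliff pair fixes ``x1`` and swaps a halogen at ``x2``: because the
twin arm preserves every fingerprint environment of the swapped-out
halogen, ECFP4 Tanimoto similarity between the pair stays above 0.9 while
the assigned pIC50 values differ by exactly ``cliff_delta``. Family
templates have pairwise-distinct cyclic skeletons, so scaffold analysis
can recover the family count exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .errors import ConfigError
from .io_curation import BioactivityRecord, records_to_frame

#: Family scaffold templates. Slot tokens are replaced by "" (hydrogen) or a
#: parenthesised substituent branch, e.g. "(F)".
FAMILY_TEMPLATES: dict[str, str] = {
    "benzene_dianilide": "COc1c(CN2CCOCC2)cc(C(=O)Nc2ccc{x1}cc2)c{y}c1C(=O)Nc1ccc{x2}cc1",
    "naphthalene_dianilide": "O=C(Nc1ccc{x1}cc1)c1cc2cc(C(=O)Nc3ccc{x2}cc3)c{y}c(CN3CCN(C)CC3)c2cc1",
    "piperazine_dibenzyl": "OCC(CO)(CO)N1CCN(CC1)C(=O)c1ccc{y}c(c1)N(Cc1ccc{x1}cc1)Cc1ccc{x2}cc1",
    "indole_dianilide": "O=S(=O)(N1CCCCC1)c1ccc2c(c1)c(C(=O)Nc1ccc{x1}cc1)c(C(=O)Nc1ccc{x2}cc1)n2CC{y_alk}",
    "benzonitrile_diamide": "N#Cc1cc(N2CCOCC2)c{y}c(c1)CN(C(=O)c1ccc{x1}cc1)C(=O)c1ccc{x2}cc1",
    "urea_dibenzyl": "O=C(N(Cc1ccc{x1}cc1)Cc1ccc{x2}cc1)N1CCC(CC1)c1ccc{y}cc1C(=O)OC",
    "quinazoline_dibenzyl": "COC(=O)c1ccc2nc(N(Cc3ccc{x1}cc3)Cc3ccc{x2}cc3)nc(N3CCOCC3)c2c1{y}",
    "sulfonamide_dibenzyl": "O=S(=O)(c1ccc{y}cc1C#N)N(CCN(Cc1ccc{x1}cc1)Cc1ccc{x2}cc1)C1CCOC1",
}

#: R-group vocabulary: substituent name -> SMILES branch ("" = hydrogen).
R_GROUPS: dict[str, str] = {
    "H": "",
    "methyl": "(C)",
    "ethyl": "(CC)",
    "F": "(F)",
    "Cl": "(Cl)",
    "Br": "(Br)",
    "nitrile": "(C#N)",
    "hydroxyl": "(O)",
    "trifluoromethyl": "(C(F)(F)F)",
    "methoxy": "(OC)",
    "amino": "(N)",
}

#: The single-position swap used for planted cliff pairs (x2 slot).
CLIFF_SWAP = ("F", "Cl")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 8 scaffold families of 40 members each, family mean pIC50
    values spanning all four activity classes with a within-family spread
    of 0.3 log units, 30 injected duplicate rows, 20 essential-value
    violations (10 missing values, 10 ``">"`` relations) and 10 planted
    cliff pairs at |delta pIC50| = 2.5.
    """

    n_scaffold_families: int = 8
    members_per_family: int | tuple[int, int] = 40
    family_mean_pic50: Sequence[float] = (5.0, 5.5, 6.3, 6.6, 7.3, 7.6, 8.3, 8.6)
    pic50_sd: float = 0.3
    n_duplicates: int = 30
    n_missing_value: int = 10
    n_noneq_relation: int = 10
    n_planted_cliffs: int = 10
    cliff_delta: float = 2.5
    pchembl_fraction: float = 0.3
    seed: int = 42

    def validate(self) -> None:
        counts = {
            "n_scaffold_families": self.n_scaffold_families,
            "n_duplicates": self.n_duplicates,
            "n_missing_value": self.n_missing_value,
            "n_noneq_relation": self.n_noneq_relation,
            "n_planted_cliffs": self.n_planted_cliffs,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.n_scaffold_families < 1:
            raise ConfigError("need at least one scaffold family")
        if self.n_scaffold_families > len(FAMILY_TEMPLATES):
            raise ConfigError(
                f"at most {len(FAMILY_TEMPLATES)} scaffold families are available"
            )
        if len(self.family_mean_pic50) < self.n_scaffold_families:
            raise ConfigError("need one family_mean_pic50 per family")
        if self.cliff_delta <= 2:
            raise ConfigError("cliff_delta must exceed 2 (the AC threshold)")
        means = list(self.family_mean_pic50)[: self.n_scaffold_families]
        if min(means) < 4 or max(means) > 9:
            raise ConfigError("family means must lie within [4, 9]")
        lo, hi = self._member_range()
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid members_per_family: {self.members_per_family}")

    def _member_range(self) -> tuple[int, int]:
        if isinstance(self.members_per_family, int):
            return self.members_per_family, self.members_per_family
        lo, hi = self.members_per_family
        return int(lo), int(hi)


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    planted_cliff_pairs: list[tuple[str, str]] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    violation_ids: list[str] = field(default_factory=list)
    family_of: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_cliff_pairs": [list(p) for p in self.planted_cliff_pairs],
                    "duplicate_ids": self.duplicate_ids,
                    "violation_ids": self.violation_ids,
                    "family_of": self.family_of,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            planted_cliff_pairs=[tuple(p) for p in data["planted_cliff_pairs"]],
            duplicate_ids=data["duplicate_ids"],
            violation_ids=data["violation_ids"],
            family_of={k: int(v) for k, v in data["family_of"].items()},
        )


def build_member_smiles(template: str, x1: str, x2: str, y: str) -> str:
    """Instantiate a family template with three R-group names; canonical SMILES."""
    smiles = template.replace("{x1}", R_GROUPS[x1]).replace("{x2}", R_GROUPS[x2])
    branch = R_GROUPS[y]
    if "{y_alk}" in smiles:
        # chain-extension slot: attach without parentheses
        smiles = smiles.replace("{y_alk}", branch[1:-1] if branch else "")
    else:
        smiles = smiles.replace("{y}", branch)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - templates/vocabulary are co-validated
        raise ConfigError(f"template instantiation failed to parse: {smiles}")
    return Chem.MolToSmiles(mol)


def _draw_unique_combo(rng, names, taken: set, max_tries: int = 2000):
    for _ in range(max_tries):
        combo = tuple(rng.choice(names) for _ in range(3))
        if combo not in taken:
            return combo
    raise ConfigError(
        "R-group vocabulary exhausted: requested more unique members than "
        "combinatorially available"
    )


def generate_dataset(
    config: Optional[SynthConfig] = None,
) -> tuple[list[BioactivityRecord], GroundTruth]:
    """Generate a synthetic bioactivity table plus its ground truth.

    Deterministic in ``config.seed``: the same config yields a
    byte-identical table.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(R_GROUPS)
    templates = list(FAMILY_TEMPLATES.values())[: config.n_scaffold_families]
    lo, hi = config._member_range()

    truth = GroundTruth()
    molecules: list[tuple[str, float, int, bool]] = []  # smiles, pic50, family, is_cliff

    # distribute planted cliffs round-robin over families
    cliffs_per_family = [0] * config.n_scaffold_families
    for c in range(config.n_planted_cliffs):
        cliffs_per_family[c % config.n_scaffold_families] += 1

    cliff_slots: list[tuple[int, int]] = []  # indices into `molecules` per pair
    for fam, template in enumerate(templates):
        mean = float(config.family_mean_pic50[fam])
        n_members = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        seen_smiles: set[str] = set()
        seen_combos: set[tuple] = set()

        n_cliff_members = 2 * cliffs_per_family[fam]
        if n_cliff_members > n_members:
            raise ConfigError(
                f"family {fam}: {cliffs_per_family[fam]} cliff pairs do not fit "
                f"into {n_members} members"
            )

        for _ in range(cliffs_per_family[fam]):
            base, swapped = CLIFF_SWAP
            for _ in range(2000):
                y = str(rng.choice(names))
                smi_a = build_member_smiles(template, base, base, y)
                smi_b = build_member_smiles(template, base, swapped, y)
                if smi_a not in seen_smiles and smi_b not in seen_smiles:
                    break
            else:
                raise ConfigError("could not place a unique cliff pair")
            seen_smiles.update((smi_a, smi_b))
            seen_combos.update({(base, base, y), (base, swapped, y)})
            ia = len(molecules)
            molecules.append((smi_a, mean + config.cliff_delta / 2, fam, True))
            molecules.append((smi_b, mean - config.cliff_delta / 2, fam, True))
            cliff_slots.append((ia, ia + 1))

        for _ in range(n_members - n_cliff_members):
            for _ in range(2000):
                combo = _draw_unique_combo(rng, names, seen_combos)
                seen_combos.add(combo)
                smi = build_member_smiles(template, *combo)
                if smi not in seen_smiles:
                    break
            else:
                raise ConfigError("R-group vocabulary exhausted for family")
            seen_smiles.add(smi)
            pic50 = float(rng.normal(mean, config.pic50_sd))
            molecules.append((smi, pic50, fam, False))

    # assemble base records with sequential ids
    records: list[BioactivityRecord] = []
    for i, (smi, pic50, fam, _is_cliff) in enumerate(molecules):
        mol_id = f"SYN{i + 1:05d}"
        truth.family_of[mol_id] = fam
        with_pchembl = bool(rng.random() < config.pchembl_fraction)
        records.append(
            BioactivityRecord(
                molecule_id=mol_id,
                smiles=smi,
                relation="=",
                standard_value=10 ** (9 - pic50),  # nM
                units="nM",
                pchembl=round(pic50, 2) if with_pchembl else None,
            )
        )
    for ia, ib in cliff_slots:
        truth.planted_cliff_pairs.append(
            (records[ia].molecule_id, records[ib].molecule_id)
        )

    # exact duplicates by molecule id
    if config.n_duplicates > len(records):
        raise ConfigError("n_duplicates exceeds the number of base records")
    dup_idx = rng.choice(len(records), size=config.n_duplicates, replace=False)
    duplicates = []
    for i in sorted(int(j) for j in dup_idx):
        src = records[i]
        truth.duplicate_ids.append(src.molecule_id)
        duplicates.append(
            BioactivityRecord(
                molecule_id=src.molecule_id,
                smiles=src.smiles,
                relation=src.relation,
                standard_value=src.standard_value,
                units=src.units,
                pchembl=src.pchembl,
            )
        )

    # essential-value violations on fresh molecule ids
    violations = []
    n_viol = config.n_missing_value + config.n_noneq_relation
    for v in range(n_viol):
        src = records[int(rng.integers(len(records)))]
        mol_id = f"SYNV{v + 1:04d}"
        truth.violation_ids.append(mol_id)
        if v < config.n_missing_value:
            violations.append(
                BioactivityRecord(
                    molecule_id=mol_id,
                    smiles=src.smiles,
                    relation="=",
                    standard_value=None,
                    units=None,
                    pchembl=None,
                )
            )
        else:
            violations.append(
                BioactivityRecord(
                    molecule_id=mol_id,
                    smiles=src.smiles,
                    relation=">",
                    standard_value=src.standard_value,
                    units=src.units,
                    pchembl=None,
                )
            )

    table = records + duplicates + violations
    order = rng.permutation(len(table))
    table = [table[int(i)] for i in order]
    return table, truth


def write_dataset(
    records: Sequence[BioactivityRecord],
    path: str | Path,
    truth: Optional[GroundTruth] = None,
    truth_path: Optional[str | Path] = None,
) -> None:
    """Write the table as a ChEMBL-layout CSV (and optionally the truth JSON)."""
    records_to_frame(records).to_csv(path, index=False)
    if truth is not None and truth_path is not None:
        truth.to_json(truth_path)
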