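"""Reading and curating ChEMBL-style bioactivity tables.

The curation pipeline follows standard practice for IC50-based SAR/QSAR
datasets:

1. drop records without essential values — no IC50 and no pChEMBL value,
   or a qualified relation (anything other than ``"="``);
2. deduplicate by molecule identifier;
3. convert IC50 to pIC50 (``pIC50 = -log10(IC50 in mol/L)``), preferring
   a reported pChEMBL value when present;
4. bin molecules into four activity classes:

   ============  ==================
   potent        pIC50 >= 8
   active        7 <= pIC50 < 8
   intermediate  6 <= pIC50 < 7
   inactive      pIC50 < 6
   ============  ==================

Group 1 is the potent+active superset, group 2 intermediate+inactive.
Molecules carrying the gonane (6-6-6-5 fused tetracyclic) ring system are
flagged as steroidal.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import CurationError, FormatError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")


class ActivityClass(str, Enum):
    POTENT = "potent"
    ACTIVE = "active"
    INTERMEDIATE = "intermediate"
    INACTIVE = "inactive"


GROUP1_CLASSES = frozenset({ActivityClass.POTENT, ActivityClass.ACTIVE})

#: Column mapping matching a ChEMBL web-client CSV export.
DEFAULT_COLUMN_MAP = {
    "molecule_id": "Molecule ChEMBL ID",
    "smiles": "Smiles",
    "standard_type": "Standard Type",
    "relation": "Standard Relation",
    "standard_value": "Standard Value",
    "units": "Standard Units",
    "pchembl": "pChEMBL Value",
}

#: Columns that must be present in an input table. ``standard_type`` and
#: ``pchembl`` are optional extras.
MANDATORY_FIELDS = ("molecule_id", "smiles", "relation", "standard_value", "units")

#: log10 offset converting an IC50 in the given unit to pIC50.
UNIT_OFFSETS = {"nM": 9.0, "uM": 6.0, "µM": 6.0, "M": 0.0}

#: Gonane — the fused 6-6-6-5 cyclopenta-perhydro-phenanthrene carbocycle.
#: Matched with generic atoms/bonds so aromatic steroids (e.g. estradiol's
#: A-ring) are recognised; swap the pattern to change the steroid definition.
GONANE_SMILES = "C1CCC2C(C1)CCC1C2CCC2CCCC21"


@dataclass
class BioactivityRecord:
    """One raw assay row from a bioactivity export."""

    molecule_id: str
    smiles: Optional[str]
    relation: Optional[str]
    standard_value: Optional[float]
    units: Optional[str]
    pchembl: Optional[float] = None
    standard_type: str = "IC50"

    def __post_init__(self):
        if not self.molecule_id:
            raise ValueError("molecule_id must be non-empty")
        if self.standard_value is not None and (
            not math.isfinite(self.standard_value) or self.standard_value < 0
        ):
            raise ValueError(
                f"standard_value must be finite and >= 0, got {self.standard_value}"
            )


@dataclass
class CuratedMolecule:
    """A deduplicated molecule with its pIC50, class, group and steroid flag."""

    molecule_id: str
    smiles: str
    pic50: float
    activity_class: ActivityClass
    group: str
    steroidal: bool


@dataclass
class CurationLog:
    """Bookkeeping of every filtering step of a curation run."""

    n_input: int = 0
    n_essential_removed: int = 0
    n_duplicate_removed: int = 0
    n_parse_failed: int = 0
    n_conversion_failed: int = 0
    n_curated: int = 0
    row_errors: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_essential_removed": self.n_essential_removed,
            "n_duplicate_removed": self.n_duplicate_removed,
            "n_parse_failed": self.n_parse_failed,
            "n_conversion_failed": self.n_conversion_failed,
            "n_curated": self.n_curated,
        }


# ---------------------------------------------------------------------------
# reading


def _cell(value):
    """Missing cells become None, never zero."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def _clean_relation(value) -> Optional[str]:
    value = _cell(value)
    if value is None:
        return None
    # ChEMBL exports quote the relation, e.g. "'='"
    return str(value).strip().strip("'\"")


def frame_to_records(
    df: pd.DataFrame, column_map: Optional[dict] = None
) -> list[BioactivityRecord]:
    """Convert a bioactivity table into records; collect row-level errors.

    Rows whose numeric cells cannot be parsed are skipped and counted;
    missing cells become ``None``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    missing = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    has_type = cmap["standard_type"] in df.columns
    has_pchembl = cmap["pchembl"] in df.columns

    records: list[BioactivityRecord] = []
    n_bad = 0
    for idx, row in df.iterrows():
        try:
            value = _cell(row[cmap["standard_value"]])
            value = float(value) if value is not None else None
            pchembl = _cell(row[cmap["pchembl"]]) if has_pchembl else None
            pchembl = float(pchembl) if pchembl is not None else None
            mol_id = _cell(row[cmap["molecule_id"]])
            if mol_id is None:
                raise ValueError("empty molecule id")
            records.append(
                BioactivityRecord(
                    molecule_id=str(mol_id),
                    smiles=_cell(row[cmap["smiles"]]),
                    relation=_clean_relation(row[cmap["relation"]]),
                    standard_value=value,
                    units=_cell(row[cmap["units"]]),
                    pchembl=pchembl,
                    standard_type=str(_cell(row[cmap["standard_type"]]) or "IC50")
                    if has_type
                    else "IC50",
                )
            )
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping row %s: %s", idx, exc)
    if n_bad:
        logger.warning("skipped %d unparsable row(s)", n_bad)
    return records


def read_bioactivity_table(
    path: str | Path,
    column_map: Optional[dict] = None,
    sep: Optional[str] = None,
) -> list[BioactivityRecord]:
    """Read a CSV/TSV bioactivity export into :class:`BioactivityRecord` s.

    ``sep=None`` sniffs the delimiter; pass ``";"`` for ChEMBL web exports.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=sep)
    return frame_to_records(df, column_map)


def records_to_frame(records: Sequence[BioactivityRecord]) -> pd.DataFrame:
    """Inverse of :func:`frame_to_records`, in ChEMBL export column layout."""
    cmap = DEFAULT_COLUMN_MAP
    return pd.DataFrame(
        {
            cmap["molecule_id"]: [r.molecule_id for r in records],
            cmap["smiles"]: [r.smiles for r in records],
            cmap["standard_type"]: [r.standard_type for r in records],
            cmap["relation"]: [r.relation for r in records],
            cmap["standard_value"]: [r.standard_value for r in records],
            cmap["units"]: [r.units for r in records],
            cmap["pchembl"]: [r.pchembl for r in records],
        }
    )


# ---------------------------------------------------------------------------
# filtering


def filter_essential(
    records: Sequence[BioactivityRecord],
) -> tuple[list[BioactivityRecord], int]:
    """Keep records with an IC50 or pChEMBL value and an exact ``"="`` relation."""
    kept = [
        r
        for r in records
        if (r.standard_value is not None or r.pchembl is not None)
        and r.relation == "="
    ]
    return kept, len(records) - len(kept)


def deduplicate(
    records: Sequence[BioactivityRecord],
) -> tuple[list[BioactivityRecord], int]:
    """Keep the first occurrence of each molecule_id, in input order."""
    seen: set[str] = set()
    kept = []
    for r in records:
        if r.molecule_id not in seen:
            seen.add(r.molecule_id)
            kept.append(r)
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# pIC50, classes, steroid flag


def compute_pic50(value: float, units: str) -> float:
    """pIC50 = -log10(IC50 in mol/L); supports nM, uM and M inputs."""
    if units not in UNIT_OFFSETS:
        raise CurationError(f"unknown units: {units!r}")
    if value is None or not math.isfinite(value) or value <= 0:
        raise CurationError(f"IC50 must be positive and finite, got {value}")
    return UNIT_OFFSETS[units] - math.log10(value)


def classify_activity(pic50: float) -> ActivityClass:
    """Four-class potency labelling on pIC50 (boundaries at 6, 7 and 8)."""
    if pic50 is None or not math.isfinite(pic50):
        raise CurationError(f"pIC50 must be finite, got {pic50}")
    if pic50 >= 8:
        return ActivityClass.POTENT
    if pic50 >= 7:
        return ActivityClass.ACTIVE
    if pic50 >= 6:
        return ActivityClass.INTERMEDIATE
    return ActivityClass.INACTIVE


def group_of(activity_class: ActivityClass) -> str:
    return "group1" if activity_class in GROUP1_CLASSES else "group2"


@lru_cache(maxsize=8)
def _steroid_query(pattern_smiles: str):
    core = Chem.MolFromSmiles(pattern_smiles)
    if core is None:
        raise CurationError(f"invalid steroid pattern: {pattern_smiles!r}")
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeAtomsGeneric = True
    params.makeBondsGeneric = True
    return Chem.AdjustQueryProperties(core, params)


def flag_steroidal(smiles: str | Chem.Mol, pattern: str = GONANE_SMILES) -> bool:
    """True iff the molecule contains the gonane 6-6-6-5 fused ring system.

    The query is element- and bond-order-agnostic, so aromatic or
    heteroatom-substituted steroid cores still match.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else smiles
    if mol is None:
        raise CurationError(f"unparsable SMILES: {smiles!r}")
    return mol.HasSubstructMatch(_steroid_query(pattern))


# ---------------------------------------------------------------------------
# curation orchestration


def _record_pic50(record: BioactivityRecord) -> float:
    """pChEMBL takes priority; otherwise convert standard_value+units."""
    if record.pchembl is not None:
        if record.standard_value is not None and record.units in UNIT_OFFSETS:
            try:
                converted = compute_pic50(record.standard_value, record.units)
                if abs(converted - record.pchembl) > 0.01:
                    logger.info(
                        "%s: pChEMBL %.3f deviates from converted pIC50 %.3f",
                        record.molecule_id,
                        record.pchembl,
                        converted,
                    )
            except CurationError:
                pass
        return record.pchembl
    return compute_pic50(record.standard_value, record.units)


def curate(
    records: Sequence[BioactivityRecord],
    dedup: str = "first",
    steroid_pattern: str = GONANE_SMILES,
) -> tuple[list[CuratedMolecule], CurationLog]:
    """Run the full curation pipeline on raw records.

    ``dedup="first"`` keeps the first record per molecule_id; ``"median"``
    aggregates pIC50 over duplicate records by median (structure taken from
    the first parsable record).
    """
    if dedup not in ("first", "median"):
        raise CurationError(f"unknown dedup policy: {dedup!r}")
    log = CurationLog(n_input=len(records))
    kept, log.n_essential_removed = filter_essential(records)

    groups: dict[str, list[BioactivityRecord]] = {}
    for r in kept:
        groups.setdefault(r.molecule_id, []).append(r)
    log.n_duplicate_removed = len(kept) - len(groups)

    curated: list[CuratedMolecule] = []
    for mol_id, grp in groups.items():
        rec = grp[0]
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            log.n_parse_failed += 1
            log.row_errors.append((mol_id, "SMILES parse failure"))
            continue
        try:
            if dedup == "median":
                values = []
                for r in grp:
                    try:
                        values.append(_record_pic50(r))
                    except CurationError:
                        pass
                if not values:
                    raise CurationError("no convertible pIC50 among duplicates")
                pic50 = statistics.median(values)
            else:
                pic50 = _record_pic50(rec)
        except CurationError as exc:
            log.n_conversion_failed += 1
            log.row_errors.append((mol_id, str(exc)))
            continue
        cls = classify_activity(pic50)
        curated.append(
            CuratedMolecule(
                molecule_id=mol_id,
                smiles=Chem.MolToSmiles(mol),
                pic50=pic50,
                activity_class=cls,
                group=group_of(cls),
                steroidal=flag_steroidal(mol, steroid_pattern),
            )
        )
    log.n_curated = len(curated)
    return curated, log


# ---------------------------------------------------------------------------
# curated-set IO


def curated_to_frame(curated: Sequence[CuratedMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in curated],
            "canonical_smiles": [m.smiles for m in curated],
            "pic50": [m.pic50 for m in curated],
            "activity_class": [m.activity_class.value for m in curated],
            "group": [m.group for m in curated],
            "steroidal": [m.steroidal for m in curated],
        }
    )


def frame_to_curated(df: pd.DataFrame) -> list[CuratedMolecule]:
    required = {"molecule_id", "canonical_smiles", "pic50", "activity_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"curated table missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        cls = ActivityClass(row["activity_class"])
        out.append(
            CuratedMolecule(
                molecule_id=str(row["molecule_id"]),
                smiles=row["canonical_smiles"],
                pic50=float(row["pic50"]),
                activity_class=cls,
                group=row.get("group", group_of(cls)),
                steroidal=bool(row.get("steroidal", False)),
            )
        )
    return out


def write_curated(curated: Sequence[CuratedMolecule], out_dir: str | Path) -> None:
    """Write the curated set as CSV plus a SMILES file (smiles + id per line)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curated_to_frame(curated).to_csv(out_dir / "curated.csv", index=False)
    with open(out_dir / "curated.smi", "w") as fh:
        for m in curated:
            fh.write(f"{m.smiles}\t{m.molecule_id}\n")


def read_curated(path: str | Path) -> list[CuratedMolecule]:
    return frame_to_curated(pd.read_csv(path))
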