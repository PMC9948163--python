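"""Structure-activity landscape: SAS maps, SALI, activity cliffs.

For every unordered molecule pair the landscape is summarised by the
Tanimoto fingerprint similarity ``sim`` and the absolute potency
difference ``|A(m1) - A(m2)|`` in pIC50 units. The SAS (structure-activity
similarity) map partitions pairs into four quadrants at thresholds 0.9
(similarity) and 2 (activity difference), both strict inequalities:

=============  ======================  ==================
quadrant       similarity              activity difference
=============  ======================  ==================
cliff          > 0.9                   > 2
smooth         > 0.9                   <= 2
nondescript    <= 0.9                  > 2
scaffold_hop   <= 0.9                  <= 2
=============  ======================  ==================

The structure-activity landscape index SALI = |A(m1) - A(m2)| / (1 - sim)
quantifies cliff character; it is undefined for structurally degenerate
pairs (sim = 1), which are flagged ``duplicate-structure`` and still
eligible as activity cliffs when their potency difference exceeds the
threshold. Activity-cliff pairs detected under every fingerprint
representation considered are "consensus" cliffs; molecules recurring in
many cliff pairs are cliff generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ChemLandscapeError
from .fingerprints import FP_SIZES, fingerprint, fingerprint_matrix
from .io_curation import CuratedMolecule

SIM_THRESHOLD = 0.9
ACT_THRESHOLD = 2.0

IdPair = tuple[str, str]


@dataclass
class ACGeneratorReport:
    molecule_id: str
    ac_count: int
    rank: int


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two empty vectors count as similarity 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ChemLandscapeError(
            f"fingerprint length mismatch: {a.shape} vs {b.shape}"
        )
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def pairwise_tanimoto(fps: np.ndarray) -> np.ndarray:
    """Full n x n Tanimoto matrix from an (n, bits) boolean matrix."""
    F = np.asarray(fps, dtype=np.float64)
    inter = F @ F.T
    counts = F.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def sali(activity_diff: float, sim: float) -> float:
    """SALI = activity difference / (1 - similarity); NaN when sim = 1."""
    if not 0 <= sim <= 1:
        raise ChemLandscapeError(f"similarity must lie in [0, 1], got {sim}")
    if activity_diff < 0:
        raise ChemLandscapeError("activity difference must be >= 0")
    if sim == 1:
        return float("nan")
    return activity_diff / (1.0 - sim)


def quadrant_of(
    sim: float,
    diff: float,
    sim_threshold: float = SIM_THRESHOLD,
    act_threshold: float = ACT_THRESHOLD,
) -> str:
    if sim > sim_threshold:
        return "cliff" if diff > act_threshold else "smooth"
    return "nondescript" if diff > act_threshold else "scaffold_hop"


def sas_map(
    curated: Sequence[CuratedMolecule],
    kind: str = "ecfp4",
    sim_threshold: float = SIM_THRESHOLD,
    act_threshold: float = ACT_THRESHOLD,
    fps: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """All n(n-1)/2 unordered pairs with similarity, SALI and quadrant.

    The output is input-order invariant: ids are sorted within each pair
    and rows sorted by (id_a, id_b). Precomputed fingerprints may be
    passed via ``fps`` (rows aligned with ``curated``).
    """
    if len(curated) < 2:
        raise ChemLandscapeError("SAS map needs at least two molecules")
    ids = [m.molecule_id for m in curated]
    act = np.array([m.pic50 for m in curated])
    if fps is None:
        fps = fingerprint_matrix([m.smiles for m in curated], kind)
    sim = pairwise_tanimoto(fps)

    iu, ju = np.triu_indices(len(curated), k=1)
    rows = []
    for i, j in zip(iu, ju):
        s = float(sim[i, j])
        d = float(abs(act[i] - act[j]))
        id_a, id_b = sorted((ids[i], ids[j]))
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "sim": s,
                "activity_diff": d,
                "sali": sali(d, s),
                "quadrant": quadrant_of(s, d, sim_threshold, act_threshold),
                "degenerate": s == 1.0,
            }
        )
    df = pd.DataFrame(rows).sort_values(["id_a", "id_b"]).reset_index(drop=True)
    return df


def ac_pairs(pairs: pd.DataFrame) -> set[IdPair]:
    """The activity-cliff pair set of a SAS-map table."""
    cliffs = pairs[pairs["quadrant"] == "cliff"]
    return {
        tuple(sorted((a, b)))
        for a, b in zip(cliffs["id_a"], cliffs["id_b"])
    }


def consensus_acs(ac_sets: Mapping[str, set[IdPair]]) -> set[IdPair]:
    """Intersection of per-fingerprint AC pair sets."""
    if len(ac_sets) < 2:
        raise ChemLandscapeError(
            "consensus needs at least two fingerprint kinds"
        )
    sets = list(ac_sets.values())
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def ac_generators(
    acs: set[IdPair], min_count: int = 2
) -> list[ACGeneratorReport]:
    """Molecules frequent among AC pairs, ranked by pair count.

    Sorted by count descending, molecule_id ascending on ties; ranks are
    1-based positions in that order.
    """
    counts = Counter()
    for a, b in acs:
        counts[a] += 1
        counts[b] += 1
    ranked = sorted(
        ((mid, c) for mid, c in counts.items() if c >= min_count),
        key=lambda t: (-t[1], t[0]),
    )
    return [
        ACGeneratorReport(molecule_id=mid, ac_count=c, rank=r + 1)
        for r, (mid, c) in enumerate(ranked)
    ]


def generators_frame(reports: Sequence[ACGeneratorReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in reports],
            "ac_count": [r.ac_count for r in reports],
            "rank": [r.rank for r in reports],
        }
    )


def run_landscape(
    curated: Sequence[CuratedMolecule],
    kinds: Sequence[str] = ("ecfp4", "maccs", "pubchem"),
    sim_threshold: float = SIM_THRESHOLD,
    act_threshold: float = ACT_THRESHOLD,
    min_gen_count: int = 2,
) -> dict:
    """SAS maps for several fingerprints plus consensus cliffs and generators."""
    pairs = {}
    acs = {}
    for kind in kinds:
        pairs[kind] = sas_map(curated, kind, sim_threshold, act_threshold)
        acs[kind] = ac_pairs(pairs[kind])
    out = {"pairs": pairs, "ac_sets": acs}
    if len(kinds) >= 2:
        out["consensus"] = consensus_acs(acs)
        out["generators"] = ac_generators(out["consensus"], min_gen_count)
    else:
        out["generators"] = ac_generators(acs[kinds[0]], min_gen_count)
    return out
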