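"""Physicochemical properties, group-wise exploratory statistics, and PCA.

Six properties span the chemical space under study: molecular weight (MW,
Da), Crippen log P, hydrogen-bond acceptor and donor counts (nHA, nHD),
rotatable-bond count (nRot) and topological polar surface area (TPSA,
Angstrom^2). Group 1 (potent+active) and group 2 (intermediate+inactive)
are contrasted per property with min/max/median/mean/skewness/kurtosis and
a two-sided Mann-Whitney U test. The same six properties, z-scored, feed
a principal component analysis of the chemical space.

Statistical conventions: skewness is the adjusted Fisher-Pearson sample
skewness and kurtosis the excess (Fisher) sample kurtosis; the U test uses
exact enumeration over rank assignments for small groups and the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ChemLandscapeError, CurationError
from .io_curation import CuratedMolecule

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("mw", "logp", "nha", "nhd", "nrot", "tpsa")

#: Largest number of rank assignments enumerated by the exact U test before
#: falling back to the normal approximation.
EXACT_ENUMERATION_LIMIT = 2_000_000


@dataclass
class PropertyVector:
    """The six-property descriptor vector of one molecule."""

    mw: float
    logp: float
    nha: int
    nhd: int
    nrot: int
    tpsa: float

    def as_tuple(self) -> tuple:
        return (self.mw, self.logp, self.nha, self.nhd, self.nrot, self.tpsa)


@dataclass
class GroupSummary:
    """Per-property, per-group summary statistics plus U-test p-values."""

    table: pd.DataFrame  # index (property, group), columns min..kurtosis
    u_pvalue: dict[str, float]


@dataclass
class PCAResult:
    """Loadings (unit-norm eigenvector coefficients), scores and variance."""

    loadings: pd.DataFrame  # properties x components
    scores: np.ndarray  # n x k
    explained_variance_pct: np.ndarray
    cumulative_variance: np.ndarray


def compute_properties(smiles: str | Chem.Mol) -> PropertyVector:
    """Compute the six-property vector for one molecule."""
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else smiles
    if mol is None:
        raise CurationError(f"unparsable SMILES: {smiles!r}")
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        nha=Lipinski.NumHAcceptors(mol),
        nhd=Lipinski.NumHDonors(mol),
        nrot=Lipinski.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
    )


def property_frame(curated: Sequence[CuratedMolecule]) -> pd.DataFrame:
    """Six properties per curated molecule, with group and class columns."""
    rows = []
    for m in curated:
        vec = compute_properties(m.smiles)
        rows.append(
            {
                "molecule_id": m.molecule_id,
                **dict(zip(PROPERTY_NAMES, vec.as_tuple())),
                "group": m.group,
                "activity_class": m.activity_class.value,
            }
        )
    return pd.DataFrame(rows).set_index("molecule_id")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic for the first sample, from midranks (handles ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Under H0 the U distribution is symmetric about n1*n2/2 (even with
    ties), so the two-sided p-value is the probability of an assignment at
    least as far from the centre as the observed one.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    centre = n1 * n2 / 2
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    d_obs = abs(u_obs - centre)
    offset = n1 * (n1 + 1) / 2
    hits = total = 0
    for subset in combinations(range(n1 + n2), n1):
        u = ranks[list(subset)].sum() - offset
        total += 1
        if abs(u - centre) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration when the smaller group has <= 8 members and the
    enumeration stays tractable; tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ChemLandscapeError("both samples must be non-empty")
    if min(len(x), len(y)) <= 8 and math.comb(
        len(x) + len(y), min(len(x), len(y))
    ) <= EXACT_ENUMERATION_LIMIT:
        return _exact_two_sided_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# group summary


def _moments(values: np.ndarray) -> dict:
    out = {
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "mean": float(values.mean()),
    }
    if len(values) > 2 and values.std(ddof=1) > 0:
        with warnings.catch_warnings():
            # near-constant samples trigger a precision-loss RuntimeWarning;
            # the resulting NaN is the documented behaviour here
            warnings.simplefilter("ignore", RuntimeWarning)
            out["skew"] = float(stats.skew(values, bias=False))
            out["kurtosis"] = float(stats.kurtosis(values, fisher=True, bias=False))
    else:
        logger.info("constant or tiny sample: skew/kurtosis undefined")
        out["skew"] = float("nan")
        out["kurtosis"] = float("nan")
    return out


def summarize_groups(curated: Sequence[CuratedMolecule]) -> GroupSummary:
    """Contrast group 1 and group 2 on all six properties."""
    frame = property_frame(curated)
    for grp in ("group1", "group2"):
        if (frame["group"] == grp).sum() == 0:
            raise ChemLandscapeError(f"{grp} is empty")
    rows = {}
    pvals = {}
    for prop in PROPERTY_NAMES:
        g1 = frame.loc[frame["group"] == "group1", prop].to_numpy(dtype=float)
        g2 = frame.loc[frame["group"] == "group2", prop].to_numpy(dtype=float)
        rows[(prop, "group1")] = _moments(g1)
        rows[(prop, "group2")] = _moments(g2)
        pvals[prop] = mann_whitney_p(g1, g2)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["property", "group"])
    return GroupSummary(table=table, u_pvalue=pvals)


# ---------------------------------------------------------------------------
# PCA


def run_pca(
    data: Sequence[PropertyVector] | pd.DataFrame | np.ndarray,
    k: Optional[int] = None,
) -> PCAResult:
    """PCA of z-scored properties (correlation-structure eigendecomposition).

    Components are ordered by decreasing explained variance. Sign
    convention: each loading column is flipped so that its
    largest-magnitude coefficient is positive.
    """
    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        X = data.to_numpy(dtype=float)
    elif isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=float)
        names = [f"var{i + 1}" for i in range(X.shape[1])]
    else:
        X = np.array([v.as_tuple() for v in data], dtype=float)
        names = list(PROPERTY_NAMES)
    n, p = X.shape
    if n < 2:
        raise ChemLandscapeError("PCA needs at least two observations")
    k = p if k is None else int(k)
    if not 1 <= k <= p:
        raise ChemLandscapeError(f"k must be in [1, {p}], got {k}")

    sd = X.std(axis=0, ddof=1)
    constant = [names[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        raise ChemLandscapeError(
            f"constant column(s) {constant}: remove before PCA"
        )
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # p x k, unit-norm columns

    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    var_pct = pca.explained_variance_ratio_ * 100.0
    return PCAResult(
        loadings=pd.DataFrame(
            loadings, index=names, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        scores=scores,
        explained_variance_pct=var_pct,
        cumulative_variance=np.cumsum(var_pct),
    )
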