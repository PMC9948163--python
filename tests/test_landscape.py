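"""Fingerprints, Tanimoto, SALI, SAS maps, cliffs, consensus, generators."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemlandscape.errors import ChemLandscapeError
from chemlandscape.fingerprints import FP_SIZES, fingerprint
from chemlandscape.io_curation import CuratedMolecule, classify_activity, group_of
from chemlandscape.landscape import (
    ac_generators,
    ac_pairs,
    consensus_acs,
    quadrant_of,
    sali,
    sas_map,
    tanimoto,
)


def molecule(mol_id, smiles, pic50):
    cls = classify_activity(pic50)
    return CuratedMolecule(mol_id, smiles, pic50, cls, group_of(cls), False)


# ---------------------------------------------------------------------------
# fingerprints


@pytest.mark.parametrize("kind", ["ecfp4", "maccs", "pubchem"])
def test_fingerprints_are_deterministic_with_fixed_length(kind):
    a = fingerprint("CC(=O)Nc1ccc(O)cc1", kind)
    b = fingerprint("CC(=O)Nc1ccc(O)cc1", kind)
    assert len(a) == FP_SIZES[kind]
    assert np.array_equal(a, b)
    assert a.any()


def test_benzene_toluene_ecfp4_similarity_strictly_between_0_and_1():
    s = tanimoto(fingerprint("c1ccccc1"), fingerprint("Cc1ccccc1"))
    assert 0.0 < s < 1.0


def test_methane_has_nearly_empty_maccs_key_set():
    assert fingerprint("C", "maccs").sum() <= 2


# ---------------------------------------------------------------------------
# tanimoto


def test_tanimoto_examples():
    a = np.array([1, 1, 0, 0], dtype=bool)
    b = np.array([1, 0, 1, 0], dtype=bool)
    assert tanimoto(a, a) == 1.0
    assert tanimoto(a, ~a) == 0.0
    assert tanimoto(a, b) == pytest.approx(1 / 3)
    assert tanimoto(np.zeros(4, bool), np.zeros(4, bool)) == 0.0


def test_tanimoto_length_mismatch_is_an_error():
    with pytest.raises(ChemLandscapeError):
        tanimoto(np.zeros(4, bool), np.zeros(5, bool))


# ---------------------------------------------------------------------------
# SALI


def test_sali_examples():
    assert sali(3.0, 0.95) == pytest.approx(60.0)
    assert sali(2.0, 0.0) == pytest.approx(2.0)
    assert math.isnan(sali(2.5, 1.0))


@given(
    d1=st.floats(0.1, 5), d2=st.floats(0.1, 5),
    s1=st.floats(0, 0.99), s2=st.floats(0, 0.99),
)
def test_sali_is_monotone_in_both_arguments(d1, d2, s1, s2):
    lo_d, hi_d = sorted((d1, d2))
    lo_s, hi_s = sorted((s1, s2))
    if hi_d > lo_d:
        assert sali(hi_d, lo_s) > sali(lo_d, lo_s)
    if hi_s > lo_s:
        assert sali(lo_d, hi_s) > sali(lo_d, lo_s)


# ---------------------------------------------------------------------------
# SAS map


def test_quadrant_boundaries_are_strict():
    assert quadrant_of(0.95, 2.5) == "cliff"
    assert quadrant_of(0.95, 2.0) == "smooth"  # diff must exceed 2
    assert quadrant_of(0.9, 2.5) == "nondescript"  # sim must exceed 0.9
    assert quadrant_of(0.5, 1.0) == "scaffold_hop"


def test_sas_map_enumerates_all_pairs(small_curated):
    curated, _ = small_curated
    subset = curated[:12]
    pairs = sas_map(subset, "maccs")
    assert len(pairs) == 12 * 11 // 2


def test_sas_map_requires_two_molecules():
    with pytest.raises(ChemLandscapeError):
        sas_map([molecule("A", "CCO", 6.0)], "maccs")


def test_sas_map_is_input_order_invariant(small_curated):
    curated, _ = small_curated
    subset = curated[:10]
    fwd = sas_map(subset, "maccs")
    rev = sas_map(subset[::-1], "maccs")
    assert fwd.to_csv(index=False) == rev.to_csv(index=False)


def test_sas_map_matches_brute_force_double_loop(small_curated):
    """Independent O(n^2) recomputation must agree pair by pair."""
    curated, _ = small_curated
    subset = curated[:15]
    pairs = sas_map(subset, "ecfp4")
    table = {(r.id_a, r.id_b): r for r in pairs.itertuples()}
    fps = {m.molecule_id: set(np.flatnonzero(fingerprint(m.smiles, "ecfp4")))
           for m in subset}
    act = {m.molecule_id: m.pic50 for m in subset}
    n_checked = 0
    for i in range(len(subset)):
        for j in range(i + 1, len(subset)):
            a, b = sorted((subset[i].molecule_id, subset[j].molecule_id))
            fa, fb = fps[a], fps[b]
            sim = len(fa & fb) / len(fa | fb) if fa | fb else 0.0
            diff = abs(act[a] - act[b])
            row = table[(a, b)]
            assert row.sim == pytest.approx(sim, abs=1e-12)
            assert row.activity_diff == pytest.approx(diff, abs=1e-12)
            if sim > 0.9 and diff > 2:
                assert row.quadrant == "cliff"
            n_checked += 1
    assert n_checked == len(pairs)


def test_degenerate_identical_structures_still_count_as_cliffs():
    mols = [molecule("A", "c1ccccc1", 9.0), molecule("B", "c1ccccc1", 5.0)]
    pairs = sas_map(mols, "ecfp4")
    row = pairs.iloc[0]
    assert row.degenerate
    assert math.isnan(row.sali)
    assert row.quadrant == "cliff"
    assert ("A", "B") in ac_pairs(pairs)


def test_planted_cliffs_recovered_and_no_flat_pair_detected(
    default_dataset, curated_default
):
    _, truth = default_dataset
    curated, _ = curated_default
    pairs = sas_map(curated, "ecfp4")
    acs = ac_pairs(pairs)
    planted = {tuple(sorted(p)) for p in truth.planted_cliff_pairs}
    assert planted <= acs
    # no near-duplicate pair with a small potency gap is called a cliff
    flat = pairs[(pairs.sim > 0.9) & (pairs.activity_diff < 0.5)]
    assert set(map(tuple, flat[["id_a", "id_b"]].values)).isdisjoint(acs)


# ---------------------------------------------------------------------------
# consensus and generators


def test_consensus_is_the_intersection():
    sets = {"a": {("A", "B"), ("C", "D")}, "b": {("A", "B")}}
    assert consensus_acs(sets) == {("A", "B")}
    assert consensus_acs({"a": {("A", "B")}, "b": {("A", "B")}}) == {("A", "B")}
    assert consensus_acs({"a": {("A", "B")}, "b": {("C", "D")}}) == set()


def test_consensus_needs_two_kinds():
    with pytest.raises(ChemLandscapeError):
        consensus_acs({"a": {("A", "B")}})


def test_generator_counting_and_ranking():
    reports = ac_generators({("A", "B"), ("A", "C"), ("A", "D")}, min_count=2)
    assert [(r.molecule_id, r.ac_count, r.rank) for r in reports] == [("A", 3, 1)]
    assert ac_generators(set(), min_count=1) == []
    assert ac_generators({("A", "B"), ("C", "D")}, min_count=2) == []


def test_generator_ties_break_by_molecule_id():
    acs = {("A", "B"), ("A", "C"), ("B", "C")}
    reports = ac_generators(acs, min_count=1)
    assert [r.molecule_id for r in reports] == ["A", "B", "C"]
    assert [r.rank for r in reports] == [1, 2, 3]
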