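"""Murcko scaffolds, cyclic skeletons, diversity, EF and R-groups."""

import pytest
from rdkit import Chem

from chemlandscape.errors import ChemLandscapeError, DecompositionError
from chemlandscape.io_curation import CuratedMolecule, classify_activity, group_of
from chemlandscape.scaffolds import (
    ACYCLIC,
    DiversityReport,
    ScaffoldRecord,
    build_scaffold_table,
    cyclic_skeleton,
    diversity_metrics,
    enrichment_factor,
    murcko_scaffold,
    rgroup_decompose,
)


def molecule(mol_id, smiles, pic50):
    cls = classify_activity(pic50)
    return CuratedMolecule(mol_id, smiles, pic50, cls, group_of(cls), False)


def canonical(smiles):
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


# ---------------------------------------------------------------------------
# scaffold / CSK extraction


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("Cc1ccccc1", "c1ccccc1"),  # terminal methyl pruned
        ("CCCCCC", ACYCLIC),  # no rings
        ("C(c1ccccc1)c1ccccc1", "C(c1ccccc1)c1ccccc1"),  # all ring or linker
    ],
)
def test_murcko_scaffold_examples(smiles, expected):
    want = canonical(expected) if expected else expected
    assert murcko_scaffold(smiles) == want


@pytest.mark.parametrize(
    "scaffold,expected",
    [
        ("c1ccccc1", "C1CCCCC1"),
        ("c1ccncc1", "C1CCCCC1"),  # heteroatom and aromaticity abstracted
        ("c1ccc2ncccc2c1", "C1CCC2CCCCC2C1"),  # quinoline -> decalin skeleton
    ],
)
def test_cyclic_skeleton_examples(scaffold, expected):
    assert cyclic_skeleton(scaffold) == canonical(expected)


def test_cyclic_skeleton_of_empty_scaffold_is_an_error():
    with pytest.raises(ChemLandscapeError):
        cyclic_skeleton("")


def test_scaffold_and_csk_are_idempotent(curated_default):
    curated, _ = curated_default
    for m in curated[:40]:
        scaffold = murcko_scaffold(m.smiles)
        assert murcko_scaffold(scaffold) == scaffold
        csk = cyclic_skeleton(scaffold)
        assert cyclic_skeleton(csk) == csk


# ---------------------------------------------------------------------------
# scaffold table


def test_scaffold_table_groups_and_sorts():
    mols = [
        molecule("T1", "Cc1ccccc1", 7.5),
        molecule("T2", "CCc1ccccc1", 6.5),
        molecule("T3", "Oc1ccccc1", 5.5),
        molecule("Q1", "c1ccc2ncccc2c1", 8.5),
    ]
    table = build_scaffold_table(mols)
    assert [r.frequency for r in table] == [3, 1]
    assert set(table[0].member_ids) == {"T1", "T2", "T3"}
    assert table[0].csk_smiles == canonical("C1CCCCC1")


def test_all_acyclic_input_is_flagged():
    mols = [molecule("A", "CCCC", 6.5), molecule("B", "CCCCC", 7.5)]
    table = build_scaffold_table(mols)
    assert len(table) == 1
    assert table[0].acyclic and table[0].scaffold_smiles == ACYCLIC


def test_scaffold_table_recovers_family_count(small_dataset, small_curated):
    _, truth = small_dataset
    curated, _ = small_curated
    table = build_scaffold_table(curated)
    assert len(table) == len(set(truth.family_of.values()))
    assert sum(r.frequency for r in table) == len(curated)


# ---------------------------------------------------------------------------
# diversity


def test_diversity_arithmetic_on_a_tiny_set():
    mols = [
        molecule("A", "Cc1ccccc1", 7.5),
        molecule("B", "CCc1ccccc1", 6.5),
        molecule("C", "c1ccc2ncccc2c1", 5.5),
        molecule("D", "C1CCNCC1", 8.5),
    ]
    # scaffolds: benzene (x2), quinoline, piperidine -> Ns=3, Nss=2
    # CSKs: cyclohexane (benzene+piperidine), decalin -> Ncsk=2
    rep = diversity_metrics(mols, by_class=False)["complete"]
    assert (rep.n, rep.ns, rep.nss, rep.ncsk) == (4, 3, 2, 2)
    assert rep.as_row()["Ns/N"] == 0.75


def test_diversity_report_ratio_arithmetic():
    rep = DiversityReport(n=4, ns=2, nss=1, ncsk=2)
    assert rep.ns_n == pytest.approx(0.5)
    assert rep.nss_n == pytest.approx(0.25)
    assert rep.ncsk_n == pytest.approx(0.5)


def test_diversity_counts_are_ordered(curated_default):
    curated, _ = curated_default
    for rep in diversity_metrics(curated).values():
        assert rep.ncsk <= rep.ns <= rep.n
        assert rep.nss <= rep.ns


def test_empty_class_report_is_omitted():
    mols = [molecule("A", "c1ccccc1", 8.5), molecule("B", "CCO", 5.0)]
    reports = diversity_metrics(mols)
    assert "active" not in reports and "complete" in reports


# ---------------------------------------------------------------------------
# enrichment factor


def scaffold_record(member_ids):
    return ScaffoldRecord("c1ccccc1", "C1CCCCC1", tuple(member_ids), len(member_ids))


def test_ef_matches_hand_arithmetic():
    # 10 molecules, 4 in group 1; scaffold of 3, all group 1 -> EF 2.5
    mols = [molecule(f"G{i}", "c1ccccc1", 8.5) for i in range(4)] + [
        molecule(f"B{i}", "c1ccccc1", 5.0) for i in range(6)
    ]
    rec = scaffold_record(["G0", "G1", "G2"])
    assert enrichment_factor(rec, mols) == pytest.approx(2.5)


def test_ef_zero_when_no_group1_members():
    mols = [molecule("G0", "c1ccccc1", 8.5)] + [
        molecule(f"B{i}", "c1ccccc1", 5.0) for i in range(3)
    ]
    assert enrichment_factor(scaffold_record(["B0", "B1"]), mols) == 0.0


def test_ef_one_when_scaffold_mix_equals_dataset_mix():
    mols = [molecule("G0", "c1ccccc1", 8.5), molecule("B0", "c1ccccc1", 5.0),
            molecule("G1", "CCO", 8.5), molecule("B1", "CCO", 5.0)]
    assert enrichment_factor(scaffold_record(["G0", "B0"]), mols) == pytest.approx(1.0)


def test_ef_undefined_without_any_group1():
    mols = [molecule("B0", "c1ccccc1", 5.0), molecule("B1", "c1ccccc1", 5.5)]
    with pytest.raises(ChemLandscapeError):
        enrichment_factor(scaffold_record(["B0"]), mols)


def test_frequency_weighted_ef_averages_to_one(curated_default):
    curated, _ = curated_default
    table = build_scaffold_table(curated)
    total = sum(r.frequency * r.ef for r in table)
    assert total / len(curated) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# R-group decomposition


def test_toluene_against_benzene_has_one_methyl():
    groups = rgroup_decompose("Cc1ccccc1", "c1ccccc1")
    assert len(groups) == 6
    values = sorted(groups.values())
    assert values.count("[H]") == 5
    assert sum("C" in v for v in values) == 1


def test_molecule_identical_to_scaffold_is_all_hydrogen():
    groups = rgroup_decompose("c1ccccc1", "c1ccccc1")
    assert set(groups.values()) == {"[H]"}


def test_non_matching_member_raises():
    with pytest.raises(DecompositionError):
        rgroup_decompose("CCO", "c1ccccc1")


def test_planted_cliff_pair_differs_at_exactly_one_position(
    small_dataset, small_curated
):
    _, truth = small_dataset
    curated, _ = small_curated
    by_id = {m.molecule_id: m for m in curated}
    for a, b in truth.planted_cliff_pairs:
        scaffold = murcko_scaffold(by_id[a].smiles)
        da = rgroup_decompose(by_id[a], scaffold)
        db = rgroup_decompose(by_id[b], scaffold)
        assert da.keys() == db.keys()
        diffs = [k for k in da if da[k] != db[k]]
        assert len(diffs) == 1
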