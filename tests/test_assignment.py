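"""Peak matching, spin-system scoring, and assignment-table assembly."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from kerassign import (
    PeakList,
    apply_referencing_offset,
    assemble_table,
    assign_spin_systems,
    match_peaklist,
    predict_dqsq,
    score_spin_system,
)
from kerassign.assignment import SpinSystemMatch
from kerassign.peak_prediction import Peak2D
from kerassign.residue_model import CompositionTable
from kerassign.synthetic_data import SyntheticConfig, generate_peaklists

TYR_FIXTURE = {"CO": 174.0, "CA": 54.0, "CB": 36.0, "CG": 130.0,
               "CD": 130.0, "CE": 116.0, "CZ": 156.0}


def _displace(peaklist, df2, df1):
    return PeakList(
        experiment=peaklist.experiment,
        peaks=[Peak2D(f2=p.f2 + df2, f1=None if p.f1 is None else p.f1 + df1,
                      intensity=p.intensity) for p in peaklist.peaks],
    )


def test_identical_lists_match_perfectly(topologies):
    pred = predict_dqsq(TYR_FIXTURE, topologies["Y"])
    result = match_peaklist(pred, pred, tolerance=0.5)
    assert result.n_matched == len(pred)
    assert result.score == 0.0
    assert not result.unmatched_observed and not result.unmatched_predicted


def test_single_peak_displacement_scores_squared_distance():
    pred = PeakList("DQSQ", [Peak2D(f2=116.0, f1=271.0)])
    obs = PeakList("DQSQ", [Peak2D(f2=116.3, f1=271.3)])
    result = match_peaklist(obs, pred, tolerance=0.5)
    assert result.n_matched == 1
    assert result.score == pytest.approx(0.18)  # 0.3^2 + 0.3^2


def test_peak_beyond_tolerance_stays_unmatched():
    pred = PeakList("DQSQ", [Peak2D(f2=116.0, f1=271.0)])
    obs = PeakList("DQSQ", [Peak2D(f2=117.0, f1=271.0)])
    result = match_peaklist(obs, pred, tolerance=0.5)
    assert result.n_matched == 0
    assert len(result.unmatched_observed) == 1


def test_experiment_mismatch_rejected():
    with pytest.raises(ValueError, match="experiment"):
        match_peaklist(PeakList("DQSQ"), PeakList("PDSD"))


def test_matching_invariant_under_peak_permutation(topologies):
    pred = predict_dqsq(TYR_FIXTURE, topologies["Y"])
    obs = _displace(pred, 0.1, 0.2)
    rng = random.Random(7)
    shuffled = PeakList("DQSQ", peaks=rng.sample(obs.peaks, len(obs.peaks)))
    r1 = match_peaklist(obs, pred, 0.5)
    r2 = match_peaklist(shuffled, pred, 0.5)
    assert r1.n_matched == r2.n_matched
    assert r1.score == pytest.approx(r2.score)


def test_matching_invariant_under_consistent_referencing_offset(topologies):
    pred = predict_dqsq(TYR_FIXTURE, topologies["Y"])
    obs = _displace(pred, 0.2, 0.3)
    base = match_peaklist(obs, pred, 0.5)
    off = match_peaklist(
        apply_referencing_offset(obs, 3.0), apply_referencing_offset(pred, 3.0), 0.5
    )
    assert off.n_matched == base.n_matched
    assert off.score == pytest.approx(base.score)


def test_score_spin_system_exact_and_with_deleted_pair(topologies):
    tyr = topologies["Y"]
    full = predict_dqsq(TYR_FIXTURE, tyr)
    m = score_spin_system(full, "Y", TYR_FIXTURE, tyr)
    assert m.n_matched == m.n_predicted
    assert m.score == 0.0
    # consensus recovers the generating shifts exactly
    for atom, shift in TYR_FIXTURE.items():
        assert m.atom_shifts[atom] == pytest.approx(shift)

    pruned = PeakList("DQSQ", [p for p in full if {p.atom_i, p.atom_j} != {"CE", "CZ"}])
    m2 = score_spin_system(pruned, "Y", TYR_FIXTURE, tyr)
    assert m2.n_matched == m2.n_predicted - 2

    empty = score_spin_system(PeakList("DQSQ"), "Y", TYR_FIXTURE, tyr)
    assert empty.n_matched == 0 and not empty.resolved


def test_zero_noise_assignment_recovers_resolvable_residues(topologies, csi_refs, composition):
    """On noiseless synthetic data every residue type with at least one
    unambiguous peak is recovered with score 0 and the generating shifts."""
    cfg = SyntheticConfig(seed=11, shift_noise_sd=0.0)
    lists, truth = generate_peaklists(cfg, csi_refs, topologies)
    matches = {m.residue: m for m in
               assign_spin_systems(lists["DQSQ"], csi_refs, topologies, composition)}
    assert any(m.resolved for m in matches.values())
    for code, m in matches.items():
        assert m.class_hint == truth.classes[code]
        assert m.score == pytest.approx(0.0, abs=1e-18)
        shifts = truth.shifts[code]
        collapsed = {
            a
            for bond in topologies[code].bonds
            for a in bond
            if abs(shifts[min(bond)] - shifts[max(bond)]) <= 2.0
        }
        for atom, val in m.atom_shifts.items():
            if atom in collapsed:
                # near-equivalent bonded pairs collapse to a single
                # autocorrelation peak: only the envelope position is known
                assert val == pytest.approx(shifts[atom], abs=1.0)
            else:
                assert val == pytest.approx(shifts[atom], abs=1e-9)


def test_assignment_invariant_under_global_offset(topologies, csi_refs, composition):
    cfg = SyntheticConfig(seed=5, shift_noise_sd=0.1)
    lists, _ = generate_peaklists(cfg, csi_refs, topologies)
    base = assign_spin_systems(lists["DQSQ"], csi_refs, topologies, composition)
    # offset both the observations and the reference table consistently
    c = 2.5
    shifted_obs = apply_referencing_offset(lists["DQSQ"], c)
    shifted_refs = type(csi_refs)(
        entries={k: (v[0] + c, v[1]) for k, v in csi_refs.entries.items()},
        provenance=dict(csi_refs.provenance),
    )
    shifted = assign_spin_systems(shifted_obs, shifted_refs, topologies, composition)
    for a, b in zip(base, shifted):
        assert a.residue == b.residue
        assert a.n_matched == b.n_matched
        assert a.score == pytest.approx(b.score, abs=1e-6)
        for atom in a.atom_shifts:
            assert b.atom_shifts[atom] - a.atom_shifts[atom] == pytest.approx(c, abs=1e-6)


def _dummy_match(residue, n=1):
    return SpinSystemMatch(residue=residue, atom_shifts={"CA": 50.0, "CB": 40.0},
                           n_matched=n, n_predicted=4, score=0.0, resolved=True)


def test_assemble_table_orders_by_abundance(composition):
    matches = [_dummy_match("G"), _dummy_match("S")]
    table = assemble_table(matches, composition)
    residues = [r.residue for r in table.rows]
    assert residues[0] == "E/Q" and residues[1] == "G"
    assert table.row("E/Q").mole_percent == 13.58
    # His and Met sit below the abundance floor with no matches
    assert table.row("H").certainty == "unobserved"
    assert table.row("M").certainty == "unobserved"


def test_assemble_table_empty_matches_all_unobserved(composition):
    table = assemble_table([], composition)
    assert all(r.certainty == "unobserved" for r in table.rows)


def test_assemble_table_breaks_mole_percent_ties_alphabetically():
    comp = CompositionTable(mole_percent={"V": 5.0, "A": 5.0, "G": 7.0})
    table = assemble_table([], comp)
    assert [r.residue for r in table.rows] == ["G", "A", "V"]


def test_duplicate_matches_rejected(composition):
    with pytest.raises(ValueError):
        assemble_table([_dummy_match("G"), _dummy_match("G")], composition)
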