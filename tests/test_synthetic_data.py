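"""Synthetic generator: determinism, intensity model, raster round trips,
and full-pipeline class recovery."""

import numpy as np
import pytest

from kerassign import (
    GridSpec,
    SyntheticConfig,
    fur_reference_table,
    generate_peaklists,
    pick_peaks,
    predict_dqsq,
    render_spectrum,
    sample_shifts,
)
from kerassign.assignment import assign_spin_systems
from kerassign.peak_prediction import Peak2D, PeakList
from kerassign.residue_model import CompositionTable
from kerassign.structure_index import index_result


def test_zero_noise_shifts_equal_references(csi_refs, topologies):
    cfg = SyntheticConfig(seed=2, shift_noise_sd=0.0)
    truth = sample_shifts(cfg, csi_refs, topologies)
    for code, shifts in truth.shifts.items():
        cls = truth.classes[code]
        for atom, val in shifts.items():
            assert val == csi_refs.lookup(code, atom, cls)[0]


def test_same_seed_is_bitwise_deterministic(csi_refs, topologies):
    cfg = SyntheticConfig(seed=42, shift_noise_sd=0.3, include_lipid=True)
    a, ta = generate_peaklists(cfg, csi_refs, topologies)
    b, tb = generate_peaklists(cfg, csi_refs, topologies)
    assert ta.classes == tb.classes
    assert ta.shifts == tb.shifts
    for tag in ("CP1D", "DQSQ", "PDSD"):
        assert [(p.f2, p.f1, p.intensity) for p in a[tag]] == \
               [(p.f2, p.f1, p.intensity) for p in b[tag]]


def test_pure_class_mix_forces_class(csi_refs, topologies):
    cfg = SyntheticConfig(seed=9, class_mix={"H": 1.0, "S": 0.0, "C": 0.0})
    for seed in (1, 2, 3):
        truth = sample_shifts(cfg.model_copy(update={"seed": seed}), csi_refs, topologies)
        assert truth.classes["V"] == "H"
        assert set(truth.classes.values()) == {"H"}


def test_class_mix_must_sum_to_one():
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, class_mix={"H": 0.5, "S": 0.2, "C": 0.2})


def test_gly_only_zero_noise_gives_co_ca_pair(fur_refs, topologies):
    """100% Gly at the observed fur shifts (CO 172, CA 43): the DQ sum rule
    puts the pair at F1 = 215 with F2 at 43 and 172."""
    cfg = SyntheticConfig(
        seed=1, shift_noise_sd=0.0,
        composition=CompositionTable(mole_percent={"G": 100.0}),
    )
    lists, _ = generate_peaklists(cfg, fur_refs, topologies)
    coords = {(p.f2, p.f1) for p in lists["DQSQ"]}
    assert coords == {(43.0, 215.0), (172.0, 215.0)}


def test_lipid_contaminant_autocorrelates_near_60(csi_refs, topologies):
    cfg = SyntheticConfig(seed=1, shift_noise_sd=0.0, include_lipid=True)
    lists, _ = generate_peaklists(cfg, csi_refs, topologies)
    lipid = [p for p in lists["DQSQ"] if p.residue == "LIPID"]
    assert len(lipid) == 1
    assert (lipid[0].f2, lipid[0].f1) == (30.0, 60.0)


def test_intensity_ratio_follows_mole_percent(csi_refs, topologies):
    cfg = SyntheticConfig(seed=1, shift_noise_sd=0.0,
                          labelling_efficiency={"G": 1.0, "I": 1.0})
    lists, _ = generate_peaklists(cfg, csi_refs, topologies)
    gly = [p for p in lists["DQSQ"] if p.residue == "G"][0]
    ile_ca = [p for p in lists["DQSQ"] if p.residue == "I" and
              {p.atom_i, p.atom_j} == {"CO", "CA"}][0]
    assert gly.intensity / ile_ca.intensity == pytest.approx(12.95 / 2.93)


def test_nonessential_labelling_attenuates(csi_refs, topologies):
    cfg = SyntheticConfig(seed=1, shift_noise_sd=0.0)
    _, truth = generate_peaklists(cfg, csi_refs, topologies)
    assert truth.intensities["G"] == pytest.approx(12.95 * 0.6)  # non-essential
    assert truth.intensities["I"] == pytest.approx(2.93 * 1.0)   # essential


def test_render_single_peak_and_integral():
    pl = PeakList("DQSQ", [Peak2D(f2=100.0, f1=200.0, intensity=2.0, linewidth=1.0)])
    grid = render_spectrum(pl, GridSpec(step=0.1))
    i, j = np.unravel_index(np.argmax(grid.intensity), grid.intensity.shape)
    assert abs(grid.f1[i] - 200.0) <= 0.1 and abs(grid.f2[j] - 100.0) <= 0.1
    # closed-form 2D Gaussian volume: intensity * 2*pi*sigma^2
    sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    expected = 2.0 * 2.0 * np.pi * sigma**2
    assert grid.intensity.sum() * 0.1**2 == pytest.approx(expected, rel=1e-3)


def test_render_empty_list_gives_zero_grid_and_clipping_reported():
    grid = render_spectrum(PeakList("DQSQ"), GridSpec(step=1.0))
    assert not grid.intensity.any()
    outside = PeakList("DQSQ", [Peak2D(f2=500.0, f1=100.0)])
    clipped = render_spectrum(outside, GridSpec(step=1.0))
    assert len(clipped.clipped) == 1
    assert not clipped.intensity.any()


def test_render_then_pick_round_trip():
    peaks = [Peak2D(f2=f2, f1=f1, intensity=1.0, linewidth=0.8)
             for f2, f1 in [(43.0, 215.3), (116.2, 271.0), (155.0, 271.0), (60.4, 96.0)]]
    grid = render_spectrum(PeakList("DQSQ", peaks), GridSpec(step=0.1))
    picked = pick_peaks(grid, threshold=0.5)
    assert len(picked) == len(peaks)
    for p in peaks:
        best = min(picked, key=lambda q: (q.f2 - p.f2) ** 2 + (q.f1 - p.f1) ** 2)
        assert abs(best.f2 - p.f2) <= 0.05 and abs(best.f1 - p.f1) <= 0.05


def test_pick_high_threshold_keeps_equal_peaks():
    peaks = [Peak2D(f2=50.0, f1=100.0, linewidth=1.0), Peak2D(f2=150.0, f1=300.0, linewidth=1.0)]
    grid = render_spectrum(PeakList("DQSQ", peaks), GridSpec(step=0.2))
    assert len(pick_peaks(grid, threshold=0.99)) == 2


def test_peaks_merged_within_a_linewidth_pick_as_one():
    # two peaks 0.3 ppm apart with 1 ppm FWHM form a single maximum
    peaks = [Peak2D(f2=100.0, f1=200.0, linewidth=1.0),
             Peak2D(f2=100.3, f1=200.0, linewidth=1.0)]
    grid = render_spectrum(PeakList("DQSQ", peaks), GridSpec(step=0.1))
    assert len(pick_peaks(grid, threshold=0.5)) == 1


def _index_resolvable(truth, topologies, tol=0.5):
    """Residues whose CA and CB each contribute >=1 predicted peak that
    overlaps no other residue's predicted peaks (brute-force oracle)."""
    preds = {c: predict_dqsq(s, topologies[c])
             for c, s in truth.shifts.items() if c != "LIPID"}
    out = set()
    for code, pl in preds.items():
        if "CB" not in topologies[code].atoms:
            continue
        clean = {"CA": False, "CB": False}
        for p in pl:
            for atom in ("CA", "CB"):
                if atom in (p.atom_i, p.atom_j):
                    clash = any(
                        abs(q.f2 - p.f2) <= tol and abs(q.f1 - p.f1) <= 2 * tol
                        for c2, other in preds.items() if c2 != code
                        for q in other
                    )
                    if not clash:
                        clean[atom] = True
        if all(clean.values()):
            out.add(code)
    return out


def test_full_pipeline_recovers_classes_of_resolvable_residues(csi_refs, topologies):
    """generate -> render -> pick -> assign -> classify recovers the
    generating structure class for every index-resolvable residue in at
    least 90% of 50 seeded replicates at 0.2 ppm shift noise."""
    ok = 0
    for rep in range(50):
        cfg = SyntheticConfig(seed=1000 + rep, shift_noise_sd=0.2)
        lists, truth = generate_peaklists(cfg, csi_refs, topologies)
        grid = render_spectrum(lists["DQSQ"], GridSpec(step=0.1))
        picked = pick_peaks(grid, threshold=0.01)
        matches = {m.residue: m for m in
                   assign_spin_systems(picked, csi_refs, topologies, cfg.composition)}
        good = True
        for code in _index_resolvable(truth, topologies):
            m = matches.get(code)
            got = (index_result(code, m.atom_shifts.get("CA"), m.atom_shifts.get("CB"),
                                csi_refs).structure_class if m else None)
            if got != truth.classes[code]:
                good = False
        ok += good
    assert ok >= 45  # >= 90% of replicates
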