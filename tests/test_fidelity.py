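"""Classification, counting, background correction, collation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripletseq import (
    IncorporationModel,
    TripletCountTable,
    background_correct,
    classify_read,
    collate_positional,
    contest_ratio,
    count_triplets,
    gen_fidelity_reads,
    positional_fidelity,
    proportional_reduction,
)
from tripletseq.design import AssayDesign, TemplateSpec
from tripletseq.fidelity import PositionalErrorProfile
from tripletseq.nucleic import ALL_TRIPLETS, TRIPLET_INDEX, revcomp


def _read_for(design, template, triplets):
    return (template.primer_variant + design.primer_core + template.upstream
            + "".join(triplets) + design.adaptor)


# ------------------------------------------------------------ classification

def test_classify_basic_assignment(design):
    t = design.templates[2]
    call = classify_read(_read_for(design, t, ["GAU"]), design)
    assert call.assigned and call.template_id == t.id
    assert call.triplets == ("GAU",)


def test_classify_short_read_unassigned(design):
    call = classify_read("ACG", design)
    assert not call.assigned and call.reason == "too_short"


def test_classify_requires_ccc_start(design):
    t = design.templates[0]
    read = t.primer_variant + design.primer_core + "GCC" + "AAA" + design.adaptor
    assert classify_read(read, design).reason == "no_ccc_start"


def test_classify_partial_triplet_dropped_and_gated(design):
    t = design.templates[1]
    # one complete triplet plus a dangling base: the partial frame is dropped
    read = (t.primer_variant + design.primer_core + t.upstream + "GAU" + "A"
            + design.adaptor)
    call = classify_read(read, design)
    assert call.assigned and call.triplets == ("GAU",)
    # a lone dangling base without any complete triplet is frame-incomplete
    read0 = t.primer_variant + design.primer_core + t.upstream + "A" + design.adaptor
    assert classify_read(read0, design).reason == "frame_incomplete"


def test_classify_gates_more_than_three_triplets(design):
    t = design.templates[1]
    read = _read_for(design, t, ["GAU"] * 4)
    assert classify_read(read, design).reason == "too_many_triplets"


def test_classify_all_64_inserted_triplets_recovered(design):
    t = design.templates[5]
    for trip in ALL_TRIPLETS:
        call = classify_read(_read_for(design, t, [trip]), design)
        assert call.assigned and call.triplets[0] == trip


def test_classify_with_mismatch_tolerance(design):
    t = design.templates[3]
    read = _read_for(design, t, ["AAA"])
    mutated = ("G" if read[0] != "G" else "A") + read[1:]
    assert classify_read(mutated, design, max_mismatch=0).reason == "no_primer_match"
    call = classify_read(mutated, design, max_mismatch=1)
    assert call.assigned and call.template_id == t.id


# ---------------------------------------------------------------- counting

def _brute_force_tally(reads, design):
    """Independent single-pass tally used as a counting oracle (clean reads)."""
    counts = {t.id: np.zeros(64) for t in design.templates}
    for r in reads:
        seq = r.seq
        for t in design.templates:
            primer = t.primer_variant + design.primer_core
            if seq.startswith(primer + t.upstream):
                rest = seq[len(primer) + 3:]
                cut = rest.find(design.adaptor)
                body = rest[:cut] if cut >= 0 else rest
                k = len(body) // 3
                if 1 <= k <= 3:
                    counts[t.id][TRIPLET_INDEX[body[:3]]] += 1
                break
    return counts


def test_counting_matches_brute_force_oracle(design, error_model):
    reads = gen_fidelity_reads(design, error_model, 5000, seed=1)
    table = count_triplets(reads, design)
    oracle = _brute_force_tally(reads, design)
    for tid in design.template_ids:
        np.testing.assert_array_equal(table.counts[tid], oracle[tid])


def test_counting_conserves_reads(design, error_model):
    reads = gen_fidelity_reads(design, error_model, 3000, seed=2)
    table = count_triplets(reads, design)
    assert table.grand_total + sum(table.discards.values()) == 3000


def test_empty_read_set_gives_zero_table(design):
    table = count_triplets([], design)
    assert table.grand_total == 0


def test_count_table_tsv_round_trip(tmp_path, design, error_model):
    reads = gen_fidelity_reads(design, error_model, 2000, seed=3)
    table = count_triplets(reads, design)
    path = tmp_path / "counts.tsv"
    table.to_tsv(path)
    back = TripletCountTable.from_tsv(path, design.template_ids)
    for tid in design.template_ids:
        np.testing.assert_array_equal(table.counts[tid], back.counts[tid])


# ----------------------------------------------------- background correction

def _single_template_design():
    t = TemplateSpec(id="T", template="GGU", cognate="ACC", upstream="CCC",
                     downstream="UCC", primer_variant="AAAA")
    return AssayDesign(templates=[t])


def _table(design, kind, assignments):
    counts = {t.id: np.zeros(64) for t in design.templates}
    for (tid, trip), n in assignments.items():
        counts[tid][TRIPLET_INDEX[trip]] = n
    return TripletCountTable(kind, counts)


def test_correction_worked_example():
    """E_x=10, E_p=2, C_x=1000, C_p=500 -> E_r = 6 and the cognate gains 4."""
    d = _single_template_design()
    exp = _table(d, "experimental", {("T", "ACC"): 1000, ("T", "GCC"): 10})
    ctl = _table(d, "control", {("T", "ACC"): 500, ("T", "GCC"): 2})
    corr = background_correct(exp, ctl, d)
    assert corr.get("T", "GCC") == pytest.approx(6.0)
    assert corr.get("T", "ACC") == pytest.approx(1004.0)


def test_correction_clamps_at_zero_and_reallocates_actual_subtraction():
    """E_x=1, E_p=2, C_x=1000, C_p=500: clamp to 0, only 1 moves to C_r."""
    d = _single_template_design()
    exp = _table(d, "experimental", {("T", "ACC"): 1000, ("T", "GCC"): 1})
    ctl = _table(d, "control", {("T", "ACC"): 500, ("T", "GCC"): 2})
    corr = background_correct(exp, ctl, d)
    assert corr.get("T", "GCC") == 0.0
    assert corr.get("T", "ACC") == pytest.approx(1001.0)


def test_correction_leaves_control_set_uncorrected():
    d = _single_template_design()
    exp = _table(d, "experimental",
                 {("T", "ACC"): 100, ("T", "CCC"): 7, ("T", "UCC"): 3})
    ctl = _table(d, "control",
                 {("T", "ACC"): 50, ("T", "CCC"): 20, ("T", "UCC"): 10})
    corr = background_correct(exp, ctl, d)
    assert corr.get("T", "CCC") == 7.0
    assert corr.get("T", "UCC") == 3.0


def test_correction_identity_on_clean_control(design, error_model):
    reads = gen_fidelity_reads(design, error_model, 4000, seed=5)
    exp = count_triplets(reads, design)
    ctl_counts = {t.id: np.zeros(64) for t in design.templates}
    for t in design.templates:
        ctl_counts[t.id][TRIPLET_INDEX[t.cognate]] = 100
    ctl = TripletCountTable("control", ctl_counts)
    corr = background_correct(exp, ctl, design)
    for tid in design.template_ids:
        np.testing.assert_allclose(corr.counts[tid], exp.counts[tid])


def test_correction_zero_control_cognate_is_hard_error():
    d = _single_template_design()
    exp = _table(d, "experimental", {("T", "ACC"): 10})
    ctl = _table(d, "control", {("T", "GCC"): 5})
    with pytest.raises(ValueError, match="T"):
        background_correct(exp, ctl, d)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 30), min_size=4, max_size=4),
    ctrl=st.lists(st.integers(0, 10), min_size=4, max_size=4),
    c_x=st.integers(1, 2000),
    c_p=st.integers(1, 1000),
)
def test_correction_conserves_mass(counts, ctrl, c_x, c_p):
    d = _single_template_design()
    errs = ["GCC", "AAA", "GGG", "AGC"]
    exp = _table(d, "experimental",
                 {("T", "ACC"): c_x, **{("T", e): c for e, c in zip(errs, counts)}})
    ctl = _table(d, "control",
                 {("T", "ACC"): c_p, **{("T", e): c for e, c in zip(errs, ctrl)}})
    corr = background_correct(exp, ctl, d)
    assert corr.total("T") == pytest.approx(exp.total("T"), abs=1e-9)
    assert corr.counts["T"].min() >= 0


# -------------------------------------------------------------- collation

def test_collation_is_linear_average_over_encoding_templates(design):
    """Three templates encoding A at position 1 with rates 1/2/3% -> 2%."""
    counts = {}
    a_templates = [t for t in design.templates if t.cognate[0] == "A"]
    assert len(a_templates) == 3
    err_rates = dict(zip((t.id for t in a_templates), (0.01, 0.02, 0.03)))
    for t in design.templates:
        v = np.zeros(64)
        e = err_rates.get(t.id, 0.0)
        v[TRIPLET_INDEX[t.cognate]] = (1 - e) * 1000
        if e:
            # error changes position 1 to a different base
            wrong = "G" if t.cognate[0] != "G" else "C"
            v[TRIPLET_INDEX[wrong + t.cognate[1:]]] = e * 1000
        counts[t.id] = v
    profile = collate_positional(TripletCountTable("corrected", counts), design)
    a_idx = 0  # base A
    assert profile.rates[0, a_idx, a_idx] == pytest.approx(1 - 0.02)


def test_cognate_only_counts_give_identity_profile(design):
    counts = {}
    for t in design.templates:
        v = np.zeros(64)
        v[TRIPLET_INDEX[t.cognate]] = 500
        counts[t.id] = v
    profile = collate_positional(TripletCountTable("corrected", counts), design)
    np.testing.assert_allclose(profile.rates, PositionalErrorProfile.identity().rates)
    result = positional_fidelity(profile)
    assert result.overall_pct == pytest.approx(100.0)
    np.testing.assert_allclose(result.positional_pct, 100.0)


def test_collation_recovers_model_marginals(design, error_model):
    """Known 64-wide profile, 1e5 clean reads: collated rates within 3 s.d."""
    reads = gen_fidelity_reads(design, error_model, 100_000, seed=8)
    table = count_triplets(reads, design)
    observed = collate_positional(table, design)
    truth_counts = {tid: p.copy() for tid, p in error_model.distributions.items()}
    truth = collate_positional(TripletCountTable("corrected", truth_counts), design)
    n_per_cell = 100_000 / 12 * 3  # reads behind each collated cell
    for p in range(3):
        for e in range(4):
            for i in range(4):
                r = truth.rates[p, e, i]
                sd = np.sqrt(max(r * (1 - r), 1e-12) / n_per_cell)
                assert abs(observed.rates[p, e, i] - r) <= max(3 * sd, 5e-4)


# ------------------------------------------------------------- summaries

def test_positional_fidelity_geometric_means():
    rates = np.broadcast_to(np.eye(4), (3, 4, 4)).copy()
    diag = [0.99, 0.98, 0.97, 0.96]
    rates[0] = np.diag(diag)
    for b, f in enumerate(diag):
        rates[0, b, (b + 1) % 4] = 1 - f
    profile = PositionalErrorProfile(rates)
    result = positional_fidelity(profile)
    assert result.positional_pct[0] == pytest.approx(97.49, abs=0.005)
    # overall is the geometric mean over the three positions
    expected = np.exp(np.mean(np.log(result.positional_pct / 100))) * 100
    assert result.overall_pct == pytest.approx(expected, abs=1e-9)


def test_overall_of_97_98_99_positions():
    vals = np.array([0.97, 0.98, 0.99])
    rates = np.zeros((3, 4, 4))
    for p, f in enumerate(vals):
        rates[p] = np.diag([f] * 4)
        for b in range(4):
            rates[p, b, (b + 1) % 4] = 1 - f
    result = positional_fidelity(PositionalErrorProfile(rates))
    assert result.overall_pct == pytest.approx(98.00, abs=0.005)


def test_geometric_mean_permutation_invariant():
    rng = np.random.default_rng(0)
    diag = rng.uniform(0.9, 1.0, size=(3, 4))
    def make(d):
        rates = np.zeros((3, 4, 4))
        for p in range(3):
            for b in range(4):
                rates[p, b, b] = d[p, b]
                rates[p, b, (b + 1) % 4] = 1 - d[p, b]
        return positional_fidelity(PositionalErrorProfile(rates)).overall_pct
    shuffled = diag[::-1, ::-1].copy()
    assert make(diag) == pytest.approx(make(shuffled), abs=1e-9)


def test_zero_diagonal_floored_not_crashing():
    rates = np.broadcast_to(np.eye(4), (3, 4, 4)).copy()
    rates[1, 2, 2] = 0.0
    rates[1, 2, 3] = 1.0
    result = positional_fidelity(PositionalErrorProfile(rates), floor=1e-4)
    assert 0 < result.overall_pct < 100
    assert result.per_base_pct[1, 2] == pytest.approx(1e-2)


# ------------------------------------------------------------- contests

def test_contest_ratio_and_reduction():
    d = _single_template_design()
    before = _table(d, "experimental", {("T", "ACC"): 900, ("T", "GCC"): 100})
    assert contest_ratio(before, "T", "ACC", "GCC") == pytest.approx(0.10)
    after = _table(d, "experimental", {("T", "ACC"): 961, ("T", "GCC"): 39})
    red = proportional_reduction(before, after, "T", "ACC", "GCC")
    assert red == pytest.approx(0.61, abs=0.0001)
    assert proportional_reduction(before, before, "T", "ACC", "GCC") == 0.0


def test_contest_zero_denominator_flagged():
    d = _single_template_design()
    empty = _table(d, "experimental", {("T", "AAA"): 5})
    with pytest.raises(ValueError, match="no counts"):
        contest_ratio(empty, "T", "ACC", "GCC")
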