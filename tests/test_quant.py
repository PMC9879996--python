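import math

import numpy as np
import pytest

from mbescope import (
    SimConfig,
    aggregate_profiles,
    allele_outcomes,
    call_window,
    context_preference,
    load_registry,
    make_amplicon,
    on_off_ratio,
    product_purity,
    rloop_stats,
    simulate_reads,
    tabulate_substitutions,
    window_profile,
)
from mbescope._seq import revcomp
from mbescope.quant import (
    AmpliconDesign,
    EditingProfile,
    ReadRejectionError,
    max_edit_frequency,
)
from mbescope.scan import PamPlacement, find_pam_sites


@pytest.fixture(scope="module")
def cbe():
    return load_registry()["miniCBE-any"]


@pytest.fixture(scope="module")
def abe():
    return load_registry()["miniABE-any"]


def simple_design(ref: str) -> AmpliconDesign:
    """Wrap *ref* with an arbitrary plus-strand placement at its start."""
    pl = PamPlacement("amp", "+", (0, 4), 3, (4, 24), "cas12f_r_zero")
    return AmpliconDesign(ref, pl)


def mutate(ref: str, idx: int, base: str) -> str:
    return ref[:idx] + base + ref[idx + 1 :]


REF = "TTTA" + "CGCG" * 14  # 60 nt, PAM at the start


def test_positionwise_counts_and_n_exclusion():
    design = simple_design(REF)
    c_pos = 4  # reference C
    reads = [REF] * 7 + [mutate(REF, c_pos, "T")] * 3
    m = tabulate_substitutions(reads, design)
    assert m.base_fraction(c_pos, "T") == pytest.approx(0.30)
    # an N call drops out of the denominator
    reads[0] = mutate(REF, c_pos, "N")
    m = tabulate_substitutions(reads, design)
    assert m.depth[c_pos] == 9
    assert m.base_fraction(c_pos, "T") == pytest.approx(3 / 9)


def test_identical_reads_have_zero_offref_frequency():
    design = simple_design(REF)
    m = tabulate_substitutions([REF] * 5, design)
    off = m.counts.sum() - sum(
        m.counts[i, "ACGT".index(b)] for i, b in enumerate(REF)
    )
    assert off == 0


def test_length_mismatch_rejection():
    design = simple_design(REF)
    m = tabulate_substitutions([REF, REF, REF[:-1]], design)
    assert m.n_rejected == 1 and m.n_reads == 2
    with pytest.raises(ReadRejectionError):
        tabulate_substitutions([REF[:-1], REF[:-2], REF], design)


def test_window_profile_plus_strand(cbe):
    design = simple_design(REF)
    # position 1 (index 4) is a C; edit 20% of reads to T
    reads = [REF] * 8 + [mutate(REF, 4, "T")] * 2
    m = tabulate_substitutions(reads, design)
    prof = window_profile(m, design, cbe)
    assert prof[1] == pytest.approx(0.20)
    # G reference positions are absent, not zero
    assert 2 not in prof.frequencies  # index 5 is G


def test_window_profile_minus_strand_complement_corrected(cbe):
    # minus-strand placement: plus-strand G at the mapped coordinate is a
    # minus-strand C; plus-strand G->A reads report as C->T
    ref = "G" * 26 + "CAAA"  # minus-strand TTTG PAM at the right end
    placements = [
        pl for pl in find_pam_sites(ref, cbe, "amp") if pl.strand == "-"
    ]
    pl = next(p for p in placements if p.pam_interval == (26, 30))
    design = AmpliconDesign(ref, pl)
    g3 = 26 - 3  # protospacer position 3
    reads = [ref] * 6 + [mutate(ref, g3, "A")] * 4
    m = tabulate_substitutions(reads, design)
    prof = window_profile(m, design, cbe)
    assert prof[3] == pytest.approx(0.40)


def test_strand_consistency_of_quantification(cbe, abe):
    """Quantifying a minus-strand design equals quantifying the
    reverse-complemented reads against the reverse-complemented reference."""
    cfg = SimConfig(seed=5, read_count=400, editing_frequencies={3: 0.3},
                    error_rate=0.01)
    design = make_amplicon(abe, 5, substrate_positions=(3,))
    reads, _ = simulate_reads(design, abe, cfg)
    rc_ref = revcomp(design.reference)
    rc_pl = next(
        pl
        for pl in find_pam_sites(rc_ref, abe, "amp")
        if pl.strand == "-"
        and pl.pam_interval
        == (
            len(rc_ref) - design.placement.pam_interval[1],
            len(rc_ref) - design.placement.pam_interval[0],
        )
    )
    rc_design = AmpliconDesign(rc_ref, rc_pl)
    m_fwd = tabulate_substitutions(reads, design)
    m_rc = tabulate_substitutions([revcomp(r) for r in reads], rc_design)
    p_fwd = window_profile(m_fwd, design, abe)
    p_rc = window_profile(m_rc, rc_design, abe)
    assert p_fwd.frequencies == p_rc.frequencies


def test_aggregate_mean_sem_and_absence_rule():
    p1 = EditingProfile("e", {4: 0.10, 2: 0.05})
    p2 = EditingProfile("e", {4: 0.30, 2: 0.15})
    p3 = EditingProfile("e", {4: 0.20})  # no substrate at position 2
    agg = aggregate_profiles([p1, p2, p3])
    assert agg.loc[4, "mean"] == pytest.approx(0.20)
    assert agg.loc[4, "n"] == 3
    assert agg.loc[2, "n"] == 2
    assert agg.loc[2, "mean"] == pytest.approx(0.10)
    sem4 = np.std([0.1, 0.3, 0.2], ddof=1) / math.sqrt(3)
    assert agg.loc[4, "sem"] == pytest.approx(sem4)


def test_aggregate_single_profile_is_identity():
    p = EditingProfile("e", {3: 0.25, 7: 0.0})
    agg = aggregate_profiles([p])
    assert dict(agg["mean"]) == p.frequencies
    assert (agg["n"] == 1).all()


def test_call_window_half_max_rule():
    agg = aggregate_profiles(
        [EditingProfile("e", {2: 0.10, 3: 0.11, 4: 0.095, 6: 0.02})]
    )
    window, peak = call_window(agg)
    assert window == {2, 3, 4}
    assert peak == 3


def test_call_window_edge_cases():
    single = aggregate_profiles([EditingProfile("e", {5: 0.4})])
    assert call_window(single) == ({5}, 5)
    uniform = aggregate_profiles(
        [EditingProfile("e", {2: 0.2, 3: 0.2, 4: 0.2})]
    )
    window, peak = call_window(uniform)
    assert window == {2, 3, 4} and peak == 2  # tie -> smallest
    zero = aggregate_profiles([EditingProfile("e", {2: 0.0, 3: 0.0})])
    assert call_window(zero) == (set(), None)


def test_product_purity_fractions():
    design = simple_design(REF)
    c_pos = 4
    reads = (
        [mutate(REF, c_pos, "T")] * 70
        + [mutate(REF, c_pos, "G")] * 20
        + [mutate(REF, c_pos, "A")] * 10
        + [REF] * 100
    )
    m = tabulate_substitutions(reads, design)
    fractions, defined = product_purity(m, c_pos, "C")
    assert defined
    assert fractions["T"] == pytest.approx(0.70)
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_product_purity_pure_and_undefined():
    design = simple_design(REF)
    m = tabulate_substitutions([mutate(REF, 4, "T")] * 5, design)
    fractions, defined = product_purity(m, 4, "C")
    assert defined and fractions["T"] == 1.0
    m0 = tabulate_substitutions([REF] * 5, design)
    _, defined0 = product_purity(m0, 4, "C")
    assert not defined0
    with pytest.raises(ValueError):
        product_purity(m0, 5, "C")  # reference G there


def test_allele_outcomes_desired_proportions(cbe):
    from mbescope.editors import with_window

    spec = with_window(cbe, {3, 4, 5})
    # editable positions 3 and 5 (position 4 is G)
    ref = list("TTTA" + "G" * 26)
    ref[3 + 3] = "C"   # position 3 -> index anchor(3)+3
    ref[3 + 5] = "C"   # position 5
    ref = "".join(ref)
    pl = [p for p in find_pam_sites(ref, spec, "amp") if p.pam_interval == (0, 4)][0]
    design = AmpliconDesign(ref, pl)
    r_t3 = mutate(ref, 6, "T")
    reads = (
        [mutate(r_t3, 8, "C")] * 40  # T3 C5: desired
        + [mutate(r_t3, 8, "T")] * 10  # T3 T5: edited, not desired
        + [ref] * 50
    )
    table = allele_outcomes(reads, design, spec, {3: "T"})
    assert table.positions == (3, 5)
    assert table.desired_among_edited == pytest.approx(0.80)
    assert table.desired_among_all == pytest.approx(0.40)
    assert table.table["proportion"].sum() == pytest.approx(1.0)
    assert table.table["is_reference"].sum() == 1
    # reads with N at a window position are excluded and counted
    table_n = allele_outcomes(
        reads + [mutate(ref, 6, "N")], design, spec, {3: "T"}
    )
    assert table_n.n_excluded == 1 and table_n.n_reads == 100


def test_allele_outcomes_all_unedited(cbe):
    from mbescope.editors import with_window

    spec = with_window(cbe, {3})
    ref = "TTTA" + "GGC" + "G" * 23  # C at position 3
    pl = [p for p in find_pam_sites(ref, spec, "amp") if p.pam_interval == (0, 4)][0]
    design = AmpliconDesign(ref, pl)
    table = allele_outcomes([ref] * 10, design, spec, {3: "T"})
    assert table.desired_among_all == 0.0
    assert math.isnan(table.desired_among_edited)


def test_context_preference_recovers_planted_ranking(cbe, abe):
    # CA-context sites edited at 0.6, all other contexts at 0.2
    from mbescope.editors import with_window

    rng_seed = 101
    entries = []
    planted = []
    spec = with_window(cbe, {3})  # profile only the planted target
    for i, ctx3 in enumerate(["A", "T", "C", "G"]):
        ref = list("TTTA" + "G" * 56)
        ref[6] = "C"       # position 3, target
        ref[7] = ctx3      # 3' neighbour
        ref = "".join(ref)
        pl = [
            p for p in find_pam_sites(ref, spec, "amp")
            if p.pam_interval == (0, 4) and p.strand == "+"
        ][0]
        design = AmpliconDesign(ref, pl)
        p = 0.6 if ctx3 == "A" else 0.2
        # a C neighbour is itself profiled; plant the same rate there so
        # every observation of its (CG) context class carries rate p
        freqs = {3: p} if ctx3 != "C" else {3: p, 4: p}
        cfg = SimConfig(
            seed=rng_seed + i, read_count=2000,
            editing_frequencies=freqs, error_rate=0.0,
        )
        reads, _ = simulate_reads(design, spec, cfg)
        entries.append((tabulate_substitutions(reads, design), design))
        planted.append((f"C{ctx3}", p))
    tables = context_preference(entries, spec)
    three = tables["three_prime"].set_index("context")
    assert three.loc["CA", "rank"] == 1
    for ctx, p in planted:
        se = math.sqrt(p * (1 - p) / 2000)
        assert abs(three.loc[ctx, "mean"] - p) < 3 * se


def test_context_preference_ties_share_rank(cbe):
    # two single-site matrices with exactly equal frequencies
    entries = []
    for ctx in ("A", "T"):
        ref = list("TTTA" + "G" * 26)
        ref[7] = "C"
        ref[8] = ctx
        ref = "".join(ref)
        pl = [
            p for p in find_pam_sites(ref, cbe, "amp")
            if p.pam_interval == (0, 4) and p.strand == "+"
        ][0]
        design = AmpliconDesign(ref, pl)
        reads = [mutate(ref, 7, "T")] * 2 + [ref] * 8
        entries.append((tabulate_substitutions(reads, design), design))
    tables = context_preference(entries, cbe)
    three = tables["three_prime"].set_index("context")
    assert three.loc["CA", "rank"] == three.loc["CT", "rank"] == 1


def test_on_off_ratio_and_floor():
    ratio, floored = on_off_ratio(0.20, 0.005, 1000)
    assert ratio == pytest.approx(40.0) and not floored
    ratio, floored = on_off_ratio(0.20, 0.0, 1000)
    assert ratio == pytest.approx(200.0) and floored
    ratio, _ = on_off_ratio(0.0, 0.01, 100)
    assert ratio == 0.0
    with pytest.raises(ValueError):
        on_off_ratio(0.2, 0.01, 0)
    with pytest.raises(ValueError):
        on_off_ratio(1.2, 0.01, 10)


def test_max_edit_frequency_modes(abe):
    cfg = SimConfig(seed=9, read_count=500,
                    editing_frequencies={3: 0.3, 4: 0.05}, error_rate=0.0)
    design = make_amplicon(abe, 9, substrate_positions=(3, 4))
    reads, _ = simulate_reads(design, abe, cfg)
    m = tabulate_substitutions(reads, design)
    assert max_edit_frequency(m, design, abe) == pytest.approx(0.3, abs=0.07)


def test_rloop_stats_sum_max_and_ties():
    ref = "CCACC" + "G" * 5
    pl = PamPlacement("amp", "+", (5, 9), 8, (9, 29), "cas12f_r_zero")
    # placement is irrelevant to rloop_stats; operate on the matrix alone
    design = AmpliconDesign(ref + "G" * 19, pl)
    reads = [design.reference] * 94
    reads += [mutate(design.reference, 0, "T")] * 1
    reads += [mutate(design.reference, 1, "T")] * 2
    reads += [mutate(design.reference, 3, "T")] * 3
    m = tabulate_substitutions(reads, design)
    stats = rloop_stats(m, (0, 5), "C")
    assert stats["defined"]
    assert stats["sum"] == pytest.approx(0.06)
    assert stats["max"] == pytest.approx(0.03)
    assert stats["max_position"] == 3
    # tie -> smallest coordinate
    reads2 = [design.reference] * 97
    reads2 += [mutate(design.reference, 1, "T")] * 3
    m2 = tabulate_substitutions(reads2 + [mutate(design.reference, 3, "T")] * 3, design)
    stats2 = rloop_stats(m2, (0, 5), "C")
    assert stats2["max_position"] == 1
    # no substrate base in window
    empty = rloop_stats(m, (5, 10), "C")
    assert empty["sum"] == 0.0 and not empty["defined"]
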