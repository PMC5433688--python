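"""Breakpoint counting, synteny blocks, LOH/junction/BIR calls, telomeres."""

import pytest

from hybridweaver.architecture import (
    build_synteny_blocks,
    chromosome_end_windows,
    count_breakpoints,
    detect_recombination_junctions,
    estimate_events,
    flag_bir_ends,
    genome_order,
    min_rotation,
    segment_loh_tracts,
    telomere_consensus,
)
from hybridweaver.classify import CategoryTrack
from hybridweaver.model import HybridweaverError
from hybridweaver.simulate import (
    SimConfig,
    apply_rearrangements,
    simulate_parent,
)


def _identity_map(order):
    return {g: g for chrom in order.values() for g, _ in chrom}


def _oracle_breakpoints(order_x, order_y, homolog_map):
    """Exhaustive adjacency comparison, max_gap=0, independent of the
    implementation: an x adjacency is broken unless its homologs are
    immediate neighbours in y with consistent relative orientation."""
    pos = {}
    for chrom, genes in order_y.items():
        for i, (g, s) in enumerate(genes):
            pos[g] = (chrom, i, s)
    broken = 0
    for chrom, genes in order_x.items():
        for (g1, s1), (g2, s2) in zip(genes, genes[1:]):
            if g1 not in homolog_map or g2 not in homolog_map:
                continue
            h1, h2 = homolog_map[g1], homolog_map[g2]
            if h1 not in pos or h2 not in pos:
                continue
            c1, i1, t1 = pos[h1]
            c2, i2, t2 = pos[h2]
            ok = False
            if c1 == c2 and abs(i1 - i2) == 1:
                rel1 = 1 if t1 == s1 else -1
                rel2 = 1 if t2 == s2 else -1
                if rel1 == rel2 and (i2 - i1) == rel1:
                    ok = True
            if not ok:
                broken += 1
    return broken


@pytest.fixture(scope="module")
def parent_and_rearranged():
    cfg = SimConfig(n_genes=300, gene_len_codons=30, seed=13, mat_enabled=False)
    parent = simulate_parent(cfg)
    rearranged, log = apply_rearrangements(parent, 17, 0.5, seed=99)
    return parent, rearranged, log


def test_identity_zero_breakpoints(parent_and_rearranged):
    parent, _, _ = parent_and_rearranged
    order = genome_order(parent.assemble())
    bset = count_breakpoints(order, order, _identity_map(order), max_gap=0)
    assert bset.count == 0


def test_single_inversion_two_breakpoints_three_blocks():
    cfg = SimConfig(n_genes=40, gene_len_codons=30, seed=3,
                    n_chromosomes_per_parent=1, mat_enabled=False)
    parent = simulate_parent(cfg)
    inv, log = apply_rearrangements(parent, 1, inversion_fraction=1.0, seed=5)
    assert log[0]["type"] == "inversion"
    ox = genome_order(inv.assemble())
    oy = genome_order(parent.assemble())
    hmap = _identity_map(ox)
    bset = count_breakpoints(ox, oy, hmap, max_gap=0)
    assert bset.count == 2 == _oracle_breakpoints(ox, oy, hmap)
    blocks = build_synteny_blocks(ox, oy, hmap, max_gap=0)
    assert len(blocks) == 3
    assert sorted(b.orientation for b in blocks).count("-") == 1


def test_single_translocation_two_breakpoints():
    cfg = SimConfig(n_genes=60, gene_len_codons=30, seed=4,
                    n_chromosomes_per_parent=2, mat_enabled=False)
    parent = simulate_parent(cfg)
    tr, log = apply_rearrangements(parent, 1, inversion_fraction=0.0, seed=6)
    assert log[0]["type"] == "translocation"
    ox = genome_order(tr.assemble())
    oy = genome_order(parent.assemble())
    hmap = _identity_map(ox)
    assert count_breakpoints(ox, oy, hmap, max_gap=0).count == 2


def test_seventeen_events_thirtyfour_breakpoints(parent_and_rearranged):
    parent, rearranged, _ = parent_and_rearranged
    ox = genome_order(rearranged.assemble())
    oy = genome_order(parent.assemble())
    hmap = _identity_map(ox)
    bset = count_breakpoints(ox, oy, hmap, max_gap=0)
    assert bset.count == 34 == _oracle_breakpoints(ox, oy, hmap)
    assert bset.event_estimate == 17
    # symmetry of the count under direction reversal
    assert count_breakpoints(oy, ox, hmap, max_gap=0).count == 34
    # block coverage of mapped genes
    blocks = build_synteny_blocks(ox, oy, hmap, max_gap=0)
    covered = sum(b.n_genes for b in blocks)
    assert covered >= 0.99 * sum(len(v) for v in ox.values())


def test_estimate_events_rules():
    assert estimate_events(34) == 17
    assert estimate_events(0) == 0
    with pytest.warns(UserWarning):
        assert estimate_events(7) == 3
    with pytest.raises(HybridweaverError):
        estimate_events(-1)


# ------------------------------------------------------------------ LOH


def _track(labels, categories, chrom="c"):
    n = len(labels)
    return CategoryTrack(chrom, [f"g{i}" for i in range(n)], categories, labels)


def test_loh_homogeneous_no_tracts():
    t = _track(["B"] * 10, ["B-in-A:B"] * 10)
    assert segment_loh_tracts(t) == []


def test_loh_eight_gene_tract_on_b_background():
    labels = ["B"] * 5 + ["A"] * 8 + ["B"] * 5
    cats = ["B-in-A:B"] * 5 + ["A-in-A:A"] * 8 + ["B-in-A:B"] * 5
    tracts = segment_loh_tracts(_track(labels, cats), min_run=3)
    assert len(tracts) == 1
    t = tracts[0]
    assert (t.start_index, t.end_index, t.length) == (5, 12, 8)
    assert t.tract_class == "A" and t.background == "B"


def test_loh_alternating_below_min_run():
    labels = ["B", "A", "B", "A", "B", "A", "B", "B", "B", "B"]
    cats = [
        "B-in-A:B" if lb == "B" else "A-in-A:A" for lb in labels
    ]
    assert segment_loh_tracts(_track(labels, cats), min_run=3) == []


def test_loh_n_genes_transparent():
    labels = ["B"] * 4 + ["A", "A", "N", "A"] + ["B"] * 4
    cats = (
        ["B-in-A:B"] * 4
        + ["A-in-A:A", "A-in-A:A", "N", "A-in-A:A"]
        + ["B-in-A:B"] * 4
    )
    tracts = segment_loh_tracts(_track(labels, cats), min_run=3)
    assert len(tracts) == 1 and tracts[0].length == 3


# ------------------------------------------------------------- junctions


def test_junction_single_crossover():
    labels = ["A"] * 6 + ["B"] * 6
    cats = ["A-in-A:B"] * 6 + ["B-in-A:B"] * 6
    j = detect_recombination_junctions(_track(labels, cats), min_run=3)
    assert len(j) == 1
    assert (j[0].left_index, j[0].right_index) == (5, 6)


def test_junction_pure_chromosome_none():
    t = _track(["A"] * 10, ["A-in-A:B"] * 10)
    assert detect_recombination_junctions(t) == []


def test_junction_loh_tract_not_a_crossover():
    labels = ["B"] * 5 + ["A"] * 4 + ["B"] * 5
    cats = ["B-in-A:B"] * 5 + ["A-in-A:A"] * 4 + ["B-in-A:B"] * 5
    track = _track(labels, cats)
    tracts = segment_loh_tracts(track, min_run=3)
    assert len(tracts) == 1
    assert detect_recombination_junctions(track, loh_tracts=tracts) == []


# ------------------------------------------------------------------- BIR


def test_bir_recovery_on_simulation(small_sim, small_summary):
    ev = small_summary["truth_eval"]
    assert ev["bir"]["precision"] == 1.0
    assert ev["bir"]["recall"] == 1.0
    # direct string-equality oracle: the two involved ends are identical
    b = small_sim.truth.bir_ends[0]
    genome = small_sim.hybrid
    donor = genome.chrom_map[b["donor_chrom"]].seq
    recip = genome.chrom_map[b["recipient_chrom"]].seq
    dg = [genome.gene(g) for g in b["donor_gene_ids"]]
    if b["donor_side"] == "L":
        donor_end = donor[: max(g.end for g in dg)]
    else:
        donor_end = donor[min(g.start for g in dg) - 1 :]
    from hybridweaver.model import revcomp

    if b["donor_side"] == b["recipient_side"]:
        ok = (recip.startswith(donor_end) if b["recipient_side"] == "L"
              else recip.endswith(donor_end))
    else:
        rc = revcomp(donor_end)
        ok = (recip.startswith(rc) if b["recipient_side"] == "L"
              else recip.endswith(rc))
    assert ok


def test_no_bir_no_flags():
    from hybridweaver.classify import categorize

    cfg = SimConfig(
        n_genes=80, gene_len_codons=40, seed=21, mat_enabled=False,
        loh_tracts=[], n_recombinations=0, bir_ends=0,
        n_disablements_per_subgenome=0, n_rearrangements=3,
    )
    from hybridweaver.simulate import simulate_hybrid_genome

    res = simulate_hybrid_genome(cfg)
    genome = res.hybrid
    labels = dict(res.truth.subgenome)
    pair_types = {tuple(p): "A:B" for p in res.truth.pairs}
    tracks, _ = categorize(genome, labels, pair_types)
    assert flag_bir_ends(tracks, genome) == []


# -------------------------------------------------------------- telomeres


def test_telomere_consensus_recovers_unit():
    unit = "TGTGGGTGGGG"
    ends = [("AC" * 30) + unit * 12, ("GT" * 25) + unit * 15]
    rep = telomere_consensus(ends)
    assert min_rotation(rep.unit) == min_rotation(unit)
    assert rep.unit_canonical == min_rotation(unit)


def test_telomere_poly_a():
    rep = telomere_consensus(["CGT" * 20 + "A" * 60, "TTG" * 15 + "A" * 45])
    assert rep.unit == "A"


def test_telomere_majority_and_minority():
    u1, u2 = "TGTGGGTGGGG", "TTAGGG"
    ends = ["C" * 40 + u1 * 10, "G" * 40 + u1 * 12, "A" * 40 + u2 * 14]
    rep = telomere_consensus(ends)
    assert min_rotation(rep.unit) == min_rotation(u1)
    assert [min_rotation(u) for u in rep.minority_units] == [min_rotation(u2)]


def test_telomere_no_repeat_warns():
    import random

    rnd = random.Random(0)
    noise = "".join(rnd.choice("ACGT") for _ in range(300))
    with pytest.warns(UserWarning):
        rep = telomere_consensus([noise])
    assert rep.unit is None


def test_simulated_chromosome_ends_yield_consensus(small_sim):
    windows = chromosome_end_windows(small_sim.hybrid)
    rep = telomere_consensus(windows)
    assert min_rotation(rep.unit) == min_rotation("TGTGGGTGGGG")
    assert rep.n_ends_detected == 2 * len(small_sim.hybrid.chromosomes)
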