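"""Disablement screen, mechanism typing, in-frame introns, +1 frameshifts."""

import random

import pytest

from hybridweaver.integrity import (
    compare_strains,
    detect_mechanism,
    find_inframe_introns,
    find_plus1_sites,
    screen_pairs,
)
from hybridweaver.ks import SENSE_CODONS, STOP_CODONS, proteome_of, translate_cds
from hybridweaver.model import AnnotatedGenome, Chromosome, Gene, HybridweaverError


def _cds(rnd, n_codons):
    return "ATG" + "".join(rnd.choice(SENSE_CODONS) for _ in range(n_codons - 2)) + "TAA"


# ------------------------------------------------------------------ screen


def test_screen_threshold_rule():
    proteins = {
        "a1": "M" * 211, "b1": "M" * 57,   # flagged (0.27)
        "a2": "M" * 100, "b2": "M" * 95,   # 0.95: not flagged
        "a3": "M" * 100, "b3": "M" * 89,   # 0.89 < 0.9: flagged
        "a4": "M" * 100, "b4": "M" * 90,   # exactly 0.9: passes
    }
    calls = screen_pairs(
        [("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4")], proteins
    )
    flagged = {c.gene_id for c in calls}
    assert flagged == {"b1", "b3"}
    assert 89 / 100 < 0.9  # the arithmetic the rule relies on
    ratios = {c.gene_id: c.length_ratio for c in calls}
    assert ratios["b1"] == pytest.approx(57 / 211)


def test_screen_symmetric_in_pair_order():
    proteins = {"x": "M" * 50, "y": "M" * 100}
    c1 = screen_pairs([("x", "y")], proteins)
    c2 = screen_pairs([("y", "x")], proteins)
    assert c1[0].gene_id == c2[0].gene_id == "x"


# --------------------------------------------------------------- mechanism


def test_mechanism_single_insertion():
    rnd = random.Random(1)
    intact = _cds(rnd, 80)
    p = 3 * 30
    broken = intact[:p] + "A" + intact[p:]
    call = detect_mechanism(broken, intact)
    assert call.mechanism == "frameshift-indel"
    assert abs(call.position - 30) <= 1


def test_mechanism_premature_stop():
    rnd = random.Random(2)
    intact = _cds(rnd, 80)
    broken = intact[:60] + "TAA" + intact[63:]
    call = detect_mechanism(broken, intact)
    assert call.mechanism == "premature-stop"
    assert call.position == 20


def test_mechanism_identical_pair_is_error():
    rnd = random.Random(3)
    cds = _cds(rnd, 50)
    with pytest.raises(HybridweaverError):
        detect_mechanism(cds, cds)


def test_mechanism_on_simulated_plants(small_sim):
    """Planted mutations are recovered with the right mechanism class."""
    cds = small_sim.hybrid.cds_sequences()
    for d in small_sim.truth.disablements:
        call = detect_mechanism(cds[d["gene_id"]], cds[d["partner_id"]])
        assert call.mechanism == d["mechanism"]


# ----------------------------------------------------------- strain compare


def test_compare_strains_disjoint_and_identical():
    from hybridweaver.integrity import DisablementCall

    c1 = [DisablementCall("g1", "p1", "premature-stop", 0.5)]
    c2 = [DisablementCall("g2", "p2", "premature-stop", 0.5)]
    shared, u1, u2 = compare_strains(c1, c2)
    assert shared == [] and u1 == ["g1"] and u2 == ["g2"]
    shared, u1, u2 = compare_strains(c1, c1)
    assert shared == ["g1"] and not u1 and not u2


def test_compare_strains_recovers_shared_plants():
    """Two descendants with 8 shared + 10/9 unique planted disablements."""
    from hybridweaver.simulate import (
        LohSpec, SimConfig, derive_strain_pair, simulate_hybrid_genome,
    )

    cfg = SimConfig(
        n_genes=160, gene_len_codons=120, seed=23,
        loh_tracts=[LohSpec(count=1, length=4)], n_recombinations=1,
        bir_ends=0, n_disablements_per_subgenome=0, n_rearrangements=5,
    )
    base = simulate_hybrid_genome(cfg)
    (sim1, t1), (sim2, t2) = derive_strain_pair(base, n_shared=8, n_unique=(10, 9), seed=3)

    def calls_for(sim, truth):
        cds = sim.assemble().cds_sequences()
        return screen_pairs(truth.pairs, proteome_of(cds), cds=cds)

    calls1, calls2 = calls_for(sim1, t1), calls_for(sim2, t2)
    shared, u1, u2 = compare_strains(calls1, calls2)
    true_shared = {d["gene_id"] for d in t1.disablements if d.get("shared")}
    assert len(true_shared) == 8
    assert set(shared) == true_shared
    assert len(u1) == 10 and len(u2) == 9


# ---------------------------------------------------------- in-frame introns


def _intron_gene(gid, intron, lead_codons=4, tail_codons=40, seed=9):
    rnd = random.Random(seed)
    exon1 = "ATG" + "".join(rnd.choice(SENSE_CODONS) for _ in range(lead_codons))
    exon2 = "".join(rnd.choice(SENSE_CODONS) for _ in range(tail_codons)) + "TAA"
    seq = exon1 + intron + exon2
    gene = Gene(gid, "c", 1, len(seq), "+",
                exons=[(1, len(exon1)), (len(exon1) + len(intron) + 1, len(seq))])
    return gene, seq


def _make_genome(entries):
    chroms = []
    for i, (gene, seq) in enumerate(entries):
        gene.chrom = f"c{i}"
        gene.exons = [(s, e) for s, e in gene.exons]
        chroms.append(Chromosome(f"c{i}", seq, [gene]))
    return AnnotatedGenome("toy", chroms)


def _stop_free_intron(length, seed=5):
    """In-frame-stop-free intron of the requested length starting GT."""
    rnd = random.Random(seed)
    while True:
        mid = "".join(rnd.choice("ACGT") for _ in range(length - 4))
        intron = "GT" + mid + "AG"
        if all(
            intron[i : i + 3] not in STOP_CODONS
            for i in range(0, length - 2, 3)
        ):
            return intron


def test_inframe_intron_rules():
    # lead of 4 codons + ATG = 15 nt, so introns start at frame 0
    good69 = _stop_free_intron(69)
    bad68 = _stop_free_intron(69)[:66] + "AG"  # 68 nt
    with_stop = good69[:30] + "TAA" + good69[33:]
    assert len(with_stop) == 69
    genome = _make_genome([
        _intron_gene("sixtynine", good69),
        _intron_gene("sixtyeight", bad68),
        _intron_gene("stopful", with_stop),
    ])
    found = find_inframe_introns(genome)
    assert [f.gene_id for f in found] == ["sixtynine"]
    assert found[0].length == 69


def test_inframe_introns_match_bruteforce_on_simulation(small_sim):
    """Function output equals an independent brute-force filter."""
    genome = small_sim.hybrid
    expected = set()
    for chrom in genome.chromosomes:
        for g in chrom.genes:
            if g.n_exons < 2 or g.strand != "+":
                continue
            local = chrom.seq[g.start - 1 : g.end]
            exons = [(s - g.start, e - g.start) for s, e in g.exons]
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                ilen = s2 - e1 - 2 + 1
                istart, iend = e1 + 1, s2 - 1
                if ilen % 3:
                    continue
                start = istart - (istart % 3)
                codons = [
                    local[i : i + 3]
                    for i in range(start, iend - 1, 3)
                    if i + 3 <= iend + 1
                ]
                if all(c not in STOP_CODONS for c in codons):
                    expected.add((g.gene_id, ilen))
    got = {(f.gene_id, f.length) for f in find_inframe_introns(genome)}
    assert got == expected


# ------------------------------------------------------------ +1 frameshift


def _plus1_cds(motif, ext_codons, seed=7):
    """CDS whose frame 0 closes just after the motif while the +1 frame
    (skipping the A) stays open for ``ext_codons`` codons."""
    rnd = random.Random(seed)
    lead = "ATG" + "".join(rnd.choice(SENSE_CODONS) for _ in range(10))
    while True:
        ext = "".join(rnd.choice(SENSE_CODONS) for _ in range(ext_codons)) + "TAA"
        cds = lead + motif + ext
        pos = len(lead)
        # frame 0 after the motif: require a stop within 30 codons
        stop0 = None
        for ci in range(pos // 3, len(cds) // 3):
            if cds[3 * ci : 3 * ci + 3] in STOP_CODONS:
                stop0 = ci - pos // 3
                break
        if stop0 is not None and stop0 <= 30:
            return cds


@pytest.mark.parametrize("motif", ["CTTAGTT", "CTTAGGC"])
def test_plus1_site_detected(motif):
    cds = _plus1_cds(motif, 60)
    sites = find_plus1_sites({"g": cds})
    assert len(sites) == 1
    assert sites[0].motif == motif
    assert sites[0].skipped_base == "A"


def test_plus1_absent_motif():
    rnd = random.Random(8)
    cds = _cds(rnd, 120).replace("CTTAGTT", "CTTCGTT").replace("CTTAGGC", "CTTCGGC")
    assert find_plus1_sites({"g": cds}) == []


def test_plus1_short_extension_rejected():
    cds = _plus1_cds("CTTAGTT", 60)
    pos = cds.find("CTTAGTT")
    # close the +1 frame immediately after the motif
    closed = cds[: pos + 4] + "TAA" + cds[pos + 7 :]
    assert all(s.position != pos for s in find_plus1_sites({"g": closed}))
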