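"""HO cleavage, NHEJ junction signatures, splice shifts, cassette catalog."""

import random

import pytest

from hybridweaver.mat import (
    HO_CORE,
    analyze_junction,
    analyze_splice_shift,
    catalog_mat_loci,
    cleave_ho,
    locate_ho_sites,
    make_junction,
    religate,
)
from hybridweaver.model import Gene, HybridweaverError, revcomp


def _duplex(pos=30, n=60, seed=1):
    rnd = random.Random(seed)
    seq = "".join(rnd.choice("ACGT") for _ in range(n))
    return seq[:pos] + HO_CORE + seq[pos + len(HO_CORE) :]


# --------------------------------------------------------------- HO sites


def test_locate_sites_both_strands():
    seq = "A" * 20 + HO_CORE + "T" * 20 + revcomp(HO_CORE) + "G" * 20
    sites = locate_ho_sites(seq)
    assert [(s.position, s.strand) for s in sites] == [(20, "+"), (47, "-")]


def test_locate_sites_absent():
    assert locate_ho_sites("ACGT" * 30) == []


def test_cleave_registration_and_overhang():
    seq = _duplex()
    site = locate_ho_sites(seq)[0]
    res = cleave_ho(seq, site)
    # documented registration: bottom cut at the core 5' boundary, top cut
    # 4 nt in, so the overhang is the core's first 4 nt on a 3' extension
    assert (res.bottom_cut, res.top_cut) == (30, 34)
    assert res.overhang_len == 4
    assert res.polarity == "3'"
    assert res.overhang_seq == HO_CORE[:4]
    assert res.top_cut > res.bottom_cut  # 3' overhang geometry


def test_cleave_religate_identity_both_strands():
    seq = _duplex()
    for probe in (seq, revcomp(seq)):
        site = locate_ho_sites(probe)[0]
        res = cleave_ho(probe, site)
        assert religate(res) == probe
        assert abs(res.top_cut - res.bottom_cut) == res.overhang_len


def test_cleave_too_close_to_end():
    seq = HO_CORE + "ACGTACGTAC"
    with pytest.raises(HybridweaverError):
        cleave_ho(seq, locate_ho_sites(seq)[0])


# ------------------------------------------------------------- junctions


def _rand_donor(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


def test_blunt_join_signature():
    rnd = random.Random(4)
    L, R = _rand_donor(rnd, 50), _rand_donor(rnd, 50)
    j, L2, R2 = make_junction(L, 25, R, 25)
    sig = analyze_junction(j, L2, R2)
    assert sig.microhomology == 0
    assert sig.duplications == [] and sig.inserted == ""


def test_junction_constructor_analyzer_inverse_seeded():
    """300 random trials across TSD lengths 0-10 and microhomology 0-6."""
    rnd = random.Random(11)
    for _ in range(300):
        L = _rand_donor(rnd, rnd.randint(40, 90))
        R = _rand_donor(rnd, rnd.randint(40, 90))
        a = rnd.randint(15, len(L) - 15)
        b = rnd.randint(15, len(R) - 15)
        if rnd.random() < 0.3:
            mh, tl, tr = rnd.randint(1, 6), 0, 0
        else:
            mh, tl, tr = 0, rnd.randint(0, 10), rnd.randint(0, 10)
        j, L2, R2 = make_junction(L, a, R, b, tsd_left=tl, tsd_right=tr,
                                  microhomology=mh)
        sig = analyze_junction(j, L2, R2)
        assert sig.microhomology == mh
        assert sig.tsd_lengths() == {"left": tl if not mh else 0,
                                     "right": tr if not mh else 0}
        assert sig.inserted == ""


def test_three_nt_microhomology():
    rnd = random.Random(12)
    L, R = _rand_donor(rnd, 60), _rand_donor(rnd, 60)
    j, L2, R2 = make_junction(L, 30, R, 30, microhomology=3)
    sig = analyze_junction(j, L2, R2)
    assert sig.microhomology == 3


def test_simulated_breakage_junction_pattern(small_sim):
    """The engineered breakage shows the 5-bp acaac + 2-bp duplication."""
    mb = small_sim.truth.mat_breakage
    sig = analyze_junction(
        mb["junction_window"], mb["donor_left_window"], mb["donor_right_window"]
    )
    assert sig.microhomology == 0
    assert sig.tsd_lengths() == {"left": 5, "right": 2}
    dup_seqs = {d.side: d.sequence for d in sig.duplications}
    assert dup_seqs["left"] == "ACAAC"


# ------------------------------------------------------------ splice shift


def _gene_with_intron(exon1, intron, exon2):
    seq = exon1 + intron + exon2
    g = Gene("toy", "c", 1, len(seq), "+",
             exons=[(1, len(exon1)), (len(exon1) + len(intron) + 1, len(seq))])
    return g, seq


def test_intact_acceptor_zero_shift():
    exon1 = "ATGAAA"
    intron = "GT" + "C" * 20 + "AG"
    exon2 = "GGGTTTTAA"
    g, seq = _gene_with_intron(exon1, intron, exon2)
    rep = analyze_splice_shift(g, seq)
    assert rep.shift == 0 and rep.frame_preserved
    assert rep.protein_length == 4  # MKG F


def test_broken_acceptor_shift_two_frameshifts():
    exon1 = "ATGAAA"
    intron = "GT" + "C" * 20 + "TTAC"  # AG -> AC
    exon2 = "AG" + "TAAGGGTTTTAA"  # next AG 2 nt downstream
    g, seq = _gene_with_intron(exon1, intron, exon2)
    rep = analyze_splice_shift(g, seq)
    assert rep.shift == 2
    assert not rep.frame_preserved
    assert rep.acceptor_dinucleotide == "AC"


@pytest.mark.parametrize("shift", range(2, 10))
def test_frame_rule_exhaustive(shift):
    """frame preserved <=> shift mod 3 == 0, over reachable shifts 2..9.

    (A shift of 1 cannot arise from an AG->AC mutation: the C occupies the
    position the new AG would need.)
    """
    exon1 = "ATGAAA"
    filler = "CTCTCTCT"[: shift - 2]
    intron = "GT" + "C" * 20 + "TTAC"
    exon2 = filler + "AG" + "GGGTTT" * 12 + "TAA"
    g, seq = _gene_with_intron(exon1, intron, exon2)
    rep = analyze_splice_shift(g, seq)
    # the next AG sits `shift` nt downstream of the mutated acceptor
    assert rep.shift == shift
    assert rep.frame_preserved == (shift % 3 == 0)


def test_unspliceable_without_downstream_ag():
    exon1 = "ATGAAA"
    intron = "GT" + "C" * 20 + "TTAC"
    exon2 = "CCCTTTCCCTTT"
    g, seq = _gene_with_intron(exon1, intron, exon2)
    rep = analyze_splice_shift(g, seq)
    assert rep.unspliceable and rep.shift is None


def test_simulated_alpha2_truncation(small_sim):
    """The B-subgenome alpha2 splice break truncates 211 aa to 57."""
    genome = small_sim.hybrid
    reports = {}
    for chrom in genome.chromosomes:
        for g in chrom.genes:
            if g.n_exons >= 2 and "alpha2" in g.gene_id:
                reports[g.gene_id] = analyze_splice_shift(g, chrom.seq)
    assert reports["MATalpha2_A"].shift == 0
    assert reports["MATalpha2_A"].protein_length == 211
    assert reports["MATalpha2_B"].shift == 2
    assert reports["MATalpha2_B"].protein_length == 57
    assert not reports["MATalpha2_B"].frame_preserved
    assert reports["HMLalpha2_B"].protein_length == 57


# ----------------------------------------------------------------- catalog


def test_catalog_on_simulation(small_sim):
    cat = catalog_mat_loci(small_sim.hybrid)
    assert cat.n_regions == 6
    assert len(cat.fragments) == 2
    assert sum(1 for l in cat.loci if l.intact) == 5
    broken = [l for l in cat.loci if not l.intact]
    assert len(broken) == 1 and broken[0].idiomorph == "alpha"
    assert cat.x_identity == 1.0 and cat.z_identity == 1.0
    assert cat.a1_absent
    assert len(cat.x_copies) == 6 and len(cat.z_copies) == 6
    kinds = sorted(l.kind for l in cat.loci if l.intact)
    assert kinds == ["HML", "HML", "HMR", "HMR", "MAT"]
    idios = sorted(l.idiomorph for l in cat.loci)
    assert idios.count("a") == 2 and idios.count("alpha") == 4


def test_catalog_empty_genome_warns():
    from hybridweaver.simulate import SimConfig, simulate_parent

    plain = simulate_parent(
        SimConfig(n_genes=30, gene_len_codons=40, seed=17, mat_enabled=False)
    ).assemble()
    with pytest.warns(UserWarning):
        cat = catalog_mat_loci(plain)
    assert cat.n_regions == 0
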