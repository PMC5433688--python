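"""Nei-Gojobori site/difference counting, codon alignment, homolog search."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from hybridweaver import ks as K
from hybridweaver.ks import (
    BestHitParams,
    CodonAlignment,
    PrematureStopError,
    SENSE_CODONS,
    STOP_CODONS,
    TranslationError,
    align_codons,
    codon_path_differences,
    codon_sites,
    estimate_ks,
    find_best_hits,
    reciprocal_best_pairs,
    translate_cds,
)

# --------------------------------------------------------------- translation


def test_translate_basic():
    assert translate_cds("ATGGGGTAA") == "MG"


def test_translate_length_error():
    with pytest.raises(TranslationError):
        translate_cds("ATGGGGTAAG")  # length 10


def test_translate_internal_stop_flags():
    with pytest.raises(PrematureStopError) as exc:
        translate_cds("ATGTAAGGGTGA")
    assert exc.value.stop_codon_index == 1
    # pseudogene mode truncates instead
    assert translate_cds("ATGTAAGGGTGA", pseudogene=True) == "M"
    assert translate_cds("ATGGGGTAAC", pseudogene=True) == "MG"


# ---------------------------------------------- NG86 oracle (independent)


def _oracle_sites(codon: str) -> float:
    """Brute-force synonymous site count of one codon."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = str(Seq(alt).translate())
            if alt_aa != "*" and alt_aa == aa:
                syn += 1 / 3
    return syn


def _oracle_differences(c1: str, c2: str) -> tuple[float, float]:
    """Enumerate every mutational order; skip stop-codon intermediates."""
    from Bio.Seq import Seq

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    clean, dirty = [], []
    for order in itertools.permutations(diffs):
        cur, sd, nd, bad = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a1, a2 = str(Seq(cur).translate()), str(Seq(nxt).translate())
            if "*" in (a1, a2):
                bad = True
                nd += 1
            elif a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if bad else clean).append((sd, nd))
    use = clean or dirty
    return (
        sum(x for x, _ in use) / len(use),
        sum(y for _, y in use) / len(use),
    )


def test_ng86_sites_match_oracle_all_codons():
    for codon in SENSE_CODONS:
        assert codon_sites(codon)[0] == pytest.approx(_oracle_sites(codon), abs=1e-12)
        assert sum(codon_sites(codon)) == pytest.approx(3.0)


def test_ng86_differences_match_oracle_all_codon_pairs():
    """Exhaustive 61x61 check against independent pathway enumeration."""
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            sd, nd = codon_path_differences(c1, c2)
            osd, ond = _oracle_differences(c1, c2)
            assert sd == pytest.approx(osd, abs=1e-12), (c1, c2)
            assert nd == pytest.approx(ond, abs=1e-12), (c1, c2)


def test_fourfold_degenerate_example():
    """100 GGT codons with 3 third-position changes: S=100, Sd=3."""
    a = ["GGT"] * 100
    b = ["GGT"] * 97 + ["GGC", "GGA", "GGG"]
    est = estimate_ks(CodonAlignment("a", "b", list(zip(a, b))))
    assert est.S == pytest.approx(100.0)
    assert est.Sd == pytest.approx(3.0)
    expected = -0.75 * math.log(1 - 4 / 3 * 0.03)
    assert est.ks == pytest.approx(expected, rel=1e-12)
    assert est.ka == pytest.approx(0.0)


def test_identical_sequences_zero_divergence():
    cds = "ATG" + "GGTAAGTTC" * 20 + "TAA"
    est = estimate_ks(align_codons(cds, cds))
    assert est.ks == 0.0 and est.ka == 0.0


def test_saturation_flag():
    pairs = [("GGT", "GGA")] * 10  # every synonymous site differs
    est = estimate_ks(CodonAlignment("a", "b", pairs))
    assert est.saturated and est.ks is None
    assert est.ps >= 0.75


@given(st.lists(st.sampled_from(SENSE_CODONS), min_size=5, max_size=60),
       st.randoms(use_true_random=False))
@settings(max_examples=50, deadline=None)
def test_estimate_symmetry_and_site_conservation(codons, rnd):
    mutated = []
    for c in codons:
        if rnd.random() < 0.4:
            alt = rnd.choice(SENSE_CODONS)
            mutated.append(alt)
        else:
            mutated.append(c)
    fwd = estimate_ks(CodonAlignment("a", "b", list(zip(codons, mutated))))
    rev = estimate_ks(CodonAlignment("b", "a", list(zip(mutated, codons))))
    assert fwd.S == pytest.approx(rev.S)
    assert fwd.Sd == pytest.approx(rev.Sd)
    assert fwd.ks == (rev.ks if fwd.ks is None else pytest.approx(rev.ks))
    assert fwd.S + fwd.N == pytest.approx(3 * len(codons))


def test_monotonicity_adding_synonymous_difference():
    base = [("GGT", "GGT")] * 50
    prev = estimate_ks(CodonAlignment("a", "b", base)).ks
    for i in range(5):
        base[i] = ("GGT", "GGC")
        cur = estimate_ks(CodonAlignment("a", "b", base)).ks
        assert cur > prev
        prev = cur


def test_against_biopython_ng86():
    """Independent cross-check of the full estimator on a diverged pair."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rnd = random.Random(5)
    a = [rnd.choice(SENSE_CODONS) for _ in range(120)]
    b = []
    for c in a:
        if rnd.random() < 0.15:
            alts = [x for x in SENSE_CODONS if sum(i != j for i, j in zip(x, c)) == 1]
            b.append(rnd.choice(alts))
        else:
            b.append(c)
    est = estimate_ks(CodonAlignment("a", "b", list(zip(a, b))))
    dn, ds = cal_dn_ds(CodonSeq("".join(a)), CodonSeq("".join(b)), method="NG86")
    assert est.ks == pytest.approx(ds, abs=1e-6)
    assert est.ka == pytest.approx(dn, abs=1e-6)


# ------------------------------------------------------------ codon alignment


def test_align_identical_no_gaps():
    cds = "ATG" + "AAGGTT" * 10 + "TAA"
    aln = align_codons(cds, cds)
    assert aln.n_codons_compared == len(cds) // 3 - 1  # stop excluded


def test_align_one_codon_insertion():
    rnd = random.Random(2)
    codons = [rnd.choice(SENSE_CODONS) for _ in range(40)]
    a = "ATG" + "".join(codons) + "TAA"
    b = "ATG" + "".join(codons[:20]) + "GCT" + "".join(codons[20:]) + "TAA"
    aln = align_codons(a, b)
    # exactly one codon of b unmatched: a single 3-nt gap in the projection
    # (where the gap lands among equal-scoring placements is unconstrained)
    assert aln.n_codons_compared == 41
    est = estimate_ks(aln)
    assert (est.ks or 0.0) <= 0.05


def test_align_frame_incompatible_raises():
    with pytest.raises(TranslationError):
        align_codons("ATGGGGTAA", "ATGGGGTA")


# --------------------------------------------------------------- best hits


BLOSUM = None


def _oracle_local_score(a: str, b: str, open_=-11, ext=-1) -> float:
    """Independent affine-gap Smith-Waterman, plain dynamic programming."""
    global BLOSUM
    if BLOSUM is None:
        from Bio.Align import substitution_matrices

        BLOSUM = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext)
            s = BLOSUM[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def test_local_score_matches_dp_oracle_on_toys():
    rnd = random.Random(3)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(25):
        n1, n2 = rnd.randint(8, 20), rnd.randint(8, 20)
        a = "".join(rnd.choice(aas) for _ in range(n1))
        b = "".join(rnd.choice(aas) for _ in range(n2))
        assert float(K._LOCAL.score(a, b)) == pytest.approx(_oracle_local_score(a, b))


def test_best_hits_identical_proteomes_self():
    prot = {
        "x": "MKTLLVLGAGGVGKSALT",
        "y": "MSDNEQFKLVILGAGGVG",
        "z": "MTEYKLVVVGAGGVGKSA",
    }
    hits = find_best_hits(prot, prot, BestHitParams(min_shared_kmers=2))
    assert {h.query_id: h.subject_id for h in hits} == {k: k for k in prot}
    # within-proteome mode excludes self
    hits2 = find_best_hits(
        prot, prot, BestHitParams(min_shared_kmers=2, exclude_self=True)
    )
    for h in hits2:
        assert h.query_id != h.subject_id


def test_no_shared_kmers_no_hit():
    hits = find_best_hits({"q": "MKKKKKKKKKKK"}, {"s": "MDDDDDDDDDDD"})
    assert hits == []


def test_reciprocal_best_pairs():
    hits_ab = [
        K.ProteinHit("a1", "b1", 100, 1.0, 1.0),
        K.ProteinHit("a2", "b2", 90, 1.0, 1.0),
        K.ProteinHit("a3", "b1", 80, 0.9, 1.0),
    ]
    hits_ba = [
        K.ProteinHit("b1", "a1", 100, 1.0, 1.0),
        K.ProteinHit("b2", "a2", 90, 1.0, 1.0),
    ]
    assert reciprocal_best_pairs(hits_ab, hits_ba) == [("a1", "b1"), ("a2", "b2")]
    # asymmetric best hit (a3 -> b1 but b1 -> a1) excluded
    assert all("a3" not in p for p in reciprocal_best_pairs(hits_ab, hits_ba))
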