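"""Homolog search and synonymous-site divergence (Ks) estimation.

The divergence estimator is Nei–Gojobori (1986) site/difference counting with
a Jukes–Cantor multiple-hit correction:

    Ks = -(3/4) * ln(1 - (4/3) * ps),   ps = Sd / S

Synonymous-site fractions are computed per codon (changes to stop codons count
as nonsynonymous, so S + N = 3 * codons exactly) and averaged over the two
sequences.  Codons differing at 2-3 positions are resolved by averaging the
synonymous/nonsynonymous step counts over all mutational pathways that avoid
stop-codon intermediates; if every pathway passes through a stop, all pathways
are used with stop steps counted as nonsynonymous.

Homologs are found by substitution-matrix-scored local alignment (BLOSUM62,
affine gaps 11/1) after a shared-k-mer prefilter, mirroring a BLASTP best-hit
search; homeolog pairs are reciprocal best hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import HybridweaverError

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODON_TABLE: dict[str, str] = {}
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            _c = _b1 + _b2 + _b3
            CODON_TABLE[_c] = str(Seq(_c).translate())

SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))


class TranslationError(HybridweaverError):
    pass


class PrematureStopError(TranslationError):
    """Internal stop codon met outside pseudogene mode: a disablement signal."""

    def __init__(self, msg: str, protein: str, stop_codon_index: int):
        super().__init__(msg)
        self.protein = protein
        self.stop_codon_index = stop_codon_index


class SaturationError(HybridweaverError):
    pass


# --------------------------------------------------------------- translation


def translate_cds(cds: str, pseudogene: bool = False) -> str:
    """Translate a CDS with the standard code; trailing stop is stripped.

    In pseudogene mode, translation stops at the first in-frame stop codon and
    a trailing partial codon is ignored.  Otherwise a non-multiple-of-3 length
    raises TranslationError and an internal stop raises PrematureStopError.
    """
    cds = cds.upper()
    if not pseudogene and len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon not in CODON_TABLE:
            raise TranslationError(f"non-ACGT codon {codon!r} at codon {i}")
        aa = CODON_TABLE[codon]
        if aa == "*":
            if i == n_codons - 1:
                return "".join(aas)
            if pseudogene:
                return "".join(aas)
            raise PrematureStopError(
                f"internal stop at codon {i}", "".join(aas), i
            )
        aas.append(aa)
    return "".join(aas)


# --------------------------------------------------------- NG86 site counting


@lru_cache(maxsize=None)
def syn_site_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of the 3 possible changes at each position that are synonymous.

    Changes to stop codons are nonsynonymous, so the three fractions plus
    their nonsynonymous complements always total 3 sites per codon.
    """
    if codon in STOP_CODONS or codon not in CODON_TABLE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    fracs = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                syn += 1
        fracs.append(syn / 3.0)
    return tuple(fracs)


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of one codon; sums to 3."""
    s = sum(syn_site_fractions(codon))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over mutational pathways.

    Pathways through stop-codon intermediates are excluded; if none survive,
    all pathways are used with any step into or out of a stop counted as
    nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        sd = nd = 0.0
        cur = c1
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                hit_stop = True
                nd += 1.0
            elif CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, hit_stop

    clean, dirty = [], []
    for order in permutations(diff_pos):
        sd, nd, hit_stop = walk(order)
        (dirty if hit_stop else clean).append((sd, nd))
    paths = clean or dirty
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


# ----------------------------------------------------------- data structures


@dataclass
class ProteinHit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    coverage: float


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    codon_pairs: list[tuple[str, str]]

    @property
    def n_codons_compared(self) -> int:
        return len(self.codon_pairs)


@dataclass
class DivergenceEstimate:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    saturated: bool
    low_confidence: bool
    n_codons: int


# ------------------------------------------------------------------ aligners


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


_LOCAL = _make_aligner("local")
_GLOBAL = _make_aligner("global")


def _alignment_stats(a: str, b: str, score: float | None = None) -> tuple[float, float, float]:
    """(score, identity, coverage-of-shorter) of the optimal local alignment.

    Equal-length pairs of high ungapped identity skip the traceback: their
    optimal local alignment is the full-length ungapped overlap.
    """
    if len(a) == len(b):
        ident = _hamming_identity(a, b)
        if ident >= 0.8:
            if score is None:
                score = float(_LOCAL.score(a, b))
            return score, ident, 1.0
    aln = _LOCAL.align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    ident = counts.identities / aligned if aligned else 0.0
    cov = aligned / min(len(a), len(b)) if min(len(a), len(b)) else 0.0
    return float(aln.score), ident, cov


@dataclass
class BestHitParams:
    k: int = 5
    min_shared_kmers: int = 4
    max_candidates: int = 10
    min_coverage: float = 0.5
    exclude_self: bool = False


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_best_hits(
    query_proteome: dict[str, str],
    subject_proteome: dict[str, str],
    params: BestHitParams | None = None,
) -> list[ProteinHit]:
    """Best subject hit per query by local-alignment score.

    A shared-k-mer prefilter keeps only subjects sharing at least
    ``min_shared_kmers`` distinct k-mers with the query.  Ties on score are
    broken by higher identity, then lexicographically smaller subject id.
    Hits covering less than ``min_coverage`` of the shorter protein are
    dropped (the query is then unpaired, class "N" downstream).
    """
    params = params or BestHitParams()
    index: dict[str, set[str]] = {}
    for sid, seq in subject_proteome.items():
        for km in _kmers(seq, params.k):
            index.setdefault(km, set()).add(sid)

    hits: list[ProteinHit] = []
    for qid in sorted(query_proteome):
        qseq = query_proteome[qid]
        if len(qseq) < params.k:
            continue
        shared: dict[str, int] = {}
        for km in _kmers(qseq, params.k):
            for sid in index.get(km, ()):
                shared[sid] = shared.get(sid, 0) + 1
        cands = sorted(
            (
                (sid, n)
                for sid, n in shared.items()
                if n >= params.min_shared_kmers
                and not (params.exclude_self and sid == qid)
            ),
            key=lambda t: (-t[1], t[0]),
        )[: params.max_candidates]
        if not cands:
            continue
        scored = sorted(
            ((float(_LOCAL.score(qseq, subject_proteome[s])), s) for s, _ in cands),
            key=lambda t: (-t[0], t[1]),
        )
        best_score = scored[0][0]
        tied = [s for sc, s in scored if sc == best_score]
        if len(tied) == 1:
            best = tied[0]
            score, ident, cov = _alignment_stats(
                qseq, subject_proteome[best], score=best_score
            )
        else:
            ranked = []
            for s in tied:
                score, ident, cov = _alignment_stats(
                    qseq, subject_proteome[s], score=best_score
                )
                ranked.append((-ident, s, score, cov))
            ranked.sort()
            _, best, score, cov = ranked[0]
            ident = -ranked[0][0]
        if cov < params.min_coverage:
            continue
        hits.append(ProteinHit(qid, best, score, ident, cov))
    return hits


def reciprocal_best_pairs(
    hits_ab: list[ProteinHit], hits_ba: list[ProteinHit]
) -> list[tuple[str, str]]:
    """Pairs where each member is the other's best hit; each gene in <= 1 pair."""
    best_ab = {h.query_id: h.subject_id for h in hits_ab}
    best_ba = {h.query_id: h.subject_id for h in hits_ba}
    pairs = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            pairs.append((a, b))
    return pairs


# ------------------------------------------------------------ codon alignment


def _hamming_identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def align_codons(
    cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b",
    pseudogene: bool = False,
) -> CodonAlignment:
    """Protein-guided codon alignment; gapped columns are excluded.

    The proteins are aligned globally (BLOSUM62, affine gaps) and the
    alignment is projected back onto codons, so gaps always fall in multiples
    of 3 nucleotides.  In pseudogene mode each CDS is truncated at its first
    in-frame stop (and to a multiple of 3) before alignment.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = translate_cds(cds_a, pseudogene=pseudogene)
    prot_b = translate_cds(cds_b, pseudogene=pseudogene)
    if not prot_a or not prot_b:
        raise TranslationError("empty protein after translation")

    if len(prot_a) == len(prot_b) and _hamming_identity(prot_a, prot_b) >= 0.8:
        idx_pairs = list(zip(range(len(prot_a)), range(len(prot_b))))
    else:
        aln = _GLOBAL.align(prot_a, prot_b)[0]
        idx_pairs = []
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            idx_pairs.extend(zip(range(a0, a1), range(b0, b1)))

    codon_pairs = []
    for ia, ib in idx_pairs:
        ca = cds_a[3 * ia : 3 * ia + 3]
        cb = cds_b[3 * ib : 3 * ib + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        codon_pairs.append((ca, cb))
    return CodonAlignment(gene_a, gene_b, codon_pairs)


# --------------------------------------------------------------- Ks estimate


def jukes_cantor(p: float) -> float | None:
    """JC distance; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


MIN_CODONS = 30


def estimate_ks(aln: CodonAlignment) -> DivergenceEstimate:
    """NG86 synonymous/nonsynonymous divergence with JC correction."""
    S = N = Sd = Nd = 0.0
    for ca, cb in aln.codon_pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return DivergenceEstimate(
        gene_a=aln.gene_a, gene_b=aln.gene_b, S=S, N=N, Sd=Sd, Nd=Nd,
        ps=ps, pn=pn, ks=ks, ka=ka,
        saturated=ks is None,
        low_confidence=aln.n_codons_compared < MIN_CODONS,
        n_codons=aln.n_codons_compared,
    )


def proteome_of(cds_map: dict[str, str]) -> dict[str, str]:
    """Pseudogene-tolerant translation of a CDS dictionary (empty dropped)."""
    out = {}
    for gid, cds in cds_map.items():
        prot = translate_cds(cds, pseudogene=True)
        if prot:
            out[gid] = prot
    return out
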