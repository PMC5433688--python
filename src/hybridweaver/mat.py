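"""Mating-type locus forensics: cassettes, HO cleavage, NHEJ junctions.

Yeast mating-type switching is initiated by the HO endonuclease, which cuts
the expressed MAT locus at the boundary of the Z repeat region; the core of
the cleavage site (cgcagca) invariably forms the first nucleotides of Z.  A
failed switch in a newly formed hybrid can instead be repaired against an
ectopic site by nonhomologous end joining (NHEJ), producing a reciprocal
translocation whose junctions carry target-site duplications and no
microhomology.  This module models the cut, catalogues MAT/HML/HMR loci by
their X/Z flanking repeats, and reads the junction and splice-site signatures
back out of sequence.

String-level operations (cleave_ho, junction analysis, HO-site scan) use
0-based offsets into the sequence they are given; the genome-level catalog
reports 1-based inclusive genomic coordinates like the rest of the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib

from .model import AnnotatedGenome, Gene, HybridweaverError, revcomp
from .ks import translate_cds

HO_CORE = "CGCAGCA"
HO_OVERHANG = 4
# Cut registration relative to the core: the top-strand cut falls
# HO_TOP_CUT_OFFSET nt into the core and the bottom-strand cut at the core's
# 5' boundary, so the 4 nt between them form a 3' overhang (top cut to the
# right of the bottom cut).  A single constant so it can be revised without
# touching callers.
HO_TOP_CUT_OFFSET = 4


@dataclass
class HoSite:
    position: int  # 0-based offset of the core's first base on the given strand
    strand: str


def locate_ho_sites(seq: str) -> list[HoSite]:
    """All occurrences of the HO core heptamer, both strands.

    Reverse-strand sites are reported at the 0-based offset (on the given
    sequence) where the reverse complement of the core begins.
    """
    seq = seq.upper()
    sites = [HoSite(m.start(), "+") for m in re.finditer(HO_CORE, seq)]
    rc_core = revcomp(HO_CORE)
    sites += [HoSite(m.start(), "-") for m in re.finditer(rc_core, seq)]
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


@dataclass
class DuplexFragment:
    """One product of a staggered double-strand cut.

    ``top`` is the fragment's top strand 5'->3'; ``bottom`` its bottom strand
    5'->3' (i.e. the reverse complement of the covered genomic interval).
    """

    top: str
    bottom: str


@dataclass
class CleavageResult:
    top_cut: int  # 0-based: cut between positions top_cut-1 and top_cut
    bottom_cut: int
    overhang_len: int
    overhang_seq: str
    polarity: str  # "3'"
    left: DuplexFragment
    right: DuplexFragment
    strand: str


def cleave_ho(seq: str, site: HoSite) -> CleavageResult:
    """Staggered cut at an HO site, leaving a 4-nt 3' overhang.

    Re-ligation of the two fragments reconstitutes the input exactly.
    """
    seq = seq.upper()
    n = len(seq)
    if site.strand == "+":
        top_cut = site.position + HO_TOP_CUT_OFFSET
        bottom_cut = site.position
        core = seq[site.position : site.position + len(HO_CORE)]
        if core != HO_CORE:
            raise HybridweaverError(f"no HO core at +{site.position}: {core!r}")
    else:
        # mirror image: the enzyme's strands swap roles
        top_cut = site.position + len(HO_CORE)
        bottom_cut = site.position + len(HO_CORE) - HO_TOP_CUT_OFFSET
        core = seq[site.position : site.position + len(HO_CORE)]
        if core != revcomp(HO_CORE):
            raise HybridweaverError(f"no HO core at -{site.position}: {core!r}")
    if bottom_cut < 10 or top_cut > n - 10:
        raise HybridweaverError("HO site too close to the sequence end")
    left = DuplexFragment(top=seq[:top_cut], bottom=revcomp(seq[:bottom_cut]))
    right = DuplexFragment(top=seq[top_cut:], bottom=revcomp(seq[bottom_cut:]))
    return CleavageResult(
        top_cut=top_cut, bottom_cut=bottom_cut,
        overhang_len=top_cut - bottom_cut,
        overhang_seq=seq[bottom_cut:top_cut],
        polarity="3'", left=left, right=right, strand=site.strand,
    )


def religate(result: CleavageResult) -> str:
    """Rejoin the two cleavage fragments; returns the restored duplex."""
    top = result.left.top + result.right.top
    genomic_bottom = revcomp(result.left.bottom) + revcomp(result.right.bottom)
    if top != genomic_bottom:
        raise HybridweaverError("fragments do not re-ligate cleanly")
    return top


# ------------------------------------------------------------ NHEJ junctions


@dataclass
class TargetSiteDuplication:
    sequence: str
    length: int
    side: str  # 'left' or 'right' donor


@dataclass
class JunctionSignature:
    microhomology: int
    duplications: list[TargetSiteDuplication] = field(default_factory=list)
    inserted: str = ""

    def tsd_lengths(self) -> dict[str, int]:
        out = {"left": 0, "right": 0}
        for d in self.duplications:
            out[d.side] = d.length
        return out


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def analyze_junction(junction: str, donor_left: str, donor_right: str) -> JunctionSignature:
    """Read the repair signature out of a junction and its two donors.

    The junction is assumed to begin with a prefix of ``donor_left`` and end
    with a suffix of ``donor_right``.  Overlap between the two matches is
    microhomology; any bases in between are classified as target-site
    duplications (tandem re-copies of the retained donor flanks, the fill-in
    signature of NHEJ on staggered ends) or untemplated insertions.
    """
    junction = junction.upper()
    donor_left = donor_left.upper()
    donor_right = donor_right.upper()
    p = _common_prefix(junction, donor_left)
    s = _common_suffix(junction, donor_right)
    if p == 0 or s == 0:
        raise HybridweaverError("donors do not align to the junction flanks")
    if p + s >= len(junction):
        return JunctionSignature(microhomology=p + s - len(junction))

    gap = junction[p : len(junction) - s]
    b = len(donor_right) - s  # first retained base of the right donor

    # left TSD: longest prefix of the gap that tandem-duplicates the end of
    # the retained left flank
    t1 = 0
    for t in range(1, min(len(gap), p) + 1):
        if gap[:t] == donor_left[p - t : p]:
            t1 = t
    rest = gap[t1:]
    # right TSD: longest suffix of the remainder that tandem-duplicates the
    # start of the retained right flank
    t2 = 0
    for t in range(1, min(len(rest), len(donor_right) - b) + 1):
        if rest[len(rest) - t :] == donor_right[b : b + t]:
            t2 = t
    inserted = rest[: len(rest) - t2]

    dups = []
    if t1:
        dups.append(TargetSiteDuplication(gap[:t1], t1, "left"))
    if t2:
        dups.append(TargetSiteDuplication(rest[len(rest) - t2 :], t2, "right"))
    return JunctionSignature(microhomology=0, duplications=dups, inserted=inserted)


_BASE_CYCLE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def make_junction(
    donor_left: str,
    cut_left: int,
    donor_right: str,
    cut_right: int,
    tsd_left: int = 0,
    tsd_right: int = 0,
    microhomology: int = 0,
    inserted: str = "",
    max_fixups: int = 200,
) -> tuple[str, str, str]:
    """Construct a junction with a prescribed repair signature.

    Returns (junction, donor_left, donor_right); the donors may have single
    bases adjusted near the break so that the signature decomposes uniquely
    (the greedy analyzer recovers exactly the prescribed lengths).  A
    microhomology-mediated join carries no duplications or insertions.
    """
    if microhomology > 0 and (tsd_left or tsd_right or inserted):
        raise HybridweaverError(
            "a microhomology join cannot also carry duplications/insertions"
        )
    if tsd_left > cut_left or microhomology > cut_left:
        raise HybridweaverError("left duplication exceeds the retained flank")
    if cut_right + tsd_right > len(donor_right):
        raise HybridweaverError("right duplication exceeds the donor")
    if microhomology > cut_right:
        raise HybridweaverError("microhomology exceeds the right donor flank")

    L = list(donor_left)
    R = list(donor_right)
    a, b, m = cut_left, cut_right, microhomology

    if m > 0:
        R[b - m : b] = L[a - m : a]

    def build() -> str:
        if m > 0:
            return "".join(L[:a]) + "".join(R[b:])
        return (
            "".join(L[:a])
            + "".join(L[a - tsd_left : a])
            + inserted
            + "".join(R[b : b + tsd_right])
            + "".join(R[b:])
        )

    def intended() -> tuple[int, int, int, str]:
        return (m, tsd_left, tsd_right, inserted)

    def set_differing(seq: list, pos: int, avoid: str) -> None:
        while seq[pos] == avoid:
            seq[pos] = _BASE_CYCLE[seq[pos]]

    tl, tr = tsd_left, tsd_right
    for _ in range(max_fixups):
        junction = build()
        Ls, Rs = "".join(L), "".join(R)
        p = _common_prefix(junction, Ls)
        s = _common_suffix(junction, Rs)
        s_expected = len(R) - b + m
        if p > a and a < len(L):
            # prefix overruns the break: L's departed base must differ from
            # the junction continuation (the base is not in the junction)
            set_differing(L, a, junction[a])
            continue
        if s > s_expected and b - m - 1 >= 0:
            set_differing(R, b - m - 1, junction[len(junction) - s_expected - 1])
            continue
        sig = analyze_junction(junction, Ls, Rs)
        got = (
            sig.microhomology,
            sig.tsd_lengths()["left"],
            sig.tsd_lengths()["right"],
            sig.inserted,
        )
        if got == intended():
            return junction, Ls, Rs
        got_tl = sig.tsd_lengths()["left"]
        got_tr = sig.tsd_lengths()["right"]
        if got_tl > tl:
            # the greedy left-duplication window extends too far back; break
            # its first character (which lies outside the duplicated gap)
            gap = junction[p : len(junction) - s]
            set_differing(L, a - got_tl, gap[0] if gap else "A")
            continue
        if got_tr > tr:
            gap = junction[p : len(junction) - s]
            rest = gap[got_tl if got_tl <= tl else tl :]
            set_differing(R, b + got_tr - 1, rest[-1] if rest else "A")
            continue
        raise HybridweaverError(
            f"junction signature {got} cannot be reconciled with {intended()}"
        )
    raise HybridweaverError("could not disambiguate the junction construction")


# --------------------------------------------------------------- splice shift


@dataclass
class SpliceShiftReport:
    gene_id: str
    intron_index: int | None  # first intron with a broken acceptor, if any
    acceptor_dinucleotide: str | None
    original_acceptor_end: int | None  # coding-strand local offset (0-based)
    new_acceptor_end: int | None
    shift: int | None
    frame_preserved: bool
    unspliceable: bool
    protein_length: int | None


def _coding_layout(gene: Gene, chrom_seq: str) -> tuple[str, list[tuple[int, int]]]:
    """Gene-local sequence and exon intervals in coding-strand orientation.

    Offsets are 0-based within the returned local sequence.
    """
    local = chrom_seq[gene.start - 1 : gene.end]
    exons = [(s - gene.start, e - gene.start) for s, e in gene.exons]
    if gene.strand == "-":
        n = len(local)
        local = revcomp(local)
        exons = [(n - 1 - e, n - 1 - s) for s, e in exons]
        exons.sort()
    return local, exons


def analyze_splice_shift(
    gene: Gene, chrom_seq: str, window: int = 50
) -> SpliceShiftReport:
    """Check intron acceptors; model splicing at the nearest downstream AG.

    An AG-to-anything mutation at a 3' splice site forces the spliceosome to
    the next downstream AG; a shift that is not a multiple of 3 frameshifts
    the coding sequence and truncates the protein.
    """
    local, exons = _coding_layout(gene, chrom_seq)
    introns = [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    if not introns:
        raise HybridweaverError(f"gene {gene.gene_id} has no annotated intron")

    broken_index = None
    acceptor_dinuc = None
    for i, (s, e) in enumerate(introns):
        dinuc = local[e - 1 : e + 1]
        if dinuc != "AG":
            broken_index = i
            acceptor_dinuc = dinuc
            break

    def spliced(exon_list):
        return "".join(local[s : e + 1] for s, e in exon_list)

    if broken_index is None:
        prot = translate_cds(spliced(exons), pseudogene=True)
        return SpliceShiftReport(
            gene_id=gene.gene_id, intron_index=None, acceptor_dinucleotide=None,
            original_acceptor_end=None, new_acceptor_end=None, shift=0,
            frame_preserved=True, unspliceable=False, protein_length=len(prot),
        )

    s, e = introns[broken_index]
    new_end = None
    for j in range(e + 1, min(e + 1 + window, len(local) - 1)):
        if local[j - 1 : j + 1] == "AG":
            new_end = j
            break
    if new_end is None:
        return SpliceShiftReport(
            gene_id=gene.gene_id, intron_index=broken_index,
            acceptor_dinucleotide=acceptor_dinuc, original_acceptor_end=e,
            new_acceptor_end=None, shift=None, frame_preserved=False,
            unspliceable=True, protein_length=None,
        )
    shift = new_end - e
    new_exons = list(exons)
    ds, de = new_exons[broken_index + 1]
    new_exons[broken_index + 1] = (ds + shift, de)
    prot = translate_cds(spliced(new_exons), pseudogene=True)
    return SpliceShiftReport(
        gene_id=gene.gene_id, intron_index=broken_index,
        acceptor_dinucleotide=acceptor_dinuc, original_acceptor_end=e,
        new_acceptor_end=new_end, shift=shift,
        frame_preserved=shift % 3 == 0, unspliceable=False,
        protein_length=len(prot),
    )


# -------------------------------------------------------------- MAT catalog


@dataclass
class MatLocus:
    kind: str  # MAT, HML, HMR, fragment
    idiomorph: str  # 'a', 'alpha', 'unknown'
    subgenome: str  # 'A', 'B', 'unknown'
    chrom: str
    start: int  # 1-based inclusive genomic
    end: int
    x_range: tuple[int, int] | None
    z_range: tuple[int, int] | None
    intact: bool
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class MatCatalog:
    loci: list[MatLocus] = field(default_factory=list)  # intact + broken (grouped)
    fragments: list[MatLocus] = field(default_factory=list)
    x_copies: list[tuple[str, int, int]] = field(default_factory=list)
    z_copies: list[tuple[str, int, int]] = field(default_factory=list)
    x_identity: float | None = None
    z_identity: float | None = None
    a1_absent: bool = True

    @property
    def n_regions(self) -> int:
        return len(self.loci)


def _repeat_regions(genome: AnnotatedGenome, k: int = 32, min_copies: int = 3):
    """Maximal same-copy-number runs of k-mers occurring >= min_copies times."""
    counts: dict[int, int] = {}
    for chrom in genome.chromosomes:
        seq = chrom.seq
        for i in range(len(seq) - k + 1):
            h = hash(seq[i : i + k])
            counts[h] = counts.get(h, 0) + 1
    regions = []
    for chrom in genome.chromosomes:
        seq = chrom.seq
        run_start = None
        run_count = None
        for i in range(len(seq) - k + 2):
            c = counts.get(hash(seq[i : i + k]), 0) if i <= len(seq) - k else 0
            c = c if c >= min_copies else 0
            if c != run_count:
                if run_count:
                    regions.append((chrom.name, run_start, i - 1 + k - 1, run_count))
                run_start = i
                run_count = c
        if run_count:
            regions.append((chrom.name, run_start, len(seq) - 1, run_count))
    return regions  # (chrom, start0, end0 inclusive, copy_number)


def _has_short_period(seq: str, max_period: int = 15) -> bool:
    probe = seq[: min(len(seq), 120)]
    for p in range(1, max_period + 1):
        if len(probe) >= 3 * p and all(
            probe[i] == probe[i % p] for i in range(min(len(probe), 6 * p))
        ):
            return True
    return False


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


_IDIO_PAT = re.compile(r"(alpha1|alpha2|a2|a1)", re.IGNORECASE)
_KIND_PAT = re.compile(r"(MAT|HML|HMR)", re.IGNORECASE)


def catalog_mat_loci(
    genome: AnnotatedGenome,
    labels: dict[str, str] | None = None,
    probes: dict[str, str] | None = None,
    min_repeat_len: int = 200,
    min_copies: int = 3,
    max_locus_span: int = 8000,
    id_min: float = 0.95,
) -> MatCatalog:
    """Discover X/Z repeats and classify MAT/HML/HMR loci.

    X and Z are found de novo as near-identical multi-copy intergenic
    elements (>= min_copies copies, length >= min_repeat_len); Z is the
    cluster whose copies begin with the HO core.  A locus is intact when an
    X copy is followed by a Z copy within ``max_locus_span`` with idiomorph
    gene stubs between; a lone flank is a fragment, and an X-fragment plus a
    Z-fragment are grouped as one broken locus.  With ``probes`` given, the
    repeats are located by alignment instead of discovered.
    """
    chrom_map = genome.chrom_map

    def overlaps_gene(chrom: str, s0: int, e0: int) -> bool:
        for g in chrom_map[chrom].genes:
            for es, ee in g.exons:
                if es - 1 <= e0 and s0 <= ee - 1:
                    return True
        return False

    copies: list[tuple[str, int, int, str]] = []  # chrom, start0, end0, seq
    if probes:
        for name in ("x", "z"):
            probe = probes[name].upper()
            for chrom in genome.chromosomes:
                seq = chrom.seq
                start = 0
                while True:
                    res = edlib.align(probe, seq[start:], mode="HW", task="locations")
                    if res["editDistance"] < 0 or res["editDistance"] > (1 - id_min) * len(probe):
                        break
                    s, e = res["locations"][0]
                    copies.append((chrom.name, start + s, start + e, name))
                    start = start + e + 1
    else:
        regions = [
            (c, s0, e0)
            for c, s0, e0, _cn in _repeat_regions(genome, min_copies=min_copies)
            if e0 - s0 + 1 >= min_repeat_len
            and not _has_short_period(chrom_map[c].seq[s0 : s0 + 120])
            and not overlaps_gene(c, s0, e0)
        ]
        # cluster by sequence identity to a representative
        clusters: list[list[tuple[str, int, int]]] = []
        reps: list[str] = []
        for c, s0, e0 in regions:
            seq = chrom_map[c].seq[s0 : e0 + 1]
            for ci, rep in enumerate(reps):
                if 0.5 < len(seq) / len(rep) < 2.0 and _identity(seq, rep) >= 0.8:
                    clusters[ci].append((c, s0, e0))
                    break
            else:
                clusters.append([(c, s0, e0)])
                reps.append(seq)
        keep = [
            (cl, rep) for cl, rep in zip(clusters, reps) if len(cl) >= min_copies
        ]
        z_clusters = [(cl, rep) for cl, rep in keep if HO_CORE in rep[:40]]
        x_clusters = [
            (cl, rep) for cl, rep in keep if HO_CORE not in rep[:40]
        ]
        if not z_clusters or not x_clusters:
            warnings.warn("no X/Z repeat families found; empty MAT catalog")
            return MatCatalog()
        z_cl = max(z_clusters, key=lambda t: len(t[0]))[0]
        x_cl = max(x_clusters, key=lambda t: (len(t[0]), len(t[1])))[0]
        for c, s0, e0 in x_cl:
            copies.append((c, s0, e0, "x"))
        for c, s0, e0 in z_cl:
            # trim the copy so it starts exactly at the HO core
            seq = chrom_map[c].seq[s0 : e0 + 1]
            off = seq.find(HO_CORE)
            if 0 <= off <= 40:
                s0 += off
            copies.append((c, s0, e0, "z"))

    x_copies = sorted((c, s0, e0) for c, s0, e0, n in copies if n == "x")
    z_copies = sorted((c, s0, e0) for c, s0, e0, n in copies if n == "z")
    if not x_copies and not z_copies:
        warnings.warn("no MAT-related repeats located; empty catalog")
        return MatCatalog()

    def pairwise_identity(cps):
        if len(cps) < 2:
            return None
        seqs = [chrom_map[c].seq[s0 : e0 + 1] for c, s0, e0 in cps]
        # truncate to the shortest copy: boundary trimming must not count
        n = min(len(s) for s in seqs)
        seqs = [s[:n] for s in seqs]
        return min(_identity(seqs[0], s) for s in seqs[1:])

    # ---- locus assembly ------------------------------------------------
    a1_absent = True
    for g in genome.genes():
        m = _IDIO_PAT.search(g.attributes.get("Name", "") or g.gene_id)
        if m and m.group(1).lower() == "a1":
            a1_absent = False

    def genes_between(chrom: str, s0: int, e0: int) -> list[Gene]:
        return [
            g for g in chrom_map[chrom].genes
            if g.start - 1 >= s0 and g.end - 1 <= e0
        ]

    def classify(genes: list[Gene]) -> tuple[str, str]:
        idio = "unknown"
        kinds = []
        names = [(g.attributes.get("Name", "") or g.gene_id) for g in genes]
        tokens = [m.group(1).lower() for n in names for m in [_IDIO_PAT.search(n)] if m]
        if any(t in ("alpha1", "alpha2") for t in tokens):
            idio = "alpha"
        elif "a2" in tokens:
            idio = "a"
        for n in names:
            m = _KIND_PAT.search(n)
            if m:
                kinds.append(m.group(1).upper())
        kind = max(set(kinds), key=kinds.count) if kinds else "MAT"
        return kind, idio

    def locus_subgenome(chrom: str, s0: int, e0: int, locus_genes: set[str]) -> str:
        if not labels:
            return "unknown"
        before = [
            g for g in chrom_map[chrom].genes
            if g.end - 1 < s0 and labels.get(g.gene_id) in ("A", "B")
        ]
        after = [
            g for g in chrom_map[chrom].genes
            if g.start - 1 > e0 and labels.get(g.gene_id) in ("A", "B")
        ]
        votes = []
        if before:
            votes.append(labels[before[-1].gene_id])
        if after:
            votes.append(labels[after[0].gene_id])
        if not votes:
            return "unknown"
        if len(votes) == 2 and votes[0] != votes[1]:
            return votes[0]  # locus at a subgenome boundary: upstream wins
        return votes[0]

    used_z: set[tuple[str, int, int]] = set()
    intact: list[MatLocus] = []
    fragments: list[MatLocus] = []
    for c, xs0, xe0 in x_copies:
        partner = None
        for zc in z_copies:
            if zc in used_z or zc[0] != c:
                continue
            zs0 = zc[1]
            if xe0 < zs0 <= xe0 + max_locus_span:
                partner = zc
                break
        if partner is None:
            genes = genes_between(c, max(0, xs0 - 200), xe0 + max_locus_span)
            kind, idio = classify(genes)
            fragments.append(
                MatLocus(
                    kind="fragment", idiomorph=idio,
                    subgenome=locus_subgenome(c, xs0, xe0, set()),
                    chrom=c, start=xs0 + 1, end=xe0 + 1,
                    x_range=(xs0 + 1, xe0 + 1), z_range=None, intact=False,
                    gene_ids=[g.gene_id for g in genes],
                )
            )
            continue
        used_z.add(partner)
        _, zs0, ze0 = partner
        genes = genes_between(c, xe0, zs0)
        kind, idio = classify(genes)
        intact.append(
            MatLocus(
                kind=kind, idiomorph=idio,
                subgenome=locus_subgenome(c, xs0, ze0, {g.gene_id for g in genes}),
                chrom=c, start=xs0 + 1, end=ze0 + 1,
                x_range=(xs0 + 1, xe0 + 1), z_range=(zs0 + 1, ze0 + 1),
                intact=True, gene_ids=[g.gene_id for g in genes],
            )
        )
    for zc in z_copies:
        if zc in used_z:
            continue
        c, zs0, ze0 = zc
        fragments.append(
            MatLocus(
                kind="fragment", idiomorph="unknown",
                subgenome=locus_subgenome(c, zs0, ze0, set()),
                chrom=c, start=zs0 + 1, end=ze0 + 1,
                x_range=None, z_range=(zs0 + 1, ze0 + 1), intact=False,
                gene_ids=[],
            )
        )

    # group one X-fragment with one Z-fragment as a single broken locus
    loci = list(intact)
    x_frags = [f for f in fragments if f.x_range is not None]
    z_frags = [f for f in fragments if f.z_range is not None]
    for xf, zf in zip(x_frags, z_frags):
        loci.append(
            MatLocus(
                kind="MAT", idiomorph=xf.idiomorph, subgenome=xf.subgenome,
                chrom=xf.chrom, start=xf.start, end=xf.end,
                x_range=xf.x_range, z_range=zf.z_range, intact=False,
                gene_ids=xf.gene_ids,
            )
        )
    loci.extend(x_frags[len(z_frags):])
    loci.extend(z_frags[len(x_frags):])

    return MatCatalog(
        loci=loci, fragments=fragments,
        x_copies=x_copies, z_copies=z_copies,
        x_identity=pairwise_identity(x_copies),
        z_identity=pairwise_identity(z_copies),
        a1_absent=a1_absent,
    )
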