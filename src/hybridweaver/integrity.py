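"""Screens for disabled homeologs, in-frame introns, and +1 frameshift motifs.

A hybrid carries two copies of nearly every gene, so disabling mutations
(frameshift indels, premature stops, splice-site breaks) can persist in one
homeolog while the other remains intact.  The screen follows the annotated
protein products: a pair is flagged when one member is shorter than
``ratio_threshold`` (default 90%) of the other, and the mechanism is then
refined by codon-aware comparison of the coding sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from .model import AnnotatedGenome, Gene, HybridweaverError
from .ks import STOP_CODONS, CODON_TABLE, translate_cds


@dataclass
class DisablementCall:
    gene_id: str
    partner_id: str
    mechanism: str  # frameshift-indel, premature-stop, splice-site, length-only
    length_ratio: float
    position: int | None = None  # codon index of the first disruption
    shared: bool | None = None


@dataclass
class InFrameIntron:
    gene_id: str
    start: int  # 1-based genomic
    end: int
    length: int
    stop_free: bool = True


@dataclass
class FrameshiftSite:
    gene_id: str
    position: int  # 0-based offset of the motif in the CDS
    motif: str
    skipped_base: str = "A"


_DNA_ALIGNER = PairwiseAligner()
_DNA_ALIGNER.mode = "global"
_DNA_ALIGNER.match_score = 2
_DNA_ALIGNER.mismatch_score = -3
_DNA_ALIGNER.open_gap_score = -7
_DNA_ALIGNER.extend_gap_score = -2


def detect_mechanism(cds_broken: str, cds_intact: str) -> DisablementCall:
    """Localize the first disruption in a damaged CDS against its intact twin.

    A 1-2 nt indel is called frameshift-indel; an in-frame stop codon before
    the disruption point is premature-stop; an unalignable pair degrades to
    length-only.  Calling on an undamaged pair is an error.
    """
    cds_broken, cds_intact = cds_broken.upper(), cds_intact.upper()
    prot_b = translate_cds(cds_broken, pseudogene=True)
    prot_i = translate_cds(cds_intact, pseudogene=True)
    ratio = min(len(prot_b), len(prot_i)) / max(len(prot_b), len(prot_i))

    # in-frame premature stop: frame intact, a stop codon before the end
    if len(cds_broken) % 3 == 0:
        n = len(cds_broken) // 3
        for ci in range(n - 1):
            codon = cds_broken[3 * ci : 3 * ci + 3]
            if codon in STOP_CODONS:
                return DisablementCall(
                    gene_id="", partner_id="", mechanism="premature-stop",
                    length_ratio=ratio, position=ci,
                )

    try:
        aln = _DNA_ALIGNER.align(cds_broken, cds_intact)[0]
    except Exception:
        return DisablementCall("", "", "length-only", ratio)
    # find the first gap of length 1-2 (a frame-changing indel)
    prev_a = prev_b = None
    blocks = list(zip(*aln.aligned))
    for idx, ((a0, a1), (b0, b1)) in enumerate(blocks):
        if prev_a is not None:
            gap_a = a0 - prev_a
            gap_b = b0 - prev_b
            indel = abs(gap_a - gap_b)
            if indel and indel % 3 != 0:
                return DisablementCall(
                    "", "", "frameshift-indel", ratio, position=prev_a // 3
                )
        prev_a, prev_b = a1, b1
    if cds_broken == cds_intact:
        raise HybridweaverError("mechanism requested for an identical CDS pair")
    return DisablementCall("", "", "length-only", ratio)


def screen_pairs(
    pairs: list[tuple[str, str]],
    proteins: dict[str, str],
    cds: dict[str, str] | None = None,
    ratio_threshold: float = 0.9,
) -> list[DisablementCall]:
    """Flag pairs whose shorter protein is < threshold of the longer.

    The comparison is symmetric in pair order and the threshold strict, so a
    ratio of exactly 0.9 passes.  With CDS provided the mechanism is refined;
    otherwise it is length-only.
    """
    calls = []
    for a, b in pairs:
        pa, pb = proteins.get(a), proteins.get(b)
        if not pa or not pb:
            continue
        ratio = min(len(pa), len(pb)) / max(len(pa), len(pb))
        if ratio >= ratio_threshold:
            continue
        broken, intact = (a, b) if len(pa) < len(pb) else (b, a)
        mechanism = "length-only"
        position = None
        if cds and broken in cds and intact in cds:
            call = detect_mechanism(cds[broken], cds[intact])
            mechanism, position = call.mechanism, call.position
        calls.append(
            DisablementCall(
                gene_id=broken, partner_id=intact, mechanism=mechanism,
                length_ratio=ratio, position=position,
            )
        )
    return calls


def compare_strains(
    calls_1: list[DisablementCall],
    calls_2: list[DisablementCall],
    ortholog_map: dict[str, str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Partition disablement calls into shared and strain-unique sets.

    Calls are shared when they hit the same (orthologous) gene with the same
    mechanism class.  Returns (shared, unique_to_1, unique_to_2) gene ids,
    keyed in strain-1 space.
    """
    omap = ortholog_map or {}
    key1 = {(c.gene_id, c.mechanism) for c in calls_1}
    key2 = {(omap.get(c.gene_id, c.gene_id), c.mechanism) for c in calls_2}
    shared = sorted(g for g, m in key1 & key2)
    unique1 = sorted(g for g, m in key1 - key2)
    unique2 = sorted(g for g, m in key2 - key1)
    return shared, unique1, unique2


def find_inframe_introns(genome: AnnotatedGenome) -> list[InFrameIntron]:
    """Introns whose length is a multiple of 3 with no in-frame stop codon.

    Such introns leave both the spliced and unspliced mRNA translatable, the
    hallmark of conditional/alternative splicing.  The reading frame of the
    intron is the frame it occupies in the unspliced transcript.
    """
    out = []
    for chrom in genome.chromosomes:
        for g in chrom.genes:
            if g.n_exons < 2:
                continue
            local = chrom.seq[g.start - 1 : g.end]
            from .model import revcomp as _rc

            seq = _rc(local) if g.strand == "-" else local
            exons = [(s - g.start, e - g.start) for s, e in g.exons]
            if g.strand == "-":
                n = len(local)
                exons = sorted((n - 1 - e, n - 1 - s) for s, e in exons)
            for (s1, e1), (s2, _) in zip(exons, exons[1:]):
                ilen = s2 - e1 - 1
                istart, iend = e1 + 1, s2 - 1
                if ilen % 3 != 0:
                    continue
                stop_free = True
                # reading frame of the unspliced transcript is simply the
                # coding-orientation position mod 3
                pad_start = istart - (istart % 3)
                read = seq[pad_start : iend + 1]
                for ci in range(0, len(read) - 2, 3):
                    if read[ci : ci + 3] in STOP_CODONS:
                        stop_free = False
                        break
                if stop_free:
                    if g.strand == "-":
                        gs = g.end - iend
                        ge = g.end - istart
                    else:
                        gs = g.start + istart
                        ge = g.start + iend
                    out.append(
                        InFrameIntron(
                            gene_id=g.gene_id, start=gs, end=ge,
                            length=ilen, stop_free=True,
                        )
                    )
    return out


PLUS1_MOTIFS = ("CTTAGTT", "CTTAGGC")  # EST3-like and ABP140-like sites


def find_plus1_sites(
    cds_map: dict[str, str], min_extension: int = 30, max_zero_tail: int = 30
) -> list[FrameshiftSite]:
    """Candidate programmed +1 frameshift sites.

    A site requires the motif (CTT-A-GTT or CTT-A-GGC, the A being the
    skipped base), the annotated frame terminating soon after the motif, and
    an open +1-frame continuation of at least ``min_extension`` codons.
    """
    sites = []
    for gid in sorted(cds_map):
        cds = cds_map[gid].upper()
        for motif in PLUS1_MOTIFS:
            for m in re.finditer(motif, cds):
                pos = m.start()
                if pos % 3 != 0:
                    continue  # CTT must sit in frame 0
                # frame 0 must close within max_zero_tail codons after the motif
                stop0 = None
                for ci in range(pos // 3, len(cds) // 3):
                    if cds[3 * ci : 3 * ci + 3] in STOP_CODONS:
                        stop0 = ci
                        break
                if stop0 is None or stop0 - pos // 3 > max_zero_tail:
                    continue
                # +1 frame (skipping the A) must stay open >= min_extension codons
                shifted = cds[pos + 4 :]
                open_codons = 0
                for ci in range(0, len(shifted) - 2, 3):
                    if shifted[ci : ci + 3] in STOP_CODONS:
                        break
                    open_codons += 1
                if open_codons >= min_extension:
                    sites.append(FrameshiftSite(gene_id=gid, position=pos, motif=motif))
    return sites
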