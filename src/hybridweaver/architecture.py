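"""Gene-order archaeology: synteny blocks, breakpoints, LOH, BIR, telomeres.

Gene orders are compared through a one-to-one homolog map.  An adjacency of
two mapped genes in genome *x* is intact when their homologs sit on one
chromosome of genome *y*, next to each other (up to ``max_gap`` unmapped
intervening genes), in a consistent relative orientation.  Every reciprocal
translocation or inversion breaks exactly two such adjacencies, so the
rearrangement-event estimate is ``breakpoints div 2``.

Loss-of-heterozygosity tracts are runs of same-label-pair genes (A:A or B:B
categories) on a chromosome whose majority label is the opposite class;
recombination junctions are persistent switches of the background label; BIR
(break-induced replication) candidates are terminal runs whose sequence is
near-identical to another chromosome end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib

from .model import AnnotatedGenome, HybridweaverError, revcomp
from .classify import CategoryTrack

# gene order type: per chromosome, ordered (gene_id, strand) tuples
GeneOrder = dict[str, list[tuple[str, str]]]


def genome_order(genome: AnnotatedGenome) -> GeneOrder:
    return {
        c.name: [(g.gene_id, g.strand) for g in c.genes]
        for c in genome.chromosomes
    }


@dataclass
class SyntenyBlock:
    chrom_x: str
    chrom_y: str
    x_range: tuple[int, int]  # inclusive gene indices on chrom_x
    y_range: tuple[int, int]
    orientation: str  # '+' or '-'
    n_genes: int


@dataclass
class Breakpoint:
    chrom_x: str
    left_gene: str
    right_gene: str
    reason: str  # 'chromosome', 'distance', 'orientation'


@dataclass
class BreakpointSet:
    breakpoints: list[Breakpoint] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.breakpoints)

    @property
    def event_estimate(self) -> int:
        return self.count // 2

    @property
    def odd(self) -> bool:
        return self.count % 2 == 1


def _y_index(order_y: GeneOrder) -> dict[str, tuple[str, int, str]]:
    idx = {}
    for chrom, genes in order_y.items():
        for i, (gid, strand) in enumerate(genes):
            idx[gid] = (chrom, i, strand)
    return idx


def _mapped_runs(
    genes: list[tuple[str, str]],
    homolog_map: dict[str, str],
    y_idx: dict[str, tuple[str, int, str]],
    max_gap: int,
):
    """Consecutive mapped genes on one x chromosome, with their positions.

    Yields (i, j) index pairs of mapped genes adjacent up to max_gap unmapped
    intervening genes.  A mapped gene is one whose homolog exists in y.
    """
    mapped = [
        i for i, (gid, _) in enumerate(genes)
        if gid in homolog_map and homolog_map[gid] in y_idx
    ]
    for a, b in zip(mapped, mapped[1:]):
        if b - a - 1 <= max_gap:
            yield a, b


def _adjacency_intact(
    g1: tuple[str, str], g2: tuple[str, str],
    homolog_map: dict[str, str],
    y_idx: dict[str, tuple[str, int, str]],
    inv_mapped: set[str],
    max_gap: int,
    order_y: GeneOrder,
) -> tuple[bool, str]:
    h1, h2 = homolog_map[g1[0]], homolog_map[g2[0]]
    c1, i1, s1 = y_idx[h1]
    c2, i2, s2 = y_idx[h2]
    if c1 != c2:
        return False, "chromosome"
    rel1 = 1 if s1 == g1[1] else -1
    rel2 = 1 if s2 == g2[1] else -1
    if rel1 != rel2:
        return False, "orientation"
    step = i2 - i1
    if step == 0 or (1 if step > 0 else -1) != rel1:
        return False, "orientation"
    lo, hi = min(i1, i2), max(i1, i2)
    between = order_y[c1][lo + 1 : hi]
    n_mapped_between = sum(1 for gid, _ in between if gid in inv_mapped)
    n_unmapped_between = len(between) - n_mapped_between
    if n_mapped_between > 0 or n_unmapped_between > max_gap:
        return False, "distance"
    return True, ""


def build_synteny_blocks(
    order_x: GeneOrder,
    order_y: GeneOrder,
    homolog_map: dict[str, str],
    max_gap: int = 2,
) -> list[SyntenyBlock]:
    """Maximal collinear runs of homologs, same or reversed order."""
    y_idx = _y_index(order_y)
    inv_mapped = {
        homolog_map[g] for g in homolog_map if homolog_map[g] in y_idx
    }
    blocks = []
    for chrom, genes in order_x.items():
        run: list[int] = []
        adjacent = dict()
        mapped_pairs = list(_mapped_runs(genes, homolog_map, y_idx, max_gap))
        pair_ok = {}
        for a, b in mapped_pairs:
            ok, _ = _adjacency_intact(
                genes[a], genes[b], homolog_map, y_idx, inv_mapped, max_gap, order_y
            )
            pair_ok[(a, b)] = ok
        mapped = sorted({i for ab in mapped_pairs for i in ab}) or [
            i for i, (gid, _) in enumerate(genes)
            if gid in homolog_map and homolog_map[gid] in y_idx
        ]

        def flush(run):
            if not run:
                return
            first, last = run[0], run[-1]
            hy = [y_idx[homolog_map[genes[i][0]]] for i in run]
            yis = [t[1] for t in hy]
            orient = "+"
            if len(run) > 1 and yis[-1] < yis[0]:
                orient = "-"
            elif len(run) == 1:
                orient = "+" if hy[0][2] == genes[first][1] else "-"
            blocks.append(
                SyntenyBlock(
                    chrom_x=chrom, chrom_y=hy[0][0],
                    x_range=(first, last),
                    y_range=(min(yis), max(yis)),
                    orientation=orient, n_genes=len(run),
                )
            )

        prev = None
        for i in mapped:
            if prev is None:
                run = [i]
            elif pair_ok.get((prev, i), False):
                run.append(i)
            else:
                flush(run)
                run = [i]
            prev = i
        flush(run)
    return blocks


def count_breakpoints(
    order_x: GeneOrder,
    order_y: GeneOrder,
    homolog_map: dict[str, str],
    max_gap: int = 2,
) -> BreakpointSet:
    """Adjacencies in x whose homologs are not adjacent (or misoriented) in y.

    Chromosome ends are not adjacencies and never counted.
    """
    y_idx = _y_index(order_y)
    inv_mapped = {
        homolog_map[g] for g in homolog_map if homolog_map[g] in y_idx
    }
    bset = BreakpointSet()
    for chrom, genes in order_x.items():
        for a, b in _mapped_runs(genes, homolog_map, y_idx, max_gap):
            ok, reason = _adjacency_intact(
                genes[a], genes[b], homolog_map, y_idx, inv_mapped, max_gap, order_y
            )
            if not ok:
                bset.breakpoints.append(
                    Breakpoint(chrom, genes[a][0], genes[b][0], reason)
                )
    return bset


def estimate_events(b: int) -> int:
    """Rearrangement events from a breakpoint count: each reciprocal
    translocation or inversion creates two synteny breakpoints, so the
    estimate is b div 2.  An odd count triggers a warning."""
    if b < 0:
        raise HybridweaverError(f"negative breakpoint count {b}")
    if b % 2 == 1:
        warnings.warn(
            f"odd breakpoint count {b}: the 2-breakpoints-per-event rule "
            "assumes reciprocal events only", stacklevel=2,
        )
    return b // 2


# ------------------------------------------------------------------ LOH/BIR


@dataclass
class LohTract:
    chrom: str
    start_index: int  # gene index on the chromosome, inclusive
    end_index: int
    tract_class: str  # 'A' or 'B'
    background: str
    length: int  # in tract-class genes
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class RecombinationJunction:
    chrom: str
    left_index: int
    right_index: int
    left_gene: str
    right_gene: str
    left_label: str
    right_label: str


@dataclass
class BirFlag:
    chrom: str
    side: str  # 'L' or 'R'
    run_indices: tuple[int, int]
    label: str
    n_genes: int
    partner: tuple[str, str] | None  # (chrom, side)
    identity: float | None


_SAME_LABEL_PAIR = {"A": "A-in-A:A", "B": "B-in-B:B"}


def chromosome_background(track: CategoryTrack) -> str | None:
    """Majority label among A/B genes; ties go to A; None when no A/B gene."""
    n_a = sum(1 for lb in track.labels if lb == "A")
    n_b = sum(1 for lb in track.labels if lb == "B")
    if n_a + n_b == 0:
        return None
    return "A" if n_a >= n_b else "B"


def segment_loh_tracts(
    track: CategoryTrack,
    min_run: int = 3,
    exclude: set[int] | None = None,
) -> list[LohTract]:
    """Maximal runs of >= min_run same-label-pair genes of the opposite class.

    N genes are transparent (neither members nor breakers); any other A/B
    gene breaks a run.  Gene indices in ``exclude`` (e.g. BIR-flagged ends)
    are skipped as if they were N.
    """
    exclude = exclude or set()
    bg = chromosome_background(track)
    if bg is None:
        warnings.warn(f"chromosome {track.chrom} has no A/B genes; skipped")
        return []
    opp = "B" if bg == "A" else "A"
    member_cat = _SAME_LABEL_PAIR[opp]

    tracts = []
    run: list[int] = []

    def flush(run):
        if len(run) >= min_run:
            tracts.append(
                LohTract(
                    chrom=track.chrom, start_index=run[0], end_index=run[-1],
                    tract_class=opp, background=bg, length=len(run),
                    gene_ids=[track.gene_ids[i] for i in run],
                )
            )

    for i, (lb, cat) in enumerate(zip(track.labels, track.categories)):
        if lb == "N" or i in exclude:
            continue
        if cat == member_cat:
            run.append(i)
        else:
            flush(run)
            run = []
    flush(run)
    return tracts


def detect_recombination_junctions(
    track: CategoryTrack,
    min_run: int = 3,
    loh_tracts: list[LohTract] | None = None,
    exclude: set[int] | None = None,
) -> list[RecombinationJunction]:
    """Positions where the background label switches persistently.

    Genes inside called LOH tracts (and excluded indices) are removed first;
    N genes are transparent.  A junction requires >= min_run genes of each
    class on its two flanks.
    """
    skip = set(exclude or set())
    for t in loh_tracts or []:
        if t.chrom == track.chrom:
            skip.update(range(t.start_index, t.end_index + 1))
    eff = [
        (i, lb)
        for i, lb in enumerate(track.labels)
        if lb in "AB" and i not in skip
    ]
    if not eff:
        return []
    # run-length encode
    runs: list[tuple[str, list[int]]] = []
    for i, lb in eff:
        if runs and runs[-1][0] == lb:
            runs[-1][1].append(i)
        else:
            runs.append((lb, [i]))
    junctions = []
    for (lb1, idx1), (lb2, idx2) in zip(runs, runs[1:]):
        if len(idx1) >= min_run and len(idx2) >= min_run:
            li, ri = idx1[-1], idx2[0]
            junctions.append(
                RecombinationJunction(
                    chrom=track.chrom, left_index=li, right_index=ri,
                    left_gene=track.gene_ids[li], right_gene=track.gene_ids[ri],
                    left_label=lb1, right_label=lb2,
                )
            )
    return junctions


_BIR_CATS = {
    "A": {"A-unpaired", "A-in-A:A"},
    "B": {"B-unpaired", "B-in-B:B"},
}


def _terminal_run(track: CategoryTrack, side: str) -> tuple[int, int, str] | None:
    """Longest terminal run of same-label unpaired/same-label-pair genes."""
    n = len(track.gene_ids)
    order = range(n) if side == "L" else range(n - 1, -1, -1)
    label = None
    members: list[int] = []
    for i in order:
        lb, cat = track.labels[i], track.categories[i]
        if lb == "N":
            continue
        if label is None:
            if cat in _BIR_CATS.get(lb, ()):
                label = lb
                members.append(i)
                continue
            return None
        if lb == label and cat in _BIR_CATS[label]:
            members.append(i)
        else:
            break
    if not members:
        return None
    return min(members), max(members), label


def flag_bir_ends(
    tracks: list[CategoryTrack],
    genome: AnnotatedGenome,
    min_bir_genes: int = 3,
    id_min: float = 0.95,
) -> list[BirFlag]:
    """Chromosome ends homogenized by break-induced replication.

    Candidates are terminal runs of >= min_bir_genes same-label genes that
    are unpaired or in same-label pairs; the partner end is the other
    chromosome end (if any) whose terminal sequence over the run is at least
    ``id_min`` identical.  BIR copies one chromosome end onto another out to
    the telomere, so true events always have a (near-)identical partner.
    """
    chrom_map = genome.chrom_map
    candidates = []
    for track in tracks:
        for side in "LR":
            hit = _terminal_run(track, side)
            if hit is None:
                continue
            lo, hi, label = hit
            n_genes = sum(
                1 for i in range(lo, hi + 1) if track.labels[i] != "N"
            )
            if n_genes < min_bir_genes:
                continue
            chrom = chrom_map[track.chrom]
            genes = chrom.genes
            if side == "L":
                terminal_seq = chrom.seq[: genes[hi].end]
            else:
                terminal_seq = chrom.seq[genes[lo].start - 1 :]
            candidates.append((track.chrom, side, (lo, hi), label, n_genes, terminal_seq))

    def end_seq(cname: str, side: str, length: int) -> str:
        seq = chrom_map[cname].seq
        return seq[:length] if side == "L" else seq[-length:]

    flags = []
    for chrom, side, rng, label, n_genes, tseq in candidates:
        best = (None, 0.0)
        for other in genome.chromosomes:
            for oside in "LR":
                if other.name == chrom and oside == side:
                    continue
                if len(other.seq) < len(tseq):
                    continue
                oseq = end_seq(other.name, oside, len(tseq))
                if oside != side:
                    oseq = revcomp(oseq)
                res = edlib.align(tseq, oseq, task="distance")
                ident = 1.0 - res["editDistance"] / max(len(tseq), 1)
                if ident > best[1]:
                    best = ((other.name, oside), ident)
        partner, ident = best
        if partner is not None and ident >= id_min:
            flags.append(BirFlag(chrom, side, rng, label, n_genes, partner, ident))
        else:
            flags.append(BirFlag(chrom, side, rng, label, n_genes, None, ident or None))
    return flags


# ----------------------------------------------------------------- telomeres


@dataclass
class TelomereReport:
    unit: str | None  # majority unit, as found
    unit_canonical: str | None  # lexicographically minimal rotation
    n_ends_detected: int
    minority_units: list[str] = field(default_factory=list)


def min_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def chromosome_end_windows(genome: AnnotatedGenome, window: int = 300) -> list[str]:
    """Terminal windows oriented so the telomere reads toward the string end.

    Right ends are taken as-is; left ends are reverse-complemented, so one
    telomerase template unit appears in the same orientation at every end.
    """
    out = []
    for chrom in genome.chromosomes:
        out.append(revcomp(chrom.seq[:window]))
        out.append(chrom.seq[-window:])
    return out


def _detect_unit(window: str, max_unit: int = 30, min_copies: int = 3) -> str | None:
    """Smallest unit whose tandem copies cover the terminal part of window."""
    best: tuple[int, int, str] | None = None  # (coverage, -unit_len, unit)
    n = len(window)
    for L in range(1, min(max_unit, n // min_copies) + 1):
        unit = window[n - L :]
        copies = 1
        pos = n - L
        while pos - L >= 0 and window[pos - L : pos] == unit:
            copies += 1
            pos -= L
        if copies < min_copies:
            continue
        coverage = copies * L
        key = (coverage, -L, unit)
        if best is None or key > best:
            best = key
    return best[2] if best else None


def telomere_consensus(
    end_windows: list[str], max_unit: int = 30, min_copies: int = 3
) -> TelomereReport:
    """Most frequent rotation-normalized tandem repeat unit among end windows."""
    found: dict[str, list[str]] = {}
    for w in end_windows:
        u = _detect_unit(w, max_unit=max_unit, min_copies=min_copies)
        if u is None:
            continue
        found.setdefault(min_rotation(u), []).append(u)
    if not found:
        warnings.warn("no terminal tandem repeat detected at any end")
        return TelomereReport(None, None, 0)
    ranked = sorted(found.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    canon, examples = ranked[0]
    minority = [kv[1][0] for kv in ranked[1:]]
    return TelomereReport(
        unit=examples[0], unit_canonical=canon,
        n_ends_detected=sum(len(v) for v in found.values()),
        minority_units=minority,
    )
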