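"""Synthetic allopolyploid hybrid genomes with complete ground truth.

The generator follows the life-cycle model inferred for recently formed
interspecies yeast hybrids: two 8-chromosome parents diverge to a synonymous
divergence peak of Ks = 0.16 (~7% nucleotide divergence) and by ~17
reciprocal translocations/inversions; they mate to form a 16-chromosome
hybrid; after hybridization the genome accumulates loss-of-heterozygosity
(LOH) tracts, interhomeolog recombination, break-induced-replication (BIR)
homogenized chromosome ends, and sporadic disabling mutations; and the
B-subgenome MAT locus is cleaved by HO endonuclease and rejoined to an
A-subgenome intergenic site by NHEJ, creating a reciprocal translocation
with target-site duplications at the junction.

Every event is recorded in a truth table so that each downstream analysis
stage can be scored for recovery.  All randomness flows from a single seed;
the same seed yields byte-identical FASTA/GFF3 output.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .model import AnnotatedGenome, Chromosome, ConfigurationError, Gene, revcomp
from .ks import CODON_TABLE, SENSE_CODONS, STOP_CODONS, codon_sites, translate_cds
from .mat import HO_CORE

TELOMERE_UNIT = "TGTGGGTGGGG"

# ----------------------------------------------------------- configuration


@dataclass
class LohSpec:
    """One batch of LOH tracts: ``count`` tracts of ``length`` genes each;
    the donor is the A homeolog with probability ``p_donor_a`` (A overwrites
    B, yielding A:A pairs) and the B homeolog otherwise."""

    count: int = 8
    length: int = 8
    p_donor_a: float = 0.75


@dataclass
class MatSpec:
    """MAT/HML/HMR architecture: X and Z flanking repeats, idiomorph gene
    stubs (alpha1, alpha2, a2 -- deliberately no a1), and the NHEJ
    target-site-duplication lengths of the breakage junction."""

    x_repeat: str | None = None  # generated if None; length 654
    z_repeat: str | None = None  # generated if None; length 266, starts cgcagca
    x_len: int = 654
    z_len: int = 266
    tsd_left_len: int = 5
    tsd_right_len: int = 2
    breakage: bool = True
    alpha2_splice_break: bool = True  # AG->AC in intron 2 of the B copies

    def validate(self) -> None:
        if self.z_repeat is not None and not self.z_repeat.upper().startswith(HO_CORE):
            raise ConfigurationError("z_repeat must begin with the HO core cgcagca")
        if self.x_repeat is not None and len(self.x_repeat) < 200:
            raise ConfigurationError("x_repeat shorter than 200 nt")
        if self.tsd_left_len < 0 or self.tsd_right_len < 0:
            raise ConfigurationError("negative TSD length")


@dataclass
class SimConfig:
    n_chromosomes_per_parent: int = 8
    n_genes: int = 1000  # total per parent
    gene_len_codons: int = 500
    target_ks: float = 0.16
    omega: float = 0.05  # acceptance probability of nonsynonymous changes
    n_rearrangements: int = 17
    inversion_fraction: float = 0.5
    loh_tracts: list[LohSpec] = field(default_factory=lambda: [LohSpec()])
    n_recombinations: int = 2
    bir_ends: int = 3
    bir_genes: int = 6
    n_disablements_per_subgenome: int = 9
    mat_enabled: bool = True
    mat_spec: MatSpec = field(default_factory=MatSpec)
    spacer_len: int = 200
    telomere_unit: str = TELOMERE_UNIT
    telomere_copies: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes_per_parent < 1:
            raise ConfigurationError("need at least one chromosome")
        for name in (
            "n_genes", "gene_len_codons", "n_rearrangements", "n_recombinations",
            "bir_ends", "n_disablements_per_subgenome", "telomere_copies",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.target_ks < 0.75):
            raise ConfigurationError(
                f"target_ks {self.target_ks} outside [0, 0.75): beyond the "
                "Jukes-Cantor saturation limit"
            )
        if not (0.0 <= self.omega <= 1.0):
            raise ConfigurationError("omega must be a probability")
        if self.mat_enabled and self.n_chromosomes_per_parent < 3:
            raise ConfigurationError("MAT architecture needs >= 3 chromosomes per parent")
        self.mat_spec.validate()


# ----------------------------------------------------- internal genome units


@dataclass
class SeqUnit:
    kind: str  # 'telomere' | 'spacer' | 'repeat' | 'junction'
    seq: str


@dataclass
class GeneUnit:
    gene_id: str
    parts: list[tuple[str, str]]  # ('exon'|'intron', genomic-orientation seq)
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def genomic_seq(self) -> str:
        return "".join(s for _, s in self.parts)

    @property
    def cds(self) -> str:
        seq = "".join(s for kind, s in self.parts if kind == "exon")
        return revcomp(seq) if self.strand == "-" else seq

    def set_cds(self, cds: str) -> None:
        if len(self.parts) != 1:
            raise ConfigurationError(
                f"cannot rewrite CDS of multi-exon gene {self.gene_id}"
            )
        self.parts = [("exon", revcomp(cds) if self.strand == "-" else cds)]


@dataclass
class SimChrom:
    name: str
    units: list = field(default_factory=list)

    def gene_units(self) -> list[tuple[int, GeneUnit]]:
        return [(i, u) for i, u in enumerate(self.units) if isinstance(u, GeneUnit)]

    def gene_ids(self) -> list[str]:
        return [u.gene_id for _, u in self.gene_units()]

    def internal_gaps(self) -> list[tuple[int, str, str]]:
        """(spacer_unit_index, left_gene_id, right_gene_id) between genes."""
        gu = self.gene_units()
        gaps = []
        for (i1, g1), (i2, g2) in zip(gu, gu[1:]):
            for j in range(i1 + 1, i2):
                if isinstance(self.units[j], SeqUnit) and self.units[j].kind in (
                    "spacer", "junction",
                ):
                    gaps.append((j, g1.gene_id, g2.gene_id))
                    break
        return gaps


@dataclass
class SimGenome:
    name: str
    chroms: list[SimChrom] = field(default_factory=list)

    def chrom(self, name: str) -> SimChrom:
        for c in self.chroms:
            if c.name == name:
                return c
        raise KeyError(name)

    def gene_unit(self, gene_id: str) -> tuple[SimChrom, int, GeneUnit]:
        for c in self.chroms:
            for i, u in c.gene_units():
                if u.gene_id == gene_id:
                    return c, i, u
        raise KeyError(gene_id)

    def gene_orders(self) -> dict[str, list[str]]:
        return {c.name: c.gene_ids() for c in self.chroms}

    def assemble(self) -> AnnotatedGenome:
        chroms = []
        for sc in self.chroms:
            pos = 0
            seq_parts = []
            genes = []
            for u in sc.units:
                if isinstance(u, SeqUnit):
                    seq_parts.append(u.seq)
                    pos += len(u.seq)
                else:
                    exons = []
                    gstart = pos + 1
                    for kind, s in u.parts:
                        if kind == "exon":
                            exons.append((pos + 1, pos + len(s)))
                        seq_parts.append(s)
                        pos += len(s)
                    genes.append(
                        Gene(
                            gene_id=u.gene_id, chrom=sc.name, start=gstart,
                            end=pos, strand=u.strand, exons=exons,
                            attributes=dict(u.attributes),
                        )
                    )
            chroms.append(Chromosome(sc.name, "".join(seq_parts), genes))
        return AnnotatedGenome(name=self.name, chromosomes=chroms)


# --------------------------------------------------------------- truth table


@dataclass
class TruthTable:
    subgenome: dict[str, str] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    event_log: list[dict] = field(default_factory=list)
    loh_tracts: list[dict] = field(default_factory=list)
    recombination_junctions: list[dict] = field(default_factory=list)
    bir_ends: list[dict] = field(default_factory=list)
    disablements: list[dict] = field(default_factory=list)
    mat_loci: list[dict] = field(default_factory=list)
    mat_breakage: dict | None = None
    parent_orders: dict[str, list[str]] = field(default_factory=dict)

    def pair_partner(self) -> dict[str, str]:
        out = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out


# ------------------------------------------------------------ random helpers


def _rng_of(seed_or_rng) -> random.Random:
    if isinstance(seed_or_rng, random.Random):
        return seed_or_rng
    return random.Random(seed_or_rng)


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_cds(rng: random.Random, n_codons: int) -> str:
    body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 2))
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + body + stop


def _spacer(rng: random.Random, n: int) -> SeqUnit:
    return SeqUnit("spacer", _random_seq(rng, n))


# -------------------------------------------------------------- simulate_parent


def simulate_parent(config: SimConfig, seed=None) -> SimGenome:
    """Parent A: random genes with intergenic spacers and telomeric ends."""
    config.validate()
    rng = _rng_of(config.seed if seed is None else seed)
    n_chrom = config.n_chromosomes_per_parent
    per_chrom = [config.n_genes // n_chrom] * n_chrom
    for i in range(config.n_genes % n_chrom):
        per_chrom[i] += 1

    tel_r = config.telomere_unit.upper() * config.telomere_copies
    tel_l = revcomp(tel_r)
    genome = SimGenome(name="parentA")
    gid = 0
    for ci in range(n_chrom):
        units: list = [SeqUnit("telomere", tel_l)]
        for _ in range(per_chrom[ci]):
            units.append(_spacer(rng, config.spacer_len))
            strand = rng.choice("+-")
            cds = _random_cds(rng, config.gene_len_codons)
            units.append(
                GeneUnit(
                    gene_id=f"g{gid:04d}",
                    # parts hold genomic-orientation sequence
                    parts=[("exon", revcomp(cds) if strand == "-" else cds)],
                    strand=strand,
                )
            )
            gid += 1
        units.append(_spacer(rng, config.spacer_len))
        units.append(SeqUnit("telomere", tel_r))
        genome.chroms.append(SimChrom(name=f"chr{ci + 1}", units=units))
    return genome


# ---------------------------------------------------------- evolve_divergence


def _classify_change(codon: str, pos: int, base: str) -> str:
    alt = codon[:pos] + base + codon[pos + 1 :]
    if alt in STOP_CODONS:
        return "stop"
    return "syn" if CODON_TABLE[alt] == CODON_TABLE[codon] else "nonsyn"


def evolve_divergence(
    parent: SimGenome, target_ks: float, omega: float, seed=0
) -> SimGenome:
    """Derive parent B by codon-wise substitution until the expected
    synonymous divergence per gene reaches ``target_ks``.

    Single-nucleotide changes are proposed at uniform positions; synonymous
    changes are accepted freely, nonsynonymous with probability ``omega``,
    and changes creating stop codons are rejected.  The per-gene number of
    accepted synonymous events is round(target_ks * S), with S the gene's
    synonymous site count, so the realized divergence (events per synonymous
    site) equals the target and the Jukes-Cantor-corrected estimate recovers
    it.  Gene order is unchanged.
    """
    if not (0.0 <= target_ks < 0.75):
        raise ConfigurationError(
            f"target_ks {target_ks} at or beyond Jukes-Cantor saturation (0.75)"
        )
    rng = _rng_of(seed)
    out = copy.deepcopy(parent)
    out.name = "parentB"
    for chrom in out.chroms:
        for _, gu in chrom.gene_units():
            cds = list(gu.cds)
            n_codons = len(cds) // 3
            if n_codons < 3 or target_ks == 0.0:
                continue
            codons = ["".join(cds[3 * i : 3 * i + 3]) for i in range(n_codons)]
            S = sum(codon_sites(c)[0] for c in codons[:-1] if c not in STOP_CODONS)
            m_target = round(target_ks * S)
            accepted_syn = 0
            # mutable range: codons 1 .. n-2 (start and stop codons fixed)
            lo, hi = 3, 3 * (n_codons - 1)
            while accepted_syn < m_target:
                p = rng.randrange(lo, hi)
                ci, off = divmod(p, 3)
                codon = "".join(cds[3 * ci : 3 * ci + 3])
                base = rng.choice("ACGT")
                if base == codon[off]:
                    continue
                kind = _classify_change(codon, off, base)
                if kind == "stop":
                    continue
                if kind == "syn":
                    cds[p] = base
                    accepted_syn += 1
                elif rng.random() < omega:
                    cds[p] = base
            gu.set_cds("".join(cds))
    return out


# -------------------------------------------------------- apply_rearrangements


def _invert_units(units: list) -> list:
    """Reverse a unit segment in place on the genome: order, strands, sequence."""
    out = []
    for u in reversed(units):
        if isinstance(u, SeqUnit):
            out.append(SeqUnit(u.kind, revcomp(u.seq)))
        else:
            parts = [(k, revcomp(s)) for k, s in reversed(u.parts)]
            strand = "-" if u.strand == "+" else "+"
            out.append(GeneUnit(u.gene_id, parts, strand, dict(u.attributes)))
    return out


def apply_rearrangements(
    genome: SimGenome,
    n_events: int,
    inversion_fraction: float = 0.5,
    seed=0,
    max_retries: int = 200,
) -> tuple[SimGenome, list[dict]]:
    """Inversions and reciprocal translocations at intergenic breakpoints.

    Each event consumes two distinct, previously intact gene adjacencies of
    the input genome and never re-creates a broken one, so the downstream
    synteny-breakpoint count against the input order is exactly 2 * n_events.
    """
    rng = _rng_of(seed)
    out = copy.deepcopy(genome)
    original = set()
    for chrom in out.chroms:
        ids = chrom.gene_ids()
        for a, b in zip(ids, ids[1:]):
            original.add(frozenset((a, b)))
    broken: set[frozenset] = set()
    log: list[dict] = []

    def eligible_gaps(chrom: SimChrom):
        return [
            (j, l, r)
            for j, l, r in chrom.internal_gaps()
            if frozenset((l, r)) in original and frozenset((l, r)) not in broken
        ]

    events_done = 0
    attempts = 0
    while events_done < n_events:
        attempts += 1
        if attempts > max_retries * max(n_events, 1):
            raise ConfigurationError(
                "could not place rearrangement breakpoints without reuse"
            )
        make_inversion = rng.random() < inversion_fraction
        if make_inversion:
            chrom = rng.choice(out.chroms)
            gaps = eligible_gaps(chrom)
            if len(gaps) < 2:
                continue
            (j1, l1, r1), (j2, l2, r2) = sorted(rng.sample(gaps, 2))
            if j1 == j2:
                continue
            segment = chrom.units[j1 + 1 : j2]
            seg_genes = [u for u in segment if isinstance(u, GeneUnit)]
            if not seg_genes:
                continue
            new_adj = [frozenset((l1, seg_genes[-1].gene_id)),
                       frozenset((seg_genes[0].gene_id, r2))]
            if any(a in original for a in new_adj):
                continue
            chrom.units[j1 + 1 : j2] = _invert_units(segment)
            broken.update((frozenset((l1, r1)), frozenset((l2, r2))))
            log.append(
                {
                    "type": "inversion", "chrom": chrom.name,
                    "seg_first_gene": seg_genes[0].gene_id,
                    "seg_last_gene": seg_genes[-1].gene_id,
                }
            )
            events_done += 1
        else:
            if len(out.chroms) < 2:
                continue
            c1, c2 = rng.sample(out.chroms, 2)
            gaps1, gaps2 = eligible_gaps(c1), eligible_gaps(c2)
            if not gaps1 or not gaps2:
                continue
            j1, l1, r1 = rng.choice(gaps1)
            j2, l2, r2 = rng.choice(gaps2)
            new_adj = [frozenset((l1, r2)), frozenset((l2, r1))]
            if any(a in original for a in new_adj):
                continue
            tail1, tail2 = c1.units[j1:], c2.units[j2:]
            c1.units = c1.units[:j1] + tail2
            c2.units = c2.units[:j2] + tail1
            broken.update((frozenset((l1, r1)), frozenset((l2, r2))))
            log.append(
                {
                    "type": "translocation", "chrom1": c1.name, "chrom2": c2.name,
                    "tail1_first_gene": r2, "tail2_first_gene": r1,
                }
            )
            events_done += 1
    return out, log


# -------------------------------------------------------------------- hybridize


def hybridize(
    parent_a: SimGenome, parent_b: SimGenome, rename: bool = True
) -> tuple[SimGenome, TruthTable]:
    """Union of the two parental chromosome sets; gene ids get _A/_B suffixes."""
    pa, pb = copy.deepcopy(parent_a), copy.deepcopy(parent_b)
    truth = TruthTable()
    truth.parent_orders = {c.name: c.gene_ids() for c in parent_a.chroms}

    hybrid = SimGenome(name="hybrid")
    base_ids: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    for sub, parent in (("A", pa), ("B", pb)):
        for i, chrom in enumerate(parent.chroms):
            new_name = f"chr{sub}{i + 1}" if rename else chrom.name
            if any(c.name == new_name for c in hybrid.chroms):
                raise ConfigurationError(f"duplicate chromosome name {new_name}")
            chrom.name = new_name
            for _, gu in chrom.gene_units():
                base = gu.gene_id
                gu.gene_id = f"{base}_{sub}"
                base_ids[sub][base] = gu.gene_id
                truth.subgenome[gu.gene_id] = sub
            hybrid.chroms.append(chrom)
    for base, aid in base_ids["A"].items():
        bid = base_ids["B"].get(base)
        if bid:
            truth.pairs.append((aid, bid))
            truth.category[aid] = "A-in-A:B"
            truth.category[bid] = "B-in-A:B"
    for sub in ("A", "B"):
        for gid in base_ids[sub].values():
            truth.category.setdefault(gid, f"{sub}-unpaired")
    truth.event_log.append({"type": "hybridize"})
    return hybrid, truth


# -------------------------------------------------------- posthybridization


def _partner_id(gene_id: str) -> str:
    if gene_id.endswith("_A"):
        return gene_id[:-2] + "_B"
    if gene_id.endswith("_B"):
        return gene_id[:-2] + "_A"
    raise KeyError(gene_id)


def _reserved_chrom_names(config: SimConfig) -> set[str]:
    """Chromosomes kept free of random events for the MAT architecture.

    HML, MAT and HMR all sit on the last chromosome of each subgenome
    (left arm / centre / right arm, the classic budding-yeast layout); one
    A-subgenome chromosome additionally hosts the breakage-junction target.
    """
    if not config.mat_enabled:
        return set()
    n = config.n_chromosomes_per_parent
    junction_num = 1 if n == 3 else 2
    return {f"chrA{n}", f"chrB{n}", f"chrA{junction_num}"}


def gene_chrom_map(genome: SimGenome) -> dict[str, str]:
    out = {}
    for c in genome.chroms:
        for gid in c.gene_ids():
            out[gid] = c.name
    return out


def apply_posthyb_events(
    hybrid: SimGenome, truth: TruthTable, config: SimConfig, seed=0
) -> None:
    """LOH tracts, interhomeolog recombination, BIR ends, disablements.

    Events are applied in that fixed order.  Chromosome numbers for the
    recombination crossovers are drawn up front so that LOH tracts and BIR
    ends stay off chromosomes whose content a later tail swap would move
    (each planted event must remain individually recoverable against its
    recorded chromosome).  LOH tracts keep a margin of ``bir_genes + 2``
    genes from the chromosome ends so they can never collide with a BIR end.
    The truth table is updated in place.
    """
    rng = _rng_of(seed)
    reserved = _reserved_chrom_names(config)
    touched_chroms: set[str] = set()
    touched_genes: set[str] = set()
    partner = truth.pair_partner()

    def eligible(c: SimChrom) -> bool:
        return c.name not in reserved and c.name not in touched_chroms

    end_margin = config.bir_genes + 2

    # ---- 1. LOH tracts ------------------------------------------------
    for spec in config.loh_tracts:
        for _ in range(spec.count):
            donor = "A" if rng.random() < spec.p_donor_a else "B"
            recipient_sub = "B" if donor == "A" else "A"
            placed = False
            for _try in range(300):
                cands = [
                    c for c in hybrid.chroms
                    if c.name.startswith(f"chr{recipient_sub}") and eligible(c)
                ]
                if not cands:
                    break
                chrom = rng.choice(cands)
                ids = chrom.gene_ids()
                if len(ids) < spec.length + 2 * end_margin:
                    continue
                start = rng.randrange(end_margin, len(ids) - spec.length - end_margin)
                tract_ids = ids[start : start + spec.length]
                if any(g in touched_genes for g in tract_ids):
                    continue
                if any(
                    partner.get(g) is None
                    or truth.category.get(g) != f"{recipient_sub}-in-A:B"
                    for g in tract_ids
                ):
                    continue
                for g in tract_ids:
                    p = partner[g]
                    _, _, gu = hybrid.gene_unit(g)
                    _, _, pu = hybrid.gene_unit(p)
                    gu.set_cds(pu.cds)
                    truth.subgenome[g] = donor
                    truth.category[g] = f"{donor}-in-{donor}:{donor}"
                    truth.category[p] = f"{donor}-in-{donor}:{donor}"
                    touched_genes.add(g)
                    touched_genes.add(p)
                truth.loh_tracts.append(
                    {
                        "chrom": chrom.name, "gene_ids": tract_ids,
                        "donor": donor, "length": spec.length,
                    }
                )
                truth.event_log.append(
                    {"type": "loh", "chrom": chrom.name, "gene_ids": tract_ids}
                )
                placed = True
                break
            if not placed:
                raise ConfigurationError("could not place an LOH tract")

    # ---- 2. interhomeolog recombination --------------------------------
    # a crossover joins an A chromosome to the B chromosome carrying the
    # homeologs of its flanking genes (not necessarily the same-numbered
    # chromosome after the prehybridization rearrangements)
    placed_recomb = 0
    for _try in range(600):
        if placed_recomb >= config.n_recombinations:
            break
        cands_a = [
            c for c in hybrid.chroms if c.name.startswith("chrA") and eligible(c)
        ]
        if not cands_a:
            break
        ca = rng.choice(cands_a)
        gaps = ca.internal_gaps()
        if len(gaps) < 5:
            continue
        j, l, r = gaps[rng.randrange(2, len(gaps) - 2)]
        try:
            bl, br = _partner_id(l), _partner_id(r)
        except KeyError:
            continue
        if any(g in touched_genes for g in (l, r, bl, br)):
            continue
        cb = bj = None
        for cb_cand in hybrid.chroms:
            if not cb_cand.name.startswith("chrB") or not eligible(cb_cand):
                continue
            for gj, gl, gr in cb_cand.internal_gaps():
                if (gl, gr) == (bl, br):
                    cb, bj = cb_cand, gj
                    break
            if cb is not None:
                break
        if cb is None:
            continue
        tail_a, tail_b = ca.units[j:], cb.units[bj:]
        moved_to_b = {u.gene_id for u in tail_a if isinstance(u, GeneUnit)}
        moved_to_a = {u.gene_id for u in tail_b if isinstance(u, GeneUnit)}
        # an LOH tract is only recoverable while its chromosome's majority
        # label differs from the tract class; redraw if a product would
        # swallow one of its tracts
        prod_a = [g for g in ca.gene_ids() if g not in moved_to_b] + sorted(moved_to_a)
        prod_b = [g for g in cb.gene_ids() if g not in moved_to_a] + sorted(moved_to_b)
        ok = True
        for prod in (prod_a, prod_b):
            labels = [truth.subgenome.get(g) for g in prod]
            n_a = labels.count("A")
            n_b = labels.count("B")
            majority = "A" if n_a >= n_b else "B"
            gene_set = set(prod)
            for tract in truth.loh_tracts:
                if set(tract["gene_ids"]) <= gene_set and tract["donor"] == majority:
                    ok = False
        if not ok:
            continue
        ca.units = ca.units[:j] + tail_b
        cb.units = cb.units[:bj] + tail_a
        # LOH tracts that rode along on a moved tail change chromosome
        # (a crossover never splits a tract: its flanks would be touched)
        for tract in truth.loh_tracts:
            if tract["gene_ids"][0] in moved_to_b:
                tract["chrom"] = cb.name
            elif tract["gene_ids"][0] in moved_to_a:
                tract["chrom"] = ca.name
        touched_chroms.update((ca.name, cb.name))
        for chrom_name, lg, rg in ((ca.name, l, br), (cb.name, bl, r)):
            truth.recombination_junctions.append(
                {"chrom": chrom_name, "left_gene": lg, "right_gene": rg,
                 "kind": "crossover"}
            )
        truth.event_log.append(
            {
                "type": "recombination", "chrom1": ca.name, "chrom2": cb.name,
                "tail1_first_gene": br, "tail2_first_gene": r,
            }
        )
        placed_recomb += 1
    if placed_recomb < config.n_recombinations:
        raise ConfigurationError("could not place a recombination event")

    # ---- 3. BIR chromosome ends ----------------------------------------
    donor_ends = [
        (c, side)
        for c in hybrid.chroms
        if c.name.startswith("chrA")
        for side in "LR"
    ]
    rng.shuffle(donor_ends)
    done = 0
    for donor_chrom, side in donor_ends:
        if done >= config.bir_ends:
            break
        # a donor chromosome may serve from both ends (copying does not
        # modify it); only recipients and recombination chromosomes are out
        if donor_chrom.name in reserved or donor_chrom.name in touched_chroms:
            continue
        ids = donor_chrom.gene_ids()
        k = config.bir_genes
        if len(ids) < k + 4:
            continue
        donor_ids = ids[:k] if side == "L" else ids[-k:]
        if any(g in touched_genes for g in donor_ids):
            continue
        try:
            b_ids = [_partner_id(g) for g in donor_ids]
        except KeyError:
            continue
        if any(b not in truth.subgenome for b in b_ids):
            continue
        # the recipient is the end carrying the homeologs of the donor-end
        # genes; their internal order is irrelevant since the whole terminal
        # segment is overwritten
        recip_chrom = None
        recip_side = None
        b_set = set(b_ids)
        for cb in hybrid.chroms:
            if not cb.name.startswith("chrB") or not eligible(cb):
                continue
            cids = cb.gene_ids()
            if len(cids) < k + 4:
                continue
            if set(cids[:k]) == b_set:
                recip_chrom, recip_side = cb, "L"
                break
            if set(cids[-k:]) == b_set:
                recip_chrom, recip_side = cb, "R"
                break
        if recip_chrom is None or any(g in touched_genes for g in b_ids):
            continue

        gu_idx = [i for i, _ in donor_chrom.gene_units()]
        if side == "L":
            donor_units = donor_chrom.units[: gu_idx[k - 1] + 1]
        else:
            donor_units = donor_chrom.units[gu_idx[-k] - 1 :]
        copied = copy.deepcopy(donor_units)
        copy_ids = []
        for u in copied:
            if isinstance(u, GeneUnit):
                base, sub = u.gene_id[:-2], u.gene_id[-1]
                u.gene_id = f"{base}c_{sub}"
                copy_ids.append(u.gene_id)

        r_gu_idx = [i for i, _ in recip_chrom.gene_units()]
        if recip_side == "L":
            recip_cutoff = r_gu_idx[k - 1] + 1
            deleted = [
                u.gene_id for u in recip_chrom.units[:recip_cutoff]
                if isinstance(u, GeneUnit)
            ]
            new_end = copied if side == "L" else _invert_units(copied)
            recip_chrom.units = new_end + recip_chrom.units[recip_cutoff:]
        else:
            recip_cutoff = r_gu_idx[-k] - 1
            deleted = [
                u.gene_id for u in recip_chrom.units[recip_cutoff:]
                if isinstance(u, GeneUnit)
            ]
            new_end = copied if side == "R" else _invert_units(copied)
            recip_chrom.units = recip_chrom.units[:recip_cutoff] + new_end

        # truth bookkeeping: recipient genes are gone; donor genes now pair
        # with their identical copies as A:A
        for b in deleted:
            truth.subgenome.pop(b, None)
            truth.category.pop(b, None)
        truth.pairs = [
            (x, y) for x, y in truth.pairs if x not in deleted and y not in deleted
        ]
        for orig, cp in zip(donor_ids, copy_ids):
            truth.subgenome[cp] = "A"
            truth.category[orig] = "A-in-A:A"
            truth.category[cp] = "A-in-A:A"
            truth.pairs.append((orig, cp))
            touched_genes.add(orig)
            touched_genes.add(cp)
        partner = truth.pair_partner()
        touched_chroms.add(recip_chrom.name)
        truth.bir_ends.append(
            {
                "donor_chrom": donor_chrom.name, "donor_side": side,
                "recipient_chrom": recip_chrom.name, "recipient_side": recip_side,
                "donor_gene_ids": donor_ids, "copy_gene_ids": copy_ids,
                "n_genes": k,
            }
        )
        truth.event_log.append(
            {
                "type": "bir", "recipient_chrom": recip_chrom.name,
                "recipient_side": recip_side, "deleted_gene_ids": deleted,
                "copy_gene_ids": copy_ids if side == recip_side else list(reversed(copy_ids)),
            }
        )
        done += 1
    if done < config.bir_ends:
        raise ConfigurationError("could not place BIR events")

    # ---- 4. disablements ------------------------------------------------
    _plant_disablements(
        hybrid, truth, config.n_disablements_per_subgenome, rng,
        touched_genes, reserved,
    )


def _disable_gene(gu: GeneUnit, mechanism: str, rng: random.Random) -> int:
    """Introduce a premature stop or 1-bp indel; returns the codon position."""
    cds = gu.cds
    n = len(cds) // 3
    if mechanism == "premature-stop":
        ci = rng.randrange(max(1, int(0.3 * n)), max(2, int(0.55 * n)))
        new = cds[: 3 * ci] + "TAA" + cds[3 * ci + 3 :]
        gu.set_cds(new)
        return ci
    for _ in range(30):
        ci = rng.randrange(max(1, int(0.3 * n)), max(2, int(0.5 * n)))
        p = 3 * ci + rng.randrange(3)
        if rng.random() < 0.5:
            new = cds[:p] + cds[p + 1 :]  # 1-bp deletion
        else:
            new = cds[:p] + rng.choice("ACGT") + cds[p:]  # 1-bp insertion
        prot = translate_cds(new, pseudogene=True)
        full = translate_cds(cds, pseudogene=True)
        if full and len(prot) / len(full) < 0.85:
            gu.set_cds(new)
            return ci
    raise ConfigurationError("could not plant an effective frameshift")


def _plant_disablements(
    hybrid: SimGenome, truth: TruthTable, n_per_subgenome: int,
    rng: random.Random, touched_genes: set[str], reserved: set[str],
) -> None:
    partner = truth.pair_partner()
    chrom_of = gene_chrom_map(hybrid)
    for sub in ("A", "B"):
        eligible_ids = [
            g
            for g in sorted(truth.subgenome)
            if truth.subgenome[g] == sub
            and truth.category.get(g) == f"{sub}-in-A:B"
            and g not in touched_genes
            and partner.get(g) is not None
            and chrom_of.get(g) not in reserved
        ]
        if len(eligible_ids) < n_per_subgenome:
            raise ConfigurationError("not enough genes to disable")
        chosen = rng.sample(eligible_ids, n_per_subgenome)
        for i, g in enumerate(sorted(chosen)):
            mechanism = "premature-stop" if i % 2 == 0 else "frameshift-indel"
            _, _, gu = hybrid.gene_unit(g)
            ci = _disable_gene(gu, mechanism, rng)
            touched_genes.add(g)
            touched_genes.add(partner[g])
            truth.disablements.append(
                {
                    "gene_id": g, "partner_id": partner[g],
                    "mechanism": mechanism, "codon": ci, "subgenome": sub,
                }
            )
            truth.event_log.append({"type": "disablement", "gene_id": g})


# ------------------------------------------------------------ MAT architecture


def _generate_repeats(spec: MatSpec, rng: random.Random) -> tuple[str, str]:
    x = spec.x_repeat.upper() if spec.x_repeat else None
    z = spec.z_repeat.upper() if spec.z_repeat else None
    while x is None or HO_CORE in x[:40]:
        x = _random_seq(rng, spec.x_len)
    if z is None:
        z = HO_CORE + _random_seq(rng, spec.z_len - len(HO_CORE))
    return x, z


def _build_alpha2(rng: random.Random, broken: bool) -> GeneUnit:
    """MATalpha2 stub: 211 aa when spliced; the broken form carries an
    AG->AC acceptor mutation in intron 2 whose nearest downstream AG lies
    2 nt away, frameshifting the protein down to 57 aa."""
    exon1 = "ATG" + "".join(rng.choice(SENSE_CODONS) for _ in range(29))  # 90 nt
    # exon2: 81 nt completing 57 codons of upstream sequence
    exon2 = "".join(rng.choice(SENSE_CODONS) for _ in range(27))
    # exon3: 465 nt = 154 codons + stop; starts with the cryptic acceptor AG
    # followed by T, so the 2-nt-shifted frame opens directly on a TAA stop
    # (AGT AAC ... in frame 0; [AG]|TAA... after the shift)
    body = "".join(rng.choice(SENSE_CODONS) for _ in range(152))
    exon3 = "AGT" + "AAC" + body + "TAA"
    assert len(exon3) == 465 and exon3[:5] == "AGTAA"

    def intron(n: int) -> str:
        mid = _random_seq(rng, n - 4)
        # canonical GT ... AG; interior free of AG right before the acceptor
        return "GT" + mid + "AG"

    i1 = intron(45)
    i2 = intron(52)
    # ensure the 2 nt after the true acceptor are not themselves preceded by
    # an accidental AG inside the intron tail
    i2 = i2[:-4] + "TTAG"
    if broken:
        i2 = i2[:-2] + "AC"
    parts = [
        ("exon", exon1), ("intron", i1),
        ("exon", exon2), ("intron", i2),
        ("exon", exon3),
    ]
    return GeneUnit("alpha2", parts, "+", {})


def _cassette_units(
    kind: str, sub: str, idiomorph: str, x: str, z: str,
    stubs: dict[str, str], rng: random.Random, alpha2_broken: bool,
) -> tuple[list, list[str]]:
    units: list = [_spacer(rng, 120)]
    units.append(SeqUnit("repeat", x))
    gene_ids = []

    def add_gene(name: str, cds: str | None = None, alpha2: bool = False):
        units.append(_spacer(rng, 80))
        gid = f"{kind}{name}_{sub}"
        if alpha2:
            gu = _build_alpha2(random.Random(rng.randrange(2**31)), alpha2_broken)
            gu.gene_id = gid
        else:
            gu = GeneUnit(gid, [("exon", cds)], "+")
        gu.attributes = {"Name": f"{kind}{name}"}
        units.append(gu)
        gene_ids.append(gid)

    if idiomorph == "alpha":
        add_gene("alpha1", stubs["alpha1"])
        add_gene("alpha2", alpha2=True)
    else:
        add_gene("a2", stubs["a2"])
    pre_z = _spacer(rng, 80)
    pre_z.seq = pre_z.seq[:-2] + "TT"  # junction disambiguation boundary
    units.append(pre_z)
    units.append(SeqUnit("repeat", z))
    units.append(_spacer(rng, 120))
    return units, gene_ids


def build_mat_architecture_and_breakage(
    hybrid: SimGenome, truth: TruthTable, spec: MatSpec, config: SimConfig, seed=0
) -> None:
    """Insert MAT/HML/HMR per subgenome; cleave and translocate the B MAT.

    The B-subgenome MAT locus is cut by HO at the Z boundary and joined by
    NHEJ to an intergenic site of the A-subgenome, creating a reciprocal
    translocation; the junction on the A-side product carries a
    ``tsd_left_len``-bp duplication of the A flank (sequence acaac) and a
    ``tsd_right_len``-bp duplication of the Z start, with no microhomology.
    """
    spec.validate()
    rng = _rng_of(seed)
    n = config.n_chromosomes_per_parent
    if n < 3:
        raise ConfigurationError("MAT architecture needs >= 3 chromosomes")
    x, z = _generate_repeats(spec, rng)
    stubs = {
        "alpha1": _random_cds(rng, 150),
        "a2": _random_cds(rng, 120),
    }
    mat_num = n
    junction_num = 1 if n == 3 else 2

    def insert_cassette(chrom: SimChrom, gap_index: int, kind: str, sub: str,
                        idiomorph: str) -> list[str]:
        broken_alpha2 = spec.alpha2_splice_break and sub == "B" and idiomorph == "alpha"
        units, gene_ids = _cassette_units(
            kind, sub, idiomorph, x, z, stubs, rng, broken_alpha2
        )
        gaps = chrom.internal_gaps()
        j, lgene, _ = gaps[gap_index]
        chrom.units[j + 1 : j + 1] = units
        for gid in gene_ids:
            truth.subgenome[gid] = "N"  # no reference homolog: class N
            truth.category[gid] = "N"
        truth.mat_loci.append(
            {
                "kind": kind, "idiomorph": idiomorph, "subgenome": sub,
                "chrom": chrom.name, "gene_ids": gene_ids, "intact": True,
            }
        )
        truth.event_log.append(
            {"type": "insert_genes", "chrom": chrom.name,
             "after_gene": lgene, "gene_ids": gene_ids}
        )
        return gene_ids

    for sub in ("A", "B"):
        mat_chrom = hybrid.chrom(f"chr{sub}{mat_num}")
        n_gaps = len(mat_chrom.internal_gaps())
        insert_cassette(mat_chrom, min(4, n_gaps - 1), "HML", sub, "alpha")
        insert_cassette(mat_chrom, len(mat_chrom.internal_gaps()) // 2, "MAT",
                        sub, "alpha")
        insert_cassette(mat_chrom, max(0, len(mat_chrom.internal_gaps()) - 5),
                        "HMR", sub, "a")

    if not spec.breakage:
        return

    # ---- HO cleavage of the B MAT and NHEJ translocation ----------------
    b_mat = hybrid.chrom(f"chrB{mat_num}")
    a_target = hybrid.chrom(f"chrA{junction_num}")

    # engineer the A-side cut: a mid-chromosome spacer ending ...TT ACAAC
    gaps = a_target.internal_gaps()
    j, a_left_gene, a_right_gene = gaps[len(gaps) // 2]
    sp: SeqUnit = a_target.units[j]
    half = len(sp.seq) // 2
    dup_l = "ACAAC"[: spec.tsd_left_len] or ""
    if spec.tsd_left_len > 5:
        dup_l = "ACAAC" + _random_seq(rng, spec.tsd_left_len - 5)
    left_spacer = SeqUnit("spacer", sp.seq[:half] + "TT" + dup_l)
    right_seq = sp.seq[half:]
    right_spacer = SeqUnit("spacer", "G" + right_seq[1:])
    a_cut_unit = j  # cut falls between left_spacer and right_spacer
    a_target.units[j : j + 1] = [left_spacer, right_spacer]

    # find the Z unit belonging to the B MAT cassette (HML also carries a Z,
    # upstream): the first Z repeat after the MATalpha genes
    mat_alpha_idx = max(
        i for i, u in b_mat.gene_units() if u.gene_id.startswith("MATalpha")
    )
    z_idx = None
    for i, u in enumerate(b_mat.units):
        if (
            i > mat_alpha_idx
            and isinstance(u, SeqUnit)
            and u.kind == "repeat"
            and u.seq.startswith(HO_CORE)
        ):
            z_idx = i
            break
    if z_idx is None:
        raise ConfigurationError("B MAT Z repeat not found")
    dup_r = z[: spec.tsd_right_len]

    b_genes = b_mat.gene_ids()
    z_right_genes = [
        u.gene_id for i, u in b_mat.gene_units() if i > z_idx
    ]
    b_left_gene = [u.gene_id for i, u in b_mat.gene_units() if i < z_idx][-1]
    b_right_gene = z_right_genes[0]

    old_a_seq = "".join(
        u.seq if isinstance(u, SeqUnit) else u.genomic_seq for u in a_target.units
    )
    old_b_seq = "".join(
        u.seq if isinstance(u, SeqUnit) else u.genomic_seq for u in b_mat.units
    )
    a_cut_offset = sum(
        len(u.seq) if isinstance(u, SeqUnit) else len(u.genomic_seq)
        for u in a_target.units[: a_cut_unit + 1]
    )
    b_cut_offset = sum(
        len(u.seq) if isinstance(u, SeqUnit) else len(u.genomic_seq)
        for u in b_mat.units[:z_idx]
    )

    junction_unit = SeqUnit("junction", dup_l + dup_r)
    a_head = a_target.units[: a_cut_unit + 1]
    a_tail = a_target.units[a_cut_unit + 1 :]
    b_head = b_mat.units[:z_idx]
    b_tail = b_mat.units[z_idx:]
    a_target.units = a_head + [junction_unit] + b_tail
    b_mat.units = b_head + a_tail

    jw = (
        old_a_seq[a_cut_offset - 30 : a_cut_offset]
        + dup_l + dup_r
        + old_b_seq[b_cut_offset : b_cut_offset + 30]
    )
    truth.mat_breakage = {
        "cut_chrom": b_mat.name, "target_chrom": a_target.name,
        "tsd_left": len(dup_l), "tsd_right": len(dup_r), "microhomology": 0,
        "junction_window": jw,
        "donor_left_window": old_a_seq[a_cut_offset - 30 : a_cut_offset + 10],
        "donor_right_window": old_b_seq[b_cut_offset - 10 : b_cut_offset + 30],
        "junction1": {"chrom": a_target.name, "left_gene": a_left_gene,
                      "right_gene": b_right_gene},
        "junction2": {"chrom": b_mat.name, "left_gene": b_left_gene,
                      "right_gene": a_right_gene},
    }
    for jn in (truth.mat_breakage["junction1"], truth.mat_breakage["junction2"]):
        truth.recombination_junctions.append({**jn, "kind": "mat_translocation"})
    # the B MAT locus is now broken in two
    for locus in truth.mat_loci:
        if locus["kind"] == "MAT" and locus["subgenome"] == "B":
            locus["intact"] = False
    truth.event_log.append(
        {
            "type": "mat_translocation", "chrom1": a_target.name,
            "chrom2": b_mat.name, "tail1_first_gene": b_right_gene,
            "tail2_first_gene": a_right_gene,
        }
    )


# ------------------------------------------------------------------- replay


def replay_event_log(
    parent_orders: dict[str, list[str]], event_log: list[dict]
) -> dict[str, list[str]]:
    """Re-derive the hybrid gene order from parent orders and the event log."""
    orders_b = {c: list(ids) for c, ids in parent_orders.items()}

    def tail_swap(orders: dict, c1: str, c2: str, new_first1: str, new_first2: str):
        """Swap tails so c1's new tail starts with new_first1 (now on c2)."""
        i1 = orders[c1].index(new_first2)  # start of the tail leaving c1
        i2 = orders[c2].index(new_first1)  # start of the tail leaving c2
        t1, t2 = orders[c1][i1:], orders[c2][i2:]
        orders[c1] = orders[c1][:i1] + t2
        orders[c2] = orders[c2][:i2] + t1

    def natural_key(name: str):
        import re as _re

        m = _re.search(r"(\d+)$", name)
        return (name[: m.start()] if m else name, int(m.group(1)) if m else 0)

    hybrid_orders: dict[str, list[str]] | None = None
    for e in event_log:
        t = e["type"]
        if hybrid_orders is None:
            if t == "inversion":
                o = orders_b[e["chrom"]]
                i = o.index(e["seg_first_gene"])
                jj = o.index(e["seg_last_gene"])
                o[i : jj + 1] = reversed(o[i : jj + 1])
            elif t == "translocation":
                tail_swap(
                    orders_b, e["chrom1"], e["chrom2"],
                    e["tail1_first_gene"], e["tail2_first_gene"],
                )
            elif t == "hybridize":
                hybrid_orders = {}
                names = sorted(parent_orders, key=natural_key)
                for i, cname in enumerate(names):
                    hybrid_orders[f"chrA{i + 1}"] = [
                        g + "_A" for g in parent_orders[cname]
                    ]
                for i, cname in enumerate(names):
                    hybrid_orders[f"chrB{i + 1}"] = [
                        g + "_B" for g in orders_b[cname]
                    ]
            continue
        if t in ("recombination", "mat_translocation"):
            tail_swap(
                hybrid_orders, e["chrom1"], e["chrom2"],
                e["tail1_first_gene"], e["tail2_first_gene"],
            )
        elif t == "bir":
            c = e["recipient_chrom"]
            o = hybrid_orders[c]
            deleted = set(e["deleted_gene_ids"])
            o = [g for g in o if g not in deleted]
            if e["recipient_side"] == "L":
                o = list(e["copy_gene_ids"]) + o
            else:
                o = o + list(e["copy_gene_ids"])
            hybrid_orders[c] = o
        elif t == "insert_genes":
            c = e["chrom"]
            o = hybrid_orders[c]
            i = o.index(e["after_gene"]) + 1 if e["after_gene"] else 0
            hybrid_orders[c] = o[:i] + list(e["gene_ids"]) + o[i:]
        # loh / disablement: no order change
    return hybrid_orders or orders_b


# -------------------------------------------------------------------- driver


@dataclass
class SimResult:
    config: SimConfig
    parent_a: SimGenome
    hybrid_sim: SimGenome
    truth: TruthTable

    _hybrid: AnnotatedGenome | None = None
    _reference: AnnotatedGenome | None = None

    @property
    def hybrid(self) -> AnnotatedGenome:
        if self._hybrid is None:
            self._hybrid = self.hybrid_sim.assemble()
        return self._hybrid

    @property
    def reference(self) -> AnnotatedGenome:
        if self._reference is None:
            ref = self.parent_a.assemble()
            ref.name = "reference"
            self._reference = ref
        return self._reference


def simulate_hybrid_genome(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Run the full evolutionary scenario and return genome plus truth."""
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    master = random.Random(config.seed)
    s_parent, s_div, s_rearr, s_post, s_mat = (
        master.randrange(2**31) for _ in range(5)
    )
    parent_a = simulate_parent(config, seed=s_parent)
    parent_b0 = evolve_divergence(parent_a, config.target_ks, config.omega, seed=s_div)
    parent_b, prehyb_log = apply_rearrangements(
        parent_b0, config.n_rearrangements, config.inversion_fraction, seed=s_rearr
    )
    hybrid, truth = hybridize(parent_a, parent_b)
    truth.event_log = prehyb_log + truth.event_log
    apply_posthyb_events(hybrid, truth, config, seed=s_post)
    if config.mat_enabled:
        build_mat_architecture_and_breakage(
            hybrid, truth, config.mat_spec, config, seed=s_mat
        )
    hybrid.name = "hybrid"
    return SimResult(config=config, parent_a=parent_a, hybrid_sim=hybrid, truth=truth)


# ------------------------------------------------------- two-strain scenario


def derive_strain_pair(
    result: SimResult, n_shared: int = 8, n_unique: tuple[int, int] = (10, 9),
    seed: int = 0,
) -> tuple[tuple[SimGenome, TruthTable], tuple[SimGenome, TruthTable]]:
    """Two descendant strains sharing ``n_shared`` planted disablements.

    Returns (genome, truth) per strain; shared disablements hit the same
    genes with the same mechanism, strain-unique ones are disjoint.
    """
    rng = random.Random(seed)
    reserved = _reserved_chrom_names(result.config)

    def fresh(n_extra: int, shared_choices, tag: str) -> tuple[SimGenome, TruthTable]:
        sim = copy.deepcopy(result.hybrid_sim)
        truth = copy.deepcopy(result.truth)
        truth.disablements = list(truth.disablements)
        partner = truth.pair_partner()
        chrom_of = gene_chrom_map(sim)
        used = {d["gene_id"] for d in truth.disablements}
        for g, mech in shared_choices:
            _, _, gu = sim.gene_unit(g)
            ci = _disable_gene(gu, mech, rng)
            truth.disablements.append(
                {"gene_id": g, "partner_id": partner[g], "mechanism": mech,
                 "codon": ci, "subgenome": truth.subgenome[g], "shared": True}
            )
            used.add(g)
        cands = [
            g for g in sorted(truth.subgenome)
            if truth.category.get(g, "").endswith("-in-A:B")
            and g not in used and partner.get(g)
            and partner[g] not in used
            and chrom_of.get(g) not in reserved
        ]
        for g in rng.sample(cands, n_extra):
            mech = rng.choice(("premature-stop", "frameshift-indel"))
            _, _, gu = sim.gene_unit(g)
            ci = _disable_gene(gu, mech, rng)
            truth.disablements.append(
                {"gene_id": g, "partner_id": partner[g], "mechanism": mech,
                 "codon": ci, "subgenome": truth.subgenome[g], "shared": False}
            )
            used.add(g)
            used.add(partner[g])
        return sim, truth

    partner = result.truth.pair_partner()
    already = {d["gene_id"] for d in result.truth.disablements}
    chrom_of_main = gene_chrom_map(result.hybrid_sim)
    cands = [
        g for g in sorted(result.truth.subgenome)
        if result.truth.category.get(g, "").endswith("-in-A:B")
        and g not in already and partner.get(g) and partner[g] not in already
        and chrom_of_main.get(g) not in reserved
    ]
    shared_genes = rng.sample(cands, n_shared)
    shared_choices = [
        (g, rng.choice(("premature-stop", "frameshift-indel"))) for g in shared_genes
    ]
    t1 = fresh(n_unique[0], shared_choices, "s1")
    t2 = fresh(n_unique[1], shared_choices, "s2")
    return t1, t2


# --------------------------------------------------------------------- output


def write_truth_tables(result: SimResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = result.hybrid
    rows = []
    for chrom in genome.chromosomes:
        for i, g in enumerate(chrom.genes):
            rows.append(
                (g.gene_id, chrom.name, i,
                 result.truth.subgenome.get(g.gene_id, "N"),
                 result.truth.category.get(g.gene_id, "N"))
            )
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tindex\ttrue_subgenome\ttrue_category\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    with open(outdir / "event_log.json", "w") as fh:
        json.dump(result.truth.event_log, fh, indent=1)


def write_genome(genome: AnnotatedGenome, outdir: str | Path, stem: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.to_fasta(outdir / f"{stem}.fa")
    genome.to_gff3(outdir / f"{stem}.gff3")
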