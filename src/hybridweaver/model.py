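"""Core genome containers and file I/O.

Internal coordinates are 1-based inclusive throughout (GFF3 convention).
BED exports are 0-based half-open; the two conversion helpers below are the
only place the convention changes, and they are round-trip tested.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio.Seq import Seq


class HybridweaverError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(HybridweaverError):
    pass


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass
class Gene:
    """A gene model: one or more CDS exons on a chromosome.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by start and
    given in genomic (plus-strand) order regardless of ``strand``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [(self.start, self.end)]
        if self.strand not in "+-":
            raise ConfigurationError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def cds(self, chrom_seq: str) -> str:
        """Spliced coding sequence, 5'->3' on the coding strand."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class Chromosome:
    name: str
    seq: str
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.gene_id))


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus ordered gene models."""

    name: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate chromosome names in {self.name}")

    @property
    def chrom_map(self) -> dict[str, Chromosome]:
        return {c.name: c for c in self.chromosomes}

    def genes(self):
        for chrom in self.chromosomes:
            yield from chrom.genes

    @property
    def n_genes(self) -> int:
        return sum(len(c.genes) for c in self.chromosomes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def cds_of(self, gene: Gene) -> str:
        return gene.cds(self.chrom_map[gene.chrom].seq)

    def cds_sequences(self) -> dict[str, str]:
        out = {}
        for chrom in self.chromosomes:
            for g in chrom.genes:
                out[g.gene_id] = g.cds(chrom.seq)
        return out

    def gene_orders(self) -> dict[str, list[str]]:
        """Per-chromosome ordered gene-id lists (by genomic coordinate)."""
        return {c.name: [g.gene_id for g in c.genes] for c in self.chromosomes}

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                fh.write(f">{chrom.name}\n")
                for i in range(0, len(chrom.seq), 80):
                    fh.write(chrom.seq[i : i + 80] + "\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in self.chromosomes:
                fh.write(f"##sequence-region {chrom.name} 1 {len(chrom.seq)}\n")
            for chrom in self.chromosomes:
                for g in chrom.genes:
                    attrs = ";".join(
                        [f"ID={g.gene_id}"]
                        + [f"{k}={v}" for k, v in sorted(g.attributes.items())]
                    )
                    fh.write(
                        f"{chrom.name}\thybridweaver\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
                    mrna = f"{g.gene_id}.t1"
                    fh.write(
                        f"{chrom.name}\thybridweaver\tmRNA\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
                    )
                    exons = g.exons if g.strand == "+" else list(reversed(g.exons))
                    phase = 0
                    for s, e in exons:
                        fh.write(
                            f"{chrom.name}\thybridweaver\tCDS\t{s}\t{e}\t.\t"
                            f"{g.strand}\t{phase}\tID={mrna}.cds;Parent={mrna}\n"
                        )
                        phase = (3 - ((e - s + 1 - phase) % 3)) % 3

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path, name: str = "genome") -> "AnnotatedGenome":
        seqs: dict[str, str] = {}
        order: list[str] = []
        with open(fasta) as fh:
            cur = None
            buf: list[str] = []
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if cur is not None:
                        seqs[cur] = "".join(buf)
                    cur = line[1:].split()[0]
                    order.append(cur)
                    buf = []
                else:
                    buf.append(line)
            if cur is not None:
                seqs[cur] = "".join(buf)

        db = gffutils.create_db(
            str(gff3), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes_by_chrom: dict[str, list[Gene]] = {n: [] for n in order}
        for feat in db.features_of_type("gene"):
            exons = []
            for mrna in db.children(feat, featuretype="mRNA"):
                exons = sorted((c.start, c.end) for c in db.children(mrna, featuretype="CDS"))
            if not exons:
                exons = sorted((c.start, c.end) for c in db.children(feat, featuretype="CDS"))
            attrs = {
                k: v[0]
                for k, v in feat.attributes.items()
                if k not in ("ID", "Parent") and v
            }
            genes_by_chrom.setdefault(feat.seqid, []).append(
                Gene(
                    gene_id=feat.id, chrom=feat.seqid, start=feat.start,
                    end=feat.end, strand=feat.strand,
                    exons=exons or [(feat.start, feat.end)], attributes=attrs,
                )
            )
        chroms = []
        for cname in order:
            c = Chromosome(cname, seqs[cname], genes_by_chrom.get(cname, []))
            c.sort_genes()
            chroms.append(c)
        return cls(name=name, chromosomes=chroms)

    def fasta_str(self) -> str:
        buf = io.StringIO()
        for chrom in self.chromosomes:
            buf.write(f">{chrom.name}\n")
            for i in range(0, len(chrom.seq), 80):
                buf.write(chrom.seq[i : i + 80] + "\n")
        return buf.getvalue()
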