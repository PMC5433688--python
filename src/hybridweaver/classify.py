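"""Subgenome labels, homeolog-pair types, and the 7-way gene category map.

A hybrid gene is labelled by its synonymous divergence from the reference
parental species: A (Ks <= 0.05, essentially identical to the reference
parent), B (0.05 < Ks <= 0.25, the divergent parent, whose Ks distribution
peaks at ~0.16), or N (Ks > 0.25, saturated, or no homolog found).  Boundary
values go to the lower class, reading the thresholds' "<=" literally.

Pairing status (reciprocal best hits within the hybrid proteome) is
independent of the reference hit used for labelling.  The cross of label and
pair type yields seven categories that partition the gene set; runs of
same-label pairs on an opposite-label background are the signature of
loss of heterozygosity, and part-A/part-B chromosomes mark recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotatedGenome, HybridweaverError

KS_A_MAX = 0.05
KS_B_MAX = 0.25

CATEGORIES = (
    "A-in-A:B",
    "B-in-A:B",
    "A-in-A:A",
    "B-in-B:B",
    "A-unpaired",
    "B-unpaired",
    "N",
)


def assign_subgenome(
    ks: float | None, ks_a: float = KS_A_MAX, ks_b: float = KS_B_MAX
) -> str:
    """A if Ks <= ks_a; B if ks_a < Ks <= ks_b; N if larger or missing."""
    if ks is None:
        return "N"
    if ks < 0:
        raise HybridweaverError(f"negative Ks {ks}")
    if ks <= ks_a:
        return "A"
    if ks <= ks_b:
        return "B"
    return "N"


def type_pairs(
    pairs: list[tuple[str, str]], labels: dict[str, str]
) -> dict[tuple[str, str], str]:
    """Pair type from member labels: A:B, A:A, B:B, or other (N member)."""
    out = {}
    for a, b in pairs:
        la, lb = labels.get(a, "N"), labels.get(b, "N")
        if "N" in (la, lb):
            out[(a, b)] = "other"
        elif la == lb:
            out[(a, b)] = f"{la}:{la}"
        else:
            out[(a, b)] = "A:B"
    return out


@dataclass
class CategoryTrack:
    chrom: str
    gene_ids: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.gene_ids)


def gene_category(label: str, pair_type: str | None) -> str:
    if label == "N":
        return "N"
    if pair_type == "A:B":
        return f"{label}-in-A:B"
    if pair_type in ("A:A", "B:B") and pair_type == f"{label}:{label}":
        return f"{label}-in-{pair_type}"
    # paired with an N gene, mismatched pair type, or genuinely unpaired
    return f"{label}-unpaired"


def categorize(
    genome: AnnotatedGenome,
    labels: dict[str, str],
    pair_types: dict[tuple[str, str], str],
) -> tuple[list[CategoryTrack], dict[str, int]]:
    """Per-chromosome category tracks plus genome-wide counts.

    Every gene receives exactly one of the seven categories; the counts
    always partition the gene set.
    """
    pair_type_of: dict[str, str] = {}
    partner: dict[str, str] = {}
    for (a, b), ptype in pair_types.items():
        for g, other in ((a, b), (b, a)):
            if g in pair_type_of:
                raise HybridweaverError(f"gene {g} is in more than one pair")
            pair_type_of[g] = ptype
            partner[g] = other

    tracks = []
    counts = {c: 0 for c in CATEGORIES}
    for chrom in genome.chromosomes:
        track = CategoryTrack(chrom.name)
        for g in chrom.genes:
            label = labels.get(g.gene_id, "N")
            cat = gene_category(label, pair_type_of.get(g.gene_id))
            track.gene_ids.append(g.gene_id)
            track.categories.append(cat)
            track.labels.append(label)
            counts[cat] += 1
        tracks.append(track)
    return tracks, counts
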