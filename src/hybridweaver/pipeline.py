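"""End-to-end orchestration: simulate -> ks -> classify -> architecture ->
mat-scan -> integrity, with truth-recovery scoring and a JSON summary.

All tunable thresholds live in :class:`PipelineConfig`; every run records
its seed and a hash of the configuration so outputs are attributable.
Internal coordinates are 1-based inclusive; BED exports 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import architecture as arch
from . import classify as cls
from . import integrity as integ
from . import ks as ksmod
from . import mat as matmod
from .model import AnnotatedGenome, to_bed
from .simulate import SimConfig, SimResult, TruthTable, simulate_hybrid_genome


@dataclass
class PipelineConfig:
    ks_a: float = 0.05
    ks_b: float = 0.25
    length_ratio: float = 0.9
    min_run: int = 3
    max_gap: int = 2
    min_bir_genes: int = 3
    bir_id_min: float = 0.95
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        for name in ("ks_a", "ks_b", "length_ratio"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.ks_a >= self.ks_b:
            raise ValueError("ks_a must be < ks_b")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log(msg: str) -> None:
    print(f"[hybridweaver] {msg}", file=sys.stderr)


# --------------------------------------------------------------- stage: ks


def ks_stage(
    hybrid: AnnotatedGenome, reference: AnnotatedGenome
) -> tuple[dict[str, float | None], pd.DataFrame, dict[str, str], dict[str, str]]:
    """Best reference hit and Ks per hybrid gene.

    Returns (ks_by_gene, table, hybrid_cds, ref_cds).  Genes without a
    reference hit have Ks None.
    """
    hyb_cds = hybrid.cds_sequences()
    ref_cds = reference.cds_sequences()
    hyb_prot = ksmod.proteome_of(hyb_cds)
    ref_prot = ksmod.proteome_of(ref_cds)
    hits = ksmod.find_best_hits(hyb_prot, ref_prot)
    ks_by_gene: dict[str, float | None] = {g: None for g in hyb_cds}
    rows = []
    for hit in hits:
        try:
            aln = ksmod.align_codons(
                hyb_cds[hit.query_id], ref_cds[hit.subject_id],
                hit.query_id, hit.subject_id, pseudogene=True,
            )
            est = ksmod.estimate_ks(aln)
        except ksmod.TranslationError:
            continue
        ks_by_gene[hit.query_id] = est.ks
        rows.append(
            {
                "gene": hit.query_id, "ref_hit": hit.subject_id,
                "score": hit.score, "identity": round(hit.identity, 4),
                "S": round(est.S, 2), "N": round(est.N, 2),
                "Sd": round(est.Sd, 2), "Nd": round(est.Nd, 2),
                "ps": round(est.ps, 5),
                "ks": None if est.ks is None else round(est.ks, 5),
                "ka": None if est.ka is None else round(est.ka, 5),
                "saturated": est.saturated,
                "low_confidence": est.low_confidence,
            }
        )
    return ks_by_gene, pd.DataFrame(rows), hyb_cds, ref_cds


def pairing_stage(hybrid_cds: dict[str, str]) -> list[tuple[str, str]]:
    """Reciprocal-best-hit homeolog pairs within the hybrid proteome."""
    prot = ksmod.proteome_of(hybrid_cds)
    hits = ksmod.find_best_hits(
        prot, prot, ksmod.BestHitParams(exclude_self=True)
    )
    pairs = ksmod.reciprocal_best_pairs(hits, hits)
    # each unordered pair appears twice (a->b and b->a); deduplicate
    seen = set()
    out = []
    for a, b in pairs:
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            out.append((a, b))
    return out


# ------------------------------------------------------------ truth scoring


def _precision_recall(called: set, true: set) -> dict:
    tp = len(called & true)
    return {
        "precision": tp / len(called) if called else 1.0,
        "recall": tp / len(true) if true else 1.0,
        "called": len(called), "true": len(true), "matched": tp,
    }


def evaluate_against_truth(
    truth: TruthTable,
    labels: dict[str, str],
    categories: dict[str, str],
    pairs: list[tuple[str, str]],
    loh_tracts: list[arch.LohTract],
    junctions: list[arch.RecombinationJunction],
    bir_flags: list[arch.BirFlag],
    disablement_calls: list[integ.DisablementCall],
    gene_index: dict[str, tuple[str, int]],
) -> dict:
    out: dict = {}
    truth_genes = set(truth.subgenome)
    n_label_ok = sum(
        1 for g in truth_genes if labels.get(g, "N") == truth.subgenome[g]
    )
    out["subgenome_label_accuracy"] = n_label_ok / len(truth_genes)
    n_cat_ok = sum(
        1 for g in truth_genes if categories.get(g, "N") == truth.category.get(g)
    )
    out["category_accuracy"] = n_cat_ok / len(truth_genes)

    called_pairs = {frozenset(p) for p in pairs}
    true_pairs = {frozenset(p) for p in truth.pairs}
    out["pairs"] = _precision_recall(called_pairs, true_pairs)

    called_tracts = {(t.chrom, tuple(t.gene_ids)) for t in loh_tracts}
    true_tracts = {(t["chrom"], tuple(t["gene_ids"])) for t in truth.loh_tracts}
    out["loh"] = _precision_recall(called_tracts, true_tracts)

    # junction match: the called switch interval must straddle the true
    # boundary between the two recorded flank genes
    true_j = []
    for tj in truth.recombination_junctions:
        li = gene_index.get(tj["left_gene"])
        ri = gene_index.get(tj["right_gene"])
        if li and ri and li[0] == ri[0]:
            true_j.append((li[0], (li[1] + ri[1]) / 2.0, tj["kind"]))
    matched_true = set()
    matched_called = set()
    for ci, cj in enumerate(junctions):
        for ti, (chrom, boundary, _kind) in enumerate(true_j):
            if cj.chrom == chrom and cj.left_index < boundary < cj.right_index:
                matched_true.add(ti)
                matched_called.add(ci)
    out["junctions"] = {
        "precision": len(matched_called) / len(junctions) if junctions else 1.0,
        "recall": len(matched_true) / len(true_j) if true_j else 1.0,
        "called": len(junctions), "true": len(true_j),
    }

    called_ends = {(f.chrom, f.side) for f in bir_flags}
    true_ends = set()
    for b in truth.bir_ends:
        true_ends.add((b["donor_chrom"], b["donor_side"]))
        true_ends.add((b["recipient_chrom"], b["recipient_side"]))
    out["bir"] = _precision_recall(called_ends, true_ends)

    # score disablement recovery on the planted set; cassette stub genes
    # (truth class N) carry their own engineered splice break and are scored
    # by the splice-shift machinery instead
    called_dis = {
        (c.gene_id, c.mechanism)
        for c in disablement_calls
        if truth.subgenome.get(c.gene_id) != "N"
    }
    true_dis = {(d["gene_id"], d["mechanism"]) for d in truth.disablements}
    out["disablements"] = _precision_recall(called_dis, true_dis)
    return out


# ------------------------------------------------------------------ pipeline


def run_pipeline(
    config: PipelineConfig | None = None,
    sim_result: SimResult | None = None,
    hybrid: AnnotatedGenome | None = None,
    reference: AnnotatedGenome | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute all stages; returns the machine-readable summary dict.

    Inputs are either a simulation result (default: simulate with
    ``config.sim``) or an explicit hybrid + reference genome pair.
    """
    config = config or PipelineConfig()
    config.validate()
    truth: TruthTable | None = None
    if hybrid is None:
        if sim_result is None:
            _log("simulating hybrid genome")
            sim_result = simulate_hybrid_genome(config.sim, seed=config.seed)
        hybrid = sim_result.hybrid
        reference = sim_result.reference
        truth = sim_result.truth
    if reference is None:
        raise ValueError("a reference genome is required")

    summary: dict = {
        "meta": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_hybrid_chromosomes": len(hybrid.chromosomes),
            "n_hybrid_genes": hybrid.n_genes,
        }
    }

    _log("ks stage: best hits against the reference parent")
    ks_by_gene, ks_table, hyb_cds, _ = ks_stage(hybrid, reference)
    labels = {
        g: cls.assign_subgenome(k, config.ks_a, config.ks_b)
        for g, k in ks_by_gene.items()
    }
    ks_vals = [k for k in ks_by_gene.values() if k is not None]
    summary["ks"] = {
        "n_with_hit": len(ks_vals),
        "mean_ks_b": (
            sum(k for k in ks_vals if k > config.ks_a)
            / max(1, sum(1 for k in ks_vals if k > config.ks_a))
        ),
        "frac_a": sum(1 for k in ks_vals if k <= config.ks_a) / max(1, hybrid.n_genes),
        "frac_b": sum(
            1 for k in ks_vals if config.ks_a < k <= config.ks_b
        ) / max(1, hybrid.n_genes),
    }

    _log("pairing stage: reciprocal best hits within the hybrid")
    pairs = pairing_stage(hyb_cds)
    pair_types = cls.type_pairs(pairs, labels)
    tracks, cat_counts = cls.categorize(hybrid, labels, pair_types)
    type_counts: dict[str, int] = {}
    for t in pair_types.values():
        type_counts[t] = type_counts.get(t, 0) + 1
    summary["classify"] = {
        "category_counts": cat_counts,
        "pair_type_counts": type_counts,
        "n_pairs": len(pairs),
    }
    categories = {}
    gene_index: dict[str, tuple[str, int]] = {}
    for tr in tracks:
        for i, g in enumerate(tr.gene_ids):
            categories[g] = tr.categories[i]
            gene_index[g] = (tr.chrom, i)

    _log("architecture stage")
    ref_hit = dict(zip(ks_table.get("gene", []), ks_table.get("ref_hit", [])))
    order_x = arch.genome_order(hybrid)
    order_y = arch.genome_order(reference)
    b_map = {g: ref_hit[g] for g in ref_hit if labels.get(g) == "B"}
    a_map = {g: ref_hit[g] for g in ref_hit if labels.get(g) == "A"}
    bset_b = arch.count_breakpoints(order_x, order_y, b_map, config.max_gap)
    bset_a = arch.count_breakpoints(order_x, order_y, a_map, config.max_gap)
    blocks = arch.build_synteny_blocks(order_x, order_y, b_map, config.max_gap)

    bir_flags = arch.flag_bir_ends(
        tracks, hybrid, min_bir_genes=config.min_bir_genes, id_min=config.bir_id_min
    )
    bir_exclude: dict[str, set[int]] = {}
    for f in bir_flags:
        bir_exclude.setdefault(f.chrom, set()).update(
            range(f.run_indices[0], f.run_indices[1] + 1)
        )
    loh_tracts: list[arch.LohTract] = []
    junctions: list[arch.RecombinationJunction] = []
    for tr in tracks:
        excl = bir_exclude.get(tr.chrom, set())
        tr_tracts = arch.segment_loh_tracts(tr, min_run=config.min_run, exclude=excl)
        loh_tracts.extend(tr_tracts)
        junctions.extend(
            arch.detect_recombination_junctions(
                tr, min_run=config.min_run, loh_tracts=tr_tracts, exclude=excl
            )
        )
    telomere = arch.telomere_consensus(arch.chromosome_end_windows(hybrid))

    summary["architecture"] = {
        "breakpoints_b_vs_ref": bset_b.count,
        "events_b_vs_ref": bset_b.event_estimate,
        "breakpoints_a_vs_ref": bset_a.count,
        "n_synteny_blocks": len(blocks),
        "n_loh_tracts": len(loh_tracts),
        "loh_tract_lengths": sorted(t.length for t in loh_tracts),
        "n_junctions": len(junctions),
        "n_bir_flagged_ends": len(bir_flags),
        "telomere_unit": telomere.unit,
        "telomere_unit_canonical": telomere.unit_canonical,
    }

    _log("mat-scan stage")
    catalog = matmod.catalog_mat_loci(hybrid, labels=labels)
    splice_reports = []
    for chrom in hybrid.chromosomes:
        for g in chrom.genes:
            if g.n_exons < 2:
                continue
            rep = matmod.analyze_splice_shift(g, chrom.seq)
            if rep.shift != 0 or rep.unspliceable:
                splice_reports.append(rep)
    junction_sig = None
    if truth is not None and truth.mat_breakage is not None:
        mb = truth.mat_breakage
        sig = matmod.analyze_junction(
            mb["junction_window"], mb["donor_left_window"], mb["donor_right_window"]
        )
        junction_sig = {
            "microhomology": sig.microhomology,
            "tsd_lengths": sig.tsd_lengths(),
            "inserted": sig.inserted,
        }
    summary["mat"] = {
        "n_regions": catalog.n_regions,
        "n_fragments": len(catalog.fragments),
        "n_intact": sum(1 for l in catalog.loci if l.intact),
        "x_identity": catalog.x_identity,
        "z_identity": catalog.z_identity,
        "a1_absent": catalog.a1_absent,
        "junction_signature": junction_sig,
        "splice_shifts": [
            {"gene": r.gene_id, "shift": r.shift, "frame_preserved": r.frame_preserved,
             "protein_length": r.protein_length}
            for r in splice_reports
        ],
    }

    _log("integrity stage")
    proteins = ksmod.proteome_of(hyb_cds)
    # screen every homeolog pair: a disabling mutation can corrupt the Ks of
    # its own gene (frameshifted tail), so restricting to clean A:B pairs
    # would hide exactly the genes the screen exists to find
    calls = integ.screen_pairs(
        pairs, proteins, cds=hyb_cds, ratio_threshold=config.length_ratio
    )
    splice_broken = {
        r.gene_id for r in splice_reports if r.unspliceable or not r.frame_preserved
    }
    for c in calls:
        if c.gene_id in splice_broken:
            c.mechanism = "splice-site"
    introns = integ.find_inframe_introns(hybrid)
    plus1 = integ.find_plus1_sites(hyb_cds)
    summary["integrity"] = {
        "n_flagged_pairs": len(calls),
        "mechanisms": sorted(c.mechanism for c in calls),
        "n_inframe_introns": len(introns),
        "n_plus1_sites": len(plus1),
    }

    if truth is not None:
        _log("truth-recovery scoring")
        summary["truth_eval"] = evaluate_against_truth(
            truth, labels, categories, pairs, loh_tracts, junctions,
            bir_flags, calls, gene_index,
        )

    if outdir is not None:
        _write_outputs(
            Path(outdir), summary, ks_table, labels, pairs, pair_types,
            tracks, blocks, bset_b, loh_tracts, junctions, bir_flags,
            catalog, calls, introns, plus1, hybrid,
        )
    return summary


def _write_outputs(
    outdir: Path, summary, ks_table, labels, pairs, pair_types, tracks,
    blocks, bset_b, loh_tracts, junctions, bir_flags, catalog, calls,
    introns, plus1, hybrid,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ks_table.to_csv(outdir / "pairs_ks.tsv", sep="\t", index=False)

    pair_of = {}
    for i, (a, b) in enumerate(pairs):
        pair_of[a] = (f"p{i:05d}", b)
        pair_of[b] = (f"p{i:05d}", a)
    rows = []
    for chrom in hybrid.chromosomes:
        for g in chrom.genes:
            pid, _ = pair_of.get(g.gene_id, ("", ""))
            rows.append(
                {
                    "gene_id": g.gene_id, "chrom": chrom.name,
                    "start": g.start, "end": g.end, "strand": g.strand,
                    "label": labels.get(g.gene_id, "N"), "pair_id": pid,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "gene_table.tsv", sep="\t", index=False)

    with open(outdir / "category_map.bed", "w") as fh:
        for tr in tracks:
            cmap = hybrid.chrom_map[tr.chrom]
            for i, g in enumerate(cmap.genes):
                b0, b1 = to_bed(g.start, g.end)
                fh.write(f"{tr.chrom}\t{b0}\t{b1}\t{tr.categories[i]}\n")

    pd.DataFrame(
        [
            {
                "chrom_x": b.chrom_x, "chrom_y": b.chrom_y,
                "x_start": b.x_range[0], "x_end": b.x_range[1],
                "y_start": b.y_range[0], "y_end": b.y_range[1],
                "orientation": b.orientation, "n_genes": b.n_genes,
            }
            for b in blocks
        ]
    ).to_csv(outdir / "synteny_blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": bp.chrom_x, "left_gene": bp.left_gene,
             "right_gene": bp.right_gene, "reason": bp.reason}
            for bp in bset_b.breakpoints
        ]
    ).to_csv(outdir / "breakpoints.tsv", sep="\t", index=False)

    with open(outdir / "loh_tracts.bed", "w") as fh:
        for t in loh_tracts:
            genes = hybrid.chrom_map[t.chrom].genes
            b0, _ = to_bed(genes[t.start_index].start, genes[t.start_index].end)
            _, b1 = to_bed(genes[t.end_index].start, genes[t.end_index].end)
            fh.write(f"{t.chrom}\t{b0}\t{b1}\tLOH_{t.tract_class}_on_{t.background}\n")
    with open(outdir / "junctions.bed", "w") as fh:
        for j in junctions:
            genes = hybrid.chrom_map[j.chrom].genes
            b0, _ = to_bed(genes[j.left_index].end, genes[j.left_index].end)
            _, b1 = to_bed(genes[j.right_index].start, genes[j.right_index].start)
            fh.write(f"{j.chrom}\t{b0}\t{b1}\t{j.left_label}>{j.right_label}\n")
    pd.DataFrame(
        [
            {"chrom": f.chrom, "side": f.side, "label": f.label,
             "n_genes": f.n_genes,
             "partner": "" if f.partner is None else f"{f.partner[0]}:{f.partner[1]}",
             "identity": f.identity}
            for f in bir_flags
        ]
    ).to_csv(outdir / "bir_report.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"kind": l.kind, "idiomorph": l.idiomorph, "subgenome": l.subgenome,
             "chrom": l.chrom, "start": l.start, "end": l.end,
             "intact": l.intact, "genes": ",".join(l.gene_ids)}
            for l in catalog.loci
        ]
    ).to_csv(outdir / "mat_catalog.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "partner_id": c.partner_id,
             "mechanism": c.mechanism, "length_ratio": round(c.length_ratio, 4),
             "position": c.position}
            for c in calls
        ]
    ).to_csv(outdir / "disablement_calls.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(i) for i in introns]).to_csv(
        outdir / "inframe_introns.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(s) for s in plus1]).to_csv(
        outdir / "plus1_sites.tsv", sep="\t", index=False
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
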