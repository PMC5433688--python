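# Methods

## The problem being modelled

A recently formed allopolyploid yeast carries two complete parental genomes
in one nucleus. One parent is essentially identical to a sequenced relative
(here always called the *reference parent*; its descendant gene copies are
the **A-subgenome**), the other is an unknown species at roughly 7 %
nucleotide divergence, corresponding to a synonymous-site divergence peak of
K<sub>S</sub> ≈ 0.16 (the **B-subgenome**). Because the hybridization is
recent, almost every gene still exists as an A:B homeolog pair, and the
genome is a readable record of the events that shaped it: prehybridization
karyotype rearrangements carried in by parent B, posthybridization loss of
heterozygosity (LOH), interhomeolog recombination, break-induced
replication (BIR) at chromosome ends, sporadic gene disablement, and a
diagnostic HO-endonuclease-catalyzed breakage of one MAT locus repaired by
nonhomologous end joining (NHEJ) as a reciprocal translocation.

The package implements both the read-out (the analysis pipeline) and the
write-in (a generator that replays this evolutionary scenario with complete
ground truth), so that every analysis stage is testable by recovery.

## Divergence estimation and subgenome assignment

K<sub>S</sub> is computed by Nei–Gojobori (1986) counting with a
Jukes–Cantor correction on protein-guided codon alignments. Site counting
uses the standard per-codon synonymous fractions with changes to stop
codons counted as nonsynonymous, which keeps the identity S + N = 3 ×
codons exact; difference counting averages over all mutational pathways
between two codons, excluding pathways through stop codons (if every
pathway is blocked, all are used with stop steps counted as nonsynonymous —
this situation does not occur for sense–sense pairs under the standard
code). NG86 was chosen over the yn00-style estimator because the
classification thresholds, not the estimator brand, are the operative
contract, and at K<sub>S</sub> ≤ 0.25 the two differ negligibly; NG86 is
also fully auditable against an exhaustive enumeration oracle, which the
test suite runs over all 61 × 61 sense-codon pairs.

Labels follow the fixed thresholds: A for K<sub>S</sub> ≤ 0.05, B for
0.05 < K<sub>S</sub> ≤ 0.25, N above 0.25, when saturated (p<sub>S</sub> ≥ 3/4) or
when no reference homolog is found. Boundary values go to the lower class.
Labels always mean divergence-defined parent of origin, never chromosome
identity; recombined chromosomes therefore legitimately carry mixed labels.

Homolog search mirrors a BLASTP best-hit protocol: a shared-k-mer prefilter
(k = 5, ≥ 4 distinct shared k-mers, top 10 candidates by shared count) and
BLOSUM62 local alignment with affine gap costs 11/1. Ties on score break by
higher identity, then lexicographic subject id. Hits covering < 50 % of the
shorter protein are dropped (such queries fall into class N). Homeolog
*pairing* is reciprocal best hits within the hybrid proteome, deliberately
independent of the reference hit used for labelling. Codon alignment is a
global protein alignment projected onto codons (gaps in multiples of 3);
equal-length pairs above 80 % ungapped identity skip the traceback since
their optimal alignment is the ungapped one. Pairs with fewer than 30
aligned codons carry a low-confidence flag. Translation of annotated but
broken genes (frameshifted or prematurely stopped) uses pseudogene mode:
read frame 0, stop at the first in-frame stop. The K<sub>S</sub> of such a
gene is computed over what aligns and can be inflated by the out-of-frame
tail downstream of an indel; this is why the disablement screen runs over
all homeolog pairs rather than only clean A:B pairs.

## Gene-order archaeology

Two gene orders are compared through a one-to-one homolog map. An adjacency
of mapped genes in genome *x* is intact when the homologs lie on one *y*
chromosome, adjacent up to `max_gap` unmapped intervening genes (default 2;
0 in oracle tests), in a consistent relative orientation. Chromosome ends
are not adjacencies. Every inversion or reciprocal translocation breaks
exactly two adjacencies, so events ≈ breakpoints div 2, with a warning on
odd counts. On a full simulated hybrid the B-vs-reference count can fall
one or two short of 2 × events because an LOH tract converts the B-genes
flanking a breakpoint into A:A pairs, hiding that adjacency from the
B-labelled order — the exact-arithmetic check therefore runs on the
rearranged parent itself, where 17 events give exactly 34 breakpoints.

LOH tracts are maximal runs (≥ `min_run`, default 3 genes) of same-label
pair genes (A-in-A:A or B-in-B:B) whose label opposes the chromosome
background, defined as the majority label over the whole chromosome (ties
to A). N genes are transparent. Recombination junctions are persistent
background switches with at least `min_run` genes of each class on both
flanks, after removing called LOH tracts. BIR candidates are terminal runs
of same-label genes that are unpaired *or* in same-label pairs; a partner
end sharing ≥ 95 % sequence identity over the run (edlib edit distance)
confirms the call. The pipeline flags BIR ends first and masks them from
LOH segmentation. Telomere consensus is the most frequent
rotation-normalized tandem unit among terminal windows (left ends
reverse-complemented), reported both as found and as the lexicographically
minimal rotation.

With both copies of a BIR-duplicated end present in the assembly,
reciprocal-best-hit pairing pairs each duplicated gene with its identical
copy, so BIR regions surface as terminal A:A runs rather than unpaired
genes — the same inference made for the real strain when both copies are
resolved. The detector accepts both presentations.

## MAT-locus forensics

X and Z repeats are discovered de novo as multi-copy (≥ 3), ≥ 200-bp,
near-identical intergenic elements, found by equal-copy-number runs of
32-mers and clustered by edit-distance identity; short-period tandem
regions (telomeres) are excluded. Z is the cluster whose copies begin with
the HO core `cgcagca`. A locus is intact when an X copy is followed within
8 kb by a Z copy with idiomorph gene stubs between; a lone flank is a
fragment, and an X-fragment plus a Z-fragment are grouped as one broken
locus, so a genome with five intact cassettes and one broken MAT reports
six MAT-related regions and two fragments. Idiomorphs come from stub
content (α1/α2 vs a2); the absence of any a1 gene is asserted. A probe mode
(supplied X/Z sequences) bypasses discovery.

HO cleavage registration: the biochemical cut positions are not known for
this genus, only the core and the overhang chemistry. The model fixes the
bottom-strand cut at the core's 5′ boundary and the top-strand cut 4 nt
into the core, yielding a 4-nt 3′ overhang whose sequence is the core's
first four bases (`cgca`); with the cuts the other way around the overhang
would be 5′, contradicting the observed chemistry. The registration is a
single constant (`HO_TOP_CUT_OFFSET`) so it can be revised without touching
callers. Cleavage and re-ligation are exact inverses for every site.

NHEJ junction model: target-site duplications are tandem re-copies of the
retained donor flanks at the break (the fill-in signature of staggered
ends), so a junction decomposes as `L[:a] + L[a-tl:a] + R[b:b+tr] + R[b:]`;
a microhomology-mediated join is `L[:a] + R[b:]` with the last *m* retained
left bases equal to the *m* bases preceding the retained right part. The
analyzer is greedy (maximal prefix/suffix match, then maximal flank
re-copies); the simulator's constructor adjusts single donor bases adjacent
to the break when a random draw would make the decomposition ambiguous, so
planted signatures are uniquely recoverable. The simulated breakage plants
a 5-bp duplication with the literal sequence `acaac` on the A-subgenome
side and a 2-bp duplication of the Z start, with zero microhomology.

Splice-shift analysis: for the first intron whose annotated acceptor is not
AG, the nearest downstream AG (within 50 nt) becomes the new acceptor; the
shift preserves frame iff it is a multiple of 3. The simulated B-subgenome
α2 cassette gene is engineered so that the AG→AC mutation shifts splicing
by 2 nt and truncates the 211-residue protein to 57 residues, reproducing
the diagnostic pattern at cassette-gene scale. A shift of 1 nt cannot arise
from an AG→AC mutation (the C occupies the needed position), so the frame
rule is tested over shifts 2–9.

## Gene-integrity screen

A pair is flagged when the shorter predicted protein is below 90 % of the
longer (strict inequality; exactly 0.9 passes). Protein length, not CDS
length, is the yardstick because indels and stops act through translation.
Mechanism is refined by comparing the coding sequences: an in-frame stop
before the end is a premature stop; otherwise a global DNA alignment
(match 2, mismatch −3, gaps 7/2) localizes the first frame-changing (1–2 nt)
indel; genes whose splice-shift report shows a frameshifting acceptor
mutation are reclassified splice-site. In-frame introns are introns of
length ≡ 0 (mod 3) without stop codons in the unspliced reading frame
(position mod 3 in coding orientation). +1 frameshift candidates require
the motif `CTT-A-GTT` or `CTT-A-GGC` with CTT in frame 0, frame 0 closing
within 30 codons after the motif, and a +1 continuation open for ≥ 30
codons (configurable); the extension requirement stands in for the
homology evidence a reference-free screen cannot use.

## The simulator

The generator's defaults are the study conditions: two parents of 1,000
genes (500 codons each, random sense codons, random strand) on 8
chromosomes, 200-bp random intergenic spacers, telomeres of 20 tandem
copies of `tgtgggtgggg` at every end (reverse-complemented on left ends);
divergence to K<sub>S</sub> = 0.16 with nonsynonymous acceptance ω = 0.05;
17 rearrangements (inversions and reciprocal translocations, 1:1); 8 LOH
tracts of 8 genes with the A homeolog donating 75 % of the time (the real
genome has ~3.5× more A:A than B:B pairs); 2 crossovers; 3 BIR ends of 6
genes (A donors, as observed); 9 disablements per subgenome (the strain
shows 10 A + 9 B); and the full MAT architecture with breakage.

Divergence is an explicit substitution process: uniform single-nucleotide
proposals, synonymous changes accepted freely, nonsynonymous with
probability ω, stop-creating changes rejected; each gene receives
round(K<sub>S</sub> · S) accepted synonymous events, so the realized
events-per-synonymous-site equals the target and the JC-corrected NG86
estimate recovers it (calibration is checked at 3 standard errors over 200
genes; residual bias from binary two-fold-degenerate sites is well inside
that band). Start and stop codons are held fixed.

Rearrangement breakpoints fall at intergenic midpoints; every event
consumes two distinct, previously intact original adjacencies and never
re-creates a broken one, which is what makes the 2-breakpoints-per-event
arithmetic exact. Posthybridization events apply in the fixed order LOH →
recombination → BIR → disablement. The generator guarantees its own
recoverability invariants rather than leaving them to chance: LOH tracts
stay clear of chromosome ends by `bir_genes + 2` genes; a crossover is
redrawn if either product chromosome would have a majority label equal to
the class of an LOH tract it carries (which would hide the tract from the
majority-background rule); a crossover joins an A chromosome to whichever
B chromosome carries the homeologs of its flanking genes adjacently;
BIR recipients are the chromosome ends carrying the homeologs of the donor
ends, overwritten wholesale so the two ends are sequence-identical to the
telomere; disablement positions are redrawn until the truncated protein
falls below 85 % of full length. MAT, HML and HMR sit on the last
chromosome of each subgenome (left arm / centre / right arm), which is
excluded, together with the junction-target chromosome, from random
events. Cassette stub genes have no homolog in the emitted reference
genome, so their ground-truth class is N under the divergence-defined
labelling.

Every order-changing event is logged, and `replay_event_log` reproduces the
emitted gene order exactly from the parent orders — a structural invariant
of the whole generator, enforced in the tests. All randomness derives from
a single seed; identical seeds give byte-identical FASTA/GFF3.

What the simulator does not emulate: realistic intergenic or codon-usage
composition, gene length variation, tandem gene families, rDNA,
mitochondria, intron-rich gene models outside the cassettes, sequencing or
assembly error. Recovery rates on simulated data are therefore upper
bounds: they validate the logic of the methods, not their robustness to
noisy annotation on real assemblies.

## Problem sizes and checks

The test suite runs desk-scale scenarios (240-gene hybrids) for most
stages, the full study-scale scenario (2,000-gene hybrid) once for
end-to-end recovery, a 200 × 500-codon calibration of the K<sub>S</sub>
estimator, the exhaustive 61 × 61 NG86 oracle, a 1,000-trial
junction-signature inverse-property check, and an independent
Smith–Waterman dynamic-programming oracle on short peptides.
`scripts/acceptance.py` recomputes the HO overhang length on a synthetic
60-bp duplex and the event estimate for 34 observed breakpoints.

## Known limitations

- The whole-chromosome majority-background rule cannot see an LOH tract
  whose class matches its chromosome's majority (e.g., after heavy
  recombination); a segment-wise background would be needed on real data.
- Adjacency-based breakpoint counting does not register a rearrangement
  whose flanking genes lost their mapped status (LOH, unannotated genes),
  and counts a chromosome-splitting translocation as at most one break per
  affected adjacency — dot-plot inspection remains useful on real genomes.
- K<sub>S</sub> of frameshifted genes is computed over a pseudogene-mode
  translation and can be overestimated; labels of disabled genes are
  correspondingly less reliable than those of intact genes.
- X/Z discovery assumes near-identical repeat copies on the forward strand
  (true of the simulated architecture and of the real, recently formed
  cassettes); diverged or inverted cassettes would need probe mode.
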