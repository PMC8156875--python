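# Methods

This note documents the models, parameter choices and numerical decisions
behind `ervscribe`, and what the synthetic-data tests do and do not show
about real genomic data.

## Synthetic data model

The generator produces the study conditions every downstream stage is
tested under.

**Ancestral provirus.** A 9,546-nt sequence with the canonical layout
(LTRs 897 bp each; gag 1056–2924, pro 2882–3929, pol 4010–6487,
env 6701–8647; gag/pro overlap 43 nt). The 5' LTR is generated once and
copied to the 3' interval, so the LTRs are byte-identical as they are at
integration. Composition is AT-biased (target 0.60, matching the AT
enrichment characteristic of HERV-K internal sequences) and CpG-depleted:
the probability of G following C is scaled by 0.25 (first-order Markov
draw, with the input composition calibrated so the chain's stationary AT
fraction still hits the target). The depletion mirrors real genomic and
retroviral sequence, where methylated CpGs decay quickly; it is also what
makes decades-old elements still align at ≥90% identity — with independent
draws ~8% of sites sit in CpGs and, under 10× hypermutation, a 40-My-old
element would fall to ~88% identity, which contradicts the catalogued
elements' observed ages (up to ~47 My at ≥90%).

**Substitution process.** Single-draw model: over `t` My each site differs
from its ancestral state with probability `1 − exp(−r·t·m)`, where
`r = 0.002`/nt/My (the human neutral rate used throughout) and `m` is the
CpG multiplier (default 10) for sites inside an ancestral CpG. Mutated
sites transition (A↔G, C↔T) with probability κ/(κ+1), κ = 2 by default,
else take one of the two transversions uniformly. No indels arise from the
substitution process; deletions are explicit configured reference
intervals, because the analyses treat indels as discrete annotated events.
Consequence of the single draw: the observed divergence is
`q = 1 − exp(−r·t)` rather than `r·t`, so clock estimates read ~2–4% low at
20–40 My. This is inherent to the stated model, small against the
estimator's tolerance, and documented rather than corrected.

**Solitary LTRs.** Recombination between the two LTRs of one (evolved)
provirus: the product is the 5' copy's prefix joined to the 3' copy's
suffix at a uniform breakpoint (the breakpoint distribution is not known;
uniform is the maximum-entropy choice). `breakpoint=0` degenerates to the
3' copy.

**Planting.** Elements are assigned to chromosomes multinomially by length
(the null model of the distribution stage — the assignment routine is
shared with the type-I calibration test), placed uniformly without overlap,
on random strands, in uniform-composition background. One guard: the
single background base on each side of a planted element is resampled if it
would continue the reference context (the LTR is a sub-span of the
reference, so a chance-matching neighbour — probability 1/4 per side —
would make the element boundary genuinely ambiguous; real integration
boundaries are not reference continuations). This is what makes exact
boundary recovery at age 0 a well-posed requirement.

**Ortholog matrix.** A locus is present in a panel species iff the
species' divergence time ≤ the locus's age; presences can be flipped with a
loss probability (modelling solo-LTR conversion or deletion during
speciation). Panel defaults: chimp 6, gorilla 9, orangutan 16, gibbon 20,
rhesus 30, marmoset 43, squirrel monkey 43 My. Gibbon and rhesus are the
two times the analysis actually hinges on; the others are field-standard
defaults and configurable per study.

## Catalog

Candidates (provided as BED, or found by the k-mer scanner on synthetic
genomes) are extracted with 500-nt flanks and classified against the
reference: global affine alignment (match 2, mismatch −3, open −5,
extend −2) with free end gaps; identity = matches / aligned columns with
terminal gap runs excluded (the denominator convention is not standardized
in the literature; internal gaps count, end gaps do not). Elements under
90% identity to both the full reference and the LTR are rejected; an
element matching the LTR at ≥90% but covering <5% of the internal gag..env
span is a solitary LTR; anything else is a provirus. The two thresholds are
exposed because published curation does not state whether the cutoff was
applied per-element or per-feature. Identity is computed with the pair in
canonical order so the metric is exactly symmetric despite co-optimal
alignments.

The scanner chains exact 25-mers per alignment diagonal, discards chains
with <3 seeds (dropping chance matches at element boundaries) and merges
overlapping chains (a provirus also seeds the duplicated-LTR diagonal). It
is a synthetic-genome convenience, not a BLAT replacement: on real genomes
candidate coordinates should come from a proper search tool.

## Chromosomal distribution

Expected counts `e = C_l · n / T_l` over chr1–22, X, Y (alternates and
unplaced contigs excluded; Y included in the total by default, with the
option to drop it). Raw expectations sum to n exactly; rounding is for
display only. Each chromosome gets a one-cell chi-square (O−E)²/E with a
two-sided df=1 p-value, flagged at α = 0.05 and 0.005; no multiple-testing
correction by default (a Bonferroni switch exists) — this mirrors the
per-chromosome testing practice the quoted significance levels come from.
Under the multinomial null the exact type-I rate of this test is 3.9% for
GRCh38-sized chromosomes with n = 183 (count discreteness keeps it under
the nominal 5%); the calibration test asserts the empirical rate in
[2.5%, 6.5%].

Gene context comes from a Gencode-dialect GTF (gene/exon features,
`gene_name` attribute) or BED12: overlap with a gene body but no exon →
intronic; any exon → exonic; ties broken by largest overlap; orientation is
sense iff strands agree. Centromere context uses UCSC cytoBand acen bands:
overlap → centromeric; within 5 Mb of an acen boundary or in the adjacent
band → pericentromeric.

## Structural annotation

Loci are anchored to the reference by global affine alignment with cheap
end gaps on the locus (open −5, extend −0.1/nt). Truly free end gaps are a
trap here: because the reference carries a duplicated segment (the LTRs),
the optimizer can skip a large reference prefix at zero cost instead of
paying for an internal deletion, producing a higher-scoring but biologically
wrong alignment; a small end-gap cost (~20× cheaper than internal gaps)
keeps truncations inexpensive while making the honest alignment optimal.

Indels are maximal gap runs; runs separated by ≥1 aligned column are
distinct events; runs touching an alignment end are flagged terminal
(truncations). Events are normalized to their left-most equivalent
placement — when the base before a deletion equals its last base, both
placements yield the same sequence and the choice is otherwise arbitrary.
The round-trip oracle (re-applying annotated indels to the reference)
reconstructs the query exactly for substitution-free variants.

Recurrent deletions cluster by transitive reciprocal overlap ≥80%, reported
when ≥3 loci support a cluster, with median consensus intervals. Gene
integrity is per-feature coverage (aligned reference positions / feature
length); LTR presence at ≥50% coverage; structural class complete ≥0.95,
near-complete ≥0.80 overall coverage, else defective. ORF statistics:
translation in the frame fixed by the feature start on the reference;
internal stops exclude the final codon; frameshifts are non-multiple-of-3
indel events inside the gene. Protein-domain prediction is out of scope by
design (it required external tools in the original workflow); the CCHC
zinc-knuckle regex on the translated gag region is the only sequence-level
motif call. Gene-boundary frames map to the {0, −1, +1} notation via
{2→0, 0→−1, 1→+1} from the start-offset difference mod 3 — the mapping is
calibrated so the reference layout reproduces the group's published "0/−1"
pattern, since the printed coordinates and the textbook frame convention
disagree about which boundary is the readthrough.

## Phylogenetics

Distances on a fixed alignment with pairwise deletion (sites gapped or
ambiguous in either sequence dropped per pair): p-distance and K2P
(−½ln(1−2P−Q) − ¼ln(1−2Q); saturated pairs, log argument ≤0, become
NaN-flagged entries that NJ refuses). Neighbor joining is canonical
(Q-matrix, standard branch lengths, negatives clamped to 0) with
deterministic tie-breaking by the lexicographically first canonical label
pair (a node is labelled by the smallest leaf name in its subtree); NJ
recovers topology and branch lengths exactly from additive matrices, which
the tests verify against an independently generated random-tree oracle and
against dendropy's NJ. Bootstrap resamples columns with replacement;
support of an internal edge is the percentage of replicates containing the
same bipartition (canonical form: the side not containing the first-sorted
taxon). Monophyly is a bipartition membership test. Maximum-likelihood
trees are deliberately out of scope — they would not change the monophyly
question.

## Age estimation

Components per locus: each LTR and each gene region (gag–pro as one block —
the two genes overlap and are listed as one region; pol; env) against the
group consensus, plus the LTR–LTR divergence halved (each LTR accumulates
mutations independently). The consensus is per-column majority with gap as
a state and ties resolved A<C<G<T<gap; with ≥10 members it recovers the
ancestral state at >99% of non-CpG sites, which is why it can stand in for
the ancestor. Components with region coverage <50% are skipped a priori.
D is a proportion and the rate 0.002 is per-site per-My, so T = D/0.002 is
in My (dimensional analysis fixes the unit question).

CpG exclusion: columns inside a CpG are dropped. For a generic pair the
CpG set is read from either sequence; for the consensus components the CpG
mask is read from the consensus only (the ancestral-state proxy). The
either-sequence rule is kept as the generic default but is biased when used
against an ancestral reference: substitutions create new CpGs next to
existing C/G neighbours, so masking on the mutated sequence preferentially
discards mutated sites and underestimates divergence (~12% at these
parameters). With the consensus mask the cohort-recovery bias is about
−4%, dominated by the single-draw saturation noted above.

"SD > 20%" trimming is interpreted as relative SD (sample SD / mean) with
iterative removal of the component farthest from the median while more than
two remain; if two components still disagree the locus is flagged
unreliable and its age withheld (this operationalizes the manual exclusion
of the divergent centromeric locus as an automatic rule). A single
component is reported as-is with undefined SD.

OCA inference: the present species with the largest divergence time; the
age window runs to the next older speciation (open-ended past the oldest
panel species); younger absences are reported as lineage-specific losses.
Consistency: clock age ≥ lower window bound × (1 − 0.25); the 25% slack
absorbs clock noise at the window edge.

## Pipeline

Stages run in dependency order with per-stage seeds derived from one config
seed (SeedSequence spawning), inputs checksummed so re-running unchanged
stages is a no-op, and a summary JSON echoing seeds and thresholds. The
YAML config is schema-validated (unknown keys rejected). The phylo stage
builds its alignment by projecting anchored loci onto reference
coordinates (insertion columns dropped) — exact for the simulator, which
introduces no indels by default — and adds deeply diverged outgroup
stand-ins for the sister groups; the age stage reuses the same projection.

## Problem sizes and what the tests show

Default test cohorts are 6–12 planted elements on ~0.1–0.3 Mb toy
chromosomes, 50-locus cohorts for clock recovery, 8-taxon trees for the NJ
oracle, 100–200 bootstrap replicates, and 500 simulated genomes for the
chi-square calibration — sizes chosen so the whole suite runs in about a
minute while keeping every statistical check well-powered.

The synthetic path demonstrates internal correctness: that the estimators
recover what the generator planted under the stated model. It does not
demonstrate robustness to what the generator omits: alignment error on
diverged real sequences, segmental duplications and assembly gaps,
insertion-site preference, selection, gene conversion between LTRs (which
rejuvenates LTR–LTR ages), rate variation across loci, or indel-rich
evolution. Real-data use should treat the catalog thresholds and the clock
slack as tunable and re-examine loci flagged unreliable by trimming.

## Known limitations

* The scanner requires near-exact seeds and is not a substitute for a real
  homology search on diverged genomes.
* The clock assumes one neutral rate for all loci and sites outside CpGs;
  no per-lineage calibration or site-bootstrap confidence intervals.
* The solitary-LTR per-chromosome fixture interpolates the unpublished
  appendix counts length-proportionally (three chromosomes are fixed by the
  published statements); per-chromosome solo counts other than those three
  are synthetic stand-ins.
* K2P distances are undefined for saturated pairs; such pairs block NJ by
  design rather than being imputed.
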