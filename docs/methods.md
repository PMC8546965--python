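# Methods

This note documents the models, conventions and design choices behind
`gcfkit`, in the order the pipeline runs them, followed by the simulator
that defines the test conditions, the numerical choices, and known
limitations.

## Genome model and GenBank conventions

Internally every interval is 0-based half-open on the forward strand; gene
sequences are stored on the coding strand (minus-strand CDS are
reverse-complemented on read). All user-facing coordinates — frameshift
positions in particular — are reported 1-based, the convention of sequence
viewers and the variation literature. GenBank round-trips are exact:
`read(write(record))` reproduces every gene, domain and label.

Standard GenBank has no qualifier for a protein domain with a substrate
prediction, so domain annotations travel in a custom CDS qualifier:

    /domain_annotation="<type>|<aa_start>|<aa_end>[|<specificity>]"

with amino-acid half-open coordinates on the gene's translation.
antiSMASH-style `aSDomain` features (with `protein_start`/`protein_end`/
`specificity` qualifiers) are also accepted on read. Ambiguity codes other
than N are mapped to N with a logged count; compound (origin-spanning)
locations are rejected — genomes are handled linearized.

`normalize_strain_fields` appends the `strain` qualifier to the organism
name when missing (idempotently): downstream MLSA and network tools need
distinct organism labels per isolate.

## Region splitting

Region detectors merge clusters that lie close on the chromosome. Given
reference panels for a left and right boundary gene, every region gene is
aligned against every panel sequence — global alignment with free end gaps,
scoring match +1, mismatch −1, gap open −5, gap extend −1 — and a gene is a
boundary hit when identity (over aligned core columns, end gaps excluded)
and coverage (aligned fraction of the reference) both reach the thresholds,
default 0.90/0.90. With exactly one left hit L upstream of one right hit R,
the region is cut so that *both* children retain the L..R span (the
intersection of the two clusters); a disjoint midpoint cut is available via
`overlap=False`. Zero or multiple hits per panel, or R before L, leave the
region whole with a logged reason — multiple hits would otherwise cut the
cluster twice. Splitting is idempotent: a child never splits again.

Whether the original search was nucleotide- or protein-level is not
specified anywhere we could anchor it; we compare nucleotide sequences,
since boundary genes are recent homologs at high identity.

## BGC similarity and gene cluster families

Pairwise similarity of two regions uses three domain-based components in
the style of cluster-similarity networks:

* **Jaccard (J)** — shared / union of domain *types*;
* **adjacency (AI)** — Jaccard over the sets of unordered adjacent
  domain-type pairs along each region's domain order (genes in genomic
  order, domains in translation order);
* **domain sequence similarity (DSS)** — same-type domain copies are
  greedily matched by descending protein identity; the score is the summed
  identity of matched pairs divided by (matched pairs + unmatched copies),
  so missing copies dilute the component.

`distance = 1 − (0.2·J + 0.7·DSS + 0.1·AI)`, all weights configurable. The
published class-specific weight sets of network tools differ; numeric
parity with any of them is a non-goal, and the anchor-domain concept is
omitted. Greedy matching equals the optimal assignment whenever each copy
has a clear best partner — true for orthologous copies within a family, and
asserted in the tests on simulated data.

Families are the **connected components** of the graph with edges at
`distance ≤ 0.30`: a deliberate transitive closure, because thresholding
alone splits families along species lines even for compounds present in
every species; intermediate members re-join them. Exact duplicate regions
(identical gene-name arrays and sequences) collapse to one node before the
all-pairs comparison and re-expand afterwards. Families are ordered by size
then smallest member id; `gcf_id` is `<rank>_<majority product class>`.

DSS identities use a unit-cost global alignment (edlib bit-parallel
Needleman-Wunsch; identity = 1 − ed/max(len)): exact for substitution-only
divergence and within ~1 point of scored-alignment identity at the
identities where decisions happen, and fast enough for the all-pairs scan.

## MLSA phylogeny

Orthologs group by exact gene-name match; unnamed genes join the first
family whose seed they match at ≥ 0.80 nucleotide identity (greedy, input
order). Among families present single-copy in every genome, the 30 with the
lowest mean pairwise p-distance are kept (ties by name). Each family is
aligned by center-star (the center minimizes summed pairwise distance;
pairwise alignments merge under "once a gap, always a gap") — adequate for
high-identity single-copy orthologs, not a general MSA — and columns with
gap fraction > 0.5 are removed. Alignments are concatenated; pairwise
p-distances use pairwise deletion (both rows ungapped) and the Jukes-Cantor
transform d = −¾·ln(1 − 4p/3), saturating to d = 5.0 at p ≥ 0.7499.

The tree is built by neighbor joining (Saitou-Nei Q criterion). Likelihood
tree search was deliberately replaced: the tree's role here is clade
structure for mapping families, and NJ is exactly testable — on any
additive matrix it provably recovers the generating topology, which the
test suite exercises against 50 random additive matrices and against an
independent NJ implementation. Ties in Q resolve to the smallest index
pair; negative branch lengths are clamped to zero with the deficit moved to
the sister branch.

Bootstrap supports: the concatenated alignment is column-resampled with
replacement (seeded; default seed 42), each replicate re-enters the full
distance+NJ path, and every internal bipartition of the point tree is
labeled with the fraction of replicates containing it. The point tree is
rerooted on the edge above the outgroup's most recent common ancestor
*before* support annotation (supports are split properties and must not be
displaced by rerooting); rerooting is idempotent.

## Occurrence matrix

`cell[strain, family]` counts the family's member regions from that strain
(post-splitting), so the grand total equals the number of regions. For
display, columns are ordered by average-linkage hierarchical clustering on
Jaccard distance between binarized presence vectors (dendrogram leaf
order; columns pre-sorted by id so ties are deterministic) — a manual
arrangement step cannot be tested, so a deterministic order replaces it,
with a user-supplied order always possible downstream. Rows follow the
tree's leaf order when a tree is given.

## Within-family variation

**Completeness groups.** Each member region's core genes are detected by
the same ≥ 90 % identity / ≥ 90 % coverage homology rule used for boundary
genes; members group by identical missing-gene sets. No missing genes →
`complete`; 1–3 missing → `missing:<sorted names>`; more than 3 →
`others`, mirroring the observation that labeled partial groups miss at
most three biosynthetic genes. Grouping by missing-gene profile is a
proxy for grouping by sub-network structure; the two coincide on clean
clade-conserved deletions.

**Iturinic classification.** The ordered adenylation-domain substrate
predictions are read across the region (genomic order); fewer than 7
predictions → `others` (iturinic products carry 7 amino acids), an exact
7-residue match against the signature table → that product, otherwise
`unclassified`. The signature table
(`src/gcfkit/data/iturin_signatures.tsv`) is editable data, not code; the
shipped defaults are compiled from the published amino-acid compositions of
iturin A, bacillomycin D/F/L and mycosubtilin and should be adjusted to the
prediction vocabulary of the annotation tool in use.

**Frameshift detection.** Query and reference genes are aligned globally
with affine gaps (same scoring as above; a fast gap-free screen via edlib
first skips the scored alignment when there are no indels at all).
Alignment identity below 0.70 raises a not-homologous error rather than
producing nonsense calls. Contiguous indel runs are left-normalized — each
run shifts left while the reference base before the run equals the run's
last base, the standard variant-normalization convention, chosen because
reported single positions do not otherwise pin down a convention — and runs
with length not divisible by 3 become calls at the 1-based reference
position of the first gap column. In-frame indels are logged, never
called. Each call carries the query's frame-0 translation to the first stop
and the reference domains not fully contained in the in-frame prefix
before the shift (`lost_domains`).

**sfp screen.** Per genome, the gene named `sfp` (or, failing that, the
best ≥ 90 %/≥ 90 % homolog of the reference) goes through frameshift
detection; genomes with no homolog get a marker distinct from "intact", so
absence and intactness are never conflated.

## The simulator

The generator emulates the input of a desk-scale comparative study:

* a clade-structured random tree — uniform labeled topologies within each
  clade and over the clade backbone, exponential branch lengths with
  backbone stems drawn 3× longer, scaled so the mean ingroup root-to-tip
  path equals `substitution_rate` (default **0.04** substitutions/site, a
  realistic within-species-complex divergence), floored at one tenth of
  that so every branch is recoverable; an outgroup leaf at 1.5× divergence;
* 30 housekeeping genes (450–900 nt) plus standalone `sfp`, evolving by
  Jukes-Cantor substitution: per branch, Poisson(b·L) events at uniform
  positions, uniform among the three other bases — exactly the process the
  JC distance inverts;
* 6 BGC family blueprints (plipastatin- and fengycin-like five-gene NRPS
  loci with module-dense megasynthetase genes, surfactin, an iturinic
  NRPS/PKS hybrid whose 7 ordered A-domain substrates spell the
  mycosubtilin signature, a trans-AT PKS, a terpene cluster); family gene
  sequences evolve under the same substitution process with domain
  coordinates carried through;
* planted events applied on a named clade's ancestral branch and inherited
  by all descendants: whole-gene deletions, fixed-position frameshift
  indels, whole-family losses, and horizontal gains that copy the family's
  ancestral sequence to one recipient leaf.

Default study conditions (`default_config`): 16 strains in 4 clades,
6 families, the *ppsD* deletion (clade C2), the *fenE* deletion (C4), the
single-base *ppsE* deletion at position 232 (C3), the 2-base *fenD*
deletion at positions 3126–3127 (C2), and one iturin transfer into C4.

Two deliberate simulator choices keep planted coordinates identifiable:
frameshift sites are placed in non-homopolymer context (so leftmost
placement equals the planted coordinate; a flag allows homopolymer
placement to exercise the ambiguity path), and substitutions are masked in
a ±4 nt window around planted indels so alignment context cannot move the
call by a base. NRPS genes are module-dense (6–7 domains each) as in real
megasynthetase loci; this matters, because family cohesion under the DSS
unmatched-copy penalty depends on how much of a region's domain content one
gene carries.

What the simulator does **not** emulate: realistic base/codon composition,
GC skew, rearrangements, within-gene recombination, annotation noise, or
assembly artifacts. Passing tests therefore demonstrate the correctness of
the algorithms under a known substitution-and-event model — not robustness
to the full messiness of public genome records.

## Numerical and determinism choices

* Tie-breaking is lexicographic/smallest-index everywhere (Q criterion,
  family ordering, greedy matching, clustering column order); all
  stochastic steps take explicit seeds; simulator and pipeline reruns are
  byte-identical (GenBank dates are pinned).
* JC saturation: p ≥ 0.7499 maps to distance 5.0.
* Negative NJ branch lengths: clamped to 0, deficit moved to the sister.
* Homology floor for frameshift alignment: 0.70 identity (ours; prevents
  calls on non-homologs).
* Bulk homology scans (completeness, sfp search, boundary-gene prefilter)
  use unit-cost edlib alignments; the scored affine aligner confirms
  boundary hits and places frameshift gaps.
* All-zero presence columns get Jaccard distance 0 by convention.

## Limitations

* Desk-scale only: the pipeline is validated on simulated strain sets; at
  hundreds of genomes the all-pairs similarity scan is the quadratic
  bottleneck and would need blocking or sketching.
* Center-star alignment degrades on low-identity or highly gapped
  families; it is fit for purpose only because MLSA genes are conserved
  single-copy orthologs.
* Connected components inherit the usual failure mode of single-linkage:
  one spurious edge can bridge families; the cutoff is the only guard.
* A-domain substrate prediction itself is out of scope — specificity
  strings are consumed as annotations, not computed from sequence.
* The frameshift caller reports one alternative translation per gene (from
  frame 0); compound events restoring frame downstream are reported as
  separate runs, with the reading-frame algebra left to the caller.
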