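# Methods

`pksurvey` re-implements, as a tested and reusable pipeline, a metagenomic
survey of type I polyketide synthase (T1PKS) ketosynthase (KS) domains:
detection and top-hit classification of KS domains, full-length extraction,
operational biosynthetic unit (OBU) clustering with richness estimation,
biome composition ordination and testing, degenerate-primer in-silico
evaluation, and an amplicon-truncation concordance experiment. This note
records the model and procedure each stage implements, the parameters that
matter, and the design choices made where the design was genuinely open.

## Domain detection and classification

Query peptides (read directly, or obtained by six-frame translation of
nucleotide contigs ≥ 600 nt) are searched against a labeled KS reference
collection by optimal local alignment (Smith–Waterman). Scoring is
blastp-like: BLOSUM62 with affine gaps costing 11 to open plus 1 per
residue. Bit scores use fixed gapped Karlin–Altschul constants
(λ = 0.267, K = 0.041) and E-values the standard E = m·n·2^(−bits) with
m the query length and n the total residues in the reference collection.
When an external aligner's 12-column tabular output is supplied instead,
its printed E-values are trusted verbatim.

A domain call requires an alignment spanning **≥ 200 aa** with
**E ≤ 10⁻³⁰** — the survey's operating point for full-length-scale
detection. The winning reference (highest raw score; ties broken by
identity, then lexicographic id — with a fixed search space, score order
equals bit-score and E-value order) supplies the leaf classification.
The 11-class leaf vocabulary (modular cis-AT, cis-loading module, olefin
synthase, iterative aromatic, iterative PTM, trans-AT, hybrid trans-AT,
hybrid cis-AT, PUFA, enediyne, FAS) maps deterministically onto coarser
functional groups (cis-AT / trans-AT / iterative cis-AT / FAS) and onto the
five similarity-network groups used for composition and primer analyses
(cis-AT/iterative, hybrid cis-AT, trans-AT, PUFA, enediyne, plus FAS).

Multimodular PKSs carry tandem KS domains, so several calls per peptide are
allowed: after each accepted call the called interval is masked with `X`
and the search repeated; a further hit is accepted only if it overlaps every
earlier call by less than half of the shorter interval. How a production
web tool resolves overlapping hits is not observable from the outside; this
50%-overlap greedy rule is this package's own convention.

Taxonomy: each domain receives the phylum of the closest reference by
E-value (ties: higher identity, then id). Matches below 75% identity are
flagged *tentative* — at that distance a phylum label is a hint, not an
assignment.

`X` (ambiguous residue) aligns with ordinary BLOSUM62 scores but **never**
counts as an identity, in classification or clustering.

## Full-length extraction

Reference-quality type I KS domains begin with the IAIVG motif and end with
GTNAH, roughly 420 aa apart. A called domain is *full length* when a start
anchor occurs before an end anchor within the called interval; the sequence
is clipped from the first anchor residue through the last. Because these
positions show some natural degeneracy, each 5-residue anchor tolerates up
to `max_mismatch` substitutions (default 1, configurable 0–2; 1 admits a
conservative substitution without admitting noise). The best (fewest
mismatch) window wins; ties go leftmost for the start anchor and rightmost
for the end anchor, which also selects the longest spanning pair.

## OBU clustering and richness

Full-length domains are grouped into OBUs — the biosynthetic analogue of
OTUs — at amino acid identity thresholds 0.70 / 0.80 / 0.90 / 0.95.
Identity is **matches / alignment columns under global alignment**, with
gap columns (terminal gaps included) in the denominator; full-length domains
are homologous end to end, so a global definition is the appropriate one.
Clustering is greedy-incremental in the style of common centroid
clusterers: sequences are visited in order of decreasing length (ties by
id) and join the first existing centroid, in founding order, with identity
≥ threshold, else found a new cluster. A cheap length-ratio bound
(min/max < threshold ⇒ identity cannot reach threshold) skips hopeless
alignments; it is exact, not heuristic.

Richness per biome: rarefy to a common depth (default 580 sequences, the
survey's smallest-biome convention; the depth auto-lowers with a warning
when a biome is smaller, as synthetic runs usually are), cluster, and
compute bias-corrected Chao1,

    S_chao1 = S_obs + F1(F1 − 1) / (2(F2 + 1)),

with F1/F2 the singleton/doubleton OBU counts, averaged over 10 replicate
rarefactions (mean ± sd reported).

Between-biome overlap: all biomes are rarefied to the common depth, pooled,
and clustered **once** per threshold; an OBU is shared by a biome pair when
it holds at least one member of each, and the shared-domain count sums the
pair's members in such OBUs. Pooled (rather than per-pair) clustering keeps
every pairwise comparison on one consistent partition.

## Composition statistics

Per-metagenome KS-class profiles come in three modes: raw counts, counts
per Gbp of metagenome (given a manifest of sizes), and rarefied mean counts
(each metagenome rarefied to 100 calls, averaged over 1,000 permutations;
sampling without replacement is multivariate hypergeometric and is sampled
directly). Permutation means are kept fractional; metagenomes below the
depth are excluded with a warning rather than up-sampled.

Downstream: Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); PCoA by
eigendecomposition of the Gower double-centered squared-distance matrix,
with coordinates scaled by √eigenvalue on positive axes, negative
eigenvalues reported unchanged and excluded from the proportion-explained
denominator (no Lingoes/Cailliez correction); PERMANOVA with
SS_total = (1/N)Σ_{i<j}d²ᵢⱼ, within-group sums analogously,
pseudo-F = (SSB/(g−1))/(SSW/(N−g)), R² = SSB/SS_total, and
p = (#{F_perm ≥ F_obs}+1)/(P+1) under free whole-sample label permutation
(999 by default, no strata). Per-class biome contrasts use one-way ANOVA
followed by Tukey's HSD, flagged at α = 0.01. ANOVA/Tukey are delegated to
scipy; PCoA and PERMANOVA are implemented here because the package pins
exact conventions (negative-eigenvalue handling, R² definition) and are
cross-checked against scikit-bio in the test suite.

## Primer evaluation

A degenerate primer (IUPAC codes) is translated into an ordered
amino-acid-set pattern: reverse primers are reverse-complemented first, a
trailing partial codon is right-padded with N, each codon expands to the
amino acids of its concrete expansions, and stop codons are dropped (a
position encoding only stops is an error). The bundled pair is KS2F
5′-GCNATGGAYCCNCARCARMGNVT-3′ → AMDPQQ(RS)(ILMV) and KS2R
5′-GTNCNNGTNCCRTGNSCYTCNAC-3′ → VE(AG)HGT(CGRSW)T; set members render in a
fixed canonical order, and `patterns_equivalent` compares renderings
set-wise so alternative orderings of the same sets compare equal. Further
primers (e.g. a PUFA-specific set) are supplied as config, since only their
translated behaviour matters here.

The pattern is placed on each domain by a sliding window maximizing the
number of positions whose residue falls in the position's set (leftmost on
ties; below 50% matched anywhere the placement is flagged low-confidence).
Profiles report, per KS group, the per-position match fraction, the
all-positions-simultaneously fraction, and each position's codon offset
from the primer's 3′ end (for a reverse primer, pattern position 1 is the
3′-proximal codon) — both readings matter because amplification failure is
dominated by 3′-proximal mismatches. Candidate rescue modifications (e.g.
also targeting H and E where the pattern has Q) are evaluated by enlarging
position sets and re-profiling; enlarging a set can never lower a match
fraction at a fixed placement.

## Amplicon-truncation concordance

Full-length domains are trimmed to a next-generation amplicon length
(default 138 aa), either starting at the located KS2F site (with a centered
fallback when no confident site exists — default) or centered, and
re-classified. The 200-aa match floor cannot apply to a 138-aa query, so
trimmed re-classification lowers it to 100 aa (logged in run manifests).
Concordance is the fraction of domains keeping their leaf label, per group
and overall; a trimmed sequence yielding no call counts as discordant.

## Synthetic data: what it emulates and what it does not

The generator builds the whole study world with truth labels:

* **Reference collection** — per leaf class, an unrelated random base
  domain (IAIVG…GTNAH, 420 aa) and 8 lineage seeds mutated from it at 82%
  identity, leaving within-leaf lineages ~60–65% identical and cross-leaf
  identity at random background (< 40%, typically ~10%). Shipped at a
  pinned seed as `data/synthetic_reference.faa` (+ metadata TSV), labeled
  synthetic: anchors, label structure and identity geometry are faithful;
  absolute sequence content is not, so absolute counts are never comparable
  to real-database results.
* **Environmental domains** — leaf labels drawn from per-biome mixture
  weights; each sequence mutates a lineage seed to a controlled identity
  (substitutions only, outside the anchors, BLOSUM62-weighted proposal), so
  realized identity is exactly (L−k)/L and the optimal global alignment is
  the unique gapless diagonal. A `full_length_fraction` subset keeps both
  anchors; the rest lose one by truncation.
* **Biome profiles** — eight bundled mixtures qualitatively mirroring the
  field's pattern (marine biomes enriched in PUFA and enediyne KSs, soils
  in modular and hybrid cis-AT); the exact weights are this package's
  illustrative choice, not measurements.
* **Contigs** — back-translation with uniform synonymous codons plus random
  flanks exercises the six-frame path.

Not emulated: insertions/deletions within domains, sequencing error,
assembly artifacts, genuine phylogenetic covariance between leaf classes,
and database incompleteness. Passing tests therefore demonstrate that the
pipeline's logic is correct under controlled identity structure — not that
a particular real biome will behave identically.

## Numerical choices and degenerate inputs

* Gap model 12/1 (open 11 + extend 1 in blastp convention) everywhere;
  oracle tests pin it.
* Deterministic tie-breaks throughout: top hits (score → identity → id),
  anchor windows (leftmost/rightmost), greedy clustering (length → id,
  first-centroid-wins), primer placement (leftmost).
* All randomness flows through explicitly passed or seeded
  `numpy.random.Generator`s; identical seeds give byte-identical tables.
* Degenerate inputs raise early: empty sequences, empty reference
  collections, all-zero composition rows, groups with < 2 members,
  identical-value ANOVA, rarefaction deeper than the pool.
* Chao1 of an all-distinct sample (all singletons) is finite because the
  bias-corrected form divides by F2+1.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the survey at desk scale: a
33-entry reference (3 lineages per leaf), 200-sequence recovery and
concordance sets, 8 metagenomes × 25 sequences per biome for the
separation experiment, pooled clustering capped at 60 domains per biome,
and composition rarefaction at depth 20. These sizes were chosen once as
the smallest conditions under which the method's statistical behaviour
(recovery ≥ 95%, concordance ≥ 90% at 138 aa, PERMANOVA separation with
R² > 0.5, zero cross-biome OBU sharing at 0.90) is stable across seeds.

## Known limitations

* The built-in aligner's E-values use fixed Karlin–Altschul constants, not
  per-search estimated ones; they are internally consistent but not
  interchangeable with BLAST's to the last digit.
* Greedy centroid clustering is order-dependent by design (deterministic
  here); it reproduces the style, not the k-mer heuristics, of production
  clusterers.
* On essentially unrelated sequence pairs the optimal global alignment may
  be non-unique and identity can differ by ~0.01 between equally optimal
  alignments; this is irrelevant at clustering thresholds (≥ 0.70) but
  means reported identities far below threshold are alignment-convention
  dependent.
* Six-frame translation is a plain frame scan with stop-codon splitting,
  not gene calling; peptide coordinates are reported 1-based on the forward
  strand.
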