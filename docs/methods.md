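# Methods

`plumhap` implements the inference chain from dominant multi-allelic PCR-band
genotypes of the duplicated *MYB10* gene cluster of Japanese plum (*Prunus
salicina* hybrids) to phased haplotypes, panel diplotype calls, gene copy
numbers, and a fruit-colour prediction rule, together with the supporting
sequence-diversity and read-depth statistics.  This note describes the models,
the decision rules and their assumptions, the synthetic-data generator that the
tests exercise the pipeline on, and the limitations of both.

## Data model

A *band* is a PCR amplicon of characteristic size scored present/absent on a
capillary electrophoresis profile.  Bands behave as dominant alleles: one copy
and two copies are indistinguishable.  A *haplotype* is the set of bands
co-transmitted on one chromosome; a diploid accession displays the union of its
two haplotypes (its *diplotype*).  The cluster contains three tandem *MYB10*
genes (homology groups G1–G3 for *MYB10.1/10.2/10.3*); because amplification
uses one conserved primer pair, alleles of all copies appear in one profile.
One band (a466, the G2 allele) is monomorphic — present in every accession and
every haplotype — and therefore uninformative for phasing but required in every
haplotype by invariant.

Fragment sizes from a GeneMapper-like table are binned to the band registry
within a tolerance (default ±0.5 bp).  Two fragments landing in one bin give a
single band call plus a collision warning; this models hidden alleles that
co-migrate (a real example: a 467-bp G1 allele hidden under the 466-bp
monomorphic band).  Registry bands closer than twice the tolerance are a
configuration error.

Colour descriptors are recoded to a binary anthocyanin trait: skin red, purple
and black are presence; mottled, yellow and green absence.  `pale_red` is not
covered by that published rule; the default maps it to presence (it is an
anthocyanin hue) behind a config switch.  Flesh red and purple are presence.

All genomic coordinates are 0-based half-open internally; 1-based inclusive
text (region strings, depth tables) is converted exactly once at parse time.

## Family phasing

The principle is the one the marker system affords: two bands on the same
parental chromosome are co-transmitted, so their presence patterns across an F1
family agree; bands on opposite chromosomes of one parent complement each
other.  The cluster is treated as non-recombining (a safe assumption at these
physical scales and family sizes), so each parent's informative bands 2-colour
into at most two haplotypes.

Observed progeny frequencies are classified against Mendelian expectations for
dominant bands — ~0.5 for a band heterozygous in one parent, ~1.0 (minus
dropout) for a band transmitted always.  The decision boundary between the two
(`0.85`) sits nearer the upper hypothesis because realistic per-band dropout is
a few percent while the alternative is 50%; both misclassification tails are
then negligible at family sizes of 30–110.  Bands below frequency 0.25 that a
parent supposedly carries are flagged rather than phased.  Progeny bands absent
from both parents are reported as genotyping errors with the offending progeny
listed; they never enter haplotypes.

Phase assignment between informative bands uses majority agreement (same phase
when patterns agree in > 50% of progeny, anti-phase otherwise), followed by a
consistency check of the full signed graph; an unbalanced graph raises a
`PhasingConflict` naming the band pairs and discordant progeny.  The `epsilon`
parameter (default 0.05) flags noisy pairs whose discordance exceeds it without
changing the call.

Bands carried by both parents cannot be phased from parental origin, so they
are conditioned on the phased backbone: each progeny is assigned to the
parental haplotype whose informative-band pattern it matches, and a shared band
that is always present on exactly one backbone belongs to that haplotype.  If
both backbones always show it, the other parent guarantees transmission and the
family genuinely cannot localise the band; it is recorded as *ambiguous* on
both haplotypes rather than guessed.  A parent with no heterozygous informative
band is a homozygote and contributes its full band set as one haplotype.

Parental genotypes are taken as verified (real studies genotype parents in
replicate); observation noise in the generator therefore applies to progeny
only.

### Catalog merging

Haplotypes recovered from different parents and families merge by band-set
identity.  Entries with ambiguous bands are resolved against the pool of
definite haplotypes: if exactly one definite haplotype lies between an entry's
definite and possible band sets, the ambiguity resolves to it.  Two further
rules make this reliable:

* **Sibling constraint.**  A parent's two haplotypes jointly cover its band
  set, so when one of them resolves to a haplotype that lacks an ambiguous
  band, that band is moved to the sibling's definite set.
* **Promotion order.**  When nothing resolves uniquely, the largest pending
  definite set is promoted to the catalog first — it is the most constrained
  candidate — and resolution is retried.

Bands present in every parent and essentially all progeny of every family are
monomorphic at the study level and join every haplotype definitively.
Near-identical catalog haplotypes (symmetric difference of one band) are
reported as candidate genotyping errors.  Haplotype ids are assigned by sorted
band-set content so output is independent of family and progeny order.

Residual failure modes are coincidences of two extreme binomial tails in the
same family (for example, a ~50% backbone fraction fluctuating above 0.85 in
the only family that can phase a given haplotype); with 50 progeny per family
these occur in well under 1% of simulated replicates noise-free and a few
percent with 2% dropout.

## Panel diplotype calling

Because genotypes are unions of haplotype band sets, explaining an unrelated
accession is set arithmetic: all unordered catalog pairs (including self-pairs)
are tested exhaustively.  Exactly one matching union ⇒ `explained`; several ⇒
`ambiguous` with all pairs listed (never resolved by frequency — e.g. H4/H5
and H4/H6 amplify identical bands); none ⇒ `unexplained`.

Unexplained accessions are resolved by greedy parsimony replacing a coalescent
phasing model, which is not applicable to dominant multi-band data over a
non-recombining cluster: preference order is (i) a pair of existing haplotypes,
(ii) one existing plus one new haplotype (the residual bands after subtracting
the existing one, plus the monomorphic backbone), (iii) two new haplotypes.
Accessions are processed in descending band-count order (ties by id) and each
accepted haplotype enters the working catalog immediately, so ids are stable
and reproducible.  Candidate new haplotypes must contain every monomorphic band
and satisfy the gene-group constraints when a band→gene map is supplied: at
most one G2 and one G3 allele and at most three G1 alleles.  No lower bounds
are imposed, because bands of unknown homology (typically rare alleles below
the 5% cloning threshold) may stand in for any gene.  The reported
`explained_fraction` always refers to the original catalog.

An exact branch-and-bound search (`exhaustive_min_new_haplotypes`) enumerates
the valid two-set covers of each unexplained accession and finds the true
minimum number of new haplotypes on instances small enough to enumerate
(≈ 8 accessions); it audits the greedy result in tests and in the acceptance
script.

## Gene copy number

Two bands segregating in phase cannot be alleles of one single-copy gene, so
the number of in-phase bands of a homology group is a *lower bound* on that
gene's copy number in the haplotype.  `copy_counts` reports exact set
cardinalities per haplotype × group and the per-group minimum copy number (the
maximum count over haplotypes); `check_single_copy_constraint` lists the
violations that trigger the duplication inference.  Every report carries the
caveat that null alleles and same-size co-migration can hide further copies;
the method cannot distinguish these, and the package never pretends otherwise.

## Association and prediction

Marker–trait association uses Pearson's chi-squared on the 2×2 carrier ×
phenotype table, 1 df upper tail, *without* continuity correction — the choice
that reproduces the published p = 1.96 × 10⁻¹⁸ from the published counts
(52/53 coloured carriers, 0/28 non-coloured) to three significant figures; a
Yates-corrected variant sits behind a flag.  Markers with carrier frequency
below 5% or carried by everyone (monomorphic, hence untestable) are excluded.
P-values are unadjusted by default; Bonferroni over the tested markers is the
only built-in adjustment.  Note that at n ≈ 81 the permutation null of a 2×2
table is discrete; the asymptotic 5% level is accurate for balanced margins
and conservative for very unbalanced ones.

Prediction: an accession is called coloured iff it carries at least one
haplotype bearing the predictive band (raw band presence when no diplotype
call is available).  Evaluation reports the confusion matrix; a coloured
non-carrier (the published H2/H6 outlier pattern) is a false negative by
construction.  Expected accuracy equals the penetrance of the colour allele.

## Sequence statistics

*Nucleotide diversity* π is the mean over sequence pairs of per-site
differences.  Gap handling is explicit because conventions differ between
tools: `gap_as_state` (default) counts a base–gap mismatch as a difference and
ignores gap–gap sites, so indel variation contributes — the choice consistent
with intron diversity exceeding exon diversity when indels concentrate in the
intron; `pairwise_deletion` and `complete_deletion` are also exposed and the
CLI reports all three, since the semantics of legacy software options are
ambiguous.  Partition masks (exon/intron) restrict π to masked columns.

*Ka/Ks* follows Nei–Gojobori (1986): per-codon synonymous/nonsynonymous site
counts, substitution counts averaged over all mutational pathways with equal
weight (pathways through stop codons excluded when avoidable), Jukes–Cantor
correction of both proportions.  Codons containing gaps or N are excluded
pairwise; Ks = 0 makes the ratio undefined and such pairs are excluded from
the panel mean with the exclusion count disclosed.  The panel mean averages
the per-pair ratios (not ΣKa/ΣKs).

*TN93* distances use the closed form with empirical base frequencies from each
pair; a saturated pair (non-positive logarithm argument) is reported as
infinite.  The implementation is validated against an independent evaluation
of the published formula (frozen reference value; cross-checked against R
`ape::dist.dna` during development).

*UPGMA* is standard average-linkage agglomeration with ties broken by the
lexicographically lowest member-id pair, giving deterministic, ultrametric
rooted trees (validated against SciPy average-linkage cophenetic distances).
Bootstrap support resamples alignment columns with replacement (default
B = 500, seeded); support of an internal node is the frequency of its leaf
clade among replicate trees.  Saturated replicates contribute no support.
Trees are scikit-bio `TreeNode` objects; Newick output carries supports as
internal node labels.

## Read depth

Input is a per-base depth table in the samtools-depth dialect (positions with
zero depth may be absent and count as zero).  Region summaries report mean
depth, depth normalised to the whole-track mean, and breadth of coverage
(fraction of positions at ≥ a threshold, default 1).  The genic/intergenic
split takes a BED annotation; because both normalised depths share the same
denominator, the genic/intergenic ratio equals the raw mean ratio.  Both the
genic/genome and genic/intergenic ratios are reported, since either denominator
is a reasonable reading of "times higher".  The published cluster spans for
peach, sweet cherry and almond are provided as constants (e.g. the peach
cluster is 72,752 bp).

## Synthetic-data generator

The generator reproduces the study design so every stage is testable offline:

* **Catalog.**  Default truth is the published six-haplotype catalog over 12
  bands (sizes 243–500 bp, a466 monomorphic): per-haplotype G1 counts
  {H1:3, H2:1, H3:3, H4:2, H5:1, H6:1}, one G2 and one G3 allele each.  A
  random mode draws structured catalogs (1–3 G1 bands per haplotype, ≥2 bp
  band spacing) for property tests.
* **Families.**  The six study crosses with their published progeny counts
  (83, 111, 48, 43, 64, 33), including one homozygous parent (H3/H3); tests
  and the acceptance script use 50 progeny per family.  Each progeny inherits
  one haplotype per parent uniformly and independently.
* **Panel.**  81 accessions: 74 drawn from common-haplotype frequencies chosen
  so that ~65% of accessions carry a colour haplotype (matching the coloured
  fraction of the discovery panel), plus 7 fixed rare-carrying accessions —
  six combining one of five rare haplotypes (Hi7–Hi11, each with at least one
  band below the 5% frequency threshold) with a common partner sharing only
  the monomorphic band, and one accession combining two rare haplotypes, as
  in the study.
* **Noise.**  Per-band, per-individual dropout and false positives (defaults
  0; false positives drawn from registry bands only), band-collision pairs
  (hidden allele mapped onto its co-migrating partner), applied to progeny
  and panel observations but not to parents.
* **Phenotype.**  Colour is driven by the a356-analog band: carriers are
  coloured with probability `penetrance` (default 0.95, the approximate
  carrier-coloured rate in the study's progenies), non-carriers with
  1 − penetrance.  Flesh colour is independent of genotype at rate 0.382, so
  the flesh scan finds nothing — as it should.
* **Depth.**  Per-base Poisson counts with mean `coverage × copies/2` inside
  genes; a zero-noise mode returns exact means.
* **Alignment.**  Alleles radiate from a common ancestor with intron
  substitution and indel rates above the exon rate (defaults 0.11 vs 0.036,
  targeting overall π ≈ 0.2 with π_intron ≈ 0.24 and π_exon ≈ 0.07); indels
  are realised as aligned gap runs.  An optional grouped mode radiates alleles
  from strongly diverged group ancestors, reproducing the three-cluster tree
  of the tandem duplicates.

All generators draw from per-component substreams of one global seed
(catalog/panel/family/depth/alignment), so modules can be regenerated
independently and every result is reproducible.

What the generator does **not** emulate: linkage to flanking markers,
recombination within the cluster, dosage signal, the three-state (mottled)
phenotype nuance, sequence-level PCR artefacts, or real fragment-size
measurement error beyond binary dropout/false positives.  Passing tests
therefore demonstrate correctness of the inference logic under the study's
stated statistical structure, not robustness to every failure mode of real
fragment data.

## Problem sizes

Tests and the acceptance script use 100 replicate seeds for phasing and panel
recovery (six families × 50 progeny; 81-accession panels), one exhaustive
parsimony audit per run, 500 bootstrap replicates for the reported tree and
100–200 in unit tests, and 10,000 permutations for the type-I-error check.
These sizes give binomial standard errors comfortably below the tolerances
asserted.

## Known limitations

* Phasing assumes exactly two haplotypes per parent (no population structure
  within a family) and no recombination within the cluster.
* The greedy panel inference is order-dependent by design (reproducibility
  over statistical efficiency); the exhaustive audit bounds the cost.
* Copy numbers are lower bounds only; comigration and null alleles are
  indistinguishable from missing copies.
* Whether historical diversity software counted gaps as a fifth state or by
  deletion is not recoverable; hence all three gap modes are first-class.
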