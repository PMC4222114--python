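# Methods

## Data model and coordinates

Input is one pre-aligned multi-FASTA per marker (a single consensus sequence
per accession) plus a delimited metadata table (`accession_id`,
`cultivar_name`, `subgroup`, optional `is_outgroup`, `clone_of`).  The
accepted alphabet has 12 symbols: A, C, G, T, the six two-base IUPAC codes
R/Y/S/W/K/M used for heterozygous diploid positions, N for an ambiguous base
call and `-` for an alignment gap.  Three- and four-base degenerate codes
are rejected at load: a diploid consensus cannot support more than two
alleles at a site.  Sequences are uppercased and U→T normalised on load; no
alignment is performed (the amplicons this workflow targets are gap-free,
and alignment is not this package's contribution).  Positions are 0-based
internally and 1-based in every report; marker order is explicit and drives
the coordinate system of concatenated genotype strings.

## SNP discovery

For a chosen accession subset, each column is classified exclusively as
`indel` (any `-`), else `ambiguous` (any N or multi-base code), else `snp`
(the union of IUB-expanded states spans ≥ 2 bases), else `monomorphic`; the
four counts always sum to the aligned length.  The filter is deliberately
conservative and subset-wide — one ambiguous call kills the column for that
comparison — because imputing states would contaminate downstream *exact*
genotype matching.  Consequently SNP sets are monotone in the accession
subset.  SNP density is reported as bases per SNP, rounded half-up to two
decimals; zero SNPs gives an *undefined* density, distinct from 0.

An optional minor-allele-frequency filter (drop a site when the most common
allele reaches 0.95 of the 2N diploid copies) exists but is **off** by
default: in a panel of selected, clonally maintained cultivars the sample is
not a random population draw, so every variable site is informative.

One known print inconsistency in the reference values used by the tests:
for a 418 bp region with 17 SNPs the density is 24.59 at half-up rounding,
while the corresponding published table prints 24.54; that cell is excluded
from the worked-example checks.

## Genotypes and diagnostic attributes

The genotype of an accession is the concatenated string of its diploid
states over the indexed SNP sites, heterozygotes kept as their IUB code.
Equality is exact string equality — homozygous `A` and heterozygous `R` are
different character states.  Genotype groups are the equivalence classes;
ids are assigned by descending size, then first-seen order.  The genotype
matrix for a subset must be built from sites re-filtered for that subset.

Diagnostic characteristic attributes (CAs) follow the pure/simple/compound
taxonomy of character-based barcoding, with "pure" required: every emitted
CA is present in all members of its group and matched by no outsider.
Single diagnostic positions (pure-simple) are found by direct scan.  When
none exists, a minimal compound CA is searched: exhaustively over position
subsets of size 2..`max_exhaustive` (default 3; smallest cardinality first,
ties broken lexicographically in site order), and beyond that by greedy set
cover over the outsider genotypes followed by subset-deletion pruning, which
guarantees minimality (no proper subset is diagnostic) though not minimum
cardinality — exact minimum search is exponential, which is why the
exhaustive depth is capped and configurable.  Every emitted CA is sound by
construction; the test suite re-verifies soundness and minimality by brute
force on randomized instances.

Naming semantics: a group carrying ≥ 2 cultivar names is a **synonymy**
candidate only for names confined to that single group; a name whose
accessions fall in ≥ 2 groups is a **homonymy/mislabel** candidate.  The
distinction matters because a mislabelled clone (one accession of cultivar A
carrying cultivar B's genotype) would otherwise masquerade as a synonym of
A and B; splitting a name across groups is the mislabel signature.  Clone
checks report, for every cultivar with ≥ 2 accessions, whether all of them
co-grouped (clonal material must show zero intra-cultivar variability).
Groups differing at exactly one site are additionally flagged as 1-off
pairs, a common parent/offspring or clonal-variant signature.

## Distances, trees, bootstrap

K2P distances use pairwise deletion of every non-ACGT site (gaps, N, *and*
heterozygous IUB codes): the model is defined on fixed bases, and this
matches common distance-software behaviour; a fractional-allele scheme was
deliberately not invented.  When a log argument is non-positive or no sites
survive deletion the distance is flagged undefined; tree construction
refuses matrices containing undefined entries rather than silently
substituting.

Neighbor-joining uses the standard rate-corrected Q-criterion with
deterministic first-minimum tie-breaking; negative branch-length estimates
are clamped to zero with the deficit moved to the sibling edge, preserving
the joined pair's path length.  The construction is exact on additive
matrices (property-tested against randomly generated trees).  Rooting
places the root on the edge separating a named outgroup set when that set
is a split of the unrooted topology, else at the outgroup MRCA edge.

Bootstrap supports resample *all* alignment columns (monomorphic included,
keeping proportions honest) with replacement from one seeded generator;
support is the percentage of replicate NJ trees containing each internal
bipartition of the point tree.  Replicates whose K2P matrix contains an
undefined distance are skipped and excluded from the denominator, and the
count of effective replicates is reported.

## Diversity statistics

Allele counts per locus come from the consensus codes: a homozygote
contributes two copies, a heterozygote one of each, so N individuals give
2N copies (sample sizes are reported as 2N).  Per locus: na = observed
alleles, ne = 1/Σp², I = −Σp ln p, H = He = 1 − Σp² (Nei's uncorrected gene
diversity — no small-sample correction, a documented choice isolated in one
function), Ho = heterozygote fraction, Fis = 1 − Ho/He where He > 0.  Table
rows are means over all loci, monomorphic ones included (na = 1, ne = 1,
I = H = Ho = 0), except Fis, which averages only over loci with He > 0.

## Synthetic data generator

The generator emulates the curated-consensus tier of a multi-accession
Sanger survey; it is the package's test bed, not a population-genetic
simulator.  Defaults are the study conditions the analysis assumes:

| parameter | default | why |
|---|---|---|
| marker lengths | 761/419/418/800/919 bp | the five nuclear amplicons (3,317 bp combined) |
| ingroup SNP rate | 1/34.5 per bp | observed cultivar-level density, ~96 expected sites |
| n_cultivars | 150 (8 subgroups) | collection size of the emulated survey |
| clonal cultivars | 6 (one ×3, five ×2) | mirrors the clone replicates sampled |
| synonym pairs / mislabels | 3 / 1 | planted naming cases to recover |
| n_outgroups | 5 | wild-species outgroup panel |
| outgroup divergence | 0.2 subs/site | deep-end distance scale (order of magnitude) |
| het_fraction | 0.30 | cultivars are highly heterozygous clones |
| ambiguous/indel column rates | 0.0 | curated consensus data; no In/Dels expected |

Mechanics: an ancestral sequence per marker is drawn uniformly; segregating
sites are selected independently at the SNP rate, each with one alternate
allele and a per-site alternate frequency ~U(0.05, 0.5); every cultivar
receives hom-ref / hom-alt / het states (het with probability
`het_fraction`), redrawn in the rare case a planted site comes out
monomorphic across the panel; heterozygous states render as the correct
two-base IUB code.  Clones copy their cultivar byte-for-byte; synonym pairs
are two names over one state vector; a mislabel is an extra clone of one
cultivar carrying another cultivar's states — chosen so it surfaces as
homonymy, the realistic signature of a labeling mistake.  Outgroup species
share an evolved stem (half the configured divergence) and then radiate
individually (the other half) under Poisson substitution counts per site
with a 2:1 transition:transversion bias, so the expected distance to the
ingroup ancestor equals the configured divergence, the ingroup|outgroup
split is carried by a real stem edge, and K2P genuinely differs from the
raw p-distance.  Optional N/`-` columns can be planted to exercise the
filters.  Sites are independent (no linkage or recombination model —
vegetative propagation fixes the genome) and there is no read-level noise.

What passing on this generator shows, and what it does not: exact recovery
of partitions, synonyms and mislabels demonstrates the correctness of the
character-based machinery under the survey's own assumptions (curated
consensuses, independent sites, no missing data).  It does not demonstrate
robustness to base-calling error beyond planted N columns, to paralogous
amplification, to somatic chimerism within a cultivar, or to alignment
uncertainty — real surveys must handle those upstream.

The ground truth records the genotype partition, planted naming cases,
outgroup ids and segregating positions, and is re-derivable from the
emitted files; the same seed yields byte-identical output.

## Pipeline and problem sizes

`run_all` executes simulate/load → discover (all-accessions and ingroup
scopes) → genotype → diagnose → distances → tree (+bootstrap) → diversity →
naming, writing delimited reports, Newick and a SHA-256 manifest; identical
config+seed gives identical manifests.  The CA key stage runs on the
ingroup scope: that is where a cultivar key is meaningful, and the deeply
diverged outgroups would otherwise flood the candidate-position set (they
are trivially diagnosable by pure-simple attributes).

The test suite and the acceptance script run everything at the default
study scale (~160 accessions × 3,317 bp) for discovery, genotyping and
distances, and use a compact panel (200 bp, 11 taxa, 100 replicates) for
the bootstrap scenario, sizes at which the planted outgroup split is
recovered at full support; exhaustive CA verification uses randomized
instances of ≤ 8 accessions × ≤ 10 sites where brute force is feasible.

## Known limitations

- Heterozygous sites are never phased; the genotype is an unphased
  character string by design, so phased-haplotype questions are out of
  scope, as are pedigree inference and chimera resolution.
- Pairwise deletion discards heterozygous sites from distances, slightly
  deflating within-cultivar divergence relative to schemes that average
  over alleles.
- The greedy compound-CA fallback guarantees minimality, not minimum size,
  beyond the exhaustive cap.
- He carries no small-sample correction; subgroup rows with few members are
  reported as computed, not bias-adjusted.
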