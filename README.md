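# vitisnp

Character-based SNP genotyping for grapevine cultivar identity.

Grapevine (*Vitis vinifera* L.) cultivars are clonally propagated, highly
heterozygous diploids, and thousands of them circulate under unstable names:
the same genotype under two names (synonymy), one name covering distinct
genotypes (homonymy), and plain labeling mistakes.  Distance-based barcoding
breaks down below the species level because within-species divergence is
tiny, so identity work at the cultivar level instead uses the *character
states themselves*: SNPs discovered on a few single-copy nuclear amplicons,
read from Sanger consensus sequences in which heterozygous positions are
recorded as two-base IUPAC codes (R, Y, S, W, K, M).

`vitisnp` implements that workflow as a reusable Python library for anyone
curating a germplasm collection or building a varietal reference system:

- **SNP discovery** on pre-aligned multi-FASTA amplicons with a conservative
  column filter (any gap → In/Del candidate, any ambiguous call → excluded),
  plus per-region SNP densities (1 SNP per *N* bp).
- **Genotype reconstruction**: per accession, the concatenated string of
  diploid states over all SNP sites — heterozygotes kept as IUB codes, not
  phased — so `A` and `R` are distinct character states.  Identical strings
  collapse into genotype groups.
- **Diagnostic keys**: for each group, *characteristic attributes* (CAs) in
  the pure/simple/compound sense — a single (position, state) pair present
  in all members and absent outside, or a provably minimal combination of
  positions that is jointly diagnostic.
- **Naming reports**: synonymy candidates (several names confined to one
  group), homonymy/mislabel candidates (one name split across groups), and
  clone-consistency checks (clonal replicates must co-group).
- **Descriptive population genetics**: Kimura 2-parameter distances with
  pairwise deletion, neighbor-joining trees with column-resampling bootstrap
  supports and outgroup rooting, and per-subgroup diversity statistics
  (na, ne = 1/Σp², I = −Σp ln p, H = He = 1 − Σp², Ho, Fis = 1 − Ho/He)
  over diploid SNP loci.
- **A ground-truthed synthetic data generator** that emulates the study
  design (five nuclear markers of 761/419/418/800/919 bp, ~160 accessions in
  geographic subgroups, planted synonym pairs, mislabels, clones and five
  diverged outgroup species), so the whole pipeline is testable end to end.

The K2P distance between two aligned sequences with transition proportion
*P* (A↔G, C↔T) and transversion proportion *Q* is

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

computed only over sites where both sequences carry a plain base; undefined
distances (saturated pairs, empty overlap) are flagged, never zeroed.

## Worked example

```bash
python examples/02_genotypes_and_diagnostics.py
```

```
15 SNP sites -> 9 genotype groups for 13 accessions
  group 1 (n=3): TTGGRGCCAKGGASC...  ['001_CV001', '002_CV001', '003_CV001']
  group 2 (n=2): TGTKRGACTTSGACC...  ['009_CV007', '013_CV008']
  group 3 (n=2): KTKTGCACAGGGACT...  ['011_CV009', '012_CV010']
  group 4 (n=1): KTKGASCCWTGCWCC...  ['004_CV002']

diagnostic CA for group 1 (pure-simple): M2:154=K
every member of group 1 matches this state pattern; no other genotype does

synonymy candidates (two names, one genotype): [(3, ('CV009', 'CV010'))]
homonymy candidates (one name, several genotypes): [('CV008', (2, 9))]
planted truth: [('CV010', 'CV009')] / [('CV008', 'clone carries', 'CV007')]
```

Reading this: 13 accessions collapse into 9 genotype groups; the three
clonal replicates of CV001 co-group (group 1), which is diagnosable by the
single heterozygous state K (G/T) at position 154 of marker M2.  The planted
synonym pair CV009/CV010 surfaces as a two-name group, and the planted
mislabelled clone of CV008 (which actually carries CV007's genotype) splits
the name CV008 across two groups — a homonymy flag, exactly as planted.

The other examples cover discovery/audit tables (`01`), K2P/NJ/bootstrap
(`03`) and the diversity table (`04`).  A thin CLI mirrors the stages
(`vitisnp simulate|discover|genotype|diagnose|distances|tree|stats|report|run-all`);
`run-all` drives everything from one YAML config and writes a checksum
manifest, identical for identical config+seed.

## Layout

```
src/vitisnp/      library (io, discovery, genotyping, distances, tree,
                  diversity, simulate, pipeline, cli)
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property-based, acceptance)
scripts/          acceptance.py
docs/methods.md   models, assumptions, parameter choices, limitations
```
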