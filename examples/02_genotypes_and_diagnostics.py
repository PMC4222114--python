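"""Genotype strings, genotype groups, diagnostic keys and naming checks.

Concatenates the per-site diploid states (heterozygotes kept as IUB codes)
into one character string per accession, collapses identical strings into
genotype groups, derives a diagnostic characteristic attribute (CA) for one
group, and prints the synonymy/homonymy report.  The planted synonym pair
and mislabel are recovered exactly.
"""

from vitisnp.discovery import discover_snps
from vitisnp.genotyping import (
    build_genotype_matrix,
    collapse_genotypes,
    diagnose_group,
    naming_report,
)
from vitisnp.simulate import SimConfig, simulate

cfg = SimConfig(
    seed=7,
    marker_lengths=[400, 300],
    n_cultivars=10,
    n_outgroups=0,
    n_synonym_pairs=1,
    n_mislabels=1,
    n_clonal_cultivars=1,
)
res = simulate(cfg)
ds = res.dataset

disc = discover_snps(ds)
profile = build_genotype_matrix(disc.all_sites, ds.accession_ids, ds.marker_names)
groups = collapse_genotypes(profile)

print(f"{profile.n_sites} SNP sites -> {len(groups)} genotype groups "
      f"for {len(ds.meta)} accessions")
for g in groups[:4]:
    print(f"  group {g.group_id} (n={g.size}): {g.genotype[:24]}...  {g.members}")

ca = diagnose_group(groups[0], profile)[0]
print(f"\ndiagnostic CA for group 1 ({ca.category}): {' & '.join(ca.labels())}")
print("every member of group 1 matches this state pattern; no other genotype does")

rep = naming_report(groups, ds.meta)
print("\nsynonymy candidates (two names, one genotype):", rep.synonymy_candidates)
print("homonymy candidates (one name, several genotypes):", rep.homonymy_candidates)
print("planted truth:", res.truth.synonym_pairs, "/",
      [(m[1], "clone carries", m[2]) for m in res.truth.mislabels])
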