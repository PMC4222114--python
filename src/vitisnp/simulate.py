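"""Ground-truthed synthetic diploid Sanger-consensus datasets.

The generator emulates the structure of a multi-accession nuclear-amplicon
survey of a clonally propagated crop: five pre-aligned marker regions, ~160
diploid accessions in geographic subgroups, heterozygous sites rendered as
two-base IUB codes in a single consensus per accession, clonal replicates
with zero intra-cultivar variability, planted synonym pairs (two names, one
genotype), planted mislabels (one name, two genotypes) and a handful of
highly diverged outgroup taxa radiating independently from the ingroup
ancestor with a 2:1 transition:transversion bias.

Simulation is at the consensus tier: there is no read-level noise and sites
are independent (vegetative propagation makes within-cultivar recombination
negligible).  Optionally, 'N' and '-' columns can be planted to exercise the
ambiguity/indel filters; both rates default to zero, matching curated
consensus data in which no indels were recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import BASES, iub_for_alleles
from .errors import SimulationConfigError
from .io import AccessionMeta, Dataset, MarkerAlignment, write_dataset

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate", "write_simulation"]

#: Default marker regions: the five single-copy nuclear amplicons (bp).
DEFAULT_MARKERS: dict[str, int] = {
    "GAI": 761,
    "ID04": 419,
    "IIC08": 418,
    "ATP": 800,
    "UFGT": 919,
}

INGROUP_SUBGROUPS: tuple[str, ...] = (
    "Local",
    "Italy",
    "Central Europe",
    "Spain",
    "Portugal",
    "Eastern Europe",
    "Near East",
    "Balkan Peninsula",
)

OUTGROUP_SPECIES: tuple[str, ...] = (
    "V_riparia",
    "V_rupestris",
    "V_berlandieri",
    "V_cinerea",
    "V_labrusca",
)

#: transition target for each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Synthetic-dataset parameters.

    Defaults reproduce the study conditions the analysis assumes: marker
    lengths 761/419/418/800/919 bp, an ingroup SNP rate of one segregating
    site per 34.5 bp, outgroup divergence of 0.2 substitutions/site, 150
    cultivars across 8 geographic subgroups plus 5 outgroup species, a few
    clonal cultivars, three synonym pairs and one mislabelled clone.
    """

    seed: int = 0
    marker_lengths: list[int] = field(default_factory=lambda: list(DEFAULT_MARKERS.values()))
    marker_names: Optional[list[str]] = None
    n_cultivars: int = 150
    clones_per_cultivar: Optional[dict[str, int]] = None
    n_clonal_cultivars: int = 6  # used only when clones_per_cultivar is None
    n_synonym_pairs: int = 3
    n_mislabels: int = 1
    n_outgroups: int = 5
    ingroup_snp_rate: float = 1.0 / 34.5
    het_fraction: float = 0.30
    outgroup_divergence: float = 0.2
    ambiguous_site_rate: float = 0.0
    indel_site_rate: float = 0.0

    def resolved_marker_names(self) -> list[str]:
        if self.marker_names is not None:
            return list(self.marker_names)
        if len(self.marker_lengths) == len(DEFAULT_MARKERS):
            return list(DEFAULT_MARKERS)
        return [f"M{i + 1}" for i in range(len(self.marker_lengths))]

    def validate(self) -> None:
        probs = {
            "ingroup_snp_rate": self.ingroup_snp_rate,
            "het_fraction": self.het_fraction,
            "ambiguous_site_rate": self.ambiguous_site_rate,
            "indel_site_rate": self.indel_site_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {p}")
        if self.outgroup_divergence < 0:
            raise SimulationConfigError("outgroup_divergence must be >= 0")
        counts = {
            "n_cultivars": self.n_cultivars,
            "n_synonym_pairs": self.n_synonym_pairs,
            "n_mislabels": self.n_mislabels,
            "n_outgroups": self.n_outgroups,
        }
        for name, c in counts.items():
            if c < 0:
                raise SimulationConfigError(f"{name} must be >= 0, got {c}")
        if self.n_cultivars < 1:
            raise SimulationConfigError("need at least one cultivar")
        if any(l <= 0 for l in self.marker_lengths):
            raise SimulationConfigError("marker lengths must be positive")
        if len(self.resolved_marker_names()) != len(self.marker_lengths):
            raise SimulationConfigError("marker_names and marker_lengths disagree")
        if 2 * self.n_synonym_pairs + 2 * self.n_mislabels > self.n_cultivars:
            raise SimulationConfigError(
                "too many synonym pairs / mislabels for the number of cultivars"
            )
        if self.n_outgroups > len(OUTGROUP_SPECIES):
            raise SimulationConfigError(
                f"at most {len(OUTGROUP_SPECIES)} outgroup species are available"
            )
        if (
            self.ingroup_snp_rate > 0
            and self.n_cultivars == 1
            and self.het_fraction == 0.0
        ):
            raise SimulationConfigError(
                "a single fully homozygous cultivar cannot carry polymorphism"
            )


@dataclass
class GroundTruth:
    """What the generator planted, re-derivable from the emitted files."""

    partition: list[list[str]]  # genotype groups over accession ids
    synonym_pairs: list[tuple[str, str]]  # cultivar-name pairs
    mislabels: list[tuple[str, str, str]]  # (accession_id, labeled_name, true_name)
    outgroups: list[str]  # accession ids
    segregating: dict[str, list[int]]  # marker -> 0-based planted SNP positions

    def partition_of(self) -> dict[str, int]:
        return {acc: i for i, grp in enumerate(self.partition) for acc in grp}

    def to_json(self) -> str:
        return json.dumps(
            {
                "partition": self.partition,
                "synonym_pairs": [list(p) for p in self.synonym_pairs],
                "mislabels": [list(m) for m in self.mislabels],
                "outgroups": self.outgroups,
                "segregating": self.segregating,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            partition=[list(g) for g in d["partition"]],
            synonym_pairs=[tuple(p) for p in d["synonym_pairs"]],
            mislabels=[tuple(m) for m in d["mislabels"]],
            outgroups=list(d["outgroups"]),
            segregating={k: list(v) for k, v in d["segregating"].items()},
        )


@dataclass
class SimResult:
    dataset: Dataset
    truth: GroundTruth
    #: cultivar -> {(marker, pos): 0 hom-ref / 1 het / 2 hom-alt}
    cultivar_codes: dict[str, dict[tuple[str, int], int]]
    #: (marker, pos) -> (ref_base, alt_base)
    site_alleles: dict[tuple[str, int], tuple[str, str]]


def _evolve_outgroup(ancestral: list[str], divergence: float, rng: np.random.Generator) -> list[str]:
    """Mutate the ancestral sequence with Poisson(divergence) substitution
    events per site, transitions twice as likely as each pair of
    transversions jointly (P(ts) = 2/3)."""
    seq = list(ancestral)
    hits = rng.poisson(divergence, size=len(seq))
    for pos in np.nonzero(hits)[0]:
        for _ in range(int(hits[pos])):
            base = seq[pos]
            if rng.random() < 2.0 / 3.0:
                seq[pos] = _TRANSITION[base]
            else:
                tv = [b for b in BASES if b != base and b != _TRANSITION[base]]
                seq[pos] = tv[int(rng.integers(0, 2))]
    return seq


def simulate(config: SimConfig) -> SimResult:
    """Generate a full synthetic dataset with ground truth.

    The same seed always yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    marker_names = config.resolved_marker_names()

    cultivars = [f"CV{i + 1:03d}" for i in range(config.n_cultivars)]
    cultivar_subgroup = {
        c: INGROUP_SUBGROUPS[i % len(INGROUP_SUBGROUPS)] for i, c in enumerate(cultivars)
    }

    # synonym pairs and mislabels use disjoint cultivar pools, drawn from the
    # tail of the list so the clonal head cultivars stay ordinary
    pool = list(cultivars)
    synonym_pairs: list[tuple[str, str]] = []
    for _ in range(config.n_synonym_pairs):
        a, b = pool.pop(), pool.pop()
        synonym_pairs.append((a, b))
    mislabel_defs: list[tuple[str, str]] = []  # (labeled cultivar A, source B)
    for _ in range(config.n_mislabels):
        a, b = pool.pop(), pool.pop()
        mislabel_defs.append((a, b))
    synonym_copy = {b: a for a, b in synonym_pairs}

    if config.clones_per_cultivar is not None:
        clones = dict(config.clones_per_cultivar)
        unknown = sorted(set(clones) - set(cultivars))
        if unknown:
            raise SimulationConfigError(f"clones_per_cultivar names unknown cultivars: {unknown}")
    else:
        n_clonal = min(config.n_clonal_cultivars, len(pool))
        clonal = [pool[i] for i in range(n_clonal)]
        clones = {c: (3 if i == 0 else 2) for i, c in enumerate(clonal)}

    # --- ancestral sequences and segregating sites -------------------------
    ancestral: dict[str, list[str]] = {}
    site_alleles: dict[tuple[str, int], tuple[str, str]] = {}
    segregating: dict[str, list[int]] = {}
    for name, length in zip(marker_names, config.marker_lengths):
        ancestral[name] = [BASES[i] for i in rng.integers(0, 4, size=length)]
        seg = np.nonzero(rng.random(length) < config.ingroup_snp_rate)[0]
        segregating[name] = [int(p) for p in seg]
        for p in segregating[name]:
            ref = ancestral[name][p]
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
            site_alleles[(name, p)] = (ref, alt)

    # --- per-cultivar diploid states at segregating sites ------------------
    all_sites = [(m, p) for m in marker_names for p in segregating[m]]
    free = [c for c in cultivars if c not in synonym_copy]
    codes_by_site: dict[tuple[str, int], dict[str, int]] = {}
    for key in all_sites:
        alt_freq = rng.uniform(0.05, 0.5)
        for attempt in range(200):
            col: dict[str, int] = {}
            for c in free:
                u = rng.random()
                if u < config.het_fraction:
                    col[c] = 1
                elif rng.random() < alt_freq:
                    col[c] = 2
                else:
                    col[c] = 0
            for b, a in synonym_copy.items():
                col[b] = col[a]
            vals = set(col.values())
            if vals not in ({0}, {2}):  # polymorphic across cultivars
                break
        else:
            raise SimulationConfigError(
                f"could not realise polymorphism at planted site {key}"
            )
        codes_by_site[key] = col

    cultivar_codes: dict[str, dict[tuple[str, int], int]] = {
        c: {key: codes_by_site[key][c] for key in all_sites} for c in cultivars
    }

    def render(cultivar: str, marker: str) -> str:
        seq = list(ancestral[marker])
        for p in segregating[marker]:
            ref, alt = site_alleles[(marker, p)]
            code = cultivar_codes[cultivar][(marker, p)]
            if code == 0:
                seq[p] = ref
            elif code == 2:
                seq[p] = alt
            else:
                seq[p] = iub_for_alleles((ref, alt))
        return "".join(seq)

    # --- assemble accessions ----------------------------------------------
    meta: list[AccessionMeta] = []
    seqs_by_marker: dict[str, dict[str, str]] = {m: {} for m in marker_names}
    truth_mislabels: list[tuple[str, str, str]] = []
    idx = 0

    def add_accession(cultivar_label: str, source_cultivar: str, subgroup: str,
                      is_outgroup: bool = False, clone_of: Optional[str] = None) -> str:
        nonlocal idx
        idx += 1
        acc = f"{idx:03d}_{cultivar_label}"
        meta.append(
            AccessionMeta(acc, cultivar_label, subgroup, is_outgroup, clone_of)
        )
        for m in marker_names:
            seqs_by_marker[m][acc] = render(source_cultivar, m)
        return acc

    for c in cultivars:
        n_copies = clones.get(c, 1)
        for k in range(n_copies):
            add_accession(c, c, cultivar_subgroup[c], clone_of=c if k > 0 else None)
    for a, b in mislabel_defs:
        acc = add_accession(a, b, cultivar_subgroup[a], clone_of=a)
        truth_mislabels.append((acc, a, b))

    # Outgroup species share a diverged stem ancestor (half the configured
    # divergence) and then radiate individually (the other half), so the
    # expected distance to the ingroup ancestor is `outgroup_divergence` and
    # the ingroup-vs-outgroup split is carried by a real stem edge.
    outgroup_ids: list[str] = []
    if config.n_outgroups:
        stem = {
            m: _evolve_outgroup(ancestral[m], config.outgroup_divergence / 2.0, rng)
            for m in marker_names
        }
        for i in range(config.n_outgroups):
            name = OUTGROUP_SPECIES[i]
            idx += 1
            acc = f"{idx:03d}_{name}"
            meta.append(AccessionMeta(acc, name, "Outgroup", True, None))
            for m in marker_names:
                seqs_by_marker[m][acc] = "".join(
                    _evolve_outgroup(stem[m], config.outgroup_divergence / 2.0, rng)
                )
            outgroup_ids.append(acc)

    # --- genotype partition from the clean sequences -----------------------
    acc_ids = [m.accession_id for m in meta]
    concat = {a: "".join(seqs_by_marker[m][a] for m in marker_names) for a in acc_ids}
    groups: dict[str, list[str]] = {}
    for a in acc_ids:
        groups.setdefault(concat[a], []).append(a)
    partition = sorted(groups.values(), key=lambda g: (-len(g), g[0]))

    # --- optional planted ambiguity / indel columns ------------------------
    for m in marker_names:
        length = len(ancestral[m])
        for pos in range(length):
            r = rng.random()
            if config.indel_site_rate and r < config.indel_site_rate:
                victim = acc_ids[int(rng.integers(0, len(acc_ids)))]
                s = seqs_by_marker[m][victim]
                seqs_by_marker[m][victim] = s[:pos] + "-" + s[pos + 1:]
            elif config.ambiguous_site_rate and r < config.indel_site_rate + config.ambiguous_site_rate:
                victim = acc_ids[int(rng.integers(0, len(acc_ids)))]
                s = seqs_by_marker[m][victim]
                seqs_by_marker[m][victim] = s[:pos] + "N" + s[pos + 1:]

    markers = [
        MarkerAlignment(m, len(ancestral[m]), seqs_by_marker[m]) for m in marker_names
    ]
    dataset = Dataset(markers=markers, meta=meta)
    truth = GroundTruth(
        partition=[list(g) for g in partition],
        synonym_pairs=synonym_pairs,
        mislabels=truth_mislabels,
        outgroups=outgroup_ids,
        segregating=segregating,
    )
    return SimResult(dataset, truth, cultivar_codes, site_alleles)


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-marker FASTA + metadata + ground-truth JSON; return paths."""
    outdir = Path(outdir)
    paths = write_dataset(result.dataset, outdir)
    tp = outdir / "ground_truth.json"
    tp.write_text(result.truth.to_json())
    paths["ground_truth"] = tp
    return paths
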