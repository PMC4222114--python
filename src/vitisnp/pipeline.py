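"""End-to-end orchestration: simulate/load -> discover -> genotype ->
diagnose -> distances -> tree (+bootstrap) -> diversity -> naming report.

Every stage is a pure function of its inputs plus explicit seeds, so an
identical config and seed produce an identical manifest of output checksums.
A stage failure aborts the run with the stage name; outputs written so far
are retained next to a ``FAILED`` marker file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import discovery as _disc
from . import genotyping as _gt
from .distances import group_distance_summary, k2p_matrix
from .diversity import diversity_table
from .errors import StageError, VitisnpError
from .io import (
    Dataset,
    distance_matrix_to_phylip,
    read_dataset,
    write_delimited,
    write_newick,
)
from .simulate import SimConfig, simulate, write_simulation
from .tree import bootstrap_supports, nj_tree, root_on_outgroup

logger = logging.getLogger("vitisnp")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """One pipeline run: either a simulate block or explicit input paths."""

    outdir: str
    seed: int = 0
    simulate: Optional[SimConfig] = None
    fasta_paths: list[str] = field(default_factory=list)
    meta_path: Optional[str] = None
    bootstrap_reps: int = 1000
    ca_max_exhaustive: int = 3
    maf_filter: bool = False

    def validate(self) -> None:
        if self.simulate is None and not (self.fasta_paths and self.meta_path):
            raise VitisnpError(
                "config needs either a simulate block or fasta_paths + meta_path"
            )
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "fasta_paths": list(self.fasta_paths),
            "meta_path": self.meta_path,
            "bootstrap_reps": self.bootstrap_reps,
            "ca_max_exhaustive": self.ca_max_exhaustive,
            "maf_filter": self.maf_filter,
        }
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("simulate")
        return cls(
            outdir=d["outdir"],
            seed=int(d.get("seed", 0)),
            simulate=SimConfig(**sim) if sim is not None else None,
            fasta_paths=list(d.get("fasta_paths", [])),
            meta_path=d.get("meta_path"),
            bootstrap_reps=int(d.get("bootstrap_reps", 1000)),
            ca_max_exhaustive=int(d.get("ca_max_exhaustive", 3)),
            maf_filter=bool(d.get("maf_filter", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, str]:
    """Execute every stage; return (and write) the manifest of checksums."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        # ------------------------------------------------------------ input
        stage = "input"
        if config.simulate is not None:
            sim_cfg = config.simulate
            result = simulate(sim_cfg)
            paths = write_simulation(result, outdir / "inputs")
            for p in paths.values():
                track(p)
            dataset: Dataset = result.dataset
            logger.info("simulated %d accessions", len(dataset.meta))
        else:
            dataset = read_dataset(config.fasta_paths, config.meta_path)
            logger.info("loaded %d accessions", len(dataset.meta))

        ingroup = dataset.ingroup_ids()
        outgroup = dataset.outgroup_ids()

        # --------------------------------------------------------- discover
        stage = "discover"
        scopes = [("all", dataset.accession_ids)]
        if outgroup:
            scopes.append(("ingroup", ingroup))
        results = [
            _disc.discover_snps(dataset, accs, scope=s, maf_filter=config.maf_filter)
            for s, accs in scopes
        ]
        all_scope = results[0]
        track(write_delimited(_disc.snp_report(all_scope), outdir / "snp_report.tsv"))
        track(write_delimited(_disc.audit_table(all_scope), outdir / "site_audit.tsv"))
        track(write_delimited(_disc.density_table(results, dataset), outdir / "snp_density.tsv"))

        # --------------------------------------------------------- genotype
        stage = "genotype"
        profile = _gt.build_genotype_matrix(
            all_scope.all_sites, dataset.accession_ids, dataset.marker_names
        )
        groups = _gt.collapse_genotypes(profile)
        track(write_delimited(_gt.genotype_table(profile, groups), outdir / "genotypes.tsv"))
        logger.info("%d genotype groups", len(groups))

        # --------------------------------------------------------- diagnose
        # The CA key targets the cultivars, so diagnosis runs on the ingroup
        # scope (sites re-filtered for ingroup accessions): the divergent
        # outgroups would otherwise flood the candidate-position set.
        stage = "diagnose"
        scope_res = results[-1]
        in_profile = _gt.build_genotype_matrix(
            scope_res.all_sites, scope_res.accessions, dataset.marker_names
        )
        in_groups = _gt.collapse_genotypes(in_profile)
        if len(in_groups) >= 2:
            cas = _gt.diagnose_all(
                in_groups, in_profile, max_exhaustive=config.ca_max_exhaustive
            )
            track(write_delimited(
                _gt.genotype_table(in_profile, in_groups), outdir / "genotypes_ingroup.tsv"
            ))
            track(write_delimited(_gt.ca_key_table(cas), outdir / "ca_key.tsv"))

        # -------------------------------------------------------- distances
        stage = "distances"
        concat = dataset.concatenated()
        dm = k2p_matrix(concat)
        df = dm.to_dataframe().reset_index().rename(columns={"index": "accession_id"})
        track(write_delimited(df, outdir / "k2p_matrix.tsv"))
        phy = outdir / "k2p_matrix.phy"
        phy.write_text(distance_matrix_to_phylip(dm.labels, dm.values))
        track(phy)
        track(write_delimited(group_distance_summary(dm, dataset.meta), outdir / "group_distances.tsv"))

        # ------------------------------------------------------------- tree
        stage = "tree"
        if dm.n >= 3:
            if config.bootstrap_reps > 0:
                boot = bootstrap_supports(concat, config.bootstrap_reps, config.seed)
                tree = boot.tree
            else:
                tree = nj_tree(dm)
            if outgroup:
                tree = root_on_outgroup(tree, outgroup)
            track(write_newick(tree, outdir / "nj_tree.nwk"))

        # ------------------------------------------------------------ stats
        stage = "stats"
        track(write_delimited(
            diversity_table(all_scope.all_sites, dataset.meta), outdir / "diversity.tsv"
        ))

        # ----------------------------------------------------------- naming
        stage = "naming"
        report = _gt.naming_report(groups, dataset.meta)
        for name, tbl in _gt.naming_tables(report).items():
            track(write_delimited(tbl, outdir / f"naming_{name}.tsv"))

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc) from exc

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
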