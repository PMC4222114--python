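"""Reading and writing of the pipeline's external formats.

Inputs are per-marker pre-aligned multi-FASTA files (one consensus sequence
per accession) and a delimited metadata table (comma or tab, auto-detected)
with at least ``accession_id``, ``cultivar_name`` and ``subgroup`` columns.
Outputs are delimited text reports, square/PHYLIP distance matrices and
Newick trees.

Alignment is *not* performed here: the amplicons are expected to arrive
already aligned (in the study system all five nuclear amplicons were
gap-free, so alignment is the identity).  Positions are held 0-based
internally and printed 1-based in every report.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET, normalize_sequence, validate_sequence
from .errors import AlignmentError, AlphabetError, MetadataError

__all__ = [
    "AccessionMeta",
    "MarkerAlignment",
    "Dataset",
    "read_fasta_alignment",
    "read_metadata",
    "read_dataset",
    "write_dataset",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class AccessionMeta:
    """One sampled accession: a vine with an id, a cultivar name and a
    population subgroup (geographic group or 'Outgroup')."""

    accession_id: str
    cultivar_name: str
    subgroup: str
    is_outgroup: bool = False
    clone_of: Optional[str] = None


@dataclass
class MarkerAlignment:
    """A pre-aligned amplicon across accessions for one nuclear marker."""

    marker_name: str
    aligned_length: int
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for acc, seq in self.sequences.items():
            if len(seq) != self.aligned_length:
                raise AlignmentError(
                    f"marker {self.marker_name!r}: record {acc!r} has length "
                    f"{len(seq)}, expected {self.aligned_length}"
                )

    @property
    def accession_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, accessions: Iterable[str]) -> "MarkerAlignment":
        accs = list(accessions)
        missing = [a for a in accs if a not in self.sequences]
        if missing:
            raise AlignmentError(
                f"marker {self.marker_name!r}: accessions not present: {missing}"
            )
        return MarkerAlignment(
            self.marker_name, self.aligned_length, {a: self.sequences[a] for a in accs}
        )


@dataclass
class Dataset:
    """All marker alignments plus accession metadata.

    The marker order is explicit and stable: it drives the coordinate system
    of concatenated genotype strings.  ``missing`` lists, per marker, any
    accession present in the metadata but absent from that alignment.
    """

    markers: list[MarkerAlignment]
    meta: list[AccessionMeta]
    missing: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.accession_id for m in self.meta]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate accession_id(s) in metadata: {dupes}")
        known = set(ids)
        for aln in self.markers:
            orphans = [a for a in aln.accession_ids if a not in known]
            if orphans:
                raise MetadataError(
                    f"marker {aln.marker_name!r}: accessions missing from "
                    f"metadata: {orphans}"
                )
        self.missing = {
            aln.marker_name: sorted(known - set(aln.accession_ids))
            for aln in self.markers
        }

    @property
    def marker_names(self) -> list[str]:
        return [m.marker_name for m in self.markers]

    @property
    def accession_ids(self) -> list[str]:
        return [m.accession_id for m in self.meta]

    @property
    def meta_by_id(self) -> dict[str, AccessionMeta]:
        return {m.accession_id: m for m in self.meta}

    @property
    def total_length(self) -> int:
        """Summed aligned length over all markers (bp)."""
        return sum(m.aligned_length for m in self.markers)

    def marker(self, name: str) -> MarkerAlignment:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise KeyError(name)

    def ingroup_ids(self) -> list[str]:
        return [m.accession_id for m in self.meta if not m.is_outgroup]

    def outgroup_ids(self) -> list[str]:
        return [m.accession_id for m in self.meta if m.is_outgroup]

    def concatenated(self, accessions: Optional[Sequence[str]] = None) -> dict[str, str]:
        """Concatenate all marker sequences per accession, in marker order.

        Accessions missing from any marker are excluded unless explicitly
        requested, in which case an error is raised.
        """
        if accessions is None:
            accessions = [
                a
                for a in self.accession_ids
                if all(a in m.sequences for m in self.markers)
            ]
        out = {}
        for a in accessions:
            try:
                out[a] = "".join(m.sequences[a] for m in self.markers)
            except KeyError:
                raise AlignmentError(
                    f"accession {a!r} is missing from at least one marker"
                )
        return out


# ---------------------------------------------------------------------------
# readers


def read_fasta_alignment(path: str | Path, marker_name: Optional[str] = None) -> MarkerAlignment:
    """Read one pre-aligned multi-FASTA file as a :class:`MarkerAlignment`.

    Sequences are uppercased, 'U' is normalised to 'T' and every symbol must
    belong to the 12-symbol consensus alphabet.  All records must have equal
    length.  The marker name defaults to the file stem.
    """
    path = Path(path)
    name = marker_name if marker_name is not None else path.stem
    seqs: dict[str, str] = {}
    length: Optional[int] = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"marker {name!r}: duplicate record id {rec.id!r}")
        seq = normalize_sequence(str(rec.seq))
        try:
            validate_sequence(seq, context=f"record {rec.id!r} of marker {name!r}")
        except AlphabetError:
            raise
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"marker {name!r}: record {rec.id!r} has length {len(seq)}, "
                f"expected {length}"
            )
        seqs[rec.id] = seq
    if length is None:
        raise AlignmentError(f"marker {name!r}: no records in {path}")
    return MarkerAlignment(name, length, seqs)


_REQUIRED_META_COLUMNS = ("accession_id", "cultivar_name", "subgroup")


def read_metadata(path: str | Path) -> list[AccessionMeta]:
    """Read the accession metadata table (comma- or tab-delimited).

    Required columns: accession_id, cultivar_name, subgroup.  Optional:
    is_outgroup (truthy values: 1/true/yes; otherwise inferred from the
    subgroup label 'Outgroup'), clone_of.  Extra columns are ignored.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise MetadataError(f"cannot parse metadata file {path}: {exc}")
    missing = [c for c in _REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata {path} lacks required column(s): {missing}")
    rows: list[AccessionMeta] = []
    for _, row in df.iterrows():
        if "is_outgroup" in df.columns and not pd.isna(row["is_outgroup"]):
            is_og = str(row["is_outgroup"]).strip().lower() in {"1", "true", "yes"}
        else:
            is_og = str(row["subgroup"]).strip().lower() == "outgroup"
        clone_of = None
        if "clone_of" in df.columns and not pd.isna(row["clone_of"]):
            clone_of = str(row["clone_of"]).strip() or None
        rows.append(
            AccessionMeta(
                accession_id=str(row["accession_id"]).strip(),
                cultivar_name=str(row["cultivar_name"]).strip(),
                subgroup=str(row["subgroup"]).strip(),
                is_outgroup=is_og,
                clone_of=clone_of,
            )
        )
    return rows


def read_dataset(fasta_paths: Sequence[str | Path], meta_path: str | Path) -> Dataset:
    """Load and validate a full dataset (fixed marker order = argument order)."""
    markers = [read_fasta_alignment(p) for p in fasta_paths]
    names = [m.marker_name for m in markers]
    if len(names) != len(set(names)):
        raise AlignmentError(f"duplicate marker names: {names}")
    meta = read_metadata(meta_path)
    return Dataset(markers=markers, meta=meta)


# ---------------------------------------------------------------------------
# writers


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write per-marker FASTA files plus ``metadata.tsv``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for aln in dataset.markers:
        p = outdir / f"{aln.marker_name}.fasta"
        records = [
            SeqRecord(Seq(seq), id=acc, description="")
            for acc, seq in aln.sequences.items()
        ]
        SeqIO.write(records, str(p), "fasta")
        paths[aln.marker_name] = p
    mp = outdir / "metadata.tsv"
    df = pd.DataFrame(
        {
            "accession_id": [m.accession_id for m in dataset.meta],
            "cultivar_name": [m.cultivar_name for m in dataset.meta],
            "subgroup": [m.subgroup for m in dataset.meta],
            "is_outgroup": [int(m.is_outgroup) for m in dataset.meta],
            "clone_of": [m.clone_of or "" for m in dataset.meta],
        }
    )
    df.to_csv(mp, sep="\t", index=False)
    paths["metadata"] = mp
    return paths


def _check_unique_leaves(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise AlignmentError(f"duplicate leaf labels in tree: {dupes}")


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    """Write a tree as Newick; integer bootstrap supports (if present as
    internal node labels) are preserved as internal labels."""
    _check_unique_leaves(tree)
    path = Path(path)
    txt = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    path.write_text(txt)
    return path


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal string."""
    s = str(path_or_string)
    if "(" in s and ";" in s:
        src = {"data": s}
    else:
        src = {"path": s}
    tree = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=True, **src)
    _check_unique_leaves(tree)
    return tree


def write_delimited(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    """Write a report table; the shared exit point for all delimited outputs."""
    path = Path(path)
    df.to_csv(path, sep=sep, index=False)
    return path


def distance_matrix_to_phylip(labels: Sequence[str], values) -> str:
    """Render a square distance matrix in PHYLIP square format."""
    buf = _io.StringIO()
    buf.write(f"{len(labels)}\n")
    for i, lab in enumerate(labels):
        row = " ".join(f"{values[i, j]:.6f}" for j in range(len(labels)))
        buf.write(f"{lab:<12s}{row}\n")
    return buf.getvalue()
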