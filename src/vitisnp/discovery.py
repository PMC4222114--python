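"""SNP discovery on IUB-coded consensus alignments.

Every alignment column is classified, for a chosen accession subset, into one
of four mutually exclusive categories:

* ``indel``       -- any selected accession carries '-';
* ``ambiguous``   -- otherwise, any selected accession carries 'N' (or a
                     3/4-base degenerate code, unscorable for a diploid);
* ``snp``         -- otherwise, the union of expanded IUB states spans >= 2
                     bases;
* ``monomorphic`` -- everything else.

The filter is deliberately conservative and dataset-wide per comparison set:
one ambiguous call in one accession excludes the column for that comparison.
Counts always reconcile to the aligned length.  SNP sets are therefore
subset-monotone: enlarging the accession set can only add polymorphism at
columns that remain scorable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import FrozenSet, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    AMBIGUOUS_LUT,
    BASES,
    MASK_LUT,
    POPCOUNT4,
    expand_iub,
    is_heterozygous,
    seq_to_bytes,
)
from .errors import AlignmentError
from .io import Dataset, MarkerAlignment

__all__ = [
    "SnpSite",
    "SiteAudit",
    "SnpDensity",
    "classify_columns",
    "discover_snps",
    "snp_density",
    "density_table",
]


@dataclass(frozen=True)
class SnpSite:
    """One valid polymorphic column: per-accession IUB states at a position."""

    marker_name: str
    position: int  # 0-based internally; reported 1-based
    states: dict[str, str]
    allele_set: FrozenSet[str]
    het_accessions: FrozenSet[str]

    @property
    def position_1based(self) -> int:
        return self.position + 1

    @property
    def label(self) -> str:
        return f"{self.marker_name}:{self.position_1based}"


@dataclass
class SiteAudit:
    """Per-marker column classification counts; they sum to aligned_length."""

    marker_name: str
    monomorphic: int
    snp: int
    indel: int
    ambiguous: int

    @property
    def total(self) -> int:
        return self.monomorphic + self.snp + self.indel + self.ambiguous


@dataclass(frozen=True)
class SnpDensity:
    """SNP frequency for a region/scope, as 'one SNP per bp_per_snp bases'."""

    name: str
    scope: str
    n_snps: int
    length_bp: int
    bp_per_snp: Optional[float]  # None when n_snps == 0 (undefined, not 0)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


def snp_density(n_snps: int, length_bp: int, name: str = "", scope: str = "") -> SnpDensity:
    """Bases per SNP, rounded half-up to 2 decimals.

    A region with zero SNPs has an *undefined* density (``bp_per_snp=None``),
    which is distinct from a density of zero.
    """
    if n_snps < 0 or length_bp < 0:
        raise ValueError("n_snps and length_bp must be non-negative")
    if length_bp == 0:
        raise ValueError("length_bp must be positive")
    if n_snps == 0:
        return SnpDensity(name, scope, 0, length_bp, None)
    return SnpDensity(name, scope, n_snps, length_bp, _round_half_up(length_bp / n_snps))


def classify_columns(
    alignment: MarkerAlignment,
    accessions: Optional[Iterable[str]] = None,
    *,
    maf_filter: bool = False,
    maf_threshold: float = 0.95,
) -> tuple[list[SnpSite], SiteAudit]:
    """Scan all columns of one marker for a chosen accession subset.

    With ``maf_filter`` enabled (off by default, matching the study's waiver
    of the frequency-based SNP definition), a polymorphic column whose most
    common allele reaches ``maf_threshold`` of the 2N diploid allele copies is
    demoted to monomorphic.
    """
    accs = list(accessions) if accessions is not None else alignment.accession_ids
    if not accs:
        raise AlignmentError("accession subset must be non-empty")
    missing = [a for a in accs if a not in alignment.sequences]
    if missing:
        raise AlignmentError(
            f"marker {alignment.marker_name!r}: accessions not in alignment: {missing}"
        )

    arr = np.vstack([seq_to_bytes(alignment.sequences[a]) for a in accs])
    masks = MASK_LUT[arr]
    col_gap = (arr == ord("-")).any(axis=0)
    col_amb = (~col_gap) & AMBIGUOUS_LUT[arr].any(axis=0)
    union = np.bitwise_or.reduce(masks, axis=0)
    n_alleles = POPCOUNT4[union]
    col_snp = ~col_gap & ~col_amb & (n_alleles >= 2)

    sites: list[SnpSite] = []
    n_demoted = 0
    for j in np.nonzero(col_snp)[0]:
        states = {a: alignment.sequences[a][int(j)] for a in accs}
        if maf_filter:
            counts: dict[str, int] = {}
            for s in states.values():
                bases = expand_iub(s)
                if len(bases) == 1:
                    (b,) = bases
                    counts[b] = counts.get(b, 0) + 2
                else:
                    for b in bases:
                        counts[b] = counts.get(b, 0) + 1
            if max(counts.values()) / (2 * len(accs)) >= maf_threshold:
                n_demoted += 1
                col_snp[j] = False
                continue
        allele_set = frozenset(
            b for b, bit in zip(BASES, range(4)) if union[j] >> bit & 1
        )
        hets = frozenset(a for a, s in states.items() if is_heterozygous(s))
        sites.append(SnpSite(alignment.marker_name, int(j), states, allele_set, hets))

    audit = SiteAudit(
        marker_name=alignment.marker_name,
        monomorphic=int(
            ((~col_gap) & (~col_amb) & (~col_snp)).sum()
        ),
        snp=int(col_snp.sum()),
        indel=int(col_gap.sum()),
        ambiguous=int(col_amb.sum()),
    )
    assert audit.total == alignment.aligned_length
    return sites, audit


@dataclass
class DiscoveryResult:
    """Per-marker SNP sites and audits for one accession scope."""

    scope: str
    accessions: list[str]
    sites_by_marker: dict[str, list[SnpSite]]
    audits: dict[str, SiteAudit]
    marker_order: list[str] = field(default_factory=list)

    @property
    def all_sites(self) -> list[SnpSite]:
        order = self.marker_order or list(self.sites_by_marker)
        return [s for m in order for s in self.sites_by_marker[m]]

    @property
    def n_snps(self) -> int:
        return sum(len(v) for v in self.sites_by_marker.values())


def discover_snps(
    dataset: Dataset,
    accessions: Optional[Sequence[str]] = None,
    scope: str = "all",
    **kwargs,
) -> DiscoveryResult:
    """Run :func:`classify_columns` over every marker of a dataset."""
    accs = list(accessions) if accessions is not None else dataset.accession_ids
    sites_by_marker: dict[str, list[SnpSite]] = {}
    audits: dict[str, SiteAudit] = {}
    for aln in dataset.markers:
        present = [a for a in accs if a in aln.sequences]
        sites, audit = classify_columns(aln, present, **kwargs)
        sites_by_marker[aln.marker_name] = sites
        audits[aln.marker_name] = audit
    return DiscoveryResult(
        scope=scope,
        accessions=accs,
        sites_by_marker=sites_by_marker,
        audits=audits,
        marker_order=dataset.marker_names,
    )


def density_table(results: Sequence[DiscoveryResult], dataset: Dataset) -> pd.DataFrame:
    """Per-marker and combined SNP counts and densities for each scope,
    mirroring the layout of a per-region SNP frequency summary table."""
    rows = []
    for res in results:
        for name in dataset.marker_names:
            n = len(res.sites_by_marker[name])
            d = snp_density(n, dataset.marker(name).aligned_length, name, res.scope)
            rows.append(
                {
                    "region": name,
                    "scope": res.scope,
                    "length_bp": d.length_bp,
                    "n_snps": d.n_snps,
                    "bp_per_snp": d.bp_per_snp,
                }
            )
        d = snp_density(res.n_snps, dataset.total_length, "Combined", res.scope)
        rows.append(
            {
                "region": "Combined",
                "scope": res.scope,
                "length_bp": d.length_bp,
                "n_snps": d.n_snps,
                "bp_per_snp": d.bp_per_snp,
            }
        )
    return pd.DataFrame(rows)


def snp_report(result: DiscoveryResult) -> pd.DataFrame:
    """Long-format SNP site report: one row per site with 1-based position,
    allele set, heterozygote count and per-accession states."""
    rows = []
    for site in result.all_sites:
        rows.append(
            {
                "marker": site.marker_name,
                "position": site.position_1based,
                "alleles": "/".join(sorted(site.allele_set)),
                "n_het": len(site.het_accessions),
                "states": "".join(site.states[a] for a in result.accessions if a in site.states),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "position", "alleles", "n_het", "states"])


def audit_table(result: DiscoveryResult) -> pd.DataFrame:
    rows = [
        {
            "marker": a.marker_name,
            "monomorphic": a.monomorphic,
            "snp": a.snp,
            "indel": a.indel,
            "ambiguous": a.ambiguous,
            "total": a.total,
        }
        for a in result.audits.values()
    ]
    return pd.DataFrame(rows)
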