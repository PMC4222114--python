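"""Per-subgroup diversity statistics over diploid SNP loci.

Allele counts come from the IUB consensus states: a homozygote contributes
two copies of its base, a heterozygote one copy of each of its two bases,
so a subgroup of N individuals contributes 2N allele copies per locus.

Per locus, with allele frequencies p_i:

* na = number of alleles observed (p_i > 0)
* ne = 1 / sum(p_i^2)          (effective number of alleles)
* I  = -sum(p_i ln p_i)        (Shannon information index)
* H  = He = 1 - sum(p_i^2)     (Nei gene diversity / expected heterozygosity,
                                uncorrected -- no small-sample correction)
* Ho = fraction of heterozygous individuals
* Fis = 1 - Ho/He              (defined only where He > 0)

Table rows are means across all loci; monomorphic loci contribute na=1,
ne=1, I=0, H=0, Ho=0, except Fis which averages only over loci with He > 0.
The reported sample size is the allele count 2N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import expand_iub, is_heterozygous
from .discovery import SnpSite
from .errors import VitisnpError
from .io import AccessionMeta

__all__ = ["LocusStats", "DiversityRow", "locus_stats", "diversity_stats", "diversity_table"]


@dataclass(frozen=True)
class LocusStats:
    na: int
    ne: float
    I: float
    H: float  # == He
    Ho: float
    Fis: Optional[float]  # None where He == 0

    @property
    def He(self) -> float:
        return self.H

    @property
    def polymorphic(self) -> bool:
        return self.na >= 2


def locus_stats(states: Mapping[str, str]) -> LocusStats:
    """Diversity statistics for one locus from per-individual IUB states."""
    if not states:
        raise VitisnpError("locus has no individuals")
    counts: dict[str, int] = {}
    n_het = 0
    for s in states.values():
        bases = expand_iub(s)
        if not 1 <= len(bases) <= 2:
            raise VitisnpError(f"state {s!r} is not a valid diploid SNP state")
        if is_heterozygous(s):
            n_het += 1
            for b in bases:
                counts[b] = counts.get(b, 0) + 1
        else:
            (b,) = bases
            counts[b] = counts.get(b, 0) + 2
    total = 2 * len(states)
    p = np.array([c / total for c in counts.values()])
    sum_p2 = float((p**2).sum())
    He = 1.0 - sum_p2
    Ho = n_het / len(states)
    Fis = (1.0 - Ho / He) if He > 0 else None
    return LocusStats(
        na=len(counts),
        ne=1.0 / sum_p2,
        I=float(-(p * np.log(p)).sum()),
        H=He,
        Ho=Ho,
        Fis=Fis,
    )


@dataclass(frozen=True)
class DiversityRow:
    subgroup: str
    sample_size: int  # allele count, 2N
    n_loci: int
    n_polymorphic: int
    pct_polymorphic: float
    na: float
    ne: float
    I: float
    H: float
    Ho: float
    He: float
    Fis: Optional[float]


def diversity_stats(
    sites: Sequence[SnpSite], accessions: Sequence[str], subgroup: str = ""
) -> DiversityRow:
    """One diversity-table row for a subgroup over the given SNP loci.

    ``sites`` are the loci valid for the *full* comparison set; each is
    restricted to the subgroup's members here, so a locus may well be
    monomorphic within the subgroup.
    """
    accs = list(accessions)
    if not accs:
        raise VitisnpError(f"subgroup {subgroup!r} has no accessions")
    per_locus = []
    for site in sites:
        missing = [a for a in accs if a not in site.states]
        if missing:
            raise VitisnpError(
                f"accession(s) {missing} lack a state at site {site.label}"
            )
        per_locus.append(locus_stats({a: site.states[a] for a in accs}))
    n_loci = len(per_locus)
    if n_loci == 0:
        return DiversityRow(subgroup, 2 * len(accs), 0, 0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, None)
    n_poly = sum(1 for l in per_locus if l.polymorphic)
    fis_vals = [l.Fis for l in per_locus if l.Fis is not None]
    mean = lambda xs: float(sum(xs) / len(xs))  # noqa: E731
    return DiversityRow(
        subgroup=subgroup,
        sample_size=2 * len(accs),
        n_loci=n_loci,
        n_polymorphic=n_poly,
        pct_polymorphic=100.0 * n_poly / n_loci,
        na=mean([l.na for l in per_locus]),
        ne=mean([l.ne for l in per_locus]),
        I=mean([l.I for l in per_locus]),
        H=mean([l.H for l in per_locus]),
        Ho=mean([l.Ho for l in per_locus]),
        He=mean([l.H for l in per_locus]),
        Fis=mean(fis_vals) if fis_vals else None,
    )


def diversity_table(
    sites: Sequence[SnpSite],
    meta: Sequence[AccessionMeta],
    include_total: bool = True,
) -> pd.DataFrame:
    """Diversity rows for every subgroup present in the metadata (plus a
    'Total' row over all accessions carrying states at the given loci)."""
    subgroups: dict[str, list[str]] = {}
    for m in meta:
        subgroups.setdefault(m.subgroup, []).append(m.accession_id)
    rows = [diversity_stats(sites, accs, sg) for sg, accs in sorted(subgroups.items())]
    if include_total:
        rows.append(diversity_stats(sites, [m.accession_id for m in meta], "Total"))
    recs = []
    for r in rows:
        recs.append(
            {
                "subgroup": r.subgroup,
                "sample_size_2N": r.sample_size,
                "n_loci": r.n_loci,
                "n_polymorphic": r.n_polymorphic,
                "pct_polymorphic": round(r.pct_polymorphic, 2),
                "na": round(r.na, 4),
                "ne": round(r.ne, 4),
                "I": round(r.I, 4),
                "H": round(r.H, 4),
                "Ho": round(r.Ho, 4),
                "He": round(r.He, 4),
                "Fis": round(r.Fis, 4) if r.Fis is not None else math.nan,
            }
        )
    return pd.DataFrame(recs)
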