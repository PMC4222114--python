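"""Character-based genotypes, diagnostic keys and naming reports.

A *genotype* here is the concatenated per-site diploid state string of an
accession over all indexed SNP sites, with heterozygous sites kept as their
two-base IUB code rather than split into phased alleles.  Two accessions
share a genotype iff their strings are identical character-for-character:
'A' and 'R' are different character states even though they share an allele,
because homozygous and heterozygous calls are distinct observations.

Diagnostic *characteristic attributes* (CAs) follow the pure/simple/compound
terminology of character-based barcoding: a pure-simple CA is a single
(position, state) pair present in every member of a genotype group and in no
outsider; a compound CA is a minimal combination of such pairs that is
jointly diagnostic when no single position suffices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .discovery import SnpSite
from .errors import VitisnpError
from .io import AccessionMeta

__all__ = [
    "GenotypeProfile",
    "GenotypeGroup",
    "CharacterAttribute",
    "NamingReport",
    "build_genotype_matrix",
    "collapse_genotypes",
    "diagnose_group",
    "diagnose_all",
    "naming_report",
    "one_off_pairs",
]


@dataclass
class GenotypeProfile:
    """Concatenated genotype strings over an ordered site index."""

    site_index: list[tuple[str, int]]  # (marker_name, 0-based position)
    genotype_strings: dict[str, str]

    def __post_init__(self) -> None:
        n = len(self.site_index)
        for acc, s in self.genotype_strings.items():
            if len(s) != n:
                raise VitisnpError(
                    f"genotype string for {acc!r} has length {len(s)}, "
                    f"expected {n}"
                )

    @property
    def accessions(self) -> list[str]:
        return list(self.genotype_strings)

    @property
    def n_sites(self) -> int:
        return len(self.site_index)

    def site_labels(self) -> list[str]:
        return [f"{m}:{p + 1}" for m, p in self.site_index]


@dataclass
class GenotypeGroup:
    """A maximal set of accessions sharing one genotype string."""

    group_id: int
    members: list[str]
    genotype: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CharacterAttribute:
    """A diagnostic (positions, states) set for one genotype group.

    ``category`` is ``"pure-simple"`` for a single diagnostic position and
    ``"compound"`` for a minimal multi-position combination.
    """

    group_id: int
    positions: tuple[tuple[str, int], ...]
    states: tuple[str, ...]
    category: str

    @property
    def size(self) -> int:
        return len(self.positions)

    def labels(self) -> list[str]:
        return [f"{m}:{p + 1}={s}" for (m, p), s in zip(self.positions, self.states)]


def build_genotype_matrix(
    sites: Sequence[SnpSite],
    accessions: Sequence[str],
    marker_order: Optional[Sequence[str]] = None,
) -> GenotypeProfile:
    """Build one genotype character string per accession.

    Sites are ordered by fixed marker order then ascending position.  Every
    accession must carry a state at every indexed site; sites must therefore
    have been discovered (filtered) for this same accession subset.
    """
    if marker_order is None:
        seen: list[str] = []
        for s in sites:
            if s.marker_name not in seen:
                seen.append(s.marker_name)
        marker_order = seen
    rank = {m: i for i, m in enumerate(marker_order)}
    ordered = sorted(sites, key=lambda s: (rank[s.marker_name], s.position))
    strings: dict[str, list[str]] = {a: [] for a in accessions}
    for site in ordered:
        for a in accessions:
            try:
                strings[a].append(site.states[a])
            except KeyError:
                raise VitisnpError(
                    f"accession {a!r} has no state at site {site.label}; "
                    "re-filter sites for this accession subset first"
                )
    return GenotypeProfile(
        site_index=[(s.marker_name, s.position) for s in ordered],
        genotype_strings={a: "".join(chars) for a, chars in strings.items()},
    )


def collapse_genotypes(profile: GenotypeProfile) -> list[GenotypeGroup]:
    """Partition accessions by exact genotype-string equality.

    Group ids are assigned by descending size, ties broken by first-seen
    order of the group's first member; ids start at 1.
    """
    by_string: dict[str, list[str]] = {}
    for acc, s in profile.genotype_strings.items():
        by_string.setdefault(s, []).append(acc)
    first_seen = {s: i for i, s in enumerate(by_string)}
    ordered = sorted(by_string.items(), key=lambda kv: (-len(kv[1]), first_seen[kv[0]]))
    return [
        GenotypeGroup(group_id=i + 1, members=members, genotype=s)
        for i, (s, members) in enumerate(ordered)
    ]


def _covers(target: str, outsiders: Sequence[str], positions: Iterable[int]) -> bool:
    """True iff no outsider matches the target string at all given positions."""
    pos = list(positions)
    return all(any(o[j] != target[j] for j in pos) for o in outsiders)


def diagnose_group(
    group: GenotypeGroup,
    profile: GenotypeProfile,
    max_exhaustive: int = 3,
) -> list[CharacterAttribute]:
    """Derive diagnostic characteristic attributes for one genotype group.

    Returns every pure-simple CA (single positions whose state occurs in no
    outsider).  If none exists, a minimal compound CA is searched: exhaustive
    over position subsets of size 2..``max_exhaustive`` (smallest first, then
    lexicographic by site order), then a greedy set-cover fallback whose
    result is pruned to minimality by subset deletion.  Because genotype
    groups are distinct strings, a compound CA always exists.
    """
    target = group.genotype
    outsiders = sorted(
        {s for s in profile.genotype_strings.values() if s != target}
    )
    if not outsiders:
        raise VitisnpError(
            f"group {group.group_id} has no complement to diagnose against"
        )
    n = profile.n_sites

    # boolean separation matrix (outsider x position), vectorised
    out_mat = np.frombuffer("".join(outsiders).encode("ascii"), np.uint8).reshape(
        len(outsiders), n
    )
    tgt = np.frombuffer(target.encode("ascii"), np.uint8)
    diff = out_mat != tgt

    pure = [int(j) for j in np.nonzero(diff.all(axis=0))[0]]
    if pure:
        return [
            CharacterAttribute(
                group_id=group.group_id,
                positions=(profile.site_index[j],),
                states=(target[j],),
                category="pure-simple",
            )
            for j in pure
        ]

    # candidate positions: those separating at least one outsider; packed as
    # per-position outsider bitmasks for fast union tests
    candidates = [int(j) for j in np.nonzero(diff.any(axis=0))[0]]
    packed = np.packbits(diff[:, candidates], axis=0)
    sep_mask = {
        j: int.from_bytes(packed[:, idx].tobytes(), "big")
        for idx, j in enumerate(candidates)
    }
    full = int.from_bytes(
        np.packbits(np.ones(len(outsiders), dtype=bool)).tobytes(), "big"
    )

    def make_ca(positions: Sequence[int]) -> CharacterAttribute:
        return CharacterAttribute(
            group_id=group.group_id,
            positions=tuple(profile.site_index[j] for j in positions),
            states=tuple(target[j] for j in positions),
            category="compound",
        )

    for k in range(2, max(2, max_exhaustive) + 1):
        if max_exhaustive < 2:
            break
        for combo in itertools.combinations(candidates, k):
            m = 0
            for j in combo:
                m |= sep_mask[j]
            if m == full:
                return [make_ca(combo)]

    # greedy set cover over outsiders, then prune to minimality
    uncovered = full
    chosen: list[int] = []
    while uncovered:
        best_j, best_gain = None, -1
        for j in candidates:
            gain = bin(sep_mask[j] & uncovered).count("1")
            if gain > best_gain:
                best_j, best_gain = j, gain
        if best_j is None or best_gain == 0:  # pragma: no cover - unreachable
            raise VitisnpError("internal error: outsiders not separable")
        chosen.append(best_j)
        uncovered &= ~sep_mask[best_j]
    for j in sorted(chosen, reverse=True):
        trial = [x for x in chosen if x != j]
        m = 0
        for x in trial:
            m |= sep_mask[x]
        if trial and m == full:
            chosen = trial
    return [make_ca(tuple(sorted(chosen)))]


def diagnose_all(
    groups: Sequence[GenotypeGroup],
    profile: GenotypeProfile,
    max_exhaustive: int = 3,
) -> dict[int, list[CharacterAttribute]]:
    """Diagnostic CA key for every group (requires >= 2 groups)."""
    if len(groups) < 2:
        raise VitisnpError("diagnosis needs at least two genotype groups")
    return {
        g.group_id: diagnose_group(g, profile, max_exhaustive=max_exhaustive)
        for g in groups
    }


@dataclass
class NamingReport:
    """Synonymy/homonymy/clone-consistency findings, all re-derivable from
    the genotype partition plus metadata.

    * synonymy: >= 2 distinct cultivar names confined to one genotype group;
    * homonymy (incl. mislabels): one cultivar name split across >= 2 groups;
    * clone_checks: cultivars with multiple accessions, and whether all of
      them fell into a single group (no intra-cultivar variability).
    """

    synonymy_candidates: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)
    homonymy_candidates: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    clone_checks: list[tuple[str, int, tuple[int, ...], bool]] = field(default_factory=list)


def naming_report(
    groups: Sequence[GenotypeGroup], meta: Sequence[AccessionMeta]
) -> NamingReport:
    by_id: Mapping[str, AccessionMeta] = {m.accession_id: m for m in meta}
    name_to_groups: dict[str, set[int]] = {}
    group_names: dict[int, list[str]] = {}
    name_to_accs: dict[str, list[str]] = {}
    for g in groups:
        names = []
        for acc in g.members:
            name = by_id[acc].cultivar_name
            names.append(name)
            name_to_groups.setdefault(name, set()).add(g.group_id)
            name_to_accs.setdefault(name, []).append(acc)
        group_names[g.group_id] = names

    homonyms = {n for n, gs in name_to_groups.items() if len(gs) >= 2}
    report = NamingReport()
    for n in sorted(homonyms):
        report.homonymy_candidates.append((n, tuple(sorted(name_to_groups[n]))))
    for g in groups:
        exclusive = sorted(set(group_names[g.group_id]) - homonyms)
        if len(exclusive) >= 2:
            report.synonymy_candidates.append((g.group_id, tuple(exclusive)))
    acc_group = {acc: g.group_id for g in groups for acc in g.members}
    for name in sorted(name_to_accs):
        accs = name_to_accs[name]
        if len(accs) >= 2:
            gids = tuple(sorted({acc_group[a] for a in accs}))
            report.clone_checks.append((name, len(accs), gids, len(gids) == 1))
    return report


def one_off_pairs(groups: Sequence[GenotypeGroup]) -> list[tuple[int, int, int]]:
    """Pairs of genotype groups differing at exactly one indexed site,
    reported as (group_id_a, group_id_b, site_offset).  Such near-identical
    genotypes often flag parent/offspring or clonal-variant relationships."""
    out = []
    for a, b in itertools.combinations(groups, 2):
        diffs = [j for j, (x, y) in enumerate(zip(a.genotype, b.genotype)) if x != y]
        if len(diffs) == 1:
            out.append((a.group_id, b.group_id, diffs[0]))
    return out


# ---------------------------------------------------------------------------
# report tables


def genotype_table(profile: GenotypeProfile, groups: Sequence[GenotypeGroup]) -> pd.DataFrame:
    acc_group = {acc: g.group_id for g in groups for acc in g.members}
    return pd.DataFrame(
        {
            "accession_id": profile.accessions,
            "group_id": [acc_group[a] for a in profile.accessions],
            "genotype": [profile.genotype_strings[a] for a in profile.accessions],
        }
    )


def ca_key_table(cas: Mapping[int, Sequence[CharacterAttribute]]) -> pd.DataFrame:
    rows = []
    for gid in sorted(cas):
        for ca in cas[gid]:
            rows.append(
                {
                    "group_id": gid,
                    "category": ca.category,
                    "n_positions": ca.size,
                    "attribute": " & ".join(ca.labels()),
                }
            )
    return pd.DataFrame(rows, columns=["group_id", "category", "n_positions", "attribute"])


def naming_tables(report: NamingReport) -> dict[str, pd.DataFrame]:
    return {
        "synonymy": pd.DataFrame(
            [
                {"group_id": gid, "cultivar_names": "; ".join(names)}
                for gid, names in report.synonymy_candidates
            ],
            columns=["group_id", "cultivar_names"],
        ),
        "homonymy": pd.DataFrame(
            [
                {"cultivar_name": n, "group_ids": "; ".join(map(str, gids))}
                for n, gids in report.homonymy_candidates
            ],
            columns=["cultivar_name", "group_ids"],
        ),
        "clones": pd.DataFrame(
            [
                {
                    "cultivar_name": n,
                    "n_accessions": k,
                    "group_ids": "; ".join(map(str, gids)),
                    "consistent": ok,
                }
                for n, k, gids, ok in report.clone_checks
            ],
            columns=["cultivar_name", "n_accessions", "group_ids", "consistent"],
        ),
    }
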