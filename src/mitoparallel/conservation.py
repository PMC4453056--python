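"""Interaction-site conservation (WCGU) over structure-annotated alignments.

For a site (a pair of alignment columns), WCGU is the percentage of
sequences carrying a canonical pair — Watson:Crick or G:U — among the
sequences that have a resolved nucleotide at *both* columns. Gapped or
ambiguous rows never enter the denominator, which makes the statistic
insensitive to rRNA length reduction. Noncanonical tertiary sites are
scored as the complement (100 − WCGU).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import InteractionSite, StructureAlignment

CANONICAL_PAIRS = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)
_NUCLEOTIDES = frozenset("ACGU")


@dataclass
class ConservationProfile:
    site_class: str
    group: str
    values: list[float]
    n_sites: int


def is_canonical_pair(b1: str, b2: str) -> bool:
    """True exactly for unordered {A,U}, {G,C}, {G,U}."""
    if b1 not in _NUCLEOTIDES or b2 not in _NUCLEOTIDES:
        return False
    return frozenset((b1, b2)) in CANONICAL_PAIRS


def wcgu(
    site: InteractionSite,
    aln: StructureAlignment,
    group_filter: Optional[str] = None,
) -> Optional[float]:
    """Canonical-pair conservation of one site, in percent.

    Only A/C/G/U count as resolved nucleotides; IUPAC ambiguity codes are
    treated like gaps. Returns None when no sequence has two resolved
    bases at the site.
    """
    if not aln.has_site(site):
        raise ValueError(f"site {site} does not belong to this alignment")
    i, j = site.col_i - 1, site.col_j - 1
    num = den = 0
    for seq, group in zip(aln.sequences, aln.seq_groups):
        if group_filter is not None and group != group_filter:
            continue
        b1, b2 = seq[i], seq[j]
        if b1 not in _NUCLEOTIDES or b2 not in _NUCLEOTIDES:
            continue
        den += 1
        if frozenset((b1, b2)) in CANONICAL_PAIRS:
            num += 1
    if den == 0:
        return None
    return 100.0 * num / den


def noncanonical_conservation(
    site: InteractionSite,
    aln: StructureAlignment,
    group_filter: Optional[str] = None,
) -> Optional[float]:
    """Complement conservation for noncanonical tertiary sites."""
    if site.site_class != "tertiary_noncanonical":
        raise ValueError(
            "noncanonical_conservation only applies to tertiary_noncanonical "
            f"sites, got {site.site_class!r}"
        )
    v = wcgu(site, aln, group_filter)
    if v is None:
        return None
    return 100.0 - v


def site_conservation(
    site: InteractionSite,
    aln: StructureAlignment,
    group_filter: Optional[str] = None,
) -> Optional[float]:
    """Class-appropriate conservation value for any site."""
    if site.site_class == "tertiary_noncanonical":
        return noncanonical_conservation(site, aln, group_filter)
    return wcgu(site, aln, group_filter)


def conservation_profiles(
    aln: StructureAlignment,
    groups: Optional[Iterable[str]] = None,
    descending: bool = True,
) -> list[ConservationProfile]:
    """Ordered conservation profiles for every (group, site class) data set.

    Three sequence groups and four site classes yield twelve profiles.
    Sites with an empty denominator are dropped; ordering is numeric with
    ties kept stable by site index.
    """
    if groups is None:
        seen: list[str] = []
        for g in aln.seq_groups:
            if g not in seen:
                seen.append(g)
        groups = seen
    classes_present: list[str] = []
    for s in aln.sites:
        if s.site_class not in classes_present:
            classes_present.append(s.site_class)
    profiles: list[ConservationProfile] = []
    for group in groups:
        for cls in classes_present:
            vals = [
                v
                for s in aln.sites
                if s.site_class == cls
                and (v := site_conservation(s, aln, group)) is not None
            ]
            vals.sort(reverse=descending)
            profiles.append(
                ConservationProfile(
                    site_class=cls, group=group, values=vals, n_sites=len(vals)
                )
            )
    return profiles


def profiles_to_frame(profiles: list[ConservationProfile]) -> pd.DataFrame:
    records = [
        {"site_class": p.site_class, "group": p.group, "rank": rank, "value": v}
        for p in profiles
        for rank, v in enumerate(p.values, start=1)
    ]
    return pd.DataFrame(records, columns=["site_class", "group", "rank", "value"])
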