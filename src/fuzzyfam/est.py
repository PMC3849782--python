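"""EST expression profiling: redundant/unique classification and group overlap.

Expressed sequence tags (ESTs) aligned to the genes of a group are
classified by multiplicity: an EST is *redundant* within a group when it
has two or more retained alignment records to genes of that group (same or
different genes — "multiple positions"), and *unique* when it has exactly
one. Comparing the redundant and unique EST id sets of two gene groups
measures how much expression evidence the groups share; subfamilies with
distinct functions are expected to share few ESTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import json

from .io import EstHit


@dataclass
class EstGroupProfile:
    """Redundant/unique EST sets for one gene group."""

    group_label: str
    genes_with_hits: int
    redundant_ests: frozenset[str]
    unique_ests: frozenset[str]

    def __post_init__(self) -> None:
        if self.redundant_ests & self.unique_ests:
            raise ValueError("redundant and unique EST sets must be disjoint")

    @property
    def n_redundant(self) -> int:
        return len(self.redundant_ests)

    @property
    def n_unique(self) -> int:
        return len(self.unique_ests)


@dataclass
class OverlapStats:
    """Cross-group common EST counts with percentages of a reference group."""

    reference_group: str
    common_redundant: int
    common_unique: int
    pct_common_redundant: float | None
    pct_common_unique: float | None


def classify_ests(hits: Iterable[EstHit], group: str) -> EstGroupProfile:
    """Build the redundant/unique EST profile of one gene group.

    ``hits`` should already be E-value-filtered and deduplicated (see
    :func:`fuzzyfam.io.read_est_hits`); only hits whose group label matches
    ``group`` are considered.
    """
    per_est: dict[str, int] = {}
    genes: set[str] = set()
    for h in hits:
        if h.group_label != group:
            continue
        per_est[h.est_id] = per_est.get(h.est_id, 0) + 1
        genes.add(h.gene_id)
    redundant = frozenset(e for e, c in per_est.items() if c >= 2)
    unique = frozenset(e for e, c in per_est.items() if c == 1)
    return EstGroupProfile(group, len(genes), redundant, unique)


def _pct(common: int, reference: int) -> float | None:
    if reference == 0:
        return None
    return round(100.0 * common / reference, 1)


def group_overlap_stats(
    profile_a: EstGroupProfile,
    profile_b: EstGroupProfile,
    reference: str | None = None,
) -> OverlapStats:
    """Common redundant/unique EST counts between two group profiles.

    Common counts are set intersections by EST id; the percentages are
    taken of the reference group's counts (default: the first profile).
    A reference group with zero ESTs of a kind yields percentage None.
    """
    reference = reference or profile_a.group_label
    if reference == profile_a.group_label:
        ref = profile_a
    elif reference == profile_b.group_label:
        ref = profile_b
    else:
        raise ValueError(f"reference {reference!r} is neither profile's group")
    common_r = len(profile_a.redundant_ests & profile_b.redundant_ests)
    common_u = len(profile_a.unique_ests & profile_b.unique_ests)
    return OverlapStats(
        reference_group=reference,
        common_redundant=common_r,
        common_unique=common_u,
        pct_common_redundant=_pct(common_r, ref.n_redundant),
        pct_common_unique=_pct(common_u, ref.n_unique),
    )


def profiles_from_counts(
    label_a: str,
    label_b: str,
    n_a: int,
    n_b: int,
    n_common: int,
    kind: str = "redundant",
) -> tuple[EstGroupProfile, EstGroupProfile]:
    """Construct two synthetic profiles realizing given set sizes and overlap.

    Useful for working from published summary counts: builds EST id sets of
    sizes ``n_a`` and ``n_b`` sharing exactly ``n_common`` ids, as either
    redundant or unique sets (the other set left empty).
    """
    if n_common > min(n_a, n_b):
        raise ValueError("common count exceeds a group's size")
    shared = [f"est_shared_{i}" for i in range(n_common)]
    only_a = [f"est_a_{i}" for i in range(n_a - n_common)]
    only_b = [f"est_b_{i}" for i in range(n_b - n_common)]
    empty = frozenset()
    set_a, set_b = frozenset(shared + only_a), frozenset(shared + only_b)
    if kind == "redundant":
        pa = EstGroupProfile(label_a, 0, set_a, empty)
        pb = EstGroupProfile(label_b, 0, set_b, empty)
    else:
        pa = EstGroupProfile(label_a, 0, empty, set_a)
        pb = EstGroupProfile(label_b, 0, empty, set_b)
    return pa, pb


def load_reference_est_counts() -> dict:
    """Load the packaged reference EST profile counts for the two CPP groups.

    Published summary counts of redundant/unique ESTs per gene group and
    their cross-group overlaps, by EST source database and species subset.
    """
    with resources.files("fuzzyfam.data").joinpath(
        "cpp_est_profiles.json"
    ).open() as fh:
        return json.load(fh)
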