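"""Residue-class composition of domain subsequences.

Extracts domain intervals (e.g. the ~46-residue cysteine-rich CXC domains
of CPP transcription factors) from protein sequences and computes the
percentage of acidic, basic and hydrophobic residues per sequence, plus
unweighted group means. The default class sets are acidic {D, E}, basic
{K, R, H} and hydrophobic {A, V, L, I, M, F, W}; cysteine is deliberately
excluded from the hydrophobic class because Cys-rich domains (CXC carries
~9 cysteines in ~46 residues) would otherwise dominate the hydrophobic
percentage. The scheme is fully configurable as long as classes stay
disjoint.

A packaged reference table (``data/cxc_domain_composition.csv``) carries
published per-gene composition percentages of CXC domains for the two
plant CPP subfamilies, used as a worked fixture for the group-mean
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import STANDARD_AA, DomainHit, SequenceRecord

DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
    "hydrophobic": frozenset("AVLIMFW"),
}


@dataclass(frozen=True)
class ResidueClassScheme:
    """Named disjoint residue classes over the 20 standard amino acids."""

    classes: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, letters in self.classes.items():
            letters = set(letters)
            if not letters <= STANDARD_AA:
                raise ValueError(f"class {name!r} contains non-standard letters")
            if letters & seen:
                raise ValueError(f"class {name!r} overlaps another class")
            seen |= letters

    @property
    def names(self) -> list[str]:
        return list(self.classes)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (3.245 -> 3.25, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def extract_domain_subsequences(
    record: SequenceRecord,
    hits: Iterable[DomainHit],
    model_filter: str | Sequence[str] | None = None,
) -> str:
    """Concatenate the residues covered by matching domain hits.

    Coordinates are 1-based inclusive; overlapping intervals are merged so
    no residue is counted twice. Returns the empty string (caller should
    flag it) when no hit matches.
    """
    if isinstance(model_filter, str):
        model_filter = [model_filter]
    intervals = []
    for h in hits:
        if h.sequence_id != record.id:
            continue
        if model_filter is not None and h.domain_model not in model_filter:
            continue
        if h.start is None or h.end is None:
            raise ValueError(
                f"hit {h.domain_model} on {record.id} lacks coordinates"
            )
        if h.end > len(record.sequence):
            raise ValueError(
                f"hit {h.domain_model} interval ({h.start},{h.end}) exceeds "
                f"sequence {record.id} length {len(record.sequence)}"
            )
        intervals.append((h.start, h.end))
    if not intervals:
        return ""
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 0:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return "".join(record.sequence[s - 1 : e] for s, e in merged)


def residue_class_percentages(
    subsequence: str, scheme: ResidueClassScheme | None = None
) -> dict[str, float]:
    """Percentage of residues in each class: 100 * count / length."""
    if not subsequence:
        raise ValueError("cannot compute composition of an empty subsequence")
    scheme = scheme or ResidueClassScheme()
    L = len(subsequence)
    return {
        name: 100.0 * sum(subsequence.count(c) for c in letters) / L
        for name, letters in scheme.classes.items()
    }


def composition_table(
    records: Sequence[SequenceRecord],
    hits: Iterable[DomainHit],
    groups: Mapping[str, str],
    model_filter: str | Sequence[str] | None = None,
    scheme: ResidueClassScheme | None = None,
) -> pd.DataFrame:
    """Per-sequence composition rows (sequence_id, group, class percentages)."""
    scheme = scheme or ResidueClassScheme()
    hits = list(hits)
    rows = []
    for rec in records:
        sub = extract_domain_subsequences(rec, hits, model_filter)
        if not sub:
            continue
        row = {"sequence_id": rec.id, "group": groups.get(rec.id, "")}
        row.update(residue_class_percentages(sub, scheme))
        rows.append(row)
    return pd.DataFrame(rows)


def group_composition_means(
    table: pd.DataFrame,
    class_names: Sequence[str] | None = None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Unweighted per-group arithmetic means of class percentages.

    Means are half-up rounded to ``ndigits`` for reporting; raw values stay
    available in ``table``. Raises on an empty table or empty group.
    """
    if table.empty:
        raise ValueError("composition table is empty")
    if class_names is None:
        class_names = [c for c in table.columns if c not in ("sequence_id", "group")]
    means = table.groupby("group")[list(class_names)].mean()
    if (table.groupby("group").size() < 1).any():
        raise ValueError("empty group in composition table")
    return means.map(lambda v: round_half_up(v, ndigits))


def load_reference_composition() -> pd.DataFrame:
    """Load the packaged CXC-domain composition reference table.

    Columns: sequence_id, group (I/II), acidic, basic, hydrophobic — the
    published per-gene percentages for CXC domains in the two plant CPP
    subfamilies (Arabidopsis, rice and maize genes).
    """
    with resources.files("fuzzyfam.data").joinpath(
        "cxc_domain_composition.csv"
    ).open() as fh:
        return pd.read_csv(fh)
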