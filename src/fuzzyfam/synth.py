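"""Synthetic protein families with planted subfamily structure.

Generates multi-family protein sets the way the clustering pipeline expects
to see them: each family descends from its own random ancestor sequence
(so families differ in k-mer content at a controlled divergence) and
carries its own domain architecture (so domain-count features separate
families too). Matching domain-hit tables, EST-hit tables with planted
redundant/unique/common composition, and the ground-truth family labels
are emitted alongside, making end-to-end parameter-recovery experiments
possible without any external database.

Amino acids are drawn uniformly over the 20 standard letters by default —
no claim of biological realism; a frequency table can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io import DomainHit, EstHit, SequenceRecord

AA_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic multi-family protein set.

    ``seed_divergence`` is the per-site substitution probability applied
    when deriving one family ancestor from another (between-family signal);
    ``within_noise`` the per-site substitution probability from ancestor to
    family member (within-family variation).
    """

    n_families: int = 2
    seqs_per_family: int = 20
    length_range: tuple[int, int] = (300, 500)
    seed_divergence: float = 0.5
    within_noise: float = 0.05
    domain_models: Sequence[Sequence[tuple[str, int]]] | None = None
    aa_freqs: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        if not (0 <= self.seed_divergence <= 1 and 0 <= self.within_noise <= 1):
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if self.length_range[0] < 4:
            raise ValueError("minimum length must cover the longest k-mer (4)")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")


@dataclass
class PlantedTruth:
    """Ground-truth family label per generated sequence id."""

    labels: dict[str, int]

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


def _aa_probs(spec: FamilySpec) -> np.ndarray:
    if spec.aa_freqs is None:
        return np.full(len(AA_LETTERS), 1.0 / len(AA_LETTERS))
    p = np.array([spec.aa_freqs.get(a, 0.0) for a in AA_LETTERS], float)
    if p.sum() <= 0:
        raise ValueError("amino-acid frequency table sums to zero")
    return p / p.sum()


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            probs: np.ndarray) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        # resample until the letter actually changes, keeping the rate exact
        new = rng.choice(len(AA_LETTERS), p=probs)
        while new == out[i]:
            new = rng.choice(len(AA_LETTERS), p=probs)
        out[i] = new
    return out


def _default_architectures(n_families: int) -> list[list[tuple[str, int]]]:
    # Family f gets one shared model (same count everywhere, uninformative)
    # plus a family-specific model, mimicking conserved-plus-diagnostic
    # domain architectures.
    return [
        [("DOM_shared", 2), (f"DOM_fam{f}", 1 + f % 2)]
        for f in range(n_families)
    ]


def generate_family_set(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], list[DomainHit], PlantedTruth]:
    """Generate sequences, domain hits and truth labels for one family set.

    Per family: one ancestor is drawn (the first uniformly at random, each
    subsequent one by mutating the first at ``seed_divergence``), then each
    member mutates the ancestor at ``within_noise``. Domain hits follow the
    family's architecture with E-values drawn below 1. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _aa_probs(spec)
    architectures = (
        list(spec.domain_models) if spec.domain_models is not None
        else _default_architectures(spec.n_families)
    )
    if len(architectures) != spec.n_families:
        raise ValueError("need one domain architecture per family")
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    base = rng.choice(len(AA_LETTERS), size=length, p=probs)
    ancestors = [base]
    for _ in range(1, spec.n_families):
        ancestors.append(_mutate(base, spec.seed_divergence, rng, probs))
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    labels: dict[str, int] = {}
    for f, ancestor in enumerate(ancestors):
        for m in range(spec.seqs_per_family):
            sid = f"fam{f}_seq{m}"
            member = _mutate(ancestor, spec.within_noise, rng, probs)
            seq = "".join(AA_LETTERS[i] for i in member)
            records.append(SequenceRecord(sid, seq))
            labels[sid] = f
            pos = 1
            for model, copies in architectures[f]:
                for _ in range(copies):
                    e = float(10 ** rng.uniform(-10, -0.1))
                    end = min(pos + 45, length)
                    hits.append(DomainHit(sid, model, e, pos, end))
                    pos = min(pos + 50, length - 45)
    return records, hits, PlantedTruth(labels)


def adjusted_rand_index(
    truth: PlantedTruth, ids: Sequence[str], labels: Sequence[int]
) -> float:
    """Chance-corrected agreement between planted and inferred partitions."""
    if set(ids) != set(truth.labels):
        raise ValueError("id sets of truth and labels differ")
    if len(ids) != len(labels):
        raise ValueError("ids and labels lengths differ")
    return float(adjusted_rand_score(truth.as_array(ids), np.asarray(labels)))


@dataclass
class PlantedEstCounts:
    """Expected Table-style counts emitted alongside a generated EST table."""

    redundant: dict[str, int]
    unique: dict[str, int]
    common_redundant: int
    common_unique: int


def generate_est_table(
    truth: PlantedTruth,
    ests_per_group: int = 50,
    redundancy_rate: float = 0.5,
    sharing_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[EstHit], PlantedEstCounts]:
    """Generate an EST-hit table with planted redundant/unique/common structure.

    For each of the (two or more) groups implied by ``truth``, draws
    ``ests_per_group`` ESTs; each is redundant (2 alignment records within
    the group) with probability ``redundancy_rate``, else unique (1
    record). A ``sharing_rate`` fraction of each kind is additionally
    aligned into the *next* group with matching multiplicity there, making
    those ESTs common between the two groups. Returns the hits plus the
    exact expected counts.
    """
    if not (0 <= redundancy_rate <= 1 and 0 <= sharing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    groups = sorted(set(truth.labels.values()))
    genes_by_group = {
        g: sorted(i for i, f in truth.labels.items() if f == g) for g in groups
    }
    hits: list[EstHit] = []
    redundant: dict[str, set[str]] = {str(g): set() for g in groups}
    unique: dict[str, set[str]] = {str(g): set() for g in groups}

    def align(est: str, group: int, n_records: int) -> None:
        genes = genes_by_group[group]
        for j in range(n_records):
            gene = genes[int(rng.integers(len(genes)))]
            e = float(10 ** rng.uniform(-30, -6))
            hits.append(EstHit(est, gene, str(group), e,
                               start=1 + 10 * j, end=100 + 10 * j))
        (redundant if n_records >= 2 else unique)[str(group)].add(est)

    for g in groups:
        nxt = groups[(groups.index(g) + 1) % len(groups)]
        for i in range(ests_per_group):
            est = f"est_g{g}_{i}"
            n_rec = 2 if rng.random() < redundancy_rate else 1
            align(est, g, n_rec)
            if rng.random() < sharing_rate:
                align(est, nxt, n_rec)
    a, b = str(groups[0]), str(groups[1])
    counts = PlantedEstCounts(
        redundant={g: len(s) for g, s in redundant.items()},
        unique={g: len(s) for g, s in unique.items()},
        common_redundant=len(redundant[a] & redundant[b]),
        common_unique=len(unique[a] & unique[b]),
    )
    return hits, counts
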