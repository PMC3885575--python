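"""Superfamily dataset assembly.

Raw domain sequences grouped by (superfamily, four-digit EC) are clustered
at 95% identity, one representative per cluster is kept, the
structure-linked representative of the enzyme is chosen, predictor
eligibility is decided (the enzyme needs a representative structure, ten or
more sequences, at least one other enzyme in the superfamily and ten or more
negative sequences), and the surviving sequences are split 80/20 into
training and test per enzyme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SequenceRecord
from .scoring import global_identity

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeGroup",
    "SuperfamilyDataset",
    "cluster_redundancy",
    "select_representative",
    "remove_redundancy",
    "build_roster",
    "split_train_test",
    "build_superfamily_dataset",
]

IDENTITY_CUTOFF = 0.95
MIN_POSITIVES = 10
MIN_NEGATIVES = 10
TRAIN_FRACTION = 0.8


def cluster_redundancy(
    records: Sequence[SequenceRecord],
    identity_cutoff: float = IDENTITY_CUTOFF,
) -> dict[str, int]:
    """Single-linkage clusters of sequences at ≥ ``identity_cutoff`` identity.

    Pairwise identity is computed from a global alignment with the shorter
    sequence length as denominator (closest to the legacy blastclust
    behaviour).  Records are pre-sorted by id, so the cluster labels are
    deterministic and independent of input order.
    """
    recs = sorted(records, key=lambda r: r.id)
    n = len(recs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(recs[i], recs[j], denominator="shorter") / 100.0
            if ident >= identity_cutoff:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    cluster_map: dict[str, int] = {}
    for i, rec in enumerate(recs):
        root = find(i)
        if root not in roots:
            roots[root] = len(roots)
        cluster_map[rec.id] = roots[root]
    return cluster_map


@dataclass
class EnzymeGroup:
    """All sequences of one four-digit EC within one superfamily."""

    ec: str
    superfamily: str
    members: list[SequenceRecord]
    representative: Optional[SequenceRecord] = None
    cluster_map: dict[str, int] = field(default_factory=dict)
    eligible: bool = True
    ineligibility_reason: str = ""

    @property
    def n_sequences(self) -> int:
        return len(self.members)


def select_representative(group: EnzymeGroup) -> Optional[SequenceRecord]:
    """Choose the enzyme's representative among structure-linked members.

    Longest sequence first; ties by numerically lowest (best) resolution;
    remaining ties by lexicographic id.  Returns None (and flags the group
    ineligible) when no member carries a structure reference.
    """
    candidates = [m for m in group.members if m.structure_ref is not None]
    if not candidates:
        group.eligible = False
        group.ineligibility_reason = "no representative structure"
        return None
    rep = min(
        candidates,
        key=lambda r: (-len(r.sequence), r.structure_ref.resolution, r.id),
    )
    rep.is_representative = True
    group.representative = rep
    return rep


def remove_redundancy(group: EnzymeGroup, identity_cutoff: float = IDENTITY_CUTOFF) -> None:
    """Cluster the group and keep one sequence per cluster.

    The cluster containing the structure-linked representative is represented
    by it; every other cluster is represented by its longest sequence (ties
    by id).
    """
    group.cluster_map = cluster_redundancy(group.members, identity_cutoff)
    clusters: dict[int, list[SequenceRecord]] = {}
    for rec in group.members:
        clusters.setdefault(group.cluster_map[rec.id], []).append(rec)
    kept: list[SequenceRecord] = []
    rep_id = group.representative.id if group.representative else None
    for cid in sorted(clusters):
        members = clusters[cid]
        if rep_id is not None and any(m.id == rep_id for m in members):
            kept.append(next(m for m in members if m.id == rep_id))
        else:
            kept.append(min(members, key=lambda r: (-len(r.sequence), r.id)))
    group.members = sorted(kept, key=lambda r: r.id)


@dataclass
class SuperfamilyDataset:
    """One superfamily's enzyme groups, predictor roster and train/test split."""

    superfamily: str
    groups: list[EnzymeGroup]
    roster: set[str] = field(default_factory=set)
    split: dict[str, str] = field(default_factory=dict)  # sequence id -> "train" | "test"
    split_seed: Optional[int] = None

    def group(self, ec: str) -> EnzymeGroup:
        for g in self.groups:
            if g.ec == ec:
                return g
        raise KeyError(f"no enzyme {ec!r} in superfamily {self.superfamily}")

    def training_members(self, ec: str) -> list[SequenceRecord]:
        return [m for m in self.group(ec).members if self.split.get(m.id) == "train"]

    def test_members(self, ec: str) -> list[SequenceRecord]:
        return [m for m in self.group(ec).members if self.split.get(m.id) == "test"]

    def negatives(self, ec: str, side: str = "train") -> list[SequenceRecord]:
        out: list[SequenceRecord] = []
        for g in self.groups:
            if g.ec == ec:
                continue
            out.extend(m for m in g.members if self.split.get(m.id) == side)
        return out


def build_roster(dataset: SuperfamilyDataset) -> set[str]:
    """Apply the three eligibility rules; counts are post-redundancy-removal.

    An EC enters the roster iff (1) the superfamily contains at least one
    other enzyme, (2) the enzyme has a representative structure and ≥ 10
    sequences, and (3) the other enzymes total ≥ 10 sequences.
    """
    roster: set[str] = set()
    total = sum(g.n_sequences for g in dataset.groups)
    for g in dataset.groups:
        if len(dataset.groups) < 2:
            continue  # rule 1
        if g.representative is None or g.n_sequences < MIN_POSITIVES:
            continue  # rule 2
        if total - g.n_sequences < MIN_NEGATIVES:
            continue  # rule 3
        roster.add(g.ec)
    dataset.roster = roster
    return roster


def _n_train(n: int, fraction: float = TRAIN_FRACTION) -> int:
    """Round half away from zero: ⌊fraction·n⌉."""
    return int(math.floor(fraction * n + 0.5))


def split_train_test(dataset: SuperfamilyDataset, seed: int) -> dict[str, str]:
    """80/20 per-enzyme random split; the representative always trains.

    The representative's training alignment feeds the enzyme's PSSM and
    conservation profile, so leaving it in the test side would leak.
    """
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for g in dataset.groups:
        ids = sorted(m.id for m in g.members)
        n = len(ids)
        if n < 2:
            logger.warning("enzyme %s has %d sequence(s); all assigned to training", g.ec, n)
            for i in ids:
                split[i] = "train"
            continue
        n_train = _n_train(n)
        rep_id = g.representative.id if g.representative else None
        order = list(rng.permutation(ids))
        if rep_id is not None and rep_id in order:
            order.remove(rep_id)
            order.insert(0, rep_id)
        for rank, seq_id in enumerate(order):
            split[seq_id] = "train" if rank < n_train else "test"
    dataset.split = split
    dataset.split_seed = seed
    return split


def build_superfamily_dataset(
    records: Sequence[SequenceRecord],
    seed: int,
    identity_cutoff: float = IDENTITY_CUTOFF,
    deduplicate: bool = True,
) -> SuperfamilyDataset:
    """Full assembly: group, select representatives, deduplicate, roster, split."""
    superfamilies = {r.superfamily for r in records}
    if len(superfamilies) != 1:
        raise ValueError(f"records span {len(superfamilies)} superfamilies; expected one")
    (sf,) = superfamilies
    by_ec: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.ec is None:
            raise ValueError(f"record {rec.id!r} lacks an EC annotation")
        by_ec.setdefault(rec.ec, []).append(rec)
    groups = [
        EnzymeGroup(ec=ec, superfamily=sf, members=sorted(ms, key=lambda r: r.id))
        for ec, ms in sorted(by_ec.items())
    ]
    for g in groups:
        select_representative(g)
        if deduplicate:
            remove_redundancy(g, identity_cutoff)
    dataset = SuperfamilyDataset(superfamily=sf, groups=groups)
    build_roster(dataset)
    split_train_test(dataset, seed)
    return dataset
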