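"""Synthetic superfamily generator with known ground truth.

Emulates a CATH-style superfamily: several enzyme classes share one
ancestral scaffold; some positions are invariant across all classes (shared
conserved), some are invariant within a class but differ between classes
(planted SDRs, the signal the forest should recover), and the rest drift
independently at a configured substitution rate.  Active-site / ligand-
binding annotations are drawn from a declared mixture of shared and
class-discriminative positions, so both the attribute machinery and the
rf-SDR recovery analyses can be exercised end to end with no downloads.

Mutation is star-topology i.i.d. (each descendant drawn independently from
its class ancestor); no phylogenetic correlation is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import AA20, AnnotationRow, SequenceRecord, StructureRef, blosum62
from .scoring import global_identity

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticSuperfamily",
    "generate_superfamily",
    "identity_band_queries",
]

# Residues whose BLOSUM62 pairwise scores are mutually <= -1; planted-SDR
# class residues are drawn from pools like this so positional attributes
# carry signal under every scoring scheme.
_MAX_PLANTED_SIM = -1


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic superfamily.

    Defaults describe a small but realistic within-superfamily problem:
    three enzyme classes of twenty domain sequences of length 150, five
    shared conserved and five planted SDR positions, 8% per-position
    background substitution, no indels.
    """

    n_enzymes: int = 3
    seqs_per_enzyme: int = 20
    length: int = 150
    n_shared_conserved: int = 5
    n_planted_sdr: int = 5
    subst: float = 0.08
    indel_prob: float = 0.0
    # annotated sites: how many planted (class-discriminative) and shared
    # positions are labelled active / binding on each representative
    asr_planted: int = 3
    asr_shared: int = 2
    lbr_planted: int = 2
    lbr_shared: int = 3
    superfamily: str = "1.10.10.10"
    ec_prefix: str = "1.1.1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_conserved + self.n_planted_sdr > self.length:
            raise ValueError("more special positions than sequence length")
        if self.asr_planted + self.lbr_planted > self.n_planted_sdr:
            raise ValueError("more annotated planted positions than planted SDRs")
        if self.asr_shared + self.lbr_shared > self.n_shared_conserved:
            raise ValueError("more annotated shared positions than shared conserved positions")
        if not 0 <= self.subst <= 1 or not 0 <= self.indel_prob <= 1:
            raise ValueError("probabilities must be in [0, 1]")

    def ec(self, k: int) -> str:
        return f"{self.ec_prefix}.{k + 1}"


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the sequences."""

    scaffold: str
    shared_positions: list[int]
    planted_positions: list[int]
    class_residues: dict[str, dict[int, str]]  # ec -> {position: residue}
    annotated: dict[str, dict[str, list[int]]]  # ec -> {"asr": [...], "lbr": [...]}
    sequence_labels: dict[str, str]  # sequence id -> ec

    def annotated_positions(self, ec: str) -> set[int]:
        return set(self.annotated[ec]["asr"]) | set(self.annotated[ec]["lbr"])

    def discriminative_annotated(self, ec: str) -> set[int]:
        return self.annotated_positions(ec) & set(self.planted_positions)

    def shared_annotated(self, ec: str) -> set[int]:
        return self.annotated_positions(ec) & set(self.shared_positions)


@dataclass
class SyntheticSuperfamily:
    config: SyntheticConfig
    records: list[SequenceRecord]  # members + per-class representatives
    annotations: list[AnnotationRow]
    truth: TruthRecord

    def representative(self, ec: str) -> SequenceRecord:
        for rec in self.records:
            if rec.is_representative and rec.ec == ec:
                return rec
        raise KeyError(ec)


def _pick_class_residues(rng: np.random.Generator, n_classes: int, matrix) -> list[str]:
    """Greedily pick residues mutually dissimilar under BLOSUM62 (pairwise <= -1)."""
    order = list(rng.permutation(list(AA20)))
    chosen: list[str] = []
    for aa in order:
        if all(matrix.score(aa, c) <= _MAX_PLANTED_SIM for c in chosen):
            chosen.append(aa)
        if len(chosen) == n_classes:
            return chosen
    raise ValueError(f"cannot find {n_classes} mutually dissimilar residues")


def _mutate(
    rng: np.random.Generator,
    ancestor: str,
    frozen: set[int],
    subst: float,
    indel_prob: float,
) -> str:
    out = []
    for i, aa in enumerate(ancestor):
        if i in frozen:
            out.append(aa)
            continue
        if indel_prob > 0 and rng.random() < indel_prob:
            continue  # single-residue deletion
        if rng.random() < subst:
            choices = [c for c in AA20 if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def generate_superfamily(config: SyntheticConfig) -> SyntheticSuperfamily:
    """Generate one superfamily: sequences, site annotations and truth.

    Per class the representative is the member consensus (tagged with a
    dummy structure reference so it passes the eligibility rules); planted
    positions are never mutated, so they are perfectly class-diagnostic.
    Byte-identical output under an identical config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    matrix = blosum62()
    L = config.length
    scaffold = "".join(AA20[i] for i in rng.integers(len(AA20), size=L))
    special = rng.choice(L, size=config.n_shared_conserved + config.n_planted_sdr, replace=False)
    shared = sorted(int(p) for p in special[: config.n_shared_conserved])
    planted = sorted(int(p) for p in special[config.n_shared_conserved :])
    frozen = set(shared) | set(planted)

    class_residues: dict[str, dict[int, str]] = {}
    per_position_residues = {pos: _pick_class_residues(rng, config.n_enzymes, matrix) for pos in planted}
    ancestors: dict[str, str] = {}
    for k in range(config.n_enzymes):
        ec = config.ec(k)
        chars = list(scaffold)
        class_residues[ec] = {}
        for pos in planted:
            chars[pos] = per_position_residues[pos][k]
            class_residues[ec][pos] = chars[pos]
        ancestors[ec] = "".join(chars)

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    annotations: list[AnnotationRow] = []
    annotated: dict[str, dict[str, list[int]]] = {}
    for k in range(config.n_enzymes):
        ec = config.ec(k)
        members: list[str] = []
        for s in range(config.seqs_per_enzyme):
            seq = _mutate(rng, ancestors[ec], frozen, config.subst, config.indel_prob)
            seq_id = f"e{k + 1}s{s + 1:02d}"
            records.append(SequenceRecord(id=seq_id, sequence=seq, ec=ec, superfamily=config.superfamily))
            labels[seq_id] = ec
            members.append(seq)
        consensus = _consensus(members, ancestors[ec])
        rep_id = f"e{k + 1}rep"
        records.append(
            SequenceRecord(
                id=rep_id,
                sequence=consensus,
                ec=ec,
                superfamily=config.superfamily,
                is_representative=True,
                structure_ref=StructureRef(pdb_id=f"SYN{k + 1}", resolution=1.5),
            )
        )
        labels[rep_id] = ec

        asr = planted[: config.asr_planted] + shared[: config.asr_shared]
        lbr = (
            planted[config.asr_planted : config.asr_planted + config.lbr_planted]
            + shared[config.asr_shared : config.asr_shared + config.lbr_shared]
        )
        annotated[ec] = {"asr": sorted(asr), "lbr": sorted(lbr)}
        for pos in sorted(asr):
            annotations.append(
                AnnotationRow(
                    superfamily=config.superfamily, ec=ec, representative_id=rep_id,
                    position=pos, category="active", evidence="synthetic-truth",
                )
            )
        for pos in sorted(lbr):
            annotations.append(
                AnnotationRow(
                    superfamily=config.superfamily, ec=ec, representative_id=rep_id,
                    position=pos, category="binding", evidence="synthetic-truth",
                )
            )

    truth = TruthRecord(
        scaffold=scaffold,
        shared_positions=shared,
        planted_positions=planted,
        class_residues=class_residues,
        annotated=annotated,
        sequence_labels=labels,
    )
    return SyntheticSuperfamily(config=config, records=records, annotations=annotations, truth=truth)


def _consensus(members: list[str], ancestor: str) -> str:
    """Majority residue per column; ties resolved toward the ancestor."""
    L = len(ancestor)
    out = []
    for i in range(L):
        counts: dict[str, int] = {}
        for m in members:
            if i < len(m):
                counts[m[i]] = counts.get(m[i], 0) + 1
        if not counts:
            out.append(ancestor[i])
            continue
        best = max(counts.values())
        winners = sorted(aa for aa, c in counts.items() if c == best)
        out.append(ancestor[i] if ancestor[i] in winners else winners[0])
    return "".join(out)


def identity_band_queries(
    superfamily: SyntheticSuperfamily,
    band: tuple[float, float],
    n_per_class: int = 4,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Test queries whose global identity to their class representative lies
    in ``band`` (percent).

    Background positions are mutated one at a time until the identity falls
    into the band; planted SDR positions are never touched, so each query's
    class label remains valid by construction.  Realized identities are
    verified by re-alignment.
    """
    lo, hi = band
    cfg = superfamily.config
    floor = 100.0 * cfg.n_planted_sdr / cfg.length
    if hi <= lo or lo < 0 or hi > 100:
        raise ValueError(f"bad identity band {band}")
    if hi < floor:
        raise ValueError(
            f"band {band} infeasible: preserved planted positions impose an identity floor of {floor:.1f}%"
        )
    rng = np.random.default_rng(seed)
    planted = set(superfamily.truth.planted_positions)
    queries: list[SequenceRecord] = []
    for k in range(cfg.n_enzymes):
        ec = cfg.ec(k)
        rep = superfamily.representative(ec)
        for q in range(n_per_class):
            seq = _walk_into_band(rng, rep.sequence, planted, lo, hi)
            queries.append(
                SequenceRecord(
                    id=f"q{k + 1}b{int(lo)}n{q + 1}",
                    sequence=seq,
                    ec=ec,
                    superfamily=cfg.superfamily,
                )
            )
    return queries


def _walk_into_band(
    rng: np.random.Generator,
    reference: str,
    frozen: set[int],
    lo: float,
    hi: float,
    max_extra: int = 30,
) -> str:
    L = len(reference)
    mutable = [i for i in range(L) if i not in frozen]
    order = list(rng.permutation(mutable))
    chars = list(reference)
    # walk by Hamming identity first (each substitution moves it by 100/L),
    # then verify against the alignment-based identity and nudge if needed
    k = 0
    while 100.0 * (L - k) / L > hi and k < len(order):
        pos = order[k]
        choices = [c for c in AA20 if c != reference[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
        k += 1
    for _ in range(max_extra):
        realized = global_identity("".join(chars), reference)
        if realized <= hi:
            break
        if k >= len(order):
            raise ValueError(f"cannot reach identity band [{lo},{hi}]")
        pos = order[k]
        choices = [c for c in AA20 if c != reference[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
        k += 1
    realized = global_identity("".join(chars), reference)
    if not lo <= realized <= hi:
        raise ValueError(f"realized identity {realized:.1f}% missed band [{lo},{hi}]")
    return "".join(chars)
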