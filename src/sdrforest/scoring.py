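"""Pairwise alignment and attribute-vector construction.

Each per-enzyme predictor consumes one attribute vector per query: a
BLAST-type top-hit bit score, one full-length similarity score per available
scoring scheme, and one per-position score per annotated functional position
and scheme.  The built-in aligner is Needleman–Wunsch / Smith–Waterman with
affine gaps over BLOSUM62 (a gap of length g costs open + g·extend);
externally produced alignments or BLAST tabular files can be supplied
instead, so a structure-aware aligner can stand in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io import AA20, GAP, ProfileMatrix, ScoringMatrix, SequenceRecord, blosum62

__all__ = [
    "PairwiseAlignment",
    "AttributeDescriptor",
    "AttributeSchema",
    "AttributeVector",
    "align_global",
    "global_identity",
    "local_score",
    "local_bitscore",
    "top_hit_score",
    "position_score",
    "full_length_score",
    "build_schema",
    "build_attribute_vector",
]

# Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1
# (the BLAST protein defaults); exposed so alternative matrices can override.
KA_LAMBDA = 0.267
KA_K = 0.041
BLAST_GAP_OPEN = 11
BLAST_GAP_EXTEND = 1


@dataclass
class PairwiseAlignment:
    """A global alignment of a query onto a representative.

    ``rep_to_query[i]`` holds the query residue aligned to representative
    position i (0-based), or None where the query has a gap; it covers every
    representative position exactly once.
    """

    query_id: str
    rep_id: str
    aligned_query: str
    aligned_rep: str
    score: float
    rep_to_query: list[Optional[str]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_rep):
            raise ValueError("aligned strings differ in length")
        if not self.rep_to_query:
            self.rep_to_query = [
                (q if q != GAP else None)
                for q, r in zip(self.aligned_query, self.aligned_rep)
                if r != GAP
            ]


def _make_aligner(matrix: ScoringMatrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    sub = Align.substitution_matrices.Array(alphabet=matrix.alphabet, dims=2)
    for i, a in enumerate(matrix.alphabet):
        for b in matrix.alphabet:
            sub[a, b] = matrix.score(a, b)
    aligner.substitution_matrix = sub
    # PairwiseAligner charges open_gap_score for the first gap position and
    # extend_gap_score thereafter; shift so a length-g gap costs open + g*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_global(
    query: SequenceRecord | str,
    representative: SequenceRecord | str,
    matrix: ScoringMatrix | None = None,
    gap_open: float = 10,
    gap_extend: float = 1,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of query onto the representative."""
    matrix = matrix or blosum62()
    qid, qseq = _id_seq(query, "query")
    rid, rseq = _id_seq(representative, "representative")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "global")
    aln = aligner.align(rseq, qseq)[0]
    return PairwiseAlignment(
        query_id=qid,
        rep_id=rid,
        aligned_query=str(aln[1]),
        aligned_rep=str(aln[0]),
        score=float(aln.score),
    )


def _id_seq(obj: SequenceRecord | str, fallback: str) -> tuple[str, str]:
    if isinstance(obj, SequenceRecord):
        return obj.id, obj.sequence
    return fallback, obj


def global_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    denominator: str = "alignment",
    matrix: ScoringMatrix | None = None,
) -> float:
    """Percent identity from a global alignment.

    ``denominator``: ``alignment`` divides identities by the alignment length
    (the MTTSI convention); ``shorter`` divides by the shorter sequence length
    (the redundancy-clustering convention).
    """
    aln = align_global(a, b, matrix=matrix)
    matches = sum(
        1 for x, y in zip(aln.aligned_query, aln.aligned_rep) if x == y and x != GAP
    )
    if denominator == "alignment":
        denom = len(aln.aligned_query)
    elif denominator == "shorter":
        denom = min(len(_id_seq(a, "a")[1]), len(_id_seq(b, "b")[1]))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * matches / denom


def local_score(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    matrix: ScoringMatrix | None = None,
    gap_open: float = BLAST_GAP_OPEN,
    gap_extend: float = BLAST_GAP_EXTEND,
) -> float:
    """Optimal Smith–Waterman affine-gap score (raw, same units as the matrix)."""
    matrix = matrix or blosum62()
    _, qseq = _id_seq(query, "query")
    _, sseq = _id_seq(subject, "subject")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    return float(aligner.score(sseq, qseq))


def local_bitscore(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    matrix: ScoringMatrix | None = None,
    ka_lambda: float = KA_LAMBDA,
    ka_k: float = KA_K,
) -> tuple[float, bool]:
    """BLAST-style bit score via the Karlin–Altschul conversion.

    bits = (λ·S_raw − ln K)/ln 2.  Returns ``(bits, defined)``; a degenerate
    raw score of 0 (no positive-scoring local alignment) reports 0 bits with
    ``defined`` False so callers can mask it.
    """
    raw = local_score(query, subject, matrix=matrix)
    if raw <= 0:
        return 0.0, False
    bits = (ka_lambda * raw - math.log(ka_k)) / math.log(2)
    return bits, True


def top_hit_score(
    query: SequenceRecord,
    training_positives: Sequence[SequenceRecord],
    mode: str = "prediction",
    blast_table: Optional[dict[tuple[str, str], float]] = None,
) -> tuple[float, bool]:
    """Best bit score of the query against an enzyme's training sequences.

    ``mode='training'`` excludes the query's own record by id (a training
    sequence must not hit itself).  With ``blast_table`` the scores are read
    from a precomputed BLAST tabular map instead of being computed.
    """
    subjects = list(training_positives)
    if mode == "training":
        subjects = [s for s in subjects if s.id != query.id]
    elif mode != "prediction":
        raise ValueError(f"unknown top-hit mode {mode!r}")
    if not subjects:
        raise ValueError(f"no training sequences left for query {query.id!r}")
    best, defined = 0.0, False
    for subj in subjects:
        if blast_table is not None:
            bits = blast_table.get((query.id, subj.id))
            ok = bits is not None
            bits = bits if ok else 0.0
        else:
            bits, ok = local_bitscore(query, subj)
        if ok and (not defined or bits > best):
            best, defined = bits, True
    return best, defined


def position_score(
    alignment: PairwiseAlignment,
    position: int,
    scorer: ScoringMatrix | ProfileMatrix,
    rep_sequence: str | None = None,
) -> tuple[float, bool]:
    """Similarity score at one annotated representative position (0-based).

    Matrix mode scores sim(rep residue, query residue); profile mode looks up
    the profile column at the query residue.  A query gap yields the scorer's
    per-position minimum with the mask flag set.
    """
    if position < 0 or position >= len(alignment.rep_to_query):
        raise IndexError(
            f"position {position} outside representative length {len(alignment.rep_to_query)}"
        )
    q = alignment.rep_to_query[position]
    if isinstance(scorer, ProfileMatrix):
        if q is None:
            return scorer.min_for(position), False
        return scorer.score(position, q), True
    rep_res = (rep_sequence or alignment.aligned_rep.replace(GAP, ""))[position]
    if q is None:
        return scorer.min_for(rep_res), False
    return scorer.score(rep_res, q), True


def full_length_score(
    alignment: PairwiseAlignment,
    scorer: ScoringMatrix | ProfileMatrix,
    normalize: bool = True,
) -> float:
    """Whole-alignment similarity: mean (default) or sum of per-column scores
    over columns where both sequences carry residues."""
    rep_seq = alignment.aligned_rep.replace(GAP, "")
    total, n_cols = 0.0, 0
    if isinstance(scorer, ProfileMatrix):
        for pos, q in enumerate(alignment.rep_to_query):
            if q is not None:
                total += scorer.score(pos, q)
                n_cols += 1
    else:
        for q, r in zip(alignment.aligned_query, alignment.aligned_rep):
            if q != GAP and r != GAP:
                total += scorer.score(r, q)
                n_cols += 1
    if n_cols == 0:
        raise ValueError("no aligned residue columns between query and representative")
    return total / n_cols if normalize else total


@dataclass(frozen=True)
class AttributeDescriptor:
    """One attribute slot: its kind, scoring scheme and (for positions) the
    0-based representative position."""

    kind: str  # "blast" | "full_length" | "position"
    matrix: str = ""  # "blosum62" | "pssm" | "esst"
    position: Optional[int] = None

    @property
    def name(self) -> str:
        if self.kind == "blast":
            return "blast"
        if self.kind == "full_length":
            return f"full_{self.matrix}"
        return f"pos{self.position + 1}_{self.matrix}"  # 1-based in reports


@dataclass
class AttributeSchema:
    """Ordered attribute layout of one enzyme's predictor.

    With all three schemes (BLOSUM62, PSSM, ESST) available the layout is
    1 blast + 3 full-length + 3 per annotated position (n = 3m + 4); without
    an external ESST profile the esst slots are dropped (n = 2m + 3).
    """

    descriptors: list[AttributeDescriptor]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")

    @property
    def n(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def matrices(self) -> list[str]:
        seen: list[str] = []
        for d in self.descriptors:
            if d.kind == "full_length":
                seen.append(d.matrix)
        return seen

    def positions(self) -> list[int]:
        return sorted({d.position for d in self.descriptors if d.kind == "position"})


def build_schema(site_positions: Sequence[int], matrices: Sequence[str] = ("blosum62", "pssm")) -> AttributeSchema:
    """Schema as a pure function of the annotated positions and available schemes."""
    desc = [AttributeDescriptor(kind="blast")]
    for m in matrices:
        desc.append(AttributeDescriptor(kind="full_length", matrix=m))
    for pos in sorted(set(site_positions)):
        for m in matrices:
            desc.append(AttributeDescriptor(kind="position", matrix=m, position=pos))
    return AttributeSchema(desc)


@dataclass
class AttributeVector:
    """One query's values under an AttributeSchema, with a missing-value mask.

    Masked entries (query gap at an annotated position; undefined bit score)
    already carry the documented gap-fill value, so ``values`` is complete.
    """

    query_id: str
    values: np.ndarray
    mask: np.ndarray  # True where the value is a fill, not an observation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")


def build_attribute_vector(
    query: SequenceRecord,
    model_spec,
    mode: str = "prediction",
    blast_table: Optional[dict[tuple[str, str], float]] = None,
    alignment: Optional[PairwiseAlignment] = None,
) -> AttributeVector:
    """Compute a query's full attribute vector for one enzyme's predictor.

    ``model_spec`` is an EnzymeModelSpec (representative, schema, scorers,
    training positives).  A precomputed query↔representative alignment may be
    passed to skip the built-in aligner.
    """
    schema: AttributeSchema = model_spec.schema
    if alignment is None:
        alignment = align_global(query, model_spec.representative, matrix=model_spec.matrix)
    if len(alignment.rep_to_query) != len(model_spec.representative.sequence):
        raise ValueError("alignment does not cover the representative sequence")
    scorers = model_spec.scorers()
    values = np.empty(schema.n)
    mask = np.zeros(schema.n, dtype=bool)
    for i, desc in enumerate(schema.descriptors):
        if desc.kind == "blast":
            bits, ok = top_hit_score(
                query, model_spec.training_positives, mode=mode, blast_table=blast_table
            )
            values[i], mask[i] = bits, not ok
        elif desc.kind == "full_length":
            values[i] = full_length_score(alignment, scorers[desc.matrix])
        else:
            values[i], ok = position_score(
                alignment,
                desc.position,
                scorers[desc.matrix],
                rep_sequence=model_spec.representative.sequence,
            )
            mask[i] = not ok
    return AttributeVector(query_id=query.id, values=values, mask=mask)
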