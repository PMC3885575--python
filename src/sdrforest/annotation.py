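"""Functional-position sets, conservation profiles and PSSMs.

For each enzyme three disjoint position sets on its representative sequence
feed the predictor: active-site residues (ASR — annotated catalytic, or both
catalytic and ligand-binding), ligand-binding residues (LBR — binding only)
and conserved-site residues (CSR — the top 10% lowest-entropy well-populated
alignment columns not already claimed).  Precedence is ASR > LBR > CSR.

Conservation uses the Shannon entropy of each column over the 20 residues
plus the gap symbol (natural log); columns with more than 20% gaps are
excluded.  The PSSM scores a residue j at position i as Σ_k W_ki·sim(k, j)
with occurrence-dependent logarithmic weights W_ki = ln(c_ki+1)/ln(N+1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import AA20, GAP, AnnotationRow, MultipleAlignment, ProfileMatrix, ScoringMatrix
from .scoring import align_global

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSets",
    "ConservationProfile",
    "PSSM",
    "assemble_sites",
    "detect_ligand_contacts",
    "column_entropy",
    "select_csrs",
    "build_pssm",
    "stack_to_reference",
]

GAP_FRACTION_CUTOFF = 0.20  # columns with gap fraction strictly above are ineligible
CSR_FRACTION = 0.10

_SYMBOLS = AA20 + GAP  # 21-symbol scheme; X counts with the gap symbol


@dataclass
class SiteSets:
    """ASR/LBR/CSR position sets (0-based) on one representative sequence."""

    asr: set[int] = field(default_factory=set)
    lbr: set[int] = field(default_factory=set)
    csr: set[int] = field(default_factory=set)
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.asr & self.lbr or self.asr & self.csr or self.lbr & self.csr:
            raise ValueError("ASR/LBR/CSR sets must be pairwise disjoint")

    @property
    def all_positions(self) -> set[int]:
        return self.asr | self.lbr | self.csr

    def category_of(self, position: int) -> str:
        if position in self.asr:
            return "asr"
        if position in self.lbr:
            return "lbr"
        if position in self.csr:
            return "csr"
        raise KeyError(f"position {position} is not an annotated site")


def assemble_sites(
    annotation_rows: Iterable[AnnotationRow],
    mapping_alignments: Optional[Mapping[str, Mapping[int, int]]] = None,
    representative_length: Optional[int] = None,
) -> SiteSets:
    """Union site annotations over structures into ASR/LBR sets.

    A position annotated as active anywhere (and hence also one annotated both
    active and binding) becomes an ASR; binding-only positions become LBRs.
    ``mapping_alignments`` maps each ``structure_id`` to a dict from structure
    position to representative position; rows with an empty structure_id are
    taken to be in representative coordinates already.  Annotated positions
    falling in a mapping gap are dropped with a warning.
    """
    mapping_alignments = mapping_alignments or {}
    active: set[int] = set()
    binding: set[int] = set()
    provenance: dict[int, str] = {}
    for row in annotation_rows:
        if row.structure_id:
            if row.structure_id not in mapping_alignments:
                raise ValueError(
                    f"no mapping alignment supplied for structure {row.structure_id!r}"
                )
            mapped = mapping_alignments[row.structure_id].get(row.position)
            if mapped is None:
                logger.warning(
                    "annotation at %s position %d falls in a mapping gap; dropped",
                    row.structure_id,
                    row.position + 1,
                )
                continue
            pos = mapped
        else:
            pos = row.position
        if representative_length is not None and pos >= representative_length:
            raise ValueError(
                f"annotated position {pos + 1} beyond representative length {representative_length}"
            )
        (active if row.category == "active" else binding).add(pos)
        provenance.setdefault(pos, row.structure_id or row.evidence or "annotation")
    asr = active
    lbr = binding - active
    return SiteSets(asr=asr, lbr=lbr, provenance=provenance)


# Donor/acceptor-capable heavy atoms for the distance-based contact substitute.
_POLAR_ELEMENTS = {"N", "O", "S"}


def detect_ligand_contacts(
    pdb_path: str | Path,
    ligand_ids: Sequence[str],
    hbond_cutoff: float = 3.5,
    hydrophobic_cutoff: float = 3.9,
    chain_id: Optional[str] = None,
) -> set[int]:
    """Distance-based substitute for interaction-diagram ligand-contact calls.

    A residue is reported iff it has at least one polar–polar (N/O/S) atom
    pair within ``hbond_cutoff`` Å AND at least one carbon–carbon pair within
    ``hydrophobic_cutoff`` Å of any listed ligand (HET group).  This is an
    approximation of hydrogen-bond plus hydrophobic interaction detection —
    no hydrogen placement or bond geometry is attempted.  Returns 0-based
    residue indices along the chain's polymer sequence.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    ligand_atoms = []
    for chain in model:
        for res in chain:
            if res.get_resname().strip() in set(ligand_ids):
                ligand_atoms.extend(a for a in res.get_atoms())
    if not ligand_atoms:
        raise ValueError(f"no ligand residues {list(ligand_ids)} found in {pdb_path}")
    lig_coords = np.array([a.get_coord() for a in ligand_atoms])
    lig_polar = np.array([a.element in _POLAR_ELEMENTS for a in ligand_atoms])
    lig_carbon = np.array([a.element == "C" for a in ligand_atoms])

    hits: set[int] = set()
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        index = 0
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            atoms = [a for a in res.get_atoms()]  # first altloc by parser default
            coords = np.array([a.get_coord() for a in atoms])
            dist = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
            polar = np.array([a.element in _POLAR_ELEMENTS for a in atoms])
            carbon = np.array([a.element == "C" for a in atoms])
            has_hbond = bool(np.any(dist[np.ix_(polar, lig_polar)] <= hbond_cutoff)) if polar.any() else False
            has_hydrophobic = (
                bool(np.any(dist[np.ix_(carbon, lig_carbon)] <= hydrophobic_cutoff)) if carbon.any() else False
            )
            if has_hbond and has_hydrophobic:
                hits.add(index)
            index += 1
    return hits


@dataclass
class ConservationProfile:
    """Per-column entropies (nats), gap fractions and eligibility flags."""

    entropy: np.ndarray
    gap_fraction: np.ndarray
    fractions: np.ndarray  # (length, 21) over AA20 + gap
    eligible: np.ndarray

    @property
    def length(self) -> int:
        return self.entropy.shape[0]


def column_entropy(msa: MultipleAlignment) -> ConservationProfile:
    """Shannon entropy per alignment column over 20 residues + gap.

    S_k = −Σ_i P^i ln P^i with 0·ln 0 ≡ 0; columns whose gap fraction exceeds
    20% are flagged ineligible (their entropy is still reported).  'X' is an
    unknown residue and is counted with the gap symbol.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    L = msa.length
    fractions = np.zeros((L, len(_SYMBOLS)))
    sym_index = {s: i for i, s in enumerate(_SYMBOLS)}
    gap_idx = sym_index[GAP]
    for k in range(L):
        col = msa.column(k)
        for c in col:
            fractions[k, sym_index.get(c, gap_idx)] += 1
        fractions[k] /= len(col)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(fractions > 0, np.log(fractions), 0.0)
    entropy = -(fractions * logp).sum(axis=1)
    gap_fraction = fractions[:, gap_idx]
    eligible = gap_fraction <= GAP_FRACTION_CUTOFF
    return ConservationProfile(
        entropy=entropy, gap_fraction=gap_fraction, fractions=fractions, eligible=eligible
    )


def select_csrs(
    profile: ConservationProfile,
    sites: SiteSets,
    fraction: float = CSR_FRACTION,
) -> SiteSets:
    """Fill the CSR set: top-``fraction`` lowest-entropy eligible columns.

    ⌈fraction·n_eligible⌉ positions are selected (ties broken by ascending
    position index); positions already annotated ASR or LBR keep those labels
    and only the remainder becomes CSRs.
    """
    eligible_idx = np.flatnonzero(profile.eligible)
    if eligible_idx.size == 0:
        logger.warning("no eligible columns; CSR set left empty")
        return SiteSets(asr=set(sites.asr), lbr=set(sites.lbr), csr=set(), provenance=dict(sites.provenance))
    k = math.ceil(fraction * eligible_idx.size)
    order = sorted((int(i) for i in eligible_idx), key=lambda i: (profile.entropy[i], i))
    selected = set(order[:k])
    csr = selected - sites.asr - sites.lbr
    provenance = dict(sites.provenance)
    for pos in csr:
        provenance.setdefault(pos, "conservation")
    return SiteSets(asr=set(sites.asr), lbr=set(sites.lbr), csr=csr, provenance=provenance)


@dataclass
class PSSM:
    """Position-specific scoring matrix with logarithmic occurrence weights.

    ``counts[i, k]`` is the number of sequences carrying residue k at column
    i (gaps contribute no count); ``weights = ln(counts+1)/ln(N+1)`` and the
    score of residue j at column i is Σ_k weights[i, k]·sim(k, j).
    """

    counts: np.ndarray
    weights: np.ndarray
    profile: ProfileMatrix
    n_sequences: int


def build_pssm(msa: MultipleAlignment, matrix: ScoringMatrix) -> PSSM:
    """Build the weighted PSSM of one enzyme's training alignment."""
    N = msa.n_rows
    if N < 2:
        raise ValueError("a PSSM needs at least two sequences")
    L = msa.length
    counts = np.zeros((L, len(AA20)))
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    for i in range(L):
        for c in msa.column(i):
            if c in aa_index:
                counts[i, aa_index[c]] += 1
    weights = np.log(counts + 1.0) / np.log(N + 1.0)
    sim = np.array([[matrix.score(a, b) for b in AA20] for a in AA20])
    scores = weights @ sim
    return PSSM(
        counts=counts,
        weights=weights,
        profile=ProfileMatrix(scores, source_tag="pssm"),
        n_sequences=N,
    )


def stack_to_reference(
    records: Sequence,
    reference,
    matrix: ScoringMatrix | None = None,
) -> MultipleAlignment:
    """Stack global alignments of each record onto reference coordinates.

    Produces a star alignment whose columns are exactly the reference
    positions (reference insertions in members are discarded), standing in
    for a full progressive MSA aligned to the representative structure.
    Exact whenever the family has no indels relative to the reference.
    """
    ids, rows = [], []
    for rec in records:
        if rec.id == reference.id:
            ids.append(rec.id)
            rows.append(reference.sequence)
            continue
        aln = align_global(rec, reference, matrix=matrix)
        ids.append(rec.id)
        rows.append("".join(q if q is not None else GAP for q in aln.rep_to_query))
    if reference.id not in ids:
        ids.insert(0, reference.id)
        rows.insert(0, reference.sequence)
    return MultipleAlignment(ids=ids, rows=rows)
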