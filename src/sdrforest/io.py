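"""Readers and writers for every external format the pipeline touches.

Sequences travel as FASTA with metadata encoded in ``|key=value`` header
tokens (``ec``, ``sf``, ``rep``, ``pdb``); a sidecar TSV carrying the same
columns is accepted as an alternative.  Alignments are aligned FASTA or
CLUSTAL, substitution matrices use the NCBI text format, BLAST hits the
12-column tabular layout (outfmt 6), site annotations and profile matrices
plain TSV, and model bundles a joblib archive with a JSON manifest.

Internally every residue coordinate is 0-based half-open; this module is the
single conversion layer, so every position read from or written to disk is
1-based.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import joblib
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AA20",
    "ALPHABET",
    "GAP",
    "SequenceRecord",
    "StructureRef",
    "MultipleAlignment",
    "ScoringMatrix",
    "ProfileMatrix",
    "AnnotationRow",
    "FormatError",
    "IncompleteECError",
    "BundleVersionError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_scoring_matrix",
    "blosum62",
    "read_blast_tabular",
    "read_site_annotations",
    "write_site_annotations",
    "read_profile_matrix",
    "write_profile_matrix",
    "save_model_bundle",
    "load_model_bundle",
]

AA20 = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AA20 + "X"
GAP = "-"

EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
SF_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

BUNDLE_FORMAT_VERSION = 1


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class IncompleteECError(FormatError):
    """An EC annotation was not a complete four-digit number."""


class BundleVersionError(FormatError):
    """A model bundle was written by an incompatible schema version."""


@dataclass(frozen=True)
class StructureRef:
    """Pointer to a representative structure: PDB-style id, resolution (Å), chain."""

    pdb_id: str
    resolution: float
    chain: str = "A"

    def token(self) -> str:
        return f"{self.pdb_id}:{self.chain}:{self.resolution:g}"

    @classmethod
    def from_token(cls, token: str) -> "StructureRef":
        parts = token.split(":")
        if len(parts) != 3:
            raise FormatError(f"bad structure token {token!r}; expected id:chain:resolution")
        return cls(pdb_id=parts[0], chain=parts[1], resolution=float(parts[2]))


@dataclass
class SequenceRecord:
    """One enzyme domain sequence with its EC and superfamily annotations."""

    id: str
    sequence: str
    ec: Optional[str] = None
    superfamily: Optional[str] = None
    is_representative: bool = False
    structure_ref: Optional[StructureRef] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise FormatError(
                f"record {self.id!r}: residues {sorted(bad)} not in the 20 standard "
                "amino acids + X (B/Z/U and other ambiguity codes are rejected)"
            )
        if self.ec is not None and not EC_RE.match(self.ec):
            raise IncompleteECError(
                f"record {self.id!r}: EC {self.ec!r} is not a complete four-digit EC number"
            )
        if self.superfamily is not None and not SF_RE.match(self.superfamily):
            raise FormatError(
                f"record {self.id!r}: superfamily {self.superfamily!r} is not a dotted CATH-style id"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_header(description: str, lineno: Optional[int] = None) -> dict:
    """Parse ``id|ec=..|sf=..|rep=1|pdb=id:chain:res`` FASTA description."""
    where = f" (header line {lineno})" if lineno is not None else ""
    tokens = description.split("|")
    out = {"id": tokens[0].split()[0]}
    for tok in tokens[1:]:
        tok = tok.strip()
        if not tok:
            continue
        if "=" not in tok:
            raise FormatError(f"malformed header token {tok!r} in {description!r}{where}")
        key, value = tok.split("=", 1)
        if key not in {"ec", "sf", "rep", "pdb"}:
            raise FormatError(f"unknown header key {key!r} in {description!r}{where}")
        out[key] = value
    return out


def _record_from_header(meta: dict, seq: str) -> SequenceRecord:
    ref = StructureRef.from_token(meta["pdb"]) if "pdb" in meta else None
    return SequenceRecord(
        id=meta["id"],
        sequence=seq,
        ec=meta.get("ec"),
        superfamily=meta.get("sf"),
        is_representative=meta.get("rep", "0") in {"1", "true", "True"},
        structure_ref=ref,
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences with ``|key=value`` metadata headers.

    Sequences are upper-cased and trailing ``*`` stop characters stripped;
    record order is preserved.  Incomplete EC annotations (``3.2.1.-``) are
    rejected, mirroring the dataset filter.
    """
    path = Path(path)
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    records = []
    for i, rec in enumerate(seqs, start=1):
        meta = _parse_header(rec.description, lineno=i)
        seq = str(rec.seq).upper().rstrip("*").replace("*", "")
        records.append(_record_from_header(meta, seq))
    return records


def _format_header(record: SequenceRecord) -> str:
    parts = [record.id]
    if record.ec:
        parts.append(f"ec={record.ec}")
    if record.superfamily:
        parts.append(f"sf={record.superfamily}")
    if record.is_representative:
        parts.append("rep=1")
    if record.structure_ref is not None:
        parts.append(f"pdb={record.structure_ref.token()}")
    return "|".join(parts)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass
class MultipleAlignment:
    """Row-major MSA; columns indexed 0-based internally."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in count")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, k: int) -> str:
        return "".join(row[k] for row in self.rows)

    def gap_fraction(self, k: int) -> float:
        col = self.column(k)
        return col.count(GAP) / len(col)

    def row_by_id(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read an MSA; ``dialect`` is ``aligned-fasta`` or ``clustal``.

    ``.`` gap characters are normalized to ``-`` and residues upper-cased.
    """
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in aln]
    return MultipleAlignment(ids=ids, rows=rows)


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n{row}\n")


class ScoringMatrix:
    """Symmetric residue-pair substitution scores with a configurable gap score."""

    def __init__(self, alphabet: str, scores: np.ndarray, name: str = "", gap_score: float | None = None):
        self.alphabet = alphabet
        self.scores = np.asarray(scores, dtype=float)
        self.name = name
        self.gap_score = float(gap_score) if gap_score is not None else float(self.scores.min())
        self._index = {aa: i for i, aa in enumerate(alphabet)}
        if self.scores.shape != (len(alphabet), len(alphabet)):
            raise FormatError("scoring matrix shape does not match alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise FormatError(f"scoring matrix {name!r} is not symmetric")

    def score(self, a: str, b: str) -> float:
        if a == GAP or b == GAP:
            return self.gap_score
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in matrix alphabet") from None

    def row(self, a: str) -> np.ndarray:
        return self.scores[self._index[a]]

    def min_for(self, a: str) -> float:
        return float(self.row(a).min())


def read_scoring_matrix(path: str | Path, gap_score: float | None = None) -> ScoringMatrix:
    """Read an NCBI-style whitespace-separated substitution matrix."""
    path = Path(path)
    with path.open() as fh:
        try:
            mat = substitution_matrices.read(fh)
        except Exception as exc:  # Bio raises bare Exception subclasses here
            raise FormatError(f"{path}: cannot parse NCBI matrix ({exc})") from exc
    letters = "".join(mat.alphabet)
    keep = [i for i, aa in enumerate(letters) if aa in ALPHABET]
    alphabet = "".join(letters[i] for i in keep)
    missing = set(ALPHABET) - set(alphabet)
    if missing:
        raise FormatError(f"{path}: matrix lacks residues {sorted(missing)}")
    arr = np.asarray(mat)[np.ix_(keep, keep)]
    return ScoringMatrix(alphabet, arr, name=path.stem, gap_score=gap_score)


_BLOSUM62: Optional[ScoringMatrix] = None


def blosum62() -> ScoringMatrix:
    """The packaged canonical NCBI BLOSUM62 matrix (half-bit integer scores)."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        ref = resources.files("sdrforest").joinpath("data/blosum62.txt")
        with resources.as_file(ref) as path:
            _BLOSUM62 = read_scoring_matrix(path)
            _BLOSUM62.name = "blosum62"
    return _BLOSUM62


def read_blast_tabular(path: str | Path) -> dict[tuple[str, str], float]:
    """Read BLAST outfmt-6 hits, retaining the maximum bit score per pair.

    An empty file yields an empty map.
    """
    path = Path(path)
    hits: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 tab-separated columns")
            try:
                bits = float(fields[11])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric bit score {fields[11]!r}"
                ) from None
            key = (fields[0], fields[1])
            if bits > hits.get(key, float("-inf")):
                hits[key] = bits
    return hits


@dataclass(frozen=True)
class AnnotationRow:
    """One functional-site annotation on a representative sequence.

    ``position`` is 0-based internally (the TSV column is 1-based).
    ``structure_id`` names the complex structure the annotation came from;
    empty means the position is already in representative coordinates.
    """

    superfamily: str
    ec: str
    representative_id: str
    position: int
    category: str  # "active" | "binding"
    evidence: str = ""
    structure_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in {"active", "binding"}:
            raise FormatError(f"annotation category must be active/binding, got {self.category!r}")
        if self.position < 0:
            raise FormatError("annotation position must be positive (1-based in the TSV)")


_ANNOT_COLS = ["superfamily", "ec", "representative_id", "position", "category", "evidence", "structure_id"]


def read_site_annotations(path: str | Path) -> list[AnnotationRow]:
    """Read the site-annotation TSV (header row required; positions 1-based)."""
    path = Path(path)
    rows: list[AnnotationRow] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_ANNOT_COLS) - 2] != _ANNOT_COLS[: len(_ANNOT_COLS) - 2]:
            raise FormatError(f"{path}: unexpected annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            fields += [""] * (len(_ANNOT_COLS) - len(fields))
            try:
                pos1 = int(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {fields[3]!r}") from None
            rows.append(
                AnnotationRow(
                    superfamily=fields[0],
                    ec=fields[1],
                    representative_id=fields[2],
                    position=pos1 - 1,
                    category=fields[4],
                    evidence=fields[5],
                    structure_id=fields[6],
                )
            )
    return rows


def write_site_annotations(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ANNOT_COLS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [r.superfamily, r.ec, r.representative_id, str(r.position + 1), r.category, r.evidence, r.structure_id]
                )
                + "\n"
            )


@dataclass
class ProfileMatrix:
    """Per-position scores for the 20 residues on a representative sequence.

    ``source_tag`` records provenance: ``pssm`` (built here), ``esst``
    (externally supplied structure-conditioned profile) or ``external``.
    """

    scores: np.ndarray  # (length, 20), columns ordered as AA20
    source_tag: str = "external"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AA20):
            raise FormatError("profile matrix must be (length, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise FormatError("profile matrix contains non-finite values")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, residue: str) -> float:
        if residue == "X":
            return float(self.scores[position].mean())
        return float(self.scores[position, AA20.index(residue)])

    def min_for(self, position: int) -> float:
        return float(self.scores[position].min())


def read_profile_matrix(path: str | Path, source_tag: str = "external") -> ProfileMatrix:
    """Read a profile TSV: header ``position`` + 20 residue columns, 1-based rows."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "position" or "".join(header[1:]) != AA20:
            raise FormatError(f"{path}: profile header must be position + {AA20}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 21:
                raise FormatError(f"{path}:{lineno}: expected 21 columns")
            rows.append((int(fields[0]), [float(x) for x in fields[1:]]))
    rows.sort(key=lambda r: r[0])
    if [r[0] for r in rows] != list(range(1, len(rows) + 1)):
        raise FormatError(f"{path}: positions must be contiguous and 1-based")
    return ProfileMatrix(np.array([r[1] for r in rows]), source_tag=source_tag)


def write_profile_matrix(profile: ProfileMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("position\t" + "\t".join(AA20) + "\n")
        for i in range(profile.length):
            fh.write(str(i + 1) + "\t" + "\t".join(f"{v:.6g}" for v in profile.scores[i]) + "\n")


def save_model_bundle(model_set, path: str | Path) -> None:
    """Persist a trained predictor set with schema, seeds and format version."""
    from . import __version__

    payload = {
        "manifest": {
            "format_version": BUNDLE_FORMAT_VERSION,
            "package_version": __version__,
        },
        "model_set": model_set,
    }
    joblib.dump(payload, Path(path))


def load_model_bundle(path: str | Path):
    payload = joblib.load(Path(path))
    manifest = payload.get("manifest", {})
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise BundleVersionError(
            f"bundle format version {manifest.get('format_version')!r} "
            f"is incompatible with this package (expects {BUNDLE_FORMAT_VERSION})"
        )
    return payload["model_set"]


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps) for manifests."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
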