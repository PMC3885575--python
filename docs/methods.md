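# Methods

## Model

Each enzyme (four-digit EC number) inside a superfamily gets an independent
one-vs-rest binary classifier.  A query is described by an attribute vector
computed from alignments, never from raw sequence directly, so the
classifier sees the same information a careful curator would: overall
similarity and residue identity at functionally annotated positions.

The attribute layout for an enzyme with m annotated positions and the two
built-in scoring schemes is `n = 2m + 3`: one top-hit bit score, two
full-length scores (BLOSUM62 and PSSM) and two scores per position.  When an
external structure-conditioned profile (ESST-type) is supplied the third
scheme is added throughout and `n = 3m + 4`.  The forest has 500 trees and
`⌊√n⌋` candidate attributes per split; both values are recorded on the
fitted model.  The positive class is the enzyme's training sequences, the
negative class all other enzymes of the superfamily.

rf-SDR extraction walks the attributes in descending importance (mean
decrease in impurity by default; permutation importance by flag), keeps the
top `3·⌊√n⌋` (capped at n), discards the bit-score and full-length entries,
and collects the representative positions of the rest, deduplicated across
schemes.  Ties in importance break by schema index so the set is
reproducible.

## Functional-position sets

- **ASR / LBR**: taken from an annotation table in representative
  coordinates, or mapped onto the representative through per-structure
  pairwise mapping alignments; a position called active anywhere (including
  both active and binding) is an ASR, binding-only positions are LBRs.
- **CSR**: Shannon entropy `S_k = −Σ P_i ln P_i` per alignment column over
  the 20 residues plus the gap symbol; columns with gap fraction strictly
  above 20% are excluded.  The `⌈0.10·n_eligible⌉` lowest-entropy eligible
  columns are selected (ties by ascending index, ceiling so tiny alignments
  still select one); those already ASR/LBR keep their labels.
- **PSSM**: `score(i, j) = Σ_k W_ki·sim(k, j)` with
  `W_ki = ln(c_ki+1)/ln(N+1)` — the weight is 0 for absent residues, 1 for
  unanimous columns, and monotone in the count.  Gaps contribute no counts.
  Entropy, PSSM score and weight are each isolated in a single function so
  an alternative functional form is a one-line change.

Natural logarithms are used for both the column entropy and the superfamily
functional entropy; with ln, equal-frequency rosters of 1 / 2–4 / ≥5
distinct third-digit EC prefixes land exactly in the low / medium / high
diversity classes at the 0.5 and 1.5 nat cutoffs, which is the
correspondence the classification is meant to encode (log2 would not match
it).  The fourth-digit classification uses raw distinct-EC4 counts (1–5 /
6–10 / >10) rather than entropy cutoffs.

## Alignment and scores

The built-in aligner is Needleman–Wunsch (global; gap open 10, extend 1) and
Smith–Waterman (local; gap open 11, extend 1 — the protein-BLAST defaults)
over BLOSUM62, via Biopython's PairwiseAligner; a gap of length g costs
`open + g·extend`.  Bit scores use the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041.  The aligner is an interface: externally produced
pairwise alignments (aligned FASTA) and BLAST tabular hit files are accepted
wherever the built-in would run, so a structure-aware aligner can stand in
without code changes.

Design choices where the design was genuinely open:

- **Full-length score is length-normalized** (mean over both-residue
  columns) so it does not trivially encode sequence length; a raw-sum mode
  exists by flag.
- **Gap fill**: a query gap at an annotated position scores the scorer's
  per-position minimum — a gap is maximally unlike the representative
  residue — and sets a mask bit; forests receive the filled value because
  they need complete vectors.
- **Top-hit score in training mode excludes the query's own record** by id;
  a raw local score of 0 reports 0 bits with the mask set.
- **Vote threshold** is 0.5 with exact ties negative.
- The **baseline model** is an entropy-criterion decision tree
  (min leaf 2) on the single bit-score attribute; on a one-dimensional
  problem any entropy-based tree reduces to the information-gain-optimal
  threshold structure, which is all the baseline needs (verified against an
  exhaustive 1-D split search in the tests).

## Dataset assembly

Redundancy removal clusters each (superfamily, EC) group by single linkage
at ≥ 95% pairwise identity (global alignment, identities ÷ shorter sequence
length) and keeps one sequence per cluster — the structure-linked
representative for its own cluster, the longest member elsewhere.  The
enzyme representative is the longest structure-linked sequence, ties by best
resolution, then id.  A predictor is built only when the superfamily has
another enzyme, the enzyme has a representative structure and ≥ 10
sequences, and the other enzymes total ≥ 10 sequences (counts taken after
redundancy removal).  The 80/20 split is per sequence within each enzyme
(`⌊0.8n⌉`, round half away from zero), with the representative forced into
training because the enzyme's PSSM and conservation profile are built from
the training alignment — leaving it in test would leak.  Per-cluster
splitting would further reduce train/test leakage and is noted as an
alternative.

The training alignment itself is a star alignment: each training positive is
globally aligned to the representative and stacked onto representative
coordinates (member insertions relative to the representative are
discarded).  This replaces a progressive MSA plus sequence-structure
alignment; it is exact for indel-free families and a deliberate
approximation otherwise.

Ligand-contact detection (`detect_ligand_contacts`) is a clearly labelled
distance-based substitute for interaction-diagram analysis: a residue
qualifies only with both a polar–polar pair within 3.5 Å and a
carbon–carbon pair within 3.9 Å of a ligand atom.  No hydrogen placement or
bond geometry is attempted; curated annotation tables are the primary path
and the detector is off by default.

## Evaluation

MTTSI (maximal test-to-training sequence identity: max global-alignment
identity, identities ÷ alignment length, against the predictor's positive
training sequences — switchable to all training sequences) stratifies
results into eight left-closed bins: [0,30), then decades to [90,100].
Precision TP/(TP+FP) and recall TP/(TP+FN) are computed per enzyme per bin
and macro-averaged, unweighted, over the enzymes for which they are defined;
undefined metrics are flagged absent, never zero-filled.  Confidence
intervals are normal-approximation 95%.  Paired t-tests compare models on
per-enzyme metrics (all-zero differences give p = 1, a constant non-zero
shift p = 0); group comparisons use the two-sided Mann–Whitney/Wilcoxon
rank-sum test with tie correction.

For identity-band comparisons (the synthetic benchmark), a model that makes
no positive prediction anywhere in a band has no defined enzyme-level
precision; its band macro precision is scored 0.0 — it has demonstrated no
correct positive call there.  This situation arises for the bit-score
baseline at 25–30% identity by construction: its learned threshold separates
training positives (high-identity, high bit score) from training negatives,
and every low-identity query scores far below it.

## Synthetic generator

`generate_superfamily` emulates the statistical structure the method
assumes: one ancestral scaffold; shared conserved positions identical in
every class; planted SDR positions invariant within a class but different
between classes, with class residues chosen mutually dissimilar under
BLOSUM62 (pairwise ≤ −1) so positional attributes carry signal under every
scheme; all other positions substituted i.i.d. per sequence.  Defaults: 3
classes × 20 sequences, length 150, 5 shared + 5 planted positions, 8%
background substitution, no indels; the per-class representative is the
member consensus tagged with a dummy structure reference.  ASR/LBR
annotations cover a declared mixture of planted and shared positions (3+2
active, 2+3 binding by default) so selection-rate analyses have both kinds.
`identity_band_queries` mutates background positions one at a time until the
realized global identity to the class representative enters the requested
band; planted positions are never touched, so labels stay valid down to very
low identity.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: phylogenetic correlation between sequences
(star topology only), indel-rich families (indels are off by default;
when enabled, only single-residue deletions in members), annotation noise
(truth annotations are exact), multi-domain parsing, and realistic
amino-acid composition at background positions.  Recovery rates measured
here are upper bounds on what curated corpora would give.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at the
default generator conditions (3 predictors per run, 5 seeds; ≈ 1 minute for
the five-seed recovery and band-comparison checks, ≈ 10 s for one acceptance
run).  These sizes exercise every stage — clustering, eligibility, star
alignment, CSR/PSSM construction, forest training, rf-SDR extraction,
MTTSI-binned evaluation — at a scale where brute-force oracles (exhaustive
alignment enumeration at length ≤ 6, direct entropy counting, exact rank-sum
permutation at n ≤ 6) remain feasible.  Floating-point comparisons in tests
use absolute tolerances of 1e-9…1e-12 except where scikit-learn's float32
tree thresholds cap the precision at ~1e-3.

## Known limitations

- Star alignment discards member insertions relative to the representative;
  families with long representative-relative insertions lose those columns.
- Single-linkage at 95% identity is a substitute for the legacy clustering
  tool; the identity denominator (shorter sequence) approximates, not
  reproduces, its behaviour.
- The exact C4.5 pruning behaviour is not reproduced; only the
  one-attribute threshold structure is guaranteed equivalent.
- Importance is impurity-based by default and can prefer high-cardinality
  attributes on real data; permutation importance is available by flag.
- B/Z/U and other ambiguity codes are rejected at parse time rather than
  remapped; only X is accepted (scored as unknown, counted with gaps in
  conservation).
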