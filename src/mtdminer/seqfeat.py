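"""Log-odds sequence evidence for two-class domain family alignments.

Builds a per-(residue, column) log-odds matrix from a labeled MSA, scores
aligned sequences, mines discriminative 3-6 column subsequence rules by
bootstrap ranking, and provides the sequence-identity redundancy filter and
the 3-nearest-neighbor sequence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
GAP_CODE = 20  # gap is the 21st symbol for normalization, no matrix row


def encode_sequence(seq: str) -> np.ndarray:
    """Map an aligned sequence to integer codes 0..19, gap/unknown -> 20."""
    return np.array([_CODE.get(c.upper(), GAP_CODE) for c in seq],
                    dtype=np.int8)


@dataclass
class LabeledAlignment:
    """Gapped two-class alignment; labels 1 = binding, 0 = non-binding."""

    names: list[str]
    rows: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.rows) != len(self.names) or len(self.rows) != len(self.labels):
            raise DataError("names, rows and labels must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DataError("alignment rows have unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def encoded(self) -> np.ndarray:
        return np.stack([encode_sequence(r) for r in self.rows])


@dataclass
class RFCMatrix:
    """Per-(residue, column) log-odds of the binding vs non-binding class.

    ``matrix`` is (20, L) with entry ln(P+ / P-); the class probability
    arrays are (21, L) including the gap symbol so columns normalize to 1.
    """

    matrix: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    pseudocount: float

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _class_probs(codes: np.ndarray, pseudocount: float) -> np.ndarray:
    n, L = codes.shape
    counts = np.zeros((21, L))
    for sym in range(21):
        counts[sym] = (codes == sym).sum(axis=0)
    return (counts + pseudocount) / (n + 21 * pseudocount)


def compute_rfc(alignment: LabeledAlignment,
                pseudocount: float = 1.0) -> RFCMatrix:
    """Log-odds evidence matrix M[a, i] = ln(P_{a,i,+} / P_{a,i,-}).

    Class probabilities use an additive pseudocount over the 21-symbol
    alphabet (20 residues + gap); the gap row is dropped from the matrix.
    """
    codes = alignment.encoded
    pos = alignment.labels == 1
    neg = alignment.labels == 0
    if not pos.any() or not neg.any():
        raise DataError("both classes must be non-empty")
    p_plus = _class_probs(codes[pos], pseudocount)
    p_minus = _class_probs(codes[neg], pseudocount)
    matrix = np.log(p_plus[:20] / p_minus[:20])
    return RFCMatrix(matrix=matrix, p_plus=p_plus, p_minus=p_minus,
                     pseudocount=pseudocount)


def _position_scores(matrix: RFCMatrix, codes: np.ndarray) -> np.ndarray:
    """(n, L) per-position contributions; gaps contribute 0."""
    codes = np.atleast_2d(codes)
    L = matrix.n_columns
    if codes.shape[1] != L:
        raise DataError(f"sequence length {codes.shape[1]} != matrix "
                        f"columns {L}")
    cols = np.arange(L)
    safe = np.where(codes == GAP_CODE, 0, codes)
    contrib = matrix.matrix[safe, cols[None, :]]
    contrib[codes == GAP_CODE] = 0.0
    return contrib


def rfc_score(matrix: RFCMatrix, aligned_sequence: str) -> float:
    """Summed evidence S = sum_i M[s_i, i] over non-gap positions."""
    return float(_position_scores(matrix, encode_sequence(aligned_sequence)).sum())


@dataclass
class SubseqRule:
    """An alignment window whose summed log-odds discriminates the classes."""

    start_column: int
    length: int
    bootstrap_rank: float  # mean class separation across bootstraps

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DataError("rule length must be positive")

    @property
    def columns(self) -> range:
        return range(self.start_column, self.start_column + self.length)


def _candidate_windows(L: int, lengths) -> list[tuple[int, int]]:
    return [(s, ln) for ln in lengths for s in range(L - ln + 1)]


def _window_sums(contrib: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    """(n_rows, n_windows) summed contributions per window, via prefix sums."""
    csum = np.concatenate(
        [np.zeros((contrib.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1)
    starts = np.array([w[0] for w in windows])
    ends = starts + np.array([w[1] for w in windows])
    return csum[:, ends] - csum[:, starts]


def mine_subseq_rules(alignment: LabeledAlignment, lengths=range(3, 7),
                      n_bootstrap: int = 50, n_rules: int = 25,
                      seed: int = 0, pseudocount: float = 1.0) -> list[SubseqRule]:
    """Top discriminative alignment windows by bootstrap-averaged separation.

    For each stratified bootstrap resample a fresh log-odds matrix is
    computed; every candidate window's potential score is the mean window
    score over binding rows minus the mean over non-binding rows of the
    original alignment. Windows are ranked by the mean potential score
    across bootstraps (ties: smaller start, then shorter length).
    """
    lengths = sorted(lengths)
    L = alignment.n_columns
    if L < max(lengths):
        raise DataError(f"alignment has {L} columns, need >= {max(lengths)}")
    windows = _candidate_windows(L, lengths)
    if n_rules > len(windows):
        raise DataError(f"n_rules={n_rules} exceeds {len(windows)} candidates")

    codes = alignment.encoded
    labels = alignment.labels
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise DataError("both classes must be non-empty")

    rng = np.random.default_rng(seed)
    total = np.zeros(len(windows))
    for _ in range(n_bootstrap):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        boot = LabeledAlignment(
            names=[alignment.names[i] for i in np.concatenate([bp, bn])],
            rows=[alignment.rows[i] for i in np.concatenate([bp, bn])],
            labels=np.concatenate([np.ones(len(bp), dtype=int),
                                   np.zeros(len(bn), dtype=int)]))
        matrix = compute_rfc(boot, pseudocount)
        contrib = _position_scores(matrix, codes)
        wsum = _window_sums(contrib, windows)
        total += wsum[pos_idx].mean(axis=0) - wsum[neg_idx].mean(axis=0)
    mean_sep = total / n_bootstrap

    order = sorted(range(len(windows)),
                   key=lambda i: (-mean_sep[i], windows[i][0], windows[i][1]))
    return [SubseqRule(start_column=windows[i][0], length=windows[i][1],
                       bootstrap_rank=float(mean_sep[i]))
            for i in order[:n_rules]]


def subseq_features(rules: list[SubseqRule], matrix: RFCMatrix,
                    aligned_sequence: str) -> np.ndarray:
    """Per-rule window scores of one aligned sequence (gaps contribute 0)."""
    contrib = _position_scores(matrix, encode_sequence(aligned_sequence))
    for rule in rules:
        if rule.start_column + rule.length > matrix.n_columns:
            raise DataError("rule window exceeds matrix columns")
    windows = [(r.start_column, r.length) for r in rules]
    return _window_sums(contrib, windows)[0]


def sequence_feature_names(rules: list[SubseqRule]) -> list[str]:
    return [f"rule_{i + 1}_c{r.start_column}_l{r.length}"
            for i, r in enumerate(rules)]


# ---------------------------------------------------------------------------
# identity, redundancy filtering, nearest-neighbor baseline
# ---------------------------------------------------------------------------

def _aligner():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Global-alignment identity: identical pairs / alignment length."""
    if not seq1 or not seq2:
        raise DataError("empty sequence")
    aln = _aligner().align(seq1, seq2)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def redundancy_reduce(sequences: list[str], cutoff: float = 0.70) -> list[int]:
    """Greedy filter: keep a sequence iff identity < cutoff to all kept."""
    if not sequences:
        raise DataError("no sequences")
    kept: list[int] = []
    for i, seq in enumerate(sequences):
        if all(pairwise_identity(seq, sequences[j]) < cutoff for j in kept):
            kept.append(i)
    return kept


def nn_baseline(train_seqs: list[str], train_labels, query_seqs: list[str],
                k: int = 3) -> np.ndarray:
    """Majority vote of the k most identical training sequences per query.

    Neighbor ties break by training index; an even vote split predicts
    positive.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    if len(train_seqs) < k:
        raise DataError(f"need >= {k} training sequences")
    preds = np.empty(len(query_seqs), dtype=int)
    for qi, query in enumerate(query_seqs):
        ids = np.array([pairwise_identity(query, t) for t in train_seqs])
        order = np.lexsort((np.arange(len(train_seqs)), -ids))
        votes = train_labels[order[:k]].sum()
        preds[qi] = 1 if 2 * votes >= k else 0
    return preds


# ---------------------------------------------------------------------------
# alignment / label I/O
# ---------------------------------------------------------------------------

def read_alignment(path, labels_path) -> LabeledAlignment:
    """Read a FASTA or Stockholm MSA plus a (name, {0,1}) label TSV."""
    from Bio import AlignIO

    path = Path(path)
    fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
        else "fasta"
    msa = AlignIO.read(str(path), fmt)
    labels = read_labels(labels_path)
    names, rows, y = [], [], []
    for record in msa:
        if record.id not in labels:
            raise DataError(f"no label for alignment row {record.id!r}")
        names.append(record.id)
        rows.append(str(record.seq).upper().replace(".", GAP))
        y.append(labels[record.id])
    return LabeledAlignment(names=names, rows=rows, labels=np.array(y))


def read_labels(path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise DataError(f"bad label line: {line!r}")
            labels[parts[0].strip()] = int(parts[1])
    return labels


def write_rules_tsv(rules: list[SubseqRule], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tstart_column\tlength\tmean_separation\n")
        for i, r in enumerate(rules, start=1):
            fh.write(f"{i}\t{r.start_column}\t{r.length}\t"
                     f"{r.bootstrap_rank:.6g}\n")
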