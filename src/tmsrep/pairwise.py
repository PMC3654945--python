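"""Pairwise alignment and shuffle-null significance statistics.

This module houses the statistical core of the pipeline: optimal global and
local alignment of protein sequences under an affine gap model, the
*comparison score* expressed in standard deviations — the alignment quality of
the real pair minus the mean quality of composition-preserving shuffles,
divided by the standard deviation of the shuffled qualities — and the homology
decision rule (comparison score >= 10 S.D. over an alignment of >= 60 residues
covering the claimed transmembrane segments).

The dynamic-programming engine is :class:`Bio.Align.PairwiseAligner`; the
statistic, decision rule, redundancy clustering and report formatting are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}

__all__ = [
    "AMINO_ACIDS",
    "ScoringScheme",
    "PairwiseAlignment",
    "ComparisonScore",
    "HomologyCriteria",
    "HomologyDecision",
    "DegenerateNullError",
    "global_align",
    "local_align",
    "shuffle_zscore",
    "homology_call",
    "cluster_reduce",
    "format_alignment",
]


class DegenerateNullError(ValueError):
    """Raised when the shuffle-null distribution has zero variance."""


def _load_matrix(name: str) -> substitution_matrices.Array:
    mat = substitution_matrices.load(name).copy()
    if "X" in mat.alphabet:
        # X is an unknown residue: scored 0 against everything.
        for a in mat.alphabet:
            mat["X", a] = 0.0
            mat[a, "X"] = 0.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Similarity matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (GCG convention).
    With ``end_gap_penalized=False`` (the default) terminal gaps are free,
    which is the appropriate global mode for comparing segments of unequal
    length.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 8.0
    gap_extend: float = 2.0
    end_gap_penalized: bool = False
    matrix: substitution_matrices.Array = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.gap_open < self.gap_extend or self.gap_extend < 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        object.__setattr__(self, "matrix", _load_matrix(self.matrix_name))

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.substitution_matrix = self.matrix
        al.mode = mode
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        if mode == "global" and not self.end_gap_penalized:
            al.open_end_gap_score = 0.0
            al.extend_end_gap_score = 0.0
        return al


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class PairwiseAlignment:
    """An optimal pairwise alignment and its summary statistics.

    ``pct_identity`` and ``pct_similarity`` use the number of aligned
    residue-pair columns as denominator, so partially overlapping segments are
    not diluted by terminal overhangs.
    """

    row_a: str
    row_b: str
    quality: float
    aligned_pairs: int
    identical: int
    similar: int
    span_a: tuple[int, int]  # 1-based inclusive range covered on a
    span_b: tuple[int, int]
    mode: str = "global"

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identical / self.aligned_pairs if self.aligned_pairs else 0.0

    @property
    def pct_similarity(self) -> float:
        return 100.0 * self.similar / self.aligned_pairs if self.aligned_pairs else 0.0

    @property
    def is_empty(self) -> bool:
        return self.aligned_pairs == 0


@dataclass
class ComparisonScore:
    """Shuffle-null comparison score in S.D. units."""

    quality: float
    mu: float
    sigma: float
    z: float
    n_shuffles: int
    seed: int


@dataclass
class HomologyCriteria:
    """Decision thresholds for calling two segments homologous."""

    z_min: float = 10.0
    min_span: int = 60
    tms_overlap_frac: float = 0.5

    def __post_init__(self):
        if self.z_min <= 0 or self.min_span < 1 or not (0 < self.tms_overlap_frac <= 1):
            raise ValueError("invalid homology criteria")


@dataclass
class HomologyDecision:
    passed: bool
    failed_criteria: list[str]


def _validate(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"sequence {name} contains invalid characters: {sorted(bad)}")


def _summarize(aln, a: str, b: str, scheme: ScoringScheme, mode: str) -> PairwiseAlignment:
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned_pairs = identical = similar = 0
    first_a = first_b = last_a = last_b = None
    ia = ib = 0
    # For local alignments Biopython rows cover only the aligned region;
    # offsets recover the parent coordinates.
    off_a = int(aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
    off_b = int(aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
    if mode == "local":
        ia, ib = off_a, off_b
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            aligned_pairs += 1
            if first_a is None:
                first_a, first_b = ia, ib
            last_a, last_b = ia, ib
            if ca == cb:
                identical += 1
            if scheme.score(ca, cb) > 0:
                similar += 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if aligned_pairs == 0:
        return PairwiseAlignment("", "", 0.0, 0, 0, 0, (0, 0), (0, 0), mode)
    return PairwiseAlignment(
        row_a,
        row_b,
        float(aln.score),
        aligned_pairs,
        identical,
        similar,
        (first_a + 1, last_a + 1),
        (first_b + 1, last_b + 1),
        mode,
    )


def global_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (end gaps free unless penalized).

    Tie-breaking is deterministic: of the co-optimal alignments the engine's
    first traceback (match preferred over gaps) is reported.
    """
    _validate(a, "a")
    _validate(b, "b")
    aln = scheme.aligner("global").align(a, b)[0]
    return _summarize(aln, a, b, scheme, "global")


def local_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment; empty when nothing scores > 0."""
    _validate(a, "a")
    _validate(b, "b")
    aligner = scheme.aligner("local")
    if aligner.score(a, b) <= 0:
        return PairwiseAlignment("", "", 0.0, 0, 0, 0, (0, 0), (0, 0), "local")
    aln = aligner.align(a, b)[0]
    return _summarize(aln, a, b, scheme, "local")


def local_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score-only local alignment (fast path for ranking candidate pairs)."""
    return float(max(0.0, scheme.aligner("local").score(a, b)))


def shuffle_zscore(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ComparisonScore:
    """Comparison score of ``a`` vs ``b`` in S.D. units of the shuffle null.

    The real global alignment quality Q is compared with the qualities of
    ``n_shuffles`` alignments in which the shorter sequence is replaced by a
    composition-preserving random permutation of itself (Fisher-Yates,
    seeded).  z = (Q - mean) / sd with the n-1 sample SD estimator.
    """
    _validate(a, "a")
    _validate(b, "b")
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    aligner = scheme.aligner("global")
    q = float(aligner.score(a, b))
    rng = np.random.default_rng(seed)
    # shuffle the shorter sequence; keep `a` fixed in the aligner calls
    shuffle_b = len(b) <= len(a)
    target = np.frombuffer((b if shuffle_b else a).encode(), dtype="S1")
    other = a if shuffle_b else b
    quals = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(target).tobytes().decode()
        quals[k] = aligner.score(other, perm)
    mu = float(quals.mean())
    sigma = float(quals.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError(
            "shuffle-null distribution is degenerate (sigma = 0); "
            "sequence composition carries no alignment information"
        )
    return ComparisonScore(q, mu, sigma, (q - mu) / sigma, n_shuffles, seed)


def _coverage(tms: tuple[int, int], span: tuple[int, int]) -> float:
    lo = max(tms[0], span[0])
    hi = min(tms[1], span[1])
    n = tms[1] - tms[0] + 1
    return max(0, hi - lo + 1) / n


def homology_call(
    score: ComparisonScore,
    aln: PairwiseAlignment,
    tms_a: list[tuple[int, int]] | None,
    tms_b: list[tuple[int, int]] | None,
    criteria: HomologyCriteria = HomologyCriteria(),
) -> HomologyDecision:
    """Apply the homology decision rule to a scored alignment.

    Passes iff z >= z_min, the alignment covers >= min_span residue pairs,
    and every claimed TMS of both segments has at least ``tms_overlap_frac``
    of its residues inside the aligned span.  TMS intervals are 1-based
    inclusive in the coordinate system of the compared segments.
    """
    failed: list[str] = []
    if score.z < criteria.z_min:
        failed.append("z_min")
    if aln.aligned_pairs < criteria.min_span:
        failed.append("min_span")
    if criteria.tms_overlap_frac > 0:
        if tms_a is None or tms_b is None:
            raise ValueError("TMS annotations required when tms_overlap_frac > 0")
        for tms_list, span in ((tms_a, aln.span_a), (tms_b, aln.span_b)):
            if any(_coverage(t, span) < criteria.tms_overlap_frac for t in tms_list):
                failed.append("tms_overlap")
                break
    return HomologyDecision(not failed, failed)


def cluster_reduce(
    records: list[tuple[str, str]],
    identity_threshold: float = 0.9,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy incremental redundancy reduction (CD-HIT style).

    Records (id, sequence) are sorted by length descending; each joins the
    first representative with global-alignment identity (identical pairs /
    shorter sequence length) >= threshold, otherwise it founds a new cluster.
    Returns (representatives, member_id -> representative_id map).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for rid, seq in ordered:
        placed = False
        for rep_id, rep_seq in reps:
            if seq == rep_seq:
                identity = 1.0
            else:
                aln = global_align(rep_seq, seq, scheme)
                identity = aln.identical / min(len(seq), len(rep_seq))
            if identity >= identity_threshold:
                assignment[rid] = rep_id
                placed = True
                break
        if not placed:
            reps.append((rid, seq))
            assignment[rid] = rid
    return reps, assignment


def _match_char(ca: str, cb: str, scheme: ScoringScheme) -> str:
    if ca == "-" or cb == "-":
        return " "
    if ca == cb:
        return "|"
    s = scheme.score(ca, cb)
    if s >= 2:
        return ":"
    if s > 0:
        return "."
    return " "


def format_alignment(
    aln: PairwiseAlignment,
    id_a: str = "a",
    id_b: str = "b",
    scheme: ScoringScheme = DEFAULT_SCHEME,
    tms_a: list[tuple[int, int]] | None = None,
    tms_b: list[tuple[int, int]] | None = None,
    width: int = 60,
) -> str:
    """Pretty-print an alignment in paired 60-column blocks.

    Line-leading numbers are 1-based residue numbers; the match line marks
    identities '|', close similarities ':' (matrix score >= 2) and more
    distant similarities '.' (score in (0, 2)).  When TMS intervals are
    supplied the sequence is written lower-case with TMS residues upper-case.
    """
    if aln.is_empty:
        return "(empty alignment)\n"

    def markup(row: str, tms: list[tuple[int, int]] | None, start: int) -> str:
        if tms is None:
            return row
        out = []
        pos = start - 1  # 0-based residue counter in parent coords
        for c in row:
            if c == "-":
                out.append(c)
                continue
            pos += 1
            inside = any(lo <= pos <= hi for lo, hi in tms)
            out.append(c.upper() if inside else c.lower())
        return "".join(out)

    start_a = aln.span_a[0] if aln.mode == "local" else 1
    start_b = aln.span_b[0] if aln.mode == "local" else 1
    row_a = markup(aln.row_a, tms_a, start_a)
    row_b = markup(aln.row_b, tms_b, start_b)
    match = "".join(_match_char(x, y, scheme) for x, y in zip(aln.row_a, aln.row_b))
    lines = []
    na, nb = start_a, start_b
    tag = max(len(id_a), len(id_b))
    for i in range(0, len(row_a), width):
        ca, cb, cm = row_a[i : i + width], row_b[i : i + width], match[i : i + width]
        lines.append(f"{id_a:<{tag}} {na:>5} {ca}")
        lines.append(f"{'':<{tag}} {'':>5} {cm}")
        lines.append(f"{id_b:<{tag}} {nb:>5} {cb}")
        lines.append("")
        na += sum(1 for c in ca if c != "-")
        nb += sum(1 for c in cb if c != "-")
    lines.append(
        f"quality {aln.quality:.1f}  aligned {aln.aligned_pairs}  "
        f"identity {aln.pct_identity:.1f}%  similarity {aln.pct_similarity:.1f}%"
    )
    return "\n".join(lines) + "\n"
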