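"""Marginal ancestral sequence reconstruction and the ancestral-boost test.

Two present-day repeat units that diverged from a common duplicated element
each accumulate independent noise; their reconstructed root sequences strip
much of that noise away, so a root-vs-root comparison can score far higher
than any extant pair.  This module reconstructs a root sequence for a set of
homologues (neighbor-joining guide tree, time-reversible substitution model,
Felsenstein pruning, per-column marginal posterior at the root) and compares
the reconstructed first-half and second-half roots of a family against the
extant cross-half comparisons.

The substitution model is a pluggable time-reversible 20-state model; the
bundled default derives its exchangeabilities from the scoring matrix
(S_ab = exp(s(a,b)/2), uniform equilibrium frequencies), matching the kernel
under which the synthetic families diverge.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .pairwise import (
    AMINO_ACIDS,
    DEFAULT_SCHEME,
    ComparisonScore,
    ScoringScheme,
    shuffle_zscore,
)
from .repeat_scan import slice_bundle
from .synthetic import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "SubstitutionModel",
    "AncestralResult",
    "protein_distance",
    "nj_tree",
    "reconstruct_root",
    "ancestral_repeat_compare",
    "align_mafft",
    "default_model",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows with ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows) or len(self.rows) < 2:
            raise ValueError("need >= 2 rows with matching ids")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def drop_gappy_rows(self, factor: float = 1.5) -> "MultipleAlignment":
        """Drop rows whose gap fraction exceeds ``factor`` x the median.

        Operationalizes the removal of homologues that introduce too many
        gaps into the multiple alignment.  Never drops below 2 rows.
        """
        fracs = np.array([r.count("-") / len(r) for r in self.rows])
        med = float(np.median(fracs))
        keep = [i for i, f in enumerate(fracs) if med == 0 or f <= factor * med]
        if len(keep) < 2:
            return self
        return MultipleAlignment([self.ids[i] for i in keep], [self.rows[i] for i in keep])


def align_mafft(records: list[SequenceRecord]) -> MultipleAlignment:
    """Multiple alignment via mafft (--auto); requires mafft on PATH."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        out = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    ids, rows, cur = [], [], []
    for line in out.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
            ids.append(line[1:].split()[0])
            cur = []
        else:
            cur.append(line.strip().upper())
    if cur:
        rows.append("".join(cur))
    return MultipleAlignment(ids, rows)


# ---------------------------------------------------------------------------
# distances and guide tree


def protein_distance(msa: MultipleAlignment, max_distance: float = 10.0) -> np.ndarray:
    """Pairwise evolutionary distances with Kimura's correction.

    d = -ln(1 - p - 0.2 p^2) where p is the proportion of differing sites
    among columns without gaps in either row; distances whose correction
    argument is non-positive are capped at ``max_distance`` with a warning.
    """
    n = len(msa.rows)
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    dist = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            both = (rows[i] != b"-") & (rows[j] != b"-")
            total = int(both.sum())
            if total == 0:
                dist[i, j] = dist[j, i] = max_distance
                capped = True
                continue
            p = float((rows[i][both] != rows[j][both]).sum()) / total
            arg = 1.0 - p - 0.2 * p * p
            if arg <= 0:
                dist[i, j] = dist[j, i] = max_distance
                capped = True
            else:
                dist[i, j] = dist[j, i] = -np.log(arg)
    if capped:
        warnings.warn("some distances exceeded the correction domain and were capped")
    return dist


def nj_tree(distances: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbor-joining tree, midpoint rooted; ties broken by label order.

    Two taxa yield a single edge split at the midpoint.  Negative NJ branch
    lengths are clamped to zero.
    """
    if len(ids) != distances.shape[0]:
        raise ValueError("ids and distance matrix disagree")
    if len(ids) == 2:
        d = float(distances[0, 1])
        root = TreeNode(name="root")
        for name in ids:
            child = TreeNode(name=name, length=d / 2)
            root.append(child)
        return root
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    dm = DistanceMatrix(distances[np.ix_(order, order)], [ids[i] for i in order])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = tree.root_at_midpoint()
    return rooted


# ---------------------------------------------------------------------------
# substitution model


@dataclass
class SubstitutionModel:
    """Time-reversible 20-state substitution model scaled to mean rate 1.

    Built from a symmetric exchangeability matrix S (zero diagonal) and
    equilibrium frequencies pi: Q_ab = S_ab pi_b (a != b), rows summing to
    zero, scaled so that -sum_a pi_a Q_aa = 1.  Transition probabilities
    P(t) = expm(Q t) come from the eigendecomposition of the symmetrized
    generator, computed once.
    """

    exchangeability: np.ndarray
    pi: np.ndarray
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self):
        S, pi = np.asarray(self.exchangeability, float), np.asarray(self.pi, float)
        if S.shape != (20, 20) or not np.allclose(S, S.T) or (S < 0).any():
            raise ValueError("exchangeability must be symmetric non-negative 20x20")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
            raise ValueError("pi must be positive and sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.dot(pi, np.diag(Q)))
        Q /= rate
        # reversibility => diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        B = sq[:, None] * Q / sq[None, :]
        B = (B + B.T) / 2.0
        w, U = np.linalg.eigh(B)
        object.__setattr__(self, "_eig", (w, U, sq))
        self.Q = Q

    def transition(self, t: float) -> np.ndarray:
        """P(t) with rows = source state; P(0) = I."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        w, U, sq = self._eig
        P = (U * np.exp(w * t)) @ U.T
        P = P / sq[:, None] * sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def default_model(scheme: ScoringScheme = DEFAULT_SCHEME) -> SubstitutionModel:
    """Scoring-matrix-derived reversible model with uniform frequencies."""
    S = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                S[i, j] = np.exp(scheme.score(a, b) / 2.0)
    return SubstitutionModel(S, np.full(20, 0.05))


# ---------------------------------------------------------------------------
# marginal reconstruction


@dataclass
class AncestralResult:
    root_sequence: str  # gap-flagged columns excluded
    posteriors: np.ndarray  # (n_cols, 20); NaN rows at gap-flagged columns
    gap_flag: np.ndarray  # (n_cols,) bool, True when > 50% gaps
    column_root: list[str]  # per-column residue ('-' at gap-flagged columns)


def _postorder_likelihood(node, msa_by_id, col, model, cache):
    if node.is_tip():
        c = msa_by_id[node.name][col]
        if c == "-" or c == "X":
            return np.ones(20)
        vec = np.zeros(20)
        vec[_AA_INDEX[c]] = 1.0
        return vec
    like = np.ones(20)
    for child in node.children:
        child_like = _postorder_likelihood(child, msa_by_id, col, model, cache)
        t = child.length if child.length is not None else 0.0
        P = cache.setdefault(round(t, 12), model.transition(t))
        like *= P @ child_like
    return like


def reconstruct_root(
    msa: MultipleAlignment,
    tree: TreeNode,
    model: SubstitutionModel | None = None,
    gap_threshold: float = 0.5,
) -> AncestralResult:
    """Per-column marginal posterior over residues at the tree root.

    Pruning-algorithm likelihoods with transition probabilities from the
    model's matrix exponential; root posterior = pi-weighted conditional
    likelihood, normalized.  The root residue is the posterior argmax with
    alphabetical tie-breaking; columns with more than ``gap_threshold`` gaps
    are flagged and excluded from the root sequence.
    """
    model = model or default_model()
    tips = {t.name for t in tree.tips()}
    if tips != set(msa.ids):
        raise ValueError("tree leaves and alignment rows disagree")
    by_id = dict(zip(msa.ids, msa.rows))
    ncol = msa.n_cols
    post = np.full((ncol, 20), np.nan)
    gap_flag = np.zeros(ncol, bool)
    cache: dict = {}
    root_chars = []
    for col in range(ncol):
        gaps = sum(1 for r in msa.rows if r[col] == "-")
        if gaps / len(msa.rows) > gap_threshold:
            gap_flag[col] = True
            root_chars.append("-")
            continue
        like = _postorder_likelihood(tree, by_id, col, model, cache)
        weighted = model.pi * like
        total = weighted.sum()
        if total == 0:
            gap_flag[col] = True
            root_chars.append("-")
            continue
        p = weighted / total
        post[col] = p
        root_chars.append(AMINO_ACIDS[int(np.argmax(p))])
    root_seq = "".join(c for c in root_chars if c != "-")
    return AncestralResult(root_seq, post, gap_flag, root_chars)


# ---------------------------------------------------------------------------
# the ancestral-boost comparison


def _half_root(
    bundles: list, model: SubstitutionModel | None
) -> tuple[str, MultipleAlignment]:
    recs = [SequenceRecord(b.protein_id, b.segment) for b in bundles]
    msa = align_mafft(recs).drop_gappy_rows()
    dist = protein_distance(msa)
    tree = nj_tree(dist, msa.ids)
    result = reconstruct_root(msa, tree, model)
    return result.root_sequence, msa


def ancestral_repeat_compare(
    records: list[SequenceRecord],
    annotations: dict,
    split_after_tms: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    model: SubstitutionModel | None = None,
    flank: int = 5,
    n_shuffles: int = 200,
    n_extant_pairs: int = 10,
    seed: int = 0,
) -> dict:
    """Root-vs-root versus extant cross-half comparison scores.

    Members are sliced at TMS ``split_after_tms``; each half set is aligned
    independently, gap-heavy rows dropped, a root reconstructed, and the two
    roots compared by shuffle z.  A sample of extant cross-half pairs
    (member i's first half vs member j's second half, i != j) is scored the
    same way.  Returns {"ancestral": ComparisonScore, "extant":
    [ComparisonScore...], "root_1", "root_2"}.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 family members")
    if len(records) == 2:
        warnings.warn("with 2 members the reconstruction is close to a consensus")
    k = split_after_tms
    firsts, seconds = [], []
    for rec in records:
        ann = annotations[rec.id]
        intervals = ann.intervals if hasattr(ann, "intervals") else ann
        if k >= len(intervals):
            raise ValueError(f"split {k} >= TMS count for {rec.id}")
        firsts.append(slice_bundle(rec, intervals, 1, k, flank))
        seconds.append(slice_bundle(rec, intervals, k + 1, len(intervals), flank))
    root1, _ = _half_root(firsts, model)
    root2, _ = _half_root(seconds, model)
    rng = np.random.default_rng(seed)
    anc = shuffle_zscore(root1, root2, scheme, n_shuffles, int(rng.integers(2**31)))
    n = len(records)
    extant: list[ComparisonScore] = []
    for _ in range(n_extant_pairs):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        while j == i and n > 1:
            j = int(rng.integers(n))
        extant.append(
            shuffle_zscore(
                firsts[i].segment, seconds[j].segment, scheme, n_shuffles,
                int(rng.integers(2**31)),
            )
        )
    return {"ancestral": anc, "extant": extant, "root_1": root1, "root_2": root2}
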