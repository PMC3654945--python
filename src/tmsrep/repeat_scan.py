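"""TMS-bundle splicing and internal-repeat / cross-family scanning.

The key manoeuvre for detecting ancient intragenic duplications: splice each
homologue into bundles of consecutive TMSs plus short flanks, then compare
the first-half bundles of *all* members against the second-half bundles of
*all* members (cross-protein comparisons included — within one protein the
two halves may have diverged past detectability while a half of one
homologue still recognizes the complementary half of another).  Candidate
pairs are ranked by a fast local-alignment score and the top candidates are
validated with the shuffle-null comparison score and the homology decision
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairwise import (
    DEFAULT_SCHEME,
    ComparisonScore,
    HomologyCriteria,
    HomologyDecision,
    PairwiseAlignment,
    ScoringScheme,
    global_align,
    homology_call,
    local_score,
    shuffle_zscore,
)
from .synthetic import SequenceRecord
from .topology import TMSAnnotation

__all__ = [
    "TMSBundle",
    "CandidatePair",
    "ScanReport",
    "slice_bundle",
    "cross_scan",
    "repeat_test",
    "ancient_rep_scan",
]


@dataclass
class TMSBundle:
    """A spliced sub-sequence covering TMSs ``i..j`` of a protein plus flanks.

    ``source_range`` is the 1-based inclusive residue range in the parent;
    ``tms_local`` holds the bundle's TMS intervals re-based to bundle
    coordinates (for the TMS-coverage criterion).
    """

    protein_id: str
    tms_range: tuple[int, int]
    segment: str
    source_range: tuple[int, int]
    flank: int
    tms_local: list[tuple[int, int]] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.protein_id}[TMS{self.tms_range[0]}-{self.tms_range[1]}]"


@dataclass
class CandidatePair:
    bundle_a: TMSBundle
    bundle_b: TMSBundle
    local_score: float
    score: ComparisonScore | None = None
    alignment: PairwiseAlignment | None = None
    decision: HomologyDecision | None = None
    seed: int = 0

    @property
    def z(self) -> float:
        return self.score.z if self.score else float("nan")

    @property
    def passed(self) -> bool:
        return bool(self.decision and self.decision.passed)


@dataclass
class ScanReport:
    pairs: list[CandidatePair]
    metadata: dict
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def passing(self) -> list[CandidatePair]:
        return [p for p in self.pairs if p.passed]

    def to_rows(self) -> list[dict]:
        rows = []
        for p in self.pairs:
            row = {
                "id_a": p.bundle_a.label,
                "id_b": p.bundle_b.label,
                "local_score": p.local_score,
                "seed": p.seed,
            }
            if p.score:
                row.update(
                    Q=p.score.quality, mu=p.score.mu, sigma=p.score.sigma, z=p.score.z
                )
            if p.alignment:
                row.update(
                    aligned_pairs=p.alignment.aligned_pairs,
                    pct_id=p.alignment.pct_identity,
                    pct_sim=p.alignment.pct_similarity,
                )
            if p.decision:
                row.update(passed=p.decision.passed, failed=",".join(p.decision.failed_criteria))
            rows.append(row)
        return rows


def slice_bundle(
    record: SequenceRecord,
    annotation: TMSAnnotation | list[tuple[int, int]],
    i: int,
    j: int,
    flank: int = 5,
) -> TMSBundle:
    """Splice the segment covering TMSs ``i..j`` (1-based) plus flanks."""
    intervals = annotation.intervals if isinstance(annotation, TMSAnnotation) else annotation
    if not 1 <= i <= j:
        raise ValueError("require 1 <= i <= j")
    if j > len(intervals):
        raise ValueError(f"TMS index {j} exceeds TMS count {len(intervals)}")
    start = max(1, intervals[i - 1][0] - flank)
    end = min(len(record.seq), intervals[j - 1][1] + flank)
    segment = record.seq[start - 1 : end]
    local = [
        (lo - start + 1, hi - start + 1) for lo, hi in intervals[i - 1 : j]
    ]
    return TMSBundle(record.id, (i, j), segment, (start, end), flank, local)


def _pair_seed(base_seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % (2**31))


def cross_scan(
    bundles_a: list[TMSBundle],
    bundles_b: list[TMSBundle],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    top_k: int = 50,
    n_shuffles: int = 200,
    criteria: HomologyCriteria = HomologyCriteria(),
    seed: int = 0,
) -> ScanReport:
    """All-vs-all bundle comparison with two-stage validation.

    Stage 1 ranks every ordered cross pair by local-alignment score; stage 2
    validates the ``top_k`` candidates with the shuffle-null comparison score
    and the homology decision rule.  Self pairs (same protein *and* same TMS
    range) are excluded.  Deterministic given ``seed``: each validated pair
    uses a seed derived from its stage-1 rank, stored for re-validation.
    """
    if not bundles_a or not bundles_b:
        raise ValueError("bundle sets must be non-empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    candidates: list[CandidatePair] = []
    for ba in bundles_a:
        for bb in bundles_b:
            if ba.protein_id == bb.protein_id and ba.tms_range == bb.tms_range:
                continue
            candidates.append(CandidatePair(ba, bb, local_score(ba.segment, bb.segment, scheme)))
    candidates.sort(key=lambda p: (-p.local_score, p.bundle_a.label, p.bundle_b.label))
    validated = candidates[:top_k]
    for rank, pair in enumerate(validated):
        pair.seed = _pair_seed(seed, rank)
        pair.score = shuffle_zscore(
            pair.bundle_a.segment, pair.bundle_b.segment, scheme, n_shuffles, pair.seed
        )
        pair.alignment = global_align(pair.bundle_a.segment, pair.bundle_b.segment, scheme)
        pair.decision = homology_call(
            pair.score,
            pair.alignment,
            pair.bundle_a.tms_local,
            pair.bundle_b.tms_local,
            criteria,
        )
    validated.sort(key=lambda p: -p.z)
    meta = {
        "n_a": len(bundles_a),
        "n_b": len(bundles_b),
        "top_k": top_k,
        "n_shuffles": n_shuffles,
        "seed": seed,
        "criteria": criteria,
        "scheme": scheme.matrix_name,
    }
    return ScanReport(validated, meta)


def repeat_test(
    records: list[SequenceRecord],
    annotations: dict[str, TMSAnnotation | list[tuple[int, int]]],
    split_after_tms: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    flank: int = 5,
    top_k: int = 50,
    n_shuffles: int = 200,
    criteria: HomologyCriteria = HomologyCriteria(),
    seed: int = 0,
) -> ScanReport:
    """Internal-repeat test: TMSs 1..k of every member vs TMSs k+1..end.

    The classic analyses split 6-TMS proteins after TMS 3, 10-TMS after 5,
    12-TMS after 6 and 20-TMS after 10, but any split is accepted as long as
    every member has more TMSs than ``split_after_tms``.
    """
    k = split_after_tms
    firsts, seconds = [], []
    for rec in records:
        ann = annotations[rec.id]
        intervals = ann.intervals if isinstance(ann, TMSAnnotation) else ann
        if k >= len(intervals):
            raise ValueError(
                f"split_after_tms={k} >= TMS count {len(intervals)} for {rec.id}"
            )
        firsts.append(slice_bundle(rec, intervals, 1, k, flank))
        seconds.append(slice_bundle(rec, intervals, k + 1, len(intervals), flank))
    report = cross_scan(firsts, seconds, scheme, top_k, n_shuffles, criteria, seed)
    report.metadata["split_after_tms"] = k
    return report


def ancient_rep_scan(
    records: list[SequenceRecord],
    annotations: dict[str, TMSAnnotation | list[tuple[int, int]]],
    unit: int = 3,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    flank: int = 5,
    n_shuffles: int = 100,
    criteria: HomologyCriteria = HomologyCriteria(),
    seed: int = 0,
) -> ScanReport:
    """Sliding-window repeat census over topology categories.

    For every start index c, the bundle of TMSs c..c+unit-1 of each record is
    compared (shuffle z) against every *downstream* same-size bundle (start
    > c) of every record.  The per-category counts of pairs reaching
    ``criteria.z_min`` expose where in the topology a repeat unit lies: a
    category whose window straddles a lineage-specific insertion shows a
    sharp drop in qualifying pairs.
    """
    if not records:
        raise ValueError("empty record set")
    windows: dict[int, list[TMSBundle]] = {}
    min_tms = None
    for rec in records:
        ann = annotations[rec.id]
        intervals = ann.intervals if isinstance(ann, TMSAnnotation) else ann
        n = len(intervals)
        min_tms = n if min_tms is None else min(min_tms, n)
        for c in range(1, n - unit + 2):
            windows.setdefault(c, []).append(slice_bundle(rec, intervals, c, c + unit - 1, flank))
    if unit > (min_tms or 0):
        raise ValueError(f"unit {unit} exceeds minimum TMS count {min_tms}")
    counts: dict[str, int] = {}
    pairs: list[CandidatePair] = []
    idx = 0
    for c in sorted(windows):
        label = "-".join(str(c + o) for o in range(unit))
        counts[label] = 0
        for ba in windows[c]:
            for c2 in sorted(windows):
                if c2 <= c:
                    continue
                for bb in windows[c2]:
                    if ba.protein_id == bb.protein_id and ba.tms_range == bb.tms_range:
                        continue
                    pair = CandidatePair(ba, bb, 0.0, seed=_pair_seed(seed, idx))
                    idx += 1
                    pair.score = shuffle_zscore(
                        ba.segment, bb.segment, scheme, n_shuffles, pair.seed
                    )
                    pair.alignment = global_align(ba.segment, bb.segment, scheme)
                    pair.decision = homology_call(
                        pair.score, pair.alignment, ba.tms_local, bb.tms_local, criteria
                    )
                    if pair.score.z >= criteria.z_min:
                        counts[label] += 1
                    pairs.append(pair)
    pairs.sort(key=lambda p: -p.z)
    meta = {"unit": unit, "n_records": len(records), "seed": seed, "n_shuffles": n_shuffles}
    return ScanReport(pairs, meta, category_counts=counts)
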