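"""Synthetic membrane-protein families with known duplication histories.

Families are grown from a primordial 3-TMS unit by block-level events —
full-length intragenic duplication, loss of a terminal TMS, insertion of a
hydrophilic loop, tail duplication — followed by per-lineage divergence.
Because indels are confined to loops and substitutions never move block
boundaries, every generated protein carries exact ground-truth TMS intervals
and a residue-level repeat-correspondence map, so repeat detection, topology
calling and ancestral reconstruction can all be scored against truth.

Residue composition is hydrophobicity-structured only: TMS blocks draw
residues with probability 0.8 from the strongly hydrophobic set
(Kyte-Doolittle value >= 1.8) and loops with probability 0.8 from the polar
set (value <= 0).  Substitutions use the kernel P(b | a) ~ exp(s(a,b)/2)
over the active scoring matrix, which ties the divergence depth ``d``
(expected substitutions per site) to detectability under the same matrix
used for scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .pairwise import AMINO_ACIDS, DEFAULT_SCHEME, ScoringScheme, global_align

HYDROPHOBIC = tuple(a for a in AMINO_ACIDS if KYTE_DOOLITTLE[a] >= 1.8)
POLAR = tuple(a for a in AMINO_ACIDS if KYTE_DOOLITTLE[a] <= 0)

# TM-helix core composition: strongly enriched in Leu/Ile/Val/Phe as in real
# bitopic and polytopic membrane proteins; Ala/Met/Cys minor.
_TM_CORE_WEIGHTS = {
    "L": 0.28, "I": 0.24, "V": 0.24, "F": 0.14, "A": 0.06, "M": 0.03, "C": 0.01,
}
_TM_CORE = tuple(_TM_CORE_WEIGHTS)
_TM_CORE_P = np.array(list(_TM_CORE_WEIGHTS.values()))
# the non-hydrophobic 20% of TMS residues: small/hydroxyl residues, which do
# occur in TM helices; charged residues are excluded from the membrane core
_TM_WEAK = ("G", "S", "T")

__all__ = [
    "TopologyBlueprint",
    "EvolutionScenario",
    "SequenceRecord",
    "TruthRecord",
    "sample_ancestor",
    "apply_events",
    "diverge",
    "make_family",
    "three_tms_blueprint",
    "PRESETS",
    "write_fasta",
    "write_truth_tsv",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# blueprints and records


@dataclass(frozen=True)
class TopologyBlueprint:
    """Alternating LOOP/TMS block layout, starting and ending with a loop.

    ``elements`` is a list of ("loop"|"tms", length) tuples; ``repeat_map``
    maps TMS indices (1-based) of one duplicated unit onto the other, e.g.
    {1: 4, 2: 5, 3: 6} for a 3+3 protein.
    """

    elements: tuple[tuple[str, int], ...]
    repeat_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        kinds = [k for k, _ in self.elements]
        if not kinds or kinds[0] != "loop" or kinds[-1] != "loop":
            raise ValueError("blueprint must start and end with a loop")
        for i, k in enumerate(kinds):
            if k != ("loop" if i % 2 == 0 else "tms"):
                raise ValueError("blocks must alternate loop/TMS")
        for k, length in self.elements:
            if length < 1:
                raise ValueError("block lengths must be positive")
            if k == "tms" and not 12 <= length <= 25:
                raise ValueError("TMS lengths must be in [12, 25]")
        src, dst = set(self.repeat_map), set(self.repeat_map.values())
        if len(dst) != len(self.repeat_map) or (src & dst):
            raise ValueError("repeat_map must be a bijection of disjoint TMS sets")
        n = sum(1 for k in kinds if k == "tms")
        if any(not 1 <= i <= n for i in src | dst):
            raise ValueError("repeat_map indexes a non-existent TMS")

    @property
    def n_tms(self) -> int:
        return sum(1 for k, _ in self.elements if k == "tms")


def three_tms_blueprint(tms_len: int = 23, loop_len: int = 22) -> TopologyBlueprint:
    """The primordial 3-TMS unit (default block sizes: 23-residue helices,
    22-residue connecting loops, typical of polytopic membrane proteins)."""
    elems: list[tuple[str, int]] = [("loop", loop_len)]
    for _ in range(3):
        elems += [("tms", tms_len), ("loop", loop_len)]
    return TopologyBlueprint(tuple(elems))


@dataclass
class SequenceRecord:
    id: str
    seq: str


@dataclass
class TruthRecord:
    """Ground truth for one generated protein."""

    id: str
    tms_intervals: list[tuple[int, int]]  # 1-based inclusive
    repeat_map: dict[int, int]  # TMS index -> TMS index
    lineage: list[str] = field(default_factory=list)

    @property
    def n_tms(self) -> int:
        return len(self.tms_intervals)

    def repeat_intervals(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Residue-interval resolution of the repeat correspondence."""
        return [
            (self.tms_intervals[i - 1], self.tms_intervals[j - 1])
            for i, j in sorted(self.repeat_map.items())
        ]


# internal block-level representation keeps truth exact under every event
@dataclass
class _Protein:
    blocks: list[tuple[str, str]]  # (kind, residues)
    repeat_map: dict[int, int]
    lineage: list[str]

    def sequence(self) -> str:
        return "".join(s for _, s in self.blocks)

    def truth(self, pid: str) -> TruthRecord:
        intervals = []
        pos = 0
        for kind, seq in self.blocks:
            if kind == "tms":
                intervals.append((pos + 1, pos + len(seq)))
            pos += len(seq)
        return TruthRecord(pid, intervals, dict(self.repeat_map), list(self.lineage))

    def record(self, pid: str) -> SequenceRecord:
        return SequenceRecord(pid, self.sequence())


# ---------------------------------------------------------------------------
# ancestor sampling


def _draw_block(kind: str, length: int, rng: np.random.Generator) -> str:
    # TMS: probability 0.8 of a strongly hydrophobic residue (KD >= 1.8),
    # 0.2 small/hydroxyl; loops: probability 0.8 polar (KD <= 0), 0.2
    # hydrophobic, mimicking hydrophobic loop residues at helix ends.
    if kind == "tms":
        pick = rng.random(length) < 0.8
        main = rng.choice(_TM_CORE, size=length, p=_TM_CORE_P)
        alt = rng.choice(_TM_WEAK, size=length)
    else:
        pick = rng.random(length) < 0.8
        main = rng.choice(POLAR, size=length)
        alt = rng.choice(_TM_CORE, size=length, p=_TM_CORE_P)
    return "".join(m if pm else a for pm, m, a in zip(pick, main, alt))


def sample_ancestor(
    blueprint: TopologyBlueprint, rng_seed: int, pid: str = "ancestor"
) -> tuple[SequenceRecord, TruthRecord]:
    """Instantiate a blueprint as a concrete sequence with ground truth."""
    prot = _sample_ancestor(blueprint, np.random.default_rng(rng_seed))
    return prot.record(pid), prot.truth(pid)


def _sample_ancestor(blueprint: TopologyBlueprint, rng: np.random.Generator) -> _Protein:
    blocks = [(k, _draw_block(k, n, rng)) for k, n in blueprint.elements]
    return _Protein(blocks, dict(blueprint.repeat_map), ["sample_ancestor"])


# ---------------------------------------------------------------------------
# evolutionary events


def _merge_adjacent_loops(blocks: list[tuple[str, str]]) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for kind, seq in blocks:
        if out and kind == "loop" and out[-1][0] == "loop":
            out[-1] = ("loop", out[-1][1] + seq)
        else:
            out.append((kind, seq))
    return out


def _apply_event(prot: _Protein, event, rng: np.random.Generator) -> _Protein:
    name = event[0] if isinstance(event, tuple) else event
    blocks = list(prot.blocks)
    n_tms = sum(1 for k, _ in blocks if k == "tms")
    rmap = dict(prot.repeat_map)
    if name == "duplicate_full":
        blocks = _merge_adjacent_loops(blocks + blocks)
        rmap = {i: i + n_tms for i in range(1, n_tms + 1)}
    elif name == "delete_n_terminal_tms":
        if n_tms <= 1:
            raise ValueError("cannot delete below 1 TMS")
        blocks = blocks[2:]  # leading loop + first TMS
        rmap = {
            i - 1: j - 1 for i, j in rmap.items() if i > 1 and j > 1
        }
    elif name == "delete_c_terminal_tms":
        if n_tms <= 1:
            raise ValueError("cannot delete below 1 TMS")
        blocks = blocks[:-2]  # last TMS + trailing loop
        rmap = {i: j for i, j in rmap.items() if i < n_tms and j < n_tms}
    elif name == "insert_loop":
        _, after_tms, length = event
        if not 0 <= after_tms <= n_tms:
            raise ValueError("insert_loop position outside protein")
        # the loop following TMS `after_tms` (0 = N-terminal loop)
        idx = 2 * after_tms
        kind, seq = blocks[idx]
        assert kind == "loop"
        mid = len(seq) // 2
        insert = _draw_block("loop", length, rng)
        blocks[idx] = ("loop", seq[:mid] + insert + seq[mid:])
    elif name == "duplicate_tail":
        _, k = event
        if not 1 <= k <= n_tms:
            raise ValueError("duplicate_tail k out of range")
        tail = blocks[-2 * k - 1 :]  # loop before TMS (n-k+1) .. trailing loop
        blocks = _merge_adjacent_loops(blocks + tail[1:])
        rmap = {n_tms - k + 1 + i: n_tms + 1 + i for i in range(k)}
    else:
        raise ValueError(f"unknown event: {name!r}")
    lineage = prot.lineage + [name if isinstance(event, str) else repr(event)]
    return _Protein(blocks, rmap, lineage)


def apply_events(
    record: SequenceRecord,
    truth: TruthRecord,
    events: list,
    rng_seed: int = 0,
) -> tuple[SequenceRecord, TruthRecord]:
    """Apply an ordered list of evolutionary events to a record.

    Events: ``"duplicate_full"``, ``"delete_n_terminal_tms"``,
    ``"delete_c_terminal_tms"``, ``("insert_loop", after_tms, length)``,
    ``("duplicate_tail", k)``.  Insertions are only ever placed inside loops.
    """
    prot = _protein_from_record(record, truth)
    rng = np.random.default_rng(rng_seed)
    for ev in events:
        prot = _apply_event(prot, ev, rng)
    return prot.record(record.id), prot.truth(record.id)


def _protein_from_record(record: SequenceRecord, truth: TruthRecord) -> _Protein:
    blocks: list[tuple[str, str]] = []
    pos = 0
    for lo, hi in truth.tms_intervals:
        if lo - 1 > pos:
            blocks.append(("loop", record.seq[pos : lo - 1]))
        elif lo - 1 < pos:
            raise ValueError("truth intervals overlap or are unsorted")
        blocks.append(("tms", record.seq[lo - 1 : hi]))
        pos = hi
    if pos < len(record.seq):
        blocks.append(("loop", record.seq[pos:]))
    if blocks and blocks[0][0] != "loop":
        raise ValueError("record must start with a loop")
    if blocks and blocks[-1][0] != "loop":
        raise ValueError("record must end with a loop")
    return _Protein(blocks, dict(truth.repeat_map), list(truth.lineage))


# ---------------------------------------------------------------------------
# divergence


def _substitution_kernel(scheme: ScoringScheme) -> np.ndarray:
    """P(b | a) ~ exp(s(a, b) / 2) over b != a, rows = source residue."""
    n = len(AMINO_ACIDS)
    kern = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                kern[i, j] = np.exp(scheme.score(a, b) / 2.0)
        kern[i] /= kern[i].sum()
    return kern


_KERNEL_CACHE: dict[str, np.ndarray] = {}


def _kernel(scheme: ScoringScheme) -> np.ndarray:
    key = scheme.matrix_name
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = _substitution_kernel(scheme)
    return _KERNEL_CACHE[key]


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _mutate(seq: str, p_sub: float, kern: np.ndarray, rng: np.random.Generator) -> str:
    if not seq:
        return seq
    idx = np.array([_AA_INDEX[c] for c in seq])
    hit = rng.random(len(seq)) < p_sub
    out = list(seq)
    for pos in np.nonzero(hit)[0]:
        out[pos] = AMINO_ACIDS[rng.choice(20, p=kern[idx[pos]])]
    return "".join(out)


def diverge(
    record: SequenceRecord,
    truth: TruthRecord,
    d: float,
    indel_rate: float = 0.0,
    rng_seed: int = 0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[SequenceRecord, TruthRecord]:
    """Diverge a lineage: substitutions at every site, indels in loops only.

    Each site is substituted with probability 1 - exp(-d); the replacement is
    drawn with probability proportional to exp(s(a, b)/2).  The number of
    indel events is Poisson(``indel_rate``); lengths are geometric with mean
    3; insertions and deletions act strictly inside loops so TMS ground truth
    is preserved exactly (truth intervals are re-mapped).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    prot = _protein_from_record(record, truth)
    rng = np.random.default_rng(rng_seed)
    p_sub = 1.0 - np.exp(-d)
    kern = _kernel(scheme)
    blocks = [(k, _mutate(s, p_sub, kern, rng) if p_sub > 0 else s) for k, s in prot.blocks]
    n_indels = rng.poisson(indel_rate) if indel_rate > 0 else 0
    loop_ids = [i for i, (k, _) in enumerate(blocks) if k == "loop"]
    for _ in range(n_indels):
        li = int(rng.choice(loop_ids))
        kind, seq = blocks[li]
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5 and len(seq) > length + 2:  # deletion, keep loop non-trivial
            start = int(rng.integers(1, len(seq) - length))
            seq = seq[:start] + seq[start + length :]
        else:  # insertion
            start = int(rng.integers(0, len(seq) + 1))
            seq = seq[:start] + _draw_block("loop", length, rng) + seq[start:]
        blocks[li] = (kind, seq)
    out = _Protein(blocks, prot.repeat_map, prot.lineage + [f"diverge(d={d})"])
    return out.record(record.id), out.truth(record.id)


# ---------------------------------------------------------------------------
# family generation


@dataclass
class EvolutionScenario:
    """A named duplication pathway plus divergence settings for a family."""

    preset: str
    events: list
    d: float = 0.6
    indel_rate: float = 1.0
    n: int = 50
    seed: int = 0
    blueprint: TopologyBlueprint = field(default_factory=three_tms_blueprint)
    target_identity_band: tuple[float, float] | None = None

    def __post_init__(self):
        if self.d < 0 or self.n < 1:
            raise ValueError("require d >= 0 and n >= 1")


# duplication pathways observed across the ABC uptake porter superfamily:
# 3 -> 6 -> (5 via N- or C-terminal TMS loss) -> 10 -> 20, 6 -> 12, and the
# MalF-like 6-TMS protein with a long hydrophilic insert between TMSs 3 and 4
PRESETS: dict[str, list] = {
    "3": [],
    "3+3": ["duplicate_full"],
    "5_Nloss": ["duplicate_full", "delete_n_terminal_tms"],
    "5_Closs": ["duplicate_full", "delete_c_terminal_tms"],
    "10_from_5": ["duplicate_full", "delete_c_terminal_tms", "duplicate_full"],
    "12_from_6": ["duplicate_full", "duplicate_full"],
    "20_from_10": [
        "duplicate_full",
        "delete_c_terminal_tms",
        "duplicate_full",
        "duplicate_full",
    ],
    "malF_like": ["duplicate_full", ("insert_loop", 3, 120)],
}


def scenario_for_preset(
    preset: str, n: int = 50, d: float = 0.6, indel_rate: float = 1.0, seed: int = 0
) -> EvolutionScenario:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return EvolutionScenario(preset, PRESETS[preset], d=d, indel_rate=indel_rate, n=n, seed=seed)


def _median_interhalf_identity(
    records: list[SequenceRecord],
    truths: list[TruthRecord],
    rng: np.random.Generator,
    max_pairs: int = 20,
) -> float | None:
    """Median cross-member %identity between first and second repeat units."""
    if not truths or not truths[0].repeat_map:
        return None
    ids = []
    n = len(records)
    for _ in range(min(max_pairs, n * (n - 1) if n > 1 else 1)):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        t_i, t_j = truths[i], truths[j]
        firsts = sorted(t_i.repeat_map)
        seconds = sorted(t_i.repeat_map[k] for k in firsts)
        half1 = records[i].seq[
            t_i.tms_intervals[firsts[0] - 1][0] - 1 : t_i.tms_intervals[firsts[-1] - 1][1]
        ]
        half2 = records[j].seq[
            t_j.tms_intervals[seconds[0] - 1][0] - 1 : t_j.tms_intervals[seconds[-1] - 1][1]
        ]
        aln = global_align(half1, half2)
        ids.append(aln.pct_identity)
    return float(np.median(ids))


def make_family(
    scenario: EvolutionScenario,
) -> tuple[list[SequenceRecord], list[TruthRecord], dict]:
    """Generate ``n`` independently diverged members of one family.

    Returns (records, truths, manifest).  The manifest records the seed,
    preset and the inter-half identity band actually achieved.  When the
    scenario requests a target identity band, the family is resampled (up to
    10 attempts with derived seeds) until the achieved median falls inside
    it; failure raises with diagnostics.
    """
    last_achieved = None
    for attempt in range(10):
        ss = np.random.SeedSequence([scenario.seed, attempt])
        child_seeds = ss.spawn(scenario.n + 2)
        anc_rng = np.random.default_rng(child_seeds[0])
        prot = _sample_ancestor(scenario.blueprint, anc_rng)
        event_rng = np.random.default_rng(child_seeds[1])
        for ev in scenario.events:
            prot = _apply_event(prot, ev, event_rng)
        anc_rec, anc_truth = prot.record("ancestor"), prot.truth("ancestor")
        records, truths = [], []
        for i in range(scenario.n):
            pid = f"{scenario.preset}_{i:03d}"
            seed_i = int(child_seeds[2 + i].generate_state(1)[0] % (2**31))
            rec, tr = diverge(
                replace(anc_rec, id=pid),
                replace(anc_truth, id=pid),
                scenario.d,
                scenario.indel_rate,
                rng_seed=seed_i,
            )
            records.append(rec)
            truths.append(tr)
        band_rng = np.random.default_rng(child_seeds[0].generate_state(1)[0] + 1)
        achieved = _median_interhalf_identity(records, truths, band_rng)
        last_achieved = achieved
        manifest = {
            "preset": scenario.preset,
            "seed": scenario.seed,
            "attempt": attempt,
            "n": scenario.n,
            "d": scenario.d,
            "indel_rate": scenario.indel_rate,
            "median_interhalf_identity": achieved,
        }
        band = scenario.target_identity_band
        if band is None or achieved is None or band[0] <= achieved <= band[1]:
            return records, truths, manifest
    raise RuntimeError(
        f"could not reach identity band {scenario.target_identity_band} "
        f"after 10 attempts (last achieved {last_achieved}); "
        f"adjust d for preset {scenario.preset!r}"
    )


# ---------------------------------------------------------------------------
# standard-format output


def write_fasta(records: list[SequenceRecord], path) -> None:
    """60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def read_fasta(path) -> list[SequenceRecord]:
    """Wrapped-line tolerant FASTA reader; id = first whitespace token."""
    records: list[SequenceRecord] = []
    rid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rid is not None:
                    records.append(SequenceRecord(rid, "".join(chunks)))
                rid = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if rid is not None:
        records.append(SequenceRecord(rid, "".join(chunks)))
    return records


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\ttms_index\tstart\tend\tunit_id\n")
        for tr in truths:
            # unit id: 1 for TMSs on the left side of the repeat map, 2 for
            # the right side, 0 for unpaired TMSs
            left, right = set(tr.repeat_map), set(tr.repeat_map.values())
            for k, (lo, hi) in enumerate(tr.tms_intervals, start=1):
                unit = 1 if k in left else 2 if k in right else 0
                fh.write(f"{tr.id}\t{k}\t{lo}\t{hi}\t{unit}\n")


def read_truth_tsv(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, _, start, end, _ = line.rstrip("\n").split("\t")
            out.setdefault(pid, []).append((int(start), int(end)))
    return out


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
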