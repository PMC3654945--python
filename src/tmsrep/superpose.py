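"""Alpha-carbon structural superposition with iterative outlier pruning.

Least-squares rigid-body fitting (Kabsch, via SVD with reflection
correction) of paired CA coordinate sets, iterated: after each fit, all
residue pairs whose post-fit distance exceeds a cutoff (2 Angstrom by
default) are dropped and the remainder refit, until no pair exceeds the
cutoff.  A superposition whose retained pair count falls below 3 is not
credible and raises.  Pairings can be supplied explicitly or derived from a
sequence alignment of the two chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairwise import DEFAULT_SCHEME, ScoringScheme, global_align

__all__ = [
    "CoordinateSegment",
    "SuperpositionResult",
    "read_ca",
    "kabsch",
    "iterative_prune",
    "pair_by_alignment",
    "write_ca_pdb",
]


@dataclass
class CoordinateSegment:
    """Ordered alpha-carbon trace for one chain/residue range."""

    chain: str
    residue_numbers: list[int]
    coords: np.ndarray  # (n, 3)
    source_range: tuple[int, int] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (len(self.residue_numbers), 3):
            raise ValueError("coords must be (n, 3) matching residue_numbers")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if any(
            b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])
        ):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    retained_pairs: list[tuple[int, int]]
    iterations: int
    rmsd_history: list[float] | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def read_ca(pdb_text: str, chain: str, residue_range: tuple[int, int] | None = None) -> CoordinateSegment:
    """Parse CA atoms of one chain from fixed-column PDB ATOM records.

    Keeps the first alternate location per residue; entries outside
    ``residue_range`` (1-based inclusive) are dropped.
    """
    numbers: list[int] = []
    coords: list[list[float]] = []
    seen: set[int] = set()
    for line in pdb_text.splitlines():
        if not line.startswith("ATOM"):
            continue
        if line[12:16].strip() != "CA":
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        if line[21] != chain:
            continue
        resnum = int(line[22:26])
        if residue_range and not residue_range[0] <= resnum <= residue_range[1]:
            continue
        if resnum in seen:
            continue
        seen.add(resnum)
        coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        numbers.append(resnum)
    if not numbers:
        raise ValueError(
            f"no CA atoms for chain {chain!r}"
            + (f" in range {residue_range}" if residue_range else "")
        )
    rng = residue_range or (numbers[0], numbers[-1])
    return CoordinateSegment(chain, numbers, np.array(coords), rng)


def _paired_coords(seg_a, seg_b, pairing):
    A = seg_a.coords[[i for i, _ in pairing]]
    B = seg_b.coords[[j for _, j in pairing]]
    return A, B


def kabsch(
    seg_a: CoordinateSegment,
    seg_b: CoordinateSegment,
    pairing: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid transform mapping seg_b onto seg_a.

    ``pairing`` holds (index_in_a, index_in_b) entries; by default the
    segments are paired positionally (requires equal lengths).  Raises for
    fewer than 3 pairs or degenerate (collinear) geometry.
    """
    if pairing is None:
        if len(seg_a) != len(seg_b):
            raise ValueError("equal lengths required for positional pairing")
        pairing = [(i, i) for i in range(len(seg_a))]
    if len(pairing) < 3:
        raise ValueError("need at least 3 atom pairs")
    A, B = _paired_coords(seg_a, seg_b, pairing)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0]), tol=1e-8) < 2:
        raise ValueError("degenerate geometry: points are collinear")
    H = B0.T @ A0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return SuperpositionResult(R, t, rmsd, list(pairing), 1)


def iterative_prune(
    seg_a: CoordinateSegment,
    seg_b: CoordinateSegment,
    pairing: list[tuple[int, int]] | None = None,
    cutoff: float = 2.0,
    max_iter: int = 50,
    drop_all: bool = True,
) -> SuperpositionResult:
    """Fit, prune pairs beyond ``cutoff`` Angstrom, refit, until stable.

    By default every above-cutoff pair is dropped each round (converges in a
    few iterations); ``drop_all=False`` prunes the single worst pair per
    round.  Raises "superposition not credible" if fewer than 3 pairs
    survive.
    """
    if pairing is None:
        if len(seg_a) != len(seg_b):
            raise ValueError("equal lengths required for positional pairing")
        pairing = [(i, i) for i in range(len(seg_a))]
    retained = list(pairing)
    history: list[float] = []
    result = None
    for it in range(1, max_iter + 1):
        if len(retained) < 3:
            raise ValueError("superposition not credible: fewer than 3 pairs retained")
        result = kabsch(seg_a, seg_b, retained)
        history.append(result.rmsd)
        A, B = _paired_coords(seg_a, seg_b, retained)
        dist = np.linalg.norm(A - (B @ result.rotation.T + result.translation), axis=1)
        over = np.nonzero(dist > cutoff)[0]
        if len(over) == 0:
            return SuperpositionResult(
                result.rotation, result.translation, result.rmsd, retained, it, history
            )
        if drop_all:
            retained = [p for i, p in enumerate(retained) if i not in set(over.tolist())]
        else:
            retained.pop(int(np.argmax(dist)))
    return SuperpositionResult(
        result.rotation, result.translation, result.rmsd, retained, max_iter, history
    )


def pair_by_alignment(
    seg_a: CoordinateSegment,
    seg_b: CoordinateSegment,
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[tuple[int, int]]:
    """Residue pairing from a global sequence alignment of the two chains.

    ``seq_a``/``seq_b`` must run parallel to the segments' CA entries
    (position k of the sequence is CA entry k).  Aligned non-gap columns map
    to (index_in_a, index_in_b) pairs.
    """
    if len(seq_a) != len(seg_a) or len(seq_b) != len(seg_b):
        raise ValueError("sequences must match segment lengths")
    aln = global_align(seq_a, seq_b, scheme)
    pairs: list[tuple[int, int]] = []
    ia = ib = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


def write_ca_pdb(seg: CoordinateSegment, seq: str | None = None) -> str:
    """Minimal PDB text (CA-only ATOM records) for a coordinate segment."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR", "X": "UNK",
    }
    lines = []
    for k, (num, xyz) in enumerate(zip(seg.residue_numbers, seg.coords), start=1):
        res = three.get(seq[k - 1], "UNK") if seq else "GLY"
        lines.append(
            f"ATOM  {k:>5}  CA  {res} {seg.chain}{num:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
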