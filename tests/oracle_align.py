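"""Brute-force alignment oracles: exhaustive enumeration over alignments.

Independent of any dynamic-programming machinery — every gapped alignment of
the two sequences is generated recursively and scored by walking its
columns, so these functions are slow but trustworthy on short sequences.
Gap runs cost gap_open + len * gap_extend; with free end gaps the first and
last maximal runs, when they are gap runs, cost nothing (matching the
convention that only the leading/trailing run of the alignment is terminal).
"""

from __future__ import annotations


def _enumerate_paths(a: str, b: str):
    """Yield alignments as lists of ops: ('M',ca,cb), ('D',ca), ('I',cb).

    'D' consumes a residue of `a` against a gap; 'I' a residue of `b`.
    """
    la, lb = len(a), len(b)

    def rec(i, j, path):
        if i == la and j == lb:
            yield list(path)
            return
        if i < la and j < lb:
            path.append(("M", a[i], b[j]))
            yield from rec(i + 1, j + 1, path)
            path.pop()
        if i < la:
            path.append(("D", a[i]))
            yield from rec(i + 1, j, path)
            path.pop()
        if j < lb:
            path.append(("I", b[j]))
            yield from rec(i, j + 1, path)
            path.pop()

    yield from rec(0, 0, [])


def _score_path(path, score, gap_open, gap_extend, free_end_gaps):
    # split into maximal runs of equal op type
    runs = []
    for op in path:
        if runs and runs[-1][0][0] == op[0]:
            runs[-1].append(op)
        else:
            runs.append([op])
    total = 0.0
    for k, run in enumerate(runs):
        if run[0][0] == "M":
            total += sum(score(ca, cb) for _, ca, cb in run)
        else:
            terminal = free_end_gaps and (k == 0 or k == len(runs) - 1)
            if not terminal:
                total -= gap_open + gap_extend * len(run)
    return total


def global_score_bruteforce(
    a: str, b: str, score, gap_open: float, gap_extend: float, free_end_gaps: bool = True
) -> float:
    """Optimal global score by enumerating every alignment."""
    best = None
    for path in _enumerate_paths(a, b):
        s = _score_path(path, score, gap_open, gap_extend, free_end_gaps)
        if best is None or s > best:
            best = s
    return best


def local_score_bruteforce(
    a: str, b: str, score, gap_open: float, gap_extend: float
) -> float:
    """Optimal local score: best fully-penalized alignment over all
    substring pairs (empty alignment allowed, score 0)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_score_bruteforce(
                        a[i1:i2], b[j1:j2], score, gap_open, gap_extend, free_end_gaps=False
                    )
                    if s > best:
                        best = s
    return best
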