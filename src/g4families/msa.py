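"""Cluster alignment: progressive MSA, gap adjustment, gap score, consensus.

Alignment is guide-tree progressive: a UPGMA tree from pairwise edit
distances orders profile-profile Needleman-Wunsch merges with affine gap
penalties.  A post-pass shifts gaps between score-neutral placements so
that guanine-tract columns stay pure, which matters because downstream
profile HMMs decide match vs insert states per column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .cluster import levenshtein

__all__ = [
    "Alignment",
    "AlignScoring",
    "progressive_align",
    "adjust_gaps",
    "gap_score",
    "filter_clusters",
    "iupac_consensus",
    "IUPAC_CODES",
]

GAP = "-"

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class AlignScoring:
    """Scoring for profile-profile alignment, tuned for short G-rich DNA."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class Alignment:
    """Gapped multiple alignment of one cluster."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def column(self, j: int) -> list[str]:
        return [r[j] for _, r in self.rows]

    def degapped(self) -> dict[str, str]:
        return {sid: r.replace(GAP, "") for sid, r in self.rows}

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)


def _pair_score(a: str, b: str, sc: AlignScoring) -> float:
    if a == GAP and b == GAP:
        return 0.0
    if a == GAP or b == GAP:
        return sc.gap_extend  # per-pair linear term used in SP scoring
    return sc.match if a == b else sc.mismatch


def sp_score(aln: Alignment, sc: AlignScoring | None = None) -> float:
    """Sum-of-pairs score over all row pairs and columns (linear gap term)."""
    sc = sc or AlignScoring()
    total = 0.0
    for (_, r1), (_, r2) in itertools.combinations(aln.rows, 2):
        total += sum(_pair_score(a, b, sc) for a, b in zip(r1, r2))
    return total


def _profile_columns(rows: list[str]) -> list[dict[str, float]]:
    cols = []
    for j in range(len(rows[0])):
        counts: dict[str, float] = {}
        for r in rows:
            counts[r[j]] = counts.get(r[j], 0) + 1
        n = len(rows)
        cols.append({c: v / n for c, v in counts.items()})
    return cols


def _col_score(ca: dict[str, float], cb: dict[str, float], sc: AlignScoring) -> float:
    s = 0.0
    for a, fa in ca.items():
        for b, fb in cb.items():
            s += fa * fb * _pair_score(a, b, sc)
    return s


def _gap_col_score(col: dict[str, float], sc: AlignScoring) -> float:
    # aligning a profile column against an all-gap column
    return sum(f * (0.0 if c == GAP else sc.gap_extend) for c, f in col.items())


def _align_profiles(
    rows_a: list[str], rows_b: list[str], sc: AlignScoring
) -> tuple[list[str], list[str]]:
    """Gotoh profile-profile alignment; ties prefer diagonal, then up."""
    ca, cb = _profile_columns(rows_a), _profile_columns(rows_b)
    n, m = len(ca), len(cb)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A column)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = sc.gap_open + (i - 1) * sc.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = sc.gap_open + (j - 1) * sc.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _col_score(ca[i - 1], cb[j - 1], sc)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + sc.gap_open, X[i - 1, j] + sc.gap_extend)
            Y[i, j] = max(M[i, j - 1] + sc.gap_open, Y[i, j - 1] + sc.gap_extend)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("A")
            out_b.append("B")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            out_a.append("A")
            out_b.append("-")
            state = 0 if M[i - 1, j] + sc.gap_open >= X[i - 1, j] + sc.gap_extend else 1
            i -= 1
        elif state == 2 and j > 0:
            out_a.append("-")
            out_b.append("B")
            state = 0 if M[i, j - 1] + sc.gap_open >= Y[i, j - 1] + sc.gap_extend else 2
            j -= 1
        elif i > 0:
            out_a.append("A")
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append("B")
            j -= 1
    ops_a = out_a[::-1]
    ops_b = out_b[::-1]
    new_a = []
    for r in rows_a:
        it = iter(r)
        new_a.append("".join(next(it) if op == "A" else GAP for op in ops_a))
    new_b = []
    for r in rows_b:
        it = iter(r)
        new_b.append("".join(next(it) if op == "B" else GAP for op in ops_b))
    return new_a, new_b


def progressive_align(
    seqs: dict[str, str], scoring: AlignScoring | None = None
) -> Alignment:
    """UPGMA-guided progressive alignment; deterministic for fixed input order."""
    scoring = scoring or AlignScoring()
    ids = list(seqs)
    if not ids:
        raise ValueError("progressive_align needs at least one sequence")
    if len(ids) == 1:
        return Alignment([(ids[0], seqs[ids[0]].upper())])
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = levenshtein(seqs[ids[i]], seqs[ids[j]])
    Z = linkage(squareform(dist, checks=False), method="average")
    # each node holds (ordered ids, aligned rows)
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]].upper()]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        ids_a, rows_a = nodes.pop(ia)
        ids_b, rows_b = nodes.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, scoring)
        nodes[n + step] = (ids_a + ids_b, new_a + new_b)
    merged_ids, merged_rows = nodes.popitem()[1]
    order = {sid: k for k, sid in enumerate(ids)}
    pairs = sorted(zip(merged_ids, merged_rows), key=lambda t: order[t[0]])
    return Alignment(list(pairs))


def adjust_gaps(aln: Alignment, scoring: AlignScoring | None = None) -> Alignment:
    """Shift gaps between score-neutral placements to purify columns.

    Candidate moves swap a gap with an adjacent residue within one row.  A
    move is taken when the sum-of-pairs score is unchanged and either the
    column-homogeneity objective strictly improves or the move is leftward
    and objective-neutral (canonical left packing).  The result is a fixed
    point, so the operation is idempotent, and degapped rows are untouched.
    """
    scoring = scoring or AlignScoring()
    rows = [list(r) for _, r in aln.rows]
    ids = [sid for sid, _ in aln.rows]
    ncols = aln.n_cols

    def _objective() -> float:
        total = 0.0
        for j in range(ncols):
            counts: dict[str, int] = {}
            for r in rows:
                c = r[j]
                if c != GAP:
                    counts[c] = counts.get(c, 0) + 1
            total += sum(v * v for v in counts.values())
        return total

    def _score() -> float:
        return sp_score(Alignment(list(zip(ids, ["".join(r) for r in rows]))), scoring)

    score0 = _score()
    obj = _objective()
    changed = True
    sweeps = 0
    while changed and sweeps < 50:
        changed = False
        sweeps += 1
        for r in rows:
            for p in range(ncols):
                if r[p] != GAP:
                    continue
                for q in (p - 1, p + 1):
                    if not (0 <= q < ncols) or r[q] == GAP:
                        continue
                    r[p], r[q] = r[q], r[p]
                    new_obj = _objective()
                    ok = False
                    if abs(_score() - score0) < 1e-9:
                        if new_obj > obj + 1e-9:
                            ok = True
                        elif abs(new_obj - obj) <= 1e-9 and q < p:
                            # objective-neutral: pack gaps leftward only
                            ok = True
                    if ok:
                        obj = new_obj
                        changed = True
                    else:
                        r[p], r[q] = r[q], r[p]
    return Alignment(list(zip(ids, ["".join(r) for r in rows])))


def gap_score(aln: Alignment) -> float:
    """Overall gap fraction: total gap characters / (rows x columns)."""
    if aln.n_cols == 0:
        raise ValueError("empty alignment has no gap score")
    gaps = sum(r.count(GAP) for _, r in aln.rows)
    return gaps / (aln.n_rows * aln.n_cols)


def filter_clusters(
    clusters: list[list[str]], min_size: int = 4
) -> list[list[str]]:
    """Drop clusters with fewer than ``min_size`` members."""
    return [c for c in clusters if len(c) >= min_size]


def iupac_consensus(aln: Alignment, plurality: float = 0.5) -> str:
    """Per-column minimal IUPAC code; gap-majority columns emit '-'.

    A base participates in the column code when its frequency is at least
    ``plurality`` times the most frequent base's.
    """
    out = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        n = len(col)
        gaps = col.count(GAP)
        if gaps * 2 > n:
            out.append(GAP)
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append(GAP)
            continue
        top = max(counts.values())
        bases = frozenset(b for b, v in counts.items() if v >= plurality * top)
        out.append(IUPAC_CODES[bases])
    return "".join(out)
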