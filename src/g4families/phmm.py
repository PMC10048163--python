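"""Plan7 profile hidden Markov models for G4 alignments.

A profile of model length m has match states M1..Mm with 4-letter emission
distributions, insert states I0..Im, and silent delete states D1..Dm.  The
seven transition types are M->M, M->I, M->D, I->I, I->M, D->M and D->D
(plus begin/end handling: begin acts as M0, end as M(m+1)).  Models are
trained from a gapped alignment by the usual counting recipe: columns at or
below the gap-fraction threshold become match columns, every emission and
transition count gets a Laplace pseudocount, and counts are normalised.

Scoring is a log-space forward recursion reported as natural-log odds
against a background null; a Viterbi recursion with deterministic
traceback supports aligning new members, and a generative sampler supports
profile-vs-profile testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "NullModel",
    "ProfileHMM",
    "ScoreResult",
    "build_from_alignment",
    "forward_log_odds",
    "viterbi",
    "sample",
    "serialize",
    "deserialize",
]

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
LOG0 = -1e30
SCHEMA_VERSION = 1


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = np.log(x)
    out[np.isneginf(out)] = LOG0
    return out


@dataclass(frozen=True)
class NullModel:
    """Background i.i.d. base distribution used for log odds."""

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("null model probabilities must sum to 1")

    def loglik(self, seq: str) -> float:
        return sum(math.log(self.probs[_IDX[c]]) for c in seq)

    @classmethod
    def from_sequences(cls, seqs: list[str], pseudocount: float = 1.0) -> "NullModel":
        counts = np.full(4, pseudocount)
        for s in seqs:
            for c in s.upper():
                if c in _IDX:
                    counts[_IDX[c]] += 1
        p = counts / counts.sum()
        return cls(tuple(p))  # type: ignore[arg-type]


@dataclass
class ProfileHMM:
    """Plan7 profile with per-node emission and transition probabilities.

    ``match_emissions`` is (m, 4); ``insert_emissions`` is (m+1, 4) for
    I0..Im.  Transition arrays are indexed by source node 0..m, node 0
    being the begin state (treated as a match state with no emission):
    t_mm[j] = P(Mj -> Mj+1) with Mm+1 = end, and similarly for the rest.
    Delete transitions from node 0 encode begin->D1.
    """

    m: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("model length must be >= 1")
        self._validate()

    def _validate(self) -> None:
        if self.match_emissions.shape != (self.m, 4):
            raise ValueError("match emission shape mismatch")
        if self.insert_emissions.shape != (self.m + 1, 4):
            raise ValueError("insert emission shape mismatch")
        for name, arr in (
            ("match", self.match_emissions),
            ("insert", self.insert_emissions),
        ):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} emission rows must sum to 1")
        out_m = self.t_mm + self.t_mi + self.t_md
        if not np.allclose(out_m, 1.0, atol=1e-9):
            raise ValueError("M outgoing transitions must sum to 1")
        if not np.allclose(self.t_im + self.t_ii, 1.0, atol=1e-9):
            raise ValueError("I outgoing transitions must sum to 1")
        # D states exist for nodes 1..m; node 0 rows are unused
        if not np.allclose((self.t_dm + self.t_dd)[1:], 1.0, atol=1e-9):
            raise ValueError("D outgoing transitions must sum to 1")


@dataclass(frozen=True)
class ScoreResult:
    seq_id: str
    family_id: str
    log_odds: float
    forward_loglik: float


def build_from_alignment(
    aln,
    pseudocount: float = 1.0,
    match_rule: float = 0.5,
    metadata: dict | None = None,
) -> ProfileHMM:
    """Train a plan7 profile from a gapped alignment by counting.

    Columns whose gap fraction is at most ``match_rule`` become match
    columns; the rest are modelled by inserts.  Laplace ``pseudocount`` is
    added to every emission and transition count before normalisation.
    """
    rows = [r.upper() for _, r in aln.rows]
    if len(rows) < 2:
        raise ValueError("profile training needs an alignment with >= 2 rows")
    ncols = len(rows[0])
    match_cols = [
        j for j in range(ncols)
        if sum(r[j] == "-" for r in rows) / len(rows) <= match_rule
    ]
    m = len(match_cols)
    if m == 0:
        raise ValueError("alignment has no match columns under this rule")
    col_node = {j: k + 1 for k, j in enumerate(match_cols)}

    e_match = np.full((m, 4), pseudocount)
    e_ins = np.full((m + 1, 4), pseudocount)
    c_mm = np.full(m + 1, pseudocount)
    c_mi = np.full(m + 1, pseudocount)
    c_md = np.full(m + 1, pseudocount)
    c_im = np.full(m + 1, pseudocount)
    c_ii = np.full(m + 1, pseudocount)
    c_dm = np.full(m + 1, pseudocount)
    c_dd = np.full(m + 1, pseudocount)

    for r in rows:
        # state path: (kind, node); begin = ('M', 0), end = ('M', m+1)
        path: list[tuple[str, int]] = [("M", 0)]
        for j in range(ncols):
            c = r[j]
            if j in col_node:
                node = col_node[j]
                if c == "-":
                    path.append(("D", node))
                else:
                    path.append(("M", node))
                    if c in _IDX:
                        e_match[node - 1, _IDX[c]] += 1
            else:
                if c != "-":
                    node = path[-1][1]  # insert node = last node passed
                    path.append(("I", node))
                    if c in _IDX:
                        e_ins[node, _IDX[c]] += 1
        path.append(("M", m + 1))
        for (k1, n1), (k2, n2) in zip(path, path[1:]):
            if k1 == "M":
                if k2 == "M":
                    c_mm[n1] += 1
                elif k2 == "I":
                    c_mi[n1] += 1
                else:
                    c_md[n1] += 1
            elif k1 == "I":
                if k2 == "I":
                    c_ii[n1] += 1
                else:
                    c_im[n1] += 1
            else:
                if k2 == "M":
                    c_dm[n1] += 1
                else:
                    c_dd[n1] += 1

    tot_m = c_mm + c_mi + c_md
    tot_i = c_im + c_ii
    tot_d = c_dm + c_dd
    hmm = ProfileHMM(
        m=m,
        match_emissions=e_match / e_match.sum(axis=1, keepdims=True),
        insert_emissions=e_ins / e_ins.sum(axis=1, keepdims=True),
        t_mm=c_mm / tot_m,
        t_mi=c_mi / tot_m,
        t_md=c_md / tot_m,
        t_im=c_im / tot_i,
        t_ii=c_ii / tot_i,
        t_dm=c_dm / tot_d,
        t_dd=c_dd / tot_d,
        metadata=dict(metadata or {}, pseudocount=pseudocount, match_rule=match_rule),
    )
    return hmm


def _log_tables(hmm: ProfileHMM):
    return (
        _log(hmm.match_emissions),
        _log(hmm.insert_emissions),
        _log(hmm.t_mm), _log(hmm.t_mi), _log(hmm.t_md),
        _log(hmm.t_im), _log(hmm.t_ii),
        _log(hmm.t_dm), _log(hmm.t_dd),
    )


def forward_loglik(hmm: ProfileHMM, seq: str, local: bool = False) -> float:
    """log P(seq | hmm) by the forward recursion over all paths.

    Global mode (default) requires the path to run begin -> node m -> end.
    ``local=True`` enables uniform entry into any match state for the first
    base and uniform exit after the last (for queries that cover only part
    of the model); flanking residues are not modelled, so queries should be
    trimmed to the candidate region.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("cannot score an empty sequence")
    if any(c not in _IDX for c in seq):
        raise ValueError("sequence must be over A,C,G,T")
    le_m, le_i, l_mm, l_mi, l_md, l_im, l_ii, l_dm, l_dd = _log_tables(hmm)
    m = hmm.m
    L = len(seq)
    # fM[j, i] = log P(paths ending in Mj having emitted seq[:i]); j=0 begin
    fM = np.full((m + 2, L + 1), LOG0)
    fI = np.full((m + 1, L + 1), LOG0)
    fD = np.full((m + 1, L + 1), LOG0)
    if not local:
        fM[0, 0] = 0.0  # local paths start only via the uniform entry

    def lse(*vals: float) -> float:
        mx = max(vals)
        if mx <= LOG0 / 2:
            return LOG0
        return mx + math.log(sum(math.exp(v - mx) for v in vals))

    l_uniform = -math.log(m)
    for i in range(L + 1):
        for j in range(m + 1):
            if j > 0 and i > 0:
                c = _IDX[seq[i - 1]]
                fM[j, i] = le_m[j - 1, c] + lse(
                    fM[j - 1, i - 1] + l_mm[j - 1],
                    fI[j - 1, i - 1] + l_im[j - 1],
                    fD[j - 1, i - 1] + l_dm[j - 1],
                    l_uniform if (local and i == 1) else LOG0,
                )
            if i > 0:
                c = _IDX[seq[i - 1]]
                fI[j, i] = le_i[j, c] + lse(
                    fM[j, i - 1] + l_mi[j],
                    fI[j, i - 1] + l_ii[j],
                )
            if j > 0:
                fD[j, i] = lse(
                    fM[j - 1, i] + l_md[j - 1],
                    fD[j - 1, i] + l_dd[j - 1] if j > 1 else LOG0,
                )
    if local:
        return lse(*[fM[j, L] + l_uniform for j in range(1, m + 1)])
    return lse(
        fM[m, L] + l_mm[m],
        fI[m, L] + l_im[m],
        fD[m, L] + l_dm[m],
    )


def forward_log_odds(
    hmm: ProfileHMM,
    seq: str,
    null: NullModel | None = None,
    seq_id: str = "",
    family_id: str = "",
    local: bool = False,
) -> ScoreResult:
    """Natural-log odds log P(seq|hmm) - log P(seq|null)."""
    null = null or NullModel()
    ll = forward_loglik(hmm, seq, local=local)
    return ScoreResult(
        seq_id=seq_id,
        family_id=family_id,
        log_odds=ll - null.loglik(seq),
        forward_loglik=ll,
    )


def viterbi(
    hmm: ProfileHMM, seq: str, null: NullModel | None = None
) -> tuple[list[str], float]:
    """Best state path and its natural-log odds; ties break M > D > I."""
    seq = seq.upper()
    if not seq:
        raise ValueError("cannot score an empty sequence")
    null = null or NullModel()
    le_m, le_i, l_mm, l_mi, l_md, l_im, l_ii, l_dm, l_dd = _log_tables(hmm)
    m = hmm.m
    L = len(seq)
    vM = np.full((m + 1, L + 1), LOG0)
    vI = np.full((m + 1, L + 1), LOG0)
    vD = np.full((m + 1, L + 1), LOG0)
    bM = np.zeros((m + 1, L + 1), dtype=np.int8)
    bI = np.zeros((m + 1, L + 1), dtype=np.int8)
    bD = np.zeros((m + 1, L + 1), dtype=np.int8)
    vM[0, 0] = 0.0
    # backpointer codes: 0=M, 1=D, 2=I  (preference order on ties)
    for i in range(L + 1):
        for j in range(m + 1):
            if j > 0 and i > 0:
                c = _IDX[seq[i - 1]]
                cands = (
                    vM[j - 1, i - 1] + l_mm[j - 1],
                    vD[j - 1, i - 1] + l_dm[j - 1],
                    vI[j - 1, i - 1] + l_im[j - 1],
                )
                best = int(np.argmax(cands))
                vM[j, i] = le_m[j - 1, c] + cands[best]
                bM[j, i] = best
            if i > 0:
                c = _IDX[seq[i - 1]]
                cands2 = (vM[j, i - 1] + l_mi[j], vI[j, i - 1] + l_ii[j])
                best2 = int(np.argmax(cands2))
                vI[j, i] = le_i[j, c] + cands2[best2]
                bI[j, i] = 0 if best2 == 0 else 2
            if j > 0:
                cands3 = (
                    vM[j - 1, i] + l_md[j - 1],
                    vD[j - 1, i] + l_dd[j - 1] if j > 1 else LOG0,
                )
                best3 = int(np.argmax(cands3))
                vD[j, i] = cands3[best3]
                bD[j, i] = 0 if best3 == 0 else 1
    endc = (vM[m, L] + l_mm[m], vD[m, L] + l_dm[m], vI[m, L] + l_im[m])
    state = [0, 1, 2][int(np.argmax(endc))]
    score = float(max(endc))
    path: list[str] = []
    j, i = m, L
    while not (state == 0 and j == 0 and i == 0):
        if state == 0:
            path.append(f"M{j}")
            prev = bM[j, i]
            j, i = j - 1, i - 1
        elif state == 1:
            path.append(f"D{j}")
            prev = bD[j, i]
            j = j - 1
        else:
            path.append(f"I{j}")
            prev = bI[j, i]
            i = i - 1
        state = int(prev)
    return path[::-1], score - null.loglik(seq)


def sample(hmm: ProfileHMM, n: int, seed: int) -> list[str]:
    """Draw n i.i.d. sequences by generative begin-to-end walks."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        chars: list[str] = []
        kind, node = "M", 0
        while True:
            if kind == "M" and node > hmm.m:
                break
            if kind == "M" and node > 0:
                chars.append(ALPHABET[rng.choice(4, p=hmm.match_emissions[node - 1])])
            elif kind == "I":
                chars.append(ALPHABET[rng.choice(4, p=hmm.insert_emissions[node])])
            if kind == "M":
                if node == hmm.m:
                    # no D(m+1): renormalise over end vs insert
                    tot = hmm.t_mm[node] + hmm.t_mi[node]
                    probs = [hmm.t_mm[node] / tot, hmm.t_mi[node] / tot, 0.0]
                else:
                    probs = [hmm.t_mm[node], hmm.t_mi[node], hmm.t_md[node]]
                nxt = rng.choice(3, p=probs)
                kind, node = (
                    ("M", node + 1) if nxt == 0
                    else ("I", node) if nxt == 1
                    else ("D", node + 1)
                )
            elif kind == "I":
                probs2 = [hmm.t_im[node], hmm.t_ii[node]]
                nxt = rng.choice(2, p=probs2)
                kind, node = (("M", node + 1) if nxt == 0 else ("I", node))
            else:
                if node == hmm.m:
                    kind, node = "M", node + 1
                    continue
                probs3 = [hmm.t_dm[node], hmm.t_dd[node]]
                nxt = rng.choice(2, p=probs3)
                kind, node = (("M", node + 1) if nxt == 0 else ("D", node + 1))
        out.append("".join(chars))
    return out


def serialize(hmm: ProfileHMM) -> str:
    """Versioned JSON encoding; lossless round trip via :func:`deserialize`."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "m": hmm.m,
        "match_emissions": hmm.match_emissions.tolist(),
        "insert_emissions": hmm.insert_emissions.tolist(),
        "transitions": {
            "mm": hmm.t_mm.tolist(), "mi": hmm.t_mi.tolist(),
            "md": hmm.t_md.tolist(), "im": hmm.t_im.tolist(),
            "ii": hmm.t_ii.tolist(), "dm": hmm.t_dm.tolist(),
            "dd": hmm.t_dd.tolist(),
        },
        "metadata": hmm.metadata,
    }
    return json.dumps(payload)


def deserialize(text: str) -> ProfileHMM:
    data = json.loads(text)
    try:
        if data["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {data['schema_version']}")
        t = data["transitions"]
        return ProfileHMM(
            m=data["m"],
            match_emissions=np.array(data["match_emissions"], dtype=float),
            insert_emissions=np.array(data["insert_emissions"], dtype=float),
            t_mm=np.array(t["mm"], dtype=float),
            t_mi=np.array(t["mi"], dtype=float),
            t_md=np.array(t["md"], dtype=float),
            t_im=np.array(t["im"], dtype=float),
            t_ii=np.array(t["ii"], dtype=float),
            t_dm=np.array(t["dm"], dtype=float),
            t_dd=np.array(t["dd"], dtype=float),
            metadata=data.get("metadata", {}),
        )
    except KeyError as exc:
        raise ValueError(f"malformed profile HMM JSON: missing {exc}") from exc
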