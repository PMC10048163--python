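"""Initial clustering of G4 sequences.

Two stages mirror the barcode-style workflow: (a) deterministic Levenshtein
sphere clustering groups near-identical sequences around centres; (b) the
leftovers get an all-vs-all local-alignment similarity (-log E-value under
the Karlin-Altschul formula) followed by hierarchical clustering, with the
number of clusters picked either by the inertia-ratio rule or by a
consensus of five internal validity indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "SphereParams",
    "ScoringParams",
    "KSelectionReport",
    "levenshtein",
    "sphere_cluster",
    "pairwise_similarity",
    "hierarchical_cluster",
    "Dendrogram",
    "select_k_inertia",
    "select_k_consensus",
    "cluster_pipeline",
]

LINKAGES = ("ward", "complete", "average", "divisive")


def levenshtein(a: str, b: str, band: int | None = None) -> int:
    """Unit-cost edit distance.

    ``band`` bounds the search: if the true distance exceeds it, ``band + 1``
    is returned (early exit for radius queries).
    """
    k = -1 if band is None else band
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    if d == -1:
        return band + 1  # type: ignore[operator]
    return d


@dataclass(frozen=True)
class SphereParams:
    """Sphere clustering controls.

    ``radius`` is the Levenshtein radius around each centre; ``ordering``
    fixes centre choice (longest-first then lexicographic by default, for
    determinism); with ``group_filter`` members must share the centre's
    G-tract count and differ in length by at most ``radius``.
    """

    radius: int = 2
    ordering: str = "length_desc"
    group_filter: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.ordering not in ("length_desc", "input"):
            raise ValueError("ordering must be length_desc or input")


def _tract_count(seq: str, min_len: int = 3) -> int:
    from .detect import find_g_tracts

    return len(find_g_tracts(seq))


def sphere_cluster(
    seqs: dict[str, str], params: SphereParams | None = None
) -> tuple[list[list[str]], list[str]]:
    """Greedy fixed-radius clustering around deterministically chosen centres.

    Returns (clusters, unassigned): each cluster is a list of ids whose
    first element is the centre; spheres that catch no member besides their
    centre are returned as unassigned for the similarity stage.
    """
    if not seqs:
        raise ValueError("sphere_cluster needs at least one sequence")
    params = params or SphereParams()
    ids = list(seqs)
    if params.ordering == "length_desc":
        ids.sort(key=lambda i: (-len(seqs[i]), seqs[i], i))
    clusters: list[list[str]] = []
    unassigned: list[str] = []
    free = set(ids)
    for center in ids:
        if center not in free:
            continue
        free.discard(center)
        cseq = seqs[center]
        ctracts = _tract_count(cseq)
        members = [center]
        for other in ids:
            if other not in free:
                continue
            oseq = seqs[other]
            if params.group_filter:
                if abs(len(oseq) - len(cseq)) > params.radius:
                    continue
                if _tract_count(oseq) != ctracts:
                    continue
            if levenshtein(cseq, oseq, band=params.radius) <= params.radius:
                members.append(other)
                free.discard(other)
        if len(members) > 1:
            clusters.append(members)
        else:
            unassigned.append(center)
    return clusters, unassigned


@dataclass(frozen=True)
class ScoringParams:
    """Local-alignment scoring and Karlin-Altschul E-value parameters.

    Defaults follow megablast-style nucleotide scoring (match +2,
    mismatch -3, gap open -5, gap extend -2) with ungapped lambda/K.
    The similarity between two sequences is max(0, -ln E) with
    E = K * m * n * exp(-lambda * S).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lam: float = 0.625
    K: float = 0.41


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int, params: ScoringParams) -> float:
    """E = K * m * n * exp(-lambda * S) for a local-alignment score S."""
    return params.K * m * n * math.exp(-params.lam * score)


def pairwise_similarity(
    seqs: dict[str, str], scoring: ScoringParams | None = None
) -> DistanceMatrix:
    """All-vs-all -log(E-value) similarity, returned as a distance matrix.

    Smith-Waterman score per pair -> Karlin-Altschul E-value on the pairwise
    search space m*n -> similarity = max(0, -ln E); distance is the matrix
    maximum similarity minus the pair similarity (0 on the diagonal pairs of
    identical sequences).
    """
    if len(seqs) < 2:
        raise ValueError("pairwise_similarity needs at least two sequences")
    scoring = scoring or ScoringParams()
    aligner = _aligner(scoring)
    labels = list(seqs)
    n = len(labels)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            score = aligner.score(a, b)
            e = karlin_altschul_evalue(score, len(a), len(b), scoring)
            sim[i, j] = sim[j, i] = max(0.0, -math.log(e)) if e > 0 else math.inf
    off = sim[np.triu_indices(n, k=1)] if n > 1 else np.array([0.0])
    finite = off[np.isfinite(off)]
    top = float(finite.max()) if finite.size else 0.0
    sim[~np.isfinite(sim)] = top
    dist = top - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(labels, dist)


class Dendrogram:
    """Merge tree supporting k-cluster cuts for all four linkage flavours.

    Agglomerative linkages wrap a scipy linkage matrix; the divisive variant
    stores the DIANA split sequence and replays the first k-1 splits.
    """

    def __init__(self, method: str, n: int, Z: np.ndarray | None = None,
                 splits: list[list[np.ndarray]] | None = None) -> None:
        self.method = method
        self.n = n
        self.Z = Z
        self._splits = splits

    def cut(self, k: int) -> np.ndarray:
        """Labels in 0..k-1 for the k-cluster partition."""
        if not (1 <= k <= self.n):
            raise ValueError("k out of range")
        if self.Z is not None:
            raw = fcluster(self.Z, t=k, criterion="maxclust")
            return _canonical_labels(raw)
        assert self._splits is not None
        groups = self._splits[min(k, len(self._splits) + 1) - 1]
        labels = np.empty(self.n, dtype=int)
        for gi, idx in enumerate(groups):
            labels[idx] = gi
        return _canonical_labels(labels)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def _diana_splits(values: np.ndarray) -> list[list[np.ndarray]]:
    """DIANA-style divisive split sequence.

    At each step the cluster with the largest diameter is split: the point
    with the highest mean dissimilarity to the rest seeds a splinter group,
    then points move to the splinter while they are on average closer to it
    than to the remainder.
    """
    n = values.shape[0]
    groups = [np.arange(n)]
    sequence = [[g.copy() for g in groups]]
    while len(groups) < n:
        diam = [values[np.ix_(g, g)].max() if len(g) > 1 else -1.0 for g in groups]
        gi = int(np.argmax(diam))
        g = groups[gi]
        sub = values[np.ix_(g, g)]
        m = len(g)
        if m == 2:
            splinter = [0]
        else:
            avg = sub.sum(axis=1) / (m - 1)
            splinter = [int(np.argmax(avg))]
            moved = True
            while moved and len(splinter) < m - 1:
                moved = False
                rest = [i for i in range(m) if i not in splinter]
                best, best_gain = None, 0.0
                for i in rest:
                    d_rest = sub[i, [j for j in rest if j != i]].mean() if len(rest) > 1 else 0.0
                    d_spl = sub[i, splinter].mean()
                    gain = d_rest - d_spl
                    if gain > best_gain + 1e-12:
                        best, best_gain = i, gain
                if best is not None:
                    splinter.append(best)
                    moved = True
        mask = np.zeros(m, dtype=bool)
        mask[splinter] = True
        a, b = g[mask], g[~mask]
        groups = groups[:gi] + [b, a] + groups[gi + 1 :]
        sequence.append([gg.copy() for gg in groups])
    return sequence


def hierarchical_cluster(D: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Merge tree for ward/complete/average (scipy) or divisive (DIANA)."""
    if D.n < 2:
        raise ValueError("need at least two observations")
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}")
    if method == "divisive":
        return Dendrogram(method, D.n, splits=_diana_splits(D.values))
    Z = linkage(D.condensed(), method=method)
    return Dendrogram(method, D.n, Z=Z)


@dataclass
class KSelectionReport:
    """Outcome of a k-selection rule."""

    mode: str
    chosen_k: int | None
    inertia: dict[int, float] = field(default_factory=dict)
    votes: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False


def _within_inertia(values: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to the cluster medoid."""
    total = 0.0
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            continue
        sub = values[np.ix_(idx, idx)]
        medoid = int(np.argmin((sub ** 2).sum(axis=1)))
        total += float((sub[medoid] ** 2).sum())
    return total


def select_k_inertia(
    D: DistanceMatrix,
    dendrogram: Dendrogram | None = None,
    k_range: tuple[int, int] | None = None,
    all_linkages: bool = False,
) -> KSelectionReport:
    """Inertia-ratio rule: the k after the largest successive inertia drop.

    I_m is the medoid-based within-cluster inertia of the m-cluster cut;
    the chosen k is m + 1 for the m maximising I_m / I_{m+1} (the split
    that produced the biggest drop).  Cuts with zero inertia are skipped
    (the ratio is undefined once every cluster is a singleton).  With
    ``all_linkages`` the rule runs on every linkage flavour and the mode
    of the per-linkage choices is reported.
    """
    lo, hi = k_range or (2, min(15, D.n - 1))
    lo = max(2, lo)
    hi = min(hi, D.n - 1)
    if hi < lo:
        return KSelectionReport(mode="inertia", chosen_k=None, degenerate=True)
    if np.allclose(D.values, 0):
        return KSelectionReport(mode="inertia", chosen_k=None, degenerate=True)

    def _choose(dg: Dendrogram) -> tuple[int | None, dict[int, float]]:
        inertia = {
            m: _within_inertia(D.values, dg.cut(m))
            for m in range(lo - 1, hi + 1)
        }
        best_k, best_ratio = None, -math.inf
        for m in range(lo - 1, hi):
            if inertia[m + 1] <= 0 or inertia[m] <= 0:
                continue
            ratio = inertia[m] / inertia[m + 1]
            if ratio > best_ratio + 1e-12:
                best_k, best_ratio = m + 1, ratio
        return best_k, inertia

    if not all_linkages:
        dg = dendrogram or hierarchical_cluster(D, "average")
        k, inertia = _choose(dg)
        return KSelectionReport(mode="inertia", chosen_k=k, inertia=inertia,
                                degenerate=k is None)
    choices = []
    inertia_last: dict[int, float] = {}
    for method in LINKAGES:
        k, inertia_last = _choose(hierarchical_cluster(D, method))
        if k is not None:
            choices.append(k)
    if not choices:
        return KSelectionReport(mode="inertia", chosen_k=None, degenerate=True)
    vals, counts = np.unique(choices, return_counts=True)
    chosen = int(vals[np.argmax(counts)])  # ties resolve to smallest k
    return KSelectionReport(mode="inertia", chosen_k=chosen, inertia=inertia_last)


# ---------------------------------------------------------------- indices


def _silhouette(values: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(values, labels, metric="precomputed"))


def _dunn(values: np.ndarray, labels: np.ndarray) -> float:
    inter = math.inf
    intra = 0.0
    for c in np.unique(labels):
        idx = labels == c
        sub = values[np.ix_(idx, idx)]
        if sub.size > 1:
            intra = max(intra, float(sub.max()))
        other = values[np.ix_(idx, ~idx)]
        if other.size:
            inter = min(inter, float(other.min()))
    if intra == 0:
        return math.inf
    return inter / intra


def _c_index(values: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(values, k=1)
    d = values[iu]
    same = (labels[iu[0]] == labels[iu[1]])
    sw = float(d[same].sum())
    nw = int(same.sum())
    if nw == 0:
        return 0.0
    ds = np.sort(d)
    smin = float(ds[:nw].sum())
    smax = float(ds[-nw:].sum())
    if smax == smin:
        return 0.0
    return (sw - smin) / (smax - smin)


def _mcclain(values: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(values, k=1)
    d = values[iu]
    same = (labels[iu[0]] == labels[iu[1]])
    nw, nb = int(same.sum()), int((~same).sum())
    if nw == 0 or nb == 0:
        return math.inf
    mean_w = float(d[same].mean())
    mean_b = float(d[~same].mean())
    if mean_b == 0:
        return math.inf
    return mean_w / mean_b


def _frey(values: np.ndarray, labels_k: np.ndarray, labels_k1: np.ndarray) -> float:
    """Frey-Van Groenewoud ratio between successive cuts k and k+1."""

    def _means(labels: np.ndarray) -> tuple[float, float]:
        iu = np.triu_indices_from(values, k=1)
        d = values[iu]
        same = (labels[iu[0]] == labels[iu[1]])
        mb = float(d[~same].mean()) if (~same).any() else 0.0
        mw = float(d[same].mean()) if same.any() else 0.0
        return mb, mw

    eb1, ew1 = _means(labels_k1)
    eb0, ew0 = _means(labels_k)
    denom = ew1 - ew0
    if denom == 0:
        return math.inf
    return (eb1 - eb0) / denom


def select_k_consensus(
    D: DistanceMatrix,
    dendrogram: Dendrogram | None = None,
    k_range: tuple[int, int] | None = None,
) -> KSelectionReport:
    """Consensus of silhouette, Dunn, C-index, McClain and Frey votes.

    Each index votes for its own optimal k over the cuts of one dendrogram
    (silhouette/Dunn maximise; C-index/McClain minimise; Frey takes the
    last k whose successive ratio stays >= 1).  The consensus is the mode,
    ties broken toward smaller k.
    """
    dg = dendrogram or hierarchical_cluster(D, "average")
    lo, hi = k_range or (2, min(15, D.n - 1))
    lo = max(2, lo)
    hi = min(hi, D.n - 1)
    if hi < lo or np.allclose(D.values, 0):
        return KSelectionReport(mode="consensus", chosen_k=None, degenerate=True)
    cuts = {k: dg.cut(k) for k in range(lo, hi + 2)}
    ks = list(range(lo, hi + 1))
    sil = {k: _silhouette(D.values, cuts[k]) for k in ks}
    dunn = {k: _dunn(D.values, cuts[k]) for k in ks}
    cidx = {k: _c_index(D.values, cuts[k]) for k in ks}
    mccl = {k: _mcclain(D.values, cuts[k]) for k in ks}
    frey = {k: _frey(D.values, cuts[k], cuts[k + 1]) for k in ks}

    def _argbest(scores: dict[int, float], maximize: bool) -> int:
        best_k = ks[0]
        for k in ks:
            s, b = scores[k], scores[best_k]
            if (s > b + 1e-12) if maximize else (s < b - 1e-12):
                best_k = k
        return best_k

    frey_k = ks[0]
    for k in ks:
        if frey[k] >= 1.0:
            frey_k = k
    votes = {
        "silhouette": _argbest(sil, True),
        "dunn": _argbest(dunn, True),
        "c_index": _argbest(cidx, False),
        "mcclain": _argbest(mccl, False),
        "frey": frey_k,
    }
    vals, counts = np.unique(list(votes.values()), return_counts=True)
    chosen = int(vals[np.argmax(counts)])  # np.unique sorts, so ties -> smaller k
    return KSelectionReport(mode="consensus", chosen_k=chosen, votes=votes)


def cluster_pipeline(
    seqs: dict[str, str],
    sphere: SphereParams | None = None,
    scoring: ScoringParams | None = None,
    linkage_method: str = "average",
    k_select: str = "inertia",
) -> list[list[str]]:
    """Two-stage initial clustering: spheres, then similarity + hierarchy.

    Sequences left unassigned by sphere clustering are clustered with the
    -log(E) similarity matrix and the chosen k-selection rule.  Returns
    clusters as lists of sequence ids (no minimum-size filtering here).
    """
    clusters, leftovers = sphere_cluster(seqs, sphere)
    if len(leftovers) == 1:
        clusters.append([leftovers[0]])
    elif len(leftovers) >= 2:
        sub = {i: seqs[i] for i in leftovers}
        D = pairwise_similarity(sub, scoring)
        dg = hierarchical_cluster(D, linkage_method)
        if k_select == "consensus":
            report = select_k_consensus(D, dg)
        else:
            report = select_k_inertia(D, dg)
        k = report.chosen_k
        if k is None:
            clusters.append(list(leftovers))
        else:
            labels = dg.cut(k)
            for c in range(k):
                members = [D.labels[i] for i in np.where(labels == c)[0]]
                if members:
                    clusters.append(members)
    return clusters
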