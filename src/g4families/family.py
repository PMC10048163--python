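"""Family refinement and classification.

The refinement engine iterates: align each cluster, train a plan7 profile,
score every cluster's sequences against every profile, and test per-profile
distinctness with one-sided Wilcoxon rank-sum tests of own-profile scores
against each competitor.  Profiles that are distinct against all rivals,
whose own members give them a mean Akaike weight at or above the membership
threshold, and whose alignments stay below the gap-score ceiling are
accepted as families; mutually non-distinct profiles are pooled and merged
(or re-clustered when the merged alignment is too gappy).  Queries are
classified by forward log odds against every family, converted to
normalised Akaike weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import false_discovery_control, mannwhitneyu

from . import msa, phmm
from .msa import Alignment, adjust_gaps, gap_score, iupac_consensus, progressive_align
from .phmm import NullModel, ProfileHMM, build_from_alignment, forward_log_odds

__all__ = [
    "Family",
    "FamilySet",
    "RefinementConfig",
    "MergeConfig",
    "ClassificationResult",
    "wilcoxon_rank_sum",
    "score_matrix",
    "divergence_test",
    "akaike_weights",
    "refine",
    "classify",
    "merge_family_sets",
]

BUNDLE_VERSION = 1


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> float:
    """One-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact distribution when min(len) <= 10 and there are no ties; normal
    approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = min(x.size, y.size) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    kwargs = {"use_continuity": True} if method == "asymptotic" else {}
    return float(
        mannwhitneyu(x, y, alternative=alternative, method=method, **kwargs).pvalue
    )


@dataclass
class Family:
    """An accepted profile with its alignment, members and provenance."""

    id: str
    hmm: ProfileHMM
    alignment: Alignment
    gap_score: float
    consensus: str
    members: list[str]
    provenance: dict = field(default_factory=dict)


@dataclass
class FamilySet:
    """The unit of classification: a bundle of families plus a shared null."""

    families: list[Family]
    null: NullModel = field(default_factory=NullModel)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.families]
        if len(ids) != len(set(ids)):
            raise ValueError("family ids must be unique")

    def __len__(self) -> int:
        return len(self.families)

    def get(self, fid: str) -> Family:
        for f in self.families:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def to_json(self) -> str:
        payload = {
            "bundle_version": BUNDLE_VERSION,
            "null": list(self.null.probs),
            "thresholds": self.thresholds,
            "families": [
                {
                    "id": f.id,
                    "hmm": json.loads(phmm.serialize(f.hmm)),
                    "alignment": f.alignment.rows,
                    "gap_score": f.gap_score,
                    "consensus": f.consensus,
                    "members": f.members,
                    "provenance": f.provenance,
                }
                for f in self.families
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FamilySet":
        data = json.loads(text)
        if data.get("bundle_version") != BUNDLE_VERSION:
            raise ValueError("unsupported family bundle version")
        fams = [
            Family(
                id=d["id"],
                hmm=phmm.deserialize(json.dumps(d["hmm"])),
                alignment=Alignment([tuple(r) for r in d["alignment"]]),
                gap_score=d["gap_score"],
                consensus=d["consensus"],
                members=d["members"],
                provenance=d.get("provenance", {}),
            )
            for d in data["families"]
        ]
        return cls(
            families=fams,
            null=NullModel(tuple(data["null"])),
            thresholds=data.get("thresholds", {}),
        )


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds of the iterative accept/merge loop."""

    alpha: float = 0.05
    member_prob: float = 0.99
    gap_max: float = 0.10
    merge_gap_max: float = 0.6
    max_iter: int = 100
    test_set: str = "members"  # or "sampled"
    sample_n: int = 30
    seed: int = 0
    membership_rule: str = "mean"  # or "min"
    min_size: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("member_prob", "gap_max", "merge_gap_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class MergeConfig:
    """Cross-method redundancy thresholds."""

    log_odds_min: float = 5.0
    akaike_min: float = 0.7
    gap_max: float = 0.07


@dataclass
class ClassificationResult:
    seq_id: str
    best_family: str
    log_odds: float
    akaike_weight: float
    scores: dict[str, float]
    weights: dict[str, float]


def akaike_weights(logliks, ks=None) -> np.ndarray:
    """Normalised Akaike weights from log-likelihoods and parameter counts.

    AIC_i = 2 k_i - 2 loglik_i; w_i = exp(-delta_i / 2) normalised, computed
    in log space.  With all k equal (the default k=0) the weights reduce to
    likelihood weights.
    """
    logliks = np.asarray(logliks, dtype=float)
    if logliks.size == 0:
        raise ValueError("need at least one model")
    ks = np.zeros_like(logliks) if ks is None else np.asarray(ks, dtype=float)
    if ks.shape != logliks.shape:
        raise ValueError("ks must match logliks in length")
    aic = 2.0 * ks - 2.0 * logliks
    half_delta = -(aic - aic.min()) / 2.0
    w = np.exp(half_delta - half_delta.max())
    return w / w.sum()


def score_matrix(
    profiles: list[ProfileHMM],
    seq_sets: list[list[str]],
    null: NullModel | None = None,
) -> list[list[np.ndarray]]:
    """scores[i][j] = log odds of every sequence in set i against profile j."""
    if len(profiles) != len(seq_sets):
        raise ValueError("one sequence set per profile is required")
    null = null or NullModel()
    out: list[list[np.ndarray]] = []
    for seqs in seq_sets:
        row = []
        for hmm in profiles:
            row.append(
                np.array([forward_log_odds(hmm, s, null).log_odds for s in seqs])
            )
        out.append(row)
    return out


def divergence_test(
    scores: list[list[np.ndarray]],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[list[bool], np.ndarray]:
    """Per-profile distinctness and the one-sided p-value matrix.

    Profile i is distinct iff, for every rival j, its own sequences score
    significantly higher on P_i than on P_j (one-sided rank-sum p < alpha).
    P-values are raw by default (no multiplicity correction);
    ``correction="bh"`` applies Benjamini-Hochberg across each profile's
    rival comparisons before thresholding.
    """
    n = len(scores)
    if n < 2:
        raise ValueError("divergence testing needs at least two profiles")
    if correction not in (None, "bh"):
        raise ValueError("correction must be None or 'bh'")
    pvals = np.full((n, n), np.nan)
    distinct = []
    for i in range(n):
        rivals = [j for j in range(n) if j != i]
        ps = np.array([
            wilcoxon_rank_sum(scores[i][i], scores[i][j], "greater")
            for j in rivals
        ])
        pvals[i, rivals] = ps
        tested = (
            false_discovery_control(ps) if correction == "bh" else ps
        )
        distinct.append(bool(np.all(tested < alpha)))
    return distinct, pvals


def _train_cluster(
    cid: str, members: dict[str, str], provenance: dict
) -> Family:
    aln = adjust_gaps(progressive_align(members))
    hmm = build_from_alignment(aln, metadata={"cluster": cid})
    return Family(
        id=cid,
        hmm=hmm,
        alignment=aln,
        gap_score=gap_score(aln),
        consensus=iupac_consensus(aln),
        members=list(members),
        provenance=provenance,
    )


def _membership_weight(fam_idx: int, scores_row: list[np.ndarray], rule: str) -> float:
    """Mean (or min) Akaike weight of a cluster's own sequences for its profile."""
    n_seqs = scores_row[0].size
    weights = []
    for s in range(n_seqs):
        logliks = [scores_row[j][s] for j in range(len(scores_row))]
        weights.append(akaike_weights(logliks)[fam_idx])
    return float(min(weights) if rule == "min" else np.mean(weights))


def _connected_components(adj: dict[int, set[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v] - seen)
        comps.append(sorted(comp))
    return comps


def refine(
    clusters: list[list[str]],
    seqs: dict[str, str],
    config: RefinementConfig | None = None,
    null: NullModel | None = None,
    provenance: str = "refine",
) -> FamilySet:
    """Iterative accept/merge refinement of clusters into families.

    ``clusters`` holds sequence-id lists (already size-filtered upstream);
    ``seqs`` maps ids to sequences.  The loop is deterministic given the
    config seed and stops at convergence (cluster partition unchanged) or
    after ``max_iter`` passes.
    """
    config = config or RefinementConfig()
    null = null or NullModel()
    working = [sorted(c) for c in clusters if len(c) >= config.min_size]
    if not working:
        return FamilySet(families=[], null=null,
                         thresholds=_thresholds_dict(config))
    converged = False
    families: list[Family] = []
    rng_seed = config.seed
    for iteration in range(config.max_iter):
        families = []
        for idx, members in enumerate(working):
            fam = _train_cluster(
                f"F{idx + 1}",
                {m: seqs[m] for m in members},
                {"method": provenance, "iteration": iteration},
            )
            families.append(fam)
        if config.test_set == "sampled":
            test_sets = []
            for i, f in enumerate(families):
                drawn = [
                    s for s in phmm.sample(
                        f.hmm, config.sample_n, (rng_seed + i) % (2**31)
                    )
                    if s  # all-delete walks emit nothing and cannot be scored
                ]
                test_sets.append(drawn or [seqs[m] for m in f.members])
        else:
            test_sets = [[seqs[m] for m in f.members] for f in families]
        scores = score_matrix([f.hmm for f in families], test_sets, null)
        if len(families) == 1:
            distinct = [True]
        else:
            distinct, _ = divergence_test(scores, config.alpha)
        # pool mutually non-distinct profiles into connected components
        adj: dict[int, set[int]] = {i: set() for i in range(len(families))}
        if len(families) > 1:
            for i in range(len(families)):
                if distinct[i]:
                    continue
                for j in range(len(families)):
                    if i == j:
                        continue
                    p = wilcoxon_rank_sum(scores[i][i], scores[i][j], "greater")
                    if p >= config.alpha:
                        adj[i].add(j)
                        adj[j].add(i)
        new_working: list[list[str]] = []
        for comp in _connected_components(adj):
            if len(comp) == 1:
                new_working.append(working[comp[0]])
                continue
            pooled = sorted({m for i in comp for m in working[i]})
            merged_aln = adjust_gaps(progressive_align({m: seqs[m] for m in pooled}))
            if gap_score(merged_aln) < config.merge_gap_max:
                new_working.append(pooled)
            else:
                # too gappy to merge outright: re-cluster the pool
                new_working.extend(_recluster_pool(pooled, seqs))
        new_working = [c for c in new_working if len(c) >= config.min_size]
        new_working.sort()
        if new_working == working:
            converged = True
            break
        working = new_working
        if not working:
            families, scores = [], []
            break

    accepted: list[Family] = []
    for idx, fam in enumerate(families):
        if fam.gap_score >= config.gap_max:
            continue
        if len(fam.members) < config.min_size:
            continue
        if len(families) > 1 and not distinct[idx]:
            continue
        w = _membership_weight(idx, scores[idx], config.membership_rule)
        if len(families) > 1 and w < config.member_prob:
            continue
        fam.provenance.update(converged=converged, membership_weight=w)
        accepted.append(fam)
    for k, fam in enumerate(accepted):
        fam.id = f"F{k + 1}"
    return FamilySet(
        families=accepted, null=null, thresholds=_thresholds_dict(config)
    )


def _thresholds_dict(config: RefinementConfig) -> dict:
    return {k: v for k, v in asdict(config).items()}


def _recluster_pool(pooled: list[str], seqs: dict[str, str]) -> list[list[str]]:
    """Average-linkage re-clustering of a pooled group, inertia-rule k."""
    from .cluster import (DistanceMatrix, hierarchical_cluster, levenshtein,
                          select_k_inertia)

    n = len(pooled)
    if n < 4:
        return [pooled]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(seqs[pooled[i]], seqs[pooled[j]])
    D = DistanceMatrix(pooled, d)
    dg = hierarchical_cluster(D, "average")
    report = select_k_inertia(D, dg)
    if report.chosen_k is None:
        return [pooled]
    labels = dg.cut(report.chosen_k)
    return [
        [pooled[i] for i in np.where(labels == c)[0]]
        for c in range(report.chosen_k)
    ]


def classify(
    seq: str, family_set: FamilySet, seq_id: str = "query"
) -> ClassificationResult:
    """Forward log odds against every family, normalised Akaike weights.

    The best family is the argmax weight; ties break toward the lowest
    family id.
    """
    if not family_set.families:
        raise ValueError("cannot classify against an empty family set")
    fams = sorted(family_set.families, key=lambda f: f.id)
    lods = [
        forward_log_odds(f.hmm, seq, family_set.null).log_odds for f in fams
    ]
    w = akaike_weights(lods)
    best = int(np.argmax(w))
    return ClassificationResult(
        seq_id=seq_id,
        best_family=fams[best].id,
        log_odds=float(lods[best]),
        akaike_weight=float(w[best]),
        scores={f.id: float(s) for f, s in zip(fams, lods)},
        weights={f.id: float(x) for f, x in zip(fams, w)},
    )


def merge_family_sets(
    sets: list[FamilySet],
    seqs: dict[str, str],
    config: MergeConfig | None = None,
    null: NullModel | None = None,
) -> FamilySet:
    """Cross-method redundancy removal.

    Families from different discovery routes are merged when one family's
    members cross-score above ``log_odds_min`` on the other profile with a
    mean cross-family Akaike weight >= ``akaike_min``.  The cross weight is
    computed with the family's own profile left out of the comparison set
    (a member's own profile otherwise always caps its twin near 0.5, and
    redundancy means "without my own profile, my members would confidently
    choose that one").  A merge is kept only if the re-aligned, re-trained
    family's gap score stays <= ``gap_max``.
    """
    if not sets:
        raise ValueError("need at least one family set")
    config = config or MergeConfig()
    null = null or (sets[0].null if sets else NullModel())
    all_fams: list[Family] = []
    for si, fs in enumerate(sets):
        for f in fs.families:
            g = Family(**{**f.__dict__, "provenance": dict(f.provenance)})
            g.id = f"S{si + 1}:{f.id}"
            all_fams.append(g)
    n = len(all_fams)
    if n <= 1:
        out = FamilySet(families=list(all_fams), null=null)
        for k, f in enumerate(out.families):
            f.id = f"F{k + 1}"
        return out
    profiles = [f.hmm for f in all_fams]
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        member_seqs = [seqs[m] for m in all_fams[i].members]
        lods = np.array(
            [
                [forward_log_odds(p, s, null).log_odds for p in profiles]
                for s in member_seqs
            ]
        )
        rivals = [j for j in range(n) if j != i]
        # leave-own-profile-out weights over the rival set
        w_rival = np.array([akaike_weights(row[rivals]) for row in lods])
        for rj, j in enumerate(rivals):
            if (
                lods[:, j].mean() >= config.log_odds_min
                and w_rival[:, rj].mean() >= config.akaike_min
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[Family] = []
    for root in sorted(groups):
        idxs = groups[root]
        if len(idxs) == 1:
            merged.append(all_fams[idxs[0]])
            continue
        members = sorted({m for i in idxs for m in all_fams[i].members})
        cand = _train_cluster(
            "merged", {m: seqs[m] for m in members},
            {"method": "merge", "sources": [all_fams[i].id for i in idxs]},
        )
        if cand.gap_score <= config.gap_max:
            merged.append(cand)
        else:
            merged.extend(all_fams[i] for i in idxs)  # merge rejected
    for k, f in enumerate(merged):
        f.id = f"F{k + 1}"
    return FamilySet(families=merged, null=null,
                     thresholds={"merge": asdict(config)})
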