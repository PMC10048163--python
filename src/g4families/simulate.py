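"""Synthetic G4 families and genomes with known truth.

The generator emulates the mutation structure the clustering assumes:
guanine tracts are conserved while loops accumulate substitutions and
short indels.  Family templates are valid G4s under the default detection
parameters; members are loop-mutated copies; genomes plant members at
non-overlapping positions on random strands in i.i.d. background of a
given GC content.  The background has no repeat structure, which is
sufficient for unit testing but unrealistic for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionParams, find_g_tracts, reverse_complement

__all__ = [
    "SimConfig",
    "Template",
    "Truth",
    "default_templates",
    "simulate_family",
    "simulate_families",
    "simulate_genome",
    "evaluate_recovery",
]

BASES = "ACGT"


@dataclass(frozen=True)
class Template:
    """A family seed: tract lengths and loop sequences, e.g. G3-TTA-G3-..."""

    tract_lengths: tuple[int, ...]
    loops: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.loops) != len(self.tract_lengths) - 1:
            raise ValueError("need one loop fewer than tracts")

    @property
    def sequence(self) -> str:
        parts = []
        for i, t in enumerate(self.tract_lengths):
            parts.append("G" * t)
            if i < len(self.loops):
                parts.append(self.loops[i])
        return "".join(parts)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Loop substitution rate 0.05 and loop indel rate 0.02 correspond to the
    divergence regime the clustering is expected to resolve; tract
    mutations are off by default (tracts are conserved in the family
    model) and can be enabled to stress-test robustness.
    """

    n_families: int = 5
    members_per_family: int = 20
    sub_rate: float = 0.05
    indel_rate: float = 0.02
    tract_mutation_rate: float = 0.0
    background_length: int = 20_000
    gc_content: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "tract_mutation_rate", "gc_content"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Truth:
    """Planted labels and intervals."""

    labels: dict[str, int]  # seq_id -> family index
    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    # (contig, start, end, seq_id, strand)


def default_templates(n: int) -> list[Template]:
    """n well-separated G4 templates with distinct loop compositions.

    Construction is deterministic: templates cycle through distinct loop
    lengths and letters so families differ in loop content and length.
    """
    letters = ["A", "T", "C", "AT", "TC", "CA", "TTA", "ACA", "CCT", "TAT"]
    templates = []
    for i in range(n):
        tracts = tuple([3 + (i % 2)] * 4)
        loop_len = 1 + (i % 3)
        loops = []
        for j in range(3):
            unit = letters[(i + j) % len(letters)]
            loops.append((unit * 3)[: loop_len + (j % 2)])
        templates.append(Template(tracts, tuple(loops)))
    return templates


def _mutate_loop(loop: str, cfg: SimConfig, rng: np.random.Generator) -> str:
    out = []
    for c in loop:
        if rng.random() < cfg.sub_rate:
            choices = [b for b in BASES if b != c and b != "G"]
            c = choices[rng.integers(len(choices))]
        out.append(c)
    # length-preserving-ish indels: at most one event per loop, and loops
    # stay inside the detectable 1..7 range
    if rng.random() < cfg.indel_rate:
        if len(out) > 1 and rng.random() < 0.5:
            out.pop(rng.integers(len(out)))
        elif len(out) < 7:
            pos = rng.integers(len(out) + 1)
            ins = [b for b in BASES if b != "G"][rng.integers(3)]
            out.insert(pos, ins)
    return "".join(out)


def simulate_family(
    template: Template, n: int, config: SimConfig, seed: int
) -> tuple[dict[str, str], Truth]:
    """n mutated copies of one template; mutations restricted to loops
    unless ``tract_mutation_rate`` > 0."""
    if len(template.tract_lengths) < 4:
        raise ValueError("template must have at least four tracts")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    for k in range(n):
        parts = []
        for i, t in enumerate(template.tract_lengths):
            tract = "G" * t
            if config.tract_mutation_rate > 0 and rng.random() < config.tract_mutation_rate:
                pos = rng.integers(t)
                b = BASES[rng.integers(3)]  # A, C or T erosion
                b = b if b != "G" else "T"
                tract = tract[:pos] + b + tract[pos + 1 :]
            parts.append(tract)
            if i < len(template.loops):
                parts.append(_mutate_loop(template.loops[i], config, rng))
        sid = f"m{k}"
        seqs[sid] = "".join(parts)
        labels[sid] = 0
    return seqs, Truth(labels=labels)


def simulate_families(
    config: SimConfig,
) -> tuple[dict[str, str], Truth, list[Template]]:
    """All families of the configured benchmark; ids are f<i>_m<j>."""
    templates = default_templates(config.n_families)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    for fi, tpl in enumerate(templates):
        fam_seqs, _ = simulate_family(
            tpl, config.members_per_family, config, seed=config.seed + 1000 + fi
        )
        for sid, s in fam_seqs.items():
            qid = f"f{fi}_{sid}"
            seqs[qid] = s
            labels[qid] = fi
    return seqs, Truth(labels=labels), templates


def simulate_genome(
    config: SimConfig, contig: str = "chrSim"
) -> tuple[dict[str, str], Truth, dict[str, str]]:
    """Background genome with planted family members on random strands.

    Returns (genome {contig: sequence}, truth with intervals, planted
    member sequences keyed by id).  Plants never overlap and are separated
    by at least 20 background bases so neighbouring plants cannot chain
    into one region.
    """
    seqs, truth, _ = simulate_families(config)
    rng = np.random.default_rng(config.seed + 7)
    total_plant = sum(len(s) for s in seqs.values())
    margin = 20
    need = total_plant + (len(seqs) + 1) * margin
    if config.background_length < need:
        raise ValueError(
            f"genome of {config.background_length} nt too short to host "
            f"{len(seqs)} plants ({need} nt needed)"
        )
    p_gc = config.gc_content
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    genome = list(rng.choice(list(BASES), size=config.background_length, p=probs))
    ids = sorted(seqs)
    slack = config.background_length - total_plant - (len(ids) + 1) * margin
    gaps = rng.multinomial(slack, np.ones(len(ids) + 1) / (len(ids) + 1))
    pos = 0
    intervals = []
    for gi, sid in enumerate(ids):
        pos += margin + int(gaps[gi])
        s = seqs[sid]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = s if strand == "+" else reverse_complement(s)
        genome[pos : pos + len(s)] = list(planted)
        intervals.append((contig, pos, pos + len(s), sid, strand))
        pos += len(s)
    truth.intervals = intervals
    return {contig: "".join(genome)}, truth, seqs


def evaluate_recovery(
    predicted: dict[str, int] | "object", truth: Truth
) -> dict:
    """Adjusted Rand index and per-family precision/recall.

    ``predicted`` is either a mapping seq_id -> cluster label or a
    FamilySet (whose family membership lists define the labels).  Only ids
    present in both partitions enter the ARI; coverage reports the
    fraction of truth ids that were assigned at all.
    """
    from sklearn.metrics import adjusted_rand_score

    if hasattr(predicted, "families"):
        mapping = {
            m: fi for fi, fam in enumerate(predicted.families) for m in fam.members
        }
    else:
        mapping = dict(predicted)
    common = sorted(set(mapping) & set(truth.labels))
    if not common:
        raise ValueError("no shared sequence ids between prediction and truth")
    pred = [mapping[i] for i in common]
    true = [truth.labels[i] for i in common]
    ari = float(adjusted_rand_score(true, pred))
    per_family: dict[int, dict[str, float]] = {}
    for fam in sorted(set(true)):
        fam_ids = {i for i in common if truth.labels[i] == fam}
        # best-matching predicted cluster
        counts: dict[int, int] = {}
        for i in fam_ids:
            counts[mapping[i]] = counts.get(mapping[i], 0) + 1
        best = max(counts, key=lambda c: counts[c])
        cluster_ids = {i for i in common if mapping[i] == best}
        tp = len(fam_ids & cluster_ids)
        per_family[fam] = {
            "precision": tp / len(cluster_ids),
            "recall": tp / len(fam_ids),
        }
    return {
        "ari": ari,
        "n_compared": len(common),
        "coverage": len(common) / len(truth.labels),
        "per_family": per_family,
        "n_predicted_clusters": len(set(pred)),
    }
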