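"""Model/Results interface over the family-discovery pipeline.

`G4FamilyModel` holds a collection of putative G4 sequences plus the run
configuration; `fit()` executes initial clustering (Levenshtein spheres,
then similarity + hierarchical clustering of the leftovers), the iterative
profile-HMM refinement, and returns a `G4FamilyResults` carrying the
accepted families, their diagnostics (gap scores, membership weights,
distinctness), a classifier, and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import cluster_pipeline
from .config import RunConfig
from .detect import DetectionParams, detect_regions
from .family import FamilySet, classify as _classify, refine
from .msa import filter_clusters
from .phmm import NullModel
from .simulate import Truth, evaluate_recovery
from .thermo import ensemble

__all__ = ["G4FamilyModel", "G4FamilyResults"]


class G4FamilyModel:
    """Family-discovery model over a set of putative G4 sequences.

    Parameters
    ----------
    sequences
        Mapping of sequence id to DNA sequence (A/C/G/T).  Use
        :meth:`from_fasta` or :meth:`from_genome` to build from files or
        raw genomic DNA.
    config
        Full run configuration; defaults are the documented operating
        points of the refinement loop.
    """

    def __init__(self, sequences: dict[str, str], config: RunConfig | None = None):
        if not sequences:
            raise ValueError("model needs at least one sequence")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.config = config or RunConfig()
        self.null = NullModel()

    @classmethod
    def from_fasta(cls, path, config: RunConfig | None = None) -> "G4FamilyModel":
        from .io import read_fasta

        return cls(read_fasta(path), config)

    @classmethod
    def from_genome(
        cls,
        contigs: dict[str, str],
        config: RunConfig | None = None,
        params: DetectionParams | None = None,
    ) -> "G4FamilyModel":
        """Detect G4 regions in genomic DNA and model their sequences."""
        config = config or RunConfig()
        params = params or config.detection
        seqs: dict[str, str] = {}
        for contig, seq in contigs.items():
            for region in detect_regions(seq, params, contig=contig):
                seqs[region.region_id] = region.sequence
        if not seqs:
            raise ValueError("no G4 regions detected in the input contigs")
        return cls(seqs, config)

    def fit(self, progress: bool = False) -> "G4FamilyResults":
        """Cluster, refine and accept families; deterministic given config."""
        cfg = self.config
        clusters = cluster_pipeline(
            self.sequences, cfg.sphere, cfg.similarity
        )
        clusters = filter_clusters(clusters, cfg.refinement.min_size)
        family_set = refine(
            clusters, self.sequences, cfg.refinement, self.null
        )
        return G4FamilyResults(
            model=self,
            family_set=family_set,
            initial_clusters=clusters,
        )


@dataclass
class G4FamilyResults:
    """Fitted family set with diagnostics and a classifier."""

    model: G4FamilyModel
    family_set: FamilySet
    initial_clusters: list[list[str]] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.family_set)

    def classify(self, seq: str, seq_id: str = "query"):
        """Akaike-weight classification of a query against the families."""
        return _classify(seq, self.family_set, seq_id)

    def labels(self) -> dict[str, int]:
        """Family membership as integer labels keyed by sequence id."""
        return {
            m: fi
            for fi, fam in enumerate(self.family_set.families)
            for m in fam.members
        }

    def classify_all(self, seqs: dict[str, str] | None = None) -> dict[str, int]:
        """Assign every sequence (default: the model's) to its best family."""
        seqs = seqs or self.model.sequences
        order = {f.id: i for i, f in enumerate(
            sorted(self.family_set.families, key=lambda f: f.id))}
        return {
            sid: order[self.classify(s, sid).best_family] for sid, s in seqs.items()
        }

    def score(self, truth: Truth) -> dict:
        """Recovery metrics (ARI, precision/recall) against planted truth."""
        return evaluate_recovery(self.family_set, truth)

    def summary(self) -> pd.DataFrame:
        """One row per family: size, consensus, gap score, thermodynamics."""
        rows = []
        for fam in self.family_set.families:
            ens = ensemble(fam.consensus)
            rows.append(
                {
                    "family": fam.id,
                    "n_members": len(fam.members),
                    "model_length": fam.hmm.m,
                    "gap_score": round(fam.gap_score, 4),
                    "consensus": fam.consensus,
                    "mfe_kcal_mol": (
                        round(ens.mfe, 2) if ens.n_placements else np.nan
                    ),
                    "ensemble_fe_kcal_mol": (
                        round(ens.ensemble_free_energy, 2)
                        if ens.n_placements else np.nan
                    ),
                    "mfe_frequency_pct": round(ens.mfe_frequency, 2),
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        return (
            f"<G4FamilyResults: {self.n_families} families from "
            f"{len(self.model.sequences)} sequences>"
        )
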