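"""Restricted quadruplex thermodynamics.

The structure space is every placement of four equal-length guanine
sub-tracts (the stacked layers) joined by 1-7 nt linkers, plus the open
chain at zero energy.  A placement with L layers and total linker length
ltot gets

    E = alpha * (L - 1) + trunc(beta * ln(ltot - 2))

with the stabilising stack-step term alpha = -18.00 kcal/mol and linker
penalty scale beta = 12.0 kcal/mol; the linker term is truncated toward
zero at the 0.01 kcal/mol energy resolution (so ltot = 3 contributes
exactly 0).  Boltzmann statistics at 37 C (RT = 0.61633 kcal/mol) over
this restricted ensemble give the ensemble free energy, the MFE-structure
frequency and the ensemble diversity.  Competing canonical base pairing is
outside the model, so these quantities describe sequences whose ensemble
is quadruplex-dominated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnergyModel",
    "Placement",
    "EnsembleSummary",
    "enumerate_placements",
    "energy",
    "mfe",
    "ensemble",
    "dot_bracket",
]


@dataclass(frozen=True)
class EnergyModel:
    """Quadruplex layer/linker energy parameters (kcal/mol)."""

    alpha: float = -18.00
    beta: float = 12.0
    resolution: float = 0.01
    rt: float = 0.61633  # 37 C
    min_layers: int = 2
    max_layers: int | None = None
    linker_min: int = 1
    linker_max: int = 7

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("alpha must be negative (stabilising)")
        if self.beta <= 0 or self.resolution <= 0 or self.rt <= 0:
            raise ValueError("beta, resolution and rt must be positive")
        if self.min_layers < 2:
            raise ValueError("min_layers must be >= 2")
        if not (1 <= self.linker_min <= self.linker_max):
            raise ValueError("invalid linker range")


@dataclass(frozen=True)
class Placement:
    """Four equal-length G sub-tracts with their linkers and energy."""

    tracts: tuple[tuple[int, int], ...]  # four (start, end) half-open
    layers: int
    linkers: tuple[int, int, int]
    energy: float

    @property
    def ltot(self) -> int:
        return sum(self.linkers)

    def positions(self) -> frozenset[int]:
        """Quadruplex-involved (tetrad) positions."""
        return frozenset(p for s, e in self.tracts for p in range(s, e))


@dataclass(frozen=True)
class EnsembleSummary:
    mfe: float
    mfe_placement: Placement | None
    ensemble_free_energy: float
    mfe_frequency: float  # percent
    diversity: float
    n_placements: int


def energy(layers: int, ltot: int, model: EnergyModel | None = None) -> float:
    """Placement energy with the linker term truncated toward zero."""
    model = model or EnergyModel()
    if ltot < 3:
        raise ValueError("total linker length must be >= 3")
    raw = model.beta * math.log(ltot - 2)
    steps = int(raw / model.resolution)  # truncation toward zero
    return model.alpha * (layers - 1) + steps * model.resolution


def _g_windows(seq: str, L: int) -> list[int]:
    """Start offsets of all length-L all-G windows (IUPAC codes are loops)."""
    return [
        i for i in range(len(seq) - L + 1)
        if all(c == "G" for c in seq[i : i + L])
    ]


def enumerate_placements(
    seq: str, model: EnergyModel | None = None
) -> list[Placement]:
    """Every 4-sub-tract placement with in-range linkers, deduplicated.

    Gaps are stripped and the sequence upper-cased first; ambiguity codes
    count as loop bases, never as G.
    """
    model = model or EnergyModel()
    seq = seq.replace("-", "").upper()
    max_run = 0
    run = 0
    for c in seq:
        run = run + 1 if c == "G" else 0
        max_run = max(max_run, run)
    top = max_run if model.max_layers is None else min(max_run, model.max_layers)
    placements: list[Placement] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    for L in range(model.min_layers, top + 1):
        windows = _g_windows(seq, L)

        def _extend(chosen: list[int]) -> None:
            if len(chosen) == 4:
                tracts = tuple((s, s + L) for s in chosen)
                if tracts in seen:
                    return
                seen.add(tracts)
                linkers = tuple(
                    chosen[k + 1] - (chosen[k] + L) for k in range(3)
                )
                placements.append(
                    Placement(
                        tracts=tracts,
                        layers=L,
                        linkers=linkers,  # type: ignore[arg-type]
                        energy=energy(L, sum(linkers), model),
                    )
                )
                return
            last_end = chosen[-1] + L
            for s in windows:
                link = s - last_end
                if link < model.linker_min:
                    continue
                if link > model.linker_max:
                    break
                _extend(chosen + [s])

        for s0 in windows:
            _extend([s0])
    return placements


def mfe(
    seq: str, model: EnergyModel | None = None
) -> tuple[float | None, Placement | None]:
    """Minimum-energy placement; ties break leftmost then most compact.

    Returns (None, None) when the sequence admits no quadruplex.
    """
    model = model or EnergyModel()
    placements = enumerate_placements(seq, model)
    if not placements:
        return None, None
    best = min(
        placements,
        key=lambda p: (p.energy, p.tracts[0][0], p.tracts[3][1] - p.tracts[0][0]),
    )
    return best.energy, best


def ensemble(seq: str, model: EnergyModel | None = None) -> EnsembleSummary:
    """Boltzmann summary of the restricted ensemble (placements + open chain)."""
    model = model or EnergyModel()
    placements = enumerate_placements(seq, model)
    if not placements:
        return EnsembleSummary(
            mfe=0.0,
            mfe_placement=None,
            ensemble_free_energy=0.0,
            mfe_frequency=100.0,
            diversity=0.0,
            n_placements=0,
        )
    e_mfe, best = mfe(seq, model)
    energies = [p.energy for p in placements]
    # factor out the MFE for numerical stability
    zs = [math.exp(-(e - e_mfe) / model.rt) for e in energies]
    z_open = math.exp(e_mfe / model.rt)  # open chain, E = 0
    z = z_open + sum(zs)
    efe = e_mfe - model.rt * math.log(z)
    freq = 100.0 * math.exp(0.0) / z  # MFE placement term is exp(0)
    probs = [w / z for w in zs]
    p_open = z_open / z
    states = [p.positions() for p in placements] + [frozenset()]
    pr = probs + [p_open]
    diversity = 0.0
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            d = len(states[i] ^ states[j])
            diversity += 2.0 * pr[i] * pr[j] * d
    return EnsembleSummary(
        mfe=e_mfe,
        mfe_placement=best,
        ensemble_free_energy=efe,
        mfe_frequency=freq,
        diversity=diversity,
        n_placements=len(placements),
    )


def dot_bracket(placement: Placement | None, seq_len: int) -> str:
    """Quadruplex dot-bracket: '+' on tetrad guanines, '.' elsewhere."""
    marks = ["."] * seq_len
    if placement is not None:
        for p in placement.positions():
            marks[p] = "+"
    return "".join(marks)
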