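"""Putative G-quadruplex detection by guanine-tract chaining.

A canonical intramolecular G4 is four runs ("tracts") of at least three
guanines separated by loops of 1-7 nucleotides.  Detection here works by
finding maximal G-tracts and chaining consecutive tracts whose gaps fall
inside the loop bounds, rather than by a literal regex: chaining makes the
"total" vs "non-overlapping" placement counts well defined for regions with
more than four tracts.

Coordinates are 0-based half-open on the plus strand throughout.  Regions
found on the minus strand carry the plus-strand (C-rich) interval; the
G-rich scanned-strand sequence is stored on the region and is what flows
into clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "DetectionParams",
    "GTract",
    "G4Region",
    "G4Match",
    "find_g_tracts",
    "detect_regions",
    "enumerate_matches",
    "count_summary",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYKMSWBDHVNacgtrykmswbdhvn",
    "TGCAYRMKSWVHDBNtgcayrmkswvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the G4 search pattern GxN(1-7) GxN(1-7) GxN(1-7) Gx.

    ``min_tract_len`` is the minimum guanine-run length x (3 for canonical
    G4s; two-tetrad scanning is available by setting 2 but off by default
    because of its elevated false-positive rate).  ``loop_min``/``loop_max``
    bound the inter-tract loop length, and ``min_tracts`` the number of
    tracts required to report a region.
    """

    min_tract_len: int = 3
    loop_min: int = 1
    loop_max: int = 7
    min_tracts: int = 4
    strands: str = "both"

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("need 1 <= loop_min <= loop_max")
        if self.min_tracts < 4:
            raise ValueError("min_tracts must be >= 4 for canonical G4s")
        if self.strands not in ("plus", "minus", "both"):
            raise ValueError("strands must be plus, minus or both")


@dataclass(frozen=True)
class GTract:
    """A maximal run of guanines on the scanned strand."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class G4Match:
    """One concrete 4-tract placement within a region."""

    tract_indices: tuple[int, int, int, int]
    loops: tuple[int, int, int]
    start: int  # within-region offsets, half-open
    end: int


@dataclass
class G4Region:
    """A maximal chain of >= min_tracts G-tracts with in-bound loops.

    ``start``/``end`` are plus-strand half-open coordinates; ``sequence``
    is the scanned-strand (G-rich) sequence, so for minus-strand regions it
    is the reverse complement of the plus-strand slice.
    """

    contig: str
    start: int
    end: int
    strand: str
    tracts: list[GTract] = field(default_factory=list)
    sequence: str = ""

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    @property
    def region_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def find_g_tracts(seq: str, params: DetectionParams | None = None) -> list[GTract]:
    """All maximal runs of G with length >= min_tract_len, ascending.

    Ambiguity codes (including N) never count as G.
    """
    params = params or DetectionParams()
    seq = seq.upper()
    tracts: list[GTract] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= params.min_tract_len:
                tracts.append(GTract(i, j - i))
            i = j
        else:
            i += 1
    return tracts


def _chain_tracts(
    tracts: list[GTract], params: DetectionParams
) -> Iterator[list[GTract]]:
    """Split the tract list into maximal chains with in-bound gaps."""
    chain: list[GTract] = []
    for tract in tracts:
        if chain:
            gap = tract.start - chain[-1].end
            if not (params.loop_min <= gap <= params.loop_max):
                if len(chain) >= params.min_tracts:
                    yield chain
                chain = []
        chain.append(tract)
    if len(chain) >= params.min_tracts:
        yield chain


def _scan_strand(
    seq: str, contig: str, strand: str, params: DetectionParams
) -> list[G4Region]:
    n = len(seq)
    regions = []
    for chain in _chain_tracts(find_g_tracts(seq, params), params):
        s, e = chain[0].start, chain[-1].end
        if strand == "+":
            start, end = s, e
        else:
            # mirror the scanned-strand interval onto the plus strand
            start, end = n - e, n - s
        tracts = [GTract(t.start - s, t.length) for t in chain]
        regions.append(
            G4Region(
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                tracts=tracts,
                sequence=seq[s:e],
            )
        )
    return regions


def detect_regions(
    seq: str,
    params: DetectionParams | None = None,
    contig: str = "seq",
) -> list[G4Region]:
    """Maximal G4 regions on the requested strands, sorted by plus-strand start.

    Tract coordinates inside each region are offsets into ``region.sequence``
    (the scanned strand).
    """
    params = params or DetectionParams()
    seq = seq.upper()
    regions: list[G4Region] = []
    if params.strands in ("plus", "both"):
        regions.extend(_scan_strand(seq, contig, "+", params))
    if params.strands in ("minus", "both"):
        regions.extend(_scan_strand(reverse_complement(seq), contig, "-", params))
    regions.sort(key=lambda r: (r.start, r.end, r.strand))
    return regions


def enumerate_matches(
    region: G4Region,
    params: DetectionParams | None = None,
    extended: bool = False,
) -> list[G4Match]:
    """All 4-tract placements within a region.

    The canonical set (used for counting) is every window of 4 consecutive
    tracts.  With ``extended=True``, non-consecutive tract subsets whose
    implied loops stay within ``loop_max`` are also emitted.
    """
    params = params or DetectionParams()
    tracts = region.tracts
    k = len(tracts)
    matches: list[G4Match] = []

    def _make(idx: tuple[int, int, int, int]) -> G4Match | None:
        loops = tuple(
            tracts[idx[j + 1]].start - tracts[idx[j]].end for j in range(3)
        )
        if any(not (params.loop_min <= lp <= params.loop_max) for lp in loops):
            return None
        return G4Match(
            tract_indices=idx,
            loops=loops,  # type: ignore[arg-type]
            start=tracts[idx[0]].start,
            end=tracts[idx[3]].end,
        )

    for i in range(k - 3):
        m = _make((i, i + 1, i + 2, i + 3))
        if m is not None:
            matches.append(m)
    if extended:
        from itertools import combinations

        seen = {m.tract_indices for m in matches}
        for idx in combinations(range(k), 4):
            if idx in seen:
                continue
            m = _make(idx)  # implied loops bridge skipped tracts
            if m is not None:
                matches.append(m)
    return matches


def count_summary(region: G4Region) -> tuple[int, int, int]:
    """(n_tracts, total placements, non-overlapping placements).

    Total counts consecutive 4-tract windows (n_tracts - 3); the
    non-overlapping count is the maximum number of disjoint windows,
    attained by greedy left-to-right selection (floor(n_tracts / 4)).
    """
    matches = enumerate_matches(region)
    total = len(matches)
    non_overlap = 0
    next_free = -1
    for m in matches:
        if m.tract_indices[0] > next_free:
            non_overlap += 1
            next_free = m.tract_indices[3]
    return (region.n_tracts, total, non_overlap)
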