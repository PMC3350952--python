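"""Chromodomain extraction, CHD_I/CHD_II classification and clade motifs.

Retrotransposon chromodomains fall into two groups defined by the aromatic
cage of classical chromodomains (dmHP1 numbering Y24/W45/Y48):

* ``CHD_I``  - classical-like, Y24 and W45 present;
* ``CHD_II`` - Y24 lost (and usually Y48), W45 retained;
* ``unclassified`` - W45 absent.

Peptides are anchored to this frame by the best chromo-box placement
(consensus (Y/f)-(L/F/Y)-(L/I/V)-K-(W/y)-(k/r)-g; capitals prominent,
lower case minor): alignment position 1 is the first chromo-box residue,
and the W45/Y48 homologue slots sit at alignment positions 28 and 31
(configurable anchor offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domains import CHD_ANCHOR_OFFSETS

PROMINENT = 1.0
MINOR = 0.5
AROMATIC_Y = frozenset("YF")


@dataclass(frozen=True)
class MotifPattern:
    """Weighted-consensus motif: per position a residue->weight map."""

    name: str
    positions: tuple  # tuple of dicts residue -> weight
    min_score: float

    def __post_init__(self):
        mx = self.max_score
        if self.min_score > mx:
            raise ValueError("min_score exceeds maximal score")
        if not any(PROMINENT in pos.values() for pos in self.positions
                   if pos):
            raise ValueError("pattern needs at least one prominent position")

    @property
    def max_score(self) -> float:
        return sum(max(pos.values(), default=0.0) for pos in self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def _pat(name, spec, frac=0.7):
    positions = tuple(spec)
    mx = sum(max(p.values(), default=0.0) for p in positions)
    return MotifPattern(name, positions, min_score=frac * mx)


CHROMO_BOX = _pat("chromo_box", [
    {"Y": PROMINENT, "F": MINOR},
    {"L": PROMINENT, "F": PROMINENT, "Y": PROMINENT},
    {"L": PROMINENT, "I": PROMINENT, "V": PROMINENT},
    {"K": PROMINENT},
    {"W": PROMINENT, "Y": MINOR},
    {"K": MINOR, "R": MINOR},
    {"G": MINOR},
])

GALADRIEL_BOX = _pat("galadriel_box", [
    {"Y": PROMINENT, "F": MINOR},
    {"L": PROMINENT, "Y": PROMINENT},
    {"I": PROMINENT, "V": PROMINENT},
    {"K": MINOR},
    {"W": PROMINENT},
    {"K": MINOR},
    {"G": MINOR},
])

TEKAY_KXLRXK = _pat("tekay_KxLRxK", [
    {"K": PROMINENT, "R": PROMINENT},
    {},
    {"L": PROMINENT, "T": PROMINENT},
    {"R": PROMINENT},
    {},
    {"K": MINOR, "R": MINOR},
])

TEKAY_EEXTWEXE = _pat("tekay_EExTWExE", [
    {"E": PROMINENT}, {"E": PROMINENT}, {}, {"T": PROMINENT},
    {"W": PROMINENT}, {"E": PROMINENT}, {}, {"E": PROMINENT},
])

CLADE_PATTERNS = (CHROMO_BOX, GALADRIEL_BOX, TEKAY_KXLRXK, TEKAY_EEXTWEXE)


def motif_scan(peptide: str, pattern: MotifPattern):
    """Best ungapped placement of a weighted-consensus motif.

    Returns ``(offset, score)`` for the best placement with score >=
    ``pattern.min_score``, else ``None``. Ties go to the smallest offset.
    """
    best = _scan_unthresholded(peptide, pattern)
    if best is None or best[1] < pattern.min_score:
        return None
    return best


def _scan_unthresholded(peptide: str, pattern: MotifPattern):
    n, m = len(peptide), len(pattern)
    if n < m:
        return None
    best = None
    for off in range(n - m + 1):
        score = sum(pos.get(peptide[off + k], 0.0)
                    for k, pos in enumerate(pattern.positions))
        if best is None or score > best[1]:
            best = (off, score)
    return best


@dataclass
class ChromodomainCall:
    """One scored chromodomain window with anchored residue flags."""

    source_id: str
    peptide: str
    window_start: int      # offset of the window in the polyprotein
    anchor: int            # chromo-box offset inside the window
    score: float
    y24: bool
    w45: bool
    y48: bool
    group: str = field(init=False)
    motif_hits: set = field(default_factory=set)

    def __post_init__(self):
        self.group = classify_flags(self.y24, self.w45, self.y48)


def classify_flags(y24: bool, w45: bool, y48: bool) -> str:
    """Total classification rule over the three aromatic-cage flags."""
    del y48  # recorded as evidence, never decisive
    if not w45:
        return "unclassified"
    return "CHD_I" if y24 else "CHD_II"


def classify_chd(call: ChromodomainCall) -> str:
    return classify_flags(call.y24, call.w45, call.y48)


def extract_chd(polyprotein: str, int_end_hint: int | None = None,
                window_sizes=(50, 70), tail: int = 150,
                anchor_offsets=CHD_ANCHOR_OFFSETS, source_id: str = "query"):
    """Best chromodomain window C-terminal of the integrase.

    Scans 50-70 aa sliding windows downstream of ``int_end_hint`` (or in
    the last ``tail`` residues when no hint is given), scores each window
    by its best chromo-box placement, and returns the anchored
    :class:`ChromodomainCall` for the best window - or ``None`` when no
    window scores above zero.
    """
    if len(polyprotein) < 1:
        return None
    if int_end_hint is None:
        region_start = max(0, len(polyprotein) - tail)
    else:
        region_start = max(0, int_end_hint)
    region = polyprotein[region_start:]
    lo, hi = window_sizes
    best = None  # (score, anchor_fits, -start, size, start, anchor)
    for start in range(0, max(1, len(region) - lo + 1)):
        for size in range(lo, hi + 1):
            window = region[start:start + size]
            if len(window) < lo and len(window) < len(region):
                continue
            hit = _scan_unthresholded(window, CHROMO_BOX)
            if hit is None or hit[1] <= 0:
                continue
            anchor, score = hit
            fits = anchor + max(anchor_offsets) < len(window)
            key = (score, fits, -start, size)
            if best is None or key > best[0]:
                best = (key, start, size, anchor, score)
            if len(window) < size:
                break
    if best is None:
        return None
    _key, start, size, anchor, score = best
    window = region[start:start + size]
    o1, o2, o3 = anchor_offsets
    res = lambda off: window[anchor + off] if anchor + off < len(window) else ""
    call = ChromodomainCall(
        source_id=source_id, peptide=window,
        window_start=region_start + start, anchor=anchor, score=score,
        y24=res(o1) in AROMATIC_Y,
        w45=res(o2) == "W",
        y48=res(o3) in AROMATIC_Y)
    call.motif_hits = detect_clade_motifs(window)
    return call


def detect_clade_motifs(peptide: str) -> set:
    """Independent motif detectors for clade-characteristic CHD motifs."""
    hits = set()
    for pattern in CLADE_PATTERNS:
        if motif_scan(peptide, pattern) is not None:
            hits.add(pattern.name)
    if "TWE" in peptide:
        hits.add("twe_core")
    return hits
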