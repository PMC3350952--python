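"""De-novo structural annotation of LTR retroelements.

The criteria mirror how intact chromoviruses are recognised: a pair of
direct long terminal repeats with TG...CA inverted termini, a 4-6 bp
target-site duplication on the immediate flanks, a primer binding site
complementary to a tRNA-Met 3' end just after the 5'LTR, a polypurine
tract immediately before the 3'LTR, and a single Gag-Pol ORF whose
domains appear in the canonical CCHC < PR < RT < RNH < INT < CHD order.

Identity is defined throughout as matches / alignment length (gaps count
against), from a global alignment with match +1, mismatch -1, gap open
-2, gap extend -0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from . import chd as chdmod
from . import domains
from .genetics import revcomp, standard_code
from .domains import SYNTHETIC_TRNA_MET_3END

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")

IDENTITY_DEFINITION = ("identity = matches / alignment length (global "
                       "alignment, match +1, mismatch -1, gap open -2, "
                       "gap extend -0.5)")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -0.5
    return a


_ALIGNER = _aligner()


def global_identity(a: str, b: str) -> float:
    """Percent identity under the package-wide definition (docstring)."""
    if a == b:
        return 100.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total


# ---------------------------------------------------------------------------
# LTR pair search
# ---------------------------------------------------------------------------

@dataclass
class LtrCandidate:
    ltr5: tuple
    ltr3: tuple
    identity: float

    @property
    def span(self) -> tuple:
        return self.ltr5[0], self.ltr3[1]


def find_ltr_pairs(seq: str, min_len: int = 100, max_len: int = 1500,
                   min_identity: float = 80.0, max_interior: int = 10000,
                   k: int = 20) -> list[LtrCandidate]:
    """Direct-repeat pairs in the LTR length/identity window.

    Seed-and-extend: exact k-mer anchors at a common diagonal offset are
    chained, extended outwards under a mismatch-streak stop rule, and the
    boundaries snapped to the best-supported position carrying TG / CA
    termini in both copies. Candidates are non-overlapping, ranked by
    identity then length.
    """
    seq = seq.upper()
    cands = _find_ltr_pairs_k(seq, min_len, max_len, min_identity,
                              max_interior, k)
    if not cands and len(seq) < 20000 and k > 12:
        cands = _find_ltr_pairs_k(seq, min_len, max_len, min_identity,
                                  max_interior, 12)
    cands.sort(key=lambda c: (-c.identity, c.ltr5[0] - c.ltr5[1],
                              c.ltr5[0]))
    kept: list[LtrCandidate] = []
    for c in cands:
        s, e = c.span
        if all(e <= o.span[0] or s >= o.span[1] for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: (-c.identity, c.ltr5[0] - c.ltr5[1]))
    return kept


def _find_ltr_pairs_k(seq, min_len, max_len, min_identity, max_interior, k):
    n = len(seq)
    if n < 2 * min_len:
        return []
    index: dict = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    diagonals: dict = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 50:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if min_len <= d <= max_len + max_interior:
                    diagonals.setdefault(d, []).append(positions[ai])
    out = []
    for d, starts in diagonals.items():
        starts.sort()
        run = [starts[0]]
        for p in starts[1:] + [starts[-1] + 10 ** 9]:
            if p - run[-1] <= 100:
                run.append(p)
            else:
                cand = _extend_and_snap(seq, run[0], run[-1] + k, d,
                                        min_len, max_len, max_interior,
                                        min_identity)
                if cand:
                    out.append(cand)
                run = [p]
    return out


def _matches(seq, i, d, lo, hi):
    """Copy-vs-copy match count over left-copy positions [lo, hi)."""
    lo = max(lo, 0)
    hi = min(hi, len(seq) - d)
    return sum(seq[p] == seq[p + d] for p in range(lo, hi))


def _extend_and_snap(seq, s, e, d, min_len, max_len, max_interior,
                     min_identity):
    n = len(seq)
    # extend left
    i, streak, last = s - 1, 0, s
    while i >= 0 and i + d < n and streak < 4:
        if seq[i] == seq[i + d]:
            last, streak = i, 0
        else:
            streak += 1
        i -= 1
    rough_start = last
    # extend right (positions inside the left copy)
    i, streak, last = e, 0, e
    while i + d < n and i < s + d and streak < 4:
        if seq[i] == seq[i + d]:
            last, streak = i + 1, 0
        else:
            streak += 1
        i += 1
    rough_end = last

    start = _snap_boundary(seq, d, rough_start, "TG", left=True)
    end = _snap_boundary(seq, d, rough_end, "CA", left=False)
    # refine with target-site-duplication consistency: integration leaves
    # identical 4-6 bp host repeats immediately flanking the element, so a
    # boundary pair supported by a TSD outranks one supported by chance
    # copy-vs-copy matching alone
    for _ in range(2):
        end = _snap_boundary(seq, d, rough_end, "CA", left=False,
                             tsd_anchor=("end", start))
        start = _snap_boundary(seq, d, rough_start, "TG", left=True,
                               tsd_anchor=("start", end + d))
    length = end - start
    if not (min_len <= length <= max_len):
        return None
    if length > d:  # overlapping copies
        return None
    if d - length > max_interior:
        return None
    a, b = seq[start:end], seq[start + d:end + d]
    identity = global_identity(a, b)
    if identity < min_identity:
        return None
    return LtrCandidate((start, end), (start + d, end + d), identity)


def _tsd_len(seq, s, e, lo=4, hi=6):
    """Longest 4-6 bp exact host repeat flanking a prospective element."""
    for L in range(hi, lo - 1, -1):
        if s >= L and e + L <= len(seq) and seq[s - L:s] == seq[e:e + L]:
            return L
    return 0


def _snap_boundary(seq, d, rough, motif, left, window=120, flank=20,
                   tsd_anchor=None):
    """Snap to the highest-scoring position where both repeat copies carry
    the terminal motif; score favours matching inside, mismatching outside,
    plus a bonus for target-site-duplication consistency when the opposite
    element boundary is provided via ``tsd_anchor``."""
    n = len(seq)
    best = None
    for pos in range(rough - window, rough + window + 1):
        if left:
            if pos < 0 or pos + d + 2 > n:
                continue
            if seq[pos:pos + 2] != motif or seq[pos + d:pos + d + 2] != motif:
                continue
            score = (_matches(seq, pos, d, pos, pos + flank)
                     - _matches(seq, pos, d, pos - flank, pos))
            if tsd_anchor is not None:
                score += 2 * _tsd_len(seq, pos, tsd_anchor[1])
            key = (score, -pos)
        else:
            if pos - 2 < 0 or pos + d > n:
                continue
            if (seq[pos - 2:pos] != motif
                    or seq[pos - 2 + d:pos + d] != motif):
                continue
            score = (_matches(seq, pos, d, pos - flank, pos)
                     - _matches(seq, pos, d, pos, pos + flank))
            if tsd_anchor is not None:
                score += 2 * _tsd_len(seq, tsd_anchor[1], pos + d)
            key = (score, pos)
        if best is None or key > best[0]:
            best = (key, pos)
    return best[1] if best else rough


# ---------------------------------------------------------------------------
# structural features
# ---------------------------------------------------------------------------

def check_itr(ltr_seq: str) -> bool:
    """Short inverted terminal repeat: sequence starts TG and ends CA."""
    if len(ltr_seq) < 4:
        raise ValueError("LTR shorter than 4 bp")
    s = ltr_seq.upper()
    return s.startswith("TG") and s.endswith("CA")


def detect_tsd(seq: str, element: tuple, len_range=(4, 6)) -> str | None:
    """Target-site duplication on the immediate flanks of the element.

    The TSD is by definition adjacent to the element, so the check is the
    longest L in the range for which the L-bp suffix of the 5' flank
    equals the L-bp prefix of the 3' flank (longest wins).
    """
    start, end = element
    lo, hi = len_range
    if start < hi or end + hi > len(seq):
        raise ValueError("need at least %d bp of flank on both sides" % hi)
    for L in range(hi, lo - 1, -1):
        left = seq[start - L:start]
        if left == seq[end:end + L]:
            return left
    return None


@dataclass
class PbsHit:
    start: int
    end: int
    trna_id: str
    length: int
    spacer: int


def find_pbs(seq: str, ltr5_end: int, trna_3ends: dict | None = None,
             min_len: int = 11, max_spacer: int = 2) -> PbsHit | None:
    """Primer binding site: longest reverse-complement match to a tRNA 3'
    end starting at most ``max_spacer`` bases after the 5'LTR."""
    if trna_3ends is None:
        trna_3ends = {"tRNA-Met": SYNTHETIC_TRNA_MET_3END}
    if not trna_3ends:
        raise ValueError("tRNA 3'-end library is empty")
    best = None
    for trna_id, trna in trna_3ends.items():
        trna = trna.upper()
        for spacer in range(max_spacer + 1):
            pos = ltr5_end + spacer
            for L in range(min(len(trna), len(seq) - pos), min_len - 1, -1):
                if seq[pos:pos + L] == revcomp(trna[-L:]):
                    key = (L, -spacer)
                    if best is None or key > best[0]:
                        best = (key, PbsHit(pos, pos + L, trna_id, L, spacer))
                    break
    return best[1] if best else None


@dataclass
class PptHit:
    start: int
    end: int
    length: int


def find_ppt(seq: str, ltr3_start: int, min_len: int = 12,
             max_gap: int = 2) -> PptHit | None:
    """Polypurine tract: longest A/G run of length >= min_len ending at
    most ``max_gap`` bases before the 3'LTR."""
    if ltr3_start < min_len:
        return None
    best = None
    for gap in range(max_gap + 1):
        end = ltr3_start - gap
        i = end
        while i > 0 and seq[i - 1] in PURINES:
            i -= 1
        run = end - i
        if run >= min_len:
            key = (run, -gap)
            if best is None or key > best[0]:
                best = (key, PptHit(i, end, run))
    return best[1] if best else None


@dataclass
class OrfHit:
    start: int
    end: int          # includes the stop codon when present
    frame: int        # +1..+3 forward, -1..-3 reverse
    n_internal_stops: int = 0


def find_orfs(seq: str, min_len_nt: int = 300,
              both_strands: bool = True) -> list[OrfHit]:
    """ATG-to-stop spans of at least ``min_len_nt`` on both strands."""
    seq = seq.upper()
    code = standard_code()
    out = []
    strands = [(seq, 1)]
    if both_strands:
        strands.append((revcomp(seq), -1))
    for s, sign in strands:
        n = len(s)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if code.is_stop(codon):
                    if start is not None and i + 3 - start >= min_len_nt:
                        out.append(_orf_hit(start, i + 3, frame, sign, n))
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
    out.sort(key=lambda o: (o.start, o.end))
    return out


def _orf_hit(start, end, frame, sign, n):
    if sign == 1:
        return OrfHit(start, end, frame + 1)
    return OrfHit(n - end, n - start, -(frame + 1))


def reconstruct_pseudo_orf(seq: str, frame: int = 0):
    """Translate through in-frame stops, recording their positions.

    Returns ``(peptide with '*' marks, list of stop positions in aa
    coordinates)``. Frameshifts are not repaired; the region from
    ``frame`` must be an exact codon multiple.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    region = seq.upper()[frame:]
    if len(region) % 3 or not region:
        raise ValueError("sequence is out of frame: length from offset "
                         f"{frame} is not a codon multiple")
    code = standard_code()
    peptide = code.translate(region)
    if peptide.endswith("*"):
        peptide_core = peptide[:-1]
    else:
        peptide_core = peptide
    stops = [i for i, aa in enumerate(peptide_core) if aa == "*"]
    return peptide, stops


def check_domain_order(detected_domains) -> tuple[bool, str]:
    """True iff the labels form a subsequence of the canonical order."""
    canon = list(domains.CANONICAL_DOMAIN_ORDER)
    report = " < ".join(canon)
    pos = -1
    for dom in detected_domains:
        if dom not in canon:
            return False, report
        p = canon.index(dom)
        if p <= pos:
            return False, report
        pos = p
    return True, report


# ---------------------------------------------------------------------------
# whole-element annotation
# ---------------------------------------------------------------------------

@dataclass
class ElementAnnotation:
    seq_id: str
    start: int
    end: int
    ltr5: tuple
    ltr3: tuple
    ltr_identity: float
    itr_ok: bool
    tsd: str | None = None
    pbs: PbsHit | None = None
    ppt: PptHit | None = None
    orfs: list = field(default_factory=list)
    domain_order: list = field(default_factory=list)
    chd: chdmod.ChromodomainCall | None = None
    intact: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start


def annotate_element(seq: str, cand: LtrCandidate,
                     seq_id: str = "seq",
                     trna_3ends: dict | None = None) -> ElementAnnotation:
    start, end = cand.span
    ltr5_seq = seq[cand.ltr5[0]:cand.ltr5[1]]
    ltr3_seq = seq[cand.ltr3[0]:cand.ltr3[1]]
    itr_ok = check_itr(ltr5_seq) and check_itr(ltr3_seq)
    hi = 6
    tsd = None
    if start >= hi and end + hi <= len(seq):
        tsd = detect_tsd(seq, (start, end))
    pbs = find_pbs(seq, cand.ltr5[1], trna_3ends)
    ppt = find_ppt(seq, cand.ltr3[0])
    interior = seq[cand.ltr5[1]:cand.ltr3[0]]
    orfs = [OrfHit(o.start + cand.ltr5[1], o.end + cand.ltr5[1], o.frame,
                   o.n_internal_stops)
            for o in find_orfs(interior, both_strands=False)]
    domain_order, chd_call = [], None
    if orfs:
        main = max(orfs, key=lambda o: o.end - o.start)
        peptide, stops = reconstruct_pseudo_orf(
            seq[main.start:main.end], 0)
        main.n_internal_stops = len(stops)
        positions = {}
        m = domains.CCHC_REGEX.search(peptide)
        if m:
            positions["CCHC"] = m.start()
        for dom, sentinel in domains.SENTINELS.items():
            p = peptide.find(sentinel)
            if p >= 0:
                positions[dom] = p
        hint = positions.get("INT")
        hint = hint + len(domains.INT_SENTINEL) if hint is not None else None
        chd_call = chdmod.extract_chd(peptide, int_end_hint=hint,
                                      source_id=seq_id)
        if chd_call is not None and chd_call.group != "unclassified":
            positions["CHD"] = chd_call.window_start + chd_call.anchor
        domain_order = [d for d, _p in
                        sorted(positions.items(), key=lambda kv: kv[1])]
    order_ok, _ = check_domain_order(domain_order)
    intact = (itr_ok and order_ok and bool(orfs)
              and all(o.n_internal_stops == 0 for o in orfs))
    return ElementAnnotation(
        seq_id=seq_id, start=start, end=end, ltr5=cand.ltr5,
        ltr3=cand.ltr3, ltr_identity=cand.identity, itr_ok=itr_ok,
        tsd=tsd, pbs=pbs, ppt=ppt, orfs=orfs,
        domain_order=domain_order, chd=chd_call, intact=intact)


def annotate_genome(seq: str, seq_id: str = "seq",
                    trna_3ends: dict | None = None,
                    **ltr_kwargs) -> list[ElementAnnotation]:
    """Full structural annotation: LTR pairs, then per-element features."""
    cands = find_ltr_pairs(seq, **ltr_kwargs)
    anns = [annotate_element(seq, c, seq_id, trna_3ends) for c in cands]
    anns.sort(key=lambda a: a.start)
    return anns


def annotation_table(annotations) -> pd.DataFrame:
    """Per-element table with the classic element-characteristics columns."""
    rows = []
    for a in annotations:
        rows.append({
            "seq_id": a.seq_id,
            "start_1based": a.start + 1,
            "end_1based": a.end,
            "element_size_bp": a.size,
            "ltr5_size_bp": a.ltr5[1] - a.ltr5[0],
            "ltr3_size_bp": a.ltr3[1] - a.ltr3[0],
            "ltr_identity_pct": round(a.ltr_identity, 1),
            "tsd": a.tsd or "ND",
            "itr": "TG...CA" if a.itr_ok else "-",
            "pbs_len": a.pbs.length if a.pbs else 0,
            "ppt_len": a.ppt.length if a.ppt else 0,
            "domains": "-".join(a.domain_order) or "ND",
            "chd_group": a.chd.group if a.chd else "none",
            "intact": a.intact,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# families and consensus
# ---------------------------------------------------------------------------

@dataclass
class FamilyAssignment:
    family_id: str
    members: list
    mean_identity: float
    mean_ltr_identity: float | None = None


def cluster_families(elements: dict, threshold: float = 80.0,
                     ltr_threshold: float = 50.0,
                     ltrs: dict | None = None) -> list[FamilyAssignment]:
    """Single-linkage clustering on pairwise global identity > threshold.

    ``elements`` maps element id -> nucleotide sequence. When ``ltrs``
    (id -> 5'LTR sequence) is given, members must additionally share at
    least ``ltr_threshold`` percent LTR identity with the family exemplar
    (the first member by id order).
    """
    ids = sorted(elements)
    ident = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident[(a, b)] = ident[(b, a)] = global_identity(
                elements[a], elements[b])
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), v in ident.items():
        if v > threshold:
            parent[find(a)] = find(b)
    groups: dict = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)

    out = []
    for n, members in enumerate(sorted(groups.values(),
                                       key=lambda m: m[0]), start=1):
        members = sorted(members)
        if ltrs:
            exemplar = members[0]
            kept = [m for m in members if m == exemplar or global_identity(
                ltrs[m], ltrs[exemplar]) >= ltr_threshold]
            dropped = [m for m in members if m not in kept]
            members = kept
        else:
            dropped = []
        pairs = [ident[(a, b)] for i, a in enumerate(members)
                 for b in members[i + 1:]]
        mean_id = float(np.mean(pairs)) if pairs else 100.0
        mean_ltr = None
        if ltrs and len(members) > 1:
            ex = members[0]
            mean_ltr = float(np.mean([global_identity(ltrs[m], ltrs[ex])
                                      for m in members[1:]]))
        out.append(FamilyAssignment(f"family{n:02d}", members, mean_id,
                                    mean_ltr))
        for m in dropped:  # LTR-divergent members become singleton families
            out.append(FamilyAssignment(
                f"family{n:02d}_ltrsplit_{m}", [m], 100.0, None))
    return out


def build_consensus(aligned_copies) -> str:
    """Column-wise majority consensus of aligned copies.

    Ties among bases go to the first-listed copy; a gap wins only when
    gaps exceed 50 percent of the column.
    """
    rows = [getattr(c, "seq", c).upper() for c in aligned_copies]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("copies must be aligned to equal length")
    out = []
    for col in zip(*rows):
        gaps = col.count("-")
        if gaps * 2 > len(col):
            out.append("-")
            continue
        counts: dict = {}
        for b in col:
            if b != "-":
                counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        for b in col:  # first-listed copy breaks ties
            if b != "-" and counts[b] == top:
                out.append(b)
                break
    return "".join(out)
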