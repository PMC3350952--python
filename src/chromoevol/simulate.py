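"""Synthetic data: codon alignments evolved along labeled trees, and toy
genomes with planted LTR retroelements carrying known structural truth.

The generator defines the study conditions every downstream stage is
tested against: site classes are drawn from the model's proportions, each
site evolves by the same GY94 process the likelihood engine uses (with
foreground classes switching to omega2 only on labeled branches), and
planted elements carry the full structural inventory of a chromovirus
(paired LTRs with TG...CA termini, 4-6 bp TSD, PBS complementary to a
tRNA-Met 3' end, polypurine tract, single Gag-Pol ORF with
CCHC-PR-RT-RNH-INT-CHD domain order).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import domains
from .codon import SiteClassModel, _EigQ, _TreeIndex
from .genetics import NUCLEOTIDES, revcomp, standard_code
from .io import CodonAlignment
from .trees import LabeledTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    tree: LabeledTree
    model: SiteClassModel
    n_sites: int
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class SimulationTruth:
    """Generated per-site classes and all ancestral states.

    ``states[k]`` is the codon-index vector of postorder node ``k`` (root
    last); ``parents[k]`` indexes the parent node, -1 for the root.
    """

    site_classes: np.ndarray          # class id per site (strings)
    states: np.ndarray                # (n_nodes, n_sites) codon indices
    parents: np.ndarray
    labels: list
    leaf_rows: np.ndarray             # node index -> alignment row (-1)


def simulate_codon_alignment(config: SimulationConfig):
    """Evolve a codon alignment along a labeled tree; see module docstring.

    Returns ``(CodonAlignment, SimulationTruth)``; deterministic given
    ``config.seed``.
    """
    model, tree = config.model, config.tree
    code = standard_code()
    rng = np.random.default_rng(config.seed)
    leaf_names = tree.leaf_names()
    if len(leaf_names) > 1 and tree.total_length() == 0:
        warnings.warn("tree has zero total length: all simulated sequences "
                      "will be identical")
    tindex = _TreeIndex(tree, leaf_names)

    weights = model.class_weights()
    cls_ids = list(weights)
    probs = np.array([weights[c] for c in cls_ids])
    site_cls = rng.choice(len(cls_ids), size=config.n_sites, p=probs)

    scale = model.background_rate()
    n_nodes = len(tindex.nodes)
    states = np.zeros((n_nodes, config.n_sites), dtype=np.int16)
    parents = np.full(n_nodes, -1, dtype=int)
    for k, kids in enumerate(tindex.children):
        for c in kids:
            parents[c] = k

    root = tindex.root
    states[root] = rng.choice(61, size=config.n_sites, p=model.freqs)

    eig_cache: dict = {}
    # reversed postorder visits parents before children (root is last in
    # postorder), so parent states are always available
    for k in range(n_nodes - 1, -1, -1):
        if k == root:
            continue
        parent = parents[k]
        for ci, cls in enumerate(cls_ids):
            sites = np.where(site_cls == ci)[0]
            if sites.size == 0:
                continue
            w = model.omega_for(cls, tindex.labels[k])
            if w not in eig_cache:
                eig_cache[w] = _EigQ(model.kappa, w, model.freqs)
            p = eig_cache[w].pmat(tindex.lengths[k] / scale)
            cdf = np.cumsum(p[states[parent, sites]], axis=1)
            u = rng.random(sites.size)
            states[k, sites] = np.minimum(
                (u[:, None] > cdf).sum(axis=1), 60)

    matrix = np.zeros((len(leaf_names), config.n_sites), dtype=np.int16)
    leaf_rows = tindex.leaf_row
    for k in range(n_nodes):
        if leaf_rows[k] >= 0:
            matrix[leaf_rows[k]] = states[k]
    aln = CodonAlignment(list(leaf_names), matrix,
                         ncols_original=config.n_sites, code=code)
    truth = SimulationTruth(
        site_classes=np.array([cls_ids[i] for i in site_cls]),
        states=states, parents=parents, labels=list(tindex.labels),
        leaf_rows=leaf_rows)
    return aln, truth


def count_substitutions(truth: SimulationTruth, code=None):
    """(nonsynonymous, synonymous) state-change counts along all branches,
    read off the recorded ancestral states."""
    code = code or standard_code()
    nonsyn = syn = 0
    for k, parent in enumerate(truth.parents):
        if parent < 0:
            continue
        diff = np.where(truth.states[k] != truth.states[parent])[0]
        for s in diff:
            a = code.sense_codons[truth.states[parent, s]]
            b = code.sense_codons[truth.states[k, s]]
            if code.aa(a) == code.aa(b):
                syn += 1
            else:
                nonsyn += 1
    return nonsyn, syn


def default_labeled_tree(foreground: str = "FG") -> LabeledTree:
    """The 8-taxon study tree used for simulation-based calibration.

    Balanced topology, 0.25 expected substitutions per codon site per
    branch (a typical within-clade divergence for retroelement domains),
    with the stem of one four-taxon clade as the labeled foreground
    branch (length 0.4).
    """
    return LabeledTree.from_newick(
        "(((t1:0.25,t2:0.25):0.25,(t3:0.25,t4:0.25):0.25)#%s:0.4,"
        "((t5:0.25,t6:0.25):0.25,(t7:0.25,t8:0.25):0.25):0.25);"
        % foreground)


# ---------------------------------------------------------------------------
# genome planting
# ---------------------------------------------------------------------------

@dataclass
class SyntheticElementSpec:
    """Blueprint of one planted Gypsy element (defaults are study-typical)."""

    name: str = "element"
    ltr_len: int = 300
    ltr_divergence: float = 0.01
    tsd: str | None = "CCTAT"
    pbs_len: int = 13
    pbs_spacer: int = 1
    ppt_len: int = 14
    orf_domains: tuple = domains.CANONICAL_DOMAIN_ORDER
    chd_group: str = "CHD_I"          # {CHD_I, CHD_II, none}
    clade_motifs: frozenset = frozenset()
    trna_3end: str = domains.SYNTHETIC_TRNA_MET_3END

    def __post_init__(self):
        if self.ltr_len < 100:
            raise ValueError("ltr_len must be >= 100")
        if not 0 <= self.ltr_divergence <= 0.5:
            raise ValueError("ltr_divergence must be in [0, 0.5]")
        if self.tsd is not None and len(self.tsd) not in (4, 5, 6):
            raise ValueError("TSD length must be 4-6 bp")
        if not 11 <= self.pbs_len <= 13:
            raise ValueError("pbs_len must be 11-13 bp")
        if not 0 <= self.pbs_spacer <= 2:
            raise ValueError("pbs_spacer must be 0-2 bp")
        if self.ppt_len < 12:
            raise ValueError("ppt_len must be >= 12")
        order = [d for d in domains.CANONICAL_DOMAIN_ORDER
                 if d in self.orf_domains]
        if list(self.orf_domains) != order:
            raise ValueError("orf_domains must respect the canonical "
                             "CCHC<PR<RT<RNH<INT<CHD order")
        if self.chd_group not in ("CHD_I", "CHD_II", "none"):
            raise ValueError("chd_group must be CHD_I, CHD_II or none")


@dataclass
class PlantedElement:
    """Ground-truth coordinates (0-based half-open, genome frame)."""

    spec: SyntheticElementSpec
    start: int = 0
    end: int = 0
    ltr5: tuple = (0, 0)
    ltr3: tuple = (0, 0)
    pbs: tuple = (0, 0)
    ppt: tuple = (0, 0)
    orf: tuple = (0, 0)
    tsd: str | None = None
    ltr_identity: float = 100.0

    def shifted(self, offset: int) -> "PlantedElement":
        sh = lambda iv: (iv[0] + offset, iv[1] + offset)
        return PlantedElement(self.spec, self.start + offset,
                              self.end + offset, sh(self.ltr5),
                              sh(self.ltr3), sh(self.pbs), sh(self.ppt),
                              sh(self.orf), self.tsd, self.ltr_identity)


@dataclass
class SyntheticGenome:
    seq: str
    truth: list  # of PlantedElement


def random_dna(n: int, rng) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=n)])


def mutate_ltr_pair(ltr: str, divergence: float, seed=0):
    """Mutate a second LTR copy to the requested divergence.

    The TG/CA termini (two bases each end) are never mutated, so the
    expected pairwise identity is 1 - divergence * (len-4)/len.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    other = list(ltr)
    for i in range(2, len(ltr) - 2):
        if rng.random() < divergence:
            choices = [b for b in NUCLEOTIDES if b != ltr[i]]
            other[i] = choices[rng.integers(0, 3)]
    return ltr, "".join(other)


def _encode_peptide(peptide: str, rng, code) -> str:
    by_aa: dict = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.aa(codon), []).append(codon)
    out = []
    for aa in peptide:
        options = by_aa[aa]
        out.append(options[rng.integers(0, len(options))])
    return "".join(out)


_FILLER_AA = "ADEGHIKLNPQRSTV"  # no M (extra starts fine), no W/Y/C/F


def _random_peptide(n: int, rng) -> str:
    return "".join(_FILLER_AA[i] for i in rng.integers(0, len(_FILLER_AA),
                                                       size=n))


def _chd_peptide(spec: SyntheticElementSpec) -> str:
    base = (domains.CHD_I_SENTINEL if spec.chd_group == "CHD_I"
            else domains.CHD_II_SENTINEL)
    extra = []
    if "tekay_KxLRxK" in spec.clade_motifs:
        extra.append("KALRQK")
    if "galadriel_box" in spec.clade_motifs:
        extra.append("YLVKWKG")
    if "tekay_EExTWExE" in spec.clade_motifs:
        extra.append("EELTWEAE")
    return base + "".join(extra)


def build_element(spec: SyntheticElementSpec, rng):
    """Assemble one element; returns (sequence, PlantedElement in element
    frame, i.e. coordinates relative to the 5'LTR start)."""
    code = standard_code()
    ltr = "TG" + random_dna(spec.ltr_len - 4, rng) + "CA"
    ltr5, ltr3 = mutate_ltr_pair(ltr, spec.ltr_divergence, rng)
    matches = sum(a == b for a, b in zip(ltr5, ltr3))
    identity = 100.0 * matches / spec.ltr_len

    pbs = revcomp(spec.trna_3end[-spec.pbs_len:])
    spacer = random_dna(spec.pbs_spacer, rng)

    # guard: the base after the PBS must not extend the tRNA match
    if spec.pbs_len < len(spec.trna_3end):
        forbidden = revcomp(spec.trna_3end[-(spec.pbs_len + 1):])[-1]
    else:
        forbidden = ""
    pad1 = random_dna(24, rng)
    if forbidden:
        while pad1[0] == forbidden:
            pad1 = random_dna(24, rng)

    # Gag-Pol peptide: sentinels in canonical order inside random filler
    pieces = [_random_peptide(8, rng)]
    for dom in spec.orf_domains:
        if dom == "CHD":
            if spec.chd_group == "none":
                continue
            pieces.append(_chd_peptide(spec))
        elif dom == "CCHC":
            pieces.append(domains.CCHC_SENTINEL)
        else:
            pieces.append(domains.SENTINELS[dom])
        pieces.append(_random_peptide(12, rng))
    peptide = "".join(pieces)
    orf_dna = "ATG" + _encode_peptide(peptide, rng, code) + "TAA"
    # in-frame stop immediately upstream pins the ORF start
    orf_guard = "TAA"

    pad2 = random_dna(21, rng)
    # pyrimidine guard so the polypurine tract has exact length
    pad2 = pad2[:-1] + ("C" if pad2[-1] in "AG" else pad2[-1])
    ppt = "".join("AG"[i] for i in rng.integers(0, 2, size=spec.ppt_len))

    parts = [ltr5, spacer, pbs, pad1, orf_guard, orf_dna, pad2, ppt, ltr3]
    seq = "".join(parts)

    pos = {}
    off = 0
    for name, part in zip(
            ["ltr5", "spacer", "pbs", "pad1", "guard", "orf", "pad2",
             "ppt", "ltr3"], parts):
        pos[name] = (off, off + len(part))
        off += len(part)

    truth = PlantedElement(
        spec=spec, start=0, end=len(seq),
        ltr5=pos["ltr5"], ltr3=pos["ltr3"], pbs=pos["pbs"],
        ppt=pos["ppt"], orf=pos["orf"], tsd=spec.tsd,
        ltr_identity=identity)
    return seq, truth


def plant_elements(background_len: int, specs, seed=0,
                   margin: int = 1000, max_tries: int = 200):
    """Plant elements (flanked by their TSD on both sides) into random
    background sequence; returns :class:`SyntheticGenome` with exact truth.
    """
    rng = np.random.default_rng(seed)
    built = [build_element(spec, rng) for spec in specs]
    total = sum(len(s) + 2 * len(t.spec.tsd or "") for s, t in built)
    if background_len < total + margin * (len(specs) + 1):
        raise ValueError("background too short for the requested elements "
                         "plus margins")
    background = random_dna(background_len, rng)

    placements = None
    for _ in range(max_tries):
        cuts = sorted(rng.integers(margin, background_len - margin,
                                   size=len(built)))
        ok = all(cuts[i + 1] - cuts[i] >= margin
                 for i in range(len(cuts) - 1))
        if ok:
            placements = cuts
            break
    if placements is None:
        raise RuntimeError("could not place elements without overlap")

    pieces, truth, prev = [], [], 0
    offset = 0
    for (elem_seq, elem_truth), cut in zip(built, placements):
        tsd = elem_truth.spec.tsd or ""
        pieces.append(background[prev:cut])
        offset += cut - prev
        insert = tsd + elem_seq + tsd
        start = offset + len(tsd)
        truth.append(elem_truth.shifted(start))
        pieces.append(insert)
        offset += len(insert)
        prev = cut
    pieces.append(background[prev:])
    return SyntheticGenome(seq="".join(pieces), truth=truth)


def default_element_specs():
    """The default planted inventory, mirroring the structural variety of
    the chromoviruses the annotator is built for: a Galadriel-like CHD_I
    element with a 5 bp CCTAT TSD, two Tekay-like CHD_II elements (one
    with a 6 bp GTTTCT TSD and a 2 nt PBS spacer), and a CHD-less element
    with a 13 bp PBS at 1 nt spacer and a 14-purine PPT."""
    return [
        SyntheticElementSpec(
            name="galadriel_like", ltr_len=919, ltr_divergence=0.003,
            tsd="CCTAT", pbs_len=11, pbs_spacer=0, ppt_len=13,
            chd_group="CHD_I", clade_motifs=frozenset({"galadriel_box"})),
        SyntheticElementSpec(
            name="chdless", ltr_len=233, ltr_divergence=0.013,
            tsd="TGCCC", pbs_len=13, pbs_spacer=1, ppt_len=14,
            orf_domains=("CCHC", "PR", "RT", "RNH", "INT"),
            chd_group="none"),
        SyntheticElementSpec(
            name="tekay_like1", ltr_len=112, ltr_divergence=0.027,
            tsd="GCGTA", pbs_len=12, pbs_spacer=1, ppt_len=14,
            chd_group="CHD_II",
            clade_motifs=frozenset({"tekay_KxLRxK", "tekay_EExTWExE"})),
        SyntheticElementSpec(
            name="tekay_like2", ltr_len=217, ltr_divergence=0.014,
            tsd="GTTTCT", pbs_len=12, pbs_spacer=2, ppt_len=14,
            chd_group="CHD_II",
            clade_motifs=frozenset({"tekay_KxLRxK"})),
    ]


def default_genome(seed: int = 0, background_len: int = 40000):
    return plant_elements(background_len, default_element_specs(),
                          seed=seed)
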