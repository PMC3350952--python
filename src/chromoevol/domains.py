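"""Polyprotein domain sentinels shared by the simulator and the annotator.

A chromovirus Gag-Pol polyprotein carries, in canonical order, a CCHC
Zn-finger, aspartyl protease (PR), reverse transcriptase (RT), RNase H
(RNH), core integrase (INT) and - in chromoviruses - a C-terminal
chromodomain (CHD). Similarity-search domain assignment is out of scope
here; instead the PR/RT/RNH/INT domains are marked by fixed sentinel
peptides that the synthetic genomes embed and the annotator looks up,
while CCHC is located by its literal Cys-X2-Cys-X4-His-X4-Cys pattern and
the CHD by chromo-box motif scanning, so those two detectors are exercised
for real.
"""

from __future__ import annotations

import re

CANONICAL_DOMAIN_ORDER = ("CCHC", "PR", "RT", "RNH", "INT", "CHD")

# Cys-X2-Cys-X4-His-X4-Cys zinc-knuckle of the Gag region
CCHC_REGEX = re.compile(r"C.{2}C.{4}H.{4}C")

# sentinel peptides (motif-flavoured, fixed package fixtures)
CCHC_SENTINEL = "CKNCGKLGHFAKDC"       # matches CCHC_REGEX
PR_SENTINEL = "ALLDTGADVTVLN"
RT_SENTINEL = "GPYMDDILIDSPN"
RNH_SENTINEL = "QVLTTDASDVGWG"
INT_SENTINEL = "WQMDVTHIPSFGR"

SENTINELS = {
    "PR": PR_SENTINEL,
    "RT": RT_SENTINEL,
    "RNH": RNH_SENTINEL,
    "INT": INT_SENTINEL,
}

# chromodomain sentinel peptides: chromo-box at anchor position 1, the
# W45 homologue at alignment position 28 (offset 27) and the Y48 homologue
# at position 31 (offset 30)
CHD_ANCHOR_OFFSETS = (0, 27, 30)

_CHD_CORE = ("{box}"                 # positions 1-7: chromo-box
             "NPDELSRAQMHTNGVDKEAS"  # filler to position 27
             "W"                     # position 28 (W45 homologue)
             "KM"
             "Y"                     # position 31 (Y48 homologue)
             "GEELTWEAEK")           # beta3-strand region with the TWE core

CHD_I_SENTINEL = _CHD_CORE.format(box="YLIKWKG")   # Y24 present
CHD_II_SENTINEL = _CHD_CORE.format(box="SLIKWKG")  # Y24 lost, W45 kept

# Synthetic stand-in for the 3' end of a plant initiator tRNA-Met; the
# minus-strand primer binding site of a planted element is the reverse
# complement of the 3'-terminal ``pbs_len`` bases of this string. Purely
# synthetic fixture (no database accession), configurable at every call
# site that takes a tRNA library.
SYNTHETIC_TRNA_MET_3END = "TCCATCGGGAGATGGACCA"


def assert_cchc(peptide: str) -> None:
    if not CCHC_REGEX.search(peptide):
        raise ValueError("sentinel does not satisfy the CCHC pattern")


assert_cchc(CCHC_SENTINEL)
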