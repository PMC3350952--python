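"""Sequence I/O, codon threading and report emission.

Internal coordinates are 0-based half-open everywhere; GFF3 and human-facing
reports use 1-based inclusive coordinates, converted only at the emission
boundary (:func:`to_gff_interval` / :func:`from_gff_interval`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, standard_code

DNA_LETTERS = frozenset("ACGTURYSWKMBDHVN-")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
UNAMBIGUOUS_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence (DNA or protein)."""

    id: str
    seq: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = DNA_LETTERS if self.moltype == "dna" else PROTEIN_LETTERS
        for pos, ch in enumerate(self.seq.upper()):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} "
                    f"at position {pos + 1}")

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


def guess_moltype(seq: str) -> str:
    return "dna" if set(seq.upper()) <= DNA_LETTERS else "protein"


def read_fasta(path, moltype: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``moltype`` may be forced; otherwise it is guessed per record. Duplicate
    ids and non-IUPAC characters are rejected with informative errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        mt = moltype or guess_moltype(seq)
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, mt))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    del width  # Biopython wraps at its default; kept for interface stability


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-cleaned, in-frame codon matrix over the 61 sense codons.

    ``codons[i, j]`` is the sense-codon index (0-60) of taxon i at kept
    column j. ``removed_columns`` records the original (pre-cleaning) column
    indices that were dropped, so site numbers can be reported in the
    original frame.
    """

    taxa: list[str]
    codons: np.ndarray
    ncols_original: int
    removed_columns: list[int] = field(default_factory=list)
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon ids must be unique")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape inconsistent with taxa")
        if self.codons.size and (self.codons.min() < 0
                                 or self.codons.max() >= self.code.n_sense):
            raise ValueError("codon indices out of range 0..60")
        if self.ncols_kept > self.ncols_original:
            raise ValueError("kept columns exceed original columns")
        if sorted(self.removed_columns) != list(self.removed_columns):
            raise ValueError("removed_columns must be sorted")

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    @property
    def ncols_kept(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def to_dna_records(self) -> list[SequenceRecord]:
        out = []
        for name, row in zip(self.taxa, self.codons):
            out.append(SequenceRecord(
                name, "".join(self.code.codon(i) for i in row), "dna"))
        return out

    def sample_columns(self, columns: Sequence[int]) -> "CodonAlignment":
        """Column-resampled copy (bootstrap support machinery)."""
        cols = np.asarray(columns, dtype=int)
        return CodonAlignment(list(self.taxa), self.codons[:, cols],
                              ncols_original=len(cols), code=self.code)


def thread_codon_alignment(protein_alignment: Sequence[SequenceRecord],
                           cds: Sequence[SequenceRecord],
                           code: GeneticCode | None = None) -> CodonAlignment:
    """Thread unaligned CDSs onto an aligned protein scaffold.

    Each protein residue is replaced by its source codon and each protein
    gap by a codon gap; columns containing a gap, an ambiguous nucleotide or
    a stop codon in any taxon are then removed (cleaning), with the removed
    original column indices recorded.
    """
    code = code or standard_code()
    cds_by_id = {r.id: r for r in cds}
    if len(cds_by_id) != len(cds):
        raise ValueError("duplicate ids in CDS set")
    ncols = {len(r.seq) for r in protein_alignment}
    if len(ncols) != 1:
        raise ValueError("protein alignment rows have unequal lengths")
    ncols = ncols.pop()

    rows = []  # per taxon: list of codon strings ("---" for gaps)
    for prot in protein_alignment:
        if prot.id not in cds_by_id:
            raise ValueError(f"no CDS for taxon {prot.id!r}")
        dna = cds_by_id[prot.id].ungapped.upper().replace("U", "T")
        if len(dna) % 3:
            raise ValueError(f"taxon {prot.id!r}: CDS length not divisible by 3")
        translated = code.translate(dna)
        expected = prot.ungapped.upper()
        # trailing stop in the CDS but not the protein row is tolerated
        if translated.endswith("*") and len(translated) == len(expected) + 1:
            translated = translated[:-1]
            dna = dna[:-3]
        if translated != expected:
            for k, (a, b) in enumerate(zip(translated, expected)):
                if a != b:
                    raise ValueError(
                        f"taxon {prot.id!r}: translated CDS mismatches protein "
                        f"row at residue {k + 1} ({a!r} != {b!r})")
            raise ValueError(
                f"taxon {prot.id!r}: translated CDS length {len(translated)} "
                f"!= protein row length {len(expected)}")
        row, k = [], 0
        for ch in prot.seq:
            if ch == "-":
                row.append("---")
            else:
                row.append(dna[3 * k:3 * k + 3])
                k += 1
        rows.append(row)

    taxa = [r.id for r in protein_alignment]
    kept, removed = [], []
    for j in range(ncols):
        column = [row[j] for row in rows]
        bad = any(
            c == "---" or set(c) - UNAMBIGUOUS_DNA or code.is_stop(c)
            for c in column)
        (removed if bad else kept).append(j)
    matrix = np.array(
        [[code.index(row[j]) for j in kept] for row in rows],
        dtype=np.int16).reshape(len(rows), len(kept))
    return CodonAlignment(taxa, matrix, ncols_original=ncols,
                          removed_columns=removed, code=code)


# ---------------------------------------------------------------------------
# coordinates and GFF3
# ---------------------------------------------------------------------------

def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start, end)."""
    if end < start:
        raise ValueError("empty or inverted interval")
    return start + 1, end


def from_gff_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open; inverse of to_gff_interval."""
    return start - 1, end


def write_gff3(annotations, path) -> None:
    """Emit GFF3 for a list of :class:`~chromoevol.annotate.ElementAnnotation`."""
    lines = ["##gff-version 3"]
    for n, ann in enumerate(annotations, start=1):
        eid = f"elem{n:03d}"
        s, e = to_gff_interval(ann.start, ann.end)
        attrs = [f"ID={eid}", f"ltr_identity={ann.ltr_identity:.1f}",
                 f"itr_ok={'true' if ann.itr_ok else 'false'}"]
        if ann.tsd:
            attrs.append(f"Note=TSD {ann.tsd}")
        lines.append(_gff_line(ann.seq_id, "LTR_retrotransposon", s, e,
                               ";".join(attrs)))
        for name, iv in (("long_terminal_repeat", ann.ltr5),
                         ("long_terminal_repeat", ann.ltr3)):
            gs, ge = to_gff_interval(*iv)
            lines.append(_gff_line(ann.seq_id, name, gs, ge, f"Parent={eid}"))
        if ann.pbs is not None:
            gs, ge = to_gff_interval(ann.pbs.start, ann.pbs.end)
            lines.append(_gff_line(ann.seq_id, "primer_binding_site", gs, ge,
                                   f"Parent={eid};trna={ann.pbs.trna_id}"))
        if ann.ppt is not None:
            gs, ge = to_gff_interval(ann.ppt.start, ann.ppt.end)
            lines.append(_gff_line(ann.seq_id, "RR_tract", gs, ge,
                                   f"Parent={eid}"))
        for orf in ann.orfs:
            gs, ge = to_gff_interval(orf.start, orf.end)
            lines.append(_gff_line(
                ann.seq_id, "ORF", gs, ge,
                f"Parent={eid};frame={orf.frame};stops={orf.n_internal_stops}"))
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_line(seqid, ftype, start, end, attrs) -> str:
    return "\t".join([seqid, "chromoevol", ftype, str(start), str(end),
                      ".", "+", ".", attrs])


def parse_gff3(path) -> list[dict]:
    """Minimal reader for files written by :func:`write_gff3` (round trips)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _src, ftype, start, end, _score, _strand, _phase, attrs = \
            line.split("\t")
        s, e = from_gff_interval(int(start), int(end))
        out.append({"seq_id": seqid, "type": ftype, "start": s, "end": e,
                    "attrs": dict(kv.split("=", 1)
                                  for kv in attrs.split(";") if "=" in kv)})
    return out
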