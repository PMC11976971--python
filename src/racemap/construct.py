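"""Expression-construct annotation.

A promoter-driven crRNA expression construct is described by its sense-strand
sequence plus the coordinates of the features the end caller needs: the +1
transcription start base, the crRNA (direct repeat + spacer, in either order),
the 3' downstream region, and the 3' box that directs Integrator-mediated 3'
end formation.  All coordinates are 0-based, half-open; reported end offsets
use the biology convention (+1 site = offset 0 at the 5' side, last annotated
crRNA base = offset 0 at the 3' side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml
from Bio import SeqIO

Span = Tuple[int, int]

_VALID = set("ACGT")


def _check_span(name: str, span: Span, length: int) -> None:
    s, e = span
    if not (0 <= s <= e <= length):
        raise ValueError(f"{name} span {span} outside sequence of length {length}")


@dataclass(frozen=True)
class ConstructAnnotation:
    """Annotated expression construct (sense strand).

    Parameters
    ----------
    seq
        Construct locus sequence over A/C/G/T.
    plus_one
        Index of the first transcribed base (+1 site).
    crrna_span
        Half-open interval of the annotated crRNA (direct repeat + spacer).
    dr_span, spacer_span
        Sub-intervals of the crRNA; order depends on the Cas13 family.
    box3_span
        Interval of the 3' box.
    anchor5
        Index where 3'-RACE inserts begin (3' end of the gene-specific primer).
    name
        Free-text label used in report tables.
    """

    seq: str
    plus_one: int
    crrna_span: Span
    dr_span: Span
    spacer_span: Span
    box3_span: Span
    anchor5: int
    name: str = "construct"

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"construct sequence contains non-ACGT characters: {sorted(bad)}")
        n = len(self.seq)
        for nm, sp in (("crrna", self.crrna_span), ("dr", self.dr_span),
                       ("spacer", self.spacer_span), ("box3", self.box3_span)):
            _check_span(nm, sp, n)
        if not (0 <= self.plus_one < n):
            raise ValueError("plus_one outside sequence")
        if not (0 <= self.anchor5 < n):
            raise ValueError("anchor5 outside sequence")
        if not (self.plus_one <= self.crrna_span[0] <= self.crrna_span[1] <= self.box3_span[0]):
            raise ValueError("expected +1 <= crRNA <= 3' box ordering on the sense strand")

    @property
    def crrna_start(self) -> int:
        return self.crrna_span[0]

    @property
    def crrna_end(self) -> int:
        """Half-open end index of the crRNA; offset 0 of 3' end calls."""
        return self.crrna_span[1]

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "plus_one": self.plus_one,
            "crrna_span": list(self.crrna_span),
            "dr_span": list(self.dr_span),
            "spacer_span": list(self.spacer_span),
            "box3_span": list(self.box3_span),
            "anchor5": self.anchor5,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def to_fasta(self, path: str | Path) -> None:
        Path(path).write_text(f">{self.name}\n{self.seq}\n")


def load_construct(fasta: str | Path, annotation_yaml: str | Path,
                   name: Optional[str] = None) -> ConstructAnnotation:
    """Load a construct from a FASTA sequence plus a YAML coordinate file."""
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta}")
    if name is None:
        rec = records[0]
    else:
        by_id = {r.id: r for r in records}
        if name not in by_id:
            raise ValueError(f"sequence {name!r} not found in {fasta}")
        rec = by_id[name]
    doc = yaml.safe_load(Path(annotation_yaml).read_text())
    return ConstructAnnotation(
        seq=str(rec.seq).upper(),
        plus_one=int(doc["plus_one"]),
        crrna_span=tuple(doc["crrna_span"]),
        dr_span=tuple(doc["dr_span"]),
        spacer_span=tuple(doc["spacer_span"]),
        box3_span=tuple(doc["box3_span"]),
        anchor5=int(doc["anchor5"]),
        name=doc.get("name", rec.id),
    )


# -- demo construct -----------------------------------------------------------
#
# A small synthetic Pol II (U1-style) construct used by the simulator defaults,
# the worked example, and the test-suite fixtures.  Layout (sense strand):
#
#   [promoter tail 19 nt][+1 A][DR 30 nt][spacer 22 nt][downstream "ACT"+7 nt][3' box 14 nt][trailer 10 nt]
#
# The direct repeat is the CasRx (RfxCas13d) DR; the spacer is an arbitrary
# EGFP-like 22-mer.  The first three downstream bases are "ACT" so that the
# modal 3' end (+3) carries the template-derived ACT extension, and the 3' box
# starts 7 nt after that +3 position, reproducing the cleavage geometry of
# snRNA-type 3' end formation.  The bases at downstream offsets 0,1,3,4,5 are
# non-T and the bases just upstream of +1 are non-G, so default simulations
# have unambiguous templated/non-templated splits.

_PROMOTER_TAIL = "TACCGTTCGTATACCATCT"          # last bases of the promoter; no G at -1
_PLUS_ONE = "A"
_DR_CASRX = "AACCCCTACCAACTGGTCGGGGTTTGAAAC"    # CasRx direct repeat (30 nt)
_SPACER = "GCACGACTTCTTCAAGTCCGCC"              # EGFP-derived 22-mer, no TTTT/AAAA
_DOWNSTREAM = "ACTCGCAGAC"                      # ACT + 7 nt; 3' box starts 7 nt after +3
_BOX3 = "CAGGTAAGTACGGT"                        # 14-nt 3' box element
_TRAILER = "GATCCGTGCA"


def demo_construct(name: str = "U1-CasRx-EGFP") -> ConstructAnnotation:
    """The package's built-in synthetic U1-style construct annotation."""
    seq = _PROMOTER_TAIL + _PLUS_ONE + _DR_CASRX + _SPACER + _DOWNSTREAM + _BOX3 + _TRAILER
    plus_one = len(_PROMOTER_TAIL)
    dr = (plus_one + 1, plus_one + 1 + len(_DR_CASRX))
    spacer = (dr[1], dr[1] + len(_SPACER))
    crrna = (dr[0], spacer[1])
    box3_start = spacer[1] + len(_DOWNSTREAM)
    return ConstructAnnotation(
        seq=seq,
        plus_one=plus_one,
        crrna_span=crrna,
        dr_span=dr,
        spacer_span=spacer,
        box3_span=(box3_start, box3_start + len(_BOX3)),
        anchor5=dr[0],
        name=name,
    )
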