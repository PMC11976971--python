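"""Screen for RNA-editing-correctable pathogenic SNVs and AAAA adjacency.

Pathogenic, amino-acid-changing single-nucleotide variants whose mRNA-level
change is G>A or T>C are revertible by the programmable editors REPAIR
(A-to-I, read as G) and RESCUE (C-to-U) respectively.  A guide spacer is the
reverse complement of the target region, so a run of four or more adenosines
near the variant puts >= 4 consecutive uridines into the spacer — a Pol III
terminator that truncates U6-promoter-driven guide expression.  The screen
counts targetable variants and flags those with an AAAA run within a
configurable adjacency window of the variant on the mRNA.

The adjacency window is not canonical; the default of 30 nt equals one spacer
length, and ``screen_summary`` can sweep several windows in one run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

REQUIRED_COLUMNS = ("Type", "ClinicalSignificance", "Name", "GeneSymbol")

SNV_TYPE = "single nucleotide variant"
PATHOGENIC_STRICT = ("Pathogenic",)
PATHOGENIC_WIDE = ("Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic")

# e.g. NM_000546.6(TP53):c.743G>A (p.Arg248Gln)
_NAME_RE = re.compile(
    r"^(?P<acc>[A-Z]{2}_\d+(?:\.\d+)?)"
    r"(?:\((?P<gene>[^)]+)\))?"
    r":c\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])"
    r"(?:\s+\((?P<prot>p\.[^)]+)\))?$"
)
_PROT_RE = re.compile(r"^p\.\(?(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|Ter|\*|=)\)?$")


@dataclass(frozen=True)
class VariantRecord:
    """One variant-summary row with its parsed coding-change fields."""

    allele_id: str
    var_type: str
    clinical_significance: str
    hgvs_name: str
    gene: str
    accession: Optional[str] = None
    c_pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    protein_change: Optional[str] = None

    @property
    def parse_ok(self) -> bool:
        return self.c_pos is not None


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA sequence with the 0-based index of its first CDS base (c.1)."""

    accession: str
    seq: str
    cds_start: int
    cds_partial: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < len(self.seq):
            raise ValueError(f"{self.accession}: cds_start outside transcript")


@dataclass(frozen=True)
class TargetableVariant:
    source: VariantRecord
    system: str  # REPAIR or RESCUE
    mrna_pos: int
    flank: str
    flank_index: int
    clipped: bool
    aaaa_adjacent: bool


def _record_from_row(row: pd.Series) -> VariantRecord:
    name = str(row["Name"])
    m = _NAME_RE.match(name)
    kwargs = {}
    if m:
        kwargs = dict(accession=m["acc"], c_pos=int(m["pos"]), ref=m["ref"],
                      alt=m["alt"], protein_change=m["prot"])
    return VariantRecord(
        allele_id=str(row.get("#AlleleID", "")),
        var_type=str(row["Type"]),
        clinical_significance=str(row["ClinicalSignificance"]),
        hgvs_name=name,
        gene=str(row["GeneSymbol"]),
        **kwargs,
    )


def parse_variant_summary(source) -> List[VariantRecord]:
    """Parse a ClinVar ``variant_summary.txt``-dialect table (plain or .gz).

    Rows whose Name field is not a simple coding SNV HGVS expression are
    retained with their parsed fields unset (``parse_ok`` False).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing required columns: {missing}")
    return [_record_from_row(row) for _, row in df.iterrows()]


def is_aa_changing(record: VariantRecord) -> bool:
    """True iff the protein annotation indicates a non-synonymous change."""
    if not record.protein_change:
        return False
    m = _PROT_RE.match(record.protein_change)
    if not m:
        return False
    return m["alt"] != "=" and m["alt"] != m["ref"]


def filter_pathogenic_aa_changing(records: Iterable[VariantRecord],
                                  mode: str = "strict") -> List[VariantRecord]:
    """Keep pathogenic, amino-acid-changing SNVs.

    ``mode`` "strict" requires ClinicalSignificance exactly "Pathogenic";
    "wide" also admits "Likely pathogenic" and the combined class.
    """
    if mode not in ("strict", "wide"):
        raise ValueError("mode must be 'strict' or 'wide'")
    allowed = PATHOGENIC_STRICT if mode == "strict" else PATHOGENIC_WIDE
    return [r for r in records
            if r.var_type == SNV_TYPE
            and r.clinical_significance in allowed
            and is_aa_changing(r)]


def classify_targetable(record: VariantRecord) -> str:
    """REPAIR for mRNA G>A, RESCUE for T>C, otherwise "none"."""
    if record.ref == "G" and record.alt == "A":
        return "REPAIR"
    if record.ref == "T" and record.alt == "C":
        return "RESCUE"
    return "none"


def load_transcripts_genbank(path: str | Path) -> Dict[str, TranscriptRecord]:
    """Load RefSeq-style mRNA records (GenBank flat file) keyed by accession."""
    out: Dict[str, TranscriptRecord] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        cds = [f for f in rec.features if f.type == "CDS"]
        if not cds:
            continue
        loc = cds[0].location
        length = int(loc.end) - int(loc.start)
        out[rec.id] = TranscriptRecord(rec.id, str(rec.seq).upper(),
                                       int(loc.start), cds_partial=length % 3 != 0)
    return out


def extract_flank(tx: TranscriptRecord, c_pos: int,
                  half_window: int = 30) -> Tuple[str, int, bool]:
    """Window of mRNA sequence around coding position ``c_pos``.

    Returns (window, index of the variant base within the window, clipped
    flag).  The variant's transcript index is cds_start + c_pos - 1.
    Raises ValueError when c_pos falls outside the transcript.
    """
    if c_pos < 1:
        raise ValueError("c_pos must be a simple positive coding position")
    mrna_pos = tx.cds_start + c_pos - 1
    if mrna_pos >= len(tx.seq):
        raise ValueError(f"{tx.accession}: c.{c_pos} beyond transcript end")
    lo = max(0, mrna_pos - half_window)
    hi = min(len(tx.seq), mrna_pos + half_window + 1)
    clipped = lo > mrna_pos - half_window or hi < mrna_pos + half_window + 1
    return tx.seq[lo:hi], mrna_pos - lo, clipped


def aaaa_adjacent(window: str, variant_index: int, run_base: str = "A",
                  run_len: int = 4, adjacency_nt: int = 30) -> bool:
    """True iff a run of >= ``run_len`` ``run_base`` has at least one base
    within ``adjacency_nt`` of the variant position (mRNA sense strand)."""
    if not 0 <= variant_index < len(window):
        raise ValueError("variant_index outside window")
    lo, hi = variant_index - adjacency_nt, variant_index + adjacency_nt
    i = 0
    n = len(window)
    while i < n:
        if window[i] == run_base:
            j = i
            while j < n and window[j] == run_base:
                j += 1
            if j - i >= run_len and i <= hi and j - 1 >= lo:
                return True
            i = j
        else:
            i += 1
    return False


def screen_variants(records: Sequence[VariantRecord],
                    transcripts: Dict[str, TranscriptRecord],
                    pathogenic_mode: str = "strict",
                    half_window: int = 30,
                    adjacency_nt: int = 30,
                    dedup: bool = True) -> Tuple[List[TargetableVariant], pd.DataFrame]:
    """Classify and annotate targetable variants; returns (hits, skip report).

    The skip report lists targetable records whose flank could not be
    extracted (unknown accession or out-of-range coding position).
    """
    kept = filter_pathogenic_aa_changing(records, mode=pathogenic_mode)
    if dedup:
        seen = set()
        unique = []
        for r in kept:
            key = (r.accession, r.c_pos, r.ref, r.alt)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        kept = unique
    hits: List[TargetableVariant] = []
    skips = []
    for r in kept:
        system = classify_targetable(r)
        if system == "none":
            continue
        tx = transcripts.get(r.accession)
        if tx is None:
            skips.append((r.allele_id, r.hgvs_name, "accession not in transcript set"))
            continue
        try:
            window, idx, clipped = extract_flank(tx, r.c_pos, half_window=half_window)
        except ValueError as exc:
            skips.append((r.allele_id, r.hgvs_name, str(exc)))
            continue
        adj = aaaa_adjacent(window, idx, adjacency_nt=adjacency_nt)
        hits.append(TargetableVariant(r, system, tx.cds_start + r.c_pos - 1,
                                      window, idx, clipped, adj))
    skip_report = pd.DataFrame(skips, columns=["allele_id", "name", "reason"])
    return hits, skip_report


def screen_summary(records: Sequence[VariantRecord],
                   transcripts: Dict[str, TranscriptRecord],
                   pathogenic_mode: str = "strict",
                   half_window: int = 30,
                   adjacency_windows: Sequence[int] = (30,),
                   dedup: bool = True) -> pd.DataFrame:
    """Summary table of the screen, one row per adjacency window.

    Columns: records in, pathogenic amino-acid-changing count, targetable
    counts (REPAIR/RESCUE disjoint), AAAA-adjacent count and percentage
    (one decimal), and skipped-record count.
    """
    rows = []
    for adjacency_nt in adjacency_windows:
        hits, skip_report = screen_variants(
            records, transcripts, pathogenic_mode=pathogenic_mode,
            half_window=half_window, adjacency_nt=adjacency_nt, dedup=dedup)
        n_path = len(filter_pathogenic_aa_changing(records, mode=pathogenic_mode))
        n_repair = sum(1 for h in hits if h.system == "REPAIR")
        n_rescue = sum(1 for h in hits if h.system == "RESCUE")
        n_target = n_repair + n_rescue
        n_adj = sum(1 for h in hits if h.aaaa_adjacent)
        pct = round(100.0 * n_adj / n_target, 1) if n_target else 0.0
        rows.append({
            "adjacency_nt": adjacency_nt,
            "n_records": len(records),
            "n_pathogenic_aa_changing": n_path,
            "n_targetable": n_target,
            "n_repair": n_repair,
            "n_rescue": n_rescue,
            "n_aaaa_adjacent": n_adj,
            "pct_aaaa_adjacent": pct,
            "n_skipped": len(skip_report),
        })
    return pd.DataFrame(rows)


def targetable_table(hits: Sequence[TargetableVariant]) -> pd.DataFrame:
    """One row per targetable variant, for ``targetable_variants.tsv``."""
    return pd.DataFrame([{
        "allele_id": h.source.allele_id,
        "gene": h.source.gene,
        "name": h.source.hgvs_name,
        "system": h.system,
        "mrna_pos": h.mrna_pos,
        "flank": h.flank,
        "flank_index": h.flank_index,
        "clipped": h.clipped,
        "aaaa_adjacent": h.aaaa_adjacent,
    } for h in hits])
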