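"""Synthetic RACE reads and ClinVar-style variant cohorts with ground truth.

Every generator draws from explicit categorical distributions and writes a
tab-separated truth sidecar (one row per emitted read or variant row), so
downstream stages can be checked against exact tallies instead of against a
re-implementation of themselves.

Library architectures emulated
------------------------------
3' RACE   insert = construct sequence from a fixed 5' anchor through the drawn
          3' end position, then a drawn non-templated oligo-U tail, then the
          adapter's 4 random 5' nucleotides, then the 3' adapter itself.
5' RACE   insert = template-switching-oligo adapter, then a drawn run of
          non-templated guanosines (3 for uncapped molecules, 4 when the m7G
          cap templates an extra C during reverse transcription), then the
          construct sequence from the drawn start position.

Reads are single-end, RNA-sense, fixed length (default 150 nt, truncating),
with flat Phred qualities and an optional uniform per-base substitution error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .construct import ConstructAnnotation
from .readprep import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PROB_TOL = 1e-9

# Adapter defaults: Illumina small-RNA 3' adapter and a SMART-style TSO handle.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTAC"


def _check_probs(name: str, probs: Dict) -> None:
    if not probs:
        raise ValueError(f"{name} must be a non-empty probability map")
    total = sum(probs.values())
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} contains negative probabilities")
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} probabilities sum to {total}, expected 1")


@dataclass(frozen=True)
class SimConfig3:
    """Configuration of a 3' RACE library simulation.

    ``end_offset_probs`` maps an end offset in nt relative to the annotated
    crRNA 3' end (0 = the last annotated base, positive = templated downstream
    extension) to its probability.  ``tail_probs`` maps a non-templated tail
    string (e.g. "", "T", "TT") to its probability.
    """

    construct: ConstructAnnotation
    end_offset_probs: Dict[int, float]
    tail_probs: Dict[str, float]
    n_reads: int = 2000
    subst_error_rate: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER3
    n_random_nt: int = 4
    read_len: int = 150
    qual: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        _check_probs("end_offset_probs", self.end_offset_probs)
        _check_probs("tail_probs", self.tail_probs)
        c = self.construct
        for off in self.end_offset_probs:
            end = c.crrna_end + off
            if not (c.anchor5 < end <= len(c.seq)):
                raise ValueError(f"end offset {off:+d} falls outside the construct")
        for tail in self.tail_probs:
            if set(tail) - set("ACGT"):
                raise ValueError(f"tail {tail!r} contains non-ACGT characters")
        if set(self.adapter_seq) - set("ACGT") or not self.adapter_seq:
            raise ValueError("adapter_seq must be a non-empty ACGT string")
        if self.n_random_nt < 0:
            raise ValueError("n_random_nt must be >= 0")
        if not 0.0 <= self.subst_error_rate <= 1.0:
            raise ValueError("subst_error_rate must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


# Default start/leader models: Pol II initiation at the +1 base; reverse
# transcriptases add three non-templated C (read as G) at the cDNA 3' end,
# plus a fourth when the template carries an m7G cap.
@dataclass(frozen=True)
class SimConfig5:
    """Configuration of a 5' RACE (template-switching) library simulation."""

    construct: ConstructAnnotation
    start_offset_probs: Dict[int, float] = field(default_factory=lambda: {0: 1.0})
    cap_fraction: float = 0.5
    leader_len_probs_uncapped: Dict[int, float] = field(default_factory=lambda: {3: 1.0})
    leader_len_probs_capped: Dict[int, float] = field(default_factory=lambda: {4: 1.0})
    tso_adapter_seq: str = DEFAULT_TSO
    n_reads: int = 2000
    subst_error_rate: float = 0.0
    read_len: int = 150
    qual: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        _check_probs("start_offset_probs", self.start_offset_probs)
        _check_probs("leader_len_probs_uncapped", self.leader_len_probs_uncapped)
        _check_probs("leader_len_probs_capped", self.leader_len_probs_capped)
        c = self.construct
        for off in self.start_offset_probs:
            if not (0 <= c.plus_one + off < len(c.seq)):
                raise ValueError(f"start offset {off:+d} falls outside the construct")
        for g in list(self.leader_len_probs_uncapped) + list(self.leader_len_probs_capped):
            if g < 0:
                raise ValueError("leader G counts must be >= 0")
        if not 0.0 <= self.cap_fraction <= 1.0:
            raise ValueError("cap_fraction must be in [0, 1]")
        if set(self.tso_adapter_seq) - set("ACGT") or not self.tso_adapter_seq:
            raise ValueError("tso_adapter_seq must be a non-empty ACGT string")
        if not 0.0 <= self.subst_error_rate <= 1.0:
            raise ValueError("subst_error_rate must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def _draw(rng: np.random.Generator, probs: Dict, n: int) -> List:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with a uniformly drawn *different* base
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        codes = {b: i for i, b in enumerate(_BASES)}
        cur = np.array([codes[b] for b in arr[hit]])
        arr[hit] = _BASES[(cur + shifts) % 4]
    return arr.tobytes().decode()


def simulate_race3(cfg: SimConfig3) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Simulate a 3' RACE library; returns reads plus the truth sidecar."""
    rng = np.random.default_rng(cfg.seed)
    c = cfg.construct
    offsets = _draw(rng, cfg.end_offset_probs, cfg.n_reads)
    tails = _draw(rng, cfg.tail_probs, cfg.n_reads)
    reads: List[ReadRecord] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        rand = "".join(_BASES[rng.integers(0, 4, size=cfg.n_random_nt)].astype(str)) \
            if cfg.n_random_nt else ""
        seq = c.seq[c.anchor5:c.crrna_end + offsets[i]] + tails[i] + rand + cfg.adapter_seq
        seq = seq[:cfg.read_len]
        seq = _apply_errors(seq, cfg.subst_error_rate, rng)
        rid = f"r3_{i:06d}"
        reads.append(ReadRecord(rid, seq, [cfg.qual] * len(seq)))
        truth_rows.append((rid, offsets[i], tails[i], "n/a"))
    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "true_end_offset", "true_tail", "true_cap_state"])
    return reads, truth


def simulate_race5(cfg: SimConfig5) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Simulate a template-switching 5' RACE library; returns reads + truth."""
    rng = np.random.default_rng(cfg.seed)
    c = cfg.construct
    starts = _draw(rng, cfg.start_offset_probs, cfg.n_reads)
    capped = rng.random(cfg.n_reads) < cfg.cap_fraction
    g_capped = _draw(rng, cfg.leader_len_probs_capped, cfg.n_reads)
    g_uncapped = _draw(rng, cfg.leader_len_probs_uncapped, cfg.n_reads)
    reads: List[ReadRecord] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        g = g_capped[i] if capped[i] else g_uncapped[i]
        seq = cfg.tso_adapter_seq + "G" * g + c.seq[c.plus_one + starts[i]:]
        seq = seq[:cfg.read_len]
        seq = _apply_errors(seq, cfg.subst_error_rate, rng)
        rid = f"r5_{i:06d}"
        reads.append(ReadRecord(rid, seq, [cfg.qual] * len(seq)))
        truth_rows.append((rid, starts[i], "G" * g, "capped" if capped[i] else "uncapped"))
    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "true_start_offset", "true_leader", "true_cap_state"])
    return reads, truth


# -- FASTQ / truth sidecar I/O ------------------------------------------------

def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{quals}\n")


def read_fastq(path: str | Path) -> List[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(ReadRecord(rec.id, str(rec.seq),
                              list(rec.letter_annotations["phred_quality"])))
    return out


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"true_tail": str, "true_leader": str})
    return df


# =============================================================================
# Variant cohort simulation (ClinVar variant_summary dialect + GenBank mRNAs)
# =============================================================================

_AA3 = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val"]
_OTHER_CHANGES = [("A", "G"), ("C", "T"), ("C", "G"), ("G", "C"), ("T", "A"), ("A", "C")]

VARIANT_SUMMARY_COLUMNS = ["#AlleleID", "Type", "Name", "GeneSymbol",
                           "ClinicalSignificance", "Assembly", "Chromosome",
                           "ReviewStatus"]


@dataclass(frozen=True)
class SimVariantConfig:
    """Configuration of a synthetic pathogenic-variant cohort.

    Fractions are marginal Bernoulli rates per emitted row; the base-change
    classes G>A / T>C (the REPAIR- and RESCUE-revertible directions) must sum
    to at most 1, with the remainder drawn from non-revertible changes.
    ``aaaa_adjacent_rate`` is the probability that a *targetable* row has an
    AAAA run planted within the adjacency window (30 nt, one spacer length);
    all other A runs of length >= 4 are scrubbed from the transcripts so truth
    labels are exact.
    """

    n_records: int = 1000
    frac_pathogenic: float = 0.5
    frac_aa_changing: float = 0.7
    frac_G_to_A: float = 0.25
    frac_T_to_C: float = 0.15
    aaaa_adjacent_rate: float = 0.17
    transcript_length: int = 300
    cds_start: int = 50
    half_window: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_pathogenic", "frac_aa_changing", "frac_G_to_A",
                     "frac_T_to_C", "aaaa_adjacent_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_G_to_A + self.frac_T_to_C > 1.0 + _PROB_TOL:
            raise ValueError("frac_G_to_A + frac_T_to_C exceed 1: jointly infeasible")
        if self.transcript_length < 2 * self.half_window + 1:
            raise ValueError("transcript_length smaller than the flank window")
        if not 0 < self.cds_start < self.transcript_length:
            raise ValueError("cds_start outside transcript")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")


def _scrub_a_runs(seq: List[str], protect: int, run_len: int = 4) -> None:
    """Break every A-run of length >= run_len, never touching ``protect``."""
    changed = True
    while changed:
        changed = False
        count = 0
        for j in range(len(seq)):
            count = count + 1 if seq[j] == "A" else 0
            if count >= run_len:
                k = j if j != protect else j - 1
                seq[k] = "C"
                changed = True
                count = 0


def simulate_variant_table(
    cfg: SimVariantConfig,
) -> Tuple[pd.DataFrame, List[SeqRecord], pd.DataFrame]:
    """Emit (variant table, transcript GenBank records, truth table).

    Each row gets its own synthetic transcript whose CDS coordinates make the
    HGVS c. position resolvable, with the reference base planted at the
    variant position.
    """
    rng = np.random.default_rng(cfg.seed)
    cds_end = cfg.transcript_length - 40
    cds_len = cds_end - cfg.cds_start
    if cds_len < 10:
        raise ValueError("transcript too short for a CDS")

    rows, truth_rows, transcripts = [], [], []
    for i in range(cfg.n_records):
        acc = f"NM_{900000 + i}.1"
        gene = f"SYNG{i:04d}"
        pathogenic = rng.random() < cfg.frac_pathogenic
        aa_changing = rng.random() < cfg.frac_aa_changing
        u = rng.random()
        if u < cfg.frac_G_to_A:
            ref, alt = "G", "A"
        elif u < cfg.frac_G_to_A + cfg.frac_T_to_C:
            ref, alt = "T", "C"
        else:
            ref, alt = _OTHER_CHANGES[rng.integers(0, len(_OTHER_CHANGES))]

        c_pos = int(rng.integers(4, cds_len + 1))
        mrna_pos = cfg.cds_start + c_pos - 1
        seq = list(_BASES[rng.integers(0, 4, size=cfg.transcript_length)].astype(str))
        seq[mrna_pos] = ref
        _scrub_a_runs(seq, protect=mrna_pos)

        system = "none"
        if pathogenic and aa_changing:
            if (ref, alt) == ("G", "A"):
                system = "REPAIR"
            elif (ref, alt) == ("T", "C"):
                system = "RESCUE"
        adjacent = False
        if system != "none" and rng.random() < cfg.aaaa_adjacent_rate:
            # plant an AAAA run inside the adjacency window, clear of the
            # variant base, padded so it cannot extend
            lo = max(3, -(mrna_pos - 1))
            hi = min(cfg.half_window - 4, cfg.transcript_length - mrna_pos - 6)
            choices = list(range(-min(cfg.half_window - 4, mrna_pos - 1), -4)) + \
                list(range(lo, hi + 1))
            d = int(choices[rng.integers(0, len(choices))])
            p = mrna_pos + d
            seq[p:p + 4] = list("AAAA")
            if p - 1 != mrna_pos and seq[p - 1] == "A":
                seq[p - 1] = "C"
            if p + 4 < len(seq) and p + 4 != mrna_pos and seq[p + 4] == "A":
                seq[p + 4] = "C"
            adjacent = True

        codon = (c_pos + 2) // 3
        ref_aa = _AA3[rng.integers(0, len(_AA3))]
        if aa_changing:
            alt_aa = _AA3[rng.integers(0, len(_AA3))]
            while alt_aa == ref_aa:
                alt_aa = _AA3[rng.integers(0, len(_AA3))]
            prot = f"p.{ref_aa}{codon}{alt_aa}"
        else:
            prot = f"p.{ref_aa}{codon}="
        name = f"{acc}({gene}):c.{c_pos}{ref}>{alt} ({prot})"
        rows.append({
            "#AlleleID": str(100000 + i),
            "Type": "single nucleotide variant",
            "Name": name,
            "GeneSymbol": gene,
            "ClinicalSignificance": "Pathogenic" if pathogenic else "Benign",
            "Assembly": "GRCh38",
            "Chromosome": str(1 + i % 22),
            "ReviewStatus": "criteria provided, single submitter",
        })
        rec = SeqRecord(Seq("".join(seq)), id=acc, name=acc.split(".")[0],
                        description=f"synthetic mRNA for {gene}")
        rec.annotations["molecule_type"] = "mRNA"
        rec.annotations["date"] = "01-JAN-2024"
        rec.features.append(SeqFeature(FeatureLocation(cfg.cds_start, cds_end),
                                       type="CDS",
                                       qualifiers={"gene": [gene]}))
        transcripts.append(rec)
        truth_rows.append({
            "allele_id": str(100000 + i),
            "accession": acc,
            "pathogenic": pathogenic,
            "aa_changing": aa_changing,
            "ref": ref,
            "alt": alt,
            "c_pos": c_pos,
            "system": system,
            "aaaa_adjacent": adjacent,
        })

    variants = pd.DataFrame(rows, columns=VARIANT_SUMMARY_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["allele_id", "accession", "pathogenic",
                                              "aa_changing", "ref", "alt", "c_pos",
                                              "system", "aaaa_adjacent"])
    return variants, transcripts, truth


def write_variant_table(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def write_transcripts_genbank(transcripts: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(transcripts), str(path), "genbank")
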