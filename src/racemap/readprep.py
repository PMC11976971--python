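"""Read preprocessing: adapter removal, quality filtering, random-nt trimming.

The pipeline order is fixed — 3' adapter removal (keeping only reads in which
the adapter was found, minimum insert length 20), quality filtering (>= 95% of
bases at Phred >= 30), removal of the 3' RACE adapter's 4 random 5'
nucleotides, then 5' adapter removal (again keeping only trimmed reads).
Adapter matching is a semi-global scan with unit mismatch cost and no indels:
the rightmost full or 3'-partial occurrence (3' adapter) or the leftmost full
or 5'-partial occurrence (5' adapter) with a mismatch rate <= ``max_err`` over
the matched span is used.  N bases count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

_ACGT = set("ACGT")

#: shortest adapter overlap accepted for a partial match at a read end
MIN_OVERLAP = 3


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: identifier, bases, per-base Phred scores."""

    id: str
    bases: str
    quals: List[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quals")
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")


@dataclass(frozen=True)
class TrimmedRead:
    """A read's post-trimming insert with provenance flags."""

    id: str
    insert: str
    adapter3_found: bool = False
    qual_pass: bool = True
    adapter5_found: bool = False


def _check_adapter(adapter: str) -> None:
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if set(adapter) - _ACGT:
        raise ValueError(f"adapter {adapter!r} contains non-ACGT characters")


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter_3p(read: ReadRecord, adapter: str, min_len: int = 20,
                    max_err: float = 0.1) -> Optional[TrimmedRead]:
    """Remove a 3' adapter and everything after it; None if discarded.

    The rightmost occurrence wins; a partial occurrence hanging off the read's
    3' end is accepted down to an overlap of MIN_OVERLAP bases.  Reads without
    an adapter hit, or whose remaining insert is shorter than ``min_len``, are
    discarded (trimmed-only semantics).
    """
    _check_adapter(adapter)
    seq = read.bases
    n, m = len(seq), len(adapter)
    for start in range(n - MIN_OVERLAP, -1, -1):
        overlap = min(m, n - start)
        if _mismatches(seq[start:start + overlap], adapter[:overlap]) <= int(max_err * overlap):
            insert = seq[:start]
            if len(insert) < min_len:
                return None
            return TrimmedRead(read.id, insert, adapter3_found=True)
    return None


def quality_filter(read: ReadRecord, q: int = 30, p: float = 95.0) -> bool:
    """True iff at least ``p`` percent of bases have Phred quality >= ``q``.

    Both boundaries are inclusive; an empty read fails.
    """
    if not read.quals:
        return False
    good = sum(1 for x in read.quals if x >= q)
    return 100.0 * good / len(read.quals) >= p


def trim_random_nt(read: TrimmedRead, n: int = 4, min_len: int = 20) -> Optional[TrimmedRead]:
    """Drop the final ``n`` insert bases (the adapter's 5' random nucleotides).

    After 3'-adapter removal those bases sit at the insert's 3' end.  Discards
    the read if fewer than ``min_len`` bases would remain.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return read
    if len(read.insert) <= n or len(read.insert) - n < min_len:
        return None
    return replace(read, insert=read.insert[:-n])


def trim_adapter_5p(read: TrimmedRead, adapter: str, min_len: int = 1,
                    max_err: float = 0.1) -> Optional[TrimmedRead]:
    """Remove a 5' adapter occurrence and everything before it; None if absent.

    The leftmost full occurrence wins; a partial occurrence hanging off the
    read's 5' end (i.e. an adapter suffix at position 0) is accepted down to
    MIN_OVERLAP bases.
    """
    _check_adapter(adapter)
    seq = read.insert
    n, m = len(seq), len(adapter)
    end: Optional[int] = None
    for start in range(0, n - m + 1):
        if _mismatches(seq[start:start + m], adapter) <= int(max_err * m):
            end = start + m
            break
    if end is None:
        # adapter suffix hanging off the read's 5' end, longest overlap first
        for overlap in range(min(m - 1, n), MIN_OVERLAP - 1, -1):
            if _mismatches(seq[:overlap], adapter[m - overlap:]) <= int(max_err * overlap):
                end = overlap
                break
    if end is None:
        return None
    insert = seq[end:]
    if len(insert) < min_len:
        return None
    return replace(read, insert=insert, adapter5_found=True)


@dataclass
class PrepStats:
    """Per-step retention counters for a preprocessing run."""

    n_in: int = 0
    n_adapter3: int = 0
    n_qual: int = 0
    n_random_nt: int = 0
    n_adapter5: int = 0
    n_out: int = 0

    def as_rows(self) -> List[Tuple[str, int]]:
        return [("input", self.n_in), ("adapter3_trimmed", self.n_adapter3),
                ("quality_pass", self.n_qual), ("random_nt_trimmed", self.n_random_nt),
                ("adapter5_trimmed", self.n_adapter5), ("output", self.n_out)]


def prep_reads(reads: Iterable[ReadRecord], adapter3: Optional[str] = None,
               adapter5: Optional[str] = None, min_len: int = 20, q: int = 30,
               p: float = 95.0, n_random_nt: int = 4,
               max_err: float = 0.1) -> Tuple[List[TrimmedRead], PrepStats]:
    """Run the full preprocessing chain over a read batch.

    Adapter steps run only when the corresponding adapter is configured (a 3'
    RACE library carries no TSO handle and a 5' RACE insert no ligated 3'
    adapter, and trimmed-only semantics would otherwise discard every read of
    the other library type).  The random-nt step belongs to the 3' adapter and
    is skipped with it.
    """
    stats = PrepStats()
    kept: List[TrimmedRead] = []
    for read in reads:
        stats.n_in += 1
        if adapter3 is not None:
            t = trim_adapter_3p(read, adapter3, min_len=min_len, max_err=max_err)
            if t is None:
                continue
            stats.n_adapter3 += 1
            # quality is judged on the retained insert bases
            if not quality_filter(ReadRecord(read.id, t.insert, read.quals[:len(t.insert)]),
                                  q=q, p=p):
                continue
            stats.n_qual += 1
            t = trim_random_nt(t, n=n_random_nt, min_len=min_len)
            if t is None:
                continue
            stats.n_random_nt += 1
        else:
            if not quality_filter(read, q=q, p=p):
                continue
            stats.n_qual += 1
            t = TrimmedRead(read.id, read.bases)
        if adapter5 is not None:
            t = trim_adapter_5p(t, adapter5, max_err=max_err)
            if t is None:
                continue
            stats.n_adapter5 += 1
        kept.append(t)
        stats.n_out += 1
    return kept, stats
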