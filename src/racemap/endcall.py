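"""End calling: top-N collapsing, templated/non-templated splits, summaries.

The caller works on trimmed inserts.  For a 3' RACE insert it measures the
maximal templated prefix against the construct starting at the 3'-RACE anchor;
whatever follows is the non-templated tail, classified into the uridylation
classes none / monoU / diU / oligoU (any non-T tail is "other").  For a 5'
RACE insert it splits the observed leading guanosine run between template and
non-templated leader by maximal templated match, giving the transcription
start offset and the leader G count from which the cap state is inferred
(3 G = uncapped, 4 G = capped — template switching adds a fourth guanosine
only on m7G-capped molecules).

Templated matching is exact by default: the upstream top-N abundance
collapsing suppresses sequencing-error variants, so a mismatch budget is only
exposed for robustness studies.  When a drawn tail base equals the next
template base the split is resolved in favour of the template (longest
templated match wins), the same convention that calls a downstream "ACT"
extension template-derived rather than a mixed tail.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from scipy.stats import beta

from .construct import ConstructAnnotation

TAIL_CLASSES = ("none", "monoU", "diU", "oligoU", "other")

#: display windows mirroring the end-position heatmaps
DEFAULT_WINDOW_3P = (-5, 10)
DEFAULT_WINDOW_5P = (-3, 3)


@dataclass(frozen=True)
class RankedSequence:
    insert: str
    count: int
    rank: int


@dataclass(frozen=True)
class EndCall3:
    """3' end call: offset 0 = last annotated crRNA base, +k = k templated
    downstream bases; ``tail`` is the non-templated suffix."""

    end_offset: int
    tail: str
    tail_class: str


@dataclass(frozen=True)
class EndCall5:
    """5' end call: offset 0 = the +1 base, negative = upstream start."""

    start_offset: int
    leading_g: int
    cap_class: str


@dataclass(frozen=True)
class EndDistribution:
    """Weighted proportions over end offsets; out-of-window mass in "other"."""

    proportions: Dict[Union[int, str], float]
    n_effective: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions)


@dataclass(frozen=True)
class ModificationSpectrum:
    proportions: Dict[Union[int, str], float]
    n_effective: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions)


@dataclass(frozen=True)
class CapFraction:
    """Capped fraction among 3G/4G calls with a Clopper–Pearson interval."""

    estimate: float
    ci_low: float
    ci_high: float
    weight_capped: float
    weight_uncapped: float


def collapse_top_n(inserts: Iterable[str], n: int = 20) -> List[RankedSequence]:
    """Rank unique insert sequences by abundance, keeping the top ``n``.

    Ties are broken lexicographically (smaller sequence first), which makes
    the rank order — and anything derived from it — deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = Counter(inserts)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return [RankedSequence(seq, cnt, rank) for rank, (seq, cnt) in enumerate(ordered, 1)]


def _templated_prefix_len(insert: str, seq: str, start: int, max_mismatch: int) -> int:
    """Length of the maximal templated prefix of ``insert`` against ``seq``
    from ``start``; trailing mismatches never count as templated."""
    last_match = 0
    mismatches = 0
    for i, ch in enumerate(insert):
        pos = start + i
        if pos >= len(seq):
            break
        if ch == seq[pos]:
            last_match = i + 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
    return last_match


def call_3prime_end(insert: str, construct: ConstructAnnotation,
                    min_anchor: int = 15, max_mismatch: int = 0) -> Optional[EndCall3]:
    """Call the 3' end and non-templated tail of one insert; None = unassigned.

    The insert must begin at the construct's 3'-RACE anchor and match the
    template for at least ``min_anchor`` bases.
    """
    L = _templated_prefix_len(insert, construct.seq, construct.anchor5, max_mismatch)
    if L < min_anchor:
        return None
    end_offset = construct.anchor5 + L - construct.crrna_end
    tail = insert[L:]
    return EndCall3(end_offset, tail, classify_tail(tail))


def classify_tail(tail: str) -> str:
    if tail == "":
        return "none"
    if set(tail) == {"T"}:
        return {1: "monoU", 2: "diU"}.get(len(tail), "oligoU")
    return "other"


def classify_cap(leading_g: int) -> str:
    return {3: "uncapped", 4: "capped"}.get(leading_g, "other")


def call_5prime_end(insert: str, construct: ConstructAnnotation,
                    min_anchor: int = 15) -> Optional[EndCall5]:
    """Call the start offset and non-templated leader G count of one insert.

    The observed leading G run is split by maximal templated match: template-
    matching guanosines are assigned to the template first, so a +1 G
    construct read with four observed G yields leader 3 and start offset 0.
    """
    seq = construct.seq
    run = len(insert) - len(insert.lstrip("G"))
    for k in range(0, run + 1):
        t = insert[k:]
        if len(t) < min_anchor:
            break
        pos = seq.find(t)
        if pos >= 0:
            return EndCall5(pos - construct.plus_one, k, classify_cap(k))
    return None


Weighted3 = Tuple[Optional[EndCall3], float]
Weighted5 = Tuple[Optional[EndCall5], float]


def _offset_of(call: Union[EndCall3, EndCall5]) -> int:
    return call.end_offset if isinstance(call, EndCall3) else call.start_offset


def end_distribution(calls: Sequence[Union[Weighted3, Weighted5]],
                     window: Tuple[int, int] = DEFAULT_WINDOW_3P) -> EndDistribution:
    """Weighted end-offset proportions within a display window.

    Unassigned calls (None) and offsets outside ``window`` (inclusive bounds)
    are pooled into "other"; proportions sum to 1.
    """
    if not calls:
        raise ValueError("no calls to summarise")
    lo, hi = window
    weights: Dict[Union[int, str], float] = {off: 0.0 for off in range(lo, hi + 1)}
    weights["other"] = 0.0
    total = 0.0
    for call, w in calls:
        if w <= 0:
            raise ValueError("weights must be positive")
        total += w
        if call is None or not (lo <= _offset_of(call) <= hi):
            weights["other"] += w
        else:
            weights[_offset_of(call)] += w
    return EndDistribution({k: v / total for k, v in weights.items()}, total)


def modification_spectrum(calls: Sequence[Union[Weighted3, Weighted5]]) -> ModificationSpectrum:
    """Weighted proportions over modification classes.

    3' calls are summarised over the uridylation classes none/monoU/diU/
    oligoU/other; 5' calls over their leading-G counts.  Unassigned calls
    count as "other".
    """
    if not calls:
        raise ValueError("no calls to summarise")
    assigned = [c for c, _ in calls if c is not None]
    is3 = all(isinstance(c, EndCall3) for c in assigned)
    weights: Dict[Union[int, str], float] = (
        {cls: 0.0 for cls in TAIL_CLASSES} if is3 else {"other": 0.0}
    )
    total = 0.0
    for call, w in calls:
        if w <= 0:
            raise ValueError("weights must be positive")
        total += w
        if call is None:
            weights["other"] = weights.get("other", 0.0) + w
        elif isinstance(call, EndCall3):
            weights[call.tail_class] += w
        else:
            weights[call.leading_g] = weights.get(call.leading_g, 0.0) + w
    return ModificationSpectrum({k: v / total for k, v in weights.items()}, total)


def cap_fraction(calls: Sequence[Weighted5], level: float = 0.95) -> CapFraction:
    """Capped fraction = w(capped) / (w(capped) + w(uncapped)).

    Calls in class "other" (leader counts other than 3 or 4) and unassigned
    calls are excluded.  The Clopper–Pearson interval is computed on the
    rounded integer weights.
    """
    w_cap = sum(w for c, w in calls if c is not None and c.cap_class == "capped")
    w_unc = sum(w for c, w in calls if c is not None and c.cap_class == "uncapped")
    denom = w_cap + w_unc
    if denom <= 0:
        raise ValueError("no capped or uncapped calls")
    est = w_cap / denom
    k, n = int(round(w_cap)), int(round(denom))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return CapFraction(est, lo, hi, w_cap, w_unc)
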