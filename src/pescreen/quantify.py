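"""Classification of editing outcomes and the screen's frequency statistics.

Assigned reads are compared against the pair's wide-target references.  A
read is an intended edit only when the excised region equals the edited
reference exactly — the desired edit present but free of any additional
mutation inside the wide target.  Frequencies are simple read-count ratios;
the adjusted fold change adds a 0.1% pseudocount to both efficiencies so a
0% baseline is defined and near-zero ratios are damped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .library_io import PairDesign, ReadRecord

__all__ = [
    "Outcome",
    "OutcomeCounts",
    "EfficiencyRecord",
    "FoldChangeRecord",
    "SubstitutionWindow",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_READS",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_PE2_THRESHOLD",
    "locate_wide_region",
    "classify_read",
    "tally_pair",
    "library_efficiency",
    "endogenous_frequencies",
    "substitution_window_counts",
    "unintended_substitution_rate",
    "coverage_filter",
    "adjusted_fold_change",
    "fold_change_table",
    "stratify_by_pe2",
]

DEFAULT_MIN_READS = 100
DEFAULT_PSEUDOCOUNT = 0.1  # percent
DEFAULT_PE2_THRESHOLD = 1.0  # percent
DEFAULT_WINDOW = (-10, 25)  # inclusive offsets from the nick
ANCHOR_LENGTH = 10


class Outcome(str, Enum):
    INTENDED = "INTENDED"
    UNINTENDED_EDIT = "UNINTENDED_EDIT"
    INDEL = "INDEL"
    WILDTYPE = "WILDTYPE"
    DISCARD = "DISCARD"


@dataclass
class OutcomeCounts:
    """Per-pair read tallies.  Discarded reads are excluded from n_total."""

    pair_id: str
    n_intended: int = 0
    n_unintended_edit: int = 0
    n_indel: int = 0
    n_wildtype: int = 0
    n_discarded: int = 0

    @property
    def n_total(self) -> int:
        return self.n_intended + self.n_unintended_edit + self.n_indel + self.n_wildtype


@dataclass
class EfficiencyRecord:
    pair_id: str
    intended_pct: float
    unintended_pct: float
    indel_pct: float
    n_total: int

    @property
    def passes_coverage(self) -> bool:
        return self.n_total >= DEFAULT_MIN_READS


@dataclass
class FoldChangeRecord:
    pair_id: str
    pe2_pct: float
    hype2_pct: float
    raw_fold: Optional[float]
    adjusted_fold: float

    @property
    def pe2_ge_1pct(self) -> bool:
        return self.pe2_pct >= DEFAULT_PE2_THRESHOLD


@dataclass
class SubstitutionWindow:
    """Per-position substitution read counts over nick offsets."""

    start_offset: int = DEFAULT_WINDOW[0]
    end_offset: int = DEFAULT_WINDOW[1]
    counts: Optional[dict[int, int]] = None

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = {o: 0 for o in range(self.start_offset, self.end_offset + 1)}


# ---------------------------------------------------------------------------
# read classification

def locate_wide_region(read_seq: str, pair: PairDesign) -> Optional[str]:
    """Excise the wide-target region between the 10-nt flanking anchors.

    Exact anchor match; the first in-order occurrence wins.  Returns None
    when either anchor is absent (the read is discarded).
    """
    a5 = pair.flank5[-ANCHOR_LENGTH:]
    a3 = pair.flank3[:ANCHOR_LENGTH]
    i = read_seq.find(a5)
    if i < 0:
        return None
    j = read_seq.find(a3, i + ANCHOR_LENGTH)
    if j < 0:
        return None
    return read_seq[i + ANCHOR_LENGTH: j]


def _has_indel(region: str, reference: str) -> bool:
    aln = edlib.align(region, reference, task="path")
    return "I" in aln["cigar"] or "D" in aln["cigar"]


def classify_read(read_seq: str, pair: PairDesign) -> Outcome:
    """Classify one assigned read against the pair's references.

    Precedence: exact match to the edited reference is INTENDED; exact match
    to the unedited reference is WILDTYPE; a length change or a gapped
    alignment with an insertion/deletion (against whichever reference is
    closer) is INDEL — so an intended edit carried alongside an extra indel
    counts as INDEL, while an intended insertion/deletion alone is INTENDED;
    any remaining substitution-only mismatch is UNINTENDED_EDIT.
    """
    region = locate_wide_region(read_seq, pair)
    if region is None:
        return Outcome.DISCARD
    if region == pair.edited_wide_target:
        return Outcome.INTENDED
    if region == pair.wide_target:
        return Outcome.WILDTYPE
    if len(region) != len(pair.wide_target) and len(region) != len(pair.edited_wide_target):
        return Outcome.INDEL
    # same length as one reference: align against the closer one
    d_wt = edlib.align(region, pair.wide_target)["editDistance"]
    d_ed = edlib.align(region, pair.edited_wide_target)["editDistance"]
    reference = pair.wide_target if d_wt <= d_ed else pair.edited_wide_target
    if _has_indel(region, reference):
        return Outcome.INDEL
    return Outcome.UNINTENDED_EDIT


def tally_pair(reads: Iterable[str | ReadRecord], pair: PairDesign) -> OutcomeCounts:
    """Tally classification outcomes for the reads assigned to one pair."""
    counter: Counter[Outcome] = Counter()
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        counter[classify_read(seq, pair)] += 1
    return OutcomeCounts(
        pair_id=pair.pair_id,
        n_intended=counter[Outcome.INTENDED],
        n_unintended_edit=counter[Outcome.UNINTENDED_EDIT],
        n_indel=counter[Outcome.INDEL],
        n_wildtype=counter[Outcome.WILDTYPE],
        n_discarded=counter[Outcome.DISCARD],
    )


# ---------------------------------------------------------------------------
# frequency statistics

def library_efficiency(counts: OutcomeCounts) -> Optional[float]:
    """Intended-edit frequency in percent; None when the pair has no reads
    (such pairs are excluded downstream)."""
    if counts.n_total == 0:
        return None
    return 100.0 * counts.n_intended / counts.n_total


def endogenous_frequencies(counts: OutcomeCounts) -> tuple[float, float, float]:
    """(intended %, unintended-edit %, indel %) out of total assigned reads."""
    total = counts.n_total
    if total == 0:
        return (0.0, 0.0, 0.0)
    return (
        100.0 * counts.n_intended / total,
        100.0 * counts.n_unintended_edit / total,
        100.0 * counts.n_indel / total,
    )


def substitution_window_counts(
    reads: Iterable[str | ReadRecord],
    pair: PairDesign,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> SubstitutionWindow:
    """Count substituted reads per nick offset across the analysis window.

    Only reads whose excised region is indel-free (same length as the
    unedited reference, mismatches only) contribute, so indel reads are not
    double-counted as substitutions.  Offsets covered by an intended
    substitution edit are skipped — those mismatches are the edit itself.
    Offset 0 is the first base 3' of the nick; negative offsets are upstream.
    """
    win = SubstitutionWindow(start_offset=window[0], end_offset=window[1])
    nick = pair.nick_index
    wide = pair.wide_target
    intended_positions: set[int] = set()
    if pair.edit.kind == "substitution":
        start = nick + pair.edit.offset_from_nick
        intended_positions = set(range(start, start + len(pair.edit.payload)))
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        region = locate_wide_region(seq, pair)
        if region is None or len(region) != len(wide):
            continue
        if _has_indel(region, wide):
            continue
        for offset in range(win.start_offset, win.end_offset + 1):
            pos = nick + offset
            if pos < 0 or pos >= len(wide) or pos in intended_positions:
                continue
            if region[pos] != wide[pos]:
                win.counts[offset] += 1
    return win


def unintended_substitution_rate(window: SubstitutionWindow, total_reads: int) -> float:
    """Average the per-position substitution counts over the window and
    express as percent of total reads."""
    if not window.counts:
        raise ValueError("substitution window is empty")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    mean_count = float(np.mean(list(window.counts.values())))
    return 100.0 * mean_count / total_reads


def coverage_filter(
    records: Sequence[EfficiencyRecord] | Sequence[OutcomeCounts],
    min_reads: int = DEFAULT_MIN_READS,
) -> list:
    """Retain pairs with at least ``min_reads`` assigned reads (99 out, 100 in)."""
    return [r for r in records if r.n_total >= min_reads]


def adjusted_fold_change(
    pe2_pct: float, hype2_pct: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Pseudocounted efficiency ratio (hyPE2% + 0.1%) / (PE2% + 0.1%).

    Defined for a 0% baseline and damps fold changes computed from
    near-noise efficiencies: 0.015% -> 0.15% gives 2.2-fold rather than
    10-fold, while 1.5% -> 15% gives 9.4-fold.
    """
    if pe2_pct < 0 or hype2_pct < 0:
        raise ValueError("efficiencies must be non-negative percentages")
    return (hype2_pct + pseudocount) / (pe2_pct + pseudocount)


def fold_change_table(
    efficiencies: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[FoldChangeRecord]:
    """Build fold-change records from a frame with columns
    pair_id, pe2_pct, hype2_pct."""
    records = []
    for row in efficiencies.itertuples(index=False):
        pe2, hy = float(row.pe2_pct), float(row.hype2_pct)
        raw = hy / pe2 if pe2 > 0 else None
        records.append(FoldChangeRecord(
            pair_id=row.pair_id, pe2_pct=pe2, hype2_pct=hy, raw_fold=raw,
            adjusted_fold=adjusted_fold_change(pe2, hy, pseudocount)))
    return records


def stratify_by_pe2(
    records: Sequence[FoldChangeRecord],
    threshold: float = DEFAULT_PE2_THRESHOLD,
    rescue_threshold: float = 1.0,
) -> dict[str, list[FoldChangeRecord]]:
    """Partition by baseline PE2 efficiency.

    ``high`` (PE2 >= threshold) is the stratum kept for fold-change
    statistics; ``low`` is excluded as noise-dominated; ``rescued`` is the
    subset of low-baseline pairs that hyPE2 nonetheless pushed to >= 1%.
    """
    high = [r for r in records if r.pe2_pct >= threshold]
    low = [r for r in records if r.pe2_pct < threshold]
    rescued = [r for r in low if r.hype2_pct >= rescue_threshold]
    return {"high": high, "low": low, "rescued": rescued}


# ---------------------------------------------------------------------------
# frame exports

def counts_to_frame(counts: Sequence[OutcomeCounts]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(pair_id=c.pair_id, n_total=c.n_total, n_intended=c.n_intended,
             n_unintended_edit=c.n_unintended_edit, n_indel=c.n_indel,
             n_wildtype=c.n_wildtype, n_discarded=c.n_discarded)
        for c in counts
    ])


def efficiencies_to_frame(records: Sequence[EfficiencyRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(pair_id=r.pair_id, intended_pct=r.intended_pct,
             unintended_pct=r.unintended_pct, indel_pct=r.indel_pct,
             n_total=r.n_total, passes_coverage=r.passes_coverage)
        for r in records
    ])


def fold_changes_to_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(pair_id=r.pair_id, pe2_pct=r.pe2_pct, hype2_pct=r.hype2_pct,
             raw_fold=r.raw_fold, adjusted_fold=r.adjusted_fold,
             pe2_ge_1pct=r.pe2_ge_1pct)
        for r in records
    ])
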