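"""Synthetic screen generators: library designer, read simulator, and a
fold-change table with a planted PBS-melting-temperature effect.

Everything is seed-deterministic.  The library designer mirrors the real
screen's arithmetic: a base set of deletion-, insertion- and
substitution-inducing pegRNAs (1:1:2 mix), a subset re-issued as PAM-silent
variants that add a synonymous NGG change to the intended edit, and three
barcodes per pegRNA.  The read simulator plants per-pair outcome
proportions and confines sequencing error to regions that do not carry the
demultiplexing key or the wide target, so planted rates survive the full
quantification path exactly up to multinomial sampling.  The fold-change
simulator draws log adjusted fold change as a linear function of the PBS
melting temperature plus Gaussian noise — fold increases that shrink as
the PBS binds more tightly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .features import melting_temperature
from .library_io import (EditSpec, PairDesign, ReadRecord, apply_edit,
                         NICK_OFFSET_IN_PROTOSPACER)

__all__ = [
    "LibraryDesignConfig",
    "ScreenTruth",
    "EffectModelConfig",
    "DesignedLibrary",
    "design_library",
    "simulate_reads",
    "simulate_fold_table",
    "random_dna",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

FLANK5 = "GTTCACTGCC"
FLANK3 = "GGCAGTGAAC"
READ_TAIL = "AGCTTGGCGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass
class LibraryDesignConfig:
    """Library designer settings.

    Defaults mirror the screened library: 507 base pegRNAs in a
    deletion:insertion:substitution mix of 100:100:200 (normalized), a
    158/507 fraction re-issued as PAM-silent variants, and three barcodes
    per pegRNA (507 + 158 = 665 pegRNAs, 665 x 3 = 1,995 oligos).
    """

    n_base_pegrnas: int = 507
    edit_mix: tuple[float, float, float] = (100.0, 100.0, 200.0)  # del, ins, sub
    pam_silent_fraction: float = 158 / 507
    barcodes_per_pegrna: int = 3
    pbs_length_range: tuple[int, int] = (7, 17)
    rt_length_range: tuple[int, int] = (10, 23)
    min_barcode_distance: int = 3
    seed: int = 0


@dataclass
class ScreenTruth:
    """Planted per-pair outcome proportions and depths.

    ``rates`` columns: pair_id, intended_rate, unintended_rate, indel_rate,
    depth.  ``seq_error_rate`` is a per-base substitution error applied
    outside the 22-nt key and outside the wide target (it can corrupt the
    flanking anchors, discarding the read, which leaves the outcome
    proportions unbiased).  ``key_errors`` optionally lets errors hit the
    key so assignment loss can be measured.
    """

    rates: pd.DataFrame
    seq_error_rate: float = 0.001
    key_errors: bool = False

    def __post_init__(self) -> None:
        r = self.rates
        needed = {"pair_id", "intended_rate", "unintended_rate", "indel_rate", "depth"}
        if not needed <= set(r.columns):
            raise ValueError(f"truth table missing columns {needed - set(r.columns)}")
        probs = r[["intended_rate", "unintended_rate", "indel_rate"]].to_numpy()
        if (probs < 0).any() or (probs.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("outcome rates must be >= 0 and sum to <= 1")
        if (r["depth"] < 0).any():
            raise ValueError("depth must be >= 0")

    @classmethod
    def uniform(cls, pair_ids: Sequence[str], intended: float = 0.12,
                unintended: float = 0.01, indel: float = 0.03,
                depth: int = 5000, **kwargs) -> "ScreenTruth":
        return cls(rates=pd.DataFrame({
            "pair_id": list(pair_ids),
            "intended_rate": intended, "unintended_rate": unintended,
            "indel_rate": indel, "depth": depth}), **kwargs)


@dataclass
class EffectModelConfig:
    """Planted fold-change effect: log F = intercept + slope * Tm(PBS) + eps.

    The default slope is negative — the fold increase shrinks as the PBS
    melts higher — with magnitudes chosen so typical folds sit around
    1-2.5x across the PBS-Tm range of 7-17-nt primers.  ``sub1_fraction``
    of pairs draw their baseline PE2 efficiency below 1% so the exclusion
    stratum is populated.
    """

    intercept: float = 1.0
    slope: float = -0.02  # per deg C, on the natural-log fold scale
    noise_sd: float = 0.15
    sub1_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class DesignedLibrary:
    pairs: list[PairDesign]
    n_pegrnas: int
    n_base: int
    n_variants: int
    n_oligos: int
    config: LibraryDesignConfig


# ---------------------------------------------------------------------------
# library design

def _distinct_barcodes(rng: np.random.Generator, n: int, length: int = 18,
                       min_distance: int = 3, max_rounds: int = 50) -> list[str]:
    """Sample barcodes with pairwise Hamming distance >= min_distance."""
    codes = rng.integers(0, 4, size=(n, length), dtype=np.int8)
    for _ in range(max_rounds):
        bad: set[int] = set()
        for start in range(0, n, 512):
            chunk = codes[start:start + 512]
            # pairwise Hamming distances chunk vs all
            d = (chunk[:, None, :] != codes[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d < min_distance)
            for a, b in zip(ii + start, jj):
                if a != b:
                    bad.add(max(a, b))
        if not bad:
            return ["".join(_BASES[c] for c in row) for row in codes]
        for i in bad:
            codes[i] = rng.integers(0, 4, size=length, dtype=np.int8)
    raise RuntimeError("could not satisfy the barcode distance constraint")


def _make_base_design(rng: np.random.Generator, idx: int, edit_kind: str,
                      cfg: LibraryDesignConfig) -> dict:
    """Draw one pegRNA/target design (sans barcode)."""
    # wide target: 4 upstream + 20 protospacer + NGG + 20 downstream = 47 nt
    while True:
        spacer = random_dna(rng, 20)
        up = random_dna(rng, 4)
        pam = random_dna(rng, 1) + "GG"
        down = random_dna(rng, 20)
        wide = up + spacer + pam + down
        if wide.count(spacer) == 1:
            break
    nick = 4 + NICK_OFFSET_IN_PROTOSPACER
    rt_len = int(rng.integers(cfg.rt_length_range[0], cfg.rt_length_range[1] + 1))
    pbs_len = int(rng.integers(cfg.pbs_length_range[0], cfg.pbs_length_range[1] + 1))
    if edit_kind == "substitution":
        offset = int(rng.integers(0, max(1, rt_len - 3)))
        ref_base = wide[nick + offset]
        payload = str(rng.choice([b for b in "ACGT" if b != ref_base]))
    elif edit_kind == "insertion":
        offset = 0
        payload = random_dna(rng, int(rng.integers(1, 4)))
    else:  # deletion
        offset = 0
        length = int(rng.integers(1, 4))
        payload = wide[nick:nick + length]
    edit = EditSpec(kind=edit_kind, offset_from_nick=offset, payload=payload)
    edited = apply_edit(wide, nick, edit)
    # PBS primes the nicked strand; RT template is copied from the edited strand
    pbs = revcomp(wide[nick - pbs_len:nick])
    rt_template = revcomp(edited[nick:nick + rt_len])
    return dict(idx=idx, spacer=spacer, wide=wide, edited=edited, edit=edit,
                pbs=pbs, rt_template=rt_template, nick=nick)


def _pam_silent_variant(base: dict) -> dict:
    """Re-issue a design with an additional synonymous change in the PAM.

    The first PAM G (wide-target index 25) becomes C in the edited target
    and the RT template is recomputed to write both changes.
    """
    wide = base["wide"]
    edit = base["edit"]
    nick = base["nick"]
    pam_g_index = 25  # 4 upstream + 20 spacer + 1 (N of NGG)
    edited = apply_edit(wide, nick, edit)
    shift = 0
    if edit.kind == "insertion":
        shift = len(edit.payload)
    elif edit.kind == "deletion":
        shift = -len(edit.payload)
    pos = pam_g_index + shift
    edited = edited[:pos] + "C" + edited[pos + 1:]
    rt_len = len(base["rt_template"])
    # the PAM edit sits +4 from the nick; make sure the RT template spans it
    rt_len = max(rt_len, pos - nick + 2)
    variant = dict(base)
    variant["edited"] = edited
    variant["rt_template"] = revcomp(edited[nick:nick + rt_len])
    return variant


def design_library(config: Optional[LibraryDesignConfig] = None) -> DesignedLibrary:
    """Generate a full pair table plus the library arithmetic.

    One PairDesign is emitted per oligo (pegRNA x barcode); pair ids are
    ``P<idx>[v]_b<k>`` where the ``v`` marks a PAM-silent variant.
    """
    cfg = config or LibraryDesignConfig()
    rng = np.random.default_rng(cfg.seed)
    mix = np.asarray(cfg.edit_mix, dtype=float)
    mix = mix / mix.sum()
    n_del = int(round(mix[0] * cfg.n_base_pegrnas))
    n_ins = int(round(mix[1] * cfg.n_base_pegrnas))
    n_sub = cfg.n_base_pegrnas - n_del - n_ins
    kinds = ["deletion"] * n_del + ["insertion"] * n_ins + ["substitution"] * n_sub

    bases = [_make_base_design(rng, i, kind, cfg) for i, kind in enumerate(kinds)]
    n_variants = int(round(cfg.pam_silent_fraction * cfg.n_base_pegrnas))
    variant_idx = sorted(rng.choice(len(bases), size=n_variants, replace=False))
    pegrnas = [(b, False) for b in bases] + [(_pam_silent_variant(bases[i]), True)
                                             for i in variant_idx]

    n_pegrnas = len(pegrnas)
    n_oligos = n_pegrnas * cfg.barcodes_per_pegrna
    barcodes = _distinct_barcodes(rng, n_oligos, min_distance=cfg.min_barcode_distance)

    pairs: list[PairDesign] = []
    b = 0
    for design, is_variant in pegrnas:
        stem = f"P{design['idx']:04d}" + ("v" if is_variant else "")
        for k in range(cfg.barcodes_per_pegrna):
            pair = PairDesign(
                pair_id=f"{stem}_b{k + 1}",
                spacer=design["spacer"], pbs=design["pbs"],
                rt_template=design["rt_template"], barcode=barcodes[b],
                upstream4=random_dna(rng, 4), wide_target=design["wide"],
                edited_wide_target=design["edited"], edit=design["edit"],
                flank5=FLANK5, flank3=FLANK3,
            ).validate()
            pairs.append(pair)
            b += 1
    return DesignedLibrary(pairs=pairs, n_pegrnas=n_pegrnas,
                           n_base=cfg.n_base_pegrnas, n_variants=n_variants,
                           n_oligos=n_oligos, config=cfg)


# ---------------------------------------------------------------------------
# read simulation

def _indel_template(rng: np.random.Generator, wide: str, nick: int) -> str:
    """A spurious 1-3-nt indel at the nick, distinct from the intended edit."""
    length = int(rng.integers(1, 4))
    if rng.random() < 0.5 and nick + length <= len(wide):
        return wide[:nick] + wide[nick + length:]
    return wide[:nick] + random_dna(rng, length) + wide[nick:]


def _substitution_template(rng: np.random.Generator, pair: PairDesign,
                           window: tuple[int, int] = (-10, 25)) -> str:
    """Wild-type region carrying one unintended substitution near the nick."""
    wide = pair.wide_target
    nick = pair.nick_index
    for _ in range(20):
        offset = int(rng.integers(window[0], window[1] + 1))
        pos = nick + offset
        if 0 <= pos < len(wide):
            break
    base = wide[pos]
    sub = str(rng.choice([b for b in "ACGT" if b != base]))
    return wide[:pos] + sub + wide[pos + 1:]


def simulate_reads(
    pairs: Sequence[PairDesign],
    truth: ScreenTruth,
    seed: int = 0,
) -> Iterator[tuple[ReadRecord, str, str]]:
    """Yield (read, pair_id, outcome_label) triples with planted proportions.

    Per pair, ``depth`` reads are drawn from a multinomial over
    {intended, unintended, indel, wildtype}; each read is the amplicon
    flank5 ++ region ++ flank3 ++ upstream4 ++ barcode ++ tail with
    per-base substitution errors outside the protected spans.  Labels name
    the planted outcome, which is the classification ground truth.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.pair_id: p for p in pairs}
    rates = truth.rates.set_index("pair_id")
    missing = set(rates.index) - set(by_id)
    if missing:
        raise ValueError(f"truth table covers unknown pairs: {sorted(missing)[:5]}")
    for pid, row in rates.iterrows():
        pair = by_id[pid]
        depth = int(row["depth"])
        if depth == 0:
            continue
        probs = [row["intended_rate"], row["unintended_rate"], row["indel_rate"]]
        probs.append(1.0 - sum(probs))
        counts = rng.multinomial(depth, probs)
        labels = np.array(["intended"] * counts[0] + ["unintended"] * counts[1]
                          + ["indel"] * counts[2] + ["wildtype"] * counts[3])
        rng.shuffle(labels)
        for r, label in enumerate(labels):
            if label == "intended":
                region = pair.edited_wide_target
            elif label == "wildtype":
                region = pair.wide_target
            elif label == "indel":
                region = _indel_template(rng, pair.wide_target, pair.nick_index)
                # a spurious indel whose length matches the edited reference
                # could read as a substitution-only variant of the intended
                # edit; redraw so the planted label stays unambiguous
                while len(region) == len(pair.edited_wide_target):
                    region = _indel_template(rng, pair.wide_target, pair.nick_index)
            else:
                region = _substitution_template(rng, pair)
                while region == pair.edited_wide_target:
                    region = _substitution_template(rng, pair)
            seq = pair.flank5 + region + pair.flank3 + pair.upstream4 + pair.barcode + READ_TAIL
            if truth.seq_error_rate > 0:
                seq = _apply_errors(rng, seq, pair, region, truth)
            yield (ReadRecord(read_id=f"{pid}:{r}", sequence=seq),
                   pid, label)


def _apply_errors(rng: np.random.Generator, seq: str, pair: PairDesign,
                  region: str, truth: ScreenTruth) -> str:
    """Per-base substitution errors outside the protected spans.

    Protected by default: the wide-target region (so planted outcome labels
    stay exact) and the 22-nt key (so demultiplexing truth is exact).
    """
    region_start = len(pair.flank5)
    region_end = region_start + len(region)
    key_start = region_end + len(pair.flank3)
    key_end = key_start + 22
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < truth.seq_error_rate)[0]
    for i in hits:
        if region_start <= i < region_end:
            continue
        if not truth.key_errors and key_start <= i < key_end:
            continue
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


# ---------------------------------------------------------------------------
# fold-change simulation

def simulate_fold_table(
    pairs: Sequence[PairDesign],
    effect: Optional[EffectModelConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fold-change table with a planted linear PBS-Tm effect.

    Columns: pair_id, pbs_tm, pe2_pct, hype2_pct, adjusted_fold (realized,
    recomputed from the drawn efficiencies), planted_log_fold.  PE2
    efficiencies come from a mixture with a sub-1% stratum; hyPE2
    efficiencies follow from the planted adjusted fold and are floored at 0
    (with the default effect scale the floor is essentially never hit).
    """
    cfg = effect or EffectModelConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for pair in pairs:
        tm = melting_temperature(pair.pbs)
        log_fold = cfg.intercept + cfg.slope * tm + rng.normal(0.0, cfg.noise_sd)
        if rng.random() < cfg.sub1_fraction:
            pe2 = float(rng.uniform(0.01, 0.99))
        else:
            pe2 = float(10 ** rng.uniform(0.0, 1.6))  # 1% .. ~40%
        hype2 = max(0.0, (pe2 + 0.1) * float(np.exp(log_fold)) - 0.1)
        adjusted = (hype2 + 0.1) / (pe2 + 0.1)
        rows.append(dict(pair_id=pair.pair_id, pbs_tm=tm, pe2_pct=pe2,
                         hype2_pct=hype2, adjusted_fold=adjusted,
                         planted_log_fold=log_fold))
    return pd.DataFrame(rows)
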