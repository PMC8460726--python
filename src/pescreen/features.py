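"""Fixed 1,820-feature encoding of a pegRNA / wide-target pair.

The encoding combines position-dependent nucleotide and dinucleotide
one-hots over the 47-nt wide target and the 42-nt pegRNA-extension window,
position-independent (di)nucleotide counts, nearest-neighbor melting
temperatures, GC content, the minimum self-folding free energy of the
pegRNA 3' extension, and an on-target activity score supplied by a
pluggable scorer.  The layout is a registry serialized alongside every
model, so an alternative breakdown with the same total can be swapped in
without touching the learners.

Feature-budget arithmetic (total 1,820):

* wide target, 47 nt fixed (4 nt upstream + 20-nt protospacer + NGG PAM +
  20 nt downstream): mono 4 x 47 = 188, di 16 x 46 = 736
* pegRNA 3' extension (RT template ++ PBS), right-aligned in a 42-nt
  window, left-padded with all-zero columns: mono 4 x 42 = 168,
  di 16 x 41 = 656
* position-independent mono (4) + di (16) counts for each of wide target,
  PBS, RT template: 60
* scalars (12): Tm of the PBS:target duplex, Tm of the RT template against
  the DNA it synthesizes (RNA/DNA-hybrid table), Tm of the full extension,
  the PBS-minus-RT Tm difference; GC count and GC fraction of PBS, RT
  template and extension; self-folding MFE of the extension; on-target
  score.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .library_io import PairDesign, ValidationError

__all__ = [
    "FeatureLayout",
    "FeatureVector",
    "build_layout",
    "extract_features",
    "feature_matrix",
    "melting_temperature",
    "self_folding_mfe",
    "deep_spcas9_score",
    "gc_count",
    "WIDE_TARGET_LENGTH",
    "EXTENSION_WINDOW",
    "TOTAL_FEATURES",
]

BASES = "ACGT"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=2)]
WIDE_TARGET_LENGTH = 47
EXTENSION_WINDOW = 42
TOTAL_FEATURES = 1820

SCALAR_NAMES = [
    "tm_pbs", "tm_rt", "tm_ext", "dtm_pbs_rt",
    "gc_cnt_pbs", "gc_cnt_rt", "gc_cnt_ext",
    "gc_frac_pbs", "gc_frac_rt", "gc_frac_ext",
    "mfe_ext", "spcas9_score",
]

GROUPS = (
    "POSDEP_MONO_TARGET", "POSDEP_DI_TARGET",
    "POSDEP_MONO_EXT", "POSDEP_DI_EXT",
    "POSINDEP_COUNTS", "SCALARS",
)


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered registry of (group, name) entries defining the vector."""

    entries: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.entries]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def group_slice(self, group: str) -> slice:
        idx = [i for i, (g, _) in enumerate(self.entries) if g == group]
        if not idx:
            raise KeyError(group)
        return slice(idx[0], idx[-1] + 1)

    @property
    def checksum(self) -> str:
        payload = "\n".join(f"{g}\t{n}" for g, n in self.entries).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"checksum": self.checksum,
                       "entries": [list(e) for e in self.entries]}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureLayout":
        with open(path) as fh:
            data = json.load(fh)
        return cls(entries=tuple((g, n) for g, n in data["entries"]))


@dataclass(frozen=True)
class FeatureVector:
    pair_id: str
    values: np.ndarray


def build_layout() -> FeatureLayout:
    entries: list[tuple[str, str]] = []
    for p in range(WIDE_TARGET_LENGTH):
        entries += [("POSDEP_MONO_TARGET", f"target_mono_p{p:02d}_{b}") for b in BASES]
    for p in range(WIDE_TARGET_LENGTH - 1):
        entries += [("POSDEP_DI_TARGET", f"target_di_p{p:02d}_{d}") for d in DINUCLEOTIDES]
    for p in range(EXTENSION_WINDOW):
        entries += [("POSDEP_MONO_EXT", f"ext_mono_p{p:02d}_{b}") for b in BASES]
    for p in range(EXTENSION_WINDOW - 1):
        entries += [("POSDEP_DI_EXT", f"ext_di_p{p:02d}_{d}") for d in DINUCLEOTIDES]
    for region in ("target", "pbs", "rt"):
        entries += [("POSINDEP_COUNTS", f"{region}_cnt_{b}") for b in BASES]
        entries += [("POSINDEP_COUNTS", f"{region}_cnt_{d}") for d in DINUCLEOTIDES]
    entries += [("SCALARS", n) for n in SCALAR_NAMES]
    layout = FeatureLayout(entries=tuple(entries))
    assert len(layout) == TOTAL_FEATURES
    return layout


_LAYOUT = build_layout()


# ---------------------------------------------------------------------------
# thermodynamics

def melting_temperature(seq: str, mode: str = "dna_dna") -> float:
    """Nearest-neighbor melting temperature in deg C.

    ``dna_dna`` uses the MeltingTemp default parameter set (Allawi &
    SantaLucia 1997 table, 50 mM Na+, 25 nM strand, entropy-based salt
    correction); ``rna_dna`` swaps in the RNA/DNA-hybrid table (Sugimoto
    1995) for segments that pair with an RNA strand.
    """
    if len(seq) < 2:
        raise ValueError("melting temperature needs at least 2 nt")
    if mode == "dna_dna":
        return float(_mt.Tm_NN(seq))
    if mode == "rna_dna":
        return float(_mt.Tm_NN(seq, nn_table=_mt.R_DNA_NN1))
    raise ValueError(f"unknown Tm mode {mode!r}")


# Bundled minimal RNA folding model: Watson-Crick pairs only, hairpin loops
# of >= 3 unpaired bases, and free energy equal to the sum of stacking
# energies of directly nested adjacent pairs (kcal/mol, Turner-style WC/WC
# stack values).  Isolated (unstacked) pairs contribute 0, so a sequence
# with no complementary stretch of length >= 2 cannot fold below 0.
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_STACK = {
    ("AU", "AU"): -0.9, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1, ("AU", "UA"): -1.1,
    ("CG", "AU"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4, ("CG", "UA"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3, ("GC", "UA"): -2.2,
    ("UA", "AU"): -1.3, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1, ("UA", "UA"): -0.9,
}
_MIN_HAIRPIN = 3


def _stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    return _STACK.get(("".join(outer), "".join(inner)), 0.0)


def _mfe_stacks(seq: str) -> float:
    """Exact minimum energy under the bundled stacking model (O(n^4) DP)."""
    n = len(seq)
    INF = float("inf")
    # C[i][j]: min energy of i..j given (i,j) paired; F[i][j]: unconstrained
    C = [[INF] * n for _ in range(n)]
    F = [[0.0] * (n + 1) for _ in range(n + 1)]  # F over half-open [i, j)

    def pairable(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in _WC and j - i - 1 >= _MIN_HAIRPIN

    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not pairable(i, j):
                continue
            best = 0.0  # hairpin closed by (i, j): no stack, energy 0
            if pairable(i + 1, j - 1):
                stacked = C[i + 1][j - 1] + _stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
                best = min(best, stacked)
            # inner structure not stacked on (i, j)
            best = min(best, _f_interval(seq, C, F, i + 1, j))
            C[i][j] = best
    return _f_interval(seq, C, F, 0, n)


def _f_interval(seq, C, F, i, j):
    """Min energy over the half-open interval [i, j), memoized in F."""
    # F is recomputed on demand; intervals are small so a direct DP suffices
    n = j - i
    if n <= _MIN_HAIRPIN:
        return 0.0
    best = [0.0] * (n + 1)  # best[k]: min energy of [i, i+k)
    for k in range(1, n + 1):
        b = best[k - 1]  # position i+k-1 unpaired
        for h in range(i, i + k - _MIN_HAIRPIN - 1 + 1):
            c = C[h][i + k - 1]
            if c < float("inf"):
                b = min(b, best[h - i] + c)
        best[k] = b
    return best[n]


def self_folding_mfe(seq: str, engine: str = "auto") -> float:
    """Minimum self-folding free energy (kcal/mol) of the sequence as RNA.

    ``engine`` is ``vienna`` (ViennaRNA MFE), ``stacks`` (the bundled
    stacking-energy model) or ``auto`` (vienna when importable, else
    stacks).  Always <= 0: the open chain has energy 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    rna = seq.upper().replace("T", "U")
    if engine == "auto":
        engine = "vienna" if _vienna_available() else "stacks"
    if engine == "vienna":
        import RNA

        _, mfe = RNA.fold(rna)
        return min(float(mfe), 0.0)
    if engine == "stacks":
        return _mfe_stacks(rna)
    raise ValueError(f"unknown folding engine {engine!r}")


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:
        return False


# ---------------------------------------------------------------------------
# on-target score plug-in

def deep_spcas9_score(
    pair: PairDesign,
    scorer: Optional[Callable[[str], float]] = None,
    score_table: Optional[Mapping[str, float]] = None,
    default: float = 0.0,
) -> tuple[float, Optional[str]]:
    """On-target activity score for the pair's protospacer.

    Resolution order: callable scorer on the spacer, then a precomputed
    table keyed by pair_id, then the configured constant (returned with a
    warning string for the manifest).  A table that lacks the pair is an
    error rather than a silent default.
    """
    if scorer is not None:
        return float(scorer(pair.spacer)), None
    if score_table is not None:
        if pair.pair_id not in score_table:
            raise KeyError(f"score table has no entry for pair {pair.pair_id}")
        return float(score_table[pair.pair_id]), None
    return default, f"no on-target scorer: constant {default} used for all pairs"


def load_score_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))


# ---------------------------------------------------------------------------
# encoding

def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def _one_hot_mono(vec: np.ndarray, offset: int, seq: str, start_pos: int) -> None:
    for k, base in enumerate(seq):
        vec[offset + (start_pos + k) * 4 + BASES.index(base)] = 1.0


def _one_hot_di(vec: np.ndarray, offset: int, seq: str, start_pos: int) -> None:
    for k in range(len(seq) - 1):
        di = DINUCLEOTIDES.index(seq[k:k + 2])
        vec[offset + (start_pos + k) * 16 + di] = 1.0


def _counts(seq: str) -> list[float]:
    mono = [float(seq.count(b)) for b in BASES]
    di = [float(sum(1 for k in range(len(seq) - 1) if seq[k:k + 2] == d))
          for d in DINUCLEOTIDES]
    return mono + di


def extract_features(
    pair: PairDesign,
    scorer: Optional[Callable[[str], float]] = None,
    score_table: Optional[Mapping[str, float]] = None,
    layout: FeatureLayout = _LAYOUT,
    mfe_engine: str = "auto",
) -> FeatureVector:
    """Encode one pair as the fixed-length feature vector.

    The wide target must be exactly 47 nt; the extension (RT template ++
    PBS) must fit the 42-nt right-aligned window.  Padding positions in the
    extension one-hot blocks are all-zero.
    """
    if len(pair.wide_target) != WIDE_TARGET_LENGTH:
        raise ValidationError(
            f"pair {pair.pair_id}: wide target must be {WIDE_TARGET_LENGTH} nt "
            f"for featurization, got {len(pair.wide_target)}")
    ext = pair.extension
    if len(ext) > EXTENSION_WINDOW:
        raise ValidationError(
            f"pair {pair.pair_id}: extension ({len(ext)} nt) exceeds the "
            f"{EXTENSION_WINDOW}-nt window")
    if set(pair.wide_target + ext) - set(BASES):
        raise ValidationError(f"pair {pair.pair_id}: non-ACGT base in sequences")

    vec = np.zeros(len(layout))
    off = 0
    _one_hot_mono(vec, off, pair.wide_target, 0)
    off += 4 * WIDE_TARGET_LENGTH
    _one_hot_di(vec, off, pair.wide_target, 0)
    off += 16 * (WIDE_TARGET_LENGTH - 1)
    pad = EXTENSION_WINDOW - len(ext)  # right-align, left-pad with zeros
    _one_hot_mono(vec, off, ext, pad)
    off += 4 * EXTENSION_WINDOW
    _one_hot_di(vec, off, ext, pad)
    off += 16 * (EXTENSION_WINDOW - 1)
    for seq in (pair.wide_target, pair.pbs, pair.rt_template):
        vals = _counts(seq)
        vec[off:off + 20] = vals
        off += 20

    tm_pbs = melting_temperature(pair.pbs)
    tm_rt = melting_temperature(pair.rt_template, mode="rna_dna")
    tm_ext = melting_temperature(ext)
    score, _ = deep_spcas9_score(pair, scorer=scorer, score_table=score_table)
    scalars = [
        tm_pbs, tm_rt, tm_ext, tm_pbs - tm_rt,
        float(gc_count(pair.pbs)), float(gc_count(pair.rt_template)), float(gc_count(ext)),
        gc_count(pair.pbs) / len(pair.pbs), gc_count(pair.rt_template) / len(pair.rt_template),
        gc_count(ext) / len(ext),
        self_folding_mfe(ext, engine=mfe_engine),
        score,
    ]
    vec[off:off + len(scalars)] = scalars
    off += len(scalars)
    assert off == len(layout)
    return FeatureVector(pair_id=pair.pair_id, values=vec)


def feature_matrix(
    pairs: Iterable[PairDesign],
    scorer: Optional[Callable[[str], float]] = None,
    score_table: Optional[Mapping[str, float]] = None,
    layout: FeatureLayout = _LAYOUT,
    mfe_engine: str = "auto",
) -> pd.DataFrame:
    """Pairs x features frame, indexed by pair_id, columns = layout names."""
    rows = {}
    for pair in pairs:
        fv = extract_features(pair, scorer=scorer, score_table=score_table,
                              layout=layout, mfe_engine=mfe_engine)
        rows[fv.pair_id] = fv.values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=layout.names)
    df.index.name = "pair_id"
    return df
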