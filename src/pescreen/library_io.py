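"""I/O and demultiplexing for barcoded prime-editing screen libraries.

A screen pairs every pegRNA with a surrogate copy of its target site,
integrated on the same amplicon next to a unique 18-nt barcode.  Reads are
assigned to pairs by exact match of a 22-nt key: the 4 nt immediately
upstream of the barcode followed by the barcode itself.
"""

from __future__ import annotations

import gzip
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "EditSpec",
    "PairDesign",
    "ReadRecord",
    "BarcodeIndex",
    "UNASSIGNED",
    "PairTableError",
    "ValidationError",
    "load_pair_table",
    "write_pair_table",
    "build_barcode_index",
    "assign_read",
    "assign_reads",
    "read_fastq",
    "write_fastq",
    "write_manifest",
]

DNA_ALPHABET = frozenset("ACGT")
KEY_LENGTH = 22
BARCODE_LENGTH = 18
UPSTREAM_LENGTH = 4
SPACER_LENGTH = 20
#: sentinel returned when a read cannot be assigned to any pair
UNASSIGNED = None

#: protospacer offset of the SpCas9 H840A nick (between positions 17 and 18)
NICK_OFFSET_IN_PROTOSPACER = 17


class PairTableError(ValueError):
    """Malformed pair-table file (missing columns, bad row)."""


class ValidationError(ValueError):
    """A PairDesign invariant is violated."""


def _check_dna(value: str, name: str, pair_id: str = "?") -> None:
    if not value or set(value) - DNA_ALPHABET:
        raise ValidationError(f"pair {pair_id}: field '{name}' is not ACGT DNA: {value!r}")


@dataclass(frozen=True)
class EditSpec:
    """The intended edit, expressed relative to the nick site.

    ``offset_from_nick`` is 0-based downstream of the nick: offset 0 is the
    first nucleotide 3' of the nick on the protospacer-containing strand
    (protospacer position 18).  ``payload`` is the substituted bases, the
    inserted bases, or the deleted bases depending on ``kind``.
    """

    kind: str  # substitution | insertion | deletion
    offset_from_nick: int
    payload: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        _check_dna(self.payload, "edit payload")
        if self.offset_from_nick < 0:
            raise ValidationError("edit offset must be >= 0 (downstream of the nick)")


@dataclass(frozen=True)
class PairDesign:
    """One pegRNA / integrated-target pair.

    ``wide_target`` is the reference region that reads are compared against:
    it contains the protospacer followed by an NGG PAM plus flanks.
    ``flank5``/``flank3`` are the 10-nt amplicon anchors immediately
    bordering the wide target, used to excise the region from a read.
    """

    pair_id: str
    spacer: str
    pbs: str
    rt_template: str
    barcode: str
    upstream4: str
    wide_target: str
    edited_wide_target: str
    edit: EditSpec
    flank5: str = "GTTCACTGCC"
    flank3: str = "GGCAGTGAAC"

    # -- derived geometry -------------------------------------------------
    @property
    def protospacer_start(self) -> int:
        return self.wide_target.index(self.spacer)

    @property
    def nick_index(self) -> int:
        """Index in ``wide_target`` of the first base 3' of the nick."""
        return self.protospacer_start + NICK_OFFSET_IN_PROTOSPACER

    @property
    def key(self) -> str:
        """22-nt demultiplexing key: upstream 4 nt ++ 18-nt barcode."""
        return self.upstream4 + self.barcode

    @property
    def extension(self) -> str:
        """pegRNA 3' extension, 5'->3': RT template then PBS (DNA alphabet)."""
        return self.rt_template + self.pbs

    def validate(self) -> "PairDesign":
        pid = self.pair_id
        for name in ("spacer", "pbs", "rt_template", "barcode", "upstream4",
                     "wide_target", "edited_wide_target", "flank5", "flank3"):
            _check_dna(getattr(self, name), name, pid)
        if len(self.barcode) != BARCODE_LENGTH:
            raise ValidationError(f"pair {pid}: barcode must be {BARCODE_LENGTH} nt, got {len(self.barcode)}")
        if len(self.upstream4) != UPSTREAM_LENGTH:
            raise ValidationError(f"pair {pid}: upstream4 must be {UPSTREAM_LENGTH} nt, got {len(self.upstream4)}")
        if len(self.spacer) != SPACER_LENGTH:
            raise ValidationError(f"pair {pid}: spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}")
        if not 7 <= len(self.pbs) <= 17:
            raise ValidationError(f"pair {pid}: PBS length {len(self.pbs)} outside 7-17 nt")
        if len(self.rt_template) < 4:
            raise ValidationError(f"pair {pid}: RT template shorter than 4 nt")
        if len(self.flank5) < 10 or len(self.flank3) < 10:
            raise ValidationError(f"pair {pid}: flanking anchors must be >= 10 nt")
        s = self.wide_target.find(self.spacer)
        if s < 0:
            raise ValidationError(f"pair {pid}: wide_target does not contain the protospacer")
        pam = self.wide_target[s + SPACER_LENGTH: s + SPACER_LENGTH + 3]
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValidationError(f"pair {pid}: protospacer not followed by NGG PAM (got {pam!r})")
        _check_edit_consistency(self)
        return self


def apply_edit(wide_target: str, nick_index: int, edit: EditSpec) -> str:
    """Apply an EditSpec to a wide-target sequence."""
    pos = nick_index + edit.offset_from_nick
    if edit.kind == "substitution":
        end = pos + len(edit.payload)
        if end > len(wide_target):
            raise ValidationError("substitution runs off the wide target")
        return wide_target[:pos] + edit.payload + wide_target[end:]
    if edit.kind == "insertion":
        return wide_target[:pos] + edit.payload + wide_target[pos:]
    # deletion
    end = pos + len(edit.payload)
    if wide_target[pos:end] != edit.payload:
        raise ValidationError(
            f"deletion payload {edit.payload!r} does not match reference {wide_target[pos:end]!r}")
    return wide_target[:pos] + wide_target[end:]


def _check_edit_consistency(pair: PairDesign) -> None:
    """edited_wide_target must equal wide_target with the edit applied,
    optionally plus a synonymous change confined to the PAM (PAM-silent
    library variants carry that extra substitution)."""
    expected = apply_edit(pair.wide_target, pair.nick_index, pair.edit)
    if expected == pair.edited_wide_target:
        return
    if len(expected) != len(pair.edited_wide_target):
        raise ValidationError(
            f"pair {pair.pair_id}: edited_wide_target inconsistent with edit spec (length)")
    s = pair.protospacer_start
    # PAM occupies wide-target indices s+20..s+22; map into edited coordinates
    shift = 0
    edit_pos = pair.nick_index + pair.edit.offset_from_nick
    if pair.edit.kind == "insertion" and edit_pos <= s + SPACER_LENGTH:
        shift = len(pair.edit.payload)
    elif pair.edit.kind == "deletion" and edit_pos <= s + SPACER_LENGTH:
        shift = -len(pair.edit.payload)
    pam_positions = {s + SPACER_LENGTH + k + shift for k in range(3)}
    diff = {i for i, (a, b) in enumerate(zip(expected, pair.edited_wide_target)) if a != b}
    if not diff <= pam_positions:
        raise ValidationError(
            f"pair {pair.pair_id}: edited_wide_target differs from the edit spec "
            f"outside the PAM (positions {sorted(diff - pam_positions)})")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - (DNA_ALPHABET | {"N"}):
            raise ValidationError(f"read {self.read_id}: sequence must be non-empty ACGTN")


@dataclass
class BarcodeIndex:
    """Exact-match lookup from 22-nt key to pair_id."""

    key_to_pair: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.key_to_pair)

    def __contains__(self, key: str) -> bool:
        return key in self.key_to_pair


# ---------------------------------------------------------------------------
# pair tables

_TABLE_COLUMNS = [
    "pair_id", "spacer", "pbs", "rt_template", "barcode", "upstream4",
    "wide_target", "edited_wide_target", "edit_type", "edit_offset",
    "edit_payload", "flank5", "flank3",
]


def load_pair_table(path: str | Path) -> list[PairDesign]:
    """Read a TSV pair table, validating every design and key uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PairTableError(f"{path}: missing columns {missing}")
    pairs: list[PairDesign] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            edit = EditSpec(kind=row.edit_type,
                            offset_from_nick=int(row.edit_offset),
                            payload=row.edit_payload)
            pair = PairDesign(
                pair_id=row.pair_id, spacer=row.spacer, pbs=row.pbs,
                rt_template=row.rt_template, barcode=row.barcode,
                upstream4=row.upstream4, wide_target=row.wide_target,
                edited_wide_target=row.edited_wide_target, edit=edit,
                flank5=row.flank5, flank3=row.flank3,
            ).validate()
        except (ValidationError, ValueError, TypeError) as exc:
            raise PairTableError(f"{path}: row {i + 2}: {exc}") from exc
        pairs.append(pair)
    ids = [p.pair_id for p in pairs]
    if len(set(ids)) != len(ids):
        dups = sorted({x for x in ids if ids.count(x) > 1})
        raise PairTableError(f"{path}: duplicate pair_id(s): {dups}")
    build_barcode_index(pairs)  # raises on 22-nt key collision
    return pairs


def pairs_to_frame(pairs: Iterable[PairDesign]) -> pd.DataFrame:
    rows = [
        dict(pair_id=p.pair_id, spacer=p.spacer, pbs=p.pbs,
             rt_template=p.rt_template, barcode=p.barcode,
             upstream4=p.upstream4, wide_target=p.wide_target,
             edited_wide_target=p.edited_wide_target,
             edit_type=p.edit.kind, edit_offset=p.edit.offset_from_nick,
             edit_payload=p.edit.payload, flank5=p.flank5, flank3=p.flank3)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_pair_table(pairs: Iterable[PairDesign], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# demultiplexing

def build_barcode_index(pairs: Iterable[PairDesign]) -> BarcodeIndex:
    index = BarcodeIndex()
    collisions: dict[str, list[str]] = {}
    for pair in pairs:
        key = pair.key
        if key in index.key_to_pair:
            collisions.setdefault(key, [index.key_to_pair[key]]).append(pair.pair_id)
        else:
            index.key_to_pair[key] = pair.pair_id
    if collisions:
        detail = "; ".join(f"{k}: {ids}" for k, ids in collisions.items())
        raise ValidationError(f"22-nt key collision between pairs: {detail}")
    return index


def assign_read(read: ReadRecord | str, index: BarcodeIndex) -> Optional[str]:
    """Assign a read by scanning for an exact 22-nt key occurrence.

    Returns the pair_id, or UNASSIGNED (None) when no key, an ambiguous
    pair of distinct keys, or an N inside the only key candidate is found.
    Exact match only; N never matches a key position.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    lookup = index.key_to_pair
    found: Optional[str] = None
    for i in range(len(seq) - KEY_LENGTH + 1):
        window = seq[i:i + KEY_LENGTH]
        pid = lookup.get(window)
        if pid is not None:  # windows containing N can never be keys
            if found is not None and pid != found:
                return UNASSIGNED  # two distinct keys -> ambiguous
            found = pid
    return found


def assign_reads(reads: Iterable[ReadRecord], index: BarcodeIndex) -> pd.DataFrame:
    """Assignment table: read_id, pair_id (empty string for unassigned)."""
    rows = [(r.read_id, assign_read(r, index) or "") for r in reads]
    return pd.DataFrame(rows, columns=["read_id", "pair_id"])


# ---------------------------------------------------------------------------
# FASTQ + manifest plumbing

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) 4-line FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper(),
                             qualities=rec.letter_annotations.get("phred_quality"))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as FASTQ (gzip if the path ends in .gz); returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for r in reads:
            quals = r.qualities or [40] * len(r.sequence)
            qual_str = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual_str}\n")
            n += 1
    return n


def write_manifest(path: str | Path, payload: dict) -> None:
    """JSON run manifest: inputs, seeds, thresholds, versions, counts."""
    import pescreen

    meta = {
        "pescreen_version": pescreen.__version__,
        "python": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump({**meta, **payload}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
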