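"""On-target allele-outcome classification from amplicon deep sequencing.

Reads from an edited locus are aligned to the amplicon reference, normalized
with a quantification-window rule (mismatches far from the protospacer are
treated as sequencing noise and reverted; indels are always kept), and
classified into exclusive outcome classes:

* base-editor / nuclease mode — ``WT``, ``expected_edit`` (the programmed
  transition at one or more editing-window positions), ``other_SNV`` (any
  other substitution near the protospacer) and ``indel`` (an insertion or
  deletion overlapping a small window around the nick/cut);
* prime-editor mode — ``WT``, ``precise_PE`` (exactly the intended edit and
  nothing else), ``imprecise_PE`` (intended edit plus scaffold incorporation
  at the pegRNA nick or another indel at either nick) and ``other``.

Class precedence in BE/nuclease mode is indel > other_SNV > expected_edit:
an allele carrying both an indel and the programmed transition is counted as
a double-strand-break repair product, the genotoxicity readout.

Coordinates are 0-based half-open internally; protospacer positions are
reported 1-based from the PAM-distal end, the editing-literature convention.
"""

from __future__ import annotations

import functools
from collections import Counter, defaultdict
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "AmpliconSpec",
    "PegSpec",
    "Substitution",
    "Deletion",
    "Insertion",
    "AlleleTable",
    "OutcomeSummary",
    "IndelProfile",
    "BE_CLASSES",
    "PE_CLASSES",
    "apply_events",
    "align_read",
    "normalize_allele",
    "classify_be_allele",
    "classify_pe_allele",
    "classify_reads",
    "summarize_outcomes",
    "indel_profile",
    "per_base_conversion_table",
    "revcomp",
]

BE_CLASSES = ("WT", "expected_edit", "other_SNV", "indel")
PE_CLASSES = ("WT", "precise_PE", "imprecise_PE", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Alignment events
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Substitution:
    """Single-base mismatch at reference position ``pos`` (0-based)."""

    pos: int
    ref: str
    alt: str


@dataclass(frozen=True, order=True)
class Deletion:
    """Deletion of reference interval [start, end) (0-based half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        # midpoint of the deleted positions start .. end-1 (inclusive)
        return (self.start + self.end - 1) / 2.0


@dataclass(frozen=True, order=True)
class Insertion:
    """Insertion of ``seq`` immediately before reference position ``pos``."""

    pos: int
    seq: str


Event = Union[Substitution, Deletion, Insertion]


def _event_pos(e: Event) -> int:
    return e.start if isinstance(e, Deletion) else e.pos


def deletion_placement_range(reference: str, d: "Deletion") -> tuple[int, int]:
    """Union of deleted positions over all equivalent placements.

    A deletion inside a repeat can be placed at several coordinates that
    yield the same read sequence; window-overlap decisions use the union
    interval so classification does not depend on the reported placement
    (and is therefore strand-symmetric).
    """
    s, e = d.start, d.end
    while s > 0 and reference[s - 1] == reference[e - 1]:
        s -= 1
        e -= 1
    lo = s
    s, e = d.start, d.end
    while e < len(reference) and reference[s] == reference[e]:
        s += 1
        e += 1
    return lo, e


def insertion_position_range(reference: str, ins: "Insertion") -> tuple[int, int]:
    """Leftmost and rightmost equivalent boundary positions of an insertion."""
    p, q = ins.pos, ins.seq
    while p > 0 and q and reference[p - 1] == q[-1]:
        q = reference[p - 1] + q[:-1]
        p -= 1
    pmin = p
    p, q = ins.pos, ins.seq
    while p < len(reference) and q and reference[p] == q[0]:
        q = q[1:] + reference[p]
        p += 1
    pmax = p
    return pmin, pmax


def apply_events(reference: str, events: Iterable[Event]) -> str:
    """Reconstruct the allele sequence from reference + events.

    Events must not overlap; insertions at a deletion boundary are emitted
    before the deleted interval.
    """
    subs = {e.pos: e for e in events if isinstance(e, Substitution)}
    dels = sorted((e for e in events if isinstance(e, Deletion)),
                  key=lambda d: d.start)
    ins = defaultdict(str)
    for e in events:
        if isinstance(e, Insertion):
            ins[e.pos] += e.seq
    out = []
    deleted = np.zeros(len(reference), dtype=bool)
    for d in dels:
        deleted[d.start:d.end] = True
    for i, base in enumerate(reference):
        if i in ins:
            out.append(ins[i])
        if deleted[i]:
            continue
        if i in subs:
            s = subs[i]
            if s.ref != base:
                raise ValueError(f"substitution ref mismatch at {i}")
            out.append(s.alt)
        else:
            out.append(base)
    if len(reference) in ins:
        out.append(ins[len(reference)])
    return "".join(out)


# ---------------------------------------------------------------------------
# Target-locus specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconSpec:
    """Geometry of one editing target on an amplicon reference.

    Parameters
    ----------
    reference : str
        Amplicon reference sequence (A/C/G/T).
    protospacer_start : int
        0-based offset of the leftmost protospacer base on the reference,
        regardless of strand.
    protospacer_strand : {"+", "-"}
        Strand on which the protospacer (and 3' PAM) lies.
    cut_offset : int
        Nick/cut placed after this many protospacer positions counted from
        the PAM-distal end; the default 17 puts the blunt cut between
        positions 17 and 18, i.e. 3 nt 5' of the PAM.
    editing_window : (int, int)
        Inclusive 1-based protospacer positions where the deaminase acts.
    conversion : (str, str) or None
        Programmed base conversion, e.g. ("C", "T") for a CBE or
        ("A", "G") for an ABE; ``None`` for a nuclease (Cas9) target.
    indel_window_halfwidth : int
        Half-width (nt) of the quantification window around the cut used to
        call an allele ``indel``.
    substitution_region_flank : int
        Mismatches farther than this many nt from the protospacer are
        reverted as sequencing noise during allele normalization.
    """

    reference: str
    protospacer_start: int
    protospacer_strand: str = "+"
    protospacer_length: int = 20
    cut_offset: int = 17
    editing_window: tuple[int, int] = (4, 8)
    conversion: Optional[tuple[str, str]] = ("C", "T")
    indel_window_halfwidth: int = 1
    substitution_region_flank: int = 10

    def __post_init__(self):
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        if self.protospacer_strand not in "+-":
            raise ValueError("protospacer_strand must be '+' or '-'")
        s, L = self.protospacer_start, self.protospacer_length
        if s < 0 or s + L > len(ref):
            raise ValueError("protospacer does not fit on the reference")
        lo, hi = self.editing_window
        if not (1 <= lo <= hi <= L):
            raise ValueError("editing_window must lie within the protospacer")
        if self.conversion is not None:
            a, b = self.conversion
            if a == b or a not in "ACGT" or b not in "ACGT":
                raise ValueError("conversion bases must differ and be A/C/G/T")
        if not (0 < self.cut_offset < L):
            raise ValueError("cut_offset must fall inside the protospacer")

    # -- coordinate helpers -------------------------------------------------

    @property
    def protospacer(self) -> str:
        """Protospacer in guide orientation (position 1 first)."""
        s = self.reference[self.protospacer_start:
                           self.protospacer_start + self.protospacer_length]
        return s if self.protospacer_strand == "+" else revcomp(s)

    def ref_coord(self, position: int) -> int:
        """0-based reference coordinate of a 1-based protospacer position."""
        if not (1 <= position <= self.protospacer_length):
            raise ValueError("protospacer position out of range")
        if self.protospacer_strand == "+":
            return self.protospacer_start + position - 1
        return self.protospacer_start + self.protospacer_length - position

    @property
    def cut(self) -> int:
        """Cut/nick as a 0-based boundary coordinate (between cut-1 and cut)."""
        if self.protospacer_strand == "+":
            return self.protospacer_start + self.cut_offset
        return self.protospacer_start + self.protospacer_length - self.cut_offset

    @property
    def window_coords(self) -> list[int]:
        """Reference coordinates of the editing-window positions."""
        lo, hi = self.editing_window
        return [self.ref_coord(p) for p in range(lo, hi + 1)]

    @property
    def editable_coords(self) -> list[int]:
        """Window coordinates whose (strand-adjusted) base is convertible."""
        if self.conversion is None:
            return []
        want = self.conversion[0]
        out = []
        for c in self.window_coords:
            base = self.reference[c]
            if self.protospacer_strand == "-":
                base = revcomp(base)
            if base == want:
                out.append(c)
        return out

    def expected_substitution(self, coord: int) -> Substitution:
        """The programmed conversion expressed on the reference top strand."""
        if self.conversion is None:
            raise ValueError("nuclease spec has no programmed conversion")
        frm, to = self.conversion
        if self.protospacer_strand == "-":
            frm, to = revcomp(frm), revcomp(to)
        return Substitution(coord, frm, to)

    @property
    def substitution_region(self) -> tuple[int, int]:
        """Half-open reference interval where substitutions are believed."""
        lo = max(0, self.protospacer_start - self.substitution_region_flank)
        hi = min(len(self.reference),
                 self.protospacer_start + self.protospacer_length
                 + self.substitution_region_flank)
        return lo, hi

    def indel_window(self) -> tuple[int, int]:
        """Inclusive reference positions counted as 'at the cut'."""
        w = self.indel_window_halfwidth
        return self.cut - w, self.cut + w - 1

    def indel_in_window(self, event: Event) -> bool:
        """Whether an indel overlaps the quantification window, under any of
        its equivalent placements."""
        lo, hi = self.indel_window()
        if isinstance(event, Deletion):
            s, e = deletion_placement_range(self.reference, event)
            return s <= hi and e - 1 >= lo
        if isinstance(event, Insertion):
            w = self.indel_window_halfwidth
            pmin, pmax = insertion_position_range(self.reference, event)
            return pmin <= self.cut + w and pmax >= self.cut - w
        return False


@dataclass(frozen=True)
class PegSpec:
    """Prime-editing target: pegRNA geometry plus the intended edit.

    ``intended_edit`` is ``(start, end, alt)`` — replace reference interval
    [start, end) by ``alt`` (0-based half-open; ``start == end`` encodes a
    pure insertion, ``alt == ""`` a pure deletion).  ``scaffold_prefix`` holds
    the 5' bases of the gRNA scaffold adjacent to the pegRNA extension,
    written as DNA; their incorporation at the nick marks imprecise editing.
    """

    base: AmpliconSpec
    intended_edit: tuple[int, int, str]
    scaffold_prefix: str
    nick_gRNA: Optional[AmpliconSpec] = None
    scaffold_min_match: int = 3

    def __post_init__(self):
        s, e, alt = self.intended_edit
        if not (0 <= s <= e <= len(self.base.reference)):
            raise ValueError("intended_edit interval outside the reference")
        if s == e and not alt:
            raise ValueError("intended_edit is a no-op")
        if any(b not in "ACGT" for b in alt):
            raise ValueError("intended_edit alt must be A/C/G/T")
        if len(self.scaffold_prefix) < 3:
            raise ValueError("scaffold_prefix must be at least 3 nt")

    @property
    def reference(self) -> str:
        return self.base.reference

    @property
    def peg_nick(self) -> int:
        return self.base.cut

    def intended_events(self) -> tuple[Event, ...]:
        """Canonical (left-normalized) event representation of the edit."""
        s, e, alt = self.intended_edit
        ref = self.base.reference
        if s == e:  # insertion
            events = [Insertion(s, alt)]
        elif not alt:  # deletion
            events = [Deletion(s, e)]
        elif e - s == len(alt):  # substitution block
            events = [Substitution(s + i, ref[s + i], alt[i])
                      for i in range(len(alt)) if ref[s + i] != alt[i]]
        else:
            events = [Deletion(s, e), Insertion(s, alt)]
        return tuple(_left_normalize(events, ref))

    def edited_reference(self) -> str:
        return apply_events(self.base.reference, self.intended_events())

    def nick_windows(self) -> list[tuple[int, int]]:
        """Inclusive position windows around the pegRNA (and PE3) nicks."""
        wins = [self.base.indel_window()]
        if self.nick_gRNA is not None:
            wins.append(self.nick_gRNA.indel_window())
        return wins


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, open_gap: float,
             extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = open_gap
    a.extend_gap_score = extend
    # reference flanks not covered by the read cost nothing
    a.end_deletion_score = 0
    return a


def _left_normalize(events: list[Event], reference: str) -> list[Event]:
    """Shift indels as far left as the sequence context allows."""
    out: list[Event] = []
    for e in events:
        if isinstance(e, Deletion):
            s, t = e.start, e.end
            while s > 0 and reference[s - 1] == reference[t - 1]:
                s -= 1
                t -= 1
            out.append(Deletion(s, t))
        elif isinstance(e, Insertion):
            p, q = e.pos, e.seq
            while p > 0 and q and reference[p - 1] == q[-1]:
                q = reference[p - 1] + q[:-1]
                p -= 1
            out.append(Insertion(p, q))
        else:
            out.append(e)
    return sorted(out, key=lambda e: (_event_pos(e), repr(e)))


def _events_from_alignment(alignment, reference: str,
                           read: str) -> tuple[list[Event], int]:
    """Extract substitution/indel events and the match count."""
    (ref_blocks, read_blocks) = alignment.aligned
    events: list[Event] = []
    matches = 0
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in zip(ref_blocks.tolist(), read_blocks.tolist()):
        if prev_r is not None:
            if rs > prev_r and qs == prev_q:
                events.append(Deletion(prev_r, rs))
            elif qs > prev_q and rs == prev_r:
                events.append(Insertion(rs, read[prev_q:qs]))
            elif rs > prev_r and qs > prev_q:
                events.append(Deletion(prev_r, rs))
                events.append(Insertion(rs, read[prev_q:qs]))
        for i in range(re_ - rs):
            rb, qb = reference[rs + i], read[qs + i]
            if rb == qb:
                matches += 1
            else:
                events.append(Substitution(rs + i, rb, qb))
        prev_r, prev_q = re_, qe
    return _left_normalize(events, reference), matches


@dataclass
class ReadAlignment:
    """Result of aligning one read to the amplicon reference."""

    events: tuple[Event, ...]
    strand: str
    score: float
    identity: float
    aligned_ref_interval: tuple[int, int]


def align_read(read: str, spec: AmpliconSpec, *, min_identity: float = 0.6,
               match: float = 5, mismatch: float = -4, open_gap: float = -20,
               extend_gap: float = -1) -> Optional[ReadAlignment]:
    """Globally align a read to the amplicon reference.

    The read is aligned end-to-end with affine gap penalties; reference
    flanks not covered by the read are free.  Orientation is auto-detected
    by aligning both the read and its reverse complement and keeping the
    higher-scoring strand.  Indels are reported left-aligned.  Returns
    ``None`` when the best alignment identity falls below ``min_identity``
    (the read is unalignable).
    """
    read = read.upper()
    if len(read) < 40:
        raise ValueError("reads shorter than 40 nt cannot be aligned reliably")
    aligner = _aligner(match, mismatch, open_gap, extend_gap)
    ref = spec.reference
    best = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        aln = aligner.align(ref, seq)
        cand = aln[0]
        if best is None or cand.score > best[0].score:
            best = (cand, strand, seq)
    aln, strand, seq = best
    events, matches = _events_from_alignment(aln, ref, seq)
    identity = matches / len(seq)
    if identity < min_identity:
        return None
    rb = aln.aligned[0]
    interval = (int(rb[0][0]), int(rb[-1][1])) if len(rb) else (0, 0)
    return ReadAlignment(tuple(events), strand, float(aln.score), identity,
                         interval)


# ---------------------------------------------------------------------------
# Normalization and classification
# ---------------------------------------------------------------------------


def normalize_allele(events: Iterable[Event],
                     spec: AmpliconSpec | PegSpec) -> tuple[Event, ...]:
    """Revert substitutions outside the substitution region.

    Mismatches far from the protospacer are treated as sequencing noise and
    corrected back to the reference; indels are never reverted.  For a
    prime-editing spec the regions of both the pegRNA spacer and the PE3
    nicking guide (if any) are kept.  Idempotent.
    """
    if isinstance(spec, PegSpec):
        regions = [spec.base.substitution_region]
        s, e, _ = spec.intended_edit
        regions.append((s, max(e, s + 1)))
        if spec.nick_gRNA is not None:
            regions.append(spec.nick_gRNA.substitution_region)
    else:
        regions = [spec.substitution_region]
    kept = []
    for ev in events:
        if isinstance(ev, Substitution):
            if not any(lo <= ev.pos < hi for lo, hi in regions):
                continue
        kept.append(ev)
    return tuple(sorted(kept, key=lambda e: (_event_pos(e), repr(e))))


def classify_be_allele(events: Iterable[Event], spec: AmpliconSpec) -> str:
    """Classify a normalized allele under the BE/nuclease taxonomy.

    Precedence: (1) ``indel`` if any insertion or deletion overlaps the
    quantification window around the cut; (2) ``other_SNV`` if any retained
    substitution is not the programmed conversion at an editing-window
    position; (3) ``expected_edit`` if at least one programmed conversion is
    present; (4) ``WT``.
    """
    events = list(events)
    if any(spec.indel_in_window(e) for e in events
           if isinstance(e, (Deletion, Insertion))):
        return "indel"
    lo, hi = spec.substitution_region
    expected = set()
    if spec.conversion is not None:
        expected = {spec.expected_substitution(c) for c in spec.editable_coords}
    n_expected = 0
    for e in events:
        if not isinstance(e, Substitution) or not (lo <= e.pos < hi):
            continue
        if e in expected:
            n_expected += 1
        else:
            return "other_SNV"
    return "expected_edit" if n_expected else "WT"


def classify_pe_allele(events: Iterable[Event], spec: PegSpec) -> str:
    """Classify a normalized allele under the prime-editing taxonomy."""
    events = tuple(sorted(events, key=repr))
    if not events:
        return "WT"
    intended = set(spec.intended_events())
    observed = set(events)
    if observed == intended:
        return "precise_PE"
    if intended and intended <= observed:
        extra = observed - intended
        if _has_imprecision(extra, spec):
            return "imprecise_PE"
    return "other"


def _has_imprecision(extra_events: Iterable[Event], spec: PegSpec) -> bool:
    """Scaffold incorporation at the pegRNA nick, or an indel at a nick."""
    ref = spec.base.reference
    wins = spec.nick_windows()
    w = spec.base.indel_window_halfwidth
    nick = spec.peg_nick
    for e in extra_events:
        if isinstance(e, Insertion):
            pmin, pmax = insertion_position_range(ref, e)
            if (pmin <= nick + w and pmax >= nick - w
                    and len(e.seq) >= spec.scaffold_min_match
                    and spec.scaffold_prefix.startswith(
                        e.seq[:min(len(e.seq), len(spec.scaffold_prefix))])):
                return True
            if any(pmin <= hi + 1 and pmax >= lo for lo, hi in wins):
                return True
        elif isinstance(e, Deletion):
            s, t = deletion_placement_range(ref, e)
            if any(s <= hi and t - 1 >= lo for lo, hi in wins):
                return True
    return False


# ---------------------------------------------------------------------------
# Allele tables and summaries
# ---------------------------------------------------------------------------


@dataclass
class AlleleTable:
    """Window-normalized alleles with read counts and class labels.

    ``records`` columns: ``allele`` (sequence), ``events`` (tuple of
    alignment events vs the reference), ``count``, ``class`` and
    ``conversions`` (per editing-window protospacer position: True when the
    programmed conversion is present).
    """

    records: pd.DataFrame
    mode: str
    spec: AmpliconSpec | PegSpec
    unalignable: int = 0
    too_short: int = 0

    @property
    def total_classified(self) -> int:
        return int(self.records["count"].sum()) if len(self.records) else 0

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df["events"] = df["events"].map(
            lambda evs: ";".join(map(repr, evs)) or ".")
        df["conversions"] = df["conversions"].map(
            lambda d: ",".join(f"{k}:{int(v)}" for k, v in d.items()) or ".")
        df.to_csv(path, sep="\t", index=False)


@dataclass
class OutcomeSummary:
    """Per-class read fractions for one sample."""

    fractions: dict[str, float]
    total_reads: int
    unalignable: int = 0
    too_short: int = 0

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.fractions.items()}


def _infer_mode(spec: AmpliconSpec | PegSpec) -> str:
    if isinstance(spec, PegSpec):
        return "pe"
    return "cas9" if spec.conversion is None else "be"


def _conversion_flags(events: Iterable[Event], spec: AmpliconSpec) -> dict:
    if spec.conversion is None:
        return {}
    subs = {e for e in events if isinstance(e, Substitution)}
    lo, hi = spec.editing_window
    flags = {}
    for p in range(lo, hi + 1):
        c = spec.ref_coord(p)
        flags[p] = (c in [x.pos for x in subs]
                    and spec.expected_substitution(c) in subs)
    return flags


def classify_reads(reads, spec: AmpliconSpec | PegSpec, *,
                   mode: Optional[str] = None, min_read_length: int = 100,
                   min_identity: float = 0.6) -> AlleleTable:
    """Align, normalize and classify a set of amplicon reads.

    ``reads`` may be a FASTQ/FASTA path or an iterable of sequences.  Reads
    shorter than ``min_read_length`` are dropped up front (assumes
    pre-trimmed input); reads whose best alignment identity is below
    ``min_identity`` are counted as unalignable and excluded from the table.
    """
    if mode is None:
        mode = _infer_mode(spec)
    if mode not in ("be", "cas9", "pe"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pe" and not isinstance(spec, PegSpec):
        raise ValueError("prime-editing mode requires a PegSpec")
    base = spec.base if isinstance(spec, PegSpec) else spec

    seqs = _iter_sequences(reads)
    counts: Counter[tuple[Event, ...]] = Counter()
    unalignable = too_short = 0
    cache: dict[str, Optional[tuple[Event, ...]]] = {}
    for seq in seqs:
        if len(seq) < min_read_length:
            too_short += 1
            continue
        if seq in cache:
            events = cache[seq]
        else:
            aln = align_read(seq, base, min_identity=min_identity)
            events = (normalize_allele(aln.events, spec)
                      if aln is not None else None)
            cache[seq] = events
        if events is None:
            unalignable += 1
            continue
        counts[events] += 1

    rows = []
    for events, n in sorted(counts.items(), key=lambda kv: (-kv[1], repr(kv[0]))):
        label = (classify_pe_allele(events, spec) if mode == "pe"
                 else classify_be_allele(events, base))
        rows.append({
            "allele": apply_events(base.reference, events),
            "events": events,
            "count": n,
            "class": label,
            "conversions": _conversion_flags(events, base),
        })
    df = pd.DataFrame(rows, columns=["allele", "events", "count", "class",
                                     "conversions"])
    return AlleleTable(df, mode, spec, unalignable=unalignable,
                       too_short=too_short)


def _iter_sequences(reads):
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fasta" if path.suffix in (".fa", ".fasta") else "fastq"
        return (str(rec.seq) for rec in SeqIO.parse(str(path), fmt))
    return (str(r) for r in reads)


def summarize_outcomes(table: AlleleTable) -> OutcomeSummary:
    """Per-class read-count fractions (unalignable reads excluded)."""
    if not len(table.records):
        raise ValueError("empty allele table")
    classes = PE_CLASSES if table.mode == "pe" else BE_CLASSES
    total = table.total_classified
    per = table.records.groupby("class")["count"].sum()
    fractions = {c: float(per.get(c, 0)) / total for c in classes}
    return OutcomeSummary(fractions, total, table.unalignable,
                          table.too_short)


@dataclass
class IndelProfile:
    """Where deletions fall on the reference, among indel-bearing reads."""

    deletion_frequency: np.ndarray  # per reference position, fraction of indel reads
    center_histogram: pd.Series    # deletion centers binned per nucleotide
    n_indel_reads: int


def indel_profile(table: AlleleTable,
                  spec: Optional[AmpliconSpec | PegSpec] = None) -> IndelProfile:
    """Deletion-position profile over reads carrying an indel.

    Each deletion contributes its covered reference positions and its center
    (midpoint of the deleted interval), weighted by read count.
    """
    spec = spec if spec is not None else table.spec
    base = spec.base if isinstance(spec, PegSpec) else spec
    L = len(base.reference)
    cover = np.zeros(L)
    centers: Counter[int] = Counter()
    n_indel = 0
    for _, row in table.records.iterrows():
        dels = [e for e in row["events"] if isinstance(e, Deletion)]
        has_indel = any(isinstance(e, (Deletion, Insertion))
                        for e in row["events"])
        if not has_indel:
            continue
        n_indel += row["count"]
        for d in dels:
            cover[d.start:d.end] += row["count"]
            centers[int(np.floor(d.center))] += row["count"]
    if n_indel:
        cover = cover / n_indel
    hist = pd.Series(centers, dtype=float).sort_index()
    return IndelProfile(cover, hist, int(n_indel))


def per_base_conversion_table(table: AlleleTable,
                              spec: Optional[AmpliconSpec] = None) -> pd.DataFrame:
    """Base composition per protospacer position (1..L, PAM-distal first).

    Returns fractions of reads carrying A/C/G/T or a deletion ('-') at each
    protospacer position, in guide orientation.
    """
    spec = spec if spec is not None else table.spec
    if isinstance(spec, PegSpec):
        spec = spec.base
    L = spec.protospacer_length
    counts = pd.DataFrame(0.0, index=range(1, L + 1),
                          columns=list("ACGT") + ["-"])
    total = 0
    for _, row in table.records.iterrows():
        n = row["count"]
        total += n
        subs = {e.pos: e.alt for e in row["events"]
                if isinstance(e, Substitution)}
        dels = [e for e in row["events"] if isinstance(e, Deletion)]
        for p in range(1, L + 1):
            c = spec.ref_coord(p)
            if any(d.start <= c < d.end for d in dels):
                counts.at[p, "-"] += n
                continue
            base = subs.get(c, spec.reference[c])
            if spec.protospacer_strand == "-":
                base = revcomp(base)
            counts.at[p, base] += n
    if total:
        counts /= total
    return counts
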