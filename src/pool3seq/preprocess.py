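"""Dual-index demultiplexing and positional polyA trimming.

Demultiplexing assigns a read to the unique well whose (i5, i7) barcode pair
is within a Hamming-distance budget on *each index independently* (index
reads come off the instrument separately, so distances are not pooled across
the two indices).  Reads matching no well go to the ``no_match`` bin; reads
within budget of more than one well are ``ambiguous``.  With the bundled
index pools (pairwise distance >= 3 within each pool) ambiguity is
impossible at a 1-mismatch budget.

PolyA trimming removes the 3' portion of a read once a sufficiently long
A-run begins past a fixed position: reads from short inserts run through the
polyA junction into the tail, and the genic prefix is what should be
aligned.  The defaults — a run of at least 12 consecutive 'A' starting at
1-based position >= 26 — implement "trim polyA runs of minimal length 12
located after the 25th position".  A run that *starts* before the cutoff is
ignored even if it extends past it, protecting genuinely A-rich 5' sequence;
``max_non_a`` optionally tolerates isolated non-A bases inside the run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .core_io import FormatError, PlateLayout, ReadRecord

__all__ = ["DemuxResult", "TrimResult", "demultiplex", "trim_polya", "trim_reads"]


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadRecord]]  # sample_id -> reads
    no_match: list[ReadRecord] = field(default_factory=list)
    ambiguous: list[ReadRecord] = field(default_factory=list)

    @property
    def counts(self) -> pd.Series:
        c = {s: len(reads) for s, reads in self.assigned.items()}
        c["no_match"] = len(self.no_match)
        c["ambiguous"] = len(self.ambiguous)
        return pd.Series(c)

    @property
    def n_assigned(self) -> int:
        return sum(len(r) for r in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.no_match) + len(self.ambiguous)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads,
    layout: PlateLayout,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Assign reads to wells by dual-index Hamming matching.

    A read is assigned iff exactly one well has Hamming(i5) <= max_mismatch
    *and* Hamming(i7) <= max_mismatch; zero candidates -> ``no_match``,
    several -> ``ambiguous``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    layout.validate()
    pairs = [(w.barcode.i5, w.barcode.i7, w.sample_id) for w in layout.wells]
    result = DemuxResult(assigned={w.sample_id: [] for w in layout.wells})
    # observed pairs recur constantly; cache the decision per (i5, i7)
    cache: dict[tuple[str, str], str | None] = {}
    for read in reads:
        if not read.i5 or not read.i7:
            raise FormatError(f"read {read.read_id} lacks index fields")
        key = (read.i5, read.i7)
        if key in cache:
            dest = cache[key]
        else:
            hits = [
                sid
                for i5, i7, sid in pairs
                if _hamming(read.i5, i5) <= max_mismatch
                and _hamming(read.i7, i7) <= max_mismatch
            ]
            dest = hits[0] if len(hits) == 1 else ("ambiguous" if hits else None)
            cache[key] = dest
        if dest is None:
            result.no_match.append(read)
        elif dest == "ambiguous":
            result.ambiguous.append(read)
        else:
            result.assigned[dest].append(read)
    return result


@dataclass
class TrimResult:
    sequence: str
    trimmed: bool
    bases_removed: int


def _find_run_start(seq: str, min_run: int, min_start: int, max_non_a: int) -> int | None:
    """Leftmost qualifying A-run start (0-based), or None.

    A qualifying run starts with 'A' at 0-based position >= min_start - 1,
    is not the continuation of an earlier A-run, and its first ``min_run``
    bases contain at most ``max_non_a`` non-A characters.
    """
    first = min_start - 1
    if max_non_a == 0:
        # maximal A-runs; the first one long enough that starts late enough
        for m in re.finditer(r"A{%d,}" % min_run, seq):
            if m.start() >= first:
                return m.start()
        return None
    n = len(seq)
    p = first
    while p + min_run <= n:
        if seq[p] == "A" and (p == 0 or seq[p - 1] != "A"):
            window = seq[p : p + min_run]
            if window.count("A") >= min_run - max_non_a:
                return p
        p += 1
    return None


def trim_polya(
    read: str | ReadRecord,
    min_run: int = 12,
    min_start: int = 26,
    max_non_a: int = 0,
) -> TrimResult:
    """Trim a 3' polyA run from a read.

    Scans for the leftmost A-run of length >= ``min_run`` (tolerating up to
    ``max_non_a`` interior non-A bases) whose start is at 1-based position
    >= ``min_start``; if found at position p, the read is cut to its first
    p - 1 bases.  Idempotent: trimming a trimmed read changes nothing.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if not seq:
        raise ValueError("empty read")
    p = _find_run_start(seq, min_run, min_start, max_non_a)
    if p is None:
        return TrimResult(sequence=seq, trimmed=False, bases_removed=0)
    return TrimResult(sequence=seq[:p], trimmed=True, bases_removed=len(seq) - p)


def trim_reads(
    reads: list[ReadRecord],
    min_run: int = 12,
    min_start: int = 26,
    max_non_a: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Trim a batch of reads, returning trimmed records and a report.

    The report has one row per read: read_id, trimmed flag, bases removed.
    Qualities are cut alongside sequences.
    """
    out = []
    rows = []
    for r in reads:
        t = trim_polya(r.sequence, min_run=min_run, min_start=min_start, max_non_a=max_non_a)
        out.append(
            ReadRecord(
                read_id=r.read_id,
                sequence=t.sequence,
                quality=r.quality[: len(t.sequence)],
                i7=r.i7,
                i5=r.i5,
            )
        )
        rows.append((r.read_id, t.trimmed, t.bases_removed))
    report = pd.DataFrame(rows, columns=["read_id", "trimmed", "bases_removed"])
    return out, report
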