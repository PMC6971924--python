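"""Transcriptome alignment, 3'-aware counting, length-free TPM and QC metrics.

Alignment is deliberately desk-scale: reads come from transcripts (one
3'-terminal fragment each), so a splice-aware genome aligner is unnecessary.
A seed-and-extend strategy over an exact k-mer index of the transcriptome
locates candidates, ungapped extension counts mismatches, and a read is
``unique`` iff exactly one location attains the best score within the
mismatch-fraction budget (mismatches <= floor(max_mismatch_frac * read
length), 0.1 by default).  Exact score ties across locations give ``multi``;
multi-mapped and antisense alignments are excluded from counting but kept in
the metrics, matching strand-specific unique-read counting.

TPM here is length-free: counts are scaled to sum to 1e6 per sample with no
gene-length division, because each transcript contributes exactly one 3'
fragment regardless of its length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureAnnotation, ReadRecord

__all__ = [
    "TranscriptomeIndex",
    "AlignmentRecord",
    "CountMatrix",
    "align_read",
    "align_reads",
    "assign_and_count",
    "compute_tpm",
    "mapping_metrics",
    "gene_body_profile",
    "downsample_detection_curve",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptomeIndex:
    """Exact k-mer index over transcript sequences (polyA tails included).

    k-mers occurring at more than ``max_hits`` locations are dropped as
    seeds (repetitive, e.g. the pure-A tail k-mer shared by every
    transcript); extension never consults them.
    """

    def __init__(self, sequences: dict[str, str], k: int = 25, max_hits: int = 64):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.genes = list(sequences)
        self._seq_bytes = {
            g: np.frombuffer(s.encode(), dtype=np.uint8) for g, s in sequences.items()
        }
        self.lengths = {g: len(s) for g, s in sequences.items()}
        kmers: dict[str, list[tuple[str, int]]] = {}
        dropped: set[str] = set()
        for g, s in sequences.items():
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if km in dropped:
                    continue
                hits = kmers.setdefault(km, [])
                hits.append((g, i))
                if len(hits) > max_hits:
                    del kmers[km]
                    dropped.add(km)
        self._kmers = kmers

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._kmers.get(kmer, [])

    def mismatches(self, gene: str, pos: int, read_bytes: np.ndarray) -> int:
        """Ungapped mismatch count of the read placed at (gene, pos).

        Bases overhanging either transcript end count as mismatches.
        """
        ref = self._seq_bytes[gene]
        L = len(read_bytes)
        lo, hi = max(pos, 0), min(pos + L, len(ref))
        if hi <= lo:
            return L
        overlap = int(np.count_nonzero(ref[lo:hi] != read_bytes[lo - pos : hi - pos]))
        return overlap + (lo - pos) + (pos + L - hi)


@dataclass
class AlignmentRecord:
    read_id: str
    gene_id: str | None
    pos: int | None  # 0-based start on the transcript
    strand: str | None  # "sense" | "antisense"
    mismatches: int | None
    status: str  # "unique" | "multi" | "unaligned"
    feature_class: str | None = None
    reason: str | None = None  # for unaligned records


_SEED_OFFSETS = (0, 22, 44)


def align_read(
    read: str | ReadRecord,
    index: TranscriptomeIndex,
    max_mismatch_frac: float = 0.1,
    seed_offsets: Sequence[int] = _SEED_OFFSETS,
    read_id: str = "",
    check_antisense: bool = True,
) -> AlignmentRecord:
    """Seed-and-extend a single read against the transcriptome.

    Seeds are exact k-mers at up to three read offsets (fallbacks tolerate
    5' sequencing errors); every candidate placement is scored by ungapped
    mismatch count.  ``unique`` iff exactly one placement attains the best
    score and that score passes the mismatch-fraction filter; exact ties ->
    ``multi``; otherwise ``unaligned``.
    """
    if isinstance(read, ReadRecord):
        read_id = read_id or read.read_id
        read = read.sequence
    L = len(read)
    k = index.k
    if L < k:
        return AlignmentRecord(read_id, None, None, None, None, "unaligned", reason="too_short")
    max_mm = int(np.floor(max_mismatch_frac * L))

    strands = [("sense", read)]
    if check_antisense:
        strands.append(("antisense", _revcomp(read)))

    best_mm = L + 1
    best: list[tuple[str, int, str]] = []  # (gene, pos, strand)
    for strand, seq in strands:
        seq_b = np.frombuffer(seq.encode(), dtype=np.uint8)
        candidates: set[tuple[str, int]] = set()
        for off in seed_offsets:
            if off + k > L:
                continue
            for gene, pos in index.seed_hits(seq[off : off + k]):
                candidates.add((gene, pos - off))
        for gene, pos in candidates:
            mm = index.mismatches(gene, pos, seq_b)
            if mm < best_mm:
                best_mm = mm
                best = [(gene, pos, strand)]
            elif mm == best_mm:
                best.append((gene, pos, strand))

    if not best or best_mm > max_mm:
        return AlignmentRecord(read_id, None, None, None, None, "unaligned", reason="no_hit")
    if len(best) > 1:
        g, p, s = best[0]
        return AlignmentRecord(read_id, g, p, s, best_mm, "multi")
    g, p, s = best[0]
    return AlignmentRecord(read_id, g, p, s, best_mm, "unique")


def align_reads(
    reads: Iterable[ReadRecord],
    index: TranscriptomeIndex,
    max_mismatch_frac: float = 0.1,
    check_antisense: bool = True,
) -> list[AlignmentRecord]:
    return [
        align_read(
            r, index, max_mismatch_frac=max_mismatch_frac, check_antisense=check_antisense
        )
        for r in reads
    ]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with companion length-free TPM."""

    counts: pd.DataFrame
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.tpm is None:
            self.tpm = compute_tpm(self.counts)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _classify(ann: FeatureAnnotation, start: int, read_len: int) -> str:
    """Feature class covering the majority of aligned bases; ties -> 3'-most."""
    end = start + read_len
    overlaps: dict[str, int] = {}
    last_pos: dict[str, int] = {}
    covered = 0
    for seg in ann.segments:
        ov = min(end, seg.end) - max(start, seg.start)
        if ov > 0:
            overlaps[seg.feature_class] = overlaps.get(seg.feature_class, 0) + ov
            last_pos[seg.feature_class] = seg.end
            covered += ov
    other = read_len - covered  # bases on unannotated sequence (incl. polyA tail)
    if other > 0:
        overlaps["other"] = other
        last_pos["other"] = ann.length + 1  # tail lies 3' of everything
    if not overlaps:
        return "other"
    best = max(overlaps.values())
    tied = [c for c, v in overlaps.items() if v == best]
    return max(tied, key=lambda c: last_pos[c])


def assign_and_count(
    alignments_by_sample: dict[str, list[AlignmentRecord]],
    annotation: dict[str, FeatureAnnotation],
    read_lengths: dict[str, int] | None = None,
    default_read_len: int = 70,
) -> CountMatrix:
    """Count unique, sense-strand alignments per gene and sample.

    Also annotates each aligned record's ``feature_class`` in place (class of
    the segment containing the majority of aligned bases, ties resolved to
    the 3'-most segment).  Multi-mapped, antisense and unaligned records are
    never counted.
    """
    samples = list(alignments_by_sample)
    genes = list(annotation)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for rec in alignments_by_sample[sample]:
            if rec.status == "unaligned" or rec.gene_id is None:
                continue
            ann = annotation.get(rec.gene_id)
            if ann is None:
                raise KeyError(f"alignment to unannotated gene {rec.gene_id}")
            L = (
                read_lengths.get(rec.read_id, default_read_len)
                if read_lengths
                else default_read_len
            )
            rec.feature_class = _classify(ann, rec.pos, L)
            if rec.status == "unique" and rec.strand == "sense":
                mat[gene_pos[rec.gene_id], j] += 1
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    return CountMatrix(counts=counts)


def compute_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Length-free TPM: scale each sample to one million, no length term."""
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero counts emitted as all-zero TPM: {list(totals.index[zero])}"
        )
    safe = totals.replace(0, 1)
    return counts.div(safe, axis=1) * 1e6


def mapping_metrics(
    alignments_by_sample: dict[str, list[AlignmentRecord]],
    count_matrix: CountMatrix,
    detection_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-sample sequencing/mapping QC in the style of a run report.

    Percentages: mapped = (unique+multi)/reads, unique = unique/reads;
    coding/UTR/rRNA fractions are over *unique* alignments by feature
    class.  Genes detected = genes with TPM above ``detection_threshold``.
    """
    rows = []
    for sample, alns in alignments_by_sample.items():
        n = len(alns)
        if n == 0:
            warnings.warn(f"sample {sample} has zero reads")
            rows.append((sample, 0, *([np.nan] * 5), 0))
            continue
        unique = [a for a in alns if a.status == "unique"]
        n_multi = sum(a.status == "multi" for a in alns)
        n_unique = len(unique)
        n_coding = sum(a.feature_class == "CDS" for a in unique)
        n_utr = sum(a.feature_class in ("UTR3", "UTR5") for a in unique)
        n_rrna = sum(a.feature_class == "rRNA" for a in unique)
        tpm = count_matrix.tpm[sample]
        detected = int((tpm > detection_threshold).sum())
        denom = max(n_unique, 1)
        rows.append(
            (
                sample,
                n,
                100.0 * (n_unique + n_multi) / n,
                100.0 * n_unique / n,
                100.0 * n_coding / denom,
                100.0 * n_utr / denom,
                100.0 * n_rrna / denom,
                detected,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "reads",
            "pct_mapped",
            "pct_unique",
            "pct_coding",
            "pct_utr",
            "pct_rrna",
            "genes_detected",
        ],
    ).set_index("sample_id")


def gene_body_profile(
    alignments: Iterable[AlignmentRecord],
    annotation: dict[str, FeatureAnnotation],
    bins: int = 100,
    read_len: int = 70,
    mrna_classes: tuple[str, ...] = ("CDS", "UTR3", "UTR5"),
) -> np.ndarray:
    """Normalised read-midpoint distribution along the gene body.

    Each unique mRNA alignment contributes its midpoint mapped to a
    percentile position on its transcript (bin 0 = 5' end, last bin = 3'
    end).  The returned vector sums to 1.
    """
    hist = np.zeros(bins)
    n = 0
    for rec in alignments:
        if rec.status != "unique" or rec.strand != "sense":
            continue
        ann = annotation.get(rec.gene_id)
        if ann is None or not any(s.feature_class in mrna_classes for s in ann.segments):
            continue
        mid = rec.pos + read_len / 2
        frac = min(max(mid / ann.length, 0.0), 1.0)
        hist[min(int(frac * bins), bins - 1)] += 1
        n += 1
    if n == 0:
        raise ValueError("no unique mRNA alignments to profile")
    return hist / n


def downsample_detection_curve(
    counts: pd.Series,
    depths: Sequence[int],
    thresholds: Sequence[float] = (1.0,),
    seed: int = 0,
) -> pd.DataFrame:
    """Genes detected at TPM thresholds for subsampled read depths.

    ``counts`` is one sample's per-gene unique-read counts.  For each depth,
    reads are drawn *without replacement* from the full pool, recounted, and
    detection is evaluated on length-free TPM of the subsample.  Returns a
    depth x threshold table of detected-gene counts.
    """
    total = int(counts.sum())
    if any(d > total for d in depths):
        raise ValueError(f"requested depth exceeds available reads ({total})")
    rng = np.random.default_rng(seed)
    gene_ids = np.repeat(np.arange(len(counts)), counts.to_numpy())
    out = np.zeros((len(depths), len(thresholds)), dtype=int)
    for i, depth in enumerate(depths):
        if depth == 0:
            continue
        if depth == total:
            sub = counts.to_numpy().astype(float)
        else:
            take = rng.choice(gene_ids, size=depth, replace=False)
            sub = np.bincount(take, minlength=len(counts)).astype(float)
        tpm = sub / depth * 1e6 if depth else sub
        for j, thr in enumerate(thresholds):
            out[i, j] = int((tpm > thr).sum())
    return pd.DataFrame(out, index=list(depths), columns=list(thresholds))
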