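"""Generative model of a pooled, dual-indexed 3'-end RNA-seq run.

The simulator emulates the library structure of the protocol: every mRNA
molecule is reverse-transcribed from an anchored oligo-dT primer, so exactly
one 3'-terminal cDNA fragment per molecule reaches the sequencer.  A library
molecule is that fragment plus a fixed adapter overhead; the insert (the
distance from the tagmentation breakpoint to the polyA anchor) is drawn from
a lognormal whose mean is calibrated so the mean total molecule length is
550 bp by default.  Reads are 70 nt of sense strand starting at the
breakpoint; when the insert is shorter than the read, the tail of the read
runs into the polyA tail and is filled with 'A'.

Two layers of technical bias mirror the plate pooling workflow:

* **column bias** — a per-i7-index (per-column) scalar efficiency factor,
  applied to each sample *before* pooling; it scales all transcripts of a
  sample equally and therefore vanishes after within-sample normalisation;
* **row bias** — a per-(pool, transcript) factor shared by every sample in a
  pool, modelling variability introduced *after* row pooling; being
  transcript-specific it perturbs composition and survives normalisation,
  which is what makes it detectable in spike-in PCA.

Counts are negative-binomial (gamma-Poisson) around the biased means.  ERCC
spike-ins have identical expected abundance in every sample before bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ErccTable,
    FeatureAnnotation,
    FeatureSegment,
    PlateLayout,
    ReadRecord,
    write_ercc_table,
    write_fasta,
    write_fastq,
    write_gtf,
)

__all__ = [
    "Transcript",
    "ReferenceSet",
    "BiasModel",
    "ExpressionProfile",
    "build_reference",
    "simulate_expression",
    "simulate_reads",
    "simulate_run",
    "DEFAULT_READ_LENGTH",
    "DEFAULT_MEAN_LIBRARY_LENGTH",
    "DEFAULT_ADAPTER_OVERHEAD",
]

DEFAULT_READ_LENGTH = 70
#: Mean total library molecule length (insert + adapters), bp.
DEFAULT_MEAN_LIBRARY_LENGTH = 550.0
#: Constant adapter contribution (i5 Nextera side + i7 TruSeq side), bp.
DEFAULT_ADAPTER_OVERHEAD = 136
#: PolyA tail length carried on mRNA/ERCC reference sequences, nt.  At least
#: readlen - min_insert (44) so that polyA read-through reads that escape
#: trimming (an A-run straddling the positional cutoff) still align to their
#: transcript instead of overhanging the reference.
DEFAULT_POLYA_LEN = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class Transcript:
    gene_id: str
    seq: str  # genic sequence, polyA tail not included
    feature_class: str  # mRNA | rRNA | ERCC
    annotation: FeatureAnnotation
    polya_len: int = DEFAULT_POLYA_LEN

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def padded_seq(self) -> str:
        """Sequence with its polyA tail, as written to the reference FASTA."""
        return self.seq + "A" * self.polya_len


@dataclass
class ReferenceSet:
    """Synthetic transcriptome: mRNA, rRNA and ERCC spike-in species."""

    transcripts: dict[str, Transcript]
    ercc: ErccTable

    def __post_init__(self) -> None:
        ercc_ids = {g for g, t in self.transcripts.items() if t.feature_class == "ERCC"}
        if ercc_ids != set(self.ercc.ids):
            raise ConfigError("ERCC transcripts and ERCC table ids must match 1:1")

    def ids_of_class(self, feature_class: str) -> list[str]:
        return [g for g, t in self.transcripts.items() if t.feature_class == feature_class]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.transcripts)

    def annotations(self) -> dict[str, FeatureAnnotation]:
        return {g: t.annotation for g, t in self.transcripts.items()}

    def fasta_sequences(self) -> dict[str, str]:
        return {g: t.padded_seq for g, t in self.transcripts.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.fasta_sequences(), outdir / "reference.fasta")
        write_gtf(self.annotations().values(), outdir / "annotation.gtf")
        write_ercc_table(self.ercc, outdir / "ercc.tsv")


@dataclass
class BiasModel:
    """Technical bias and error parameters of a simulated run.

    ``sigma_col``/``sigma_row`` are lognormal standard deviations (natural
    log scale) of the column-efficiency and pool-composition factors; both 0
    gives the identity model.  ``error_rate`` is the per-base substitution
    probability in the read, ``index_error_rate`` the same for index bases.
    """

    sigma_col: float = 0.2
    sigma_row: float = 0.5
    error_rate: float = 1e-3
    index_error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.sigma_col, self.sigma_row, self.error_rate, self.index_error_rate) < 0:
            raise ConfigError("bias parameters must be non-negative")

    @classmethod
    def identity(cls) -> "BiasModel":
        return cls(sigma_col=0.0, sigma_row=0.0, error_rate=0.0, index_error_rate=0.0)


@dataclass
class ExpressionProfile:
    """Expected abundances and realised true molecule counts per sample."""

    layout: PlateLayout
    abundance: pd.DataFrame  # genes x samples, pre-bias relative abundance
    counts: pd.DataFrame  # genes x samples, true molecule counts (int)
    dispersion: pd.Series  # per-gene NB dispersion
    depth: float
    col_factors: pd.Series = field(default=None)  # per sample
    row_factors: pd.DataFrame = field(default=None)  # genes x pools

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def build_reference(
    n_mrna: int = 2000,
    mean_length: float = 2700.0,
    length_sigma: float = 0.7,
    min_length: int = 400,
    n_rrna: int = 1,
    rrna_length: int = 4500,
    n_ercc: int = 92,
    ercc_length_range: tuple[int, int] = (250, 2000),
    ercc_log2_dynamic_range: float = 20.0,
    polya_len: int = DEFAULT_POLYA_LEN,
    seed: int = 0,
) -> ReferenceSet:
    """Generate a synthetic transcriptome.

    mRNA lengths are lognormal with the configured mean (default 2700 nt,
    the typical mammalian transcript length); each mRNA is annotated as
    5'UTR / CDS / 3'UTR and carries a polyA tail.  The spike-in set has
    ``n_ercc`` species (92 by default, as in the commercial mix) with known
    relative concentrations log2-spaced over the configured dynamic range.
    Deterministic for a given seed.
    """
    if n_mrna < 1 or n_ercc < 1 or n_rrna < 0:
        raise ConfigError("species counts must be positive")
    if mean_length <= 0 or min_length <= 0:
        raise ConfigError("lengths must be positive")
    rng = np.random.default_rng(seed)
    transcripts: dict[str, Transcript] = {}

    mu = np.log(mean_length) - length_sigma**2 / 2
    lengths = np.maximum(
        rng.lognormal(mu, length_sigma, size=n_mrna).astype(int), min_length
    )
    for i, length in enumerate(lengths):
        gene_id = f"GENE{i + 1:05d}"
        length = int(length)
        # rough anatomy: 10% 5'UTR, 60% CDS, 30% 3'UTR
        u5 = max(1, int(0.1 * length))
        cds_end = max(u5 + 1, int(0.7 * length))
        ann = FeatureAnnotation(
            gene_id=gene_id,
            length=length,
            segments=[
                FeatureSegment("UTR5", 0, u5),
                FeatureSegment("CDS", u5, cds_end),
                FeatureSegment("UTR3", cds_end, length),
            ],
        )
        transcripts[gene_id] = Transcript(
            gene_id, _random_seq(rng, length), "mRNA", ann, polya_len=polya_len
        )

    for i in range(n_rrna):
        gene_id = f"RRNA{i + 1:03d}"
        ann = FeatureAnnotation(
            gene_id=gene_id,
            length=rrna_length,
            segments=[FeatureSegment("rRNA", 0, rrna_length)],
        )
        transcripts[gene_id] = Transcript(
            gene_id, _random_seq(rng, rrna_length), "rRNA", ann, polya_len=0
        )

    lo, hi = ercc_length_range
    ercc_lengths = rng.integers(lo, hi + 1, size=n_ercc)
    log2_conc = np.linspace(0.0, ercc_log2_dynamic_range, n_ercc)
    rng.shuffle(log2_conc)
    rows = []
    for i in range(n_ercc):
        gene_id = f"ERCC-{i + 1:05d}"
        length = int(ercc_lengths[i])
        ann = FeatureAnnotation(
            gene_id=gene_id,
            length=length,
            segments=[FeatureSegment("ERCC", 0, length)],
        )
        transcripts[gene_id] = Transcript(
            gene_id, _random_seq(rng, length), "ERCC", ann, polya_len=polya_len
        )
        rows.append((gene_id, length, float(2.0 ** log2_conc[i])))
    ercc = ErccTable(pd.DataFrame(rows, columns=["ercc_id", "length", "concentration"]))
    return ReferenceSet(transcripts=transcripts, ercc=ercc)


def simulate_expression(
    layout: PlateLayout,
    reference: ReferenceSet,
    fc_spec: dict[str, dict[str, float]] | None = None,
    depth: float = 100_000,
    bias: BiasModel | None = None,
    dispersion: float | pd.Series = 0.1,
    ercc_fraction: float = 0.03,
    rrna_fraction: float = 2e-5,
    abundance_sigma: float = 1.5,
    input_scale: dict[str, float] | None = None,
    seed: int = 0,
) -> ExpressionProfile:
    """Draw per-sample true molecule counts for every well of a plate.

    Parameters
    ----------
    fc_spec
        ``{condition: {gene_id: log2FC}}``; genes of samples in that
        condition get abundance multiplied by ``2**log2FC`` relative to
        baseline.  Conditions absent from the map are baseline.
    depth
        Expected number of library molecules (reads) per sample before bias.
    bias
        Bias model; defaults to :class:`BiasModel` defaults.  Column factors
        are drawn per i7 index (plate column), row factors per (pool,
        transcript) and shared by all samples of a pool.
    dispersion
        NB dispersion alpha (variance = mu + alpha*mu^2); scalar or per-gene.
    input_scale
        Optional per-sample multiplier on expected depth, modelling unequal
        RNA input amounts.
    """
    if depth < 0:
        raise ConfigError("depth must be non-negative")
    bias = bias if bias is not None else BiasModel()
    rng = np.random.default_rng(seed)
    genes = reference.gene_ids
    samples = layout.sample_ids
    conditions = layout.condition_of()
    if fc_spec:
        known = set(conditions.values())
        for cond in fc_spec:
            if cond not in known:
                raise ConfigError(f"fc_spec condition {cond!r} not present on the plate")
        for cond, genemap in fc_spec.items():
            unknown = set(genemap) - set(genes)
            if unknown:
                raise ConfigError(f"fc_spec genes not in reference: {sorted(unknown)[:5]}")

    mrna = reference.ids_of_class("mRNA")
    rrna = reference.ids_of_class("rRNA")
    ercc = reference.ids_of_class("ERCC")

    base = pd.Series(0.0, index=genes)
    base[mrna] = rng.lognormal(0.0, abundance_sigma, size=len(mrna))
    mrna_frac = 1.0 - ercc_fraction - rrna_fraction
    base[mrna] *= mrna_frac / base[mrna].sum()
    if ercc:
        conc = reference.ercc.concentrations().reindex(ercc)
        base[ercc] = (conc / conc.sum()).to_numpy() * ercc_fraction
    if rrna:
        base[rrna] = rrna_fraction / len(rrna)

    abundance = pd.DataFrame(
        np.tile(base.to_numpy()[:, None], (1, len(samples))), index=genes, columns=samples
    )
    if fc_spec:
        for cond, genemap in fc_spec.items():
            cond_samples = [s for s in samples if conditions[s] == cond]
            for g, lfc in genemap.items():
                abundance.loc[g, cond_samples] = base[g] * 2.0**lfc

    # column bias: one factor per i7 index, i.e. per plate column
    col_of = layout.col_of()
    n_cols = layout.cols
    col_f = rng.lognormal(0.0, bias.sigma_col, size=n_cols) if bias.sigma_col > 0 else np.ones(n_cols)
    col_factors = pd.Series([col_f[col_of[s]] for s in samples], index=samples)

    # row (pool) bias: per (pool, transcript), shared within a pool
    pool_of = layout.pool_of()
    pools = sorted(set(pool_of.values()))
    if bias.sigma_row > 0:
        row_f = rng.lognormal(0.0, bias.sigma_row, size=(len(genes), len(pools)))
    else:
        row_f = np.ones((len(genes), len(pools)))
    row_factors = pd.DataFrame(row_f, index=genes, columns=pools)

    scale = pd.Series(1.0, index=samples)
    if input_scale:
        for s, v in input_scale.items():
            scale[s] = v

    disp = (
        dispersion.reindex(genes).astype(float)
        if isinstance(dispersion, pd.Series)
        else pd.Series(float(dispersion), index=genes)
    )

    mean = abundance.to_numpy() * depth
    mean = mean * col_factors.to_numpy()[None, :] * scale.to_numpy()[None, :]
    pool_idx = np.array([pools.index(pool_of[s]) for s in samples])
    mean = mean * row_f[:, pool_idx]

    alpha = disp.to_numpy()[:, None]
    counts = np.zeros_like(mean, dtype=np.int64)
    pois_mask = (alpha <= 0) | (mean == 0)
    pois_mask = np.broadcast_to(pois_mask, mean.shape)
    counts[pois_mask] = rng.poisson(mean[pois_mask])
    nb = ~pois_mask
    if nb.any():
        a = np.broadcast_to(alpha, mean.shape)[nb]
        lam = rng.gamma(shape=1.0 / a, scale=mean[nb] * a)
        counts[nb] = rng.poisson(lam)

    return ExpressionProfile(
        layout=layout,
        abundance=abundance,
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        dispersion=disp,
        depth=depth,
        col_factors=col_factors,
        row_factors=row_factors,
    )


def _apply_substitutions(
    rng: np.random.Generator, seqs: list[str], error_rate: float
) -> list[str]:
    """Independent per-base substitutions at ``error_rate`` (in place copy)."""
    if error_rate <= 0:
        return seqs
    out = seqs
    n_err = rng.binomial(np.array([len(s) for s in seqs]), error_rate)
    hit = np.nonzero(n_err)[0]
    for i in hit:
        s = bytearray(out[i], "ascii")
        for pos in rng.integers(0, len(s), size=n_err[i]):
            old = s[pos]
            choices = [b for b in b"ACGT" if b != old]
            s[pos] = choices[rng.integers(0, len(choices))]
        out[i] = s.decode()
    return out


def simulate_reads(
    profile: ExpressionProfile,
    reference: ReferenceSet,
    bias: BiasModel | None = None,
    readlen: int = DEFAULT_READ_LENGTH,
    mean_library: float = DEFAULT_MEAN_LIBRARY_LENGTH,
    adapter_overhead: int = DEFAULT_ADAPTER_OVERHEAD,
    insert_sigma: float = 0.7,
    min_insert: int = 26,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Sequence one 3'-terminal fragment per true molecule.

    For each molecule the insert length (tagmentation breakpoint to polyA
    anchor) is lognormal with mean ``mean_library - adapter_overhead``
    (414 bp by default) and a broad tagmentation-like spread
    (``insert_sigma`` on the natural-log scale), clamped to
    ``[min_insert, transcript length]``.
    The read is ``readlen`` nt of sense strand starting at the breakpoint;
    if the insert is shorter than the read the remainder reads into the
    polyA tail and is emitted as 'A'.  rRNA molecules have no polyA anchor
    and are fragmented at a uniform random position instead.

    Returns the reads plus a truth table with one row per read:
    ``read_id, sample_id, gene_id, insert_len, offset3p`` (the breakpoint
    offset from the transcript 3' end, equal to the realised insert).
    Library molecule length is ``insert_len + adapter_overhead``.
    """
    bias = bias if bias is not None else BiasModel()
    if profile.counts.to_numpy().sum() == 0:
        raise ConfigError("profile contains no molecules to simulate")
    mean_insert = mean_library - adapter_overhead
    if mean_insert <= min_insert:
        raise ConfigError("mean library length must exceed adapter overhead + min insert")
    rng = np.random.default_rng(seed)
    mu = np.log(mean_insert) - insert_sigma**2 / 2
    qual = chr(33 + 30)  # constant Q30; the pipeline never uses qualities

    genes = list(profile.counts.index)
    glen = np.array([reference.transcripts[g].length for g in genes])
    is_rrna = np.array(
        [reference.transcripts[g].feature_class == "rRNA" for g in genes]
    )
    padded = {
        g: reference.transcripts[g].seq + "A" * (readlen + 1) for g in genes
    }
    barcode_of = {w.sample_id: w.barcode for w in profile.layout.wells}

    records: list[ReadRecord] = []
    truth_rows: list[tuple] = []
    serial = 0
    for sample in profile.sample_ids:
        counts = profile.counts[sample].to_numpy()
        gidx = np.repeat(np.arange(len(genes)), counts)
        n = len(gidx)
        if n == 0:
            continue
        inserts = rng.lognormal(mu, insert_sigma, size=n)
        inserts = np.clip(np.rint(inserts).astype(int), min_insert, glen[gidx])
        # rRNA: no polyA anchor, uniform fragmentation instead
        rr = is_rrna[gidx]
        if rr.any():
            max_start = np.maximum(glen[gidx[rr]] - readlen, 0)
            starts = (rng.random(rr.sum()) * (max_start + 1)).astype(int)
            inserts[rr] = glen[gidx[rr]] - starts
        breakpoints = glen[gidx] - inserts

        seqs = [padded[genes[g]][b : b + readlen] for g, b in zip(gidx, breakpoints)]
        seqs = _apply_substitutions(rng, seqs, bias.error_rate)

        bc = barcode_of[sample]
        i5s = [bc.i5] * n
        i7s = [bc.i7] * n
        if bias.index_error_rate > 0:
            i5s = _apply_substitutions(rng, i5s, bias.index_error_rate)
            i7s = _apply_substitutions(rng, i7s, bias.index_error_rate)

        for j in range(n):
            read_id = f"r{serial:09d}"
            serial += 1
            records.append(
                ReadRecord(
                    read_id=read_id,
                    sequence=seqs[j],
                    quality=qual * readlen,
                    i7=i7s[j],
                    i5=i5s[j],
                )
            )
            truth_rows.append(
                (read_id, sample, genes[gidx[j]], int(inserts[j]), int(inserts[j]))
            )

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "gene_id", "insert_len", "offset3p"]
    )
    return records, truth


def simulate_run(
    outdir: str | Path,
    layout: PlateLayout,
    reference: ReferenceSet | None = None,
    seed: int = 0,
    **kwargs,
) -> dict[str, Path]:
    """End-to-end convenience: reference + expression + reads, written to disk.

    Keyword arguments are routed to :func:`build_reference` /
    :func:`simulate_expression` / :func:`simulate_reads` by name.  Writes
    ``reads.fastq``, ``truth.tsv``, ``true_counts.tsv`` and the reference
    files; returns the paths.
    """
    import inspect

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _kwargs_for(fn):
        params = set(inspect.signature(fn).parameters)
        return {k: v for k, v in kwargs.items() if k in params}

    if reference is None:
        reference = build_reference(seed=seed, **_kwargs_for(build_reference))
    reference.write(outdir)
    bias = kwargs.get("bias")
    profile = simulate_expression(
        layout, reference, seed=seed + 1, **_kwargs_for(simulate_expression)
    )
    read_kwargs = _kwargs_for(simulate_reads)
    read_kwargs.pop("bias", None)
    records, truth = simulate_reads(
        profile, reference, bias=bias, seed=seed + 2, **read_kwargs
    )
    paths = {
        "fastq": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "true_counts": outdir / "true_counts.tsv",
        "reference": outdir / "reference.fasta",
        "annotation": outdir / "annotation.gtf",
        "ercc": outdir / "ercc.tsv",
    }
    write_fastq(records, paths["fastq"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    profile.counts.to_csv(paths["true_counts"], sep="\t")
    return paths
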