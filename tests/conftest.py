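import numpy as np
import pandas as pd
import pytest

from pool3seq import core_io, preprocess, quantify, simulate


@pytest.fixture(scope="session")
def small_layout():
    return core_io.make_row_pooling_layout(
        2, 3, conditions=["A", "A", "A", "B", "B", "B"]
    )


@pytest.fixture(scope="session")
def small_reference():
    return simulate.build_reference(n_mrna=60, seed=11)


@pytest.fixture(scope="session")
def clean_run(small_layout, small_reference):
    """A zero-noise simulated run processed end to end.

    No biases, no sequencing error, Poisson counting only; shared by tests
    that compare pipeline output against the simulator truth tables.
    """
    profile = simulate.simulate_expression(
        small_layout,
        small_reference,
        fc_spec={"B": {"GENE00001": 2.0, "GENE00002": -1.5}},
        depth=5000,
        bias=simulate.BiasModel.identity(),
        dispersion=0.0,
        seed=21,
    )
    reads, truth = simulate.simulate_reads(
        profile, small_reference, bias=simulate.BiasModel.identity(), seed=22
    )
    demux = preprocess.demultiplex(reads, small_layout, max_mismatch=1)
    trimmed = {
        s: preprocess.trim_reads(rs)[0] for s, rs in demux.assigned.items()
    }
    index = quantify.TranscriptomeIndex(small_reference.fasta_sequences())
    alignments = {s: quantify.align_reads(rs, index) for s, rs in trimmed.items()}
    lengths = {r.read_id: len(r.sequence) for rs in trimmed.values() for r in rs}
    counts = quantify.assign_and_count(
        alignments, small_reference.annotations(), read_lengths=lengths
    )
    return {
        "layout": small_layout,
        "reference": small_reference,
        "profile": profile,
        "reads": reads,
        "truth": truth,
        "demux": demux,
        "trimmed": trimmed,
        "index": index,
        "alignments": alignments,
        "counts": counts,
    }
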