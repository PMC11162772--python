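import numpy as np
import pytest

from bowlseq.assign import extract_read_ends
from bowlseq.readprep import dedup_umi, demultiplex, prep_reads
from bowlseq.simulate import (
    GeneSimSpec,
    SimConfig,
    TailDistribution,
    make_gene_specs,
    random_reference,
    simulate_library,
    simulate_truth_alignments,
    transcript_seq,
)
from bowlseq.tailcall import call_tail_softclip


def test_same_seed_is_byte_identical(tmp_path, small_reference):
    specs = tuple(make_gene_specs(small_reference, n_genes=3))
    cfg = SimConfig(seed=42, genes=specs, reads_per_gene=15)
    paths = []
    for i in range(2):
        lib = simulate_library(cfg, small_reference)
        p = tmp_path / f"run{i}.fastq"
        lib.write_fastq(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_different_seed_differs(small_reference):
    specs = tuple(make_gene_specs(small_reference, n_genes=2))
    a = simulate_library(SimConfig(seed=1, genes=specs, reads_per_gene=5),
                         small_reference)
    b = simulate_library(SimConfig(seed=2, genes=specs, reads_per_gene=5),
                         small_reference)
    assert [r.seq for r in a.reads] != [r.seq for r in b.reads]


def test_noiseless_round_trip_recovers_every_tail(noiseless_library, tmp_path):
    """Zero noise: parsing + truth alignments return each 60-nt tail exactly."""
    lib = noiseless_library
    parsed, rejected = prep_reads(lib.reads)
    assert sum(rejected.values()) == 0 and len(parsed) == len(lib.reads)
    by_sample, unassigned = demultiplex(parsed, lib.config.sample_sheet)
    assert not unassigned
    sam = tmp_path / "truth.sam"
    simulate_truth_alignments(lib, sam)
    inserts = {r.read_id: r for s in by_sample.values() for r in s}
    ends, _ = extract_read_ends(sam)
    assert len(ends) == len(lib.reads)
    for e in ends:
        call = call_tail_softclip(inserts[e.read_id], e.align_end_offset)
        assert call.tail_len == 60 and call.non_a_count == 0


def test_truth_alignments_reproduce_cleavage_positions(noisy_library, tmp_path):
    lib = noisy_library
    sam = tmp_path / "truth.sam"
    simulate_truth_alignments(lib, sam)
    ends, _ = extract_read_ends(sam, min_tail_len=0)
    truth = {r.read_id: int(r.cleavage_pos) for r in lib.truth.itertuples(index=False)
             if r.kind == "gene"}
    assert len(ends) == len(truth)
    for e in ends:
        assert e.cleavage_pos == truth[e.read_id]


def test_two_exon_genes_align_across_the_intron(small_reference, tmp_path):
    specs = make_gene_specs(
        small_reference, n_genes=2, n_exons=2,
        tail=TailDistribution("constant", 30.0),
    )
    cfg = SimConfig(seed=9, genes=tuple(specs), reads_per_gene=8,
                    duplicate_rate=0.0, index_error_rate=0.0,
                    cleavage_jitter_sd=0.0, non_a_rate=0.0)
    lib = simulate_library(cfg, small_reference)
    sam = tmp_path / "truth.sam"
    simulate_truth_alignments(lib, sam)
    ends, _ = extract_read_ends(sam)
    truth = dict(zip(lib.truth["read_id"], lib.truth["cleavage_pos"]))
    assert len(ends) == len(lib.reads)
    for e in ends:
        assert e.cleavage_pos == truth[e.read_id]
        assert e.tail_len == 30


@pytest.mark.parametrize("strand", ["+", "-"])
def test_transcript_sequence_is_spliced_and_oriented(strand):
    ref = {"chr1": "".join("ACGT"[i % 4] for i in range(100))}
    from bowlseq.annotation import GeneModel

    gene = GeneModel.from_exons("g", "chr1", strand, [(10, 20), (30, 40)], 35)
    if strand == "+":
        seq = transcript_seq(ref, gene, 35)
        assert seq == ref["chr1"][10:20] + ref["chr1"][30:36]
    else:
        seq = transcript_seq(ref, gene, 35)
        from bowlseq.readprep import reverse_complement

        assert seq == reverse_complement(ref["chr1"][35:40])


def test_duplicate_rate_and_dedup_restore_unique_count(small_reference):
    specs = tuple(make_gene_specs(small_reference, n_genes=2))
    cfg = SimConfig(seed=5, genes=specs, reads_per_gene=50, duplicate_rate=0.5,
                    index_error_rate=0.0)
    lib = simulate_library(cfg, small_reference)
    n_dup = int(lib.truth["is_duplicate"].sum())
    n_orig = int((~lib.truth["is_duplicate"]).sum())
    assert n_orig == 100
    se = (0.5 * 0.5 / n_orig) ** 0.5
    assert abs(n_dup / n_orig - 0.5) <= 3 * se
    parsed, _ = prep_reads(lib.reads)
    by_sample, _ = demultiplex(parsed, cfg.sample_sheet)
    total_unique = sum(len(dedup_umi(reads)) for reads in by_sample.values())
    expected = lib.truth.groupby("sample")["true_umi"].nunique().sum()
    assert total_unique == expected


def test_half_of_reads_are_flipped(noisy_library):
    from bowlseq.readprep import prep_reads

    parsed, _ = prep_reads(noisy_library.reads)
    frac = np.mean([r.orientation_flipped for r in parsed])
    assert 0.4 < frac < 0.6


def test_gene_outside_reference_errors(small_reference):
    from bowlseq.annotation import GeneModel

    bad = GeneSimSpec(
        model=GeneModel.from_exons("g", "chrMissing", "+", [(0, 500)], 100),
        site_offsets=(20,),
        usage=(1.0,),
    )
    with pytest.raises(ValueError, match="chromosome"):
        simulate_library(SimConfig(seed=0, genes=(bad,)), small_reference)


def test_usage_probabilities_validated():
    from bowlseq.annotation import GeneModel

    model = GeneModel.from_exons("g", "chr1", "+", [(0, 500)], 100)
    with pytest.raises(ValueError, match="sum to 1"):
        GeneSimSpec(model=model, site_offsets=(20, 100), usage=(0.5, 0.4))
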