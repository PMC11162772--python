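"""End-to-end orchestration: readprep -> tailcall -> assign -> apacall.

:func:`run_pipeline` takes raw structured reads, a sample sheet, a gene
annotation and spliced alignments of the clean inserts, and produces
per-stage tables plus a run manifest with read counts in and out of every
stage. The pipeline itself is deterministic; all randomness lives in the
simulator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import GeneModel, load_annotation
from .apacall import (
    ApaParams,
    apa_shift_test,
    assign_reads_to_sites,
    call_sites,
    distal_ratio,
    label_sites,
)
from .assign import ReadEnd, assign_genes, extract_read_ends, write_read_ends_bed
from .readprep import (
    OligoLayout,
    CleanRead,
    demultiplex,
    dedup_umi,
    prep_reads,
    read_fastx,
    read_sample_sheet,
    write_clean_fastq,
)
from .tailcall import call_tail_softclip

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "apa_gene_tables", "write_sites"]


def apa_gene_tables(
    ends: Sequence[ReadEnd],
    genes: Sequence[GeneModel],
    params: ApaParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Call, quantify and label poly(A) sites for every gene.

    ``ends`` must already carry gene assignments. Sites are called on the
    pooled reads of each gene and then counted per sample. Returns
    (site table, per-read assignment table, summary dict). The summary
    counts genes by number of called sites (genes with zero sites included,
    mirroring an "APA site = 0" category) and reports per-sample distal-read
    fractions.
    """
    params = params or ApaParams()
    gene_by_id = {g.gene_id: g for g in genes}
    by_gene: dict[str, list[ReadEnd]] = {}
    for e in ends:
        if e.gene_id is not None:
            by_gene.setdefault(e.gene_id, []).append(e)

    samples = sorted({e.sample for e in ends if e.sample is not None})
    site_rows, read_rows = [], []
    sites_per_gene: dict[str, int] = {}
    distal_reads = {s: 0 for s in samples}
    total_reads = {s: 0 for s in samples}
    for gene_id, gene_ends in sorted(by_gene.items()):
        gene = gene_by_id[gene_id]
        sites = call_sites(gene_ends, params)
        sites_per_gene[gene_id] = len(sites)
        if not sites:
            continue
        sites, _unassigned = assign_reads_to_sites(gene_ends, sites, params)
        label_sites(sites, gene)
        for rank, s in enumerate(
            sorted(sites, key=lambda s: abs(s.dist_to_stop)), start=1
        ):
            row = {
                "gene_id": gene_id,
                "chrom": s.chrom,
                "strand": s.strand,
                "pos": s.pos,
                "windowed_depth": s.windowed_depth,
                "dist_to_stop": s.dist_to_stop,
                "label": s.label,
                "rank": rank,
            }
            for sample in samples:
                row[f"reads_{sample}"] = s.assigned_reads.get(sample, 0)
                total_reads[sample] += s.assigned_reads.get(sample, 0)
                if s.label == "distal":
                    distal_reads[sample] += s.assigned_reads.get(sample, 0)
            site_rows.append(row)
        # per-read table for shift testing: each read inherits its site's
        # stop-codon distance
        strand = sites[0].strand
        for e in gene_ends:
            nearest = min(
                sites,
                key=lambda s: (
                    abs(e.cleavage_pos - s.pos),
                    s.pos if strand == "+" else -s.pos,
                ),
            )
            if abs(e.cleavage_pos - nearest.pos) <= params.assign_radius:
                read_rows.append(
                    {
                        "read_id": e.read_id,
                        "sample": e.sample,
                        "gene_id": gene_id,
                        "site_pos": nearest.pos,
                        "dist_to_stop": nearest.dist_to_stop,
                        "label": nearest.label,
                        "tail_len": e.tail_len,
                    }
                )

    site_df = pd.DataFrame(site_rows)
    read_df = pd.DataFrame(
        read_rows,
        columns=[
            "read_id", "sample", "gene_id", "site_pos", "dist_to_stop",
            "label", "tail_len",
        ],
    )
    n_sites_hist: dict[int, int] = {}
    for n in sites_per_gene.values():
        n_sites_hist[n] = n_sites_hist.get(n, 0) + 1
    summary = {
        "genes_by_site_count": {str(k): v for k, v in sorted(n_sites_hist.items())},
        "distal_read_fraction": {
            s: (distal_reads[s] / total_reads[s] if total_reads[s] else None)
            for s in samples
        },
    }
    return site_df, read_df, summary


def write_sites(site_df: pd.DataFrame, path: str | Path) -> None:
    """Emit called sites as BED6+ (name=gene:rank, score=windowed depth)."""
    with open(path, "w") as fh:
        for row in site_df.itertuples(index=False):
            extras = [
                str(getattr(row, c))
                for c in site_df.columns
                if c.startswith("reads_")
            ]
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        str(row.pos),
                        str(row.pos + 1),
                        f"{row.gene_id}:{row.rank}",
                        str(row.windowed_depth),
                        row.strand,
                        str(row.dist_to_stop),
                        row.label,
                    ]
                    + extras
                )
                + "\n"
            )


def run_pipeline(
    fastq: str | Path,
    sample_sheet: str | Path,
    annotation: str | Path,
    alignments: str | Path,
    outdir: str | Path,
    layout: OligoLayout | None = None,
    params: ApaParams | None = None,
    conditions: tuple[str, str] | None = None,
    flank: int = 1000,
    min_tail_len: int = 1,
    annotation_format: str | None = None,
) -> dict:
    """Run the full pipeline and write all stage outputs under ``outdir``.

    ``conditions`` names the two samples compared in the APA-shift test
    (default: the first two sheet samples). Returns the manifest dict, also
    written to ``outdir/manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = layout or OligoLayout()
    params = params or ApaParams()

    for p in (fastq, sample_sheet, annotation, alignments):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    sheet = read_sample_sheet(sample_sheet)
    fmt = annotation_format or (
        "bed12" if str(annotation).endswith(".bed") else "refgene_table"
    )
    genes = load_annotation(annotation, format=fmt)

    # --- stage 1: parse, demultiplex, deduplicate -------------------------
    raw = read_fastx(fastq)
    parsed, rejected = prep_reads(raw, layout)
    by_sample, unassigned = demultiplex(parsed, sheet, layout)
    clean: dict[str, list[CleanRead]] = {
        s: dedup_umi(reads) for s, reads in by_sample.items()
    }
    for sample, reads in clean.items():
        write_clean_fastq(reads, outdir / f"clean_{sample}.fastq")
    pd.DataFrame(
        sorted(rejected.items()), columns=["reason", "count"]
    ).to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    retained: dict[str, CleanRead] = {
        r.read_id: r for reads in clean.values() for r in reads
    }

    # --- stage 2: read ends + tails from alignments -----------------------
    ends_all, end_counts = extract_read_ends(alignments, min_tail_len=min_tail_len)
    ends, tail_rows = [], []
    for e in ends_all:
        r = retained.get(e.read_id)
        if r is None:  # duplicate/rejected/unassigned read
            continue
        offset = min(e.align_end_offset, len(r.insert_seq))
        call = call_tail_softclip(r, offset)
        tail_rows.append(
            {
                "read_id": r.read_id,
                "sample": r.sample,
                "tail_len": call.tail_len,
                "non_a_count": call.non_a_count,
                "non_a_frac": round(call.non_a_frac, 6),
                "method": call.method,
            }
        )
        ends.append(replace(e, sample=r.sample, tail_len=call.tail_len))
    pd.DataFrame(
        tail_rows,
        columns=["read_id", "sample", "tail_len", "non_a_count", "non_a_frac",
                 "method"],
    ).to_csv(outdir / "tails.tsv", sep="\t", index=False)

    # --- stage 3: gene assignment ----------------------------------------
    assigned, assign_counts = assign_genes(ends, genes, flank=flank)
    write_read_ends_bed(assigned, outdir / "read_ends.bed")
    ends_df = pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "sample": e.sample,
                "chrom": e.chrom,
                "strand": e.strand,
                "cleavage_pos": e.cleavage_pos,
                "tail_len": e.tail_len,
                "gene_id": e.gene_id,
            }
            for e in assigned
        ]
    )
    ends_df.to_csv(outdir / "read_ends.tsv", sep="\t", index=False)

    # --- stage 4: APA calling + shift test --------------------------------
    site_df, read_df, apa_summary = apa_gene_tables(assigned, genes, params)
    site_df.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    if len(site_df):
        write_sites(site_df, outdir / "sites.bed")
    read_df.to_csv(outdir / "reads_at_sites.tsv", sep="\t", index=False)

    samples = sorted({s for s in sheet.values()})
    if conditions is None and len(samples) >= 2:
        conditions = (samples[0], samples[1])
    shift = None
    if conditions is not None and len(read_df):
        da = read_df.loc[read_df["sample"] == conditions[0], "dist_to_stop"]
        db = read_df.loc[read_df["sample"] == conditions[1], "dist_to_stop"]
        if len(da) and len(db):
            res = apa_shift_test(
                da.tolist(), db.tolist(), cutoff=params.stop_codon_cutoff
            )
            shift = {
                "condition_a": conditions[0],
                "condition_b": conditions[1],
                "cutoff": params.stop_codon_cutoff,
                "table": [list(r) for r in res.table],
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "continuity_corrected": res.continuity_corrected,
            }

    manifest = {
        "tool": "bowlseq",
        "version": __version__,
        "inputs": {
            "fastq": str(fastq),
            "sample_sheet": str(sample_sheet),
            "annotation": str(annotation),
            "alignments": str(alignments),
        },
        "params": {**asdict(params), **asdict(layout), "flank": flank,
                   "min_tail_len": min_tail_len},
        "counts": {
            "raw_reads": len(raw),
            "parsed": len(parsed),
            "rejected": dict(sorted(rejected.items())),
            "demultiplexed": {s: len(r) for s, r in sorted(by_sample.items())},
            "demux_unassigned": len(unassigned),
            "deduplicated": {s: len(r) for s, r in sorted(clean.items())},
            "alignment_records": dict(sorted(end_counts.items())),
            "ends_with_tail": len(ends),
            "gene_assignment": dict(sorted(assign_counts.items())),
        },
        "apa": apa_summary,
        "shift_test": shift,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
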