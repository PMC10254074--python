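"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython, VCF through pysam (with a custom per-sample
``LQA`` integer carrying low-quality alt-read counts), depth tracks are
BED-style 0-based half-open ``chrom start end depth`` tables, and truth /
summary tables are plain TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .callable_sites import CallableSummary, CoverageTrack
from .denovo_filter import MutationCandidate, ReadSupport, VariantRecord
from .synthetic_data import Reference, TruthTable

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_repeats_bed",
    "write_depth_bed",
    "read_depth_bed",
    "write_vcf",
    "read_vcf",
    "write_truth",
    "write_candidates",
    "write_mask_bed",
    "write_callable_summary",
]


# --- FASTA -----------------------------------------------------------------

def write_fasta(reference: Reference, path) -> None:
    records = [
        SeqRecord(Seq(arr.tobytes().decode()), id=chrom, description="")
        for chrom, arr in reference.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Reference:
    sequences = {
        rec.id: np.frombuffer(str(rec.seq).upper().encode(), dtype="S1").copy()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return Reference(sequences=sequences, repeats=[])


def write_repeats_bed(reference: Reference, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in reference.repeats:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# --- depth BED -------------------------------------------------------------

def write_depth_bed(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, d in track.to_intervals():
            fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_depth_bed(
    path, individual: str, chrom_lengths: Optional[Mapping[str, int]] = None
) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str},
    )
    intervals = [
        (r.chrom, int(r.start), int(r.end), int(r.depth)) for r in df.itertuples()
    ]
    return CoverageTrack.from_intervals(individual, intervals, chrom_lengths)


# --- VCF -------------------------------------------------------------------

def _vcf_header(
    individuals: Sequence[str], chrom_lengths: Mapping[str, int]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add(
        "LQA", 1, "Integer", "Low-quality alternative-allele read count"
    )
    for ind in individuals:
        header.add_sample(ind)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    individuals: Sequence[str],
    chrom_lengths: Mapping[str, int],
    path,
) -> None:
    """Write a multi-sample VCF with DP/AD plus the custom LQA field."""
    header = _vcf_header(individuals, chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for ind in individuals:
                s = rec.support.get(ind, ReadSupport(0, 0, 0))
                sample = row.samples[ind]
                sample["GT"] = (1,) if s.alt_depth > 0 else (0,)
                sample["DP"] = s.depth
                sample["AD"] = (s.depth - s.alt_depth, s.alt_depth)
                sample["LQA"] = s.low_quality_alt
            vcf.write(row)


def read_vcf(path, var_class: str = "SNV") -> List[VariantRecord]:
    """Read a multi-sample VCF into variant records (multi-allelics split)."""
    out: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            for alt in row.alts or ():
                support: Dict[str, ReadSupport] = {}
                for ind in samples:
                    s = row.samples[ind]
                    dp = s.get("DP") or 0
                    ad = s.get("AD")
                    alt_depth = int(ad[1]) if ad and ad[1] is not None else 0
                    lqa = int(s.get("LQA") or 0)
                    support[ind] = ReadSupport(int(dp), alt_depth, lqa)
                out.append(
                    VariantRecord(
                        chrom=row.chrom, pos=row.pos, ref=row.ref, alt=alt,
                        var_class=var_class, support=support,
                    )
                )
    return out


# --- truth, candidates, callable summaries --------------------------------

def write_truth(truth: TruthTable, path) -> None:
    rows = []
    for ind, chrom, pos, ref, alt in truth.true_mutations:
        rows.append(("true_mutation", chrom, pos, ind, f"{ref}>{alt}"))
    for chrom, pos, carriers in truth.standing_variants:
        rows.append(("standing_variant", chrom, pos, ",".join(carriers), ""))
    for ind, chrom, pos, frac in truth.somatic_events:
        rows.append(("somatic_event", chrom, pos, ind, f"{frac:.3f}"))
    for chrom, pos, affected in truth.artifacts:
        rows.append(("artifact", chrom, pos, ",".join(affected), ""))
    for ind, chroms in truth.duplicated_chromosomes.items():
        rows.append(("duplicated_chromosomes", ",".join(chroms), 0, ind, ""))
    pd.DataFrame(
        rows, columns=["event", "chrom", "pos", "individuals", "detail"]
    ).to_csv(path, sep="\t", index=False)


def write_candidates(candidates: Sequence[MutationCandidate], path) -> None:
    rows = [
        (
            c.record.chrom, c.record.pos, c.record.ref, c.record.alt,
            c.record.var_class, c.carrier or "", c.status, c.reason or "",
        )
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "var_class", "carrier", "status", "reason"],
    ).to_csv(path, sep="\t", index=False)


def write_mask_bed(mask: Mapping[str, np.ndarray], path) -> None:
    """Write callable runs of a boolean per-position mask as BED intervals."""
    with open(path, "w") as fh:
        for chrom, m in mask.items():
            if m.size == 0:
                continue
            padded = np.concatenate(([False], m, [False]))
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_callable_summary(summary: CallableSummary, path) -> None:
    pd.DataFrame(
        [
            {
                "scheme": summary.scheme,
                "min_depth": summary.min_depth,
                "min_individuals": summary.min_individuals,
                "G_star": summary.G_star,
                "distinct_positions": summary.distinct_positions,
                "genome_length": summary.genome_length,
                "callable_fraction": summary.callable_fraction,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
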