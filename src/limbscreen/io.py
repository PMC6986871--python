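"""Readers and writers for the pipeline's file formats.

FASTQ parsing goes through pysam's fast C parser; references travel as
FASTA with ``key=value`` annotations (cut site, primer length, role) in the
description line; tabular interchange (sample sheet, counts, normalized
alleles, pairs) is TSV via pandas.
"""

from __future__ import annotations

import gzip

import pandas as pd
import pysam

from .alleles import AlleleCountTable, AlleleKey, AmpliconTarget
from .quantify import NormalizedAllele, PairedAllele

SHEET_COLUMNS = ["sample_id", "animal_id", "limb", "gene", "index_seq", "is_control"]


def read_fastq(path):
    """Yield ``(name, sequence)`` from a FASTQ file (gzip transparent)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_fastq(records, path) -> None:
    """Write ``(name, sequence)`` pairs as 4-line FASTQ with constant quality."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_targets(path) -> dict[str, AmpliconTarget]:
    """Load amplicon targets from an annotated FASTA.

    Each record's description must carry ``cut_site=<int>`` and
    ``primer_len=<int>``; ``role=control|experimental`` is optional.
    """
    targets: dict[str, AmpliconTarget] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            attrs = dict(kv.split("=", 1) for kv in (entry.comment or "").split()
                         if "=" in kv)
            if "cut_site" not in attrs or "primer_len" not in attrs:
                raise ValueError(
                    f"{entry.name}: FASTA description needs cut_site= and primer_len=")
            seq = entry.sequence.upper()
            targets[entry.name] = AmpliconTarget(
                gene_name=entry.name, reference_seq=seq,
                cut_site=int(attrs["cut_site"]),
                gene_primer=seq[: int(attrs["primer_len"])],
                role=attrs.get("role", "experimental"))
    return targets


def write_targets(targets, path) -> None:
    with open(path, "w") as fh:
        for t in targets.values() if isinstance(targets, dict) else targets:
            fh.write(f">{t.gene_name} cut_site={t.cut_site} "
                     f"primer_len={len(t.gene_primer)} role={t.role}\n"
                     f"{t.reference_seq}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet["is_control"] = sheet["is_control"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes"))
    return sheet


def write_count_tables(tables, path) -> None:
    """Write allele count tables as one long-form TSV."""
    rows = []
    for t in tables.values() if isinstance(tables, dict) else tables:
        for key, c in sorted(t.counts.items(), key=lambda kv: kv[0].descriptor):
            rows.append({"sample_id": t.sample_id, "gene": t.gene,
                         "allele_descriptor": key.descriptor, "unique_reads": c,
                         "total_assigned": t.total_assigned,
                         "unassigned_reads": t.unassigned_reads})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_tables(path) -> dict[tuple[str, str], AlleleCountTable]:
    df = pd.read_csv(path, sep="\t", dtype={"allele_descriptor": str})
    tables: dict[tuple[str, str], AlleleCountTable] = {}
    for (sid, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        counts = {AlleleKey(gene, d): int(c)
                  for d, c in zip(grp["allele_descriptor"], grp["unique_reads"])}
        tables[(sid, gene)] = AlleleCountTable(
            sample_id=sid, gene=gene, counts=counts,
            total_assigned=sum(counts.values()),
            unassigned_reads=int(grp["unassigned_reads"].iloc[0]))
    return tables


def normalized_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "gene": r.gene,
        "allele_descriptor": r.allele.descriptor, "unique_reads": r.unique_reads,
        "rp10k": r.rp10k, "log2_rp10k": r.log_score, "frequency": r.frequency,
    } for r in records])


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal": p.animal, "gene": p.gene,
        "allele_descriptor": p.allele.descriptor,
        "primary_reads": p.primary.unique_reads,
        "secondary_reads": p.secondary.unique_reads,
        "primary_rp10k": p.primary.rp10k, "secondary_rp10k": p.secondary.rp10k,
        "primary_log2_rp10k": p.primary.log_score,
        "secondary_log2_rp10k": p.secondary.log_score,
        "primary_frequency": p.primary.frequency,
        "lost": p.lost, "fold_change": p.fold_change,
    } for p in pairs])


def read_allele_score_table(path) -> dict[str, list[PairedAllele]]:
    """Load an external per-allele score table as pairs grouped by gene.

    Expected TSV columns: ``animal``, ``gene``, ``allele_descriptor`` (or
    ``allele``), ``primary_reads``, ``secondary_reads``, ``primary_rp10k``,
    ``secondary_rp10k``; log scores are taken from
    ``primary_log2_rp10k``/``secondary_log2_rp10k`` when present and
    computed as log2(RP10K + 1) otherwise. This is the route for analyzing
    published per-allele supplementary tables with the same statistics as
    pipeline output.
    """
    import math

    df = pd.read_csv(path, sep="\t")
    if "allele" in df.columns and "allele_descriptor" not in df.columns:
        df = df.rename(columns={"allele": "allele_descriptor"})
    for col in ("primary_log2_rp10k", "secondary_log2_rp10k"):
        side = col.split("_")[0]
        if col not in df.columns:
            df[col] = (df[f"{side}_rp10k"] + 1.0).map(math.log2)
    by_gene: dict[str, list[PairedAllele]] = {}
    for row in df.itertuples(index=False):
        key = AlleleKey(row.gene, str(row.allele_descriptor))
        prim = NormalizedAllele(
            sample_id=f"{row.animal}_primary", gene=row.gene, allele=key,
            unique_reads=int(row.primary_reads), rp10k=float(row.primary_rp10k),
            log_score=float(row.primary_log2_rp10k), frequency=float("nan"))
        sec = NormalizedAllele(
            sample_id=f"{row.animal}_secondary", gene=row.gene, allele=key,
            unique_reads=int(row.secondary_reads), rp10k=float(row.secondary_rp10k),
            log_score=float(row.secondary_log2_rp10k), frequency=float("nan"))
        by_gene.setdefault(row.gene, []).append(PairedAllele(
            animal=str(row.animal), gene=row.gene, allele=key,
            primary=prim, secondary=sec))
    return by_gene
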