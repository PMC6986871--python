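"""End-to-end orchestration: FASTQ -> allele counts -> pairs -> screen report.

The read-level pass is streaming (one pass over the pooled FASTQ, constant
memory per unique molecule) and memoizes allele calls per insert, so the
alignment cost scales with the number of distinct error patterns rather
than the number of reads.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from . import io as lsio
from .alleles import (
    AlleleCaller,
    AlleleCountTable,
    AlleleKey,
    ReadLayout,
    Unassigned,
    _mismatches_over,
    _resolve_umi,
    filter_artifacts,
    load_index_map,
)
from .quantify import (
    NormalizedAllele,
    PairedAllele,
    SampleFailedError,
    normalize,
    pair_limbs,
)
from .sim import DEFAULT_ADAPTER
from .stats import ScreenReport, build_screen_report

logger = logging.getLogger(__name__)

DEFAULT_LAYOUT = ReadLayout(adapter_seq=DEFAULT_ADAPTER)


@dataclass
class CallResult:
    """Per-sample-per-gene count tables plus read-accounting."""

    tables: dict[tuple[str, str], AlleleCountTable]
    unassigned: pd.DataFrame  # columns: sample_id, reason, reads

    def table(self, sample_id: str, gene: str) -> AlleleCountTable:
        return self.tables[(sample_id, gene)]


@dataclass
class DatasetPairs:
    pairs_by_gene: dict[str, list[PairedAllele]]
    secondary_only: list[NormalizedAllele] = field(default_factory=list)
    normalized: list[NormalizedAllele] = field(default_factory=list)
    failed_samples: list[tuple[str, str]] = field(default_factory=list)


def call_fastq(fastq_path, targets, sheet: pd.DataFrame,
               layout: ReadLayout = DEFAULT_LAYOUT,
               control_filter: bool = True) -> CallResult:
    """Demultiplex, extract UMIs, call alleles and deduplicate, streaming.

    ``targets`` maps gene name -> AmpliconTarget; ``sheet`` is a sample
    sheet frame (one row per sample x gene). When ``control_filter`` is on,
    alleles recurring in each gene's non-mutant control sample are removed
    from the other samples of that gene.
    """
    rows = sheet.to_dict("records")
    index_map = load_index_map(rows)
    index_lengths = sorted({len(k) for k in index_map})
    genes_for_sample: dict[str, list[str]] = defaultdict(list)
    for row in rows:
        genes_for_sample[row["sample_id"]].append(row["gene"])
    sample_index = {row["sample_id"]: row["index_seq"] for row in rows}

    callers = {g: AlleleCaller(t) for g, t in targets.items()}
    primers = {g: t.gene_primer for g, t in targets.items()}
    adapter = layout.adapter_seq
    exact_prefix = {sid: idx + adapter for sid, idx in sample_index.items()}

    # UMI accumulators: the common path stores (key, n_reads) per UMI; UMIs
    # whose reads disagree are promoted to a Counter and resolved by majority.
    consensus: dict[tuple[str, str], dict[str, tuple[AlleleKey, int]]] = defaultdict(dict)
    conflicts: dict[tuple[str, str], dict[str, Counter]] = defaultdict(dict)
    unassigned: Counter = Counter()

    for _name, seq in lsio.read_fastq(fastq_path):
        sid = None
        for n in index_lengths:
            sid = index_map.get(seq[:n])
            if sid is not None:
                break
        if sid is None:
            unassigned[("", "no_index")] += 1
            continue
        prefix = exact_prefix[sid]
        if seq.startswith(prefix):
            pos = len(prefix)
        else:
            ilen = len(sample_index[sid])
            window = seq[ilen : ilen + len(adapter)]
            if len(window) < len(adapter) or _mismatches_over(window, adapter, 1):
                unassigned[(sid, "no_adapter")] += 1
                continue
            pos = ilen + len(adapter)
        umi = seq[pos : pos + layout.umi_len]
        insert = seq[pos + layout.umi_len :]
        if len(umi) < layout.umi_len:
            unassigned[(sid, "no_adapter")] += 1
            continue
        gene = None
        for g in genes_for_sample[sid]:
            if insert.startswith(primers[g]):
                gene = g
                break
        if gene is None:
            for g in genes_for_sample[sid]:
                head = insert[: len(primers[g])]
                if len(head) == len(primers[g]) and not _mismatches_over(
                        head, primers[g], 1):
                    gene = g
                    break
        if gene is None:
            unassigned[(sid, "bad_primer")] += 1
            continue
        result = callers[gene](insert)
        if isinstance(result, Unassigned):
            unassigned[(sid, result.reason)] += 1
            continue
        slot = consensus[(sid, gene)]
        prev = slot.get(umi)
        if prev is None:
            conf = conflicts[(sid, gene)].get(umi)
            if conf is None:
                slot[umi] = (result, 1)
            else:
                conf[result] += 1
        elif prev[0] == result:
            slot[umi] = (result, prev[1] + 1)
        else:
            conflicts[(sid, gene)][umi] = Counter({prev[0]: prev[1], result: 1})
            del slot[umi]

    sample_unassigned = Counter()
    for (sid, _reason), n in unassigned.items():
        sample_unassigned[sid] += n

    tables: dict[tuple[str, str], AlleleCountTable] = {}
    for row in rows:
        sid, gene = row["sample_id"], row["gene"]
        counts: Counter = Counter()
        dropped = 0
        for key, _n in consensus.get((sid, gene), {}).values():
            counts[key] += 1
        for counter in conflicts.get((sid, gene), {}).values():
            winner = _resolve_umi(counter)
            if winner is None:
                dropped += 1
            else:
                counts[winner] += 1
        tables[(sid, gene)] = AlleleCountTable(
            sample_id=sid, gene=gene, counts=dict(counts),
            total_assigned=sum(counts.values()),
            unassigned_reads=sample_unassigned.get(sid, 0),
            dropped_umis=dropped)

    if control_filter:
        control_for_gene = {row["gene"]: row["sample_id"]
                            for row in rows if row["is_control"]}
        for (sid, gene), table in list(tables.items()):
            csid = control_for_gene.get(gene)
            if csid == sid:
                continue
            control = tables.get((csid, gene)) if csid else None
            tables[(sid, gene)] = filter_artifacts(table, control)

    una = pd.DataFrame(
        [{"sample_id": sid, "reason": reason, "reads": n}
         for (sid, reason), n in sorted(unassigned.items())],
        columns=["sample_id", "reason", "reads"])
    return CallResult(tables=tables, unassigned=una)


def pair_dataset(tables: dict[tuple[str, str], AlleleCountTable],
                 sheet: pd.DataFrame) -> DatasetPairs:
    """Normalize per limb sample and pair primary/secondary per animal x gene."""
    out = DatasetPairs(pairs_by_gene=defaultdict(list))
    exp = sheet[~sheet["is_control"]]
    for (animal, gene), grp in exp.groupby(["animal_id", "gene"], sort=False):
        sids = dict(zip(grp["limb"], grp["sample_id"]))
        if "primary" not in sids or "secondary" not in sids:
            logger.warning("%s/%s: missing a limb sample; skipped", animal, gene)
            continue
        try:
            prim = normalize(tables[(sids["primary"], gene)])
            sec = normalize(tables[(sids["secondary"], gene)])
        except SampleFailedError as exc:
            logger.warning("excluded failed sample: %s", exc)
            out.failed_samples.append((animal, gene))
            continue
        out.normalized.extend(prim)
        out.normalized.extend(sec)
        pairs, sec_only = pair_limbs(prim, sec, animal=animal)
        out.pairs_by_gene[gene].extend(pairs)
        out.secondary_only.extend(sec_only)
    out.pairs_by_gene = dict(out.pairs_by_gene)
    return out


def run_simulated_screen(config, alpha: float = 0.05,
                         workdir=None) -> ScreenReport:
    """Generate a synthetic screen dataset and run the full pipeline on it.

    Writes the dataset (FASTQ, references, sample sheet) to ``workdir`` (a
    temporary directory by default), then calls, quantifies and screens it.
    """
    import tempfile

    from . import io as lsio_mod
    from .sim import generate_screen_dataset

    def _run(d):
        generate_screen_dataset(config, d)
        targets = lsio_mod.read_targets(f"{d}/refs.fa")
        sheet = lsio_mod.read_sample_sheet(f"{d}/sheet.tsv")
        report, _data, _calls = run_screen(f"{d}/reads.fastq", targets, sheet,
                                           alpha=alpha)
        return report

    if workdir is not None:
        return _run(str(workdir))
    with tempfile.TemporaryDirectory() as d:
        return _run(d)


def simulate_count_screen(config, rng) -> dict[str, list[PairedAllele]]:
    """Simulate a screen at the unique-molecule level, skipping reads.

    Draws each animal's mosaic limbs, regenerates them through the founder
    bottleneck, and samples UMI counts per allele directly — the same
    generative model as the FASTQ route minus PCR duplication and
    sequencing error, which affect read-level calling but not the molecule
    counts that drive the selection statistics. Useful for statistical
    calibration studies that need many replicates.
    """
    from .sim import draw_mosaic_limb, regenerate_limb, sample_allele_counts

    pairs_by_gene: dict[str, list[PairedAllele]] = defaultdict(list)
    for i in range(config.n_animals):
        animal = f"A{i + 1:02d}"
        for spec in config.genes:
            primary = draw_mosaic_limb(spec, rng, animal=animal)
            secondary = regenerate_limb(primary, config, spec, rng)
            tables = []
            for limb, truth in (("primary", primary), ("secondary", secondary)):
                counts = sample_allele_counts(truth, config.umi_depth, rng)
                keys = {AlleleKey(spec.gene_name, a): c
                        for a, c in counts.items() if c > 0}
                tables.append(AlleleCountTable(
                    sample_id=f"{animal}_{limb}", gene=spec.gene_name,
                    counts=keys, total_assigned=sum(keys.values())))
            pairs, _ = pair_limbs(normalize(tables[0]), normalize(tables[1]),
                                  animal=animal)
            pairs_by_gene[spec.gene_name].extend(pairs)
    return dict(pairs_by_gene)


def run_screen(fastq_path, targets, sheet: pd.DataFrame, control_genes=None,
               alpha: float = 0.05, layout: ReadLayout = DEFAULT_LAYOUT,
               control_filter: bool = True,
               ) -> tuple[ScreenReport, DatasetPairs, CallResult]:
    """Full pipeline: call alleles, quantify, and build the screen report.

    ``control_genes`` defaults to the targets annotated ``role=control``.
    """
    if control_genes is None:
        control_genes = [g for g, t in targets.items() if t.role == "control"]
    calls = call_fastq(fastq_path, targets, sheet, layout=layout,
                       control_filter=control_filter)
    data = pair_dataset(calls.tables, sheet)
    report = build_screen_report(data.pairs_by_gene, control_genes, alpha=alpha)
    return report, data, calls
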