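"""Simulation of mosaic mutant limbs, regeneration under selection, and
UMI-tagged amplicon sequencing.

The generative model mirrors the screen design: a limb is a mosaic of clonal
cell lineages, each lineage carrying one distinct Cas9-induced indel allele
at the targeted locus (one allele per locus in a haploid limb). Regeneration
passes the limb through a founder-cell bottleneck — ``blastema_founders``
cells are drawn multinomially from the primary limb — and negative selection
acts once at that bottleneck: each mutant founder of a targeted gene
survives independently with probability ``1 - s``. Sequencing draws
``umi_depth`` template molecules per target per limb, tags each with a
distinct 10-nt UMI, duplicates it a shifted-Poisson number of times, and
applies uniform per-base substitution errors.

Default parameters are calibrated so that the neutral (s = 0) screen
reproduces the empirically observed fidelity of limb regeneration: roughly
a quarter of primary-limb alleles absent from the regenerate, driven almost
entirely by low-frequency lineages, with a mean detected-allele frequency
near 3.5%.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .variants import (
    WT,
    apply_events,
    format_descriptor,
    normalize_events,
    parse_descriptor,
)

logger = logging.getLogger(__name__)

#: Universal adapter placed between the sample index and the UMI.
DEFAULT_ADAPTER = "ACACGACGCTCTTCCGATCT"

_BASES = "ACGT"

DEFAULT_REF_LEN = 180
DEFAULT_CUT_SITE = 90
DEFAULT_PRIMER_LEN = 20
DEFAULT_INDEX_LEN = 5


@dataclass(frozen=True)
class GeneSimSpec:
    """Per-gene simulation parameters.

    selection_coefficient
        Per-regeneration fitness penalty ``s`` of mutant lineages; each
        mutant blastema founder survives with probability ``1 - s``.
    n_lineages
        Number of distinct mutant clones induced in the limb.
    lineage_concentration
        Symmetric Dirichlet concentration shaping clone sizes; small values
        give the observed many-rare/few-common allele spectrum.
    mutant_fraction
        Total mutant cell fraction of the limb at this locus.
    """

    gene_name: str
    selection_coefficient: float = 0.0
    n_lineages: int = 10
    lineage_concentration: float = 0.2
    mutant_fraction: float = 0.277

    def __post_init__(self) -> None:
        if not 0.0 <= self.selection_coefficient <= 1.0:
            raise ValueError("selection_coefficient must be in [0, 1]")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if not 0.0 < self.mutant_fraction < 1.0:
            raise ValueError("mutant_fraction must be in (0, 1)")
        if self.lineage_concentration <= 0:
            raise ValueError("lineage_concentration must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Screen-wide simulation parameters and ground-truth bookkeeping."""

    genes: tuple[GeneSimSpec, ...]
    n_animals: int = 12
    blastema_founders: int = 900
    umi_depth: int = 10_000
    pcr_duplication_mean: float = 1.5
    sequencing_error_rate: float = 0.002
    read_length: int = 250
    seed: int = 0
    control_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.umi_depth <= 0:
            raise ValueError("umi_depth must be positive")
        if self.blastema_founders <= 0:
            raise ValueError("blastema_founders must be positive")
        if self.pcr_duplication_mean < 1:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        known = {g.gene_name for g in self.genes}
        if len(known) != len(self.genes):
            raise ValueError("duplicate gene names in config")
        missing = set(self.control_genes) - known
        if missing:
            raise ValueError(f"control_genes not in genes: {sorted(missing)}")


@dataclass
class LimbTruth:
    """Ground-truth allele frequencies of one limb at one locus."""

    animal: str
    limb: str  # "primary" or "secondary"
    gene: str
    allele_frequencies: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.allele_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.allele_frequencies.values()):
            raise ValueError("negative allele frequency")

    @property
    def mutant_alleles(self) -> list[str]:
        return [a for a in self.allele_frequencies if a != WT]


def draw_random_allele(rng: np.random.Generator, cut_site: int, ref: str | None = None,
                       ref_len: int | None = None) -> str:
    """Draw one random Cas9-style indel allele descriptor at a cut site.

    Deletions (4:1 odds over insertions) have geometric(p=0.3) length
    truncated to [1, 30] and span the cut; insertions of 1-10 random bases
    land at the cut. When the reference sequence is supplied the event is
    left-aligned so the descriptor matches what the allele caller reports.
    """
    if ref is not None:
        ref_len = len(ref)
    if ref_len is None:
        raise ValueError("need ref or ref_len")
    if rng.random() < 0.8:
        length = int(rng.geometric(0.3))
        while length > 30:
            length = int(rng.geometric(0.3))
        lo = max(1, cut_site - length)
        hi = min(cut_site, ref_len - length - 1)
        if hi < lo:
            hi = lo
        start = int(rng.integers(lo, hi + 1))
        event = ("D", start, length)
    else:
        k = int(rng.integers(1, 11))
        bases = "".join(_BASES[i] for i in rng.integers(0, 4, size=k))
        event = ("I", cut_site, bases)
    if ref is not None:
        event = normalize_events(ref, [event])[0]
    return format_descriptor([event])


def draw_mosaic_limb(spec: GeneSimSpec, rng: np.random.Generator, *,
                     ref: str | None = None, cut_site: int = DEFAULT_CUT_SITE,
                     ref_len: int = DEFAULT_REF_LEN, animal: str = "sim",
                     ) -> LimbTruth:
    """Draw the primary-limb clone structure for one gene.

    Clone sizes are a symmetric Dirichlet draw scaled to ``mutant_fraction``;
    each clone carries a distinct random indel allele; the remainder of the
    limb is wild-type.
    """
    sizes = rng.dirichlet(np.full(spec.n_lineages, spec.lineage_concentration))
    sizes = sizes * spec.mutant_fraction
    alleles: list[str] = []
    seen = set()
    for _ in range(spec.n_lineages):
        for _attempt in range(1000):
            a = draw_random_allele(rng, cut_site, ref=ref, ref_len=ref_len)
            if a not in seen:
                seen.add(a)
                alleles.append(a)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a distinct allele")
    freqs = {a: float(s) for a, s in zip(alleles, sizes)}
    freqs[WT] = 1.0 - spec.mutant_fraction
    return LimbTruth(animal=animal, limb="primary", gene=spec.gene_name,
                     allele_frequencies=freqs)


def regenerate_limb(primary: LimbTruth, config: SimulationConfig,
                    spec: GeneSimSpec, rng: np.random.Generator) -> LimbTruth:
    """Pass a limb through the blastema bottleneck with selection.

    ``blastema_founders`` cells are drawn multinomially from the primary
    frequencies; each mutant founder survives with probability ``1 - s``;
    wild-type founders always survive; surviving counts renormalized give
    the regenerated-limb frequencies.
    """
    alleles = list(primary.allele_frequencies)
    freqs = np.array([primary.allele_frequencies[a] for a in alleles])
    founders = rng.multinomial(config.blastema_founders, freqs)
    s = spec.selection_coefficient
    survivors = founders.copy()
    if s > 0:
        for i, a in enumerate(alleles):
            if a != WT:
                survivors[i] = rng.binomial(founders[i], 1.0 - s)
    total = int(survivors.sum())
    if total == 0:
        logger.warning("no surviving founders for %s/%s; regenerate is all wild-type",
                       primary.animal, primary.gene)
        return LimbTruth(animal=primary.animal, limb="secondary",
                         gene=primary.gene, allele_frequencies={WT: 1.0})
    new = {a: float(c) / total for a, c in zip(alleles, survivors) if c > 0 or a == WT}
    if WT not in new:
        new[WT] = 0.0
    return LimbTruth(animal=primary.animal, limb="secondary", gene=primary.gene,
                     allele_frequencies=new)


def sample_allele_counts(truth: LimbTruth, depth: int,
                         rng: np.random.Generator) -> dict[str, int]:
    """Draw unique-molecule (UMI) counts per allele: one multinomial sample
    of ``depth`` template molecules from the limb's allele frequencies."""
    alleles = list(truth.allele_frequencies)
    freqs = np.array([truth.allele_frequencies[a] for a in alleles])
    counts = rng.multinomial(depth, freqs)
    return {a: int(c) for a, c in zip(alleles, counts)}


def _umi_strings(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    """n distinct random UMIs (sampling without replacement over 4^length)."""
    codes = rng.choice(4 ** length, size=n, replace=False)
    digits = np.empty((n, length), dtype=np.uint8)
    rem = codes.copy()
    for j in range(length - 1, -1, -1):
        digits[:, j] = rem % 4
        rem //= 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = lut[digits]
    return [bytes(row).decode() for row in arr]


def _apply_errors(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Uniform substitution errors, vectorized over the concatenated reads.

    Error positions are drawn on the joined byte buffer (position collisions
    are negligible at realistic rates); each hit base is replaced by one of
    the three other bases.
    """
    if rate <= 0 or not reads:
        return reads
    buf = np.frombuffer("".join(reads).encode(), dtype=np.uint8).copy()
    n_err = rng.binomial(len(buf), rate)
    if n_err:
        pos = rng.integers(0, len(buf), size=n_err)
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        # shift each hit base by 1-3 within ACGT so it always changes
        idx = np.searchsorted(lut, buf[pos])
        buf[pos] = lut[(idx + rng.integers(1, 4, size=n_err)) % 4]
    lengths = np.cumsum([0] + [len(r) for r in reads])
    raw = buf.tobytes().decode()
    return [raw[a:b] for a, b in zip(lengths[:-1], lengths[1:])]


def simulate_sample_reads(truth: LimbTruth, target, config: SimulationConfig,
                          rng: np.random.Generator, *, index_seq: str,
                          sample_id: str, adapter_seq: str = DEFAULT_ADAPTER,
                          ) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Simulate sequencing of one limb at one target.

    Returns ``(reads, molecule_counts)`` where reads are ``(name, sequence)``
    pairs and ``molecule_counts`` is the realized multinomial draw of unique
    molecules per allele (the quantity UMI deduplication should recover).

    Each read is ``index + adapter + UMI + gene-specific insert`` (the insert
    starts at the gene primer), truncated to ``read_length``, with uniform
    per-base substitution errors. Every molecule receives a distinct UMI and
    a shifted-Poisson(``pcr_duplication_mean``) number of reads.
    """
    prefix = index_seq + adapter_seq
    layout_min = len(prefix) + 10 + len(target.gene_primer) + 30
    if config.read_length < layout_min:
        raise ValueError(
            f"read_length {config.read_length} shorter than read layout ({layout_min})")
    counts = sample_allele_counts(truth, config.umi_depth, rng)
    umis = _umi_strings(rng, config.umi_depth)
    dup_extra = rng.poisson(config.pcr_duplication_mean - 1.0, size=config.umi_depth)
    p0 = target.primer_offset
    reads: list[str] = []
    mol = 0
    for allele in counts:
        c = counts[allele]
        if c == 0:
            continue
        insert = apply_events(target.reference_seq, parse_descriptor(allele))[p0:]
        for _ in range(c):
            molecule = (prefix + umis[mol] + insert)[: config.read_length]
            for _r in range(1 + dup_extra[mol]):
                reads.append(molecule)
            mol += 1
    reads = _apply_errors(reads, config.sequencing_error_rate, rng)
    named = [(f"{sample_id}:{target.gene_name}:{i}", r) for i, r in enumerate(reads)]
    return named, counts


def sequence_limb(truth: LimbTruth, target, config: SimulationConfig,
                  rng: np.random.Generator, *, index_seq: str = "ACGTC",
                  sample_id: str = "sample",
                  adapter_seq: str = DEFAULT_ADAPTER) -> list[tuple[str, str]]:
    """FASTQ-ready ``(name, sequence)`` reads for one limb at one target."""
    reads, _ = simulate_sample_reads(truth, target, config, rng,
                                     index_seq=index_seq, sample_id=sample_id,
                                     adapter_seq=adapter_seq)
    return reads


def _random_reference(rng: np.random.Generator, length: int = DEFAULT_REF_LEN) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _index_pool(rng: np.random.Generator, n: int,
                length: int = DEFAULT_INDEX_LEN) -> list[str]:
    codes = rng.choice(4 ** length, size=n, replace=False)
    out = []
    for code in codes:
        s = ""
        for _ in range(length):
            s = _BASES[code % 4] + s
            code //= 4
        out.append(s)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_screen_dataset(config: SimulationConfig, out_dir) -> dict:
    """Write a complete synthetic screen dataset and return its manifest.

    Produces, under ``out_dir``: ``refs.fa`` (amplicon references annotated
    with cut site, primer length and control/experimental role),
    ``sheet.tsv`` (sample sheet), ``reads.fastq`` (all samples pooled, as
    from one sequencing run), ``truth.tsv`` (ground-truth allele
    frequencies), and ``manifest.json`` listing every file with a sha256
    checksum. One non-mutant control sample per target is included
    (wild-type molecules only, sequencing errors still applied).
    """
    from .alleles import AmpliconTarget  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    targets = {}
    for spec in config.genes:
        ref = _random_reference(rng)
        role = "control" if spec.gene_name in config.control_genes else "experimental"
        targets[spec.gene_name] = AmpliconTarget(
            gene_name=spec.gene_name, reference_seq=ref,
            cut_site=DEFAULT_CUT_SITE, gene_primer=ref[:DEFAULT_PRIMER_LEN],
            role=role)

    animals = [f"A{i + 1:02d}" for i in range(config.n_animals)]
    sample_ids = [f"{a}_{limb}" for a in animals for limb in ("primary", "secondary")]
    control_ids = [f"CTRL_{spec.gene_name}" for spec in config.genes]
    indexes = dict(zip(sample_ids + control_ids,
                       _index_pool(rng, len(sample_ids) + len(control_ids))))

    # Ground truth: per animal x gene, a primary draw and its regenerate.
    truths: dict[tuple[str, str, str], LimbTruth] = {}
    for animal in animals:
        for spec in config.genes:
            t = targets[spec.gene_name]
            primary = draw_mosaic_limb(spec, rng, ref=t.reference_seq,
                                       cut_site=t.cut_site, animal=animal)
            secondary = regenerate_limb(primary, config, spec, rng)
            truths[(animal, "primary", spec.gene_name)] = primary
            truths[(animal, "secondary", spec.gene_name)] = secondary

    # Reference FASTA.
    refs_path = out / "refs.fa"
    with open(refs_path, "w") as fh:
        for t in targets.values():
            fh.write(f">{t.gene_name} cut_site={t.cut_site} "
                     f"primer_len={len(t.gene_primer)} role={t.role}\n")
            fh.write(t.reference_seq + "\n")

    # Sample sheet: one row per sample x gene.
    sheet_path = out / "sheet.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tanimal_id\tlimb\tgene\tindex_seq\tis_control\n")
        for animal in animals:
            for limb in ("primary", "secondary"):
                sid = f"{animal}_{limb}"
                for spec in config.genes:
                    fh.write(f"{sid}\t{animal}\t{limb}\t{spec.gene_name}\t"
                             f"{indexes[sid]}\tFalse\n")
        for spec in config.genes:
            sid = f"CTRL_{spec.gene_name}"
            fh.write(f"{sid}\tcontrol\tprimary\t{spec.gene_name}\t"
                     f"{indexes[sid]}\tTrue\n")

    # Pooled FASTQ.
    fastq_path = out / "reads.fastq"
    with open(fastq_path, "w") as fh:
        for animal in animals:
            for limb in ("primary", "secondary"):
                sid = f"{animal}_{limb}"
                for spec in config.genes:
                    truth = truths[(animal, limb, spec.gene_name)]
                    reads = sequence_limb(truth, targets[spec.gene_name], config,
                                          rng, index_seq=indexes[sid], sample_id=sid)
                    fh.write("".join(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n"
                                     for name, seq in reads))
        for spec in config.genes:
            sid = f"CTRL_{spec.gene_name}"
            wt = LimbTruth(animal="control", limb="primary", gene=spec.gene_name,
                           allele_frequencies={WT: 1.0})
            reads = sequence_limb(wt, targets[spec.gene_name], config, rng,
                                  index_seq=indexes[sid], sample_id=sid)
            fh.write("".join(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n"
                             for name, seq in reads))

    # Ground-truth table.
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("animal\tlimb\tgene\tallele\tfrequency\n")
        for (animal, limb, gene), truth in truths.items():
            for allele, freq in truth.allele_frequencies.items():
                fh.write(f"{animal}\t{limb}\t{gene}\t{allele}\t{freq:.10g}\n")

    files = [refs_path, sheet_path, fastq_path, truth_path]
    manifest = {
        "seed": config.seed,
        "n_animals": config.n_animals,
        "genes": {g.gene_name: {"selection_coefficient": g.selection_coefficient}
                  for g in config.genes},
        "control_genes": list(config.control_genes),
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
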