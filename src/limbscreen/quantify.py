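"""RP10K normalization, limb pairing, and the frequency x fold-change x
lost/preserved classification.

Counts are rescaled so each sample's assigned unique molecules total
10,000 ("reads per ten thousand", RP10K, roughly the number of cells the
template represents); log scores are log2(RP10K + 1) so absent alleles map
to 0. An allele's pair couples its abundance in the primary limb with its
abundance in the regenerated limb of the same animal; the allele universe
is everything detected in the primary limb, with regenerate-only alleles
reported separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .alleles import AlleleCountTable, AlleleKey
from .variants import WT

#: Denominator of the normalization: unique molecules per sample are
#: rescaled to sum to this.
RP10K_TOTAL = 10_000.0


class SampleFailedError(ValueError):
    """Raised for a sample with zero assigned reads (excluded downstream)."""


@dataclass(frozen=True)
class NormalizedAllele:
    sample_id: str
    gene: str
    allele: AlleleKey
    unique_reads: int
    rp10k: float
    log_score: float
    frequency: float


@dataclass(frozen=True)
class PairedAllele:
    """One allele's abundance in the primary and regenerated limb.

    ``lost`` means zero unique molecules in the regenerate. Fold change is
    computed on pseudocounted RP10K, max(r1+1, r2+1) / min(r1+1, r2+1), so
    it is defined (and >= 1) for lost alleles too.
    """

    animal: str
    gene: str
    allele: AlleleKey
    primary: NormalizedAllele
    secondary: NormalizedAllele

    @property
    def lost(self) -> bool:
        return self.secondary.unique_reads == 0

    @property
    def fold_change(self) -> float:
        a = self.primary.rp10k + 1.0
        b = self.secondary.rp10k + 1.0
        return max(a, b) / min(a, b)


@dataclass(frozen=True)
class ClassificationConfig:
    low_freq_threshold: float = 0.016
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.low_freq_threshold <= 0 or self.fold_threshold <= 0:
            raise ValueError("thresholds must be positive")


#: Cell keys of the classification: (frequency class, fate, fold class).
FREQ_CLASSES = ("low", "high")
FATES = ("lost", "preserved")
FOLD_CLASSES = ("<2", ">=2")


@dataclass
class ClassificationTable:
    """Counts of paired alleles in the 2x2x2 frequency/fate/fold layout."""

    label: str
    cells: dict[tuple[str, str, str], int]
    total_alleles: int

    def cell(self, freq: str, fate: str, fold: str) -> int:
        return self.cells.get((freq, fate, fold), 0)

    def marginal(self, *, freq: str | None = None, fate: str | None = None,
                 fold: str | None = None) -> int:
        return sum(c for (f, s, d), c in self.cells.items()
                   if (freq is None or f == freq)
                   and (fate is None or s == fate)
                   and (fold is None or d == fold))

    def summary(self) -> dict[str, float]:
        """Headline percentages: overall fate and low-frequency fidelity."""
        n = self.total_alleles
        nlow = self.marginal(freq="low")
        return {
            "pct_preserved": 100.0 * self.marginal(fate="preserved") / n if n else 0.0,
            "pct_lost": 100.0 * self.marginal(fate="lost") / n if n else 0.0,
            "pct_low_freq_preserved": (100.0 * self.marginal(freq="low", fate="preserved")
                                       / nlow if nlow else 0.0),
            "pct_low_freq_fold_lt2": (100.0 * self.marginal(freq="low", fold="<2")
                                      / nlow if nlow else 0.0),
        }


def normalize(table: AlleleCountTable) -> list[NormalizedAllele]:
    """RP10K-normalize every assigned allele (wild-type included).

    The coefficient is 10,000 divided by the sample's total assigned unique
    molecules, computed per gene per limb sample.
    """
    if table.total_assigned == 0:
        raise SampleFailedError(
            f"{table.sample_id}/{table.gene}: no assigned reads")
    coeff = RP10K_TOTAL / table.total_assigned
    out = []
    for key, c in table.counts.items():
        rp10k = c * coeff
        out.append(NormalizedAllele(
            sample_id=table.sample_id, gene=table.gene, allele=key,
            unique_reads=c, rp10k=rp10k, log_score=math.log2(rp10k + 1.0),
            frequency=c / table.total_assigned))
    return out


def _zero_allele(template: NormalizedAllele, sample_id: str) -> NormalizedAllele:
    return NormalizedAllele(sample_id=sample_id, gene=template.gene,
                            allele=template.allele, unique_reads=0, rp10k=0.0,
                            log_score=0.0, frequency=0.0)


def pair_limbs(primary: list[NormalizedAllele], secondary: list[NormalizedAllele],
               *, animal: str = "",
               ) -> tuple[list[PairedAllele], list[NormalizedAllele]]:
    """Pair each primary-limb mutant allele with its regenerate abundance.

    Wild-type is excluded. Alleles absent from the regenerate pair against
    an explicit zero. Returns ``(pairs, secondary_only)`` where the second
    list holds regenerate-only alleles (reported, never paired).
    """
    for group in (primary, secondary):
        keys = [a.allele for a in group]
        dup = [k for k, n in Counter(keys).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate allele keys within a limb: {dup}")
    sec_by_key = {a.allele: a for a in secondary}
    pairs = []
    for a in primary:
        if a.allele.is_wt:
            continue
        sec = sec_by_key.get(a.allele)
        if sec is None:
            sec = _zero_allele(a, secondary[0].sample_id if secondary else "")
        pairs.append(PairedAllele(animal=animal, gene=a.gene, allele=a.allele,
                                  primary=a, secondary=sec))
    primary_keys = {a.allele for a in primary}
    secondary_only = [a for a in secondary
                      if not a.allele.is_wt and a.allele not in primary_keys]
    return pairs, secondary_only


def classify(pairs: list[PairedAllele],
             cfg: ClassificationConfig = ClassificationConfig(),
             label: str = "") -> ClassificationTable:
    """Sort paired alleles into the frequency x fate x fold-change table.

    The frequency class comes from the primary-limb frequency with a strict
    "<" at the threshold; the fold class uses fold_change < threshold
    versus >= threshold.
    """
    cells: Counter = Counter()
    for p in pairs:
        freq = "low" if p.primary.frequency < cfg.low_freq_threshold else "high"
        fate = "lost" if p.lost else "preserved"
        fold = "<2" if p.fold_change < cfg.fold_threshold else ">=2"
        cells[(freq, fate, fold)] += 1
    return ClassificationTable(label=label, cells=dict(cells),
                               total_alleles=len(pairs))


def pairs_from_cell_counts(cells: dict[tuple[str, str, str], int], *,
                           gene: str = "gene", animal: str = "x",
                           cfg: ClassificationConfig = ClassificationConfig(),
                           ) -> list[PairedAllele]:
    """Build a synthetic pair list realizing given classification counts.

    Each cell is populated with representative alleles whose primary
    frequency, fate and fold change land in that cell — the inverse of
    :func:`classify`, used to analyze published summary tables at the
    allele level and to check classification self-consistency.
    """
    # A fixed total > 10,000 keeps single-read alleles below RP10K 1, which
    # is what allows a lost allele to sit in the fold < threshold bucket
    # (its fold change is rp10k + 1). A high-frequency lost allele always
    # has fold >= threshold, so that cell is structurally empty.
    total = 30_000
    pairs = []
    i = 0
    for (freq, fate, fold), n in cells.items():
        if n == 0:
            continue
        if freq == "high" and fate == "lost" and fold == "<2":
            raise ValueError("a high-frequency lost allele cannot have "
                             "fold change below the threshold")
        if freq == "low":
            # single read for lost/<2 (fold = rp1+1 must stay < threshold),
            # otherwise half the frequency threshold
            reads1 = 1 if fate == "lost" and fold == "<2" else int(
                cfg.low_freq_threshold * total * 0.5)
        else:
            reads1 = int(cfg.low_freq_threshold * total * 4)
        rp1 = reads1 * (RP10K_TOTAL / total)
        if fate == "lost":
            reads2 = 0
        elif fold == "<2":
            reads2 = reads1  # identical abundance: fold change 1
        else:
            # rp2 + 1 >= threshold * (rp1 + 1), with margin
            reads2 = int((cfg.fold_threshold * (rp1 + 1.0) * 1.5)
                         * total / RP10K_TOTAL)
        for _ in range(n):
            key = AlleleKey(gene, f"D:{i}:1")
            i += 1
            prim = NormalizedAllele(sample_id=f"{animal}_primary", gene=gene,
                                    allele=key, unique_reads=reads1,
                                    rp10k=rp1, log_score=math.log2(rp1 + 1.0),
                                    frequency=reads1 / total)
            rp2 = reads2 * (RP10K_TOTAL / total)
            sec = NormalizedAllele(sample_id=f"{animal}_secondary", gene=gene,
                                   allele=key, unique_reads=reads2,
                                   rp10k=rp2, log_score=math.log2(rp2 + 1.0),
                                   frequency=reads2 / total)
            pairs.append(PairedAllele(animal=animal, gene=gene, allele=key,
                                      primary=prim, secondary=sec))
    return pairs
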