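"""Published summary counts from a haploid axolotl limb-regeneration screen.

These are the printed per-gene-set classification counts (frequency class x
lost/preserved x fold-change class) from the multiplex CRISPR
negative-selection screen this package analyzes: two inessential control
loci (*tyrosinase* and a *methyltransferase-like* gene) and a pool of
candidate regeneration genes among which *fetuin-b* (fetub) and *catalase*
showed negative selection. They serve as inputs for reproducing the
published loss comparisons and as fixtures for classification
self-consistency — the per-allele sequencing data behind them is not
redistributed here.

Cell keys are ``(frequency_class, fate, fold_class)`` as in
:mod:`limbscreen.quantify`; frequency class "low" means a primary-limb
frequency under 1.6%, the fold classes split at two-fold.
"""

from __future__ import annotations

#: gene-set label -> classification cell counts
CLASSIFICATION_COUNTS: dict[str, dict[tuple[str, str, str], int]] = {
    "controls": {
        ("low", "lost", "<2"): 5, ("low", "lost", ">=2"): 17,
        ("low", "preserved", "<2"): 35, ("low", "preserved", ">=2"): 18,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 0,
        ("high", "preserved", "<2"): 15, ("high", "preserved", ">=2"): 2,
    },
    "all_targets": {
        ("low", "lost", "<2"): 24, ("low", "lost", ">=2"): 36,
        ("low", "preserved", "<2"): 71, ("low", "preserved", ">=2"): 23,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 2,
        ("high", "preserved", "<2"): 13, ("high", "preserved", ">=2"): 7,
    },
    "fetub": {
        ("low", "lost", "<2"): 9, ("low", "lost", ">=2"): 11,
        ("low", "preserved", "<2"): 21, ("low", "preserved", ">=2"): 4,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 2,
        ("high", "preserved", "<2"): 0, ("high", "preserved", ">=2"): 1,
    },
    "targets_except_fetub": {
        ("low", "lost", "<2"): 15, ("low", "lost", ">=2"): 25,
        ("low", "preserved", "<2"): 50, ("low", "preserved", ">=2"): 19,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 0,
        ("high", "preserved", "<2"): 13, ("high", "preserved", ">=2"): 6,
    },
    "catalase": {
        ("low", "lost", "<2"): 1, ("low", "lost", ">=2"): 5,
        ("low", "preserved", "<2"): 1, ("low", "preserved", ">=2"): 0,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 0,
        ("high", "preserved", "<2"): 0, ("high", "preserved", ">=2"): 1,
    },
    "targets_except_catalase": {
        ("low", "lost", "<2"): 23, ("low", "lost", ">=2"): 31,
        ("low", "preserved", "<2"): 70, ("low", "preserved", ">=2"): 23,
        ("high", "lost", "<2"): 0, ("high", "lost", ">=2"): 2,
        ("high", "preserved", "<2"): 13, ("high", "preserved", ">=2"): 6,
    },
}


def lost_total(label: str) -> tuple[int, int]:
    """(alleles lost, total alleles) for one published gene set."""
    cells = CLASSIFICATION_COUNTS[label]
    lost = sum(c for (_f, fate, _d), c in cells.items() if fate == "lost")
    return lost, sum(cells.values())
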