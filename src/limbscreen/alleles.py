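"""From raw amplicon reads to unique-molecule allele counts.

The stages mirror the wet protocol's read layout — a 4-6 nt sample index, a
universal adapter, a 10-nt UMI, then 18-28 nt of gene-specific primer and
the amplified locus:

1. ``demultiplex``: exact sample-index match at the read start.
2. ``extract_umi``: locate the adapter (<=1 mismatch), take the next 10 nt
   as the UMI, require the gene primer (<=1 mismatch) right after it.
3. ``call_allele``: global alignment of the insert to the reference with a
   free 3' end gap; indels within +/-20 bp of the Cas9 cut site define the
   allele; substitutions are ignored as sequencing error.
4. ``dedup_umis``: each UMI contributes one unique molecule to the strict
   majority allele among its reads; ties are dropped.
5. ``filter_artifacts``: alleles recurrently present in the matched
   non-mutant control sample are removed as PCR/sequencing artifacts.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from .variants import WT, format_descriptor, normalize_events

logger = logging.getLogger(__name__)

#: Half-width of the window around the cut site within which indels are
#: accepted as Cas9-induced alleles.
INDEL_WINDOW = 20

#: Minimum insert length considered callable.
MIN_INSERT_LEN = 30

#: Minimum alignment identity outside indels.
MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplified locus: reference, cut site, and primer anchor.

    ``cut_site`` is the 0-based offset of the first reference base 3' of the
    blunt Cas9 cut. ``gene_primer`` must anchor an exact substring of the
    reference; the insert used for allele calling starts at that anchor.
    """

    gene_name: str
    reference_seq: str
    cut_site: int
    gene_primer: str
    role: str = "experimental"

    def __post_init__(self) -> None:
        if self.gene_primer not in self.reference_seq:
            raise ValueError(f"{self.gene_name}: gene_primer not found in reference")
        if not 0 < self.cut_site < len(self.reference_seq):
            raise ValueError(f"{self.gene_name}: cut_site outside reference")
        if self.role not in ("control", "experimental"):
            raise ValueError(f"{self.gene_name}: role must be control|experimental")

    @property
    def primer_offset(self) -> int:
        return self.reference_seq.index(self.gene_primer)


@dataclass(frozen=True)
class ReadLayout:
    """Fixed structural features of every read."""

    adapter_seq: str
    umi_len: int = 10
    index_len_range: tuple[int, int] = (4, 6)

    def __post_init__(self) -> None:
        if self.umi_len != 10:
            raise ValueError("umi_len must be 10")


@dataclass(frozen=True)
class AlleleKey:
    gene: str
    descriptor: str

    @property
    def is_wt(self) -> bool:
        return self.descriptor == WT


@dataclass(frozen=True)
class Unassigned:
    """Marker result for a read that could not be processed."""

    reason: str


@dataclass
class AlleleCountTable:
    """Unique-UMI counts per allele for one sample x gene."""

    sample_id: str
    gene: str
    counts: dict[AlleleKey, int] = field(default_factory=dict)
    total_assigned: int = 0
    unassigned_reads: int = 0
    dropped_umis: int = 0

    def __post_init__(self) -> None:
        if self.total_assigned != sum(self.counts.values()):
            raise ValueError("total_assigned does not equal the sum of counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")

    @property
    def wt_key(self) -> AlleleKey:
        return AlleleKey(self.gene, WT)


def _mismatches_over(a: str, b: str, limit: int) -> bool:
    """True once mismatches between equal-length strings exceed ``limit``."""
    if a == b:
        return False
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return True
    return False


def load_index_map(sheet_rows) -> dict[str, str]:
    """index_seq -> sample_id from sample-sheet rows, rejecting ambiguity.

    Indexes must identify a unique sample and be mutually non-prefixing so
    that variable-length exact matching is unambiguous.
    """
    index_map: dict[str, str] = {}
    for row in sheet_rows:
        idx, sid = row["index_seq"], row["sample_id"]
        if idx in index_map and index_map[idx] != sid:
            raise ValueError(f"index {idx} assigned to two samples")
        index_map[idx] = sid
    keys = sorted(index_map)
    for a, b in zip(keys, keys[1:]):
        if b.startswith(a):
            raise ValueError(f"index {a} is a prefix of index {b}")
    return index_map


def demultiplex(reads, index_map: dict[str, str],
                layout: ReadLayout) -> tuple[dict[str, list[str]], int]:
    """Group read sequences by exact sample-index match at the read start.

    ``reads`` is an iterable of sequences or ``(name, sequence)`` pairs.
    Returns ``(groups, n_unassigned)``; reads whose start matches no index
    exactly are unassigned.
    """
    lengths = sorted({len(k) for k in index_map})
    lo, hi = layout.index_len_range
    bad = [n for n in lengths if not lo <= n <= hi]
    if bad:
        raise ValueError(f"index lengths {bad} outside layout range {lo}-{hi}")
    groups: dict[str, list[str]] = defaultdict(list)
    unassigned = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        for n in lengths:
            sid = index_map.get(seq[:n])
            if sid is not None:
                groups[sid].append(seq)
                break
        else:
            unassigned += 1
    return dict(groups), unassigned


def extract_umi(read: str, target: AmpliconTarget, layout: ReadLayout,
                index_len: int | None = None):
    """Locate the UMI and the gene-specific insert in a demultiplexed read.

    Returns ``(umi, insert)`` where the insert starts at the gene primer, or
    an :class:`Unassigned` with reason ``no_adapter`` / ``bad_primer``.
    """
    if index_len is not None:
        starts = [index_len]
    else:
        starts = range(layout.index_len_range[0], layout.index_len_range[1] + 1)
    adapter = layout.adapter_seq
    pos = None
    for start in starts:
        window = read[start : start + len(adapter)]
        if len(window) == len(adapter) and not _mismatches_over(window, adapter, 1):
            pos = start + len(adapter)
            break
    if pos is None:
        return Unassigned("no_adapter")
    umi = read[pos : pos + layout.umi_len]
    if len(umi) < layout.umi_len:
        return Unassigned("no_adapter")
    insert = read[pos + layout.umi_len :]
    primer = target.gene_primer
    head = insert[: len(primer)]
    if len(head) < len(primer) or _mismatches_over(head, primer, 1):
        return Unassigned("bad_primer")
    return umi, insert


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    # The 3' end of the read is free: the read may stop short of the
    # reference end, or (after an insertion) run past it.
    new_names = ("open_right_insertion_score", "extend_right_insertion_score",
                 "open_right_deletion_score", "extend_right_deletion_score")
    old_names = ("target_right_open_gap_score", "target_right_extend_gap_score",
                 "query_right_open_gap_score", "query_right_extend_gap_score")
    names = new_names if hasattr(aligner, new_names[0]) else old_names
    for name in names:
        setattr(aligner, name, 0)
    return aligner


_ALIGNER = _make_aligner()


def call_allele(insert: str, target: AmpliconTarget):
    """Call the indel allele of one insert against its reference.

    Global alignment (match +2, mismatch -3, gap open -8, extend -1, free
    3' end gap) of the insert to the reference from the primer anchor
    onward. Indels within +/-20 bp of the cut site define the descriptor;
    substitutions are ignored. Returns an :class:`AlleleKey` or
    :class:`Unassigned` (``too_short``, ``low_quality``, ``off_window``).
    """
    if len(insert) < MIN_INSERT_LEN:
        return Unassigned("too_short")
    p0 = target.primer_offset
    ref_seg = target.reference_seq[p0:]
    if insert == ref_seg or ref_seg.startswith(insert):
        return AlleleKey(target.gene_name, WT)
    alignment = _ALIGNER.align(ref_seg, insert)[0]
    t_blocks, q_blocks = alignment.aligned

    events = []
    matches = mismatches = 0
    if len(t_blocks) == 0:
        return Unassigned("low_quality")
    # Leading gap (the 5' end is anchored, so it counts as an event).
    if t_blocks[0][0] > 0:
        events.append(("D", 0, int(t_blocks[0][0])))
    if q_blocks[0][0] > 0:
        events.append(("I", int(t_blocks[0][0]), insert[: q_blocks[0][0]]))
    for i, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        for x, y in zip(ref_seg[ts:te], insert[qs:qe]):
            if x == y:
                matches += 1
            else:
                mismatches += 1
        if i + 1 < len(t_blocks):
            dt = int(t_blocks[i + 1][0]) - int(te)
            dq = int(q_blocks[i + 1][0]) - int(qe)
            if dt > 0:
                events.append(("D", int(te), dt))
            if dq > 0:
                events.append(("I", int(te) + max(dt, 0), insert[qe : qe + dq]))
    # Trailing gaps are free end gaps, not events.

    if matches + mismatches == 0 or matches / (matches + mismatches) < MIN_IDENTITY:
        return Unassigned("low_quality")
    return _finalize_events(events, target)


def _finalize_events(events, target: AmpliconTarget):
    """Window-check, left-normalize and format segment-coordinate events."""
    if not events:
        return AlleleKey(target.gene_name, WT)
    p0 = target.primer_offset
    lo, hi = target.cut_site - INDEL_WINDOW, target.cut_site + INDEL_WINDOW
    shifted = []
    for ev in events:
        pos = ev[1] + p0
        if ev[0] == "D":
            if pos + ev[2] < lo or pos > hi:
                return Unassigned("off_window")
            shifted.append(("D", pos, ev[2]))
        else:
            if pos < lo or pos > hi:
                return Unassigned("off_window")
            shifted.append(("I", pos, ev[2]))
    shifted = normalize_events(target.reference_seq, shifted)
    return AlleleKey(target.gene_name, format_descriptor(shifted))


class AlleleCaller:
    """Memoizing, accelerated front end to :func:`call_allele` for one target.

    Identical inserts are called once (reads differ mostly by their UMIs and
    scattered errors, so the cache absorbs the bulk of the stream). A new
    insert first goes through a vectorized single-indel placement search:
    the net length difference against the reference fixes the indel size,
    and the split point minimizing substitution mismatches fixes its
    position. The search result is accepted only when at most
    ``max_substitutions`` mismatches remain and the optimal placement is
    unambiguous — in that regime it provably coincides with the affine
    alignment's call, because any alternative gap structure costs more than
    the substitutions it could absorb. Everything else (multi-indel
    alleles, heavily errored or truncated reads, ambiguous placements)
    falls back to the full aligner.
    """

    def __init__(self, target: AmpliconTarget, max_substitutions: int = 3):
        self.target = target
        self.max_substitutions = max_substitutions
        self._cache: dict[str, object] = {}
        ref_seg = target.reference_seq[target.primer_offset :]
        self._ref_bytes = np.frombuffer(ref_seg.encode(), dtype=np.uint8)
        self._ref_seg = ref_seg
        self.fallback_calls = 0

    def _fast_single_indel(self, insert: str):
        """Best single-indel-plus-substitutions interpretation, or None."""
        ref = self._ref_bytes
        x = np.frombuffer(insert.encode(), dtype=np.uint8)
        d = len(ref) - len(x)
        budget = self.max_substitutions
        if d == 0:
            n_mm = int((x != ref).sum())
            if n_mm == 0:
                return AlleleKey(self.target.gene_name, WT)
            if n_mm <= budget:
                return _finalize_events([], self.target)
            return None
        if d > 0:  # candidate deletion of d reference bases
            pre = x != ref[: len(x)]
            suf = x != ref[d:]
        else:  # candidate insertion of -d read bases
            k = -d
            pre = x[: len(ref)] != ref
            suf = x[k:] != ref
        pre_cum = np.concatenate([[0], np.cumsum(pre)])
        suf_cum = np.concatenate([[0], np.cumsum(suf)])
        total_suf = suf_cum[-1]
        # mism(s) = mismatches before the split + mismatches after it
        n = len(pre_cum)
        mism = pre_cum + (total_suf - suf_cum[:n])
        best = int(mism.min())
        if best > budget:
            return None
        argmins = np.flatnonzero(mism == best)
        if d > 0:
            ev_first = ("D", int(argmins[0]), d)
            ev_last = ("D", int(argmins[-1]), d)
        else:
            ev_first = ("I", int(argmins[0]), insert[argmins[0] : argmins[0] - d])
            ev_last = ("I", int(argmins[-1]), insert[argmins[-1] : argmins[-1] - d])
        if len(argmins) > 1:
            # accept ties only when all optimal placements are equivalent
            first = _finalize_events([ev_first], self.target)
            last = _finalize_events([ev_last], self.target)
            return first if first == last else None
        return _finalize_events([ev_first], self.target)

    def __call__(self, insert: str):
        result = self._cache.get(insert)
        if result is not None:
            return result
        if len(insert) < MIN_INSERT_LEN:
            result = Unassigned("too_short")
        elif insert == self._ref_seg or self._ref_seg.startswith(insert):
            result = AlleleKey(self.target.gene_name, WT)
        else:
            result = None
            # reads shorter than the reference may be truncated rather than
            # deleted; the fast path assumes full coverage, so only use it
            # when the implied placement is clean, never to reject
            if abs(len(insert) - len(self._ref_seg)) <= 60:
                result = self._fast_single_indel(insert)
            if result is None or isinstance(result, Unassigned):
                self.fallback_calls += 1
                result = call_allele(insert, self.target)
        self._cache[insert] = result
        return result


def _resolve_umi(counter: Counter):
    """Strict-majority allele for one UMI's reads, or None on a tie."""
    top = counter.most_common(2)
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None
    return top[0][0]


def dedup_umis(calls, *, sample_id: str = "", gene: str = "",
               unassigned_reads: int = 0) -> AlleleCountTable:
    """Collapse ``(umi, AlleleKey)`` read-level calls to unique-UMI counts.

    Reads are grouped by UMI; each UMI contributes one unique molecule to
    the strict-majority allele among its reads; tied UMIs are dropped.
    """
    by_umi: dict[str, Counter] = defaultdict(Counter)
    for umi, key in calls:
        by_umi[umi][key] += 1
    counts: Counter = Counter()
    dropped = 0
    for umi, counter in by_umi.items():
        winner = _resolve_umi(counter)
        if winner is None:
            dropped += 1
        else:
            counts[winner] += 1
    if dropped:
        logger.debug("%s/%s: dropped %d tied UMIs", sample_id, gene, dropped)
    return AlleleCountTable(sample_id=sample_id, gene=gene, counts=dict(counts),
                            total_assigned=sum(counts.values()),
                            unassigned_reads=unassigned_reads,
                            dropped_umis=dropped)


def filter_artifacts(sample: AlleleCountTable,
                     control: AlleleCountTable | None) -> AlleleCountTable:
    """Remove alleles that recur in the matched non-mutant control sample.

    A non-WT allele is treated as a PCR/sequencing artifact if its count in
    the control exceeds ``max(2 UMIs, 0.05% of the control total)``.
    """
    if control is None:
        logger.warning("%s/%s: no control sample; artifact filter skipped",
                       sample.sample_id, sample.gene)
        return sample
    threshold = max(2.0, 0.0005 * control.total_assigned)
    artifacts = {key for key, c in control.counts.items()
                 if not key.is_wt and c > threshold}
    if not artifacts:
        return sample
    removed = {k: c for k, c in sample.counts.items() if k in artifacts}
    if removed:
        logger.info("%s/%s: removed %d artifact alleles (%d UMIs)",
                    sample.sample_id, sample.gene, len(removed),
                    sum(removed.values()))
    kept = {k: c for k, c in sample.counts.items() if k not in artifacts}
    return replace(sample, counts=kept, total_assigned=sum(kept.values()))
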