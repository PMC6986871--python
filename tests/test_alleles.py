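"""Read processing: demultiplexing, UMI extraction, indel calling,
UMI deduplication, and control-based artifact filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbscreen import (
    AlleleCaller,
    AlleleCountTable,
    AlleleKey,
    ReadLayout,
    Unassigned,
    call_allele,
    dedup_umis,
    demultiplex,
    extract_umi,
    filter_artifacts,
    load_index_map,
)
from limbscreen.sim import DEFAULT_ADAPTER, draw_random_allele
from limbscreen.variants import WT, apply_events, parse_descriptor


def _hypothesis_target():
    """Same construction as the `target` fixture, usable inside @given."""
    from limbscreen import AmpliconTarget

    ref = "".join("ACGT"[i]
                  for i in np.random.default_rng(7).integers(0, 4, size=180))
    return AmpliconTarget(gene_name="gene1", reference_seq=ref, cut_site=90,
                          gene_primer=ref[:20])


def read_for(target, layout, *, index="ACGTC", umi="ACGTACGTAC", allele=WT):
    insert = apply_events(target.reference_seq, parse_descriptor(allele))
    return index + layout.adapter_seq + umi + insert[target.primer_offset :]


class TestDemultiplex:
    SHEET = [{"sample_id": "s1", "index_seq": "ACGTC"},
             {"sample_id": "s2", "index_seq": "GGATT"}]

    def test_exact_match_assigns_single_mismatch_does_not(self, layout):
        index_map = load_index_map(self.SHEET)
        reads = ["ACGTC" + DEFAULT_ADAPTER + "A" * 40,
                 "TCGTC" + DEFAULT_ADAPTER + "A" * 40]  # one mismatch in index
        groups, unassigned = demultiplex(reads, index_map, layout)
        assert len(groups.get("s1", [])) == 1
        assert "s2" not in groups
        assert unassigned == 1

    def test_empty_input_gives_empty_groups(self, layout):
        groups, unassigned = demultiplex([], load_index_map(self.SHEET), layout)
        assert groups == {} and unassigned == 0

    def test_ambiguous_index_tables_rejected(self):
        with pytest.raises(ValueError, match="prefix"):
            load_index_map([{"sample_id": "s1", "index_seq": "ACGT"},
                            {"sample_id": "s2", "index_seq": "ACGTC"}])
        with pytest.raises(ValueError, match="two samples"):
            load_index_map([{"sample_id": "s1", "index_seq": "ACGTC"},
                            {"sample_id": "s2", "index_seq": "ACGTC"}])


class TestExtractUmi:
    def test_constructed_read_round_trips(self, target, layout):
        read = read_for(target, layout, umi="GATTACAGAT")
        umi, insert = extract_umi(read, target, layout)
        assert umi == "GATTACAGAT"
        assert insert.startswith(target.gene_primer)

    def test_adapter_with_one_mismatch_tolerated(self, target, layout):
        read = read_for(target, layout)
        mutated = read[:7] + ("A" if read[7] != "A" else "C") + read[8:]
        result = extract_umi(mutated, target, layout)
        assert not isinstance(result, Unassigned)

    def test_missing_adapter_unassigned(self, target, layout):
        read = "ACGTC" + "T" * len(layout.adapter_seq) + "ACGTACGTAC" + "A" * 60
        assert extract_umi(read, target, layout) == Unassigned("no_adapter")

    def test_primer_with_two_mismatches_unassigned(self, target, layout):
        read = read_for(target, layout)
        p = 5 + len(layout.adapter_seq) + 10
        bad = list(read)
        for offset in (0, 3):
            bad[p + offset] = "A" if bad[p + offset] != "A" else "C"
        assert extract_umi("".join(bad), target, layout) == Unassigned("bad_primer")


class TestCallAllele:
    def test_wild_type_and_truncated_wild_type(self, target):
        ref = target.reference_seq
        assert call_allele(ref, target) == AlleleKey("gene1", WT)
        assert call_allele(ref[:120], target) == AlleleKey("gene1", WT)

    def test_deletion_spanning_cut_site(self, target):
        # remove [cut-3, cut+2): a 5-bp deletion starting at cut-3
        ref, cut = target.reference_seq, target.cut_site
        insert = ref[: cut - 3] + ref[cut + 2 :]
        assert call_allele(insert, target).descriptor == f"D:{cut - 3}:5"

    def test_insertion_at_cut_site(self, target):
        from limbscreen.variants import format_descriptor, normalize_events

        ref, cut = target.reference_seq, target.cut_site
        insert = ref[:cut] + "TTAG" + ref[cut:]
        # expected descriptor is the left-aligned canonical form
        expected = format_descriptor(normalize_events(ref, [("I", cut, "TTAG")]))
        assert call_allele(insert, target).descriptor == expected

    def test_substitution_far_from_cut_is_wild_type(self, target):
        seq = list(target.reference_seq)
        p = target.cut_site + 40
        seq[p] = "A" if seq[p] != "A" else "C"
        assert call_allele("".join(seq), target) == AlleleKey("gene1", WT)

    def test_indel_outside_window_unassigned(self, target):
        ref = target.reference_seq
        insert = ref[:30] + ref[36:]  # deletion 60 bp from the cut
        assert call_allele(insert, target) == Unassigned("off_window")

    def test_short_insert_unassigned(self, target):
        assert call_allele(target.reference_seq[:25], target) == \
            Unassigned("too_short")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_substitution_noise_never_changes_the_call(self, seed):
        """Mutating up to 2% of insert bases (no indels) leaves the
        descriptor unchanged."""
        target = _hypothesis_target()
        rng = np.random.default_rng(seed)
        allele = draw_random_allele(rng, target.cut_site, ref=target.reference_seq)
        insert = apply_events(target.reference_seq, parse_descriptor(allele))
        clean = call_allele(insert, target)
        n_subs = max(1, int(0.02 * len(insert)))
        # substitutions stay clear of the indel region: a hit exactly on the
        # boundary-distinguishing base can genuinely reconstruct an adjacent
        # allele's sequence, which is an ambiguity of the data, not the caller
        cut = target.cut_site
        eligible = [i for i in range(len(insert)) if not cut - 45 <= i <= cut + 45]
        seq = bytearray(insert, "ascii")
        for pos in rng.choice(eligible, size=n_subs, replace=False):
            options = [b for b in b"ACGT" if b != seq[pos]]
            seq[pos] = options[rng.integers(0, 3)]
        assert call_allele(seq.decode(), target) == clean

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fast_caller_agrees_with_full_alignment(self, seed):
        target = _hypothesis_target()
        rng = np.random.default_rng(seed)
        allele = (WT if rng.random() < 0.3
                  else draw_random_allele(rng, target.cut_site,
                                          ref=target.reference_seq))
        seq = bytearray(apply_events(target.reference_seq,
                                     parse_descriptor(allele)), "ascii")
        for _ in range(rng.poisson(0.6)):
            pos = rng.integers(0, len(seq))
            options = [b for b in b"ACGT" if b != seq[pos]]
            seq[pos] = options[rng.integers(0, 3)]
        read = seq.decode()
        assert AlleleCaller(target)(read) == call_allele(read, target)


class TestDedupUmis:
    A = AlleleKey("g", "D:90:2")
    B = AlleleKey("g", WT)

    def test_duplicates_collapse_to_one_unique_read(self):
        table = dedup_umis([("U1", self.A)] * 3)
        assert table.counts == {self.A: 1} and table.total_assigned == 1

    def test_majority_wins_within_a_umi(self):
        table = dedup_umis([("U1", self.A), ("U1", self.A), ("U1", self.B)])
        assert table.counts == {self.A: 1}

    def test_tied_umi_dropped(self):
        table = dedup_umis([("U1", self.A), ("U1", self.B)])
        assert table.counts == {} and table.dropped_umis == 1

    def test_idempotent_and_bounded_by_distinct_umis(self, rng):
        calls = [(f"U{rng.integers(0, 50)}", self.A if rng.random() < 0.7 else self.B)
                 for _ in range(300)]
        table = dedup_umis(calls)
        assert table.total_assigned <= len({u for u, _ in calls})
        again = dedup_umis([(f"U{i}", key) for i, key in enumerate(
            k for k, c in table.counts.items() for _ in range(c))])
        assert again.counts == table.counts


class TestFilterArtifacts:
    @staticmethod
    def table(sample_id, counts):
        return AlleleCountTable(sample_id=sample_id, gene="g", counts=counts,
                                total_assigned=sum(counts.values()))

    A = AlleleKey("g", "D:90:2")
    B = AlleleKey("g", "I:90:T")
    WTK = AlleleKey("g", WT)

    def test_recurrent_control_allele_removed(self):
        sample = self.table("s", {self.A: 50, self.B: 30, self.WTK: 920})
        control = self.table("c", {self.A: 30, self.WTK: 9970})  # 0.3% > threshold
        filtered = filter_artifacts(sample, control)
        assert self.A not in filtered.counts
        assert filtered.counts[self.B] == 30
        assert filtered.total_assigned == 950

    def test_allele_absent_from_control_retained(self):
        sample = self.table("s", {self.B: 30, self.WTK: 970})
        control = self.table("c", {self.WTK: 10_000})
        assert filter_artifacts(sample, control) == sample

    def test_low_level_control_noise_tolerated(self):
        # 2 UMIs in a deep control is within the noise floor
        sample = self.table("s", {self.A: 40, self.WTK: 960})
        control = self.table("c", {self.A: 2, self.WTK: 9998})
        assert filter_artifacts(sample, control).counts[self.A] == 40

    def test_missing_control_passes_through_with_warning(self, caplog):
        sample = self.table("s", {self.A: 40, self.WTK: 960})
        with caplog.at_level("WARNING"):
            assert filter_artifacts(sample, None) == sample
        assert any("control" in r.message for r in caplog.records)
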