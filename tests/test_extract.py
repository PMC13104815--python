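"""Anchor scanning, barcode QC cascade, UMI dedup, cell resolution, cell QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clonetracer as ct
from clonetracer.extract import HitStatus

ANCHOR = ct.DEFAULT_ANCHOR


def naive_find(seq, anchor, maxmm):
    """Independent oracle: exhaustive sliding-window Hamming scan."""
    for i in range(len(seq) - len(anchor) + 1):
        if sum(a != b for a, b in zip(seq[i:i + len(anchor)], anchor)) <= maxmm:
            return i
    return None


class TestFindAnchor:
    def test_exact_anchor_located_at_offset(self):
        read = "GG" + ANCHOR + "ACGTACGT"
        assert ct.find_anchor(read, ANCHOR, 2) == 2

    def test_no_anchor_like_window_returns_absent(self):
        assert ct.find_anchor("ACGT" * 30, ANCHOR, 2) is None

    def test_anchor_longer_than_read_returns_absent(self):
        assert ct.find_anchor("ACGT", ANCHOR, 2) is None

    def test_single_substitution_found_at_same_position(self):
        mutated = "T" + ANCHOR[1:]
        read = "CCCCC" + mutated + "A" * 20
        assert ct.find_anchor(read, ANCHOR, 2) == 5
        assert ct.find_anchor(read, ANCHOR, 2) == naive_find(read, ANCHOR, 2)

    @settings(max_examples=100, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=0, max_size=120),
        maxmm=st.integers(min_value=0, max_value=3),
        anchor=st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_matches_exhaustive_hamming_oracle(self, seq, maxmm, anchor):
        assert ct.find_anchor(seq, anchor, maxmm) == naive_find(seq, anchor, maxmm)


class TestExtractBarcode:
    @pytest.fixture()
    def pat(self):
        return ct.BarcodePattern()

    def _read(self, seq, cb="CB1", umi="U1"):
        return ct.TaggedRead(read_id="r", sequence=seq, cell_barcode=cb, umi=umi)

    def test_conformant_barcode_passes_with_first_ten_bases_as_clone_id(self, pat):
        bc = ct.simulate_library(pat, 1, seed=0)[0]
        hit = ct.extract_barcode(self._read("GG" + ANCHOR + bc), pat)
        assert hit.status is HitStatus.PASS
        assert hit.anchor_position == 2
        assert hit.clone_id == bc[:10]
        assert hit.barcode_sequence == bc

    def test_anchor_near_read_end_is_short_barcode(self, pat):
        hit = ct.extract_barcode(self._read("AA" + ANCHOR + "ACGTC"), pat)
        assert hit.status is HitStatus.SHORT_BARCODE

    def test_anchor_followed_by_vector_sequence_is_empty_vector(self, pat):
        seq = ANCHOR + pat.downstream_fixed + "ACGT" * 10
        hit = ct.extract_barcode(self._read(seq), pat)
        assert hit.status is HitStatus.EMPTY_VECTOR

    def test_no_anchor_status(self, pat):
        hit = ct.extract_barcode(self._read("ACGT" * 80), pat)
        assert hit.status is HitStatus.NO_ANCHOR

    def test_pattern_violation_is_bad_pattern(self):
        # a pattern whose clone-ID region only allows purines
        pat = ct.BarcodePattern(length=20, id_length=10, pattern="R" * 20)
        hit = ct.extract_barcode(self._read(ANCHOR + "CCCCCCCCCC" + "A" * 10), pat)
        assert hit.status is HitStatus.BAD_PATTERN

    def test_bulk_read_found_on_reverse_strand(self, pat):
        bc = ct.simulate_library(pat, 1, seed=1)[0]
        fwd = "CC" + ANCHOR + bc
        read = ct.TaggedRead(read_id="b", sequence=ct.reverse_complement(fwd))
        hit = ct.extract_barcode(read, pat)
        assert hit.status is HitStatus.PASS
        assert hit.orientation == "-"
        assert hit.clone_id == bc[:10]

    def test_tagged_read_not_rescued_from_reverse_strand(self, pat):
        bc = ct.simulate_library(pat, 1, seed=1)[0]
        read = self._read(ct.reverse_complement(ANCHOR + bc))
        assert ct.extract_barcode(read, pat).status is HitStatus.NO_ANCHOR

    def test_every_read_classified_exactly_once(self, clean_hits, clean_run):
        # conservation of reads across PASS + rejection categories
        assert len(clean_hits) == len(clean_run["sim"].reads)
        assert all(isinstance(h.status, HitStatus) for h in clean_hits)


class TestDedup:
    def _hit(self, cb, umi, cid, rid="r1"):
        return ct.BarcodeHit(
            read_id=rid, status=HitStatus.PASS, clone_id=cid,
            cell_barcode=cb, umi=umi, sample="s",
        )

    def test_identical_cb_umi_clone_collapse_to_one_molecule(self):
        mol = ct.dedup_umis([self._hit("C", "U", "AAAA", "r1"),
                             self._hit("C", "U", "AAAA", "r2")])
        assert len(mol) == 1
        assert mol["read_count"].iloc[0] == 2

    def test_distinct_umis_stay_distinct_molecules(self):
        mol = ct.dedup_umis([self._hit("C", "U1", "AAAA"),
                             self._hit("C", "U2", "AAAA")])
        assert len(mol) == 2

    def test_missing_umi_in_tagged_mode_excluded_with_reason(self):
        bad = ct.BarcodeHit(read_id="x", status=HitStatus.PASS, clone_id="AAAA",
                            cell_barcode="C", umi=None, sample="s")
        mol = ct.dedup_umis([bad, self._hit("C", "U", "AAAA")])
        assert len(mol) == 1
        assert mol.attrs["excluded"] == ["x"]


class TestResolveCells:
    def _mols(self, cell_entries):
        rows = []
        for cb, cid, n in cell_entries:
            for i in range(n):
                rows.append(("s", cb, f"{cid}-{i}", cid))
        return pd.DataFrame(rows, columns=["sample", "cell_barcode", "umi", "clone_id"])

    def test_single_clone_cell_is_kept(self):
        table = ct.resolve_cells(self._mols([("c1", "AAAAAAAAAA", 5)]))
        assert list(table.assignments.clone_id) == ["AAAAAAAAAA"]
        assert table.rejected.empty

    def test_two_genuine_clones_rejected_as_multi_barcode(self):
        table = ct.resolve_cells(
            self._mols([("c1", "AAAAAAAAAA", 20), ("c1", "GGGGGGGGGG", 18)])
        )
        assert table.assignments.empty
        assert list(table.rejected.reason) == ["MULTI_BARCODE"]

    def test_single_umi_minor_barcode_is_noise(self):
        # X:40, Y:1 -> Y falls below both noise floors, cell kept with X
        table = ct.resolve_cells(
            self._mols([("c1", "AAAAAAAAAA", 40), ("c1", "GGGGGGGGGG", 1)])
        )
        assert list(table.assignments.clone_id) == ["AAAAAAAAAA"]
        assert table.assignments.umi_count.iloc[0] == 40

    def test_sequencing_error_neighbor_id_merged_into_parent(self):
        # one UMI carrying a Hamming-1 neighbour of the dominant ID
        table = ct.resolve_cells(
            self._mols([("c1", "AAAAAAAAAA", 30), ("c1", "AAAAAAAAAT", 1)])
        )
        assert list(table.assignments.clone_id) == ["AAAAAAAAAA"]
        assert table.assignments.umi_count.iloc[0] == 31

    def test_comparable_neighbor_counts_never_merged(self):
        # directional rule: 2*18 > 20, so even Hamming-1 IDs stay separate
        table = ct.resolve_cells(
            self._mols([("c1", "AAAAAAAAAA", 20), ("c1", "AAAAAAAAAT", 18)])
        )
        assert list(table.rejected.reason) == ["MULTI_BARCODE"]

    def test_order_independence_of_resolution(self, clean_hits):
        mol = ct.dedup_umis(clean_hits)
        shuffled = mol.sample(frac=1.0, random_state=7).reset_index(drop=True)
        t1 = ct.resolve_cells(mol)
        t2 = ct.resolve_cells(shuffled)
        key = ["sample", "cell_barcode"]
        pd.testing.assert_frame_equal(
            t1.assignments.sort_values(key).reset_index(drop=True),
            t2.assignments.sort_values(key).reset_index(drop=True),
        )


class TestTruthRecovery:
    @staticmethod
    def recall_precision(sim, assignments):
        truth = sim.cell_truth
        single = truth[truth.n_integrations == 1]
        tmap = dict(zip(single.cell_barcode, single.full_barcode.str[:10]))
        amap = dict(zip(assignments.cell_barcode, assignments.clone_id))
        correct = sum(1 for cb, cid in tmap.items() if amap.get(cb) == cid)
        called_in_truth = [cb for cb in amap if cb in tmap]
        precision = (
            sum(1 for cb in called_in_truth if amap[cb] == tmap[cb])
            / len(called_in_truth)
        )
        return correct / len(tmap), precision

    def test_error_free_assignments_match_truth_exactly(self, clean_run, clean_hits):
        table = ct.resolve_cells(ct.dedup_umis(clean_hits))
        recall, precision = self.recall_precision(clean_run["sim"], table.assignments)
        assert recall == 1.0
        assert precision == 1.0

    def test_extraction_order_independent(self, clean_run, pattern, clean_hits):
        reads = list(clean_run["sim"].reads)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(reads))
        hits2 = ct.extract_hits([reads[i] for i in perm], pattern)
        t1 = ct.resolve_cells(ct.dedup_umis(clean_hits))
        t2 = ct.resolve_cells(ct.dedup_umis(hits2))
        key = ["sample", "cell_barcode"]
        pd.testing.assert_frame_equal(
            t1.assignments.sort_values(key).reset_index(drop=True),
            t2.assignments.sort_values(key).reset_index(drop=True),
        )


class TestCellQC:
    def _metrics(self, rows):
        return pd.DataFrame(
            rows, columns=["cell_id", "n_genes", "n_umis", "mito_fraction",
                           "mouse_fraction"]
        )

    def test_healthy_cell_retained(self):
        kept, rej = ct.cell_qc_filter(
            self._metrics([("a", 2500, 20000, 0.05, 0.03)])
        )
        assert kept == {"a"} and rej.empty

    @pytest.mark.parametrize(
        "row,reason",
        [
            (("b", 1999, 20000, 0.05, 0.03), "LOW_GENES"),
            (("c", 2500, 50001, 0.05, 0.03), "HIGH_UMIS"),
            (("d", 2500, 20000, 0.21, 0.03), "HIGH_MITO"),
            (("e", 2500, 20000, 0.05, 0.21), "MOUSE"),
        ],
    )
    def test_threshold_violations_rejected_with_reason(self, row, reason):
        kept, rej = ct.cell_qc_filter(self._metrics([row]))
        assert not kept
        assert rej.reason.iloc[0] == reason

    def test_boundary_values_retained(self):
        kept, _ = ct.cell_qc_filter(
            self._metrics([("f", 2000, 50000, 0.20, 0.20)])
        )
        assert kept == {"f"}

    def test_missing_mouse_column_is_allowed(self):
        df = pd.DataFrame(
            [("g", 2500, 1000, 0.1)],
            columns=["cell_id", "n_genes", "n_umis", "mito_fraction"],
        )
        kept, _ = ct.cell_qc_filter(df)
        assert kept == {"g"}

    def test_missing_required_column_raises(self):
        df = pd.DataFrame([("h", 2500)], columns=["cell_id", "n_genes"])
        with pytest.raises(ValueError, match="missing columns"):
            ct.cell_qc_filter(df)
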