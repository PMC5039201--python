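import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import barseqfit as bf
from barseqfit.counting import TagIndex, _AMBIGUOUS, _UNASSIGNED

from conftest import assign_oracle, hamming_oracle

DNA = st.text(alphabet="ACGT", min_size=20, max_size=20)


class TestHamming:
    def test_identity(self):
        assert bf.hamming_mismatches("ACGT", "ACGT") == 0

    def test_single_substitution(self):
        assert bf.hamming_mismatches("AAAA", "AAAT") == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            bf.hamming_mismatches("ACG", "ACGT")

    @settings(derandomize=True, max_examples=200)
    @given(DNA, DNA)
    def test_matches_positionwise_oracle(self, a, b):
        assert bf.hamming_mismatches(a, b) == hamming_oracle(a, b)


class TestDemultiplex:
    def test_listed_index(self, samplesheet_hom):
        read = samplesheet_hom["index"].iloc[0] + "G" * 44
        assert bf.demultiplex(read, samplesheet_hom) == samplesheet_hom.sample_id.iloc[0]

    def test_unlisted_index(self, samplesheet_hom):
        bad = "AAAAAA"
        assert bad not in set(samplesheet_hom["index"])
        assert bf.demultiplex(bad + "G" * 44, samplesheet_hom) == "unassigned_index"

    def test_one_mismatch_tolerance_and_ties(self, samplesheet_hom):
        idx = samplesheet_hom["index"].iloc[2]
        mutated = ("T" if idx[0] != "T" else "G") + idx[1:]
        read = mutated + "G" * 44
        assert bf.demultiplex(read, samplesheet_hom) == "unassigned_index"
        got = bf.demultiplex(read, samplesheet_hom, max_index_mismatch=1)
        # sheet indices are >=3 apart, so a 1-off index is uniquely closest
        assert got == samplesheet_hom.sample_id.iloc[2]
        # equidistant to two indices -> unassigned
        sheet = pd.DataFrame({"sample_id": ["s1", "s2"],
                              "index": ["AAAAAA", "TTAAAA"],
                              "condition": ["t0", "t0"],
                              "replicate": [1, 2], "generations": [0, 0]})
        # "TAAAAA" is 1 mismatch from both indices: tied, so unassigned
        assert bf.demultiplex("TAAAAA" + "G" * 44, sheet,
                              max_index_mismatch=1) == "unassigned_index"


class TestLocateTagWindow:
    def test_up_read_roundtrip(self, small_catalog, samplesheet_hom):
        layout = bf.DEFAULT_LAYOUT
        tag = small_catalog.up_tag.iloc[0]
        read = "ACGTAC" + layout.up_common_primer + tag + "A" * 6
        assert bf.locate_tag_window(read, layout) == (tag, "up")

    def test_down_read_roundtrip(self, small_catalog):
        layout = bf.DEFAULT_LAYOUT
        tag = small_catalog.down_tag.iloc[0]
        read = "ACGTAC" + layout.down_common_primer + tag + "A" * 7
        assert bf.locate_tag_window(read, layout) == (tag, "down")

    def test_two_substitutions_still_located(self):
        layout = bf.DEFAULT_LAYOUT
        primer = list(layout.up_common_primer)
        primer[0] = "C" if primer[0] != "C" else "T"
        primer[5] = "C" if primer[5] != "C" else "T"
        read = "ACGTAC" + "".join(primer) + "A" * 20 + "T" * 6
        window, kind = bf.locate_tag_window(read, layout)
        assert kind == "up" and window == "A" * 20

    def test_random_reads_rarely_match(self):
        layout = bf.DEFAULT_LAYOUT
        rng = np.random.default_rng(5)
        n = 20_000
        hits = 0
        bases = np.array(list("ACGT"))
        for seq in ["".join(r) for r in bases[rng.integers(0, 4, (n, 50))]]:
            if bf.locate_tag_window(seq, layout) is not None:
                hits += 1
        # expected false-primer rate < 1e-4 per read
        assert hits <= 4


class TestAssignTag:
    def test_exact_match(self, small_catalog):
        assert bf.assign_tag(small_catalog.up_tag.iloc[3], small_catalog) == (
            small_catalog.strain_id.iloc[3], "up")

    def test_three_mismatches_unassigned(self, small_catalog):
        tag = list(small_catalog.down_tag.iloc[0])
        for i in range(3):
            tag[i] = "A" if tag[i] != "A" else "C"
        # catalog distance >=5 guarantees no other tag is within 2
        assert bf.assign_tag("".join(tag), small_catalog) == "unassigned_tag"

    def test_fast_index_equals_scan(self, small_catalog):
        rng = np.random.default_rng(8)
        tindex = TagIndex(small_catalog)
        tags = bf.tags_frame(small_catalog)
        bases = np.array(list("ACGT"))
        windows = ["".join(w) for w in bases[rng.integers(0, 4, (300, 20))]]
        # bias towards near-tag windows: mutate catalog tags 0-4 times
        for _ in range(300):
            t = list(tags.seq.iloc[rng.integers(len(tags))])
            for i in rng.choice(20, size=rng.integers(0, 5), replace=False):
                t[i] = "ACGT"[rng.integers(4)]
            windows.append("".join(t))
        for w in windows:
            expected = assign_oracle(w, small_catalog)
            got = tindex.assign(w.encode())
            if got == _UNASSIGNED:
                got = "unassigned_tag"
            elif got == _AMBIGUOUS:
                got = "ambiguous_tag"
            else:
                got = (tindex.strain_id[got], tindex.kind[got])
            assert got == expected
            assert bf.assign_tag(w, small_catalog) == expected

    def test_strict_threshold_flag(self, small_catalog):
        tag = list(small_catalog.up_tag.iloc[1])
        tag[0] = "A" if tag[0] != "A" else "C"
        tag[1] = "A" if tag[1] != "A" else "C"
        w = "".join(tag)
        assert bf.assign_tag(w, small_catalog, max_mismatch=2) != "unassigned_tag"
        assert bf.assign_tag(w, small_catalog, max_mismatch=1) == "unassigned_tag"


class TestCountTags:
    def test_roundtrip_exact(self, small_catalog, samplesheet_hom,
                             small_tag_counts, tmp_path):
        path = tmp_path / "rt.fastq.gz"
        bf.simulate_reads(small_tag_counts, small_catalog, samplesheet_hom, path,
                          error_rate=0.0, seed=2)
        cm = bf.count_tags(path, small_catalog, samplesheet_hom)
        assert cm.counts[small_tag_counts.columns].equals(small_tag_counts)
        assert cm.ledger.drop("(unassigned)")["unassigned_tag"].sum() == 0

    def test_ledger_conservation(self, small_catalog, samplesheet_hom,
                                 small_tag_counts, tmp_path):
        path = tmp_path / "err.fastq.gz"
        bf.simulate_reads(small_tag_counts, small_catalog, samplesheet_hom, path,
                          error_rate=0.01, seed=3)
        cm = bf.count_tags(path, small_catalog, samplesheet_hom)
        assert cm.total_reads == small_tag_counts.values.sum()
        # per-sample: assigned equals the count-matrix column sum
        for s in cm.samples:
            assert cm.ledger.loc[s, "assigned"] == cm.counts[s].sum()

    def test_loss_bounded_at_low_error(self, small_catalog, samplesheet_hom,
                                       small_tag_counts, tmp_path):
        path = tmp_path / "e2.fastq.gz"
        bf.simulate_reads(small_tag_counts, small_catalog, samplesheet_hom, path,
                          error_rate=0.01, seed=4)
        cm = bf.count_tags(path, small_catalog, samplesheet_hom,
                           max_index_mismatch=1)
        # with 1-mismatch demultiplexing, only primer/tag failures lose reads;
        # tags tolerate 2 mismatches so per-sample recovery is within 2%
        for s in cm.samples:
            total = small_tag_counts[s].sum()
            assert abs(cm.counts[s].sum() - total) / total < 0.02

    def test_empty_fastq(self, small_catalog, samplesheet_hom, tmp_path):
        path = tmp_path / "empty.fastq.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("")
        cm = bf.count_tags(path, small_catalog, samplesheet_hom)
        assert (cm.counts.values == 0).all() and cm.total_reads == 0

    def test_order_independence(self, small_catalog, samplesheet_hom,
                                small_tag_counts, tmp_path):
        p1 = tmp_path / "a.fastq.gz"
        bf.simulate_reads(small_tag_counts, small_catalog, samplesheet_hom, p1,
                          error_rate=0.005, seed=5)
        with gzip.open(p1, "rt") as fh:
            lines = fh.read().strip().split("\n")
        records = [lines[i:i + 4] for i in range(0, len(lines), 4)]
        rng = np.random.default_rng(0)
        rng.shuffle(records)
        p2 = tmp_path / "b.fastq.gz"
        with gzip.open(p2, "wt") as fh:
            fh.write("\n".join("\n".join(r) for r in records) + "\n")
        cm1 = bf.count_tags(p1, small_catalog, samplesheet_hom)
        cm2 = bf.count_tags(p2, small_catalog, samplesheet_hom)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(cm1.ledger, cm2.ledger)

    def test_malformed_fastq_reported(self, small_catalog, samplesheet_hom, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@read1\nACGT\nJUNK\n")
        with pytest.raises(ValueError, match="bad.fastq"):
            bf.count_tags(path, small_catalog, samplesheet_hom)


class TestAggregate:
    def test_up_plus_down(self, small_catalog, samplesheet_hom):
        tags = bf.tags_frame(small_catalog)
        counts = pd.DataFrame(0, index=tags.tag_id, columns=["s1"])
        sid = small_catalog.strain_id.iloc[0]
        counts.loc[f"{sid}:up", "s1"] = 10
        counts.loc[f"{sid}:down", "s1"] = 15
        cm = bf.CountMatrix(counts=counts, ledger=pd.DataFrame())
        agg = bf.aggregate_strains(cm, small_catalog)
        assert agg.counts.loc[sid, "s1"] == 25

    def test_column_sums_preserved(self, small_catalog, small_tag_counts):
        cm = bf.CountMatrix(counts=small_tag_counts, ledger=pd.DataFrame())
        agg = bf.aggregate_strains(cm, small_catalog)
        assert (agg.counts.sum() == small_tag_counts.sum()).all()

    def test_orphan_tag_rejected(self, small_catalog, small_tag_counts):
        counts = small_tag_counts.copy()
        counts.loc["GHOST:up"] = 1
        cm = bf.CountMatrix(counts=counts, ledger=pd.DataFrame())
        with pytest.raises(ValueError, match="GHOST"):
            bf.aggregate_strains(cm, small_catalog)
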