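import gzip

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

import barseqfit as bf


class TestCatalog:
    def test_single_strain_contract(self):
        cat = bf.generate_catalog(1, seed=7)
        assert len(cat) == 1
        assert len(cat.up_tag.iloc[0]) == 20 and len(cat.down_tag.iloc[0]) == 20

    def test_determinism(self):
        a = bf.generate_catalog(10, seed=1)
        b = bf.generate_catalog(10, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_tag_distance_small(self, small_catalog):
        tags = bf.tags_frame(small_catalog)["seq"]
        codes = np.stack([np.frombuffer(t.encode(), np.uint8) for t in tags])
        d = pdist(codes, "hamming") * 20
        assert d.min() >= 5

    def test_unique_strain_ids(self, small_catalog):
        assert small_catalog.strain_id.is_unique

    def test_impossible_request_raises(self):
        # 20-mers at pairwise distance >= 19: far more tags than the space holds
        with pytest.raises(RuntimeError):
            bf.generate_catalog(500, seed=1, min_distance=19, max_rounds=3)


class TestTruth:
    def test_null_model_all_zero(self, small_catalog):
        t = bf.generate_truth(small_catalog, frac_impaired=0, frac_advantaged=0,
                              frac_artifact=0, seed=5)
        nonsent = t[~t.role.isin(["hog1_like", "bul1_like"])]
        assert (nonsent[["s_basal", "s_glucose", "s_sorbitol"]] == 0).all().all()

    def test_sentinels(self, small_truth):
        hog = small_truth[small_truth.role == "hog1_like"].iloc[0]
        assert hog.s_glucose <= -2 and hog.s_sorbitol <= -2 and hog.s_basal == 0
        bul = small_truth[small_truth.role == "bul1_like"].iloc[0]
        assert 0.13 <= bul.s_glucose <= 0.16 and 0.13 <= bul.s_sorbitol <= 0.16

    def test_frequencies_sum_to_one(self, small_truth):
        assert small_truth.initial_frequency.sum() == pytest.approx(1, abs=1e-12)

    def test_artifact_sign_by_collection(self):
        genes = [f"G{i}" for i in range(200)]
        hom = bf.generate_catalog(200, seed=3, genes=genes)
        het = bf.generate_catalog(200, seed=4, collection="heterozygous", genes=genes)
        th = bf.generate_truth(hom, seed=9)
        te = bf.generate_truth(het, seed=9)
        art = th.suppressor_artifact
        # same genes flagged in both pools, opposite basal behaviour
        assert (art == te.suppressor_artifact).all() and art.any()
        assert (th.loc[art, "s_basal"] >= 0).all()
        assert (te.loc[art, "s_basal"] <= -0.3).all()

    def test_effect_mixture_at_scale(self):
        cat = bf.generate_catalog(4300, seed=1)
        t = bf.generate_truth(cat, frac_impaired=0.05, frac_advantaged=0.03,
                              frac_artifact=0.12, seed=2)
        frac = t.role.value_counts(normalize=True)
        assert frac["impaired"] == pytest.approx(0.05, abs=0.002)
        assert frac["advantaged"] == pytest.approx(0.03, abs=0.002)
        assert frac["artifact"] == pytest.approx(0.12, abs=0.002)
        imp = t.loc[t.role == "impaired", ["s_glucose", "s_sorbitol"]].to_numpy()
        vals = imp[imp != 0]
        # spike-and-slab slab: -|N(0.2, 0.1)|, folded-normal mean ~ -0.2017
        assert vals.mean() == pytest.approx(-0.2017, abs=0.02)
        assert (vals < 0).all()

    def test_invalid_fractions(self, small_catalog):
        with pytest.raises(ValueError):
            bf.generate_truth(small_catalog, frac_impaired=0.8, frac_artifact=0.4)


class TestCompetition:
    def test_neutral_equal_frequencies(self, small_catalog):
        t = bf.generate_truth(small_catalog, frac_impaired=0, frac_advantaged=0,
                              frac_artifact=0, freq_sigma=0, seed=5)
        t.loc[:, ["s_basal", "s_glucose", "s_sorbitol"]] = 0.0
        f = bf.expected_frequencies(t, "glucose", 10)
        assert np.allclose(f, 1 / len(t), atol=1e-15)

    def test_frequency_conservation(self, small_truth):
        for g in [0, 3, 10, 20]:
            f = bf.expected_frequencies(small_truth, "sorbitol", g)
            assert f.sum() == pytest.approx(1, abs=1e-12)

    def test_single_selected_strain_closed_form(self):
        cat = bf.generate_catalog(4300, seed=1)
        t = bf.generate_truth(cat, frac_impaired=0, frac_advantaged=0,
                              frac_artifact=0, freq_sigma=0, seed=2)
        t.loc[:, ["s_basal", "s_glucose", "s_sorbitol"]] = 0.0
        t.loc[0, "s_glucose"] = -0.3
        f0 = bf.expected_frequencies(t, "glucose", 0)
        fG = bf.expected_frequencies(t, "glucose", 10)
        lfc = np.log2(fG.iloc[0] / f0.iloc[0])
        assert lfc == pytest.approx(10 * -0.3, abs=0.01)  # renormalisation ~1/4300

    def test_determinism_and_depth(self, small_catalog, small_truth):
        a = bf.simulate_competition(small_catalog, small_truth, "basal", 10, 9999, seed=4)
        b = bf.simulate_competition(small_catalog, small_truth, "basal", 10, 9999, seed=4)
        pd.testing.assert_frame_equal(a.tag_counts, b.tag_counts)
        assert (a.tag_counts.sum() == 9999).all()


class TestReads:
    def test_exact_roundtrip_by_string_match(self, small_catalog, small_truth,
                                             samplesheet_hom, small_tag_counts,
                                             tmp_path):
        path = tmp_path / "r.fastq.gz"
        bf.simulate_reads(small_tag_counts, small_catalog, samplesheet_hom, path,
                          error_rate=0.0, seed=1)
        layout = bf.DEFAULT_LAYOUT
        tags = bf.tags_frame(small_catalog)
        by_seq = {(r.kind, r.seq): r.tag_id for r in tags.itertuples()}
        by_index = dict(zip(samplesheet_hom["index"], samplesheet_hom.sample_id))
        got = {}
        n_reads = 0
        with gzip.open(path, "rt") as fh:
            for i, line in enumerate(fh):
                if i % 4 != 1:
                    continue
                n_reads += 1
                seq = line.strip()
                sample = by_index[seq[:6]]
                if seq[6:24] == layout.up_common_primer:
                    key = ("up", seq[24:44])
                else:
                    assert seq[6:23] == layout.down_common_primer
                    key = ("down", seq[23:43])
                got[(by_seq[key], sample)] = got.get((by_seq[key], sample), 0) + 1
        assert n_reads == small_tag_counts.values.sum()
        stacked = small_tag_counts.stack()
        for (tag, sample), c in stacked[stacked > 0].items():
            assert got[(tag, sample)] == c

    def test_error_rate_hits_tag_window(self, small_catalog, small_truth, tmp_path):
        # fraction of reads with >=1 substitution in the 20-nt tag ~ 1-(1-e)^20
        sheet = bf.make_samplesheet("homozygous", n_replicates=1, seed=13)
        sheet = sheet[sheet.condition == "t0"].reset_index(drop=True)
        n = 100_000
        counts = pd.DataFrame(0, index=bf.tags_frame(small_catalog).tag_id,
                              columns=sheet.sample_id)
        counts.iloc[0, 0] = n
        tag = bf.tags_frame(small_catalog).seq.iloc[0]
        path = tmp_path / "e.fastq.gz"
        bf.simulate_reads(counts, small_catalog, sheet, path, error_rate=0.001, seed=3)
        hit = 0
        with gzip.open(path, "rt") as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1 and line.strip()[24:44] != tag:
                    hit += 1
        expected = 1 - (1 - 0.001) ** 20
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hit / n - expected) < 4 * se

    def test_zero_counts_empty_fastq(self, small_catalog, samplesheet_hom, tmp_path):
        counts = pd.DataFrame(0, index=bf.tags_frame(small_catalog).tag_id,
                              columns=samplesheet_hom.sample_id)
        path = tmp_path / "empty.fastq.gz"
        bf.simulate_reads(counts, small_catalog, samplesheet_hom, path, seed=1)
        with gzip.open(path, "rt") as fh:
            assert fh.read() == ""


class TestAnnotation:
    def test_planted_maximal_overlap(self, small_catalog, small_truth):
        impaired = small_truth[small_truth.role.isin(["impaired", "hog1_like"])]
        k = len(impaired)
        ann = bf.generate_annotation(small_catalog, small_truth, n_terms=5,
                                     planted_term_size=k, planted_overlap=k, seed=1)
        planted = set(ann.loc[ann.term == "T0000:planted", "gene"])
        assert planted == set(impaired.gene)

    def test_impossible_overlap_rejected(self, small_catalog, small_truth):
        with pytest.raises(ValueError):
            bf.generate_annotation(small_catalog, small_truth,
                                   planted_term_size=5, planted_overlap=25)

    def test_random_terms_near_background(self):
        cat = bf.generate_catalog(500, seed=2)
        truth = bf.generate_truth(cat, seed=3)
        ann = bf.generate_annotation(cat, truth, n_terms=40, planted_term_size=20,
                                     planted_overlap=0, term_size_range=(30, 60), seed=4)
        hits = set(truth[truth.role == "impaired"].gene)
        background = len(hits) / len(cat)
        fracs = [len(set(g) & hits) / len(set(g))
                 for t, g in ann.groupby("term")["gene"] if t != "T0000:planted"]
        # binomial sampling error around the background rate
        assert abs(np.mean(fracs) - background) < 0.05

    def test_roundtrip_through_reader(self, small_catalog, small_truth, tmp_path):
        from barseqfit import io
        ann = bf.generate_annotation(small_catalog, small_truth,
                                     planted_term_size=3, planted_overlap=2, seed=1)
        io.write_tsv(ann, tmp_path / "ann.tsv")
        back = io.read_annotation(tmp_path / "ann.tsv")
        pd.testing.assert_frame_equal(ann, back)
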