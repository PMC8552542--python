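"""Clonotype table I/O, productive filtering, phenotype disambiguation,
and downsampling."""

from __future__ import annotations

import numpy as np
import pytest

from allotrace import (
    ClonotypeTableError,
    assign_phenotypes,
    downsample,
    downsampled_mean_statistic,
    filter_productive,
    merge_samples,
    read_clonotype_table,
    write_clonotype_table,
)
from allotrace.types import Compartment, Phenotype, Timepoint

from conftest import make_meta, make_sample


def _write_table(tmp_path, rows, header="cloneCount\tnSeqCDR3\taaSeqCDR3\tbestVGene\tbestDGene\tbestJGene"):
    path = tmp_path / "sample.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadClonotypeTable:
    def test_frequencies_recomputed_from_counts(self, tmp_path):
        path = _write_table(
            tmp_path,
            [
                "10\tTGTGCA\tCA\tTRBV1\t\tTRBJ1",
                "30\tTGTGCC\tCA\tTRBV1\t\tTRBJ1",
                "60\tTGTGCG\tCA\tTRBV1\t\tTRBJ1",
            ],
        )
        sample = read_clonotype_table(path, make_meta())
        assert sorted(c.frequency for c in sample.clonotypes) == [0.1, 0.3, 0.6]
        assert sample.total_reads == 100

    def test_duplicate_keys_merged(self, tmp_path):
        path = _write_table(
            tmp_path,
            [
                "5\tTGTGCA\tCA\tTRBV1\t\tTRBJ1",
                "15\tTGTGCA\tCA\tTRBV1\t\tTRBJ1",
            ],
        )
        sample = read_clonotype_table(path, make_meta())
        assert sample.n_clonotypes == 1
        assert sample.clonotypes[0].count == 20

    def test_stated_frequency_column_is_advisory(self, tmp_path):
        # a cloneFraction column summing to 0.97 is ignored; output resums to 1
        header = "cloneCount\tcloneFraction\tnSeqCDR3\taaSeqCDR3\tbestVGene\tbestDGene\tbestJGene"
        path = _write_table(
            tmp_path,
            [
                "50\t0.47\tTGTGCA\tCA\tTRBV1\t\tTRBJ1",
                "50\t0.50\tTGTGCC\tCA\tTRBV1\t\tTRBJ1",
            ],
            header=header,
        )
        sample = read_clonotype_table(path, make_meta())
        assert sum(c.frequency for c in sample.clonotypes) == pytest.approx(1.0, abs=1e-12)

    def test_gene_scores_stripped(self, tmp_path):
        header = "cloneCount\tnSeqCDR3\taaSeqCDR3\tallVHitsWithScore\tbestDGene\tbestJGene"
        path = _write_table(
            tmp_path, ["7\tTGTGCA\tCA\tTRBV7-9*00(1290.2)\t\tTRBJ2-7*00(211)"], header=header
        )
        sample = read_clonotype_table(path, make_meta())
        assert sample.clonotypes[0].v_gene == "TRBV7-9"
        assert sample.clonotypes[0].j_gene == "TRBJ2-7"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write_table(
            tmp_path, ["1\tCA\tTRBV1\tTRBJ1"], header="cloneCount\taaSeqCDR3\tbestVGene\tbestJGene"
        )
        with pytest.raises(ClonotypeTableError, match="cdr3_nt"):
            read_clonotype_table(path, make_meta())

    def test_empty_table_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("cloneCount\tnSeqCDR3\taaSeqCDR3\tbestVGene\tbestDGene\tbestJGene\n")
        with pytest.raises(ClonotypeTableError):
            read_clonotype_table(path, make_meta())

    def test_roundtrip_identity_on_keys_and_counts(self, tmp_path):
        sample = make_sample([5, 9, 21, 3])
        path = write_clonotype_table(sample, tmp_path / "canonical.tsv")
        back = read_clonotype_table(path, sample.meta)
        assert back.count_by_key() == sample.count_by_key()


class TestFilterProductive:
    def test_stop_and_frameshift_markers_removed(self):
        sample = make_sample([1, 1, 1], aa_seqs=["CASSF", "CAS*F", "CA_SF"])
        kept = filter_productive(sample)
        assert [c.cdr3_aa for c in kept.clonotypes] == ["CASSF"]
        assert kept.clonotypes[0].frequency == 1.0

    def test_identity_when_all_productive(self, uniform_sample):
        kept = filter_productive(uniform_sample)
        assert kept.count_by_key() == uniform_sample.count_by_key()

    def test_planted_nonproductive_counted_by_independent_scan(self):
        rng = np.random.default_rng(11)
        n = 100
        aa = [f"CASS{'ACDEFGHIKL'[int(d)]}{i:03d}F" for i, d in enumerate(rng.integers(0, 10, n).astype(str))]
        planted = rng.choice(n, size=7, replace=False)
        for i in planted:
            aa[i] = aa[i][:3] + "*" + aa[i][4:]
        sample = make_sample([1] * n, aa_seqs=aa)
        expected = sum(1 for s in aa if "*" not in s and "_" not in s)  # independent scan
        assert expected == 93
        assert filter_productive(sample).n_clonotypes == expected

    def test_all_nonproductive_errors(self):
        sample = make_sample([1, 2], aa_seqs=["CA*F", "C_AF"])
        with pytest.raises(ValueError, match="non-productive"):
            filter_productive(sample)


class TestAssignPhenotypes:
    def _one(self, cd4_freqs, cd8_freqs):
        """Build single-clone samples sharing one key with given frequencies."""
        shared_aa, shared_nt = "CASSSHAREDF", "TGTAGTCATGCT"

        def build(freq, comp, tp):
            total = 100000
            shared = int(round(freq * total))
            return make_sample(
                [shared, total - shared],
                meta=make_meta(compartment=comp, timepoint=tp),
                aa_seqs=[shared_aa, f"CAAA{comp.value}{tp.value[:3]}F"],
                nt_seqs=[shared_nt, f"TGT{comp.value}{tp.value}"],
            )

        cd4 = [build(f, Compartment.CD4, tp) for f, tp in cd4_freqs]
        cd8 = [build(f, Compartment.CD8, tp) for f, tp in cd8_freqs]
        result = assign_phenotypes(cd4, cd8)
        return {a.key.cdr3_nt: a for a in result}[shared_nt]

    def test_doubling_assigns_cd4(self):
        a = self._one([(0.02, Timepoint.PRE_TX)], [(0.005, Timepoint.PRE_TX)])
        assert a.assigned is Phenotype.CD4

    def test_neither_doubles_dropped(self):
        a = self._one([(0.010, Timepoint.PRE_TX)], [(0.008, Timepoint.PRE_TX)])
        assert a.assigned is Phenotype.DROPPED

    def test_maximum_across_timepoints(self):
        a = self._one(
            [(0.003, Timepoint.PRE_TX)],
            [(0.001, Timepoint.PRE_TX), (0.006, Timepoint.POST_TX)],
        )
        assert a.assigned is Phenotype.CD8

    def test_exact_double_counts_as_doubling(self):
        a = self._one([(0.010, Timepoint.PRE_TX)], [(0.005, Timepoint.PRE_TX)])
        assert a.assigned is Phenotype.CD4

    def test_partition_of_key_union(self):
        rng = np.random.default_rng(5)
        cd4 = make_sample(rng.integers(1, 100, 50), meta=make_meta(compartment=Compartment.CD4))
        cd8_counts = rng.integers(1, 100, 50)
        # share 30 of the 50 keys
        cd8 = make_sample(
            cd8_counts,
            meta=make_meta(compartment=Compartment.CD8),
            nt_seqs=[cd4.clonotypes[i].cdr3_nt for i in range(30)]
            + [f"TGTCD8ONLY{i}" for i in range(20)],
            aa_seqs=[cd4.clonotypes[i].cdr3_aa for i in range(30)]
            + [f"CASSCDEIGHT{'ACDEFGHIKLMNPQRSTVWY'[i]}F" for i in range(20)],
        )
        result = assign_phenotypes([cd4], [cd8])
        union = {c.key for c in cd4.clonotypes} | {c.key for c in cd8.clonotypes}
        assert {a.key for a in result} == union
        assert len(result) == len(union)  # each key classified exactly once


class TestDownsample:
    def test_full_depth_is_identity(self, two_clone_sample):
        out = downsample(two_clone_sample, two_clone_sample.total_reads, seed=0)
        assert out.count_by_key() == two_clone_sample.count_by_key()

    def test_hypergeometric_expectation(self, two_clone_sample):
        # {A:9000, B:1000}, depth 1000: E[count A] = 900, Var from MVHG
        reps = 1000
        counts_a = np.array(
            [
                downsample(two_clone_sample, 1000, seed=s).count_by_key().get(
                    two_clone_sample.clonotypes[0].key, 0
                )
                for s in range(reps)
            ]
        )
        n, k, d = 10000, 9000, 1000
        var = d * (k / n) * (1 - k / n) * (n - d) / (n - 1)
        se = np.sqrt(var / reps)
        assert abs(counts_a.mean() - 900) < 3 * se

    def test_same_seed_reproducible(self, two_clone_sample):
        a = downsample(two_clone_sample, 500, seed=42)
        b = downsample(two_clone_sample, 500, seed=42)
        assert a.count_by_key() == b.count_by_key()

    def test_depth_conserved_and_frequencies_normalized(self, uniform_sample):
        out = downsample(uniform_sample, 37, seed=3)
        assert out.total_reads == 37
        assert abs(sum(c.frequency for c in out.clonotypes) - 1.0) < 1e-9

    @pytest.mark.parametrize("depth", [0, 10001])
    def test_invalid_depth_errors(self, two_clone_sample, depth):
        with pytest.raises(ValueError):
            downsample(two_clone_sample, depth, seed=0)


class TestDownsampledMeanStatistic:
    def test_total_reads_conserved_exactly(self, two_clone_sample):
        mean, sd = downsampled_mean_statistic(
            two_clone_sample, 1000, lambda s: s.total_reads, n_reps=20, seed=0
        )
        assert mean == 1000 and sd == 0

    def test_frequency_expectation_preserved(self, two_clone_sample):
        key = two_clone_sample.clonotypes[0].key
        mean, sd = downsampled_mean_statistic(
            two_clone_sample,
            1000,
            lambda s: s.freq_by_key().get(key, 0.0),
            n_reps=400,
            seed=1,
        )
        assert abs(mean - 0.9) < 3 * sd / np.sqrt(400)

    def test_single_rep_matches_single_downsample(self, two_clone_sample):
        key = two_clone_sample.clonotypes[1].key
        mean, _ = downsampled_mean_statistic(
            two_clone_sample, 800, lambda s: s.freq_by_key().get(key, 0.0), n_reps=1, seed=9
        )
        direct = downsample(two_clone_sample, 800, seed=9).freq_by_key().get(key, 0.0)
        assert mean == direct


class TestMergeSamples:
    def test_shared_keys_summed(self):
        a = make_sample([10, 20])
        b = make_sample([5, 5])  # same default keys
        merged = merge_samples([a, b])
        assert merged.total_reads == 40
        assert sorted(merged.count_by_key().values()) == [15, 25]
        assert merged.meta.compartment is Compartment.BULK
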