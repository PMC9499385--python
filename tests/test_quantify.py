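"""Assignment, isomiR classification, counting and the count-level filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from plasmir.errors import InputError
from plasmir.quantify import (
    CountMatrix,
    assign_read,
    classify_isomir,
    count_samples,
    cpm,
    expression_filter,
    filter_noisy,
    isoform_filter,
    sample_qc_gate,
)
from plasmir.reference import MatureRecord, MiRNAReference
from plasmir.synthdata import CohortConfig, generate_cohort, generate_reference


def oracle_assign(read, reference, max_shift=3, max_mismatch=2):
    """Exhaustive enumeration of every gapless placement, written as plain
    loops with no shared code with the aligner."""
    best = None
    for rec in reference.matures:
        hp = reference.hairpins[rec.hairpin_id]
        M = rec.end - rec.start
        for o5 in range(-max_shift, max_shift + 1):
            o3 = len(read) - M + o5
            if abs(o3) > max_shift:
                continue
            s = rec.start + o5
            internal = 0
            for k, ch in enumerate(read):
                p = s + k
                if rec.start <= p < rec.end and hp[p] != ch:
                    internal += 1
            if internal > max_mismatch:
                continue
            key = (internal, abs(o5) + abs(o3), rec.name)
            if best is None or key < best[0]:
                best = (key, rec.name, o5, o3, internal)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


class TestAssignRead:
    def test_identity_read(self, toy_reference):
        asg = assign_read("ACGTACGTACGTACGTAC", toy_reference)
        assert (asg.mirna, asg.offset5, asg.offset3, asg.n_internal_mismatches) == ("mirA", 0, 0, 0)

    def test_unalignable_read(self, toy_reference):
        assert assign_read("T" * 20, toy_reference) is None

    def test_bad_alphabet(self, toy_reference):
        with pytest.raises(InputError):
            assign_read("ACGUACGUACGUACGUAC", toy_reference)

    def test_tie_broken_by_lexicographic_name(self):
        # twin matures with identical sequence in different hairpins
        seq = "ACGTTGCAACGTTGCAAC"
        hp = "GGGGG" + seq + "CCCCC"
        matures = [
            MatureRecord(name="mirZ", sequence=seq, hairpin_id="h1", start=5, end=23),
            MatureRecord(name="mirA", sequence=seq, hairpin_id="h2", start=5, end=23),
        ]
        ref = MiRNAReference(matures=matures, hairpins={"h1": hp, "h2": hp})
        asg = assign_read(seq, ref)
        assert asg.mirna == "mirA"
        assert oracle_assign(seq, ref)[0] == "mirA"

    def test_matches_exhaustive_oracle_on_randomized_reads(self):
        """1000 randomized reads against a 5-hairpin reference: the aligner
        agrees with brute-force enumeration on name, offsets, mismatches."""
        ref = generate_reference(5, seed=21)
        rng = np.random.default_rng(22)
        reads = []
        seqs = {m.name: m for m in ref.matures}
        names = list(seqs)
        for _ in range(1000):
            roll = rng.random()
            m = seqs[names[rng.integers(len(names))]]
            hp = ref.hairpins[m.hairpin_id]
            if roll < 0.25:  # exact hairpin window
                o5 = int(rng.integers(-3, 4))
                o3 = int(rng.integers(-3, 4))
                s, e = m.start + o5, m.end + o3
                if s < 0 or e > len(hp) or e - s < 16 or e - s > 28:
                    continue
                read = hp[s:e]
            elif roll < 0.6:  # mutated mature
                read = list(m.sequence)
                for _ in range(int(rng.integers(1, 4))):
                    pos = int(rng.integers(len(read)))
                    read[pos] = "ACGT"[rng.integers(4)]
                read = "".join(read)
            elif roll < 0.8:  # mature + random tail
                read = m.sequence + "".join("ACGT"[i] for i in rng.integers(0, 4, size=2))
                read = read[:28]
            else:  # random
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(16, 29))))
            got = assign_read(read, ref)
            want = oracle_assign(read, ref)
            if want is None:
                assert got is None, read
            else:
                assert got is not None, read
                assert (got.mirna, got.offset5, got.offset3, got.n_internal_mismatches) == want, read


class TestClassifyIsomir:
    def classify(self, read, ref):
        asg = assign_read(read, ref)
        assert asg is not None
        return classify_isomir(asg, ref)

    def test_canonical(self, toy_reference):
        ann = self.classify("ACGTACGTACGTACGTAC", toy_reference)
        assert ann.class_labels == {"canonical"}
        assert ann.internal_mismatches == ()

    def test_trim3_by_one(self, toy_reference):
        ann = self.classify("ACGTACGTACGTACGTA", toy_reference)
        assert ann.class_labels == {"trim3"}
        assert ann.offset3 == -1

    def test_ext3_templated_vs_nontemplated(self, toy_reference):
        # hairpin hpA continues with T after the mature end
        templated = self.classify("ACGTACGTACGTACGTAC" + "T", toy_reference)
        assert templated.class_labels == {"ext3_templated"}
        nontemplated = self.classify("ACGTACGTACGTACGTAC" + "A", toy_reference)
        assert nontemplated.class_labels == {"ext3_nontemplated"}

    def test_ext5_templated_vs_nontemplated(self, toy_reference):
        # hairpin hpA has G before the mature start
        assert self.classify("G" + "ACGTACGTACGTACGTAC", toy_reference).class_labels == {"ext5_templated"}
        assert self.classify("T" + "ACGTACGTACGTACGTAC", toy_reference).class_labels == {"ext5_nontemplated"}

    def test_polymorphic_records_mismatch(self, toy_reference):
        ann = self.classify("ACGTACGTTCGTACGTAC", toy_reference)
        assert ann.class_labels == {"polymorphic"}
        assert ann.internal_mismatches == ((8, "A", "T"),)

    def test_every_assigned_read_gets_a_label(self):
        """Classifier totality: over random assignable reads, >= 1 label and
        canonical is exclusive."""
        ref = generate_reference(5, seed=31)
        rng = np.random.default_rng(32)
        n_checked = 0
        for _ in range(300):
            m = ref.matures[rng.integers(len(ref.matures))]
            hp = ref.hairpins[m.hairpin_id]
            o5, o3 = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
            s, e = m.start + o5, m.end + o3
            if s < 0 or e > len(hp) or not 16 <= e - s <= 28:
                continue
            read = hp[s:e]
            asg = assign_read(read, ref)
            if asg is None:
                continue
            ann = classify_isomir(asg, ref)
            n_checked += 1
            assert len(ann.class_labels) >= 1
            if "canonical" in ann.class_labels:
                assert ann.class_labels == {"canonical"}
        assert n_checked > 100


class TestCountSamples:
    def test_three_reads_one_mirna(self, toy_reference):
        cm, iso = count_samples({"s1": ["ACGTACGTACGTACGTAC"] * 3}, toy_reference)
        assert cm.counts.loc["mirA", "s1"] == 3
        assert cm.counts["s1"].sum() == 3
        assert iso.loc[0, "labels"] == "canonical"

    def test_duplicate_sample_ids_rejected(self, toy_reference):
        with pytest.raises(InputError, match="duplicate"):
            count_samples([("s1", []), ("s1", [])], toy_reference)

    def test_column_sums_equal_assigned_totals(self, toy_reference):
        reads = {"s1": ["ACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG", "T" * 20]}
        cm, _ = count_samples(reads, toy_reference)
        assert cm.counts["s1"].sum() == 2
        assert cm.samples.loc["s1", "percent_mirna_reads"] == pytest.approx(200 / 3)

    def test_counts_within_multinomial_error_of_ground_truth(self, tmp_path):
        """Reads-route counts agree with ground-truth proportions by a
        chi-square goodness-of-fit test (p > 0.001)."""
        from plasmir.preprocess import _iter_fastq, preprocess_fastq

        cfg = CohortConfig(
            n_subjects=1,
            n_mirnas=35,
            library_depth_mean=20_000,
            mirna_fraction_mean=1.0,
            mirna_fraction_sd=0.0,
            dropout_rate=0.0,
            seed=41,
        )
        c = generate_cohort(cfg)
        paths = c.write_fastq(tmp_path)
        for sample in list(paths)[:2]:
            clean = tmp_path / f"{sample}.clean.fastq"
            preprocess_fastq(paths[sample], clean)
            reads = [seq for _, seq, _ in _iter_fastq(clean)]
            cm, _ = count_samples({sample: reads}, c.reference)
            obs = cm.counts[sample].to_numpy(float)
            exp = c.ground_truth.true_proportions[sample].to_numpy() * obs.sum()
            keep = exp > 5
            stat, p = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
            assert p > 0.001

    def test_isomir_class_fractions_recover_generation_rates(self, tmp_path):
        """Aggregated per-class fractions track the configured modification
        rates within Monte-Carlo error."""
        from plasmir.pipeline import _isomir_class_fractions
        from plasmir.preprocess import _iter_fastq, preprocess_fastq

        cfg = CohortConfig(
            n_subjects=1,
            groups=("ACD", "Citrate", "CTAD", "EDTA"),
            n_mirnas=40,
            library_depth_mean=15_000,
            mirna_fraction_mean=1.0,
            mirna_fraction_sd=0.0,
            dropout_rate=0.0,
            seed=43,
        )
        c = generate_cohort(cfg)
        paths = c.write_fastq(tmp_path)
        sample = "s01A"
        clean = tmp_path / "c.fastq"
        preprocess_fastq(paths[sample], clean)
        reads = [seq for _, seq, _ in _iter_fastq(clean)]
        cm, iso = count_samples({sample: reads}, c.reference)
        fr = _isomir_class_fractions(iso, [sample])
        rates = cfg.isomir_rates
        assert fr["canonical"] == pytest.approx(1 - sum(rates.as_probs()[1:]), abs=0.05)
        assert fr["trim3"] == pytest.approx(rates.trim3, abs=0.05)
        assert fr["ext3_templated"] > fr["ext3_nontemplated"]
        assert fr["polymorphic"] == pytest.approx(rates.snv, abs=0.04)


class TestFilters:
    def test_noisy_filter_boundary_rows(self):
        n = 20
        row_removed = [0] * 19 + [40]  # mean 2.0, zero in 95%
        row_kept_mean = [0] * 10 + [4] * 10  # mean 2.0, zero in 50%
        row_kept_abundant = [100] * n
        counts = pd.DataFrame(
            [row_removed, row_kept_mean, row_kept_abundant],
            index=["removed", "kept_mean", "kept_abundant"],
            columns=[f"s{j}" for j in range(n)],
        )
        cm = CountMatrix(counts=counts, samples=pd.DataFrame(index=counts.columns))
        out = filter_noisy(cm)
        assert list(out.counts.index) == ["kept_mean", "kept_abundant"]

    def test_noisy_filter_matches_brute_force(self, random_count_matrix):
        out = filter_noisy(random_count_matrix)
        expected = [
            m
            for m in random_count_matrix.counts.index
            if not (
                random_count_matrix.counts.loc[m].mean() <= 2
                and (random_count_matrix.counts.loc[m] == 0).mean() >= 0.9
            )
        ]
        assert list(out.counts.index) == expected

    def test_cpm_basics(self):
        counts = pd.DataFrame({"s1": [5, 999_995], "s2": [10, 999_990]}, index=["a", "b"])
        cm = CountMatrix(counts=counts, samples=pd.DataFrame(index=counts.columns))
        c = cpm(cm)
        assert c.loc["a", "s1"] == pytest.approx(5.0)
        assert np.allclose(c.sum(axis=0), 1e6)
        doubled = cpm(CountMatrix(counts=counts * 2, samples=pd.DataFrame(index=counts.columns)))
        pd.testing.assert_frame_equal(c, doubled)

    def test_cpm_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["a"])
        cm = CountMatrix(counts=counts, samples=pd.DataFrame(index=counts.columns))
        with pytest.raises(InputError, match="empty"):
            cpm(cm)

    def test_expression_filter_boundaries_and_oracle(self, random_count_matrix):
        n = 12
        c = pd.DataFrame(
            [[2.0] * n, [2.1] * 10 + [0.0] * (n - 10), [2.1] * 9 + [0.0] * (n - 9)],
            index=["at_threshold", "just_enough", "one_short"],
            columns=[f"s{j}" for j in range(n)],
        )
        assert expression_filter(c) == ["just_enough"]
        cpm_df = cpm(random_count_matrix)
        got = expression_filter(cpm_df, min_cpm=2, min_samples=5)
        want = [m for m in cpm_df.index if (cpm_df.loc[m] > 2).sum() >= 5]
        assert got == want

    def test_filters_order_stable_under_row_permutation(self, random_count_matrix):
        rng = np.random.default_rng(5)
        perm = rng.permutation(random_count_matrix.counts.index)
        permuted = CountMatrix(
            counts=random_count_matrix.counts.loc[perm], samples=random_count_matrix.samples
        )
        a = set(expression_filter(cpm(filter_noisy(random_count_matrix)), min_samples=5))
        b = set(expression_filter(cpm(filter_noisy(permuted)), min_samples=5))
        assert a == b

    def test_isoform_filter_rules(self):
        n = 12
        samples = [f"s{j}" for j in range(n)]
        iso = pd.DataFrame(
            [
                {"mirna": "mirA", "sequence": "AAA", "offset5": 0, "offset3": 0, "labels": "canonical",
                 **dict.fromkeys(samples, 10)},  # mean exactly 10 -> removed (strict)
                {"mirna": "mirA", "sequence": "AAB", "offset5": 0, "offset3": -1, "labels": "trim3",
                 **dict.fromkeys(samples, 11)},  # retained
                {"mirna": "mirB", "sequence": "CCC", "offset5": 0, "offset3": 0, "labels": "canonical",
                 **dict.fromkeys(samples, 500)},  # parent fails CPM gate below
            ]
        )
        cpm_df = pd.DataFrame(
            [[50.0] * n, [1.0] * n], index=["mirA", "mirB"], columns=samples
        )
        retained, major = isoform_filter(iso, cpm_df, min_samples=10)
        assert list(retained["sequence"]) == ["AAB"]
        assert "AAB" in set(major["sequence"])  # 11*12 of mirA pool 21*12 > 10%

    def test_isoform_filter_matches_brute_force(self):
        rng = np.random.default_rng(77)
        n = 15
        samples = [f"s{j}" for j in range(n)]
        mirnas = [f"m{i}" for i in range(8)]
        rows = []
        for i in range(60):
            rows.append(
                {"mirna": mirnas[rng.integers(8)], "sequence": f"seq{i}", "offset5": 0, "offset3": 0,
                 "labels": "canonical", **{s: int(rng.integers(0, 30)) for s in samples}}
            )
        iso = pd.DataFrame(rows)
        cpm_df = pd.DataFrame(rng.uniform(0, 10, size=(8, n)), index=mirnas, columns=samples)
        retained, _ = isoform_filter(iso, cpm_df, min_samples=5)
        parents = {m for m in mirnas if (cpm_df.loc[m] > 2).sum() >= 5}
        want = [
            r["sequence"]
            for _, r in iso.iterrows()
            if r["mirna"] in parents and np.mean([r[s] for s in samples]) > 10
        ]
        assert list(retained["sequence"]) == want

    def test_unknown_parent_mirna_raises(self):
        iso = pd.DataFrame([{"mirna": "ghost", "sequence": "AAA", "offset5": 0, "offset3": 0,
                             "labels": "canonical", "s0": 1}])
        cpm_df = pd.DataFrame([[1.0]], index=["real"], columns=["s0"])
        with pytest.raises(InputError, match="ghost"):
            isoform_filter(iso, cpm_df)


class TestSampleQC:
    def make_cm(self, pct, unaligned):
        counts = pd.DataFrame({f"s{i}": [10] for i in range(len(pct))}, index=["m"])
        meta = pd.DataFrame(
            {"percent_mirna_reads": pct, "unaligned_pct": unaligned}, index=counts.columns
        )
        return CountMatrix(counts=counts, samples=meta)

    def test_boundary_at_15_percent(self):
        cm = self.make_cm([15.0, 14.9], [0, 0])
        kept, log = sample_qc_gate(cm)
        assert list(kept.counts.columns) == ["s0"]
        assert log == [{"sample": "s1", "reason": "low_mirna_fraction", "value": 14.9, "excluded": True}]

    def test_high_unaligned_flagged_and_strictness(self):
        cm = self.make_cm([80.0, 80.0], [50.0, 50.1])
        kept_strict, log = sample_qc_gate(cm)
        assert list(kept_strict.counts.columns) == ["s0"]
        assert log[0]["reason"] == "high_unaligned"
        kept_lenient, log2 = sample_qc_gate(cm, strict=False)
        assert list(kept_lenient.counts.columns) == ["s0", "s1"]
        assert log2[0]["excluded"] is False

    def test_planted_degenerates_excluded_exactly(self):
        c = generate_cohort(CohortConfig(seed=3, degenerate_samples=("s03B", "s07C")))
        kept, log = sample_qc_gate(c.counts)
        excluded = {e["sample"] for e in log if e["excluded"]}
        assert excluded == {"s03B", "s07C"}
        assert set(kept.counts.columns) == set(c.counts.counts.columns) - excluded
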