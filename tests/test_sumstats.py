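"""Data model, I/O, QC, harmonization and clumping."""

import numpy as np
import pytest

from mrlink.exceptions import ConfigurationError, DomainError, InputError
from mrlink.simulate import TwoSampleSimConfig, ar1_ld, simulate_two_sample
from mrlink.sumstats import (LDMatrix, clump, f_statistic, harmonize,
                             kept_pairs, pairs_to_records, qc_filter,
                             read_sumstats, write_sumstats)

from conftest import make_record


class TestReadWrite:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\tP\tN\n"
                        "rs1\tA\tG\t0.1\t0.02\t5.7e-7\t1000\n"
                        "rs2\tT\tC\t-0.05\t0.05\t0.317\t1000\n")
        res = read_sumstats(path)
        assert len(res.records) == 2 and not res.rejects
        assert res.records[0].snp_id == "rs1"
        assert res.records[1].beta == -0.05

    def test_zero_se_rejected_with_reason(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\tP\n"
                        "rs1\tA\tG\t0.1\t0.0\t0.5\n"
                        "rs2\tT\tC\t0.1\t0.05\t0.0455\n")
        res = read_sumstats(path)
        assert len(res.records) == 1
        assert res.rejects == [(0, "nonpositive SE")]

    def test_column_map_and_missing_column(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("variant\tref\talt\tb\tstderr\tpv\n"
                        "rs1\tG\tA\t0.1\t0.05\t0.0455\n")
        res = read_sumstats(path, column_map={"SNP": "variant", "EA": "ref",
                                              "OA": "alt", "BETA": "b",
                                              "SE": "stderr", "P": "pv"})
        assert res.records[0].effect_allele == "G"
        with pytest.raises(ConfigurationError, match="missing mandatory"):
            read_sumstats(path)

    def test_zero_valid_rows_is_input_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\tP\nrs1\tA\tG\t0.1\t-1\t0.5\n")
        with pytest.raises(InputError):
            read_sumstats(path)

    def test_simulator_round_trip_identity(self, tmp_path):
        exp, _ = simulate_two_sample(TwoSampleSimConfig(k=40, theta=0.1, seed=3))
        path = tmp_path / "sim.tsv"
        write_sumstats(exp, path)
        back = read_sumstats(path)
        assert not back.rejects
        for orig, rec in zip(exp, back.records):
            assert orig == rec


class TestQC:
    def test_rules_and_order(self):
        recs = [
            make_record("rs1", ea="A", oa="T"),              # palindromic
            make_record("rs2", eaf=0.995),                   # MAF 0.005
            make_record("rs3", ea="AT", oa="A"),             # indel
            make_record("rs4"),
            make_record("rs4"),                              # duplicate
        ]
        kept, report = qc_filter(recs)
        assert [r.snp_id for r in kept] == ["rs4"]
        assert (report.n_indel, report.n_ambiguous, report.n_duplicate,
                report.n_low_maf) == (1, 1, 1, 1)
        assert report.n_retained == len(kept)
        assert report.n_removed == report.n_input - len(kept)

    def test_clean_simulated_panel_fully_retained(self):
        exp, _ = simulate_two_sample(TwoSampleSimConfig(k=100, seed=5))
        kept, report = qc_filter(exp)
        assert len(kept) == 100 and report.n_removed == 0

    def test_flags_disable_rules(self):
        recs = [make_record("rs1", ea="C", oa="G")]
        kept, _ = qc_filter(recs, drop_ambiguous=False)
        assert len(kept) == 1


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        ex = [make_record("rs1", ea="A", oa="G", beta=0.1)]
        oy = [make_record("rs1", ea="G", oa="A", beta=0.2, eaf=0.7)]
        (pair,) = harmonize(ex, oy)
        assert pair.action == "allele_flipped"
        assert pair.beta_y == pytest.approx(-0.2)
        assert pair.eaf_y == pytest.approx(0.3)

    def test_strand_flip_recognised(self):
        ex = [make_record("rs1", ea="A", oa="G", beta=0.1)]
        oy = [make_record("rs1", ea="T", oa="C", beta=0.2)]
        (pair,) = harmonize(ex, oy)
        assert pair.action == "kept" and pair.beta_y == pytest.approx(0.2)

    def test_palindromic_ambiguous_eaf_dropped(self):
        ex = [make_record("rs1", ea="A", oa="T", eaf=0.50)]
        oy = [make_record("rs1", ea="A", oa="T", eaf=0.30)]
        (pair,) = harmonize(ex, oy)
        assert pair.action == "dropped" and "EAF" in pair.reason

    def test_palindromic_inferred_when_eafs_agree(self):
        ex = [make_record("rs1", ea="A", oa="T", eaf=0.2)]
        oy = [make_record("rs1", ea="A", oa="T", eaf=0.25)]
        (pair,) = harmonize(ex, oy)
        assert pair.action == "palindromic_inferred"

    def test_palindromic_side_mismatch_dropped(self):
        ex = [make_record("rs1", ea="A", oa="T", eaf=0.2)]
        oy = [make_record("rs1", ea="A", oa="T", eaf=0.8)]
        (pair,) = harmonize(ex, oy)
        assert pair.action == "dropped"

    def test_incompatible_alleles_dropped_with_reason(self):
        ex = [make_record("rs1", ea="A", oa="C")]
        oy = [make_record("rs1", ea="A", oa="G")]
        (pair,) = harmonize(ex, oy)
        assert (pair.action, pair.reason) == ("dropped", "allele mismatch")

    def test_simulated_shared_coding_no_flips_no_drops(self):
        exp, out = simulate_two_sample(TwoSampleSimConfig(k=60, seed=9))
        pairs = harmonize(exp, out)
        assert len(pairs) == 60
        assert all(p.action == "kept" for p in pairs)

    def test_idempotence(self):
        exp, out = simulate_two_sample(TwoSampleSimConfig(k=30, seed=1))
        out[3] = make_record(out[3].snp_id, chrom=out[3].chrom,
                             pos=out[3].pos, ea=out[3].other_allele,
                             oa=out[3].effect_allele, eaf=0.4, beta=-0.02)
        first = kept_pairs(harmonize(exp, out))
        ex2 = pairs_to_records(first, "exposure")
        oy2 = pairs_to_records(first, "outcome")
        second = kept_pairs(harmonize(ex2, oy2))
        assert len(second) == len(first)
        for p1, p2 in zip(first, second):
            assert p2.action in ("kept", "palindromic_inferred")
            assert p2.beta_y == pytest.approx(p1.beta_y)
            assert p2.effect_allele == p1.effect_allele


class TestFStatistic:
    def test_examples(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_matches_squared_z_on_grid(self, rng):
        beta = rng.normal(size=200)
        se = rng.uniform(0.01, 1.0, size=200)
        assert np.allclose(f_statistic(beta, se), (beta / se) ** 2)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            f_statistic(0.1, 0.0)


class TestLDMatrix:
    def test_validation(self):
        with pytest.raises(InputError, match="symmetric"):
            LDMatrix(["a", "b"], [[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(InputError, match="diagonal"):
            LDMatrix(["a", "b"], [[0.9, 0.5], [0.5, 1.0]])
        ld = LDMatrix(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        assert ld.r2("a", "b") == pytest.approx(0.25)
        assert ld.r2("a", "zzz") is None

    def test_tsv_round_trip(self, tmp_path):
        ld = LDMatrix(["a", "b"], [[1.0, -0.3], [-0.3, 1.0]])
        ld.to_tsv(tmp_path / "ld.tsv")
        back = LDMatrix.from_tsv(tmp_path / "ld.tsv")
        assert back.snp_ids == ld.snp_ids
        assert np.allclose(back.r, ld.r)


def _ld_panel(n=50, rho=0.8, seed=0, spacing=10_000):
    """Dense same-chromosome panel with AR(1) LD, all within the window."""
    rng = np.random.default_rng(seed)
    ids = [f"rs{i}" for i in range(n)]
    recs = [make_record(ids[i], chrom="2", pos=1_000_000 + i * spacing,
                        beta=float(rng.normal(0, 0.05)), se=0.005)
            for i in range(n)]
    return recs, LDMatrix(ids, ar1_ld(n, rho))


class TestClump:
    def test_greedy_keeps_best_of_correlated_pair(self):
        recs = [make_record("rs1", chrom="1", pos=100, beta=0.2, se=0.02),
                make_record("rs2", chrom="1", pos=200, beta=0.19, se=0.02)]
        ld = LDMatrix(["rs1", "rs2"],
                      [[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        iset = clump(recs, ld, p_threshold=1e-8)
        assert iset.snp_ids == ["rs1"]

    def test_cross_chromosome_both_retained(self):
        recs = [make_record("rs1", chrom="1", pos=100, beta=0.2, se=0.02),
                make_record("rs2", chrom="2", pos=100, beta=0.19, se=0.02)]
        iset = clump(recs, ld=None, p_threshold=1e-8)
        assert sorted(iset.snp_ids) == ["rs1", "rs2"]

    def test_missing_in_window_entry_blocks(self):
        recs = [make_record("rs1", chrom="1", pos=100, beta=0.2, se=0.02),
                make_record("rs2", chrom="1", pos=200, beta=0.19, se=0.02)]
        ld = LDMatrix(["rs1"], [[1.0]])  # rs2 absent
        iset = clump(recs, ld, p_threshold=1e-8)
        assert iset.snp_ids == ["rs1"]

    def test_no_candidates_warns_not_raises(self):
        recs = [make_record("rs1", beta=0.01, se=0.05)]
        with pytest.warns(UserWarning, match="no SNP passes"):
            iset = clump(recs, None, p_threshold=5e-8)
        assert len(iset) == 0

    def test_greedy_validity_and_maximality_on_block_panel(self):
        recs, ld = _ld_panel()
        iset = clump(recs, ld, p_threshold=1e-4, r2_threshold=0.05)
        chosen = iset.snp_ids
        by_id = {r.snp_id: r for r in recs}
        # validity: pairwise r2 below threshold among retained
        for i, a in enumerate(chosen):
            for b in chosen[i + 1:]:
                assert ld.r2(a, b) < 0.05
        # greedy maximality: every excluded candidate conflicts with a
        # retained SNP of smaller p
        for r in recs:
            if r.snp_id in chosen or r.pval >= 1e-4:
                continue
            conflicts = [a for a in chosen
                         if by_id[a].pval <= r.pval
                         and ld.r2(r.snp_id, a) >= 0.05]
            assert conflicts, f"{r.snp_id} excluded without cause"

    def test_row_order_invariance(self, rng):
        recs, ld = _ld_panel(seed=4)
        iset1 = clump(recs, ld, p_threshold=1e-4, r2_threshold=0.05)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        iset2 = clump(shuffled, ld, p_threshold=1e-4, r2_threshold=0.05)
        assert iset1.snp_ids == iset2.snp_ids
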