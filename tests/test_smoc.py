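"""Seed extension, k-mer screening, repeat detection and copy counting."""

import numpy as np
import pytest

from silkforge._seq import cyclic_identity, revcomp, translate
from silkforge.genes import SpidroinGeneModel, generate_gene, make_contig_fixtures
from silkforge.reads import ReadSimConfig, simulate_long_reads, simulate_short_reads
from silkforge.smoc import (
    PWM,
    UnitConflictError,
    assemble_curated_gene,
    build_kmer_screen,
    curate_gene,
    detect_repeat_unit,
    estimate_iterations,
    extend_consensus,
    find_seeds,
    recruit_and_align,
)


# ----------------------------------------------------------------------
def brute_force_period(seq, min_period=1, threshold=0.9, min_window=12):
    """Independent exhaustive scan over every candidate period."""
    n = len(seq)
    for p in range(max(min_period, 1), n // 2 + 1):
        w = min(n, max(3 * p, min_window))
        if w < 2 * p:
            continue
        tail = seq[n - w:]
        pairs = list(zip(tail[p:], tail[:-p]))
        if pairs and sum(a == b for a, b in pairs) / len(pairs) >= threshold:
            return p
    return None


class TestKmerIndex:
    def test_indexed_position_count(self):
        read = "ACGT" * 40          # 160 nt
        idx = build_kmer_screen({"r1": read}, k=100)
        # 61 anchor positions per strand
        assert len(idx) == 2 * (160 - 100 + 1)

    def test_k_longer_than_read_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_kmer_screen({"r1": "ACGT" * 10}, k=100)

    def test_duplicate_reads_keep_multiplicity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        idx = build_kmer_screen({"a": seq, "b": seq}, k=40)
        assert len(idx.lookup(seq[:40])) == 2


class TestRecruitAndAlign:
    KMER = "ACCGGAGCCACAAGCGGAAC"  # 20 nt anchor

    def _reads(self, overhangs):
        return {f"r{i}": self.KMER + o for i, o in enumerate(overhangs)}

    def test_overhang_columns(self):
        reads = self._reads(["AAG", "AAG", "AAT"])
        idx = build_kmer_screen(reads, k=20)
        got = recruit_and_align(self.KMER, idx, reads)
        pwm = PWM.from_overhangs([o for _, o in got])
        assert pwm.counts[:, 2].tolist() == [0, 0, 2, 1]  # A,C,G,T at column 3

    def test_zero_overhang_read_recruited(self):
        reads = self._reads([""])
        idx = build_kmer_screen(reads, k=20)
        got = recruit_and_align(self.KMER, idx, reads)
        assert got == [("r0", "")]

    def test_absent_kmer_recruits_nothing(self):
        reads = self._reads(["AAG"])
        idx = build_kmer_screen(reads, k=20)
        assert recruit_and_align("G" * 20, idx, reads) == []

    def test_pwm_counts_conserve_support(self, rng):
        overhangs = ["".join(rng.choice(list("ACGT"), rng.integers(0, 30)))
                     for _ in range(25)]
        pwm = PWM.from_overhangs(overhangs)
        covering = np.array([sum(1 for o in overhangs if len(o) > j)
                             for j in range(pwm.n_cols)])
        assert (pwm.counts.sum(axis=0) == covering).all()
        assert len(pwm.consensus()) == pwm.n_cols


class TestExtendConsensus:
    def test_zero_error_extension_reaches_repeat_exactly(self, small_gene, clean_read_bundle):
        short, _ = clean_read_bundle
        idx = build_kmer_screen(short, k=100)
        state = extend_consensus(small_gene.ntd, idx, short)
        assert state.stop_reason == "repeat_detected"
        assert state.repeat is not None
        # every accepted base matches the true gene: identity 100%
        assert small_gene.cds.startswith(state.consensus)
        unit, period, _ = state.repeat
        assert period == len(small_gene.model.repeat_unit_nt)
        assert cyclic_identity(unit, small_gene.model.repeat_unit_nt) == 1.0

    def test_low_error_reads_give_same_consensus(self, small_gene, clean_read_bundle):
        short_clean, _ = clean_read_bundle
        idx_clean = build_kmer_screen(short_clean, k=100)
        clean = extend_consensus(small_gene.ntd, idx_clean, short_clean)
        cfg = ReadSimConfig(rng_seed=21, short_error_rate=0.001)
        r1, r2 = simulate_short_reads([(small_gene.gene_id, small_gene.cds)], cfg)
        noisy = {r.name: r.seq for r in r1 + r2}
        idx = build_kmer_screen(noisy, k=100)
        state = extend_consensus(small_gene.ntd, idx, noisy)
        assert state.consensus == clean.consensus

    def test_min_depth_above_coverage_stops_immediately(self, small_gene, clean_read_bundle):
        short, _ = clean_read_bundle
        idx = build_kmer_screen(short, k=100)
        state = extend_consensus(small_gene.ntd, idx, short, min_depth=10_000)
        assert state.stop_reason == "support_exhausted"
        assert state.consensus == small_gene.ntd

    def test_seed_shorter_than_k_rejected(self, clean_read_bundle):
        short, _ = clean_read_bundle
        idx = build_kmer_screen(short, k=100)
        with pytest.raises(ValueError, match="seed"):
            extend_consensus("ACGT", idx, short)


class TestDetectRepeatUnit:
    def test_trivial_triplet_period(self):
        unit, period, phase = detect_repeat_unit("ACGACGACGACG")
        assert (unit, period, phase) == ("ACG", 3, 9)

    def test_planted_unit_recovered(self, rng):
        prefix = "".join(rng.choice(list("ACGT"), 500))
        unit = "".join(rng.choice(list("ACGT"), 300))
        seq = prefix + unit * 4
        got = detect_repeat_unit(seq, min_period=30)
        assert got is not None
        assert got[1] == 300
        assert got[0] == unit
        assert brute_force_period(seq, min_period=30) == 300

    def test_aperiodic_sequence_none(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        got = detect_repeat_unit(seq, min_period=30)
        assert got == brute_force_period(seq, min_period=30) is None

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(60, 2000))
        seq = "".join(rng.choice(list("ACGT"), n))
        if trial % 2:  # plant a tandem tail on half the trials
            u = int(rng.integers(20, 200))
            unit = "".join(rng.choice(list("ACGT"), u))
            seq = seq[: n // 2] + unit * int(rng.integers(2, 5))
        got = detect_repeat_unit(seq, min_period=10)
        expect = brute_force_period(seq, min_period=10)
        assert (got[1] if got else None) == expect


class TestEstimateIterations:
    def test_error_free_spanning_read_counts_exactly(self):
        m = SpidroinGeneModel.from_family(
            "CrSp", species_seed=2, per_copy_divergence=0.0, species_divergence=0.0
        )
        g = generate_gene(m, seed=4)
        reads = {"span1": g.cds}
        est, span, cont, low = estimate_iterations(g.ntd, m.repeat_unit_nt, g.ctd, reads)
        assert (est, cont, low) == (11, True, False)
        assert span == ["span1"]

    def test_noisy_reads_within_one_copy(self):
        m = SpidroinGeneModel.from_family("MiSp", species_seed=3, unit_len=600,
                                          n_copies=12)
        g = generate_gene(m, seed=5)
        cfg = ReadSimConfig(rng_seed=6, long_error_rate=0.10, span_fraction=0.8)
        lr = simulate_long_reads([(g.gene_id, g.cds)], cfg)
        reads = {r.name: r.seq for r in lr}
        est, _, cont, low = estimate_iterations(g.ntd, m.repeat_unit_nt, g.ctd, reads)
        assert cont and not low
        assert abs(est - 12) <= 1

    def test_unrelated_reads_flag_low_confidence(self, small_gene, rng):
        other = "".join(rng.choice(list("ACGT"), 5000))
        est, span, cont, low = estimate_iterations(
            small_gene.ntd, small_gene.model.repeat_unit_nt, small_gene.ctd,
            {"noise": other},
        )
        assert not cont and low and span == []


class TestFindSeeds:
    def test_exact_ctd_found_at_true_interval(self, small_gene, gene_profiles):
        g = small_gene
        contigs = [("c1", g.cds)]
        hits = [h for h in find_seeds(contigs, gene_profiles) if h.category == "CTD"]
        assert hits
        s, e = g.domains["CTD"]
        assert hits[0].strand == "+"
        assert abs(hits[0].start - s) <= 15 and abs(hits[0].end - e) <= 15

    def test_reverse_complement_contig_flagged(self, small_gene, gene_profiles):
        hits = find_seeds([("c1", revcomp(small_gene.cds))], gene_profiles)
        cats = {h.category: h.strand for h in hits}
        assert cats.get("CTD") == "-"

    def test_random_contigs_rarely_hit(self, gene_profiles, rng):
        contigs = [(f"r{i}", "".join(rng.choice(list("ACGT"), 2000)))
                   for i in range(40)]
        hits = find_seeds(contigs, gene_profiles)
        assert len(hits) == 0

    def test_malformed_fasta_errors(self, gene_profiles):
        with pytest.raises(ValueError, match="nucleotide"):
            find_seeds([("bad", "MKVLAA")], gene_profiles)


class TestAssembleCuratedGene:
    def test_complete_record_has_no_partial_flags(self):
        cg = assemble_curated_gene(
            "g", "A" * 300, "C" * 300, "ACG" * 100, None, (7, ["r1"], True, False)
        )
        assert not cg.ntd_partial and not cg.ctd_partial
        assert cg.continuity_validated and cg.n_copies_estimate == 7

    def test_missing_ctd_flagged_partial(self):
        cg = assemble_curated_gene("g", "A" * 300, None, "ACG" * 100, None, None)
        assert cg.ctd_partial and not cg.ntd_partial
        assert cg.confidence == "partial span"

    def test_conflicting_units_raise_with_both_listed(self, rng):
        u1 = "".join(rng.choice(list("ACGT"), 120))
        u2 = "".join(rng.choice(list("ACGT"), 120))
        with pytest.raises(UnitConflictError) as exc:
            assemble_curated_gene("g", "A" * 300, "C" * 300, u1, u2, None)
        assert u1[:40] in str(exc.value) and u2[:40] in str(exc.value)


class TestCurateGene:
    def test_collapsed_contig_full_recovery(self, small_gene, clean_read_bundle, gene_profiles):
        g = small_gene
        short, long_reads = clean_read_bundle
        contigs = make_contig_fixtures([g], "repeat_collapse")
        cg = curate_gene(contigs, short, long_reads, gene_profiles,
                         gene_id=g.gene_id, family_label="MiSp")
        assert cyclic_identity(cg.repeat_unit_nt, g.model.repeat_unit_nt) == 1.0
        assert cg.n_copies_estimate == g.n_copies
        assert cg.continuity_validated
        # terminal boundaries are exact up to repeat-phase ambiguity (the
        # NTD/CTD edge bases may coincide with unit edge bases)
        assert g.cds.startswith(cg.ntd_nt)
        assert g.cds.endswith(cg.ctd_nt)
        assert abs(len(cg.ntd_nt) - len(g.ntd)) <= 6
        assert abs(len(cg.ctd_nt) - len(g.ctd)) <= 6
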