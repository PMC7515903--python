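"""Digestion rules, observability, emPAI and web-region quantification."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from silkforge.proteomics import (
    CARBAMIDOMETHYL,
    PROTON,
    WATER,
    digest,
    empai,
    match_observations,
    observable_filter,
    observable_set,
    region_report,
)
from silkforge.webproteome import (
    DEFAULT_ABUNDANCES,
    PeptideObservationModel,
    simulate_peptide_observations,
)


# ----------------------------------------------------------------------
def brute_force_peptides(protein, max_missed):
    """Independent enumeration: every substring bounded by cleavage sites."""
    # the regex matches at the position just after K/R unless it is a P
    sites = [0] + [m.start() for m in re.finditer("(?<=[KR])(?!P)", protein)
                   if 0 < m.start() < len(protein)] + [len(protein)]
    out = set()
    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(sites))):
            out.add(protein[sites[i]: sites[j]])
    return out


class TestDigest:
    def test_rp_blocks_cleavage(self):
        peps = {p.sequence for p in digest("AKGRPGLK", max_missed=0)}
        assert peps == {"AK", "GRPGLK"}
        with_missed = {p.sequence for p in digest("AKGRPGLK", max_missed=1)}
        assert with_missed == {"AK", "GRPGLK", "AKGRPGLK"}

    def test_no_sites_returns_whole_protein(self):
        peps = digest("GASGASGAS")
        assert [p.sequence for p in peps] == ["GASGASGAS"]

    def test_lysine_run_distinct_peptides(self):
        assert {p.sequence for p in digest("KKK", max_missed=2)} == {"K", "KK", "KKK"}

    def test_missed_cleavage_counts_recorded(self):
        by_seq = {p.sequence: p.missed_cleavages for p in digest("AKGKGLR")}
        assert by_seq["AK"] == 0 and by_seq["AKGK"] == 1 and by_seq["AKGKGLR"] == 2

    def test_nonstandard_residue_flagged_without_mass(self):
        (pep,) = [p for p in digest("GAXGA") if "X" in p.sequence]
        assert pep.nonstandard and pep.mass is None

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), rng.integers(20, 300)))
        got = {p.sequence for p in digest(protein, max_missed=2)}
        assert got == brute_force_peptides(protein, 2)

    def test_matches_pyteomics_cleave(self):
        from pyteomics import parser

        rng = np.random.default_rng(9)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        expect = parser.cleave(protein, parser.expasy_rules["trypsin"], missed_cleavages=2)
        assert {p.sequence for p in digest(protein, max_missed=2)} == set(expect)


class TestMasses:
    def test_mass_formula_with_cys_modification(self):
        (pep,) = digest("GCK", max_missed=0)
        # G 57.02146 + C 103.00919 + K 128.09496 + water + carbamidomethyl
        expect = 57.02146 + 103.00919 + 128.09496 + WATER + CARBAMIDOMETHYL
        assert pep.mass == pytest.approx(expect, abs=1e-3)

    def test_mz_charge_relation(self):
        (pep,) = digest("GASGASGASK", max_missed=0)
        m = pep.mass
        for z in (1, 2, 3):
            assert pep.mz(z) == pytest.approx((m + z * PROTON) / z)


class TestObservableFilter:
    def test_kilodalton_peptide_observable_at_z2(self):
        # mass ~1000 Da -> m/z ~501 at z=2, inside the 400-1500 scan range
        peps = digest("GASGASGASK", max_missed=0)   # 792.37 Da
        assert peps[0].mz(2) < 400 < 1500
        big = digest("LLLLLLLLK", max_missed=0)     # 1038.77 Da
        assert observable_filter(big) == {"LLLLLLLLK"}

    def test_tiny_dipeptide_never_observable(self):
        peps = digest("GG", max_missed=0)
        assert peps[0].mass == pytest.approx(132.05, abs=0.01)
        assert observable_filter(peps) == set()

    def test_empty_list(self):
        assert observable_filter([]) == set()

    def test_z1_excluded_by_default_but_configurable(self):
        peps = digest("GASGAK", max_missed=0)       # ~503.3 Da; z=1 ~504, z=2 ~253
        assert observable_filter(peps) == set()
        assert observable_filter(peps, charges=(1, 2, 3)) == {"GASGAK"}


class TestEmpai:
    def test_bounds_and_examples(self):
        assert empai(0, 10) == 0.0
        assert empai(10, 10) == pytest.approx(9.0)
        assert empai(5, 10) == pytest.approx(10 ** 0.5 - 1, abs=1e-9)

    def test_zero_observable_errors(self):
        with pytest.raises(ValueError):
            empai(0, 0)
        with pytest.raises(ValueError):
            empai(5, 3)

    @given(st.integers(1, 50))
    @settings(max_examples=25, deadline=None)
    def test_strictly_increasing_in_observed(self, n_observable):
        values = [empai(k, n_observable) for k in range(n_observable + 1)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert 0.0 <= values[0] and values[-1] <= 9.0 + 1e-12


class TestMatchObservations:
    PROTEINS = {
        "CrSp": "ASSAALLTTKGGQLVNNNKLLPQRTTSSAAK" * 3,
        "MaSp": "GGAGGQLAAAAKGGLGGQKAAGGAGQGGYGGLGSQGK",
    }

    def test_unique_peptide_increments_one_protein(self):
        crsp_obs = sorted(observable_set(self.PROTEINS["CrSp"]))
        pep = crsp_obs[0]
        obs = pd.DataFrame([{"region": "whole_web", "peptide": pep}])
        records, unmatched = match_observations(obs, self.PROTEINS)
        by_id = {r.protein_id: r for r in records}
        assert by_id["CrSp"].n_observed == 1
        assert by_id["MaSp"].n_observed == 0
        assert unmatched.empty

    def test_unknown_peptide_reported_unmatched(self):
        obs = pd.DataFrame([{"region": "whole_web", "peptide": "WWWWWWWWWK"}])
        records, unmatched = match_observations(obs, self.PROTEINS)
        assert list(unmatched.peptide) == ["WWWWWWWWWK"]
        assert all(r.n_observed == 0 for r in records)

    def test_repeat_peptide_counted_once(self):
        # the CrSp sequence repeats its unit 3x: its observable set, and so
        # any emPAI built on it, is invariant to the copy number
        single = observable_set("ASSAALLTTKGGQLVNNNKLLPQRTTSSAAK")
        triple = observable_set(self.PROTEINS["CrSp"])
        shared = single & triple
        assert shared
        obs = pd.DataFrame([{"region": "w", "peptide": p} for p in shared])
        records, _ = match_observations(obs, {"CrSp": self.PROTEINS["CrSp"]})
        (rec,) = [r for r in records if r.protein_id == "CrSp"]
        assert rec.n_observed == len(shared)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            match_observations(pd.DataFrame({"region": []}), self.PROTEINS)


class TestRegionReport:
    def _records(self, proteins, model):
        obs = simulate_peptide_observations(proteins, model)
        db = {pid: seq for pid, (_fam, seq) in proteins.items()}
        records, _ = match_observations(obs[["region", "peptide"]], db)
        return records

    def _proteins(self):
        from silkforge.genes import SpidroinGeneModel, generate_gene
        from silkforge._seq import translate

        out = {}
        for fam in ("MaSp", "MiSp", "CrSp", "Pflag", "AcSp"):
            m = SpidroinGeneModel.from_family(fam, species_seed=4)
            out[fam] = (fam, generate_gene(m, seed=4).protein)
        return out

    def test_acsp_tops_stabilimentum(self):
        records = self._records(self._proteins(), PeptideObservationModel(rng_seed=11))
        report = region_report(records)
        assert report["ranks"].loc["AcSp", "stabilimentum"] == 1.0

    def test_zero_abundance_zero_peptides(self):
        model = PeptideObservationModel(rng_seed=1)
        obs = simulate_peptide_observations(self._proteins(), model)
        assert not (obs[obs.region == "whole_web"].protein == "Flag").any()

    def test_equal_abundances_give_symmetric_regions(self):
        flat = {r: {"MaSp": 5.0} for r in DEFAULT_ABUNDANCES}
        model = PeptideObservationModel(abundances=flat, rng_seed=2, p_max=1.0,
                                        half_saturation=0.0)
        proteins = {k: v for k, v in self._proteins().items() if k == "MaSp"}
        records = self._records(proteins, model)
        report = region_report(records)
        assert report["ratios"].ratio.dropna().between(0.99, 1.01).all()

    def test_region_without_observations_scores_zero(self):
        ab = {r: dict(v) for r, v in DEFAULT_ABUNDANCES.items()}
        ab["stabilimentum"] = {}
        records = self._records(self._proteins(),
                                PeptideObservationModel(abundances=ab, rng_seed=3))
        report = region_report(records)
        assert "stabilimentum" not in report["empai"].columns


class TestObservationSimulator:
    def test_detection_probability_monotone_and_bounded(self):
        model = PeptideObservationModel()
        probs = [model.detection_probability(a) for a in np.linspace(0, 50, 40)]
        assert all(0 <= p <= 1 for p in probs)
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_detection_prob_one_emits_full_observable_set(self):
        from silkforge.genes import SpidroinGeneModel, generate_gene

        m = SpidroinGeneModel.from_family("MaSp", species_seed=8)
        prot = generate_gene(m, seed=8).protein
        model = PeptideObservationModel(
            abundances={"whole_web": {"MaSp": 100.0}}, p_max=1.0,
            half_saturation=0.0, rng_seed=5,
        )
        obs = simulate_peptide_observations({"g": ("MaSp", prot)}, model)
        assert set(obs.peptide) == observable_set(prot)

    def test_enriched_protein_observed_more_where_enriched(self):
        from silkforge.genes import SpidroinGeneModel, generate_gene

        m = SpidroinGeneModel.from_family("AcSp", species_seed=9)
        prot = generate_gene(m, seed=9).protein
        ab = {"stabilimentum": {"AcSp": 10.0}, "radius_spiral": {"AcSp": 1.0}}
        counts = {"stabilimentum": 0, "radius_spiral": 0}
        for seed in range(10):
            model = PeptideObservationModel(abundances=ab, rng_seed=seed)
            obs = simulate_peptide_observations({"g": ("AcSp", prot)}, model)
            for region in counts:
                counts[region] += (obs.region == region).sum()
        assert counts["stabilimentum"] > counts["radius_spiral"]

    def test_emitted_peptides_subset_of_observable(self):
        from silkforge.genes import SpidroinGeneModel, generate_gene

        m = SpidroinGeneModel.from_family("MiSp", species_seed=10)
        prot = generate_gene(m, seed=10).protein
        model = PeptideObservationModel(rng_seed=6)
        obs = simulate_peptide_observations({"g": ("MiSp", prot)}, model)
        assert set(obs.peptide) <= observable_set(prot)
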