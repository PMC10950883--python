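"""Simulator: determinism, digestion rules, site assignment, capture, spectra."""

import numpy as np
import pytest

from nitroscope.catalog import build_catalog, overlap_summary, union_catalog
from nitroscope.masses import InputError, Peptidoform
from nitroscope.similarity import compare_spectra
from nitroscope.simulate import (
    AntibodyConfig,
    SimulationConfig,
    assign_nitration_sites,
    digest_trypsin,
    generate_proteome,
    generate_validation_set,
    nitropeptide_candidates,
    simulate_capture,
    simulate_spectrum,
    simulate_spectrum_pair,
)


class TestDeterminism:
    def test_proteome_is_seed_reproducible(self, small_cfg):
        f1 = generate_proteome(small_cfg, small_cfg.rng(0))
        f2 = generate_proteome(small_cfg, small_cfg.rng(0))
        assert f1 == f2

    def test_spectra_are_seed_reproducible(self, small_cfg):
        p = Peptidoform("LLYNNVSNFGR", ((3, "nitroY"),), charge=2)
        s1 = simulate_spectrum(p, small_cfg, np.random.default_rng(5), noisy=True)
        s2 = simulate_spectrum(p, small_cfg, np.random.default_rng(5), noisy=True)
        np.testing.assert_array_equal(s1.mz, s2.mz)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_validation_set_reproducible(self, small_cfg):
        v1 = generate_validation_set(small_cfg, 20)
        v2 = generate_validation_set(small_cfg, 20)
        assert v1.pairs.equals(v2.pairs)
        np.testing.assert_array_equal(v1.experimental[0].mz, v2.experimental[0].mz)


class TestProteome:
    def test_entry_count(self, small_cfg):
        assert len(generate_proteome(small_cfg, small_cfg.rng(0))) == 60

    def test_residue_frequencies_recovered(self):
        cfg = SimulationConfig(seed=2, n_proteins=300, protein_length_mean=400)
        fasta = generate_proteome(cfg, cfg.rng(0))
        joined = "".join(fasta.values())
        total = len(joined)
        probs = {aa: v for aa, v in cfg.background.items()}
        norm = sum(probs.values())
        for aa, w in probs.items():
            expected = w / norm
            observed = joined.count(aa) / total
            se = (expected * (1 - expected) / total) ** 0.5
            assert abs(observed - expected) < 5 * se


class TestDigestion:
    @pytest.mark.parametrize(
        "sequence,kwargs,expected",
        [
            (
                "MKAYRGGKR",
                dict(missed_cleavage_max=0, length_bounds=(1, 30)),
                [("MK", 1), ("AYR", 3), ("GGK", 6), ("R", 9)],
            ),
            (
                "AKPGR",
                dict(missed_cleavage_max=0, length_bounds=(1, 30)),
                [("AKPGR", 1)],  # no cleavage after K before P
            ),
            (
                "AKPGR",
                dict(missed_cleavage_max=0, length_bounds=(1, 30), proline_rule=False),
                [("AK", 1), ("PGR", 3)],
            ),
            (
                "GGAGGA",
                dict(missed_cleavage_max=2, length_bounds=(1, 30)),
                [("GGAGGA", 1)],  # no K/R: one peptide spanning the protein
            ),
        ],
    )
    def test_cleavage_rules(self, sequence, kwargs, expected):
        assert digest_trypsin(sequence, **kwargs) == expected

    def test_missed_cleavages_enumerated(self):
        products = digest_trypsin("MKAYRGGKR", missed_cleavage_max=2,
                                  length_bounds=(1, 30))
        peptides = {p for p, _ in products}
        assert {"MK", "MKAYR", "MKAYRGGK", "AYR", "AYRGGK", "AYRGGKR",
                "GGK", "GGKR", "R"} == peptides

    def test_agrees_with_pyteomics_cleave(self, rng):
        """Independent digestion oracle on sequences without the rare
        W/M-before-KP exceptions of the full expasy rule."""
        parser = pytest.importorskip("pyteomics.parser")
        aas = list("ACDEFGHILNQSTVY")  # no K/R/P/W/M: cut sites added manually
        for _ in range(20):
            parts = ["".join(rng.choice(aas, rng.integers(1, 6))) for _ in range(5)]
            seq = parts[0]
            for part in parts[1:]:
                seq += ("K" if rng.random() < 0.5 else "R") + part
            mine = {p for p, _ in digest_trypsin(seq, 2, (1, 100))}
            theirs = parser.cleave(seq, "trypsin", missed_cleavages=2)
            assert mine == set(theirs)


class TestNitration:
    def test_zero_base_rate_yields_no_sites(self, small_cfg):
        cfg = SimulationConfig(seed=13, n_proteins=60, nitration_base_rate=0.0)
        fasta = generate_proteome(cfg, cfg.rng(0))
        assert assign_nitration_sites(fasta, cfg, cfg.rng(1)) == {}

    def test_all_sites_are_tyrosines(self, small_cfg):
        fasta = generate_proteome(small_cfg, small_cfg.rng(0))
        sites = assign_nitration_sites(fasta, small_cfg, small_cfg.rng(1))
        for acc, positions in sites.items():
            for pos in positions:
                assert fasta[acc][pos - 1] == "Y"

    def test_context_bonus_enriches_flanking_context(self):
        cfg = SimulationConfig(seed=21, n_proteins=400, nitration_context_bonus=25.0,
                               nitration_base_rate=0.01)
        fasta = generate_proteome(cfg, cfg.rng(0))
        sites = assign_nitration_sites(fasta, cfg, cfg.rng(1))
        ctx = set(cfg.context_residues)

        def has_context(seq, pos):
            i = pos - 1
            window = seq[max(0, i - 2) : i] + seq[i + 1 : i + 3]
            return any(c in ctx for c in window)

        nitrated = [has_context(fasta[a], p) for a, ps in sites.items() for p in ps]
        all_y = [
            has_context(seq, i + 1)
            for seq in fasta.values()
            for i, r in enumerate(seq)
            if r == "Y"
        ]
        assert np.mean(nitrated) > np.mean(all_y)


class TestCapture:
    def test_unknown_mode_rejected(self, small_cfg):
        with pytest.raises(InputError):
            simulate_capture([], small_cfg, "both", small_cfg.rng(0))

    def test_full_capture_makes_four_way_intersection_equal_union(self):
        cfg = SimulationConfig(
            seed=8,
            n_proteins=80,
            antibodies=tuple(
                AntibodyConfig(f"AB{i}", capture_probability=1.0) for i in range(1, 5)
            ),
        )
        fasta = generate_proteome(cfg, cfg.rng(0))
        sites = assign_nitration_sites(fasta, cfg, cfg.rng(1))
        cands = nitropeptide_candidates(fasta, sites, cfg)
        psms = simulate_capture(cands, cfg, "protein_level", cfg.rng(2))
        records, _ = build_catalog(psms, fasta)
        ov = overlap_summary(records, unit="protein")
        assert ov.intersection_counts[frozenset(ov.antibodies)] == ov.union_count

    def test_every_psm_traces_to_a_planted_site(self, small_cfg):
        fasta = generate_proteome(small_cfg, small_cfg.rng(0))
        sites = assign_nitration_sites(fasta, small_cfg, small_cfg.rng(1))
        cands = nitropeptide_candidates(fasta, sites, small_cfg)
        for mode in ("protein_level", "peptide_level"):
            for psm in simulate_capture(cands, small_cfg, mode, small_cfg.rng(3)):
                site = psm.peptide_start + psm.peptidoform.nitro_positions[0] - 1
                assert site in sites[psm.protein_accession]

    def test_protein_mode_has_no_positional_bias(self):
        from nitroscope.catalog import n_terminal_fraction

        cfg = SimulationConfig(seed=17, n_proteins=400)
        fasta = generate_proteome(cfg, cfg.rng(0))
        sites = assign_nitration_sites(fasta, cfg, cfg.rng(1))
        cands = nitropeptide_candidates(fasta, sites, cfg)
        baseline = sum(1 for k in {c.key for c in cands} if k[1] == 1) / len(
            {c.key for c in cands}
        )
        psms = simulate_capture(cands, cfg, "protein_level", cfg.rng(2))
        records, _ = build_catalog(psms, fasta)
        table = n_terminal_fraction(records)
        for frac in table["fraction"]:
            assert frac == pytest.approx(baseline, abs=0.05)


class TestSpectra:
    def test_zero_noise_twin_scores_near_one(self):
        cfg = SimulationConfig(seed=3, peak_dropout_probability=0.0, mz_jitter_sd=0.0,
                               intensity_noise_cv=0.0, n_contaminant_peaks=0)
        p = Peptidoform("VFSWGFGGYGR", ((9, "nitroY"),), charge=2)
        exp, syn = simulate_spectrum_pair(p, cfg, np.random.default_rng(1))
        assert compare_spectra(exp, syn).score >= 0.99

    def test_heavy_noise_destroys_similarity(self):
        """Dropout 0.9 plus 50 contaminant peaks should break the match for
        the overwhelming majority of draws."""
        cfg = SimulationConfig(seed=3, peak_dropout_probability=0.9,
                               n_contaminant_peaks=50)
        p = Peptidoform("LLYNNVSNFGR", ((3, "nitroY"),), charge=2)
        rng = np.random.default_rng(77)
        low = sum(
            compare_spectra(*simulate_spectrum_pair(p, cfg, rng)).score < 0.5
            for _ in range(200)
        )
        # matched survivors share their intensity draw, so a small tail of
        # draws keeps moderate scores even at 90% dropout
        assert low >= 180

    def test_charge_two_fragments_only_above_mass_floor(self, small_cfg):
        from nitroscope.masses import PROTON_MASS, fragment_series

        p = Peptidoform("LLYNNVSNFGRAK", ((3, "nitroY"),), charge=2)
        s = simulate_spectrum(p, small_cfg, np.random.default_rng(0), noisy=False)
        expected = set()
        for ion in fragment_series(p, max_fragment_charge=2):
            neutral = ion.mz * ion.charge - ion.charge * PROTON_MASS
            if ion.charge == 1 or neutral >= small_cfg.charge2_fragment_mass_min:
                expected.add(round(ion.mz, 9))
        assert {round(m, 9) for m in s.mz} == expected


class TestValidationSet:
    def test_decoy_count_is_exact(self, small_cfg):
        vset = generate_validation_set(small_cfg, 100)
        assert int(vset.pairs["is_decoy"].sum()) == 30
        assert len(vset.pairs) == 100

    def test_too_many_pairs_requested_is_error(self, small_cfg):
        with pytest.raises(InputError):
            generate_validation_set(small_cfg, 10**6)

    def test_true_pairs_score_high_decoys_low(self, small_cfg):
        vset = generate_validation_set(small_cfg, 60)
        scores = np.array(
            [
                compare_spectra(e, s).score
                for e, s in zip(vset.experimental, vset.synthetic)
            ]
        )
        decoy = vset.pairs["is_decoy"].to_numpy()
        assert np.median(scores[~decoy]) > 0.8
        assert np.median(scores[decoy]) < 0.2
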