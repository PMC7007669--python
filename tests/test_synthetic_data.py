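"""Simulator calibration, determinism, truth labels, and polymorphism scenarios."""

import numpy as np
import pytest
from scipy import stats

from hml2quant.diagnostic_alleles import (
    count_allele_matches_records,
    find_unique_alleles,
    revcomp,
)
from hml2quant.provirus_db import pairwise_divergence
from hml2quant.synthetic_data import (
    SharedAllelePlanting,
    SimConfig,
    reference_family_config,
    simulate_family,
    simulate_genome,
    simulate_reads,
)


class TestFamilyGeneration:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(n_short_reads=500)
        f1, f2 = simulate_family(cfg, 5), simulate_family(cfg, 5)
        assert [r.sequence for r in f1.proviruses] == [
            r.sequence for r in f2.proviruses
        ]
        assert f1.env_alignment.rows == f2.env_alignment.rows
        g1, g2 = simulate_genome(f1, 6), simulate_genome(f2, 6)
        assert g1.present == g2.present and g1.proportions == g2.proportions
        r1, _ = simulate_reads(f1, g1, 7, "short")
        r2, _ = simulate_reads(f2, g2, 7, "short")
        assert r1 == r2

    def test_divergence_calibration_young_subfamily(self):
        cfg = SimConfig()
        for seed in (1, 2, 3):
            fam = simulate_family(cfg, seed)
            d = pairwise_divergence(fam.env_alignment)
            assert 0.012 <= d <= 0.018  # within 20% of the 1.5% target

    def test_old_divergence_calibration(self):
        cfg = SimConfig(n_old=8, old_len_range=(6000, 6000))
        fam = simulate_family(cfg, 9)
        from hml2quant.provirus_db import GappedAlignment

        old = GappedAlignment(
            fam.old_names, [fam.proviruses[n].sequence for n in fam.old_names]
        )
        d = pairwise_divergence(old)
        assert 0.12 <= d <= 0.18

    def test_zero_divergence_degenerate_family_has_no_alleles(self):
        cfg = SimConfig(
            young_divergence=0.0,
            young_sister_divergence=None,
            tandem_dup=False,
            premature_stop_rate=0.0,
            type1_fraction=0.0,
        )
        fam = simulate_family(cfg, 4)
        young_rows = fam.env_alignment.rows
        assert len(set(young_rows)) == 1
        assert find_unique_alleles(fam.env_alignment, fam.proviruses, 31) == []

    def test_type1_deletion_shortens_locus_and_gaps_alignment(self, family20):
        cfg = family20.cfg
        assert family20.type1_names  # default fraction produces some
        for nm in family20.type1_names:
            rec = family20.proviruses[nm]
            assert len(rec.sequence) == cfg.ancestral_len - cfg.type1_del_len
            assert rec.type1 and not rec.env_encoding
            row = family20.env_alignment.row(nm)
            assert row[: cfg.type1_del_len] == "-" * cfg.type1_del_len

    def test_alignment_rows_ungap_into_provirus_sequences(self, family20):
        for nm in family20.env_alignment.names:
            ung = family20.env_alignment.ungapped(nm)
            assert ung in family20.proviruses[nm].sequence

    def test_tandem_pair_env_identical_with_outside_differences(self, family20):
        a, b = next(
            (r.name, r.tandem_partner) for r in family20.proviruses if r.tandem_partner
        )
        assert family20.env_alignment.row(a) == family20.env_alignment.row(b)
        assert family20.proviruses[a].sequence != family20.proviruses[b].sequence

    def test_hypermutated_locus_shows_g_to_a_excess(self):
        cfg = SimConfig(n_hypermutated=1, hypermut_rate=0.3)
        fam = simulate_family(cfg, 13)
        hyper = fam.proviruses["H1"].sequence
        # compare against a young locus at homologous (full-length) positions:
        # G->A transitions must dominate A->G at binomial p < 0.01
        ref = next(
            fam.proviruses[n].sequence
            for n in fam.young_names
            if n not in fam.type1_names
        )
        g_to_a = sum(1 for x, y in zip(ref, hyper) if x == "G" and y == "A")
        a_to_g = sum(1 for x, y in zip(ref, hyper) if x == "A" and y == "G")
        p = stats.binomtest(g_to_a, g_to_a + a_to_g, 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_reference_configuration_scale(self):
        fam = simulate_family(reference_family_config(), 1)
        assert len(fam.proviruses) == 95
        assert len(fam.proviruses.env_encoding_names) == 8
        assert len(fam.env_alignment) == 20

    def test_contradictory_shared_allele_rejected(self):
        cfg = SimConfig(
            shared_alleles=(SharedAllelePlanting(100, None, "Y1a", "nonexistent"),)
        )
        with pytest.raises(ValueError, match="not in family"):
            simulate_family(cfg, 1)


class TestGenomeAndReads:
    def test_presence_follows_population_frequency(self):
        cfg = SimConfig(
            polymorphic_fraction=0.0,
            population_frequency_overrides={"Y1a": 0.0, "O1": 1.0},
        )
        fam = simulate_family(cfg, 2)
        gen = simulate_genome(fam, 3)
        assert "Y1a" not in gen.present and "O1" in gen.present
        assert "Y1a" not in gen.proportions
        assert sum(gen.proportions.values()) == pytest.approx(1.0)

    def test_cryptic_share_on_absent_sharer_is_contradictory(self):
        cfg = SimConfig(
            polymorphic_fraction=0.0,
            shared_alleles=(
                SharedAllelePlanting(500, None, "Y2a", "Y1a", cryptic=True),
            ),
            population_frequency_overrides={"Y1a": 0.0},
        )
        fam = simulate_family(cfg, 2)
        with pytest.raises(ValueError, match="absent"):
            simulate_genome(fam, 3)

    def test_error_free_reads_are_exact_source_substrings(self):
        cfg = SimConfig(n_short_reads=300, short_error_rate=0.0)
        fam = simulate_family(cfg, 8)
        gen = simulate_genome(fam, 9)
        reads, truth = simulate_reads(fam, gen, 10, "short")
        truth = truth.set_index("read_id")
        for rid, seq, qual in reads:
            src = gen.sequences[truth.loc[rid, "source"]]
            assert seq in src or revcomp(seq) in src
            assert set(qual) == {"I"}  # error 0 -> Phred 40

    def test_source_frequencies_within_multinomial_bounds(self):
        cfg = SimConfig(
            n_short_reads=10_000,
            expression_proportions={"Y1a": 0.7, "O1": 0.3},
            polymorphic_fraction=0.0,
        )
        fam = simulate_family(cfg, 30)
        gen = simulate_genome(fam, 31)
        assert gen.proportions == {"Y1a": 0.7, "O1": 0.3}
        _, truth = simulate_reads(fam, gen, 32, "short")
        n = len(truth)
        k = (truth.source == "Y1a").sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.7)
        assert lo <= k <= hi

    def test_truth_conservation_counts_match_reads(self):
        cfg = SimConfig(n_short_reads=2000)
        fam = simulate_family(cfg, 14)
        gen = simulate_genome(fam, 15)
        reads, truth = simulate_reads(fam, gen, 16, "short")
        assert len(reads) == len(truth) == 2000
        assert set(truth.source) <= set(gen.present)
        assert (truth.length >= 50).all() and (truth.length <= 200).all()

    def test_long_reads_have_low_identity(self):
        cfg = SimConfig(n_long_reads=400, long_error_rate=0.12)
        fam = simulate_family(cfg, 17)
        gen = simulate_genome(fam, 18)
        _, truth = simulate_reads(fam, gen, 19, "long")
        identity = 1.0 - truth.n_errors / truth.length
        assert identity.median() < 0.90
        assert truth.length.mean() > 1000

    def test_recombinant_reads_splice_two_sources(self):
        cfg = SimConfig(
            n_long_reads=50, long_error_rate=0.0, recombinant_fraction=1.0,
            polymorphic_fraction=0.0,
        )
        fam = simulate_family(cfg, 20)
        gen = simulate_genome(fam, 21)
        reads, truth = simulate_reads(fam, gen, 22, "long")
        rec = truth[truth.source2 != ""]
        assert len(rec) > 0
        by_id = {r: s for r, s, _q in reads}
        for row in rec.itertuples():
            seq = by_id[row.read_id]
            a = gen.sequences[row.source]
            b = gen.sequences[row.source2]
            expect = (
                a[row.start : row.start + row.breakpoint]
                + b[row.start + row.breakpoint : row.start + row.length]
            )
            assert seq == expect or seq == revcomp(expect)

    def test_probe_survival_matches_analytic_rate(self):
        """P(31-mer intact) = (1-e)^31 under the substitution-only error model."""
        e = 0.02
        cfg = SimConfig(
            n_short_reads=20_000,
            short_error_rate=e,
            expression_proportions={"Y1a": 1.0},
            polymorphic_fraction=0.0,
        )
        fam = simulate_family(cfg, 23)
        gen = simulate_genome(fam, 24)
        reads, truth = simulate_reads(fam, gen, 25, "short")
        src = gen.sequences["Y1a"]
        pos = 1000  # window [1000, 1031) of the expressed locus
        window = src[pos : pos + 31]
        covering = intact = 0
        for (rid, seq, _q), row in zip(reads, truth.itertuples()):
            if row.start <= pos and row.start + row.length >= pos + 31:
                covering += 1
                if window in seq or revcomp(window) in seq:
                    intact += 1
        assert covering > 200
        lo, hi = stats.binom.ppf([0.0005, 0.9995], covering, (1 - e) ** 31)
        assert lo <= intact <= hi


class TestPolymorphismScenarios:
    """One scenario per polymorphism class, each with its pipeline consequence."""

    def test_insertional_absence_gives_zero_allele_counts(self):
        cfg = SimConfig(
            polymorphic_fraction=0.0,
            population_frequency_overrides={"Y2a": 0.0},
            n_short_reads=3000,
            short_error_rate=0.0,
        )
        fam = simulate_family(cfg, 40)
        gen = simulate_genome(fam, 41)
        reads, _ = simulate_reads(fam, gen, 42, "short")
        alleles = [
            a
            for a in find_unique_alleles(fam.env_alignment, fam.proviruses, 31)
            if a.provirus == "Y2a" and a.verified_unique
        ]
        if alleles:  # the locus carries private SNPs in this draw
            rep = count_allele_matches_records(
                {"r": [s for _r, s, _q in reads]}, alleles, 31
            )
            assert all(v == [0] for v in rep.counts.values())

    def test_truncated_old_locus_lacks_env(self):
        cfg = SimConfig(old_len_range=(2000, 2500))
        fam = simulate_family(cfg, 43)
        lens = [len(fam.proviruses[n].sequence) for n in fam.old_names]
        assert all(2000 <= ln <= 2500 for ln in lens)

    def test_visible_shared_snp_is_caught_by_verification(self):
        cfg = SimConfig(
            polymorphic_fraction=0.0,
            old_len_range=(6000, 6000),
            shared_alleles=(SharedAllelePlanting(800, None, "Y2a", "O1"),),
        )
        fam = simulate_family(cfg, 44)
        planted = [
            a
            for a in find_unique_alleles(fam.env_alignment, fam.proviruses, 31)
            if a.provirus == "Y2a" and a.column == fam.cfg.env_start * 0 + 801
        ]
        assert planted and not planted[0].verified_unique
        assert "O1" in planted[0].shared_with

    def test_cryptic_shared_snp_misattributes_reads(self):
        """The misattribution artifact: an absent locus's 'unique' allele
        collects read counts because an expressed locus secretly shares it."""
        cfg = SimConfig(
            polymorphic_fraction=0.0,
            n_short_reads=8000,
            short_error_rate=0.0,
            expression_proportions={"Y1a": 0.6, "O1": 0.4},
            population_frequency_overrides={"Y2a": 0.0},
            shared_alleles=(
                SharedAllelePlanting(900, None, "Y2a", "Y1a", cryptic=True),
            ),
        )
        fam = simulate_family(cfg, 45)
        gen = simulate_genome(fam, 46)
        reads, truth = simulate_reads(fam, gen, 47, "short")
        assert (truth.source == "Y2a").sum() == 0  # zero true expression
        planted = [
            a
            for a in find_unique_alleles(fam.env_alignment, fam.proviruses, 31)
            if a.provirus == "Y2a" and a.column == 901 and a.verified_unique
        ]
        assert planted
        rep = count_allele_matches_records(
            {"r": [s for _r, s, _q in reads]}, planted, 31
        )
        assert rep.counts[planted[0].key][0] > 0

    def test_premature_stop_flag_set(self):
        cfg = SimConfig(premature_stop_rate=1.0)
        fam = simulate_family(cfg, 48)
        stopped = [
            r for r in fam.proviruses
            if r.env_encoding and not r.env_full_orf
        ]
        assert stopped
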