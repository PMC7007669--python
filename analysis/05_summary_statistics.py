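#!/usr/bin/env python
"""Summary statistics: Env fraction, replicate concordance, enrichment fold,
and a cross-study style relative-expression table.

Runs two replicate short-read draws through the default pipeline to measure
Spearman rank concordance, compares an enriched run against an unenriched
(background-dominated) control for the enrichment fold, and exports a
column-normalised loci x samples matrix with per-sample Env-encoding
fractions, with the tandem pair optionally merged.
"""

from pathlib import Path

import pandas as pd

from hml2quant.provirus_db import build_faux_genome
from hml2quant.quantify_stats import (
    enrichment_fold,
    env_fraction,
    rank_concordance,
    rpkm,
    study_table,
)
from hml2quant.read_processing import align_reads, assign_counts
from hml2quant.synthetic_data import (
    SimConfig,
    simulate_family,
    simulate_genome,
    simulate_reads,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 20260923


def _profile(fam, gen, faux, seed, n_reads=30_000):
    cfg = fam.cfg
    cfg.n_short_reads = n_reads
    reads, _ = simulate_reads(fam, gen, seed, "short")
    hits = align_reads(((r, s) for r, s, _q in reads), faux)
    table = assign_counts(hits, fam.proviruses.names, "random_multimap", seed)
    return rpkm(table, faux.locus_lengths(), source=f"run{seed}"), len(hits), len(reads)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(n_short_reads=30_000)
    fam = simulate_family(cfg, SEED)
    gen = simulate_genome(fam, SEED + 1)
    faux, _ = build_faux_genome(fam.proviruses, cfg.spacer_len)

    prof1, _, _ = _profile(fam, gen, faux, SEED + 2)
    prof2, _, _ = _profile(fam, gen, faux, SEED + 3)
    rho = rank_concordance(prof1, prof2)
    env = fam.proviruses.env_encoding_names
    ef1, ef2 = env_fraction(prof1, env), env_fraction(prof2, env)

    # enrichment: same genome, with and without overwhelming off-target
    # background; the fold is the ratio of family-assigned read fractions
    cfg_bg = SimConfig(n_short_reads=10_000, background_fraction=0.998,
                       polymorphic_fraction=0.0)
    fam_bg = simulate_family(cfg_bg, SEED)
    gen_bg = simulate_genome(fam_bg, SEED + 1)
    reads_bg, _ = simulate_reads(fam_bg, gen_bg, SEED + 4, "short")
    hits_bg = align_reads(((r, s) for r, s, _q in reads_bg), faux)
    control_frac = len(hits_bg) / len(reads_bg)
    cfg_en = SimConfig(n_short_reads=10_000, background_fraction=0.10,
                       polymorphic_fraction=0.0)
    fam_en = simulate_family(cfg_en, SEED)
    gen_en = simulate_genome(fam_en, SEED + 1)
    reads_en, _ = simulate_reads(fam_en, gen_en, SEED + 5, "short")
    hits_en = align_reads(((r, s) for r, s, _q in reads_en), faux)
    enriched_frac = len(hits_en) / len(reads_en)
    fold = enrichment_fold(enriched_frac, control_frac)

    # cross-study style matrix: two replicate profiles as 'samples'
    mat = pd.DataFrame(
        {"run1": prof1.rpkm, "run2": prof2.rpkm}
    )
    mat.index.name = "locus"
    tandem = next(
        (r.name, r.tandem_partner) for r in fam.proviruses if r.tandem_partner
    )
    study = study_table(mat, merge_tandem=[(*tandem, tandem[0][:-1] + "ab")])
    study.fractions.to_csv(OUT / "study_matrix.tsv", sep="\t")

    summary = pd.DataFrame(
        [
            ("spearman_rank_concordance", round(rho, 4)),
            ("env_fraction_run1", round(ef1, 4)),
            ("env_fraction_run2", round(ef2, 4)),
            ("enriched_family_fraction", round(enriched_frac, 5)),
            ("control_family_fraction", round(control_frac, 5)),
            ("enrichment_fold", round(fold, 1)),
        ],
        columns=["statistic", "value"],
    )
    summary.to_csv(OUT / "summary_statistics.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nReplicate profiles agree (Spearman rho = {rho:.2f}); enrichment "
        f"raises the family-assigned read fraction {fold:.0f}-fold over the "
        "background-dominated control."
    )


if __name__ == "__main__":
    main()
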