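#!/usr/bin/env python
"""Discover provirus-unique env SNP alleles and count them in reads.

Finds every single-carrier SNP allele in the young subfamily's env
alignment, verifies each 31-nt window against the whole reference set,
counts exact matches in three replicate short-read runs (31-nt window) and
one high-error long-read run (17-nt window), and scans long reads for
multi-allele (recombinant-like) evidence with the 11-nt window.  Includes a
cryptic shared allele on an absent locus, so the output shows the
misattribution artifact alongside honest counts.
"""

from pathlib import Path

import pandas as pd

from hml2quant.diagnostic_alleles import (
    alleles_to_frame,
    count_allele_matches_records,
    detect_multi_allele_records,
    find_unique_alleles,
)
from hml2quant.synthetic_data import (
    SharedAllelePlanting,
    SimConfig,
    simulate_family,
    simulate_genome,
    simulate_reads,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 20260923


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(
        n_short_reads=20_000,
        n_long_reads=1_000,
        recombinant_fraction=0.05,
        polymorphic_fraction=0.0,
        population_frequency_overrides={"Y2a": 0.0},  # insertionally absent
        shared_alleles=(
            SharedAllelePlanting(1000, None, "Y2a", "Y1a", cryptic=True),
        ),
        expression_proportions={"Y1a": 0.45, "Y3a": 0.15, "Y4a": 0.1, "O1": 0.3},
    )
    fam = simulate_family(cfg, SEED)
    gen = simulate_genome(fam, SEED + 1)

    alleles = find_unique_alleles(fam.env_alignment, fam.proviruses, window=31)
    alleles_to_frame(alleles).to_csv(OUT / "alleles.tsv", sep="\t", index=False)
    verified = [a for a in alleles if a.verified_unique]

    runs = {}
    for i in range(3):  # three replicate short-read growths
        reads, _ = simulate_reads(fam, gen, SEED + 10 + i, "short")
        runs[f"short_run{i + 1}"] = [s for _r, s, _q in reads]
    rep31 = count_allele_matches_records(runs, verified, window=31)
    df = rep31.to_frame()

    long_reads, truth_l = simulate_reads(fam, gen, SEED + 20, "long")
    rep17 = count_allele_matches_records(
        {"long_run": [s for _r, s, _q in long_reads]}, verified, window=17,
        mode="long",
    )
    df["long_run_17nt"] = [rep17.counts[a.key][0] for a in verified]
    df.to_csv(OUT / "allele_counts.tsv", sep="\t")

    flagged = detect_multi_allele_records(
        [(r, s) for r, s, _q in long_reads], verified, window=11
    )
    pd.DataFrame(
        [
            {"read_id": f.read_id, "proviruses": "+".join(f.proviruses),
             "alleles": ";".join(f.allele_keys)}
            for f in flagged
        ]
    ).to_csv(OUT / "multi_allele_long_reads.tsv", sep="\t", index=False)

    absent = df[df.index.str.startswith("Y2a")]
    print(df.to_string())
    print(
        f"\n{len(verified)} verified-unique alleles; "
        f"{len(flagged)} long reads carry alleles of two different proviruses, "
        f"from {int((truth_l.source2 != '').sum())} true recombinants plus "
        "reads exposing the cryptic shared polymorphism — multi-allele reads "
        "cannot distinguish recombination from unsequenced allele sharing."
    )
    if (absent["mean"] > 0).any():
        print(
            "Note: locus Y2a is absent from the genome yet one of its "
            "'unique' alleles still collects reads — a cryptic polymorphism "
            "shared with the expressed Y1a, the signature misattribution "
            "artifact."
        )


if __name__ == "__main__":
    main()
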