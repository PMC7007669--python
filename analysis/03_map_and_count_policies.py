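#!/usr/bin/env python
"""Map simulated short reads to the faux genome and count under every
multi-mapping policy.

Simulates one genome and 50,000 short reads at the default study
conditions, aligns them with the built-in best-match aligner, assigns
counts under random_multimap / unique_only / count_all / proportional, and
writes per-policy count and RPKM tables plus a comparison against the
simulator's truth.  The headline observation: unique-read counting
collapses the young subfamily's share, random multi-mapping preserves it.
"""

from pathlib import Path

import pandas as pd

from hml2quant.synthetic_data import SimConfig, end_to_end_recovery

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 20260923


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig()  # default study conditions, incl. 0.5% read error
    rep = end_to_end_recovery(cfg, SEED)

    names = rep["family"].proviruses.names
    young = set(rep["family"].young_names)
    rows = []
    for nm in names:
        row = {
            "locus": nm,
            "young": nm in young,
            "true_proportion": rep["truth_count_proportions"][nm],
            "true_rpkm_proportion": rep["truth_rpkm_proportions"][nm],
        }
        for pol, d in rep["policies"].items():
            row[f"count_{pol}"] = d["counts"][nm]
            row[f"rpkm_prop_{pol}"] = d["rpkm_proportions"][nm]
        rows.append(row)
    pd.DataFrame(rows).to_csv(OUT / "counts_by_policy.tsv", sep="\t", index=False)

    summary = []
    for pol, d in rep["policies"].items():
        summary.append(
            {
                "policy": pol,
                "young_share": round(d["young_share"], 4),
                "true_young_share": round(rep["truth_young_share"], 4),
                "env_fraction": round(d["env_fraction"], 4),
                "max_abs_err_rpkm": round(d["max_abs_err_rpkm"], 4),
                "total_assigned": round(d["counts"].total_assigned, 1),
            }
        )
    df = pd.DataFrame(summary)
    df.to_csv(OUT / "policy_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    t = rep["truth_young_share"]
    u = rep["policies"]["unique_only"]["young_share"]
    r = rep["policies"]["random_multimap"]["young_share"]
    print(
        f"\nTrue young-subfamily share {t:.1%}: random multi-mapping "
        f"estimates {r:.1%}, unique-only counting only {u:.1%} "
        f"({u / t:.2f}x the truth) — dropping multi-mappers hides the "
        "near-identical young loci."
    )


if __name__ == "__main__":
    main()
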