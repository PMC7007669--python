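"""Normalisation and summary statistics for locus-resolved expression.

RPKM (reads per kilobase of transcript per million mapped reads) corrects
raw per-provirus counts for locus length and sequencing depth:

    RPKM_i = count_i / ( (length_i / 1e3) * (total_mapped / 1e6) )

where ``total_mapped`` is the number of reads assigned to any locus in the
table (family-assigned reads, not total sequenced reads).  On top of the
profile sit the headline statistics of an enrichment study: the fraction of
expression from Env-encoding loci, the enrichment fold of an enriched run
over an unenriched control, Spearman rank concordance between replicate
runs, and column-normalised cross-study relative-expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .read_processing import CountTable


@dataclass
class ExpressionProfile:
    """Per-locus RPKM values for one run/policy."""

    rpkm: dict[str, float]
    lengths: dict[str, int]
    source: str = ""

    def __getitem__(self, locus: str) -> float:
        return self.rpkm[locus]

    @property
    def loci(self) -> list[str]:
        return list(self.rpkm)

    def proportions(self) -> dict[str, float]:
        total = sum(self.rpkm.values())
        if total <= 0:
            raise ValueError("all-zero profile")
        return {k: v / total for k, v in self.rpkm.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": list(self.rpkm),
                "length": [self.lengths[k] for k in self.rpkm],
                "rpkm": list(self.rpkm.values()),
            }
        )


def rpkm(
    counts: CountTable, lengths: Mapping[str, int], source: str = ""
) -> ExpressionProfile:
    """Length- and depth-normalise a count table to RPKM."""
    if counts.total_mapped <= 0:
        raise ValueError("zero total mapped reads")
    bad = [k for k, v in lengths.items() if v <= 0]
    if bad:
        raise ValueError(f"non-positive lengths for {bad}")
    denom_reads = counts.total_mapped / 1e6
    vals = {}
    for locus, c in counts.counts.items():
        vals[locus] = c / ((lengths[locus] / 1e3) * denom_reads)
    return ExpressionProfile(vals, dict(lengths), source or counts.policy)


def env_fraction(
    profile: ExpressionProfile | Mapping[str, float], env_set: Sequence[str]
) -> float:
    """Fraction of total RPKM carried by the Env-encoding loci."""
    vals = profile.rpkm if isinstance(profile, ExpressionProfile) else dict(profile)
    missing = [n for n in env_set if n not in vals]
    if missing:
        raise KeyError(f"env loci absent from profile: {missing}")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all-zero profile")
    return sum(vals[n] for n in env_set) / total


def enrichment_fold(
    enriched_frac: float, control_frac: float, pseudocount_frac: float | None = None
) -> float:
    """Fold increase in the family-assigned read proportion due to enrichment.

    Each fraction is (family-assigned reads) / (total QC-passed reads) for
    one run.  A zero control fraction is an error unless
    ``pseudocount_frac`` supplies the 1-read-equivalent floor, in which case
    the result is a lower bound.
    """
    if control_frac < 0 or enriched_frac < 0:
        raise ValueError("fractions must be non-negative")
    if control_frac == 0:
        if pseudocount_frac is None:
            raise ValueError("control fraction is zero (use pseudocount_frac for a bound)")
        control_frac = pseudocount_frac
    return enriched_frac / control_frac


def rank_concordance(
    p: ExpressionProfile | Mapping[str, float],
    q: ExpressionProfile | Mapping[str, float],
) -> float:
    """Spearman rank correlation between two profiles (average ranks for ties)."""
    pv = p.rpkm if isinstance(p, ExpressionProfile) else dict(p)
    qv = q.rpkm if isinstance(q, ExpressionProfile) else dict(q)
    if set(pv) != set(qv):
        raise ValueError("profiles cover different locus sets")
    loci = sorted(pv)
    if len(loci) < 3:
        raise ValueError("need at least 3 loci for rank concordance")
    rho, _ = stats.spearmanr([pv[k] for k in loci], [qv[k] for k in loci])
    return float(rho)


@dataclass
class StudyMatrix:
    """Loci x samples matrix of relative expression fractions (columns sum to 1)."""

    fractions: pd.DataFrame

    def env_fractions(self, env_set: Sequence[str]) -> pd.Series:
        present = [n for n in env_set if n in self.fractions.index]
        return self.fractions.loc[present].sum(axis=0)


def study_table(
    csv_path_or_df: str | pd.DataFrame,
    merge_tandem: Sequence[tuple[str, str, str]] = (),
    known_loci: Sequence[str] | None = None,
) -> StudyMatrix:
    """Column-normalise a cross-study expression matrix (locus rows x sample cols).

    ``merge_tandem`` lists (locus_a, locus_b, merged_name) triples whose rows
    are summed — tandem-duplicate pairs most studies report as one provirus.
    Unknown locus names (against ``known_loci``) warn and pass through.
    """
    if isinstance(csv_path_or_df, pd.DataFrame):
        df = csv_path_or_df.copy()
    else:
        df = pd.read_csv(csv_path_or_df, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce").fillna(0.0)
    if known_loci is not None:
        unknown = [n for n in df.index if n not in set(known_loci)]
        if unknown:
            import warnings

            warnings.warn(f"unknown locus names passed through: {unknown}")
    for a, b, merged in merge_tandem:
        if a in df.index and b in df.index:
            df.loc[merged] = df.loc[a] + df.loc[b]
            df = df.drop(index=[a, b])
    col_sums = df.sum(axis=0)
    if (col_sums <= 0).any():
        bad = list(col_sums.index[col_sums <= 0])
        raise ValueError(f"all-zero sample columns: {bad}")
    return StudyMatrix(df / col_sums)
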