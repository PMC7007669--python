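"""FASTQ QC, alignment ingestion, a desk-scale best-match aligner, and
per-provirus counting under explicit multi-mapping policies.

The counting policies are the contract this module exists for.  A read whose
best alignment ties across several proviruses (a multi-mapper) can be

* assigned to one best hit uniformly at random (``random_multimap``; what a
  default short-read pipeline does),
* dropped (``unique_only``; the default of unique-read counters, which
  underestimates similar young proviruses),
* counted once at every best hit (``count_all``; a read tying 10 loci is
  counted 10 times, overestimating), or
* divided fractionally across best hits in proportion to each locus's
  unique-read count (``proportional``; biased toward older, more diverged
  loci, which accrue more unique reads).

Production-scale alignment stays with external tools (SAM/BAM in); the
built-in semi-global edit-distance aligner exists to validate the policies
at synthetic scale with exactly controlled tie structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .diagnostic_alleles import iter_fastq, revcomp
from .provirus_db import FauxGenome

log = logging.getLogger(__name__)

POLICIES = ("random_multimap", "unique_only", "count_all", "proportional")


@dataclass
class QCParams:
    """Read-level QC thresholds.

    ``max_err_prob`` is the mean per-base error probability (Phred-decoded)
    above which a read is discarded; length bounds drop abnormally short or
    long reads (the long bound depends on the sequencing kit: 200 or 400).
    """

    min_len: int = 50
    max_len: int = 200
    max_err_prob: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        if not 0.0 < self.max_err_prob < 1.0:
            raise ValueError("max_err_prob must be in (0,1)")


@dataclass
class QCReport:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0

    @property
    def discarded(self) -> int:
        return self.too_short + self.too_long + self.low_quality

    @property
    def total(self) -> int:
        return self.kept + self.discarded


def mean_error_prob(qual: str) -> float:
    """Mean per-base error probability from a Phred+33 quality string."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.float64) - 33.0
    return float(np.mean(10.0 ** (-q / 10.0)))


def qc_filter(
    fastq: str | Path,
    params: QCParams,
    out_fastq: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], QCReport]:
    """Filter reads on length and mean error probability.

    Returns the kept records (id, seq, qual) and a report with per-reason
    discard counts; optionally writes the filtered FASTQ.
    """
    kept: list[tuple[str, str, str]] = []
    rep = QCReport()
    for i, (rid, seq, qual) in enumerate(iter_fastq(fastq)):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {i} ({rid})")
        if len(seq) < params.min_len:
            rep.too_short += 1
        elif len(seq) > params.max_len:
            rep.too_long += 1
        elif mean_error_prob(qual) > params.max_err_prob:
            rep.low_quality += 1
        else:
            rep.kept += 1
            kept.append((rid, seq, qual))
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for rid, seq, qual in kept:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return kept, rep


@dataclass
class ReadHits:
    """Best-scoring loci for one read.

    ``hits`` lists ``(locus, score)`` for every locus attaining the best
    score (lower = better for edit distance).  ``is_unique`` is true iff a
    single locus attains it.
    """

    read_id: str
    hits: list[tuple[str, float]]
    mapq: int | None = None

    @property
    def is_unique(self) -> bool:
        return len(self.hits) == 1

    @property
    def loci(self) -> list[str]:
        return [name for name, _ in self.hits]


def best_match_align(
    read: str,
    faux: FauxGenome,
    max_edit_frac: float = 0.25,
    read_id: str = "read",
) -> ReadHits | None:
    """Semi-global best-match search of a read against every faux-genome locus.

    The read and its reverse complement are scored against each locus by
    edit distance (read fully aligned, free ends on the locus); all loci
    attaining the minimal distance are returned, provided that distance is
    at most ``max_edit_frac`` x read length.  Returns None for unmapped.
    """
    if len(read) < 20:
        return None
    k = int(max_edit_frac * len(read))
    rc = revcomp(read)
    targets = _locus_targets(faux)
    # exact-substring pre-pass (C-speed): a distance-0 hit anywhere means the
    # best-hit set is exactly the loci containing the read verbatim
    exact = [
        (name, 0.0)
        for name, target in targets.items()
        if read in target or rc in target
    ]
    if exact:
        return ReadHits(read_id, exact)
    best = k
    hits: list[tuple[str, float]] = []
    for name, target in targets.items():
        d = _min_edit(read, rc, target, best)
        if d is None or d > best:
            continue
        if d < best:
            best = d
            hits = [(name, float(d))]
        else:
            hits.append((name, float(d)))
    if not hits:
        return None
    return ReadHits(read_id, hits)


def _locus_targets(faux: FauxGenome) -> dict[str, str]:
    """Per-locus target strings, cached on the genome object."""
    cached = getattr(faux, "_targets", None)
    if cached is None:
        cached = {n: faux.sequence[s:e] for n, (s, e) in faux.intervals.items()}
        faux._targets = cached
    return cached


def _min_edit(read: str, rc: str, target: str, cap: int) -> int | None:
    """Min semi-global edit distance of read or its RC within target, capped."""
    d1 = edlib.align(read, target, mode="HW", task="distance", k=cap)["editDistance"]
    d2 = edlib.align(rc, target, mode="HW", task="distance", k=cap)["editDistance"]
    ds = [d for d in (d1, d2) if d != -1]
    return min(ds) if ds else None


def align_reads(
    reads: Iterable[tuple[str, str]],
    faux: FauxGenome,
    max_edit_frac: float = 0.25,
) -> list[ReadHits]:
    """best_match_align over an iterable of (read_id, sequence); unmapped dropped."""
    out = []
    for rid, seq in reads:
        h = best_match_align(seq, faux, max_edit_frac, read_id=rid)
        if h is not None:
            out.append(h)
    return out


def ingest_alignment(
    sam_or_bam: str | Path,
    faux: FauxGenome,
    mapq_min: int | None = None,
) -> list[ReadHits]:
    """Collapse SAM/BAM records into one ReadHits per read.

    Primary and secondary alignments of one read are pooled; hits whose
    alignment score (AS tag, higher better) ties the read's best are kept,
    so aligner-reported multi-mappers surface as ``is_unique = False``.
    Records are attributed to the locus interval enclosing their reference
    span; records landing in a spacer are logged and skipped.  Reads whose
    primary mapq falls below ``mapq_min`` are dropped (the long-read
    reliability gate).
    """
    import pysam

    per_read: dict[str, list[tuple[str, float, int]]] = {}
    unassigned = 0
    with pysam.AlignmentFile(str(sam_or_bam), check_sq=False) as fh:
        multi_ref = fh.nreferences > 1
        for rec in fh:
            if rec.is_unmapped:
                continue
            if multi_ref:
                locus = rec.reference_name if rec.reference_name in faux.intervals else None
            else:
                locus = faux.locus_of(rec.reference_start)
            if locus is None:
                unassigned += 1
                continue
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            per_read.setdefault(rec.query_name, []).append(
                (locus, score, rec.mapping_quality)
            )
    if unassigned:
        log.info("%d alignment records outside locus intervals (spacer)", unassigned)
    out: list[ReadHits] = []
    for rid, recs in per_read.items():
        best = max(s for _, s, _ in recs)
        mapq = max(q for _, _, q in recs)
        if mapq_min is not None and mapq < mapq_min:
            continue
        seen: dict[str, float] = {}
        for locus, s, _ in recs:
            if s == best:
                seen[locus] = s
        out.append(ReadHits(rid, sorted(seen.items()), mapq=mapq))
    return out


@dataclass
class CountTable:
    """Per-locus read counts under one multi-mapping policy.

    Invariants: ``unique_only`` and ``random_multimap`` sum to at most the
    number of mapped reads (equality for random_multimap); ``count_all``
    sums to at least it; per locus
    unique_only <= random_multimap expected <= count_all.
    """

    counts: dict[str, float]
    policy: str
    total_mapped: int
    seed: int | None = None

    def __getitem__(self, locus: str) -> float:
        return self.counts.get(locus, 0.0)

    @property
    def total_assigned(self) -> float:
        return float(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"locus": list(self.counts), "count": list(self.counts.values())}
        )
        df["policy"] = self.policy
        df["seed"] = self.seed
        return df


def assign_counts(
    hits: Sequence[ReadHits],
    loci: Sequence[str],
    policy: str = "random_multimap",
    seed: int = 0,
) -> CountTable:
    """Assign mapped reads to loci under an explicit multi-mapping policy.

    ``loci`` fixes the table's row set (zero-count loci included) so that
    downstream RPKM profiles are comparable across policies.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    counts: dict[str, float] = {name: 0.0 for name in loci}
    rng = np.random.default_rng(seed)
    if policy == "proportional":
        unique_counts = {name: 0.0 for name in loci}
        for h in hits:
            if h.is_unique:
                unique_counts[h.hits[0][0]] += 1.0
    for h in hits:
        if h.is_unique:
            counts[h.hits[0][0]] += 1.0
            continue
        names = h.loci
        if policy == "unique_only":
            continue
        if policy == "count_all":
            for n in names:
                counts[n] += 1.0
        elif policy == "random_multimap":
            counts[names[rng.integers(len(names))]] += 1.0
        else:  # proportional
            weights = np.array([unique_counts[n] for n in names])
            if weights.sum() == 0:
                weights = np.ones(len(names))
            weights = weights / weights.sum()
            for n, w in zip(names, weights):
                counts[n] += float(w)
    return CountTable(counts, policy, total_mapped=len(hits), seed=seed)


def write_sam(
    hits: Sequence[ReadHits],
    reads: dict[str, str],
    faux: FauxGenome,
    path: str | Path,
) -> None:
    """Write ReadHits as a minimal SAM against the faux genome (text, unsorted).

    The first hit is primary, further tied hits secondary; AS carries the
    negated edit distance so ties round-trip through :func:`ingest_alignment`.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"LN": len(faux.sequence), "SN": "faux"}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for h in hits:
            seq = reads[h.read_id]
            for i, (locus, score) in enumerate(h.hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = h.read_id
                a.query_sequence = seq if i == 0 else None
                a.flag = 0 if i == 0 else 256
                a.reference_id = 0
                a.reference_start = faux.intervals[locus][0]
                a.mapping_quality = 0 if len(h.hits) > 1 else 60
                a.cigarstring = f"{len(seq)}M" if i == 0 else None
                a.set_tag("AS", int(-score))
                out.write(a)
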