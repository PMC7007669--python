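"""Provirus-diagnostic SNP alleles: discovery, uniqueness checks, read counting.

Mapping cannot distinguish near-identical proviruses, but a SNP allele
carried by exactly one locus can.  From a gapped *env* alignment this module
selects every column where a single row dissents from the majority
(commonality infers the ancestral state), builds windowed probe sequences
centred on the variant (31 nt for short reads, 17 nt for error-prone long
reads, 11 nt for the multi-allele recombinant scan), verifies each probe is
an exact substring of no other provirus in the full universe, and counts
exact probe matches in FASTQ reads.

Notation follows the field: ``G(96)A`` is ancestral G at 1-based alignment
column 96 with derived allele A.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .provirus_db import GAP, GappedAlignment, ProvirusSet

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file, gzip-transparent."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


@dataclass
class DiagnosticAllele:
    """One provirus-unique SNP allele with its windowed probes.

    ``carriers`` usually holds one locus; for a tandem-duplicate pair with
    identical *env* it holds both, treated as a single carrier.
    ``probes`` maps window length (odd) to the probe extracted from the
    carrier's ungapped provirus sequence, centred on the variant.
    ``combination`` flags a second in-window variant, so uniqueness holds for
    the combination rather than the single base.
    """

    provirus: str
    column: int  # 1-based alignment column
    ancestral_base: str
    derived_base: str
    probes: dict[int, str]
    carriers: tuple[str, ...] = ()
    combination: bool = False
    verified_unique: bool = False
    shared_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.carriers:
            self.carriers = (self.provirus,)

    @property
    def label(self) -> str:
        return f"{self.ancestral_base}({self.column}){self.derived_base}"

    @property
    def key(self) -> str:
        return f"{self.provirus} {self.label}"

    def probe(self, window: int) -> str:
        return self.probes[window]

    @property
    def probe31(self) -> str | None:
        return self.probes.get(31)

    @property
    def probe17(self) -> str | None:
        return self.probes.get(17)

    @property
    def probe11(self) -> str | None:
        return self.probes.get(11)


@dataclass
class AlleleCountReport:
    """Per-allele exact-match read counts for a set of runs.

    ``counts`` is allele key -> one count per run (reads matching the probe,
    each read counted at most once per allele); ``mean`` is the arithmetic
    mean across runs.
    """

    alleles: list[DiagnosticAllele]
    runs: list[str]
    counts: dict[str, list[int]]
    window: int
    mode: str = "short"

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.counts, orient="index", columns=self.runs)
        df.index.name = "allele"
        df["mean"] = df.mean(axis=1)
        return df


def occurs_in(probe: str, sequence: str, search_rc: bool = True) -> bool:
    """Exact substring occurrence of probe (optionally its reverse complement)."""
    return probe in sequence or (search_rc and revcomp(probe) in sequence)


def _column_to_seq_pos(row: str, col0: int) -> int:
    """Ungapped position of alignment column ``col0`` within its own row."""
    return len(row[:col0].replace(GAP, ""))


def find_unique_alleles(
    aln: GappedAlignment,
    universe: ProvirusSet | None,
    window: int = 31,
    extra_windows: Sequence[int] = (17, 11),
    search_rc: bool = True,
    tandem_as_one: bool = True,
    exclude: Sequence[str] = (),
) -> list[DiagnosticAllele]:
    """Discover SNP alleles carried by exactly one alignment row.

    For each column the majority base over non-gap rows is taken as ancestral
    (ties skipped with a log message).  A minority base present in exactly
    one row — or, with ``tandem_as_one``, exactly the tandem-duplicate pair —
    yields a candidate allele.  The probe of length ``window`` (odd) is cut
    from the carrier's ungapped provirus sequence, centred on the variant;
    variants closer than ``window // 2`` to a sequence end are skipped with a
    warning.  Each probe is then searched for exact occurrence (both strands
    when ``search_rc``) in every universe sequence; ``verified_unique`` is
    true when only the carrier(s) contain it, with any other loci recorded
    in ``shared_with``.  ``exclude`` drops alignment rows first (the
    "delete one tandem copy" re-analysis mode).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if exclude:
        keep = [n for n in aln.names if n not in set(exclude)]
        aln = aln.subset(keep)

    tandem_pairs: dict[str, str] = {}
    if universe is not None and tandem_as_one:
        for rec in universe:
            if rec.tandem_partner is not None and rec.name in aln._by_name:
                tandem_pairs[rec.name] = rec.tandem_partner

    windows = sorted({window, *extra_windows}, reverse=True)
    alleles: list[DiagnosticAllele] = []
    n_cols = aln.n_columns

    # Precompute per-row ungapped sequences and their location inside the
    # full provirus (the alignment usually covers only the env gene).
    full_seq: dict[str, str] = {}
    offset: dict[str, int] = {}
    for name in aln.names:
        ung = aln.ungapped(name)
        if universe is not None and name in universe:
            prov = universe[name].sequence
            off = prov.find(ung)
            if off >= 0:
                full_seq[name], offset[name] = prov, off
                continue
        full_seq[name], offset[name] = ung, 0

    # Per-column majority base (ancestral by commonality), reused for the
    # in-window second-variant check.
    def _majority(col: int) -> str | None:
        bases = [r[col] for r in aln.rows if r[col] not in (GAP, "N")]
        if len(bases) < 2:
            return None
        counts = Counter(bases).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            return None  # ambiguous ancestral state
        return counts[0][0]

    majority = [_majority(c) for c in range(n_cols)]

    for col in range(n_cols):
        anc = majority[col]
        if anc is None:
            if any(r[col] not in (GAP, "N") for r in aln.rows):
                log.debug("column %d: ancestral state ambiguous, skipped", col + 1)
            continue
        carriers_by_base: dict[str, list[str]] = {}
        for name, row in zip(aln.names, aln.rows):
            b = row[col]
            if b in (GAP, "N") or b == anc:
                continue
            carriers_by_base.setdefault(b, []).append(name)

        for derived, carrier_names in carriers_by_base.items():
            if len(carrier_names) == 1:
                carriers = tuple(carrier_names)
            elif (
                len(carrier_names) == 2
                and tandem_pairs.get(carrier_names[0]) == carrier_names[1]
            ):
                carriers = tuple(carrier_names)  # tandem pair = one carrier
            else:
                continue
            rep = carriers[0]
            row = aln.row(rep)
            pos = offset[rep] + _column_to_seq_pos(row, col)
            seq = full_seq[rep]
            probes: dict[int, str] = {}
            ok = True
            for w in windows:
                flank = w // 2
                if pos - flank < 0 or pos + flank + 1 > len(seq):
                    if w == window:
                        log.warning(
                            "allele %s(%d)%s on %s too close to sequence end; skipped",
                            anc, col + 1, derived, rep,
                        )
                        ok = False
                        break
                    continue
                probes[w] = seq[pos - flank : pos + flank + 1]
            if not ok or window not in probes:
                continue
            assert probes[window][window // 2] == derived

            # second variant inside the primary window => combination allele
            combination = False
            flank = window // 2
            span_cols = _window_columns(row, col, flank)
            for c2 in span_cols:
                if c2 == col:
                    continue
                m = majority[c2]
                b2 = row[c2]
                if m is not None and b2 not in (GAP, "N") and b2 != m:
                    combination = True
                    break

            shared: list[str] = []
            if universe is not None:
                probe = probes[window]
                carrier_group = set(carriers)
                if tandem_as_one:
                    for c in carriers:
                        p = tandem_pairs.get(c)
                        if p:
                            carrier_group.add(p)
                for rec in universe:
                    if rec.name in carrier_group:
                        continue
                    if occurs_in(probe, rec.sequence, search_rc):
                        shared.append(rec.name)
            alleles.append(
                DiagnosticAllele(
                    provirus=rep,
                    column=col + 1,
                    ancestral_base=anc,
                    derived_base=derived,
                    probes=probes,
                    carriers=carriers,
                    combination=combination,
                    verified_unique=not shared,
                    shared_with=tuple(shared),
                )
            )
    return alleles


def _window_columns(row: str, col: int, flank: int) -> list[int]:
    """Alignment columns spanned by ``flank`` non-gap bases either side of col."""
    cols = [col]
    seen = 0
    c = col - 1
    while c >= 0 and seen < flank:
        if row[c] != GAP:
            seen += 1
            cols.append(c)
        c -= 1
    seen = 0
    c = col + 1
    while c < len(row) and seen < flank:
        if row[c] != GAP:
            seen += 1
            cols.append(c)
        c += 1
    return sorted(cols)


def count_allele_matches(
    fastq_paths: Sequence[str | Path],
    alleles: Sequence[DiagnosticAllele],
    window: int = 31,
    search_rc: bool = True,
    mode: str = "short",
) -> AlleleCountReport:
    """Count reads containing each allele's probe as an exact substring.

    One count per read per allele at most; per-run counts plus the mean
    across runs are reported, mirroring how replicate sequencing runs are
    summarised.
    """
    runs = {}
    for p in fastq_paths:
        if not Path(p).exists():
            raise FileNotFoundError(p)
        runs[Path(p).name] = (seq for _rid, seq, _q in iter_fastq(p))
    return count_allele_matches_records(runs, alleles, window, search_rc, mode)


def count_allele_matches_records(
    named_runs: Mapping[str, Iterable[str]],
    alleles: Sequence[DiagnosticAllele],
    window: int = 31,
    search_rc: bool = True,
    mode: str = "short",
) -> AlleleCountReport:
    """As :func:`count_allele_matches`, over in-memory read sequences per run."""
    usable = [a for a in alleles if window in a.probes]
    if not usable:
        raise ValueError(f"no alleles carry a {window}-nt probe")
    probes = []
    for a in usable:
        p = a.probes[window]
        probes.append((a.key, p, revcomp(p) if search_rc else None))
    counts: dict[str, list[int]] = {a.key: [] for a in usable}
    for _run, seqs in named_runs.items():
        run_counts = Counter()
        for seq in seqs:
            if not seq:
                continue
            for key, fwd, rc in probes:
                if fwd in seq or (rc is not None and rc in seq):
                    run_counts[key] += 1
        for a in usable:
            counts[a.key].append(run_counts[a.key])
    return AlleleCountReport(list(usable), list(named_runs), counts, window, mode)


@dataclass
class MultiAlleleRead:
    """A long read matching unique alleles of two (or more) different proviruses."""

    read_id: str
    proviruses: tuple[str, ...]
    allele_keys: tuple[str, ...]


def detect_multi_allele_reads(
    fastq: str | Path,
    alleles: Sequence[DiagnosticAllele],
    window: int = 11,
    search_rc: bool = True,
) -> list[MultiAlleleRead]:
    """Flag reads carrying unique SNP alleles of >= 2 different proviruses.

    Such reads indicate either an unsequenced shared polymorphism or a
    recombinant transcript; either way the alleles involved are not truly
    diagnostic for the sample at hand.  Alleles whose carrier sets overlap
    (e.g. a tandem pair) never trigger a flag between themselves.
    """
    reads = ((rid, seq) for rid, seq, _q in iter_fastq(fastq))
    return detect_multi_allele_records(reads, alleles, window, search_rc)


def detect_multi_allele_records(
    reads: Iterable[tuple[str, str]],
    alleles: Sequence[DiagnosticAllele],
    window: int = 11,
    search_rc: bool = True,
) -> list[MultiAlleleRead]:
    """As :func:`detect_multi_allele_reads`, over (read_id, sequence) pairs."""
    usable = [a for a in alleles if window in a.probes]
    probes = [
        (a, a.probes[window], revcomp(a.probes[window]) if search_rc else None)
        for a in usable
    ]
    out: list[MultiAlleleRead] = []
    for rid, seq in reads:
        if not seq:
            continue
        hits = [
            a
            for a, fwd, rc in probes
            if fwd in seq or (rc is not None and rc in seq)
        ]
        if len(hits) < 2:
            continue
        groups: list[tuple[DiagnosticAllele, set[str]]] = [
            (a, set(a.carriers)) for a in hits
        ]
        distinct = any(
            g1.isdisjoint(g2)
            for i, (_, g1) in enumerate(groups)
            for _, g2 in groups[i + 1 :]
        )
        if distinct:
            provs = tuple(sorted({a.provirus for a in hits}))
            out.append(MultiAlleleRead(rid, provs, tuple(a.key for a in hits)))
    return out


def alleles_to_frame(alleles: Iterable[DiagnosticAllele]) -> pd.DataFrame:
    """Tabulate alleles (TSV-ready): locus, column, bases, probes, uniqueness."""
    rows = []
    for a in alleles:
        rows.append(
            {
                "provirus": a.provirus,
                "column": a.column,
                "ancestral": a.ancestral_base,
                "derived": a.derived_base,
                "combination": a.combination,
                "verified_unique": a.verified_unique,
                "shared_with": ",".join(a.shared_with),
                **{f"probe{w}": p for w, p in sorted(a.probes.items(), reverse=True)},
            }
        )
    return pd.DataFrame(rows)
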