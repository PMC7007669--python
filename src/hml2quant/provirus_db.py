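"""Data model and I/O for HML-2 provirus sets, the faux genome, and gapped alignments.

HERV-K(HML-2) proviruses are integrated retroviral copies named by
cytogenetic band (e.g. ``12q14.1``).  Locus-resolved expression analysis maps
reads against a "faux genome": an artificial reference built by concatenating
only the provirus sequences, so that every alignment lands inside exactly one
locus interval.  This module holds the record types, the FASTA/TSV/GTF I/O,
and the pairwise-divergence statistic used to characterise how similar the
recently integrated subfamily is.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

_CODON_TABLE = None


def _translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' for stop, 'X' ambiguous)."""
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        _CODON_TABLE = dict(fwd)
        for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon, "X")


@dataclass
class ProvirusRecord:
    """One provirus locus with its annotation flags.

    Parameters
    ----------
    name : str
        Locus identifier, unique within a set (e.g. ``"12q14.1"``).
    sequence : str
        Uppercase DNA over ``{A,C,G,T,N}``.
    chrom_coords : str, optional
        Display-only genomic interval + orientation.
    env_encoding : bool
        Locus carries a (near) full-length *env* ORF.
    env_full_orf : bool
        *env* ORF is complete (no premature stop).
    type1 : bool
        Carries the 292-nt deletion at the *pol*-*env* junction.
    population_frequency : float, optional
        Fraction of individuals carrying the provirus (insertional
        polymorphism), in [0, 1].
    tandem_partner : str, optional
        Name of the other member of a tandem-duplicate pair
        (the 7p22.1a/b situation).
    """

    name: str
    sequence: str
    chrom_coords: str | None = None
    env_encoding: bool = False
    env_full_orf: bool = False
    type1: bool = False
    population_frequency: float | None = None
    tandem_partner: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.name!r}: sequence is empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.name!r}: non-ACGTN characters {sorted(bad)!r}"
            )
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValueError(
                f"record {self.name!r}: population_frequency outside [0,1]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ProvirusSet:
    """Ordered collection of :class:`ProvirusRecord` with unique names."""

    def __init__(self, records: Iterable[ProvirusRecord]):
        self.records: list[ProvirusRecord] = list(records)
        if not self.records:
            raise ValueError("no records")
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate record names: {sorted(dupes)}")
        self._by_name = {r.name: r for r in self.records}
        # tandem links must be symmetric
        for r in self.records:
            if r.tandem_partner is not None:
                partner = self._by_name.get(r.tandem_partner)
                if partner is None or partner.tandem_partner != r.name:
                    raise ValueError(
                        f"tandem_partner link {r.name!r}->{r.tandem_partner!r} "
                        "is not symmetric"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ProvirusRecord:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def env_encoding_names(self) -> list[str]:
        return [r.name for r in self.records if r.env_encoding]

    def subset(self, names: Sequence[str]) -> "ProvirusSet":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"names not in set: {missing}")
        recs = []
        keep = set(names)
        for n in names:
            r = self._by_name[n]
            partner = r.tandem_partner if r.tandem_partner in keep else None
            recs.append(
                ProvirusRecord(
                    name=r.name,
                    sequence=r.sequence,
                    chrom_coords=r.chrom_coords,
                    env_encoding=r.env_encoding,
                    env_full_orf=r.env_full_orf,
                    type1=r.type1,
                    population_frequency=r.population_frequency,
                    tandem_partner=partner,
                )
            )
        return ProvirusSet(recs)


@dataclass
class FauxGenome:
    """Concatenated provirus sequences with per-locus half-open intervals.

    ``intervals`` maps locus name to a 0-based half-open ``(start, end)`` on
    ``sequence``; proviruses are separated by runs of ``spacer_len`` N's.
    """

    sequence: str
    intervals: dict[str, tuple[int, int]]
    spacer_len: int = 0

    def locus_of(self, pos: int) -> str | None:
        """Locus whose interval contains position ``pos``, or None (spacer)."""
        for name, (s, e) in self.intervals.items():
            if s <= pos < e:
                return name
        return None

    def extract(self, name: str) -> str:
        s, e = self.intervals[name]
        return self.sequence[s:e]

    def locus_lengths(self) -> dict[str, int]:
        return {n: e - s for n, (s, e) in self.intervals.items()}


@dataclass
class GappedAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}.

    Columns are 0-based internally; user-facing allele notation such as
    ``G(96)A`` refers to the 1-based column.
    """

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for n, r in zip(self.names, self.rows):
            if len(r) != L:
                raise ValueError(f"ragged alignment row: {n!r}")
        self.rows = [r.upper() for r in self.rows]
        self._by_name = dict(zip(self.names, self.rows))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self._by_name[name]

    def ungapped(self, name: str) -> str:
        return self._by_name[name].replace(GAP, "")

    def subset(self, names: Sequence[str]) -> "GappedAlignment":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"names not in alignment: {missing}")
        return GappedAlignment(list(names), [self._by_name[n] for n in names])

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]


# ---------------------------------------------------------------------------
# I/O


def read_provirus_fasta(
    path: str | Path, metadata: str | Path | None = None
) -> ProvirusSet:
    """Read a provirus FASTA, optionally annotating from a TSV metadata table.

    The metadata table has a header and columns drawn from
    ``name, env_encoding, type1, population_frequency, tandem_partner, coords``;
    names present in the table must be a superset of the FASTA names.
    Unknown flags default to false/absent.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate record name in FASTA: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError("no records")

    meta: dict[str, dict] = {}
    if metadata is not None:
        with open(metadata, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                meta[row["name"]] = row
        missing = [n for n in seqs if n not in meta]
        if missing:
            raise ValueError(f"metadata missing entries for: {missing}")

    def _bool(v: str | None) -> bool:
        return str(v).strip().lower() in {"1", "true", "yes"}

    records = []
    for name, seq in seqs.items():
        m = meta.get(name, {})
        pf = m.get("population_frequency")
        records.append(
            ProvirusRecord(
                name=name,
                sequence=seq,
                chrom_coords=m.get("coords") or None,
                env_encoding=_bool(m.get("env_encoding")),
                env_full_orf=_bool(m.get("env_full_orf")),
                type1=_bool(m.get("type1")),
                population_frequency=float(pf) if pf not in (None, "", "NA") else None,
                tandem_partner=m.get("tandem_partner") or None,
            )
        )
    return ProvirusSet(records)


def write_provirus_fasta(proviruses: ProvirusSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in proviruses
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_gapped_alignment(path: str | Path) -> GappedAlignment:
    """Read a gapped FASTA alignment; ragged rows raise with the row name."""
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise ValueError("no alignment records")
    L = len(rows[0])
    for n, r in zip(names, rows):
        if len(r) != L:
            raise ValueError(f"ragged alignment row: {n!r} ({len(r)} != {L})")
    aln = GappedAlignment(names, rows)
    log.info("read alignment: %d sequences x %d columns", len(aln), aln.n_columns)
    return aln


def write_gapped_alignment(aln: GappedAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Faux genome


def build_faux_genome(
    proviruses: ProvirusSet, spacer_len: int = 100
) -> tuple[FauxGenome, str]:
    """Concatenate proviruses (input order) with N-spacers; emit GTF annotation.

    Returns the :class:`FauxGenome` and a GTF string (1-based inclusive, one
    ``exon`` feature per locus, ``gene_id`` = locus name) usable by external
    counters such as featureCounts.
    """
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    parts: list[str] = []
    intervals: dict[str, tuple[int, int]] = {}
    pos = 0
    spacer = "N" * spacer_len
    for i, rec in enumerate(proviruses):
        if i > 0 and spacer_len:
            parts.append(spacer)
            pos += spacer_len
        start = pos
        parts.append(rec.sequence)
        pos += len(rec.sequence)
        intervals[rec.name] = (start, pos)
    genome = FauxGenome("".join(parts), intervals, spacer_len)

    gtf_lines = []
    for name, (s, e) in intervals.items():
        gtf_lines.append(
            "\t".join(
                [
                    "faux",
                    "hml2quant",
                    "exon",
                    str(s + 1),  # GTF is 1-based inclusive
                    str(e),
                    ".",
                    "+",
                    ".",
                    f'gene_id "{name}"; transcript_id "{name}";',
                ]
            )
        )
    return genome, "\n".join(gtf_lines) + "\n"


def read_gtf_intervals(gtf_text: str) -> dict[str, tuple[int, int]]:
    """Parse the faux-genome GTF back into 0-based half-open intervals."""
    intervals: dict[str, tuple[int, int]] = {}
    for line in gtf_text.strip().splitlines():
        f = line.split("\t")
        attrs = f[8]
        name = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
        intervals[name] = (int(f[3]) - 1, int(f[4]))
    return intervals


# ---------------------------------------------------------------------------
# Divergence


def pairwise_divergence(
    aln: GappedAlignment,
    subset: Sequence[str] | None = None,
    level: str = "nucleotide",
) -> float:
    """Mean pairwise divergence over all unordered row pairs.

    Nucleotide level: per pair, mismatches / compared sites, where any site
    with a gap in either row is excluded.  Amino-acid level: rows must keep
    frame (gaps in multiples of 3 as laid out in the alignment); codons are
    compared after translation, codons containing a gap in either row are
    excluded, and a stop codon mismatches every residue including another
    stop (degraded sequence, not a conserved state).
    """
    sub = aln if subset is None else aln.subset(list(subset))
    if len(sub) < 2:
        raise ValueError("need at least two rows")
    if level not in ("nucleotide", "amino-acid"):
        raise ValueError(f"unknown level {level!r}")

    divs = []
    n = len(sub)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sub.rows[i], sub.rows[j]
            if level == "nucleotide":
                pairs = [
                    (x, y) for x, y in zip(a, b) if x != GAP and y != GAP
                ]
                if not pairs:
                    continue
                mism = sum(x != y for x, y in pairs)
                divs.append(mism / len(pairs))
            else:
                compared = mism = 0
                for k in range(0, sub.n_columns - 2, 3):
                    ca, cb = a[k : k + 3], b[k : k + 3]
                    if GAP in ca or GAP in cb or "N" in ca or "N" in cb:
                        continue
                    ra, rb = _translate_codon(ca), _translate_codon(cb)
                    compared += 1
                    if ra != rb or ra == "*" or rb == "*":
                        mism += 1
                if compared:
                    divs.append(mism / compared)
    if not divs:
        raise ValueError("no comparable sites in any pair")
    return float(sum(divs) / len(divs))
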