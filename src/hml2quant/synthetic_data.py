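"""Synthetic provirus families, genomes, expression profiles, and reads.

The generator emulates the statistical structure the locus-resolved analysis
has to cope with in the HML-2 family:

* a *young* subfamily of recently integrated, barely diverged proviruses
  (mean pairwise divergence ~1.5% nt), organised as sister pairs on a
  two-level star phylogeny — recent duplications and near-twin integrations
  leave some pairs only a few substitutions apart, which is what makes
  unique-read counting collapse;
* *old* proviruses diverged up to ~15%, often truncated (internal sequence
  missing, the solo-LTR-like degradation class);
* a tandem-duplicate pair with an identical *env* region;
* type-1 loci carrying the 292-nt deletion at the *pol*-*env* junction;
* premature stop codons, APOBEC3G-style G->A hypermutated loci;
* insertional polymorphism (per-locus population frequency, so loci can be
  absent from a simulated genome);
* SNP alleles secretly shared between loci — either visible in the
  reference set (uniqueness check catches them) or *cryptic* (only the
  sampled genome's copy carries the window, reproducing the
  misattribution artifact where an absent locus collects read counts);
* expression dominated by a few loci (Dirichlet with small concentration);
* short reads (median ~110 nt, low substitution error) and long reads
  (mean ~2 kb, error high enough that most reads fall below 90% identity),
  both with optional template-switch recombinants.

Errors are substitution-only so exact k-mer counting has the analytic
expectation P(probe intact) = (1 - e)^k.  Truth tables record per-locus
presence and expression and per-read source labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostic_alleles import revcomp
from .provirus_db import GappedAlignment, ProvirusRecord, ProvirusSet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
DECOY = "__decoy__"


@dataclass(frozen=True)
class SharedAllelePlanting:
    """A SNP window deliberately shared between two loci.

    ``carrier`` is the locus the allele looks unique to; ``other`` also
    carries the identical 31-nt window.  With ``cryptic=False`` the sharing
    is visible in the reference set (the uniqueness check must catch it);
    with ``cryptic=True`` only the sampled genome's copy of ``other``
    carries the window — an unsequenced shared polymorphism, invisible to
    verification, that misattributes reads to ``carrier``.
    """

    env_offset: int  # 0-based position within the env region
    base: str | None  # None: pick a base absent from every young locus there
    carrier: str
    other: str
    cryptic: bool = False


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions being emulated."""

    # family structure
    n_young: int = 8
    young_divergence: float = 0.015  # target mean pairwise, young subfamily
    young_sister_divergence: float | None = 0.002  # None -> one-level star
    n_old: int = 12
    old_divergence: float = 0.15
    n_hypermutated: int = 0
    hypermut_rate: float = 0.3
    # locus geometry
    ancestral_len: int = 6000
    env_start: int = 3000
    env_len: int = 2100  # multiple of 3; in-frame ORF
    old_len_range: tuple[int, int] = (2000, 6000)
    type1_fraction: float = 0.4
    type1_del_len: int = 292
    premature_stop_rate: float = 0.15
    tandem_dup: bool = True
    tandem_extra_diffs: int = 2  # outside env, so env stays identical
    # insertional polymorphism
    polymorphic_fraction: float = 0.1
    polymorphic_freq: float = 0.5
    population_frequency_overrides: dict[str, float] = field(default_factory=dict)
    # shared-allele plantings
    shared_alleles: tuple[SharedAllelePlanting, ...] = ()
    # expression
    expression_alpha: float = 0.3  # small -> a few dominant loci
    expression_proportions: dict[str, float] | None = None
    # reads
    n_short_reads: int = 50_000
    short_len_median: int = 110
    short_len_sd: int = 25
    short_error_rate: float = 0.005
    n_long_reads: int = 2_000
    long_len_mean: int = 2_000
    long_len_sd: int = 900
    long_error_rate: float = 0.12
    recombinant_fraction: float = 0.0
    # enrichment background
    background_fraction: float = 0.0
    decoy_len: int = 5_000
    spacer_len: int = 100

    def __post_init__(self) -> None:
        if self.n_young < 2:
            raise ValueError("need at least 2 young loci")
        if self.env_len % 3:
            raise ValueError("env_len must be a multiple of 3")
        if self.env_start + self.env_len > self.ancestral_len:
            raise ValueError("env region exceeds ancestral length")
        for name, frac in [
            ("young_divergence", self.young_divergence),
            ("old_divergence", self.old_divergence),
            ("polymorphic_fraction", self.polymorphic_fraction),
            ("recombinant_fraction", self.recombinant_fraction),
            ("background_fraction", self.background_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if self.tandem_dup and self.n_young < 4:
            raise ValueError("tandem_dup needs n_young >= 4")


def reference_family_config() -> SimConfig:
    """The 95-locus reference configuration: a full-size synthetic family.

    20 young loci (10 sister pairs, one of them the tandem duplicate with
    identical env; 12 of them type 1, leaving 8 Env-encoding), 2
    hypermutated young-clade loci excluded from the env alignment, and 73
    old, partially truncated loci.
    """
    return SimConfig(
        n_young=20,
        n_old=73,
        n_hypermutated=2,
        hypermut_rate=0.3,
        type1_fraction=0.6,
        polymorphic_fraction=0.15,
    )


@dataclass
class SimFamily:
    """A generated provirus family with its true env alignment."""

    proviruses: ProvirusSet
    env_alignment: GappedAlignment
    cfg: SimConfig
    young_names: list[str]
    old_names: list[str]
    hypermut_names: list[str]
    # ancestral-coordinate bookkeeping for coordinate mapping
    type1_names: set[str]
    old_windows: dict[str, tuple[int, int]]

    def final_pos(self, name: str, anc_pos: int) -> int:
        """Map an ancestral coordinate to the locus's final sequence coordinate.

        Raises ValueError when the position was deleted or truncated away.
        """
        cfg = self.cfg
        if name in self.old_windows:
            s, e = self.old_windows[name]
            if not s <= anc_pos < e:
                raise ValueError(f"position {anc_pos} truncated away in {name}")
            return anc_pos - s
        if name in self.type1_names:
            d0, d1 = cfg.env_start, cfg.env_start + cfg.type1_del_len
            if d0 <= anc_pos < d1:
                raise ValueError(f"position {anc_pos} inside type-1 deletion of {name}")
            return anc_pos - cfg.type1_del_len if anc_pos >= d1 else anc_pos
        return anc_pos


@dataclass
class SimGenome:
    """One sampled genome: locus presence, per-copy sequences, expression."""

    present: list[str]
    sequences: dict[str, str]  # genome copies (may differ from the reference set)
    proportions: dict[str, float]  # over present loci, sums to 1
    decoy: str | None = None


def _branch_p(pairwise_d: float) -> float:
    """Per-branch substitution probability for a star giving observed pairwise d.

    Two branches of rate p observe P(differ) = 2p - (4/3)p^2 (same-site double
    hits agree with probability 1/3); inverted for p.
    """
    if pairwise_d <= 0:
        return 0.0
    disc = 4.0 - (16.0 / 3.0) * pairwise_d
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def _mutate(
    arr: np.ndarray,
    p: float,
    rng: np.random.Generator,
    strata: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Substitute sites at density p (to a different base), stratified.

    Each stratum receives an exact round(len * p) substitutions at uniform
    positions; without strata the whole sequence is one stratum.  Fixing the
    per-branch count (rather than drawing it binomially) keeps the realized
    divergence of every emitted alignment tight around its target, which is
    the generator's calibration contract.
    """
    out = arr.copy()
    if p <= 0:
        return out
    if strata is None:
        strata = [(0, len(arr))]
    for s, e in strata:
        n = int(round((e - s) * p))
        if n == 0:
            continue
        pos = s + rng.choice(e - s, size=n, replace=False)
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(BASES, out[pos])
        out[pos] = BASES[(idx + shift) % 4]
    return out


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons: an open reading frame with no internal stop."""
    codons = ["ATG"]
    alphabet = "ACGT"
    while len(codons) < n_codons:
        c = "".join(alphabet[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_family(cfg: SimConfig, seed: int) -> SimFamily:
    """Generate the provirus family and its true (gap-consistent) env alignment.

    Young loci sit on a two-level star phylogeny: ancestral sequence ->
    sister-pair ancestors -> tips, with branch rates solved so the realized
    mean pairwise divergence of the young env alignment matches
    ``cfg.young_divergence`` (within sampling error).  Old loci are single
    branches from the ancestor with ``cfg.old_divergence`` pairwise, then
    truncated to a random window.  Deletions, stops, hypermutation and
    shared-allele windows are applied in ancestral coordinates before
    materialisation, so the emitted alignment stays gap-consistent.
    """
    rng = np.random.default_rng(seed)
    cfg = replace(cfg)  # defensive copy

    anc = np.empty(cfg.ancestral_len, dtype=np.uint8)
    anc[:] = BASES[rng.integers(0, 4, size=cfg.ancestral_len)]
    env = _random_orf(cfg.env_len // 3, rng)
    anc[cfg.env_start : cfg.env_start + cfg.env_len] = np.frombuffer(
        env.encode(), dtype=np.uint8
    )
    strata = [
        (0, cfg.env_start),
        (cfg.env_start, cfg.env_start + cfg.env_len),
        (cfg.env_start + cfg.env_len, cfg.ancestral_len),
    ]

    # --- young subfamily: sister pairs (two-level star) -------------------
    n = cfg.n_young
    k_pairs = n // 2
    singleton = n % 2 == 1
    d_w = cfg.young_sister_divergence
    C = n * (n - 1) // 2
    names_young: list[str] = []
    arrays: dict[str, np.ndarray] = {}
    tandem_pair: tuple[str, str] | None = None

    if d_w is None:
        p_tip = _branch_p(cfg.young_divergence)
        for i in range(n):
            name = f"Y{i + 1}"
            names_young.append(name)
            arrays[name] = _mutate(anc, p_tip, rng, strata)
    else:
        n_within = k_pairs  # within-pair comparisons
        tandem_within = 1 if cfg.tandem_dup else 0
        if C == n_within:
            raise ValueError("no between-pair comparisons; increase n_young")
        d_b = (C * cfg.young_divergence - (n_within - tandem_within) * d_w) / (
            C - n_within
        )
        if d_b <= d_w:
            raise ValueError(
                "young_divergence too small for the requested sister divergence"
            )
        p_t = d_w / 2.0
        p_a = d_b / 2.0 - p_t
        pair_defs: list[int] = [2] * k_pairs + ([1] if singleton else [])
        pair_idx = 0
        for size in pair_defs:
            pair_idx += 1
            pair_anc = _mutate(anc, p_a, rng, strata)
            is_tandem = cfg.tandem_dup and size == 2 and pair_idx == k_pairs
            if is_tandem:
                a_name, b_name = f"Y{pair_idx}a", f"Y{pair_idx}b"
                tip = _mutate(pair_anc, p_t, rng, strata)
                twin = tip.copy()
                # a handful of differences outside env: the env stays identical
                outside = np.concatenate(
                    [
                        np.arange(0, cfg.env_start),
                        np.arange(cfg.env_start + cfg.env_len, cfg.ancestral_len),
                    ]
                )
                for pos in rng.choice(
                    outside, size=cfg.tandem_extra_diffs, replace=False
                ):
                    idx = int(np.searchsorted(BASES, twin[pos]))
                    twin[pos] = BASES[(idx + int(rng.integers(1, 4))) % 4]
                arrays[a_name], arrays[b_name] = tip, twin
                names_young += [a_name, b_name]
                tandem_pair = (a_name, b_name)
            elif size == 2:
                a_name, b_name = f"Y{pair_idx}a", f"Y{pair_idx}b"
                arrays[a_name] = _mutate(pair_anc, p_t, rng, strata)
                arrays[b_name] = _mutate(pair_anc, p_t, rng, strata)
                names_young += [a_name, b_name]
            else:
                name = f"Y{pair_idx}"
                arrays[name] = _mutate(pair_anc, p_t, rng, strata)
                names_young.append(name)

    # --- hypermutated young-clade loci (excluded from the env alignment) --
    names_hyper: list[str] = []
    p_y = _branch_p(cfg.young_divergence)
    for i in range(cfg.n_hypermutated):
        name = f"H{i + 1}"
        arr = _mutate(anc, p_y, rng, strata)
        g_sites = np.flatnonzero(arr == ord("G"))
        hit = g_sites[rng.random(len(g_sites)) < cfg.hypermut_rate]
        arr[hit] = ord("A")
        arrays[name] = arr
        names_hyper.append(name)

    # --- old, diverged, truncated loci ------------------------------------
    names_old: list[str] = []
    old_windows: dict[str, tuple[int, int]] = {}
    p_old = _branch_p(cfg.old_divergence)
    lo, hi = cfg.old_len_range
    hi = min(hi, cfg.ancestral_len)
    for i in range(cfg.n_old):
        name = f"O{i + 1}"
        arr = _mutate(anc, p_old, rng, strata)
        olen = int(rng.integers(lo, hi + 1))
        ostart = int(rng.integers(0, cfg.ancestral_len - olen + 1))
        arrays[name] = arr
        old_windows[name] = (ostart, ostart + olen)
        names_old.append(name)

    # --- type-1 deletions and premature stops -----------------------------
    eligible = [
        nm for nm in names_young if tandem_pair is None or nm not in tandem_pair
    ]
    n_type1 = min(int(round(cfg.type1_fraction * n)), len(eligible))
    type1_names = set(
        rng.choice(eligible, size=n_type1, replace=False).tolist()
    ) if n_type1 else set()

    stop_names: set[str] = set()
    n_codons = cfg.env_len // 3
    for nm in names_young:
        if nm in type1_names or (tandem_pair and nm in tandem_pair):
            continue
        if rng.random() < cfg.premature_stop_rate:
            codon = int(rng.integers(10, n_codons - 10))
            pos = cfg.env_start + 3 * codon
            arrays[nm][pos : pos + 3] = np.frombuffer(b"TAA", dtype=np.uint8)
            stop_names.add(nm)

    # --- shared-allele plantings (ancestral coordinates) ------------------
    flank = 15
    for pl in cfg.shared_alleles:
        for nm in (pl.carrier, pl.other):
            if nm not in arrays:
                raise ValueError(f"shared-allele locus {nm!r} not in family")
        pos = cfg.env_start + pl.env_offset
        if not 0 <= pl.env_offset < cfg.env_len:
            raise ValueError("shared-allele env_offset outside env region")
        for nm in (pl.carrier, pl.other):
            if nm in type1_names and pos < cfg.env_start + cfg.type1_del_len:
                raise ValueError(
                    f"shared-allele window deleted in type-1 locus {nm!r}"
                )
            if nm in old_windows:
                s, e = old_windows[nm]
                if not (s + flank <= pos < e - flank):
                    raise ValueError(
                        f"shared-allele window outside truncated locus {nm!r}"
                    )
        young_bases = {chr(arrays[nm][pos]) for nm in names_young}
        if pl.base is None:
            free = [b for b in "ACGT" if b not in young_bases]
            if not free:
                raise ValueError(
                    f"no free base at env offset {pl.env_offset}; move the planting"
                )
            derived = free[0]
        else:
            derived = pl.base.upper()
            others = {
                chr(arrays[nm][pos]) for nm in names_young if nm != pl.carrier
            }
            if derived in others:
                raise ValueError(
                    f"planted base {derived!r} at env offset {pl.env_offset} is "
                    "not distinct among young loci (use base=None to auto-pick)"
                )
        arrays[pl.carrier][pos] = ord(derived)
        if not pl.cryptic:
            w = arrays[pl.carrier][pos - flank : pos + flank + 1]
            arrays[pl.other][pos - flank : pos + flank + 1] = w

    # --- materialise records and the env alignment ------------------------
    del0, del1 = cfg.env_start, cfg.env_start + cfg.type1_del_len
    records: list[ProvirusRecord] = []
    aln_names: list[str] = []
    aln_rows: list[str] = []
    pop_freq: dict[str, float] = {}
    all_names = names_young + names_hyper + names_old
    n_poly = int(round(cfg.polymorphic_fraction * len(all_names)))
    poly = set(rng.choice(all_names, size=n_poly, replace=False).tolist()) if n_poly else set()
    for nm in all_names:
        pop_freq[nm] = cfg.polymorphic_freq if nm in poly else 1.0
    pop_freq.update(cfg.population_frequency_overrides)

    for nm in names_young:
        arr = arrays[nm]
        env_chars = _arr_to_str(arr[cfg.env_start : cfg.env_start + cfg.env_len])
        if nm in type1_names:
            seq = _arr_to_str(np.concatenate([arr[:del0], arr[del1:]]))
            row = "-" * cfg.type1_del_len + env_chars[cfg.type1_del_len :]
        else:
            seq = _arr_to_str(arr)
            row = env_chars
        aln_names.append(nm)
        aln_rows.append(row)
        is_tandem = tandem_pair is not None and nm in tandem_pair
        records.append(
            ProvirusRecord(
                name=nm,
                sequence=seq,
                env_encoding=nm not in type1_names,
                env_full_orf=nm not in type1_names and nm not in stop_names,
                type1=nm in type1_names,
                population_frequency=pop_freq[nm],
                tandem_partner=(
                    tandem_pair[1] if is_tandem and nm == tandem_pair[0]
                    else tandem_pair[0] if is_tandem else None
                ),
            )
        )
    for nm in names_hyper:
        records.append(
            ProvirusRecord(
                name=nm,
                sequence=_arr_to_str(arrays[nm]),
                population_frequency=pop_freq[nm],
            )
        )
    for nm in names_old:
        s, e = old_windows[nm]
        records.append(
            ProvirusRecord(
                name=nm,
                sequence=_arr_to_str(arrays[nm][s:e]),
                population_frequency=pop_freq[nm],
            )
        )

    return SimFamily(
        proviruses=ProvirusSet(records),
        env_alignment=GappedAlignment(aln_names, aln_rows),
        cfg=cfg,
        young_names=names_young,
        old_names=names_old,
        hypermut_names=names_hyper,
        type1_names=type1_names,
        old_windows=old_windows,
    )


def simulate_genome(family: SimFamily, seed: int) -> SimGenome:
    """Draw one genome: locus presence, genome copies, expression proportions.

    Presence is Bernoulli per locus at its population frequency.  Cryptic
    shared-allele plantings splice the carrier's 31-nt window into the
    genome copy of the sharing locus (the reference set stays unchanged).
    A cryptic planting whose expressed sharer is absent is a contradictory
    configuration and raises.
    """
    cfg = family.cfg
    rng = np.random.default_rng(seed)
    present: list[str] = []
    for rec in family.proviruses:
        f = rec.population_frequency if rec.population_frequency is not None else 1.0
        if f >= 1.0 or rng.random() < f:
            present.append(rec.name)
    if not present:
        raise ValueError("no loci present in the sampled genome")

    sequences = {nm: family.proviruses[nm].sequence for nm in present}
    flank = 15
    for pl in cfg.shared_alleles:
        if not pl.cryptic:
            continue
        if pl.other not in sequences:
            raise ValueError(
                f"cryptic shared allele on absent locus {pl.other!r}"
            )
        anc_pos = cfg.env_start + pl.env_offset
        carrier_seq = family.proviruses[pl.carrier].sequence
        c_pos = family.final_pos(pl.carrier, anc_pos)
        window = carrier_seq[c_pos - flank : c_pos + flank + 1]
        o_pos = family.final_pos(pl.other, anc_pos)
        s = sequences[pl.other]
        sequences[pl.other] = s[: o_pos - flank] + window + s[o_pos + flank + 1 :]

    if cfg.expression_proportions is not None:
        props = {
            nm: max(0.0, cfg.expression_proportions.get(nm, 0.0)) for nm in present
        }
        total = sum(props.values())
        if total <= 0:
            raise ValueError("explicit expression proportions are zero over present loci")
        props = {nm: v / total for nm, v in props.items() if v > 0}
    else:
        draw = rng.dirichlet([cfg.expression_alpha] * len(present))
        props = dict(zip(present, draw.tolist()))

    decoy = None
    if cfg.background_fraction > 0:
        decoy = _arr_to_str(BASES[rng.integers(0, 4, size=cfg.decoy_len)])
    return SimGenome(present, sequences, props, decoy)


def simulate_reads(
    family: SimFamily,
    genome: SimGenome,
    seed: int,
    kind: str = "short",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate reads from the genome's expressed loci, with truth labels.

    Sources are multinomial over the expression proportions; fragment starts
    are uniform within each locus; errors are i.i.d. substitutions at the
    configured rate, with the Phred quality string encoding that true rate.
    A ``recombinant_fraction`` of reads template-switch between two distinct
    full-length young loci at a uniform breakpoint; a
    ``background_fraction`` is drawn from the decoy (off-target) sequence.
    Reads are emitted on a random strand.  The truth frame has one row per
    read: source, secondary source, breakpoint (read coordinate; -1 if
    none), start, length, n_errors.
    """
    cfg = family.cfg
    if kind == "short":
        n, err = cfg.n_short_reads, cfg.short_error_rate
    elif kind == "long":
        n, err = cfg.n_long_reads, cfg.long_error_rate
    else:
        raise ValueError(f"unknown read kind {kind!r}")
    if n <= 0:
        raise ValueError("number of reads must be positive")
    rng = np.random.default_rng(seed)

    loci = list(genome.proportions)
    probs = np.array([genome.proportions[nm] for nm in loci])
    probs = probs / probs.sum()
    seq_arrays = {
        nm: np.frombuffer(genome.sequences[nm].encode(), dtype=np.uint8)
        for nm in loci
    }
    recomb_ok = [
        nm
        for nm in loci
        if nm in family.young_names
        and nm not in family.type1_names
        and genome.proportions[nm] > 0
    ]

    qual_char = chr(
        33 + (40 if err <= 0 else max(2, min(40, int(round(-10 * math.log10(err))))))
    )

    def _length(src_len: int) -> int:
        if kind == "short":
            ln = int(round(rng.normal(cfg.short_len_median, cfg.short_len_sd)))
            ln = max(50, min(200, ln))
        else:
            ln = int(round(rng.normal(cfg.long_len_mean, cfg.long_len_sd)))
            ln = max(200, ln)
        return min(ln, src_len)

    n_bg = rng.binomial(n, cfg.background_fraction) if genome.decoy else 0
    n_fam = n - n_bg
    n_rec = (
        rng.binomial(n_fam, cfg.recombinant_fraction) if len(recomb_ok) >= 2 else 0
    )
    sources = rng.choice(len(loci), size=n_fam, p=probs)

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    decoy_arr = (
        np.frombuffer(genome.decoy.encode(), dtype=np.uint8) if genome.decoy else None
    )

    def _emit(rid: str, frag: np.ndarray, src: str, src2: str, bp: int, start: int):
        n_err = 0
        if err > 0:
            mask = rng.random(len(frag)) < err
            n_err = int(mask.sum())
            if n_err:
                frag = frag.copy()
                pos = np.flatnonzero(mask)
                idx = np.searchsorted(BASES, frag[pos])
                frag[pos] = BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]
        seq = _arr_to_str(frag)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((rid, seq, qual_char * len(seq)))
        truth_rows.append(
            {
                "read_id": rid,
                "source": src,
                "source2": src2,
                "breakpoint": bp,
                "start": start,
                "length": len(seq),
                "n_errors": n_err,
            }
        )

    for i in range(n_fam):
        rid = f"{kind}_{i:07d}"
        if i < n_rec:
            a, b = rng.choice(len(recomb_ok), size=2, replace=False)
            sa, sb = recomb_ok[int(a)], recomb_ok[int(b)]
            arr_a, arr_b = seq_arrays[sa], seq_arrays[sb]
            max_len = min(len(arr_a), len(arr_b))
            ln = _length(max_len)
            start = int(rng.integers(0, max_len - ln + 1))
            bp = int(rng.integers(10, ln - 9))
            frag = np.concatenate(
                [arr_a[start : start + bp], arr_b[start + bp : start + ln]]
            )
            _emit(rid, frag, sa, sb, bp, start)
        else:
            src = loci[int(sources[i])]
            arr = seq_arrays[src]
            ln = _length(len(arr))
            start = int(rng.integers(0, len(arr) - ln + 1))
            _emit(rid, arr[start : start + ln], src, "", -1, start)

    for i in range(n_bg):
        rid = f"{kind}_bg_{i:07d}"
        ln = _length(len(decoy_arr))
        start = int(rng.integers(0, len(decoy_arr) - ln + 1))
        _emit(rid, decoy_arr[start : start + ln], DECOY, "", -1, start)

    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# End-to-end recovery harness


def _spawn_seeds(seed: int, k: int) -> list[int]:
    """Derive k child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(k)]


def true_rpkm_proportions(
    family: SimFamily, genome: SimGenome
) -> dict[str, float]:
    """Expression truth in RPKM space: p_i / length_i, renormalised, absent = 0."""
    lengths = {r.name: len(r.sequence) for r in family.proviruses}
    raw = {
        nm: genome.proportions.get(nm, 0.0) / lengths[nm]
        for nm in family.proviruses.names
    }
    total = sum(raw.values())
    return {nm: v / total for nm, v in raw.items()}


def end_to_end_recovery(
    cfg: SimConfig,
    seed: int,
    policies: Sequence[str] = ("random_multimap", "unique_only", "count_all", "proportional"),
    max_edit_frac: float = 0.25,
    include_alleles: bool = True,
) -> dict:
    """Simulate -> align (built-in) -> count under each policy -> normalise,
    plus the diagnostic-allele route, against the simulator's truth.

    Returns a report dict with the truth (count-space and RPKM-space
    proportions, young-subfamily share, Env fraction), the per-policy
    estimates and their errors, and (optionally) the discovered alleles with
    their short-read counts.
    """
    from .provirus_db import build_faux_genome
    from .quantify_stats import env_fraction, rpkm
    from .read_processing import align_reads, assign_counts
    from .diagnostic_alleles import count_allele_matches_records, find_unique_alleles

    s_fam, s_gen, s_reads, s_assign = _spawn_seeds(seed, 4)
    family = simulate_family(cfg, s_fam)
    genome = simulate_genome(family, s_gen)
    reads, truth = simulate_reads(family, genome, s_reads, kind="short")

    faux, _gtf = build_faux_genome(family.proviruses, cfg.spacer_len)
    hits = align_reads(((rid, seq) for rid, seq, _q in reads), faux, max_edit_frac)

    all_names = family.proviruses.names
    lengths = faux.locus_lengths()
    young = set(family.young_names)
    env_set = family.proviruses.env_encoding_names

    truth_props = {nm: genome.proportions.get(nm, 0.0) for nm in all_names}
    truth_rpkm = true_rpkm_proportions(family, genome)
    truth_young_share = sum(v for nm, v in truth_props.items() if nm in young)
    truth_env_frac = sum(truth_rpkm[nm] for nm in env_set)

    report: dict = {
        "family": family,
        "genome": genome,
        "reads": reads,
        "truth": truth,
        "hits": hits,
        "n_mapped": len(hits),
        "truth_count_proportions": truth_props,
        "truth_rpkm_proportions": truth_rpkm,
        "truth_young_share": truth_young_share,
        "truth_env_fraction": truth_env_frac,
        "policies": {},
    }
    for policy in policies:
        table = assign_counts(hits, all_names, policy=policy, seed=s_assign)
        total = table.total_assigned
        count_props = {nm: table[nm] / total for nm in all_names} if total else {}
        profile = rpkm(table, lengths, source=policy)
        rp = profile.proportions()
        report["policies"][policy] = {
            "counts": table,
            "count_proportions": count_props,
            "rpkm_proportions": rp,
            "young_share": sum(v for nm, v in count_props.items() if nm in young),
            "env_fraction": env_fraction(profile, env_set) if env_set else float("nan"),
            "max_abs_err_rpkm": max(
                abs(rp[nm] - truth_rpkm[nm]) for nm in all_names
            ),
        }
    if include_alleles:
        alleles = find_unique_alleles(
            family.env_alignment, family.proviruses, window=31
        )
        verified = [a for a in alleles if a.verified_unique]
        report["alleles"] = alleles
        report["allele_counts"] = (
            count_allele_matches_records(
                {"run1": [seq for _r, seq, _q in reads]}, verified, window=31
            )
            if verified
            else None
        )
    return report
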