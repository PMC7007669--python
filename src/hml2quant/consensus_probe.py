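"""Enrichment-bait consensus construction and tiling-probe layout.

Targeted RNA enrichment for the HML-2 family uses baits tiled across a single
consensus of the internal (LTR-free) regions of the recently integrated
proviruses.  The consensus here is mechanical majority rule: columns where
gaps are in the majority are dropped, otherwise the most frequent base among
non-gap rows is emitted (ties broken A<C<G<T).  Probes of a fixed length are
laid out with a tiling factor ``t`` so each interior consensus position is
covered by exactly ``t`` probes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .provirus_db import GAP, GappedAlignment

_BASE_ORDER = "ACGTN"


@dataclass
class ConsensusResult:
    """Majority-rule consensus with per-column support.

    ``per_column_support[i]`` is the fraction of non-gap rows agreeing with
    the emitted base at consensus position ``i`` (in (0, 1]).
    """

    sequence: str
    per_column_support: list[float]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeSet:
    """Tiling probes as (start, length) intervals on the consensus."""

    probes: list[tuple[int, int]]
    tile_factor: int
    probe_len: int

    def __len__(self) -> int:
        return len(self.probes)

    def coverage(self, consensus_len: int) -> list[int]:
        """Per-position probe coverage over the consensus."""
        cov = [0] * consensus_len
        for s, ln in self.probes:
            for p in range(s, min(s + ln, consensus_len)):
                cov[p] += 1
        return cov

    def to_bed(self, name: str = "consensus") -> str:
        lines = [
            f"{name}\t{s}\t{s + ln}\tprobe_{i}"
            for i, (s, ln) in enumerate(self.probes)
        ]
        return "\n".join(lines) + "\n"


def build_consensus(
    aln: GappedAlignment,
    subset: Sequence[str] | None = None,
    min_nongap_fraction: float = 0.5,
) -> ConsensusResult:
    """Majority-rule consensus of an alignment (optionally a row subset).

    A column is dropped when the non-gap fraction is below
    ``min_nongap_fraction`` (default: drop gap-majority columns).  Among
    non-gap rows the most frequent base wins; ties break in fixed base order
    A<C<G<T so the result is deterministic and row-order invariant.
    """
    sub = aln if subset is None else aln.subset(list(subset))
    if len(sub) < 2:
        raise ValueError("need at least two rows to build a consensus")
    seq_chars: list[str] = []
    support: list[float] = []
    n_rows = len(sub)
    for col in range(sub.n_columns):
        bases = [r[col] for r in sub.rows if r[col] != GAP]
        if len(bases) / n_rows < min_nongap_fraction or not bases:
            continue
        counts = Counter(bases)
        best = max(counts, key=lambda b: (counts[b], -_BASE_ORDER.index(b)))
        seq_chars.append(best)
        support.append(counts[best] / len(bases))
    if not seq_chars:
        raise ValueError("alignment is all gaps; no consensus columns")
    return ConsensusResult("".join(seq_chars), support)


def design_tiling_probes(
    consensus: ConsensusResult | str, probe_len: int = 120, tile_factor: int = 10
) -> ProbeSet:
    """Lay out probes start 0, step ``probe_len // tile_factor``, last right-aligned.

    Interior consensus positions (further than ``probe_len`` from either end)
    are covered by exactly ``tile_factor`` probes.
    """
    L = len(consensus.sequence if isinstance(consensus, ConsensusResult) else consensus)
    if probe_len > L:
        raise ValueError(f"probe_len {probe_len} exceeds consensus length {L}")
    if tile_factor < 1:
        raise ValueError("tile_factor must be >= 1")
    step = probe_len // tile_factor
    if step < 1:
        step = 1
    starts = list(range(0, L - probe_len + 1, step))
    last = L - probe_len
    if starts[-1] != last:
        starts.append(last)  # right-align the final probe
    return ProbeSet([(s, probe_len) for s in starts], tile_factor, probe_len)
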