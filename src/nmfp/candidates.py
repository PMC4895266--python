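"""From binary G columns to a filtered, frequency-ranked isoform candidate pool.

A fitted NMF run yields a binary bin-membership matrix G whose columns are
raw isoform candidates over bins.  Each column is translated into
subexon-inclusion vectors: bins assert their boundary subexons present and
the subexons they span skipped; a subexon asserted both present and skipped
by different included bins is *ambiguous*, and both statuses are expanded
(up to ``2^#ambiguous`` vectors, capped).  Candidates whose implied splice
junctions lack spliced-read support are discarded.

Because NMF solutions are not unique, the estimation is repeated for N
independently seeded runs and candidates are pooled; only high-frequency
candidates, produced in at least r of the N runs, survive.  The pool is
returned ranked by run frequency (descending, ties broken by inclusion
vector) — the reduced search space handed to downstream isoform-discovery
methods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .binning import BinScheme, CountMatrix, NormalizedMatrix
from .gene_model import GeneModel, Isoform
from .nmf import NMFConfig, fit, select_rank

__all__ = [
    "IsoformCandidate",
    "JunctionSupport",
    "PipelineConfig",
    "column_to_candidates",
    "junction_supported",
    "candidate_junctions",
    "rank_selection_policy",
    "run_nmfp",
]


@dataclass(frozen=True)
class IsoformCandidate:
    """A candidate isoform with its multi-run frequency and support flag."""

    inclusion: tuple[int, ...]
    frequency: int = 1
    supported: bool = True

    def __post_init__(self) -> None:
        if not any(self.inclusion):
            raise ValueError("candidate must include at least one subexon")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")

    @property
    def bits(self) -> str:
        return "".join(str(v) for v in self.inclusion)

    def to_isoform(self, gene_id: str, label: str = "") -> Isoform:
        return Isoform(gene_id, self.inclusion, label or self.bits)


@dataclass
class JunctionSupport:
    """Spliced-read counts per junction (donor subexon, acceptor subexon)."""

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    min_reads: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("junction counts must be non-negative")

    def supported(self, a: int, b: int) -> bool:
        return self.counts.get((a, b), 0) >= self.min_reads

    @classmethod
    def from_reads(cls, reads: Iterable, min_reads: int = 1) -> "JunctionSupport":
        from .binning import count_junctions

        return cls(count_junctions(reads), min_reads)

    @classmethod
    def from_count_matrix(cls, counts: CountMatrix, min_reads: int = 1) -> "JunctionSupport":
        """Junction evidence from spanning-bin counts summed over samples.

        A read in bin (k, l), l > k, is a spliced read over junction
        (k, l); per-bin totals therefore double as junction support when
        individual read records are not available.
        """
        totals = counts.U.sum(axis=1)
        tally = {
            (b.k, b.l): int(totals[b.row])
            for b in counts.scheme.bins
            if b.spanning and totals[b.row] > 0
        }
        return cls(tally, min_reads)


@dataclass
class PipelineConfig:
    """Multi-run aggregation settings wrapped around an NMF configuration.

    N runs are aggregated and candidates kept when produced in at least r
    runs; the rank is chosen once per gene by the gap statistic over
    ``candidate_ranks`` (policy ``"once"``), re-chosen each run
    (``"per-run"``), or forced via ``rank``.
    """

    N: int = 100
    r: int = 20
    max_ambiguous: int = 10
    rank: Optional[int] = None
    rank_policy: str = "once"
    candidate_ranks: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    nmf: NMFConfig = field(default_factory=NMFConfig)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 1 <= self.r <= self.N:
            raise ValueError("need 1 <= r <= N")
        if self.rank_policy not in ("once", "per-run"):
            raise ValueError("rank_policy must be 'once' or 'per-run'")


def candidate_junctions(
    inclusion: Sequence[int], gene: GeneModel
) -> list[tuple[int, int]]:
    """Splice junctions a candidate implies: consecutive included subexon
    pairs that skip at least one subexon or cross an intron; genomically
    abutting included pairs produce no junction in reads."""
    included = [i + 1 for i, v in enumerate(inclusion) if v]
    juncs = []
    for a, b in zip(included, included[1:]):
        if b > a + 1 or not gene.is_contiguous(a, b):
            juncs.append((a, b))
    return juncs


def junction_supported(
    candidate: IsoformCandidate | Sequence[int],
    gene: GeneModel,
    support: JunctionSupport,
) -> bool:
    """True iff every splice junction of the candidate has enough spliced reads."""
    inclusion = (
        candidate.inclusion if isinstance(candidate, IsoformCandidate) else candidate
    )
    if len(inclusion) != gene.n:
        raise ValueError("inclusion length does not match gene subexon count")
    return all(support.supported(a, b) for a, b in candidate_junctions(inclusion, gene))


def column_to_candidates(
    column: Sequence[int] | np.ndarray,
    scheme: BinScheme,
    support: JunctionSupport,
    max_ambiguous: int = 10,
) -> list[IsoformCandidate]:
    """Expand one binary bin-membership column into supported candidates.

    Included bins assert their boundary subexons present and their interior
    subexons skipped.  Subexons asserted both ways are ambiguous: every
    combination of their statuses is enumerated (2^#ambiguous vectors, the
    column is skipped with a warning beyond ``max_ambiguous``).  Subexons
    asserted neither way are absent.  Only candidates whose junctions pass
    ``junction_supported`` are returned.
    """
    column = np.asarray(column)
    if column.shape[0] != scheme.p:
        raise ValueError(f"column length {column.shape[0]} != p = {scheme.p}")
    gene = scheme.gene
    present: set[int] = set()
    skipped: set[int] = set()
    for b in scheme.bins:
        if column[b.row]:
            present |= b.asserted_present()
            skipped |= b.asserted_skipped()
    if not present:
        return []
    ambiguous = sorted(present & skipped)
    if len(ambiguous) > max_ambiguous:
        warnings.warn(
            f"column has {len(ambiguous)} ambiguous subexons "
            f"(> max_ambiguous = {max_ambiguous}); skipped",
            stacklevel=2,
        )
        return []
    base = [0] * gene.n
    for i in present - skipped:
        base[i - 1] = 1
    out = []
    for combo in itertools.product((1, 0), repeat=len(ambiguous)):
        inclusion = list(base)
        for sub, status in zip(ambiguous, combo):
            inclusion[sub - 1] = status
        if not any(inclusion):
            continue
        if junction_supported(inclusion, gene, support):
            out.append(IsoformCandidate(tuple(inclusion)))
    return out


def rank_selection_policy(
    V: NormalizedMatrix,
    scheme: BinScheme,
    config: PipelineConfig,
) -> Optional[int]:
    """Rank used for all N runs, or None under per-run re-selection."""
    if config.rank is not None:
        return int(config.rank)
    if config.rank_policy == "per-run":
        return None
    return select_rank(V, config.candidate_ranks, config.nmf, scheme.conflicts)


def run_nmfp(
    V: NormalizedMatrix,
    scheme: BinScheme,
    support: JunctionSupport,
    config: PipelineConfig | None = None,
) -> list[IsoformCandidate]:
    """Full preselection pipeline: N seeded NMF runs, pooling and filtering.

    Run t uses seed ``base_seed + t``.  A candidate's frequency counts the
    number of runs that produced it (once per run however many G columns
    yielded it).  Unsupported candidates are removed inside the expansion;
    candidates below frequency r are dropped; the survivors are returned
    sorted by frequency descending, ties by inclusion vector.
    """
    config = config or PipelineConfig()
    fixed_rank = rank_selection_policy(V, scheme, config)
    pool: dict[tuple[int, ...], int] = {}
    base_seed = config.nmf.seed
    for t in range(1, config.N + 1):
        seed_t = int((base_seed + t) % (2**31 - 1))
        cfg = replace(config.nmf, seed=seed_t)
        if fixed_rank is not None:
            s = fixed_rank
        else:
            s = select_rank(V, config.candidate_ranks, cfg, scheme.conflicts)
        res = fit(V, s, cfg, scheme.conflicts)
        run_candidates: set[tuple[int, ...]] = set()
        for col in range(res.G.shape[1]):
            for cand in column_to_candidates(
                res.G[:, col], scheme, support, config.max_ambiguous
            ):
                run_candidates.add(cand.inclusion)
        for inclusion in run_candidates:
            pool[inclusion] = pool.get(inclusion, 0) + 1
    kept = [
        IsoformCandidate(inclusion, frequency=freq, supported=True)
        for inclusion, freq in pool.items()
        if freq >= config.r
    ]
    if not kept:
        warnings.warn("candidate pool is empty after filtering", stacklevel=2)
    kept.sort(key=lambda cand: (-cand.frequency, cand.inclusion))
    return kept
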