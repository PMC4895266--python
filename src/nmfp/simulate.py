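"""Synthetic genes, bin-count matrices and reads with the structure NMFP assumes.

The generator emulates a multi-sample RNA-seq experiment on one gene:
subexon lengths are drawn from a fixed choice set, each sample expresses a
mixture of known true isoforms with proportions drawn uniformly and
normalized, single-end reads of fixed length are placed uniformly along
each isoform's spliced sequence, and additive white Gaussian noise is added
to the raw bin-count matrix U before normalization.  Expected read totals
follow RPKM (reads per kilobase of transcript per million mapped reads)
against a fixed library size.

The default configuration is the package's reference experiment: an 8-exon
gene with exon lengths from {100, 150, ..., 500}, three true isoforms
10111111, 10011111 and 01111111 (skipping exon 2, exons 2-3, and exon 1),
ten samples, 76 bp reads and unit Gaussian count noise.

Per-isoform bin probabilities are computed by exact enumeration of read
start positions on the spliced isoform, which doubles as the oracle for
read-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binning import BinScheme, CountMatrix, ReadRecord, enumerate_bins, normalize
from .candidates import (
    IsoformCandidate,
    JunctionSupport,
    PipelineConfig,
    run_nmfp,
)
from .gene_model import GeneModel, Isoform, Subexon

__all__ = [
    "SimConfig",
    "make_gene",
    "isoform_bin_probabilities",
    "simulate_bin_counts",
    "simulate_reads",
    "min_candidates_to_cover",
    "expression_sweep",
    "summarize_sweep",
]

#: default exon-length choice set (base pairs)
DEFAULT_LENGTH_CHOICES = tuple(range(100, 501, 50))

#: default true isoform mixture of the reference experiment
DEFAULT_TRUE_ISOFORMS = ("10111111", "10011111", "01111111")


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the reference 8-exon experiment.

    ``total_mapped_reads`` fixes the library size the RPKM unit is defined
    against (default 5e7, a typical bulk RNA-seq library), so expected gene
    reads are ``RPKM * spliced_kb * total_mapped_reads / 1e6``.
    ``noise_sd`` is the standard deviation of the additive Gaussian noise
    applied to U (negative values are clipped at zero before rounding).
    """

    n_exons: int = 8
    exon_length_choices: tuple[int, ...] = DEFAULT_LENGTH_CHOICES
    true_isoforms: tuple[str, ...] = DEFAULT_TRUE_ISOFORMS
    m_samples: int = 10
    rpkm_per_sample: tuple[float, ...] = (3.0,) * 10
    read_length: int = 76
    noise_sd: float = 1.0
    total_mapped_reads: float = 5e7
    intron_length: int = 200
    gene_id: str = "simgene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if any(l <= 0 for l in self.exon_length_choices):
            raise ValueError("exon lengths must be positive")
        if len(self.rpkm_per_sample) != self.m_samples:
            raise ValueError("rpkm_per_sample must have m_samples entries")
        if any(r < 0 for r in self.rpkm_per_sample):
            raise ValueError("rpkm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for bits in self.true_isoforms:
            if len(bits) != self.n_exons:
                raise ValueError(
                    f"true isoform {bits} does not match n_exons = {self.n_exons}"
                )

    def isoforms(self) -> list[Isoform]:
        return [
            Isoform.from_string(self.gene_id, bits, label=f"iso{t + 1}")
            for t, bits in enumerate(self.true_isoforms)
        ]


def make_gene(config: SimConfig) -> GeneModel:
    """Build a gene whose subexon lengths are drawn from the choice set.

    All consecutive subexons are separated by introns, so every junction
    between included subexons of an isoform is a splice junction.
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.choice(config.exon_length_choices, size=config.n_exons)
    subexons = []
    pos = 1000
    for i, length in enumerate(lengths, start=1):
        subexons.append(Subexon(i, pos, pos + int(length)))
        pos += int(length) + config.intron_length
    return GeneModel(config.gene_id, "chrSim", "+", subexons)


def isoform_bin_probabilities(
    gene: GeneModel, isoform: Isoform, read_length: int, scheme: BinScheme
) -> Optional[np.ndarray]:
    """Exact bin distribution of uniform read starts on one isoform.

    Enumerates every valid start position on the spliced isoform, maps the
    read's first and last base to subexons through cumulative spliced
    lengths, and returns the length-p probability vector; None when the
    isoform is shorter than the read.
    """
    included = list(isoform.included)
    lens = np.array([gene.subexons[i - 1].length for i in included])
    total = int(lens.sum())
    n_starts = total - read_length + 1
    if n_starts < 1:
        return None
    cum = np.cumsum(lens)
    starts = np.arange(n_starts)
    k_idx = np.searchsorted(cum, starts, side="right")
    l_idx = np.searchsorted(cum, starts + read_length - 1, side="right")
    probs = np.zeros(scheme.p)
    rows = np.array(
        [scheme.row(included[a], included[b]) for a, b in zip(k_idx, l_idx)]
    )
    np.add.at(probs, rows, 1.0)
    return probs / n_starts


def simulate_bin_counts(
    gene: GeneModel,
    config: SimConfig,
    scheme: Optional[BinScheme] = None,
) -> CountMatrix:
    """Simulate the raw bin-count matrix U under the uniform-placement model.

    Per sample: isoform proportions are drawn U[0, 1] and normalized,
    expected gene reads follow RPKM against the configured library size,
    reads are apportioned to isoforms proportionally to proportion times
    spliced length and spread over bins by the exact uniform-start
    distribution; Gaussian noise N(0, noise_sd^2) is then added entrywise,
    negatives clipped at zero, and entries rounded to integer counts.
    """
    if not any(r > 0 for r in config.rpkm_per_sample):
        raise ValueError("zero total expression across all samples")
    scheme = scheme or enumerate_bins(gene)
    rng = np.random.default_rng(config.seed)
    isoforms = config.isoforms()
    probs = []
    iso_len = []
    for iso in isoforms:
        pvec = isoform_bin_probabilities(gene, iso, config.read_length, scheme)
        if pvec is None:
            raise ValueError(
                f"isoform {iso.label} shorter than the read length"
            )
        probs.append(pvec)
        iso_len.append(iso.spliced_length(gene))
    probs_mat = np.stack(probs, axis=1)            # p x s
    iso_len = np.array(iso_len, dtype=float)
    gene_kb = gene.spliced_length / 1000.0

    E = np.zeros((scheme.p, config.m_samples))
    for j, rpkm in enumerate(config.rpkm_per_sample):
        pi = rng.uniform(0.0, 1.0, size=len(isoforms))
        pi = pi / pi.sum()
        total_reads = rpkm * gene_kb * config.total_mapped_reads / 1e6
        weights = pi * iso_len
        reads_per_iso = total_reads * weights / weights.sum()
        E[:, j] = probs_mat @ reads_per_iso
    U = E
    if config.noise_sd > 0:
        U = U + rng.normal(0.0, config.noise_sd, size=E.shape)
    U = np.rint(np.clip(U, 0.0, None)).astype(np.int64)
    return CountMatrix(scheme, [f"sample{j + 1}" for j in range(config.m_samples)], U)


def simulate_reads(
    gene: GeneModel,
    isoform_abundances: Sequence[tuple[Isoform, float]],
    depth: int,
    read_length: int,
    seed: int,
    sample_id: str = "sample1",
) -> list[ReadRecord]:
    """Place ``depth`` uniform reads on isoforms and report subexon spans.

    Expected per-isoform read counts are proportional to abundance times
    spliced length; isoforms shorter than the read are excluded (an error
    when none remains).  Each read records its start/end subexon and the
    chain of splice junctions it crosses.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    usable = [
        (iso, ab)
        for iso, ab in isoform_abundances
        if iso.spliced_length(gene) >= read_length
    ]
    if not usable:
        raise ValueError("read_length longer than every isoform")
    if depth == 0:
        return []
    rng = np.random.default_rng(seed)
    weights = np.array(
        [ab * iso.spliced_length(gene) for iso, ab in usable], dtype=float
    )
    counts = rng.multinomial(depth, weights / weights.sum())
    reads: list[ReadRecord] = []
    for (iso, _), cnt in zip(usable, counts):
        if cnt == 0:
            continue
        included = list(iso.included)
        lens = np.array([gene.subexons[i - 1].length for i in included])
        cum = np.cumsum(lens)
        n_starts = int(lens.sum()) - read_length + 1
        starts = rng.integers(0, n_starts, size=cnt)
        k_idx = np.searchsorted(cum, starts, side="right")
        l_idx = np.searchsorted(cum, starts + read_length - 1, side="right")
        for a, b in zip(k_idx, l_idx):
            span = included[a : b + 1]
            chain = tuple(
                (x, y)
                for x, y in zip(span, span[1:])
                if y > x + 1 or not gene.is_contiguous(x, y)
            )
            reads.append(
                ReadRecord(sample_id, included[a], included[b], chain)
            )
    return reads


def min_candidates_to_cover(
    pool: Sequence[IsoformCandidate],
    truths: Sequence[Isoform | Sequence[int]],
) -> Optional[int]:
    """Smallest prefix of the ranked pool containing every truth exactly.

    Returns None when some truth is absent from the whole pool, 0 for an
    empty truth set.
    """
    wanted = {
        tuple(t.inclusion) if isinstance(t, Isoform) else tuple(t) for t in truths
    }
    if not wanted:
        return 0
    seen: set[tuple[int, ...]] = set()
    for idx, cand in enumerate(pool, start=1):
        if cand.inclusion in wanted:
            seen.add(cand.inclusion)
            if seen == wanted:
                return idx
    return None


def _condition_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def expression_sweep(
    settings: Sequence[float],
    n_replicates: int = 5,
    base_seed: int = 0,
    fixed_rpkm: float = 3.0,
    sim_config: Optional[SimConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
) -> list[dict]:
    """Expression-level sweep of the reference experiment.

    Sample 1 is held at ``fixed_rpkm`` while the other samples' expression
    takes each value in ``settings``; per replicate a fresh gene and fresh
    isoform proportions are drawn.  For each condition the full pipeline
    runs and the minimum covering prefix of the ranked candidate pool is
    recorded.  When the pool does not cover all truths the pool size is
    recorded as a censored lower bound (``covered`` is False).
    """
    base_sim = sim_config or SimConfig()
    records: list[dict] = []
    for rep in range(n_replicates):
        gene_cfg = SimConfig(
            **{**base_sim.__dict__, "seed": _condition_seed(base_seed, rep, 9999)}
        )
        gene = make_gene(gene_cfg)
        scheme = enumerate_bins(gene)
        truths = gene_cfg.isoforms()
        for si, level in enumerate(settings):
            cond_seed = _condition_seed(base_seed, rep, si)
            rpkm = (float(fixed_rpkm),) + (float(level),) * (base_sim.m_samples - 1)
            cfg = SimConfig(
                **{
                    **base_sim.__dict__,
                    "rpkm_per_sample": rpkm,
                    "seed": cond_seed,
                }
            )
            counts = simulate_bin_counts(gene, cfg, scheme)
            support = JunctionSupport.from_count_matrix(counts)
            V = normalize(counts)
            base_pipe = pipeline_config or PipelineConfig()
            nmf_cfg = _nmf_config_with_seed(
                base_pipe.nmf, _condition_seed(base_seed, rep, si, 7)
            )
            pipe = PipelineConfig(
                N=base_pipe.N, r=base_pipe.r, max_ambiguous=base_pipe.max_ambiguous,
                rank=base_pipe.rank, rank_policy=base_pipe.rank_policy,
                candidate_ranks=base_pipe.candidate_ranks, nmf=nmf_cfg,
            )
            pool = run_nmfp(V, scheme, support, pipe)
            mc = min_candidates_to_cover(pool, truths)
            records.append(
                {
                    "setting": float(level),
                    "replicate": rep,
                    "seed": cond_seed,
                    "covered": mc is not None,
                    "min_cover": mc if mc is not None else len(pool),
                    "cover_depth": _frequency_cover_depth(pool, truths, len(pool)),
                    "pool_size": len(pool),
                }
            )
    return records


def _frequency_cover_depth(pool, truths, censor: int) -> int:
    """Candidates needed to cover all truths when ranking is by frequency only.

    Candidates of equal frequency are indistinguishable to the ranking, so
    the covering prefix must include the whole frequency class of the
    weakest truth; an uncovered truth censors the value at the pool size.
    """
    wanted = {tuple(t.inclusion) for t in truths}
    freq = {c.inclusion: c.frequency for c in pool}
    if not wanted <= set(freq):
        return censor
    cutoff = min(freq[t] for t in wanted)
    return sum(1 for c in pool if c.frequency >= cutoff)


def _nmf_config_with_seed(template, seed: int):
    """Copy an NMF configuration with a replaced seed."""
    import dataclasses

    return dataclasses.replace(template, seed=int(seed))


def summarize_sweep(records: Sequence[dict]) -> dict[float, float]:
    """Mean recorded covering prefix per expression setting."""
    by_setting: dict[float, list[float]] = {}
    for rec in records:
        by_setting.setdefault(rec["setting"], []).append(float(rec["min_cover"]))
    return {k: float(np.mean(v)) for k, v in sorted(by_setting.items())}
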