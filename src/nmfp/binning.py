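"""Read bins, the raw count matrix U, and its normalization into V.

Mapped reads of a gene with ``n`` subexons are categorized into *bins*
``(k, l)``: the read starts in subexon ``k`` and ends in subexon ``l``
(``1 <= k <= l <= n``), giving ``p = n + C(n, 2)`` bins in total.  Counting
reads per bin per sample yields the ``p x m`` matrix ``U``, which is
normalized into ``V`` by removing sequencing-depth and bin-length effects
under the model ``U_ij = R_j * P_i`` (``R_j`` the per-sample gene read
total, ``P_i`` the bin probability, assumed proportional to bin length).

A spanning bin ``(k, l)`` with ``l > k`` is read as evidence of a splice
junction from subexon ``k`` to subexon ``l``: it asserts subexons ``k`` and
``l`` present and every subexon strictly between them skipped.  Two bins
*conflict* when one asserts present a subexon the other asserts skipped;
e.g. (1,3) conflicts with (2,2).  The conflict relation feeds the NMF
penalty downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .gene_model import GeneModel

__all__ = [
    "Bin",
    "BinScheme",
    "ReadRecord",
    "CountMatrix",
    "NormalizedMatrix",
    "enumerate_bins",
    "conflicting",
    "assign_read",
    "build_count_matrix",
    "count_junctions",
    "normalize",
    "reads_from_alignments",
    "read_records_tsv",
    "write_read_records_tsv",
    "read_count_matrix_tsv",
    "write_count_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class Bin:
    """Read category (k, l): starts in subexon k, ends in subexon l (1-based)."""

    k: int
    l: int
    row: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.l:
            raise ValueError(f"bin ({self.k},{self.l}): need 1 <= k <= l")

    @property
    def spanning(self) -> bool:
        return self.l > self.k

    def asserted_present(self) -> frozenset[int]:
        return frozenset((self.k, self.l))

    def asserted_skipped(self) -> frozenset[int]:
        return frozenset(range(self.k + 1, self.l))


def conflicting(bin_i: Bin, bin_j: Bin) -> bool:
    """True iff the two bins assert incompatible subexon statuses.

    Bin (k, l) asserts subexons k and l present and everything strictly
    between skipped; a conflict arises when a subexon asserted present by
    one bin is asserted skipped by the other.  Symmetric, false on the
    diagonal.
    """
    return bool(
        bin_i.asserted_present() & bin_j.asserted_skipped()
        or bin_j.asserted_present() & bin_i.asserted_skipped()
    )


@dataclass
class BinScheme:
    """Enumeration of all p bins of one gene, with lengths, P and conflicts."""

    gene: GeneModel
    bins: list[Bin]
    P: np.ndarray
    conflicts: np.ndarray
    _row_of: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._row_of:
            self._row_of = {(b.k, b.l): b.row for b in self.bins}

    @property
    def p(self) -> int:
        return len(self.bins)

    def row(self, k: int, l: int) -> int:
        return self._row_of[(k, l)]

    def bin_at(self, k: int, l: int) -> Bin:
        return self.bins[self._row_of[(k, l)]]


def enumerate_bins(gene: GeneModel) -> BinScheme:
    """Enumerate the p = n + C(n,2) bins of a gene in deterministic row order.

    Single-subexon bins (k, k) come first in increasing k, then spanning
    bins (k, l), k < l, in lexicographic order.  A single-subexon bin has
    the subexon's length; a spanning bin (k, l) has length
    ``len(k) + len(l)`` (the read start may fall anywhere in k and the end
    anywhere in l under the junction interpretation).  ``P`` is
    proportional to bin length and sums to one.
    """
    n = gene.n
    lengths = gene.subexon_lengths
    bins: list[Bin] = []
    for k in range(1, n + 1):
        bins.append(Bin(k, k, len(bins), int(lengths[k - 1])))
    for k in range(1, n + 1):
        for l in range(k + 1, n + 1):
            bins.append(Bin(k, l, len(bins), int(lengths[k - 1] + lengths[l - 1])))
    blen = np.array([b.length for b in bins], dtype=float)
    P = blen / blen.sum()
    p = len(bins)
    conflicts = np.zeros((p, p), dtype=bool)
    for bi in bins:
        for bj in bins:
            if bi.row < bj.row and conflicting(bi, bj):
                conflicts[bi.row, bj.row] = conflicts[bj.row, bi.row] = True
    return BinScheme(gene, bins, P, conflicts)


@dataclass(frozen=True)
class ReadRecord:
    """One mapped read reduced to its subexon span and splice-junction chain."""

    sample_id: str
    start_subexon: int
    end_subexon: int
    junction_chain: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start_subexon > self.end_subexon:
            raise ValueError("read start_subexon must be <= end_subexon")
        for a, b in self.junction_chain:
            if not (self.start_subexon <= a < b <= self.end_subexon):
                raise ValueError("junction chain outside read subexon span")


def assign_read(read: ReadRecord, scheme: BinScheme) -> Optional[Bin]:
    """Bin for (start_subexon, end_subexon), or None if outside the gene.

    The read's junction chain does not affect bin identity (long reads are
    binned by their outermost subexons); junction evidence is tallied
    separately by :func:`count_junctions`.
    """
    n = scheme.gene.n
    if not (1 <= read.start_subexon and read.end_subexon <= n):
        return None
    return scheme.bin_at(read.start_subexon, read.end_subexon)


@dataclass
class CountMatrix:
    """Raw p x m bin-by-sample read counts U with per-sample totals R."""

    scheme: BinScheme
    samples: list[str]
    U: np.ndarray

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample required")
        if self.U.shape != (self.scheme.p, len(self.samples)):
            raise ValueError(
                f"U shape {self.U.shape} != (p={self.scheme.p}, m={len(self.samples)})"
            )
        if (self.U < 0).any():
            raise ValueError("U must be non-negative")

    @property
    def m(self) -> int:
        return len(self.samples)

    @property
    def R(self) -> np.ndarray:
        return self.U.sum(axis=0)


@dataclass
class NormalizedMatrix:
    """Depth- and bin-length-normalized counts V (p x m)."""

    scheme: BinScheme
    V: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.V).all() or (self.V < 0).any():
            raise ValueError("V must be finite and non-negative")


def build_count_matrix(
    reads: Iterable[ReadRecord], scheme: BinScheme, samples: Sequence[str]
) -> CountMatrix:
    """Count reads per bin per sample into U; reads outside the gene are dropped."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    col = {s: j for j, s in enumerate(samples)}
    U = np.zeros((scheme.p, len(samples)), dtype=np.int64)
    for read in reads:
        if read.sample_id not in col:
            raise ValueError(f"read sample {read.sample_id!r} not in sample list")
        b = assign_read(read, scheme)
        if b is not None:
            U[b.row, col[read.sample_id]] += 1
    return CountMatrix(scheme, samples, U)


def count_junctions(reads: Iterable[ReadRecord]) -> dict[tuple[int, int], int]:
    """Tally spliced-read support per junction (donor subexon, acceptor subexon).

    A read with an explicit junction chain supports each junction in the
    chain; a chain-less read spanning two subexons supports the junction
    between its outermost subexons.
    """
    counts: dict[tuple[int, int], int] = {}
    for read in reads:
        if read.junction_chain:
            juncs: Iterable[tuple[int, int]] = read.junction_chain
        elif read.end_subexon > read.start_subexon:
            juncs = [(read.start_subexon, read.end_subexon)]
        else:
            juncs = []
        for j in juncs:
            counts[j] = counts.get(j, 0) + 1
    return counts


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Remove depth and bin-length effects: U'_ij = U_ij * Rbar/R_j, V = U'/(p P_i).

    ``Rbar`` is the arithmetic mean of the per-sample totals over all m
    samples (zero-depth samples included); zero-depth columns stay zero.
    """
    R = counts.R.astype(float)
    if not (R > 0).any():
        raise ValueError("empty gene: all samples have zero reads")
    Rbar = R.mean()
    scale = np.where(R > 0, Rbar / np.where(R > 0, R, 1.0), 0.0)
    Uprime = counts.U * scale[np.newaxis, :]
    P = counts.scheme.P
    V = Uprime / (counts.scheme.p * P)[:, np.newaxis]
    return NormalizedMatrix(counts.scheme, V)


def _subexon_of(gene: GeneModel, pos: int) -> Optional[int]:
    """1-based subexon containing genomic position pos, or None."""
    for sub in gene.subexons:
        if sub.start <= pos < sub.end:
            return sub.index
    return None


def reads_from_alignments(
    path: str | os.PathLike, gene: GeneModel, sample_id: str
) -> list[ReadRecord]:
    """Reduce spliced SAM/BAM alignments overlapping one gene to ReadRecords.

    Each aligned segment (each end of a pair independently) becomes one
    record: start/end subexons from the outermost aligned bases, junction
    chain from gaps between aligned blocks whose flanks land in distinct
    subexons.  Alignments whose endpoints fall outside the gene's subexons
    are skipped.
    """
    import pysam

    records: list[ReadRecord] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name != gene.chrom:
                continue
            blocks = aln.get_blocks()
            if not blocks:
                continue
            start_sub = _subexon_of(gene, blocks[0][0])
            end_sub = _subexon_of(gene, blocks[-1][1] - 1)
            if start_sub is None or end_sub is None:
                continue
            chain = []
            for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
                donor = _subexon_of(gene, e0 - 1)
                acceptor = _subexon_of(gene, s1)
                if donor is not None and acceptor is not None and acceptor > donor:
                    chain.append((donor, acceptor))
            records.append(
                ReadRecord(sample_id, start_sub, end_sub, tuple(chain))
            )
    return records


def write_read_records_tsv(reads: Iterable[ReadRecord], out_path: str | os.PathLike,
                           header: str | None = None) -> None:
    """Write ReadRecords as TSV (sample_id, start_subexon, end_subexon, junctions)."""
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("sample_id\tstart_subexon\tend_subexon\tjunctions\n")
        for r in reads:
            chain = ";".join(f"{a}-{b}" for a, b in r.junction_chain)
            fh.write(f"{r.sample_id}\t{r.start_subexon}\t{r.end_subexon}\t{chain}\n")


def read_records_tsv(path: str | os.PathLike) -> list[ReadRecord]:
    """Read the TSV written by :func:`write_read_records_tsv`."""
    records: list[ReadRecord] = []
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#") and ln.strip()]
    if not lines or lines[0].rstrip("\n").split("\t")[0] != "sample_id":
        raise ValueError(f"{path}: not a read-record table")
    for ln in lines[1:]:
        sample_id, start, end, chain = ln.rstrip("\n").split("\t")
        junctions = tuple(
            (int(a), int(b))
            for a, b in (pair.split("-") for pair in chain.split(";") if pair)
        )
        records.append(ReadRecord(sample_id, int(start), int(end), junctions))
    return records


def write_count_matrix_tsv(counts: CountMatrix, out_path: str | os.PathLike,
                           header: str | None = None) -> None:
    """Write U as TSV with a `k,l` bin-index column and sample columns."""
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("bin\t" + "\t".join(counts.samples) + "\n")
        for b in counts.scheme.bins:
            row = counts.U[b.row]
            fh.write(f"{b.k},{b.l}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_matrix_tsv(scheme: BinScheme, M: np.ndarray, samples: Sequence[str],
                     out_path: str | os.PathLike, header: str | None = None) -> None:
    """Write any p x m matrix (e.g. V) with the bin-index header layout."""
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("bin\t" + "\t".join(samples) + "\n")
        for b in scheme.bins:
            fh.write(f"{b.k},{b.l}\t" + "\t".join(f"{v:.10g}" for v in M[b.row]) + "\n")


def read_count_matrix_tsv(path: str | os.PathLike, scheme: BinScheme) -> CountMatrix:
    """Read a TSV written by :func:`write_count_matrix_tsv` against a scheme."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#") and ln.strip()]
    headers = lines[0].rstrip("\n").split("\t")
    if headers[0] != "bin":
        raise ValueError(f"{path}: first column must be 'bin'")
    samples = headers[1:]
    U = np.zeros((scheme.p, len(samples)), dtype=np.int64)
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        k, l = (int(x) for x in fields[0].split(","))
        U[scheme.row(k, l)] = [int(round(float(v))) for v in fields[1:]]
    return CountMatrix(scheme, samples, U)
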