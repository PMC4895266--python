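"""Gene models built from subexons, and GTF input/output.

A gene is represented by its *subexons*: the exonic intervals between two
adjacent splice sites, obtained by pooling the exon boundaries of all
annotated transcripts of the gene.  Subexons are the atomic unit of isoform
description throughout the package: an mRNA isoform is a binary
subexon-inclusion vector of length ``n`` (the number of subexons).

Coordinates are 0-based half-open internally and 1-based inclusive in GTF
files, following the usual convention split.  Strand is carried through but
all downstream logic operates in genomic (left-to-right) subexon order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import numpy as np

__all__ = [
    "Subexon",
    "GeneModel",
    "Isoform",
    "load_gene_models",
    "write_candidates_gtf",
    "load_subexon_table",
    "write_subexon_table",
]


@dataclass(frozen=True)
class Subexon:
    """One exonic interval between two adjacent splice sites.

    ``index`` is the 1-based ordinal of the subexon along the gene in
    genomic order; ``start``/``end`` are 0-based half-open genomic
    coordinates.
    """

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"subexon {self.index}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered, non-overlapping subexons of one gene.

    ``adjacency[i]`` describes the relation between subexons ``i+1`` and
    ``i+2`` (1-based): ``"contiguous"`` when they abut on the genome,
    ``"intron"`` when separated by an intron.  Contiguity matters for
    candidate output (abutting included subexons merge into one exon) and
    for junction support (only intron-separated or skipping junctions need
    spliced-read evidence).
    """

    gene_id: str
    chrom: str
    strand: str
    subexons: list[Subexon]
    adjacency: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subexons:
            raise ValueError(f"gene {self.gene_id}: needs at least one subexon")
        starts = [s.start for s in self.subexons]
        if starts != sorted(starts):
            raise ValueError(f"gene {self.gene_id}: subexons must be sorted by start")
        for a, b in zip(self.subexons, self.subexons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"gene {self.gene_id}: subexons {a.index} and {b.index} overlap"
                )
        if not self.adjacency:
            self.adjacency = [
                "contiguous" if a.end == b.start else "intron"
                for a, b in zip(self.subexons, self.subexons[1:])
            ]
        if len(self.adjacency) != len(self.subexons) - 1:
            raise ValueError(
                f"gene {self.gene_id}: adjacency must have n-1 entries"
            )

    @property
    def n(self) -> int:
        return len(self.subexons)

    @property
    def subexon_lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.subexons], dtype=np.int64)

    @property
    def spliced_length(self) -> int:
        return int(self.subexon_lengths.sum())

    def is_contiguous(self, a: int, b: int) -> bool:
        """True iff 1-based subexons ``a`` and ``b`` == ``a+1`` abut on the genome."""
        if b != a + 1:
            return False
        return self.adjacency[a - 1] == "contiguous"


@dataclass(frozen=True)
class Isoform:
    """A transcript expressed as a binary subexon-inclusion vector."""

    gene_id: str
    inclusion: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not any(self.inclusion):
            raise ValueError(f"isoform {self.label or self.gene_id}: empty inclusion")
        if any(v not in (0, 1) for v in self.inclusion):
            raise ValueError("inclusion vector must be binary")

    @classmethod
    def from_string(cls, gene_id: str, bits: str, label: str = "") -> "Isoform":
        return cls(gene_id, tuple(int(b) for b in bits), label)

    @property
    def included(self) -> tuple[int, ...]:
        """1-based indices of included subexons."""
        return tuple(i + 1 for i, v in enumerate(self.inclusion) if v)

    def exons(self, gene: GeneModel) -> list[tuple[int, int]]:
        """Genomic exons: maximal runs of included, genomically abutting subexons."""
        if len(self.inclusion) != gene.n:
            raise ValueError("inclusion length does not match gene subexon count")
        exons: list[tuple[int, int]] = []
        for idx in self.included:
            sub = gene.subexons[idx - 1]
            if exons and exons[-1][1] == sub.start:
                exons[-1] = (exons[-1][0], sub.end)
            else:
                exons.append((sub.start, sub.end))
        return exons

    def spliced_length(self, gene: GeneModel) -> int:
        return sum(gene.subexons[i - 1].length for i in self.included)


def _subexons_from_exons(exon_sets: Iterable[Iterable[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Split the union of exons at every distinct splice site.

    Splice sites are the pooled starts and ends of all exons; subexons are
    the maximal intervals of the exon union lying between consecutive sites.
    """
    sites: set[int] = set()
    intervals: list[tuple[int, int]] = []
    for exons in exon_sets:
        for s, e in exons:
            sites.add(s)
            sites.add(e)
            intervals.append((s, e))
    # union of exon intervals
    intervals.sort()
    union: list[tuple[int, int]] = []
    for s, e in intervals:
        if union and s <= union[-1][1]:
            union[-1] = (union[-1][0], max(union[-1][1], e))
        else:
            union.append((s, e))
    ordered = sorted(sites)
    out: list[tuple[int, int]] = []
    for a, b in zip(ordered, ordered[1:]):
        if any(us <= a and b <= ue for us, ue in union):
            out.append((a, b))
    return out


def load_gene_models(annotation_path: str | os.PathLike) -> list[tuple[GeneModel, list[Isoform]]]:
    """Read an Ensembl-dialect GTF and derive per-gene subexon structures.

    Returns one ``(GeneModel, annotated isoforms)`` pair per gene, each
    annotated transcript re-expressed as a binary inclusion vector over the
    gene's subexons.  Raises ``ValueError`` when a transcript's exons do not
    decompose into whole subexons (which cannot happen for a self-consistent
    annotation) and lets gffutils surface malformed-GTF parse errors.
    """
    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )
    genes: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes["gene_id"][0]
        tx_id = exon.attributes["transcript_id"][0]
        rec = genes.setdefault(
            gene_id,
            {"chrom": exon.seqid, "strand": exon.strand or "+", "tx": {}},
        )
        # GTF is 1-based inclusive; internal is 0-based half-open
        rec["tx"].setdefault(tx_id, []).append((exon.start - 1, exon.end))

    out: list[tuple[GeneModel, list[Isoform]]] = []
    for gene_id in sorted(genes):
        rec = genes[gene_id]
        tx = {t: sorted(ex) for t, ex in rec["tx"].items()}
        sub_ivals = _subexons_from_exons(tx.values())
        subexons = [Subexon(i + 1, s, e) for i, (s, e) in enumerate(sub_ivals)]
        gene = GeneModel(gene_id, rec["chrom"], rec["strand"], subexons)
        iso: list[Isoform] = []
        bounds = {(s.start, s.end): s.index for s in subexons}
        for tx_id in sorted(tx):
            inclusion = [0] * gene.n
            for es, ee in tx[tx_id]:
                # the exon must tile exactly into consecutive subexons
                pos = es
                while pos < ee:
                    hit = next(
                        (s for s in subexons if s.start == pos and s.end <= ee), None
                    )
                    if hit is None:
                        raise ValueError(
                            f"transcript {tx_id}: exon [{es},{ee}) not decomposable "
                            f"into whole subexons of gene {gene_id}"
                        )
                    inclusion[hit.index - 1] = 1
                    pos = hit.end
            iso.append(Isoform(gene_id, tuple(inclusion), label=tx_id))
        out.append((gene, iso))
    return out


def write_candidates_gtf(
    gene: GeneModel,
    candidates: Sequence[Isoform],
    out_path: str | os.PathLike,
    source: str = "nmfp",
    header: str | None = None,
    append: bool = False,
) -> None:
    """Write isoform candidates of one gene as an Ensembl-dialect GTF.

    One transcript per candidate; included subexons that abut on the genome
    are merged into single exon features.  Coordinates are emitted 1-based
    inclusive.  All-zero candidates are rejected upstream by ``Isoform``.
    """
    mode = "a" if append else "w"
    with open(out_path, mode) as fh:
        if not append:
            fh.write(header or "##gff-version 2\n")
        for t, cand in enumerate(candidates, start=1):
            if len(cand.inclusion) != gene.n:
                raise ValueError(
                    f"candidate {t}: inclusion length {len(cand.inclusion)} != n={gene.n}"
                )
            tx_id = cand.label or f"{gene.gene_id}.cand{t}"
            exons = cand.exons(gene)
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
            tx_start, tx_end = exons[0][0] + 1, exons[-1][1]
            fh.write(
                "\t".join(
                    [gene.chrom, source, "transcript", str(tx_start), str(tx_end),
                     ".", gene.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in exons:
                fh.write(
                    "\t".join(
                        [gene.chrom, source, "exon", str(s + 1), str(e),
                         ".", gene.strand, ".", attrs]
                    )
                    + "\n"
                )


def write_subexon_table(
    genes: Sequence[GeneModel], out_path: str | os.PathLike
) -> None:
    """Write a TSV subexon table (gene_id, index, chrom, strand, start, end, adjacency)."""
    with open(out_path, "w") as fh:
        fh.write("gene_id\tindex\tchrom\tstrand\tstart\tend\tadjacency_next\n")
        for gene in genes:
            for sub in gene.subexons:
                adj = (
                    gene.adjacency[sub.index - 1]
                    if sub.index < gene.n
                    else "."
                )
                fh.write(
                    f"{gene.gene_id}\t{sub.index}\t{gene.chrom}\t{gene.strand}"
                    f"\t{sub.start}\t{sub.end}\t{adj}\n"
                )


def load_subexon_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read the TSV written by :func:`write_subexon_table`."""
    rows: dict[str, list[tuple[int, str, str, int, int, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "index"]:
            raise ValueError(f"{path}: not a subexon table")
        for line in fh:
            if not line.strip():
                continue
            gid, idx, chrom, strand, start, end, adj = line.rstrip("\n").split("\t")
            rows.setdefault(gid, []).append(
                (int(idx), chrom, strand, int(start), int(end), adj)
            )
    genes = []
    for gid, recs in rows.items():
        recs.sort()
        subexons = [Subexon(i, s, e) for i, _, _, s, e, _ in recs]
        adjacency = [adj for *_, adj in recs[:-1]]
        genes.append(
            GeneModel(gid, recs[0][1], recs[0][2], subexons, adjacency)
        )
    return genes
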