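"""Chromosomal context of family members from GFF3 gene models.

Gene coordinates are stored 0-based half-open internally; GFF3 is 1-based
inclusive and is converted at the parse/write boundary.  The per-chromosome
gene *rank* (1-based position in start-sorted order) defined here is the
substrate of the tandem-duplication rule (rank difference of exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "RankIndex",
    "parse_gff_genes",
    "exon_count",
    "assign_gene_ranks",
    "chromosome_distribution",
    "linked_pairs",
    "render_chromosome_map",
    "structure_table",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; coordinates 0-based half-open on its chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def position_string(self) -> str:
        """1-based inclusive display form, e.g. ``Chr05: 42988293-42990818``."""
        return f"{self.chromosome}: {self.start + 1}-{self.end}"


def parse_gff_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon features, Parent links).

    When a gene has several mRNAs, the exons of the longest one (summed exon
    length, ties by mRNA id) are kept — the same non-redundancy rule applied
    to protein isoforms.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.end < g.start:
            raise ValueError(f"gene {g.id}: end < start")
        best_exons: tuple[tuple[int, int], ...] = ()
        best_key: tuple[int, str] | None = None
        for mrna in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(mrna, featuretype="exon")
                )
            )
            total = sum(e - s for s, e in exons)
            key = (-total, mrna.id)
            if best_key is None or key < best_key:
                best_key, best_exons = key, exons
        if not best_exons:
            # gene with no annotated mRNA/exons: whole span is one exon
            best_exons = ((g.start - 1, g.end),)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=best_exons,
            )
        )
    return genes


def exon_count(gene: GeneModel) -> int:
    return len(gene.exons)


class RankIndex:
    """Per-chromosome 1-based gene ranks in start-coordinate order."""

    def __init__(self, genes: Sequence[GeneModel]):
        ids = [g.gene_id for g in genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        self._genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.by_chromosome: dict[str, list[str]] = {}
        by_chr: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chr.setdefault(g.chromosome, []).append(g)
        self._rank: dict[str, int] = {}
        for chrom, glist in by_chr.items():
            glist.sort(key=lambda g: (g.start, g.gene_id))
            self.by_chromosome[chrom] = [g.gene_id for g in glist]
            for i, g in enumerate(glist, start=1):
                self._rank[g.gene_id] = i

    def rank(self, gene_id: str) -> int:
        return self._rank[gene_id]

    def chromosome(self, gene_id: str) -> str:
        return self._genes[gene_id].chromosome

    def gene(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    def __len__(self) -> int:
        return len(self._rank)


def assign_gene_ranks(genes: Sequence[GeneModel]) -> RankIndex:
    """Number genes 1..n per chromosome by start (ties by gene id)."""
    return RankIndex(genes)


def chromosome_distribution(
    member_gene_ids: Iterable[str], genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Family-member count per chromosome (zero-count chromosomes included)."""
    by_id = {g.gene_id: g for g in genes}
    counts = {chrom: 0 for chrom in sorted({g.chromosome for g in genes})}
    missing = [m for m in member_gene_ids if m not in by_id]
    if missing:
        raise KeyError(f"member gene ids absent from gene models: {sorted(missing)}")
    for m in member_gene_ids:
        counts[by_id[m].chromosome] += 1
    return counts


def linked_pairs(
    member_gene_ids: Iterable[str],
    rank_index: RankIndex,
    max_rank_gap: int = 10,
) -> list[tuple[str, str]]:
    """Member pairs on one chromosome within *max_rank_gap* ranks.

    A permissive operationalisation of genes "linked on the same chromosome";
    set ``max_rank_gap=1`` for strict adjacency.  Each unordered pair is
    reported once, lexicographically sorted.
    """
    members = sorted(set(member_gene_ids))
    pairs = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if rank_index.chromosome(a) != rank_index.chromosome(b):
                continue
            if abs(rank_index.rank(a) - rank_index.rank(b)) <= max_rank_gap:
                pairs.append((a, b))
    return pairs


def structure_table(
    member_gene_ids: Iterable[str], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Exon/intron summary per member gene."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for m in sorted(set(member_gene_ids)):
        g = by_id[m]
        rows.append(
            {
                "gene": m,
                "chromosome": g.chromosome,
                "position": g.position_string,
                "strand": g.strand,
                "exon_count": exon_count(g),
                "intron_count": exon_count(g) - 1,
                "exon_lengths": ",".join(str(e - s) for s, e in g.exons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "chromosome", "position", "strand",
                 "exon_count", "intron_count", "exon_lengths"],
    )


def render_chromosome_map(
    member_gene_ids: Iterable[str],
    genes: Sequence[GeneModel],
    out: str | Path,
    bar_width: int = 18,
    height: int = 600,
    spacing: int = 70,
) -> Path:
    """Minimal deterministic SVG: one bar per chromosome, a tick per member.

    Tick height is proportional to gene start over the chromosome's maximum
    coordinate.  Byte-identical output for identical input.
    """
    by_id = {g.gene_id: g for g in genes}
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chromosome] = max(chrom_len.get(g.chromosome, 0), g.end)
    chroms = sorted(chrom_len)
    members = sorted(set(member_gene_ids))
    missing = [m for m in members if m not in by_id]
    if missing:
        raise KeyError(f"member gene ids absent from gene models: {missing}")

    width = spacing * (len(chroms) + 1)
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height + 80}">'
    ]
    for i, chrom in enumerate(chroms):
        x = spacing * (i + 1) - bar_width // 2
        lines.append(
            f'<rect x="{x}" y="30" width="{bar_width}" height="{height}" '
            f'rx="8" fill="#d9d9d9" stroke="#555"/>'
        )
        lines.append(
            f'<text x="{spacing * (i + 1)}" y="{height + 55}" '
            f'text-anchor="middle" font-size="12">{chrom}</text>'
        )
    for m in members:
        g = by_id[m]
        i = chroms.index(g.chromosome)
        x = spacing * (i + 1) - bar_width // 2
        y = 30 + round(height * g.start / chrom_len[g.chromosome], 1)
        lines.append(
            f'<line x1="{x}" y1="{y}" x2="{x + bar_width}" y2="{y}" '
            f'stroke="#c0392b" stroke-width="2"/>'
        )
        lines.append(
            f'<text x="{x + bar_width + 4}" y="{y + 4}" font-size="9">{m}</text>'
        )
    lines.append("</svg>")
    out = Path(out)
    out.write_text("\n".join(lines) + "\n")
    return out
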