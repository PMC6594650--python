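"""Duplication and selection analysis: tandem arrays, collinear blocks, Ka/Ks.

Tandem duplicates are homologous gene pairs sitting at adjacent ranks
(|Δrank| = 1) on one chromosome.  Collinear (syntenic) blocks are chains of
homologous anchor pairs whose ranks advance monotonically in both genomes
— a simplified dynamic-programming stand-in for MCScanX-style chaining.
Selection on ortholog pairs is quantified with the Nei-Gojobori (1986)
counting method: per-codon synonymous/nonsynonymous site fractions,
pathway-averaged difference counts, and a Jukes-Cantor multiple-hit
correction; ω = Ka/Ks classifies pairs as purifying (ω < 1), neutral
(ω = 1) or positive (ω > 1).  Ks further converts to a divergence time via
T = Ks / (2r) given a synonymous substitution rate r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome import RankIndex

__all__ = [
    "HomologyHit",
    "TandemPair",
    "CollinearBlock",
    "OrthologPair",
    "CodonAlignment",
    "SaturationError",
    "parse_homology_table",
    "detect_tandem_arrays",
    "chain_collinear_blocks",
    "extract_ortholog_pairs",
    "codon_sites",
    "codon_differences",
    "ng86_kaks",
    "codon_alignment_from_protein",
    "classify_selection",
    "divergence_time",
    "tandem_percentage",
]

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if CODON_TO_AA[c] != "*"
)
_NTS = "ACGT"


@dataclass(frozen=True)
class HomologyHit:
    query_gene: str
    subject_gene: str
    percent_identity: float
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    chromosome: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[tuple[str, str], ...]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    score: float

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    ka: float
    ks: float
    omega: float | None
    selection_class: str
    multiplicity: str = "1:1"


# ---------------------------------------------------------------------------
# homology table


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_homology_table(
    path: str | Path, e_max: float | None = None
) -> list[HomologyHit]:
    """Read 12-column BLAST tabular output; self-hits are dropped."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_BLAST_COLUMNS,
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    bad = df[pd.to_numeric(df["evalue"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric e-value at data row {bad.index[0] + 1}")
    hits = []
    for row in df.itertuples(index=False):
        if row.qseqid == row.sseqid:
            continue
        if e_max is not None and float(row.evalue) >= e_max:
            continue
        hits.append(
            HomologyHit(
                query_gene=row.qseqid,
                subject_gene=row.sseqid,
                percent_identity=float(row.pident),
                e_value=float(row.evalue),
                bit_score=float(row.bitscore),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# tandem arrays


def detect_tandem_arrays(
    hits: Sequence[HomologyHit], rank_index: RankIndex
) -> list[TandemPair]:
    """Homologous pairs at adjacent ranks on one chromosome.

    Each unordered pair is reported once, genes sorted lexicographically.
    """
    seen: set[tuple[str, str]] = set()
    out: list[TandemPair] = []
    for h in hits:
        for g in (h.query_gene, h.subject_gene):
            if g not in rank_index:
                raise KeyError(f"gene {g!r} absent from rank index")
        a, b = sorted((h.query_gene, h.subject_gene))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if rank_index.chromosome(a) != rank_index.chromosome(b):
            continue
        ra, rb = rank_index.rank(a), rank_index.rank(b)
        if abs(ra - rb) == 1:
            out.append(TandemPair(a, b, rank_index.chromosome(a), ra, rb))
    out.sort(key=lambda t: (t.chromosome, min(t.rank_a, t.rank_b)))
    return out


def tandem_percentage(n_tandem_genes: int, family_size: int) -> float:
    """Share of family genes involved in tandem duplication, 1-decimal %."""
    if family_size <= 0:
        raise ValueError("family_size must be positive")
    return round(100.0 * n_tandem_genes / family_size, 1)


# ---------------------------------------------------------------------------
# collinear block chaining


def _chain_orientation(
    anchors: list[tuple[int, int, str, str]],
    min_anchors: int,
    max_gap: int,
    inverted: bool,
) -> list[tuple[list[tuple[str, str]], float]]:
    """Best-chain extraction by DP; returns (anchor pair list, score) chains.

    *anchors* holds (a_rank, b_rank, gene_a, gene_b).  A-ranks must strictly
    increase along a chain; B-ranks strictly increase (same orientation) or
    strictly decrease (inverted); rank gaps on either axis may not exceed
    *max_gap*.  Score: +1 per anchor minus (gap_a + gap_b)/(2*max_gap) per
    transition.  Chains are peeled off best-first, each anchor used once.
    """
    sign = -1 if inverted else 1
    pts = sorted(
        ((a, sign * b, ga, gb) for a, b, ga, gb in anchors),
        key=lambda t: (t[0], t[1]),
    )
    used = [False] * len(pts)
    chains = []
    while True:
        best_score = [1.0] * len(pts)
        back: list[int | None] = [None] * len(pts)
        for j in range(len(pts)):
            if used[j]:
                continue
            for i in range(j):
                if used[i]:
                    continue
                gap_a = pts[j][0] - pts[i][0] - 1
                gap_b = pts[j][1] - pts[i][1] - 1
                if gap_a < 0 or gap_b < 0 or gap_a > max_gap or gap_b > max_gap:
                    continue
                cand = best_score[i] + 1.0 - (gap_a + gap_b) / (2.0 * max_gap)
                if cand > best_score[j]:
                    best_score[j] = cand
                    back[j] = i
        # pick terminal of the best chain still available
        order = [j for j in range(len(pts)) if not used[j]]
        if not order:
            break
        end = max(order, key=lambda j: best_score[j])
        chain_idx = []
        k: int | None = end
        while k is not None:
            chain_idx.append(k)
            k = back[k]
        chain_idx.reverse()
        if len(chain_idx) < min_anchors:
            break
        for k in chain_idx:
            used[k] = True
        chains.append(
            ([(pts[k][2], pts[k][3]) for k in chain_idx], best_score[end])
        )
    return chains


def chain_collinear_blocks(
    hits: Sequence[HomologyHit],
    rank_index_a: RankIndex,
    rank_index_b: RankIndex,
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain cross-genome homology anchors into collinear blocks.

    Hits whose query is in genome A and subject in genome B become anchors;
    chaining runs per chromosome pair, separately for the two orientations.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    seen: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_gene not in rank_index_a or h.subject_gene not in rank_index_b:
            continue
        key = (h.query_gene, h.subject_gene)
        if key in seen:
            continue
        seen.add(key)
        ca = rank_index_a.chromosome(h.query_gene)
        cb = rank_index_b.chromosome(h.subject_gene)
        by_pair.setdefault((ca, cb), []).append(
            (
                rank_index_a.rank(h.query_gene),
                rank_index_b.rank(h.subject_gene),
                h.query_gene,
                h.subject_gene,
            )
        )
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_pair.items()):
        for inverted in (False, True):
            for pair_list, score in _chain_orientation(
                anchors, min_anchors, max_gap, inverted
            ):
                blocks.append(
                    CollinearBlock(
                        anchors=tuple(pair_list),
                        chrom_a=ca,
                        chrom_b=cb,
                        orientation="inverted" if inverted else "same",
                        score=score,
                    )
                )
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b))
    return blocks


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


class SaturationError(ValueError):
    """Proportion of differences too large for the Jukes-Cantor correction."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pair of aligned coding sequences (no internal stops)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("sequences have different lengths")
        if len(a) % 3:
            raise ValueError("length not divisible by 3")
        if set(a + b) - set(_NTS):
            raise ValueError("alphabet must be ACGT")
        for seq in (a, b):
            for i in range(0, len(seq) - 3, 3):
                if CODON_TO_AA[seq[i : i + 3]] == "*":
                    raise ValueError(f"internal stop codon at position {i + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def codon_sites(codon: str, count_stops_nonsyn: bool = False) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Each of the three positions contributes one site, split by the fraction
    of its single-nucleotide changes that are synonymous.  By default
    changes creating a stop codon are excluded from the denominator
    (renormalisation within the position); with *count_stops_nonsyn* they
    count as nonsynonymous instead.
    """
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError("stop codon has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if CODON_TO_AA[mut] == "*" and not count_stops_nonsyn:
                continue
            valid += 1
            syn += CODON_TO_AA[mut] == aa
        if valid:
            s += syn / valid
    return s, 3.0 - s


def codon_differences(
    codon_a: str, codon_b: str, count_stops_nonsyn: bool = False
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    All orderings of the differing positions are enumerated as substitution
    pathways; pathways passing through a stop codon are excluded (unless
    *count_stops_nonsyn*, which keeps them and counts stop-crossing steps
    as nonsynonymous).  Counts are averaged over admissible pathways.  When
    stop exclusion removes every pathway, the unrestricted set is used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and not count_stops_nonsyn:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur] and CODON_TO_AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:  # every route crosses a stop; fall back to all routes
        for order in permutations(diff_pos):
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur] and CODON_TO_AA[nxt] != "*":
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            pathways.append((sd, nd))
    n = len(pathways)
    return (sum(p[0] for p in pathways) / n, sum(p[1] for p in pathways) / n)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(
    pair: CodonAlignment, count_stops_nonsyn: bool = False
) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) Ka, Ks and ω for a codon alignment.

    Site counts are averaged over the two sequences; difference counts are
    pathway-averaged per codon; ps and pn receive the Jukes-Cantor
    correction d = -(3/4) ln(1 - 4p/3).  ω is None when Ks = 0.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_counted = 0
    for ca, cb in pair.codons():
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            continue  # tolerated terminal stop carries no sites
        n_counted += 1
        sa, _ = codon_sites(ca, count_stops_nonsyn)
        sb, _ = codon_sites(cb, count_stops_nonsyn)
        s_a += sa
        s_b += sb
        d_s, d_n = codon_differences(ca, cb, count_stops_nonsyn)
        sd += d_s
        nd += d_n
    n_total = 3.0 * n_counted
    s_sites = (s_a + s_b) / 2.0
    n_sites = n_total - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    omega = None if ks == 0 else ka / ks
    return ka, ks, omega


def codon_alignment_from_protein(
    prot_row_a: str, prot_row_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its coding sequences.

    A terminal stop codon on either CDS is tolerated and stripped.  Columns
    gapped in either protein row are dropped in codon triplets.
    """
    out_a: list[str] = []
    out_b: list[str] = []
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for seq, prot in ((cds_a, prot_row_a), (cds_b, prot_row_b)):
        ungapped = prot.replace("-", "")
        need = 3 * len(ungapped)
        if len(seq) == need + 3 and CODON_TO_AA.get(seq[-3:]) == "*":
            continue
        if len(seq) != need:
            raise ValueError(
                f"CDS length {len(seq)} does not match protein length {len(ungapped)}"
            )
    ia = ib = 0
    for aa_a, aa_b in zip(prot_row_a, prot_row_b):
        ca = cds_a[3 * ia : 3 * ia + 3] if aa_a != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3] if aa_b != "-" else None
        ia += aa_a != "-"
        ib += aa_b != "-"
        if ca is not None and cb is not None:
            out_a.append(ca)
            out_b.append(cb)
    return CodonAlignment("".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# ortholog pairs, selection, divergence time


def classify_selection(omega: float | None, tol: float = 1e-9) -> str:
    if omega is None:
        return "undefined"
    if abs(omega - 1.0) <= tol:
        return "neutral"
    return "purifying" if omega < 1.0 else "positive"


def extract_ortholog_pairs(
    blocks: Sequence[CollinearBlock],
    family_roster_a: Iterable[str],
    family_roster_b: Iterable[str],
    kaks_fn: Callable[[str, str], tuple[float, float, float | None]],
    ks_max: float = 3.0,
) -> tuple[list[OrthologPair], list[str]]:
    """Family ortholog pairs from collinear blocks by the minimum-Ks rule.

    Every family gene of genome A appearing as a block anchor gathers its
    anchor mates as candidate partners; the partner with the smallest Ks is
    kept, provided Ks <= *ks_max* (saturation guard).  Genes with no anchor
    land in the returned unpaired list.  Multiplicity flags mark genes
    sharing partners (one-to-many / many-to-one).
    """
    fam_a = set(family_roster_a)
    fam_b = set(family_roster_b)
    mates: dict[str, set[str]] = {}
    for blk in blocks:
        for ga, gb in blk.anchors:
            if ga in fam_a:
                mates.setdefault(ga, set()).add(gb)
    chosen: list[tuple[str, str, float, float, float | None]] = []
    unpaired = sorted(g for g in fam_a if g not in mates)
    for ga in sorted(mates):
        best = None
        for gb in sorted(mates[ga]):
            ka, ks, omega = kaks_fn(ga, gb)
            if ks > ks_max:
                continue
            if best is None or ks < best[3]:
                best = (ga, gb, ka, ks, omega)
        if best is None:
            unpaired.append(ga)
            continue
        chosen.append((best[0], best[1], best[2], best[3], best[4]))
    partner_count: dict[str, int] = {}
    for _, gb, *_ in chosen:
        partner_count[gb] = partner_count.get(gb, 0) + 1
    pairs = []
    for ga, gb, ka, ks, omega in chosen:
        mult = "1:1"
        if len(mates[ga]) > 1:
            mult = "1:many"
        if partner_count[gb] > 1:
            mult = "many:1" if mult == "1:1" else "many:many"
        if gb not in fam_b:
            mult += ",partner-not-family"
        pairs.append(
            OrthologPair(ga, gb, ka, ks, omega, classify_selection(omega), mult)
        )
    return pairs, sorted(unpaired)


def divergence_time(ks: float, rate: float) -> float:
    """Divergence time in years: T = Ks / (2r), r in subs/synonymous site/year."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return ks / (2.0 * rate)
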