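"""Seeded synthetic inputs with planted truth for every pipeline stage.

Each generator is a pure function of its configuration and seed and
returns in-memory objects plus a truth table sufficient to score precision
and recall of the corresponding detection stage.  Writers serialise the
objects to the exact text formats the parsers ingest (FASTA, GFF3,
domtblout dialect, BLAST tabular, Ct TSV), so write-then-parse round trips
are part of the test surface.

What is emulated: proteomes with planted family members (class-correct
domain envelopes plus a real glycine-rich window) and two decoy kinds
(domain evidence without glycine richness; glycine richness without an
RNA-binding domain); paired genomes sharing ordered orthologous segments
with optional inversions, insertions/deletions and adjacent-rank tandem
copies; codon pairs diverged under a known ω; alignments evolved under an
equal-rate substitution model on a tree; and qPCR Ct tables with known
log2 effects and Gaussian Ct noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .family import (
    DomainClass,
    DomainHit,
    FamilyClass,
    ProteinRecord,
    write_domain_table,
)
from .genome import GeneModel
from .phylo import Alignment
from .synteny import CODON_TO_AA, SENSE_CODONS, CodonAlignment, HomologyHit

__all__ = [
    "ProteomeConfig",
    "GenomePairConfig",
    "ProteomeSim",
    "GenomePairSim",
    "simulate_proteome",
    "simulate_genome_pair",
    "simulate_codon_pair",
    "simulate_alignment_on_tree",
    "simulate_ct_table",
    "write_proteome_fasta",
    "write_gff",
    "write_homology_table",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NTS = "ACGT"

# fixed sub-stream ids so adding a generator never perturbs the others
_GEN_IDS = {
    "proteome": 1,
    "genomes": 2,
    "codons": 3,
    "alignment": 4,
    "ct": 5,
}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _GEN_IDS[generator]])


def _random_aa(rng: np.random.Generator, n: int, gly_freq: float = 0.07) -> str:
    """Background residues: glycine at *gly_freq*, the rest uniform."""
    other = [a for a in AA20 if a != "G"]
    p = [gly_freq] + [(1 - gly_freq) / len(other)] * len(other)
    return "".join(rng.choice(["G"] + other, size=n, p=p))


# ---------------------------------------------------------------------------
# proteome with planted family members and decoys


_ACCESSION_FOR = {
    DomainClass.RRM: "PF00076",
    DomainClass.CSD: "PF00313",
    DomainClass.ZNF_CCHC: "PF00098",
    DomainClass.ZNF_RANBP2: "PF00641",
}
_DOMAIN_LEN = {
    DomainClass.RRM: 80,
    DomainClass.CSD: 65,
    DomainClass.ZNF_CCHC: 20,
    DomainClass.ZNF_RANBP2: 22,
}

#: architecture variants planted per subfamily (cycled through)
_ARCH_VARIANTS: dict[FamilyClass, tuple[tuple[DomainClass, ...], ...]] = {
    FamilyClass.IVA: ((DomainClass.RRM,),),
    FamilyClass.IVB: (
        (DomainClass.RRM, DomainClass.ZNF_CCHC),
        (DomainClass.RRM, DomainClass.ZNF_RANBP2, DomainClass.ZNF_RANBP2),
    ),
    FamilyClass.IVC: (
        (DomainClass.CSD, DomainClass.ZNF_CCHC, DomainClass.ZNF_CCHC),
        (DomainClass.CSD, DomainClass.ZNF_CCHC),
    ),
    FamilyClass.IVD: ((DomainClass.RRM, DomainClass.RRM),),
}


@dataclass(frozen=True)
class ProteomeConfig:
    seed: int = 0
    n_background: int = 30
    class_mix: Mapping[str, int] = field(
        default_factory=lambda: {"IVa": 4, "IVb": 3, "IVc": 3, "IVd": 2}
    )
    n_decoy_domain_only: int = 4
    n_decoy_glycine_only: int = 4
    n_noise_hits: int = 0
    window: int = 20
    planted_evalue: float = 1e-12
    noise_evalue: float = 5e-3


@dataclass
class ProteomeSim:
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    truth: dict


def _cap_glycine(seq: str, window: int, max_g: int) -> str:
    """Replace glycines until no window holds more than *max_g* of them."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        for i in range(max(1, len(chars) - window + 1)):
            win = chars[i : i + window]
            if win.count("G") > max_g:
                chars[i + win.index("G")] = "A"
                changed = True
    return "".join(chars)


def _glycine_block(rng: np.random.Generator, window: int) -> str:
    """A window-length stretch with well over half glycine (14 of 20)."""
    n_g = max(int(0.7 * window), (window // 2) + 2)
    pos = rng.choice(window, size=n_g, replace=False)
    chars = [c for c in _random_aa(rng, window)]
    for p in pos:
        chars[p] = "G"
    return "".join(chars)


def simulate_proteome(config: ProteomeConfig) -> ProteomeSim:
    """Proteome FASTA + domain table + truth for the identification stage.

    Planted members carry class-consistent domain envelopes and a genuine
    glycine-rich window placed after the last domain.  Domain-only decoys
    keep the envelopes but have every 20-residue window capped at 9
    glycines; glycine-only decoys are rich but lack any RRM/CSD hit (half
    of them get a lone CCHC zinc-finger hit to exercise the domain
    requirement).  Optional noise rows carry above-threshold e-values.
    """
    rng = _rng(config.seed, "proteome")
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth: dict = {
        "members": {},
        "decoys_domain_only": [],
        "decoys_glycine_only": [],
        "background": [],
    }
    counter = 0

    def next_ids() -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}", f"G{counter:04d}"

    def build_domains(arch: Sequence[DomainClass]) -> tuple[str, list[tuple[DomainClass, int, int]]]:
        parts = [_cap_glycine(_random_aa(rng, 12), config.window, 6)]
        pos = 12
        envelopes = []
        for dc in arch:
            dlen = _DOMAIN_LEN[dc]
            seg = _cap_glycine(_random_aa(rng, dlen), config.window, 6)
            envelopes.append((dc, pos + 1, pos + dlen))  # 1-based inclusive
            parts.append(seg)
            pos += dlen
            linker = _cap_glycine(_random_aa(rng, 15), config.window, 6)
            parts.append(linker)
            pos += 15
        return "".join(parts), envelopes

    def emit_hits(pid: str, envelopes, seq_len: int) -> None:
        for dc, s, e in envelopes:
            hits.append(
                DomainHit(
                    protein_id=pid,
                    accession=_ACCESSION_FOR[dc],
                    domain_class=dc,
                    env_start=s,
                    env_end=min(e, seq_len),
                    full_seq_evalue=config.planted_evalue,
                    domain_ievalue=config.planted_evalue * 10,
                    bit_score=float(rng.integers(40, 120)),
                )
            )

    # planted family members
    variant_idx: dict[str, int] = {}
    for cls_name, count in config.class_mix.items():
        fam = FamilyClass(cls_name)
        for _ in range(count):
            pid, gid = next_ids()
            i = variant_idx.get(cls_name, 0)
            arch = _ARCH_VARIANTS[fam][i % len(_ARCH_VARIANTS[fam])]
            variant_idx[cls_name] = i + 1
            body, envelopes = build_domains(arch)
            gly_start = len(body) + 1
            gly = _glycine_block(rng, config.window)
            tail = _cap_glycine(_random_aa(rng, 10), config.window, 6)
            seq = body + gly + tail
            proteins.append(ProteinRecord(pid, gid, seq))
            emit_hits(pid, envelopes, len(seq))
            truth["members"][pid] = {
                "gene_id": gid,
                "class": fam.value,
                "architecture": [dc.value for dc in arch],
                "glycine_window_start": gly_start,
            }

    # decoy kind A: domain evidence, glycine capped at 9/20
    for _ in range(config.n_decoy_domain_only):
        pid, gid = next_ids()
        arch = (DomainClass.RRM,)
        body, envelopes = build_domains(arch)
        seq = _cap_glycine(body + _random_aa(rng, 40), config.window, 9)
        proteins.append(ProteinRecord(pid, gid, seq))
        emit_hits(pid, envelopes, len(seq))
        truth["decoys_domain_only"].append(pid)

    # decoy kind B: glycine-rich, no RRM/CSD evidence
    for k in range(config.n_decoy_glycine_only):
        pid, gid = next_ids()
        seq = (
            _cap_glycine(_random_aa(rng, 60), config.window, 6)
            + _glycine_block(rng, config.window)
            + _cap_glycine(_random_aa(rng, 20), config.window, 6)
        )
        proteins.append(ProteinRecord(pid, gid, seq))
        if k % 2 == 0:
            hits.append(
                DomainHit(
                    protein_id=pid,
                    accession=_ACCESSION_FOR[DomainClass.ZNF_CCHC],
                    domain_class=DomainClass.ZNF_CCHC,
                    env_start=5,
                    env_end=24,
                    full_seq_evalue=config.planted_evalue,
                    domain_ievalue=config.planted_evalue * 10,
                    bit_score=35.0,
                )
            )
        truth["decoys_glycine_only"].append(pid)

    # plain background proteins
    for _ in range(config.n_background):
        pid, gid = next_ids()
        n = int(rng.integers(150, 400))
        seq = _cap_glycine(_random_aa(rng, n), config.window, 8)
        proteins.append(ProteinRecord(pid, gid, seq))
        truth["background"].append(pid)

    # noise rows: above-threshold e-values on random background proteins
    for _ in range(config.n_noise_hits):
        pid = truth["background"][int(rng.integers(len(truth["background"])))]
        plen = next(p.length for p in proteins if p.protein_id == pid)
        start = int(rng.integers(1, max(2, plen - 60)))
        hits.append(
            DomainHit(
                protein_id=pid,
                accession="PF00076",
                domain_class=DomainClass.RRM,
                env_start=start,
                env_end=min(start + 60, plen),
                full_seq_evalue=config.noise_evalue,
                domain_ievalue=config.noise_evalue,
                bit_score=12.0,
            )
        )

    return ProteomeSim(proteins, hits, truth)


# ---------------------------------------------------------------------------
# paired genomes with planted blocks and tandem duplicates


@dataclass(frozen=True)
class BlockSpec:
    """One planted collinear segment: genome A source and B placement."""

    chrom_a: int  # 0-based chromosome index in genome A
    start_index: int  # 0-based gene index on that chromosome
    length: int
    inverted: bool = False
    chrom_b: int = 0


@dataclass(frozen=True)
class GenomePairConfig:
    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 60
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec(chrom_a=0, start_index=10, length=8, inverted=False, chrom_b=0),
        BlockSpec(chrom_a=1, start_index=25, length=7, inverted=True, chrom_b=1),
    )
    gap_rate: float = 0.0
    tandem_pairs: int = 2
    n_noise_hits: int = 0
    gene_span: int = 2000
    gene_step: int = 5000


@dataclass
class GenomePairSim:
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    hits_ab: list[HomologyHit]  # cross-genome homology (A query, B subject)
    hits_bb: list[HomologyHit]  # within-genome-B paralogy
    truth: dict


def _make_gene(gene_id: str, chrom: str, index: int, rng: np.random.Generator,
               span: int, step: int) -> GeneModel:
    start = 1000 + index * step
    end = start + span
    n_ex = int(rng.integers(1, 4))
    bounds = sorted(rng.choice(range(start + 1, end - 1), size=2 * (n_ex - 1),
                               replace=False)) if n_ex > 1 else []
    edges = [start] + [int(b) for b in bounds] + [end]
    exons = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_ex))
    return GeneModel(gene_id, chrom, start, end,
                     "+" if rng.integers(2) else "-", exons)


def simulate_genome_pair(config: GenomePairConfig) -> GenomePairSim:
    """Two annotated genomes with planted collinear blocks and tandem copies.

    Genome A is a fresh gene order.  Each planted block copies an ordered
    A segment onto a B chromosome (reversed when inverted); at *gap_rate*
    copied genes are skipped (deletions) or filler genes inserted.  Tandem
    pairs are adjacent-rank duplicates of copied B genes, connected by a
    within-B homology hit.  Cross-genome hits cover all planted ortholog
    pairs plus *n_noise_hits* uniform non-orthologous pairs.
    """
    rng = _rng(config.seed, "genomes")
    for spec in config.blocks:
        if spec.start_index + spec.length > config.genes_per_chromosome:
            raise ValueError(f"block {spec} exceeds chromosome length")
        if spec.chrom_a >= config.n_chromosomes or spec.chrom_b >= config.n_chromosomes:
            raise ValueError(f"block {spec} names an absent chromosome")

    genes_a: list[GeneModel] = []
    a_by_chrom: list[list[str]] = []
    for c in range(config.n_chromosomes):
        chrom = f"A{c + 1:02d}"
        ids = []
        for i in range(config.genes_per_chromosome):
            gid = f"ga_{c + 1:02d}_{i + 1:03d}"
            genes_a.append(_make_gene(gid, chrom, i, rng,
                                      config.gene_span, config.gene_step))
            ids.append(gid)
        a_by_chrom.append(ids)

    # genome B: filler + copied segments, per B chromosome
    b_orders: list[list[str]] = [[] for _ in range(config.n_chromosomes)]
    ortholog_of: dict[str, str] = {}  # B gene -> A gene
    filler_n = 0

    def filler(chrom_list: list[str], count: int) -> None:
        nonlocal filler_n
        for _ in range(count):
            filler_n += 1
            chrom_list.append(f"gb_f{filler_n:03d}")

    truth_blocks = []
    for c in range(config.n_chromosomes):
        filler(b_orders[c], 5)
    for spec in config.blocks:
        src = a_by_chrom[spec.chrom_a][spec.start_index : spec.start_index + spec.length]
        if spec.inverted:
            src = src[::-1]
        anchors = []
        for a_gene in src:
            if config.gap_rate > 0 and rng.random() < config.gap_rate:
                continue  # deletion
            if config.gap_rate > 0 and rng.random() < config.gap_rate:
                filler(b_orders[spec.chrom_b], 1)  # insertion
            b_gene = a_gene.replace("ga_", "gb_")
            b_orders[spec.chrom_b].append(b_gene)
            ortholog_of[b_gene] = a_gene
            anchors.append((a_gene, b_gene))
        truth_blocks.append(
            {
                "chrom_a": f"A{spec.chrom_a + 1:02d}",
                "chrom_b": f"B{spec.chrom_b + 1:02d}",
                "orientation": "inverted" if spec.inverted else "same",
                # anchors listed in increasing A-rank order
                "anchors": anchors[::-1] if spec.inverted else anchors,
            }
        )
        filler(b_orders[spec.chrom_b], 5)

    # tandem duplicates: adjacent-rank copies of copied B genes
    copied = [g for order in b_orders for g in order if g in ortholog_of]
    n_tandem = min(config.tandem_pairs, len(copied))
    tandem_sources = list(rng.choice(copied, size=n_tandem, replace=False))
    tandem_truth = []
    for src_gene in tandem_sources:
        dup = src_gene + "_td"
        for order in b_orders:
            if src_gene in order:
                order.insert(order.index(src_gene) + 1, dup)
                break
        tandem_truth.append(tuple(sorted((src_gene, dup))))

    genes_b: list[GeneModel] = []
    for c, order in enumerate(b_orders):
        chrom = f"B{c + 1:02d}"
        for i, gid in enumerate(order):
            genes_b.append(_make_gene(gid, chrom, i, rng,
                                      config.gene_span, config.gene_step))

    hits_ab: list[HomologyHit] = []
    for b_gene, a_gene in sorted(ortholog_of.items()):
        hits_ab.append(HomologyHit(a_gene, b_gene, 85.0, 1e-50, 300.0))
    # noise: uniform non-orthologous cross pairs
    a_ids = [g.gene_id for g in genes_a]
    b_ids = [g.gene_id for g in genes_b]
    planted = {(a, b) for b, a in ortholog_of.items()}
    made = 0
    while made < config.n_noise_hits:
        qa = a_ids[int(rng.integers(len(a_ids)))]
        sb = b_ids[int(rng.integers(len(b_ids)))]
        if (qa, sb) in planted:
            continue
        hits_ab.append(HomologyHit(qa, sb, 40.0, 1e-6, 60.0))
        made += 1

    hits_bb = [
        HomologyHit(a, b, 95.0, 1e-80, 500.0) for a, b in tandem_truth
    ]

    truth = {
        "ortholog_map": {a: b for b, a in ortholog_of.items()},
        "blocks": truth_blocks,
        "tandem_pairs_b": [list(t) for t in sorted(tandem_truth)],
    }
    return GenomePairSim(genes_a, genes_b, hits_ab, hits_bb, truth)


# ---------------------------------------------------------------------------
# codon pair divergence under known omega


def simulate_codon_pair(
    length_codons: int,
    omega_true: float,
    t: float,
    seed: int,
) -> tuple[CodonAlignment, dict]:
    """Ancestor/descendant codon pair diverged under acceptance ratio ω.

    The ancestor is uniform over sense codons.  Each nucleotide site
    proposes Poisson(*t*) point mutations; synonymous proposals are always
    accepted, nonsynonymous ones with probability *omega_true*, and
    proposals creating a stop codon are rejected.  Realised accepted counts
    are recorded in the truth dict.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if t < 0 or omega_true < 0:
        raise ValueError("t and omega_true must be >= 0")
    rng = _rng(seed, "codons")
    anc = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=length_codons)]
    des = list(anc)
    n_events = rng.poisson(t, size=3 * length_codons)
    syn_acc = nonsyn_acc = rejected_stop = 0
    for site, k in enumerate(n_events):
        ci, pos = divmod(site, 3)
        for _ in range(k):
            cur = des[ci]
            nt = _NTS[(( _NTS.index(cur[pos]) + 1 + int(rng.integers(3))) % 4)]
            mut = cur[:pos] + nt + cur[pos + 1 :]
            if CODON_TO_AA[mut] == "*":
                rejected_stop += 1
                continue
            if CODON_TO_AA[mut] == CODON_TO_AA[cur]:
                des[ci] = mut
                syn_acc += 1
            elif rng.random() < omega_true:
                des[ci] = mut
                nonsyn_acc += 1
    truth = {
        "omega_true": omega_true,
        "t": t,
        "synonymous_accepted": syn_acc,
        "nonsynonymous_accepted": nonsyn_acc,
        "stop_rejected": rejected_stop,
    }
    return CodonAlignment("".join(anc), "".join(des)), truth


# ---------------------------------------------------------------------------
# alignment evolved on a tree


def simulate_alignment_on_tree(
    tree: dendropy.Tree, n_sites: int, seed: int
) -> Alignment:
    """Evolve amino-acid sites independently along a tree.

    Equal-rate model: each branch applies Poisson(branch length) jumps per
    site, each jump replacing the residue with a uniformly chosen different
    one — the regime the Poisson distance correction assumes.
    """
    rng = _rng(seed, "alignment")
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(20, size=n_sites)
    names, rows = [], []
    for node in tree.preorder_node_iter():
        if node is not root:
            parent_seq = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            seq = parent_seq.copy()
            ks = rng.poisson(bl, size=n_sites)
            for site in np.nonzero(ks)[0]:
                for _ in range(ks[site]):
                    seq[site] = (seq[site] + 1 + rng.integers(19)) % 20
            seqs[id(node)] = seq
        if node.is_leaf():
            names.append(node.taxon.label if node.taxon else f"leaf{len(names)}")
            rows.append("".join(AA20[i] for i in seqs[id(node)]))
    return Alignment(tuple(names), tuple(rows))


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct_table(
    effects: Mapping[str, Mapping[str, float]],
    control_sample: str,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "actin",
    baseline_reference: float = 20.0,
    baseline_target: float = 25.0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table with known per-sample log2 effects.

    *effects* maps target gene -> sample -> true log2 fold change relative
    to the control sample (the control's effect is forced to 0).  The
    reference gene sits at a constant baseline; each target's Ct is
    baseline − effect; every measurement gets Gaussian noise of sd
    *noise_sd* across *replicates* replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    samples: list[str] = []
    for per_sample in effects.values():
        for s in per_sample:
            if s not in samples:
                samples.append(s)
    if control_sample not in samples:
        samples.insert(0, control_sample)
    rng = _rng(seed, "ct")
    rows = []
    for s in samples:
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample": s,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": baseline_reference + rng.normal(0.0, noise_sd),
                }
            )
        for gene, per_sample in effects.items():
            eff = 0.0 if s == control_sample else per_sample.get(s, 0.0)
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": s,
                        "gene": gene,
                        "replicate": rep,
                        "ct": baseline_target - eff + rng.normal(0.0, noise_sd),
                    }
                )
    truth = {
        "control_sample": control_sample,
        "reference_gene": reference_gene,
        "effects": {g: dict(p) for g, p in effects.items()},
        "noise_sd": noise_sd,
        "replicates": replicates,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# writers (text formats matching the parsers)


def write_proteome_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id} gene={p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    return path


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> Path:
    """GFF3 with gene/mRNA/exon features; 1-based inclusive on disk."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.start + 1, g.end
            fh.write(
                f"{g.chromosome}\trbgrp-sim\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chromosome}\trbgrp-sim\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\trbgrp-sim\texon\t{es + 1}\t{ee}\t.\t"
                    f"{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
    return path


def write_homology_table(hits: Sequence[HomologyHit], path: str | Path) -> Path:
    """12-column BLAST tabular."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t{h.percent_identity:.2f}\t"
                f"500\t10\t0\t1\t500\t1\t500\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )
    return path


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return path
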