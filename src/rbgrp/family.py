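"""Identification and classification of RNA-binding glycine-rich proteins.

RB-GRPs (class IV of the glycine-rich protein superfamily) combine an
RNA-binding domain — an RNA-recognition motif (RRM) or a cold-shock domain
(CSD) — with glycine-rich regions arranged as (Gly)n-X repeats.  A proteome
is mined for them in two steps: profile-HMM domain evidence (ingested here
as a precomputed domain table, one row per domain envelope) filtered at an
E-value threshold, followed by a sliding-window glycine-content filter that
demands more than 50% glycine within some 20-residue window.  Survivors are
classified by domain architecture into subfamilies:

* IVa — a single RRM;
* IVb — one RRM plus one or more zinc fingers (CCHC or RanBP2 type);
* IVc — a CSD plus zinc finger(s);
* IVd — two RRMs.

The module also computes the physicochemical descriptors customarily
reported for a family roster: length, average molecular weight and
theoretical isoelectric point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

__all__ = [
    "DomainClass",
    "FamilyClass",
    "ProteinRecord",
    "DomainHit",
    "GlycineProfile",
    "FamilyAssignment",
    "ProteinProperties",
    "FamilyMember",
    "DEFAULT_ACCESSION_MAP",
    "parse_proteome",
    "parse_domain_table",
    "filter_domain_hits",
    "glycine_profile",
    "resolve_domains",
    "resolve_architecture",
    "classify_family",
    "compute_molecular_weight",
    "compute_isoelectric_point",
    "extract_domain_segments",
    "identify_family_members",
    "roster_table",
]

WATER_DA = 18.0153
#: average residue (not free amino acid) masses, Da
_RESIDUE_MASS = {aa: w - WATER_DA for aa, w in protein_weights.items()}
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)


class DomainClass(str, Enum):
    RRM = "RRM"
    CSD = "CSD"
    ZNF_CCHC = "ZnF_CCHC"
    ZNF_RANBP2 = "ZnF_RanBP2"
    OTHER = "OTHER"


class FamilyClass(str, Enum):
    IVA = "IVa"
    IVB = "IVb"
    IVC = "IVc"
    IVD = "IVd"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Pfam accession -> domain class.  The seven RRM-clan profiles and the CSD
#: profile are the family-defining searches; the two zinc-finger profiles
#: only refine the architecture.  Unknown accessions map to OTHER.
DEFAULT_ACCESSION_MAP: dict[str, DomainClass] = {
    "PF00076": DomainClass.RRM,
    "PF04059": DomainClass.RRM,
    "PF08777": DomainClass.RRM,
    "PF10378": DomainClass.RRM,
    "PF10598": DomainClass.RRM,
    "PF13893": DomainClass.RRM,
    "PF14259": DomainClass.RRM,
    "PF00313": DomainClass.CSD,
    "PF00098": DomainClass.ZNF_CCHC,
    "PF00641": DomainClass.ZNF_RANBP2,
}

#: token strings accepted in architecture labels, hyphen-joined
_ARCH_LABEL = {
    DomainClass.RRM: "RRM",
    DomainClass.CSD: "CSD",
    DomainClass.ZNF_CCHC: "C2HC",
    DomainClass.ZNF_RANBP2: "RanBP2",
}


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain envelope on one protein (coordinates 1-based inclusive)."""

    protein_id: str
    accession: str
    domain_class: DomainClass
    env_start: int
    env_end: int
    full_seq_evalue: float
    domain_ievalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"bad envelope {self.env_start}-{self.env_end} on {self.protein_id}"
            )
        if self.full_seq_evalue <= 0 or self.domain_ievalue <= 0:
            raise ValueError("e-values must be positive")


@dataclass(frozen=True)
class GlycineProfile:
    window_length: int
    max_window_fraction: float
    best_window_start: int | None
    is_glycine_rich: bool


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    architecture: tuple[DomainClass, ...]
    family_class: FamilyClass

    @property
    def architecture_string(self) -> str:
        return "-".join(_ARCH_LABEL.get(t, t.value) for t in self.architecture)


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    molecular_weight_kda: float
    isoelectric_point: float


@dataclass(frozen=True)
class FamilyMember:
    protein: ProteinRecord
    assignment: FamilyAssignment
    glycine: GlycineProfile
    properties: ProteinProperties


# ---------------------------------------------------------------------------
# parsing


def parse_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA.

    The gene locus is taken from a ``gene=<id>`` token in the description
    when present, otherwise the record id itself is used (single-isoform
    proteomes need no annotation).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene_id = tok[5:]
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, gene_id, str(rec.seq).upper()))
    return records


class DomainTableError(ValueError):
    pass


def parse_domain_table(
    path: str | Path,
    accession_map: Mapping[str, DomainClass] | None = None,
) -> list[DomainHit]:
    """Parse a HMMER per-domain table (domtblout dialect).

    Whitespace-separated, ``#`` comment lines skipped.  Column layout follows
    hmmsearch --domtblout: target (sequence) name in column 1, query profile
    accession in column 5, full-sequence E-value in column 7, per-domain
    independent E-value in column 13, domain bit score in column 14 and the
    envelope in columns 20-21.  Accessions are mapped to a domain class via
    *accession_map* (version suffixes like ``PF00076.22`` are tolerated);
    unknown accessions become OTHER.
    """
    amap = DEFAULT_ACCESSION_MAP if accession_map is None else accession_map
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise DomainTableError(
                    f"{path}:{lineno}: expected >=22 columns, got {len(fields)}"
                )
            try:
                protein_id = fields[0]
                accession = fields[4].split(".")[0]
                full_e = float(fields[6])
                ieval = float(fields[12])
                score = float(fields[13])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    accession=accession,
                    domain_class=amap.get(accession, DomainClass.OTHER),
                    env_start=env_start,
                    env_end=env_end,
                    full_seq_evalue=full_e,
                    domain_ievalue=ieval,
                    bit_score=score,
                )
            )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits back out in the domtblout column layout (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("# target_name acc tlen query_name accession qlen E-value score "
                 "bias # of c-Evalue i-Evalue score bias hmm_from hmm_to "
                 "ali_from ali_to env_from env_to acc description\n")
        for h in hits:
            fh.write(
                f"{h.protein_id} - 0 {h.domain_class.value} {h.accession} 0 "
                f"{h.full_seq_evalue:.3g} {h.bit_score:.1f} 0.0 1 1 "
                f"{h.domain_ievalue:.3g} {h.domain_ievalue:.3g} {h.bit_score:.1f} 0.0 "
                f"1 1 {h.env_start} {h.env_end} {h.env_start} {h.env_end} 0.90 -\n"
            )


# ---------------------------------------------------------------------------
# filtering and classification


def filter_domain_hits(hits: Sequence[DomainHit], e_max: float = 1e-4) -> list[DomainHit]:
    """Keep hits with full-sequence E-value strictly below *e_max*."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.full_seq_evalue < e_max]


def glycine_profile(
    sequence: str, window: int = 20, threshold: float = 0.5
) -> GlycineProfile:
    """Best glycine fraction over all length-*window* substrings.

    A protein is glycine-rich when some window holds strictly more than
    *threshold* glycine (default: >50%, i.e. at least 11 G in 20 residues).
    Sequences shorter than the window are scored over their full length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        frac = seq.count("G") / n
        best = 1
    else:
        count = seq[:window].count("G")
        best_count, best = count, 1
        for i in range(1, n - window + 1):
            count += (seq[i + window - 1] == "G") - (seq[i - 1] == "G")
            if count > best_count:
                best_count, best = count, i + 1
        frac = best_count / window
    rich = frac > threshold
    return GlycineProfile(window, frac, best if frac > 0 else None, rich)


@dataclass(frozen=True)
class ResolvedDomain:
    """A merged domain envelope contributing one architecture token."""

    domain_class: DomainClass
    env_start: int
    env_end: int


def _reciprocal_overlap(a: ResolvedDomain, h: DomainHit) -> float:
    ov = min(a.env_end, h.env_end) - max(a.env_start, h.env_start) + 1
    if ov <= 0:
        return 0.0
    shorter = min(a.env_end - a.env_start + 1, h.env_end - h.env_start + 1)
    return ov / shorter


def resolve_domains(hits: Sequence[DomainHit]) -> list[ResolvedDomain]:
    """Merge same-class overlapping envelopes into single architecture tokens.

    Hits are ordered by envelope start; two envelopes of the same domain
    class overlapping by more than half the shorter one are treated as one
    domain (repeated weak profile hits on the same RRM must not be read as
    two RRMs).  OTHER-class hits never form tokens.
    """
    if hits:
        ids = {h.protein_id for h in hits}
        if len(ids) > 1:
            raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    merged: list[ResolvedDomain] = []
    for h in sorted(hits, key=lambda h: (h.env_start, h.env_end)):
        if h.domain_class is DomainClass.OTHER:
            continue
        for i, m in enumerate(merged):
            if m.domain_class is h.domain_class and _reciprocal_overlap(m, h) > 0.5:
                merged[i] = ResolvedDomain(
                    m.domain_class,
                    min(m.env_start, h.env_start),
                    max(m.env_end, h.env_end),
                )
                break
        else:
            merged.append(ResolvedDomain(h.domain_class, h.env_start, h.env_end))
    merged.sort(key=lambda m: (m.env_start, m.env_end))
    return merged


def resolve_architecture(hits: Sequence[DomainHit]) -> list[DomainClass]:
    """Ordered architecture tokens for one protein's filtered hits."""
    return [m.domain_class for m in resolve_domains(hits)]


def classify_family(architecture: Sequence[DomainClass]) -> FamilyClass:
    """Map a domain architecture to its class IV subfamily.

    Precedence: any CSD wins (IVc, with or without zinc fingers, matching
    observed family rosters where a CSD plus a single CCHC is still IVc);
    then two or more RRMs (IVd); then one RRM plus at least one zinc finger
    of either type (IVb); then exactly one RRM (IVa).  Anything else is
    UNCLASSIFIED.  Total and deterministic.
    """
    tokens = list(architecture)
    n_rrm = sum(t is DomainClass.RRM for t in tokens)
    n_znf = sum(
        t in (DomainClass.ZNF_CCHC, DomainClass.ZNF_RANBP2) for t in tokens
    )
    if any(t is DomainClass.CSD for t in tokens):
        return FamilyClass.IVC
    if n_rrm >= 2:
        return FamilyClass.IVD
    if n_rrm == 1 and n_znf >= 1:
        return FamilyClass.IVB
    if n_rrm == 1:
        return FamilyClass.IVA
    return FamilyClass.UNCLASSIFIED


# ---------------------------------------------------------------------------
# physicochemical properties


def compute_molecular_weight(sequence: str, allow_x: bool = False) -> float:
    """Average-isotope molecular weight in kDa (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_DA
    for aa in sequence.upper():
        if aa == "X":
            if not allow_x:
                raise ValueError("unknown residue 'X' (pass allow_x=True to average)")
            total += _MEAN_RESIDUE_MASS
        else:
            try:
                total += _RESIDUE_MASS[aa]
            except KeyError:
                raise ValueError(f"unknown residue {aa!r}") from None
    return total / 1000.0


def compute_isoelectric_point(sequence: str) -> float:
    """Theoretical pI: pH of zero net charge under the Bjellqvist pKa set.

    The Henderson-Hasselbalch charge model (termini plus D, E, C, Y, H, K, R
    side chains) is the one behind the ExPASy calculator; the root is found
    by bisection on [0, 14] to |charge| < 1e-6.
    """
    if not sequence:
        raise ValueError("empty sequence")
    ip = IsoelectricPoint(sequence.upper())
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = ip.charge_at_pH(mid)
        if abs(q) < 1e-6:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


# ---------------------------------------------------------------------------
# domain segments for downstream alignment


def extract_domain_segments(
    protein: ProteinRecord, domains: Sequence[ResolvedDomain]
) -> list[tuple[str, str]]:
    """Cut resolved domain envelopes out of the protein sequence.

    Multi-domain proteins get positional suffixes so each domain can enter a
    phylogeny as its own taxon: two domains become ``<id> N`` / ``<id> C``,
    three or more add ``M`` (``M1``, ``M2``, ... when several middles).
    """
    doms = sorted(domains, key=lambda d: (d.env_start, d.env_end))
    for d in doms:
        if d.env_end > protein.length:
            raise ValueError(
                f"envelope {d.env_start}-{d.env_end} outside {protein.protein_id} "
                f"(length {protein.length})"
            )
    k = len(doms)
    out = []
    for i, d in enumerate(doms):
        if k == 1:
            name = protein.protein_id
        elif i == 0:
            name = f"{protein.protein_id} N"
        elif i == k - 1:
            name = f"{protein.protein_id} C"
        elif k == 3:
            name = f"{protein.protein_id} M"
        else:
            name = f"{protein.protein_id} M{i}"
        out.append((name, protein.sequence[d.env_start - 1 : d.env_end]))
    return out


# ---------------------------------------------------------------------------
# the composite identification stage


def _longest_isoform(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    # non-redundancy rule: one protein per gene locus, the longest isoform;
    # length ties broken toward the lexicographically smaller protein id
    best: dict[str, ProteinRecord] = {}
    for p in proteins:
        cur = best.get(p.gene_id)
        if cur is None or p.length > cur.length or (
            p.length == cur.length and p.protein_id < cur.protein_id
        ):
            best[p.gene_id] = p
    return [best[g] for g in sorted(best)]


def identify_family_members(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    e_max: float = 1e-4,
    window: int = 20,
    gly_threshold: float = 0.5,
) -> list[FamilyMember]:
    """Run the full identification pipeline and return the family roster.

    Stages: longest-isoform-per-gene reduction; full-sequence E-value filter
    (< *e_max*); require at least one RRM or CSD hit; glycine-window filter;
    architecture resolution (per-domain independent E-value also < *e_max*)
    and subfamily classification.  Only classified proteins are returned,
    each with molecular weight and pI computed.
    """
    keep = _longest_isoform(proteins)
    by_protein: dict[str, list[DomainHit]] = {}
    for h in filter_domain_hits(hits, e_max):
        by_protein.setdefault(h.protein_id, []).append(h)

    members: list[FamilyMember] = []
    for prot in keep:
        phits = [h for h in by_protein.get(prot.protein_id, [])
                 if h.env_end <= prot.length]
        if not any(
            h.domain_class in (DomainClass.RRM, DomainClass.CSD) for h in phits
        ):
            continue
        gly = glycine_profile(prot.sequence, window, gly_threshold)
        if not gly.is_glycine_rich:
            continue
        arch_hits = [h for h in phits if h.domain_ievalue < e_max]
        arch = resolve_architecture(arch_hits)
        fam = classify_family(arch)
        if fam is FamilyClass.UNCLASSIFIED:
            continue
        props = ProteinProperties(
            length=prot.length,
            molecular_weight_kda=compute_molecular_weight(prot.sequence, allow_x=True),
            isoelectric_point=compute_isoelectric_point(prot.sequence),
        )
        members.append(
            FamilyMember(
                protein=prot,
                assignment=FamilyAssignment(prot.protein_id, tuple(arch), fam),
                glycine=gly,
                properties=props,
            )
        )
    return members


def roster_table(
    members: Sequence[FamilyMember],
    positions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabular roster report (gene, position, domains, class, size, Mw, pI)."""
    rows = []
    for m in members:
        rows.append(
            {
                "gene": m.protein.gene_id,
                "protein": m.protein.protein_id,
                "position": (positions or {}).get(m.protein.gene_id, ""),
                "domain": m.assignment.architecture_string,
                "class": m.assignment.family_class.value,
                "size_aa": m.properties.length,
                "mw_kda": round(m.properties.molecular_weight_kda, 2),
                "pi": round(m.properties.isoelectric_point, 2),
                "max_gly_window": round(m.glycine.max_window_fraction, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "protein", "position", "domain", "class",
            "size_aa", "mw_kda", "pi", "max_gly_window",
        ],
    )
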