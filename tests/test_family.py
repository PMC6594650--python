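"""Family identification: parsing, filtering, classification, properties."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from rbgrp.family import (
    DomainClass,
    DomainHit,
    FamilyClass,
    ProteinRecord,
    classify_family,
    compute_isoelectric_point,
    compute_molecular_weight,
    extract_domain_segments,
    filter_domain_hits,
    glycine_profile,
    identify_family_members,
    parse_domain_table,
    parse_proteome,
    resolve_architecture,
    resolve_domains,
    roster_table,
    write_domain_table,
)
from rbgrp.simulate import ProteomeConfig, simulate_proteome, write_proteome_fasta

D = DomainClass


def _hit(pid="P1", acc="PF00076", dc=D.RRM, s=1, e=80, fe=1e-10, ie=1e-8):
    return DomainHit(pid, acc, dc, s, e, fe, ie, 50.0)


# ---------------------------------------------------------------------------
# domain table parsing


class TestDomainTable:
    def test_comment_only_file_yields_no_hits(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text("# comment\n#\n\n")
        assert parse_domain_table(p) == []

    def test_csd_accession_maps_to_cold_shock_domain(self, tmp_path):
        p = tmp_path / "t.domtbl"
        row = ("prot1 - 200 CSD PF00313.23 70 1e-20 80 0 1 1 "
               "1e-18 1e-18 78 0 1 70 5 70 3 72 0.9 -")
        p.write_text(row + "\n")
        hits = parse_domain_table(p)
        assert len(hits) == 1
        h = hits[0]
        assert h.domain_class is D.CSD
        assert (h.env_start, h.env_end) == (3, 72)
        assert h.full_seq_evalue == pytest.approx(1e-20)

    def test_write_then_parse_round_trips_all_fields(self, tmp_path, rng):
        hits = [
            _hit(pid=f"P{i}", s=int(rng.integers(1, 50)),
                 e=int(rng.integers(60, 200)),
                 fe=float(10.0 ** -rng.integers(5, 30)))
            for i in range(25)
        ]
        path = tmp_path / "round.domtbl"
        write_domain_table(hits, path)
        back = parse_domain_table(path)
        assert len(back) == 25
        for a, b in zip(hits, back):
            assert (a.protein_id, a.accession, a.domain_class) == (
                b.protein_id, b.accession, b.domain_class)
            assert (a.env_start, a.env_end) == (b.env_start, b.env_end)
            assert b.full_seq_evalue == pytest.approx(a.full_seq_evalue, rel=1e-2)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.domtbl"
        p.write_text("# ok\nonly three cols\n")
        with pytest.raises(ValueError, match=":2"):
            parse_domain_table(p)


class TestEvalueFilter:
    def test_threshold_is_strict(self):
        hits = [_hit(fe=1e-5), _hit(fe=1e-4), _hit(fe=1e-3)]
        kept = filter_domain_hits(hits, 1e-4)
        assert [h.full_seq_evalue for h in kept] == [1e-5]

    def test_matches_linear_scan_and_is_idempotent(self, rng):
        hits = [_hit(fe=float(10.0 ** rng.uniform(-8, 0))) for _ in range(100)]
        kept = filter_domain_hits(hits, 1e-4)
        oracle = [h for h in hits if h.full_seq_evalue < 1e-4]
        assert kept == oracle
        assert filter_domain_hits(kept, 1e-4) == kept
        assert set(map(id, kept)) <= set(map(id, hits))

    def test_empty_input(self):
        assert filter_domain_hits([], 1e-4) == []


# ---------------------------------------------------------------------------
# glycine window


class TestGlycineProfile:
    def test_all_glycine_window_is_rich(self):
        prof = glycine_profile("G" * 20)
        assert prof.max_window_fraction == 1.0 and prof.is_glycine_rich

    def test_no_glycine_is_not_rich(self):
        prof = glycine_profile("A" * 40)
        assert prof.max_window_fraction == 0.0 and not prof.is_glycine_rich

    def test_eleven_in_window_passes_ten_fails(self):
        clustered = ("AG" * 10 + "G") + "A" * 9  # 11 G inside positions 1-21
        assert glycine_profile("G" * 11 + "A" * 19).is_glycine_rich
        # 10 G in every window: alternate G with pairs of A
        spread = ("GAA" * 10)  # any 20-mer holds at most 7 G
        assert not glycine_profile(spread).is_glycine_rich
        assert glycine_profile("G" * 10 + "A" * 20).max_window_fraction == 0.5
        assert not glycine_profile("G" * 10 + "A" * 20).is_glycine_rich

    def test_short_sequence_scored_on_own_length(self):
        prof = glycine_profile("GGGGA")  # 4/5 > 0.5
        assert prof.max_window_fraction == pytest.approx(0.8)
        assert prof.is_glycine_rich

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(15, 120))
            seq = "".join(rng.choice(list("GAVLSTPRK"), size=n))
            prof = glycine_profile(seq)
            if n < 20:
                expect = seq.count("G") / n
            else:
                expect = max(
                    seq[i : i + 20].count("G") / 20 for i in range(n - 19)
                )
            assert prof.max_window_fraction == pytest.approx(expect)
            assert prof.is_glycine_rich == (expect > 0.5)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            glycine_profile("")


# ---------------------------------------------------------------------------
# architecture resolution and classification


class TestResolveArchitecture:
    def test_empty(self):
        assert resolve_architecture([]) == []

    def test_disjoint_hits_ordered_by_start(self):
        hits = [_hit(dc=D.ZNF_CCHC, acc="PF00098", s=100, e=118),
                _hit(dc=D.RRM, s=5, e=80)]
        assert resolve_architecture(hits) == [D.RRM, D.ZNF_CCHC]

    def test_nested_same_class_hits_merge(self):
        hits = [_hit(s=5, e=80), _hit(s=10, e=78)]
        assert resolve_architecture(hits) == [D.RRM]
        hits = [_hit(s=5, e=80), _hit(s=120, e=190)]
        assert resolve_architecture(hits) == [D.RRM, D.RRM]

    def test_merge_rule_matches_interval_oracle(self, rng):
        for _ in range(100):
            s1 = int(rng.integers(1, 100)); e1 = s1 + int(rng.integers(10, 80))
            s2 = int(rng.integers(1, 100)); e2 = s2 + int(rng.integers(10, 80))
            hits = [_hit(s=s1, e=e1), _hit(s=s2, e=e2)]
            ov = min(e1, e2) - max(s1, s2) + 1
            shorter = min(e1 - s1 + 1, e2 - s2 + 1)
            expect = 1 if ov > 0.5 * shorter else 2
            assert len(resolve_architecture(hits)) == expect

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(ValueError):
            resolve_architecture([_hit(pid="A"), _hit(pid="B")])


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "arch,expect",
        [
            ([D.RRM], FamilyClass.IVA),
            ([D.RRM, D.ZNF_CCHC], FamilyClass.IVB),
            ([D.CSD, D.ZNF_CCHC, D.ZNF_CCHC], FamilyClass.IVC),
            ([D.RRM, D.RRM], FamilyClass.IVD),
            ([D.CSD, D.ZNF_CCHC], FamilyClass.IVC),
            ([D.CSD, D.ZNF_CCHC, D.ZNF_CCHC, D.ZNF_CCHC], FamilyClass.IVC),
            ([D.RRM, D.ZNF_RANBP2, D.ZNF_RANBP2], FamilyClass.IVB),
            ([], FamilyClass.UNCLASSIFIED),
            ([D.ZNF_CCHC], FamilyClass.UNCLASSIFIED),
        ],
    )
    def test_architecture_to_class(self, arch, expect):
        assert classify_family(arch) is expect

    def test_total_and_deterministic_on_random_architectures(self, rng):
        tokens = list(D)
        for _ in range(200):
            arch = [tokens[i] for i in rng.integers(len(tokens),
                                                    size=rng.integers(0, 5))]
            out = classify_family(arch)
            assert isinstance(out, FamilyClass)
            assert out is classify_family(arch)


# ---------------------------------------------------------------------------
# physicochemical properties


class TestProperties:
    def test_glycine_weight(self):
        assert compute_molecular_weight("G") * 1000 == pytest.approx(75.07, abs=0.01)
        assert compute_molecular_weight("GG") * 1000 == pytest.approx(132.12, abs=0.01)

    def test_weight_additive_up_to_one_water(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, size=int(rng.integers(1, 30))))
            b = "".join(rng.choice(aas, size=int(rng.integers(1, 30))))
            lhs = compute_molecular_weight(a + b) * 1000
            rhs = (compute_molecular_weight(a) + compute_molecular_weight(b)) * 1000
            assert lhs == pytest.approx(rhs - 18.0153, abs=1e-6)

    def test_unknown_residue_policy(self):
        with pytest.raises(ValueError):
            compute_molecular_weight("GXG")
        assert compute_molecular_weight("GXG", allow_x=True) > 0

    def test_pi_basic_vs_acidic(self):
        assert compute_isoelectric_point("KKKKK") > 7
        assert compute_isoelectric_point("DDDDD") < 7

    def test_charge_at_pi_is_zero(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            seq = "".join(rng.choice(aas, size=50))
            pi = compute_isoelectric_point(seq)
            assert abs(IsoelectricPoint(seq).charge_at_pH(pi)) < 1e-3

    def test_pi_matches_grid_scan(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            seq = "".join(rng.choice(aas, size=40))
            pi = compute_isoelectric_point(seq)
            ip = IsoelectricPoint(seq)
            # coarse bracket then 1e-4 grid: first sign change of the charge
            grid = np.arange(max(0.0, pi - 0.05), pi + 0.05, 1e-4)
            charges = np.array([ip.charge_at_pH(x) for x in grid])
            sign_change = np.nonzero(np.diff(np.sign(charges)))[0]
            assert len(sign_change) >= 1
            assert abs(grid[sign_change[0]] - pi) < 0.01


# ---------------------------------------------------------------------------
# domain segments


class TestDomainSegments:
    def _protein(self, n=300):
        return ProteinRecord("P1", "G1", "ACDEFGHIKLMNPQRSTVWY" * (n // 20))

    def test_single_domain_keeps_bare_name(self):
        p = self._protein()
        segs = extract_domain_segments(p, resolve_domains([_hit(s=5, e=80)]))
        assert segs == [("P1", p.sequence[4:80])]

    def test_two_domains_get_n_and_c_suffixes(self):
        p = self._protein()
        segs = extract_domain_segments(
            p, resolve_domains([_hit(s=5, e=80), _hit(s=120, e=190)])
        )
        assert [s[0] for s in segs] == ["P1 N", "P1 C"]

    def test_three_domains_match_manual_slices(self):
        p = self._protein()
        hits = [_hit(s=5, e=60), _hit(s=80, e=140), _hit(s=160, e=220)]
        segs = extract_domain_segments(p, resolve_domains(hits))
        assert [s[0] for s in segs] == ["P1 N", "P1 M", "P1 C"]
        assert [s[1] for s in segs] == [
            p.sequence[4:60], p.sequence[79:140], p.sequence[159:220]
        ]

    def test_envelope_beyond_sequence_raises(self):
        p = ProteinRecord("P1", "G1", "A" * 50)
        with pytest.raises(ValueError):
            extract_domain_segments(p, resolve_domains([_hit(s=10, e=80)]))


# ---------------------------------------------------------------------------
# composite identification


class TestIdentifyFamilyMembers:
    def test_empty_domain_table_gives_empty_roster(self):
        prots = [ProteinRecord("P1", "G1", "G" * 40)]
        assert identify_family_members(prots, []) == []

    def test_planted_members_recovered_decoys_rejected(self):
        cfg = ProteomeConfig(seed=11, class_mix={"IVa": 4, "IVb": 3, "IVc": 3,
                                                 "IVd": 2})
        sim = simulate_proteome(cfg)
        members = identify_family_members(sim.proteins, sim.hits)
        got = {m.protein.protein_id: m.assignment.family_class.value
               for m in members}
        want = {pid: t["class"] for pid, t in sim.truth["members"].items()}
        assert got == want

    def test_longest_isoform_per_gene_is_kept(self):
        gly = "G" * 14 + "AVLSTP"
        short = ProteinRecord("P1.2", "G1", "M" * 30 + gly)
        long = ProteinRecord("P1.1", "G1", "M" * 90 + gly)
        hits = [_hit(pid="P1.1", s=1, e=80), _hit(pid="P1.2", s=1, e=25)]
        members = identify_family_members([short, long], hits)
        assert [m.protein.protein_id for m in members] == ["P1.1"]

    def test_roster_table_columns(self, tmp_path):
        sim = simulate_proteome(ProteomeConfig(seed=2, class_mix={"IVa": 2}))
        members = identify_family_members(sim.proteins, sim.hits)
        df = roster_table(members)
        assert list(df["class"]) == ["IVa", "IVa"]
        assert (df["mw_kda"] > 0).all() and df["pi"].between(0, 14).all()

    def test_fasta_round_trip(self, tmp_path):
        sim = simulate_proteome(ProteomeConfig(seed=4))
        path = write_proteome_fasta(sim.proteins, tmp_path / "prot.fa")
        back = parse_proteome(path)
        assert [(p.protein_id, p.gene_id, p.sequence) for p in back] == [
            (p.protein_id, p.gene_id, p.sequence) for p in sim.proteins
        ]
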