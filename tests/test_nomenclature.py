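import pytest

from cypclass.io_formats import ProteinRecord
from cypclass.mcl_core import Clustering
from cypclass.nomenclature import (
    UNASSIGNED,
    ClanRecord,
    NamedReference,
    NomenclatureParams,
    assign_family,
    global_identity,
    infer_clans,
)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKTAYIAKQR", "MKTAYIAKQR") == 100.0

    def test_no_identical_columns(self):
        assert global_identity("AAAA", "CCCC") == 0.0

    def test_symmetric(self):
        a, b = "MKTAYIAKQRQISF", "MKTAWIAKQRQISF"
        assert global_identity(a, b) == global_identity(b, a)

    def test_forced_ungapped_alignment(self):
        # equal-length pair differing at 3 of 12 positions; a gap would cost
        # far more than the mismatches, so the alignment is the ungapped one
        # and identity is exactly 9/12
        a = "MKTAYIAKQRQI"
        b = "MKTWYIAKNRQV"
        assert global_identity(a, b) == pytest.approx(100 * 9 / 12)

    def test_single_deletion(self):
        # one residue deleted: alignment length 12, one gap column, 11 matches
        a = "MKTAYIAKQRQI"
        b = "MKTAYIKQRQI"
        assert global_identity(a, b) == pytest.approx(100 * 11 / 12)

    def test_gapless_denominator_mode(self):
        a = "MKTAYIAKQRQI"
        b = "MKTAYIKQRQI"
        assert global_identity(a, b, gaps_in_denominator=False) == pytest.approx(100.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "MKT")

    def test_identity_100_iff_identical(self):
        assert global_identity("MKTAYI", "MKTAYL") < 100.0


def ref(pid, seq, family, subfamily=None):
    return NamedReference(
        record=ProteinRecord(id=pid, sequence=seq), family=family, subfamily=subfamily
    )


AA_CYCLE = "ACDEFGHIKLMNPQRSTVWY"


def mutate_to_identity(seq, target_pct):
    """Substitute evenly spaced positions to hit an exact ungapped identity.

    Scattered single substitutions keep the optimal global alignment gap-free
    (one mismatch is far cheaper than two gap openings), so the realized
    identity is exactly the ungapped one.
    """
    n_diff = round(len(seq) * (1 - target_pct / 100))
    out = list(seq)
    for i in range(n_diff):
        pos = i * len(seq) // n_diff
        out[pos] = AA_CYCLE[(AA_CYCLE.index(out[pos]) + 1) % len(AA_CYCLE)]
    return "".join(out)


class TestAssignFamily:
    SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"

    def query(self, seq):
        return ProteinRecord(id="q", sequence=seq)

    def test_between_thresholds_family_only(self):
        refs = [ref("r1", self.SEQ, "CYP51", "CYP51A")]
        q = self.query(mutate_to_identity(self.SEQ, 45))
        a = assign_family(q, refs)
        assert a.family == "CYP51" and a.subfamily is None
        assert 40 < a.best_identity <= 55

    def test_above_subfamily_threshold(self):
        refs = [ref("r1", self.SEQ, "CYP51", "CYP51A")]
        q = self.query(mutate_to_identity(self.SEQ, 60))
        a = assign_family(q, refs)
        assert a.family == "CYP51" and a.subfamily == "CYP51A"

    def test_exactly_40_percent_unassigned(self):
        # 60-residue reference, query differing at exactly 36 positions: the
        # ungapped identity is exactly 40.0%, which fails the strict rule
        seq = self.SEQ[:60]
        q = self.query(mutate_to_identity(seq, 40))
        refs = [ref("r1", seq, "CYP51")]
        a = assign_family(q, refs)
        assert a.best_identity == pytest.approx(40.0)
        assert a.family == UNASSIGNED and a.subfamily is None

    def test_reference_order_invariant_with_id_tie_break(self):
        refs_fwd = [ref("r2", self.SEQ, "CYP52"), ref("r1", self.SEQ, "CYP51")]
        refs_rev = refs_fwd[::-1]
        q = self.query(self.SEQ)
        a, b = assign_family(q, refs_fwd), assign_family(q, refs_rev)
        assert a == b
        assert a.best_ref_id == "r1"  # lexicographically smallest on tie

    def test_runner_up_family_within_margin(self):
        near = mutate_to_identity(self.SEQ, 99)
        refs = [ref("r1", self.SEQ, "CYP51"), ref("r2", near, "CYP52")]
        a = assign_family(self.query(self.SEQ), refs)
        assert a.family == "CYP51"
        assert a.runner_up_family == "CYP52"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            assign_family(self.query(self.SEQ), [])


class TestInferClans:
    def make_clustering(self, groups):
        return Clustering(
            clusters=[frozenset(g) for g in groups],
            n_nodes=sum(len(g) for g in groups),
        )

    def test_two_known_clans_yield_merge_proposal(self):
        clustering = self.make_clustering([["p1", "p2", "p3"]])
        family_of = {"p1": "CYP531A", "p2": "CYP532A", "p3": "CYP531A"}
        known = {"CYP531A": "CYP531", "CYP532A": "CYP532"}
        (rec,) = infer_clans(clustering, family_of, known)
        assert rec.status == "merge_proposal"
        assert rec.merged_clans == frozenset({"CYP531", "CYP532"})

    def test_singlet_unmapped_family_is_orphan(self):
        clustering = self.make_clustering([["p1"]])
        (rec,) = infer_clans(clustering, {"p1": "CYP9999"}, {})
        assert rec.status == "orphan"
        assert rec.families == frozenset({"CYP9999"})
        assert rec.clan_name == "CYP9999"

    def test_single_known_clan_gains_clanless_families(self):
        clustering = self.make_clustering([["p1", "p2", "p3", "p4", "p5"]])
        family_of = {f"p{i}": f"FAM{i}" for i in range(1, 6)}
        known = {"FAM3": "CLANX"}
        (rec,) = infer_clans(clustering, family_of, known)
        assert rec.status == "known" and rec.clan_name == "CLANX"
        assert rec.families == frozenset({f"FAM{i}" for i in range(1, 6)})

    def test_novel_clan_for_unmapped_multifamily_cluster(self):
        clustering = self.make_clustering([["p1", "p2"]])
        family_of = {"p1": "FAMA", "p2": "FAMB"}
        records = infer_clans(clustering, family_of, {})
        (rec,) = records
        assert rec.status == "novel"
        assert rec.clan_name.startswith("CLAN_")

    def test_every_family_in_exactly_one_record(self):
        clustering = self.make_clustering([["p1", "p2"], ["p3"], ["p4", "p5"]])
        family_of = {"p1": "F1", "p2": "F2", "p3": "F3", "p4": "F4", "p5": "F4"}
        records = infer_clans(clustering, family_of, {"F1": "C1"})
        seen = [f for r in records for f in r.families]
        assert sorted(seen) == sorted(set(seen))
        assert set(seen) == {"F1", "F2", "F3", "F4"}

    def test_unassigned_proteins_ignored(self):
        clustering = self.make_clustering([["p1", "p2"]])
        family_of = {"p1": UNASSIGNED, "p2": UNASSIGNED}
        assert infer_clans(clustering, family_of, {}) == []


class TestRecordInvariants:
    def test_orphan_requires_single_family(self):
        with pytest.raises(ValueError):
            ClanRecord(
                clan_name="X", families=frozenset({"A", "B"}),
                status="orphan", source_cluster_id=0,
            )

    def test_merge_requires_two_clans(self):
        with pytest.raises(ValueError):
            ClanRecord(
                clan_name="X", families=frozenset({"A"}),
                status="merge_proposal", source_cluster_id=0,
                merged_clans=frozenset({"C1"}),
            )

    def test_params_ordering_enforced(self):
        with pytest.raises(ValueError):
            NomenclatureParams(family_identity_min=60, subfamily_identity_min=55)
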