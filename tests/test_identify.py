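import numpy as np
import pandas as pd
import pytest

import barcomm as bc
from barcomm.barcode_identify import (loo_identify, pairwise_identity,
                                      recovery_table, recovery_times_ci,
                                      IdentificationReport, QueryOutcome)


def _flag_frame(triples):
    return pd.DataFrame(triples, columns=["sample", "marker", "success"])


@pytest.fixture
def flat_taxonomy():
    """Ten species in ten separate genera/families/orders."""
    return bc.CommunityTaxonomy(pd.DataFrame(
        [(f"sp{i}", f"g{i}", f"f{i}", f"o{i}") for i in range(10)],
        columns=["species", "genus", "family", "order"]))


class TestRecoveryTable:
    def test_all_success_everywhere(self, flat_taxonomy):
        rows = [(f"s{i}", m, True) for i in range(10) for m in bc.seqio_taxonomy.MARKERS]
        rt = recovery_table(_flag_frame(rows), {f"s{i}": f"sp{i}" for i in range(10)},
                            flat_taxonomy)
        assert (rt.percentages == 100.0).all().all()

    def test_any_sample_rule_at_species_level(self, small_taxonomy):
        rows = [("a", "rbcLa", False), ("b", "rbcLa", True)]
        rt = recovery_table(_flag_frame(rows), {"a": "sp1", "b": "sp1"}, small_taxonomy)
        assert rt.counts.at["species", "rbcLa"] == 1
        assert rt.counts.at["sample", "rbcLa"] == 1

    def test_union_columns_apply_any_marker_per_sample(self, small_taxonomy):
        rows = [("a", "rbcLa", True), ("a", "matK", False),
                ("b", "rbcLa", False), ("b", "matK", True)]
        rt = recovery_table(_flag_frame(rows), {"a": "sp1", "b": "sp2"}, small_taxonomy)
        assert rt.counts.at["sample", "rbcLa+matK"] == 2
        assert rt.counts.at["sample", "all"] == 2
        assert rt.counts.at["sample", "trnH-psbA"] == 0

    def test_success_propagates_to_coarser_levels(self, small_taxonomy):
        rows = [("a", "matK", True)]
        rt = recovery_table(_flag_frame(rows), {"a": "sp4"}, small_taxonomy)
        for level in ("species", "genus", "family", "order"):
            assert rt.counts.at[level, "matK"] == 1

    def test_union_count_at_least_single_marker(self, small_taxonomy):
        rng = np.random.default_rng(0)
        samples = {f"smp{i}": f"sp{(i % 6) + 1}" for i in range(12)}
        rows = [(s, m, bool(rng.random() < 0.5))
                for s in samples for m in bc.seqio_taxonomy.MARKERS]
        rt = recovery_table(_flag_frame(rows), samples, small_taxonomy)
        for level in rt.counts.index:
            assert rt.counts.at[level, "all"] >= rt.counts.loc[level, ["rbcLa", "trnH-psbA", "matK"]].max()

    def test_unmapped_sample_rejected(self, small_taxonomy):
        with pytest.raises(ValueError, match="ghost"):
            recovery_table(_flag_frame([("ghost", "rbcLa", True)]), {}, small_taxonomy)


class TestLooIdentify:
    def _rec(self, sid, sp, seq):
        return bc.SequenceRecord(sid, sp, "rbcLa", seq)

    def test_duplicate_per_species_gives_perfect_ci(self, flat_taxonomy):
        rng = np.random.default_rng(1)
        base = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
        recs = []
        for i, seq in enumerate(base):
            recs.append(self._rec(f"a{i}", f"sp{i}", seq))
            recs.append(self._rec(f"b{i}", f"sp{i}", seq))
        rep = loo_identify(recs, flat_taxonomy, "species")
        assert rep.ci == 1.0

    def test_identical_congeners_wrong_species_right_genus(self):
        tax = bc.CommunityTaxonomy(pd.DataFrame(
            [("sp1", "g1", "f1", "o1"), ("sp2", "g1", "f1", "o1"),
             ("sp3", "g2", "f1", "o1")],
            columns=["species", "genus", "family", "order"]))
        seq = "ACGTACGTACGTACGTACGTACGT"
        recs = [self._rec("a", "sp1", seq), self._rec("b", "sp2", seq),
                self._rec("c", "sp3", "ACGTTTTTACGTACGAACGTACGA")]
        rep = loo_identify(recs, tax, "species")
        by_sample = {o.sample_id: o for o in rep.outcomes}
        assert not by_sample["a"].correct_at["species"]
        assert by_sample["a"].correct_at["genus"]
        assert not by_sample["b"].correct_at["species"]

    def test_constructed_confusion_matrix(self):
        """Ten duplicated species, one sister pair identical: species CI 80%.

        The two identical sister species produce ties spanning both
        species (wrong at species rank, right at genus); every other
        species has an exact conspecific duplicate as unique best hit.
        """
        rng = np.random.default_rng(3)
        rows, recs = [], []
        shared = "".join(rng.choice(list("ACGT"), size=80))
        for i in range(5):
            genus = f"g{i}"
            if i == 0:
                pair = [shared, shared]  # identical sister species
            else:
                a = "".join(rng.choice(list("ACGT"), size=80))
                b = list(a)
                for p in rng.choice(80, size=5, replace=False):
                    b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
                pair = [a, "".join(b)]
            for j, seq in enumerate(pair):
                sp = f"sp{i}{j}"
                rows.append((sp, genus, "f", "o"))
                recs.append(self._rec(f"{sp}q1", sp, seq))
                recs.append(self._rec(f"{sp}q2", sp, seq))
        tax = bc.CommunityTaxonomy(pd.DataFrame(
            rows, columns=["species", "genus", "family", "order"]))
        rep = loo_identify(recs, tax, "species")
        assert rep.ci == pytest.approx(0.8)
        assert rep.ci_at("genus") == pytest.approx(1.0)

    def test_ci_monotone_with_rank_coarsening(self, sim_community):
        truth, records = sim_community
        rep = loo_identify(records["rbcLa"], truth.taxonomy, "species")
        cis = [rep.ci_at(r) for r in ("species", "genus", "family", "order")]
        assert all(a <= b + 1e-12 for a, b in zip(cis, cis[1:]))

    def test_requires_two_sequences(self, flat_taxonomy):
        with pytest.raises(ValueError):
            loo_identify([self._rec("a", "sp1", "ACGT")], flat_taxonomy, "species")


class TestRecoveryTimesCI:
    def _stub_report(self, marker, n_correct, n_total):
        outcomes = [QueryOutcome(f"q{i}", "sp", [], 1.0,
                                 {r: i < n_correct for r in
                                  ("species", "genus", "family", "order")})
                    for i in range(n_total)]
        return IdentificationReport(marker, "species", n_correct / n_total, outcomes)

    def test_product_rounds_half_up(self, flat_taxonomy):
        rows = [(f"s{i}", "matK", i < 7) for i in range(10)]
        rt = recovery_table(_flag_frame(rows), {f"s{i}": f"sp{i}" for i in range(10)},
                            flat_taxonomy)
        rep = self._stub_report("matK", 10, 10)
        out = recovery_times_ci(rt, {("matK", "species"): rep})
        assert out.at["species", "matK"] == 70

    def test_zero_ci_gives_zero(self, flat_taxonomy):
        rows = [(f"s{i}", "rbcLa", True) for i in range(10)]
        rt = recovery_table(_flag_frame(rows), {f"s{i}": f"sp{i}" for i in range(10)},
                            flat_taxonomy)
        rep = self._stub_report("rbcLa", 0, 10)
        assert recovery_times_ci(rt, {("rbcLa", "species"): rep}).at["species", "rbcLa"] == 0

    def test_half_product(self, flat_taxonomy):
        rows = [(f"s{i}", "rbcLa", i < 5) for i in range(10)]
        rt = recovery_table(_flag_frame(rows), {f"s{i}": f"sp{i}" for i in range(10)},
                            flat_taxonomy)
        rep = self._stub_report("rbcLa", 5, 10)
        assert recovery_times_ci(rt, {("rbcLa", "species"): rep}).at["species", "rbcLa"] == 25

    def test_missing_key_rejected(self, flat_taxonomy):
        rows = [(f"s{i}", "rbcLa", True) for i in range(10)]
        rt = recovery_table(_flag_frame(rows), {f"s{i}": f"sp{i}" for i in range(10)},
                            flat_taxonomy)
        with pytest.raises(KeyError):
            recovery_times_ci(rt, {("ITS2", "species"): self._stub_report("ITS2", 1, 1)})


def test_pairwise_identity_basics():
    assert pairwise_identity("ACGT", "ACGT") == 1.0
    assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC"[:5]) == 1.0  # prefix, free end gaps
    assert pairwise_identity("AAAA", "TTTT") < 0.5
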