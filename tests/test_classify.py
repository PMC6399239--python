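"""Category taxonomy: per-sequence predicates and data-set aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sftest import (
    EvidenceRecord,
    Thresholds,
    UnclassifiableError,
    classify_dataset,
    classify_permissive,
    lrt_tally,
    sequence_meets,
)
from sftest.comparisons import ComparisonResult
from sftest.gof import GofResult
from sftest.powerlaw import PowerLawResults

FAMS = ("exponential", "lognormal", "weibull", "powerlaw_cutoff")


def make_record(p=0.2, n_tail=60, alpha=2.5, favored=(), provenance="seq"):
    """Synthetic evidence record with the given test outcomes."""
    fit = PowerLawResults(k_min=2, alpha=alpha, n_tail=n_tail, ks=0.05,
                          log_likelihood=-100.0, n=max(n_tail, 100),
                          degrees=np.arange(2, 2 + max(n_tail, 5)))
    gof = GofResult(p_value=p, n_boot=100, observed_ks=0.05, plausible=p >= 0.1)
    comps = tuple(
        ComparisonResult(
            fam,
            -1.0 if fam in favored else 0.5,
            0.01 if fam in favored else 0.5,
            "favors_alternative" if fam in favored else "inconclusive",
            fam == "powerlaw_cutoff",
        )
        for fam in FAMS
    )
    return EvidenceRecord(provenance, fit=fit, gof=gof, comparisons=comps)


record_strategy = st.builds(
    make_record,
    p=st.sampled_from([0.0, 0.05, 0.09, 0.1, 0.3, 0.9]),
    n_tail=st.sampled_from([5, 49, 50, 80, 500]),
    alpha=st.sampled_from([1.5, 2.0, 2.1, 2.9, 3.0, 4.5]),
    favored=st.sets(st.sampled_from(FAMS)).map(tuple),
)


class TestSequenceMeets:
    def test_fully_satisfying_record(self):
        r = make_record(p=0.2, n_tail=60, alpha=2.5, favored=())
        assert all(sequence_meets(r, c) for c in
                   ("superweak", "weakest", "weak", "strong"))

    def test_gof_rejection_blocks_weakest(self):
        r = make_record(p=0.05, n_tail=500, alpha=2.5)
        assert not sequence_meets(r, "weakest")
        assert not sequence_meets(r, "weak")
        assert not sequence_meets(r, "strong")

    def test_alpha_boundaries_strict(self):
        for alpha in (2.0, 3.0):
            assert not sequence_meets(make_record(alpha=alpha), "strong")
        assert sequence_meets(make_record(alpha=2.0001), "strong")

    def test_gof_threshold_inclusive(self):
        assert sequence_meets(make_record(p=0.1), "weakest")

    def test_n_tail_threshold(self):
        assert sequence_meets(make_record(n_tail=50), "weak")
        assert not sequence_meets(make_record(n_tail=49), "weak")

    def test_any_favored_alternative_blocks_superweak(self):
        r = make_record(favored=("lognormal",))
        assert not sequence_meets(r, "superweak")
        assert not sequence_meets(r, "strong")
        assert sequence_meets(r, "weak")

    def test_untestable_record_rejected(self):
        r = EvidenceRecord("x", untestable=True, reason="too_sparse")
        with pytest.raises(ValueError):
            sequence_meets(r, "weakest")


class TestClassifyDataset:
    def test_single_perfect_graph_hits_all_categories(self):
        out = classify_dataset([make_record()])
        assert out.categories == frozenset(
            {"SuperWeak", "Weakest", "Weak", "Strong", "Strongest"})

    def test_half_satisfying_reaches_strong_not_strongest(self):
        good = make_record()
        bad = make_record(p=0.01, n_tail=10, alpha=5.0, favored=FAMS)
        out = classify_dataset([good, bad])
        assert {"SuperWeak", "Weakest", "Weak", "Strong"} <= out.categories
        assert "Strongest" not in out.categories

    def test_failing_everything_is_not_scale_free(self):
        out = classify_dataset([make_record(p=0.03, favored=("lognormal",))])
        assert out.categories == frozenset({"NotScaleFree"})
        assert out.label == "NotScaleFree"

    def test_all_untestable_is_an_error(self):
        records = [EvidenceRecord("x", untestable=True, reason="too_dense")]
        with pytest.raises(UnclassifiableError):
            classify_dataset(records)

    def test_untestable_records_excluded_from_denominator(self):
        records = [make_record(),
                   EvidenceRecord("x", untestable=True, reason="too_sparse")]
        out = classify_dataset(records)
        assert out.fractions["strong"] == 1.0
        assert out.n_testable == 1 and out.n_untestable == 1

    @given(st.lists(record_strategy, min_size=1, max_size=8))
    def test_nesting_invariants(self, records):
        out = classify_dataset(records)
        c = out.categories
        if "Strongest" in c:
            assert "Strong" in c
        if "Strong" in c:
            assert "Weak" in c and "SuperWeak" in c
        if "Weak" in c:
            assert "Weakest" in c
        assert ("NotScaleFree" in c) == (
            "SuperWeak" not in c and "Weakest" not in c)

    @given(st.lists(record_strategy, min_size=1, max_size=8),
           st.integers(0, 2**31 - 1))
    def test_order_invariance(self, records, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert classify_dataset(records).categories == \
            classify_dataset(shuffled).categories


class TestClassifyPermissive:
    def test_one_scale_free_sequence_suffices_for_strongest(self):
        # e.g. a directed network whose in-degree view alone is scale-free
        records = [
            make_record(provenance="in-degree view"),
            make_record(p=0.01, alpha=5.0, favored=FAMS,
                        provenance="out-degree view"),
            make_record(p=0.02, alpha=4.0, favored=("exponential",),
                        provenance="undirected collapse"),
        ]
        out = classify_permissive(records)
        assert "Strongest" in out.categories
        assert "Strong" in out.categories
        # under the default thresholds the same records are weaker
        strict = classify_dataset(records)
        assert "Strongest" not in strict.categories

    def test_vacuous_case_not_scale_free(self):
        records = [make_record(p=0.01, favored=("weibull",))]
        out = classify_permissive(records)
        assert out.categories == frozenset({"NotScaleFree"})

    @given(st.lists(record_strategy, min_size=1, max_size=8))
    def test_permissive_is_superset_of_default(self, records):
        strict = classify_dataset(records).categories - {"NotScaleFree"}
        loose = classify_permissive(records).categories - {"NotScaleFree"}
        assert strict <= loose

    @given(st.lists(record_strategy, min_size=1, max_size=8))
    def test_permissive_strong_equals_strongest(self, records):
        c = classify_permissive(records).categories
        assert ("Strong" in c) == ("Strongest" in c)


class TestLrtTally:
    def test_single_inconclusive_record(self):
        t = lrt_tally([make_record()])
        assert t["lognormal"] == {"favors_powerlaw": 0.0, "inconclusive": 1.0,
                                  "favors_alternative": 0.0}

    def test_mixed_outcomes_arithmetic(self):
        recs = [make_record() for _ in range(4)]
        # override lognormal outcomes: 2 PL, 1 inconclusive, 1 Alt
        def with_ln(verdict, r):
            comps = tuple(
                ComparisonResult(c.family, 1.0 if verdict == "favors_powerlaw"
                                 else -1.0, 0.01 if verdict != "inconclusive"
                                 else 0.9, verdict, c.nested)
                if c.family == "lognormal" else c
                for c in r.comparisons
            )
            return EvidenceRecord(r.provenance, fit=r.fit, gof=r.gof,
                                  comparisons=comps)
        recs = [with_ln("favors_powerlaw", recs[0]),
                with_ln("favors_powerlaw", recs[1]),
                with_ln("inconclusive", recs[2]),
                with_ln("favors_alternative", recs[3])]
        t = lrt_tally(recs)
        assert t["lognormal"] == {"favors_powerlaw": 0.5, "inconclusive": 0.25,
                                  "favors_alternative": 0.25}

    @given(st.lists(record_strategy, min_size=1, max_size=6))
    def test_rows_sum_to_one(self, records):
        for row in lrt_tally(records).values():
            assert sum(row.values()) == pytest.approx(1.0)
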