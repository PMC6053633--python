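"""Modified hazard quotient and ecological contamination index."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedqual import (
    GuidelineEntry,
    MhqResult,
    ValidationError,
    classify_eci,
    classify_mhq,
    compute_eci,
    compute_mhq,
    rank_metals_by_mhq,
)
from sedqual.new_indices import ECI_EDGES, ECI_LABELS, MHQ_EDGES, MHQ_LABELS

CD = GuidelineEntry(tel=0.68, pel=4.21, sel=10)
PB = GuidelineEntry(tel=35, pel=91.3, sel=250)


def brute_mhq(c, tel, pel, sel):
    return math.sqrt(c * (1 / tel + 1 / pel + 1 / sel))


class TestMhq:
    @pytest.mark.parametrize(
        "c, entry, expected",
        [
            (4.8, CD, 2.946),    # cadmium-like concentration against Cd guidelines
            (178, PB, 2.783),    # lead-like concentration against Pb guidelines
            (0.0, CD, 0.0),
        ],
    )
    def test_matches_direct_evaluation(self, c, entry, expected):
        value = compute_mhq(c, entry)
        assert value == pytest.approx(brute_mhq(c, entry.tel, entry.pel, entry.sel), rel=1e-12)
        assert round(value, 3) == pytest.approx(expected, abs=5e-4)

    def test_reciprocal_sum_concentration_gives_unity(self):
        c = 1.0 / (1 / CD.tel + 1 / CD.pel + 1 / CD.sel)
        assert compute_mhq(c, CD) == pytest.approx(1.0, rel=1e-12)

    def test_missing_sel_uses_remaining_terms(self):
        partial = GuidelineEntry(tel=0.68, pel=4.21, sel=None)
        assert compute_mhq(4.8, partial) == pytest.approx(
            math.sqrt(4.8 * (1 / 0.68 + 1 / 4.21)), rel=1e-12
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            compute_mhq(-0.1, CD)

    @given(c=st.floats(1e-6, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_square_root_scaling_law(self, c):
        # quadrupling the concentration doubles the index
        assert compute_mhq(4 * c, CD) == pytest.approx(2 * compute_mhq(c, CD), rel=1e-9)

    @given(c1=st.floats(0, 1e5), c2=st.floats(0, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_concentration(self, c1, c2):
        lo, hi = sorted([c1, c2])
        assert compute_mhq(lo, CD) <= compute_mhq(hi, CD)


class TestClassification:
    @pytest.mark.parametrize(
        "value, label",
        [(3.6, "Extreme severity of contamination"),
         (0.3, "Nil to very low severity of contamination"),
         (2.5, "High severity of contamination")],
    )
    def test_mhq_examples(self, value, label):
        assert classify_mhq(value) == label

    @pytest.mark.parametrize("edge, upper_idx", [(e, i + 1) for i, e in enumerate(MHQ_EDGES)])
    def test_mhq_boundaries_belong_to_upper_class(self, edge, upper_idx):
        assert classify_mhq(edge) == MHQ_LABELS[upper_idx]
        assert classify_mhq(edge - 1e-9) == MHQ_LABELS[upper_idx - 1]

    @pytest.mark.parametrize(
        "value, label",
        [(5.06, "Considerably to highly contaminated"),
         (1.5, "Uncontaminated"),
         (3.46, "Slightly to moderately contaminated")],
    )
    def test_eci_examples(self, value, label):
        assert classify_eci(value) == label

    @pytest.mark.parametrize("edge, upper_idx", [(e, i + 1) for i, e in enumerate(ECI_EDGES)])
    def test_eci_boundaries_belong_to_upper_class(self, edge, upper_idx):
        assert classify_eci(edge) == ECI_LABELS[upper_idx]
        assert classify_eci(edge - 1e-9) == ECI_LABELS[upper_idx - 1]

    @given(x=st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_every_nonnegative_value_gets_exactly_one_label(self, x):
        assert classify_mhq(x) in MHQ_LABELS
        assert classify_eci(x) in ECI_LABELS

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            classify_mhq(-0.1)
        with pytest.raises(ValidationError):
            classify_eci(-0.1)


def _mhqs(site, values):
    metals = ["Cd", "Pb", "Cu", "Cr", "Ni"]
    return [
        MhqResult(site=site, metal=m, mhq=v, severity_class=classify_mhq(v))
        for m, v in zip(metals, values)
    ]


class TestEci:
    def test_site_aggregate_matches_direct_evaluation(self):
        mhqs = _mhqs("DOU", [2.946, 2.783, 1.270, 0.955, 0.461])
        result = compute_eci(mhqs, bn=1 / 1.705)
        assert result.eci == pytest.approx(sum(r.mhq for r in mhqs) / 1.705, rel=1e-12)
        assert result.eci == pytest.approx(4.936, abs=2e-3)
        assert result.contamination_class == "Moderately to considerably contaminated"

    def test_single_term(self):
        (r,) = _mhqs("A", [2.0])[:1]
        assert compute_eci([r], bn=0.5).eci == pytest.approx(1.0)

    def test_contributions_sum_to_100_and_reconstruct_eci(self):
        mhqs = _mhqs("A", [2.9, 1.3, 0.7, 0.2, 0.05])
        result = compute_eci(mhqs, bn=0.44)
        assert sum(result.contributions.values()) == pytest.approx(100.0, rel=1e-9)
        total = sum(r.mhq for r in mhqs)
        rebuilt = sum(pct / 100 * total for pct in result.contributions.values()) * result.bn
        assert rebuilt == pytest.approx(result.eci, rel=1e-12)

    def test_all_zero_mhqs_reported_uniform_with_warning(self):
        mhqs = _mhqs("A", [0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="uniform"):
            result = compute_eci(mhqs, bn=1.0)
        assert result.eci == 0
        assert all(v == pytest.approx(20.0) for v in result.contributions.values())

    def test_monotone_in_any_single_mhq(self):
        base = _mhqs("A", [2.0, 1.0, 0.5, 0.4, 0.3])
        bumped = _mhqs("A", [2.5, 1.0, 0.5, 0.4, 0.3])
        assert compute_eci(bumped, 0.5).eci > compute_eci(base, 0.5).eci

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            compute_eci([], bn=1.0)

    def test_nonpositive_bn_rejected(self):
        with pytest.raises(ValidationError):
            compute_eci(_mhqs("A", [1.0]), bn=0.0)

    def test_mixed_sites_rejected(self):
        mhqs = _mhqs("A", [1.0]) + _mhqs("B", [1.0])
        with pytest.raises(ValidationError, match="multiple sites"):
            compute_eci(mhqs, bn=1.0)


class TestRanking:
    def test_descending_order(self):
        ranking = rank_metals_by_mhq(_mhqs("A", [2.9, 2.7, 1.6, 0.8, 0.4]))
        assert ranking.order == ("Cd", "Pb", "Cu", "Cr", "Ni")
        assert not ranking.tied

    def test_ties_broken_alphabetically_and_flagged(self):
        ranking = rank_metals_by_mhq(_mhqs("A", [1.0, 1.0]))
        assert ranking.order == ("Cd", "Pb")
        assert ranking.ties == (("Cd", "Pb"),)

    def test_singleton(self):
        ranking = rank_metals_by_mhq(_mhqs("A", [1.0])[:1])
        assert ranking.order == ("Cd",)
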