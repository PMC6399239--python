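"""Evidence aggregation and the scale-free category taxonomy.

A network data set yields one :class:`EvidenceRecord` per degree sequence
that survived simplification and the density filter.  Categories are
assigned at data-set level from the fractions of testable sequences meeting
each per-sequence requirement:

* Super-Weak — no alternative favored over the power law (>= 50% of graphs)
* Weakest — power law not rejected by the GoF test, p >= 0.1 (>= 50%)
* Weak — Weakest and a power-law region of at least 50 nodes (>= 50%)
* Strong — Weak and Super-Weak hold, and 2 < alpha < 3 (>= 50%)
* Strongest — Strong requirements for >= 90% and Super-Weak for >= 95%
* Not Scale Free — neither Super-Weak nor Weakest

The permissive variant grants each category if a single sequence meets its
requirements; Strong and Strongest then coincide by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .comparisons import ComparisonResult
from .gof import GofResult
from .powerlaw import PowerLawResults

__all__ = [
    "CRITERIA",
    "Thresholds",
    "EvidenceRecord",
    "CategoryAssignment",
    "UnclassifiableError",
    "sequence_meets",
    "classify_dataset",
    "classify_permissive",
    "lrt_tally",
]

CRITERIA = ("superweak", "weakest", "weak", "strong")


class UnclassifiableError(ValueError):
    """Every record in the data set is untestable."""


@dataclass(frozen=True)
class Thresholds:
    """Category fraction thresholds (defaults: the primary evaluation)."""

    superweak: float = 0.50
    weakest: float = 0.50
    weak: float = 0.50
    strong: float = 0.50
    strongest_strong: float = 0.90
    strongest_superweak: float = 0.95
    n_tail_min: int = 50
    alpha_range: tuple = (2.0, 3.0)
    gof_p: float = 0.1


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-sequence test outcomes (or a marker that the sequence was untestable)."""

    provenance: str
    fit: PowerLawResults | None = None
    gof: GofResult | None = None
    comparisons: tuple = ()
    untestable: bool = False
    reason: str = ""

    def __post_init__(self):
        if self.untestable:
            assert self.fit is None and self.gof is None
        else:
            assert self.fit is not None and self.gof is not None


def sequence_meets(record: EvidenceRecord, criterion: str,
                   thresholds: Thresholds = Thresholds()) -> bool:
    """Pure per-sequence predicate for one evidence criterion."""
    if record.untestable:
        raise ValueError("untestable record has no evidence")
    t = thresholds
    if criterion == "superweak":
        return not any(c.verdict == "favors_alternative" for c in record.comparisons)
    if criterion == "weakest":
        return record.gof.p_value >= t.gof_p
    if criterion == "weak":
        return (
            sequence_meets(record, "weakest", t)
            and record.fit.n_tail >= t.n_tail_min
        )
    if criterion == "strong":
        lo, hi = t.alpha_range
        return (
            sequence_meets(record, "weak", t)
            and sequence_meets(record, "superweak", t)
            and lo < record.fit.alpha < hi
        )
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass(frozen=True)
class CategoryAssignment:
    categories: frozenset
    fractions: dict = field(compare=False)
    lrt_tally: dict = field(compare=False)
    n_testable: int = 0
    n_untestable: int = 0
    permissive: bool = False

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    @property
    def label(self) -> str:
        """The strongest category attained (for display)."""
        for c in ("Strongest", "Strong", "Weak", "Weakest", "SuperWeak"):
            if c in self.categories:
                return c
        return "NotScaleFree"


def _testable(records) -> list:
    return [r for r in records if not r.untestable]


def _fractions(records, thresholds: Thresholds) -> dict:
    ok = _testable(records)
    if not ok:
        raise UnclassifiableError("all records untestable")
    return {
        c: sum(sequence_meets(r, c, thresholds) for r in ok) / len(ok)
        for c in CRITERIA
    }


def _assemble(records, fractions, categories, thresholds, permissive):
    ok = _testable(records)
    if not ("SuperWeak" in categories or "Weakest" in categories):
        categories.add("NotScaleFree")
    return CategoryAssignment(
        frozenset(categories),
        fractions,
        lrt_tally(records),
        n_testable=len(ok),
        n_untestable=len(records) - len(ok),
        permissive=permissive,
    )


def classify_dataset(records, thresholds: Thresholds = Thresholds()) -> CategoryAssignment:
    """Assign evidence categories from the fractions of testable sequences."""
    t = thresholds
    frac = _fractions(records, t)
    cats = set()
    if frac["superweak"] >= t.superweak:
        cats.add("SuperWeak")
    if frac["weakest"] >= t.weakest:
        cats.add("Weakest")
        if frac["weak"] >= t.weak:
            cats.add("Weak")
            if "SuperWeak" in cats and frac["strong"] >= t.strong:
                cats.add("Strong")
                if (
                    frac["strong"] >= t.strongest_strong
                    and frac["superweak"] >= t.strongest_superweak
                ):
                    cats.add("Strongest")
    return _assemble(records, frac, cats, t, permissive=False)


def classify_permissive(records, thresholds: Thresholds = Thresholds()) -> CategoryAssignment:
    """Grant each category if at least one sequence meets its requirements.

    Strong and Strongest coincide under this parameterization.
    """
    t = thresholds
    frac = _fractions(records, t)
    ok = _testable(records)
    any_of = {c: any(sequence_meets(r, c, t) for r in ok) for c in CRITERIA}
    cats = set()
    if any_of["superweak"]:
        cats.add("SuperWeak")
    if any_of["weakest"]:
        cats.add("Weakest")
        if any_of["weak"]:
            cats.add("Weak")
            if any_of["strong"]:
                cats.update({"Strong", "Strongest"})
    return _assemble(records, frac, cats, t, permissive=True)


def lrt_tally(records) -> dict:
    """Per-family fractions of (favors_powerlaw, inconclusive, favors_alternative).

    Normalized over testable records; each row sums to one, mirroring the
    three-way outcome columns used to summarize likelihood-ratio tests.
    """
    ok = _testable(records)
    tally: dict = {}
    if not ok:
        return tally
    for r in ok:
        for c in r.comparisons:
            row = tally.setdefault(
                c.family,
                {"favors_powerlaw": 0.0, "inconclusive": 0.0, "favors_alternative": 0.0},
            )
            row[c.verdict] += 1.0
    for family, row in tally.items():
        total = sum(row.values())
        for key in row:
            row[key] /= total
    return tally
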