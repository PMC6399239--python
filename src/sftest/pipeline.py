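"""End-to-end evaluation: simplify -> fit -> GoF -> compare -> classify.

:func:`evaluate` runs the full pipeline on one network data set and returns
the per-sequence evidence records, the data-set-level category assignment,
and the per-sequence moment reports, together with a filter accounting of
the simplified graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .alternatives import FitFailure, fit_alternative
from .classify import (
    CategoryAssignment,
    EvidenceRecord,
    Thresholds,
    classify_dataset,
    classify_permissive,
)
from .comparisons import compare_all
from .distributions import FAMILIES
from .gof import gof_pvalue
from .moments import MomentReport, moment_ratio
from .powerlaw import PowerLaw, UnfittableSequenceError, DegenerateTailError
from .simplify import (
    DegreeSequence,
    NetworkDataset,
    degree_sequence,
    density_filter,
    simplify_dataset,
)

__all__ = ["RunConfig", "EvaluationReport", "evaluate", "evaluate_sequences"]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one evaluation run (defaults: the primary scheme)."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    n_boot: int = 1000
    seed: int | None = None
    method: str = "lrt"  # lrt | ic
    include_cutoff: bool = True
    aggregation: str = "default"  # default | permissive

    def __post_init__(self):
        if self.method not in ("lrt", "ic"):
            raise ValueError("method must be 'lrt' or 'ic'")
        if self.aggregation not in ("default", "permissive"):
            raise ValueError("aggregation must be 'default' or 'permissive'")

    @property
    def families(self) -> tuple:
        if self.include_cutoff:
            return FAMILIES
        return tuple(f for f in FAMILIES if f != "powerlaw_cutoff")


@dataclass(frozen=True)
class EvaluationReport:
    identifier: str
    records: tuple
    assignment: CategoryAssignment
    moments: tuple
    filter_counts: dict
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        recs = []
        for r in self.records:
            d = {"provenance": r.provenance, "untestable": r.untestable,
                 "reason": r.reason}
            if not r.untestable:
                d["fit"] = {
                    "k_min": r.fit.k_min, "alpha": r.fit.alpha,
                    "n_tail": r.fit.n_tail, "ks": r.fit.ks,
                    "log_likelihood": r.fit.log_likelihood,
                }
                d["gof"] = {
                    "p_value": r.gof.p_value, "n_boot": r.gof.n_boot,
                    "plausible": r.gof.plausible,
                }
                d["comparisons"] = [
                    {"family": c.family, "R": c.R, "p_value": c.p_value,
                     "verdict": c.verdict, "nested": c.nested}
                    for c in r.comparisons
                ]
            recs.append(d)
        return {
            "schema_version": self.schema_version,
            "identifier": self.identifier,
            "categories": sorted(self.assignment.categories),
            "label": self.assignment.label,
            "fractions": self.assignment.fractions,
            "lrt_tally": self.assignment.lrt_tally,
            "filter_counts": self.filter_counts,
            "records": recs,
            "moments": [asdict(m) for m in self.moments],
        }


def _evidence_for_sequence(
    seq: DegreeSequence, config: RunConfig, seed,
) -> tuple[EvidenceRecord, MomentReport | None]:
    try:
        fit = PowerLaw(seq.degrees).fit()
    except (UnfittableSequenceError, DegenerateTailError) as err:
        return (
            EvidenceRecord(seq.provenance, untestable=True, reason=str(err)),
            None,
        )
    gof = gof_pvalue(seq.degrees, fit, n_boot=config.n_boot, seed=seed)
    alts = []
    for fam in config.families:
        try:
            alts.append(fit_alternative(seq.degrees, fit.k_min, fam))
        except (FitFailure, ValueError):
            continue
    comps = tuple(compare_all(fit.tail, fit, alts, method=config.method))
    record = EvidenceRecord(seq.provenance, fit=fit, gof=gof, comparisons=comps)
    return record, moment_ratio(seq)


def evaluate_sequences(
    identifier: str, sequences, config: RunConfig = RunConfig()
) -> EvaluationReport:
    """Evaluate pre-extracted degree sequences as one data set."""
    sequences = list(sequences)
    ss = np.random.SeedSequence(config.seed)
    counts = {"retain": 0, "too_sparse": 0, "too_dense": 0}
    records, moments = [], []
    seeds = ss.spawn(max(len(sequences), 1))
    for seq, child in zip(sequences, seeds):
        outcome = density_filter(seq)
        counts[outcome] += 1
        if outcome != "retain":
            records.append(EvidenceRecord(
                seq.provenance, untestable=True, reason=outcome))
            continue
        record, report = _evidence_for_sequence(seq, config, child)
        records.append(record)
        if report is not None:
            moments.append(report)
    classifier = (
        classify_permissive if config.aggregation == "permissive" else classify_dataset
    )
    assignment = classifier(records, config.thresholds)
    return EvaluationReport(identifier, tuple(records), assignment,
                            tuple(moments), counts)


def evaluate(dataset: NetworkDataset, config: RunConfig = RunConfig()) -> EvaluationReport:
    """Full pipeline on a network data set.

    Deterministic given ``(dataset, config.seed)``.  Raises
    :class:`sftest.classify.UnclassifiableError` when every simplified graph
    is filtered out or unfittable.
    """
    graphs = simplify_dataset(dataset)
    sequences = [degree_sequence(g) for g in graphs]
    return evaluate_sequences(dataset.identifier, sequences, config)
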