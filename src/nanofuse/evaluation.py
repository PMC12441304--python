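"""Clinical-concordance scoring: confusion matrices, sensitivity, specificity.

Samples carry a clinically confirmed truth (one or more fusions, or
negative) and the pipeline's call.  Matching is unordered and name-based:
``A::B`` equals ``B::A``.  A sample with several truth fusions scores TP
only when every truth fusion is called; partial detections are tallied
separately.  Group C (regulatory-element fusions / unknown partners) is
reported descriptively and excluded from sensitivity/specificity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "SampleRecord",
    "ConfusionMatrix",
    "NEGATIVE",
    "parse_fusions",
    "score_sample",
    "sensitivity",
    "specificity",
    "evaluate_cohort",
    "read_truth_table",
    "blind_test_fixture_path",
]

NEGATIVE = "-"
_METRIC_GROUPS = ("A", "B")


def parse_fusions(cell: str) -> set[frozenset[str]]:
    """Parse a fusion cell ('A::B', 'A::B;C::D', or '-') into unordered pairs."""
    cell = cell.strip()
    if not cell or cell in (NEGATIVE, "—", "NA"):
        return set()
    pairs: set[frozenset[str]] = set()
    for token in cell.replace(",", ";").split(";"):
        token = token.strip()
        if not token:
            continue
        genes = [g.strip() for g in token.split("::")]
        if len(genes) != 2 or not all(genes):
            raise ValueError(f"malformed fusion {token!r}")
        pairs.add(frozenset(genes))
    return pairs


@dataclass
class SampleRecord:
    sample_id: str
    group: str
    truth_fusion: str  # raw cell, '-' for negative
    called_fusion: str
    rin_class: str = "unknown"  # '>3', '<=3', or 'unknown'

    @property
    def truth_pairs(self) -> set[frozenset[str]]:
        return parse_fusions(self.truth_fusion)

    @property
    def called_pairs(self) -> set[frozenset[str]]:
        return parse_fusions(self.called_fusion)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def add(self, outcome: str) -> None:
        setattr(self, outcome.lower(), getattr(self, outcome.lower()) + 1)

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def score_sample(record: SampleRecord) -> str:
    """Score one sample as TP/FN/TN/FP (strict all-truth-fusions-called rule)."""
    if not record.sample_id or not record.group:
        raise ValueError("incomplete sample record")
    truth, called = record.truth_pairs, record.called_pairs
    if truth:
        return "TP" if truth <= called else "FN"
    return "FP" if called else "TN"


def sensitivity(cm: ConfusionMatrix) -> float | None:
    """100 * TP / (TP + FN); ``None`` with no positives."""
    if cm.positives == 0:
        return None
    return 100.0 * cm.tp / cm.positives


def specificity(cm: ConfusionMatrix) -> float | None:
    """100 * TN / (TN + FP); ``None`` with no negatives."""
    if cm.negatives == 0:
        return None
    return 100.0 * cm.tn / cm.negatives


def evaluate_cohort(records: Iterable[SampleRecord], by_group: bool = True) -> dict:
    """Confusion matrices and metrics per group and overall.

    Groups outside A/B (descriptive groups) are excluded from the overall
    matrix; for them only detected/partial counts are reported.
    """
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate sample_id {rec.sample_id}")
        seen.add(rec.sample_id)

    report: dict = {"groups": {}, "overall": None, "descriptive": {}}
    overall = ConfusionMatrix()
    groups = sorted({r.group for r in records}) if by_group else []
    for group in groups:
        members = [r for r in records if r.group == group]
        if group in _METRIC_GROUPS:
            cm = ConfusionMatrix()
            partial = 0
            for rec in members:
                outcome = score_sample(rec)
                cm.add(outcome)
                overall.add(outcome)
                if outcome == "FN" and rec.called_pairs & rec.truth_pairs:
                    partial += 1
            report["groups"][group] = {
                "confusion": cm.to_dict(),
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
                "partial_detections": partial,
                "n": len(members),
            }
        else:
            detected = sum(
                1 for r in members if r.truth_pairs and r.truth_pairs <= r.called_pairs
            )
            any_call = sum(1 for r in members if r.called_pairs)
            report["descriptive"][group] = {
                "n": len(members),
                "fully_detected": detected,
                "samples_with_any_call": any_call,
            }
    if records:
        report["overall"] = {
            "confusion": overall.to_dict(),
            "sensitivity": sensitivity(overall),
            "specificity": specificity(overall),
        }
    return report


def read_truth_table(source: str | Path | TextIO) -> list[SampleRecord]:
    """Read a TSV with columns sample_id, group, truth_fusion, called_fusion
    and optionally rin_class."""
    close = False
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        records = []
        for row in reader:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    truth_fusion=row["truth_fusion"],
                    called_fusion=row["called_fusion"],
                    rin_class=row.get("rin_class", "unknown"),
                )
            )
        return records
    finally:
        if close:
            handle.close()


def blind_test_fixture_path() -> Path:
    """Path to the packaged 39-sample blind-test truth/call table."""
    return Path(str(resources.files("nanofuse").joinpath("data/table2.tsv")))


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(report, out, indent=2)
        out.write("\n")
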