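"""Benchmarking of pipeline detections against a simulation truth set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from ._util import reciprocal_overlap
from .pipeline import StrainResult
from .synthetic import TruthSet

__all__ = ["ElementEval", "NgaroEval", "evaluate_elements",
           "evaluate_ngaros", "typing_ari"]

MATCH_OVERLAP = 0.8   # reciprocal overlap required to pair a call with truth


@dataclass
class ElementEval:
    recall: float
    precision: float
    boundary_errors: list[int]          # per matched end, bp
    tsd_expected: int
    tsd_exact: int
    matches: dict[str, str] = field(default_factory=dict)  # truth id -> call

    @property
    def max_boundary_error(self) -> int:
        return max(self.boundary_errors) if self.boundary_errors else 0


@dataclass
class NgaroEval:
    recall: float
    precision: float
    container_correct: int
    type_correct: int
    variant_correct: int
    total_matched: int
    matches: dict[str, str] = field(default_factory=dict)


def evaluate_elements(result: StrainResult, truth: TruthSet,
                      assembly=None) -> ElementEval:
    """Match detected elements to planted truth by reciprocal overlap and
    score recall, precision, boundary accuracy and TSD recovery.

    TSD recovery is exact only when both the length and the recovered
    sequence equal the planted duplication (sequence checked when the
    assembly is supplied)."""
    truth_els = truth.by_class("element")
    calls = {el.element_id: el for el in result.elements}
    matches: dict[str, str] = {}
    used = set()
    for tr in truth_els:
        best, best_ov = None, 0.0
        for cid, el in calls.items():
            if cid in used or el.contig != tr.contig:
                continue
            ov = reciprocal_overlap(tr.interval, el.interval)
            if ov > best_ov:
                best, best_ov = cid, ov
        if best is not None and best_ov >= MATCH_OVERLAP:
            matches[tr.feature_id] = best
            used.add(best)
    recall = len(matches) / len(truth_els) if truth_els else float("nan")
    precision = len(matches) / len(calls) if calls else float("nan")
    boundary_errors = []
    tsd_expected = tsd_exact = 0
    for tid, cid in matches.items():
        tr, el = truth.get(tid), calls[cid]
        boundary_errors.extend([abs(tr.start - el.start),
                                abs(tr.end - el.end)])
        want = int(tr.attrs.get("tsd_length", 0))
        if want > 0:
            tsd_expected += 1
            if el.tsd is not None and el.tsd.length == want:
                if assembly is None:
                    tsd_exact += 1
                else:
                    planted = assembly.contigs[tr.contig][tr.end:tr.end + want]
                    tsd_exact += int(el.tsd.sequence == planted)
    return ElementEval(recall, precision, boundary_errors, tsd_expected,
                       tsd_exact, matches)


def evaluate_ngaros(result: StrainResult, truth: TruthSet,
                    element_matches: dict[str, str]) -> NgaroEval:
    """Score retrotransposon recovery: detection, container (element vs
    host), type and ORF1-variant calls against the planted truth."""
    truth_ng = truth.by_class("ngaro")
    calls = {n.ngaro_id: n for n in result.ngaros}
    matches: dict[str, str] = {}
    used = set()
    for tr in truth_ng:
        best, best_ov = None, 0.0
        for cid, n in calls.items():
            if cid in used or n.contig != tr.contig:
                continue
            ov = reciprocal_overlap(tr.interval, n.interval)
            if ov > best_ov:
                best, best_ov = cid, ov
        if best is not None and best_ov >= 0.5:
            matches[tr.feature_id] = best
            used.add(best)
    container_ok = type_ok = variant_ok = 0
    for tid, cid in matches.items():
        tr, n = truth.get(tid), calls[cid]
        want_container = tr.attrs.get("container", "host")
        if n.container == want_container:
            if want_container == "host":
                container_ok += 1
            else:
                want_el = element_matches.get(tr.parent_id)
                container_ok += int(n.container_element_id == want_el)
        type_ok += int(n.type_id == tr.type_id)
        variant_ok += int(n.variant == tr.attrs.get("variant", "full"))
    recall = len(matches) / len(truth_ng) if truth_ng else float("nan")
    precision = len(matches) / len(calls) if calls else float("nan")
    return NgaroEval(recall, precision, container_ok, type_ok, variant_ok,
                     len(matches), matches)


def typing_ari(result: StrainResult, truth: TruthSet,
               element_matches: dict[str, str]) -> float:
    """Adjusted Rand index between truth types and detected clusters over
    matched complete elements."""
    true_labels, pred_labels = [], []
    for tr in truth.by_class("element"):
        if tr.attrs.get("completeness") != "complete":
            continue
        cid = element_matches.get(tr.feature_id)
        if cid is None:
            continue
        el = next(e for e in result.elements if e.element_id == cid)
        if not isinstance(el.type_assignment, (int, np.integer)):
            continue
        true_labels.append(tr.type_id)
        pred_labels.append(int(el.type_assignment))
    if len(true_labels) < 2:
        return float("nan")
    return float(adjusted_rand_score(true_labels, pred_labels))
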