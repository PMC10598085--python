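"""Scoring pipeline output against simulator ground truth.

The recovery report quantifies every stage against the planted truth:
member detection (sensitivity / decoy false positives), clustering purity,
group and type accuracy, domain-architecture agreement, novel-domain count
and length error, and activity-prediction accuracy.  Type labels are
compared up to a relabelling: pipeline type names are matched to planted
lineages by majority membership, and the match must be one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .pipeline import PipelineResult
from .simulate import KNOWN_TEMPLATES, TEMPLATE_SPECS


@dataclass(frozen=True)
class RecoveryReport:
    detection_sensitivity: float
    decoy_false_positives: int
    detection_specificity: float
    clustering_purity: float
    group_accuracy: float
    type_accuracy: float
    architecture_match_rate: float
    novel_domain_count: int
    novel_domain_max_length_error: float
    activity_accuracy: float

    def to_dict(self) -> dict:
        return asdict(self)


def expected_recovery_report(truth: pd.DataFrame, result: PipelineResult) -> RecoveryReport:
    truth = truth.set_index("id", drop=False)
    known_ids = set(truth.index)
    for h in result.hits:
        if h.target_id not in known_ids:
            raise KeyError(f"pipeline hit id {h.target_id!r} absent from truth")
    for c in result.calls:
        if c.protein_id not in known_ids:
            raise KeyError(f"call id {c.protein_id!r} absent from truth")

    fam = truth[~truth.is_decoy]
    decoys = truth[truth.is_decoy]
    detected = {h.target_id for h in result.hits}
    sens = len(detected & set(fam.index)) / len(fam) if len(fam) else float("nan")
    fp = len(detected & set(decoys.index))
    spec = 1.0 - fp / len(decoys) if len(decoys) else 1.0

    # clustering purity: fraction of clustered genes in their cluster's
    # majority lineage
    n_pure = n_tot = 0
    for cl in result.clusters:
        lineages = [truth.loc[m, "lineage"] for m in cl.member_ids
                    if m in truth.index and not truth.loc[m, "is_decoy"]]
        if not lineages:
            continue
        counts = pd.Series(lineages).value_counts()
        n_pure += int(counts.iloc[0])
        n_tot += len(lineages)
    purity = n_pure / n_tot if n_tot else float("nan")

    calls_fam = [c for c in result.calls
                 if c.protein_id in truth.index
                 and not truth.loc[c.protein_id, "is_decoy"]]
    grp_ok = sum(c.group == truth.loc[c.protein_id, "group"] for c in calls_fam)
    grp_acc = grp_ok / len(calls_fam) if calls_fam else float("nan")

    type_acc = _type_accuracy(truth, calls_fam)
    arch_rate = _architecture_match_rate(truth, result)

    act_ok = sum(c.predicted_activity == truth.loc[c.protein_id, "activity"]
                 for c in calls_fam)
    act_acc = act_ok / len(calls_fam) if calls_fam else float("nan")

    nd_count = len(result.novel_domains)
    nd_err = _novel_length_error(truth, result)

    return RecoveryReport(
        detection_sensitivity=sens,
        decoy_false_positives=fp,
        detection_specificity=spec,
        clustering_purity=purity,
        group_accuracy=grp_acc,
        type_accuracy=type_acc,
        architecture_match_rate=arch_rate,
        novel_domain_count=nd_count,
        novel_domain_max_length_error=nd_err,
        activity_accuracy=act_acc,
    )


def _type_accuracy(truth: pd.DataFrame, calls_fam) -> float:
    """Accuracy of type labelling up to a one-to-one lineage relabelling.

    Only lineages the generator plants as cross-species types (more than one
    lineage within a group) are scored.
    """
    by_lineage: dict[str, list] = {}
    for c in calls_fam:
        lin = truth.loc[c.protein_id, "lineage"]
        grp = truth.loc[c.protein_id, "group"]
        n_lineages_in_group = truth[(truth.group == grp) & ~truth.is_decoy][
            "lineage"].nunique()
        if n_lineages_in_group < 2:
            continue  # single-lineage groups carry no type labels
        by_lineage.setdefault(lin, []).append(c)
    if not by_lineage:
        return float("nan")
    majority: dict[str, str] = {}
    for lin, cs in by_lineage.items():
        labels = pd.Series([c.type_label for c in cs]).value_counts()
        majority[lin] = labels.index[0]
    # the lineage -> label map must be injective and use real type labels
    used = list(majority.values())
    ok = tot = 0
    for lin, cs in by_lineage.items():
        lab = majority[lin]
        valid = lab.startswith("t") and used.count(lab) == 1
        for c in cs:
            tot += 1
            if valid and c.type_label == lab:
                ok += 1
    return ok / tot if tot else float("nan")


def _parse_domains(spec: str) -> list[tuple[str, int, int]]:
    out = []
    if not spec:
        return out
    for part in spec.split(";"):
        name, span = part.split(":")
        s, e = span.split("-")
        out.append((name, int(s), int(e)))
    return out


def _architecture_match_rate(truth: pd.DataFrame, result: PipelineResult) -> float:
    """Fraction of family representatives whose annotated domains match the
    planted ones one-for-one with reciprocal >= 50% span overlap (names of
    discovered novel domains are not required to match template names)."""
    ok = tot = 0
    for rid, arch in result.architectures.items():
        if rid not in truth.index or truth.loc[rid, "is_decoy"]:
            continue
        planted = _parse_domains(truth.loc[rid, "domains"])
        if not planted:
            continue
        tot += 1
        hits = list(arch.hits)
        if len(hits) != len(planted):
            continue
        good = True
        for (name, s, e), h in zip(planted, hits):
            ov = max(0, min(e, h.end) - max(s, h.start) + 1)
            if ov < 0.5 * (e - s + 1) or ov < 0.5 * (h.end - h.start + 1):
                good = False
                break
        ok += good
    return ok / tot if tot else float("nan")


def _novel_length_error(truth: pd.DataFrame, result: PipelineResult) -> float:
    """Max |mean discovered length - planted template length| over discovered
    novel domains, matched to planted replacement domains by member lineage."""
    if not result.novel_domains:
        return float("nan")
    errors = []
    for nd in result.novel_domains:
        lineages = []
        for h in nd.members:
            if h.protein_id in truth.index:
                lineages.append(truth.loc[h.protein_id, "lineage"])
        if not lineages:
            continue
        lin = pd.Series(lineages).value_counts().index[0]
        planted_rows = truth[(truth.lineage == lin) & ~truth.is_isoform & ~truth.is_decoy]
        if planted_rows.empty:
            continue
        planted = _parse_domains(planted_rows.iloc[0]["domains"])
        novel_templates = [(n, e - s + 1) for n, s, e in planted
                           if n not in KNOWN_TEMPLATES]
        if not novel_templates:
            continue
        # closest planted novel span
        err = min(abs(nd.mean_length - ln) for _n, ln in novel_templates)
        errors.append(err)
    return float(max(errors)) if errors else float("nan")
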