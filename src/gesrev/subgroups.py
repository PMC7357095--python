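"""Subgroup assignment for unique drug-disease pairs.

Five classification categories, mirroring common drug/disease taxonomies:

- ``disease_class``  — ICD-11 level-1 class of the disease (one label);
- ``target``         — the drug's main therapeutic target subfamily, after
  grouping of near-identical subfamilies (e.g. the three beta-adrenergic
  receptors into one label); multi-target drugs multi-label;
- ``tf_level``       — whether any main target is a human transcription
  factor ("directly"), a human protein/DNA structure that is not a TF
  ("not-directly"), or a non-human structure ("non-human"); one label;
- ``chemotherapy``   — chemo vs non-chemo by the target class (DNA
  cross-linking/alkylation, DNA/ligase, DNA/methyltransferase,
  DNA/polymerase, human DNA/topoisomerase, micro-tubules, nucleotide
  synthesis, thymidylate synthase define chemotherapy); a drug with
  context-dependent main targets may carry both labels;
- ``atc``            — ATC level-3 code(s) of the drug, with route-specific
  variants unified to the systemic-use code; multi-label.

All annotation content is user-supplied tabular data; only the assignment
logic lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .signatures import normalize_name

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "TF_DIRECTLY",
    "TF_NOT_DIRECTLY",
    "TF_NON_HUMAN",
    "AnnotationBundle",
    "assign_tf_level",
    "assign_chemotherapy",
    "build_subgroup_table",
]

CATEGORIES = ("disease_class", "target", "tf_level", "chemotherapy", "atc")

TF_DIRECTLY = "directly"
TF_NOT_DIRECTLY = "not-directly"
TF_NON_HUMAN = "non-human"

CHEMO = "chemo"
NON_CHEMO = "non_chemo"

SUBGROUP_COLUMNS = ["drug_name", "disease_name", "category", "subgroup"]


def _norm_map(mapping: Mapping[str, object], values_are_sets: bool) -> dict:
    out: dict = {}
    for key, value in mapping.items():
        if values_are_sets:
            out[normalize_name(key)] = frozenset(str(v) for v in value)
        else:
            out[normalize_name(key)] = str(value)
    return out


@dataclass(frozen=True)
class AnnotationBundle:
    """Curated drug and disease annotation tables driving subgroup assignment.

    ``target_grouping`` maps a raw target subfamily to its grouped label and
    defaults to identity for unmapped targets.  ``nonhuman_targets`` flags
    targets that are non-human structures (viral/bacterial proteins, 16S
    rRNA, ...).  ``atc_systemic_map`` maps route-specific ATC level-3 codes
    to their systemic-use variant.  ``chemo_context`` optionally resolves a
    both-labelled drug to one chemotherapy label for a specific disease.
    """

    drug_targets: Mapping[str, frozenset[str]]
    icd11_level1: Mapping[str, str]
    atc3: Mapping[str, frozenset[str]]
    tf_targets: frozenset[str] = frozenset()
    nonhuman_targets: frozenset[str] = frozenset()
    chemo_target_classes: frozenset[str] = frozenset()
    target_grouping: Mapping[str, str] = field(default_factory=dict)
    atc_systemic_map: Mapping[str, str] = field(default_factory=dict)
    chemo_context: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_targets", _norm_map(self.drug_targets, True))
        object.__setattr__(self, "icd11_level1", _norm_map(self.icd11_level1, False))
        object.__setattr__(self, "atc3", _norm_map(self.atc3, True))
        object.__setattr__(self, "tf_targets", frozenset(str(t) for t in self.tf_targets))
        object.__setattr__(
            self, "nonhuman_targets", frozenset(str(t) for t in self.nonhuman_targets)
        )
        object.__setattr__(
            self,
            "chemo_target_classes",
            frozenset(str(t) for t in self.chemo_target_classes),
        )
        object.__setattr__(
            self,
            "chemo_context",
            {
                (normalize_name(d), normalize_name(z)): str(v)
                for (d, z), v in self.chemo_context.items()
            },
        )

    def grouped_targets(self, drug: str) -> frozenset[str]:
        raw = self.drug_targets.get(normalize_name(drug), frozenset())
        return frozenset(self.target_grouping.get(t, t) for t in raw)

    def systemic_atc(self, drug: str) -> frozenset[str]:
        raw = self.atc3.get(normalize_name(drug), frozenset())
        return frozenset(self.atc_systemic_map.get(code, code) for code in raw)

    # -- TSV round trip ----------------------------------------------------

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def _pairs(mapping, key, value, sets):
            rows = []
            for k in sorted(mapping):
                vals = sorted(mapping[k]) if sets else [mapping[k]]
                rows.extend({key: k, value: v} for v in vals)
            return pd.DataFrame(rows, columns=[key, value])

        _pairs(self.drug_targets, "drug", "target", True).to_csv(
            directory / "drug_targets.tsv", sep="\t", index=False
        )
        _pairs(self.icd11_level1, "disease", "icd11_class", False).to_csv(
            directory / "disease_classes.tsv", sep="\t", index=False
        )
        _pairs(self.atc3, "drug", "atc3", True).to_csv(
            directory / "drug_atc3.tsv", sep="\t", index=False
        )
        _pairs(dict(self.target_grouping), "target", "grouped_target", False).to_csv(
            directory / "target_grouping.tsv", sep="\t", index=False
        )
        _pairs(dict(self.atc_systemic_map), "atc3", "systemic_atc3", False).to_csv(
            directory / "atc_systemic.tsv", sep="\t", index=False
        )
        flags = pd.DataFrame(
            [
                {"target": t, "flag": "tf"}
                for t in sorted(self.tf_targets)
            ]
            + [{"target": t, "flag": "non_human"} for t in sorted(self.nonhuman_targets)]
            + [
                {"target": t, "flag": "chemo_class"}
                for t in sorted(self.chemo_target_classes)
            ],
            columns=["target", "flag"],
        )
        flags.to_csv(directory / "target_flags.tsv", sep="\t", index=False)
        ctx = pd.DataFrame(
            [
                {"drug": d, "disease": z, "label": v}
                for (d, z), v in sorted(self.chemo_context.items())
            ],
            columns=["drug", "disease", "label"],
        )
        ctx.to_csv(directory / "chemo_context.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "AnnotationBundle":
        directory = Path(directory)

        def _read(name):
            path = directory / name
            if not path.exists():
                return pd.DataFrame()
            return pd.read_csv(path, sep="\t", dtype=str).fillna("")

        def _set_map(frame, key, value):
            out: dict[str, set[str]] = {}
            for _, row in frame.iterrows():
                out.setdefault(row[key], set()).add(row[value])
            return {k: frozenset(v) for k, v in out.items()}

        targets = _read("drug_targets.tsv")
        classes = _read("disease_classes.tsv")
        atc = _read("drug_atc3.tsv")
        grouping = _read("target_grouping.tsv")
        systemic = _read("atc_systemic.tsv")
        flags = _read("target_flags.tsv")
        ctx = _read("chemo_context.tsv")
        return cls(
            drug_targets=_set_map(targets, "drug", "target") if not targets.empty else {},
            icd11_level1=(
                dict(zip(classes["disease"], classes["icd11_class"]))
                if not classes.empty
                else {}
            ),
            atc3=_set_map(atc, "drug", "atc3") if not atc.empty else {},
            target_grouping=(
                dict(zip(grouping["target"], grouping["grouped_target"]))
                if not grouping.empty
                else {}
            ),
            atc_systemic_map=(
                dict(zip(systemic["atc3"], systemic["systemic_atc3"]))
                if not systemic.empty
                else {}
            ),
            tf_targets=(
                frozenset(flags.loc[flags["flag"] == "tf", "target"])
                if not flags.empty
                else frozenset()
            ),
            nonhuman_targets=(
                frozenset(flags.loc[flags["flag"] == "non_human", "target"])
                if not flags.empty
                else frozenset()
            ),
            chemo_target_classes=(
                frozenset(flags.loc[flags["flag"] == "chemo_class", "target"])
                if not flags.empty
                else frozenset()
            ),
            chemo_context=(
                {
                    (row["drug"], row["disease"]): row["label"]
                    for _, row in ctx.iterrows()
                }
                if not ctx.empty
                else {}
            ),
        )


def assign_tf_level(
    drug_targets: Mapping[str, frozenset[str]],
    tf_targets: frozenset[str],
    nonhuman_targets: frozenset[str] = frozenset(),
) -> dict[str, str]:
    """Label each drug by its main targets' relation to human TFs.

    "directly" if any main target is a human transcription factor;
    "non-human" if every main target is a non-human structure; otherwise
    "not-directly".  Drugs without target annotation are omitted (reported
    by the caller).
    """
    labels: dict[str, str] = {}
    for drug, targets in drug_targets.items():
        if not targets:
            continue
        if targets & tf_targets:
            labels[drug] = TF_DIRECTLY
        elif targets <= nonhuman_targets:
            labels[drug] = TF_NON_HUMAN
        else:
            labels[drug] = TF_NOT_DIRECTLY
    return labels


def assign_chemotherapy(
    drug_targets: Mapping[str, frozenset[str]],
    chemo_target_classes: frozenset[str],
) -> dict[str, frozenset[str]]:
    """Label each drug chemo/non-chemo by its main target classes.

    A drug whose annotation lists both a chemotherapy-defining target class
    and another main target carries both labels (context-dependent main
    therapeutic targets, e.g. an antifolate used in both oncology and
    rheumatology).
    """
    labels: dict[str, frozenset[str]] = {}
    for drug, targets in drug_targets.items():
        if not targets:
            continue
        out = set()
        if targets & chemo_target_classes:
            out.add(CHEMO)
        if targets - chemo_target_classes:
            out.add(NON_CHEMO)
        labels[drug] = frozenset(out)
    return labels


def build_subgroup_table(pairs: pd.DataFrame, bundle: AnnotationBundle) -> pd.DataFrame:
    """One row per (unique pair × category × applicable subgroup label).

    ``tf_level`` and ``disease_class`` assign exactly one label per
    annotated pair; ``target``, ``atc`` and ``chemotherapy`` may
    multi-label.  Pairs lacking an annotation in one category are omitted
    from that category only (logged), never from the others.
    """
    tf_labels = assign_tf_level(
        bundle.drug_targets, bundle.tf_targets, bundle.nonhuman_targets
    )
    chemo_labels = assign_chemotherapy(bundle.drug_targets, bundle.chemo_target_classes)
    rows: list[dict[str, str]] = []
    unannotated: dict[str, int] = {c: 0 for c in CATEGORIES}
    for drug, disease in zip(pairs["drug_name"], pairs["disease_name"]):
        drug_n, disease_n = normalize_name(drug), normalize_name(disease)

        icd = bundle.icd11_level1.get(disease_n)
        if icd:
            rows.append(
                {"drug_name": drug_n, "disease_name": disease_n,
                 "category": "disease_class", "subgroup": icd}
            )
        else:
            unannotated["disease_class"] += 1

        targets = bundle.grouped_targets(drug_n)
        if targets:
            rows.extend(
                {"drug_name": drug_n, "disease_name": disease_n,
                 "category": "target", "subgroup": t}
                for t in sorted(targets)
            )
        else:
            unannotated["target"] += 1

        tf = tf_labels.get(drug_n)
        if tf:
            rows.append(
                {"drug_name": drug_n, "disease_name": disease_n,
                 "category": "tf_level", "subgroup": tf}
            )
        else:
            unannotated["tf_level"] += 1

        chemo = chemo_labels.get(drug_n, frozenset())
        if chemo:
            if len(chemo) == 2:
                context = bundle.chemo_context.get((drug_n, disease_n))
                chemo = frozenset({context}) if context else chemo
            rows.extend(
                {"drug_name": drug_n, "disease_name": disease_n,
                 "category": "chemotherapy", "subgroup": label}
                for label in sorted(chemo)
            )
        else:
            unannotated["chemotherapy"] += 1

        atc = bundle.systemic_atc(drug_n)
        if atc:
            rows.extend(
                {"drug_name": drug_n, "disease_name": disease_n,
                 "category": "atc", "subgroup": code}
                for code in sorted(atc)
            )
        else:
            unannotated["atc"] += 1

    for category, count in unannotated.items():
        if count:
            log.info("%d pair(s) unannotated in category %s", count, category)
    return pd.DataFrame(rows, columns=SUBGROUP_COLUMNS)
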