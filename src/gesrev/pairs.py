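"""Drug-disease pairing: pruning, unique-pair aggregation, indication split.

A drug or disease measured in several assay series is one entity (identity
is by normalised name).  Every retained drug-signature × disease-signature
SJI is averaged within its (drug, disease) name combination to give one
score per unique pair.  Pairs whose disease appears on the drug's FDA-label
indication list form the indicated group; every other unique pair is a
random control — the full cross, not a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .signatures import EntityKind, FilterReport, GeneSignature, normalize_name

log = logging.getLogger(__name__)

__all__ = [
    "IndicationTable",
    "PairRecord",
    "NoAnalyzablePairsError",
    "prune_unpaired",
    "build_unique_pairs",
    "split_by_indication",
]

PAIR_COLUMNS = [
    "drug_name",
    "disease_name",
    "n_signature_pairs",
    "mean_sji",
    "indicated",
]


class NoAnalyzablePairsError(ValueError):
    """Pruning removed every signature: no indicated drug-disease pair exists."""


@dataclass(frozen=True)
class IndicationTable:
    """Mapping drug name -> indicated disease names (FDA-label indications)."""

    indications: Mapping[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "IndicationTable":
        table: dict[str, set[str]] = {}
        for drug, disease in pairs:
            table.setdefault(normalize_name(drug), set()).add(normalize_name(disease))
        return cls({d: frozenset(s) for d, s in table.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IndicationTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if not {"drug", "disease"} <= set(frame.columns):
            raise ValueError(f"{path}: expected columns 'drug' and 'disease'")
        return cls.from_pairs(list(frame[["drug", "disease"]].itertuples(index=False)))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"drug": drug, "disease": disease}
            for drug in sorted(self.indications)
            for disease in sorted(self.indications[drug])
        ]
        pd.DataFrame(rows, columns=["drug", "disease"]).to_csv(
            path, sep="\t", index=False
        )

    def is_indicated(self, drug: str, disease: str) -> bool:
        return normalize_name(disease) in self.indications.get(normalize_name(drug), frozenset())

    def diseases_for(self, drug: str) -> frozenset[str]:
        return self.indications.get(normalize_name(drug), frozenset())

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self.indications)


@dataclass(frozen=True)
class PairRecord:
    """One unique drug-disease combination."""

    drug_name: str
    disease_name: str
    signature_pair_sjis: tuple[float, ...]
    mean_sji: float
    n_signature_pairs: int
    indicated: bool


def prune_unpaired(
    signatures: Sequence[GeneSignature],
    indications: IndicationTable,
    report: FilterReport | None = None,
) -> list[GeneSignature]:
    """Drop signatures that cannot participate in any indicated pair.

    A drug signature survives only if at least one of the drug's indicated
    diseases still has a retained disease signature; a disease signature
    survives only if some retained drug indicates it.  Removal can cascade
    (dropping a drug may orphan a disease), so the rule iterates to a fixed
    point.  Exclusions are tallied under ``no_indication_partner`` when a
    report is supplied.
    """
    kept = list(signatures)
    while True:
        drugs_present = {
            s.entity_name for s in kept if s.entity_kind is EntityKind.DRUG
        }
        diseases_present = {
            s.entity_name for s in kept if s.entity_kind is EntityKind.DISEASE
        }
        indicated_diseases = set().union(
            *(indications.diseases_for(d) for d in drugs_present), set()
        )
        next_kept = []
        for sig in kept:
            if sig.entity_kind is EntityKind.DRUG:
                ok = bool(indications.diseases_for(sig.entity_name) & diseases_present)
            else:
                ok = sig.entity_name in indicated_diseases
            if ok:
                next_kept.append(sig)
            else:
                log.debug(
                    "pruning %s (%s): no indicated partner",
                    sig.signature_id,
                    sig.entity_name,
                )
        if len(next_kept) == len(kept):
            break
        kept = next_kept
    if report is not None:
        kept_ids = {s.signature_id for s in kept}
        report.record_exclusion(
            "no_indication_partner",
            [s.signature_id for s in signatures if s.signature_id not in kept_ids],
        )
        report.retained_drugs = sum(
            1 for s in kept if s.entity_kind is EntityKind.DRUG
        )
        report.retained_diseases = sum(
            1 for s in kept if s.entity_kind is EntityKind.DISEASE
        )
        report.check_conservation()
    if not kept:
        raise NoAnalyzablePairsError(
            "no analyzable pairs: every signature was pruned (no indicated "
            "drug-disease relationship is present in the data)"
        )
    return kept


def build_unique_pairs(
    sji_matrix: pd.DataFrame,
    signatures: Sequence[GeneSignature],
    indications: IndicationTable,
) -> pd.DataFrame:
    """Aggregate signature-level SJIs to one record per unique (drug, disease).

    The unique-pair score is the unweighted arithmetic mean of all SJIs of
    signature pairs sharing that drug-disease name combination.  The
    ``indicated`` flag partitions the table into the indicated group and the
    all-remaining-pairs control group.
    """
    name_by_sig = {s.signature_id: s.entity_name for s in signatures}
    frame = sji_matrix.copy()
    frame["drug_name"] = frame["drug_signature_id"].map(name_by_sig)
    frame["disease_name"] = frame["disease_signature_id"].map(name_by_sig)
    if frame["drug_name"].isna().any() or frame["disease_name"].isna().any():
        missing = sorted(
            set(frame.loc[frame["drug_name"].isna(), "drug_signature_id"])
            | set(frame.loc[frame["disease_name"].isna(), "disease_signature_id"])
        )
        raise ValueError(f"SJI matrix references unknown signature ids: {missing}")
    grouped = (
        frame.groupby(["drug_name", "disease_name"], sort=True)["sji"]
        .agg(["count", "mean"])
        .reset_index()
        .rename(columns={"count": "n_signature_pairs", "mean": "mean_sji"})
    )
    grouped["indicated"] = [
        indications.is_indicated(drug, disease)
        for drug, disease in zip(grouped["drug_name"], grouped["disease_name"])
    ]
    return grouped[PAIR_COLUMNS]


def split_by_indication(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a unique-pair table into (indicated, control)."""
    indicated = pairs[pairs["indicated"]]
    control = pairs[~pairs["indicated"]]
    if indicated.empty:
        raise NoAnalyzablePairsError(
            "no indicated pairs: indicated-vs-control analysis is undefined"
        )
    if control.empty:
        log.warning("every unique pair is indicated: control group is empty")
    return indicated, control
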