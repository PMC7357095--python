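"""Reading, validation and inclusion filtering of gene-expression signatures.

A gene-expression signature (GES) is a pair of gene sets — up-regulated and
down-regulated symbols — characterising a perturbation: either a drug
treatment or a disease state.  Signatures arrive in the CREEDS JSON dialect
(one record per signature, gene lists either plain symbols or
``[symbol, weight]`` pairs) or as a pair of GMT files, one per direction.

The inclusion protocol mirrors the curation applied to the CREEDS manual
signatures before similarity analysis:

1. keep only signatures from allowed organisms (human by default),
2. keep only drug signatures whose drug is on an approval list,
3. drop explicitly excluded (mis-specified) signature identifiers,
4. resolve GEO series that contributed both a drug and a disease signature
   (dual-labelled assays), keeping the disease side by default.

Every exclusion is tallied in a :class:`FilterReport`, whose conservation
invariant (input = retained + excluded) holds on every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "EntityKind",
    "DualLabelPolicy",
    "GeneSignature",
    "FilterConfig",
    "FilterReport",
    "SignatureParseError",
    "SignatureValidationError",
    "normalize_symbol",
    "normalize_name",
    "build_signature",
    "read_creeds_json",
    "write_creeds_json",
    "read_gmt_pair",
    "write_gmt_pair",
    "resolve_dual_labels",
    "apply_inclusion_filters",
]


class SignatureParseError(ValueError):
    """A signature file could not be parsed."""


class SignatureValidationError(ValueError):
    """One or more signature records violated the schema."""

    def __init__(self, message: str, offending_ids: Sequence[str] = ()):
        super().__init__(message)
        self.offending_ids = list(offending_ids)


class EntityKind(str, Enum):
    DRUG = "drug"
    DISEASE = "disease"


class DualLabelPolicy(str, Enum):
    KEEP_DISEASE = "keep_disease"
    KEEP_DRUG = "keep_drug"
    DROP_BOTH = "drop_both"


#: organism synonym table; keys are canonical labels, values match case-insensitively
ORGANISM_SYNONYMS: dict[str, frozenset[str]] = {
    "human": frozenset({"human", "homo sapiens", "h. sapiens", "hsapiens"}),
    "mouse": frozenset({"mouse", "mus musculus", "m. musculus"}),
    "rat": frozenset({"rat", "rattus norvegicus"}),
}

_CANONICAL_ORGANISM = {
    syn: canon for canon, syns in ORGANISM_SYNONYMS.items() for syn in syns
}


def normalize_symbol(symbol: object) -> str:
    """Uppercase and strip a gene symbol.  No alias mapping is attempted."""
    return str(symbol).strip().upper()


def normalize_name(name: object) -> str:
    """Normalise an entity (drug/disease) name: lowercase, collapsed whitespace."""
    return " ".join(str(name).strip().lower().split())


def canonical_organism(organism: str) -> str:
    """Map an organism string to its canonical label ("Homo sapiens" -> "human")."""
    key = " ".join(organism.strip().lower().split())
    return _CANONICAL_ORGANISM.get(key, key)


@dataclass(frozen=True)
class GeneSignature:
    """One differential-expression signature.

    ``up_genes`` and ``down_genes`` must be disjoint and their union
    non-empty; construction raises otherwise.  Use :func:`build_signature`
    to construct from raw gene lists (it normalises symbols and resolves
    up/down conflicts with a warning).
    """

    signature_id: str
    entity_kind: EntityKind
    entity_name: str
    organism: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    series_id: str = ""

    def __post_init__(self) -> None:
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise SignatureValidationError(
                f"signature {self.signature_id!r}: genes in both up and down: "
                f"{sorted(overlap)}",
                offending_ids=[self.signature_id],
            )
        if not (self.up_genes or self.down_genes):
            raise SignatureValidationError(
                f"signature {self.signature_id!r}: empty gene sets",
                offending_ids=[self.signature_id],
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def swapped(self) -> "GeneSignature":
        """Return a copy with up and down sets exchanged."""
        return replace(self, up_genes=self.down_genes, down_genes=self.up_genes)


def build_signature(
    signature_id: str,
    entity_kind: EntityKind | str,
    entity_name: str,
    organism: str,
    up: Iterable[object],
    down: Iterable[object],
    series_id: str = "",
) -> GeneSignature:
    """Normalise raw gene lists and construct a validated :class:`GeneSignature`.

    Symbols are uppercased, stripped and de-duplicated.  A gene listed in
    both directions is contradictory and removed from both sets, with a
    warning naming the signature.
    """
    up_set = frozenset(normalize_symbol(g) for g in up) - {""}
    down_set = frozenset(normalize_symbol(g) for g in down) - {""}
    conflict = up_set & down_set
    if conflict:
        log.warning(
            "signature %s: %d gene(s) in both up and down removed: %s",
            signature_id,
            len(conflict),
            ",".join(sorted(conflict)),
        )
        up_set -= conflict
        down_set -= conflict
    return GeneSignature(
        signature_id=str(signature_id),
        entity_kind=EntityKind(entity_kind),
        entity_name=normalize_name(entity_name),
        organism=str(organism).strip(),
        up_genes=up_set,
        down_genes=down_set,
        series_id=str(series_id),
    )


# ---------------------------------------------------------------------------
# CREEDS JSON dialect
# ---------------------------------------------------------------------------

def _extract_symbols(raw: object) -> list[str]:
    """Gene list entries are plain symbols or [symbol, weight] pairs."""
    out: list[str] = []
    for item in raw or []:
        if isinstance(item, (list, tuple)):
            if not item:
                continue
            out.append(str(item[0]))
        else:
            out.append(str(item))
    return out


def _record_to_signature(record: Mapping[str, object], index: int) -> GeneSignature:
    try:
        sig_id = str(record["id"])
    except KeyError:
        raise SignatureValidationError(f"record {index}: missing 'id' field")
    up = _extract_symbols(record.get("up_genes"))
    down = _extract_symbols(record.get("down_genes"))
    if not up and not down:
        raise SignatureValidationError(
            f"record {index} ({sig_id}): missing both up_genes and down_genes",
            offending_ids=[sig_id],
        )
    kind_field = record.get("entity_kind") or record.get("kind")
    if kind_field is not None:
        kind = EntityKind(str(kind_field))
    elif sig_id.startswith("drug:"):
        kind = EntityKind.DRUG
    elif sig_id.startswith(("dz:", "disease:")):
        kind = EntityKind.DISEASE
    else:
        raise SignatureValidationError(
            f"record {index} ({sig_id}): cannot infer entity kind from id prefix",
            offending_ids=[sig_id],
        )
    name = (
        record.get("drug_name")
        or record.get("disease_name")
        or record.get("name")
        or ""
    )
    if not name:
        raise SignatureValidationError(
            f"record {index} ({sig_id}): missing entity name",
            offending_ids=[sig_id],
        )
    return build_signature(
        signature_id=sig_id,
        entity_kind=kind,
        entity_name=str(name),
        organism=str(record.get("organism", "")),
        up=up,
        down=down,
        series_id=str(record.get("geo_id", "")),
    )


def read_creeds_json(
    path: str | Path, *, strict: bool = True
) -> list[GeneSignature] | tuple[list[GeneSignature], list[SignatureValidationError]]:
    """Read a CREEDS-style JSON array of signature records.

    With ``strict=True`` (default) the first invalid record raises a
    :class:`SignatureValidationError` naming the record index and id.  With
    ``strict=False`` returns ``(signatures, errors)`` so a partially valid
    file can still be used.
    """
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SignatureParseError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(records, list):
        raise SignatureParseError(f"{path}: expected a JSON array of records")
    signatures: list[GeneSignature] = []
    errors: list[SignatureValidationError] = []
    seen: set[str] = set()
    for index, record in enumerate(records):
        try:
            sig = _record_to_signature(record, index)
            if sig.signature_id in seen:
                raise SignatureValidationError(
                    f"record {index}: duplicate signature id {sig.signature_id!r}",
                    offending_ids=[sig.signature_id],
                )
            seen.add(sig.signature_id)
            signatures.append(sig)
        except SignatureValidationError as exc:
            if strict:
                raise
            errors.append(exc)
    if strict:
        return signatures
    return signatures, errors


def write_creeds_json(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    """Write signatures in the CREEDS JSON dialect (plain symbol lists)."""
    records = []
    for sig in signatures:
        name_key = "drug_name" if sig.entity_kind is EntityKind.DRUG else "disease_name"
        records.append(
            {
                "id": sig.signature_id,
                "organism": sig.organism,
                "geo_id": sig.series_id,
                name_key: sig.entity_name,
                "up_genes": sorted(sig.up_genes),
                "down_genes": sorted(sig.down_genes),
            }
        )
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# GMT pair (one file per direction)
# ---------------------------------------------------------------------------

def _meta_description(sig: GeneSignature) -> str:
    return (
        f"kind={sig.entity_kind.value}|name={sig.entity_name}"
        f"|organism={sig.organism}|series={sig.series_id}"
    )


def _parse_description(desc: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for part in desc.split("|"):
        if "=" in part:
            key, _, value = part.partition("=")
            meta[key] = value
    return meta


def _read_gmt(path: Path) -> dict[str, tuple[str, list[str]]]:
    entries: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise SignatureParseError(f"{path}:{lineno}: fewer than two GMT fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        entries[name] = (desc, [g for g in genes if g.strip()])
    return entries


def read_gmt_pair(up_path: str | Path, down_path: str | Path) -> list[GeneSignature]:
    """Read one signature per shared set name from an up/down GMT file pair.

    The description field may carry ``kind=..|name=..|organism=..|series=..``
    metadata (as written by :func:`write_gmt_pair`); otherwise kind is
    inferred from the id prefix and name falls back to the id.
    """
    up_entries = _read_gmt(Path(up_path))
    down_entries = _read_gmt(Path(down_path))
    orphans = sorted(set(up_entries) ^ set(down_entries))
    if orphans:
        raise SignatureValidationError(
            f"set names present in only one GMT file: {orphans}",
            offending_ids=orphans,
        )
    signatures = []
    for name in sorted(up_entries):
        desc, up = up_entries[name]
        _, down = down_entries[name]
        meta = _parse_description(desc)
        if "kind" in meta:
            kind: EntityKind | str = meta["kind"]
        elif name.startswith("drug:"):
            kind = EntityKind.DRUG
        elif name.startswith(("dz:", "disease:")):
            kind = EntityKind.DISEASE
        else:
            raise SignatureValidationError(
                f"GMT set {name!r}: no kind metadata and no id prefix",
                offending_ids=[name],
            )
        signatures.append(
            build_signature(
                signature_id=name,
                entity_kind=kind,
                entity_name=meta.get("name", name),
                organism=meta.get("organism", ""),
                up=up,
                down=down,
                series_id=meta.get("series", ""),
            )
        )
    return signatures


def write_gmt_pair(
    signatures: Sequence[GeneSignature],
    up_path: str | Path,
    down_path: str | Path,
) -> None:
    """Write signatures as an up/down GMT file pair (round-trips metadata)."""
    up_lines, down_lines = [], []
    for sig in sorted(signatures, key=lambda s: s.signature_id):
        desc = _meta_description(sig)
        up_lines.append("\t".join([sig.signature_id, desc, *sorted(sig.up_genes)]))
        down_lines.append("\t".join([sig.signature_id, desc, *sorted(sig.down_genes)]))
    Path(up_path).write_text("\n".join(up_lines) + "\n")
    Path(down_path).write_text("\n".join(down_lines) + "\n")


# ---------------------------------------------------------------------------
# Inclusion filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Inclusion-filter settings.

    ``approved_drugs`` is an explicit snapshot list (names normalised like
    entity names), never an API lookup.  ``excluded_ids`` carries signature
    ids known to be mis-specified at the source.
    """

    allowed_organisms: frozenset[str] = frozenset({"human"})
    approved_drugs: frozenset[str] = frozenset()
    excluded_ids: frozenset[str] = frozenset()
    dual_label_policy: DualLabelPolicy = DualLabelPolicy.KEEP_DISEASE

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "allowed_organisms",
            frozenset(canonical_organism(o) for o in self.allowed_organisms),
        )
        object.__setattr__(
            self,
            "approved_drugs",
            frozenset(normalize_name(d) for d in self.approved_drugs),
        )
        object.__setattr__(self, "excluded_ids", frozenset(self.excluded_ids))
        object.__setattr__(
            self, "dual_label_policy", DualLabelPolicy(self.dual_label_policy)
        )


_REASONS = (
    "non_human",
    "not_approved",
    "mis_specified",
    "dual_label",
    "no_indication_partner",
)


@dataclass
class FilterReport:
    """Bookkeeping for the inclusion protocol; conserves every input signature."""

    n_input: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in _REASONS}
    )
    excluded_ids: dict[str, list[str]] = field(
        default_factory=lambda: {reason: [] for reason in _REASONS}
    )
    retained_drugs: int = 0
    retained_diseases: int = 0

    @property
    def n_retained(self) -> int:
        return self.retained_drugs + self.retained_diseases

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    def check_conservation(self) -> None:
        if self.n_retained + self.n_excluded != self.n_input:
            raise AssertionError(
                f"filter report does not conserve signatures: "
                f"{self.n_retained} retained + {self.n_excluded} excluded "
                f"!= {self.n_input} input"
            )

    def record_exclusion(self, reason: str, signature_ids: Iterable[str]) -> None:
        ids = list(signature_ids)
        self.excluded[reason] += len(ids)
        self.excluded_ids[reason].extend(ids)

    def to_frame(self):
        import pandas as pd

        rows = [{"reason": r, "n_excluded": self.excluded[r]} for r in _REASONS]
        rows.append({"reason": "retained_drug", "n_excluded": self.retained_drugs})
        rows.append({"reason": "retained_disease", "n_excluded": self.retained_diseases})
        return pd.DataFrame(rows).rename(columns={"n_excluded": "count"})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def resolve_dual_labels(
    signatures: Sequence[GeneSignature],
    policy: DualLabelPolicy | str = DualLabelPolicy.KEEP_DISEASE,
) -> list[GeneSignature]:
    """Resolve GEO series that contributed both drug and disease signatures.

    An assay series labelled for both a drug treatment and a disease yields
    correlated up/down sets on both sides, which would bias the similarity of
    that drug-disease pair; one side is therefore dropped.  The default
    (``keep_disease``) drops the drug-side signatures of every dual series.
    """
    policy = DualLabelPolicy(policy)
    kinds_by_series: dict[str, set[EntityKind]] = {}
    for sig in signatures:
        if sig.series_id:
            kinds_by_series.setdefault(sig.series_id, set()).add(sig.entity_kind)
    dual_series = {
        series for series, kinds in kinds_by_series.items() if len(kinds) == 2
    }
    if not dual_series:
        return list(signatures)
    drop_kinds: set[EntityKind]
    if policy is DualLabelPolicy.KEEP_DISEASE:
        drop_kinds = {EntityKind.DRUG}
    elif policy is DualLabelPolicy.KEEP_DRUG:
        drop_kinds = {EntityKind.DISEASE}
    else:
        drop_kinds = {EntityKind.DRUG, EntityKind.DISEASE}
    kept = []
    for sig in signatures:
        if sig.series_id in dual_series and sig.entity_kind in drop_kinds:
            log.debug(
                "dual-label series %s: dropping %s (%s)",
                sig.series_id,
                sig.signature_id,
                policy.value,
            )
            continue
        kept.append(sig)
    return kept


def apply_inclusion_filters(
    signatures: Sequence[GeneSignature], config: FilterConfig
) -> tuple[list[GeneSignature], FilterReport]:
    """Apply the inclusion protocol in order: organism, approval, explicit
    exclusions, dual-label resolution.

    Each input signature is accounted for exactly once in the returned
    :class:`FilterReport` (idempotent: re-filtering the output with the same
    config changes nothing).
    """
    if any(s.entity_kind is EntityKind.DRUG for s in signatures) and not config.approved_drugs:
        raise ValueError(
            "FilterConfig.approved_drugs must be non-empty when drug "
            "signatures are present"
        )
    report = FilterReport(n_input=len(signatures))

    stage = []
    for sig in signatures:
        if canonical_organism(sig.organism) not in config.allowed_organisms:
            report.record_exclusion("non_human", [sig.signature_id])
        else:
            stage.append(sig)

    stage2 = []
    for sig in stage:
        if (
            sig.entity_kind is EntityKind.DRUG
            and sig.entity_name not in config.approved_drugs
        ):
            report.record_exclusion("not_approved", [sig.signature_id])
        else:
            stage2.append(sig)

    stage3 = []
    for sig in stage2:
        if sig.signature_id in config.excluded_ids:
            report.record_exclusion("mis_specified", [sig.signature_id])
        else:
            stage3.append(sig)

    kept = resolve_dual_labels(stage3, config.dual_label_policy)
    kept_ids = {s.signature_id for s in kept}
    report.record_exclusion(
        "dual_label",
        [s.signature_id for s in stage3 if s.signature_id not in kept_ids],
    )

    report.retained_drugs = sum(1 for s in kept if s.entity_kind is EntityKind.DRUG)
    report.retained_diseases = sum(
        1 for s in kept if s.entity_kind is EntityKind.DISEASE
    )
    report.check_conservation()
    log.info(
        "inclusion filters: %d input -> %d retained (%s)",
        report.n_input,
        report.n_retained,
        ", ".join(f"{r}={report.excluded[r]}" for r in _REASONS if report.excluded[r]),
    )
    return kept, report
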