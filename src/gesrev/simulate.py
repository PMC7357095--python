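"""Synthetic drug-disease signature studies with planted reversal structure.

The generator emulates the statistical structure the reversal analysis
assumes: disease signatures are uniform random up/down gene sets; drug
signatures of drugs in *sensitive* subgroups copy a fraction ρ of their
indicated diseases' signature genes with the direction flipped (treatment
reverses disease expression), while all other drug signatures overlap
diseases only through a direction-neutral background pool.  At ρ = 0 every
drug-disease pair — indicated or not — is statistically identical, giving
an exact null for calibration; at ρ = 1 every indicated sensitive pair is
strongly anti-correlated and the flipped ("planted") genes are recoverable
from the gene-level reversal ranking.

``ground_truth`` records everything a test needs: sensitive drugs and
subgroup labels, planted genes per drug, and the indicated pair list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairs import IndicationTable
from .signatures import (
    EntityKind,
    GeneSignature,
    build_signature,
    write_creeds_json,
)
from .subgroups import AnnotationBundle

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_study",
    "write_study",
    "make_fixture_bundle",
    "FIXTURE_APPROVED_EXTRA",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generator settings.

    Defaults describe a small but realistic screening study: a 500-gene
    effective universe, 20 drugs × 25 diseases with one or two signatures
    each of 20–40 genes per direction, ~8% indication density, and a
    planted reversal of strength ρ = 0.8 in the drugs carrying the
    sensitive target label.
    """

    seed: int
    n_genes: int = 500
    n_drugs: int = 20
    n_diseases: int = 25
    signatures_per_entity: tuple[int, int] = (1, 2)
    signature_size: tuple[int, int] = (20, 40)
    indication_density: float = 0.08
    sensitive_subgroups: frozenset[str] = frozenset({"target-T01"})
    reversal_strength: float = 0.8
    background_overlap: float = 0.1
    n_target_labels: int = 6
    n_atc_labels: int = 5
    n_disease_classes: int = 5

    def validate(self) -> None:
        lo, hi = self.signature_size
        if not (0 < lo <= hi):
            raise ValueError("signature_size range must be non-empty and positive")
        if 2 * hi > self.n_genes:
            raise ValueError("signature_size * 2 must not exceed n_genes")
        slo, shi = self.signatures_per_entity
        if not (0 < slo <= shi):
            raise ValueError("signatures_per_entity range must be non-empty")
        if not 0.0 < self.indication_density < 1.0:
            raise ValueError("indication_density must be in (0, 1)")
        for name in ("reversal_strength", "background_overlap"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_drugs < 1 or self.n_diseases < 1:
            raise ValueError("need at least one drug and one disease")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its planted ground truth."""

    signatures: list[GeneSignature]
    indications: IndicationTable
    annotations: AnnotationBundle
    ground_truth: dict
    config: SimulationConfig


def _target_label(i: int) -> str:
    return f"target-T{i + 1:02d}"


def _gene(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate signatures, indications, annotations and ground truth.

    Fully deterministic given ``config.seed``; each stage draws from its own
    child stream of the seed sequence, so adding a later stage never
    perturbs an earlier one.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_disease, rng_indic, rng_drug, _spare = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]

    genes = np.array([_gene(i) for i in range(config.n_genes)])
    drugs = [f"drug-{i + 1:02d}" for i in range(config.n_drugs)]
    diseases = [f"disease-{j + 1:02d}" for j in range(config.n_diseases)]

    lo_n, hi_n = config.signatures_per_entity
    lo_s, hi_s = config.signature_size

    # --- disease signatures: uniform random direction-labelled sets -------
    disease_sigs: dict[str, list[GeneSignature]] = {}
    sig_counter = 0
    signatures: list[GeneSignature] = []
    for disease in diseases:
        disease_sigs[disease] = []
        for _ in range(int(rng_disease.integers(lo_n, hi_n + 1))):
            size = int(rng_disease.integers(lo_s, hi_s + 1))
            chosen = rng_disease.choice(genes, size=2 * size, replace=False)
            sig_counter += 1
            sig = build_signature(
                signature_id=f"dz:{sig_counter}",
                entity_kind=EntityKind.DISEASE,
                entity_name=disease,
                organism="human",
                up=chosen[:size],
                down=chosen[size:],
                series_id=f"GSE9{sig_counter:04d}",
            )
            disease_sigs[disease].append(sig)
            signatures.append(sig)

    # --- indication table: Bernoulli(density), each drug forced >=1 -------
    indicated_pairs: list[tuple[str, str]] = []
    for drug in drugs:
        hits = [
            disease
            for disease in diseases
            if rng_indic.random() < config.indication_density
        ]
        if not hits:
            hits = [diseases[int(rng_indic.integers(len(diseases)))]]
        indicated_pairs.extend((drug, disease) for disease in hits)
    indications = IndicationTable.from_pairs(indicated_pairs)

    # --- annotations: round-robin labels over small pools ------------------
    target_pool = [_target_label(i) for i in range(config.n_target_labels)]
    atc_pool = [f"atc-A{i + 1:02d}" for i in range(config.n_atc_labels)]
    icd_pool = [f"icd-C{i + 1:02d}" for i in range(config.n_disease_classes)]
    drug_targets = {
        drug: frozenset({target_pool[i % len(target_pool)]})
        for i, drug in enumerate(drugs)
    }
    annotations = AnnotationBundle(
        drug_targets=drug_targets,
        icd11_level1={
            disease: icd_pool[j % len(icd_pool)] for j, disease in enumerate(diseases)
        },
        atc3={
            drug: frozenset({atc_pool[i % len(atc_pool)]})
            for i, drug in enumerate(drugs)
        },
        tf_targets=frozenset({_target_label(1)}),        # T02 targets are TFs
        nonhuman_targets=frozenset({_target_label(5)}),  # T06 is non-human
        chemo_target_classes=frozenset({_target_label(4)}),  # T05 defines chemo
    )

    sensitive_drugs = sorted(
        drug
        for drug, targets in drug_targets.items()
        if targets & config.sensitive_subgroups
    )

    # --- drug signatures ----------------------------------------------------
    # direction-neutral background pool: every (gene, direction) entry of
    # every disease signature, so non-planted overlap is pair-agnostic
    global_pool = [
        (gene, direction)
        for sigs in disease_sigs.values()
        for sig in sigs
        for direction, members in (("up", sig.up_genes), ("down", sig.down_genes))
        for gene in sorted(members)
    ]

    planted_genes: dict[str, set[str]] = {}
    for i, drug in enumerate(drugs):
        own_diseases = sorted(indications.diseases_for(drug))
        sensitive = drug in sensitive_drugs and config.reversal_strength > 0
        # flip pool: the (gene, direction) entries of the drug's indicated
        # diseases' signatures; copying these flipped plants anti-correlation
        flip_pool = [
            (gene, direction)
            for disease in own_diseases
            for sig in disease_sigs.get(disease, [])
            for direction, members in (("up", sig.up_genes), ("down", sig.down_genes))
            for gene in sorted(members)
        ]
        for _ in range(int(rng_drug.integers(lo_n, hi_n + 1))):
            size = int(rng_drug.integers(lo_s, hi_s + 1))
            total = 2 * size
            up: set[str] = set()
            down: set[str] = set()
            if sensitive and flip_pool:
                k = round(config.reversal_strength * total)
                pool, flip = flip_pool, True
            else:
                k = round(config.background_overlap * total)
                pool, flip = global_pool, False
            if k and pool:
                order = rng_drug.permutation(len(pool))
                for idx in order:
                    if len(up) + len(down) >= k:
                        break
                    gene, direction = pool[idx]
                    if gene in up or gene in down:
                        continue
                    if flip:
                        (down if direction == "up" else up).add(gene)
                        planted_genes.setdefault(drug, set()).add(gene)
                    else:
                        (up if rng_drug.random() < 0.5 else down).add(gene)
            # fill the remainder with fresh random genes, balanced up/down;
            # planted signatures avoid their diseases' genes entirely so the
            # filler never dilutes or contradicts the planted directions
            remaining = total - len(up) - len(down)
            if remaining > 0:
                used = up | down
                if flip:
                    used = used | {gene for gene, _ in flip_pool}
                free = np.array([g for g in genes if g not in used])
                if free.size < remaining:
                    free = np.array([g for g in genes if g not in (up | down)])
                fill = rng_drug.choice(free, size=remaining, replace=False)
                half = remaining // 2
                up.update(fill[:half])
                down.update(fill[half:])
            sig_counter += 1
            signatures.append(
                build_signature(
                    signature_id=f"drug:{sig_counter}",
                    entity_kind=EntityKind.DRUG,
                    entity_name=drug,
                    organism="human",
                    up=sorted(up),
                    down=sorted(down),
                    series_id=f"GSE9{sig_counter:04d}",
                )
            )

    sensitive_labels = sorted(config.sensitive_subgroups)
    ground_truth = {
        "seed": config.seed,
        "sensitive_subgroups": sensitive_labels,
        "sensitive_drugs": sensitive_drugs,
        "planted_genes": {d: sorted(g) for d, g in sorted(planted_genes.items())},
        "planted_union": sorted(set().union(*planted_genes.values(), set())),
        "indicated_pairs": sorted(indicated_pairs),
        "n_drugs": config.n_drugs,
        "n_diseases": config.n_diseases,
        "expected_effect_sign": -1 if config.reversal_strength > 0 else 0,
    }
    return SyntheticStudy(
        signatures=signatures,
        indications=indications,
        annotations=annotations,
        ground_truth=ground_truth,
        config=config,
    )


def write_study(study: SyntheticStudy, directory: str | Path) -> None:
    """Materialise a study in the exact input formats the pipeline consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_creeds_json(study.signatures, directory / "signatures.json")
    study.indications.to_tsv(directory / "indications.tsv")
    study.annotations.to_dir(directory / "annotations")
    (directory / "ground_truth.json").write_text(
        json.dumps(study.ground_truth, indent=1, sort_keys=True)
    )
    cfg = asdict(study.config)
    cfg["sensitive_subgroups"] = sorted(study.config.sensitive_subgroups)
    cfg["signatures_per_entity"] = list(study.config.signatures_per_entity)
    cfg["signature_size"] = list(study.config.signature_size)
    (directory / "sim_config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
    approved = sorted({s.entity_name for s in study.signatures
                       if s.entity_kind is EntityKind.DRUG})
    (directory / "approved_drugs.txt").write_text("\n".join(approved) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixture: exercises every inclusion-filter branch
# ---------------------------------------------------------------------------

#: extra approved drug names planted into the fixture (beyond the generated ones)
FIXTURE_APPROVED_EXTRA = ("duplexin", "anesthetine")


def make_fixture_bundle() -> SyntheticStudy:
    """A small deterministic study whose metadata covers every filter branch.

    Built on a 20-drug × 25-disease generated base (every disease indicated
    by at least one drug, so the base itself never prunes) plus five planted
    special cases: a mouse-assay signature, a non-approved drug, a
    dual-labelled GEO series, an explicitly excluded (mis-specified)
    signature id, and an approved drug whose only indication has no disease
    signature (so it prunes).  ``ground_truth["fixture"]`` records the exact
    expected exclusion counts and pair-table bookkeeping.
    """
    # no planted effect: the fixture exercises plumbing, not power
    config = SimulationConfig(seed=20200616, reversal_strength=0.0)
    study = generate_study(config)
    drugs = [f"drug-{i + 1:02d}" for i in range(config.n_drugs)]
    diseases = [f"disease-{j + 1:02d}" for j in range(config.n_diseases)]

    # deterministic full-coverage indication table: drug i -> diseases
    # i mod 25 and (i+7) mod 25, which jointly cover all 25 diseases
    indicated = sorted(
        (drugs[i], diseases[j])
        for i in range(len(drugs))
        for j in {i % 25, (i + 7) % 25}
    )
    indications = IndicationTable.from_pairs(
        indicated
        + [("duplexin", "disease-02"), ("anesthetine", "local anesthesia")]
    )

    specials = [
        # excluded: non-human assay (mouse mis-labelled upstream)
        build_signature(
            "dz:9001", EntityKind.DISEASE, "murine-only disease", "Mus musculus",
            up=["G0001", "G0002"], down=["G0003"], series_id="GSE77001",
        ),
        # excluded: drug not on the approval list
        build_signature(
            "drug:9002", EntityKind.DRUG, "experimentine", "human",
            up=["G0004"], down=["G0005", "G0006"], series_id="GSE77002",
        ),
        # dual-label series: drug side dropped under keep_disease
        build_signature(
            "drug:9003", EntityKind.DRUG, "duplexin", "human",
            up=["G0007"], down=["G0008"], series_id="GSE77003",
        ),
        build_signature(
            "dz:9004", EntityKind.DISEASE, "disease-03", "Homo sapiens",
            up=["G0009", "G0010"], down=["G0011"], series_id="GSE77003",
        ),
        # excluded: mis-specified record (explicit exclusion list)
        build_signature(
            "dz:9005", EntityKind.DISEASE, "disease-04", "human",
            up=["G0012"], down=["G0013"], series_id="GSE77005",
        ),
        # pruned: indication ("local anesthesia") absent from disease data
        build_signature(
            "drug:9006", EntityKind.DRUG, "anesthetine", "human",
            up=["G0014", "G0015"], down=["G0016"], series_id="GSE77006",
        ),
    ]
    signatures = study.signatures + specials

    n_total = len(signatures)
    study.ground_truth["fixture"] = {
        "excluded_ids": ["dz:9005"],
        "approved_drugs": sorted(drugs) + sorted(FIXTURE_APPROVED_EXTRA),
        "expected_filter_counts": {
            "non_human": 1,
            "not_approved": 1,
            "mis_specified": 1,
            "dual_label": 1,
            "no_indication_partner": 1,
        },
        "n_input_signatures": n_total,
        "n_retained_signatures": n_total - 5,
        # unique-pair bookkeeping after filtering: the 20 base drugs against
        # all 25 base diseases (specials contribute no retained drug and one
        # extra disease-03 signature, not a new disease)
        "n_unique_pairs": len(drugs) * len(diseases),
        "n_indicated_pairs": len(indicated),
        "n_control_pairs": len(drugs) * len(diseases) - len(indicated),
    }
    study.ground_truth["indicated_pairs"] = indicated
    return SyntheticStudy(
        signatures=signatures,
        indications=indications,
        annotations=study.annotations,
        ground_truth=study.ground_truth,
        config=config,
    )
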