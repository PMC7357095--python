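"""End-to-end pipeline: filter -> pair -> annotate -> stats -> gene reversal.

Deterministic given its inputs; every stage's output is written as TSV so a
partial rerun can start from any stage.  A manifest records the config
hash, input checksums and stage counts for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import gene_reversal as gr
from . import pairs as pr
from . import similarity as sim
from . import stats as st
from . import subgroups as sg
from .signatures import (
    DualLabelPolicy,
    EntityKind,
    FilterConfig,
    apply_inclusion_filters,
    read_creeds_json,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    signatures_path: Path
    indications_path: Path
    annotations_dir: Path
    output_dir: Path
    approved_drugs_path: Path | None = None
    excluded_ids: tuple[str, ...] = ()
    allowed_organisms: tuple[str, ...] = ("human",)
    dual_label_policy: str = DualLabelPolicy.KEEP_DISEASE.value
    t_test_variant: str = "pooled"
    fdr_family: str = "pooled"
    fdr_threshold: float = 0.05
    # gene-reversal scope: (category, subgroup) or "auto" = lowest-q subgroup
    gene_scope: str | tuple[str, str] = "auto"
    top_fraction: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def _p(key):
            return (base / raw[key]).resolve() if key in raw else None
        cfg = cls(
            signatures_path=_p("signatures"),
            indications_path=_p("indications"),
            annotations_dir=_p("annotations"),
            output_dir=_p("output_dir") or base / "results",
            approved_drugs_path=_p("approved_drugs"),
        )
        for key in (
            "excluded_ids", "allowed_organisms", "dual_label_policy",
            "t_test_variant", "fdr_family", "fdr_threshold",
            "gene_scope", "top_fraction", "seed",
        ):
            if key in raw:
                value = raw[key]
                if key in ("excluded_ids", "allowed_organisms"):
                    value = tuple(value)
                elif key == "gene_scope" and isinstance(value, list):
                    value = tuple(value)
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        for name in ("signatures_path", "indications_path", "annotations_dir"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    # output location does not alter the analysis: two runs of the same
    # inputs into different directories share a hash
    payload = {
        k: str(v) for k, v in vars(config).items() if k != "output_dir"
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def _resolve_scope(results: pd.DataFrame, scope) -> tuple[str, str]:
    if scope == "auto":
        tested = results[results["tested"]]
        if tested.empty:
            raise st.DegenerateDataError("no tested subgroup to choose a scope from")
        best = tested.sort_values(["q_value", "p_value"]).iloc[0]
        return str(best["category"]), str(best["subgroup"])
    category, subgroup = scope
    return category, subgroup


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all outputs; returns the run manifest.

    On a stage failure, partial outputs are kept and a ``FAILED`` marker
    naming the stage and error is written before the exception propagates.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "inputs": {
            "signatures": _sha256(Path(config.signatures_path)),
            "indications": _sha256(Path(config.indications_path)),
        },
        "stages": {},
    }
    stage = "load"
    try:
        signatures = read_creeds_json(config.signatures_path)
        indications = pr.IndicationTable.from_tsv(config.indications_path)
        bundle = sg.AnnotationBundle.from_dir(config.annotations_dir)
        if config.approved_drugs_path:
            approved = frozenset(
                line.strip()
                for line in Path(config.approved_drugs_path).read_text().splitlines()
                if line.strip()
            )
        else:
            # absent an explicit approval snapshot, approve every drug present
            approved = frozenset(
                s.entity_name for s in signatures if s.entity_kind is EntityKind.DRUG
            )
        manifest["stages"]["load"] = {"n_signatures": len(signatures)}

        stage = "filter"
        filter_config = FilterConfig(
            allowed_organisms=frozenset(config.allowed_organisms),
            approved_drugs=approved,
            excluded_ids=frozenset(config.excluded_ids),
            dual_label_policy=config.dual_label_policy,
        )
        kept, report = apply_inclusion_filters(signatures, filter_config)
        kept = pr.prune_unpaired(kept, indications, report)
        report.to_tsv(out / "filter_report.tsv")
        manifest["stages"]["filter"] = {
            "n_retained": report.n_retained,
            "excluded": dict(report.excluded),
        }

        stage = "similarity"
        drug_sigs = [s for s in kept if s.entity_kind is EntityKind.DRUG]
        disease_sigs = [s for s in kept if s.entity_kind is EntityKind.DISEASE]
        matrix = sim.pairwise_sji_matrix(drug_sigs, disease_sigs)
        matrix.to_csv(out / "sji_matrix.tsv", sep="\t", index=False)
        manifest["stages"]["similarity"] = {"n_signature_pairs": len(matrix)}

        stage = "pair"
        unique_pairs = pr.build_unique_pairs(matrix, kept, indications)
        indicated, control = pr.split_by_indication(unique_pairs)
        unique_pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        manifest["stages"]["pair"] = {
            "n_unique_pairs": len(unique_pairs),
            "n_indicated": len(indicated),
            "n_control": len(control),
        }

        stage = "overall_test"
        overall = st.overall_t_test(
            indicated["mean_sji"], control["mean_sji"], config.t_test_variant
        )
        manifest["stages"]["overall_test"] = {
            "t": overall.statistic,
            "df": overall.df,
            "p": overall.p_value,
            "variant": overall.variant,
            "mean_indicated": float(indicated["mean_sji"].mean()),
            "sd_indicated": float(indicated["mean_sji"].std(ddof=1)),
            "mean_control": float(control["mean_sji"].mean()),
            "sd_control": float(control["mean_sji"].std(ddof=1)),
        }

        stage = "subgroup_stats"
        subgroup_table = sg.build_subgroup_table(unique_pairs, bundle)
        results = st.subgroup_analysis(
            unique_pairs, subgroup_table, fdr_family=config.fdr_family
        )
        st.format_results_table(results).to_csv(
            out / "subgroup_stats.tsv", sep="\t", index=False
        )
        n_sig = int((results["q_value"] < config.fdr_threshold).sum())
        manifest["stages"]["subgroup_stats"] = {
            "n_subgroups": len(results),
            "n_tested": int(results["tested"].sum()),
            "n_significant": n_sig,
        }

        stage = "gene_reversal"
        category, subgroup = _resolve_scope(results, config.gene_scope)
        scoped = subgroup_table[
            (subgroup_table["category"] == category)
            & (subgroup_table["subgroup"] == subgroup)
        ]
        scope_pairs = set(zip(scoped["drug_name"], scoped["disease_name"]))
        scope_drugs = {d for d, _ in scope_pairs}
        sig_by_name: dict[tuple[str, str], list] = {}
        for s in kept:
            sig_by_name.setdefault((s.entity_kind.value, s.entity_name), []).append(s)
        indicated_keys = {
            (d, z)
            for d, z in zip(unique_pairs["drug_name"], unique_pairs["disease_name"])
            if indications.is_indicated(d, z)
        }
        # assay-level pairs: indicated pairs inside the chosen subgroup vs
        # control (non-indicated) pairs involving that subgroup's drugs
        ind_assays = [
            (ds, zs)
            for (d, z) in sorted(scope_pairs & indicated_keys)
            for ds in sig_by_name.get(("drug", d), [])
            for zs in sig_by_name.get(("disease", z), [])
        ]
        disease_names = sorted({s.entity_name for s in disease_sigs})
        rand_assays = [
            (ds, zs)
            for d in sorted(scope_drugs)
            for z in disease_names
            if (d, z) not in indicated_keys
            for ds in sig_by_name.get(("drug", d), [])
            for zs in sig_by_name.get(("disease", z), [])
        ]
        if ind_assays and rand_assays:
            scores = gr.g_ir_scores(ind_assays, rand_assays)
            scores.to_csv(out / "gene_scores.tsv", sep="\t", index=False)
            top = gr.select_top_reversed(scores, fraction=config.top_fraction)
            gr.write_ranked_list(
                top, out / "top_reversed_genes.txt", out / "top_reversed_genes.gmt"
            )
            manifest["stages"]["gene_reversal"] = {
                "category": category,
                "subgroup": subgroup,
                "n_indicated_assay_pairs": len(ind_assays),
                "n_random_assay_pairs": len(rand_assays),
                "n_genes_scored": len(scores),
                "n_top": len(top),
            }
        else:
            manifest["stages"]["gene_reversal"] = {
                "category": category,
                "subgroup": subgroup,
                "skipped": "no assay pairs in scope",
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
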