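"""Subgroup assignment logic across the five classification categories."""

import pandas as pd
import pytest

from gesrev.subgroups import (
    CATEGORIES,
    TF_DIRECTLY,
    TF_NON_HUMAN,
    TF_NOT_DIRECTLY,
    AnnotationBundle,
    assign_chemotherapy,
    assign_tf_level,
    build_subgroup_table,
)

CHEMO_CLASSES = frozenset({
    "DNA cross-linking/alkylation", "DNA/ligase", "DNA/methyltransferase",
    "DNA/polymerase", "DNA/topoisomerase-human", "micro-tubules",
    "nucleotide synthesis", "Thymidylate synthase",
})


class TestTfLevel:
    def test_tf_target_is_directly(self):
        labels = assign_tf_level(
            {"prednisone": frozenset({"glucocorticoid receptor"})},
            tf_targets=frozenset({"glucocorticoid receptor"}),
        )
        assert labels["prednisone"] == TF_DIRECTLY

    def test_all_nonhuman_targets(self):
        labels = assign_tf_level(
            {"doxycycline": frozenset({"16S ribosomal RNA"})},
            tf_targets=frozenset(),
            nonhuman_targets=frozenset({"16S ribosomal RNA"}),
        )
        assert labels["doxycycline"] == TF_NON_HUMAN

    def test_human_non_tf_target(self):
        labels = assign_tf_level(
            {"imatinib": frozenset({"tyrosine kinase"})},
            tf_targets=frozenset({"glucocorticoid receptor"}),
            nonhuman_targets=frozenset({"16S ribosomal RNA"}),
        )
        assert labels["imatinib"] == TF_NOT_DIRECTLY

    def test_mixed_targets_prefer_directly(self):
        labels = assign_tf_level(
            {"x": frozenset({"glucocorticoid receptor", "16S ribosomal RNA"})},
            tf_targets=frozenset({"glucocorticoid receptor"}),
            nonhuman_targets=frozenset({"16S ribosomal RNA"}),
        )
        assert labels["x"] == TF_DIRECTLY


class TestChemotherapy:
    def test_microtubule_target_is_chemo(self):
        labels = assign_chemotherapy(
            {"paclitaxel": frozenset({"micro-tubules"})}, CHEMO_CLASSES
        )
        assert labels["paclitaxel"] == frozenset({"chemo"})

    def test_non_chemo_target(self):
        labels = assign_chemotherapy(
            {"simvastatin": frozenset({"HMG-CoA reductase"})}, CHEMO_CLASSES
        )
        assert labels["simvastatin"] == frozenset({"non_chemo"})

    def test_context_dependent_drug_carries_both(self):
        labels = assign_chemotherapy(
            {"methotrexate": frozenset({"nucleotide synthesis",
                                        "aminoimidazole transformylase"})},
            CHEMO_CLASSES,
        )
        assert labels["methotrexate"] == frozenset({"chemo", "non_chemo"})


class TestBuildSubgroupTable:
    def _bundle(self, **overrides):
        fields = dict(
            drug_targets={
                "peginterferon": frozenset({"Interferon receptor"}),
                "atenolol": frozenset({"Beta-1 adrenergic receptor"}),
            },
            icd11_level1={"hepatitis c": "certain infectious diseases"},
            atc3={
                "peginterferon": frozenset({"immunostimulants"}),
                "atenolol": frozenset({"beta blocking agents, topical"}),
            },
            tf_targets=frozenset(),
            nonhuman_targets=frozenset(),
            chemo_target_classes=CHEMO_CLASSES,
            target_grouping={
                "Beta-1 adrenergic receptor": "Beta adrenergic receptors",
                "Beta-2 adrenergic receptor": "Beta adrenergic receptors",
                "Beta-3 adrenergic receptor": "Beta adrenergic receptors",
            },
            atc_systemic_map={
                "beta blocking agents, topical": "beta blocking agents, systemic"
            },
        )
        fields.update(overrides)
        return AnnotationBundle(**fields)

    def _pairs(self):
        return pd.DataFrame(
            [
                {"drug_name": "peginterferon", "disease_name": "hepatitis c"},
                {"drug_name": "atenolol", "disease_name": "hypertension"},
            ]
        )

    def test_target_and_atc_rows_for_annotated_pair(self):
        table = build_subgroup_table(self._pairs(), self._bundle())
        inter = table[table["drug_name"] == "peginterferon"]
        assert ("target", "Interferon receptor") in set(
            zip(inter["category"], inter["subgroup"])
        )
        assert ("atc", "immunostimulants") in set(
            zip(inter["category"], inter["subgroup"])
        )

    def test_target_grouping_and_atc_route_unification(self):
        table = build_subgroup_table(self._pairs(), self._bundle())
        atenolol = table[table["drug_name"] == "atenolol"]
        labels = set(zip(atenolol["category"], atenolol["subgroup"]))
        assert ("target", "Beta adrenergic receptors") in labels
        assert ("atc", "beta blocking agents, systemic") in labels
        assert not any(label.endswith("topical") for _, label in labels)

    def test_unannotated_pair_dropped_from_that_category_only(self):
        table = build_subgroup_table(self._pairs(), self._bundle())
        atenolol = table[table["drug_name"] == "atenolol"]
        # hypertension has no ICD class in the bundle: no disease_class row,
        # but the drug-side categories are still present
        assert "disease_class" not in set(atenolol["category"])
        assert {"target", "tf_level", "chemotherapy", "atc"} <= set(
            atenolol["category"]
        )

    def test_single_label_categories_partition(self):
        table = build_subgroup_table(self._pairs(), self._bundle())
        for category in ("tf_level", "disease_class"):
            sub = table[table["category"] == category]
            assert not sub.duplicated(["drug_name", "disease_name"]).any()

    def test_assignment_is_deterministic(self):
        first = build_subgroup_table(self._pairs(), self._bundle())
        second = build_subgroup_table(self._pairs().iloc[::-1], self._bundle())
        key = ["drug_name", "disease_name", "category", "subgroup"]
        assert sorted(map(tuple, first[key].values.tolist())) == sorted(
            map(tuple, second[key].values.tolist())
        )

    def test_chemo_context_resolves_both_labelled_drug(self):
        bundle = self._bundle(
            drug_targets={
                "methotrexate": frozenset(
                    {"nucleotide synthesis", "aminoimidazole transformylase"}
                )
            },
            atc3={"methotrexate": frozenset({"antimetabolites"})},
            chemo_context={("methotrexate", "osteosarcoma"): "chemo"},
        )
        pairs = pd.DataFrame(
            [
                {"drug_name": "methotrexate", "disease_name": "osteosarcoma"},
                {"drug_name": "methotrexate", "disease_name": "rheumatoid arthritis"},
            ]
        )
        table = build_subgroup_table(pairs, bundle)
        chemo = table[table["category"] == "chemotherapy"]
        osteo = chemo[chemo["disease_name"] == "osteosarcoma"]["subgroup"]
        ra = chemo[chemo["disease_name"] == "rheumatoid arthritis"]["subgroup"]
        assert set(osteo) == {"chemo"}
        assert set(ra) == {"chemo", "non_chemo"}

    def test_round_trip_through_tsv_dir(self, tmp_path):
        bundle = self._bundle()
        bundle.to_dir(tmp_path)
        back = AnnotationBundle.from_dir(tmp_path)
        assert back.grouped_targets("atenolol") == bundle.grouped_targets("atenolol")
        assert back.systemic_atc("atenolol") == bundle.systemic_atc("atenolol")
        assert back.chemo_target_classes == bundle.chemo_target_classes
        first = build_subgroup_table(self._pairs(), bundle)
        second = build_subgroup_table(self._pairs(), back)
        assert first.equals(second)


def test_generated_study_row_counts_match_bookkeeping():
    """Synthetic annotations: one label per category per pair by design."""
    from gesrev.pairs import build_unique_pairs
    from gesrev.signatures import EntityKind
    from gesrev.similarity import pairwise_sji_matrix
    from gesrev.simulate import SimulationConfig, generate_study

    study = generate_study(SimulationConfig(seed=11))
    drugs = [s for s in study.signatures if s.entity_kind is EntityKind.DRUG]
    dzs = [s for s in study.signatures if s.entity_kind is EntityKind.DISEASE]
    pairs = build_unique_pairs(
        pairwise_sji_matrix(drugs, dzs), study.signatures, study.indications
    )
    table = build_subgroup_table(pairs, study.annotations)
    # generator assigns exactly one target, atc and icd label per entity and
    # no both-labelled chemo drugs, so each category contributes one row per pair
    assert len(table) == len(pairs) * len(CATEGORIES)
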