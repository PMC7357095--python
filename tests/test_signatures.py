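"""Signature IO, normalization and the inclusion-filter protocol."""

import json

import pytest

from gesrev.signatures import (
    DualLabelPolicy,
    EntityKind,
    FilterConfig,
    GeneSignature,
    SignatureParseError,
    SignatureValidationError,
    apply_inclusion_filters,
    build_signature,
    read_creeds_json,
    read_gmt_pair,
    resolve_dual_labels,
    write_gmt_pair,
)

from conftest import make_sig


class TestReadCreedsJson:
    def test_weighted_gene_lists_and_field_mapping(self, tmp_path):
        path = tmp_path / "sigs.json"
        path.write_text(json.dumps([
            {"id": "drug:1", "organism": "human", "drug_name": "aspirin",
             "geo_id": "GSE1",
             "up_genes": [["MX1", 0.2]], "down_genes": [["FTL", -0.1]]},
        ]))
        (sig,) = read_creeds_json(path)
        assert sig.signature_id == "drug:1"
        assert sig.entity_kind is EntityKind.DRUG
        assert sig.entity_name == "aspirin"
        assert sig.series_id == "GSE1"
        assert sig.up_genes == {"MX1"}
        assert sig.down_genes == {"FTL"}

    def test_symbol_normalization_is_idempotent(self, tmp_path):
        path = tmp_path / "sigs.json"
        path.write_text(json.dumps([
            {"id": "dz:1", "organism": "human", "disease_name": "colitis",
             "up_genes": ["mx1", "MX1 ", " Mx1"], "down_genes": ["ftl"]},
        ]))
        (sig,) = read_creeds_json(path)
        assert sig.up_genes == {"MX1"}

    def test_record_without_gene_lists_collected_as_error(self, tmp_path):
        path = tmp_path / "sigs.json"
        path.write_text(json.dumps([
            {"id": "drug:1", "organism": "human", "drug_name": "a",
             "up_genes": ["A"], "down_genes": ["B"]},
            {"id": "dz:2", "organism": "human", "disease_name": "d"},
            {"id": "dz:3", "organism": "human", "disease_name": "e",
             "up_genes": ["C"], "down_genes": ["D"]},
        ]))
        with pytest.raises(SignatureValidationError, match="dz:2"):
            read_creeds_json(path)
        sigs, errors = read_creeds_json(path, strict=False)
        assert [s.signature_id for s in sigs] == ["drug:1", "dz:3"]
        assert len(errors) == 1 and "dz:2" in errors[0].offending_ids

    def test_malformed_json_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("[{not json")
        with pytest.raises(SignatureParseError):
            read_creeds_json(path)


def test_gene_in_both_directions_removed_with_warning(caplog):
    with caplog.at_level("WARNING"):
        sig = build_signature("drug:1", "drug", "a", "human",
                              up=["A", "B"], down=["B", "C"])
    assert sig.up_genes == {"A"}
    assert sig.down_genes == {"C"}
    assert "drug:1" in caplog.text


def test_direct_construction_rejects_invalid_sets():
    with pytest.raises(SignatureValidationError):
        GeneSignature("x", EntityKind.DRUG, "a", "human",
                      frozenset({"A"}), frozenset({"A"}))
    with pytest.raises(SignatureValidationError):
        GeneSignature("x", EntityKind.DRUG, "a", "human",
                      frozenset(), frozenset())


class TestGmtPair:
    def test_basic_pair(self, tmp_path):
        (tmp_path / "up.gmt").write_text("drug:sigA\tdesc\tA\tB\n")
        (tmp_path / "down.gmt").write_text("drug:sigA\tdesc\tC\n")
        (sig,) = read_gmt_pair(tmp_path / "up.gmt", tmp_path / "down.gmt")
        assert sig.up_genes == {"A", "B"} and sig.down_genes == {"C"}

    def test_orphan_key_names_offender(self, tmp_path):
        (tmp_path / "up.gmt").write_text("dz:sigA\td\tA\ndz:sigB\td\tB\n")
        (tmp_path / "down.gmt").write_text("dz:sigA\td\tC\n")
        with pytest.raises(SignatureValidationError, match="sigB"):
            read_gmt_pair(tmp_path / "up.gmt", tmp_path / "down.gmt")

    def test_round_trip_identity(self, tmp_path):
        sigs = [
            make_sig("drug:1", ["A", "B"], ["C"], name="aspirin", series="GSE1"),
            make_sig("dz:2", ["D"], ["E", "F"], kind="disease", name="colitis"),
        ]
        write_gmt_pair(sigs, tmp_path / "up.gmt", tmp_path / "down.gmt")
        back = read_gmt_pair(tmp_path / "up.gmt", tmp_path / "down.gmt")
        assert sorted(back, key=lambda s: s.signature_id) == sorted(
            sigs, key=lambda s: s.signature_id
        )


class TestInclusionFilters:
    def _config(self, **kwargs):
        defaults = dict(approved_drugs=frozenset({"aspirin", "prednisone"}))
        defaults.update(kwargs)
        return FilterConfig(**defaults)

    def test_mouse_signature_excluded_as_non_human(self):
        sigs = [
            make_sig("drug:1", ["A"], ["B"], name="aspirin"),
            make_sig("dz:724", ["C"], ["D"], kind="disease",
                     name="x", organism="Mus musculus"),
        ]
        kept, report = apply_inclusion_filters(sigs, self._config())
        assert [s.signature_id for s in kept] == ["drug:1"]
        assert report.excluded["non_human"] == 1

    def test_organism_synonym_matches_homo_sapiens(self):
        sigs = [make_sig("dz:1", ["A"], ["B"], kind="disease",
                         name="x", organism="Homo sapiens")]
        kept, report = apply_inclusion_filters(
            sigs, FilterConfig(approved_drugs=frozenset({"unused"}))
        )
        assert len(kept) == 1 and report.n_excluded == 0

    def test_explicit_exclusion_list(self):
        sigs = [
            make_sig("drug:2772", ["A"], ["B"], name="aspirin", series="GSE10432"),
            make_sig("dz:297", ["C"], ["D"], kind="disease",
                     name="y", series="GSE10432"),
        ]
        kept, report = apply_inclusion_filters(
            sigs, self._config(excluded_ids=frozenset({"dz:297"}))
        )
        assert [s.signature_id for s in kept] == ["drug:2772"]
        assert report.excluded["mis_specified"] == 1

    def test_identity_when_nothing_to_exclude(self):
        sigs = [
            make_sig("drug:1", ["A"], ["B"], name="aspirin"),
            make_sig("dz:1", ["C"], ["D"], kind="disease", name="x"),
        ]
        kept, report = apply_inclusion_filters(sigs, self._config())
        assert kept == sigs
        assert all(count == 0 for count in report.excluded.values())

    def test_filtering_is_idempotent(self, fixture_study):
        meta = fixture_study.ground_truth["fixture"]
        config = FilterConfig(
            approved_drugs=frozenset(meta["approved_drugs"]),
            excluded_ids=frozenset(meta["excluded_ids"]),
        )
        once, _ = apply_inclusion_filters(fixture_study.signatures, config)
        twice, report = apply_inclusion_filters(once, config)
        assert twice == once
        assert report.n_excluded == 0

    def test_report_conservation(self, fixture_study):
        meta = fixture_study.ground_truth["fixture"]
        config = FilterConfig(
            approved_drugs=frozenset(meta["approved_drugs"]),
            excluded_ids=frozenset(meta["excluded_ids"]),
        )
        kept, report = apply_inclusion_filters(fixture_study.signatures, config)
        assert report.n_retained + report.n_excluded == report.n_input
        assert report.n_input == len(fixture_study.signatures)

    def test_missing_approval_list_rejected(self):
        sigs = [make_sig("drug:1", ["A"], ["B"], name="aspirin")]
        with pytest.raises(ValueError, match="approved_drugs"):
            apply_inclusion_filters(sigs, FilterConfig())


class TestDualLabels:
    def _series(self):
        return [
            make_sig("drug:2485", ["A"], ["B"], name="omalizumab", series="GSE31773"),
            make_sig("dz:712", ["C"], ["D"], kind="disease", name="asthma1",
                     series="GSE31773"),
            make_sig("dz:713", ["E"], ["F"], kind="disease", name="asthma2",
                     series="GSE31773"),
            make_sig("dz:714", ["G"], ["H"], kind="disease", name="asthma3",
                     series="GSE31773"),
            make_sig("dz:715", ["I"], ["J"], kind="disease", name="asthma4",
                     series="GSE31773"),
        ]

    def test_keep_disease_drops_drug_side(self):
        kept = resolve_dual_labels(self._series(), DualLabelPolicy.KEEP_DISEASE)
        assert [s.signature_id for s in kept] == ["dz:712", "dz:713", "dz:714", "dz:715"]

    def test_multiple_drug_signatures_in_one_series(self):
        sigs = [
            make_sig("drug:3289", ["A"], ["B"], name="mesalazine", series="GSE38713"),
            make_sig("drug:3194", ["C"], ["D"], name="mesalazine", series="GSE38713"),
            make_sig("drug:3195", ["E"], ["F"], name="mesalazine", series="GSE38713"),
            make_sig("dz:810", ["G"], ["H"], kind="disease", name="colitis",
                     series="GSE38713"),
        ]
        kept = resolve_dual_labels(sigs, "keep_disease")
        assert [s.signature_id for s in kept] == ["dz:810"]

    def test_disease_only_series_unchanged(self):
        sigs = [
            make_sig("dz:1", ["A"], ["B"], kind="disease", name="x", series="GSE9"),
            make_sig("dz:2", ["C"], ["D"], kind="disease", name="y", series="GSE9"),
        ]
        assert resolve_dual_labels(sigs) == sigs

    @pytest.mark.parametrize(
        "policy,expected",
        [
            (DualLabelPolicy.KEEP_DRUG, ["drug:2485"]),
            (DualLabelPolicy.DROP_BOTH, []),
        ],
    )
    def test_alternative_policies(self, policy, expected):
        kept = resolve_dual_labels(self._series(), policy)
        assert [s.signature_id for s in kept] == expected
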