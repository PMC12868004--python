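"""RNA specificity rule and proteome-transcriptome concordance classes."""

import numpy as np
import pandas as pd
import pytest

from brainprot import (
    AnalysisConfig,
    GeneratorParams,
    Region,
    RnaTable,
    ValidationError,
    call_region_specific,
    generate_proteome_dataset,
    generate_rna_table,
)
from brainprot.crossomics import (
    CONCORDANCE_CLASSES,
    concordance_classify,
    map_protein_regions_to_rna,
    rna_specificity,
)
from brainprot.preprocess import normalize


def _rna(rows: dict[str, list], labels: list[str]) -> RnaTable:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    frame.index.name = "gene_id"
    return RnaTable(ntpm=frame)


LABELS = ["Cx", "CB", "BS", "HIP", "THA_HT"]


class TestRnaRule:
    def test_clear_specific_case(self):
        """nTPM 16 vs four regions at 2: log2 4 >= 2 * 1."""
        calls = rna_specificity(_rna({"g1": [16, 2, 2, 2, 2]}, LABELS))
        row = calls.iloc[0]
        assert bool(row["specific"]) and row["max_region"] == "Cx"
        assert row["max_log2"] == pytest.approx(4.0)
        assert row["mean_rest_log2"] == pytest.approx(1.0)

    def test_boundary_is_non_strict(self):
        calls = rna_specificity(_rna({"g1": [4, 2, 2, 2, 2]}, LABELS))
        assert bool(calls.iloc[0]["specific"])  # 2 >= 2*1 exactly

    def test_all_below_floor_not_specific(self):
        calls = rna_specificity(_rna({"g1": [0.5, 0.9, 0.2, 0.1, 0.0]}, LABELS))
        row = calls.iloc[0]
        assert not row["specific"]
        assert pd.isna(row["max_region"])

    def test_only_max_region_expressed_follows_limit_convention(self):
        """All remaining regions floored: specific iff max_log2 > 0."""
        positive = rna_specificity(_rna({"g1": [8, 0.5, 0.5, 0.5, 0.5]}, LABELS))
        assert bool(positive.iloc[0]["specific"])
        assert positive.iloc[0]["n_rest"] == 0
        boundary = rna_specificity(_rna({"g1": [1.0, 0.5, 0.5, 0.5, 0.5]}, LABELS))
        assert not bool(boundary.iloc[0]["specific"])  # max_log2 == 0

    def test_rest_mean_zero_limit_convention(self):
        """Remaining regions at the floor exactly (log2 = 0)."""
        calls = rna_specificity(_rna({"g1": [2, 1, 1, 1, 1]}, LABELS))
        assert bool(calls.iloc[0]["specific"])  # max_log2 = 1 > 0

    def test_invariant_to_region_and_gene_order(self):
        rows = {"g1": [16, 2, 2, 2, 2], "g2": [3, 3, 3, 3, 3]}
        base = rna_specificity(_rna(rows, LABELS)).set_index("gene_id")
        flipped_rows = {"g2": rows["g2"][::-1], "g1": rows["g1"][::-1]}
        flipped = rna_specificity(
            _rna(flipped_rows, LABELS[::-1])
        ).set_index("gene_id")
        for gene in rows:
            assert base.loc[gene, "specific"] == flipped.loc[gene, "specific"]

    def test_monotone_in_max_region_ntpm(self):
        base = _rna({"g1": [16, 2, 2, 2, 2]}, LABELS)
        assert bool(rna_specificity(base).iloc[0]["specific"])
        for boost in (32, 64, 1000):
            bumped = _rna({"g1": [boost, 2, 2, 2, 2]}, LABELS)
            assert bool(rna_specificity(bumped).iloc[0]["specific"])


class TestRegionMapping:
    def _spec_table(self, region, call=True):
        return pd.DataFrame(
            {
                "protein_id": ["p1"],
                "max_region": pd.array([region], dtype="string"),
                "call": [call],
            }
        )

    def test_lobe_maps_to_cortex(self):
        mapped = map_protein_regions_to_rna(self._spec_table("PL"))
        assert mapped.iloc[0]["rna_region"] == "Cx"

    def test_ventricle_is_unmappable(self):
        mapped = map_protein_regions_to_rna(self._spec_table("VT"))
        assert mapped.iloc[0]["unmappable"]
        assert pd.isna(mapped.iloc[0]["rna_region"])

    def test_identity_map_passes_through(self):
        identity = {r: r.value for r in Region}
        mapped = map_protein_regions_to_rna(self._spec_table("VT"), identity)
        assert mapped.iloc[0]["rna_region"] == "VT"

    def test_missing_map_entry_is_error(self):
        partial = {Region.FL: "Cx"}
        with pytest.raises(ValidationError, match="TL"):
            map_protein_regions_to_rna(self._spec_table("TL"), partial)

    def test_uncalled_protein_needs_no_map_entry(self):
        mapped = map_protein_regions_to_rna(self._spec_table("TL", call=False), {})
        assert not mapped.iloc[0]["call"]


class TestConcordance:
    def _inputs(self):
        protein_calls = pd.DataFrame(
            {
                "protein_id": ["p1", "p2", "p3", "p4"],
                "call": [True, True, False, False],
                "rna_region": pd.array(["Cx", "CB", None, None], dtype="string"),
                "unmappable": [False, False, False, False],
            }
        )
        rna_calls = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "max_region": pd.array(["Cx", "BS", "HIP"], dtype="string"),
                "specific": [True, False, True],
            }
        )
        id_map = pd.DataFrame(
            {"protein_id": ["p1", "p2", "p3"], "gene_id": ["g1", "g2", "g3"]}
        )
        return protein_calls, rna_calls, id_map

    def test_class_assignment_and_region_agreement(self):
        classes = concordance_classify(*self._inputs()).set_index("protein_id")
        assert classes.loc["p1", "class"] == "both"
        assert classes.loc["p1", "region_agreement"] == True  # noqa: E712
        assert classes.loc["p2", "class"] == "protein_only"
        assert classes.loc["p3", "class"] == "rna_only"
        assert classes.loc["p4", "class"] == "unmapped"

    def test_classes_partition_universe(self):
        classes = concordance_classify(*self._inputs())
        assert classes["class"].isin(CONCORDANCE_CLASSES).all()
        assert len(classes) == 4
        assert not classes["protein_id"].duplicated().any()

    def test_duplicate_id_map_rejected(self):
        protein_calls, rna_calls, id_map = self._inputs()
        bad = pd.concat([id_map, id_map.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="p1"):
            concordance_classify(protein_calls, rna_calls, bad)


class TestEndToEndConcordance:
    def _pipeline(self, rna_concordance):
        params = GeneratorParams(
            n_proteins=800,
            markers_per_region=10,
            log2_effect=2.0,
            resid_sd=0.5,
            donor_sd=0.3,
            mcar_rate=0.10,
            mnar_mid=3.5,
            rna_concordance=rna_concordance,
            unmapped_fraction=0.1,
            seed=41,
        )
        matrix, annotations, truth = generate_proteome_dataset(params)
        rna, id_map = generate_rna_table(truth, params)
        result = call_region_specific(normalize(matrix), annotations)
        mapped = map_protein_regions_to_rna(result.table)
        rna_calls = rna_specificity(rna)
        classes = concordance_classify(mapped, rna_calls, id_map)
        return truth, result, mapped, classes, id_map

    def test_full_concordance_called_mapped_markers_are_both(self):
        truth, result, mapped, classes, id_map = self._pipeline(1.0)
        classes = classes.set_index("protein_id")
        mapped = mapped.set_index("protein_id")
        in_map = set(id_map["protein_id"])
        called_mapped_markers = [
            pid
            for pid in truth.marker_ids
            if pid in in_map
            and bool(result.table.set_index("protein_id").loc[pid, "call"])
            and not mapped.loc[pid, "unmappable"]
        ]
        assert len(called_mapped_markers) > 50
        for pid in called_mapped_markers:
            assert classes.loc[pid, "class"] == "both"
            assert classes.loc[pid, "region_agreement"] == True  # noqa: E712

    def test_zero_concordance_yields_no_both_markers(self):
        truth, _, _, classes, _ = self._pipeline(0.0)
        marker_classes = classes[classes["protein_id"].isin(truth.marker_ids)]
        assert not (marker_classes["class"] == "both").any()

    def test_partition_covers_whole_specificity_table(self):
        _, result, _, classes, _ = self._pipeline(0.5)
        assert set(classes["protein_id"]) == set(result.table["protein_id"])
        assert classes["class"].isin(CONCORDANCE_CLASSES).all()
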