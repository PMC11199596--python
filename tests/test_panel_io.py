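"""Panel/transition table parsing: dialects, validation, round trips."""

import numpy as np
import pandas as pd
import pytest

from iomrm import panel_io
from iomrm.quant_core import HEAVY_OVER_LIGHT, summarize_measurements


def test_peptide_id_derived_from_gene_and_first_four_residues():
    t = panel_io.PanelTarget(gene_symbol="MUTYH", sequence="MGQQVLDNFFR")
    assert t.peptide_id == "MUTYH_MGQQ"
    mod = panel_io.PanelTarget(gene_symbol="MUTYH", sequence="MGQQVLDNFFR", modification="ox")
    assert mod.peptide_id == "MUTYH_MGQQox"


def test_extended_heavy_sequence_must_contain_target():
    panel_io.PanelTarget(
        gene_symbol="MUTYH", sequence="MGQQVLDNFFR",
        extended_heavy_sequence="ASMGQQVLDNFFRQK",
    )
    with pytest.raises(panel_io.ValidationError):
        panel_io.PanelTarget(
            gene_symbol="MUTYH", sequence="MGQQVLDNFFR",
            extended_heavy_sequence="ASGGGVLDNFFRQK",
        )


def test_non_tryptic_terminus_warns_but_is_allowed(caplog):
    with caplog.at_level("WARNING", logger="iomrm"):
        panel_io.PanelTarget(gene_symbol="G", sequence="AAAAQ")
    assert any("non-tryptic" in m for m in caplog.messages)


def test_duplicate_peptide_ids_rejected():
    t = panel_io.PanelTarget(gene_symbol="G1", sequence="AAAK")
    with pytest.raises(panel_io.ValidationError, match="duplicate"):
        panel_io.PanelDefinition(targets=[t, t])


def test_read_panel_table_csv_and_empty(tmp_path, caplog):
    path = tmp_path / "panel.csv"
    pd.DataFrame(
        {
            "Gene Symbol": ["MUTYH", "B2M"],
            "Target Peptide Sequence": ["MGQQVLDNFFR", "VNHVTLSQPK"],
            "Extended Peptide Sequence": ["ASMGQQVLDNFFRQK", "SRVNHVTLSQPKIV"],
            "Antibody": ["Ab1", "Ab2"],
        }
    ).to_csv(path, index=False)
    panel = panel_io.read_panel_table(path)
    assert panel.peptide_ids == ["MUTYH_MGQQ", "B2M_VNHV"]

    empty = tmp_path / "empty.csv"
    pd.DataFrame(columns=["Gene", "Peptide"]).to_csv(empty, index=False)
    with caplog.at_level("WARNING", logger="iomrm"):
        assert len(panel_io.read_panel_table(empty)) == 0
    assert any("empty" in m for m in caplog.messages)


def test_missing_mandatory_column_names_the_column(tmp_path):
    path = tmp_path / "panel.csv"
    pd.DataFrame({"Gene": ["A"], "Something": ["x"]}).to_csv(path, index=False)
    with pytest.raises(panel_io.SchemaError, match="sequence"):
        panel_io.read_panel_table(path)


def _report_frame(area_col="Area"):
    rows = []
    for pep in ("P1", "P2"):
        for label in ("light", "heavy"):
            for frag in ("y3", "y4", "y5"):
                rows.append(
                    {
                        "Peptide": pep,
                        "Isotope Label Type": label,
                        "Replicate Name": "r1",
                        "Fragment Ion": frag,
                        area_col: 100.0,
                        "Background": 5.0,
                        "Retention Time": 12.0,
                    }
                )
    return pd.DataFrame(rows)


def test_transition_report_count_preserved_and_dialect_equivalent(tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    _report_frame("Area").to_csv(a, index=False)
    _report_frame("Total Area").to_csv(b, index=False)
    ra, rb = panel_io.read_transition_report(a), panel_io.read_transition_report(b)
    assert len(ra) == 12
    pd.testing.assert_frame_equal(ra, rb)


def test_negative_area_rejected_with_row_numbers(tmp_path):
    df = _report_frame()
    df.loc[3, "Area"] = -1.0
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(panel_io.ValidationError, match=r"\[3\]"):
        panel_io.read_transition_report(path)


def test_shuffled_rows_give_identical_characterization(tmp_path, small_bundle):
    _, records, _ = small_bundle
    curve = records[records["design"] == "curve"]
    shuffled = curve.sample(frac=1.0, random_state=5).reset_index(drop=True)
    out_a = summarize_measurements(curve, orientation=HEAVY_OVER_LIGHT)
    out_b = summarize_measurements(shuffled, orientation=HEAVY_OVER_LIGHT)
    pd.testing.assert_frame_equal(out_a, out_b)


def test_characterization_roundtrip_and_overwrite_refusal(tmp_path):
    table = pd.DataFrame(
        {
            "peptide_id": ["P1"],
            "matrix": ["tissue"],
            "slope": [1.002345678],
            "lloq_fmol": [0.205],
            "dynamic_range_log10": [3.989276],
        }
    )
    path = tmp_path / "char.csv"
    panel_io.write_characterization_table(table, path, metadata={"seed": 1})
    with pytest.raises(FileExistsError):
        panel_io.write_characterization_table(table, path)
    back = panel_io.read_characterization_table(path)
    for col in ("slope", "lloq_fmol", "dynamic_range_log10"):
        # lossless at the declared precision: 6 significant digits
        assert f"{back[col].iloc[0]:.6g}" == f"{table[col].iloc[0]:.6g}"
    with pytest.raises(ValueError):
        panel_io.write_characterization_table(table.iloc[:0], tmp_path / "e.csv")
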