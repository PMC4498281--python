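"""Floor transform, replicate screening and DEG calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abanet import qc_deg
from abanet.io import ExpressionMatrix, SampleDesign
from abanet.synthetic import SyntheticConfig, generate_dataset
from oracles import pooled_t_pvalue


def _design(times, reps):
    rows = [
        {"sample_id": f"t{t:g}_r{r}", "time_h": t, "replicate": r}
        for t in times
        for r in range(1, reps + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def _matrix(values, design):
    return ExpressionMatrix(
        pd.DataFrame(
            np.asarray(values, dtype=float),
            index=[f"g{i}" for i in range(len(values))],
            columns=design.sample_ids,
        )
    )


@pytest.mark.parametrize("value,expected", [(3.2, 4.0), (4.0, 4.0), (7.5, 7.5)])
def test_floor_transform_values(value, expected):
    design = _design([0, 2], 2)
    matrix = _matrix([[value] * 4], design)
    floored = qc_deg.floor_transform(matrix)
    assert floored.data.iloc[0, 0] == expected


def test_floor_transform_idempotent(default_dataset):
    matrix, _, _, _ = default_dataset
    once = qc_deg.floor_transform(matrix)
    twice = qc_deg.floor_transform(once)
    assert np.array_equal(once.data.values, twice.data.values)


def test_globally_shifted_replicate_is_flagged():
    """One sample shifted by +10 log2 units must be caught by the PC screen."""
    cfg = SyntheticConfig(n_genes=150, seed=4)
    matrix, design, _ = generate_dataset(cfg)
    data = matrix.data.copy()
    data["t12h_r2"] += 10.0
    report = qc_deg.detect_outlier_samples(ExpressionMatrix(data), design)
    assert "t12h_r2" in report.flagged_samples


def test_zero_variance_data_yields_no_flags():
    design = _design([0, 2, 12], 2)
    matrix = _matrix([[5.0] * 6, [6.0] * 6, [7.0] * 6], design)
    report = qc_deg.detect_outlier_samples(matrix, design)
    assert report.flagged_samples == []


def test_clean_replicates_not_flagged(default_dataset):
    matrix, design, _, _ = default_dataset
    report = qc_deg.detect_outlier_samples(matrix, design)
    assert report.flagged_samples == []


def test_variance_fractions_are_a_spectrum(default_dataset):
    matrix, design, _, _ = default_dataset
    report = qc_deg.detect_outlier_samples(matrix, design)
    fr = report.pc_variance_fractions
    assert np.all(fr >= 0) and np.all(fr <= 1)
    assert np.all(np.diff(fr) <= 1e-12)
    assert fr.sum() <= 1 + 1e-9


def test_too_few_samples_for_pca_rejected():
    design = _design([0], 2)
    matrix = _matrix([[5.0, 6.0]], design)
    with pytest.raises(ValueError):
        qc_deg.detect_outlier_samples(matrix, design, n_pcs=2)


def test_constant_gene_has_zero_fc_and_p_one():
    design = _design([0, 2, 12], 3)
    matrix = _matrix([[5.0] * 9], design)
    table = qc_deg.fit_timepoint_contrasts(matrix, design)
    assert np.allclose(table.log2fc.values, 0.0)
    assert np.allclose(table.p_value.values, 1.0)


def test_two_group_contrast_equals_textbook_pooled_t():
    """With exactly two groups the pooled-variance contrast is the classic
    equal-variance two-sample t test."""
    rng = np.random.default_rng(11)
    design = _design([0, 24], 3)
    for _ in range(50):
        values = rng.normal(7, 1, size=(1, 6))
        table = qc_deg.fit_timepoint_contrasts(_matrix(values, design), design)
        expected = pooled_t_pvalue(values[0, 3:], values[0, :3])
        assert table.p_value.iloc[0, 0] == pytest.approx(expected, abs=1e-12)


def test_replicate_label_swap_is_invariant(default_dataset):
    matrix, design, _, _ = default_dataset
    table = qc_deg.fit_timepoint_contrasts(matrix, design)
    # swap replicate labels within the 12 h group
    swapped = design.table.copy()
    at12 = swapped["time_h"] == 12.0
    swapped.loc[at12, "replicate"] = swapped.loc[at12, "replicate"].values[::-1]
    table2 = qc_deg.fit_timepoint_contrasts(matrix, SampleDesign(swapped))
    pd.testing.assert_frame_equal(table.log2fc, table2.log2fc)
    pd.testing.assert_frame_equal(table.p_value, table2.p_value)


def test_group_with_single_replicate_rejected():
    design = _design([0, 2], 2)
    trimmed = SampleDesign(design.table.iloc[:-1])
    matrix = _matrix([[5.0, 5.1, 5.2]], trimmed)
    with pytest.raises(ValueError, match="2"):
        qc_deg.fit_timepoint_contrasts(matrix, trimmed)


def _toy_table(fc, p):
    frame = lambda v: pd.DataFrame({2.0: [v]}, index=["g0"])  # noqa: E731
    return qc_deg.DegTable(log2fc=frame(fc), p_value=frame(p))


@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (2.0, 0.01, True),  # both thresholds inclusive
        (1.9, 1e-9, False),  # fold-change gate
        (5.0, 0.02, False),  # p gate
        (-2.0, 0.01, True),  # absolute fold change
    ],
)
def test_deg_gate_boundaries(fc, p, expected):
    called = qc_deg.call_degs(_toy_table(fc, p))
    assert bool(called.is_deg.iloc[0, 0]) is expected


def test_negative_thresholds_rejected():
    with pytest.raises(ValueError):
        qc_deg.call_degs(_toy_table(1.0, 0.5), fc_threshold=-1.0)


def test_direction_follows_sign():
    up = qc_deg.call_degs(_toy_table(3.0, 0.001))
    down = qc_deg.call_degs(_toy_table(-3.0, 0.001))
    assert up.direction.iloc[0, 0] == "accumulating"
    assert down.direction.iloc[0, 0] == "declining"


def test_summarize_counts_and_union(default_dataset):
    _, _, _, table = default_dataset
    summary = qc_deg.summarize_degs(table)
    # total = accumulating + declining at every time point
    assert (
        summary.table["total"]
        == summary.table["accumulating"] + summary.table["declining"]
    ).all()
    assert summary.union == int(table.deg_any.sum())
    assert summary.union >= summary.table["total"].max()


def test_summarize_single_gene_single_time():
    table = qc_deg.call_degs(
        qc_deg.DegTable(
            log2fc=pd.DataFrame({2.0: [3.0], 24.0: [0.1]}, index=["g0"]),
            p_value=pd.DataFrame({2.0: [0.001], 24.0: [0.9]}, index=["g0"]),
        )
    )
    summary = qc_deg.summarize_degs(table)
    assert summary.table.loc[2.0].tolist() == [1, 0, 1]
    assert summary.table.loc[24.0].tolist() == [0, 0, 0]
    assert summary.union == 1


def test_deg_table_round_trip(tmp_path, default_dataset):
    _, _, _, table = default_dataset
    qc_deg.write_deg_table(table, tmp_path / "deg.tsv")
    back = qc_deg.read_deg_table(tmp_path / "deg.tsv")
    assert back.deg_genes == table.deg_genes
    assert np.allclose(back.log2fc.values, table.log2fc.values, atol=1e-8)
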