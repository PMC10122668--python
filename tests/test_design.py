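import numpy as np
import pandas as pd
import pytest

import illusiongame as ig
from illusiongame import constants as C


def test_nonlinear_levels_worked_example():
    levels = ig.nonlinear_levels(0.1, 1.0, 4, "exponential")
    assert np.allclose(levels, [0.1, 0.34, 0.64, 1.0], atol=1e-12)


@pytest.mark.parametrize("kind", ["exponential", "square", "cubic"])
def test_nonlinear_levels_endpoints_and_monotonicity(kind):
    levels = ig.nonlinear_levels(0.2, 5.0, 16, kind)
    assert levels[0] == pytest.approx(0.2, abs=1e-12)
    assert levels[-1] == pytest.approx(5.0, abs=1e-12)
    assert np.all(np.diff(levels) > 0)
    assert levels.size == 16


def test_nonlinear_levels_rejects_bad_input():
    with pytest.raises(ValueError):
        ig.nonlinear_levels(1.0, 0.1, 4, "exponential")
    with pytest.raises(ValueError):
        ig.nonlinear_levels(0.1, 1.0, 1, "exponential")
    with pytest.raises(ValueError):
        ig.nonlinear_levels(0.1, 1.0, 4, "logarithmic")


def test_strength_levels_symmetric_with_exact_zero():
    levels = ig.strength_levels(30.0, 15)
    assert levels.size == 15
    assert levels[7] == 0.0
    assert np.allclose(levels, -levels[::-1], atol=1e-12)
    assert np.sum(levels > 0) == 7 and np.sum(levels < 0) == 7
    with pytest.raises(ValueError):
        ig.strength_levels(30.0, 14)
    with pytest.raises(ValueError):
        ig.strength_levels(-1.0, 15)


def test_stimulus_set_counts(config):
    for ill in config.illusions:
        rows = ig.build_stimulus_set(ill, config, seed=3)
        assert len(rows) == 134
        counts = rows["series"].value_counts()
        assert counts["A"] == 56 and counts["B"] == 72
        assert counts["practice"] == 6
        # no repeated (strength, difficulty) cell in the main series
        main = rows[rows.series != "practice"]
        assert not main.duplicated(["strength", "difficulty"]).any()
        assert rows["stimulus_id"].is_unique


def test_stimulus_set_grid_structure(config):
    rows = ig.build_stimulus_set("ponzo", config, seed=3)
    main = rows[rows.series != "practice"]
    assert main["difficulty"].nunique() == 16
    assert main["strength"].nunique() == 15
    a = rows[rows.series == "A"]
    b = rows[rows.series == "B"]
    # zero strength appears in both series but on disjoint difficulty levels
    assert (a.strength == 0).sum() == 8 and (b.strength == 0).sum() == 8
    assert not set(a.difficulty) & set(b.difficulty)
    # practice uses the 3 easiest (largest) difficulty levels
    practice = rows[rows.series == "practice"]
    assert set(practice.difficulty) == set(np.sort(main.difficulty.unique())[-3:])


def test_full_design_shape_and_order(config, manifest):
    assert len(manifest) == 1340
    assert list(manifest["trial_index"]) == list(range(1340))
    # practice first, then ten A blocks, then ten B blocks
    series_seq = manifest["series"].to_numpy()
    assert set(series_seq[:60]) == {"practice"}
    assert set(series_seq[60:620]) == {"A"}
    assert set(series_seq[620:]) == {"B"}
    # blocks are contiguous per illusion within each series
    for series, block_len in (("A", 56), ("B", 72)):
        sub = manifest[manifest.series == series]
        blocks = [sub.illusion.iloc[i:i + block_len].unique()
                  for i in range(0, len(sub), block_len)]
        assert all(len(b) == 1 for b in blocks)


def test_full_design_deterministic(config):
    d1 = ig.build_full_design(config, participant_seed=5)
    d2 = ig.build_full_design(config, participant_seed=5)
    d3 = ig.build_full_design(config, participant_seed=6)
    pd.testing.assert_frame_equal(d1, d2)
    assert not d1.equals(d3)
    # same stimuli, different order
    key = ["illusion", "series", "strength", "difficulty"]
    pd.testing.assert_frame_equal(
        d1[key].sort_values(key).reset_index(drop=True),
        d3[key].sort_values(key).reset_index(drop=True))


def test_manifest_csv_round_trip(tmp_path, manifest):
    path = tmp_path / "manifest.csv"
    ig.write_manifest(manifest, path)
    back = ig.read_manifest(path)
    assert list(back.columns) == list(manifest.columns)
    assert np.allclose(back["strength"], manifest["strength"], atol=1e-9)
    assert np.allclose(back["difficulty"], manifest["difficulty"], atol=1e-9)
    assert (back["target"] == manifest["target"]).all()


def test_read_manifest_rejects_malformed(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text('a,b\n1,2,3,4\n"unclosed\n')
    with pytest.raises(ValueError):
        ig.read_manifest(bad)


def test_design_config_yaml_round_trip(tmp_path, config):
    path = tmp_path / "design.yaml"
    config.to_yaml(path)
    back = ig.DesignConfig.from_yaml(path)
    assert back == config


def test_design_config_validation():
    with pytest.raises(ValueError):
        ig.DesignConfig(n_strength_levels=14)
    with pytest.raises(ValueError):
        ig.DesignConfig(series_sizes=(50, 78))


def test_rows_to_specs(manifest):
    specs = ig.rows_to_specs(manifest.head(70))
    assert len(specs) == 70
    assert all(isinstance(s, ig.StimulusSpec) for s in specs)
    assert specs[0].is_practice


def test_all_illusions_present(manifest):
    assert set(manifest["illusion"]) == set(C.ILLUSIONS)
    assert len(C.ILLUSIONS) == 10
    assert (manifest.groupby("illusion").size() == 134).all()
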