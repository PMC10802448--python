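"""Population sampling, rate filtering and dataset assembly."""

import numpy as np
import pytest
from scipy import stats

from ipsctwin.model_core import ConductanceSet, StimulusSpec
from ipsctwin.population import (
    Dataset,
    PopulationSpec,
    build_dataset,
    filter_spontaneous,
    physiological_condition,
    sample_population,
    spontaneous_rate,
)
from ipsctwin.protocols import Condition, Recording

from conftest import triangle_recording


class TestSamplePopulation:
    def test_zero_sigma_gives_exact_baseline(self):
        cells = sample_population(PopulationSpec(n=5, sigma=0.0, seed=1))
        for c in cells:
            assert np.array_equal(c.to_vector(), np.ones(16))

    def test_seed_reproducibility(self):
        a = sample_population(PopulationSpec(n=20, sigma=0.2, seed=42))
        b = sample_population(PopulationSpec(n=20, sigma=0.2, seed=42))
        for x, y in zip(a, b):
            assert np.array_equal(x.to_vector(), y.to_vector())

    def test_median_multiplier_near_one_large_sample(self):
        """Log-normal with median 1: Monte-Carlo check at n = 10,000."""
        cells = sample_population(PopulationSpec(n=10000, sigma=0.2, seed=3))
        mat = np.stack([c.to_vector() for c in cells])
        med = np.median(mat, axis=0)
        assert np.all(med > 0.98) and np.all(med < 1.02)

    def test_log_multipliers_pass_ks_against_normal(self):
        """Distributional correctness: KS test of ln(multiplier) against
        N(0, sigma) passes at alpha = 0.01 for n = 10,000."""
        cells = sample_population(PopulationSpec(n=10000, sigma=0.2, seed=9))
        draws = np.log(np.stack([c.to_vector() for c in cells])[:, 0])
        p = stats.kstest(draws, "norm", args=(0.0, 0.2)).pvalue
        assert p > 0.01

    @pytest.mark.parametrize("kw", [{"n": 0}, {"sigma": -0.1},
                                    {"rate_band_hz": (1.0, 0.3)}])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            PopulationSpec(**kw)


class TestSpontaneousRate:
    def test_square_pulse_train_rate(self):
        """A constructed 2 Hz train reads back exactly 2.0 Hz."""
        rec = triangle_recording(n_beats=10, period_ms=500.0, fall_ms=200.0)
        assert spontaneous_rate(rec) == pytest.approx(10 / rec.window_s,
                                                      abs=1e-9)
        assert spontaneous_rate(rec) == pytest.approx(2.0, abs=0.01)

    def test_flat_trace_is_zero(self):
        t = np.arange(0, 5000.1, 0.1)
        rec = Recording("flat", t, np.full_like(t, -70.0), np.zeros_like(t))
        assert spontaneous_rate(rec) == 0.0

    def test_baseline_cell_rate_in_automaticity_band(self, baseline_recording):
        rate = spontaneous_rate(baseline_recording)
        assert 0.3 <= rate <= 1.0


class TestFilterSpontaneous:
    def test_unbounded_band_is_identity(self):
        cells = sample_population(PopulationSpec(n=4, sigma=0.1, seed=5))
        kept, _, rejected = filter_spontaneous(
            cells, (0.0, np.inf), rates=[0.5, 0.9, 1.4, 0.1])
        assert kept == cells
        assert rejected == []

    def test_empty_input_gives_empty_output(self):
        kept, rates, rejected = filter_spontaneous([], (0.3, 1.0), rates=[])
        assert kept == [] and rejected == []

    def test_rejections_carry_reasons(self):
        cells = sample_population(PopulationSpec(n=3, sigma=0.1, seed=5))
        kept, _, rejected = filter_spontaneous(cells, (0.3, 1.0),
                                               rates=[0.5, 1.4, 0.2])
        assert len(kept) == 1
        assert len(rejected) == 2
        assert all("outside" in reason for _, reason in rejected)

    def test_baseline_cell_retained(self, baseline_cell, baseline_recording):
        rate = spontaneous_rate(baseline_recording)
        kept, _, _ = filter_spontaneous([baseline_cell], (0.3, 1.0),
                                        rates=[rate])
        assert kept == [baseline_cell]


@pytest.fixture(scope="module")
def tiny_dataset(baseline_cell, solver):
    catalog = [physiological_condition(8.0),
               Condition("paced", pacing=StimulusSpec.paced(1.0),
                         duration_s=8.0)]
    return build_dataset([baseline_cell], catalog, normalized=False,
                         solver=solver, seed=11)


class TestBuildDataset:
    def test_recording_shape_and_labels(self, tiny_dataset):
        assert len(tiny_dataset.cells) == 1
        recs = tiny_dataset.cells[0].recordings
        assert set(recs) == {"spont-physio", "paced"}
        assert all(r.n_samples == 50001 for r in recs.values())

    def test_normalized_variant_spans_unit_interval(self, baseline_cell,
                                                    solver):
        catalog = [physiological_condition(8.0)]
        ds = build_dataset([baseline_cell], catalog, normalized=True,
                           solver=solver)
        rec = ds.cells[0].recordings["spont-physio"]
        assert rec.normalized
        assert rec.vm.min() == pytest.approx(0.0)
        assert rec.vm.max() == pytest.approx(1.0)

    def test_save_load_round_trip(self, tiny_dataset, tmp_path):
        h5 = tmp_path / "ds.h5"
        tsv = tmp_path / "truth.tsv"
        tiny_dataset.save(h5, tsv)
        back = Dataset.load(h5)
        assert back.normalized == tiny_dataset.normalized
        orig = tiny_dataset.cells[0]
        got = back.cell(orig.cell_id)
        assert np.array_equal(got.truth.to_vector(), orig.truth.to_vector())
        for label in orig.recordings:
            assert np.array_equal(got.recordings[label].vm,
                                  orig.recordings[label].vm)
        import pandas as pd

        table = pd.read_csv(tsv, sep="\t")
        assert table.shape == (1, 17)

    def test_rebuild_is_deterministic(self, tiny_dataset, baseline_cell,
                                      solver):
        catalog = [physiological_condition(8.0),
                   Condition("paced", pacing=StimulusSpec.paced(1.0),
                             duration_s=8.0)]
        again = build_dataset([baseline_cell], catalog, normalized=False,
                              solver=solver, seed=11)
        for label, rec in tiny_dataset.cells[0].recordings.items():
            assert np.array_equal(again.cells[0].recordings[label].vm, rec.vm)

    def test_truth_never_equals_recordings_namespace(self, tiny_dataset):
        """Ground truth lives beside, not inside, the recordings: the
        calibration surface only ever sees Recording objects."""
        ds_targets = tiny_dataset.targets(["spont-physio"])
        for recs in ds_targets.values():
            assert all(isinstance(r, type(recs[0])) for r in recs)
            assert not any(hasattr(r, "truth") for r in recs)
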