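import numpy as np
import pytest

from seadose import (
    LocationTruth,
    ScenarioConfig,
    ValidationError,
    generate_activity_dataset,
    generate_metal_dataset,
    generate_peak_table,
    quantify_sample,
)
from seadose.io import frame_from_records


class TestActivityDataset:
    def test_seeded_determinism(self):
        a = frame_from_records(generate_activity_dataset(ScenarioConfig(seed=42)))
        b = frame_from_records(generate_activity_dataset(ScenarioConfig(seed=42)))
        assert a.to_csv() == b.to_csv()
        c = frame_from_records(generate_activity_dataset(ScenarioConfig(seed=43)))
        assert a.to_csv() != c.to_csv()

    def test_zero_dispersion_returns_truth(self):
        config = ScenarioConfig(seed=1, replicate_dispersion=0.0)
        records = generate_activity_dataset(config)
        truths = {loc.name: loc for loc in config.locations}
        for rec in records:
            truth = truths[rec.location]
            table = truth.fish_bq_per_kg if rec.matrix == "fish" else truth.water_bq_per_kg
            for chain, meas in rec.activities.items():
                assert meas.value == table[chain]

    def test_cardinality(self):
        records = generate_activity_dataset(ScenarioConfig(seed=0))
        assert len(records) == 18  # 3 locations x 3 replicates x (fish + water)
        assert sum(r.matrix == "fish" for r in records) == 9

    def test_uncertainty_budget_range(self):
        # combined relative uncertainties span the quadrature budget range
        records = generate_activity_dataset(ScenarioConfig(seed=2))
        rels = [
            m.uncertainty / m.value
            for r in records
            for m in r.activities.values()
            if m.value > 0
        ]
        assert min(rels) >= 0.0435
        assert max(rels) <= 0.1095

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(replicate_dispersion=-0.1)


class TestPeakTable:
    def test_cardinality_one_row_per_primary_line(self):
        peaks = generate_peak_table(ScenarioConfig(seed=0))
        assert len(peaks) == 9 * 6  # 9 fish samples x 6 primary lines

    def test_null_source_leaves_only_background(self):
        silent = LocationTruth(
            "Nowhere", "Nw",
            {"Ra-226": 0.0, "Th-232": 0.0, "K-40": 0.0},
            {"Ra-226": 0.0, "Th-232": 0.0, "K-40": 0.0},
        )
        config = ScenarioConfig(seed=5, locations=(silent,), replicates_per_location=2)
        peaks = generate_peak_table(config)
        bg = config.detector.background_counts
        for p in peaks:
            # net counts are a difference of two Poisson(bg) draws, floored at 0
            assert p.net_counts < 6 * np.sqrt(bg)
            assert p.background_counts > bg - 6 * np.sqrt(bg)

    def test_poisson_concentration_at_high_counts(self):
        # expected counts ~1e6 -> observed within 1% of expectation in >=99% of draws
        rng = np.random.default_rng(123)
        expected = 1e6
        draws = rng.poisson(expected, size=2000)
        frac = np.mean(np.abs(draws - expected) / expected < 0.01)
        assert frac >= 0.99

    def test_truth_is_recoverable(self):
        config = ScenarioConfig(seed=9, replicate_dispersion=0.0)
        peaks, truth = generate_peak_table(config, return_truth=True)
        curve = config.detector.efficiency_curve()
        by_code = {}
        for p in peaks:
            by_code.setdefault(p.sample_code, []).append(p)
        for code, sample_peaks in by_code.items():
            acts = quantify_sample(sample_peaks, curve)
            for chain, meas in acts.items():
                assert abs(meas.value - truth[code][chain]) <= 4 * meas.uncertainty


class TestMetalDataset:
    def test_detect_probability_one_gives_no_nondetects(self):
        config = ScenarioConfig(seed=3)
        profiles = {
            el: type(p)(p.mean_mg_per_kg, p.rel_sd, 1.0)
            for el, p in config.metal_profiles.items()
        }
        config = ScenarioConfig(seed=3, metal_profiles=profiles)
        assert all(r.detected for r in generate_metal_dataset(config))

    def test_fully_censored_element_propagates(self, bundle):
        from seadose import MetalProfile, edi_table

        config = ScenarioConfig(
            seed=4,
            metal_profiles={
                "Pb": MetalProfile(0.02, 0.3, 0.0),
                "As": MetalProfile(0.5, 0.2, 1.0),
            },
        )
        records = generate_metal_dataset(config)
        frame = edi_table(records, bundle.params, bundle.tdi_by_element)
        assert "Pb" not in set(frame["element"])

    def test_seeded_determinism(self):
        a = generate_metal_dataset(ScenarioConfig(seed=7))
        b = generate_metal_dataset(ScenarioConfig(seed=7))
        assert a == b


class TestParameterRecovery:
    def test_location_means_recover_truth_within_three_standard_errors(self):
        # default dispersion (10%), 3 replicates: the location-mean activity
        # lies within 3 SE of truth in >= 95% of seeded scenarios.  The SE
        # uses the known generative dispersion (sigma/sqrt(n)); estimating
        # it from 3 replicates would give t_2-distributed deviations whose
        # 3-SE coverage is only ~90%.
        n_scenarios = 500
        hits = total = 0
        for seed in range(n_scenarios):
            config = ScenarioConfig(seed=seed)
            records = generate_activity_dataset(config)
            truths = {loc.name: loc.fish_bq_per_kg for loc in config.locations}
            by_loc: dict[tuple[str, str], list[float]] = {}
            for rec in records:
                if rec.matrix != "fish":
                    continue
                for chain, meas in rec.activities.items():
                    by_loc.setdefault((rec.location, chain), []).append(meas.value)
            for (loc, chain), values in by_loc.items():
                truth = truths[loc][chain]
                se = config.replicate_dispersion * truth / np.sqrt(len(values))
                if se == 0:
                    continue
                total += 1
                if abs(np.mean(values) - truth) <= 3 * se:
                    hits += 1
        assert hits / total >= 0.95
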