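"""QC cascade: percent difference, ion assignment, consensus, trendline, build."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtims import chem
from dtims.curation import (
    CurationConfig,
    build_library,
    fit_ccs_mz_trendline,
    filter_trendline,
    pct_diff,
    replicate_consensus,
)
from dtims.library_io import write_library, read_library
from dtims.calibration import SingleFieldCalibration
from dtims.synthetic import SimulationConfig, simulate_campaign


class TestPctDiff:
    def test_identity(self):
        assert pct_diff(150.0, 150.0) == 0.0

    def test_hand_arithmetic(self):
        assert pct_diff(150.0, 152.0) == pytest.approx(100 * 2 / 151, rel=1e-12)
        assert pct_diff(150.0, 152.0) == pytest.approx(1.3245, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pct_diff(0.0, 1.0)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_nonnegative(self, a, b):
        assert pct_diff(a, b) == pct_diff(b, a) >= 0.0


def make_observation(chemical_id, formula, ion_type, mode, ppm_offset=0.0,
                     ratio_scale=1.0, ccs=150.0, replicate=1, abund_m=1e5):
    f = chem.parse_formula(formula)
    mz = chem.ion_mz(f, ion_type) * (1 + ppm_offset * 1e-6)
    ratio = chem.predicted_m1_ratio(f) * ratio_scale
    return {
        "run_id": f"{mode}_rep{replicate}", "chemical_id": chemical_id,
        "mode": mode, "ion_type": ion_type, "mz": mz, "arrival_time_ms": np.nan,
        "ccs_A2": ccs, "abund_M": abund_m, "abund_M1": abund_m * ratio,
        "replicate": replicate,
    }


INVENTORY = pd.DataFrame({
    "chemical_id": ["CHEM1", "CHEM2", "CHEM3"],
    "name": ["one", "two", "three"],
    "formula": ["C10H7N3S", "C20H30O5", "C8H14ClN5"],
    "class": ["Pesticide"] * 3,
})


class TestAssignExpectedIons:
    def test_exact_observation_retained_with_annotations(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+")])
        kept, rejected = assign_expected_ions(obs, INVENTORY)
        assert len(kept) == 1 and len(rejected) == 0
        assert abs(kept["mass_error_ppm"].iloc[0]) < 1e-6
        assert kept["isotope_ratio"].iloc[0] == pytest.approx(
            chem.predicted_m1_ratio(chem.parse_formula("C10H7N3S")), rel=1e-9
        )

    def test_twelve_ppm_offset_rejected_as_mass_error(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([
            make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+", ppm_offset=12.0)
        ])
        kept, rejected = assign_expected_ions(obs, INVENTORY)
        assert len(kept) == 0
        assert rejected["reason"].tolist() == ["mass_error"]

    def test_wrong_isotope_ratio_rejected(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([
            make_observation("CHEM2", "C20H30O5", "[M+H]+", "ESI+", ratio_scale=3.0)
        ])
        kept, rejected = assign_expected_ions(obs, INVENTORY)
        assert rejected["reason"].tolist() == ["isotope"]

    def test_zero_base_abundance_rejected_not_raised(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([
            make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+", abund_m=0.0)
        ])
        kept, rejected = assign_expected_ions(obs, INVENTORY)
        assert rejected["reason"].tolist() == ["isotope"]

    def test_unknown_chemical_rejected_as_missing_formula(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([make_observation("GHOST", "C10H7N3S", "[M+H]+", "ESI+")])
        kept, rejected = assign_expected_ions(obs, INVENTORY)
        assert rejected["reason"].tolist() == ["missing_formula"]

    def test_ppm_gate_strict_versus_inclusive_at_boundary(self):
        from dtims.curation import assign_expected_ions

        obs = pd.DataFrame([
            make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+", ppm_offset=8.0)
        ])
        theo = chem.ion_mz(chem.parse_formula("C10H7N3S"), "[M+H]+")
        err = abs(chem.ppm_error(float(obs["mz"].iloc[0]), theo))
        # gate set exactly at the observed error: strict < rejects, <= keeps
        kept_strict, rej_strict = assign_expected_ions(
            obs, INVENTORY, CurationConfig(ppm_max=err)
        )
        kept_incl, _ = assign_expected_ions(
            obs, INVENTORY, CurationConfig(ppm_max=err, ppm_inclusive=True)
        )
        assert len(kept_strict) == 0 and rej_strict["reason"].tolist() == ["mass_error"]
        assert len(kept_incl) == 1


def consensus_group(ccs_values):
    rows = [
        make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+", ccs=c, replicate=i + 1)
        for i, c in enumerate(ccs_values)
    ]
    df = pd.DataFrame(rows)
    df["mz_theoretical"] = chem.ion_mz(chem.parse_formula("C10H7N3S"), "[M+H]+")
    df["mass_error_ppm"] = 0.0
    return df


class TestReplicateConsensus:
    def test_identical_duplicates_pass(self):
        entry, rejected = replicate_consensus(consensus_group([150.0, 150.0]))
        assert entry is not None
        assert entry["ccs_mean_A2"] == 150.0
        assert entry["replicate_pct_diff"] == 0.0
        assert entry["n_replicates"] == 2
        assert len(rejected) == 0

    def test_divergent_duplicates_rejected(self):
        entry, rejected = replicate_consensus(consensus_group([150.0, 152.0]))
        assert entry is None
        assert rejected["reason"].unique().tolist() == ["replicate"]

    def test_single_replicate_insufficient(self):
        entry, rejected = replicate_consensus(consensus_group([150.0]))
        assert entry is None
        assert rejected["reason"].tolist() == ["insufficient_replicates"]

    def test_outlier_replicate_excluded_from_consensus(self):
        entry, rejected = replicate_consensus(consensus_group([150.0, 150.3, 160.0]))
        assert entry is not None
        assert entry["n_replicates"] == 2
        assert entry["ccs_mean_A2"] == pytest.approx(150.15)
        assert rejected["reason"].tolist() == ["replicate"]

    def test_boundary_one_percent_is_inclusive(self):
        a = 150.0
        # choose b so that 200|a-b|/(a+b) == 1 exactly: b = a*201/199
        b = a * 201 / 199
        entry, _ = replicate_consensus(consensus_group([a, b]))
        assert entry is not None
        assert entry["replicate_pct_diff"] == pytest.approx(1.0, rel=1e-12)


class TestTrendline:
    def test_exact_power_law_recovery(self, rng):
        mz = rng.uniform(100, 800, 40)
        entries = pd.DataFrame({
            "mz_measured_mean": mz, "ccs_mean_A2": 10.0 * mz**0.5,
        })
        trend = fit_ccs_mz_trendline(entries)
        assert trend.a == pytest.approx(10.0, rel=1e-9)
        assert trend.b == pytest.approx(0.5, rel=1e-9)

    def test_outlier_barely_moves_robust_fit(self, rng):
        mz = rng.uniform(100, 800, 60)
        ccs = 10.0 * mz**0.5 * np.exp(rng.normal(0, 0.01, 60))
        clean = fit_ccs_mz_trendline(
            pd.DataFrame({"mz_measured_mean": mz, "ccs_mean_A2": ccs})
        )
        mz2 = np.append(mz, 400.0)
        ccs2 = np.append(ccs, 2 * 10.0 * 400**0.5)  # +100% outlier
        dirty = fit_ccs_mz_trendline(
            pd.DataFrame({"mz_measured_mean": mz2, "ccs_mean_A2": ccs2})
        )
        assert abs(dirty.b - clean.b) < 0.01

    def test_degenerate_single_mz_rejected(self):
        entries = pd.DataFrame({
            "mz_measured_mean": [300.0] * 6, "ccs_mean_A2": [150, 151, 152, 153, 154, 155],
        })
        with pytest.raises(ValueError):
            fit_ccs_mz_trendline(entries)

    def test_too_few_entries_rejected(self):
        entries = pd.DataFrame({
            "mz_measured_mean": [100.0, 200, 300, 400], "ccs_mean_A2": [100.0, 140, 170, 200],
        })
        with pytest.raises(ValueError):
            fit_ccs_mz_trendline(entries)

    def test_filter_retains_on_trend_and_boundary(self):
        from dtims.curation import TrendlineFit

        # trend predicts exactly 200 A^2 at m/z 400 (10 * sqrt(400))
        trend = TrendlineFit(a=10.0, b=0.5, form="power", n_used=30, resid_mad=0.0)
        entries = pd.DataFrame({
            "mz_measured_mean": [400.0, 400.0, 400.0],
            "ccs_mean_A2": [200.0, 230.0, 280.0],  # 0%, exactly 15.0%, 40%
            "_obs_index": [[0], [1], [2]],
        })
        kept, removed = filter_trendline(entries, trend)
        assert kept["ccs_mean_A2"].tolist() == [200.0, 230.0]  # 15.0% inclusive
        assert kept["trend_pct_dev"].tolist() == [0.0, 15.0]
        assert removed["reason"].tolist() == ["trendline"]
        assert removed["trend_pct_dev"].iloc[0] == pytest.approx(40.0, rel=1e-12)


class TestBuildLibrary:
    def test_noise_free_campaign_recovered_losslessly(self, noiseless_campaign):
        data = noiseless_campaign
        fit = SingleFieldCalibration(data["calibrant_arrivals"], data["calibrants"]).fit()
        lib, log = build_library(data["features"], data["inventory"], fit=fit)
        assert len(log) == 0
        # every (chemical, ion, mode) emitted appears exactly once in the library
        expected_keys = set(
            map(tuple, data["features"][["chemical_id", "ion_type", "mode"]]
                .drop_duplicates().itertuples(index=False))
        )
        got_keys = set(
            map(tuple, lib.entries[["chemical_id", "ion_type", "mode"]]
                .itertuples(index=False))
        )
        assert got_keys == expected_keys
        # recovered CCS matches the generator's truth
        ions = data["truth"].ions.set_index(["chemical_id", "ion_type"])
        for row in lib.entries.itertuples():
            true_ccs = ions.loc[(row.chemical_id, row.ion_type)]["ccs_true"]
            assert row.ccs_mean_A2 == pytest.approx(true_ccs, rel=1e-9)

    def test_conservation_of_observations(self, campaign100, calibration_fit):
        data = campaign100
        lib, log = build_library(data["features"], data["inventory"], fit=calibration_fit)
        contributing = sum(len(ix) for ix in lib._obs_index)
        assert contributing + len(log) == len(data["features"])
        assert contributing == lib.entries["n_replicates"].sum()

    def test_all_gates_hold_post_hoc(self, campaign100, calibration_fit):
        cfg = CurationConfig()
        lib, _ = build_library(
            campaign100["features"], campaign100["inventory"],
            fit=calibration_fit, config=cfg,
        )
        e = lib.entries
        assert (e["mass_error_ppm"].abs() < cfg.ppm_max).all()
        assert (e["replicate_pct_diff"] <= cfg.replicate_pct_max).all()
        dev = e["trend_pct_dev"].dropna()
        assert (dev <= cfg.trend_pct_max).all()
        assert (e["n_replicates"] >= cfg.min_replicates).all()

    def test_multimer_artifacts_rejected_by_trendline(self):
        # noise-free except CCS scatter, so the trendline gate acts alone:
        # every dimer-scale artifact (+25-60% CCS) must fall outside the 15%
        # band and be logged with reason 'trendline'
        cfg = SimulationConfig(
            n_chemicals=300, seed=31, multimer_rate=0.08, degraded_rate=0.0,
            ccs_scatter_sigma=0.03, drift_noise_sigma_ms=0.0,
            mz_noise_sigma_ppm=0.0, isotope_noise_rel=0.0,
        )
        data = simulate_campaign(cfg)
        fit = SingleFieldCalibration(data["calibrant_arrivals"], data["calibrants"]).fit()
        lib, log = build_library(data["features"], data["inventory"], fit=fit)
        mult = set(
            data["truth"].chemicals.loc[data["truth"].chemicals.multimer, "chemical_id"]
        )
        emitted_mult = mult & set(data["features"]["chemical_id"])
        assert emitted_mult, "fixture must contain emitted multimer artifacts"
        assert not lib.entries["chemical_id"].isin(mult).any()
        rej_mult = log.loc[log["chemical_id"].isin(mult)]
        assert len(rej_mult) == int(data["features"]["chemical_id"].isin(mult).sum())
        assert (rej_mult["reason"] == "trendline").all()

    def test_single_measurement_chemical_goes_to_rejection_log(self):
        obs = pd.DataFrame([make_observation("CHEM1", "C10H7N3S", "[M+H]+", "ESI+")])
        lib, log = build_library(obs, INVENTORY, fit=None)
        assert len(lib) == 0
        assert log["reason"].tolist() == ["insufficient_replicates"]

    def test_recuration_of_expanded_library_is_idempotent(self, noiseless_campaign):
        data = noiseless_campaign
        fit = SingleFieldCalibration(data["calibrant_arrivals"], data["calibrants"]).fit()
        lib, _ = build_library(data["features"], data["inventory"], fit=fit)
        # re-expand each entry into n identical synthetic observations
        rows = []
        for r in lib.entries.itertuples():
            f = chem.parse_formula(r.formula)
            ratio = chem.predicted_m1_ratio(f)
            for rep in range(1, 3):
                rows.append({
                    "run_id": f"{r.mode}_rep{rep}", "chemical_id": r.chemical_id,
                    "mode": r.mode, "ion_type": r.ion_type,
                    "mz": r.mz_measured_mean, "arrival_time_ms": np.nan,
                    "ccs_A2": r.ccs_mean_A2, "abund_M": 1e5,
                    "abund_M1": 1e5 * ratio, "replicate": rep,
                })
        lib2, log2 = build_library(pd.DataFrame(rows), data["inventory"], fit=None)
        assert len(log2) == 0
        merged = lib.entries.merge(
            lib2.entries, on=["chemical_id", "ion_type", "mode"], suffixes=("_1", "_2")
        )
        assert len(merged) == len(lib.entries) == len(lib2.entries)
        assert np.allclose(merged["ccs_mean_A2_1"], merged["ccs_mean_A2_2"], rtol=1e-12)

    @pytest.mark.parametrize("param, loose, tight", [
        ("ppm_max", 10.0, 3.0),
        ("replicate_pct_max", 1.0, 0.3),
        ("trend_pct_max", 15.0, 5.0),
    ])
    def test_tightening_thresholds_never_gains_entries(
        self, campaign100, calibration_fit, param, loose, tight
    ):
        data = campaign100
        n = {}
        for value in (loose, tight):
            cfg = CurationConfig(**{param: value})
            lib, _ = build_library(
                data["features"], data["inventory"], fit=calibration_fit, config=cfg
            )
            n[value] = len(lib)
        assert n[tight] <= n[loose]
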