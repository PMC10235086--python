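"""Generator invariants: determinism, class fidelity, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from cenrna.classify import classify_frame
from cenrna.profiles import start_site_count
from cenrna.simulate import (
    SimulationConfig,
    SimulationError,
    simulate_experiment,
    simulate_fragments,
    simulate_genome,
)

# generated block tag -> expected class after re-classification
TAG_TO_CLASS = {
    "cen": "CEN",
    "pnc": "PERICEN_NONCODING",
    "pc": "PERICEN_CODING",
    "bg": "OTHER",
}


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    def test_term_composition_sums_to_one(self):
        cfg = SimulationConfig()
        for cond in ("mock", "auxin"):
            comp = cfg.term_composition(cond)
            assert sum(comp.values()) == pytest.approx(1.0)
        assert cfg.term_composition("mock")["FULL_CEN"] == 0.48
        assert cfg.term_composition("auxin")["FULL_CEN"] == 0.32

    def test_auxin_deficit_moves_to_cdei(self):
        cfg = SimulationConfig()
        mock, auxin = cfg.term_composition("mock"), cfg.term_composition("auxin")
        assert auxin["CDEI"] == pytest.approx(mock["CDEI"] + 0.16)
        assert auxin["CDEII"] == pytest.approx(mock["CDEII"])
        assert auxin["CDEIII"] == pytest.approx(mock["CDEIII"])

    def test_condition_totals_follow_multipliers(self):
        cfg = SimulationConfig()
        m, a = cfg.condition_totals("mock"), cfg.condition_totals("auxin")
        assert m["short_cen"] == m["long_cen"] == 210          # 1:1 mixture
        assert a["long_cen"] == m["long_cen"]                  # long unaffected
        assert a["short_cen"] + a["long_cen"] == round(
            (m["short_cen"] + m["long_cen"]) * cfg.auxin_cen_multiplier
        )
        assert a["noncoding"] == round(m["noncoding"] * cfg.auxin_noncoding_multiplier)
        assert a["coding"] == m["coding"]                      # coding unaffected
        # depletion raises only the short class: short-to-long ratio ~3:1
        assert 3.0 <= a["short_cen"] / a["long_cen"] <= 4.0

    @pytest.mark.parametrize(
        "override",
        [
            {"pericen_init_prob": 1.5},
            {"term_cde_weights": (-1.0, 0.5, 0.5)},
            {"short_cen_median": 0},
            {"replicates": 0},
            {"chromosome_length": 5_000},
            {"length_threshold": 100},
            {"term_full_auxin": 0.99},  # would need a negative CDEI share
        ],
    )
    def test_infeasible_configs_rejected(self, override):
        cfg = SimulationConfig(**override)
        with pytest.raises(SimulationError):
            cfg.validate()
            cfg.term_composition("auxin")

    def test_yaml_roundtrip(self, tmp_path, small_config):
        p = tmp_path / "config.yaml"
        small_config.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == small_config

    def test_unknown_key_rejected(self):
        with pytest.raises(SimulationError, match="unknown config key"):
            SimulationConfig.from_dict({"typo_key": 1})


class TestGenome:
    def test_one_core_per_chromosome_within_width_band(self):
        model = simulate_genome(SimulationConfig())
        assert len(model.cores) == 16
        assert all(115 <= c.width <= 119 for c in model.cores.values())

    def test_configured_orf_count_intersects_windows(self):
        model = simulate_genome(SimulationConfig())
        assert len(model.pericen_orfs()) == 22

    def test_no_orf_within_200bp_of_any_core(self):
        model = simulate_genome(SimulationConfig())
        for orf in model.orfs:
            core = model.cores[orf.chrom]
            assert orf.end <= core.start - 200 or orf.start >= core.end + 200

    def test_same_seed_identical_genome(self):
        cfg = SimulationConfig(seed=5)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_different_seeds_differ(self):
        assert simulate_genome(SimulationConfig(seed=1)) != simulate_genome(
            SimulationConfig(seed=2)
        )


class TestFragments:
    def test_every_fragment_lands_in_intended_class(self, small_config):
        model = simulate_genome(small_config)
        for cond in ("mock", "auxin"):
            frame, _ = simulate_fragments(small_config, model, cond, 0)
            cl = classify_frame(frame, model,
                                length_threshold=small_config.length_threshold)
            expected = cl["name"].map(TAG_TO_CLASS)
            assert (cl["tclass"] == expected).all()

    def test_sheet_row_counts_library(self, small_config):
        model = simulate_genome(small_config)
        frame, row = simulate_fragments(small_config, model, "mock", 0)
        assert row["total_fragments"] == len(frame)
        assert row["sample"] == "mock1" and row["condition"] == "mock"

    def test_determinism_and_replicate_independence(self, small_config):
        model = simulate_genome(small_config)
        f1, _ = simulate_fragments(small_config, model, "mock", 0)
        f2, _ = simulate_fragments(small_config, model, "mock", 0)
        pd.testing.assert_frame_equal(f1, f2)
        f3, _ = simulate_fragments(small_config, model, "mock", 1)
        assert not f1.drop(columns="sample").equals(f3.drop(columns="sample"))

    def test_replicate_split_conserves_condition_totals(self, small_config):
        model = simulate_genome(small_config)
        totals = small_config.condition_totals("mock")
        n_cen = n_pnc = 0
        for rep in range(small_config.replicates):
            frame, _ = simulate_fragments(small_config, model, "mock", rep)
            n_cen += (frame["name"] == "cen").sum()
            n_pnc += (frame["name"] == "pnc").sum()
        assert n_cen == totals["short_cen"] + totals["long_cen"]
        assert n_pnc == totals["noncoding"]

    def test_zero_cen_total_yields_no_cen_fragments(self):
        cfg = SimulationConfig(cen_total=0, scale=1, noncoding_pericen_total=50,
                               coding_pericen_multiplier=1.0, background_fragments=50)
        model = simulate_genome(cfg)
        frame, _ = simulate_fragments(cfg, model, "mock", 0)
        cl = classify_frame(frame, model)
        assert (cl["tclass"] != "CEN").all()

    def test_initiation_fraction_recovered(self):
        cfg = SimulationConfig(cen_total=5000, scale=1, noncoding_pericen_total=10,
                               coding_pericen_multiplier=0.0, background_fragments=10,
                               replicates=1)
        model = simulate_genome(cfg)
        frame, _ = simulate_fragments(cfg, model, "mock", 0)
        cl = classify_frame(frame, model)
        init = cl.loc[cl["tclass"] == "CEN", "initiated_in_pericen"].mean()
        assert abs(init - 0.79) < 0.03

    def test_plus_strand_bias_on_dominant_chromosomes(self):
        cfg = SimulationConfig(cen_total=5000, scale=1, noncoding_pericen_total=10,
                               coding_pericen_multiplier=0.0, background_fragments=10,
                               replicates=1)
        model = simulate_genome(cfg)
        frame, _ = simulate_fragments(cfg, model, "mock", 0)
        cen = frame[frame["name"] == "cen"]
        dominant = set(list(model.chromosomes)[: cfg.plus_dominant_chromosomes])
        plus_frac = cen.groupby(cen["chrom"].isin(dominant))["strand"].apply(
            lambda s: (s == "+").mean()
        )
        assert plus_frac[True] > 0.6
        assert plus_frac[False] < 0.4

    def test_depletion_adds_distinct_start_sites(self):
        """More distinct cen 5' positions after depletion in >=95/100 runs."""
        wins = 0
        for seed in range(1, 101):
            cfg = SimulationConfig(
                seed=seed, cen_total=42, scale=1, noncoding_pericen_total=0,
                coding_pericen_multiplier=0.0, background_fragments=0, replicates=1,
            )
            model = simulate_genome(cfg)
            distinct = {}
            for cond in ("mock", "auxin"):
                frame, _ = simulate_fragments(cfg, model, cond, 0)
                cl = classify_frame(frame, model)
                total = 0
                for chrom in model.cores:
                    win = model.windows[chrom]
                    d, _t = start_site_count(cl, (chrom, win.span[0], win.span[1]))
                    total += d
                distinct[cond] = total
            if distinct["auxin"] > distinct["mock"]:
                wins += 1
        assert wins >= 95


class TestExperiment:
    def test_end_to_end_dataset_layout(self, tmp_path, small_config):
        out = simulate_experiment(small_config, tmp_path / "exp")
        assert len(out["fragment_paths"]) == 6
        sheet = out["sheet"]
        assert sheet.conditions == ["mock", "auxin"]
        for p in out["fragment_paths"].values():
            assert p.exists() and p.stat().st_size > 0
        counts = pd.read_csv(out["reference_counts_path"], sep="\t")
        assert set(counts["id"]) == {"DOA1", "KAP104", "POL1", "PDR5"}

    def test_same_seed_identical_bed_bytes(self, tmp_path, small_config):
        a = simulate_experiment(small_config, tmp_path / "a")
        b = simulate_experiment(small_config, tmp_path / "b")
        for sample in a["fragment_paths"]:
            assert (
                a["fragment_paths"][sample].read_bytes()
                == b["fragment_paths"][sample].read_bytes()
            )

    def test_existing_outdir_requires_overwrite(self, tmp_path, small_config):
        simulate_experiment(small_config, tmp_path / "exp")
        with pytest.raises(SimulationError, match="overwrite"):
            simulate_experiment(small_config, tmp_path / "exp")
        simulate_experiment(small_config, tmp_path / "exp", overwrite=True)
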