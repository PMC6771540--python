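"""Synthetic-data generators: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from droughtcross.expression import (
    aggregate_transcripts_to_genes, log2_transform, read_sample_metadata,
    read_tpm_table, write_tpm_table,
)
from droughtcross.orthology import parse_blast_tab
from droughtcross.phenotype import first_growth_reduction_day, stockiness
from droughtcross.simulate import (
    GroundTruth, GrowthSpec, ModuleSpec, OrthologySpec, ResponseClassSpec,
    SimulationConfig, gene_id, simulate_expression, simulate_growth,
    simulate_orthology, write_blast_tab,
)
from droughtcross.timing import log2_fold_change


def small_cfg(**kw):
    defaults = dict(seed=42, n_genes=300, species=("Ath", "Aly", "Esa"),
                    modules=[ModuleSpec(40, 0.9, "treatment_wd")],
                    responses=[ResponseClassSpec("Ath_specific", 30, {
                        "Ath": {"T5": 0.0, "T11": 2.0, "T14": 1.5},
                        "Aly": {"T5": 0.0, "T11": 0.0, "T14": 0.0},
                        "Esa": {"T5": 0.0, "T11": 0.0, "T14": 0.0},
                    })])
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateExpression:
    def test_same_seed_identical(self):
        a, _, _ = simulate_expression(small_cfg())
        b, _, _ = simulate_expression(small_cfg())
        for sp in a:
            pd.testing.assert_frame_equal(a[sp].values, b[sp].values)

    def test_different_seed_differs(self):
        a, _, _ = simulate_expression(small_cfg(seed=1))
        b, _, _ = simulate_expression(small_cfg(seed=2))
        va, vb = a["Ath"].values.to_numpy(), b["Ath"].values.to_numpy()
        # transcript counts are themselves random, so shapes may differ
        assert va.shape != vb.shape or not np.allclose(va, vb)

    def test_design_layout(self):
        mats, maps, _ = simulate_expression(small_cfg())
        assert set(mats) == {"Ath", "Aly", "Esa"}
        m = mats["Ath"]
        assert m.n_samples == 24  # 2 conditions x 4 timepoints x 3 replicates
        assert set(m.samples["condition"]) == {"WW", "WD"}
        assert set(m.samples["timepoint"]) == {"T0", "T5", "T11", "T14"}

    def test_perfect_within_correlation(self):
        cfg = small_cfg(modules=[ModuleSpec(10, 1.0, None)], responses=[],
                        noise_sigma=0.0, max_transcripts_per_gene=1)
        mats, maps, truth = simulate_expression(cfg)
        genes = [gene_id("Ath", f) for f, lab in truth.module_assignments.items()]
        x = mats["Ath"].values.loc[[g + ".1" for g in genes]].to_numpy()
        r = np.corrcoef(np.log2(x + 1e-12))
        assert r.min() > 0.999999

    def test_transcript_split_conserves_gene_tpm(self):
        cfg = small_cfg(max_transcripts_per_gene=4)
        mats, maps, _ = simulate_expression(cfg)
        m = mats["Aly"]
        agg = aggregate_transcripts_to_genes(m, maps["Aly"])
        assert agg.n_features == cfg.n_genes
        assert (agg.values.to_numpy() >= 0).all()

    def test_planted_fold_change_exact_with_zero_noise(self):
        lfc = 2.0
        cfg = small_cfg(noise_sigma=0.0, modules=[],
                        responses=[ResponseClassSpec("solo", 20, {
                            "Ath": {"T5": 0.0, "T11": lfc, "T14": 0.0},
                            "Aly": {"T5": 0.0, "T11": 0.0, "T14": 0.0},
                            "Esa": {"T5": 0.0, "T11": 0.0, "T14": 0.0},
                        })],
                        max_transcripts_per_gene=1)
        mats, maps, truth = simulate_expression(cfg)
        genes = aggregate_transcripts_to_genes(mats["Ath"], maps["Ath"])
        fc = log2_fold_change(genes)
        fc11 = fc[fc["timepoint"] == "T11"].set_index("gene_id")["log2fc"]
        for f in truth.response_class:
            assert fc11[gene_id("Ath", f)] == pytest.approx(lfc, abs=1e-9)

    def test_emitted_files_round_trip(self, tmp_path):
        mats, maps, _ = simulate_expression(small_cfg())
        m = mats["Esa"]
        write_tpm_table(m, tmp_path / "tpm.tsv")
        m.samples.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        meta = read_sample_metadata(tmp_path / "meta.tsv")
        back = read_tpm_table(tmp_path / "tpm.tsv", meta)
        np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy())

    def test_overplanted_config_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_expression(small_cfg(n_genes=50))


class TestSimulateOrthology:
    def test_deterministic(self, tmp_path):
        cfg = small_cfg()
        h1, t1 = simulate_orthology(cfg)
        h2, t2 = simulate_orthology(cfg)
        assert t1 == t2
        assert h1[("Ath", "Aly")] == h2[("Ath", "Aly")]

    def test_missing_rate_one_empties_table(self):
        cfg = small_cfg(orthology=OrthologySpec(1.0, 0.0, 1.0))
        _, triples = simulate_orthology(cfg)
        assert triples == []

    def test_decoys_score_below_true_hits(self):
        cfg = small_cfg(orthology=OrthologySpec(1.0, 0.5, 0.0))
        hits, _ = simulate_orthology(cfg)
        ab = hits[("Ath", "Aly")]
        best = {}
        for h in ab:
            best.setdefault(h.query_id, []).append(h)
        for q, hs in best.items():
            if len(hs) > 1:
                top = max(hs, key=lambda h: h.bitscore)
                fam = int(q.split("G")[1])
                assert top.subject_id == gene_id("Aly", fam)

    def test_written_files_parse_cleanly(self, tmp_path):
        cfg = small_cfg()
        hits, _ = simulate_orthology(cfg)
        p = tmp_path / "ab.tsv"
        write_blast_tab(hits[("Ath", "Aly")], p)
        parsed = parse_blast_tab(p, max_evalue=1.0)
        assert len(parsed) == len(hits[("Ath", "Aly")])


class TestSimulateGrowth:
    def test_no_divergence_zero_noise_identical_arms(self):
        cfg = small_cfg()
        cfg.growth = GrowthSpec(n_plants_per_group=4, rate_reduction=0.0,
                                plant_scale_sigma=0.0)
        table = simulate_growth(cfg)
        ww = table[table["treatment"] == "WW"].sort_values(["species", "day"])
        wd = table[table["treatment"] == "WD"].sort_values(["species", "day"])
        np.testing.assert_allclose(ww["area"].to_numpy(), wd["area"].to_numpy())

    def test_planted_divergence_recovered(self):
        cfg = small_cfg()
        truth = GroundTruth()
        table = simulate_growth(cfg, truth)
        for sp in cfg.species:
            sub = table[table["species"] == sp]
            ww = sub[sub["treatment"] == "WW"]
            wd = sub[sub["treatment"] == "WD"]
            assert first_growth_reduction_day(ww, wd) == truth.divergence_day[sp]

    def test_stockiness_in_unit_interval(self):
        cfg = small_cfg()
        table = simulate_growth(cfg)
        s = table.apply(lambda r: stockiness(r["area"], r["perimeter"]), axis=1)
        assert ((s > 0) & (s <= 1)).all()

    def test_survival_outcomes_recorded_per_replicate(self):
        cfg = small_cfg()
        truth = GroundTruth()
        simulate_growth(cfg, truth)
        for sp in cfg.species:
            reps = truth.survival[sp]
            assert len(reps) == 3 and all(len(r) == 27 for r in reps)
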