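"""Partner selection, threshold choice and the per-amplicon voting caller."""

import numpy as np
import pandas as pd
import pytest

from ampcnv.coverage import CoverageMatrix
from ampcnv.model import AmpliconCnvModel
from ampcnv.simulate import CnvEvent, SimulationParams, simulate
from ampcnv.unsupervised import (InsufficientSamplesError, UnsupervisedConfig,
                                 call_amplicons, candidate_correlations,
                                 choose_corr_threshold, merge_calls,
                                 select_partners)

from conftest import make_panel


def _three_gene_panel(per_gene=6):
    spec = []
    for g in range(3):
        for k in range(per_gene):
            spec.append((f"g{g}a{k}", f"chr{g + 1}", 1000 * k, 1000 * k + 250,
                         f"G{g + 1}", f"G{g + 1}_ex{k + 1}"))
    return make_panel(spec)


def _correlated_matrix(panel, n_samples=30, seed=0, noise=0.01):
    """All amplicons driven by one shared per-sample factor (one group)."""
    rng = np.random.default_rng(seed)
    factor = rng.normal(0.0, 0.3, size=n_samples)
    depth = rng.uniform(300, 900, size=len(panel))
    mu = depth[:, None] * np.exp(factor[None, :]
                                 + rng.normal(0, noise, size=(len(panel), n_samples)))
    counts = pd.DataFrame(np.maximum(mu.round().astype(int), 1),
                          index=panel.ids,
                          columns=[f"S{i:02d}" for i in range(n_samples)])
    return CoverageMatrix(panel, counts)


class TestThresholdChoice:
    def test_perfectly_correlated_panel_hits_grid_maximum(self):
        panel = _three_gene_panel()
        matrix = _correlated_matrix(panel, noise=0.001)
        usable = np.ones(len(panel), bool)
        corr = candidate_correlations(matrix, usable)
        t = choose_corr_threshold(corr, matrix, usable, 5, gene_cap=3)
        assert t == pytest.approx(0.99)

    def test_independent_noise_panel_falls_back_with_warning(self):
        panel = _three_gene_panel()
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(300, 900, size=(len(panel), 30)),
                              index=panel.ids,
                              columns=[f"S{i:02d}" for i in range(30)])
        matrix = CoverageMatrix(panel, counts)
        usable = np.ones(len(panel), bool)
        corr = candidate_correlations(matrix, usable)
        with pytest.warns(UserWarning):
            t = choose_corr_threshold(corr, matrix, usable, 5, gene_cap=3)
        assert t == 0.0

    def test_qualifying_amplicons_non_increasing_in_threshold(self):
        from ampcnv.unsupervised import partner_counts
        panel = _three_gene_panel()
        matrix = _correlated_matrix(panel, noise=0.3)
        corr = candidate_correlations(matrix, np.ones(len(panel), bool))
        previous = None
        for t in np.arange(0.0, 1.0, 0.05):
            n_ok = (partner_counts(corr, panel, t, 3) >= 5).sum()
            if previous is not None:
                assert n_ok <= previous
            previous = n_ok


class TestPartnerSelection:
    def test_identical_candidate_ranks_first_and_same_gene_excluded(self):
        panel = _three_gene_panel()
        matrix = _correlated_matrix(panel, noise=0.05)
        # make g1a0 an exact copy of g0a0 (different gene)
        matrix.counts.loc["g1a0"] = matrix.counts.loc["g0a0"]
        corr = candidate_correlations(matrix, np.ones(len(panel), bool))
        cfg = UnsupervisedConfig(min_samples=10, allow_small_cohort=True)
        partners = select_partners(panel.index_of("g0a0"), corr, matrix, cfg, 0.5)
        assert partners[0] == panel.index_of("g1a0")
        assert corr[panel.index_of("g0a0"), partners[0]] == pytest.approx(1.0)
        target_gene = panel.gene_of("g0a0")
        assert all(panel.amplicons[j].gene != target_gene for j in partners)

    def test_per_gene_cap_respected(self):
        panel = _three_gene_panel()
        matrix = _correlated_matrix(panel, noise=0.01)
        corr = candidate_correlations(matrix, np.ones(len(panel), bool))
        cfg = UnsupervisedConfig()
        partners = select_partners(0, corr, matrix, cfg, 0.5)
        genes = [panel.amplicons[j].gene for j in partners]
        assert len(partners) == 5
        assert max(genes.count(g) for g in set(genes)) <= cfg.gene_cap


class TestCaller:
    def test_cohort_below_minimum_refused(self):
        panel = _three_gene_panel()
        matrix = _correlated_matrix(panel, n_samples=10)
        with pytest.raises(InsufficientSamplesError):
            call_amplicons(matrix, UnsupervisedConfig())
        calls, _ = call_amplicons(
            matrix, UnsupervisedConfig(allow_small_cohort=True))
        assert isinstance(calls, pd.DataFrame)

    def test_half_coverage_called_het_del(self, panel130):
        sites = [s for s in panel130.sites if s.startswith("GENE1")]
        run = tuple(sites[2:4])
        amps = [a for s in run for a in panel130.sites[s]]
        events = [CnvEvent(sample="S07", gene="GENE1", sites=run, multiplier=0.5)]
        matrix, truth = simulate(SimulationParams(panel=panel130,
                                                  cnv_events=events, seed=88))
        calls, _ = call_amplicons(matrix, UnsupervisedConfig())
        hit = calls[(calls["sample"] == "S07") & calls["amplicon"].isin(amps)]
        assert (hit["state"] == "HET_DEL").all()
        assert (hit["votes"] >= 4).all()
        # no other sample called on those amplicons
        others = calls[(calls["sample"] != "S07") & calls["amplicon"].isin(amps)]
        assert (others["state"] == "NORMAL").all()

    @pytest.mark.parametrize("multiplier", [1.5, 2.0])
    def test_duplications_reported_as_dup(self, panel130, multiplier):
        sites = [s for s in panel130.sites if s.startswith("GENE2")]
        run = tuple(sites[1:3])
        amps = [a for s in run for a in panel130.sites[s]]
        events = [CnvEvent(sample="S11", gene="GENE2", sites=run,
                           multiplier=multiplier)]
        matrix, _ = simulate(SimulationParams(panel=panel130,
                                              cnv_events=events, seed=89))
        calls, _ = call_amplicons(matrix, UnsupervisedConfig())
        hit = calls[(calls["sample"] == "S11") & calls["amplicon"].isin(amps)]
        # copy numbers >= 3 are not separated: both 1.5 and 2.0 appear as DUP
        assert (hit["state"] == "DUP").mean() >= 0.8

    def test_global_rescaling_of_one_sample_produces_no_calls(self, null_run):
        matrix, _ = null_run
        scaled = matrix.copy()
        scaled.counts["S10"] = scaled.counts["S10"] * 3
        calls, _ = call_amplicons(scaled, UnsupervisedConfig())
        assert (calls["state"] == "NORMAL").all()

    def test_deletion_shift_never_moves_call_toward_dup(self, null_run):
        matrix, _ = null_run
        tweaked = matrix.copy()
        amp = tweaked.amplicon_ids[17]
        tweaked.counts.loc[amp, "S05"] = \
            int(tweaked.counts.loc[amp, "S05"] * 0.5)
        calls, _ = call_amplicons(tweaked, UnsupervisedConfig())
        state = calls[(calls["amplicon"] == amp)
                      & (calls["sample"] == "S05")]["state"].iloc[0]
        assert state in ("HET_DEL", "NORMAL")

    def test_single_model_configuration_degenerates_to_outlier_detection(
            self, panel130):
        sites = [s for s in panel130.sites if s.startswith("GENE3")][:2]
        amps = [a for s in sites for a in panel130.sites[s]]
        events = [CnvEvent(sample="S03", gene="GENE3", sites=tuple(sites),
                           multiplier=0.5)]
        matrix, _ = simulate(SimulationParams(panel=panel130,
                                              cnv_events=events, seed=90))
        cfg = UnsupervisedConfig(n_partners=1, votes_required=1,
                                 max_partners_per_gene=1)
        calls, _ = call_amplicons(matrix, cfg)
        hit = calls[(calls["sample"] == "S03") & calls["amplicon"].isin(amps)]
        assert (hit["state"] == "HET_DEL").all()


class TestMergedCalls:
    def test_consecutive_same_state_amplicons_collapse(self, panel130):
        amps = panel130.sites["GENE1_ex2"] + panel130.sites["GENE1_ex3"]
        calls = pd.DataFrame({
            "amplicon": amps,
            "sample": ["S01"] * len(amps),
            "state": ["HET_DEL"] * len(amps),
            "votes": [5] * len(amps),
            "bayes_factor_K": [10.0] * len(amps),
        })
        runs = merge_calls(calls, panel130)
        assert len(runs) == 1
        row = runs.iloc[0]
        assert row["first_site"] == "GENE1_ex2"
        assert row["last_site"] == "GENE1_ex3"
        assert row["n_amplicons"] == len(amps)
        assert not row["single_site_dup"]

    def test_single_site_duplication_flagged(self, panel130):
        site = "GENE2_ex1"
        amps = panel130.sites[site]
        calls = pd.DataFrame({
            "amplicon": amps,
            "sample": ["S01"] * len(amps),
            "state": ["DUP"] * len(amps),
            "votes": [4] * len(amps),
            "bayes_factor_K": [5.0] * len(amps),
        })
        runs = merge_calls(calls, panel130)
        assert len(runs) == 1
        assert bool(runs.iloc[0]["single_site_dup"])
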