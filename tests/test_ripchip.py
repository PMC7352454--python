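"""RIP-chip: presence filtering, IP/T ratios, target calling, chi-squared."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirscreen import ripchip
from mirscreen.simulate import RipSimParams, simulate_ripchip
from mirscreen.types import ValidationError

from conftest import make_rip_experiment


def _paired_experiment(ratio_by_probe, t_value=100.0, conditions=("miR", "EV"), dups=(1, 2)):
    """Experiment where every probe has the given IP/T ratio everywhere."""
    n = len(ratio_by_probe)
    values = {}
    for cond in conditions:
        for dup in dups:
            values[(cond, "T", dup)] = [t_value] * n
            values[(cond, "IP", dup)] = [t_value * r for r in ratio_by_probe]
    return make_rip_experiment(values)


class TestPresenceFilter:
    def test_probe_absent_in_one_total_sample_dropped(self):
        values = {
            ("miR", "T", 1): [10, 10],
            ("miR", "IP", 1): [10, 10],
            ("EV", "T", 1): [10, 10],
            ("EV", "IP", 1): [10, 10],
        }
        present = {k: [True, True] for k in values}
        present[("EV", "T", 1)] = [True, False]
        exp = make_rip_experiment(values, present=present)
        assert ripchip.presence_filter(exp, lower_percentile=0) == ["P1"]

    def test_uniform_values_all_kept(self):
        exp = _paired_experiment([2.0] * 8)
        assert ripchip.presence_filter(exp) == [f"P{i + 1}" for i in range(8)]

    def test_matches_brute_force_rule(self, rng):
        n = 1000
        t_cols = {}
        for cond in ("miR", "EV"):
            for dup in (1, 2):
                t_cols[(cond, "T", dup)] = np.exp(rng.normal(5, 1, n))
                t_cols[(cond, "IP", dup)] = np.exp(rng.normal(5, 1, n))
        # plant ~30% low values in one total sample
        low = rng.random(n) < 0.3
        t_cols[("miR", "T", 1)][low] *= 0.01
        present = {k: list(v > 1.0) for k, v in t_cols.items()}
        exp = make_rip_experiment(
            {k: list(v) for k, v in t_cols.items()}, present=present
        )
        kept = set(ripchip.presence_filter(exp, lower_percentile=25))
        # independent re-evaluation of the rule
        expected = set(exp.values.index)
        for name, key in exp.samples.items():
            if key.fraction != "T":
                continue
            flags = exp.present[name]
            floor = np.percentile(exp.values.loc[flags, name], 25)
            for probe in exp.values.index:
                if not flags[probe] or exp.values.loc[probe, name] < floor:
                    expected.discard(probe)
        assert kept == expected


class TestIpTRatios:
    def test_simple_ratio(self):
        exp = _paired_experiment([4.0], t_value=10.0)
        ratios = ripchip.ip_t_ratios(exp, ["P1"])
        assert ratios.loc["G1", "ratio_miR"] == 4.0

    def test_duplicates_averaged(self):
        values = {
            ("miR", "T", 1): [10.0],
            ("miR", "IP", 1): [20.0],
            ("miR", "T", 2): [10.0],
            ("miR", "IP", 2): [40.0],
            ("EV", "T", 1): [10.0],
            ("EV", "IP", 1): [20.0],
            ("EV", "T", 2): [10.0],
            ("EV", "IP", 2): [20.0],
        }
        exp = make_rip_experiment(values)
        ratios = ripchip.ip_t_ratios(exp, ["P1"])
        assert ratios.loc["G1", "ratio_miR"] == 3.0  # mean of 2 and 4

    def test_inconsistent_duplicates_dropped(self):
        # ratios 0.4 and 1.2: opposite sides of 1 and 3-fold apart
        values = {
            ("miR", "T", 1): [10.0, 10.0],
            ("miR", "IP", 1): [4.0, 30.0],
            ("miR", "T", 2): [10.0, 10.0],
            ("miR", "IP", 2): [12.0, 30.0],
            ("EV", "T", 1): [10.0, 10.0],
            ("EV", "IP", 1): [20.0, 30.0],
            ("EV", "T", 2): [10.0, 10.0],
            ("EV", "IP", 2): [20.0, 30.0],
        }
        exp = make_rip_experiment(values)
        ratios = ripchip.ip_t_ratios(exp, ["P1", "P2"])
        assert list(ratios.index) == ["G2"]

    def test_gene_collapse_takes_best_probe(self):
        values = {
            ("miR", "T", 1): [10.0, 10.0],
            ("miR", "IP", 1): [20.0, 50.0],
            ("EV", "T", 1): [10.0, 10.0],
            ("EV", "IP", 1): [20.0, 20.0],
        }
        exp = make_rip_experiment(values, probe_gene={"P1": "G", "P2": "G"})
        ratios = ripchip.ip_t_ratios(exp, ["P1", "P2"])
        assert ratios.loc["G", "ratio_miR"] == 5.0
        assert ripchip.ip_t_ratios(exp, ["P1", "P2"], collapse="mean").loc[
            "G", "ratio_miR"
        ] == 3.5

    def test_ratio_invariant_to_probe_order(self):
        exp = _paired_experiment([1.5, 3.0, 4.5])
        a = ripchip.ip_t_ratios(exp, ["P1", "P2", "P3"])
        b = ripchip.ip_t_ratios(exp, ["P3", "P1", "P2"])
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_missing_matched_fraction_rejected(self):
        values = {
            ("miR", "T", 1): [10.0],
            ("miR", "IP", 1): [20.0],
            ("miR", "T", 2): [10.0],
        }
        exp = make_rip_experiment(values)
        with pytest.raises(ValidationError):
            ripchip._duplicate_ratios(exp, ["P1"])


class TestTargetCalling:
    def test_boundary_ratio_excluded(self):
        exp = _paired_experiment([1.99, 2.0, 2.01])
        ratios = ripchip.ip_t_ratios(exp, ["P1", "P2", "P3"])
        assert ripchip.enriched_genes(ratios, "miR", min_ratio=2) == {"G2", "G3"}

    def test_tiers_are_nested(self):
        exp = _paired_experiment([1.5, 2.5, 3.0, 4.5, 6.0, 9.0, 16.0])
        ratios = ripchip.ip_t_ratios(exp, list(exp.values.index))
        tiers = {
            m: ripchip.enriched_genes(ratios, "miR", min_ratio=m) for m in (2, 4, 8)
        }
        assert tiers[8] <= tiers[4] <= tiers[2]
        assert len(tiers[2]) > len(tiers[4]) > len(tiers[8])

    def test_differential_enrichment_rules(self):
        values = {}
        # P1: miR 4.4 / EV 2.0 -> fc 2.2 (hit); P2: 4.0/4.0 -> fc 1 (no)
        # P3: miR 1.9 / EV 0.9 -> fc 2.1 but miR ratio < 2 (no)
        for dup in (1, 2):
            values[("miR", "T", dup)] = [10.0, 10.0, 10.0]
            values[("miR", "IP", dup)] = [44.0, 40.0, 19.0]
            values[("EV", "T", dup)] = [10.0, 10.0, 10.0]
            values[("EV", "IP", dup)] = [20.0, 40.0, 9.0]
        exp = make_rip_experiment(values)
        ratios = ripchip.ip_t_ratios(exp, ["P1", "P2", "P3"])
        hits = ripchip.differential_enrichment(ratios)
        assert list(hits.index) == ["G1"]
        assert hits.loc["G1", "fc"] == pytest.approx(2.2)

    def test_overlap_reports_shared_and_exclusive(self):
        shared, only = ripchip.overlap_targets(
            {"X": {"A", "B", "C"}, "Y": {"B", "C", "D"}}
        )
        assert shared == {"B", "C"}
        assert only == {"X": {"A"}, "Y": {"D"}}

    def test_overlap_disjoint_and_idempotent(self):
        shared, _ = ripchip.overlap_targets({"X": {"A"}, "Y": {"B"}})
        assert shared == set()
        s = {"A", "B"}
        shared, only = ripchip.overlap_targets({"X": set(s), "Y": set(s)})
        assert shared == s and only == {"X": set(), "Y": set()}

    def test_study_scale_overlap_sizes_round_trip(self):
        # target sets of size 94 and 59 sharing 47 genes
        shared_genes = {f"S{i}" for i in range(47)}
        st486 = shared_genes | {f"A{i}" for i in range(47)}
        dg75 = shared_genes | {f"B{i}" for i in range(12)}
        shared, only = ripchip.overlap_targets({"ST486": st486, "DG75": dg75})
        assert (len(st486), len(dg75), len(shared)) == (94, 59, 47)
        assert len(only["ST486"]) == 47 and len(only["DG75"]) == 12

    def test_recovers_planted_targets(self):
        exps, truth = simulate_ripchip(RipSimParams(seed=11))
        true = set(truth.gene[truth.is_target])
        for exp in exps.values():
            probes = ripchip.presence_filter(exp)
            ratios = ripchip.ip_t_ratios(exp, probes)
            hits = set(ripchip.differential_enrichment(ratios).index)
            sens = len(hits & true) / len(true)
            fdr = len(hits - true) / max(len(hits), 1)
            assert sens >= 0.9
            assert fdr <= 0.1


class TestChisqEnrichment:
    def test_exact_background_fraction_gives_null(self):
        chi2, p, low = ripchip.chisq_enrichment(15, 100, 0.15)
        assert chi2 == 0.0 and p == 1.0 and not low

    def test_closed_form_example(self):
        chi2, p, low = ripchip.chisq_enrichment(30, 100, 0.15)
        assert chi2 == pytest.approx((30 - 15) ** 2 / 15 + (70 - 85) ** 2 / 85)
        assert chi2 == pytest.approx(17.647058823529413)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))
        assert not low

    def test_small_expected_cell_flagged(self):
        _, _, low = ripchip.chisq_enrichment(1, 10, 0.01)
        assert low

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ripchip.chisq_enrichment(5, 0, 0.5)
        with pytest.raises(ValidationError):
            ripchip.chisq_enrichment(5, 10, 1.5)
        with pytest.raises(ValidationError):
            ripchip.chisq_enrichment(11, 10, 0.5)


class TestRankedList:
    def test_descending_and_rnk_round_trip(self, tmp_path):
        exp = _paired_experiment([1.0, 3.0, 2.0])
        # boost miR-condition IP for P2, P3
        ratios = ripchip.ip_t_ratios(exp, ["P1", "P2", "P3"])
        score = ripchip.ranked_list(ratios)
        assert list(score.values) == sorted(score.values, reverse=True)
        ripchip.write_rnk(score, tmp_path / "x.rnk")
        back = pd.read_csv(tmp_path / "x.rnk", sep="\t", header=None, index_col=0)
        assert list(back.index) == list(score.index)
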