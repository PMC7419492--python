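"""Genome-scan machinery: greedy selection, CIM conditioning, backward
elimination, cross-method consolidation."""

import numpy as np
import pandas as pd
import pytest

from mppme import (
    BlueTable,
    QtlModel,
    ScanProfile,
    WaldResult,
    backward_elimination,
    cim_scan,
    consolidate_qtls,
    method_data_m1,
    method_data_m2,
    method_data_m3,
    select_cofactors,
    select_qtls,
    sim_scan,
    simulate_map,
    simulate_nam_genotypes,
)
from mppme.pipeline import build_designs, build_method_data
from mppme.scan import QtlRecord
from mppme.simulate import SimConfig


def _profile(rows):
    return ScanProfile(
        pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM",
                                    "neglog10p"]),
        "M1",
        "parental",
    )


class TestGreedySelection:
    def test_all_below_threshold_empty(self):
        prof = _profile([("a", 1, 10.0, 2.0), ("b", 1, 30.0, 3.9)])
        assert select_cofactors(prof, threshold=4.0) == []

    def test_hand_trace(self):
        prof = _profile(
            [("a", 1, 10.0, 5.0), ("b", 1, 30.0, 6.0), ("c", 1, 90.0, 4.5)]
        )
        assert select_cofactors(prof, threshold=4.0, min_dist_cM=50.0) == ["b", "c"]

    def test_tie_prefers_map_order(self):
        prof = _profile([("a", 1, 10.0, 5.0), ("b", 2, 10.0, 5.0)])
        assert select_cofactors(prof, threshold=4.0, min_dist_cM=50.0) == ["a", "b"]
        prof2 = _profile([("a", 1, 10.0, 5.0), ("b", 1, 20.0, 5.0)])
        assert select_cofactors(prof2, threshold=4.0, min_dist_cM=50.0) == ["a"]

    def test_plateau_keeps_leftmost(self):
        prof = _profile(
            [("a", 1, 0.0, 5.0), ("b", 1, 8.0, 5.0), ("c", 1, 16.0, 5.0)]
        )
        assert select_qtls(prof, threshold=4.0, min_dist_cM=20.0) == ["a"]

    def test_three_admissible_peaks(self):
        prof = _profile(
            [
                ("a", 1, 0.0, 7.0),
                ("b", 1, 15.0, 6.0),   # excluded by a (15 < 20)
                ("c", 1, 40.0, 5.0),
                ("d", 2, 5.0, 4.5),
                ("e", 2, 90.0, 3.0),   # below threshold
            ]
        )
        assert select_qtls(prof, threshold=4.0, min_dist_cM=20.0) == ["a", "c", "d"]

    def test_row_order_invariance(self):
        rows = [
            ("a", 1, 0.0, 7.0), ("b", 1, 30.0, 6.0), ("c", 2, 10.0, 5.0),
            ("d", 2, 25.0, 4.2),
        ]
        base = select_qtls(_profile(rows), 4.0, 20.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            assert select_qtls(_profile(perm), 4.0, 20.0) == base

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            select_qtls(_profile([("a", 1, 0.0, 5.0)]), threshold=0.0)


class TestConsolidation:
    def _model(self, method, positions, env=None):
        w = WaldResult(10.0, 1, 1e-5, 5.0)
        qtls = [
            QtlRecord(f"m{i}", ch, pos, pd.DataFrame(), w)
            for i, (ch, pos) in enumerate(positions)
        ]
        return QtlModel(method, "parental", qtls, None, 4.0, env)

    def test_nearby_positions_merge(self):
        df = consolidate_qtls(
            [self._model("M1", [(10, 45.0)]), self._model("M3", [(10, 45.2)])],
            merge_dist_cM=10.0,
        )
        assert df["cluster"].nunique() == 1

    def test_distant_positions_stay_separate(self):
        df = consolidate_qtls(
            [self._model("M1", [(1, 10.0)]), self._model("M3", [(1, 22.0)])],
            merge_dist_cM=10.0,
        )
        assert df["cluster"].nunique() == 2

    def test_single_linkage_chains(self):
        df = consolidate_qtls(
            [self._model("M1", [(1, 0.0), (1, 8.0), (1, 16.0)])],
            merge_dist_cM=10.0,
        )
        assert df["cluster"].nunique() == 1

    def test_empty_models(self):
        df = consolidate_qtls([self._model("M1", [])])
        assert df.empty


@pytest.fixture(scope="module")
def scan_setup(small_experiment):
    exp = small_experiment
    designs = build_designs("parental", exp.gmap, exp.geno, exp.crosses)
    md1 = build_method_data("M1", exp.plots)
    return exp, designs, md1


class TestScans:
    def test_cim_without_cofactors_equals_sim(self, scan_setup):
        exp, designs, md1 = scan_setup
        chrom1 = exp.gmap.table[exp.gmap.table["chromosome"] == 1]["marker"]
        sub = {m: designs[m] for m in chrom1[:6]}
        sim = sim_scan(md1, sub, exp.gmap, "parental")
        cim = cim_scan(md1, sub, exp.gmap, "parental", cofactors=[])
        pd.testing.assert_frame_equal(sim.table, cim.table)

    def test_cofactor_excluded_at_own_position(self, scan_setup):
        """At the cofactor's own position the conditioning set drops it, so
        CIM equals SIM there when it is the only cofactor on the
        chromosome."""
        exp, designs, md1 = scan_setup
        sim = sim_scan(md1, designs, exp.gmap, "parental")
        peak = sim.peak()["marker"]
        cim = cim_scan(md1, designs, exp.gmap, "parental", cofactors=[peak])
        at_peak = lambda prof: float(
            prof.table.set_index("marker").loc[peak, "neglog10p"]
        )
        assert at_peak(cim) == pytest.approx(at_peak(sim), abs=1e-6)

    def test_m2_returns_one_profile_per_environment(self, small_experiment):
        from mppme import detect_qtls

        exp = small_experiment
        results = detect_qtls(
            exp.gmap, exp.geno, exp.crosses, exp.plots,
            method="M2", allele_model="biallelic",
        )
        assert sorted(results) == exp.plots.environments
        for res in results.values():
            assert len(res.sim_profile.table) == len(exp.gmap.markers)

    def test_m3_single_environment_equals_m2(self, small_experiment):
        """With one environment the joint CS+ECSE model degenerates to the
        per-environment model: identical profiles."""
        from mppme import fit_blues_within

        exp = small_experiment
        blues = fit_blues_within(exp.plots, "E2")
        designs = build_designs("parental", exp.gmap, exp.geno, exp.crosses)
        sub = {m: designs[m] for m in exp.gmap.markers[:8]}
        md2 = method_data_m2(blues, "E2")
        md3 = method_data_m3([blues])
        p2 = sim_scan(md2, sub, exp.gmap, "parental").table["neglog10p"]
        p3 = sim_scan(md3, sub, exp.gmap, "parental").table["neglog10p"]
        np.testing.assert_allclose(p2, p3, atol=1e-5)

    def test_null_simulation_type_one_error(self):
        """Under the null (no QTL) the fraction of positions exceeding the
        detection threshold of 4 stays at the nominal chi-square rate
        (~1e-4)."""
        exceed = total = 0
        for rep in range(25):
            cfg = SimConfig(
                n_parents=3, cross_sizes=60, n_chromosomes=2,
                chrom_length_cM=100.0, marker_density=0.25,
                n_environments=1, seed=500 + rep,
            )
            gmap = simulate_map(cfg)
            sim = simulate_nam_genotypes(cfg, gmap)
            rng = np.random.default_rng(900 + rep)
            inds = sim.geno.individuals
            cross = [sim.crosses.cross_of(i) for i in inds]
            blue = pd.DataFrame(
                {
                    "genotype": inds,
                    "cross": cross,
                    "environment": "ALL",
                    "blue": rng.normal(100, 5, len(inds))
                    + np.where(np.array(cross) == "X1", 2.0, 0.0),
                    "se": 0.0,
                }
            )
            md = method_data_m1(BlueTable(blue))
            from mppme import impute_biallelic
            from mppme.scan import designs_genomewide

            geno = impute_biallelic(sim.geno, sim.crosses, 1)
            designs = designs_genomewide("biallelic", gmap, sim.crosses, geno=geno)
            prof = sim_scan(md, designs, gmap, "biallelic")
            vals = prof.table["neglog10p"].dropna()
            exceed += int((vals >= 4.0).sum())
            total += len(vals)
        assert exceed / total <= 0.002


class TestBackwardElimination:
    def test_significant_candidates_all_retained(self, scan_setup, small_experiment):
        exp, designs, _ = scan_setup
        md3 = build_method_data("M3", exp.plots)
        sim = sim_scan(md3, designs, exp.gmap, "parental")
        candidates = select_qtls(sim, 4.0, 20.0)
        assert candidates  # the planted QTL is strong
        model = backward_elimination(
            md3, designs, candidates, exp.gmap, "parental", threshold=4.0
        )
        assert all(q.wald.neglog10p >= 4.0 for q in model.qtls)
        # the planted QTL at chr 1 / 40 cM is among the retained positions
        assert any(
            q.chromosome == 1 and abs(q.position_cM - 40.0) <= 10.0
            for q in model.qtls
        )

    def test_noise_candidate_dropped_before_true_qtl(self, scan_setup):
        """Adding an unlinked null position to the candidate list: backward
        elimination discards it and keeps the true QTL."""
        exp, designs, md1 = scan_setup
        md3 = build_method_data("M3", exp.plots)
        sim = sim_scan(md3, designs, exp.gmap, "parental")
        peak = sim.peak()["marker"]
        null_marker = exp.gmap.table[exp.gmap.table["chromosome"] == 2].iloc[-1][
            "marker"
        ]
        model = backward_elimination(
            md3, designs, [peak, null_marker], exp.gmap, "parental", threshold=4.0
        )
        retained = [q.marker for q in model.qtls]
        assert peak in retained
        assert null_marker not in retained

    def test_single_insignificant_candidate_gives_empty_model(self, scan_setup):
        exp, designs, md1 = scan_setup
        null_marker = exp.gmap.table[exp.gmap.table["chromosome"] == 2].iloc[-1][
            "marker"
        ]
        model = backward_elimination(
            md1, designs, [null_marker], exp.gmap, "parental", threshold=4.0
        )
        assert model.qtls == []

    def test_empty_candidates_rejected(self, scan_setup):
        exp, designs, md1 = scan_setup
        with pytest.raises(ValueError):
            backward_elimination(md1, designs, [], exp.gmap, "parental")
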