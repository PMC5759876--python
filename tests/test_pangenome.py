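"""Core/dispensable/unique partitioning, accumulation curves, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pangtm.clustering import FamilySet
from pangtm.pangenome import (
    accumulation_curves,
    compare_pangenomes,
    core_fraction_pct,
    genome_summary,
    hierarchical_heatmap_export,
    new_gene_rate,
    partition_families,
    presence_absence,
    presence_absence_from_membership,
    shared_fraction_pct,
)


def matrix_from_carriage(carriage: dict[str, set[str]], genomes: list[str]):
    return presence_absence_from_membership(carriage, genomes)


class TestPresenceAbsence:
    def test_counts_and_binary(self):
        fs = FamilySet(families={
            "F1": {"g1": ["a"], "g2": ["b"]},
            "F2": {"g1": ["c", "d"]},
        })
        mat = presence_absence(fs, ["g1", "g2"])
        assert mat.loc["F1"].tolist() == [1, 1]
        assert mat.loc["F2"].tolist() == [2, 0]  # paralogues count, binary is >0

    def test_simulator_roundtrip(self, small_sim):
        cfg, _, _, truth = small_sim
        mat = presence_absence_from_membership(
            truth.family_membership, list(cfg.taxa)
        )
        for fid, members in truth.family_membership.items():
            assert set(mat.columns[mat.loc[fid] > 0]) == members


class TestPartition:
    def test_toy_partition(self):
        carriage = {
            "f1": {"g1", "g2", "g3"},
            "f2": {"g1", "g2", "g3"},
            "f3": {"g1", "g2"},
            "f4": {"g2", "g3"},
            "f5": {"g1"},
            "f6": {"g3"},
        }
        part = partition_families(matrix_from_carriage(carriage, ["g1", "g2", "g3"]))
        assert part.core == {"f1", "f2"}
        assert part.dispensable == {"f3", "f4"}
        assert part.unique == {"f5": "g1", "f6": "g3"}
        assert part.variable == {"f3", "f4", "f5", "f6"}

    def test_counts_sum_to_total(self, small_sim):
        cfg, _, _, truth = small_sim
        mat = presence_absence_from_membership(
            truth.family_membership, list(cfg.strains)
        )
        part = partition_families(mat)
        assert part.n_total == len(mat)

    def test_core_fraction_on_published_counts(self):
        # 1200 core vs 2433 variable families -> roughly a third core
        assert core_fraction_pct(1200, 2433) == 33


class TestAccumulationCurves:
    def test_identical_genomes_flat_curves(self):
        carriage = {f"f{i}": {"g1", "g2", "g3"} for i in range(5)}
        curve = accumulation_curves(matrix_from_carriage(carriage, ["g1", "g2", "g3"]))
        assert (curve.pan_mean == 5).all() and (curve.core_mean == 5).all()

    def test_monotonicity_on_seeded_matrix(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            (rng.random((60, 10)) < 0.5).astype(int),
            index=[f"f{i}" for i in range(60)],
            columns=[f"g{i}" for i in range(10)],
        )
        mat = mat[mat.sum(axis=1) > 0]
        curve = accumulation_curves(mat, n_permutations=30, seed=1)
        assert (np.diff(curve.pan_mean) >= 0).all()
        assert (np.diff(curve.core_mean) <= 0).all()

    def test_exhaustive_three_genome_average(self):
        """Means over all 3! orderings equal the hand-enumerated average."""
        carriage = {
            "f1": {"g1", "g2", "g3"},
            "f2": {"g1", "g2"},
            "f3": {"g2", "g3"},
            "f4": {"g1"},
        }
        mat = matrix_from_carriage(carriage, ["g1", "g2", "g3"])
        curve = accumulation_curves(mat)
        assert curve.exhaustive and curve.n_permutations == 6
        # independent exhaustive oracle by direct set arithmetic
        sets = {g: {f for f, m in carriage.items() if g in m} for f in [0] for g in ["g1", "g2", "g3"]}
        pans, cores = [], []
        for order in itertools.permutations(["g1", "g2", "g3"]):
            pan_row, core_row = [], []
            for n in range(1, 4):
                chosen = [sets[g] for g in order[:n]]
                pan_row.append(len(set().union(*chosen)))
                core_row.append(len(set.intersection(*chosen)))
            pans.append(pan_row)
            cores.append(core_row)
        assert curve.pan_mean.tolist() == pytest.approx(np.mean(pans, axis=0).tolist())
        assert curve.core_mean.tolist() == pytest.approx(np.mean(cores, axis=0).tolist())

    def test_first_point_is_mean_single_genome_size(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(
            (rng.random((40, 6)) < 0.6).astype(int),
            index=[f"f{i}" for i in range(40)],
            columns=[f"g{i}" for i in range(6)],
        )
        mat = mat[mat.sum(axis=1) > 0]
        curve = accumulation_curves(mat)
        expected = (mat > 0).sum(axis=0).mean()
        assert curve.pan_mean[0] == pytest.approx(expected)
        assert curve.core_mean[0] == pytest.approx(expected)

    def test_fit_skipped_below_three_genomes(self):
        carriage = {"f1": {"g1", "g2"}, "f2": {"g1"}}
        with pytest.warns(UserWarning, match="fits skipped"):
            curve = accumulation_curves(matrix_from_carriage(carriage, ["g1", "g2"]))
        assert curve.fitted_pan is None and curve.fitted_core is None

    def test_core_asymptote_recovery(self, default_sim):
        """Fitted core asymptote lands within 5% of the designed core size."""
        cfg, _, _, truth = default_sim
        mat = presence_absence_from_membership(
            truth.family_membership, list(cfg.strains)
        )
        curve = accumulation_curves(mat, n_permutations=100, seed=2)
        omega = curve.fitted_core[0]
        assert abs(omega - cfg.core_size) / cfg.core_size < 0.05


class TestNewGeneRate:
    def test_constant_curve_rate_zero(self):
        carriage = {f"f{i}": {"g1", "g2", "g3"} for i in range(4)}
        curve = accumulation_curves(matrix_from_carriage(carriage, ["g1", "g2", "g3"]))
        assert new_gene_rate(curve, 2, 3) == 0.0

    def test_hand_computed_rate(self):
        # build a curve object directly from a known mean pan trajectory
        from pangtm.pangenome import AccumulationCurve

        curve = AccumulationCurve(
            N=np.arange(1, 5),
            pan_mean=np.array([10.0, 13.0, 15.0, 16.0]),
            pan_sd=np.zeros(4), core_mean=np.zeros(4), core_sd=np.zeros(4),
            n_permutations=1, exhaustive=True, seed=None,
            fitted_pan=None, fitted_core=None,
        )
        assert new_gene_rate(curve, 2, 4) == pytest.approx(2.0)  # (3+2+1)/3

    def test_rate_declines_with_finite_pool(self, small_sim):
        cfg, _, _, truth = small_sim
        mat = presence_absence_from_membership(
            truth.family_membership, list(cfg.strains)
        )
        curve = accumulation_curves(mat, n_permutations=50, seed=3)
        g = len(curve.N)
        early = new_gene_rate(curve, 2, 3)
        late = new_gene_rate(curve, g - 1, g)
        assert late < early

    def test_out_of_range_rejected(self):
        from pangtm.pangenome import AccumulationCurve

        curve = AccumulationCurve(
            N=np.arange(1, 4), pan_mean=np.zeros(3), pan_sd=np.zeros(3),
            core_mean=np.zeros(3), core_sd=np.zeros(3), n_permutations=1,
            exhaustive=True, seed=None, fitted_pan=None, fitted_core=None,
        )
        with pytest.raises(ValueError):
            new_gene_rate(curve, 1, 3)
        with pytest.raises(ValueError):
            new_gene_rate(curve, 2, 4)


class TestComparePangenomes:
    def test_published_overlap_arithmetic(self):
        # 5970 families, 1698 with no representative in the sub-collection
        assert shared_fraction_pct(5970, 1698) == 72

    def test_full_subset_is_total(self):
        carriage = {"f1": {"g1"}, "f2": {"g2"}, "f3": {"g1", "g2"}}
        mat = matrix_from_carriage(carriage, ["g1", "g2"])
        assert compare_pangenomes(mat, ["g1", "g2"]) == (100, 0)

    def test_toy_subset(self):
        carriage = {f"f{i}": {"g1"} for i in range(7)}
        carriage.update({f"h{i}": {"g2"} for i in range(3)})
        mat = matrix_from_carriage(carriage, ["g1", "g2"])
        assert compare_pangenomes(mat, ["g1"]) == (70, 3)

    def test_empty_subset_rejected(self):
        mat = matrix_from_carriage({"f1": {"g1"}}, ["g1"])
        with pytest.raises(ValueError):
            compare_pangenomes(mat, [])


class TestGenomeSummary:
    def test_single_genome(self):
        stats = pd.DataFrame(
            {"orfs": [2000], "genome_size_bp": [2.4e6], "gc_percent": [60.0]},
            index=["g1"],
        )
        summary = genome_summary(stats)
        assert summary["orfs"]["mean"] == 2000 and summary["orfs"]["sd"] == 0

    def test_population_sd_and_rounding(self):
        stats = pd.DataFrame(
            {
                "orfs": [100, 200],
                "genome_size_bp": [2e6, 3e6],
                "gc_percent": [59.0, 60.0],
            },
            index=["a", "b"],
        )
        summary = genome_summary(stats)
        assert summary["orfs"]["sd"] == 50  # population sd, not sample (71)
        assert summary["genome_size_mbp"]["mean"] == 2.5
        assert summary["gc_percent"]["mean"] == 59.5


class TestHeatmapExport:
    def test_identical_genomes_cluster_first(self):
        carriage = {
            "f1": {"g1", "g2", "g3"},
            "f2": {"g1", "g2"},
            "f3": {"g3"},
        }
        mat = matrix_from_carriage(carriage, ["g1", "g2", "g3"])
        ordered, linkage, newick = hierarchical_heatmap_export(mat)
        # g1 and g2 share identical columns -> adjacent leaves
        order = list(ordered.columns)
        assert abs(order.index("g1") - order.index("g2")) == 1
        assert linkage[0][2] == pytest.approx(0.0)  # first merge at distance 0

    def test_hand_computed_average_linkage(self):
        carriage = {
            "f1": {"g1", "g2"},
            "f2": {"g1", "g2"},
            "f3": {"g3", "g4"},
            "f4": {"g3"},
            "f5": {"g1", "g3"},
        }
        mat = matrix_from_carriage(carriage, ["g1", "g2", "g3", "g4"])
        from scipy.spatial.distance import pdist
        from scipy.cluster.hierarchy import average

        binary = (mat.loc[:, sorted(mat.columns)].to_numpy() > 0).T
        expected = average(pdist(binary, "jaccard"))
        _, linkage, _ = hierarchical_heatmap_export(mat)
        assert np.allclose(linkage, expected)

    def test_requires_two_genomes(self):
        mat = matrix_from_carriage({"f1": {"g1"}}, ["g1"])
        with pytest.raises(ValueError):
            hierarchical_heatmap_export(mat)
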