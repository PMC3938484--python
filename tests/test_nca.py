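"""NCA identifiability, ALS recovery, gauge fixing and ΔTFA significance."""

import numpy as np
import pandas as pd
import pytest

from acidstress.errors import InvalidInputError
from acidstress.nca import (
    RegulatoryTopology,
    check_identifiability,
    delta_tfa,
    nca_decompose,
)
from acidstress.synth import demo_topology, gen_expression


def diagonal_topology(n_tf=3, targets=3):
    """Each TF gets its own private block of target genes."""
    pairs = [
        (f"TF{j + 1}", f"g{j}_{t}") for j in range(n_tf) for t in range(targets)
    ]
    return RegulatoryTopology.from_edges(pairs)


def gauge_normalize(P, A):
    """Reference gauge for comparisons (same rule as the implementation)."""
    A, P = A.copy(), P.copy()
    for tf in A.columns:
        col = A[tf].to_numpy()
        scale = col[np.argmax(np.abs(col))]
        A[tf] = col / scale
        P.loc[tf] = P.loc[tf] * scale
    return P, A


class TestIdentifiability:
    def test_diagonal_topology_passes(self):
        report = check_identifiability(diagonal_topology(), n_conditions=4)
        assert report.passed

    def test_demo_topology_passes(self):
        report = check_identifiability(demo_topology(), n_conditions=6)
        assert report.passed

    def test_identical_target_sets_fail(self):
        pairs = [("TF1", "g1"), ("TF1", "g2"), ("TF2", "g1"), ("TF2", "g2")]
        report = check_identifiability(
            RegulatoryTopology.from_edges(pairs), n_conditions=4
        )
        assert not report.passed
        assert {"TF1", "TF2"} <= set(report.offending_tfs)

    def test_nested_regulon_fails_reduced_rank(self):
        # TF2's targets are a subset of TF1's: removing TF1 leaves TF2 with
        # no private genes to pin it down
        pairs = [("TF1", "g1"), ("TF1", "g2"), ("TF1", "g3"), ("TF2", "g1")]
        report = check_identifiability(
            RegulatoryTopology.from_edges(pairs), n_conditions=4
        )
        assert not report.passed

    def test_too_few_conditions_flagged(self):
        report = check_identifiability(diagonal_topology(n_tf=3), n_conditions=2)
        assert not report.passed
        assert any("conditions" in issue for issue in report.issues)

    def test_duplicate_edges_rejected(self):
        with pytest.raises(InvalidInputError):
            RegulatoryTopology.from_edges([("TF1", "g1"), ("TF1", "g1")])


class TestDecompose:
    def test_noiseless_recovery_toy_system(self):
        """6 genes / 2 TFs / 4 conditions: exact reconstruction + factor match."""
        topology = diagonal_topology(n_tf=2, targets=3)
        rng = np.random.default_rng(0)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (2, 4)), index=topology.tfs,
            columns=[f"cond{i}" for i in range(4)],
        )
        study, truth = gen_expression(topology, true_p, noise_sd=0.0,
                                      n_replicates=1, seed=0)
        result = nca_decompose(study.matrix, topology, seed=1)
        E = study.matrix.to_numpy()
        recon = result.A.to_numpy() @ result.P.to_numpy()
        assert np.abs(recon - E).max() <= 1e-8
        # compare factors in the common gauge
        P_ref, A_ref = gauge_normalize(
            truth.params["P"].copy().set_axis(study.matrix.columns, axis=1),
            truth.params["A"],
        )
        assert np.allclose(result.P.to_numpy(), P_ref.to_numpy(), atol=1e-6)
        assert np.allclose(result.A.to_numpy(), A_ref.to_numpy(), atol=1e-6)

    def test_zero_matrix_gives_zero_activities(self):
        topology = diagonal_topology()
        E = pd.DataFrame(
            0.0, index=topology.genes, columns=["a", "b", "c"]
        )
        result = nca_decompose(E, topology, seed=0)
        assert np.allclose(result.P.to_numpy(), 0.0)

    def test_noisy_recovery_correlation(self):
        """σ=0.05 noise: per-TF activity correlation with truth >= 0.95."""
        topology = demo_topology()
        rng = np.random.default_rng(21)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (len(topology.tfs), 6)), index=topology.tfs,
            columns=[f"c{i}" for i in range(6)],
        )
        study, truth = gen_expression(topology, true_p, noise_sd=0.05,
                                      n_replicates=1, seed=21)
        result = nca_decompose(study.matrix, topology, seed=5)
        for tf in topology.tfs:
            r = np.corrcoef(
                result.P.loc[tf].to_numpy(),
                truth.params["P"].loc[tf].to_numpy(),
            )[0, 1]
            assert abs(r) >= 0.95

    def test_residual_trace_monotone_nonincreasing(self):
        topology = demo_topology()
        rng = np.random.default_rng(2)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (len(topology.tfs), 5)), index=topology.tfs,
            columns=[f"c{i}" for i in range(5)],
        )
        study, _ = gen_expression(topology, true_p, noise_sd=0.2,
                                  n_replicates=1, seed=2)
        result = nca_decompose(study.matrix, topology, seed=3)
        res = np.array(result.residuals)
        assert np.all(np.diff(res) <= 1e-12)

    def test_support_preserved_exactly(self):
        topology = demo_topology()
        rng = np.random.default_rng(4)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (len(topology.tfs), 6)), index=topology.tfs,
            columns=[f"c{i}" for i in range(6)],
        )
        study, _ = gen_expression(topology, true_p, noise_sd=0.1,
                                  n_replicates=1, seed=4)
        result = nca_decompose(study.matrix, topology, seed=6)
        mask = topology.support().to_numpy() != 0
        assert np.all(result.A.to_numpy()[~mask] == 0.0)

    def test_gauge_uniqueness_across_seeds(self):
        """5 random starts on identifiable noiseless data agree to 1e-6."""
        topology = diagonal_topology(n_tf=3, targets=3)
        rng = np.random.default_rng(8)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (3, 5)), index=topology.tfs,
            columns=[f"c{i}" for i in range(5)],
        )
        study, _ = gen_expression(topology, true_p, noise_sd=0.0,
                                  n_replicates=1, seed=8)
        results = [
            nca_decompose(study.matrix, topology, seed=s).P.to_numpy()
            for s in range(5)
        ]
        for other in results[1:]:
            assert np.abs(other - results[0]).max() <= 1e-6

    def test_scaling_gauge_equivalence(self):
        """(A·D, D⁻¹·P) reproduces E for any diagonal invertible D."""
        topology = diagonal_topology(n_tf=2, targets=3)
        rng = np.random.default_rng(12)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (2, 4)), index=topology.tfs,
            columns=[f"c{i}" for i in range(4)],
        )
        study, _ = gen_expression(topology, true_p, noise_sd=0.0,
                                  n_replicates=1, seed=12)
        result = nca_decompose(study.matrix, topology, seed=0)
        D = np.diag([2.5, -0.7])
        recon = (result.A.to_numpy() @ D) @ (np.linalg.inv(D) @ result.P.to_numpy())
        assert np.allclose(recon, study.matrix.to_numpy(), atol=1e-7)

    def test_extra_genes_excluded_but_carried(self):
        topology = diagonal_topology(n_tf=2, targets=3)
        rng = np.random.default_rng(13)
        true_p = pd.DataFrame(
            rng.normal(0, 1, (2, 4)), index=topology.tfs,
            columns=[f"c{i}" for i in range(4)],
        )
        study, _ = gen_expression(topology, true_p, noise_sd=0.0,
                                  n_replicates=1, seed=13)
        extra = study.matrix.copy()
        extra.loc["orphan_gene"] = 1.0
        result = nca_decompose(extra, topology, seed=0)
        assert result.excluded_genes == ("orphan_gene",)
        assert "orphan_gene" not in result.A.index

    def test_missing_topology_genes_rejected(self):
        topology = diagonal_topology(n_tf=2, targets=3)
        E = pd.DataFrame(np.ones((2, 4)), index=topology.genes[:2],
                         columns=list("abcd"))
        with pytest.raises(InvalidInputError):
            nca_decompose(E, topology)


class TestDeltaTfa:
    def _activity_frame(self, rng, shift=0.0, n_rep=4):
        tfs = ["TF1", "TF2", "TF3"]
        cols = [f"control_{i}" for i in range(n_rep)] + [
            f"treated_{i}" for i in range(n_rep)
        ]
        data = rng.normal(0, 0.3, (3, 2 * n_rep))
        data[0, n_rep:] += shift
        labels = ["control"] * n_rep + ["treated"] * n_rep
        return pd.DataFrame(data, index=tfs, columns=cols), labels

    def test_identical_groups_null(self):
        P = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]], index=["TF1"],
            columns=["c1", "c2", "t1", "t2"],
        )
        changes = delta_tfa(P, ["control", "control", "treated", "treated"],
                            n_boot=500, seed=0)
        assert changes[0].delta == pytest.approx(0.0)
        assert changes[0].p > 0.5

    def test_shifted_tf_flagged(self):
        rng = np.random.default_rng(31)
        P, labels = self._activity_frame(rng, shift=0.9)  # 3σ of the 0.3 noise
        changes = {c.tf: c for c in delta_tfa(P, labels, n_boot=2000, seed=1)}
        assert changes["TF1"].significant
        assert changes["TF1"].direction == "+"
        assert not changes["TF2"].significant
        assert not changes["TF3"].significant

    def test_sign_flips_with_labels(self):
        rng = np.random.default_rng(32)
        P, labels = self._activity_frame(rng, shift=1.0)
        swapped = ["treated" if l == "control" else "control" for l in labels]
        d1 = delta_tfa(P, labels, n_boot=100, seed=0)[0].delta
        d2 = delta_tfa(P, swapped, n_boot=100, seed=0)[0].delta
        assert d1 == pytest.approx(-d2)

    def test_single_replicate_omits_p(self):
        P = pd.DataFrame([[1.0, 3.0]], index=["TF1"], columns=["c", "t"])
        changes = delta_tfa(P, ["control", "treated"], n_boot=100, seed=0)
        assert changes[0].p is None
        assert changes[0].delta == pytest.approx(2.0)
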