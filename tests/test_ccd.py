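"""Unit and property tests for the CCD statistic and its building blocks.

The independent oracles here (explicit rank enumeration for Spearman,
exhaustive upper-triangle summation for the distance) deliberately avoid the
vectorized code paths they check.
"""

import math

import numpy as np
import pytest

from stratccd import (
    ClockGenePanel,
    CorrelationMatrix,
    EstimationError,
    ExpressionMatrix,
    ReferenceMatrix,
    ValidationError,
    build_reference,
    ccd,
    delta_ccd,
    spearman_matrix,
)
from stratccd.ccd import align_panel_reference

from conftest import random_correlation_values, random_expression


# ---------------------------------------------------------------------------
# independent oracles


def oracle_spearman(a, b):
    """Average-rank Spearman by direct rank enumeration and the Pearson formula."""

    def ranks(x):
        out = []
        for v in x:
            less = sum(1 for w in x if w < v)
            equal = sum(1 for w in x if w == v)
            out.append(1 + less + (equal - 1) / 2)
        return out

    ra, rb = ranks(a), ranks(b)
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    da = math.sqrt(sum((x - ma) ** 2 for x in ra))
    db = math.sqrt(sum((y - mb) ** 2 for y in rb))
    if da == 0 or db == 0:
        return 0.0
    return num / (da * db)


def oracle_ccd(obs, ref, metric="euclidean"):
    """Distance by an explicit loop over all upper-triangle entries."""
    n = obs.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = obs[i, j] - ref[i, j]
            total += d * d if metric == "euclidean" else abs(d)
    return math.sqrt(total) if metric == "euclidean" else total


def wrap(values, genes, n_samples=10, reference=False):
    panel = ClockGenePanel(tuple(genes), min_genes=3)
    cls = ReferenceMatrix if reference else CorrelationMatrix
    return cls(panel=panel, values=values, n_samples=n_samples)


# ---------------------------------------------------------------------------
# spearman_matrix


class TestSpearmanMatrix:
    def test_monotone_pairs_give_plus_minus_one(self):
        expr = ExpressionMatrix(
            ["A", "B", "C"],
            ["s1", "s2", "s3", "s4"],
            np.array([[1, 2, 3, 4], [2, 4, 6, 8], [8, 6, 4, 2]], dtype=float),
        )
        m = spearman_matrix(expr, ClockGenePanel(("A", "B", "C"), min_genes=3))
        assert m.entry("A", "B") == pytest.approx(1.0, abs=1e-12)
        assert m.entry("A", "C") == pytest.approx(-1.0, abs=1e-12)

    def test_ties_match_average_rank_oracle(self):
        a = [1.0, 2.0, 2.0, 4.0]
        b = [1.0, 3.0, 2.0, 4.0]
        expr = ExpressionMatrix(["A", "B", "C"], list("wxyz"),
                                np.array([a, b, [5.0, 1.0, 2.0, 2.0]]))
        m = spearman_matrix(expr, ClockGenePanel(("A", "B", "C"), min_genes=3))
        assert m.entry("A", "B") == pytest.approx(oracle_spearman(a, b), abs=1e-12)
        assert m.entry("A", "C") == pytest.approx(
            oracle_spearman(a, [5.0, 1.0, 2.0, 2.0]), abs=1e-12
        )

    def test_random_instances_match_oracle(self, rng):
        """Vectorized Spearman equals direct rank enumeration to 1e-12."""
        for _ in range(25):
            n_genes = rng.integers(3, 7)
            n_samples = rng.integers(4, 26)
            values = rng.integers(0, 8, size=(n_genes, n_samples)).astype(float)
            expr = ExpressionMatrix(
                [f"G{i}" for i in range(n_genes)],
                [f"S{i}" for i in range(n_samples)],
                values,
            )
            m = spearman_matrix(
                expr, ClockGenePanel(tuple(expr.gene_ids), min_genes=3)
            )
            for i in range(n_genes):
                for j in range(n_genes):
                    expected = (
                        1.0 if i == j else oracle_spearman(values[i], values[j])
                    )
                    assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_gets_zero_with_warning(self):
        expr = ExpressionMatrix(
            ["A", "B", "C"], list("wxyz"),
            np.array([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]], dtype=float),
        )
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(expr, ClockGenePanel(("A", "B", "C"), min_genes=3))
        assert m.entry("A", "B") == 0.0
        assert m.entry("B", "B") == 1.0

    def test_too_few_samples_errors(self, rng):
        expr = random_expression(rng, n_genes=3, n_samples=2)
        with pytest.raises(EstimationError):
            spearman_matrix(expr, ClockGenePanel(tuple(expr.gene_ids), min_genes=3))

    def test_monotone_transform_invariance(self, rng):
        """Spearman is invariant to strictly monotone per-gene transforms."""
        expr = random_expression(rng, n_genes=4, n_samples=15)
        panel = ClockGenePanel(tuple(expr.gene_ids), min_genes=3)
        transformed = ExpressionMatrix(
            list(expr.gene_ids),
            list(expr.sample_ids),
            np.vstack(
                [
                    np.exp(expr.values[0]),
                    expr.values[1] ** 3,
                    5 * expr.values[2] - 2,
                    np.arctan(expr.values[3]),
                ]
            ),
        )
        a = spearman_matrix(expr, panel)
        b = spearman_matrix(transformed, panel)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


# ---------------------------------------------------------------------------
# ccd distance


class TestCCD:
    def test_identity_is_zero(self, rng):
        c = random_correlation_values(rng, 4)
        genes = ["G0", "G1", "G2", "G3"]
        assert ccd(wrap(c, genes), wrap(c, genes, reference=True)) == 0.0

    def test_single_entry_difference(self):
        genes = ["A", "B", "C"]
        ref = np.eye(3)
        obs = np.eye(3)
        obs[0, 1] = obs[1, 0] = 0.37
        assert ccd(
            wrap(obs, genes), wrap(ref, genes, reference=True)
        ) == pytest.approx(0.37, abs=1e-12)

    def test_matches_exhaustive_oracle_12_genes(self, rng):
        genes = [f"G{i}" for i in range(12)]
        a = random_correlation_values(rng, 12)
        b = random_correlation_values(rng, 12)
        for metric in ("euclidean", "l1"):
            assert ccd(
                wrap(a, genes), wrap(b, genes, reference=True), metric
            ) == pytest.approx(oracle_ccd(a, b, metric), abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        genes = ["G0", "G1", "G2", "G3"]
        a, b = (random_correlation_values(rng, 4) for _ in range(2))
        d1 = ccd(wrap(a, genes), wrap(b, genes, reference=True))
        d2 = ccd(wrap(b, genes), wrap(a, genes, reference=True))
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 >= 0

    def test_triangle_inequality_on_random_triples(self, rng):
        genes = ["G0", "G1", "G2", "G3", "G4"]
        for _ in range(50):
            a, b, c = (random_correlation_values(rng, 5) for _ in range(3))
            dab = ccd(wrap(a, genes), wrap(b, genes, reference=True))
            dbc = ccd(wrap(b, genes), wrap(c, genes, reference=True))
            dac = ccd(wrap(a, genes), wrap(c, genes, reference=True))
            assert dac <= dab + dbc + 1e-12

    def test_panel_mismatch_errors(self, rng):
        a = random_correlation_values(rng, 3)
        with pytest.raises(ValidationError, match="panels differ"):
            ccd(wrap(a, ["A", "B", "C"]), wrap(a, ["A", "B", "D"], reference=True))


# ---------------------------------------------------------------------------
# delta_ccd


class TestDeltaCCD:
    def test_antisymmetry_under_label_swap(self, rng, reference):
        from stratccd import SyntheticCohortConfig, simulate_cohort

        cfg = SyntheticCohortConfig(
            n_per_group={"AD": 20, "IC": 20}, disruption_rho=0.5, seed=5
        )
        expr, ann, _ = simulate_cohort(cfg)
        labels = ann["group"].to_numpy()
        swapped = np.where(labels == "AD", "IC", "AD")
        d = delta_ccd(expr, labels, cfg.panel, reference)
        d_sw = delta_ccd(expr, swapped, cfg.panel, reference)
        assert d_sw == pytest.approx(-d, abs=1e-12)

    def test_identical_groups_give_zero(self, rng, reference):
        from stratccd import SyntheticCohortConfig, simulate_cohort

        cfg = SyntheticCohortConfig(n_per_group={"AD": 15, "IC": 15}, seed=3)
        expr, _, _ = simulate_cohort(cfg)
        # duplicate every sample into both groups: identical sample multisets
        doubled = ExpressionMatrix(
            list(expr.gene_ids),
            [f"{s}_{g}" for g in ("a", "b") for s in expr.sample_ids],
            np.hstack([expr.values, expr.values]),
        )
        labels = ["AD"] * expr.n_samples + ["IC"] * expr.n_samples
        assert delta_ccd(doubled, labels, cfg.panel, reference) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_small_group_errors(self, rng, reference):
        from stratccd import SyntheticCohortConfig, simulate_cohort

        cfg = SyntheticCohortConfig(n_per_group={"AD": 10, "IC": 2}, seed=3)
        expr, ann, _ = simulate_cohort(cfg)
        with pytest.raises(EstimationError):
            delta_ccd(expr, ann["group"].to_numpy(), cfg.panel, reference)


# ---------------------------------------------------------------------------
# panel plumbing


class TestPanelPolicy:
    def test_missing_genes_dropped_from_both(self, reference):
        panel = ClockGenePanel()
        available = [g for g in panel.gene_ids if g not in ("CRY1", "TEF")] + ["X"]
        p2, r2 = align_panel_reference(panel, reference, available)
        assert "CRY1" not in p2.gene_ids and "TEF" not in p2.gene_ids
        assert p2.gene_ids == r2.panel.gene_ids
        # surviving entries are unchanged
        assert r2.entry("ARNTL", "PER2") == pytest.approx(
            reference.entry("ARNTL", "PER2")
        )

    def test_below_min_genes_errors(self, reference):
        panel = ClockGenePanel()
        with pytest.raises(EstimationError, match="panel genes"):
            align_panel_reference(panel, reference, list(panel.gene_ids[:5]))


class TestBuildReference:
    def test_single_input_unchanged(self, rng):
        genes = ["G0", "G1", "G2"]
        c = random_correlation_values(rng, 3)
        ref = build_reference([wrap(c, genes)])
        np.testing.assert_allclose(ref.values, c, atol=1e-12)

    def test_median_symmetry(self):
        genes = ["A", "B", "C"]
        a, b = np.eye(3), np.eye(3)
        a[0, 1] = a[1, 0] = 0.4
        b[0, 1] = b[1, 0] = -0.4
        ref = build_reference([wrap(a, genes), wrap(b, genes)])
        assert ref.values[0, 1] == 0.0

    def test_simulated_entrained_cohorts_yield_antiphase_entry(self):
        """Median reference from 5 entrained cohorts keeps ARNTL-PER2 negative."""
        from stratccd import SyntheticCohortConfig, simulate_cohort

        mats = []
        for seed in range(5):
            cfg = SyntheticCohortConfig(
                n_per_group={"AD": 60, "IC": 60}, seed=seed, covariates=()
            )
            expr, _, _ = simulate_cohort(cfg)
            mats.append(spearman_matrix(expr, cfg.panel))
        ref = build_reference(mats)
        assert ref.entry("ARNTL", "PER2") < 0
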