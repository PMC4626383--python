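"""Topology indices against independent brute-force oracles and endpoints."""

import itertools
import math

import numpy as np
import pytest

from conftest import bmat, cmat, random_admitted_binary, random_admitted_counts
from mosaicweb.topology_metrics import (
    descriptive_metrics,
    full_metrics,
    h2_entropy_bounds,
    h2_specialization,
    interaction_strength_asymmetry,
    linkage_density,
    nodf,
    specialist_fractions,
    weighted_connectance,
)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def nodf_oracle(values: np.ndarray, weighted: bool = False) -> float:
    """Pair-by-pair scoring straight from the metric's definition."""
    def axis_scores(rows):
        out = []
        for a, b in itertools.combinations(range(rows.shape[0]), 2):
            u, v = rows[a], rows[b]
            mt_u = u.sum() if weighted else (u > 0).sum()
            mt_v = v.sum() if weighted else (v > 0).sum()
            if mt_u == mt_v:
                out.append(0.0)
                continue
            if mt_v > mt_u:
                u, v = v, u
            if weighted:
                num = sum(1 for k in range(len(v)) if 0 < v[k] < u[k])
            else:
                num = sum(1 for k in range(len(v)) if v[k] > 0 and u[k] > 0)
            den = (v > 0).sum()
            out.append(100.0 * num / den if den else 0.0)
        return out

    rows = axis_scores(values)
    cols = axis_scores(values.T)
    return (sum(rows) + sum(cols)) / (len(rows) + len(cols))


def enumerate_tables(row_totals, col_totals):
    """All nonnegative integer tables with the given margins (tiny cases)."""
    n_r, n_c = len(row_totals), len(col_totals)

    def rows_for(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in rows_for(total - first, caps[1:]):
                yield (first,) + rest

    def fill(i, remaining_cols):
        if i == n_r:
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        for row in rows_for(row_totals[i], tuple(remaining_cols)):
            yield from ([list(row)] + rest
                        for rest in fill(i + 1,
                                         [c - r for c, r in zip(remaining_cols, row)]))

    for table in fill(0, list(col_totals)):
        yield np.array(table, dtype=float)


def entropy(values: np.ndarray) -> float:
    p = values[values > 0] / values.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Descriptive metrics
# ---------------------------------------------------------------------------

class TestDescriptive:
    def test_full_matrix(self):
        r = descriptive_metrics(bmat(np.ones((2, 2))))
        assert (r.I, r.M, r.C, r.L, r.L_P, r.L_A) == (4, 4, 1.0, 1.0, 2.0, 2.0)

    def test_perfect_matching(self):
        r = descriptive_metrics(bmat(np.eye(2)))
        assert (r.I, r.C, r.L_P, r.L_A) == (2, 0.5, 1.0, 1.0)

    def test_random_matrix_against_cell_count(self, rng):
        for _ in range(20):
            m = random_admitted_binary(rng)
            r = descriptive_metrics(m)
            links = int(sum(1 for i in range(m.n_plants) for j in range(m.n_insects)
                            if m.values[i, j] > 0))
            assert r.I == links
            assert r.C == pytest.approx(links / (m.n_plants * m.n_insects))
            assert r.L == pytest.approx(links / (m.n_plants + m.n_insects))
            assert r.S == r.P + r.A and r.M == r.P * r.A

    def test_specialists(self):
        assert specialist_fractions(bmat(np.eye(3))) == (1.0, 1.0)
        assert specialist_fractions(bmat(np.ones((3, 3)))) == (0.0, 0.0)
        m = bmat([[1, 0, 0], [0, 1, 0], [1, 1, 1]])
        assert specialist_fractions(m)[0] == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def strictly_nested(n: int) -> np.ndarray:
    values = np.zeros((n, n))
    for i in range(n):
        values[i, : n - i] = 1
    return values


class TestNODF:
    def test_perfectly_nested_scores_100(self):
        assert nodf(bmat(strictly_nested(5))).nodf == pytest.approx(100.0)

    def test_equal_degrees_score_0(self):
        assert nodf(bmat(np.eye(4))).nodf == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(200):
            m = random_admitted_binary(rng, max_dim=6)
            assert nodf(m).nodf == pytest.approx(nodf_oracle(m.values), abs=1e-12)

    def test_weighted_matches_bruteforce(self, rng):
        for _ in range(100):
            m = random_admitted_counts(rng)
            got = nodf(m, weighted=True).nodf
            assert got == pytest.approx(nodf_oracle(m.values, weighted=True), abs=1e-12)

    def test_binary_matrix_has_zero_weighted_nodf(self, rng):
        for _ in range(20):
            m = random_admitted_binary(rng)
            assert nodf(m, weighted=True).nodf == 0.0

    def test_transpose_swaps_components(self, rng):
        m = random_admitted_binary(rng)
        a, b = nodf(m), nodf(m.transposed())
        assert a.nodf == pytest.approx(b.nodf)
        assert a.row_component == pytest.approx(b.col_component)

    def test_permutation_invariance(self, rng):
        m = random_admitted_binary(rng, max_dim=5)
        perm_r = rng.permutation(m.n_plants)
        perm_c = rng.permutation(m.n_insects)
        shuffled = bmat(m.values[np.ix_(perm_r, perm_c)])
        assert nodf(m).nodf == pytest.approx(nodf(shuffled).nodf)

    def test_adding_nested_row_preserves_perfection(self):
        values = strictly_nested(4)
        grown = np.vstack([np.ones(4), values])  # still strictly nested
        grown = np.column_stack([grown, [1, 0, 0, 0, 0]])
        assert nodf(bmat(grown)).nodf == pytest.approx(100.0)

    def test_matches_vegan_reference_implementation(self, rng, tmp_path):
        """Binary NODF agrees with the R vegan package (nestednodf) to its
        printed precision on random fixtures."""
        import subprocess

        for _ in range(4):
            m = random_admitted_binary(rng, max_dim=6)
            path = tmp_path / "m.csv"
            np.savetxt(path, m.values, delimiter=",", fmt="%d")
            script = (
                f'm <- as.matrix(read.csv("{path}", header=FALSE));'
                's <- vegan::nestednodf(m, order=TRUE);'
                'cat(sprintf("%.8f", unname(s$statistic["NODF"])))'
            )
            proc = subprocess.run(["Rscript", "-e", script],
                                  capture_output=True, text=True, timeout=120)
            assert proc.returncode == 0, proc.stderr
            assert nodf(m).nodf == pytest.approx(float(proc.stdout), abs=1e-6)

    def test_denominator_counts_all_pairs(self):
        # two tied rows score zero but stay in the denominator
        m = bmat([[1, 1, 0], [1, 1, 0], [1, 0, 0]])
        b = nodf(m)
        assert b.n_row_pairs == 3 and b.n_col_pairs == 3
        assert b.nodf == pytest.approx(nodf_oracle(m.values))


# ---------------------------------------------------------------------------
# Weighted connectance / linkage density
# ---------------------------------------------------------------------------

class TestWeightedConnectance:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_uniform_diagonal(self, n):
        m = cmat(np.eye(n) * 3)
        assert linkage_density(m) == pytest.approx(1.0)
        assert weighted_connectance(m) == pytest.approx(1 / (2 * n))

    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_all_ones_is_half(self, n):
        assert weighted_connectance(bmat(np.ones((n, n)))) == pytest.approx(0.5)

    def test_toy_counts_against_entropy_oracle(self):
        values = np.array([[4.0, 1.0, 0.0], [0.0, 2.0, 3.0]])
        T = values.sum()
        acc = 0.0
        for axis in (0, 1):
            rows = values if axis else values.T
            for col in rows.T:
                tot = col.sum()
                p = col[col > 0] / tot
                h = -(p * np.log2(p)).sum()
                acc += (tot / T) * 2.0 ** h
        expected = 0.5 * acc / 5
        assert weighted_connectance(cmat(values)) == pytest.approx(expected)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            linkage_density(
                cmat([[1, 0], [0, 1]]).__class__(
                    ("a", "b"), ("x", "y"), np.zeros((2, 2)), "counts")
            )


# ---------------------------------------------------------------------------
# Interaction strength asymmetry
# ---------------------------------------------------------------------------

class TestISA:
    def test_uniform_square_is_zero(self):
        assert interaction_strength_asymmetry(cmat(np.full((3, 3), 2.0))) == (
            pytest.approx(0.0))

    def test_shared_plant_sign_convention(self):
        # one plant visited by several single-host insects: those insects
        # depend fully on it while it spreads its dependence, so the
        # asymmetry is positive (higher trophic level more dependent)
        m = bmat([[1, 1, 1, 0], [0, 0, 0, 1], [0, 0, 0, 1]])
        values = m.values
        r = values.sum(axis=1)
        c = values.sum(axis=0)
        per_link = []
        for i in range(3):
            for j in range(4):
                if values[i, j]:
                    da = values[i, j] / c[j]
                    dp = values[i, j] / r[i]
                    per_link.append(((i, j), (da - dp) / max(da, dp)))
        hub_links = [v for (i, _), v in per_link if i == 0]
        assert all(v > 0 for v in hub_links)

    def test_toy_counts_against_bruteforce(self, rng):
        for _ in range(30):
            m = random_admitted_counts(rng, max_dim=4)
            values = m.values
            r = values.sum(axis=1)
            c = values.sum(axis=0)
            terms = []
            for i in range(values.shape[0]):
                for j in range(values.shape[1]):
                    if values[i, j] > 0:
                        da = values[i, j] / c[j]
                        dp = values[i, j] / r[i]
                        terms.append((da - dp) / max(da, dp))
            assert interaction_strength_asymmetry(m) == pytest.approx(np.mean(terms))
            assert -1.0 <= interaction_strength_asymmetry(m) <= 1.0


# ---------------------------------------------------------------------------
# H2' specialization
# ---------------------------------------------------------------------------

class TestH2:
    def test_uniform_weighted_diagonal_is_one(self):
        assert h2_specialization(cmat(np.eye(4) * 4)).h2_prime == pytest.approx(1.0)

    def test_outer_product_is_zero(self):
        # independence structure: a_ij proportional to r_i * c_j
        assert h2_specialization(bmat(np.ones((3, 3)))).h2_prime == pytest.approx(0.0)
        outer = np.outer([1, 2, 3], [2, 2, 2])
        assert h2_specialization(cmat(outer)).h2_prime == pytest.approx(0.0, abs=1e-9)

    def test_single_event_support_degenerates_to_zero(self):
        # unit-weight diagonal: every feasible table has the same entropy
        r = h2_specialization(bmat(np.eye(3)))
        assert r.h_min == pytest.approx(r.h_max)
        assert r.h2_prime == 0.0

    def test_scaling_counts_leaves_h2_nearly_invariant(self):
        base = np.array([[5.0, 1.0, 0.0], [1.0, 4.0, 2.0], [0.0, 1.0, 6.0]])
        h1 = h2_specialization(cmat(base)).h2_prime
        h3 = h2_specialization(cmat(base * 3)).h2_prime
        assert h3 == pytest.approx(h1, abs=0.05)

    def test_observed_entropy_between_bounds(self, rng):
        for _ in range(20):
            m = random_admitted_counts(rng)
            r = h2_specialization(m)
            assert r.h_min - 1e-9 <= r.h_observed <= r.h_max + 1e-9
            assert 0.0 <= r.h2_prime <= 1.0


class TestH2BoundsOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_heuristics_near_exhaustive_extrema(self, seed):
        rng = np.random.default_rng(900 + seed)
        while True:
            values = rng.integers(0, 3, size=(3, 3))
            rt, ct = values.sum(axis=1), values.sum(axis=0)
            if (rt > 0).all() and (ct > 0).all() and rt.max() <= 6 and ct.max() <= 6:
                break
        h_min, h_max = h2_entropy_bounds(rt, ct)
        entropies = [entropy(t) for t in enumerate_tables(tuple(rt), tuple(ct))]
        assert h_min <= min(entropies) + 0.05
        assert h_max >= max(entropies) - 0.05
        # heuristics can never escape the feasible set
        assert h_min >= min(entropies) - 1e-9
        assert h_max <= max(entropies) + 1e-9


class TestFullMetrics:
    def test_ranges_on_random_matrices(self, rng):
        for _ in range(10):
            m = random_admitted_counts(rng)
            r = full_metrics(m)
            assert 0 < r.C <= 1
            assert 0 <= r.NODF <= 100 and 0 <= r.WNODF <= 100
            assert 0 <= r.H2 <= 1
            assert -1 <= r.ISA <= 1
            assert 0 <= r.pct_spec_P <= 1 and 0 <= r.pct_spec_A <= 1
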