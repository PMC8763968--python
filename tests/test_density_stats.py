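"""Clustering, convex hulls and group statistics vs independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temquant.density_stats import (cell_profile, chi_square_2x2,
                                    cluster_vesicles, convex_hull_area,
                                    ks_two_sample, simulate_density_experiment,
                                    summarize_groups)


# ---------------------------------------------------------------------------
# brute-force oracles


def dbscan_oracle(pts, eps, min_pts):
    """Reachability-closure DBSCAN: core adjacency components + border
    attachment. Returns (labels-up-to-renaming signature, noise set)."""
    n = len(pts)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_pts}
    # connected components over core points
    comp = {}
    for i in core:
        if i in comp:
            continue
        stack, cid = [i], len(set(comp.values()))
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp[j] = cid
            stack.extend(k for k in neighbors[j] & core if k not in comp)
    clusters = {}
    for i, cid in comp.items():
        clusters.setdefault(cid, set()).add(i)
    border = {}
    for i in set(range(n)) - core:
        cands = {comp[j] for j in neighbors[i] if j in core}
        if cands:
            border[i] = cands          # ambiguous: any is a valid assignment
    noise = set(range(n)) - core - set(border)
    return comp, border, noise


def hull_area_oracle(pts):
    """Gift-wrapping hull + shoelace, independent of scipy."""
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    if len(pts) < 3:
        return None
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull, cur = [start], start
    while True:
        nxt = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u, v = pts[j] - pts[cur], pts[nxt] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross > 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[nxt] - pts[cur])):
                nxt = j
        if nxt == start:
            break
        hull.append(nxt)
        cur = nxt
        if len(hull) > len(pts):
            break
    h = pts[hull]
    if len(h) < 3:
        return None
    x, y = h[:, 0], h[:, 1]
    a = abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2
    return None if a == 0 else a


# ---------------------------------------------------------------------------
# clustering


class TestClustering:
    def test_two_distant_groups_form_two_clusters(self, rng):
        a = rng.normal(0, 10, (5, 2))
        b = rng.normal(0, 10, (5, 2)) + 1000.0
        labels = cluster_vesicles(np.vstack([a, b]), eps_nm=100, min_pts=3,
                                  nm_per_px=1.0)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_all_isolated_points_are_noise(self):
        pts = np.arange(10)[:, None] * [1000.0, 0.0]
        labels = cluster_vesicles(pts, eps_nm=10, min_pts=2, nm_per_px=1.0)
        assert set(labels) == {-1}

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_reachability_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        pts = rng.uniform(0, 100, (n, 2))
        eps, min_pts = 20.0, 3
        labels = cluster_vesicles(pts, eps_nm=eps, min_pts=min_pts,
                                  nm_per_px=1.0)
        comp, border, noise = dbscan_oracle(pts, eps, min_pts)
        # noise must match exactly
        assert set(np.flatnonzero(labels == -1)) == noise
        # core labels must match up to renaming
        mapping = {}
        for i, cid in comp.items():
            mapping.setdefault(labels[i], set()).add(cid)
        assert all(len(v) == 1 for v in mapping.values())
        inv = {next(iter(v)): k for k, v in mapping.items()}
        assert len(inv) == len(mapping)
        # border points must sit in one of their admissible clusters
        for i, cands in border.items():
            assert labels[i] in {inv[c] for c in cands}


# ---------------------------------------------------------------------------
# convex hull


class TestHullArea:
    def test_unit_square_corners(self):
        pts = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        assert convex_hull_area(pts, nm_per_px=1.0) == pytest.approx(1.0)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        assert convex_hull_area(pts) is None

    def test_fewer_than_three_points_degenerate(self):
        assert convex_hull_area(np.array([[0.0, 0.0], [1.0, 1.0]])) is None

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_gift_wrapping_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(0, 50, (int(rng.integers(3, 50)), 2))
        mine = convex_hull_area(pts, nm_per_px=1000.0)
        oracle = hull_area_oracle(pts)
        if oracle is None:
            assert mine is None
        else:
            assert mine == pytest.approx(oracle, rel=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_adding_a_point_never_decreases_area(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (8, 2))
        base = convex_hull_area(pts, nm_per_px=1000.0)
        bigger = convex_hull_area(
            np.vstack([pts, rng.uniform(0, 10, (1, 2))]), nm_per_px=1000.0)
        assert bigger >= base - 1e-12


# ---------------------------------------------------------------------------
# cell profiles


class TestCellProfile:
    def test_empty_cell(self):
        p = cell_profile([], cell_id="c0", group="WT")
        assert p.vesicle_count == 0 and not p.detectable
        assert p.density_per_um2 is None

    def test_square_corner_density(self):
        pts = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]],
                       dtype=float)
        p = cell_profile(pts, min_count=1, nm_per_px=1.0, eps_nm=2000.0)
        assert p.detectable
        assert p.density_per_um2 == pytest.approx(4.0)

    def test_generator_density_recovered(self):
        from temquant.synth import WT_VESICLE_DENSITY
        profiles = simulate_density_experiment(
            20, WT_VESICLE_DENSITY, seed=0, group="g")
        dens = [p.density_per_um2 for p in profiles
                if p.density_per_um2 is not None]
        # the raw hull underestimates the occupied field, so the recovered
        # density runs a little high; the median stays within 25%
        assert np.median(dens) == pytest.approx(WT_VESICLE_DENSITY, rel=0.25)

    def test_ripley_rasson_correction_tightens_recovery(self):
        from temquant.synth import WT_VESICLE_DENSITY
        raw = simulate_density_experiment(
            30, WT_VESICLE_DENSITY, seed=1, group="g")
        corr = simulate_density_experiment(
            30, WT_VESICLE_DENSITY, seed=1, group="g",
            area_estimator="ripley_rasson")
        m_raw = np.median([p.density_per_um2 for p in raw])
        m_corr = np.median([p.density_per_um2 for p in corr])
        assert abs(m_corr - WT_VESICLE_DENSITY) < \
            abs(m_raw - WT_VESICLE_DENSITY)
        assert m_corr == pytest.approx(WT_VESICLE_DENSITY, rel=0.15)

    def test_doubling_density_doubles_recovered_median(self):
        from temquant.synth import KO_VESICLE_DENSITY, WT_VESICLE_DENSITY
        lo = simulate_density_experiment(20, WT_VESICLE_DENSITY, seed=2,
                                         group="lo")
        hi = simulate_density_experiment(20, KO_VESICLE_DENSITY, seed=3,
                                         group="hi")
        m_lo = np.median([p.density_per_um2 for p in lo])
        m_hi = np.median([p.density_per_um2 for p in hi])
        assert m_hi / m_lo == pytest.approx(2.0, rel=0.30)


# ---------------------------------------------------------------------------
# statistics


class TestChiSquare:
    def test_homogeneous_table(self):
        c = chi_square_2x2([[10, 10], [10, 10]])
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_hand_computed_table(self):
        # margins 25 everywhere, E = 12.5, chi2 = 4 * 7.5^2/12.5 = 18
        c = chi_square_2x2([[20, 5], [5, 20]])
        assert c.statistic == pytest.approx(18.0, abs=1e-9)
        assert c.p_value == pytest.approx(2.209e-5, rel=1e-3)

    def test_row_and_column_swap_invariance(self, rng):
        t = rng.integers(1, 40, (2, 2))
        a = chi_square_2x2(t)
        b = chi_square_2x2(t[::-1, ::-1])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_bad_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestKS:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        c = ks_two_sample(x, x)
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_disjoint_supports(self):
        c = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert c.statistic == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        obs = ks_two_sample(x, y)

        def ks_stat(a, b):
            allv = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), allv, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), allv, side="right") / len(b)
            return np.abs(fa - fb).max()

        pooled = np.concatenate([x, y])
        count = total = 0
        for pick in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(pick)] = True
            d = ks_stat(pooled[mask], pooled[~mask])
            count += d >= obs.statistic - 1e-12
            total += 1
        assert obs.p_value == pytest.approx(count / total, abs=1e-6)


class TestSummaries:
    def test_closed_form_sem(self):
        profs = [cell_profile(np.array([[0, 0], [1000, 0], [1000, 1000],
                                        [0, 1000]]) * (1 + 0.1 * i),
                              group="g", min_count=1, nm_per_px=1.0,
                              eps_nm=5000.0)
                 for i in range(3)]
        s = summarize_groups(profs)["g"]
        dens = [p.density_per_um2 for p in profs]
        assert s["density_mean"] == pytest.approx(np.mean(dens))
        assert s["density_sem"] == pytest.approx(
            np.std(dens, ddof=1) / math.sqrt(3))

    def test_single_value_group_flagged(self):
        p = cell_profile(np.array([[0, 0], [1000, 0], [0, 1000], [900, 900]],
                                  dtype=float),
                         group="solo", min_count=1, nm_per_px=1.0,
                         eps_nm=5000.0)
        s = summarize_groups([p])["solo"]
        assert s["density_sem"] == 0.0 and s["sem_flagged_n1"]

    def test_sem_close_to_bootstrap_se(self, rng):
        vals = rng.gamma(4.0, 1.0, size=200)
        profs = []
        for i, v in enumerate(vals):
            # fabricate a profile carrying density v directly
            side = math.sqrt(4.0 / v) * 1000
            pts = np.array([[0, 0], [side, 0], [side, side], [0, side]])
            profs.append(cell_profile(pts, group="g", min_count=1,
                                      nm_per_px=1.0, eps_nm=1e7))
        s = summarize_groups(profs)["g"]
        dens = np.array([p.density_per_um2 for p in profs])
        boot = np.array([rng.choice(dens, 200).mean() for _ in range(2000)])
        assert s["density_sem"] == pytest.approx(boot.std(), rel=0.10)
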