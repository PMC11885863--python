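"""Rank-sum comparisons, flagging scheme, and superposition maps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootphen import mann_whitney, superposition_map, timeseries_compare
from rootphen.cohortstats import _rotate_mask_about_start


def permutation_pvalue(a, b):
    """Full enumeration oracle: two-sided p of the Mann-Whitney U under all
    C(n1+n2, n1) relabelings (no ties)."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = a + b
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(sample1):
        r1 = sum(ranks[v] for v in sample1)
        return r1 - n1 * (n1 + 1) / 2

    mid = n1 * n2 / 2
    obs = abs(u_of(a) - mid)
    count = total = 0
    for comb in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(comb) - mid) >= obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_samples_p_one(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(200))
    def test_exact_regime_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 13 - n1))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct => no ties
        a, b = vals[:n1], vals[n1:]
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(permutation_pvalue(a, b), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_u_statistic_identity(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(1, 20)), int(rng.integers(1, 20))
        a = rng.integers(0, 10, n1).astype(float)  # ties included
        b = rng.integers(0, 10, n2).astype(float)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(n1 * n2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def cohort_table(groups: dict, hours, rng, feature="angle"):
    """Tidy feature table: groups maps group id -> (n, mean, sd)."""
    rows = []
    for g, (n, mean, sd) in groups.items():
        for p in range(n):
            for h in hours:
                rows.append({"feature": feature, "hour": h, "group": g,
                             "plant_id": f"{g}{p}", "value": rng.normal(mean, sd)})
    return pd.DataFrame(rows)


class TestTimeseriesCompare:
    def test_flags_and_both_lines(self):
        rng = np.random.default_rng(0)
        df = cohort_table(
            {"wt": (15, 60, 5), "m1": (15, 80, 5), "m2": (15, 80, 5)},
            hours=[10, 11], rng=rng,
        )
        out = timeseries_compare(df, control="wt")
        assert set(out["group"]) == {"m1", "m2"}
        assert out["significant"].all()
        assert out["both_lines"].all()

    def test_both_lines_requires_every_line(self):
        rng = np.random.default_rng(1)
        df = cohort_table(
            {"wt": (15, 60, 5), "m1": (15, 85, 5), "m2": (15, 60.5, 5)},
            hours=[5], rng=rng,
        )
        out = timeseries_compare(df, control="wt")
        m1 = out[out.group == "m1"].iloc[0]
        assert m1["significant"] and not m1["both_lines"]

    def test_small_group_hours_skipped(self):
        rng = np.random.default_rng(2)
        df = cohort_table({"wt": (15, 60, 5), "m1": (15, 80, 5)}, [3], rng)
        df = pd.concat(
            [df, pd.DataFrame([{"feature": "angle", "hour": 4, "group": "m1",
                                "plant_id": "m1x", "value": 80.0}])]
        )
        out = timeseries_compare(df, control="wt")
        assert set(out["hour"]) == {3}

    def test_null_calibration(self):
        """Identical populations flag at about the nominal alpha: the
        false-flag rate over 100 seeded cohorts sits inside the binomial
        95% CI of 0.05."""
        rng = np.random.default_rng(12345)
        flags = total = 0
        for _ in range(100):
            df = cohort_table({"wt": (15, 60, 10), "m1": (15, 60, 10)},
                              hours=range(6), rng=rng)
            out = timeseries_compare(df, control="wt")
            flags += int(out["significant"].sum())
            total += len(out)
        rate = flags / total
        half = 1.96 * math.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= half

    def test_power_monotone_in_offset(self):
        """Detection of an injected angle offset rises with its size and
        reaches >= 90% at 20 degrees (n = 15 per group)."""
        rng = np.random.default_rng(99)
        rates = []
        for off in (5.0, 10.0, 20.0):
            det = 0
            for _ in range(20):
                df = cohort_table({"wt": (15, 60, 10), "m1": (15, 60 + off, 10)},
                                  hours=[0], rng=rng)
                out = timeseries_compare(df, control="wt")
                det += int(out["significant"].iloc[0])
            rates.append(det / 20)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9

    def test_fdr_flag_available(self):
        rng = np.random.default_rng(3)
        df = cohort_table({"wt": (10, 60, 5), "m1": (10, 62, 5)}, range(8), rng)
        out = timeseries_compare(df, control="wt", fdr=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


def plant_mask(shape=(60, 40)):
    mask = np.zeros(shape, dtype=np.uint8)
    rr = np.arange(5, 50)
    cc = (20 + 0.3 * (rr - 5)).astype(int)   # slanted MR
    mask[rr, cc] = 1
    mask[30, 25:35] = 1                      # one lateral
    start, end = (5, 20), (49, int(20 + 0.3 * 44))
    return mask, start, end


class TestSuperposition:
    def test_single_plant_counts(self):
        mask, start, end = plant_mask()
        smap = superposition_map([(mask, start, end)], out_shape=(90, 80),
                                 reference_px=(10, 40))
        rotated = _rotate_mask_about_start(mask, start, end, (10, 40), (90, 80))
        assert smap.counts.max() == 1
        assert smap.counts.sum() == rotated.sum()

    def test_n_copies_stack_to_n(self):
        mask, start, end = plant_mask()
        n = 5
        smap = superposition_map([(mask, start, end)] * n, out_shape=(90, 80),
                                 reference_px=(10, 40))
        nz = smap.counts[smap.counts > 0]
        assert smap.n_plants == n
        assert np.all(nz == n)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        plants = []
        for _ in range(4):
            mask, start, end = plant_mask()
            plants.append((mask, start, end))
        smap = superposition_map(plants, out_shape=(100, 90), reference_px=(12, 45))
        per_plant = sum(
            _rotate_mask_about_start(m, s, e, (12, 45), (100, 90)).sum()
            for m, s, e in plants
        )
        assert smap.counts.sum() == per_plant

    @pytest.mark.parametrize("angle_deg", [-60, -25, 0, 30, 75])
    def test_mr_end_lands_on_vertical_through_reference(self, angle_deg):
        """After rotation the MR chord is vertical: the end pixel sits on the
        reference column (within 1 px)."""
        shape = (120, 220)
        mask = np.zeros(shape, dtype=np.uint8)
        start = (20, 110)
        L = 70
        er = int(round(start[0] + L * math.cos(math.radians(angle_deg))))
        ec = int(round(start[1] + L * math.sin(math.radians(angle_deg))))
        from skimage.draw import line

        rr, cc = line(*start, er, ec)
        mask[rr, cc] = 1
        ref = (15, 110)
        rotated = _rotate_mask_about_start(mask, start, (er, ec), ref, (160, 220))
        rows, cols = np.nonzero(rotated)
        bottom = rows.argmax()
        assert abs(cols[bottom] - ref[1]) <= 1
        assert rows.max() - ref[0] == pytest.approx(
            math.dist(start, (er, ec)), abs=2
        )

    def test_degenerate_plant_excluded(self):
        mask, start, end = plant_mask()
        smap = superposition_map([(mask, start, end), (mask, start, start)],
                                 out_shape=(90, 80), reference_px=(10, 40))
        assert smap.n_plants == 1
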