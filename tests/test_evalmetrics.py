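"""DSC / ICC / ASD metrics against independent oracles; method comparison."""

import numpy as np
import pytest
from scipy import ndimage, stats

from idseg.evalmetrics import (MetricReport, STRUCTURE_NAMES, aggregate_reports,
                               asd, compare_methods, dsc, evaluate_pair, icc)
from idseg.io_prep import LabelMap


# ---------------------------------------------------------------------------
# brute-force oracles


def dsc_brute(a, b):
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    sa, sb = int(a.sum()), int(b.sum())
    return float("nan") if sa + sb == 0 else 2.0 * inter / (sa + sb)


def surface_brute(mask):
    pts = []
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = list(idx)
                nb[ax] += d
                if not (0 <= nb[ax] < mask.shape[ax]) or not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return pts


def asd_brute(a, b, spacing):
    sa, sb = surface_brute(a), surface_brute(b)
    if not sa or not sb:
        return float("nan")
    sp = np.asarray(spacing)

    def directed(src, dst):
        total = 0.0
        for p in src:
            best = min(np.sqrt((((np.array(p) - np.array(q)) * sp) ** 2).sum())
                       for q in dst)
            total += best
        return total / len(src)

    return 0.5 * (directed(sa, sb) + directed(sb, sa))


# ---------------------------------------------------------------------------


class TestDsc:
    def test_examples(self):
        a = np.zeros((3, 3, 1), bool)
        b = np.zeros((3, 3, 1), bool)
        a[:2, :2] = True              # |A| = 4
        b[1:, :2] = True              # |B| = 4, overlap 2
        assert dsc(a, b) == pytest.approx(0.5)
        assert dsc(a, a) == 1.0
        assert dsc(a, ~a) == 0.0
        assert np.isnan(dsc(np.zeros_like(a), np.zeros_like(b)))

    def test_symmetry_fuzzed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((4, 5, 3)) < 0.4
            b = rng.random((4, 5, 3)) < 0.4
            assert dsc(a, b) == dsc(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((3, 2, 2), bool))

    def test_exhaustive_small_masks_match_brute_force(self):
        # all 2^9 3x3x1 masks against a subsample of partners
        rng = np.random.default_rng(1)
        masks = [np.array([(m >> i) & 1 for i in range(9)], bool).reshape(3, 3, 1)
                 for m in range(512)]
        for a in masks:
            for b in (masks[i] for i in rng.integers(0, 512, 4)):
                got, want = dsc(a, b), dsc_brute(a, b)
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestIcc:
    def test_perfect_agreement(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        assert icc(a, a.copy()) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        roi = np.ones_like(a)
        assert icc(a, ~a, roi=roi) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_icc3(self, seed):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) < 0.5
        b = rng.random((6, 6, 6)) < 0.5
        roi = np.ones_like(a)
        mine = icc(a, b, roi=roi)
        n = a.size
        df = pd.DataFrame({
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["r1", "r2"], n),
            "score": np.concatenate([a.ravel(), b.ravel()]).astype(float),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        consistency_single = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        want = float(ref.loc[consistency_single, "ICC"].iloc[0])
        assert mine == pytest.approx(want, abs=1e-8)

    def test_zero_variance_sentinel(self):
        a = np.zeros((4, 4, 4), bool)
        assert np.isnan(icc(a, a.copy(), roi=np.ones_like(a)))


class TestAsd:
    def test_identical_masks_zero(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:4, 1:4, 1:4] = True
        assert asd(a, a.copy()) == 0.0

    def test_two_voxels_two_apart_half_mm(self):
        a = np.zeros((7, 3, 3), bool)
        b = np.zeros((7, 3, 3), bool)
        a[2, 1, 1] = True
        b[4, 1, 1] = True
        assert asd(a, b, spacing=(0.5, 0.5, 0.5)) == pytest.approx(1.0)

    def test_empty_mask_sentinel(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        b[1, 1, 1] = True
        assert np.isnan(asd(a, b))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_blobs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = (6, 5, 4)
        a = ndimage.binary_dilation(rng.random(shape) < 0.1)
        b = ndimage.binary_dilation(rng.random(shape) < 0.1)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        spacing = (0.9, 1.1, 0.7)
        assert asd(a, b, spacing) == pytest.approx(asd_brute(a, b, spacing), abs=1e-9)

    def test_symmetry_and_spacing_scaling(self):
        rng = np.random.default_rng(9)
        a = ndimage.binary_dilation(rng.random((6, 6, 6)) < 0.08)
        b = ndimage.binary_dilation(rng.random((6, 6, 6)) < 0.08)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        assert asd(a, b) == pytest.approx(asd(b, a))
        assert asd(a, b, (2.0, 2.0, 2.0)) == pytest.approx(2.0 * asd(a, b), rel=1e-12)


class TestEvaluatePair:
    def test_perfect_prediction(self, default_phantom):
        _, lab = default_phantom
        rep = evaluate_pair(lab, lab)
        for name in STRUCTURE_NAMES.values():
            assert rep.values[name]["dsc"] == 1.0
            assert rep.values[name]["icc"] == pytest.approx(1.0)
            assert rep.values[name]["asd"] == 0.0

    def test_missing_structure_isolated(self, default_phantom):
        _, lab = default_phantom
        pred = LabelMap(np.where(lab.codes == 4, 0, lab.codes).astype(np.int16),
                        lab.label_set, lab.spacing)
        rep = evaluate_pair(pred, lab)
        assert np.isnan(rep.values["right_amygdala"]["asd"])
        assert "right_amygdala" in rep.reasons
        assert rep.values["left_amygdala"]["dsc"] == 1.0

    def test_label_set_mismatch(self, default_phantom):
        _, lab = default_phantom
        other = LabelMap(np.zeros_like(lab.codes), frozenset({0, 1}))
        with pytest.raises(ValueError, match="label-set"):
            evaluate_pair(other, lab)

    def test_batch_aggregation_matches_hand_means(self, default_phantom):
        _, lab = default_phantom
        reports = []
        vals = []
        for shift in (0, 1):
            pred = np.roll(lab.codes, shift, axis=0)
            rep = evaluate_pair(LabelMap(pred, lab.label_set, lab.spacing), lab)
            reports.append(rep)
            vals.append(rep.values["left_hippocampus"]["dsc"])
        agg = aggregate_reports(reports)
        row = agg[(agg.structure == "left_hippocampus") & (agg.metric == "dsc")]
        assert float(row["mean"].iloc[0]) == pytest.approx(np.mean(vals))


def _report(value):
    return MetricReport({"s": {"dsc": value}})


class TestCompareMethods:
    def test_identical_groups_null_f(self):
        rng = np.random.default_rng(0)
        vals = rng.random(10)
        methods = {m: [_report(v) for v in vals] for m in ("a", "b", "c")}
        out = compare_methods(methods)
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_f_consistent_with_df_between_2(self):
        rng = np.random.default_rng(1)
        methods = {m: [_report(v) for v in rng.random(12)] for m in ("a", "b", "c")}
        out = compare_methods(methods)
        f, p = out["F"].iloc[0], out["p"].iloc[0]
        # recomputing p from F with df = (k-1, N-k) = (2, 33) must agree
        assert p == pytest.approx(float(stats.f.sf(f, 2, 33)), rel=1e-10)

    def test_unequal_subject_sets_error(self):
        with pytest.raises(ValueError, match="unequal"):
            compare_methods({"a": [_report(0.5)] * 3, "b": [_report(0.5)] * 4})

    def test_power_under_one_sd_shift(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            methods = {
                "a": [_report(v) for v in rng.normal(0.0, 1.0, 20)],
                "b": [_report(v) for v in rng.normal(1.0, 1.0, 20)],
                "c": [_report(v) for v in rng.normal(0.0, 1.0, 20)],
            }
            out = compare_methods(methods)
            hits += bool(out["p_adj"].iloc[0] < 0.05)
        assert hits / reps >= 0.8
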