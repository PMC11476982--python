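import numpy as np
import pytest

from repdil.curves import (
    classical_efficiency,
    cqcq_fit,
    fit_collinear,
    flag_outliers,
    refit_without_outliers,
)
from repdil.synthetic import make_ground_truth, simulate

from conftest import random_ground_truth


def oracle_lstsq(ds, amplicon):
    """Independent normal-equations solve on an explicitly built design."""
    sub = ds.wells[(ds.wells["amplicon"] == amplicon) & ds.wells["cq"].notna()]
    # keep only replicates with >=2 distinct dilutions
    ok = sub.groupby(["group", "replicate_id"])["dilution"].transform("nunique") >= 2
    sub = sub[ok]
    reps = list(dict.fromkeys(zip(sub["group"], sub["replicate_id"])))
    x = []
    for _, row in sub.iterrows():
        ind = [1.0 if (row["group"], row["replicate_id"]) == k else 0.0 for k in reps]
        x.append(ind + [np.log10(row["dilution"])])
    x = np.asarray(x)
    y = sub["cq"].to_numpy(float)
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return {k: beta[i] for i, k in enumerate(reps)}, beta[-1]


def test_noiseless_recovery_slope_efficiency_r2():
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=3,
        efficiencies={"RG": 2.0, "G": 2.0},
    )
    ds, _ = simulate(gt)
    fit = fit_collinear(ds, "G")
    assert fit.slope_b == pytest.approx(np.log2(10), abs=1e-9)  # 3.321928...
    assert fit.efficiency_E == pytest.approx(2.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    assert fit.n_wells_used == 9


def test_intercept_difference_encodes_template_ratio():
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}, "B": {"RG": 1.0, "G": 0.5}}, n_replicates=1
    )
    ds, _ = simulate(gt)
    fit = fit_collinear(ds, "G")
    a1 = fit.intercepts_a[("A", "1")]
    a2 = fit.intercepts_a[("B", "1")]
    assert a2 - a1 == pytest.approx(1.0, abs=1e-9)


def test_collinear_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        ds, gt = simulate(random_ground_truth(rng))
        for amp in gt.amplicons:
            fit = fit_collinear(ds, amp)
            intercepts, slope = oracle_lstsq(ds, amp)
            assert fit.slope_b == pytest.approx(slope, abs=1e-10)
            for k, a in intercepts.items():
                assert fit.intercepts_a[k] == pytest.approx(a, abs=1e-10)


def test_noisy_efficiency_recovery_median_error():
    """With sd 0.2 cycles and 9 replicates, Ê is within 0.05 of truth."""
    errs = []
    for seed in range(100):
        gt = make_ground_truth(
            {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=9,
            efficiencies={"RG": 2.0, "G": 1.9},
            noise_sd=0.2, seed=seed,
        )
        ds, _ = simulate(gt)
        errs.append(abs(fit_collinear(ds, "G").efficiency_E - 1.9))
    assert np.median(errs) < 0.05


def test_slope_se_decreases_with_replicates():
    ses = []
    for n in (2, 4, 8):
        gt = make_ground_truth(
            {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=n,
            noise_sd=0.2, seed=3,
        )
        ds, _ = simulate(gt)
        ses.append(fit_collinear(ds, "G").slope_se)
    assert ses[0] >= ses[1] >= ses[2]


def test_outlier_flagging_finds_injected_well():
    gt = make_ground_truth({"A": {"RG": 1.0, "G": 1.0}}, n_replicates=4)
    ds, _ = simulate(gt)
    idx = ds.wells[(ds.wells["amplicon"] == "G")].index[4]
    ds.wells.loc[idx, "cq"] += 5.0
    fit = flag_outliers(fit_collinear(ds, "G"))
    flagged = fit.outlier_flags[fit.outlier_flags].index.tolist()
    assert flagged == [idx]
    # refit on request recovers the clean fit
    refit = refit_without_outliers(ds, fit)
    assert refit.efficiency_E == pytest.approx(2.0, abs=1e-9)


def test_no_flags_on_clean_data_or_infinite_threshold():
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=4, noise_sd=0.3, seed=1
    )
    ds, _ = simulate(gt)
    fit = fit_collinear(ds, "G")
    assert not flag_outliers(fit, threshold=np.inf).outlier_flags.any()
    gt0 = make_ground_truth({"A": {"RG": 1.0, "G": 1.0}}, n_replicates=4)
    ds0, _ = simulate(gt0)
    assert not flag_outliers(fit_collinear(ds0, "G")).outlier_flags.any()


def test_flagging_warns_with_few_degrees_of_freedom():
    gt = make_ground_truth({"A": {"RG": 1.0, "G": 1.0}}, n_replicates=1)
    ds, _ = simulate(gt)
    fit = fit_collinear(ds, "G")  # 3 wells, 2 params -> df_resid = 1
    with pytest.warns(UserWarning, match="degrees of freedom"):
        out = flag_outliers(fit)
    assert not out.outlier_flags.any()


def test_cqcq_slope_ratio_and_offsets():
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 2.0}}, n_replicates=3,
        efficiencies={"RG": 2.0, "G": 2.0},
    )
    ds, _ = simulate(gt)
    cc = cqcq_fit(fit_collinear(ds, "G"), fit_collinear(ds, "RG"))
    assert cc.slope_ratio == pytest.approx(1.0, abs=1e-9)
    # identical normalized expression in all replicates -> equal offsets
    offs = list(cc.offsets.values())
    np.testing.assert_allclose(offs, offs[0], atol=1e-9)


def test_cqcq_slope_ratio_for_unequal_efficiencies():
    e_goi, slope_rg = 2.0, 3.5
    e_rg = 10 ** (1 / slope_rg)  # ~1.9307
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=2,
        efficiencies={"RG": e_rg, "G": e_goi},
    )
    ds, _ = simulate(gt)
    cc = cqcq_fit(fit_collinear(ds, "G"), fit_collinear(ds, "RG"))
    assert cc.slope_ratio == pytest.approx(np.log2(10) / 3.5, abs=1e-9)  # 0.949122


@pytest.mark.parametrize(
    "slope,expected", [(-np.log2(10), 2.0), (-3.5, 1.930698)]
)
def test_classical_efficiency_formula(slope, expected):
    conc = np.array([1.0, 0.2, 0.04])
    cq = 20.0 + slope * np.log10(conc)
    assert classical_efficiency(list(zip(conc, cq))) == pytest.approx(
        expected, abs=1e-6
    )


def test_classical_efficiency_requires_three_points():
    with pytest.raises(ValueError):
        classical_efficiency([(1.0, 20.0), (0.2, 22.0)])


def test_classical_and_collinear_conventions_agree():
    """E from Cq~log10(1/D) with negative slope equals 10^(1/b)."""
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=1,
        efficiencies={"RG": 1.9, "G": 1.9},
    )
    ds, _ = simulate(gt)
    g = ds.wells[ds.wells["amplicon"] == "G"]
    series = list(zip(1.0 / g["dilution"], g["cq"]))
    fit = fit_collinear(ds, "G")
    assert classical_efficiency(series) == pytest.approx(
        fit.efficiency_E, abs=1e-9
    )


def test_rank_deficient_design_rejected():
    gt = make_ground_truth(
        {"A": {"RG": 1.0, "G": 1.0}}, n_replicates=2,
        dilution_factors=[1.0, 5.0],
    )
    ds, _ = simulate(gt)
    ds.wells = ds.wells[ds.wells["dilution"] == 1.0].reset_index(drop=True)
    with pytest.raises(ValueError):
        fit_collinear(ds, "G")
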