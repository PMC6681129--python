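"""Pearson testing, Bonferroni control, replication labeling and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycoproteomap.association import (
    association_matrix,
    bonferroni_threshold,
    consistency_report,
    discovery_scan,
    pearson_test,
    replicate,
    summarize,
)


def test_perfect_linearity():
    res = pearson_test([1, 2, 3], [2, 4, 6])
    assert res.r == pytest.approx(1.0)
    assert res.p == 0.0
    assert res.n == 3


def test_hand_computed_three_point_case():
    # r = sqrt(3)/2; t = sqrt(3) on 1 df, two-sided Cauchy-tail p = 1/3
    res = pearson_test([1, 2, 3], [1, 2, 2])
    assert res.r == pytest.approx(np.sqrt(3) / 2, rel=1e-12)
    assert res.p == pytest.approx(1.0 / 3.0, rel=1e-9)


def test_perfect_anticorrelation():
    res = pearson_test([1, 2, 3, 4], [4, 3, 2, 1])
    assert res.r == pytest.approx(-1.0)
    assert res.p == 0.0


def test_pairwise_complete_and_errors():
    res = pearson_test([1, 2, 3, np.nan, 5], [2, 4, 6, 8, np.nan])
    assert res.n == 3
    with pytest.raises(ValueError, match="constant"):
        pearson_test([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError, match=">= 3"):
        pearson_test([1, 2, np.nan], [1, 2, 3])


def test_symmetry_in_x_and_y():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=30), rng.normal(size=30)
    a, b = pearson_test(x, y), pearson_test(y, x)
    assert (a.r, a.p, a.n) == (b.r, b.p, b.n)


@given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
@settings(derandomize=True, max_examples=50)
def test_affine_invariance(scale, shift):
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=25), rng.normal(size=25)
    base = pearson_test(x, y)
    up = pearson_test(scale * x + shift, y)
    down = pearson_test(-scale * x + shift, y)
    assert up.r == pytest.approx(base.r, abs=1e-9)
    assert down.r == pytest.approx(-base.r, abs=1e-9)
    assert up.p == pytest.approx(base.p, rel=1e-6, abs=1e-12)


def test_t_p_value_matches_permutation_oracle():
    """On random small vectors the t-formula p agrees with a permutation p."""
    rng = np.random.default_rng(123)
    n, n_perm = 12, 2000
    for _ in range(20):
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = pearson_test(x, y)
        xc = x - x.mean()
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        yp = y[perms]
        ypc = yp - yp.mean(axis=1, keepdims=True)
        r_perm = (ypc @ xc) / np.sqrt((ypc ** 2).sum(axis=1) * (xc @ xc))
        p_perm = (np.sum(np.abs(r_perm) >= abs(res.r) - 1e-12) + 1) / (n_perm + 1)
        assert abs(p_perm - res.p) < 0.05


def test_bonferroni_threshold():
    assert f"{bonferroni_threshold(1116, 113):.2e}" == "3.96e-07"
    assert bonferroni_threshold(1, 1) == pytest.approx(0.05)
    assert bonferroni_threshold(50, 113) == pytest.approx(8.85e-6, rel=1e-3)
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 113)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 10, alpha=1.5)


def _cohort(n, n_prot, n_gly, seed, planted_r=None):
    """Independent normals; optionally plant corr(protein 0, glycan 0) = r."""
    rng = np.random.default_rng(seed)
    prot = rng.normal(size=(n, n_prot))
    gly = rng.normal(size=(n, n_gly))
    if planted_r is not None:
        gly[:, 0] = planted_r * prot[:, 0] + np.sqrt(1 - planted_r ** 2) * rng.normal(size=n)
    idx = [f"S{i}" for i in range(n)]
    return (pd.DataFrame(prot, index=idx, columns=[f"P{j}" for j in range(n_prot)]),
            pd.DataFrame(gly, index=idx, columns=[f"G{j}" for j in range(n_gly)]))


def test_discovery_scan_is_cartesian_and_ordered():
    prot, gly = _cohort(20, 2, 2, seed=0)
    rec = discovery_scan(prot, gly)
    assert len(rec) == 4
    assert rec["glycan_id"].tolist() == ["G0", "G0", "G1", "G1"]  # glycan-major
    assert rec["protein_id"].tolist() == ["P0", "P1", "P0", "P1"]
    assert set(rec["status"]) <= {"discovered", "not_significant"}


def test_discovery_scan_finds_strong_planted_pair():
    for seed in range(5):
        prot, gly = _cohort(344, 5, 8, seed=seed, planted_r=0.6)
        rec = discovery_scan(prot, gly)
        row = rec[(rec.protein_id == "P0") & (rec.glycan_id == "G0")].iloc[0]
        assert row.status == "discovered"
        assert row.n_disc == 344


def test_discovery_scan_matches_pearson_test_per_pair():
    prot, gly = _cohort(40, 3, 4, seed=5)
    prot.iloc[3, 0] = np.nan
    gly.iloc[7, 2] = np.nan
    rec = discovery_scan(prot, gly)
    for row in rec.itertuples(index=False):
        ref = pearson_test(prot[row.protein_id], gly[row.glycan_id])
        assert row.r_disc == pytest.approx(ref.r, rel=1e-12)
        assert row.p_disc == pytest.approx(ref.p, rel=1e-9)
        assert row.n_disc == ref.n


def test_replication_rule_labels():
    """Same-sign nominal -> replicated; opposite-sign -> conflicting; weak -> not."""
    n = 40
    rng = np.random.default_rng(9)
    prot, gly = _cohort(344, 3, 1, seed=1)
    # make all three protein-glycan pairs strongly discovered
    for j in range(3):
        gly[f"G{j}"] = 0.0  # placeholder
    gly = pd.DataFrame({f"G{j}": 0.7 * prot[f"P{j}"] +
                        0.5 * rng.normal(size=len(prot)) for j in range(3)},
                       index=prot.index)
    rec = discovery_scan(prot, gly)
    assert (rec.loc[rec.protein_id == rec.glycan_id.str.replace("G", "P"),
                    "status"] == "discovered").all()

    # replication cohort engineered per pair
    rep_prot = pd.DataFrame(rng.normal(size=(n, 3)), columns=["P0", "P1", "P2"],
                            index=[f"R{i}" for i in range(n)])
    rep_gly = pd.DataFrame(index=rep_prot.index, columns=["G0", "G1", "G2"],
                           dtype=float)
    rep_gly["G0"] = rep_prot["P0"] + 0.2 * rng.normal(size=n)        # same sign, strong
    rep_gly["G1"] = -rep_prot["P1"] + 0.2 * rng.normal(size=n)       # opposite sign
    rep_gly["G2"] = rng.normal(size=n)                               # null
    out = replicate(rec, rep_prot, rep_gly)

    def status(p, g):
        return out[(out.protein_id == p) & (out.glycan_id == g)].iloc[0].status

    assert status("P0", "G0") == "replicated"
    assert status("P1", "G1") == "conflicting"
    assert status("P2", "G2") == "not_replicated"
    # non-discovered records are never upgraded
    assert (out.loc[out.p_disc >= out.attrs["bonferroni_threshold"], "status"]
            == "not_significant").all()


def test_replication_boundary_is_strict():
    rec = pd.DataFrame({
        "protein_id": ["P0"], "glycan_id": ["G0"],
        "r_disc": [0.5], "p_disc": [1e-8], "n_disc": [344],
        "status": ["discovered"],
    })
    # replication data whose correlation p lands just above 0.05
    rng = np.random.default_rng(3)
    n = 30
    x = rng.normal(size=n)
    y = 0.1 * x + rng.normal(size=n)
    rep_prot = pd.DataFrame({"P0": x}, index=[f"R{i}" for i in range(n)])
    rep_gly = pd.DataFrame({"G0": y}, index=rep_prot.index)
    p_rep = pearson_test(x, y).p
    out = replicate(rec, rep_prot, rep_gly)
    expected = "replicated" if p_rep < 0.05 else "not_replicated"
    assert out.iloc[0].status == expected
    # forcing the cutoff right at the achieved p keeps it non-replicated (strict <)
    out2 = replicate(rec, rep_prot, rep_gly, p_cutoff=p_rep)
    assert out2.iloc[0].status == "not_replicated"


def test_replication_untestable_pair():
    rec = pd.DataFrame({
        "protein_id": ["P0"], "glycan_id": ["G0"],
        "r_disc": [0.5], "p_disc": [1e-8], "n_disc": [344],
        "status": ["discovered"],
    })
    rep_prot = pd.DataFrame({"P0": [1.0, 2.0]}, index=["a", "b"])
    rep_gly = pd.DataFrame({"G0": [1.0, 2.0]}, index=["a", "b"])
    out = replicate(rec, rep_prot, rep_gly)
    assert out.iloc[0].status == "not_replicated"
    assert "untestable" in out.iloc[0].replication_note


def _records(rows):
    df = pd.DataFrame(rows, columns=["protein_id", "glycan_id", "r_disc", "p_disc",
                                     "r_rep", "p_rep", "status"])
    df["n_disc"] = 344
    df["n_rep"] = 46
    return df


def test_association_matrix_signed_r_squared():
    rec = _records([("IgG", "PGP69", -0.69, 8.0e-50, -0.36, 1.5e-2, "replicated")])
    mat = association_matrix(rec)
    assert mat.shape == (1, 1)
    assert mat.loc["PGP69", "IgG"] == pytest.approx(-0.4761)


def test_association_matrix_empty_and_shared_protein():
    assert association_matrix(_records([])).shape == (0, 0)
    rec = _records([
        ("IgG", "PGP93", 0.68, 3.7e-47, 0.31, 3.7e-2, "replicated"),
        ("IgG", "PGP75", 0.44, 1.3e-17, 0.35, 1.9e-2, "replicated"),
        ("IgM", "PGP16", 0.59, 3.6e-34, 0.61, 6.0e-6, "not_replicated"),
    ])
    mat = association_matrix(rec)
    assert mat.shape == (2, 1)
    assert list(mat.columns) == ["IgG"]
    assert np.sign(mat.loc["PGP93", "IgG"]) == np.sign(0.68)


def test_consistency_report_concordance():
    rec = _records([
        ("A", "G1", 0.5, 1e-9, 0.4, 0.01, "replicated"),
        ("A", "G2", -0.4, 1e-8, -0.2, 0.2, "not_replicated"),
        ("B", "G3", 0.3, 1e-7, 0.1, 0.4, "not_replicated"),
    ])
    table, concordance = consistency_report(rec)
    assert concordance == 1.0
    assert table["r_disc"].abs().is_monotonic_decreasing


def test_consistency_null_concordance_near_half():
    rng = np.random.default_rng(21)
    rows = [(f"P{i}", f"G{i}", r1, 1e-8, r2, 0.5, "not_replicated")
            for i, (r1, r2) in enumerate(zip(rng.uniform(-1, 1, 200),
                                             rng.uniform(-1, 1, 200)))]
    _, concordance = consistency_report(_records(rows))
    assert abs(concordance - 0.5) < 0.1


def test_summarize_counts():
    rec = _records([
        ("A", "G1", 0.5, 1e-9, 0.4, 0.01, "replicated"),
        ("B", "G1", 0.4, 1e-8, -0.3, 0.02, "conflicting"),
        ("C", "G2", 0.1, 0.2, np.nan, np.nan, "not_significant"),
    ])
    s = summarize(rec)
    assert s["counts_by_status"]["replicated"] == 1
    assert s["counts_by_status"]["conflicting"] == 1
    assert s["pairs_tested"] == 3
    assert s["replicated_glycans"] == 1 and s["replicated_proteins"] == 1
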