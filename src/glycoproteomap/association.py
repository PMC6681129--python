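"""All-pairs protein-glycan association with discovery-replication design.

Every protein feature is tested against every glycan trait by Pearson
correlation on inverse-normal scaled values.  Discovery uses a Bonferroni
threshold over the full pair grid; a discovered pair replicates if it is
nominally significant (p < 0.05) in the second cohort *and* the correlation
has the same sign.  Replicated pairs are assembled into a glycan x protein
matrix of signed r-squared values.

Missing values are handled pairwise-complete: each pair's n is the number
of samples with both measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PearsonResult",
    "pearson_test",
    "bonferroni_threshold",
    "pairwise_pearson",
    "discovery_scan",
    "replicate",
    "association_matrix",
    "consistency_report",
    "STATUS_ORDER",
]

STATUS_ORDER = ("not_significant", "discovered", "replicated",
                "conflicting", "not_replicated")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson_test(x, y) -> PearsonResult:
    """Pearson correlation with a two-sided t-test p-value.

    Uses pairwise-complete observations; ``p`` comes from
    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` against the t distribution with
    ``n - 2`` degrees of freedom, with ``|r| = 1`` mapping to ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 pairwise-complete observations, got {n}")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("correlation undefined for a constant input")
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    r = float(xs @ ys / np.sqrt((xs @ xs) * (ys @ ys)))
    r = max(-1.0, min(1.0, r))
    p = _p_from_r(np.array(r), n)
    return PearsonResult(r, float(p), n)


def _p_from_r(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n (array-friendly)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2.0) / np.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def bonferroni_threshold(n_proteins: int, n_glycans: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (n_proteins * n_glycans)."""
    if n_proteins < 1 or n_glycans < 1:
        raise ValueError("feature counts must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (n_proteins * n_glycans)


def pairwise_pearson(x: pd.DataFrame, y: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r, p and n for every column pair.

    Returns arrays of shape (x columns, y columns).  Pairs with n < 3 or a
    constant margin get r = p = nan.
    """
    if not x.index.equals(y.index):
        raise ValueError("sample ids must match between the two matrices")
    X = x.to_numpy(dtype=float)
    Y = y.to_numpy(dtype=float)
    Mx = (~np.isnan(X)).astype(float)
    My = (~np.isnan(Y)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    Y0 = np.where(np.isnan(Y), 0.0, Y)

    n = Mx.T @ My
    sx = X0.T @ My
    sy = Mx.T @ Y0
    sxx = (X0 * X0).T @ My
    syy = Mx.T @ (Y0 * Y0)
    sxy = X0.T @ Y0

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        denom = np.sqrt(vx * vy)
        r = cov / denom
    bad = (n < 3) | ~np.isfinite(r)
    r = np.clip(np.where(bad, np.nan, r), -1.0, 1.0)
    p = np.where(bad, np.nan, _p_from_r(r, n))
    return r, p, n.astype(int)


def discovery_scan(proteins: pd.DataFrame, glycans: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Test every protein x glycan pair in the discovery cohort.

    Returns one row per pair, glycan-major then protein order, with columns
    protein_id, glycan_id, r_disc, p_disc, n_disc and status
    ("discovered" where p_disc < alpha / (n_proteins * n_glycans), else
    "not_significant").
    """
    common = proteins.index.intersection(glycans.index)
    if len(common) == 0:
        raise ValueError("no shared samples between protein and glycan matrices")
    prot = proteins.loc[common]
    gly = glycans.loc[common]
    thr = bonferroni_threshold(prot.shape[1], gly.shape[1], alpha)
    r, p, n = pairwise_pearson(gly, prot)  # glycans x proteins

    g_ids = np.repeat(gly.columns.to_numpy(), prot.shape[1])
    p_ids = np.tile(prot.columns.to_numpy(), gly.shape[1])
    records = pd.DataFrame({
        "protein_id": p_ids,
        "glycan_id": g_ids,
        "r_disc": r.ravel(),
        "p_disc": p.ravel(),
        "n_disc": n.ravel(),
    })
    records["status"] = np.where(records["p_disc"] < thr, "discovered", "not_significant")
    records.attrs["bonferroni_threshold"] = thr
    records.attrs["alpha"] = alpha
    return records


def replicate(records: pd.DataFrame, rep_proteins: pd.DataFrame,
              rep_glycans: pd.DataFrame, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Attempt replication of every discovered pair in a second cohort.

    A discovered pair becomes ``replicated`` if its replication p-value is
    below *p_cutoff* (strict) and the replication correlation has the same
    (nonzero) sign as the discovery correlation; ``conflicting`` if
    nominally significant with the opposite sign; ``not_replicated``
    otherwise (including untestable pairs with replication n < 3 and pairs
    with an exactly zero replication r, whose sign is undefined).
    Records that were not discovered are never upgraded.
    """
    common = rep_proteins.index.intersection(rep_glycans.index)
    prot = rep_proteins.loc[common]
    gly = rep_glycans.loc[common]

    out = records.copy()
    out["r_rep"] = np.nan
    out["p_rep"] = np.nan
    out["n_rep"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["replication_note"] = ""

    disc = out.index[out["status"] == "discovered"]
    if len(disc) == 0:
        return out

    gpos = {c: i for i, c in enumerate(gly.columns)}
    ppos = {c: i for i, c in enumerate(prot.columns)}
    r, p, n = pairwise_pearson(gly, prot)

    for idx in disc:
        gid = out.at[idx, "glycan_id"]
        pid = out.at[idx, "protein_id"]
        if gid not in gpos or pid not in ppos:
            out.at[idx, "status"] = "not_replicated"
            out.at[idx, "replication_note"] = "feature absent in replication cohort"
            continue
        i, j = gpos[gid], ppos[pid]
        nn = int(n[i, j])
        out.at[idx, "n_rep"] = nn
        if nn < 3 or np.isnan(r[i, j]):
            out.at[idx, "status"] = "not_replicated"
            out.at[idx, "replication_note"] = "untestable: fewer than 3 complete pairs"
            continue
        rr, pp = float(r[i, j]), float(p[i, j])
        out.at[idx, "r_rep"] = rr
        out.at[idx, "p_rep"] = pp
        if pp < p_cutoff and rr != 0.0 and np.sign(rr) == np.sign(out.at[idx, "r_disc"]):
            out.at[idx, "status"] = "replicated"
        elif pp < p_cutoff and rr != 0.0:
            out.at[idx, "status"] = "conflicting"
        else:
            out.at[idx, "status"] = "not_replicated"
            if rr == 0.0 and pp < p_cutoff:
                out.at[idx, "replication_note"] = "zero replication correlation"
    out.attrs.update(records.attrs)
    out.attrs["replication_p_cutoff"] = p_cutoff
    return out


def association_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Signed-r-squared matrix over replicated pairs.

    Rows are glycan traits and columns proteins that carry at least one
    replicated association; each replicated entry is sign(r_disc) *
    r_disc^2, everything else is missing.  With no replicated pairs the
    matrix is 0 x 0.
    """
    rep = records[records["status"] == "replicated"]
    if rep.empty:
        return pd.DataFrame(dtype=float)
    glycans = list(dict.fromkeys(rep["glycan_id"]))
    proteins = list(dict.fromkeys(rep["protein_id"]))
    mat = pd.DataFrame(np.nan, index=glycans, columns=proteins)
    for row in rep.itertuples(index=False):
        mat.at[row.glycan_id, row.protein_id] = np.sign(row.r_disc) * row.r_disc ** 2
    return mat


def consistency_report(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Cross-cohort effect-size table and sign-concordance fraction.

    Considers every record carrying statistics from both cohorts, sorted by
    |r_disc| descending.  Concordance is the fraction of pairs whose two
    correlations have equal sign; an exactly zero correlation on either
    side counts as discordant.
    """
    both = records.dropna(subset=["r_disc", "r_rep"]).copy()
    both = both.sort_values("r_disc", key=lambda s: s.abs(), ascending=False,
                            kind="mergesort").reset_index(drop=True)
    if both.empty:
        return both[["protein_id", "glycan_id", "r_disc", "r_rep"]], float("nan")
    signs_ok = (np.sign(both["r_disc"]) == np.sign(both["r_rep"])) \
        & (both["r_disc"] != 0) & (both["r_rep"] != 0)
    concordance = float(signs_ok.mean())
    cols = ["protein_id", "glycan_id", "r_disc", "r_rep", "p_disc", "p_rep", "status"]
    cols = [c for c in cols if c in both.columns]
    return both[cols], concordance


def summarize(records: pd.DataFrame) -> dict:
    """Counts by status plus the thresholds used, for the run summary JSON."""
    counts = {s: int((records["status"] == s).sum()) for s in STATUS_ORDER}
    rep = records[records["status"] == "replicated"]
    return {
        "pairs_tested": int(len(records)),
        "counts_by_status": counts,
        "replicated_glycans": int(rep["glycan_id"].nunique()),
        "replicated_proteins": int(rep["protein_id"].nunique()),
        "bonferroni_threshold": records.attrs.get("bonferroni_threshold"),
        "alpha": records.attrs.get("alpha"),
        "replication_p_cutoff": records.attrs.get("replication_p_cutoff"),
    }
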