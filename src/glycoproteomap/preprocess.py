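"""Rank-based inverse-normal scaling and discovery/replication cohort alignment.

Both omics layers (glycan traits in percent / ratio units, aptamer protein
readouts in relative fluorescence units) are mapped feature-by-feature onto
standard-normal quantiles before correlation, which makes Pearson tests
robust to skew and heavy tails and makes the two layers directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "InsufficientDataError",
    "ConstantFeatureError",
    "inverse_normal",
    "transform_matrix",
    "AlignmentReport",
    "align_cohorts",
    "BLOM_OFFSET",
]

BLOM_OFFSET = 3.0 / 8.0


class InsufficientDataError(ValueError):
    """Fewer than three non-missing observations."""


class ConstantFeatureError(ValueError):
    """All non-missing observations tie; ranks carry no information."""


def inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    A non-missing value with (average, tie-shared) rank ``r`` among ``n``
    non-missing observations maps to ``Phi^-1((r - c) / (n - 2c + 1))``
    with ``c = 3/8`` by default, i.e. the Blom convention
    ``(r - 3/8)/(n + 1/4)``.  Tied values share a rank and hence a
    transformed value; missing entries stay missing.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 non-missing values, got {n}")
    xs = x[ok]
    if np.all(xs == xs[0]):
        raise ConstantFeatureError("all non-missing values are identical")
    ranks = rankdata(xs, method="average")
    out = np.full(x.shape, np.nan)
    out[ok] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def transform_matrix(df: pd.DataFrame, offset: float = BLOM_OFFSET
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise :func:`inverse_normal` over a samples x features table.

    Constant or nearly empty (< 3 non-missing) columns cannot be scaled;
    they are dropped and their names returned alongside the result.
    """
    cols: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name in df.columns:
        try:
            cols[name] = inverse_normal(df[name].to_numpy(dtype=float), offset)
        except (InsufficientDataError, ConstantFeatureError):
            excluded.append(name)
    return pd.DataFrame(cols, index=df.index), excluded


@dataclass
class AlignmentReport:
    """What feature harmonization between two cohorts dropped or renamed."""

    common: list[str] = field(default_factory=list)
    dropped_discovery: list[str] = field(default_factory=list)
    dropped_replication: list[str] = field(default_factory=list)
    renamed: dict[str, str] = field(default_factory=dict)


def _canon(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def align_cohorts(discovery: pd.DataFrame, replication: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame, AlignmentReport]:
    """Restrict two cohorts' feature columns to their intersection.

    Feature ids are matched after whitespace normalization and case
    folding; matches under a non-identical canonical form are recorded in
    the report.  Column order follows the discovery cohort.
    """
    disc_canon = {_canon(c): c for c in discovery.columns}
    rep_canon = {_canon(c): c for c in replication.columns}
    report = AlignmentReport()
    common_disc, common_rep = [], []
    for c in discovery.columns:
        key = _canon(c)
        if key in rep_canon:
            common_disc.append(c)
            common_rep.append(rep_canon[key])
            if rep_canon[key] != c:
                report.renamed[rep_canon[key]] = c
        else:
            report.dropped_discovery.append(c)
    report.dropped_replication = [c for c in replication.columns
                                  if _canon(c) not in disc_canon]
    if not common_disc:
        raise ValueError("no features in common between the cohorts")
    report.common = common_disc
    rep = replication[common_rep].copy()
    rep.columns = common_disc
    return discovery[common_disc].copy(), rep, report
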