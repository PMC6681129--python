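"""Matrix file I/O, run configuration and the end-to-end pipeline.

All tabular interchange is TSV with a header row and ``sample_id`` as the
first column; empty cells are missing values.  TSV is used rather than CSV
because glycan trait names contain commas (e.g. ``A4F1G3S(3,3,6)3``).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, preprocess, traits
from .synthetic import SyntheticConfig, generate_cohorts
from .traits import PEAK_IDS, TraitCatalog, builtin_catalog, load_annotations

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("glycoproteomap")


class MatrixParseError(ValueError):
    """A matrix file violates the TSV contract; the message names the line."""


def read_matrix(path: str | Path, kind: str = "protein") -> pd.DataFrame:
    """Read a samples x features TSV matrix.

    *kind* is one of ``protein``, ``peak`` or ``trait``; ``peak`` matrices
    must carry exactly the 36 GP columns.  Duplicate sample ids, ragged
    rows and non-numeric cells are rejected with the offending line number
    (line 1 is the header).
    """
    if kind not in ("protein", "peak", "trait"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise MatrixParseError(f"{path}: first column must be 'sample_id', "
                               f"got {df.columns[0]!r}")
    ids = df["sample_id"]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        line = int(dup.index[0]) + 2
        raise MatrixParseError(f"{path}: duplicate sample id {dup.iloc[0]!r} at line {line}")
    out = df.set_index("sample_id")
    for col in out.columns:
        raw = out[col]
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise MatrixParseError(
                f"{path}: non-numeric cell {raw[bad].iloc[0]!r} in column "
                f"{col!r} at line {line}")
        out[col] = vals
    if kind == "peak":
        missing = [p for p in PEAK_IDS if p not in out.columns]
        if missing:
            raise MatrixParseError(f"{path}: missing peak columns {missing}")
        out = out[list(PEAK_IDS)]
    return out


def write_matrix(df: pd.DataFrame, path: str | Path,
                 full_precision: bool = False) -> None:
    """Write a samples x features matrix as TSV (6 significant digits).

    Missing values render as empty cells; ``full_precision`` switches to
    round-trip float formatting.
    """
    fmt = None if full_precision else "%.6g"
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="", float_format=fmt)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``synthetic`` is set (the cohorts are simulated) or the four
    input paths are set (protein + peak/trait TSV per cohort).
    ``peaks_are_raw`` declares whether peak tables hold raw areas (to be
    normalized) or percentages.
    """

    out_dir: str | Path = "glycoproteomap_out"
    synthetic: SyntheticConfig | None = None
    discovery_proteins: str | Path | None = None
    discovery_peaks: str | Path | None = None
    replication_proteins: str | Path | None = None
    replication_peaks: str | Path | None = None
    peaks_are_raw: bool = True
    alpha: float = 0.05
    replication_p_cutoff: float = 0.05
    inverse_normal_offset: float = preprocess.BLOM_OFFSET
    structure_policy: str = "dominant"
    swap_roles: bool = False
    annotation_path: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.synthetic is None:
            paths = [self.discovery_proteins, self.discovery_peaks,
                     self.replication_proteins, self.replication_peaks]
            if any(p is None for p in paths):
                raise ValueError("need either a synthetic config or all four input paths")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")


@dataclass
class PipelineResult:
    records: pd.DataFrame
    matrix: pd.DataFrame
    consistency: pd.DataFrame
    concordance: float
    summary: dict
    out_dir: Path


def _derive_and_scale(prot: pd.DataFrame, peaks: pd.DataFrame,
                      cfg: RunConfig, catalog: TraitCatalog,
                      annotations) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    if cfg.peaks_are_raw:
        peaks = traits.normalize_table(peaks)
    trait_mat = traits.derive_all(peaks, catalog, annotations, cfg.structure_policy)
    prot_s, prot_excl = preprocess.transform_matrix(prot, cfg.inverse_normal_offset)
    gly_s, gly_excl = preprocess.transform_matrix(trait_mat, cfg.inverse_normal_offset)
    return prot_s, gly_s, {"excluded_proteins": prot_excl, "excluded_glycans": gly_excl}


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """simulate/load -> derive traits -> scale -> associate -> report.

    Writes ``records.tsv``, ``matrix.tsv``, ``consistency.tsv`` and
    ``summary.json`` into ``cfg.out_dir`` and returns everything in
    memory.  Deterministic for a fixed config and seed.
    """
    logging.basicConfig(level=cfg.log_level, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    cfg.validate()
    catalog = builtin_catalog()
    annotations = load_annotations(cfg.annotation_path)

    stage = "input"
    try:
        if cfg.synthetic is not None:
            sim = cfg.synthetic
            if sim.seed != cfg.seed:
                sim = SyntheticConfig(**{**sim.__dict__, "seed": cfg.seed})
            disc, rep, _truth = generate_cohorts(sim, annotations, catalog)
            d_prot, d_peaks = disc.proteins, disc.peaks
            r_prot, r_peaks = rep.proteins, rep.peaks
            peaks_are_raw = False
        else:
            d_prot = read_matrix(cfg.discovery_proteins, "protein")
            d_peaks = read_matrix(cfg.discovery_peaks, "peak")
            r_prot = read_matrix(cfg.replication_proteins, "protein")
            r_peaks = read_matrix(cfg.replication_peaks, "peak")
            peaks_are_raw = cfg.peaks_are_raw

        if cfg.swap_roles:
            d_prot, r_prot = r_prot, d_prot
            d_peaks, r_peaks = r_peaks, d_peaks

        stage = "derive_and_scale"
        sub_cfg = RunConfig(**{**cfg.__dict__, "peaks_are_raw": peaks_are_raw})
        d_prot_s, d_gly_s, d_excl = _derive_and_scale(d_prot, d_peaks, sub_cfg,
                                                      catalog, annotations)
        r_prot_s, r_gly_s, r_excl = _derive_and_scale(r_prot, r_peaks, sub_cfg,
                                                      catalog, annotations)

        stage = "align"
        d_prot_s, r_prot_s, prot_report = preprocess.align_cohorts(d_prot_s, r_prot_s)
        d_gly_s, r_gly_s, gly_report = preprocess.align_cohorts(d_gly_s, r_gly_s)

        stage = "associate"
        records = association.discovery_scan(d_prot_s, d_gly_s, cfg.alpha)
        records = association.replicate(records, r_prot_s, r_gly_s,
                                        cfg.replication_p_cutoff)
        matrix = association.association_matrix(records)
        if matrix.empty:
            log.warning("no replicated associations; matrix is empty")
        consistency, concordance = association.consistency_report(records)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = association.summarize(records)
    summary.update({
        "n_discovery_samples": int(d_prot_s.shape[0]),
        "n_replication_samples": int(r_prot_s.shape[0]),
        "n_proteins_common": int(d_prot_s.shape[1]),
        "n_glycans_common": int(d_gly_s.shape[1]),
        "excluded_features": {"discovery": d_excl, "replication": r_excl},
        "sign_concordance": None if np.isnan(concordance) else concordance,
        "matrix_shape": list(matrix.shape),
        "seed": cfg.seed,
        "swap_roles": cfg.swap_roles,
    })

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records.to_csv(out_dir / "records.tsv", sep="\t", index=False,
                   na_rep="", float_format="%.6g")
    matrix.to_csv(out_dir / "matrix.tsv", sep="\t", index_label="glycan_id",
                  na_rep="", float_format="%.6g")
    consistency.to_csv(out_dir / "consistency.tsv", sep="\t", index=False,
                       na_rep="", float_format="%.6g")
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("pipeline finished: %s", summary["counts_by_status"])
    return PipelineResult(records, matrix, consistency, concordance, summary, out_dir)
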