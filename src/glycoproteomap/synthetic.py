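"""Synthetic paired proteome + glycome cohorts with planted ground truth.

The generative model follows the causal picture behind protein-glycan
correlation mapping: the total plasma N-glycome is a mixture of
protein-specific glycoform contributions.  Each sample draws log-normal
protein abundances; the raw peak vector is the abundance-weighted sum of
per-protein glycoform composition profiles (rows on the 36-peak simplex),
including unassayed background proteins, degraded by multiplicative
log-normal noise and closed to percentages.  The protein readout emulates a
relative-quantification assay as noisy log-abundance.

Two link types can be planted:

* ``source`` — the protein carries a distinctive glycoform profile, so its
  abundance drives the percentage of its dominant peaks (a protein that is
  a major source of a glycan);
* ``enzyme`` — the protein multiplies designated peak fractions by
  ``abundance**gamma`` before closure (a biosynthetic enzyme).

The planted truth (which traits should correlate, and with which sign) is
derivable from the configuration and the trait catalog, enabling
end-to-end recovery tests of the association pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .traits import PEAK_IDS, PeakAnnotation, TraitCatalog, resolve_peaks

__all__ = [
    "PlantedLink",
    "SyntheticConfig",
    "CohortPair",
    "SyntheticTruth",
    "LinkSignature",
    "baseline_profile",
    "null_config",
    "planted_source_config",
    "generate_cohorts",
    "expected_signatures",
]


def baseline_profile() -> np.ndarray:
    """A fixed, realistic-shaped background composition over the 36 peaks.

    Mass is concentrated in the biantennary mono-/disialylated region (the
    bulk of a plasma N-glycome), with smaller neutral, high-mannose and
    tri-/tetraantennary contributions; every peak receives some mass so no
    derived-trait denominator degenerates.
    """
    w = np.array([
        1.0, 2.5, 0.8, 1.2, 1.5, 1.8, 0.9, 4.0, 1.0, 3.5,
        1.5, 1.2, 1.8, 9.0, 4.5, 2.5, 1.5, 1.0, 16.0, 5.0,
        2.0, 5.0, 2.5, 4.5, 2.5, 1.5, 1.2, 1.5, 2.0, 3.0,
        1.5, 2.0, 1.5, 2.5, 0.8, 1.2,
    ])
    return w / w.sum()


@dataclass(frozen=True)
class PlantedLink:
    """One planted protein-glycan causal link."""

    protein_id: str
    peaks: tuple[str, ...]
    sign: int = 1               # expected correlation sign on the peaks' traits
    kind: str = "source"        # "source" | "enzyme"
    gamma: float = 1.0          # enzyme links scale peak mass by abundance**gamma

    def __post_init__(self) -> None:
        if self.kind not in ("source", "enzyme"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a two-cohort simulation.

    ``glycoform_profiles`` has one row per protein (assayed proteins first,
    then background proteins), each row a composition over the 36 peaks.
    Cohort sizes default to the 344-discovery / 46-replication design.
    """

    n_proteins: int
    n_background_proteins: int
    glycoform_profiles: np.ndarray
    abundance_log_mean: np.ndarray
    abundance_log_sd: np.ndarray
    n_discovery: int = 344
    n_replication: int = 46
    glycan_noise_cv: float = 0.05
    protein_readout_noise_sd: float = 0.2
    planted_links: tuple[PlantedLink, ...] = ()
    contribution_threshold: float = 0.05
    seed: int = 0

    @property
    def n_total_proteins(self) -> int:
        return self.n_proteins + self.n_background_proteins

    @property
    def protein_ids(self) -> list[str]:
        return [f"PROT{i + 1}" for i in range(self.n_proteins)]

    def validate(self) -> None:
        prof = np.asarray(self.glycoform_profiles, dtype=float)
        if prof.shape != (self.n_total_proteins, len(PEAK_IDS)):
            raise ValueError(
                f"glycoform_profiles must be {self.n_total_proteins} x {len(PEAK_IDS)}")
        if (prof < 0).any() or not np.allclose(prof.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each glycoform profile must lie on the simplex")
        if self.glycan_noise_cv < 0 or self.protein_readout_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if min(self.n_discovery, self.n_replication) < 3:
            raise ValueError("cohort sizes must be >= 3")
        if (np.asarray(self.abundance_log_sd) < 0).any():
            raise ValueError("abundance_log_sd must be >= 0")
        known = set(self.protein_ids)
        for link in self.planted_links:
            if link.protein_id not in known:
                raise ValueError(f"planted link references unknown protein {link.protein_id!r}")
            bad = [p for p in link.peaks if p not in PEAK_IDS]
            if bad:
                raise ValueError(f"planted link references unknown peaks {bad}")


class CohortPair(NamedTuple):
    proteins: pd.DataFrame   # samples x assayed proteins (log-scale readout)
    peaks: pd.DataFrame      # samples x 36 peak percentages


@dataclass(frozen=True)
class LinkSignature:
    protein_id: str
    peaks: tuple[str, ...]
    expected_sign: int
    positive_traits: tuple[str, ...]
    negative_traits: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    links: tuple[LinkSignature, ...] = ()


# ---------------------------------------------------------------------------
# configuration factories

def null_config(n_proteins: int = 50, n_background_proteins: int = 10,
                seed: int = 0, **overrides) -> SyntheticConfig:
    """A no-signal configuration: every protein shares the same profile.

    With identical glycoform profiles the closed composition is independent
    of all abundances, so every protein-trait correlation is null; only the
    multiplicative peak noise moves the glycome.
    """
    P = n_proteins + n_background_proteins
    prof = np.tile(baseline_profile(), (P, 1))
    cfg = SyntheticConfig(
        n_proteins=n_proteins,
        n_background_proteins=n_background_proteins,
        glycoform_profiles=prof,
        abundance_log_mean=np.zeros(P),
        abundance_log_sd=np.full(P, 0.5),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def planted_source_config(n_proteins: int = 20, n_background_proteins: int = 10,
                          link_peaks: tuple[str, ...] = ("GP22",),
                          link_strength: float = 0.2,
                          link_log_sd: float = 0.8,
                          seed: int = 0, **overrides) -> SyntheticConfig:
    """One planted source link: PROT1 contributes a distinctive glycoform.

    PROT1's profile is a point mass spread uniformly over *link_peaks*;
    ``link_strength`` sets its mean abundance relative to a single
    background protein (exp of its abundance log-mean).  The defaults were
    calibrated once, by measuring the induced correlation between PROT1's
    readout and its dominant peak percentage at large n, to give a
    population |r| of about 0.5 — the middle of the effect-size range the
    pipeline targets.
    """
    P = n_proteins + n_background_proteins
    prof = np.tile(baseline_profile(), (P, 1))
    mask = np.isin(np.array(PEAK_IDS), np.array(link_peaks))
    prof[0] = mask / mask.sum()
    log_mean = np.zeros(P)
    log_mean[0] = np.log(link_strength)
    log_sd = np.full(P, 0.5)
    log_sd[0] = link_log_sd
    cfg = SyntheticConfig(
        n_proteins=n_proteins,
        n_background_proteins=n_background_proteins,
        glycoform_profiles=prof,
        abundance_log_mean=log_mean,
        abundance_log_sd=log_sd,
        glycan_noise_cv=0.15,
        planted_links=(PlantedLink("PROT1", tuple(link_peaks), sign=1, kind="source"),),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation

def _draw_cohort(cfg: SyntheticConfig, n: int, rng: np.random.Generator,
                 prefix: str) -> CohortPair:
    P = cfg.n_total_proteins
    mu = np.asarray(cfg.abundance_log_mean, dtype=float)
    sd = np.asarray(cfg.abundance_log_sd, dtype=float)
    prof = np.asarray(cfg.glycoform_profiles, dtype=float)

    A = np.exp(mu + sd * rng.standard_normal((n, P)))
    raw = A @ prof
    for link in cfg.planted_links:
        if link.kind == "enzyme":
            i = cfg.protein_ids.index(link.protein_id)
            cols = [PEAK_IDS.index(p) for p in link.peaks]
            raw[:, cols] *= A[:, [i]] ** link.gamma
    if cfg.glycan_noise_cv > 0:
        s = np.sqrt(np.log1p(cfg.glycan_noise_cv ** 2))
        raw *= np.exp(-0.5 * s * s + s * rng.standard_normal(raw.shape))

    totals = raw.sum(axis=1)
    for _ in range(100):
        bad = ~(totals > 0)
        if not bad.any():
            break
        nb = int(bad.sum())
        A_new = np.exp(mu + sd * rng.standard_normal((nb, P)))
        raw[bad] = A_new @ prof
        A[bad] = A_new
        totals = raw.sum(axis=1)
    else:
        raise RuntimeError("degenerate (all-zero) samples persisted after 100 retries")

    peaks = 100.0 * raw / totals[:, None]
    readout = np.log(A[:, :cfg.n_proteins])
    if cfg.protein_readout_noise_sd > 0:
        readout = readout + cfg.protein_readout_noise_sd * rng.standard_normal(readout.shape)

    idx = [f"{prefix}_S{i + 1}" for i in range(n)]
    return CohortPair(
        proteins=pd.DataFrame(readout, index=idx, columns=cfg.protein_ids),
        peaks=pd.DataFrame(peaks, index=idx, columns=list(PEAK_IDS)),
    )


def generate_cohorts(cfg: SyntheticConfig,
                     annotations: dict[str, PeakAnnotation] | None = None,
                     catalog: TraitCatalog | None = None
                     ) -> tuple[CohortPair, CohortPair, SyntheticTruth]:
    """Draw the discovery and replication cohorts and the planted truth.

    Both cohorts use identical population parameters but independent
    samples (distinct child seeds of ``cfg.seed``).  Bit-identical output
    for identical configurations.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    d_ss, r_ss = ss.spawn(2)
    discovery = _draw_cohort(cfg, cfg.n_discovery, np.random.default_rng(d_ss), "DISC")
    replication = _draw_cohort(cfg, cfg.n_replication, np.random.default_rng(r_ss), "REP")
    if annotations is not None and catalog is not None:
        truth = expected_signatures(cfg, catalog, annotations)
    else:
        truth = SyntheticTruth(tuple(
            LinkSignature(l.protein_id, l.peaks, l.sign,
                          tuple(f"PGP{PEAK_IDS.index(p) + 1}" for p in l.peaks), ())
            for l in cfg.planted_links))
    return discovery, replication, truth


def expected_signatures(cfg: SyntheticConfig, catalog: TraitCatalog,
                        annotations: dict[str, PeakAnnotation],
                        policy: str = "dominant") -> SyntheticTruth:
    """Propagate planted links through the catalog to expected trait signs.

    A link is expected to correlate positively with every non-ratio trait
    whose numerator peaks overlap the link's peaks, and negatively with
    traits whose numerator peaks are disjoint but carry at least
    ``cfg.contribution_threshold`` of the mean glycome mass (the
    compositional complement: when the planted contribution rises, every
    other percentage must fall).
    """
    cfg.validate()
    mu = np.asarray(cfg.abundance_log_mean, dtype=float)
    sd = np.asarray(cfg.abundance_log_sd, dtype=float)
    mean_abund = np.exp(mu + 0.5 * sd * sd)
    mean_mass = mean_abund @ np.asarray(cfg.glycoform_profiles, dtype=float)
    mass_frac = mean_mass / mean_mass.sum()
    peak_pos = {p: i for i, p in enumerate(PEAK_IDS)}

    sigs = []
    for link in cfg.planted_links:
        link_set = set(link.peaks)
        pos, neg = [], []
        for defn in catalog.traits:
            if defn.kind == "ratio":
                continue
            num_peaks = set(resolve_peaks(defn.numerator, annotations, policy))
            if num_peaks & link_set:
                pos.append(defn.trait_id)
            else:
                frac = sum(mass_frac[peak_pos[p]] for p in num_peaks)
                if frac >= cfg.contribution_threshold:
                    neg.append(defn.trait_id)
        if link.sign < 0:
            pos, neg = neg, pos
        sigs.append(LinkSignature(link.protein_id, link.peaks, link.sign,
                                  tuple(pos), tuple(neg)))
    return SyntheticTruth(tuple(sigs))
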