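"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the four measurement kinds the analysis
consumes:

* :func:`simulate_lcm_counts` — negative-binomial gene x sample count
  tables with a two-domain (apical/basal) replicate design, genuine
  enrichment effects with |log2FC| within the bona fide band, and
  extreme-fold-change contaminant genes nearly absent from the depleted
  domain (mimicking cross-tissue carry-over during microdissection);
* :func:`simulate_polarity_measurements` — apical/basal/background
  m.f.i. triples with a configurable true Degree of Apicality and a
  knockdown effect;
* :func:`simulate_axis_profiles` — exponential-shape intensity line
  profiles along the apical-basal axis with configurable apical bias
  and an analytically known half-area position;
* :func:`simulate_tpm_tables` — paired ribosome-footprint / RNA-seq TPM
  tables with a group-wise translation-efficiency shift.

All generators draw from one explicitly seeded
``numpy.random.Generator`` per call — identical config + seed gives
bit-identical output; no global RNG state is touched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from apicobasal.enrichment import (
    BONA_FIDE_APICAL,
    BONA_FIDE_BASAL,
    MUSCLE_CONTAMINANT,
    OOCYTE_CONTAMINANT,
)
from apicobasal.polarity import KD, WT, PolarityMeasurement
from apicobasal.profiles import AxisProfile

logger = logging.getLogger(__name__)

NOT_ENRICHED = "not_enriched"

#: expected count of a contaminant gene in its depleted domain.  A small
#: positive constant ("absent or in very low number") keeps every fold
#: change defined while preserving extreme |log2FC|.
CONTAMINANT_FLOOR_MEAN = 0.5

#: fluorescence signal scale (arbitrary units) of simulated basal m.f.i.
POLARITY_SIGNAL_SCALE = 100.0


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SimCountConfig:
    """Configuration for the LCM count simulator.

    Class fractions default to the observed proportions of the follicle
    cell study design at 2000 genes (~300 apical, ~220 basal bona fide,
    a couple of oocyte and a few tens of muscle contaminants).
    ``dispersion`` is the reciprocal of the NB size parameter
    (variance = mu + dispersion * mu^2); 0 gives Poisson counts.
    """

    n_genes: int = 2000
    n_replicates_per_domain: int = 4
    baseline_mean_log_range: tuple[float, float] = (1.7, 3.0)
    dispersion: float = 0.05
    frac_apical_enriched: float = 0.15
    frac_basal_enriched: float = 0.11
    frac_oocyte_contaminant: float = 0.001
    frac_muscle_contaminant: float = 0.0165
    enriched_lfc_range: tuple[float, float] = (1.5, 2.5)
    contaminant_lfc_min: float = 5.0
    library_size_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if self.n_replicates_per_domain < 2:
            raise ConfigError("need >= 2 replicates per domain")
        lo, hi = self.baseline_mean_log_range
        if not lo < hi:
            raise ConfigError("baseline_mean_log_range must be (low, high) with low < high")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        fracs = (
            self.frac_apical_enriched,
            self.frac_basal_enriched,
            self.frac_oocyte_contaminant,
            self.frac_muscle_contaminant,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("class fractions must lie in [0,1] and sum to <= 1")
        e_lo, e_hi = self.enriched_lfc_range
        if not (0 < e_lo <= e_hi <= 3):
            raise ConfigError("enriched_lfc_range must lie within (0, 3]")
        if self.contaminant_lfc_min <= 3:
            raise ConfigError("contaminant_lfc_min must be > 3")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be >= 0")


@dataclass(frozen=True)
class SimPolarityConfig:
    """Configuration for the smFISH polarity-measurement simulator."""

    n_groups_wt: int = 10
    n_groups_kd: int = 10
    true_doa_wt: float = 1.0
    kd_effect: float = 1.0
    background_mean: float = 20.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups_wt < 1 or self.n_groups_kd < 1:
            raise ConfigError("need >= 1 group per cell type")
        if self.true_doa_wt <= 0 or self.kd_effect <= 0:
            raise ConfigError("true_doa_wt and kd_effect must be > 0")
        if self.background_mean < 0 or self.noise_cv < 0:
            raise ConfigError("background_mean and noise_cv must be >= 0")


@dataclass(frozen=True)
class SimProfileConfig:
    """Configuration for the axis-profile simulator.

    ``apical_bias`` > 0 concentrates mass apically (exponential decay
    along the axis), 0 gives a uniform profile, < 0 shifts it basally.
    """

    n_positions: int = 101
    apical_bias: float = 0.0
    noise_sd: float = 0.0
    n_profiles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 3:
            raise ConfigError("n_positions must be >= 3")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_profiles < 1:
            raise ConfigError("n_profiles must be >= 1")


def _truth_class(lfc: float, enriched: bool, fc_threshold: float = 3.0) -> str:
    if not enriched or lfc == 0:
        return NOT_ENRICHED
    if lfc > fc_threshold:
        return OOCYTE_CONTAMINANT
    if lfc > 0:
        return BONA_FIDE_APICAL
    if lfc >= -fc_threshold:
        return BONA_FIDE_BASAL
    return MUSCLE_CONTAMINANT


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, size = 1/dispersion) counts; Poisson in the limit."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_lcm_counts(cfg: SimCountConfig):
    """Simulate a two-domain LCM count table with known per-gene truth.

    Returns
    -------
    (CountTable, pandas.DataFrame)
        The count table (apical samples ``A1..``, basal ``B1..``) and a
        truth table with columns ``id``, ``true_class``, ``true_lfc``.
    """
    from apicobasal.enrichment import APICAL, BASAL, CountTable

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    r = cfg.n_replicates_per_domain
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    samples = [f"A{j + 1}" for j in range(r)] + [f"B{j + 1}" for j in range(r)]
    domains = pd.Series([APICAL] * r + [BASAL] * r, index=samples)

    n_ap = round(cfg.frac_apical_enriched * n)
    n_ba = round(cfg.frac_basal_enriched * n)
    n_oo = round(cfg.frac_oocyte_contaminant * n)
    n_mu = round(cfg.frac_muscle_contaminant * n)
    order = rng.permutation(n)
    idx_ap = order[:n_ap]
    idx_ba = order[n_ap:n_ap + n_ba]
    idx_oo = order[n_ap + n_ba:n_ap + n_ba + n_oo]
    idx_mu = order[n_ap + n_ba + n_oo:n_ap + n_ba + n_oo + n_mu]

    log_lo, log_hi = cfg.baseline_mean_log_range
    base = 10.0 ** rng.uniform(log_lo, log_hi, size=n)
    e_lo, e_hi = cfg.enriched_lfc_range

    true_lfc = np.zeros(n)
    true_lfc[idx_ap] = rng.uniform(e_lo, e_hi, size=n_ap)
    true_lfc[idx_ba] = -rng.uniform(e_lo, e_hi, size=n_ba)
    c_lo, c_hi = cfg.contaminant_lfc_min, cfg.contaminant_lfc_min + 2.0
    true_lfc[idx_oo] = rng.uniform(c_lo, c_hi, size=n_oo)
    true_lfc[idx_mu] = -rng.uniform(c_lo, c_hi, size=n_mu)

    # bona fide / null genes split the baseline geometrically between
    # domains; contaminants sit at a small floor in the depleted domain
    mu_a = base * 2.0 ** (true_lfc / 2.0)
    mu_b = base * 2.0 ** (-true_lfc / 2.0)
    mu_a[idx_mu] = CONTAMINANT_FLOOR_MEAN
    mu_b[idx_mu] = CONTAMINANT_FLOOR_MEAN * 2.0 ** (-true_lfc[idx_mu])
    mu_b[idx_oo] = CONTAMINANT_FLOOR_MEAN
    mu_a[idx_oo] = CONTAMINANT_FLOOR_MEAN * 2.0 ** (true_lfc[idx_oo])

    if cfg.library_size_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.library_size_cv**2))
        size_factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=2 * r)
    else:
        size_factors = np.ones(2 * r)

    counts = np.empty((n, 2 * r), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = (mu_a if domains[sample] == APICAL else mu_b) * size_factors[j]
        counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)

    enriched = np.zeros(n, dtype=bool)
    for idx in (idx_ap, idx_ba, idx_oo, idx_mu):
        enriched[idx] = True
    truth = pd.DataFrame(
        {
            "id": gene_ids,
            "true_class": [
                _truth_class(lfc, enr) for lfc, enr in zip(true_lfc, enriched)
            ],
            "true_lfc": true_lfc,
        }
    )
    table = CountTable(pd.DataFrame(counts, index=gene_ids, columns=samples), domains)
    return table, truth


def _noise_factor(rng: np.random.Generator, cv: float, max_tries: int = 1000) -> float:
    """Multiplicative (1 + eps) noise factor, resampled while <= 0."""
    if cv == 0:
        return 1.0
    for _ in range(max_tries):
        f = 1.0 + rng.normal(0.0, cv)
        if f > 1e-6:
            return f
    raise ConfigError("noise_cv too large: cannot draw a positive signal factor")


def simulate_polarity_measurements(cfg: SimPolarityConfig):
    """Simulate paired wt/kd smFISH polarity measurements.

    Each group gets ``basal = bg + S * (1 + eps_b)`` and
    ``apical = bg + S * DoA_target * (1 + eps_a)`` with signal scale
    S = 100 a.u.; kd groups use ``DoA_target = true_doa_wt * kd_effect``.
    Noise factors are resampled while non-positive (logged via the
    ConfigError path), so every m.f.i. stays strictly above background.
    Paired groups share a ``p{i}`` group-id stem (``p1_wt`` / ``p1_kd``).

    Returns
    -------
    (list[PolarityMeasurement], dict)
        The measurements and the ground truth
        ``{"true_doa_wt": ..., "kd_effect": ...}``.
    """
    rng = np.random.default_rng(cfg.seed)
    s = POLARITY_SIGNAL_SCALE
    measurements: list[PolarityMeasurement] = []
    specs = [(WT, cfg.n_groups_wt, cfg.true_doa_wt), (KD, cfg.n_groups_kd, cfg.true_doa_wt * cfg.kd_effect)]
    for cell_type, n_groups, doa_target in specs:
        for i in range(n_groups):
            apical = cfg.background_mean + s * doa_target * _noise_factor(rng, cfg.noise_cv)
            basal = cfg.background_mean + s * _noise_factor(rng, cfg.noise_cv)
            measurements.append(
                PolarityMeasurement(
                    group_id=f"p{i + 1}_{cell_type}",
                    apical_mfi=apical,
                    basal_mfi=basal,
                    bg_mfi=cfg.background_mean,
                    cell_type=cell_type,
                    condition="sim",
                    rna_id="simRNA",
                )
            )
    truth = {"true_doa_wt": cfg.true_doa_wt, "kd_effect": cfg.kd_effect}
    return measurements, truth


def true_auc50_exponential(bias: float) -> float:
    """Half-area position of the noise-free shape exp(-bias * x) on [0, 1]."""
    if bias == 0:
        return 0.5
    return float(-math.log(1.0 - 0.5 * (1.0 - math.exp(-bias))) / bias)


def simulate_axis_profiles(cfg: SimProfileConfig):
    """Simulate apical-basal intensity profiles with known auc50 truth.

    The noise-free shape is ``exp(-apical_bias * x)`` on positions
    evenly spaced over [0, 1] (0 = apical), rescaled to peak 1;
    Gaussian noise of sd ``noise_sd`` is added and clipped at 0.

    Returns
    -------
    (list[AxisProfile], pandas.DataFrame)
        Profiles and a truth table with ``id`` and ``true_auc50``.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.linspace(0.0, 1.0, cfg.n_positions)
    shape = np.exp(-cfg.apical_bias * x)
    shape = shape / shape.max()
    auc50 = true_auc50_exponential(cfg.apical_bias)
    profiles = []
    for i in range(cfg.n_profiles):
        values = shape + rng.normal(0.0, cfg.noise_sd, size=cfg.n_positions)
        values = np.clip(values, 0.0, None)
        profiles.append(
            AxisProfile(profile_id=f"prof{i + 1:03d}", positions=x.copy(), values=values)
        )
    truth = pd.DataFrame(
        {"id": [p.profile_id for p in profiles], "true_auc50": auc50}
    )
    return profiles, truth


def simulate_tpm_tables(n_genes: int, shift: float, seed: int = 0):
    """Simulate paired RFP/RNA TPM tables with a group-wise TE shift.

    Two groups of ``n_genes`` genes each (labelled apical and basal);
    per-gene log2 translation efficiency is N(0, 0.5) in the apical
    group and N(shift, 0.5) in the basal group — positive ``shift``
    makes basal transcripts more translated.  All TPM values are > 0.

    Returns
    -------
    (pandas.Series, pandas.Series, pandas.Series)
        ``rfp_tpm``, ``rna_tpm`` and group labels, indexed by gene id.
    """
    if n_genes < 2:
        raise ConfigError("need >= 2 genes per group")
    rng = np.random.default_rng(seed)
    total = 2 * n_genes
    ids = [f"g{i + 1:05d}" for i in range(total)]
    labels = pd.Series(
        [BONA_FIDE_APICAL] * n_genes + [BONA_FIDE_BASAL] * n_genes,
        index=ids, name="loc_class",
    )
    rna = 10.0 ** rng.normal(1.5, 0.5, size=total)
    log2_te = rng.normal(0.0, 0.5, size=total)
    log2_te[n_genes:] += shift
    rfp = rna * 2.0 ** log2_te
    return (
        pd.Series(rfp, index=ids, name="rfp_tpm"),
        pd.Series(rna, index=ids, name="rna_tpm"),
        labels,
    )
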