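"""Degree-of-Apicality (DoA) statistics for smFISH polarity measurements.

A polarity measurement is one cell group's background, apical, and basal
mean fluorescence intensities (m.f.i.).  The DoA is the
background-corrected apical/basal ratio

    DoA = (apical_mfi - bg_mfi) / (basal_mfi - bg_mfi)

so DoA > 1 indicates apical bias.  Localization changes in mutant clones
are quantified as the KD/wt DoA ratio between knockdown and neighboring
wild-type cell groups of the same image stack (or, for whole-mutant egg
chambers, against the average wild-type DoA), tested against the
no-change null of 1 with a one-sample t-test.  The module also carries
the full significance-test battery the figures use: Student/Welch
two-sample t, one-way ANOVA with Tukey HSD post-hoc tests, total-signal
degradation checks, and paired A/B ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WT = "wt"
KD = "kd"

TWO_SIDED = "two_sided"
LESS = "less"
GREATER = "greater"

_SCIPY_ALT = {TWO_SIDED: "two-sided", LESS: "less", GREATER: "greater"}


class InvalidMeasurementError(ValueError):
    """Signal not above background: the DoA denominator is non-positive."""


@dataclass
class PolarityMeasurement:
    """One cell group's apical/basal/background m.f.i. with labels."""

    group_id: str
    apical_mfi: float
    basal_mfi: float
    bg_mfi: float
    cell_type: str = WT
    condition: str = ""
    rna_id: str = ""

    @property
    def is_valid(self) -> bool:
        """Both signals strictly above background."""
        return self.apical_mfi > self.bg_mfi and self.basal_mfi > self.bg_mfi


@dataclass
class DoAResult:
    group_id: str
    doa: float
    cell_type: str = WT
    condition: str = ""


@dataclass
class TestResult:
    """Uniform container for a significance test."""

    method: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alternative: str = TWO_SIDED
    estimate: float = float("nan")
    n: int | tuple[int, ...] = 0
    degenerate: bool = False
    #: for post-hoc results: the pair of group labels compared
    groups: tuple[str, str] | None = None

    def stars(self) -> str:
        """Figure-legend significance stars at 0.05 / 0.01 / 0.001."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def degree_of_apicality(m: PolarityMeasurement) -> DoAResult:
    """Background-corrected apical/basal ratio of one cell group.

    Raises :class:`InvalidMeasurementError` when either signal is not
    above background (non-positive denominator or numerator).
    """
    if m.basal_mfi <= m.bg_mfi:
        raise InvalidMeasurementError(
            f"group {m.group_id!r}: basal m.f.i. {m.basal_mfi} not above "
            f"background {m.bg_mfi} (division by non-positive denominator)"
        )
    if m.apical_mfi <= m.bg_mfi:
        raise InvalidMeasurementError(
            f"group {m.group_id!r}: apical m.f.i. {m.apical_mfi} not above "
            f"background {m.bg_mfi}"
        )
    doa = (m.apical_mfi - m.bg_mfi) / (m.basal_mfi - m.bg_mfi)
    return DoAResult(group_id=m.group_id, doa=doa, cell_type=m.cell_type, condition=m.condition)


def kd_wt_doa(doa_kd: float, doa_wt: float) -> float:
    """DoA ratio of paired knockdown over wild-type cells; 1 = no change."""
    if doa_kd <= 0 or doa_wt <= 0:
        raise ValueError("DoA values must be positive")
    return doa_kd / doa_wt


def null_vs_wt_doa(doa_mut: float, wt_doas: Sequence[float]) -> float:
    """Whole-mutant variant: one mutant DoA over the mean wild-type DoA.

    Used where mosaic tissue cannot be obtained and the comparison is a
    single mutant egg chamber against *n* wild-type egg chambers.
    """
    wt_doas = np.asarray(wt_doas, dtype=float)
    if wt_doas.size == 0:
        raise ValueError("wild-type DoA list must be non-empty")
    if doa_mut <= 0 or (wt_doas <= 0).any():
        raise ValueError("DoA values must be positive")
    return float(doa_mut / wt_doas.mean())


def one_sample_t_vs_one(values: Sequence[float], alternative: str = TWO_SIDED) -> TestResult:
    """One-sample Student t-test against the reference value mu = 1.

    ``alternative="less"`` gives the lower-tailed variant used for
    signal-degradation checks.  Zero-variance samples are degenerate:
    p = 1 when the mean sits on the null side, p = 0 when all values
    agree on a departure, flagged via ``degenerate``.
    """
    if alternative not in _SCIPY_ALT:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a one-sample t-test")
    mean = float(x.mean())
    if x.std(ddof=1) == 0.0:
        if alternative == TWO_SIDED:
            p = 1.0 if mean == 1.0 else 0.0
        elif alternative == LESS:
            p = 0.0 if mean < 1.0 else 1.0
        else:
            p = 0.0 if mean > 1.0 else 1.0
        return TestResult(
            method="one_sample_t_vs_one",
            statistic=0.0 if mean == 1.0 else float("inf") * np.sign(mean - 1.0),
            df=x.size - 1,
            p_value=p,
            alternative=alternative,
            estimate=mean,
            n=int(x.size),
            degenerate=True,
        )
    res = stats.ttest_1samp(x, popmean=1.0, alternative=_SCIPY_ALT[alternative])
    return TestResult(
        method="one_sample_t_vs_one",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        alternative=alternative,
        estimate=mean,
        n=int(x.size),
    )


def total_signal_ratio(m_kd: PolarityMeasurement, m_wt: PolarityMeasurement) -> float:
    """KD/wt ratio of total (apical + basal) background-corrected signal.

    Near 1 when knockdown redistributes rather than degrades the RNA;
    tested against 1 with ``one_sample_t_vs_one(alternative="less")`` to
    detect degradation.
    """
    num = (m_kd.apical_mfi - m_kd.bg_mfi) + (m_kd.basal_mfi - m_kd.bg_mfi)
    den = (m_wt.apical_mfi - m_wt.bg_mfi) + (m_wt.basal_mfi - m_wt.bg_mfi)
    if den <= 0:
        raise InvalidMeasurementError("wild-type total signal not above background")
    if num <= 0:
        raise InvalidMeasurementError("knockdown total signal not above background")
    return num / den


def two_sample_t(a: Sequence[float], b: Sequence[float], pooled: bool = True) -> TestResult:
    """Two-sided two-sample t-test (pooled Student or unpooled Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        same = a.mean() == b.mean()
        df = float(a.size + b.size - 2)
        return TestResult(
            method="student_t" if pooled else "welch_t",
            statistic=0.0 if same else float("inf") * np.sign(a.mean() - b.mean()),
            df=df,
            p_value=1.0 if same else 0.0,
            estimate=float(a.mean() - b.mean()),
            n=(int(a.size), int(b.size)),
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TestResult(
        method="student_t" if pooled else "welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
        n=(int(a.size), int(b.size)),
    )


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA followed by Tukey HSD post-hoc pairwise tests.

    Unequal group sizes use the Tukey-Kramer correction (as implemented
    by the studentized-range HSD).  Identically constant groups yield
    F = 0, p = 1 with a degenerate flag.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df = (float(k - 1), float(n_total - k))

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        anova = TestResult(
            method="one_way_anova", statistic=0.0, df=df, p_value=1.0,
            n=tuple(int(g.size) for g in arrays), degenerate=True,
        )
        pairwise = [
            TestResult(
                method="tukey_hsd", statistic=0.0, df=df[1], p_value=1.0,
                estimate=0.0, n=(int(arrays[i].size), int(arrays[j].size)),
                degenerate=True, groups=(labels[i], labels[j]),
            )
            for i in range(k) for j in range(i + 1, k)
        ]
        return anova, pairwise

    f_res = stats.f_oneway(*arrays)
    anova = TestResult(
        method="one_way_anova",
        statistic=float(f_res.statistic),
        df=df,
        p_value=float(f_res.pvalue),
        n=tuple(int(g.size) for g in arrays),
    )
    hsd = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            pairwise.append(
                TestResult(
                    method="tukey_hsd",
                    statistic=float(hsd.statistic[i, j]),
                    df=df[1],
                    p_value=float(hsd.pvalue[i, j]),
                    estimate=float(arrays[i].mean() - arrays[j].mean()),
                    n=(int(arrays[i].size), int(arrays[j].size)),
                    groups=(labels[i], labels[j]),
                )
            )
    return anova, pairwise


def ab_ratio_vs_one(a_values: Sequence[float], b_values: Sequence[float]) -> TestResult:
    """Paired apical/basal intensity ratios tested against A/B = 1.

    Used for diffuse signals (e.g. GFP-tagged proteins) where per-pair
    A/B ratios replace the background-corrected DoA.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired equal-length lists with n >= 2")
    if (b <= 0).any():
        raise ValueError("basal values must be positive")
    return one_sample_t_vs_one(a / b, alternative=TWO_SIDED)


def _pair_key(group_id: str) -> str:
    """Pairing key for wt/kd groups of the same image stack.

    Convention: a trailing ``_wt`` / ``_kd`` suffix is stripped; group
    ids without the suffix pair on the full id.
    """
    lowered = group_id.lower()
    for suffix in ("_wt", "_kd"):
        if lowered.endswith(suffix):
            return group_id[: -len(suffix)]
    return group_id


class PolarityExperiment:
    """DoA analysis over a table of smFISH polarity measurements.

    Measurements failing the signal-above-background check are excluded
    (logged), never clamped.  ``fit()`` computes per-measurement DoAs,
    pairs knockdown with wild-type groups of the same stack by the
    group-id stem, forms KD/wt DoA ratios, and tests each
    (rna, condition) cell against the no-change null KD/wt DoA = 1.
    """

    def __init__(self, measurements: Iterable[PolarityMeasurement]) -> None:
        measurements = list(measurements)
        self.excluded = [m for m in measurements if not m.is_valid]
        for m in self.excluded:
            logger.warning(
                "excluding group %r (%s/%s): m.f.i. not above background",
                m.group_id, m.rna_id, m.condition,
            )
        self.measurements = [m for m in measurements if m.is_valid]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PolarityExperiment":
        """Build from a table with columns group_id, rna_id, condition,
        cell_type, apical_mfi, basal_mfi, bg_mfi."""
        return cls(
            PolarityMeasurement(
                group_id=str(r.group_id),
                apical_mfi=float(r.apical_mfi),
                basal_mfi=float(r.basal_mfi),
                bg_mfi=float(r.bg_mfi),
                cell_type=str(r.cell_type),
                condition=str(getattr(r, "condition", "")),
                rna_id=str(getattr(r, "rna_id", "")),
            )
            for r in df.itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path) -> "PolarityExperiment":
        return cls.from_dataframe(pd.read_csv(path))

    def doas(self) -> pd.DataFrame:
        """Per-measurement DoA table."""
        rows = []
        for m in self.measurements:
            d = degree_of_apicality(m)
            rows.append(
                {
                    "group_id": m.group_id,
                    "rna_id": m.rna_id,
                    "condition": m.condition,
                    "cell_type": m.cell_type,
                    "doa": d.doa,
                    "pair_key": _pair_key(m.group_id),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["group_id", "rna_id", "condition", "cell_type", "doa", "pair_key"],
        )

    def kd_wt_ratios(self) -> pd.DataFrame:
        """Paired KD/wt DoA ratios, one per stack with both cell types."""
        doas = self.doas()
        rows = []
        for (rna, cond, key), sub in doas.groupby(["rna_id", "condition", "pair_key"]):
            wt = sub[sub["cell_type"] == WT]["doa"]
            kd = sub[sub["cell_type"] == KD]["doa"]
            if len(wt) == 0 or len(kd) == 0:
                logger.debug("unpaired stack %r (%s/%s) skipped", key, rna, cond)
                continue
            rows.append(
                {
                    "rna_id": rna,
                    "condition": cond,
                    "pair_key": key,
                    "kd_wt_doa": kd_wt_doa(float(kd.mean()), float(wt.mean())),
                }
            )
        return pd.DataFrame(rows, columns=["rna_id", "condition", "pair_key", "kd_wt_doa"])

    def fit(self) -> "PolarityResults":
        ratios = self.kd_wt_ratios()
        rows = []
        tests: dict[tuple[str, str], TestResult] = {}
        for (rna, cond), sub in ratios.groupby(["rna_id", "condition"]):
            values = sub["kd_wt_doa"].to_numpy()
            if len(values) < 2:
                logger.warning(
                    "rna %r condition %r: only %d paired stacks, no test",
                    rna, cond, len(values),
                )
                continue
            t = one_sample_t_vs_one(values, alternative=TWO_SIDED)
            tests[(rna, cond)] = t
            rows.append(
                {
                    "rna_id": rna,
                    "condition": cond,
                    "mean_kd_wt_doa": float(values.mean()),
                    "sd": float(values.std(ddof=1)),
                    "n": len(values),
                    "t": t.statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                    "significance": t.stars(),
                }
            )
        summary = pd.DataFrame(
            rows,
            columns=[
                "rna_id", "condition", "mean_kd_wt_doa", "sd", "n",
                "t", "df", "p_value", "significance",
            ],
        )
        return PolarityResults(self, ratios, summary, tests)


@dataclass
class PolarityResults:
    """Per-RNA/condition KD/wt DoA summary with one-sample t-tests."""

    experiment: PolarityExperiment
    ratios: pd.DataFrame
    table: pd.DataFrame
    tests: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            "KD/wt Degree-of-Apicality summary",
            "=" * 70,
            f"{'rna':<10}{'condition':<14}{'mean':>8}{'sd':>8}{'n':>4}"
            f"{'t':>9}{'p':>12}  sig",
            "-" * 70,
        ]
        for r in self.table.itertuples(index=False):
            lines.append(
                f"{r.rna_id:<10}{r.condition:<14}{r.mean_kd_wt_doa:>8.3f}"
                f"{r.sd:>8.3f}{r.n:>4d}{r.t:>9.3f}{r.p_value:>12.3e}  {r.significance}"
            )
        return "\n".join(lines)
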