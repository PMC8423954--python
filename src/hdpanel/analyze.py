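"""Per-feature group-comparison pipeline over a biomarker table.

:class:`BiomarkerStats` is the model object: it takes a
:class:`~hdpanel.cohort.BiomarkerTable` plus analysis options, and
``fit()`` runs, for every feature and planned contrast:

1. single-pass 2-SD outlier removal (per feature, per group);
2. exclusion of features missing in more than half the subjects
   (mirrors dropping assays that sit below the detection limit);
3. test dispatch — Monte-Carlo-calibrated KS normality on both contrast
   groups, then an F-ratio variance check: non-normal -> Mann-Whitney U,
   normal + unequal variance -> Welch's t, otherwise one-way ANOVA with
   Fisher's LSD planned contrasts (MSE pooled over all groups);
4. two-stage Benjamini-Krieger-Yekutieli FDR within each modality family
   (single-feature families are left unadjusted at alpha);
5. effect size (pooled-SD Cohen's d), post-hoc noncentral-t power and
   percent change attached per contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import GROUPS, BiomarkerTable

__all__ = [
    "Contrast",
    "PLANNED_CONTRASTS",
    "StatsConfig",
    "ContrastResult",
    "BiomarkerStats",
    "FeatureStatsResults",
]

logger = logging.getLogger("hdpanel.analyze")


@dataclass(frozen=True)
class Contrast:
    """A planned two-group comparison (group_a is the reference)."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")
        for g in (self.group_a, self.group_b):
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")


#: The three comparisons reported in the study design: disease effect,
#: treatment effect within the disease genotype, treatment effect in WT.
PLANNED_CONTRASTS = (
    Contrast("genotype", "WT-Veh", "R6/2-Veh"),
    Contrast("treatment", "R6/2-Veh", "R6/2-C31"),
    Contrast("wt_treatment", "WT-Veh", "WT-C31"),
)


@dataclass
class StatsConfig:
    """Options for the univariate pipeline."""

    alpha: float = 0.05          # test-dispatch and single-feature decisions
    q: float = 0.05              # FDR level for the BKY procedure
    contrasts: tuple[Contrast, ...] = PLANNED_CONTRASTS
    outlier_removal: bool = True
    min_group_n: int = 3         # smaller groups flag the result
    normality_min_n: int = 5     # below this, treated as normal (logged)
    max_missing_fraction: float = 0.5


@dataclass
class ContrastResult:
    feature: str
    contrast: str
    test_used: str               # anova_lsd | welch_t | mann_whitney
    statistic: float
    p_raw: float
    q_decision: bool
    cohens_d: float              # standardized shift of group_b relative to group_a
    power_posthoc: float
    percent_change: float        # 100 * (mean_b - mean_a) / mean_a
    n_a: int
    n_b: int
    fdr_family: str
    normality_p_a: float | None = None
    normality_p_b: float | None = None
    variance_test_p: float | None = None
    flags: list[str] = field(default_factory=list)


class BiomarkerStats:
    """Univariate group-comparison model for a biomarker table."""

    def __init__(self, table: BiomarkerTable, config: StatsConfig | None = None) -> None:
        self.table = table
        self.config = config or StatsConfig()

    # -- helpers -----------------------------------------------------------

    def _group_values(self, feature: str) -> dict[str, np.ndarray]:
        """Per-group finite values of one feature, outlier-filtered."""
        out = {}
        labels = self.table.group_labels
        col = self.table.data[feature]
        for g in GROUPS:
            vals = col[labels == g].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            if self.config.outlier_removal and vals.size >= 3:
                filtered, removed = st.remove_outliers_2sd(vals)
                if removed:
                    logger.info(
                        "outlier removal: feature=%s group=%s removed=%d", feature, g, len(removed)
                    )
                vals = filtered
            out[g] = vals
        return out

    def _dispatch(
        self, groups: dict[str, np.ndarray], contrast: Contrast, res: ContrastResult
    ) -> None:
        """Pick and run the test for one contrast; fills ``res`` in place."""
        cfg = self.config
        a = groups[contrast.group_a]
        b = groups[contrast.group_b]
        norm_ps = []
        for vals, attr in ((a, "normality_p_a"), (b, "normality_p_b")):
            if vals.size >= cfg.normality_min_n:
                p = st.ks_normality(vals)
            else:
                p = None
                res.flags.append(f"normality-skipped-small-n ({attr})")
                logger.info(
                    "normality: feature=%s contrast=%s n=%d too small, treated as normal",
                    res.feature, contrast.name, vals.size,
                )
            setattr(res, attr, p)
            norm_ps.append(p)
        normal = all(p is None or p > cfg.alpha for p in norm_ps)

        if not normal:
            res.test_used = "mann_whitney"
            res.statistic, res.p_raw = st.mann_whitney_u(a, b)
            return
        res.variance_test_p = st.levene_equal_var(a, b)
        if res.variance_test_p <= cfg.alpha:
            res.test_used = "welch_t"
            res.statistic, _, res.p_raw = st.welch_t(a, b)
            return
        res.test_used = "anova_lsd"
        labels = [g for g in GROUPS if g in groups and groups[g].size >= 2]
        ia, ib = labels.index(contrast.group_a), labels.index(contrast.group_b)
        _, tests = st.anova_fisher_lsd([groups[g] for g in labels], [(ia, ib)])
        res.statistic, _, res.p_raw = tests[0]

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "FeatureStatsResults":
        cfg = self.config
        n_subjects = len(self.table.data)
        results: list[ContrastResult] = []
        excluded: dict[str, str] = {}

        for feature in self.table.features:
            col = self.table.data[feature]
            if col.isna().sum() > cfg.max_missing_fraction * n_subjects:
                excluded[feature] = "missing in more than half the subjects"
                logger.info("excluded feature=%s: %s", feature, excluded[feature])
                continue
            modality = self.table.modality(feature)
            groups = self._group_values(feature)
            for contrast in cfg.contrasts:
                if contrast.group_a not in groups or contrast.group_b not in groups:
                    continue
                a, b = groups[contrast.group_a], groups[contrast.group_b]
                res = ContrastResult(
                    feature=feature, contrast=contrast.name, test_used="",
                    statistic=np.nan, p_raw=np.nan, q_decision=False,
                    cohens_d=np.nan, power_posthoc=np.nan, percent_change=np.nan,
                    n_a=int(a.size), n_b=int(b.size), fdr_family=modality,
                )
                if a.size < cfg.min_group_n or b.size < cfg.min_group_n:
                    res.flags.append("group-too-small")
                    results.append(res)
                    continue
                self._dispatch(groups, contrast, res)
                res.cohens_d = st.cohens_d(b, a)
                res.power_posthoc = st.posthoc_power(abs(res.cohens_d), a.size, b.size, cfg.alpha)
                res.percent_change = float(100 * (b.mean() - a.mean()) / a.mean())
                results.append(res)

        self._apply_fdr(results)
        return FeatureStatsResults(results, excluded, self.config, self.table)

    def _apply_fdr(self, results: list[ContrastResult]) -> None:
        """BKY within each modality family; singleton families unadjusted."""
        cfg = self.config
        families: dict[str, list[ContrastResult]] = {}
        for r in results:
            if np.isfinite(r.p_raw):
                families.setdefault(r.fdr_family, []).append(r)
        for family, members in families.items():
            n_features = len({r.feature for r in members})
            if n_features == 1:
                for r in members:
                    r.q_decision = bool(r.p_raw <= cfg.alpha)
                continue
            reject, diag = st.bky_fdr([r.p_raw for r in members], cfg.q)
            for r, rej in zip(members, reject):
                r.q_decision = bool(rej)
            logger.info(
                "fdr: family=%s m=%d r1=%d rejected=%d",
                family, len(members), diag["r1"], int(reject.sum()),
            )


class FeatureStatsResults:
    """Fitted per-feature, per-contrast comparison results."""

    def __init__(
        self,
        results: list[ContrastResult],
        excluded: dict[str, str],
        config: StatsConfig,
        table: BiomarkerTable,
    ) -> None:
        self.results = results
        self.excluded = excluded
        self.config = config
        self.table = table

    def to_frame(self) -> pd.DataFrame:
        """One row per feature x contrast."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "feature": r.feature, "contrast": r.contrast, "family": r.fdr_family,
                    "test": r.test_used, "statistic": r.statistic, "p_raw": r.p_raw,
                    "fdr_reject": r.q_decision, "cohens_d": r.cohens_d,
                    "power": r.power_posthoc, "percent_change": r.percent_change,
                    "n_a": r.n_a, "n_b": r.n_b, "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)

    def significant_features(self, contrast: str | None = None) -> list[str]:
        """Features with at least one FDR-rejected (optionally named) contrast."""
        feats = []
        for r in self.results:
            if r.q_decision and (contrast is None or r.contrast == contrast):
                if r.feature not in feats:
                    feats.append(r.feature)
        return feats

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Biomarker group-comparison summary",
            "=" * 70,
            f"subjects: {len(self.table.data)}   features analyzed: {df['feature'].nunique()}"
            f"   excluded: {len(self.excluded)}",
            f"contrasts: {', '.join(c.name for c in self.config.contrasts)}"
            f"   FDR: two-stage adaptive at q={self.config.q}",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            cols = ["feature", "contrast", "test", "p_raw", "fdr_reject",
                    "cohens_d", "power", "percent_change"]
            lines.append(df[cols].round(4).to_string(index=False))
        if self.excluded:
            lines.append("")
            for f, why in self.excluded.items():
                lines.append(f"excluded: {f} ({why})")
        return "\n".join(lines)
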