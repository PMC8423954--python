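"""Synthetic 2x2 cohort generation and the cohort table container.

The generator draws a genotype x treatment cohort (groups WT-Veh, WT-C31,
R6/2-Veh, R6/2-C31) from a per-feature Gaussian location-shift model:

    WT-Veh mean    = baseline_mean
    R6/2-Veh mean  = baseline + d_genotype * SD
    R6/2-C31 mean  = R6/2-Veh mean + d_treatment * SD
    WT-C31 mean    = baseline + d_wt_treatment * SD

with SD = baseline_mean * baseline_cv shared by all groups, optional
equicorrelated noise within each modality block (Gaussian copula), and an
optional log-normal marginal (moment-matched) as a sensitivity mode.
Contamination (gross outliers, below-detection-limit censoring) is injected
separately so the ground truth stays recoverable for testing the
downstream 2-SD filter and exclusion rules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FeatureSpec, default_panel

__all__ = [
    "GROUPS",
    "CohortConfig",
    "BiomarkerTable",
    "generate_cohort",
    "inject_contamination",
]

#: Canonical group order: genotype x treatment.
GROUPS = ("WT-Veh", "WT-C31", "R6/2-Veh", "R6/2-C31")

#: Default per-group sizes (the MRI volumetry cohort).
DEFAULT_GROUP_SIZES = {"WT-Veh": 12, "WT-C31": 8, "R6/2-Veh": 14, "R6/2-C31": 16}

_GENOTYPE = {"WT-Veh": "WT", "WT-C31": "WT", "R6/2-Veh": "R6/2", "R6/2-C31": "R6/2"}
_TREATMENT = {"WT-Veh": "Veh", "WT-C31": "C31", "R6/2-Veh": "Veh", "R6/2-C31": "C31"}

# Positive floor (in units of baseline_mean) used when clipping negative
# Gaussian draws for positively-supported features.
_CLIP_FRACTION = 1e-6


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort draw.

    Parameters
    ----------
    group_sizes : dict
        Group label -> number of subjects (>= 4). Realistic cohorts for
        this design run 4-50 per group; much larger sizes are supported
        for calibration studies of the generator itself.
    features : list of FeatureSpec
        Per-feature generative parameters; defaults to the 27-marker panel.
    correlation_rho : float
        Equicorrelation of the noise terms within each modality block,
        in [0, 1). Features of different modalities are independent.
    outlier_rate : float
        Per-cell probability of a gross outlier, in [0, 0.1].
    outlier_scale : float
        Outlier displacement in within-group SD units (>= 3).
    detection_floor : dict
        Feature name -> assay detection limit; values below it are
        censored to missing by :func:`inject_contamination`.
    lognormal : bool
        Use a moment-matched log-normal marginal instead of Gaussian.
    seed : int
        Seed for the cohort draw; identical config+seed gives an
        identical table.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    features: list[FeatureSpec] = field(default_factory=default_panel)
    correlation_rho: float = 0.2
    outlier_rate: float = 0.0
    outlier_scale: float = 5.0
    detection_floor: dict[str, float] = field(default_factory=dict)
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        for g, n in self.group_sizes.items():
            if int(n) < 4:
                raise ValueError(f"group size for {g} must be >= 4, got {n}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in config")
        if not 0 <= self.correlation_rho < 1:
            raise ValueError("correlation_rho must be in [0, 1)")
        if not 0 <= self.outlier_rate <= 0.1:
            raise ValueError("outlier_rate must be in [0, 0.1]")
        if self.outlier_rate > 0 and self.outlier_scale < 3:
            raise ValueError("outlier_scale must be >= 3 SD units")
        unknown = set(self.detection_floor) - set(names)
        if unknown:
            raise ValueError(f"detection_floor names unknown features: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def spec(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


class BiomarkerTable:
    """Subject x feature table with group labels and feature metadata.

    ``data`` holds one row per subject (index = subject id) with columns
    ``genotype``, ``treatment`` and then the feature columns. Feature
    metadata maps each feature to its (modality, units). ``contamination``
    records ground truth about injected outliers and censored cells.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_meta: dict[str, dict[str, str]],
        contamination: dict | None = None,
    ) -> None:
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated subject ids: {dupes}")
        for col in ("genotype", "treatment"):
            if col not in data.columns:
                raise ValueError(f"missing required column {col!r}")
        bad = set(data["genotype"]) - {"WT", "R6/2"}
        if bad:
            raise ValueError(f"invalid genotype labels: {sorted(bad)}")
        bad = set(data["treatment"]) - {"Veh", "C31"}
        if bad:
            raise ValueError(f"invalid treatment labels: {sorted(bad)}")
        feats = [c for c in data.columns if c not in ("genotype", "treatment")]
        missing_meta = set(feats) - set(feature_meta)
        if missing_meta:
            raise ValueError(f"features without metadata: {sorted(missing_meta)}")
        self.data = data
        self.feature_meta = feature_meta
        self.contamination = contamination or {"outliers": [], "below_floor": []}

    # -- basic access ------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("genotype", "treatment")]

    @property
    def group_labels(self) -> pd.Series:
        """Per-subject '<genotype>-<treatment>' labels."""
        return self.data["genotype"].str.cat(self.data["treatment"], sep="-")

    def group(self, label: str) -> pd.DataFrame:
        """Feature sub-table of one group ('WT-Veh', ...)."""
        if label not in GROUPS:
            raise KeyError(label)
        return self.data.loc[self.group_labels == label, self.features]

    def group_sizes(self) -> dict[str, int]:
        counts = self.group_labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def modality(self, feature: str) -> str:
        return self.feature_meta[feature]["modality"]

    def copy(self) -> "BiomarkerTable":
        return BiomarkerTable(
            self.data.copy(),
            {k: dict(v) for k, v in self.feature_meta.items()},
            json.loads(json.dumps(self.contamination)),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = ", ".join(f"{g}: {n}" for g, n in self.group_sizes().items())
        return f"<BiomarkerTable {len(self.data)} subjects x {len(self.features)} features ({sizes})>"

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, index=False)
        sidecar = {"feature_meta": self.feature_meta, "contamination": self.contamination}
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "BiomarkerTable":
        """Read a table written by :meth:`to_csv` (sidecar optional)."""
        path = Path(path)
        raw = pd.read_csv(path, dtype={"subject_id": str})
        for col in ("subject_id", "genotype", "treatment"):
            if col not in raw.columns:
                raise ValueError(f"{path}: malformed header, missing column {col!r}")
        feats = [c for c in raw.columns if c not in ("subject_id", "genotype", "treatment")]
        for col in feats:
            if not pd.api.types.is_numeric_dtype(raw[col]):
                coerced = pd.to_numeric(raw[col], errors="coerce")
                bad = raw.index[coerced.isna() & raw[col].notna()]
                if len(bad):
                    raise ValueError(
                        f"{path}: non-numeric cell at row {bad[0] + 2}, column {col!r}"
                    )
                raw[col] = coerced
        data = raw.set_index("subject_id")
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            sidecar = json.loads(meta_path.read_text())
            meta = sidecar["feature_meta"]
            contamination = sidecar.get("contamination")
        else:
            meta = {f: {"modality": "unknown", "units": ""} for f in feats}
            contamination = None
        return cls(data, meta, contamination)


def _group_mean(spec: FeatureSpec, group: str) -> float:
    base, sd = spec.baseline_mean, spec.sd
    if group == "WT-Veh":
        return base
    if group == "WT-C31":
        return base + spec.d_wt_treatment * sd
    if group == "R6/2-Veh":
        return base + spec.d_genotype * sd
    if group == "R6/2-C31":
        return base + (spec.d_genotype + spec.d_treatment) * sd
    raise KeyError(group)


def _block_noise(rng: np.random.Generator, n: int, m: int, rho: float, block: str) -> np.ndarray:
    """n x m equicorrelated standard-normal draws for one modality block."""
    z = rng.standard_normal((n, m))
    if rho == 0 or m == 1:
        return z
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:  # unreachable for rho in [0,1)
        raise ValueError(
            f"correlation block for modality {block!r} is not positive definite"
        ) from err
    return z @ chol.T


def generate_cohort(config: CohortConfig) -> BiomarkerTable:
    """Draw a synthetic cohort table from ``config``.

    Subjects are ordered by group (canonical group order) with ids
    ``<group>-<i>``. The same config and seed reproduce the table exactly.
    Negative draws for these positively-supported features are clipped to
    a small positive floor; a warning reports the clip count.
    """
    rng = np.random.default_rng(config.seed)
    groups = [g for g in GROUPS if config.group_sizes.get(g, 0) > 0]
    sizes = [config.group_sizes[g] for g in groups]
    n_total = int(sum(sizes))
    feats = config.features

    # Noise: one equicorrelated block per modality, all subjects at once.
    noise = np.empty((n_total, len(feats)))
    modalities = [f.modality for f in feats]
    for block in dict.fromkeys(modalities):
        idx = [j for j, m in enumerate(modalities) if m == block]
        noise[:, idx] = _block_noise(rng, n_total, len(idx), config.correlation_rho, block)

    means = np.empty((n_total, len(feats)))
    row = 0
    subject_ids, genotype, treatment = [], [], []
    for g, n in zip(groups, sizes):
        for j, f in enumerate(feats):
            means[row : row + n, j] = _group_mean(f, g)
        subject_ids += [f"{g}-{i + 1:02d}" for i in range(n)]
        genotype += [_GENOTYPE[g]] * n
        treatment += [_TREATMENT[g]] * n
        row += n

    sds = np.array([f.sd for f in feats])
    if config.lognormal:
        # Match the target mean/SD per cell via log-normal moments.
        sigma2 = np.log1p((sds / np.maximum(means, 1e-300)) ** 2)
        mu = np.log(np.maximum(means, 1e-300)) - sigma2 / 2
        values = np.exp(mu + np.sqrt(sigma2) * noise)
    else:
        values = means + noise * sds

    floors = np.array([_CLIP_FRACTION * f.baseline_mean for f in feats])
    n_clipped = int((values < floors).sum())
    if n_clipped:
        warnings.warn(
            f"clipped {n_clipped} negative draws to a positive floor", stacklevel=2
        )
        values = np.maximum(values, floors)

    data = pd.DataFrame(values, columns=[f.name for f in feats])
    data.insert(0, "treatment", treatment)
    data.insert(0, "genotype", genotype)
    data.index = pd.Index(subject_ids, name="subject_id")
    meta = {f.name: {"modality": f.modality, "units": f.units} for f in feats}
    return BiomarkerTable(data, meta)


def inject_contamination(table: BiomarkerTable, config: CohortConfig) -> BiomarkerTable:
    """Add gross outliers and below-detection censoring to a cohort table.

    Each cell independently becomes an outlier with probability
    ``config.outlier_rate``: it is displaced from its current value by
    ``outlier_scale`` within-group SDs with random sign. Afterwards, cells
    below a feature's ``detection_floor`` are set to missing. Both kinds of
    perturbation are recorded in ``contamination`` (ground truth).
    """
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    feats = [f for f in config.features if f.name in out.features]

    if config.outlier_rate > 0:
        vals = out.data[[f.name for f in feats]].to_numpy(copy=True)
        hit = rng.random(vals.shape) < config.outlier_rate
        sign = rng.choice([-1.0, 1.0], size=vals.shape)
        sds = np.array([f.sd for f in feats])
        vals = np.where(hit, vals + sign * config.outlier_scale * sds, vals)
        out.data[[f.name for f in feats]] = vals
        rows, cols = np.nonzero(hit)
        out.contamination["outliers"] = [
            [str(out.data.index[r]), feats[c].name] for r, c in zip(rows, cols)
        ]

    for name, floor in config.detection_floor.items():
        if name not in out.features:
            continue
        below = out.data.index[out.data[name] < floor]
        out.data.loc[below, name] = np.nan
        out.contamination["below_floor"] += [[str(s), name] for s in below]

    return out
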