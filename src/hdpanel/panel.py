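"""Feature specifications for the default 27-marker panel.

The panel spans the modalities measured in a genotype x treatment (2x2)
R6/2 Huntington's-disease mouse study: MRI volumetry (regional volumes
proportional to total brain volume), diffusion-tensor metrics (MD, FA),
NODDI orientation dispersion (ODI), multi-echo relaxometry (R2*), plasma
cytokines, and urinary p75NTR extracellular domain normalized to
creatinine.

Each :class:`FeatureSpec` carries the feature's healthy-vehicle (WT-Veh)
baseline, its coefficient of variation, and signed standardized effect
sizes (Cohen's d, in units of the within-group SD) for the genotype shift
(WT-Veh -> R6/2-Veh), the treatment shift within the disease genotype
(R6/2-Veh -> R6/2-C31), and the treatment shift within wild types.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FeatureSpec", "MODALITIES", "default_panel"]

MODALITIES = (
    "volume",
    "MD",
    "FA",
    "ODI",
    "R2*",
    "R2*_per_vol",
    "cytokine",
    "urinary_p75",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Generative specification of one biomarker feature.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    modality : str
        One of :data:`MODALITIES`; also defines the FDR family and the
        within-modality correlation block.
    roi_or_analyte : str
        Brain region (imaging features) or analyte (biofluid features).
    units : str
        Measurement units of the raw feature values.
    baseline_mean : float
        WT-Veh group mean, in feature units. Must be positive.
    baseline_cv : float
        Coefficient of variation; the within-group SD is
        ``baseline_mean * baseline_cv`` for every group (homoscedastic).
    d_genotype : float
        Standardized WT-Veh -> R6/2-Veh mean shift (signed Cohen's d).
    d_treatment : float
        Standardized R6/2-Veh -> R6/2-C31 mean shift.
    d_wt_treatment : float
        Standardized WT-Veh -> WT-C31 mean shift (usually 0).
    """

    name: str
    modality: str
    roi_or_analyte: str
    units: str
    baseline_mean: float
    baseline_cv: float
    d_genotype: float = 0.0
    d_treatment: float = 0.0
    d_wt_treatment: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.baseline_mean > 0:
            raise ValueError(f"{self.name}: baseline_mean must be positive")
        if not 0 < self.baseline_cv < 1:
            raise ValueError(f"{self.name}: baseline_cv must be in (0, 1)")
        if not self.units:
            raise ValueError(f"{self.name}: units must be non-empty")

    @property
    def sd(self) -> float:
        """Within-group standard deviation in feature units."""
        return self.baseline_mean * self.baseline_cv


# Effect magnitudes for features with published values; the rest default to
# |d_genotype| = 1.5 and |d_treatment| = 1.0 with directions taken from the
# reported direction of change (disease: volumes down, MD up, striatal FA up
# and other-region FA down, ODI down, raw R2* down, cytokines up, urinary
# p75 up; treatment moves the disease group back toward wild type).
#
# Where a percent change was published alongside d, the CV is chosen so both
# calibrations hold at once: cv = |percent|/100/|d| (e.g. striatal volume:
# a 16% reduction at d = 3.13 gives cv = 0.0511).
def default_panel() -> list[FeatureSpec]:
    """Return the 27-feature default panel, in canonical column order."""
    f = FeatureSpec
    return [
        # -- MRI volumetry: ROI volume / total brain volume ----------------
        f("vol_striatum", "volume", "striatum", "fraction of brain",
          0.052, 0.16 / 3.13, d_genotype=-3.13, d_treatment=1.20),
        f("vol_globus_pallidus", "volume", "globus pallidus", "fraction of brain",
          0.0040, 0.22 / 2.00, d_genotype=-2.00, d_treatment=2.00),
        f("vol_cortex", "volume", "cortex", "fraction of brain",
          0.26, 0.16 / 3.66, d_genotype=-3.66, d_treatment=0.97),
        f("vol_corpus_callosum", "volume", "corpus callosum/ec", "fraction of brain",
          0.022, 0.09 / 1.90, d_genotype=-1.90, d_treatment=1.00),
        f("vol_hippocampus", "volume", "dorsal hippocampus", "fraction of brain",
          0.026, 0.05, d_genotype=-1.5, d_treatment=1.0),
        f("vol_thalamus", "volume", "thalamus", "fraction of brain",
          0.042, 0.05, d_genotype=-1.5, d_treatment=1.0),
        # -- diffusion: mean diffusivity -----------------------------------
        f("md_striatum", "MD", "striatum", "um^2/ms",
          0.72, 0.05, d_genotype=1.5, d_treatment=0.0),
        f("md_globus_pallidus", "MD", "globus pallidus", "um^2/ms",
          0.70, 0.05, d_genotype=1.5, d_treatment=-1.0),
        f("md_corpus_callosum", "MD", "corpus callosum/ec", "um^2/ms",
          0.75, 0.05, d_genotype=1.5, d_treatment=-1.0),
        # -- diffusion: fractional anisotropy ------------------------------
        f("fa_striatum", "FA", "striatum", "unitless",
          0.18, 0.08, d_genotype=1.5, d_treatment=-1.32),
        f("fa_hippocampus", "FA", "dorsal hippocampus", "unitless",
          0.22, 0.08, d_genotype=-1.5, d_treatment=1.0),
        f("fa_corpus_callosum", "FA", "corpus callosum/ec", "unitless",
          0.38, 0.08, d_genotype=-1.5, d_treatment=0.0),
        f("fa_cortex", "FA", "cortex", "unitless",
          0.20, 0.08, d_genotype=-1.5, d_treatment=0.0),
        f("fa_thalamus", "FA", "thalamus", "unitless",
          0.30, 0.08, d_genotype=-1.5, d_treatment=0.0),
        # -- NODDI orientation dispersion ----------------------------------
        f("odi_striatum", "ODI", "striatum", "unitless",
          0.35, 0.08, d_genotype=-1.5, d_treatment=1.0),
        f("odi_globus_pallidus", "ODI", "globus pallidus", "unitless",
          0.30, 0.08, d_genotype=-1.5, d_treatment=1.0),
        # -- multi-echo relaxometry (raw R2*) ------------------------------
        f("r2s_striatum", "R2*", "striatum", "1/s",
          31.0, 0.05, d_genotype=-2.57, d_treatment=1.0),
        f("r2s_globus_pallidus", "R2*", "globus pallidus", "1/s",
          34.0, 0.05, d_genotype=-1.60, d_treatment=1.0),
        f("r2s_cortex", "R2*", "cortex", "1/s",
          27.0, 0.05, d_genotype=-1.83, d_treatment=0.0),
        f("r2s_thalamus", "R2*", "thalamus", "1/s",
          29.0, 0.05, d_genotype=-1.5, d_treatment=1.0),
        # -- plasma cytokines ----------------------------------------------
        f("tnf_alpha", "cytokine", "TNF-alpha", "pg/ml",
          8.5, 0.30, d_genotype=1.5, d_treatment=-1.0),
        f("il_1b", "cytokine", "IL-1beta", "pg/ml",
          1.6, 0.30, d_genotype=1.5, d_treatment=-1.0),
        f("il_6", "cytokine", "IL-6", "pg/ml",
          11.0, 0.30, d_genotype=1.5, d_treatment=-1.0),
        f("il_5", "cytokine", "IL-5", "pg/ml",
          5.2, 0.30, d_genotype=1.5, d_treatment=-1.0),
        f("il_10", "cytokine", "IL-10", "pg/ml",
          12.0, 0.30, d_genotype=1.5, d_treatment=0.0, d_wt_treatment=1.0),
        f("il_2", "cytokine", "IL-2", "pg/ml",
          4.5, 0.30, d_genotype=1.5, d_treatment=0.0),
        # -- urinary p75NTR extracellular domain ---------------------------
        f("p75_urinary", "urinary_p75", "p75NTR-ecd", "ng/mg creatinine",
          38.0, 0.44 / 1.71, d_genotype=1.71, d_treatment=-0.68),
    ]
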