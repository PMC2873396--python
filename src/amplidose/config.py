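"""Analysis thresholds and simulation parameters.

Two frozen configuration objects travel through the pipeline: the
published analysis cutoffs (copy-number calling thresholds, the 50-kb
integration window, the 7% expression percentile, the 1.5-fold FISH gain
ratio, the 0.05 significance level) and the synthetic-cohort generator
settings used to exercise the pipeline against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class InvalidParameterError(ValueError):
    """A configuration or operation parameter violates its contract."""


@dataclass(frozen=True)
class AnalysisThresholds:
    """Cutoffs used across the pipeline.

    Parameters
    ----------
    amp_log2 : float
        Minimum (exclusive) log2 copy-number ratio for an amplified locus.
    high_amp_log2 : float
        Minimum (exclusive) log2 ratio for a high-level amplification.
    loss_log2 : float
        Maximum (exclusive) log2 ratio for a loss. The default −1.0
        corresponds to a linear ratio of 0.5 (hemizygous loss); set to
        ``0.5`` to reproduce a literal "log2 < 0.5" reading, which also
        labels copy-neutral loci as lost.
    min_probes : int
        Minimum number of qualifying oligos for a reported segment.
    max_gap_probes : int
        Number of interior non-qualifying probes a run may bridge.
    window_bp : int
        Half-width (inclusive) of the copy-number window around a probe
        set's genomic position.
    extreme_percentile : float
        Percentile (per tail) defining over/underexpression calls.
    fish_gain_ratio : float
        Test/centromere signal ratio at or above which a tumor is
        scored as gained.
    alpha : float
        Significance level for all hypothesis tests.
    yates_correction : bool
        Apply the Yates continuity correction in 2x2 chi-square tests.
    """

    amp_log2: float = 2.0
    high_amp_log2: float = 3.5
    loss_log2: float = -1.0
    min_probes: int = 2
    max_gap_probes: int = 0
    window_bp: int = 50_000
    extreme_percentile: float = 7.0
    fish_gain_ratio: float = 1.5
    alpha: float = 0.05
    yates_correction: bool = False

    def __post_init__(self) -> None:
        if not (self.high_amp_log2 > self.amp_log2 > 0 > self.loss_log2):
            # the literal "log2 < 0.5" loss reading relaxes the last leg
            if not (self.high_amp_log2 > self.amp_log2 > 0
                    and self.loss_log2 < self.amp_log2):
                raise InvalidParameterError(
                    "thresholds must satisfy high_amp_log2 > amp_log2 > 0 "
                    f"> loss_log2; got {self}")
        if not 0 < self.extreme_percentile < 50:
            raise InvalidParameterError(
                f"extreme_percentile must be in (0, 50); got "
                f"{self.extreme_percentile}")
        if self.fish_gain_ratio <= 1:
            raise InvalidParameterError(
                f"fish_gain_ratio must exceed 1; got {self.fish_gain_ratio}")
        if self.min_probes < 1 or self.max_gap_probes < 0:
            raise InvalidParameterError("invalid probe-count thresholds")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError(f"alpha must be in (0,1); got {self.alpha}")

    def with_(self, **kwargs) -> "AnalysisThresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generator settings.

    Defaults mirror the study conditions: 14/33 gained tumors, 7/33
    MYCN-amplified, 1/33 with both; 20-60 scorable nuclei per tumor;
    risk-group hazards ordered worst (MYCN-amplified) to best (neither
    alteration) 3:2:1; a unit dosage slope coupling expression to copy
    number; a +3-sigma expression shift for planted tumor-elevated genes.
    """

    seed: int = 0
    probe_spacing_bp: int = 10_000
    noise_sd: float = 0.1
    dosage_slope: float = 1.0
    expression_noise_sd: float = 0.5
    gain_prevalence: float = 14 / 33
    myc_prevalence: float = 7 / 33
    both_prevalence: float = 1 / 33
    nuclei_range: tuple[int, int] = (20, 60)
    gained_ratio_mean: float = 2.0
    centromere_mean: float = 2.0
    group_hazards: dict = field(default_factory=lambda: {
        "MYCN_AMP": 0.3, "GAIN_12Q24": 0.2, "NEITHER": 0.1})
    censoring_rate: float = 0.2
    compendium_baseline_sd: float = 1.0
    elevated_effect: float = 3.0

    def __post_init__(self) -> None:
        for name in ("gain_prevalence", "myc_prevalence", "both_prevalence",
                     "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name} must be in [0,1]; got {v}")
        if self.both_prevalence > min(self.gain_prevalence, self.myc_prevalence):
            raise InvalidParameterError(
                "both_prevalence cannot exceed either marginal prevalence")
        if self.gain_prevalence + self.myc_prevalence - self.both_prevalence > 1:
            raise InvalidParameterError("prevalences imply a negative group")
        lo, hi = self.nuclei_range
        if lo < 1 or hi < lo:
            raise InvalidParameterError(
                f"nuclei_range must satisfy 1 <= low <= high; got {self.nuclei_range}")
        if self.probe_spacing_bp <= 0:
            raise InvalidParameterError("probe_spacing_bp must be positive")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
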