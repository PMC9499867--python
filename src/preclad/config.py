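"""Single source of truth for every cutoff and tuning constant in the pipeline.

No stage hard-codes a threshold: everything below is carried by
:class:`RunConfig`, echoed into the run manifest, and overridable from a
plain-text YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: CSF Abeta42/40 below this is amyloid-positive (A+).
CSF_AB4240_POSITIVITY = 0.071
#: CSF M-p-tau181 above this is tau-positive (T+), pg/ml.
CSF_MPTAU181_POSITIVITY = 24.0
#: Centiloid stage boundaries: emerging vs established plaque pathology.
CL_EARLY = 12.0
CL_ESTABLISHED = 30.0
#: Reference stratum for z-scoring: CSF Abeta42/40 strictly above this.
REFERENCE_AB4240 = 0.1
#: Abnormality thresholds on the reference z-scale (SD above reference mean).
ABNORMALITY_THRESHOLDS = (1.5, 2.0)
#: Fixed-sensitivity operating point.
FIXED_SENSITIVITY = 0.85
#: Age-stratification cutoffs: conventional 65 and the cohort median age.
AGE_CUTOFF = 65.0
AGE_CUTOFF_MEDIAN = 61.8
#: Robust-LOWESS span as an observation count, and bootstrap replicates.
SPAN_POINTS = 300
N_BOOT = 1000


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``seed`` is the master seed; each stage derives an independent child
    stream from it (recorded in the manifest), so toggling one stage never
    perturbs another.
    """

    # input: either a cohort CSV (+ optional follow-up CSV) or synthetic
    cohort_csv: str | None = None
    followup_csv: str | None = None
    column_mapping: str | None = None
    synthetic: bool = True
    n_participants: int = 397
    output_dir: str = "preclad_out"
    seed: int = 20220811

    # stage toggles
    run_preprocess: bool = True
    run_effects: bool = True
    run_trajectory: bool = True
    run_discrimination: bool = True
    run_longitudinal: bool = True

    # constants registry (defaults are the study's printed values)
    csf_ab4240_positivity: float = CSF_AB4240_POSITIVITY
    csf_mptau181_positivity: float = CSF_MPTAU181_POSITIVITY
    cl_early: float = CL_EARLY
    cl_established: float = CL_ESTABLISHED
    reference_ab4240: float = REFERENCE_AB4240
    abnormality_thresholds: tuple[float, ...] = ABNORMALITY_THRESHOLDS
    fixed_sensitivity: float = FIXED_SENSITIVITY
    age_cutoff: float = AGE_CUTOFF
    age_cutoff_median: float = AGE_CUTOFF_MEDIAN
    span_points: int = SPAN_POINTS
    n_boot: int = N_BOOT
    #: order of age/sex correction vs reference standardization (see docs)
    residualize_before_zscore: bool = True

    def validate(self) -> None:
        if not self.synthetic and self.cohort_csv is None:
            raise ValueError("either synthetic=true or cohort_csv must be set")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.span_points < 3:
            raise ValueError("span_points must be >= 3")
        for t in self.abnormality_thresholds:
            if t <= 0:
                raise ValueError("abnormality thresholds must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["abnormality_thresholds"] = list(self.abnormality_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "abnormality_thresholds" in raw:
            raw["abnormality_thresholds"] = tuple(raw["abnormality_thresholds"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
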