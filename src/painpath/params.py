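"""Ground-truth generative parameters for the synthetic self-regulation study.

The generative model has two dissociated routes from the experimental
manipulations to the pain report:

* nociceptive route — stimulus temperature drives a signature-like scalar
  response (``temp_to_sig``), which in turn drives pain (``sig_to_pain``);
  temperature also has a direct path (``temp_to_pain``);
* self-regulatory route — the regulation instruction drives a first mediator
  region m1 (``reg_to_m1``), m1 drives a second mediator m2 (``m1_to_m2``),
  and m2 drives pain (``m2_to_pain``); regulation also has a direct path
  (``reg_to_pain_direct``).

Crucially the signature never responds to regulation and the m1/m2 chain
never responds to temperature, so the two routes are separately modifiable
by construction and their dissociation is recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import yaml

__all__ = ["GroundTruthParams", "DEFAULT_PARAMS"]

# Celsius values of the six stimulation levels (1 degC apart).
TEMP_LEVELS_C = {1: 44.3, 2: 45.3, 3: 46.3, 4: 47.3, 5: 48.3, 6: 49.3}
#: centering constant for the temperature predictor (mid-range, level 3)
TEMP_CENTER_C = 46.3


@dataclass
class GroundTruthParams:
    """Population-level generative parameters with per-path heterogeneity.

    Slopes are in outcome units per predictor unit: ratings on a 0-100
    visual-analogue scale, temperature in degC, regulation coded +1/0/-1,
    signature and mediator activity in arbitrary activation units.

    ``between_subject_sd`` maps path names to the SD of subject-level random
    slopes/intercepts; ``residual_sd`` maps each generative equation to its
    trial-level noise SD.
    """

    # population path coefficients
    rating_intercept: float = 48.0
    temp_to_pain: float = 7.0        # direct heat effect, rating units / degC
    reg_to_pain_direct: float = 5.0  # direct regulation effect (c')
    sig_intercept: float = 5.0
    temp_to_sig: float = 2.5         # signature units / degC
    sig_to_pain: float = 1.6         # rating units / signature unit
    reg_to_m1: float = -1.0          # m1 units / regulation code unit
    m1_to_m2: float = 0.8            # m2 units / m1 unit
    m2_to_pain: float = -4.0         # rating units / m2 unit

    between_subject_sd: dict = field(default_factory=lambda: {
        "rating_intercept": 8.0,
        "temp_to_pain": 1.4,
        "reg_to_pain_direct": 2.0,
        "sig_intercept": 1.0,
        "temp_to_sig": 0.5,
        "sig_to_pain": 0.32,
        "reg_to_m1": 0.25,
        "m1_to_m2": 0.15,
        "m2_to_pain": 0.8,
    })
    residual_sd: dict = field(default_factory=lambda: {
        "sig": 1.5,
        "m1": 0.5,
        "m2": 0.5,
        "rating": 8.0,
    })

    decision_threshold: float = 50.0  # rating above which the trial is "pain"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sd in self.between_subject_sd.items():
            if sd < 0:
                raise ValueError(f"between_subject_sd[{name!r}] must be >= 0")
        for name, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError(f"residual_sd[{name!r}] must be >= 0")

    # -- config round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthParams":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GroundTruthParams":
        if isinstance(source, (str, bytes)) and "\n" in str(source):
            d = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "GroundTruthParams":
        return dataclasses.replace(self, **kwargs)

    def zero_noise(self) -> "GroundTruthParams":
        """Copy with every noise source silenced (exact algebraic checks)."""
        return self.replace(
            between_subject_sd={k: 0.0 for k in self.between_subject_sd},
            residual_sd={k: 0.0 for k in self.residual_sd},
        )


DEFAULT_PARAMS = GroundTruthParams()
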