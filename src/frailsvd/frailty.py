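"""Fried physical-frailty phenotype scoring.

Five components are scored from raw measurements:

* **slowness** — timed up-and-go strictly over 10 s;
* **weakness** — maximal hand grip at or below the sex- and BMI-stratum
  cutoff (table shipped as an editable YAML config);
* **weight loss** — self-reported unintentional loss of >= 5% or >= 3 kg in
  the previous year;
* **exhaustion** and **mobility** — questionnaire-derived boolean inputs
  (the exact item/combination rules live upstream of this package).

A subject with 0 positive components is non-frail, 1–2 pre-frail, and >= 3
frail.  Classification is a pure function of the component count.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Optional

import yaml

NON_FRAIL = "non_frail"
PRE_FRAIL = "pre_frail"
FRAIL = "frail"
GROUPS = (NON_FRAIL, PRE_FRAIL, FRAIL)

COMPONENTS = ("slowness", "weakness", "weight_loss", "exhaustion", "mobility")

TUG_SLOW_SECONDS = 10.0  # strictly over
WEIGHT_LOSS_PCT = 5.0  # inclusive
WEIGHT_LOSS_KG = 3.0  # inclusive
OBESITY_BMI = 30.0  # inclusive
HADS_DEPRESSION_CUTOFF = 8  # inclusive


@dataclass
class FrailtyInputs:
    """Raw per-subject measurements feeding the five components."""

    tug_seconds: float
    grip_kg: float
    sex: str  # "female" | "male"
    bmi: float
    weight_loss_kg: float = 0.0
    weight_loss_pct: float = 0.0
    exhaustion_flag: bool = False
    mobility_difficulty_flag: bool = False
    hads_depression: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tug_seconds is not None and self.tug_seconds <= 0:
            raise ValueError("tug_seconds must be positive")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass
class FrailtyProfile:
    slowness: bool
    weakness: bool
    weight_loss: bool
    exhaustion: bool
    mobility: bool

    @property
    def n_components(self) -> int:
        return sum(
            bool(getattr(self, c)) for c in COMPONENTS
        )

    @property
    def category(self) -> str:
        return classify(self.n_components)


def load_grip_cutoffs(path=None) -> dict:
    """Load the sex x BMI-stratum grip cutoff table (kg).

    The packaged default follows the canonical frailty-phenotype strata;
    pass ``path`` to substitute a site-specific table.
    """
    if path is None:
        ref = importlib.resources.files("frailsvd.data") / "grip_cutoffs.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {}
    for sex, rows in raw.items():
        table[sex] = [(float(b), float(c)) for b, c in rows]
    return table


def grip_cutoff_kg(sex: str, bmi: float, cutoffs: dict | None = None) -> float:
    """Weakness cutoff for a subject's sex/BMI stratum."""
    cutoffs = cutoffs or load_grip_cutoffs()
    if sex not in cutoffs:
        raise KeyError(f"no grip cutoffs for sex {sex!r}")
    for upper, cut in cutoffs[sex]:
        if bmi <= upper:
            return cut
    raise KeyError(f"no grip-cutoff stratum for sex={sex!r}, bmi={bmi}")


def score_components(
    inputs: FrailtyInputs, grip_cutoffs: dict | None = None
) -> FrailtyProfile:
    """Score the five frailty components from raw measurements."""
    cutoff = grip_cutoff_kg(inputs.sex, inputs.bmi, grip_cutoffs)
    return FrailtyProfile(
        slowness=inputs.tug_seconds > TUG_SLOW_SECONDS,
        weakness=inputs.grip_kg <= cutoff,
        weight_loss=(
            inputs.weight_loss_pct >= WEIGHT_LOSS_PCT
            or inputs.weight_loss_kg >= WEIGHT_LOSS_KG
        ),
        exhaustion=bool(inputs.exhaustion_flag),
        mobility=bool(inputs.mobility_difficulty_flag),
    )


def classify(n_components: int) -> str:
    """0 components -> non-frail; 1–2 -> pre-frail; >= 3 -> frail."""
    if not 0 <= n_components <= len(COMPONENTS):
        raise ValueError(
            f"n_components must lie in [0, {len(COMPONENTS)}], got {n_components}"
        )
    if n_components == 0:
        return NON_FRAIL
    if n_components <= 2:
        return PRE_FRAIL
    return FRAIL


def derived_demographics(inputs: FrailtyInputs) -> dict:
    """Demographic flags used in the cohort description table."""
    flags = {"obesity": inputs.bmi >= OBESITY_BMI}
    if inputs.hads_depression is not None and not (
        isinstance(inputs.hads_depression, float) and math.isnan(inputs.hads_depression)
    ):
        flags["depressive_symptoms"] = inputs.hads_depression >= HADS_DEPRESSION_CUTOFF
    else:
        flags["depressive_symptoms"] = None
    return flags
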