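"""Synthetic cohort generator with a planted code→cancer hazard structure.

Real disease-registry data of the kind this package models are access
restricted, so every component is exercised on simulated cohorts that emulate
the relevant statistics of such registries:

* two visit regimes — long, sparse histories (``dk_like``: median ~22 codes
  over ~23 years, the shape of a national inpatient registry) and short,
  dense ones (``va_like``: median ~188 codes over ~12 years, the shape of an
  integrated EHR system);
* a low-incidence cancer label (defaults near 0.3% of patients);
* planted **early-risk codes**: carried by a fraction of patients years before
  onset, each multiplying the per-month cancer hazard from its first
  occurrence onward;
* planted **late-symptom codes**: emitted only within a short lead window
  (default 6 months) before onset, mimicking prodromal symptoms — the signal
  an exclusion-window experiment removes.

Cancer onset follows a discrete-time monthly hazard
``h_m = h0 * prod(multipliers of risk codes present by month m)``; upon
onset a reserved cancer code is written at the diagnosis date. Background
codes are drawn from a Zipf-like popularity distribution (exponent 1.2).
Everything is driven by a single seeded generator: identical config + seed
gives byte-identical files.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .dates import DAYS_PER_MONTH, DAYS_PER_YEAR, add_months
from .records import DiseaseEvent, PatientRecord

__all__ = ["RiskCodeSpec", "GeneratorConfig", "generate_cohort", "CANCER_CODE"]

CANCER_CODE = "C25"

REGIMES = {
    "dk_like": {"median_span_years": 23.0, "median_events": 22, "span_sigma": 0.35},
    "va_like": {"median_span_years": 12.0, "median_events": 188, "span_sigma": 0.35},
}


@dataclass(frozen=True)
class RiskCodeSpec:
    """A planted code with a hazard effect and/or a pre-onset lead window."""

    code_index: int
    hazard_multiplier: float = 1.0
    lead_window_months: float = 0.0  # symptom codes: emitted only in-window
    carrier_prob: float = 0.06       # risk codes: fraction of patients planted
    emit_prob: float = 0.9           # symptom codes: emission prob per case

    def __post_init__(self):
        if self.hazard_multiplier < 1.0:
            raise ValueError("hazard_multiplier must be >= 1")
        if self.lead_window_months < 0:
            raise ValueError("lead window must be non-negative")


def _default_risk_codes() -> list[RiskCodeSpec]:
    return [
        RiskCodeSpec(10, hazard_multiplier=15.0, carrier_prob=0.08),
        RiskCodeSpec(11, hazard_multiplier=15.0, carrier_prob=0.08),
        RiskCodeSpec(12, hazard_multiplier=8.0, carrier_prob=0.08),
        RiskCodeSpec(13, hazard_multiplier=8.0, carrier_prob=0.08),
    ]


def _default_symptom_codes() -> list[RiskCodeSpec]:
    return [
        RiskCodeSpec(20, lead_window_months=6.0),
        RiskCodeSpec(21, lead_window_months=6.0),
        RiskCodeSpec(22, lead_window_months=6.0),
    ]


@dataclass
class GeneratorConfig:
    """Cohort-level knobs of the simulator."""

    n_patients: int = 10_000
    vocab_size: int = 200
    regime: str = "dk_like"
    baseline_incidence: float = 0.0005
    risk_codes: list[RiskCodeSpec] = field(default_factory=_default_risk_codes)
    late_symptom_codes: list[RiskCodeSpec] = field(
        default_factory=_default_symptom_codes)
    zipf_exponent: float = 1.2
    carrier_time_fraction: float = 0.6  # risk codes planted in this early span
    data_end: dt.date = dt.date(2019, 12, 31)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.baseline_incidence <= 0.05:
            raise ValueError("baseline_incidence must lie in [0, 0.05]")
        for spec in self.risk_codes + self.late_symptom_codes:
            if not 0 <= spec.code_index < self.vocab_size:
                raise ValueError(f"code index {spec.code_index} outside vocabulary")
        # expected incidence under the planted multipliers must stay low;
        # first-order approximation assuming independent carriage
        boost = 1.0
        for spec in self.risk_codes:
            boost *= 1.0 + spec.carrier_prob * (spec.hazard_multiplier - 1.0)
        if self.baseline_incidence * boost > 0.05:
            raise ValueError(
                f"config implies expected incidence ~"
                f"{self.baseline_incidence * boost:.3f} > 5%"
            )


def _code_name(index: int) -> str:
    """Synthetic three-character level-3-style code for vocabulary slot i."""
    return f"{chr(65 + index // 100)}{index % 100:02d}"


def code_token(index: int) -> tuple[str, str]:
    return ("icd10", _code_name(index))


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Simulate one cohort of PatientRecords (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    regime = REGIMES[config.regime]
    symptom_idx = {s.code_index for s in config.late_symptom_codes}

    # background popularity: Zipf-like long tail; planted codes (risk and
    # symptom) enter only through their mechanisms, never as background noise
    popularity = (np.arange(config.vocab_size) + 1.0) ** (-config.zipf_exponent)
    for idx in symptom_idx | {s.code_index for s in config.risk_codes}:
        popularity[idx] = 0.0
    popularity /= popularity.sum()

    # monthly baseline hazard chosen so a code-free patient observed for the
    # regime's median span reaches the configured incidence
    median_months = regime["median_span_years"] * 12.0
    h0 = -np.log1p(-config.baseline_incidence) / median_months

    records: list[PatientRecord] = []
    end_ord = config.data_end.toordinal()
    for i in range(config.n_patients):
        birth_ord = int(rng.integers(
            dt.date(1925, 1, 1).toordinal(), dt.date(1975, 12, 31).toordinal()
        ))
        span_years = regime["median_span_years"] * float(
            rng.lognormal(0.0, regime["span_sigma"]))
        max_span = (end_ord - birth_ord) / DAYS_PER_YEAR - 18.0
        span_years = min(span_years, max(max_span, 1.0))
        start_ord = end_ord - int(span_years * DAYS_PER_YEAR)

        n_events = max(1, int(rng.poisson(
            regime["median_events"] * rng.lognormal(0.0, 0.4))))
        event_ords = np.sort(rng.integers(start_ord, end_ord + 1, size=n_events))
        event_codes = rng.choice(config.vocab_size, size=n_events, p=popularity)

        events = [(int(o), int(c)) for o, c in zip(event_ords, event_codes)]

        # plant early-risk carrier codes
        plant_span = max(1.0, config.carrier_time_fraction * (end_ord - start_ord))
        for spec in config.risk_codes:
            if spec.carrier_prob > 0 and rng.random() < spec.carrier_prob:
                t = start_ord + int(rng.random() * plant_span)
                events.append((t, spec.code_index))
        events.sort()

        # discrete monthly hazard with multiplicative code effects
        n_months = max(1, int((end_ord - start_ord) / DAYS_PER_MONTH))
        mult = np.ones(n_months)
        by_code: dict[int, float] = {
            s.code_index: s.hazard_multiplier for s in config.risk_codes
        }
        applied: set[int] = set()  # a code's effect counts once, at first occurrence
        for t, c in events:
            m = by_code.get(c)
            if m is not None and m > 1.0 and c not in applied:
                applied.add(c)
                first_month = int((t - start_ord) / DAYS_PER_MONTH) + 1
                if first_month < n_months:
                    mult[first_month:] *= m
        hazard = np.minimum(h0 * mult, 0.5)
        draws = rng.random(n_months)
        hits = np.flatnonzero(draws < hazard)

        cancer_date = None
        end_of_data = config.data_end
        if len(hits):
            onset_ord = start_ord + int((hits[0] + 1) * DAYS_PER_MONTH)
            onset_ord = min(onset_ord, end_ord)
            cancer_date = dt.date.fromordinal(onset_ord)
            # prodromal symptom codes inside their lead windows
            for spec in config.late_symptom_codes:
                if rng.random() < spec.emit_prob and spec.lead_window_months > 0:
                    w_days = spec.lead_window_months * DAYS_PER_MONTH
                    t = onset_ord - int(rng.random() * w_days) - 1
                    if t >= start_ord:
                        events.append((t, spec.code_index))
            events.append((onset_ord, -1))  # reserved cancer code
            death_ord = onset_ord + int(rng.integers(30, 366))
            end_of_data = dt.date.fromordinal(min(death_ord, end_ord))
            if cancer_date > end_of_data:
                end_of_data = cancer_date
        events.sort()

        end_of_data_ord = end_of_data.toordinal()
        disease_events = [
            DiseaseEvent(
                code=CANCER_CODE if c == -1 else _code_name(c),
                date=dt.date.fromordinal(t),
                system="icd10",
            )
            for t, c in events
            if t <= end_of_data_ord
        ]
        records.append(
            PatientRecord(
                patient_id=f"P{i:07d}",
                birth_date=dt.date.fromordinal(birth_ord),
                end_of_data=end_of_data,
                sex=("F" if rng.random() < 0.5 else "M"),
                cancer_date=cancer_date,
                events=disease_events,
            )
        )
    return records
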