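"""Synthetic referral cohorts with planted, recoverable ground truth.

The generator emulates the structure of a pediatric-endocrinology referral
cohort drawn from outpatient EHR extracts, without any real data:

* each patient independently carries zero or more endocrine *condition
  profiles* (hypothyroidism, obesity, amenorrhea, ...), each with a planted
  conditional probability P(order B | condition C) for the specialist's
  first-visit workup orders;
* specialist orders are drawn by a noisy-OR over the patient's conditions
  plus a small base rate for generic orders, so multi-condition patients
  have a well-defined ground truth;
* *marker labs* (TSH, BMI, fasting glucose, ...) are measured in the
  pre-referral window with numeric values around or outside reference
  ranges, so categorization (TSH/high vs TSH/low) carries real signal;
* high-prevalence, specialty-irrelevant *noise items* (well-child visits,
  URIs, routine vaccines) appear on charts at equal rates inside and outside
  the cohort — they are the reason query-item weighting helps;
* condition items are enriched in the cohort relative to the outpatient
  background by a configurable factor (default 20x), which is the planted
  relative-risk weight;
* referral dates span several calendar years and visit delays are
  exponential, so the temporal split and the 183-day wait cutoff are both
  exercised.

Everything is drawn from a single ``numpy`` Generator, so output is
deterministic (byte-identical tables) for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import BackgroundStats
from .ehr_model import ClinicalItem, EventRecord
from .errors import ConfigurationError

QUERY_WINDOW_DAYS = 183


@dataclass(frozen=True)
class MarkerLab:
    """A numeric lab whose abnormal category flags specific conditions."""

    concept_id: str
    ref_low: float
    ref_high: float
    #: condition concept -> abnormal direction ("high"/"low") it induces
    directions: Mapping[str, str]
    measured_given_condition: float = 0.85
    abnormal_given_condition: float = 0.85
    background_measured_rate: float = 0.12
    background_abnormal_rate: float = 0.05


@dataclass(frozen=True)
class ConditionProfile:
    """One referral condition with its planted workup-order probabilities."""

    concept_id: str
    cohort_frequency: float
    #: cohort prevalence / outside-cohort outpatient prevalence
    enrichment: float
    #: target order concept -> planted P(order | this condition)
    target_probs: Mapping[str, float]


@dataclass(frozen=True)
class NoiseItem:
    """A chart item with no association to the specialist's orders."""

    concept_id: str
    domain: str
    cohort_prevalence: float
    outpatient_prevalence: float


@dataclass
class GeneratorConfig:
    n_train_patients: int = 2000
    n_test_patients: int = 500
    train_years: tuple[int, int] = (2015, 2019)
    test_year: int = 2020
    visit_delay_mean_days: float = 45.0
    conditions: list[ConditionProfile] = dc_field(default_factory=list)
    markers: list[MarkerLab] = dc_field(default_factory=list)
    noise_items: list[NoiseItem] = dc_field(default_factory=list)
    #: target order concept -> (domain, outpatient order prevalence)
    targets: dict[str, tuple[str, float]] = dc_field(default_factory=dict)
    #: condition-independent base order probabilities (generic labs)
    base_order_probs: dict[str, float] = dc_field(default_factory=dict)
    #: stale-chart noise: chance of one extra noise event before the window
    p_stale_event: float = 0.2
    n_outpt: int = 100_000
    #: outpatient prevalence of categorized marker items, keyed (concept, qualifier)
    marker_outpt_prevalence: dict[tuple[str, str], float] = dc_field(default_factory=dict)

    def validate(self) -> None:
        probs = (
            [c.cohort_frequency for c in self.conditions]
            + [p for c in self.conditions for p in c.target_probs.values()]
            + [n.cohort_prevalence for n in self.noise_items]
            + [n.outpatient_prevalence for n in self.noise_items]
            + [p for _, p in self.targets.values()]
            + list(self.base_order_probs.values())
            + [self.p_stale_event]
            + list(self.marker_outpt_prevalence.values())
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.train_years[0] >= self.test_year:
            raise ConfigurationError("training years must precede the test year")
        for c in self.conditions:
            for b in c.target_probs:
                if b not in self.targets:
                    raise ConfigurationError(f"profile {c.concept_id} references unknown target {b}")
        for b in self.base_order_probs:
            if b not in self.targets:
                raise ConfigurationError(f"base order {b} not in targets")

    @property
    def n_patients(self) -> int:
        return self.n_train_patients + self.n_test_patients


@dataclass
class GroundTruth:
    """What the generator planted, for estimator-recovery checks."""

    #: planted P(B | C) per (condition concept, target concept)
    planted_ppv: dict[tuple[str, str], float]
    #: marginal P(B | patient has C), accounting for co-conditions + base rates
    true_ppv: dict[tuple[str, str], float]
    #: planted cohort enrichment per condition concept
    true_rr: dict[str, float]
    #: per patient, the target concepts ranked by true conditional probability
    optimal_topk: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_ppv": {f"{c}|{b}": p for (c, b), p in self.planted_ppv.items()},
            "true_ppv": {f"{c}|{b}": p for (c, b), p in self.true_ppv.items()},
            "true_rr": self.true_rr,
            "optimal_topk": self.optimal_topk,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def default_config() -> GeneratorConfig:
    """Desk-scale defaults: 2000 train + 500 test patients, ~10 condition
    profiles over ~120 vocabulary items, 20x condition enrichment."""
    M, P = "measurement", "procedure"
    targets = {
        "tsh": (M, 0.025), "free_t4": (M, 0.008), "tpo_antibody": (M, 0.001),
        "thyroglobulin_antibody": (M, 0.0008), "total_t3": (M, 0.0012),
        "tsi": (M, 0.0005), "thyroid_ultrasound": (P, 0.002),
        "hba1c": (M, 0.02), "lipid_panel": (M, 0.03), "cmp": (M, 0.05),
        "alt": (M, 0.01), "vitamin_d": (M, 0.015), "cbc": (M, 0.06),
        "prolactin": (M, 0.001), "lh": (M, 0.0012), "fsh": (M, 0.0015),
        "estradiol": (M, 0.001), "17ohp": (M, 0.0005), "dheas": (M, 0.0008),
        "pelvic_ultrasound": (P, 0.003), "igf1": (M, 0.001),
        "igfbp3": (M, 0.0004), "bone_age_xray": (P, 0.002),
        "celiac_panel": (M, 0.004), "insulin_level": (M, 0.001),
        "cortisol": (M, 0.0012), "acth": (M, 0.0004), "pth": (M, 0.0008),
        "testosterone": (M, 0.0015),
    }
    conditions = [
        ConditionProfile("hypothyroidism", 0.16, 20.0, {
            "tsh": 0.85, "free_t4": 0.80, "tpo_antibody": 0.50,
            "thyroglobulin_antibody": 0.45, "thyroid_ultrasound": 0.12}),
        ConditionProfile("hyperthyroidism", 0.06, 20.0, {
            "tsh": 0.85, "free_t4": 0.80, "total_t3": 0.60, "tsi": 0.45,
            "thyroid_ultrasound": 0.25}),
        ConditionProfile("obesity", 0.20, 20.0, {
            "hba1c": 0.60, "lipid_panel": 0.50, "cmp": 0.45, "alt": 0.30,
            "vitamin_d": 0.30, "tsh": 0.35}),
        ConditionProfile("amenorrhea", 0.07, 20.0, {
            "prolactin": 0.60, "lh": 0.55, "fsh": 0.55, "estradiol": 0.40,
            "17ohp": 0.30, "dheas": 0.30, "pelvic_ultrasound": 0.20}),
        ConditionProfile("short_stature", 0.13, 20.0, {
            "igf1": 0.70, "bone_age_xray": 0.75, "cmp": 0.40, "tsh": 0.40,
            "celiac_panel": 0.35}),
        ConditionProfile("precocious_puberty", 0.09, 20.0, {
            "lh": 0.65, "fsh": 0.60, "estradiol": 0.40, "testosterone": 0.40,
            "bone_age_xray": 0.70, "17ohp": 0.25}),
        ConditionProfile("diabetes_risk", 0.08, 20.0, {
            "hba1c": 0.80, "cmp": 0.50, "lipid_panel": 0.45, "insulin_level": 0.40}),
        ConditionProfile("adrenal_disorder", 0.04, 20.0, {
            "cortisol": 0.70, "acth": 0.60, "17ohp": 0.50, "dheas": 0.40}),
        ConditionProfile("gh_deficiency", 0.04, 20.0, {
            "igf1": 0.80, "igfbp3": 0.60, "bone_age_xray": 0.60}),
        ConditionProfile("vitd_deficiency", 0.04, 20.0, {
            "vitamin_d": 0.80, "pth": 0.40, "cmp": 0.30}),
    ]
    markers = [
        MarkerLab("tsh", 0.5, 4.5,
                  {"hypothyroidism": "high", "hyperthyroidism": "low"}),
        MarkerLab("bmi", 14.0, 25.0, {"obesity": "high"},
                  background_measured_rate=0.55, background_abnormal_rate=0.08),
        MarkerLab("glucose", 70.0, 100.0, {"diabetes_risk": "high"},
                  background_measured_rate=0.20),
        MarkerLab("vitamin_d_level", 30.0, 100.0, {"vitd_deficiency": "low"},
                  background_measured_rate=0.10),
        MarkerLab("hemoglobin", 11.0, 15.0, {},
                  background_measured_rate=0.25, background_abnormal_rate=0.04),
    ]
    noise = [
        NoiseItem("well_child_visit", "condition", 0.60, 0.60),
        NoiseItem("uri", "condition", 0.35, 0.35),
        NoiseItem("allergic_rhinitis", "condition", 0.25, 0.25),
        NoiseItem("otitis_media", "condition", 0.18, 0.18),
        NoiseItem("atopic_dermatitis", "condition", 0.15, 0.15),
        NoiseItem("asthma", "condition", 0.14, 0.14),
        NoiseItem("acne", "condition", 0.12, 0.12),
        NoiseItem("adhd", "condition", 0.10, 0.10),
        NoiseItem("amoxicillin", "medication", 0.30, 0.30),
        NoiseItem("multivitamin", "medication", 0.25, 0.25),
        NoiseItem("ibuprofen", "medication", 0.20, 0.20),
        NoiseItem("cetirizine", "medication", 0.18, 0.18),
        NoiseItem("albuterol", "medication", 0.15, 0.15),
        NoiseItem("influenza_vaccine", "procedure", 0.50, 0.50),
        NoiseItem("vision_screen", "procedure", 0.40, 0.40),
        NoiseItem("hearing_screen", "procedure", 0.30, 0.30),
        NoiseItem("fluoride_treatment", "procedure", 0.20, 0.20),
    ]
    # filler chart items pad the vocabulary toward realistic size; deterministic
    # prevalences, enrichment 1 (pure distractors)
    for i in range(40):
        p = round(0.012 + 0.138 * ((7 * i) % 40) / 40, 4)
        dom = ("condition", "medication")[i % 2]
        noise.append(NoiseItem(f"misc_{dom[:4]}_{i:02d}", dom, p, p))
    marker_outpt = {}
    for m in markers:
        dirs = set(m.directions.values())
        marker_outpt[(m.concept_id, "normal")] = 0.06
        for q in ("high", "low"):
            marker_outpt[(m.concept_id, q)] = 0.004 if q in dirs else 0.002
    return GeneratorConfig(
        conditions=conditions,
        markers=markers,
        noise_items=noise,
        targets=targets,
        base_order_probs={"cmp": 0.06, "tsh": 0.08, "free_t4": 0.04,
                          "cbc": 0.06, "vitamin_d": 0.04},
        marker_outpt_prevalence=marker_outpt,
    )


def single_association_config(
    p_target: float = 0.6,
    cohort_frequency: float = 0.5,
    enrichment: float = 20.0,
    n_train_patients: int = 2000,
    n_test_patients: int = 0,
) -> GeneratorConfig:
    """Minimal one-condition, one-target config for estimator-recovery checks.

    With no base rates and at most one condition per patient, the empirical
    N_AB/N_A estimates the planted ``p_target`` exactly in expectation, and
    the empirical relative-risk weight estimates ``enrichment``.
    """
    return GeneratorConfig(
        n_train_patients=n_train_patients,
        n_test_patients=n_test_patients,
        conditions=[ConditionProfile("cond_a", cohort_frequency, enrichment,
                                     {"lab_b": p_target})],
        noise_items=[NoiseItem("noise_common", "condition", 0.5, 0.5)],
        targets={"lab_b": ("measurement", cohort_frequency / enrichment * p_target)},
    )


def _true_order_prob(config: GeneratorConfig, cond_set: Sequence[str], b: str) -> float:
    """Noisy-OR probability of order B given an exact condition set."""
    miss = 1.0 - config.base_order_probs.get(b, 0.0)
    for c in config.conditions:
        if c.concept_id in cond_set:
            miss *= 1.0 - c.target_probs.get(b, 0.0)
    return 1.0 - miss


def _marginal_ppv(config: GeneratorConfig, cond: str, b: str) -> float:
    """P(B | patient has condition ``cond``), other conditions marginalized."""
    miss = 1.0 - config.base_order_probs.get(b, 0.0)
    for c in config.conditions:
        if c.concept_id == cond:
            miss *= 1.0 - c.target_probs.get(b, 0.0)
        else:
            miss *= 1.0 - c.cohort_frequency * c.target_probs.get(b, 0.0)
    return 1.0 - miss


def generate_cohort(
    config: GeneratorConfig, seed: int
) -> tuple[list[EventRecord], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate events, referrals, and visits tables plus the planted truth.

    Returns raw (uncategorized) event records; run them through
    ``ehr_model.categorize_events`` and ``filter_rare_items`` exactly as for
    real extracts.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    events: list[EventRecord] = []
    referral_rows, visit_rows = [], []
    optimal: dict[str, list[str]] = {}
    target_list = sorted(config.targets)
    train_lo, train_hi = config.train_years

    for idx in range(config.n_patients):
        pid = f"P{idx:05d}"
        if idx < config.n_train_patients:
            year = int(rng.integers(train_lo, train_hi + 1))
        else:
            year = config.test_year
        referral = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        delay = int(rng.exponential(config.visit_delay_mean_days))
        visit = referral + timedelta(days=delay)
        referral_rows.append((pid, referral.isoformat(), f"E{idx:05d}"))
        visit_rows.append((pid, visit.isoformat()))

        cond_set = [
            c.concept_id for c in config.conditions
            if rng.random() < c.cohort_frequency
        ]
        for c in cond_set:
            d = referral - timedelta(days=int(rng.integers(0, QUERY_WINDOW_DAYS + 1)))
            events.append(EventRecord(pid, ClinicalItem(c, "condition"), d))

        for m in config.markers:
            dirs = sorted(m.directions[c] for c in cond_set if c in m.directions)
            if dirs:
                measured = rng.random() < m.measured_given_condition
                abnormal = rng.random() < m.abnormal_given_condition
                direction = dirs[0]
            else:
                measured = rng.random() < m.background_measured_rate
                abnormal = rng.random() < m.background_abnormal_rate
                direction = "high" if rng.random() < 0.5 else "low"
            if not measured:
                continue
            if abnormal and direction == "high":
                value = float(m.ref_high * rng.uniform(1.2, 3.0))
            elif abnormal:
                value = float(m.ref_low * rng.uniform(0.1, 0.8))
            else:
                value = float(rng.uniform(m.ref_low, m.ref_high))
            d = referral - timedelta(days=int(rng.integers(0, QUERY_WINDOW_DAYS + 1)))
            events.append(
                EventRecord(pid, ClinicalItem(m.concept_id, "measurement"), d,
                            numeric_value=round(value, 2),
                            ref_low=m.ref_low, ref_high=m.ref_high)
            )

        for noise in config.noise_items:
            if rng.random() < noise.cohort_prevalence:
                d = referral - timedelta(days=int(rng.integers(0, QUERY_WINDOW_DAYS + 1)))
                events.append(EventRecord(pid, ClinicalItem(noise.concept_id, noise.domain), d))
        if config.noise_items and rng.random() < config.p_stale_event:
            # an old chart item outside the lookback window
            noise = config.noise_items[int(rng.integers(0, len(config.noise_items)))]
            d = referral - timedelta(days=QUERY_WINDOW_DAYS + 1 + int(rng.integers(0, 180)))
            events.append(EventRecord(pid, ClinicalItem(noise.concept_id, noise.domain), d))

        probs = {b: _true_order_prob(config, cond_set, b) for b in target_list}
        for b in target_list:
            if rng.random() < probs[b]:
                events.append(EventRecord(pid, ClinicalItem(b, config.targets[b][0]), visit))
        optimal[pid] = [
            b for b in sorted(target_list, key=lambda x: (-probs[x], x)) if probs[b] > 0
        ][:4]

    referrals = pd.DataFrame(referral_rows, columns=["patient_id", "referral_date", "encounter_id"])
    visits = pd.DataFrame(visit_rows, columns=["patient_id", "visit_date"])
    referrals["referral_date"] = [date.fromisoformat(d) for d in referrals["referral_date"]]
    visits["visit_date"] = [date.fromisoformat(d) for d in visits["visit_date"]]

    cond_ids = [c.concept_id for c in config.conditions]
    truth = GroundTruth(
        planted_ppv={(c.concept_id, b): p for c in config.conditions
                     for b, p in c.target_probs.items()},
        true_ppv={(c, b): _marginal_ppv(config, c, b)
                  for c in cond_ids for b in target_list},
        true_rr={c.concept_id: c.enrichment for c in config.conditions},
        optimal_topk=optimal,
    )
    return events, referrals, visits, truth


def generate_background(
    config: GeneratorConfig,
    seed: int,
    query_counts: Mapping[ClinicalItem, int] | None = None,
    n_cohort: int = 0,
) -> BackgroundStats:
    """Outpatient-wide item counts consistent with the configured prevalences.

    The planted prevalences describe outpatients *outside* the referral
    cohort; when the trained matrix's ``query_counts``/``n_cohort`` are
    passed, the cohort's own contribution is added on top so that
    enrichment estimates against this background are unbiased.  Without
    them, counts are drawn over the full outpatient population.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_outside = config.n_outpt - n_cohort
    if n_outside <= 0:
        raise ConfigurationError("n_outpt must exceed the cohort size")
    counts: dict[ClinicalItem, int] = {}

    def _draw(item: ClinicalItem, prev: float) -> None:
        n = int(rng.binomial(n_outside, prev)) if prev > 0 else 0
        if query_counts is not None:
            n += query_counts.get(item, 0)
        counts[item] = min(n, config.n_outpt)

    for c in config.conditions:
        _draw(ClinicalItem(c.concept_id, "condition"), c.cohort_frequency / c.enrichment)
    for noise in config.noise_items:
        _draw(ClinicalItem(noise.concept_id, noise.domain), noise.outpatient_prevalence)
    for (concept, qualifier), prev in sorted(config.marker_outpt_prevalence.items()):
        _draw(ClinicalItem(concept, "measurement", qualifier), prev)
    for b, (domain, prev) in sorted(config.targets.items()):
        item = ClinicalItem(b, domain)
        if item not in counts:
            _draw(item, prev)
    return BackgroundStats(n_outpt=config.n_outpt, outpt_counts=counts)
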