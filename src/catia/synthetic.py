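"""Synthetic populations, banks, and response matrices.

Emulates the data regime the pipeline assumes: a standard-normal latent
trait, 5-category graded responses, two-level demographic covariates, and a
questionnaire-style binary diagnosis. Quality-control defects can be
planted so every screen in the QC pipeline has a detectable target:

* ``NoiseItem`` — responses uniform over the five categories (no loading);
* ``LowDiscrimination`` — a clean GRM item with a small slope;
* ``DIFItem`` — thresholds shifted for one covariate group at equal theta;
* ``DependentPair`` — one item copies another's response with a small
  re-draw rate (local dependence);
* ``SecondFactor`` — designated items load partly on an independent second
  latent variable.

All generation is driven by seed-derived substreams, so identical designs
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bank import DOMAINS, SOURCE_SCALES, ItemBank, ItemRecord
from .grm import category_prob_table
from .responses import ResponseMatrix

__all__ = [
    "NoiseItem",
    "LowDiscrimination",
    "DIFItem",
    "DependentPair",
    "SecondFactor",
    "SyntheticDesign",
    "Population",
    "generate_population",
    "generate_bank",
    "generate_responses",
]


@dataclass(frozen=True)
class NoiseItem:
    index: int


@dataclass(frozen=True)
class LowDiscrimination:
    index: int
    a: float = 0.6


@dataclass(frozen=True)
class DIFItem:
    index: int
    group: str = "gender"
    shift: float = 0.8


@dataclass(frozen=True)
class DependentPair:
    source: int
    copy: int
    noise: float = 0.1


@dataclass(frozen=True)
class SecondFactor:
    indices: tuple[int, ...]
    loading: float = 0.6


@dataclass(frozen=True)
class SyntheticDesign:
    """Study-condition defaults for synthetic data.

    Item slopes span the packaged bank's range (roughly 1.1-2.6) and
    thresholds span about [-2, 3.5]. Covariate rates follow the survey
    sample (50.2% female, 58.9% rural; 35% under 18). The diagnosis label
    is ``theta > diagnosis_cut`` with a small label-noise flip rate.
    """

    n_persons: int = 1000
    n_items: int = 20
    a_range: tuple[float, float] = (1.1, 2.6)
    b1_range: tuple[float, float] = (-2.0, 0.0)
    step_range: tuple[float, float] = (0.5, 1.3)
    defects: tuple = ()
    female_rate: float = 0.502
    rural_rate: float = 0.589
    under18_rate: float = 0.35
    diagnosis_cut: float = 0.5
    diagnosis_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.female_rate, self.rural_rate, self.under18_rate,
                     self.diagnosis_noise):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for defect in self.defects:
            idx = getattr(defect, "index", None)
            indices = (
                [idx] if idx is not None
                else list(getattr(defect, "indices", ()))
                + [getattr(defect, "source", 0), getattr(defect, "copy", 0)]
            )
            for i in indices:
                if not 0 <= i < self.n_items:
                    raise ValueError(f"defect {defect} references invalid item index {i}")


@dataclass(frozen=True)
class Population:
    theta: np.ndarray
    covariates: pd.DataFrame  # gender, age_group, region, diagnosis_true


def _streams(design: SyntheticDesign, *keys: int):
    return [
        np.random.default_rng(np.random.SeedSequence(entropy=design.seed, spawn_key=(k,)))
        for k in keys
    ]


def generate_population(design: SyntheticDesign) -> Population:
    """Draw theta ~ N(0,1), Bernoulli covariates, and noisy diagnosis labels."""
    (rng,) = _streams(design, 0)
    n = design.n_persons
    theta = rng.standard_normal(n)
    gender = np.where(rng.random(n) < design.female_rate, "female", "male")
    region = np.where(rng.random(n) < design.rural_rate, "rural", "urban")
    age = np.where(rng.random(n) < design.under18_rate, "under18", "adult")
    flips = rng.random(n) < design.diagnosis_noise
    diagnosis = (theta > design.diagnosis_cut) ^ flips
    cov = pd.DataFrame(
        {
            "gender": gender,
            "age_group": age,
            "region": region,
            "diagnosis_true": diagnosis,
        }
    )
    return Population(theta, cov)


def generate_bank(design: SyntheticDesign) -> ItemBank:
    """Draw a GRM bank with slopes/thresholds in the design's ranges.

    ``LowDiscrimination`` defects overwrite the drawn slope; metadata is
    assigned round-robin from the scale/domain vocabularies.
    """
    (rng,) = _streams(design, 1)
    items = []
    low_a = {d.index: d.a for d in design.defects if isinstance(d, LowDiscrimination)}
    for j in range(design.n_items):
        a = float(rng.uniform(*design.a_range))
        if j in low_a:
            a = float(low_a[j])
        b1 = rng.uniform(*design.b1_range)
        steps = rng.uniform(*design.step_range, size=3)
        b = b1 + np.concatenate(([0.0], np.cumsum(steps)))
        items.append(
            ItemRecord(
                f"SYN-{j + 1:02d}",
                SOURCE_SCALES[j % len(SOURCE_SCALES)],
                DOMAINS[j % len(DOMAINS)],
                "synthetic item",
                a,
                tuple(float(x) for x in b),
            )
        )
    return ItemBank(tuple(items))


def _draw_grm(rng, bank: ItemBank, theta: np.ndarray, b_shift: np.ndarray | float = 0.0):
    """Sample one response per (person, item) with optional threshold shift."""
    table = category_prob_table(
        _shifted(bank, b_shift) if np.any(b_shift) else bank, theta
    )
    cum = np.cumsum(table, axis=-1)  # (J, n, 5)
    u = rng.random((len(theta), len(bank)))
    return (u.T[..., None] > cum).sum(axis=-1).T  # (n, J)


def _shifted(bank: ItemBank, shift: float) -> ItemBank:
    items = [
        ItemRecord(
            it.item_id, it.source_scale, it.domain, it.label, it.a,
            tuple(b + shift for b in it.b),
        )
        for it in bank
    ]
    return ItemBank(tuple(items))


def generate_responses(
    bank: ItemBank, population: Population, design: SyntheticDesign
) -> ResponseMatrix:
    """Simulate responses with the design's planted defects applied."""
    (rng,) = _streams(design, 2)
    theta = population.theta
    n, J = len(theta), len(bank)

    second = [d for d in design.defects if isinstance(d, SecondFactor)]
    eta = rng.standard_normal(n) if second else None

    scores = _draw_grm(rng, bank, theta)

    for d in second:
        lam = d.loading
        mixed = np.sqrt(1 - lam**2) * theta + lam * eta
        sub = ItemBank(tuple(bank.items[i] for i in d.indices))
        scores[:, list(d.indices)] = _draw_grm(rng, sub, mixed)

    for d in design.defects:
        if isinstance(d, NoiseItem):
            scores[:, d.index] = rng.integers(0, 5, size=n)
        elif isinstance(d, DIFItem):
            codes = (
                population.covariates[d.group]
                == np.unique(population.covariates[d.group])[1]
            ).to_numpy()
            sub = ItemBank((bank.items[d.index],))
            shifted_scores = _draw_grm(
                rng, _shifted(sub, d.shift), theta[codes]
            )
            scores[codes, d.index] = shifted_scores[:, 0]
        elif isinstance(d, DependentPair):
            redraw = rng.random(n) < d.noise
            own = scores[:, d.copy].copy()
            scores[:, d.copy] = np.where(redraw, own, scores[:, d.source])

    return ResponseMatrix(bank.item_ids, scores, population.covariates.copy())
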