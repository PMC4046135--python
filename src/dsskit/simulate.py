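"""Seeded synthetic data: dose-response screens with known ground truth.

The generators emulate an ex vivo drug sensitivity and resistance testing
(DSRT) screen: each drug is tested on each sample as a 5-point 10-fold
dilution series spanning a 10,000-fold concentration window (an 8-point
CCLE-style grid is available too), readouts are percent growth inhibition
with additive Gaussian plate noise, and a cohort mixes patient samples with
healthy-donor controls.  Responder sub-groups, mechanism-of-action classes
and kinase addictions can be planted with known effect sizes so downstream
detection can be validated against recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curves import DoseResponseCurve
from .kiss import TargetMatrix
from .logistic import LogisticFit, predict_response
from .scoring import ScoreSettings, dss

__all__ = [
    "tenfold_doses",
    "CCLE_DOSES",
    "PlantedSubgroup",
    "CohortSpec",
    "simulate_curve",
    "simulate_cohort",
    "simulate_target_matrix",
]

# 8-point CCLE-style grid, nM
CCLE_DOSES = (2.5, 8.0, 25.0, 80.0, 250.0, 800.0, 2530.0, 8000.0)


def tenfold_doses(n_points: int = 5, top_nM: float = 10000.0, fold: float = 10.0) -> np.ndarray:
    """Serial dilution grid: ``n_points`` doses ending at ``top_nM``.

    The default 5-point 10-fold series (1 ... 10,000 nM) spans a
    10,000-fold concentration range.
    """
    return top_nM / fold ** np.arange(n_points - 1, -1, -1, dtype=float)


@dataclass(frozen=True)
class PlantedSubgroup:
    """A drug with a planted right-tail responder sub-group.

    ``effect`` is the amount (in score units of the cohort's metric) by which
    the responders' true scores exceed the drug's background response level.
    """

    drug_id: str
    responder_ids: tuple
    effect: float = 25.0


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic DSRT cohort.

    Defaults mirror a primary-sample screen: 22 patient samples, 4 healthy
    controls, 5-point 10-fold dilutions to 10,000 nM, 5 % inhibition noise.
    Each drug has a background response level (uniform on
    [level_lo, level_hi]) around which samples scatter uniformly within
    +/- jitter: a low active band, clear of the score floor at 0
    (floor-pinned scores compress the left tail and fake positive skew on
    undisturbed drugs), with biological spread dominating the technical
    noise of the fitted score, as in real screens.  Planted responders sit
    tightly at level + effect, the "distinct outlier group" structure the
    responder screen is meant to find; planted mechanism-of-action classes
    share their scatter across samples so their profiles correlate.
    """

    n_patients: int = 22
    n_controls: int = 4
    n_drugs: int = 8
    dilution_points: int = 5
    fold: float = 10.0
    top_nM: float = 10000.0
    noise_sd: float = 5.0
    a_min: float = 10.0
    metric: str = "DSS2"
    level_lo: float = 12.0
    level_hi: float = 18.0
    jitter: float = 6.0
    planted_subgroups: tuple[PlantedSubgroup, ...] = ()
    planted_moa: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_drugs, self.dilution_points) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        patients = set(self.patient_ids)
        for sub in self.planted_subgroups:
            if not set(sub.responder_ids) <= patients:
                raise ValueError(f"responder ids of {sub.drug_id} are not patient ids")

    @property
    def patient_ids(self) -> list[str]:
        return [f"patient_{i+1:02d}" for i in range(self.n_patients)]

    @property
    def control_ids(self) -> list[str]:
        return [f"control_{i+1:02d}" for i in range(self.n_controls)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug_{i+1:02d}" for i in range(self.n_drugs)]

    @property
    def doses(self) -> np.ndarray:
        return tenfold_doses(self.dilution_points, self.top_nM, self.fold)


def simulate_curve(truth: LogisticFit, doses: Sequence[float], noise_sd: float,
                   seed, sample_id: str = "sim", drug_id: str = "drug") -> DoseResponseCurve:
    """Noisy realization of a true 4PL curve on a dose grid.

    Responses are the model values plus iid Gaussian noise, clipped to
    [0, 100] like normalized plate readouts.  ``seed`` may be an int or a
    Generator; the output is a pure function of (truth, doses, noise_sd, seed).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    doses = np.asarray(doses, dtype=float)
    clean = predict_response(truth, np.log10(doses))
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=doses.size) if noise_sd > 0 else clean,
                    0.0, 100.0)
    return DoseResponseCurve(sample_id, drug_id, doses, np.atleast_1d(noisy))


def _solve_cell_params(target: float, m: float, s: float, settings: ScoreSettings,
                       window: tuple[float, float], metric: str) -> tuple[float, float]:
    """(r_max, m) whose noiseless score equals ``target``.

    The score is monotone increasing in r_max and decreasing in m, so first
    bisect on the top asymptote at the drug's own half-max point; if even a
    full-efficacy curve cannot reach the target there (a weak/late-potency
    drug shape), hold r_max = 100 and shift the cell's half-max point toward
    lower concentrations instead — the responder cell responds to smaller
    doses, which is how a strongly elevated planted effect manifests.
    """

    def f_rmax(r_max):
        return dss(LogisticFit(0.0, r_max, m, s), settings, window=window,
                   metric=metric) - target

    if f_rmax(100.0) > 0:
        return float(brentq(f_rmax, settings.a_min + 1e-9, 100.0, xtol=1e-10)), m

    def f_m(m_cell):
        return dss(LogisticFit(0.0, 100.0, m_cell, s), settings, window=window,
                   metric=metric) - target

    m_floor = window[0] - 2.0
    if f_m(m_floor) <= 0:  # target beyond any curve in this window
        return 100.0, m_floor
    return 100.0, float(brentq(f_m, m_floor, m, xtol=1e-10))


def simulate_cohort(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format dose-response table plus a ground-truth record.

    True per-cell scores are drawn first (per-drug background level plus
    per-sample scatter, shared latent factors within planted MoA classes,
    responders pinned at level + effect), then each cell's curve parameters
    are solved so the noiseless curve scores exactly its target, and finally
    noisy readouts are realized.  The truth record holds the target score
    matrix, per-drug curve shape parameters, planted facts and the scoring
    window.
    """
    rng = np.random.default_rng(seed)
    samples = spec.patient_ids + spec.control_ids
    drugs = spec.drug_ids
    x_lo, x_hi = float(np.log10(spec.doses.min())), float(np.log10(spec.doses.max()))
    settings = ScoreSettings(a_min=spec.a_min, x_lo=x_lo, x_hi=x_hi, metric=spec.metric)

    # per-drug curve shape: mid-window half-max point, moderate slopes
    m_of = {d: rng.uniform(x_lo + 0.35 * (x_hi - x_lo), x_lo + 0.75 * (x_hi - x_lo))
            for d in drugs}
    s_of = {d: rng.uniform(0.8, 2.0) for d in drugs}

    targets = pd.DataFrame(index=samples, columns=drugs, dtype=float)
    classes = sorted(set(spec.planted_moa.values()))
    latent = {c: rng.uniform(-1.0, 1.0, size=len(samples)) for c in classes}
    for d in drugs:
        level = rng.uniform(spec.level_lo, spec.level_hi)
        cls = spec.planted_moa.get(d)
        if cls is None:
            scatter = rng.uniform(-1.0, 1.0, size=len(samples))
        else:
            # same-class drugs share a sample-wise latent factor -> correlated profiles
            scatter = 0.9 * latent[cls] + 0.1 * rng.uniform(-1.0, 1.0, size=len(samples))
        targets[d] = level + spec.jitter * scatter
        for sub in spec.planted_subgroups:
            if sub.drug_id == d:
                # responders form a tight outlier group at level + effect
                targets.loc[list(sub.responder_ids), d] = (
                    level + sub.effect + rng.uniform(-1.0, 1.0, size=len(sub.responder_ids)))

    rows = []
    for d in drugs:
        for s_id in samples:
            tgt = float(targets.loc[s_id, d])
            r_max, m_cell = _solve_cell_params(tgt, m_of[d], s_of[d], settings,
                                               (x_lo, x_hi), spec.metric)
            truth_fit = LogisticFit(0.0, r_max, m_cell, s_of[d])
            curve = simulate_curve(truth_fit, spec.doses, spec.noise_sd, rng,
                                   sample_id=s_id, drug_id=d)
            for conc, resp in zip(curve.concentrations, curve.responses):
                rows.append((s_id, d, conc, resp))
    table = pd.DataFrame(rows, columns=["sample_id", "drug_id", "concentration_nM", "response"])

    truth = {
        "metric": spec.metric,
        "a_min": spec.a_min,
        "window": (x_lo, x_hi),
        "patient_ids": spec.patient_ids,
        "control_ids": spec.control_ids,
        "target_scores": targets,
        "curve_m": m_of,
        "curve_s": s_of,
        "planted_subgroups": [
            {"drug_id": p.drug_id, "responder_ids": list(p.responder_ids), "effect": p.effect}
            for p in spec.planted_subgroups
        ],
        "moa": dict(spec.planted_moa),
    }
    return table, truth


def simulate_target_matrix(n_drugs: int, n_kinases: int, density: float,
                           planted_addiction: tuple[str, Sequence[str]] | None = None,
                           seed: int = 0) -> tuple[TargetMatrix, dict]:
    """Random binary drug x kinase matrix with an optional planted kinase.

    ``planted_addiction = (kinase_id, drug_ids)`` forces that kinase's column
    to be exactly the stated drug subset.  ``density`` is the Bernoulli rate
    of the remaining entries and must lie strictly inside (0, 1).
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    drug_ids = [f"drug_{i+1:02d}" for i in range(n_drugs)]
    kinase_ids = [f"KIN{i+1:02d}" for i in range(n_kinases)]
    vals = (rng.uniform(size=(n_drugs, n_kinases)) < density).astype(int)
    df = pd.DataFrame(vals, index=drug_ids, columns=kinase_ids)
    truth: dict = {"density": density}
    if planted_addiction is not None:
        kinase, targeting = planted_addiction
        if kinase not in df.columns:
            df[kinase] = 0
        df[kinase] = [1 if d in set(targeting) else 0 for d in df.index]
        truth["planted_kinase"] = kinase
        truth["planted_drugs"] = list(targeting)
    return TargetMatrix(df), truth
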