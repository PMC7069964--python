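"""Synthetic NSCLC-like cohorts with the statistical structure the
pipeline assumes, so every downstream stage is testable without any
external download.

The generator emulates, in stylized form, a merged lung-adenocarcinoma
microarray cohort: log2 expression with bimodal marginals for the anchor
biomarker genes, an aggressive molecular subtype that switches on a
co-expression module among the planted prognostic genes, clinical
covariates with the published category structure (age, sex, stage), and
exponential proportional-hazards survival times with independent
exponential censoring. A single latent subtype drives all anchor
biomarkers, so the planted module is recoverable from every anchor's
subgroup-network pair - the property the feature selector is tested
against.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .network import Interactome, canonical_pair

__all__ = [
    "LITERATURE_BIOMARKERS", "STAGE_LEVELS", "STAGE_PROBS", "SimConfig",
    "GroundTruth", "CohortBundle", "simulate_expression",
    "simulate_clinical_survival", "assemble_cohort", "simulate_interactome",
]

#: Literature NSCLC biomarkers used as subgroup anchors.
LITERATURE_BIOMARKERS = ("EPCAM", "HIF1A", "PKM", "PTK7", "ALCAM", "CADM1",
                         "SLC2A1")

#: Tumor stage categories (stage III and IV collapsed).
STAGE_LEVELS = ("IA", "IB", "IIA", "IIB", "III/IV")

#: Stage frequencies resembling an early-stage surgical ADC cohort
#: (IA/IB dominant).
STAGE_PROBS = (0.49, 0.34, 0.025, 0.095, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the package's study conditions.

    ``bimodal_gap`` separates the low/high biomarker modes (log2 units)
    around a low mode at 6; ``network_effect`` is the within-subtype
    Pearson correlation planted on module gene pairs (0 disables the
    module); ``effect_log_hr`` is the per-gene log hazard ratio per SD of
    expression for each planted gene; ``baseline_hazard`` is in events
    per month; ``censor_rate`` the expected censored fraction. Stage and
    age carry their own modest hazard effects so the clinical modality
    holds prognostic signal independent of expression.
    """

    n_samples: int = 512
    n_genes: int = 120
    biomarker_genes: tuple[str, ...] = LITERATURE_BIOMARKERS
    n_planted_prognostic: int = 8
    bimodal_gap: float = 4.0
    within_mode_sd: float = 1.0
    network_effect: float = 0.9
    baseline_hazard: float = 0.004
    effect_log_hr: float = 0.25
    stage_log_hr: float = 0.35
    age_log_hr: float = 0.015
    censor_rate: float = 0.3
    split_fractions: tuple[float, float, float] = (0.5, 0.166, 0.334)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        needed = len(self.biomarker_genes) + self.n_planted_prognostic
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {needed} "
                "biomarker + planted genes")
        if self.n_planted_prognostic < 0:
            raise ValueError("n_planted_prognostic must be non-negative")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0.0 <= self.network_effect < 1.0:
            raise ValueError("network_effect must lie in [0, 1)")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split_fractions must be 3 non-negative reals "
                             "summing to 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    planted_prognostic_genes: tuple[str, ...]
    planted_edge_differences: frozenset[tuple[str, str]]
    true_log_hr: dict[str, float]
    true_biomarker_thresholds: dict[str, float]
    subtype: pd.Series | None = None  # True = aggressive subtype


@dataclass
class CohortBundle:
    """Aligned expression, clinical, survival and split assignment."""

    expression: pd.DataFrame  # genes x samples, log2 units
    clinical: pd.DataFrame    # index sample_id: age, sex, stage
    survival: pd.DataFrame    # index sample_id: time_months, event
    splits: pd.Series | None = None  # sample_id -> train/validation/test
    truth: GroundTruth | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def split_ids(self, name: str) -> list[str]:
        if self.splits is None:
            raise ValueError("bundle has no split assignment")
        return list(self.splits.index[self.splits == name])


def _planted_names(n: int) -> list[str]:
    return [f"PRG{i + 1:02d}" for i in range(n)]


def simulate_expression(config: SimConfig,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the log2 expression matrix and its ground truth.

    Anchor biomarkers follow a two-component mixture (modes 6 and
    6 + gap, SD ``within_mode_sd``) tied to one latent aggressive
    subtype. Planted prognostic genes share a latent module factor inside
    the aggressive subtype with pairwise correlation ``network_effect``
    and are independent outside it; all remaining pairs have
    expectation-zero correlation.
    """
    config.validate()
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    subtype = rng.random(n) < 0.5
    planted = _planted_names(config.n_planted_prognostic)
    n_bg = config.n_genes - len(config.biomarker_genes) - len(planted)
    background = [f"BG{i + 1:03d}" for i in range(n_bg)]
    genes = list(config.biomarker_genes) + planted + background

    rows = {}
    thresholds = {}
    low = 6.0
    for g in config.biomarker_genes:
        rows[g] = low + config.bimodal_gap * subtype \
            + rng.normal(0.0, config.within_mode_sd, n)
        thresholds[g] = low + config.bimodal_gap / 2.0
    rho = config.network_effect
    factor = rng.normal(size=n)
    for g in planted:
        noise = rng.normal(size=n)
        z = np.where(subtype,
                     np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise,
                     noise)
        rows[g] = 7.0 + z
    for g in background:
        rows[g] = rng.uniform(4.0, 10.0) + rng.normal(0.0, 1.0, n)

    expr = pd.DataFrame(np.vstack([rows[g] for g in genes]),
                        index=pd.Index(genes, name="gene"), columns=samples)
    if rho > 0.0:
        edges = frozenset(canonical_pair(a, b)
                          for i, a in enumerate(planted)
                          for b in planted[i + 1:])
    else:
        edges = frozenset()
    truth = GroundTruth(tuple(planted), edges,
                        {g: config.effect_log_hr for g in planted},
                        thresholds,
                        pd.Series(subtype, index=samples, name="subtype"))
    return expr, truth


def _stage_rank(stage: pd.Series) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(STAGE_LEVELS)}
    return np.array([lookup[s] for s in stage], dtype=float)


def simulate_clinical_survival(config: SimConfig, expression: pd.DataFrame,
                               truth: GroundTruth,
                               rng: np.random.Generator
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical covariates and exponential PH survival times.

    The per-patient log hazard is ``log(baseline_hazard)`` plus the sum of
    per-gene effects on standardized planted-gene expression, plus
    centered stage and age effects. Censoring is an independent
    exponential calibrated so the expected censored fraction equals
    ``censor_rate``; time is recorded in months and event=1 means an
    observed death.
    """
    missing = [g for g in truth.planted_prognostic_genes
               if g not in expression.index]
    if missing:
        raise ValueError(f"planted genes absent from expression: {missing}")
    n = expression.shape[1]
    samples = list(expression.columns)
    age = rng.uniform(32.0, 86.0, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    stage = rng.choice(STAGE_LEVELS, size=n, p=STAGE_PROBS)
    clinical = pd.DataFrame({"age": np.round(age, 1), "sex": sex,
                             "stage": stage},
                            index=pd.Index(samples, name="sample_id"))

    lp = np.zeros(n)
    for g, b in truth.true_log_hr.items():
        v = expression.loc[g].to_numpy(dtype=float)
        sd = v.std()
        if sd > 0:
            lp += b * (v - v.mean()) / sd
    srank = _stage_rank(clinical["stage"])
    lp += config.stage_log_hr * (srank - srank.mean())
    lp += config.age_log_hr * (age - age.mean())
    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0.0:
        def censored_frac(lam):
            return float(np.mean(lam / (lam + hazard))) - config.censor_rate
        lam_c = brentq(censored_frac, 1e-12, 1e6)
        t_cens = rng.exponential(1.0 / lam_c, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    surv = pd.DataFrame({"time_months": time, "event": event},
                        index=pd.Index(samples, name="sample_id"))
    return clinical, surv


def _assign_splits(samples: Sequence[str], fractions, rng) -> pd.Series:
    n = len(samples)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test  # rounding remainder goes to training
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:n_train + n_val]] = "validation"
    labels[order[n_train + n_val:]] = "test"
    return pd.Series(labels, index=pd.Index(samples, name="sample_id"),
                     name="split")


def assemble_cohort(config: SimConfig) -> CohortBundle:
    """Generate a complete, deterministic cohort bundle from the config.

    The same config (including seed) always yields a bitwise-identical
    bundle. Splits are assigned by shuffling sample IDs and cutting at
    the cumulative split fractions; no sample is ever dropped.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    expr, truth = simulate_expression(config, rng)
    clinical, surv = simulate_clinical_survival(config, expr, truth, rng)
    splits = _assign_splits(list(expr.columns), config.split_fractions, rng)
    return CohortBundle(expr, clinical, surv, splits, truth)


def simulate_interactome(gene_ids: Sequence[str],
                         truth: GroundTruth | None = None,
                         n_background_edges: int = 150,
                         rng: np.random.Generator | None = None,
                         seed: int = 0) -> Interactome:
    """Reference interactome containing the planted module edges plus
    random background pairs (the mask the network builder respects)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    pairs: set[tuple[str, str]] = set()
    if truth is not None:
        pairs |= set(truth.planted_edge_differences)
    tries = 0
    while len(pairs) < (0 if truth is None else len(truth.planted_edge_differences)) \
            + n_background_edges and tries < 50 * n_background_edges:
        a, b = rng.choice(len(genes), size=2, replace=False)
        pairs.add(canonical_pair(genes[a], genes[b]))
        tries += 1
    return Interactome.from_pairs(sorted(pairs))
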