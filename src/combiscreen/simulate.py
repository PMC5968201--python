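"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of a miRNA/drug
combination screen so that the full analysis chain can be exercised and
calibrated without any external download:

* an MTS single-agent screen — a panel of cell lines, each miRNA in
  quadruplicate wells, multiplicative per-(miRNA, cell line) viability
  effects and well-level multiplicative log-normal noise;
* 8-point serial-dilution dose-response curves with 4PL structure and
  additive Gaussian noise;
* four-arm combination experiments (untreated / miRNA / drug /
  combination) with 6 replicate wells per arm (duplicates x 3 repeats);
* expression cohorts with a planted set of genes rank-correlated
  (Gaussian copula) with a driver variable.

Noise is mean-preserving log-normal: ``signal = baseline * effect *
exp(N(-sigma^2/2, sigma^2))`` with ``sigma^2 = ln(1 + cv^2)``, so a
planted effect equals the expected signal ratio. All generators are
deterministic functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit
from .errors import ValidationError
from .expression import ExpressionCohort
from .interaction import ArmSet
from .plate_data import Assay, ViabilityRecord

__all__ = [
    "ScreenSimConfig",
    "ComboSimConfig",
    "simulate_mts_screen",
    "simulate_dose_response",
    "simulate_combination",
    "simulate_expression_cohort",
    "planted_screen_config",
]


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-preserving multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the single-agent MTS screen.

    Defaults mirror the screen design: 38 candidate miRNAs across a panel
    of 12 cell lines, quadruplicate wells per miRNA (2 repeats x 2
    duplicate wells), and 10% well-level CV — a typical colorimetric-assay
    noise level. ``effect_map`` maps (mirna, cell_line) to a
    multiplicative viability effect (1 = none); unlisted pairs are null.
    """

    n_mirnas: int = 38
    n_cell_lines: int = 12
    wells_per_mirna: int = 4
    effect_map: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.10
    baseline_signal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_cell_lines < 1 or self.wells_per_mirna < 1:
            raise ValidationError("screen dimensions must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.baseline_signal <= 0:
            raise ValidationError("baseline_signal must be positive")
        if any(e <= 0 for e in self.effect_map.values()):
            raise ValidationError("effects must be positive")

    @property
    def mirnas(self) -> list[str]:
        return [f"miR-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def cell_lines(self) -> list[str]:
        return [f"line-{i:02d}" for i in range(1, self.n_cell_lines + 1)]


@dataclass(frozen=True)
class ComboSimConfig:
    """Study conditions of one four-arm combination experiment.

    Effects are multiplicative on the untreated mean; a planted
    interaction makes ``combo_effect`` smaller than both single-agent
    effects. Six wells per arm (duplicates x 3 repeats) and 5% CV match
    the combination-assay design.
    """

    mirna_effect: float = 1.0
    drug_effect: float = 1.0
    combo_effect: float = 1.0
    wells_per_arm: int = 6
    noise_cv: float = 0.05
    baseline_signal: float = 100.0
    seed: int = 0
    cell_line: str = "line-01"
    mirna: str = "miR-001"
    drug: str = "drug-01"

    def __post_init__(self) -> None:
        if min(self.mirna_effect, self.drug_effect, self.combo_effect) <= 0:
            raise ValidationError("effects must be positive")
        if self.wells_per_arm < 2:
            raise ValidationError("need at least 2 wells per arm")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


def simulate_mts_screen(config: ScreenSimConfig) -> list[ViabilityRecord]:
    """Generate one full MTS screen as validated well records."""
    rng = np.random.default_rng(config.seed)
    records: list[ViabilityRecord] = []
    for line in config.cell_lines:
        for mirna in config.mirnas:
            effect = float(config.effect_map.get((mirna, line), 1.0))
            signals = (
                config.baseline_signal
                * effect
                * _lognormal_noise(rng, config.noise_cv, config.wells_per_mirna)
            )
            for w, s in enumerate(signals):
                records.append(
                    ViabilityRecord(
                        cell_line=line,
                        mirna=mirna,
                        drug=None,
                        dose=0.0,
                        repeat_id=w // 2 + 1,
                        well_id=w % 2 + 1,
                        assay=Assay.MTS,
                        signal=float(s),
                    )
                )
    return records


def planted_screen_config(
    seed: int,
    n_planted: int = 6,
    anti_effect: float = 0.5,
    pro_effect: float = 1.5,
    **kwargs,
) -> tuple[ScreenSimConfig, dict[str, float]]:
    """A screen config with strong planted miRNAs active across the panel.

    Half the planted miRNAs (rounded up) are anti-proliferative at
    ``anti_effect``, the rest proliferative at ``pro_effect``; each acts
    in every cell line, emulating broadly active strong hits. Returns the
    config and the planted (mirna -> effect) ground truth.
    """
    base = ScreenSimConfig(seed=seed, **kwargs)
    if n_planted > base.n_mirnas:
        raise ValidationError("cannot plant more miRNAs than exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(base.mirnas, size=n_planted, replace=False)
    truth = {
        str(m): (anti_effect if i < (n_planted + 1) // 2 else pro_effect)
        for i, m in enumerate(chosen)
    }
    effect_map = {
        (m, line): e for m, e in truth.items() for line in base.cell_lines
    }
    return ScreenSimConfig(
        n_mirnas=base.n_mirnas,
        n_cell_lines=base.n_cell_lines,
        wells_per_mirna=base.wells_per_mirna,
        effect_map=effect_map,
        noise_cv=base.noise_cv,
        baseline_signal=base.baseline_signal,
        seed=seed,
    ), truth


def simulate_dose_response(
    true_fit: DoseResponseFit,
    doses,
    noise_sd: float,
    seed: int,
) -> list[ViabilityRecord]:
    """Responses on a 4PL curve with additive Gaussian noise, truncated at 0."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or doses.size == 0 or (doses <= 0).any():
        raise ValidationError("doses must be a non-empty 1-D array of positives")
    rng = np.random.default_rng(seed)
    responses = true_fit.predict(doses) + rng.normal(0.0, noise_sd, doses.size)
    responses = np.clip(responses, 0.0, None)
    return [
        ViabilityRecord(
            cell_line=true_fit.cell_line or "line-01",
            mirna=None,
            drug=true_fit.drug or "drug-01",
            dose=float(d),
            repeat_id=1,
            well_id=i + 1,
            assay=Assay.ALAMAR,
            signal=float(r),
        )
        for i, (d, r) in enumerate(zip(doses, responses))
    ]


def simulate_combination(config: ComboSimConfig) -> ArmSet:
    """Four-arm combination experiment with multiplicative arm effects."""
    rng = np.random.default_rng(config.seed)
    n = config.wells_per_arm

    def arm(effect: float) -> tuple[float, ...]:
        return tuple(
            float(s)
            for s in config.baseline_signal * effect * _lognormal_noise(rng, config.noise_cv, n)
        )

    return ArmSet(
        cell_line=config.cell_line,
        mirna=config.mirna,
        drug=config.drug,
        untreated=arm(1.0),
        mirna_only=arm(config.mirna_effect),
        drug_only=arm(config.drug_effect),
        combination=arm(config.combo_effect),
    )


def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson r that yields the target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_expression_cohort(
    n_genes: int,
    n_samples: int,
    n_planted: int,
    planted_rho: float,
    seed: int,
) -> ExpressionCohort:
    """Expression cohort with genes rank-correlated to a standard-normal driver.

    Planted genes are generated through a Gaussian copula whose latent
    Pearson correlation is chosen so the *Spearman* correlation with the
    driver equals ``planted_rho`` (r = 2 sin(pi rho_s / 6)); the copula is
    the right construction for a rank-based screen. All latent values are
    exponentiated so expression is non-negative and log-normal-like.
    Planted gene identities are recorded on the returned cohort.
    """
    if n_genes < 1 or n_samples < 4:
        raise ValidationError("need >= 1 gene and >= 4 samples")
    if not 0 <= n_planted <= n_genes:
        raise ValidationError("n_planted must be in [0, n_genes]")
    if not abs(planted_rho) < 1:
        raise ValidationError("|planted_rho| must be < 1")
    rng = np.random.default_rng(seed)
    driver = rng.standard_normal(n_samples)
    latent = rng.standard_normal((n_genes, n_samples))
    if n_planted:
        r = _pearson_for_spearman(planted_rho)
        latent[:n_planted] = r * driver + math.sqrt(1.0 - r * r) * latent[:n_planted]
    genes = [f"gene-{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i:04d}" for i in range(1, n_samples + 1)]
    values = pd.DataFrame(np.exp(2.0 + latent), index=genes, columns=samples)
    return ExpressionCohort(
        values=values,
        driver=pd.Series(driver, index=samples, name="driver"),
        planted_genes=tuple(genes[:n_planted]),
    )
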