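"""Fixtures and synthetic variant-production datasets.

Two kinds of inputs live here.  First, the small printed inputs of the
study: the 14 family signal peptides with their essential-amino-acid
summaries, and the DMEM amino-acid supply together with the representative
full-length antibody demand.  Second, a generator of synthetic
variant-production datasets with the statistical structure the predictor
assumes — amino-acid count features around the representative antibody
composition, a planted linear effect of (standardized) counts on a latent
production score, a monotone squashing of that score onto a 0–250% rate
scale with Gaussian measurement noise, and the 20/70 three-class labels
with a deliberate minority of high producers.

The real 168-variant production table is not public; the generator stands
in for it so the split/fit/evaluate protocol and its acceptance properties
are testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .amino_acids import ALPHABET, DEFAULT_TABLE
from .media_stoichiometry import DemandProfile, MediaFormulation
from .production_model import (
    DEFAULT_SCHEME,
    FEATURE_ORDER,
    LabelScheme,
    VariantRecord,
    categorize,
)
from .sp_composition import SignalPeptide

# ---------------------------------------------------------------------------
# printed fixtures

#: The 14 family signal peptides: (name, family, chain, sequence).
#: VH1 and VH7 carry the same amino-acid sequence (distinct germline codons).
_SP_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("Vk1", "Vk1", "light", "MDMRVPAQLLGLLLLWLPGARC"),
    ("Vk2", "Vk2", "light", "MRLPAQLLGLLMLWVPGSSA"),
    ("Vk3", "Vk3", "light", "MEAPAQLLFLLLLWLPDTTG"),
    ("Vk4", "Vk4", "light", "MVLQTQVFISLLLWISGAYG"),
    ("Vk5", "Vk5", "light", "MGSQVHLLSFLLLWISDTRA"),
    ("Vk6", "Vk6", "light", "MLPSQLIGFLLLWVPASRG"),
    ("VH1", "VH1", "heavy", "MDWTWRILFLVAAATGAHS"),
    ("VH2", "VH2", "heavy", "MDILCSTLLLLTVPSWVLS"),
    ("VH3", "VH3", "heavy", "MEFGLSWVFLVAILKGVQC"),
    ("VH4", "VH4", "heavy", "MKHLWFFLLLVAAPRWVLS"),
    ("VH5", "VH5", "heavy", "MGSTAILALLLAVLQGVCS"),
    ("VH6", "VH6", "heavy", "MSVSFLIFLPVLGLPWGVLS"),
    ("VH7", "VH7", "heavy", "MDWTWRILFLVAAATGAHS"),
    ("IgE", "IgE", "heavy", "MDWTWILFLVAAATRVHS"),
)

#: Representative full-length antibody residue demand per amino acid.
ANTIBODY_DEMAND: Mapping[str, int] = {
    "A": 68, "C": 32, "D": 58, "E": 62, "F": 50, "G": 84, "H": 26,
    "I": 34, "K": 92, "L": 116, "M": 14, "N": 51, "P": 96, "Q": 63,
    "R": 35, "S": 160, "T": 112, "V": 128, "W": 25, "Y": 62,
}

#: DMEM free amino-acid supply, molecules x 1e20 (five NEAAs absent).
DMEM_SUPPLY_1E20: Mapping[str, float] = {
    "A": 0.0, "C": 3.11, "D": 0.0, "E": 0.0, "F": 2.41, "G": 2.41,
    "H": 1.63, "I": 4.82, "K": 6.01, "L": 4.82, "M": 1.21, "N": 0.0,
    "P": 0.0, "Q": 24.07, "R": 2.91, "S": 2.41, "T": 4.80, "V": 4.83,
    "W": 0.47, "Y": 3.45,
}


def sp_fixture() -> list[SignalPeptide]:
    """The 14 family signal peptides (light Vκ1–6, heavy VH1–7, and IgE)."""
    return [
        SignalPeptide(name=n, family=f, chain=c, sequence=s, table=DEFAULT_TABLE)
        for n, f, c, s in _SP_ROWS
    ]


def media_fixture() -> tuple[MediaFormulation, DemandProfile]:
    """DMEM supply (raw molecule counts) and representative antibody demand."""
    media = MediaFormulation(
        molecules={aa: v * 1e20 for aa, v in DMEM_SUPPLY_1E20.items()},
        source="DMEM (D1152)",
    )
    demand = DemandProfile(
        counts={aa: float(v) for aa, v in ANTIBODY_DEMAND.items()},
        protein="representative full-length antibody",
    )
    return media, demand


# ---------------------------------------------------------------------------
# synthetic dataset generator

#: Planted per-amino-acid effects (on z-scored counts) of the default
#: generator, following the qualitative composition trends seen across the
#: variant panels: more W, L, R, S associated with better production; more
#: F, H, I, A, N with poorer; K and D weakly negative.
DEFAULT_PLANTED: Mapping[str, float] = {
    "W": 1.0, "L": 0.8, "R": 0.6, "S": 0.5,
    "F": -0.7, "I": -0.6, "H": -0.5, "A": -0.5, "N": -0.5,
    "K": -0.3, "D": -0.3,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of the synthetic variant-production study.

    Defaults emulate the real dataset's shape: 168 variants, a minority
    (~20%) of high producers, counts perturbed around the representative
    antibody composition, and a 10% (of the reference) Gaussian noise on
    the measured rate.
    """

    n_variants: int = 168
    proportions: tuple[float, float, float] = (0.40, 0.40, 0.20)  # low/medium/high
    planted_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED)
    )
    base_composition: Mapping[str, int] = field(
        default_factory=lambda: dict(ANTIBODY_DEMAND)
    )
    perturbation_rate: float = 0.1  # Poisson mean as a fraction of the base count
    rate_noise_sd: float = 10.0  # % points
    rate_ceiling: float = 250.0  # rates reach ~240% in practice
    scheme: LabelScheme = DEFAULT_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 3:
            raise ValueError("n_variants must be at least 3")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) < 0:
            raise ValueError("proportions must be non-negative and sum to 1")
        if self.rate_noise_sd < 0:
            raise ValueError("rate noise SD must be non-negative")
        if self.rate_ceiling <= self.scheme.high_cut:
            raise ValueError("rate ceiling must exceed the high cut")
        for p in self.proportions:
            if 0 < p * self.n_variants < 1:
                raise ValueError(
                    "a non-empty class has expected count < 1; increase n_variants"
                )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated records plus the ground truth that generated them."""

    records: list[VariantRecord]
    planted_coefficients: np.ndarray  # in FEATURE_ORDER
    latent_scores: np.ndarray
    true_labels: np.ndarray  # labels of the noiseless rates
    config: GeneratorConfig

    def ground_truth(self) -> dict:
        return {
            "planted_coefficients": dict(zip(FEATURE_ORDER, self.planted_coefficients)),
            "true_labels": self.true_labels.tolist(),
            "seed": self.config.seed,
        }


def _calibrated_rate_map(scores: np.ndarray, config: GeneratorConfig):
    """Affine-logistic map of latent scores onto [0, ceiling]% rates.

    Calibrated by quantile matching: the score quantile at the target low
    share maps to the low cut, the quantile at low+medium maps to the high
    cut, so noiseless class shares equal the configured proportions.
    """
    p_low, p_med, _ = config.proportions
    ceiling = config.rate_ceiling
    s_lo = np.quantile(scores, p_low)
    s_hi = np.quantile(scores, p_low + p_med)
    t_lo = logit(config.scheme.low_cut / ceiling)
    t_hi = logit(config.scheme.high_cut / ceiling)
    if s_hi - s_lo < 1e-12:
        raise ValueError("latent scores are degenerate; cannot calibrate the rate map")
    a = (t_hi - t_lo) / (s_hi - s_lo)
    b = t_lo - a * s_lo
    return lambda s: ceiling * expit(a * s + b)


def generate_variants(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Draw a synthetic variant-production dataset.

    Counts are the base composition plus a symmetric Poisson-difference
    integer perturbation (clipped at zero); the latent production score is
    the planted affine function of z-scored counts; the measured rate is a
    calibrated monotone squashing of the score with Gaussian noise,
    clipped at zero (rates may exceed 100%); labels follow the 20/70 cuts.
    """
    rng = np.random.default_rng(config.seed)
    base = np.array([config.base_composition.get(aa, 0) for aa in FEATURE_ORDER], float)
    lam = np.maximum(config.perturbation_rate * base, 1.0)
    n = config.n_variants
    counts = base + rng.poisson(lam, size=(n, 20)) - rng.poisson(lam, size=(n, 20))
    counts = np.clip(counts, 0, None).astype(float)

    sd = counts.std(axis=0)
    sd[sd == 0] = 1.0
    z = (counts - counts.mean(axis=0)) / sd
    beta = np.array([config.planted_coefficients.get(aa, 0.0) for aa in FEATURE_ORDER])
    scores = z @ beta

    rate_map = _calibrated_rate_map(scores, config)
    clean_rates = rate_map(scores)
    rates = np.clip(clean_rates + rng.normal(0.0, config.rate_noise_sd, size=n), 0, None)

    records = [
        VariantRecord(
            id=f"variant_{i:04d}",
            features=counts[i],
            production_rate=float(rates[i]),
            scheme=config.scheme,
        )
        for i in range(n)
    ]
    true_labels = np.array([categorize(r, config.scheme) for r in clean_rates])
    return SyntheticDataset(
        records=records,
        planted_coefficients=beta,
        latent_scores=scores,
        true_labels=true_labels,
        config=config,
    )


def recovered_sign_agreement(
    model, planted: Sequence[float] | np.ndarray, min_effect: float = 0.5
) -> float:
    """Fraction of strong planted effects whose sign the fit recovers.

    The recovered direction of a feature is the sign of its high-class
    minus low-class coefficient in the one-vs-rest fit; only planted
    effects with \\|effect\\| >= ``min_effect`` (in SD units) are scored.
    """
    planted = np.asarray(planted, dtype=float)
    direction = model.coefficients[-1] - model.coefficients[0]
    strong = np.abs(planted) >= min_effect
    if not np.any(strong):
        raise ValueError("no planted effect reaches the minimum magnitude")
    return float(np.mean(np.sign(direction[strong]) == np.sign(planted[strong])))
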