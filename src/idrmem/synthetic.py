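"""Synthetic IDR-like sequences and model-derived noisy contact profiles.

Everything downstream (fitting, CLI, acceptance checks) can be exercised
without any external data: sequences of controlled charge composition
are drawn at random and contact profiles are generated from the weight
model itself plus truncated Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ModelParameters,
    classify_residues,
    relative_weights,
)
from .fitting import TrainingProtein

POSITIVE_POOL = "KR"
NEGATIVE_POOL = "DE"
NEUTRAL_POOL = "ACFGHILMNPQSTVWY"


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a random sequence of controlled charge composition."""

    length: int
    fraction_positive: float = 0.0
    fraction_negative: float = 0.0
    seed: int | None = None
    motifs: tuple[tuple[int, str], ...] = ()  # (1-based start, motif) overwrites

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.fraction_positive < 0 or self.fraction_negative < 0:
            raise ValueError("fractions must be >= 0")
        if self.fraction_positive + self.fraction_negative > 1:
            raise ValueError("charge fractions sum to more than 1")
        for start, motif in self.motifs:
            if start < 1 or start + len(motif) - 1 > self.length:
                raise ValueError(f"motif {motif!r} at {start} falls outside sequence")


def random_idr_sequence(spec: SequenceSpec, rng: np.random.Generator | None = None) -> str:
    """Random sequence with the requested charge composition (exact counts)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_pos = round(spec.length * spec.fraction_positive)
    n_neg = round(spec.length * spec.fraction_negative)
    if n_pos + n_neg > spec.length:
        raise ValueError("infeasible composition after rounding")
    n_neu = spec.length - n_pos - n_neg
    letters = np.concatenate(
        [
            rng.choice(list(POSITIVE_POOL), n_pos),
            rng.choice(list(NEGATIVE_POOL), n_neg),
            rng.choice(list(NEUTRAL_POOL), n_neu),
        ]
    )
    letters = letters[rng.permutation(spec.length)]
    for start, motif in spec.motifs:
        letters[start - 1 : start - 1 + len(motif)] = list(motif.upper())
    return "".join(letters)


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for a model-derived contact profile with additive noise."""

    params: ModelParameters
    scale: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None
    termini: str = "free"

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synthetic_contact_profile(
    sequence: str,
    spec: SyntheticProfileSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """clip(c * w_n / w_max + Gaussian noise, 0, 1), seeded and reproducible."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes = classify_residues(sequence, termini=spec.termini)
    profile = spec.scale * relative_weights(classes, spec.params)
    if spec.noise_sd > 0:
        profile = profile + rng.normal(0.0, spec.noise_sd, size=profile.size)
    return np.clip(profile, 0.0, 1.0)


@dataclass(frozen=True)
class TrainingSetSpec:
    """Recipe for a whole synthetic training set (one seed, substreams)."""

    n_proteins: int = 5
    length: int = 100
    fraction_positive: float = 0.2
    fraction_negative: float = 0.1
    params: ModelParameters = field(
        default_factory=lambda: ModelParameters(q_plus=2.43, q_minus=0.26, q_zero=0.59)
    )
    scale: float = 0.8
    noise_sd: float = 0.02
    termini: str = "free"
    seed: int = 0


def synthetic_training_set(spec: TrainingSetSpec) -> list[TrainingProtein]:
    """Independent substreams per protein for sequence and noise."""
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_proteins)
    training = []
    for k, ss in enumerate(streams):
        seq_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        seq = random_idr_sequence(
            SequenceSpec(
                length=spec.length,
                fraction_positive=spec.fraction_positive,
                fraction_negative=spec.fraction_negative,
            ),
            rng=seq_rng,
        )
        profile = synthetic_contact_profile(
            seq,
            SyntheticProfileSpec(
                params=spec.params,
                scale=spec.scale,
                noise_sd=spec.noise_sd,
                termini=spec.termini,
            ),
            rng=noise_rng,
        )
        training.append(
            TrainingProtein(
                protein_id=f"synth{k + 1}",
                classes=classify_residues(seq, termini=spec.termini),
                observed=profile,
                group=f"g{k + 1}",
            )
        )
    return training
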