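"""Sequence-based membrane-association propensity model.

Each residue ``n`` of a disordered sequence receives a statistical weight

    w_n = prod_i  q(class_i, |i - n|)

where the product runs over every site ``i`` in the sequence (including
``i = n``) plus, for free termini, a positive pseudo-site co-located with
residue 1 and a negative pseudo-site co-located with residue N.  Each
site's contributing factor starts at a class amplitude at sequence
distance 0 and decays toward 1 with distance:

    q(cls, d) = 1 + (q0_cls - 1) / (1 + a_cls * d + b_cls * d**2)

Propensities are the weights normalized by the sequence maximum and
scaled by a per-protein constant ``c``:  P_n = c * w_n / w_max.

Weights are accumulated in log space so long sequences cannot overflow.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE_AA = set("KR")
NEGATIVE_AA = set("DE")


class ResidueClass(enum.Enum):
    """Charge class of a residue (three-class scheme)."""

    POSITIVE = 1
    NEGATIVE = -1
    NEUTRAL = 0

    @property
    def charge(self) -> int:
        return self.value

    @property
    def symbol(self) -> str:
        return {1: "+", -1: "-", 0: "0"}[self.value]


@dataclass(frozen=True)
class ModelParameters:
    """Amplitudes and distance-attenuation constants of the weight model.

    ``q_plus``/``q_minus``/``q_zero`` are the zero-distance amplitudes of
    positive, negative, and neutral sites.  Charged sites attenuate with
    ``a_pm`` and ``b_pm``; neutral sites attenuate with ``a_zero`` (their
    quadratic coefficient is fixed at 0).
    """

    q_plus: float
    q_minus: float
    q_zero: float
    a_pm: float = 0.0982
    b_pm: float = 0.00305
    a_zero: float = 0.521

    def __post_init__(self) -> None:
        for name in ("q_plus", "q_minus", "q_zero"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("a_pm", "b_pm", "a_zero"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def amplitude(self, cls: ResidueClass) -> float:
        return {
            ResidueClass.POSITIVE: self.q_plus,
            ResidueClass.NEGATIVE: self.q_minus,
            ResidueClass.NEUTRAL: self.q_zero,
        }[cls]

    def replace_amplitudes(
        self, q_plus: float, q_minus: float, q_zero: float
    ) -> "ModelParameters":
        """New parameter set with the same distance constants."""
        return ModelParameters(
            q_plus=q_plus,
            q_minus=q_minus,
            q_zero=q_zero,
            a_pm=self.a_pm,
            b_pm=self.b_pm,
            a_zero=self.a_zero,
        )


#: Amplitudes trained on fully disordered regions.
DISORDERED_PARAMS = ModelParameters(q_plus=2.43, q_minus=0.26, q_zero=0.59)

#: Amplitudes trained on regions containing amphipathic helices.
HELIX_PARAMS = ModelParameters(q_plus=2.29, q_minus=0.64, q_zero=1.17)

PARAMETER_SETS = {"disordered": DISORDERED_PARAMS, "helix": HELIX_PARAMS}


@dataclass(frozen=True)
class ResidueClasses:
    """Per-residue charge classes plus optional terminal pseudo-sites.

    With free termini, an extra positive site sits on top of residue 1
    and an extra negative site on top of residue N; the terminal residues
    keep their own classes.  Capped termini carry no pseudo-sites.
    """

    sequence: str
    classes: tuple[ResidueClass, ...]
    n_term_site: bool
    c_term_site: bool

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.sequence):
            raise ValueError("classes length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def charges(self) -> np.ndarray:
        """Integer charge per residue, excluding pseudo-sites."""
        return np.array([c.charge for c in self.classes], dtype=float)


def normalize_sequence(sequence: str) -> str:
    """Uppercase and strip all whitespace; the documented normalization."""
    return "".join(sequence.split()).upper()


def classify_residues(sequence: str, termini: str = "free") -> ResidueClasses:
    """Assign charge classes: K/R positive, D/E negative, rest neutral.

    ``termini="free"`` adds the terminal pseudo-sites; ``"capped"`` does
    not.  ``X`` is accepted as neutral with a warning; any other
    non-standard letter raises with its position.
    """
    if termini not in ("free", "capped"):
        raise ValueError(f"termini must be 'free' or 'capped', got {termini!r}")
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("sequence is empty")
    classes = []
    for pos, aa in enumerate(seq, start=1):
        if aa in POSITIVE_AA:
            classes.append(ResidueClass.POSITIVE)
        elif aa in NEGATIVE_AA:
            classes.append(ResidueClass.NEGATIVE)
        elif aa in STANDARD_AA:
            classes.append(ResidueClass.NEUTRAL)
        elif aa == "X":
            logger.warning("position %d: unknown residue X treated as neutral", pos)
            classes.append(ResidueClass.NEUTRAL)
        else:
            raise ValueError(f"invalid residue {aa!r} at position {pos}")
    free = termini == "free"
    return ResidueClasses(
        sequence=seq,
        classes=tuple(classes),
        n_term_site=free,
        c_term_site=free,
    )


def distance_factor(cls: ResidueClass, d: float, params: ModelParameters) -> float:
    """Contributing factor of a site of class ``cls`` at sequence distance ``d``."""
    if d < 0:
        raise ValueError("sequence distance must be >= 0")
    q0 = params.amplitude(cls)
    if cls is ResidueClass.NEUTRAL:
        a, b = params.a_zero, 0.0
    else:
        a, b = params.a_pm, params.b_pm
    return 1.0 + (q0 - 1.0) / (1.0 + a * d + b * d * d)


def _log_factor_table(
    cls: ResidueClass, max_d: int, params: ModelParameters
) -> np.ndarray:
    """log q(cls, d) for d = 0 .. max_d (inclusive), vectorized."""
    d = np.arange(max_d + 1, dtype=float)
    q0 = params.amplitude(cls)
    if cls is ResidueClass.NEUTRAL:
        a, b = params.a_zero, 0.0
    else:
        a, b = params.a_pm, params.b_pm
    return np.log1p((q0 - 1.0) / (1.0 + a * d + b * d * d))


def log_weights(classes: ResidueClasses, params: ModelParameters) -> np.ndarray:
    """log w_n for every residue, as a length-N array.

    Sums log contributing factors over all sites (and the terminal
    pseudo-sites when present) — the log-space route used everywhere.
    """
    n_res = len(classes)
    dist = np.abs(np.subtract.outer(np.arange(n_res), np.arange(n_res)))
    logw = np.zeros(n_res)
    for cls in ResidueClass:
        idx = [i for i, c in enumerate(classes.classes) if c is cls]
        if not idx:
            continue
        table = _log_factor_table(cls, n_res - 1, params)
        logw += table[dist[:, idx]].sum(axis=1)
    if classes.n_term_site:
        table = _log_factor_table(ResidueClass.POSITIVE, n_res - 1, params)
        logw += table[np.arange(n_res)]
    if classes.c_term_site:
        table = _log_factor_table(ResidueClass.NEGATIVE, n_res - 1, params)
        logw += table[np.arange(n_res)[::-1]]
    return logw


def statistical_weight(
    n: int, classes: ResidueClasses, params: ModelParameters
) -> float:
    """w_n for 1-based residue index ``n`` (computed in log space)."""
    if not 1 <= n <= len(classes):
        raise IndexError(f"residue index {n} out of range 1..{len(classes)}")
    return float(math.exp(log_weights(classes, params)[n - 1]))


def relative_weights(classes: ResidueClasses, params: ModelParameters) -> np.ndarray:
    """w_n / w_max for every residue; the max entry is exactly 1."""
    logw = log_weights(classes, params)
    return np.exp(logw - logw.max())


@dataclass
class PropensityProfile:
    """Per-residue weights and normalized propensities for one sequence."""

    sequence: str
    classes: tuple[ResidueClass, ...]
    weights: np.ndarray
    propensities: np.ndarray
    scale: float = 1.0
    numbering_offset: int = 0
    record_id: str | None = None
    indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.propensities = np.asarray(self.propensities, dtype=float)
        if not (
            len(self.sequence)
            == len(self.classes)
            == self.weights.size
            == self.propensities.size
        ):
            raise ValueError("profile arrays must match sequence length")
        self.indices = np.arange(1, len(self.sequence) + 1) + self.numbering_offset

    @property
    def w_max(self) -> float:
        return float(self.weights.max())

    def argmax_index(self) -> int:
        """Index (with numbering offset) of the propensity maximum."""
        return int(self.indices[int(np.argmax(self.propensities))])


def propensity_profile(
    classes: ResidueClasses,
    params: ModelParameters,
    c: float = 1.0,
    numbering_offset: int = 0,
    record_id: str | None = None,
) -> PropensityProfile:
    """P_n = c * w_n / w_max over the whole sequence."""
    if c <= 0:
        raise ValueError("scale c must be strictly positive")
    logw = log_weights(classes, params)
    rel = np.exp(logw - logw.max())
    return PropensityProfile(
        sequence=classes.sequence,
        classes=classes.classes,
        weights=np.exp(logw),
        propensities=c * rel,
        scale=c,
        numbering_offset=numbering_offset,
        record_id=record_id,
    )


def predict(
    sequence: str,
    mode: str = "disordered",
    termini: str = "free",
    c: float = 1.0,
    numbering_offset: int = 0,
    record_id: str | None = None,
) -> PropensityProfile:
    """One-call prediction from a raw sequence string."""
    try:
        params = PARAMETER_SETS[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; use 'disordered' or 'helix'")
    classes = classify_residues(sequence, termini=termini)
    return propensity_profile(
        classes, params, c=c, numbering_offset=numbering_offset, record_id=record_id
    )
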