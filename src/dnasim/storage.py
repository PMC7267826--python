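"""Storage-stage mutation models.

Four alternatives to rule-based storage errors:

* **in vitro depurination** — hydrolytic loss of purines (A/G) at a rate
  determined by pH and absolute temperature; over a storage duration d each
  purine is lost independently with probability 1 - exp(-k d).  A lost
  purine is realized as a deletion: an abasic site has no representation in
  the strict ACGT alphabet, and a deletion is its conservative
  sequencing-visible consequence.
* **Kimura two-parameter (K80) substitution** — transitions (A<->G, C<->T)
  at rate alpha and each transversion at rate beta, applied i.i.d. per site
  from the closed-form transition-probability matrix.
* **binary erasure channel** — each base independently erased with
  probability p; erasures delete the base (no 'N' placeholder), with the
  provenance ledger preserving the erased positions.
* **additive white Gaussian noise channel** — bases are mapped to the
  PAM-4-style signal levels A=-3, C=-1, G=+1, T=+3, Gaussian noise of
  standard deviation sigma is added and the result re-quantized to the
  nearest level, so only substitutions occur and level-adjacent
  substitutions dominate.
"""

from __future__ import annotations

import math
from typing import Literal, Union

import numpy as np
from pydantic import BaseModel, ConfigDict

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: signal levels of the AWGN channel, indexed like BASES
AWGN_LEVELS = np.array([-3.0, -1.0, 1.0, 3.0])
_AWGN_THRESHOLDS = np.array([-2.0, 0.0, 2.0])


# --------------------------------------------------------------------------
# Depurination
# --------------------------------------------------------------------------

def depurination_log_rate(ph: float, temperature_k: float) -> float:
    """log10 of the depurination rate k (per base per second).

    Empirical two-branch law in pH and absolute temperature T:

        pH <  2.5:  lg k = 14.6 - 0.707 pH - 5.63e3 / T
        pH >= 2.5:  lg k = 16.5 - 0.982 pH - 5.85e3 / T

    The boundary pH 2.5 belongs to the second branch.
    """
    if temperature_k <= 0:
        raise ValueError("absolute temperature must be positive")
    if ph < 2.5:
        return 14.6 - 0.707 * ph - 5.63e3 / temperature_k
    return 16.5 - 0.982 * ph - 5.85e3 / temperature_k


def depurination_rate(ph: float, temperature_k: float) -> float:
    """Depurination rate k in events per base per second."""
    return 10.0 ** depurination_log_rate(ph, temperature_k)


def depurination_loss_probability(ph: float, temperature_k: float, duration_s: float) -> float:
    """Probability that one purine is lost during ``duration_s`` seconds."""
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    k = depurination_rate(ph, temperature_k)
    return -math.expm1(-k * duration_s)


# --------------------------------------------------------------------------
# Kimura two-parameter model
# --------------------------------------------------------------------------

def kimura_substitution_probs(alpha: float, beta: float, t: float) -> np.ndarray:
    """K80 transition-probability matrix after time ``t`` (rows/cols A,C,G,T).

    alpha is the transition rate, beta the rate of *each* of the two
    transversions, per site per unit time.  Closed form:

        P(transition)        = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
        P(each transversion) = 1/4 - 1/4 e^{-4 beta t}

    Rows sum to 1; t=0 gives the identity.
    """
    if alpha < 0 or beta < 0 or t < 0:
        raise ValueError("alpha, beta and t must be non-negative")
    e4b = math.exp(-4.0 * beta * t)
    e2ab = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    for base, partner in TRANSITION_PARTNER.items():
        P[_BASE_INDEX[base], _BASE_INDEX[partner]] = p_ts
    np.fill_diagonal(P, p_same)
    return P


# --------------------------------------------------------------------------
# Channels
# --------------------------------------------------------------------------

def apply_erasure_channel(
    seq: str, p: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Erase each base independently with probability p.

    Returns the surviving sequence and the (input-coordinate) list of erased
    positions.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("erasure probability must lie in [0, 1]")
    if not seq:
        return "", []
    mask = rng.random(len(seq)) < p
    erased = [int(i) for i in np.flatnonzero(mask)]
    kept = "".join(c for c, m in zip(seq, mask) if not m)
    return kept, erased


def apply_awgn_channel(seq: str, sigma: float, rng: np.random.Generator) -> str:
    """Transmit the sequence through the AWGN channel and re-quantize.

    Level mapping A,C,G,T -> -3,-1,+1,+3 with decision thresholds at
    -2, 0, +2; sigma = 0 is the exact identity.
    """
    if sigma < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if not seq or sigma == 0.0:
        return seq
    idx = np.array([_BASE_INDEX[c] for c in seq])
    noisy = AWGN_LEVELS[idx] + rng.normal(0.0, sigma, len(seq))
    decoded = np.digitize(noisy, _AWGN_THRESHOLDS)
    return "".join(BASES[i] for i in decoded)


# --------------------------------------------------------------------------
# Stage adapters: parameter models + site-event generation for the engine
# --------------------------------------------------------------------------

class KimuraStorage(BaseModel):
    model_config = ConfigDict(extra="ignore")
    model: Literal["kimura"] = "kimura"
    alpha: float = 0.0
    beta: float = 0.0
    t: float = 0.0


class DepurinationStorage(BaseModel):
    model_config = ConfigDict(extra="ignore")
    model: Literal["depurination"] = "depurination"
    ph: float = 7.0
    temperature_k: float = 310.15
    duration_s: float = 0.0


class ErasureStorage(BaseModel):
    model_config = ConfigDict(extra="ignore")
    model: Literal["erasure"] = "erasure"
    p: float = 0.0


class AwgnStorage(BaseModel):
    model_config = ConfigDict(extra="ignore")
    model: Literal["awgn"] = "awgn"
    sigma: float = 0.0


StorageModelConfig = Union[KimuraStorage, DepurinationStorage, ErasureStorage, AwgnStorage]

#: site event: (position on the stage's input sequence, type, before, after)
SiteEvent = tuple[int, str, str, str]


def storage_model_events(
    model: StorageModelConfig, seq: str, rng: np.random.Generator
) -> list[SiteEvent]:
    """Draw this model's mutations as position-sorted single-site events.

    Events are expressed on the stage-input coordinates; the simulation
    engine applies them sequentially and records provenance, so ledger and
    seeding behave exactly as for rule-based stages.
    """
    n = len(seq)
    if n == 0:
        return []
    events: list[SiteEvent] = []
    if isinstance(model, KimuraStorage):
        P = kimura_substitution_probs(model.alpha, model.beta, model.t)
        cum = P.cumsum(axis=1)
        idx = np.array([_BASE_INDEX[c] for c in seq])
        u = rng.random(n)
        new_idx = (u[:, None] > cum[idx]).sum(axis=1)
        for i in np.flatnonzero(new_idx != idx):
            events.append((int(i), "substitution", seq[i], BASES[new_idx[i]]))
    elif isinstance(model, DepurinationStorage):
        p_loss = depurination_loss_probability(model.ph, model.temperature_k, model.duration_s)
        mask = rng.random(n) < p_loss  # one draw per base; only purines can be lost
        for i in np.flatnonzero(mask):
            if seq[i] in "AG":
                events.append((int(i), "deletion", seq[i], ""))
    elif isinstance(model, ErasureStorage):
        if not 0.0 <= model.p <= 1.0:
            raise ValueError("erasure probability must lie in [0, 1]")
        mask = rng.random(n) < model.p
        for i in np.flatnonzero(mask):
            events.append((int(i), "deletion", seq[i], ""))
    elif isinstance(model, AwgnStorage):
        mutated = apply_awgn_channel(seq, model.sigma, rng)
        for i, (a, b) in enumerate(zip(seq, mutated)):
            if a != b:
                events.append((i, "substitution", a, b))
    else:  # pragma: no cover - union is closed
        raise TypeError(f"unknown storage model {model!r}")
    return events
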