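"""Randomized perturbation mechanisms for beacon databases.

Two per-entry mechanisms trade beacon accuracy for membership privacy,
both driven by a truth-retention bias b in [0, 1] (values in (1, 100] are
accepted as percentages and normalized):

* ``eliminate_random`` — each catalogued presence bit is kept with
  probability b and flipped with probability 1-b (symmetric false
  positives and negatives). A deletion-only variant (presence bits
  dropped, never added) is available behind a flag.
* ``biased_rr`` — biased randomized response: a first b-coin keeps the
  true bit; on failure a second b-coin keeps it, else flips. The net
  truth-retention probability is 1-(1-b)², and the mechanism is
  ε-differentially private with ε = |ln(1/(1-b)² - 1)|.

The two mechanisms coincide in distribution when b1 = 2·b2 - b2².
Perturbation never changes the member count or the catalogued position
set — only the presence bits. Preprocessing the database once (the
default) is preferred over perturbing answers at query time, because an
online mechanism is vulnerable to repeat-query averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beacon import BeaconDB, BeaconQuery, query_beacon

__all__ = [
    "PrivacyConfig",
    "DPGuarantee",
    "normalize_bias",
    "perturb_eliminate_random",
    "perturb_randomized_response",
    "epsilon_of_bias",
    "bias_equivalence",
    "answer_online",
]

_MECHANISMS = ("eliminate_random", "biased_rr")


def normalize_bias(bias: float) -> float:
    """Normalize a bias given on [0, 1] or as a percent in (1, 100]."""
    b = float(bias)
    if 1.0 < b <= 100.0:
        b /= 100.0
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"bias must lie in [0, 1] (or (1, 100] as percent), got {bias}")
    return b


@dataclass
class PrivacyConfig:
    """Mechanism selection for protecting a beacon."""

    mechanism: str = "biased_rr"
    bias: float = 0.5
    mode: str = "preprocess"
    seed: int | None = None
    _rng: np.random.Generator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if self.mode not in ("preprocess", "online"):
            raise ValueError("mode must be 'preprocess' or 'online'")
        self.bias = normalize_bias(self.bias)

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng

    @property
    def truth_probability(self) -> float:
        """P(answer = truth) per entry under the selected mechanism."""
        b = self.bias
        return b if self.mechanism == "eliminate_random" else 1.0 - (1.0 - b) ** 2


@dataclass(frozen=True)
class DPGuarantee:
    """The differential-privacy level implied by a randomized-response bias."""

    bias: float
    epsilon: float
    degenerate: bool = False


def _mechanism_meta(name: str, bias: float, seed) -> dict:
    eps = epsilon_of_bias(bias).epsilon if 0.0 < bias < 1.0 else float("inf")
    return {"mechanism": name, "bias": bias, "seed": seed, "epsilon": eps}


def perturb_eliminate_random(
    db: BeaconDB, bias: float, seed: int | None = None, deletion_only: bool = False
) -> BeaconDB:
    """Mechanism 1: keep each presence bit with probability b, flip otherwise.

    With ``deletion_only`` presence bits are dropped with probability 1-b
    and absences are never promoted (no false positives).
    """
    b = normalize_bias(bias)
    rng = np.random.default_rng(seed)
    flip = rng.random(db.num_entries) >= b
    if deletion_only:
        present = db.present & ~flip
    else:
        present = db.present ^ flip
    meta = _mechanism_meta("eliminate_random", b, seed)
    if deletion_only:
        meta["deletion_only"] = True
    return db.replace_present(present, provenance="perturbed", mechanism=meta)


def perturb_randomized_response(
    db: BeaconDB, bias: float, seed: int | None = None
) -> BeaconDB:
    """Mechanism 2: two-stage biased randomized response per presence bit.

    With probability b the true bit is kept; otherwise a second b-coin is
    flipped — kept on success, inverted on failure. Net truth-retention
    probability 1-(1-b)².
    """
    b = normalize_bias(bias)
    rng = np.random.default_rng(seed)
    coin1 = rng.random(db.num_entries) < b
    coin2 = rng.random(db.num_entries) < b
    flip = ~coin1 & ~coin2
    return db.replace_present(
        db.present ^ flip,
        provenance="perturbed",
        mechanism=_mechanism_meta("biased_rr", b, seed),
    )


def epsilon_of_bias(bias: float) -> DPGuarantee:
    """Differential-privacy level of biased randomized response.

    ε = |ln(1/(1-b)² - 1)|: zero at b = 1 - 1/sqrt(2) (perfect
    indistinguishability), growing toward +inf as b → 1 (no noise, full
    disclosure) and as b → 0 (deterministic inversion) — both degenerate
    endpoints are flagged.
    """
    b = normalize_bias(bias)
    if b in (0.0, 1.0):
        return DPGuarantee(bias=b, epsilon=float("inf"), degenerate=True)
    ratio = 1.0 / (1.0 - b) ** 2 - 1.0
    return DPGuarantee(bias=b, epsilon=abs(math.log(ratio)))


def bias_equivalence(b2: float) -> float:
    """Mechanism-1 bias with the same truth-retention as mechanism 2 at b2:
    b1 = 2·b2 - b2²."""
    b2 = normalize_bias(b2)
    return 2.0 * b2 - b2 * b2


def answer_online(db: BeaconDB, query: BeaconQuery, config: PrivacyConfig) -> bool:
    """Perturb a single true answer at query time.

    Documented as vulnerable to repeat-query averaging: repeated identical
    queries let an adversary majority-vote the truth back, which is why
    preprocessing is the default mode.
    """
    if config.mode != "online":
        raise ValueError("answer_online requires mode='online'")
    truth = query_beacon(db, query)
    rng = config.rng
    b = config.bias
    if config.mechanism == "eliminate_random":
        keep = rng.random() < b
    else:
        keep = (rng.random() < b) or (rng.random() < b)
    return truth if keep else not truth
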