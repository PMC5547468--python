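"""The likelihood-ratio membership-inference attack on a beacon.

The adversary holds a (possibly noisy, possibly relative's) copy of a
target genome, queries the beacon at sites where that copy carries an
alternate allele, and tests

    H0: the target is not among the beacon's N genomes
    H1: the target is in the beacon

via the log likelihood ratio Λ = L_H0(R) - L_H1(R) of the response
vector R. Under the two-binomial response model Λ collapses to the linear
form n·B + C·Σx_i with

    B = log(D_N / (δ·D_{N-1}))
    C = log(δ·D_{N-1}·(1-D_N) / (D_N·(1-δ·D_{N-1})))

and, because C < 0 whenever δ·D_{N-1} < D_N, the decision reduces to
rejecting H0 when the yes-count Σx_i exceeds the threshold t'_α.
Thresholds are always recomputed at the actually-issued budget n so that
partial budgets remain calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .beacon import ALT, BeaconDB, BeaconQuery, ResponseVector, query_beacon
from .riskmodel import RiskProfile, profile_from_panel
from .synthpop import GenotypeMatrix, SNPPanel, apply_sequencing_error, make_relative

__all__ = [
    "QueryPlan",
    "LRTStatistics",
    "AttackOutcome",
    "select_query_positions",
    "collect_responses",
    "lrt_statistics",
    "decide_membership",
    "run_attack_cohort",
    "power_curve",
    "power_analytic",
]


@dataclass(frozen=True)
class QueryPlan:
    """An ordered list of panel SNP indices to query, with bookkeeping."""

    indices: np.ndarray
    requested: int
    shortfall: int
    inconclusive: bool

    @property
    def n(self) -> int:
        return int(self.indices.size)

    def as_queries(self, panel: SNPPanel) -> list[BeaconQuery]:
        return [
            BeaconQuery(chrom=panel.chrom[i], pos=int(panel.pos[i]), allele=ALT)
            for i in self.indices
        ]


def select_query_positions(
    target_row: np.ndarray, panel: SNPPanel, budget: int, seed=None
) -> QueryPlan:
    """Choose the sites the adversary queries.

    All panel SNPs where the adversary's copy of the target carries at
    least one alternate allele, shuffled with the seed and truncated to
    the budget. A target with no alternate sites yields an empty,
    explicitly inconclusive plan; a budget exceeding the available sites
    records the shortfall.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    target_row = np.asarray(target_row)
    if target_row.shape != (panel.num_snps,):
        raise ValueError("target_row length must equal panel.num_snps")
    alt = np.flatnonzero(target_row > 0)
    if alt.size == 0:
        return QueryPlan(
            indices=alt, requested=budget, shortfall=budget, inconclusive=True
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(alt)
    chosen = alt[:budget]
    return QueryPlan(
        indices=chosen,
        requested=budget,
        shortfall=max(0, budget - alt.size),
        inconclusive=False,
    )


def collect_responses(db: BeaconDB, queries) -> ResponseVector:
    """Issue queries in order and collect the 0/1 answers."""
    return ResponseVector(
        x=np.fromiter(
            (int(query_beacon(db, q)) for q in queries), dtype=np.int8, count=-1
        )
    )


@dataclass(frozen=True)
class LRTStatistics:
    """Per-target attack state: response summary and likelihood terms."""

    n: int
    sum_x: int
    r_e: float
    L_H0: float
    L_H1: float
    B: float
    C: float
    lam: float
    h1_impossible: bool = False

    @property
    def linear_form(self) -> float:
        """n·B + C·Σx_i, the collapsed form of Λ."""
        return self.n * self.B + self.C * self.sum_x


def lrt_statistics(
    responses, D_N: float, D_N1: float, delta: float
) -> LRTStatistics:
    """Evaluate both forms of the log likelihood ratio for a response vector.

    Requires 0 < δ·D_{N-1} ≤ D_N < 1 (so C ≤ 0); the degenerate equality
    D_N = δ·D_{N-1} yields B = C = Λ = 0. With δ = 0 an observed "no" is
    impossible under the exact H1 model: L_H1 = -inf is flagged rather
    than raised.
    """
    x = responses.x if isinstance(responses, ResponseVector) else np.asarray(responses)
    x = ResponseVector(x=x).x
    if not 0.0 < D_N < 1.0:
        raise ValueError("D_N must lie strictly in (0, 1)")
    q1 = delta * D_N1  # P(x_i = 0 | H1)
    if q1 < 0.0 or q1 > D_N:
        raise ValueError("need 0 <= delta*D_{N-1} <= D_N for a one-sided rule")
    n = int(x.size)
    sum_x = int(x.sum())
    l_h0 = sum_x * np.log(1.0 - D_N) + (n - sum_x) * np.log(D_N)
    if q1 == 0.0:
        if sum_x < n:
            return LRTStatistics(
                n=n,
                sum_x=sum_x,
                r_e=sum_x / n if n else float("nan"),
                L_H0=float(l_h0),
                L_H1=float("-inf"),
                B=float("inf"),
                C=float("-inf"),
                lam=float("inf"),
                h1_impossible=True,
            )
        l_h1 = 0.0  # all yes: n*log(1) under H1
        return LRTStatistics(
            n=n,
            sum_x=sum_x,
            r_e=sum_x / n if n else float("nan"),
            L_H0=float(l_h0),
            L_H1=l_h1,
            B=float("inf"),
            C=float("-inf"),
            lam=float(l_h0 - l_h1),
            h1_impossible=False,
        )
    l_h1 = sum_x * np.log(1.0 - q1) + (n - sum_x) * np.log(q1)
    b = np.log(D_N / q1)
    c = np.log(q1 * (1.0 - D_N) / (D_N * (1.0 - q1)))
    return LRTStatistics(
        n=n,
        sum_x=sum_x,
        r_e=sum_x / n if n else float("nan"),
        L_H0=float(l_h0),
        L_H1=float(l_h1),
        B=float(b),
        C=float(c),
        lam=float(l_h0 - l_h1),
    )


def decide_membership(stats: LRTStatistics, profile: RiskProfile) -> bool:
    """Reject H0 (declare "in beacon") iff Σx_i > t'_α at the issued budget.

    The threshold is recomputed from the profile with n = stats.n so
    partial budgets stay calibrated; the inequality is strict. An
    inconclusive target (no queries) is never rejected.
    """
    if stats.n == 0:
        return False
    return stats.sum_x > profile.threshold_at(stats.n)


@dataclass
class AttackOutcome:
    """Cohort result at one query budget."""

    budget: int
    power: float
    type1_error: float
    n_cases: int
    n_controls: int
    nominal_threshold: int
    case_sums: np.ndarray = field(repr=False)
    case_ns: np.ndarray = field(repr=False)
    control_sums: np.ndarray = field(repr=False)
    control_ns: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0 or not 0.0 <= self.type1_error <= 1.0:
            raise ValueError("power and type-I error must lie in [0, 1]")


def _target_records(
    rows: np.ndarray,
    panel: SNPPanel,
    presence: np.ndarray,
    delta: float,
    max_budget: int,
    seeds,
    kinship: float | None,
    source_rows: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-target yes-count prefix sums (cumulative over the shuffled plan)."""
    cums, lens = [], []
    for i, row in enumerate(rows):
        ss = seeds[i]
        child = ss.spawn(3)
        if kinship is not None and source_rows is not None:
            row = make_relative(source_rows[i], panel, kinship, child[2])
        noisy = apply_sequencing_error(row, delta, child[0])
        plan = select_query_positions(noisy, panel, max_budget, child[1])
        x = presence[plan.indices].astype(np.int64)
        cums.append(np.cumsum(x))
        lens.append(plan.n)
    return cums, np.asarray(lens)


def run_attack_cohort(
    db: BeaconDB,
    panel: SNPPanel,
    genotypes: GenotypeMatrix,
    case_indices,
    control_indices,
    budgets,
    profile: RiskProfile | None = None,
    delta: float = 1e-3,
    alpha: float = 0.05,
    dn_source: str = "spectrum",
    seed: int | None = None,
    kinship: float | None = None,
) -> list[AttackOutcome]:
    """Run the cohort attack at each budget.

    For every target the adversary's copy is degraded with the mismatch
    rate δ (and, when ``kinship`` is given, cases are replaced by a
    simulated relative of that kinship), query sites are a seeded shuffle
    of the copy's alternate-allele sites, and the decision compares the
    yes-count against the α-level threshold at the actually-issued budget.
    Cohort power is the fraction of in-beacon targets rejected; the type-I
    error is the fraction of out-of-beacon targets rejected. The default
    risk profile estimates D_N from the panel's frequency spectrum
    (``dn_source``); pass ``profile`` to override.
    """
    case_indices = np.asarray(case_indices, dtype=np.int64)
    control_indices = np.asarray(control_indices, dtype=np.int64)
    if np.intersect1d(case_indices, control_indices).size:
        raise ValueError("case and control indices must be disjoint")
    budgets = [int(b) for b in budgets]
    if any(b < 0 for b in budgets):
        raise ValueError("budgets must be non-negative")
    if profile is None:
        profile = profile_from_panel(
            panel, db.n_members, delta=delta, alpha=alpha, dn_source=dn_source
        )
    presence = db.presence_vector(panel)
    max_budget = max(budgets) if budgets else 0

    root = np.random.SeedSequence(seed)
    case_seeds = root.spawn(case_indices.size)
    control_seeds = root.spawn(control_indices.size)

    if max_budget == 0:
        zeros_c = np.zeros(case_indices.size, dtype=np.int64)
        zeros_k = np.zeros(control_indices.size, dtype=np.int64)
        return [
            AttackOutcome(
                budget=b, power=0.0, type1_error=0.0,
                n_cases=case_indices.size, n_controls=control_indices.size,
                nominal_threshold=0,
                case_sums=zeros_c, case_ns=zeros_c,
                control_sums=zeros_k, control_ns=zeros_k,
            )
            for b in budgets
        ]

    case_rows = genotypes.entries[case_indices]
    case_cums, case_lens = _target_records(
        case_rows, panel, presence, delta, max_budget, case_seeds,
        kinship, case_rows if kinship is not None else None,
    )
    control_cums, control_lens = _target_records(
        genotypes.entries[control_indices], panel, presence, delta, max_budget,
        control_seeds, None, None,
    )

    outcomes = []
    for b in budgets:
        def evaluate(cums, lens):
            sums = np.empty(len(cums), dtype=np.int64)
            ns = np.minimum(lens, b)
            reject = np.zeros(len(cums), dtype=bool)
            for i, cum in enumerate(cums):
                nb = ns[i]
                sums[i] = cum[nb - 1] if nb > 0 else 0
                if nb > 0:
                    reject[i] = sums[i] > profile.threshold_at(nb)
            return sums, ns, reject

        if b == 0:
            z_c = np.zeros(len(case_cums), dtype=np.int64)
            z_k = np.zeros(len(control_cums), dtype=np.int64)
            outcomes.append(AttackOutcome(
                budget=b, power=0.0, type1_error=0.0,
                n_cases=case_indices.size, n_controls=control_indices.size,
                nominal_threshold=0,
                case_sums=z_c, case_ns=z_c, control_sums=z_k, control_ns=z_k,
            ))
            continue
        c_sums, c_ns, c_rej = evaluate(case_cums, case_lens)
        k_sums, k_ns, k_rej = evaluate(control_cums, control_lens)
        outcomes.append(
            AttackOutcome(
                budget=b,
                power=float(c_rej.mean()) if c_rej.size else 0.0,
                type1_error=float(k_rej.mean()) if k_rej.size else 0.0,
                n_cases=case_indices.size,
                n_controls=control_indices.size,
                nominal_threshold=profile.threshold_at(b),
                case_sums=c_sums,
                case_ns=c_ns,
                control_sums=k_sums,
                control_ns=k_ns,
            )
        )
    return outcomes


def power_curve(outcomes: list[AttackOutcome]) -> pd.DataFrame:
    """Tabulate a power curve with binomial standard errors."""
    rows = []
    for o in outcomes:
        se_p = np.sqrt(o.power * (1 - o.power) / o.n_cases) if o.n_cases else np.nan
        se_t = (
            np.sqrt(o.type1_error * (1 - o.type1_error) / o.n_controls)
            if o.n_controls
            else np.nan
        )
        rows.append(
            {
                "budget": o.budget,
                "power": o.power,
                "type1_error": o.type1_error,
                "se_power": se_p,
                "se_type1": se_t,
                "threshold": o.nominal_threshold,
            }
        )
    return pd.DataFrame(rows)


def power_analytic(profile: RiskProfile, n: int) -> float:
    """Model-implied power at budget n: P(Binomial(n, θ1) > t'_α(n)).

    With δ = 0 (θ1 = 1) this is a step function: power 1 once n exceeds
    the crossover n ≈ z²(1-D_N)/D_N at which t'(n) first drops below n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    t = profile.threshold_at(n)
    return float(binom.sf(t, n, profile.theta1))
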