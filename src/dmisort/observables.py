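"""Outcome classification and replicate statistics.

The 16 haplotypes partition into eight classes by allele content (the
partition is architecture-independent): ancestral, the two parental
haplotypes, the two reciprocally-sorted hybrid haplotypes, four
"epistasis-free" F2 recombinants carrying a single derived allele, three
haplotypes expressing only the first incompatibility, three expressing only
the second, and the doubly incompatible haplotype.  Hybrid speciation is
the fixation of a hybrid haplotype (A1b1a2B2 or a1B1A2b2), which carries an
incompatibility against each parental population.

Monte-Carlo outcome probabilities are reported with exact (Clopper-Pearson)
binomial confidence intervals; conditional mean times are withheld below a
minimum event count (4 by default) because such means are dominated by
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .engine import OutcomeRecord, SimulationConfig, run_replicates
from .haplotypes import ALLELES, HYBRID_HAPLOTYPES, N_HAPLOTYPES

HAPLOTYPE_CLASSES = (
    "ancestral",
    "parental-1",
    "parental-2",
    "hybrid",
    "epistasis-free-F2",
    "DMI-1-incompatible",
    "DMI-2-incompatible",
    "double-incompatible",
)

OUTCOME_CLASSES = HAPLOTYPE_CLASSES + ("unresolved",)


def classify_haplotype(h: int) -> str:
    """Class of haplotype ``h`` in the eight-way partition (by allele content)."""
    if not 0 <= h < N_HAPLOTYPES:
        raise ValueError(f"haplotype index out of range: {h}")
    a1, b1, a2, b2 = ALLELES[h]
    dmi1 = bool(a1 and b1)
    dmi2 = bool(a2 and b2)
    if dmi1 and dmi2:
        return "double-incompatible"
    if dmi1:
        return "DMI-1-incompatible"
    if dmi2:
        return "DMI-2-incompatible"
    n_derived = int(a1 + b1 + a2 + b2)
    if n_derived == 0:
        return "ancestral"
    if n_derived == 1:
        return "epistasis-free-F2"
    # two derived alleles, no incompatible pair
    if a1 and a2:
        return "parental-1"
    if b1 and b2:
        return "parental-2"
    return "hybrid"


def is_hybrid_speciation(fixed: int) -> bool:
    """True iff the fixed haplotype is one of the two reciprocally sorted ones."""
    return fixed in HYBRID_HAPLOTYPES


def detect_resolution(
    trajectory: np.ndarray, tol: float = 0.0
) -> tuple[int | None, int | None]:
    """Per-DMI resolution times from a (T, 16) haplotype-frequency trajectory.

    DMI k is resolved at the first generation where derived allele A_k or
    B_k has frequency <= tol (tol = 0 for exact counts; use e.g. 1e-8 for
    deterministic trajectories).  None marks a conflict unresolved within
    the trajectory.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[1] != N_HAPLOTYPES:
        raise ValueError("trajectory must have 16 haplotype-frequency columns")
    derived = traj @ ALLELES  # (T, 4) derived-allele frequencies
    times: list[int | None] = []
    for k in range(2):
        lost = (derived[:, 2 * k] <= tol) | (derived[:, 2 * k + 1] <= tol)
        idx = np.flatnonzero(lost)
        times.append(int(idx[0]) if idx.size else None)
    return times[0], times[1]


@dataclass
class OutcomeSummary:
    """Per-outcome-class replicate statistics.

    ``table`` has one row per outcome class with columns: n_events,
    probability, ci_low, ci_high (Clopper-Pearson at level 1 - alpha),
    mean_fixation_time, se_fixation_time, mean_resolution_time and
    times_reported (False when the class had fewer than ``min_events``
    events, in which case the conditional times are withheld as NaN).
    """

    table: pd.DataFrame
    n_replicates: int
    min_events: int
    alpha: float

    def probability(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "probability"])

    @property
    def hybrid_speciation_probability(self) -> float:
        return self.probability("hybrid")


def summarize_outcomes(
    records: list[OutcomeRecord],
    min_events: int = 4,
    alpha: float = 0.05,
) -> OutcomeSummary:
    """Aggregate replicate outcomes into per-class estimates with exact CIs."""
    n = len(records)
    if n < 1:
        raise ValueError("at least one replicate required")
    rows = []
    for cls in OUTCOME_CLASSES:
        hits = [r for r in records if r.outcome == cls]
        k = len(hits)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        fix_times = np.array(
            [r.fixation_time for r in hits if r.fixation_time is not None], dtype=float
        )
        res_times = np.array(
            [
                max(r.resolution_times)
                for r in hits
                if None not in r.resolution_times
            ],
            dtype=float,
        )
        report = k >= min_events
        rows.append(
            {
                "outcome": cls,
                "n_events": k,
                "probability": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "mean_fixation_time": (
                    float(fix_times.mean()) if report and fix_times.size else np.nan
                ),
                "se_fixation_time": (
                    float(fix_times.std(ddof=1) / np.sqrt(fix_times.size))
                    if report and fix_times.size > 1
                    else np.nan
                ),
                "mean_resolution_time": (
                    float(res_times.mean()) if report and res_times.size else np.nan
                ),
                "times_reported": bool(report),
            }
        )
    table = pd.DataFrame(rows).set_index("outcome")
    return OutcomeSummary(table=table, n_replicates=n, min_events=min_events, alpha=alpha)


def estimate_outcome_probabilities(
    config: SimulationConfig,
    reps: int,
    base_seed: int | None = None,
    min_events: int = 4,
    alpha: float = 0.05,
) -> OutcomeSummary:
    """Run ``reps`` replicates of ``config`` and summarize the outcomes."""
    records = run_replicates(config, reps, base_seed=base_seed)
    return summarize_outcomes(records, min_events=min_events, alpha=alpha)


def hybrid_speciation_probability(
    records: list[OutcomeRecord], alpha: float = 0.05
) -> tuple[float, float, float]:
    """Estimate and Clopper-Pearson CI of the hybrid-speciation probability."""
    n = len(records)
    k = sum(r.hybrid_speciation for r in records)
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return k / n, float(lo), float(hi)


def reciprocal_sorting_prediction(single_dmi_records: list[OutcomeRecord]) -> float:
    """Predicted hybrid-speciation probability from independent single DMIs.

    From the single-DMI haplotype fixation frequencies P(Ab) and P(aB), two
    independent copies of the DMI resolve toward opposite derived alleles
    with probability 2 P(Ab) P(aB).
    """
    n = len(single_dmi_records)
    # single-DMI runs: only locus pair (A1, B1) segregates
    p_Ab = sum(r.fixed_haplotype == 8 for r in single_dmi_records) / n
    p_aB = sum(r.fixed_haplotype == 4 for r in single_dmi_records) / n
    return 2.0 * p_Ab * p_aB


def independent_dmi_prediction(
    config: SimulationConfig, reps: int, base_seed: int | None = None
) -> float:
    """Run a single-DMI configuration and return the reciprocal-sorting
    prediction for two independent DMIs (see
    :func:`reciprocal_sorting_prediction`)."""
    if config.parental_haplotypes != (8, 4):
        raise ValueError("independent-DMI prediction needs a two-locus configuration")
    return reciprocal_sorting_prediction(run_replicates(config, reps, base_seed))


def fixation_correlation(records: list[OutcomeRecord]) -> float:
    """Sample correlation of the fixation indicators of alleles A1 and A2.

    NaN when either indicator is constant across replicates (correlation
    undefined) or when no replicate fixed.
    """
    fixed = [r.fixed_haplotype for r in records if r.fixed_haplotype is not None]
    if not fixed:
        return float("nan")
    x = np.array([ALLELES[h, 0] for h in fixed], dtype=float)  # A1 fixed
    y = np.array([ALLELES[h, 2] for h in fixed], dtype=float)  # A2 fixed
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def outcome_table_tsv(summary: OutcomeSummary, path, config_header: dict | None = None):
    """Write an outcome summary as TSV with a ``#``-comment config header."""
    with open(path, "w") as fh:
        if config_header:
            for key, val in config_header.items():
                fh.write(f"# {key}: {val}\n")
        fh.write(f"# n_replicates: {summary.n_replicates}\n")
        summary.table.reset_index().to_csv(fh, sep="\t", index=False)


__all__ = [
    "HAPLOTYPE_CLASSES",
    "OUTCOME_CLASSES",
    "OutcomeSummary",
    "classify_haplotype",
    "detect_resolution",
    "estimate_outcome_probabilities",
    "fixation_correlation",
    "hybrid_speciation_probability",
    "independent_dmi_prediction",
    "is_hybrid_speciation",
    "outcome_table_tsv",
    "reciprocal_sorting_prediction",
    "summarize_outcomes",
]
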