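"""Scoring ranked outputs against truth.

Top-1/top-10 recovery with percentages over the cases whose causative
variant received a rank, lower-median rank, information-content–vs–rank
correlation (Spearman), and the clean/comorbid/dropout/two-variant
experiment conditions over a spike-in cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .prioritize import RankedResult, prioritize_records
from .similarity import PhenotypeProfile
from .simulate import (
    Case,
    SignalModel,
    World,
    generate_cohort,
    most_similar_disease,
    perturb_profile,
    spike_in_case,
)
from .training import CausativeVariantClassifier


class EvaluationError(ValueError):
    pass


@dataclass
class RecoverySummary:
    """Causative-variant recovery counts for a set of cases.

    Percentages are computed over ``n_ranked`` — the cases whose causative
    variant received a rank; unranked cases are counted in ``n_total``
    only.  ``median_rank`` is the lower median of the observed ranks.
    """

    n_total: int
    n_ranked: int
    n_top1: int
    n_top10: int
    median_rank: float | None
    strata: dict = field(default_factory=dict)

    @property
    def pct_top1(self) -> float:
        return 100.0 * self.n_top1 / self.n_ranked if self.n_ranked else math.nan

    @property
    def pct_top10(self) -> float:
        return 100.0 * self.n_top10 / self.n_ranked if self.n_ranked else math.nan

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_ranked": self.n_ranked,
            "n_top1": self.n_top1,
            "n_top10": self.n_top10,
            "pct_top1": round(self.pct_top1, 2) if self.n_ranked else None,
            "pct_top10": round(self.pct_top10, 2) if self.n_ranked else None,
            "median_rank": self.median_rank,
            **({"strata": self.strata} if self.strata else {}),
        }


def lower_median(values: Sequence[float]) -> float | None:
    if not values:
        return None
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def summarize_ranks(ranks: Sequence[int | None]) -> RecoverySummary:
    """Recovery summary from per-case causative ranks (None = unranked)."""
    observed = [r for r in ranks if r is not None]
    return RecoverySummary(
        n_total=len(ranks),
        n_ranked=len(observed),
        n_top1=sum(1 for r in observed if r == 1),
        n_top10=sum(1 for r in observed if r <= 10),
        median_rank=lower_median(observed),
    )


def rank_recovery(
    results: Sequence[RankedResult], truths: Sequence[str]
) -> RecoverySummary:
    """Recovery summary for ranked results against per-case truth keys.

    A truth key matching more than one ranked variant is ambiguous and
    rejected; a truth variant absent from the ranking leaves that case
    unranked (excluded from the percentage denominator).
    """
    if len(results) != len(truths):
        raise EvaluationError("one truth key required per case")
    ranks: list[int | None] = []
    for res, key in zip(results, truths):
        matches = [rank for rank, rec, _ in res.entries if rec.key == key]
        if len(matches) > 1:
            raise EvaluationError(f"truth key {key!r} matches multiple variants")
        ranks.append(matches[0] if matches else None)
    return summarize_ranks(ranks)


def ic_rank_correlation(
    profiles: Sequence[Iterable[str]],
    ranks: Sequence[int],
    ic: Mapping[str, float],
) -> float:
    """Spearman correlation between profile information content (sum of
    class ICs) and causative-variant rank.

    Undefined (constant IC or constant rank) inputs return NaN with a
    warning.
    """
    if len(profiles) != len(ranks) or len(ranks) < 3:
        raise EvaluationError("need >= 3 paired (profile, rank) cases")
    totals = [sum(ic[c] for c in p) for p in profiles]
    if len(set(totals)) < 2 or len(set(ranks)) < 2:
        warnings.warn("constant IC or rank: correlation undefined", stacklevel=2)
        return math.nan
    rho, _ = stats.spearmanr(totals, ranks)
    return float(rho)


# ---------------------------------------------------------------------------
# experiment conditions
# ---------------------------------------------------------------------------

CONDITIONS = ("clean", "comorbid", "dropout", "two_variant")


def _rank_case(
    case: Case,
    profile: PhenotypeProfile,
    world: World,
    model: CausativeVariantClassifier,
    sources,
    extra_records=None,
) -> RankedResult:
    records = case.records if extra_records is None else case.records + extra_records
    return prioritize_records(
        records,
        profile,
        model,
        world.engine(sources),
        world.genes,
        world.panel,
        score_tables=case.score_tables,
        maf_table=case.maf_table,
    )


def experiment_suite(
    world: World,
    model: CausativeVariantClassifier,
    n_cases: int,
    background_n: int,
    signal: SignalModel,
    seed: int,
    conditions: Sequence[str] = CONDITIONS,
    dropout_p: float = 1 / 3,
    sources: Sequence[str] = ("human", "mouse", "zebrafish"),
) -> dict:
    """Run the pipeline per case under each experimental condition.

    ``clean`` uses the disease profile as-is; ``comorbid`` unions in a
    second disease's phenotypes; ``dropout`` removes each profile class
    with probability ``dropout_p``; ``two_variant`` spikes a second
    causative variant for the most phenotypically similar disease and
    records the ranks of both variants while the profile matches the
    first.  The same cohort (seeded) underlies every condition, so
    comparisons are paired.
    """
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise EvaluationError(f"unknown conditions: {sorted(unknown)}")
    cases = generate_cohort(world, n_cases, background_n, signal, seed)
    rng = np.random.default_rng(seed + 1)
    report: dict = {"n_cases": n_cases, "background_n": background_n}
    per_condition_ranks: dict[str, list[int | None]] = {}
    for condition in conditions:
        if condition == "two_variant":
            v1_ranks: list[int | None] = []
            v2_ranks: list[int | None] = []
            for case in cases:
                other = most_similar_disease(world, case.truth.disease_id)
                second = spike_in_case(
                    world,
                    other,
                    background_n=0,
                    signal=signal,
                    seed=int(rng.integers(2**31 - 1)),
                )
                sv = second.records[-1]
                extra = [sv]
                for t, ct in zip(case.score_tables, second.score_tables):
                    t.setdefault(sv.key, ct.get(sv.key))
                res = _rank_case(case, case.profile, world, model, sources, extra)
                v1_ranks.append(res.rank_of(case.truth.variant_key))
                v2_ranks.append(res.rank_of(sv.key))
            report["two_variant"] = {
                "v1": summarize_ranks(v1_ranks).as_dict(),
                "v2": summarize_ranks(v2_ranks).as_dict(),
            }
            continue
        ranks: list[int | None] = []
        for case in cases:
            profile = case.profile
            if condition == "comorbid":
                profile = perturb_profile(
                    profile, "comorbid", world,
                    seed=int(rng.integers(2**31 - 1)),
                    disease_id=case.truth.disease_id,
                )
            elif condition == "dropout":
                profile = perturb_profile(
                    profile, "dropout", world,
                    seed=int(rng.integers(2**31 - 1)), dropout_p=dropout_p,
                )
            res = _rank_case(case, profile, world, model, sources)
            ranks.append(res.rank_of(case.truth.variant_key))
        per_condition_ranks[condition] = ranks
        report[condition] = summarize_ranks(ranks).as_dict()
    report["_ranks"] = per_condition_ranks
    return report
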