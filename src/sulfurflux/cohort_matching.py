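"""Recursive-elimination selection of matched case/control subsets.

Candidates carrying hard exclusion flags are removed first; the remaining
pool is then shrunk one sample at a time, always removing the sample whose
exclusion most improves a composite deviation score: Kolmogorov-Smirnov
statistics for the age and BMI distributions between selected cases and
controls, plus the fraction of selected subjects carrying each soft flag
(medication use, risk-allele carriage).  Sex balance across groups is a hard
constraint — removals that would make it unattainable are not considered —
and each soft criterion enters the sum with equal weight, normalized to
[0, 1] (the theoretically achievable optimum of every component is 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Candidate:
    subject_id: str
    is_case: bool
    age: float
    bmi: float
    sex: int  # 1 = male, 0 = female
    flags: dict[str, int] = field(default_factory=dict)


@dataclass
class SelectionScore:
    ks_age: float
    ks_bmi: float
    flag_fractions: dict[str, float]
    sex_balanced: bool
    total: float


def candidates_from_frame(df: pd.DataFrame) -> list[Candidate]:
    flag_cols = [
        c for c in df.columns
        if c not in ("subject_id", "is_case", "age", "bmi", "sex")
    ]
    return [
        Candidate(
            str(r["subject_id"]), bool(r["is_case"]), float(r["age"]),
            float(r["bmi"]), int(r["sex"]),
            {c: int(r[c]) for c in flag_cols},
        )
        for _, r in df.iterrows()
    ]


def prefilter(candidates: list[Candidate], exclusion_flags) -> list[Candidate]:
    """Hard-exclude subjects carrying any of the named flags."""
    kept = [
        c for c in candidates
        if not any(c.flags.get(f, 0) for f in exclusion_flags)
    ]
    if not kept:
        logger.warning("prefilter removed every candidate")
    return kept


def score_selection(cases: list[Candidate], controls: list[Candidate]) -> SelectionScore:
    """Composite deviation score of the current selection (lower is better)."""
    if not cases or not controls:
        raise ValueError("both groups must be non-empty")
    ks_age = float(
        stats.ks_2samp([c.age for c in cases], [c.age for c in controls]).statistic
    )
    ks_bmi = float(
        stats.ks_2samp([c.bmi for c in cases], [c.bmi for c in controls]).statistic
    )
    everyone = cases + controls
    flag_names = sorted({f for c in everyone for f in c.flags})
    fractions = {
        f: sum(c.flags.get(f, 0) for c in everyone) / len(everyone)
        for f in flag_names
    }
    balanced = sum(c.sex for c in cases) == sum(c.sex for c in controls)
    total = ks_age + ks_bmi + sum(fractions.values())
    return SelectionScore(ks_age, ks_bmi, fractions, balanced, total)


def _sex_balance_attainable(cases, controls, n_cases, n_controls) -> bool:
    """Can targets be reached with equal male counts across groups?"""
    mc = sum(c.sex for c in cases)
    fc = len(cases) - mc
    mk = sum(c.sex for c in controls)
    fk = len(controls) - mk
    for m in range(0, min(mc, mk, n_cases, n_controls) + 1):
        if fc >= n_cases - m and fk >= n_controls - m:
            if n_cases - m >= 0 and n_controls - m >= 0:
                return True
    return False


def recursive_match(
    candidates: list[Candidate],
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Greedy recursive elimination to the target sizes.

    At every step the removable sample (from an oversized group, keeping sex
    balance attainable) whose removal minimises the selection score is
    dropped; ties break on the lowest subject id.  Returns the selected ids
    and the score trace (initial score first).
    """
    cases = sorted((c for c in candidates if c.is_case), key=lambda c: c.subject_id)
    controls = sorted((c for c in candidates if not c.is_case), key=lambda c: c.subject_id)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"infeasible targets: have {len(cases)} cases / {len(controls)} "
            f"controls, need {n_cases}/{n_controls}"
        )
    if not _sex_balance_attainable(cases, controls, n_cases, n_controls):
        raise ValueError("infeasible targets: sex balance unattainable")

    trace = [score_selection(cases, controls).total]
    while len(cases) > n_cases or len(controls) > n_controls:
        best = None
        pools = []
        if len(cases) > n_cases:
            pools.append(("case", cases))
        if len(controls) > n_controls:
            pools.append(("control", controls))
        for kind, pool in pools:
            for i, cand in enumerate(pool):
                rest = pool[:i] + pool[i + 1:]
                cs = rest if kind == "case" else cases
                ks = rest if kind == "control" else controls
                if not _sex_balance_attainable(cs, ks, n_cases, n_controls):
                    continue
                total = score_selection(cs, ks).total
                key = (total, cand.subject_id)
                if best is None or key < best[0]:
                    best = (key, kind, i)
        if best is None:
            raise ValueError("no removable sample keeps sex balance attainable")
        _, kind, i = best
        if kind == "case":
            cases = cases[:i] + cases[i + 1:]
        else:
            controls = controls[:i] + controls[i + 1:]
        trace.append(score_selection(cases, controls).total)

    # final sex balancing happens implicitly: reaching the targets with
    # balance attainable and exact sizes forces equal male counts only if the
    # greedy path preserved it; warn if the final selection is off-balance.
    final = score_selection(cases, controls)
    if not final.sex_balanced:
        logger.warning("final selection is not sex balanced")
    if any(b > a + 1e-12 for a, b in zip(trace, trace[1:])):
        logger.warning("greedy score trace increased at some step")
    return [c.subject_id for c in cases + controls], trace
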