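"""Symptom-domain subgrouping and demographic statistics.

ASD subjects are assigned to one of three core-symptom subgroups (SI =
social interaction, VA = verbal communication, RRB = restricted repetitive
behaviors) by normalizing each ADI-R subscale score to [0, 1] as
``X' = X / X_MAX`` and taking the strictly largest of the three normalized
values (S, V, R). Ties exclude the subject. The same machinery runs on
ADOS subscales via a column mapping, so subgrouping is instrument-agnostic.

Also houses the demographic test battery: Pearson chi-squared on 2x2 gender
tables (no continuity correction), two-sample t-tests, and Kruskal-Wallis +
Dunn pairwise comparisons with Bonferroni correction for subscale contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_MAX_SCORES",
    "NormalizedScores",
    "PhenotypeRecord",
    "SubgroupAssignment",
    "assign_subgroup",
    "assign_subgroups_table",
    "chi_square_2x2",
    "match_controls",
    "normalize_subscales",
    "subscale_pairwise_nonparametric",
    "two_sample_t",
]

#: Instrument maxima used to normalize ADI-R subscales (social, verbal, RRB).
DEFAULT_MAX_SCORES = (30.0, 26.0, 12.0)

LABELS = ("SI", "VA", "RRB")
EXCLUDED = "EXCLUDED"


@dataclass
class PhenotypeRecord:
    """One subject's demographic, diagnostic, and symptom-scale data."""

    subject_id: str
    site: str
    diagnosis: str  # "ASD" or "TD"
    age: float
    gender: str  # "male" or "female"
    adir_social: int | None = None
    adir_verbal: int | None = None
    adir_rrb: int | None = None
    ados_social: int | None = None
    ados_comm: int | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.diagnosis not in ("ASD", "TD"):
            raise ValueError(f"diagnosis must be ASD or TD, got {self.diagnosis!r}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male or female, got {self.gender!r}")


@dataclass(frozen=True)
class NormalizedScores:
    """Subscale scores divided by their maxima; each lies in [0, 1]."""

    s: float
    v: float
    r: float


@dataclass(frozen=True)
class SubgroupAssignment:
    subject_id: str
    label: str  # SI / VA / RRB / EXCLUDED
    normalized: NormalizedScores


def normalize_subscales(
    record: PhenotypeRecord,
    max_scores: Sequence[float] = DEFAULT_MAX_SCORES,
) -> NormalizedScores:
    """Divide each subscale score by its maximum: ``X' = X / X_MAX``."""
    raw = (record.adir_social, record.adir_verbal, record.adir_rrb)
    names = ("social", "verbal", "rrb")
    out = []
    for x, xmax, name in zip(raw, max_scores, names):
        if x is None:
            raise ValueError(f"missing ADI-R {name} subscale for {record.subject_id}")
        if xmax <= 0:
            raise ValueError(f"max score for {name} must be positive, got {xmax}")
        if not 0 <= x <= xmax:
            raise ValueError(f"{name} score {x} outside [0, {xmax}]")
        out.append(x / xmax)
    return NormalizedScores(*out)


def assign_subgroup(
    scores: NormalizedScores, subject_id: str = "", tie_rule: str = "max"
) -> SubgroupAssignment:
    """Strict-max rule over (S, V, R); ties exclude the subject.

    tie_rule
        ``"max"`` (default): a tie at the maximum excludes; a subject with
        a strict maximum but equal lower scores is still assigned.
        ``"any"``: any pairwise equality among S, V, R excludes (the tie
        rule read literally: if S = V or S = R or V = R, exclude).
    """
    vals = (scores.s, scores.v, scores.r)
    if tie_rule == "any":
        tied = vals[0] == vals[1] or vals[0] == vals[2] or vals[1] == vals[2]
    elif tie_rule == "max":
        m = max(vals)
        tied = sum(v == m for v in vals) > 1
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if tied:
        return SubgroupAssignment(subject_id, EXCLUDED, scores)
    return SubgroupAssignment(subject_id, LABELS[int(np.argmax(vals))], scores)


# Column sets for instrument-agnostic subgrouping of a phenotype table.
INSTRUMENT_COLUMNS: Mapping[str, tuple[str, str, str]] = {
    "adir": ("ADI_R_SOCIAL_TOTAL_A", "ADI_R_VERBAL_TOTAL_BV", "ADI_RRB_TOTAL_C"),
    "ados": ("ADOS_SOCIAL", "ADOS_COMM", "ADOS_STEREO_BEHAV"),
}


def assign_subgroups_table(
    pheno: pd.DataFrame,
    instrument: str = "adir",
    max_scores: Sequence[float] = DEFAULT_MAX_SCORES,
    tie_rule: str = "max",
) -> pd.DataFrame:
    """Assign every ASD row of a phenotype table to SI/VA/RRB/EXCLUDED.

    Returns a frame with columns subject_id, label, s, v, r. Rows with any
    missing subscale are dropped (subgrouping requires complete scores).
    """
    cols = INSTRUMENT_COLUMNS[instrument]
    asd = pheno[pheno["DX_GROUP"] == 1]
    asd = asd.dropna(subset=list(cols))
    rows = []
    for _, row in asd.iterrows():
        rec = PhenotypeRecord(
            subject_id=str(row["SUB_ID"]),
            site=str(row["SITE_ID"]),
            diagnosis="ASD",
            age=float(row["AGE_AT_SCAN"]),
            gender="male" if int(row["SEX"]) == 1 else "female",
            adir_social=int(row[cols[0]]),
            adir_verbal=int(row[cols[1]]),
            adir_rrb=int(row[cols[2]]),
        )
        ns = normalize_subscales(rec, max_scores)
        a = assign_subgroup(ns, rec.subject_id, tie_rule=tie_rule)
        rows.append((a.subject_id, a.label, ns.s, ns.v, ns.r))
    return pd.DataFrame(rows, columns=["subject_id", "label", "s", "v", "r"])


def records_from_table(pheno: pd.DataFrame) -> list[PhenotypeRecord]:
    """Demographic-only records (no subscales) from a phenotype table."""
    out = []
    for _, row in pheno.iterrows():
        out.append(
            PhenotypeRecord(
                subject_id=str(row["SUB_ID"]),
                site=str(row["SITE_ID"]),
                diagnosis="ASD" if int(row["DX_GROUP"]) == 1 else "TD",
                age=float(row["AGE_AT_SCAN"]),
                gender="male" if int(row["SEX"]) == 1 else "female",
            )
        )
    return out


def match_controls(
    cases_by_analysis: Mapping[str, Sequence[PhenotypeRecord]],
    pool: Sequence[PhenotypeRecord],
    age_tolerance: float = 2.0,
    seed: int = 0,
) -> dict[str, dict[str, list[str]]]:
    """Greedy random age/gender/site matching, independently per analysis.

    For each analysis, every case gets one randomly chosen pool member from
    the same site and gender within ``age_tolerance`` years, without
    replacement inside that analysis. A control may serve several analyses
    (matched repeatedly across analyses, never twice within one). Returns
    ``{analysis: {"controls": [...ids...], "unmatched": [...case ids...]}}``.
    """
    if any(rec.diagnosis != "TD" for rec in pool):
        raise ValueError("control pool must contain only TD records")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, list[str]]] = {}
    for analysis in sorted(cases_by_analysis):
        cases = cases_by_analysis[analysis]
        taken: set[str] = set()
        chosen: list[str] = []
        unmatched: list[str] = []
        for case in cases:
            eligible = [
                rec
                for rec in pool
                if rec.subject_id not in taken
                and rec.site == case.site
                and rec.gender == case.gender
                and abs(rec.age - case.age) <= age_tolerance
            ]
            if not eligible:
                unmatched.append(case.subject_id)
                continue
            pick = eligible[int(rng.integers(len(eligible)))]
            taken.add(pick.subject_id)
            chosen.append(pick.subject_id)
        out[analysis] = {"controls": chosen, "unmatched": unmatched}
    return out


def chi_square_2x2(counts: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(counts, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def two_sample_t(
    group_a: Iterable[float], group_b: Iterable[float], pooled: bool = True
) -> tuple[float, float]:
    """Two-sided independent two-sample t-test (pooled variance by default)."""
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def subscale_pairwise_nonparametric(
    groups: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus followed by Dunn's pairwise z comparisons.

    Dunn's standardized statistic for groups a, b on pooled mid-ranks is
    ``(Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T) * (1/n_a + 1/n_b))`` with the
    tie correction ``T = sum(t^3 - t) / (12 (N - 1))``. Pairwise two-sided
    normal p-values are Bonferroni-multiplied by the number of pairs and
    capped at 1. Returns one row per pair plus omnibus stats as attrs.
    """
    names = list(groups)
    if len(names) != 3:
        raise ValueError("expected exactly three groups")
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction over pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    splits = np.cumsum([len(a) for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {n: gr.mean() for n, gr in zip(names, group_ranks)}
    sizes = {n: len(groups[n]) for n in names}

    identical = all((a == arrays[0][0]).all() for a in arrays) and (
        arrays[0] == arrays[0][0]
    ).all()
    if identical:
        h_stat, h_p = 0.0, 1.0
    else:
        h_stat, h_p = stats.kruskal(*arrays)

    pairs = [(names[0], names[1]), (names[0], names[2]), (names[1], names[2])]
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        raw_p = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
        rows.append((f"{a} vs {b}", float(z), min(1.0, 3.0 * raw_p)))
    table = pd.DataFrame(rows, columns=["pair", "std_statistic", "p_bonferroni"])
    table.attrs["kruskal_h"] = float(h_stat)
    table.attrs["kruskal_p"] = float(h_p)
    return table
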