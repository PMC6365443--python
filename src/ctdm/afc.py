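"""Two-alternative forced-choice (2AFC) discrimination statistics.

A 2AFC response set pairs one composite from each group per trial and
records whether the participant picked the objectively-outgroup face.
Pair types are labelled "i_j" where i indexes the first group's three
composite categories (1 farthest from the other group, 2 average, 3
closest) and j the second group's (4 closest, 5 average, 6 farthest).

The module provides the participant exclusion rule (too little time
spent in the home culture), the left/right counterbalance check,
accuracy tables, one-proportion z-tests against chance, Cochran's Q as
an omnibus test over pair types, and matched McNemar comparisons with
Hochberg familywise adjustment. The closed-form tests delegate to
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .errors import ConstantInputError

__all__ = [
    "AFCResponseSet",
    "PAIR_TYPES",
    "DEFAULT_COMPARISON_PLAN",
    "exclusion_filter",
    "counterbalance_check",
    "accuracy_table",
    "one_proportion_ztest",
    "cochran_q",
    "mcnemar_test",
    "hochberg_adjust",
    "pairwise_comparisons",
]

PAIR_TYPES = tuple(f"{i}_{j}" for i in (1, 2, 3) for j in (4, 5, 6))

# Hold one composite fixed and contrast the far/average ingroup composite
# against the one closest to the outgroup (per face gender).
DEFAULT_COMPARISON_PLAN = tuple(
    (f"{i}_{j}", f"3_{j}") for j in (4, 5, 6) for i in (1, 2)
)


@dataclass
class AFCResponseSet:
    """Participants and their per-trial binary correctness.

    ``trials`` columns: participant_id, pair (e.g. "1_4"), side
    ("left"/"right" of the outgroup face), correct (0/1), and optionally
    face_gender. ``participants`` columns: participant_id plus metadata
    (age_months, months_abroad, nationality, ...).
    """

    trials: pd.DataFrame
    participants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"participant_id", "pair", "correct"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials table missing columns: {sorted(missing)}")
        if not set(self.trials["correct"].unique()) <= {0, 1}:
            raise ValueError("correct must be binary 0/1")

    @property
    def n_participants(self) -> int:
        return self.trials["participant_id"].nunique()

    def correctness_matrix(self, face_gender: str | None = None) -> pd.DataFrame:
        """Participants x pair-types 0/1 matrix (complete cases only)."""
        t = self.trials
        if face_gender is not None:
            t = t[t["face_gender"] == face_gender]
        mat = t.pivot_table(
            index="participant_id", columns="pair", values="correct", aggfunc="first"
        )
        cols = [p for p in PAIR_TYPES if p in mat.columns]
        return mat[cols]


@dataclass
class ExclusionReport:
    excluded: list = field(default_factory=list)  # (participant_id, reason)
    retained_flagged: list = field(default_factory=list)  # missing-data retentions


def exclusion_filter(
    responses: AFCResponseSet, min_months_home: float = 1.0
) -> tuple[AFCResponseSet, ExclusionReport]:
    """Drop participants who spent at most ``min_months_home`` months at home.

    Months in the home culture is age in months minus months reported
    abroad. Participants with missing data on either field are retained
    and flagged rather than excluded.
    """
    report = ExclusionReport()
    parts = responses.participants
    if parts.empty or "age_months" not in parts.columns:
        return responses, report
    keep = []
    for _, row in parts.iterrows():
        pid = row["participant_id"]
        age = row.get("age_months")
        abroad = row.get("months_abroad")
        if pd.isna(age) or pd.isna(abroad):
            report.retained_flagged.append(pid)
            keep.append(pid)
            continue
        months_home = float(age) - float(abroad)
        if months_home <= min_months_home:
            report.excluded.append((pid, f"months in homeland = {months_home:g}"))
        else:
            keep.append(pid)
    keep_set = set(keep)
    filtered = AFCResponseSet(
        trials=responses.trials[responses.trials["participant_id"].isin(keep_set)].copy(),
        participants=parts[parts["participant_id"].isin(keep_set)].copy(),
    )
    return filtered, report


def counterbalance_check(responses: AFCResponseSet) -> tuple[pd.DataFrame, dict]:
    """Left-vs-right accuracy difference per pair type.

    Returns a per-pair table of p_hat(left) - p_hat(right) and a summary
    with the mean and range of the differences. Pairs shown on one side
    only get a NaN difference and are flagged.
    """
    t = responses.trials
    if "side" not in t.columns:
        raise ValueError("trials table has no 'side' column")
    keys = ["pair"] + (["face_gender"] if "face_gender" in t.columns else [])
    acc = t.groupby(keys + ["side"])["correct"].mean().unstack("side")
    for side in ("left", "right"):
        if side not in acc.columns:
            acc[side] = np.nan
    acc["difference"] = acc["left"] - acc["right"]
    flagged = list(acc.index[acc["difference"].isna()])
    diffs = acc["difference"].dropna()
    summary = {
        "mean_difference": float(diffs.mean()) if len(diffs) else np.nan,
        "min_difference": float(diffs.min()) if len(diffs) else np.nan,
        "max_difference": float(diffs.max()) if len(diffs) else np.nan,
        "one_sided_pairs": flagged,
    }
    return acc.reset_index(), summary


def accuracy_table(responses: AFCResponseSet) -> pd.DataFrame:
    """Proportion correct per pair type, with per-gender and global averages.

    Rows follow the canonical pair ordering; the averages are unweighted
    means of the pair-level proportions.
    """
    t = responses.trials
    has_gender = "face_gender" in t.columns
    if has_gender:
        table = t.pivot_table(index="pair", columns="face_gender", values="correct", aggfunc="mean")
    else:
        table = t.groupby("pair")["correct"].mean().to_frame("accuracy")
    table = table.reindex([p for p in PAIR_TYPES if p in table.index])
    averages = table.mean(axis=0)
    table.loc["average_within_gender" if has_gender else "average"] = averages
    table.loc["global_average"] = float(np.nanmean(table.iloc[:-1].to_numpy()))
    return table


def one_proportion_ztest(
    successes: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> tuple[float, float]:
    """One-proportion z-test with the null variance p0(1-p0)/n.

    ``z = (p_hat - p0) / sqrt(p0 (1 - p0) / n)``, no continuity
    correction; p from the normal upper tail (``alternative="greater"``)
    or both tails.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    alt = {"greater": "larger", "two-sided": "two-sided"}[alternative]
    z, p = proportions_ztest(successes, n, value=p0, alternative=alt, prop_var=p0)
    return float(z), float(p)


def cochran_q(binary: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q over k matched binary conditions.

    ``Q = (k-1) [k sum C_j^2 - (sum C_j)^2] / (k sum R_i - sum R_i^2)``
    with column totals C_j and row totals R_i; df = k-1; p from the
    chi-square upper tail. Undefined when every row is constant.
    """
    x = np.asarray(binary, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a participants x conditions matrix with k >= 2")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("matrix must be binary")
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - np.sum(row**2)
    if denom == 0:
        raise ConstantInputError("all rows constant; Cochran's Q undefined")
    q = (k - 1) * (k * np.sum(col**2) - col.sum() ** 2) / denom
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return float(q), df, p


@dataclass
class McNemarResult:
    chi2: float
    p: float
    b: int
    c: int
    corrected: bool
    no_discordance: bool = False


def mcnemar_test(b: int, c: int, correction: bool = False) -> McNemarResult:
    """Asymptotic McNemar test from the two discordance counts.

    ``chi2 = (b - c)^2 / (b + c)`` (uncorrected default; the continuity
    correction subtracts 1 from |b - c|). With no discordant pairs the
    statistic is undefined and the result is flagged instead of raising.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if b + c == 0:
        return McNemarResult(np.nan, np.nan, b, c, correction, no_discordance=True)
    table = np.array([[0, b], [c, 0]])
    res = _sm_mcnemar(table, exact=False, correction=correction)
    return McNemarResult(float(res.statistic), float(res.pvalue), b, c, correction)


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg step-up familywise adjustment of a p-value family."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="simes-hochberg")[1]


def pairwise_comparisons(
    responses: AFCResponseSet,
    plan: tuple[tuple[str, str], ...] = DEFAULT_COMPARISON_PLAN,
    correction: bool = False,
) -> pd.DataFrame:
    """Matched McNemar comparisons between pair types, Hochberg-adjusted.

    For each planned comparison the per-participant responses to the
    two pair types are matched; participants missing either trial are
    dropped from that comparison. The Hochberg family is the set of
    comparisons within each face gender (or the whole plan when no
    gender column exists).
    """
    t = responses.trials
    genders = (
        sorted(t["face_gender"].dropna().unique()) if "face_gender" in t.columns else [None]
    )
    rows = []
    for g in genders:
        mat = responses.correctness_matrix(face_gender=g)
        family_p = []
        family_rows = []
        for pair_a, pair_b in plan:
            if pair_a not in mat.columns or pair_b not in mat.columns:
                raise ValueError(f"pair type missing from responses: {pair_a} or {pair_b}")
            sub = mat[[pair_a, pair_b]].dropna()
            b = int(((sub[pair_a] == 1) & (sub[pair_b] == 0)).sum())
            c = int(((sub[pair_a] == 0) & (sub[pair_b] == 1)).sum())
            res = mcnemar_test(b, c, correction=correction)
            family_rows.append(
                {
                    "face_gender": g,
                    "comparison": f"{pair_a} vs. {pair_b}",
                    "n_matched": len(sub),
                    "b": b,
                    "c": c,
                    "chi2": res.chi2,
                    "p_raw": res.p,
                }
            )
            family_p.append(res.p)
        adjusted = hochberg_adjust(np.nan_to_num(np.asarray(family_p), nan=1.0))
        for row, adj, raw in zip(family_rows, adjusted, family_p):
            row["p_adjusted"] = float(adj) if np.isfinite(raw) else np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    if genders == [None]:
        out = out.drop(columns=["face_gender"])
    return out
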