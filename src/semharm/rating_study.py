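"""Expert pre-test design and validation statistics.

The pre-test asks domain experts to rate a stratified sample of scored item
pairs.  For each instrument, three score-based candidate groups are built —
the five most similar eligible pairs, the five closest to the instrument's
mean score, and the five least similar — one group per instrument is chosen
at random, the chosen groups are pooled, and a fixed number of pairs is
drawn from the pool.  Expert answers (binary harmonization suitability plus
a 1–10 perceived-similarity score, PSS) are then compared against the
model's positive/negative call to estimate agreement, and the PSS is rank-
correlated with the model's cosine score (SES).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError

GROUP_TOP = "most_similar"
GROUP_MID = "mean_closest"
GROUP_BOTTOM = "least_similar"

RATING_COLUMNS = ["pair_id", "rater_id", "suitable", "pss", "comment"]


@dataclass
class CandidateGroups:
    """The three score-stratified candidate groups of one instrument.

    Each group is a pair-table slice; groups are disjoint whenever the
    instrument has at least 3 × group_size eligible pairs.
    """

    instrument: str
    top: pd.DataFrame
    middle: pd.DataFrame
    bottom: pd.DataFrame
    eligible_mean: float

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {GROUP_TOP: self.top, GROUP_MID: self.middle, GROUP_BOTTOM: self.bottom}


def eligible_pairs(pairs: pd.DataFrame, instrument: str) -> pd.DataFrame:
    """Pairs with at least one member item belonging to ``instrument``."""
    mask = (pairs["instrument_a"] == instrument) | (pairs["instrument_b"] == instrument)
    return pairs[mask]


def build_candidate_groups(
    pairs: pd.DataFrame, instrument: str, group_size: int = 5
) -> CandidateGroups:
    """Build the three score-based groups for one instrument.

    Ties are broken deterministically by smaller pair_id.  When fewer than
    3 × group_size eligible pairs exist, groups are de-duplicated with
    priority top > bottom > middle, so their union is every eligible pair.
    """
    elig = eligible_pairs(pairs, instrument)
    if len(elig) == 0:
        raise EmptyInputError(f"instrument {instrument!r} has no eligible pairs")
    mean_score = float(elig["score"].mean())

    by_desc = elig.sort_values(["score", "pair_id"], ascending=[False, True], kind="mergesort")
    by_asc = elig.sort_values(["score", "pair_id"], ascending=[True, True], kind="mergesort")
    dev = (elig["score"] - mean_score).abs()
    by_mid = elig.assign(_dev=dev).sort_values(
        ["_dev", "pair_id"], ascending=[True, True], kind="mergesort"
    )

    top = by_desc.head(group_size)
    taken = set(top["pair_id"])
    bottom = by_asc[~by_asc["pair_id"].isin(taken)].head(group_size)
    taken |= set(bottom["pair_id"])
    middle = by_mid[~by_mid["pair_id"].isin(taken)].head(group_size).drop(columns="_dev")

    return CandidateGroups(
        instrument=instrument,
        top=top.reset_index(drop=True),
        middle=middle.reset_index(drop=True),
        bottom=bottom.reset_index(drop=True),
        eligible_mean=mean_score,
    )


@dataclass
class StudySample:
    """Result of the stratified sampling procedure.

    ``preselected`` holds one row per (instrument, chosen group, pair)
    entry — the pool size counts these entries, so full groups over m
    instruments give exactly ``group_size × m`` — and ``final`` is the
    without-replacement draw of distinct pairs from the pool.
    """

    chosen_groups: dict[str, str]
    preselected: pd.DataFrame  # columns: instrument, group, pair rows
    final: pd.DataFrame
    seed: int
    group_size: int = 5

    @property
    def n_preselected(self) -> int:
        return len(self.preselected)

    @property
    def n_final(self) -> int:
        return len(self.final)


def sample_study_pairs(
    groups: Mapping[str, CandidateGroups],
    n_final: int = 20,
    seed: int = 0,
    group_size: int = 5,
    clamp: bool = False,
) -> StudySample:
    """Choose one group per instrument at random, pool, then draw the sample.

    All randomness flows from ``seed``.  The final sample contains
    ``n_final`` distinct pairs drawn uniformly without replacement from the
    distinct pairs of the pool; each sampled pair keeps the provenance of
    the first pool entry that contributed it.
    """
    if not groups:
        raise EmptyInputError("no instrument groups supplied")
    rng = np.random.default_rng(seed)
    group_names = [GROUP_TOP, GROUP_MID, GROUP_BOTTOM]
    chosen: dict[str, str] = {}
    pool_parts: list[pd.DataFrame] = []
    for instrument in sorted(groups):
        g = groups[instrument]
        name = group_names[rng.integers(0, 3)]
        chosen[instrument] = name
        part = g.as_dict()[name].copy()
        part.insert(0, "group", name)
        part.insert(0, "instrument", instrument)
        pool_parts.append(part)
    pool = pd.concat(pool_parts, ignore_index=True)

    distinct = pool.drop_duplicates(subset="pair_id", keep="first").reset_index(drop=True)
    if n_final > len(distinct) and clamp:
        n_final = len(distinct)
    if n_final > len(distinct):
        raise ValueError(
            f"n_final={n_final} exceeds the {len(distinct)} distinct preselected pairs"
        )
    idx = rng.choice(len(distinct), size=n_final, replace=False)
    final = distinct.iloc[np.sort(idx)].reset_index(drop=True)
    return StudySample(
        chosen_groups=chosen,
        preselected=pool,
        final=final,
        seed=int(seed),
        group_size=group_size,
    )


def design_study(
    pairs: pd.DataFrame,
    group_size: int = 5,
    n_final: int = 20,
    seed: int = 0,
    clamp: bool = False,
) -> StudySample:
    """Full sampling design over every instrument present in ``pairs``."""
    instruments = sorted(set(pairs["instrument_a"]) | set(pairs["instrument_b"]))
    groups = {
        inst: build_candidate_groups(pairs, inst, group_size=group_size)
        for inst in instruments
    }
    return sample_study_pairs(
        groups, n_final=n_final, seed=seed, group_size=group_size, clamp=clamp
    )


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-based confidence interval (sample SD, df = n−1).

    Bounds are not truncated: an interval on a percentage may exceed
    [0, 100], as untruncated t-intervals do.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("mean_ci requires at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = float(stats.t.ppf((1 + level) / 2, df=arr.size - 1) * sd / np.sqrt(arr.size))
    return mean, mean - half, mean + half


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Ties receive average ranks; rho is the Pearson correlation of the rank
    vectors.  For |rho| = 1 the p-value is reported as 0.0 (below machine
    resolution of the t tail).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires at least 3 observations")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("undefined correlation: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
    return rho, p


@dataclass
class AgreementStats:
    """Expert-vs-model agreement summary of a rating study."""

    positive_mean: float
    positive_ci: tuple[float, float]
    negative_mean: float
    negative_ci: tuple[float, float]
    spearman_rho: float
    spearman_p: float
    per_pair: pd.DataFrame
    excluded_pairs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "positive_mean_agreement_pct": self.positive_mean,
            "positive_ci": list(self.positive_ci),
            "negative_mean_agreement_pct": self.negative_mean,
            "negative_ci": list(self.negative_ci),
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n_pairs": int(len(self.per_pair)),
            "n_excluded": len(self.excluded_pairs),
        }


def agreement_stats(
    ratings: pd.DataFrame,
    model_classes: Mapping[str, str],
    ses: Mapping[str, float] | None = None,
    level: float = 0.95,
    high_variance_sd: float = 1.0,
) -> AgreementStats:
    """Agreement of expert suitability calls with the model classification.

    Per pair, agreement is the percentage of raters whose binary
    ``suitable`` answer matches the model class (suitable ↔ positive).
    Class-level means carry t-based CIs.  When ``ses`` scores are given,
    Spearman's rho between per-pair mean PSS and SES is included.  Pairs
    rated by nobody, or missing a model class, are excluded with a warning.
    ``per_pair`` flags pairs whose PSS standard deviation is at or above
    ``high_variance_sd`` as harder to rate.
    """
    required = {"pair_id", "rater_id", "suitable", "pss"}
    if not required <= set(ratings.columns):
        raise ValueError(f"ratings table must have columns {sorted(required)}")
    if ratings["pss"].min() < 1 or ratings["pss"].max() > 10:
        raise ValueError("pss must lie on the 1-10 scale")

    excluded = [pid for pid in pd.unique(ratings["pair_id"]) if pid not in model_classes]
    if excluded:
        warnings.warn(f"{len(excluded)} rated pair(s) have no model class; excluded", stacklevel=2)
    usable = ratings[~ratings["pair_id"].isin(excluded)]
    if usable.empty:
        raise EmptyInputError("no rated pairs with a model class")

    rows = []
    for pid, grp in usable.groupby("pair_id", sort=True):
        model_class = model_classes[pid]
        expert_positive = grp["suitable"].astype(bool)
        agree = expert_positive == (model_class == "positive")
        pss = grp["pss"].to_numpy(dtype=np.float64)
        pss_sd = float(pss.std(ddof=1)) if len(pss) > 1 else 0.0
        rows.append(
            {
                "pair_id": pid,
                "model_class": model_class,
                "n_raters": len(grp),
                "agreement_pct": 100.0 * float(agree.mean()),
                "pss_mean": float(pss.mean()),
                "pss_sd": pss_sd,
                "hard_to_rate": pss_sd >= high_variance_sd,
            }
        )
    per_pair = pd.DataFrame(rows)

    def class_ci(label: str) -> tuple[float, tuple[float, float]]:
        vals = per_pair.loc[per_pair["model_class"] == label, "agreement_pct"]
        if len(vals) == 0:
            raise EmptyInputError(f"no rated pairs in class {label!r}")
        if len(vals) == 1:
            v = float(vals.iloc[0])
            return v, (v, v)
        m, lo, hi = mean_ci(vals, level=level)
        return m, (lo, hi)

    pos_mean, pos_ci = class_ci("positive")
    neg_mean, neg_ci = class_ci("negative")

    rho, p = np.nan, np.nan
    if ses is not None:
        have = per_pair[per_pair["pair_id"].isin(ses.keys())]
        if len(have) >= 3:
            rho, p = spearman(
                have["pss_mean"].to_numpy(),
                np.array([ses[pid] for pid in have["pair_id"]]),
            )
    return AgreementStats(
        positive_mean=pos_mean,
        positive_ci=pos_ci,
        negative_mean=neg_mean,
        negative_ci=neg_ci,
        spearman_rho=float(rho),
        spearman_p=float(p),
        per_pair=per_pair,
        excluded_pairs=list(excluded),
    )


def model_classes_from_threshold(pairs: pd.DataFrame, tau: float = 0.751) -> dict[str, str]:
    """Binary model class per pair: positive iff SES strictly above ``tau``."""
    return {
        row.pair_id: ("positive" if row.score > tau else "negative")
        for row in pairs.itertuples(index=False)
    }


def load_ratings(path: str | Path) -> pd.DataFrame:
    """Read an expert-ratings CSV (pair_id, rater_id, suitable, pss[, comment])."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = {"pair_id", "rater_id", "suitable", "pss"} - set(table.columns)
    if missing:
        raise ValueError(f"ratings CSV missing column(s) {sorted(missing)}")
    if table["suitable"].dtype == object:
        table["suitable"] = (
            table["suitable"].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "y"))
        )
    return table


def export_study_sample(sample: StudySample, path: str | Path) -> None:
    """Write the final study sample with group provenance as CSV."""
    sample.final.to_csv(path, index=False, encoding="utf-8")
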