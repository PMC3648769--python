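"""Scoring of a 25-item, 7-point Likert empathy questionnaire.

22 items are worded positively (agreement = more empathy) and 3 negatively
(disagreement = more empathy); 13 items probe fictitious and 12 real-life
situations. The total score sums the positive responses and the
reverse-coded (r -> 8 - r) negative responses, giving a range of 25..175.

The Kolmogorov-Smirnov normality check is run against the normal fitted to
the sample. Note the Lilliefors caveat: estimating mean and SD from the same
sample makes the resulting p-value anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

N_ITEMS = 25
N_POSITIVE = 22
N_NEGATIVE = 3
N_FICTITIOUS = 13
N_REAL_LIFE = 12
SCALE_MIN, SCALE_MAX = 1, 7
TOTAL_MIN = N_ITEMS * SCALE_MIN  # 25
TOTAL_MAX = N_ITEMS * SCALE_MAX  # 175


@dataclass(frozen=True)
class EScaleKey:
    """Per-item polarity and subscale assignment.

    polarity: 25 tokens in {positive, negative}, exactly 22/3.
    subscale: 25 tokens in {fictitious, real_life}, exactly 13/12.
    """

    polarity: tuple
    subscale: tuple

    def __post_init__(self):
        pol = tuple(self.polarity)
        sub = tuple(self.subscale)
        if len(pol) != N_ITEMS or len(sub) != N_ITEMS:
            raise ValidationError(f"key must cover exactly {N_ITEMS} items")
        if any(p not in ("positive", "negative") for p in pol):
            raise ValidationError("polarity tokens must be positive|negative")
        if any(s not in ("fictitious", "real_life") for s in sub):
            raise ValidationError("subscale tokens must be fictitious|real_life")
        n_pos = sum(p == "positive" for p in pol)
        if n_pos != N_POSITIVE or len(pol) - n_pos != N_NEGATIVE:
            raise ValidationError(
                f"need {N_POSITIVE} positive and {N_NEGATIVE} negative items, "
                f"got {n_pos}/{len(pol) - n_pos}"
            )
        n_fic = sum(s == "fictitious" for s in sub)
        if n_fic != N_FICTITIOUS or len(sub) - n_fic != N_REAL_LIFE:
            raise ValidationError(
                f"need {N_FICTITIOUS} fictitious and {N_REAL_LIFE} real_life "
                f"items, got {n_fic}/{len(sub) - n_fic}"
            )
        object.__setattr__(self, "polarity", pol)
        object.__setattr__(self, "subscale", sub)

    @property
    def negative_items(self) -> tuple:
        """0-based indices of the reverse-coded items."""
        return tuple(i for i, p in enumerate(self.polarity) if p == "negative")


def default_key() -> EScaleKey:
    """A synthetic stand-in key (the true item assignment is not public):
    items 5, 14, 23 (1-based) negative; items 1-13 fictitious, 14-25 real-life."""
    polarity = [
        "negative" if i in (4, 13, 22) else "positive" for i in range(N_ITEMS)
    ]
    subscale = ["fictitious" if i < 13 else "real_life" for i in range(N_ITEMS)]
    return EScaleKey(polarity=tuple(polarity), subscale=tuple(subscale))


def read_key(source) -> EScaleKey:
    """Key CSV with columns item, polarity, subscale (item = 1..25)."""
    df = pd.read_csv(source)
    for col in ("item", "polarity", "subscale"):
        if col not in df.columns:
            raise ValidationError(f"key file missing column {col!r}")
    df = df.sort_values("item")
    if list(df["item"]) != list(range(1, N_ITEMS + 1)):
        raise ValidationError("key file must list items 1..25 exactly once")
    return EScaleKey(polarity=tuple(df["polarity"]), subscale=tuple(df["subscale"]))


def write_key(key: EScaleKey, dest) -> None:
    pd.DataFrame(
        {
            "item": range(1, N_ITEMS + 1),
            "polarity": key.polarity,
            "subscale": key.subscale,
        }
    ).to_csv(dest, index=False)


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    responses: tuple
    total_score: int

    @property
    def per_item_mean(self) -> float:
        return self.total_score / N_ITEMS


def score_escale(responses, key: EScaleKey) -> int:
    """Total score of one subject's 25 responses under the key."""
    responses = list(responses)
    if len(responses) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} responses, got {len(responses)}")
    total = 0
    for i, (r, pol) in enumerate(zip(responses, key.polarity), start=1):
        if r is None or (isinstance(r, float) and not np.isfinite(r)):
            raise ValidationError(f"item {i:02d}: missing response")
        ri = int(r)
        if ri != r or not (SCALE_MIN <= ri <= SCALE_MAX):
            raise ValidationError(
                f"item {i:02d}: response {r!r} outside {SCALE_MIN}..{SCALE_MAX}"
            )
        total += ri if pol == "positive" else (SCALE_MAX + 1) - ri
    return total


@dataclass(frozen=True)
class CohortDescriptives:
    n: int
    mean_total: float
    sd_total: float
    mean_per_item: float
    sd_per_item: float


def cohort_descriptives(totals) -> CohortDescriptives:
    """Sample mean and SD (n - 1 denominator) of total scores, plus the same
    statistics on the per-item scale (totals / 25)."""
    t = np.asarray(list(totals), dtype=float)
    if t.size < 2:
        raise ValidationError("need at least 2 subjects for an SD")
    mean = float(t.mean())
    sd = float(t.std(ddof=1))
    return CohortDescriptives(
        n=int(t.size),
        mean_total=mean,
        sd_total=sd,
        mean_per_item=mean / N_ITEMS,
        sd_per_item=sd / N_ITEMS,
    )


def ks_normality(totals, mean=None, sd=None):
    """One-sample KS test of the totals against a normal reference.

    By default the reference is fitted to the sample (mean, SD with n - 1);
    explicit ``mean``/``sd`` override the fit. Returns (D, p). p uses the
    asymptotic KS distribution and is anti-conservative when the parameters
    come from the same sample.
    """
    t = np.asarray(list(totals), dtype=float)
    if t.size < 5:
        raise ValidationError("need at least 5 subjects")
    mean = t.mean() if mean is None else float(mean)
    sd = t.std(ddof=1) if sd is None else float(sd)
    if sd == 0:
        raise ValidationError("zero-variance sample")
    res = stats.kstest(t, "norm", args=(mean, sd))
    return float(res.statistic), float(res.pvalue)


def read_responses(source) -> list:
    """Responses CSV: subject_id plus item01..item25 columns."""
    df = pd.read_csv(source)
    item_cols = [f"item{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in ["subject_id", *item_cols] if c not in df.columns]
    if missing:
        raise ValidationError(f"responses file missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append((str(row["subject_id"]), [row[c] for c in item_cols]))
    return records


def write_responses(records, dest) -> None:
    """Write CohortRecords in the dialect read_responses expects."""
    data = {"subject_id": [r.subject_id for r in records]}
    for i in range(N_ITEMS):
        data[f"item{i + 1:02d}"] = [r.responses[i] for r in records]
    pd.DataFrame(data).to_csv(dest, index=False)
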