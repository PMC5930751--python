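"""Group comparisons of per-side cumulative enrichment.

Asymmetric pairs: the per-pair sum on the highly expressed gene's side of
the midpoint (``High_exp``) is compared with the sum on the lowly
expressed side (``Low_exp``). Symmetrically expressed pairs: left-of-
midpoint sums (``Similar_left``) against right-of-midpoint sums
(``Similar_right``). Both use a two-sided unpaired t-test; Welch's
unequal-variance form is the default, with Student's form selectable.
Silent pairs are excluded from both comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    values_a: np.ndarray
    values_b: np.ndarray
    t_stat: float
    p_value: float

    @property
    def n_a(self) -> int:
        return len(self.values_a)

    @property
    def n_b(self) -> int:
        return len(self.values_b)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format values for violin plotting."""
        return pd.DataFrame(
            {
                "group": [self.group_a_label] * self.n_a + [self.group_b_label] * self.n_b,
                "value": np.concatenate([self.values_a, self.values_b]),
            }
        )

    def summary_row(self) -> dict:
        return {
            "group_a": self.group_a_label,
            "group_b": self.group_b_label,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
        }


def unpaired_t_test(
    values_a,
    values_b,
    variant: str = "welch",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided unpaired t-test (Welch by default, Student selectable).

    Two completely degenerate identical groups (all values equal across
    both) give t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each group needs >= 2 values (got {len(a)} and {len(b)})")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite value in a comparison group")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return GroupComparison(labels[0], labels[1], a, b, 0.0, 1.0)
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    t, p = float(t), float(p)
    if np.isnan(t):
        # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return GroupComparison(labels[0], labels[1], a, b, t, p)


def _merged(side_enrichments: pd.DataFrame, classifications: pd.DataFrame) -> pd.DataFrame:
    need_s = {"pair_id", "left_sum", "right_sum"}
    need_c = {"pair_id", "label", "high_side"}
    if not need_s.issubset(side_enrichments.columns):
        raise ValueError(f"side enrichment table needs columns {sorted(need_s)}")
    if not need_c.issubset(classifications.columns):
        raise ValueError(f"classification table needs columns {sorted(need_c)}")
    return side_enrichments.merge(
        classifications[["pair_id", "label", "high_side"]], on="pair_id", how="inner"
    )


def compare_asymmetric(
    side_enrichments: pd.DataFrame,
    classifications: pd.DataFrame,
    variant: str = "welch",
) -> GroupComparison:
    """High-expressed side vs low-expressed side over asymmetric pairs.

    The left sum covers the minus-strand gene's side of the midpoint, so
    for a ``high_side == 'minus'`` pair the high group takes the left sum.
    """
    df = _merged(side_enrichments, classifications)
    asym = df[df["label"] == "asymmetric"]
    if len(asym) < 2:
        raise ValueError(f"need >= 2 asymmetric pairs, got {len(asym)}")
    minus_high = asym["high_side"] == "minus"
    high = np.where(minus_high, asym["left_sum"], asym["right_sum"]).astype(float)
    low = np.where(minus_high, asym["right_sum"], asym["left_sum"]).astype(float)
    return unpaired_t_test(high, low, variant=variant, labels=("High_exp", "Low_exp"))


def compare_symmetric(
    side_enrichments: pd.DataFrame,
    classifications: pd.DataFrame,
    variant: str = "welch",
) -> GroupComparison:
    """Left-of-midpoint vs right-of-midpoint sums over symmetric expressed pairs."""
    df = _merged(side_enrichments, classifications)
    sym = df[df["label"] == "symmetric_expressed"]
    if len(sym) < 2:
        raise ValueError(f"need >= 2 symmetric expressed pairs, got {len(sym)}")
    return unpaired_t_test(
        sym["left_sum"].to_numpy(float),
        sym["right_sum"].to_numpy(float),
        variant=variant,
        labels=("Similar_left", "Similar_right"),
    )
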