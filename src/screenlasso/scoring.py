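"""PCQ scoring: item responses -> subscale and total scores.

The negative-consequence form of the Psychological Consequences of
Screening Questionnaire (PCQ) is scored here as a plain item sum: each
item is answered 0-3, the emotional subscale has 5 items (0-15), the
physical subscale 4 items (0-12) and the social subscale 3 items (0-9);
the total is the sum of the three subscales (0-36). The 5/4/3 item split
is an assumption derived from the subscale maxima under 0-3 item scoring
and can be overridden via ``item_counts``.

Missing items are handled by ``missing_rule``:

``"complete"`` (default)
    any missing item renders the whole case missing (no prorating);
``"prorate"``
    missing items are replaced by the mean of the answered items of the
    same subscale provided at least half of them are answered, and the
    prorated sum is rounded to the nearest integer; otherwise the case
    is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["PcqItemResponse", "PcqScores", "score_pcq", "ITEM_COUNTS"]

#: default items per subscale (emotional, physical, social)
ITEM_COUNTS = {"emotional": 5, "physical": 4, "social": 3}

_ITEM_MAX = 3


@dataclass
class PcqItemResponse:
    """Raw 0-3 item answers for one respondent; ``None``/NaN marks a skip."""

    emotional_items: Sequence[Optional[float]]
    physical_items: Sequence[Optional[float]]
    social_items: Sequence[Optional[float]]
    respondent: str = ""


@dataclass(frozen=True)
class PcqScores:
    """Scored PCQ scales; ``total == emotional + physical + social``."""

    total: int
    emotional: int
    physical: int
    social: int


def _score_subscale(
    items: Sequence[Optional[float]],
    n_items: int,
    subscale: str,
    missing_rule: str,
    respondent: str,
) -> Optional[int]:
    arr = np.array([np.nan if v is None else float(v) for v in items], dtype=float)
    if arr.shape[0] != n_items:
        raise ValueError(
            f"{subscale} subscale expects {n_items} items, got {arr.shape[0]}"
            + (f" (respondent {respondent!r})" if respondent else "")
        )
    answered = arr[~np.isnan(arr)]
    bad = answered[(answered < 0) | (answered > _ITEM_MAX) | (answered != np.round(answered))]
    if bad.size:
        raise ValueError(
            f"invalid {subscale} item value {bad[0]!r}"
            + (f" for respondent {respondent!r}" if respondent else "")
            + f": items must be integers in [0, {_ITEM_MAX}]"
        )
    n_missing = n_items - answered.size
    if n_missing == 0:
        return int(answered.sum())
    if missing_rule == "complete":
        return None
    if missing_rule == "prorate":
        if answered.size * 2 < n_items:
            return None
        return int(np.rint(answered.mean() * n_items))
    raise ValueError(f"unknown missing_rule {missing_rule!r}")


def score_pcq(
    resp: PcqItemResponse,
    missing_rule: str = "complete",
    item_counts: dict[str, int] = ITEM_COUNTS,
) -> Optional[PcqScores]:
    """Score one PCQ response; returns ``None`` if any scale is missing."""
    parts = {}
    for subscale, items in (
        ("emotional", resp.emotional_items),
        ("physical", resp.physical_items),
        ("social", resp.social_items),
    ):
        score = _score_subscale(
            items, item_counts[subscale], subscale, missing_rule, resp.respondent
        )
        if score is None:
            return None
        parts[subscale] = score
    return PcqScores(total=sum(parts.values()), **parts)
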