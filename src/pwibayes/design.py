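"""Factorial trial design for picture-word interference experiments.

A participant names each picture once under every distractor condition, so
the experimental trial list is the full item x condition factorial. The
standard design in this package is 22 pictures x 4 distractor conditions
(neutral XXX, unrelated, semantically related, phonologically related) = 88
experimental trials per participant, optionally preceded by practice trials
that never enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical distractor-condition labels, in within-participant order.
DEFAULT_CONDITIONS: tuple[str, ...] = ("neutral", "unrelated", "related", "phonological")

#: Default number of distinct pictures.
DEFAULT_N_ITEMS: int = 22


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one participant's trial list.

    Parameters
    ----------
    n_items
        Number of distinct pictures; each appears once per condition.
    conditions
        Ordered distractor-condition labels.
    n_practice
        Practice trials preceding the experimental block (excluded from
        analysis and from :attr:`n_trials`).
    presentations_per_item_condition
        Times each (item, condition) pair is shown; fixed at 1 in the
        standard design.
    """

    n_items: int = DEFAULT_N_ITEMS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_practice: int = 7
    presentations_per_item_condition: int = 1
    item_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 distractor conditions")
        if len(set(self.conditions)) != len(self.conditions):
            dupes = sorted({c for c in self.conditions if list(self.conditions).count(c) > 1})
            raise ValueError(f"duplicate condition labels: {dupes}")
        if self.presentations_per_item_condition != 1:
            raise ValueError("presentations_per_item_condition is fixed at 1")
        if self.n_practice < 0:
            raise ValueError("n_practice must be >= 0")
        object.__setattr__(
            self, "item_ids", tuple(f"item{i + 1:02d}" for i in range(self.n_items))
        )

    @property
    def n_trials(self) -> int:
        """Experimental trials per participant (practice excluded)."""
        return self.n_items * len(self.conditions) * self.presentations_per_item_condition

    def trial_list(self, rng: np.random.Generator | None = None) -> list[tuple[str, str]]:
        """Full factorial (item_id, condition) list, optionally shuffled.

        Trial order is cosmetic for every analysis in this package (medians
        are order-insensitive), so shuffling only makes simulated logs look
        like real session logs.
        """
        trials = [(item, cond) for item in self.item_ids for cond in self.conditions]
        if rng is not None:
            order = rng.permutation(len(trials))
            trials = [trials[i] for i in order]
        return trials


def build_design(
    n_items: int = DEFAULT_N_ITEMS,
    conditions: tuple[str, ...] | list[str] = DEFAULT_CONDITIONS,
    n_practice: int = 7,
) -> DesignSpec:
    """Construct the factorial item x condition design.

    >>> build_design().n_trials
    88
    """
    return DesignSpec(n_items=n_items, conditions=tuple(conditions), n_practice=n_practice)
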